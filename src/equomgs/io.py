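"""Readers and writers for the pipeline's on-disk formats.

Genomes travel as FASTA (one file per genome, multi-contig allowed) with a
tab-separated metadata table; alignment records, gene catalogs, MGS models,
coverage tables, profiles and result tables are all TSV; dendrograms are
Newick.  A SAM adapter extracts alignment identity from mapped records.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genomics import AniMatrix, Dendrogram, GenomeRecord
from .pathway import ProteinQuery
from .profiling import AlignmentRecord, MgsModel

GENOME_METADATA_COLUMNS = [
    "genome_id",
    "source",
    "completeness",
    "contamination",
    "host_species",
    "geography",
]


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

def write_genomes(genomes: Iterable[GenomeRecord], outdir: str) -> str:
    """Write one FASTA per genome plus a metadata TSV; returns the TSV path."""
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for g in genomes:
        records = [
            SeqRecord(Seq(c), id=f"{g.genome_id}_c{i}", description="")
            for i, c in enumerate(g.contigs)
        ]
        SeqIO.write(records, os.path.join(outdir, f"{g.genome_id}.fasta"), "fasta")
        rows.append(
            {
                "genome_id": g.genome_id,
                "source": g.source,
                "completeness": g.completeness,
                "contamination": g.contamination,
                "host_species": g.host_species,
                "geography": g.geography,
            }
        )
    path = os.path.join(outdir, "genome_metadata.tsv")
    pd.DataFrame(rows, columns=GENOME_METADATA_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_genomes(indir: str) -> list[GenomeRecord]:
    """Read genomes written by :func:`write_genomes` (FASTA dir + metadata TSV)."""
    meta_path = os.path.join(indir, "genome_metadata.tsv")
    if not os.path.exists(meta_path):
        raise FileNotFoundError(f"missing metadata table: {meta_path}")
    meta = pd.read_csv(meta_path, sep="\t")
    genomes = []
    for _, row in meta.iterrows():
        fasta = os.path.join(indir, f"{row.genome_id}.fasta")
        if not os.path.exists(fasta):
            raise FileNotFoundError(f"missing genome FASTA: {fasta}")
        contigs = [str(rec.seq) for rec in SeqIO.parse(fasta, "fasta")]
        genomes.append(
            GenomeRecord(
                genome_id=str(row.genome_id),
                contigs=contigs,
                source=str(row.source),
                completeness=None if pd.isna(row.completeness) else float(row.completeness),
                contamination=None if pd.isna(row.contamination) else float(row.contamination),
                host_species=str(row.host_species),
                geography=None if pd.isna(row.geography) else str(row.geography),
            )
        )
    return genomes


def read_protein_queries(path: str) -> list[ProteinQuery]:
    """Protein queries from FASTA; the role is the first header token."""
    queries = []
    for rec in SeqIO.parse(path, "fasta"):
        parts = rec.description.split()
        accession = parts[1] if len(parts) > 1 else rec.id
        queries.append(ProteinQuery(role=rec.id, accession=accession, sequence=str(rec.seq)))
    return queries


def write_protein_queries(queries: Iterable[ProteinQuery], path: str) -> None:
    records = [
        SeqRecord(Seq(q.sequence), id=q.role, description=q.accession) for q in queries
    ]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# alignment records / catalog / MGS model
# ---------------------------------------------------------------------------

def write_alignments(records: Iterable[AlignmentRecord], path: str) -> None:
    """TSV dialect: one candidate per row (read_id, read_length, gene_id, identity)."""
    rows = [
        {"read_id": r.read_id, "read_length": r.read_length, "gene_id": g, "identity": ident}
        for r in records
        for g, ident in r.candidates
    ]
    pd.DataFrame(rows, columns=["read_id", "read_length", "gene_id", "identity"]).to_csv(
        path, sep="\t", index=False
    )


def read_alignments(path: str) -> list[AlignmentRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for (rid, rlen), grp in df.groupby(["read_id", "read_length"], sort=False):
        records.append(
            AlignmentRecord(
                read_id=str(rid),
                read_length=int(rlen),
                candidates=[(str(g), float(i)) for g, i in zip(grp.gene_id, grp.identity)],
            )
        )
    return records


def read_alignments_sam(path: str) -> list[AlignmentRecord]:
    """Adapter: alignment records from SAM, identity from the NM tag.

    Identity = 100 * (1 - NM / aligned_length); unmapped reads are skipped;
    multiple alignments of one read become its candidate list.
    """
    import pysam

    by_read: dict[str, AlignmentRecord] = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.reference_name is None:
                continue
            alen = aln.query_alignment_length
            if not alen:
                continue
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            identity = 100.0 * (1.0 - nm / alen)
            cand = (aln.reference_name, max(0.0, identity))
            if aln.query_name in by_read:
                by_read[aln.query_name].candidates.append(cand)
            else:
                by_read[aln.query_name] = AlignmentRecord(
                    aln.query_name, aln.query_length or alen, [cand]
                )
    return list(by_read.values())


def write_catalog(catalog: dict[str, int], path: str) -> None:
    pd.DataFrame(
        {"gene_id": list(catalog), "length": list(catalog.values())}
    ).to_csv(path, sep="\t", index=False)


def read_catalog(path: str) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    if (df["length"] <= 0).any():
        raise ValueError("catalog contains non-positive gene lengths")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in catalog")
    return dict(zip(df.gene_id.astype(str), df.length.astype(int)))


def write_mgs_model(model: MgsModel, path: str) -> None:
    markers = set(model.marker_genes)
    pd.DataFrame(
        {
            "mgs_id": model.mgs_id,
            "gene_id": model.all_genes,
            "is_marker": [int(g in markers) for g in model.all_genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_mgs_model(path: str) -> MgsModel:
    df = pd.read_csv(path, sep="\t")
    (mgs_id,) = df["mgs_id"].unique()
    return MgsModel(
        mgs_id=str(mgs_id),
        marker_genes=[str(g) for g in df.loc[df.is_marker == 1, "gene_id"]],
        all_genes=[str(g) for g in df["gene_id"]],
    )


# ---------------------------------------------------------------------------
# tables and trees
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label or df.index.name or "id")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_ani_matrix(matrix: AniMatrix, path: str) -> None:
    pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids).to_csv(
        path, sep="\t", index_label="genome_id"
    )


def read_ani_matrix(path: str) -> AniMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AniMatrix(ids=[str(i) for i in df.index], values=df.to_numpy(dtype=float))


def write_newick(dendrogram: Dendrogram, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(dendrogram.to_newick() + "\n")
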