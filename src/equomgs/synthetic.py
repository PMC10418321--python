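"""Synthetic data with planted ground truth for every pipeline stage.

Three generators cover the study designs the pipeline analyses:

* genome populations with a planted two-phylogroup ANI structure (a common
  ancestor split at a between-group divergence, members radiating at a
  within-group divergence), phylogroup-linked equol-operon carriage and
  host-geography profiles;
* cohort sample x gene coverage tables with a zero-inflated lognormal
  abundance model -- per-group carriage probability (prevalence) times a
  lognormal depth for carriers -- spread over marker genes with Poisson read
  sampling and multiplicative marker noise;
* read-to-gene alignment record sets with a controlled multi-mapping rate,
  the fixture for the two-step counting procedure.

All generators are pure functions of their spec and seed.  The four pathway
protein queries used for operon planting are synthetic stand-ins of
realistic lengths (the real proteins are referenced by accession only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .genomics import GenomeRecord
from .pathway import ROLES, ProteinQuery
from .profiling import AlignmentRecord, MgsModel

__all__ = [
    "GEOGRAPHIES",
    "GenomePopulationSpec",
    "SyntheticGenomeSet",
    "CohortSpec",
    "ReadAssignmentSet",
    "make_base_genome",
    "mutate_genome",
    "plant_operon",
    "default_pathway_proteins",
    "simulate_genome_population",
    "simulate_cohort",
    "cohort_mgs_model",
    "simulate_read_assignments",
]

GEOGRAPHIES = ("Asia", "Europe", "North America", "other")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_DECODE = {65: 0, 67: 1, 71: 2, 84: 3}

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _TABLE11.forward_table.items():
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
for _aa in _AA_TO_CODONS:
    _AA_TO_CODONS[_aa].sort()
_AA_LETTERS = sorted(_AA_TO_CODONS)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# sequence-level generators
# ---------------------------------------------------------------------------

def make_base_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """Random genome of the given length and expected GC fraction."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def _encode_acgt(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.zeros(len(arr), dtype=np.uint8)
    for byte, code in _DECODE.items():
        out[arr == byte] = code
    return out


def mutate_genome(
    base: str, divergence: float, indel_rate: float = 0.0, seed: int = 0
) -> tuple[str, float]:
    """Substitute each site independently with probability ``divergence``.

    Substitutions always change the base (uniform over the other three).
    Returns the mutated sequence and the exact realized substituted-site
    fraction (computed before indels).  Indels, applied after substitutions,
    are single events of 1-3 bp, half deletions and half insertions.
    """
    if not (0.0 <= divergence < 0.25):
        raise ValueError("divergence must be in [0, 0.25)")
    if indel_rate < 0:
        raise ValueError("indel_rate must be non-negative")
    rng = np.random.default_rng(seed)
    arr = _encode_acgt(base)
    n = len(arr)
    mask = rng.random(n) < divergence
    shifts = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
    arr = arr.copy()
    arr[mask] = (arr[mask] + shifts) % 4
    realized = float(mask.sum()) / n
    seq = _BASES[arr].tobytes().decode("ascii")
    if indel_rate > 0:
        events = np.nonzero(rng.random(n) < indel_rate)[0]
        pieces = []
        prev = 0
        for pos in events:
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # deletion
                pieces.append(seq[prev:pos])
                prev = min(pos + size, n)
            else:  # insertion
                ins = _BASES[rng.integers(0, 4, size=size)].tobytes().decode("ascii")
                pieces.append(seq[prev:pos] + ins)
                prev = pos
        pieces.append(seq[prev:])
        seq = "".join(pieces)
    return seq, realized


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform seeded codon choice per amino acid, bacterial code."""
    codons = []
    for aa in protein:
        options = _AA_TO_CODONS[aa]
        codons.append(options[int(rng.integers(len(options)))])
    return "".join(codons)


def _mutate_protein(protein: str, aa_divergence: float, rng: np.random.Generator) -> str:
    out = list(protein)
    for i, aa in enumerate(out):
        if rng.random() < aa_divergence:
            choices = [a for a in _AA_LETTERS if a != aa]
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def plant_operon(
    genome: str,
    proteins: list[ProteinQuery],
    aa_divergence: float = 0.0,
    seed: int = 0,
) -> tuple[str, list[dict]]:
    """Insert reverse-translated (optionally diverged) pathway genes.

    Each protein is mutated at the amino-acid level with per-residue
    probability ``aa_divergence``, reverse-translated with seeded uniform
    codon choice, flanked by stop codons, and spliced into the genome at a
    seeded position on a seeded strand.  Positions are non-overlapping.
    Returns the new sequence and the insertion records.
    """
    if not (0.0 <= aa_divergence <= 1.0):
        raise ValueError("aa_divergence must be in [0, 1]")
    if not proteins:
        return genome, []
    rng = np.random.default_rng(seed)
    cds_list = []
    for q in proteins:
        mutated = _mutate_protein(q.sequence, aa_divergence, rng)
        cds = "TAA" + _reverse_translate(mutated, rng) + "TAA"
        cds_list.append((q.role, cds))
    total = sum(len(c) for _, c in cds_list)
    if len(genome) < total:
        raise ValueError("genome too short to host all pathway genes")
    positions = np.sort(rng.choice(len(genome), size=len(cds_list), replace=False))
    inserts = []
    # splice from the right so earlier positions stay valid
    seq = genome
    for (role, cds), pos in sorted(
        zip(cds_list, positions), key=lambda t: -int(t[1])
    ):
        strand = "+" if rng.random() < 0.5 else "-"
        payload = cds if strand == "+" else _revcomp(cds)
        seq = seq[: int(pos)] + payload + seq[int(pos):]
        inserts.append(
            {"role": role, "position": int(pos), "strand": strand, "length": len(payload)}
        )
    return seq, sorted(inserts, key=lambda r: r["position"])


_SYNTHETIC_PROTEIN_LENGTHS = {"dzr": 450, "ddr": 300, "tdr": 380, "racemase": 250}


def default_pathway_proteins(seed: int = 7) -> list[ProteinQuery]:
    """Synthetic stand-ins for the four equol-pathway proteins.

    Random amino-acid sequences of realistic enzyme lengths, generated from a
    fixed seed so they are identical across calls; real counterparts exist
    only as database accessions and are not bundled.
    """
    rng = np.random.default_rng(seed)
    queries = []
    for role in ROLES:
        length = _SYNTHETIC_PROTEIN_LENGTHS[role]
        seq = "".join(
            _AA_LETTERS[int(i)] for i in rng.integers(len(_AA_LETTERS), size=length)
        )
        if seq[0] != "M":
            seq = "M" + seq[1:]
        queries.append(ProteinQuery(role=role, accession=f"SYN_{role}", sequence=seq))
    return queries


# ---------------------------------------------------------------------------
# genome population
# ---------------------------------------------------------------------------

@dataclass
class GenomePopulationSpec:
    """Parameters of a planted multi-phylogroup genome population."""

    n_genomes: int = 20
    genome_length: int = 100_000
    n_phylogroups: int = 2
    within_divergence: float = 0.02
    between_divergence: float = 0.09
    operon_carriage: tuple = (0.60, 0.088)
    geography_profile: tuple = (
        {"Asia": 0.82, "Europe": 0.08, "North America": 0.05, "other": 0.05},
        {"Asia": 0.04, "Europe": 0.55, "North America": 0.37, "other": 0.04},
    )
    indel_rate: float = 0.0
    gc: float = 0.64
    operon_aa_divergence: float = 0.0
    isolate_fraction: float = 11 / 165
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < self.n_phylogroups or self.n_phylogroups < 1:
            raise ValueError("need at least one genome per phylogroup")
        if not (0.0 <= self.within_divergence < self.between_divergence < 0.25):
            raise ValueError("require 0 <= within < between < 0.25")
        if len(self.operon_carriage) != self.n_phylogroups:
            raise ValueError("operon_carriage must have one entry per phylogroup")
        if any(not (0.0 <= p <= 1.0) for p in self.operon_carriage):
            raise ValueError("carriage probabilities must be in [0, 1]")
        if len(self.geography_profile) != self.n_phylogroups:
            raise ValueError("geography_profile must have one entry per phylogroup")
        for prof in self.geography_profile:
            if abs(sum(prof.values()) - 1.0) > 1e-9:
                raise ValueError("geography profile must sum to 1")


@dataclass
class SyntheticGenomeSet:
    """Genomes plus the planted truths the tests score against."""

    genomes: list[GenomeRecord]
    truth_phylogroup: dict[str, int]
    truth_producer: dict[str, bool]
    realized_divergence: pd.DataFrame

    def __post_init__(self) -> None:
        ids = [g.genome_id for g in self.genomes]
        if sorted(ids) != sorted(self.truth_phylogroup) or sorted(ids) != sorted(
            self.truth_producer
        ):
            raise ValueError("truth maps must cover every genome exactly once")
        rd = self.realized_divergence
        if not np.allclose(rd.values, rd.values.T) or not np.allclose(
            np.diag(rd.values), 0.0
        ):
            raise ValueError("realized_divergence must be symmetric with zero diagonal")


def _base_rate_for_pairwise(target: float) -> float:
    """Per-lineage substitution rate so two independently mutated copies of
    an ancestor differ at the target pairwise fraction.

    Pairwise differing probability for per-lineage rate r is
    2 r (1 - r) + (2/3) r^2 (two independent hits coincide 1/3 of the time).
    """
    if target == 0:
        return 0.0
    # solve -(4/3) r^2 + 2 r - target = 0 for the smaller root
    disc = 4.0 - (16.0 / 3.0) * target
    return (2.0 - math.sqrt(disc)) / (8.0 / 3.0)


def simulate_genome_population(
    spec: GenomePopulationSpec,
    proteins: list[ProteinQuery] | None = None,
) -> SyntheticGenomeSet:
    """Generate a genome population with planted phylogroups and operons.

    One base genome per phylogroup descends from a common ancestor such that
    base-base pairwise divergence matches ``between_divergence``; members
    descend from their base at ``within_divergence``.  Operons are planted
    per-phylogroup with the carriage probabilities; geography, host species
    and MAG QC values are drawn from fixed profiles.
    """
    rng = np.random.default_rng(spec.seed)
    if proteins is None:
        proteins = default_pathway_proteins()
    ancestor = make_base_genome(
        spec.genome_length, spec.gc, seed=int(rng.integers(2**31 - 1))
    )
    r_base = _base_rate_for_pairwise(spec.between_divergence)
    bases = [
        mutate_genome(ancestor, r_base, 0.0, seed=int(rng.integers(2**31 - 1)))[0]
        for _ in range(spec.n_phylogroups)
    ]
    # round-robin assignment of genomes to phylogroups
    membership = [i % spec.n_phylogroups for i in range(spec.n_genomes)]
    genomes: list[GenomeRecord] = []
    truth_pg: dict[str, int] = {}
    truth_prod: dict[str, bool] = {}
    sub_sequences: list[str] = []
    counters = [0] * spec.n_phylogroups
    for pg in membership:
        counters[pg] += 1
        gid = f"pg{pg + 1}_{counters[pg]:03d}"
        seq, _realized = mutate_genome(
            bases[pg],
            spec.within_divergence,
            0.0,
            seed=int(rng.integers(2**31 - 1)),
        )
        sub_sequences.append(seq)
        carrier = bool(rng.random() < spec.operon_carriage[pg])
        final_seq = seq
        if spec.indel_rate > 0:
            final_seq, _ = mutate_genome(
                final_seq, 0.0, spec.indel_rate, seed=int(rng.integers(2**31 - 1))
            )
        if carrier:
            final_seq, _ = plant_operon(
                final_seq,
                proteins,
                spec.operon_aa_divergence,
                seed=int(rng.integers(2**31 - 1)),
            )
        prof = spec.geography_profile[pg]
        geography = rng.choice(list(prof), p=list(prof.values()))
        is_isolate = bool(rng.random() < spec.isolate_fraction)
        host = rng.choice(
            ["human", "mouse", "rat"], p=[154 / 165, 10 / 165, 1 / 165]
        )
        genomes.append(
            GenomeRecord(
                genome_id=gid,
                contigs=[final_seq],
                source="isolate" if is_isolate else "MAG",
                completeness=100.0 if is_isolate else float(rng.uniform(80, 100)),
                contamination=0.0 if is_isolate else float(rng.uniform(0, 5)),
                host_species=str(host),
                geography=str(geography),
            )
        )
        truth_pg[gid] = pg
        truth_prod[gid] = carrier
    # realized pairwise divergence on the substitution-only sequences
    ids = [g.genome_id for g in genomes]
    enc = np.stack([_encode_acgt(s) for s in sub_sequences])
    n = len(ids)
    rd = np.zeros((n, n))
    for i in range(n):
        diff = (enc[i + 1:] != enc[i]).mean(axis=1)
        rd[i, i + 1:] = diff
        rd[i + 1:, i] = diff
    return SyntheticGenomeSet(
        genomes=genomes,
        truth_phylogroup=truth_pg,
        truth_producer=truth_prod,
        realized_divergence=pd.DataFrame(rd, index=ids, columns=ids),
    )


# ---------------------------------------------------------------------------
# cohort coverage tables
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Zero-inflated lognormal cohort model across ordered severity groups.

    Defaults emulate a healthy-vs-cirrhosis comparison: group sizes 102/112
    with carriage probabilities 0.57/0.16 and a roughly one-decade drop in
    carrier sequencing depth.
    """

    groups: tuple = ("healthy", "cirrhosis")
    n_per_group: tuple = (102, 112)
    prevalence_per_group: tuple = (0.57, 0.16)
    log10_abundance_mean: tuple = (-1.0, -1.8)
    log10_abundance_sd: tuple = (0.7, 0.7)
    n_marker_genes: int = 100
    n_background_genes: int = 200
    gene_length_range: tuple = (500, 1500)
    read_length: int = 100
    marker_noise_sd: float = 0.5
    background_log10_mean: float = -1.5
    background_log10_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("groups must be nonempty")
        lengths = {
            len(self.n_per_group),
            len(self.prevalence_per_group),
            len(self.log10_abundance_mean),
            len(self.log10_abundance_sd),
        }
        if lengths != {len(self.groups)}:
            raise ValueError("per-group parameter lengths must match groups")
        if any(not (0.0 <= p <= 1.0) for p in self.prevalence_per_group):
            raise ValueError("prevalences must be in [0, 1]")
        if self.n_marker_genes < 10:
            raise ValueError("need >= 10 marker genes for the 10% rule")


def cohort_mgs_model(spec: CohortSpec, mgs_id: str = "msp_synth") -> MgsModel:
    """The MGS model (marker-gene list) matching a simulated cohort table."""
    markers = [f"{mgs_id}_marker_{i:03d}" for i in range(spec.n_marker_genes)]
    return MgsModel(mgs_id=mgs_id, marker_genes=markers, species="synthetic species")


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a sample x gene coverage table with planted carriage truth.

    Returns (coverage table, sample metadata, truth table).  Carriers draw an
    MGS depth from the group's lognormal and spread it over the marker genes
    through per-marker multiplicative noise and Poisson read sampling;
    non-carriers have zero on every marker.  Every carrier is guaranteed at
    least ceil(0.1 * n_markers) nonzero markers, so the detection rule can
    never misclassify a planted carrier.
    """
    rng = np.random.default_rng(spec.seed)
    model = cohort_mgs_model(spec)
    markers = model.marker_genes
    background = [f"bg_{i:04d}" for i in range(spec.n_background_genes)]
    genes = markers + background
    lo, hi = spec.gene_length_range
    gene_lengths = rng.integers(lo, hi + 1, size=len(genes)).astype(float)
    rows = []
    meta = []
    truth = []
    min_nonzero = math.ceil(0.1 * spec.n_marker_genes)
    sample_num = 0
    for gi, group in enumerate(spec.groups):
        for _ in range(spec.n_per_group[gi]):
            sid = f"s{sample_num:04d}"
            sample_num += 1
            carrier = bool(rng.random() < spec.prevalence_per_group[gi])
            marker_cov = np.zeros(len(markers))
            depth = 0.0
            if carrier:
                depth = 10.0 ** rng.normal(
                    spec.log10_abundance_mean[gi], spec.log10_abundance_sd[gi]
                )
                noise = np.exp(
                    rng.normal(
                        -spec.marker_noise_sd**2 / 2,
                        spec.marker_noise_sd,
                        size=len(markers),
                    )
                )
                lam = depth * noise * gene_lengths[: len(markers)] / spec.read_length
                reads = rng.poisson(lam).astype(float)
                short = min_nonzero - int((reads > 0).sum())
                if short > 0:  # guarantee the 10% rule holds for carriers
                    zeros = np.nonzero(reads == 0)[0][:short]
                    reads[zeros] = 1.0
                marker_cov = reads * spec.read_length / gene_lengths[: len(markers)]
            bg_depth = 10.0 ** rng.normal(
                spec.background_log10_mean,
                spec.background_log10_sd,
                size=len(background),
            )
            bg_lam = bg_depth * gene_lengths[len(markers):] / spec.read_length
            bg_reads = rng.poisson(bg_lam).astype(float)
            bg_cov = bg_reads * spec.read_length / gene_lengths[len(markers):]
            rows.append(np.concatenate([marker_cov, bg_cov]))
            meta.append({"sample_id": sid, "group": group})
            truth.append(
                {
                    "sample_id": sid,
                    "group": group,
                    "carrier": carrier,
                    "planted_depth": depth,
                }
            )
    index = [m["sample_id"] for m in meta]
    coverage = pd.DataFrame(np.vstack(rows), index=index, columns=genes)
    metadata = pd.DataFrame(meta).set_index("sample_id")
    truth_df = pd.DataFrame(truth).set_index("sample_id")
    return coverage, metadata, truth_df


# ---------------------------------------------------------------------------
# read assignments
# ---------------------------------------------------------------------------

@dataclass
class ReadAssignmentSet:
    """Alignment records with the true origin gene of every read."""

    records: list[AlignmentRecord]
    truth_origin: dict[str, str]

    def __post_init__(self) -> None:
        for rec in self.records:
            origin = self.truth_origin.get(rec.read_id)
            if origin is None:
                raise ValueError(f"read {rec.read_id} missing from truth_origin")
            if origin not in [g for g, _ in rec.candidates]:
                raise ValueError(f"read {rec.read_id}: origin not among candidates")


def simulate_read_assignments(
    catalog: dict[str, int],
    depths: dict[str, float],
    read_length: int = 100,
    multimap_rate: float = 0.0,
    seed: int = 0,
) -> ReadAssignmentSet:
    """Draw Poisson read counts per gene and attach multi-mapping candidates.

    A ``multimap_rate`` fraction of reads receives 1-3 extra candidate genes;
    alignment identities are sampled uniformly in [95, 100].
    """
    if not catalog:
        raise ValueError("empty catalog")
    if not (0.0 <= multimap_rate < 1.0):
        raise ValueError("multimap_rate must be in [0, 1)")
    if any(d < 0 for d in depths.values()):
        raise ValueError("depths must be non-negative")
    rng = np.random.default_rng(seed)
    genes = sorted(catalog)
    records = []
    truth = {}
    read_num = 0
    for gene in genes:
        depth = depths.get(gene, 0.0)
        n_reads = int(rng.poisson(depth))
        for _ in range(n_reads):
            rid = f"r{read_num:07d}"
            read_num += 1
            candidates = [(gene, float(rng.uniform(95, 100)))]
            if len(genes) > 1 and rng.random() < multimap_rate:
                n_extra = int(rng.integers(1, 4))
                others = [g for g in genes if g != gene]
                extra_idx = rng.choice(len(others), size=min(n_extra, len(others)), replace=False)
                for ei in extra_idx:
                    candidates.append((others[int(ei)], float(rng.uniform(95, 100))))
            records.append(AlignmentRecord(rid, read_length, candidates))
            truth[rid] = gene
    return ReadAssignmentSet(records=records, truth_origin=truth)
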