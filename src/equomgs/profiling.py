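"""Gene-level quantification and MGS abundance calls from alignment records.

Pipeline: keep alignments with nucleotide identity >= 95% (intra-species
variability against a non-redundant catalog), optionally subsample reads to a
common depth, count reads per gene with a two-step procedure that first
counts uniquely mapped reads and then distributes each multi-mapped read
across its candidate genes proportionally to those unique counts, convert
counts to coverage depth using gene length and mean read length, and finally
quantify a metagenomic species (MGS) as the mean coverage of its marker
genes -- with the abundance set to null when fewer than 10% of the markers
are seen in a sample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlignmentRecord",
    "MgsModel",
    "filter_alignments",
    "subsample_reads",
    "two_step_count",
    "compute_coverage",
    "mgs_abundance",
    "log10_with_sentinel",
    "profile_sample",
]


@dataclass
class AlignmentRecord:
    """One read and its candidate gene alignments (gene id, identity %)."""

    read_id: str
    read_length: int
    candidates: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError(f"read {self.read_id} has no candidates")
        for _, ident in self.candidates:
            if not (0.0 <= ident <= 100.0):
                raise ValueError(f"identity {ident} outside [0, 100]")


@dataclass
class MgsModel:
    """A metagenomic species as its gene lists.

    ``marker_genes`` are the species-specific core genes whose abundances
    co-vary most tightly (canonically 100); abundance is their mean coverage.
    """

    mgs_id: str
    marker_genes: list[str]
    all_genes: list[str] = field(default_factory=list)
    species: str | None = None
    annotated_fraction: float | None = None

    def __post_init__(self) -> None:
        if not self.marker_genes:
            raise ValueError("marker gene list is empty")
        if len(set(self.marker_genes)) != len(self.marker_genes):
            raise ValueError("duplicate marker genes")
        if not self.all_genes:
            self.all_genes = list(self.marker_genes)
        if not set(self.marker_genes) <= set(self.all_genes):
            raise ValueError("marker_genes must be a subset of all_genes")


def filter_alignments(
    records: Iterable[AlignmentRecord], min_identity: float = 95.0
) -> list[AlignmentRecord]:
    """Keep candidates with identity >= min_identity (boundary inclusive).

    Records whose candidates all fall below the threshold are dropped;
    input order is preserved.
    """
    out = []
    for rec in records:
        kept = [(g, i) for g, i in rec.candidates if i >= min_identity]
        if kept:
            out.append(AlignmentRecord(rec.read_id, rec.read_length, kept))
    return out


def subsample_reads(
    records: Sequence[AlignmentRecord], target_n: int, seed: int
) -> list[AlignmentRecord]:
    """Uniform sample of min(target_n, len(records)) records, without replacement.

    When fewer records than the target are available the input is returned
    unchanged (with a warning): samples below the target depth are kept.
    """
    if target_n < 0:
        raise ValueError("target_n must be non-negative")
    records = list(records)
    if target_n >= len(records):
        if target_n > len(records):
            warnings.warn(
                f"only {len(records)} records available for target {target_n}; keeping all",
                stacklevel=2,
            )
        return records
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(records), size=target_n, replace=False))
    return [records[i] for i in idx]


def two_step_count(records: Iterable[AlignmentRecord]) -> dict[str, float]:
    """Two-step gene counting that handles multi-mapped reads.

    Step 1: each uniquely mapping read adds 1 to its gene.  Step 2: each
    multi-mapped read distributes weight 1 across its candidate genes
    proportionally to the step-1 unique counts; when every candidate has a
    zero unique count the weight splits equally.  Total counts equal the
    number of reads exactly (mass conservation).
    """
    unique: dict[str, float] = {}
    multi: list[AlignmentRecord] = []
    counts: dict[str, float] = {}
    for rec in records:
        genes = [g for g, _ in rec.candidates]
        if len(set(genes)) == 1:
            unique[genes[0]] = unique.get(genes[0], 0.0) + 1.0
        else:
            multi.append(rec)
    counts.update(unique)
    for rec in multi:
        genes = list(dict.fromkeys(g for g, _ in rec.candidates))
        weights = np.array([unique.get(g, 0.0) for g in genes])
        total = weights.sum()
        if total == 0:
            weights = np.full(len(genes), 1.0 / len(genes))
        else:
            weights = weights / total
        for g, w in zip(genes, weights):
            counts[g] = counts.get(g, 0.0) + float(w)
    return counts


def compute_coverage(
    counts: Mapping[str, float],
    catalog: Mapping[str, int],
    mean_read_length: float,
    formula: str = "depth",
) -> dict[str, float]:
    """Convert raw gene counts to coverage.

    ``formula='depth'`` (default) computes mean sequencing depth,
    count x read_length / gene_length; ``formula='normalized'`` computes
    count / (gene_length x read_length).
    """
    if mean_read_length <= 0:
        raise ValueError("mean read length must be positive")
    if formula not in ("depth", "normalized"):
        raise ValueError(f"unknown coverage formula {formula!r}")
    out = {}
    for gene, count in counts.items():
        if gene not in catalog:
            raise KeyError(f"gene {gene!r} missing from catalog")
        length = catalog[gene]
        if length <= 0:
            raise ValueError(f"gene {gene!r} has non-positive length")
        if formula == "depth":
            out[gene] = count * mean_read_length / length
        else:
            out[gene] = count / (length * mean_read_length)
    return out


def mgs_abundance(
    coverage: pd.DataFrame,
    model: MgsModel,
    min_marker_fraction: float = 0.10,
) -> pd.DataFrame:
    """Per-sample MGS abundance, detection flag and marker fraction seen.

    Abundance is the arithmetic mean coverage over ALL marker genes (zeros
    included); if strictly fewer than ``min_marker_fraction`` of the markers
    have coverage > 0 in a sample, the abundance is set to null (0) and the
    species is not detected.  Marker genes absent from the table count as
    zero coverage.
    """
    markers = model.marker_genes
    cov = coverage.reindex(columns=markers, fill_value=0.0).astype(float)
    seen = (cov > 0).sum(axis=1) / len(markers)
    abundance = cov.mean(axis=1)
    abundance[seen < min_marker_fraction] = 0.0
    return pd.DataFrame(
        {
            "abundance": abundance,
            "detected": abundance > 0,
            "marker_fraction_seen": seen,
        }
    )


def log10_with_sentinel(profile: pd.DataFrame, sentinel: float = -10.0) -> pd.Series:
    """log10 abundance with an artificial sentinel for undetected samples.

    The sentinel (default -10, the "M10" convention on the log10 scale) must
    lie strictly below every finite transformed value; if it does not, a
    warning is emitted and the sentinel is lowered.
    """
    detected = profile["detected"].astype(bool)
    out = pd.Series(float(sentinel), index=profile.index, name="log10_abundance")
    if detected.any():
        logs = np.log10(profile.loc[detected, "abundance"].astype(float))
        finite_min = float(logs.min())
        if sentinel >= finite_min:
            new_sentinel = math.floor(finite_min - 1.0)
            warnings.warn(
                f"sentinel {sentinel} not below minimum log10 abundance "
                f"{finite_min:.3f}; lowered to {new_sentinel}",
                stacklevel=2,
            )
            out[:] = float(new_sentinel)
        out[detected] = logs
    return out


def profile_sample(
    records: Iterable[AlignmentRecord],
    catalog: Mapping[str, int],
    min_identity: float = 95.0,
    subsample_to: int | None = None,
    seed: int = 0,
    formula: str = "depth",
) -> tuple[dict[str, float], float]:
    """Filter, optionally subsample, count and convert one sample's alignments.

    Returns (per-gene coverage, mean read length of retained reads).
    """
    kept = filter_alignments(records, min_identity=min_identity)
    if subsample_to is not None:
        kept = subsample_reads(kept, subsample_to, seed)
    if not kept:
        return {}, float("nan")
    mean_rl = float(np.mean([r.read_length for r in kept]))
    counts = two_step_count(kept)
    return compute_coverage(counts, catalog, mean_rl, formula=formula), mean_rl
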