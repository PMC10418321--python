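"""Run configuration: the audited single source of every numeric threshold.

A run is configured by one JSON document with a versioned schema.  Every
threshold the pipeline applies anywhere -- the 95% alignment identity filter,
the 10% marker rule, the 95% ANI species cutoff, the 90/90 protein detection
thresholds, the 75% producer rule, the 80/5 genome QC bounds -- lives here,
is range-checked on load, and round-trips losslessly through serialization.
Seeds are mandatory: no stage draws silent entropy.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

__all__ = ["RunConfig", "validate_config", "config_hash"]

COHORT_KEYS = {
    "groups",
    "n_per_group",
    "prevalence_per_group",
    "log10_abundance_mean",
    "log10_abundance_sd",
    "n_marker_genes",
    "n_background_genes",
    "gene_length_range",
    "read_length",
    "marker_noise_sd",
    "background_log10_mean",
    "background_log10_sd",
    "seed",
}

GENOME_POPULATION_KEYS = {
    "n_genomes",
    "genome_length",
    "n_phylogroups",
    "within_divergence",
    "between_divergence",
    "operon_carriage",
    "geography_profile",
    "indel_rate",
    "gc",
    "operon_aa_divergence",
    "isolate_fraction",
    "seed",
}

STAGES = (
    "simulate",
    "profile",
    "associate",
    "simulate_genomes",
    "qc",
    "ani",
    "cluster",
    "nmds",
    "equol",
    "genome_associate",
)


@dataclass
class RunConfig:
    """All thresholds, seeds and stage selections of one pipeline run."""

    seed: int
    outdir: str = "results"
    stages: tuple = STAGES
    schema_version: int = 1
    # quantification
    min_identity: float = 95.0
    min_marker_fraction: float = 0.10
    m10_sentinel: float = -10.0
    coverage_formula: str = "depth"  # depth | normalized
    sharing: str = "single_pass"
    subsample_target: int | None = None
    # genome population
    qc_min_completeness: float = 80.0
    qc_max_contamination: float = 5.0
    ani_cutoff: float = 95.0
    fragment_length: int = 3000
    kmer_size: int = 16
    min_fragment_kmer_hits: int = 5
    ani_floor: float = 70.0
    nmds_restarts: int = 8
    nmds_max_iter: int = 500
    nmds_tol: float = 1e-6
    # pathway detection
    protein_min_identity: float = 90.0
    protein_min_coverage: float = 90.0
    producer_min_fraction: float = 0.75
    # statistics
    alpha: float = 0.05
    adjust: str = "fdr_bh"
    combine: str = "both"  # both | either | fisher_combination
    # synthetic-data overrides (keyword arguments of the two spec dataclasses)
    cohort: dict = field(default_factory=dict)
    genome_population: dict = field(default_factory=dict)
    # optional external inputs
    input_genomes: str | None = None
    input_proteins: str | None = None
    input_coverage: str | None = None
    input_metadata: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


_RANGES = {
    "min_identity": (0.0, 100.0),
    "min_marker_fraction": (0.0, 1.0),
    "ani_cutoff": (0.0, 100.0),
    "protein_min_identity": (0.0, 100.0),
    "protein_min_coverage": (0.0, 100.0),
    "producer_min_fraction": (0.0, 1.0),
    "qc_min_completeness": (0.0, 100.0),
    "qc_max_contamination": (0.0, 100.0),
    "ani_floor": (0.0, 100.0),
    "alpha": (0.0, 1.0),
}


def validate_config(raw: str | dict) -> RunConfig:
    """Parse and validate a JSON config; defaults fill missing keys.

    Unknown keys and out-of-range thresholds are rejected.  An empty document
    yields full defaults (seed 0).
    """
    if isinstance(raw, str):
        raw = json.loads(raw) if raw.strip() else {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a JSON object")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    raw = dict(raw)
    raw.setdefault("seed", 0)
    if "stages" in raw:
        bad = set(raw["stages"]) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        raw["stages"] = tuple(raw["stages"])
    for sub, keys in (("cohort", COHORT_KEYS), ("genome_population", GENOME_POPULATION_KEYS)):
        if sub in raw:
            bad = set(raw[sub]) - keys
            if bad:
                raise ValueError(f"unknown {sub} keys: {sorted(bad)}")
    cfg = RunConfig(**raw)
    for name, (lo, hi) in _RANGES.items():
        value = getattr(cfg, name)
        if not (lo <= value <= hi):
            raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
    if cfg.coverage_formula not in ("depth", "normalized"):
        raise ValueError(f"unknown coverage_formula {cfg.coverage_formula!r}")
    if cfg.combine not in ("both", "either", "fisher_combination"):
        raise ValueError(f"unknown combine rule {cfg.combine!r}")
    if cfg.fragment_length <= cfg.kmer_size:
        raise ValueError("fragment_length must exceed kmer_size")
    if not isinstance(cfg.seed, int):
        raise ValueError("seed must be an integer")
    return cfg


def config_hash(config: RunConfig) -> str:
    """Stable hash of the canonical JSON form (reproducibility audit)."""
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]
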