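"""End-to-end orchestration of the synthetic-data analysis pipeline.

Two stage chains run independently, sharing one config and seed:

* cohort chain: ``simulate`` -> ``profile`` -> ``associate`` -- coverage
  table to MGS profile to prevalence/abundance statistics;
* genome chain: ``simulate_genomes`` -> ``qc`` -> ``ani`` -> ``cluster`` ->
  ``nmds`` -> ``equol`` -> ``genome_associate`` -- assemblies to
  genomospecies, ordination, producer genotypes and metadata associations.

Every artifact is written as TSV (or Newick for the dendrogram) under the
config's output directory, and a RunReport summarises counts and test
results per stage.  Identical config + seed gives identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io
from .config import RunConfig, config_hash
from .genomics import build_ani_matrix, cut_clusters, metadata_association, nmds, qc_filter, upgma
from .pathway import genotype_genome
from .profiling import log10_with_sentinel, mgs_abundance
from .stats import (
    chi_squared,
    fisher_exact,
    kruskal_wallis,
    mann_whitney_auc,
    prevalence_by_group,
)
from .synthetic import (
    CohortSpec,
    GenomePopulationSpec,
    cohort_mgs_model,
    default_pathway_proteins,
    simulate_cohort,
    simulate_genome_population,
)

__all__ = ["RunReport", "run_pipeline", "render_report"]


@dataclass
class RunReport:
    """Per-stage summaries of one pipeline run."""

    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)  # figure-panel style tables


def _result_row(result, comparison: str) -> dict:
    return {
        "comparison": comparison,
        "method": result.method,
        "statistic": result.statistic,
        "df": result.df if result.df is not None else "",
        "p_value": result.p_value,
        "effect": result.effect if result.effect is not None else "",
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in dependency order and write artifacts."""
    from . import __version__

    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        fh.write(config.to_json())
    report = RunReport(config_hash=config_hash(config), version=__version__)
    stages = set(config.stages)

    # ------------------------------------------------------------- cohort
    coverage = metadata = None
    cohort_spec = None
    if "simulate" in stages:
        kwargs = dict(config.cohort)
        kwargs.setdefault("seed", config.seed)
        cohort_spec = CohortSpec(**kwargs)
        coverage, metadata, truth = simulate_cohort(cohort_spec)
        io.write_table(coverage, os.path.join(outdir, "coverage.tsv"), "sample_id")
        io.write_table(metadata, os.path.join(outdir, "sample_metadata.tsv"))
        io.write_table(truth, os.path.join(outdir, "truth_cohort.tsv"))
        io.write_mgs_model(cohort_mgs_model(cohort_spec), os.path.join(outdir, "mgs_model.tsv"))
        report.stages["simulate"] = {
            "n_samples": len(coverage),
            "n_genes": coverage.shape[1],
            "groups": list(cohort_spec.groups),
        }
    elif config.input_coverage:
        coverage = io.read_table(config.input_coverage)
        metadata = io.read_table(config.input_metadata) if config.input_metadata else None

    profile = None
    if "profile" in stages:
        if coverage is None:
            raise ValueError("profile stage needs a coverage table (enable simulate or set input_coverage)")
        model = cohort_mgs_model(cohort_spec) if cohort_spec else io.read_mgs_model(
            os.path.join(outdir, "mgs_model.tsv")
        )
        profile = mgs_abundance(coverage, model, config.min_marker_fraction)
        profile["log10_abundance"] = log10_with_sentinel(profile, config.m10_sentinel)
        io.write_table(profile, os.path.join(outdir, "mgs_profile.tsv"))
        report.stages["profile"] = {
            "n_samples": len(profile),
            "n_detected": int(profile["detected"].sum()),
        }

    if "associate" in stages:
        if profile is None or metadata is None:
            raise ValueError("associate stage needs a profile and sample metadata")
        groups = metadata["group"]
        order = list(dict.fromkeys(groups))
        prev, table = prevalence_by_group(profile["detected"], groups, order)
        rows = []
        first, last = order[0], order[-1]
        if len(order) >= 2:
            sub = table[[first, last]]
            rows.append(_result_row(fisher_exact(sub.to_numpy()), f"{first}_vs_{last}"))
            x = profile.loc[groups == first, "log10_abundance"]
            y = profile.loc[groups == last, "log10_abundance"]
            rows.append(_result_row(mann_whitney_auc(x, y), f"{first}_vs_{last}"))
            rows.append(_result_row(chi_squared(table.to_numpy()), "detected_x_group"))
            grouped = {
                g: profile.loc[groups == g, "log10_abundance"].to_numpy() for g in order
            }
            try:
                rows.append(_result_row(kruskal_wallis(grouped), "all_groups"))
            except ValueError:
                pass  # degenerate (all values identical)
        assoc = pd.DataFrame(rows)
        io.write_table(assoc, os.path.join(outdir, "association.tsv"), "row")
        report.stages["associate"] = {
            "prevalence": {g: float(prev[g]) for g in order},
            "tests": rows,
        }
        report.tables["prevalence_by_group"] = prev.to_frame()
        report.tables["detection_by_group"] = table
        summary = pd.DataFrame(
            {
                "median_log10_abundance": [
                    float(profile.loc[groups == g, "log10_abundance"].median())
                    for g in order
                ]
            },
            index=order,
        )
        report.tables["abundance_by_group"] = summary

    # ------------------------------------------------------------- genomes
    genomes = None
    truth_pg = truth_producer = None
    proteins = None
    if "simulate_genomes" in stages:
        kwargs = dict(config.genome_population)
        kwargs.setdefault("seed", config.seed + 1)
        pop_spec = GenomePopulationSpec(**kwargs)
        proteins = default_pathway_proteins()
        pop = simulate_genome_population(pop_spec, proteins)
        genomes = pop.genomes
        truth_pg, truth_producer = pop.truth_phylogroup, pop.truth_producer
        gdir = os.path.join(outdir, "genomes")
        io.write_genomes(genomes, gdir)
        io.write_protein_queries(proteins, os.path.join(outdir, "pathway_proteins.faa"))
        pd.DataFrame(
            {
                "genome_id": list(truth_pg),
                "phylogroup": list(truth_pg.values()),
                "producer": [truth_producer[g] for g in truth_pg],
            }
        ).to_csv(os.path.join(outdir, "truth_genomes.tsv"), sep="\t", index=False)
        report.stages["simulate_genomes"] = {
            "n_genomes": len(genomes),
            "n_phylogroups": pop_spec.n_phylogroups,
        }
    elif config.input_genomes:
        genomes = io.read_genomes(config.input_genomes)
        if config.input_proteins:
            proteins = io.read_protein_queries(config.input_proteins)

    if "qc" in stages:
        if genomes is None:
            raise ValueError("qc stage needs genomes (enable simulate_genomes or set input_genomes)")
        n_in = len(genomes)
        genomes = qc_filter(genomes, config.qc_min_completeness, config.qc_max_contamination)
        report.stages["qc"] = {"n_in": n_in, "n_out": len(genomes)}

    matrix = None
    if "ani" in stages:
        if genomes is None:
            raise ValueError("ani stage needs genomes")
        matrix = build_ani_matrix(
            genomes,
            fragment_length=config.fragment_length,
            k=config.kmer_size,
            min_fragment_kmer_hits=config.min_fragment_kmer_hits,
            floor=config.ani_floor,
        )
        io.write_ani_matrix(matrix, os.path.join(outdir, "ani_matrix.tsv"))
        report.stages["ani"] = {
            "n_genomes": len(matrix.ids),
            "n_floored_pairs": len(matrix.floored_pairs),
        }

    assignment = None
    if "cluster" in stages:
        if matrix is None:
            raise ValueError("cluster stage needs an ANI matrix")
        dend = upgma(matrix)
        assignment = cut_clusters(dend, config.ani_cutoff)
        io.write_newick(dend, os.path.join(outdir, "dendrogram.nwk"))
        clusters_df = pd.DataFrame(
            {"genome_id": list(assignment.labels), "cluster": list(assignment.labels.values())}
        ).set_index("genome_id")
        io.write_table(clusters_df, os.path.join(outdir, "clusters.tsv"))
        sizes = {c: len(m) for c, m in assignment.clusters().items()}
        report.stages["cluster"] = {"n_clusters": len(sizes), "sizes": sizes}

    if "nmds" in stages:
        if matrix is None:
            raise ValueError("nmds stage needs an ANI matrix")
        emb = nmds(
            matrix,
            dims=2,
            n_restarts=config.nmds_restarts,
            max_iter=config.nmds_max_iter,
            tol=config.nmds_tol,
            seed=config.seed + 2,
        )
        emb_df = pd.DataFrame(emb.coordinates, index=emb.ids, columns=["x", "y"])
        if assignment is not None:
            emb_df["cluster"] = [assignment.labels[g] for g in emb.ids]
        io.write_table(emb_df, os.path.join(outdir, "nmds.tsv"), "genome_id")
        report.stages["nmds"] = {"stress": emb.stress, "restarts": emb.restarts_used}

    calls = None
    if "equol" in stages:
        if genomes is None:
            raise ValueError("equol stage needs genomes")
        if proteins is None:
            proteins = default_pathway_proteins()
        calls = [
            genotype_genome(
                g,
                proteins,
                min_identity=config.protein_min_identity,
                min_coverage=config.protein_min_coverage,
                producer_min_fraction=config.producer_min_fraction,
            )
            for g in genomes
        ]
        rows = [
            {
                "genome_id": c.genome_id,
                "role": role,
                "identity": c.hits[role].identity,
                "coverage": c.hits[role].coverage,
                "detected": c.detected[role],
                "is_producer": c.is_producer,
            }
            for c in calls
            for role in c.detected
        ]
        pd.DataFrame(rows).to_csv(
            os.path.join(outdir, "producer_calls.tsv"), sep="\t", index=False
        )
        report.stages["equol"] = {
            "n_genomes": len(calls),
            "n_producers": sum(c.is_producer for c in calls),
        }

    if "genome_associate" in stages:
        if assignment is None:
            raise ValueError("genome_associate stage needs clusters")
        geo = {g.genome_id: g.geography for g in genomes if g.geography}
        rows = []
        if len(set(geo.values())) >= 2 and len(set(assignment.labels.values())) >= 2:
            rows.append(
                _result_row(metadata_association(assignment, geo), "phylogroup_x_geography")
            )
            geo_table = pd.crosstab(
                pd.Series({g: assignment.labels[g] for g in geo}, name="phylogroup"),
                pd.Series(geo, name="geography"),
            )
            report.tables["phylogroup_x_geography"] = geo_table
        if calls is not None:
            prod = pd.Series({c.genome_id: c.is_producer for c in calls})
            clusters = pd.Series(assignment.labels)
            table = pd.crosstab(clusters.loc[prod.index], prod)
            report.tables["producer_x_phylogroup"] = table
            if table.shape == (2, 2):
                rows.append(_result_row(chi_squared(table.to_numpy()), "producer_x_phylogroup"))
            frac = prod.groupby(clusters.loc[prod.index]).mean()
            report.stages.setdefault("genome_associate", {})["producer_fraction"] = {
                int(c): float(v) for c, v in frac.items()
            }
        assoc = pd.DataFrame(rows)
        io.write_table(assoc, os.path.join(outdir, "genome_association.tsv"), "row")
        report.stages.setdefault("genome_associate", {})["tests"] = rows

    render_report(report, outdir)
    return report


def render_report(report: RunReport, outdir: str, formats: tuple = ("markdown", "tsv")) -> list[str]:
    """Write the run summary as markdown and/or TSV; numbers are identical."""
    os.makedirs(outdir, exist_ok=True)
    written = []
    stage_rows = []
    for stage, summary in report.stages.items():
        for key, value in summary.items():
            stage_rows.append({"stage": stage, "key": key, "value": repr(value)})
    stage_df = pd.DataFrame(stage_rows, columns=["stage", "key", "value"])
    if "tsv" in formats:
        path = os.path.join(outdir, "report.tsv")
        stage_df.to_csv(path, sep="\t", index=False)
        written.append(path)
    if "markdown" in formats:
        path = os.path.join(outdir, "report.md")
        lines = [
            "# Pipeline run report",
            "",
            f"- version: {report.version}",
            f"- config hash: {report.config_hash}",
            "",
            "## Stage summaries",
            "",
        ]
        for _, row in stage_df.iterrows():
            lines.append(f"- **{row.stage}** {row.key}: {row.value}")
        for name, table in report.tables.items():
            lines += ["", f"## {name}", "", table.to_csv(sep="\t").rstrip()]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        written.append(path)
    return written
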