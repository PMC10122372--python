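"""Study-flow orchestration: simulate (or ingest) -> redox groups ->
prevalence filter -> microbiability -> differential taxa -> metabolome ->
networks -> report, with a machine-readable run manifest.

Every stage writes TSV/JSON outputs under the run directory and records a
content hash in the manifest, so reruns with the same config and seed are
bit-identical (timings are kept outside the hashed stage records).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import prevalence_filter
from .differential import lefse, wilcoxon_fold_change
from .metabolome import (MetaboliteTable, OriginAnnotation, classify_origins,
                         pathway_enrichment, pqn_normalize, qc_filter)
from .microbiability import build_relationship_matrix, fit_lmm_reml
from .networks import (compare_networks, cooccurrence_network,
                       feature_phenotype_correlations)
from .redox import compare_groups, compute_osi, select_extreme_groups
from .simulate import StudySpec, simulate_two_group_study
from .tables import read_table, sha256_of, write_json, write_table

logger = logging.getLogger(__name__)

#: analysis decisions echoed into every manifest, so paper-gap choices are
#: visible in every run
DECISIONS = {
    "sigma2_p_convention": "sigma2_m + sigma2_e (model-based)",
    "p_adjust_method": "benjamini-hochberg",
    "shared_edge_rule": "same unordered pair and same correlation sign",
    "filter_boundaries": "strict (> min_abundance, > min_prevalence)",
    "fold_change_orientation": "HOS / LOS",
    "pqn_reference": "feature-wise median of QC samples",
    "log_transform": "natural log with offset = half min positive intensity",
}


@dataclass
class RunConfig:
    """Validated configuration for a full study run."""

    outdir: str = "results/run"
    seed: int = 0
    mode: str = "simulate"  # simulate | load
    # simulation spec (mode = simulate)
    n_cohort: int = 63
    k: int = 9
    n_taxa: int = 150
    true_microbiability: float = 0.431
    # input paths (mode = load)
    abundance_path: str | None = None
    phenotypes_path: str | None = None
    metabolome_path: str | None = None
    qc_samples: list[str] = field(default_factory=list)
    annotation_path: str | None = None
    # thresholds: paper mode is the zero-config behavior
    min_abundance: float = 1e-4
    min_prevalence: float = 0.5
    rho_min: float = 0.70
    alpha: float = 0.05
    lda_cutoff: float = 2.0
    qc_presence_min: float = 0.5
    rsd_max: float = 0.30
    match_alpha: float = 0.10
    covariates: list[str] = field(default_factory=lambda: ["parity", "milk_yield"])
    matching: list[str] = field(default_factory=lambda: ["milk_yield", "parity", "bcs"])
    phenotype_col: str = "OSI"
    lda_boot: int = 30
    make_plots: bool = False

    def validate(self) -> None:
        unit_fields = ["min_prevalence", "alpha", "qc_presence_min", "rsd_max",
                       "match_alpha", "true_microbiability"]
        for name in unit_fields:
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"config field {name!r} = {value} outside [0, 1]")
        for name in ["min_abundance", "rho_min", "lda_cutoff"]:
            if getattr(self, name) < 0:
                raise ValueError(f"config field {name!r} must be non-negative")
        if self.rho_min > 1:
            raise ValueError(f"config field 'rho_min' = {self.rho_min} outside [0, 1]")
        if self.mode not in ("simulate", "load"):
            raise ValueError(f"config field 'mode' must be simulate|load, got {self.mode!r}")
        if self.mode == "load":
            for name in ("abundance_path", "phenotypes_path"):
                if getattr(self, name) is None:
                    raise ValueError(f"config field {name!r} required in load mode")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    decisions: dict
    stages: dict = field(default_factory=dict)  # stage -> {outputs: {path: sha256}}
    timings: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path], elapsed: float) -> None:
        self.stages[stage] = {
            "outputs": {p.name: sha256_of(p) for p in sorted(outputs)}
        }
        self.timings[stage] = round(elapsed, 3)

    def to_dict(self) -> dict:
        return {
            "config": self.config, "version": self.version, "seed": self.seed,
            "decisions": self.decisions, "stages": self.stages,
            "timings": self.timings,
        }


def run_study(config: RunConfig) -> RunManifest:
    """Execute the full study flow under ``config``; returns the manifest.

    Stages run in dependency order; a failure propagates after the
    manifest (with the completed stages) is written to disk.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=asdict(config), version=__version__, seed=config.seed,
        decisions=dict(DECISIONS),
    )
    manifest_path = outdir / "manifest.json"
    try:
        _run_stages(config, outdir, manifest)
    finally:
        write_json(manifest.to_dict(), manifest_path)
    return manifest


def _run_stages(config: RunConfig, outdir: Path, manifest: RunManifest) -> None:
    # -- stage: inputs ------------------------------------------------
    t0 = time.perf_counter()
    if config.mode == "simulate":
        spec = StudySpec(
            n_cohort=config.n_cohort, k=config.k, n_taxa=config.n_taxa,
            true_microbiability=config.true_microbiability,
        )
        bundle = simulate_two_group_study(spec, seed=config.seed)
        abundance, phenotypes = bundle.abundance, bundle.phenotypes
        metabolome, annotation = bundle.metabolome, bundle.annotation
        outputs = [
            write_table(abundance, outdir / "abundance.tsv"),
            write_table(phenotypes, outdir / "phenotypes.tsv"),
            write_table(metabolome.intensities, outdir / "metabolome.tsv"),
            write_table(annotation.to_frame().rename_axis("feature"),
                        outdir / "annotation.tsv"),
            write_json(bundle.truth.to_dict(), outdir / "truth.json"),
        ]
        qc_samples = metabolome.qc_samples
    else:
        abundance = read_table(config.abundance_path)
        phenotypes = read_table(config.phenotypes_path)
        metabolome = annotation = None
        qc_samples = list(config.qc_samples)
        if config.metabolome_path:
            metabolome = MetaboliteTable(read_table(config.metabolome_path),
                                         qc_samples=qc_samples)
        if config.annotation_path:
            ann = pd.read_csv(config.annotation_path, sep="\t", index_col=0)
            annotation = OriginAnnotation.from_frame(ann)
        outputs = []
    manifest.record("inputs", outputs, time.perf_counter() - t0)
    logger.info("inputs ready: %d samples x %d taxa", *abundance.shape)

    # -- stage: redox --------------------------------------------------
    t0 = time.perf_counter()
    if config.phenotype_col == "OSI" and "OSI" not in phenotypes.columns:
        phenotypes = phenotypes.assign(
            OSI=compute_osi(phenotypes["TOS"], phenotypes["T-AOC"])
        )
    matching = [c for c in config.matching if c in phenotypes.columns]
    assignment = select_extreme_groups(
        phenotypes, k=config.k, matching=matching,
        match_alpha=config.match_alpha, osi_col=config.phenotype_col,
    )
    group_stats = group_stat_table(phenotypes, assignment.labels)
    outputs = [
        write_table(assignment.labels.to_frame(), outdir / "groups.tsv"),
        write_table(assignment.matching_report.set_index("covariate"),
                    outdir / "matching_report.tsv"),
        write_table(group_stats.rename_axis("item"), outdir / "group_stats.tsv"),
    ]
    manifest.record("redox", outputs, time.perf_counter() - t0)
    logger.info("groups selected: %d LOS, %d HOS (%d swaps)",
                len(assignment.los), len(assignment.hos), assignment.swaps)

    # -- stage: filter --------------------------------------------------
    t0 = time.perf_counter()
    filt = prevalence_filter(abundance, config.min_abundance, config.min_prevalence)
    outputs = [
        write_table(filt.table, outdir / "abundance_filtered.tsv"),
        write_json({"removed": filt.removed,
                    "min_abundance": filt.min_abundance,
                    "min_prevalence": filt.min_prevalence},
                   outdir / "filter_removed.json"),
    ]
    manifest.record("filter", outputs, time.perf_counter() - t0)
    logger.info("prevalence filter: %d taxa kept, %d removed",
                filt.table.shape[1], len(filt.removed))

    # -- stage: microbiability -------------------------------------------
    t0 = time.perf_counter()
    M = build_relationship_matrix(filt.table)
    covs = phenotypes.loc[filt.table.index, config.covariates]
    vc = fit_lmm_reml(phenotypes.loc[filt.table.index, config.phenotype_col],
                      covs, M)
    outputs = [
        write_table(M.to_frame().rename_axis("sample_id"), outdir / "m_matrix.tsv"),
        write_json(vc.to_dict(), outdir / "microbiability.json"),
    ]
    manifest.record("microbiability", outputs, time.perf_counter() - t0)
    logger.info("microbiability = %.3f (sigma2_m=%.4g, sigma2_e=%.4g)",
                vc.microbiability, vc.sigma2_m, vc.sigma2_e)

    # -- stage: differential taxa ------------------------------------------
    t0 = time.perf_counter()
    selected = assignment.los + assignment.hos
    taxa_sel = filt.table.loc[selected]
    res = lefse(taxa_sel, assignment.labels.loc[selected],
                n_boot=config.lda_boot, seed=config.seed,
                alpha=config.alpha, lda_cutoff=config.lda_cutoff)
    outputs = [write_table(res.table.rename_axis("taxon"),
                           outdir / "differential_taxa.tsv")]
    manifest.record("differential", outputs, time.perf_counter() - t0)
    logger.info("differential taxa: %d significant of %d",
                int(res.table["significant"].sum()), len(res.table))

    # -- stage: metabolome ---------------------------------------------------
    diff_metab = None
    if metabolome is not None:
        t0 = time.perf_counter()
        qc_res = qc_filter(metabolome, config.qc_presence_min, config.rsd_max)
        pqn = pqn_normalize(qc_res.table)
        bio = pqn.table.biological
        met_groups = assignment.labels.reindex(bio.index).dropna()
        met_groups = met_groups[met_groups != "unassigned"]
        diff_metab = wilcoxon_fold_change(bio.loc[met_groups.index], met_groups,
                                          alpha=config.alpha, log_scale=True)
        outputs = [
            write_table(pqn.table.intensities, outdir / "metabolome_normalized.tsv"),
            write_table(pqn.quotients.to_frame(), outdir / "pqn_quotients.tsv"),
            write_json({"removed_presence": qc_res.removed_presence,
                        "removed_rsd": qc_res.removed_rsd,
                        "log_offset": pqn.log_offset},
                       outdir / "metabolome_qc.json"),
            write_table(diff_metab.rename_axis("feature"),
                        outdir / "differential_metabolites.tsv"),
        ]
        if annotation is not None:
            universe = list(bio.columns)
            counts, _ = classify_origins(universe, annotation)
            sig = diff_metab.index[diff_metab["significant"]].tolist()
            enrich = pathway_enrichment(sig, universe, annotation, alpha=config.alpha)
            outputs += [
                write_table(counts.to_frame().rename_axis("origin"),
                            outdir / "origin_counts.tsv"),
                write_table(enrich.set_index(["pathway", "origin"]),
                            outdir / "pathway_enrichment.tsv"),
            ]
        manifest.record("metabolome", outputs, time.perf_counter() - t0)
        logger.info("metabolome: %d features after QC, %d differential",
                    pqn.table.intensities.shape[1],
                    int(diff_metab["significant"].sum()))

    # -- stage: networks -----------------------------------------------------
    t0 = time.perf_counter()
    nets = {}
    for label, members in (("LOS", assignment.los), ("HOS", assignment.hos)):
        nets[label] = cooccurrence_network(
            filt.table.loc[members], group=label,
            rho_min=config.rho_min, alpha=config.alpha,
        )
    comparison = compare_networks(nets["LOS"], nets["HOS"])
    sig_taxa = res.table.index[res.table["significant"]]
    osi_panel = feature_phenotype_correlations(
        taxa_sel[sig_taxa], phenotypes.loc[selected, config.phenotype_col]
    )
    outputs = [
        write_table(nets["LOS"].edges.rename_axis("edge"), outdir / "network_LOS.tsv"),
        write_table(nets["HOS"].edges.rename_axis("edge"), outdir / "network_HOS.tsv"),
        write_table(comparison.closeness.rename_axis("taxon"),
                    outdir / "network_closeness.tsv"),
        write_json({"shared_edges": len(comparison.shared_edges),
                    "unique_LOS": comparison.unique_a,
                    "unique_HOS": comparison.unique_b},
                   outdir / "network_comparison.json"),
        write_table(osi_panel.rename_axis("taxon"), outdir / "osi_correlations.tsv"),
    ]
    manifest.record("networks", outputs, time.perf_counter() - t0)
    logger.info("networks: %d LOS edges, %d HOS edges, %d shared",
                len(nets["LOS"].edges), len(nets["HOS"].edges),
                len(comparison.shared_edges))

    # -- stage: report ----------------------------------------------------------
    t0 = time.perf_counter()
    report = render_report(manifest, outdir)
    manifest.record("report", [report], time.perf_counter() - t0)


def group_stat_table(phenotypes: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Group-statistics table in the layout LOS | HOS | SEM | P value."""
    selected = labels[labels != "unassigned"]
    rows = {}
    for col in phenotypes.columns:
        vals = phenotypes.loc[selected.index, col]
        if vals.isna().any() or not np.issubdtype(vals.dtype, np.number):
            continue
        res = compare_groups(vals, selected)
        s = res.group_summaries
        rows[col] = {
            "LOS": s.loc["LOS", "mean"], "HOS": s.loc["HOS", "mean"],
            "SEM": vals.sem(ddof=1), "P value": res.pvalue,
        }
    return pd.DataFrame(rows).T


def render_report(manifest: RunManifest, outdir: str | Path) -> Path:
    """Render a markdown summary from a run's on-disk outputs.

    Pure function of the manifest and the written tables: regenerating
    from a saved manifest reproduces the report exactly.  Missing stages
    are flagged as gaps rather than failing.
    """
    outdir = Path(outdir)
    lines = ["# Study report", "",
             f"Package version {manifest.version}; seed {manifest.seed}.", ""]
    lines += ["## Decisions in effect", ""]
    for key, val in sorted(manifest.decisions.items()):
        lines.append(f"- {key}: {val}")
    lines.append("")

    def table_md(df: pd.DataFrame, max_rows: int = 25) -> list[str]:
        df = df.head(max_rows)
        out = ["| " + " | ".join(str(c) for c in df.reset_index().columns) + " |",
               "|" + "---|" * (df.shape[1] + 1)]
        for idx, row in df.iterrows():
            cells = [str(idx)] + [
                f"{v:.4g}" if isinstance(v, float) else str(v) for v in row
            ]
            out.append("| " + " | ".join(cells) + " |")
        return out + [""]

    sections = [
        ("Group statistics (LOS vs HOS)", "group_stats.tsv", None),
        ("Differential taxa", "differential_taxa.tsv", "significant"),
        ("Differential metabolites", "differential_metabolites.tsv", "significant"),
        ("Pathway enrichment", "pathway_enrichment.tsv", "significant"),
        ("Network closeness", "network_closeness.tsv", None),
    ]
    for title, fname, flag in sections:
        lines.append(f"## {title}")
        lines.append("")
        path = outdir / fname
        if not path.exists():
            lines += ["(stage did not run)", ""]
            continue
        df = pd.read_csv(path, sep="\t", index_col=0)
        if flag is not None and flag in df.columns:
            df = df[df[flag].astype(bool)]
            if df.empty:
                lines += ["no significant features", ""]
                continue
        lines += table_md(df)

    cmp_path = outdir / "network_comparison.json"
    if cmp_path.exists():
        import json
        with open(cmp_path) as fh:
            cmp = json.load(fh)
        lines += ["## Network comparison", "",
                  f"- shared edges: {cmp['shared_edges']}",
                  f"- unique to LOS: {cmp['unique_LOS']}",
                  f"- unique to HOS: {cmp['unique_HOS']}", ""]

    report = outdir / "report.md"
    report.write_text("\n".join(lines))
    if manifest.config.get("make_plots"):
        _plot_osi(outdir)
    return report


def _plot_osi(outdir: Path) -> None:
    path = outdir / "phenotypes.tsv"
    if not path.exists():
        return
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    phen = pd.read_csv(path, sep="\t", index_col=0)
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.hist(phen["OSI"].dropna(), bins=30, color="steelblue")
    ax.set_xlabel("OSI")
    ax.set_ylabel("cows")
    fig.tight_layout()
    fig.savefig(outdir / "osi_distribution.png", dpi=120)
    plt.close(fig)
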