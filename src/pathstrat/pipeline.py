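"""End-to-end orchestration: screens -> intersections -> targeting -> profiles.

The full analysis runs, per dataset: gene-state fitting, pathway scoring,
a gene-tier survival screen and a pathway-tier survival screen; then
intersects the per-dataset significant sets (all pairwise plus the full
intersection), scans the first dataset's CNV and methylation calls for
pathway targeting, and characterizes every pathway in the full pathway-tier
intersection.  Outputs are pure functions of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

from . import __version__
from .characterize import GroupProfile, profile_pathway
from .exceptions import ConfigError, PathstratError
from .io import (align_samples, read_clinical, read_matrix, read_pathway_set)
from .mixture import fit_all_genes
from .pathways import PathwaySet, score_pathways
from .survival import SurvivalScreen, intersect_significant
from .targeting import TargetingScan, call_cnv, call_methylation

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineReport", "analyze_cohort", "run_full_analysis"]


@dataclass
class RunConfig:
    """File-based pipeline configuration (see the YAML example in README)."""

    datasets: List[dict]            # each: name, expression, clinical[, cnv, methylation]
    pathway_file: str
    alpha: float = 0.05
    family_alpha: float = 0.05
    metric: str = "activity"        # pathway screen metric: activity | consistency
    seed: int = 0
    output_dir: str = "pathstrat_out"

    def validate(self) -> "RunConfig":
        if not self.datasets:
            raise ConfigError("at least one dataset is required")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.metric not in ("activity", "consistency"):
            raise ConfigError(f"unknown metric {self.metric!r}")
        for entry in self.datasets:
            for key in ("name", "expression", "clinical"):
                if key not in entry:
                    raise ConfigError(f"dataset entry missing {key!r}: {entry}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            datasets=raw["datasets"], pathway_file=raw["pathways"],
            alpha=raw.get("alpha", 0.05), family_alpha=raw.get("family_alpha", 0.05),
            metric=raw.get("metric", "activity"), seed=raw.get("seed", 0),
            output_dir=raw.get("output_dir", "pathstrat_out")).validate()


@dataclass
class PipelineReport:
    """All per-stage results of one full analysis."""

    gene_screens: Dict[str, SurvivalScreen]
    pathway_screens: Dict[str, SurvivalScreen]
    gene_intersection: set
    gene_pairwise: dict
    pathway_intersection: set
    pathway_pairwise: dict
    targeting: Dict[str, TargetingScan] = field(default_factory=dict)
    profiles: Dict[str, GroupProfile] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def gene_significant(self, name: str) -> set:
        return self.gene_screens[name].significant_

    def pathway_significant(self, name: str) -> set:
        return self.pathway_screens[name].significant_


def _intersections(sig_sets: List[set]):
    if len(sig_sets) == 1:
        return set(sig_sets[0]), {}
    return intersect_significant(sig_sets)


def analyze_cohort(cohort, alpha: float = 0.05, family_alpha: float = 0.05,
                   metric: str = "activity", seed: int = 0,
                   run_targeting: bool = True,
                   characterize: bool = True) -> PipelineReport:
    """Run the full analysis on an in-memory :class:`SyntheticCohort`.

    The first dataset plays the multi-omic discovery cohort: its CNV and
    methylation calls feed the targeting scan and the characterization of the
    robust pathways.
    """
    gene_screens, pathway_screens = {}, {}
    scores_by_ds = {}
    for ds in cohort.datasets:
        models = fit_all_genes(ds.expression, seed=seed)
        scores = score_pathways(cohort.pathway_set, models, ds.expression)
        scores_by_ds[ds.name] = scores
        gene_screens[ds.name] = SurvivalScreen(alpha=alpha, feature_kind="gene").fit(
            ds.expression.data, ds.clinical)
        feat = scores.activity if metric == "activity" else scores.consistency
        pathway_screens[ds.name] = SurvivalScreen(
            alpha=alpha, feature_kind=f"pathway_{metric}").fit(feat, ds.clinical)

    names = [ds.name for ds in cohort.datasets]
    g_int, g_pair = _intersections([gene_screens[n].significant_ for n in names])
    p_int, p_pair = _intersections([pathway_screens[n].significant_ for n in names])

    report = PipelineReport(
        gene_screens=gene_screens, pathway_screens=pathway_screens,
        gene_intersection=g_int, gene_pairwise=g_pair,
        pathway_intersection=p_int, pathway_pairwise=p_pair)

    first = cohort.datasets[0]
    if run_targeting:
        cnv_calls = call_cnv(first.cnv)
        meth_calls = call_methylation(first.methylation)
        report.targeting["cnv"] = TargetingScan(alpha=family_alpha).fit(
            cnv_calls, cohort.pathway_set)
        report.targeting["methylation"] = TargetingScan(alpha=family_alpha).fit(
            meth_calls, cohort.pathway_set)
    if characterize and run_targeting:
        cnv_calls = call_cnv(first.cnv)
        for pid in sorted(report.pathway_intersection):
            strat = pathway_screens[first.name].results_.get(pid)
            if strat is None:
                continue
            report.profiles[pid] = profile_pathway(
                pid, cohort.pathway_set.genes(pid), cnv_calls, strat,
                expression=first.expression, cnv=first.cnv,
                methylation=first.methylation)
    report.manifest = {
        "pathstrat_version": __version__, "seed": seed, "alpha": alpha,
        "family_alpha": family_alpha, "metric": metric,
        "datasets": names, "n_pathways": len(cohort.pathway_set),
    }
    return report


@dataclass
class _LoadedDataset:
    name: str
    expression: object
    clinical: object
    cnv: object = None
    methylation: object = None


@dataclass
class _FileCohort:
    datasets: list
    pathway_set: PathwaySet


def _load_datasets(config: RunConfig):
    loaded = []
    for entry in config.datasets:
        ds = _LoadedDataset(
            name=entry["name"],
            expression=read_matrix(entry["expression"], kind="expression"),
            clinical=read_clinical(entry["clinical"]))
        if entry.get("cnv"):
            ds.cnv = read_matrix(entry["cnv"], kind="cnv")
        if entry.get("methylation"):
            ds.methylation = read_matrix(entry["methylation"], kind="methylation")
        align_samples(ds.expression, ds.clinical)
        loaded.append(ds)
    return loaded


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {"datasets": config.datasets, "pathways": config.pathway_file,
         "alpha": config.alpha, "family_alpha": config.family_alpha,
         "metric": config.metric, "seed": config.seed}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_full_analysis(config: RunConfig) -> PipelineReport:
    """File-based pipeline: read inputs, analyze, write per-stage outputs.

    Any stage failure aborts with a stage-named error; outputs written so far
    are kept next to a ``FAILED`` marker file.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        datasets = _load_datasets(config)
        pathway_set = read_pathway_set(config.pathway_file)

        stage = "screen"
        gene_screens, pathway_screens = {}, {}
        for ds in datasets:
            models = fit_all_genes(ds.expression, seed=config.seed)
            scores = score_pathways(pathway_set, models, ds.expression)
            gene_screens[ds.name] = SurvivalScreen(
                alpha=config.alpha, feature_kind="gene").fit(ds.expression.data, ds.clinical)
            feat = scores.activity if config.metric == "activity" else scores.consistency
            pathway_screens[ds.name] = SurvivalScreen(
                alpha=config.alpha, feature_kind=f"pathway_{config.metric}").fit(
                feat, ds.clinical)
            gene_screens[ds.name].to_frame().to_csv(
                out / f"gene_screen_{ds.name}.tsv", sep="\t", float_format="%.10g")
            pathway_screens[ds.name].to_frame().to_csv(
                out / f"pathway_screen_{ds.name}.tsv", sep="\t", float_format="%.10g")

        stage = "intersect"
        names = [ds.name for ds in datasets]
        g_int, g_pair = _intersections([gene_screens[n].significant_ for n in names])
        p_int, p_pair = _intersections([pathway_screens[n].significant_ for n in names])
        with open(out / "intersections.json", "w") as fh:
            json.dump({
                "gene": {"full": sorted(g_int),
                         "pairwise": {f"{names[i]}&{names[j]}": sorted(v)
                                      for (i, j), v in g_pair.items()}},
                "pathway": {"full": sorted(p_int),
                            "pairwise": {f"{names[i]}&{names[j]}": sorted(v)
                                         for (i, j), v in p_pair.items()}},
            }, fh, indent=1, sort_keys=True)

        report = PipelineReport(
            gene_screens=gene_screens, pathway_screens=pathway_screens,
            gene_intersection=g_int, gene_pairwise=g_pair,
            pathway_intersection=p_int, pathway_pairwise=p_pair)

        stage = "targeting"
        first = datasets[0]
        if first.cnv is not None:
            scan = TargetingScan(alpha=config.family_alpha).fit(
                call_cnv(first.cnv), pathway_set)
            report.targeting["cnv"] = scan
            scan.to_frame().to_csv(out / "targeting_cnv.tsv", sep="\t",
                                   float_format="%.10g")
        if first.methylation is not None:
            scan = TargetingScan(alpha=config.family_alpha).fit(
                call_methylation(first.methylation), pathway_set)
            report.targeting["methylation"] = scan
            scan.to_frame().to_csv(out / "targeting_methylation.tsv", sep="\t",
                                   float_format="%.10g")

        stage = "characterize"
        if first.cnv is not None:
            cnv_calls = call_cnv(first.cnv)
            for pid in sorted(p_int):
                strat = pathway_screens[first.name].results_.get(pid)
                if strat is None:
                    continue
                prof = profile_pathway(pid, pathway_set.genes(pid), cnv_calls, strat,
                                       expression=first.expression, cnv=first.cnv,
                                       methylation=first.methylation)
                report.profiles[pid] = prof
                if prof.deletion_freq is not None:
                    prof.deletion_freq.to_csv(out / f"profile_{pid}_deletion.tsv",
                                              sep="\t", float_format="%.10g")
                corr = prof.correlations_frame()
                if not corr.empty:
                    corr.to_csv(out / f"profile_{pid}_correlations.tsv", sep="\t",
                                index=False, float_format="%.10g")

        stage = "manifest"
        report.manifest = {
            "pathstrat_version": __version__, "config_hash": _config_hash(config),
            "seed": config.seed, "alpha": config.alpha,
            "family_alpha": config.family_alpha, "metric": config.metric,
            "datasets": names, "n_pathways": len(pathway_set),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(report.manifest, fh, indent=1, sort_keys=True)
        return report
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise PathstratError(f"pipeline failed at stage {stage!r}: {exc}") from exc
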