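"""Synthetic multi-cohort generator with a planted driver pathway.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage is testable end-to-end without external downloads:

* per-gene bimodal expression — each gene is a two-gamma mixture on an
  RMA-like positive scale;
* a latent binary driver state per sample (Bernoulli(1/2)) to which the
  genes of one designated *driver pathway* are coupled (each driver gene
  follows the latent state with probability ``state_coupling``);
* per-dataset gene-level instability — in every dataset an independent
  random ``decouple_fraction`` of driver genes is severed from the latent
  state and behaves like background, which is the designed mechanism by
  which single genes fail the cross-cohort intersection while the pathway
  aggregate survives;
* right-censored exponential survival whose hazard is multiplied by
  ``hazard_ratio`` when the latent driver state is high, censored uniformly
  on (0, censor_max);
* CNV log2 ratios and methylation betas with alteration spikes enriched in
  driver-pathway genes (rates ``alt_rate_driver`` vs ``alt_rate_background``).

Identical configuration and seed give bit-identical cohorts.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import AlterationSource, ClinicalTable, ExpressionMatrix
from .pathways import Interaction, PathwaySet

__all__ = ["CohortConfig", "SyntheticDataset", "SyntheticCohort",
           "generate_cohort", "truth_report"]


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions.

    Dataset sizes mirror the relative sizes of one large discovery cohort and
    two smaller validation cohorts.  Expression components sit on a log2-like
    scale with modest separation (down mean 5, up mean 6.8, sd 1.5), so a single
    gene's state call is noisy while a 60-gene pathway average is clean.
    Survival is in days: baseline hazard 0.002/day (median ~1 year) and a
    long administrative censoring horizon (most deaths observed).
    """

    n_genes: int = 200
    n_samples_per_dataset: Tuple[int, ...] = (200, 120, 50)
    n_pathways: int = 15
    pathway_size_range: Tuple[int, int] = (8, 30)
    driver_pathway_id: str = "PW00"
    driver_pathway_size: int = 60
    down_shape: float = 100.0 / 9.0      # mean 5, sd 1.5
    down_scale: float = 0.45
    up_shape: float = 1156.0 / 56.25     # mean 6.8, sd 1.5
    up_scale: float = 6.8 * 56.25 / 1156.0
    state_coupling: float = 0.9
    decouple_fraction: float = 0.3
    hazard_base: float = 0.002
    hazard_ratio: float = 3.0
    censor_max: float = 8000.0
    alt_rate_background: float = 0.05
    alt_rate_driver: float = 0.25
    seed: int = 0

    def validate(self) -> "CohortConfig":
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ConfigError(f"invalid pathway_size_range {self.pathway_size_range}")
        if hi > self.n_genes or self.driver_pathway_size > self.n_genes:
            raise ConfigError("pathway sizes exceed the number of genes")
        if self.up_shape * self.up_scale <= self.down_shape * self.down_scale:
            raise ConfigError("up-state mean must exceed down-state mean")
        if not 0.0 <= self.state_coupling <= 1.0:
            raise ConfigError("state_coupling must lie in [0, 1]")
        if not 0.0 <= self.decouple_fraction <= 1.0:
            raise ConfigError("decouple_fraction must lie in [0, 1]")
        if self.hazard_ratio <= 0 or self.hazard_base <= 0:
            raise ConfigError("hazard parameters must be positive")
        for rate in (self.alt_rate_background, self.alt_rate_driver):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("alteration rates must lie in [0, 1]")
        if min(self.n_samples_per_dataset) < 4:
            raise ConfigError("each dataset needs >= 4 samples")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticDataset:
    """One cohort's matrices plus its slice of the generative truth."""

    name: str
    expression: ExpressionMatrix
    clinical: ClinicalTable
    cnv: AlterationSource
    methylation: AlterationSource
    latent_state: pd.Series            # per-sample driver state in {0, 1}
    decoupled_genes: List[str]         # driver genes severed in this dataset
    gene_state: pd.DataFrame           # realised per-gene up/down draws (bool)
    cnv_spikes: pd.DataFrame           # planted CNV alteration mask (bool)
    meth_spikes: pd.DataFrame          # planted methylation alteration mask


@dataclass
class SyntheticCohort:
    """Multi-dataset synthetic study sharing one pathway database."""

    datasets: List[SyntheticDataset]
    pathway_set: PathwaySet
    driver_pathway_id: str
    driver_genes: List[str]
    config: CohortConfig


def _build_interactions(pid: str, genes: List[str], rng: np.random.Generator,
                        inhibitor_rate: float = 0.1) -> List[Interaction]:
    """Wire a gene list into a signalling cascade of typed interactions.

    The backbone is a ring of single-promoter edges (g_i promotes g_{i+1}),
    so every member gene enters the pathway's activity mean exactly once and
    with equal weight; on top, a quarter as many two-input interactions add
    cooperative (two-promoter) and, at ``inhibitor_rate``, repressive edges.
    """
    order = list(rng.permutation(genes))
    n = len(order)
    interactions = []
    for i in range(n):
        interactions.append(Interaction(
            interaction_id=f"{pid}_I{i:02d}",
            promoter_genes=(order[i],), output_genes=(order[(i + 1) % n],)))
    k = n
    for j in range(n // 4):
        a, b, out = order[(2 * j) % n], order[(2 * j + 1) % n], order[(2 * j + 2) % n]
        if rng.uniform() < inhibitor_rate:
            ia = Interaction(interaction_id=f"{pid}_I{k:02d}",
                             promoter_genes=(a,), inhibitor_genes=(b,),
                             output_genes=(out,))
        else:
            ia = Interaction(interaction_id=f"{pid}_I{k:02d}",
                             promoter_genes=(a, b), output_genes=(out,))
        interactions.append(ia)
        k += 1
    return interactions


def _build_pathways(config: CohortConfig, rng: np.random.Generator):
    genes = [f"G{i:03d}" for i in range(config.n_genes)]
    driver_genes = sorted(rng.choice(genes, size=config.driver_pathway_size,
                                     replace=False))
    other_genes = [g for g in genes if g not in set(driver_genes)]
    pathways: Dict[str, List[Interaction]] = {}
    names: Dict[str, str] = {}
    pid = config.driver_pathway_id
    pathways[pid] = _build_interactions(pid, driver_genes, rng)
    names[pid] = "Driver signaling pathway"
    lo, hi = config.pathway_size_range
    for i in range(1, config.n_pathways):
        pw_id = f"PW{i:02d}"
        size = int(rng.integers(lo, hi + 1))
        members = sorted(rng.choice(other_genes, size=size, replace=False))
        pathways[pw_id] = _build_interactions(pw_id, members, rng)
        names[pw_id] = f"Background pathway {i}"
    return genes, driver_genes, PathwaySet(pathways=pathways, names=names)


def _sample_expression(config, rng, genes, driver_genes, decoupled, latent):
    """Draw the genes x samples expression matrix and the realised states."""
    n = latent.size
    coupled = [g for g in driver_genes if g not in decoupled]
    coupled_set = set(coupled)
    states = np.empty((len(genes), n), dtype=bool)
    for gi, g in enumerate(genes):
        if g in coupled_set:
            follows = rng.uniform(size=n) < config.state_coupling
            states[gi] = (latent == 1) & follows
        else:
            pi = rng.uniform(0.25, 0.75)
            states[gi] = rng.uniform(size=n) < pi
    down = rng.gamma(config.down_shape, config.down_scale, size=states.shape)
    up = rng.gamma(config.up_shape, config.up_scale, size=states.shape)
    values = np.where(states, up, down)
    return values, states


def generate_cohort(config: Optional[CohortConfig] = None) -> SyntheticCohort:
    """Generate a deterministic multi-dataset cohort from ``config``."""
    config = (config or CohortConfig()).validate()
    rng = np.random.default_rng(config.seed)
    genes, driver_genes, pathway_set = _build_pathways(config, rng)
    gene_index = pd.Index(genes, name="gene")
    n_decouple = math.floor(config.decouple_fraction * len(driver_genes))
    driver_set = set(driver_genes)

    datasets = []
    for d, n in enumerate(config.n_samples_per_dataset):
        name = f"D{d}"
        sample_ids = pd.Index([f"{name}_S{i:03d}" for i in range(n)], name="sample_id")
        latent = (rng.uniform(size=n) < 0.5).astype(int)
        decoupled = sorted(rng.choice(driver_genes, size=n_decouple, replace=False))

        values, states = _sample_expression(config, rng, genes, driver_genes,
                                            set(decoupled), latent)
        expression = ExpressionMatrix(
            data=pd.DataFrame(values, index=gene_index, columns=sample_ids))

        rate = config.hazard_base * np.power(config.hazard_ratio, latent)
        t_event = rng.exponential(1.0 / rate)
        t_censor = rng.uniform(0.0, config.censor_max, size=n)
        time = np.minimum(t_event, t_censor)
        event = (t_event <= t_censor).astype(int)
        clinical = ClinicalTable(data=pd.DataFrame(
            {"time": time, "event": event}, index=sample_ids))

        is_driver = np.array([g in driver_set for g in genes])
        rates = np.where(is_driver, config.alt_rate_driver,
                         config.alt_rate_background)[:, None]
        cnv_mask = rng.uniform(size=(len(genes), n)) < rates
        cnv_vals = rng.normal(0.0, 0.1, size=(len(genes), n))
        signs = np.where(rng.uniform(size=(len(genes), n)) < 0.5, 1.0, -1.0)
        cnv_vals = cnv_vals + np.where(cnv_mask, 0.8 * signs, 0.0)
        cnv = AlterationSource(kind="cnv", data=pd.DataFrame(
            cnv_vals, index=gene_index, columns=sample_ids))

        meth_mask = rng.uniform(size=(len(genes), n)) < rates
        meth_bg = rng.beta(1.5, 10.0, size=(len(genes), n))
        meth_hi = 0.7 + 0.25 * rng.beta(2.0, 2.0, size=(len(genes), n))
        meth_vals = np.where(meth_mask, meth_hi, meth_bg)
        methylation = AlterationSource(kind="methylation", data=pd.DataFrame(
            meth_vals, index=gene_index, columns=sample_ids))

        datasets.append(SyntheticDataset(
            name=name, expression=expression, clinical=clinical,
            cnv=cnv, methylation=methylation,
            latent_state=pd.Series(latent, index=sample_ids),
            decoupled_genes=list(decoupled),
            gene_state=pd.DataFrame(states, index=gene_index, columns=sample_ids),
            cnv_spikes=pd.DataFrame(cnv_mask, index=gene_index, columns=sample_ids),
            meth_spikes=pd.DataFrame(meth_mask, index=gene_index, columns=sample_ids)))

    return SyntheticCohort(datasets=datasets, pathway_set=pathway_set,
                           driver_pathway_id=config.driver_pathway_id,
                           driver_genes=list(driver_genes), config=config)


def truth_report(cohort: SyntheticCohort) -> pd.DataFrame:
    """One row per sample: dataset, sample id and latent driver state.

    Per-dataset decoupled gene lists live on the dataset objects
    (``cohort.datasets[d].decoupled_genes``) and in the JSON truth file.
    """
    rows = []
    for ds in cohort.datasets:
        for sid, state in ds.latent_state.items():
            rows.append({"dataset": ds.name, "sample_id": sid,
                         "latent_driver_state": int(state)})
    return pd.DataFrame(rows)


def write_truth(cohort: SyntheticCohort, path) -> None:
    """Serialize the generative truth (for test assertions) as JSON."""
    truth = {
        "driver_pathway_id": cohort.driver_pathway_id,
        "driver_genes": cohort.driver_genes,
        "datasets": {
            ds.name: {
                "latent_state": {str(k): int(v) for k, v in ds.latent_state.items()},
                "decoupled_genes": ds.decoupled_genes,
            } for ds in cohort.datasets
        },
        "config": cohort.config.to_dict(),
    }
    Path(path).write_text(json.dumps(truth, indent=1))
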