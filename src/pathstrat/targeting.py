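"""Genomic / epigenomic targeting of pathways.

Continuous alteration measurements are first thresholded into binary calls:
CNV log2 ratios are altered when > +0.3 (amplification) or < -0.3 (deletion);
methylation beta values are altered (methylated) when > 0.5.  For each
patient j and pathway i, the number of altered pathway genes x is compared
with a hypergeometric draw of N_i genes (pathway size) from the M tested
genes of which K_j are altered in that patient.  Per-patient tail
probabilities are combined across patients with Fisher's omnibus statistic
-2 * sum(ln p_j) ~ chi-square(2n), and pathways are flagged "targeted" at a
Bonferroni-corrected family-wise level (alpha / number of pathways tested).

Tail conventions
----------------
``patient_pathway_p`` defaults to the exclusive tail P(X > x) = 1 - CDF(x),
which assigns p = 0 whenever x attains its maximum (floored before the log).
The inclusive tail P(X >= x) (``inclusive=True``) is the statistically
conventional choice and the default of :class:`TargetingScan`: the exclusive
tail is anti-conservative per patient (E[-2 ln p] > 2 under the null), an
excess that accumulates linearly in the patient count and destroys the
calibration of the omnibus statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import ConfigError, ValidationError
from .pathways import PathwaySet

logger = logging.getLogger(__name__)

__all__ = [
    "AlterationCalls",
    "TargetingResult",
    "TargetingScan",
    "call_cnv",
    "call_methylation",
    "patient_pathway_p",
    "fisher_omnibus",
    "targeting_scan",
    "bonferroni_threshold",
]

_P_FLOOR = 1e-300


@dataclass
class AlterationCalls:
    """Binary genes x patients alteration matrix plus the thresholds used."""

    kind: str                       # "cnv" | "methylation"
    data: pd.DataFrame              # 0/1, genes x patients
    thresholds: Dict[str, float]
    amplified: pd.DataFrame = None  # cnv only: 0/1 sub-calls
    deleted: pd.DataFrame = None

    @property
    def gene_ids(self):
        return list(self.data.index)

    @property
    def sample_ids(self):
        return list(self.data.columns)


def call_cnv(source, amp_threshold: float = 0.3, del_threshold: float = -0.3) -> AlterationCalls:
    """Threshold CNV log2 ratios into alteration calls (strict inequalities)."""
    if amp_threshold <= del_threshold:
        raise ConfigError(
            f"amplification threshold ({amp_threshold}) must exceed deletion "
            f"threshold ({del_threshold})")
    if source.kind != "cnv":
        raise ValidationError(f"call_cnv expects a cnv source, got {source.kind!r}")
    amp = (source.data > amp_threshold).astype(int)
    dele = (source.data < del_threshold).astype(int)
    return AlterationCalls(kind="cnv", data=((amp + dele) > 0).astype(int),
                           thresholds={"amp": amp_threshold, "del": del_threshold},
                           amplified=amp, deleted=dele)


def call_methylation(source, threshold: float = 0.5) -> AlterationCalls:
    """Tag genes methylated when beta strictly exceeds the threshold."""
    if source.kind != "methylation":
        raise ValidationError(
            f"call_methylation expects a methylation source, got {source.kind!r}")
    calls = (source.data > threshold).astype(int)
    return AlterationCalls(kind="methylation", data=calls,
                           thresholds={"beta": threshold})


def patient_pathway_p(x: int, M: int, K: int, N: int, inclusive: bool = False) -> float:
    """Hypergeometric tail probability of the per-patient pathway hit count.

    Parameters: ``x`` altered genes in the pathway for this patient, ``M``
    genes tested in total, ``K`` altered genes in the patient, ``N`` genes in
    the pathway.  Default is the exclusive tail P(X > x) = 1 - CDF(x);
    ``inclusive=True`` gives P(X >= x).
    """
    x, M, K, N = int(x), int(M), int(K), int(N)
    if K > M or N > M:
        raise ValidationError(f"require K <= M and N <= M (x={x}, M={M}, K={K}, N={N})")
    if x < 0 or x > min(K, N):
        raise ValidationError(f"x must lie in [0, min(K, N)] (x={x}, K={K}, N={N})")
    if inclusive:
        p = stats.hypergeom.sf(x - 1, M, K, N)
    else:
        p = stats.hypergeom.sf(x, M, K, N)
    return float(min(max(p, 0.0), 1.0))


def fisher_omnibus(p_values) -> tuple:
    """Fisher's combination: statistic -2*sum(ln p), chi-square(2n) tail."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("fisher_omnibus: empty p-value vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("fisher_omnibus: p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn(f"fisher_omnibus: flooring {int((p == 0).sum())} zero "
                      f"p-value(s) at {_P_FLOOR}")
        p = np.maximum(p, _P_FLOOR)
    stat = float(-2.0 * np.log(p).sum())
    return stat, float(stats.chi2.sf(stat, df=2 * p.size))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise ConfigError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class TargetingResult:
    """One pathway's omnibus targeting statistic over all patients."""

    pathway_id: str
    n_genes: int                    # pathway genes within the tested universe
    patient_p: np.ndarray
    fisher_stat: float
    combined_p: float
    bonferroni_alpha: float
    targeted: bool


class TargetingScan(BaseEstimator):
    """Scan every pathway for enrichment of alteration calls across patients.

    Parameters
    ----------
    alpha : float, default 0.05
        Family-wise level; the per-pathway threshold is alpha / n pathways.
    inclusive : bool, default True
        Use the inclusive hypergeometric tail P(X >= x) (calibrated); set
        False for the exclusive 1 - CDF(x) convention.
    """

    def __init__(self, alpha: float = 0.05, inclusive: bool = True):
        self.alpha = alpha
        self.inclusive = inclusive

    def fit(self, calls: AlterationCalls, pathway_set: PathwaySet):
        universe = sorted(set(calls.gene_ids) & set(pathway_set.all_genes()))
        if not universe:
            raise ValidationError("no genes shared between calls and pathways")
        mat = calls.data.loc[universe]
        M = len(universe)
        K = mat.sum(axis=0).to_numpy()                      # per patient
        uni = frozenset(universe)

        scored: List[tuple] = []
        excluded = []
        for pid in pathway_set:
            genes = sorted(pathway_set.genes(pid) & uni)
            if not genes:
                excluded.append(pid)
                logger.info("targeting: pathway %s has no genes in call matrix", pid)
                continue
            scored.append((pid, genes))
        n_tests = len(scored)
        if n_tests == 0:
            raise ValidationError("no pathway overlaps the alteration call matrix")
        bonf = bonferroni_threshold(self.alpha, n_tests)

        results = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-p flooring logged below instead
            for pid, genes in scored:
                N = len(genes)
                x = mat.loc[genes].sum(axis=0).to_numpy()
                shift = 1 if self.inclusive else 0
                pj = stats.hypergeom.sf(x - shift, M, K, N)
                pj = np.clip(pj, 0.0, 1.0)
                n_zero = int((pj == 0).sum())
                if n_zero:
                    logger.info("targeting: pathway %s — flooring %d zero patient "
                                "p-values at %g", pid, n_zero, _P_FLOOR)
                stat, comb = fisher_omnibus(pj)
                results.append(TargetingResult(
                    pathway_id=pid, n_genes=N, patient_p=pj, fisher_stat=stat,
                    combined_p=comb, bonferroni_alpha=bonf,
                    targeted=comb < bonf))
        self.results_ = results
        self.excluded_ = excluded
        self.M_ = M
        self.bonferroni_alpha_ = bonf
        return self

    @property
    def targeted_(self) -> List[str]:
        return [r.pathway_id for r in self.results_ if r.targeted]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"pathway_id": r.pathway_id, "n_genes": r.n_genes,
                 "fisher_stat": r.fisher_stat, "combined_p": r.combined_p,
                 "bonferroni_alpha": r.bonferroni_alpha, "targeted": r.targeted}
                for r in self.results_]
        return pd.DataFrame(rows).set_index("pathway_id")


def targeting_scan(calls: AlterationCalls, pathways: PathwaySet,
                   alpha: float = 0.05, inclusive: bool = True) -> List[TargetingResult]:
    """Run :class:`TargetingScan` and return the per-pathway results."""
    return TargetingScan(alpha=alpha, inclusive=inclusive).fit(calls, pathways).results_
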