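"""Two-group survival stratification and genome-/interactome-wide screens.

Every feature (one gene's expression, or one pathway's activity/consistency
score) is split into two groups by exact one-dimensional 2-means: the values
are sorted and the split minimizing total within-cluster sum of squares is
chosen exhaustively.  This returns the optimum that K-means (K = 2) searches
for, without random-initialization nondeterminism.  Group 1 is always the
lower-mean cluster (the paper's better-prognosis convention).  The two groups
are then compared with the Kaplan-Meier product-limit estimator and the
two-group log-rank chi-square test (1 df); features with p < alpha are flagged
significant, and robustness across cohorts is assessed by intersecting the
per-cohort significant sets.

Multiple-testing note: the screen uses raw per-feature p-values by design —
robustness comes from the cross-cohort intersection, not from within-cohort
correction.  A Benjamini-Hochberg option is available (``correction="bh"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "StratificationResult",
    "ScreenReport",
    "TwoMeansSplitter",
    "two_means_1d",
    "km_estimate",
    "KaplanMeierCurve",
    "logrank_test",
    "screen_features",
    "intersect_significant",
]


# ---------------------------------------------------------------------------
# exact 1-D two-means


class TwoMeansSplitter(BaseEstimator, ClusterMixin):
    """Exact two-cluster split of one-dimensional values.

    Sorting makes the optimal 2-means partition a contiguous split; all n-1
    splits are evaluated and the one with minimal within-cluster sum of
    squares wins.  Ties (equal WSS to within 1e-9 relative) go to the more
    balanced split.  Labels: 1 = lower-mean cluster, 2 = higher-mean cluster.
    """

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if x.size < 4:
            raise ValidationError(f"two-means needs >= 4 values, got {x.size}")
        if np.ptp(x) == 0:
            raise ValidationError("unclusterable feature: all values identical")
        order = np.argsort(x, kind="stable")
        xs = x[order]
        n = x.size
        csum = np.cumsum(xs)
        csum2 = np.cumsum(xs * xs)
        k = np.arange(1, n)  # left cluster sizes
        left_ss = csum2[:-1] - csum[:-1] ** 2 / k
        right_sum = csum[-1] - csum[:-1]
        right_ss = (csum2[-1] - csum2[:-1]) - right_sum ** 2 / (n - k)
        wss = left_ss + right_ss
        best = float(wss.min())
        tied = np.flatnonzero(wss <= best + 1e-9 * (abs(best) + 1.0))
        split = tied[np.argmin(np.abs(n - 2 * k[tied]))]  # most balanced tie
        labels = np.ones(n, dtype=int)
        labels[order[split + 1:]] = 2
        self.labels_ = labels
        self.cluster_means_ = (float(csum[split] / (split + 1)),
                               float(right_sum[split] / (n - split - 1)))
        self.inertia_ = best
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def two_means_1d(values) -> np.ndarray:
    """Exact optimal 1-D 2-means labels (1 = lower-mean, 2 = higher-mean)."""
    return TwoMeansSplitter().fit_predict(values)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


@dataclass
class KaplanMeierCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    event_times: np.ndarray     # distinct times with >= 1 observed death
    survival: np.ndarray        # S(t) just after each event time

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]


def km_estimate(times, events) -> KaplanMeierCurve:
    """Kaplan-Meier estimator: S(t) = prod over deaths <= t of (1 - d_i/n_i).

    Tied deaths decrement simultaneously; censored observations leave the
    risk set but contribute no factor.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.size == 0:
        raise ValidationError("km_estimate: empty input")
    if np.any(t <= 0):
        raise ValidationError("km_estimate: times must be positive")
    if not np.isin(e, [0, 1]).all():
        raise ValidationError("km_estimate: events must be 0/1")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order].astype(int)
    uniq = np.unique(t[e == 1])
    n = t.size
    surv, s = [], 1.0
    for u in uniq:
        at_risk = n - np.searchsorted(t, u, side="left")
        d = int(((t == u) & (e == 1)).sum())
        s *= 1.0 - d / at_risk
        surv.append(s)
    return KaplanMeierCurve(event_times=uniq, survival=np.asarray(surv))


def logrank_test(times, events, groups) -> Tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    At each distinct death time the observed group-1 deaths are compared with
    their hypergeometric expectation given the pooled risk sets; the squared
    standardized sum is chi-square with 1 df.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValidationError(f"log-rank requires exactly 2 non-empty groups, got {labels.size}")
    in1 = g == labels[0]
    death_times = np.unique(t[e == 1])
    if death_times.size == 0:
        return 0.0, 1.0
    # risk sets per group at each death time (counts of t >= u)
    t1s = np.sort(t[in1])
    t2s = np.sort(t[~in1])
    n1 = t1s.size - np.searchsorted(t1s, death_times, side="left")
    n2 = t2s.size - np.searchsorted(t2s, death_times, side="left")
    nj = n1 + n2
    d1t = np.sort(t[in1 & (e == 1)])
    dt = np.sort(t[e == 1])
    d1 = np.searchsorted(d1t, death_times, side="right") - np.searchsorted(d1t, death_times, side="left")
    d = np.searchsorted(dt, death_times, side="right") - np.searchsorted(dt, death_times, side="left")
    exp1 = d * n1 / nj
    with np.errstate(invalid="ignore", divide="ignore"):
        var1 = d * (n1 / nj) * (n2 / nj) * (nj - d) / (nj - 1)
    var1 = np.where(nj > 1, var1, 0.0)
    obs_minus_exp = float((d1 - exp1).sum())
    var = float(var1.sum())
    if var <= 0:
        return 0.0, 1.0
    stat = obs_minus_exp ** 2 / var
    return float(stat), float(stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# screening


@dataclass
class StratificationResult:
    """One feature's two-group split and its log-rank outcome."""

    feature_id: str
    feature_kind: str           # gene | pathway_activity | pathway_consistency
    groups: pd.Series           # per-sample label in {1, 2}; 1 = lower mean
    logrank_stat: float
    p_value: float
    n1: int
    n2: int

    @property
    def significant_at(self):
        return lambda alpha: self.p_value < alpha


@dataclass
class ScreenReport:
    """Per-dataset screen results with significant sets and intersections."""

    results: Dict[str, Dict[str, StratificationResult]]  # dataset -> feature -> result
    alpha: float

    def significant(self, dataset: str) -> Set[str]:
        return {f for f, r in self.results[dataset].items() if r.p_value < self.alpha}

    def intersection(self) -> Set[str]:
        sets = [self.significant(d) for d in self.results]
        return set.intersection(*sets) if sets else set()


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


class SurvivalScreen(BaseEstimator):
    """Screen a feature x sample matrix for survival stratification power.

    Parameters
    ----------
    alpha : float, default 0.05
        Per-feature significance level on the (raw) log-rank p-value.
    feature_kind : str, default "gene"
        Recorded in every result (gene / pathway_activity / pathway_consistency).
    correction : {"none", "bh"}, default "none"
        Optional Benjamini-Hochberg adjustment before thresholding.
    """

    def __init__(self, alpha: float = 0.05, feature_kind: str = "gene",
                 correction: str = "none"):
        self.alpha = alpha
        self.feature_kind = feature_kind
        self.correction = correction

    def fit(self, X: pd.DataFrame, clinical):
        """X: features x samples; clinical: ClinicalTable (or its DataFrame)."""
        cdata = clinical.data if hasattr(clinical, "data") else clinical
        common = [s for s in X.columns if s in cdata.index]
        if not common:
            raise ValidationError("no samples shared between features and clinical data")
        if len(common) < len(X.columns):
            logger.info("screen: %d/%d samples have clinical data", len(common), len(X.columns))
        times = cdata.loc[common, "time"].to_numpy(dtype=float)
        events = cdata.loc[common, "event"].to_numpy(dtype=int)
        results: Dict[str, StratificationResult] = {}
        skipped = 0
        for fid in X.index:
            vals = X.loc[fid, common].to_numpy(dtype=float)
            if np.isnan(vals).any() or np.ptp(vals) == 0 or vals.size < 4:
                skipped += 1
                logger.info("screen: skipping unclusterable feature %s", fid)
                continue
            labels = two_means_1d(vals)
            stat, p = logrank_test(times, events, labels)
            results[str(fid)] = StratificationResult(
                feature_id=str(fid), feature_kind=self.feature_kind,
                groups=pd.Series(labels, index=common),
                logrank_stat=stat, p_value=p,
                n1=int((labels == 1).sum()), n2=int((labels == 2).sum()))
        if self.correction == "bh" and results:
            ids = list(results)
            adj = _bh_adjust(np.array([results[i].p_value for i in ids]))
            self.adjusted_p_ = dict(zip(ids, adj))
        else:
            self.adjusted_p_ = None
        self.results_ = results
        self.n_skipped_ = skipped
        return self

    @property
    def significant_(self) -> Set[str]:
        if self.adjusted_p_ is not None:
            return {f for f, p in self.adjusted_p_.items() if p < self.alpha}
        return {f for f, r in self.results_.items() if r.p_value < self.alpha}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"feature": f, "kind": r.feature_kind, "statistic": r.logrank_stat,
                 "p": r.p_value, "n1": r.n1, "n2": r.n2,
                 "significant": r.p_value < self.alpha}
                for f, r in self.results_.items()]
        return pd.DataFrame(rows).set_index("feature") if rows else pd.DataFrame(
            columns=["kind", "statistic", "p", "n1", "n2", "significant"])


def screen_features(feature_matrix: pd.DataFrame, clinical, alpha: float = 0.05,
                    feature_kind: str = "gene") -> Dict[str, StratificationResult]:
    """Per-feature two-means + log-rank screen; see :class:`SurvivalScreen`."""
    screen = SurvivalScreen(alpha=alpha, feature_kind=feature_kind)
    return screen.fit(feature_matrix, clinical).results_


def plot_km(times, events, groups, path, title: str = "") -> None:
    """Render the two groups' Kaplan-Meier curves to an SVG file.

    Imports matplotlib lazily; plotting is an optional extra.
    """
    import matplotlib
    matplotlib.use("svg", force=False)
    import matplotlib.pyplot as plt

    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, color in zip(np.unique(g), ("tab:blue", "tab:green")):
        sel = g == label
        curve = km_estimate(t[sel], e[sel])
        grid = np.concatenate([[0.0], np.repeat(curve.event_times, 2), [t.max()]])
        surv = np.concatenate([[1.0, 1.0], np.repeat(curve.survival, 2)])
        ax.plot(grid, surv[:grid.size], color=color, label=f"group {label} (n={sel.sum()})")
    stat, p = logrank_test(t, e, g)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    ax.set_title(f"{title} log-rank p = {p:.3g}".strip())
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def intersect_significant(significant_sets: Sequence[Set[str]]):
    """Full and pairwise intersections of per-dataset significant sets.

    Returns ``(robust, pairwise)`` where ``robust`` is the intersection over
    all datasets and ``pairwise`` maps index pairs to their intersections.
    """
    sets = [set(s) for s in significant_sets]
    if len(sets) < 2:
        raise ValidationError("intersection requires >= 2 datasets")
    robust = set.intersection(*sets)
    pairwise = {(i, j): sets[i] & sets[j] for i, j in combinations(range(len(sets)), 2)}
    return robust, pairwise
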