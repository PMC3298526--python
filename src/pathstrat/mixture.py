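"""Two-component gamma mixture models of per-gene expression state.

Across a cohort, a transcriptionally regulated gene shows a low ("down",
suppressed — often near-exponential) and a high ("up", promoted — bell-shaped)
expression mode.  Both modes are modelled as gamma densities, so the marginal
per-gene distribution is

    f(x) = (1 - w) * Gamma(x; k_d, theta_d) + w * Gamma(x; k_u, theta_u)

with mixing weight ``w`` of the up component.  The model is fitted by EM with
an exact weighted maximum-likelihood M-step (gamma shape solved by Newton on
``log k - psi(k) = log(mean) - mean(log)``), which guarantees a non-decreasing
log-likelihood.  The per-sample posterior probability of the up state,
``P(up | x)``, is the quantity every downstream pathway metric consumes.

Initialization is deterministic: values are split at the median and each half
is fitted by the method of moments.  The ``seed`` only feeds an optional
jittered restart used when EM collapses (a component weight or variance
underflowing); a gene whose restart also collapses — or whose data are
(near-)constant or too few (< 20 values) — gets a *degenerate* model whose
posteriors are all 0.5 (maximal uncertainty), keeping pathway scores defined.
"""

from __future__ import annotations

import json
import logging
import warnings
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, polygamma
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import RangeError

logger = logging.getLogger(__name__)

__all__ = [
    "GammaMixture",
    "GeneStateModels",
    "GeneStateTransformer",
    "fit_gamma_mixture",
    "posterior_up",
    "fit_all_genes",
]

_WEIGHT_FLOOR = 0.01      # mixing weight below which a component collapsed
_VAR_FLOOR = 1e-8         # overall variance below which the gene is constant
_CSTAT_FLOOR = 1e-10      # log(mean)-mean(log) floor: component variance underflow
_POST_CLIP = 1e-12
_MIN_N = 20


def _solve_gamma_shape(c: float) -> float:
    """Solve log(k) - digamma(k) = c by Newton from Minka's closed-form start."""
    k = (3.0 - c + np.sqrt((c - 3.0) ** 2 + 24.0 * c)) / (12.0 * c)
    for _ in range(6):
        f = np.log(k) - digamma(k) - c
        fp = 1.0 / k - polygamma(1, k)
        step = f / fp
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) < 1e-12 * k:
            k = k_new
            break
        k = k_new
    return float(k)


def _gamma_logpdf(x, lnx, shape, scale):
    return (shape - 1.0) * lnx - x / scale - gammaln(shape) - shape * np.log(scale)


def _moments_init(x):
    m, v = float(np.mean(x)), float(np.var(x))
    if v <= 0:
        return 100.0, m / 100.0
    shape = np.clip(m * m / v, 1e-2, 1e4)
    return float(shape), float(m / shape)


def _weighted_mle(w, x, lnx):
    """Weighted gamma MLE; returns (shape, scale) or None on variance underflow."""
    W = w.sum()
    if W <= 0:
        return None
    A = float((w * x).sum() / W)
    B = float((w * lnx).sum() / W)
    c = np.log(A) - B
    if c <= _CSTAT_FLOOR:
        return None
    shape = _solve_gamma_shape(c)
    if not np.isfinite(shape) or shape > 1e6:
        return None
    return shape, A / shape


def _em_run(x, lnx, init, tol, max_iter):
    """One EM run from ``init``; returns (params, trace, status)."""
    (kd, td), (ku, tu), w = init
    trace = []
    ll_prev = -np.inf
    status = "maxiter"
    for _ in range(max_iter):
        lfd = _gamma_logpdf(x, lnx, kd, td)
        lfu = _gamma_logpdf(x, lnx, ku, tu)
        a = np.log1p(-w) + lfd
        b = np.log(w) + lfu
        ll_i = np.logaddexp(a, b)
        ll = float(ll_i.sum())
        trace.append(ll)
        if ll - ll_prev < tol * (abs(ll_prev) + 1.0) and np.isfinite(ll_prev):
            status = "converged"
            break
        ll_prev = ll
        r_up = np.exp(b - ll_i)
        w = float(r_up.mean())
        if w < _WEIGHT_FLOOR or w > 1.0 - _WEIGHT_FLOOR:
            return None, trace, "collapsed"
        mle_d = _weighted_mle(1.0 - r_up, x, lnx)
        mle_u = _weighted_mle(r_up, x, lnx)
        if mle_d is None or mle_u is None:
            return None, trace, "collapsed"
        (kd, td), (ku, tu) = mle_d, mle_u
    return ((kd, td), (ku, tu), w), trace, status


class GammaMixture(BaseEstimator):
    """Two-component gamma mixture of one gene's expression values.

    Parameters
    ----------
    tol : float, default 1e-6
        Relative log-likelihood change below which EM stops.
    max_iter : int, default 500
        Maximum EM iterations.
    random_state : int, default 0
        Seeds the jittered restart attempted when EM collapses.

    Attributes
    ----------
    shape_down_, scale_down_, shape_up_, scale_up_ : float
        Gamma parameters, relabelled so the up component has the larger mean.
    weight_up_ : float
        Mixing proportion of the up component.
    degenerate_ : bool
        True when no two-component fit exists; posteriors are then 0.5.
    loglik_trace_ : ndarray
        Log-likelihood after each EM iteration (non-decreasing).
    n_iter_ : int
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 500, random_state: int = 0):
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _set_degenerate(self, trace=()):
        self.degenerate_ = True
        self.shape_down_ = self.scale_down_ = self.shape_up_ = self.scale_up_ = np.nan
        self.weight_up_ = np.nan
        self.loglik_trace_ = np.asarray(trace, dtype=float)
        self.n_iter_ = len(self.loglik_trace_)
        return self

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if x.size and (not np.all(np.isfinite(x)) or np.any(x <= 0)):
            raise RangeError("gamma mixture requires finite, strictly positive values")
        if x.size < _MIN_N or np.var(x) < _VAR_FLOOR:
            return self._set_degenerate()
        lnx = np.log(x)

        med = np.median(x)
        hi = x > med
        if hi.sum() < 2 or (~hi).sum() < 2:
            return self._set_degenerate()
        init = (_moments_init(x[~hi]), _moments_init(x[hi]), float(hi.mean()))

        params, trace, status = _em_run(x, lnx, init, self.tol, self.max_iter)
        if params is None:
            # one jittered restart before declaring the gene degenerate
            rng = np.random.default_rng(self.random_state)
            (kd, td), (ku, tu), w = init
            jit = rng.uniform(0.8, 1.25, size=4)
            init2 = ((kd * jit[0], td * jit[1]), (ku * jit[2], tu * jit[3]),
                     float(np.clip(w + rng.uniform(-0.1, 0.1), 0.05, 0.95)))
            params, trace, status = _em_run(x, lnx, init2, self.tol, self.max_iter)
        if params is None:
            return self._set_degenerate(trace)

        (kd, td), (ku, tu), w = params
        if kd * td > ku * tu:  # relabel: up = larger-mean component
            (kd, td, ku, tu), w = (ku, tu, kd, td), 1.0 - w
        self.degenerate_ = False
        self.shape_down_, self.scale_down_ = kd, td
        self.shape_up_, self.scale_up_ = ku, tu
        self.weight_up_ = w
        self.loglik_trace_ = np.asarray(trace, dtype=float)
        self.n_iter_ = len(trace)
        return self

    @property
    def mean_down_(self) -> float:
        return self.shape_down_ * self.scale_down_

    @property
    def mean_up_(self) -> float:
        return self.shape_up_ * self.scale_up_

    def predict_proba(self, X) -> np.ndarray:
        """Posterior state probabilities, columns ``[P(down), P(up)]``."""
        x = np.asarray(X, dtype=float).ravel()
        if self.degenerate_:
            warnings.warn("degenerate gamma mixture: returning posterior 0.5")
            half = np.full(x.shape, 0.5)
            return np.column_stack([half, half])
        if np.any(x <= 0):
            raise RangeError("posterior evaluation requires strictly positive values")
        lnx = np.log(x)
        a = np.log1p(-self.weight_up_) + _gamma_logpdf(x, lnx, self.shape_down_, self.scale_down_)
        b = np.log(self.weight_up_) + _gamma_logpdf(x, lnx, self.shape_up_, self.scale_up_)
        up = np.clip(1.0 / (1.0 + np.exp(a - b)), _POST_CLIP, 1.0 - _POST_CLIP)
        return np.column_stack([1.0 - up, up])

    def posterior_up(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def score(self, X) -> float:
        """Mean log-likelihood under the fitted mixture."""
        x = np.asarray(X, dtype=float).ravel()
        lnx = np.log(x)
        a = np.log1p(-self.weight_up_) + _gamma_logpdf(x, lnx, self.shape_down_, self.scale_down_)
        b = np.log(self.weight_up_) + _gamma_logpdf(x, lnx, self.shape_up_, self.scale_up_)
        return float(np.logaddexp(a, b).mean())


def fit_gamma_mixture(values, tol: float = 1e-6, max_iter: int = 500,
                      seed: int = 0) -> GammaMixture:
    """Fit one gene's two-gamma mixture; see :class:`GammaMixture`."""
    return GammaMixture(tol=tol, max_iter=max_iter, random_state=seed).fit(values)


def posterior_up(model: GammaMixture, x) -> np.ndarray:
    """P(up | x) under a fitted model (0.5 with a warning when degenerate)."""
    scalar = np.isscalar(x)
    out = model.posterior_up(np.atleast_1d(x))
    return float(out[0]) if scalar else out


class GeneStateModels:
    """A fitted mixture model per gene, with posterior-matrix evaluation."""

    def __init__(self, models: Dict[str, GammaMixture]):
        self.models = models

    def __getitem__(self, gene) -> GammaMixture:
        return self.models[gene]

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    @property
    def n_degenerate(self) -> int:
        return sum(m.degenerate_ for m in self.models.values())

    def posterior_matrix(self, matrix) -> pd.DataFrame:
        """Genes x samples matrix of P(up) for every modelled gene."""
        data = matrix.data if hasattr(matrix, "data") else matrix
        rows = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for g, m in self.models.items():
                if m.degenerate_:
                    rows[g] = np.full(data.shape[1], 0.5)
                else:
                    rows[g] = m.posterior_up(data.loc[g].to_numpy(dtype=float))
        return pd.DataFrame(rows, index=data.columns).T

    def to_json(self, path=None) -> Optional[str]:
        records = []
        for g, m in self.models.items():
            rec = {"gene_id": g, "degenerate": bool(m.degenerate_)}
            if not m.degenerate_:
                rec.update(shape_down=m.shape_down_, scale_down=m.scale_down_,
                           shape_up=m.shape_up_, scale_up=m.scale_up_,
                           weight_up=m.weight_up_)
            records.append(rec)
        text = json.dumps(records, indent=1)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_json(cls, source) -> "GeneStateModels":
        if isinstance(source, str) and source.lstrip().startswith("["):
            records = json.loads(source)
        else:
            with open(source) as fh:
                records = json.load(fh)
        models = {}
        for rec in records:
            m = GammaMixture()
            if rec["degenerate"]:
                m._set_degenerate()
            else:
                m.degenerate_ = False
                m.shape_down_ = rec["shape_down"]
                m.scale_down_ = rec["scale_down"]
                m.shape_up_ = rec["shape_up"]
                m.scale_up_ = rec["scale_up"]
                m.weight_up_ = rec["weight_up"]
                m.loglik_trace_ = np.asarray([])
                m.n_iter_ = 0
            models[rec["gene_id"]] = m
        return cls(models)


def fit_all_genes(matrix, tol: float = 1e-6, max_iter: int = 500,
                  seed: int = 0) -> GeneStateModels:
    """Fit every gene in an expression matrix independently (deterministic).

    Each gene's restart seed is derived from ``seed`` and the gene's row
    position, so results do not depend on dict ordering elsewhere.
    """
    data = matrix.data if hasattr(matrix, "data") else matrix
    models = {}
    for i, g in enumerate(data.index):
        models[g] = GammaMixture(tol=tol, max_iter=max_iter,
                                 random_state=(seed * 100003 + i) % (2**31)
                                 ).fit(data.loc[g].to_numpy(dtype=float))
    gm = GeneStateModels(models)
    if gm.n_degenerate:
        logger.info("fit_all_genes: %d/%d genes degenerate", gm.n_degenerate, len(gm))
    return gm


class GeneStateTransformer(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper: expression matrix in, up-posterior matrix out."""

    def __init__(self, tol: float = 1e-6, max_iter: int = 500, random_state: int = 0):
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        self.models_ = fit_all_genes(X, tol=self.tol, max_iter=self.max_iter,
                                     seed=self.random_state)
        return self

    def transform(self, X) -> pd.DataFrame:
        return self.models_.posterior_matrix(X)
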