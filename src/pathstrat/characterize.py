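"""Molecular characterization of the two survival groups of a pathway.

Given a pathway's two-group stratification, this module reports (a) per-gene
amplification/deletion/methylation frequencies within each group, (b)
correlations between data layers (CNV vs expression, methylation vs
expression, methylation vs CNV) for a gene within each group, and (c)
co-expression of a gene pair per group — the analysis pattern behind the
JUN-FOS contrast, where a proto-oncogene and its antagonist are correlated in
the better-prognosis group and decorrelated in the poor-prognosis group.

Correlations are Pearson by default (all layers are continuous and the
phenomenon of interest is linear co-movement); Spearman is available via
``method="spearman"``.  A correlation is called "present" when r >= a strength
threshold (default 0.3) with p < 0.05; both are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GroupProfile",
    "alteration_frequency",
    "layer_correlation",
    "gene_pair_correlation",
    "correlation_consistency",
]

_MIN_GROUP = 5


def _group_samples(groups, label, universe) -> List[str]:
    g = groups.groups if hasattr(groups, "groups") else groups  # StratificationResult or Series
    members = [s for s in g.index if g[s] == label and s in universe]
    return members


def alteration_frequency(calls, groups, gene: str, direction: str = "deletion") -> Dict[int, float]:
    """Percent of each group's patients carrying the alteration in ``gene``.

    ``direction`` is "deletion" or "amplification" for CNV calls, or "any"
    (plain calls, also the only choice for methylation).
    """
    gene = gene.upper()
    if direction == "deletion":
        mat = calls.deleted
    elif direction == "amplification":
        mat = calls.amplified
    elif direction == "any":
        mat = calls.data
    else:
        raise ValidationError(f"unknown direction {direction!r}")
    if mat is None:
        raise ValidationError(f"{calls.kind} calls carry no {direction!r} sub-matrix")
    if gene not in mat.index:
        raise ValidationError(f"gene {gene!r} absent from alteration calls")
    out = {}
    universe = set(mat.columns)
    for label in (1, 2):
        members = _group_samples(groups, label, universe)
        if not members:
            out[label] = float("nan")
            continue
        out[label] = 100.0 * float(mat.loc[gene, members].sum()) / len(members)
    return out


def _corr(a: np.ndarray, b: np.ndarray, method: str) -> Tuple[float, float]:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan"), float("nan")
    if method == "spearman":
        r, p = stats.spearmanr(a, b)
    else:
        r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def layer_correlation(layer_a, layer_b, gene: str, group_samples,
                      method: str = "pearson") -> Tuple[float, float]:
    """Correlation of one gene's values across two data layers within a group.

    Returns ``(r, p)``; ``(nan, nan)`` when either vector has zero variance.
    """
    gene = gene.upper()
    da = layer_a.data if hasattr(layer_a, "data") else layer_a
    db = layer_b.data if hasattr(layer_b, "data") else layer_b
    for d, name in ((da, "layer_a"), (db, "layer_b")):
        if gene not in d.index:
            raise ValidationError(f"gene {gene!r} absent from {name}")
    samples = [s for s in group_samples if s in da.columns and s in db.columns]
    if len(samples) < _MIN_GROUP:
        raise ValidationError(f"need >= {_MIN_GROUP} group samples shared by both "
                              f"layers, got {len(samples)}")
    return _corr(da.loc[gene, samples].to_numpy(dtype=float),
                 db.loc[gene, samples].to_numpy(dtype=float), method)


def gene_pair_correlation(matrix, gene_a: str, gene_b: str, groups,
                          method: str = "pearson") -> Dict[int, Tuple[float, float]]:
    """Per-group co-expression of two genes: {group label: (r, p)}."""
    gene_a, gene_b = gene_a.upper(), gene_b.upper()
    data = matrix.data if hasattr(matrix, "data") else matrix
    for g in (gene_a, gene_b):
        if g not in data.index:
            raise ValidationError(f"gene {g!r} absent from expression matrix")
    out = {}
    universe = set(data.columns)
    for label in (1, 2):
        members = _group_samples(groups, label, universe)
        if len(members) < _MIN_GROUP:
            out[label] = (float("nan"), float("nan"))
            continue
        out[label] = _corr(data.loc[gene_a, members].to_numpy(dtype=float),
                           data.loc[gene_b, members].to_numpy(dtype=float), method)
    return out


def correlation_consistency(per_dataset: List[Dict[int, Tuple[float, float]]],
                            r_threshold: float = 0.3,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Cross-dataset presence/absence table for a per-group correlation.

    A correlation is "present" when r >= r_threshold and p < alpha.  Rows are
    datasets, columns the two groups; the robustness pattern of interest is
    presence in group 1 of every dataset and absence in group 2.
    """
    rows = []
    for i, per_group in enumerate(per_dataset):
        row = {"dataset": i}
        for label in (1, 2):
            r, p = per_group.get(label, (float("nan"), float("nan")))
            row[f"r_group{label}"] = r
            row[f"p_group{label}"] = p
            row[f"present_group{label}"] = bool(np.isfinite(r) and r >= r_threshold
                                                and p < alpha)
        rows.append(row)
    return pd.DataFrame(rows).set_index("dataset")


@dataclass
class GroupProfile:
    """Per-group alteration frequencies and correlation records for a pathway."""

    pathway_id: str
    deletion_freq: pd.DataFrame = None        # genes x groups, percent
    amplification_freq: pd.DataFrame = None
    correlations: List[dict] = field(default_factory=list)

    def add_correlation(self, kind: str, target: str, group: int, r: float, p: float):
        self.correlations.append({"kind": kind, "target": target, "group": group,
                                  "r": r, "p": p})

    def correlations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.correlations)


def profile_pathway(pathway_id: str, pathway_genes, calls, strat,
                    expression=None, cnv=None, methylation=None) -> GroupProfile:
    """Build a :class:`GroupProfile` for one pathway's two survival groups.

    ``calls`` drives the per-group alteration frequencies; the continuous
    layers (``expression``, ``cnv``, ``methylation``) drive the per-group
    between-layer correlations where provided.
    """
    profile = GroupProfile(pathway_id=pathway_id)
    genes = [g for g in sorted(pathway_genes) if g in calls.data.index]
    if calls.kind == "cnv":
        for direction, name in (("deletion", "deletion_freq"),
                                ("amplification", "amplification_freq")):
            freq = {g: alteration_frequency(calls, strat, g, direction) for g in genes}
            setattr(profile, name,
                    pd.DataFrame(freq).T.rename(columns=lambda c: f"group{c}"))
    group_sets = {label: _group_samples(strat, label, set(calls.data.columns))
                  for label in (1, 2)}
    layer_pairs = [("expression~cnv", expression, cnv),
                   ("expression~methylation", expression, methylation),
                   ("methylation~cnv", methylation, cnv)]
    for kind, la, lb in layer_pairs:
        if la is None or lb is None:
            continue
        for g in genes:
            for label, members in group_sets.items():
                try:
                    r, p = layer_correlation(la, lb, g, members)
                except ValidationError:
                    continue
                profile.add_correlation(kind, g, label, r, p)
    return profile
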