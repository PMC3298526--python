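"""Pathway interaction graphs and per-sample activity / consistency scores.

A pathway is modelled as a flat collection of typed interactions.  Each
interaction has input genes acting as *promoters* or *inhibitors* and zero or
more *output* genes.  Given per-gene posterior probabilities of being in the
transcriptional "up" state, the probability that an interaction is active is

    activity = prod_{g in promoters} P(up_g) * prod_{g in inhibitors} (1 - P(up_g))

i.e. all promoting inputs up and all inhibiting inputs down.  Consistency
compares the interaction's activity with the observed state of its output
genes: with ``a`` the activity and ``q`` the mean up-posterior over outputs,

    consistency = a*q + (1-a)*(1-q)

(the output is expected up exactly when the interaction is active; for an
interaction that represses its output the two terms are flipped).  Pathway
scores are arithmetic means over the pathway's scoreable interactions, so both
metrics live in [0, 1] and are comparable across pathways of different size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "Interaction",
    "PathwaySet",
    "PathwayScoreMatrix",
    "PathwayScorer",
    "interaction_activity",
    "interaction_consistency",
    "score_pathways",
]


@dataclass(frozen=True)
class Interaction:
    """One typed interaction: promoter/inhibitor inputs and optional outputs.

    ``output_inhibited`` marks interactions whose effect on the output genes is
    repressive, flipping the consistency expectation.  The TSV dialect does not
    carry this flag; it is available programmatically.
    """

    interaction_id: str
    promoter_genes: tuple = ()
    inhibitor_genes: tuple = ()
    output_genes: tuple = ()
    output_inhibited: bool = False

    def __post_init__(self):
        object.__setattr__(self, "promoter_genes", tuple(g.upper() for g in self.promoter_genes))
        object.__setattr__(self, "inhibitor_genes", tuple(g.upper() for g in self.inhibitor_genes))
        object.__setattr__(self, "output_genes", tuple(g.upper() for g in self.output_genes))
        if not self.promoter_genes and not self.inhibitor_genes:
            raise FormatError(
                f"interaction {self.interaction_id!r} has no input genes "
                "(promoter or inhibitor role required)"
            )

    @property
    def input_genes(self) -> tuple:
        return self.promoter_genes + self.inhibitor_genes

    @property
    def genes(self) -> tuple:
        return self.input_genes + self.output_genes


@dataclass
class PathwaySet:
    """A named collection of pathways, each a list of interactions."""

    pathways: Dict[str, List[Interaction]]
    names: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for pid, interactions in self.pathways.items():
            if not interactions:
                raise FormatError(f"pathway {pid!r} has no interactions")
        for pid in self.pathways:
            self.names.setdefault(pid, pid)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __contains__(self, pathway_id) -> bool:
        return pathway_id in self.pathways

    def genes(self, pathway_id: str) -> frozenset:
        """All genes (inputs and outputs) of one pathway."""
        return frozenset(g for ia in self.pathways[pathway_id] for g in ia.genes)

    def all_genes(self) -> frozenset:
        return frozenset(g for pid in self.pathways for g in self.genes(pid))


@dataclass
class PathwayScoreMatrix:
    """Per-sample activity and consistency scores for each scored pathway."""

    activity: pd.DataFrame      # pathways x samples, in [0, 1]
    consistency: pd.DataFrame   # pathways x samples, NaN where no interaction has outputs
    coverage: pd.Series         # fraction of member genes present in the expression data
    excluded: List[str] = field(default_factory=list)

    @property
    def pathway_ids(self):
        return list(self.activity.index)

    @property
    def sample_ids(self):
        return list(self.activity.columns)


def _input_terms(interaction: Interaction, posteriors: Mapping[str, np.ndarray]):
    """Posterior factors for the available input genes; None if all missing."""
    terms = []
    for g in interaction.promoter_genes:
        if g in posteriors:
            terms.append(np.asarray(posteriors[g]))
    for g in interaction.inhibitor_genes:
        if g in posteriors:
            terms.append(1.0 - np.asarray(posteriors[g]))
    return terms or None


def interaction_activity(interaction: Interaction, posteriors: Mapping[str, float]):
    """Probability the interaction is active: promoters up, inhibitors down.

    Genes without a posterior are dropped; returns None when no input gene has
    a posterior (the interaction is then unscoreable and skipped upstream).
    """
    terms = _input_terms(interaction, posteriors)
    if terms is None:
        return None
    out = terms[0]
    for t in terms[1:]:
        out = out * t
    return out


def interaction_consistency(interaction: Interaction, posteriors: Mapping[str, float]):
    """Agreement between an interaction's activity and its outputs' states.

    Returns None when the interaction has no output gene with a posterior
    (consistency undefined, excluded from the pathway mean).
    """
    outs = [np.asarray(posteriors[g]) for g in interaction.output_genes if g in posteriors]
    if not outs:
        return None
    a = interaction_activity(interaction, posteriors)
    if a is None:
        return None
    q = np.mean(outs, axis=0)
    if interaction.output_inhibited:
        return a * (1.0 - q) + (1.0 - a) * q
    return a * q + (1.0 - a) * (1.0 - q)


class PathwayScorer(BaseEstimator, TransformerMixin):
    """Transform a gene x sample up-posterior matrix into pathway scores.

    Parameters
    ----------
    pathway_set : PathwaySet
        Interaction graphs to score.
    min_coverage : float, default 0.5
        Pathways with a smaller fraction of member genes present in the
        posterior matrix are excluded (reported in ``excluded_``).
    """

    def __init__(self, pathway_set: PathwaySet = None, min_coverage: float = 0.5):
        self.pathway_set = pathway_set
        self.min_coverage = min_coverage

    def fit(self, X: pd.DataFrame, y=None):
        """Record coverage and which pathways are scoreable on these genes."""
        if self.pathway_set is None:
            raise ValueError("pathway_set is required")
        genes = frozenset(str(g).upper() for g in X.index)
        self.coverage_ = {}
        self.excluded_ = []
        for pid in self.pathway_set:
            members = self.pathway_set.genes(pid)
            cov = len(members & genes) / len(members) if members else 0.0
            self.coverage_[pid] = cov
            if cov < self.min_coverage:
                self.excluded_.append(pid)
        if self.excluded_:
            logger.info(
                "excluding %d/%d pathways below coverage %.2f: %s",
                len(self.excluded_), len(self.pathway_set), self.min_coverage,
                ", ".join(self.excluded_),
            )
        return self

    def transform(self, X: pd.DataFrame) -> PathwayScoreMatrix:
        """Score every retained pathway on every sample (column of X)."""
        if not hasattr(self, "coverage_"):
            raise ValueError("PathwayScorer must be fitted before transform")
        posteriors = {str(g).upper(): X.loc[g].to_numpy(dtype=float) for g in X.index}
        n = X.shape[1]
        act_rows, con_rows, kept = [], [], []
        for pid in self.pathway_set:
            if pid in self.excluded_:
                continue
            acts, cons = [], []
            for ia in self.pathway_set.pathways[pid]:
                a = interaction_activity(ia, posteriors)
                if a is None:
                    logger.info("pathway %s: interaction %s unscoreable (all inputs missing)",
                                pid, ia.interaction_id)
                    continue
                acts.append(np.broadcast_to(a, (n,)))
                c = interaction_consistency(ia, posteriors)
                if c is not None:
                    cons.append(np.broadcast_to(c, (n,)))
            if not acts:
                logger.info("pathway %s excluded: zero scoreable interactions", pid)
                self.excluded_.append(pid)
                continue
            kept.append(pid)
            act_rows.append(np.mean(acts, axis=0))
            con_rows.append(np.mean(cons, axis=0) if cons else np.full(n, np.nan))
        activity = pd.DataFrame(act_rows, index=kept, columns=X.columns)
        consistency = pd.DataFrame(con_rows, index=kept, columns=X.columns)
        coverage = pd.Series({pid: self.coverage_[pid] for pid in kept}, dtype=float)
        return PathwayScoreMatrix(activity=activity, consistency=consistency,
                                  coverage=coverage, excluded=list(self.excluded_))


def score_pathways(pathway_set: PathwaySet, models, matrix, min_coverage: float = 0.5) -> PathwayScoreMatrix:
    """Convenience wrapper: gene state models + expression -> pathway scores.

    ``models`` is a fitted :class:`pathstrat.mixture.GeneStateModels`; the
    posterior matrix is evaluated on ``matrix`` and fed through
    :class:`PathwayScorer`.
    """
    post = models.posterior_matrix(matrix)
    scorer = PathwayScorer(pathway_set=pathway_set, min_coverage=min_coverage)
    return scorer.fit(post).transform(post)
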