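"""Pathway activity/consistency: closed forms, aggregation, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathstrat import (Interaction, PathwaySet, PathwayScorer, fit_all_genes,
                       interaction_activity, interaction_consistency,
                       score_pathways)
from pathstrat.exceptions import FormatError


class TestInteractionActivity:
    def test_two_promoters_product(self):
        ia = Interaction("i", promoter_genes=("A", "B"))
        assert interaction_activity(ia, {"A": 0.9, "B": 0.8}) == pytest.approx(0.72)

    def test_inhibitor_complement(self):
        ia = Interaction("i", promoter_genes=("A",), inhibitor_genes=("B",))
        assert interaction_activity(ia, {"A": 0.9, "B": 0.3}) == pytest.approx(0.63)

    def test_zero_promoter_annihilates(self):
        ia = Interaction("i", promoter_genes=("A", "B"))
        assert interaction_activity(ia, {"A": 0.0, "B": 0.7}) == pytest.approx(0.0)

    def test_missing_gene_dropped(self):
        ia = Interaction("i", promoter_genes=("A", "B"))
        assert interaction_activity(ia, {"A": 0.9}) == pytest.approx(0.9)

    def test_all_inputs_missing_returns_none(self):
        ia = Interaction("i", promoter_genes=("A",))
        assert interaction_activity(ia, {"Z": 0.5}) is None

    def test_no_inputs_rejected_at_construction(self):
        with pytest.raises(FormatError):
            Interaction("i", output_genes=("A",))

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_activity_in_unit_interval_and_order_invariant(self, ps):
        genes = [f"G{i}" for i in range(len(ps))]
        post = dict(zip(genes, ps))
        ia = Interaction("i", promoter_genes=tuple(genes))
        a = interaction_activity(ia, post)
        assert 0.0 <= a <= 1.0
        ia_rev = Interaction("i", promoter_genes=tuple(reversed(genes)))
        assert interaction_activity(ia_rev, post) == pytest.approx(a)


class TestInteractionConsistency:
    @pytest.mark.parametrize("post,expected", [
        ({"A": 1.0, "O": 1.0}, 1.0),     # active, output up: consistent
        ({"A": 0.5, "O": 0.9}, 0.5),     # uninformative interaction
        ({"A": 1.0, "O": 0.0}, 0.0),     # active, output down: inconsistent
    ])
    def test_closed_forms(self, post, expected):
        ia = Interaction("i", promoter_genes=("A",), output_genes=("O",))
        assert interaction_consistency(ia, post) == pytest.approx(expected)

    def test_inhibited_output_flips(self):
        ia = Interaction("i", promoter_genes=("A",), output_genes=("O",),
                         output_inhibited=True)
        assert interaction_consistency(ia, {"A": 1.0, "O": 0.0}) == pytest.approx(1.0)

    def test_no_output_undefined(self):
        ia = Interaction("i", promoter_genes=("A",))
        assert interaction_consistency(ia, {"A": 0.8}) is None


def _posterior_frame(post, samples=("s1",)):
    return pd.DataFrame({s: post for s in samples}).T.T


class TestScorePathways:
    def test_mean_aggregation_of_interactions(self):
        ps = PathwaySet(pathways={"p": [
            Interaction("i1", promoter_genes=("A", "B")),
            Interaction("i2", promoter_genes=("A",), inhibitor_genes=("C",)),
        ]})
        post = pd.DataFrame({"s1": {"A": 0.9, "B": 0.8, "C": 0.3}})
        scorer = PathwayScorer(pathway_set=ps).fit(post)
        out = scorer.transform(post)
        assert out.activity.loc["p", "s1"] == pytest.approx((0.72 + 0.63) / 2)

    def test_duplicated_interaction_changes_mean_unless_equal(self):
        """Aggregation is a mean, not a sum: duplicating a non-mean-valued
        interaction moves the pathway score toward it."""
        i1 = Interaction("i1", promoter_genes=("A",))
        i2 = Interaction("i2", promoter_genes=("B",))
        post = pd.DataFrame({"s1": {"A": 0.9, "B": 0.5}})
        base = PathwaySet(pathways={"p": [i1, i2]})
        dup = PathwaySet(pathways={"p": [i1, i2, i2]})
        a_base = PathwayScorer(pathway_set=base).fit(post).transform(post)
        a_dup = PathwayScorer(pathway_set=dup).fit(post).transform(post)
        assert a_base.activity.iloc[0, 0] == pytest.approx(0.7)
        assert a_dup.activity.iloc[0, 0] == pytest.approx((0.9 + 0.5 + 0.5) / 3)

    def test_all_degenerate_closed_form(self):
        """With all posteriors 0.5, each interaction scores 0.5^k."""
        ps = PathwaySet(pathways={"p": [
            Interaction("i1", promoter_genes=("A", "B")),   # 0.25
            Interaction("i2", promoter_genes=("C",)),       # 0.5
        ]})
        post = pd.DataFrame({"s1": {"A": 0.5, "B": 0.5, "C": 0.5}})
        out = PathwayScorer(pathway_set=ps).fit(post).transform(post)
        assert out.activity.loc["p", "s1"] == pytest.approx((0.25 + 0.5) / 2)

    def test_low_coverage_pathway_excluded(self):
        ps = PathwaySet(pathways={
            "ok": [Interaction("i1", promoter_genes=("A",), output_genes=("B",))],
            "sparse": [Interaction("i2", promoter_genes=("X", "Y"),
                                   output_genes=("Z",))]})
        post = pd.DataFrame({"s1": {"A": 0.9, "B": 0.4}})
        out = PathwayScorer(pathway_set=ps, min_coverage=0.5).fit(post).transform(post)
        assert out.pathway_ids == ["ok"]
        assert "sparse" in out.excluded

    def test_scores_bounded_and_interaction_order_invariant(self, small_cohort):
        ds = small_cohort.datasets[0]
        models = fit_all_genes(ds.expression, seed=2)
        out = score_pathways(small_cohort.pathway_set, models, ds.expression)
        assert ((out.activity.to_numpy() >= 0) & (out.activity.to_numpy() <= 1)).all()
        cons = out.consistency.to_numpy()
        assert ((cons[np.isfinite(cons)] >= 0) & (cons[np.isfinite(cons)] <= 1)).all()
        # permute interaction order within every pathway
        perm = PathwaySet(pathways={pid: list(reversed(ias)) for pid, ias in
                                    small_cohort.pathway_set.pathways.items()})
        out2 = score_pathways(perm, models, ds.expression)
        np.testing.assert_allclose(out.activity.to_numpy(), out2.activity.to_numpy())

    def test_driver_activity_separates_latent_groups(self):
        from pathstrat import CohortConfig, generate_cohort
        cfg = CohortConfig(n_genes=40, n_samples_per_dataset=(120,), n_pathways=4,
                           pathway_size_range=(6, 10), driver_pathway_size=15,
                           state_coupling=1.0, decouple_fraction=0.0, seed=5)
        cohort = generate_cohort(cfg)
        ds = cohort.datasets[0]
        models = fit_all_genes(ds.expression, seed=5)
        out = score_pathways(cohort.pathway_set, models, ds.expression)
        act = out.activity.loc[cohort.driver_pathway_id]
        hi = act[ds.latent_state == 1].mean()
        lo = act[ds.latent_state == 0].mean()
        assert hi > lo
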