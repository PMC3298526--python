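"""Alteration calling, hypergeometric tails, Fisher omnibus, targeting scan."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathstrat import (AlterationSource, Interaction, PathwaySet, TargetingScan,
                       bonferroni_threshold, call_cnv, call_methylation,
                       fisher_omnibus, patient_pathway_p)
from pathstrat.exceptions import ConfigError, ValidationError


def _source(kind, rows, genes=None, samples=None):
    arr = np.atleast_2d(np.asarray(rows, dtype=float))
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j}" for j in range(arr.shape[1])]
    return AlterationSource(kind=kind, data=pd.DataFrame(arr, index=genes,
                                                         columns=samples))


class TestCalling:
    def test_cnv_threshold_rule(self):
        calls = call_cnv(_source("cnv", [[0.5, -0.5, 0.1]]))
        np.testing.assert_array_equal(calls.data.to_numpy()[0], [1, 1, 0])
        np.testing.assert_array_equal(calls.amplified.to_numpy()[0], [1, 0, 0])
        np.testing.assert_array_equal(calls.deleted.to_numpy()[0], [0, 1, 0])

    def test_cnv_boundary_strict(self):
        calls = call_cnv(_source("cnv", [[0.3, -0.3]]))
        assert calls.data.to_numpy().sum() == 0

    def test_cnv_zero_matrix(self):
        calls = call_cnv(_source("cnv", np.zeros((3, 4))))
        assert calls.data.to_numpy().sum() == 0

    def test_cnv_threshold_order_enforced(self):
        with pytest.raises(ConfigError):
            call_cnv(_source("cnv", [[0.0]]), amp_threshold=-0.3, del_threshold=0.3)

    def test_methylation_threshold_rule(self):
        calls = call_methylation(_source("methylation", [[0.9, 0.2]]))
        np.testing.assert_array_equal(calls.data.to_numpy()[0], [1, 0])

    def test_methylation_boundary_strict(self):
        calls = call_methylation(_source("methylation", [[0.5]]))
        assert calls.data.to_numpy().sum() == 0

    def test_methylation_all_zero(self):
        calls = call_methylation(_source("methylation", np.zeros((2, 3))))
        assert calls.data.to_numpy().sum() == 0


def enumeration_tail(x, M, K, N, inclusive=False):
    """Brute-force oracle: enumerate all C(M, N) pathway draws."""
    hits = 0
    total = 0
    altered = set(range(K))
    for draw in combinations(range(M), N):
        total += 1
        k = len(altered & set(draw))
        if (k >= x) if inclusive else (k > x):
            hits += 1
    return hits / total


class TestPatientPathwayP:
    def test_no_alterations_gives_zero(self):
        # K = 0: only the i=0 term exists and carries all mass
        assert patient_pathway_p(0, M=100, K=0, N=10) == 0.0

    def test_max_count_gives_zero(self):
        assert patient_pathway_p(3, M=10, K=3, N=5) == 0.0

    def test_matches_enumeration_small_case(self):
        p = patient_pathway_p(1, M=10, K=4, N=5)
        assert p == pytest.approx(enumeration_tail(1, 10, 4, 5), abs=1e-12)

    def test_inclusive_tail_matches_enumeration(self):
        p = patient_pathway_p(2, M=9, K=4, N=4, inclusive=True)
        assert p == pytest.approx(enumeration_tail(2, 9, 4, 4, inclusive=True),
                                  abs=1e-12)

    def test_monotone_nonincreasing_in_x(self):
        ps = [patient_pathway_p(x, M=40, K=12, N=8) for x in range(0, 9)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            patient_pathway_p(6, M=10, K=5, N=5)
        with pytest.raises(ValidationError):
            patient_pathway_p(1, M=10, K=12, N=5)

    def test_large_scale_no_overflow(self):
        p = patient_pathway_p(10, M=20000, K=2000, N=18)
        assert np.isfinite(p) and 0.0 <= p <= 1.0


class TestFisherOmnibus:
    def test_single_p_identity(self):
        for p1 in (0.001, 0.2, 0.77):
            stat, comb = fisher_omnibus([p1])
            assert comb == pytest.approx(p1, rel=1e-12)

    def test_all_ones(self):
        stat, comb = fisher_omnibus(np.ones(7))
        assert stat == 0.0 and comb == 1.0

    def test_permutation_invariance_and_monotonicity(self, rng):
        p = rng.uniform(0.01, 1.0, size=20)
        s1, c1 = fisher_omnibus(p)
        s2, c2 = fisher_omnibus(rng.permutation(p))
        assert c1 == pytest.approx(c2, rel=1e-12)
        p_better = p.copy()
        p_better[3] /= 10
        _, c3 = fisher_omnibus(p_better)
        assert c3 < c1

    def test_zero_floored_with_warning(self):
        with pytest.warns(UserWarning, match="flooring"):
            stat, comb = fisher_omnibus([0.0, 0.5])
        assert np.isfinite(stat) and comb > 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            fisher_omnibus([])


def test_bonferroni_threshold():
    assert bonferroni_threshold(0.05, 10) == pytest.approx(0.005)
    with pytest.raises(ConfigError):
        bonferroni_threshold(0.05, 0)


class TestTargetingScan:
    def _toy(self, rng, enriched=True):
        genes = [f"G{i}" for i in range(40)]
        pw = PathwaySet(pathways={
            "driver": [Interaction("a", promoter_genes=(g,))
                       for g in genes[:10]],
            "other": [Interaction("b", promoter_genes=(g,))
                      for g in genes[10:20]]})
        rate = np.full((40, 60), 0.05)
        if enriched:
            rate[:10] = 0.5
        vals = np.where(rng.uniform(size=(40, 60)) < rate, 0.8, 0.0)
        src = _source("cnv", vals, genes=genes,
                      samples=[f"S{j}" for j in range(60)])
        return call_cnv(src), pw

    def test_enriched_pathway_flagged(self, rng):
        calls, pw = self._toy(rng, enriched=True)
        scan = TargetingScan().fit(calls, pw)
        assert "driver" in scan.targeted_
        assert scan.bonferroni_alpha_ == pytest.approx(0.05 / 2)

    def test_pathway_without_called_genes_excluded(self, rng):
        calls, pw = self._toy(rng)
        pw.pathways["ghost"] = [Interaction("g", promoter_genes=("ZZZ",))]
        scan = TargetingScan().fit(calls, pw)
        assert scan.excluded_ == ["ghost"]
        # Bonferroni divides by tested pathways only
        assert scan.bonferroni_alpha_ == pytest.approx(0.05 / 2)

    def test_exclusive_convention_matches_patient_pathway_p(self, rng):
        calls, pw = self._toy(rng)
        scan = TargetingScan(inclusive=False).fit(calls, pw)
        res = next(r for r in scan.results_ if r.pathway_id == "driver")
        universe = sorted(set(calls.gene_ids) & pw.all_genes())
        mat = calls.data.loc[sorted(set(universe) & pw.genes("driver"))]
        j = 5
        K = int(calls.data.loc[universe].sum(axis=0).iloc[j])
        x = int(mat.sum(axis=0).iloc[j])
        expected = patient_pathway_p(x, M=len(universe), K=K, N=mat.shape[0])
        assert res.patient_p[j] == pytest.approx(expected, abs=1e-12)
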