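"""Mixture EM, information criteria, K selection and MQTL summaries.

The EM oracle used here seeds the algorithm from *every* partition of the
points into K non-empty groups, guaranteeing the global optimum on tiny
instances; the production fit (quantile restarts) must match it.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from metaqtl.meta import (
    MetaConfig,
    MixtureFit,
    criteria_table,
    em_fit,
    information_criteria,
    run_chromosome,
    select_k,
    summarize_mqtl,
)
from metaqtl.projection import ProjectedQTL

from conftest import make_qtl


def proj(position, ci_width=3.92, qtl_id="Q1", study="S1", lod=3.0, pve=8.0, chrom="1H"):
    """ProjectedQTL with sd = ci_width / 3.92."""
    rec = make_qtl(
        position, ci_lo=position - ci_width / 2, ci_hi=position + ci_width / 2,
        qtl_id=qtl_id, study=study, lod=lod, pve=pve, chrom=chrom,
    )
    return ProjectedQTL(
        rec, True, proj_position=position,
        proj_ci_lo=position - ci_width / 2, proj_ci_hi=position + ci_width / 2,
    )


def _all_partitions(indices, k):
    """All ways to split indices into k non-empty unlabeled groups."""
    if k == 1:
        yield [list(indices)]
        return
    first, rest = indices[0], indices[1:]
    for parts in _all_partitions(rest, k - 1):
        yield [[first]] + parts
    if len(rest) >= k:
        for parts in _all_partitions(rest, k):
            for i in range(len(parts)):
                yield parts[:i] + [[first] + parts[i]] + parts[i + 1:]


def _oracle_best_loglik(x, sd, k):
    """Best EM log-likelihood over restarts from every k-partition."""
    from metaqtl.meta import _em_single

    best = -np.inf
    prec = 1.0 / sd**2
    for parts in _all_partitions(list(range(len(x))), k):
        means0 = np.array(
            [np.sum(prec[g] * x[g]) / np.sum(prec[g]) for g in map(list, parts)]
        )
        ll = _em_single(x, sd, means0, 1000, 1e-12)[3]
        best = max(best, ll)
    return best


class TestEMFit:
    def test_k1_equal_sds_gives_plain_mean(self):
        fit = em_fit([10.0, 20.0], [1.0, 1.0], K=1)
        assert fit.means[0] == pytest.approx(15.0, abs=1e-10)

    def test_k1_equals_precision_weighted_mean(self):
        # x = {0, 30}, sd = {1, 2}: mean = (0/1 + 30/4) / (1/1 + 1/4) = 6
        fit = em_fit([0.0, 30.0], [1.0, 2.0], K=1)
        assert fit.means[0] == pytest.approx(6.0, abs=1e-10)

    def test_k1_closed_form_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(2, 30)
            x = rng.normal(50, 20, n)
            sd = rng.uniform(0.5, 5.0, n)
            fit = em_fit(x, sd, K=1)
            expected = np.sum(x / sd**2) / np.sum(1 / sd**2)
            assert fit.means[0] == pytest.approx(expected, abs=1e-10)

    def test_two_component_recovery(self):
        rng = np.random.default_rng(5)
        truth = np.array([20.0, 80.0])
        z = rng.integers(2, size=20)
        x = truth[z] + rng.normal(0, 2.0, 20)
        fit = em_fit(x, np.full(20, 2.0), K=2, seed=5)
        assert np.abs(np.sort(fit.means) - truth).max() < 1.0

    def test_loglik_nondecreasing_every_iteration(self):
        rng = np.random.default_rng(7)
        for rep in range(50):
            n = int(rng.integers(4, 25))
            x = rng.uniform(0, 100, n)
            sd = rng.uniform(0.2, 4.0, n)
            K = int(rng.integers(1, min(5, n) + 1))
            fit = em_fit(x, sd, K, seed=rep)
            diffs = np.diff(fit.loglik_trace)
            assert (diffs >= -1e-9).all(), f"decreasing loglik at rep {rep}"

    def test_invariants_of_fit(self):
        fit = em_fit([1.0, 2.0, 50.0, 52.0], [1.0, 1.0, 1.0, 1.0], K=2, seed=0)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(fit.resp.sum(axis=1), 1.0, atol=1e-9)
        assert list(fit.means) == sorted(fit.means)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            em_fit([1.0, 2.0], [1.0, 1.0], K=3)
        with pytest.raises(ValueError):
            em_fit([1.0, np.nan], [1.0, 1.0], K=1)
        with pytest.raises(ValueError):
            em_fit([1.0, 2.0], [1.0, 0.0], K=1)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_all_partition_oracle_on_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        x = np.sort(rng.uniform(0, 60, n))
        sd = rng.uniform(0.5, 3.0, n)
        for k in (2, 3):
            fit = em_fit(x, sd, k, seed=seed)
            oracle = _oracle_best_loglik(x, sd, k)
            assert fit.loglik >= oracle - 1e-6


class TestCriteria:
    def _fit(self, lnl, K, n):
        resp = np.zeros((n, K))
        resp[:, 0] = 1.0
        return MixtureFit(K, np.zeros(K), np.full(K, 1.0 / K), resp, lnl, True, 1, 0)

    def test_aic_formula(self):
        # lnL = -100, p = 2K-1 = 3 -> AIC = 200 + 6 = 206
        x, sd = np.zeros(50), np.ones(50)
        crits = information_criteria(self._fit(-100.0, 2, 50), x, sd)
        assert crits["AIC"] == pytest.approx(206.0)

    def test_bic_formula(self):
        x, sd = np.zeros(50), np.ones(50)
        crits = information_criteria(self._fit(-100.0, 2, 50), x, sd)
        assert crits["BIC"] == pytest.approx(200 + 3 * math.log(50))
        assert crits["AIC3"] == pytest.approx(209.0)
        assert crits["AICc"] == pytest.approx(206.0 + 2 * 3 * 4 / (50 - 4))

    def test_awe_reduces_to_closed_form_for_k1(self):
        # single component: hard classification likelihood equals the
        # mixture likelihood, so AWE = -2 lnL + 2 p (3/2 + ln n) with p = 1
        x = np.array([1.0, 3.0])
        sd = np.ones(2)
        fit = em_fit(x, sd, K=1)
        crits = information_criteria(fit, x, sd)
        expected = -2 * fit.loglik + 2 * 1 * (1.5 + math.log(2))
        assert crits["AWE"] == pytest.approx(expected, rel=1e-12)

    def test_aicc_undefined_when_n_too_small(self):
        x, sd = np.zeros(4), np.ones(4)
        crits = information_criteria(self._fit(-10.0, 2, 4), x, sd)  # p=3, n=4
        assert math.isnan(crits["AICc"])


class TestSelectK:
    def _table(self, votes):
        # build a criteria table whose per-criterion argmins equal `votes`
        ks = range(1, 7)
        data = {}
        for crit, kstar in zip(("AIC", "AICc", "AIC3", "BIC", "AWE"), votes):
            data[crit] = [abs(k - kstar) + 1.0 for k in ks]
        return pd.DataFrame(data, index=pd.Index(ks, name="K"))

    def test_unanimous(self):
        k, votes = select_k(self._table([4, 4, 4, 4, 4]))
        assert k == 4 and set(votes.values()) == {4}

    def test_tie_broken_toward_smallest(self):
        k, _ = select_k(self._table([2, 2, 3, 3, 5]))
        assert k == 2

    def test_single_point_selects_one(self):
        x, sd = np.array([5.0]), np.array([1.0])
        table, fits = criteria_table(x, sd, MetaConfig(k_max=20))
        k, _ = select_k(table)
        assert k == 1 and list(table.index) == [1]


class TestSummarize:
    def test_singleton_cluster_reproduces_qtl(self):
        p = proj(12.0, ci_width=3.92)
        fit = em_fit([12.0], [1.0], K=1)
        (m,) = summarize_mqtl(fit, [p], "1H")
        assert m.position == pytest.approx(12.0)
        assert m.ci_width == pytest.approx(2 * 1.959963984540054, rel=1e-6)
        assert m.n_qtl == 1 and m.name == "MQTL1H-1"

    def test_two_equal_members_shrink_ci_by_sqrt2(self):
        ps = [proj(10.0, qtl_id="Q1"), proj(10.0, qtl_id="Q2")]
        fit = em_fit([10.0, 10.0], [1.0, 1.0], K=1)
        (m,) = summarize_mqtl(fit, ps, "1H")
        single_width = 2 * 1.959963984540054
        assert m.ci_width == pytest.approx(single_width / math.sqrt(2), rel=1e-6)

    def test_mean_lod_pve_are_arithmetic_means(self):
        ps = [proj(10.0, qtl_id="Q1", lod=3.0, pve=8.0),
              proj(10.2, qtl_id="Q2", lod=5.0, pve=12.0)]
        fit = em_fit([10.0, 10.2], [1.0, 1.0], K=1)
        (m,) = summarize_mqtl(fit, ps, "1H")
        assert m.mean_lod == pytest.approx(4.0)
        assert m.mean_pve == pytest.approx(10.0)

    def test_mqtl_ci_no_wider_than_tightest_member(self):
        """Precision pooling: the MQTL CI is at most the narrowest member CI
        (hard membership makes the pooled precision a sum over members)."""
        rng = np.random.default_rng(9)
        for rep in range(10):
            n = int(rng.integers(2, 12))
            x = rng.normal(50, 0.5, n)
            widths = rng.uniform(1.0, 10.0, n)
            ps = [proj(float(xi), ci_width=float(w), qtl_id=f"Q{i}")
                  for i, (xi, w) in enumerate(zip(x, widths))]
            fit = em_fit(x, widths / 3.92, K=1)
            (m,) = summarize_mqtl(fit, ps, "1H", membership="hard")
            assert m.ci_width <= widths.min() + 1e-9

    def test_names_rank_ordered_by_position(self):
        ps = [proj(80.0, qtl_id="Q1"), proj(20.0, qtl_id="Q2"), proj(82.0, qtl_id="Q3")]
        x = np.array([80.0, 20.0, 82.0])
        fit = em_fit(x, np.ones(3), K=2, seed=0)
        ms = summarize_mqtl(fit, ps, "3H")
        assert [m.name for m in ms] == ["MQTL3H-1", "MQTL3H-2"]
        assert ms[0].position < ms[1].position


class TestRunChromosome:
    def test_single_qtl_yields_identical_mqtl(self):
        res = run_chromosome([proj(40.0)], MetaConfig())
        assert res.k_selected == 1
        assert len(res.mqtls) == 1
        assert res.mqtls[0].position == pytest.approx(40.0)

    def test_identical_positions_select_one_component(self):
        ps = [proj(10.0, qtl_id=f"Q{i}") for i in range(6)]
        res = run_chromosome(ps, MetaConfig())
        assert res.k_selected == 1
        assert len(res.mqtls) == 1

    def test_well_separated_clusters_recovered(self):
        rng = np.random.default_rng(21)
        centers = [20.0, 60.0, 100.0, 140.0, 180.0]
        ps = []
        i = 0
        for c in centers:
            for _ in range(8):
                x = float(rng.normal(c, 1.0))
                ps.append(proj(x, ci_width=3.92, qtl_id=f"Q{i}", study=f"S{i % 5}"))
                i += 1
        res = run_chromosome(ps, MetaConfig(seed=21))
        assert res.k_selected == 5
        est = sorted(m.position for m in res.mqtls)
        assert np.abs(np.array(est) - np.array(centers)).max() < 1.0

    def test_counts_conserved_including_unintegrated(self):
        rng = np.random.default_rng(2)
        ps = [proj(float(rng.normal(30, 1.0)), ci_width=3.92, qtl_id=f"Q{i}")
              for i in range(12)]
        # a displaced member: low precision (does not drag the mean) but its
        # own CI lies far from the cluster's pooled CI
        ps.append(proj(50.0, ci_width=2.0, qtl_id="Qout"))
        res = run_chromosome(ps, MetaConfig(seed=2, k_max=1))
        total = sum(m.n_qtl for m in res.mqtls) + len(res.unassigned)
        assert total == len(ps)
        assert any(p.record.qtl_id == "Qout" for p in res.unassigned)
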