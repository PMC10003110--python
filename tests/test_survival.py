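"""Cox fits, concordance, cutpoints, log-rank and BH adjustment."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from deltapcc.survival import (
    SurvivalData,
    bh_adjust,
    c_index,
    cox_univariate,
    logrank_test,
    optimal_cutpoint,
    screen_pairs,
)


def brute_force_c_index(time, event, eta, tie_value=0.0):
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j or not (time[i] > time[j] and event[j] == 1):
                continue
            den += 1
            if eta[i] < eta[j]:
                num += 1
            elif eta[i] == eta[j]:
                num += tie_value
    return num / den if den else float("nan")


def brute_force_logrank(time, event, group):
    """Direct O-E / V tabulation over distinct event times."""
    o_minus_e = v = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n_t, n1 = at_risk.sum(), (at_risk & group).sum()
        d_t = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & group).sum()
        o_minus_e += d1 - n1 * d_t / n_t
        if n_t > 1:
            v += d_t * (n1 / n_t) * (1 - n1 / n_t) * (n_t - d_t) / (n_t - 1)
    return o_minus_e**2 / v if v > 0 else 0.0


class TestCIndex:
    def test_perfect_concordance(self):
        d = SurvivalData([1, 2, 3], [1, 1, 1], [3, 2, 1])
        assert c_index(d) == 1.0

    def test_perfect_discordance(self):
        d = SurvivalData([1, 2, 3], [1, 1, 1], [1, 2, 3])
        assert c_index(d) == 0.0

    def test_censoring_fixture_vs_enumeration(self):
        t, e, eta = [5, 3, 4, 1], [0, 1, 1, 1], [0.2, 0.9, 0.4, 1.5]
        d = SurvivalData(t, e, eta)
        assert c_index(d) == pytest.approx(brute_force_c_index(t, e, eta))

    @pytest.mark.parametrize("tie_value", [0.0, 0.5])
    def test_random_instances_vs_enumeration(self, rng, tie_value):
        for _ in range(25):
            n = int(rng.integers(3, 25))
            t = rng.integers(1, 10, n).astype(float)
            e = rng.integers(0, 2, n)
            eta = rng.integers(0, 5, n).astype(float)  # ties likely
            d = SurvivalData(t, e, eta)
            got = c_index(d, tie_value=tie_value)
            want = brute_force_c_index(t, e, eta, tie_value)
            assert (np.isnan(got) and np.isnan(want)) or got == want

    def test_matches_lifelines_on_tie_free_data(self, rng):
        from lifelines.utils import concordance_index

        t = rng.exponential(10, 40)
        e = rng.integers(0, 2, 40)
        eta = rng.standard_normal(40)
        ours = c_index(SurvivalData(t, e, eta))
        # lifelines counts higher score with longer survival; negate eta
        assert ours == pytest.approx(concordance_index(t, -eta, e))

    def test_no_comparable_pairs_is_nan(self):
        assert np.isnan(c_index(SurvivalData([1, 1], [0, 0], [1, 2])))


class TestCoxUnivariate:
    def test_null_predictor_beta_near_zero(self, rng):
        n = 500
        x = rng.standard_normal(n)
        t = rng.exponential(100, n)
        res = cox_univariate(SurvivalData(t, np.ones(n, int), x))
        assert abs(res.beta) < 0.15
        assert res.hr == pytest.approx(np.exp(res.beta))

    def test_recovers_true_beta(self, rng):
        n = 500
        x = rng.standard_normal(n)
        t = rng.exponential(1.0 / (0.01 * np.exp(1.0 * x)))
        res = cox_univariate(SurvivalData(t, np.ones(n, int), x))
        assert res.beta == pytest.approx(1.0, abs=0.15)

    def test_constant_predictor_errors(self):
        with pytest.raises(ValueError, match="constant"):
            cox_univariate(SurvivalData([1, 2, 3], [1, 1, 1], [2, 2, 2]))

    def test_matches_r_coxph_efron(self, rng, tmp_path):
        """Independent oracle: R survival::coxph with Efron ties."""
        n = 80
        x = rng.standard_normal(n)
        t = np.round(rng.exponential(1.0 / (0.01 * np.exp(0.8 * x))), 1)
        e = (rng.random(n) > 0.25).astype(int)
        res = cox_univariate(SurvivalData(t, e, x))
        path = tmp_path / "surv.tsv"
        pd.DataFrame({"time": t, "event": e, "x": x}).to_csv(path, sep="\t", index=False)
        script = (
            "suppressMessages(library(survival)); "
            f'd <- read.table("{path}", header=TRUE); '
            'f <- coxph(Surv(time, event) ~ x, data=d, ties="efron"); '
            'cat(sprintf("%.10f", coef(f)))'
        )
        proc = subprocess.run(["Rscript", "-e", script],
                              capture_output=True, text=True, check=True)
        assert res.beta == pytest.approx(float(proc.stdout), abs=1e-5)

    def test_separation_is_flagged_and_capped(self):
        # predictor perfectly orders the death times: monotone likelihood
        t = np.arange(1.0, 13.0)
        x = -t
        res = cox_univariate(SurvivalData(t, np.ones(12, int), x))
        assert not res.converged
        assert np.isfinite(res.beta)


class TestLogrank:
    def test_identical_groups(self):
        t = np.array([1.0, 2, 3, 4])
        e = np.array([1, 1, 0, 1])
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_tabulated_oracle(self):
        ta, tb = np.array([1.0, 2, 3]), np.array([10.0, 20, 30])
        ea = eb = np.array([1, 1, 1])
        stat, p = logrank_test(ta, ea, tb, eb)
        time = np.concatenate([ta, tb])
        event = np.concatenate([ea, eb])
        group = np.array([False] * 3 + [True] * 3)
        assert stat == pytest.approx(brute_force_logrank(time, event, group))

    def test_permutation_p_distribution_uniform(self, rng):
        """Relabeling groups at random yields a uniform p-value distribution."""
        time = rng.exponential(10, 24)
        event = rng.integers(0, 2, 24)
        event[0] = 1
        pvals = []
        for _ in range(200):
            grp = rng.permutation(np.repeat([True, False], 12))
            _, p = logrank_test(time[grp], event[grp], time[~grp], event[~grp])
            pvals.append(p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestOptimalCutpoint:
    def test_separable_clusters(self, rng):
        n = 20
        time = np.concatenate([rng.uniform(1, 5, n // 2), rng.uniform(50, 90, n // 2)])
        event = np.concatenate([np.ones(n // 2, int), np.zeros(n // 2, int)])
        x = np.concatenate([np.full(n // 2, 10.0), np.full(n // 2, 1.0)])
        cut, stat, p = optimal_cutpoint(SurvivalData(time, event, x))
        assert cut == pytest.approx(5.5)
        assert p < 0.01

    def test_matches_brute_force_scan(self, rng):
        for _ in range(20):
            n = 30
            d = SurvivalData(
                rng.exponential(10, n), rng.integers(0, 2, n) | 1,
                rng.standard_normal(n),
            )
            cut, stat, _ = optimal_cutpoint(d)
            uniq = np.unique(d.predictor)
            mids = (uniq[:-1] + uniq[1:]) / 2
            best_stat, best_cut = -1.0, None
            for c in mids:
                grp = d.predictor > c
                if grp.sum() < 3 or (~grp).sum() < 3:
                    continue
                s = brute_force_logrank(d.time, d.event, grp)
                if s > best_stat:
                    best_stat, best_cut = s, c
            assert stat == pytest.approx(best_stat, abs=1e-9)
            assert cut == pytest.approx(best_cut)

    def test_statistic_agrees_with_lifelines_at_cut(self, rng):
        d = SurvivalData(
            rng.exponential(10, 40), np.ones(40, int), rng.standard_normal(40)
        )
        cut, stat, _ = optimal_cutpoint(d)
        grp = d.predictor > cut
        ll_stat, _ = logrank_test(d.time[grp], d.event[grp],
                                  d.time[~grp], d.event[~grp])
        assert stat == pytest.approx(ll_stat, rel=1e-9)

    def test_two_values_cut_at_midpoint(self):
        d = SurvivalData([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1],
                         [1.0, 1.0, 1.0, 3.0, 3.0, 3.0])
        cut, _, _ = optimal_cutpoint(d)
        assert cut == pytest.approx(2.0)

    def test_constant_predictor_errors(self):
        with pytest.raises(ValueError, match="distinct"):
            optimal_cutpoint(SurvivalData([1, 2, 3], [1, 1, 1], [5, 5, 5]))


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_formula(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_stay_equal(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    @given(
        p=st.lists(st.floats(1e-6, 1.0, exclude_min=False), min_size=2, max_size=20),
        seed=st.integers(0, 1000),
    )
    def test_order_invariance(self, p, seed):
        perm = np.random.default_rng(seed).permutation(len(p))
        direct = bh_adjust(p)
        via_perm = np.empty(len(p))
        via_perm[perm] = bh_adjust(np.asarray(p)[perm])
        assert np.allclose(direct, via_perm)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def _make_delta_clinical(rng, n_pairs=6, n_patients=80, prognostic_row=0, beta=1.5):
    """ΔPCC-style table plus clinical frame with one prognostic pair."""
    pairs = pd.MultiIndex.from_tuples(
        [(f"m{i}", f"r{i}") for i in range(n_pairs)], names=["mirna", "rna"]
    )
    patients = [f"t{i}" for i in range(n_patients)]
    values = rng.normal(0, 0.3, size=(n_pairs, n_patients))
    table = pd.DataFrame(values, index=pairs, columns=patients)
    hazard = 0.01 * np.exp(beta * np.abs(values[prognostic_row]))
    time = rng.exponential(1.0 / hazard)
    clinical = pd.DataFrame(
        {"os_time": time, "os_event": np.ones(n_patients, int)}, index=patients
    )
    return table, clinical


class TestScreenPairs:
    def test_planted_prognostic_pair_ranks_first(self, rng):
        table, clinical = _make_delta_clinical(rng)
        results = screen_pairs(table, clinical, alpha_adj=1.0)
        assert (results[0].mirna, results[0].rna) == ("m0", "r0")

    def test_alpha_one_returns_all_testable(self, rng):
        table, clinical = _make_delta_clinical(rng)
        results = screen_pairs(table, clinical, alpha_adj=1.0)
        assert len(results) == 6
        assert all(r.kept for r in results)

    def test_adjusted_monotone_and_sorted(self, rng):
        table, clinical = _make_delta_clinical(rng)
        results = screen_pairs(table, clinical, alpha_adj=0.01)
        raw = [r.logrank_p for r in results]
        assert raw == sorted(raw)
        assert all(r.logrank_p_adj >= r.logrank_p - 1e-15 for r in results)

    def test_permuted_survival_rarely_keeps_anything(self, rng):
        """Breaking the survival link by permutation almost never leaves a
        significant pair at adjusted p < 0.01."""
        table, clinical = _make_delta_clinical(rng)
        clean = 0
        for k in range(10):
            perm = clinical.sample(frac=1.0, random_state=k).reset_index(drop=True)
            perm.index = clinical.index
            results = screen_pairs(table, perm, alpha_adj=0.01)
            clean += sum(r.kept for r in results) == 0
        assert clean >= 9
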