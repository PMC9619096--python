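import numpy as np
import pytest
from scipy.stats import norm

from tonelab.analysis import (
    compare_groups,
    confusion,
    dprime_mafc,
    experience_correlation,
    holm_adjust,
    pc_given_dprime,
    summarize_log,
)
from tonelab.listener import ListenerParams, simulate_log


class TestPcGivenDprime:
    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_chance_at_zero_sensitivity(self, m):
        assert pc_given_dprime(0.0, m) == pytest.approx(1.0 / m, abs=1e-9)

    @pytest.mark.parametrize("d", [0.5, 1.0, 2.0])
    def test_2afc_closed_form(self, d):
        """For m=2 the integral collapses to Phi(d/sqrt(2))."""
        assert pc_given_dprime(d, 2) == pytest.approx(norm.cdf(d / np.sqrt(2)),
                                                      abs=1e-6)

    def test_matches_adaptive_quadrature(self):
        for d in (-1.0, 0.3, 1.61, 4.0):
            for m in (2, 3, 4):
                assert pc_given_dprime(d, m) == pytest.approx(
                    pc_given_dprime(d, m, method="quad"), abs=1e-8)

    def test_monte_carlo_oracle(self):
        """Max-rule simulation: signal N(d,1) vs m-1 noise draws."""
        rng = np.random.default_rng(123)
        n = 400_000
        for d, m in [(1.0, 3), (2.0, 4)]:
            signal = rng.normal(d, 1.0, n)
            noise = rng.normal(0.0, 1.0, (n, m - 1))
            mc = np.mean(signal > noise.max(axis=1))
            assert pc_given_dprime(d, m) == pytest.approx(mc, abs=0.005)

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            pc_given_dprime(1.0, 1)
        with pytest.raises(ValueError):
            pc_given_dprime(np.inf, 3)


class TestDprimeMafc:
    @pytest.mark.parametrize("d,m", [(0.1, 2), (0.5, 3), (1.0, 4), (2.5, 3), (4.0, 4)])
    def test_roundtrip_identity(self, d, m):
        back = dprime_mafc(pc_given_dprime(d, m), m)
        assert back.d_prime == pytest.approx(d, abs=1e-6)

    def test_zero_at_chance(self):
        assert dprime_mafc(1 / 3 + 1e-9, 3).d_prime == pytest.approx(0.0, abs=1e-6)

    def test_monotone_in_p(self):
        ds = [dprime_mafc(p, 3).d_prime for p in (0.4, 0.6, 0.8, 0.95)]
        assert ds == sorted(ds)
        assert ds[0] > 0

    def test_ceiling_clamped_with_n(self):
        res = dprime_mafc(1.0, 3, n=180)
        assert res.clamped
        assert res.p == pytest.approx(1 - 1 / 360)
        assert np.isfinite(res.d_prime)

    def test_floor_clamped_with_n(self):
        res = dprime_mafc(0.2, 4, n=100)
        assert res.clamped
        assert res.p == pytest.approx(0.25 + 1 / 200)
        assert res.d_prime == pytest.approx(0.0, abs=0.1)

    def test_edges_without_n_rejected(self):
        with pytest.raises(ValueError):
            dprime_mafc(1.0, 3)
        with pytest.raises(ValueError):
            dprime_mafc(0.3, 3)
        with pytest.raises(ValueError):
            dprime_mafc(1.2, 3)

    def test_zero_proportion_clamped_with_n(self):
        res = dprime_mafc(0.0, 3, n=180)
        assert res.clamped
        assert res.p == pytest.approx(1 / 3 + 1 / 360)


class TestSummaries:
    def test_pitch_only_listener_hits_clamped_ceiling(self, di_plan, manifest):
        log = simulate_log(di_plan, manifest, ListenerParams(50, 0, 0), seed=31)
        s = summarize_log(log, subsets=("Cov", "Conf")).set_index("subset")
        assert s.loc["Cov", "p"] == 1.0 and s.loc["Conf", "p"] == 1.0
        assert s["clamped"].all()

    def test_chance_listener_dprime_near_zero(self, di_plan, manifest):
        log = simulate_log(di_plan, manifest, ListenerParams(0, 0, 0), seed=32)
        s = summarize_log(log, subsets=("Di",)).set_index("subset")
        assert abs(s.loc["Di", "d_prime"]) < 0.35

    def test_empty_subset_reported_not_dropped(self, di_plan, manifest):
        log = simulate_log(di_plan, manifest, ListenerParams(2, 0, 0), seed=33)
        s = summarize_log(log, subsets=("Mono",)).set_index("subset")
        assert s.loc["Mono", "n"] == 0
        assert np.isnan(s.loc["Mono", "p"])


class TestConfusion:
    def test_pitch_only_identity(self, di_plan, manifest):
        log = simulate_log(di_plan, manifest, ListenerParams(50, 0, 0), seed=41)
        mat = confusion(log, "Di")
        assert np.allclose(np.diag(mat.values), 100.0)

    def test_rows_sum_to_100(self, di_plan, manifest):
        log = simulate_log(di_plan, manifest, ListenerParams(1, 1, 0.2), seed=42)
        mat = confusion(log, "Di")
        assert np.allclose(mat.sum(axis=1), 100.0, atol=0.1)

    def test_chance_cells_near_uniform(self, di_plan, manifest):
        log = simulate_log(di_plan, manifest, ListenerParams(0, 0, 0), seed=43)
        mat = confusion(log, "Di")
        assert np.all(np.abs(mat.values - 100 / 3) < 16)

    def test_loudness_only_mass_at_loudness_tones(self, di_plan, manifest):
        """Errors of a loudness-driven listener land exactly on the tone the
        loudness contour implies: each off-diagonal cell gets one loudness
        variant of three, i.e. ~33%."""
        log = simulate_log(di_plan, manifest, ListenerParams(0, 50, 0), seed=44)
        mat = confusion(log, "Di")
        off = mat.values[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 100 / 3, atol=1e-9)


class TestCompareGroups:
    def test_identical_paired_vectors_no_effect(self):
        res = compare_groups([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res["p_value"] == 1.0

    def test_holm_stepdown_hand_computed(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_family_adjustment_applied(self):
        res = compare_groups([1, 2, 3, 4, 5], [2, 3, 4, 5, 6], "paired",
                             family_pvalues=[0.01])
        assert res["p_adjusted"] >= res["p_value"]

    def test_small_samples_refused(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            compare_groups([1, 2], [2, 3])

    def test_unpaired_rank_sum_direction(self):
        rng = np.random.default_rng(0)
        lo = rng.normal(0, 1, 20)
        hi = rng.normal(2, 1, 20)
        res = compare_groups(lo, hi, "unpaired")
        assert res["p_value"] < 0.001
        assert res["median_a"] < res["median_b"]


class TestExperienceCorrelation:
    def test_perfect_monotone(self):
        out = experience_correlation([1, 2, 3, 4, 5], [2, 4, 5, 8, 9])
        assert out["rho"] == pytest.approx(1.0)

    def test_reversed(self):
        out = experience_correlation([5, 4, 3, 2, 1], [2, 4, 5, 8, 9])
        assert out["rho"] == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            experience_correlation([1.0] * 5, [1, 2, 3, 4, 5])

    def test_noisy_monotone_recovery(self):
        """Scores = monotone(experience) + noise at n=17: the recovered rho
        tracks the generating rank correlation within 0.15 on average."""
        from scipy.stats import spearmanr
        rng = np.random.default_rng(7)
        # population rank correlation of the generative model, by large sample
        big_x = rng.uniform(1, 18, 20000)
        big_y = 0.5 * big_x + rng.normal(0, 2.0, 20000)
        rho_pop = spearmanr(big_y, big_x).statistic
        rhos = []
        for _ in range(100):
            exp_years = rng.uniform(1, 18, 17)
            scores = 0.5 * exp_years + rng.normal(0, 2.0, 17)
            rhos.append(experience_correlation(scores, exp_years)["rho"])
        assert abs(np.mean(rhos) - rho_pop) < 0.15
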