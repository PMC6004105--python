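import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pstfst.markers import (
    allele_frequencies,
    band_frequencies,
    diversity_summary,
    estimate_null_freq,
    fit_beta_prior,
    fst_wright,
    gst_partition,
    nei_li_distance,
)
from pstfst.simulate import SimulationConfig, simulate_markers

from conftest import make_markers


class TestBandFrequencies:
    def test_direct_count(self):
        m = make_markers([[1, 1], [1, 0], [1, 0], [0, 0]], ["A"] * 4)
        _, freq, n_eff = band_frequencies(m)
        assert freq[0, 0] == 0.75 and freq[0, 1] == 0.25
        assert n_eff[0, 0] == 4

    def test_all_missing_cell_flagged(self):
        m = make_markers(
            [[1, np.nan], [0, np.nan], [1, 1], [0, 1]], ["A", "A", "B", "B"]
        )
        _, freq, n_eff = band_frequencies(m)
        assert np.isnan(freq[0, 1]) and n_eff[0, 1] == 0

    def test_matches_loop_oracle(self, rng):
        bands = (rng.random((12, 8)) < 0.5).astype(float)
        bands[rng.random((12, 8)) < 0.1] = np.nan
        pops = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        m = make_markers(bands, pops)
        names, freq, n_eff = band_frequencies(m)
        for i, p in enumerate(names):
            rows = [r for r, q in enumerate(pops) if q == p]
            for j in range(8):
                vals = [bands[r, j] for r in rows if np.isfinite(bands[r, j])]
                if vals:
                    assert freq[i, j] == pytest.approx(np.mean(vals))
                    assert n_eff[i, j] == len(vals)
                else:
                    assert np.isnan(freq[i, j])


class TestNullFreqEstimators:
    def test_sqrt_examples(self):
        assert estimate_null_freq(4, 4, "sqrt") == 1.0
        assert estimate_null_freq(1, 4, "sqrt") == 0.5

    def test_bayes_matches_quadrature_oracle(self):
        # E[sqrt(x)] under the Beta(3, 9) posterior, scipy.integrate.quad
        expected = 0.4847057640125677
        got = estimate_null_freq(2, 10, "bayes_nonuniform", prior=(1.0, 1.0))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_m_greater_than_n_rejected(self):
        with pytest.raises(ValueError):
            estimate_null_freq(5, 4, "sqrt")

    def test_bad_prior_rejected(self):
        with pytest.raises(ValueError):
            estimate_null_freq(1, 4, "bayes_nonuniform", prior=(0.0, 1.0))

    @pytest.mark.parametrize("method", ["sqrt", "lynch_milligan", "bayes_nonuniform"])
    def test_monotone_in_m(self, method):
        n = 20
        prior = (2.0, 3.0) if method == "bayes_nonuniform" else None
        q = [estimate_null_freq(m, n, method, prior=prior) for m in range(n + 1)]
        assert np.all(np.diff(q) >= -1e-12)

    def test_bayes_converges_to_sqrt(self):
        n = 10000
        for frac in (0.1, 0.3, 0.5, 0.7, 0.9):
            m = int(frac * n)
            b = estimate_null_freq(m, n, "bayes_nonuniform", prior=(2.0, 2.0))
            s = estimate_null_freq(m, n, "sqrt")
            assert abs(b - s) < 0.01

    def test_lynch_milligan_corrects_upwards(self):
        # the sqrt estimator is biased down; the correction must raise it
        assert estimate_null_freq(5, 20, "lynch_milligan") > estimate_null_freq(
            5, 20, "sqrt"
        )


class TestBetaPrior:
    def test_method_of_moments_hand_value(self):
        # mean 0.5, variance 0.05: ratio = 0.25/0.05 - 1 = 4 -> a = b = 2
        vals = np.array([0.5 + d for d in (-0.3, -0.1, 0.1, 0.3)])
        vals = (vals - vals.mean()) / vals.std(ddof=1) * np.sqrt(0.05) + 0.5
        a, b = fit_beta_prior(vals)
        assert a == pytest.approx(2.0, rel=1e-9)
        assert b == pytest.approx(2.0, rel=1e-9)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="uniform prior"):
            fit_beta_prior(np.full(10, 0.4))

    def test_simulation_recovery(self, rng):
        x = rng.beta(3.0, 7.0, size=10000)
        a, b = fit_beta_prior(x)
        assert abs(a - 3.0) / 3.0 < 0.1
        assert abs(b - 7.0) / 7.0 < 0.1


class TestDiversity:
    def test_monomorphic_matrix(self):
        m = make_markers(np.ones((6, 10)), ["A"] * 3 + ["B"] * 3)
        df = diversity_summary(m)
        per_pop = df[df.population != "MEAN(SD)"]
        assert (per_pop.pct_polymorphic == 0).all()
        assert (per_pop.H_nei == 0).all()
        assert (per_pop.n_private_bands == 0).all()

    def test_private_band(self):
        bands = np.array(
            [[1, 1], [1, 0], [0, 1], [0, 0]], dtype=float
        )  # L1 present only in pop A
        m = make_markers(bands, ["A", "A", "B", "B"])
        df = diversity_summary(m)
        assert df.loc[df.population == "A", "n_private_bands"].item() == 1
        assert df.loc[df.population == "B", "n_private_bands"].item() == 0

    def test_unbiased_h_exceeds_h(self, small_marker_matrix):
        df = diversity_summary(small_marker_matrix)
        per_pop = df[df.population != "MEAN(SD)"]
        assert (per_pop.UH_nei >= per_pop.H_nei).all()
        # factor 2n/(2n-1) with n = 5 individuals, no missing data
        assert np.allclose(per_pop.UH_nei, per_pop.H_nei * 10 / 9)

    def test_percent_polymorphic_range(self, small_marker_matrix):
        df = diversity_summary(small_marker_matrix)
        assert ((df.pct_polymorphic >= 0) & (df.pct_polymorphic <= 100)).all()
        assert ((df.H_nei >= 0) & (df.H_nei <= 0.5)).all()


class TestGstPartition:
    def test_opposite_fixation(self):
        bands = np.vstack([np.ones((3, 4)), np.zeros((3, 4))])
        m = make_markers(bands, ["A"] * 3 + ["B"] * 3)
        part = gst_partition(allele_frequencies(m, method="sqrt"))
        assert part.H_S == pytest.approx(0.0)
        assert part.H_T == pytest.approx(0.5)
        assert part.G_ST == pytest.approx(1.0)
        assert part.Nm == 0.0

    def test_identical_populations(self):
        block = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])  # polymorphic
        bands = np.vstack([block, block])  # same frequencies in both pops
        m = make_markers(bands, ["A"] * 3 + ["B"] * 3)
        part = gst_partition(allele_frequencies(m, method="sqrt"))
        assert part.G_ST == pytest.approx(0.0, abs=1e-12)
        assert part.Nm is None

    def test_fmodel_recovery(self):
        cfg = SimulationConfig(
            n_pops=20, n_ind=50, n_loci=500, F=0.2, q_bar=0.6, theta=4.0, seed=42
        )
        m = simulate_markers(cfg)
        part = gst_partition(allele_frequencies(m, method="sqrt"))
        assert abs(part.G_ST - 0.2) < 0.03


class TestFstWright:
    def test_identical_populations_near_zero(self, rng):
        profile = (rng.random(100) < 0.5).astype(float)
        bands = np.tile(profile, (12, 1))
        flip = rng.random((12, 100)) < 0.2  # shared noise pattern per individual
        bands = np.abs(bands - flip.astype(float))
        pops = ["A"] * 6 + ["B"] * 6
        m = make_markers(bands, pops)
        res = fst_wright(m, n_boot=0, n_perm=200, seed=1)
        assert abs(res.fst_overall) < 0.05
        assert res.perm_p > 0.2

    def test_fixed_opposite_is_one(self):
        bands = np.vstack([np.ones((4, 50)), np.zeros((4, 50))])
        m = make_markers(bands, ["A"] * 4 + ["B"] * 4)
        for method in ("beta_fmodel", "sqrt"):
            res = fst_wright(m, method=method, n_boot=0, n_perm=0)
            assert res.fst_overall == pytest.approx(1.0, abs=1e-6)

    def test_two_population_pairwise_equals_overall(self, rng):
        bands = (rng.random((16, 60)) < rng.random(60)).astype(float)
        m = make_markers(bands, ["A"] * 8 + ["B"] * 8)
        res = fst_wright(m, n_boot=0, n_perm=0)
        assert res.fst_pairwise.values[0, 1] == pytest.approx(
            res.fst_overall, abs=1e-12
        )

    def test_recovery_at_study_scale(self):
        cfg = SimulationConfig(n_pops=10, n_ind=15, n_loci=171, F=0.365, seed=7)
        m = simulate_markers(cfg)
        res = fst_wright(m, n_boot=200, n_perm=0, seed=7)
        assert abs(res.fst_overall - 0.365) < 0.05
        assert res.ci95[0] <= res.fst_overall <= res.ci95[1]

    def test_recovery_within_three_mc_standard_errors(self):
        # F-model recovery across the F grid at 200 loci, 10 pops x 15 ind
        for F in (0.05, 0.2, 0.365, 0.6):
            ests = []
            for seed in range(10):
                cfg = SimulationConfig(
                    n_pops=10, n_ind=15, n_loci=200, F=F, seed=1000 + seed
                )
                ests.append(
                    fst_wright(simulate_markers(cfg), n_boot=0, n_perm=0).fst_overall
                )
            se = np.std(ests, ddof=1) / np.sqrt(len(ests))
            assert abs(np.mean(ests) - F) < 3 * se + 1e-3

    def test_permutation_detects_structure(self):
        cfg = SimulationConfig(n_pops=4, n_ind=10, n_loci=80, F=0.3, seed=3)
        m = simulate_markers(cfg)
        res = fst_wright(m, n_boot=0, n_perm=199, seed=3)
        assert res.perm_p == pytest.approx(1 / 200)

    def test_requires_two_populations(self, rng):
        bands = (rng.random((4, 10)) < 0.5).astype(float)
        m = make_markers(bands, ["A"] * 4)
        with pytest.raises(ValueError):
            fst_wright(m)


class TestNeiLi:
    def test_examples(self):
        bands = np.array([[1, 1, 0], [1, 0, 1], [1, 1, 0]], dtype=float)
        m = make_markers(bands, ["A", "A", "B"])
        D = nei_li_distance(m).values
        assert D[0, 1] == pytest.approx(0.5)  # 1 - 2*1/(2+2)
        assert D[0, 2] == pytest.approx(0.0)  # identical profiles

    def test_disjoint_profiles(self):
        bands = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=float)
        m = make_markers(bands, ["A", "B"])
        assert nei_li_distance(m).values[0, 1] == pytest.approx(1.0)

    def test_matches_dice_set_oracle(self, rng):
        bands = (rng.random((8, 25)) < 0.5).astype(float)
        bands[:, 0] = 1.0  # guarantee non-empty profiles
        m = make_markers(bands, ["A"] * 4 + ["B"] * 4)
        D = nei_li_distance(m).values
        for i in range(8):
            for j in range(8):
                si = {k for k in range(25) if bands[i, k] == 1}
                sj = {k for k in range(25) if bands[j, k] == 1}
                dice = 2 * len(si & sj) / (len(si) + len(sj))
                assert D[i, j] == pytest.approx(1 - dice, abs=1e-9)

    def test_all_zero_profile_rejected(self):
        bands = np.array([[0, 0], [1, 1]], dtype=float)
        m = make_markers(bands, ["A", "B"])
        with pytest.raises(ValueError, match="ind1"):
            nei_li_distance(m)


@settings(max_examples=25, deadline=None)
@given(
    m=st.integers(min_value=0, max_value=12),
    a=st.floats(min_value=0.1, max_value=5.0),
    b=st.floats(min_value=0.1, max_value=5.0),
)
def test_bayes_estimate_stays_in_unit_interval(m, a, b):
    q = estimate_null_freq(m, 12, "bayes_nonuniform", prior=(a, b))
    assert 0.0 < q < 1.0
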