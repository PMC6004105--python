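import numpy as np
import pytest

from pstfst.amova import amova, pairwise_sq_euclidean
from pstfst.io import LabelledDistanceMatrix

from conftest import make_markers


def amova_trace_oracle(X, pops, regions=None):
    """Independent AMOVA oracle.

    Sums of squares come from per-locus one-way sums (not distances); the
    expected-mean-square coefficients are obtained numerically from trace
    identities E[x'Ax] = tr(A Cov) with Cov = sigma_a^2 B_region +
    sigma_b^2 B_pop + sigma_c^2 I, then the linear system is solved with
    numpy. Completely separate from the implementation's distance algebra
    and closed-form unequal-size coefficients.
    """
    X = np.asarray(X, dtype=float)
    pops = np.asarray(pops)
    N = len(pops)

    def proj(labels):
        P = np.zeros((N, N))
        for g in set(labels):
            ix = np.flatnonzero(labels == g)
            P[np.ix_(ix, ix)] = 1.0 / len(ix)
        return P

    def block(labels):
        B = np.zeros((N, N))
        for g in set(labels):
            ix = np.flatnonzero(labels == g)
            B[np.ix_(ix, ix)] = 1.0
        return B

    Pg, P1 = proj(pops), np.ones((N, N)) / N
    I = np.eye(N)
    B_pop = block(pops)

    def ss(A):
        return float(sum(x @ A @ x for x in X.T))

    if regions is None:
        A_w, A_a = I - Pg, Pg - P1
        coef = np.array(
            [
                [np.trace(A_a @ B_pop), np.trace(A_a)],
                [np.trace(A_w @ B_pop), np.trace(A_w)],
            ]
        )
        rhs = np.array([ss(A_a), ss(A_w)])
        sigma_b, sigma_c = np.linalg.solve(coef, rhs)
        return {
            "SS_among": rhs[0],
            "SS_within": rhs[1],
            "sigma_a": 0.0,
            "sigma_b": sigma_b,
            "sigma_c": sigma_c,
        }
    region_labels = np.asarray([regions[p] for p in pops])
    Pr, B_reg = proj(region_labels), block(region_labels)
    A_w, A_b, A_a = I - Pg, Pg - Pr, Pr - P1
    coef = np.array(
        [
            [np.trace(A @ B_reg), np.trace(A @ B_pop), np.trace(A)]
            for A in (A_a, A_b, A_w)
        ]
    )
    rhs = np.array([ss(A_a), ss(A_b), ss(A_w)])
    sigma_a, sigma_b, sigma_c = np.linalg.solve(coef, rhs)
    return {
        "SS_regions": rhs[0],
        "SS_among": rhs[1],
        "SS_within": rhs[2],
        "sigma_a": sigma_a,
        "sigma_b": sigma_b,
        "sigma_c": sigma_c,
    }


class TestSquaredEuclidean:
    def test_examples(self):
        m = make_markers([[1, 0, 1], [0, 0, 1], [1, 0, 1]], ["A", "A", "B"])
        D = pairwise_sq_euclidean(m).values
        assert D[0, 1] == 1.0
        assert D[0, 2] == 0.0

    def test_matches_mismatch_loop(self, rng):
        bands = (rng.random((6, 10)) < 0.5).astype(float)
        m = make_markers(bands, ["A"] * 3 + ["B"] * 3)
        D = pairwise_sq_euclidean(m).values
        for i in range(6):
            for j in range(6):
                assert D[i, j] == sum(bands[i] != bands[j])

    def test_missing_rescaling(self):
        # 1 mismatch over 2 shared loci, 4 loci total -> 1 * 4/2 = 2
        bands = np.array(
            [[1, 0, np.nan, np.nan], [0, 0, 1, 1]], dtype=float
        )
        m = make_markers(bands, ["A", "B"])
        assert pairwise_sq_euclidean(m).values[0, 1] == pytest.approx(2.0)


class TestAmovaOneLevel:
    def test_perfect_structure(self):
        bands = np.vstack([np.ones((2, 6)), np.zeros((2, 6))])
        m = make_markers(bands, ["A", "A", "B", "B"])
        res = amova(pairwise_sq_euclidean(m), m.population_of, n_perm=0)
        assert res.phi_st == pytest.approx(1.0)
        assert res.sigma2_c == pytest.approx(0.0)

    def test_all_identical_flagged(self):
        bands = np.ones((6, 5))
        m = make_markers(bands, ["A"] * 3 + ["B"] * 3)
        res = amova(pairwise_sq_euclidean(m), m.population_of, n_perm=0)
        assert res.sigma2_b == 0.0 and res.sigma2_c == 0.0
        assert np.isnan(res.phi_st)

    def test_matches_trace_oracle(self, rng):
        bands = (rng.random((9, 12)) < 0.5).astype(float)
        pops = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        m = make_markers(bands, pops)
        res = amova(pairwise_sq_euclidean(m), m.population_of, n_perm=0)
        oracle = amova_trace_oracle(bands, pops)
        tab = res.table.set_index("stratum")
        assert tab.loc["among_populations", "SS"] == pytest.approx(
            oracle["SS_among"], abs=1e-9
        )
        assert tab.loc["within_populations", "SS"] == pytest.approx(
            oracle["SS_within"], abs=1e-9
        )
        assert res.sigma2_raw[1] == pytest.approx(oracle["sigma_b"], abs=1e-9)
        assert res.sigma2_raw[2] == pytest.approx(oracle["sigma_c"], abs=1e-9)

    def test_unequal_sizes_match_oracle(self, rng):
        bands = (rng.random((10, 15)) < 0.4).astype(float)
        pops = ["A"] * 2 + ["B"] * 5 + ["C"] * 3
        m = make_markers(bands, pops)
        res = amova(pairwise_sq_euclidean(m), m.population_of, n_perm=0)
        oracle = amova_trace_oracle(bands, pops)
        assert res.sigma2_raw[1] == pytest.approx(oracle["sigma_b"], abs=1e-9)
        assert res.sigma2_raw[2] == pytest.approx(oracle["sigma_c"], abs=1e-9)

    def test_ss_decomposition_and_df(self, small_marker_matrix):
        m = small_marker_matrix
        res = amova(pairwise_sq_euclidean(m), m.population_of, n_perm=0)
        tab = res.table.set_index("stratum")
        assert tab.loc["total", "SS"] == pytest.approx(
            tab.loc["among_populations", "SS"] + tab.loc["within_populations", "SS"],
            abs=1e-9,
        )
        assert tab.loc["total", "df"] == m.n_individuals - 1
        assert sum(res.percentages.values()) == pytest.approx(100.0, abs=1e-6)

    def test_phi_invariant_under_relabelling(self, rng):
        bands = (rng.random((8, 10)) < 0.5).astype(float)
        pops = ["A"] * 4 + ["B"] * 4
        m = make_markers(bands, pops)
        base = amova(pairwise_sq_euclidean(m), m.population_of, n_perm=0).phi_st
        # permute loci and individuals within populations
        perm_loci = rng.permutation(10)
        order = np.concatenate([rng.permutation(4), 4 + rng.permutation(4)])
        m2 = make_markers(bands[np.ix_(order, perm_loci)], pops)
        assert amova(
            pairwise_sq_euclidean(m2), m2.population_of, n_perm=0
        ).phi_st == pytest.approx(base, abs=1e-12)

    def test_permutation_p_detects_structure(self):
        rng = np.random.default_rng(5)
        profile = (rng.random(40) < 0.5).astype(float)
        flip = lambda: np.abs(profile - (rng.random((5, 40)) < 0.1))
        bands = np.vstack([flip(), 1 - flip()])  # two near-opposite groups
        pops = ["A"] * 5 + ["B"] * 5
        m = make_markers(bands, pops)
        res = amova(pairwise_sq_euclidean(m), m.population_of, n_perm=199, seed=1)
        assert res.p_values["phi_st"] <= 0.05


class TestAmovaTwoLevel:
    def test_matches_trace_oracle(self, rng):
        bands = (rng.random((12, 14)) < 0.5).astype(float)
        pops = ["A"] * 3 + ["B"] * 3 + ["C"] * 3 + ["D"] * 3
        regions = {"A": "R1", "B": "R1", "C": "R2", "D": "R2"}
        m = make_markers(bands, pops)
        res = amova(
            pairwise_sq_euclidean(m), m.population_of, regions=regions, n_perm=0
        )
        oracle = amova_trace_oracle(bands, pops, regions)
        assert res.sigma2_raw[0] == pytest.approx(oracle["sigma_a"], abs=1e-9)
        assert res.sigma2_raw[1] == pytest.approx(oracle["sigma_b"], abs=1e-9)
        assert res.sigma2_raw[2] == pytest.approx(oracle["sigma_c"], abs=1e-9)
        tab = res.table.set_index("stratum")
        assert tab.loc["among_regions", "SS"] == pytest.approx(
            oracle["SS_regions"], abs=1e-9
        )

    def test_single_region_collapses_to_one_level(self, rng):
        bands = (rng.random((9, 10)) < 0.5).astype(float)
        pops = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        m = make_markers(bands, pops)
        one = amova(pairwise_sq_euclidean(m), m.population_of, n_perm=0)
        two = amova(
            pairwise_sq_euclidean(m),
            m.population_of,
            regions={"A": "R", "B": "R", "C": "R"},
            n_perm=0,
        )
        assert two.phi_st == pytest.approx(one.phi_st, abs=1e-12)
        assert two.sigma2_b == pytest.approx(one.sigma2_b, abs=1e-12)
        assert two.sigma2_c == pytest.approx(one.sigma2_c, abs=1e-12)

    def test_phi_identity(self, rng):
        bands = (rng.random((16, 20)) < 0.5).astype(float)
        pops = sum([[p] * 4 for p in "ABCD"], [])
        regions = {"A": "R1", "B": "R1", "C": "R2", "D": "R2"}
        m = make_markers(bands, pops)
        res = amova(
            pairwise_sq_euclidean(m), m.population_of, regions=regions, n_perm=49,
            seed=2,
        )
        a, b, c = res.sigma2_raw
        assert res.phi_st == pytest.approx((a + b) / (a + b + c), abs=1e-12)
        assert set(res.p_values) == {"phi_st", "phi_sc", "phi_rt"}
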