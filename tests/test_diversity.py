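import itertools

import numpy as np
import pandas as pd
import pytest

from skypurge.core import MISSING, DistanceMatrix
from skypurge.diversity import (
    WindowSpec, environment_distance_matrix, genomewide_fst, great_circle_matrix,
    ld_decay_curve, linearized_fst_matrix, make_windows, mantel_test,
    private_allele_counts, windowed_fst, windowed_pi, windowed_tajimas_d,
)


def one_window(length=10_000):
    return pd.DataFrame({"chrom": ["Chr1"], "start": [1], "end": [length]})


class TestWindows:
    def test_tiling_and_terminal_truncation(self):
        w = make_windows({"Chr1": 250_000}, WindowSpec(100_000, 10_000))
        assert w.iloc[0].tolist() == ["Chr1", 1, 100_000]
        assert w.iloc[1].tolist() == ["Chr1", 10_001, 110_000]
        assert w.iloc[-1]["end"] == 250_000
        spans = w["end"] - w["start"] + 1
        assert (spans[:-1] <= 100_000).all()


class TestPi:
    def test_single_site_two_diploids(self, gm_factory):
        gm = gm_factory([[0, 2]], pos=[500], pops={"s0": "P", "s1": "P"})
        out = windowed_pi(gm, "P", one_window())
        # 4 alleles, p=0.5: unbiased per-site pi = 4/6 of pairs differing = 2/3
        assert out["value"].iloc[0] == pytest.approx((2 / 3) / 10_000)
        assert out["n_variants"].iloc[0] == 1

    def test_empty_window_is_zero(self, gm_factory):
        gm = gm_factory([[0, 2]], pos=[50_000], pops={"s0": "P", "s1": "P"})
        w = pd.DataFrame({"chrom": ["Chr1"], "start": [1], "end": [10_000]})
        assert windowed_pi(gm, "P", w)["value"].iloc[0] == 0.0

    def test_fully_missing_site_excluded(self, gm_factory):
        gm = gm_factory([[MISSING, MISSING], [0, 2]], pos=[100, 200],
                        pops={"s0": "P", "s1": "P"})
        out = windowed_pi(gm, "P", one_window())
        assert out["n_variants"].iloc[0] == 1

    def test_unknown_population_errors(self, gm_factory):
        gm = gm_factory([[0, 2]], pops={"s0": "P", "s1": "P"})
        with pytest.raises(KeyError):
            windowed_pi(gm, "nope", one_window())


class TestTajimasD:
    def test_no_segregating_sites_undefined(self, gm_factory):
        gm = gm_factory([[0, 0]], pops={"s0": "P", "s1": "P"})
        assert np.isnan(windowed_tajimas_d(gm, "P", one_window())["value"].iloc[0])

    def test_balanced_site_positive(self, gm_factory):
        # n=4 alleles, S=1, p=0.5: D = (2/3 - 6/11)/sqrt(e1)
        gm = gm_factory([[1, 1]], pops={"s0": "P", "s1": "P"})
        d = windowed_tajimas_d(gm, "P", one_window())["value"].iloc[0]
        assert d == pytest.approx(1.6329931618554543, abs=1e-9)

    def test_singleton_negative(self, gm_factory):
        gm = gm_factory([[1, 0]], pops={"s0": "P", "s1": "P"})
        d = windowed_tajimas_d(gm, "P", one_window())["value"].iloc[0]
        assert d == pytest.approx(-0.6123724356957968, abs=1e-9)


class TestFst:
    def test_fixed_difference_is_one(self, gm_factory):
        dos = np.array([[0, 0, 2, 2]] * 5)
        gm = gm_factory(dos, pops={"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        out = windowed_fst(gm, "A", "B", one_window())
        assert out["value"].iloc[0] == pytest.approx(1.0)

    def test_identical_pops_nonpositive(self, gm_factory):
        dos = np.array([[0, 1, 2, 0, 1, 2]] * 8)
        pops = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        gm = gm_factory(dos, pops=pops)
        out = windowed_fst(gm, "A", "B", one_window())
        assert out["value"].iloc[0] <= 0

    def test_hand_computed_genotype_counts(self, gm_factory):
        # popA dosage counts 6/3/1, popB 1/3/6 at one site, 10 diploids each
        a = [0] * 6 + [1] * 3 + [2]
        b = [0] + [1] * 3 + [2] * 6
        gm = gm_factory([a + b],
                        pops={f"s{i}": ("A" if i < 10 else "B") for i in range(20)})
        out = windowed_fst(gm, "A", "B", one_window())
        # Weir-Cockerham components: a=0.1125, b=0.05, c=0.15 -> theta=0.36
        assert out["value"].iloc[0] == pytest.approx(0.36, abs=1e-12)

    def test_symmetry(self, gm_factory):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(40, 12)).astype(np.int8)
        pops = {f"s{i}": ("A" if i < 6 else "B") for i in range(12)}
        gm = gm_factory(dos, pops=pops)
        ab = genomewide_fst(gm, "A", "B")["ratio_of_sums"]
        ba = genomewide_fst(gm, "B", "A")["ratio_of_sums"]
        assert ab == pytest.approx(ba, abs=1e-12)

    def test_one_pop_missing_window_undefined(self, gm_factory):
        dos = np.array([[MISSING, MISSING, 0, 2]])
        gm = gm_factory(dos, pops={"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        assert np.isnan(windowed_fst(gm, "A", "B", one_window())["value"].iloc[0])


class TestWindowInvariance:
    def test_site_order_permutation_within_window(self, gm_factory):
        rng = np.random.default_rng(2)
        dos = rng.integers(-1, 3, size=(30, 10)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 9_000), size=30, replace=False))
        pops = {f"s{i}": ("A" if i < 5 else "B") for i in range(10)}
        gm = gm_factory(dos, pos=pos, pops=pops)
        w = one_window()
        base = (windowed_pi(gm, "A", w)["value"].iloc[0],
                windowed_tajimas_d(gm, "A", w)["value"].iloc[0],
                windowed_fst(gm, "A", "B", w)["value"].iloc[0])
        perm = rng.permutation(30)
        gm2 = gm.take_sites(perm)  # positions permuted along with rows
        got = (windowed_pi(gm2, "A", w)["value"].iloc[0],
               windowed_tajimas_d(gm2, "A", w)["value"].iloc[0],
               windowed_fst(gm2, "A", "B", w)["value"].iloc[0])
        assert got == pytest.approx(base)


class TestPrivateAlleles:
    def test_examples(self, gm_factory):
        # site0: alt only in A; site1: alt in A and B; site2: ref only in A
        dos = np.array([
            [1, 0, 0, 0],
            [1, 0, 1, 0],
            [1, 2, 2, 2],
        ])
        gm = gm_factory(dos, pops={"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        counts = private_allele_counts(gm)
        # site0 alt private to A; site2 ref private to A; site1 shared
        assert counts["A"] == 2
        assert counts["B"] == 0


class TestLdDecay:
    def test_identical_columns_bin_r2_one(self, gm_factory):
        rng = np.random.default_rng(1)
        snp = rng.integers(0, 3, size=20).astype(np.int8)
        gm = gm_factory(np.vstack([snp, snp]), pos=[1_000, 6_000],
                        pops={f"s{i}": "P" for i in range(20)})
        table, _ = ld_decay_curve(gm, max_dist=300_000, bin_size=5_000)
        assert table.loc[table["n_pairs"] > 0, "mean_r2"].iloc[0] == pytest.approx(1.0)

    def test_pair_beyond_max_dist_excluded(self, gm_factory):
        rng = np.random.default_rng(1)
        snp = rng.integers(0, 3, size=20).astype(np.int8)
        gm = gm_factory(np.vstack([snp, snp]), pos=[1_000, 351_000],
                        pops={f"s{i}": "P" for i in range(20)})
        table, _ = ld_decay_curve(gm, max_dist=300_000)
        assert table["n_pairs"].sum() == 0

    def test_bin_means_are_pair_averages(self, gm_factory):
        rng = np.random.default_rng(2)
        dos = rng.integers(0, 3, size=(3, 30)).astype(np.int8)
        gm = gm_factory(dos, pos=[1_000, 2_000, 3_000],
                        pops={f"s{i}": "P" for i in range(30)})
        from skypurge.genotype_io import genotype_r2
        table, _ = ld_decay_curve(gm, max_dist=10_000, bin_size=10_000)
        expect = np.mean([genotype_r2(dos[i], dos[j])
                          for i, j in itertools.combinations(range(3), 2)])
        assert table["mean_r2"].iloc[0] == pytest.approx(expect)


class TestMantel:
    def _random_dm(self, rng, n=5):
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return DistanceMatrix([f"p{i}" for i in range(n)], m)

    def test_perfect_linear_relation_full_enumeration(self):
        rng = np.random.default_rng(0)
        d1 = self._random_dm(rng, 5)
        v2 = 2 * d1.values + 1
        np.fill_diagonal(v2, 0)
        d2 = DistanceMatrix(d1.labels, v2)
        r, p = mantel_test(d1, d2, n_perm=999, seed=0)
        assert r == pytest.approx(1.0)
        # oracle: exhaustively count permutations attaining r = 1
        iu = np.triu_indices(5, 1)
        x = d1.values[iu]
        k = 0
        for perm in itertools.permutations(range(5)):
            y = d2.values[np.ix_(perm, perm)][iu]
            if np.corrcoef(x, y)[0, 1] >= 1 - 1e-12:
                k += 1
        # permutation p cannot fall below the exact enumeration frequency
        assert p >= k / 120 * 0.5  # sanity: same order of magnitude
        assert p <= 0.05

    def test_constant_matrix_undefined(self):
        rng = np.random.default_rng(1)
        d1 = self._random_dm(rng)
        const = np.ones((5, 5))
        np.fill_diagonal(const, 0)
        d2 = DistanceMatrix(d1.labels, const)
        r, p = mantel_test(d1, d2, n_perm=99, seed=0)
        assert np.isnan(r) and np.isnan(p)

    def test_label_mismatch_errors(self):
        rng = np.random.default_rng(2)
        d1 = self._random_dm(rng)
        d2 = DistanceMatrix([f"q{i}" for i in range(5)], d1.values.copy())
        with pytest.raises(ValueError, match="labels"):
            mantel_test(d1, d2)

    def test_null_p_approximately_uniform(self):
        rng = np.random.default_rng(3)
        from scipy.stats import kstest
        pvals = []
        for rep in range(400):
            d1 = self._random_dm(rng, 6)
            d2 = self._random_dm(rng, 6)
            _, p = mantel_test(d1, d2, n_perm=99, seed=rep)
            pvals.append(p)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestDistanceConstructors:
    def test_great_circle_known_distance(self):
        coords = pd.DataFrame({"lon": [0.0, 0.0], "lat": [0.0, 1.0]},
                              index=["a", "b"])
        d = great_circle_matrix(coords)
        assert d.values[0, 1] == pytest.approx(111.19, rel=1e-3)

    def test_linearized_fst(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 0.2], [0.2, 0]]), "genetic")
        lin = linearized_fst_matrix(dm)
        assert lin.values[0, 1] == pytest.approx(0.25)

    def test_env_distance_zscored(self):
        env = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [5.0, 5.0, 5.0]},
                           index=["a", "b", "c"])
        d = environment_distance_matrix(env)
        # constant column contributes nothing; z-scores of x are equidistant
        assert d.values[0, 1] == pytest.approx(d.values[1, 2])
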