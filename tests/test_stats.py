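import itertools

import numpy as np
import pandas as pd
import pytest

from imsfs import DistanceMatrix, amova, diversity, geo_distances, mantel
from imsfs.stats import DesignError, MatrixError, _amova_components
from conftest import make_genotypes


class TestDiversity:
    def test_all_heterozygous_locus(self):
        # 2 diploids, both het: H_O = 1, unbiased H_E = (4/3) * 0.5 = 2/3
        geno = make_genotypes({"a": [1], "b": [1]}, {"a": "P", "b": "P"})
        res = diversity(geno).per_population
        assert res.loc[0, "H_O"] == 1.0
        assert res.loc[0, "H_E"] == pytest.approx(2 / 3)

    def test_monomorphic_locus_gives_zero(self):
        geno = make_genotypes({"a": [0, 2], "b": [0, 2]}, {"a": "P", "b": "P"})
        res = diversity(geno).per_population
        assert res.loc[0, "H_O"] == 0.0
        assert res.loc[0, "H_E"] == 0.0
        assert res.loc[0, "pi_S"] == 0.0

    def test_matches_exhaustive_pairwise_enumeration(self):
        dosages = {"a": [0, 1, 2], "b": [1, 1, 0], "c": [2, 0, 1]}
        geno = make_genotypes(dosages, {k: "P" for k in dosages})
        res = diversity(geno).per_population

        # oracle: enumerate all allele pairs per locus
        pis, hes, ho_n, ho_d = [], [], 0, 0
        for l in range(3):
            alleles = []
            for ind in dosages:
                d = dosages[ind][l]
                alleles += [1] * d + [0] * (2 - d)
                ho_n += d == 1
                ho_d += 1
            diffs = [a != b for a, b in itertools.combinations(alleles, 2)]
            pis.append(np.mean(diffs))
            n = len(alleles)
            p = np.mean(alleles)
            hes.append(n / (n - 1) * 2 * p * (1 - p))
        assert res.loc[0, "pi_S"] == pytest.approx(np.mean(pis), abs=1e-12)
        assert res.loc[0, "H_E"] == pytest.approx(np.mean(hes), abs=1e-12)
        assert res.loc[0, "H_O"] == pytest.approx(ho_n / ho_d, abs=1e-12)

    def test_per_lineage_aggregates_present(self):
        geno = make_genotypes(
            {"a": [0, 1], "b": [1, 1], "c": [2, 0], "d": [2, 1]},
            {"a": "W1", "b": "W1", "c": "E1", "d": "E1"},
            {"W1": "west", "E1": "east"})
        res = diversity(geno)
        assert set(res.per_lineage["lineage"]) == {"west", "east"}


def brute_force_amova(geno_matrix, pops, groups):
    """Variance components computed directly from the sums-of-squares
    definitions with explicit loops (independent oracle)."""
    x = np.asarray(geno_matrix, dtype=float)
    n = x.shape[0]
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d2[i, j] = np.sum((x[i] - x[j]) ** 2)

    def ssd(idx):
        tot = 0.0
        for i in idx:
            for j in idx:
                tot += d2[i, j]
        return tot / (2 * len(idx))

    every = list(range(n))
    pop_ids = sorted(set(pops))
    grp_ids = sorted(set(groups))
    P, G = len(pop_ids), len(grp_ids)
    ssd_t = ssd(every)
    ssd_wp = sum(ssd([i for i in every if pops[i] == p]) for p in pop_ids)
    ssd_wg = sum(ssd([i for i in every if groups[i] == g]) for g in grp_ids)
    df_a, df_b, df_c = G - 1, P - G, n - P

    sizes = {p: sum(1 for q in pops if q == p) for p in pop_ids}
    gsizes = {g: sum(1 for h in groups if h == g) for g in grp_ids}
    gop = {p: groups[pops.index(p)] for p in pop_ids}
    s1 = sum(sum(sizes[p] ** 2 for p in pop_ids if gop[p] == g) / gsizes[g]
             for g in grp_ids)
    s2 = sum(sizes[p] ** 2 for p in pop_ids) / n
    s3 = sum(gsizes[g] ** 2 for g in grp_ids) / n
    n1 = (n - s1) / df_b
    n2 = (s1 - s2) / df_a
    n3 = (n - s3) / df_a
    sc = ssd_wp / df_c
    sb = ((ssd_wg - ssd_wp) / df_b - sc) / n1
    sa = ((ssd_t - ssd_wg) / df_a - sc - n2 * sb) / n3
    return sa, sb, sc


class TestAmova:
    def test_components_match_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        x = rng.integers(0, 3, size=(12, 30))
        pops = ["P1"] * 3 + ["P2"] * 3 + ["P3"] * 3 + ["P4"] * 3
        group_of = {"P1": "G1", "P2": "G1", "P3": "G2", "P4": "G2"}
        groups = [group_of[p] for p in pops]
        sa, sb, sc = brute_force_amova(x, pops, groups)
        got_a, got_b, got_c, _ = _amova_components(
            _sq_dist(x), np.array(pops), np.array(groups))
        assert got_a == pytest.approx(sa, abs=1e-12)
        assert got_b == pytest.approx(sb, abs=1e-12)
        assert got_c == pytest.approx(sc, abs=1e-12)

    def test_nested_ssd_decomposition_is_exact(self):
        # SSD(total) = SSD(among groups) + SSD(among pops in groups) + SSD(within)
        rng = np.random.default_rng(3)
        x = rng.integers(0, 3, size=(10, 25))
        pops = ["A"] * 3 + ["B"] * 2 + ["C"] * 3 + ["D"] * 2
        groups = ["G1"] * 5 + ["G2"] * 5
        d2 = _sq_dist(x)
        n = len(pops)

        def ssd(idx):
            return d2[np.ix_(idx, idx)].sum() / (2 * len(idx))

        ssd_t = ssd(list(range(n)))
        ssd_wp = sum(ssd([i for i, q in enumerate(pops) if q == p])
                     for p in set(pops))
        ssd_wg = sum(ssd([i for i, h in enumerate(groups) if h == g])
                     for g in set(groups))
        assert (ssd_t - ssd_wg) + (ssd_wg - ssd_wp) + ssd_wp == pytest.approx(
            ssd_t, abs=1e-9)
        # and the fitted components reproduce these SSDs through the mean
        # squares (within-population component equals SSD_WP / df exactly)
        sa, sb, sc, df = _amova_components(d2, np.array(pops),
                                           np.array(groups))
        assert sc == pytest.approx(ssd_wp / df[2], abs=1e-12)

    def test_complete_fixation_gives_phi_st_one(self):
        geno = make_genotypes(
            {"a": [0, 0, 0], "b": [0, 0, 0], "c": [2, 2, 2], "d": [2, 2, 2]},
            {"a": "W", "b": "W", "c": "E", "d": "E"},
            {"W": "west", "E": "east"})
        res = amova(geno, groups=geno.lineages, n_perm=50, rng=0)
        assert res.phi_st == pytest.approx(1.0)
        assert res.sigma_c == pytest.approx(0.0)

    def test_identical_individuals_flagged_degenerate(self):
        geno = make_genotypes(
            {"a": [1, 1], "b": [1, 1], "c": [1, 1], "d": [1, 1]},
            {"a": "W", "b": "W", "c": "E", "d": "E"},
            {"W": "west", "E": "east"})
        res = amova(geno, groups=geno.lineages, n_perm=10, rng=0)
        assert res.degenerate
        assert np.isnan(res.phi_st)

    def test_permutation_pvalues_in_unit_interval(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, size=(12, 20))
        pops = {"i%d" % i: f"P{i // 3}" for i in range(12)}
        geno = make_genotypes({f"i{i}": list(x[i]) for i in range(12)}, pops)
        groups = {"P0": "G1", "P1": "G1", "P2": "G2", "P3": "G2"}
        res = amova(geno, groups=groups, n_perm=99, rng=2)
        for p in (res.p_st, res.p_sc, res.p_ct):
            assert 0 < p <= 1

    def test_missing_group_rejected(self):
        geno = make_genotypes(
            {"a": [0], "b": [1], "c": [2], "d": [1]},
            {"a": "W", "b": "W", "c": "E", "d": "E"})
        with pytest.raises(DesignError):
            amova(geno, groups={"W": "G1"}, n_perm=10)


def _sq_dist(x):
    x = np.asarray(x, dtype=float)
    return ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)


class TestMantel:
    @staticmethod
    def matrix(vals, labels=None):
        vals = np.asarray(vals, dtype=float)
        labels = labels or [f"s{i}" for i in range(vals.shape[0])]
        return DistanceMatrix(vals, labels)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        v = rng.random((5, 5))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        a = self.matrix(v)
        res = mantel(a, a, exact=False, n_perm=99, rng=1)
        assert res.r == pytest.approx(1.0)

    def test_order_reversing_transform_gives_minus_one(self):
        rng = np.random.default_rng(2)
        v = rng.random((5, 5)) + 0.1
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        w = v.max() + 0.5 - v
        np.fill_diagonal(w, 0)
        res = mantel(self.matrix(v), self.matrix(w), exact=False, n_perm=99,
                     rng=1)
        assert res.r == pytest.approx(-1.0)

    def test_exact_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        va = rng.random((4, 4))
        va = (va + va.T) / 2
        np.fill_diagonal(va, 0)
        vb = rng.random((4, 4))
        vb = (vb + vb.T) / 2
        np.fill_diagonal(vb, 0)
        a, b = self.matrix(va), self.matrix(vb)
        res = mantel(a, b, exact=True)

        # oracle: enumerate all 24 label permutations independently
        iu = np.triu_indices(4, 1)
        x = va[iu]
        r_obs = np.corrcoef(x, vb[iu])[0, 1]
        count = 0
        for perm in itertools.permutations(range(4)):
            p = np.asarray(perm)
            r = np.corrcoef(x, vb[np.ix_(p, p)][iu])[0, 1]
            if r >= r_obs - 1e-12:
                count += 1
        assert res.exact
        assert res.n_perm == 24
        assert res.p == pytest.approx(count / 24, abs=1e-12)
        assert res.r == pytest.approx(r_obs, abs=1e-12)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(150):
            va = rng.random((8, 8))
            va = (va + va.T) / 2
            np.fill_diagonal(va, 0)
            vb = rng.random((8, 8))
            vb = (vb + vb.T) / 2
            np.fill_diagonal(vb, 0)
            res = mantel(self.matrix(va), self.matrix(vb), exact=False,
                         n_perm=99, rng=rng)
            ps.append(res.p)
        assert 0.35 < np.mean(ps) < 0.65

    def test_label_mismatch_rejected(self):
        v = np.zeros((3, 3))
        a = self.matrix(v, ["x", "y", "z"])
        b = self.matrix(v, ["x", "y", "w"])
        with pytest.raises(MatrixError):
            mantel(a, b)

    def test_constant_matrix_flagged(self):
        v = np.ones((4, 4)) - np.eye(4)
        rngm = np.random.default_rng(1).random((4, 4))
        rngm = (rngm + rngm.T) / 2
        np.fill_diagonal(rngm, 0)
        res = mantel(self.matrix(v), self.matrix(rngm))
        assert np.isnan(res.r)
        assert res.p is None


class TestGeoDistances:
    def test_identical_points_are_zero(self):
        coords = pd.DataFrame({"latitude": [10.0, 10.0],
                               "longitude": [20.0, 20.0]}, index=["a", "b"])
        d = geo_distances(coords)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_antipodal_points(self):
        coords = pd.DataFrame({"latitude": [0.0, 0.0],
                               "longitude": [0.0, 180.0]}, index=["a", "b"])
        d = geo_distances(coords)
        assert d.values[0, 1] == pytest.approx(np.pi * 6371.0, rel=1e-9)

    def test_quarter_meridian(self):
        coords = pd.DataFrame({"latitude": [0.0, 0.0],
                               "longitude": [0.0, 90.0]}, index=["a", "b"])
        d = geo_distances(coords)
        assert d.values[0, 1] == pytest.approx(6371.0 * np.pi / 2, rel=1e-9)

    def test_out_of_range_rejected(self):
        coords = pd.DataFrame({"latitude": [95.0], "longitude": [0.0]},
                              index=["a"])
        with pytest.raises(MatrixError):
            geo_distances(coords)


class TestDistanceMatrix:
    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(MatrixError):
            DistanceMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]), ["a", "b"])

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(MatrixError):
            DistanceMatrix(np.array([[1.0, 0.0], [0.0, 0.0]]), ["a", "b"])

    def test_csv_round_trip(self, tmp_path):
        v = np.array([[0.0, 2.5], [2.5, 0.0]])
        d = DistanceMatrix(v, ["a", "b"])
        path = str(tmp_path / "d.csv")
        d.write_csv(path)
        back = DistanceMatrix.read_csv(path)
        np.testing.assert_allclose(back.values, v)
        assert back.labels == ["a", "b"]
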