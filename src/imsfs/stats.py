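"""Diversity, hierarchical AMOVA, and Mantel tests on SNP genotype data.

These support the demographic analysis: per-population heterozygosity and
per-SNP nucleotide diversity, a two-level (groups / populations within
groups / within populations) analysis of molecular variance with
permutation p-values, and Mantel matrix-correlation tests for isolation by
distance/environment/resistance.

Conventions: AMOVA uses squared Euclidean distances on genotype dosage
vectors (the locus-by-locus formulation summed over loci); permutation
p-values use the add-one rule p = (1 + #{perm >= obs}) / (n_perm + 1) and so
are never zero; pi_S is per SNP site over the retained variable loci.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


class DesignError(ValueError):
    """Invalid population/group design for a hierarchical analysis."""


class MatrixError(ValueError):
    """Distance-matrix validation failure."""


EARTH_RADIUS_KM = 6371.0


# --- diversity -------------------------------------------------------------

@dataclass
class DiversityResult:
    """Per-population H_O, unbiased H_E, and per-SNP nucleotide diversity."""

    per_population: pd.DataFrame
    per_lineage: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return self.per_population


def _pop_diversity(d: np.ndarray) -> tuple[float, float, float]:
    """(H_O, H_E, pi_S) for one population's dosage block (ind x loci)."""
    ho_num = ho_den = 0.0
    he_vals = []
    pi_vals = []
    for l in range(d.shape[1]):
        col = d[:, l]
        obs = col[col >= 0]
        n = obs.size
        if n == 0:
            continue
        ho_num += float((obs == 1).sum())
        ho_den += n
        an = 2 * n  # allele count
        if an < 2:
            continue
        p = obs.sum() / an
        he = (an / (an - 1.0)) * 2.0 * p * (1.0 - p)
        he_vals.append(he)
        # mean pairwise difference per site over all C(an, 2) allele pairs
        der = int(obs.sum())
        pi_vals.append(der * (an - der) / (an * (an - 1) / 2.0))
    ho = ho_num / ho_den if ho_den else float("nan")
    he = float(np.mean(he_vals)) if he_vals else float("nan")
    pi = float(np.mean(pi_vals)) if pi_vals else float("nan")
    return ho, he, pi


def diversity(geno) -> DiversityResult:
    """H_O, unbiased H_E, and pi_S per population (and per lineage if mapped).

    H_O is the heterozygote fraction among non-missing genotypes; H_E uses
    the small-sample correction 2n/(2n-1) * 2p(1-p); pi_S is the mean
    pairwise allele difference per SNP site.
    """
    rows = []
    for pop in geno.populations:
        idx = geno.individuals_of(pop)
        if not idx:
            raise DesignError(f"population {pop} has no individuals")
        ho, he, pi = _pop_diversity(geno.genotypes[idx, :])
        rows.append({"population": pop, "n": len(idx),
                     "H_O": ho, "H_E": he, "pi_S": pi})
    per_pop = pd.DataFrame(rows)
    per_lin = None
    if geno.lineages:
        lin_rows = []
        for lin in dict.fromkeys(geno.lineages.values()):
            idx = [i for i, ind in enumerate(geno.individuals)
                   if geno.lineages.get(geno.popmap[ind]) == lin]
            if not idx:
                continue
            ho, he, pi = _pop_diversity(geno.genotypes[idx, :])
            lin_rows.append({"lineage": lin, "n": len(idx),
                             "H_O": ho, "H_E": he, "pi_S": pi})
        per_lin = pd.DataFrame(lin_rows)
    return DiversityResult(per_population=per_pop, per_lineage=per_lin)


# --- AMOVA -----------------------------------------------------------------

@dataclass
class AmovaResult:
    """Hierarchical AMOVA variance components and Phi statistics."""

    sigma_a: float          # among groups
    sigma_b: float          # among populations within groups
    sigma_c: float          # within populations
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_ct: float | None
    p_sc: float | None
    p_st: float | None
    n_perm: int
    df: tuple[int, int, int] = (0, 0, 0)
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "sigma_among_groups": self.sigma_a,
            "sigma_among_pops_within_groups": self.sigma_b,
            "sigma_within_pops": self.sigma_c,
            "Phi_CT": self.phi_ct, "Phi_SC": self.phi_sc, "Phi_ST": self.phi_st,
            "p_CT": self.p_ct, "p_SC": self.p_sc, "p_ST": self.p_st,
            "n_perm": self.n_perm, "degenerate": self.degenerate,
        }


def _dosage_distances(geno) -> np.ndarray:
    """Pairwise squared Euclidean distances on dosage vectors.

    Missing entries are excluded pairwise and the sum rescaled by
    L / L_observed so every pair is on the same per-genome scale.
    """
    x = np.asarray(geno.genotypes, dtype=float)
    x[x < 0] = np.nan
    n, L = x.shape
    d2 = np.zeros((n, n))
    for i in range(n):
        diff = x[i] - x[i + 1:]
        sq = diff ** 2
        valid = ~np.isnan(sq)
        with np.errstate(invalid="ignore"):
            sums = np.nansum(sq, axis=1)
        counts = valid.sum(axis=1)
        if np.any(counts == 0):
            raise DesignError("a pair of individuals shares no genotyped locus")
        vals = sums * (L / counts)
        d2[i, i + 1:] = vals
        d2[i + 1:, i] = vals
    return d2


def _ssd(d2: np.ndarray, idx: np.ndarray) -> float:
    """Sum of squared deviations of a set from distances: (1/n) sum_{i<j} d2."""
    if len(idx) == 0:
        return 0.0
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / (2.0 * len(idx)))


def _amova_components(d2: np.ndarray, pops: np.ndarray, groups: np.ndarray):
    """Variance components from the standard nested sums of squares."""
    n_tot = len(pops)
    pop_ids = np.unique(pops)
    grp_ids = np.unique(groups)
    P, G = len(pop_ids), len(grp_ids)

    ssd_total = _ssd(d2, np.arange(n_tot))
    ssd_wp = 0.0
    for p in pop_ids:
        ssd_wp += _ssd(d2, np.flatnonzero(pops == p))
    ssd_wg = 0.0
    for g in grp_ids:
        ssd_wg += _ssd(d2, np.flatnonzero(groups == g))
    ssd_ap = ssd_wg - ssd_wp          # among pops within groups
    ssd_ag = ssd_total - ssd_wg       # among groups

    df_a, df_b, df_c = G - 1, P - G, n_tot - P
    if df_c <= 0:
        raise DesignError("need more individuals than populations")

    pop_sizes = {p: int((pops == p).sum()) for p in pop_ids}
    grp_sizes = {g: int((groups == g).sum()) for g in grp_ids}
    grp_of_pop = {}
    for p in pop_ids:
        gset = np.unique(groups[pops == p])
        if len(gset) != 1:
            raise DesignError("each population must lie in exactly one group")
        grp_of_pop[p] = gset[0]

    sum_n2_over_ng = 0.0
    for g in grp_ids:
        s = sum(pop_sizes[p] ** 2 for p in pop_ids if grp_of_pop[p] == g)
        sum_n2_over_ng += s / grp_sizes[g]
    sum_n2_over_n = sum(pop_sizes[p] ** 2 for p in pop_ids) / n_tot
    sum_g2_over_n = sum(grp_sizes[g] ** 2 for g in grp_ids) / n_tot

    n1 = (n_tot - sum_n2_over_ng) / df_b if df_b > 0 else float("nan")
    n2 = (sum_n2_over_ng - sum_n2_over_n) / df_a if df_a > 0 else float("nan")
    n3 = (n_tot - sum_g2_over_n) / df_a if df_a > 0 else float("nan")

    ms_c = ssd_wp / df_c
    sigma_c = ms_c
    sigma_b = ((ssd_ap / df_b) - sigma_c) / n1 if df_b > 0 else 0.0
    sigma_a = ((ssd_ag / df_a) - sigma_c - n2 * sigma_b) / n3 if df_a > 0 else 0.0
    return sigma_a, sigma_b, sigma_c, (df_a, df_b, df_c)


def amova(
    geno=None,
    popmap: dict[str, str] | None = None,
    groups: dict[str, str] | None = None,
    n_perm: int = 5000,
    rng: np.random.Generator | int | None = None,
    distances: np.ndarray | None = None,
    pop_labels: list[str] | None = None,
) -> AmovaResult:
    """Two-level hierarchical AMOVA with permutation tests.

    Input is either a :class:`~imsfs.sfs.GenotypeMatrix` (distances computed
    from dosage vectors) or a precomputed squared-distance matrix with
    ``pop_labels`` per individual.  ``groups`` maps population -> group.
    Permutations: whole populations among groups for Phi_CT, individuals
    among populations within groups for Phi_SC, individuals among all
    populations for Phi_ST.
    """
    rng = np.random.default_rng(rng)
    if distances is None:
        if geno is None:
            raise DesignError("provide a genotype matrix or a distance matrix")
        d2 = _dosage_distances(geno)
        popmap = popmap or geno.popmap
        pop_labels = [popmap[ind] for ind in geno.individuals]
    else:
        d2 = np.asarray(distances, dtype=float)
        if pop_labels is None or len(pop_labels) != d2.shape[0]:
            raise DesignError("pop_labels must match the distance matrix")
    if groups is None:
        raise DesignError("a population -> group mapping is required")
    pops = np.asarray(pop_labels)
    unique_pops = np.unique(pops)
    if len(unique_pops) < 2:
        raise DesignError("need at least two populations")
    missing = [p for p in unique_pops if p not in groups]
    if missing:
        raise DesignError(f"populations without a group: {missing}")
    grp = np.asarray([groups[p] for p in pops])
    n_groups = len(np.unique(grp))

    sigma_a, sigma_b, sigma_c, df = _amova_components(d2, pops, grp)
    total = sigma_a + sigma_b + sigma_c
    if total <= 0:
        return AmovaResult(sigma_a, sigma_b, sigma_c,
                           float("nan"), float("nan"), float("nan"),
                           None, None, None, 0, df, degenerate=True)

    phi_ct = sigma_a / total if n_groups > 1 else float("nan")
    phi_sc = (sigma_b / (sigma_b + sigma_c)
              if sigma_b + sigma_c > 0 else float("nan"))
    phi_st = (sigma_a + sigma_b) / total

    n = len(pops)
    pop_of_group = {g: list(np.unique(pops[grp == g]))
                    for g in np.unique(grp)}

    cnt_ct = cnt_sc = cnt_st = 0
    n_eff_ct = 0
    for _ in range(n_perm):
        # Phi_ST: permute individuals among all populations
        perm = rng.permutation(n)
        pa, pb, pc, _ = _amova_components(d2, pops[perm], grp[perm])
        tot = pa + pb + pc
        if tot > 0 and (pa + pb) / tot >= phi_st - 1e-12:
            cnt_st += 1
        # Phi_SC: permute individuals among populations within groups
        perm2 = np.arange(n)
        for g in np.unique(grp):
            members = np.flatnonzero(grp == g)
            perm2[members] = members[rng.permutation(len(members))]
        pa, pb, pc, _ = _amova_components(d2, pops[perm2], grp)
        if (pb + pc) > 0 and pb / (pb + pc) >= phi_sc - 1e-12:
            cnt_sc += 1
        # Phi_CT: permute whole populations among groups (sizes preserved)
        if n_groups > 1 and len(unique_pops) > n_groups:
            shuffled = rng.permutation(unique_pops)
            new_group_of_pop = {}
            pos = 0
            for g, pl in pop_of_group.items():
                for _p in pl:
                    new_group_of_pop[shuffled[pos]] = g
                    pos += 1
            new_grp = np.asarray([new_group_of_pop[p] for p in pops])
            pa, pb, pc, _ = _amova_components(d2, pops, new_grp)
            tot = pa + pb + pc
            n_eff_ct += 1
            if tot > 0 and pa / tot >= phi_ct - 1e-12:
                cnt_ct += 1

    p_st = (1 + cnt_st) / (n_perm + 1)
    p_sc = (1 + cnt_sc) / (n_perm + 1) if math.isfinite(phi_sc) else None
    p_ct = (1 + cnt_ct) / (n_eff_ct + 1) if n_eff_ct else None
    return AmovaResult(sigma_a, sigma_b, sigma_c, phi_ct, phi_sc, phi_st,
                       p_ct, p_sc, p_st, n_perm, df)


# --- distance matrices and Mantel -----------------------------------------

@dataclass
class DistanceMatrix:
    """Labeled square symmetric matrix with zero diagonal."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise MatrixError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise MatrixError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise MatrixError("diagonal must be zero")
        if np.any(self.values < -1e-12):
            raise MatrixError("distances must be nonnegative")

    @classmethod
    def read_csv(cls, path: str) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.values, [str(c) for c in df.columns])

    def write_csv(self, path: str) -> None:
        pd.DataFrame(self.values, index=self.labels,
                     columns=self.labels).to_csv(path)


@dataclass
class MantelResult:
    r: float
    p: float | None
    n_perm: int
    exact: bool = False


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int = 9999,
    rng: np.random.Generator | int | None = None,
    exact: bool | None = None,
) -> MantelResult:
    """Mantel matrix-correlation test.

    r is the Pearson correlation over the off-diagonal upper triangles;
    permutations relabel B's rows and columns simultaneously; p is one-tailed
    for positive association.  With ``exact`` (default when n <= 7) all n!
    permutations are enumerated and p = #{perm r >= observed r} / n!.
    """
    if a.labels != b.labels:
        raise MatrixError("matrix labels do not match")
    n = len(a.labels)
    va = _upper(a.values)
    if va.std() == 0 or _upper(b.values).std() == 0:
        return MantelResult(float("nan"), None, 0)

    def corr(perm: np.ndarray) -> float:
        vb = _upper(b.values[np.ix_(perm, perm)])
        return float(np.corrcoef(va, vb)[0, 1])

    r_obs = corr(np.arange(n))
    if exact is None:
        exact = n <= 7
    if exact:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if corr(np.asarray(perm)) >= r_obs - 1e-12:
                count += 1
        return MantelResult(r_obs, count / total, total, exact=True)
    rng = np.random.default_rng(rng)
    count = 0
    for _ in range(n_perm):
        if corr(rng.permutation(n)) >= r_obs - 1e-12:
            count += 1
    return MantelResult(r_obs, (1 + count) / (n_perm + 1), n_perm)


def geo_distances(coords: pd.DataFrame) -> DistanceMatrix:
    """Great-circle distances (km) from a table with latitude/longitude columns.

    Haversine formula with Earth radius 6371 km; the index provides labels.
    """
    lat = np.asarray(coords["latitude"], dtype=float)
    lon = np.asarray(coords["longitude"], dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 360):
        raise MatrixError("coordinates out of range")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = (np.sin(dphi / 2.0) ** 2
         + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, [str(i) for i in coords.index])
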