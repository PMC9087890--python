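"""Joint site-frequency spectra: construction, projection, folding, and IO.

The central container is :class:`JointSFS`, a (n_west+1) x (n_east+1) count
matrix indexed by derived (or minor) allele counts in the two lineages, with
the monomorphic corners (0,0) and (n_west, n_east) masked out of every total.
Spectra are read and written in two text dialects: the dadi single-block
format (dims header, flattened values, mask line) and a fastsimcoal-style
.obs table.

Missing genotypes are handled by hypergeometric projection: per locus, allele
counts are taken over non-missing genotypes and projected down to a fixed
target size; loci with too few non-missing alleles are dropped and counted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom


class SFSFormatError(ValueError):
    """Malformed spectrum file or inconsistent header/shape."""


class GenotypeDataError(ValueError):
    """Genotype input violating the biallelic/grouping contract."""


class FoldError(ValueError):
    """Folding applied to an already-folded spectrum."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci dosage matrix with population metadata.

    ``genotypes`` holds counts of the non-reference allele in {0, 1, 2} with
    -1 for missing.  ``popmap`` maps individual id -> population label;
    ``lineages`` maps population label -> lineage label (e.g. "west"/"east").
    """

    genotypes: np.ndarray
    individuals: list[str]
    loci: list[str]
    popmap: dict[str, str]
    lineages: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.individuals), len(self.loci)):
            raise GenotypeDataError("genotype matrix shape mismatch")
        bad = set(np.unique(self.genotypes)) - {-1, 0, 1, 2}
        if bad:
            raise GenotypeDataError(f"invalid dosage values: {sorted(bad)}")

    @property
    def populations(self) -> list[str]:
        seen = []
        for ind in self.individuals:
            p = self.popmap[ind]
            if p not in seen:
                seen.append(p)
        return seen

    def individuals_of(self, population: str) -> list[int]:
        return [i for i, ind in enumerate(self.individuals)
                if self.popmap[ind] == population]


@dataclass
class JointSFS:
    """Two-dimensional site-frequency spectrum with masked monomorphic corners.

    ``counts[i, j]`` is the number (possibly fractional, after projection) of
    SNPs with i derived/minor alleles among ``n_west`` sampled in the western
    lineage and j among ``n_east`` in the eastern.  ``n_sites`` optionally
    records the total number of surveyed sites including monomorphic ones,
    which anchors absolute scale during fitting.
    """

    counts: np.ndarray
    n_west: int
    n_east: int
    folded: bool = False
    n_sites: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n_west + 1, self.n_east + 1):
            raise SFSFormatError("counts shape inconsistent with sample sizes")
        if np.any(self.counts < 0):
            raise SFSFormatError("negative counts")

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros_like(self.counts, dtype=bool)
        m[0, 0] = True
        m[-1, -1] = True
        return m

    @property
    def total(self) -> float:
        """Total count over unmasked cells."""
        return float(self.counts[~self.mask].sum())

    def copy(self) -> "JointSFS":
        return JointSFS(self.counts.copy(), self.n_west, self.n_east,
                        self.folded, self.n_sites)


@dataclass(frozen=True)
class SFSProjection:
    """Down-projection from source to target haploid sample sizes."""

    source_west: int
    source_east: int
    target_west: int
    target_east: int

    def __post_init__(self) -> None:
        for tgt, src in ((self.target_west, self.source_west),
                         (self.target_east, self.source_east)):
            if not 2 <= tgt <= src:
                raise SFSFormatError(
                    "projection targets must satisfy 2 <= target <= source")


def _projection_matrix(n_from: int, n_to: int) -> np.ndarray:
    """P[i, i'] = hypergeometric P(i' derived among n_to | i among n_from)."""
    P = np.zeros((n_from + 1, n_to + 1))
    for i in range(n_from + 1):
        lo = max(0, n_to - (n_from - i))
        hi = min(i, n_to)
        ks = np.arange(lo, hi + 1)
        P[i, ks] = hypergeom.pmf(ks, n_from, i, n_to)
    return P


def project_jsfs(jsfs: JointSFS, projection: SFSProjection) -> JointSFS:
    """Hypergeometric down-projection of a binned spectrum.

    Fractional mass is allowed; mass landing on the monomorphic corners is
    dropped and recorded on the result as ``projection_loss``.
    """
    if (projection.source_west, projection.source_east) != (jsfs.n_west, jsfs.n_east):
        raise SFSFormatError("projection source sizes do not match the spectrum")
    Pw = _projection_matrix(jsfs.n_west, projection.target_west)
    Pe = _projection_matrix(jsfs.n_east, projection.target_east)
    counts = jsfs.counts.copy()
    counts[jsfs.mask] = 0.0
    out = Pw.T @ counts @ Pe
    loss = float(out[0, 0] + out[-1, -1])
    out[0, 0] = 0.0
    out[-1, -1] = 0.0
    result = JointSFS(out, projection.target_west, projection.target_east,
                      jsfs.folded, jsfs.n_sites)
    result.projection_loss = loss  # type: ignore[attr-defined]
    return result


def fold_matrix(mat: np.ndarray) -> np.ndarray:
    """Fold an unfolded (n_w+1)x(n_e+1) matrix onto minor-allele classes.

    Cell (i, j) is merged with its complement (n_w-i, n_e-j); the member with
    the lower total count i+j receives the mass (ties broken toward the
    lexicographically smaller index pair); self-paired central cells are
    unchanged.
    """
    nw, ne = mat.shape[0] - 1, mat.shape[1] - 1
    out = np.zeros_like(np.asarray(mat, dtype=float))
    for i in range(nw + 1):
        for j in range(ne + 1):
            ci, cj = nw - i, ne - j
            if (i, j) == (ci, cj):
                out[i, j] += mat[i, j]
            elif (i + j, i, j) < (ci + cj, ci, cj):
                out[i, j] += mat[i, j] + mat[ci, cj]
    return out


def fold_jsfs(jsfs: JointSFS) -> JointSFS:
    """Fold a spectrum onto minor-allele classes (see :func:`fold_matrix`)."""
    if jsfs.folded:
        raise FoldError("spectrum is already folded")
    return JointSFS(fold_matrix(jsfs.counts), jsfs.n_west, jsfs.n_east,
                    folded=True, n_sites=jsfs.n_sites)


def jsfs_from_genotypes(
    geno: GenotypeMatrix,
    grouping: dict[str, str] | None = None,
    polarized: bool = True,
    projection: tuple[int, int] | None = None,
) -> JointSFS:
    """Tally the joint SFS of two lineages from a genotype matrix.

    ``grouping`` maps population label -> lineage, overriding
    ``geno.lineages``; exactly two lineages must result, conventionally
    ordered ("west", "east") when those labels are used, alphabetically
    otherwise.  With ``projection`` (haploid target sizes per lineage), each
    locus contributes its hypergeometric expectation over non-missing allele
    counts; without it, loci with any missing genotype are rejected.  Loci
    monomorphic in the pooled sample are excluded; the number of loci dropped
    for insufficient non-missing data is recorded as ``n_dropped`` and the
    projection mass lost to the corners as ``projection_loss``.
    """
    grouping = dict(grouping or geno.lineages)
    if not grouping:
        raise GenotypeDataError("no population -> lineage grouping provided")
    lineage_names = sorted(set(grouping.values()))
    if len(lineage_names) != 2:
        raise GenotypeDataError("exactly two lineages are required")
    if set(lineage_names) == {"west", "east"}:
        lineage_names = ["west", "east"]
    idx: dict[str, list[int]] = {l: [] for l in lineage_names}
    for i, ind in enumerate(geno.individuals):
        pop = geno.popmap[ind]
        if pop in grouping:
            idx[grouping[pop]].append(i)
    if any(len(v) == 0 for v in idx.values()):
        raise GenotypeDataError("a lineage has no individuals")

    gw = geno.genotypes[idx[lineage_names[0]], :]
    ge = geno.genotypes[idx[lineage_names[1]], :]
    full_w, full_e = 2 * gw.shape[0], 2 * ge.shape[0]
    if projection is None:
        tw, te = full_w, full_e
    else:
        tw, te = projection
        for t, f in ((tw, full_w), (te, full_e)):
            if not 2 <= t <= f:
                raise SFSFormatError("projection target outside [2, 2*n_diploids]")

    counts = np.zeros((tw + 1, te + 1))
    n_dropped = 0
    loss = 0.0
    pw_cache: dict[int, np.ndarray] = {}
    pe_cache: dict[int, np.ndarray] = {}
    for l in range(len(geno.loci)):
        cw = gw[:, l]
        ce = ge[:, l]
        nw_obs = 2 * int((cw >= 0).sum())
        ne_obs = 2 * int((ce >= 0).sum())
        if nw_obs < tw or ne_obs < te:
            n_dropped += 1
            continue
        dw = int(cw[cw >= 0].sum())
        de = int(ce[ce >= 0].sum())
        if dw + de == 0 or dw + de == nw_obs + ne_obs:
            continue  # monomorphic in the pooled sample
        if nw_obs == tw and ne_obs == te:
            counts[dw, de] += 1.0
            continue
        if nw_obs not in pw_cache:
            pw_cache[nw_obs] = _projection_matrix(nw_obs, tw)
        if ne_obs not in pe_cache:
            pe_cache[ne_obs] = _projection_matrix(ne_obs, te)
        contrib = np.outer(pw_cache[nw_obs][dw], pe_cache[ne_obs][de])
        loss += float(contrib[0, 0] + contrib[-1, -1])
        contrib[0, 0] = 0.0
        contrib[-1, -1] = 0.0
        counts += contrib

    jsfs = JointSFS(counts, tw, te, folded=False)
    if not polarized:
        jsfs = fold_jsfs(jsfs)
    jsfs.n_dropped = n_dropped  # type: ignore[attr-defined]
    jsfs.projection_loss = loss  # type: ignore[attr-defined]
    return jsfs


# --- text dialects ---------------------------------------------------------

def write_jsfs(jsfs: JointSFS, path: str, dialect: str = "dadi") -> None:
    """Write a spectrum in the dadi or fastsimcoal-style .obs dialect."""
    if dialect == "dadi":
        _write_dadi(jsfs, path)
    elif dialect == "obs":
        _write_obs(jsfs, path)
    else:
        raise SFSFormatError(f"unknown dialect: {dialect}")


def read_jsfs(path: str, dialect: str = "dadi") -> JointSFS:
    """Read a spectrum written by :func:`write_jsfs` (round-trip identity)."""
    if dialect == "dadi":
        return _read_dadi(path)
    if dialect == "obs":
        return _read_obs(path)
    raise SFSFormatError(f"unknown dialect: {dialect}")


def _write_dadi(jsfs: JointSFS, path: str) -> None:
    with open(path, "w") as fh:
        if jsfs.n_sites is not None:
            fh.write(f"# n_sites={jsfs.n_sites}\n")
        fold = "folded" if jsfs.folded else "unfolded"
        fh.write(f"{jsfs.n_west + 1} {jsfs.n_east + 1} {fold}\n")
        fh.write(" ".join(f"{v:.10g}" for v in jsfs.counts.ravel()) + "\n")
        fh.write(" ".join(str(int(v)) for v in jsfs.mask.ravel().astype(int)) + "\n")


def _read_dadi(path: str) -> JointSFS:
    with open(path) as fh:
        lines = [l.strip() for l in fh if l.strip()]
    n_sites = None
    while lines and lines[0].startswith("#"):
        m = re.search(r"n_sites=(\d+)", lines[0])
        if m:
            n_sites = int(m.group(1))
        lines.pop(0)
    if len(lines) < 2:
        raise SFSFormatError("truncated dadi spectrum file")
    header = lines[0].split()
    if len(header) < 2:
        raise SFSFormatError("malformed dadi header")
    try:
        d1, d2 = int(header[0]), int(header[1])
    except ValueError as err:
        raise SFSFormatError("malformed dadi header") from err
    folded = len(header) > 2 and header[2] == "folded"
    values = np.array(lines[1].split(), dtype=float)
    if values.size != d1 * d2:
        raise SFSFormatError("value count inconsistent with header shape")
    counts = values.reshape(d1, d2)
    counts[0, 0] = 0.0
    counts[-1, -1] = 0.0
    return JointSFS(counts, d1 - 1, d2 - 1, folded=folded, n_sites=n_sites)


def _write_obs(jsfs: JointSFS, path: str) -> None:
    with open(path, "w") as fh:
        extra = f" n_sites={jsfs.n_sites}" if jsfs.n_sites is not None else ""
        fold = "folded" if jsfs.folded else "unfolded"
        fh.write(f"1 observations. {fold}{extra}\n")
        fh.write("\t" + "\t".join(f"d_e_{j}" for j in range(jsfs.n_east + 1)) + "\n")
        for i in range(jsfs.n_west + 1):
            row = "\t".join(f"{v:.10g}" for v in jsfs.counts[i])
            fh.write(f"d_w_{i}\t{row}\n")


def _read_obs(path: str) -> JointSFS:
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if len(lines) < 3 or "observation" not in lines[0]:
        raise SFSFormatError("malformed .obs file")
    folded = "folded" in lines[0] and "unfolded" not in lines[0]
    m = re.search(r"n_sites=(\d+)", lines[0])
    n_sites = int(m.group(1)) if m else None
    header = lines[1].split("\t")
    d2 = len([h for h in header if h])
    rows = []
    for line in lines[2:]:
        parts = line.split("\t")
        rows.append([float(v) for v in parts[1:]])
    counts = np.array(rows)
    if counts.shape[1] != d2:
        raise SFSFormatError("row width inconsistent with .obs header")
    counts[0, 0] = 0.0
    counts[-1, -1] = 0.0
    return JointSFS(counts, counts.shape[0] - 1, counts.shape[1] - 1,
                    folded=folded, n_sites=n_sites)


# --- VCF / tables ----------------------------------------------------------

def read_popmap(path: str) -> dict[str, str]:
    """Two-column TSV (individual, population) -> dict."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise SFSFormatError(f"malformed popmap line: {line!r}")
            out[parts[0]] = parts[1]
    return out


def read_lineage_map(path: str) -> dict[str, str]:
    """Two-column TSV (population, lineage) -> dict."""
    return read_popmap(path)


def read_vcf(path: str, popmap: dict[str, str],
             lineages: dict[str, str] | None = None) -> GenotypeMatrix:
    """Load biallelic SNP genotypes from a VCF into a dosage matrix.

    Positions are 1-based, genotypes come from the diploid GT field with "."
    treated as missing; multiallelic records are rejected, not split.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    individuals = list(vcf.samples)
    missing_pops = [s for s in individuals if s not in popmap]
    if missing_pops:
        raise GenotypeDataError(
            f"individuals absent from popmap: {missing_pops[:5]}")
    loci: list[str] = []
    rows: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise GenotypeDataError(
                f"multiallelic record at {variant.CHROM}:{variant.POS}")
        dosages = np.empty(len(individuals), dtype=np.int8)
        for i, g in enumerate(variant.genotypes):
            a, b = g[0], g[1]
            dosages[i] = -1 if (a < 0 or b < 0) else a + b
        loci.append(f"{variant.CHROM}:{variant.POS}")
        rows.append(dosages)
    geno = np.array(rows).T if rows else np.empty((len(individuals), 0), np.int8)
    return GenotypeMatrix(geno, individuals, loci, dict(popmap),
                          dict(lineages or {}))
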