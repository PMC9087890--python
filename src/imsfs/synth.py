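"""Synthetic ddRAD-like datasets with two diverged lineages.

Emulates the statistical structure the inference assumes: unlinked biallelic
loci with one SNP each (about 1,200 loci by default), two lineages produced
by a chosen two-deme demographic history, optional admixed populations, a
uniform missing-genotype rate of a few percent, and coordinate/environment
tables laid out on a west-east gradient so isolation-by-distance and
isolation-by-environment tests have known positive effects.

Admixture is haplotype-level: each of an admixed individual's two haplotypes
at each locus descends from the western parental pool with probability alpha
and from the eastern pool otherwise, which produces the mixed-ancestry
heterozygosity signature of a contact zone with a single knob.

Per locus one genealogy is simulated for all parental haplotypes and a
single segregating site is placed on a branch chosen with probability
proportional to its length (one random SNP per locus, conditioned on
polymorphism).  Loci monomorphic among the non-missing genotypes after
masking are redrawn and counted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .coalescent import SampleConfig, accumulate_expected_jsfs, simulate_genealogy
from .models import InferenceSettings, ModelParams, build_model
from .sfs import GenotypeMatrix, JointSFS


class SyntheticSpecError(ValueError):
    """Invalid synthetic-dataset specification."""


@dataclass
class PopulationSpec:
    """One sampled population: size in diploids and lineage membership.

    ``lineage`` is "west" or "east"; ``alpha`` (ancestry proportion drawn
    from the western pool) marks a population as admixed and overrides
    ``lineage`` for haplotype sampling.
    """

    name: str
    n_diploid: int
    lineage: str = "west"
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.n_diploid < 1:
            raise SyntheticSpecError("population size must be >= 1")
        if self.alpha is not None and not 0.0 <= self.alpha <= 1.0:
            raise SyntheticSpecError("alpha must lie in [0, 1]")
        if self.alpha is None and self.lineage not in ("west", "east"):
            raise SyntheticSpecError("lineage must be 'west' or 'east'")


def default_populations() -> list[PopulationSpec]:
    """Four western and four eastern populations of five diploids each."""
    pops = [PopulationSpec(f"W{i+1}", 5, "west") for i in range(4)]
    pops += [PopulationSpec(f"E{i+1}", 5, "east") for i in range(4)]
    return pops


@dataclass
class SyntheticSpec:
    """Recipe for a ddRAD-like dataset.

    Defaults mirror the scale of a typical two-lineage ddRAD study: 1,179
    unlinked one-SNP loci and ~3% missing genotypes.
    """

    model_id: str
    params: ModelParams
    settings: InferenceSettings = field(default_factory=InferenceSettings)
    populations: list[PopulationSpec] = field(default_factory=default_populations)
    n_loci: int = 1179
    missing_rate: float = 0.03
    seed: int = 0
    lon_range: tuple[float, float] = (10.0, 120.0)
    lat_center: float = 45.0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise SyntheticSpecError("n_loci must be >= 1")
        if not 0.0 <= self.missing_rate <= 0.2:
            raise SyntheticSpecError("missing_rate must lie in [0, 0.2]")
        if not self.populations:
            raise SyntheticSpecError("at least one population is required")

    def to_yaml(self) -> str:
        block = {
            "model": self.model_id,
            "params": self.params.to_dict(),
            "n_loci": self.n_loci,
            "missing_rate": self.missing_rate,
            "seed": self.seed,
            "populations": [
                {"name": p.name, "n_diploid": p.n_diploid,
                 "lineage": p.lineage, "alpha": p.alpha}
                for p in self.populations
            ],
        }
        return yaml.safe_dump(block, sort_keys=False)


@dataclass
class SyntheticDataset:
    """Generated genotypes plus the side tables the analyses consume."""

    genotypes: GenotypeMatrix
    coordinates: pd.DataFrame
    environment: pd.DataFrame
    n_redrawn: int
    spec: SyntheticSpec

    def write(self, prefix: str) -> dict[str, str]:
        """Write VCF, popmap TSV, coordinates CSV, environment CSV, YAML echo."""
        paths = {
            "vcf": f"{prefix}.vcf",
            "popmap": f"{prefix}.popmap.tsv",
            "coords": f"{prefix}.coords.csv",
            "env": f"{prefix}.env.csv",
            "spec": f"{prefix}.spec.yaml",
        }
        with open(paths["vcf"], "w") as fh:
            fh.write(self.to_vcf())
        with open(paths["popmap"], "w") as fh:
            for ind in self.genotypes.individuals:
                fh.write(f"{ind}\t{self.genotypes.popmap[ind]}\n")
        self.coordinates.to_csv(paths["coords"])
        self.environment.to_csv(paths["env"])
        with open(paths["spec"], "w") as fh:
            fh.write(self.spec.to_yaml())
        return paths

    def to_vcf(self) -> str:
        g = self.genotypes
        buf = io.StringIO()
        buf.write("##fileformat=VCFv4.2\n")
        buf.write("##source=imsfs-synthetic\n")
        buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for locus in g.loci:
            chrom = locus.split(":")[0]
            buf.write(f"##contig=<ID={chrom}>\n")
        buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(g.individuals) + "\n")
        code = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for l, locus in enumerate(g.loci):
            chrom, pos = locus.split(":")
            gts = "\t".join(code[int(v)] for v in g.genotypes[:, l])
            buf.write(f"{chrom}\t{pos}\t{locus}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")
        return buf.getvalue()


def generate_dataset(spec: SyntheticSpec,
                     rng: np.random.Generator | int | None = None) -> SyntheticDataset:
    """Simulate a full ddRAD-like dataset under the spec's demographic model."""
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    model = build_model(spec.model_id, spec.params, spec.settings)

    pops = spec.populations
    n_ind = sum(p.n_diploid for p in pops)
    individuals: list[str] = []
    popmap: dict[str, str] = {}
    lineages: dict[str, str] = {}
    for p in pops:
        for i in range(p.n_diploid):
            name = f"{p.name}_{i+1:02d}"
            individuals.append(name)
            popmap[name] = p.name
        lineages[p.name] = "admixed" if p.alpha is not None else p.lineage

    # per-haplotype probability of drawing from the western parental pool
    alpha_of_pop = {p.name: (p.alpha if p.alpha is not None
                             else (1.0 if p.lineage == "west" else 0.0))
                    for p in pops}
    hap_alpha = np.repeat([alpha_of_pop[p.name] for p in pops],
                          [2 * p.n_diploid for p in pops])
    n_hap = hap_alpha.size

    geno = np.empty((n_ind, spec.n_loci), dtype=np.int8)
    n_redrawn = 0
    max_redraws = 50 * spec.n_loci
    locus = 0
    while locus < spec.n_loci:
        if n_redrawn > max_redraws:
            raise SyntheticSpecError(
                "retry budget exhausted: model yields too few polymorphic loci")
        from_west = rng.random(n_hap) < hap_alpha
        n_w = int(from_west.sum())
        n_e = n_hap - n_w
        if n_w + n_e < 2:
            raise SyntheticSpecError("need at least two haplotypes")
        gene = simulate_genealogy(model, SampleConfig(n_w, n_e), rng)
        # one segregating site: branch chosen proportional to length
        branches = gene.branches
        lengths = np.array([b[0] for b in branches])
        non_root = [v for v in range(len(gene.parent)) if gene.parent[v] >= 0]
        pick = non_root[rng.choice(len(non_root), p=lengths / lengths.sum())]
        carriers = set(gene.leaf_sets[pick].tolist())
        # map genealogy leaves back to haplotypes: west leaves 0..n_w-1 are the
        # haplotypes with from_west=True in order, east leaves follow
        hap_leaf = np.empty(n_hap, dtype=int)
        hap_leaf[from_west] = np.arange(n_w)
        hap_leaf[~from_west] = n_w + np.arange(n_e)
        derived = np.isin(hap_leaf, list(carriers))
        dosage = derived.reshape(n_ind, 2).sum(axis=1).astype(np.int8)
        # uniform missingness
        if spec.missing_rate > 0:
            miss = rng.random(n_ind) < spec.missing_rate
            dosage[miss] = -1
        obs = dosage[dosage >= 0]
        if obs.size == 0 or obs.sum() == 0 or obs.sum() == 2 * obs.size:
            n_redrawn += 1
            continue
        geno[:, locus] = dosage
        locus += 1

    loci = [f"locus{l+1}:{(l+1) * 1000}" for l in range(spec.n_loci)]
    gmat = GenotypeMatrix(geno, individuals, loci, popmap, lineages)

    # west-east longitudinal layout with jitter; environment tracks longitude
    lon_lo, lon_hi = spec.lon_range
    west_pops = [p for p in pops if alpha_of_pop[p.name] >= 0.5]
    east_pops = [p for p in pops if alpha_of_pop[p.name] < 0.5]
    lons = {}
    for k, p in enumerate(west_pops):
        lons[p.name] = lon_lo + (lon_hi - lon_lo) * 0.4 * (k + 1) / (len(west_pops) + 1)
    for k, p in enumerate(east_pops):
        lons[p.name] = lon_lo + (lon_hi - lon_lo) * (0.6 + 0.4 * (k + 1) / (len(east_pops) + 1))
    rows = []
    for p in pops:
        lon = lons[p.name] + rng.normal(0, 1.0)
        lat = spec.lat_center + rng.normal(0, 2.0)
        rows.append({"population": p.name, "latitude": lat, "longitude": lon})
    coords = pd.DataFrame(rows).set_index("population")
    env = pd.DataFrame({
        "temperature": 20.0 - 0.05 * (coords["longitude"] - lon_lo)
        + rng.normal(0, 0.5, len(pops)),
        "aridity": 0.01 * (coords["longitude"] - lon_lo)
        + rng.normal(0, 0.05, len(pops)),
    }, index=coords.index)

    return SyntheticDataset(genotypes=gmat, coordinates=coords,
                            environment=env, n_redrawn=n_redrawn, spec=spec)


def generate_jsfs(
    model_id: str,
    params: ModelParams,
    settings: InferenceSettings,
    n_west: int,
    n_east: int,
    n_snps: int,
    rng: np.random.Generator | int | None = None,
    n_sims: int = 200_000,
    with_n_sites: bool = True,
) -> JointSFS:
    """Multinomial draw of ``n_snps`` SNPs from a model's expected joint SFS.

    The expected spectrum is estimated from ``n_sims`` genealogies; when
    ``with_n_sites`` is set, the spectrum records the implied total number of
    surveyed sites n_snps / P(site polymorphic), giving downstream fits an
    absolute-scale anchor consistent with the generating model.
    """
    if n_snps < 1:
        raise SyntheticSpecError("n_snps must be >= 1")
    rng = np.random.default_rng(rng)
    model = build_model(model_id, params, settings)
    sim_seed = int(rng.integers(2**31))
    bct = accumulate_expected_jsfs(model, SampleConfig(n_west, n_east),
                                   n_sims, sim_seed)
    q = bct.normalized()
    mask = np.zeros_like(q, dtype=bool)
    mask[0, 0] = mask[-1, -1] = True
    probs = q[~mask] / q[~mask].sum()
    draws = rng.multinomial(n_snps, probs)
    counts = np.zeros_like(q)
    counts[~mask] = draws
    n_sites = None
    if with_n_sites:
        p_poly = float(np.mean(-np.expm1(-settings.mu * bct.tree_lengths)))
        n_sites = int(round(n_snps / p_poly))
    return JointSFS(counts, n_west, n_east, folded=False, n_sites=n_sites)
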