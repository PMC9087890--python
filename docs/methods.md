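# Methods

This note records the modelling conventions, numerical choices, and known
limitations of `imsfs`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model space and conventions

The ten candidate histories are two-deme (west/east) divergence models
differing only in when migration operates and in which direction:

| id  | migration epoch          | direction (forward in time) |
|-----|--------------------------|-----------------------------|
| M1  | none                     | —                           |
| M2  | continuous [0, T_div)    | symmetric                   |
| M3  | continuous               | west → east                 |
| M4  | continuous               | east → west                 |
| M5  | ancient [T_contact, T_div) | symmetric                 |
| M6  | recent [0, T_contact)    | bidirectional               |
| M7  | recent                   | west → east                 |
| M8  | recent                   | east → west                 |
| M9  | ancient                  | west → east                 |
| M10 | ancient                  | east → west                 |

This assignment of labels to topologies is a package convention, recorded in
an explicit, overridable table (`MODEL_TOPOLOGY`); the "recent bidirectional"
reading of M6 pins the secondary-contact case. Sizes are diploid effective
sizes (coalescence rate k(k−1)/2 · 1/(2N) per generation for k lineages);
times are user-facing in years and internal in generations (divided by the
generation time, default 0.5 y); mutation rate defaults to 3.5e-9 per site
per generation.

Migration parameters are per-generation probabilities with the forward
reading "m_EW = migration of the eastern lineage into the western lineage".
Backward in time this is the rate at which a lineage sampled in the **west**
traces into the **east**. Whether published rates of this kind are forward or
backward quantities is often ambiguous; the convention here is stated once in
`imsfs.models` and is swappable by exchanging the two rates.

Default search bounds: sizes 1e2–1e8 diploids, times 1e2–1e7 years, migration
1e-9–1e-3, all searched on a log10 scale. They bracket plausible estimates
for a widespread insect by at least two orders of magnitude on each side.

## Coalescent engine

Genealogies are simulated under the continuous-time structured coalescent
(exponential waiting times; error O(1/N) relative to the discrete-generation
model). Within an epoch the four competing clocks are within-deme coalescence
at rate k_d(k_d−1)/(4N_d) and per-lineage migration at rate k_d·m_d. A
waiting time that overshoots the next epoch boundary (or the merge at T_div)
advances the state to the boundary and redraws clocks; the merge moves all
lineages into the ancestral deme instantaneously. Coalescing pairs are chosen
uniformly within the deme.

The expected joint SFS is estimated by accumulating branch length per
(i, j) descendant-count class over genealogies (a Rao-Blackwellized
estimator) rather than by dropping Poisson mutations — strictly lower
variance for the same number of genealogies, and the likelihood only needs
relative class masses. The batch kernel is numba-compiled and deterministic
given a seed; a plain-Python single-genealogy path retains full topology for
newick export and per-locus genotype simulation. The engine is checked
against the closed forms E[T_2] = 2N and E[L_i] = 4N/i, and against msprime
on the secondary-contact topology (total-variation distance of normalized
spectra ≈ 1e-3 at 50,000 genealogies per side).

## Likelihood and its absolute scale

With observed counts m_ij over unmasked cells (the monomorphic corners (0,0)
and (n_w, n_e) never contribute) and floored, renormalized expected
probabilities p_ij, the composite log-likelihood is Σ m_ij ln p_ij. The floor
for empty expected cells defaults to 1/(10 · n_sims · n_cells), which
prevents −∞ while vanishing as simulation effort grows. Natural logarithms
are used throughout and AIC = 2k − 2 lnL; the log base only shifts all
models equally on a fixed dataset, so Akaike weights are unaffected.

A likelihood restricted to polymorphic cells is exactly invariant under the
rescaling (N, T, m) → (cN, cT, m/c): the conditional spectrum shape carries
no information about absolute sizes or times. Scale is anchored through the
known mutation rate: when a spectrum records the total number of surveyed
sites L (`JointSFS.n_sites`), the objective adds the binomial term
S ln p_poly + (L−S) ln(1−p_poly), where p_poly = E[1 − exp(−μ·T_tree)] is the
per-site polymorphism probability under the model and S the SNP count. The
synthetic generator records the L implied by its generating model, and
spectra built from real data can carry the surveyed-site count of their
assembly. Without `n_sites` the fit explores the scale ridge freely and only
ratios are meaningful.

## Optimization and model comparison

Each of `n_reps` replicates starts from an independent log10-uniform point in
the search box (with T_contact resampled below T_div) and runs up to
`n_cycles` conditional-maximization cycles: one bounded Brent search per free
parameter per cycle (absolute tolerance 0.015 log10 units), with dynamic
bounds keeping T_contact < T_div. Within a replicate the simulation seed of
every expected-SFS evaluation is fixed (common random numbers), making the
surface deterministic and the 1-D searches well-posed; evaluations are
memoized. Cycling stops early once a full cycle improves the likelihood by
less than 0.05 units. The winning replicate minimizes the gap between the
saturated bound and the fitted likelihood, ties going to the lower replicate
index.

Because each replicate's likelihood is measured on its own finite-simulation
surface, values carried directly into AIC would differ across models by
Monte-Carlo noise of several units — enough to reverse rankings between
near-equivalent models and even to violate nesting. The reported `lnL_est`
is therefore re-evaluated at the winning optimum with 10× the optimization
`n_sims`, and model selection shares one evaluation seed across all
candidates, so AIC differences are measured on a common high-precision
surface.

## Parametric bootstrap

Each replicate redraws a spectrum of the observed SNP count multinomially
from the fitted model's expected spectrum (carrying the implied surveyed-site
count) and refits the same model; the 2.5/97.5 percentiles of the replicate
estimates form the 95% interval and the replicate mean is reported alongside.
Refits default to 5 replicates instead of the 50 used for primary fits — a
tractability choice restorable via `n_reps_boot`. Intervals therefore include
refit Monte-Carlo noise on top of sampling noise. Coverage is verified at
reduced scale in the test suite (20 truths × 50 bootstrap replicates on a
two-free-parameter isolation model).

## Population-genetic statistics

* **Diversity** per population: H_O is the heterozygote fraction among
  non-missing genotypes; H_E uses the small-sample correction
  2n/(2n−1) · 2p̂(1−p̂); π_S is the mean pairwise allele difference per SNP
  site, computed over the retained (variable) loci — this per-SNP denominator
  is stated in the output metadata because per-sequence-site alternatives
  exist.
* **AMOVA** (two levels: groups / populations within groups / within
  populations) uses squared Euclidean distances on genotype dosage vectors,
  equivalent to the standard locus-by-locus formulation summed over loci;
  missing entries are excluded pairwise with the distance rescaled to the
  full locus count. Permutation schemes: whole populations among groups for
  Φ_CT, individuals among populations within groups for Φ_SC, individuals
  among all populations for Φ_ST. P-values use the add-one rule
  (1 + #{perm ≥ obs})/(n_perm + 1) and are never zero; degenerate inputs
  (zero total variance) are flagged rather than divided through.
* **Mantel** tests correlate off-diagonal upper triangles, permuting rows and
  columns of the second matrix simultaneously, one-tailed for positive
  association; for ≤ 7 labels all permutations are enumerated exactly.
  Geographic distances are haversine great-circle distances (Earth radius
  6371 km). Environmental and resistance matrices are accepted as
  precomputed inputs.

## Synthetic data generator

The generator emulates the structure of a two-lineage ddRAD SNP panel:
~1,179 unlinked loci with one segregating site each (the site is placed on a
branch chosen proportionally to length, i.e. one random SNP per locus
conditioned on polymorphism), uniform missing genotypes at ~3%, populations
laid on a west–east longitudinal gradient with environment variables tracking
longitude, and optional admixed populations. Admixture is haplotype-level:
each haplotype of an admixed individual descends from the western parental
pool with probability α, independently per locus — this reproduces the
mixed-ancestry heterozygosity signature of a contact zone with a single knob,
without simulating the contact demography per individual. Loci monomorphic
among the observed genotypes after masking are redrawn and counted.

Not emulated: locus dropout correlated with divergence (allele dropout),
linked sites within loci, sequencing error, genotype-likelihood uncertainty,
or mito-nuclear discordance. Passing tests on these data therefore speak to
the statistical machinery under the stated sampling model, not to robustness
against RAD-specific artefacts.

## Study scales and identifiability limits

The packaged recovery studies run at desk scale: 20,000 SNPs at samples
(10, 10) for model selection (5,000 simulations per evaluation, 20 cycles, 5
replicates per model, ~10 minutes on one CPU), and 20 truths × 50 bootstrap
replicates at (6, 6) with 2,000 SNPs for interval coverage. Two genuine
identifiability limits at this scale are worth stating plainly:

* **Contact time.** With weak recent migration, T_contact and the migration
  rates enter the spectrum almost exclusively through their product: the
  profile likelihood along the (m · T_contact = const) ridge is flat to
  within ~1 log-likelihood unit across more than an order of magnitude in
  T_contact, which is below the Monte-Carlo noise of the evaluations. The
  T_contact point estimate is therefore an essentially arbitrary point on the
  ridge; the product, and the direction asymmetry of the rates, are what the
  data determine.
* **Support for the richest model.** When the weaker migration direction
  contributes ~0.02 expected migrant lineages per locus, a 20,000-SNP
  spectrum contains almost no evidence for it: the fitted likelihood gap
  between the bidirectional secondary-contact model and its best
  single-direction competitor is below the AIC penalty of the extra
  parameter, so parsimony-driven selection can prefer the reduced history.
  Decisive weights for the full model require the information content of a
  much larger dataset than the desk-scale study simulates.

Sizes (N_west, N_east), the divergence time, and — through the post-merge
mixing signal — the ancestral size are well identified at this scale.

## Other design decisions

* Spectra default to unfolded in simulation studies (ancestral state known by
  construction) and can be folded for real, unpolarized data; folding merges
  (i, j) with its complement, the lower-total-count member receiving the
  mass. Projection targets for real data are configuration, since assembly
  missingness patterns vary.
* VCF input follows the plain diploid-GT conventions: 1-based positions, "."
  as missing, multiallelic records rejected rather than split.
* Serialized outputs (TSV/JSON/YAML) echo all seeds and settings so any run
  can be replayed exactly.
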