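"""Composite-likelihood fitting of demographic models to a joint SFS.

The likelihood treats SNPs as independent draws from the model's expected
joint-SFS cell probabilities (a multinomial composite likelihood); the
monomorphic corner cells never contribute.  Expected probabilities come from
Monte-Carlo branch-class totals (:mod:`imsfs.coalescent`), floored and
renormalized so empty cells cannot produce -inf.

Absolute scale.  A likelihood over polymorphic cells alone is invariant under
(N, T, m) -> (cN, cT, m/c), so sizes and times in physical units are not
identifiable from the spectrum shape.  When the observed spectrum records the
total number of surveyed sites (``JointSFS.n_sites``), the fitting objective
adds a binomial polymorphic/monomorphic term: with per-site polymorphism
probability p_poly = E[1 - exp(-mu * T_tree)], the S observed SNPs among
n_sites sites anchor the absolute time scale through the known mutation
rate.  Without ``n_sites`` the fit explores the scale ridge freely and only
shape parameters (ratios) are meaningful.

Optimization mirrors the cycle structure of SFS-based coalescent fitters:
each replicate starts from a random point in the (log10) search box and runs
conditional-maximization cycles, one bounded 1-D search per free parameter
per cycle, with the Monte-Carlo seed fixed within a replicate (common random
numbers) so the surface is deterministic.  The replicate minimizing
``lnL_obs - lnL_est`` wins; ties go to the lower replicate index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .coalescent import SampleConfig, accumulate_expected_jsfs
from .models import (
    InferenceSettings,
    ModelParams,
    build_model,
    expand_params,
    free_parameters,
    model_id as make_model_id,
)
from .sfs import JointSFS, fold_matrix


class SpectrumMismatchError(ValueError):
    """Observed and expected spectra have incompatible shape or orientation."""


class OptimizationFailure(RuntimeError):
    """All optimization replicates returned non-finite likelihoods."""


@dataclass
class ExpectedJSFS:
    """Simulator-derived cell probabilities conditioned on polymorphism.

    ``probs`` sums to one over unmasked cells after flooring at ``floor`` and
    renormalizing.  ``p_poly`` is the per-site polymorphism probability under
    the generating mutation rate (None when no rate was supplied).
    """

    probs: np.ndarray
    n_sims: int
    floor: float
    model: str
    params: ModelParams
    mean_tree_length: float
    p_poly: float | None = None
    folded: bool = False


def _mask(shape: tuple[int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[0, 0] = True
    m[-1, -1] = True
    return m


def expected_jsfs(
    identifier: str,
    params: ModelParams,
    settings: InferenceSettings,
    config: SampleConfig,
    seed: int,
    folded: bool | None = None,
) -> ExpectedJSFS:
    """Monte-Carlo expected joint SFS for a model at given parameters."""
    model = build_model(identifier, params, settings)
    bct = accumulate_expected_jsfs(model, config, settings.n_sims, seed)
    totals = bct.totals
    fold = settings.folded if folded is None else folded
    if fold:
        totals = fold_matrix(totals)
    mask = _mask(totals.shape)
    if fold:
        # cells that fold onto others carry no mass and stay excluded
        mask |= _fold_shadow(totals.shape)
    n_unmasked = int((~mask).sum())
    floor = settings.min_cell_prob
    if floor is None:
        floor = 1.0 / (10.0 * settings.n_sims * n_unmasked)
    q = np.zeros_like(totals)
    s = totals[~mask].sum()
    q[~mask] = totals[~mask] / s
    q[~mask] = np.maximum(q[~mask], floor)
    q[~mask] /= q[~mask].sum()
    p_poly = float(np.mean(-np.expm1(-settings.mu * bct.tree_lengths)))
    return ExpectedJSFS(
        probs=q, n_sims=settings.n_sims, floor=floor, model=identifier,
        params=params, mean_tree_length=bct.mean_tree_length,
        p_poly=p_poly, folded=fold,
    )


def _fold_shadow(shape: tuple[int, int]) -> np.ndarray:
    """Cells that a fold maps onto their complements (zero after folding)."""
    nw, ne = shape[0] - 1, shape[1] - 1
    shadow = np.zeros(shape, dtype=bool)
    for i in range(nw + 1):
        for j in range(ne + 1):
            ci, cj = nw - i, ne - j
            if (i + j, i, j) > (ci + cj, ci, cj):
                shadow[i, j] = True
    return shadow


def composite_loglik(obs: JointSFS, expected: ExpectedJSFS) -> float:
    """Sum of m_ij * ln p_ij over unmasked cells (monomorphic corners excluded)."""
    if obs.counts.shape != expected.probs.shape or obs.folded != expected.folded:
        raise SpectrumMismatchError("observed and expected spectra do not align")
    mask = _mask(obs.counts.shape)
    m = obs.counts[~mask]
    p = expected.probs[~mask]
    if np.any((m > 0) & (p <= 0)):
        raise SpectrumMismatchError(
            "expected spectrum has an unfloored zero cell with observed mass"
        )
    sel = m > 0
    return float(np.sum(m[sel] * np.log(p[sel])))


def max_obs_loglik(obs: JointSFS) -> float:
    """Saturated log-likelihood of the observed spectrum.

    Sum of m_ij ln(m_ij / M) over occupied cells; when the spectrum carries a
    total-site count, the saturated binomial polymorphism term is included so
    the value is comparable with :func:`model_loglik`.
    """
    mask = _mask(obs.counts.shape)
    m = obs.counts[~mask]
    total = m.sum()
    if total <= 0:
        raise SpectrumMismatchError("empty spectrum")
    sel = m > 0
    ll = float(np.sum(m[sel] * np.log(m[sel] / total)))
    if obs.n_sites is not None:
        s, sites = float(total), float(obs.n_sites)
        phat = s / sites
        ll += s * math.log(phat) + (sites - s) * math.log1p(-phat)
    return ll


def model_loglik(obs: JointSFS, expected: ExpectedJSFS) -> float:
    """Full fitting objective: cell composite likelihood plus scale anchor.

    Equals :func:`composite_loglik` when ``obs.n_sites`` is absent.
    """
    ll = composite_loglik(obs, expected)
    if obs.n_sites is not None:
        if expected.p_poly is None:
            raise SpectrumMismatchError("expected spectrum lacks p_poly")
        s = float(obs.total)
        sites = float(obs.n_sites)
        p = min(max(expected.p_poly, 1e-300), 1.0 - 1e-12)
        ll += s * math.log(p) + (sites - s) * math.log1p(-p)
    return ll


@dataclass
class FitResult:
    """Best replicate of a composite-likelihood fit for one model."""

    model: str
    params: ModelParams
    lnL_est: float
    lnL_obs: float
    delta: float
    aic: float
    k: int
    n_evaluations: int
    replicate: int
    seed: int
    converged: bool
    free_values: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "model": self.model, "lnL_est": self.lnL_est,
            "lnL_obs": self.lnL_obs, "delta": self.delta, "aic": self.aic,
            "k": self.k, "n_evaluations": self.n_evaluations,
            "replicate": self.replicate, "seed": self.seed,
            "converged": self.converged,
        }
        d.update({f"param_{k}": v for k, v in self.params.to_dict().items()})
        return d


def _replicate_fit(obs, identifier, settings, free, fixed, rep_index, rep_seed,
                   start_rng):
    """One conditional-maximization replicate; returns (lnL, values, n_eval)."""
    config = SampleConfig(obs.n_west, obs.n_east)
    lo = {name: math.log10(l) for name, l, _, _ in free}
    hi = {name: math.log10(h) for name, _, h, _ in free}
    x = {}
    for name, l, h, _ in free:
        x[name] = start_rng.uniform(lo[name], hi[name])
    # keep the epoch ordering T_contact < T_div from the start
    if "T_contact" in x and "T_div" in x and x["T_contact"] >= x["T_div"]:
        x["T_contact"] = start_rng.uniform(lo["T_contact"], x["T_div"])

    cache: dict[tuple, float] = {}
    n_eval = 0

    def objective(xdict) -> float:
        nonlocal n_eval
        key = tuple(round(v, 7) for v in xdict.values())
        if key in cache:
            return cache[key]
        values = {n: 10.0 ** v for n, v in xdict.items()}
        values.update(fixed)
        params = expand_params(identifier, values)
        exp = expected_jsfs(identifier, params, settings, config, rep_seed,
                            folded=obs.folded)
        ll = model_loglik(obs, exp)
        n_eval += 1
        cache[key] = ll
        return ll

    best = objective(x)
    converged = False
    for cycle in range(settings.n_cycles):
        cycle_start = best
        for name in x:
            a, b = lo[name], hi[name]
            # dynamic bounds keep T_contact strictly below T_div
            if name == "T_contact" and "T_div" in x:
                b = min(b, x["T_div"] - 1e-6)
            elif name == "T_div" and "T_contact" in x:
                a = max(a, x["T_contact"] + 1e-6)
            if b <= a:
                continue

            def neg(v, _name=name):
                trial = dict(x)
                trial[_name] = float(v)
                return -objective(trial)

            res = minimize_scalar(neg, bounds=(a, b), method="bounded",
                                  options={"xatol": 0.015, "maxiter": 25})
            if -res.fun >= best:
                x[name] = float(res.x)
                best = -res.fun
        if best - cycle_start < 0.05:
            converged = True
            break
    values = {n: 10.0 ** v for n, v in x.items()}
    values.update(fixed)
    return best, values, n_eval, converged


def fit_model(
    obs: JointSFS,
    identifier: str,
    settings: InferenceSettings,
    seed: int | None = None,
    fixed: dict[str, float] | None = None,
    final_n_sims: int | None = None,
    final_seed: int | None = None,
) -> FitResult:
    """Fit one model by replicated conditional-maximization.

    ``fixed`` pins named parameters (removing them from the search), e.g. for
    restricted or profile fits.  Deterministic given ``seed``.

    The reported ``lnL_est`` is re-evaluated at the winning optimum with
    ``final_n_sims`` genealogies (default 10x the optimization setting) and
    the evaluation seed ``final_seed``: likelihoods compared across models
    should share one high-precision Monte-Carlo surface rather than each
    model's own optimization noise.
    """
    if obs.total <= 0:
        raise SpectrumMismatchError("observed spectrum is empty")
    base_seed = settings.seed if seed is None else seed
    if base_seed is None:
        base_seed = 0
    fixed = dict(fixed or {})
    free = [f for f in free_parameters(identifier) if f[0] not in fixed]
    mid = make_model_id(identifier)

    lnl_obs = max_obs_loglik(obs)
    results = []
    total_eval = 0
    for rep in range(settings.n_reps):
        ss = np.random.SeedSequence([int(base_seed) % (2**31), rep])
        sim_seed, start_seed = ss.generate_state(2)
        start_rng = np.random.default_rng(start_seed)
        try:
            lnl, values, n_eval, conv = _replicate_fit(
                obs, identifier, settings, free, fixed, rep, int(sim_seed),
                start_rng)
        except FloatingPointError:
            continue
        total_eval += n_eval
        if math.isfinite(lnl):
            results.append((lnl_obs - lnl, rep, lnl, values, conv))
    if not results:
        raise OptimizationFailure(
            f"{identifier}: no replicate produced a finite likelihood")
    # smallest MaxObs-MaxEst gap wins; ties resolved by replicate index
    results.sort(key=lambda r: (r[0], r[1]))
    delta, rep, lnl, values, conv = results[0]
    params = expand_params(identifier, values)
    k = len(free)

    # common-surface re-evaluation of the winning optimum
    if final_n_sims is None:
        final_n_sims = 10 * settings.n_sims
    if final_seed is None:
        final_seed = int(np.random.SeedSequence(
            [int(base_seed) % (2**31), 999_983]).generate_state(1)[0])
    final_settings = InferenceSettings(
        mu=settings.mu, gen_time=settings.gen_time, n_sims=int(final_n_sims),
        n_cycles=settings.n_cycles, n_reps=settings.n_reps, seed=settings.seed,
        folded=settings.folded, min_cell_prob=settings.min_cell_prob,
    )
    exp = expected_jsfs(identifier, params, final_settings,
                        SampleConfig(obs.n_west, obs.n_east),
                        int(final_seed) % (2**32), folded=obs.folded)
    lnl = model_loglik(obs, exp)
    delta = lnl_obs - lnl
    return FitResult(
        model=identifier, params=params, lnL_est=lnl, lnL_obs=lnl_obs,
        delta=delta, aic=2.0 * k - 2.0 * lnl, k=k, n_evaluations=total_eval,
        replicate=rep, seed=int(base_seed), converged=conv,
        free_values={n: values[n] for n in (f[0] for f in free)},
    )


@dataclass
class ModelSelection:
    """Per-model best fits with AIC differences and Akaike weights."""

    fits: dict[str, FitResult]
    delta_aic: dict[str, float]
    weights: dict[str, float]
    best_model: str
    failed: dict[str, str] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        rows = []
        for ident, fit in self.fits.items():
            row = fit.to_dict()
            row["delta_aic"] = self.delta_aic[ident]
            row["akaike_weight"] = self.weights[ident]
            rows.append(row)
        return pd.DataFrame(rows).sort_values("delta_aic").reset_index(drop=True)


def akaike_weights(aics: dict[str, float]) -> tuple[dict[str, float], dict[str, float]]:
    """AIC differences and normalized Akaike weights."""
    best = min(aics.values())
    delta = {k: v - best for k, v in aics.items()}
    raw = {k: math.exp(-d / 2.0) for k, d in delta.items()}
    z = sum(raw.values())
    return delta, {k: v / z for k, v in raw.items()}


def select_models(
    obs: JointSFS,
    identifiers: list[str],
    settings: InferenceSettings,
    seed: int | None = None,
) -> ModelSelection:
    """Fit each candidate model and rank by AIC (natural-log likelihoods)."""
    if not identifiers:
        raise ValueError("need at least one model identifier")
    base_seed = settings.seed if seed is None else seed
    if base_seed is None:
        base_seed = 0
    fits: dict[str, FitResult] = {}
    failed: dict[str, str] = {}
    # one high-precision evaluation seed shared by every model, so AIC
    # differences are measured on a common Monte-Carlo surface
    final_seed = int(np.random.SeedSequence(
        [int(base_seed) % (2**31), 999_983]).generate_state(1)[0])
    for i, ident in enumerate(identifiers):
        model_seed = int(np.random.SeedSequence(
            [int(base_seed) % (2**31), 10_000 + i]).generate_state(1)[0] % (2**31))
        try:
            fits[ident] = fit_model(obs, ident, settings, seed=model_seed,
                                    final_seed=final_seed)
        except OptimizationFailure as err:
            failed[ident] = str(err)
    if not fits:
        raise OptimizationFailure("every candidate model failed to fit")
    delta, weights = akaike_weights({k: f.aic for k, f in fits.items()})
    best = min(delta, key=lambda k: (delta[k], k))
    return ModelSelection(fits=fits, delta_aic=delta, weights=weights,
                          best_model=best, failed=failed)
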