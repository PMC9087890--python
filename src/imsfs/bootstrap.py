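"""Parametric-bootstrap confidence intervals for fitted demographic models.

Each replicate draws a joint SFS of the observed SNP count multinomially
from the fitted model's expected spectrum and refits the same model; the
percentile method gives the 95% interval and the replicate mean is reported
alongside.  Refits default to a reduced replicate count (5 rather than the
50 used for the primary fit) — restore with ``n_reps_boot``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import FitResult, OptimizationFailure, fit_model
from .models import InferenceSettings
from .synth import generate_jsfs


class BootstrapError(ValueError):
    """Invalid bootstrap request."""


@dataclass
class BootstrapResult:
    """Replicate table plus per-parameter mean and 95% percentile interval."""

    replicates: pd.DataFrame
    summary: dict[str, dict[str, float]]
    n_boot: int
    n_failed: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return self.replicates


def parametric_bootstrap(
    fit: FitResult,
    obs_size: int,
    settings: InferenceSettings,
    n_boot: int = 100,
    rng: np.random.Generator | int | None = None,
    n_reps_boot: int = 5,
    n_sims_expected: int = 100_000,
    fixed: dict[str, float] | None = None,
    failure_budget: float = 0.2,
    n_west: int | None = None,
    n_east: int | None = None,
) -> BootstrapResult:
    """Percentile 95% CIs from parametric-bootstrap refits.

    ``obs_size`` is the SNP count of each simulated spectrum (normally the
    observed total).  ``fixed`` pins parameters during refits, matching a
    restricted original fit.  Refit failures beyond ``failure_budget`` (as a
    fraction of ``n_boot``) raise :class:`OptimizationFailure`.
    """
    if n_boot < 1:
        raise BootstrapError("n_boot must be >= 1")
    if n_west is None or n_east is None:
        raise BootstrapError("n_west/n_east haploid sample sizes are required")
    rng = np.random.default_rng(rng)
    seed = int(rng.integers(2**31))
    master = np.random.default_rng(seed)

    boot_settings = InferenceSettings(
        mu=settings.mu, gen_time=settings.gen_time, n_sims=settings.n_sims,
        n_cycles=settings.n_cycles, n_reps=n_reps_boot, seed=None,
        folded=settings.folded, min_cell_prob=settings.min_cell_prob,
    )

    rows = []
    n_failed = 0
    for b in range(n_boot):
        draw_rng = np.random.default_rng(master.integers(2**31))
        jsfs = generate_jsfs(
            fit.model, fit.params, settings, n_west, n_east, obs_size,
            rng=draw_rng, n_sims=n_sims_expected,
        )
        try:
            refit = fit_model(jsfs, fit.model, boot_settings,
                              seed=int(master.integers(2**31)), fixed=fixed)
        except OptimizationFailure:
            n_failed += 1
            continue
        row = {"replicate": b, "lnL_est": refit.lnL_est, "delta": refit.delta}
        row.update(refit.free_values)
        rows.append(row)
    if n_failed > failure_budget * n_boot:
        raise OptimizationFailure(
            f"{n_failed}/{n_boot} bootstrap refits failed")
    table = pd.DataFrame(rows)
    param_cols = [c for c in table.columns
                  if c not in ("replicate", "lnL_est", "delta")]
    summary = {}
    for c in param_cols:
        vals = table[c].to_numpy()
        lo, hi = np.percentile(vals, [2.5, 97.5])
        summary[c] = {"mean": float(vals.mean()),
                      "lo": float(lo), "hi": float(hi)}
    return BootstrapResult(replicates=table, summary=summary, n_boot=n_boot,
                           n_failed=n_failed, seed=seed)
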