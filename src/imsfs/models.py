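"""Two-population isolation–migration model space.

Ten variants of a two-deme (west/east) divergence history are supported,
differing only in when gene flow operates and in which direction:

========  ==========================  ==========================================
 id        migration epoch             direction (forward in time)
========  ==========================  ==========================================
 M1        none                        —
 M2        continuous [0, T_div)       symmetric
 M3        continuous [0, T_div)       west → east
 M4        continuous [0, T_div)       east → west
 M5        ancient [T_contact, T_div)  symmetric
 M6        recent [0, T_contact)       bidirectional (secondary contact)
 M7        recent [0, T_contact)       west → east
 M8        recent [0, T_contact)       east → west
 M9        ancient [T_contact, T_div)  west → east
 M10       ancient [T_contact, T_div)  east → west
========  ==========================  ==========================================

Times are user-facing in years and internal in generations.  Sizes are diploid
effective sizes; the coalescence rate for k lineages in a deme of size N is
k(k-1)/2 * 1/(2N) per generation.

Direction convention (stated once, used everywhere): ``m_EW`` is the
per-generation probability of migration of the eastern lineage into the
western lineage, forward in time.  Backward in time this is the rate at which
a lineage currently sampled in the *west* traces its ancestry into the *east*.
``m_WE`` is the mirror image.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass

import numpy as np
import yaml


class UnknownModelError(KeyError):
    """Raised for a model identifier outside M1..M10."""


class ModelParameterError(ValueError):
    """Raised when a required demographic parameter is missing or invalid."""


class TimeOrderingError(ValueError):
    """Raised when T_contact >= T_div or times are otherwise inconsistent."""


@dataclass(frozen=True)
class ModelParams:
    """Demographic quantities of a two-population history.

    Sizes are diploid effective sizes (individuals); times are years before
    present; migration values are per-generation probabilities.  Fields unused
    by a given model are left at zero.
    """

    N_anc: float = 0.0
    N_west: float = 0.0
    N_east: float = 0.0
    T_div: float = 0.0
    T_contact: float = 0.0
    m_EW: float = 0.0
    m_WE: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass
class InferenceSettings:
    """Knobs of the composite-likelihood machinery.

    mu
        Mutation rate per site per generation (default 3.5e-9).
    gen_time
        Generation time in years (default 0.5).
    n_sims
        Coalescent genealogies per expected-SFS evaluation (full scale 50,000).
    n_cycles
        Conditional-maximization cycles per optimization replicate (full
        scale 40).
    n_reps
        Independent optimization replicates per model (full scale 50).
    min_cell_prob
        Probability floor applied to empty expected cells; ``None`` selects
        1 / (10 * n_sims * n_unmasked_cells) at evaluation time.
    """

    mu: float = 3.5e-9
    gen_time: float = 0.5
    n_sims: int = 50_000
    n_cycles: int = 40
    n_reps: int = 50
    seed: int | None = None
    folded: bool = False
    min_cell_prob: float | None = None

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ModelParameterError("mu must be > 0")
        if self.gen_time <= 0:
            raise ModelParameterError("gen_time must be > 0")
        for name in ("n_sims", "n_cycles", "n_reps"):
            if getattr(self, name) < 1:
                raise ModelParameterError(f"{name} must be >= 1")
        if self.min_cell_prob is not None and not (0 < self.min_cell_prob < 1):
            raise ModelParameterError("min_cell_prob must lie in (0, 1)")


# --- topology ledger -------------------------------------------------------

# (epoch, direction); epoch in {none, continuous, recent, ancient},
# direction in {none, sym, WE, EW, both}.  "WE" = forward west->east flow
# (parameter m_WE), "EW" = forward east->west flow (parameter m_EW).
MODEL_TOPOLOGY: dict[str, tuple[str, str]] = {
    "M1": ("none", "none"),
    "M2": ("continuous", "sym"),
    "M3": ("continuous", "WE"),
    "M4": ("continuous", "EW"),
    "M5": ("ancient", "sym"),
    "M6": ("recent", "both"),
    "M7": ("recent", "WE"),
    "M8": ("recent", "EW"),
    "M9": ("ancient", "WE"),
    "M10": ("ancient", "EW"),
}

MODEL_IDS = tuple(MODEL_TOPOLOGY)

# default log10-scaled search bounds; sizes and times bracket plausible
# insect-population histories by well over two orders of magnitude
SIZE_BOUNDS = (1e2, 1e8)        # diploid individuals
TIME_BOUNDS = (1e2, 1e7)        # years
MIG_BOUNDS = (1e-9, 1e-3)       # per-generation probability


@dataclass(frozen=True)
class ModelID:
    """A model identifier together with its free-parameter ledger entry."""

    identifier: str
    k: int
    free_params: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.k != len(self.free_params):
            raise ModelParameterError("k must equal len(free_params)")


def _free_param_names(identifier: str) -> tuple[str, ...]:
    if identifier not in MODEL_TOPOLOGY:
        raise UnknownModelError(identifier)
    epoch, direction = MODEL_TOPOLOGY[identifier]
    names = ["N_anc", "N_west", "N_east", "T_div"]
    if epoch in ("recent", "ancient"):
        names.append("T_contact")
    if direction == "sym":
        names.append("m_sym")
    elif direction == "WE":
        names.append("m_WE")
    elif direction == "EW":
        names.append("m_EW")
    elif direction == "both":
        names.extend(["m_EW", "m_WE"])
    return tuple(names)


def model_id(identifier: str) -> ModelID:
    """Return the :class:`ModelID` for an identifier in M1..M10."""
    names = _free_param_names(identifier)
    return ModelID(identifier=identifier, k=len(names), free_params=names)


def free_parameters(identifier: str | ModelID) -> list[tuple[str, float, float, bool]]:
    """Search-space ledger for a model.

    Returns ``(name, lower, upper, log10_scale)`` per free parameter.  The
    symmetric models expose a single shared ``m_sym`` that is applied in both
    directions.  All parameters are searched on a log10 scale.
    """
    ident = identifier.identifier if isinstance(identifier, ModelID) else identifier
    out = []
    for name in _free_param_names(ident):
        if name.startswith("N_"):
            lo, hi = SIZE_BOUNDS
        elif name.startswith("T_"):
            lo, hi = TIME_BOUNDS
        else:
            lo, hi = MIG_BOUNDS
        out.append((name, lo, hi, True))
    return out


def expand_params(identifier: str, values: dict[str, float]) -> ModelParams:
    """Map a free-parameter value dict (possibly using ``m_sym``) to ModelParams."""
    vals = dict(values)
    if "m_sym" in vals:
        m = vals.pop("m_sym")
        vals["m_EW"] = m
        vals["m_WE"] = m
    return ModelParams(**{k: float(v) for k, v in vals.items()})


def years_to_generations(t_years: float, settings: InferenceSettings) -> float:
    """Convert a time in years to generations (exact division)."""
    if t_years < 0:
        raise ModelParameterError("time must be nonnegative")
    return t_years / settings.gen_time


@dataclass
class DemographicModel:
    """Executable epoch description of a two-deme history.

    Epochs run forward from the present (time 0) to the merge at ``T_div``
    generations, at which point all lineages move into the ancestral deme of
    size ``N_anc``.  Arrays are per epoch, aligned with ``epoch_starts``.
    ``m_west_east`` is the backward rate at which a lineage in the west jumps
    to the east (forward flow east->west, i.e. ``m_EW``); ``m_east_west`` is
    the mirror (``m_WE``).
    """

    epoch_starts: np.ndarray          # generations, strictly increasing, [0, ...]
    N_west: np.ndarray
    N_east: np.ndarray
    m_west_east: np.ndarray
    m_east_west: np.ndarray
    T_div: float                      # generations
    N_anc: float
    deme_labels: tuple[str, str] = ("west", "east")

    def __post_init__(self) -> None:
        self.epoch_starts = np.asarray(self.epoch_starts, dtype=float)
        for name in ("N_west", "N_east", "m_west_east", "m_east_west"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.epoch_starts[0] != 0.0 or np.any(np.diff(self.epoch_starts) <= 0):
            raise TimeOrderingError("epoch starts must begin at 0 and increase")
        if self.epoch_starts[-1] >= self.T_div:
            raise TimeOrderingError("all epoch starts must precede T_div")
        if self.T_div <= 0:
            raise TimeOrderingError("T_div must be positive")
        if self.N_anc <= 0 or np.any(self.N_west <= 0) or np.any(self.N_east <= 0):
            raise ModelParameterError("all deme sizes must be positive")
        rates = np.concatenate([self.m_west_east, self.m_east_west])
        if np.any(~np.isfinite(rates)) or np.any(rates < 0):
            raise ModelParameterError("migration rates must be finite and nonnegative")


def build_model(
    ident: str | ModelID,
    params: ModelParams,
    settings: InferenceSettings,
) -> DemographicModel:
    """Assemble the executable epoch model for one of M1..M10.

    Migration is switched on exactly in the epochs the topology ledger
    dictates; times are converted to generations with ``settings.gen_time``.
    """
    identifier = ident.identifier if isinstance(ident, ModelID) else ident
    if identifier not in MODEL_TOPOLOGY:
        raise UnknownModelError(identifier)
    epoch, direction = MODEL_TOPOLOGY[identifier]

    for name in ("N_anc", "N_west", "N_east"):
        if getattr(params, name) <= 0:
            raise ModelParameterError(f"{identifier} requires {name} > 0")
    if params.T_div <= 0:
        raise ModelParameterError(f"{identifier} requires T_div > 0")

    m_we = params.m_WE  # forward west->east
    m_ew = params.m_EW  # forward east->west
    if direction == "sym" and m_we != m_ew:
        raise ModelParameterError(f"{identifier} is symmetric: m_EW must equal m_WE")
    for m in (m_we, m_ew):
        if not 0 <= m < 1:
            raise ModelParameterError("migration probabilities must lie in [0, 1)")
    if direction == "WE":
        m_ew = 0.0
    elif direction == "EW":
        m_we = 0.0
    elif direction == "none":
        m_ew = m_we = 0.0

    t_div = years_to_generations(params.T_div, settings)
    needs_contact = epoch in ("recent", "ancient")
    if needs_contact:
        if params.T_contact <= 0:
            raise ModelParameterError(f"{identifier} requires T_contact > 0")
        if params.T_contact >= params.T_div:
            raise TimeOrderingError("T_contact must be < T_div")
        t_contact = years_to_generations(params.T_contact, settings)
        starts = np.array([0.0, t_contact])
        # backward rates per epoch: lineage in west -> east is m_EW
        if epoch == "recent":
            wm = np.array([m_ew, 0.0])
            em = np.array([m_we, 0.0])
        else:  # ancient
            wm = np.array([0.0, m_ew])
            em = np.array([0.0, m_we])
    else:
        starts = np.array([0.0])
        wm = np.array([m_ew])
        em = np.array([m_we])

    n_epochs = len(starts)
    return DemographicModel(
        epoch_starts=starts,
        N_west=np.full(n_epochs, params.N_west),
        N_east=np.full(n_epochs, params.N_east),
        m_west_east=wm,
        m_east_west=em,
        T_div=t_div,
        N_anc=params.N_anc,
    )


# --- serialization ---------------------------------------------------------

def params_to_yaml(identifier: str, params: ModelParams,
                   settings: InferenceSettings | None = None) -> str:
    """Serialize a model configuration block to YAML."""
    block: dict = {"model": identifier, "params": params.to_dict()}
    if settings is not None:
        block["settings"] = {
            "mu": settings.mu, "gen_time": settings.gen_time,
            "n_sims": settings.n_sims, "n_cycles": settings.n_cycles,
            "n_reps": settings.n_reps, "seed": settings.seed,
            "folded": settings.folded, "min_cell_prob": settings.min_cell_prob,
        }
    return yaml.safe_dump(block, sort_keys=False)


def params_from_yaml(text: str) -> tuple[str, ModelParams, InferenceSettings]:
    block = yaml.safe_load(text)
    identifier = block["model"]
    if identifier not in MODEL_TOPOLOGY:
        raise UnknownModelError(identifier)
    params = ModelParams.from_dict(block["params"])
    settings = InferenceSettings(**block.get("settings", {}) or {})
    return identifier, params, settings


def export_par(identifier: str, params: ModelParams,
               settings: InferenceSettings) -> str:
    """Human-readable fastsimcoal-style .par-like text (not bit-compatible)."""
    model = build_model(identifier, params, settings)
    buf = io.StringIO()
    buf.write(f"// {identifier}: two-deme isolation-migration history\n")
    buf.write("2 demes (0=west, 1=east), diploid sizes\n")
    buf.write(f"{model.N_west[0]:.6g} {model.N_east[0]:.6g}\n")
    buf.write("epochs (start_gen  N_west  N_east  m_west->east(bwd)  m_east->west(bwd))\n")
    for e, start in enumerate(model.epoch_starts):
        buf.write(
            f"{start:.6g} {model.N_west[e]:.6g} {model.N_east[e]:.6g} "
            f"{model.m_west_east[e]:.6g} {model.m_east_west[e]:.6g}\n"
        )
    buf.write("historical event: merge at T_div\n")
    buf.write(f"{model.T_div:.6g} all lineages -> ancestral deme, N = {model.N_anc:.6g}\n")
    buf.write(f"mutation rate {settings.mu:g} /site/generation, "
              f"generation time {settings.gen_time:g} y\n")
    return buf.getvalue()
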