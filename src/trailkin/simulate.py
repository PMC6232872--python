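"""Integration of configured models and trajectory statistics.

The cascade spans rate scales from 1e-3 to 1e9 1/s, so integration uses a
stiff multistep method (BDF) with the analytic mass-action Jacobian.  An
:class:`ExposureProtocol` drives one or two integration phases: the
E-selectin tether is modeled by integrating with ligand present for the
tether lifetime and then removing free ligand while every other species
carries over.

Trajectory statistics implemented here:

* :func:`time_to_death` — T_d, the first (linearly interpolated) time the
  death marker cPARP reaches half its maximum;
* :func:`normalize_profiles` — each species scaled by its own maximum;
* :func:`align_to_death` — time axis re-centered on T_d;
* :func:`relative_profiles` — species scaled by a reference run's maxima;
* :func:`transition_fraction` — how far a species has progressed from its
  initial toward its extreme value at a given time.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .apoptosis import ConfiguredModel, ScenarioConfig
from .network import NetworkModel, conserved_moieties, jacobian_function, rate_function

__all__ = [
    "SolverError",
    "IntegrationQualityError",
    "ExposurePhase",
    "ExposureProtocol",
    "TimeCourse",
    "DeathTime",
    "protocol_for_scenario",
    "run_protocol",
    "time_to_death",
    "normalize_profiles",
    "align_to_death",
    "relative_profiles",
    "transition_fraction",
    "DEFAULT_HORIZON",
    "SWEEP_HORIZON",
]

#: Simulation horizon for single runs (s): 24 h, comfortably past the
#: longest death time of interest (12.5 h).
DEFAULT_HORIZON = 24 * 3600.0

#: Horizon used by parameter sweeps (s): 30 h; cells that never cross are
#: reported as censored, never as a sentinel number.
SWEEP_HORIZON = 30 * 3600.0

#: If the death marker never exceeds this fraction of the total PARP pool,
#: the cell is declared non-apoptotic rather than assigned the half-max time
#: of an essentially flat curve.
CPARP_ACTIVITY_FLOOR = 0.01

#: "Begins to transition" / "has completed its transition" thresholds on the
#: transition fraction.
TRANSITION_ONSET = 0.05
TRANSITION_COMPLETE = 0.95


class SolverError(RuntimeError):
    """The stiff integrator failed to complete a phase."""


class IntegrationQualityError(RuntimeError):
    """The integration finished but violated a quality bound
    (negative amounts beyond tolerance, or conserved-moiety drift)."""


@dataclass(frozen=True)
class ExposurePhase:
    """One integration phase: a duration (``None`` = run to the horizon) and
    the free-ligand condition during the phase.

    ``"retain"`` integrates the full system.  ``"zero"`` removes free ligand
    at the phase start and holds it at zero for the whole phase: once the
    tether has broken there is no apposed carrier surface, so ligand
    dissociating from the receptor leaves the contact zone instead of
    rebinding.  (Merely zeroing the amount once would let the bound pool
    replenish free ligand within microseconds.)
    """

    duration: Optional[float]
    ligand: str = "retain"      # "retain" | "zero"

    def __post_init__(self) -> None:
        if self.ligand not in ("retain", "zero"):
            raise ValueError(f"unknown ligand condition {self.ligand!r}")
        if self.duration is not None and not (self.duration > 0):
            raise ValueError("phase duration must be > 0")


@dataclass(frozen=True)
class ExposureProtocol:
    """Ordered phases plus horizon and output-grid size.

    At most one open-ended phase is allowed and it must be last; the horizon
    must cover the finite phases.  The output grid is log-spaced so that the
    millisecond tether window and the 10-hour transitions are resolved
    simultaneously.
    """

    phases: tuple[ExposurePhase, ...]
    horizon: float = DEFAULT_HORIZON
    n_points: int = 2000
    t_min: float = 1e-6         # first strictly positive output time (s)

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("protocol needs at least one phase")
        open_ended = [i for i, p in enumerate(self.phases) if p.duration is None]
        if open_ended and (len(open_ended) > 1 or open_ended[0] != len(self.phases) - 1):
            raise ValueError("at most one open-ended phase, and it must be last")
        finite = sum(p.duration for p in self.phases if p.duration is not None)
        if self.horizon < finite:
            raise ValueError("horizon must cover the finite phases")
        if self.n_points < 10:
            raise ValueError("output grid too coarse")

    def boundaries(self) -> list[tuple[float, float, ExposurePhase]]:
        """(t_start, t_end, phase) triples covering [0, horizon]."""
        out, t = [], 0.0
        for p in self.phases:
            t_end = self.horizon if p.duration is None else t + p.duration
            out.append((t, t_end, p))
            t = t_end
        if out[-1][1] < self.horizon:
            out[-1] = (out[-1][0], self.horizon, out[-1][2])
        return out


def protocol_for_scenario(
    scenario: ScenarioConfig,
    horizon: float = DEFAULT_HORIZON,
    n_points: int = 2000,
) -> ExposureProtocol:
    """Continuous exposure, or a finite tether phase followed by
    ligand removal, depending on the scenario."""
    if scenario.exposure is None:
        phases = (ExposurePhase(None, "retain"),)
    else:
        phases = (ExposurePhase(scenario.exposure, "retain"),
                  ExposurePhase(None, "zero"))
    return ExposureProtocol(phases=phases, horizon=horizon, n_points=n_points)


@dataclass(frozen=True, eq=False)
class TimeCourse:
    """A time grid (s) and one trajectory per species."""

    t: np.ndarray                       # (n_t,), strictly increasing
    y: np.ndarray                       # (n_species, n_t), clipped at 0
    names: tuple[str, ...]
    scenario: Optional[str] = None
    solver_stats: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.y[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no species named {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def to_frame(self) -> pd.DataFrame:
        """Wide table: index time_s, one column per species."""
        df = pd.DataFrame(self.y.T, columns=list(self.names))
        df.insert(0, "time_s", self.t)
        return df.set_index("time_s")


@dataclass(frozen=True)
class DeathTime:
    """Time until apoptosis: first half-maximum crossing of cPARP."""

    t_d: Optional[float]        # seconds; None when no crossing
    cparp_max: float
    crossing_found: bool

    @property
    def hours(self) -> Optional[float]:
        return None if self.t_d is None else self.t_d / 3600.0


_moiety_cache: dict[bytes, list[np.ndarray]] = {}


def _cached_moieties(model: NetworkModel) -> list[np.ndarray]:
    key = hashlib.sha256(
        np.ascontiguousarray(model.stoichiometry).tobytes()
        + repr(model.names).encode()
    ).digest()
    if key not in _moiety_cache:
        _moiety_cache[key] = conserved_moieties(model)
    return _moiety_cache[key]


def _phase_grid(t0: float, t1: float, t_min: float, n: int) -> np.ndarray:
    """Log-spaced output times in (t0, t1]."""
    lo = max(t0 + t_min, t_min)
    if t1 <= lo:
        return np.array([t1])
    pts = np.geomspace(lo, t1, n)
    pts[-1] = t1
    return pts


def run_protocol(
    model: Union[ConfiguredModel, NetworkModel],
    protocol: ExposureProtocol,
    rtol: float = 1e-8,
    atol_floor: float = 1e-6,
    check_conservation: bool = True,
    conservation_rtol: float = 1e-3,
) -> TimeCourse:
    """Integrate a model under its exposure protocol.

    Per-species absolute tolerances are ``atol_floor * max(initial_i, 1)``.
    Amounts are clipped at zero for reporting only; a state more negative
    than ``1e-6`` times the largest initial amount raises
    :class:`IntegrationQualityError`, as does conserved-moiety drift beyond
    ``conservation_rtol`` within any phase (moieties containing the zeroed
    ligand are exempt across the zeroing boundary by construction, since the
    check is per phase).
    """
    scenario_name = None
    if isinstance(model, ConfiguredModel):
        scenario_name = model.scenario.name
        model = model.model
    f = rate_function(model)
    jac = jacobian_function(model)
    y0 = model.initial_state
    scale = np.maximum(y0, 1.0)
    atol = atol_floor * scale
    neg_floor = -1e-6 * float(scale.max())
    ligand_idx = np.array(
        [i for i, s in enumerate(model.species) if s.role == "ligand"], dtype=int)
    moieties = _cached_moieties(model) if check_conservation else []

    def clamped(func):
        # free ligand held at zero: its row of the derivative (and Jacobian)
        # is masked, so dissociated ligand is lost instead of rebinding
        def g(t, state):
            out = func(t, state)
            out[ligand_idx] = 0.0
            return out
        return g

    ts: list[np.ndarray] = [np.array([0.0])]
    ys: list[np.ndarray] = [y0[:, None]]
    stats = {"n_phases": 0, "nfev": 0, "njev": 0, "max_drift": 0.0}
    y = y0.copy()
    for t_start, t_end, phase in protocol.boundaries():
        zero_ligand = phase.ligand == "zero" and len(ligand_idx) > 0
        if zero_ligand:
            y = y.copy()
            y[ligand_idx] = 0.0
        f_p = clamped(f) if zero_ligand else f
        jac_p = clamped(jac) if zero_ligand else jac
        t_eval = _phase_grid(t_start, t_end, protocol.t_min, protocol.n_points)
        sol = solve_ivp(
            f_p, (t_start, t_end), y, method="BDF", jac=jac_p,
            t_eval=t_eval, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise SolverError(
                f"integration failed in phase [{t_start:g}, {t_end:g}] s: {sol.message}")
        if sol.y.min() < neg_floor:
            raise IntegrationQualityError(
                f"state reached {sol.y.min():.3g}, below the negativity floor "
                f"{neg_floor:.3g}")
        for c in moieties:
            if zero_ligand and c[ligand_idx].any():
                continue  # moieties through the clamped ligand are open here
            totals = c @ np.column_stack([y[:, None], sol.y])
            ref = max(abs(totals[0]), 1.0)
            drift = float(np.abs(totals - totals[0]).max() / ref)
            stats["max_drift"] = max(stats["max_drift"], drift)
            if drift > conservation_rtol:
                raise IntegrationQualityError(
                    f"conserved moiety drifted by {drift:.3g} (> {conservation_rtol:g})")
        stats["n_phases"] += 1
        stats["nfev"] += sol.nfev
        stats["njev"] += sol.njev
        if zero_ligand:
            sol.y[ligand_idx] = 0.0   # scrub solver round-off on the clamp
        y = sol.y[:, -1].copy()
        ts.append(sol.t)
        ys.append(sol.y)
    t = np.concatenate(ts)
    Y = np.concatenate(ys, axis=1)
    keep = np.concatenate([[True], np.diff(t) > 0])
    return TimeCourse(t=t[keep], y=np.clip(Y[:, keep], 0.0, None),
                      names=model.names, scenario=scenario_name,
                      solver_stats=stats)


def _interp_crossing(t: np.ndarray, v: np.ndarray, level: float) -> Optional[float]:
    above = v >= level
    if not above.any():
        return None
    k = int(np.argmax(above))
    if k == 0:
        return float(t[0])
    t0, t1, v0, v1 = t[k - 1], t[k], v[k - 1], v[k]
    if v1 == v0:
        return float(t1)
    return float(t0 + (level - v0) * (t1 - t0) / (v1 - v0))


def time_to_death(
    tc: TimeCourse,
    species: str = "cPARP",
    activity_floor: float = CPARP_ACTIVITY_FLOOR,
    pool_species: Sequence[str] = ("PARP", "C3*:PARP", "cPARP"),
) -> DeathTime:
    """T_d: first time the death marker crosses half its maximum.

    The crossing is linearly interpolated between grid points.  If the
    marker's maximum stays below ``activity_floor`` times the total PARP
    pool (evaluated at t = 0 over ``pool_species`` when present, else
    relative to the marker maximum alone, i.e. no floor), the cell is
    declared non-apoptotic and ``crossing_found`` is False.
    """
    if species not in tc:
        raise KeyError(f"time course lacks the death marker {species!r}")
    v = tc[species]
    vmax = float(v.max())
    pool = sum(float(tc[p][0]) for p in pool_species if p in tc)
    if pool > 0 and vmax < activity_floor * pool:
        return DeathTime(t_d=None, cparp_max=vmax, crossing_found=False)
    if vmax == 0.0:
        return DeathTime(t_d=None, cparp_max=0.0, crossing_found=False)
    t_d = _interp_crossing(tc.t, v, 0.5 * vmax)
    return DeathTime(t_d=t_d, cparp_max=vmax, crossing_found=t_d is not None)


def normalize_profiles(tc: TimeCourse) -> TimeCourse:
    """Scale each trajectory by its own maximum (all-zero species stay zero).

    Idempotent, and preserves every relative-threshold crossing time."""
    maxima = tc.y.max(axis=1)
    safe = np.where(maxima > 0, maxima, 1.0)
    return _dc_replace(tc, y=tc.y / safe[:, None])


def align_to_death(tc: TimeCourse, dt: DeathTime) -> TimeCourse:
    """Shift the time axis so that t = 0 is the moment of death."""
    if not dt.crossing_found:
        raise ValueError("cannot align a time course with no death crossing")
    return _dc_replace(tc, t=tc.t - dt.t_d)


def relative_profiles(tc: TimeCourse, reference: TimeCourse) -> TimeCourse:
    """Scale each species by that species' maximum in ``reference``.

    Values may exceed 1 where this run overshoots the reference.  A species
    that is flat zero in the reference but active here has no defined ratio
    and is emitted as NaN.
    """
    if set(tc.names) != set(reference.names):
        raise ValueError("time courses describe different species sets")
    ref_max = np.array([reference[n].max() for n in tc.names])
    out = np.full_like(tc.y, np.nan)
    for i, n in enumerate(tc.names):
        if ref_max[i] > 0:
            out[i] = tc.y[i] / ref_max[i]
        elif not tc.y[i].any():
            out[i] = 0.0
    return _dc_replace(tc, y=out)


def transition_fraction(
    t: np.ndarray, values: np.ndarray, at: float
) -> Optional[float]:
    """Fraction of a trajectory's transition completed at time ``at``.

    The transition runs from the initial value to the extreme value
    (the point farthest from the initial).  Returns
    ``(value(at) - initial) / (extreme - initial)`` clipped to [0, 1],
    or ``None`` for a flat trajectory.
    """
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    v0 = values[0]
    extreme = values[np.argmax(np.abs(values - v0))]
    if extreme == v0:
        return None
    v_at = float(np.interp(at, t, values))
    return float(np.clip((v_at - v0) / (extreme - v0), 0.0, 1.0))
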