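"""Two-parameter maps of the time until apoptosis.

A :class:`SweepSpec` varies two receptor-module parameters (TRAIL density,
death-receptor density, binding on-rate k_plus, binding off-rate k_minus)
on log-spaced grids around a base scenario; every grid cell is an
independent deterministic simulation whose T_d (hours) lands in a
:class:`TdMap`.  Cells whose cPARP never crosses within the sweep horizon
are censored (NaN value + flag), never reported as a sentinel number.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .apoptosis import ScenarioConfig, configure_scenario
from .network import NetworkModel
from .simulate import (
    SWEEP_HORIZON,
    SolverError,
    IntegrationQualityError,
    protocol_for_scenario,
    run_protocol,
    time_to_death,
)

__all__ = ["SweepSpec", "TdMap", "sweep_td", "find_interior_minimum", "SWEEP_PARAMETERS"]

#: Sweepable receptor-module parameters (ScenarioConfig field per name).
SWEEP_PARAMETERS = {
    "trail": "sigma_L",
    "dr": "sigma_R",
    "k_plus": "k_plus",
    "k_minus": "k_minus",
}


@dataclass(frozen=True)
class SweepAxis:
    parameter: str              # key of SWEEP_PARAMETERS
    minimum: float
    maximum: float
    points: int

    def __post_init__(self) -> None:
        if self.parameter not in SWEEP_PARAMETERS:
            raise ValueError(f"unknown sweep parameter {self.parameter!r}; "
                             f"choose from {sorted(SWEEP_PARAMETERS)}")
        if not (0 < self.minimum <= self.maximum):
            raise ValueError("axis range must be positive and ordered")
        if self.points < 3:
            raise ValueError("axis needs at least 3 points")

    @property
    def grid(self) -> np.ndarray:
        return np.geomspace(self.minimum, self.maximum, self.points)


@dataclass(frozen=True)
class SweepSpec:
    """Base scenario plus two distinct log-spaced axes and a horizon."""

    base: ScenarioConfig
    axis1: SweepAxis
    axis2: SweepAxis
    horizon: float = SWEEP_HORIZON
    n_points: int = 600         # output grid per cell; T_d is interpolated

    def __post_init__(self) -> None:
        if self.axis1.parameter == self.axis2.parameter:
            raise ValueError("sweep axes must vary distinct parameters")


@dataclass(frozen=True, eq=False)
class TdMap:
    """T_d (hours) over a 2D parameter grid; NaN + flag marks censoring."""

    spec: SweepSpec
    grid1: np.ndarray           # axis1 values (rows)
    grid2: np.ndarray           # axis2 values (columns)
    td_hours: np.ndarray        # (len(grid1), len(grid2)), NaN where censored
    censored: np.ndarray        # bool, True where no crossing / cell failed
    failures: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        """Long table: axis1, axis2, td_h, censored."""
        r, c = np.meshgrid(self.grid1, self.grid2, indexing="ij")
        return pd.DataFrame({
            self.spec.axis1.parameter: r.ravel(),
            self.spec.axis2.parameter: c.ravel(),
            "td_h": self.td_hours.ravel(),
            "censored": self.censored.ravel(),
        })

    def write_tsv(self, path) -> None:
        """Delimited-text matrix with header rows for both axes; censored
        cells are left empty and flagged in a parallel block."""
        lines = [f"# T_d map (hours); base scenario: {self.spec.base.name}",
                 f"# rows: {self.spec.axis1.parameter}; "
                 f"columns: {self.spec.axis2.parameter}"]
        lines.append("\t".join([""] + [repr(v) for v in self.grid2]))
        for i, v1 in enumerate(self.grid1):
            row = [repr(v1)]
            for j in range(len(self.grid2)):
                row.append("" if self.censored[i, j] else repr(self.td_hours[i, j]))
            lines.append("\t".join(row))
        lines.append("[censored]")
        for i in range(len(self.grid1)):
            lines.append("\t".join(str(bool(x)) for x in self.censored[i]))
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\n".join(lines) + "\n")


def _apply_override(base: ScenarioConfig, parameter: str, value: float) -> ScenarioConfig:
    return replace(base, **{SWEEP_PARAMETERS[parameter]: float(value)})


def sweep_td(
    network: NetworkModel,
    spec: SweepSpec,
    max_failure_fraction: float = 0.5,
) -> TdMap:
    """Run every grid cell and collect T_d.

    Traversal is row-major and deterministic.  Integration failures are
    recorded per cell (as censored) rather than aborting — unless more than
    ``max_failure_fraction`` of cells fail, which raises ``RuntimeError``
    with the collected diagnostics.
    """
    g1, g2 = spec.axis1.grid, spec.axis2.grid
    td = np.full((len(g1), len(g2)), np.nan)
    cens = np.ones((len(g1), len(g2)), dtype=bool)
    failures: list[str] = []
    for i, v1 in enumerate(g1):
        for j, v2 in enumerate(g2):
            sc = _apply_override(spec.base, spec.axis1.parameter, v1)
            sc = _apply_override(sc, spec.axis2.parameter, v2)
            sc = replace(sc, name=f"{spec.base.name}[{i},{j}]")
            protocol = protocol_for_scenario(sc, horizon=spec.horizon,
                                             n_points=spec.n_points)
            try:
                tc = run_protocol(configure_scenario(network, sc), protocol)
                dt = time_to_death(tc)
            except (SolverError, IntegrationQualityError) as exc:
                failures.append(f"cell ({i},{j}): {exc}")
                continue
            if dt.crossing_found:
                td[i, j] = dt.t_d / 3600.0
                cens[i, j] = False
    if len(failures) > max_failure_fraction * td.size:
        raise RuntimeError(
            f"{len(failures)} of {td.size} sweep cells failed integration:\n"
            + "\n".join(failures[:10]))
    return TdMap(spec=spec, grid1=g1, grid2=g2, td_hours=td, censored=cens,
                 failures=tuple(failures))


def find_interior_minimum(td_row: np.ndarray) -> Optional[int]:
    """Index of a strict interior minimum of a T_d profile, or ``None``.

    Censored entries (NaN) are excluded; the minimum must be strictly lower
    than its nearest finite neighbor on each side.
    """
    v = np.asarray(td_row, dtype=float)
    finite = np.flatnonzero(np.isfinite(v))
    if len(finite) < 3:
        return None
    for pos in range(1, len(finite) - 1):
        i = finite[pos]
        left, right = v[finite[pos - 1]], v[finite[pos + 1]]
        if v[i] < left and v[i] < right:
            return int(i)
    return None
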