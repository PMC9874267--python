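"""Parameter sweeps of the evolutionary attractors and bistability detection.

A sweep varies one model parameter over a grid and records, at every grid
value, the co-singular strategies of the resistance coevolution together
with the resident ecological densities at each attractor.  Two tracking
modes are provided: ``continuation`` seeds the search at each point with the
attractors from the previous point (fast, follows branches, can exhibit
hysteresis), ``global`` re-runs the full multistart search at every point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from .ecology import basic_reproduction_number, endemic_equilibrium, host_viable
from .invasion import SingularPoint, find_cosingular
from .params import Params, ResistancePair, TradeoffWiring
from .tradeoffs import effective_rates

__all__ = ["SweepSpec", "SweepResult", "run_sweep", "detect_bistability"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweepSpec:
    """Specification of a one-parameter sweep.

    ``param`` names any :class:`Params` field; ``values`` must be strictly
    monotone.  ``overrides`` fixes other parameters; ``mode`` selects
    attractor tracking (``continuation`` | ``global``).
    """

    param: str
    values: tuple[float, ...]
    wiring: TradeoffWiring
    overrides: dict = dataclass_field(default_factory=dict)
    mode: str = "continuation"

    def __post_init__(self) -> None:
        if self.param not in Params.field_names():
            raise ValueError(
                f"unknown sweep parameter {self.param!r}; "
                f"valid names: {Params.field_names()}"
            )
        v = np.asarray(self.values, dtype=float)
        if len(v) < 2 or not (np.all(np.diff(v) > 0) or np.all(np.diff(v) < 0)):
            raise ValueError("sweep grid must be strictly monotone with >= 2 points")
        if self.mode not in ("continuation", "global"):
            raise ValueError(f"mode must be 'continuation' or 'global', got {self.mode!r}")

    def params_at(self, value: float) -> Params:
        return Params(**{**Params().to_dict(), **self.overrides, self.param: value})


@dataclass
class SweepResult:
    """Long-format table of attractors (and other singular points) per grid
    value, with resident densities at each attractor."""

    spec: SweepSpec
    table: pd.DataFrame

    def attractors_at(self, value: float) -> pd.DataFrame:
        t = self.table
        return t[(t["value"] == value) & t["is_attractor"] & ~t["failed"]]

    @property
    def n_attractors(self) -> pd.Series:
        ok = self.table[self.table["is_attractor"] & ~self.table["failed"]]
        return ok.groupby("value").size().reindex(
            sorted(set(self.table["value"])), fill_value=0
        )


def _point_rows(
    value: float, p: Params, w: TradeoffWiring, points: list[SingularPoint]
) -> list[dict]:
    rows = []
    base_rates = effective_rates(p, w, ResistancePair(0.0, 0.0))
    viable0 = host_viable(base_rates)
    for s in points:
        row = {
            "value": value,
            "rJ_star": s.rJ,
            "rA_star": s.rA,
            "classification": s.classification,
            "is_attractor": s.is_attractor,
            "es_J": s.es_J,
            "es_A": s.es_A,
            "convergent": s.convergent,
            "strongly_convergent": s.strongly_convergent,
            "boundary": s.boundary,
            "host_viable": viable0,
            "failed": False,
        }
        try:
            eq = endemic_equilibrium(p, w, s.traits)
            row["N_star"] = eq.state.N
            row["infected_star"] = eq.state.infected
            row["disease_present"] = eq.kind == "endemic"
            row["equilibrium_kind"] = eq.kind
        except Exception as exc:  # pragma: no cover - diagnostic path
            row["N_star"] = np.nan
            row["infected_star"] = np.nan
            row["disease_present"] = False
            row["equilibrium_kind"] = f"error: {exc}"
        rows.append(row)
    if not points:
        rows.append(
            {
                "value": value,
                "rJ_star": np.nan,
                "rA_star": np.nan,
                "classification": "none-found",
                "is_attractor": False,
                "es_J": None,
                "es_A": None,
                "convergent": None,
                "strongly_convergent": None,
                "boundary": False,
                "host_viable": viable0,
                "failed": False,
                "N_star": np.nan,
                "infected_star": np.nan,
                "disease_present": False,
                "equilibrium_kind": "n/a",
            }
        )
    return rows


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Run the sweep; per-point solver failures are logged and marked, the
    sweep continues."""
    rows: list[dict] = []
    prev_attractors: list[tuple[float, float]] = []
    for k, value in enumerate(spec.values):
        p = spec.params_at(value)
        w = spec.wiring
        try:
            if spec.mode == "continuation" and k > 0:
                points = find_cosingular(
                    p, w, starts=prev_attractors or None, n_grid=3, n_sign_grid=9
                )
            else:
                points = find_cosingular(p, w)
            prev_attractors = [(s.rJ, s.rA) for s in points if s.is_attractor]
            new_rows = _point_rows(value, p, w, points)
            logger.info(
                "sweep %s=%g: %d singular point(s), %d attractor(s)",
                spec.param, value, len(points), len(prev_attractors),
            )
        except Exception as exc:
            logger.warning("sweep %s=%g failed: %s", spec.param, value, exc)
            new_rows = [
                {
                    "value": value, "rJ_star": np.nan, "rA_star": np.nan,
                    "classification": f"error: {exc}", "is_attractor": False,
                    "es_J": None, "es_A": None, "convergent": None,
                    "strongly_convergent": None, "boundary": False,
                    "host_viable": False, "failed": True,
                    "N_star": np.nan, "infected_star": np.nan,
                    "disease_present": False, "equilibrium_kind": "error",
                }
            ]
        rows.extend(new_rows)
    return SweepResult(spec=spec, table=pd.DataFrame(rows))


@dataclass
class BistableRegion:
    """A maximal run of consecutive grid values with >= 2 attractors."""

    start: float
    stop: float
    values: tuple[float, ...]
    divergent_stage_split: bool


def _is_divergent_split(att: pd.DataFrame, high: float = 0.3, low: float = 0.05) -> bool:
    """True when coexisting attractors pair high resistance at one stage
    with (near) zero at the other in opposite arrangements."""
    pairs = list(zip(att["rJ_star"], att["rA_star"]))
    for i, (aJ, aA) in enumerate(pairs):
        for bJ, bA in pairs[i + 1:]:
            if (aJ > high and aA < low and bA > high and bJ < low) or (
                aA > high and aJ < low and bJ > high and bA < low
            ):
                return True
    return False


def detect_bistability(spec: SweepSpec) -> tuple[SweepResult, list[BistableRegion]]:
    """Global multistart at every grid point; returns the sweep plus maximal
    regions of the swept parameter with two or more coexisting attractors.

    Each region also records whether any attractor pair splits the stages
    (high resistance at one stage, none at the other, in opposite
    arrangements); the model predicts such splits do not occur.
    """
    gspec = SweepSpec(spec.param, spec.values, spec.wiring, dict(spec.overrides), "global")
    result = run_sweep(gspec)
    counts = result.n_attractors
    regions: list[BistableRegion] = []
    run: list[float] = []
    for value in spec.values:
        if counts.get(value, 0) >= 2:
            run.append(value)
        elif run:
            regions.append(_close_region(result, run))
            run = []
    if run:
        regions.append(_close_region(result, run))
    return result, regions


def _close_region(result: SweepResult, run: list[float]) -> BistableRegion:
    split = any(_is_divergent_split(result.attractors_at(v)) for v in run)
    return BistableRegion(
        start=min(run), stop=max(run), values=tuple(run), divergent_stage_split=split
    )
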