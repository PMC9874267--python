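"""Desk-scale reproductions of the headline experiment grids.

Each driver returns (and optionally writes as CSV) the long-format tables
behind the corresponding result: sterility-virulence sweeps over all six
trade-off wirings, the two contrasting phase planes (single CSS vs
bistability), transmissibility sweeps, and mortality-virulence sweeps.
Default resolution is 21 points per swept axis.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ALL_WIRINGS, Params, TradeoffWiring
from .phaseplane import PhasePlane, phase_plane
from .sweeps import SweepSpec, run_sweep

__all__ = [
    "sterility_virulence_grid",
    "phase_plane_pair",
    "transmissibility_grid",
    "mortality_virulence_grid",
    "reproduce_figure",
]

logger = logging.getLogger(__name__)


def _wiring_frame(wiring: TradeoffWiring, table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    out.insert(0, "juvenile_target", wiring.juvenile_target)
    out.insert(1, "adult_target", wiring.adult_target)
    return out


def sterility_virulence_grid(
    n_points: int = 21,
    beta0: float = 8.0,
    wirings: tuple[TradeoffWiring, ...] = ALL_WIRINGS,
    mode: str = "continuation",
) -> pd.DataFrame:
    """Attractors vs sterility virulence ``1 - f`` for each trade-off wiring
    (transmissibility ``beta0 = 8``, no mortality virulence)."""
    fs = tuple(np.linspace(1.0, 0.0, n_points))
    frames = []
    for w in wirings:
        spec = SweepSpec("f", fs, w, {"beta0": beta0, "alpha": 0.0}, mode)
        res = run_sweep(spec)
        tab = res.table
        tab.insert(0, "sterility_virulence", 1.0 - tab["value"])
        frames.append(_wiring_frame(w, tab))
    return pd.concat(frames, ignore_index=True)


def phase_plane_pair(grid_n: int = 21) -> dict[str, PhasePlane]:
    """The two contrasting phase planes: a single continuously stable
    strategy (beta0=8, f=0.1, juvenile~mortality / adult~reproduction) and
    bistability (beta0=1000, f=0.5, both stages ~ mortality)."""
    return {
        "css": phase_plane(
            Params(beta0=8.0, f=0.1, alpha=0.0),
            TradeoffWiring("juvenile_mortality", "reproduction"),
            grid_n=grid_n,
        ),
        "bistable": phase_plane(
            Params(beta0=1000.0, f=0.5, alpha=0.0),
            TradeoffWiring("juvenile_mortality", "adult_mortality"),
            grid_n=grid_n,
        ),
    }


def transmissibility_grid(
    n_points: int = 13,
    beta0_max: float = 2000.0,
    mode: str = "global",
) -> pd.DataFrame:
    """Attractors vs baseline transmissibility for the two wiring/virulence
    combinations of the transmissibility analysis (log-spaced grid; global
    multistart so coexisting attractors are all recorded)."""
    betas = tuple(np.geomspace(1.0, beta0_max, n_points))
    cases = [
        (TradeoffWiring("juvenile_mortality", "adult_mortality"), 0.3, "a"),
        (TradeoffWiring("reproduction", "reproduction"), 0.5, "b"),
        (TradeoffWiring("juvenile_mortality", "adult_mortality"), 0.5, "c"),
        (TradeoffWiring("reproduction", "reproduction"), 0.3, "d"),
    ]
    frames = []
    for w, f, panel in cases:
        spec = SweepSpec("beta0", betas, w, {"f": f, "alpha": 0.0}, mode)
        tab = run_sweep(spec).table
        tab.insert(0, "panel", panel)
        tab.insert(1, "f", f)
        frames.append(_wiring_frame(w, tab))
    return pd.concat(frames, ignore_index=True)


def mortality_virulence_grid(
    n_points: int = 21,
    alpha_max: float = 6.0,
    beta0: float = 8.0,
    wirings: tuple[TradeoffWiring, ...] = ALL_WIRINGS,
    mode: str = "continuation",
) -> pd.DataFrame:
    """Attractors vs mortality virulence ``alpha`` for each trade-off wiring
    (``f = 1``: no sterility virulence)."""
    alphas = tuple(np.linspace(0.0, alpha_max, n_points))
    frames = []
    for w in wirings:
        spec = SweepSpec("alpha", alphas, w, {"beta0": beta0, "f": 1.0}, mode)
        frames.append(_wiring_frame(w, run_sweep(spec).table))
    return pd.concat(frames, ignore_index=True)


def reproduce_figure(
    number: int, out_dir: str | Path, n_points: int | None = None, plot: bool = False
) -> list[Path]:
    """Run the experiment grid behind headline figure ``number`` (2-5) at
    desk resolution and write CSV output(s); returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if number == 2:
        df = sterility_virulence_grid(n_points or 21)
        path = out_dir / "figure2_sterility_sweeps.csv"
        df.to_csv(path, index=False)
        written.append(path)
    elif number == 3:
        planes = phase_plane_pair(n_points or 21)
        for name, pp in planes.items():
            path = out_dir / f"figure3_{name}_phaseplane.csv"
            pp.to_frame().to_csv(path, index=False)
            written.append(path)
            apath = out_dir / f"figure3_{name}_attractors.csv"
            pd.DataFrame(
                [
                    {"rJ_star": a.rJ, "rA_star": a.rA, "classification": a.classification}
                    for a in pp.attractors
                ]
            ).to_csv(apath, index=False)
            written.append(apath)
    elif number == 4:
        df = transmissibility_grid(n_points or 13)
        path = out_dir / "figure4_transmissibility_sweeps.csv"
        df.to_csv(path, index=False)
        written.append(path)
    elif number == 5:
        df = mortality_virulence_grid(n_points or 21)
        path = out_dir / "figure5_mortality_sweeps.csv"
        df.to_csv(path, index=False)
        written.append(path)
    else:
        raise ValueError("figure number must be 2, 3, 4 or 5")
    if plot:
        _plot_figure(number, written, out_dir)
    return written


def _plot_figure(number: int, csv_paths: list[Path], out_dir: Path) -> None:
    """Optional quick-look plots (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for path in csv_paths:
        df = pd.read_csv(path)
        if "rJ_star" not in df.columns:
            continue
        fig, ax = plt.subplots()
        att = df[df.get("is_attractor", True) == True]  # noqa: E712
        x = att.columns[att.columns.str.contains("value|sterility")][0] if "value" in att else None
        if "value" in att.columns:
            ax.plot(att["value"], att["rJ_star"], "r.", label="juvenile")
            ax.plot(att["value"], att["rA_star"], "b.", label="adult")
            ax.set_xlabel("swept parameter")
        else:
            ax.plot(att["rJ_star"], att["rA_star"], "ko")
            ax.set_xlabel("rJ")
            ax.set_ylabel("rA")
        ax.set_ylim(-0.02, 1.02)
        ax.legend(loc="best")
        fig.savefig(path.with_suffix(".png"), dpi=120)
        plt.close(fig)
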