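"""Phase planes of the evolutionary dynamics over resistance trait space.

Evaluates the selection-gradient field on a lattice over [0, 1]^2, extracts
juvenile and adult nullclines by zero contouring, locates the attractors and
labels each lattice cell with the basin of attraction reached by the
gradient flow (the canonical equation with equal mutational input in both
traits reduces to ``dr/dtau`` proportional to the gradient vector).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import contourpy
import numpy as np
import pandas as pd

from .ecology import endemic_equilibrium
from .invasion import SingularPoint, find_cosingular, selection_gradient_map
from .params import Params, ResistancePair, TradeoffWiring

__all__ = ["PhasePlane", "phase_plane"]

#: trait-space distance at which a flow trajectory counts as captured
CAPTURE_RADIUS = 0.03


@dataclass
class PhasePlane:
    """Gradient signs, nullclines, attractors and basins on a trait lattice.

    ``basin[i, j]`` is the index into ``attractors`` of the attractor reached
    from lattice point ``(rJ_grid[i], rA_grid[j])``, or -1 where no attractor
    was reached (non-viable host cells, flow escaping the capture radius).
    ``cell_labels[i, j]`` distinguishes ``ok`` / ``no_disease`` /
    ``host_nonviable`` cells.
    """

    rJ_grid: np.ndarray
    rA_grid: np.ndarray
    gradJ: np.ndarray
    gradA: np.ndarray
    cell_labels: np.ndarray
    attractors: list[SingularPoint]
    singular_points: list[SingularPoint]
    basin: np.ndarray
    nullclines_J: list[np.ndarray] = field(default_factory=list)
    nullclines_A: list[np.ndarray] = field(default_factory=list)

    @property
    def n_basins(self) -> int:
        return len(set(self.basin[self.basin >= 0].ravel()))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per lattice point."""
        rows = []
        for i, rJ in enumerate(self.rJ_grid):
            for j, rA in enumerate(self.rA_grid):
                rows.append(
                    {
                        "rJ": rJ,
                        "rA": rA,
                        "dwJ": self.gradJ[i, j],
                        "dwA": self.gradA[i, j],
                        "dwJ_sign": int(np.sign(self.gradJ[i, j])),
                        "dwA_sign": int(np.sign(self.gradA[i, j])),
                        "cell": self.cell_labels[i, j],
                        "basin_id": int(self.basin[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def _flow_to_attractor(
    G,
    start: tuple[float, float],
    attractors: list[SingularPoint],
    step: float = 0.02,
    max_steps: int = 600,
) -> tuple[int, list[tuple[float, float]]]:
    """Follow the normalized gradient flow until an attractor captures it.

    Returns the attractor index (or -1) and the visited path.  Fixed-length
    steps along the gradient direction are adequate for basin labelling: only
    the destination matters, not the time parametrization.
    """
    r = np.array(start, dtype=float)
    path = [tuple(r)]
    for _ in range(max_steps):
        for k, a in enumerate(attractors):
            if np.hypot(r[0] - a.rJ, r[1] - a.rA) < CAPTURE_RADIUS:
                return k, path
        g = G(r[0], r[1])
        norm = np.hypot(g[0], g[1])
        if norm < 1e-12:
            break
        r = np.clip(r + step * g / norm, 0.0, 1.0)
        # pinned on a boundary with inward gradient component zeroed
        path.append(tuple(r))
        if len(path) >= 3 and np.allclose(path[-1], path[-3], atol=1e-12):
            break  # flip-flopping across an attractor smaller than the step
    # final proximity check with a looser radius (boundary attractors)
    for k, a in enumerate(attractors):
        if np.hypot(r[0] - a.rJ, r[1] - a.rA) < 3 * CAPTURE_RADIUS:
            return k, path
    return -1, path


def phase_plane(
    p: Params,
    w: TradeoffWiring,
    grid_n: int = 21,
    compute_basins: bool = True,
) -> PhasePlane:
    """Build the phase plane of the resistance coevolution on a
    ``grid_n x grid_n`` lattice.

    Nullclines are zero contours of each gradient component; basins are
    labelled by integrating the gradient flow from every lattice point, with
    cells visited en route inheriting the destination label.
    """
    G = selection_gradient_map(p, w)
    axis = np.linspace(0.0, 1.0, grid_n)
    gradJ = np.zeros((grid_n, grid_n))
    gradA = np.zeros((grid_n, grid_n))
    labels = np.full((grid_n, grid_n), "ok", dtype=object)
    for i, rJ in enumerate(axis):
        for j, rA in enumerate(axis):
            try:
                eq = endemic_equilibrium(p, w, ResistancePair(rJ, rA))
            except Exception:
                labels[i, j] = "host_nonviable"
                gradJ[i, j] = gradA[i, j] = np.nan
                continue
            if eq.kind == "extinct":
                labels[i, j] = "host_nonviable"
            elif eq.kind == "disease_free":
                labels[i, j] = "no_disease"
            g = G(rJ, rA)
            gradJ[i, j], gradA[i, j] = g

    singular = find_cosingular(p, w)
    attractors = [s for s in singular if s.is_attractor]

    # nullclines from zero contours (x ~ rA along columns, y ~ rJ along rows)
    nullJ: list[np.ndarray] = []
    nullA: list[np.ndarray] = []
    for comp, dest in ((gradJ, nullJ), (gradA, nullA)):
        filled = np.nan_to_num(comp, nan=-1.0)
        gen = contourpy.contour_generator(
            x=axis, y=axis, z=filled.T  # contourpy: z[j, i] over x[i], y[j]
        )
        for line in gen.lines(0.0):
            dest.append(np.column_stack([line[:, 1], line[:, 0]]))  # (rJ, rA)

    basin = np.full((grid_n, grid_n), -1, dtype=int)
    if compute_basins and attractors:
        done = np.zeros((grid_n, grid_n), dtype=bool)

        def nearest_cell(rJ: float, rA: float) -> tuple[int, int]:
            return (
                int(round(rJ * (grid_n - 1))),
                int(round(rA * (grid_n - 1))),
            )

        for i, rJ in enumerate(axis):
            for j, rA in enumerate(axis):
                if done[i, j]:
                    continue
                if labels[i, j] == "host_nonviable":
                    done[i, j] = True
                    continue
                k = None
                # shortcut: inherit from an already-labelled cell on the path
                _, path = None, None
                k, path = _flow_to_attractor(G, (rJ, rA), attractors)
                for (prJ, prA) in path:
                    ci, cj = nearest_cell(prJ, prA)
                    if done[ci, cj] and basin[ci, cj] >= 0 and k == -1:
                        k = basin[ci, cj]
                basin[i, j] = k
                done[i, j] = True
                for (prJ, prA) in path:
                    ci, cj = nearest_cell(prJ, prA)
                    if not done[ci, cj] and abs(axis[ci] - prJ) < 1e-9 and abs(axis[cj] - prA) < 1e-9:
                        basin[ci, cj] = k
                        done[ci, cj] = True

    return PhasePlane(
        rJ_grid=axis,
        rA_grid=axis,
        gradJ=gradJ,
        gradA=gradA,
        cell_labels=labels,
        attractors=attractors,
        singular_points=singular,
        basin=basin,
        nullclines_J=nullJ,
        nullclines_A=nullA,
    )
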