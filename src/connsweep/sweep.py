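"""Sparsity-threshold sweep and AUC summarization.

A cohort's connectomes are binarized over a grid of sparsity values.  The
analysis range is the largest contiguous sub-grid on which the small-world
scalar sigma is estimable and exceeds 1.0 for *every* subject.  Each metric's
curve over the retained grid is reduced to a single area-under-the-curve
scalar per subject (trapezoidal rule), giving threshold-independent
quantities for the group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .graphmetrics import (
    EstimabilityError,
    global_metrics,
    nodal_metrics,
    small_world_normalization,
)
from .netcon import BinaryNetwork, ConnectivityMatrix, binarize_at_sparsity


class SweepError(ValueError):
    pass


@dataclass
class SparsityGrid:
    s_min: float
    s_max: float
    step: float
    points: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.s_min <= self.s_max < 1:
            raise SweepError("need 0 < s_min <= s_max < 1")
        n = int(round((self.s_max - self.s_min) / self.step))
        pts = self.s_min + self.step * np.arange(n + 1)
        pts = np.round(pts, 10)
        if abs(pts[-1] - self.s_max) > 1e-9:
            raise SweepError("step does not evenly divide the range")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    def subgrid(self, i0: int, i1: int) -> "SparsityGrid":
        """Contiguous sub-grid from point i0 to i1 inclusive."""
        return SparsityGrid(float(self.points[i0]), float(self.points[i1]), self.step)


GLOBAL_METRIC_NAMES = ("cp", "lp", "eglob", "eloc", "gamma", "lambda", "sigma")
NODAL_METRIC_NAMES = ("degree", "nodal_efficiency", "betweenness")


def sigma_over_grid(
    conns: dict[str, ConnectivityMatrix],
    grid: SparsityGrid,
    n_null: int = 100,
    swaps_per_edge: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """sigma for every subject at every grid point (NaN where not estimable).

    The null-ensemble seed for each cell is derived from
    (seed, subject_id, sparsity), so any cell is reproducible in isolation
    and independent of evaluation order.
    """
    rows = {}
    for sid, conn in conns.items():
        vals = np.full(len(grid), np.nan)
        for k, s in enumerate(grid.points):
            try:
                net = binarize_at_sparsity(conn, float(s))
                _, _, sigma = small_world_normalization(
                    net, n_null=n_null, swaps_per_edge=swaps_per_edge,
                    seed=derive_seed(seed, sid, f"{s:.6f}"),
                )
                vals[k] = sigma
            except (EstimabilityError, ValueError):
                vals[k] = np.nan
        rows[sid] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(grid.points))


def determine_sparsity_range(
    conns: dict[str, ConnectivityMatrix],
    candidate_grid: SparsityGrid,
    n_null: int = 100,
    swaps_per_edge: int = 10,
    seed: int = 0,
    sigma_table: pd.DataFrame | None = None,
) -> SparsityGrid:
    """Largest contiguous sub-grid where sigma > 1 and estimable for all subjects.

    ``sigma_table`` (from :func:`sigma_over_grid` with identical arguments)
    can be supplied to avoid recomputation.  Ties between equally long runs
    go to the lower-sparsity run.
    """
    if len(candidate_grid) == 0:
        raise SweepError("candidate grid is empty")
    if sigma_table is None:
        sigma_table = sigma_over_grid(conns, candidate_grid, n_null=n_null,
                                      swaps_per_edge=swaps_per_edge, seed=seed)
    vals = sigma_table.to_numpy()
    ok = np.isfinite(vals) & (vals > 1.0)
    col_ok = ok.all(axis=0)
    best_len, best_start, run_start = 0, -1, None
    for k, flag in enumerate(list(col_ok) + [False]):
        if flag and run_start is None:
            run_start = k
        elif not flag and run_start is not None:
            if k - run_start > best_len:
                best_len, best_start = k - run_start, run_start
            run_start = None
    if best_len == 0:
        violations = (~ok).sum(axis=1)
        worst = violations.sort_values(ascending=False) if isinstance(violations, pd.Series) \
            else pd.Series(violations, index=sigma_table.index).sort_values(ascending=False)
        raise SweepError(
            "no grid point satisfies sigma > 1 for all subjects; worst subjects: "
            + ", ".join(f"{s} ({int(v)} failing points)" for s, v in worst.head(5).items())
        )
    return candidate_grid.subgrid(best_start, best_start + best_len - 1)


@dataclass
class MetricCurves:
    """Per-subject metric values over the grid."""

    subject_id: str
    grid: SparsityGrid
    global_curves: dict[str, np.ndarray]       # metric -> vector over grid
    nodal_curves: dict[str, np.ndarray]        # metric -> (n_nodes, n_points)


def metric_curves(
    conn: ConnectivityMatrix,
    grid: SparsityGrid,
    n_null: int = 100,
    swaps_per_edge: int = 10,
    seed: int = 0,
    subject_id: str = "subject",
) -> MetricCurves:
    """Binarize at each grid point and compute all global and nodal metrics."""
    n = conn.n_regions
    g = {m: np.empty(len(grid)) for m in GLOBAL_METRIC_NAMES}
    nd = {m: np.empty((n, len(grid))) for m in NODAL_METRIC_NAMES}
    for k, s in enumerate(grid.points):
        try:
            net = binarize_at_sparsity(conn, float(s))
            gm = global_metrics(net)
            gamma, lambda_, sigma = small_world_normalization(
                net, n_null=n_null, swaps_per_edge=swaps_per_edge,
                seed=derive_seed(seed, subject_id, f"{s:.6f}"),
            )
            nm = nodal_metrics(net)
        except (EstimabilityError, ValueError) as exc:
            raise SweepError(f"metrics failed at sparsity {s}: {exc}") from exc
        g["cp"][k], g["lp"][k] = gm.cp, gm.lp
        g["eglob"][k], g["eloc"][k] = gm.eglob, gm.eloc
        g["gamma"][k], g["lambda"][k], g["sigma"][k] = gamma, lambda_, sigma
        nd["degree"][:, k] = nm.degree
        nd["nodal_efficiency"][:, k] = nm.nodal_efficiency
        nd["betweenness"][:, k] = nm.betweenness
    return MetricCurves(subject_id, grid, g, nd)


def curve_auc(curve: np.ndarray, grid: SparsityGrid) -> float:
    """Trapezoidal area under a metric curve over the grid."""
    curve = np.asarray(curve, dtype=float)
    if len(grid) < 2:
        raise SweepError("AUC needs at least two grid points")
    if curve.shape[-1] != len(grid):
        raise SweepError("curve length must equal grid size")
    return float(np.trapezoid(curve, grid.points))


@dataclass
class AUCSummary:
    subject_id: str
    global_auc: dict[str, float]
    nodal_auc: dict[str, np.ndarray]  # metric -> per-node scalar


def auc_summary(curves: MetricCurves) -> AUCSummary:
    """Reduce every metric curve (global and per-node) to its AUC scalar."""
    g = {m: curve_auc(v, curves.grid) for m, v in curves.global_curves.items()}
    nd = {
        m: np.trapezoid(mat, curves.grid.points, axis=1)
        for m, mat in curves.nodal_curves.items()
    }
    return AUCSummary(curves.subject_id, g, nd)


def cohort_curves(
    conns: dict[str, ConnectivityMatrix],
    grid: SparsityGrid,
    n_null: int = 100,
    swaps_per_edge: int = 10,
    seed: int = 0,
) -> dict[str, MetricCurves]:
    return {
        sid: metric_curves(conn, grid, n_null=n_null, swaps_per_edge=swaps_per_edge,
                           seed=seed, subject_id=sid)
        for sid, conn in conns.items()
    }


def curves_to_long(curves: dict[str, MetricCurves],
                   region_labels: list[str] | None = None) -> pd.DataFrame:
    """Long-format table: subject, metric, node (or 'global'), sparsity, value."""
    rows = []
    for sid, c in curves.items():
        labels = region_labels or [f"R{i:03d}" for i in
                                   range(next(iter(c.nodal_curves.values())).shape[0])]
        for m, vec in c.global_curves.items():
            for s, v in zip(c.grid.points, vec):
                rows.append((sid, m, "global", float(s), float(v)))
        for m, mat in c.nodal_curves.items():
            for i, lab in enumerate(labels):
                for s, v in zip(c.grid.points, mat[i]):
                    rows.append((sid, m, lab, float(s), float(v)))
    return pd.DataFrame(rows, columns=["subject", "metric", "node", "sparsity", "value"])


def auc_table(curves: dict[str, MetricCurves],
              region_labels: list[str] | None = None) -> pd.DataFrame:
    """Wide subject x metric table of AUCs (nodal metrics suffixed by region)."""
    rows = {}
    for sid, c in curves.items():
        summ = auc_summary(c)
        labels = region_labels or [f"R{i:03d}" for i in
                                   range(next(iter(c.nodal_curves.values())).shape[0])]
        row: dict[str, float] = dict(summ.global_auc)
        for m, vec in summ.nodal_auc.items():
            for lab, v in zip(labels, vec):
                row[f"{m}:{lab}"] = float(v)
        rows[sid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject"
    return df
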