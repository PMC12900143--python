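"""Normalized topographic scalp maps of band power.

Band powers are rescaled to [0, 1] within each (group, event, band)
panel across the 14 electrode means — matching per-panel colour scales —
then interpolated over a disk-masked grid from the 2-D projected
electrode positions. The default interpolator is inverse-distance
weighting (power 2), which is exact at electrode sites and bounded by
the input range; a thin-plate spline is available behind a switch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MontageError, ParameterError, SampleError
from .montage import Montage, mni_lookup  # re-exported: region annotation lookup

__all__ = ["normalize_bandpower", "HeatmapGrid", "render_topomap", "mni_lookup"]

#: Disk mask radius as a multiple of the outermost electrode radius.
MASK_RADIUS_FACTOR = 1.1


def normalize_bandpower(
    table: pd.DataFrame,
    scope: Sequence[str] = ("group", "event", "band"),
    value_column: str = "power",
) -> pd.DataFrame:
    """Min-max normalize electrode means within each scope panel.

    Within every combination of the ``scope`` keys, the electrode-level
    means of ``value_column`` are mapped to ``(v − min)/(max − min)``; a
    degenerate panel (max = min) maps every electrode to 0.5. Returns the
    electrode-mean table with an added ``norm`` column.
    """
    if table.empty:
        raise SampleError("empty band-power table")
    scope = list(scope)
    means = (
        table.groupby(scope + ["electrode"], as_index=False)[value_column]
        .mean()
        .rename(columns={value_column: "power"})
    )

    def _norm(panel: pd.DataFrame) -> pd.DataFrame:
        lo, hi = panel["power"].min(), panel["power"].max()
        if hi > lo:
            panel = panel.assign(norm=(panel["power"] - lo) / (hi - lo))
        else:
            panel = panel.assign(norm=0.5)
        return panel

    return (
        means.groupby(scope, group_keys=False)[means.columns]
        .apply(_norm)
        .reset_index(drop=True)
    )


@dataclass(frozen=True)
class HeatmapGrid:
    """A rendered scalp map: masked grid plus electrode overlay."""

    grid: np.ndarray  # (resolution, resolution), NaN outside the head disk
    xs: np.ndarray
    ys: np.ndarray
    electrodes: pd.DataFrame  # label, x, y, value
    band: str = ""
    event: int | None = None
    group: str = ""

    def value_at(self, x: float, y: float) -> float:
        """Grid value at the node nearest to (x, y)."""
        ix = int(np.argmin(np.abs(self.xs - x)))
        iy = int(np.argmin(np.abs(self.ys - y)))
        return float(self.grid[iy, ix])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.grid, index=self.ys, columns=self.xs).to_csv(path)


def _idw(points: np.ndarray, values: np.ndarray, targets: np.ndarray, power: float = 2.0) -> np.ndarray:
    """Inverse-distance-weighted interpolation, exact at data sites."""
    d2 = ((targets[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
    out = np.empty(targets.shape[0])
    exact = d2 < 1e-24
    has_exact = exact.any(axis=1)
    with np.errstate(divide="ignore"):
        weights = d2 ** (-power / 2.0)
    weights[has_exact] = 0.0
    out = np.where(
        has_exact,
        values[np.argmax(exact, axis=1)],
        (np.nan_to_num(weights) @ values) / np.nan_to_num(weights).sum(axis=1).clip(min=1e-300),
    )
    return out


def render_topomap(
    values: Mapping[str, float],
    montage: Montage | None = None,
    resolution: int = 64,
    method: str = "idw",
    band: str = "",
    event: int | None = None,
    group: str = "",
) -> HeatmapGrid:
    """Interpolate 14 electrode values over the head disk.

    ``values`` maps each montage label to its (normalized) value. The
    grid spans the disk of radius 1.1× the outermost electrode; nodes
    outside the disk are NaN. ``method`` is ``"idw"`` (default) or
    ``"spline"`` (thin-plate RBF, not bounded by the input range).
    """
    montage = montage or Montage()
    labels = set(montage.labels)
    unknown = set(values) - labels
    if unknown:
        raise MontageError(f"labels not in montage: {sorted(unknown)}")
    if set(values) != labels:
        raise ParameterError("need a value for each of the 14 montage electrodes")

    pos = montage.pos2d
    points = np.array([pos[label] for label in montage.labels])
    vals = np.array([float(values[label]) for label in montage.labels])
    radius = MASK_RADIUS_FACTOR * np.linalg.norm(points, axis=1).max()

    xs = np.linspace(-radius, radius, resolution)
    ys = np.linspace(-radius, radius, resolution)
    gx, gy = np.meshgrid(xs, ys)
    targets = np.column_stack([gx.ravel(), gy.ravel()])

    if method == "idw":
        flat = _idw(points, vals, targets)
    elif method == "spline":
        from scipy.interpolate import RBFInterpolator

        flat = RBFInterpolator(points, vals, kernel="thin_plate_spline")(targets)
    else:
        raise ParameterError(f"unknown interpolation method {method!r}")

    grid = flat.reshape(resolution, resolution)
    grid[gx**2 + gy**2 > radius**2] = np.nan

    electrodes = pd.DataFrame(
        {
            "label": montage.labels,
            "x": points[:, 0],
            "y": points[:, 1],
            "value": vals,
        }
    )
    return HeatmapGrid(
        grid=grid, xs=xs, ys=ys, electrodes=electrodes, band=band, event=event, group=group
    )


def interpolate_at(
    values: Mapping[str, float], targets: np.ndarray, montage: Montage | None = None
) -> np.ndarray:
    """Evaluate the IDW interpolant at arbitrary (x, y) points."""
    montage = montage or Montage()
    pos = montage.pos2d
    points = np.array([pos[label] for label in montage.labels])
    vals = np.array([float(values[label]) for label in montage.labels])
    return _idw(points, vals, np.atleast_2d(np.asarray(targets, dtype=float)))
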