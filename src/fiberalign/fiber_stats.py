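"""Discrete-fiber alignment statistics on the axial circle.

Fiber orientations are axial quantities: theta and theta + 180 are the same
fiber, so all statistics are computed on doubled angles.  The alignment
index is the 2-D nematic order parameter

    S = 2 <cos^2 theta> - 1 = <cos 2 theta>,

with theta measured from the mean fiber axis (the major axis of the
second-order orientation tensor <u u^T>).  S = 0 for an isotropic set and
S = 1 for perfect alignment.  For axially wrapped-normal angles with SD
sigma (radians), E[cos 2 theta] = exp(-2 sigma^2), a closed form used as an
analytic oracle in testing.

Fiber tables are consumed in the CT-FIRE CSV convention
(``fiber_id, angle_deg, length_um, width_um, straightness``), with column
aliases accepted for raw CT-FIRE exports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


class FiberError(ValueError):
    pass


#: accepted aliases for each fiber-table column (lowercased for matching)
COLUMN_ALIASES = {
    "angle_deg": ("angle_deg", "angle", "fiber_angle", "orientation"),
    "length_um": ("length_um", "length", "fiber_length"),
    "width_um": ("width_um", "width", "fiber_width"),
    "straightness": ("straightness", "fiber_straightness"),
}


def wrap_axial(angles_deg) -> np.ndarray:
    """Wrap angles to the axial domain [0, 180)."""
    return np.mod(np.asarray(angles_deg, float), 180.0)


@dataclass
class FiberSet:
    """Fiber axial angles with optional per-fiber geometry."""

    angles_deg: np.ndarray
    lengths_um: np.ndarray | None = None
    widths_um: np.ndarray | None = None
    straightness: np.ndarray | None = None
    roi_size_um: float = 100.0

    def __post_init__(self) -> None:
        self.angles_deg = wrap_axial(self.angles_deg)
        n = self.angles_deg.size
        for name in ("lengths_um", "widths_um", "straightness"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, float)
                if v.size != n:
                    raise FiberError(f"{name} length {v.size} != n fibers {n}")
                setattr(self, name, v)

    def __len__(self) -> int:
        return self.angles_deg.size


@dataclass
class AlignmentResult:
    S: float
    mean_axis_deg: float
    theta_sd_deg: float
    n_fibers: int
    axis_defined: bool = True
    theta_sd_arithmetic_deg: float = float("nan")


def read_fiber_table(path) -> FiberSet:
    """Read a CT-FIRE-style fiber CSV; the angle column is mandatory."""
    path = Path(path)
    if not path.exists():
        raise FiberError(f"fiber table not found: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise FiberError(f"{path}: empty fiber table")
    lower = {c.lower().strip(): c for c in df.columns}

    def find(field: str):
        for alias in COLUMN_ALIASES[field]:
            if alias in lower:
                return lower[alias]
        return None

    angle_col = find("angle_deg")
    if angle_col is None:
        raise FiberError(f"{path}: no angle column found "
                         f"(accepted: {COLUMN_ALIASES['angle_deg']})")
    angles = pd.to_numeric(df[angle_col], errors="coerce")
    bad = angles.index[angles.isna()]
    if len(bad):
        raise FiberError(f"{path}: non-numeric angle at row {bad[0]}")

    def opt(field: str):
        col = find(field)
        if col is None:
            return None
        vals = pd.to_numeric(df[col], errors="coerce")
        return vals.to_numpy(float) if not vals.isna().any() else None

    return FiberSet(angles_deg=angles.to_numpy(float),
                    lengths_um=opt("length_um"), widths_um=opt("width_um"),
                    straightness=opt("straightness"))


def _doubled_resultant(angles_deg: np.ndarray,
                       weights: np.ndarray | None = None) -> tuple[float, float]:
    """(C, S) components of the doubled-angle resultant, optionally weighted."""
    a = np.radians(2.0 * angles_deg)
    if weights is None:
        return float(np.cos(a).mean()), float(np.sin(a).mean())
    w = weights / weights.sum()
    return float((w * np.cos(a)).sum()), float((w * np.sin(a)).sum())


def mean_fiber_axis(f: FiberSet) -> tuple[float, bool]:
    """Major axis of the orientation tensor, in degrees on [0, 180).

    Returns ``(axis_deg, defined)``; an isotropic set (zero doubled-angle
    resultant, e.g. {0, 90}) has no preferred axis and ``defined`` is False.
    """
    if len(f) < 2:
        raise FiberError("mean fiber axis needs >= 2 fibers")
    C, S2 = _doubled_resultant(f.angles_deg)
    R = float(np.hypot(C, S2))
    if R < 1e-12:
        return float("nan"), False
    return float(np.degrees(np.arctan2(S2, C)) * 0.5 % 180.0), True


def alignment_index(f: FiberSet, length_weighted: bool = False) -> AlignmentResult:
    """Alignment index S = <cos 2 theta> about the mean fiber axis.

    Fibers are counted, not length-weighted, by default; pass
    ``length_weighted=True`` to weight each fiber by its length.
    The angular SD is the axial circular SD (doubled-angle circular SD,
    halved); the arithmetic SD about the axis is reported alongside.
    """
    if len(f) < 2:
        raise FiberError("alignment index needs >= 2 fibers")
    weights = None
    if length_weighted:
        if f.lengths_um is None:
            raise FiberError("length_weighted requested but no lengths present")
        weights = f.lengths_um
    C, S2 = _doubled_resultant(f.angles_deg, weights)
    R = float(np.hypot(C, S2))
    if R < 1e-12:
        # isotropic: no preferred axis; S attains 0 for every candidate axis
        return AlignmentResult(S=0.0, mean_axis_deg=float("nan"),
                               theta_sd_deg=90.0 / np.sqrt(2),  # limit value
                               n_fibers=len(f), axis_defined=False)
    axis = float(np.degrees(np.arctan2(S2, C)) * 0.5 % 180.0)
    # S about the mean axis equals the doubled-angle resultant length R
    rel = np.radians(2.0 * (f.angles_deg - axis))
    if weights is None:
        S = float(np.cos(rel).mean())
    else:
        w = weights / weights.sum()
        S = float((w * np.cos(rel)).sum())
    sd_axial = float(np.degrees(0.5 * np.sqrt(max(0.0, -2.0 * np.log(R)))))
    # arithmetic SD of signed deviations in (-90, 90] about the axis
    dev = (f.angles_deg - axis + 90.0) % 180.0 - 90.0
    sd_arith = float(dev.std(ddof=1))
    return AlignmentResult(S=max(0.0, S), mean_axis_deg=axis,
                           theta_sd_deg=sd_axial, n_fibers=len(f),
                           axis_defined=True,
                           theta_sd_arithmetic_deg=sd_arith)


def polar_histogram(f: FiberSet, bin_deg: float = 10.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of axial angles with half-open bins [lo, hi) covering [0, 180)."""
    nbins = 180.0 / bin_deg
    if abs(nbins - round(nbins)) > 1e-9:
        raise FiberError(f"bin width {bin_deg} does not divide 180")
    edges = np.linspace(0.0, 180.0, int(round(nbins)) + 1)
    counts, _ = np.histogram(f.angles_deg, bins=edges)
    return edges, counts


def plot_polar_histogram(f: FiberSet, bin_deg: float = 10.0, ax=None,
                         title: str = ""):
    """Polar rose of the (axial, mirrored) angle distribution."""
    import matplotlib.pyplot as plt

    edges, counts = polar_histogram(f, bin_deg)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    centers = np.radians((edges[:-1] + edges[1:]) / 2.0)
    width = np.radians(bin_deg)
    ax.bar(np.concatenate([centers, centers + np.pi]),
           np.concatenate([counts, counts]), width=width, alpha=0.7)
    if title:
        ax.set_title(title)
    return ax
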