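"""Spectral preprocessing chain for polarized Raman spectra.

The chain is fixed, in this order:

1. baseline subtraction — iterative modified polynomial fitting (modpoly)
   of order 11, removing the smooth PBS/fluorescence background while
   preserving bands;
2. Savitzky–Golay smoothing (3rd-order polynomial, 11-point frame);
3. standard normal variate (SNV) normalization — per-spectrum zero mean,
   unit sample SD;
4. cropping to the 1400–1800 cm^-1 analysis window (amide I / CH2 region);
   the crop comes last so Savitzky–Golay edge effects fall outside it;
5. optional replicate averaging per (location, roi, point, angle) — after
   SNV, so each shot is normalized before pooling.

The order is part of the method and is refused, not reinterpreted, if a
configuration tries to permute it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .raman_io import AcquisitionMeta, RamanIOError, Spectrum, SpectrumSet, group_by

CANONICAL_STEPS = ("baseline", "smooth", "snv", "crop")


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    baseline_order: int = 11
    sg_polyorder: int = 3
    sg_window: int = 11
    crop_lo: float = 1400.0
    crop_hi: float = 1800.0
    average_replicates: bool = True
    #: step order; anything but the canonical order is refused
    steps: tuple = CANONICAL_STEPS

    def __post_init__(self) -> None:
        if self.baseline_order < 1:
            raise PreprocessError("baseline_order must be >= 1")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise PreprocessError("sg_window must be odd and > sg_polyorder")
        if not self.crop_lo < self.crop_hi:
            raise PreprocessError("crop_lo must be < crop_hi")
        if tuple(self.steps) != CANONICAL_STEPS:
            raise PreprocessError(
                f"processing order is fixed as {CANONICAL_STEPS}; "
                f"got {tuple(self.steps)}")


def subtract_baseline(s: Spectrum, order: int = 11, max_iter: int = 100,
                      tol_frac: float = 1e-6) -> Spectrum:
    """Subtract an iteratively fitted polynomial baseline (modpoly).

    A polynomial of the given order is fitted to the spectrum, the working
    curve is replaced by the pointwise minimum of itself and the fit, and
    the fit repeats until the baseline moves by less than ``tol_frac`` of
    the intensity range.  Peaks are progressively excluded from the fit,
    so a pure polynomial input is annihilated exactly on the first pass.
    """
    y = s.intensities
    n = y.size
    if n <= order + 1:
        raise PreprocessError(
            f"need more than order+1 = {order + 1} points, got {n}")
    # scale abscissa to [-1, 1] for conditioning at order 11
    w = s.wavenumbers
    x = 2.0 * (w - w[0]) / (w[-1] - w[0]) - 1.0 if w[-1] > w[0] else w * 0.0
    V = np.polynomial.polynomial.polyvander(x, order)
    # one factorization reused across iterations
    pinv = np.linalg.pinv(V)
    rng = np.ptp(y)
    tol = tol_frac * (rng if rng > 0 else 1.0)
    work = y.copy()
    baseline = V @ (pinv @ work)
    converged = False
    for _ in range(max_iter):
        work = np.minimum(work, baseline)
        new_baseline = V @ (pinv @ work)
        if np.max(np.abs(new_baseline - baseline)) < tol:
            baseline = new_baseline
            converged = True
            break
        baseline = new_baseline
    if not converged:
        warnings.warn("baseline iteration did not converge; "
                      "returning last iterate", RuntimeWarning, stacklevel=2)
    return s.with_intensities(y - baseline)


def smooth_sg(s: Spectrum, polyorder: int = 3, window: int = 11) -> Spectrum:
    """Savitzky–Golay smoothing; reproduces polynomials up to ``polyorder``."""
    if window % 2 == 0 or window <= polyorder:
        raise PreprocessError("window must be odd and > polyorder")
    if len(s) < window:
        raise PreprocessError(f"spectrum shorter than window ({len(s)} < {window})")
    return s.with_intensities(savgol_filter(s.intensities, window, polyorder))


def snv(s: Spectrum) -> Spectrum:
    """Standard normal variate: zero mean, unit sample SD (n-1 denominator)."""
    y = s.intensities
    if y.size < 2:
        raise PreprocessError("SNV needs at least 2 samples")
    sd = np.std(y, ddof=1)
    if sd <= 0:
        raise PreprocessError("SNV undefined for zero-variance spectrum")
    return s.with_intensities((y - np.mean(y)) / sd)


def crop(s: Spectrum, lo: float = 1400.0, hi: float = 1800.0) -> Spectrum:
    """Keep samples with lo <= wavenumber <= hi (closed interval)."""
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if not mask.any():
        raise PreprocessError(f"crop [{lo}, {hi}] leaves no samples")
    return Spectrum(s.wavenumbers[mask], s.intensities[mask], s.meta)


def preprocess_spectrum(s: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """baseline -> Savitzky–Golay -> SNV -> crop on a single spectrum."""
    s = subtract_baseline(s, cfg.baseline_order)
    s = smooth_sg(s, cfg.sg_polyorder, cfg.sg_window)
    s = snv(s)
    s = crop(s, cfg.crop_lo, cfg.crop_hi)
    return s


def average_replicates(sset: SpectrumSet) -> SpectrumSet:
    """Average spectra over replicates per (sample, location, roi, point, angle).

    The pooled spectrum carries ``replicate=0`` in its metadata.
    """
    groups = group_by(sset, ["sample_id", "location", "roi", "point",
                             "pol_angle_deg"])
    out = []
    for (sample_id, location, roi, point, angle), g in groups.items():
        grid = g.common_grid()
        mean = g.matrix().mean(axis=0)
        meta = AcquisitionMeta(sample_id=sample_id, location=location, roi=roi,
                               point=point, replicate=0, pol_angle_deg=angle)
        out.append(Spectrum(grid.copy(), mean, meta))
    return SpectrumSet(out)


def preprocess(sset: SpectrumSet, cfg: PreprocessConfig | None = None) -> SpectrumSet:
    """Apply the fixed chain to every spectrum, then optionally pool replicates."""
    cfg = cfg or PreprocessConfig()
    try:
        grid = sset.common_grid()
    except RamanIOError as exc:
        raise PreprocessError(
            "spectra must share a grid before preprocessing; "
            "resample explicitly first") from exc
    del grid
    processed = SpectrumSet([preprocess_spectrum(s, cfg) for s in sset])
    if cfg.average_replicates:
        processed = average_replicates(processed)
    return processed
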