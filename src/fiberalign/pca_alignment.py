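"""PCA master-loading projection and polarization sine-fit alignment metrics.

The extent and direction of protein-fiber alignment are read out of
polarized Raman spectra in three steps:

1. a *master loading function* — the first principal-component loading of a
   highly aligned reference tissue's preprocessed spectra (1400–1800 cm^-1)
   — defines a fixed linear functional dominated by the amide-I C=O band;
2. each test spectrum is centered by the reference mean and projected onto
   that loading, giving a single PC1 score per acquisition;
3. across polarization angles phi the score of an aligned region oscillates
   as ``PC1 = PC1_0 + A sin(pi (phi - phi_c) / 90)`` (period 180 degrees);
   the fitted amplitude A measures the extent of alignment and
   ``beta_PRS = (phi_c + 45) mod 180`` is the dominant fiber direction.

Within one sample, amplitudes are compared through the alignment aspect
ratio ``gamma = A / A_max``.

The sine model is linear in ``(PC1_0, A cos Phi, -A sin Phi)`` with
``Phi = pi phi_c / 90``, so the least-squares fit is solved in closed form;
the A >= 0, phi_c in [0, 180) branch is selected by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .raman_io import AcquisitionMeta, Spectrum, SpectrumSet

#: wavenumber (cm^-1) anchoring the loading sign convention: the amide-I
#: C=O stretching coefficient is required to be non-negative, which pins
#: the otherwise arbitrary PCA sign and makes scores reproducible.
AMIDE_I_ANCHOR = 1665.0


class AlignmentError(ValueError):
    pass


def _wrap180(angle: float) -> float:
    """Wrap to [0, 180); float mod can round -eps to exactly 180.0."""
    a = float(angle) % 180.0
    return 0.0 if a >= 180.0 else a


@dataclass
class LoadingFunction:
    """Unit-norm PC1 loading + reference mean on a fixed wavenumber grid."""

    grid: np.ndarray
    coefficients: np.ndarray
    reference_mean: np.ndarray
    variance_explained: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        self.coefficients = np.asarray(self.coefficients, float)
        self.reference_mean = np.asarray(self.reference_mean, float)
        self.variance_explained = np.asarray(self.variance_explained, float)
        if not (self.grid.shape == self.coefficients.shape
                == self.reference_mean.shape):
            raise AlignmentError("grid, coefficients and reference_mean "
                                 "must share one shape")
        nrm = np.linalg.norm(self.coefficients)
        if not np.isclose(nrm, 1.0, atol=1e-8):
            raise AlignmentError(f"loading must be unit-norm, got |c| = {nrm}")


@dataclass
class SineFit:
    """Least-squares fit of the polarization sine model at one point."""

    pc1_offset: float
    amplitude: float
    phase_deg: float
    beta_prs_deg: float
    rmse: float
    n_angles: int
    aligned: bool

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise AlignmentError("amplitude must be >= 0")
        if not 0.0 <= self.phase_deg < 180.0:
            raise AlignmentError("phase must lie in [0, 180)")


@dataclass
class RegionAlignment:
    """Per-location summary over measurement-point sine fits."""

    location: str
    amplitude_mean: float
    amplitude_sd: float
    ci_lo: float
    ci_hi: float
    beta_prs_deg: float
    n_points: int
    gamma: float = float("nan")


def derive_loading(reference: SpectrumSet) -> LoadingFunction:
    """Derive the master loading function from preprocessed reference spectra.

    Mean-centers the reference matrix, extracts all principal components,
    and returns PC1 with the amide-I sign convention plus the
    variance-explained fractions of every component.
    """
    if len(reference) < 2:
        raise AlignmentError("need at least 2 reference spectra")
    grid = reference.common_grid()
    X = reference.matrix()
    if np.allclose(X, X[0], atol=1e-12):
        raise AlignmentError("degenerate reference set: all spectra identical")
    pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]))
    pca.fit(X)
    if pca.explained_variance_[0] <= 0:
        raise AlignmentError("reference set has zero variance")
    pc1 = pca.components_[0]
    idx = int(np.argmin(np.abs(grid - AMIDE_I_ANCHOR)))
    if pc1[idx] < 0:
        pc1 = -pc1
    return LoadingFunction(grid=grid, coefficients=pc1,
                           reference_mean=X.mean(axis=0),
                           variance_explained=pca.explained_variance_ratio_)


def project_pc1(sset: SpectrumSet,
                loading: LoadingFunction) -> list[tuple[AcquisitionMeta, float]]:
    """Project spectra to PC1 scores: dot(s - reference_mean, coefficients).

    Grid mismatch is a hard error; resampling is an explicit I/O operation,
    never done silently here.
    """
    out = []
    for s in sset:
        if s.wavenumbers.shape != loading.grid.shape or not np.allclose(
                s.wavenumbers, loading.grid, rtol=0, atol=1e-9):
            raise AlignmentError("spectrum grid does not match loading grid; "
                                 "resample explicitly first")
        score = float(np.dot(s.intensities - loading.reference_mean,
                             loading.coefficients))
        out.append((s.meta, score))
    return out


def variance_explained(sset: SpectrumSet) -> np.ndarray:
    """Fractions of total variance per principal component of a spectrum set."""
    if len(sset) < 2:
        raise AlignmentError("need at least 2 spectra")
    X = sset.matrix()
    if np.allclose(X, X[0], atol=1e-12):
        raise AlignmentError("degenerate set: all spectra identical")
    pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]))
    pca.fit(X)
    return pca.explained_variance_ratio_


def fit_sine(scores_by_angle) -> SineFit:
    """Fit ``PC1_0 + A sin(pi (phi - phi_c)/90)`` over (angle, score) pairs.

    ``scores_by_angle`` maps polarization angle (degrees) to one score or a
    list of scores.  At least 3 distinct angles are required.  The fit is
    the exact linear-least-squares optimum; when the amplitude is below the
    noise floor (A < 2 RMSE) the phase is unidentifiable and the result is
    flagged ``aligned=False``.
    """
    phis, ys = [], []
    for phi, val in scores_by_angle.items():
        vals = np.atleast_1d(np.asarray(val, float))
        phis.extend([float(phi)] * vals.size)
        ys.extend(vals.tolist())
    phis = np.asarray(phis, float)
    ys = np.asarray(ys, float)
    distinct = np.unique(np.round(phis % 180.0, 9))
    if distinct.size < 3:
        raise AlignmentError(
            f"need >= 3 distinct polarization angles, got {distinct.size}")
    arg = np.pi * phis / 90.0
    M = np.column_stack([np.ones_like(phis), np.sin(arg), np.cos(arg)])
    coef, *_ = np.linalg.lstsq(M, ys, rcond=None)
    c0, a, b = coef
    A = float(np.hypot(a, b))
    # a = A cos(pi phi_c/90), b = -A sin(pi phi_c/90); phase wraps mod 180
    phase = _wrap180(np.degrees(np.arctan2(-b, a)) * 0.5)
    resid = ys - M @ coef
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    scale = max(1.0, float(np.max(np.abs(ys))) if ys.size else 1.0)
    aligned = (A >= 2.0 * rmse) and (A > 1e-9 * scale)
    return SineFit(pc1_offset=float(c0), amplitude=A, phase_deg=phase,
                   beta_prs_deg=_wrap180(phase + 45.0), rmse=rmse,
                   n_angles=int(distinct.size), aligned=aligned)


def alignment_angle(fit: SineFit) -> float:
    """beta_PRS = (phi_c + 45) mod 180; defined only for aligned fits."""
    if not fit.aligned:
        raise AlignmentError("alignment angle undefined: amplitude below "
                             "noise floor (unaligned fit)")
    return (fit.phase_deg + 45.0) % 180.0


def confidence_interval(values, alpha: float = 0.05) -> tuple[float, float]:
    """mean +/- t_{1-alpha/2, n-1} SD/sqrt(n) with sample (n-1) SD."""
    v = np.asarray(values, float)
    n = v.size
    if n < 2:
        raise AlignmentError("confidence interval needs n >= 2")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, n - 1))
    half = tcrit * sd / np.sqrt(n)
    return (mean - half, mean + half)


def aspect_ratio(amplitudes: dict) -> dict:
    """gamma = A / A_max across locations of one sample; max location gets 1."""
    if not amplitudes:
        raise AlignmentError("no amplitudes given")
    vals = np.asarray(list(amplitudes.values()), float)
    if np.any(vals <= 0):
        raise AlignmentError("all amplitudes must be positive")
    amax = float(vals.max())
    return {k: float(v) / amax for k, v in amplitudes.items()}


def axial_mean_deg(angles_deg) -> float:
    """Mean of axial angles (period 180) via the doubled-angle resultant."""
    a = np.radians(2.0 * np.asarray(angles_deg, float))
    return float(np.degrees(np.arctan2(np.sin(a).mean(), np.cos(a).mean()))
                 * 0.5 % 180.0)


def summarize_region(location: str, fits: list[SineFit],
                     alpha: float = 0.05) -> RegionAlignment:
    """Summarize per-point sine fits for one location: mean A, SD, CI, beta."""
    if not fits:
        raise AlignmentError("no fits to summarize")
    amps = np.array([f.amplitude for f in fits])
    betas = [f.beta_prs_deg for f in fits if f.aligned]
    beta = axial_mean_deg(betas) if betas else float("nan")
    if len(fits) >= 2:
        lo, hi = confidence_interval(amps, alpha)
        sd = float(amps.std(ddof=1))
    else:
        lo = hi = float(amps[0])
        sd = 0.0
    return RegionAlignment(location=location, amplitude_mean=float(amps.mean()),
                           amplitude_sd=sd, ci_lo=lo, ci_hi=hi,
                           beta_prs_deg=beta, n_points=len(fits))


def save_loading(loading: LoadingFunction, path) -> None:
    """Serialize as two-column text plus a JSON sidecar (mean + variance)."""
    import json
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# wavenumber_cm-1 loading_coefficient\n")
        for w, c in zip(loading.grid, loading.coefficients):
            fh.write(f"{float(w)!r} {float(c)!r}\n")
    sidecar = {"reference_mean": loading.reference_mean.tolist(),
               "variance_explained": loading.variance_explained.tolist()}
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh)


def load_loading(path) -> LoadingFunction:
    import json
    from pathlib import Path

    path = Path(path)
    arr = np.loadtxt(path, comments="#", ndmin=2)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    return LoadingFunction(grid=arr[:, 0], coefficients=arr[:, 1],
                           reference_mean=np.asarray(sidecar["reference_mean"]),
                           variance_explained=np.asarray(
                               sidecar["variance_explained"]))
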