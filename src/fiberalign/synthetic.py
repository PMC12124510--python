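"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the three measurement modalities:

* polarization-modulated Raman spectra of an engineered-tissue point:
  Gaussian bands at the soft-tissue positions (1445 CH2 bend, 1465 CH2/CH3
  deformation, 1605 C=C, 1656 and 1675 cm^-1 amide I), a smooth
  polynomial fluorescence/PBS baseline, and i.i.d. Gaussian noise.  The
  amide-I band heights are modulated with the polarization angle phi as
  ``height * (1 + m sin(pi (phi - phi_c)/90))`` — period 180 degrees, the
  same law the downstream sine fit assumes — so the generator's (m, phi_c)
  are recoverable ground truth;
* a reference set emulating highly aligned muscle spectra spanning many
  polarization angles, whose dominant variance direction is the amide-I
  modulation axis (what the master loading function is derived from);
* fiber-angle populations drawn from an axial wrapped normal (wrap at
  180 degrees), whose closed form E[cos 2 theta] = exp(-2 sigma^2) gives
  an analytic oracle for the alignment index S.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fiber_stats import FiberSet
from .raman_io import AcquisitionMeta, Spectrum, SpectrumSet, STANDARD_ANGLES

__all__ = ["Band", "SpectrumModel", "FiberModel", "gen_polarized_spectra",
           "gen_reference_set", "gen_fiber_angles", "gen_location_acquisitions"]


class SynthesisError(ValueError):
    pass


@dataclass(frozen=True)
class Band:
    center_cm1: float
    width_cm1: float      # Gaussian sigma
    height: float         # base intensity (counts)
    mod_depth: float = 0.0  # polarization modulation depth m in [0, 1]


#: default band table: CH2 / CH2-CH3 / C=C fixed, amide I polarization-modulated
def _default_bands(m: float = 0.5) -> tuple[Band, ...]:
    return (
        Band(1445.0, 12.0, 900.0, 0.0),
        Band(1465.0, 10.0, 650.0, 0.0),
        Band(1605.0, 9.0, 400.0, 0.0),
        Band(1656.0, 14.0, 1100.0, m),
        Band(1675.0, 11.0, 850.0, m),
    )


@dataclass(frozen=True)
class SpectrumModel:
    """Generative model of one measurement point's polarized spectra."""

    bands: tuple[Band, ...] = field(default_factory=_default_bands)
    phase_deg: float = 75.0          # phi_c of the modulated bands
    baseline_coefs: tuple[float, ...] = (400.0, -150.0, 60.0)  # Chebyshev-ish, on [-1,1]
    noise_sd: float = 10.0           # additive Gaussian, intensity counts
    # the acquisition range: spectra are collected over 1400-1800 cm^-1
    grid_lo: float = 1400.0
    grid_hi: float = 1800.0
    grid_step: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SynthesisError("noise_sd must be >= 0")
        for b in self.bands:
            if not 0.0 <= b.mod_depth <= 1.0:
                raise SynthesisError("modulation depth must lie in [0, 1]")
            if not self.grid_lo <= b.center_cm1 <= self.grid_hi:
                raise SynthesisError(f"band center {b.center_cm1} outside grid")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_hi - self.grid_lo) / self.grid_step)) + 1
        return self.grid_lo + self.grid_step * np.arange(n)

    def with_mod_depth(self, m: float) -> "SpectrumModel":
        bands = tuple(replace(b, mod_depth=m if b.mod_depth > 0 else 0.0)
                      for b in self.bands)
        return replace(self, bands=bands)


def _baseline(model: SpectrumModel, w: np.ndarray) -> np.ndarray:
    x = 2.0 * (w - w[0]) / (w[-1] - w[0]) - 1.0
    return np.polynomial.polynomial.polyval(x, np.asarray(model.baseline_coefs))


def _clean_spectrum(model: SpectrumModel, w: np.ndarray, phi: float) -> np.ndarray:
    y = _baseline(model, w)
    for b in model.bands:
        h = b.height * (1.0 + b.mod_depth
                        * np.sin(np.pi * (phi - model.phase_deg) / 90.0))
        if h < 0:
            raise SynthesisError(
                f"modulation drives band at {b.center_cm1} negative")
        y = y + h * np.exp(-0.5 * ((w - b.center_cm1) / b.width_cm1) ** 2)
    return y


def gen_polarized_spectra(model: SpectrumModel,
                          angles=STANDARD_ANGLES,
                          replicates: int = 1,
                          meta_base: AcquisitionMeta | None = None) -> SpectrumSet:
    """Generate ``replicates`` noisy spectra at each polarization angle.

    Deterministic for a fixed ``model.seed``.  ``meta_base`` supplies the
    sample/location/roi/point identity; replicates are numbered within each
    angle so metadata keys stay unique.
    """
    rng = np.random.default_rng(model.seed)
    w = model.grid()
    base = meta_base or AcquisitionMeta(sample_id="synthetic", location="MC",
                                        roi=1, point=1, replicate=1,
                                        pol_angle_deg=0.0)
    spectra = []
    for phi in angles:
        clean = _clean_spectrum(model, w, float(phi))
        for rep in range(1, replicates + 1):
            noise = rng.normal(0.0, model.noise_sd, size=w.size) \
                if model.noise_sd > 0 else 0.0
            meta = AcquisitionMeta(sample_id=base.sample_id,
                                   location=base.location, roi=base.roi,
                                   point=base.point, replicate=rep,
                                   pol_angle_deg=float(phi))
            spectra.append(Spectrum(w.copy(), clean + noise, meta))
    return SpectrumSet(spectra, shared_grid=w)


def gen_reference_set(model: SpectrumModel | None = None,
                      n: int = 110) -> SpectrumSet:
    """Emulate a highly aligned reference tissue's spectrum library.

    ``n`` spectra span polarization angles uniformly over [0, 180) with a
    strong amide-I modulation, so the first principal direction of the
    preprocessed set is the amide-I modulation axis.
    """
    model = model or SpectrumModel(bands=_default_bands(0.8), noise_sd=8.0,
                                   phase_deg=0.0)
    rng = np.random.default_rng(model.seed)
    w = model.grid()
    angles = np.linspace(0.0, 180.0, n, endpoint=False)
    spectra = []
    for i, phi in enumerate(angles):
        clean = _clean_spectrum(model, w, float(phi))
        noise = rng.normal(0.0, model.noise_sd, size=w.size) \
            if model.noise_sd > 0 else 0.0
        meta = AcquisitionMeta(sample_id="reference-muscle", location="MC",
                               roi=1, point=i + 1, replicate=1,
                               pol_angle_deg=float(phi))
        spectra.append(Spectrum(w.copy(), clean + noise, meta))
    return SpectrumSet(spectra, shared_grid=w)


def gen_location_acquisitions(model: SpectrumModel, location: str,
                              sample_id: str = "synthetic",
                              n_points: int = 11, n_roi: int = 2,
                              n_replicates: int = 12,
                              point_jitter_rel: float = 0.06) -> SpectrumSet:
    """Emulate the full acquisition scheme of one construct location.

    ``n_points`` points per ROI, ``n_roi`` ROIs, ``n_replicates`` replicate
    shots per point.  The 12 replicates cycle through the 6 standard
    polarization angles twice (replicate r measures angle
    ``30 * ((r - 1) mod 6)``), giving 264 spectra over 22 points with 44
    spectra per angle — the counting structure of the real protocol.
    Point-to-point biological variability enters as a relative jitter on
    the amide-I modulation depth.
    """
    rng = np.random.default_rng(model.seed)
    spectra = []
    w = model.grid()
    for roi in range(1, n_roi + 1):
        for point in range(1, n_points + 1):
            jitter = 1.0 + point_jitter_rel * rng.standard_normal()
            pm = model.with_mod_depth(
                float(np.clip(max(b.mod_depth for b in model.bands)
                              * jitter, 0.0, 0.999)))
            for rep in range(1, n_replicates + 1):
                phi = STANDARD_ANGLES[(rep - 1) % len(STANDARD_ANGLES)]
                clean = _clean_spectrum(pm, w, phi)
                noise = rng.normal(0.0, model.noise_sd, size=w.size) \
                    if model.noise_sd > 0 else 0.0
                meta = AcquisitionMeta(sample_id=sample_id, location=location,
                                       roi=roi, point=point, replicate=rep,
                                       pol_angle_deg=phi)
                spectra.append(Spectrum(w.copy(), clean + noise, meta))
    return SpectrumSet(spectra, shared_grid=w)


@dataclass(frozen=True)
class FiberModel:
    """Axial wrapped-normal fiber-angle population."""

    n: int = 150
    mean_deg: float = 90.0
    sd_deg: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SynthesisError("n must be >= 1")
        if self.sd_deg < 0:
            raise SynthesisError("sd_deg must be >= 0")


def gen_fiber_angles(model: FiberModel) -> FiberSet:
    """Draw n angles from a wrapped normal on the axial circle (wrap 180)."""
    rng = np.random.default_rng(model.seed)
    draws = rng.normal(model.mean_deg, model.sd_deg, size=model.n)
    return FiberSet(angles_deg=np.mod(draws, 180.0))
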