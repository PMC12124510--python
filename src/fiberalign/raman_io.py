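"""Reading, writing and grouping of polarized Raman acquisitions.

A polarized Raman (PRS) acquisition is a single spectrum — intensity counts
on a strictly increasing wavenumber grid — tagged with where and how it was
taken: sampling location in the construct (corner edge CE, middle edge ME,
middle center MC), region of interest, point index along the measurement
line, replicate index, and the polarization angle of the analyser relative
to the sample axis.  Angles live on the axial circle [0, 180) because a
protein fiber at angle theta is indistinguishable from one at theta + 180.

Spectra are exchanged as plain two-column text files (wavenumber, intensity;
whitespace or comma delimited, '#' comments allowed), the dialect most
instrument exports can be coerced into, indexed by a manifest CSV with
columns ``file,sample_id,location,roi,point,replicate,pol_angle_deg``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

LOCATIONS = ("CE", "ME", "MC")

#: polarization angles used by the rotation protocol (30-degree increments,
#: stopping at 150 because of the 180-degree periodicity of fiber axes)
STANDARD_ANGLES = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)

MANIFEST_COLUMNS = (
    "file", "sample_id", "location", "roi", "point", "replicate", "pol_angle_deg",
)


class RamanIOError(ValueError):
    """Raised for malformed spectra files, manifests or metadata."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Metadata of one PRS acquisition.

    ``replicate`` 0 denotes a replicate-averaged (pooled) spectrum produced
    by preprocessing; raw acquisitions are numbered from 1.
    """

    sample_id: str
    location: str
    roi: int
    point: int
    replicate: int
    pol_angle_deg: float
    nonstandard_angle: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise RamanIOError("sample_id must be non-empty")
        if self.location not in LOCATIONS:
            raise RamanIOError(
                f"location must be one of {LOCATIONS}, got {self.location!r}")
        if self.roi < 1:
            raise RamanIOError(f"roi must be >= 1, got {self.roi}")
        if self.point < 1:
            raise RamanIOError(f"point must be >= 1, got {self.point}")
        if self.replicate < 0:
            raise RamanIOError(f"replicate must be >= 0, got {self.replicate}")
        angle = float(self.pol_angle_deg) % 180.0
        object.__setattr__(self, "pol_angle_deg", angle)
        # angles outside the standard rotation protocol are legal but flagged
        flagged = not any(abs(angle - a) < 1e-9 for a in STANDARD_ANGLES)
        object.__setattr__(self, "nonstandard_angle", flagged)

    def key(self) -> tuple:
        return (self.location, self.roi, self.point, self.replicate,
                self.pol_angle_deg)


@dataclass
class Spectrum:
    """Intensity counts on a strictly increasing wavenumber grid (cm^-1)."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or y.ndim != 1 or w.shape != y.shape:
            raise RamanIOError("wavenumbers and intensities must be equal-length 1-D")
        if w.size and not np.all(np.diff(w) > 0):
            raise RamanIOError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise RamanIOError("intensities must be finite")
        self.wavenumbers = w
        self.intensities = y

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, y: np.ndarray) -> "Spectrum":
        return Spectrum(self.wavenumbers.copy(), np.asarray(y, float), self.meta)


@dataclass
class SpectrumSet:
    """A collection of spectra, optionally constrained to one shared grid."""

    spectra: list[Spectrum]
    shared_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.shared_grid is not None:
            g = np.asarray(self.shared_grid, float)
            for s in self.spectra:
                if s.wavenumbers.shape != g.shape or not np.allclose(
                        s.wavenumbers, g, rtol=0, atol=1e-9):
                    raise RamanIOError("spectrum does not conform to shared_grid")
            self.shared_grid = g

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    def matrix(self) -> np.ndarray:
        """(n_spectra, n_wavenumbers) intensity matrix; requires a common grid."""
        grid = self.common_grid()
        return np.vstack([s.intensities for s in self.spectra]) if self.spectra \
            else np.empty((0, grid.size))

    def common_grid(self) -> np.ndarray:
        if self.shared_grid is not None:
            return self.shared_grid
        if not self.spectra:
            raise RamanIOError("empty SpectrumSet has no grid")
        g = self.spectra[0].wavenumbers
        for s in self.spectra[1:]:
            if s.wavenumbers.shape != g.shape or not np.allclose(
                    s.wavenumbers, g, rtol=0, atol=1e-9):
                raise RamanIOError("spectra are not on a common grid")
        return g


def read_spectrum_file(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column text spectrum (wavenumber, intensity)."""
    path = Path(path)
    if not path.exists():
        raise RamanIOError(f"spectrum file not found: {path}")
    try:
        arr = np.loadtxt(path, comments="#", delimiter=None, ndmin=2)
    except ValueError:
        try:
            arr = np.loadtxt(path, comments="#", delimiter=",", ndmin=2)
        except ValueError as exc:
            raise RamanIOError(f"unparsable spectrum file {path}: {exc}") from exc
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise RamanIOError(f"{path}: expected two numeric columns")
    w, y = arr[:, 0], arr[:, 1]
    if not np.all(np.diff(w) > 0):
        raise RamanIOError(f"{path}: wavenumbers not strictly increasing")
    return w, y


def write_spectrum_file(path: str | os.PathLike, wavenumbers: np.ndarray,
                        intensities: np.ndarray, header: str = "") -> None:
    """Write the two-column dialect; round-trips bit-exactly via repr floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# wavenumber_cm-1 intensity\n")
        for w, y in zip(np.asarray(wavenumbers, float), np.asarray(intensities, float)):
            # repr of a Python float round-trips bit-exactly through loadtxt
            fh.write(f"{float(w)!r} {float(y)!r}\n")


def read_spectra(manifest_path: str | os.PathLike,
                 data_dir: str | os.PathLike | None = None) -> SpectrumSet:
    """Read every acquisition listed in a manifest CSV.

    Any missing or unparsable file is a hard error naming the offending row;
    duplicate (location, roi, point, replicate, angle) keys are rejected.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise RamanIOError(f"manifest not found: {manifest_path}")
    data_dir = Path(data_dir) if data_dir is not None else manifest_path.parent
    df = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise RamanIOError(f"manifest missing columns: {sorted(missing)}")
    spectra: list[Spectrum] = []
    seen: dict[tuple, int] = {}
    for i, row in df.iterrows():
        fpath = data_dir / str(row["file"])
        try:
            w, y = read_spectrum_file(fpath)
            meta = AcquisitionMeta(
                sample_id=str(row["sample_id"]),
                location=str(row["location"]),
                roi=int(row["roi"]),
                point=int(row["point"]),
                replicate=int(row["replicate"]),
                pol_angle_deg=float(row["pol_angle_deg"]),
            )
        except (RamanIOError, ValueError) as exc:
            raise RamanIOError(f"manifest row {i} ({row['file']}): {exc}") from exc
        key = meta.key()
        if key in seen:
            raise RamanIOError(
                f"manifest row {i}: duplicate acquisition key {key} "
                f"(first seen at row {seen[key]})")
        seen[key] = i
        spectra.append(Spectrum(w, y, meta))
    return SpectrumSet(spectra)


def write_spectra(sset: SpectrumSet, out_dir: str | os.PathLike,
                  manifest_name: str = "manifest.csv") -> Path:
    """Write a SpectrumSet as one file per acquisition plus a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(sset):
        m = s.meta
        fname = (f"{m.sample_id}_{m.location}_roi{m.roi}_p{m.point:02d}"
                 f"_r{m.replicate:02d}_a{int(round(m.pol_angle_deg)):03d}.txt")
        write_spectrum_file(out_dir / fname, s.wavenumbers, s.intensities)
        rows.append({"file": fname, "sample_id": m.sample_id,
                     "location": m.location, "roi": m.roi, "point": m.point,
                     "replicate": m.replicate, "pol_angle_deg": m.pol_angle_deg})
    manifest = out_dir / manifest_name
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, index=False)
    return manifest


_META_FIELDS = ("sample_id", "location", "roi", "point", "replicate",
                "pol_angle_deg")


def group_by(sset: SpectrumSet,
             keys: Sequence[str]) -> dict[tuple, SpectrumSet]:
    """Partition a SpectrumSet by metadata fields.

    The groups are a true partition: their sizes sum to ``len(sset)``.
    """
    for k in keys:
        if k not in _META_FIELDS:
            raise RamanIOError(f"unknown metadata field {k!r}; "
                               f"valid fields: {_META_FIELDS}")
    groups: dict[tuple, list[Spectrum]] = {}
    for s in sset:
        key = tuple(getattr(s.meta, k) for k in keys)
        groups.setdefault(key, []).append(s)
    return {k: SpectrumSet(v) for k, v in sorted(groups.items())}


def resample(sset: SpectrumSet, grid: np.ndarray) -> SpectrumSet:
    """Linearly resample every spectrum onto ``grid`` (explicit, never implicit)."""
    grid = np.asarray(grid, float)
    if not np.all(np.diff(grid) > 0):
        raise RamanIOError("target grid must be strictly increasing")
    out = []
    for s in sset:
        if grid[0] < s.wavenumbers[0] - 1e-9 or grid[-1] > s.wavenumbers[-1] + 1e-9:
            raise RamanIOError("target grid extends beyond spectrum support")
        out.append(Spectrum(grid.copy(), np.interp(grid, s.wavenumbers,
                                                   s.intensities), s.meta))
    return SpectrumSet(out, shared_grid=grid)
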