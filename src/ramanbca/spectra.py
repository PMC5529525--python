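"""Spectrum and component-library containers with plain-text I/O.

A :class:`Spectrum` is a wavenumber axis (cm^-1) plus an intensity trace in
arbitrary detector units, with optional acquisition metadata (cell, organelle,
timestamp).  A :class:`ComponentLibrary` bundles calibrated reference spectra
of the biomolecular classes (protein, RNA, DNA, lipid) on one common grid,
each carrying the concentration in mg/ml that corresponds to spectral
weight 1.0.

File dialects are deliberately minimal: two-column whitespace- or
comma-delimited text with ``#`` comment headers for spectra, and a directory
with a JSON manifest plus one spectrum file per component for libraries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

ORGANELLES = ("nucleolus", "ER", "mitochondrion", "other")

#: metadata keys serialized into spectrum file headers
_META_KEYS = (
    "cell_id",
    "cell_line",
    "organelle",
    "timestamp_min",
    "accumulation_s",
    "replicate_index",
)

_MIN_POINTS = 16


class SpectrumFormatError(ValueError):
    """Raised when a spectrum file cannot be parsed or violates invariants."""


class LibraryError(ValueError):
    """Raised for malformed or inconsistent component libraries."""


@dataclass(frozen=True)
class Spectrum:
    """One Raman spectrum: intensity versus wavenumber shift.

    Parameters
    ----------
    wavenumbers : array-like
        Strictly increasing Raman shifts in cm^-1, length >= 16.
    intensities : array-like
        Finite intensities (arbitrary units), same length as `wavenumbers`.
    meta : mapping, optional
        Acquisition metadata; recognised keys are cell_id, cell_line,
        organelle, timestamp_min, accumulation_s, replicate_index.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wn.ndim != 1 or it.ndim != 1 or wn.shape != it.shape:
            raise SpectrumFormatError(
                "wavenumbers and intensities must be 1-D of equal length"
            )
        if wn.size < _MIN_POINTS:
            raise SpectrumFormatError(
                f"spectrum too short: {wn.size} points (need >= {_MIN_POINTS})"
            )
        if not np.all(np.diff(wn) > 0):
            raise SpectrumFormatError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(it)):
            raise SpectrumFormatError("intensities contain NaN or Inf")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", it)
        object.__setattr__(self, "meta", dict(self.meta))
        org = self.meta.get("organelle")
        if org is not None and org not in ORGANELLES:
            raise SpectrumFormatError(
                f"unknown organelle {org!r}; expected one of {ORGANELLES}"
            )

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def with_intensities(self, intensities: np.ndarray, **meta_updates) -> "Spectrum":
        """Return a copy on the same grid with new intensities (metadata kept)."""
        meta = {**self.meta, **meta_updates}
        return Spectrum(self.wavenumbers, intensities, meta)

    def same_grid(self, other: "Spectrum", atol: float = 1e-9) -> bool:
        return self.wavenumbers.shape == other.wavenumbers.shape and np.allclose(
            self.wavenumbers, other.wavenumbers, atol=atol, rtol=0.0
        )


@dataclass(frozen=True)
class ComponentProfile:
    """A calibrated reference spectrum for one biomolecular class.

    ``unit_concentration`` is the concentration in mg/ml that corresponds to
    spectral weight 1.0 of this component in a linear-combination fit
    (100 mg/ml for protein, 20 mg/ml for RNA, DNA and lipid by default).
    """

    name: str
    reference: Spectrum
    unit_concentration: float

    def __post_init__(self) -> None:
        if not self.name:
            raise LibraryError("component name must be non-empty")
        if np.any(self.reference.intensities < 0):
            raise LibraryError(f"component {self.name!r}: negative reference intensity")
        if not (self.unit_concentration > 0):
            raise LibraryError(
                f"component {self.name!r}: unit_concentration must be > 0"
            )


@dataclass(frozen=True)
class ComponentLibrary:
    """An ordered set of calibrated component profiles on one common grid."""

    components: tuple[ComponentProfile, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        if not comps:
            raise LibraryError("library must contain at least one component")
        names = [c.name for c in comps]
        if len(set(names)) != len(names):
            raise LibraryError(f"duplicate component names: {names}")
        grid = comps[0].reference.wavenumbers
        for c in comps[1:]:
            if not comps[0].reference.same_grid(c.reference):
                raise LibraryError(
                    f"component {c.name!r} is not on the library grid"
                )
        # collinearity guard: near-identical shapes make the fit singular
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                a = comps[i].reference.intensities
                b = comps[j].reference.intensities
                na, nb = np.linalg.norm(a), np.linalg.norm(b)
                if na > 0 and nb > 0:
                    cos = float(np.dot(a, b) / (na * nb))
                    if cos >= 0.999:
                        raise LibraryError(
                            f"components {comps[i].name!r} and {comps[j].name!r} "
                            f"are collinear (cosine {cos:.6f} >= 0.999)"
                        )
        object.__setattr__(self, "components", comps)

    @property
    def grid(self) -> np.ndarray:
        return self.components[0].reference.wavenumbers

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    def __getitem__(self, name: str) -> ComponentProfile:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __len__(self) -> int:
        return len(self.components)

    def matrix(self) -> np.ndarray:
        """Component references stacked as columns, shape (n_channels, n_components)."""
        return np.column_stack([c.reference.intensities for c in self.components])

    def reordered(self, names: Sequence[str]) -> "ComponentLibrary":
        if sorted(names) != sorted(self.names):
            raise LibraryError("reordered() needs a permutation of component names")
        return ComponentLibrary(
            tuple(self[n] for n in names), provenance=self.provenance
        )


# ---------------------------------------------------------------------------
# spectrum file I/O


def _parse_meta_value(raw: str):
    raw = raw.strip()
    try:
        f = float(raw)
        return int(f) if f.is_integer() and "." not in raw and "e" not in raw.lower() else f
    except ValueError:
        return raw


def read_spectrum(path, format: str = "two_column_ascii") -> Spectrum:
    """Read a two-column (wavenumber, intensity) text spectrum.

    Header lines starting with ``#`` may carry ``key = value`` metadata.
    Rows are sorted by wavenumber if the file is unsorted; duplicate
    wavenumbers are rejected.
    """
    if format not in ("two_column_ascii", "csv"):
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    meta: dict = {}
    wn: list[float] = []
    it: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key = key.strip()
                    if key in _META_KEYS:
                        meta[key] = _parse_meta_value(val)
                continue
            parts = line.split(",") if format == "csv" else line.split()
            if len(parts) < 2:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: expected >= 2 numeric columns, got {line!r}"
                )
            try:
                wn.append(float(parts[0]))
                it.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumFormatError(f"{path}:{lineno}: {exc}") from exc
    if len(wn) < _MIN_POINTS:
        raise SpectrumFormatError(
            f"{path}: only {len(wn)} data rows (need >= {_MIN_POINTS})"
        )
    wn_arr = np.asarray(wn)
    it_arr = np.asarray(it)
    order = np.argsort(wn_arr, kind="stable")
    wn_arr, it_arr = wn_arr[order], it_arr[order]
    if np.any(np.diff(wn_arr) == 0):
        dup = wn_arr[:-1][np.diff(wn_arr) == 0][0]
        raise SpectrumFormatError(f"{path}: duplicate wavenumber {dup:g}")
    return Spectrum(wn_arr, it_arr, meta)


def write_spectrum(spectrum: Spectrum, path, format: str = "two_column_ascii") -> None:
    """Write a spectrum as two-column text; metadata goes to ``#`` header lines."""
    if format not in ("two_column_ascii", "csv"):
        raise ValueError(f"unknown format {format!r}")
    sep = "," if format == "csv" else " "
    path = Path(path)
    lines = []
    for key in _META_KEYS:
        if key in spectrum.meta:
            lines.append(f"# {key} = {spectrum.meta[key]}")
    for w, i in zip(spectrum.wavenumbers, spectrum.intensities):
        lines.append(f"{w:.10g}{sep}{i:.10g}")
    path.write_text("\n".join(lines) + "\n")


def resample(spectrum: Spectrum, grid: Iterable[float]) -> Spectrum:
    """Linearly interpolate a spectrum onto a new wavenumber grid.

    The target grid must lie within the spectrum's range: extrapolation is
    refused rather than silently invented.  Linear interpolation is exact at
    shared grid points and for affine intensity traces, and never overshoots.
    """
    grid = np.asarray(list(grid) if not isinstance(grid, np.ndarray) else grid,
                      dtype=float)
    lo, hi = spectrum.wavenumbers[0], spectrum.wavenumbers[-1]
    if grid[0] < lo - 1e-12 or grid[-1] > hi + 1e-12:
        raise ValueError(
            f"resample would extrapolate: target [{grid[0]:g}, {grid[-1]:g}] "
            f"outside data [{lo:g}, {hi:g}]"
        )
    new = np.interp(grid, spectrum.wavenumbers, spectrum.intensities)
    return Spectrum(grid, new, spectrum.meta)


# ---------------------------------------------------------------------------
# component-library bundle I/O


def write_component_library(lib: ComponentLibrary, path) -> None:
    """Write a library as a directory: manifest.json + one file per component."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {"provenance": lib.provenance, "components": []}
    for comp in lib.components:
        fname = f"{comp.name}.txt"
        write_spectrum(comp.reference, path / fname)
        manifest["components"].append(
            {
                "name": comp.name,
                "unit_concentration": comp.unit_concentration,
                "file": fname,
            }
        )
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def read_component_library(path) -> ComponentLibrary:
    """Read a library bundle written by :func:`write_component_library`."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise LibraryError(f"no manifest.json in {path}")
    manifest = json.loads(manifest_path.read_text())
    comps = []
    for entry in manifest.get("components", []):
        if "unit_concentration" not in entry:
            raise LibraryError(
                f"manifest entry {entry.get('name', '?')!r} lacks unit_concentration"
            )
        ref = read_spectrum(path / entry["file"])
        comps.append(
            ComponentProfile(
                name=entry["name"],
                reference=ref,
                unit_concentration=float(entry["unit_concentration"]),
            )
        )
    return ComponentLibrary(tuple(comps), provenance=manifest.get("provenance", ""))


def default_grid(start: float = 600.0, stop: float = 1800.0, step: float = 1.0) -> np.ndarray:
    """The package's default fingerprint-region wavenumber grid (cm^-1)."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)
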