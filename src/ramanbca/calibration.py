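"""Concentration calibration of reference component profiles.

A component profile enters the linear-combination fit already scaled so that
spectral weight 1.0 corresponds to a fixed *unit concentration*: 100 mg/ml
for protein and 20 mg/ml for RNA, DNA and lipid.  Calibration builds that
scaling from spectra of pure-compound solutions at known concentrations
(bovine serum albumin, calf thymus DNA, yeast RNA, heart-lipid extracts are
typical calibrants): each measured spectrum is projected onto the common
normalized shape, and a regression through the origin of projection
amplitude versus concentration gives the intensity per mg/ml.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .spectra import ComponentLibrary, ComponentProfile, Spectrum

#: unit concentrations (mg/ml) corresponding to spectral weight 1.0
DEFAULT_UNIT_CONCENTRATIONS: dict[str, float] = {
    "protein": 100.0,
    "RNA": 20.0,
    "DNA": 20.0,
    "lipid": 20.0,
}


@dataclass(frozen=True)
class CalibrationRecord:
    """Provenance of one component's concentration calibration."""

    analyte: str
    concentrations: tuple[float, ...]
    fitted_scale: float  # projection amplitude per mg/ml
    r_squared: float

    def __post_init__(self):
        if len(self.concentrations) < 1 or any(c <= 0 for c in self.concentrations):
            raise ValueError("calibration needs concentrations > 0")
        if not (self.fitted_scale > 0):
            raise ValueError("fitted_scale must be > 0")


def calibrate_component(
    analyte: str,
    measurements: Sequence[tuple[float, Spectrum]],
    unit_concentration: float,
) -> tuple[ComponentProfile, CalibrationRecord]:
    """Build a calibrated component profile from pure-solution spectra.

    Parameters
    ----------
    analyte : str
        Component name (protein, RNA, DNA, lipid, or custom).
    measurements : sequence of (concentration mg/ml, Spectrum)
        Preprocessed pure-compound spectra on a common grid, >= 1 distinct
        concentration (>= 2 recommended; a single point raises a warning).
    unit_concentration : float
        The mg/ml that spectral weight 1.0 should represent.

    Returns
    -------
    profile : ComponentProfile
        Mean shape scaled so that projecting a pure spectrum measured at
        ``unit_concentration`` yields weight 1.0.
    record : CalibrationRecord
    """
    if not measurements:
        raise ValueError("no calibration measurements given")
    if unit_concentration <= 0:
        raise ValueError("unit_concentration must be > 0")
    concs = np.array([c for c, _ in measurements], dtype=float)
    if np.any(concs <= 0):
        raise ValueError("calibration concentrations must be > 0")
    grid = measurements[0][1].wavenumbers
    for _, s in measurements[1:]:
        if not measurements[0][1].same_grid(s):
            raise ValueError("calibration spectra are not on a common grid")
    if len(set(concs.tolist())) == 1 and len(concs) > 1:
        warnings.warn("all calibration measurements at one concentration")

    # common shape: intensity-normalized mean of per-spectrum unit shapes
    stack = np.vstack([s.intensities for _, s in measurements])
    shapes = stack / np.linalg.norm(stack, axis=1, keepdims=True)
    mean_shape = shapes.mean(axis=0)
    mean_shape = np.clip(mean_shape, 0.0, None)
    mean_shape /= np.linalg.norm(mean_shape)

    # per-spectrum amplitude by least-squares projection onto the shape
    amplitudes = stack @ mean_shape  # ||shape|| == 1

    if len(concs) == 1:
        warnings.warn(
            f"{analyte}: single calibration concentration; scale from one point"
        )
        slope = float(amplitudes[0] / concs[0])
        r2 = 1.0
    else:
        # regression through the origin: zero concentration -> zero signal
        slope = float(np.dot(amplitudes, concs) / np.dot(concs, concs))
        resid = amplitudes - slope * concs
        ss_tot = float(np.dot(amplitudes, amplitudes))
        r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 0.0
    if slope <= 0:
        raise ValueError(f"{analyte}: non-positive calibration slope {slope:g}")

    # scale shape so that a pure spectrum at unit_concentration fits weight 1
    reference = mean_shape * slope * unit_concentration
    profile = ComponentProfile(
        name=analyte,
        reference=Spectrum(grid, reference),
        unit_concentration=float(unit_concentration),
    )
    record = CalibrationRecord(
        analyte=analyte,
        concentrations=tuple(concs.tolist()),
        fitted_scale=slope,
        r_squared=r2,
    )
    return profile, record


def weights_to_concentrations(
    weights: Mapping[str, float], library: ComponentLibrary
) -> dict[str, float]:
    """Convert spectral weights to mg/ml: concentration = weight x unit."""
    out = {}
    for analyte, w in weights.items():
        if analyte not in library:
            raise KeyError(f"analyte {analyte!r} not in library {library.names}")
        out[analyte] = w * library[analyte].unit_concentration
    return out
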