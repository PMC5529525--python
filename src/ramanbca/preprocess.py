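"""Spectral preprocessing: background subtraction, smoothing, baseline removal.

The chain mirrors standard chemometric practice for fluorescence-contaminated
Raman spectra: subtract a measured substrate/medium background, optionally
smooth with a Savitzky-Golay filter, then remove the slowly varying
autofluorescence baseline before linear-combination fitting.  Every step is
conservative in the accounting sense: the raw trace always equals
corrected + baseline (+ background) channel by channel.

The baseline corrector is exposed both as functions and as an
:class:`AslsBaseline` scikit-learn transformer so it can sit in a Pipeline in
front of the decomposition estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .spectra import Spectrum

logger = logging.getLogger(__name__)


class BaselineConvergenceError(RuntimeError):
    """ALS weight iteration failed to converge within max_iter."""

    def __init__(self, iterations: int, change: float):
        self.iterations = iterations
        super().__init__(
            f"baseline weights not converged after {iterations} iterations "
            f"(last change {change:.3g})"
        )


@dataclass
class PreprocessResult:
    """Outcome of a preprocessing chain on one organelle's spectrum.

    ``processed + baseline + background`` reproduces the raw input exactly
    (background omitted from the sum when not subtracted).
    """

    processed: Spectrum
    baseline: Spectrum
    background: Spectrum | None = None
    per_channel_sd: np.ndarray | None = None
    log: list = field(default_factory=list)


def subtract_background(
    spectrum: Spectrum, background: Spectrum, scale: float = 1.0
) -> Spectrum:
    """Subtract ``scale`` x a measured background spectrum (same grid)."""
    if not spectrum.same_grid(background):
        raise ValueError("background is not on the spectrum's grid; resample first")
    out = spectrum.with_intensities(spectrum.intensities - scale * background.intensities)
    logger.info("subtract_background: scale=%g", scale)
    return out


def smooth(spectrum: Spectrum, window_points: int = 9, polyorder: int = 3) -> Spectrum:
    """Savitzky-Golay smoothing; polynomials of degree <= polyorder pass unchanged."""
    if window_points % 2 == 0 or window_points < 5:
        raise ValueError(f"window_points must be odd and >= 5, got {window_points}")
    if polyorder >= window_points - 1:
        # polyorder == window-1 interpolates instead of smoothing
        raise ValueError(
            f"polyorder ({polyorder}) must be < window_points - 1 ({window_points - 1})"
        )
    if window_points > len(spectrum):
        raise ValueError("window larger than spectrum")
    out = savgol_filter(spectrum.intensities, window_points, polyorder)
    logger.info("smooth: window=%d polyorder=%d", window_points, polyorder)
    return spectrum.with_intensities(out)


def asls_baseline(
    y: np.ndarray,
    lam: float = 1e8,
    p: float = 0.01,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> np.ndarray:
    """Asymmetric-least-squares baseline of a 1-D signal.

    Whittaker smoother with a second-difference roughness penalty ``lam`` and
    asymmetric residual weights: points above the baseline (Raman peaks) get
    weight ``p``, points below get ``1 - p``, iterated until the weight
    vector is stable.  Returns the baseline estimate.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    penalty = lam * (D.T @ D)
    w = np.ones(n)
    z = y
    change = np.inf
    for _ in range(max_iter):
        W = sparse.diags(w)
        z = spsolve((W + penalty).tocsc(), w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        change = float(np.max(np.abs(w_new - w)))
        w = w_new
        if change < tol:
            return z
    raise BaselineConvergenceError(max_iter, change)


def _poly_baseline(y: np.ndarray, x: np.ndarray, degree: int) -> np.ndarray:
    xs = (x - x.mean()) / (x.max() - x.min())  # conditioning
    coeffs = np.polynomial.polynomial.polyfit(xs, y, degree)
    return np.polynomial.polynomial.polyval(xs, coeffs)


def correct_baseline(
    spectrum: Spectrum,
    method: str = "asls",
    lam: float = 1e8,
    p: float = 0.01,
    max_iter: int = 50,
    tol: float = 1e-6,
    degree: int = 3,
) -> tuple[Spectrum, Spectrum]:
    """Estimate and remove the slowly varying baseline.

    Returns ``(corrected, baseline)`` with ``corrected = spectrum - baseline``
    exactly.  ``method`` is ``"asls"`` (default; asymmetric least squares,
    the community standard for fluorescence under Raman peaks) or
    ``"polynomial"`` (ordinary polynomial fit of the given degree).
    """
    if method == "asls":
        base = asls_baseline(spectrum.intensities, lam=lam, p=p, max_iter=max_iter, tol=tol)
        logger.info("correct_baseline: asls lam=%g p=%g", lam, p)
    elif method == "polynomial":
        base = _poly_baseline(spectrum.intensities, spectrum.wavenumbers, degree)
        logger.info("correct_baseline: polynomial degree=%d", degree)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    corrected = spectrum.with_intensities(spectrum.intensities - base)
    baseline = spectrum.with_intensities(base)
    return corrected, baseline


def average_replicates(spectra: Sequence[Spectrum]) -> PreprocessResult:
    """Average sequential replicate acquisitions of the same organelle.

    Returns the pointwise mean as ``processed`` and the pointwise sample SD
    as ``per_channel_sd`` (ddof=1), for use as fit weights downstream.
    Replicates must share the grid and the organelle metadata;
    ``replicate_index`` is dropped from the merged metadata.
    """
    if len(spectra) < 2:
        raise ValueError("need >= 2 replicates to average")
    first = spectra[0]
    organelles = {s.meta.get("organelle") for s in spectra}
    if len(organelles) > 1:
        raise ValueError(f"mixed organelle labels in replicates: {organelles}")
    for s in spectra[1:]:
        if not first.same_grid(s):
            raise ValueError("replicates are not on a common grid")
    stack = np.vstack([s.intensities for s in spectra])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    meta = {k: v for k, v in first.meta.items() if k != "replicate_index"}
    processed = Spectrum(first.wavenumbers, mean, meta)
    result = PreprocessResult(
        processed=processed,
        baseline=Spectrum(first.wavenumbers, np.zeros(len(first)), meta),
        per_channel_sd=sd,
        log=[("average_replicates", {"n": len(spectra)})],
    )
    return result


def preprocess(
    spectrum: Spectrum,
    background: Spectrum | None = None,
    background_scale: float = 1.0,
    smooth_enabled: bool = False,
    smooth_window: int = 9,
    smooth_polyorder: int = 3,
    baseline_method: str = "asls",
    baseline_lam: float = 1e8,
    baseline_p: float = 0.01,
    baseline_max_iter: int = 50,
    baseline_degree: int = 3,
) -> PreprocessResult:
    """Run the full chain background -> (smoothing) -> baseline in fixed order.

    Smoothing is off by default: the linear-combination fit itself averages
    channel noise, and smoothing before fitting correlates it.
    """
    log: list = []
    current = spectrum
    bg_used = None
    if background is not None:
        current = subtract_background(current, background, background_scale)
        bg_used = background.with_intensities(background_scale * background.intensities)
        log.append(("subtract_background", {"scale": background_scale}))
    if smooth_enabled:
        current = smooth(current, smooth_window, smooth_polyorder)
        log.append(("smooth", {"window": smooth_window, "polyorder": smooth_polyorder}))
    corrected, baseline = correct_baseline(
        current,
        method=baseline_method,
        lam=baseline_lam,
        p=baseline_p,
        max_iter=baseline_max_iter,
        degree=baseline_degree,
    )
    log.append(
        (
            "correct_baseline",
            {"method": baseline_method, "lam": baseline_lam, "p": baseline_p}
            if baseline_method == "asls"
            else {"method": baseline_method, "degree": baseline_degree},
        )
    )
    return PreprocessResult(
        processed=corrected, baseline=baseline, background=bg_used, log=log
    )


class AslsBaseline(TransformerMixin, BaseEstimator):
    """Asymmetric-least-squares baseline removal as a sklearn transformer.

    Operates row-wise on a 2-D array of intensity traces; ``transform``
    returns the baseline-corrected traces.  The estimated baselines of the
    last ``transform`` call are stored on ``baselines_``.

    Parameters
    ----------
    lam : float, default 1e8
        Second-difference roughness penalty; larger means stiffer baseline.
    p : float, default 0.01
        Asymmetry: weight of points above the baseline (peaks).
    max_iter : int, default 50
        Maximum reweighting iterations.
    tol : float, default 1e-6
        Convergence threshold on the maximum weight change.
    """

    def __init__(self, lam: float = 1e8, p: float = 0.01, max_iter: int = 50,
                 tol: float = 1e-6):
        self.lam = lam
        self.p = p
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        baselines = np.vstack(
            [
                asls_baseline(row, lam=self.lam, p=self.p,
                              max_iter=self.max_iter, tol=self.tol)
                for row in X
            ]
        )
        self.baselines_ = baselines
        return X - baselines
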