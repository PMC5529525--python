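"""Biomolecular component analysis: the linear-combination decomposition engine.

A preprocessed organelle spectrum S(nu) is modelled as a non-negative
weighted sum of calibrated reference profiles plus a low-order residual
polynomial, with an optional global wavenumber shift as the nonlinear
nuisance parameter:

    S(nu) ~= sum_i c_i R_i(nu - delta) + P(nu),   c_i >= 0

The inner problem at fixed shift delta is a bounded linear least squares
(non-negative component weights, unconstrained polynomial coefficients),
solved exactly by an active-set method; delta is found by a bounded 1-D
search over the inner optimum.  Weights c_i convert to absolute
concentrations through each component's unit concentration (weight 1.0 =
100 mg/ml protein, 20 mg/ml RNA/DNA/lipid).

The engine is a scikit-learn style estimator (:class:`BCADecomposer`):
``fit`` binds the component library, ``transform`` maps a matrix of spectra
to a matrix of weights, and :meth:`BCADecomposer.decompose` returns the full
per-spectrum diagnostics.  :func:`fit_lcm` is the functional wrapper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear, minimize_scalar
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .calibration import weights_to_concentrations
from .spectra import ComponentLibrary, Spectrum

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitOptions:
    """Settings of the linear-combination fit.

    Attributes
    ----------
    nonneg : bool
        Constrain component weights to be >= 0 (physical concentrations).
    residual_poly_degree : int
        Degree of the in-fit residual polynomial absorbing leftover
        baseline; -1 disables it.
    allow_shift : bool
        Fit a global wavenumber shift delta (the nonlinear parameter).
    shift_bounds : float
        Half-width of the shift search interval in cm^-1.
    detection_threshold : float
        Minimum spectral weight for a component to be flagged detected.
    """

    nonneg: bool = True
    residual_poly_degree: int = 3
    allow_shift: bool = True
    shift_bounds: float = 3.0
    detection_threshold: float = 0.1
    max_iter: int = 200
    tol: float = 1e-12

    def __post_init__(self):
        if self.shift_bounds < 0:
            raise ValueError("shift_bounds must be >= 0")
        if self.detection_threshold < 0:
            raise ValueError("detection_threshold must be >= 0")
        if self.residual_poly_degree < -1:
            raise ValueError("residual_poly_degree must be >= -1")


@dataclass(frozen=True)
class BCAResult:
    """Decomposition of one spectrum into biomolecular components."""

    weights: dict[str, float]
    concentrations: dict[str, float]
    weight_sd: dict[str, float]
    shift: float
    fitted: Spectrum
    residual: Spectrum
    residual_poly: np.ndarray
    detected: dict[str, bool]
    r_squared: float
    rms_residual: float
    options: FitOptions = field(default=FitOptions())


class CollinearLibraryError(ValueError):
    """Design matrix numerically singular for this spectrum/library pair."""


def _poly_columns(grid: np.ndarray, degree: int) -> np.ndarray:
    """Chebyshev-like polynomial columns on the grid, conditioned to [-1, 1]."""
    if degree < 0:
        return np.empty((grid.size, 0))
    x = 2.0 * (grid - grid[0]) / (grid[-1] - grid[0]) - 1.0
    return np.vander(x, degree + 1, increasing=True)


def _shifted_components(library: ComponentLibrary, delta: float) -> np.ndarray:
    """Component references evaluated at nu - delta (edge-clamped)."""
    grid = library.grid
    if delta == 0.0:
        return library.matrix()
    return np.column_stack(
        [
            np.interp(grid - delta, grid, c.reference.intensities)
            for c in library.components
        ]
    )


def _solve_inner(
    y: np.ndarray,
    comps: np.ndarray,
    poly: np.ndarray,
    row_weights: np.ndarray | None,
    nonneg: bool,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Bounded linear least squares at fixed shift.

    Returns (component weights, poly coefficients, weighted SSE, full design).
    """
    A = np.hstack([comps, poly])
    b = y
    if row_weights is not None:
        A = A * row_weights[:, None]
        b = y * row_weights
    k_comp = comps.shape[1]
    k_poly = poly.shape[1]
    lower = np.concatenate(
        [np.zeros(k_comp) if nonneg else np.full(k_comp, -np.inf),
         np.full(k_poly, -np.inf)]
    )
    upper = np.full(k_comp + k_poly, np.inf)
    try:
        res = lsq_linear(
            A, b, bounds=(lower, upper), method="bvls", tol=tol,
            max_iter=max(max_iter, 3 * A.shape[1]),
        )
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
        raise CollinearLibraryError(str(exc)) from exc
    x = res.x
    sse = float(res.cost * 2.0)
    return x[:k_comp], x[k_comp:], sse, A


def _weight_sd(
    A: np.ndarray, b: np.ndarray, x: np.ndarray, k_comp: int, sse: float
) -> np.ndarray:
    """Per-component SD from the active-set covariance sigma^2 (X'X)^-1.

    Components pinned at the zero bound get SD 0 (no local curvature
    information for them); polynomial columns are always active.
    """
    n = A.shape[0]
    active = list(np.flatnonzero(x[:k_comp] > 0)) + list(range(k_comp, A.shape[1]))
    k = len(active)
    sd = np.zeros(k_comp)
    if n <= k or not active:
        return sd
    Xa = A[:, active]
    sigma2 = sse / (n - k)
    try:
        cov = sigma2 * np.linalg.inv(Xa.T @ Xa)
    except np.linalg.LinAlgError:
        return sd
    for idx, col in enumerate(active):
        if col < k_comp:
            sd[col] = np.sqrt(max(cov[idx, idx], 0.0))
    return sd


class BCADecomposer(TransformerMixin, BaseEstimator):
    """Decompose Raman spectra into calibrated biomolecular component weights.

    Scikit-learn estimator over a fixed component library: ``transform`` maps
    an (n_spectra, n_channels) intensity matrix on the library grid to an
    (n_spectra, n_components) weight matrix.  Full per-spectrum diagnostics
    (concentrations, shift, residual, detection flags) come from
    :meth:`decompose`.

    Parameters
    ----------
    library : ComponentLibrary
        Calibrated reference profiles on a common wavenumber grid.
    nonneg : bool, default True
        Constrain weights to >= 0.
    residual_poly_degree : int, default 3
        Degree of the in-fit residual polynomial (-1 disables).
    allow_shift : bool, default True
        Fit a global wavenumber shift within ``+-shift_bounds`` cm^-1.
    shift_bounds : float, default 3.0
    detection_threshold : float, default 0.1
        Weight below which a component is flagged as not reliably detected.

    Attributes
    ----------
    components_ : ndarray of shape (n_components, n_channels)
        The library reference profiles.
    analytes_ : tuple of str
        Component names in column order of ``transform`` output.
    """

    def __init__(
        self,
        library: ComponentLibrary | None = None,
        nonneg: bool = True,
        residual_poly_degree: int = 3,
        allow_shift: bool = True,
        shift_bounds: float = 3.0,
        detection_threshold: float = 0.1,
        max_iter: int = 200,
        tol: float = 1e-12,
    ):
        self.library = library
        self.nonneg = nonneg
        self.residual_poly_degree = residual_poly_degree
        self.allow_shift = allow_shift
        self.shift_bounds = shift_bounds
        self.detection_threshold = detection_threshold
        self.max_iter = max_iter
        self.tol = tol

    # -- sklearn plumbing ---------------------------------------------------

    def _options(self) -> FitOptions:
        return FitOptions(
            nonneg=self.nonneg,
            residual_poly_degree=self.residual_poly_degree,
            allow_shift=self.allow_shift,
            shift_bounds=self.shift_bounds,
            detection_threshold=self.detection_threshold,
            max_iter=self.max_iter,
            tol=self.tol,
        )

    def fit(self, X=None, y=None):
        """Bind the component library; X (spectra) only checks channel count."""
        if self.library is None:
            raise ValueError("BCADecomposer requires a ComponentLibrary")
        self._options()  # validates parameter ranges
        self.components_ = self.library.matrix().T
        self.analytes_ = self.library.names
        self.n_features_in_ = self.components_.shape[1]
        if X is not None:
            X = check_array(X)
            if X.shape[1] != self.n_features_in_:
                raise ValueError(
                    f"spectra have {X.shape[1]} channels, library grid has "
                    f"{self.n_features_in_}"
                )
        return self

    def transform(self, X) -> np.ndarray:
        """Weights for each spectrum row; shape (n_spectra, n_components)."""
        check_is_fitted(self)
        X = check_array(X)
        grid = self.library.grid
        out = np.empty((X.shape[0], len(self.analytes_)))
        for i, row in enumerate(X):
            res = self.decompose(Spectrum(grid, row))
            out[i] = [res.weights[a] for a in self.analytes_]
        return out

    # -- the decomposition --------------------------------------------------

    def decompose(
        self, spectrum: Spectrum, per_channel_sd: np.ndarray | None = None
    ) -> BCAResult:
        """Full decomposition of one preprocessed spectrum.

        ``per_channel_sd``, when given (e.g. from replicate averaging),
        weights channels by 1/sd; zero SDs fall back to the unweighted fit.
        """
        if not hasattr(self, "components_"):
            self.fit()
        lib = self.library
        opts = self._options()
        grid = lib.grid
        y = np.asarray(spectrum.intensities, dtype=float)
        if y.shape != grid.shape or not np.allclose(spectrum.wavenumbers, grid):
            raise ValueError("spectrum is not on the library grid; resample first")

        row_weights = None
        if per_channel_sd is not None:
            sd = np.asarray(per_channel_sd, dtype=float)
            if sd.shape != y.shape:
                raise ValueError("per_channel_sd length mismatch")
            if np.all(sd > 0):
                row_weights = 1.0 / sd

        poly = _poly_columns(grid, opts.residual_poly_degree)
        k_comp = len(lib)

        def inner(delta: float):
            comps = _shifted_components(lib, delta)
            return _solve_inner(
                y, comps, poly, row_weights, opts.nonneg, opts.tol, opts.max_iter
            )

        if opts.allow_shift and opts.shift_bounds > 0:
            b = opts.shift_bounds
            coarse = np.linspace(-b, b, max(int(round(2 * b / 0.25)) + 1, 5))
            sses = [inner(d)[2] for d in coarse]
            i0 = int(np.argmin(sses))
            lo = coarse[max(i0 - 1, 0)]
            hi = coarse[min(i0 + 1, len(coarse) - 1)]
            res1d = minimize_scalar(
                lambda d: inner(d)[2], bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-4},
            )
            shift = float(np.clip(res1d.x, -b, b))
            if inner(shift)[2] > sses[i0]:
                shift = float(coarse[i0])
        else:
            shift = 0.0

        comps = _shifted_components(lib, shift)
        c, pcoef, sse, A = inner(shift)
        model = comps @ c + poly @ pcoef
        residual = y - model
        b_w = y if row_weights is None else y * row_weights
        x_full = np.concatenate([c, pcoef])
        sd = _weight_sd(A, b_w, x_full, k_comp, sse)

        tss = float(np.sum((y - y.mean()) ** 2))
        rss = float(np.sum(residual**2))
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        weights = {name: float(w) for name, w in zip(lib.names, c)}
        detected = {
            name: w >= opts.detection_threshold for name, w in weights.items()
        }
        return BCAResult(
            weights=weights,
            concentrations=weights_to_concentrations(weights, lib),
            weight_sd={name: float(s) for name, s in zip(lib.names, sd)},
            shift=shift,
            fitted=spectrum.with_intensities(model),
            residual=spectrum.with_intensities(residual),
            residual_poly=pcoef,
            detected=detected,
            r_squared=r2,
            rms_residual=float(np.sqrt(rss / y.size)),
            options=opts,
        )


def fit_lcm(
    spectrum: Spectrum,
    library: ComponentLibrary,
    options: FitOptions | None = None,
    per_channel_sd: np.ndarray | None = None,
) -> BCAResult:
    """Fit one spectrum as a non-negative linear combination of library components."""
    opts = options or FitOptions()
    dec = BCADecomposer(
        library=library,
        nonneg=opts.nonneg,
        residual_poly_degree=opts.residual_poly_degree,
        allow_shift=opts.allow_shift,
        shift_bounds=opts.shift_bounds,
        detection_threshold=opts.detection_threshold,
        max_iter=opts.max_iter,
        tol=opts.tol,
    ).fit()
    return dec.decompose(spectrum, per_channel_sd=per_channel_sd)


def apply_detection_threshold(result: BCAResult, threshold: float) -> BCAResult:
    """Recompute detection flags at a new threshold; weights are never zeroed.

    Sub-threshold components stay in the result as trace contributions that
    are reported but marked unreliable.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    detected = {a: w >= threshold for a, w in result.weights.items()}
    return replace(
        result,
        detected=detected,
        options=replace(result.options, detection_threshold=threshold),
    )


REQUIRED_META = ("cell_id", "cell_line", "organelle")


def batch_fit(
    spectra: Sequence[Spectrum],
    library: ComponentLibrary,
    options: FitOptions | None = None,
) -> pd.DataFrame:
    """Fit a collection of spectra into a tidy organelle-profile table.

    Returns one row per (spectrum, analyte) with columns cell_line, cell_id,
    organelle, analyte, weight, weight_sd, concentration_mgml, detected,
    r_squared, ordered by (cell_line, cell_id, organelle, analyte order in
    library).  Spectra lacking cell_id/cell_line/organelle metadata are
    skipped with a warning and counted in ``df.attrs['n_skipped']``.
    """
    opts = options or FitOptions()
    rows = []
    n_skipped = 0
    for spec in spectra:
        missing = [k for k in REQUIRED_META if spec.meta.get(k) in (None, "")]
        if missing:
            logger.warning("skipping spectrum lacking metadata: %s", missing)
            n_skipped += 1
            continue
        res = fit_lcm(spec, library, opts)
        for analyte in library.names:
            rows.append(
                {
                    "cell_line": spec.meta["cell_line"],
                    "cell_id": spec.meta["cell_id"],
                    "organelle": spec.meta["organelle"],
                    "analyte": analyte,
                    "weight": res.weights[analyte],
                    "weight_sd": res.weight_sd[analyte],
                    "concentration_mgml": res.concentrations[analyte],
                    "detected": res.detected[analyte],
                    "r_squared": res.r_squared,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "cell_line", "cell_id", "organelle", "analyte", "weight",
            "weight_sd", "concentration_mgml", "detected", "r_squared",
        ],
    )
    if len(df):
        analyte_order = {a: i for i, a in enumerate(library.names)}
        df = (
            df.assign(_a=df["analyte"].map(analyte_order))
            .sort_values(["cell_line", "cell_id", "organelle", "_a"],
                         kind="stable")
            .drop(columns="_a")
            .reset_index(drop=True)
        )
    df.attrs["n_skipped"] = n_skipped
    if n_skipped:
        logger.warning("batch_fit skipped %d spectra with missing metadata", n_skipped)
    return df
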