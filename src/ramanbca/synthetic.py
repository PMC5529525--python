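"""Synthetic fixtures with known ground truth.

Everything the pipeline consumes can be generated here: reference component
profiles built from canonical Raman band positions, organelle spectra
(weighted component sums plus a broad fluorescence baseline and channel
noise), cell populations with a specified concentration mean/covariance
structure, and ~1 h time-lapse series with tunable oscillation frequency.
Every generator returns its ground truth alongside the data, and all
randomness flows through one seeded :class:`numpy.random.Generator`.

Default population parameters emulate published single-organelle
concentration ranges (e.g. nucleolar protein roughly 50-120 mg/ml, RNA
10-45 mg/ml) by setting the mean at the range midpoint with +-2 SD spanning
the range; within-organelle protein-RNA correlation defaults to ~0.8 for
nucleolus and ER and ~0.3 for mitochondria, with strong cross-organelle
coupling in the fibroblast-like line and near-zero coupling in the
transformed line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import DEFAULT_UNIT_CONCENTRATIONS
from .dynamics import TimeSeries
from .spectra import ComponentLibrary, ComponentProfile, Spectrum, default_grid


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# peak shapes and component profiles


@dataclass(frozen=True)
class PeakSpec:
    """One Raman band: position, width, height and line shape."""

    center: float  # cm^-1
    fwhm: float  # cm^-1
    amplitude: float = 1.0
    shape: str = "lorentzian"  # gaussian | lorentzian | pseudo_voigt
    eta: float = 0.5  # Lorentzian fraction for pseudo_voigt

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must be in [0, 1]")
        if self.shape not in ("gaussian", "lorentzian", "pseudo_voigt"):
            raise ValueError(f"unknown shape {self.shape!r}")

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        x = np.asarray(grid, dtype=float) - self.center
        hw = self.fwhm / 2.0
        lor = hw**2 / (x**2 + hw**2)
        gau = np.exp(-4.0 * np.log(2.0) * (x / self.fwhm) ** 2)
        if self.shape == "gaussian":
            prof = gau
        elif self.shape == "lorentzian":
            prof = lor
        else:
            prof = self.eta * lor + (1.0 - self.eta) * gau
        return self.amplitude * prof


def make_component_profile(
    name: str,
    peaks: Sequence[PeakSpec],
    grid: np.ndarray | None = None,
    unit_concentration: float | None = None,
) -> ComponentProfile:
    """Deterministic reference profile: max-normalized sum of band shapes."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    for pk in peaks:
        if not (grid[0] <= pk.center <= grid[-1]):
            raise ValueError(
                f"peak at {pk.center:g} cm^-1 outside grid "
                f"[{grid[0]:g}, {grid[-1]:g}]"
            )
    y = np.zeros_like(grid)
    for pk in peaks:
        y = y + pk.evaluate(grid)
    peak_max = y.max()
    if peak_max > 0:
        y = y / peak_max
    if unit_concentration is None:
        unit_concentration = DEFAULT_UNIT_CONCENTRATIONS.get(name, 100.0)
    return ComponentProfile(
        name=name, reference=Spectrum(grid, y), unit_concentration=unit_concentration
    )


#: canonical band positions (cm^-1) used for the default synthetic library;
#: approximate textbook assignments (phenylalanine ring breathing 1003,
#: CH2 deformations ~1440-1450, amide I ~1660, nucleic-acid ring/backbone
#: modes 785/811/1094/1100/1375/1480/1575, lipid C-C/C=O 1063/1301/1745)
DEFAULT_PEAKS: dict[str, tuple[PeakSpec, ...]] = {
    "protein": (
        PeakSpec(1003, 12, 1.0),
        PeakSpec(1250, 45, 0.45),
        PeakSpec(1450, 30, 0.65),
        PeakSpec(1660, 38, 0.9),
    ),
    "RNA": (
        PeakSpec(785, 18, 0.9),
        PeakSpec(811, 16, 0.6),
        PeakSpec(1100, 25, 0.5),
        PeakSpec(1240, 30, 0.45),
        PeakSpec(1480, 22, 0.7),
        PeakSpec(1575, 20, 0.8),
    ),
    "DNA": (
        PeakSpec(785, 16, 0.8),
        PeakSpec(1094, 20, 1.0),
        PeakSpec(1375, 22, 0.5),
        PeakSpec(1578, 18, 0.6),
    ),
    "lipid": (
        PeakSpec(1063, 16, 0.7),
        PeakSpec(1301, 20, 0.85),
        PeakSpec(1440, 24, 1.0),
        PeakSpec(1745, 20, 0.45),
    ),
}


def default_library(grid: np.ndarray | None = None) -> ComponentLibrary:
    """The four-component synthetic reference library (protein, RNA, DNA, lipid)."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    comps = tuple(
        make_component_profile(name, peaks, grid)
        for name, peaks in DEFAULT_PEAKS.items()
    )
    return ComponentLibrary(comps, provenance="synthetic canonical-band library")


# ---------------------------------------------------------------------------
# spectra


def fluorescence_baseline(
    grid: np.ndarray,
    amplitude: float,
    center: float = 1100.0,
    width: float = 700.0,
) -> np.ndarray:
    """Broad Gaussian autofluorescence background."""
    return amplitude * np.exp(-0.5 * ((grid - center) / width) ** 2)


def simulate_spectrum(
    library: ComponentLibrary,
    weights: Mapping[str, float],
    baseline_amplitude: float = 0.0,
    baseline_center: float = 1100.0,
    baseline_width: float = 700.0,
    noise_sd: float = 0.0,
    shift: float = 0.0,
    seed=0,
    noise_model: str = "gaussian",
    meta: Mapping | None = None,
) -> tuple[Spectrum, dict]:
    """Forward model: S = sum_i c_i R_i(nu - shift) + B(nu) + noise.

    Returns the spectrum and a truth record (weights, baseline parameters,
    shift, noise_sd, seed).  The same seed reproduces the spectrum bit for
    bit.  ``noise_model`` is ``gaussian`` (additive, CCD read + shot
    approximation) or ``poisson`` (intensities treated as counts scaled so
    the noise SD at the mean signal matches ``noise_sd``).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be >= 0")
    rng = _rng(seed)
    grid = library.grid
    clean = np.zeros_like(grid)
    for name, w in weights.items():
        ref = library[name].reference.intensities
        shifted = np.interp(grid - shift, grid, ref) if shift else ref
        clean = clean + w * shifted
    base = fluorescence_baseline(grid, baseline_amplitude, baseline_center,
                                 baseline_width)
    signal = clean + base
    if noise_sd > 0:
        if noise_model == "gaussian":
            noisy = signal + rng.normal(0.0, noise_sd, size=grid.size)
        elif noise_model == "poisson":
            level = max(float(np.mean(signal)), 1e-12)
            gain = level / noise_sd**2  # counts per intensity unit
            noisy = rng.poisson(np.clip(signal, 0, None) * gain) / gain
        else:
            raise ValueError(f"unknown noise_model {noise_model!r}")
    else:
        noisy = signal.copy()
    truth = {
        "weights": dict(weights),
        "baseline": {
            "amplitude": baseline_amplitude,
            "center": baseline_center,
            "width": baseline_width,
        },
        "shift": shift,
        "noise_sd": noise_sd,
        "noise_model": noise_model,
    }
    return Spectrum(grid, noisy, dict(meta or {})), truth


# ---------------------------------------------------------------------------
# populations


@dataclass(frozen=True)
class PopulationSpec:
    """A cell population's concentration structure.

    ``labels`` enumerates the (organelle, analyte) variables; ``mu`` is the
    mean concentration vector (mg/ml) and ``cov`` the covariance across all
    variables, so both within-organelle and cross-organelle correlations are
    expressible.
    """

    n_cells: int
    cell_line: str
    labels: tuple[tuple[str, str], ...]  # (organelle, analyte)
    mu: np.ndarray  # mg/ml
    cov: np.ndarray
    distribution: str = "truncated_normal"  # or lognormal
    min_concentration: float = 1.0  # truncation floor, mg/ml

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        k = len(self.labels)
        if mu.shape != (k,) or cov.shape != (k, k):
            raise ValueError("mu/cov shapes must match labels")
        if self.n_cells < 3:
            raise ValueError("n_cells must be >= 3")
        if np.any(mu <= 0):
            raise ValueError("mean concentrations must be > 0")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-8 * max(eigvals.max(), 1.0):
            raise ValueError(
                f"covariance not positive semidefinite: eigenvalue {eigvals.min():.4g}"
            )
        if self.distribution not in ("truncated_normal", "lognormal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "cov", cov)


#: per-organelle (mean, SD) defaults in mg/ml, midpoint +-2 SD spanning the
#: published single-cell ranges
DEFAULT_CONCENTRATIONS: dict[str, dict[str, tuple[float, float]]] = {
    "nucleolus": {"protein": (85.0, 17.5), "RNA": (27.5, 8.75), "lipid": (22.5, 6.25)},
    "ER": {"protein": (70.0, 25.0), "RNA": (12.5, 3.75), "lipid": (32.5, 13.75)},
    "mitochondrion": {"protein": (72.5, 18.75), "RNA": (12.5, 3.75), "lipid": (21.5, 9.25)},
}


def build_population_spec(
    n_cells: int,
    cell_line: str = "HeLa",
    organelles: Sequence[str] = ("nucleolus", "ER", "mitochondrion"),
    analytes: Sequence[str] = ("protein", "RNA", "lipid"),
    correlations: Mapping[tuple[tuple[str, str], tuple[str, str]], float] | None = None,
    distribution: str = "truncated_normal",
) -> PopulationSpec:
    """Assemble a PopulationSpec from per-variable (mean, SD) defaults.

    ``correlations`` maps unordered ((organelle, analyte), (organelle,
    analyte)) pairs to Pearson r; unspecified pairs default to 0.
    """
    labels = tuple((o, a) for o in organelles for a in analytes)
    k = len(labels)
    mu = np.empty(k)
    sd = np.empty(k)
    for i, (o, a) in enumerate(labels):
        m, s = DEFAULT_CONCENTRATIONS[o][a]
        mu[i], sd[i] = m, s
    corr = np.eye(k)
    if correlations:
        idx = {lab: i for i, lab in enumerate(labels)}
        for (la, lb), r in correlations.items():
            i, j = idx[la], idx[lb]
            corr[i, j] = corr[j, i] = r
    if np.linalg.eigvalsh(corr).min() < 0:
        # pairwise targets need not be jointly consistent; use the nearest
        # valid correlation matrix and tell the user
        from statsmodels.stats.correlation_tools import corr_nearest
        from statsmodels.tools.sm_exceptions import IterationLimitWarning

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IterationLimitWarning)
            nearest = corr_nearest(corr, threshold=1e-8, n_fact=1000)
        if np.linalg.eigvalsh(nearest).min() < -1e-10:  # pragma: no cover
            raise ValueError("nearest-correlation projection failed")
        shift = float(np.max(np.abs(nearest - corr)))
        warnings.warn(
            f"requested correlations are not jointly positive semidefinite; "
            f"projected to the nearest valid matrix (max entry change {shift:.3f})"
        )
        corr = nearest
    cov = corr * np.outer(sd, sd)
    return PopulationSpec(
        n_cells=n_cells, cell_line=cell_line, labels=labels, mu=mu, cov=cov,
        distribution=distribution,
    )


#: within- and cross-organelle correlation presets emulating the two studied
#: phenotypes: a primary fibroblast-like line with strongly coupled
#: nucleolus/ER content, and a transformed line where the coupling is lost
CELL_LINE_CORRELATIONS: dict[str, dict] = {
    "WI-38": {
        (("nucleolus", "protein"), ("nucleolus", "RNA")): 0.80,
        (("ER", "protein"), ("ER", "RNA")): 0.80,
        (("mitochondrion", "protein"), ("mitochondrion", "RNA")): 0.25,
        (("nucleolus", "protein"), ("ER", "protein")): 0.75,
        (("nucleolus", "protein"), ("ER", "RNA")): 0.70,
        (("nucleolus", "RNA"), ("ER", "protein")): 0.70,
        (("nucleolus", "RNA"), ("ER", "RNA")): 0.50,
        (("nucleolus", "protein"), ("mitochondrion", "protein")): 0.60,
        (("nucleolus", "RNA"), ("mitochondrion", "RNA")): 0.40,
    },
    "HeLa": {
        (("nucleolus", "protein"), ("nucleolus", "RNA")): 0.80,
        (("ER", "protein"), ("ER", "RNA")): 0.80,
        (("mitochondrion", "protein"), ("mitochondrion", "RNA")): 0.35,
        (("nucleolus", "protein"), ("ER", "protein")): 0.15,
        (("nucleolus", "protein"), ("ER", "RNA")): 0.10,
        (("nucleolus", "RNA"), ("ER", "RNA")): 0.10,
        (("nucleolus", "protein"), ("mitochondrion", "protein")): 0.30,
        (("nucleolus", "RNA"), ("mitochondrion", "RNA")): 0.15,
    },
}


def default_population_spec(cell_line: str, n_cells: int = 100) -> PopulationSpec:
    """Preset population for one of the two emulated cell lines."""
    if cell_line not in CELL_LINE_CORRELATIONS:
        raise KeyError(f"no preset for cell line {cell_line!r}")
    return build_population_spec(
        n_cells=n_cells, cell_line=cell_line,
        correlations=CELL_LINE_CORRELATIONS[cell_line],
    )


def simulate_population(spec: PopulationSpec, seed=0) -> pd.DataFrame:
    """Draw per-cell concentration vectors; tidy long-format profile table.

    Returns one row per (cell, organelle, analyte) with columns cell_line,
    cell_id, organelle, analyte, concentration_mgml, weight.  The sample
    correlation matrix converges to the spec's as n grows; all
    concentrations are positive (truncation floor or lognormal draw).
    """
    rng = _rng(seed)
    k = len(spec.labels)
    if spec.distribution == "truncated_normal":
        draws = np.empty((spec.n_cells, k))
        filled = 0
        attempts = 0
        while filled < spec.n_cells and attempts < 100:
            need = spec.n_cells - filled
            cand = rng.multivariate_normal(spec.mu, spec.cov, size=need,
                                           method="cholesky")
            ok = np.all(cand >= spec.min_concentration, axis=1)
            n_ok = int(ok.sum())
            draws[filled:filled + n_ok] = cand[ok]
            filled += n_ok
            attempts += 1
        if filled < spec.n_cells:  # pathological spec: clip the remainder
            cand = rng.multivariate_normal(spec.mu, spec.cov,
                                           size=spec.n_cells - filled,
                                           method="cholesky")
            draws[filled:] = np.clip(cand, spec.min_concentration, None)
    else:  # lognormal with matched mean and covariance (moment transform)
        cv2 = np.diag(spec.cov) / spec.mu**2
        sigma2 = np.log1p(cv2)
        mu_log = np.log(spec.mu) - sigma2 / 2.0
        corr = spec.cov / np.sqrt(np.outer(np.diag(spec.cov), np.diag(spec.cov)))
        cov_log = np.log1p(corr * np.sqrt(np.outer(cv2, cv2)))
        z = rng.multivariate_normal(mu_log, cov_log, size=spec.n_cells,
                                    method="cholesky")
        draws = np.exp(z)

    rows = []
    width = len(str(spec.n_cells))
    for c in range(spec.n_cells):
        cell_id = f"{spec.cell_line}-{c + 1:0{width}d}"
        for j, (organelle, analyte) in enumerate(spec.labels):
            conc = float(draws[c, j])
            unit = DEFAULT_UNIT_CONCENTRATIONS.get(analyte, 100.0)
            rows.append(
                {
                    "cell_line": spec.cell_line,
                    "cell_id": cell_id,
                    "organelle": organelle,
                    "analyte": analyte,
                    "concentration_mgml": conc,
                    "weight": conc / unit,
                }
            )
    return pd.DataFrame(rows)


def population_spectra(
    profiles: pd.DataFrame,
    library: ComponentLibrary,
    baseline_amplitude: float = 0.5,
    noise_sd: float = 0.0,
    seed=0,
) -> list[tuple[Spectrum, dict]]:
    """Render each (cell, organelle) profile row-set as a full spectrum."""
    rng = _rng(seed)
    out = []
    for (cell_line, cell_id, organelle), grp in profiles.groupby(
        ["cell_line", "cell_id", "organelle"], sort=True
    ):
        weights = {
            row.analyte: row.concentration_mgml / library[row.analyte].unit_concentration
            for row in grp.itertuples()
        }
        spec, truth = simulate_spectrum(
            library,
            weights,
            baseline_amplitude=baseline_amplitude,
            noise_sd=noise_sd,
            seed=rng,
            meta={"cell_line": cell_line, "cell_id": cell_id, "organelle": organelle},
        )
        out.append((spec, truth))
    return out


# ---------------------------------------------------------------------------
# time series


@dataclass(frozen=True)
class TimeSeriesSpec:
    """A sinusoid-plus-noise concentration trajectory.

    ``frequency`` is in cycles per hour; sampling covers ``duration_min``
    at ``interval_min`` spacing (inclusive endpoints), matching ~1 h
    time-lapse sessions at ~10 min intervals.
    """

    baseline_level: float  # mg/ml
    amplitude: float  # mg/ml
    frequency: float  # cycles / hour
    noise_sd: float = 0.0  # mg/ml
    duration_min: float = 60.0
    interval_min: float = 10.0
    analyte: str = "RNA"
    organelle: str = "nucleolus"

    def __post_init__(self):
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be >= 0")
        if self.interval_min > self.duration_min:
            raise ValueError("interval must not exceed duration")


def simulate_timeseries(
    spec: TimeSeriesSpec,
    seed=0,
    cell_id: str = "",
    cell_line: str = "",
    phase: float | None = None,
) -> tuple[TimeSeries, dict]:
    """c(t) = level + amplitude sin(2 pi f t + phi) + noise, phi seeded.

    Returns the series and its truth record; identical seeds give identical
    series bit for bit.
    """
    rng = _rng(seed)
    phi = float(rng.uniform(0, 2 * np.pi)) if phase is None else float(phase)
    n = int(np.floor(spec.duration_min / spec.interval_min + 1e-9)) + 1
    t = spec.interval_min * np.arange(n)
    clean = spec.baseline_level + spec.amplitude * np.sin(
        2 * np.pi * spec.frequency * t / 60.0 + phi
    )
    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else np.zeros(n)
    values = clean + noise
    series = TimeSeries(
        times=t, values=values,
        sds=np.full(n, spec.noise_sd) if spec.noise_sd > 0 else None,
        cell_id=cell_id, cell_line=cell_line,
        organelle=spec.organelle, analyte=spec.analyte,
    )
    truth = {
        "baseline_level": spec.baseline_level,
        "amplitude": spec.amplitude,
        "frequency_cph": spec.frequency,
        "phase": phi,
        "noise_sd": spec.noise_sd,
    }
    return series, truth
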