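"""Population-level statistics of single-organelle concentration profiles.

Input is the tidy long-format profile table produced by ``batch_fit`` or
``simulate_population``: one row per (cell, organelle, analyte) with a
concentration in mg/ml.  The module provides per-group summaries,
within-organelle and cross-organelle Pearson correlations (paired strictly
by cell), one-way ANOVA between cell lines, and a full correlation matrix
with Benjamini-Hochberg adjusted significance flags.

Pearson r is identical on weights and on mg/ml (the unit conversion is a
positive scaling), so correlations are computed on concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .spectra import ORGANELLES

PROFILE_COLUMNS = ("cell_line", "cell_id", "organelle", "analyte", "concentration_mgml")


@dataclass(frozen=True)
class OrganelleProfile:
    """One cell x organelle record of analyte concentrations (mg/ml)."""

    cell_id: str
    cell_line: str
    organelle: str
    concentrations: dict[str, float]
    uncertainties: dict[str, float] | None = None
    source: str = ""

    def __post_init__(self):
        if self.organelle not in ORGANELLES:
            raise ValueError(f"unknown organelle {self.organelle!r}")
        if any(v < 0 for v in self.concentrations.values()):
            raise ValueError("concentrations must be >= 0")


def strength_label(r: float) -> str:
    """Verbal strength of a correlation coefficient.

    |r| < 0.3 weak, 0.3-0.5 moderate, 0.5-0.7 moderate-to-high, > 0.7 strong.
    """
    a = abs(r)
    if a < 0.3:
        return "weak"
    if a < 0.5:
        return "moderate"
    if a <= 0.7:
        return "moderate-to-high"
    return "strong"


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between two (organelle, analyte) variables."""

    pair: tuple[tuple[str, str], tuple[str, str]]
    r: float
    n: int
    ci95: tuple[float, float]
    p: float
    strength: str

    def __post_init__(self):
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"r out of range: {self.r}")
        if self.n < 3:
            raise ValueError("correlation needs n >= 3")


@dataclass(frozen=True)
class AnovaResult:
    """One-way fixed-effects ANOVA across cell lines."""

    analyte: str
    organelle: str
    groups: dict[str, int]  # label -> n
    F: float
    p: float
    alpha: float
    significant: bool


def _check_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PROFILE_COLUMNS if c not in profiles.columns]
    if missing:
        raise ValueError(f"profile table lacks columns {missing}")
    if profiles.empty:
        raise ValueError("empty profile table")
    return profiles


def summarize_profiles(
    profiles: pd.DataFrame,
    group_by: Sequence[str] = ("cell_line", "organelle"),
) -> pd.DataFrame:
    """Per-group n/mean/SD/min/max of concentration for each analyte.

    SD is the sample SD (ddof=1); a single-observation group reports SD 0
    and is flagged in the ``single_obs`` column.
    """
    profiles = _check_profiles(profiles)
    keys = list(group_by) + ["analyte"]
    g = profiles.groupby(keys, sort=True)["concentration_mgml"]
    out = g.agg(n="count", mean="mean", sd="std", min="min", max="max").reset_index()
    out["single_obs"] = out["n"] == 1
    out["sd"] = out["sd"].fillna(0.0)
    return out


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0:
        return (r, r)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    q = stats.norm.ppf(0.5 + level / 2.0)
    return (float(np.tanh(z - q * se)), float(np.tanh(z + q * se)))


def _pearson(x: np.ndarray, y: np.ndarray, pair) -> CorrelationResult:
    n = x.size
    if n < 3:
        raise ValueError(f"correlation {pair}: only {n} complete pairs (need >= 3)")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError(f"correlation {pair}: zero variance, r undefined")
    r, p = stats.pearsonr(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    return CorrelationResult(
        pair=pair, r=r, n=n, ci95=_fisher_ci(r, n), p=float(p),
        strength=strength_label(r),
    )


def _cell_vector(
    profiles: pd.DataFrame, organelle: str, analyte: str, occurrence: int = 0
) -> pd.Series:
    """Per-cell concentration of one (organelle, analyte), indexed by cell_id.

    ``occurrence`` selects among duplicated organelle records of the same
    cell (e.g. two mitochondria measured per cell) in acquisition (row)
    order.
    """
    sub = profiles[
        (profiles["organelle"] == organelle) & (profiles["analyte"] == analyte)
    ]
    picked = sub.groupby("cell_id", sort=True).nth(occurrence)
    return picked.set_index("cell_id")["concentration_mgml"]


def correlate_within(
    profiles: pd.DataFrame,
    organelle: str,
    analyte_pair: tuple[str, str],
    cell_line: str | None = None,
) -> CorrelationResult:
    """Pearson r between two analytes in the same organelle, paired by cell."""
    profiles = _check_profiles(profiles)
    if cell_line is not None:
        profiles = profiles[profiles["cell_line"] == cell_line]
    a, b = analyte_pair
    xa = _cell_vector(profiles, organelle, a)
    xb = _cell_vector(profiles, organelle, b)
    joined = pd.concat([xa.rename("a"), xb.rename("b")], axis=1, join="inner").dropna()
    pair = ((organelle, a), (organelle, b))
    return _pearson(joined["a"].to_numpy(), joined["b"].to_numpy(), pair)


def correlate_between(
    profiles: pd.DataFrame,
    organelle_a: str,
    analyte_a: str,
    organelle_b: str,
    analyte_b: str,
    cell_line: str | None = None,
    instances: tuple[int, int] | None = None,
) -> CorrelationResult:
    """Pearson r between variables of two organelles of the same cell.

    Pairing is strictly by cell_id.  ``instances`` selects among duplicated
    records of the same organelle per cell, in acquisition order; by default
    it is (0, 0), switching to (0, 1) when both ends name the *same*
    (organelle, analyte) variable — e.g. protein in two different
    mitochondria of one cell.
    """
    profiles = _check_profiles(profiles)
    if cell_line is not None:
        profiles = profiles[profiles["cell_line"] == cell_line]
    if instances is None:
        same_var = (organelle_a, analyte_a) == (organelle_b, analyte_b)
        instances = (0, 1) if same_var else (0, 0)
    xa = _cell_vector(profiles, organelle_a, analyte_a, occurrence=instances[0])
    xb = _cell_vector(profiles, organelle_b, analyte_b, occurrence=instances[1])
    joined = pd.concat([xa.rename("a"), xb.rename("b")], axis=1, join="inner").dropna()
    pair = ((organelle_a, analyte_a), (organelle_b, analyte_b))
    if len(joined) < 3:
        n_a, n_b = len(xa), len(xb)
        raise ValueError(
            f"correlation {pair}: only {len(joined)} cells have both organelles "
            f"({n_a} have {organelle_a}, {n_b} have {organelle_b}; need >= 3)"
        )
    return _pearson(joined["a"].to_numpy(), joined["b"].to_numpy(), pair)


def anova_between_lines(
    profiles: pd.DataFrame,
    organelle: str,
    analyte: str,
    alpha: float = 0.05,
) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA of concentration across cell lines."""
    profiles = _check_profiles(profiles)
    sub = profiles[
        (profiles["organelle"] == organelle) & (profiles["analyte"] == analyte)
    ]
    groups = {
        label: grp["concentration_mgml"].to_numpy()
        for label, grp in sub.groupby("cell_line", sort=True)
    }
    if len(groups) < 2:
        raise ValueError(f"ANOVA needs >= 2 cell lines, got {list(groups)}")
    for label, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {label!r} has n={vals.size} (need >= 2)")
    arrays = list(groups.values())
    grand = np.concatenate(arrays)
    ss_between = sum(a.size * (a.mean() - grand.mean()) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0.0 and ss_between == 0.0:
        F, p = 0.0, 1.0  # all observations identical
    elif ss_within == 0.0:
        F, p = np.inf, 0.0
    else:
        F, p = stats.f_oneway(*arrays)
        F, p = float(F), float(p)
    return AnovaResult(
        analyte=analyte,
        organelle=organelle,
        groups={k: int(v.size) for k, v in groups.items()},
        F=F,
        p=p,
        alpha=alpha,
        significant=bool(p < alpha),
    )


def correlation_matrix(
    profiles: pd.DataFrame,
    organelles: Sequence[str] | None = None,
    analytes: Sequence[str] | None = None,
    cell_line: str | None = None,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise correlations over the requested (organelle, analyte) scope.

    Returns a tidy table with one row per unordered variable pair, including
    diagonal self-pairs (r = 1 by definition), Fisher-z 95% CIs, raw p values
    and Benjamini-Hochberg adjusted flags (``significant_fdr``).  Adjusted
    flags are supplementary columns, never filters.  Pairs whose element
    computation fails (too few complete pairs, zero variance) are reported
    with the error message in the ``error`` column rather than aborting the
    matrix.
    """
    profiles = _check_profiles(profiles)
    if cell_line is not None:
        profiles = profiles[profiles["cell_line"] == cell_line]
    if organelles is None:
        organelles = sorted(profiles["organelle"].unique())
    if analytes is None:
        analytes = sorted(profiles["analyte"].unique())
    variables = [(o, a) for o in organelles for a in analytes]
    rows = []
    for i, va in enumerate(variables):
        for j in range(i, len(variables)):
            vb = variables[j]
            row = {
                "organelle_a": va[0], "analyte_a": va[1],
                "organelle_b": vb[0], "analyte_b": vb[1],
                "within_organelle": va[0] == vb[0],
                "diagonal": i == j,
            }
            if i == j:
                n = profiles[
                    (profiles["organelle"] == va[0]) & (profiles["analyte"] == va[1])
                ]["cell_id"].nunique()
                row.update(r=1.0, n=n, ci_lo=1.0, ci_hi=1.0, p=0.0,
                           strength="strong", error="")
            else:
                try:
                    res = correlate_between(profiles, va[0], va[1], vb[0], vb[1])
                    row.update(
                        r=res.r, n=res.n, ci_lo=res.ci95[0], ci_hi=res.ci95[1],
                        p=res.p, strength=res.strength, error="",
                    )
                except ValueError as exc:
                    row.update(r=np.nan, n=0, ci_lo=np.nan, ci_hi=np.nan,
                               p=np.nan, strength="", error=str(exc))
            rows.append(row)
    out = pd.DataFrame(rows)
    offdiag = (~out["diagonal"]) & out["p"].notna()
    out["significant_fdr"] = False
    if offdiag.any():
        rejected, _, _, _ = multipletests(
            out.loc[offdiag, "p"].to_numpy(), alpha=fdr_alpha, method="fdr_bh"
        )
        out.loc[offdiag, "significant_fdr"] = rejected
    return out
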