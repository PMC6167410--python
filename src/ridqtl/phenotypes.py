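"""Strain-level phenotype statistics for limited-access intake records.

Converts long-format animal-level intake records into the strain-averaged
traits the genome scans consume (weekly 2 h averages ``W1avg..W5avg``,
weekly 4 h sessions ``W1D4..W5D4``, the first exposure ``W1D1``), and
computes the descriptive statistics reported alongside them: one-way ANOVA
heritability (SS_strain/SS_total), per-strain 5-week escalation slopes and
intercepts, slope/intercept correlations, week-to-week trait correlations,
and quantile winsorization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ETHANOL_DENSITY_G_PER_ML

__all__ = [
    "AnovaResult",
    "intake_g_per_kg",
    "weekly_strain_means",
    "trait_series",
    "strain_anova",
    "fit_strain_slopes",
    "slope_trait_correlation",
    "winsorize",
    "week_correlation_matrix",
    "load_published_slope_table",
]

WEEKLY_2H_TRAITS = tuple(f"W{k}avg" for k in range(1, 6))
WEEKLY_4H_TRAITS = tuple(f"W{k}D4" for k in range(1, 6))


def intake_g_per_kg(
    volume_ml: float | np.ndarray,
    ethanol_vv: float,
    body_g: float | np.ndarray,
    density_g_per_ml: float = ETHANOL_DENSITY_G_PER_ML,
) -> float | np.ndarray:
    """Grams of ethanol consumed per kg body mass.

    ``volume_ml x ethanol_vv x density / (body_g / 1000)`` — e.g. 1 ml of
    20% (v/v) ethanol drunk by a 25 g mouse is 6.3144 g/kg.
    """
    if not 0.0 < ethanol_vv <= 1.0:
        raise ValueError("ethanol_vv must be in (0, 1]")
    if np.any(np.asarray(body_g) <= 0):
        raise ValueError("body mass must be positive")
    if np.any(np.asarray(volume_ml) < 0):
        raise ValueError("volume must be non-negative")
    return volume_ml * ethanol_vv * density_g_per_ml / (np.asarray(body_g) / 1000.0)


def weekly_strain_means(records: pd.DataFrame) -> pd.DataFrame:
    """Strain-averaged traits from long-format intake records.

    ``Wkavg`` pools all 2 h animal-sessions of a strain in week k (up to
    animals × 3 days values); ``WkD4`` averages the single 4 h session;
    ``W1D1`` is the first-ever exposure.  Missing sessions simply drop out
    of the mean.  Returns a long frame ``strain, trait_id, value,
    n_animals`` with one row per available (strain, trait).
    """
    if records.empty:
        raise ValueError("no intake records")
    rec = records
    out = []

    def _agg(sub: pd.DataFrame, trait_id: str) -> None:
        if sub.empty:
            return
        grp = sub.groupby("strain")
        agg = grp["intake_gkg"].mean()
        n = grp["animal_id"].nunique()
        for strain, value in agg.items():
            out.append((strain, trait_id, float(value), int(n[strain])))

    _agg(rec[(rec["week"] == 1) & (rec["day"] == 1)], "W1D1")
    for k in range(1, int(rec["week"].max()) + 1):
        wk = rec[rec["week"] == k]
        _agg(wk[wk["access_h"] == 2], f"W{k}avg")
        _agg(wk[(wk["day"] == 4) & (wk["access_h"] == 4)], f"W{k}D4")
    return pd.DataFrame(out, columns=["strain", "trait_id", "value", "n_animals"])


def trait_series(traits: pd.DataFrame, trait_id: str) -> pd.Series:
    """One trait as a strain-indexed Series (the scans' phenotype vector)."""
    sub = traits[traits["trait_id"] == trait_id]
    if sub.empty:
        raise KeyError(f"trait {trait_id!r} not present")
    return sub.set_index("strain")["value"].astype(float)


@dataclass(frozen=True)
class AnovaResult:
    """One-way fixed-effects ANOVA on strain, with h2 = SS_strain/SS_total."""

    F: float
    p: float
    df_between: int
    df_within: int
    h2: float


def strain_anova(values: pd.DataFrame | dict[str, np.ndarray]) -> AnovaResult:
    """One-way ANOVA of animal-level values grouped by strain.

    Broad-sense panel heritability is estimated as the between-strain sum
    of squares over the total sum of squares.  Accepts a frame with
    ``strain``/``value`` columns or a ``{strain: values}`` mapping.
    """
    if isinstance(values, pd.DataFrame):
        groups = {s: g["value"].to_numpy(float) for s, g in values.groupby("strain")}
    else:
        groups = {s: np.asarray(v, dtype=float) for s, v in values.items()}
    groups = {s: v[~np.isnan(v)] for s, v in groups.items()}
    groups = {s: v for s, v in groups.items() if len(v) > 0}
    if len(groups) < 2:
        raise ValueError("need >=2 strains with data")
    if max(len(v) for v in groups.values()) < 2:
        raise ValueError("need >=1 strain with >=2 animals")
    allv = np.concatenate(list(groups.values()))
    grand = allv.mean()
    ss_total = float(np.sum((allv - grand) ** 2))
    ss_between = float(sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values()))
    df_between = len(groups) - 1
    df_within = len(allv) - len(groups)
    if ss_total <= 0:
        warnings.warn("all values identical; F undefined, returning h2 = 0")
        return AnovaResult(F=np.nan, p=np.nan, df_between=df_between,
                           df_within=df_within, h2=0.0)
    ss_within = ss_total - ss_between
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within if df_within > 0 else np.nan
    if ms_within == 0 or df_within == 0:
        F, p = np.inf, 0.0
    else:
        F = ms_between / ms_within
        p = float(stats.f.sf(F, df_between, df_within))
    return AnovaResult(F=float(F), p=p, df_between=df_between,
                       df_within=df_within, h2=ss_between / ss_total)


def fit_strain_slopes(traits: pd.DataFrame, duration: str = "2h") -> pd.DataFrame:
    """Per-strain least-squares escalation fits over the 5 weekly values.

    Regresses weekly strain means (``W1avg..W5avg`` for 2 h, ``W1D4..W5D4``
    for 4 h) on week index 1..5; the intercept is reported at week 0 (the
    extrapolated pre-study baseline).  The slope standard error and
    two-sided p come from the 3-df t test of slope = 0.  Strains missing a
    week are skipped with a warning.

    Returns a frame with ``strain, slope, intercept, se_slope, p_slope``.
    """
    if duration not in ("2h", "4h"):
        raise ValueError("duration must be '2h' or '4h'")
    week_traits = WEEKLY_2H_TRAITS if duration == "2h" else WEEKLY_4H_TRAITS
    wide = (
        traits[traits["trait_id"].isin(week_traits)]
        .pivot(index="strain", columns="trait_id", values="value")
        .reindex(columns=list(week_traits))
    )
    weeks = np.arange(1, 6, dtype=float)
    rows = []
    for strain, y in wide.iterrows():
        yv = y.to_numpy(float)
        if np.isnan(yv).any():
            warnings.warn(f"strain {strain}: missing weekly value, skipped")
            continue
        fit = stats.linregress(weeks, yv)
        rows.append((strain, float(fit.slope), float(fit.intercept),
                     float(fit.stderr), float(fit.pvalue)))
    return pd.DataFrame(rows, columns=["strain", "slope", "intercept", "se_slope", "p_slope"])


_SLOPE_PAIRS = {
    ("slope4h", "intercept4h"): ("slope_4h", "intercept_4h"),
    ("slope2h", "intercept2h"): ("slope_2h", "intercept_2h"),
    ("slope2h", "slope4h"): ("slope_2h", "slope_4h"),
}


def slope_trait_correlation(fits: pd.DataFrame, pair: tuple[str, str]) -> float:
    """Pearson correlation across strains between two slope-table columns.

    ``fits`` is a wide per-strain table with columns ``slope_2h,
    intercept_2h, slope_4h, intercept_4h`` (e.g. from
    :func:`load_published_slope_table` or two merged
    :func:`fit_strain_slopes` outputs).  ``pair`` uses the short names
    ``slope2h, intercept2h, slope4h, intercept4h``.
    """
    key = tuple(pair)
    if key not in _SLOPE_PAIRS:
        raise KeyError(f"unsupported pair {pair}; one of {sorted(_SLOPE_PAIRS)}")
    ca, cb = _SLOPE_PAIRS[key]
    sub = fits[[ca, cb]].dropna()
    if len(sub) < 3:
        raise ValueError("need >=3 strains with both values")
    a, b = sub[ca].to_numpy(float), sub[cb].to_numpy(float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a column")
    return float(stats.pearsonr(a, b).statistic)


def winsorize(values: np.ndarray, lower_q: float = 0.025, upper_q: float = 0.975) -> np.ndarray:
    """Clamp values to the [lower_q, upper_q] quantile bounds.

    Limits outlier influence before mapping; order and length preserved.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty vector")
    if not 0.0 <= lower_q < upper_q <= 1.0:
        raise ValueError("need 0 <= lower_q < upper_q <= 1")
    lo, hi = np.quantile(v, [lower_q, upper_q])
    return np.clip(v, lo, hi)


def week_correlation_matrix(traits: pd.DataFrame, duration: str = "2h",
                            include_w1d1: bool = True) -> pd.DataFrame:
    """Across-strain Pearson correlations between weekly traits.

    Adjacent weeks correlate more strongly than distant ones when strain
    trajectories are autocorrelated; the matrix makes that decay visible.
    """
    week_traits = list(WEEKLY_2H_TRAITS if duration == "2h" else WEEKLY_4H_TRAITS)
    if include_w1d1 and (traits["trait_id"] == "W1D1").any():
        week_traits = ["W1D1"] + week_traits
    wide = (
        traits[traits["trait_id"].isin(week_traits)]
        .pivot(index="strain", columns="trait_id", values="value")
        .reindex(columns=week_traits)
    )
    if (wide.notna().sum() < 3).any():
        raise ValueError("need >=3 strains per week")
    if (wide.std() == 0).any():
        raise ValueError("zero-variance week")
    return wide.corr()


def load_published_slope_table() -> pd.DataFrame:
    """Reference 41-strain 5-week escalation slope/intercept table.

    Published per-strain 2 h and 4 h DID escalation estimates for 39 BXD
    strains plus both parents, as printed (strain-indexed wide frame with
    columns ``slope_2h, intercept_2h, se_2h, slope_4h, intercept_4h,
    se_4h``).  Used for desk reproduction of the slope/intercept
    correlation structure.
    """
    from importlib.resources import files

    path = files("ridqtl.data").joinpath("bxd_did_slopes.csv")
    with path.open() as fh:
        return pd.read_csv(fh, index_col="strain")
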