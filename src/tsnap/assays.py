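"""Assay-derived statistics: morphological-profiling activity calls,
MTT viability, dilution series, MIC from growth curves and single-point
percent inhibition.

Conventions
-----------
* Concentrations are micromolar throughout; nanomolar appears only in
  presentation strings.
* The activity threshold for morphological fingerprints is five times
  the **mean** activity score of negative-control wells by default; a
  flag switches to the median (both conventions circulate for this
  statistic, and the choice is surfaced rather than hidden).
* Fingerprint column filtering removes, per concentration slice, any
  feature column containing a value more than three sample standard
  deviations above that column's median in the slice.  Removal is
  slice-local (masked to NaN), so a column can survive at one
  concentration and be dropped at another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# dilution series


@dataclass(frozen=True)
class DilutionSeries:
    """Geometric dilution series, descending from ``start_uM``."""

    start_uM: float
    n_points: int
    factor: float

    def __post_init__(self):
        if self.start_uM <= 0:
            raise ValueError("start concentration must be positive")
        if self.n_points < 1:
            raise ValueError("need at least one dilution point")
        if self.factor <= 1:
            raise ValueError("dilution factor must exceed 1")

    @property
    def concentrations_uM(self) -> np.ndarray:
        k = np.arange(self.n_points)
        return self.start_uM / self.factor ** k

    @property
    def concentrations_nM(self) -> np.ndarray:
        return self.concentrations_uM * 1e3

    @property
    def lowest_nM(self) -> float:
        return float(self.concentrations_nM[-1])

    def describe(self) -> str:
        lo = self.lowest_nM
        return (f"{self.start_uM:g} uM to {lo:.2f} nM "
                f"({self.n_points} x {self.factor:g}-fold)")


def dilution_series(start_uM: float, n_points: int, factor: float = 2.0) -> DilutionSeries:
    """Exact geometric series: concentrations[k] = start / factor**k."""
    return DilutionSeries(start_uM, n_points, factor)


# ---------------------------------------------------------------------------
# morphological fingerprints


def filter_fingerprint_columns(table: pd.DataFrame,
                               concentration_col: str = "concentration_uM",
                               n_sd: float = 3.0) -> pd.DataFrame:
    """Mask outlier feature columns per concentration slice.

    For each concentration, a feature column is removed (set to NaN in
    that slice) if any of its values exceeds ``median + n_sd * SD``,
    both computed over that column within the slice.  Slices with a
    single row have undefined SD and are skipped with a warning.
    """
    feature_cols = [c for c in table.columns
                    if c != concentration_col and pd.api.types.is_numeric_dtype(table[c])]
    out = table.copy()
    for conc, idx in table.groupby(concentration_col).groups.items():
        block = table.loc[idx, feature_cols]
        if len(idx) < 2:
            warnings.warn(f"concentration {conc}: single well, SD undefined; slice skipped")
            continue
        med = block.median(axis=0)
        sd = block.std(axis=0, ddof=1)
        exceeds = (block > med + n_sd * sd).any(axis=0)
        drop = exceeds[exceeds].index
        out.loc[idx, drop] = np.nan
    return out


def activity_score(fingerprint_row: pd.Series | np.ndarray) -> float:
    """Euclidean norm of the (filtered) fingerprint; NaN entries are ignored."""
    values = np.asarray(fingerprint_row, dtype=float)
    values = values[np.isfinite(values)]
    return float(np.sqrt(np.sum(values ** 2)))


def active_concentrations(scores_by_concentration: dict[float, float] | pd.Series,
                          negative_scores: np.ndarray,
                          fold: float = 5.0,
                          center: str = "mean") -> float | None:
    """Lowest concentration whose activity score clears the control threshold.

    The threshold is ``fold`` times the mean (default) or median of the
    negative-control activity scores.  Returns None when nothing clears
    it.  A zero threshold (all-null controls) is degenerate and is
    reported with a warning rather than an error.
    """
    neg = np.asarray(negative_scores, dtype=float)
    if neg.size == 0:
        raise ValueError("need at least one negative-control score")
    if center == "mean":
        ref = float(neg.mean())
    elif center == "median":
        ref = float(np.median(neg))
    else:
        raise ValueError("center must be 'mean' or 'median'")
    threshold = fold * ref
    if threshold == 0.0:
        warnings.warn("negative controls are all zero: threshold degenerates to 0")
    if isinstance(scores_by_concentration, pd.Series):
        items = list(scores_by_concentration.items())
    else:
        items = list(scores_by_concentration.items())
    active = [conc for conc, score in items if score > threshold]
    return min(active) if active else None


# ---------------------------------------------------------------------------
# MTT viability


def mtt_viability(treatment_abs: float | np.ndarray,
                  mtt_only_abs: np.ndarray,
                  dmso_abs: np.ndarray) -> float | np.ndarray:
    """Percent viability with background subtraction.

    100 * (A - mean(background)) / mean(DMSO - mean(background)).
    """
    mtt_only = np.asarray(mtt_only_abs, dtype=float)
    dmso = np.asarray(dmso_abs, dtype=float)
    if mtt_only.size == 0 or dmso.size == 0:
        raise ValueError("control well sets must be non-empty")
    background = mtt_only.mean()
    denom = (dmso - background).mean()
    if denom == 0:
        raise ZeroDivisionError("adjusted DMSO control absorbance is zero")
    result = 100.0 * (np.asarray(treatment_abs, dtype=float) - background) / denom
    return float(result) if np.isscalar(treatment_abs) else result


# ---------------------------------------------------------------------------
# growth curves, MIC and percent inhibition


@dataclass(frozen=True)
class MicResult:
    """MIC call for one strain/compound dilution series."""

    value_uM: float | None  # None when censored
    censored: bool
    max_tested_uM: float

    def __str__(self) -> str:
        if self.censored:
            return f">{self.max_tested_uM:g} uM"
        return f"{self.value_uM:g} uM"


def mic_from_curves(records: pd.DataFrame, inhibition_cut: float = 0.90,
                    concentration_col: str = "concentration_uM") -> MicResult:
    """MIC from endpoint growth (OD600 at t20 minus t0) for one series.

    ``records`` holds one strain/compound series with columns
    ``role`` (treatment / vehicle / blank), ``concentration_uM``,
    ``od600_t0`` and ``od600_t20``.  Growth is the OD delta; percent
    inhibition is measured against mean vehicle growth after blank
    subtraction.  The MIC is the lowest concentration at which
    inhibition reaches ``inhibition_cut`` *and* stays there for all
    higher concentrations; a series that never reaches the cut is
    censored as greater-than the highest tested concentration.
    """
    growth = records["od600_t20"] - records["od600_t0"]
    vehicle = growth[records["role"] == "vehicle"]
    if vehicle.empty:
        raise ValueError("no vehicle wells in growth records")
    blank = growth[records["role"] == "blank"]
    blank_mean = float(blank.mean()) if not blank.empty else 0.0
    vehicle_growth = float(vehicle.mean()) - blank_mean
    if vehicle_growth <= 0:
        raise ValueError("vehicle shows no growth over blank; series invalid")

    treated = records[records["role"] == "treatment"]
    by_conc = (
        pd.DataFrame({concentration_col: treated[concentration_col],
                      "growth": growth[treated.index] - blank_mean})
        .groupby(concentration_col)["growth"].mean().sort_index(ascending=False)
    )
    inhibition = 1.0 - by_conc / vehicle_growth
    max_tested = float(by_conc.index.max())

    mic = None
    for conc, inh in inhibition.items():  # descending concentrations
        if inh >= inhibition_cut:
            mic = float(conc)
        else:
            break  # monotone-above requirement broken
    if mic is None:
        return MicResult(None, True, max_tested)
    return MicResult(mic, False, max_tested)


def percent_inhibition(od_treated: float, od_vehicle: float, od_blank: float) -> float:
    """Single-point growth inhibition: 100 * (1 - (T - B)/(V - B)).

    Values above 100 are clamped to 100 (treated below blank); negative
    values (growth promotion) are reported as-is.
    """
    if od_vehicle <= od_blank:
        raise ValueError("vehicle OD must exceed blank OD")
    value = 100.0 * (1.0 - (od_treated - od_blank) / (od_vehicle - od_blank))
    return min(value, 100.0)
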