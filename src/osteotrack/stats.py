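"""Agreement, sample-size, dose and group-comparison statistics.

The longitudinal study design rests on four statistical pieces:

* **Interobserver agreement** of the manually delineated 3-D ROIs:
  Bland-Altman limits of agreement over all observer pairs, plus a
  two-way intraclass correlation coefficient with Cronbach's alpha.
* **Sample size** from the repeated-measures formula
  ``n = 2 + C (s/d)^2`` (C = 7.85 for 80% power at alpha = 0.05),
  rounded up to whole animals.
* **Radiation dose ledger**: cumulative dose = per-scan dose x number of
  scans, to verify the protocol stays in the low-dose regime.
* **Group-by-time comparison** of healing curves (e.g. reamed vs
  unreamed femurs): two-way ANOVA with per-timepoint contrasts under a
  Sidak multiple-comparison correction.

All mean squares are computed directly from the data; the test suite
cross-checks them against independent brute-force and library oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# Bland-Altman agreement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlandAltman:
    """Limits of agreement: mean difference +/- 1.96 SD of the differences."""

    mean_diff: float
    sd_diff: float
    limits_low: float
    limits_high: float
    n: int


def bland_altman(x, y) -> BlandAltman:
    """Agreement between two paired raters.

    The "95% interval" reported for observer agreement is the classical
    Bland-Altman limits of agreement, mean difference +/- 1.96 x SD of
    the paired differences (SD with the n-1 denominator).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired observations differ in length: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(mean, sd, mean - 1.96 * sd, mean + 1.96 * sd, int(d.size))


def bland_altman_pairwise(table: pd.DataFrame) -> dict:
    """Two-by-two Bland-Altman over all observer columns, plus pooled limits.

    ``table``: rows = scans, columns = observers (e.g. A, B, C).  For
    three observers the pairs are A-B, B-C, C-A; the pooled entry stacks
    all pairwise differences before taking mean +/- 1.96 SD, which is the
    single interval quoted for a multi-observer study.  ``percent_of_mean``
    expresses the pooled half-width relative to the mean measured value,
    as a secondary descriptive column.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least two observers")
    pairs = [(cols[i], cols[(i + 1) % len(cols)]) for i in range(len(cols))]
    if len(cols) == 2:
        pairs = [(cols[0], cols[1])]
    out: dict = {"pairs": {}}
    all_diffs = []
    for a, b in pairs:
        out["pairs"][f"{a}-{b}"] = bland_altman(table[a], table[b])
        all_diffs.append(table[a].to_numpy(float) - table[b].to_numpy(float))
    pooled = np.concatenate(all_diffs)
    mean = float(pooled.mean())
    sd = float(pooled.std(ddof=1))
    out["pooled"] = BlandAltman(
        mean, sd, mean - 1.96 * sd, mean + 1.96 * sd, int(pooled.size)
    )
    grand_mean = float(table.to_numpy(float).mean())
    out["percent_of_mean"] = (
        100.0 * 1.96 * sd / grand_mean if grand_mean != 0 else float("nan")
    )
    return out


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IccResult:
    """Two-way ICC with its F test, plus Cronbach's alpha.

    ``model`` records the variance-components form: ICC3 is two-way
    mixed, consistency; ICC2 is two-way random, absolute agreement.
    Both single-measure and average-measure coefficients are reported
    since published values rarely say which was used.
    """

    icc_single: float
    icc_average: float
    cronbach_alpha: float
    f_statistic: float
    df1: int
    df2: int
    p_value: float
    model: str
    n_targets: int
    n_raters: int


def _two_way_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of a complete targets x raters table."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc(table: pd.DataFrame | np.ndarray, model: str = "ICC3") -> IccResult:
    """Intraclass correlation of a complete targets x raters table.

    ``model="ICC3"`` (default): two-way mixed, single-measure,
    consistency — (MSR - MSE) / (MSR + (k-1) MSE).  ``model="ICC2"``:
    two-way random, absolute agreement, which additionally charges the
    rater variance component.  The F test of MSR/MSE (df n-1, (n-1)(k-1))
    applies to both.  Cronbach's alpha (= 1 - MSE/MSR, the
    average-measure consistency coefficient) is reported alongside.
    """
    data = np.asarray(table, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need a 2-D table with >=2 targets and >=2 raters")
    if np.isnan(data).any():
        raise ValueError("ICC requires a complete table (no missing cells)")
    n, k = data.shape
    msr, msc, mse = _two_way_mean_squares(data)
    if msr <= 0:
        raise ValueError("no between-target variance; ICC is undefined")
    if model == "ICC3":
        single = (msr - mse) / (msr + (k - 1) * mse)
        average = (msr - mse) / msr
    elif model == "ICC2":
        single = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        average = (msr - mse) / (msr + (msc - mse) / n)
    else:
        raise ValueError(f"unknown ICC model {model!r} (use 'ICC3' or 'ICC2')")
    f = msr / mse if mse > 0 else float("inf")
    df1, df2 = n - 1, (n - 1) * (k - 1)
    p = float(sps.f.sf(f, df1, df2))
    alpha = 1.0 - mse / msr
    return IccResult(
        icc_single=float(single),
        icc_average=float(average),
        cronbach_alpha=float(alpha),
        f_statistic=float(f),
        df1=df1,
        df2=df2,
        p_value=p,
        model=model,
        n_targets=n,
        n_raters=k,
    )


# ---------------------------------------------------------------------------
# Sample size
# ---------------------------------------------------------------------------


def sample_size(C: float, s: float, d: float) -> int:
    """Animals needed per the repeated-measures formula n = 2 + C (s/d)^2.

    ``C`` encodes power and significance level (7.85 for 80% power at
    alpha = 0.05); ``s`` is the standard deviation of the paired
    difference and ``d`` the difference to detect, in the same units.
    Fractional animals are rounded up.
    """
    if C <= 0 or s <= 0:
        raise ValueError("C and s must be positive")
    if d <= 0:
        raise ValueError("difference to detect must be positive")
    return int(math.ceil(2.0 + C * (s / d) ** 2))


# ---------------------------------------------------------------------------
# Dose ledger
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseLedger:
    """Cumulative radiation bookkeeping for a scan schedule (cGy)."""

    per_scan_dose: float
    n_scans: int
    cumulative: float

    def under(self, limit_cgy: float) -> bool:
        return self.cumulative < limit_cgy


def dose_ledger(per_scan: float, schedule) -> DoseLedger:
    """Cumulative dose = per-scan dose x number of scheduled scans."""
    if per_scan <= 0:
        raise ValueError("per-scan dose must be positive")
    n = len(schedule)
    return DoseLedger(per_scan, n, per_scan * n)


# ---------------------------------------------------------------------------
# Two-way ANOVA with Sidak-adjusted per-time contrasts
# ---------------------------------------------------------------------------


def sidak_adjust(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Sidak multiple-comparison adjustment, p_adj = 1 - (1 - p)^m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return 1.0 - (1.0 - np.asarray(p, dtype=float)) ** m


@dataclass
class AnovaResult:
    """Two-way ANOVA table plus Sidak-adjusted per-timepoint contrasts."""

    anova_table: pd.DataFrame  # index: group, time, interaction, residual
    contrasts: pd.DataFrame  # per timepoint: mean_diff, t, df, p, p_sidak
    m_comparisons: int


def two_way_anova_sidak(data: pd.DataFrame) -> AnovaResult:
    """Compare two groups across shared timepoints.

    ``data`` must have columns ``group``, ``time``, ``value`` with two
    group levels, every timepoint present in both groups, and an equal
    number of replicates per cell (the balanced layout produced by a
    fixed cohort scanned on a fixed schedule; unbalanced tables are
    rejected rather than silently reweighted).

    The sums of squares (group, time, interaction, residual) follow the
    standard balanced two-way decomposition.  Each timepoint's group
    contrast is a t test on the cell means pooled over the residual mean
    square, with the Sidak family-wise adjustment over the number of
    timepoints, mirroring per-timepoint post hoc comparisons after a
    two-way ANOVA.
    """
    for col in ("group", "time", "value"):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    groups = sorted(data["group"].unique().tolist())
    times = sorted(data["time"].unique().tolist())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    cell_sizes = data.groupby(["group", "time"])["value"].count()
    if len(cell_sizes) != len(groups) * len(times):
        raise ValueError("every (group, time) cell must be populated")
    if cell_sizes.nunique() != 1:
        raise ValueError("unbalanced design: unequal replicates per cell")
    r = int(cell_sizes.iloc[0])
    if r < 2:
        raise ValueError("need >=2 subjects per cell to estimate the interaction")

    y = data["value"].to_numpy(dtype=float)
    grand = y.mean()
    a, b = len(groups), len(times)
    cell_mean = data.groupby(["group", "time"])["value"].mean()
    g_mean = data.groupby("group")["value"].mean()
    t_mean = data.groupby("time")["value"].mean()

    ss_group = b * r * float(((g_mean - grand) ** 2).sum())
    ss_time = a * r * float(((t_mean - grand) ** 2).sum())
    ss_cells = r * float(((cell_mean - grand) ** 2).sum())
    ss_inter = ss_cells - ss_group - ss_time
    ss_total = float(((y - grand) ** 2).sum())
    ss_resid = ss_total - ss_cells

    df_group, df_time = a - 1, b - 1
    df_inter = df_group * df_time
    df_resid = a * b * (r - 1)
    mse = ss_resid / df_resid

    rows = []
    for name, ss, df in (
        ("group", ss_group, df_group),
        ("time", ss_time, df_time),
        ("interaction", ss_inter, df_inter),
        ("residual", ss_resid, df_resid),
    ):
        ms = ss / df
        if name == "residual":
            rows.append({"effect": name, "SS": ss, "df": df, "MS": ms,
                         "F": np.nan, "p": np.nan})
        else:
            f = ms / mse
            rows.append({"effect": name, "SS": ss, "df": df, "MS": ms,
                         "F": f, "p": float(sps.f.sf(f, df, df_resid))})
    anova_table = pd.DataFrame(rows).set_index("effect")

    m = len(times)
    contrast_rows = []
    for t in times:
        m0 = cell_mean[(groups[0], t)]
        m1 = cell_mean[(groups[1], t)]
        se = math.sqrt(mse * (2.0 / r))
        tstat = (m0 - m1) / se if se > 0 else np.nan
        p = float(2 * sps.t.sf(abs(tstat), df_resid)) if np.isfinite(tstat) else np.nan
        contrast_rows.append(
            {
                "time": t,
                "mean_diff": float(m0 - m1),
                "t": float(tstat),
                "df": df_resid,
                "p": p,
                "p_sidak": float(sidak_adjust(p, m)) if np.isfinite(tstat) else np.nan,
            }
        )
    contrasts = pd.DataFrame(contrast_rows)
    return AnovaResult(anova_table=anova_table, contrasts=contrasts, m_comparisons=m)
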