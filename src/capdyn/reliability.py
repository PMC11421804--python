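"""State-trait reliability statistics for temporal CAP measures.

Day-to-day reliability is quantified three ways:

* ICC(2,1) — single-measure absolute-agreement intraclass correlation from
  the two-way random-effects ANOVA (subjects x sessions);
* between-day Pearson correlation of permutation-averaged values across
  subjects;
* coefficient of variation (SD/mean across subjects) of each measure per
  day — the three-axes state-trait representation, one point per CAP with
  axes (CV of FO, CV of mean DT, CV of var DT), whose between-day
  displacement reads out state variance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .temporal import METRIC_NAMES


class UndefinedStatisticError(ArithmeticError):
    """A reliability statistic is undefined on this input (e.g. zero variance)."""


def icc_2_1(scores: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``scores`` is subjects x sessions.  With n subjects, k sessions,
    MSR/MSC/MSE the between-subject, between-session and residual mean
    squares of the two-way ANOVA,

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).

    Raises :class:`UndefinedStatisticError` when the total variance is zero.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("scores must be a subjects x sessions matrix, both >= 2")
    if not np.isfinite(X).all():
        raise ValueError("scores contain non-finite values")
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_total = ((X - grand) ** 2).sum()
    if ss_total == 0:
        raise UndefinedStatisticError("zero total variance; ICC undefined")
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise UndefinedStatisticError("degenerate ANOVA decomposition; ICC undefined")
    return float((msr - mse) / denom)


def _day_pivot(metrics: pd.DataFrame, cap: str, metric: str,
               present_only: bool) -> pd.DataFrame:
    col = f"{metric}_present" if present_only else metric
    sub = metrics[metrics["cap_label"] == cap]
    pivot = sub.pivot_table(index="subject_id", columns="day", values=col,
                            aggfunc="first")
    pivot = pivot.dropna()
    if present_only:
        # subjects structurally lacking the CAP on both days carry no signal
        pivot = pivot[(pivot != 0).any(axis=1)]
    return pivot


def day_reliability(metrics: pd.DataFrame, extra_label: str = "III"
                    ) -> pd.DataFrame:
    """Pearson r (with two-sided p) between day-1 and day-2 values per CAP x metric.

    ``metrics`` is the permutation-averaged tidy table from
    :func:`capdyn.temporal.aggregate_metrics`.  For the extra CAP (III),
    subject pairs that are zero on both days — subjects in whose splits the
    CAP never appeared — are excluded, and the present-only averages are
    used, mirroring the reliability convention.
    """
    import warnings

    rows = []
    for cap in sorted(metrics["cap_label"].unique()):
        for metric in METRIC_NAMES:
            pivot = _day_pivot(metrics, cap, metric, present_only=(cap == extra_label))
            x, y = pivot[1].to_numpy(), pivot[2].to_numpy()
            if pivot.shape[0] < 3 or np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(
                    f"day correlation undefined for {cap}/{metric} "
                    f"(n={pivot.shape[0]} or constant values)", stacklevel=2,
                )
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, y)
            rows.append({"cap_label": cap, "metric": metric, "r": r, "p": p,
                         "n_subjects": pivot.shape[0]})
    return pd.DataFrame(rows)


def icc_report(metrics: pd.DataFrame, extra_label: str = "III") -> pd.DataFrame:
    """ICC(2,1) of each CAP x metric across days on permutation-averaged values."""
    rows = []
    for cap in sorted(metrics["cap_label"].unique()):
        for metric in METRIC_NAMES:
            pivot = _day_pivot(metrics, cap, metric, present_only=(cap == extra_label))
            try:
                if pivot.shape[0] < 2:
                    raise UndefinedStatisticError("fewer than 2 subjects")
                icc = icc_2_1(pivot.to_numpy())
                rows.append({"cap_label": cap, "metric": metric, "icc21": icc,
                             "n_subjects": pivot.shape[0]})
            except UndefinedStatisticError:
                rows.append({"cap_label": cap, "metric": metric, "icc21": np.nan,
                             "n_subjects": pivot.shape[0]})
    return pd.DataFrame(rows)


def three_axes_table(metrics: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Coefficient of variation across subjects per CAP x metric x day.

    CV = SD/mean of the permutation-averaged value across subjects
    (population SD by default; ``ddof=1`` switches to sample SD).  Cells
    with non-positive mean are undefined and set to NaN with the mean
    recorded for inspection.
    """
    rows = []
    for (cap, day), grp in metrics.groupby(["cap_label", "day"]):
        if grp["subject_id"].nunique() < 2:
            raise ValueError("need >= 2 subjects for a CV")
        row = {"cap_label": cap, "day": day}
        for metric in METRIC_NAMES:
            vals = grp.groupby("subject_id")[metric].first().to_numpy()
            mean = vals.mean()
            row[f"cv_{metric}"] = (
                vals.std(ddof=ddof) / mean if mean > 0 else np.nan
            )
            row[f"mean_{metric}"] = mean
        rows.append(row)
    return pd.DataFrame(rows)
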