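"""Observer/method agreement statistics for zone-width measurements.

For each fluorescein zone the study compares paired measurements — the two
observers within one software, or the two software packages using the mean
of both observers — with the standard battery: mean +/- SD of the paired
differences, Bland-Altman limits of agreement (mean +/- 1.96 * SD), a
confidence interval for each limit, a two-sided paired Student's t-test,
and the Pearson correlation between the two series.

The LoA multiplier is fixed at 1.96 (the normal 95% quantile, the classic
Bland-Altman convention), not a t quantile.  Limit confidence intervals
default to the Bland-Altman large-sample approximation
SE(limit) = SD * sqrt(1/n + z^2 / (2(n-1))); an exact parametric interval
via the noncentral-t construction is available as an opt-in mode.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ZONES",
    "AgreementSummary",
    "MeasurementTable",
    "paired_summary",
    "loa_confidence_interval",
    "agreement_report",
    "limits_of_agreement",
    "bland_altman_plot",
    "summary_frame",
]

ZONES = ("central_bearing", "tear_reservoir", "mid_peripheral", "edge_lift")
METHODS = ("algorithm", "imagej")
LOA_Z = 1.96


def limits_of_agreement(mean_diff: float, sd_diff: float) -> tuple[float, float]:
    """Bland-Altman limits: mean difference -/+ 1.96 * SD of differences."""
    return mean_diff - LOA_Z * sd_diff, mean_diff + LOA_Z * sd_diff


@dataclass(frozen=True)
class AgreementSummary:
    """Paired-difference statistics for one zone and one comparison.

    Differences are (first-listed - second-listed); ``label_a``/``label_b``
    record the order.  ``pearson_r`` is ``None`` when either series has
    zero variance (the correlation is undefined), with ``r_note`` saying
    so.  ``loa_low_ci`` / ``loa_high_ci`` are (lower, upper) bounds of the
    confidence interval for each agreement limit.
    """

    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    loa_low_ci: tuple[float, float]
    loa_high_ci: tuple[float, float]
    t_stat: float
    df: int
    p_value: float
    pearson_r: float | None
    r_p_value: float | None
    mean_a: float
    sd_a: float
    ci_a: tuple[float, float]
    mean_b: float
    sd_b: float
    ci_b: tuple[float, float]
    label_a: str = "a"
    label_b: str = "b"
    r_note: str | None = None

    def as_row(self) -> dict:
        """Flatten for tabular rendering (full precision)."""
        return {
            "n": self.n,
            "label_a": self.label_a,
            "label_b": self.label_b,
            "mean_a": self.mean_a,
            "sd_a": self.sd_a,
            "ci_a_low": self.ci_a[0],
            "ci_a_high": self.ci_a[1],
            "mean_b": self.mean_b,
            "sd_b": self.sd_b,
            "ci_b_low": self.ci_b[0],
            "ci_b_high": self.ci_b[1],
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "loa_low_ci_low": self.loa_low_ci[0],
            "loa_low_ci_high": self.loa_low_ci[1],
            "loa_high_ci_low": self.loa_high_ci[0],
            "loa_high_ci_high": self.loa_high_ci[1],
            "t": self.t_stat,
            "df": self.df,
            "p": self.p_value,
            "r": np.nan if self.pearson_r is None else self.pearson_r,
            "r_p": np.nan if self.r_p_value is None else self.r_p_value,
        }


def _mean_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """t-based confidence interval for the mean of one series."""
    n = len(x)
    m = float(np.mean(x))
    se = float(np.std(x, ddof=1)) / np.sqrt(n)
    h = sps.t.ppf((1 + level) / 2, n - 1) * se
    return m - h, m + h


def paired_summary(
    a, b, label_a: str = "a", label_b: str = "b", ci_level: float = 0.95
) -> AgreementSummary:
    """Full agreement battery for two paired series of equal length >= 3.

    d = a - b; t = mean(d) / (SD(d)/sqrt(n)) with df = n - 1 (two-sided p);
    SDs use the n-1 denominator.  If the differences are all identical the
    t statistic is undefined and reported as NaN; if either series is
    constant the Pearson correlation is reported as ``None``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"paired series must be 1-D and equal length, got {a.shape} vs {b.shape}")
    n = len(a)
    if n < 3:
        raise ValueError(f"at least 3 pairs are required, got {n}")
    d = a - b
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    loa_low, loa_high = limits_of_agreement(mean_diff, sd_diff)
    if sd_diff > 0:
        t_stat = mean_diff / (sd_diff / np.sqrt(n))
        p_value = 2.0 * float(sps.t.sf(abs(t_stat), n - 1))
    else:
        t_stat = float("nan") if mean_diff == 0 else float("inf") * np.sign(mean_diff)
        p_value = float("nan") if mean_diff == 0 else 0.0
    r_note = None
    if np.std(a, ddof=1) == 0 or np.std(b, ddof=1) == 0:
        pearson_r = None
        r_p_value = None
        r_note = "Pearson r undefined: at least one series has zero variance"
    else:
        r_res = sps.pearsonr(a, b)
        pearson_r = float(r_res.statistic)
        r_p_value = float(r_res.pvalue)
    summary = AgreementSummary(
        n=n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=loa_low,
        loa_high=loa_high,
        loa_low_ci=(loa_low, loa_low),
        loa_high_ci=(loa_high, loa_high),
        t_stat=float(t_stat),
        df=n - 1,
        p_value=p_value,
        pearson_r=pearson_r,
        r_p_value=r_p_value,
        mean_a=float(np.mean(a)),
        sd_a=float(np.std(a, ddof=1)),
        ci_a=_mean_ci(a, ci_level),
        mean_b=float(np.mean(b)),
        sd_b=float(np.std(b, ddof=1)),
        ci_b=_mean_ci(b, ci_level),
        label_a=label_a,
        label_b=label_b,
        r_note=r_note,
    )
    low_ci, high_ci = loa_confidence_interval(summary, level=ci_level)
    return replace(summary, loa_low_ci=low_ci, loa_high_ci=high_ci)


def loa_confidence_interval(
    summary: AgreementSummary, level: float = 0.95, mode: str = "approximate"
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Confidence intervals for the two agreement limits.

    ``approximate`` (default) is the Bland-Altman construction:
    SE(limit) = SD * sqrt(1/n + z^2/(2(n-1))) with z = 1.96, and interval
    limit +/- t_{n-1} * SE.  ``exact`` treats each limit as the normal
    quantile mu +/- z*sigma and inverts the noncentral-t pivot
    sqrt(n)(mean - limit)/SD ~ t'_{n-1}(nc = -/+ sqrt(n) z), giving an
    exact parametric interval.  Returns ((low_lo, low_hi), (high_lo, high_hi)).
    """
    n, mean, sd = summary.n, summary.mean_diff, summary.sd_diff
    if n < 3:
        raise ValueError("confidence intervals need n >= 3")
    if sd == 0:
        return (mean, mean), (mean, mean)
    alpha = 1 - level
    if mode == "approximate":
        se = sd * np.sqrt(1.0 / n + LOA_Z**2 / (2.0 * (n - 1)))
        h = float(sps.t.ppf(1 - alpha / 2, n - 1) * se)
        return (
            (summary.loa_low - h, summary.loa_low + h),
            (summary.loa_high - h, summary.loa_high + h),
        )
    if mode == "exact":
        scale = sd / np.sqrt(n)
        nc = np.sqrt(n) * LOA_Z
        # upper limit mu + z*sigma: sqrt(n)(xbar - theta)/s ~ nct(n-1, -nc)
        q_lo, q_hi = sps.nct.ppf([alpha / 2, 1 - alpha / 2], n - 1, -nc)
        high_ci = (mean - scale * q_hi, mean - scale * q_lo)
        # lower limit mu - z*sigma: sqrt(n)(xbar - theta)/s ~ nct(n-1, +nc)
        q_lo, q_hi = sps.nct.ppf([alpha / 2, 1 - alpha / 2], n - 1, nc)
        low_ci = (mean - scale * q_hi, mean - scale * q_lo)
        return (float(low_ci[0]), float(low_ci[1])), (float(high_ci[0]), float(high_ci[1]))
    raise ValueError(f"unknown mode {mode!r}; use 'approximate' or 'exact'")


class MeasurementTable:
    """Per-eye zone widths keyed by (eye_id, observer, method).

    Backed by a long-format DataFrame with columns ``eye_id``, ``observer``
    (1 or 2), ``method`` (``algorithm`` or ``imagej``), ``zone`` (one of
    :data:`ZONES`) and ``width_mm``.  Keys must be unique and widths
    positive.
    """

    REQUIRED = ("eye_id", "observer", "method", "zone", "width_mm")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"measurement table missing columns: {missing}")
        frame = frame.loc[:, list(self.REQUIRED)].copy()
        frame["observer"] = frame["observer"].astype(int)
        frame["method"] = frame["method"].astype(str).str.lower()
        frame["zone"] = frame["zone"].astype(str)
        frame["width_mm"] = frame["width_mm"].astype(float)
        bad_zone = set(frame["zone"]) - set(ZONES)
        if bad_zone:
            raise ValueError(f"unknown zones {sorted(bad_zone)}; expected {ZONES}")
        bad_method = set(frame["method"]) - set(METHODS)
        if bad_method:
            raise ValueError(f"unknown methods {sorted(bad_method)}; expected {METHODS}")
        if (frame["width_mm"] <= 0).any():
            bad = frame.loc[frame["width_mm"] <= 0]
            raise ValueError(f"non-positive widths for keys {bad[['eye_id', 'observer', 'method', 'zone']].values.tolist()}")
        keys = frame[["eye_id", "observer", "method", "zone"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].values.tolist()
            raise ValueError(f"duplicate measurement keys: {dup}")
        self.frame = frame

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeasurementTable":
        """Read a long-format CSV (columns eye_id, observer, method, zone, width_mm)."""
        return cls(pd.read_csv(path))

    @classmethod
    def from_wide_csv(
        cls, path: str | Path, column_map: dict[str, tuple[str, int, str]], eye_column: str = "eye_id"
    ) -> "MeasurementTable":
        """Read a wide-format CSV, one row per eye.

        ``column_map`` sends each measurement column name to a
        (zone, observer, method) triple, accommodating spreadsheet layouts
        with one column per zone x observer x method combination.
        """
        wide = pd.read_csv(path)
        if eye_column not in wide.columns:
            raise ValueError(f"wide table missing eye column {eye_column!r}")
        records = []
        for col, (zone, observer, method) in column_map.items():
            if col not in wide.columns:
                raise ValueError(f"wide table missing mapped column {col!r}")
            for eye, value in zip(wide[eye_column], wide[col]):
                records.append(
                    {"eye_id": eye, "observer": observer, "method": method, "zone": zone, "width_mm": value}
                )
        return cls(pd.DataFrame.from_records(records))

    def _series(self, zone: str, observer: int | None, method: str) -> pd.Series:
        f = self.frame
        sel = (f["zone"] == zone) & (f["method"] == method)
        if observer is not None:
            sel &= f["observer"] == observer
            sub = f.loc[sel].set_index("eye_id")["width_mm"]
            if sub.index.duplicated().any():
                raise ValueError(f"duplicate eyes for {zone}/{method}/obs{observer}")
            return sub
        # observer mean per eye
        sub = f.loc[sel].pivot(index="eye_id", columns="observer", values="width_mm")
        if sub.isna().any().any():
            missing = sub[sub.isna().any(axis=1)].index.tolist()
            raise ValueError(f"incomplete observer pairs for {zone}/{method}: eyes {missing}")
        return sub.mean(axis=1)


def agreement_report(
    table: MeasurementTable,
    comparison: str,
    method: str | None = None,
) -> dict[str, AgreementSummary]:
    """One AgreementSummary per zone for the requested comparison.

    ``comparison="inter_observer"`` compares observer 1 against observer 2
    within one ``method``; ``comparison="inter_method"`` compares the
    algorithm against ImageJ, each eye represented by the mean of the two
    observers' measurements.  Eyes must pair completely; missing partners
    are reported by key.
    """
    out: dict[str, AgreementSummary] = {}
    for zone in ZONES:
        if comparison == "inter_observer":
            if method is None:
                raise ValueError("inter_observer comparison requires method=")
            s1 = table._series(zone, 1, method)
            s2 = table._series(zone, 2, method)
            label_a, label_b = f"{method}_obs1", f"{method}_obs2"
        elif comparison == "inter_method":
            s1 = table._series(zone, None, "algorithm")
            s2 = table._series(zone, None, "imagej")
            label_a, label_b = "algorithm", "imagej"
        else:
            raise ValueError(
                f"unknown comparison {comparison!r}; use 'inter_observer' or 'inter_method'"
            )
        common = s1.index.intersection(s2.index)
        missing = s1.index.symmetric_difference(s2.index).tolist()
        if missing:
            raise ValueError(
                f"incomplete pairing for zone {zone!r}: unmatched eyes {missing}"
            )
        a = s1.loc[common].to_numpy()
        b = s2.loc[common].to_numpy()
        out[zone] = paired_summary(a, b, label_a=label_a, label_b=label_b)
    return out


def summary_frame(report: dict[str, AgreementSummary]) -> pd.DataFrame:
    """Render an agreement report as one DataFrame row per zone."""
    rows = {zone: s.as_row() for zone, s in report.items()}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "zone"
    return frame


def bland_altman_plot(a, b, summary: AgreementSummary, ax=None, title: str | None = None):
    """Difference-vs-mean plot with mean line, LoA and their CI bands."""
    import matplotlib.pyplot as plt

    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2, a - b, s=18, color="k", zorder=3)
    ax.axhline(summary.mean_diff, color="k", lw=1.5)
    for limit, ci in (
        (summary.loa_low, summary.loa_low_ci),
        (summary.loa_high, summary.loa_high_ci),
    ):
        ax.axhline(limit, color="k", ls="--", lw=1.0)
        ax.axhspan(ci[0], ci[1], color="grey", alpha=0.25, lw=0)
    ax.set_xlabel("mean of pair (mm)")
    ax.set_ylabel(f"{summary.label_a} - {summary.label_b} (mm)")
    if title:
        ax.set_title(title)
    return ax
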