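"""Signal-detection scoring of paired melanoma/nevus reader studies.

Each reader classifies the same images twice — once from the dermoscopy
image alone ("without") and once with the imaging-biomarker cue overlaid
("with") — against gold-standard pathology.  Melanoma is the positive
class throughout.  Per reader and condition we tally the confusion
counts, report sensitivity and specificity as percentages, and compute
the equal-variance Gaussian index of discriminability

    d' = z(hit rate) - z(false-alarm rate),

with the standard 1/(2n) correction when a rate is exactly 0 or 1.
Condition differences are compared with matched-sample t-tests
(df = readers - 1).

Report-table parity: published summary tables of this kind print
percentages to 1 decimal and derive d' from those printed (rounded)
percentages, so :func:`build_study_report` does the same by default;
``dprime_from="counts"`` switches to the raw count rates.  Display
rounding is decimal half-up (0.465 -> 0.47), not float banker's rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LABELS",
    "CONDITIONS",
    "ResponseTable",
    "ReaderPerformance",
    "PairedComparison",
    "DegenerateTestError",
    "dprime",
    "score_reader",
    "paired_test",
    "paired_test_from_differences",
    "build_study_report",
    "roc_pair_points",
    "plot_roc_pairs",
    "round_half_up",
]

LABELS = ("melanoma", "nevus")
CONDITIONS = ("without", "with")
REPORT_COLUMNS = [
    "sens_without",
    "spec_without",
    "sens_with",
    "spec_with",
    "sens_increase",
    "spec_increase",
    "dprime_without",
    "dprime_with",
    "dprime_increase",
]


class DegenerateTestError(ValueError):
    """Raised when a paired test is undefined (zero variance of differences)."""


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up of a float, as printed tables round."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class ResponseTable:
    """Paired per-reader binary decisions against ground truth.

    Wraps a DataFrame with columns ``reader_id, image_id, truth,
    decision_without, decision_with`` where the label columns take values
    ``melanoma`` / ``nevus``.  Every (reader, image) pair must be unique,
    both decisions must be present (paired design), and every reader must
    see at least one melanoma and one nevus.
    """

    COLUMNS = ["reader_id", "image_id", "truth", "decision_without", "decision_with"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"response table missing column(s): {missing}")
        df = df[self.COLUMNS].copy()
        if df.isna().any().any():
            raise ValueError("response table contains missing values (paired design)")
        for col in ("truth", "decision_without", "decision_with"):
            bad = set(df[col].unique()) - set(LABELS)
            if bad:
                raise ValueError(f"unknown label(s) {sorted(bad)} in column {col}")
        if df.duplicated(["reader_id", "image_id"]).any():
            raise ValueError("duplicate (reader_id, image_id) pairs")
        per_reader = df.groupby("reader_id")["truth"].agg(set)
        incomplete = [r for r, s in per_reader.items() if s != set(LABELS)]
        if incomplete:
            raise ValueError(
                f"reader(s) {incomplete} lack at least one melanoma and one nevus"
            )
        self.df = df

    @classmethod
    def from_csv(cls, path: str | Path) -> "ResponseTable":
        return cls(pd.read_csv(path, dtype=str))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @property
    def reader_ids(self) -> list:
        return list(dict.fromkeys(self.df["reader_id"]))

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class ReaderPerformance:
    """Confusion counts and accuracy of one reader in one condition."""

    reader_id: str
    condition: str
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    sensitivity: float = field(init=False)  # percent
    specificity: float = field(init=False)  # percent
    dprime: float = field(init=False)

    def __post_init__(self):
        n_pos = self.hits + self.misses
        n_neg = self.false_alarms + self.correct_rejections
        if n_pos == 0 or n_neg == 0:
            raise ValueError("need at least one melanoma and one nevus")
        object.__setattr__(self, "sensitivity", 100.0 * self.hits / n_pos)
        object.__setattr__(
            self, "specificity", 100.0 * self.correct_rejections / n_neg
        )
        object.__setattr__(
            self,
            "dprime",
            dprime(self.hits / n_pos, self.correct_rejections / n_neg, n_pos, n_neg),
        )

    @property
    def n_melanoma(self) -> int:
        return self.hits + self.misses

    @property
    def n_nevus(self) -> int:
        return self.false_alarms + self.correct_rejections


def dprime(
    sensitivity: float,
    specificity: float,
    n_pos: int | None = None,
    n_neg: int | None = None,
) -> float:
    """Equal-variance Gaussian discriminability from a (sens, spec) pair.

    Rates are proportions in [0, 1].  A rate of exactly 0 or 1 has an
    infinite z and is replaced by 1/(2n) or 1 - 1/(2n); the class size
    ``n_pos`` (melanomas) / ``n_neg`` (nevi) must then be supplied.
    """

    def _z(rate: float, n: int | None, what: str) -> float:
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{what} must lie in [0, 1], got {rate}")
        if rate in (0.0, 1.0):
            if n is None:
                raise ValueError(
                    f"{what} is exactly {rate:g}; provide the class size n to "
                    "apply the 1/(2n) extreme-rate correction"
                )
            rate = 1 / (2 * n) if rate == 0.0 else 1 - 1 / (2 * n)
        return float(stats.norm.ppf(rate))

    hit = _z(sensitivity, n_pos, "sensitivity")
    fa = _z(1.0 - specificity, n_neg, "false-alarm rate")
    return hit - fa


def score_reader(table: ResponseTable, reader_id: str, condition: str) -> ReaderPerformance:
    """Tally one reader's confusion counts in one condition."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    sub = table.df[table.df["reader_id"] == reader_id]
    if sub.empty:
        raise ValueError(f"reader {reader_id!r} not present in table")
    decision = sub[f"decision_{condition}"]
    is_mel = sub["truth"] == "melanoma"
    called_mel = decision == "melanoma"
    return ReaderPerformance(
        reader_id=reader_id,
        condition=condition,
        hits=int((is_mel & called_mel).sum()),
        misses=int((is_mel & ~called_mel).sum()),
        false_alarms=int((~is_mel & called_mel).sum()),
        correct_rejections=int((~is_mel & ~called_mel).sum()),
    )


@dataclass(frozen=True)
class PairedComparison:
    """Matched-sample t-test on per-reader condition differences."""

    metric: str
    differences: tuple  # with - without, one value per reader
    mean_diff: float
    sd_diff: float  # sample SD, n-1 denominator
    t_statistic: float
    df: int
    p_value: float
    sidedness: str  # "two" or "one"


def paired_test_from_differences(
    differences: Sequence[float], sidedness: str = "two", metric: str = ""
) -> PairedComparison:
    """Matched-sample t-test given the per-reader differences directly.

    One-sided tests the alternative that the mean difference is positive
    (the cue improves the metric).
    """
    if sidedness not in ("two", "one"):
        raise ValueError(f"sidedness must be 'two' or 'one', got {sidedness!r}")
    d = np.asarray(differences, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least two readers for a paired test")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise DegenerateTestError(
            "all per-reader differences are identical; t-test undefined"
        )
    t = mean / (sd / np.sqrt(n))
    if sidedness == "two":
        p = float(2 * stats.t.sf(abs(t), n - 1))
    else:
        p = float(stats.t.sf(t, n - 1))
    return PairedComparison(
        metric=metric,
        differences=tuple(d.tolist()),
        mean_diff=mean,
        sd_diff=sd,
        t_statistic=float(t),
        df=n - 1,
        p_value=p,
        sidedness=sidedness,
    )


def paired_test(
    values_without: Sequence[float],
    values_with: Sequence[float],
    sidedness: str = "two",
    metric: str = "",
) -> PairedComparison:
    """Matched-sample t-test of with-condition minus without-condition."""
    wo = np.asarray(values_without, dtype=float)
    wi = np.asarray(values_with, dtype=float)
    if wo.shape != wi.shape:
        raise ValueError("paired vectors must have equal length")
    return paired_test_from_differences(wi - wo, sidedness=sidedness, metric=metric)


def _report_row(perf_wo: ReaderPerformance, perf_wi: ReaderPerformance, dprime_from: str):
    sens_wo = round_half_up(perf_wo.sensitivity, 1)
    spec_wo = round_half_up(perf_wo.specificity, 1)
    sens_wi = round_half_up(perf_wi.sensitivity, 1)
    spec_wi = round_half_up(perf_wi.specificity, 1)
    if dprime_from == "rounded_rates":
        d_wo = dprime(sens_wo / 100, spec_wo / 100, perf_wo.n_melanoma, perf_wo.n_nevus)
        d_wi = dprime(sens_wi / 100, spec_wi / 100, perf_wi.n_melanoma, perf_wi.n_nevus)
    else:
        d_wo, d_wi = perf_wo.dprime, perf_wi.dprime
    return {
        "sens_without": sens_wo,
        "spec_without": spec_wo,
        "sens_with": sens_wi,
        "spec_with": spec_wi,
        "sens_increase": round_half_up(sens_wi - sens_wo, 1),
        "spec_increase": round_half_up(spec_wi - spec_wo, 1),
        "dprime_without": round_half_up(d_wo, 2),
        "dprime_with": round_half_up(d_wi, 2),
        "dprime_increase": round_half_up(d_wi - d_wo, 2),
    }


def _decimal_mean(cells: Iterable[float], ndigits: int) -> float:
    vals = [Decimal(repr(float(c))) for c in cells]
    mean = sum(vals) / Decimal(len(vals))
    return float(mean.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


def build_study_report(
    table: ResponseTable, dprime_from: str = "rounded_rates"
) -> pd.DataFrame:
    """Per-reader accuracy table in the conventional printed layout.

    One row per reader (order of first appearance) with sensitivity /
    specificity per condition and their increases (percent, 1 decimal),
    plus d' per condition and its increase (2 decimals), and a final
    ``Mean`` row averaging the rounded per-reader cells (percent means to
    2 decimals, d' means to 2 decimals, in exact decimal arithmetic).

    ``dprime_from``: ``"rounded_rates"`` (default) derives d' from the
    printed 1-decimal percentages so each row is self-consistent with what
    it displays; ``"counts"`` uses the raw count rates.
    """
    if dprime_from not in ("rounded_rates", "counts"):
        raise ValueError(f"dprime_from must be 'rounded_rates' or 'counts'")
    rows = {}
    for reader in table.reader_ids:
        perf_wo = score_reader(table, reader, "without")
        perf_wi = score_reader(table, reader, "with")
        rows[reader] = _report_row(perf_wo, perf_wi, dprime_from)
    report = pd.DataFrame.from_dict(rows, orient="index", columns=REPORT_COLUMNS)
    mean_row = {
        col: _decimal_mean(report[col], 2) for col in REPORT_COLUMNS
    }
    report.loc["Mean"] = mean_row
    report.index.name = "reader_id"
    return report


def roc_pair_points(report: pd.DataFrame) -> pd.DataFrame:
    """Per-reader paired ROC points from a study report.

    Returns, per reader, the operating points (1 - specificity,
    sensitivity) as proportions for both conditions: the segment from the
    "without" point to the "with" point is each reader's gain from the cue.
    """
    per_reader = report.drop(index="Mean", errors="ignore")
    out = pd.DataFrame(
        {
            "fpr_without": 1 - per_reader["spec_without"] / 100,
            "tpr_without": per_reader["sens_without"] / 100,
            "fpr_with": 1 - per_reader["spec_with"] / 100,
            "tpr_with": per_reader["sens_with"] / 100,
        }
    )
    if ((out < -1e-12) | (out > 1 + 1e-12)).any().any():
        raise ValueError("ROC points fall outside the unit square")
    return out


def plot_roc_pairs(points: pd.DataFrame, path: str | Path | None = None):
    """Render paired ROC points: red = without cue, green = with cue.

    Black segments connect each reader's two operating points.
    """
    from matplotlib.figure import Figure

    fig = Figure(figsize=(5, 5))
    ax = fig.add_subplot(111)
    for _, row in points.iterrows():
        ax.plot(
            [row.fpr_without, row.fpr_with],
            [row.tpr_without, row.tpr_with],
            color="black",
            lw=0.8,
            zorder=1,
        )
    ax.scatter(points.fpr_without, points.tpr_without, c="red", label="without cue", zorder=2)
    ax.scatter(points.fpr_with, points.tpr_with, c="green", label="with cue", zorder=2)
    ax.plot([0, 1], [0, 1], ls=":", c="gray", lw=0.8)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
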