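"""Published reader-study benchmark and its count-level reconstruction.

A published reader study had ten clinicians of varying dermoscopy
expertise classify the same set of 78 dermoscopic images (melanomas and
clinically atypical nevi) twice — first from the image alone, then with
the clock-sweep imaging-biomarker cue overlaid — and summarised each
reader's sensitivity, specificity and d' per condition in a printed
table.  That table is input data here: this module stores it verbatim,
reconstructs the underlying confusion counts from the printed
percentages (exhaustive integer-denominator search), rebuilds a
count-level :class:`~dermibc.readerstats.ResponseTable`, and reruns the
published comparisons.

One printed cell is internally inconsistent: the second
dermatopathologist's sensitivity increase is printed as 2.5 although the
row's own columns give 84.2 - 81.6 = 2.6.  That typo propagates to the
printed mean sensitivity increase (7.87; the consistent columns give
7.88) and to the two-sided p-value (the printed 0.0051 matches the test
on the with/without columns, while the printed increase column gives
0.0052).  Both computation routes are exposed; nothing is patched.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .readerstats import (
    ResponseTable,
    build_study_report,
    paired_test,
    paired_test_from_differences,
    round_half_up,
)

__all__ = [
    "published_reader_table",
    "reconstruct_denominators",
    "reconstruct_counts",
    "reconstruct_response_table",
    "analyze_reader_table",
    "N_IMAGES",
    "N_MELANOMA",
    "N_NEVUS",
]

N_IMAGES = 78  # images scored per reader in the benchmark study
N_MELANOMA = 38  # melanoma denominator implied by the printed percentages
N_NEVUS = 40  # nevus denominator implied by the printed percentages

# Printed per-reader summary: role, sensitivity/specificity without and
# with the cue, their increases, and d' without/with/increase, exactly as
# published (including the 2.5 typo discussed in the module docstring).
_ROWS = [
    ("Expert Dermoscopist", 71.1, 70.0, 81.6, 77.5, 10.5, 7.5, 1.08, 1.66, 0.57),
    ("Dermatopathologist", 81.6, 55.0, 94.7, 57.5, 13.1, 2.5, 1.03, 1.81, 0.78),
    ("Expert Dermoscopist", 92.1, 60.0, 92.1, 67.5, 0.0, 7.5, 1.67, 1.87, 0.20),
    ("Mohs Surgeon", 68.4, 57.5, 78.9, 60.0, 10.5, 2.5, 0.67, 1.06, 0.39),
    ("Dermatology Resident", 73.7, 57.5, 76.3, 55.0, 2.6, -2.5, 0.82, 0.84, 0.02),
    ("Dermatopathologist", 81.6, 70.0, 84.2, 62.5, 2.5, -7.5, 1.42, 1.32, -0.10),
    ("Mohs Surgeon", 57.9, 65.0, 71.1, 67.5, 13.2, 2.5, 0.58, 1.01, 0.43),
    ("Mohs Surgeon", 60.5, 55.0, 78.9, 70.0, 18.4, 15.0, 0.39, 1.33, 0.94),
    ("Expert Dermoscopist", 73.7, 62.5, 84.2, 75.0, 10.5, 12.5, 0.95, 1.68, 0.72),
    ("Mohs Surgeon", 76.3, 52.5, 73.7, 80.0, -2.6, 27.5, 0.78, 1.48, 0.70),
]
_COLUMNS = [
    "role",
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
_MEAN_ROW = (73.69, 60.50, 81.57, 67.25, 7.87, 6.75, 0.94, 1.41, 0.47)


def published_reader_table(include_mean: bool = False) -> pd.DataFrame:
    """The printed per-reader accuracy table of the benchmark study."""
    df = pd.DataFrame(_ROWS, columns=_COLUMNS)
    df.index = [f"reader_{i + 1:02d}" for i in range(len(df))]
    df.index.name = "reader_id"
    if include_mean:
        df.loc["Mean"] = ("Mean", *_MEAN_ROW)
    return df


def _denominator_fits(percentages, n: int) -> bool:
    """True if every printed percentage is round(100*k/n, 1) for some k."""
    return all(
        any(round_half_up(100.0 * k / n, 1) == round(p, 1) for k in range(n + 1))
        for p in percentages
    )


def reconstruct_denominators(
    table: pd.DataFrame | None = None, n_total: int = N_IMAGES
) -> tuple[int, int]:
    """Unique (n_melanoma, n_nevus) rationalizing every printed percentage.

    Exhaustive search over integer splits of ``n_total`` images: a split
    is feasible when every printed sensitivity is an integer count over
    the melanoma denominator (to 1 decimal) and likewise for specificity.
    Raises if no split or more than one split fits.
    """
    if table is None:
        table = published_reader_table()
    sens = list(table["sens_without"]) + list(table["sens_with"])
    spec = list(table["spec_without"]) + list(table["spec_with"])
    solutions = [
        (n_pos, n_total - n_pos)
        for n_pos in range(1, n_total)
        if _denominator_fits(sens, n_pos) and _denominator_fits(spec, n_total - n_pos)
    ]
    if len(solutions) != 1:
        raise ValueError(
            f"denominator reconstruction not unique for total {n_total}: {solutions}"
        )
    return solutions[0]


def _count_from_percentage(pct: float, n: int, what: str) -> int:
    matches = [k for k in range(n + 1) if round_half_up(100.0 * k / n, 1) == round(pct, 1)]
    if len(matches) != 1:
        raise ValueError(f"{what} = {pct}% has {len(matches)} count solutions over n={n}")
    return matches[0]


def reconstruct_counts(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-reader confusion counts implied by the printed percentages."""
    if table is None:
        table = published_reader_table()
    n_pos, n_neg = reconstruct_denominators(table)
    out = {}
    for reader, row in table.iterrows():
        out[reader] = {
            "hits_without": _count_from_percentage(row.sens_without, n_pos, "sensitivity"),
            "cr_without": _count_from_percentage(row.spec_without, n_neg, "specificity"),
            "hits_with": _count_from_percentage(row.sens_with, n_pos, "sensitivity"),
            "cr_with": _count_from_percentage(row.spec_with, n_neg, "specificity"),
        }
    df = pd.DataFrame.from_dict(out, orient="index")
    df["n_melanoma"] = n_pos
    df["n_nevus"] = n_neg
    return df


def reconstruct_response_table(table: pd.DataFrame | None = None) -> ResponseTable:
    """Deterministic count-level response table matching the printed summary.

    Decisions are assigned to image ids in a fixed order (the first k
    melanomas are the hits, etc.); only the per-reader marginal counts are
    constrained by the printed table, not which image drew which call.
    """
    counts = reconstruct_counts(table)
    n_pos = int(counts["n_melanoma"].iloc[0])
    n_neg = int(counts["n_nevus"].iloc[0])
    image_ids = [f"mel_{i + 1:03d}" for i in range(n_pos)] + [
        f"nev_{i + 1:03d}" for i in range(n_neg)
    ]
    truth = ["melanoma"] * n_pos + ["nevus"] * n_neg
    records = []
    for reader, row in counts.iterrows():
        decisions = {}
        for cond in ("without", "with"):
            h = int(row[f"hits_{cond}"])
            cr = int(row[f"cr_{cond}"])
            mel_calls = ["melanoma"] * h + ["nevus"] * (n_pos - h)
            nev_calls = ["nevus"] * cr + ["melanoma"] * (n_neg - cr)
            decisions[cond] = mel_calls + nev_calls
        for i, image_id in enumerate(image_ids):
            records.append(
                {
                    "reader_id": reader,
                    "image_id": image_id,
                    "truth": truth[i],
                    "decision_without": decisions["without"][i],
                    "decision_with": decisions["with"][i],
                }
            )
    return ResponseTable(pd.DataFrame.from_records(records))


def analyze_reader_table(
    table: pd.DataFrame | None = None, sidedness: str = "two"
) -> dict:
    """Rerun the published paired comparisons on a printed summary table.

    For each metric the matched-sample t-test is computed two ways: from
    the with/without columns (``from_columns``) and from the printed
    increase column taken as the differences (``from_increase_column``).
    The two agree except where the printed increase column is internally
    inconsistent with its own summary columns.
    """
    if table is None:
        table = published_reader_table()
    out = {}
    for metric, wo_col, wi_col, inc_col in [
        ("sensitivity", "sens_without", "sens_with", "sens_increase"),
        ("specificity", "spec_without", "spec_with", "spec_increase"),
        ("dprime", "dprime_without", "dprime_with", "dprime_increase"),
    ]:
        out[metric] = {
            "from_columns": paired_test(
                table[wo_col], table[wi_col], sidedness=sidedness, metric=metric
            ),
            "from_increase_column": paired_test_from_differences(
                table[inc_col], sidedness=sidedness, metric=metric
            ),
        }
    return out
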