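"""Rater-agreement statistics for thrombus calls against a contrast reference.

The study design is n patients rated by k readers (two blinded observers of
the enhanced loops plus contrast echocardiography as the reference), each call
one of {positive, negative, nondiagnostic}.  This module provides:

* confusion counts and the standard diagnostic metrics (sensitivity,
  specificity, PPV, NPV, accuracy) in exact rational arithmetic;
* the single-operating-point ROC area, ``AUC = (Se + Sp) / 2``;
* the tie-corrected Friedman test over related rating columns, with
  mid-ranks within each patient row and the standard correction divisor
  ``C = 1 - sum(t^3 - t) / (n k (k^2 - 1))`` — binary ratings are heavily
  tied, so the correction is essential;
* a reconstruction of the full study rating table from its published
  marginal counts, shipped as a packaged CSV fixture.

Ratings enter as pandas DataFrames (rows = patients, columns = raters).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

__all__ = [
    "CATEGORIES",
    "POSITIVE",
    "NEGATIVE",
    "NONDIAGNOSTIC",
    "ConfusionCounts",
    "DiagnosticMetrics",
    "FriedmanResult",
    "confusion",
    "diagnostic_metrics",
    "binary_auc",
    "friedman_test",
    "chi2_upper_tail",
    "reconstruct_study_table",
    "find_overlap",
    "load_ratings",
    "study_table",
    "evaluate_ratings",
]

POSITIVE = "positive"
NEGATIVE = "negative"
NONDIAGNOSTIC = "nondiagnostic"
CATEGORIES = (POSITIVE, NEGATIVE, NONDIAGNOSTIC)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN of one rater against the reference (nondiagnostic excluded)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _percent(x: Fraction | None) -> int | None:
    """Round a rational proportion to a whole percentage, half away from zero."""
    if x is None:
        return None
    return int((200 * x + 1) // 2)  # floor((100x) + 1/2) in exact arithmetic


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Diagnostic test metrics as exact rationals; ``None`` marks 0/0 ratios."""

    sensitivity: Fraction | None
    specificity: Fraction | None
    ppv: Fraction | None
    npv: Fraction | None
    accuracy: Fraction | None

    def as_percentages(self) -> dict[str, int | None]:
        """Whole-number percentages, the precision used for reporting."""
        return {
            "sensitivity": _percent(self.sensitivity),
            "specificity": _percent(self.specificity),
            "ppv": _percent(self.ppv),
            "npv": _percent(self.npv),
            "accuracy": _percent(self.accuracy),
        }


@dataclass(frozen=True)
class FriedmanResult:
    """Tie-corrected Friedman test over k related rating columns."""

    rank_sums: np.ndarray
    mean_ranks: np.ndarray
    chi_square: float
    df: int
    p_value: float
    tie_correction: float
    degenerate: bool = False  # every row fully tied: the table carries no information


def _codes(column: pd.Series | np.ndarray) -> np.ndarray:
    """Map categorical calls to codes: negative=0, positive=1, nondiagnostic=-1."""
    arr = np.asarray(column)
    if arr.dtype.kind in "iufb":
        return arr.astype(int)
    out = np.empty(arr.shape, dtype=int)
    for idx, val in np.ndenumerate(arr):
        v = str(val).strip().lower()
        if v == POSITIVE:
            out[idx] = 1
        elif v == NEGATIVE:
            out[idx] = 0
        elif v in (NONDIAGNOSTIC, "non-diagnostic"):
            out[idx] = -1
        else:
            raise ValueError(f"unknown rating category {val!r} at position {idx}")
    return out


def confusion(ratings, reference) -> ConfusionCounts:
    """Cross-tabulate one rater's calls against the reference.

    Nondiagnostic entries in either column are excluded pairwise, so the
    counts cover only patients evaluable by both.
    """
    r = _codes(ratings)
    ref = _codes(reference)
    if r.shape != ref.shape:
        raise ValueError("rater and reference columns differ in length")
    keep = (r >= 0) & (ref >= 0)
    r, ref = r[keep], ref[keep]
    return ConfusionCounts(
        tp=int(np.sum((r == 1) & (ref == 1))),
        fp=int(np.sum((r == 1) & (ref == 0))),
        fn=int(np.sum((r == 0) & (ref == 1))),
        tn=int(np.sum((r == 0) & (ref == 0))),
    )


def _ratio(num: int, den: int) -> Fraction | None:
    return None if den == 0 else Fraction(num, den)


def diagnostic_metrics(counts: ConfusionCounts) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy from confusion counts.

    Ratios with a zero denominator are returned as ``None`` (undefined), not
    silently zeroed.
    """
    return DiagnosticMetrics(
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        npv=_ratio(counts.tn, counts.tn + counts.fn),
        accuracy=_ratio(counts.tp + counts.tn, counts.n),
    )


def binary_auc(counts: ConfusionCounts) -> float:
    """ROC area of a single operating point.

    The ROC through (0,0), (1-Sp, Se), (1,1) has trapezoidal area
    (Se + Sp) / 2.
    """
    m = diagnostic_metrics(counts)
    if m.sensitivity is None or m.specificity is None:
        raise ValueError("AUC undefined: sensitivity or specificity has zero denominator")
    return float((m.sensitivity + m.specificity) / 2)


def chi2_upper_tail(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution (for df=2, exp(-x/2))."""
    if x < 0:
        raise ValueError("chi-square statistic must be non-negative")
    if df < 1:
        raise ValueError("df must be a positive integer")
    return float(stats.chi2.sf(x, df))


def friedman_test(table) -> FriedmanResult:
    """Tie-corrected Friedman test for k related samples over n blocks.

    Within each row (patient) the k ratings receive mid-ranks; tied values
    share the average of the ranks they span.  With column rank sums Rj the
    uncorrected statistic is

        chi2_u = 12 * sum(Rj^2) / (n k (k+1)) - 3 n (k+1)

    and the tie correction divides by

        C = 1 - sum_rows sum_tiegroups (t^3 - t) / (n k (k^2 - 1)).

    Binary tables are almost entirely ties, so C is far below 1.  If every
    row is fully tied (C = 0) the table carries no information: the result is
    flagged degenerate with chi_square 0 and p 1.
    """
    if isinstance(table, pd.DataFrame):
        data = np.column_stack([_codes(table[c]) for c in table.columns]).astype(float)
        data = data[~np.any(data < 0, axis=1)]  # listwise exclusion of nondiagnostic
    else:
        data = np.asarray(table, dtype=float)
    if data.ndim != 2:
        raise ValueError("rating table must be 2-D (patients x raters)")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 blocks and 2 raters, got {n}x{k}")
    ranks = np.apply_along_axis(rankdata, 1, data)  # mid-ranks within each row
    rank_sums = ranks.sum(axis=0)
    chi2_u = 12.0 * np.sum(rank_sums**2) / (n * k * (k + 1)) - 3.0 * n * (k + 1)
    tie_term = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    C = 1.0 - tie_term / (n * k * (k**2 - 1))
    df = k - 1
    if C <= 0:
        return FriedmanResult(
            rank_sums=rank_sums,
            mean_ranks=rank_sums / n,
            chi_square=0.0,
            df=df,
            p_value=1.0,
            tie_correction=0.0,
            degenerate=True,
        )
    chi_square = chi2_u / C
    # chi2_u can be a tiny negative number from floating round-off when all
    # rank sums are equal
    chi_square = max(chi_square, 0.0)
    return FriedmanResult(
        rank_sums=rank_sums,
        mean_ranks=rank_sums / n,
        chi_square=float(chi_square),
        df=df,
        p_value=chi2_upper_tail(chi_square, df),
        tie_correction=float(C),
    )


# -- study table reconstruction ----------------------------------------------

_STUDY_N = 29
_STUDY_OBS1_POS = 14
_STUDY_OBS2_POS = 15
_STUDY_REF_POS = 11
_STUDY_COLUMNS = ("observer_1", "observer_2", "contrast")


def reconstruct_study_table(
    n: int = _STUDY_N,
    rater1_pos: int = _STUDY_OBS1_POS,
    rater2_pos: int = _STUDY_OBS2_POS,
    reference_pos: int = _STUDY_REF_POS,
    overlap: int = 1,
) -> pd.DataFrame:
    """Build a patients x (rater1, rater2, reference) binary rating table from marginals.

    The construction assumes no false negatives for either rater (both call
    every reference-positive patient positive), so each rater's extra
    positives are overcalls among the reference-negatives.  ``overlap`` is
    the number of reference-negative patients overcalled by *both* raters —
    the one degree of freedom the marginals leave open.  The packaged study
    fixture uses overlap=1 (see :func:`find_overlap`).

    Column rank sums of the Friedman ranking depend only on the marginals,
    not on ``overlap``; the tie structure (hence the corrected statistic)
    does depend on it.
    """
    e1 = rater1_pos - reference_pos  # rater 1 overcalls
    e2 = rater2_pos - reference_pos
    neg = n - reference_pos
    if e1 < 0 or e2 < 0:
        raise ValueError(
            "marginals violate the no-false-negative constraint: "
            "each rater must call at least every reference positive"
        )
    if reference_pos < 0 or reference_pos > n:
        raise ValueError("reference positives must lie in [0, n]")
    if not (max(0, e1 + e2 - neg) <= overlap <= min(e1, e2)):
        raise ValueError(
            f"overlap={overlap} inconsistent with marginals: "
            f"needs {max(0, e1 + e2 - neg)} <= overlap <= {min(e1, e2)}"
        )
    rows: list[tuple[int, int, int]] = []
    rows += [(1, 1, 1)] * reference_pos
    rows += [(1, 1, 0)] * overlap
    rows += [(1, 0, 0)] * (e1 - overlap)
    rows += [(0, 1, 0)] * (e2 - overlap)
    rows += [(0, 0, 0)] * (neg - e1 - e2 + overlap)
    labels = np.array([NEGATIVE, POSITIVE])
    data = labels[np.array(rows)]
    return pd.DataFrame(
        data,
        columns=list(_STUDY_COLUMNS),
        index=pd.Index([f"patient_{i + 1:02d}" for i in range(n)], name="patient_id"),
    )


def find_overlap(target_chi_square: float = 4.333, tol: float = 5e-4) -> int:
    """Identify the shared-overcall count by brute force against the reported statistic.

    Enumerates every overlap value the study marginals allow, computes the
    tie-corrected Friedman statistic of each candidate table, and returns the
    value whose statistic matches ``target_chi_square`` at the reported
    3-decimal precision.  Raises if no candidate (or more than one) matches.
    """
    matches = []
    e1 = _STUDY_OBS1_POS - _STUDY_REF_POS
    e2 = _STUDY_OBS2_POS - _STUDY_REF_POS
    for a in range(0, min(e1, e2) + 1):
        table = reconstruct_study_table(overlap=a)
        chi = friedman_test(table).chi_square
        if abs(chi - target_chi_square) < tol:
            matches.append(a)
    if len(matches) != 1:
        raise ValueError(
            f"expected exactly one overlap matching chi-square {target_chi_square}, "
            f"found {matches}"
        )
    return matches[0]


def load_ratings(path: str | Path, index_col: int | str | None = 0) -> pd.DataFrame:
    """Read a rating CSV (rows = patients, columns = raters + reference).

    Every cell must be one of {positive, negative, nondiagnostic}; a bad
    token is rejected naming the row and column.
    """
    df = pd.read_csv(path, index_col=index_col)
    for col in df.columns:
        for row_label, val in df[col].items():
            v = str(val).strip().lower()
            if v not in CATEGORIES and v != "non-diagnostic":
                raise ValueError(
                    f"{path}: unknown rating category {val!r} in row {row_label!r}, "
                    f"column {col!r}"
                )
    return df


def study_table() -> pd.DataFrame:
    """The packaged 29-patient study fixture (overlap = 1)."""
    with resources.as_file(resources.files("lvtdm.data") / "study_ratings.csv") as p:
        return load_ratings(p)


def evaluate_ratings(table: pd.DataFrame, reference: str = "contrast") -> dict:
    """Full evaluation report: per-rater counts, metrics, AUC, plus the Friedman test.

    Returns a JSON-serializable dict.  Metrics are reported as whole-number
    percentages and AUC to 3 decimals; the exact fractions are also included.
    """
    if reference not in table.columns:
        raise ValueError(f"reference column {reference!r} not in table columns {list(table.columns)}")
    raters = [c for c in table.columns if c != reference]
    report: dict = {"reference": reference, "n_patients": int(len(table)), "raters": {}}
    for rater in raters:
        counts = confusion(table[rater], table[reference])
        metrics = diagnostic_metrics(counts)
        entry = {
            "counts": {"tp": counts.tp, "fp": counts.fp, "fn": counts.fn, "tn": counts.tn},
            "metrics_percent": metrics.as_percentages(),
            "metrics_exact": {
                name: (None if frac is None else [frac.numerator, frac.denominator])
                for name, frac in (
                    ("sensitivity", metrics.sensitivity),
                    ("specificity", metrics.specificity),
                    ("ppv", metrics.ppv),
                    ("npv", metrics.npv),
                    ("accuracy", metrics.accuracy),
                )
            },
        }
        try:
            entry["auc"] = round(binary_auc(counts), 3)
        except ValueError:
            entry["auc"] = None
        report["raters"][str(rater)] = entry
    fr = friedman_test(table)
    report["friedman"] = {
        "columns": [str(c) for c in table.columns],
        "rank_sums": [float(r) for r in fr.rank_sums],
        "mean_ranks": [round(float(r), 2) for r in fr.mean_ranks],
        "chi_square": round(fr.chi_square, 3),
        "df": fr.df,
        "p_value": round(fr.p_value, 3),
        "tie_correction": fr.tie_correction,
        "degenerate": fr.degenerate,
    }
    return report
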