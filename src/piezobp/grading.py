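"""Agreement statistics and BHS letter grading for BP estimates.

Errors follow the pred - ref sign convention throughout.  The British
Hypertension Society (BHS) scheme grades a device by the cumulative
percentage of absolute errors under 5, 10 and 15 mmHg: Grade A requires
at least 60/85/95%, B at least 50/75/90%, C at least 40/65/85%, and
anything weaker is D.  The comparison at each threshold is strict
("difference < 5 mmHg"); an inclusive variant is available via
``strict=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError

__all__ = [
    "ErrorStats",
    "BlandAltman",
    "BhsReport",
    "BHS_THRESHOLDS_MMHG",
    "BHS_GRADE_TABLE",
    "error_stats",
    "bland_altman",
    "bhs_grade",
]

BHS_THRESHOLDS_MMHG = (5.0, 10.0, 15.0)

#: Minimum cumulative percentages (at 5/10/15 mmHg) per letter grade.
BHS_GRADE_TABLE = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}


@dataclass(frozen=True)
class ErrorStats:
    mean_error: float  # mmHg, pred - ref
    sd: float  # sample SD (n-1)
    mae: float
    rmse: float
    pearson_r: float | None  # None when either input has zero variance
    n: int


@dataclass(frozen=True)
class BlandAltman:
    bias: float  # mean difference, mmHg
    loa_lower: float  # bias - 1.96 SD
    loa_upper: float  # bias + 1.96 SD


@dataclass(frozen=True)
class BhsReport:
    pct_within: tuple[float, float, float]  # cumulative % under 5/10/15 mmHg
    grade: str  # A-D


def _paired(pred, ref) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise DataError("pred and ref must be equal-length 1-D arrays")
    if pred.size < 2:
        raise DataError("need at least 2 paired values")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(ref))):
        raise DataError("non-finite values in input")
    return pred, ref


def error_stats(pred, ref) -> ErrorStats:
    """Mean error, SD, MAE, RMSE and Pearson r of paired estimates."""
    pred, ref = _paired(pred, ref)
    err = pred - ref
    if np.std(pred) == 0 or np.std(ref) == 0:
        r = None  # correlation undefined for constant input
    else:
        r = float(stats.pearsonr(pred, ref).statistic)
    return ErrorStats(
        mean_error=float(np.mean(err)),
        sd=float(np.std(err, ddof=1)),
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err**2))),
        pearson_r=r,
        n=pred.size,
    )


def bland_altman(pred, ref) -> BlandAltman:
    """Bias and 95% limits of agreement (bias +/- 1.96 SD)."""
    pred, ref = _paired(pred, ref)
    err = pred - ref
    bias = float(np.mean(err))
    sd = float(np.std(err, ddof=1))
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd)


def bhs_grade(errors, strict: bool = True) -> BhsReport:
    """Cumulative error percentages at 5/10/15 mmHg and the BHS letter grade."""
    errors = np.atleast_1d(np.asarray(errors, dtype=float))
    if errors.size == 0:
        raise DataError("empty error list")
    abs_err = np.abs(errors)
    compare = np.less if strict else np.less_equal
    pct = tuple(float(100.0 * np.mean(compare(abs_err, t))) for t in BHS_THRESHOLDS_MMHG)
    grade = "D"
    for letter, mins in BHS_GRADE_TABLE.items():
        if all(p >= m for p, m in zip(pct, mins)):
            grade = letter
            break
    return BhsReport(pct, grade)
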