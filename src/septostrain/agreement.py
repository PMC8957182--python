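"""Agreement and reliability statistics.

The statistical battery used to assess test-retest, intra-observer and
inter-observer agreement of strain indices:

- normalized strain-curve similarity (Pearson r after amplitude
  normalization and down-sampling of the longer cycle),
- Bland-Altman bias and 95% limits of agreement,
- intraclass correlation ICC(A,1): two-way model, absolute agreement,
  single measurement (McGraw & Wong), with an F-based 95% CI,
- Cohen's kappa for categorical agreement of exercise-induced changes,
- the paired Student's t-test,
- feasibility tallies (acquired / attended-twice / sufficient-quality
  counts and grade distributions per exercise intensity).

Formulas are implemented explicitly from the ANOVA mean squares so they
can be verified against independent oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .curves import StrainCurve
from .errors import (
    DegenerateVarianceError,
    InsufficientDataError,
    MissingDataError,
    UndefinedCorrelationError,
    UndefinedKappaError,
    UndefinedTestError,
)

__all__ = [
    "PairedMeasurements",
    "BlandAltmanResult",
    "ICCResult",
    "AgreementReport",
    "curve_similarity",
    "bland_altman",
    "icc_absolute_single",
    "cohen_kappa",
    "paired_ttest",
    "feasibility_tally",
    "agreement_report",
]

logger = logging.getLogger(__name__)

_CONTEXTS = ("test_retest", "intra_observer", "inter_observer")


@dataclass
class PairedMeasurements:
    """Paired measurements of one metric (same units in both columns).

    Incomplete pairs (NaN in either column) are dropped with a logged
    count; at least two complete pairs are required for any statistic.
    """

    value_a: np.ndarray
    value_b: np.ndarray
    subject_ids: np.ndarray | None = None
    condition: str = ""
    context: str = "test_retest"

    def __post_init__(self) -> None:
        if self.context not in _CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        a = np.asarray(self.value_a, dtype=float)
        b = np.asarray(self.value_b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("value_a and value_b must be 1-D and equally long")
        ids = (
            np.asarray(self.subject_ids)
            if self.subject_ids is not None
            else np.arange(len(a))
        )
        keep = np.isfinite(a) & np.isfinite(b)
        dropped = int((~keep).sum())
        if dropped:
            logger.info(
                "dropping %d incomplete pair(s) for %s/%s",
                dropped,
                self.condition,
                self.context,
            )
        self.value_a = a[keep]
        self.value_b = b[keep]
        self.subject_ids = ids[keep]
        self.n_dropped = dropped

    @property
    def n_pairs(self) -> int:
        return len(self.value_a)

    @property
    def differences(self) -> np.ndarray:
        return self.value_a - self.value_b


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "sd": self.sd,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "n_pairs": self.n_pairs,
        }


def bland_altman(pairs: PairedMeasurements) -> BlandAltmanResult:
    """Bland-Altman agreement: bias, SD and 1.96-SD limits of agreement.

    Differences are ``value_a - value_b``; limits are reported in the
    measurement's own (absolute) units.
    """
    if pairs.n_pairs < 2:
        raise InsufficientDataError(
            f"Bland-Altman needs >= 2 complete pairs, got {pairs.n_pairs}"
        )
    d = pairs.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n_pairs=pairs.n_pairs,
    )


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_raters: int

    def to_dict(self) -> dict:
        return {
            "icc": self.icc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_subjects": self.n_subjects,
            "n_raters": self.n_raters,
        }


def icc_absolute_single(
    matrix: np.ndarray, confidence: float = 0.95
) -> ICCResult:
    """ICC(A,1): two-way model, absolute agreement, single measurement.

    From the two-way ANOVA mean squares (rows = subjects, MSR; columns =
    raters, MSC; residual, MSE)::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with the McGraw-Wong F-based confidence interval.
    """
    y = np.asarray(matrix, dtype=float)
    if y.ndim != 2:
        raise ValueError("matrix must be subjects x raters")
    n, k = y.shape
    if n < 3 or k < 2:
        raise InsufficientDataError("need >= 3 subjects and >= 2 raters")
    if not np.isfinite(y).all():
        raise MissingDataError("incomplete matrix; no imputation is performed")

    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 1e-12:
        raise DegenerateVarianceError("zero variance: ICC undefined")
    icc = (msr - mse) / denom

    # McGraw & Wong (1996) CI for ICC(A,1)
    alpha = 1.0 - confidence
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a) and mse > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1.0 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1.0 - alpha / 2, v, n - 1)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:
        lower = upper = icc
    lower = min(lower, icc)
    upper = max(upper, icc)
    return ICCResult(
        icc=float(icc),
        ci_low=float(lower),
        ci_high=float(upper),
        n_subjects=n,
        n_raters=k,
    )


def cohen_kappa(ratings_a, ratings_b) -> float:
    """Cohen's kappa: chance-corrected agreement of two categorical raters."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("ratings must be equally long 1-D vectors of length >= 2")
    cats = np.unique(np.concatenate([a, b]))
    n = len(a)
    p_o = float((a == b).mean())
    p_e = 0.0
    for c in cats:
        p_e += float((a == c).mean()) * float((b == c).mean())
    if abs(1.0 - p_e) < 1e-12:
        raise UndefinedKappaError(
            "both raters constant and identical: chance agreement is 1"
        )
    return (p_o - p_e) / (1.0 - p_e)


def paired_ttest(pairs: PairedMeasurements) -> tuple[float, float]:
    """Paired Student's t-test on the pair differences (two-sided)."""
    if pairs.n_pairs < 2:
        raise InsufficientDataError("paired t-test needs >= 2 pairs")
    d = pairs.differences
    sd = d.std(ddof=1)
    if sd < 1e-12:
        raise UndefinedTestError("zero-variance differences: t undefined")
    n = len(d)
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return t, p


def curve_similarity(curve_a: StrainCurve, curve_b: StrainCurve) -> float:
    """Pearson correlation of two normalized strain curves.

    The longer curve is down-sampled by linear interpolation to the
    shorter curve's sample count (cycle-length differences between
    visits come from heart-rate differences); both are then divided by
    their peak absolute strain and correlated.
    """
    a, b = curve_a, curve_b
    if a.n_samples > b.n_samples:
        a = a.resampled(b.n_samples)
    elif b.n_samples > a.n_samples:
        b = b.resampled(a.n_samples)
    xa, xb = a.strain, b.strain
    if np.ptp(xa) < 1e-12 or np.ptp(xb) < 1e-12:
        raise UndefinedCorrelationError("constant curve: correlation undefined")
    xa = xa / np.abs(xa).max()
    xb = xb / np.abs(xb).max()
    return float(np.corrcoef(xa, xb)[0, 1])


def feasibility_tally(acquisition_log: pd.DataFrame) -> pd.DataFrame:
    """Acquisition/quality accounting per condition and overall.

    ``acquisition_log`` needs one row per potential loop with boolean
    columns ``acquired``, ``attended_both_visits``, ``sufficient_quality``
    and a ``grade`` column (good / moderate / poor, NaN if not graded),
    plus a ``condition`` label. Percentages of attended-twice and
    sufficient-quality are relative to acquired loops; grade percentages
    are relative to graded loops.
    """
    cols = ["condition", "acquired", "attended_both_visits", "sufficient_quality", "grade"]
    if acquisition_log.empty:
        return pd.DataFrame(
            columns=[
                "condition", "n_potential", "n_acquired", "pct_acquired",
                "n_attended_both", "pct_attended_both", "n_sufficient",
                "pct_sufficient", "n_good", "n_moderate", "n_poor",
                "pct_good", "pct_moderate", "pct_poor",
            ]
        )
    missing = set(cols) - set(acquisition_log.columns)
    if missing:
        raise ValueError(f"acquisition log lacks columns {sorted(missing)}")

    def _one(group: pd.DataFrame, label: str) -> dict:
        n_pot = len(group)
        n_acq = int(group["acquired"].sum())
        acq = group[group["acquired"].astype(bool)]
        n_att = int(acq["attended_both_visits"].sum())
        n_suf = int(acq["sufficient_quality"].sum())
        graded = acq["grade"].dropna()
        n_graded = len(graded)
        out = {
            "condition": label,
            "n_potential": n_pot,
            "n_acquired": n_acq,
            "pct_acquired": 100.0 * n_acq / n_pot if n_pot else np.nan,
            "n_attended_both": n_att,
            "pct_attended_both": 100.0 * n_att / n_acq if n_acq else np.nan,
            "n_sufficient": n_suf,
            "pct_sufficient": 100.0 * n_suf / n_acq if n_acq else np.nan,
        }
        for g in ("good", "moderate", "poor"):
            ng = int((graded == g).sum())
            out[f"n_{g}"] = ng
            out[f"pct_{g}"] = 100.0 * ng / n_graded if n_graded else np.nan
        return out

    rows = [
        _one(g, str(label))
        for label, g in acquisition_log.groupby("condition", sort=True)
    ]
    rows.append(_one(acquisition_log, "overall"))
    return pd.DataFrame(rows)


@dataclass
class AgreementReport:
    """Full agreement summary for one set of paired measurements."""

    context: str
    condition: str
    n_pairs: int
    bland_altman: BlandAltmanResult
    icc: ICCResult | None
    pearson_r: float | None
    t_stat: float | None
    p_value: float | None
    kappa: float | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "context": self.context,
            "condition": self.condition,
            "n_pairs": self.n_pairs,
            "bland_altman": self.bland_altman.to_dict(),
            "icc": self.icc.to_dict() if self.icc else None,
            "pearson_r": self.pearson_r,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
            "kappa": self.kappa,
            "notes": self.notes,
        }


def agreement_report(pairs: PairedMeasurements) -> AgreementReport:
    """Bland-Altman + ICC(A,1) + Pearson r + paired t for one pairing.

    Statistics that are undefined for the data at hand (degenerate
    variance, too few pairs) are reported as None with a note rather
    than raising, so a cohort report never aborts on one condition.
    """
    notes: list[str] = []
    ba = bland_altman(pairs)
    icc = None
    try:
        icc = icc_absolute_single(
            np.stack([pairs.value_a, pairs.value_b], axis=1)
        )
    except (InsufficientDataError, DegenerateVarianceError) as exc:
        notes.append(f"icc: {exc}")
    r = None
    if pairs.value_a.std() > 1e-12 and pairs.value_b.std() > 1e-12:
        r = float(np.corrcoef(pairs.value_a, pairs.value_b)[0, 1])
    else:
        notes.append("pearson_r: zero variance")
    t = p = None
    try:
        t, p = paired_ttest(pairs)
    except (InsufficientDataError, UndefinedTestError) as exc:
        notes.append(f"paired_t: {exc}")
    return AgreementReport(
        context=pairs.context,
        condition=pairs.condition,
        n_pairs=pairs.n_pairs,
        bland_altman=ba,
        icc=icc,
        pearson_r=r,
        t_stat=t,
        p_value=p,
        notes=notes,
    )
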