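"""Agreement and reliability statistics for paired angle traces.

The two time-normalized traces of an :class:`~mvkin.alignment.AlignedTracePair`
form an n x 2 ratings table: the n normalized frames play the role of
subjects and the two measurement systems the role of raters.  On that table
the module computes:

* the two-way, one-observation-per-cell ANOVA mean squares,
* Shrout–Fleiss intraclass correlations — ICC(2,1) two-way random absolute
  agreement (the default for concurrent validity), ICC(3,1) two-way mixed
  consistency, and ICC(3,k) average-measures consistency — each with exact
  F-based 95% confidence intervals (McGraw & Wong),
* the method-error coefficient of variation (Dahlberg form by default),
* the standard error of measurement SEM = SD * sqrt(1 - ICC), and
* the minimal detectable change MDC95 = 1.96 * sqrt(2) * SEM.

``literal`` variants of CV and SEM evaluate the formulas exactly as some
reports print them (without the radicals); they exist for fidelity audits
and are never the default.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist

from .alignment import AlignedTracePair
from .errors import ConfigurationError, UndefinedStatisticError

__all__ = [
    "MeanSquares",
    "IccEstimate",
    "ReliabilityResult",
    "two_way_mean_squares",
    "icc",
    "cv_method_error",
    "sem",
    "mdc95",
    "classify_icc",
    "reliability_report",
    "ICC_FORMS",
    "MDC_FACTOR",
]

ICC_FORMS = ("icc21", "icc31", "icc3k")
#: MDC95 / SEM, i.e. 1.96 * sqrt(2)
MDC_FACTOR = 1.96 * math.sqrt(2.0)

# ICC interpretation bands: (exclusive upper edge, label); a value on a band
# boundary falls in the upper band.  The "methods" scheme keeps 0.90 itself in
# "good" (its bands are printed as closed ranges), hence the nextafter edge.
_BANDS = {
    # scheme used to label the study's results
    "results": ((0.4, "poor"), (0.6, "normal"), (0.75, "good"), (math.inf, "very good")),
    # alternative scheme sometimes quoted in methods sections
    "methods": (
        (0.5, "poor"),
        (0.76, "moderate"),
        (float(np.nextafter(0.90, np.inf)), "good"),
        (math.inf, "high"),
    ),
}


@dataclass(frozen=True)
class MeanSquares:
    """Two-way one-observation-per-cell ANOVA decomposition."""

    msr: float  # between-subjects (rows)
    msc: float  # between-raters (columns)
    mse: float  # residual
    df_rows: int
    df_cols: int
    df_error: int
    ss_total: float

    @property
    def ss_rows(self) -> float:
        return self.msr * self.df_rows

    @property
    def ss_cols(self) -> float:
        return self.msc * self.df_cols

    @property
    def ss_error(self) -> float:
        return self.mse * self.df_error


@dataclass(frozen=True)
class IccEstimate:
    form: str
    value: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05


@dataclass
class ReliabilityResult:
    """One report row: agreement of the two systems on one trial."""

    participant: str
    task: str
    side: str
    m: float
    sd: float
    icc_form: str
    icc: float
    ci_low: float
    ci_high: float
    cv_pct: float
    sem_deg: float
    mdc95_deg: float
    band: str
    cv_variant: str = "dahlberg"
    sem_variant: str = "rooted"


def _as_table(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ConfigurationError("ratings table must be 2-dimensional")
    n, k = t.shape
    if n < 2 or k < 2:
        raise ConfigurationError(f"ratings table needs >= 2 subjects and >= 2 raters, got {t.shape}")
    if not np.isfinite(t).all():
        raise ConfigurationError("ratings table contains non-finite entries")
    return t


def two_way_mean_squares(table: np.ndarray) -> MeanSquares:
    """Exact two-way ANOVA mean squares of an n x k ratings table.

    The decomposition is exhaustive: SS_rows + SS_cols + SS_error equals
    the total sum of squares about the grand mean (to rounding).
    """
    t = _as_table(table)
    n, k = t.shape
    grand = t.mean()
    rows = t.mean(axis=1)
    cols = t.mean(axis=0)
    ss_rows = k * float(np.sum((rows - grand) ** 2))
    ss_cols = n * float(np.sum((cols - grand) ** 2))
    resid = t - rows[:, None] - cols[None, :] + grand
    ss_err = float(np.sum(resid**2))
    ss_total = float(np.sum((t - grand) ** 2))
    return MeanSquares(
        msr=ss_rows / (n - 1),
        msc=ss_cols / (k - 1),
        mse=ss_err / ((n - 1) * (k - 1)),
        df_rows=n - 1,
        df_cols=k - 1,
        df_error=(n - 1) * (k - 1),
        ss_total=ss_total,
    )


def icc(table: np.ndarray, form: str = "icc21", alpha: float = 0.05) -> IccEstimate:
    """Shrout–Fleiss intraclass correlation with exact F-based CI.

    Forms: ``icc21`` two-way random, absolute agreement, single measure;
    ``icc31`` two-way mixed, consistency, single measure; ``icc3k`` the
    average-measures version of icc31.  A table with zero between-subject
    variance has no defined ICC and raises
    :class:`~mvkin.errors.UndefinedStatisticError`.
    """
    if form not in ICC_FORMS:
        raise ConfigurationError(f"unknown ICC form {form!r}; expected one of {ICC_FORMS}")
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must be in (0, 1)")
    t = _as_table(table)
    n, k = t.shape
    ms = two_way_mean_squares(t)
    msb, msj, mse = ms.msr, ms.msc, ms.mse
    if ms.ss_rows <= 0:
        raise UndefinedStatisticError(
            "zero between-subject variance: ICC is undefined for this table"
        )
    if mse == 0 and msj == 0:
        # raters agree perfectly: every form is exactly 1 with a point CI
        return IccEstimate(form, 1.0, 1.0, 1.0, alpha)

    if form == "icc21":
        est = (msb - mse) / (msb + (k - 1) * mse + k * (msj - mse) / n)
        # Satterthwaite df for the lower/upper F bounds (McGraw & Wong 1996)
        a = k * est / (n * (1.0 - est)) if est < 1.0 else np.inf
        b = 1.0 + k * est * (n - 1.0) / (n * (1.0 - est)) if est < 1.0 else np.inf
        if np.isinf(a) or np.isinf(b):
            return IccEstimate(form, 1.0, 1.0, 1.0, alpha)
        v = (a * msj + b * mse) ** 2 / (
            (a * msj) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_lo = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f_up = f_dist.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msb - f_lo * mse) / (
            f_lo * (k * msj + (k * n - k - n) * mse) + n * msb
        )
        upper = n * (f_up * msb - mse) / (
            k * msj + (k * n - k - n) * mse + n * f_up * msb
        )
    else:
        if mse == 0:
            return IccEstimate(form, 1.0, 1.0, 1.0, alpha)
        fstat = msb / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = fstat / f_dist.ppf(1 - alpha / 2, df1, df2)
        fu = fstat * f_dist.ppf(1 - alpha / 2, df2, df1)
        if form == "icc31":
            est = (msb - mse) / (msb + (k - 1) * mse)
            lower = (fl - 1.0) / (fl + k - 1.0)
            upper = (fu - 1.0) / (fu + k - 1.0)
        else:  # icc3k
            est = (msb - mse) / msb
            lower = 1.0 - 1.0 / fl
            upper = 1.0 - 1.0 / fu
    return IccEstimate(form, float(est), float(lower), float(upper), alpha)


def cv_method_error(x1, x2, variant: str = "dahlberg") -> float:
    """Method-error coefficient of variation between two paired series (%).

    ``dahlberg`` (default): 100 * (SD_d / sqrt(2)) / |grand mean|, where
    SD_d is the sample standard deviation of the paired differences and
    the grand mean is (mean(x1) + mean(x2)) / 2.  ``literal`` evaluates
    100 * SD_d / |mean(x1) + mean(x2)|, the formula as printed in some
    reports.  The denominator is taken in magnitude so the CV stays
    non-negative for signed angle traces (e.g. a side dip to the right,
    whose mean is negative).  Undefined when the combined mean is zero.
    """
    if variant not in ("dahlberg", "literal"):
        raise ConfigurationError(f"unknown CV variant {variant!r}")
    a = np.asarray(x1, float)
    b = np.asarray(x2, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ConfigurationError("x1 and x2 must be equal-length 1-d series of length >= 2")
    total = abs(float(a.mean() + b.mean()))
    if total == 0.0:
        raise UndefinedStatisticError("combined mean is zero: method-error CV undefined")
    sd_d = float(np.std(a - b, ddof=1))
    if variant == "dahlberg":
        return 100.0 * (sd_d / math.sqrt(2.0)) / (total / 2.0)
    return 100.0 * sd_d / total


def sem(sd: float, icc_value: float, variant: str = "rooted") -> float:
    """Standard error of measurement in degrees.

    ``rooted`` (default): SD * sqrt(1 - ICC), the standard form.
    ``literal``: SD * (1 - ICC).  SEM is 0 exactly when ICC = 1.
    """
    if variant not in ("rooted", "literal"):
        raise ConfigurationError(f"unknown SEM variant {variant!r}")
    if sd < 0:
        raise ConfigurationError("sd must be >= 0")
    if icc_value > 1:
        raise ConfigurationError("icc must be <= 1")
    if variant == "rooted":
        return float(sd * math.sqrt(1.0 - icc_value))
    return float(sd * (1.0 - icc_value))


def mdc95(sem_value: float) -> float:
    """Minimal detectable change at 95% confidence: 1.96 * sqrt(2) * SEM."""
    if sem_value < 0:
        raise ConfigurationError("sem must be >= 0")
    return float(MDC_FACTOR * sem_value)


def classify_icc(estimate: float, scheme: str = "results") -> str:
    """Map an ICC estimate onto an interpretation band.

    ``results`` (default): <0.4 poor, 0.4-0.6 normal, 0.6-0.75 good,
    0.75-1.00 very good.  ``methods``: <0.50 poor, 0.50-0.75 moderate,
    0.76-0.90 good, >0.90 high.  Boundary values go to the upper band.
    """
    if scheme not in _BANDS:
        raise ConfigurationError(f"unknown banding scheme {scheme!r}")
    if estimate > 1:
        raise ConfigurationError("ICC estimate must be <= 1")
    for edge, label in _BANDS[scheme]:
        if estimate < edge:
            return label
    raise AssertionError("unreachable")  # pragma: no cover


def reliability_report(
    pairs: list[AlignedTracePair],
    form: str = "icc21",
    cv_variant: str = "dahlberg",
    sem_variant: str = "rooted",
    alpha: float = 0.05,
    pooled_descriptives: bool = True,
    band_scheme: str = "results",
) -> list[ReliabilityResult]:
    """One agreement row per aligned pair, in input order.

    M and SD summarize the pooled 2n values of both systems by default
    (``pooled_descriptives=False`` restricts them to the test system); the
    ICC comes from the n x 2 frames-by-systems table; CV, SEM and MDC95
    quantify absolute agreement in the trace's units.
    """
    results = []
    for pair in pairs:
        table = pair.as_table()
        pooled = table.ravel() if pooled_descriptives else pair.test
        m = float(np.mean(pooled))
        sd = float(np.std(pooled, ddof=1))
        est = icc(table, form=form, alpha=alpha)
        sem_val = sem(sd, est.value, variant=sem_variant)
        prov = pair.provenance
        results.append(
            ReliabilityResult(
                participant=str(prov.get("participant", "")),
                task=str(prov.get("task", "")),
                side=str(prov.get("side", "")),
                m=m,
                sd=sd,
                icc_form=form,
                icc=est.value,
                ci_low=est.ci_low,
                ci_high=est.ci_high,
                cv_pct=cv_method_error(pair.test, pair.reference, variant=cv_variant),
                sem_deg=sem_val,
                mdc95_deg=mdc95(sem_val),
                band=classify_icc(est.value, scheme=band_scheme),
                cv_variant=cv_variant,
                sem_variant=sem_variant,
            )
        )
    return results
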