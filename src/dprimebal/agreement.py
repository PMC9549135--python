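"""Agreement and reliability statistics for paired session measurements.

Implements the statistical layer used to ask whether the reconstitution
time constant tau (or a predicted TTE) is consistent between two interval
sessions performed by the same swimmers: paired t-test with confidence
interval, Bland-Altman bias and limits of agreement, the within-subject
coefficient of variation (SD of the paired differences divided by sqrt(2),
relative to the grand mean), and linear / exponential-decay regression of
tau against CS.  Differences are signed and taken first-argument minus
second throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PairedSample",
    "AgreementResult",
    "RegressionResult",
    "paired_t_ci",
    "bland_altman",
    "within_subject_cv",
    "regress_tau_cs",
    "exclude_subjects",
]


@dataclass(frozen=True)
class PairedSample:
    """Two measurements per subject (e.g. tau from each of two sessions)."""

    ids: tuple
    a: tuple[float, ...]
    b: tuple[float, ...]
    units: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "a", tuple(float(x) for x in self.a))
        object.__setattr__(self, "b", tuple(float(x) for x in self.b))
        if not (len(self.ids) == len(self.a) == len(self.b)):
            raise ValueError("ids, a and b must have equal lengths")
        if len(self.ids) < 2:
            raise ValueError("paired sample needs n >= 2")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("subject ids must be unique")

    @property
    def n(self) -> int:
        return len(self.ids)

    def differences(self) -> np.ndarray:
        """Signed per-subject differences a - b."""
        return np.asarray(self.a) - np.asarray(self.b)


@dataclass(frozen=True)
class AgreementResult:
    """Bias, limits of agreement, CV and paired-t summary for one pair."""

    bias: float
    loa_low: float
    loa_high: float
    cv_percent: float
    t_stat: float
    df: int
    ci_low: float
    ci_high: float
    n: int
    units: str = ""
    mean_abs_difference: float = float("nan")
    sd_abs_difference: float = float("nan")


@dataclass(frozen=True)
class RegressionResult:
    """Linear or exponential-decay fit of tau on CS.

    For ``exp_decay`` the model is ``tau = a * exp(-b * cs) + c``; a failed
    least-squares fit is reported through ``converged=False`` with params
    and r_squared absent (None), never raised.
    """

    form: str
    params: tuple[float, ...] | None
    r_squared: float | None
    converged: bool


def paired_t_ci(
    sample: PairedSample, alpha: float = 0.05
) -> tuple[float, int, tuple[float, float]]:
    """Paired t statistic, df and (1-alpha) CI for the mean difference.

    t = mean(d) / (sd(d)/sqrt(n)) with d = a - b and the n-1 sample SD;
    the CI uses the Student critical value at df = n - 1.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    d = sample.differences()
    n = sample.n
    sd = d.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("zero-variance differences: t undefined")
    se = sd / np.sqrt(n)
    t_stat = float(d.mean() / se)
    df = n - 1
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    ci = (float(d.mean() - t_crit * se), float(d.mean() + t_crit * se))
    return t_stat, df, ci


def bland_altman(sample: PairedSample, k: float = 1.96) -> AgreementResult:
    """Bland-Altman bias and limits of agreement (bias +/- k*SD of d)."""
    d = sample.differences()
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    absd = np.abs(d)
    try:
        t_stat, df, ci = paired_t_ci(sample)
    except ZeroDivisionError:
        t_stat, df, ci = float("nan"), sample.n - 1, (bias, bias)
    try:
        cv = within_subject_cv(sample)
    except ValueError:
        cv = float("nan")
    return AgreementResult(
        bias=bias,
        loa_low=bias - k * sd,
        loa_high=bias + k * sd,
        cv_percent=cv,
        t_stat=t_stat,
        df=df,
        ci_low=ci[0],
        ci_high=ci[1],
        n=sample.n,
        units=sample.units,
        mean_abs_difference=float(absd.mean()),
        sd_abs_difference=float(absd.std(ddof=1)),
    )


def per_subject_means(sample: PairedSample) -> np.ndarray:
    """(a + b)/2 per subject — the x axis of a Bland-Altman plot."""
    return (np.asarray(sample.a) + np.asarray(sample.b)) / 2.0


def within_subject_cv(sample: PairedSample) -> float:
    """Within-subject coefficient of variation, percent.

    SD of the signed paired differences divided by sqrt(2), relative to
    the grand mean of all 2n values.
    """
    d = sample.differences()
    grand_mean = float(np.mean(np.concatenate([sample.a, sample.b])))
    if grand_mean <= 0:
        raise ValueError("grand mean must be > 0 for a CV")
    return float(100.0 * (d.std(ddof=1) / np.sqrt(2)) / grand_mean)


def regress_tau_cs(
    cs_values: Sequence[float],
    tau_values: Sequence[float],
    form: str = "linear",
) -> RegressionResult:
    """Regress tau on CS, linearly or as exponential decay.

    The decay form ``tau = a*exp(-b*cs) + c`` starts from the
    cycling-calibrated amplitude and offset (546, 316) with the rate
    rescaled to the covariate's magnitude; see ``estimate_tau_skiba``.
    """
    x = np.asarray(cs_values, dtype=float)
    y = np.asarray(tau_values, dtype=float)
    if form == "linear":
        if len(x) < 3:
            raise ValueError("linear regression needs n >= 3")
        res = stats.linregress(x, y)
        return RegressionResult(
            form="linear",
            params=(float(res.slope), float(res.intercept)),
            r_squared=float(res.rvalue**2),
            converged=True,
        )
    if form == "exp_decay":
        if len(x) < 4:
            raise ValueError("exp_decay regression needs n >= 4")

        def model(cs, a, b, c):
            return a * np.exp(-b * cs) + c

        p0 = (546.0, 1.0 / max(x.mean(), 1e-9), 316.0)
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                popt, _ = optimize.curve_fit(model, x, y, p0=p0, maxfev=10000)
            resid = y - model(x, *popt)
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            if not np.all(np.isfinite(popt)) or ss_tot == 0:
                raise RuntimeError("degenerate fit")
            r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        except (RuntimeError, optimize.OptimizeWarning, ValueError):
            return RegressionResult("exp_decay", None, None, False)
        return RegressionResult("exp_decay", tuple(map(float, popt)), r2, True)
    raise ValueError(f"unknown regression form {form!r}")


def exclude_subjects(sample: PairedSample, ids: Sequence) -> PairedSample:
    """Drop the listed subjects; unknown ids raise, naming the offender."""
    ids = list(ids)
    known = set(sample.ids)
    for sid in ids:
        if sid not in known:
            raise KeyError(f"unknown subject id {sid!r}")
    drop = set(ids)
    kept = [
        (i, a, b)
        for i, a, b in zip(sample.ids, sample.a, sample.b)
        if i not in drop
    ]
    if len(kept) < 2:
        raise ValueError("exclusion leaves fewer than 2 subjects")
    ki, ka, kb = zip(*kept)
    return PairedSample(ids=ki, a=ka, b=kb, units=sample.units)
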