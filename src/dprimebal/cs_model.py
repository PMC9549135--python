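"""Critical speed (CS) and D' from the distance-time linear model.

For severe-intensity swimming, total distance d covered in a maximal effort
of duration t is well described by ``d = CS * t + D'``: the slope CS
(m/s) is the highest speed sustainable without drawing on the finite
supra-CS distance capacity D' (m, the intercept).  Fitting ordinary least
squares of distance on time over a set of maximal time trials yields both
parameters together with their standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TimeTrial",
    "CsFit",
    "DegenerateTrialsError",
    "fit_distance_time",
    "target_speed",
    "percent_of_pace",
]


class DegenerateTrialsError(ValueError):
    """Raised when the trial set cannot identify a slope and intercept."""


@dataclass(frozen=True)
class TimeTrial:
    """One maximal swim: total distance (m) covered in a given time (s)."""

    distance: float
    time: float

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError(f"distance must be > 0, got {self.distance}")
        if self.time <= 0:
            raise ValueError(f"time must be > 0, got {self.time}")

    @property
    def mean_speed(self) -> float:
        """Average pace of the trial in m/s."""
        return self.distance / self.time


@dataclass(frozen=True)
class CsFit:
    """Distance-time regression result.

    Attributes
    ----------
    cs : float
        Critical speed, the regression slope (m/s).
    d_prime : float
        Finite distance capacity above CS, the intercept (m).
    r_squared : float
        Coefficient of determination of the linear fit.
    see_cs, see_d_prime : float
        Standard errors of slope and intercept (m/s and m).  Zero when the
        trials are exactly collinear.
    n_trials : int
        Number of trials entering the fit.
    negative_d_prime : bool
        Flag set when the intercept is negative; the fit is still returned
        so that stress tests on degenerate synthetic athletes can proceed.
    """

    cs: float
    d_prime: float
    r_squared: float
    see_cs: float
    see_d_prime: float
    n_trials: int
    negative_d_prime: bool = False

    @property
    def see_cs_percent(self) -> float:
        """Slope standard error as a percentage of CS."""
        return 100.0 * self.see_cs / self.cs

    @property
    def see_d_prime_percent(self) -> float:
        """Intercept standard error as a percentage of D' (nan if D' = 0)."""
        if self.d_prime == 0:
            return float("nan")
        return 100.0 * self.see_d_prime / abs(self.d_prime)


def fit_distance_time(trials: list[TimeTrial]) -> CsFit:
    """Fit ``distance = CS * time + D'`` by ordinary least squares.

    Parameters
    ----------
    trials
        At least two maximal efforts with distinct times.

    Returns
    -------
    CsFit
        Slope (CS), intercept (D'), R^2 and parameter standard errors.

    Raises
    ------
    DegenerateTrialsError
        Fewer than two trials, or all trial times identical.
    """
    if len(trials) < 2:
        raise DegenerateTrialsError(
            f"need at least 2 time trials, got {len(trials)}"
        )
    t = np.asarray([tr.time for tr in trials], dtype=float)
    d = np.asarray([tr.distance for tr in trials], dtype=float)
    if np.ptp(t) == 0:
        raise DegenerateTrialsError("all trial times identical; slope undefined")

    res = stats.linregress(t, d)
    n = len(trials)
    # linregress leaves R^2 = nan for an exact 2-point fit's p-machinery only
    # in pathological cases; residual-based R^2 is robust for n = 2 as well.
    pred = res.slope * t + res.intercept
    ss_res = float(np.sum((d - pred) ** 2))
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot

    if n > 2:
        se_slope = float(res.stderr)
        se_icpt = float(res.intercept_stderr)
    else:
        # exact interpolation: residual df = 0, SEs are identically zero
        se_slope, se_icpt = 0.0, 0.0

    d_prime = float(res.intercept)
    negative = d_prime < 0
    if negative:
        warnings.warn(
            f"negative D' intercept ({d_prime:.2f} m); fit returned flagged",
            stacklevel=2,
        )
    return CsFit(
        cs=float(res.slope),
        d_prime=d_prime,
        r_squared=min(r2, 1.0),
        see_cs=se_slope,
        see_d_prime=se_icpt,
        n_trials=n,
        negative_d_prime=negative,
    )


def target_speed(fit: CsFit, tte: float) -> float:
    """Constant speed predicted to exhaust D' in ``tte`` seconds.

    Inverts the two-parameter model: Speed = CS + D'/t.  As t grows the
    target tends to CS from above.
    """
    if tte <= 0:
        raise ValueError(f"tte must be > 0, got {tte}")
    return fit.cs + fit.d_prime / tte


def percent_of_pace(speed: float, reference_trial: TimeTrial) -> float:
    """Express ``speed`` as a percentage of a reference trial's mean pace."""
    return 100.0 * speed / reference_trial.mean_speed
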