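"""Statistical primitives: D'Agostino skew z, the Tadpole test, pooled t, Mann-Whitney U.

The Tadpole test targets a pattern that does not arise naturally in two-group
continuous data: the higher-mean group is *more right-skewed* and the
lower-mean group *more left-skewed*, i.e. the two tails point away from each
other ("kissing tadpoles").  Selective handling of clinically surprising
values -- remeasuring, removing, or reclassifying the low tail of the group
believed high and the high tail of the group believed low -- produces exactly
this signature.  The test compares the D'Agostino (1970) skewness z-scores of
the two groups, oriented by their sample means, against a one-sided 5%
threshold of ``1.64 * sqrt(2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TADPOLE_THRESHOLD",
    "MIN_SKEW_N",
    "InvalidInputError",
    "TadpoleResult",
    "TestResult",
    "dagostino_skew_z",
    "tadpole_test",
    "t_test_pooled",
    "mann_whitney",
]

#: One-sided 5% threshold on the oriented difference of two skew z-scores.
TADPOLE_THRESHOLD: float = 1.64 * math.sqrt(2.0)

#: Minimum group size for the D'Agostino skewness transformation.
MIN_SKEW_N: int = 9


class InvalidInputError(ValueError):
    """Raised when a sample violates a test's preconditions."""


@dataclass(frozen=True)
class TadpoleResult:
    """Outcome of the Tadpole test.

    Attributes
    ----------
    z_high, z_low : float
        D'Agostino skew z-scores of the higher- and lower-mean group.
    z_diff : float
        ``z_high - z_low`` (``|z_a - z_b|`` when means tie exactly).
    threshold : float
        The constant ``1.64 * sqrt(2)``.
    significant : bool
        ``z_diff > threshold``.
    higher_group_label : str
        Label of the group with the larger sample mean.
    mean_tie : bool
        True when the two sample means are exactly equal (degenerate input).
    """

    z_high: float
    z_low: float
    z_diff: float
    threshold: float
    significant: bool
    higher_group_label: str
    mean_tie: bool = False


@dataclass(frozen=True)
class TestResult:
    """A significance-test outcome: statistic, two-sided p-value, test name."""

    statistic: float
    p_value: float
    test_name: str


def _validate(values: np.ndarray, min_n: int, name: str) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise InvalidInputError(f"{name}: expected a 1-D sample, got shape {x.shape}")
    if x.size < min_n:
        raise InvalidInputError(
            f"{name}: sample has {x.size} values but at least {min_n} are required"
        )
    if not np.all(np.isfinite(x)):
        raise InvalidInputError(f"{name}: sample contains non-finite values")
    return x


def dagostino_skew_z(sample, *, axis: int | None = None):
    """D'Agostino (1970) skewness z-score.

    Transforms the sample skewness ``sqrt(b1) = m3 / m2**1.5`` into an
    approximately standard-normal statistic via the Johnson SU
    variance-stabilising fit.  Odd in the sample skewness: symmetric data map
    to exactly 0.  Requires ``n >= 9`` and positive variance.

    Parameters
    ----------
    sample : array-like
        Measurements.  With ``axis`` given, an array of samples is scored
        along that axis (used by the vectorised Monte-Carlo engine).
    axis : int, optional
        Axis holding each sample.  ``None`` (default) requires 1-D input and
        returns a scalar.

    Returns
    -------
    float or ndarray
        The skew z-score(s).
    """
    if axis is None:
        x = _validate(sample, MIN_SKEW_N, "dagostino_skew_z")
        ax = -1
    else:
        x = np.asarray(sample, dtype=float)
        ax = axis
    n = x.shape[ax]
    if n < MIN_SKEW_N:
        raise InvalidInputError(
            f"dagostino_skew_z: sample size {n} below minimum {MIN_SKEW_N}"
        )
    d = x - x.mean(axis=ax, keepdims=True)
    m2 = np.mean(d * d, axis=ax)
    m3 = np.mean(d * d * d, axis=ax)
    if np.any(m2 <= 0.0):
        raise InvalidInputError("dagostino_skew_z: sample variance is zero")
    b1 = m3 / m2**1.5
    y = b1 * math.sqrt((n + 1.0) * (n + 3.0) / (6.0 * (n - 2.0)))
    beta2 = (
        3.0 * (n**2 + 27.0 * n - 70.0) * (n + 1.0) * (n + 3.0)
        / ((n - 2.0) * (n + 5.0) * (n + 7.0) * (n + 9.0))
    )
    w2 = -1.0 + math.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / math.sqrt(math.log(math.sqrt(w2)))
    alpha = math.sqrt(2.0 / (w2 - 1.0))
    z = delta * np.log(y / alpha + np.sqrt((y / alpha) ** 2 + 1.0))
    if axis is None:
        return float(z)
    return z


def tadpole_z_diff(a, b, *, axis: int = -1):
    """Oriented skew-z difference for arrays of paired samples.

    ``z(higher-mean) - z(lower-mean)`` elementwise; on an exact mean tie the
    absolute difference is returned.  Vectorised core shared by
    :func:`tadpole_test` and the simulation engine.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    za = dagostino_skew_z(a, axis=axis)
    zb = dagostino_skew_z(b, axis=axis)
    ma = a.mean(axis=axis)
    mb = b.mean(axis=axis)
    diff = np.where(ma > mb, za - zb, zb - za)
    return np.where(ma == mb, np.abs(za - zb), diff)


def tadpole_test(a, b, *, labels: tuple[str, str] = ("a", "b")) -> TadpoleResult:
    """Run the Tadpole test on two samples.

    Orientation is by observed sample mean, never by argument order, so
    swapping ``a`` and ``b`` leaves ``z_diff`` unchanged.  Significant when
    the higher-mean group's skew z exceeds the lower-mean group's by more
    than ``1.64 * sqrt(2)`` -- one-sided, because only tails pointing *away*
    from each other are implausible in nature.

    When the two means tie exactly (measure-zero on continuous data) the
    result carries ``z_diff = |z_a - z_b|`` and ``mean_tie=True``.
    """
    xa = _validate(a, MIN_SKEW_N, "tadpole_test(a)")
    xb = _validate(b, MIN_SKEW_N, "tadpole_test(b)")
    za = dagostino_skew_z(xa)
    zb = dagostino_skew_z(xb)
    ma, mb = float(xa.mean()), float(xb.mean())
    if ma == mb:
        z_hi, z_lo = max(za, zb), min(za, zb)
        z_diff = abs(za - zb)
        hi_label = labels[0] if za >= zb else labels[1]
        tie = True
    elif ma > mb:
        z_hi, z_lo, z_diff, hi_label, tie = za, zb, za - zb, labels[0], False
    else:
        z_hi, z_lo, z_diff, hi_label, tie = zb, za, zb - za, labels[1], False
    return TadpoleResult(
        z_high=z_hi,
        z_low=z_lo,
        z_diff=z_diff,
        threshold=TADPOLE_THRESHOLD,
        significant=bool(z_diff > TADPOLE_THRESHOLD),
        higher_group_label=hi_label,
        mean_tie=tie,
    )


def t_test_pooled(a, b) -> TestResult:
    """Two-sided pooled-variance Student t-test (df = n_a + n_b - 2)."""
    xa = _validate(a, 2, "t_test_pooled(a)")
    xb = _validate(b, 2, "t_test_pooled(b)")
    if np.var(xa, ddof=1) + np.var(xb, ddof=1) <= 0.0:
        raise InvalidInputError("t_test_pooled: pooled variance is zero")
    t, p = _sps.ttest_ind(xa, xb, equal_var=True)
    return TestResult(statistic=float(t), p_value=float(p), test_name="t_pooled")


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney U via the normal approximation.

    Continuity and tie corrections applied; exact enumeration is not used
    (ties are measure-zero on continuous data, and simulated groups of
    n >= 20 sit comfortably inside the approximation's range).
    """
    xa = _validate(a, 2, "mann_whitney(a)")
    xb = _validate(b, 2, "mann_whitney(b)")
    u, p = _sps.mannwhitneyu(
        xa, xb, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return TestResult(statistic=float(u), p_value=float(p), test_name="mann_whitney")
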