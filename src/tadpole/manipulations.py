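"""The three "evil R" operators: remeasurement, removal, reclassification.

Each operator models a well-intentioned clinician-researcher who believes one
group runs higher than the other and, on meeting a clinically surprising
value, handles it in the direction of that belief: surprisingly *low* values
in the believed-higher group and surprisingly *high* values in the
believed-lower group are remeasured, removed, or transferred to the other
group.  Applied to truly null data these habits manufacture a group
difference while attenuating the facing tails -- the "kissing tadpoles"
signature the Tadpole test detects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TwoGroupStudy",
    "ManipulationSpec",
    "KINDS",
    "select_surprising",
    "remeasure",
    "remove",
    "reclassify",
    "apply_manipulation",
]

KINDS = ("remeasure", "remove", "reclassify", "none")


@dataclass(frozen=True)
class TwoGroupStudy:
    """Two samples plus the researcher's prior belief about their ordering.

    ``group_high`` is the group the researcher *believes* has higher values;
    the belief fixes the direction of manipulation and need not match the
    data.  Groups start equal-sized in simulation but may end unequal after
    removal.
    """

    group_high: np.ndarray
    group_low: np.ndarray
    labels: tuple[str, str] = ("high", "low")

    def __post_init__(self):
        object.__setattr__(self, "group_high", np.asarray(self.group_high, dtype=float))
        object.__setattr__(self, "group_low", np.asarray(self.group_low, dtype=float))


@dataclass(frozen=True)
class ManipulationSpec:
    """What to do, to how many patients per group, and under what model.

    Parameters
    ----------
    kind : {"remeasure", "remove", "reclassify", "none"}
    k : int
        Patients manipulated per group.
    icc : float
        Intraclass correlation between first and repeat measurement
        (remeasurement only).  Default 0.5: measurement noise variance
        equals true-value variance.
    population_mean, population_sd : float
        Marginal distribution of a measurement, shared by both measurements
        of a patient (no systematic bias between first and second reading).
    less_extreme : {"directional", "absolute"}
        How "less extreme" is judged when deciding whether the repeat
        replaces the original.  "directional" (default): less extreme in the
        direction that made the value surprising, i.e. keep
        ``max(old, new)`` on the low tail of the believed-high group and
        ``min(old, new)`` on the high tail of the believed-low group.
        "absolute": keep whichever measurement lies closer to the population
        mean (sensitivity-analysis variant).
    """

    kind: str
    k: int
    icc: float = 0.5
    population_mean: float = 0.0
    population_sd: float = 1.0
    less_extreme: str = "directional"

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown manipulation kind {self.kind!r}; choose from {KINDS}")
        if self.k < 0:
            raise ValueError(f"k must be non-negative, got {self.k}")
        if self.kind == "remeasure" and not 0.0 < self.icc < 1.0:
            raise ValueError(f"icc must lie in (0, 1), got {self.icc}")
        if self.population_sd <= 0.0:
            raise ValueError("population_sd must be positive")
        if self.less_extreme not in ("directional", "absolute"):
            raise ValueError(f"unknown less_extreme rule {self.less_extreme!r}")


def select_surprising(sample, k: int, tail: str) -> np.ndarray:
    """Indices of the ``k`` most surprising values in the stated tail.

    Rank-based: the k smallest (``tail="low"``) or k largest
    (``tail="high"``) values.  Deterministic; exact ties broken by original
    position (stable sort).
    """
    x = np.asarray(sample, dtype=float)
    if not 0 <= k <= x.size:
        raise ValueError(f"k={k} out of range for sample of size {x.size}")
    if tail not in ("low", "high"):
        raise ValueError(f"tail must be 'low' or 'high', got {tail!r}")
    if k == 0:
        return np.empty(0, dtype=np.intp)
    order = np.argsort(x, kind="stable")
    return order[:k] if tail == "low" else order[-k:]


def _check_k(spec: ManipulationSpec, study: TwoGroupStudy, strict: bool) -> None:
    for g, name in ((study.group_high, "group_high"), (study.group_low, "group_low")):
        if strict and spec.k >= g.size:
            raise ValueError(f"k={spec.k} must leave at least one patient in {name} (n={g.size})")
        if spec.k > g.size:
            raise ValueError(f"k={spec.k} exceeds size of {name} (n={g.size})")


def remeasure(
    study: TwoGroupStudy, spec: ManipulationSpec, rng: np.random.Generator
) -> TwoGroupStudy:
    """Selectively remeasure surprising values, keeping the less extreme reading.

    The repeat measurement is drawn from the conditional law of a second
    measurement given the first under a bivariate normal with common marginal
    N(mean, sd^2) and correlation ``icc``:

        new = mu + icc * (old - mu) + sd * sqrt(1 - icc^2) * eps

    Each selected patient is remeasured once; the repeat replaces the
    original only if it is less extreme (see ``ManipulationSpec``), so
    group means can only move in the believed direction.  Group sizes are
    unchanged.
    """
    if spec.kind != "remeasure":
        raise ValueError(f"spec.kind is {spec.kind!r}, expected 'remeasure'")
    _check_k(spec, study, strict=False)
    if spec.k == 0:
        return study
    mu, sd, rho = spec.population_mean, spec.population_sd, spec.icc

    def redo(values: np.ndarray, tail: str) -> np.ndarray:
        out = values.copy()
        idx = select_surprising(values, spec.k, tail)
        old = values[idx]
        new = mu + rho * (old - mu) + sd * np.sqrt(1.0 - rho * rho) * rng.standard_normal(idx.size)
        if spec.less_extreme == "directional":
            kept = np.maximum(old, new) if tail == "low" else np.minimum(old, new)
        else:
            kept = np.where(np.abs(new - mu) < np.abs(old - mu), new, old)
        out[idx] = kept
        return out

    return replace(
        study,
        group_high=redo(study.group_high, "low"),
        group_low=redo(study.group_low, "high"),
    )


def remove(study: TwoGroupStudy, spec: ManipulationSpec) -> TwoGroupStudy:
    """Delete the k lowest values of the believed-high group and the k highest
    of the believed-low group; each group shrinks by exactly k."""
    if spec.kind != "remove":
        raise ValueError(f"spec.kind is {spec.kind!r}, expected 'remove'")
    _check_k(spec, study, strict=True)
    if spec.k == 0:
        return study
    hi_idx = select_surprising(study.group_high, spec.k, "low")
    lo_idx = select_surprising(study.group_low, spec.k, "high")
    return replace(
        study,
        group_high=np.delete(study.group_high, hi_idx),
        group_low=np.delete(study.group_low, lo_idx),
    )


def reclassify(study: TwoGroupStudy, spec: ManipulationSpec) -> TwoGroupStudy:
    """Transfer surprising patients between groups.

    The k lowest values of the believed-high group and the k highest of the
    believed-low group swap groups *simultaneously* (computed from the
    pre-manipulation order statistics, so the operation is order-independent).
    Group sizes and the pooled multiset of values are conserved exactly.
    """
    if spec.kind != "reclassify":
        raise ValueError(f"spec.kind is {spec.kind!r}, expected 'reclassify'")
    _check_k(spec, study, strict=False)
    if spec.k == 0:
        return study
    hi_idx = select_surprising(study.group_high, spec.k, "low")
    lo_idx = select_surprising(study.group_low, spec.k, "high")
    moved_down = study.group_high[hi_idx]
    moved_up = study.group_low[lo_idx]
    new_high = np.concatenate([np.delete(study.group_high, hi_idx), moved_up])
    new_low = np.concatenate([np.delete(study.group_low, lo_idx), moved_down])
    return replace(study, group_high=new_high, group_low=new_low)


def apply_manipulation(
    study: TwoGroupStudy,
    spec: ManipulationSpec,
    rng: np.random.Generator | None = None,
) -> TwoGroupStudy:
    """Dispatch on ``spec.kind``; ``kind="none"`` returns the study untouched."""
    if spec.kind == "none":
        return study
    if spec.kind == "remeasure":
        if rng is None:
            raise ValueError("remeasurement requires a random generator")
        return remeasure(study, spec, rng)
    if spec.kind == "remove":
        return remove(study, spec)
    return reclassify(study, spec)
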