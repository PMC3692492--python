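"""Monte-Carlo engine: null studies, manipulation sweeps, minimal-k search.

The engine answers the study's central question: starting from two groups
drawn from one and the same normal population (so any "positive" result is
false), how many patients per group must be remeasured, removed, or
reclassified before the *majority* of simulated studies reach p < 0.05?

Sweeps over the manipulation count k use common random numbers: the same
underlying replicate studies are re-manipulated at every k, which makes the
positive-fraction curve monotone in k and pins the majority crossing with
far fewer replicates than independent draws would need.  All heavy paths are
vectorised over the replicate axis; a scalar :func:`run_once` path built from
the per-study operators is kept for auditing and cross-checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .manipulations import KINDS, ManipulationSpec, TwoGroupStudy, apply_manipulation
from .stats import MIN_SKEW_N, TADPOLE_THRESHOLD, tadpole_z_diff

__all__ = [
    "SimulationConfig",
    "SweepResult",
    "generate_null_study",
    "run_once",
    "sweep_k",
    "tadpole_detection_k",
]

logger = logging.getLogger("tadpole.engine")

TESTS = ("t_pooled", "mann_whitney")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation experiment.

    ``reps`` defaults to 2,000: at the 50% majority boundary the binomial
    standard error is then ~1.1%, which resolves the minimal k to about one
    patient; raise to 100,000 for full-precision replication.
    """

    n_per_group: int
    manipulation: str = "remeasure"
    significance_test: str = "t_pooled"
    reps: int = 2000
    alpha: float = 0.05
    icc: float = 0.5
    majority_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if self.manipulation not in KINDS:
            raise ValueError(f"unknown manipulation {self.manipulation!r}")
        if self.significance_test not in TESTS:
            raise ValueError(f"unknown significance test {self.significance_test!r}")
        if self.reps < 1:
            raise ValueError("reps must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.majority_threshold < 1.0:
            raise ValueError("majority_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class SweepResult:
    """Positive fractions along a manipulation-count sweep.

    ``minimal_k`` is the smallest k whose significance-test positive
    fraction strictly exceeds the majority threshold (None if never
    reached); ``tadpole_minimal_k`` is the analogue for Tadpole detection,
    computed unconditionally on the same replicates.
    """

    n_per_group: int
    manipulation: str
    significance_test: str
    reps: int
    seed: int
    k_values: np.ndarray
    positive_fraction: np.ndarray
    tadpole_fraction: np.ndarray
    minimal_k: int | None
    tadpole_minimal_k: int | None
    majority_threshold: float = 0.5

    def to_frame(self) -> pd.DataFrame:
        """Flat table (one row per k) for plotting and regression tests."""
        return pd.DataFrame(
            {
                "n": self.n_per_group,
                "kind": self.manipulation,
                "test": self.significance_test,
                "k": self.k_values,
                "positive_fraction": self.positive_fraction,
                "tadpole_fraction": self.tadpole_fraction,
                "reps": self.reps,
                "seed": self.seed,
            }
        )


def generate_null_study(n_per_group: int, rng: np.random.Generator) -> TwoGroupStudy:
    """Two independent N(0,1) samples of equal size.

    The believed-higher group is designated arbitrarily but consistently
    (it encodes the researcher's belief, not anything in the data).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    return TwoGroupStudy(
        group_high=rng.standard_normal(n_per_group),
        group_low=rng.standard_normal(n_per_group),
        labels=("believed-high", "believed-low"),
    )


def _check_k_bounds(config: SimulationConfig, k: int) -> None:
    n = config.n_per_group
    if k < 0 or k > n:
        raise ValueError(f"k={k} out of range for n_per_group={n}")
    if config.manipulation == "remove" and n - k < MIN_SKEW_N:
        raise ValueError(
            f"removal of k={k} from n={n} leaves fewer than {MIN_SKEW_N} patients"
        )


def run_once(config: SimulationConfig, k: int, rng: np.random.Generator) -> dict:
    """One replicate through the scalar per-study path.

    Generates a null study, applies the configured manipulation at count k,
    and returns ``{"p_value": float, "tadpole_significant": bool}`` from the
    configured significance test and the Tadpole test on the same data.
    """
    from . import stats as _stats

    _check_k_bounds(config, k)
    study = generate_null_study(config.n_per_group, rng)
    spec = ManipulationSpec(kind=config.manipulation, k=k, icc=config.icc)
    study = apply_manipulation(study, spec, rng)
    if config.significance_test == "t_pooled":
        res = _stats.t_test_pooled(study.group_high, study.group_low)
    else:
        res = _stats.mann_whitney(study.group_high, study.group_low)
    tad = _stats.tadpole_test(study.group_high, study.group_low, labels=study.labels)
    return {"p_value": res.p_value, "tadpole_significant": tad.significant}


def _manipulated_arrays(kind, hs, ls, kept_h, kept_l, k):
    """Apply a manipulation at count k to pre-sorted replicate matrices.

    ``hs``/``ls`` are (reps, n) with each row sorted ascending; the
    believed-high group's surprising tail is columns [:k] of ``hs`` and the
    believed-low group's is columns [n-k:] of ``ls``.
    """
    n = hs.shape[1]
    if kind == "none" or k == 0:
        return hs, ls
    if kind == "remove":
        return hs[:, k:], ls[:, : n - k]
    if kind == "reclassify":
        a = np.concatenate([hs[:, k:], ls[:, n - k :]], axis=1)
        b = np.concatenate([ls[:, : n - k], hs[:, :k]], axis=1)
        return a, b
    # remeasure: replace tail columns with the pre-drawn keep-if-less-extreme values
    a = hs.copy()
    a[:, :k] = kept_h[:, :k]
    b = ls.copy()
    b[:, n - k :] = kept_l[:, :k][:, ::-1]
    return a, b


def _pvalues(test: str, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if test == "t_pooled":
        return _sps.ttest_ind(a, b, axis=1, equal_var=True).pvalue
    return _sps.mannwhitneyu(
        a, b, axis=1, alternative="two-sided", method="asymptotic", use_continuity=True
    ).pvalue


def sweep_k(config: SimulationConfig, k_max: int) -> SweepResult:
    """Sweep the manipulation count k = 0..k_max under common random numbers.

    For each k the same ``reps`` null studies are re-manipulated, the
    configured significance test and the Tadpole test are run on every
    replicate, and the positive fractions recorded.  Returns the minimal k
    for each criterion (strictly more than ``majority_threshold`` of
    replicates positive), or None where the sweep never crosses.
    """
    _check_k_bounds(config, k_max)
    n, reps = config.n_per_group, config.reps
    if n < MIN_SKEW_N:
        raise ValueError(f"n_per_group must be >= {MIN_SKEW_N} for the Tadpole test")
    rng = np.random.default_rng(config.seed)
    hs = np.sort(rng.standard_normal((reps, n)), axis=1)
    ls = np.sort(rng.standard_normal((reps, n)), axis=1)

    kept_h = kept_l = None
    if config.manipulation == "remeasure" and k_max > 0:
        rho = config.icc
        scale = np.sqrt(1.0 - rho * rho)
        # noise drawn position-major (both groups per position) so the noise
        # at tail position j does not depend on the chosen k_max
        eps = rng.standard_normal((k_max, 2, reps))
        eps_h = eps[:, 0, :].T
        eps_l = eps[:, 1, :].T
        old_h = hs[:, :k_max]  # k lowest of believed-high group
        old_l = ls[:, n - k_max :][:, ::-1]  # k highest of believed-low, extreme first
        kept_h = np.maximum(old_h, rho * old_h + scale * eps_h)
        kept_l = np.minimum(old_l, rho * old_l + scale * eps_l)

    ks = np.arange(k_max + 1)
    pos = np.empty(k_max + 1)
    tad = np.empty(k_max + 1)
    report_every = max(1, (k_max + 1) // 10)
    for i, k in enumerate(ks):
        a, b = _manipulated_arrays(config.manipulation, hs, ls, kept_h, kept_l, int(k))
        pos[i] = np.mean(_pvalues(config.significance_test, a, b) < config.alpha)
        tad[i] = np.mean(tadpole_z_diff(a, b, axis=1) > TADPOLE_THRESHOLD)
        if i % report_every == 0 or i == k_max:
            logger.info(
                "sweep n=%d kind=%s test=%s: k=%d/%d (%d reps) positive=%.3f tadpole=%.3f",
                n, config.manipulation, config.significance_test,
                k, k_max, reps, pos[i], tad[i],
            )

    def first_crossing(frac: np.ndarray) -> int | None:
        hits = np.nonzero(frac > config.majority_threshold)[0]
        return int(ks[hits[0]]) if hits.size else None

    return SweepResult(
        n_per_group=n,
        manipulation=config.manipulation,
        significance_test=config.significance_test,
        reps=reps,
        seed=config.seed,
        k_values=ks,
        positive_fraction=pos,
        tadpole_fraction=tad,
        minimal_k=first_crossing(pos),
        tadpole_minimal_k=first_crossing(tad),
        majority_threshold=config.majority_threshold,
    )


def tadpole_detection_k(config: SimulationConfig, k_max: int) -> int | None:
    """Smallest k at which the Tadpole test flags the majority of replicates."""
    return sweep_k(config, k_max).tadpole_minimal_k
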