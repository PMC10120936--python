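"""Longitudinal comparison machinery: balanced date sampling, one-sided
Wilcoxon rank-sum tests and Bonferroni correction.

Spontaneous vocalization counts vary wildly across recording sessions, so
comparisons draw equal numbers of squeals from every recording date inside a
phase window before testing — otherwise a single noisy day dominates the
sample.  Each animal serves as its own control: pre-surgery squeals are
compared against the first two post-surgery weeks in the direction of
expected worsening, and later windows are compared against the early
post-surgery window with the direction inverted to test for improvement.
Family-wise error is controlled with Bonferroni (2 tests for evaluation A,
36 for evaluation B), deliberately conservative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .io_audio import PHASES, RecoveryPhase

__all__ = [
    "SamplingPlan",
    "TestSpec",
    "TestResult",
    "DEFAULT_POST_DIRECTIONS",
    "default_direction_table",
    "balanced_sample",
    "wilcoxon_rank_sum",
    "bonferroni",
    "compare_phases",
    "run_comparisons",
]

Direction = Literal["a_greater", "a_less"]

#: Expected direction of each parameter's change after surgery, used to set
#: the one-sided alternatives: Q50 and P60 drop with the loss of
#: high-frequency energy, the flux measures and Spread rise with phonation
#: instability, and LPC8 rises (toward zero from negative values).
DEFAULT_POST_DIRECTIONS: dict[str, str] = {
    "q50": "decrease",
    "flux1": "increase",
    "flux2": "increase",
    "spread": "increase",
    "p60": "decrease",
    "lpc8": "increase",
}


def default_direction_table() -> pd.DataFrame:
    """Direction table (feature, post_direction, description) as CSV-ready df."""
    desc = {
        "q50": "50% energy spectrum quantile (Hz)",
        "flux1": "average spectral change, evaluation A formulation",
        "flux2": "spectral change, alternative formulation",
        "spread": "Mel-spectral deviation about the centroid",
        "p60": "Mel frequency reaching 60% cumulative energy",
        "lpc8": "8th of 16 linear-prediction coefficients",
    }
    return pd.DataFrame(
        {
            "feature": list(DEFAULT_POST_DIRECTIONS),
            "post_direction": list(DEFAULT_POST_DIRECTIONS.values()),
            "description": [desc[f] for f in DEFAULT_POST_DIRECTIONS],
        }
    )


@dataclass(frozen=True)
class SamplingPlan:
    """Balanced per-date sampling parameters for one comparison."""

    per_date_count: int | None = None   # None -> min per-date count
    allow_fewer: bool = False
    seed: int = 0


@dataclass(frozen=True)
class TestSpec:
    __test__ = False  # not a pytest class, despite the name

    feature_name: str
    direction: Direction
    family_size: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.family_size < 1:
            raise ValueError("family_size >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha in (0, 1)")
        if self.direction not in ("a_greater", "a_less"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class TestResult:
    __test__ = False  # not a pytest class, despite the name

    feature_name: str
    phase_a: str
    phase_b: str
    n_a: int
    n_b: int
    rank_sum_statistic: float
    p_one_sided: float
    p_corrected: float
    significant: bool


# ---------------------------------------------------------------------------


def balanced_sample(
    squeal_table: pd.DataFrame,
    phase: str | RecoveryPhase,
    per_date_count: int | None = None,
    seed: int | np.random.Generator = 0,
    allow_fewer: bool = False,
) -> pd.DataFrame:
    """Draw equal numbers of squeals from every recording date in a phase.

    Sampling is uniform without replacement within each date.  With
    ``per_date_count=None`` the minimum per-date squeal count is used (the
    largest possible balanced sample).  ``allow_fewer`` lets a sparse date
    contribute everything it has instead of raising.
    """
    phase_obj = PHASES[phase] if isinstance(phase, str) else phase
    days = squeal_table["days_from_surgery"]
    in_phase = squeal_table[(days >= phase_obj.lo) & (days <= phase_obj.hi)]
    if in_phase.empty:
        raise ValueError(f"no squeals in phase {phase_obj.name}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    counts = in_phase.groupby("recording_date").size()
    if per_date_count is None:
        per_date_count = int(counts.min())
    if per_date_count < 1:
        raise ValueError("per_date_count must be >= 1")
    if not allow_fewer and (counts < per_date_count).any():
        short = counts[counts < per_date_count].index.tolist()
        raise ValueError(
            f"dates {short} have fewer than {per_date_count} squeals "
            "(pass allow_fewer=True to keep them)"
        )
    picks = []
    for _, group in in_phase.groupby("recording_date", sort=True):
        take = min(per_date_count, len(group))
        idx = rng.choice(len(group), size=take, replace=False)
        picks.append(group.iloc[np.sort(idx)])
    return pd.concat(picks, axis=0)


def wilcoxon_rank_sum(
    a: np.ndarray,
    b: np.ndarray,
    direction: Direction,
    exact_max_n: int = 16,
) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum test of sample ``a`` against ``b``.

    Returns ``(rank_sum_statistic, p_one_sided)`` where the statistic is the
    sum of midranks of ``a`` in the pooled sample.  The p-value is exact
    (full enumeration) when the pooled size is at most ``exact_max_n`` and
    tie-free, otherwise a normal approximation with tie and continuity
    corrections is used.  ``direction='a_less'`` tests the alternative that
    ``a`` is stochastically smaller than ``b``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= exact_max_n and no_ties) else "asymptotic"
    alternative = "less" if direction == "a_less" else "greater"
    res = mannwhitneyu(a, b, alternative=alternative, method=method)
    # rank-sum statistic W = U + n_a (n_a + 1) / 2
    w = float(res.statistic + a.size * (a.size + 1) / 2)
    return w, float(res.pvalue)


def bonferroni(
    p_values: Sequence[float] | np.ndarray,
    family_size: int,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni correction: ``p_corr = min(1, family_size * p)``.

    ``family_size`` may exceed the number of p-values supplied (directions
    could not be fixed for every candidate feature, but the family stays at
    its full size).  Returns ``(p_corrected, significant)``.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if family_size < p.size:
        raise ValueError("family_size smaller than the number of hypotheses")
    p_corr = np.minimum(1.0, family_size * p)
    return p_corr, p_corr <= alpha


def compare_phases(
    feature_table: pd.DataFrame,
    feature: str,
    phase_a: str,
    phase_b: str,
    spec: TestSpec,
    plan: SamplingPlan = SamplingPlan(),
) -> TestResult:
    """Balanced-sample two phases and run the one-sided test for one feature.

    ``spec.direction`` refers to phase_a vs phase_b (e.g. ``a_greater`` for
    a PRE-vs-POST_EARLY Q50 drop).  Correction uses ``spec.family_size``.
    """
    rng = np.random.default_rng(plan.seed)
    sub_a = balanced_sample(
        feature_table, phase_a, plan.per_date_count, rng, plan.allow_fewer
    )
    sub_b = balanced_sample(
        feature_table, phase_b, plan.per_date_count, rng, plan.allow_fewer
    )
    stat, p = wilcoxon_rank_sum(
        sub_a[feature].to_numpy(), sub_b[feature].to_numpy(), spec.direction
    )
    p_corr, sig = bonferroni([p], spec.family_size, spec.alpha)
    return TestResult(
        feature_name=feature,
        phase_a=phase_a if isinstance(phase_a, str) else phase_a.name,
        phase_b=phase_b if isinstance(phase_b, str) else phase_b.name,
        n_a=len(sub_a),
        n_b=len(sub_b),
        rank_sum_statistic=stat,
        p_one_sided=p,
        p_corrected=float(p_corr[0]),
        significant=bool(sig[0]),
    )


def _direction_for(
    feature: str,
    phase_a: str,
    phase_b: str,
    post_directions: Mapping[str, str],
) -> Direction:
    """One-sided alternative for a comparison given the post-surgery change
    direction of the feature.

    PRE vs POST_EARLY tests worsening: a feature that decreases after
    surgery makes PRE the larger group ('a_greater').  Comparisons of
    POST_EARLY against later windows invert the direction to test for
    improvement (the later window moves back toward PRE).
    """
    try:
        post_dir = post_directions[feature]
    except KeyError:
        raise ValueError(f"no test direction known for feature {feature!r}")
    worsening: Direction = "a_greater" if post_dir == "decrease" else "a_less"
    if phase_a == "PRE":
        return worsening
    # improvement: later phase (b) moves back toward PRE, i.e. the early
    # post window is extreme in the worsened direction
    return "a_less" if worsening == "a_greater" else "a_greater"


def run_comparisons(
    feature_table: pd.DataFrame,
    features: Sequence[str],
    comparisons: Sequence[tuple[str, str]],
    family_size: int,
    post_directions: Mapping[str, str] = DEFAULT_POST_DIRECTIONS,
    alpha: float = 0.05,
    plan: SamplingPlan = SamplingPlan(),
) -> pd.DataFrame:
    """Run a family of phase comparisons and return a tidy results table.

    ``comparisons`` are (phase_a, phase_b) name pairs, e.g.
    ``[("PRE", "POST_EARLY")]`` or ``[("POST_EARLY", "POST_LATE")]``.  Test
    directions are derived per feature from ``post_directions``; directions
    invert automatically for improvement (post-vs-later) comparisons.
    """
    rows = []
    comparisons = list(comparisons)
    children = np.random.SeedSequence(plan.seed).spawn(len(comparisons))
    for (phase_a, phase_b), child in zip(comparisons, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        for feature in features:
            direction = _direction_for(feature, phase_a, phase_b, post_directions)
            spec = TestSpec(feature, direction, family_size, alpha)
            res = compare_phases(
                feature_table, feature, phase_a, phase_b, spec,
                SamplingPlan(plan.per_date_count, plan.allow_fewer, sub_seed),
            )
            rows.append(
                {
                    "feature": res.feature_name,
                    "phase_a": res.phase_a,
                    "phase_b": res.phase_b,
                    "direction": direction,
                    "n_a": res.n_a,
                    "n_b": res.n_b,
                    "rank_sum": res.rank_sum_statistic,
                    "p_one_sided": res.p_one_sided,
                    "p_corrected": res.p_corrected,
                    "significant": res.significant,
                }
            )
    return pd.DataFrame(rows)
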