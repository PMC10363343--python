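"""Statistical comparison of paradigm-labeled centrality scores.

Implements the inference layer of the analysis: a Shapiro-Wilk normality
gate choosing between the paired t-test and a paired sign-flip permutation
test, the two-sided permutation rule p = 2 min(p_l, p_g), Bonferroni
correction, directional hypothesis evaluation across a Mapper parameter
sweep, and modularity-response-time correlation.

The permutation test's null distribution is generated by independently
negating each subject's paired difference ("swapping" the two paradigms'
scores for that subject): exact enumeration of all 2^n sign patterns for
small cohorts, seeded Monte Carlo sampling otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import InsufficientDataError, UsageError

logger = logging.getLogger(__name__)

#: Exact enumeration is used whenever the number of pairs is at most this.
EXACT_ENUMERATION_LIMIT = 20

_ALTERNATIVES = ("two_sided", "greater", "less")


@dataclass
class PairedSample:
    """Per-subject paired scores for two conditions.

    One instance holds, for every subject, the score under condition A and
    the score under condition B (e.g. mean closeness centrality of the
    working-memory-dominated vs story/math-dominated Mapper nodes).
    """

    subject_ids: list[str]
    score_a: np.ndarray
    score_b: np.ndarray
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        self.score_a = np.asarray(self.score_a, dtype=float)
        self.score_b = np.asarray(self.score_b, dtype=float)
        n = len(self.subject_ids)
        if not (len(self.score_a) == len(self.score_b) == n):
            raise UsageError("subject ids and both score lists must have equal length")
        if n < 2:
            raise UsageError("a paired sample needs at least 2 pairs")

    def __len__(self) -> int:
        return len(self.subject_ids)


@dataclass
class TestResult:
    """Outcome of one paired test.

    ``p_l`` and ``p_g`` are the lower/upper tail probabilities of the test
    statistic under the null; for the two-sided permutation test the raw p
    is ``min(1, 2 min(p_l, p_g))``.
    """

    test_type: str
    statistic: float
    p_l: float
    p_g: float
    p_raw: float
    alternative: str
    n_pairs: int
    n_permutations: int | str | None = None
    p_corrected: float | None = None


@dataclass
class HypothesisResult:
    """Directional hypothesis evaluated across a Mapper parameter sweep."""

    hypothesis: str
    satisfied: bool
    n_triples: int
    n_satisfied: int
    required_fraction: float
    per_triple: dict = field(default_factory=dict)


def paired_differences(sample: PairedSample) -> np.ndarray:
    """Per-subject differences ``score_a - score_b``, order preserved."""
    return sample.score_a - sample.score_b


def normality_gate(differences: Sequence[float], alpha: float = 0.05) -> tuple[str, float]:
    """Choose the paired test from a Shapiro-Wilk check of the differences.

    Returns ``(test_type, shapiro_p)`` where ``test_type`` is
    ``"paired_permutation"`` when normality is rejected at ``alpha`` (or the
    differences are constant, where normality is undefined) and
    ``"paired_t"`` otherwise.
    """
    d = np.asarray(differences, dtype=float)
    if len(d) < 3:
        raise UsageError("normality gate needs at least 3 differences")
    if np.ptp(d) == 0:
        logger.warning("constant differences: normality undefined, using permutation test")
        return "paired_permutation", float("nan")
    p = float(sps.shapiro(d).pvalue)
    return ("paired_permutation" if p < alpha else "paired_t"), p


def paired_t_test(sample: PairedSample, alternative: str = "two_sided") -> TestResult:
    """Classical paired t-test on ``score_a - score_b``."""
    if alternative not in _ALTERNATIVES:
        raise UsageError(f"unknown alternative {alternative!r}")
    d = paired_differences(sample)
    if np.ptp(d) == 0:
        raise UsageError("paired t-test undefined for constant differences")
    t = float(sps.ttest_rel(sample.score_a, sample.score_b).statistic)
    df = len(d) - 1
    p_g = float(sps.t.sf(t, df))
    p_l = float(sps.t.cdf(t, df))
    p_raw = {"two_sided": min(1.0, 2 * min(p_l, p_g)), "greater": p_g, "less": p_l}[alternative]
    return TestResult(
        test_type="paired_t",
        statistic=t,
        p_l=p_l,
        p_g=p_g,
        p_raw=p_raw,
        alternative=alternative,
        n_pairs=len(d),
    )


def _exact_sign_flip_tails(d: np.ndarray, mu_obs: float) -> tuple[float, float, int]:
    """Enumerate all 2^n sign patterns of ``d`` and return inclusive tails."""
    n = len(d)
    total = 1 << n
    tol = 1e-12 * max(1.0, abs(mu_obs))
    count_ge = 0
    count_le = 0
    chunk = 1 << 16
    for start in range(0, total, chunk):
        codes = np.arange(start, min(start + chunk, total), dtype=np.int64)
        # bit j of the code decides the sign of difference j
        bits = (codes[:, None] >> np.arange(n)) & 1
        signs = 1 - 2 * bits  # 0 -> +1, 1 -> -1
        means = signs @ d / n
        count_ge += int(np.sum(means >= mu_obs - tol))
        count_le += int(np.sum(means <= mu_obs + tol))
    return count_ge / total, count_le / total, total


def paired_permutation_test(
    sample: PairedSample,
    alternative: str = "two_sided",
    n_perm: int = 10_000,
    seed: int = 0,
    mode: str | None = None,
) -> TestResult:
    """Paired sign-flip permutation test with statistic = mean of differences.

    The null hypothesis of no paradigm difference makes each subject's pair
    exchangeable, so permuted datasets are formed by swapping the two scores
    (negating the difference) for any subset of subjects. ``mode="exact"``
    enumerates all ``2^n`` sign patterns (automatic for ``n <= 20``);
    ``mode="monte_carlo"`` draws ``n_perm`` seeded patterns and reports
    add-one smoothed tail proportions. Two-sided p is
    ``min(1, 2 min(p_l, p_g))``; one-sided alternatives report the
    corresponding tail.
    """
    if alternative not in _ALTERNATIVES:
        raise UsageError(f"unknown alternative {alternative!r}")
    d = paired_differences(sample)
    n = len(d)
    mu_obs = float(d.mean())
    if mode is None:
        mode = "exact" if n <= EXACT_ENUMERATION_LIMIT else "monte_carlo"
    if mode not in ("exact", "monte_carlo"):
        raise UsageError(f"unknown mode {mode!r}")

    if mode == "exact":
        p_g, p_l, total = _exact_sign_flip_tails(d, mu_obs)
        n_used: int | str = "exact"
    else:
        if n_perm < 1:
            raise UsageError("monte_carlo mode needs n_perm >= 1")
        rng = np.random.default_rng(seed)
        tol = 1e-12 * max(1.0, abs(mu_obs))
        count_ge = 0
        count_le = 0
        chunk = 1 << 14
        remaining = n_perm
        while remaining > 0:
            b = min(chunk, remaining)
            signs = rng.choice((-1.0, 1.0), size=(b, n))
            means = signs @ d / n
            count_ge += int(np.sum(means >= mu_obs - tol))
            count_le += int(np.sum(means <= mu_obs + tol))
            remaining -= b
        # add-one smoothing keeps Monte Carlo p strictly positive
        p_g = (count_ge + 1) / (n_perm + 1)
        p_l = (count_le + 1) / (n_perm + 1)
        n_used = n_perm

    p_raw = {"two_sided": min(1.0, 2 * min(p_l, p_g)), "greater": p_g, "less": p_l}[alternative]
    return TestResult(
        test_type="paired_permutation",
        statistic=mu_obs,
        p_l=float(p_l),
        p_g=float(p_g),
        p_raw=float(p_raw),
        alternative=alternative,
        n_pairs=n,
        n_permutations=n_used,
    )


def bonferroni(raw_p: float, m: int) -> float:
    """Bonferroni-corrected p value ``min(1, m * raw_p)``."""
    if not 0 <= raw_p <= 1:
        raise UsageError("raw p must lie in [0, 1]")
    if m < 1:
        raise UsageError("family size must be >= 1")
    return min(1.0, m * raw_p)


def run_paired_test(
    sample: PairedSample,
    alternative: str = "two_sided",
    alpha_normality: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[TestResult, float]:
    """Gate on normality of the differences, then run the chosen paired test.

    Returns the test result together with the Shapiro-Wilk p value used by
    the gate.
    """
    d = paired_differences(sample)
    if len(d) < 3:
        logger.warning("fewer than 3 pairs: normality unassessable, using permutation test")
        test_type, shapiro_p = "paired_permutation", float("nan")
    else:
        test_type, shapiro_p = normality_gate(d, alpha=alpha_normality)
    if test_type == "paired_t":
        result = paired_t_test(sample, alternative=alternative)
    else:
        result = paired_permutation_test(sample, alternative=alternative, n_perm=n_perm, seed=seed)
    return result, shapiro_p


def compare_paradigms(
    samples_by_triple: Mapping[object, PairedSample],
    hypothesis: str = "a_greater",
    alpha: float = 0.05,
    family_size: int | None = None,
    required_fraction: float = 0.95,
    n_perm: int = 10_000,
    seed: int = 0,
) -> HypothesisResult:
    """Evaluate a directional hypothesis across a Mapper parameter sweep.

    For every parameter triple, the per-subject paired sample of paradigm
    mean centralities is tested two-sided (normality-gated), Bonferroni
    corrected with ``family_size`` (default: the number of triples), and the
    direction is read off the sample means. A triple supports the hypothesis
    when the corrected p is below ``alpha`` AND the sample-mean ordering
    matches; the hypothesis is "satisfied" when the supporting fraction of
    triples reaches ``required_fraction``.

    ``hypothesis`` is ``"a_greater"`` (condition A's mean exceeds B's) or
    ``"b_greater"``.
    """
    if hypothesis not in ("a_greater", "b_greater"):
        raise UsageError(f"unknown hypothesis {hypothesis!r}")
    if not samples_by_triple:
        raise InsufficientDataError("no parameter triples supplied")
    m = family_size if family_size is not None else len(samples_by_triple)

    per_triple: dict = {}
    n_sat = 0
    for triple, sample in samples_by_triple.items():
        if len(sample) < 2:
            raise InsufficientDataError("paired comparison needs >= 2 complete subjects")
        result, shapiro_p = run_paired_test(sample, alternative="two_sided", n_perm=n_perm, seed=seed)
        result.p_corrected = bonferroni(result.p_raw, m)
        mean_a = float(sample.score_a.mean())
        mean_b = float(sample.score_b.mean())
        direction = "a_greater" if mean_a > mean_b else "b_greater"
        supported = result.p_corrected < alpha and direction == hypothesis
        n_sat += supported
        per_triple[triple] = {
            "test": result,
            "shapiro_p": shapiro_p,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "direction": direction,
            "supported": bool(supported),
        }
    satisfied = n_sat >= required_fraction * len(per_triple)
    return HypothesisResult(
        hypothesis=hypothesis,
        satisfied=bool(satisfied),
        n_triples=len(per_triple),
        n_satisfied=n_sat,
        required_fraction=required_fraction,
        per_triple=per_triple,
    )


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation coefficient and two-sided significance p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise UsageError("correlate needs two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UsageError("correlation undefined for a constant input")
    if method == "pearson":
        r = sps.pearsonr(x, y)
    elif method == "spearman":
        r = sps.spearmanr(x, y)
    else:
        raise UsageError(f"unknown correlation method {method!r}")
    return float(r.statistic), float(r.pvalue)
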