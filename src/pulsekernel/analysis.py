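"""Kernel summaries, group statistics, controls, and session QC.

A session's temporal weighting is summarized by two scalars computed on
the unit-norm kernel: the *slope* of an ordinary least-squares line fit to
weight vs. pulse index (negative = early weighting, positive = late), and
the *energy*, the sum of squared deviations of the weights from their mean
(zero for perfectly uniform weighting). Group comparisons use an exact
sign test against zero slope per condition, one-way ANOVA on condition
means, and pairwise Bartlett tests on condition variances.

Two further analyses mirror the behavioral controls: the consistency
analysis compares accuracy on "inconsistent" trials (strongest single
pulse opposing the net direction) against difficulty-matched consistent
trials, which separates genuine temporal integration from extrema
detection; and session QC applies three inclusion rules (minimum trial
count, minimum accuracy at the strongest motion values, and a
median-absolute-deviation screen on psychophysical thresholds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .psychometrics import PsychometricFit
from .stimulus import TrialRecord

__all__ = [
    "KernelSummary",
    "SessionStats",
    "SessionQCResult",
    "ConsistencyResult",
    "GroupStatistics",
    "kernel_slope",
    "kernel_energy",
    "summarize_kernel",
    "group_statistics",
    "threshold_weighting_correlation",
    "consistency_analysis",
    "summarize_session",
    "session_qc",
    "MIN_TRIALS",
    "MIN_STRONG_ACCURACY",
    "MAD_THRESHOLD_FACTOR",
]

MIN_TRIALS = 250
MIN_STRONG_ACCURACY = 0.85
MAD_THRESHOLD_FACTOR = 2.0


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class KernelSummary:
    slope: float
    intercept: float
    energy: float


@dataclass(frozen=True)
class SessionStats:
    """Per-session quantities the QC rules and group analyses consume."""

    session_id: str
    subject_id: str
    condition: str
    n_trials: int
    strong_accuracy: float
    threshold: float
    slope: float = float("nan")
    energy: float = float("nan")


@dataclass(frozen=True)
class SessionQCResult:
    session_id: str
    included: bool
    reasons: tuple = ()


@dataclass(frozen=True)
class ConsistencyResult:
    """Accuracies (vs. net direction) on inconsistent and matched trials."""

    inconsistent_accuracy: float
    consistent_accuracy: float
    inconsistent_ci: tuple
    consistent_ci: tuple
    n_inconsistent: int
    n_consistent: int
    n_unmatched: int


@dataclass(frozen=True)
class GroupStatistics:
    sign_test_p: dict
    anova_p: float
    bartlett_p: dict
    group_mean: dict
    group_median: dict
    group_sd: dict


def kernel_slope(weights: Sequence[float]) -> tuple[float, float]:
    """OLS line through (pulse index, weight); returns (slope, intercept).

    Pulse indices are 1-based. A negative slope indicates early weighting,
    a positive slope late weighting.
    """
    w = np.asarray(weights, dtype=float)
    if len(w) < 2:
        raise ValueError("at least two weights are required for a slope")
    idx = np.arange(1, len(w) + 1, dtype=float)
    slope, intercept = np.polyfit(idx, w, 1)
    return float(slope), float(intercept)


def kernel_energy(weights: Sequence[float]) -> float:
    """Sum of squared deviations of the weights from their mean."""
    w = np.asarray(weights, dtype=float)
    return float(np.sum((w - w.mean()) ** 2))


def summarize_kernel(weights_normalized: Sequence[float]) -> KernelSummary:
    slope, intercept = kernel_slope(weights_normalized)
    return KernelSummary(slope, intercept, kernel_energy(weights_normalized))


def _sign_test_p(values: np.ndarray) -> float:
    """Exact two-sided sign test of the median against zero (ties dropped)."""
    nonzero = values[values != 0]
    if len(nonzero) == 0:
        return 1.0
    k = int((nonzero > 0).sum())
    return float(stats.binomtest(k, len(nonzero), 0.5).pvalue)


def group_statistics(
    slopes_by_condition: Mapping[str, Sequence[float]],
    sign_test: str = "sign",
) -> GroupStatistics:
    """Compare slope distributions across stimulus conditions.

    Per condition: a test of median slope against zero (exact sign test by
    default; ``sign_test='signed-rank'`` switches to Wilcoxon signed-rank),
    plus mean/median/SD. Across conditions: one-way ANOVA on means and
    pairwise Bartlett tests on variances.
    """
    groups = {c: np.asarray(v, dtype=float) for c, v in slopes_by_condition.items()}
    for c, v in groups.items():
        if len(v) == 0:
            raise ValueError(f"condition {c!r} has no observations")
    sign_p = {}
    for c, v in groups.items():
        if len(v) < 6:
            raise InsufficientDataError(
                f"condition {c!r} has {len(v)} slopes; >= 6 required for the sign test"
            )
        if sign_test == "sign":
            sign_p[c] = _sign_test_p(v)
        elif sign_test == "signed-rank":
            sign_p[c] = float(stats.wilcoxon(v).pvalue)
        else:
            raise ValueError("sign_test must be 'sign' or 'signed-rank'")
    names = list(groups)
    if len(names) < 2:
        raise InsufficientDataError("ANOVA and Bartlett need >= 2 conditions")
    anova_p = float(stats.f_oneway(*groups.values()).pvalue)
    bartlett_p = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            bartlett_p[(a, b)] = float(stats.bartlett(groups[a], groups[b]).pvalue)
    return GroupStatistics(
        sign_test_p=sign_p,
        anova_p=anova_p,
        bartlett_p=bartlett_p,
        group_mean={c: float(v.mean()) for c, v in groups.items()},
        group_median={c: float(np.median(v)) for c, v in groups.items()},
        group_sd={c: float(v.std(ddof=1)) if len(v) > 1 else float("nan") for c, v in groups.items()},
    )


def threshold_weighting_correlation(
    sessions: pd.DataFrame, min_sessions: int = 4
) -> dict:
    """Pearson r (with two-sided p) of threshold vs. slope and vs. energy.

    ``sessions`` needs columns ``condition``, ``threshold``, ``slope``,
    ``energy``; correlations are computed within each condition.
    """
    required = {"condition", "threshold", "slope", "energy"}
    missing = required - set(sessions.columns)
    if missing:
        raise ValueError(f"sessions table is missing columns: {sorted(missing)}")
    out: dict = {}
    for cond, grp in sessions.groupby("condition"):
        if len(grp) < min_sessions:
            raise InsufficientDataError(
                f"condition {cond!r} has {len(grp)} sessions; >= {min_sessions} required"
            )
        res = {}
        for metric in ("slope", "energy"):
            x = grp["threshold"].to_numpy(dtype=float)
            y = grp[metric].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                raise ValueError(
                    f"constant {metric if np.ptp(y) == 0 else 'threshold'} values "
                    f"in condition {cond!r}: correlation undefined"
                )
            r, p = stats.pearsonr(x, y)
            res[metric] = {"r": float(r), "p": float(p)}
        out[cond] = res
    return out


def _clopper_pearson(k: int, n: int) -> tuple[float, float]:
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    return float(ci.low), float(ci.high)


def consistency_analysis(
    trials: Sequence[TrialRecord],
    choices: Optional[Sequence[int]] = None,
    max_match_distance_lattice: float = 0.5,
    min_inconsistent: int = 20,
) -> ConsistencyResult:
    """Extrema-detection control on inconsistent vs. matched trials.

    The strongest pulse of a trial is the one with the largest absolute
    element count (earliest pulse on ties). Trials where its direction
    opposes the sign of the net strength are *inconsistent*; those where
    it agrees are consistent candidates. Each inconsistent trial is
    matched (greedy nearest-neighbor, no reuse) to a consistent candidate
    on absolute net strength, within ``max_match_distance_lattice`` lattice
    steps; unmatched inconsistent trials are dropped and counted. Accuracy
    is the fraction of choices agreeing with the net direction, with exact
    (Clopper-Pearson) 95% binomial CIs.

    An observer doing extrema detection scores near zero on inconsistent
    trials; a temporal integrator performs comparably on both sets.
    """
    if choices is None:
        if any(t.choice is None for t in trials):
            raise ValueError("trials lack choices; pass a choices vector")
        choices = np.array([t.choice for t in trials], dtype=int)
    else:
        choices = np.asarray(choices, dtype=int)
        if len(choices) != len(trials):
            raise ValueError("one choice per trial required")

    counts = np.vstack([t.pulse_element_counts for t in trials])
    nets = np.array([t.net_strength for t in trials])
    strongest_idx = np.argmax(np.abs(counts), axis=1)
    strongest = counts[np.arange(len(trials)), strongest_idx]

    valid = (nets != 0) & (strongest != 0)
    inconsistent = valid & (np.sign(strongest) != np.sign(nets))
    consistent_pool = valid & (np.sign(strongest) == np.sign(nets))

    inc_idx = np.flatnonzero(inconsistent)
    if len(inc_idx) < min_inconsistent:
        raise InsufficientDataError(
            f"only {len(inc_idx)} inconsistent trials; >= {min_inconsistent} required"
        )

    # lattice step = one element; tolerance expressed in strength units
    n_elem = _infer_n_elements(trials)
    tol = max_match_distance_lattice / n_elem

    pool_idx = list(np.flatnonzero(consistent_pool))
    pool_abs = np.abs(nets)[pool_idx]
    used = np.zeros(len(pool_idx), dtype=bool)
    matched_inc: list[int] = []
    matched_con: list[int] = []
    n_unmatched = 0
    for i in inc_idx:
        d = np.abs(pool_abs - abs(nets[i]))
        d[used] = np.inf
        j = int(np.argmin(d)) if len(d) else -1
        if j >= 0 and d[j] <= tol + 1e-12:
            used[j] = True
            matched_inc.append(i)
            matched_con.append(pool_idx[j])
        else:
            n_unmatched += 1

    if not matched_inc:
        raise InsufficientDataError("no inconsistent trial could be difficulty-matched")

    def _accuracy(idx: list[int]) -> tuple[float, int, int]:
        signs = np.sign(nets[idx])
        ch = np.where(choices[idx] == 1, 1, -1)
        k = int((ch == signs).sum())
        return k / len(idx), k, len(idx)

    acc_i, k_i, n_i = _accuracy(matched_inc)
    acc_c, k_c, n_c = _accuracy(matched_con)
    return ConsistencyResult(
        inconsistent_accuracy=acc_i,
        consistent_accuracy=acc_c,
        inconsistent_ci=_clopper_pearson(k_i, n_i),
        consistent_ci=_clopper_pearson(k_c, n_c),
        n_inconsistent=n_i,
        n_consistent=n_c,
        n_unmatched=n_unmatched,
    )


def _infer_n_elements(trials: Sequence[TrialRecord]) -> int:
    """Lattice denominator: counts/strengths ratio on any nonzero pulse."""
    for t in trials:
        nz = np.flatnonzero(t.pulse_element_counts)
        if len(nz):
            return int(round(t.pulse_element_counts[nz[0]] / t.pulse_strengths[nz[0]]))
    return 1


def summarize_session(
    trials: Sequence[TrialRecord],
    fit: PsychometricFit,
    *,
    slope: float = float("nan"),
    energy: float = float("nan"),
) -> SessionStats:
    """Collect the per-session numbers QC and the group analyses need.

    ``strong_accuracy`` is the proportion correct on trials drawn from the
    largest-|mu| generating distributions, pooling both signs.
    """
    if any(t.choice is None for t in trials):
        raise ValueError("all trials need choices to summarize a session")
    mus = np.array([t.distribution_mu for t in trials])
    strongest_mu = np.max(np.abs(mus))
    strong = np.abs(mus) == strongest_mu
    correct = np.array([t.correct for t in trials], dtype=float)
    strong_acc = float(correct[strong].mean()) if strong.any() else float("nan")
    first = trials[0]
    return SessionStats(
        session_id=first.session_id,
        subject_id=first.subject_id,
        condition=first.condition,
        n_trials=len(trials),
        strong_accuracy=strong_acc,
        threshold=float(fit.threshold75),
        slope=slope,
        energy=energy,
    )


def session_qc(sessions: Sequence[SessionStats]) -> list[SessionQCResult]:
    """Apply the three inclusion rules to a cohort of sessions.

    A session is excluded if it has fewer than 250 completed trials, if
    accuracy on the strongest motion values falls below 85%, or if its
    psychophysical threshold lies more than 2 median absolute deviations
    (unscaled MAD) from the median of that subject's sessions. The MAD
    rule needs at least 3 sessions per subject and is otherwise skipped
    with a warning; it is evaluated on all candidate sessions, before the
    other rules remove any. Results are independent of session order.
    """
    mad_outlier: dict[str, bool] = {}
    by_subject: dict[str, list[SessionStats]] = {}
    for s in sessions:
        by_subject.setdefault(s.subject_id, []).append(s)
    for subject, group in by_subject.items():
        thr = np.array([s.threshold for s in group], dtype=float)
        if len(group) < 3:
            warnings.warn(
                f"subject {subject!r} has {len(group)} sessions; "
                "threshold MAD rule skipped",
                stacklevel=2,
            )
            for s in group:
                mad_outlier[s.session_id] = False
            continue
        med = np.median(thr)
        mad = np.median(np.abs(thr - med))
        for s in group:
            if mad == 0:
                mad_outlier[s.session_id] = s.threshold != med
            else:
                mad_outlier[s.session_id] = (
                    abs(s.threshold - med) > MAD_THRESHOLD_FACTOR * mad
                )

    results = []
    for s in sessions:
        reasons = []
        if s.n_trials < MIN_TRIALS:
            reasons.append("too_few_trials")
        if s.strong_accuracy < MIN_STRONG_ACCURACY:
            reasons.append("low_strong_accuracy")
        if mad_outlier.get(s.session_id, False):
            reasons.append("threshold_outlier")
        results.append(
            SessionQCResult(
                session_id=s.session_id,
                included=not reasons,
                reasons=tuple(reasons),
            )
        )
    return results
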