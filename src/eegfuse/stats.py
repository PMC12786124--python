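"""Statistical comparison across demographic groups and interpretation
of the fusion attention weights.

The paired Wilcoxon signed-rank test uses the exact null distribution
(full sign-assignment enumeration over the ranks of |d|, average ranks
for ties, zeros discarded) for n <= 12 and the tie-corrected normal
approximation beyond; the two-sided p-value is twice the smaller tail,
capped at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fusion import FusionTrace
from .preprocess import EMOTIONS

__all__ = [
    "WilcoxonResult", "paired_wilcoxon", "bonferroni", "difference_ci",
    "group_comparison", "evidence_tier", "summarize_fusion_weights",
    "ImportanceSummary", "demographic_importance",
]

EXACT_N_MAX = 12
OUTCOMES = EMOTIONS + ("overall",)


@dataclass
class WilcoxonResult:
    statistic: float       # W+ = sum of ranks of positive differences
    p_value: float
    n: int                 # differences remaining after zero removal
    method: str            # "exact" | "approx" | "degenerate"
    degenerate: bool = False


def paired_wilcoxon(differences) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test on a difference vector."""
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("differences must be a non-empty 1-D vector")
    d = d[d != 0]                      # classic zero-discard convention
    n = d.size
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n=0,
                              method="degenerate", degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1   # (2^n, n)
        w_all = signs @ ranks
        eps = 1e-9
        p_ge = float((w_all >= w_plus - eps).mean())
        p_le = float((w_all <= w_plus + eps).mean())
        p = min(1.0, 2.0 * min(p_ge, p_le))
        return WilcoxonResult(w_plus, p, n, "exact")
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    if sigma == 0:
        return WilcoxonResult(w_plus, 1.0, n, "degenerate", degenerate=True)
    z = (w_plus - mu) / sigma
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return WilcoxonResult(w_plus, p, n, "approx")


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Family-wise adjustment: p -> min(1, m * p); m defaults to the
    number of supplied p-values."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be at least 1")
    return np.minimum(1.0, m * p)


def difference_ci(differences, level: float = 0.95,
                  method: str = "t", n_boot: int = 10000,
                  seed: int = 0) -> tuple[float, float]:
    """Confidence interval for the mean difference.

    ``t``: mean +/- t_{n-1, (1+level)/2} * SD / sqrt(n).
    ``bootstrap``: percentile interval over resampled means.
    """
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least two differences for an interval")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if np.ptp(d) == 0:
        return float(d[0]), float(d[0])
    if method == "t":
        mean = d.mean()
        sd = d.std(ddof=1)
        half = sps.t.ppf((1 + level) / 2.0, n - 1) * sd / np.sqrt(n)
        return float(mean - half), float(mean + half)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        means = rng.choice(d, size=(n_boot, n), replace=True).mean(axis=1)
        lo, hi = np.quantile(means, [(1 - level) / 2.0, (1 + level) / 2.0])
        return float(lo), float(hi)
    raise ValueError(f"unknown method {method!r}")


def evidence_tier(p: float) -> str:
    """Interpretation bands: <0.01 strong, <0.05 moderate, <0.1 weak."""
    if p < 0.01:
        return "strong"
    if p < 0.05:
        return "moderate"
    if p < 0.1:
        return "weak"
    return "none"


_GROUPERS = {
    "nationality": lambda df: df["nationality"],
    "sex": lambda df: df["sex"],
    "age": lambda df: df["age_group"],
}


def group_comparison(subject_diffs: pd.DataFrame, grouping: str,
                     ci_level: float = 0.95) -> pd.DataFrame:
    """Wilcoxon tests of per-subject accuracy differences within each
    demographic group, for each emotion and overall.

    The Bonferroni family is the whole grouping figure: m = number of
    cells actually tested (groups with >= 2 subjects x 4 outcomes).
    Cells with fewer than two subjects are flagged ``insufficient-n``
    and receive no p-value.
    """
    if grouping not in _GROUPERS:
        raise ValueError(f"grouping must be one of {sorted(_GROUPERS)}")
    if "age_group" not in subject_diffs.columns and grouping == "age":
        subject_diffs = subject_diffs.assign(
            age_group=np.where(subject_diffs["age"] <= 23, "age<=23", "age>23"))
    groups = _GROUPERS[grouping](subject_diffs)
    rows = []
    for group_value in sorted(groups.unique()):
        sub = subject_diffs[groups == group_value]
        for outcome in OUTCOMES:
            d = sub[outcome].to_numpy(dtype=float)
            row = {"grouping": grouping, "group": group_value,
                   "outcome": outcome, "n": len(sub),
                   "mean_diff": float(d.mean()) if len(d) else np.nan}
            if len(sub) < 2:
                row.update(p_raw=np.nan, tested=False, flag="insufficient-n")
            else:
                res = paired_wilcoxon(d)
                row.update(p_raw=res.p_value, tested=True,
                           flag="degenerate" if res.degenerate else "")
                lo, hi = difference_ci(d, level=ci_level)
                row.update(ci_lower=lo, ci_upper=hi)
            rows.append(row)
    report = pd.DataFrame(rows)
    m = int(report["tested"].sum())
    report["m"] = m
    report["p_adjusted"] = np.where(
        report["tested"], bonferroni(report["p_raw"].fillna(1.0), m), np.nan)
    report["tier"] = [evidence_tier(p) if t else ""
                      for p, t in zip(report["p_adjusted"], report["tested"])]
    return report


def summarize_fusion_weights(traces: list[FusionTrace]) -> pd.DataFrame:
    """Mean attention weight per fused dimension across all test samples
    (mean omega1 + mean omega2 = 1 per dimension by construction)."""
    if not traces:
        raise ValueError("no traces supplied")
    w1 = np.concatenate([t.omega1 for t in traces], axis=0)
    w2 = np.concatenate([t.omega2 for t in traces], axis=0)
    return pd.DataFrame({
        "dimension": np.arange(w1.shape[1]),
        "mean_omega1": w1.mean(axis=0),
        "mean_omega2": w2.mean(axis=0),
    }).set_index("dimension")


@dataclass
class ImportanceSummary:
    """Normalized demographic-variable importance, per emotion category."""

    per_emotion: pd.DataFrame      # rows = emotions, cols = demographic vars
    per_subject: pd.DataFrame      # one row per (subject, emotion)


def demographic_importance(traces: list[FusionTrace], L: np.ndarray | None = None,
                           condition_on: str = "true") -> ImportanceSummary:
    """Importance of each original demographic variable, per emotion.

    For every subject and emotion category: take the subject's mean
    omega2 over that category's samples, form |mean_omega2_j * L_ij|
    (the rows of the gated expansion matrix), average over the 16 fused
    columns to a per-variable vector, normalize it to sum 1, then
    average the normalized vectors across subjects.

    ``L`` defaults to each trace's own trained expansion matrix;
    ``condition_on`` selects true or predicted labels.
    """
    if condition_on not in ("true", "predicted"):
        raise ValueError("condition_on must be 'true' or 'predicted'")
    rows = []
    for trace in traces:
        mat = trace.L if L is None else np.asarray(L, dtype=float)
        labels = (trace.true_labels if condition_on == "true"
                  else trace.predicted_labels)
        for subject in np.unique(trace.subject_ids):
            s_mask = trace.subject_ids == subject
            for e_idx, emotion in enumerate(EMOTIONS):
                mask = s_mask & (labels == e_idx)
                if not mask.any():
                    continue
                omega2_bar = trace.omega2[mask].mean(axis=0)       # (16,)
                contrib = np.abs(omega2_bar[None, :] * mat)        # (d, 16)
                v = contrib.mean(axis=1)                           # (d,)
                total = v.sum()
                if total == 0:
                    warnings.warn(
                        f"subject {subject} / {emotion}: zero omega2 mass, "
                        "cell excluded", stacklevel=2)
                    continue
                v = v / total
                rows.append({"subject_id": subject, "emotion": emotion,
                             **dict(zip(trace.demo_columns, v))})
    if not rows:
        raise ValueError("no (subject, emotion) cells with samples")
    per_subject = pd.DataFrame(rows)
    var_cols = [c for c in per_subject.columns
                if c not in ("subject_id", "emotion")]
    per_emotion = per_subject.groupby("emotion")[var_cols].mean().reindex(
        list(EMOTIONS))
    return ImportanceSummary(per_emotion=per_emotion, per_subject=per_subject)
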