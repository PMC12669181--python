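"""Behavioral discrimination indices, inclusion rule, effect sizes, normalization.

The discrimination index D1 for one trial is ``(tNO - tFO) / (tNO + tFO)``
where ``tNO`` and ``tFO`` are the seconds spent exploring the novel and the
familiar object.  D2 applies the same ratio to exploration times accumulated
across trials, which damps single-trial noise; an animal's final D2 must be
strictly above chance (0) for it to enter the activation analyses.

Regional activation counts are normalized within condition as
``value / group mean * 100`` so that every (group, region) cell has mean 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectSize",
    "discrimination_index_d1",
    "cumulative_d2",
    "d2_table",
    "include_by_chance_rule",
    "one_sample_vs_chance",
    "hedges_g",
    "cliffs_delta",
    "omega_squared",
    "normalize_expression",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EffectSize:
    kind: str
    value: float
    label: str


def discrimination_index_d1(t_novel: float, t_familiar: float) -> float:
    """Single-trial discrimination index in [-1, 1]; NaN when nothing was explored."""
    if t_novel < 0 or t_familiar < 0:
        raise ValueError("exploration times must be non-negative")
    total = t_novel + t_familiar
    if total == 0:
        logger.warning("zero total exploration; D1 undefined for this trial")
        return float("nan")
    return (t_novel - t_familiar) / total


def _trial_arrays(trials) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trials, pd.DataFrame):
        novel = trials["t_novel_s"].to_numpy(dtype=float)
        familiar = trials["t_familiar_s"].to_numpy(dtype=float)
    else:
        arr = np.asarray(trials, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("trials must be a (novel, familiar) pair per row")
        novel, familiar = arr[:, 0], arr[:, 1]
    if novel.size == 0:
        raise ValueError("no trials supplied")
    if (novel < 0).any() or (familiar < 0).any():
        raise ValueError("exploration times must be non-negative")
    return novel, familiar


def cumulative_d2(trials) -> np.ndarray:
    """Cumulative discrimination index per trial; the last value is the
    animal's inclusion statistic.

    ``trials`` is either a DataFrame with ``t_novel_s``/``t_familiar_s``
    columns sorted by trial, or an array of (novel, familiar) rows.
    """
    novel, familiar = _trial_arrays(trials)
    cn, cf = np.cumsum(novel), np.cumsum(familiar)
    total = cn + cf
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = np.where(total > 0, (cn - cf) / np.where(total > 0, total, 1.0), np.nan)
    if np.isnan(d2).any():
        logger.warning("zero cumulative exploration at some trial; D2 set to NaN")
    return d2


def d2_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-animal D2 trajectory and inclusion flag from a long behavioral table."""
    out = []
    for animal, sub in trials.sort_values("trial").groupby("animal_id", sort=False):
        d2 = cumulative_d2(sub)
        for trial, value in zip(sub["trial"], d2):
            out.append((animal, int(trial), value))
    table = pd.DataFrame(out, columns=["animal_id", "trial", "d2"])
    final = table.sort_values("trial").groupby("animal_id")["d2"].last()
    table["included"] = table["animal_id"].map(
        final.map(include_by_chance_rule)
    )
    return table


def include_by_chance_rule(final_d2: float) -> bool:
    """Strict above-chance rule: the animal is included iff its final D2 > 0."""
    if final_d2 is None or np.isnan(final_d2):
        logger.warning("missing final D2; animal excluded")
        return False
    return final_d2 > 0


def one_sample_vs_chance(values) -> tuple[float, float]:
    """One-sample t test of the discrimination indices against chance (0)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("at least two values are required")
    if np.ptp(arr) == 0:
        raise ValueError("zero variance; t statistic undefined")
    res = stats.ttest_1samp(arr, popmean=0.0)
    return float(res.statistic), float(res.pvalue)


def hedges_g(x, y) -> EffectSize:
    """Bias-corrected standardized mean difference for two independent samples.

    Pooled-SD Cohen's d times the small-sample correction
    ``J = 1 - 3 / (4 df - 1)`` with ``df = n1 + n2 - 2``.  Labels: |g| <= 0.2
    small, < 0.5 medium, >= 0.5 large.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two values")
    df = x.size + y.size - 2
    pooled_var = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if pooled_var == 0:
        raise ValueError("zero pooled variance; g undefined")
    d = (x.mean() - y.mean()) / np.sqrt(pooled_var)
    g = d * (1.0 - 3.0 / (4.0 * df - 1.0))
    mag = abs(g)
    label = "small" if mag <= 0.2 else ("medium" if mag < 0.5 else "large")
    return EffectSize("hedges_g", float(g), label)


def cliffs_delta(x, y) -> EffectSize:
    """Cliff's delta by exhaustive pair enumeration; ordinal dominance in [-1, 1].

    Labels (closed on the larger-effect side): |delta| < 0.147 none,
    >= 0.147 small, >= 0.33 moderate, >= 0.474 large.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    diff = x[:, None] - y[None, :]
    delta = (np.count_nonzero(diff > 0) - np.count_nonzero(diff < 0)) / diff.size
    mag = abs(delta)
    if mag >= 0.474:
        label = "large"
    elif mag >= 0.33:
        label = "moderate"
    elif mag >= 0.147:
        label = "small"
    else:
        label = "none"
    return EffectSize("cliffs_delta", float(delta), label)


def omega_squared(groups) -> EffectSize:
    """Omega squared from the one-way ANOVA decomposition.

    ``(SS_between - df_between * MS_within) / (SS_total + MS_within)``.
    Labels: < 0.01 small, < 0.14 medium, >= 0.14 large.
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2 or any(s.size < 2 for s in samples):
        raise ValueError("need at least two groups of at least two values each")
    grand = np.concatenate(samples)
    ss_total = ((grand - grand.mean()) ** 2).sum()
    if ss_total == 0:
        raise ValueError("zero total variance; omega squared undefined")
    ss_between = sum(s.size * (s.mean() - grand.mean()) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_between = len(samples) - 1
    df_within = grand.size - len(samples)
    ms_within = ss_within / df_within
    omega = (ss_between - df_between * ms_within) / (ss_total + ms_within)
    label = "small" if omega < 0.01 else ("medium" if omega < 0.14 else "large")
    return EffectSize("omega_squared", float(omega), label)


def normalize_expression(table: pd.DataFrame) -> pd.DataFrame:
    """Express each region value as percent of its (group, region) mean.

    After normalization every (group, region) cell has mean exactly 100.
    Non-region columns ``animal_id`` and ``group`` are passed through.
    """
    regions = [c for c in table.columns if c not in ("animal_id", "group")]
    means = table.groupby("group")[regions].transform("mean")
    bad = means.columns[(means <= 0).any(axis=0)]
    if len(bad):
        zero = table.groupby("group")[regions].mean()
        culprits = [
            f"region {r!r} in group {g!r}"
            for r in bad
            for g in zero.index[zero[r] <= 0]
        ]
        raise ValueError("non-positive group mean for " + "; ".join(culprits))
    out = table.copy()
    out[regions] = table[regions] / means * 100.0
    return out
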