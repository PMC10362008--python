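"""Feature-outcome correlations and dependent overlapping-correlation tests.

Each retained feature's continuous value is correlated (Pearson) with each
behavioral outcome; differences in correlation magnitude between two
features against the same outcome are tested with overlapping dependent-
correlation statistics, which account for the correlation between the two
feature values themselves.  Bonferroni correction multiplies p-values by
the number of outcomes in the outcome's family (impulsive behavior: 2;
substance use: 4 by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OutcomeTable", "CorrelationEstimate", "DependentComparisonResult",
    "pearson_pairwise", "dependent_overlapping_test", "bonferroni_adjust",
    "build_comparison_table", "DEFAULT_FAMILY_SIZES",
]

#: Bonferroni family sizes: number of measures per outcome family.
DEFAULT_FAMILY_SIZES = {"impulsive_behavior": 2, "substance_use": 4}


class UndefinedCorrelationError(ValueError):
    """Too few joint observations or zero variance."""


class AlignmentError(ValueError):
    """Participant ids do not line up across tables."""


@dataclass(frozen=True)
class OutcomeTable:
    """Participants x outcomes with a mask and per-outcome family labels."""

    participant_ids: tuple
    values: pd.DataFrame          # numeric, NaN where missing
    families: dict[str, str]      # outcome name -> family label

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.families]
        if missing:
            raise ValueError(f"no family label for outcome(s): {missing}")
        if len(self.participant_ids) != len(self.values):
            raise ValueError("participant_ids length mismatch")

    @property
    def outcome_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> np.ndarray:
        return self.values.notna().to_numpy()


@dataclass(frozen=True)
class CorrelationEstimate:
    feature_id: int | str
    outcome: str
    r: float
    n_effective: int
    p: float


@dataclass(frozen=True)
class DependentComparisonResult:
    feature_j: int | str
    feature_k: int | str
    outcome: str
    r_jy: float
    r_ky: float
    r_jk: float
    statistic: float
    p: float
    n: int
    bonferroni_m: int
    significant_adjusted: bool


def pearson_pairwise(a, b) -> tuple[float, int, float]:
    """Pearson r over jointly observed pairs; returns (r, n, p).

    Missing entries are NaN.  The p-value is two-sided from
    t = r sqrt((n-2)/(1-r^2)).  Fewer than 3 joint pairs or zero variance
    raises :class:`UndefinedCorrelationError`.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    joint = np.isfinite(a) & np.isfinite(b)
    n = int(joint.sum())
    if n < 3:
        raise UndefinedCorrelationError(
            f"only {n} jointly observed pair(s); need >= 3")
    aj, bj = a[joint], b[joint]
    if aj.std() == 0 or bj.std() == 0:
        raise UndefinedCorrelationError("zero variance in a joint sample")
    r, p = stats.pearsonr(aj, bj)
    return float(r), n, float(p)


def _check_triple(r_jy: float, r_ky: float, r_jk: float) -> None:
    for name, r in (("r_jy", r_jy), ("r_ky", r_ky), ("r_jk", r_jk)):
        if abs(r) >= 1:
            raise ValueError(f"{name} = {r} is degenerate (|r| >= 1)")
    c = np.array([[1, r_jk, r_jy], [r_jk, 1, r_ky], [r_jy, r_ky, 1.0]])
    if np.linalg.eigvalsh(c).min() < -1e-10:
        raise ValueError("correlation triple is not positive semidefinite")


def dependent_overlapping_test(r_jy: float, r_ky: float, r_jk: float,
                               n: int, method: str = "steiger"
                               ) -> tuple[float, float]:
    """Test H0: rho_jy = rho_ky for two correlations sharing variable y.

    ``steiger`` (default): Dunn-Clark-type z on Fisher-transformed
    correlations, with the covariance term evaluated at the average of the
    two overlapping correlations.  ``williams``: Williams' t with n - 3
    degrees of freedom.  ``zou``: difference statistic with a p-value
    derived from the confidence interval for rho_jy - rho_ky built from
    back-transformed Fisher limits.

    Returns (statistic, two-sided p).  The statistic is antisymmetric in
    (j, k); p is invariant.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if r_jy == r_ky:
        # the null holds exactly, whatever the overlap (including the
        # degenerate identical-features case r_jk = 1)
        return 0.0, 1.0
    _check_triple(r_jy, r_ky, r_jk)
    if method == "steiger":
        rbar = (r_jy + r_ky) / 2.0
        cov = (r_jk * (1 - 2 * rbar ** 2)
               - 0.5 * rbar ** 2 * (1 - 2 * rbar ** 2 - r_jk ** 2))
        cov /= (1 - rbar ** 2) ** 2
        z = ((math.atanh(r_jy) - math.atanh(r_ky))
             * math.sqrt((n - 3) / (2.0 - 2.0 * cov)))
        return z, 2 * stats.norm.sf(abs(z))
    if method == "williams":
        rbar = (r_jy + r_ky) / 2.0
        det = (1 - r_jy ** 2 - r_ky ** 2 - r_jk ** 2
               + 2 * r_jy * r_ky * r_jk)
        denom = (2 * det * (n - 1) / (n - 3)
                 + rbar ** 2 * (1 - r_jk) ** 3)
        t = (r_jy - r_ky) * math.sqrt((n - 1) * (1 + r_jk) / denom)
        return t, 2 * stats.t.sf(abs(t), n - 3)
    if method == "zou":
        diff = r_jy - r_ky
        # p such that the level-(1-p) Zou interval just touches zero
        lo, hi = zou_confidence_interval(r_jy, r_ky, r_jk, n, alpha=0.05)
        # invert numerically on the confidence level
        from scipy.optimize import brentq
        def edge(alpha):
            lo, hi = zou_confidence_interval(r_jy, r_ky, r_jk, n, alpha)
            return lo if diff > 0 else hi
        if diff == 0:
            return 0.0, 1.0
        try:
            p = brentq(edge, 1e-12, 1 - 1e-12, xtol=1e-12)
        except ValueError:
            p = 1.0
        return diff, min(1.0, p)
    raise ValueError(f"unknown method {method!r}")


def zou_confidence_interval(r_jy: float, r_ky: float, r_jk: float, n: int,
                            alpha: float = 0.05) -> tuple[float, float]:
    """Zou-style 100(1-alpha)% CI for rho_jy - rho_ky (overlapping case)."""
    _check_triple(r_jy, r_ky, r_jk)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    se = 1.0 / math.sqrt(n - 3)
    l1, u1 = (math.tanh(math.atanh(r_jy) + s * zcrit * se) for s in (-1, 1))
    l2, u2 = (math.tanh(math.atanh(r_ky) + s * zcrit * se) for s in (-1, 1))
    c = ((r_jk - 0.5 * r_jy * r_ky)
         * (1 - r_jy ** 2 - r_ky ** 2 - r_jk ** 2) + r_jk ** 3)
    c /= (1 - r_jy ** 2) * (1 - r_ky ** 2)
    diff = r_jy - r_ky
    lo = diff - math.sqrt((r_jy - l1) ** 2 + (u2 - r_ky) ** 2
                          - 2 * c * (r_jy - l1) * (u2 - r_ky))
    hi = diff + math.sqrt((u1 - r_jy) ** 2 + (r_ky - l2) ** 2
                          - 2 * c * (u1 - r_jy) * (r_ky - l2))
    return lo, hi


def bonferroni_adjust(p: float, m: int) -> float:
    """min(1, m * p) — family-size Bonferroni correction."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def build_comparison_table(values: np.ndarray | pd.DataFrame,
                           outcomes: OutcomeTable,
                           feature_ids=None,
                           family_sizes: dict[str, int] | None = None,
                           alpha: float = 0.05,
                           method: str = "steiger",
                           participant_ids=None
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate features with outcomes and compare all feature pairs.

    ``values`` holds the continuous feature values (participants x
    features).  Returns two tables: a wide correlation table (one row per
    outcome, one r column per feature) and a long comparison table with one
    row per outcome and feature pair (r_jy, r_ky, r_jk, statistic, p,
    p_adjusted, significant).  Every comparison uses the subsample jointly
    observed on both features and the outcome, so the correlation triple is
    internally consistent.  Outcomes observed on no participant are
    excluded with a warning.
    """
    if family_sizes is None:
        family_sizes = dict(DEFAULT_FAMILY_SIZES)
    if isinstance(values, pd.DataFrame):
        if participant_ids is None:
            participant_ids = tuple(values.index)
        feat_names = list(values.columns)
        vals = values.to_numpy(float)
    else:
        vals = np.asarray(values, float)
        feat_names = list(range(vals.shape[1]))
    if participant_ids is not None:
        if tuple(participant_ids) != tuple(outcomes.participant_ids):
            bad = [pid for pid, oid in zip(participant_ids,
                                           outcomes.participant_ids)
                   if pid != oid]
            raise AlignmentError(
                f"participant ids misaligned with outcomes: {bad[:5]}...")
    if len(vals) != len(outcomes.values):
        raise AlignmentError("row count mismatch between feature values "
                             "and outcomes")
    if feature_ids is None:
        feature_ids = list(range(vals.shape[1]))
    feature_ids = list(feature_ids)

    corr_rows, comp_rows = [], []
    for yname in outcomes.outcome_names:
        y = outcomes.values[yname].to_numpy(float)
        if not np.isfinite(y).any():
            warnings.warn(f"outcome {yname!r} has no observed values; "
                          "excluded from the comparison table")
            continue
        family = outcomes.families[yname]
        m_family = family_sizes.get(family, 1)
        row = {"outcome": yname, "family": family}
        for k in feature_ids:
            try:
                r, n_eff, p = pearson_pairwise(vals[:, k], y)
            except UndefinedCorrelationError:
                r, n_eff, p = np.nan, 0, np.nan
            row[f"r_feature_{feat_names[k]}"] = r
            row[f"n_feature_{feat_names[k]}"] = n_eff
        corr_rows.append(row)
        for j, k in combinations(feature_ids, 2):
            joint = (np.isfinite(vals[:, j]) & np.isfinite(vals[:, k])
                     & np.isfinite(y))
            n = int(joint.sum())
            if n < 4:
                continue
            try:
                r_jy, _, _ = pearson_pairwise(
                    np.where(joint, vals[:, j], np.nan), y)
                r_ky, _, _ = pearson_pairwise(
                    np.where(joint, vals[:, k], np.nan), y)
                r_jk, _, _ = pearson_pairwise(
                    np.where(joint, vals[:, j], np.nan),
                    np.where(joint, vals[:, k], np.nan))
            except UndefinedCorrelationError:
                continue
            stat, p = dependent_overlapping_test(r_jy, r_ky, r_jk, n,
                                                 method=method)
            p_adj = bonferroni_adjust(p, m_family) if np.isfinite(p) else p
            comp_rows.append({
                "outcome": yname, "family": family,
                "feature_j": feat_names[j], "feature_k": feat_names[k],
                "r_jy": r_jy, "r_ky": r_ky, "r_jk": r_jk,
                "statistic": stat, "p": p, "n": n,
                "bonferroni_m": m_family, "p_adjusted": p_adj,
                "significant_adjusted": bool(p_adj < alpha)})
    corr = pd.DataFrame(corr_rows)
    comp = pd.DataFrame(comp_rows, columns=[
        "outcome", "family", "feature_j", "feature_k", "r_jy", "r_ky",
        "r_jk", "statistic", "p", "n", "bonferroni_m", "p_adjusted",
        "significant_adjusted"])
    return corr, comp
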