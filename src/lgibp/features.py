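"""Feature filtering, profiling, demographic checks and split-half stability.

Features with very few members are individually informative but do not
support group-level conclusions, so downstream analyses retain only
features sampled by at least a fixed fraction of the sample (default 5%).
Retained features are profiled as per-measure mean z-scores over their
members, checked for demographic balance, and (optionally) assessed for
stability by refitting on random halves of the sample and matching features
across the two fits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .preprocessing import StandardizedBattery
from .sampler import SamplerConfig, run_sampler

__all__ = [
    "FeatureFilterResult", "FeatureProfile", "FeatureMatchResult",
    "inclusion_threshold", "filter_features", "summarize_feature",
    "feature_profiles", "demographic_tests", "match_features",
    "split_half_stability",
]


@dataclass(frozen=True)
class FeatureFilterResult:
    threshold_count: int
    retained_feature_ids: tuple[int, ...]
    counts: dict[int, int]  # member counts for every feature, kept or not

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": list(self.counts),
            "count": list(self.counts.values()),
            "retained": [f in self.retained_feature_ids for f in self.counts],
        })


@dataclass(frozen=True)
class FeatureProfile:
    """Per-measure mean z-score and standard error over a feature's members.

    Means use members' observed cells only; SE = SD / sqrt(number of
    contributing cells), reported as NaN when fewer than two cells
    contribute.
    """

    feature_id: int
    measure_ids: tuple[str, ...]
    mean_z: np.ndarray
    se: np.ndarray
    member_count: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.feature_id, "measure": list(self.measure_ids),
            "mean_z": self.mean_z, "se": self.se, "n": self.member_count})


@dataclass(frozen=True)
class FeatureMatchResult:
    """One-to-one matching of features across two fits."""

    pairs: tuple[tuple[int, int], ...]
    similarities: tuple[float, ...]
    unmatched_first: tuple[int, ...] = ()
    unmatched_second: tuple[int, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature_first": [p[0] for p in self.pairs],
            "feature_second": [p[1] for p in self.pairs],
            "cosine_similarity": list(self.similarities)})


def inclusion_threshold(n: int, fraction: float = 0.05) -> int:
    """Minimum member count for retention: floor(fraction * n).

    With n = 673 and the default 5% fraction this gives 33.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    return math.floor(fraction * n)


def filter_features(z: np.ndarray, threshold: int) -> FeatureFilterResult:
    """Retain exactly the features whose final-iteration member count
    reaches ``threshold``; counts are reported for all features."""
    counts = {k: int(z[:, k].sum()) for k in range(z.shape[1])}
    retained = tuple(k for k, c in counts.items() if c >= threshold)
    return FeatureFilterResult(threshold, retained, counts)


def summarize_feature(battery: StandardizedBattery, members: np.ndarray,
                      feature_id: int = 0) -> FeatureProfile:
    """Profile one feature: per-measure mean and SE of members' z-scores."""
    members = np.asarray(members)
    if members.dtype == bool:
        members = np.flatnonzero(members)
    if len(members) == 0:
        raise ValueError("feature has no members")
    vals = battery.values[members]
    mask = battery.mask[members]
    d = battery.n_measures
    mean_z = np.full(d, np.nan)
    se = np.full(d, np.nan)
    for j in range(d):
        cells = vals[mask[:, j], j]
        if cells.size:
            mean_z[j] = cells.mean()
        if cells.size >= 2:
            se[j] = cells.std(ddof=1) / math.sqrt(cells.size)
    return FeatureProfile(feature_id, tuple(battery.schema.measure_ids),
                          mean_z, se, int(len(members)))


def feature_profiles(battery: StandardizedBattery, z: np.ndarray,
                     feature_ids=None) -> pd.DataFrame:
    """Long-format profile table (feature, measure, mean_z, se, n) for the
    given features (default: all)."""
    if feature_ids is None:
        feature_ids = range(z.shape[1])
    frames = [summarize_feature(battery, z[:, k].astype(bool), k).to_frame()
              for k in feature_ids]
    return (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=["feature", "measure", "mean_z",
                                       "se", "n"]))


def demographic_tests(z: np.ndarray, demographics: pd.DataFrame,
                      feature_ids=None, age_col: str = "age",
                      categorical_cols: tuple[str, ...] = ("sex", "race")
                      ) -> pd.DataFrame:
    """Member/non-member demographic balance checks per feature.

    Age: one-way ANOVA F test between members and non-members.  Each
    categorical column: chi-square test of independence of membership vs
    category.  Tests with an all-zero expected cell are skipped with a
    warning.  Returns a long table (feature, variable, test, statistic, df,
    p).
    """
    if feature_ids is None:
        feature_ids = range(z.shape[1])
    rows = []
    for k in feature_ids:
        member = z[:, k].astype(bool)
        if member.all() or not member.any():
            warnings.warn(f"feature {k}: degenerate membership, "
                          "demographic tests skipped")
            continue
        if age_col in demographics:
            age = demographics[age_col].to_numpy(float)
            f, p = stats.f_oneway(age[member], age[~member])
            rows.append({"feature": k, "variable": age_col, "test": "anova",
                         "statistic": float(f), "df": 1.0, "p": float(p)})
        for col in categorical_cols:
            if col not in demographics:
                continue
            tab = pd.crosstab(member, demographics[col])
            if (tab.to_numpy() == 0).all(axis=0).any() or tab.shape[0] < 2:
                warnings.warn(f"feature {k}: empty expected cell for "
                              f"{col}, chi-square skipped")
                continue
            chi2, p, dof, _ = stats.chi2_contingency(tab)
            rows.append({"feature": k, "variable": col, "test": "chi2",
                         "statistic": float(chi2), "df": float(dof),
                         "p": float(p)})
    return pd.DataFrame(rows, columns=["feature", "variable", "test",
                                       "statistic", "df", "p"])


def _cosine_matrix(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    n1 = np.linalg.norm(a1, axis=1, keepdims=True)
    n2 = np.linalg.norm(a2, axis=1, keepdims=True)
    n1[n1 == 0] = 1.0
    n2[n2 == 0] = 1.0
    return (a1 / n1) @ (a2 / n2).T


def match_features(a_first: np.ndarray, a_second: np.ndarray
                   ) -> FeatureMatchResult:
    """One-to-one match of two fits' features maximizing total cosine
    similarity of their weight (or profile) vectors.

    Feature identity is not meaningful across runs (label switching), so
    every cross-run comparison goes through this assignment.
    """
    k1, k2 = a_first.shape[0], a_second.shape[0]
    if k1 == 0 or k2 == 0:
        return FeatureMatchResult((), (), tuple(range(k1)),
                                  tuple(range(k2)))
    sim = _cosine_matrix(np.asarray(a_first, float),
                         np.asarray(a_second, float))
    ri, ci = linear_sum_assignment(-sim)
    pairs = tuple(zip(ri.tolist(), ci.tolist()))
    sims = tuple(float(sim[i, j]) for i, j in pairs)
    return FeatureMatchResult(
        pairs, sims,
        tuple(i for i in range(k1) if i not in set(ri.tolist())),
        tuple(j for j in range(k2) if j not in set(ci.tolist())))


def split_half_stability(battery: StandardizedBattery,
                         config: SamplerConfig | None = None,
                         seed: int = 0, filter_fraction: float = 0.05
                         ) -> FeatureMatchResult:
    """Refit on two random halves of the sample and match retained features.

    The split is a seeded permutation; each half is fitted independently
    (sampler seeds derived from ``seed``), features are filtered at
    ``filter_fraction`` of the half-sample size, and retained features are
    matched across halves on weight-vector cosine similarity.  Zero retained
    features in a half is reported as unmatched, not an error.
    """
    if config is None:
        config = SamplerConfig()
    n = battery.n_participants
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    halves = perm[:n // 2], perm[n // 2:]
    fits = []
    for half_idx, rows in enumerate(halves):
        sub = StandardizedBattery(
            tuple(battery.participant_ids[i] for i in rows),
            battery.values[rows], battery.mask[rows], battery.schema,
            battery.column_means, battery.column_sds)
        cfg = SamplerConfig(**{**config.__dict__,
                               "seed": int(rng.integers(2 ** 31))})
        state, _ = run_sampler(sub, cfg)
        thr = inclusion_threshold(len(rows), filter_fraction)
        kept = filter_features(state.z, thr).retained_feature_ids
        fits.append(state.a[list(kept)] if kept
                    else np.zeros((0, battery.n_measures)))
    return match_features(fits[0], fits[1])
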