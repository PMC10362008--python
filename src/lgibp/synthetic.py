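"""Synthetic batteries, outcomes and demographics with planted ground truth.

The generator emulates the statistical structure the analysis assumes — a
binary-feature linear-Gaussian battery with missing-completely-at-random
cells, plus outcomes with controlled correlations to the planted feature
memberships — so every pipeline stage can be verified against known truth.
Memberships are planted as independent Bernoulli draws (not the IBP prior)
so feature popularity, and hence filter behavior, is controllable; the IBP
prior simulator in :mod:`lgibp.sampler` covers prior-distribution testing.
Batteries can be emitted on an arbitrary raw scale (per-measure shift and
scale) so the preprocessing stage is exercised end-to-end; z-scoring is
affine-invariant, so this does not change the fitted model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import rankdata

from .correlations import OutcomeTable
from .preprocessing import RawBattery
from .schema import Battery, MeasureDescriptor, MeasureSchema, default_schema

__all__ = [
    "OutcomeSpec", "SyntheticConfig", "PlantedModel", "SyntheticDataset",
    "plant_model", "generate_battery", "generate_outcomes",
    "generate_demographics", "generate_dataset", "recovery_report",
    "RecoveryReport",
]


@dataclass(frozen=True)
class OutcomeSpec:
    """One synthetic outcome: name, Bonferroni family, and the target
    population correlation with each planted feature's membership."""

    name: str
    family: str
    rho: tuple[float, ...]


@dataclass
class SyntheticConfig:
    """Ground-truth generating conditions.

    Defaults mirror a desk-scale version of the study design: 27 measures,
    five planted features each loading on a disjoint block of measures,
    moderate membership rates, noise SD 0.5, and 5% missing cells.
    """

    n_participants: int = 300
    n_measures: int = 27
    planted_k: int = 5
    weight_scale: float = 1.0
    noise_sd: float = 0.5
    missing_rate: float = 0.05
    membership_probs: tuple[float, ...] | float = 0.3
    block_weights: bool = True
    raw_scale: bool = True
    outcome_specs: tuple[OutcomeSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_measures) < 1:
            raise ValueError("dimensions must be positive")
        if self.planted_k < 0:
            raise ValueError("planted_k must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        probs = self.probs_vector()
        if self.planted_k and not ((probs > 0) & (probs < 1)).all():
            raise ValueError("membership_probs must lie in (0, 1)")
        for spec in self.outcome_specs:
            if len(spec.rho) != self.planted_k:
                raise ValueError(
                    f"outcome {spec.name!r}: need one rho per planted "
                    "feature")
            if any(abs(r) >= 1 for r in spec.rho):
                raise ValueError("|rho| must be < 1")

    def probs_vector(self) -> np.ndarray:
        p = self.membership_probs
        if np.isscalar(p):
            return np.full(self.planted_k, float(p))
        return np.asarray(p, float)


@dataclass(frozen=True)
class PlantedModel:
    """Ground truth behind a synthetic dataset."""

    z_true: np.ndarray          # N x K binary memberships
    a_true: np.ndarray          # K x D weights
    noise_sd: float
    outcome_betas: dict[str, np.ndarray]
    outcome_noise_sd: dict[str, float]


@dataclass(frozen=True)
class SyntheticDataset:
    battery: RawBattery
    outcomes: OutcomeTable
    demographics: pd.DataFrame
    planted: PlantedModel
    config: SyntheticConfig


def _synthetic_schema(d: int) -> MeasureSchema:
    if d == 27:
        return default_schema()
    return MeasureSchema(tuple(
        MeasureDescriptor(f"measure_{j + 1:02d}", Battery.CNB, "synthetic",
                          f"synthetic score {j + 1}")
        for j in range(d)))


def plant_model(config: SyntheticConfig) -> PlantedModel:
    """Draw ground-truth memberships and weights.

    Memberships: independent Bernoulli per feature.  Weights: iid
    Normal(0, weight_scale^2); with ``block_weights`` each feature's
    support is restricted to its own disjoint block of measures, giving
    interpretable, well-separated features for recovery studies.
    """
    k, d = config.planted_k, config.n_measures
    if config.block_weights and k > 0 and k > d:
        raise ValueError("block weights need planted_k <= n_measures")
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seed, 0x5eed]))
    probs = config.probs_vector()
    z = (rng.random((config.n_participants, k)) < probs).astype(np.int8)
    a = rng.normal(0.0, config.weight_scale, size=(k, d))
    if config.block_weights and k > 0:
        blocks = np.array_split(np.arange(d), k)
        keep = np.zeros((k, d), dtype=bool)
        for i, b in enumerate(blocks):
            keep[i, b] = True
        a = np.where(keep, a, 0.0)
    betas, noises = _solve_outcome_coefficients(config, probs)
    return PlantedModel(z, a, config.noise_sd, betas, noises)


def _solve_outcome_coefficients(config: SyntheticConfig, probs: np.ndarray
                                ) -> tuple[dict, dict]:
    """beta_k and outcome noise SD so that corr(y, z_k) = rho_k exactly in
    population, with unit outcome variance: beta_k = rho_k / sd(z_k), noise
    variance 1 - sum rho_k^2 (memberships are independent)."""
    betas, noises = {}, {}
    for spec in config.outcome_specs:
        rho = np.asarray(spec.rho, float)
        resid_var = 1.0 - float(rho @ rho)
        if resid_var <= 0:
            raise ValueError(
                f"outcome {spec.name!r}: requested correlations imply "
                f"non-positive noise variance ({resid_var:.3f})")
        sd_z = np.sqrt(probs * (1 - probs))
        betas[spec.name] = rho / sd_z if len(rho) else rho
        noises[spec.name] = float(np.sqrt(resid_var))
    return betas, noises


def generate_battery(planted: PlantedModel, config: SyntheticConfig
                     ) -> RawBattery:
    """X = Z A + noise, MCAR-masked, optionally shifted/scaled per measure
    onto an arbitrary raw scale."""
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seed, 0xba77]))
    n, d = config.n_participants, config.n_measures
    values = planted.z_true @ planted.a_true + rng.normal(
        0.0, planted.noise_sd, size=(n, d))
    if config.raw_scale:
        shift = rng.uniform(10.0, 100.0, size=d)
        scale = rng.uniform(1.0, 15.0, size=d)
        values = shift + scale * values
    mask = rng.random((n, d)) >= config.missing_rate
    values = np.where(mask, values, 0.0)
    ids = tuple(f"P{i + 1:04d}" for i in range(n))
    return RawBattery(ids, values, mask, _synthetic_schema(d))


def generate_outcomes(planted: PlantedModel, config: SyntheticConfig
                      ) -> OutcomeTable:
    """Outcomes linear in planted memberships with calibrated correlations."""
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seed, 0x07c0]))
    n = config.n_participants
    ids = tuple(f"P{i + 1:04d}" for i in range(n))
    cols, families = {}, {}
    zf = planted.z_true.astype(float)
    for spec in config.outcome_specs:
        beta = planted.outcome_betas[spec.name]
        noise = planted.outcome_noise_sd[spec.name]
        y = (zf @ beta if len(beta) else np.zeros(n)) \
            + rng.normal(0.0, noise, size=n)
        cols[spec.name] = y
        families[spec.name] = spec.family
    values = pd.DataFrame(cols, index=pd.Index(ids, name="participant_id"))
    return OutcomeTable(ids, values, families)


def generate_demographics(n: int, seed: int = 0,
                          p_female: float = 0.64,
                          race_probs: tuple[float, ...] = (0.6, 0.2, 0.12,
                                                           0.08)
                          ) -> pd.DataFrame:
    """Age (uniform integers 18-55, the study's inclusion band), sex and
    race/ethnicity categories — independent of any planted feature."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xde30]))
    ids = [f"P{i + 1:04d}" for i in range(n)]
    age = rng.integers(18, 56, size=n)
    sex = np.where(rng.random(n) < p_female, "female", "male")
    cats = [f"group_{i + 1}" for i in range(len(race_probs))]
    race = rng.choice(cats, size=n, p=np.asarray(race_probs) /
                      np.sum(race_probs))
    return pd.DataFrame({"participant_id": ids, "age": age, "sex": sex,
                         "race": race}).set_index("participant_id")


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Battery + outcomes + demographics + ground truth, all from one seed."""
    planted = plant_model(config)
    return SyntheticDataset(
        battery=generate_battery(planted, config),
        outcomes=generate_outcomes(planted, config),
        demographics=generate_demographics(config.n_participants,
                                           config.seed),
        planted=planted, config=config)


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write battery/outcomes/demographics CSVs plus a ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.battery.to_dataframe().to_csv(outdir / "battery.csv")
    dataset.outcomes.values.to_csv(outdir / "outcomes.csv")
    dataset.demographics.to_csv(outdir / "demographics.csv")
    truth = {
        "z_true": dataset.planted.z_true.tolist(),
        "a_true": dataset.planted.a_true.tolist(),
        "noise_sd": dataset.planted.noise_sd,
        "config": {k: (list(v) if isinstance(v, tuple) and
                       not isinstance(v, str) else v)
                   for k, v in asdict(dataset.config).items()},
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth))


# ---------------------------------------------------------------------------
# recovery


def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formula."""
    pos = labels.astype(bool)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass(frozen=True)
class RecoveryReport:
    modal_k: int
    planted_k: int
    matched_pairs: tuple[tuple[int, int], ...]   # (fitted, planted)
    membership_auc: tuple[float, ...]
    weight_correlation: tuple[float, ...]
    sigma_x_fit: float
    sigma_x_true: float

    @property
    def sigma_x_relative_error(self) -> float:
        return abs(self.sigma_x_fit - self.sigma_x_true) / self.sigma_x_true

    def to_dict(self) -> dict:
        return {
            "modal_k": self.modal_k, "planted_k": self.planted_k,
            "matched_pairs": list(map(list, self.matched_pairs)),
            "membership_auc": list(self.membership_auc),
            "weight_correlation": list(self.weight_correlation),
            "sigma_x_fit": self.sigma_x_fit,
            "sigma_x_true": self.sigma_x_true,
            "sigma_x_relative_error": self.sigma_x_relative_error,
        }


def recovery_report(dataset: SyntheticDataset, state, values: np.ndarray,
                    trace: pd.DataFrame, retained=None) -> RecoveryReport:
    """Compare a fit against the dataset's planted truth.

    Fitted (retained) features are matched one-to-one to planted features
    by cosine similarity of weight vectors; the report gives the modal K of
    the trace tail (last half of sweeps), per-matched-feature membership
    agreement (AUC of continuous values against true membership), the
    correlation of matched weight vectors, and the noise-scale recovery
    error.  Pure function of its inputs.
    """
    planted = dataset.planted
    tail = trace["k"].to_numpy()[len(trace) // 2:]
    modal_k = int(pd.Series(tail).mode().iloc[0])
    if retained is None:
        retained = list(range(state.k))
    retained = list(retained)
    a_fit = state.a[retained]
    kf, kt = a_fit.shape[0], planted.a_true.shape[0]
    pairs, aucs, wcorr = [], [], []
    if kf and kt:
        nf = np.linalg.norm(a_fit, axis=1, keepdims=True)
        nt = np.linalg.norm(planted.a_true, axis=1, keepdims=True)
        nf[nf == 0] = 1
        nt[nt == 0] = 1
        sim = (a_fit / nf) @ (planted.a_true / nt).T
        ri, ci = linear_sum_assignment(-sim)
        for i, j in zip(ri, ci):
            pairs.append((retained[i], int(j)))
            aucs.append(_auc(values[:, retained[i]], planted.z_true[:, j]))
            wcorr.append(float(np.corrcoef(a_fit[i],
                                           planted.a_true[j])[0, 1]))
    return RecoveryReport(modal_k, kt, tuple(pairs), tuple(aucs),
                          tuple(wcorr), float(state.hypers.sigma_x),
                          float(planted.noise_sd))
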