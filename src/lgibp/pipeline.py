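"""End-to-end pipeline: preprocess -> sample -> filter/profile -> correlate.

A single global seed, split deterministically into per-stage seeds,
determines all randomness; the run manifest (config, seed, stage status,
software version) fully determines the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlations import OutcomeTable, build_comparison_table, \
    DEFAULT_FAMILY_SIZES
from .features import (demographic_tests, feature_profiles, filter_features,
                       inclusion_threshold)
from .model import IBPLinearGaussianModel
from .preprocessing import load_battery, standardize_battery
from .schema import default_schema
from .synthetic import SyntheticConfig, generate_dataset, write_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "multi_feature_report"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``battery_path`` (real data) or ``synthetic``
    (generator settings) must be supplied.
    """

    battery_path: str | None = None
    outcomes_path: str | None = None
    demographics_path: str | None = None
    outcome_families: dict | None = None
    synthetic: SyntheticConfig | None = None
    id_column: str = "participant_id"
    apply_preprocessing: bool = True
    sweeps: int = 50
    k_cap: int = 4
    alpha_init: float = 5.0
    filter_fraction: float = 0.05
    correlation_test: str = "steiger"
    family_sizes: dict = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_SIZES))
    alpha_level: float = 0.05
    outdir: str = "lgibp_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.battery_path is None) == (self.synthetic is None):
            raise ValueError("supply exactly one of battery_path or "
                             "synthetic config")


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def multi_feature_report(z: np.ndarray) -> pd.DataFrame:
    """Frequency of each distinct combination of sampled features.

    Returns a table with the feature-set label (e.g. ``{1,3}``; ``{}`` for
    no features) and the participant count per combination; counts sum to
    N.
    """
    combos = {}
    for row in z:
        label = "{" + ",".join(str(k + 1)
                               for k in np.flatnonzero(row)) + "}"
        combos[label] = combos.get(label, 0) + 1
    out = pd.DataFrame({"combination": list(combos),
                        "count": list(combos.values())})
    return out.sort_values("count", ascending=False,
                           ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write artifacts into ``config.outdir``.

    Writes: standardized battery + audit JSON, sampler trace, final Z and
    continuous feature values, filter report, feature profiles,
    demographic tests, correlation and comparison tables, the
    multi-feature combination report, and a run manifest.  Returns a dict
    of the main in-memory results.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = {
        "version": __version__, "seed": config.seed,
        "stage_seeds": seeds, "stages": {}, "complete": False,
        "warnings": [],
    }
    cfg_dict = asdict(config)
    if config.synthetic is not None:
        cfg_dict["synthetic"] = asdict(config.synthetic)
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()
    results: dict = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
                manifest["stages"][name] = {
                    "status": "ok",
                    "seconds": round(time.perf_counter() - t0, 3)}
            except Exception as exc:
                manifest["stages"][name] = {"status": "error",
                                            "error": str(exc)}
                manifest["complete"] = False
                (outdir / "manifest.json").write_text(
                    json.dumps(manifest, indent=2, default=str))
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return deco

    @stage("load")
    def _load():
        if config.synthetic is not None:
            from dataclasses import replace
            syn = replace(config.synthetic, seed=seeds[0])
            dataset = generate_dataset(syn)
            write_dataset(dataset, outdir / "synthetic")
            results["dataset"] = dataset
            results["raw_battery"] = dataset.battery
            results["outcomes"] = dataset.outcomes
            results["demographics"] = dataset.demographics
        else:
            schema = default_schema()
            results["raw_battery"] = load_battery(
                config.battery_path, schema, config.id_column)
            results["outcomes"] = _load_outcomes(config)
            results["demographics"] = _load_demographics(config)

    @stage("preprocess")
    def _preprocess():
        if config.apply_preprocessing:
            std = standardize_battery(results["raw_battery"])
        else:
            from .preprocessing import zscore_columns
            std = zscore_columns(results["raw_battery"])
        std.write_csv(outdir / "battery_standardized.csv",
                      outdir / "column_stats.json")
        results["battery"] = std

    @stage("sample")
    def _sample():
        model = IBPLinearGaussianModel(results["battery"])
        fit = model.fit(sweeps=config.sweeps, seed=seeds[1],
                        k_cap=config.k_cap, alpha_init=config.alpha_init)
        fit.save_trace(outdir / "trace.csv")
        fit.feature_values_frame().to_csv(outdir / "feature_values.csv")
        pd.DataFrame(
            fit.z, index=fit.feature_values_frame().index,
            columns=fit.feature_values_frame().columns
        ).to_csv(outdir / "features_z.csv")
        results["fit"] = fit

    @stage("features")
    def _features():
        fit = results["fit"]
        thr = inclusion_threshold(results["battery"].n_participants,
                                  config.filter_fraction)
        filt = filter_features(fit.z, thr)
        filt.to_frame().to_csv(outdir / "filter_report.csv", index=False)
        results["filter"] = filt
        profiles = feature_profiles(results["battery"], fit.z,
                                    filt.retained_feature_ids)
        profiles.to_csv(outdir / "feature_profiles.csv", index=False)
        results["profiles"] = profiles
        multi = multi_feature_report(fit.z)
        multi.to_csv(outdir / "multi_feature_report.csv", index=False)
        results["multi_feature"] = multi
        demo = results.get("demographics")
        if demo is not None and filt.retained_feature_ids:
            tests = demographic_tests(fit.z, demo,
                                      filt.retained_feature_ids)
            tests.to_csv(outdir / "demographic_tests.csv", index=False)
            results["demographic_tests"] = tests

    @stage("correlate")
    def _correlate():
        outcomes = results.get("outcomes")
        filt = results["filter"]
        if outcomes is None or len(filt.retained_feature_ids) < 2:
            manifest["warnings"].append(
                "correlation stage skipped: fewer than two retained "
                "features or no outcomes")
            empty = pd.DataFrame()
            empty.to_csv(outdir / "correlations.csv", index=False)
            empty.to_csv(outdir / "comparisons.csv", index=False)
            results["correlations"] = results["comparisons"] = empty
            return
        corr, comp = build_comparison_table(
            results["fit"].feature_values, outcomes,
            feature_ids=filt.retained_feature_ids,
            family_sizes=config.family_sizes, alpha=config.alpha_level,
            method=config.correlation_test,
            participant_ids=results["fit"].model.participant_ids)
        corr.to_csv(outdir / "correlations.csv", index=False)
        comp.to_csv(outdir / "comparisons.csv", index=False)
        results["correlations"], results["comparisons"] = corr, comp

    manifest["complete"] = True
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results


def _load_outcomes(config: RunConfig) -> OutcomeTable | None:
    if config.outcomes_path is None:
        return None
    df = pd.read_csv(config.outcomes_path).set_index(config.id_column)
    families = config.outcome_families or {}
    missing = [c for c in df.columns if c not in families]
    if missing:
        raise ValueError(f"no family label for outcome(s): {missing}; "
                         "supply outcome_families")
    return OutcomeTable(tuple(df.index), df, dict(families))


def _load_demographics(config: RunConfig) -> pd.DataFrame | None:
    if config.demographics_path is None:
        return None
    return pd.read_csv(config.demographics_path).set_index(config.id_column)


def load_run_config(path, **overrides) -> RunConfig:
    """Read a RunConfig from YAML; keyword overrides win."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    syn = raw.pop("synthetic", None)
    if syn is not None:
        if "outcome_specs" in syn:
            from .synthetic import OutcomeSpec
            syn["outcome_specs"] = tuple(
                OutcomeSpec(s["name"], s["family"], tuple(s["rho"]))
                for s in syn["outcome_specs"])
        syn = SyntheticConfig(**syn)
    return RunConfig(synthetic=syn, **raw)
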