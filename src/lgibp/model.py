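"""Model/Results interface to the linear-Gaussian IBP.

:class:`IBPLinearGaussianModel` holds the (standardized) battery;
``fit()`` runs the Gibbs sampler and returns :class:`IBPResults`, which
carries the final feature matrix, weights, hyperparameter draws, the
per-sweep trace, and convenience methods for filtering, profiling,
outcome correlation and plotting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import features as _feat
from .correlations import OutcomeTable, build_comparison_table
from .preprocessing import RawBattery, StandardizedBattery, \
    standardize_battery
from .sampler import (SamplerConfig, SamplerState, as_model_data,
                      continuous_feature_values, prior_draw, run_sampler)

__all__ = ["IBPLinearGaussianModel", "IBPResults"]


class IBPLinearGaussianModel:
    """Linear-Gaussian Indian Buffet Process model of a test battery.

    The observed participants x measures matrix is modelled as
    ``X = Z A + noise`` with an IBP prior on the binary membership matrix
    Z and iid Gaussian weights A.  Missing cells are handled exactly by
    the sampler; no imputation takes place.

    Parameters
    ----------
    endog : array-like, StandardizedBattery, or DataFrame
        Standardized battery; NaN entries (or the battery mask) mark
        missing cells.
    """

    def __init__(self, endog, mask=None, measure_names=None,
                 participant_ids=None):
        if isinstance(endog, StandardizedBattery):
            self.data = as_model_data(endog)
            self.measure_names = list(endog.schema.measure_ids)
            self.participant_ids = list(endog.participant_ids)
            self.battery = endog
        else:
            arr = np.asarray(endog, float)
            if mask is not None:
                self.data = as_model_data((arr, np.asarray(mask, bool)))
            else:
                self.data = as_model_data(arr)
            self.measure_names = (list(measure_names) if measure_names
                                  is not None else
                                  [f"measure_{j}" for j in
                                   range(self.data.d)])
            self.participant_ids = (list(participant_ids) if participant_ids
                                    is not None else
                                    list(range(self.data.n)))
            self.battery = None

    @classmethod
    def from_battery(cls, battery: RawBattery | StandardizedBattery
                     ) -> "IBPLinearGaussianModel":
        """Build from a battery, standardizing a raw one first."""
        if isinstance(battery, RawBattery):
            battery = standardize_battery(battery)
        return cls(battery)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, standardize: bool = False
                       ) -> "IBPLinearGaussianModel":
        """Build from a participants x measures DataFrame (NaN = missing).

        With ``standardize=True`` columns are z-scored over observed cells
        first.
        """
        vals = df.to_numpy(float)
        mask = np.isfinite(vals)
        if standardize:
            for j in range(vals.shape[1]):
                col = vals[mask[:, j], j]
                vals[mask[:, j], j] = (col - col.mean()) / col.std(ddof=1)
        return cls(np.where(mask, vals, np.nan), measure_names=df.columns,
                   participant_ids=df.index)

    def simulate_prior(self, alpha: float, seed=None) -> np.ndarray:
        """Draw a membership matrix for this sample size from the IBP
        prior."""
        return prior_draw(self.data.n, alpha, seed)

    def fit(self, sweeps: int = 50, seed: int = 0, **config_kwargs
            ) -> "IBPResults":
        """Run the Gibbs sampler; alpha starts at 5 unless overridden."""
        config = SamplerConfig(sweeps=sweeps, seed=seed, **config_kwargs)
        state, trace = run_sampler(self.data, config)
        return IBPResults(self, state, trace, config)


class IBPResults:
    """Posterior fit: final state, per-sweep trace, derived quantities."""

    def __init__(self, model: IBPLinearGaussianModel, state: SamplerState,
                 trace: pd.DataFrame, config: SamplerConfig):
        self.model = model
        self.state = state
        self.trace = trace
        self.config = config
        self._values: np.ndarray | None = None

    # -- basic accessors ---------------------------------------------------
    @property
    def k(self) -> int:
        """Number of features in the final iteration."""
        return self.state.k

    @property
    def z(self) -> np.ndarray:
        """Final-iteration binary membership matrix (N x K)."""
        return self.state.z

    @property
    def weights(self) -> np.ndarray:
        """Final-iteration feature-to-measure weights (K x D)."""
        return self.state.a

    @property
    def alpha(self) -> float:
        return self.state.hypers.alpha

    @property
    def sigma_x(self) -> float:
        return self.state.hypers.sigma_x

    @property
    def sigma_a(self) -> float:
        return self.state.hypers.sigma_a

    @property
    def convergence_window(self) -> int:
        """Terminal sweeps over which K and rounded alpha were constant."""
        return int(self.trace.attrs.get("convergence_window", 0))

    @property
    def feature_values(self) -> np.ndarray:
        """Continuous feature values (N x K, entries in [0, 1]).

        By default the full-conditional inclusion probability of each
        final-iteration feature; with ``value_average_window`` set in the
        fit config, the average of binary membership over the terminal
        stable-K window instead."""
        if self._values is None:
            if (self.config.value_average_window
                    and "averaged_values" in self.trace.attrs):
                self._values = self.trace.attrs["averaged_values"]
            else:
                self._values = continuous_feature_values(self.state,
                                                         self.model.data)
        return self._values

    def feature_values_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.feature_values,
            index=pd.Index(self.model.participant_ids,
                           name="participant_id"),
            columns=[f"feature_{k + 1}" for k in range(self.k)])

    # -- analysis ----------------------------------------------------------
    def filter_features(self, fraction: float = 0.05
                        ) -> _feat.FeatureFilterResult:
        """Retain features sampled by at least floor(fraction * N)
        participants."""
        thr = _feat.inclusion_threshold(self.model.data.n, fraction)
        return _feat.filter_features(self.z, thr)

    def profiles(self, feature_ids=None) -> pd.DataFrame:
        """Per-feature mean-z profiles over members (battery input
        required)."""
        if self.model.battery is None:
            raise ValueError("profiles need a StandardizedBattery-backed "
                             "model")
        return _feat.feature_profiles(self.model.battery, self.z,
                                      feature_ids)

    def compare_with_outcomes(self, outcomes: OutcomeTable,
                              feature_ids=None, **kwargs):
        """Correlation and dependent-comparison tables for the given
        outcomes (default: all retained features at the 5% threshold)."""
        if feature_ids is None:
            feature_ids = self.filter_features().retained_feature_ids
        return build_comparison_table(
            self.feature_values, outcomes, feature_ids=feature_ids,
            participant_ids=self.model.participant_ids, **kwargs)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        """Plain-text fit summary."""
        tail = self.trace.tail(max(1, len(self.trace) // 2))
        counts = self.z.sum(axis=0)
        lines = [
            "Linear-Gaussian Indian Buffet Process fit",
            "=" * 45,
            f"Participants:            {self.model.data.n}",
            f"Measures:                {self.model.data.d}",
            f"Observed cells:          {int(self.model.data.mask.sum())}"
            f" / {self.model.data.mask.size}",
            f"Sweeps:                  {len(self.trace)}"
            f"  (seed {self.config.seed})",
            f"Final K:                 {self.k}",
            f"Modal K (trace tail):    "
            f"{int(tail['k'].mode().iloc[0]) if len(tail) else self.k}",
            f"alpha (final):           {self.alpha:.3f}",
            f"sigma_x (final):         {self.sigma_x:.3f}",
            f"sigma_a (final):         {self.sigma_a:.3f}",
            f"Convergence window:      {self.convergence_window} sweep(s)",
            f"Log joint (final):       "
            f"{self.trace['log_joint'].iloc[-1]:.2f}",
            "",
            "Feature sampling counts (final iteration):",
        ]
        for j, c in enumerate(counts):
            lines.append(f"  feature_{j + 1:<3d} {int(c):>5d}")
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """Traceplots of K, alpha, sigma_x, sigma_a against sweep."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(4, 1, sharex=True, figsize=(7, 8))
        for a, col in zip(np.ravel(ax), ["k", "alpha", "sigma_x",
                                         "sigma_a"]):
            a.plot(self.trace["iteration"], self.trace[col])
            a.set_ylabel(col)
        np.ravel(ax)[-1].set_xlabel("sweep")
        return ax

    def save_trace(self, path) -> None:
        self.trace.to_csv(path, index=False)
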