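"""Gibbs sampling for the linear-Gaussian Indian Buffet Process.

The model: each of N participants either samples or does not sample each of
an unbounded set of latent features (binary matrix Z, IBP prior with
concentration ``alpha``); each feature carries a real-valued weight vector
over the D measures (rows of A, iid Normal(0, sigma_a**2)); the observed
battery is X = Z A + Normal(0, sigma_x**2) noise, cell-wise.  Missing cells
are handled exactly by dropping their likelihood terms — no imputation.

The sampler keeps A explicit (uncollapsed) so per-cell missingness is exact:

* existing features are resampled entry-wise from their full conditional,
  prior odds ``m_{-i,k} / (N - m_{-i,k})`` times the data likelihood ratio;
* each row's singleton features are removed and re-proposed from a truncated
  Poisson(alpha/N) birth step with the new weights integrated out, then new
  weights are drawn from their exact posterior given that row;
* A is redrawn column-wise (per measure) from its Gaussian full conditional
  restricted to rows observed on that measure;
* ``alpha`` has a conjugate Gamma update; the two noise scales move by
  random-walk Metropolis on the log scale under Jeffreys scale priors.

``sigma_x`` and ``sigma_a`` are standard deviations throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .preprocessing import StandardizedBattery

__all__ = [
    "Hyperparameters", "SamplerConfig", "ModelData", "SamplerState",
    "prior_draw", "ibp_log_prior", "collapsed_log_marginal",
    "conditional_inclusion_probability", "sample_weights", "resample_alpha",
    "resample_noise_scales", "gibbs_sweep", "run_sampler",
    "continuous_feature_values", "harmonic_number",
]


def harmonic_number(n: int) -> float:
    """H_n = sum_{i=1..n} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n + 1)))


@dataclass
class Hyperparameters:
    """Scalar parameters of the sampler.

    ``alpha`` is the IBP concentration (expected K is alpha * H_N);
    ``sigma_x`` the observation-noise SD; ``sigma_a`` the weight prior SD.
    ``alpha_prior_shape`` / ``alpha_prior_rate`` parameterize the Gamma
    prior on alpha; ``sigma_proposal_scale`` is the log-scale random-walk
    SD for the noise-scale updates.
    """

    alpha: float = 5.0
    sigma_x: float = 1.0
    sigma_a: float = 1.0
    alpha_prior_shape: float = 1.0
    alpha_prior_rate: float = 1.0
    sigma_proposal_scale: float = 0.1

    def __post_init__(self) -> None:
        for name in ("alpha", "sigma_x", "sigma_a", "alpha_prior_shape",
                     "alpha_prior_rate"):
            if getattr(self, name) <= 0 and not (name == "alpha"
                                                 and self.alpha == 0):
                raise ValueError(f"{name} must be positive")
        if self.sigma_proposal_scale < 0:
            raise ValueError("sigma_proposal_scale must be nonnegative")


@dataclass
class SamplerConfig:
    """Run settings for :func:`run_sampler`.

    ``k_cap`` bounds the number of new singleton features proposed per row
    per sweep; ``max_features`` optionally truncates the total feature count
    (used by the exact-enumeration cross-check).  ``resample_alpha`` /
    ``resample_scales`` turn the hyperparameter moves off for fixed-
    hyperparameter runs.  ``value_average_window`` switches the continuous
    feature values from final-iteration conditional probabilities to the
    average of binary z over the last that many sweeps.
    """

    sweeps: int = 50
    seed: int = 0
    k_cap: int = 4
    max_features: int | None = None
    alpha_init: float = 5.0
    sigma_x_init: float = 1.0
    sigma_a_init: float = 1.0
    alpha_prior_shape: float = 1.0
    alpha_prior_rate: float = 1.0
    sigma_proposal_scale: float = 0.1
    resample_alpha: bool = True
    resample_scales: bool = True
    init: str = "empty"              # "empty" or "prior"
    alpha_hold_sweeps: int = 10      # sweeps before alpha resampling starts
    recruit_newborn: bool = True     # column scan for newly born features
    swap_moves: bool = True          # complement-flip Metropolis moves
    feature_moves: bool = True       # whole-feature birth/death MH moves
    collapsed: bool = True           # Rao-Blackwellized (weights integrated) scan
    value_average_window: int | None = None

    def __post_init__(self) -> None:
        if self.sweeps < 1:
            raise ValueError("sweeps must be >= 1")
        if self.k_cap < 0:
            raise ValueError("k_cap must be >= 0")


@dataclass
class ModelData:
    """Observed matrix with zero-filled masked cells plus the mask."""

    x: np.ndarray       # N x D, masked cells hold 0 and are never read
    mask: np.ndarray    # N x D bool, True = observed

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def d(self) -> int:
        return self.x.shape[1]


def as_model_data(x) -> ModelData:
    """Coerce a StandardizedBattery, (values, mask) pair, or plain array."""
    if isinstance(x, ModelData):
        return x
    if isinstance(x, StandardizedBattery):
        vals = np.where(x.mask, x.values, 0.0)
        return ModelData(vals.astype(float), x.mask.astype(bool))
    if isinstance(x, tuple) and len(x) == 2:
        vals, mask = np.asarray(x[0], float), np.asarray(x[1], bool)
        return ModelData(np.where(mask, vals, 0.0), mask)
    arr = np.asarray(x, float)
    mask = np.isfinite(arr)
    return ModelData(np.where(mask, arr, 0.0), mask)


@dataclass
class SamplerState:
    """Current sampler configuration: Z, A, hyperparameters, iteration."""

    z: np.ndarray                 # N x K binary
    a: np.ndarray                 # K x D weights
    hypers: Hyperparameters
    iteration: int = 0
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0))

    @property
    def k(self) -> int:
        return self.z.shape[1]

    @property
    def n(self) -> int:
        return self.z.shape[0]


# ---------------------------------------------------------------------------
# prior


def prior_draw(n: int, alpha: float, seed=None) -> np.ndarray:
    """Simulate one binary matrix from the IBP culinary construction.

    Customer 1 takes Poisson(alpha) new dishes; customer i takes existing
    dish k with probability m_k / i and Poisson(alpha / i) new dishes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    cols: list[np.ndarray] = []
    counts: list[int] = []
    for i in range(1, n + 1):
        for k in range(len(cols)):
            if rng.random() < counts[k] / i:
                cols[k][i - 1] = 1
                counts[k] += 1
        for _ in range(rng.poisson(alpha / i)):
            c = np.zeros(n, dtype=np.int8)
            c[i - 1] = 1
            cols.append(c)
            counts.append(1)
    if not cols:
        return np.zeros((n, 0), dtype=np.int8)
    return np.column_stack(cols)


def ibp_log_prior(z: np.ndarray, alpha: float) -> float:
    """Log IBP probability of the column-multiset equivalence class of z.

    Zero-count columns are not permitted; K = 0 is allowed.
    """
    n, k = z.shape
    m = z.sum(axis=0)
    if k and (m == 0).any():
        raise ValueError("all-zero columns are not in the IBP support")
    hn = harmonic_number(n)
    if k == 0:
        return -alpha * hn
    if alpha == 0:
        return -math.inf
    # multiplicity of each distinct column ("dish history")
    _, counts = np.unique(z, axis=1, return_counts=True)
    lp = k * math.log(alpha) - alpha * hn - gammaln(counts + 1).sum()
    lp += (gammaln(n - m + 1) + gammaln(m) - gammaln(n + 1)).sum()
    return float(lp)


# ---------------------------------------------------------------------------
# likelihoods


def collapsed_log_marginal(x, z: np.ndarray, sigma_x: float,
                           sigma_a: float) -> float:
    """log p(X | Z, sigma_x, sigma_a) with the weights integrated out.

    Complete data only; raises on any masked cell (the uncollapsed sampler
    handles missingness).
    """
    data = as_model_data(x)
    if not data.mask.all():
        raise ValueError("collapsed marginal supports complete data only; "
                         "use the uncollapsed sampler for masked cells")
    xv = data.x
    n, d = xv.shape
    z = np.asarray(z, float)
    k = z.shape[1]
    r = sigma_x ** 2 / sigma_a ** 2
    g = z.T @ z + r * np.eye(k)
    sign, logdet = np.linalg.slogdet(g) if k else (1.0, 0.0)
    m = np.linalg.inv(g) if k else np.zeros((0, 0))
    quad = np.trace(xv.T @ (np.eye(n) - z @ m @ z.T) @ xv)
    return float(
        -quad / (2 * sigma_x ** 2)
        - (n * d / 2) * math.log(2 * math.pi)
        - (n - k) * d * math.log(sigma_x)
        - k * d * math.log(sigma_a)
        - (d / 2) * logdet)


def _row_loglik_ratio(e0_obs: np.ndarray, d_obs: np.ndarray,
                      sigma_x: float) -> float:
    """log L(z_ik=1) - log L(z_ik=0) given the z_ik=0 residual e0."""
    return (2.0 * float(e0_obs @ d_obs) - float(d_obs @ d_obs)) / (
        2 * sigma_x ** 2)


def conditional_inclusion_probability(state: SamplerState, x, i: int,
                                      k: int) -> float:
    """P(z_ik = 1 | A, hyperparameters, row i's observed cells).

    Prior odds are ``m_{-i,k} / (N - m_{-i,k})`` with ``m_{-i,k}`` the
    feature's popularity excluding row i; a fully masked row returns the
    prior probability ``m_{-i,k} / N`` exactly.  Popularity-zero columns are
    the province of the singleton birth step, not this operation.
    """
    data = as_model_data(x)
    n = state.n
    m_minus = int(state.z[:, k].sum() - state.z[i, k])
    if m_minus == 0:
        raise ValueError("column has popularity 0 excluding row i; "
                         "handled by the new-feature step")
    obs = data.mask[i]
    e0 = data.x[i, obs] - (state.z[i] @ state.a)[obs] \
        + state.z[i, k] * state.a[k, obs]
    llr = _row_loglik_ratio(e0, state.a[k, obs], state.hypers.sigma_x)
    logit = math.log(m_minus / (n - m_minus)) + llr
    if logit > 35:
        return 1.0
    if logit < -35:
        return 0.0
    return 1.0 / (1.0 + math.exp(-logit))


# ---------------------------------------------------------------------------
# conditional updates


def sample_weights(z: np.ndarray, data: ModelData, sigma_x: float,
                   sigma_a: float, rng: np.random.Generator) -> np.ndarray:
    """Draw A column-by-column (per measure) from its Gaussian full
    conditional, using only rows observed on that measure.  A measure with
    no observed rows draws its weight column from the prior."""
    n, k = z.shape
    d = data.d
    a = np.empty((k, d))
    if k == 0:
        return a
    zf = z.astype(float)
    eye = np.eye(k)
    for j in range(d):
        obs = data.mask[:, j]
        if not obs.any():
            a[:, j] = rng.normal(0.0, sigma_a, size=k)
            continue
        zj = zf[obs]
        prec = (zj.T @ zj) / sigma_x ** 2 + eye / sigma_a ** 2
        chol = np.linalg.cholesky(prec)
        b = zj.T @ data.x[obs, j] / sigma_x ** 2
        mean = np.linalg.solve(prec, b)
        # x = mean + L^{-T} u  has covariance prec^{-1}
        u = rng.standard_normal(k)
        a[:, j] = mean + np.linalg.solve(chol.T, u)
    return a


def resample_alpha(k_plus: int, n: int, shape: float, rate: float,
                   rng: np.random.Generator) -> float:
    """Conjugate Gamma update: K ~ Poisson(alpha * H_N) marginally, so
    alpha | K ~ Gamma(shape + K, rate + H_N)."""
    return float(rng.gamma(shape + k_plus, 1.0 / (rate + harmonic_number(n))))


def _mh_log_scale(sigma: float, n_terms: float, ss: float, prop_sd: float,
                  rng: np.random.Generator) -> float:
    """One random-walk Metropolis step for a Gaussian scale parameter on the
    log scale under a Jeffreys prior (density 1/sigma): the acceptance ratio
    reduces to the likelihood ratio of the n_terms residuals with sum of
    squares ss."""
    prop = sigma * math.exp(rng.normal(0.0, prop_sd)) if prop_sd > 0 else sigma
    def ll(s):
        return -n_terms * math.log(s) - ss / (2 * s * s)
    if math.log(rng.random() + 1e-300) < ll(prop) - ll(sigma):
        return prop
    return sigma


def resample_noise_scales(state: SamplerState, data: ModelData,
                          residuals: np.ndarray | None = None
                          ) -> tuple[float, float]:
    """Metropolis updates of sigma_x (from observed-cell residuals) and
    sigma_a (from the weight entries).  Returns the new pair; the state is
    not mutated."""
    if residuals is None:
        residuals = data.x - state.z @ state.a
    obs = data.mask
    ss_x = float((residuals[obs] ** 2).sum())
    n_x = int(obs.sum())
    sx = _mh_log_scale(state.hypers.sigma_x, n_x, ss_x,
                       state.hypers.sigma_proposal_scale, state.rng)
    ss_a = float((state.a ** 2).sum())
    n_a = state.a.size
    if n_a:
        sa = _mh_log_scale(state.hypers.sigma_a, n_a, ss_a,
                           state.hypers.sigma_proposal_scale, state.rng)
    else:
        sa = state.hypers.sigma_a
    return sx, sa


# ---------------------------------------------------------------------------
# sweeps


def _singleton_step(state: SamplerState, data: ModelData, i: int,
                    e_obs: np.ndarray, obs: np.ndarray,
                    config: SamplerConfig) -> np.ndarray:
    """Remove row i's singleton features and redraw their count from the
    truncated-Poisson birth conditional (new weights integrated out), then
    draw accepted weights from their posterior given row i.  Returns the
    updated z_ik=0 residual over observed cells."""
    z, a = state.z, state.a
    sx, sa = state.hypers.sigma_x, state.hypers.sigma_a
    m = z.sum(axis=0)
    own = (z[i] == 1) & (m == 1)
    if own.any():
        e_obs = e_obs + a[own][:, obs].sum(axis=0)
        keep = ~own
        state.z = z = z[:, keep]
        state.a = a = a[keep]
    jmax = config.k_cap
    if config.max_features is not None:
        jmax = min(jmax, config.max_features - z.shape[1])
    lam = state.hypers.alpha / data.n
    if jmax <= 0 or lam <= 0:
        return e_obs
    n_obs = int(obs.sum())
    js = np.arange(jmax + 1)
    var = sx ** 2 + js * sa ** 2
    ss = float(e_obs @ e_obs)
    logw = (js * math.log(lam) - gammaln(js + 1)
            - 0.5 * n_obs * np.log(2 * math.pi * var) - ss / (2 * var))
    logw -= logw.max()
    w = np.exp(logw)
    j_new = int(state.rng.choice(js, p=w / w.sum()))
    if j_new == 0:
        return e_obs
    # exact posterior draw for the j_new weight vectors at each observed
    # measure via Matheron's rule; masked measures fall back to the prior
    d = data.d
    w0 = state.rng.normal(0.0, sa, size=(j_new, d))
    eps = state.rng.normal(0.0, sx, size=d)
    y0 = w0.sum(axis=0) + eps
    e_full = np.zeros(d)
    e_full[obs] = e_obs
    shift = sa ** 2 * (e_full - y0) / (sx ** 2 + j_new * sa ** 2)
    w_new = w0 + np.where(obs, shift, 0.0)[None, :]
    zcols = np.zeros((data.n, j_new), dtype=z.dtype)
    zcols[i] = 1
    state.z = np.concatenate([z, zcols], axis=1)
    state.a = np.concatenate([a, w_new], axis=0)
    return e_obs - w_new[:, obs].sum(axis=0)


def _gibbs_entry(state: SamplerState, n: int, i: int, k: int,
                 e_obs: np.ndarray, dvec: np.ndarray, m: np.ndarray
                 ) -> np.ndarray:
    """Resample one z entry given the current residual; returns the updated
    residual row."""
    z = state.z
    e0 = e_obs + dvec if z[i, k] else e_obs
    llr = _row_loglik_ratio(e0, dvec, state.hypers.sigma_x)
    logit = math.log(m[k] - z[i, k]) - math.log(n - m[k] + z[i, k]) + llr
    if logit > 35:
        p1 = 1.0
    elif logit < -35:
        p1 = 0.0
    else:
        p1 = 1.0 / (1.0 + math.exp(-logit))
    new = 1 if state.rng.random() < p1 else 0
    if new != z[i, k]:
        m[k] += new - z[i, k]
        z[i, k] = new
    return e0 - dvec if new else e0


def _column_scan(state: SamplerState, data: ModelData, cols) -> None:
    """Extra Gibbs scan over whole columns: lets a newly born feature
    recruit its members (or lose them) within the same sweep.  Weights are
    refreshed after each scanned column."""
    n = data.n
    for k in cols:
        if k >= state.k:
            continue
        m = state.z.sum(axis=0)
        dfull = state.a[k]
        for i in range(n):
            if m[k] - state.z[i, k] == 0:
                continue
            obs = data.mask[i]
            e_obs = data.x[i, obs] - (state.z[i] @ state.a)[obs]
            _gibbs_entry(state, n, i, k, e_obs, dfull[obs], m)
        state.a = sample_weights(state.z, data, state.hypers.sigma_x,
                                 state.hypers.sigma_a, state.rng)


def _swap_moves(state: SamplerState, data: ModelData,
                universal_fraction: float = 0.85) -> None:
    """Complement-swap Metropolis moves.

    When a near-universal feature u exists, any other feature k can be
    re-expressed through its complement: z_k -> 1 - z_k, w_k -> -w_k,
    w_u -> w_u + w_k leaves every row with z_iu = 1 unchanged, so the
    likelihood only moves through u's non-members.  The map is an
    involution with unit Jacobian; acceptance combines that likelihood
    change with the IBP prior ratio (which favors the rarer orientation)
    and the Gaussian weight-prior change for w_u.  These moves dismantle
    the "intercept plus complemented features" local modes that entry-wise
    Gibbs cannot leave.
    """
    n = data.n
    thr = int(math.ceil(universal_fraction * n))
    sx, sa = state.hypers.sigma_x, state.hypers.sigma_a
    # deterministic scan over ordered pairs: each (u, k) kernel proposes an
    # involution that leaves m_u unchanged, so the move is its own reverse
    for u in range(state.k):
        if state.z[:, u].sum() < thr:
            continue
        for k in range(state.k):
            if k == u:
                continue
            mk = int(state.z[:, k].sum())
            if mk == n or mk == 0:
                continue
            wk = state.a[k]
            wu = state.a[u]
            rows = state.z[:, u] == 0
            dll = 0.0
            if rows.any():
                e = (data.x[rows] - state.z[rows] @ state.a)
                msk = data.mask[rows].astype(float)
                dll = -float(((2 * e * msk) @ wk).sum()
                             + (msk @ (wk ** 2)).sum()) / (2 * sx ** 2)
            z_after = state.z.copy()
            z_after[:, k] = 1 - z_after[:, k]
            dlp = (ibp_log_prior(z_after, state.hypers.alpha)
                   - ibp_log_prior(state.z, state.hypers.alpha))
            dlw = -(float(((wu + wk) ** 2).sum())
                    - float((wu ** 2).sum())) / (2 * sa ** 2)
            log_acc = dll + dlp + dlw
            if math.log(state.rng.random() + 1e-300) < log_acc:
                state.a[u] = wu + wk
                state.a[k] = -wk
                state.z = z_after


class _MarginalScan:
    """Accelerated (collapsed) Gibbs scan with the weights integrated out.

    Under MCAR missingness the marginal likelihood factorizes over
    measures: p(X_obs | Z) = prod_d N(x_{O_d,d}; 0, sigma_x^2 I +
    sigma_a^2 Z_d Z_d^T) with Z_d the membership rows observed on measure
    d.  The scan maintains, per measure, G_d = Z_d^T Z_d + r I (with r =
    sigma_x^2 / sigma_a^2), its inverse and h_d = Z_d^T x_d, updating them
    by rank-1 identities as entries flip; membership updates then use the
    exact Gaussian predictive of each observed cell given the rest of its
    column.  Integrating the weights removes their stickiness and is what
    makes the sampler converge in tens of sweeps.
    """

    def __init__(self, data: ModelData, z: np.ndarray, sigma_x: float,
                 sigma_a: float):
        self.data = data
        self.z = z
        self.sx2 = sigma_x ** 2
        self.r = sigma_x ** 2 / sigma_a ** 2
        self.maskf = data.mask.astype(float)
        self.n_d = data.mask.sum(axis=0)
        self.xx = (data.x ** 2).sum(axis=0)
        self.rebuild()

    def rebuild(self) -> None:
        zf = self.z.astype(float)
        k = zf.shape[1]
        self.zf = zf
        self.G = (np.einsum("nd,nk,nl->dkl", self.maskf, zf, zf)
                  + self.r * np.eye(k)[None, :, :])
        self.M = np.linalg.inv(self.G) if k else np.zeros(
            (self.data.d, 0, 0))
        self.h = np.einsum("nd,nk->dk", self.data.x, zf)

    @property
    def k(self) -> int:
        return self.z.shape[1]

    def total_loglik(self, z: np.ndarray | None = None) -> float:
        """Full marginal log-likelihood sum over measures."""
        if z is None:
            zf, g, m, h = self.zf, self.G, self.M, self.h
        else:
            zf = z.astype(float)
            g = (np.einsum("nd,nk,nl->dkl", self.maskf, zf, zf)
                 + self.r * np.eye(zf.shape[1])[None, :, :])
            m = np.linalg.inv(g) if zf.shape[1] else np.zeros(
                (self.data.d, 0, 0))
            h = np.einsum("nd,nk->dk", self.data.x, zf)
        k = zf.shape[1]
        if k:
            _, logdet = np.linalg.slogdet(g)
            quad = self.xx - np.einsum("dk,dkl,dl->d", h, m, h)
        else:
            logdet = np.zeros(self.data.d)
            quad = self.xx
        ll = (-0.5 * self.n_d * math.log(2 * math.pi * self.sx2)
              - 0.5 * (logdet - k * math.log(self.r))
              - quad / (2 * self.sx2))
        return float(ll.sum())

    def update_entry(self, i: int, k: int, m: np.ndarray,
                     rng: np.random.Generator) -> None:
        """Gibbs update of z_ik from its collapsed full conditional."""
        n = self.data.n
        m_minus = m[k] - self.z[i, k]
        if m_minus == 0:
            return
        obs = np.flatnonzero(self.data.mask[i])
        if obs.size == 0:
            # fully masked row: conditional is the prior m_{-i,k} / N
            new = 1 if rng.random() < m_minus / n else 0
            if new != self.z[i, k]:
                self.z[i, k] = new
                self.zf[i, k] = float(new)
                m[k] += 2 * new - 1
            return
        v = self.zf[i].copy()
        mo = self.M[obs]
        mv = mo @ v
        denom = np.maximum(1.0 - mv @ v, 1e-12)
        mm = mo + mv[:, :, None] * mv[:, None, :] / denom[:, None, None]
        xi = self.data.x[i, obs]
        hm = self.h[obs] - v[None, :] * xi[:, None]
        lls = []
        for s in (0.0, 1.0):
            vs = v.copy()
            vs[k] = s
            w = mm @ vs
            mu = (w * hm).sum(axis=1)
            var = self.sx2 * (1.0 + w @ vs)
            lls.append(float(-0.5 * (np.log(2 * math.pi * var)
                                     + (xi - mu) ** 2 / var).sum()))
        logit = (math.log(m_minus) - math.log(n - m_minus)
                 + lls[1] - lls[0])
        if logit > 35:
            p1 = 1.0
        elif logit < -35:
            p1 = 0.0
        else:
            p1 = 1.0 / (1.0 + math.exp(-logit))
        new = 1 if rng.random() < p1 else 0
        if new != self.z[i, k]:
            self._commit(i, k, new, obs, mm, hm)
            m[k] += new - (1 - new)  # old value was 1 - new
        # else: stacks unchanged

    def _commit(self, i: int, k: int, new: int, obs, mm, hm) -> None:
        old = self.z[i, k]
        self.z[i, k] = new
        self.zf[i, k] = float(new)
        if obs is None or len(obs) == 0 or mm is None:
            return
        vn = self.zf[i].copy()
        xi = self.data.x[i, obs]
        mvn = mm @ vn
        d2 = 1.0 + mvn @ vn
        self.M[obs] = mm - mvn[:, :, None] * mvn[:, None, :] / \
            d2[:, None, None]
        vold = vn.copy()
        vold[k] = float(old)
        self.G[obs] += (np.outer(vn, vn) - np.outer(vold, vold))[None, :, :]
        self.h[obs] = hm + vn[None, :] * xi[:, None]

    def birth_loglik(self, i: int, jmax: int) -> np.ndarray:
        """Marginal log-likelihood gain of j = 0..jmax new singleton
        features for row i (new weights integrated against their prior)."""
        obs = np.flatnonzero(self.data.mask[i])
        out = np.zeros(jmax + 1)
        if obs.size == 0:
            return out
        v = self.zf[i]
        if self.k:
            mo = self.M[obs]
            a = 1.0 - np.einsum("ok,okl,ol->o", np.broadcast_to(
                v, (obs.size, self.k)), mo, np.broadcast_to(
                v, (obs.size, self.k)))
            yhat = np.einsum("k,okl,ol->o", v, mo, self.h[obs])
        else:
            a = np.ones(obs.size)
            yhat = np.zeros(obs.size)
        resid2 = (self.data.x[i, obs] - yhat) ** 2
        for j in range(1, jmax + 1):
            gain = (-0.5 * np.log((self.r + j * a) / self.r)
                    + resid2 * (j / (self.r + j * a)) / (2 * self.sx2))
            out[j] = float(gain.sum())
        return out

    def remove_columns(self, cols) -> None:
        keep = np.ones(self.k, dtype=bool)
        keep[list(cols)] = False
        self.z = self.z[:, keep]
        self.rebuild()

    def add_singletons(self, i: int, j: int) -> None:
        newcols = np.zeros((self.data.n, j), dtype=self.z.dtype)
        newcols[i] = 1
        self.z = np.concatenate([self.z, newcols], axis=1)
        self.rebuild()


def _residual_matrix(scan: "_MarginalScan") -> np.ndarray:
    """Masked residuals against the posterior-mean weights implied by the
    current stacks (a deterministic function of Z and the data)."""
    if scan.k == 0:
        return scan.data.x * scan.maskf
    ahat = np.einsum("dkl,dl->dk", scan.M, scan.h)  # (D, K) posterior mean
    fitted = scan.zf @ ahat.T
    return (scan.data.x - fitted) * scan.maskf


def _birth_membership_logprob(resid: np.ndarray, z_new: np.ndarray,
                              q_floor: float = 0.02,
                              kappa: float = 8.0) -> float:
    """Log proposal probability of membership vector ``z_new`` under the
    residual-correlation birth proposal, marginalized over the anchor row.

    The proposal picks an anchor row uniformly, then includes each row
    independently with probability sigmoid(kappa * cosine(resid_row,
    resid_anchor)) squeezed into [q_floor, 1 - q_floor]."""
    norms = np.linalg.norm(resid, axis=1)
    norms[norms == 0] = 1.0
    c = (resid / norms[:, None]) @ (resid / norms[:, None]).T
    q = q_floor + (1 - 2 * q_floor) / (1 + np.exp(-kappa * (c - 0.30)))
    lp_rows = (z_new[None, :] * np.log(q)
               + (1 - z_new[None, :]) * np.log(1 - q)).sum(axis=1)
    return float(logsumexp(lp_rows) - math.log(len(resid)))


def _rj_feature_moves(scan: "_MarginalScan", state: SamplerState,
                      config: SamplerConfig, n_attempts: int = 2) -> None:
    """Metropolis-Hastings birth/death of whole features.

    Entry-wise Gibbs can only create features one member at a time, so a
    weak feature shared by many people is effectively unreachable: no
    single row justifies it alone.  These moves propose an entire
    membership column at once — drawn from the correlation structure of
    the current residuals — and delete whole columns in the reverse move.
    With the weights integrated out the state is just Z, so the
    acceptance ratio is an ordinary MH ratio of marginal posterior times
    proposal probabilities; no Jacobian terms arise.
    """
    rng = state.rng
    n = scan.data.n

    def p_birth(k: int) -> float:
        # probability the kernel proposes a birth at feature count k
        if k == 0:
            return 1.0
        if config.max_features is not None and k >= config.max_features:
            return 0.0
        return 0.5

    for _ in range(n_attempts):
        pb = p_birth(scan.k)
        if rng.random() < pb:
            # ---- birth of a whole feature
            resid = _residual_matrix(scan)
            anchor = int(rng.integers(n))
            r_a = resid[anchor]
            norms = np.linalg.norm(resid, axis=1)
            norms[norms == 0] = 1.0
            c = (resid @ r_a) / (norms * max(np.linalg.norm(r_a), 1e-12))
            q = 0.02 + 0.96 / (1 + np.exp(-8.0 * (c - 0.30)))
            z_new = (rng.random(n) < q).astype(scan.z.dtype)
            if z_new.sum() == 0:
                continue
            lp_fwd = _birth_membership_logprob(resid, z_new)
            z_alt = np.concatenate([scan.z, z_new[:, None]], axis=1)
            cur = scan.total_loglik() + ibp_log_prior(
                scan.z, state.hypers.alpha)
            alt = scan.total_loglik(z_alt) + ibp_log_prior(
                z_alt, state.hypers.alpha)
            pd_rev = 1.0 - p_birth(scan.k + 1)
            log_acc = (alt - cur
                       + math.log(pd_rev) - math.log(scan.k + 1)
                       - math.log(pb) - lp_fwd)
            if math.log(rng.random() + 1e-300) < log_acc:
                scan.z = z_alt
                scan.rebuild()
        elif scan.k >= 1:
            # ---- death of an entire feature
            k_del = int(rng.integers(scan.k))
            z_alt = np.delete(scan.z, k_del, axis=1)
            z_dead = scan.z[:, k_del]
            cur = scan.total_loglik() + ibp_log_prior(
                scan.z, state.hypers.alpha)
            alt = scan.total_loglik(z_alt) + ibp_log_prior(
                z_alt, state.hypers.alpha)
            # reverse birth is proposed from the post-death residuals
            scan_alt = _MarginalScan(
                scan.data, z_alt,
                math.sqrt(scan.sx2), math.sqrt(scan.sx2 / scan.r))
            lp_rev = _birth_membership_logprob(
                _residual_matrix(scan_alt), z_dead.astype(float))
            log_acc = (alt - cur
                       + math.log(p_birth(scan.k - 1)) + lp_rev
                       - math.log(1.0 - pb) + math.log(scan.k))
            if math.log(rng.random() + 1e-300) < log_acc:
                scan.z = z_alt
                scan.rebuild()


def _collapsed_sweep(state: SamplerState, data: ModelData,
                     config: SamplerConfig) -> None:
    """Row scan of the accelerated sampler: entry updates, singleton
    birth/death, newborn recruitment, complement-flip moves."""
    n = data.n
    sx, sa = state.hypers.sigma_x, state.hypers.sigma_a
    scan = _MarginalScan(data, state.z, sx, sa)
    rng = state.rng
    lam = state.hypers.alpha / n
    for i in range(n):
        m = scan.z.sum(axis=0)
        for k in range(scan.k):
            scan.update_entry(i, k, m, rng)
        # death of row-owned singletons, then truncated-Poisson rebirth
        m = scan.z.sum(axis=0)
        own = np.flatnonzero((scan.z[i] == 1) & (m == 1))
        if own.size:
            scan.remove_columns(own)
        jmax = config.k_cap
        if config.max_features is not None:
            jmax = min(jmax, config.max_features - scan.k)
        if jmax > 0 and lam > 0:
            js = np.arange(jmax + 1)
            logw = (js * math.log(lam) - gammaln(js + 1)
                    + scan.birth_loglik(i, jmax))
            logw -= logw.max()
            w = np.exp(logw)
            j_new = int(rng.choice(js, p=w / w.sum()))
            if j_new:
                k_before = scan.k
                scan.add_singletons(i, j_new)
                if config.recruit_newborn:
                    for k in range(k_before, scan.k):
                        mm2 = scan.z.sum(axis=0)
                        for i2 in range(n):
                            scan.update_entry(i2, k, mm2, rng)
    if config.feature_moves:
        _rj_feature_moves(scan, state, config)
    if config.swap_moves and scan.k >= 2:
        thr = int(math.ceil(0.85 * n))
        m = scan.z.sum(axis=0)
        if (m >= thr).any():
            cur_ll = scan.total_loglik()
            cur_lp = ibp_log_prior(scan.z, state.hypers.alpha)
            for u in np.flatnonzero(m >= thr):
                for k in range(scan.k):
                    mk = int(scan.z[:, k].sum())
                    if k == u or mk in (0, n):
                        continue
                    z_alt = scan.z.copy()
                    z_alt[:, k] = 1 - z_alt[:, k]
                    alt_ll = scan.total_loglik(z_alt)
                    alt_lp = ibp_log_prior(z_alt, state.hypers.alpha)
                    if math.log(rng.random() + 1e-300) < \
                            (alt_ll + alt_lp) - (cur_ll + cur_lp):
                        scan.z = z_alt
                        scan.rebuild()
                        cur_ll, cur_lp = alt_ll, alt_lp
    state.z = scan.z


def gibbs_sweep(state: SamplerState, x, config: SamplerConfig | None = None
                ) -> SamplerState:
    """One full sweep: per row, resample every shared feature's z entry and
    the row's singleton features (with an immediate recruitment scan for
    newborn features); then complement-flip moves, a weight redraw, the
    alpha and noise-scale updates; prune empty columns and advance the
    iteration counter.  Mutates and returns ``state``."""
    if config is None:
        config = SamplerConfig()
    data = as_model_data(x)
    n = data.n
    if config.collapsed:
        _collapsed_sweep(state, data, config)
    else:
        sx = state.hypers.sigma_x
        for i in range(n):
            obs = data.mask[i]
            z = state.z
            e_obs = data.x[i, obs] - (z[i] @ state.a)[obs]
            a_obs = state.a[:, obs]
            m = z.sum(axis=0)
            for k in range(z.shape[1]):
                m_minus = m[k] - z[i, k]
                if m_minus == 0:
                    continue  # row-owned singleton: birth step handles it
                dvec = a_obs[k]
                e0 = e_obs + dvec if z[i, k] else e_obs
                llr = _row_loglik_ratio(e0, dvec, sx)
                logit = math.log(m_minus / (n - m_minus)) + llr
                if logit > 35:
                    p1 = 1.0
                elif logit < -35:
                    p1 = 0.0
                else:
                    p1 = 1.0 / (1.0 + math.exp(-logit))
                new = 1 if state.rng.random() < p1 else 0
                if new != z[i, k]:
                    m[k] += new - z[i, k]
                    z[i, k] = new
                e_obs = e0 - dvec if new else e0
            k_before = state.k
            _singleton_step(state, data, i, e_obs, obs, config)
            if config.recruit_newborn and state.k > k_before:
                _column_scan(state, data, range(k_before, state.k))
        if config.swap_moves and state.k >= 2:
            _swap_moves(state, data)
    # prune (defensive: the birth step already removes abandoned singletons)
    m = state.z.sum(axis=0)
    if state.k and (m == 0).any():
        keep = m > 0
        state.z = state.z[:, keep]
        state.a = state.a[keep]
    state.a = sample_weights(state.z, data, state.hypers.sigma_x,
                             state.hypers.sigma_a, state.rng)
    if config.resample_alpha and state.iteration + 1 > config.alpha_hold_sweeps:
        state.hypers.alpha = resample_alpha(
            state.k, n, state.hypers.alpha_prior_shape,
            state.hypers.alpha_prior_rate, state.rng)
    if config.resample_scales:
        state.hypers.sigma_x, state.hypers.sigma_a = resample_noise_scales(
            state, data)
    state.iteration += 1
    return state


def log_joint(state: SamplerState, data: ModelData) -> float:
    """log p(X_obs, A, [Z] | hyperparameters) at the current state."""
    resid = data.x - state.z @ state.a
    obs = data.mask
    sx, sa = state.hypers.sigma_x, state.hypers.sigma_a
    n_obs = int(obs.sum())
    ll = (-0.5 * n_obs * math.log(2 * math.pi * sx ** 2)
          - float((resid[obs] ** 2).sum()) / (2 * sx ** 2))
    la = (-0.5 * state.a.size * math.log(2 * math.pi * sa ** 2)
          - float((state.a ** 2).sum()) / (2 * sa ** 2))
    return ll + la + ibp_log_prior(state.z, state.hypers.alpha)


def _convergence_window(ks: Sequence[int], alphas: Sequence[float]) -> int:
    """Longest terminal run over which K and alpha (rounded to 0.1) are
    constant."""
    if not len(ks):
        return 0
    w = 1
    for t in range(len(ks) - 2, -1, -1):
        if ks[t] == ks[-1] and round(alphas[t], 1) == round(alphas[-1], 1):
            w += 1
        else:
            break
    return w


def run_sampler(x, config: SamplerConfig | None = None
                ) -> tuple[SamplerState, pd.DataFrame]:
    """Run the Gibbs sampler and return the final state plus the trace.

    The trace has one row per completed sweep with columns iteration, k,
    alpha, sigma_x, sigma_a, log_joint.  ``trace.attrs`` carries the
    terminal convergence-window length (sweeps over which K and rounded
    alpha stayed constant); convergence is reported, never enforced.
    """
    if config is None:
        config = SamplerConfig()
    data = as_model_data(x)
    rng = np.random.default_rng(config.seed)
    hypers = Hyperparameters(
        alpha=config.alpha_init, sigma_x=config.sigma_x_init,
        sigma_a=config.sigma_a_init,
        alpha_prior_shape=config.alpha_prior_shape,
        alpha_prior_rate=config.alpha_prior_rate,
        sigma_proposal_scale=config.sigma_proposal_scale)
    if config.init == "prior":
        z = prior_draw(data.n, config.alpha_init, rng).astype(np.int8)
        if (config.max_features is not None
                and z.shape[1] > config.max_features):
            z = z[:, :config.max_features]
            z = z[:, z.sum(axis=0) > 0]
    elif config.init == "empty":
        z = np.zeros((data.n, 0), dtype=np.int8)
    else:
        raise ValueError("init must be 'empty' or 'prior'")
    state = SamplerState(z=z, a=np.empty((z.shape[1], data.d)),
                         hypers=hypers, iteration=0, rng=rng)
    state.a = sample_weights(state.z, data, hypers.sigma_x, hypers.sigma_a,
                             rng)
    records = []
    z_history: list[np.ndarray] = []
    for _ in range(config.sweeps):
        gibbs_sweep(state, data, config)
        records.append({
            "iteration": state.iteration, "k": state.k,
            "alpha": state.hypers.alpha, "sigma_x": state.hypers.sigma_x,
            "sigma_a": state.hypers.sigma_a,
            "log_joint": log_joint(state, data)})
        if config.value_average_window:
            z_history.append(state.z.copy())
            if len(z_history) > config.value_average_window:
                z_history.pop(0)
    trace = pd.DataFrame(records)
    trace.attrs["convergence_window"] = _convergence_window(
        trace["k"].to_numpy(), trace["alpha"].to_numpy())
    trace.attrs["seed"] = config.seed
    if config.value_average_window:
        # average binary memberships over the terminal window of sweeps in
        # which K stayed constant (column identity is only stable while no
        # features are born or die)
        run = []
        for z in reversed(z_history):
            if z.shape != state.z.shape:
                break
            run.append(z)
        trace.attrs["averaged_values"] = averaged_feature_values(run)
    return state, trace


def continuous_feature_values(state: SamplerState, x) -> np.ndarray:
    """Per-person probability of sampling each retained feature.

    Entry (i, k) is the full-conditional inclusion probability of z_ik at
    the final state — prior odds m_{-i,k}/(N - m_{-i,k}) times the
    likelihood ratio over row i's observed cells.  A fully masked row gets
    exactly m_{-i,k}/N; a feature whose popularity excluding i is zero gets
    0 (its prior mass comes entirely from the birth step).
    """
    data = as_model_data(x)
    n, k = state.z.shape
    if k == 0:
        return np.zeros((n, 0))
    sx = state.hypers.sigma_x
    resid = data.x - state.z @ state.a
    maskf = data.mask.astype(float)
    values = np.zeros((n, k))
    m = state.z.sum(axis=0)
    for j in range(k):
        d = state.a[j]
        e0 = resid + state.z[:, j:j + 1] * d[None, :]
        ed = (e0 * maskf) @ d
        dd = maskf @ (d ** 2)
        llr = (2 * ed - dd) / (2 * sx ** 2)
        m_minus = m[j] - state.z[:, j]
        with np.errstate(divide="ignore"):
            logit = np.where(
                m_minus > 0,
                np.log(m_minus / np.maximum(n - m_minus, 1e-300)) + llr,
                -np.inf)
        values[:, j] = np.where(
            m_minus >= n, 1.0,
            1.0 / (1.0 + np.exp(-np.clip(logit, -700, 700))))
    return values


def averaged_feature_values(states_z: Sequence[np.ndarray]) -> np.ndarray:
    """Alternative continuous values: mean of binary z over a window of
    sweeps (features must be aligned, i.e., from a frozen-K terminal
    window)."""
    return np.mean([z.astype(float) for z in states_z], axis=0)
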