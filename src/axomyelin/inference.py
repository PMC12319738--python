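"""Two-stage Metropolis–Hastings estimation of the tissue parameters.

The posterior of θ = (f_ia, f_dot, d_a, D∥ia, ec_perp_frac, σ) given the
normalized spherical-mean signal is sampled with a random-walk
Metropolis–Hastings chain under uniform priors and a Gaussian likelihood.
Two stages are run per voxel: stage 1 samples all parameters; stage 2 fixes
the diffusivities (D∥ia and the extra-cellular perpendicular fraction) at
their stage-1 posterior means and re-samples the fractions, the diameter and
σ, which lowers the posterior uncertainty of f_ia and d_a at essentially the
same likelihood.

Chains for many voxels are advanced together as a vectorized batch of
independent samplers; each chain consumes its own RNG substream keyed by a
stable voxel index, so results do not depend on batch composition or voxel
order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .signal_model import (
    AcquisitionProtocol,
    SphericalMeanSignal,
    _combine,
    _compartment_signals,
    effective_perp_diffusivity,
    smt_axisymmetric,
)

__all__ = [
    "PARAM_NAMES",
    "PriorSet",
    "MCMCConfig",
    "PosteriorSummary",
    "TwoStageResult",
    "log_likelihood",
    "mh_sample",
    "two_stage_fit",
    "fit_volume",
]

#: Canonical parameter order used by all arrays in this module.
PARAM_NAMES = ("f_ia", "f_dot", "d_a", "d_par_ia", "ec_perp_frac", "sigma")
_IDX = {n: i for i, n in enumerate(PARAM_NAMES)}

_F_IA, _F_DOT, _D_A, _D_PAR, _EC_FRAC, _SIGMA = range(6)


@dataclass(frozen=True)
class PriorSet:
    """Uniform prior ranges; fractions carry the joint constraint f_ia+f_dot ≤ 1."""

    f_ia: tuple[float, float] = (0.0, 1.0)
    f_dot: tuple[float, float] = (0.0, 1.0)
    d_a: tuple[float, float] = (0.1, 10.0)          # µm
    d_par_ia: tuple[float, float] = (0.01, 0.9)     # µm²/ms
    ec_perp_frac: tuple[float, float] = (0.0, 1.0)
    sigma: tuple[float, float] = (0.001, 0.1)
    #: Identifiability constraint: the intra-axonal compartment is the more
    #: restricted one perpendicular to the fiber, D⊥ia(d_a) ≤ D⊥ec.  Both
    #: anisotropic compartments are axially symmetric Gaussians sharing D∥
    #: in the spherical-mean signal, so without an ordering their labels can
    #: swap; this breaks the exchange degeneracy.
    order_perp_diffusivities: bool = True

    def __post_init__(self):
        for name in PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"prior for {name} needs lower < upper")

    @property
    def lower(self) -> np.ndarray:
        return np.array([getattr(self, n)[0] for n in PARAM_NAMES])

    @property
    def upper(self) -> np.ndarray:
        return np.array([getattr(self, n)[1] for n in PARAM_NAMES])

    def contains(self, theta: np.ndarray) -> bool:
        theta = np.asarray(theta)
        ok = np.all(theta >= self.lower) and np.all(theta <= self.upper)
        return bool(ok and theta[_F_IA] + theta[_F_DOT] <= 1.0 + 1e-12)


_DEFAULT_PROPOSAL_SD = {
    "f_ia": 0.02,
    "f_dot": 0.02,
    "d_a": 0.2,
    "d_par_ia": 0.02,
    "ec_perp_frac": 0.02,
    "sigma": 0.002,
}


@dataclass
class MCMCConfig:
    """Chain length and proposal scales.

    Defaults follow the estimation scheme this package targets: a burn-in of
    20,000 iterations, then one retained sample every 100 iterations until
    500 samples are collected (70,000 iterations total).  One randomly-walked
    parameter is updated per iteration, cycling deterministically through the
    free parameters; proposal SDs aim at a 20–50% acceptance rate.
    """

    burn_in: int = 20_000
    thin: int = 100
    n_samples: int = 500
    proposal_sd: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPOSAL_SD))
    seed: int = 0
    #: Initial temperature of the annealed burn-in.  The likelihood is
    #: tempered (divided by T) with T decaying geometrically from
    #: ``anneal_t0`` to 1 over the first 60% of the burn-in, so chains can
    #: cross between near-degenerate modes (stick vs. cylinder, compartment
    #: swap) early on and settle into the dominant one before sampling.
    #: Set to 1.0 to disable.
    anneal_t0: float = 10.0

    def __post_init__(self):
        if self.burn_in < 0 or self.thin <= 0 or self.n_samples <= 0:
            raise ValueError("burn_in >= 0, thin > 0, n_samples > 0 required")
        if self.anneal_t0 < 1.0:
            raise ValueError("anneal_t0 must be >= 1")
        unknown = set(self.proposal_sd) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown proposal_sd entries: {sorted(unknown)}")

    @property
    def total_iterations(self) -> int:
        return self.burn_in + self.thin * self.n_samples

    @property
    def proposal_sd_array(self) -> np.ndarray:
        sd = dict(_DEFAULT_PROPOSAL_SD)
        sd.update(self.proposal_sd)
        return np.array([sd[n] for n in PARAM_NAMES])


@dataclass
class PosteriorSummary:
    """Posterior means/SDs per parameter plus chain diagnostics.

    Arrays have shape (V, 6) / (V,) over the batch of voxels; scalar access
    goes through :meth:`mean` and :meth:`sd`.
    """

    means: np.ndarray
    sds: np.ndarray
    acceptance_rate: np.ndarray
    log_likelihood: np.ndarray   # mean log-likelihood over retained samples
    stage: int
    f_ec_mean: np.ndarray | None = None
    f_ec_sd: np.ndarray | None = None
    flags: np.ndarray | None = None  # True where the chain failed

    def mean(self, name: str) -> np.ndarray:
        return self.means[:, _IDX[name]]

    def sd(self, name: str) -> np.ndarray:
        return self.sds[:, _IDX[name]]


@dataclass
class TwoStageResult:
    stage1: PosteriorSummary
    stage2: PosteriorSummary

    @property
    def final(self) -> PosteriorSummary:
        return self.stage2


def log_likelihood(measured, predicted, sigma):
    """Gaussian log-likelihood of the spherical-mean signal.

    −(n/2)·ln(2πσ²) − Σᵢ (S̃ᵢ − Sᵢ)² / (2σ²) over the n non-zero b-values.
    Accepts arrays broadcast over a leading voxel axis.
    """
    measured = np.asarray(measured, float)
    predicted = np.asarray(predicted, float)
    if measured.shape != predicted.shape:
        raise ValueError("measured and predicted must have the same shape")
    sigma = np.asarray(sigma, float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    n = measured.shape[-1]
    ssr = ((measured - predicted) ** 2).sum(axis=-1)
    out = -0.5 * n * np.log(2.0 * np.pi * sigma**2) - ssr / (2.0 * sigma**2)
    return out if np.ndim(out) else float(out)


def _midpoint_start(priors: PriorSet) -> np.ndarray:
    theta0 = 0.5 * (priors.lower + priors.upper)
    # fraction midpoints 0.5/0.5 sit on the simplex boundary; keep them (valid)
    return theta0


def _grid_init(y, b, delta, Delta, gamma, priors: PriorSet,
               fixed_scalar: dict[str, float]) -> np.ndarray:
    """Deterministic coarse-grid start states, one per voxel.

    The posterior is multimodal: an extra-cellular compartment with a small
    perpendicular fraction can mimic the cylinder compartment (and vice
    versa), and a random-walk chain started at the prior midpoint can lock
    into the swapped mode.  Each chain therefore starts at the grid point of
    a fixed coarse parameter grid with the smallest sum of squared residuals
    against its voxel's signal; σ starts at the residual RMS (clipped to its
    prior).  The grid is data-independent, so the start is reproducible and
    adds one vectorized scan per batch.
    """
    lo, hi = priors.lower, priors.upper

    def axis(idx: int, n: int) -> np.ndarray:
        name = PARAM_NAMES[idx]
        if name in fixed_scalar:
            return np.array([fixed_scalar[name]])
        pad = 0.05 * (hi[idx] - lo[idx])
        return np.linspace(lo[idx] + pad, hi[idx] - pad, n)

    d_a_ax = axis(_D_A, 13)
    d_par_ax = axis(_D_PAR, 5)
    ec_ax = axis(_EC_FRAC, 5)
    shape_axes = np.array(np.meshgrid(d_a_ax, d_par_ax, ec_ax,
                                      indexing="ij")).reshape(3, -1)
    if priors.order_perp_diffusivities:
        dpe = effective_perp_diffusivity(shape_axes[0], delta, Delta,
                                         shape_axes[1], gamma=gamma)
        keep = dpe <= shape_axes[2] * shape_axes[1] + 1e-12
        if np.any(keep):
            shape_axes = shape_axes[:, keep]
    s_ia, s_ec = _compartment_signals(shape_axes[0], shape_axes[1],
                                      shape_axes[2], b, delta, Delta,
                                      gamma=gamma)
    f_levels = np.linspace(0.0, 1.0, 21)
    if "f_ia" in fixed_scalar:
        fia_lv = np.array([fixed_scalar["f_ia"]])
    else:
        fia_lv = f_levels[(f_levels >= lo[_F_IA]) & (f_levels <= hi[_F_IA])]
    if "f_dot" in fixed_scalar:
        fdot_lv = np.array([fixed_scalar["f_dot"]])
    else:
        fdot_lv = f_levels[(f_levels >= lo[_F_DOT]) & (f_levels <= hi[_F_DOT])]
    pairs = np.array([(fi, fd) for fi in fia_lv for fd in fdot_lv
                      if fi + fd <= 1.0 + 1e-12])
    # model signals for every (fraction pair) x (shape combo)
    f_ec = 1.0 - pairs.sum(axis=1)
    sig = (pairs[:, 0, None, None] * s_ia[None]
           + f_ec[:, None, None] * s_ec[None]
           + pairs[:, 1, None, None])            # (P, C, S)
    sig = sig.reshape(-1, b.size)                 # (P*C, S)
    ssr = ((y[:, None, :] - sig[None, :, :]) ** 2).sum(axis=-1) \
        if y.shape[0] * sig.shape[0] * b.size < 2e7 else None
    if ssr is None:  # chunk over voxels to bound memory
        ssr = np.empty((y.shape[0], sig.shape[0]))
        step = max(1, int(2e7 / (sig.shape[0] * b.size)))
        for i in range(0, y.shape[0], step):
            ssr[i:i + step] = ((y[i:i + step, None, :] - sig[None]) ** 2).sum(-1)
    best = np.argmin(ssr, axis=1)
    pair_idx, combo_idx = np.unravel_index(best, (pairs.shape[0],
                                                  shape_axes.shape[1]))
    V = y.shape[0]
    theta0 = np.empty((V, 6))
    theta0[:, _F_IA] = pairs[pair_idx, 0]
    theta0[:, _F_DOT] = pairs[pair_idx, 1]
    theta0[:, _D_A] = shape_axes[0, combo_idx]
    theta0[:, _D_PAR] = shape_axes[1, combo_idx]
    theta0[:, _EC_FRAC] = shape_axes[2, combo_idx]
    sigma0 = np.sqrt(ssr[np.arange(V), best] / b.size)
    theta0[:, _SIGMA] = np.clip(sigma0, lo[_SIGMA] * 1.001, hi[_SIGMA] * 0.999)
    return theta0


def _run_chains(y, b, delta, Delta, gamma, priors, config, free_idx, theta0,
                chain_keys, stage, prior_only=False, n_roots=14,
                return_samples=False):
    """Advance V independent MH chains over the same protocol.

    y : (V, S) measured spherical means; theta0 : (V, 6) start states.
    Returns a PosteriorSummary (and optionally the retained samples).
    """
    V, S = y.shape
    lo, hi = priors.lower, priors.upper
    sd = config.proposal_sd_array
    theta = theta0.copy()
    order = priors.order_perp_diffusivities

    def _dpe(d_a, d_par):
        return effective_perp_diffusivity(d_a, delta, Delta, d_par, n_roots,
                                          gamma)

    def _smt_b(d_par, d_perp):
        return smt_axisymmetric(b[None, :], d_par[:, None], d_perp[:, None])

    dpe_ia = _dpe(theta[:, _D_A], theta[:, _D_PAR])
    s_ia = _smt_b(theta[:, _D_PAR], dpe_ia)
    s_ec = _smt_b(theta[:, _D_PAR], theta[:, _EC_FRAC] * theta[:, _D_PAR])
    pred = _combine(theta[:, _F_IA], theta[:, _F_DOT], s_ia, s_ec)
    ssr = ((y - pred) ** 2).sum(axis=1)
    sigma = theta[:, _SIGMA]
    norm_const = -0.5 * S * np.log(2.0 * np.pi * sigma**2)
    ll = norm_const - ssr / (2.0 * sigma**2)

    total = config.total_iterations
    n_free = len(free_idx)
    anneal_end = int(0.6 * config.burn_in)
    t0_log = np.log(config.anneal_t0)
    samples = np.empty((config.n_samples, V, 6))
    ll_samples = np.empty((config.n_samples, V))
    n_accept = np.zeros(V)
    sample_i = 0

    gens = [np.random.default_rng([int(config.seed), int(stage), int(k)])
            for k in chain_keys]
    block = 4096
    it = 0
    while it < total:
        nb = min(block, total - it)
        normals = np.stack([g.standard_normal(nb) for g in gens])
        unifs = np.stack([g.random(nb) for g in gens])
        for t in range(nb):
            j = free_idx[it % n_free]
            prop = theta[:, j] + sd[j] * normals[:, t]
            ok = (prop >= lo[j]) & (prop <= hi[j])
            if j == _F_IA:
                ok &= prop + theta[:, _F_DOT] <= 1.0
            elif j == _F_DOT:
                ok &= prop + theta[:, _F_IA] <= 1.0
            val = np.where(ok, prop, theta[:, j])

            new_s_ia, new_s_ec, new_dpe = s_ia, s_ec, dpe_ia
            if j == _D_A:
                new_dpe = _dpe(val, theta[:, _D_PAR])
                if order:
                    ok &= new_dpe <= theta[:, _EC_FRAC] * theta[:, _D_PAR] + 1e-12
                new_s_ia = _smt_b(theta[:, _D_PAR], new_dpe)
            elif j == _D_PAR:
                new_dpe = _dpe(theta[:, _D_A], val)
                if order:
                    ok &= new_dpe <= theta[:, _EC_FRAC] * val + 1e-12
                new_s_ia = _smt_b(val, new_dpe)
                new_s_ec = _smt_b(val, theta[:, _EC_FRAC] * val)
            elif j == _EC_FRAC:
                if order:
                    ok &= val * theta[:, _D_PAR] >= dpe_ia - 1e-12
                new_s_ec = _smt_b(theta[:, _D_PAR], val * theta[:, _D_PAR])

            if j == _SIGMA:
                new_pred, new_ssr = pred, ssr
                new_norm = -0.5 * S * np.log(2.0 * np.pi * val**2)
                new_ll = new_norm - ssr / (2.0 * val**2)
            else:
                f_ia = val if j == _F_IA else theta[:, _F_IA]
                f_dot = val if j == _F_DOT else theta[:, _F_DOT]
                new_pred = _combine(f_ia, f_dot, new_s_ia, new_s_ec)
                new_ssr = ((y - new_pred) ** 2).sum(axis=1)
                new_norm = norm_const
                new_ll = norm_const - new_ssr / (2.0 * theta[:, _SIGMA] ** 2)

            if prior_only:
                accept = ok
            else:
                # tempering applies to the structural parameters only; σ
                # updates stay at T=1 so the noise level keeps tracking the
                # current misfit instead of diffusing while the surface is
                # flattened
                inv_t = (np.exp(-t0_log * (1.0 - it / anneal_end))
                         if (it < anneal_end and j != _SIGMA) else 1.0)
                with np.errstate(divide="ignore"):
                    accept = ok & (np.log(unifs[:, t]) < inv_t * (new_ll - ll))

            if np.any(accept):
                theta[accept, j] = prop[accept]
                a2 = accept[:, None]
                if j in (_D_A, _D_PAR):
                    s_ia = np.where(a2, new_s_ia, s_ia)
                    dpe_ia = np.where(accept, new_dpe, dpe_ia)
                if j in (_D_PAR, _EC_FRAC):
                    s_ec = np.where(a2, new_s_ec, s_ec)
                if j != _SIGMA:
                    pred = np.where(a2, new_pred, pred)
                    ssr = np.where(accept, new_ssr, ssr)
                else:
                    norm_const = np.where(accept, new_norm, norm_const)
                ll = np.where(accept, new_ll, ll)
                n_accept += accept

            it += 1
            if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
                samples[sample_i] = theta
                ll_samples[sample_i] = ll
                sample_i += 1

    assert sample_i == config.n_samples
    flags = np.isnan(ll) | (n_accept == 0)
    if np.any(np.isnan(ll)):
        warnings.warn("NaN likelihood encountered; affected voxels flagged")
    if np.any(n_accept == 0):
        warnings.warn("chain(s) with zero acceptance; flagged")
    means = samples.mean(axis=0)
    sds = samples.std(axis=0)
    f_ec_samples = 1.0 - samples[:, :, _F_IA] - samples[:, :, _F_DOT]
    summary = PosteriorSummary(
        means=means, sds=sds,
        acceptance_rate=n_accept / total,
        log_likelihood=ll_samples.mean(axis=0),
        stage=stage,
        f_ec_mean=f_ec_samples.mean(axis=0),
        f_ec_sd=f_ec_samples.std(axis=0),
        flags=flags,
    )
    return (summary, samples) if return_samples else summary


def _as_batch(signal: SphericalMeanSignal) -> tuple[np.ndarray, bool]:
    y = np.asarray(signal.means, float)
    if y.ndim == 1:
        return y[None, :], True
    if y.ndim == 2:
        return y, False
    raise ValueError("signal means must be 1-D (voxel) or 2-D (batch)")


def mh_sample(signal: SphericalMeanSignal, protocol: AcquisitionProtocol,
              priors: PriorSet | None = None,
              config: MCMCConfig | None = None,
              fixed: dict[str, float | np.ndarray] | None = None,
              chain_keys=None, prior_only: bool = False,
              return_samples: bool = False, stage: int = 1,
              init: str = "grid", theta_init: np.ndarray | None = None):
    """Sample the posterior of θ with a random-walk MH chain.

    ``fixed`` pins named parameters (e.g. the diffusivities in stage 2, or
    D∥ia to a literature constant) at scalar or per-voxel values; pinned
    parameters are excluded from the update cycle.  ``prior_only`` forces a
    constant likelihood, turning the sampler into a prior sampler for
    diagnostics.  Identical inputs, seed and chain keys give bit-identical
    chains.

    ``init`` selects the start state: ``"grid"`` (default) starts each chain
    at the best-fitting point of a deterministic coarse parameter grid,
    which avoids locking into the swapped-compartment mode of this
    multimodal posterior; ``"midpoint"`` starts at the prior midpoints.
    ``theta_init`` ((V, 6) or (6,)) overrides both.
    """
    priors = priors or PriorSet()
    config = config or MCMCConfig()
    y, single = _as_batch(signal)
    b = np.asarray(signal.b_values, float)
    if not np.allclose(b, protocol.b_values, rtol=1e-6):
        raise ValueError("signal b-values do not match the protocol shells")
    if y.shape[1] < 6:
        warnings.warn("fewer than 6 shells; estimates may be poorly determined")
    V = y.shape[0]
    if chain_keys is None:
        chain_keys = np.arange(V)
    chain_keys = np.asarray(chain_keys)
    if chain_keys.shape[0] != V:
        raise ValueError("chain_keys length must match the number of voxels")

    if init not in ("grid", "midpoint"):
        raise ValueError("init must be 'grid' or 'midpoint'")
    fixed = dict(fixed) if fixed else {}
    fixed_scalar = {k: float(np.asarray(v)) for k, v in fixed.items()
                    if np.ndim(v) == 0}
    if theta_init is not None:
        theta0 = np.array(np.broadcast_to(np.asarray(theta_init, float),
                                          (V, 6)))
    elif (init == "grid" and not prior_only
          and len(fixed_scalar) == len(fixed)):
        theta0 = _grid_init(y, b, protocol.delta, protocol.Delta,
                            protocol.gamma, priors, fixed_scalar)
    else:
        theta0 = np.tile(_midpoint_start(priors), (V, 1))
    free = np.ones(6, dtype=bool)
    for name, value in fixed.items():
        i = _IDX[name]
        theta0[:, i] = np.broadcast_to(np.asarray(value, float), (V,))
        free[i] = False
    if not np.any(free):
        raise ValueError("at least one parameter must be free")
    free_idx = np.flatnonzero(free)

    out = _run_chains(y, b, protocol.delta, protocol.Delta, protocol.gamma,
                      priors, config, free_idx, theta0, chain_keys, stage,
                      prior_only=prior_only, return_samples=return_samples)
    return out


_STAGE2_FIXED = ("d_par_ia", "ec_perp_frac")


def two_stage_fit(signal: SphericalMeanSignal, protocol: AcquisitionProtocol,
                  priors: PriorSet | None = None,
                  config: MCMCConfig | None = None,
                  chain_keys=None,
                  fix_d_par: float | None = None) -> TwoStageResult:
    """Two-stage MCMC fit; the stage-2 summary is the deliverable.

    Stage 1 samples all six parameters (unless ``fix_d_par`` pins D∥ia to a
    constant such as 0.6 µm²/ms ex vivo, for comparison runs).  Stage 2 fixes
    D∥ia and the extra-cellular perpendicular fraction at their stage-1
    posterior means, voxel by voxel, and re-samples f_ia, d_a, f_dot and σ.
    """
    fixed1 = {"d_par_ia": fix_d_par} if fix_d_par is not None else None
    stage1 = mh_sample(signal, protocol, priors, config, fixed=fixed1,
                       chain_keys=chain_keys, stage=1)
    fixed2 = {name: stage1.mean(name) for name in _STAGE2_FIXED}
    stage2 = mh_sample(signal, protocol, priors, config, fixed=fixed2,
                       chain_keys=chain_keys, stage=2,
                       theta_init=stage1.means)  # warm start from stage 1
    return TwoStageResult(stage1=stage1, stage2=stage2)


def fit_volume(smean_volume, protocol: AcquisitionProtocol,
               mask: np.ndarray | None = None,
               priors: PriorSet | None = None,
               config: MCMCConfig | None = None,
               fix_d_par: float | None = None) -> dict[str, np.ndarray]:
    """Fit every masked voxel of a spherical-mean volume.

    Accepts a :class:`~axomyelin.signal_model.SphericalMeanVolume` (or a bare
    (X, Y, Z, S) array together with the protocol's shells).  Voxels are
    batched into one vectorized run with RNG substreams keyed by flat voxel
    index, so the result is independent of mask shape and voxel order.
    Returns 3-D maps ``<param>_mean`` / ``<param>_sd`` for the stage-2 free
    parameters plus ``f_ec_mean``, the pinned diffusivities, an acceptance
    map and the mean log-likelihood map; NaN outside the mask.
    """
    means4d = getattr(smean_volume, "means", smean_volume)
    means4d = np.asarray(means4d, float)
    if means4d.ndim != 4:
        raise ValueError("expected a 4-D spherical-mean volume")
    b = getattr(smean_volume, "b_values", protocol.b_values)
    shape = means4d.shape[:3]
    if mask is None:
        mask = np.ones(shape, bool)
    mask = np.asarray(mask, bool)
    if mask.shape != shape:
        raise ValueError("mask shape mismatch")
    valid = getattr(smean_volume, "valid", None)
    if valid is not None:
        mask = mask & valid
    mask = mask & np.isfinite(means4d).all(axis=-1)
    flat_idx = np.flatnonzero(mask.reshape(-1))
    if flat_idx.size == 0:
        raise ValueError("mask selects no valid voxels")

    y = means4d.reshape(-1, means4d.shape[-1])[flat_idx]
    signal = SphericalMeanSignal(b_values=b, means=y)
    result = two_stage_fit(signal, protocol, priors, config,
                           chain_keys=flat_idx, fix_d_par=fix_d_par)
    s2, s1 = result.stage2, result.stage1

    def scatter(values: np.ndarray) -> np.ndarray:
        out = np.full(np.prod(shape), np.nan)
        out[flat_idx] = values
        return out.reshape(shape)

    maps: dict[str, np.ndarray] = {}
    for name in ("f_ia", "f_dot", "d_a", "sigma"):
        maps[f"{name}_mean"] = scatter(s2.mean(name))
        maps[f"{name}_sd"] = scatter(s2.sd(name))
    maps["f_ec_mean"] = scatter(s2.f_ec_mean)
    for name in _STAGE2_FIXED:
        maps[f"{name}_mean"] = scatter(s1.mean(name))
        maps[f"{name}_sd"] = scatter(s1.sd(name))
    maps["acceptance"] = scatter(s2.acceptance_rate)
    maps["log_likelihood"] = scatter(s2.log_likelihood)
    return maps
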