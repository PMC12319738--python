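"""Forward model for powder-averaged (spherical-mean) diffusion MRI signals.

The tissue model has three compartments, suited to fixed ex vivo white
matter:

* **intra-axonal** — impermeable parallel cylinders; perpendicular signal
  attenuation follows the Gaussian-phase-distribution (GPD) approximation of
  restricted diffusion inside a cylinder (the van Gelderen series over roots
  of the derivative of the first-order Bessel function), parallel diffusion
  is free with diffusivity equal to the intrinsic diffusivity D0;
* **extra-cellular** — hindered anisotropic Gaussian diffusion with parallel
  diffusivity tied to D0 and perpendicular diffusivity a fraction of it;
* **dot** — fully restricted, immobile water producing a non-decaying signal
  floor at high b-value, substantial in fixed tissue.

Powder averaging (averaging the diffusion-weighted signal over gradient
directions at fixed b) removes the dependence on fiber orientation; the
spherical mean of an axially symmetric compartment has the closed form
implemented in :func:`smt_axisymmetric`.

Units are consistent throughout the package: times in ms, lengths in µm,
gradient strength in mT/m, b-values in ms/µm², diffusivities in µm²/ms,
gyromagnetic ratio in rad·ms⁻¹·mT⁻¹.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.special import erf, jnp_zeros

__all__ = [
    "GAMMA_PROTON",
    "AcquisitionProtocol",
    "Shell",
    "ShellTable",
    "SphericalMeanSignal",
    "SphericalMeanVolume",
    "TissueParams",
    "bvalue_from_gradients",
    "gradient_from_bvalue",
    "cylinder_perp_attenuation_gpd",
    "effective_perp_diffusivity",
    "smt_axisymmetric",
    "model_signal",
    "powder_average",
    "spherical_mean_snr_gain",
    "default_exvivo_protocol",
]

#: Proton gyromagnetic ratio, rad · ms⁻¹ · mT⁻¹ (2.675e8 rad s⁻¹ T⁻¹).
GAMMA_PROTON = 267.52218744

# mT/m -> mT/µm
_G_TO_UM = 1e-6


def bvalue_from_gradients(gamma: float, delta: float, Delta: float, G: float):
    """Pulsed-gradient spin-echo b-value, b = (γ δ G)² (Δ − δ/3).

    Parameters
    ----------
    gamma : gyromagnetic ratio, rad·ms⁻¹·mT⁻¹.
    delta : gradient pulse duration δ, ms.
    Delta : gradient pulse separation Δ, ms.
    G : gradient strength, mT/m. May be an array.

    Returns
    -------
    b-value in ms/µm².
    """
    _check_timings(gamma, delta, Delta)
    G = np.asarray(G, dtype=float)
    if np.any(G < 0):
        raise ValueError("gradient strength must be non-negative")
    q = gamma * delta * G * _G_TO_UM  # rad/µm
    b = q**2 * (Delta - delta / 3.0)
    return b if b.ndim else float(b)


def gradient_from_bvalue(gamma: float, delta: float, Delta: float, b: float):
    """Gradient strength (mT/m) producing b-value `b` at the given timings."""
    _check_timings(gamma, delta, Delta)
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-value must be non-negative")
    G = np.sqrt(b / (Delta - delta / 3.0)) / (gamma * delta * _G_TO_UM)
    return G if G.ndim else float(G)


def _check_timings(gamma: float, delta: float, Delta: float) -> None:
    if gamma <= 0 or delta <= 0 or Delta <= 0:
        raise ValueError("gamma, delta and Delta must be positive")
    if delta >= Delta:
        raise ValueError(f"need delta < Delta, got delta={delta}, Delta={Delta}")


@lru_cache(maxsize=8)
def _bessel_prime_roots(n_roots: int) -> np.ndarray:
    # roots of J1'(x) = 0
    return jnp_zeros(1, n_roots)


def gpd_neg_log_attenuation(d_a, delta, Delta, G, D0, n_roots: int = 14,
                            gamma: float = GAMMA_PROTON) -> np.ndarray:
    """−ln of the GPD perpendicular attenuation of a cylinder of diameter d_a.

    Series over the first `n_roots` roots β_m of J₁′; with α_m = β_m / r,

        −ln A = 2 (γ G)² Σ_m [2 D α² δ − 2 + 2e^{−Dα²δ} + 2e^{−Dα²Δ}
                               − e^{−Dα²(Δ−δ)} − e^{−Dα²(Δ+δ)}]
                              / (D² α⁶ (β_m² − 1))

    which is quadratic in G: the restricted compartment behaves like a
    Gaussian compartment with a timing-dependent effective perpendicular
    diffusivity (see :func:`effective_perp_diffusivity`).
    """
    if n_roots < 1:
        raise ValueError("n_roots must be >= 1")
    _check_timings(gamma, delta, Delta)
    d_a, G, D0 = np.broadcast_arrays(
        np.asarray(d_a, float), np.asarray(G, float), np.asarray(D0, float)
    )
    if np.any(d_a <= 0):
        raise ValueError("axon diameter must be positive")
    if np.any(D0 <= 0):
        raise ValueError("intrinsic diffusivity must be positive")
    roots = _bessel_prime_roots(n_roots)
    r = 0.5 * d_a[..., None]
    alpha2 = (roots / r) ** 2  # 1/µm²
    x = D0[..., None] * alpha2  # 1/ms
    num = (
        2.0 * x * delta
        - 2.0
        + 2.0 * np.exp(-x * delta)
        + 2.0 * np.exp(-x * Delta)
        - np.exp(-x * (Delta - delta))
        - np.exp(-x * (Delta + delta))
    )
    den = D0[..., None] ** 2 * alpha2**3 * (roots**2 - 1.0)
    s = (num / den).sum(axis=-1)
    out = 2.0 * (gamma * G * _G_TO_UM) ** 2 * s
    return out


def cylinder_perp_attenuation_gpd(d_a, delta, Delta, G, D0, n_roots: int = 14,
                                  gamma: float = GAMMA_PROTON,
                                  check_convergence: bool = False,
                                  conv_tol: float = 1e-8):
    """Perpendicular signal attenuation of an impermeable cylinder (GPD).

    Monotone non-increasing in both ``d_a`` and ``G``; equals 1 at G=0 and in
    the small-diameter limit.  With ``check_convergence`` the truncated series
    is compared against a doubled root count and a ``RuntimeError`` is raised
    if the result moves by more than ``conv_tol``.
    """
    neg_log = gpd_neg_log_attenuation(d_a, delta, Delta, G, D0, n_roots, gamma)
    if check_convergence:
        neg_log2 = gpd_neg_log_attenuation(d_a, delta, Delta, G, D0, 2 * n_roots, gamma)
        if np.any(np.abs(np.exp(-neg_log) - np.exp(-neg_log2)) > conv_tol):
            raise RuntimeError(
                "GPD series not converged: attenuation changed by more than "
                f"{conv_tol} when doubling n_roots from {n_roots}"
            )
    out = np.exp(-neg_log)
    return out if np.ndim(out) else float(out)


def effective_perp_diffusivity(d_a, delta, Delta, D0, n_roots: int = 14,
                               gamma: float = GAMMA_PROTON):
    """Effective perpendicular diffusivity of the GPD cylinder, −ln A / b.

    The GPD log-attenuation is quadratic in G, so −ln A / b does not depend on
    the reference gradient used; it is evaluated at the G giving b = 1 ms/µm².
    Vanishes as d_a → 0 and grows monotonically with d_a at fixed timings.
    """
    g_ref = gradient_from_bvalue(gamma, delta, Delta, 1.0)
    out = gpd_neg_log_attenuation(d_a, delta, Delta, g_ref, D0, n_roots, gamma)
    return out if np.ndim(out) else float(out)


# series threshold below which the erf formula is replaced by its expansion
_SMT_SMALL = 1e-6


def smt_axisymmetric(b, D_par, D_perp):
    """Spherical mean of an axially symmetric Gaussian compartment.

    For directional signal exp(−b(D⊥ + (D∥−D⊥)cos²θ)) the average over
    uniformly distributed orientations is

        exp(−b D⊥) · √π · erf(√(b(D∥−D⊥))) / (2 √(b(D∥−D⊥)))

    with the Taylor branch 1 − x/3 + x²/10 (x = b(D∥−D⊥)) near x = 0.
    """
    b = np.asarray(b, float)
    D_par = np.asarray(D_par, float)
    D_perp = np.asarray(D_perp, float)
    if np.any(b < 0):
        raise ValueError("b must be non-negative")
    if np.any(D_perp < 0) or np.any(D_perp > D_par + 1e-12):
        raise ValueError("need D_par >= D_perp >= 0")
    x = b * (D_par - D_perp)
    small = x < _SMT_SMALL
    xs = np.where(small, 1.0, x)  # placeholder to keep sqrt well-defined
    sq = np.sqrt(xs)
    m = 0.5 * np.sqrt(np.pi) * erf(sq) / sq
    m = np.where(small, 1.0 - x / 3.0 + x * x / 10.0, m)
    out = np.exp(-b * D_perp) * m
    return out if out.ndim else float(out)


def spherical_mean_snr_gain(n_directions: int) -> float:
    """SNR gain of the spherical mean over a single DW image: √N.

    Averaging N measurements with independent noise of equal variance reduces
    the noise standard deviation by √N.
    """
    if n_directions < 1:
        raise ValueError("n_directions must be >= 1")
    return float(np.sqrt(n_directions))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Shell:
    """One b-shell of a PGSE acquisition."""

    b_value: float              # ms/µm²
    n_directions: int
    gradient_strength: float    # mT/m
    delta: float                # ms
    Delta: float                # ms


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Multi-shell PGSE acquisition: shells plus b=0 references.

    Each shell stores its b-value and the (γ, δ, Δ, G) that produce it; on
    construction the stored b must match ``bvalue_from_gradients`` within 1%.
    """

    shells: tuple[Shell, ...]
    gamma: float = GAMMA_PROTON
    n_b0: int = 1

    def __post_init__(self):
        if not self.shells:
            raise ValueError("protocol needs at least one shell")
        bvals = [s.b_value for s in self.shells]
        if any(b <= 0 for b in bvals):
            raise ValueError("shell b-values must be strictly positive")
        if len(set(bvals)) != len(bvals):
            raise ValueError("shell b-values must be unique")
        for s in self.shells:
            _check_timings(self.gamma, s.delta, s.Delta)
            b_check = bvalue_from_gradients(self.gamma, s.delta, s.Delta,
                                            s.gradient_strength)
            if abs(b_check - s.b_value) > 0.01 * s.b_value:
                raise ValueError(
                    f"shell b={s.b_value} inconsistent with its gradients "
                    f"(computed {b_check:.4g})"
                )

    @classmethod
    def from_shell_table(cls, b_values: Sequence[float],
                         n_directions: Sequence[int],
                         delta: float, Delta: float,
                         gamma: float = GAMMA_PROTON,
                         n_b0: int = 1) -> "AcquisitionProtocol":
        """Build a protocol deriving each shell's G from its b-value."""
        shells = tuple(
            Shell(float(b), int(n), gradient_from_bvalue(gamma, delta, Delta, b),
                  delta, Delta)
            for b, n in zip(b_values, n_directions, strict=True)
        )
        return cls(shells=shells, gamma=gamma, n_b0=n_b0)

    @property
    def b_values(self) -> np.ndarray:
        return np.array([s.b_value for s in self.shells])

    @property
    def n_directions(self) -> np.ndarray:
        return np.array([s.n_directions for s in self.shells])

    @property
    def delta(self) -> float:
        deltas = {s.delta for s in self.shells}
        if len(deltas) != 1:
            raise ValueError("shells do not share a single delta")
        return deltas.pop()

    @property
    def Delta(self) -> float:
        Deltas = {s.Delta for s in self.shells}
        if len(Deltas) != 1:
            raise ValueError("shells do not share a single Delta")
        return Deltas.pop()


def default_exvivo_protocol(gamma: float = GAMMA_PROTON) -> AcquisitionProtocol:
    """The 8-shell ex vivo protocol used throughout this package.

    b = 1, 2.5, 5, 7.5, 11.1, 18.1, 25, 43 ms/µm² with 12 directions on the
    shells up to 7.5 and 32 on the shells from 11.1; δ = 11 ms, Δ = 15 ms;
    one b=0 before each shell (8 total).  Gradient strengths are derived from
    the b-values; the top shell lands at the scanner maximum of 660 mT/m.
    """
    b_values = [1.0, 2.5, 5.0, 7.5, 11.1, 18.1, 25.0, 43.0]
    n_dirs = [12 if b <= 7.5 else 32 for b in b_values]
    return AcquisitionProtocol.from_shell_table(
        b_values, n_dirs, delta=11.0, Delta=15.0, gamma=gamma, n_b0=8
    )


@dataclass
class TissueParams:
    """Per-voxel tissue state θ of the three-compartment model.

    ``d_par_ia`` is both the intra-axonal parallel diffusivity and the
    intrinsic diffusivity D0; the extra-cellular parallel diffusivity is tied
    equal to it and the extra-cellular perpendicular diffusivity is
    ``ec_perp_frac * d_par_ia``.
    """

    f_ia: float
    f_dot: float
    d_a: float              # µm
    d_par_ia: float         # µm²/ms
    ec_perp_frac: float     # D⊥ec = ec_perp_frac · D∥ec, in [0, 1]
    sigma: float = 0.01     # noise SD on normalized signal

    def __post_init__(self):
        for name in ("f_ia", "f_dot", "ec_perp_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.f_ia + self.f_dot > 1.0 + 1e-12:
            raise ValueError("f_ia + f_dot must not exceed 1")
        if self.d_a <= 0:
            raise ValueError("d_a must be positive")
        if self.d_par_ia <= 0:
            raise ValueError("d_par_ia must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def f_ec(self) -> float:
        return 1.0 - self.f_ia - self.f_dot

    @property
    def d_perp_ec(self) -> float:
        return self.ec_perp_frac * self.d_par_ia

    def as_array(self) -> np.ndarray:
        return np.array([self.f_ia, self.f_dot, self.d_a, self.d_par_ia,
                         self.ec_perp_frac, self.sigma])

    @classmethod
    def from_array(cls, arr) -> "TissueParams":
        return cls(*[float(v) for v in np.asarray(arr)])


@dataclass
class SphericalMeanSignal:
    """Normalized spherical-mean signal per non-zero b-shell."""

    b_values: np.ndarray
    means: np.ndarray
    b0_mean: float = 1.0

    def __post_init__(self):
        self.b_values = np.asarray(self.b_values, float)
        self.means = np.asarray(self.means, float)
        if self.means.shape[-1] != self.b_values.shape[0]:
            raise ValueError("means and b_values length mismatch")
        finite = self.means[np.isfinite(self.means)]
        if finite.size and (np.any(finite <= 0) or np.any(finite > 1.5)):
            raise ValueError("normalized spherical means must lie in (0, 1.5]")


# ---------------------------------------------------------------------------
# batched forward evaluation (shared with the MCMC sampler)
# ---------------------------------------------------------------------------

def _compartment_signals(d_a, d_par, ec_perp_frac, b, delta, Delta,
                         n_roots: int = 14, gamma: float = GAMMA_PROTON):
    """Spherical-mean signals of the IA and EC compartments.

    Parameters are 1-D arrays over voxels/chains (length V), b is (S,);
    returns two (V, S) arrays.
    """
    d_a = np.atleast_1d(np.asarray(d_a, float))
    d_par = np.atleast_1d(np.asarray(d_par, float))
    ec_perp_frac = np.atleast_1d(np.asarray(ec_perp_frac, float))
    b = np.asarray(b, float)
    d_perp_ia = effective_perp_diffusivity(d_a, delta, Delta, d_par, n_roots, gamma)
    s_ia = smt_axisymmetric(b[None, :], d_par[:, None], d_perp_ia[:, None])
    s_ec = smt_axisymmetric(b[None, :], d_par[:, None],
                            (ec_perp_frac * d_par)[:, None])
    return s_ia, s_ec


def _combine(f_ia, f_dot, s_ia, s_ec):
    f_ia = np.atleast_1d(np.asarray(f_ia, float))
    f_dot = np.atleast_1d(np.asarray(f_dot, float))
    f_ec = 1.0 - f_ia - f_dot
    return f_ia[:, None] * s_ia + f_ec[:, None] * s_ec + f_dot[:, None]


def model_signal(theta: TissueParams, protocol: AcquisitionProtocol,
                 n_roots: int = 14) -> SphericalMeanSignal:
    """Powder-averaged three-compartment signal at the protocol's shells.

    S(b) = f_ia·S_ia(b) + f_ec·S_ec(b) + f_dot, normalized so S(0) = 1; tends
    to f_dot as b → ∞ and is non-increasing in b.
    """
    b = protocol.b_values
    s_ia, s_ec = _compartment_signals(
        theta.d_a, theta.d_par_ia, theta.ec_perp_frac, b,
        protocol.delta, protocol.Delta, n_roots, protocol.gamma
    )
    means = _combine(theta.f_ia, theta.f_dot, s_ia, s_ec)[0]
    return SphericalMeanSignal(b_values=b, means=means, b0_mean=1.0)


# ---------------------------------------------------------------------------
# powder averaging of measured volumes
# ---------------------------------------------------------------------------

@dataclass
class ShellTable:
    """Assignment of DWI volumes to b-shells (−1 marks b=0 volumes)."""

    shell_b: np.ndarray      # (n_shells,) representative b-value per shell
    assignment: np.ndarray   # (n_volumes,) shell index, -1 for b=0

    @classmethod
    def from_bvals(cls, bvals, rtol: float = 0.05, b0_max: float = 0.05) -> "ShellTable":
        """Group a .bval series into shells.

        b-values within ``rtol`` (relative) of a group's running mean share a
        shell; values below ``b0_max`` ms/µm² count as b=0.
        """
        bvals = np.asarray(bvals, float)
        if bvals.ndim != 1:
            raise ValueError("bvals must be a 1-D sequence")
        assignment = np.full(bvals.shape, -1, dtype=int)
        groups: list[list[int]] = []
        for idx in np.argsort(bvals, kind="stable"):
            b = bvals[idx]
            if b <= b0_max:
                continue
            if groups:
                cur = groups[-1]
                mean = bvals[cur].mean()
                if abs(b - mean) <= rtol * mean:
                    cur.append(idx)
                    continue
            groups.append([idx])
        shell_b = np.array([bvals[g].mean() for g in groups])
        for i, g in enumerate(groups):
            assignment[g] = i
        return cls(shell_b=shell_b, assignment=assignment)

    @property
    def n_shells(self) -> int:
        return len(self.shell_b)


@dataclass
class SphericalMeanVolume:
    """Per-shell spherical-mean maps, normalized by the mean b=0 image."""

    means: np.ndarray        # (X, Y, Z, n_shells)
    b0_mean: np.ndarray      # (X, Y, Z)
    b_values: np.ndarray     # (n_shells,)
    valid: np.ndarray        # (X, Y, Z) bool; False where b0 mean <= 0


def powder_average(dwi_volume: np.ndarray, shell_table: ShellTable,
                   mask: np.ndarray | None = None) -> SphericalMeanVolume:
    """Direction-average a 4-D DWI series per shell and normalize by b=0.

    Voxels whose mean b=0 signal is non-positive are flagged invalid and set
    to NaN.  Voxels outside ``mask`` are NaN.
    """
    dwi = np.asarray(dwi_volume, float)
    if dwi.ndim != 4:
        raise ValueError("dwi_volume must be 4-D")
    assignment = shell_table.assignment
    if dwi.shape[3] != assignment.shape[0]:
        raise ValueError(
            f"{dwi.shape[3]} volumes but shell table covers {assignment.shape[0]}"
        )
    if not np.any(assignment == -1):
        raise ValueError("shell table contains no b=0 volumes")
    b0_mean = dwi[..., assignment == -1].mean(axis=-1)
    n_shells = shell_table.n_shells
    means = np.empty(dwi.shape[:3] + (n_shells,))
    for s in range(n_shells):
        sel = assignment == s
        if not np.any(sel):
            raise ValueError(f"shell {s} has no assigned volumes")
        means[..., s] = dwi[..., sel].mean(axis=-1)
    valid = b0_mean > 0
    in_mask = (np.ones(dwi.shape[:3], bool) if mask is None
               else np.asarray(mask, bool))
    if np.any(~valid & in_mask):
        warnings.warn("some voxels have non-positive b=0 mean; flagged invalid")
    valid &= in_mask
    with np.errstate(divide="ignore", invalid="ignore"):
        means = means / b0_mean[..., None]
    means[~valid] = np.nan
    return SphericalMeanVolume(means=means, b0_mean=b0_mean,
                               b_values=shell_table.shell_b, valid=valid)
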