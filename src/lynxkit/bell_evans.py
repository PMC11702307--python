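"""Bell–Evans model of forced bond dissociation and dynamic-force-spectrum fitting.

The Bell–Evans (Evans–Ritchie) model describes how a pulling force ``f``
lowers the activation barrier of a receptor–ligand bond and accelerates its
dissociation:

    k(f) = k0 · exp(f·γ / kBT)

where ``k0`` is the zero-force off-rate (1/s) and ``γ`` the width of the
activation barrier along the pulling coordinate (nm).  At a constant loading
rate ``rf`` (pN/s) the rupture-force density is

    p(f) = (k0/rf) · exp(γf/kBT) · exp[(k0·kBT/(γ·rf)) · (1 − exp(γf/kBT))]

whose mode — the most probable unbinding force — is linear in ln(rf):

    f* = (kBT/γ) · ln(γ·rf / (k0·kBT))

Fitting a line to f* versus ln(rf) therefore recovers γ from the slope and
k0 from the intercept; the zero-force bond lifetime is 1/k0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, thermal_energy

__all__ = [
    "BellEvansParams",
    "DfsPoint",
    "DfsFit",
    "DfsFitError",
    "off_rate",
    "bond_lifetime",
    "rupture_force_pdf",
    "rupture_force_cdf",
    "inverse_cdf",
    "most_probable_force",
    "fit_dfs",
    "single_bond_probability",
    "loading_rate_from_trace",
    "lifetime_fold_change",
]


@dataclass(frozen=True)
class BellEvansParams:
    """Kinetic parameters of a single slip bond.

    Parameters
    ----------
    k0 : float
        Zero-force dissociation rate, 1/s.  The zero-force bond lifetime
        is ``1/k0``.
    gamma : float
        Activation-barrier width γ, nm.
    temperature : float
        Absolute temperature, K.
    """

    k0: float
    gamma: float
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        for name in ("k0", "gamma", "temperature"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and positive, got {value}")

    @property
    def kbt(self) -> float:
        """Thermal energy kB·T, pN·nm."""
        return thermal_energy(self.temperature)

    @property
    def lifetime(self) -> float:
        """Zero-force bond lifetime 1/k0, s."""
        return 1.0 / self.k0


@dataclass(frozen=True)
class DfsPoint:
    """One point of a dynamic force spectrum.

    ``f_star`` is the most probable unbinding force (histogram mode) at
    loading rate ``loading_rate``; ``uncertainty`` is the half bin width of
    the force histogram it was read from.
    """

    loading_rate: float  # pN/s
    f_star: float  # pN
    uncertainty: float = 0.0  # pN

    def __post_init__(self) -> None:
        if not self.loading_rate > 0:
            raise ValueError(f"loading_rate must be positive, got {self.loading_rate}")
        if self.uncertainty < 0:
            raise ValueError(f"uncertainty must be >= 0, got {self.uncertainty}")


class DfsFitError(ValueError):
    """Raised when a dynamic-force-spectrum fit is ill-posed or fails."""


@dataclass(frozen=True)
class DfsFit:
    """Result of fitting f* = slope·ln(rf) + intercept to a force spectrum.

    ``slope`` equals kBT/γ (pN); ``k0_est`` is expressed in 1/s under the
    convention that loading rates entered the logarithm in pN/s.
    """

    slope: float  # pN
    intercept: float  # pN
    gamma_est: float  # nm
    k0_est: float  # 1/s
    lifetime: float  # s
    residuals: np.ndarray = field(repr=False)  # pN, one per point
    temperature: float = DEFAULT_TEMPERATURE
    weighted: bool = False


def _as_force(force) -> np.ndarray:
    f = np.asarray(force, dtype=float)
    if not np.all(np.isfinite(f)) or np.any(f < 0):
        raise ValueError("force must be finite and non-negative")
    return f


def off_rate(params: BellEvansParams, force) -> np.ndarray | float:
    """Force-dependent dissociation rate k(f) = k0·exp(f·γ/kBT), 1/s."""
    f = _as_force(force)
    out = params.k0 * np.exp(f * params.gamma / params.kbt)
    return float(out) if out.ndim == 0 else out


def bond_lifetime(params: BellEvansParams, force) -> np.ndarray | float:
    """Force-dependent bond lifetime t(f) = 1/k(f), s."""
    out = 1.0 / off_rate(params, force)
    return out


def rupture_force_pdf(params: BellEvansParams, loading_rate: float, force):
    """Evans–Ritchie rupture-force probability density, 1/pN.

    Normalized over f ∈ [0, ∞) for any positive loading rate.
    """
    if not loading_rate > 0:
        raise ValueError(f"loading_rate must be positive, got {loading_rate}")
    f = _as_force(force)
    beta = params.gamma / params.kbt  # 1/pN
    a = params.k0 * params.kbt / (params.gamma * loading_rate)
    # single exponential keeps the deep tail at 0 instead of inf*0
    with np.errstate(over="ignore"):
        out = (params.k0 / loading_rate) * np.exp(
            beta * f + a * (1.0 - np.exp(beta * f))
        )
    return float(out) if np.ndim(out) == 0 else out


def rupture_force_cdf(params: BellEvansParams, loading_rate: float, force):
    """Analytic CDF of the Evans–Ritchie rupture-force density."""
    if not loading_rate > 0:
        raise ValueError(f"loading_rate must be positive, got {loading_rate}")
    f = _as_force(force)
    beta = params.gamma / params.kbt
    a = params.k0 * params.kbt / (params.gamma * loading_rate)
    with np.errstate(over="ignore"):
        out = 1.0 - np.exp(a * (1.0 - np.exp(beta * f)))
    return float(out) if np.ndim(out) == 0 else out


def inverse_cdf(params: BellEvansParams, loading_rate: float, u):
    """Quantile function of the rupture-force distribution.

    Inverts the analytic CDF:  f(u) = (kBT/γ)·ln(1 − (γ·rf/(k0·kBT))·ln(1−u)).
    ``u`` must lie in the open interval (0, 1).
    """
    if not loading_rate > 0:
        raise ValueError(f"loading_rate must be positive, got {loading_rate}")
    uu = np.asarray(u, dtype=float)
    if np.any(uu <= 0) or np.any(uu >= 1):
        raise ValueError("u must lie strictly inside (0, 1)")
    beta = params.gamma / params.kbt
    a = params.k0 * params.kbt / (params.gamma * loading_rate)
    out = np.log1p(-np.log1p(-uu) / a) / beta
    return float(out) if out.ndim == 0 else out


def most_probable_force(params: BellEvansParams, loading_rate: float) -> float:
    """Most probable unbinding force f*, pN.

    Returns (kBT/γ)·ln(γ·rf/(k0·kBT)), clamped to 0 when the analytic mode
    is negative — at very low loading rates the density is monotonically
    decreasing and its mode sits at the f = 0 boundary.
    """
    if not loading_rate > 0:
        raise ValueError(f"loading_rate must be positive, got {loading_rate}")
    kbt = params.kbt
    analytic = (kbt / params.gamma) * math.log(
        params.gamma * loading_rate / (params.k0 * kbt)
    )
    return max(0.0, analytic)


def fit_dfs(
    points,
    temperature: float = DEFAULT_TEMPERATURE,
    weighted: bool = False,
) -> DfsFit:
    """Least-squares fit of f* against ln(rf) and kinetic-parameter extraction.

    Parameters
    ----------
    points : sequence of DfsPoint
        At least two points with distinct loading rates.
    temperature : float
        Temperature used to convert the slope into γ = kBT/slope.
    weighted : bool
        If True, apply inverse-variance weights from each point's
        half-bin ``uncertainty`` (all must then be positive); default is
        ordinary least squares.

    Returns
    -------
    DfsFit
        slope (kBT/γ), intercept, γ estimate, k0 estimate (1/s, pN/s
        loading-rate convention), zero-force lifetime 1/k0 and residuals.
    """
    points = list(points)
    rates = np.array([p.loading_rate for p in points], dtype=float)
    if len(points) < 2 or len(np.unique(rates)) < 2:
        raise DfsFitError("need at least 2 points with distinct loading rates")
    x = np.log(rates)
    y = np.array([p.f_star for p in points], dtype=float)
    if weighted:
        sig = np.array([p.uncertainty for p in points], dtype=float)
        if np.any(sig <= 0):
            raise DfsFitError("weighted fit requires positive uncertainties")
        w = 1.0 / sig**2
    else:
        w = np.ones_like(y)
    # weighted linear least squares via the normal equations
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    if sxx == 0:
        raise DfsFitError("degenerate design: loading rates collapse after weighting")
    slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    if slope <= 0:
        raise DfsFitError(
            f"non-positive slope {slope:.4g} pN: spectrum inconsistent with a "
            "single Bell-Evans barrier"
        )
    kbt = thermal_energy(temperature)
    gamma_est = kbt / slope
    k0_est = (1.0 / slope) * math.exp(-intercept / slope)
    return DfsFit(
        slope=slope,
        intercept=intercept,
        gamma_est=gamma_est,
        k0_est=k0_est,
        lifetime=1.0 / k0_est,
        residuals=y - (slope * x + intercept),
        temperature=temperature,
        weighted=weighted,
    )


def single_bond_probability(adhesion_frequency: float) -> float:
    """Probability that an adhesion event was mediated by exactly one bond.

    Under Poisson bond formation with mean ⟨n⟩, the adhesion frequency is
    Pa = 1 − e^(−⟨n⟩), so ⟨n⟩ = −ln(1 − Pa) and

        P(n = 1 | n ≥ 1) = ⟨n⟩·(1 − Pa)/Pa.

    Keeping Pa low (the study operated near 30%) keeps this above ~83%,
    justifying the single-bond interpretation of rupture events.
    """
    pa = float(adhesion_frequency)
    if not 0.0 < pa < 1.0:
        raise ValueError(f"adhesion frequency must be in (0, 1), got {pa}")
    mean_bonds = -math.log1p(-pa)
    return mean_bonds * (1.0 - pa) / pa


def loading_rate_from_trace(
    system_spring_constant: float,
    retraction_speed: float,
    speed_unit: str = "nm/s",
) -> float:
    """Loading rate rf = ks × v, pN/s.

    ``speed_unit`` may be ``"nm/s"`` (default) or ``"um/s"``/``"μm/s"``,
    in which case the retraction speed is converted to nm/s first.
    """
    ks = float(system_spring_constant)
    v = float(retraction_speed)
    if ks < 0 or v < 0:
        raise ValueError("spring constant and retraction speed must be non-negative")
    if speed_unit in ("um/s", "μm/s", "um_per_s"):
        v *= 1000.0
    elif speed_unit not in ("nm/s", "nm_per_s"):
        raise ValueError(f"unknown speed unit {speed_unit!r}")
    return ks * v


def _round_sig(value: float, sig: int = 2) -> float:
    if value == 0:
        return 0.0
    return round(value, -int(math.floor(math.log10(abs(value)))) + (sig - 1))


@dataclass(frozen=True)
class FoldChange:
    """Exact lifetime ratio plus a 2-significant-figure presentation."""

    ratio: float
    presented: float


def lifetime_fold_change(lifetime_a: float, lifetime_b: float) -> FoldChange:
    """Fold change lifetime_a / lifetime_b between two bond lifetimes."""
    a, b = float(lifetime_a), float(lifetime_b)
    if a <= 0 or b <= 0:
        raise ValueError("lifetimes must be positive")
    ratio = a / b
    return FoldChange(ratio=ratio, presented=_round_sig(ratio, 2))
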