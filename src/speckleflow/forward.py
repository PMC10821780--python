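"""Forward light-correlation models for diffuse optical blood-flow monitoring.

This module computes normalized field (``g1``) and intensity (``g2``)
autocorrelation functions and the fundamental speckle contrast for two
classes of forward model:

* the analytic solution of the correlation diffusion equation for a
  semi-infinite homogeneous medium in reflectance geometry, and
* the photon-history estimator, which sums per-detected-photon dynamic
  dephasing over the partial pathlengths and dimensionless momentum
  transfer recorded by a (Monte Carlo) transport simulation.

Scatterer motion is modeled as effective Brownian diffusion,
``<dr^2(tau)> = 6 * BFi * tau``, where the blood flow index BFi (cm^2/s)
is the quantity all downstream fitting recovers.

Canonical internal units are cm, s, cm^2/s and 1/cm; wavelengths enter in
nm and source-detector separations in mm at the public boundaries and are
converted immediately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import interpolate

__all__ = [
    "OpticalProperties",
    "FlowState",
    "SemiInfiniteGeometry",
    "CorrelationCurve",
    "SpeckleContrastBudget",
    "effective_reflection_coefficient",
    "in_medium_wavenumber",
    "semi_infinite_g1",
    "siegert_g2",
    "g1_from_histories",
    "speckle_contrast_from_g1",
    "multitau_grid",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of one tissue type.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient (1/cm).
    mu_s_prime : float
        Reduced scattering coefficient (1/cm).
    refractive_index : float
        Refractive index (dimensionless), default 1.4 for soft tissue.
    """

    mu_a: float
    mu_s_prime: float
    refractive_index: float = 1.4

    def __post_init__(self) -> None:
        if not (self.mu_a >= 0 and np.isfinite(self.mu_a)):
            raise ValueError(f"mu_a must be >= 0 and finite, got {self.mu_a}")
        if not (self.mu_s_prime > 0 and np.isfinite(self.mu_s_prime)):
            raise ValueError(f"mu_s_prime must be > 0, got {self.mu_s_prime}")
        if self.refractive_index < 1:
            raise ValueError(f"refractive_index must be >= 1, got {self.refractive_index}")

    @property
    def l_star(self) -> float:
        """Transport mean free path 1/mu_s_prime (cm)."""
        return 1.0 / self.mu_s_prime


@dataclass(frozen=True)
class FlowState:
    """Blood flow index per tissue label (cm^2/s)."""

    bfi_by_tissue: Mapping[str, float]

    def __post_init__(self) -> None:
        for label, bfi in self.bfi_by_tissue.items():
            if bfi < 0 or not np.isfinite(bfi):
                raise ValueError(f"BFi for {label!r} must be >= 0, got {bfi}")

    def perturbed(self, tissue: str, factor: float) -> "FlowState":
        """Return a copy with one tissue's BFi multiplied by ``factor``."""
        d = dict(self.bfi_by_tissue)
        d[tissue] = d[tissue] * factor
        return FlowState(d)


def effective_reflection_coefficient(n: float) -> float:
    """Effective Fresnel reflection coefficient R_eff(n) for the
    extrapolated-boundary condition of the diffusion equation.

    Uses the cubic-in-1/n empirical polynomial
    ``R_eff = -1.440/n^2 + 0.71/n + 0.668 + 0.0636*n``.
    """
    if not np.isfinite(n) or n < 1:
        raise ValueError(f"refractive index must be >= 1, got {n}")
    return -1.440 / n**2 + 0.71 / n + 0.668 + 0.0636 * n


def in_medium_wavenumber(wavelength_nm: float, n: float) -> float:
    """In-medium optical wavenumber k = 2*pi*n/lambda (1/cm)."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    lam_cm = wavelength_nm * 1e-7
    return 2.0 * math.pi * n / lam_cm


@dataclass(frozen=True)
class SemiInfiniteGeometry:
    """Geometric quantities of the semi-infinite reflectance solution.

    Build with :meth:`from_measurement`; all lengths in cm.
    """

    rho: float
    l_star: float
    z_b: float
    r1: float
    r_b: float
    r_eff: float
    k: float

    @classmethod
    def from_measurement(
        cls, sds_mm: float, optics: OpticalProperties, wavelength_nm: float
    ) -> "SemiInfiniteGeometry":
        """Construct from a source-detector separation (mm), tissue optics
        and vacuum wavelength (nm)."""
        if sds_mm <= 0:
            raise ValueError("source-detector separation must be positive")
        rho = sds_mm * 0.1  # mm -> cm
        l_star = optics.l_star
        r_eff = effective_reflection_coefficient(optics.refractive_index)
        z_b = (2.0 / (3.0 * optics.mu_s_prime)) * (1.0 + r_eff) / (1.0 - r_eff)
        r1 = math.hypot(rho, l_star)
        r_b = math.hypot(rho, l_star + 2.0 * z_b)
        k = in_medium_wavenumber(wavelength_nm, optics.refractive_index)
        return cls(rho=rho, l_star=l_star, z_b=z_b, r1=r1, r_b=r_b, r_eff=r_eff, k=k)


@dataclass(frozen=True)
class CorrelationCurve:
    """An autocorrelation curve on a delay grid.

    ``kind`` is ``"field_g1"`` or ``"intensity_g2"``; ``beta`` is the
    Siegert coherence parameter and is carried only by g2 curves.
    """

    tau: np.ndarray
    values: np.ndarray
    kind: str = "field_g1"
    beta: float | None = None

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "values", values)
        if tau.ndim != 1 or tau.shape != values.shape:
            raise ValueError("tau and values must be 1-d arrays of equal length")
        if tau.size and tau[0] < 0:
            raise ValueError("delays must be non-negative")
        if tau.size > 1 and np.any(np.diff(tau) <= 0):
            raise ValueError("delay grid must be strictly increasing")
        if self.kind not in ("field_g1", "intensity_g2"):
            raise ValueError(f"unknown curve kind {self.kind!r}")

    def interpolator(self):
        """Linear-in-log-tau interpolator, constant extension at the ends.

        The first grid point may be tau=0; interpolation below the first
        positive delay falls back to linear in tau.
        """
        return interpolate.interp1d(
            self.tau, self.values, kind="linear", bounds_error=False,
            fill_value=(self.values[0], self.values[-1]),
        )


@dataclass(frozen=True)
class SpeckleContrastBudget:
    """Squared speckle-contrast budget at one exposure time.

    The measured squared contrast is the sum of a fundamental (tissue
    dynamics) term and shot/read/dark noise terms:
    ``K^2 = Kf^2 + Ks^2 + Kr^2 + Kd^2``.
    """

    t_exp: float
    kf2: float
    ks2: float = 0.0
    kr2: float = 0.0
    kd2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("kf2", "ks2", "kr2", "kd2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.t_exp <= 0:
            raise ValueError("t_exp must be positive")

    @property
    def k2_total(self) -> float:
        return self.kf2 + self.ks2 + self.kr2 + self.kd2


def multitau_grid(
    first_bin: float = 1e-6, bins_per_octave: int = 8, tau_max: float = 0.1,
    include_zero: bool = True,
) -> np.ndarray:
    """Quasi-logarithmic multi-tau-style delay grid (s).

    The first octave holds ``2 * bins_per_octave`` linearly spaced lags of
    width ``first_bin``; each later octave doubles the lag spacing, as in
    hardware correlators.
    """
    if first_bin <= 0 or tau_max <= first_bin:
        raise ValueError("need 0 < first_bin < tau_max")
    lags = [first_bin * i for i in range(1, 2 * bins_per_octave + 1)]
    width = first_bin
    while lags[-1] < tau_max:
        width *= 2.0
        for _ in range(bins_per_octave):
            nxt = lags[-1] + width
            if nxt > tau_max:
                break
            lags.append(nxt)
        else:
            continue
        break
    grid = np.asarray(lags)
    if include_zero:
        grid = np.concatenate(([0.0], grid))
    return grid


def multitau_bin_widths(tau: np.ndarray, first_bin: float = 1e-6,
                        bins_per_octave: int = 8) -> np.ndarray:
    """Accumulator bin width at each lag of a multi-tau grid.

    The first ``2 * bins_per_octave`` lags use the base width; each later
    octave doubles it.  Lags of zero inherit the base width.
    """
    tau = np.asarray(tau, dtype=float)
    idx = np.maximum(np.rint(tau / first_bin).astype(int), 1)
    octave = np.maximum(np.ceil(np.log2(idx / bins_per_octave)).astype(int), 1)
    return first_bin * 2.0 ** (octave - 1)


def _check_finite(**params: float) -> None:
    for name, value in params.items():
        if not np.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value}")


def semi_infinite_g1(
    geometry: SemiInfiniteGeometry,
    optics: OpticalProperties,
    bfi: float,
    tau: np.ndarray,
) -> CorrelationCurve:
    """Normalized field autocorrelation of a semi-infinite medium.

    Implements the reflectance-geometry solution of the correlation
    diffusion equation with an extrapolated boundary:

        g1(tau) = [rb e^{-K(tau) r1} - r1 e^{-K(tau) rb}]
                / [rb e^{-K(0) r1} - r1 e^{-K(0) rb}]

    with K(tau) = sqrt(3 mu_a mu_s' + 6 k^2 mu_s'^2 BFi tau) and k the
    in-medium wavenumber. g1(0) = 1 exactly.
    """
    _check_finite(bfi=bfi, mu_a=optics.mu_a, mu_s_prime=optics.mu_s_prime)
    if bfi < 0:
        raise ValueError("BFi must be >= 0")
    tau = np.asarray(tau, dtype=float)
    if tau.size and (tau[0] < 0 or np.any(np.diff(tau) <= 0)):
        raise ValueError("tau must be non-negative and strictly increasing")

    mu_a, mu_sp = optics.mu_a, optics.mu_s_prime
    r1, rb, k = geometry.r1, geometry.r_b, geometry.k
    kappa = np.sqrt(3.0 * mu_a * mu_sp + 6.0 * k**2 * mu_sp**2 * bfi * tau)
    kappa0 = math.sqrt(3.0 * mu_a * mu_sp)

    # Factor out the static attenuation so numerator/denominator stay in
    # floating range even at large rho * kappa.
    num = rb * np.exp(-(kappa - kappa0) * r1) - r1 * np.exp(-(kappa * rb - kappa0 * r1))
    den = rb - r1 * math.exp(-kappa0 * (rb - r1))
    values = num / den
    return CorrelationCurve(tau=tau, values=values, kind="field_g1")


def siegert_g2(g1: CorrelationCurve, beta: float) -> CorrelationCurve:
    """Siegert relation ``g2(tau) = 1 + beta * |g1(tau)|^2``."""
    if not (0 < beta <= 1):
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    if g1.kind != "field_g1":
        raise ValueError("siegert_g2 expects a field (g1) curve")
    return CorrelationCurve(
        tau=g1.tau, values=1.0 + beta * np.abs(g1.values) ** 2,
        kind="intensity_g2", beta=beta,
    )


def g1_from_histories(
    histories,
    optics_by_tissue: Mapping[str, OpticalProperties],
    flow: FlowState,
    tau: np.ndarray,
    detector_id: int | None = None,
) -> CorrelationCurve:
    """Normalized field autocorrelation from a photon-history table.

    Each detected photon n contributes

        exp(-(1/3) sum_i k_i^2 Y_{n,i} 6 BFi_i tau) * exp(-sum_i mu_a,i L_{n,i})

    where Y and L are the per-tissue dimensionless momentum transfer and
    partial pathlength, k_i the in-medium wavenumber in tissue i, and the
    result is normalized by its tau=0 value (so absorption weights set the
    relative photon contributions but cancel overall scaling).

    Parameters
    ----------
    histories : PhotonHistoryTable
        Table of detected-photon records (see :mod:`speckleflow.histories`).
    detector_id : int, optional
        Restrict to one detector; required when the table holds several.
    """
    labels = list(histories.tissue_labels)
    missing = [t for t in labels if t not in optics_by_tissue or t not in flow.bfi_by_tissue]
    if missing:
        raise KeyError(f"tissue labels missing optics/flow entries: {missing}")

    L, Y = histories.select(detector_id)
    if L.shape[0] == 0:
        raise ValueError(f"no detected photons for detector {detector_id!r}")

    tau = np.asarray(tau, dtype=float)
    k2 = np.array(
        [in_medium_wavenumber(histories.wavelength_nm, optics_by_tissue[t].refractive_index) ** 2
         for t in labels]
    )
    mua = np.array([optics_by_tissue[t].mu_a for t in labels])
    bfi = np.array([flow.bfi_by_tissue[t] for t in labels])

    absorb_w = np.exp(-L @ mua)                      # (Np,)
    decay = 2.0 * (Y @ (k2 * bfi))                   # (Np,) 1/s; (1/3)*6 = 2
    # G1(tau)/G1(0) = sum_n w_n exp(-decay_n tau) / sum_n w_n
    values = (absorb_w[None, :] @ np.exp(-np.outer(tau, decay).T)).ravel()
    if tau.size and tau[0] == 0.0:
        values /= values[0]  # same summation path: exactly 1 at zero delay
    else:
        values /= absorb_w.sum()
    return CorrelationCurve(tau=tau, values=values, kind="field_g1")


def _contrast_nodes():
    """Composite 8-point Gauss-Legendre nodes/weights on log-spaced
    panels of [0, 1]; the integrand may be concentrated arbitrarily close
    to zero when the exposure far exceeds the decorrelation time."""
    panels = np.concatenate(([0.0], np.logspace(-8, 0, 33)))
    gl_x, gl_w = np.polynomial.legendre.leggauss(8)
    a, b = panels[:-1], panels[1:]
    mid, half = (a + b) / 2.0, (b - a) / 2.0
    nodes = (mid[:, None] + half[:, None] * gl_x[None, :]).ravel()
    weights = (half[:, None] * gl_w[None, :]).ravel()
    return nodes, weights


_CONTRAST_NODES, _CONTRAST_WEIGHTS = _contrast_nodes()


def speckle_contrast_from_g1(g1, beta: float, t_exp: float) -> float:
    """Fundamental squared speckle contrast at exposure time ``t_exp``.

    Evaluates ``Kf^2 = (2 beta / Texp) * int_0^Texp g1(tau)^2 (1 - tau/Texp) dtau``
    by composite Gauss-Legendre quadrature on log-spaced panels
    (relative accuracy well below 1e-6 for smooth decays).  ``g1`` may be
    a :class:`CorrelationCurve` (interpolated, extended by its last value
    beyond the grid) or a vectorizable callable ``g1(tau)``.
    """
    if t_exp <= 0:
        raise ValueError("t_exp must be positive")
    f = g1 if callable(g1) else g1.interpolator()
    g = np.asarray(f(_CONTRAST_NODES * t_exp), dtype=float)
    val = float(_CONTRAST_WEIGHTS @ (g * g * (1.0 - _CONTRAST_NODES)))
    return 2.0 * beta * val
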