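"""Detector, laser, fiber and illumination-strategy models.

Covers the hardware side of the measurement: skin-safe laser power
(ANSI Z136.1 CW maximum permissible exposure), guided-mode counting for
step-index fibers and bundles, speckle-to-pixel sampling limits, single
photon detector dead-time saturation, the four laser delivery
strategies, and photon-flux calibration against a reference
source-detector separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import special

__all__ = [
    "DetectorModel",
    "LaserModel",
    "FiberModel",
    "IlluminationPlan",
    "FluxCalibration",
    "ansi_limited_power",
    "count_guided_modes",
    "bundle_mode_count",
    "min_speckle_to_pixel",
    "saturation_limit",
    "illumination_plan",
    "photon_flux_per_mode",
    "DETECTOR_PRESETS",
    "LASER_PRESETS",
    "FIBER_PRESETS",
]


@dataclass(frozen=True)
class DetectorModel:
    """A photodetector: point photon counter (n_pixels=1) or camera."""

    name: str
    quantum_efficiency: float
    dark_count_rate: float = 0.0     # cps (photon counters) or e-/s (cameras)
    read_noise_e: float = 0.0        # e- RMS per read
    hold_off: float = 0.0            # s; 0 = no dead time
    max_frame_rate: float | None = None  # Hz; None = free running
    n_pixels: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.quantum_efficiency <= 1:
            raise ValueError("quantum efficiency must be in (0, 1]")
        if self.dark_count_rate < 0 or self.read_noise_e < 0 or self.hold_off < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")


@dataclass(frozen=True)
class LaserModel:
    wavelength_nm: float
    max_output_power_mw: float
    spot_diameter_mm: float = 3.5
    ansi_power_mw: float | None = None
    """Configured skin-safe power per spot; ``None`` computes it from the
    MPE formula.  Presets may pin a rounded configured value."""

    def __post_init__(self) -> None:
        if self.max_output_power_mw <= 0 or self.spot_diameter_mm <= 0:
            raise ValueError("powers and spot diameter must be positive")

    @property
    def p_ansi_mw(self) -> float:
        if self.ansi_power_mw is not None:
            return self.ansi_power_mw
        return ansi_limited_power(self.wavelength_nm, self.spot_diameter_mm)


@dataclass(frozen=True)
class FiberModel:
    core_diameter_um: float
    numerical_aperture: float
    n_fibers: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.numerical_aperture < 1:
            raise ValueError("NA must be in (0, 1)")
        if self.core_diameter_um <= 0 or self.n_fibers < 1:
            raise ValueError("core diameter > 0 and n_fibers >= 1 required")

    def v_number(self, wavelength_nm: float) -> float:
        return math.pi * self.core_diameter_um * self.numerical_aperture / (wavelength_nm * 1e-3)


def ansi_limited_power(wavelength_nm: float, spot_diameter_mm: float = 3.5) -> float:
    """Maximum skin-safe CW power (mW) for a circular illumination spot.

    ANSI Z136.1 skin CW MPE: ``0.2 * 10^(0.002 (lambda - 700)) W/cm^2``
    for 700-1050 nm and ``1.0 W/cm^2`` for 1050-1400 nm, times spot area.
    """
    if not 700 <= wavelength_nm <= 1400:
        raise ValueError(f"wavelength {wavelength_nm} nm outside supported 700-1400 nm band")
    if wavelength_nm <= 1050:
        mpe_w_cm2 = 0.2 * 10 ** (0.002 * (wavelength_nm - 700.0))
    else:
        mpe_w_cm2 = 1.0
    area_cm2 = math.pi * (spot_diameter_mm * 0.1 / 2.0) ** 2
    return mpe_w_cm2 * area_cm2 * 1000.0  # W -> mW


def count_guided_modes(fiber: FiberModel, wavelength_nm: float) -> int:
    """Total guided modes (orientation and polarization degeneracy
    included) of a step-index fiber by LP-mode cutoff counting.

    The cutoff of LP_lm is the m-th zero of the Bessel function J_{l-1}
    (with the l=0 family starting at cutoff 0); each l>=1 mode carries two
    orientations and every mode two polarizations.  For large V
    (V >= 15) the quadratic estimate V^2/2 is used instead.
    """
    v = fiber.v_number(wavelength_nm)
    if v >= 15.0:
        return round(v * v / 2.0)
    total_spatial = 0
    max_m = int(v / math.pi) + 3
    l = 0
    while True:
        if l == 0:
            # LP0m cutoffs: 0, then the zeros of J1
            cutoffs = np.concatenate(([0.0], special.jn_zeros(1, max_m)))
        else:
            cutoffs = special.jn_zeros(l - 1, max_m)
            if l - 1 == 0:
                pass  # zeros of J0 are all positive already
        n_below = int(np.count_nonzero(cutoffs < v))
        if n_below == 0:
            break
        total_spatial += n_below * (1 if l == 0 else 2)
        l += 1
    return 2 * total_spatial


def bundle_mode_count(bundle: FiberModel, wavelength_nm: float, per_fiber: str = "v2_over_2") -> float:
    """Estimated guided modes of a multimode fiber bundle.

    ``per_fiber`` selects the counting convention: ``"v2_over_2"``
    (default, V^2/2 per fiber) or ``"v2"`` (V^2, both polarizations of
    every spatial mode).
    """
    v = bundle.v_number(wavelength_nm)
    if v < 2.405:
        raise ValueError("bundle_mode_count expects the multimode regime (V >> 2.405)")
    per = v * v / 2.0 if per_fiber == "v2_over_2" else v * v
    return bundle.n_fibers * per


def min_speckle_to_pixel(n_pixels: float, n_modes: float) -> float:
    """Smallest usable speckle-to-pixel size ratio, sqrt(pixels/modes):
    below it the available modes underfill the sensor."""
    if n_modes <= 0:
        raise ValueError("n_modes must be positive")
    return math.sqrt(n_pixels / n_modes)


def saturation_limit(hold_off: float) -> float:
    """Sustained count-rate cap 1/hold_off (cps); ``inf`` if no dead time."""
    if hold_off < 0:
        raise ValueError("hold_off must be >= 0")
    if hold_off == 0:
        return math.inf
    return 1.0 / hold_off


_STRATEGIES = ("cw_single", "cw_multi", "pulsed_power_limited", "pulsed_frame_limited")


@dataclass(frozen=True)
class IlluminationPlan:
    """Resolved laser delivery: instantaneous power per source, duty
    cycle, number of sources and (SCOS) effective frame rate.  Average
    delivered power per spot never exceeds the ANSI limit."""

    strategy: str
    instantaneous_power_mw: float
    duty_cycle: float
    n_sources: int = 1
    effective_frame_rate: float | None = None
    p_ansi_mw: float | None = None
    """Skin-safe power per spot of the laser this plan was resolved for
    (the reference for relative-flux scaling)."""

    def __post_init__(self) -> None:
        if self.strategy not in _STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0 < self.duty_cycle <= 1:
            raise ValueError("duty cycle must be in (0, 1]")
        if self.instantaneous_power_mw <= 0 or self.n_sources < 1:
            raise ValueError("power must be > 0 and n_sources >= 1")

    @property
    def average_power_per_spot_mw(self) -> float:
        return self.instantaneous_power_mw * self.duty_cycle

    @property
    def flux_boost(self) -> float:
        """Instantaneous detected-flux multiplier relative to a single CW
        ANSI-limited source (sources add incoherently)."""
        return self.n_sources * self.instantaneous_power_mw


def illumination_plan(
    strategy: str,
    laser: LaserModel,
    t_exp: float | None = None,
    camera_max_fps: float | None = None,
    n_sources: int | None = None,
) -> IlluminationPlan:
    """Resolve one of the four laser delivery strategies into a plan.

    DCS (``t_exp=None``): ``cw_single`` runs one spot at the ANSI limit;
    ``cw_multi`` arrays floor(Pmax/P_ANSI) ANSI-limited spots (override
    ``n_sources`` to split Pmax into more sub-ANSI spots); either pulsed
    strategy reduces the duty cycle to P_ANSI/Pmax while emitting Pmax.

    SCOS (``t_exp`` set): ``pulsed_power_limited`` keeps the frame rate
    and raises instantaneous power to P_ANSI/(fs*Texp) capped at Pmax;
    ``pulsed_frame_limited`` emits Pmax and lowers the frame rate so the
    average stays at the ANSI limit.
    """
    p_ansi = laser.p_ansi_mw
    p_max = laser.max_output_power_mw

    if strategy == "cw_single":
        return IlluminationPlan(strategy, min(p_ansi, p_max), 1.0, 1,
                                effective_frame_rate=_fs(t_exp, camera_max_fps),
                                p_ansi_mw=p_ansi)
    if strategy == "cw_multi":
        if n_sources is None:
            n_sources = max(1, int(p_max / p_ansi))
        per_source = min(p_ansi, p_max / n_sources)
        return IlluminationPlan(strategy, per_source, 1.0, n_sources,
                                effective_frame_rate=_fs(t_exp, camera_max_fps),
                                p_ansi_mw=p_ansi)
    if t_exp is None:
        # DCS pulsed: full power with duty cycle P_ANSI / P_max
        duty = min(1.0, p_ansi / p_max)
        return IlluminationPlan(strategy, p_max, duty, 1, p_ansi_mw=p_ansi)
    if t_exp <= 0:
        raise ValueError("t_exp must be positive for SCOS plans")
    if strategy == "pulsed_power_limited":
        fs = _fs(t_exp, camera_max_fps)
        duty = min(1.0, fs * t_exp)
        p_inst = min(p_max, p_ansi / duty)
        return IlluminationPlan(strategy, p_inst, duty, 1, effective_frame_rate=fs,
                                p_ansi_mw=p_ansi)
    # pulsed_frame_limited: emit P_max, slow the camera to stay skin safe
    fs = min(_fs(t_exp, camera_max_fps), p_ansi / (p_max * t_exp))
    duty = min(1.0, fs * t_exp)
    return IlluminationPlan(strategy, p_max, duty, 1, effective_frame_rate=fs,
                            p_ansi_mw=p_ansi)


def _fs(t_exp: float | None, camera_max_fps: float | None) -> float | None:
    if t_exp is None:
        return camera_max_fps
    fs = 1.0 / t_exp
    if camera_max_fps is not None:
        fs = min(fs, camera_max_fps)
    return fs


@dataclass(frozen=True)
class FluxCalibration:
    """Detected photon flux per mode for a single CW ANSI-limited source
    at a reference separation, anchoring the relative reflectance curve."""

    reference_sds_mm: float
    cps_per_mode_at_reference: float
    wavelength_nm: float

    def __post_init__(self) -> None:
        if self.cps_per_mode_at_reference <= 0:
            raise ValueError("calibration flux must be positive")


def load_reflectance_fixture(wavelength_nm: float):
    """Shipped diffuse-reflectance curve (sds_mm, reflectance per cm^2)
    for the 15 mm extracerebral slab preset, from a cached high-photon
    transport run; use when no geometry-specific curve is available."""
    from importlib import resources

    wl = int(round(wavelength_nm))
    if wl not in (850, 1064):
        raise KeyError(f"no shipped reflectance curve for {wavelength_nm} nm")
    ref = resources.files("speckleflow.data") / f"slab_reflectance_{wl}nm.csv"
    data = np.loadtxt(str(ref), delimiter=",", skiprows=3)
    return data[:, 0], data[:, 1]


#: Per-mode detected flux for one ANSI-limited CW source at 25 mm.
FLUX_CALIBRATIONS = {
    850: FluxCalibration(25.0, 10_000.0, 850),
    1064: FluxCalibration(25.0, 67_100.0, 1064),
}


def photon_flux_per_mode(
    sds_mm: float,
    reflectance_sds_mm: np.ndarray,
    reflectance: np.ndarray,
    calibration: FluxCalibration,
    plan: IlluminationPlan,
    per_mode_throughput_factor: float = 1.0,
) -> float:
    """Instantaneous detected photon flux per mode (cps) at ``sds_mm``.

    Scales the calibrated reference flux by the relative diffuse
    reflectance R(sds)/R(reference) (log-interpolated on the supplied
    curve) and by the plan's instantaneous power relative to a single
    ANSI source.  Quantum efficiency is applied downstream at detection.
    ``per_mode_throughput_factor`` models optical coupling losses
    (e.g. 1/9 for a bundle-coupled camera with poor per-mode throughput).
    """
    r = np.asarray(reflectance_sds_mm, dtype=float)
    refl = np.asarray(reflectance, dtype=float)
    lo, hi = r.min(), r.max()
    for s in (sds_mm, calibration.reference_sds_mm):
        if not lo <= s <= hi:
            raise ValueError(f"SDS {s} mm outside reflectance curve range [{lo}, {hi}] mm")
    if np.any(refl <= 0):
        raise ValueError("reflectance curve must be strictly positive")
    logr = np.interp([sds_mm, calibration.reference_sds_mm], r, np.log(refl))
    ratio = math.exp(logr[0] - logr[1])
    power_factor = (plan.n_sources * plan.instantaneous_power_mw) / _ansi_of(plan, calibration)
    return (calibration.cps_per_mode_at_reference * ratio * power_factor
            * per_mode_throughput_factor)


def _ansi_of(plan: IlluminationPlan, calibration: FluxCalibration) -> float:
    # the calibration is defined per ANSI-limited source at the same wavelength
    if plan.p_ansi_mw is not None:
        return plan.p_ansi_mw
    return ansi_limited_power(calibration.wavelength_nm)


# -- Hardware presets -------------------------------------------------------

DETECTOR_PRESETS = {
    # silicon SPAD for 850 nm DCS; dark counts configurable 0-1500 cps
    "dcs_850_sispad": DetectorModel(
        "dcs_850_sispad", quantum_efficiency=0.55, dark_count_rate=0.0,
        read_noise_e=0.0, hold_off=22e-9, n_pixels=1,
    ),
    # SNSPD for 1064 nm DCS
    "dcs_1064_snspd": DetectorModel(
        "dcs_1064_snspd", quantum_efficiency=0.90, dark_count_rate=0.0,
        read_noise_e=0.0, hold_off=33e-9, n_pixels=1,
    ),
    # aggregated CMOS camera for 850 nm SCOS
    "scos_850_cmos": DetectorModel(
        "scos_850_cmos", quantum_efficiency=0.20, dark_count_rate=0.0,
        read_noise_e=2.5, hold_off=0.0, max_frame_rate=150.0,
        n_pixels=2_500_000,
    ),
}

LASER_PRESETS = {
    # 300 mW source at 850 nm (7.9x the 38 mW single-spot skin limit)
    "laser_850": LaserModel(850.0, 300.0, 3.5, ansi_power_mw=38.0),
    # 1 W source at 1064 nm; configured skin limit pinned at the rounded 100 mW
    "laser_1064": LaserModel(1064.0, 1000.0, 3.5, ansi_power_mw=100.0),
}

FIBER_PRESETS = {
    "single_mode_780hp": FiberModel(4.4, 0.13),
    "few_mode_smf28": FiberModel(8.2, 0.14),
    "bundle_2000x50um": FiberModel(50.0, 0.66, n_fibers=2000),
}
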