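"""Performance pipeline: sensitivity, CoV and CNR for DCS and SCOS.

Orchestrates the full simulated measurement: forward correlation curves
from photon histories for a baseline and a perturbed (+20% cerebral
flow) state, instrument-constrained photon flux, measurement noise,
ensembles of noisy realizations, BFi inversion, and the three
comparison metrics:

* sensitivity — the fraction of the true relative cerebral flow change
  recovered in the fitted BFi;
* CoV — std/mean of the fitted BFi over the noise ensemble at the
  10 Hz sample rate (instrument precision; physiological variability is
  ~0.1, which sets the acceptability threshold);
* CNR — sensitivity / CoV (>= 1 desired).

Sweep drivers reproduce the four study axes (fit range / exposure time,
illumination strategy, modal content / speckle sampling, extracerebral
thickness) on layered-slab geometries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import instruments as instr
from .fitting import (
    FIT_OPTICS,
    FitSettings,
    estimate_decay_rate,
    fit_ensemble_contrast,
    fit_ensemble_g2,
    fit_range_cutoff,
)
from .forward import (
    CorrelationCurve,
    multitau_bin_widths,
    FlowState,
    g1_from_histories,
    multitau_grid,
    siegert_g2,
    speckle_contrast_from_g1,
)
from .histories import PhotonHistoryTable
from .montecarlo import TABLE1_FLOW_BASELINE, TABLE1_FLOW_PERTURBED, TABLE1_OPTICS
from .noise import (
    DcsNoiseParams,
    dcs_noise_sigma,
    gaussian_noise_realizations,
    measured_contrast_stats,
    speckle_field_sequence,
)

__all__ = [
    "MeasurementConfig",
    "PerformanceMetrics",
    "sensitivity",
    "coefficient_of_variation",
    "contrast_to_noise",
    "evaluate_configuration",
    "sweep",
]

SENSITIVITY_THRESHOLD = 0.10
COV_THRESHOLD = 0.10
CNR_THRESHOLD = 1.0


@dataclass(frozen=True)
class MeasurementConfig:
    """One fully specified simulated measurement."""

    technique: str                       # "dcs" | "scos"
    wavelength_nm: float
    sds_mm: float
    detector: instr.DetectorModel
    laser: instr.LaserModel
    fiber: instr.FiberModel
    strategy: str = "cw_single"
    fit_fraction: float | None = None    # DCS
    t_exp: float | None = None           # SCOS
    s_over_p: float | None = None        # SCOS
    sample_rate: float = 10.0
    n_realizations: int = 100
    seed: int = 0
    dark_count_rate: float | None = None  # overrides the detector preset
    per_mode_throughput_factor: float = 1.0
    correlator_bin_s: float = 1e-6       # DCS first-bin width T

    def __post_init__(self) -> None:
        if self.technique not in ("dcs", "scos"):
            raise ValueError("technique must be 'dcs' or 'scos'")
        if self.technique == "dcs":
            if self.fit_fraction is None or self.t_exp is not None:
                raise ValueError("DCS configs set fit_fraction and not t_exp")
        else:
            if self.t_exp is None or self.fit_fraction is not None:
                raise ValueError("SCOS configs set t_exp and not fit_fraction")
            if self.s_over_p is None or self.s_over_p <= 0:
                raise ValueError("SCOS configs need s_over_p > 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @classmethod
    def dcs_preset(cls, wavelength_nm: float, sds_mm: float, **kw) -> "MeasurementConfig":
        name = "dcs_850_sispad" if int(wavelength_nm) == 850 else "dcs_1064_snspd"
        laser = instr.LASER_PRESETS["laser_850" if int(wavelength_nm) == 850 else "laser_1064"]
        kw.setdefault("fit_fraction", 1.0)
        kw.setdefault("fiber", instr.FIBER_PRESETS["single_mode_780hp"])
        return cls(technique="dcs", wavelength_nm=wavelength_nm, sds_mm=sds_mm,
                   detector=instr.DETECTOR_PRESETS[name], laser=laser, **kw)

    @classmethod
    def scos_preset(cls, sds_mm: float, t_exp: float, **kw) -> "MeasurementConfig":
        kw.setdefault("s_over_p", 1.0)
        kw.setdefault("fiber", instr.FIBER_PRESETS["bundle_2000x50um"])
        return cls(technique="scos", wavelength_nm=850.0, sds_mm=sds_mm,
                   detector=instr.DETECTOR_PRESETS["scos_850_cmos"],
                   laser=instr.LASER_PRESETS["laser_850"], t_exp=t_exp, **kw)


@dataclass(frozen=True)
class PerformanceMetrics:
    """Sensitivity, CoV and CNR with their ensemble inputs and flags."""

    sensitivity: float
    cov: float
    cnr: float
    bfi_base_mean: float
    bfi_base_std: float
    bfi_pert_mean: float
    bfi_pert_std: float
    n_failed: int = 0
    saturation_capped: bool = False
    detected_rate_cps: float | None = None
    beta: float | None = None

    @property
    def sensitivity_ok(self) -> bool:
        return self.sensitivity >= SENSITIVITY_THRESHOLD

    @property
    def cov_ok(self) -> bool:
        return self.cov <= COV_THRESHOLD

    @property
    def cnr_ok(self) -> bool:
        return self.cnr >= CNR_THRESHOLD

    def as_row(self) -> dict:
        return {
            "sensitivity": self.sensitivity, "cov": self.cov, "cnr": self.cnr,
            "bfi_base_mean": self.bfi_base_mean, "bfi_base_std": self.bfi_base_std,
            "bfi_pert_mean": self.bfi_pert_mean, "bfi_pert_std": self.bfi_pert_std,
            "n_failed": self.n_failed, "saturation_capped": self.saturation_capped,
            "detected_rate_cps": self.detected_rate_cps, "beta": self.beta,
            "sensitivity_ok": self.sensitivity_ok, "cov_ok": self.cov_ok,
            "cnr_ok": self.cnr_ok,
        }


def sensitivity(bfi_base: float, bfi_pert: float,
                cbf_base: float = TABLE1_FLOW_BASELINE["brain"],
                cbf_pert: float = TABLE1_FLOW_PERTURBED["brain"]) -> float:
    """Fraction of the true relative cerebral flow change recovered:
    (dBFi/BFi_base) / (dCBF/CBF_base)."""
    if bfi_base <= 0 or cbf_base <= 0:
        raise ValueError("baselines must be positive")
    return ((bfi_pert - bfi_base) / bfi_base) / ((cbf_pert - cbf_base) / cbf_base)


def coefficient_of_variation(fitted_bfi: np.ndarray) -> float:
    """Sample std / sample mean of a fitted-BFi ensemble (ddof=1)."""
    x = np.asarray(fitted_bfi, dtype=float)
    if x.size < 2:
        raise ValueError("need an ensemble of >= 2 fits")
    mu = x.mean()
    if mu <= 0:
        raise ValueError("ensemble mean must be positive")
    return float(x.std(ddof=1) / mu)


def contrast_to_noise(sens: float, cov: float) -> float:
    """CNR = sensitivity / CoV; infinite for a noiseless ensemble."""
    if cov < 0:
        raise ValueError("cov must be >= 0")
    if cov == 0:
        return math.inf
    return sens / cov


def _g1_pair(config, histories_base, histories_pert, tau):
    """Baseline/perturbed normalized g1 at the configured separation."""
    wl = int(round(config.wavelength_nm))
    optics = TABLE1_OPTICS[wl]
    labels = histories_base.tissue_labels
    flow_base = FlowState({t: TABLE1_FLOW_BASELINE[t] for t in labels})
    flow_pert = FlowState({t: TABLE1_FLOW_PERTURBED[t] for t in labels})
    det = None
    for d in histories_base.detectors:
        if abs(d.sds_mm - config.sds_mm) < 1e-9:
            det = d.detector_id
            break
    if det is None:
        raise ValueError(f"history table has no detector at {config.sds_mm} mm")
    g1b = g1_from_histories(histories_base, optics, flow_base, tau, det)
    g1p = g1_from_histories(histories_pert, optics, flow_pert, tau, det)
    return g1b, g1p


def _flux_per_mode(config, plan, reflectance):
    sds, refl = reflectance
    cal = instr.FLUX_CALIBRATIONS[int(round(config.wavelength_nm))]
    return instr.photon_flux_per_mode(
        config.sds_mm, sds, refl, cal, plan,
        per_mode_throughput_factor=config.per_mode_throughput_factor,
    )


def evaluate_configuration(
    config: MeasurementConfig,
    histories_base: PhotonHistoryTable,
    histories_pert: PhotonHistoryTable,
    reflectance: tuple,
) -> PerformanceMetrics:
    """Run the full noise-ensemble pipeline for one configuration.

    ``reflectance`` is the (sds_mm, reflectance) curve of the simulated
    geometry (use ``McRunResult.reflectance_curve()``); the same seed and
    config give identical metrics.
    """
    if config.technique == "dcs":
        return _evaluate_dcs(config, histories_base, histories_pert, reflectance)
    return _evaluate_scos(config, histories_base, histories_pert, reflectance)


def _evaluate_dcs(config, histories_base, histories_pert, reflectance):
    tau = multitau_grid(first_bin=config.correlator_bin_s, tau_max=0.1)
    g1b, g1p = _g1_pair(config, histories_base, histories_pert, tau)

    n_modes = instr.count_guided_modes(config.fiber, config.wavelength_nm)
    beta = 1.0 / n_modes  # unpolarized fully developed speckle
    plan = instr.illumination_plan(config.strategy, config.laser)
    flux_sig = (_flux_per_mode(config, plan, reflectance) * n_modes
                * config.detector.quantum_efficiency)
    cap = instr.saturation_limit(config.detector.hold_off)
    capped = flux_sig > cap
    flux_sig = min(flux_sig, cap)
    dark = (config.detector.dark_count_rate if config.dark_count_rate is None
            else config.dark_count_rate)
    rate_total = flux_sig + dark
    # uncorrelated dark counts dilute the Siegert intercept quadratically
    beta_eff = beta * (flux_sig / rate_total) ** 2

    g2b = siegert_g2(g1b, beta_eff)
    g2p = siegert_g2(g1p, beta_eff)
    gamma = estimate_decay_rate(g2b)
    T = config.correlator_bin_s
    t_avg = plan.duty_cycle / config.sample_rate
    # evaluate the noise model with the local accumulator width of the
    # multi-tau grid: coarser bins at longer lags collect more counts
    widths = multitau_bin_widths(tau, T)
    sigma = np.empty_like(tau)
    for w in np.unique(widths):
        mask = widths == w
        params = DcsNoiseParams(w, t_avg, beta_eff, gamma, rate_total * w)
        sigma[mask] = dcs_noise_sigma(params, tau[mask])

    settings = FitSettings(optics=FIT_OPTICS[int(round(config.wavelength_nm))],
                           wavelength_nm=config.wavelength_nm, beta=beta_eff,
                           fit_fraction=config.fit_fraction)
    tau_max = fit_range_cutoff(g2b, config.fit_fraction)
    # sensitivity from the noiseless curves (stable in every flux regime);
    # the noise ensemble sets the CoV
    clean_b = fit_ensemble_g2(tau, g2b.values, settings, config.sds_mm, tau_max)
    clean_p = fit_ensemble_g2(tau, g2p.values, settings, config.sds_mm, tau_max)
    seeds = np.random.SeedSequence(config.seed).spawn(1)
    ens_b = fit_ensemble_g2(
        tau, gaussian_noise_realizations(g2b, sigma, config.n_realizations, seeds[0]),
        settings, config.sds_mm, tau_max,
    )
    return _metrics(clean_b, clean_p, ens_b, capped, rate_total, beta_eff)


def _pick_substeps(g1_curve, t_exp, max_substeps=32):
    """Enough substeps that the field decorrelation is resolved."""
    idx = min(int(np.searchsorted(-g1_curve.values, -0.5)), g1_curve.tau.size - 1)
    half = g1_curve.tau[idx]
    return int(np.clip(math.ceil(8.0 * t_exp / max(half, 1e-9)), 16, max_substeps))


def _evaluate_scos(config, histories_base, histories_pert, reflectance):
    tau = np.concatenate(([0.0], np.geomspace(1e-8, 0.2, 300)))
    g1b, g1p = _g1_pair(config, histories_base, histories_pert, tau)

    n_modes = instr.bundle_mode_count(config.fiber, config.wavelength_nm)
    # the bundle image covers modes * (s/p)^2 pixels: a larger image than
    # the sensor spills light past it (overfilling), a smaller one leaves
    # pixels dark (underfilling); either way the per-pixel signal follows
    # the image area, not the sensor area
    n_pix_image = n_modes * config.s_over_p**2
    n_pix_used = min(config.detector.n_pixels, int(n_pix_image))
    plan = instr.illumination_plan(
        config.strategy, config.laser, t_exp=config.t_exp,
        camera_max_fps=config.detector.max_frame_rate,
    )
    frames_per_sample = int(plan.effective_frame_rate / config.sample_rate)
    if frames_per_sample < 1:
        raise ValueError(
            f"exposure {config.t_exp}s leaves no full frame per "
            f"{1 / config.sample_rate}s sample"
        )
    flux_mode = _flux_per_mode(config, plan, reflectance)
    pe_total = flux_mode * n_modes * config.detector.quantum_efficiency * config.t_exp
    pe_pixel = pe_total / n_pix_image

    seeds = np.random.SeedSequence(config.seed).spawn(4)
    substeps = _pick_substeps(g1b, config.t_exp)
    # sub-pixel speckles need a fine synthesis subgrid; trade camera-pixel
    # window size against it to keep the cost bounded
    grid = 24 if config.s_over_p >= 1.0 else 16
    stack = speckle_field_sequence(
        g1b, config.s_over_p, grid_size=grid, substeps=substeps,
        seed=int(seeds[0].generate_state(1)[0] % 2**31),
        n_exposures=56, t_exp=config.t_exp, polarized=False,
    )
    stats = measured_contrast_stats(
        stack, max(pe_pixel, 1e-3), config.detector.read_noise_e,
        seed=int(seeds[1].generate_state(1)[0] % 2**31),
    )
    beta = stats.beta_est
    # per-frame sigma(K^2) rescaled from the simulated pixel window to the
    # camera (NIO scales with used pixels at fixed s/p), then to one
    # 10 Hz sample by frame averaging
    npix_sim = stack.intensities.shape[-1] * stack.intensities.shape[-2]
    sigma_k2 = (stats.sigma_k2 * math.sqrt(npix_sim / n_pix_used)
                / math.sqrt(frames_per_sample))

    kf2_b = speckle_contrast_from_g1(g1b, beta, config.t_exp)
    kf2_p = speckle_contrast_from_g1(g1p, beta, config.t_exp)
    settings = FitSettings(optics=FIT_OPTICS[int(round(config.wavelength_nm))],
                           wavelength_nm=config.wavelength_nm, beta=beta)
    clean_b = fit_ensemble_contrast(config.t_exp, np.array([kf2_b]), settings, config.sds_mm)
    clean_p = fit_ensemble_contrast(config.t_exp, np.array([kf2_p]), settings, config.sds_mm)
    rng_b = np.random.default_rng(seeds[2])
    ens_b = fit_ensemble_contrast(
        config.t_exp, kf2_b + sigma_k2 * rng_b.standard_normal(config.n_realizations),
        settings, config.sds_mm,
    )
    rate = pe_pixel * n_pix_used / config.t_exp  # photoelectrons on the sensor
    return _metrics(clean_b, clean_p, ens_b, False, rate, beta)


def _metrics(clean_b, clean_p, ens_b, capped, rate, beta):
    sens = sensitivity(clean_b.mean, clean_p.mean)
    cov = coefficient_of_variation(ens_b.bfi)
    return PerformanceMetrics(
        sensitivity=sens, cov=cov, cnr=contrast_to_noise(sens, cov),
        bfi_base_mean=ens_b.mean, bfi_base_std=ens_b.std,
        bfi_pert_mean=clean_p.mean, bfi_pert_std=0.0,
        n_failed=ens_b.n_failed,
        saturation_capped=capped, detected_rate_cps=rate, beta=beta,
    )


# -- Sweep drivers ----------------------------------------------------------

DEFAULT_SDS_GRID = (5, 10, 15, 20, 25, 30, 35, 40)
_PRESETS = ("fit_range", "strategy", "modes_sp", "thickness")


def sweep(
    preset: str,
    histories,
    reflectance=None,
    technique: str = "dcs",
    wavelength_nm: float = 850.0,
    sds_mm: Sequence[float] = DEFAULT_SDS_GRID,
    values: Sequence | None = None,
    t_exp_grid: Sequence[float] = (1e-5, 1e-4, 3e-4, 1e-3, 3e-3, 6.67e-3, 2e-2),
    n_realizations: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Run one of the four study sweeps and return a long-form table.

    ``histories`` is either a single pair ``(base, pert)`` of
    :class:`PhotonHistoryTable` (or one table used for both states, since
    flow enters only through the correlation weighting) together with a
    ``reflectance`` curve, or, for the ``thickness`` preset, a mapping
    ``{thickness_mm: ((base, pert), reflectance)}``.

    ``values`` overrides the default grid of the swept parameter
    (fit fractions, strategies, mode counts / s/p ratios, thicknesses).
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {_PRESETS}")
    if preset == "thickness":
        rows = []
        for thick, ((hb, hp), refl) in histories.items():
            if values is not None and thick not in values:
                continue
            rows.extend(_thickness_rows(
                thick, hb, hp, refl, technique, wavelength_nm, sds_mm,
                t_exp_grid, n_realizations, seed,
            ))
        return pd.DataFrame(rows)

    if isinstance(histories, PhotonHistoryTable):
        hb = hp = histories
    else:
        hb, hp = histories
    if reflectance is None:
        raise ValueError("supply the geometry's reflectance curve")

    rows = []
    if preset == "fit_range":
        grid = values if values is not None else (
            (0.1, 0.25, 0.5, 0.75, 1.0) if technique == "dcs" else t_exp_grid
        )
        for sds in sds_mm:
            for v in grid:
                cfg = _base_config(technique, wavelength_nm, sds, v,
                                   strategy="cw_single", seed=seed,
                                   n_realizations=n_realizations)
                m = evaluate_configuration(cfg, hb, hp, reflectance)
                rows.append(_row(cfg, "fit_fraction" if technique == "dcs" else "t_exp", v, m))
    elif preset == "strategy":
        strategies = values if values is not None else (
            ("cw_single", "cw_multi", "pulsed_frame_limited") if technique == "dcs"
            else ("cw_single", "cw_multi", "pulsed_power_limited", "pulsed_frame_limited")
        )
        for sds in sds_mm:
            for strat in strategies:
                if technique == "dcs":
                    cfg = _base_config(technique, wavelength_nm, sds, 1.0,
                                       strategy=strat, seed=seed,
                                       n_realizations=n_realizations)
                    m = evaluate_configuration(cfg, hb, hp, reflectance)
                    rows.append(_row(cfg, "strategy", strat, m))
                else:
                    for t_exp in t_exp_grid:
                        cfg = _base_config(technique, wavelength_nm, sds, t_exp,
                                           strategy=strat, seed=seed,
                                           n_realizations=n_realizations)
                        m = evaluate_configuration(cfg, hb, hp, reflectance)
                        rows.append(_row(cfg, "strategy", strat, m, t_exp=t_exp))
    elif preset == "modes_sp":
        if technique == "dcs":
            fibers = values if values is not None else (
                ("single_mode_780hp", 0.0), ("single_mode_780hp", 1500.0),
                ("few_mode_smf28", 0.0), ("few_mode_smf28", 1500.0),
            )
            for sds in sds_mm:
                for fiber_name, dark in fibers:
                    cfg = MeasurementConfig.dcs_preset(
                        wavelength_nm, sds, fiber=instr.FIBER_PRESETS[fiber_name],
                        strategy="cw_single", dark_count_rate=dark, seed=seed,
                        n_realizations=n_realizations,
                    )
                    m = evaluate_configuration(cfg, hb, hp, reflectance)
                    rows.append(_row(cfg, "fiber", f"{fiber_name}/dark={dark:g}", m))
        else:
            sp_grid = values if values is not None else (2.0, 1.0, 0.41)
            for sds in sds_mm:
                for sp in sp_grid:
                    best = None
                    for t_exp in t_exp_grid:
                        cfg = _base_config(technique, wavelength_nm, sds, t_exp,
                                           strategy="pulsed_frame_limited",
                                           s_over_p=sp, seed=seed,
                                           n_realizations=n_realizations)
                        m = evaluate_configuration(cfg, hb, hp, reflectance)
                        if best is None or m.cnr > best[1].cnr:
                            best = (cfg, m, t_exp)
                    rows.append(_row(best[0], "s_over_p", sp, best[1], t_exp=best[2]))
    return pd.DataFrame(rows)


def _thickness_rows(thick, hb, hp, refl, technique, wavelength_nm, sds_mm,
                    t_exp_grid, n_realizations, seed):
    rows = []
    for sds in sds_mm:
        if technique == "dcs":
            best = None
            for strat in ("cw_single", "pulsed_frame_limited"):
                cfg = _base_config(technique, wavelength_nm, sds, 1.0,
                                   strategy=strat, seed=seed,
                                   n_realizations=n_realizations)
                m = evaluate_configuration(cfg, hb, hp, refl)
                if best is None or m.cnr > best[1].cnr:
                    best = (cfg, m)
            rows.append(_row(best[0], "thickness_mm", thick, best[1]))
        else:
            best = None
            for t_exp in t_exp_grid:
                cfg = _base_config(technique, wavelength_nm, sds, t_exp,
                                   strategy="pulsed_frame_limited", s_over_p=0.41,
                                   seed=seed, n_realizations=n_realizations)
                m = evaluate_configuration(cfg, hb, hp, refl)
                if best is None or m.cnr > best[1].cnr:
                    best = (cfg, m, t_exp)
            rows.append(_row(best[0], "thickness_mm", thick, best[1], t_exp=best[2]))
    return rows


def _base_config(technique, wavelength_nm, sds, value, strategy,
                 s_over_p=1.0, seed=0, n_realizations=100):
    if technique == "dcs":
        return MeasurementConfig.dcs_preset(
            wavelength_nm, sds, fit_fraction=value, strategy=strategy,
            seed=seed, n_realizations=n_realizations,
        )
    return MeasurementConfig.scos_preset(
        sds, value, strategy=strategy, s_over_p=s_over_p, seed=seed,
        n_realizations=n_realizations,
    )


def _row(cfg, param, value, metrics, **extra):
    row = {
        "technique": cfg.technique, "wavelength_nm": cfg.wavelength_nm,
        "sds_mm": cfg.sds_mm, "param": param, "value": value,
    }
    row.update(extra)
    row.update(metrics.as_row())
    return row
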