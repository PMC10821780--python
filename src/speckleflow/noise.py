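"""Measurement-noise models for DCS and SCOS.

Four ingredients:

* the analytic standard deviation of a photon-counting intensity
  autocorrelation estimate (single-exponential-decay correlation noise
  model), used to perturb noiseless g2 curves;
* a dynamic speckle simulator: circular-Gaussian complex fields with a
  Fourier-aperture speckle size and a prescribed temporal field
  correlation, integrated over camera exposures with shot and read
  noise, from which the squared-contrast budget, its per-frame noise
  sigma(K^2), the coherence parameter beta(s/p) and the effective number
  of independent observations (NIO) are estimated empirically;
* a photon timestamp generator (doubly stochastic Poisson process driven
  by simulated speckle intensity, plus dark counts and detector
  hold-off), and
* a multi-tau software correlator turning timestamp series back into g2,
  which closes the loop for validating the analytic noise model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .forward import CorrelationCurve

__all__ = [
    "DcsNoiseParams",
    "TimestampSeries",
    "SpeckleFrameStack",
    "ContrastStats",
    "dcs_noise_sigma",
    "gaussian_noise_realizations",
    "shot_read_dark_contrast",
    "speckle_field_sequence",
    "measured_contrast_stats",
    "photon_timestamps",
    "multitau_autocorrelation",
]


@dataclass(frozen=True)
class DcsNoiseParams:
    """Inputs of the correlation noise model.

    bin_width_T: correlator bin width (s); averaging_time_t: total
    integration per correlogram (s); gamma: effective intensity-decay
    rate of g2 modeled as 1 + beta exp(-Gamma tau) (1/s);
    counts_per_bin_n: mean detected counts per bin T.
    """

    bin_width_T: float
    averaging_time_t: float
    beta: float
    gamma: float
    counts_per_bin_n: float

    def __post_init__(self) -> None:
        if self.bin_width_T <= 0:
            raise ValueError("bin width T must be positive")
        if self.averaging_time_t < self.bin_width_T:
            raise ValueError("averaging time must be >= bin width")
        if self.gamma <= 0:
            raise ValueError("Gamma must be positive (flat curves have no defined decay)")
        if self.counts_per_bin_n <= 0:
            raise ValueError("counts per bin must be positive")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must be in (0, 1]")


def dcs_noise_sigma(params: DcsNoiseParams, tau: np.ndarray) -> np.ndarray:
    """Standard deviation sigma(tau) of a photon-counting g2 estimate.

    sigma(tau) = sqrt(T/t) * [ beta^2 ((1+e^{-2 G T})(1+e^{-2 G tau})
                    + 2 (tau/T)(1-e^{-2 G T}) e^{-2 G tau}) / (1-e^{-2 G T})
                  + 2 <n>^-1 beta (1+e^{-2 G tau})
                  + <n>^-2 (1 + beta e^{-G tau}) ]^{1/2}

    The first bracket term is the speckle (beta) contribution independent
    of count rate; the <n>^-1 and <n>-2 terms are shot-noise
    contributions that dominate in the photon-starved regime.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be non-negative")
    T, t = params.bin_width_T, params.averaging_time_t
    beta, gamma, n = params.beta, params.gamma, params.counts_per_bin_n
    e2gt = math.exp(-2.0 * gamma * T)
    if 1.0 - e2gt == 0.0:
        raise ZeroDivisionError("Gamma*T too small: 1 - exp(-2 Gamma T) underflows")
    e2gtau = np.exp(-2.0 * gamma * tau)
    egtau = np.exp(-gamma * tau)
    bracket = (
        beta**2 * ((1.0 + e2gt) * (1.0 + e2gtau)
                   + 2.0 * (tau / T) * (1.0 - e2gt) * e2gtau) / (1.0 - e2gt)
        + 2.0 / n * beta * (1.0 + e2gtau)
        + 1.0 / n**2 * (1.0 + beta * egtau)
    )
    return math.sqrt(T / t) * np.sqrt(bracket)


def gaussian_noise_realizations(
    curve: CorrelationCurve, sigma: np.ndarray, n_real: int, seed: int
) -> np.ndarray:
    """``n_real`` independent Gaussian perturbations of a correlation
    curve, one row per realization; amplitude ``sigma`` per delay.

    Child random streams are spawned deterministically per realization
    index so ensembles are reproducible and extensible.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != curve.tau.shape:
        raise ValueError("sigma grid does not match the curve's delay grid")
    if n_real < 1:
        raise ValueError("n_real must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out = np.empty((n_real, curve.tau.size))
    for i, child in enumerate(ss.spawn(n_real)):
        rng = np.random.default_rng(child)
        out[i] = curve.values + sigma * rng.standard_normal(curve.tau.size)
    return out


def shot_read_dark_contrast(
    mean_pe: float, read_noise_e: float = 0.0, dark_e: float = 0.0
) -> tuple[float, float, float]:
    """Shot, read and dark squared-contrast terms for a mean pixel signal
    of ``mean_pe`` photoelectrons: Ks^2 = 1/<S>, Kr^2 = sigma_r^2/<S>^2,
    Kd^2 = S_dark/<S>^2 (dark defaults to zero: short-exposure regime)."""
    if mean_pe <= 0:
        raise ValueError("mean photoelectron count must be positive")
    return 1.0 / mean_pe, read_noise_e**2 / mean_pe**2, dark_e / mean_pe**2


# -- Dynamic speckle simulator ---------------------------------------------


@dataclass
class SpeckleFrameStack:
    """Sub-exposure intensity frames from the dynamic speckle model.

    ``intensities`` has shape (n_exposures, substeps, ny, nx) on the
    camera-pixel grid, normalized to unit mean; exposures are mutually
    independent blocks whose substeps carry the target field correlation.
    """

    intensities: np.ndarray
    dt: float
    s_over_p: float
    polarized: bool
    seed: int

    def __post_init__(self) -> None:
        if self.intensities.ndim != 4:
            raise ValueError("expected (n_exposures, substeps, ny, nx) intensities")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_exposures(self) -> int:
        return self.intensities.shape[0]

    @property
    def substeps_per_exposure(self) -> int:
        return self.intensities.shape[1]

    @property
    def t_exp(self) -> float:
        return self.dt * self.substeps_per_exposure


def _g1_callable(g1_target):
    """Normalize the accepted g1 specifications to a vectorized callable."""
    if g1_target is None:
        return lambda tau: np.ones_like(np.asarray(tau, dtype=float))
    if isinstance(g1_target, CorrelationCurve):
        f = g1_target.interpolator()
        return lambda tau: np.asarray(f(tau), dtype=float)
    if np.isscalar(g1_target):
        gamma_f = float(g1_target)
        return lambda tau: np.exp(-gamma_f * np.asarray(tau, dtype=float))
    if callable(g1_target):
        return g1_target
    raise TypeError("g1_target must be None, a decay rate, a CorrelationCurve or a callable")


def _temporal_mixing(g1_fun, substeps: int, dt: float) -> np.ndarray:
    """Cholesky factor of the substep field covariance C_ij = g1(|i-j| dt).

    A tiny diagonal jitter guards against indefiniteness from
    interpolated targets.
    """
    lags = np.abs(np.subtract.outer(np.arange(substeps), np.arange(substeps))) * dt
    cov = g1_fun(lags)
    cov = cov + 1e-10 * np.eye(substeps)
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        # project onto the PSD cone (eigenvalue clipping)
        w, v = np.linalg.eigh(cov)
        w = np.clip(w, 1e-12, None)
        return v * np.sqrt(w)


def speckle_field_sequence(
    g1_target,
    s_over_p: float,
    grid_size: int = 32,
    substeps: int = 16,
    seed: int = 0,
    n_exposures: int = 64,
    t_exp: float | None = None,
    dt: float | None = None,
    polarized: bool = False,
) -> SpeckleFrameStack:
    """Simulate dynamic, fully developed speckle on a camera-pixel grid.

    Each spatial field is a circular-Gaussian random field whose spatial
    bandwidth is set by a circular Fourier aperture such that the minimum
    speckle size equals ``s_over_p`` camera pixels; for ``s_over_p < 2``
    the field is synthesized on a finer subgrid and the intensity binned
    into camera pixels, so sub-pixel speckles are represented without
    aliasing.  The temporal field correlation across the ``substeps`` of
    one exposure follows ``g1_target`` exactly (Gaussian-process mixing
    of substep fields); separate exposures are independent.

    ``g1_target`` may be None (static), a scalar field decay rate
    (exponential g1), a :class:`~speckleflow.forward.CorrelationCurve`,
    or a callable.  Provide either ``t_exp`` (then ``dt = t_exp /
    substeps``) or ``dt`` directly; a static target needs neither.

    Unpolarized light (default) sums two independent polarization
    channels, halving the contrast (beta ~ 1/2 at large s/p).
    """
    if s_over_p <= 0:
        raise ValueError("s_over_p must be positive")
    if substeps < 1 or n_exposures < 1:
        raise ValueError("substeps and n_exposures must be >= 1")
    if dt is None:
        if t_exp is not None:
            dt = t_exp / substeps
        elif g1_target is None:
            dt = 1.0
        else:
            raise ValueError("provide t_exp or dt for a dynamic target")
    g1_fun = _g1_callable(g1_target)
    if g1_target is not None and substeps > 1:
        # resolution guard: substeps must sample the decorrelation
        g_step = float(np.atleast_1d(g1_fun(np.array([dt])))[0])
        if g_step < 0.2 and float(np.atleast_1d(g1_fun(np.array([dt * substeps])))[0]) < 0.9:
            import warnings

            warnings.warn(
                f"substep spacing {dt:.3g}s is coarse: field correlation drops "
                f"to {g_step:.2f} within one substep", stacklevel=2,
            )

    # Gaussian spatial field correlation mu(d) = exp(-d^2 / (2 sigma_x^2));
    # the speckle size is the 1/e^2 diameter of the intensity correlation
    # |mu|^2, i.e. s = 2 sqrt(2) sigma_x (this convention reproduces the
    # reference calibration NIO ~ 0.95 n_pixels at s/p = 0.4).
    sigma_x = s_over_p / (2.0 * math.sqrt(2.0))  # camera pixels
    # synthesize on a subgrid fine enough that the Gaussian spectral
    # envelope vanishes at the subgrid Nyquist frequency
    m = max(1, math.ceil(1.2 / sigma_x))
    n_sub = grid_size * m
    fx = np.fft.fftfreq(n_sub)
    env2 = np.exp(-2.0 * math.pi**2 * (sigma_x * m) ** 2
                  * (fx[:, None] ** 2 + fx[None, :] ** 2))
    amp_full = np.sqrt(env2).ravel()
    mode_idx = np.flatnonzero(amp_full > 1e-6)
    amp = amp_full[mode_idx]
    n_modes = mode_idx.size
    if n_modes < 2:
        raise ValueError("grid too small for the requested speckle size")

    Lmix = _temporal_mixing(g1_fun, substeps, dt)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_pol = 1 if polarized else 2

    out = np.empty((n_exposures, substeps, grid_size, grid_size))
    spec = np.zeros((substeps, n_sub * n_sub), dtype=np.complex128)
    for e in range(n_exposures):
        acc = np.zeros((substeps, grid_size, grid_size))
        for _ in range(n_pol):
            w = (rng.standard_normal((substeps, n_modes))
                 + 1j * rng.standard_normal((substeps, n_modes)))
            spec[:, mode_idx] = (Lmix @ w) * amp  # correlated in time
            field = np.fft.ifft2(spec.reshape(substeps, n_sub, n_sub), axes=(1, 2))
            inten = np.abs(field) ** 2
            acc += inten.reshape(substeps, grid_size, m, grid_size, m).sum(axis=(2, 4))
        out[e] = acc
    out /= out.mean()
    return SpeckleFrameStack(out, dt=dt, s_over_p=s_over_p, polarized=polarized, seed=seed)


@dataclass(frozen=True)
class ContrastStats:
    """Empirical squared-contrast statistics from the speckle simulator."""

    kf2_mean: float
    ks2: float
    kr2: float
    sigma_k2: float
    beta_est: float
    nio_est: float
    n_exposures: int

    @property
    def k2_total(self) -> float:
        return self.kf2_mean + self.ks2 + self.kr2


def _k2(frames: np.ndarray) -> np.ndarray:
    """Per-frame squared spatial contrast var/mean^2 over pixels."""
    flat = frames.reshape(frames.shape[0], -1)
    mu = flat.mean(axis=1)
    return flat.var(axis=1, ddof=1) / mu**2


def measured_contrast_stats(
    stack: SpeckleFrameStack,
    photon_scale: float,
    read_noise_e: float = 0.0,
    seed: int = 0,
    min_exposures: int = 50,
) -> ContrastStats:
    """Exposure-integrated contrast budget and its per-frame noise.

    Integrates each exposure's substeps, applies Poisson shot noise at
    ``photon_scale`` photoelectrons per pixel per exposure and Gaussian
    read noise, and measures per-frame K^2 over the pixel window.  The
    shot and read terms are subtracted (assumed perfectly corrected), so
    ``sigma_k2`` is the standard deviation of the corrected fundamental
    contrast across frames.  ``beta_est`` is the zero-exposure contrast
    (first substep of each exposure) and ``nio_est`` the effective number
    of independent observations 2 <Kf^2>^2 / var(Kf^2) of the *noiseless*
    per-frame contrast.
    """
    if photon_scale <= 0:
        raise ValueError("photon_scale must be positive")
    if stack.n_exposures < min_exposures:
        raise ValueError(
            f"need >= {min_exposures} exposures for stable noise statistics, "
            f"got {stack.n_exposures}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    integrated = stack.intensities.mean(axis=1)            # (n_exp, ny, nx)
    kf2_clean = _k2(integrated)
    beta_frames = _k2(stack.intensities[:, 0])

    expected = integrated * photon_scale
    counts = rng.poisson(expected).astype(float)
    if read_noise_e > 0:
        counts += read_noise_e * rng.standard_normal(counts.shape)
    k2_meas = _k2(counts)
    ks2, kr2, _ = shot_read_dark_contrast(photon_scale, read_noise_e)
    kf2_corrected = k2_meas - ks2 - kr2

    var_clean = kf2_clean.var(ddof=1)
    nio = 2.0 * kf2_clean.mean() ** 2 / var_clean if var_clean > 0 else math.inf
    return ContrastStats(
        kf2_mean=float(kf2_corrected.mean()),
        ks2=ks2,
        kr2=kr2,
        sigma_k2=float(kf2_corrected.std(ddof=1)),
        beta_est=float(beta_frames.mean()),
        nio_est=float(nio),
        n_exposures=stack.n_exposures,
    )


# -- Photon timestamps and the multi-tau correlator -------------------------


@dataclass(frozen=True)
class TimestampSeries:
    """Detected photon event times (s) on [0, duration)."""

    event_times: np.ndarray
    duration: float
    applied_hold_off: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        object.__setattr__(self, "event_times", t)
        if t.size and (t[0] < 0 or t[-1] >= self.duration):
            raise ValueError("event times must lie in [0, duration)")
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ValueError("event times must be sorted")

    @property
    def n_events(self) -> int:
        return int(self.event_times.size)

    @property
    def rate(self) -> float:
        return self.n_events / self.duration


@njit(cache=True)
def _dead_time_filter(times: np.ndarray, hold_off: float) -> np.ndarray:
    keep = np.empty(times.size, dtype=np.bool_)
    last = -1e300
    for i in range(times.size):
        if times[i] - last >= hold_off:
            keep[i] = True
            last = times[i]
        else:
            keep[i] = False
    return keep


def _correlated_intensity(gamma_field: float, n_steps: int, dt: float,
                          n_modes: int, rng) -> np.ndarray:
    """Normalized speckle intensity series: sum of ``n_modes`` independent
    squared complex Ornstein-Uhlenbeck channels with field correlation
    exp(-gamma_field tau), synthesized spectrally (circulant embedding)."""
    n_fft = 1
    while n_fft < 2 * n_steps:
        n_fft *= 2
    # circulant embedding of c(tau) = exp(-gamma_f |tau|); eigenvalues are
    # the DFT of the covariance row (clip tiny numerical negatives)
    lag = np.minimum(np.arange(n_fft), n_fft - np.arange(n_fft)) * dt
    eig = np.fft.fft(np.exp(-gamma_field * lag)).real
    amp = np.sqrt(np.clip(eig, 0.0, None) / n_fft)
    intensity = np.zeros(n_steps)
    for _ in range(n_modes):
        w = (rng.standard_normal(n_fft) + 1j * rng.standard_normal(n_fft)) / math.sqrt(2.0)
        e_field = np.fft.fft(amp * w)[:n_steps]
        intensity += np.abs(e_field) ** 2  # E[|E|^2] = c(0) = 1 per mode
    return intensity / n_modes


def photon_timestamps(
    mean_rate: float,
    g1_target=None,
    beta: float = 0.5,
    dark_rate: float = 0.0,
    hold_off: float = 0.0,
    duration: float = 1.0,
    seed: int = 0,
    dt: float | None = None,
) -> TimestampSeries:
    """Realistic photon-detection timestamps.

    Signal photons form a doubly stochastic Poisson process whose
    intensity is a simulated speckle signal: the sum of ``round(1/beta)``
    independent speckle channels (squared complex Gaussian processes)
    whose field correlation follows ``g1_target`` (None for constant
    intensity, or a scalar field decay rate for exponential g1).  Dark
    counts are an independent homogeneous Poisson process, and events
    closer than ``hold_off`` to the previously accepted event are
    discarded (non-paralyzable dead time).
    """
    if mean_rate < 0 or dark_rate < 0:
        raise ValueError("rates must be >= 0")
    if hold_off < 0:
        raise ValueError("hold_off must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    if g1_target is None or mean_rate == 0:
        n_sig = rng.poisson(mean_rate * duration)
        sig_times = rng.uniform(0.0, duration, n_sig)
    else:
        if not np.isscalar(g1_target):
            raise TypeError("photon_timestamps supports None or an exponential "
                            "field decay rate as g1_target")
        gamma_f = float(g1_target)
        if duration * gamma_f < 10:
            raise ValueError("duration must span many field decorrelation times")
        n_modes = max(1, round(1.0 / beta))
        if dt is None:
            dt = 1.0 / (gamma_f * 64.0)
        n_steps = int(math.ceil(duration / dt))
        intensity = _correlated_intensity(gamma_f, n_steps, dt, n_modes, rng)
        counts = rng.poisson(intensity * mean_rate * dt)
        starts = np.repeat(np.arange(n_steps) * dt, counts)
        sig_times = starts + rng.uniform(0.0, dt, starts.size)
        sig_times = sig_times[sig_times < duration]

    n_dark = rng.poisson(dark_rate * duration)
    times = np.concatenate([sig_times, rng.uniform(0.0, duration, n_dark)])
    times.sort()
    if hold_off > 0 and times.size:
        times = times[_dead_time_filter(times, hold_off)]
    return TimestampSeries(times, duration=duration, applied_hold_off=hold_off)


def multitau_autocorrelation(
    series: TimestampSeries,
    bins_per_octave: int = 8,
    first_bin: float = 1e-6,
    min_events: int = 100,
    tau_max: float | None = None,
) -> tuple[CorrelationCurve, float]:
    """Multi-tau intensity autocorrelation of a timestamp series.

    Bins events at ``first_bin`` width, correlates the first
    ``2 * bins_per_octave`` lags, then repeatedly coarsens the bins by a
    factor of two correlating ``bins_per_octave`` lags per octave, using
    the symmetric normalization (left/right mean rates per lag).

    Returns the g2 curve and the mean counts per first bin <n> (the
    quantity the analytic noise model needs).
    """
    if series.n_events < min_events:
        raise ValueError(f"need >= {min_events} events, got {series.n_events}")
    n_bins = int(series.duration / first_bin)
    if n_bins < 4 * bins_per_octave:
        raise ValueError("duration too short for the requested correlator scheme")
    counts = np.bincount(
        np.minimum((series.event_times / first_bin).astype(np.int64), n_bins - 1),
        minlength=n_bins,
    ).astype(float)
    mean_n = counts.mean()

    taus: list[float] = []
    g2s: list[float] = []
    width = first_bin
    level = counts
    lags = range(1, 2 * bins_per_octave + 1)
    while True:
        n = level.size
        for k in lags:
            if (tau_max is not None and k * width > tau_max) or n - k < 2:
                continue
            left = level[: n - k]
            right = level[k:]
            ml, mr = left.mean(), right.mean()
            if ml > 0 and mr > 0:
                taus.append(k * width)
                g2s.append(float(left @ right) / (n - k) / (ml * mr))
        if level.size < 4 * bins_per_octave or (
            tau_max is not None and width * bins_per_octave > tau_max
        ):
            break
        if level.size % 2:
            level = level[:-1]
        level = level[0::2] + level[1::2]
        width *= 2.0
        lags = range(bins_per_octave + 1, 2 * bins_per_octave + 1)

    order = np.argsort(taus)
    curve = CorrelationCurve(
        tau=np.asarray(taus)[order], values=np.asarray(g2s)[order], kind="intensity_g2"
    )
    return curve, float(mean_n)
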