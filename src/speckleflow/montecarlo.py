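"""Layered-slab dynamic-light-scattering Monte Carlo.

Generates photon-history tables (per-detected-photon partial pathlengths
and momentum transfer per tissue layer) and diffuse reflectance for
planar scalp/skull/CSF/brain geometries, standing in for full
mesh-based head-model transport at desk scale.

Transport uses the similarity relation: isotropic scattering at the
reduced scattering coefficient mu_s'.  Absorption is never applied
during transport; it is recorded analytically downstream through the
partial pathlengths (``exp(-sum_i mu_a,i L_i)``), which lets a single
run serve any absorption values.  Under isotropic scattering the
expected momentum transfer per scattering event, E[1 - cos(theta)], is
exactly 1, so the per-layer momentum transfer ``Y`` is accumulated as
the per-layer scattering-event count (a zero-variance substitution of
the per-event expectation).

Detectors exploit the cylindrical symmetry of the slab: each detector is
an annulus of half-width ``radius_mm`` centered on its source-detector
separation, with an exit-angle acceptance set by its numerical aperture
measured in the exit medium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .forward import OpticalProperties
from .histories import DetectorSpec, PhotonHistoryTable

__all__ = [
    "SlabGeometry",
    "McRunResult",
    "run_layered_mc",
    "parametric_histories",
    "slab_preset",
    "TABLE1_OPTICS",
    "TABLE1_FLOW_BASELINE",
    "TABLE1_FLOW_PERTURBED",
]

# Optical and flow properties of the four head-tissue categories used for
# all preset simulations (per wavelength in nm).
TABLE1_OPTICS: dict[int, dict[str, OpticalProperties]] = {
    850: {
        "scalp": OpticalProperties(0.164, 7.4),
        "skull": OpticalProperties(0.155, 8.1),
        "csf": OpticalProperties(0.017, 0.1),
        "brain": OpticalProperties(0.170, 11.6),
    },
    1064: {
        "scalp": OpticalProperties(0.11, 5.3),
        "skull": OpticalProperties(0.13, 5.8),
        "csf": OpticalProperties(0.122, 0.07),
        "brain": OpticalProperties(0.17, 8.3),
    },
}

TABLE1_FLOW_BASELINE = {"scalp": 1e-8, "skull": 1e-10, "csf": 1e-10, "brain": 6e-8}
TABLE1_FLOW_PERTURBED = {"scalp": 1e-8, "skull": 1e-10, "csf": 1e-10, "brain": 7.2e-8}


@dataclass(frozen=True)
class SlabGeometry:
    """Planar layered medium: ordered (label, thickness_mm) with the last
    layer semi-infinite (thickness ``None``), plus surface detectors."""

    layers: tuple
    detectors: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        object.__setattr__(self, "detectors", tuple(self.detectors))
        if not self.layers:
            raise ValueError("need at least one layer")
        for label, thick in self.layers[:-1]:
            if thick is None or thick <= 0:
                raise ValueError(f"finite layer {label!r} needs thickness > 0")
        if self.layers[-1][1] is not None:
            raise ValueError("last layer must be semi-infinite (thickness None)")
        for d in self.detectors:
            if d.sds_mm <= 0:
                raise ValueError("detector SDS must be positive")

    @property
    def tissue_labels(self) -> tuple:
        return tuple(label for label, _ in self.layers)


def slab_preset(
    extracerebral_mm: float = 15.0,
    sds_mm: Sequence[float] = (5, 10, 15, 20, 25, 30, 35, 40),
    detector_radius_mm: float = 0.5,
    detector_na: float = 1.0,
) -> SlabGeometry:
    """Four-layer head slab with the requested scalp-to-brain distance.

    Scalp is fixed at 5 mm and CSF at 2 mm; the skull layer absorbs the
    remainder so scalp+skull+CSF equals ``extracerebral_mm`` exactly.
    """
    skull = extracerebral_mm - 7.0
    if skull <= 0:
        raise ValueError("extracerebral thickness must exceed 7 mm")
    detectors = tuple(
        DetectorSpec(i, float(s), detector_radius_mm, detector_na)
        for i, s in enumerate(sds_mm)
    )
    return SlabGeometry(
        layers=(("scalp", 5.0), ("skull", skull), ("csf", 2.0), ("brain", None)),
        detectors=detectors,
    )


@dataclass
class McRunResult:
    """Output of one transport run.

    ``reflectance`` is the detected fraction per launched photon per cm^2
    of detector area (angularly filtered by each detector's NA), indexed
    like ``geometry.detectors``; ``fractions`` holds the photon-fate
    bookkeeping (escaped_top, transmitted_deep, lateral_escape,
    terminated_events) as fractions of launched photons.
    """

    histories: PhotonHistoryTable
    reflectance: np.ndarray
    fractions: dict
    seed: int
    n_launched: int

    def reflectance_curve(self):
        """(sds_mm, reflectance per cm^2) arrays sorted by separation."""
        sds = np.array([d.sds_mm for d in self.histories.detectors])
        order = np.argsort(sds)
        return sds[order], self.reflectance[order]


@njit(cache=True)
def _transport_kernel(  # pragma: no cover - exercised via run_layered_mc
    n_photons, seed, z_edges, musp, det_rlo, det_rhi, det_sinmax,
    z_kill, r_max, max_events,
    out_det, out_L, out_Y,
):
    np.random.seed(seed)
    n_layers = musp.size
    n_det = det_rlo.size
    cap = out_det.shape[0]
    n_rec = 0
    n_escaped = 0
    n_deep = 0
    n_lateral = 0
    n_events_kill = 0

    L = np.zeros(n_layers)
    Yc = np.zeros(n_layers)

    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        for i in range(n_layers):
            L[i] = 0.0
            Yc[i] = 0.0
        events = 0
        layer = 0
        fate = -1  # 0 escape, 1 deep, 2 lateral, 3 events

        while fate < 0:
            u = -math.log(np.random.random())  # optical depth to next scatter
            # traverse layers until the sampled optical depth is spent
            while True:
                # distance to the layer boundary along the current direction
                if uz > 0.0:
                    d_bound = (z_edges[layer] - z) / uz
                elif uz < 0.0:
                    z_lo = 0.0 if layer == 0 else z_edges[layer - 1]
                    d_bound = (z - z_lo) / (-uz)
                else:
                    d_bound = 1.0e30
                s_scat = u / musp[layer]
                if s_scat <= d_bound:
                    # scatter inside the current layer
                    x += ux * s_scat
                    y += uy * s_scat
                    z += uz * s_scat
                    L[layer] += s_scat
                    Yc[layer] += 1.0
                    events += 1
                    # new isotropic direction
                    uz = 2.0 * np.random.random() - 1.0
                    phi = 2.0 * math.pi * np.random.random()
                    sq = math.sqrt(max(0.0, 1.0 - uz * uz))
                    ux = sq * math.cos(phi)
                    uy = sq * math.sin(phi)
                    break
                # move to the boundary and continue in the adjacent layer
                x += ux * d_bound
                y += uy * d_bound
                z += uz * d_bound
                L[layer] += d_bound
                u -= d_bound * musp[layer]
                if uz > 0.0:
                    layer += 1
                    z = z_edges[layer - 1]
                else:
                    if layer == 0:
                        fate = 0  # escaped through the top surface
                        break
                    layer -= 1
                    z = z_edges[layer]
                if z >= z_kill:
                    fate = 1
                    break
            if fate >= 0:
                break
            if z >= z_kill:
                fate = 1
            elif x * x + y * y >= r_max * r_max:
                fate = 2
            elif events >= max_events:
                fate = 3

        if fate == 0:
            n_escaped += 1
            r = math.sqrt(x * x + y * y)
            sin_exit = math.sqrt(ux * ux + uy * uy)
            for d in range(n_det):
                if det_rlo[d] <= r <= det_rhi[d] and sin_exit <= det_sinmax[d]:
                    if n_rec < cap:
                        out_det[n_rec] = d
                        for i in range(n_layers):
                            out_L[n_rec, i] = L[i]
                            out_Y[n_rec, i] = Yc[i]
                        n_rec += 1
                    break
        elif fate == 1:
            n_deep += 1
        elif fate == 2:
            n_lateral += 1
        else:
            n_events_kill += 1

    return n_rec, n_escaped, n_deep, n_lateral, n_events_kill


def run_layered_mc(
    geometry: SlabGeometry,
    optics_by_tissue: Mapping[str, OpticalProperties],
    n_photons: int,
    seed: int,
    wavelength_nm: float = 850.0,
    z_kill_cm: float = 15.0,
    r_max_cm: float = 20.0,
    max_events: int = 1_000_000,
    chunk: int = 500_000,
) -> McRunResult:
    """Run the layered-slab Monte Carlo and return histories + reflectance.

    Photons are launched as a pencil beam at the origin; reproducible for
    a given ``seed`` (chunk seeds are spawned deterministically).
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    labels = geometry.tissue_labels
    missing = [t for t in labels if t not in optics_by_tissue]
    if missing:
        raise KeyError(f"missing optical properties for layers: {missing}")

    musp = np.array([optics_by_tissue[t].mu_s_prime for t in labels])
    z_edges = np.empty(len(labels))
    acc = 0.0
    for i, (_, thick) in enumerate(geometry.layers):
        acc += (thick or 0.0) * 0.1  # mm -> cm
        z_edges[i] = acc
    z_edges[-1] = 1e30  # semi-infinite

    det_rlo = np.array([(d.sds_mm - d.radius_mm) * 0.1 for d in geometry.detectors])
    det_rhi = np.array([(d.sds_mm + d.radius_mm) * 0.1 for d in geometry.detectors])
    n_exit = optics_by_tissue[labels[0]].refractive_index
    det_sinmax = np.array([min(1.0, d.na / n_exit) for d in geometry.detectors])

    rng_seeds = np.random.SeedSequence(seed).generate_state(
        max(1, math.ceil(n_photons / chunk))
    ) % (2**31)

    det_parts, L_parts, Y_parts = [], [], []
    counts = np.zeros(4, dtype=np.int64)
    remaining = n_photons
    for cseed in rng_seeds:
        n_this = min(chunk, remaining)
        out_det = np.empty(n_this, dtype=np.int64)
        out_L = np.empty((n_this, len(labels)))
        out_Y = np.empty((n_this, len(labels)))
        n_rec, n_esc, n_deep, n_lat, n_ev = _transport_kernel(
            n_this, int(cseed), z_edges, musp, det_rlo, det_rhi, det_sinmax,
            z_kill_cm, r_max_cm, max_events, out_det, out_L, out_Y,
        )
        det_parts.append(out_det[:n_rec].copy())
        L_parts.append(out_L[:n_rec].copy())
        Y_parts.append(out_Y[:n_rec].copy())
        counts += np.array([n_esc, n_deep, n_lat, n_ev])
        remaining -= n_this
        if remaining <= 0:
            break

    det_id = np.concatenate(det_parts)
    histories = PhotonHistoryTable(
        n_launched=n_photons,
        tissue_labels=labels,
        wavelength_nm=wavelength_nm,
        detectors=geometry.detectors,
        detector_id=det_id,
        L=np.concatenate(L_parts),
        Y=np.concatenate(Y_parts),
        source=f"layered_mc seed={seed} n_photons={n_photons}",
    )
    areas = np.pi * (det_rhi**2 - det_rlo**2)  # cm^2
    # absorption enters analytically: each detected photon carries
    # weight exp(-sum_i mu_a,i L_i)
    mua = np.array([optics_by_tissue[t].mu_a for t in labels])
    weights = np.exp(-histories.L @ mua)
    det_weight = np.bincount(det_id, weights=weights,
                             minlength=len(geometry.detectors))
    reflectance = det_weight / n_photons / areas
    fractions = {
        "escaped_top": counts[0] / n_photons,
        "transmitted_deep": counts[1] / n_photons,
        "lateral_escape": counts[2] / n_photons,
        "terminated_events": counts[3] / n_photons,
    }
    return McRunResult(
        histories=histories, reflectance=reflectance, fractions=fractions,
        seed=seed, n_launched=n_photons,
    )


def parametric_histories(
    spec: Mapping[str, Mapping[str, tuple]],
    n_rows: int,
    seed: int,
    wavelength_nm: float = 850.0,
    sds_mm: float = 25.0,
) -> PhotonHistoryTable:
    """Fast synthetic-parametric history generator for tests and fixtures.

    ``spec`` maps tissue label -> {"L": dist, "Y": dist} where dist is one
    of ``("constant", c)``, ``("exponential", mean)``,
    ``("gamma", shape, scale)`` or, for Y only, ``("scaled_L", factor)``
    (momentum transfer proportional to the sampled pathlength, as for a
    homogeneous scatterer where Y ~ L * mu_s').  Rows are i.i.d.
    """
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    rng = np.random.default_rng(seed)
    labels = tuple(spec.keys())

    def draw(dist: tuple, base: np.ndarray | None) -> np.ndarray:
        kind = dist[0]
        if kind == "constant":
            return np.full(n_rows, float(dist[1]))
        if kind == "exponential":
            return rng.exponential(float(dist[1]), n_rows)
        if kind == "gamma":
            return rng.gamma(float(dist[1]), float(dist[2]), n_rows)
        if kind == "scaled_L":
            if base is None:
                raise ValueError("scaled_L is only valid for Y")
            return base * float(dist[1])
        raise ValueError(f"unknown distribution {kind!r}")

    L = np.empty((n_rows, len(labels)))
    Y = np.empty((n_rows, len(labels)))
    for j, t in enumerate(labels):
        L[:, j] = draw(spec[t]["L"], None)
        Y[:, j] = draw(spec[t]["Y"], L[:, j])
    return PhotonHistoryTable(
        n_launched=n_rows,
        tissue_labels=labels,
        wavelength_nm=wavelength_nm,
        detectors=(DetectorSpec(0, sds_mm),),
        detector_id=np.zeros(n_rows, dtype=np.int64),
        L=L,
        Y=Y,
        source=f"synthetic-parametric seed={seed}",
    )
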