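"""Synthetic phase spaces and water-phantom dose data.

This module generates inputs with the statistical structure the analysis
stages assume, so the whole pipeline is testable without vendor-restricted
phase-space files or measured beam data.  It is a parametric sampling model,
not a transport simulation: no bremsstrahlung, pair production or electron
transport is performed, and none of the spectral or angular shapes are
physics claims — they are configuration.

The photon model emulates a flattened linac beam: a point-like bremsstrahlung
source with a circular Gaussian focal spot, photons tallied on a plane
~26 cm below the target, a bounded bremsstrahlung-like energy spectrum whose
mean softens with off-axis radius, and an optional extra Gaussian angular
scatter on top of the point-source direction.

The dose model is an analytic water-phantom surrogate: depth dose with
buildup + exponential attenuation, lateral profiles with error-function
penumbrae and divergence-projected field edges, an output-factor table, and
optional per-voxel Gaussian noise mimicking Monte Carlo statistical
uncertainty.

All generators are pure functions of (configuration, size, seed); the random
stream is a counter-based Philox generator seeded per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import erf

from .grids import DoseGrid, ProfilePoints
from .phasespace import DECODED_DTYPE, PHOTON, PhaseSpace, PhaseSpaceHeader

__all__ = [
    "SourceConfig",
    "PhotonBeamModel",
    "DoseModel",
    "BEAM_PRESETS",
    "beam_preset",
    "sample_primary_electrons",
    "generate_phasespace",
    "analytic_pdd",
    "analytic_profile",
    "depth_of_maximum",
    "generate_dose_grid",
    "generate_rbd_like_dataset",
]


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(seed))


@dataclass(frozen=True)
class SourceConfig:
    """Initial electron beam hitting the bremsstrahlung target.

    E0: mean kinetic energy (MeV); sigma_E: Gaussian energy spread (MeV);
    sigma_R: std of the circular Gaussian focal spot (cm); epsilon: Gaussian
    divergence (mrad), applied per transverse axis.
    """

    E0: float
    sigma_E: float = 0.0
    sigma_R: float = 0.0
    epsilon: float = 0.0

    def __post_init__(self):
        if self.E0 <= 0:
            raise ValueError("E0 must be > 0")
        if min(self.sigma_E, self.sigma_R, self.epsilon) < 0:
            raise ValueError("spreads must be non-negative")


@dataclass(frozen=True)
class PhotonBeamModel:
    """Parametric photon source tallied on a plane below the target.

    The spectrum is f(E) ∝ (E_max − E)·E^a·exp(−b·E) on (E_cut, E_max).
    offaxis_softening is the fractional mean-energy reduction per cm of
    radius on the tally plane.  plane_radius bounds the illuminated disc;
    plane positions are sampled uniformly over it (flat planar fluence).
    lowE_* optionally inject extra low-energy fluence near the CAX, used to
    emulate a beam whose head differs from the reference design.
    """

    source: SourceConfig
    z_plane: float = 26.70
    E_max: float = 6.0
    E_cut: float = 0.05
    spectrum_a: float = 1.0
    spectrum_b: float = 0.5
    offaxis_softening: float = 0.005
    angular_spread_extra: float = 0.0  # mrad
    yield_per_history: float = 0.5
    plane_radius: float = 10.0
    lowE_excess_frac: float = 0.0
    lowE_band: Tuple[float, float] = (0.10, 0.75)
    lowE_radius: float = 1.0

    def __post_init__(self):
        if not (0 < self.E_cut < self.E_max):
            raise ValueError("need 0 < E_cut < E_max")
        if self.yield_per_history <= 0:
            raise ValueError("yield_per_history must be > 0")

    def spectrum_pdf(self, e: np.ndarray) -> np.ndarray:
        """Unnormalized spectral density on (E_cut, E_max), zero outside."""
        e = np.asarray(e, dtype=float)
        f = (self.E_max - e) * e**self.spectrum_a * np.exp(-self.spectrum_b * e)
        return np.where((e > self.E_cut) & (e < self.E_max), np.maximum(f, 0.0), 0.0)

    def spectrum_mean_energy(self, n_grid: int = 4001) -> float:
        e = np.linspace(self.E_cut, self.E_max, n_grid)
        f = self.spectrum_pdf(e)
        return float(np.trapezoid(e * f, e) / np.trapezoid(f, e))


# Initial-electron presets for the four flattened nominal energies studied:
# (E0 MeV, sigma_E MeV, sigma_R cm).  The divergence is left at 0 mrad: its
# value could not be established unambiguously from the available
# documentation and the analyses here do not depend on it.
BEAM_PRESETS: Dict[str, SourceConfig] = {
    "6MV": SourceConfig(E0=6.18, sigma_E=0.053, sigma_R=0.072),
    "8MV": SourceConfig(E0=8.74, sigma_E=0.074, sigma_R=0.089),
    "10MV": SourceConfig(E0=10.7, sigma_E=0.091, sigma_R=0.085),
    "15MV": SourceConfig(E0=13.5, sigma_E=0.115, sigma_R=0.061),
}


def beam_preset(name: str) -> PhotonBeamModel:
    """Photon beam model for a named preset.

    ``"15MV-discrepant"`` is the 15 MV preset with 40% extra fluence in the
    0.10–0.75 MeV band within 1 cm of the CAX, reproducing qualitatively a
    surrogate head whose target/flattening-filter differs from the
    reference design.
    """
    discrepant = name == "15MV-discrepant"
    key = "15MV" if discrepant else name
    if key not in BEAM_PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: "
            + ", ".join(sorted(BEAM_PRESETS) + ["15MV-discrepant"])
        )
    src = BEAM_PRESETS[key]
    return PhotonBeamModel(
        source=src,
        E_max=src.E0,
        lowE_excess_frac=0.40 if discrepant else 0.0,
    )


def sample_primary_electrons(cfg: SourceConfig, n: int, seed: int) -> np.ndarray:
    """Sample n initial electrons at the target.

    Returns a structured array with fields x, y (cm, circular Gaussian focal
    spot), u, v, w (direction cosines; Gaussian tilt of epsilon mrad per
    transverse axis) and E (MeV, Gaussian truncated at E > 0).
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = _rng(seed)
    out = np.empty(n, dtype=[("x", float), ("y", float), ("u", float),
                             ("v", float), ("w", float), ("E", float)])
    out["x"] = rng.normal(0.0, cfg.sigma_R, n) if cfg.sigma_R > 0 else 0.0
    out["y"] = rng.normal(0.0, cfg.sigma_R, n) if cfg.sigma_R > 0 else 0.0
    e = rng.normal(cfg.E0, cfg.sigma_E, n) if cfg.sigma_E > 0 else np.full(n, cfg.E0)
    while (bad := e <= 0).any():  # truncation at E > 0 by resampling
        e[bad] = rng.normal(cfg.E0, cfg.sigma_E, int(bad.sum()))
    out["E"] = e
    if cfg.epsilon > 0:
        tilt = cfg.epsilon * 1e-3
        u = rng.normal(0.0, tilt, n)
        v = rng.normal(0.0, tilt, n)
        norm = np.sqrt(1.0 + u * u + v * v)  # small-angle tangent tilts
        out["u"] = u / norm
        out["v"] = v / norm
        out["w"] = 1.0 / norm
    else:
        out["u"] = 0.0
        out["v"] = 0.0
        out["w"] = 1.0
    return out


def _sample_spectrum(model: PhotonBeamModel, n: int, rng: np.random.Generator,
                     band: Optional[Tuple[float, float]] = None) -> np.ndarray:
    """Inverse-CDF sampling from the tabulated spectral density."""
    lo, hi = band if band is not None else (model.E_cut, model.E_max)
    e = np.linspace(lo, hi, 4001)
    f = model.spectrum_pdf(e)
    cdf = np.concatenate([[0.0], np.cumsum((f[1:] + f[:-1]) * 0.5 * np.diff(e))])
    if cdf[-1] <= 0:
        raise ValueError("spectrum has zero mass on the requested band")
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, e)


def generate_phasespace(model: PhotonBeamModel, n_histories: int, seed: int) -> PhaseSpace:
    """Generate a photon phase space on the tally plane.

    Per primary history, Poisson(yield_per_history) photons reach the plane.
    Each photon originates at its history's focal-spot position, crosses the
    plane at a position drawn uniformly on the illuminated disc, and carries
    an energy drawn from the configured spectrum with its mean reduced by
    offaxis_softening per cm of plane radius.  The first photon of every
    contributing history carries the new-history flag.
    """
    if n_histories <= 0:
        raise ValueError("n_histories must be > 0")
    rng = _rng(seed)
    counts = rng.poisson(model.yield_per_history, n_histories)
    m = int(counts.sum())
    src = model.source

    # focal-spot origin, shared by all photons of one history
    if src.sigma_R > 0:
        x0h = rng.normal(0.0, src.sigma_R, n_histories)
        y0h = rng.normal(0.0, src.sigma_R, n_histories)
        x0 = np.repeat(x0h, counts)
        y0 = np.repeat(y0h, counts)
    else:
        x0 = np.zeros(m)
        y0 = np.zeros(m)

    # plane position: uniform over the illuminated disc
    r = model.plane_radius * np.sqrt(rng.random(m))
    phi = rng.uniform(0.0, 2.0 * np.pi, m)
    x = r * np.cos(phi)
    y = r * np.sin(phi)

    # direction from focal spot to plane point
    dz = model.z_plane
    norm = np.sqrt((x - x0) ** 2 + (y - y0) ** 2 + dz * dz)
    u = (x - x0) / norm
    v = (y - y0) / norm
    if model.angular_spread_extra > 0:
        sa = model.angular_spread_extra * 1e-3
        u = u + rng.normal(0.0, sa, m)
        v = v + rng.normal(0.0, sa, m)
        s = u * u + v * v
        over = s >= 1.0
        if over.any():  # keep directions forward-going
            scale = np.sqrt(0.999999 / s[over])
            u[over] *= scale
            v[over] *= scale

    energy = _sample_spectrum(model, m, rng)
    if model.offaxis_softening > 0:
        energy = energy * np.maximum(1.0 - model.offaxis_softening * r, 0.05)
    energy = np.maximum(energy, 1e-4)

    new_history = np.zeros(m, dtype=bool)
    first = np.concatenate([[0], np.cumsum(counts)[:-1]])[counts > 0]
    new_history[first] = True

    rec = np.empty(m, dtype=DECODED_DTYPE)
    rec["kind"] = PHOTON
    rec["energy"] = energy
    rec["x"] = x
    rec["y"] = y
    rec["u"] = u
    rec["v"] = v
    rec["w"] = np.sqrt(np.maximum(0.0, 1.0 - u * u - v * v))
    rec["weight"] = 1.0
    rec["new_history"] = new_history

    if model.lowE_excess_frac > 0:
        rec = np.concatenate([rec, _lowE_extras(model, rec, rng)])

    header = PhaseSpaceHeader(
        z_plane=model.z_plane,
        n_original_histories=n_histories,
        n_records=len(rec),
    )
    return PhaseSpace(header=header, records=rec)


def _lowE_extras(model: PhotonBeamModel, rec: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Extra low-energy photons near the CAX for the discrepant preset."""
    lo, hi = model.lowE_band
    r = np.hypot(rec["x"], rec["y"])
    in_band = (rec["energy"] >= lo) & (rec["energy"] < hi) & (r < model.lowE_radius)
    n_extra = int(rng.poisson(model.lowE_excess_frac * int(in_band.sum())))
    if n_extra == 0:
        return np.empty(0, dtype=DECODED_DTYPE)
    extra = np.empty(n_extra, dtype=DECODED_DTYPE)
    re_ = model.lowE_radius * np.sqrt(rng.random(n_extra))
    phi = rng.uniform(0.0, 2 * np.pi, n_extra)
    extra["kind"] = PHOTON
    extra["energy"] = _sample_spectrum(model, n_extra, rng, band=(lo, hi))
    extra["x"] = re_ * np.cos(phi)
    extra["y"] = re_ * np.sin(phi)
    nrm = np.sqrt(re_**2 + model.z_plane**2)
    extra["u"] = extra["x"] / nrm
    extra["v"] = extra["y"] / nrm
    extra["w"] = model.z_plane / nrm
    extra["weight"] = 1.0
    extra["new_history"] = False
    return extra


@dataclass(frozen=True)
class DoseModel:
    """Analytic water-phantom dose surrogate for a square flattened field.

    Depth dose: D100·OF(field)·(1 − exp(−buildup_mu·z))·exp(−atten_mu·z).
    Lateral profile: sum of error functions with penumbra_sigma at the
    divergence-projected field edges, times an optional quadratic off-axis
    horn.  Defaults approximate a 6 MV flattened beam (dose maximum near
    1.8 cm, ~4%/cm distal falloff, ~5 mm penumbra 80–20%).
    """

    D100: float = 1.0
    buildup_mu: float = 2.2  # cm^-1
    atten_mu: float = 0.045  # cm^-1
    penumbra_sigma: float = 0.3  # cm
    horn_coeff: float = 0.0  # cm^-2
    field_side: float = 10.0  # cm at SSD
    ssd: float = 100.0  # cm
    of_table: Dict[float, float] = field(default_factory=lambda: {
        2.0: 0.92, 3.0: 0.94, 6.0: 0.97, 10.0: 1.00,
        15.0: 1.02, 20.0: 1.04, 30.0: 1.055, 40.0: 1.06,
    })

    def output_factor(self) -> float:
        """Relative output for this field side (linear interp over of_table)."""
        sides = np.array(sorted(self.of_table))
        vals = np.array([self.of_table[s] for s in sides])
        return float(np.interp(self.field_side, sides, vals))


def depth_of_maximum(model: DoseModel) -> float:
    """Closed-form depth of the dose maximum, ln(1 + b/a)/b with b=buildup_mu."""
    b, a = model.buildup_mu, model.atten_mu
    if a == 0:
        return math.inf
    return math.log(1.0 + b / a) / b


def analytic_pdd(model: DoseModel, z) -> np.ndarray:
    """Central-axis depth dose at depth z (cm); zero at the surface."""
    z = np.asarray(z, dtype=float)
    if (z < 0).any():
        raise ValueError("depth must be >= 0")
    amp = model.D100 * model.output_factor()
    return amp * (1.0 - np.exp(-model.buildup_mu * z)) * np.exp(-model.atten_mu * z)


def analytic_profile(model: DoseModel, x, z) -> np.ndarray:
    """Relative lateral profile at off-axis distance x (cm) and depth z (cm).

    The geometric field edge at depth is the field side projected by the
    source divergence, (ssd + z)/ssd.  Symmetric in x by construction.
    """
    x = np.asarray(x, dtype=float)
    half = 0.5 * model.field_side * (model.ssd + np.asarray(z, dtype=float)) / model.ssd
    s = math.sqrt(2.0) * model.penumbra_sigma
    p = 0.5 * (erf((half - x) / s) + erf((half + x) / s))
    return p * (1.0 + model.horn_coeff * x * x)


def _analytic_grid_dose(model: DoseModel, xc, yc, zc) -> np.ndarray:
    """Separable product dose on the grid: pdd(z)·profile(x,z)·profile(y,z)."""
    z = zc[np.newaxis, np.newaxis, :]
    px = analytic_profile(model, xc[:, np.newaxis, np.newaxis], z)
    py = analytic_profile(model, yc[np.newaxis, :, np.newaxis], z)
    pz = analytic_pdd(model, zc)[np.newaxis, np.newaxis, :]
    return px * py * pz


def generate_dose_grid(
    model: DoseModel,
    origin: Tuple[float, float, float],
    voxel: Tuple[float, float, float],
    dims: Tuple[int, int, int],
    seed: int = 0,
    target_mean_rel_unc: float = 0.0,
) -> DoseGrid:
    """Voxelize the analytic dose model, optionally adding statistical noise.

    The noise model is independent per-voxel Gaussian with sigma_i = k·√D_i,
    k calibrated in closed form so the mean relative uncertainty over voxels
    with dose above half the maximum equals target_mean_rel_unc.  The stored
    rel_unc raster carries the calibrated per-voxel relative sigma.
    """
    if any(n <= 0 for n in dims):
        raise ValueError("voxel counts must be positive")
    xc = origin[0] + voxel[0] * np.arange(dims[0])
    yc = origin[1] + voxel[1] * np.arange(dims[1])
    zc = origin[2] + voxel[2] * np.arange(dims[2])
    dose = _analytic_grid_dose(model, xc, yc, zc)
    if target_mean_rel_unc <= 0:
        return DoseGrid(origin=origin, voxel=voxel, dose=dose,
                        rel_unc=np.zeros_like(dose))
    mask = dose > 0.5 * dose.max()
    # rel unc of voxel i is k/sqrt(D_i); solve the half-max mean exactly
    k = target_mean_rel_unc / float(np.mean(1.0 / np.sqrt(dose[mask])))
    pos = dose > 0
    rel_unc = np.zeros_like(dose)
    rel_unc[pos] = k / np.sqrt(dose[pos])
    rng = _rng(seed)
    noisy = dose + rng.normal(0.0, 1.0, dose.shape) * k * np.sqrt(dose)
    np.maximum(noisy, 0.0, out=noisy)
    return DoseGrid(origin=origin, voxel=voxel, dose=noisy, rel_unc=rel_unc)


def field_grid_spec(
    model: DoseModel,
    margin: float = 4.0,
    dx: float = 0.15,
    dy: float = 0.5,
    dz: float = 0.15,
    z_max: float = 35.0,
) -> Tuple[Tuple[float, float, float], Tuple[float, float, float], Tuple[int, int, int]]:
    """(origin, voxel, dims) of a phantom grid covering the field.

    0.15 cm pitch along x and depth (the scan directions), 0.5 cm along y;
    lateral extent reaches ``margin`` cm beyond the projected field edge at
    z_max, and the CAX is a column of voxel centers.
    """
    half = 0.5 * model.field_side * (model.ssd + z_max) / model.ssd + margin
    nx = 2 * int(math.ceil(half / dx)) + 1
    ny = 2 * int(math.ceil(half / dy)) + 1
    nz = int(math.ceil(z_max / dz)) + 1
    origin = (-dx * (nx // 2), -dy * (ny // 2), 0.0)
    return origin, (dx, dy, dz), (nx, ny, nz)


_DEFAULT_FIELDS = (3.0, 6.0, 10.0, 20.0, 30.0)


def _depth_positions(z_max: float = 35.0) -> np.ndarray:
    fine = np.arange(0.0, 5.0, 0.1)
    coarse = np.arange(5.0, z_max + 1e-9, 0.5)
    return np.concatenate([fine, coarse])


def _crossline_positions(model: DoseModel, depth: float, margin: float = 3.0) -> np.ndarray:
    """Measurement-like spacing: 0.2 cm near the penumbra, 0.5 cm elsewhere."""
    half = 0.5 * model.field_side * (model.ssd + depth) / model.ssd
    limit = half + margin
    pos = set(np.round(np.arange(0.0, limit + 1e-9, 0.5), 6))
    band = np.arange(max(half - 1.5, 0.0), min(half + 1.5, limit) + 1e-9, 0.2)
    pos.update(np.round(band, 6))
    right = np.array(sorted(pos))
    return np.concatenate([-right[:0:-1], right])


def generate_rbd_like_dataset(
    models: Dict[float, DoseModel],
    depths: Sequence[float] = (5.0,),
    z_max: float = 35.0,
) -> List[ProfilePoints]:
    """Noiseless measurement-like scans from the analytic models.

    For each field: one depth-dose scan (0.1 cm steps through buildup, then
    0.5 cm) normalized to its maximum, and one crossline scan per requested
    depth normalized to the CAX value, both sampled directly from the
    analytic model.
    """
    out: List[ProfilePoints] = []
    for field_cm, model in models.items():
        zs = _depth_positions(z_max)
        pdd = analytic_pdd(model, zs) * analytic_profile(model, 0.0, zs) ** 2
        out.append(ProfilePoints(
            axis="depth", positions=zs, doses=100.0 * pdd / pdd.max(),
            field_cm=field_cm, normalization="max",
        ))
        for depth in depths:
            xs = _crossline_positions(model, depth)
            prof = (analytic_profile(model, xs, depth)
                    * analytic_profile(model, 0.0, depth))
            cax = analytic_profile(model, 0.0, depth) ** 2
            out.append(ProfilePoints(
                axis="crossline", positions=xs,
                doses=100.0 * prof / cax,
                field_cm=field_cm, depth_cm=depth, normalization="cax",
            ))
    return out
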