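"""Phase-space characterization statistics.

Energy spectra in concentric rings about the central axis (CAX), angular
distributions per unit solid angle in a circular region, radial planar
energy fluence, and the percentage-of-agreement (PA) score

    PA = 100 · [1 − δ / max(A_a, A_b)],

where A_a, A_b are the areas under the two binned distributions and δ is the
integrated absolute difference Σ|f_a − f_b|·Δbin.  δ is read as an area so
that it is commensurable with the denominator; PA is clamped to [0, 100].

Conventions
-----------
* Spectra are fluence-weighted (Σ weight per energy bin); the radial
  distribution is energy-fluence-weighted (Σ E·weight).  Planar quantities
  count plane crossings and do not divide by |w|.
* Everything is normalized per original history using the header count; two
  phase spaces with different history counts are each normalized by their
  own N before comparison.
* Binning is half-open [lo, hi) with the final bin closed.
* Spectra and angular distributions include photons only by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .phasespace import PHOTON, PhaseSpace

__all__ = [
    "Histogram1D",
    "RegionSpec",
    "PAResult",
    "DEFAULT_E_BIN_WIDTH",
    "DEFAULT_THETA_BIN_WIDTH",
    "ring_energy_spectrum",
    "angular_distribution",
    "radial_energy_fluence",
    "percentage_agreement",
    "pa_matrix",
    "default_regions",
    "histogram_to_frame",
]

DEFAULT_E_BIN_WIDTH = 0.05  # MeV
DEFAULT_THETA_BIN_WIDTH = 0.5  # degrees


@dataclass
class Histogram1D:
    """A binned distribution with per-bin statistical uncertainties.

    values are per original history; norm_tag records the weighting:
    'per_history_fluence' (Σw/N), 'per_history_energy_fluence'
    (Σ E·w / N / ring area) or 'per_solid_angle' (Σw / N / ΔΩ).
    overflow_weight collects content that fell outside the binned range
    (e.g. backward-travelling particles) — reported, never silently dropped.
    """

    edges: np.ndarray
    values: np.ndarray
    unc: np.ndarray
    norm_tag: str
    overflow_weight: float = 0.0

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.unc = np.asarray(self.unc, dtype=float)
        if len(self.values) != len(self.edges) - 1:
            raise ValueError("need len(values) == len(edges) - 1")
        if (np.diff(self.edges) <= 0).any():
            raise ValueError("edges must be strictly increasing")

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def area(self) -> float:
        """Σ value·binwidth, the area entering the PA score."""
        return float(np.sum(self.values * self.widths))

    def same_binning(self, other: "Histogram1D") -> bool:
        return (len(self.edges) == len(other.edges)
                and np.allclose(self.edges, other.edges)
                and self.norm_tag == other.norm_tag)


@dataclass(frozen=True)
class RegionSpec:
    """A ring or circle about the CAX on the tally plane, radii in cm."""

    shape: str  # 'ring' or 'circle'
    r_lo: float
    r_hi: float

    def __post_init__(self):
        if self.shape not in ("ring", "circle"):
            raise ValueError("shape must be 'ring' or 'circle'")
        if not (0 <= self.r_lo < self.r_hi):
            raise ValueError("need 0 <= r_lo < r_hi")

    @property
    def label(self) -> str:
        return f"[{self.r_lo:g}-{self.r_hi:g}]"

    @property
    def area(self) -> float:
        return float(np.pi * (self.r_hi**2 - self.r_lo**2))


@dataclass(frozen=True)
class PAResult:
    """Percentage of agreement between two equally binned distributions."""

    pa: float
    delta: float
    area_a: float
    area_b: float


def _select(ps: PhaseSpace, region: Optional[RegionSpec],
            kinds: Optional[Iterable[int]]) -> np.ndarray:
    rec = ps.records
    mask = np.ones(len(rec), dtype=bool)
    if kinds is not None:
        mask &= np.isin(rec["kind"], list(kinds))
    if region is not None:
        r = np.hypot(rec["x"], rec["y"])
        mask &= (r >= region.r_lo) & (r < region.r_hi)
    return rec[mask]


def _n_hist(ps: PhaseSpace) -> int:
    n = ps.header.n_original_histories
    if n <= 0:
        raise ValueError("header declares no original histories; cannot normalize")
    return n


def _binned(values: np.ndarray, weights: np.ndarray, edges: np.ndarray):
    """Half-open [lo, hi) binning with the final bin closed; returns (Σw, Σw²)."""
    edges = np.asarray(edges, dtype=float)
    idx = np.searchsorted(edges, values, side="right") - 1
    last = values == edges[-1]
    idx[last] = len(edges) - 2
    ok = (idx >= 0) & (idx < len(edges) - 1) & ((values < edges[-1]) | last)
    sw = np.bincount(idx[ok], weights=weights[ok], minlength=len(edges) - 1)
    sw2 = np.bincount(idx[ok], weights=weights[ok] ** 2, minlength=len(edges) - 1)
    return sw, sw2


def ring_energy_spectrum(
    ps: PhaseSpace,
    region: RegionSpec,
    e_edges: Sequence[float],
    kinds: Iterable[int] = (PHOTON,),
) -> Histogram1D:
    """Fluence-weighted energy spectrum of particles in a ring, per history.

    Bin value = Σ weight / N_histories for records with radius in
    [r_lo, r_hi) and energy in the bin; uncertainty √(Σw²)/N.
    """
    e_edges = np.asarray(e_edges, dtype=float)
    if (np.diff(e_edges) <= 0).any():
        raise ValueError("e_edges must be strictly increasing")
    n = _n_hist(ps)
    rec = _select(ps, region, kinds)
    sw, sw2 = _binned(rec["energy"], rec["weight"], e_edges)
    return Histogram1D(edges=e_edges, values=sw / n, unc=np.sqrt(sw2) / n,
                       norm_tag="per_history_fluence")


def angular_distribution(
    ps: PhaseSpace,
    region: RegionSpec,
    theta_edges: Optional[Sequence[float]] = None,
    kinds: Iterable[int] = (PHOTON,),
) -> Histogram1D:
    """Angular distribution per unit solid angle in a circular region.

    θ = arccos(w) in degrees; bin value = Σ weight / (N · ΔΩ) with
    ΔΩ = 2π(cos θ_lo − cos θ_hi).  Backward-travelling records (w ≤ 0) are
    accumulated into overflow_weight (per history), never silently dropped.
    """
    if theta_edges is None:
        theta_edges = np.arange(0.0, 90.0 + 1e-9, DEFAULT_THETA_BIN_WIDTH)
    theta_edges = np.asarray(theta_edges, dtype=float)
    if theta_edges.min() < 0 or theta_edges.max() > 90.0:
        raise ValueError("theta_edges must lie within [0, 90] degrees")
    n = _n_hist(ps)
    rec = _select(ps, region, kinds)
    backward = rec["w"] <= 0
    overflow = float(rec["weight"][backward].sum()) / n
    rec = rec[~backward]
    theta = np.degrees(np.arccos(np.clip(rec["w"], -1.0, 1.0)))
    sw, sw2 = _binned(theta, rec["weight"], theta_edges)
    rad = np.radians(theta_edges)
    domega = 2.0 * np.pi * (np.cos(rad[:-1]) - np.cos(rad[1:]))
    return Histogram1D(edges=theta_edges, values=sw / (n * domega),
                       unc=np.sqrt(sw2) / (n * domega),
                       norm_tag="per_solid_angle", overflow_weight=overflow)


def radial_energy_fluence(
    ps: PhaseSpace,
    r_max: float = 5.0,
    dr: float = 0.2,
    kinds: Iterable[int] = (PHOTON,),
) -> Histogram1D:
    """Radial planar energy fluence, MeV·cm⁻² per history.

    Ring [r, r+dr) value = Σ(E·weight) / (N · π(r_hi² − r_lo²)); crossings
    are counted without dividing by |w| (planar convention).
    """
    if r_max <= 0 or dr <= 0:
        raise ValueError("r_max and dr must be positive")
    edges = np.arange(0.0, r_max + dr * 0.5, dr)
    n = _n_hist(ps)
    rec = _select(ps, None, kinds)
    r = np.hypot(rec["x"], rec["y"])
    ew = rec["energy"] * rec["weight"]
    # exclude the closed top edge: the outermost ring is [r_max-dr, r_max)
    inside = r < edges[-1]
    sw, sw2 = _binned(r[inside], ew[inside], edges)
    ring_area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    return Histogram1D(edges=edges, values=sw / (n * ring_area),
                       unc=np.sqrt(sw2) / (n * ring_area),
                       norm_tag="per_history_energy_fluence")


def percentage_agreement(h_a: Histogram1D, h_b: Histogram1D) -> PAResult:
    """PA = 100·[1 − δ/max(A_a, A_b)] with δ = Σ|a − b|·Δbin, clamped to ≥ 0.

    Identical histograms score 100; a non-zero histogram against zero scores
    0.  When both areas are zero PA is defined as 100.  Histograms must share
    edges and normalization; no silent resampling is performed.
    """
    if not h_a.same_binning(h_b):
        raise ValueError("histograms must share edges and norm_tag")
    widths = h_a.widths
    area_a = float(np.sum(h_a.values * widths))
    area_b = float(np.sum(h_b.values * widths))
    delta = float(np.sum(np.abs(h_a.values - h_b.values) * widths))
    denom = max(area_a, area_b)
    if denom == 0:
        pa = 100.0
    else:
        pa = 100.0 * (1.0 - delta / denom)
    return PAResult(pa=max(0.0, pa), delta=delta, area_a=area_a, area_b=area_b)


def default_regions() -> Tuple[RegionSpec, ...]:
    """Seven 1-cm rings [0–1]…[6–7] plus the 6-cm circle [0–6]."""
    rings = tuple(RegionSpec("ring", float(i), float(i + 1)) for i in range(7))
    return rings + (RegionSpec("circle", 0.0, 6.0),)


def pa_matrix(
    ps_a: PhaseSpace,
    ps_b: PhaseSpace,
    regions: Optional[Sequence[RegionSpec]] = None,
    e_edges: Optional[Sequence[float]] = None,
    kinds: Iterable[int] = (PHOTON,),
) -> pd.DataFrame:
    """PA of the ring energy spectra of two phase spaces, one column per region.

    Default regions are the seven 1-cm rings plus the 0–6 cm circle; default
    energy bins are 50 keV wide up to the larger maximum record energy.
    Returns a single-row DataFrame with columns pa_<region>, plus matching
    delta_<region> rows of metadata in ``attrs``.
    """
    if regions is None:
        regions = default_regions()
    if e_edges is None:
        e_top = 0.0
        for ps in (ps_a, ps_b):
            if len(ps.records):
                e_top = max(e_top, float(ps.records["energy"].max()))
        e_top = max(e_top, DEFAULT_E_BIN_WIDTH)
        n_bins = int(np.ceil(e_top / DEFAULT_E_BIN_WIDTH))
        e_edges = DEFAULT_E_BIN_WIDTH * np.arange(n_bins + 1)
    row = {}
    details: Dict[str, PAResult] = {}
    for region in regions:
        h_a = ring_energy_spectrum(ps_a, region, e_edges, kinds)
        h_b = ring_energy_spectrum(ps_b, region, e_edges, kinds)
        res = percentage_agreement(h_a, h_b)
        row[region.label] = res.pa
        details[region.label] = res
    df = pd.DataFrame([row])
    df.attrs["pa_results"] = details
    return df


def histogram_to_frame(h: Histogram1D, **meta) -> pd.DataFrame:
    """Flatten a histogram to a bin_lo/bin_hi/value/unc table for CSV export."""
    df = pd.DataFrame({
        "bin_lo": h.edges[:-1],
        "bin_hi": h.edges[1:],
        "value": h.values,
        "unc": h.unc,
    })
    df.attrs.update(norm_tag=h.norm_tag, overflow_weight=h.overflow_weight, **meta)
    return df
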