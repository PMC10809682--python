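"""Dose-distribution comparison against reference scans.

Profiles are pulled out of 3D dose grids by trilinear interpolation at the
reference (measurement-like) points, normalized by the field's convention —
depth-dose curves to their maximum, lateral profiles to the central-axis
value — and compared point by point with the gamma index

    γ(r) = min over eval positions p near r of
           sqrt( ‖p − r‖²/DTA² + (D_eval(p) − D_ref(r))²/ΔD² ),

with ΔD = dose_pct/100 · norm_value (global normalization by default; the
standard commissioning criteria are 2%, 2 mm).  A point passes when γ ≤ 1;
the gamma pass rate (GPR) is the percentage of passing points.  Output
factors are central-axis dose ratios at 10 cm depth relative to a reference
field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .grids import DoseGrid, ProfilePoints

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "OutputFactorTable",
    "OutOfBoundsError",
    "interpolate_trilinear",
    "extract_depth_dose",
    "extract_crossline",
    "gamma_points",
    "gamma_brute_force",
    "aggregate_gpr",
    "output_factors",
    "mean_relative_uncertainty",
]


class OutOfBoundsError(ValueError):
    """A query point lies outside the convex hull of voxel centers."""


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma-analysis acceptance criteria and search discretization.

    dose_pct: dose-difference criterion as a percentage of the normalization
    dose (global gamma) or of the local reference dose (local=True).
    dta_mm: distance-to-agreement in mm.  The search window spans
    search_radius_factor·DTA around each reference point, sub-sampled at
    step_fraction·DTA.  threshold_pct optionally drops reference points
    below that percentage of norm_value from the pass-rate (off by default).
    """

    dose_pct: float = 2.0
    dta_mm: float = 2.0
    search_radius_factor: float = 3.0
    step_fraction: float = 0.1
    local: bool = False
    threshold_pct: Optional[float] = None

    def __post_init__(self):
        if self.dose_pct <= 0 or self.dta_mm <= 0:
            raise ValueError("dose_pct and dta_mm must be positive")
        if self.step_fraction > 0.2 or self.step_fraction <= 0:
            raise ValueError("step_fraction must be in (0, 0.2]")

    @property
    def dta_cm(self) -> float:
        return self.dta_mm / 10.0


@dataclass
class GammaResult:
    """Per-reference-point gamma values and pass-rate summary.

    gammas holds one value per reference point, NaN where the point was
    excluded (search window leaving the evaluation domain, or below the
    optional dose threshold).  gpr is over the n_points evaluated points.
    """

    gammas: np.ndarray
    gpr: float
    n_points: int
    n_excluded: int = 0

    @classmethod
    def from_gammas(cls, gammas: np.ndarray, n_excluded: int = 0) -> "GammaResult":
        gammas = np.asarray(gammas, dtype=float)
        ok = ~np.isnan(gammas)
        n = int(ok.sum())
        gpr = 100.0 * float(np.sum(gammas[ok] <= 1.0)) / n if n else float("nan")
        return cls(gammas=gammas, gpr=gpr, n_points=n, n_excluded=n_excluded)


@dataclass
class OutputFactorTable:
    """Relative output versus field size at fixed depth on the CAX."""

    field_sides: np.ndarray
    of_values: np.ndarray
    unc: np.ndarray
    reference_field: float
    depth_cm: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "field_cm": self.field_sides,
            "output_factor": self.of_values,
            "rel_unc": self.unc,
        })


def _interpolator(grid: DoseGrid, values: Optional[np.ndarray] = None):
    axes = tuple(grid.axis_centers(i) for i in range(3))
    vals = grid.dose if values is None else values
    return RegularGridInterpolator(axes, vals, method="linear",
                                   bounds_error=True, fill_value=None)


def interpolate_trilinear(grid: DoseGrid, points) -> np.ndarray:
    """Trilinear interpolation of grid dose at (x, y, z) points (cm).

    Exact at voxel centers and for any dose field affine in (x, y, z).
    Points outside the hull of voxel centers raise OutOfBoundsError listing
    the offenders; no extrapolation is performed.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    lo = np.array(grid.origin)
    hi = lo + np.array(grid.voxel) * (np.array(grid.dims) - 1)
    bad = ((pts < lo - 1e-12) | (pts > hi + 1e-12)).any(axis=1)
    if bad.any():
        offenders = pts[bad][:5].tolist()
        raise OutOfBoundsError(
            f"{int(bad.sum())} point(s) outside the grid, e.g. {offenders}"
        )
    interp = _interpolator(grid)
    return interp(np.clip(pts, lo, hi))


def _line_points(axis: str, positions: np.ndarray, depth: Optional[float]) -> np.ndarray:
    """Map scan coordinates to 3D phantom points."""
    positions = np.asarray(positions, dtype=float)
    pts = np.zeros((len(positions), 3))
    if axis == "depth":
        pts[:, 2] = positions
    elif axis == "crossline":
        if depth is None:
            raise ValueError("crossline scans need a depth")
        pts[:, 0] = positions
        pts[:, 2] = depth
    elif axis == "inline":
        if depth is None:
            raise ValueError("inline scans need a depth")
        pts[:, 1] = positions
        pts[:, 2] = depth
    else:
        raise ValueError(f"unknown scan axis {axis!r}")
    return pts


def extract_depth_dose(grid: DoseGrid, positions: Sequence[float],
                       field_cm: float = float("nan")) -> ProfilePoints:
    """Central-axis depth dose, normalized so the curve maximum is 100."""
    positions = np.asarray(positions, dtype=float)
    doses = interpolate_trilinear(grid, _line_points("depth", positions, None))
    top = doses.max()
    if top <= 0:
        raise ValueError("depth-dose curve has no positive maximum")
    return ProfilePoints(axis="depth", positions=positions,
                         doses=100.0 * doses / top,
                         field_cm=field_cm, normalization="max")


def extract_crossline(grid: DoseGrid, depth: float, positions: Sequence[float],
                      field_cm: float = float("nan")) -> ProfilePoints:
    """Crossline profile at a depth, normalized so the CAX value is 100."""
    positions = np.asarray(positions, dtype=float)
    doses = interpolate_trilinear(grid, _line_points("crossline", positions, depth))
    cax = float(interpolate_trilinear(grid, [(0.0, 0.0, depth)])[0])
    if cax <= 0:
        raise ValueError("CAX dose is not positive; cannot normalize")
    return ProfilePoints(axis="crossline", positions=positions,
                         doses=100.0 * doses / cax,
                         field_cm=field_cm, depth_cm=depth, normalization="cax")


class _LineSampler:
    """Evaluate the evaluation distribution along the reference scan line,
    on the reference's normalization scale."""

    def __init__(self, reference: ProfilePoints,
                 eval_obj: Union[DoseGrid, ProfilePoints],
                 norm_value: float, step_cm: float):
        self.axis = reference.axis
        self.depth = reference.depth_cm
        if isinstance(eval_obj, ProfilePoints):
            if eval_obj.axis != reference.axis:
                raise ValueError("reference and evaluation scan axes differ")
            self._pos = eval_obj.positions
            self._dose = eval_obj.doses
            self.lo = float(self._pos[0])
            self.hi = float(self._pos[-1])
            self._grid = None
            self._scale = 1.0  # pre: same normalization scale
        elif isinstance(eval_obj, DoseGrid):
            self._grid = eval_obj
            ax = {"depth": 2, "crossline": 0, "inline": 1}[reference.axis]
            centers = eval_obj.axis_centers(ax)
            self.lo = float(centers[0])
            self.hi = float(centers[-1])
            # normalization factor from the same convention the reference uses
            span_lo = max(self.lo, float(reference.positions[0]))
            span_hi = min(self.hi, float(reference.positions[-1]))
            probe = np.arange(span_lo, span_hi + step_cm * 0.5, step_cm)
            raw = interpolate_trilinear(
                eval_obj, _line_points(self.axis, probe, self.depth))
            if reference.normalization == "max":
                ref_level = raw.max()
            elif reference.normalization == "cax":
                ref_level = float(interpolate_trilinear(
                    eval_obj, _line_points(self.axis, np.array([0.0]),
                                           self.depth))[0])
            else:
                ref_level = norm_value
            if ref_level <= 0:
                raise ValueError("cannot normalize evaluation distribution")
            self._scale = norm_value / ref_level
        else:
            raise TypeError("eval_obj must be a DoseGrid or ProfilePoints")

    def __call__(self, positions: np.ndarray) -> np.ndarray:
        if self._grid is None:
            return np.interp(positions, self._pos, self._dose)
        raw = interpolate_trilinear(
            self._grid, _line_points(self.axis, np.asarray(positions).ravel(),
                                     self.depth))
        return (self._scale * raw).reshape(np.shape(positions))


def _threshold_mask(reference: ProfilePoints, criteria: GammaCriteria,
                    norm_value: float) -> np.ndarray:
    if criteria.threshold_pct is None:
        return np.zeros(len(reference), dtype=bool)
    return reference.doses < criteria.threshold_pct / 100.0 * norm_value


def gamma_points(
    reference: ProfilePoints,
    eval_obj: Union[DoseGrid, ProfilePoints],
    criteria: GammaCriteria = GammaCriteria(),
    norm_value: float = 100.0,
) -> GammaResult:
    """Gamma index of each reference point against the evaluation distribution.

    The evaluation is sampled along the reference scan line within
    search_radius_factor·DTA of each point, at step_fraction·DTA, by linear
    interpolation (trilinear for a DoseGrid, which is first rescaled to the
    reference's normalization convention).  The dose denominator is global
    (dose_pct of norm_value) unless criteria.local is set.  Points whose
    search window leaves the evaluation domain are excluded from the pass
    rate and counted in n_excluded.
    """
    if norm_value <= 0:
        raise ValueError("norm_value must be positive")
    dta = criteria.dta_cm
    window = criteria.search_radius_factor * dta
    step = criteria.step_fraction * dta
    sampler = _LineSampler(reference, eval_obj, norm_value, step)

    n_off = int(round(window / step))
    offsets = step * np.arange(-n_off, n_off + 1)

    r = reference.positions
    inside = (r - window >= sampler.lo - 1e-12) & (r + window <= sampler.hi + 1e-12)
    below = _threshold_mask(reference, criteria, norm_value)
    use = inside & ~below

    gammas = np.full(len(r), np.nan)
    if use.any():
        cand = r[use, None] + offsets[None, :]
        d_eval = sampler(cand)
        if criteria.local:
            dd = criteria.dose_pct / 100.0 * reference.doses[use, None]
        else:
            dd = criteria.dose_pct / 100.0 * norm_value
        dose_term = (d_eval - reference.doses[use, None]) / dd
        dist_term = (cand - r[use, None]) / dta
        gammas[use] = np.sqrt(dist_term**2 + dose_term**2).min(axis=1)
    return GammaResult.from_gammas(gammas, n_excluded=int((~use).sum()))


def gamma_brute_force(
    reference: ProfilePoints,
    eval_obj: Union[DoseGrid, ProfilePoints],
    criteria: GammaCriteria = GammaCriteria(),
    norm_value: float = 100.0,
) -> GammaResult:
    """Exhaustive-search gamma oracle at a dense step of DTA/100.

    Same definition as gamma_points, implemented independently with a naive
    per-point loop over a dense candidate set; intended for small instances
    (≲ 10³ reference points) and for validating the fast path.
    """
    if norm_value <= 0:
        raise ValueError("norm_value must be positive")
    dta = criteria.dta_cm
    window = criteria.search_radius_factor * dta
    sampler = _LineSampler(reference, eval_obj, norm_value, dta / 100.0)
    # dense step = window/n_side <= dta/100 (guard against float round-up)
    n_side = int(math.ceil(100.0 * criteria.search_radius_factor - 1e-9))
    below = _threshold_mask(reference, criteria, norm_value)
    gammas = np.full(len(reference), np.nan)
    n_excluded = 0
    for i, (ri, di) in enumerate(zip(reference.positions, reference.doses)):
        if below[i] or ri - window < sampler.lo - 1e-12 \
                or ri + window > sampler.hi + 1e-12:
            n_excluded += 1
            continue
        p = np.linspace(ri - window, ri + window, 2 * n_side + 1)
        de = sampler(p)
        if criteria.local:
            dd = criteria.dose_pct / 100.0 * di
        else:
            dd = criteria.dose_pct / 100.0 * norm_value
        g2 = ((p - ri) / dta) ** 2 + ((de - di) / dd) ** 2
        gammas[i] = math.sqrt(float(g2.min()))
    return GammaResult.from_gammas(gammas, n_excluded=n_excluded)


def aggregate_gpr(groups: Dict[str, Sequence[Union[GammaResult, float]]]) -> pd.DataFrame:
    """Per-beam mean and sample standard deviation of per-field pass rates."""
    rows = []
    for beam, results in groups.items():
        if len(results) == 0:
            raise ValueError(f"empty result group for beam {beam!r}")
        gprs = np.array([r.gpr if isinstance(r, GammaResult) else float(r)
                         for r in results])
        std = float(np.std(gprs, ddof=1)) if len(gprs) > 1 else 0.0
        rows.append({"beam": beam, "n_fields": len(gprs),
                     "mean_gpr": float(gprs.mean()), "std_gpr": std})
    return pd.DataFrame(rows)


def output_factors(
    grids: Dict[float, DoseGrid],
    depth: float = 10.0,
    reference_field: float = 10.0,
) -> OutputFactorTable:
    """Central-axis dose ratios at depth, relative to the reference field.

    The uncertainty of each ratio combines the two voxel relative
    uncertainties in quadrature; the reference entry is exactly 1 with zero
    uncertainty (same voxel in numerator and denominator).
    """
    if reference_field not in grids:
        raise ValueError(f"missing reference field grid ({reference_field} cm)")
    point = [(0.0, 0.0, depth)]

    def cax_dose(g: DoseGrid) -> float:
        return float(interpolate_trilinear(g, point)[0])

    def cax_unc(g: DoseGrid) -> float:
        if g.rel_unc is None:
            return 0.0
        u = _interpolator(g, g.rel_unc)(np.asarray(point))
        return float(u[0])

    d_ref = cax_dose(grids[reference_field])
    if d_ref <= 0:
        raise ValueError("reference CAX dose is not positive")
    u_ref = cax_unc(grids[reference_field])
    sides = np.array(sorted(grids))
    ofs, uncs = [], []
    for f in sides:
        if f == reference_field:
            ofs.append(1.0)
            uncs.append(0.0)
        else:
            ofs.append(cax_dose(grids[f]) / d_ref)
            uncs.append(math.hypot(cax_unc(grids[f]), u_ref))
    return OutputFactorTable(field_sides=sides, of_values=np.array(ofs),
                             unc=np.array(uncs), reference_field=reference_field,
                             depth_cm=depth)


def mean_relative_uncertainty(grid: DoseGrid) -> float:
    """Mean relative uncertainty over voxels with dose above half the maximum.

    The inequality is strict: voxels at exactly half the maximum are
    excluded.
    """
    if grid.rel_unc is None:
        raise ValueError("grid carries no uncertainty data")
    mask = grid.dose > 0.5 * grid.dose.max()
    if not mask.any():
        raise ValueError("no voxel above half the maximum dose")
    return float(grid.rel_unc[mask].mean())
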