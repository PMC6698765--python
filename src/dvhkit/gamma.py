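"""2D gamma-index comparison of dose planes (3%/3mm, 10% threshold, >=90% pass).

The gamma index combines a dose-difference criterion (percent of the
normalization dose) and a distance-to-agreement (DTA) criterion: for each
reference point r above the low-dose threshold,

    gamma(r) = min over evaluated positions e of
               sqrt( |e - r|^2 / DTA^2  +  (D_eval(e) - D_ref(r))^2 / dD^2 )

and a point passes when gamma <= 1.  The search is reference-point-centric:
the evaluated plane is bilinearly interpolated on a sub-grid of DTA/10 within
a radius of 3*DTA around each reference point, which bounds the
discretization error on gamma below about 0.05.

Normalization is global by default (dose criterion and low-dose threshold are
percentages of the reference-plane maximum); local mode divides the dose
difference by the local reference dose instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = ["DosePlane", "GammaCriteria", "GammaResult", "compute_gamma_map", "evaluate_passing"]


class GammaError(ValueError):
    """Invalid dose planes or gamma criteria."""


@dataclass(frozen=True)
class DosePlane:
    """2D dose distribution on a regular grid with uniform spacing (mm)."""

    spacing: float
    origin: tuple[float, float]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if not self.spacing > 0:
            raise GammaError(f"spacing must be > 0 mm, got {self.spacing}")
        if vals.ndim != 2 or min(vals.shape) < 2:
            raise GammaError("dose plane must be a 2D array with at least 2x2 points")
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise GammaError("dose values must be finite and non-negative")

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(y, x) coordinate vectors in mm (row axis first)."""
        ny, nx = self.values.shape
        return (
            self.origin[1] + self.spacing * np.arange(ny),
            self.origin[0] + self.spacing * np.arange(nx),
        )


@dataclass(frozen=True)
class GammaCriteria:
    dose_criterion: float = 3.0       # % of normalization dose
    distance_criterion: float = 3.0   # mm (DTA)
    low_dose_threshold: float = 10.0  # % of reference global max
    normalization: str = "global"     # "global" or "local"
    search_subdivision: int = 10      # offset step = DTA / subdivision

    def __post_init__(self) -> None:
        if min(self.dose_criterion, self.distance_criterion, self.low_dose_threshold) <= 0:
            raise GammaError("gamma criteria must all be strictly positive")
        if self.search_subdivision < 2:
            raise GammaError("search_subdivision must be >= 2")
        if self.normalization not in ("global", "local"):
            raise GammaError(f"normalization must be 'global' or 'local', got {self.normalization!r}")


@dataclass(frozen=True)
class GammaResult:
    """Per-reference-point gamma map (NaN where excluded) and the passing rate."""

    gamma_map: np.ndarray
    passing_rate: float  # percent of evaluated (non-excluded) points with gamma <= 1
    evaluated_points: int
    criteria: GammaCriteria = field(default=GammaCriteria())


def _search_offsets(dta: float, step: float) -> np.ndarray:
    """(K, 2) [dy, dx] displacements covering a disc of radius 3*DTA."""
    radius = 3.0 * dta
    g = np.arange(-radius, radius + step / 2, step)
    dy, dx = np.meshgrid(g, g, indexing="ij")
    mask = dy**2 + dx**2 <= radius**2
    return np.column_stack([dy[mask], dx[mask]])


def compute_gamma_map(
    reference: DosePlane, evaluated: DosePlane, criteria: GammaCriteria = GammaCriteria()
) -> GammaResult:
    """Gamma map and passing rate of ``evaluated`` against ``reference``.

    Reference points below the low-dose threshold are excluded (NaN in the
    map) and do not enter the passing rate.
    """
    dta = criteria.distance_criterion
    if reference.spacing > dta or evaluated.spacing > dta:
        raise GammaError(
            f"grid spacing ({reference.spacing}/{evaluated.spacing} mm) coarser than the "
            f"distance criterion ({dta} mm)"
        )
    ry, rx = reference.axis_coords()
    ey, ex = evaluated.axis_coords()
    if ry[-1] < ey[0] or ey[-1] < ry[0] or rx[-1] < ex[0] or ex[-1] < rx[0]:
        raise GammaError("reference and evaluated planes do not overlap spatially")

    global_max = float(reference.values.max())
    if global_max <= 0:
        raise GammaError("reference plane has no dose")
    threshold = criteria.low_dose_threshold / 100.0 * global_max

    interp = RegularGridInterpolator(
        (ey, ex), evaluated.values, method="linear", bounds_error=False, fill_value=np.nan
    )
    offsets = _search_offsets(dta, dta / criteria.search_subdivision)
    off_dist2 = (offsets**2).sum(axis=1) / dta**2  # (K,) squared distance term

    yy, xx = np.meshgrid(ry, rx, indexing="ij")
    ref_points = np.column_stack([yy.ravel(), xx.ravel()])
    ref_dose = reference.values.ravel()
    include = ref_dose >= threshold

    gamma_flat = np.full(ref_dose.size, np.nan)
    idx = np.nonzero(include)[0]
    if criteria.normalization == "global":
        dd_crit = np.full(idx.size, criteria.dose_criterion / 100.0 * global_max)
    else:
        dd_crit = criteria.dose_criterion / 100.0 * ref_dose[idx]

    chunk = max(1, int(2_000_000 // max(1, offsets.shape[0])))
    for start in range(0, idx.size, chunk):
        sel = idx[start:start + chunk]
        pts = ref_points[sel][:, None, :] + offsets[None, :, :]      # (c, K, 2)
        dose = interp(pts.reshape(-1, 2)).reshape(len(sel), -1)       # (c, K)
        dd2 = (dose - ref_dose[sel][:, None]) ** 2 / dd_crit[start:start + chunk, None] ** 2
        g2 = dd2 + off_dist2[None, :]
        g2 = np.where(np.isnan(g2), np.inf, g2)  # outside evaluated extent
        gamma_flat[sel] = np.sqrt(g2.min(axis=1))

    gamma_map = gamma_flat.reshape(reference.values.shape)
    n_eval = int(include.sum())
    passing = float(100.0 * np.sum(gamma_flat[include] <= 1.0) / n_eval) if n_eval else 0.0
    return GammaResult(
        gamma_map=gamma_map, passing_rate=passing, evaluated_points=n_eval, criteria=criteria
    )


def evaluate_passing(result: GammaResult, acceptance: float = 90.0) -> tuple[bool, float]:
    """QA verdict: (pass, margin); pass iff passing_rate >= acceptance (inclusive)."""
    if not 0 < acceptance <= 100:
        raise GammaError(f"acceptance must be in (0, 100], got {acceptance}")
    return result.passing_rate >= acceptance, result.passing_rate - acceptance
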