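"""Dose-volume histogram data model and interpolated dosimetric metrics.

A cumulative DVH gives, for each dose level, the fraction of a structure's
volume receiving at least that dose.  All doses are absolute Gy(RBE) (a
constant proton RBE of 1.1 is assumed to be baked into the input doses);
volumes are relative fractions in [0, 1], with an optional absolute structure
volume in cc for absolute-volume metrics such as D(0.03 cc).

The cumulative curve is treated as piecewise linear between its knots
("volume receiving >= dose" convention, matching clinical DVH exports).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DoseVolumeHistogram",
    "DifferentialDVH",
    "FractionationScheme",
    "Plan",
    "DVHError",
    "to_differential",
    "dose_at_relative_volume",
    "dose_at_absolute_volume",
    "relative_volume_at_dose",
    "mean_dose",
]


class DVHError(ValueError):
    """Invalid DVH data or metric request."""


@dataclass(frozen=True)
class FractionationScheme:
    """Treatment course: total prescription dose delivered in n equal fractions."""

    n_fractions: int
    prescription_dose: float  # Gy(RBE)

    def __post_init__(self) -> None:
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise DVHError(f"n_fractions must be a positive integer, got {self.n_fractions}")
        if not self.prescription_dose > 0:
            raise DVHError(f"prescription_dose must be > 0, got {self.prescription_dose}")

    @property
    def dose_per_fraction(self) -> float:
        """Per-fraction dose d_f = D / n_f, Gy(RBE)."""
        return self.prescription_dose / self.n_fractions


@dataclass(frozen=True)
class DoseVolumeHistogram:
    """Cumulative DVH of one structure.

    Parameters
    ----------
    structure_name : str
    dose_edges : array-like
        Strictly increasing dose values in Gy(RBE); the first edge must be 0.
    cumulative_volume : array-like
        Fraction of structure volume receiving >= the corresponding dose;
        non-increasing, starts at 1.0, values in [0, 1].
    total_volume : float, optional
        Absolute structure volume in cc (> 0); required only for
        absolute-volume metrics.
    """

    structure_name: str
    dose_edges: np.ndarray
    cumulative_volume: np.ndarray
    total_volume: float | None = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.dose_edges, dtype=float)
        cum = np.asarray(self.cumulative_volume, dtype=float)
        object.__setattr__(self, "dose_edges", edges)
        object.__setattr__(self, "cumulative_volume", cum)
        if edges.ndim != 1 or cum.shape != edges.shape:
            raise DVHError("dose_edges and cumulative_volume must be 1-D and equal length")
        if edges.size < 1:
            raise DVHError("empty DVH")
        if not np.all(np.isfinite(edges)) or not np.all(np.isfinite(cum)):
            raise DVHError("non-finite DVH values")
        if edges[0] != 0.0:
            raise DVHError(f"first dose edge must be 0, got {edges[0]}")
        if np.any(np.diff(edges) <= 0):
            raise DVHError("dose_edges must be strictly increasing")
        if np.any(np.diff(cum) > 0):
            raise DVHError("cumulative_volume must be non-monotone-free: non-increasing")
        if cum[0] != 1.0:
            raise DVHError(f"cumulative volume at dose 0 must be 1.0, got {cum[0]}")
        if np.any(cum < 0) or np.any(cum > 1):
            raise DVHError("cumulative_volume values must lie in [0, 1]")
        if self.total_volume is not None and not self.total_volume > 0:
            raise DVHError(f"total_volume must be > 0, got {self.total_volume}")

    @property
    def max_dose_edge(self) -> float:
        return float(self.dose_edges[-1])


@dataclass(frozen=True)
class DifferentialDVH:
    """Differential DVH: partial volumes v_i at bin-center doses, sum(v_i) = 1."""

    bin_centers: np.ndarray
    bin_fractions: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.bin_centers, dtype=float)
        frac = np.asarray(self.bin_fractions, dtype=float)
        object.__setattr__(self, "bin_centers", centers)
        object.__setattr__(self, "bin_fractions", frac)
        if centers.shape != frac.shape or centers.ndim != 1 or centers.size == 0:
            raise DVHError("bin_centers and bin_fractions must be equal-length 1-D arrays")
        if np.any(np.diff(centers) <= 0):
            raise DVHError("bin_centers must be strictly increasing")
        if np.any(frac < 0):
            raise DVHError("bin_fractions must be non-negative")
        if abs(frac.sum() - 1.0) > 1e-9:
            raise DVHError(f"bin fractions must sum to 1, got {frac.sum()!r}")

    @property
    def bin_count(self) -> int:
        return int(self.bin_centers.size)


@dataclass
class Plan:
    """One plan variant for one patient: named structure DVHs + fractionation."""

    patient_id: str
    variant_label: str
    structures: dict[str, DoseVolumeHistogram] = field(default_factory=dict)
    fractionation: FractionationScheme = field(
        default_factory=lambda: FractionationScheme(28, 50.4)
    )
    scenario_label: str | None = None

    def __post_init__(self) -> None:
        for name, dvh in self.structures.items():
            if dvh.structure_name != name:
                raise DVHError(
                    f"structure key {name!r} != DVH structure_name {dvh.structure_name!r}"
                )


def to_differential(dvh: DoseVolumeHistogram) -> DifferentialDVH:
    """Difference the cumulative curve into partial volumes.

    v_i = cumulative[i] - cumulative[i+1] at the midpoint of consecutive edges;
    if the curve does not reach zero, a closing bin at the final edge absorbs
    the residual volume.  Zero-volume bins are dropped.
    """
    edges = dvh.dose_edges
    cum = dvh.cumulative_volume
    if edges.size < 2:
        raise DVHError("single-point DVH has no bins")
    centers = 0.5 * (edges[:-1] + edges[1:])
    fractions = cum[:-1] - cum[1:]
    if cum[-1] > 0:
        centers = np.append(centers, edges[-1])
        fractions = np.append(fractions, cum[-1])
    keep = fractions > 0
    if not keep.any():
        raise DVHError("degenerate DVH: no volume in any bin")
    return DifferentialDVH(bin_centers=centers[keep], bin_fractions=fractions[keep])


def dose_at_relative_volume(dvh: DoseVolumeHistogram, x: float) -> float:
    """D_x%: dose received by at least x percent of the volume, Gy(RBE).

    On plateaus the highest dose at which the curve still equals x/100 is
    returned (conservative for target coverage).  Returns 0 if the requested
    fraction exceeds the curve maximum.
    """
    if not 0 < x <= 100:
        raise DVHError(f"relative volume must be in (0, 100], got {x}")
    f = x / 100.0
    cum = dvh.cumulative_volume
    edges = dvh.dose_edges
    if f > cum[0]:
        return 0.0
    # last knot with cumulative >= f (rightmost, handles plateaus)
    idx = int(np.nonzero(cum >= f)[0][-1])
    if idx == cum.size - 1 or cum[idx] == f:
        return float(edges[idx])
    # interpolate on the segment where the curve crosses f
    c0, c1 = cum[idx], cum[idx + 1]
    d0, d1 = edges[idx], edges[idx + 1]
    return float(d0 + (c0 - f) / (c0 - c1) * (d1 - d0))


def dose_at_absolute_volume(dvh: DoseVolumeHistogram, v_cc: float) -> float:
    """D_vcc: dose received by an absolute volume v in cc (e.g. D(0.03 cc))."""
    if dvh.total_volume is None:
        raise DVHError(
            f"{dvh.structure_name}: total_volume (cc) is required for absolute-volume "
            "metrics; supply it in the DVH file or request a relative metric"
        )
    if not 0 < v_cc <= dvh.total_volume:
        raise DVHError(f"absolute volume must be in (0, {dvh.total_volume}] cc, got {v_cc}")
    return dose_at_relative_volume(dvh, 100.0 * v_cc / dvh.total_volume)


def relative_volume_at_dose(dvh: DoseVolumeHistogram, d: float) -> float:
    """V_dGy: percent of volume receiving at least d Gy(RBE); 0 beyond the curve."""
    if d < 0:
        raise DVHError(f"dose must be >= 0, got {d}")
    if d > dvh.max_dose_edge:
        return 0.0
    return 100.0 * float(np.interp(d, dvh.dose_edges, dvh.cumulative_volume))


def mean_dose(dvh: DoseVolumeHistogram) -> float:
    """Mean structure dose, Gy(RBE): sum of v_i * bin-center dose."""
    ddvh = to_differential(dvh)
    return float(np.dot(ddvh.bin_fractions, ddvh.bin_centers))
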