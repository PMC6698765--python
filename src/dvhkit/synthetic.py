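"""Synthetic cohort generator emulating PB-vs-MC dose-calculation differences.

No patient data ship with the package; this module fabricates a cohort whose
*summary statistics* match the study conditions the analysis consumes: three
plan variants per patient (PB-PB, PB-MC, MC-MC) whose target-coverage averages
sit at the configured (Dmean%, D95%) pairs, near-zero heart dose, ipsilateral
lung V20 around 12-14%, and skin D(0.03 cc) around 100% of prescription.

Voxel-dose models per structure kind:

* ``target`` — truncated normal (0 to 115% of prescription): the simplest
  two-parameter family reproducing a requested (Dmean, D95) pair, via
  sigma = (Dmean - D95) / z_95 with z_95 = 1.6449.
* ``oar-low`` — exponential low-dose bath hitting a requested mean.
* ``oar-lung`` — three-component mixture (in-field normal above 20 Gy,
  mid-dose uniform, exponential bath) tuned to requested V20/V5.
* ``skin`` — small hot fraction near prescription, upper-truncated at the
  requested Dmax, over an exponential bath; carries an absolute volume so
  D(0.03 cc) is defined.

Randomness: one master seed expands through named substreams per
(patient, variant, structure), so adding a patient never changes existing
patients.  Everything is a pure function of config + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dvh import DoseVolumeHistogram, DVHError, FractionationScheme, Plan
from .gamma import DosePlane

__all__ = [
    "SyntheticCohortConfig",
    "ScenarioMagnitudes",
    "PlanePerturbation",
    "SyntheticCohort",
    "generate_structure_dvh",
    "generate_cohort",
    "generate_scenario_dvhs",
    "generate_dose_plane_pair",
    "default_spot_layout",
    "TARGET_STRUCTURES",
    "SCENARIO_LABELS",
]

Z95 = 1.6449  # standard normal 95th percentile: D95 = mean - Z95 * sigma

TARGET_STRUCTURES = (
    "CTV_Total", "CTV_AxI", "CTV_AxII", "CTV_AxIII", "CTV_CW_Breast", "CTV_IMN", "CTV_SCVN",
)
SCENARIO_LABELS = ("range+", "range-", "X+", "X-", "Y+", "Y-", "Z+", "Z-")


@dataclass(frozen=True)
class ScenarioMagnitudes:
    """DVH-level perturbation bounds for the eight robustness scenarios.

    Range errors of +/-3.5% and 5 mm isocenter shifts are mapped to small
    dose scalings plus a high-dose-tail erosion; the bounds cap the
    worst-case target D95 degradation (robustly optimised plans do not lose
    the full range error as output dose).
    """

    range_dose_scale: float = 0.010      # fractional dose change for range+/-
    shift_dose_scale_max: float = 0.008  # max fractional dose loss per shift scenario
    erosion_max: float = 0.02            # max exponent excess in cumulative**(1+eps)


@dataclass(frozen=True)
class PlanePerturbation:
    """Measured-vs-calculated plane discrepancy: rigid shift, scale, noise."""

    shift_mm: tuple[float, float] = (1.0, 0.0)
    dose_scale: float = 1.01
    noise_sd: float = 0.0  # Gy(RBE), additive white noise on the evaluated plane


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_patients: int = 10
    seed: int = 0
    fractionation: FractionationScheme = field(
        default_factory=lambda: FractionationScheme(28, 50.4)
    )
    # per-variant (Dmean %, D95 %) of prescription for target structures
    variant_targets: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "PB-PB": (100.3, 97.5),
            "PB-MC": (97.6, 93.5),
            "MC-MC": (100.0, 97.1),
        }
    )
    patient_shift_sd: float = 1.0      # pp; shared per-patient systematic, clipped
    patient_shift_clip: float = 2.0    # truncation in units of sigma
    structure_noise_sd: float = 0.3    # pp; per-substructure jitter on the mean
    variant_noise_sd: float = 0.2      # pp; independent per-variant jitter
    heart_mean_range: tuple[float, float] = (0.12, 1.07)     # Gy(RBE), log-uniform
    lad_mean_range: tuple[float, float] = (0.43, 9.21)
    esophagus_mean_range: tuple[float, float] = (3.33, 17.24)
    contralateral_mean_range: tuple[float, float] = (0.3, 2.5)
    lung_v20: tuple[float, float, float, float] = (12.4, 5.0, 2.0, 24.0)  # mean, sd, lo, hi %
    lung_v5_excess: tuple[float, float, float, float] = (20.4, 4.0, 8.0, 30.0)  # V5 - V20
    skin_dmax: tuple[float, float, float, float] = (100.2, 2.0, 95.0, 105.0)  # % of presc
    skin_hot_fraction: float = 0.05
    skin_total_volume_cc: float = 500.0
    oar_variant_scale_sd: float = 0.03  # multiplicative variant jitter on OAR doses
    n_voxels: int = 20000
    bin_width: float = 0.05  # Gy(RBE)
    scenario: ScenarioMagnitudes = field(default_factory=ScenarioMagnitudes)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise DVHError("n_patients must be >= 1")
        for label, (mean, d95) in self.variant_targets.items():
            if mean <= 0 or d95 <= 0 or d95 >= mean:
                raise DVHError(f"variant {label!r}: need 0 < D95 < Dmean, got ({mean}, {d95})")


@dataclass
class SyntheticCohort:
    """Per patient: nominal Plan per variant plus its eight scenario Plans."""

    config: SyntheticCohortConfig
    nominal: dict[str, dict[str, Plan]]  # patient_id -> variant -> Plan
    scenarios: dict[str, dict[str, list[Plan]]]  # patient_id -> variant -> 8 Plans

    @property
    def patient_ids(self) -> list[str]:
        return list(self.nominal)


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *key]))


def _bin_voxels(
    doses: np.ndarray, bin_width: float, name: str, total_volume: float | None = None
) -> DoseVolumeHistogram:
    """Cumulative DVH of sampled voxel doses on a uniform dose grid."""
    doses = np.maximum(doses, 0.0)
    top = float(doses.max()) + bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    # fraction of voxels receiving >= each edge
    counts = np.searchsorted(np.sort(doses), edges, side="left")
    cum = 1.0 - counts / doses.size
    cum[0] = 1.0
    return DoseVolumeHistogram(
        structure_name=name, dose_edges=edges, cumulative_volume=cum, total_volume=total_volume
    )


def generate_structure_dvh(
    mean: float,
    spread: float,
    kind: str,
    frac: FractionationScheme,
    seed: int,
    *,
    name: str = "structure",
    v20: float | None = None,
    v5: float | None = None,
    dmax_percent: float | None = None,
    hot_fraction: float = 0.05,
    total_volume: float | None = None,
    n_voxels: int = 20000,
    bin_width: float = 0.05,
) -> DoseVolumeHistogram:
    """Sample one structure DVH; deterministic given ``seed``.

    ``mean``/``spread`` are percent of prescription for ``target`` and
    ``skin`` kinds, and Gy(RBE) (spread unused) for ``oar-low``.  The lung
    kind is driven by ``v20``/``v5`` instead.
    """
    rng = np.random.default_rng(seed)
    presc = frac.prescription_dose

    if kind == "target":
        mu = mean / 100.0 * presc
        sigma = spread / 100.0 * presc
        if sigma <= 0:
            doses = np.full(n_voxels, mu)
        else:
            doses = rng.normal(mu, sigma, size=n_voxels)
            doses = np.clip(doses, 0.0, 1.15 * presc)  # truncation bounds
        return _bin_voxels(doses, bin_width, name, total_volume)

    if kind == "oar-low":
        doses = np.minimum(rng.exponential(scale=max(mean, 1e-6), size=n_voxels), presc)
        return _bin_voxels(doses, bin_width, name, total_volume)

    if kind == "oar-lung":
        if v20 is None or v5 is None:
            raise DVHError("oar-lung kind needs v20 and v5 (%)")
        if not 0 <= v20 < v5 <= 100:
            raise DVHError(f"infeasible lung constraints: need 0 <= V20 < V5, got {v20}/{v5}")
        n_hi = int(round(v20 / 100.0 * n_voxels))
        n_mid = int(round((v5 - v20) / 100.0 * n_voxels))
        n_lo = n_voxels - n_hi - n_mid
        hi = np.clip(rng.normal(40.0, 6.0, size=n_hi), 20.5, 1.05 * presc)
        mid = rng.uniform(5.5, 19.5, size=n_mid)
        lo = np.clip(rng.exponential(1.5, size=n_lo), 0.0, 4.5)
        return _bin_voxels(np.concatenate([hi, mid, lo]), bin_width, name, total_volume)

    if kind == "skin":
        if dmax_percent is None:
            raise DVHError("skin kind needs dmax_percent")
        dmax_gy = dmax_percent / 100.0 * presc
        n_hot = int(round(hot_fraction * n_voxels))
        hot = rng.normal(mean / 100.0 * presc, spread / 100.0 * presc, size=4 * n_hot)
        hot = hot[hot <= dmax_gy][:n_hot]  # upper truncation at the requested Dmax
        if hot.size < n_hot:
            hot = np.concatenate([hot, np.full(n_hot - hot.size, 0.98 * dmax_gy)])
        hot[0] = dmax_gy  # pin the hottest voxel at the request
        cold = np.clip(rng.exponential(2.0, size=n_voxels - n_hot), 0.0, 10.0)
        return _bin_voxels(np.concatenate([hot, cold]), bin_width, name, total_volume)

    raise DVHError(f"unknown structure kind {kind!r}")


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _trunc_normal(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def generate_cohort(config: SyntheticCohortConfig | None = None) -> SyntheticCohort:
    """Full synthetic cohort: nominal plans per variant plus scenario plans."""
    cfg = config or SyntheticCohortConfig()
    variants = list(cfg.variant_targets)
    nominal: dict[str, dict[str, Plan]] = {}
    scenarios: dict[str, dict[str, list[Plan]]] = {}

    for p_idx in range(cfg.n_patients):
        pid = f"P{p_idx + 1:02d}"
        prng = _rng(cfg.seed, 1, p_idx)
        # shared per-patient systematic coverage shift (pp), truncated at +/- clip*sd
        shift = cfg.patient_shift_sd * np.clip(
            prng.standard_normal(), -cfg.patient_shift_clip, cfg.patient_shift_clip
        )
        # per-patient anatomy: OAR dose levels shared across variants
        heart_mean = _loguniform(prng, *cfg.heart_mean_range)
        lad_mean = _loguniform(prng, *cfg.lad_mean_range)
        eso_mean = _loguniform(prng, *cfg.esophagus_mean_range)
        contra_mean = _loguniform(prng, *cfg.contralateral_mean_range)
        v20 = _trunc_normal(prng, *cfg.lung_v20)
        v5 = v20 + _trunc_normal(prng, *cfg.lung_v5_excess)
        dmax = _trunc_normal(prng, *cfg.skin_dmax)
        struct_noise = {
            s: cfg.structure_noise_sd * prng.standard_normal() for s in TARGET_STRUCTURES
        }

        nominal[pid] = {}
        scenarios[pid] = {}
        for v_idx, variant in enumerate(variants):
            vrng = _rng(cfg.seed, 2, p_idx, v_idx)
            mean_t, d95_t = cfg.variant_targets[variant]
            spread = (mean_t - d95_t) / Z95  # pp -> sigma of the truncated normal
            structures: dict[str, DoseVolumeHistogram] = {}
            for s_idx, sname in enumerate(TARGET_STRUCTURES):
                m = mean_t + shift + struct_noise[sname] + cfg.variant_noise_sd * vrng.standard_normal()
                structures[sname] = generate_structure_dvh(
                    m, spread, "target", cfg.fractionation,
                    seed=int(vrng.integers(2**31)), name=sname,
                    n_voxels=cfg.n_voxels, bin_width=cfg.bin_width,
                )
            oar_scale = float(np.exp(cfg.oar_variant_scale_sd * vrng.standard_normal()))
            for sname, m in (
                ("Heart", heart_mean), ("LAD", lad_mean),
                ("Esophagus", eso_mean), ("Lung_Contralateral", contra_mean),
            ):
                structures[sname] = generate_structure_dvh(
                    m * oar_scale, 0.0, "oar-low", cfg.fractionation,
                    seed=int(vrng.integers(2**31)), name=sname,
                    n_voxels=cfg.n_voxels, bin_width=cfg.bin_width,
                )
            structures["Lung_Ipsilateral"] = generate_structure_dvh(
                0.0, 0.0, "oar-lung", cfg.fractionation,
                seed=int(vrng.integers(2**31)), name="Lung_Ipsilateral",
                v20=min(v20 * oar_scale, 99.0), v5=min(v5 * oar_scale, 100.0),
                n_voxels=cfg.n_voxels, bin_width=cfg.bin_width,
            )
            structures["Skin"] = generate_structure_dvh(
                90.0, 5.0, "skin", cfg.fractionation,
                seed=int(vrng.integers(2**31)), name="Skin",
                dmax_percent=dmax, hot_fraction=cfg.skin_hot_fraction,
                total_volume=cfg.skin_total_volume_cc,
                n_voxels=cfg.n_voxels, bin_width=cfg.bin_width,
            )
            plan = Plan(
                patient_id=pid, variant_label=variant,
                structures=structures, fractionation=cfg.fractionation,
            )
            nominal[pid][variant] = plan
            scenarios[pid][variant] = generate_scenario_dvhs(
                plan, cfg.scenario, seed=int(vrng.integers(2**31))
            )
    return SyntheticCohort(config=cfg, nominal=nominal, scenarios=scenarios)


def _perturb_dvh(dvh: DoseVolumeHistogram, scale: float, erosion: float) -> DoseVolumeHistogram:
    """Scale all doses and erode the cumulative curve (volume**(1+erosion))."""
    edges = dvh.dose_edges * scale
    cum = dvh.cumulative_volume ** (1.0 + erosion)
    cum[0] = 1.0
    return replace(dvh, dose_edges=edges, cumulative_volume=cum)


def generate_scenario_dvhs(
    plan: Plan, magnitudes: ScenarioMagnitudes | None = None, seed: int = 0
) -> list[Plan]:
    """The eight labelled perturbation scenarios of one plan.

    Range scenarios scale the dose up/down by ``range_dose_scale``; shift
    scenarios combine a dose loss drawn below ``shift_dose_scale_max`` with a
    high-dose-tail erosion below ``erosion_max``.  Zero magnitudes reproduce
    the nominal plan exactly.
    """
    mags = magnitudes or ScenarioMagnitudes()
    rng = np.random.default_rng(seed)
    out = []
    for label in SCENARIO_LABELS:
        if label == "range+":
            scale, erosion = 1.0 - mags.range_dose_scale, 0.0
        elif label == "range-":
            scale, erosion = 1.0 + mags.range_dose_scale, 0.0
        else:
            scale = 1.0 - mags.shift_dose_scale_max * rng.uniform(0.2, 1.0)
            erosion = mags.erosion_max * rng.uniform(0.0, 1.0)
        structures = {
            name: _perturb_dvh(dvh, scale, erosion) for name, dvh in plan.structures.items()
        }
        sp = Plan(
            patient_id=plan.patient_id, variant_label=plan.variant_label,
            structures=structures, fractionation=plan.fractionation,
        )
        sp.scenario_label = label
        out.append(sp)
    return out


def default_spot_layout() -> list[tuple[float, float, float, float]]:
    """A broad QA field: (x_mm, y_mm, sigma_mm, amplitude_gy) Gaussian spots."""
    return [
        (0.0, 0.0, 12.0, 1.8),
        (-15.0, 8.0, 10.0, 1.2),
        (14.0, -10.0, 10.0, 1.4),
        (8.0, 12.0, 9.0, 1.0),
    ]


def _sum_spots(spots, xs, ys, shift=(0.0, 0.0)) -> np.ndarray:
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    total = np.zeros_like(xx)
    for x0, y0, sigma, amp in spots:
        total += amp * np.exp(
            -((xx - x0 - shift[0]) ** 2 + (yy - y0 - shift[1]) ** 2) / (2.0 * sigma**2)
        )
    return total


def generate_dose_plane_pair(
    spot_layout=None,
    perturbation: PlanePerturbation | None = None,
    spacing: float = 2.0,
    seed: int = 0,
    extent_mm: float = 40.0,
) -> tuple[DosePlane, DosePlane]:
    """(reference, evaluated) planes: Gaussian spot sum vs its perturbed copy."""
    spots = spot_layout if spot_layout is not None else default_spot_layout()
    if not spots:
        raise DVHError("empty spot layout")
    pert = perturbation or PlanePerturbation()
    coords = np.arange(-extent_mm, extent_mm + spacing / 2, spacing)
    origin = (float(coords[0]), float(coords[0]))
    ref = _sum_spots(spots, coords, coords)
    ev = pert.dose_scale * _sum_spots(spots, coords, coords, shift=pert.shift_mm)
    if pert.noise_sd > 0:
        ev = ev + np.random.default_rng(seed).normal(0.0, pert.noise_sd, size=ev.shape)
    ev = np.maximum(ev, 0.0)
    return (
        DosePlane(spacing=spacing, origin=origin, values=ref),
        DosePlane(spacing=spacing, origin=origin, values=ev),
    )
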