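"""Plan evaluation into metric reports, robustness checks, and cohort statistics.

The report stage turns each plan into long-form rows of
(patient, variant, structure, metric, value, unit); the cohort stage averages
those rows over patients and attaches two-sided Mann-Whitney U p-values of
each variant against a baseline (default PB-PB, significance 0.05).  Target
coverage metrics are reported as percent of the prescription dose; OAR mean
doses in Gy(RBE); V_dGy in percent volume; TCP/NTCP in percent probability.

The robustness criterion follows worst-case scenario evaluation: a plan is
robust when the total-target D95% of every perturbation scenario (range
+/-3.5%, isocenter shifts of +/-5 mm along X, Y, Z — eight scenarios) stays
at or above 90% of the prescription.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dvh import (
    DVHError,
    Plan,
    dose_at_absolute_volume,
    dose_at_relative_volume,
    mean_dose,
    relative_volume_at_dose,
    to_differential,
)
from .radiobiology import (
    NormalTissueModelParams,
    TumorModelParams,
    compute_eud,
    compute_ntcp_lkb,
    compute_tcp_poisson_lq,
    load_registry,
)

__all__ = [
    "MetricRequest",
    "MetricReport",
    "RobustnessOutcome",
    "SCENARIO_LABELS",
    "default_metric_spec",
    "evaluate_plan",
    "robustness_evaluate",
    "mann_whitney_u",
    "cohort_summary",
]

#: The eight perturbation scenarios: proton range error and isocenter shifts.
SCENARIO_LABELS = ("range+", "range-", "X+", "X-", "Y+", "Y-", "Z+", "Z-")


@dataclass(frozen=True)
class MetricRequest:
    """One metric for one structure; ``model`` names a parameter-registry entry."""

    structure: str
    metric: str
    model: str | None = None


@dataclass
class MetricReport:
    """Long-form metric table plus parameter provenance and per-row errors."""

    data: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class RobustnessOutcome:
    patient_id: str
    variant_label: str
    scenario_d95: dict[str, float]  # Gy(RBE) per scenario label
    threshold: float  # Gy(RBE)
    passed: bool


def default_metric_spec() -> list[MetricRequest]:
    """The study's metric panel: target coverage, OAR dose, and dose-response."""
    spec = [MetricRequest("CTV_Total", m) for m in ("D99%", "D95%", "Dmean%", "D2%")]
    targets = ("CTV_Total", "CTV_AxI", "CTV_AxII", "CTV_AxIII",
               "CTV_CW_Breast", "CTV_IMN", "CTV_SCVN")
    for s in targets:
        spec.append(MetricRequest(s, "EUD", model="breast_tumor"))
        spec.append(MetricRequest(s, "TCP", model="breast_tumor"))
    for s in ("Heart", "LAD", "Esophagus"):
        spec.append(MetricRequest(s, "Dmean"))
    spec.append(MetricRequest("Skin", "D0.03cc%"))
    for s in ("Lung_Ipsilateral",):
        spec.append(MetricRequest(s, "V20Gy"))
        spec.append(MetricRequest(s, "V5Gy"))
    spec.append(MetricRequest("Lung_Contralateral", "V5Gy"))
    spec.append(MetricRequest("Heart", "NTCP", model="heart"))
    spec.append(MetricRequest("Lung_Ipsilateral", "NTCP", model="lung_ipsilateral"))
    spec.append(MetricRequest("Skin", "NTCP", model="skin"))
    return spec


_REL_DOSE = re.compile(r"^D(\d+(?:\.\d+)?)%$")
_ABS_VOL = re.compile(r"^D(\d+(?:\.\d+)?)cc%$")
_VOL_AT = re.compile(r"^V(\d+(?:\.\d+)?)Gy$")


def _compute_metric(plan: Plan, req: MetricRequest, registry) -> tuple[float, str]:
    """Dispatch one metric; returns (value, unit)."""
    dvh = plan.structures[req.structure]
    presc = plan.fractionation.prescription_dose
    m = req.metric
    if m == "Dmean":
        return mean_dose(dvh), "Gy(RBE)"
    if m == "Dmean%":
        return 100.0 * mean_dose(dvh) / presc, "%"
    if match := _REL_DOSE.match(m):
        return 100.0 * dose_at_relative_volume(dvh, float(match.group(1))) / presc, "%"
    if match := _ABS_VOL.match(m):
        return 100.0 * dose_at_absolute_volume(dvh, float(match.group(1))) / presc, "%"
    if match := _VOL_AT.match(m):
        return relative_volume_at_dose(dvh, float(match.group(1))), "%"
    if m in ("EUD", "TCP", "NTCP"):
        if req.model is None or req.model not in registry:
            raise DVHError(f"metric {m} for {req.structure!r} needs a registry model")
        params = registry[req.model]
        ddvh = to_differential(dvh)
        if m == "EUD":
            if not isinstance(params, TumorModelParams):
                raise DVHError(f"EUD needs tumour parameters, got {req.model!r}")
            return compute_eud(ddvh, params, plan.fractionation), "Gy(RBE)"
        if m == "TCP":
            if not isinstance(params, TumorModelParams):
                raise DVHError(f"TCP needs tumour parameters, got {req.model!r}")
            return 100.0 * compute_tcp_poisson_lq(ddvh, params, plan.fractionation), "%"
        if not isinstance(params, NormalTissueModelParams):
            raise DVHError(f"NTCP needs normal-tissue parameters, got {req.model!r}")
        res = compute_ntcp_lkb(ddvh, params, plan.fractionation, structure_name=req.structure)
        return 100.0 * res.ntcp, "%"
    raise DVHError(f"unknown metric {m!r}")


def evaluate_plan(
    plan: Plan,
    metric_spec: list[MetricRequest] | None = None,
    registry=None,
) -> MetricReport:
    """Evaluate one plan into a MetricReport.

    Missing structures (or other per-metric failures) become entries in the
    error summary; all remaining rows are still produced.
    """
    if metric_spec is None:
        metric_spec = default_metric_spec()
    if registry is None:
        registry = load_registry()
    rows, errors = [], []
    for req in metric_spec:
        if req.structure not in plan.structures:
            errors.append(f"{plan.patient_id}/{plan.variant_label}: structure "
                          f"{req.structure!r} missing (metric {req.metric})")
            continue
        try:
            value, unit = _compute_metric(plan, req, registry)
        except DVHError as exc:
            errors.append(f"{plan.patient_id}/{plan.variant_label}/{req.structure}: {exc}")
            continue
        rows.append((plan.patient_id, plan.variant_label, req.structure, req.metric, value, unit))
    data = pd.DataFrame(
        rows, columns=["patient_id", "variant", "structure", "metric", "value", "unit"]
    )
    provenance = {
        "fractionation": f"{plan.fractionation.n_fractions} x "
                         f"{plan.fractionation.dose_per_fraction:.4g} Gy(RBE)",
    }
    for name, p in registry.items():
        provenance[f"model:{name}"] = repr(p)
    return MetricReport(data=data, provenance=provenance, errors=errors)


def robustness_evaluate(
    nominal: Plan,
    scenario_plans: list[Plan],
    target_name: str = "CTV_Total",
    threshold_fraction: float = 0.90,
) -> RobustnessOutcome:
    """Worst-case coverage check over the eight perturbation scenarios.

    threshold = threshold_fraction * prescription (45.36 Gy(RBE) for 0.90 of
    50.4); the plan passes iff every scenario's target D95% meets it.
    """
    labels = [p.scenario_label for p in scenario_plans]
    missing = [lab for lab in SCENARIO_LABELS if lab not in labels]
    if len(scenario_plans) != 8 or missing:
        raise DVHError(
            f"expected exactly the 8 scenarios {SCENARIO_LABELS}, got {len(scenario_plans)} "
            f"plan(s); missing labels: {missing}"
        )
    threshold = threshold_fraction * nominal.fractionation.prescription_dose
    d95 = {
        p.scenario_label: dose_at_relative_volume(p.structures[target_name], 95.0)
        for p in scenario_plans
    }
    return RobustnessOutcome(
        patient_id=nominal.patient_id,
        variant_label=nominal.variant_label,
        scenario_d95=d95,
        threshold=threshold,
        passed=min(d95.values()) >= threshold,
    )


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (U of sample_a, p).

    Exact p by enumeration when both samples have n <= 12 and no ties occur;
    otherwise the normal approximation with tie and continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DVHError("Mann-Whitney U requires two non-empty samples")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and a.size <= 12 and b.size <= 12:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def cohort_summary(
    reports: list[MetricReport],
    baseline: str = "PB-PB",
    style: str = "sd",
) -> pd.DataFrame:
    """Per-metric cohort statistics with p-values of each variant vs baseline.

    ``style`` selects the dispersion column convention: "sd" (sample standard
    deviation, n-1) or "range" (min-max); both are always computed.
    Requires the same patient set in every variant.
    """
    if style not in ("sd", "range"):
        raise DVHError(f"style must be 'sd' or 'range', got {style!r}")
    data = pd.concat([r.data for r in reports], ignore_index=True)
    if data.empty:
        raise DVHError("no metric rows to summarize")
    variants = sorted(data["variant"].unique())
    if baseline not in variants:
        raise DVHError(f"baseline variant {baseline!r} not present (have {variants})")
    patient_sets = {v: frozenset(data.loc[data["variant"] == v, "patient_id"]) for v in variants}
    base_patients = patient_sets[baseline]
    for v, pats in patient_sets.items():
        if pats != base_patients:
            diff = sorted(base_patients ^ pats)
            raise DVHError(f"patient mismatch between {baseline!r} and {v!r}: {diff}")

    rows = []
    for (structure, metric, unit), grp in data.groupby(["structure", "metric", "unit"]):
        base = grp.loc[grp["variant"] == baseline].sort_values("patient_id")["value"].to_numpy()
        for v in variants:
            vals = grp.loc[grp["variant"] == v].sort_values("patient_id")["value"].to_numpy()
            p = np.nan if v == baseline else mann_whitney_u(vals, base)[1]
            rows.append({
                "structure": structure, "metric": metric, "unit": unit, "variant": v,
                "n": vals.size, "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
                "min": float(np.min(vals)), "max": float(np.max(vals)),
                "p_value_vs_baseline": p,
            })
    summary = pd.DataFrame(rows)
    summary.attrs["baseline"] = baseline
    summary.attrs["style"] = style
    return summary


def format_summary_table(summary: pd.DataFrame, ndigits: int = 1) -> str:
    """Aligned-text rendering of a cohort summary (one decimal, table style)."""
    style = summary.attrs.get("style", "sd")
    lines = []
    header = f"{'structure':<18}{'metric':<10}{'variant':<8}{'avg':>8}"
    header += f"{'sd':>7}" if style == "sd" else f"{'range':>16}"
    header += f"{'p':>8}"
    lines.append(header)
    for _, r in summary.iterrows():
        row = f"{r['structure']:<18}{r['metric']:<10}{r['variant']:<8}{r['mean']:>8.{ndigits}f}"
        if style == "sd":
            row += f"{r['sd']:>7.{ndigits}f}"
        else:
            row += f"{r['min']:>7.{ndigits}f}-{r['max']:<8.{ndigits}f}"
        p = r["p_value_vs_baseline"]
        row += f"{'':>8}" if np.isnan(p) else f"{p:>8.3f}"
        lines.append(row)
    return "\n".join(lines)
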