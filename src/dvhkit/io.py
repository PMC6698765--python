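"""Plain-text I/O for plans (DVH CSV dialect) and 2D dose planes.

DVH file layout (UTF-8, comma separated, ``.`` decimal)::

    # patient=<id>
    # variant=<label>
    # fractions=<n>
    # prescription_gy_rbe=<D>
    # scenario=<label>              (optional, robustness scenarios only)
    structure,<name>,total_volume_cc,<v or NA>
    dose_gy_rbe,cumulative_volume_fraction
    0.0,1.0
    ...

Dose-plane files carry ``# spacing_mm=<s>`` and ``# origin_mm=<x>,<y>``
headers followed by rows of dose values (one grid row per line).
"""

from __future__ import annotations

import os

import numpy as np

from .dvh import DoseVolumeHistogram, DVHError, FractionationScheme, Plan

__all__ = ["DVHParseError", "read_dvh_file", "write_dvh_file", "read_dose_plane", "write_dose_plane"]


class DVHParseError(ValueError):
    """Malformed DVH or dose-plane file; message names the offending line."""


def _header_value(line: str, key: str, lineno: int) -> str:
    prefix = f"# {key}="
    if not line.startswith(prefix):
        raise DVHParseError(f"line {lineno}: expected header '{prefix}<value>', got {line!r}")
    return line[len(prefix):].strip()


def read_dvh_file(path: str | os.PathLike) -> Plan:
    """Parse one plan (all its structure DVHs) from the DVH CSV dialect."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) < 4:
        raise DVHParseError("file too short: missing header block")

    patient = _header_value(lines[0], "patient", 1)
    variant = _header_value(lines[1], "variant", 2)
    try:
        n_fractions = int(_header_value(lines[2], "fractions", 3))
        prescription = float(_header_value(lines[3], "prescription_gy_rbe", 4))
    except ValueError as exc:
        raise DVHParseError(f"header: non-numeric fractionation value ({exc})") from exc

    idx = 4
    scenario = None
    if idx < len(lines) and lines[idx].startswith("# scenario="):
        scenario = _header_value(lines[idx], "scenario", idx + 1)
        idx += 1

    structures: dict[str, DoseVolumeHistogram] = {}
    name: str | None = None
    total_volume: float | None = None
    doses: list[float] = []
    volumes: list[float] = []

    def _close_block(lineno: int) -> None:
        nonlocal name
        if name is None:
            return
        if not doses:
            raise DVHParseError(f"line {lineno}: structure {name!r} has no DVH rows")
        try:
            dvh = DoseVolumeHistogram(
                structure_name=name,
                dose_edges=np.array(doses),
                cumulative_volume=np.array(volumes),
                total_volume=total_volume,
            )
        except DVHError as exc:
            raise DVHParseError(f"structure {name!r} ending at line {lineno}: {exc}") from exc
        if name in structures:
            raise DVHParseError(f"line {lineno}: duplicate structure {name!r}")
        structures[name] = dvh
        name = None

    for lineno, line in enumerate(lines[idx:], start=idx + 1):
        fields = line.split(",")
        if fields[0] == "structure":
            _close_block(lineno)
            if len(fields) != 4 or fields[2] != "total_volume_cc":
                raise DVHParseError(
                    f"line {lineno}: malformed structure header "
                    "(expected 'structure,<name>,total_volume_cc,<v or NA>')"
                )
            name = fields[1]
            total_volume = None if fields[3] == "NA" else float(fields[3])
            doses, volumes = [], []
        elif fields[0] == "dose_gy_rbe":
            if fields != ["dose_gy_rbe", "cumulative_volume_fraction"]:
                raise DVHParseError(f"line {lineno}: malformed column header {line!r}")
        else:
            if name is None:
                raise DVHParseError(f"line {lineno}: data row outside a structure block")
            if len(fields) != 2:
                raise DVHParseError(f"line {lineno}: expected 'dose,volume', got {line!r}")
            try:
                d, v = float(fields[0]), float(fields[1])
            except ValueError as exc:
                raise DVHParseError(f"line {lineno}: non-numeric value ({exc})") from exc
            if d < 0:
                raise DVHParseError(f"line {lineno}: negative dose {d}")
            if volumes and v > volumes[-1]:
                raise DVHParseError(
                    f"line {lineno}: non-monotone cumulative volume ({v} after {volumes[-1]})"
                )
            doses.append(d)
            volumes.append(v)
    _close_block(len(lines))

    plan = Plan(
        patient_id=patient,
        variant_label=variant,
        structures=structures,
        fractionation=FractionationScheme(n_fractions, prescription),
    )
    plan.scenario_label = scenario
    return plan


def write_dvh_file(plan: Plan, path: str | os.PathLike) -> None:
    """Write a plan in the DVH CSV dialect; output round-trips through read_dvh_file."""
    out: list[str] = [
        f"# patient={plan.patient_id}",
        f"# variant={plan.variant_label}",
        f"# fractions={plan.fractionation.n_fractions}",
        f"# prescription_gy_rbe={plan.fractionation.prescription_dose!r}",
    ]
    if plan.scenario_label is not None:
        out.append(f"# scenario={plan.scenario_label}")
    for name in plan.structures:
        dvh = plan.structures[name]
        tv = "NA" if dvh.total_volume is None else repr(float(dvh.total_volume))
        out.append(f"structure,{name},total_volume_cc,{tv}")
        out.append("dose_gy_rbe,cumulative_volume_fraction")
        for d, v in zip(dvh.dose_edges, dvh.cumulative_volume):
            out.append(f"{float(d)!r},{float(v)!r}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(out) + "\n")


def read_dose_plane(path: str | os.PathLike):
    """Read a 2D dose plane (returns a gamma.DosePlane)."""
    from .gamma import DosePlane

    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise DVHParseError("dose-plane file too short")
    spacing = float(_header_value(lines[0], "spacing_mm", 1))
    ox, oy = (float(t) for t in _header_value(lines[1], "origin_mm", 2).split(","))
    try:
        values = np.array([[float(x) for x in ln.split(",")] for ln in lines[2:]])
    except ValueError as exc:
        raise DVHParseError(f"dose-plane data: {exc}") from exc
    return DosePlane(spacing=spacing, origin=(ox, oy), values=values)


def write_dose_plane(plane, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# spacing_mm={plane.spacing!r}\n")
        fh.write(f"# origin_mm={plane.origin[0]!r},{plane.origin[1]!r}\n")
        for row in plane.values:
            fh.write(",".join(repr(float(x)) for x in row) + "\n")
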