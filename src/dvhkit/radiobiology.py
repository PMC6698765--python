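"""Radiobiological models on differential DVHs.

All models first convert each DVH bin's total course dose D_i to the
equieffective dose in 2 Gy fractions (EQD2) under the linear-quadratic model,

    EQD2_i = D_i * (alpha/beta + D_i/n_f) / (alpha/beta + 2),

where n_f is the number of fractions of the course, then combine bins with
their partial volumes v_i (sum v_i = 1, relative reference volume V_ref = 1):

* EUD (Niemierko): generalized power mean ``(sum v_i EQD2_i^a)^(1/a)``.
  Negative exponents (a = -7.2 for breast tumour) penalize cold spots.
* TCP (Poisson-LQ, Kallman closed form): volume-weighted geometric product of
  per-bin Poisson control probabilities parameterized by D50 and the maximum
  normalized response gradient gamma, with e*gamma as the slope constant.
* NTCP (Lyman-Kutcher-Burman): probit in the generalized-mean effective dose
  Deff = (sum v_i EQD2_i^(1/n))^n with slope m and volume parameter n.

Shipped parameter sets (``load_registry``): ``breast_tumor`` for EUD/TCP and
``heart`` / ``lung_ipsilateral`` / ``skin`` for NTCP.  The OAR alpha/beta for
EQD2 conversion defaults to 3 Gy (conventional late-responding tissue) and is
configurable per structure; every report should echo the value used.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.special import ndtr

from .dvh import DifferentialDVH, FractionationScheme

__all__ = [
    "TumorModelParams",
    "NormalTissueModelParams",
    "RadiobioResult",
    "eqd2_bin",
    "eqd2_inverse",
    "compute_eud",
    "compute_tcp_poisson_lq",
    "compute_deff",
    "compute_ntcp_lkb",
    "load_registry",
    "DEFAULT_OAR_ALPHA_BETA",
    "EQD2_FLOOR",
]

#: Default alpha/beta (Gy) for OAR EQD2 conversion (late-responding tissue).
DEFAULT_OAR_ALPHA_BETA = 3.0

#: EQD2 floor (Gy(RBE)) clamping zero-dose bins under negative EUD exponents.
EQD2_FLOOR = 1e-3


class ParameterError(ValueError):
    """Invalid radiobiological model parameters."""


@dataclass(frozen=True)
class TumorModelParams:
    """Target dose-response parameters: D50, gamma (TCP) and a, alpha/beta (EUD)."""

    d50: float
    gamma: float
    alpha_beta: float
    a: float

    def __post_init__(self) -> None:
        if not self.d50 > 0:
            raise ParameterError(f"d50 must be > 0, got {self.d50}")
        if not self.gamma > 0:
            raise ParameterError(f"gamma must be > 0, got {self.gamma}")
        if not self.alpha_beta > 0:
            raise ParameterError(f"alpha_beta must be > 0, got {self.alpha_beta}")
        if self.a == 0:
            raise ParameterError("EUD exponent a must be nonzero")


@dataclass(frozen=True)
class NormalTissueModelParams:
    """LKB parameters: D50, slope m, volume dependence n, plus alpha/beta for EQD2."""

    d50: float
    m: float
    n: float
    alpha_beta: float = DEFAULT_OAR_ALPHA_BETA

    def __post_init__(self) -> None:
        if not self.d50 > 0:
            raise ParameterError(f"d50 must be > 0, got {self.d50}")
        if not self.m > 0:
            raise ParameterError(f"m must be > 0, got {self.m}")
        if not 0 < self.n <= 1:
            raise ParameterError(f"n must be in (0, 1], got {self.n}")
        if not self.alpha_beta > 0:
            raise ParameterError(f"alpha_beta must be > 0, got {self.alpha_beta}")


@dataclass(frozen=True)
class RadiobioResult:
    """Radiobiological indices of one structure under one plan."""

    structure_name: str
    eud: float | None = None
    tcp: float | None = None
    ntcp: float | None = None
    deff: float | None = None
    t_statistic: float | None = None


def eqd2_bin(
    d_total: float | np.ndarray, frac: FractionationScheme, alpha_beta: float
) -> float | np.ndarray:
    """EQD2 of a bin's total course dose delivered in ``frac.n_fractions`` fractions."""
    d = np.asarray(d_total, dtype=float)
    if np.any(d < 0):
        raise ParameterError("negative dose")
    out = d * (alpha_beta + d / frac.n_fractions) / (alpha_beta + 2.0)
    return float(out) if np.isscalar(d_total) else out


def eqd2_inverse(eqd2: float, frac: FractionationScheme, alpha_beta: float) -> float:
    """Total course dose whose EQD2 equals ``eqd2`` (closed-form quadratic root)."""
    if eqd2 < 0:
        raise ParameterError("negative EQD2")
    nf = frac.n_fractions
    return nf / 2.0 * (-alpha_beta + math.sqrt(alpha_beta**2 + 4.0 * eqd2 * (alpha_beta + 2.0) / nf))


def _bin_eqd2(
    ddvh: DifferentialDVH, frac: FractionationScheme, alpha_beta: float, use_eqd2: bool
) -> np.ndarray:
    if not use_eqd2:
        return ddvh.bin_centers.copy()
    return eqd2_bin(ddvh.bin_centers, frac, alpha_beta)


def compute_eud(
    ddvh: DifferentialDVH,
    params: TumorModelParams,
    frac: FractionationScheme,
    *,
    use_eqd2: bool = True,
) -> float:
    """Equivalent uniform dose, Gy(RBE): power mean of bin EQD2 with exponent a.

    Bins with EQD2 below ``EQD2_FLOOR`` are clamped to the floor (with a
    warning) so that negative exponents keep their cold-spot penalty finite.
    """
    e = _bin_eqd2(ddvh, frac, params.alpha_beta, use_eqd2)
    if params.a < 0 and np.any(e < EQD2_FLOOR):
        warnings.warn(
            f"EUD: clamping {int(np.sum(e < EQD2_FLOOR))} near-zero-dose bin(s) to "
            f"{EQD2_FLOOR} Gy(RBE) floor",
            stacklevel=2,
        )
        e = np.maximum(e, EQD2_FLOOR)
    # log-space power mean: stable for large |a|
    with np.errstate(divide="ignore"):
        loge = np.log(np.maximum(e, np.finfo(float).tiny))
    return float(np.exp(_log_power_mean(loge, ddvh.bin_fractions, params.a)))


def _log_power_mean(log_values: np.ndarray, weights: np.ndarray, p: float) -> float:
    """log of (sum w_i exp(p*log_v_i))^(1/p), computed via logsumexp."""
    z = p * log_values + np.log(weights)
    zmax = z.max()
    return (zmax + math.log(np.exp(z - zmax).sum())) / p


def compute_tcp_poisson_lq(
    ddvh: DifferentialDVH,
    params: TumorModelParams,
    frac: FractionationScheme,
    *,
    use_eqd2: bool = True,
    slope_constant: float = math.e,
) -> float:
    """Poisson-LQ tumour control probability in [0, 1].

    Per bin, ln TCP_i = -exp(e*gamma - (EQD2_i/D50) * (e*gamma - ln ln 2));
    bins combine as a v_i-weighted geometric product (V_ref = 1).  At uniform
    EQD2 = D50 the exponent collapses to ln ln 2 and TCP = 1/2 exactly.
    ``slope_constant`` exposes the e*gamma convention (default Euler's e).
    """
    e = _bin_eqd2(ddvh, frac, params.alpha_beta, use_eqd2)
    eg = slope_constant * params.gamma
    lnln2 = math.log(math.log(2.0))
    log_tcp_bins = -np.exp(eg - (e / params.d50) * (eg - lnln2))
    return float(np.exp(np.dot(ddvh.bin_fractions, log_tcp_bins)))


def compute_deff(
    ddvh: DifferentialDVH,
    n: float,
    frac: FractionationScheme,
    alpha_beta: float,
    *,
    use_eqd2: bool = True,
) -> float:
    """LKB effective uniform dose: (sum v_i EQD2_i^(1/n))^n, Gy(RBE)."""
    if not n > 0:
        raise ParameterError(f"volume parameter n must be > 0, got {n}")
    e = _bin_eqd2(ddvh, frac, alpha_beta, use_eqd2)
    with np.errstate(divide="ignore"):
        loge = np.log(np.maximum(e, np.finfo(float).tiny))
    return float(np.exp(_log_power_mean(loge, ddvh.bin_fractions, 1.0 / n)))


def compute_ntcp_lkb(
    ddvh: DifferentialDVH,
    params: NormalTissueModelParams,
    frac: FractionationScheme,
    *,
    structure_name: str = "",
    use_eqd2: bool = True,
) -> RadiobioResult:
    """LKB NTCP: Phi((Deff - D50) / (m * D50)), with Deff and t recorded.

    The normal CDF goes through the complementary-error-function route
    (scipy.special.ndtr), so deeply negative t (~ -10 for a near-zero heart
    dose) yields a well-defined tiny probability rather than NaN.
    """
    deff = compute_deff(ddvh, params.n, frac, params.alpha_beta, use_eqd2=use_eqd2)
    t = (deff - params.d50) / (params.m * params.d50)
    return RadiobioResult(
        structure_name=structure_name, ntcp=float(ndtr(t)), deff=deff, t_statistic=t
    )


def load_registry(path: str | None = None) -> dict[str, TumorModelParams | NormalTissueModelParams]:
    """Load a named parameter registry (shipped defaults when ``path`` is None)."""
    if path is None:
        raw = json.loads(
            resources.files("dvhkit").joinpath("data/parameters.json").read_text("utf-8")
        )
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
    registry: dict[str, TumorModelParams | NormalTissueModelParams] = {}
    for name, entry in raw.items():
        model = entry.get("model")
        if model == "poisson_lq_tcp":
            registry[name] = TumorModelParams(
                d50=entry["d50"], gamma=entry["gamma"],
                alpha_beta=entry["alpha_beta"], a=entry["a"],
            )
        elif model == "lkb_ntcp":
            registry[name] = NormalTissueModelParams(
                d50=entry["d50"], m=entry["m"], n=entry["n"],
                alpha_beta=entry.get("alpha_beta", DEFAULT_OAR_ALPHA_BETA),
            )
        else:
            raise ParameterError(f"registry entry {name!r}: unknown model {model!r}")
    return registry
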