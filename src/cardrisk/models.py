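"""Dose-response models for radiogenic cardiac toxicity.

Three models from the late-effects literature are implemented:

* **Linear relative risk.**  RR(D) = 1 + α1·D on the mean heart dose, with
  α1 = 0.6 Gy⁻¹ (95% CI 0.2 to 2.5) fitted on childhood-cancer survivor
  follow-up data.  Confidence bounds on RR propagate the α1 interval.

* **Relative seriality (Källman) NTCP.**  Per-subvolume Poisson response
  P(D) = 2^(−exp[e·γ·(1 − D/D50)]), where D50 gives a 50% complication
  probability and γ is the maximum normalised slope, combined over the
  differential DVH through the seriality parameter s in (0, 1]
  (s = 1 fully serial, s → 0 parallel):

      NTCP = [1 − Π_i (1 − P(D_i)^s)^(v_i)]^(1/s).

  For a uniform whole-organ dose this reduces to P(D) for every s.  The
  product is evaluated in log space so that the near-zero complication
  probabilities typical of out-of-field organs do not underflow.

* **Lyman NTCP.**  NTCP = Φ(t) with t = (D − TD50(V)) / (m·TD50(V)) and
  the partial-volume tolerance dose TD50(V) = TD50(1)/Vⁿ (n close to 1
  means a strong volume effect; m is inversely proportional to the slope).
  Inhomogeneous DVHs are reduced to an equivalent (D_max, V_eff) pair by
  the Kutcher-Burman effective-volume transform
  V_eff = Σ v_i (D_i/D_max)^(1/n), the standard companion reduction for
  this model; for a two-level DVH with one irradiated level it coincides
  with the exact partial-volume formula.

NTCP values that underflow double precision (< ~1e-300) are reported as 0
by the probability-scale functions; ratio computations should use the
``log_``-variants, which stay finite far below that floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dvh import DifferentialDVH

__all__ = [
    "LinearRiskParams",
    "RiskEstimate",
    "RSParams",
    "LymanParams",
    "relative_risk",
    "poisson_response",
    "log_poisson_response",
    "ntcp_relative_seriality",
    "log_ntcp_relative_seriality",
    "td50_partial",
    "ntcp_lyman_uniform",
    "log_ntcp_lyman_uniform",
    "effective_volume",
    "ntcp_lyman_dvh",
    "log_ntcp_lyman_dvh",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class LinearRiskParams:
    """Linear excess-relative-risk coefficient per Gy with its 95% CI."""

    alpha1: float = 0.6
    ci_low: float = 0.2
    ci_high: float = 2.5

    def __post_init__(self) -> None:
        if not self.alpha1 > 0:
            raise ValueError("alpha1 must be positive")
        if not self.ci_low <= self.alpha1 <= self.ci_high:
            raise ValueError("alpha1 must lie inside its confidence interval")


@dataclass(frozen=True)
class RiskEstimate:
    """Point estimate with 95% confidence bounds."""

    value: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class RSParams:
    """Relative-seriality model parameters (D50 in Gy EQD2)."""

    d50: float
    gamma: float
    s: float

    def __post_init__(self) -> None:
        if not self.d50 > 0:
            raise ValueError("d50 must be positive")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if not 0 < self.s <= 1:
            raise ValueError("relative seriality s must be in (0, 1]")


@dataclass(frozen=True)
class LymanParams:
    """Lyman model parameters: TD50(1) in Gy EQD2, volume exponent n, slope m.

    The volume exponent here is named ``n_vol`` to keep it distinct from
    the voxel count that appears in the relative-seriality product.
    """

    td50_full: float
    n_vol: float
    m: float

    def __post_init__(self) -> None:
        if not self.td50_full > 0:
            raise ValueError("td50_full must be positive")
        if not 0 < self.n_vol <= 1:
            raise ValueError("volume exponent n_vol must be in (0, 1]")
        if not self.m > 0:
            raise ValueError("slope parameter m must be positive")


# ---------------------------------------------------------------------------
# linear relative risk

def relative_risk(mean_dose: float, params: LinearRiskParams | None = None) -> RiskEstimate:
    """RR = 1 + α1·D on the mean organ dose, CI bounds from the α1 interval."""
    if mean_dose < 0:
        raise ValueError("mean dose must be non-negative")
    p = params or LinearRiskParams()
    return RiskEstimate(
        value=1.0 + p.alpha1 * mean_dose,
        ci_low=1.0 + p.ci_low * mean_dose,
        ci_high=1.0 + p.ci_high * mean_dose,
    )


# ---------------------------------------------------------------------------
# relative seriality

def log_poisson_response(dose, params: RSParams):
    """Natural log of the Poisson dose-response P(D); vectorised."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(over="ignore"):
        exponent = np.exp(np.e * params.gamma * (1.0 - dose / params.d50))
    return -_LN2 * exponent


def poisson_response(dose, params: RSParams):
    """P(D) = 2^(−exp[e·γ·(1 − D/D50)]); P(D50) = 0.5, increasing in D."""
    out = np.exp(log_poisson_response(dose, params))
    return float(out) if np.ndim(out) == 0 else out


def log_ntcp_relative_seriality(dvh: DifferentialDVH, params: RSParams) -> float:
    """Natural log of the relative-seriality NTCP, safe against underflow."""
    log_p = log_poisson_response(dvh.doses, params)  # <= 0
    # per-bin log(1 - P^s); exp(s*log_p) underflows harmlessly to 0
    with np.errstate(divide="ignore"):
        terms = np.log1p(-np.exp(params.s * log_p))
    mask = dvh.volumes > 0
    log_product = float(np.dot(dvh.volumes[mask], terms[mask]))
    if log_product == 0.0:
        return -math.inf
    if math.isinf(log_product):
        return 0.0  # some bin has P == 1 exactly: certain complication
    # NTCP^s = 1 - exp(log_product)
    return math.log(-math.expm1(log_product)) / params.s


def ntcp_relative_seriality(dvh: DifferentialDVH, params: RSParams) -> float:
    """Relative-seriality NTCP of a differential DVH, in [0, 1]."""
    return math.exp(log_ntcp_relative_seriality(dvh, params))


# ---------------------------------------------------------------------------
# Lyman model

def td50_partial(td50_full: float, volume_fraction: float, n_vol: float) -> float:
    """Partial-volume tolerance dose TD50(V) = TD50(1) / V^n."""
    if not 0 < volume_fraction <= 1:
        raise ValueError("volume fraction must be in (0, 1]")
    if not td50_full > 0:
        raise ValueError("td50_full must be positive")
    return td50_full / volume_fraction**n_vol


def _lyman_t(dose: float, volume_fraction: float, params: LymanParams) -> float:
    td50v = td50_partial(params.td50_full, volume_fraction, params.n_vol)
    return (dose - td50v) / (params.m * td50v)


def ntcp_lyman_uniform(dose: float, volume_fraction: float, params: LymanParams) -> float:
    """Lyman NTCP = Φ(t) for a uniform dose to a partial volume."""
    if dose < 0:
        raise ValueError("dose must be non-negative")
    return float(stats.norm.cdf(_lyman_t(dose, volume_fraction, params)))


def log_ntcp_lyman_uniform(dose: float, volume_fraction: float, params: LymanParams) -> float:
    """Natural log of the uniform-dose Lyman NTCP (finite far into the tail)."""
    if dose < 0:
        raise ValueError("dose must be non-negative")
    return float(stats.norm.logcdf(_lyman_t(dose, volume_fraction, params)))


def effective_volume(dvh: DifferentialDVH, n_vol: float) -> float:
    """Kutcher-Burman effective volume at the maximum DVH dose.

    V_eff = Σ v_i (D_i / D_max)^(1/n); a DVH uniformly at D_max has
    V_eff = 1, and a two-level DVH with cold level at zero dose has
    V_eff equal to the hot volume fraction.
    """
    dmax = dvh.max_dose()
    if dmax == 0.0:
        return 1.0
    ratio = np.clip(dvh.doses / dmax, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        powered = np.where(ratio > 0, ratio ** (1.0 / n_vol), 0.0)
    return float(np.dot(dvh.volumes, powered))


def _lyman_reduce(dvh: DifferentialDVH, params: LymanParams) -> tuple[float, float]:
    dmax = dvh.max_dose()
    if dmax == 0.0:
        return 0.0, 1.0
    return dmax, effective_volume(dvh, params.n_vol)


def ntcp_lyman_dvh(dvh: DifferentialDVH, params: LymanParams) -> float:
    """Lyman NTCP of an inhomogeneous DVH via effective-volume reduction."""
    dose, veff = _lyman_reduce(dvh, params)
    return ntcp_lyman_uniform(dose, veff, params)


def log_ntcp_lyman_dvh(dvh: DifferentialDVH, params: LymanParams) -> float:
    """Log of :func:`ntcp_lyman_dvh`."""
    dose, veff = _lyman_reduce(dvh, params)
    return log_ntcp_lyman_uniform(dose, veff, params)
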