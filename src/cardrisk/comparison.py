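"""Patient-level pipeline: dose inputs -> RR, NTCP, RRR and RNTCP.

A :class:`Case` bundles everything needed to compare one patient's proton
and photon plans: the mean-dose table (primary absorbed dose, stray
neutron equivalent dose, and the total equivalent dose per structure and
modality), optional differential DVHs, the fractionation scheme, and the
radiation weighting factors.

:func:`run_case` then produces, per structure,

* the linear-model relative risk for each modality from the *total* mean
  equivalent dose (w̄R-weighted primary plus scaled stray for protons; the
  TPS mean for photons, whose stray component is already inside the
  planned dose), and their ratio RRR = RR_proton / RR_photon;
* for every applicable NTCP parameter set, the NTCP of each modality from
  the DVH pipeline (weighting -> uniform neutron shift -> EQD2 -> model)
  and the ratio RNTCP = NTCP_proton / NTCP_photon.

When the dose table carries a pre-tabulated total equivalent dose (the
printed patient dose tables are quoted to 2 decimals) and the neutron
scale is nominal, that tabulated value is used directly for the RR
computation, so results round exactly as the source tables do; sweeps
with a non-nominal neutron scale always recompute the total from its
components at full precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .dvh import DifferentialDVH
from .models import (
    LinearRiskParams,
    RiskEstimate,
    log_ntcp_lyman_dvh,
    log_ntcp_relative_seriality,
    ntcp_lyman_dvh,
    ntcp_relative_seriality,
    relative_risk,
)
from .params import ParameterSet, parameter_sets
from .radiobiology import (
    FractionationScheme,
    WeightingFactors,
    add_uniform_dose,
    eqd2_correct,
    total_mean_equivalent_dose,
    weight_dvh,
)

__all__ = [
    "StructureDose",
    "Case",
    "StructureRisk",
    "ComparisonResult",
    "compute_rrr",
    "compute_rntcp",
    "run_case",
    "processed_dvhs",
    "round_half_up",
    "EPS_NTCP",
]

logger = logging.getLogger(__name__)

#: probabilities below this are treated as zero when forming NTCP ratios
EPS_NTCP = 1e-12

#: tolerance when cross-checking tabulated vs recomputed equivalent doses
#: (the dose tables are quoted to 2 decimals, so half a unit in the last
#: digit plus a little slack for the reconstructed neutron wR)
_TABLE_TOL = 0.011


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up after suppressing sub-ULP float noise.

    Used only in the presentation layer; all comparisons are carried at
    full precision internally.
    """
    if not math.isfinite(x):
        return x
    snapped = repr(round(x, ndigits + 7))
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(snapped).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StructureDose:
    """Mean doses for one structure under one modality.

    ``primary_mean_gy`` is the TPS mean absorbed dose (for protons quoted
    in Gy (RBE)/1.1, i.e. the unweighted absorbed dose).  Stray fields are
    zero for photons, whose out-of-field dose is already in the TPS dose.
    ``total_equivalent_sv``, when given, is the tabulated total mean
    equivalent dose used for RR at nominal neutron scaling.
    """

    structure: str
    modality: str  # "proton" | "photon"
    primary_mean_gy: float
    stray_mean_absorbed_gy: float = 0.0
    stray_mean_equivalent_sv: float = 0.0
    total_equivalent_sv: float | None = None
    dvh: DifferentialDVH | None = None

    def __post_init__(self) -> None:
        if self.modality not in ("proton", "photon"):
            raise ValueError(f"unknown modality {self.modality!r}")
        for name in ("primary_mean_gy", "stray_mean_absorbed_gy", "stray_mean_equivalent_sv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class Case:
    """One patient's paired proton/photon dose description."""

    patient: str
    fractionation: FractionationScheme
    weighting: WeightingFactors
    doses: tuple[StructureDose, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(self.doses))
        seen = set()
        for sd in self.doses:
            key = (sd.structure, sd.modality)
            if key in seen:
                raise ValueError(f"duplicate dose entry for {key}")
            seen.add(key)
        self.validate_consistency()

    def validate_consistency(self) -> None:
        w = self.weighting
        for sd in self.doses:
            if sd.modality != "proton":
                continue
            if w.wr_neutron is not None and sd.stray_mean_absorbed_gy > 0:
                implied = sd.stray_mean_absorbed_gy * w.wr_neutron
                if abs(implied - sd.stray_mean_equivalent_sv) > _TABLE_TOL:
                    raise ValueError(
                        f"{sd.structure}: stray equivalent dose "
                        f"{sd.stray_mean_equivalent_sv} Sv inconsistent with "
                        f"absorbed {sd.stray_mean_absorbed_gy} Gy x wR {w.wr_neutron}"
                    )
            if sd.total_equivalent_sv is not None:
                computed = total_mean_equivalent_dose(
                    sd.primary_mean_gy, w.wr_proton_primary, sd.stray_mean_equivalent_sv
                )
                if abs(computed - sd.total_equivalent_sv) > _TABLE_TOL:
                    raise ValueError(
                        f"{sd.structure}: tabulated total {sd.total_equivalent_sv} Sv "
                        f"inconsistent with recomputed {computed:.4f} Sv"
                    )

    # -- access helpers ------------------------------------------------
    def structures(self) -> tuple[str, ...]:
        out: list[str] = []
        for sd in self.doses:
            if sd.structure not in out:
                out.append(sd.structure)
        return tuple(out)

    def dose(self, structure: str, modality: str) -> StructureDose:
        for sd in self.doses:
            if sd.structure == structure and sd.modality == modality:
                return sd
        raise KeyError(f"no dose entry for ({structure}, {modality})")

    def with_weighting(self, weighting: WeightingFactors) -> "Case":
        return replace(self, weighting=weighting)

    def total_equivalent(self, structure: str, modality: str) -> float:
        """Total mean equivalent dose (Sv) entering the RR computation."""
        sd = self.dose(structure, modality)
        w = self.weighting
        if modality == "photon":
            if sd.total_equivalent_sv is not None:
                return sd.total_equivalent_sv
            return w.wr_photon * sd.primary_mean_gy
        if sd.total_equivalent_sv is not None and w.neutron_scale == 1.0:
            return sd.total_equivalent_sv
        return total_mean_equivalent_dose(
            sd.primary_mean_gy,
            w.wr_proton_primary,
            sd.stray_mean_equivalent_sv,
            w.neutron_scale,
        )


# ---------------------------------------------------------------------------
# ratios

def compute_rrr(rr_proton: float, rr_photon: float) -> float:
    """RRR = RR_proton / RR_photon."""
    if not rr_photon > 0:
        raise ValueError("photon RR must be positive")
    return rr_proton / rr_photon


def compute_rntcp(
    ntcp_proton: float, ntcp_photon: float, eps: float = EPS_NTCP
) -> tuple[float, str]:
    """RNTCP = NTCP_proton / NTCP_photon with zero-probability flagging.

    Returns ``(value, flag)``: when both probabilities are below ``eps``
    the ratio is reported as 0 with flag ``both_zero`` (the convention of
    the source risk tables); when only the photon NTCP vanishes there is
    no finite ratio and ``inf`` is returned with flag ``photon_zero``.
    """
    if not (0 <= ntcp_proton <= 1 and 0 <= ntcp_photon <= 1):
        raise ValueError("NTCP inputs must be probabilities in [0, 1]")
    if ntcp_proton < eps and ntcp_photon < eps:
        return 0.0, "both_zero"
    if ntcp_photon < eps:
        return math.inf, "photon_zero"
    return ntcp_proton / ntcp_photon, "ok"


# ---------------------------------------------------------------------------
# DVH preparation

def processed_dvhs(
    case: Case, structure: str
) -> tuple[DifferentialDVH, DifferentialDVH]:
    """EQD2-corrected equivalent-dose DVHs (proton, photon) for a structure.

    Proton: primary DVH (Gy (RBE), tagged Sv; a Gy-tagged DVH is weighted
    by w̄R first) -> uniform neutron equivalent-dose shift (scaled) ->
    per-bin EQD2.  Photon: TPS DVH -> w̄R = 1 weighting -> per-bin EQD2.
    """
    scheme = case.fractionation
    w = case.weighting

    sd_p = case.dose(structure, "proton")
    sd_ph = case.dose(structure, "photon")
    if sd_p.dvh is None or sd_ph.dvh is None:
        raise ValueError(f"NTCP for {structure!r} requested but a DVH is missing")

    proton = sd_p.dvh
    if proton.dose_unit == "Gy":
        proton = weight_dvh(proton, w.wr_proton_primary)
    proton = add_uniform_dose(proton, w.neutron_scale * sd_p.stray_mean_equivalent_sv)
    proton = eqd2_correct(proton, scheme)

    photon = sd_ph.dvh
    if photon.dose_unit == "Gy":
        photon = weight_dvh(photon, w.wr_photon)
    photon = eqd2_correct(photon, scheme)
    return proton, photon


# ---------------------------------------------------------------------------
# results

@dataclass(frozen=True)
class StructureRisk:
    """Linear-model relative risks for one structure."""

    structure: str
    dose_proton_sv: float
    dose_photon_sv: float
    rr_proton: RiskEstimate
    rr_photon: RiskEstimate
    rrr: float


@dataclass(frozen=True)
class ComparisonResult:
    """Full output of :func:`run_case`.

    ``rr`` maps structure name to :class:`StructureRisk`; ``ntcp`` is a
    long-form table with one row per (structure, parameter set).
    """

    patient: str
    rr: dict[str, StructureRisk]
    ntcp: pd.DataFrame = field(default_factory=pd.DataFrame)

    def rr_frame(self) -> pd.DataFrame:
        rows = []
        for sr in self.rr.values():
            rows.append(
                {
                    "patient": self.patient,
                    "structure": sr.structure,
                    "dose_proton_sv": sr.dose_proton_sv,
                    "dose_photon_sv": sr.dose_photon_sv,
                    "rr_proton": sr.rr_proton.value,
                    "rr_proton_lo": sr.rr_proton.ci_low,
                    "rr_proton_hi": sr.rr_proton.ci_high,
                    "rr_photon": sr.rr_photon.value,
                    "rr_photon_lo": sr.rr_photon.ci_low,
                    "rr_photon_hi": sr.rr_photon.ci_high,
                    "rrr": sr.rrr,
                }
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Machine-readable flat table (full precision) for CSV export."""
        rr = self.rr_frame()
        rr.insert(1, "kind", "rr")
        if self.ntcp.empty:
            return rr
        ntcp = self.ntcp.copy()
        ntcp.insert(0, "patient", self.patient)
        ntcp.insert(1, "kind", "ntcp")
        return pd.concat([rr, ntcp], ignore_index=True)

    def to_text(self) -> str:
        """Aligned human-readable report, rounded as in clinical tables."""
        lines = [f"Patient {self.patient}: linear-model relative risk (mean equivalent dose)"]
        fmt = "  {:<14} RRp={:>6} ({}, {})  RRph={:>6} ({}, {})  RRR={:>5}"
        for sr in self.rr.values():
            lines.append(
                fmt.format(
                    sr.structure,
                    round_half_up(sr.rr_proton.value),
                    round_half_up(sr.rr_proton.ci_low),
                    round_half_up(sr.rr_proton.ci_high),
                    round_half_up(sr.rr_photon.value),
                    round_half_up(sr.rr_photon.ci_low),
                    round_half_up(sr.rr_photon.ci_high),
                    round_half_up(sr.rrr),
                )
            )
        if not self.ntcp.empty:
            lines.append("NTCP models")
            for _, row in self.ntcp.iterrows():
                if row["report_absolute"]:
                    detail = (
                        f"NTCPp={100 * row['ntcp_proton']:.2f}% "
                        f"NTCPph={100 * row['ntcp_photon']:.2f}% "
                    )
                else:
                    detail = ""
                rn = row["rntcp"]
                rn_txt = f"{rn:.2g}" if np.isfinite(rn) else "inf"
                lines.append(
                    f"  {row['structure']:<14} {row['key']:<24} {detail}RNTCP={rn_txt}"
                    + (f" [{row['flag']}]" if row["flag"] != "ok" else "")
                )
        return "\n".join(lines)


def run_case(
    case: Case,
    linear: LinearRiskParams | None = None,
    param_sets: tuple[ParameterSet, ...] | None = None,
    eps: float = EPS_NTCP,
    report_absolute_all: bool = False,
) -> ComparisonResult:
    """Run the full RR + NTCP comparison for one patient case.

    RR is computable from the mean-dose table alone; NTCP rows are emitted
    only for structures with DVHs on both modalities and are restricted to
    parameter sets matching the structure.  Deterministic given fixed
    inputs.
    """
    linear = linear or LinearRiskParams()
    logger.info(
        "run_case patient=%s fractions=%d alpha_beta=%s wr=(%s, %s, %s) scale=%s alpha1=%s",
        case.patient,
        case.fractionation.n_fractions,
        case.fractionation.alpha_beta,
        case.weighting.wr_proton_primary,
        case.weighting.wr_photon,
        case.weighting.wr_neutron,
        case.weighting.neutron_scale,
        linear.alpha1,
    )

    rr: dict[str, StructureRisk] = {}
    ntcp_rows: list[dict] = []
    for structure in case.structures():
        try:
            sd_p = case.dose(structure, "proton")
            sd_ph = case.dose(structure, "photon")
        except KeyError:
            continue
        d_p = case.total_equivalent(structure, "proton")
        d_ph = case.total_equivalent(structure, "photon")
        rr_p = relative_risk(d_p, linear)
        rr_ph = relative_risk(d_ph, linear)
        rr[structure] = StructureRisk(
            structure, d_p, d_ph, rr_p, rr_ph, compute_rrr(rr_p.value, rr_ph.value)
        )

        if sd_p.dvh is None or sd_ph.dvh is None:
            continue
        proton_dvh, photon_dvh = processed_dvhs(case, structure)
        sets = param_sets if param_sets is not None else parameter_sets(structure)
        for ps in sets:
            if ps.structure != structure:
                continue
            logger.info("  NTCP %s via %s (%s)", structure, ps.key, ps.model)
            if ps.model == "rs":
                n_p = ntcp_relative_seriality(proton_dvh, ps.params)
                n_ph = ntcp_relative_seriality(photon_dvh, ps.params)
                log_p = log_ntcp_relative_seriality(proton_dvh, ps.params)
                log_ph = log_ntcp_relative_seriality(photon_dvh, ps.params)
            else:
                n_p = ntcp_lyman_dvh(proton_dvh, ps.params)
                n_ph = ntcp_lyman_dvh(photon_dvh, ps.params)
                log_p = log_ntcp_lyman_dvh(proton_dvh, ps.params)
                log_ph = log_ntcp_lyman_dvh(photon_dvh, ps.params)
            rntcp, flag = compute_rntcp(n_p, n_ph, eps)
            ntcp_rows.append(
                {
                    "structure": structure,
                    "model": ps.model,
                    "key": ps.key,
                    "source": ps.source,
                    "ntcp_proton": n_p,
                    "ntcp_photon": n_ph,
                    "log_ntcp_proton": log_p,
                    "log_ntcp_photon": log_ph,
                    "rntcp": rntcp,
                    "flag": flag,
                    "report_absolute": report_absolute_all or ps.report_absolute,
                }
            )
    return ComparisonResult(case.patient, rr, pd.DataFrame(ntcp_rows))
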