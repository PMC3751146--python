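"""Dose corrections applied before risk modelling.

Three physical bookkeeping steps sit between a treatment-planning DVH and
a dose-response model:

1. **Radiation weighting** — absorbed dose D_T (Gy) times a mean radiation
   weighting factor w̄R gives equivalent dose H_T (Sv).  Therapeutic proton
   fields use w̄R = 1.1 (i.e. doses quoted in Gy (RBE)), photon fields 1.0,
   and stray neutrons a patient-specific factor of order 10 that enters as
   a configuration input.
2. **Uniform stray-dose addition** — the secondary neutron field inside
   the patient is spatially nearly uniform, so its mean equivalent dose is
   added as a rigid shift of the primary proton DVH's dose axis.
3. **EQD2 correction** — each DVH bin is converted to the biologically
   equivalent dose delivered at 2 Gy per fraction using the linear
   quadratic model, EQD2_i = D_i (d_i + α/β) / (2 + α/β) with per-bin dose
   per fraction d_i = D_i / n_fractions and α/β = 3 Gy for cardiac late
   effects.

The per-bin d_i convention assumes each subvolume receives its bin dose
spread evenly over all fractions, the standard DVH-wise LQ practice.
Applying the LQ correction after the neutron shift operates on an
Sv-valued axis; this is a documented approximation (the alternative,
correcting only the primary component, is available by reordering calls).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dvh import DifferentialDVH, DVHError

__all__ = [
    "FractionationScheme",
    "WeightingFactors",
    "UnitMismatchError",
    "equivalent_dose",
    "total_mean_equivalent_dose",
    "weight_dvh",
    "add_uniform_dose",
    "eqd2_correct",
]


class UnitMismatchError(DVHError):
    """Gy/Sv mixed without an explicit weighting step."""


@dataclass(frozen=True)
class FractionationScheme:
    """Fraction count and LQ tissue parameters for one treatment course.

    The study cases use 18 fractions (mediastinal HD course, 36 Gy) and 13
    fractions (craniospinal MB course, 23.4 Gy); alpha_beta = 3 Gy for late
    cardiac effects; the reference schedule is 2 Gy per fraction.
    """

    n_fractions: int
    alpha_beta: float = 3.0
    reference_dose_per_fraction: float = 2.0

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if not self.alpha_beta > 0:
            raise ValueError("alpha_beta must be positive")
        if not self.reference_dose_per_fraction > 0:
            raise ValueError("reference_dose_per_fraction must be positive")


@dataclass(frozen=True)
class WeightingFactors:
    """Mean radiation weighting factors w̄R per field type.

    ``wr_neutron`` is patient specific (obtained from Monte Carlo transport
    elsewhere; here a config input).  ``neutron_scale`` is a dimensionless
    multiplier on the stray neutron equivalent dose used by the wR
    sensitivity sweep; 1 is the nominal value.
    """

    wr_proton_primary: float = 1.1
    wr_photon: float = 1.0
    wr_neutron: float | None = None
    neutron_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("wr_proton_primary", "wr_photon", "neutron_scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.wr_neutron is not None and not self.wr_neutron > 0:
            raise ValueError("wr_neutron must be positive")


def equivalent_dose(organ_dose: float, wr: float) -> float:
    """H_T = w̄R x D_T: absorbed organ dose (Gy) to equivalent dose (Sv)."""
    if organ_dose < 0:
        raise ValueError("organ dose must be non-negative")
    if wr < 0:
        raise ValueError("weighting factor must be non-negative")
    return wr * organ_dose


def total_mean_equivalent_dose(
    primary: float,
    wr_primary: float,
    stray_equivalent: float,
    neutron_scale: float = 1.0,
) -> float:
    """Total mean equivalent dose: w̄R·D_primary + scale·H_stray (Sv).

    `primary` is the mean absorbed primary dose in Gy, `stray_equivalent`
    the mean stray (neutron) equivalent dose already in Sv.
    """
    if primary < 0 or stray_equivalent < 0:
        raise ValueError("doses must be non-negative")
    if neutron_scale < 0:
        raise ValueError("neutron_scale must be non-negative")
    return wr_primary * primary + neutron_scale * stray_equivalent


def weight_dvh(dvh: DifferentialDVH, wr: float) -> DifferentialDVH:
    """Convert a Gy-valued DVH to equivalent dose by scaling the dose axis."""
    if dvh.dose_unit != "Gy":
        raise UnitMismatchError("weight_dvh expects an absorbed-dose (Gy) DVH")
    if not wr > 0:
        raise ValueError("weighting factor must be positive")
    bw = None if dvh.bin_width is None else dvh.bin_width * wr
    return DifferentialDVH(dvh.structure, "Sv", dvh.doses * wr, dvh.volumes, bw)


def add_uniform_dose(dvh: DifferentialDVH, shift: float) -> DifferentialDVH:
    """Shift every bin center up by a spatially uniform equivalent dose.

    The DVH must already be in equivalent-dose units (Sv); volumes are
    unchanged and the mean dose increases by exactly `shift`.
    """
    if dvh.dose_unit != "Sv":
        raise UnitMismatchError(
            "uniform stray equivalent dose can only be added to an Sv-valued DVH; "
            "apply weight_dvh first"
        )
    if shift < 0:
        raise ValueError("shift must be non-negative")
    if shift == 0:
        return dvh
    return dvh.with_doses(dvh.doses + shift, dvh.bin_width)


def eqd2_correct(dvh: DifferentialDVH, scheme: FractionationScheme) -> DifferentialDVH:
    """Per-bin linear-quadratic correction to the 2 Gy/fraction schedule.

    Each bin dose D_i maps to D_i (d_i + α/β) / (d_ref + α/β) with
    d_i = D_i / n_fractions.  The map is strictly increasing in D_i, so bin
    ordering is preserved, but spacing becomes non-uniform; the result
    therefore carries ``bin_width=None``.  It is the identity exactly where
    d_i equals the reference dose per fraction.
    """
    d_i = dvh.doses / scheme.n_fractions
    factor = (d_i + scheme.alpha_beta) / (scheme.reference_dose_per_fraction + scheme.alpha_beta)
    new_doses = dvh.doses * factor
    if np.allclose(new_doses, dvh.doses, rtol=0.0, atol=0.0):
        return dvh
    return dvh.with_doses(new_doses, None)
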