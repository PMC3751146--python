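"""Synthetic DVHs and dose tables emulating the two study cases.

The original treatment-planning DVHs are not publicly deposited, so this
module generates differential DVHs whose *mean* doses match the published
per-structure dose table exactly, with heuristic but radiotherapy-shaped
dose distributions:

* **HD (mediastinal Hodgkin field)** — a bimodal ("two-level") heart DVH:
  a hot in-field component near the prescription dose plus a colder
  scatter/penumbra component, for both modalities.
* **MB photon (craniospinal exit dose)** — a broad unimodal distribution
  of moderate exit dose through the heart.
* **MB proton** — near-zero primary dose (>95% of the heart volume below
  1 Gy), to which the pipeline later adds the uniform stray neutron bath.

Shapes are free modelling choices; only the mean doses are anchored to
the published table (enforced exactly by a final affine rescale of the
dose axis, which keeps generation deterministic).  Absolute NTCP values
computed on these fixtures are therefore order-of-magnitude stand-ins,
while mean-dose quantities (RR, RRR, equivalent-dose bookkeeping) are
exact; see docs/methods.md.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .comparison import Case, StructureDose
from .dvh import DifferentialDVH, rebin
from .radiobiology import FractionationScheme, WeightingFactors

__all__ = [
    "GeneratorSettings",
    "DVHShape",
    "StructureTemplate",
    "CaseTemplate",
    "generate_dvh",
    "build_case",
    "build_dose_table_case",
    "hd_template",
    "mb_template",
    "case_template",
    "perturb_contour_variant",
]


@dataclass(frozen=True)
class GeneratorSettings:
    """Reproducibility and discretisation knobs for DVH synthesis."""

    seed: int = 0
    bin_width: float = 0.05  # Gy; default DVH export resolution
    mean_tolerance: float = 0.005  # relative guard on the achieved mean

    def __post_init__(self) -> None:
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")
        if not self.mean_tolerance > 0:
            raise ValueError("mean_tolerance must be positive")


@dataclass(frozen=True)
class DVHShape:
    """Shape family of a synthetic differential DVH.

    ``kind`` is ``uniform`` (all volume at one dose), ``logistic``
    (unimodal, logistic-cumulative with scale ``heterogeneity`` in Gy) or
    ``two_level`` (mixture of a hot logistic bump at ``hot_dose``
    containing ``hot_fraction`` of the volume and a colder bump placed so
    the target mean is met).
    """

    kind: str
    heterogeneity: float = 0.0
    hot_fraction: float | None = None
    hot_dose: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "logistic", "two_level"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be non-negative")
        if self.kind == "two_level":
            if self.hot_fraction is None or self.hot_dose is None:
                raise ValueError("two_level shape needs hot_fraction and hot_dose")
            if not 0 < self.hot_fraction < 1:
                raise ValueError("hot_fraction must be in (0, 1)")
            if not self.hot_dose > 0:
                raise ValueError("hot_dose must be positive")


def _substream(settings: GeneratorSettings, label: str) -> np.random.Generator:
    """Independent, label-stable random stream derived from the master seed."""
    return np.random.default_rng([settings.seed, zlib.crc32(label.encode())])


def _logistic_weights(centers: np.ndarray, mu: float, scale: float) -> np.ndarray:
    z = (centers - mu) / scale
    # logistic pdf ~ sech^2(z/2); computed stably via exp of -|z|
    e = np.exp(-np.abs(z))
    return e / (1.0 + e) ** 2


def generate_dvh(
    target_mean: float,
    shape: DVHShape,
    settings: GeneratorSettings,
    *,
    structure: str = "organ",
    dose_unit: str = "Gy",
) -> DifferentialDVH:
    """Generate a valid differential DVH with the requested mean dose.

    The mean is enforced exactly (up to float rounding) by an affine
    rescale of the dose axis after shaping, so the generator is both
    deterministic given ``settings.seed`` and mean-accurate well within
    ``settings.mean_tolerance``.  A small seeded jitter on the shape
    location/scale makes distinct seeds produce distinct (but equally
    valid) histograms.
    """
    if target_mean < 0:
        raise ValueError("target mean must be non-negative")
    w = settings.bin_width
    if target_mean == 0 or shape.kind == "uniform":
        return DifferentialDVH(structure, dose_unit, [target_mean], [1.0], w)

    rng = _substream(settings, f"{structure}:{shape.kind}:{target_mean!r}")
    jitter = 1.0 + 0.02 * rng.standard_normal()
    scale = max(shape.heterogeneity * (1.0 + 0.05 * abs(rng.standard_normal())), w)

    if shape.kind == "logistic":
        mu = target_mean * jitter
        upper = mu + 10.0 * scale
        n_bins = int(np.ceil(upper / w))
        centers = (np.arange(n_bins) + 0.5) * w
        vols = _logistic_weights(centers, mu, scale)
    else:  # two_level
        f, hot = shape.hot_fraction, shape.hot_dose
        cold = (target_mean - f * hot) / (1.0 - f)
        if cold < 0:
            raise ValueError(
                f"infeasible two_level shape: hot_fraction {f} at {hot} "
                f"already exceeds target mean {target_mean}"
            )
        hot_mu = hot * jitter
        cold_mu = max(cold * jitter, 0.0)
        upper = hot_mu + 8.0 * scale
        n_bins = int(np.ceil(upper / w))
        centers = (np.arange(n_bins) + 0.5) * w
        vols = f * _logistic_weights(centers, hot_mu, scale)
        vols += (1.0 - f) * _logistic_weights(centers, cold_mu, scale)

    vols = vols / vols.sum()
    achieved = float(np.dot(vols, centers))
    k = target_mean / achieved
    dvh = DifferentialDVH(structure, dose_unit, centers * k, vols, w * k)
    rel_err = abs(dvh.mean_dose() - target_mean) / target_mean
    if rel_err > settings.mean_tolerance:
        raise RuntimeError(f"generated mean off target by {rel_err:.2%}")
    return dvh


# ---------------------------------------------------------------------------
# case templates

@dataclass(frozen=True)
class StructureTemplate:
    """Published mean doses plus DVH shape choices for one structure."""

    name: str
    proton_primary_gy: float
    proton_stray_absorbed_gy: float
    proton_stray_sv: float
    proton_total_sv: float
    photon_gy: float
    proton_shape: DVHShape
    photon_shape: DVHShape


@dataclass(frozen=True)
class CaseTemplate:
    """Everything needed to synthesise one patient case."""

    patient: str
    n_fractions: int
    wr_neutron: float
    structures: tuple[StructureTemplate, ...]
    alpha_beta: float = 3.0
    wr_proton_primary: float = 1.1
    wr_photon: float = 1.0


def hd_template() -> CaseTemplate:
    """Mediastinal Hodgkin-disease case: in-field heart, 36 Gy (RBE)/18 fx.

    Mean doses are the published per-structure values; the neutron w̄R is
    reconstructed from the tabulated stray dose ratio (equivalent/absorbed
    ~ 0.66/0.078 ≈ 8.5) and is not an authoritative measurement.  Both
    modalities use bimodal in-field/out-of-field DVH shapes.
    """
    shape_p = DVHShape("two_level", heterogeneity=1.5, hot_fraction=0.25, hot_dose=33.0)
    shape_ph = DVHShape("two_level", heterogeneity=1.5, hot_fraction=0.30, hot_dose=34.0)
    return CaseTemplate(
        patient="HD",
        n_fractions=18,
        wr_neutron=0.66 / 0.078,  # reconstructed, not authoritative
        structures=(
            StructureTemplate("pericardium", 11.15, 0.081, 0.69, 12.96, 14.26, shape_p, shape_ph),
            StructureTemplate("myocardium", 9.05, 0.077, 0.65, 10.60, 12.23, shape_p, shape_ph),
            StructureTemplate("whole_heart", 8.90, 0.078, 0.66, 10.45, 12.28, shape_p, shape_ph),
        ),
    )


def mb_template() -> CaseTemplate:
    """Craniospinal medulloblastoma case: exit dose only, 23.4 Gy/13 fx.

    Photon DVHs are broad moderate exit-dose distributions; proton primary
    DVHs are near zero (>95% of volume below 1 Gy) with the uniform
    neutron bath added later by the pipeline.
    """
    return CaseTemplate(
        patient="MB",
        n_fractions=13,
        wr_neutron=0.26 / 0.032,  # reconstructed, not authoritative
        structures=(
            StructureTemplate(
                "pericardium", 0.55, 0.032, 0.26, 0.87, 10.59,
                DVHShape("logistic", heterogeneity=0.25),
                DVHShape("logistic", heterogeneity=2.5),
            ),
            StructureTemplate(
                "myocardium", 0.13, 0.033, 0.26, 0.40, 11.72,
                DVHShape("logistic", heterogeneity=0.08),
                DVHShape("logistic", heterogeneity=2.5),
            ),
            StructureTemplate(
                "whole_heart", 0.19, 0.032, 0.26, 0.47, 12.31,
                DVHShape("logistic", heterogeneity=0.15),
                DVHShape("logistic", heterogeneity=2.5),
            ),
        ),
    )


def case_template(name: str) -> CaseTemplate:
    """Shipped template by patient label (``HD`` or ``MB``)."""
    name = name.upper()
    if name == "HD":
        return hd_template()
    if name == "MB":
        return mb_template()
    raise KeyError(f"unknown case template {name!r}; shipped templates: HD, MB")


def build_case(template: CaseTemplate, settings: GeneratorSettings | None = None) -> Case:
    """Materialise a template into a run-ready :class:`Case` with DVHs.

    Proton DVHs are generated on the Gy (RBE) axis (unit ``Sv``) with mean
    w̄R x primary absorbed dose; photon DVHs on the Gy axis with the TPS
    mean.  The tabulated total equivalent doses are attached so that RR
    reproduces the published dose-table arithmetic exactly.
    """
    settings = settings or GeneratorSettings()
    doses: list[StructureDose] = []
    for st in template.structures:
        proton_dvh = generate_dvh(
            template.wr_proton_primary * st.proton_primary_gy,
            st.proton_shape,
            settings,
            structure=f"{st.name}_proton",
            dose_unit="Sv",
        )
        photon_dvh = generate_dvh(
            st.photon_gy,
            st.photon_shape,
            settings,
            structure=f"{st.name}_photon",
            dose_unit="Gy",
        )
        doses.append(
            StructureDose(
                structure=st.name,
                modality="proton",
                primary_mean_gy=st.proton_primary_gy,
                stray_mean_absorbed_gy=st.proton_stray_absorbed_gy,
                stray_mean_equivalent_sv=st.proton_stray_sv,
                total_equivalent_sv=st.proton_total_sv,
                dvh=proton_dvh,
            )
        )
        doses.append(
            StructureDose(
                structure=st.name,
                modality="photon",
                primary_mean_gy=st.photon_gy,
                dvh=photon_dvh,
            )
        )
    return Case(
        patient=template.patient,
        fractionation=FractionationScheme(template.n_fractions, template.alpha_beta),
        weighting=WeightingFactors(
            template.wr_proton_primary, template.wr_photon, template.wr_neutron
        ),
        doses=tuple(doses),
    )


def build_dose_table_case(template: CaseTemplate) -> Case:
    """Materialise a template's mean-dose table only (no DVHs).

    Relative risks and their ratios need only mean equivalent doses, so a
    means-only case suffices to reproduce the published RR/RRR arithmetic;
    NTCP requests on such a case raise an explicit error.
    """
    doses: list[StructureDose] = []
    for st in template.structures:
        doses.append(
            StructureDose(
                structure=st.name,
                modality="proton",
                primary_mean_gy=st.proton_primary_gy,
                stray_mean_absorbed_gy=st.proton_stray_absorbed_gy,
                stray_mean_equivalent_sv=st.proton_stray_sv,
                total_equivalent_sv=st.proton_total_sv,
            )
        )
        doses.append(
            StructureDose(structure=st.name, modality="photon", primary_mean_gy=st.photon_gy)
        )
    return Case(
        patient=template.patient,
        fractionation=FractionationScheme(template.n_fractions, template.alpha_beta),
        weighting=WeightingFactors(
            template.wr_proton_primary, template.wr_photon, template.wr_neutron
        ),
        doses=tuple(doses),
    )


# ---------------------------------------------------------------------------
# contour-variant perturbation

def _mix_dvhs(a: DifferentialDVH, b: DifferentialDVH, weight_a: float) -> DifferentialDVH:
    """Volume-weighted mixture of two DVHs on a common uniform grid."""
    widths = [d.bin_width for d in (a, b) if d.bin_width is not None]
    w = min(widths) if widths else 0.05
    ra, rb = rebin(a, w), rebin(b, w)
    n = max(ra.doses.size, rb.doses.size)
    va = np.zeros(n)
    vb = np.zeros(n)
    va[: ra.doses.size] = ra.volumes
    vb[: rb.doses.size] = rb.volumes
    centers = (np.arange(n) + 0.5) * w
    mixed = weight_a * va + (1.0 - weight_a) * vb
    return DifferentialDVH(a.structure, a.dose_unit, centers, mixed / mixed.sum(), w)


def perturb_contour_variant(case: Case, thickness_factor: float) -> Case:
    """Deterministic alternative case emulating thicker shell contours.

    A shell structure re-contoured ``thickness_factor`` times thicker
    sweeps up tissue from the structure interior; this is emulated at the
    DVH level by volume-weighted mixing: the revised pericardium keeps a
    1/factor share of the original shell DVH and takes the remainder from
    the myocardium DVH, and the revised myocardium likewise mixes toward
    the whole-heart DVH.  Mean-dose entries are updated from the mixed
    DVHs (proton stray components are unchanged).  ``thickness_factor=1``
    is the identity.
    """
    if not thickness_factor >= 1:
        raise ValueError("thickness_factor must be >= 1")
    if thickness_factor == 1:
        return case
    w_orig = 1.0 / thickness_factor
    donors = {"pericardium": "myocardium", "myocardium": "whole_heart"}
    new_doses: list[StructureDose] = []
    for sd in case.doses:
        donor = donors.get(sd.structure)
        if donor is None or sd.dvh is None:
            new_doses.append(sd)
            continue
        donor_dvh = case.dose(donor, sd.modality).dvh
        if donor_dvh is None:
            new_doses.append(sd)
            continue
        mixed = _mix_dvhs(sd.dvh, donor_dvh, w_orig)
        mean = mixed.mean_dose()
        if sd.modality == "proton":
            new_doses.append(
                replace(
                    sd,
                    dvh=mixed,
                    primary_mean_gy=mean / case.weighting.wr_proton_primary,
                    total_equivalent_sv=None,
                )
            )
        else:
            new_doses.append(replace(sd, dvh=mixed, primary_mean_gy=mean))
    return replace(case, doses=tuple(new_doses))
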