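"""Uncertainty analyses: parameter sweeps, neutron-wR scaling, contours.

Three analyses probe how the proton/photon risk ratios respond to what is
genuinely uncertain in the modelling:

* **NTCP-parameter sweeps** — RNTCP evaluated on a full Cartesian grid of
  model parameters (D50, γ, s for relative seriality; TD50, n, m for the
  Lyman model) over their plausible literature ranges, plus named
  min/max presets for the conventional "reasonable combination" summary.
  Ratios are formed in log space so that the extremely small NTCP values
  of out-of-field organs still yield finite, strictly ordered ratios.

* **Neutron-wR scaling** — the stray neutron equivalent dose is scaled by
  a factor f and the mean-dose RRR (and DVH-based RNTCP, when DVHs are
  present) recomputed.  RRR is continuous and strictly increasing in f,
  and crosses 1 exactly at f* = (D_photon − w̄R·D_primary) / H_stray.

* **Contour variants** — the same pipeline re-run on alternative DVH
  inputs representing revised (thicker-shell) structure contours, with
  baseline and variant RNTCP reported side by side.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .comparison import (
    Case,
    ComparisonResult,
    compute_rrr,
    processed_dvhs,
    run_case,
)
from .models import (
    LinearRiskParams,
    LymanParams,
    RSParams,
    log_ntcp_lyman_dvh,
    log_ntcp_relative_seriality,
    relative_risk,
)
from .params import ParameterSet, parameter_sets
from .radiobiology import WeightingFactors

__all__ = [
    "SweepSpec",
    "SweepResult",
    "sweep_parameters",
    "sweep_neutron_wr",
    "rrr_at_scale",
    "rrr_crossing_factor",
    "table2_presets",
    "compare_contour_variants",
    "plot_sweep_surface",
]


@dataclass(frozen=True)
class SweepSpec:
    """A gridded sweep over NTCP parameters for one structure.

    ``axes`` maps parameter names to ordered value grids.  Relative
    seriality (``model="rs"``) accepts ``d50``, ``gamma``, ``s``; the
    Lyman model accepts ``td50``, ``n_vol``, ``m``.  Axes not supplied
    stay at the values of ``baseline`` (a bundled parameter set key or an
    explicit params object).
    """

    structure: str
    model: str  # "rs" | "lyman"
    axes: dict[str, tuple] = field(default_factory=dict)
    baseline: RSParams | LymanParams | None = None

    _RS_AXES = ("d50", "gamma", "s")
    _LYMAN_AXES = ("td50", "n_vol", "m")

    def __post_init__(self) -> None:
        if self.model not in ("rs", "lyman"):
            raise ValueError("model must be 'rs' or 'lyman'")
        valid = self._RS_AXES if self.model == "rs" else self._LYMAN_AXES
        for name, grid in self.axes.items():
            if name not in valid:
                raise ValueError(f"unknown axis {name!r} for {self.model}; valid: {valid}")
            if len(tuple(grid)) == 0:
                raise ValueError(f"axis {name!r} is empty")

    def default_params(self) -> RSParams | LymanParams:
        if self.baseline is not None:
            return self.baseline
        for ps in parameter_sets(self.structure):
            if ps.model == self.model:
                return ps.params
        raise ValueError(f"no bundled {self.model} baseline for {self.structure!r}")


@dataclass(frozen=True)
class SweepResult:
    """Long-form grid table plus min/max summary helpers."""

    table: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Min/max finite RNTCP per structure across the grid."""
        t = self.table[np.isfinite(self.table["rntcp"])]
        return t.groupby("structure")["rntcp"].agg(["min", "max"]).reset_index()


def _params_from(model: str, values: dict) -> RSParams | LymanParams:
    if model == "rs":
        return RSParams(d50=values["d50"], gamma=values["gamma"], s=values["s"])
    return LymanParams(td50_full=values["td50"], n_vol=values["n_vol"], m=values["m"])


def _log_rntcp(proton_dvh, photon_dvh, model, params) -> tuple[float, float, float]:
    if model == "rs":
        lp = log_ntcp_relative_seriality(proton_dvh, params)
        lph = log_ntcp_relative_seriality(photon_dvh, params)
    else:
        lp = log_ntcp_lyman_dvh(proton_dvh, params)
        lph = log_ntcp_lyman_dvh(photon_dvh, params)
    if math.isinf(lp) and math.isinf(lph):
        return lp, lph, 0.0  # both complication-free: ratio reported as 0
    if math.isinf(lph):
        return lp, lph, math.inf
    return lp, lph, math.exp(lp - lph)


def sweep_parameters(case: Case, spec: SweepSpec) -> SweepResult:
    """Evaluate RNTCP on the full Cartesian grid of ``spec.axes``.

    Pure function of the grid point: evaluation order cannot affect
    results.  Grid points outside model validity (s <= 0, m <= 0, ...)
    are skipped with a warning.  A degenerate one-point grid reproduces
    the corresponding baseline RNTCP exactly.
    """
    proton_dvh, photon_dvh = processed_dvhs(case, spec.structure)
    base = spec.default_params()
    base_values = (
        {"d50": base.d50, "gamma": base.gamma, "s": base.s}
        if spec.model == "rs"
        else {"td50": base.td50_full, "n_vol": base.n_vol, "m": base.m}
    )
    names = list(spec.axes)
    grids = [tuple(spec.axes[n]) for n in names]
    rows = []
    for combo in itertools.product(*grids):
        values = dict(base_values)
        values.update(zip(names, combo))
        try:
            params = _params_from(spec.model, values)
        except ValueError as exc:
            warnings.warn(f"skipping grid point {values}: {exc}", stacklevel=2)
            continue
        lp, lph, rntcp = _log_rntcp(proton_dvh, photon_dvh, spec.model, params)
        rows.append(
            {
                "structure": spec.structure,
                "model": spec.model,
                **values,
                "log_ntcp_proton": lp,
                "log_ntcp_photon": lph,
                "rntcp": rntcp,
            }
        )
    return SweepResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# neutron-wR scaling

def rrr_at_scale(
    case: Case,
    factor: float,
    structure: str = "whole_heart",
    linear: LinearRiskParams | None = None,
) -> float:
    """Mean-dose RRR with the stray neutron equivalent dose scaled by ``factor``.

    Always recomputes the proton total from its components (full
    precision), so the curve is continuous in ``factor``.
    """
    scaled = case.with_weighting(
        WeightingFactors(
            case.weighting.wr_proton_primary,
            case.weighting.wr_photon,
            case.weighting.wr_neutron,
            neutron_scale=factor,
        )
    )
    sd = scaled.dose(structure, "proton")
    # bypass the tabulated total even at factor == 1: sweeps are component-based
    d_p = (
        scaled.weighting.wr_proton_primary * sd.primary_mean_gy
        + factor * sd.stray_mean_equivalent_sv
    )
    d_ph = scaled.total_equivalent(structure, "photon")
    lin = linear or LinearRiskParams()
    return compute_rrr(relative_risk(d_p, lin).value, relative_risk(d_ph, lin).value)


def rrr_crossing_factor(case: Case, structure: str = "whole_heart") -> float:
    """Closed-form neutron scale f* at which RRR crosses 1.

    RR is linear in dose, so RRR = 1 exactly when the proton total equals
    the photon dose: w̄R·D_primary + f*·H_stray = D_photon.
    """
    sd = case.dose(structure, "proton")
    d_ph = case.total_equivalent(structure, "photon")
    if sd.stray_mean_equivalent_sv == 0:
        raise ValueError("no stray dose: RRR does not depend on the neutron scale")
    return (d_ph - case.weighting.wr_proton_primary * sd.primary_mean_gy) / (
        sd.stray_mean_equivalent_sv
    )


def sweep_neutron_wr(
    case: Case,
    factors,
    linear: LinearRiskParams | None = None,
    param_sets_: tuple[ParameterSet, ...] | None = None,
) -> SweepResult:
    """RRR (mean doses) and RNTCP (DVHs, when present) per scaling factor.

    Long-form output: one row per (factor, structure, metric), with
    ``metric`` equal to ``"rrr"`` or a parameter-set key for RNTCP rows.
    """
    rows = []
    for factor in factors:
        if factor < 0:
            warnings.warn(f"skipping negative neutron scale {factor}", stacklevel=2)
            continue
        scaled = case.with_weighting(
            WeightingFactors(
                case.weighting.wr_proton_primary,
                case.weighting.wr_photon,
                case.weighting.wr_neutron,
                neutron_scale=factor,
            )
        )
        for structure in case.structures():
            rows.append(
                {
                    "factor": factor,
                    "structure": structure,
                    "metric": "rrr",
                    "value": rrr_at_scale(case, factor, structure, linear),
                }
            )
        has_dvh = any(sd.dvh is not None for sd in case.doses)
        if has_dvh:
            result = run_case(scaled, linear, param_sets_)
            for _, r in result.ntcp.iterrows():
                rows.append(
                    {
                        "factor": factor,
                        "structure": r["structure"],
                        "metric": r["key"],
                        "value": r["rntcp"],
                    }
                )
    return SweepResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# named min/max presets (the "reasonable combinations" convention)

def table2_presets() -> dict[str, dict[str, RSParams | LymanParams]]:
    """Named min/max parameter combinations per structure.

    For the Lyman pericardium the minimum-RNTCP combination is the
    shallow-volume-effect, steep-slope corner (TD50 = 40 Gy, n = 1,
    m = 0.05) and the maximum the opposite corner (80, 0.2, 0.5); for the
    relative-seriality structures min is (D50 = 40, γ = 1.5, s = 0.5) and
    max (80, 0.8, 1).
    """
    rs_min = RSParams(d50=40.0, gamma=1.5, s=0.5)
    rs_max = RSParams(d50=80.0, gamma=0.8, s=1.0)
    return {
        "pericardium": {
            "min": LymanParams(td50_full=40.0, n_vol=1.0, m=0.05),
            "max": LymanParams(td50_full=80.0, n_vol=0.2, m=0.5),
        },
        "myocardium": {"min": rs_min, "max": rs_max},
        "whole_heart": {"min": rs_min, "max": rs_max},
    }


# ---------------------------------------------------------------------------
# contour variants

def compare_contour_variants(
    case_a: Case,
    case_b: Case,
    param_sets_: tuple[ParameterSet, ...] | None = None,
) -> pd.DataFrame:
    """Side-by-side RNTCP for a baseline and a revised-contour case."""
    res_a = run_case(case_a, param_sets=param_sets_)
    res_b = run_case(case_b, param_sets=param_sets_)
    cols = ["structure", "model", "key", "rntcp", "flag"]
    a = res_a.ntcp[cols].rename(columns={"rntcp": "rntcp_baseline", "flag": "flag_baseline"})
    b = res_b.ntcp[cols].rename(columns={"rntcp": "rntcp_revised", "flag": "flag_revised"})
    return a.merge(b, on=["structure", "model", "key"], validate="one_to_one")


# ---------------------------------------------------------------------------
# optional plotting layer

def plot_sweep_surface(result: SweepResult, x: str, y: str, ax=None):
    """Plot log10(RNTCP) over a 2-D slice of a sweep grid (optional layer).

    Requires matplotlib (``pip install cardrisk[plot]``).
    """
    import matplotlib.pyplot as plt  # deferred: plotting is optional

    t = result.table
    pivot = t.pivot_table(index=y, columns=x, values="rntcp", aggfunc="mean")
    if ax is None:
        _, ax = plt.subplots()
    with np.errstate(divide="ignore"):
        z = np.log10(pivot.to_numpy())
    mesh = ax.pcolormesh(pivot.columns.to_numpy(), pivot.index.to_numpy(), z, shading="auto")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.figure.colorbar(mesh, ax=ax, label="log10 RNTCP")
    return ax
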