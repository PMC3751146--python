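"""Bundled NTCP parameter library for cardiac structures.

Each entry pairs a cardiac structure with a published dose-response
parameter set, identified by the clinical population it was fitted on:

* ``hodgkin`` — relative-seriality fits on mediastinal Hodgkin-disease
  outcome data (the only sets considered transferable enough to report
  absolute NTCP values for the HD case);
* ``breast`` — relative-seriality fits from breast-cancer cardiac data;
* ``esophagus`` — a Lyman fit from esophageal-cancer pericarditis data;
* ``historical`` — the classic pooled-tolerance Lyman parameters.

All tolerance doses are in Gy at 2 Gy/fraction (EQD2).  Selection is by
``key`` (CLI / config) or by structure.
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import LymanParams, RSParams

__all__ = ["ParameterSet", "PARAMETER_SETS", "parameter_sets", "get_parameter_set"]


@dataclass(frozen=True)
class ParameterSet:
    """A named (structure, model, parameters) triple from the literature."""

    key: str
    structure: str
    source: str
    model: str  # "rs" | "lyman"
    params: RSParams | LymanParams

    @property
    def report_absolute(self) -> bool:
        """Whether absolute NTCP values are reported for the HD case.

        Only Hodgkin-derived parameter sets are used for absolute values;
        every set still participates in ratio (RNTCP) calculations.
        """
        return self.source == "hodgkin"


PARAMETER_SETS: tuple[ParameterSet, ...] = (
    ParameterSet(
        "pericardium-historical", "pericardium", "historical", "lyman",
        LymanParams(td50_full=48.0, n_vol=0.35, m=0.1),
    ),
    ParameterSet(
        "pericardium-esophagus", "pericardium", "esophagus", "lyman",
        LymanParams(td50_full=50.6, n_vol=0.64, m=0.13),
    ),
    ParameterSet(
        "myocardium-breast", "myocardium", "breast", "rs",
        RSParams(d50=52.2, gamma=1.25, s=0.87),
    ),
    ParameterSet(
        "myocardium-hodgkin", "myocardium", "hodgkin", "rs",
        RSParams(d50=70.3, gamma=0.96, s=1.0),
    ),
    ParameterSet(
        "whole_heart-breast", "whole_heart", "breast", "rs",
        RSParams(d50=52.3, gamma=1.28, s=1.0),
    ),
    ParameterSet(
        "whole_heart-hodgkin-63", "whole_heart", "hodgkin", "rs",
        RSParams(d50=63.3, gamma=0.93, s=1.0),
    ),
    ParameterSet(
        "whole_heart-hodgkin-70", "whole_heart", "hodgkin", "rs",
        RSParams(d50=70.3, gamma=0.96, s=1.0),
    ),
)


def parameter_sets(structure: str | None = None) -> tuple[ParameterSet, ...]:
    """All bundled parameter sets, optionally filtered by structure."""
    if structure is None:
        return PARAMETER_SETS
    return tuple(ps for ps in PARAMETER_SETS if ps.structure == structure)


def get_parameter_set(key: str) -> ParameterSet:
    """Look up a bundled parameter set by its key."""
    for ps in PARAMETER_SETS:
        if ps.key == key:
            return ps
    known = ", ".join(ps.key for ps in PARAMETER_SETS)
    raise KeyError(f"unknown parameter set {key!r}; known keys: {known}")
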