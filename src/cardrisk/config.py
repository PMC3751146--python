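"""YAML case-configuration schema: validation, loading, emission.

A case config is a human-readable YAML file describing one patient
comparison.  All defaults mirror the study's stated modelling choices
(α/β = 3 Gy, w̄R 1.1/1.0, α1 = 0.6 with CI 0.2-2.5)::

    patient: HD
    fractions: 18
    alpha_beta: 3.0
    weighting:
      wr_proton_primary: 1.1
      wr_photon: 1.0
      wr_neutron: 8.46
      neutron_scale: 1.0
    linear_model: {alpha1: 0.6, ci_low: 0.2, ci_high: 2.5}
    parameter_sets: default          # or a list of bundled keys
    structures:
      - name: whole_heart
        proton:
          primary_gy: 8.90
          stray_absorbed_gy: 0.078
          stray_sv: 0.66
          total_sv: 10.45
          dvh: whole_heart_proton.dvh     # optional, relative to the config
        photon:
          mean_gy: 12.28
          dvh: whole_heart_photon.dvh     # optional

Validation errors name the offending schema path.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .comparison import Case, StructureDose
from .dvh import DifferentialDVH, read_dvh, write_dvh
from .models import LinearRiskParams
from .params import PARAMETER_SETS, ParameterSet, get_parameter_set
from .radiobiology import FractionationScheme, WeightingFactors
from .synthetic import CaseTemplate, GeneratorSettings, build_case

__all__ = [
    "ConfigError",
    "load_config",
    "validate_config",
    "case_from_config",
    "load_case",
    "emit_case",
]


class ConfigError(ValueError):
    """A case config violates the schema; message names the schema path."""


def _require(mapping, key, path, types):
    if not isinstance(mapping, dict):
        raise ConfigError(f"{path}: expected a mapping")
    if key not in mapping:
        raise ConfigError(f"{path}.{key}: missing required key")
    value = mapping[key]
    if not isinstance(value, types):
        raise ConfigError(f"{path}.{key}: expected {types}, got {type(value).__name__}")
    return value


def _number(mapping, key, path, default=None, minimum=None):
    if key not in mapping:
        if default is None:
            raise ConfigError(f"{path}.{key}: missing required key")
        return default
    value = mapping[key]
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"{path}.{key}: expected a number")
    if minimum is not None and value < minimum:
        raise ConfigError(f"{path}.{key}: must be >= {minimum}")
    return float(value)


def load_config(path) -> dict:
    """Read and schema-validate a YAML case config."""
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    validate_config(cfg, base_dir=path.parent)
    return cfg


def validate_config(cfg: dict, base_dir: Path | None = None) -> None:
    """Validate schema and (when ``base_dir`` is given) referenced files."""
    _require(cfg, "patient", "config", str)
    fractions = _number(cfg, "fractions", "config", minimum=1)
    if fractions != int(fractions):
        raise ConfigError("config.fractions: must be an integer")
    _number(cfg, "alpha_beta", "config", default=3.0, minimum=1e-9)

    weighting = cfg.get("weighting", {})
    if not isinstance(weighting, dict):
        raise ConfigError("config.weighting: expected a mapping")
    for key in ("wr_proton_primary", "wr_photon", "wr_neutron", "neutron_scale"):
        if key in weighting:
            _number(weighting, key, "config.weighting", minimum=1e-12)

    linear = cfg.get("linear_model", {})
    if not isinstance(linear, dict):
        raise ConfigError("config.linear_model: expected a mapping")
    for key in ("alpha1", "ci_low", "ci_high"):
        if key in linear:
            _number(linear, key, "config.linear_model", minimum=0.0)

    psets = cfg.get("parameter_sets", "default")
    if psets != "default":
        if not isinstance(psets, list):
            raise ConfigError("config.parameter_sets: expected 'default' or a list of keys")
        known = {ps.key for ps in PARAMETER_SETS}
        for i, key in enumerate(psets):
            if key not in known:
                raise ConfigError(
                    f"config.parameter_sets[{i}]: unknown key {key!r}; known: {sorted(known)}"
                )

    structures = _require(cfg, "structures", "config", list)
    if not structures:
        raise ConfigError("config.structures: must not be empty")
    for i, st in enumerate(structures):
        path_i = f"config.structures[{i}]"
        _require(st, "name", path_i, str)
        proton = _require(st, "proton", path_i, dict)
        _number(proton, "primary_gy", f"{path_i}.proton", minimum=0.0)
        _number(proton, "stray_absorbed_gy", f"{path_i}.proton", default=0.0, minimum=0.0)
        _number(proton, "stray_sv", f"{path_i}.proton", default=0.0, minimum=0.0)
        photon = _require(st, "photon", path_i, dict)
        _number(photon, "mean_gy", f"{path_i}.photon", minimum=0.0)
        if base_dir is not None:
            for modality, block in (("proton", proton), ("photon", photon)):
                dvh_path = block.get("dvh")
                if dvh_path is not None and not (base_dir / dvh_path).is_file():
                    raise ConfigError(
                        f"{path_i}.{modality}.dvh: file not found: {base_dir / dvh_path}"
                    )


def case_from_config(
    cfg: dict, base_dir: Path | None = None
) -> tuple[Case, LinearRiskParams, tuple[ParameterSet, ...] | None]:
    """Build a :class:`Case` (plus model selections) from a validated config."""
    validate_config(cfg, base_dir=base_dir)
    weighting_cfg = cfg.get("weighting", {})
    weighting = WeightingFactors(
        wr_proton_primary=_number(weighting_cfg, "wr_proton_primary", "w", default=1.1),
        wr_photon=_number(weighting_cfg, "wr_photon", "w", default=1.0),
        wr_neutron=weighting_cfg.get("wr_neutron"),
        neutron_scale=_number(weighting_cfg, "neutron_scale", "w", default=1.0),
    )
    linear_cfg = cfg.get("linear_model", {})
    linear = LinearRiskParams(
        alpha1=_number(linear_cfg, "alpha1", "l", default=0.6),
        ci_low=_number(linear_cfg, "ci_low", "l", default=0.2),
        ci_high=_number(linear_cfg, "ci_high", "l", default=2.5),
    )
    psets_cfg = cfg.get("parameter_sets", "default")
    psets = (
        None
        if psets_cfg == "default"
        else tuple(get_parameter_set(key) for key in psets_cfg)
    )

    def _load_dvh(block) -> DifferentialDVH | None:
        rel = block.get("dvh")
        if rel is None:
            return None
        dvh = read_dvh((base_dir or Path(".")) / rel)
        if not isinstance(dvh, DifferentialDVH):
            raise ConfigError(f"{rel}: NTCP pipeline needs a differential DVH")
        return dvh

    doses: list[StructureDose] = []
    for st in cfg["structures"]:
        proton, photon = st["proton"], st["photon"]
        doses.append(
            StructureDose(
                structure=st["name"],
                modality="proton",
                primary_mean_gy=proton["primary_gy"],
                stray_mean_absorbed_gy=proton.get("stray_absorbed_gy", 0.0),
                stray_mean_equivalent_sv=proton.get("stray_sv", 0.0),
                total_equivalent_sv=proton.get("total_sv"),
                dvh=_load_dvh(proton),
            )
        )
        doses.append(
            StructureDose(
                structure=st["name"],
                modality="photon",
                primary_mean_gy=photon["mean_gy"],
                dvh=_load_dvh(photon),
            )
        )
    case = Case(
        patient=cfg["patient"],
        fractionation=FractionationScheme(int(cfg["fractions"]), cfg.get("alpha_beta", 3.0)),
        weighting=weighting,
        doses=tuple(doses),
    )
    return case, linear, psets


def load_case(path) -> tuple[Case, LinearRiskParams, tuple[ParameterSet, ...] | None]:
    """Load a case config file and materialise the case."""
    path = Path(path)
    cfg = load_config(path)
    return case_from_config(cfg, base_dir=path.parent)


def emit_case(template: CaseTemplate, settings: GeneratorSettings, out_dir) -> Path:
    """Write synthetic DVH files plus a run-ready ``case.yaml``.

    Returns the path of the written config.  Output is byte-deterministic
    for a fixed template and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    case = build_case(template, settings)
    structures = []
    for st in template.structures:
        files = {}
        for modality in ("proton", "photon"):
            sd = case.dose(st.name, modality)
            fname = f"{st.name}_{modality}.dvh"
            write_dvh(sd.dvh, out_dir / fname)
            files[modality] = fname
        structures.append(
            {
                "name": st.name,
                "proton": {
                    "primary_gy": st.proton_primary_gy,
                    "stray_absorbed_gy": st.proton_stray_absorbed_gy,
                    "stray_sv": st.proton_stray_sv,
                    "total_sv": st.proton_total_sv,
                    "dvh": files["proton"],
                },
                "photon": {"mean_gy": st.photon_gy, "dvh": files["photon"]},
            }
        )
    cfg = {
        "patient": template.patient,
        "fractions": template.n_fractions,
        "alpha_beta": template.alpha_beta,
        "weighting": {
            "wr_proton_primary": template.wr_proton_primary,
            "wr_photon": template.wr_photon,
            "wr_neutron": float(template.wr_neutron),
            "neutron_scale": 1.0,
        },
        "linear_model": {"alpha1": 0.6, "ci_low": 0.2, "ci_high": 2.5},
        "parameter_sets": "default",
        "seed": settings.seed,
        "structures": structures,
    }
    config_path = out_dir / "case.yaml"
    with open(config_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return config_path
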