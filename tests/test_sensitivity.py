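"""Parameter sweeps, neutron-wR scaling and contour-variant comparisons."""

import numpy as np
import pytest
from scipy.optimize import brentq

import cardrisk as cr
from cardrisk.comparison import Case, StructureDose, round_half_up, run_case
from cardrisk.radiobiology import FractionationScheme, WeightingFactors
from cardrisk.sensitivity import (
    SweepSpec,
    rrr_at_scale,
    rrr_crossing_factor,
    sweep_neutron_wr,
    sweep_parameters,
    table2_presets,
)
from cardrisk.synthetic import (
    DVHShape,
    GeneratorSettings,
    generate_dvh,
    perturb_contour_variant,
)


class TestParameterSweep:
    def test_degenerate_grid_reproduces_baseline(self, mb_case):
        spec = SweepSpec(
            structure="whole_heart",
            model="rs",
            axes={"d50": (70.3,), "gamma": (0.96,), "s": (1.0,)},
        )
        res = sweep_parameters(mb_case, spec)
        assert len(res.table) == 1
        baseline = run_case(mb_case).ntcp
        row = baseline[baseline.key == "whole_heart-hodgkin-70"].iloc[0]
        assert res.table["rntcp"].iloc[0] == pytest.approx(row["rntcp"], rel=1e-9)

    def test_invalid_grid_points_skipped_with_warning(self, mb_case):
        spec = SweepSpec(structure="whole_heart", model="rs", axes={"s": (-0.5, 1.0)})
        with pytest.warns(UserWarning, match="skipping"):
            res = sweep_parameters(mb_case, spec)
        assert len(res.table) == 1

    def test_grid_is_pure_function_of_parameters(self, mb_case):
        axes = {"d50": (40.0, 80.0), "gamma": (0.8, 1.5)}
        fwd = sweep_parameters(mb_case, SweepSpec("myocardium", "rs", axes))
        rev = sweep_parameters(
            mb_case,
            SweepSpec("myocardium", "rs", {k: tuple(reversed(v)) for k, v in axes.items()}),
        )
        merged = fwd.table.merge(rev.table, on=["d50", "gamma"], suffixes=("_f", "_r"))
        assert np.allclose(merged["rntcp_f"], merged["rntcp_r"], rtol=0, atol=0)

    def test_summary_brackets_baseline(self, mb_case):
        spec = SweepSpec(
            structure="pericardium",
            model="lyman",
            axes={"m": (0.05, 0.1, 0.5)},  # includes the baseline m = 0.1
        )
        res = sweep_parameters(mb_case, spec)
        summary = res.summary().iloc[0]
        baseline = res.table[res.table.m == 0.1]["rntcp"].iloc[0]
        assert summary["min"] <= baseline <= summary["max"]

    def test_named_min_max_presets_are_ordered(self, mb_case):
        for structure, presets in table2_presets().items():
            model = "lyman" if structure == "pericardium" else "rs"
            lo_hi = []
            for which in ("min", "max"):
                p = presets[which]
                axes = (
                    {"td50": (p.td50_full,), "n_vol": (p.n_vol,), "m": (p.m,)}
                    if model == "lyman"
                    else {"d50": (p.d50,), "gamma": (p.gamma,), "s": (p.s,)}
                )
                res = sweep_parameters(mb_case, SweepSpec(structure, model, axes))
                lo_hi.append(res.table["rntcp"].iloc[0])
            assert lo_hi[0] <= lo_hi[1] < 1.0


class TestNeutronScaling:
    def test_published_scaling_endpoints(self, hd_means):
        assert round_half_up(rrr_at_scale(hd_means, 0.5)) == 0.85
        assert round_half_up(rrr_at_scale(hd_means, 10.0)) == 1.29
        assert round_half_up(rrr_at_scale(hd_means, 1.0)) == 0.87

    def test_rrr_strictly_increasing_in_scale(self, hd_means):
        factors = np.linspace(0.5, 10.0, 40)
        values = [rrr_at_scale(hd_means, f) for f in factors]
        assert np.all(np.diff(values) > 0)

    def test_crossing_factor_matches_closed_form(self, hd_means):
        # RRR = 1 when 1.1 * 8.90 + f * 0.66 equals the photon 12.28 Gy
        expected = (12.28 - 9.79) / 0.66
        assert rrr_crossing_factor(hd_means) == pytest.approx(expected, abs=1e-9)
        numeric = brentq(lambda f: rrr_at_scale(hd_means, f) - 1.0, 0.1, 20.0, xtol=1e-12)
        assert numeric == pytest.approx(expected, abs=1e-9)

    def test_mb_stays_below_unity_across_sweep(self, mb_means):
        res = sweep_neutron_wr(mb_means, [0.5, 1.0, 2.0, 5.0, 10.0])
        rrr = res.table[res.table.metric == "rrr"]
        assert (rrr["value"] < 1.0).all()

    def test_sweep_includes_rntcp_rows_when_dvhs_present(self, mb_case):
        res = sweep_neutron_wr(mb_case, [1.0, 5.0])
        metrics = set(res.table["metric"])
        assert "rrr" in metrics
        assert "whole_heart-hodgkin-70" in metrics
        # more neutron dose can only raise the proton NTCP, hence the ratio
        t = res.table[res.table.metric == "whole_heart-hodgkin-70"].sort_values("factor")
        assert t["value"].is_monotonic_increasing


def _simple_case(dvh_a, dvh_b) -> Case:
    return Case(
        patient="S",
        fractionation=FractionationScheme(13),
        weighting=WeightingFactors(wr_proton_primary=1.0),
        doses=(
            StructureDose(
                "whole_heart",
                "proton",
                dvh_a.mean_dose(),
                total_equivalent_sv=dvh_a.mean_dose(),
                dvh=dvh_a,
            ),
            StructureDose("whole_heart", "photon", dvh_b.mean_dose(), dvh=dvh_b),
        ),
    )


class TestContourVariants:
    def test_identical_cases_give_identical_columns(self, mb_case):
        table = cr.compare_contour_variants(mb_case, mb_case)
        assert np.allclose(table["rntcp_baseline"], table["rntcp_revised"], rtol=0, atol=0)

    def test_factor_one_is_identity(self, mb_case):
        assert perturb_contour_variant(mb_case, 1.0) is mb_case

    def test_thicker_shell_pulls_pericardium_toward_interior(self, mb_case):
        revised = perturb_contour_variant(mb_case, 5.0)
        for modality in ("proton", "photon"):
            orig = mb_case.dose("pericardium", modality).dvh.mean_dose()
            interior = mb_case.dose("myocardium", modality).dvh.mean_dose()
            mixed = revised.dose("pericardium", modality).dvh.mean_dose()
            lo, hi = sorted((orig, interior))
            assert lo - 1e-6 <= mixed <= hi + 1e-6

    def test_mb_revised_rntcp_still_far_below_unity(self, mb_case):
        revised = perturb_contour_variant(mb_case, 5.0)
        table = cr.compare_contour_variants(mb_case, revised)
        finite = table[np.isfinite(table["rntcp_revised"])]
        assert (finite["rntcp_revised"] < 0.5).all()

    def test_swapping_modalities_inverts_the_ratio(self):
        settings = GeneratorSettings(seed=3)
        a = generate_dvh(
            9.0, DVHShape("logistic", 2.0), settings, structure="a", dose_unit="Sv"
        )
        b_gy = generate_dvh(12.0, DVHShape("logistic", 2.5), settings, structure="b")
        b_sv = generate_dvh(
            12.0, DVHShape("logistic", 2.5), settings, structure="b", dose_unit="Sv"
        )
        a_gy = generate_dvh(9.0, DVHShape("logistic", 2.0), settings, structure="a")
        fwd = run_case(_simple_case(a, b_gy)).ntcp
        rev = run_case(_simple_case(b_sv, a_gy)).ntcp
        for key in fwd["key"]:
            f = fwd[fwd.key == key]["rntcp"].iloc[0]
            r = rev[rev.key == key]["rntcp"].iloc[0]
            assert f * r == pytest.approx(1.0, rel=1e-9)
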