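import math

import numpy as np
import pandas as pd
import pytest

from lipidims.cohort import (
    CohortDesign,
    GenerativeModel,
    generate_cohort,
    predicted_ccs_table,
    reference_ccs_table,
    render_mobilogram,
    simulate,
    species_grid,
    true_ccs,
    true_rt,
)
from lipidims.shorthand import Linkage, LipidSpecies, parse_shorthand

from conftest import zero_noise_model


class TestDesign:
    def test_default_layout(self, default_design, default_sim):
        features = default_sim.features
        assert default_design.n_samples == 18
        assert features["sample_id"].nunique() == 18

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            CohortDesign(replicates_per_group=0)
        with pytest.raises(ValueError):
            CohortDesign(cc_grid=())

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            GenerativeModel(ccs_noise_sd=-1.0)
        with pytest.raises(ValueError):
            GenerativeModel(ccs_per_carbon=float("nan"))


class TestOccupancy:
    def test_genotype_exclusivity(self, default_sim):
        by_sample = default_sim.features.groupby("sample_id")["species"].agg(set)
        for sample_id, species in by_sample.items():
            linkages = {parse_shorthand(s).linkage for s in species}
            assert Linkage.ACYL in linkages
            if "WT" in sample_id:
                assert Linkage.ALKYL not in linkages
                assert Linkage.ALKENYL in linkages
            else:
                assert Linkage.ALKENYL not in linkages
                assert Linkage.ALKYL in linkages

    def test_no_sample_holds_both_isobars(self, default_sim):
        by_sample = default_sim.features.groupby("sample_id")["species"].agg(set)
        for species in by_sample:
            assert not ({"PE O-38:6", "PE P-38:5"} <= species)


class TestDeterminism:
    def test_same_seed_same_table(self, default_design, default_model):
        a = generate_cohort(default_design, default_model)
        b = generate_cohort(default_design, default_model)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, default_design, default_model):
        import dataclasses

        other = dataclasses.replace(default_design, seed=2)
        a = generate_cohort(default_design, default_model)
        b = generate_cohort(other, default_model)
        assert not a["raw_mobility"].equals(b["raw_mobility"])


class TestGenerator:
    def test_plus_two_carbons_is_exactly_5p4(self):
        model = GenerativeModel()
        a = true_ccs(parse_shorthand("PE 34:1"), model)
        b = true_ccs(parse_shorthand("PE 36:1"), model)
        assert b - a == pytest.approx(5.4)

    def test_zero_noise_duplicate_rows_identical(self, default_design):
        model = zero_noise_model()
        a = generate_cohort(default_design, model)
        b = generate_cohort(default_design, model)
        pd.testing.assert_frame_equal(a, b)

    def test_all_ccs_coefficients_recoverable_by_finite_difference(self):
        model = GenerativeModel()
        base = parse_shorthand("PE 36:2")
        assert true_ccs(parse_shorthand("PE 37:2"), model) - true_ccs(base, model) == (
            pytest.approx(model.ccs_per_carbon)
        )
        assert true_ccs(parse_shorthand("PE 36:3"), model) - true_ccs(base, model) == (
            pytest.approx(model.ccs_per_db)
        )
        o = true_ccs(parse_shorthand("PE O-36:2"), model)
        p = true_ccs(parse_shorthand("PE P-36:2"), model)
        assert o - true_ccs(base, model) == pytest.approx(model.ccs_ether)
        assert p - o == pytest.approx(model.ccs_delta1)

    def test_all_rt_coefficients_recoverable_by_log_difference(self):
        model = GenerativeModel()
        base = parse_shorthand("PE 36:2")
        lr = lambda sp: math.log(true_rt(sp, model))
        assert lr(parse_shorthand("PE 37:2")) - lr(base) == pytest.approx(
            model.rt_log_per_carbon
        )
        assert lr(parse_shorthand("PE 36:3")) - lr(base) == pytest.approx(
            model.rt_log_per_db
        )
        o = lr(parse_shorthand("PE O-36:2"))
        assert o - lr(base) == pytest.approx(model.rt_log_ether)
        assert lr(parse_shorthand("PE P-36:2")) - o == pytest.approx(
            model.rt_log_delta1
        )

    def test_high_db_molecular_chain_offset(self):
        model = GenerativeModel()
        species_level = parse_shorthand("PE 38:4")
        molecular = parse_shorthand("PE 18:0_20:4")
        assert true_ccs(molecular, model) - true_ccs(species_level, model) == (
            pytest.approx(model.high_db_chain_ccs_offset)
        )

    def test_mean_ether_ccs_near_printed_average(self, default_sim):
        features = default_sim.features
        ether = features[features["species"].str.contains("O-|P-")]
        model = default_sim.model
        true_vals = [true_ccs(parse_shorthand(s), model) for s in ether["species"]]
        assert np.mean(true_vals) == pytest.approx(268.4, abs=1.0)

    def test_raw_mobility_encodes_affine_distortion(self, default_design):
        model = zero_noise_model(
            ccs_scale_range=(1.02, 1.02), ccs_offset_range=(3.0, 3.0)
        )
        features = generate_cohort(default_design, model)
        row = features.iloc[0]
        expected = (true_ccs(parse_shorthand(row["species"]), model) - 3.0) / 1.02
        assert row["raw_mobility"] == pytest.approx(expected)

    def test_mz_matches_shorthand_engine_at_zero_noise(self, default_design):
        from lipidims.shorthand import mz_deprotonated

        features = generate_cohort(default_design, zero_noise_model())
        sub = features.drop_duplicates("species")
        for _, row in sub.iterrows():
            assert row["mz"] == pytest.approx(
                mz_deprotonated(parse_shorthand(row["species"])), abs=1e-9
            )


class TestAuxTables:
    def test_reference_table_is_acyl_only(self, default_design, default_model):
        ref = reference_ccs_table(default_design, default_model)
        assert len(ref) == len(default_design.cc_grid) * len(default_design.db_grid)
        for name in ref["species"]:
            assert parse_shorthand(name).linkage is Linkage.ACYL

    def test_predicted_table_bias(self, default_design, default_model):
        pred = predicted_ccs_table(default_design, default_model, {"alkyl": 1.09})
        merged = pred.set_index("species")
        sp = "PE O-36:2"
        assert merged.loc[sp, "predicted_ccs"] == pytest.approx(
            true_ccs(parse_shorthand(sp), default_model) / 1.09
        )


class TestMobilogram:
    def _features(self, centers, intensities):
        return pd.DataFrame(
            {
                "ccs": centers,
                "intensity": intensities,
            }
        )

    def test_single_feature_peaks_at_its_ccs(self):
        trace = render_mobilogram(self._features([268.4], [1000.0]), 87.0)
        assert trace.loc[trace["intensity"].idxmax(), "ccs"] == pytest.approx(
            268.4, abs=0.05
        )

    def test_baseline_separation_shows_two_modes(self):
        trace = render_mobilogram(
            self._features([268.4, 269.68], [1000.0, 1000.0]), 534.0, grid_step=0.005
        )
        y = trace["intensity"].to_numpy()
        interior = (y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])
        assert interior.sum() == 2
        # valley between the modes drops to near baseline
        lo = trace["ccs"].sub(269.04).abs().idxmin()
        assert y[lo] < 0.05 * y.max()

    def test_unresolved_at_study_resolving_power(self):
        trace = render_mobilogram(
            self._features([268.4, 269.68], [1000.0, 1000.0]), 87.0, grid_step=0.005
        )
        y = trace["intensity"].to_numpy()
        interior = (y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])
        assert interior.sum() == 1

    def test_area_conservation_and_linearity(self):
        f = self._features([268.4, 270.0], [1000.0, 500.0])
        trace = render_mobilogram(f, 87.0, grid_step=0.01)
        area = np.trapezoid(trace["intensity"], trace["ccs"])
        assert area == pytest.approx(1500.0, rel=1e-3)
        doubled = render_mobilogram(
            f.assign(intensity=f["intensity"] * 2), 87.0, grid_step=0.01
        )
        area2 = np.trapezoid(doubled["intensity"], doubled["ccs"])
        assert area2 == pytest.approx(2 * area, rel=1e-9)

    def test_errors(self):
        f = self._features([268.4], [1.0])
        with pytest.raises(ValueError):
            render_mobilogram(f, 87.0, grid_step=0.0)
        with pytest.raises(ValueError):
            render_mobilogram(f, 0.0)
        with pytest.raises(ValueError):
            render_mobilogram(self._features([np.nan], [1.0]), 87.0)
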