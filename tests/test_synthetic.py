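import numpy as np
import pandas as pd
import pytest

from screenkit.hit_calling import flag_promiscuous
from screenkit.plate_io import validate_well_table
from screenkit.synthetic import (
    DoseDesign,
    ScreenConfig,
    ScreenConfigError,
    generate_annotations,
    generate_dose_series,
    generate_null_screen,
    generate_promiscuity,
    generate_screen,
    read_config,
    write_config,
)


class TestScreenConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"neutral_cv": 1.5},
            {"frac_true_inhibitors": -0.1},
            {"n_compounds": 0},
            {"inhibitor_effect_range": (0.9, 0.3)},
            {"n_neutral_wells_per_plate": 1},
            {"n_neutral_wells_per_plate": 17},  # more than one column of rows
            {"n_cols": 2},  # controls leave no compound wells
            {"noise_model": "cauchy"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises((ScreenConfigError, ValueError)):
            ScreenConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        cfg = ScreenConfig(n_compounds=123, seed=9, neutral_cv=0.05)
        path = tmp_path / "cfg.yaml"
        write_config(cfg, path)
        assert read_config(path) == cfg


class TestGenerateScreen:
    def test_deterministic_and_byte_identical(self, tmp_path):
        cfg = ScreenConfig(n_compounds=400, seed=7)
        w1, l1, t1 = generate_screen(cfg)
        w2, l2, t2 = generate_screen(cfg)
        pd.testing.assert_frame_equal(w1, w2)
        pd.testing.assert_frame_equal(t1, t2)
        p1, p2 = tmp_path / "1.csv", tmp_path / "2.csv"
        w1.to_csv(p1, index=False, float_format="%.6g")
        w2.to_csv(p2, index=False, float_format="%.6g")
        assert p1.read_bytes() == p2.read_bytes()

    def test_distinct_seeds_differ(self):
        w1 = generate_null_screen(100, ScreenConfig(seed=1))
        w2 = generate_null_screen(100, ScreenConfig(seed=2))
        assert not np.array_equal(w1["raw_signal"], w2["raw_signal"])

    def test_compound_well_conservation_and_layout(self, small_screen):
        cfg, wells, _, _ = small_screen
        validate_well_table(wells)
        for rep, grp in wells.groupby("replicate_id"):
            comp = grp[grp.well_type == "compound"]
            assert len(comp) == cfg.n_compounds
            assert comp["compound_id"].nunique() == cfg.n_compounds
        # identical compound placement across replicates
        placement = wells[wells.well_type == "compound"].pivot_table(
            index="compound_id", columns="replicate_id",
            values=["row", "col"], aggfunc="first",
        )
        assert placement["row"].nunique(axis=1).max() == 1
        assert placement["col"].nunique(axis=1).max() == 1
        # every plate has fixed control columns
        for _, plate in wells.groupby(["replicate_id", "plate_id"]):
            assert (plate.loc[plate.well_type == "neutral", "col"] == 0).all()
            assert (plate.loc[plate.well_type == "positive", "col"] == cfg.n_cols - 1).all()
            assert len(plate[plate.well_type == "neutral"]) == cfg.n_neutral_wells_per_plate

    def test_null_zero_noise_screen_is_exactly_flat(self):
        cfg = ScreenConfig(
            n_compounds=200, frac_true_inhibitors=0.0, background_effect_sd=0.0,
            neutral_cv=0.0, replicate_noise_cv=0.0, plate_gradient_amplitude=0.0,
            seed=0,
        )
        wells, _, _ = generate_screen(cfg)
        comp = wells[wells.well_type == "compound"]
        assert (comp["raw_signal"] == cfg.neutral_mean).all()

    def test_positive_controls_suppressed_by_configured_effect(self):
        cfg = ScreenConfig(
            n_compounds=50, neutral_mean=10000.0, positive_effect=0.98,
            neutral_cv=0.0, replicate_noise_cv=0.0, plate_gradient_amplitude=0.0,
            seed=0,
        )
        wells, _, _ = generate_screen(cfg)
        pos = wells.loc[wells.well_type == "positive", "raw_signal"]
        assert np.allclose(pos, 200.0)

    def test_ground_truth_matches_library_universe(self, small_screen):
        cfg, wells, library, truth = small_screen
        assert set(truth["compound_id"]) == set(library["compound_id"])
        assert truth["is_inhibitor"].sum() > 0
        assert truth.loc[truth.is_inhibitor, "true_ic50_uM"].notna().all()


class TestDoseDesign:
    def test_default_ladder_descends_fiftyfold(self):
        conc = DoseDesign().concentrations
        assert conc[0] == 50.0
        assert conc[-1] == pytest.approx(0.390625)
        assert (np.diff(conc) < 0).all()
        assert np.allclose(conc[:-1] / conc[1:], 2.0)

    @pytest.mark.parametrize(
        "kwargs", [{"top_concentration": -5}, {"dilution_factor": 1.0}, {"n_doses": 0}]
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DoseDesign(**kwargs)


class TestGenerateDoseSeries:
    def test_noiseless_midpoint_and_flat_degenerate(self):
        design = DoseDesign(replicates_per_dose=1)
        df = generate_dose_series(100, 100, 5.0, 2.0, design, noise_cv=0.0)
        at5 = df.loc[np.isclose(df.concentration_uM, 6.25), "response"]
        # halfway response occurs exactly at x = alpha
        mid = 100 - 100 / (1 + (5.0 / 6.25) ** 2)
        assert at5.iloc[0] == pytest.approx(mid)
        flat = generate_dose_series(100, 0.0, None, 2.0, design, noise_cv=0.0)
        assert (flat["response"] == 100.0).all()

    def test_mean_response_converges_to_noiseless_curve(self):
        design = DoseDesign(replicates_per_dose=1)
        clean = generate_dose_series(100, 100, 5.0, 2.0, design, noise_cv=0.0)
        acc = np.zeros(len(clean))
        n_seeds = 1000
        for s in range(n_seeds):
            acc += generate_dose_series(100, 100, 5.0, 2.0, design,
                                        noise_cv=0.05, seed=s)["response"].to_numpy()
        mean = acc / n_seeds
        assert np.allclose(mean, clean["response"], rtol=0.01)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            generate_dose_series(100, 100, -2.0, 2.0, DoseDesign())


def test_generated_promiscuity_recovers_planted_frequent_hitters():
    cfg = ScreenConfig(n_compounds=2000, seed=3)
    _, _, truth = generate_screen(cfg)
    records, truth_flagged = generate_promiscuity(truth, seed=4)
    flags = flag_promiscuous(records)
    planted = truth_flagged.set_index("compound_id")["is_promiscuous"]
    assert flags.sort_index().equals(planted.sort_index())
    assert 0 < planted.sum() < 200


def test_generated_annotations_contain_enriched_term():
    cfg = ScreenConfig(n_compounds=2000, seed=5)
    _, _, truth = generate_screen(cfg)
    ann = generate_annotations(truth, seed=6)
    assert ann.duplicated(subset=["term", "compound_id"]).sum() == 0
    assert ann["term"].nunique() == 117
    enriched = ann[ann.term == "reporter pathway inhibitor"]["compound_id"]
    inhib = set(truth.loc[truth.is_inhibitor, "compound_id"])
    assert len(set(enriched) & inhib) >= 0.8 * len(enriched)
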