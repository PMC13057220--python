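"""Generator checks: demographics, factor structure, outcomes, phantoms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from organ_age import synthetic
from organ_age.config import (
    ORGANS,
    AgingFactorConfig,
    ConfigurationError,
    HazardConfig,
    OutcomeHazard,
    PhantomConfig,
)


class TestCohort:
    def test_empty_cohort(self):
        df = synthetic.generate_cohort(0, seed=0)
        assert len(df) == 0

    def test_mean_chronological_age_matches_target(self):
        df = synthetic.generate_cohort(10000, seed=1)
        assert abs(df["ca_at_imaging"].mean() - 64.23) < 0.3
        assert df["ca_at_imaging"].between(44, 83).all()

    def test_identical_seeds_give_byte_identical_cohorts(self, tmp_path):
        a = synthetic.generate_cohort(5000, seed=9)
        b = synthetic.generate_cohort(5000, seed=9)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        synthetic.write_cohort_csv(a, pa)
        synthetic.write_cohort_csv(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_retrieval_age_never_precedes_imaging(self, small_cohort):
        assert (small_cohort["retrieval_age"]
                >= small_cohort["ca_at_imaging"]).all()

    def test_cohort_csv_round_trip(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        synthetic.write_cohort_csv(small_cohort, path)
        back = synthetic.read_cohort_csv(path)
        assert list(back.columns) == list(small_cohort.columns)
        np.testing.assert_allclose(back["ca_at_imaging"],
                                   small_cohort["ca_at_imaging"], atol=1e-5)


class TestOrganPagFactorStructure:
    def test_zero_loadings_give_independent_organs(self):
        factors = AgingFactorConfig(
            systemic_loading={o: 0.0 for o in ORGANS},
            pair_loading={"kidney": 0.0, "fundus": 0.0})
        pags = synthetic.sample_organ_pags(5000, factors, seed=2)
        corr = np.corrcoef(pags.T)
        off = corr[~np.eye(9, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_kidney_pair_correlation_near_design_value(self):
        pags = synthetic.sample_organ_pags(5000, seed=3)
        i = ORGANS.index("kidney_left")
        j = ORGANS.index("kidney_right")
        r = np.corrcoef(pags[:, i], pags[:, j])[0, 1]
        assert abs(r - 0.43) < 0.05

    def test_empirical_correlation_converges_to_implied(self):
        factors = AgingFactorConfig()
        pags = synthetic.sample_organ_pags(20000, factors, seed=4)
        implied = factors.implied_correlation()
        empirical = np.corrcoef(pags.T)
        assert np.abs(empirical - implied).max() < 0.03

    def test_marginal_sd_matches_pag_sd(self):
        factors = AgingFactorConfig()
        pags = synthetic.sample_organ_pags(20000, factors, seed=5)
        for j, organ in enumerate(ORGANS):
            assert pags[:, j].std() == pytest.approx(factors.pag_sd[organ],
                                                     rel=0.05)

    def test_overloaded_factors_rejected_as_non_psd(self):
        factors = AgingFactorConfig(
            systemic_loading={**AgingFactorConfig().systemic_loading,
                              "kidney_left": 0.95})
        with pytest.raises(ConfigurationError, match="PSD|residual"):
            synthetic.sample_organ_pags(10, factors, seed=0)


class TestOutcomes:
    def test_zero_baseline_rate_gives_no_events(self):
        hz = HazardConfig(outcomes={
            "disease": OutcomeHazard(0.0, 0.2, "brain", 0.0)})
        df = synthetic.generate_cohort(500, hazards=hz, seed=6)
        assert df["age_disease"].isna().all()

    def test_null_log_hr_gives_pag_independent_incidence(self):
        hz = HazardConfig(outcomes={
            "disease": OutcomeHazard(0.01, 0.0, "brain", 0.0)})
        df = synthetic.generate_cohort(5000, hazards=hz, seed=7)
        event = df["age_disease"].notna().to_numpy()
        high = (df["pag_brain"] > df["pag_brain"].median()).to_numpy()
        table = pd.crosstab(high, event)
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_event_age_windows(self, small_cohort):
        df = small_cohort
        for col in [c for c in df.columns if c.startswith("age_")]:
            ages = df[col].dropna()
            assert (ages > 40).all()
            assert (ages <= df.loc[ages.index, "retrieval_age"]).all()
        future = df["age_ckd"].notna() & (df["age_ckd"] >= df["ca_at_imaging"])
        assert (df.loc[future, "age_ckd"]
                <= df.loc[future, "retrieval_age"]).all()

    def test_disease_acceleration_shifts_affected_organ_pags(self):
        hz = HazardConfig(outcomes={
            "disease": OutcomeHazard(0.01, 0.0, "liver", 5.0)})
        base = synthetic.generate_cohort(4000, hazards=HazardConfig(outcomes={
            "disease": OutcomeHazard(0.01, 0.0, "liver", 0.0)}), seed=8)
        shifted = synthetic.generate_cohort(4000, hazards=hz, seed=8)
        diagnosed = shifted["age_disease"].notna()
        delta = shifted["pag_liver"] - base["pag_liver"]
        assert np.allclose(delta[diagnosed], 5.0)
        assert np.allclose(delta[~diagnosed], 0.0)

    def test_unknown_source_organ_rejected(self):
        hz = HazardConfig(outcomes={
            "disease": OutcomeHazard(0.01, 0.0, "gallbladder", 0.0)})
        with pytest.raises(ConfigurationError, match="gallbladder"):
            synthetic.generate_cohort(10, hazards=hz, seed=0)


class TestPhantoms:
    def test_zero_slope_decouples_radius_from_age(self):
        df = synthetic.generate_cohort(120, seed=10)
        phantom = PhantomConfig(slope_b=0.0, r0=6.0)
        radii, ages = [], []
        for i, (_, row) in enumerate(df.iterrows()):
            img = synthetic.render_organ_image(row, "brain", phantom,
                                               seed=synthetic.render_seed(1, i, "brain"))
            radii.append(synthetic.measure_cavity_radius(img))
            ages.append(row["ca_at_imaging"])
        slope, _, _, p, _ = stats.linregress(ages, radii)
        assert abs(slope) < 0.01

    def test_biological_age_difference_moves_cavity_radius(self):
        """+20 y of BA at the same nuisance seed shifts the radius by 20*slope_b."""
        df = synthetic.generate_cohort(1, seed=11)
        row = df.iloc[0].copy()
        phantom = PhantomConfig(intensity_noise_sd=0.0, radius_noise_sd=0.0,
                                texture_blur_levels=(0.5,))
        a = synthetic.render_organ_image(row, "liver", phantom, seed=123)
        row["pag_liver"] += 20.0
        b = synthetic.render_organ_image(row, "liver", phantom, seed=123)
        diff = (synthetic.measure_cavity_radius(b)
                - synthetic.measure_cavity_radius(a))
        assert diff == pytest.approx(20.0 * phantom.slope_b, abs=0.25)

    def test_masks_nonempty_and_inside_grid(self):
        df = synthetic.generate_cohort(200, seed=12)
        for i, (_, row) in enumerate(df.iterrows()):
            organ = ("fundus_left", "spleen")[i % 2]
            img = synthetic.render_organ_image(
                row, organ, seed=synthetic.render_seed(2, i, organ))
            assert img.mask.any()
            # no mask voxel on any face of the grid
            for axis in range(img.mask.ndim):
                assert not np.take(img.mask, 0, axis=axis).any()
                assert not np.take(img.mask, -1, axis=axis).any()

    def test_radius_strictly_increasing_in_biological_age(self):
        df = synthetic.generate_cohort(1, seed=13)
        row = df.iloc[0].copy()
        phantom = PhantomConfig(intensity_noise_sd=0.0, radius_noise_sd=0.0,
                                texture_blur_levels=(0.5,))
        radii = []
        for shift in (0.0, 8.0, 16.0):
            r = row.copy()
            r["pag_heart"] += shift
            img = synthetic.render_organ_image(r, "heart", phantom, seed=77)
            radii.append(synthetic.measure_cavity_radius(img))
        assert radii[0] < radii[1] < radii[2]

    def test_oversized_cavity_rejected(self):
        df = synthetic.generate_cohort(1, seed=14)
        row = df.iloc[0].copy()
        row["pag_brain"] += 60.0  # BA far outside the grid's capacity
        with pytest.raises(ConfigurationError, match="cavity|grid"):
            synthetic.render_organ_image(row, "brain",
                                         PhantomConfig(r0=5.0, slope_b=0.07),
                                         seed=0)

    def test_invalid_grid_configuration_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomConfig(grid_shape=(16, 16, 16), r0=4.0, slope_b=0.08).validate()

    def test_rendering_is_deterministic(self):
        df = synthetic.generate_cohort(2, seed=15)
        row = df.iloc[1]
        a = synthetic.render_organ_image(row, "pancreas", seed=5)
        b = synthetic.render_organ_image(row, "pancreas", seed=5)
        np.testing.assert_array_equal(a.voxels, b.voxels)
        np.testing.assert_array_equal(a.mask, b.mask)
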