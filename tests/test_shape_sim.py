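"""Reactivity simulation, pseudo-energy conversion and .shape file I/O."""

import math

import numpy as np
import pytest

from esdfold import (
    PseudoEnergyParams,
    ShapeDistributionSet,
    ShapeProfile,
    StructuralClass,
    parse_dotbracket,
    pseudo_energy_per_site,
    pseudo_energy_total,
    read_shape,
    simulate_shape,
    write_shape,
)
from esdfold.shape_sim import ClassDistribution, fit_distribution_set


class TestPseudoEnergyPerSite:
    def test_zero_reactivity_gives_intercept(self):
        assert pseudo_energy_per_site(0.0, PseudoEnergyParams()) == pytest.approx(-0.8)

    def test_analytic_value_at_e_minus_one(self):
        sr = math.e - 1.0  # ln(sr + 1) = 1
        assert pseudo_energy_per_site(sr, PseudoEnergyParams()) == pytest.approx(1.8)

    def test_zero_parameters_annihilate(self):
        params = PseudoEnergyParams(m=0.0, b=0.0)
        for sr in (0.0, 0.5, 3.7):
            assert pseudo_energy_per_site(sr, params) == 0.0

    def test_missing_reactivity_contributes_nothing(self):
        assert pseudo_energy_per_site(float("nan"), PseudoEnergyParams()) == 0.0

    def test_monotone_in_reactivity_for_positive_slope(self):
        params = PseudoEnergyParams()
        values = [pseudo_energy_per_site(sr, params) for sr in (0.0, 0.5, 1.0, 2.0)]
        assert values == sorted(values)


class TestPseudoEnergyTotal:
    def test_four_pair_helix_with_zero_reactivities(self):
        # 4 stacked (doubled) + 4 helix-end positions, all dG = b = -0.8
        ss = parse_dotbracket("((((....))))")
        profile = ShapeProfile(values=np.zeros(12))
        total = pseudo_energy_total(ss, profile, PseudoEnergyParams())
        assert total == pytest.approx(2 * 4 * -0.8 + 4 * -0.8) == pytest.approx(-9.6)

    def test_empty_structure_is_zero(self):
        ss = parse_dotbracket("......")
        profile = ShapeProfile(values=np.ones(6))
        assert pseudo_energy_total(ss, profile, PseudoEnergyParams()) == 0.0

    def test_linearity_in_slope_with_zero_intercept(self):
        ss = parse_dotbracket("(((....)))")
        rng = np.random.default_rng(0)
        profile = ShapeProfile(values=rng.uniform(0, 2, size=10))
        single = pseudo_energy_total(ss, profile, PseudoEnergyParams(m=1.3, b=0.0))
        double = pseudo_energy_total(ss, profile, PseudoEnergyParams(m=2.6, b=0.0))
        assert double == pytest.approx(2 * single)

    def test_all_zero_profile_closed_form(self):
        ss = parse_dotbracket("(((((....)))))..((...))")
        profile = ShapeProfile(values=np.zeros(23))
        from esdfold import classify_positions

        labels = classify_positions(ss)
        stacked = labels.count(StructuralClass.STACKED)
        helix_end = labels.count(StructuralClass.HELIX_END)
        b = -0.8
        expected = b * (2 * stacked + helix_end)
        assert pseudo_energy_total(ss, profile, PseudoEnergyParams()) == pytest.approx(
            expected
        )

    def test_length_mismatch_rejected(self):
        ss = parse_dotbracket("(....)")
        with pytest.raises(ValueError, match="length"):
            pseudo_energy_total(ss, ShapeProfile(values=np.zeros(5)), PseudoEnergyParams())


class TestSimulateShape:
    def test_point_masses_label_every_position(self):
        ss = parse_dotbracket("(....)")
        dists = ShapeDistributionSet.point_masses(
            unpaired=1.0, stacked=0.0, helix_end=0.2
        )
        profile = simulate_shape(ss, dists, np.random.default_rng(0))
        assert profile.values.tolist() == [0.2, 1.0, 1.0, 1.0, 1.0, 0.2]

    def test_same_seed_gives_identical_profile(self):
        ss = parse_dotbracket("((((....))))....")
        dists = ShapeDistributionSet(
            by_class={
                StructuralClass.UNPAIRED: ClassDistribution("gev", (-0.2, 0.6, 0.4)),
                StructuralClass.STACKED: ClassDistribution("exponential", (0.07,)),
                StructuralClass.HELIX_END: ClassDistribution("exponential", (0.25,)),
            }
        )
        a = simulate_shape(ss, dists, np.random.default_rng(11))
        b = simulate_shape(ss, dists, np.random.default_rng(11))
        assert np.array_equal(a.values, b.values)

    def test_unpaired_sample_mean_converges(self):
        """Law of large numbers: empirical mean near the distribution mean."""
        dist = ClassDistribution("exponential", (0.8,))
        rng = np.random.default_rng(5)
        samples = dist.sample(100_000, rng)
        se = 0.8 / math.sqrt(len(samples))
        assert abs(samples.mean() - dist.mean()) < 3 * se

    def test_samples_are_truncated_at_zero(self):
        # a GEV with low location produces negative draws before truncation
        dist = ClassDistribution("gev", (0.1, -0.5, 0.3))
        samples = dist.sample(10_000, np.random.default_rng(1))
        assert samples.min() >= 0.0


class TestDistributionConfig:
    def test_default_set_covers_all_classes(self):
        dists = ShapeDistributionSet.default()
        assert set(dists.by_class) == set(StructuralClass)

    def test_yaml_roundtrip(self, tmp_path):
        dists = ShapeDistributionSet.point_masses(0.9, 0.1, 0.3)
        path = tmp_path / "dists.yaml"
        dists.to_yaml(path)
        back = ShapeDistributionSet.from_yaml(path)
        assert back.to_dict() == dists.to_dict()

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ClassDistribution("cauchy", (0.0, 1.0))

    def test_ml_refit_recovers_parameters(self):
        """Fit-from-samples recovery for each supported parametric family."""
        rng = np.random.default_rng(77)
        n = 10_000
        for family, params in [
            ("exponential", (0.8,)),
            ("gamma", (2.0, 0.4)),
            ("lognormal", (0.5, 0.6)),
        ]:
            truth = ClassDistribution(family, params)
            samples = truth.sample(n, rng)
            fitted = ClassDistribution.fit(family, samples)
            for got, want in zip(fitted.params, params):
                assert got == pytest.approx(want, rel=0.05)

    def test_fit_distribution_set_by_structural_class(self):
        ss = parse_dotbracket("((((((....))))))" + "." * 24)
        dists = ShapeDistributionSet(
            by_class={
                StructuralClass.UNPAIRED: ClassDistribution("exponential", (0.9,)),
                StructuralClass.STACKED: ClassDistribution("exponential", (0.05,)),
                StructuralClass.HELIX_END: ClassDistribution("exponential", (0.3,)),
            }
        )
        rng = np.random.default_rng(3)
        # average many simulated profiles into one long training sample by
        # concatenating per-class values from repeated simulations
        from esdfold import classify_positions

        labels = classify_positions(ss)
        refit = fit_distribution_set(
            ss,
            simulate_shape(ss, dists, rng),
            families={c: "exponential" for c in StructuralClass},
        )
        # single profile is small, so only check the fit ran per class
        assert set(refit.by_class) == set(StructuralClass)


class TestShapeFileIO:
    def test_missing_sentinel_parsed(self, tmp_path):
        f = tmp_path / "p.shape"
        f.write_text("1 0.0\n2 -999\n")
        profile = read_shape(f)
        assert profile.values[0] == 0.0
        assert np.isnan(profile.values[1])
        assert profile.source == "experimental"

    def test_roundtrip_of_simulated_profile_is_bit_exact(self, tmp_path):
        rng = np.random.default_rng(8)
        values = rng.uniform(0, 3, size=100)
        values[[7, 42]] = np.nan
        profile = ShapeProfile(values=values)
        path = tmp_path / "sim.shape"
        write_shape(path, profile)
        back = read_shape(path)
        assert np.array_equal(back.values, profile.values, equal_nan=True)

    def test_non_numeric_row_rejected(self, tmp_path):
        f = tmp_path / "bad.shape"
        f.write_text("1 abc\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_shape(f)

    def test_negative_reactivity_clamped_with_warning(self, tmp_path):
        f = tmp_path / "neg.shape"
        f.write_text("1 -0.4\n2 1.0\n")
        with pytest.warns(UserWarning, match="clamped"):
            profile = read_shape(f)
        assert profile.values[0] == 0.0
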