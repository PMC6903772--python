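"""Abundance/ratio algebra and the two-source mixing model."""

import math

import numpy as np
import pytest
from hypothesis import given
import hypothesis.strategies as st

from zntrace import (
    AbundanceVector,
    RatioSet,
    SourcePair,
    abundances_from_ratios,
    plant_ratio,
    ratios_from_abundances,
    summarize_treatment,
    zndf_fertilizer,
)
from zntrace.errors import (
    DomainError,
    IncompleteRatioSetError,
    InsufficientReplicationError,
    UnresolvableMixtureError,
)

from conftest import abundance_vectors, source_pairs

# full vectors whose A66/A67 entries match the worked mixing example
SOIL_EXAMPLE = AbundanceVector({64: 49.0, 66: 27.5, 67: 8.0, 68: 15.0, 70: 0.5})
FERT_EXAMPLE = AbundanceVector({64: 40.0, 66: 13.5, 67: 31.0, 68: 15.0, 70: 0.5})


class TestAbundanceVector:
    def test_natural_abundances_normalized(self, natural):
        assert math.isclose(sum(natural.abundance.values()), 100.0, abs_tol=1e-9)
        assert natural[67] == pytest.approx(4.04)

    @pytest.mark.parametrize(
        "bad",
        [
            {64: 50.0, 66: 30.0, 67: 4.0, 68: 18.0},  # missing isotope
            {64: -1.0, 66: 32.0, 67: 4.0, 68: 64.0, 70: 1.0},  # negative
            {64: 10.0, 66: 10.0, 67: 10.0, 68: 10.0, 70: 10.0},  # sum != 100
        ],
    )
    def test_invalid_vectors_rejected(self, bad):
        with pytest.raises(DomainError):
            AbundanceVector(bad)


class TestConversions:
    def test_iupac_ratios_recover_a67(self, natural):
        rs = ratios_from_abundances(natural)
        assert rs[66] == pytest.approx(4.04 / 27.73, rel=1e-12)
        back = abundances_from_ratios(rs)
        assert back[67] == pytest.approx(4.04, rel=1e-12)

    def test_unit_ratios_give_uniform_abundances(self):
        rs = RatioSet({64: 1.0, 66: 1.0, 68: 1.0, 70: 1.0})
        av = abundances_from_ratios(rs)
        for m in (64, 66, 67, 68, 70):
            assert av[m] == pytest.approx(20.0, rel=1e-12)
        uniform = AbundanceVector({m: 20.0 for m in (64, 66, 67, 68, 70)})
        assert all(
            r == pytest.approx(1.0, rel=1e-12)
            for r in ratios_from_abundances(uniform).ratios.values()
        )

    @given(abundance_vectors())
    def test_round_trip_is_identity(self, av):
        back = abundances_from_ratios(ratios_from_abundances(av))
        for m in (64, 66, 67, 68, 70):
            assert back[m] == pytest.approx(av[m], rel=1e-12)

    def test_incomplete_ratio_set_rejected(self):
        with pytest.raises(IncompleteRatioSetError):
            RatioSet({64: 1.0, 66: 1.0})

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(DomainError):
            RatioSet({64: 1.0, 66: -0.1, 68: 1.0, 70: 1.0})

    def test_zero_reference_abundance_rejected(self):
        av = AbundanceVector({64: 50.0, 66: 30.0, 67: 0.0, 68: 19.0, 70: 1.0})
        with pytest.raises(DomainError):
            ratios_from_abundances(av)


class TestMixingModel:
    def test_endpoints_return_source_ratios(self):
        pair = SourcePair(SOIL_EXAMPLE, FERT_EXAMPLE)
        assert plant_ratio(0.0, pair) == SOIL_EXAMPLE.ratio()
        assert plant_ratio(1.0, pair) == FERT_EXAMPLE.ratio()

    def test_worked_mixture(self):
        # 30% fertilizer Zn: (0.3*31 + 0.7*8) / (0.3*13.5 + 0.7*27.5) = 14.9/23.3
        pair = SourcePair(SOIL_EXAMPLE, FERT_EXAMPLE)
        r = plant_ratio(0.30, pair)
        assert r == pytest.approx(14.9 / 23.3, rel=1e-12)
        assert r == pytest.approx(0.639485, abs=5e-7)
        z, flagged = zndf_fertilizer(r, pair)
        assert z == pytest.approx(30.0, abs=1e-10)
        assert not flagged

    def test_endpoint_inversion(self):
        pair = SourcePair(SOIL_EXAMPLE, FERT_EXAMPLE)
        z0, _ = zndf_fertilizer(plant_ratio(0.0, pair), pair)
        z1, _ = zndf_fertilizer(plant_ratio(1.0, pair), pair)
        assert z0 == pytest.approx(0.0, abs=1e-12)
        assert z1 == pytest.approx(100.0, abs=1e-10)

    @given(source_pairs(), st.floats(0.0, 1.0))
    def test_inverse_property(self, pair, f):
        z, _ = zndf_fertilizer(plant_ratio(f, pair), pair)
        assert z == pytest.approx(100.0 * f, abs=1e-8)

    @given(source_pairs())
    def test_monotonic_in_fraction(self, pair):
        grid = np.linspace(0.0, 1.0, 21)
        ratios = [plant_ratio(f, pair) for f in grid]
        diffs = np.diff(ratios)
        sign = np.sign(pair.fertilizer.ratio() - pair.soil.ratio())
        assert np.all(np.sign(diffs) == sign)

    def test_soil_plus_fertilizer_fraction_is_total(self):
        pair = SourcePair(SOIL_EXAMPLE, FERT_EXAMPLE)
        z, _ = zndf_fertilizer(0.5, pair)
        from zntrace import MixingResult

        res = MixingResult(
            zndf_fertilizer_pct=z, per_replicate=(z,), sd=0.0, ci95_half_width=0.0
        )
        assert res.zndf_fertilizer_pct + res.zndf_soil_pct == 100.0

    def test_out_of_range_estimate_flagged_not_rejected(self):
        pair = SourcePair(SOIL_EXAMPLE, FERT_EXAMPLE)
        # a ratio beyond the fertilizer endmember implies > 100%
        beyond = FERT_EXAMPLE.ratio() * 1.5
        z, flagged = zndf_fertilizer(beyond, pair)
        assert flagged and z > 110.0

    def test_identical_sources_unresolvable(self, natural):
        with pytest.raises(UnresolvableMixtureError):
            SourcePair(natural, natural)

    def test_fraction_outside_unit_interval_rejected(self):
        pair = SourcePair(SOIL_EXAMPLE, FERT_EXAMPLE)
        with pytest.raises(DomainError):
            plant_ratio(1.2, pair)


class TestTreatmentSummary:
    def test_identical_replicates_zero_width(self):
        res = summarize_treatment([20.0, 20.0, 20.0, 20.0])
        assert res.zndf_fertilizer_pct == 20.0
        assert res.ci95_half_width == 0.0

    def test_hand_computed_mean_and_sd(self):
        res = summarize_treatment([10.0, 12.0, 11.0, 13.0])
        assert res.zndf_fertilizer_pct == pytest.approx(11.5)
        assert res.sd == pytest.approx(1.29099, abs=1e-5)
        # t(0.975, 3) = 3.18245; CI half-width = t * sd / sqrt(4)
        assert res.ci95_half_width == pytest.approx(3.18245 * 1.2909944 / 2.0, rel=1e-5)

    def test_single_replicate_rejected(self):
        with pytest.raises(InsufficientReplicationError):
            summarize_treatment([10.0])
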