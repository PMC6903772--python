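"""Standard-sample-standard bracketing and power-law mass-bias correction."""

import numpy as np
import pytest

from zntrace import (
    AbundanceVector,
    BracketingSequence,
    RatioSet,
    SequenceEvent,
    correct_ratios,
    correct_sequence,
    fit_bracketing,
    labeled_abundances,
    ratios_from_abundances,
)
from zntrace.calibration import CorrectionModel, apply_mass_bias
from zntrace.core import DEFAULT_SYSTEM
from zntrace.errors import DomainError, UnbracketedSampleError
from zntrace.simulate import InstrumentProfile, _bracketed_sequence, simulate_measurement

NATURAL = AbundanceVector.natural()
NATURAL_RS = ratios_from_abundances(NATURAL)
DM66 = DEFAULT_SYSTEM.mass_difference(66)


def _std_event(t, ratios=NATURAL_RS):
    return SequenceEvent(t, "standard", "std", ratios)


class TestFitBracketing:
    def test_exact_standard_gives_unit_bias(self):
        seq = BracketingSequence(
            events=[_std_event(0.0), _std_event(2.0)], standard_true=NATURAL
        )
        model = fit_bracketing(seq)
        for t in (0.0, 1.0, 2.0):
            assert model.bias_at(t) == pytest.approx(1.0, rel=1e-14)

    def test_closed_form_bias_from_biased_standard(self):
        # standard true 67:66 = 0.145691, measured 0.150000 at both brackets:
        # per-amu bias b = (0.150 / 0.145691)^(1/dm); the 66-channel
        # correction factor b^(-dm) must be the exact measured/true quotient
        true_r = 0.145691
        meas = NATURAL_RS.scaled({66: 0.150000 / NATURAL_RS[66]})
        seq = BracketingSequence(
            events=[_std_event(0.0, meas), _std_event(2.0, meas)],
            standard_true=NATURAL,
        )
        model = fit_bracketing(seq)
        b = model.bias_at(1.0)
        assert b == pytest.approx((0.150000 / NATURAL_RS[66]) ** (1.0 / DM66), rel=1e-12)
        assert b ** (-DM66) == pytest.approx(NATURAL_RS[66] / 0.150000, rel=1e-12)

    def test_linear_interpolation_at_midpoint(self):
        b_before, b_after = 0.97, 0.99
        ev0 = _std_event(0.0, apply_mass_bias(NATURAL_RS, b_before))
        ev1 = _std_event(2.0, apply_mass_bias(NATURAL_RS, b_after))
        seq = BracketingSequence(events=[ev0, ev1], standard_true=NATURAL)
        model = fit_bracketing(seq)
        assert model.bias_at(1.0) == pytest.approx(0.98, rel=1e-10)

    def test_joint_estimate_matches_single_ratio_for_pure_power_law(self):
        biased = apply_mass_bias(NATURAL_RS, 1.02)
        seq = BracketingSequence(
            events=[_std_event(0.0, biased), _std_event(2.0, biased)],
            standard_true=NATURAL,
        )
        single = fit_bracketing(seq).bias_at(1.0)
        joint = fit_bracketing(seq, joint=True).bias_at(1.0)
        assert joint == pytest.approx(single, rel=1e-12)

    def test_unbracketed_sample_rejected(self):
        with pytest.raises(UnbracketedSampleError):
            BracketingSequence(
                events=[
                    _std_event(0.0),
                    SequenceEvent(1.0, "sample", "s", NATURAL_RS),
                ],
                standard_true=NATURAL,
            )

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(DomainError):
            BracketingSequence(
                events=[_std_event(1.0), _std_event(0.5)], standard_true=NATURAL
            )


class TestCorrectRatios:
    def test_unit_bias_is_identity(self):
        model = CorrectionModel(
            standard_times=np.array([0.0, 2.0]),
            standard_bias=np.array([1.0, 1.0]),
            envelope=(0.0, 2.0),
        )
        out = correct_ratios(NATURAL_RS, model, 1.0)
        for m in (64, 66, 68, 70):
            assert out[m] == NATURAL_RS[m]

    def test_known_correction_factor_on_67_66(self):
        # correction factor for the 66 channel fixed at 0.971273:
        # raw 0.300000 -> 0.291382
        factor = 0.971273
        b = factor ** (-1.0 / DM66)
        model = CorrectionModel(
            standard_times=np.array([0.0, 2.0]),
            standard_bias=np.array([b, b]),
            envelope=(0.0, 2.0),
        )
        raw = NATURAL_RS.scaled({66: 0.300000 / NATURAL_RS[66]})
        out = correct_ratios(raw, model, 1.0)
        assert out[66] == pytest.approx(0.291382, abs=5e-7)

    def test_correction_commutes_with_subsetting(self):
        model = CorrectionModel(
            standard_times=np.array([0.0, 2.0]),
            standard_bias=np.array([1.017, 1.019]),
            envelope=(0.0, 2.0),
        )
        full = correct_ratios(NATURAL_RS, model, 0.7)
        for m in (64, 66, 68, 70):
            sub_first = RatioSet({m: NATURAL_RS[m], **{
                k: NATURAL_RS[k] for k in (64, 66, 68, 70) if k != m
            }})
            assert correct_ratios(sub_first, model, 0.7)[m] == full[m]

    def test_outside_envelope_rejected(self):
        model = CorrectionModel(
            standard_times=np.array([0.0, 2.0]),
            standard_bias=np.array([1.0, 1.0]),
            envelope=(0.0, 2.0),
        )
        with pytest.raises(UnbracketedSampleError):
            correct_ratios(NATURAL_RS, model, 3.0)


class TestEndToEndRecovery:
    def test_standard_self_consistency(self):
        """Correcting a measurement of the standard itself returns the
        standard's true ratios exactly."""
        biased = apply_mass_bias(NATURAL_RS, 1.025)
        seq = BracketingSequence(
            events=[
                _std_event(0.0, biased),
                SequenceEvent(1.0, "sample", "std_as_sample", biased),
                _std_event(2.0, biased),
            ],
            standard_true=NATURAL,
        )
        [(_, corrected)] = correct_sequence(seq)
        for m in (64, 66, 68, 70):
            assert corrected[m] == pytest.approx(NATURAL_RS[m], rel=1e-12)

    @pytest.mark.parametrize("a67", [4.04, 8.1, 31.0])
    def test_linear_drift_zero_noise_recovers_truth(self, a67):
        """With linear per-amu drift and no noise, bracketing correction
        recovers the true sample ratios to 1e-10 relative."""
        profile = InstrumentProfile(
            name="Q",
            ratio_rsd={64: 0.0, 66: 0.0, 68: 0.0, 70: 0.0},
            repeats=6,
            mass_bias_b0=1.03,
            mass_bias_drift=2e-3,
        )
        true_av = labeled_abundances(a67)
        rng = np.random.default_rng(0)
        run = simulate_measurement(true_av, profile, t=1.0, rng=rng)
        seq = _bracketed_sequence(run, NATURAL, profile, rng, DEFAULT_SYSTEM)
        true_rs = ratios_from_abundances(true_av)
        for _, corrected in correct_sequence(seq):
            for m in (64, 66, 68, 70):
                assert corrected[m] == pytest.approx(true_rs[m], rel=1e-10)
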