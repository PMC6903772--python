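"""Synthetic measurement generator: determinism, noise honesty, interference."""

import numpy as np
import pytest

from zntrace import (
    AbundanceVector,
    InstrumentProfile,
    InterferenceProfile,
    Treatment,
    VirtualExperiment,
    apply_interference,
    labeled_abundances,
    ratios_from_abundances,
    simulate_experiment,
    simulate_measurement,
    zndf_fertilizer,
)
from zntrace.core import SourcePair
from zntrace.errors import ConfigError, DomainError
from zntrace.io import sequence_to_frame
from zntrace.pipeline import replicate_ratio_table

NATURAL = AbundanceVector.natural()

NOISELESS = InstrumentProfile(
    name="Q", ratio_rsd={64: 0.0, 66: 0.0, 68: 0.0, 70: 0.0}, repeats=3
)


def test_zero_noise_unit_bias_reproduces_truth():
    rng = np.random.default_rng(0)
    run = simulate_measurement(NATURAL, NOISELESS, t=0.0, rng=rng)
    true_rs = ratios_from_abundances(NATURAL)
    for rep in run.replicates:
        for m in (64, 66, 68, 70):
            assert rep[m] == true_rs[m]


def test_same_seed_gives_identical_runs():
    prof = InstrumentProfile.quadrupole()
    r1 = simulate_measurement(NATURAL, prof, 0.0, np.random.default_rng(42))
    r2 = simulate_measurement(NATURAL, prof, 0.0, np.random.default_rng(42))
    assert r1 == r2


def test_empirical_rsd_matches_configuration():
    """At 10^4 repeats the observed 67:66 RSD is within 5% (relative) of the
    configured 1.3%."""
    prof = InstrumentProfile(name="Q", ratio_rsd=dict.fromkeys((64, 66, 68, 70), 0.013),
                             repeats=10_000)
    run = simulate_measurement(NATURAL, prof, 0.0, np.random.default_rng(7))
    vals = np.array([rep[66] for rep in run.replicates])
    rsd = vals.std(ddof=1) / vals.mean()
    assert rsd == pytest.approx(0.013, rel=0.05)


def test_mc_profile_emits_block_means():
    prof = InstrumentProfile.multicollector()
    run = simulate_measurement(NATURAL, prof, 0.0, np.random.default_rng(1))
    assert len(run.replicates) == 3
    # block means of 20 cycles at 0.05% RSD scatter far less than one cycle
    vals = np.array([rep[66] for rep in run.replicates])
    assert vals.std(ddof=1) / vals.mean() < 0.0005


class TestInterference:
    def test_zero_level_is_identity_object(self):
        rng = np.random.default_rng(0)
        run = simulate_measurement(NATURAL, NOISELESS, 0.0, rng)
        assert apply_interference(run, InterferenceProfile({67: 0.01}), 0.0) is run
        assert apply_interference(run, InterferenceProfile(), 1.0) is run

    def test_interference_at_67_raises_ratio(self):
        rng = np.random.default_rng(0)
        run = simulate_measurement(NATURAL, NOISELESS, 0.0, rng)
        bumped = apply_interference(run, InterferenceProfile({67: 0.002}), 1.0)
        for before, after in zip(run.replicates, bumped.replicates):
            assert after[66] > before[66]
        assert bumped.interference_flag

    def test_worked_signal_arithmetic(self):
        # 0.4% of total signal onto mass 67 at natural composition:
        # 67:66 becomes (4.04 + 0.4) / 27.73
        rng = np.random.default_rng(0)
        run = simulate_measurement(NATURAL, NOISELESS, 0.0, rng)
        bumped = apply_interference(run, InterferenceProfile({67: 0.004}), 1.0)
        assert bumped.replicates[0][66] == pytest.approx((4.04 + 0.4) / 27.73, rel=1e-9)
        assert bumped.replicates[0][66] == pytest.approx(0.160115, abs=5e-7)

    def test_negative_level_rejected(self):
        rng = np.random.default_rng(0)
        run = simulate_measurement(NATURAL, NOISELESS, 0.0, rng)
        with pytest.raises(DomainError):
            apply_interference(run, InterferenceProfile({67: 0.01}), -1.0)


def _tiny_experiment():
    return VirtualExperiment(
        sources={"soil": NATURAL, "fert": labeled_abundances(31.0)},
        treatments=(
            Treatment("ref", "soil", "fert", 0.0, n_replicates=2),
            Treatment("fertilized", "soil", "fert", 0.10, n_replicates=2),
        ),
    )


class TestSimulateExperiment:
    def test_undefined_source_rejected(self):
        with pytest.raises(ConfigError):
            VirtualExperiment(
                sources={"soil": NATURAL},
                treatments=(Treatment("t", "soil", "missing", 0.1),),
            )

    def test_noise_free_end_to_end_identity(self):
        """Noise off, bias off: the downstream mixing model recovers each
        treatment's true fertilizer fraction exactly."""
        ve = _tiny_experiment()
        ds = simulate_experiment(ve, [NOISELESS], seed=0)
        table = replicate_ratio_table(ds)
        pair = SourcePair(ve.sources["soil"], ve.sources["fert"])
        for _, row in table.iterrows():
            z, _ = zndf_fertilizer(row["ratio_67_66"], pair)
            assert z == pytest.approx(row["true_zndf_pct"], abs=1e-9)

    def test_fixed_seed_byte_identical_output(self):
        ve = _tiny_experiment()
        prof = InstrumentProfile.quadrupole()
        ds1 = simulate_experiment(ve, [prof], seed=123)
        ds2 = simulate_experiment(ve, [prof], seed=123)
        for key in ds1.sequences:
            csv1 = sequence_to_frame(ds1.sequences[key]).to_csv(index=False)
            csv2 = sequence_to_frame(ds2.sequences[key]).to_csv(index=False)
            assert csv1 == csv2

    def test_recovery_within_sampling_error(self):
        """Direct-labeling design at 10% truth: over 50 re-simulations the
        recovered mean stays within 3 standard errors of the truth."""
        ve = VirtualExperiment(
            sources={"soil": NATURAL, "fert": labeled_abundances(31.08)},
            treatments=(Treatment("t", "soil", "fert", 0.10, n_replicates=4),),
        )
        pair = SourcePair(ve.sources["soil"], ve.sources["fert"])
        prof = InstrumentProfile.quadrupole()
        means = []
        for s in range(50):
            ds = simulate_experiment(ve, [prof], seed=1000 + s)
            tab = replicate_ratio_table(ds)
            zs = [zndf_fertilizer(r, pair)[0] for r in tab["ratio_67_66"]]
            means.append(np.mean(zs))
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean() - 10.0) < 3 * se
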