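"""Generator contracts: determinism, physical consistency, range fidelity."""

import numpy as np
import pytest

from punchlab import metrics, signals, synthetic
from punchlab.reference import (
    FORCE_ENVELOPE_N,
    RISE_TIME_ENVELOPE_S,
    VELOCITY_ENVELOPE_MPS,
)

from conftest import ZERO_NOISE


class TestMakeCohort:
    def test_seeded_determinism(self):
        a = synthetic.make_cohort(1, (0.5, 0.5), seed=0)[0]
        b = synthetic.make_cohort(1, (0.5, 0.5), seed=0)[0]
        assert a.force_scale == b.force_scale
        assert a.rise_time_base == b.rise_time_base
        assert a.velocity_base == b.velocity_base
        assert np.array_equal(
            a.template.pulse_amplitudes, b.template.pulse_amplitudes
        )

    def test_unique_ids_and_elite_force_range(self):
        cohort = synthetic.make_cohort(10, (0.8, 1.0), seed=7)
        assert len({p.boxer_id for p in cohort}) == 10
        for p in cohort:
            assert 790.0 <= p.force_scale <= 1410.0

    @pytest.mark.parametrize(
        "n,skill", [(0, (0.5, 0.6)), (3, (0.7, 0.2)), (3, (-0.1, 0.5)), (3, (0.5, 1.2))]
    )
    def test_rejects_bad_parameters(self, n, skill):
        with pytest.raises(ValueError):
            synthetic.make_cohort(n, skill, seed=0)

    def test_skill_quartiles_ordered_by_quality(self):
        """Mean q_p of the top skill quartile exceeds the bottom quartile,
        verified by direct q_p recomputation from the generated (F, t, v)."""
        cohort = synthetic.make_cohort(100, (0.0, 1.0), seed=3)
        qp = []
        for p in cohort:
            ds = synthetic.simulate_session(p, 5, seed=p.seed, **ZERO_NOISE)
            qp.append(
                np.mean(
                    [
                        (pp.truth.F_true / pp.truth.t_true) * pp.truth.v_true
                        for pp in ds.punches
                    ]
                )
            )
        order = np.argsort([p.skill for p in cohort])
        qp = np.asarray(qp)[order]
        assert qp[75:].mean() > qp[:25].mean()


class TestSimulatePunch:
    def test_zero_noise_velocity_integral(self, clean_punch):
        tr = clean_punch.truth
        v = signals.estimate_impact_velocity(
            clean_punch.segment, tr.onset_time, tr.impact_time
        )
        assert abs(v - tr.v_true) / tr.v_true < 1e-6

    def test_force_curve_shape(self, clean_punch):
        """Monotone rise from 0 at onset to F exactly at onset + t, then decay."""
        tr, curve = clean_punch.truth, clean_punch.force
        rate = curve.rate
        i_on = int(round(tr.onset_time * rate))
        i_pk = int(round(tr.peak_time * rate))
        f = curve.force
        assert f[i_on] == 0.0
        assert np.all(np.diff(f[i_on : i_pk + 1]) > 0)
        assert f[i_pk] == pytest.approx(tr.F_true, abs=1e-9)
        assert int(np.argmax(f)) == i_pk
        assert np.all(f[i_pk + 1 :] < tr.F_true)

    def test_elite_truths_inside_published_envelopes(self, elite_profile):
        ds = synthetic.simulate_session(elite_profile, 200, seed=5)
        df = ds.truth_frame()
        assert df.F_N.between(*FORCE_ENVELOPE_N).all()
        assert df.t_s.between(*RISE_TIME_ENVELOPE_S).all()
        assert df.v_mps.between(*VELOCITY_ENVELOPE_MPS).all()
        assert not df.clipped.any()

    def test_noisy_force_recovery_unbiased(self, elite_profile):
        """Detected peak force over many noisy punches matches the configured
        mean within two standard errors (Monte-Carlo over the generator)."""
        rng = np.random.default_rng(17)
        recovered = []
        for _ in range(1000):
            p = synthetic.simulate_punch(elite_profile, rng, force_noise_frac=0.02)
            ev = signals.detect_punches(p.force)[0]
            recovered.append(ev.F)
        recovered = np.asarray(recovered)
        configured_mean = elite_profile.force_scale  # E[jitter] = 1, right hand
        se = recovered.std(ddof=1) / np.sqrt(recovered.size)
        # detection picks the max of noisy samples near the peak: tolerate the
        # small positive bias via the jitter-dominated spread
        assert abs(recovered.mean() - configured_mean) < 2 * se + 0.02 * configured_mean

    def test_saturation_flagged_not_silent(self):
        profile = synthetic.CohortProfile(
            boxer_id="x",
            skill=1.0,
            template=synthetic.default_template(),
            force_scale=1000.0,
            rise_time_base=0.15,
            velocity_base=25.0,  # needs > 16 g on the punch axis
            jitter_sd=0.0,
            seed=0,
        )
        p = synthetic.simulate_punch(profile, np.random.default_rng(0), **ZERO_NOISE)
        assert p.truth.clipped
        assert np.abs(p.segment.channels[:3]).max() <= signals.ACCEL_RANGE_G + 1e-12


class TestSimulateSession:
    def test_exact_count_and_determinism(self, elite_profile):
        a = synthetic.simulate_session(elite_profile, 40, seed=9)
        b = synthetic.simulate_session(elite_profile, 40, seed=9)
        assert len(a) == 40
        for pa, pb in zip(a.punches, b.punches):
            assert np.array_equal(pa.segment.channels, pb.segment.channels)
            assert np.array_equal(pa.force.force, pb.force.force)

    def test_singleton_relative_quality_is_one(self, elite_profile):
        ds = synthetic.simulate_session(elite_profile, 1, seed=2)
        df = metrics.add_metrics(ds.truth_frame())
        assert df.q_rp.iloc[0] == 1.0
        assert df.is_best.iloc[0]

    def test_train_and_test_sessions_share_no_draws(self, elite_profile):
        train = synthetic.simulate_session(elite_profile, 500, seed=1)
        test = synthetic.simulate_session(elite_profile, 300, seed=2)
        f_train = train.truth_frame().F_N.to_numpy()
        f_test = test.truth_frame().F_N.to_numpy()
        assert not np.any(np.isin(f_test, f_train))

    def test_best_fraction_rule(self, elite_profile):
        ds = synthetic.simulate_session(elite_profile, 60, seed=4)
        assert ds.truth_frame().is_best.sum() == 3

    def test_rejects_empty_session(self, elite_profile):
        with pytest.raises(ValueError):
            synthetic.simulate_session(elite_profile, 0, seed=1)
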