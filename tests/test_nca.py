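"""Non-compartmental endpoints: trapezoid AUC, Cmax/tmax, BLQ conventions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bectoss import (
    Treatment,
    cmax_tmax,
    compute_endpoints,
    concentration_at,
    endpoints_frame,
    simulate_trial,
    trapezoid_auc,
)
from bectoss.nca import AucTruncationWarning

from _support import SCHEDULE


class TestTrapezoidAuc:
    def test_constant_profile_is_a_rectangle(self):
        assert trapezoid_auc(SCHEDULE, np.full(17, 10.0)) == pytest.approx(720.0)

    def test_hand_computed_trapezoid(self):
        """(0+2)/2*1 + (2+4)/2*2 + (4+1)/2*69 = 179.5."""
        with pytest.warns(AucTruncationWarning):
            # last sample exactly at t_end=72 raises nothing; use 72 directly
            trapezoid_auc([0, 1, 3, 71], [0, 2, 4, 1])
        assert trapezoid_auc([0, 1, 3, 72], [0, 2, 4, 1]) == pytest.approx(179.5)

    def test_interpolation_at_t_end(self):
        """A segment straddling 72 h is linearly cut at exactly 72 h."""
        auc = trapezoid_auc([0, 70, 74], [0, 10, 6], t_end=72.0)
        # c(72) = 10 + (6-10)*(72-70)/4 = 8; area = 350 + (10+8)/2*2
        assert auc == pytest.approx(350.0 + 18.0)

    def test_truncation_warns_and_does_not_extrapolate(self):
        with pytest.warns(AucTruncationWarning, match="truncated"):
            auc = trapezoid_auc([0, 24, 48], [0, 10, 10], t_end=72.0)
        assert auc == pytest.approx(120.0 + 240.0)

    @pytest.mark.parametrize(
        "times, concs, match",
        [([0, 2, 1], [1, 1, 1], "strictly increasing"),
         ([0, 1, 2], [1, -1, 1], "negative"),
         ([1, 2, 3], [1, 1, 1], "start at time 0")],
    )
    def test_input_validation(self, times, concs, match):
        with pytest.raises(ValueError, match=match):
            trapezoid_auc(times, concs)

    def test_additivity_across_an_interior_grid_point(self):
        rng = np.random.default_rng(1)
        concs = rng.uniform(1, 30, SCHEDULE.size)
        full = trapezoid_auc(SCHEDULE, concs, t_end=72.0)
        head = trapezoid_auc(SCHEDULE, concs, t_end=24.0)
        k = int(np.where(SCHEDULE == 24.0)[0][0])
        tail = sum(
            0.5 * (concs[i] + concs[i + 1]) * (SCHEDULE[i + 1] - SCHEDULE[i])
            for i in range(k, SCHEDULE.size - 1)
        )
        assert head + tail == pytest.approx(full, rel=1e-12)

    def test_error_decreases_with_grid_refinement(self):
        """On the smooth kinetic curve, trapezoid error shrinks with density."""
        errors = []
        ke = math.log(2) / 31
        exact = (
            1000.0 * 4 / 83.0 * (
                (1 - math.exp(-ke * 72)) / ke - (1 - math.exp(-72.0)) / 1.0
            ) * 1.0 / (1.0 - ke)
        )
        for n in (10, 40, 160, 640):
            t = np.linspace(0, 72, n + 1)
            c = concentration_at(t, 4, 1.0, ke, 83.0)
            errors.append(abs(trapezoid_auc(t, c) - exact))
        assert all(e1 > e2 for e1, e2 in zip(errors, errors[1:]))

    def test_lin_log_option_differs_and_is_smaller_on_decline(self):
        t = np.array([0.0, 1.0, 24.0, 72.0])
        c = np.array([0.0, 30.0, 10.0, 2.0])
        lin = trapezoid_auc(t, c)
        loglin = trapezoid_auc(t, c, log_down=True)
        assert loglin < lin


class TestCmaxTmax:
    def test_tie_takes_earliest_time(self):
        assert cmax_tmax([0, 1, 2, 3, 8], [0, 5, 9, 9, 4]) == (9.0, 2.0)

    def test_strictly_decreasing_profile(self):
        assert cmax_tmax([0, 0.5, 1, 2], [8, 6, 4, 2]) == (8.0, 0.0)

    def test_all_blq_profile_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            cmax_tmax([0, 1, 2], [0, 0, 0])

    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_scale_equivariance(self, scale):
        """x k: AUC and Cmax scale by k, tmax is unchanged."""
        rng = np.random.default_rng(9)
        concs = np.r_[0.0, rng.uniform(1, 30, SCHEDULE.size - 1)]
        auc0 = trapezoid_auc(SCHEDULE, concs)
        cmax0, tmax0 = cmax_tmax(SCHEDULE, concs)
        auc1 = trapezoid_auc(SCHEDULE, scale * concs)
        cmax1, tmax1 = cmax_tmax(SCHEDULE, scale * concs)
        assert auc1 == pytest.approx(scale * auc0, rel=1e-12)
        assert cmax1 == pytest.approx(scale * cmax0, rel=1e-12)
        assert tmax1 == tmax0


class TestComputeEndpoints:
    def test_one_row_per_subject_and_arm(self, default_trial):
        frame = endpoints_frame(compute_endpoints(default_trial))
        assert len(frame) == 48
        assert frame.groupby("treatment").size().tolist() == [24, 24]
        # tmax is always one of the subject's actual sampling times
        for e in compute_endpoints(default_trial):
            actual = [r.actual_time_h for r in
                      default_trial.profile(e.subject_id, e.treatment)]
            assert e.tmax in actual
            assert e.cmax >= max(
                (r.concentration for r in
                 default_trial.profile(e.subject_id, e.treatment)
                 if not r.blq),
            )

    def test_noise_free_endpoints_match_closed_form(self, quiet_config):
        """Without noise every subject reproduces the typical curve exactly."""
        from bectoss import noise_free_profile

        frame = endpoints_frame(compute_endpoints(simulate_trial(quiet_config)))
        sched = np.asarray(quiet_config.schedule)
        for arm, trt in (("A", Treatment.A_FED), ("B", Treatment.B_FASTED)):
            c = noise_free_profile(quiet_config, trt)
            sub = frame[frame["treatment"] == arm]
            assert np.allclose(sub["cmax"], c.max(), rtol=1e-12)
            assert np.allclose(sub["auc_0_72"], np.trapezoid(c, sched), rtol=1e-12)
            assert np.allclose(sub["tmax"], sched[c.argmax()])

    def test_predose_blq_does_not_move_auc(self, tmp_path):
        """The study's situation: BLQ only at pre-dose; the leading-zero
        convention leaves AUC identical to an explicit zero."""
        from bectoss import read_trial

        header = ("subject_id,sequence,period,treatment,"
                  "nominal_time_h,actual_time_h,concentration_ng_ml\n")
        def rows(conc0):
            out = []
            for period, trt in ((1, "A"), (2, "B")):
                out.append(f"S1,AB,{period},{trt},0,0,{conc0}")
                for t, c in ((0.5, 3.0), (2, 9.0), (72, 1.0)):
                    out.append(f"S1,AB,{period},{trt},{t},{t},{c}")
            return "\n".join(out) + "\n"

        (tmp_path / "blq.csv").write_text(header + rows("BLQ"))
        (tmp_path / "zero.csv").write_text(header + rows("0.0"))
        with pytest.warns(UserWarning):  # 0.0 below LLOQ -> coercion warning
            zero = compute_endpoints(read_trial(tmp_path / "zero.csv"))
        blq = compute_endpoints(read_trial(tmp_path / "blq.csv"))
        for a, b in zip(blq, zero):
            assert a.auc_0_72 == b.auc_0_72
            assert (a.cmax, a.tmax) == (b.cmax, b.tmax)

    def test_embedded_blq_is_spanned(self):
        """A BLQ between quantifiable samples is excluded; the trapezoid
        spans the gap."""
        from bectoss.nca import _usable_profile
        from bectoss import ConcentrationRecord, SequenceGroup

        def rec(t, c, blq=False):
            return ConcentrationRecord(
                subject_id="S1", sequence=SequenceGroup.AB, period=1,
                treatment=Treatment.A_FED, nominal_time_h=t, actual_time_h=t,
                concentration=None if blq else c, blq=blq,
            )

        recs = (rec(0, None, True), rec(1, 4.0), rec(2, None, True), rec(3, 6.0))
        times, concs = _usable_profile(recs)
        assert times.tolist() == [0.0, 1.0, 3.0]
        assert concs.tolist() == [0.0, 4.0, 6.0]
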