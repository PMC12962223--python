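"""Q-matrix SAR evaluation, VOP compression safety, and the multiplexing
SAR-interference statistics."""

import numpy as np
import pytest

import ptxmux as px
from ptxmux.sar import (
    QMatrixSet,
    compress_vop,
    concat_rows,
    local_sar,
    mode_survey,
    multiplexed_mode_sar,
    random_modes,
    switched_drive_sar,
    voxelwise_sar_ratio,
    worst_case_mode,
)
from ptxmux.synth import generate_gaussian_row_q


def random_psd_set(rng, n_voxels, nc, rank=3):
    e = rng.standard_normal((n_voxels, nc, rank)) + 1j * rng.standard_normal((n_voxels, nc, rank))
    mats = np.einsum("vck,vdk->vcd", e, e.conj())
    return QMatrixSet(mats)


def single_step_pulse(p, dt=1e-2, tr=1e-2):
    p = np.atleast_2d(np.asarray(p, dtype=complex))
    return px.PulseProgram(p, np.zeros((p.shape[0], 3)), px.PulseTiming(dt, tr),
                           px.ChannelSchedule.static(p.shape[1], p.shape[0]))


class TestLocalSar:
    def test_identity_q_unit_power_duty_one(self):
        q = QMatrixSet(np.eye(4)[None])
        p = np.zeros(4, dtype=complex)
        p[0] = np.sqrt(0.5)
        p[2] = np.sqrt(0.5) * 1j
        rep = local_sar(single_step_pulse(p), q)  # dt == TR: 100% duty
        assert rep.psar == pytest.approx(1.0, rel=1e-14)

    def test_zero_pulse_zero_sar(self):
        rng = np.random.default_rng(0)
        q = random_psd_set(rng, 10, 4)
        rep = local_sar(single_step_pulse(np.zeros(4)), q)
        assert np.all(rep.sar == 0)

    def test_matches_per_voxel_loop(self):
        rng = np.random.default_rng(1)
        q = random_psd_set(rng, 500, 8)
        nt = 3
        amp = rng.standard_normal((nt, 8)) + 1j * rng.standard_normal((nt, 8))
        pulse = px.PulseProgram(amp, np.zeros((nt, 3)), px.PulseTiming(1e-4, 5e-3),
                                px.ChannelSchedule.static(8, nt))
        rep = local_sar(pulse, q)
        best = 0.0
        for v in range(q.n_voxels):
            s = sum((amp[j].conj() @ q.matrices[v] @ amp[j]).real
                    * pulse.timing.sub_pulse_duration for j in range(nt)) / pulse.timing.tr
            best = max(best, s)
        assert rep.psar == pytest.approx(best, rel=1e-12)

    def test_row_switched_evaluation_uses_matching_row(self):
        rng = np.random.default_rng(2)
        qtop = random_psd_set(rng, 20, 4)
        qbot = random_psd_set(rng, 20, 4)
        sched = px.ChannelSchedule(np.tile(np.arange(4), (2, 1)), ("top", "bottom"))
        amp = rng.standard_normal((2, 4)) + 1j * rng.standard_normal((2, 4))
        pulse = px.PulseProgram(amp, np.zeros((2, 3)), px.PulseTiming(1e-4, 1e-3), sched)
        rep = local_sar(pulse, {"top": qtop, "bottom": qbot})
        coef = pulse.timing.sub_pulse_duration / pulse.timing.tr
        expect = coef * (
            np.einsum("c,vcd,d->v", amp[0].conj(), qtop.matrices, amp[0]).real
            + np.einsum("c,vcd,d->v", amp[1].conj(), qbot.matrices, amp[1]).real
        )
        np.testing.assert_allclose(rep.sar, expect, rtol=1e-12)

    def test_dimension_mismatch_raises(self):
        q = QMatrixSet(np.eye(4)[None])
        with pytest.raises(ValueError, match="dimension"):
            local_sar(single_step_pulse(np.ones(3)), q)


class TestConcatRows:
    def test_two_single_voxel_sets(self):
        a = QMatrixSet(np.eye(8)[None], model_tags=np.array(["top"]))
        b = QMatrixSet(2 * np.eye(8)[None], model_tags=np.array(["bottom"]))
        c = concat_rows(a, b)
        assert c.n_voxels == 2
        assert list(c.model_tags) == ["top", "bottom"]

    def test_joint_compression_never_underestimates_either_row(self, dataset, qcombined):
        # per-row SAR contributions are provably dominated by the joint VOPs
        vop = compress_vop(qcombined, 0.1, probe_modes=0)
        rng = np.random.default_rng(3)
        modes = random_modes(rng, 1000, 16)
        pred = switched_drive_sar(modes, vop).max(axis=1)
        top_part = 2 * dataset.qtop.sar_modes(modes[:, :8]).max(axis=1)
        bot_part = 2 * dataset.qbottom.sar_modes(modes[:, 8:]).max(axis=1)
        assert np.all(pred >= top_part)
        assert np.all(pred >= bot_part)


class TestCompressVop:
    def test_single_voxel_degenerate(self):
        rng = np.random.default_rng(4)
        q = random_psd_set(rng, 1, 4)
        vop = compress_vop(q, 0.05, probe_modes=64, probe_seed=0)
        assert vop.n_vops == 1
        m = random_modes(rng, 50, 4)
        exact = q.sar_modes(m)[:, 0]
        pred = vop.sar_modes(m)[:, 0]
        u_max = np.linalg.eigvalsh(vop.overestimation_term)[-1].real
        power = np.sum(np.abs(m) ** 2, axis=1)
        assert np.all(pred >= exact - 1e-12)
        assert np.all(pred <= exact + u_max * power * (1 + 1e-12))

    def test_identical_matrices_collapse_to_one(self):
        rng = np.random.default_rng(5)
        base = random_psd_set(rng, 1, 6).matrices[0]
        q = QMatrixSet(np.repeat(base[None], 100, axis=0))
        assert compress_vop(q, 0.05, probe_modes=0).n_vops == 1

    def test_compression_and_safety_on_smooth_fixture(self, qcombined):
        # smooth 2000+-voxel synthetic set: strictly fewer VOPs than voxels
        # and no underestimation over thousands of random modes
        vop = compress_vop(qcombined, 0.05, probe_modes=0)
        assert vop.n_vops < qcombined.n_voxels
        rng = np.random.default_rng(6)
        modes = random_modes(rng, 4096, 8)
        exact = qcombined.sar_modes(modes).max(axis=1)
        pred = vop.sar_modes(modes).max(axis=1)
        assert np.all(pred >= exact)

    def test_vop_count_monotone_in_overestimation(self, qcombined):
        counts = [compress_vop(qcombined, f, probe_modes=0).n_vops
                  for f in (0.02, 0.05, 0.1, 0.2)]
        assert counts == sorted(counts, reverse=True)

    def test_psd_validation_rejects_nonpsd(self):
        m = np.eye(4)[None].astype(complex)
        m[0, 0, 0] = -1.0
        with pytest.raises(ValueError, match="eigenvalue"):
            QMatrixSet(m)


class TestWorstCaseMode:
    def test_diagonal_example(self):
        q = QMatrixSet(np.diag([4.0, 1.0])[None])
        mode = worst_case_mode(q)
        # e1 direction up to phase, normalized to 1 W into 50 ohm
        assert abs(mode[1]) < 1e-12
        assert np.sum(np.abs(mode) ** 2) / 50.0 == pytest.approx(1.0)

    def test_beats_random_modes_on_its_voxel(self):
        rng = np.random.default_rng(7)
        q = random_psd_set(rng, 30, 8)
        mode = worst_case_mode(q)
        ev = np.linalg.eigvalsh(q.matrices)[:, -1]
        v = int(np.argmax(ev))
        own = q.sar_modes(mode)[0, v]
        rand = q.sar_modes(random_modes(rng, 1000, 8))[:, v]
        assert np.all(own >= rand - 1e-12)

    def test_phase_invariance(self):
        rng = np.random.default_rng(8)
        q = random_psd_set(rng, 5, 4)
        mode = worst_case_mode(q)
        np.testing.assert_allclose(q.sar_modes(mode * np.exp(0.7j)),
                                   q.sar_modes(mode), rtol=1e-12)


class TestModeSurvey:
    def test_top_row_only_modes_have_equal_psar(self, dataset):
        # modes with zero bottom-row entries: no inter-row interference,
        # simultaneous and multiplexed exact pSAR coincide
        rng = np.random.default_rng(9)
        modes = random_modes(rng, 64, 16)
        modes[:, 8:] = 0.0
        simul = dataset.qfull.sar_modes(modes).max(axis=1)
        mux = multiplexed_mode_sar(modes, dataset.qtop, dataset.qbottom).max(axis=1)
        np.testing.assert_allclose(mux, 2 * simul, rtol=1e-12)
        # (keep-duration doubling: the single live row deposits twice the
        # time-average at halved duration and doubled amplitude)

    def test_constructive_and_destructive_limits(self):
        # rank-1 voxel with equal row field vectors -> ratio 1; opposite -> 0
        rng = np.random.default_rng(10)
        e = rng.standard_normal((8, 1, 3)) + 1j * rng.standard_normal((8, 1, 3))
        for sign, expect in ((1.0, 1.0), (-1.0, 0.0)):
            e16 = np.concatenate([e, sign * e], axis=0)
            gram = np.einsum("cvk,dvk->vcd", e16, e16.conj())
            qfull = QMatrixSet(gram)
            qtop = QMatrixSet(gram[:, :8, :8])
            qbot = QMatrixSet(gram[:, 8:, 8:])
            mode = random_modes(rng, 1, 16)
            mode[0, 8:] = mode[0, :8]  # identical half-drives
            ratio, _ = voxelwise_sar_ratio(mode[0], qtop, qbot, qfull)
            if expect == 0.0:
                assert ratio.size == 0 or ratio[0] == pytest.approx(0.0, abs=1e-10)
            else:
                assert ratio[0] == pytest.approx(expect, abs=1e-10)

    def test_orthogonal_row_fields_give_half(self):
        # cross term zero by construction -> ratio exactly 0.5
        e_top = np.zeros((8, 1, 3), dtype=complex)
        e_bot = np.zeros((8, 1, 3), dtype=complex)
        e_top[:, 0, 0] = 1.0 + 0.5j
        e_bot[:, 0, 1] = 0.3 - 1.0j   # orthogonal field components
        e16 = np.concatenate([e_top, e_bot], axis=0)
        gram = np.einsum("cvk,dvk->vcd", e16, e16.conj())
        rng = np.random.default_rng(11)
        mode = random_modes(rng, 1, 16)[0]
        ratio, _ = voxelwise_sar_ratio(mode, QMatrixSet(gram[:, :8, :8]),
                                       QMatrixSet(gram[:, 8:, 8:]), QMatrixSet(gram))
        assert ratio[0] == pytest.approx(0.5, abs=1e-12)

    def test_mean_inverse_penalty_half_on_decorrelated_rows(self):
        # independent per-row Gaussian E-fields: mean voxel-wise ratio 0.5
        qtop, qbot, qfull = generate_gaussian_row_q(500, seed=12)
        rng = np.random.default_rng(13)
        modes = random_modes(rng, 4096, 16)
        simul = qfull.sar_modes(modes)
        mux = multiplexed_mode_sar(modes, qtop, qbot)
        assert (simul / mux).mean() == pytest.approx(0.5, abs=0.02)

    def test_survey_table_and_safety_columns(self, dataset, qcombined, vops):
        rng = np.random.default_rng(14)
        modes = random_modes(rng, 256, 16)
        extras = {"cp": px.cp_mode(dataset.fields),
                  "worst_case": worst_case_mode(dataset.qfull)}
        df, summary = mode_survey(modes, dataset.qfull, vops["full_vop"],
                                  qcombined, vops["combined_vop"],
                                  extra_modes=extras)
        assert len(df) == 258
        assert set(summary["median_psar"]) == {"qfull", "qfull_vop",
                                               "qcombined", "qcombined_vop"}
        # full16 VOP predictions never underestimate the exact values
        assert (df.psar_qfull_vop >= df.psar_qfull - 1e-12).all()
        # amplification may fall below 1 for individual modes; the survey
        # must not assume otherwise (no assertion of >= 1 here)
        assert np.isfinite(df.amp_q).all()

    def test_voxelwise_ratio_bounds(self, dataset):
        # parallelogram identity: simultaneous SAR <= 2x(row SAR sum),
        # hence the inverse ratio lies in [0, 1]
        rng = np.random.default_rng(15)
        for mode in random_modes(rng, 8, 16):
            ratio, summary = voxelwise_sar_ratio(mode, dataset.qtop,
                                                 dataset.qbottom, dataset.qfull)
            assert ratio.min() >= -1e-12
            assert ratio.max() <= 1.0 + 1e-10
            assert summary["iqr"][0] <= summary["median"] <= summary["iqr"][1]
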