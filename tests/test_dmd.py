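"""Exact and Hankel DMD: construction, truncation rules, spectra, reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitdmd.dmd import (
    DMDModel,
    HankelDMD,
    RankRule,
    SnapshotPair,
    build_hankel,
    choose_truncation,
    compute_amplitudes,
    exact_dmd,
    hankel_dmd,
    reconstruct,
)
from gaitdmd.synthetic import BASE_MODES, ModeParams, step_force_from_params

DT = 0.02


def damped_signal(triplets, n=100, dt=DT):
    return step_force_from_params(
        [ModeParams(a, f, s) for a, f, s in triplets], n, dt)


BASE_SIGNAL = step_force_from_params(
    [ModeParams(a, f, s) for a, f, s in BASE_MODES], 100, DT)


class TestBuildHankel:
    def test_definition(self):
        H = build_hankel([1, 2, 3, 4], rows=2, cols=3)
        assert H.tolist() == [[1, 2, 3], [2, 3, 4]]

    def test_single_row_is_series(self):
        s = np.arange(5.0)
        assert np.array_equal(build_hankel(s, rows=1), s[None, :])

    def test_constant_series_rank_one(self):
        H = build_hankel(np.full(10, 3.0), rows=4)
        assert np.linalg.matrix_rank(H) == 1

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError, match="too short"):
            build_hankel([1, 2, 3], rows=3, cols=3)

    def test_first_row_reproduces_series(self):
        s = np.sin(np.arange(20) * 0.3)
        H = build_hankel(s, rows=6)
        assert np.array_equal(H[0], s[:15])


class TestExactDMD:
    def test_scalar_decay_single_eigenvalue(self):
        series = 0.9 ** np.arange(20)
        D = build_hankel(series, rows=2)
        model = exact_dmd(SnapshotPair.from_snapshots(D), RankRule.fixed(1))
        assert model.eigvals.shape == (1,)
        assert model.eigvals[0] == pytest.approx(0.9, abs=1e-12)

    def test_matrix_iteration_recovers_spectrum(self):
        # oracle: direct eigendecomposition of the generating 2x2 map
        A = np.array([[0.9, 0.3], [-0.2, 0.7]])
        x = np.array([1.0, 2.0])
        snaps = [x]
        for _ in range(12):
            snaps.append(A @ snaps[-1])
        D = np.stack(snaps, axis=1)
        model = exact_dmd(SnapshotPair.from_snapshots(D), RankRule.fixed(2))
        expected = np.linalg.eigvals(A)
        assert np.allclose(sorted(model.eigvals, key=np.real),
                           sorted(expected, key=np.real), rtol=1e-10)

    def test_noiseless_three_pair_fit_error(self):
        sig = damped_signal([(-4.0, 1.0, 0.7 - 0.2j), (-3.0, 3.0, 0.3 + 0.1j),
                             (-2.0, 6.0, 0.1 + 0.4j)])
        D = build_hankel(sig, rows=20)
        pair = SnapshotPair.from_snapshots(D)
        model = exact_dmd(pair, RankRule.fixed(6))
        assert model.fit_error <= 1e-8 * np.linalg.norm(pair.Y, 2)

    def test_zero_matrix_raises(self):
        with pytest.raises(ValueError, match="zero data"):
            exact_dmd(SnapshotPair(np.zeros((3, 4)), np.zeros((3, 4))))

    def test_conjugate_closure_real_input(self, rng):
        sig = BASE_SIGNAL + 0.5 * rng.standard_normal(100)
        model = hankel_dmd(sig, rows=40, rank_rule=RankRule.fixed(12), dt=DT)
        mu = model.eigvals
        for m in mu:
            if abs(m.imag) > 1e-9:
                assert np.min(np.abs(mu - np.conj(m))) < 1e-9 * np.abs(mu).max()

    def test_rank_clamped_to_numerical_rank(self):
        sig = damped_signal([(-3.0, 1.0, 1.0)])  # rank-2 signal
        D = build_hankel(sig, rows=10)
        model = exact_dmd(SnapshotPair.from_snapshots(D), RankRule.fixed(30))
        assert model.rank <= 4  # clamped far below 30


class TestChooseTruncation:
    def test_exact_rank_recovery(self):
        sig = damped_signal([(-3.0, 2.0, 1.0)])
        pair = SnapshotPair.from_snapshots(build_hankel(sig, rows=10))
        assert choose_truncation(pair, RankRule.error_threshold(1e-10)) == 2

    def test_full_variance_gives_full_rank(self):
        sig = BASE_SIGNAL
        pair = SnapshotPair.from_snapshots(build_hankel(sig, rows=20))
        r_full = choose_truncation(pair, RankRule.variance_retained(1.0))
        assert r_full == 12  # numerical rank of the 6-pair signal

    def test_monotone_in_tolerance(self):
        pair = SnapshotPair.from_snapshots(build_hankel(BASE_SIGNAL, rows=30))
        rs = [choose_truncation(pair, RankRule.error_threshold(eps))
              for eps in (1e-8, 1e-4, 1e0, 1e4)]
        assert rs == sorted(rs, reverse=True)

    def test_monotone_in_variance_fraction(self):
        pair = SnapshotPair.from_snapshots(build_hankel(BASE_SIGNAL, rows=30))
        rs = [choose_truncation(pair, RankRule.variance_retained(q))
              for q in (0.9, 0.99, 0.999, 1.0)]
        assert rs == sorted(rs)

    def test_invalid_rules(self):
        with pytest.raises(ValueError):
            RankRule.fixed(0)
        with pytest.raises(ValueError):
            RankRule.variance_retained(1.5)
        with pytest.raises(ValueError):
            RankRule.error_threshold(-1.0)


class TestAmplitudes:
    def test_single_mode_identity(self):
        d0 = np.array([1.0, 2.0, 3.0])
        b = compute_amplitudes(d0[:, None], d0)
        assert b[0] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_modes_inner_products(self):
        M = np.eye(3)[:, :2]
        d0 = np.array([0.4, -1.2, 9.0])
        b = compute_amplitudes(M, d0)
        assert np.allclose(b, d0[:2])

    def test_noiseless_amplitude_recovery(self, base_profile):
        model = hankel_dmd(BASE_SIGNAL, dt=DT, stance_len=44)
        from gaitdmd.features import featurize_step

        fs = featurize_step(model, n_modes=6)
        truth = np.array([abs(s) for _, _, s in BASE_MODES])
        got = np.array([f.s0 for f in fs.features])
        assert np.allclose(np.sort(got), np.sort(truth), rtol=1e-6)


class TestHankelDMD:
    def test_pure_exponential_single_real_eigenvalue(self):
        series = np.exp(-3.0 * np.arange(50) * DT)
        model = hankel_dmd(series, rows=5, rank_rule=RankRule.fixed(1), dt=DT)
        assert model.eigvals[0] == pytest.approx(np.exp(-3.0 * DT), abs=1e-10)

    def test_noiseless_six_pair_recovery(self):
        from gaitdmd.features import featurize_step

        model = hankel_dmd(BASE_SIGNAL, dt=DT, stance_len=44)
        fs = featurize_step(model, n_modes=6)
        truth = np.array([[a, f, abs(s)] for a, f, s in BASE_MODES])
        assert np.allclose(fs.as_array(), truth, rtol=1e-6)

    def test_embedding_invariance(self):
        from gaitdmd.features import featurize_step

        arrs = []
        for rows in (30, 40):
            model = hankel_dmd(BASE_SIGNAL, rows=rows,
                               rank_rule=RankRule.fixed(12), dt=DT)
            arrs.append(featurize_step(model, n_modes=6).as_array())
        assert np.allclose(arrs[0], arrs[1], rtol=1e-6)

    def test_fit_error_monotone_in_rank(self):
        errs = [hankel_dmd(BASE_SIGNAL, rows=30, rank_rule=RankRule.fixed(r),
                           dt=DT).fit_error for r in (2, 4, 8, 12)]
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_bare_series_requires_dt(self):
        with pytest.raises(ValueError, match="dt"):
            hankel_dmd(np.ones(10))


class TestReconstruct:
    def test_constant_mode(self):
        model = DMDModel(eigvals=np.array([1.0 + 0j]),
                         modes=np.array([[1.0 + 0j]]),
                         amplitudes=np.array([2.5 + 0j]),
                         rank=1, fit_error=0.0, dt=DT)
        assert np.allclose(reconstruct(model, 5), 2.5)

    def test_roundtrip_noiseless(self):
        model = hankel_dmd(BASE_SIGNAL, dt=DT, stance_len=44)
        rec = reconstruct(model, 100)
        assert np.linalg.norm(rec - BASE_SIGNAL) <= 1e-6 * np.linalg.norm(BASE_SIGNAL)

    def test_two_mode_truncation_correlates(self):
        from gaitdmd.features import featurize_step, reconstruct_from_features

        model = hankel_dmd(BASE_SIGNAL, dt=DT, stance_len=44)
        rec2 = reconstruct_from_features(featurize_step(model, n_modes=2), 100, DT)
        assert np.corrcoef(rec2, BASE_SIGNAL)[0, 1] >= 0.9


class TestSerialization:
    def test_json_roundtrip(self, tmp_path):
        model = hankel_dmd(BASE_SIGNAL, rows=30, rank_rule=RankRule.fixed(12), dt=DT)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = DMDModel.from_json(path)
        assert np.allclose(back.eigvals, model.eigvals)
        assert np.allclose(back.modes, model.modes)
        assert np.allclose(back.amplitudes, model.amplitudes)
        assert back.rank == model.rank and back.hankel_rows == model.hankel_rows


class TestModelObject:
    def test_fit_results_and_summary(self):
        res = HankelDMD(BASE_SIGNAL, dt=DT, rank_rule=RankRule.fixed(12)).fit()
        assert res.rank == 12
        assert res.rel_reconstruction_error() < 1e-8
        text = res.summary()
        assert "rank r: 12" in text and "alpha" in text

    def test_fit_accepts_step_signal(self, base_profile, rng):
        from gaitdmd.synthetic import simulate_step_force

        sig = simulate_step_force(base_profile, rng)
        res = HankelDMD(sig).fit()
        assert res.fit_error < 1e-6


@settings(max_examples=25, deadline=None, derandomize=True)
@given(alpha=st.floats(-6.0, -1.0), freq=st.floats(0.5, 8.0),
       re=st.floats(-1.0, 1.0), im=st.floats(0.2, 1.0))
def test_single_pair_recovery_property(alpha, freq, re, im):
    """Any damped conjugate pair below Nyquist is recovered from its own signal."""
    sig = damped_signal([(alpha, freq, complex(re, im))])
    model = hankel_dmd(sig, rows=10, rank_rule=RankRule.fixed(2), dt=DT)
    mu = model.eigvals[np.argmax(model.eigvals.imag)]
    assert np.log(mu).real / DT == pytest.approx(alpha, rel=1e-6, abs=1e-8)
    assert np.log(mu).imag / (2 * np.pi * DT) == pytest.approx(freq, rel=1e-6)
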