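import numpy as np
import pytest

from eegcs.codec import CodecConfig, QuantizerSpec, compress_epoch
from eegcs.io_core import demean, nmse
from eegcs.recon import (
    ReconstructionConfig,
    bpdn_solve,
    default_sigma,
    reconstruct_epoch,
)
from eegcs.sensing import generate_sparse_binary_matrix


class TestBPDNSolve:
    def test_zero_measurements_give_zero(self, rng):
        A = rng.normal(size=(10, 30))
        res = bpdn_solve(A, np.zeros(10), sigma=0.0)
        assert np.all(res.coef == 0.0) and res.converged

    def test_large_sigma_gives_zero(self, rng):
        A = rng.normal(size=(10, 30))
        y = rng.normal(size=10)
        res = bpdn_solve(A, y, sigma=2.0 * np.linalg.norm(y))
        assert np.all(res.coef == 0.0)

    def test_planted_sparse_recovery(self, rng):
        A = rng.normal(size=(40, 120)) / np.sqrt(40)
        c0 = np.zeros(120)
        idx = rng.choice(120, 5, replace=False)
        c0[idx] = rng.normal(size=5) * 3
        res = bpdn_solve(A, A @ c0, sigma=0.0)
        assert np.linalg.norm(res.coef - c0) / np.linalg.norm(c0) < 1e-6

    def test_matches_linear_program_oracle(self, rng):
        """Equality-constrained basis pursuit agrees with the LP formulation
        min 1'(c+ + c-) s.t. A(c+ - c-) = y solved by an independent solver."""
        from scipy.optimize import linprog

        A = rng.normal(size=(15, 40))
        c0 = np.zeros(40)
        c0[[3, 17, 31]] = [2.0, -1.5, 0.7]
        y = A @ c0
        res = bpdn_solve(A, y, sigma=0.0)
        lp = linprog(
            np.ones(80),
            A_eq=np.hstack([A, -A]),
            b_eq=y,
            bounds=(0, None),
            method="highs",
        )
        c_lp = lp.x[:40] - lp.x[40:]
        assert abs(res.l1_norm - np.abs(c_lp).sum()) < 1e-6 * max(1, np.abs(c_lp).sum())
        np.testing.assert_allclose(res.coef, c_lp, atol=1e-5)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            bpdn_solve(rng.normal(size=(5, 8)), np.zeros(6))


def test_default_sigma_is_quantization_rms():
    assert default_sigma(1.0, 12) == pytest.approx(1.0)
    assert default_sigma(0.5, 300) == pytest.approx(0.5 * np.sqrt(300 / 12))


class TestReconstructEpoch:
    def test_constant_channels_exact(self, dict128):
        from eegcs.io_core import Epoch

        e = Epoch(np.column_stack([np.full(128, 40.0), np.full(128, -12.0)]))
        comp = compress_epoch(e, CodecConfig(cr_target=2.0, seed=3))
        out = reconstruct_epoch(comp, dict128)
        np.testing.assert_allclose(out.F_rec, e.F, atol=1.0)

    def test_oracle_equivalence_square_system(self, dict128, rng):
        """With M = N and an invertible dense sensing matrix at sigma = 0,
        f_hat = Psi c must reproduce the least-squares (exact) inversion."""
        from eegcs.recon import reconstruct_measurements

        N = 128
        Phi = np.eye(N) + 0.01 * rng.normal(size=(N, N))
        f = dict128.Psi[:, 37] * 50 + dict128.Psi[:, 200] * 20
        y = Phi @ f
        A = Phi @ dict128.Psi
        res = bpdn_solve(A, y, sigma=0.0)
        f_hat = dict128.Psi @ res.coef
        f_ls = np.linalg.solve(Phi, y)
        np.testing.assert_allclose(f_hat, f_ls, atol=1e-6 * np.abs(f_ls).max())

    def test_planted_epoch_full_digital_path(self, dict128):
        """Gabor-sparse channels survive the full 15-bit digital path."""
        from eegcs.io_core import Epoch

        rng = np.random.default_rng(5)
        F = np.zeros((128, 3))
        for j in range(3):
            idx = rng.choice(dict128.K - 1, 5, replace=False)
            F[:, j] = dict128.Psi[:, idx] @ (rng.normal(size=5) * 300)
        e = Epoch(F)
        comp = compress_epoch(e, CodecConfig(cr_target=2.0, seed=9))
        out = reconstruct_epoch(comp, dict128)
        vals = [nmse(e.F[:, j], out.F_rec[:, j]) for j in range(3)]
        assert np.mean(vals) < 1e-3

    def test_quantizer_calibrated_sigma_not_worse_than_exact_fit(self, dict128):
        """On inputs whose only distortion is quantization noise, the
        noise-calibrated residual bound must not lose to forcing an exact fit
        of the quantized measurements."""
        from eegcs.io_core import Epoch

        rng = np.random.default_rng(17)
        vals_auto, vals_zero = [], []
        for t in range(4):
            F = np.zeros((128, 2))
            for j in range(2):
                idx = rng.choice(dict128.K - 1, 6, replace=False)
                # small amplitudes: quantization error is the dominant noise
                F[:, j] = dict128.Psi[:, idx] @ (rng.normal(size=6) * 40)
            e = Epoch(F)
            comp = compress_epoch(e, CodecConfig(cr_target=2.0, seed=t))
            out_a = reconstruct_epoch(comp, dict128)
            out_z = reconstruct_epoch(
                comp, dict128, cfg=ReconstructionConfig(sigma=0.0)
            )
            vals_auto.append(np.mean([nmse(e.F[:, j], out_a.F_rec[:, j]) for j in range(e.C)]))
            vals_zero.append(np.mean([nmse(e.F[:, j], out_z.F_rec[:, j]) for j in range(e.C)]))
        assert np.mean(vals_auto) <= np.mean(vals_zero)

    def test_lost_packets_degrade_gracefully(self, dict128, small_epochs):
        e = small_epochs[4]
        comp = compress_epoch(e, CodecConfig(cr_target=2.0, seed=6))
        out0 = reconstruct_epoch(comp, dict128)
        out1 = reconstruct_epoch(comp, dict128, lost_packets=[0])
        assert len(out1.lost_rows) > 0
        n0 = np.mean([nmse(e.F[:, j], out0.F_rec[:, j]) for j in range(e.C)])
        n1 = np.mean([nmse(e.F[:, j], out1.F_rec[:, j]) for j in range(e.C)])
        assert n1 < 1.0  # still far better than predicting the mean
        assert n0 <= n1 + 0.05
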