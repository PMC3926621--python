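"""Server-side reconstruction.

Each channel is recovered independently by basis pursuit denoise,

    min ||c||_1   subject to   ||y - A c||_2 <= sigma,    A = Phi Psi,

solved with a spectral projected-gradient method on the LASSO subproblem
combined with Newton root finding on the Pareto curve phi(tau) = ||r(tau)||_2
(the classic approach for this problem class).  With sigma = 0 the same
routine solves equality-constrained basis pursuit to tolerance.

The default residual tolerance is calibrated to the quantizer: a uniform
quantizer with step q contributes q^2/12 error variance per measurement, so
sigma = q * sqrt(M / 12) matches the RMS quantization noise aggregated over
M measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from . import codec as _codec
from .gabor import GaborDictionary
from .io_core import Epoch
from .redundancy import DifferenceBlock, invert_differences
from .sensing import MeasurementMatrix, generate_sparse_binary_matrix


@dataclass
class ReconstructionConfig:
    sigma: Optional[float] = None  # None -> quantizer-calibrated default
    max_matvec: int = 4000
    tol: float = 1e-7
    inner_iter: int = 150
    debias: bool = True  # least-squares polish on the support when sigma = 0

    def __post_init__(self) -> None:
        if self.sigma is not None and self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


def default_sigma(step: float, M: int) -> float:
    """RMS quantization noise over M measurements: step * sqrt(M / 12)."""
    return step * math.sqrt(M / 12.0)


def _project_l1(v: np.ndarray, tau: float) -> np.ndarray:
    """Euclidean projection onto the l1 ball of radius tau (sort-based)."""
    if tau <= 0.0:
        return np.zeros_like(v)
    a = np.abs(v)
    if a.sum() <= tau:
        return v.copy()
    u = np.sort(a)[::-1]
    cssv = np.cumsum(u) - tau
    k = np.arange(1, u.size + 1)
    rho = np.nonzero(u - cssv / k > 0)[0][-1]
    theta = cssv[rho] / (rho + 1.0)
    return np.sign(v) * np.maximum(a - theta, 0.0)


@dataclass
class BPDNResult:
    coef: np.ndarray
    residual_norm: float
    l1_norm: float
    n_matvec: int
    converged: bool


def bpdn_solve(
    A: np.ndarray,
    y: np.ndarray,
    sigma: float = 0.0,
    cfg: ReconstructionConfig | None = None,
) -> BPDNResult:
    """Solve min ||c||_1 s.t. ||y - A c||_2 <= sigma.

    ``A`` is a dense M x K matrix (the composed operator Phi Psi).  Returns
    the best iterate with diagnostics; ``converged`` is False if the matvec
    budget ran out first.
    """
    cfg = cfg or ReconstructionConfig()
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    m, K = A.shape
    if y.size != m:
        raise ValueError("measurement length does not match operator")

    bnorm = float(np.linalg.norm(y))
    if bnorm == 0.0 or bnorm <= sigma:
        return BPDNResult(np.zeros(K), bnorm, 0.0, 0, True)

    nmv = 0

    def matvec(c):
        nonlocal nmv
        nmv += 1
        return A @ c

    def rmatvec(r):
        nonlocal nmv
        nmv += 1
        return A.T @ r

    x = np.zeros(K)
    r = y.copy()
    g = -rmatvec(r)
    f = 0.5 * float(r @ r)
    tau = 0.0
    rnorm = bnorm
    # Hitting the residual target much more precisely than a couple of
    # percent of sigma does not change the reconstruction; it only burns
    # matvecs walking the Pareto curve.
    tol_res = max(cfg.tol * max(1.0, bnorm), 0.02 * sigma)
    alpha_bb = 1.0 / max(np.abs(g).max(), 1e-12)
    converged = False
    shrink = 1e-3  # step for the overshoot polish below

    for _outer in range(120):
        gnorm_inf = float(np.abs(g).max())
        if gnorm_inf <= 1e-14:
            converged = True
            break
        if _outer > 0 and rnorm <= sigma + tol_res:
            # Feasible. An iterate strictly inside the l1 ball means the
            # Newton step overshot the Pareto root (the subproblem optimum
            # is then non-unique); shrink the ball towards the iterate's own
            # l1 norm and re-solve, walking tau back down to the root.
            l1 = float(np.abs(x).sum())
            if l1 >= tau * (1.0 - 1e-6):
                converged = True
                break
            tau = l1 * (1.0 - shrink)
            shrink = min(0.2, 2.0 * shrink)
        else:
            shrink = 1e-3
            # Newton step on phi(tau) = ||r||: phi' = -||A'r||_inf / ||r||
            tau_new = tau + (rnorm - sigma) * rnorm / gnorm_inf
            if tau_new <= tau:
                tau_new = tau + max(1e-12, 0.1 * (rnorm - sigma) * rnorm / gnorm_inf)
            tau = tau_new

        # Spectral projected gradient on min 0.5||y-Ac||^2 s.t. ||c||_1 <= tau
        x = _project_l1(x, tau)
        r = y - matvec(x)
        f = 0.5 * float(r @ r)
        g = -rmatvec(r)
        hist: List[float] = [f]
        # Subproblem accuracy: loose while the Pareto root is far, tight at
        # the end — inexact subproblems make the Newton step overshoot tau.
        gap_tol = 10.0 * cfg.tol
        for _inner in range(cfg.inner_iter):
            # LASSO duality gap (primal 0.5||r||^2): gap = r'(r-y) + tau*||A'r||_inf
            gap = float(r @ (r - y)) + tau * float(np.abs(g).max())
            if gap / max(1.0, f) <= gap_tol:
                break
            x_try = _project_l1(x - alpha_bb * g, tau)
            d = x_try - x
            dnorm = float(np.abs(d).max())
            if dnorm <= 1e-15:
                break
            gtd = float(g @ d)
            lam = 1.0
            fmax = max(hist)
            while True:
                xt = x + lam * d
                rt = y - matvec(xt)
                ft = 0.5 * float(rt @ rt)
                if ft <= fmax + 1e-4 * lam * gtd or lam < 1e-9:
                    break
                lam *= 0.5
            s = xt - x
            g_new = -rmatvec(rt)
            yk = g_new - g
            sty = float(s @ yk)
            alpha_bb = (
                min(1e10, max(1e-10, float(s @ s) / sty)) if sty > 1e-16 else 1.0
            )
            x, r, f, g = xt, rt, ft, g_new
            hist.append(f)
            if len(hist) > 8:
                hist.pop(0)
            rnorm = math.sqrt(2.0 * f)
            if rnorm <= sigma + tol_res:
                break
            if nmv >= cfg.max_matvec:
                break
        rnorm = float(np.linalg.norm(r))
        if nmv >= cfg.max_matvec:
            converged = rnorm <= sigma + tol_res
            break

    if cfg.debias and sigma == 0.0 and np.any(x):
        # Final polish for equality-constrained basis pursuit: least squares
        # on the sparsest detected support that still fits the measurements.
        # Scanning thresholds from coarse to fine both removes the l1
        # shrinkage bias and discards small spurious coefficients that slow
        # first-order convergence on coherent dictionaries.
        amax = float(np.abs(x).max())
        fit_tol = max(tol_res, 1e-9 * bnorm)
        # Only supports well below M qualify: an exact fit with few atoms is
        # evidence of true sparsity, while any ~M-atom support can fit y
        # exactly and would silently replace the l1 solution on merely
        # compressible signals.
        for thr in (0.1, 0.03, 0.01, 3e-3, 1e-3, 1e-4, 1e-5):
            support = np.abs(x) > thr * amax
            ns = int(support.sum())
            if ns == 0 or ns > m // 2:
                continue
            sol, *_ = np.linalg.lstsq(A[:, support], y, rcond=None)
            res_norm = float(np.linalg.norm(y - A[:, support] @ sol))
            if res_norm <= fit_tol:
                x = np.zeros_like(x)
                x[support] = sol
                r = y - A @ x
                rnorm = res_norm
                converged = True
                break

    return BPDNResult(
        coef=x,
        residual_norm=rnorm,
        l1_norm=float(np.abs(x).sum()),
        n_matvec=nmv,
        converged=converged,
    )


@dataclass
class ReconstructedEpoch:
    F_rec: np.ndarray
    diagnostics: List[BPDNResult]
    lost_rows: Sequence[int] = field(default_factory=tuple)

    @property
    def epoch(self) -> Epoch:
        return Epoch(self.F_rec)


def reconstruct_measurements(
    Y: np.ndarray,
    phi: MeasurementMatrix,
    dictionary: GaborDictionary,
    cfg: ReconstructionConfig | None = None,
    sigma: float | None = None,
    keep_rows: Optional[np.ndarray] = None,
) -> ReconstructedEpoch:
    """Per-channel BPDN against Phi Psi, for already-decoded measurements Y.

    ``keep_rows`` restricts the system to the measurement rows that survived
    transmission (packet loss deletes rows of Phi and Y alike).
    """
    cfg = cfg or ReconstructionConfig()
    Phi = phi.toarray()
    if keep_rows is not None:
        Phi = Phi[keep_rows, :]
        Y = Y[keep_rows, :]
    A = Phi @ dictionary.Psi
    if sigma is None:
        sigma = cfg.sigma if cfg.sigma is not None else 0.0
    F = np.empty((dictionary.N, Y.shape[1]))
    diags = []
    for j in range(Y.shape[1]):
        res = bpdn_solve(A, Y[:, j], sigma=sigma, cfg=cfg)
        F[:, j] = dictionary.Psi @ res.coef
        diags.append(res)
    return ReconstructedEpoch(F_rec=F, diagnostics=diags)


def reconstruct_epoch(
    comp: "_codec.CompressedEpoch",
    dictionary: GaborDictionary,
    cfg: ReconstructionConfig | None = None,
    lost_packets: Sequence[int] = (),
) -> ReconstructedEpoch:
    """Full server-side path: depacketize, entropy-decode, dequantize,
    de-interleave, invert differences, BPDN per channel, restore means.

    With ``lost_packets``, symbols whose bits fell in lost packets are
    dropped; a measurement row with any missing channel is deleted for all
    channels (the difference schedule couples channels within a row) and
    reconstruction proceeds from the row-deleted system.
    """
    cfg = cfg or ReconstructionConfig()
    h = comp.header
    codes, lost_symbols = _codec.decode_payload(comp, lost_packets=lost_packets)
    v = _codec.dequantize(codes, comp.quantizer)
    Yt = _codec.deinterleave(v, h.M, h.C)

    lost_rows = sorted({k // h.C for k in lost_symbols})
    keep = np.setdiff1d(np.arange(h.M), np.asarray(lost_rows, dtype=int))
    if keep.size == 0:
        raise ValueError("all measurement rows lost; nothing to reconstruct")

    # Difference inversion acts row-by-row, so it commutes with row deletion.
    Yq = invert_differences(DifferenceBlock(Yt[keep, :]), comp.pair_list)
    phi = generate_sparse_binary_matrix(h.M, h.N, h.d, h.seed)
    sigma = cfg.sigma
    if sigma is None:
        sigma = default_sigma(comp.quantizer.step, keep.size)
    A = phi.toarray()[keep, :] @ dictionary.Psi
    F = np.empty((dictionary.N, h.C))
    diags = []
    for j in range(h.C):
        res = bpdn_solve(A, Yq.Y[:, j], sigma=sigma, cfg=cfg)
        F[:, j] = dictionary.Psi @ res.coef
        diags.append(res)
    F += comp.means[None, :]
    return ReconstructedEpoch(F_rec=F, diagnostics=diags, lost_rows=tuple(lost_rows))
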