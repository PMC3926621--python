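"""Sparse binary measurement matrices and addition-only projection.

The sensing operator is an M x N binary matrix with exactly ``d`` ones per
column (default d = 8).  Projecting a channel is then N*d additions — no
multiplications — which is what makes the sensor-side cost so low.  The
matrix is never transmitted: sensor and server regenerate it bit-exactly
from (M, N, d, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import DemeanedEpoch

DEFAULT_D = 8


@dataclass(frozen=True)
class MeasurementMatrix:
    """Sparse binary sensing matrix stored as per-column row-index patterns."""

    M: int
    N: int
    d: int
    seed: int
    pattern: np.ndarray  # d x N int array: rows holding 1 in each column

    def toarray(self) -> np.ndarray:
        """Dense {0,1} matrix (reference form; the codec never materializes it)."""
        Phi = np.zeros((self.M, self.N))
        for j in range(self.N):
            Phi[self.pattern[:, j], j] = 1.0
        return Phi


@dataclass
class MeasurementBlock:
    """Y = [Phi f1 | ... | Phi fC]: compressed measurements, one column per channel."""

    Y: np.ndarray

    @property
    def M(self) -> int:
        return self.Y.shape[0]

    @property
    def C(self) -> int:
        return self.Y.shape[1]


def generate_sparse_binary_matrix(
    M: int, N: int, d: int = DEFAULT_D, seed: int = 0
) -> MeasurementMatrix:
    """Draw, per column, ``d`` distinct row indices uniformly without replacement.

    Deterministic given ``seed`` (a dedicated PCG64 stream), so the matrix can
    be shared between sensor and server by exchanging the seed alone.
    """
    if d < 1 or d > M:
        raise ValueError(f"need 1 <= d <= M, got d={d}, M={M}")
    if M > N:
        raise ValueError(f"need M <= N, got M={M}, N={N}")
    rng = np.random.Generator(np.random.PCG64(seed))
    pattern = np.empty((d, N), dtype=np.int64)
    for j in range(N):
        pattern[:, j] = rng.choice(M, size=d, replace=False)
    return MeasurementMatrix(M=M, N=N, d=d, seed=seed, pattern=pattern)


def project(phi: MeasurementMatrix, e: DemeanedEpoch) -> MeasurementBlock:
    """Y[:, j] = Phi @ ftilde_j, computed by index-gather additions only."""
    if phi.N != e.N:
        raise ValueError(f"matrix expects N={phi.N}, epoch has N={e.N}")
    Y = np.zeros((phi.M, e.C))
    # Each column j of Phi contributes sample j of every channel to d rows.
    for j in range(phi.N):
        Y[phi.pattern[:, j], :] += e.Ftilde[j, :]
    return MeasurementBlock(Y)


def project_vector(phi: MeasurementMatrix, x: np.ndarray) -> np.ndarray:
    """Single-channel projection by the same gather-add scheme."""
    x = np.asarray(x, dtype=float)
    if x.shape != (phi.N,):
        raise ValueError("vector length must equal N")
    y = np.zeros(phi.M)
    for j in range(phi.N):
        y[phi.pattern[:, j]] += x[j]
    return y


def sensor_op_count(phi: MeasurementMatrix, C: int) -> int:
    """Additions performed by the projection stage for a C-channel epoch: C*N*d."""
    if C < 0:
        raise ValueError("channel count must be nonnegative")
    return C * phi.N * phi.d


def measurements_for_cr(N: int, cr: float) -> int:
    """Default operating point: M = round(N / CR) measurements for a target CR.

    The realized compression ratio is measured after entropy coding; this only
    fixes the number of linear projections.
    """
    if cr <= 0:
        raise ValueError("target CR must be positive")
    M = int(round(N / cr))
    if M < 1 or M > N:
        raise ValueError(f"target CR {cr} gives invalid M={M} for N={N}")
    return M
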