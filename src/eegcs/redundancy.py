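"""Interchannel redundancy removal.

Nearby EEG channels record the same underlying brain activity, so their
measurement vectors (same sensing matrix for every channel) are strongly
correlated.  The server selects channel pairs whose measurements correlate
above a threshold T (default 0.6); the sensor then transmits sign-matched
differences y_i - sign(R_ij) * y_j instead of raw measurement vectors.  The
difference columns have a much narrower distribution and entropy-code in
fewer bits.  The pair schedule is chosen greedily by |correlation|, keeping
only pairs whose signed incidence rows are linearly independent so the C x C
system stays exactly invertible; leftover slots are filled with
minimum-variance singleton channels.

Pair selection runs at the server on the previous epoch's measurements (the
"predictive" protocol) — the sensor only performs M subtractions per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .sensing import MeasurementBlock

DEFAULT_THRESHOLD = 0.6
_RANK_TOL = 1e-10


@dataclass
class CorrelationMatrix:
    """Pearson correlations between measurement columns, with their variances."""

    R: np.ndarray
    variances: np.ndarray


@dataclass
class PairList:
    """Ordered difference schedule: C entries (i, j, sign); j = 0 marks a singleton.

    Channel indices are 1-based in the entries (0 is reserved for "no partner"),
    matching the difference rule ytilde_k = y_{i_k} - sign_k * y_{j_k} with
    y_0 defined as zero.
    """

    entries: List[Tuple[int, int, int]]
    T: float = DEFAULT_THRESHOLD
    epoch_stamp: int = 0

    @property
    def C(self) -> int:
        return len(self.entries)

    def incidence_matrix(self) -> np.ndarray:
        """Signed C x C system mapping channel columns to difference columns."""
        C = self.C
        A = np.zeros((C, C))
        for k, (i, j, s) in enumerate(self.entries):
            A[k, i - 1] = 1.0
            if j != 0:
                A[k, j - 1] -= float(s)
        return A

    def n_pairs(self) -> int:
        return sum(1 for _, j, _ in self.entries if j != 0)


def correlation_matrix(Y: MeasurementBlock) -> CorrelationMatrix:
    """Pearson correlation between measurement columns; zero-variance columns
    get zero correlations (with a warning) rather than NaNs."""
    import warnings

    Ymat = Y.Y
    if Ymat.shape[0] < 2:
        raise ValueError("need at least 2 measurements per channel")
    var = Ymat.var(axis=0, ddof=1)
    dead = var == 0.0
    if dead.any():
        warnings.warn("zero-variance measurement column; correlations set to 0")
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.corrcoef(Ymat, rowvar=False)
        R[dead, :] = 0.0
        R[:, dead] = 0.0
        np.fill_diagonal(R, 1.0)
    else:
        R = np.corrcoef(Ymat, rowvar=False)
    return CorrelationMatrix(R=np.atleast_2d(R), variances=var)


def _independent(row: np.ndarray, basis: List[np.ndarray]) -> np.ndarray | None:
    """Gram-Schmidt residual of ``row`` against ``basis``; None if dependent."""
    r = row.astype(float).copy()
    for b in basis:
        r -= (r @ b) * b
    nrm = np.linalg.norm(r)
    if nrm <= _RANK_TOL * max(1.0, np.linalg.norm(row)):
        return None
    return r / nrm


def select_pairs(
    corr: CorrelationMatrix, T: float = DEFAULT_THRESHOLD, epoch_stamp: int = 0
) -> PairList:
    """Greedy pair selection.

    Repeatedly takes the largest remaining |R_ij| >= T whose signed incidence
    row e_i - sign(R_ij) e_j is linearly independent of the rows already kept
    (dependent candidates are discarded from the pool); once pairs run out,
    fills the schedule with the smallest-variance channels whose unit rows are
    still independent.  Ties in |R| break to the lexicographically smallest
    (i, j).  The result is invertible by construction.
    """
    R = corr.R
    C = R.shape[0]
    entries: List[Tuple[int, int, int]] = []
    basis: List[np.ndarray] = []

    # Candidate pool: upper-triangle entries sorted by (-|R|, i, j).
    cand = [
        (i, j)
        for i in range(C)
        for j in range(i + 1, C)
        if abs(R[i, j]) >= T and R[i, j] != 0.0
    ]
    cand.sort(key=lambda ij: (-abs(R[ij[0], ij[1]]), ij[0], ij[1]))

    for i, j in cand:
        if len(entries) == C:
            break
        s = 1 if R[i, j] > 0 else -1
        row = np.zeros(C)
        row[i] = 1.0
        row[j] = -float(s)
        q = _independent(row, basis)
        if q is None:
            continue  # redundant pair: discard, keep scanning the pool
        basis.append(q)
        entries.append((i + 1, j + 1, s))

    if len(entries) < C:
        order = sorted(range(C), key=lambda c: (corr.variances[c], c))
        for c in order:
            if len(entries) == C:
                break
            row = np.zeros(C)
            row[c] = 1.0
            q = _independent(row, basis)
            if q is None:
                continue
            basis.append(q)
            entries.append((c + 1, 0, 1))

    assert len(entries) == C, "singleton fallback failed to complete the system"
    return PairList(entries=entries, T=T, epoch_stamp=epoch_stamp)


@dataclass
class DifferenceBlock:
    """M x C matrix of difference signals ytilde_k = y_{i_k} - sign_k y_{j_k}."""

    Ytilde: np.ndarray

    @property
    def M(self) -> int:
        return self.Ytilde.shape[0]

    @property
    def C(self) -> int:
        return self.Ytilde.shape[1]


def apply_differences(Y: MeasurementBlock, p: PairList) -> DifferenceBlock:
    """Sensor-side stage: M subtractions per true pair, copies for singletons."""
    if p.C != Y.C:
        raise ValueError("PairList channel count does not match block")
    Yt = np.empty_like(Y.Y)
    for k, (i, j, s) in enumerate(p.entries):
        if not (1 <= i <= Y.C) or not (0 <= j <= Y.C):
            raise IndexError(f"pair entry {k} out of range: {(i, j, s)}")
        if j == 0:
            Yt[:, k] = Y.Y[:, i - 1]
        else:
            Yt[:, k] = Y.Y[:, i - 1] - s * Y.Y[:, j - 1]
    return DifferenceBlock(Yt)


def invert_differences(Yt: DifferenceBlock, p: PairList) -> MeasurementBlock:
    """Server-side exact inversion of the difference schedule (solves the
    C x C signed incidence system once for all measurement rows)."""
    if p.C != Yt.C:
        raise ValueError("PairList channel count does not match block")
    A = p.incidence_matrix()
    try:
        # Ytilde = Y @ A.T  =>  A @ Y.T = Ytilde.T
        Y = np.linalg.solve(A, Yt.Ytilde.T).T
    except np.linalg.LinAlgError as exc:
        rank = np.linalg.matrix_rank(A)
        bad = next(
            (k for k in range(p.C) if np.linalg.matrix_rank(A[: k + 1]) <= k), p.C - 1
        )
        raise ValueError(
            f"singular pair schedule (rank {rank} < {p.C}); first dependent "
            f"entry: index {bad} = {p.entries[bad]}"
        ) from exc
    return MeasurementBlock(Y)


def difference_op_count(p: PairList, M: int) -> int:
    """Sensor-side subtraction count for one epoch: M per true pair."""
    return M * p.n_pairs()
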