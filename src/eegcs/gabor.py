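"""Redundant Gabor dictionary for sparse reconstruction.

EEG epochs are compressible in a Gabor frame: each atom is a unit-norm
sinusoidally-modulated Gaussian

    g(n; n0, f0, s) = K * exp(-(n - n0)^2 / (2 s^2)) * sin(2 pi f0 (n - n0)),

parameterized by center time n0 (samples), center frequency f0
(cycles/sample) and spread s (samples).  Spreads follow a dyadic scale
s in {B, B^2, ...} with base B = 2; the time grid step grows with the
spread (Delta_n0 = c_t * s) and the frequency grid step shrinks with it
(Delta_f0 = c_f / (s N)), with

    c_t = 2 alpha / pi,   c_f = 8 pi alpha,   alpha = 0.5 ln(0.5 (B + 1/B)).

A DC atom is appended so any demeaning residue is representable.  If the raw
grid exceeds the atom-count cap, both grid steps are scaled up by a common
factor, which preserves the time/frequency proportionality while keeping the
dictionary (and the server-side solve) a manageable size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

DEFAULT_BASE = 2.0
DEFAULT_CAP_FACTOR = 4  # atom cap = cap_factor * N
# Atoms whose correlation with an already-accepted atom exceeds this are
# dropped: at the largest spreads the Gaussian window barely modulates the
# sinusoid and adjacent scales produce near-duplicate atoms, which add no
# representational power but ruin coefficient identifiability.
DEFAULT_MAX_COHERENCE = 0.95
_ENERGY_TOL = 1e-8


def alpha(B: float = DEFAULT_BASE) -> float:
    """Discretization constant alpha = 0.5 ln(0.5 (B + 1/B))."""
    if B <= 0:
        raise ValueError("base must be positive")
    return 0.5 * math.log(0.5 * (B + 1.0 / B))


def gabor_atom(n0: float, f0: float, s: float, N: int) -> np.ndarray:
    """Unit-norm Gabor atom sampled on n = 0..N-1; raises on zero-energy atoms."""
    if s <= 0:
        raise ValueError("spread must be positive")
    if not (0 < f0 <= 0.5):
        raise ValueError("center frequency must lie in (0, 0.5] cycles/sample")
    n = np.arange(N, dtype=float)
    g = np.exp(-((n - n0) ** 2) / (2.0 * s * s)) * np.sin(2.0 * np.pi * f0 * (n - n0))
    nrm = np.linalg.norm(g)
    if nrm < _ENERGY_TOL:
        raise ValueError(
            f"zero-energy atom (n0={n0}, f0={f0}, s={s}): rejected"
        )
    return g / nrm


@dataclass
class GaborDictionary:
    """N x K frame of unit-norm atoms plus their (n0, f0, s) parameters.

    ``params`` has one row per atom; the DC atom is flagged with s = inf and
    f0 = 0.  Rebuilt deterministically from (N, B, c_t, c_f, cap).
    """

    Psi: np.ndarray
    params: np.ndarray  # K x 3 array of (n0, f0, s)
    B: float
    c_t: float
    c_f: float
    cap: int

    @property
    def N(self) -> int:
        return self.Psi.shape[0]

    @property
    def K(self) -> int:
        return self.Psi.shape[1]


def _grid_counts(N: int, scales: List[float], c_t: float, c_f: float, lam: float):
    """Time/frequency grids per scale for a coarsening factor lam >= 1."""
    out = []
    for s in scales:
        dn = max(1.0, lam * c_t * s)
        df = max(1.0 / N, lam * c_f / (s * N))
        n0s = np.arange(0.0, N, dn)
        f0s = np.arange(df, 0.5 + 1e-12, df)
        out.append((s, n0s, f0s))
    return out


def build_dictionary(
    N: int,
    B: float = DEFAULT_BASE,
    cap: int | None = None,
    c_t: float | None = None,
    c_f: float | None = None,
    max_coherence: float = DEFAULT_MAX_COHERENCE,
) -> GaborDictionary:
    """Build the dyadic-scale Gabor frame for epoch length N (plus a DC atom)."""
    if N < 8:
        raise ValueError("epoch length too short for a dictionary")
    a = alpha(B)
    if c_t is None:
        c_t = 2.0 * a / math.pi
    if c_f is None:
        c_f = 8.0 * math.pi * a
    if cap is None:
        cap = DEFAULT_CAP_FACTOR * N

    scales = []
    p = 1
    while B**p <= N:
        scales.append(float(B**p))
        p += 1
    if not scales:
        raise ValueError("no admissible scales for this N and base")

    def total(lam: float) -> int:
        return sum(
            len(n0s) * len(f0s) for _, n0s, f0s in _grid_counts(N, scales, c_t, c_f, lam)
        )

    if cap < len(scales) + 1:
        raise ValueError("atom cap too small to cover the dyadic scales")

    lam = 1.0
    if total(lam) > cap:
        lo, hi = 1.0, 2.0
        while total(hi) > cap:
            lo, hi = hi, hi * 2.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if total(mid) > cap:
                lo = mid
            else:
                hi = mid
        lam = hi

    atoms: List[np.ndarray] = []
    params: List[Tuple[float, float, float]] = []
    for s, n0s, f0s in _grid_counts(N, scales, c_t, c_f, lam):
        for n0 in n0s:
            for f0 in f0s:
                try:
                    g = gabor_atom(n0, f0, s, N)
                except ValueError:
                    continue  # boundary/zero-energy atoms are skipped
                atoms.append(g)
                params.append((n0, f0, s))

    # Greedy coherence pruning in construction order (fine scales first).
    if max_coherence < 1.0 and atoms:
        P = np.column_stack(atoms)
        G = np.abs(P.T @ P)
        kept: List[int] = []
        for i in range(P.shape[1]):
            if not kept or G[i, kept].max() <= max_coherence:
                kept.append(i)
        atoms = [atoms[i] for i in kept]
        params = [params[i] for i in kept]

    # DC atom so demeaning residue stays representable.
    atoms.append(np.full(N, 1.0 / math.sqrt(N)))
    params.append((0.0, 0.0, math.inf))

    Psi = np.column_stack(atoms)
    return GaborDictionary(
        Psi=Psi, params=np.asarray(params), B=B, c_t=c_t, c_f=c_f, cap=cap
    )


def matching_pursuit(
    Psi: np.ndarray, x: np.ndarray, n_atoms: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Plain matching pursuit: greedy atom selection against the residual.

    Returns (coefficient vector, residual).  Used to quantify compressibility
    (energy captured by the best few atoms) and as a greedy reference point
    for the convex solver; it is not part of the production path.
    """
    r = np.asarray(x, dtype=float).copy()
    coef = np.zeros(Psi.shape[1])
    for _ in range(n_atoms):
        c = Psi.T @ r
        k = int(np.argmax(np.abs(c)))
        if c[k] == 0.0:
            break
        coef[k] += c[k]
        r -= c[k] * Psi[:, k]
    return coef, r


def energy_captured(Psi: np.ndarray, x: np.ndarray, n_atoms: int) -> float:
    """Fraction of ||x||^2 captured by ``n_atoms`` matching-pursuit atoms."""
    x = np.asarray(x, dtype=float)
    e0 = float(x @ x)
    if e0 == 0.0:
        return 1.0
    _, r = matching_pursuit(Psi, x, n_atoms)
    return 1.0 - float(r @ r) / e0
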