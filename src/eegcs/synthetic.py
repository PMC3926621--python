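"""Synthetic multichannel EEG-like recordings.

The generator emulates the statistical structure the codec relies on:

* Gabor-domain compressibility — each latent source is a sparse combination
  of atoms from the reconstruction dictionary family (rhythmic, transient
  oscillations, as in real EEG);
* strong interchannel correlation — channels are linear mixtures of the
  sources with smooth spatial-decay weights (nearby channels see nearly the
  same mixture), calibrated analytically so the mean pairwise |r| hits a
  requested coherence;
* a 1/f ("pink") background per channel at a configurable SNR;
* 12-bit integer amplitudes at a nominal 128 Hz.

It does NOT emulate physiological morphology (spindles, seizures, artifacts)
or volume-conduction head models; it provides exactly the correlation and
sparsity structure needed to exercise every codec stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .gabor import GaborDictionary, build_dictionary
from .io_core import RawRecording

AMP_12BIT = 2047.0


@dataclass
class SynthConfig:
    C: int = 8
    N: int = 512
    n_epochs: int = 4
    fs: float = 128.0
    n_sources: int = 4
    mixing_coherence: float = 0.8
    atoms_per_source: int = 10
    pink_noise_snr: float = 20.0  # dB; +inf disables the background
    seed: int = 0
    dictionary: Optional[GaborDictionary] = None  # default: module default frame

    def __post_init__(self) -> None:
        if self.n_sources > self.C:
            raise ValueError("need n_sources <= C")
        if not (0.0 <= self.mixing_coherence <= 1.0):
            raise ValueError("mixing_coherence must lie in [0, 1]")


def _source_centers(C: int, n_sources: int) -> np.ndarray:
    """Source positions spread evenly along the (1-D) channel axis."""
    return (np.arange(n_sources) + 0.5) * C / n_sources


def _mixing_matrix(C: int, n_sources: int, ell: float) -> np.ndarray:
    """Unit-row-norm Gaussian spatial-decay mixing weights."""
    centers = _source_centers(C, n_sources)
    ch = np.arange(C)[:, None] + 0.5
    W = np.exp(-((ch - centers[None, :]) ** 2) / (2.0 * ell * ell))
    W /= np.maximum(np.linalg.norm(W, axis=1, keepdims=True), 1e-300)
    return W


def _mean_abs_corr(W: np.ndarray) -> float:
    """Mean pairwise |r| implied by unit-norm mixing rows of independent
    unit-variance sources: r_ij = <w_i, w_j>."""
    G = W @ W.T
    iu = np.triu_indices_from(G, k=1)
    return float(np.mean(np.abs(G[iu])))


def calibrate_decay(C: int, n_sources: int, target: float) -> float:
    """Bisection on the decay length so the implied mean |r| hits ``target``."""
    import warnings

    lo, hi = 1e-2, 100.0 * C
    if _mean_abs_corr(_mixing_matrix(C, n_sources, lo)) > target:
        warnings.warn("requested coherence below the floor of this geometry")
        return lo
    for _ in range(80):
        mid = math.sqrt(lo * hi)
        if _mean_abs_corr(_mixing_matrix(C, n_sources, mid)) < target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with a 1/f amplitude spectrum (FFT shaping)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # keep DC finite; demeaning removes it anyway
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def generate_recording(cfg: SynthConfig) -> RawRecording:
    """Deterministic (per seed) synthetic recording of n_epochs * N samples."""
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    Psi = cfg.dictionary if cfg.dictionary is not None else build_dictionary(cfg.N)
    K = Psi.K

    # Correlation target is inflated slightly to undo the per-channel noise
    # dilution: additive noise at snr scales r by p/(p + p_noise).
    snr_lin = math.inf if math.isinf(cfg.pink_noise_snr) else 10.0 ** (
        cfg.pink_noise_snr / 10.0
    )
    dilution = 1.0 if math.isinf(snr_lin) else snr_lin / (1.0 + snr_lin)
    target = min(0.999, cfg.mixing_coherence / dilution) if cfg.mixing_coherence else 0.0
    ell = calibrate_decay(cfg.C, cfg.n_sources, target) if target > 0 else 1e-2
    W = _mixing_matrix(cfg.C, cfg.n_sources, ell)

    blocks = []
    for _ in range(cfg.n_epochs):
        S = np.zeros((cfg.N, cfg.n_sources))
        for k in range(cfg.n_sources):
            idx = rng.choice(K - 1, size=cfg.atoms_per_source, replace=False)
            amps = rng.standard_normal(cfg.atoms_per_source) * (
                1.0 + rng.exponential(1.0, cfg.atoms_per_source)
            )
            S[:, k] = Psi.Psi[:, idx] @ amps
            S[:, k] /= max(S[:, k].std(), 1e-12)
        X = S @ W.T  # N x C, unit-ish variance per channel
        if not math.isinf(snr_lin):
            sig_p = X.var(axis=0)
            for c in range(cfg.C):
                X[:, c] += _pink_noise(cfg.N, rng) * math.sqrt(sig_p[c] / snr_lin)
        blocks.append(X)

    X = np.vstack(blocks)
    # Scale into the 12-bit integer range and round (last, so quantization
    # assumptions downstream hold).
    X *= 0.9 * AMP_12BIT / max(np.abs(X).max(), 1e-12)
    X = np.round(X)
    return RawRecording(X, fs=cfg.fs, labels=[f"ch{i}" for i in range(cfg.C)])


def add_gaussian_noise(
    x: np.ndarray, snr_db: float, seed: int = 0
) -> np.ndarray:
    """Additive white Gaussian noise at an exactly realized SNR.

    The noise vector is rescaled so 10 log10(P_signal / P_noise) equals
    ``snr_db`` to float precision (white noise at fs = 128 Hz occupies the
    0-64 Hz band).  ``snr_db = inf`` returns the input unchanged.
    """
    x = np.asarray(x, dtype=float)
    if math.isinf(snr_db):
        return x.copy()
    rng = np.random.Generator(np.random.PCG64(seed))
    noise = rng.standard_normal(x.shape)
    sig_p = float(np.mean((x - x.mean()) ** 2))
    noise_p = float(np.mean(noise**2))
    scale = math.sqrt(sig_p / (noise_p * 10.0 ** (snr_db / 10.0)))
    return x + scale * noise
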