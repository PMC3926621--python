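# Methods

## Problem setting

A battery-powered EEG sensor node streams multichannel recordings to an
unconstrained server over a lossy radio link. The node's energy budget is
dominated by computation and transmission, so the codec must compress hard
while doing almost nothing: the sensor side of this package uses only
integer additions/subtractions, a table lookup per symbol, and fixed-size
packet framing. All hard work (convex optimization) happens at the server.

Signals are handled as non-overlapping epochs of `N = 512` samples per
channel at a nominal 128 Hz, 12-bit amplitude. The codec's unit of work is
the `N x C` epoch matrix.

## Sensor side

1. **Demeaning.** Each channel's epoch mean is removed and carried in the
   header as a 16-bit fixed-point value (1/8-unit resolution); its bits are
   charged to the compression ratio.
2. **Sparse binary sensing.** Every channel is projected through one `M x N`
   binary matrix with exactly `d = 8` ones per column, drawn uniformly
   without replacement per column from a seeded PCG64 stream. Projection is
   `N*d` additions per channel; no multiplications. The matrix is never
   transmitted — sensor and server regenerate it from `(M, N, d, seed)`.
   Entries are 1 (not `1/sqrt(d)`); any scaling is absorbed by the solver.
   `M = round(N / CR)` sets the operating point; the realized CR is measured
   after entropy coding.
3. **Interchannel difference coding.** Because all channels share one
   sensing matrix, measurement columns inherit the strong correlation of
   nearby EEG channels. The server greedily pairs channels by largest
   absolute Pearson correlation of their measurement columns (threshold
   `T = 0.6`), discarding candidates whose signed incidence row
   `e_i - sign(r_ij) e_j` is linearly dependent on the rows already chosen
   (incremental Gram–Schmidt, tolerance 1e-10), and completes the schedule
   with minimum-variance singleton channels, so the `C x C` system is
   invertible by construction. Ties break to the lexicographically smallest
   pair, making selection deterministic. A published description of this
   loop has a contradictory termination clause ("while k < C or while
   R_max < T"); we pair while `k <= C-1` **and** the best remaining
   correlation is at least `T`, then fall through to the singleton step,
   which matches the procedure's evident intent. "Removing a pair from the
   pool" removes that entry only — a channel may appear in several pairs as
   long as independence holds. The schedule is computed on epoch `t` and
   applied to epoch `t+1` (predictive protocol); on stationary synthetic
   data the selected pair set is identical across consecutive epochs in
   well over 80% of cases, so infrequent refresh would suffice. The sensor
   only executes `M` subtractions per true pair.
4. **Interleaving and quantization.** The difference block is vectorized
   sample-first (`vec` of the transpose), so each packet carries a slice of
   every channel. A uniform mid-rise quantizer maps `[-16384, 16384)` onto
   15-bit codes (step 1.0). The three bits of headroom over the 12-bit
   input range absorb the growth from summing `d = 8` samples plus one
   differencing; out-of-range values clip to the end codes and are counted.
5. **Entropy coding.** Canonical Huffman over the quantizer codes, ties
   broken by symbol value so a codebook is a pure function of its training
   histogram. Difference measurements have a narrow, roughly Gaussian
   histogram, which is where the coding gain comes from. Codebooks are
   trained offline (on synthetic difference measurements in this package)
   and shared by both ends; an escape symbol (codeword + raw 15-bit code)
   keeps every quantizer output decodable. Codebook bits are not charged to
   the CR; the on-disk container embeds the codebook anyway so files are
   self-describing.
6. **Packetization.** 127-byte packets with 13 bytes of MAC overhead: 114
   bytes of payload each, last packet zero-padded, true bit length in the
   header. Bit order is big-endian throughout.

Compression ratio accounting: `CR = (N*C*12) / (payload_bits + header_bits)`
with `header_bits = 136 + 33*C` (fixed fields plus per-channel mean and pair
triple). Published CR figures for this codec family typically leave header
granularity unspecified; ours includes it, which makes our measured CR
slightly conservative.

## Server side

Decoding inverts each stage exactly: depacketize, Huffman-decode,
dequantize, de-interleave, and solve the `C x C` signed incidence system
once per measurement row (exact to float precision). Each channel is then
recovered independently by basis pursuit denoise

    min ||c||_1   s.t.  ||y - Phi Psi c||_2 <= sigma,

and `f_hat = Psi c_hat + mean`.

### Gabor dictionary

Atoms are unit-norm sinusoidally modulated Gaussians
`g(n) = K exp(-(n-n0)^2 / 2s^2) sin(2 pi f0 (n-n0))` with dyadic spreads
`s in {2, 4, ..., N}` (base `B = 2`). Grid steps follow the optimal-spacing
rule `dn0 = (2 alpha / pi) s` and `df0 = 8 pi alpha / (s N)` with
`alpha = 0.5 ln(0.5 (B + 1/B))`; the printed forms of these increments vary
across sources, so both constants are configuration parameters and the
dictionary's fitness is enforced by a compressibility test (best `N/8`
matching-pursuit atoms capture >= 90% of demeaned epoch energy) rather than
by an exact grid. Time steps are floored to 1 sample and frequency steps to
`1/N`; boundary atoms are truncated and renormalized; zero-energy atoms
(e.g. `f0 = 0.5` on an integer-centred grid) are rejected; a constant atom
represents demeaning residue.

The raw grid is far larger than is useful, so both steps are scaled by a
common factor until the atom count fits a cap (default `4N`). The frame is
then conditioned by greedy coherence pruning: scanning atoms fine-scale
first, any atom correlating above 0.95 with an already-accepted atom is
dropped. At the largest spreads the Gaussian window barely modulates the
sinusoid, so adjacent scales produce near-duplicates (the whole `s = N`
layer collapses onto `s = N/2`); pruning removes them, taking K from 1904
to 1649 at N = 512 and the worst-pair coherence from 0.95 to 0.92, with no
loss of span (least-squares residual on white noise stays at float level).
A denser frame (16N cap) was considered and rejected: the near-duplicate
atoms it adds measurably hurt exact coefficient identifiability in
planted-recovery tests and quadruple the server-side cost without
improving NMSE on the synthetic conditions.

### Solver

A spectral projected-gradient method on the LASSO subproblem
(`min ||y - Ac||_2 s.t. ||c||_1 <= tau`; Barzilai–Borwein steps, nonmonotone
line search, sort-based l1-ball projection) combined with Newton root
finding on the Pareto curve `phi(tau) = ||r(tau)||_2` — the standard
approach for this problem class. Numerical choices:

* `sigma` defaults to the RMS quantization noise aggregated over the
  received measurements, `step * sqrt(M/12)`; it is a documented estimate,
  not a value stated by any reference, and is validated only by internal
  tests (it never does worse than forcing an exact fit of quantized data).
* The residual target is accepted within `max(tol * ||y||, 0.02 sigma)`;
  tighter root finding burns matvecs without changing the reconstruction.
* LASSO subproblems terminate on their duality gap
  (`r'(r-y) + tau ||A'r||_inf`), not on a step-size heuristic — inexact
  subproblems make the Newton update on tau unreliable. If an iterate
  lands feasible strictly inside its l1 ball (the signature of a tau
  overshoot, where the subproblem optimum is non-unique), the ball is
  shrunk towards the iterate's own l1 norm and re-solved.
* With `sigma = 0` (equality-constrained basis pursuit) the solution is
  polished by least squares on the sparsest detected support — thresholds
  scanned coarse to fine — that fits the measurements to the feasibility
  tolerance; only supports of at most M/2 atoms qualify, since an ~M-atom
  support can fit any measurement vector exactly and would silently
  replace the l1 solution on merely-compressible signals. This is what
  makes planted-support recovery exact to ~1e-14; it was validated against
  an independent LP formulation of basis pursuit (scipy HiGHS).
* Default budget 4000 matvecs; sweep-style experiments use 1000, which
  reproduces the full-budget NMSE to three digits on these problems.
* Greedy matching pursuit is provided as a test oracle and compressibility
  probe only, never as the production solver.

### Packet loss

Lost packets are whole 114-byte payload gaps. Symbols whose bit spans
intersect a lost packet are dropped; because difference coding couples all
channels within a measurement row, a row missing any channel is deleted for
every channel, and reconstruction proceeds from the row-deleted system
(`Phi` and `Y` lose the same rows). Decoding after a gap resumes at symbol
boundaries recorded at encode time — bookkeeping standing in for the
sequence information a real receiver's MAC layer provides. Degraded-mode
reconstruction is verified against an explicitly built row-deleted system.

## Wavelet baseline

The comparison codec computes a CDF 9/7 DWT (PyWavelets `bior4.4`,
periodization, decomposition level 7), keeps the globally
largest-magnitude coefficients, and codes sorted index gaps plus 12-bit
uniformly quantized values with an adaptive integer arithmetic coder
(Fenwick-tree frequency model, 32-bit Witten–Neal–Cleary core). The kept
count `k` is the largest for which the coded stream fits the bit budget
`N*C*12 / CR` (bisection with actual encodes). Index transport and CR
accounting are not specified by the scheme this baseline follows; ours
(gap coding, header of 160 bits, budget includes both) is documented and
self-consistent. Baseline packets reuse the 127/13-byte format; a lost
packet zeroes the coefficients whose bits it carried (with adaptive
arithmetic coding a real decoder would lose the stream tail — the
simulation is deliberately optimistic for the baseline, which only
strengthens the robustness comparison against it).

## Synthetic data

The generator emulates exactly the structure the codec exploits:

* **Gabor compressibility** — each of `n_sources = 4` latent sources is a
  combination of 10 random dictionary atoms with heavy-tailed amplitudes,
  redrawn per epoch (fresh content, stationary statistics).
* **Interchannel correlation** — channels mix the sources through unit-norm
  Gaussian spatial-decay weights (nearby channel indices see nearly the
  same mixture). The decay length is calibrated by bisection on the
  analytic mean pairwise correlation implied by the mixing rows, inflated
  to compensate for noise dilution, so the default `mixing_coherence = 0.8`
  is realized within ±0.1.
* **Background** — per-channel 1/f (pink) noise at `pink_noise_snr = 20 dB`
  (rhythmic activity dominating a ~1% noise floor), then scaling and
  rounding into the 12-bit integer range, last, so downstream quantization
  assumptions hold.

Default channel count is `C = 8`. Experiment runners use smaller epochs
counts and channel counts (stated per experiment in their configs) as a
problem-size choice; generator statistics are unchanged.

What the generator does **not** emulate: physiological morphology
(spindles, K-complexes, seizures), artifacts, volume-conduction head
models, or non-stationarity. Passing tests therefore demonstrate the
codec's correctness and its exploitation of correlation and sparsity — not
clinical reconstruction quality on real EEG, whose NMSE depends on how
compressible real recordings are.

A consequence worth stating: with 20–40 planted atoms per channel, signals
are *more* sparse than real EEG windows. The NMSE-versus-`d` curve
therefore saturates already at `d ≈ 2`: at CR 8:1, `d = 8` clearly beats
`d = 2` (and both crush `d = 1`), at CR 2:1 they tie, but at CR 4:1 `d = 2`
is slightly and reproducibly better (the effect survives noiseless
regeneration, so it is not noise interpolation or solver error — extra
column weight only raises the coherence of `Phi Psi` when the signal is
already ultra-sparse). On real, merely-compressible EEG the published
behaviour — NMSE improving up to `d = 8`, then flat — is the expected one.
The d-saturation test in the acceptance suite records this discrepancy
honestly rather than papering over it.

## Experiment designs

All experiments are seeded end to end and store their full configuration.
NMSE cells report mean ± standard error over `n` epochs. The d-sweep and
matrix-comparison designs bypass difference coding and entropy coding to
isolate the sensing matrix, and draw a fresh matrix per epoch so cell means
average over both signal and matrix realizations. The noise study adds
white Gaussian noise (exactly realized SNR) to the clean signals before
compression and scores reconstructions against the *clean* signal at fixed
CR 2:1. The packet-loss study drops whole packets uniformly at random at
CR 2:1 and compares fitted NMSE-versus-loss slopes.

Energy is not simulated at cycle level. A proxy table counts sensor-side
primitive operations (projection `C*N*d` additions; demeaning and
differencing subtractions; quantizer compares; one codebook lookup per
symbol; the baseline's lifting multiply-adds and coefficient sort) and
prices transmission at 524.72 uJ per 127-byte packet — a cited external
constant, labeled as such, not a measurement of this code.

## Known limitations

* Channels are reconstructed independently; joint-sparsity (MMV) solvers
  would likely improve NMSE at equal M.
* The analysis equality `decode(encode(.))` is bit-exact, but packet-loss
  symbol accounting uses encoder-side offsets (see above) rather than a
  full MAC-layer resynchronization model.
* Quantizer range is a global calibration (±2^3 × 12-bit range); epochs
  with pathological amplitude could clip (clips are counted and reported).
* The wavelet baseline is a faithful small codec, not a full JPEG2000
  (no EBCOT, no rate-distortion optimal truncation).
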