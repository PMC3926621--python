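# eegcs

Energy-efficient compressed-sensing codec for multichannel EEG
telemonitoring over wireless body sensor networks.

A battery-powered sensor node cannot afford a conventional transform codec:
adaptive wavelet compression burns most of its energy finding the large
coefficients before transmitting them. This package implements the opposite
split. The sensor compresses each 512-sample epoch of C channels with
nothing but additions — a sparse binary random projection
`Y = [Phi f~_1 | ... | Phi f~_C]` where `Phi` is an `M x N` {0,1} matrix
with exactly `d = 8` ones per column — subtracts sign-matched measurement
vectors of highly correlated channel pairs (`y~_k = y_i - sign(r_ij) y_j`,
pairs chosen server-side above a correlation threshold `T = 0.6`),
quantizes to 15 bits, Huffman-codes, and ships 127-byte packets. The server
inverts the exactly invertible digital stages and recovers each channel by
basis pursuit denoise

    min ||c||_1   subject to   ||y - Phi Psi c||_2 <= sigma

against a redundant Gabor frame `Psi` (sinusoidally modulated Gaussian
atoms on a dyadic scale grid), then adds the channel means back.
Reconstruction quality is scored as
`NMSE = ||x - x_hat||^2 / ||x - mean(x)||^2` and compression as
`CR = original bits / compressed bits`.

A wavelet comparison codec (CDF 9/7, top-coefficient thresholding,
adaptive arithmetic coding), a synthetic multichannel EEG generator with
controlled interchannel coherence and Gabor-domain sparsity, and runners
for the d-sweep, sensing-matrix comparison, Gaussian-noise and packet-loss
robustness experiments are included, so the whole system is exercisable
without any recordings.

## Worked example

```sh
eegcs synth --seed 3 --out rec.csv
eegcs compress --in rec.csv --cr 2 --d 8 --seed 7 --out epoch.eegcs
eegcs reconstruct --in epoch.eegcs --out rec_hat.csv --report diag.json
```

which prints (seed 3, first epoch of the default 8-channel recording):

```
wrote 2048 x 8 recording to rec.csv
epoch 0: 256 measurements/channel, 22 packets, measured CR 2.41:1
reconstructed 512 x 8 epoch to rec_hat.csv
```

Read: at the `M = N/2` operating point the entropy coder pushes the
realized compression past 2:1 (2.41:1 including header bits), the epoch
fits in 22 radio packets, and the per-channel diagnostics in `diag.json`
report the BPDN residual norms. Comparing `rec.csv` and `rec_hat.csv` over
the first epoch gives a mean per-channel NMSE of 0.016 — well below the
0.1 that is usually quoted as clinically tolerable.

The same pipeline is available as a library:

```python
from eegcs import (SynthConfig, generate_recording, epoch_stream,
                   CodecConfig, compress_epoch, build_dictionary,
                   reconstruct_epoch, epoch_nmse)

rec = generate_recording(SynthConfig(seed=3))
e = next(epoch_stream(rec, 512))
comp = compress_epoch(e, CodecConfig(cr_target=2.0, seed=7))
out = reconstruct_epoch(comp, build_dictionary(512))
print(comp.measured_cr, epoch_nmse(e, out.epoch))
```

Experiment runners: `eegcs sweep-d`, `eegcs compare-matrices`,
`eegcs noise`, `eegcs packet-loss`, `eegcs energy-proxy` (see `--help`).

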