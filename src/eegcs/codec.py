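"""Sensor-side encoding: interleaving, quantization, Huffman coding, packets.

The difference measurements of one epoch are vectorized sample-first
(interleaved across channels, so one lost packet hurts every channel a
little instead of one channel a lot), uniformly quantized to 15-bit codes
(three bits of headroom over the 12-bit raw signals, to absorb the range
growth of the linear projections), Huffman coded against an offline
codebook, and split into 127-byte packets of which 13 bytes are MAC
overhead.

Compression-ratio accounting charges the payload bits plus the per-epoch
header (dimensions, matrix seed, fixed-point channel means, pair schedule);
the Huffman codebook is shared offline by sensor and server and is not
charged, although the on-disk container embeds it so files stay
self-describing.
"""

from __future__ import annotations

import heapq
import struct
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._bitio import BitReader, BitWriter
from .io_core import Epoch, demean
from .redundancy import (
    DifferenceBlock,
    PairList,
    apply_differences,
    correlation_matrix,
    select_pairs,
)
from .sensing import generate_sparse_binary_matrix, measurements_for_cr, project

PACKET_BYTES = 127
PACKET_OVERHEAD_BYTES = 13
PAYLOAD_BYTES = PACKET_BYTES - PACKET_OVERHEAD_BYTES  # 114
DEFAULT_BITS = 15
DEFAULT_RAW_BITS = 12
# 12-bit signals span +-2048; projections and differences grow the range by
# roughly the column weight d, absorbed by 2^3 headroom at 15 bits.
DEFAULT_LO = -(2.0**3) * 2048.0
DEFAULT_HI = (2.0**3) * 2048.0

MAGIC = b"EEGCS1"


# ---------------------------------------------------------------------------
# Interleaving


def interleave(Yt: DifferenceBlock) -> np.ndarray:
    """vec of Ytilde^T: [y1(1), y2(1), ..., yC(1), y1(2), ...]."""
    return Yt.Ytilde.reshape(-1)


def deinterleave(v: np.ndarray, M: int, C: int) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.size != M * C:
        raise ValueError("vector length does not match M*C")
    return v.reshape(M, C)


# ---------------------------------------------------------------------------
# Quantization


@dataclass(frozen=True)
class QuantizerSpec:
    """Uniform mid-rise quantizer mapping [lo, hi) onto {0..2^bits - 1}."""

    bits: int = DEFAULT_BITS
    lo: float = DEFAULT_LO
    hi: float = DEFAULT_HI

    def __post_init__(self) -> None:
        if self.bits < 2:
            raise ValueError("need at least 2 quantizer bits")
        if self.lo >= self.hi:
            raise ValueError("invalid quantizer range: lo >= hi")

    @property
    def levels(self) -> int:
        return 1 << self.bits

    @property
    def step(self) -> float:
        return (self.hi - self.lo) / self.levels


def quantize(v: np.ndarray, q: QuantizerSpec) -> Tuple[np.ndarray, int]:
    """Return (codes, number of clipped samples)."""
    v = np.asarray(v, dtype=float)
    raw = np.floor((v - q.lo) / q.step).astype(np.int64)
    clipped = int(np.count_nonzero((raw < 0) | (raw > q.levels - 1)))
    codes = np.clip(raw, 0, q.levels - 1)
    return codes, clipped


def dequantize(codes: np.ndarray, q: QuantizerSpec) -> np.ndarray:
    codes = np.asarray(codes, dtype=np.int64)
    return q.lo + (codes + 0.5) * q.step


# ---------------------------------------------------------------------------
# Canonical Huffman with escape


ESCAPE = -1  # internal marker; serialized as symbol value 2**bits


@dataclass
class HuffmanCodebook:
    """Canonical prefix code over quantizer codes plus an escape symbol.

    Unseen symbols are sent as the escape codeword followed by the raw
    ``bits``-bit code, so any quantizer output is decodable.  Codes are
    assigned canonically with ties broken by symbol value, which makes the
    codebook a pure function of the training histogram.
    """

    lengths: Dict[int, int]  # symbol -> code length (ESCAPE included)
    bits: int = DEFAULT_BITS
    id: int = 0
    _enc: Dict[int, Tuple[int, int]] = field(default_factory=dict, repr=False)
    _dec: Dict[Tuple[int, int], int] = field(default_factory=dict, repr=False)
    _max_len: int = 0

    def __post_init__(self) -> None:
        self._assign()

    def _sort_key(self, sym: int) -> int:
        return (1 << self.bits) if sym == ESCAPE else sym

    def _assign(self) -> None:
        order = sorted(self.lengths, key=lambda s: (self.lengths[s], self._sort_key(s)))
        code = 0
        prev_len = 0
        self._enc.clear()
        self._dec.clear()
        for sym in order:
            ln = self.lengths[sym]
            code <<= ln - prev_len
            self._enc[sym] = (code, ln)
            self._dec[(ln, code)] = sym
            code += 1
            prev_len = ln
        self._max_len = max(self.lengths.values())

    def mean_code_length(self, codes: np.ndarray) -> float:
        """Average emitted bits per symbol for a given code vector."""
        total = 0
        esc_len = self.lengths[ESCAPE] + self.bits
        for s in np.asarray(codes).ravel():
            cl = self.lengths.get(int(s))
            total += esc_len if cl is None else cl
        return total / max(1, codes.size)


def build_huffman_codebook(
    training_codes: np.ndarray,
    bits: int = DEFAULT_BITS,
    id: int = 0,
    escape: bool = True,
) -> HuffmanCodebook:
    """Canonical Huffman codebook from a training sample of quantizer codes.

    With ``escape`` (the default, required for offline codebooks that must
    survive out-of-support values) an escape symbol with unit count joins the
    histogram; its payload is the raw ``bits``-bit code.
    """
    codes = np.asarray(training_codes).ravel()
    if codes.size == 0:
        raise ValueError("empty training sample")
    syms, counts = np.unique(codes.astype(np.int64), return_counts=True)
    freqs: List[Tuple[int, int]] = [(int(c), int(s)) for s, c in zip(syms, counts)]
    if escape:
        freqs.append((1, ESCAPE))  # escape: rare but always representable

    if len(freqs) == 1:  # degenerate: single symbol gets a 1-bit code
        return HuffmanCodebook(lengths={freqs[0][1]: 1}, bits=bits, id=id)

    # Huffman tree on (count, tiebreak) with deterministic merge order.
    heap = [
        (cnt, self_key, [sym])
        for cnt, sym in freqs
        for self_key in [((1 << bits) if sym == ESCAPE else sym,)]
    ]
    heapq.heapify(heap)
    depth: Dict[int, int] = {sym: 0 for _, sym in freqs}
    while len(heap) > 1:
        c1, k1, s1 = heapq.heappop(heap)
        c2, k2, s2 = heapq.heappop(heap)
        for sym in s1 + s2:
            depth[sym] += 1
        heapq.heappush(heap, (c1 + c2, min(k1, k2), s1 + s2))
    lengths = {sym: max(1, d) for sym, d in depth.items()}
    return HuffmanCodebook(lengths=lengths, bits=bits, id=id)


def huffman_encode(
    codes: np.ndarray, cb: HuffmanCodebook
) -> Tuple[bytes, int, np.ndarray]:
    """Encode a code vector; returns (bytes, bit length, symbol bit offsets).

    ``offsets`` has one entry per symbol plus a final sentinel equal to the
    total bit length; it is bookkeeping for the packet-loss simulation and is
    never transmitted.
    """
    w = BitWriter()
    codes = np.asarray(codes).ravel()
    offsets = np.empty(codes.size + 1, dtype=np.int64)
    esc = cb._enc.get(ESCAPE)
    for k, s in enumerate(codes):
        offsets[k] = w.nbits
        entry = cb._enc.get(int(s))
        if entry is None:
            if esc is None:
                raise ValueError(f"symbol {s} not in codebook and no escape")
            w.write(esc[0], esc[1])
            w.write(int(s), cb.bits)
        else:
            w.write(entry[0], entry[1])
    offsets[-1] = w.nbits
    return w.getvalue(), w.nbits, offsets


def huffman_decode(
    data: bytes, cb: HuffmanCodebook, n_symbols: int, nbits: int | None = None
) -> np.ndarray:
    r = BitReader(data, nbits)
    out = np.empty(n_symbols, dtype=np.int64)
    for k in range(n_symbols):
        code = 0
        ln = 0
        sym = None
        while ln < cb._max_len:
            try:
                code = (code << 1) | r.read_bit()
            except EOFError as exc:
                raise ValueError(f"truncated bitstream at symbol {k}") from exc
            ln += 1
            sym = cb._dec.get((ln, code))
            if sym is not None:
                break
        if sym is None:
            raise ValueError(f"invalid codeword at symbol {k}")
        if sym == ESCAPE:
            try:
                sym = r.read(cb.bits)
            except EOFError as exc:
                raise ValueError(f"truncated escape payload at symbol {k}") from exc
        out[k] = sym
    return out


# ---------------------------------------------------------------------------
# Packetization


@dataclass
class Packet:
    seq: int
    payload: bytes  # exactly PAYLOAD_BYTES


@dataclass
class PacketSequence:
    packets: List[Packet]
    payload_bits: int  # true bit length before final-packet padding

    def __len__(self) -> int:
        return len(self.packets)


def packetize(data: bytes, nbits: int) -> PacketSequence:
    """Split a bitstream into 114-byte payloads (last one zero-padded)."""
    if nbits > 8 * len(data):
        raise ValueError("bit length exceeds buffer")
    nbytes = (nbits + 7) // 8
    data = data[:nbytes]
    packets = []
    for seq, start in enumerate(range(0, nbytes, PAYLOAD_BYTES)):
        chunk = data[start : start + PAYLOAD_BYTES]
        chunk += bytes(PAYLOAD_BYTES - len(chunk))
        packets.append(Packet(seq=seq, payload=chunk))
    return PacketSequence(packets=packets, payload_bits=nbits)


def depacketize(p: PacketSequence) -> Tuple[bytes, List[int]]:
    """Reassemble the bitstream; returns (bytes, missing sequence numbers).

    Missing packets are filled with zero bytes so bit offsets are preserved;
    the caller decides what to do with the gaps.
    """
    if not p.packets:
        return b"", []
    n_expected = ((p.payload_bits + 7) // 8 + PAYLOAD_BYTES - 1) // PAYLOAD_BYTES
    present = {pk.seq: pk for pk in p.packets}
    missing = [s for s in range(n_expected) if s not in present]
    buf = bytearray()
    for s in range(n_expected):
        buf += present[s].payload if s in present else bytes(PAYLOAD_BYTES)
    nbytes = (p.payload_bits + 7) // 8
    return bytes(buf[:nbytes]), missing


def packet_bit_range(seq: int) -> Tuple[int, int]:
    """Bit interval [start, stop) of payload carried by packet ``seq``."""
    return 8 * PAYLOAD_BYTES * seq, 8 * PAYLOAD_BYTES * (seq + 1)


# ---------------------------------------------------------------------------
# Whole-epoch compression


@dataclass
class EpochHeader:
    N: int
    C: int
    M: int
    d: int
    bits: int
    seed: int
    codebook_id: int
    payload_bits: int

    @property
    def header_bits(self) -> int:
        """Bits charged to the compressed stream for this header.

        Fixed fields: N(16) C(8) M(16) d(8) bits(8) seed(32) codebook_id(16)
        payload_bits(32) = 136; per channel: 16-bit fixed-point mean plus a
        17-bit pair triple (i:8, j:8, sign:1).
        """
        return 136 + 33 * self.C


@dataclass
class CodecConfig:
    cr_target: float = 2.0
    M: Optional[int] = None  # overrides cr_target when given
    d: int = 8
    seed: int = 0
    quantizer: QuantizerSpec = field(default_factory=QuantizerSpec)
    codebook: Optional[HuffmanCodebook] = None  # None: train on this epoch
    pair_list: Optional[PairList] = None  # None: compute from this epoch
    pair_threshold: float = 0.6
    raw_bits: int = DEFAULT_RAW_BITS


@dataclass
class CompressedEpoch:
    header: EpochHeader
    means: np.ndarray  # dequantized 16-bit fixed-point channel means
    pair_list: PairList
    quantizer: QuantizerSpec
    packets: PacketSequence
    codebook: HuffmanCodebook
    n_clipped: int = 0
    symbol_offsets: Optional[np.ndarray] = None  # encode-time bookkeeping

    @property
    def compressed_bits(self) -> int:
        return self.header.payload_bits + self.header.header_bits

    @property
    def measured_cr(self) -> float:
        raw = self.header.N * self.header.C * DEFAULT_RAW_BITS
        return raw / self.compressed_bits


def _quantize_means(means: np.ndarray) -> np.ndarray:
    """16-bit Q3 fixed point: 1/8-unit resolution over the 12-bit range."""
    q = np.clip(np.round(np.asarray(means) * 8.0), -32768, 32767).astype(np.int64)
    return q


def compress_epoch(e: Epoch, cfg: CodecConfig | None = None) -> CompressedEpoch:
    """Full sensor-side path: demean, project, difference, interleave,
    quantize, Huffman-encode, packetize."""
    cfg = cfg or CodecConfig()
    M = cfg.M if cfg.M is not None else measurements_for_cr(e.N, cfg.cr_target)
    phi = generate_sparse_binary_matrix(M, e.N, cfg.d, cfg.seed)

    dm = demean(e)
    Y = project(phi, dm)
    pair_list = cfg.pair_list
    if pair_list is None:
        pair_list = select_pairs(correlation_matrix(Y), T=cfg.pair_threshold)
    Yt = apply_differences(Y, pair_list)

    v = interleave(Yt)
    codes, n_clipped = quantize(v, cfg.quantizer)
    codebook = cfg.codebook
    if codebook is None:
        codebook = build_huffman_codebook(codes, bits=cfg.quantizer.bits)
    payload, nbits, offsets = huffman_encode(codes, codebook)
    packets = packetize(payload, nbits)

    means_q = _quantize_means(dm.means)
    header = EpochHeader(
        N=e.N,
        C=e.C,
        M=M,
        d=cfg.d,
        bits=cfg.quantizer.bits,
        seed=cfg.seed,
        codebook_id=codebook.id,
        payload_bits=nbits,
    )
    return CompressedEpoch(
        header=header,
        means=means_q / 8.0,
        pair_list=pair_list,
        quantizer=cfg.quantizer,
        packets=packets,
        codebook=codebook,
        n_clipped=n_clipped,
        symbol_offsets=offsets,
    )


def decompress_header(comp: CompressedEpoch) -> EpochHeader:
    return comp.header


def compress_recording(
    epochs, cfg: CodecConfig | None = None, pair_refresh: int = 1
):
    """Predictive-pairing driver: compress a stream of epochs, applying the
    pair schedule computed from epoch t to epoch t+1.

    The first epoch is coded with an all-singleton schedule (the server has
    seen nothing yet); afterwards the schedule is refreshed from the latest
    measurements every ``pair_refresh`` epochs, mirroring a server that
    periodically retransmits updated channel pairs.  Yields CompressedEpoch
    objects.
    """
    cfg = cfg or CodecConfig()
    if pair_refresh < 1:
        raise ValueError("refresh interval must be at least 1")
    pair_list: Optional[PairList] = None
    for t, e in enumerate(epochs):
        if pair_list is None:
            schedule = PairList(
                entries=[(j + 1, 0, 1) for j in range(e.C)],
                T=cfg.pair_threshold,
                epoch_stamp=t,
            )
        else:
            schedule = pair_list
        ecfg = replace(cfg, pair_list=schedule)
        comp = compress_epoch(e, ecfg)
        yield comp
        if t % pair_refresh == 0:
            # server side: recompute the schedule from this epoch's
            # measurements for use on the next epoch(s)
            M = cfg.M if cfg.M is not None else measurements_for_cr(e.N, cfg.cr_target)
            phi = generate_sparse_binary_matrix(M, e.N, cfg.d, cfg.seed)
            Y = project(phi, demean(e))
            pair_list = select_pairs(
                correlation_matrix(Y), T=cfg.pair_threshold, epoch_stamp=t
            )


def decode_payload(
    comp: CompressedEpoch, lost_packets: Sequence[int] = ()
) -> Tuple[np.ndarray, List[int]]:
    """Huffman-decode the packetized payload back to quantizer codes.

    Returns (codes, lost symbol indices).  Lost symbols (any symbol whose
    bits overlap a lost packet) are returned as code 0 and reported in the
    index list; the reconstruction stage deletes the corresponding
    measurement rows.  Decoding after a gap resumes at the recorded symbol
    boundaries (encode-time bookkeeping standing in for the sequence
    knowledge a real receiver would get from its MAC layer).
    """
    h = comp.header
    n_symbols = h.M * h.C
    lost = sorted(set(int(s) for s in lost_packets))
    kept = PacketSequence(
        packets=[p for p in comp.packets.packets if p.seq not in lost],
        payload_bits=comp.packets.payload_bits,
    )
    data, missing = depacketize(kept)
    missing = sorted(set(missing) | set(s for s in lost))

    if not missing:
        codes = huffman_decode(data, comp.codebook, n_symbols, nbits=h.payload_bits)
        return codes, []

    if comp.symbol_offsets is None:
        raise ValueError("packet loss requires encode-time symbol offsets")
    off = comp.symbol_offsets
    lost_bits = [packet_bit_range(s) for s in missing]

    def symbol_lost(k: int) -> bool:
        a, b = off[k], off[k + 1]
        return any(a < stop and start < b for start, stop in lost_bits)

    codes = np.zeros(n_symbols, dtype=np.int64)
    lost_syms: List[int] = []
    r = BitReader(data, h.payload_bits)
    for k in range(n_symbols):
        if symbol_lost(k):
            lost_syms.append(k)
            continue
        r.seek(int(off[k]))
        codes[k] = huffman_decode_one(r, comp.codebook)
    return codes, lost_syms


def huffman_decode_one(r: BitReader, cb: HuffmanCodebook) -> int:
    """Decode a single symbol from the reader's current position."""
    code = 0
    ln = 0
    while ln < cb._max_len:
        code = (code << 1) | r.read_bit()
        ln += 1
        sym = cb._dec.get((ln, code))
        if sym is not None:
            return r.read(cb.bits) if sym == ESCAPE else sym
    raise ValueError("invalid codeword")


# ---------------------------------------------------------------------------
# On-disk container


def write_compressed(path, comp: CompressedEpoch) -> None:
    """Serialize to the EEGCS1 container (embeds the codebook for
    self-description; the codebook is not charged to the compression ratio)."""
    h = comp.header
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(
            struct.pack(
                "<HHHHBIHI",
                h.N,
                h.C,
                h.M,
                h.d,
                h.bits,
                h.seed,
                h.codebook_id,
                h.payload_bits,
            )
        )
        fh.write(struct.pack("<dd", comp.quantizer.lo, comp.quantizer.hi))
        fh.write(struct.pack(f"<{h.C}h", *(_quantize_means(comp.means)).tolist()))
        fh.write(struct.pack("<d", comp.pair_list.T))
        for i, j, s in comp.pair_list.entries:
            fh.write(struct.pack("<BBb", i, j, s))
        lengths = comp.codebook.lengths
        fh.write(struct.pack("<I", len(lengths)))
        for sym in sorted(lengths, key=lambda s: (1 << h.bits) if s == ESCAPE else s):
            val = (1 << h.bits) if sym == ESCAPE else sym
            fh.write(struct.pack("<IB", val, lengths[sym]))
        fh.write(struct.pack("<H", len(comp.packets.packets)))
        for p in comp.packets.packets:
            fh.write(struct.pack("<H", p.seq))
            fh.write(p.payload)


def read_compressed(path) -> CompressedEpoch:
    with open(path, "rb") as fh:
        if fh.read(6) != MAGIC:
            raise ValueError("not an EEGCS1 file")
        N, C, M, d, bits, seed, cb_id, payload_bits = struct.unpack(
            "<HHHHBIHI", fh.read(19)
        )
        lo, hi = struct.unpack("<dd", fh.read(16))
        means_q = np.array(struct.unpack(f"<{C}h", fh.read(2 * C)), dtype=np.int64)
        (T,) = struct.unpack("<d", fh.read(8))
        entries = [struct.unpack("<BBb", fh.read(3)) for _ in range(C)]
        (n_len,) = struct.unpack("<I", fh.read(4))
        lengths = {}
        for _ in range(n_len):
            val, ln = struct.unpack("<IB", fh.read(5))
            sym = ESCAPE if val == (1 << bits) else val
            lengths[sym] = ln
        (n_packets,) = struct.unpack("<H", fh.read(2))
        packets = []
        for _ in range(n_packets):
            (seq,) = struct.unpack("<H", fh.read(2))
            packets.append(Packet(seq=seq, payload=fh.read(PAYLOAD_BYTES)))
    header = EpochHeader(
        N=N, C=C, M=M, d=d, bits=bits, seed=seed, codebook_id=cb_id,
        payload_bits=payload_bits,
    )
    return CompressedEpoch(
        header=header,
        means=means_q / 8.0,
        pair_list=PairList(entries=[tuple(e) for e in entries], T=T),
        quantizer=QuantizerSpec(bits=bits, lo=lo, hi=hi),
        packets=PacketSequence(packets=packets, payload_bits=payload_bits),
        codebook=HuffmanCodebook(lengths=lengths, bits=bits, id=cb_id),
        symbol_offsets=None,
    )
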