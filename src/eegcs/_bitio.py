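"""Big-endian bit-level readers and writers.

The whole digital path (Huffman payloads, packet payloads, headers) uses a
single bit convention: the first bit written is the most significant bit of
the first byte.  Stating the convention makes independently written encoders
and decoders interoperable.
"""

from __future__ import annotations


class BitWriter:
    """Accumulates bits most-significant-first into a byte buffer."""

    def __init__(self) -> None:
        self._buf = bytearray()
        self._acc = 0
        self._nacc = 0
        self.nbits = 0

    def write(self, value: int, nbits: int) -> None:
        """Append the ``nbits`` low-order bits of ``value``, MSB first."""
        if nbits < 0:
            raise ValueError("negative bit count")
        if nbits == 0:
            return
        if value < 0 or value >> nbits:
            raise ValueError(f"value {value} does not fit in {nbits} bits")
        self._acc = (self._acc << nbits) | value
        self._nacc += nbits
        self.nbits += nbits
        while self._nacc >= 8:
            self._nacc -= 8
            self._buf.append((self._acc >> self._nacc) & 0xFF)
        self._acc &= (1 << self._nacc) - 1

    def write_bit(self, bit: int) -> None:
        self.write(bit & 1, 1)

    def getvalue(self) -> bytes:
        """Byte string, final partial byte zero-padded on the right."""
        out = bytes(self._buf)
        if self._nacc:
            out += bytes([(self._acc << (8 - self._nacc)) & 0xFF])
        return out


class BitReader:
    """Reads bits MSB-first from a byte string."""

    def __init__(self, data: bytes, nbits: int | None = None) -> None:
        self._data = data
        self.nbits = 8 * len(data) if nbits is None else nbits
        self.pos = 0

    def read(self, nbits: int) -> int:
        if self.pos + nbits > self.nbits:
            raise EOFError(
                f"bitstream exhausted at bit {self.pos} (wanted {nbits} more)"
            )
        value = 0
        pos = self.pos
        for _ in range(nbits):
            byte = self._data[pos >> 3]
            value = (value << 1) | ((byte >> (7 - (pos & 7))) & 1)
            pos += 1
        self.pos = pos
        return value

    def read_bit(self) -> int:
        return self.read(1)

    def seek(self, bitpos: int) -> None:
        if bitpos < 0 or bitpos > self.nbits:
            raise ValueError("seek out of range")
        self.pos = bitpos

    @property
    def remaining(self) -> int:
        return self.nbits - self.pos
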