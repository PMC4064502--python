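"""Bit-packed DNA sequences and the Kimura two-parameter (K80) mutation operator.

Sequences over the strict alphabet {A, C, G, T} are stored two bits per base,
32 bases per 64-bit word, little-endian within each word (site 0 occupies the
lowest two bits of word 0).  The 2-bit codes are A=00, C=01, G=10, T=11, which
makes every transition (A<->G, C<->T) an XOR with 0b10 and the two transversion
choices XORs with 0b01 and 0b11 — so a mutation event is a single XOR and can
never be silent.

Batch kernels (:func:`pack_codes`, :func:`unpack_codes`, :func:`mutate_words`,
:func:`hamming_words`) operate on ``(n, n_words)`` uint64 arrays; the whole
simulator is built on them.  :class:`PackedSequence` is the single-sequence
wrapper used at API boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BASES_PER_WORD",
    "AlphabetError",
    "PackedSequence",
    "MutationModel",
    "encode",
    "decode_words",
    "hamming",
    "hamming_words",
    "mutate",
    "mutate_words",
    "n_words",
    "pack_codes",
    "unpack_codes",
]

BASES_PER_WORD = 32
ALPHABET = "ACGT"

_CHAR_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _CHAR_TO_CODE[ord(_c)] = _i
_CODE_TO_CHAR = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)

# one bit set per 2-bit site lane, used to collapse an XOR into per-site flags
_PAIR_MASK = np.uint64(0x5555555555555555)
_SHIFTS = (2 * np.arange(BASES_PER_WORD, dtype=np.uint64)).astype(np.uint64)


class AlphabetError(ValueError):
    """Raised for characters outside the strict A/C/G/T alphabet."""


def n_words(length: int) -> int:
    """Number of 64-bit words needed for ``length`` sites (ceil(L/32))."""
    return -(-int(length) // BASES_PER_WORD)


def pack_codes(codes: np.ndarray) -> np.ndarray:
    """Pack an ``(n, L)`` array of 2-bit codes into ``(n, ceil(L/32))`` uint64."""
    codes = np.asarray(codes)
    squeeze = codes.ndim == 1
    if squeeze:
        codes = codes[None, :]
    n, length = codes.shape
    w = n_words(length)
    padded = np.zeros((n, w * BASES_PER_WORD), dtype=np.uint64)
    padded[:, :length] = codes
    lanes = padded.reshape(n, w, BASES_PER_WORD) << _SHIFTS
    words = np.bitwise_or.reduce(lanes, axis=2)
    return words[0] if squeeze else words


def unpack_codes(words: np.ndarray, length: int) -> np.ndarray:
    """Inverse of :func:`pack_codes`: ``(n, W)`` uint64 -> ``(n, L)`` uint8 codes."""
    words = np.asarray(words, dtype=np.uint64)
    squeeze = words.ndim == 1
    if squeeze:
        words = words[None, :]
    n, w = words.shape
    lanes = (words[:, :, None] >> _SHIFTS) & np.uint64(3)
    codes = lanes.reshape(n, w * BASES_PER_WORD)[:, :length].astype(np.uint8)
    return codes[0] if squeeze else codes


@dataclass(frozen=True)
class PackedSequence:
    """An immutable DNA sequence of ``length`` sites packed 2 bits per base."""

    length: int
    words: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("sequence length must be >= 1")
        words = np.ascontiguousarray(self.words, dtype=np.uint64)
        if words.shape != (n_words(self.length),):
            raise ValueError(
                f"expected {n_words(self.length)} words for length {self.length}, "
                f"got shape {words.shape}"
            )
        tail = self.length % BASES_PER_WORD
        if tail and (words[-1] >> np.uint64(2 * tail)) != 0:
            raise ValueError("bits beyond the last site must be zero")
        words.flags.writeable = False
        object.__setattr__(self, "words", words)

    @classmethod
    def from_string(cls, dna: str) -> "PackedSequence":
        return encode(dna)

    def decode(self) -> str:
        return decode_words(self.words, self.length)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PackedSequence):
            return NotImplemented
        return self.length == other.length and bool(
            np.array_equal(self.words, other.words)
        )

    def __hash__(self) -> int:
        return hash((self.length, self.words.tobytes()))


def encode(dna: str) -> PackedSequence:
    """Encode an uppercase A/C/G/T string into a :class:`PackedSequence`."""
    if not dna:
        raise AlphabetError("cannot encode an empty sequence")
    raw = np.frombuffer(dna.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _CHAR_TO_CODE[raw]
    if (codes == 255).any():
        bad = dna[int(np.argmax(codes == 255))]
        raise AlphabetError(f"invalid character {bad!r}: only uppercase ACGT allowed")
    return PackedSequence(len(dna), pack_codes(codes))


def decode_words(words: np.ndarray, length: int) -> str:
    codes = unpack_codes(np.asarray(words, dtype=np.uint64), length)
    return _CODE_TO_CHAR[codes].tobytes().decode("ascii")


def hamming_words(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-row Hamming distance between packed arrays of identical shape.

    Works on ``(W,)`` or ``(n, W)`` arrays; trailing pad bits must be zero in
    both operands (guaranteed by the packing functions).
    """
    z = np.bitwise_xor(np.asarray(a, dtype=np.uint64), np.asarray(b, dtype=np.uint64))
    per_site = (z | (z >> np.uint64(1))) & _PAIR_MASK
    return np.bitwise_count(per_site).sum(axis=-1)


def hamming(a: PackedSequence, b: PackedSequence) -> int:
    """Number of sites at which two equal-length sequences differ."""
    if a.length != b.length:
        raise ValueError(f"length mismatch: {a.length} != {b.length}")
    return int(hamming_words(a.words, b.words))


@dataclass(frozen=True)
class MutationModel:
    """Kimura two-parameter model: per-site rate ``mu``, transition:transversion
    probability-mass ratio ``tstv`` (R).  A mutation event is a transition with
    probability R/(R+1), else one of the two transversions (each 1/(2(R+1)))."""

    mu: float
    tstv: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must be in [0, 1], got {self.mu}")
        if not self.tstv > 0.0:
            raise ValueError(f"tstv ratio must be > 0, got {self.tstv}")

    @property
    def p_transition(self) -> float:
        return self.tstv / (self.tstv + 1.0)

    def scaled(self, factor: float) -> "MutationModel":
        return MutationModel(mu=self.mu * factor, tstv=self.tstv)


def _sample_distinct(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random k-subset of range(n), as an int64 array.

    For small k relative to n this draws with replacement and keeps the first k
    distinct values in draw order (a label-symmetric rule, hence uniform);
    otherwise it falls back to a partial permutation.
    """
    if k > n:
        raise ValueError("k > n")
    if k == 0:
        return np.empty(0, dtype=np.int64)
    if 3 * k >= n:
        return rng.permutation(n)[:k].astype(np.int64)
    out = np.empty(0, dtype=np.int64)
    while out.size < k:
        need = k - out.size
        batch = rng.integers(0, n, size=need + need // 2 + 8, dtype=np.int64)
        merged = np.concatenate([out, batch])
        _, first = np.unique(merged, return_index=True)
        keep = np.sort(first)[:k]  # first-occurrence order
        out = merged[keep]
    return out


def mutate_words(
    words: np.ndarray, length: int, model: MutationModel, rng: np.random.Generator
) -> None:
    """Apply one round of K2P mutation in place to ``(M, W)`` packed sequences.

    Each of the M*L sites mutates independently with probability ``model.mu``
    (equivalently: per sequence, a Binomial(L, mu) number of hits at distinct
    uniform positions).  Each hit is an XOR with 2 (transition) or 1/3 (the two
    transversions), so a hit always changes the base.
    """
    if model.mu == 0.0:
        return
    m, w = words.shape
    total = m * length
    k = int(rng.binomial(total, model.mu))
    if k == 0:
        return
    pos = _sample_distinct(total, k, rng)
    u = rng.random(k)
    p_ts = model.p_transition
    delta = np.where(u < p_ts, 2, np.where(u < p_ts + (1.0 - p_ts) / 2.0, 1, 3)).astype(
        np.uint64
    )
    site = pos % length
    seq = pos // length
    shift = ((site % BASES_PER_WORD) * 2).astype(np.uint64)
    flat_idx = seq * w + site // BASES_PER_WORD
    flat = words.reshape(-1)
    np.bitwise_xor.at(flat, flat_idx, delta << shift)


def mutate(
    seq: PackedSequence, model: MutationModel, rng: np.random.Generator
) -> PackedSequence:
    """Return a new sequence with one round of K2P mutation applied."""
    words = seq.words.copy().reshape(1, -1)
    mutate_words(words, seq.length, model, rng)
    return PackedSequence(seq.length, words[0])
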