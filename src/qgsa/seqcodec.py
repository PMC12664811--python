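"""Binary encoding of DNA sequences for quantum pattern-matching circuits.

Two encoding schemes are supported:

* **2 bits/base** — A=00, C=01, G=10, T=11.  Compact, but a target whose
  length is not a power of two cannot be padded, and cyclic shifts can
  produce wrap-around pseudo-matches.
* **3 bits/base** — the 2-bit codes zero-extended (A=000, C=001, G=010,
  T=011) plus a terminator symbol ``$`` = 100.  The terminator matches no
  base, so padding a target with ``$`` both reaches a power-of-two number
  of positions and blocks start–end-contact false matches.

The index register of the search circuit addresses *symbol* positions, so
the power-of-two requirement applies to the number of symbols; a cyclic
shift moves whole symbols, i.e. multiples of ``bits_per_base`` bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Optional

__all__ = [
    "EncodingScheme",
    "EncodedSequence",
    "SCHEME_2BIT",
    "SCHEME_3BIT",
    "TERMINATOR",
    "encode",
    "decode",
    "pad_to_power_of_two",
    "shift_offsets",
]

TERMINATOR = "$"
_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class EncodingScheme:
    """A fixed-width binary code for the DNA alphabet.

    Parameters
    ----------
    bits_per_base:
        Code width ``k`` (2 or 3).
    code_map:
        Mapping from symbol to its ``k``-bit code.  Must cover exactly
        A, C, G, T, plus ``$`` iff ``k == 3``.
    terminator_code:
        The code of ``$`` when present (must be ``"100"``), else ``None``.
    """

    bits_per_base: int
    code_map: Mapping[str, str]
    terminator_code: Optional[str] = None

    def __post_init__(self) -> None:
        k = self.bits_per_base
        if k not in (2, 3):
            raise ValueError(f"bits_per_base must be 2 or 3, got {k}")
        expected = set(_BASES) | ({TERMINATOR} if k == 3 else set())
        if set(self.code_map) != expected:
            raise ValueError(
                f"code_map must cover exactly {sorted(expected)}, "
                f"got {sorted(self.code_map)}"
            )
        codes = list(self.code_map.values())
        if len(set(codes)) != len(codes):
            raise ValueError("codes must be distinct")
        for sym, code in self.code_map.items():
            if len(code) != k or set(code) - {"0", "1"}:
                raise ValueError(f"code for {sym!r} is not a {k}-bit string: {code!r}")
        if k == 3:
            if self.code_map[TERMINATOR] != "100":
                raise ValueError("terminator code must be 100")
            if self.terminator_code != "100":
                raise ValueError("terminator_code field must be 100 for k=3")
        elif self.terminator_code is not None:
            raise ValueError("2-bit scheme has no terminator")
        # freeze the mapping
        object.__setattr__(self, "code_map", MappingProxyType(dict(self.code_map)))

    @property
    def decode_map(self) -> dict:
        return {code: sym for sym, code in self.code_map.items()}


SCHEME_2BIT = EncodingScheme(2, {"A": "00", "C": "01", "G": "10", "T": "11"})
SCHEME_3BIT = EncodingScheme(
    3,
    {"A": "000", "C": "001", "G": "010", "T": "011", TERMINATOR: "100"},
    terminator_code="100",
)


@dataclass(frozen=True)
class EncodedSequence:
    """A DNA sequence in bit-string form under a declared scheme."""

    bits: str
    scheme: EncodingScheme
    n_bases: int

    def __post_init__(self) -> None:
        if len(self.bits) != self.scheme.bits_per_base * self.n_bases:
            raise ValueError(
                f"bit length {len(self.bits)} != "
                f"{self.scheme.bits_per_base} x {self.n_bases}"
            )
        if set(self.bits) - {"0", "1"}:
            raise ValueError("bits must be a 0/1 string")

    def __len__(self) -> int:
        return len(self.bits)


def _normalize(sequence: str, scheme: EncodingScheme) -> str:
    seq = sequence.upper()
    alphabet = set(scheme.code_map)
    for pos, sym in enumerate(seq, start=1):
        if sym not in alphabet:
            extra = (
                " ('$' requires the 3-bit scheme)"
                if sym == TERMINATOR
                else ""
            )
            raise ValueError(f"unknown symbol {sym!r} at position {pos}{extra}")
    return seq


def encode(sequence: str, scheme: EncodingScheme = SCHEME_2BIT) -> EncodedSequence:
    """Encode a DNA string (case-insensitive) as a bit string.

    The result is the concatenation of per-base codes in sequence order,
    so encoding is homomorphic over string concatenation.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = _normalize(sequence, scheme)
    bits = "".join(scheme.code_map[sym] for sym in seq)
    return EncodedSequence(bits=bits, scheme=scheme, n_bases=len(seq))


def decode(encoded, scheme: EncodingScheme | None = None) -> str:
    """Invert :func:`encode`.  Accepts an :class:`EncodedSequence` or a raw
    bit string together with a scheme."""
    if isinstance(encoded, EncodedSequence):
        bits, scheme = encoded.bits, encoded.scheme
    else:
        bits = encoded
        if scheme is None:
            raise ValueError("a scheme is required when decoding a raw bit string")
    k = scheme.bits_per_base
    if len(bits) % k:
        raise ValueError(f"bit length {len(bits)} not divisible by {k}")
    rev = scheme.decode_map
    out = []
    for i in range(0, len(bits), k):
        block = bits[i : i + k]
        try:
            out.append(rev[block])
        except KeyError:
            raise ValueError(
                f"invalid {k}-bit code {block!r} at block {i // k}"
            ) from None
    return "".join(out)


def _is_pow2(x: int) -> bool:
    return x > 0 and (x & (x - 1)) == 0


def pad_to_power_of_two(encoded: EncodedSequence) -> EncodedSequence:
    """Pad with terminator symbols until the symbol count is a power of two.

    The index register addresses 2^m symbol positions and shifts move whole
    symbols, so the power-of-two constraint is on the number of symbols.
    A 2-bit sequence has no terminator and is only accepted if its symbol
    count is already a power of two.
    """
    n = encoded.n_bases
    if _is_pow2(n):
        return encoded
    if encoded.scheme.terminator_code is None:
        raise ValueError(
            f"symbol count {n} is not a power of two and the 2-bit scheme has "
            "no terminator; re-encode with the 3-bit scheme to pad with '$'"
        )
    target = 1
    while target < n:
        target *= 2
    pad = encoded.scheme.terminator_code * (target - n)
    return EncodedSequence(
        bits=encoded.bits + pad, scheme=encoded.scheme, n_bases=target
    )


def shift_offsets(encoded_length: int, k: int) -> list[int]:
    """Bit-shift amounts of the cyclic-shift ladder, one per index qubit.

    For a target of ``k * 2^m`` bits encoded at ``k`` bits per symbol, the
    legal shift intervals are ``k*2^0, k*2^1, ..., k*2^(m-1)``: each index
    qubit controls a rotate-left by one of these offsets, and composing
    them over an index value ``r`` rotates by ``k*r`` bits (whole symbols
    only, so every shifted string is a valid symbol string).
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    if encoded_length % k:
        raise ValueError(f"encoded length {encoded_length} not a multiple of k={k}")
    symbols = encoded_length // k
    if not _is_pow2(symbols):
        raise ValueError(
            f"encoded length {encoded_length} is not k*2^m for k={k}"
        )
    out = []
    off = k
    while off < encoded_length:
        out.append(off)
        off *= 2
    return out
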