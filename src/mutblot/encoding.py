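"""Numeric encoding of mutation sequences.

Each base is a 1x2 code (A=[0,0], T=[0,1], C=[1,0], G=[1,1], N=[-1,-1]);
a flank base b occupies a matrix row [b|b] and the mutation site occupies
the row [alt|ref] — mutant code in columns 0-1, reference code in columns
2-3.  With F flanking bases on each side the full encoding is a
(2F+1) x 4 matrix.

The mutation-row column order [alt|ref] is fixed by decoding the worked
CATTG>CACTG example: its middle row [1,0,0,1] is the C code followed by
the T code for a T>C substitution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sbs_io import MutationSequence

BASE_CODES: dict[str, tuple[int, int]] = {
    "A": (0, 0),
    "T": (0, 1),
    "C": (1, 0),
    "G": (1, 1),
    "N": (-1, -1),
}

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}

#: the six canonical (pyrimidine-referenced) substitution types
CANONICAL_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


class EncodingError(ValueError):
    pass


@dataclass(frozen=True)
class EncodedMutation:
    """(2F+1) x 4 encoding of a flanked substitution.

    ``site_index`` is the 0-based row of the mutation (= F).
    """

    matrix: np.ndarray
    site_index: int

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise EncodingError(f"matrix must be n x 4, got {self.matrix.shape}")


@dataclass(frozen=True)
class CanonicalSubstitution:
    """Substitution in pyrimidine-referenced form with its flanks.

    If the original reference base was a purine, the whole flanked
    sequence has been reverse-complemented, so flanks read 5'->3' on the
    opposite strand.
    """

    sub_type: str
    five_prime_flank: str
    three_prime_flank: str

    def __post_init__(self) -> None:
        if self.sub_type not in CANONICAL_TYPES:
            raise ValueError(f"non-canonical substitution type {self.sub_type!r}")


def _code(base: str) -> tuple[int, int]:
    try:
        return BASE_CODES[base]
    except KeyError:
        raise EncodingError(f"cannot encode base {base!r}") from None


def encode_mutation_sequence(seq: MutationSequence) -> EncodedMutation:
    """Encode a flanked substitution as a (2F+1) x 4 integer matrix."""
    if seq.ref_allele not in "ACGT" or seq.alt_allele not in "ACGT":
        raise EncodingError(
            f"ref/alt alleles must be A/C/G/T, got {seq.ref_allele!r}>{seq.alt_allele!r}"
        )
    F = seq.flank_length
    n = 2 * F + 1
    matrix = np.empty((n, 4), dtype=np.int8)
    for i, base in enumerate(seq.five_prime_flank):
        matrix[i, :2] = matrix[i, 2:] = _code(base)
    matrix[F, :2] = _code(seq.alt_allele)
    matrix[F, 2:] = _code(seq.ref_allele)
    for i, base in enumerate(seq.three_prime_flank):
        matrix[F + 1 + i, :2] = matrix[F + 1 + i, 2:] = _code(base)
    return EncodedMutation(matrix=matrix, site_index=F)


def decode_matrix(enc: EncodedMutation) -> MutationSequence:
    """Invert :func:`encode_mutation_sequence` (used for round-trip checks)."""
    rev = {v: k for k, v in BASE_CODES.items()}
    rows = enc.matrix
    five = "".join(rev[tuple(r[:2])] for r in rows[: enc.site_index])
    three = "".join(rev[tuple(r[:2])] for r in rows[enc.site_index + 1:])
    alt = rev[tuple(rows[enc.site_index, :2])]
    ref = rev[tuple(rows[enc.site_index, 2:])]
    return MutationSequence(five, ref, alt, three)


def split_bidirectional(enc: EncodedMutation) -> tuple[np.ndarray, np.ndarray]:
    """The two directional reads toward the mutation site.

    Returns (five_to_site, three_to_site): the 5' read in natural order
    and the 3' read reversed, each of length F+1 and each ending in the
    shared mutation row, so the site sits at the end of both sequences.
    """
    m, s = enc.matrix, enc.site_index
    five_to_site = m[: s + 1]
    three_to_site = m[s:][::-1]
    return five_to_site, three_to_site


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def pyrimidine_collapse(seq: MutationSequence) -> CanonicalSubstitution:
    """Represent a substitution by the strand whose reference base is C/T.

    Purine-reference substitutions are complemented and their flanked
    sequence reverse-complemented, so the original 3' flank becomes the
    new 5' flank; pyrimidine-reference inputs pass through unchanged.
    """
    if seq.ref_allele in ("C", "T"):
        return CanonicalSubstitution(
            sub_type=f"{seq.ref_allele}>{seq.alt_allele}",
            five_prime_flank=seq.five_prime_flank,
            three_prime_flank=seq.three_prime_flank,
        )
    return CanonicalSubstitution(
        sub_type=f"{COMPLEMENT[seq.ref_allele]}>{COMPLEMENT[seq.alt_allele]}",
        five_prime_flank=reverse_complement(seq.three_prime_flank),
        three_prime_flank=reverse_complement(seq.five_prime_flank),
    )


def encode_batch(sequences) -> np.ndarray:
    """Stack encodings of equal-length MutationSequences into (B, n, 4)."""
    mats = [encode_mutation_sequence(s).matrix for s in sequences]
    lengths = {m.shape[0] for m in mats}
    if len(lengths) > 1:
        raise EncodingError(f"mixed sequence lengths in batch: {sorted(lengths)}")
    return np.stack(mats).astype(np.float64)
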