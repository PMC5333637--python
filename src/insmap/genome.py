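"""Genome sequences with motif, restriction-site, and mappability indexes.

All coordinates are 0-based half-open throughout the package (BED
convention).  Sequences are held as small integer code arrays
(A=0, C=1, G=2, T=3, anything else=4) so that motif scanning, restriction
mapping, and k-mer uniqueness are plain vectorised numpy operations.  An
``N`` (code 4) never matches any motif or recognition sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeIndex",
    "MotifIndex",
    "RestrictionIndex",
    "scan_motif_positions",
    "index_restriction_sites",
    "reverse_complement",
]

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode_sequence(codes: np.ndarray) -> str:
    return _DECODE[np.minimum(codes, 4)].tobytes().decode("ascii")


class GenomeIndex:
    """An in-memory genome: ordered chromosomes plus a sequence accessor.

    Parameters
    ----------
    sequences
        Mapping of chromosome name to DNA string (order preserved).
    """

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("genome must contain at least one chromosome")
        names = list(sequences)
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        self._codes: dict[str, np.ndarray] = {}
        for name, seq in sequences.items():
            if len(seq) == 0:
                raise ValueError(f"chromosome {name!r} has zero length")
            self._codes[name] = encode_sequence(seq)
        self._uniqueness_cache: dict[int, dict[str, np.ndarray]] = {}

    # -- construction -----------------------------------------------------
    @classmethod
    def from_fasta(cls, path) -> "GenomeIndex":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    # -- basic accessors --------------------------------------------------
    @property
    def names(self) -> list[str]:
        return list(self._codes)

    @property
    def chromosomes(self) -> list[tuple[str, int]]:
        return [(name, len(codes)) for name, codes in self._codes.items()]

    def __contains__(self, name: str) -> bool:
        return name in self._codes

    def length(self, chrom: str) -> int:
        return len(self.codes(chrom))

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self._codes.values())

    def codes(self, chrom: str) -> np.ndarray:
        try:
            return self._codes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Uppercase sequence of ``[start, end)``; rejects out-of-bounds slices."""
        codes = self.codes(chrom)
        if not (0 <= start <= end <= len(codes)):
            raise ValueError(
                f"slice [{start}, {end}) out of bounds for {chrom} "
                f"(length {len(codes)})"
            )
        return decode_sequence(codes[start:end])

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, codes in self._codes.items():
                fh.write(f">{name}\n")
                seq = decode_sequence(codes)
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    # -- mappability -------------------------------------------------------
    def kmer_uniqueness(self, k: int) -> dict[str, np.ndarray]:
        """Boolean array per chromosome: position p is True iff the k-mer
        starting at p occurs exactly once in the whole genome, counting
        forward-strand and reverse-complement occurrences together.

        Windows containing non-ACGT bases are never unique.  Results are
        cached per ``k``.
        """
        if k <= 0:
            raise ValueError("k must be positive")
        if k > 64:
            raise ValueError("k-mer uniqueness supports k <= 64")
        shortest = min(len(c) for c in self._codes.values())
        if k > shortest:
            raise ValueError(
                f"k={k} exceeds the shortest chromosome length ({shortest})"
            )
        if k in self._uniqueness_cache:
            return self._uniqueness_cache[k]

        h = min(k, 32)  # bases packed into the high word
        per_chrom_codes = []
        for name, codes in self._codes.items():
            n = len(codes) - k + 1
            fwd_hi = np.zeros(n, dtype=np.uint64)
            fwd_lo = np.zeros(n, dtype=np.uint64)
            rc_hi = np.zeros(n, dtype=np.uint64)
            rc_lo = np.zeros(n, dtype=np.uint64)
            c64 = codes.astype(np.uint64)
            rc64 = (np.uint64(3) - np.minimum(c64, 3)) % np.uint64(4)
            for j in range(k):
                base = c64[j : j + n]
                rbase = rc64[k - 1 - j : k - 1 - j + n]
                if j < h:
                    fwd_hi = (fwd_hi << np.uint64(2)) | base
                    rc_hi = (rc_hi << np.uint64(2)) | rbase
                else:
                    fwd_lo = (fwd_lo << np.uint64(2)) | base
                    rc_lo = (rc_lo << np.uint64(2)) | rbase
            valid = (
                np.convolve((codes == 4).astype(np.int32), np.ones(k, np.int32))[
                    k - 1 : k - 1 + n
                ]
                == 0
            )
            # canonical = lexicographic min of (forward, reverse complement)
            swap = (rc_hi < fwd_hi) | ((rc_hi == fwd_hi) & (rc_lo < fwd_lo))
            can_hi = np.where(swap, rc_hi, fwd_hi)
            can_lo = np.where(swap, rc_lo, fwd_lo)
            per_chrom_codes.append((name, can_hi, can_lo, valid))

        all_hi = np.concatenate([c[1][c[3]] for c in per_chrom_codes])
        all_lo = np.concatenate([c[2][c[3]] for c in per_chrom_codes])
        order = np.lexsort((all_lo, all_hi))
        hi_s, lo_s = all_hi[order], all_lo[order]
        if len(hi_s):
            new_run = np.empty(len(hi_s), dtype=bool)
            new_run[0] = True
            new_run[1:] = (hi_s[1:] != hi_s[:-1]) | (lo_s[1:] != lo_s[:-1])
            run_id = np.cumsum(new_run) - 1
            run_sizes = np.bincount(run_id)
            unique_sorted = run_sizes[run_id] == 1
            unique_flat = np.empty(len(hi_s), dtype=bool)
            unique_flat[order] = unique_sorted
        else:
            unique_flat = np.empty(0, dtype=bool)

        result: dict[str, np.ndarray] = {}
        offset = 0
        for name, _hi, _lo, valid in per_chrom_codes:
            m = valid.sum()
            mask = np.zeros(len(self._codes[name]), dtype=bool)
            vals = np.zeros(len(valid), dtype=bool)
            vals[valid] = unique_flat[offset : offset + m]
            mask[: len(valid)] = vals
            result[name] = mask
            offset += m
        self._uniqueness_cache[k] = result
        return result


@dataclass
class MotifIndex:
    """Exact forward-strand occurrences of a short motif, per chromosome."""

    motif: str
    positions: dict[str, np.ndarray] = field(default_factory=dict)

    def count(self) -> int:
        return sum(len(p) for p in self.positions.values())


@dataclass
class RestrictionIndex:
    """Cut coordinates of a restriction enzyme across the genome.

    The cut coordinate of a recognition match starting at ``s`` is
    ``s + cut_offset`` (e.g. HaeIII GG^CC: recognition GGCC, offset 2).
    """

    name: str
    recognition: str
    cut_offset: int
    cuts: dict[str, np.ndarray] = field(default_factory=dict)

    def count(self) -> int:
        return sum(len(c) for c in self.cuts.values())


def _validate_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq or any(b not in "ACGT" for b in seq):
        raise ValueError(f"{what} must be a non-empty string over A/C/G/T: {seq!r}")
    return seq


def _match_positions(codes: np.ndarray, motif_codes: np.ndarray) -> np.ndarray:
    n = len(codes) - len(motif_codes) + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    mask = codes[:n] == motif_codes[0]
    for j in range(1, len(motif_codes)):
        mask &= codes[j : j + n] == motif_codes[j]
    return np.flatnonzero(mask).astype(np.int64)


def scan_motif_positions(
    genome: GenomeIndex, motif: str, both_strands: bool = False
) -> MotifIndex:
    """All exact matches of ``motif``, overlapping matches included.

    The search is forward-strand only by default; the canonical target-site
    motifs (TA, TTAA) and HaeIII GGCC are palindromic, so nothing is lost.
    ``both_strands=True`` additionally matches the reverse complement (match
    start still reported in forward coordinates).
    """
    motif = _validate_dna(motif, "motif")
    mcodes = encode_sequence(motif)
    rc = reverse_complement(motif)
    positions: dict[str, np.ndarray] = {}
    for name in genome.names:
        codes = genome.codes(name)
        pos = _match_positions(codes, mcodes)
        if both_strands and rc != motif:
            pos = np.union1d(pos, _match_positions(codes, encode_sequence(rc)))
        positions[name] = pos
    return MotifIndex(motif=motif, positions=positions)


def index_restriction_sites(
    genome: GenomeIndex,
    recognition: str = "GGCC",
    cut_offset: int = 2,
    name: str | None = None,
) -> RestrictionIndex:
    """Cut coordinates for every forward-strand recognition match.

    Defaults describe HaeIII (GGCC, blunt cut GG^CC, offset 2).
    """
    recognition = _validate_dna(recognition, "recognition sequence")
    if not (0 <= cut_offset <= len(recognition)):
        raise ValueError("cut_offset must lie within the recognition sequence")
    rcodes = encode_sequence(recognition)
    cuts = {
        chrom: _match_positions(genome.codes(chrom), rcodes) + cut_offset
        for chrom in genome.names
    }
    return RestrictionIndex(
        name=name or recognition,
        recognition=recognition,
        cut_offset=cut_offset,
        cuts=cuts,
    )
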