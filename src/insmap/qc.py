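"""Post-alignment insertion-calling filters.

Converts generic alignment records into accepted insertion sites by the
platform-appropriate rules: long-read (restriction) libraries are filtered
on percent identity and coverage, short paired-end (shear) libraries on
mapping quality, proper pairing, uniqueness, and duplicate-collapsed
support.  Vector-specific target-site motifs (TTAA for piggyBac, TA for
Sleeping Beauty) are confirmed against the genome; vectors without a
target-site motif (MLV, Tol2) pass unconditionally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeIndex
from .sites import InsertionSet

__all__ = [
    "AlignmentRecord",
    "read_alignment_table",
    "filter_alignment_records",
    "verify_insertion_motif",
    "DEFAULT_VECTOR_MOTIFS",
]

log = logging.getLogger(__name__)

# piggyBac duplicates TTAA, Sleeping Beauty TA; MLV and Tol2 have no
# target-site consensus.
DEFAULT_VECTOR_MOTIFS: dict[str, str | None] = {
    "PB": "TTAA",
    "SB": "TA",
    "MLV": None,
    "Tol2": None,
}


@dataclass(frozen=True)
class AlignmentRecord:
    chrom: str
    position: int
    strand: str
    mapq: int = 0
    proper_pair: bool = True
    identity: float | None = None
    coverage: float | None = None
    support: int = 1
    multimapper: bool = False

    def __post_init__(self):
        if self.mapq < 0:
            raise ValueError("mapping quality must be >= 0")
        for val, what in ((self.identity, "identity"), (self.coverage, "coverage")):
            if val is not None and not (0 <= val <= 100):
                raise ValueError(f"percent {what} must lie in [0, 100]")
        if self.support < 1:
            raise ValueError("supporting-read count must be >= 1")


def read_alignment_table(path) -> list[AlignmentRecord]:
    """TSV with columns chrom, position, strand, mapq, proper_pair,
    identity, coverage, support, multimapper (identity/coverage may be
    empty for short-read records)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            AlignmentRecord(
                chrom=row.chrom,
                position=int(row.position),
                strand=row.strand,
                mapq=int(getattr(row, "mapq", 0)),
                proper_pair=bool(getattr(row, "proper_pair", True)),
                identity=None if pd.isna(getattr(row, "identity", np.nan)) else float(row.identity),
                coverage=None if pd.isna(getattr(row, "coverage", np.nan)) else float(row.coverage),
                support=int(getattr(row, "support", 1)),
                multimapper=bool(getattr(row, "multimapper", False)),
            )
        )
    return records


def filter_alignment_records(
    records: list[AlignmentRecord],
    min_mapq: int | None = 30,
    require_proper_pair: bool = True,
    min_identity: float | None = 90.0,
    min_coverage: float | None = 90.0,
    min_support: int = 2,
    drop_multimappers: bool = True,
    vector: str = "PB",
    platform: str = "shear",
    collapse_duplicates: bool = True,
) -> InsertionSet:
    """Apply the read-acceptance rules and emit an :class:`InsertionSet`.

    Thresholds are strict where quoted as strict: mapping quality must
    exceed ``min_mapq`` (>30, not >=30) and identity/coverage must exceed
    their thresholds.  Records at identical (chrom, position, strand) are
    collapsed before support counting, since duplicate junction reads are
    what the >=2-read rule counts.  Any filter can be disabled by passing
    ``None`` (or ``require_proper_pair=False``).  An empty result is a
    warning, not an error.
    """
    dropped = {
        "mapq": 0,
        "proper_pair": 0,
        "identity": 0,
        "coverage": 0,
        "multimapper": 0,
        "support": 0,
    }
    surviving = []
    for rec in records:
        if drop_multimappers and rec.multimapper:
            dropped["multimapper"] += 1
            continue
        if min_mapq is not None and not rec.mapq > min_mapq:
            dropped["mapq"] += 1
            continue
        if require_proper_pair and not rec.proper_pair:
            dropped["proper_pair"] += 1
            continue
        if min_identity is not None and rec.identity is not None and not rec.identity > min_identity:
            dropped["identity"] += 1
            continue
        if min_coverage is not None and rec.coverage is not None and not rec.coverage > min_coverage:
            dropped["coverage"] += 1
            continue
        surviving.append(rec)

    if collapse_duplicates:
        merged: dict[tuple, int] = {}
        for rec in surviving:
            key = (rec.chrom, rec.position, rec.strand)
            merged[key] = merged.get(key, 0) + rec.support
    else:
        merged = {
            (rec.chrom, rec.position, rec.strand, i): rec.support
            for i, rec in enumerate(surviving)
        }

    kept = []
    for key, support in merged.items():
        if support < min_support:
            dropped["support"] += 1
            continue
        kept.append((key[0], key[1], key[2]))

    for rule, n in dropped.items():
        if n:
            log.info("filter_alignment_records: dropped %d record(s) by %s", n, rule)
    if not kept:
        log.warning("filter_alignment_records: all records dropped")
        kept_arr = pd.DataFrame(columns=["chrom", "position", "strand"])
    else:
        kept_arr = pd.DataFrame(kept, columns=["chrom", "position", "strand"])
    kept_arr["vector"] = vector
    kept_arr["platform"] = platform
    out = InsertionSet(kept_arr, label="filtered")
    out.metadata["dropped"] = dropped
    return out


def verify_insertion_motif(
    iset: InsertionSet,
    genome: GenomeIndex,
    vector_motifs: dict[str, str | None] | None = None,
) -> InsertionSet:
    """Keep only sites whose genomic sequence carries the vector's
    target-site motif at the insertion position.

    Vectors mapped to ``None`` (MLV, Tol2) pass unconditionally.  Sites too
    close to a chromosome end for the motif window are dropped with a
    warning.
    """
    motifs = DEFAULT_VECTOR_MOTIFS if vector_motifs is None else vector_motifs
    vector = iset.vector
    if vector not in motifs:
        raise ValueError(f"no motif rule for vector {vector!r}")
    motif = motifs[vector]
    if motif is None:
        return iset

    keep = np.zeros(len(iset), dtype=bool)
    truncated = 0
    for i, (chrom, pos) in enumerate(
        zip(iset.df["chrom"].to_numpy(), iset.df["position"].to_numpy())
    ):
        end = pos + len(motif)
        if end > genome.length(chrom):
            truncated += 1
            continue
        keep[i] = genome.fetch(chrom, pos, end) == motif
    if truncated:
        log.warning(
            "verify_insertion_motif: %d site(s) too close to a chromosome end",
            truncated,
        )
    n_dropped = int((~keep).sum())
    log.info(
        "verify_insertion_motif: kept %d, dropped %d", int(keep.sum()), n_dropped
    )
    out = iset.subset(np.flatnonzero(keep))
    out.metadata["motif_dropped"] = n_dropped
    return out
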