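"""Insertion-site records and the tabular reader/writer.

An insertion site is the genomic coordinate of a vector-genome junction:
``position`` is the first base of the target site on the forward strand
(for piggyBac this is the first T of the TTAA duplication, for Sleeping
Beauty the T of the TA), regardless of which flank was sequenced.
``strand`` records the direction of the sequenced flank and orients the
restriction fragment; ``fragment_length`` is the distance in bp from the
junction to the anchoring restriction cut (restriction platform) or the
sheared end (shear platform, optional).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .genome import GenomeIndex

__all__ = [
    "InsertionSite",
    "InsertionSet",
    "read_insertion_table",
    "write_insertion_table",
]

COLUMNS = [
    "chrom",
    "position",
    "strand",
    "vector",
    "replicate",
    "selection",
    "platform",
    "fragment_length",
]

VECTORS = ("MLV", "PB", "Tol2", "SB")
PLATFORMS = ("restriction", "shear")


@dataclass(frozen=True)
class InsertionSite:
    chrom: str
    position: int
    strand: str
    vector: str = "PB"
    replicate: str = "1"
    selection: str = "G418"
    platform: str = "restriction"
    fragment_length: float | None = None


class InsertionSet:
    """A labelled collection of insertion sites, array-backed.

    Wraps a :class:`pandas.DataFrame` with the canonical columns so that
    genome-scale analyses stay vectorised; individual sites are available
    through :meth:`sites`.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        label: str = "",
        genome: GenomeIndex | None = None,
        metadata: dict | None = None,
    ):
        df = df.copy().reset_index(drop=True)
        for col in COLUMNS:
            if col not in df.columns:
                if col == "fragment_length":
                    df[col] = np.nan
                elif col == "selection":
                    df[col] = "none"
                elif col == "platform":
                    df[col] = "shear"
                elif col == "replicate":
                    df[col] = "1"
                elif col == "vector":
                    df[col] = "custom"
                else:
                    raise ValueError(f"missing required column {col!r}")
        df["position"] = df["position"].astype(np.int64)
        df["fragment_length"] = pd.to_numeric(df["fragment_length"], errors="coerce")
        self._validate(df, genome)
        self.df = df[COLUMNS]
        self.label = label
        self.metadata = dict(metadata or {})
        vectors = df["vector"].unique()
        if len(vectors) > 1:
            raise ValueError(f"vector label must be uniform across sites: {vectors}")
        self.metadata.setdefault("vector", vectors[0] if len(vectors) else "custom")

    @staticmethod
    def _validate(df: pd.DataFrame, genome: GenomeIndex | None) -> None:
        bad_strand = ~df["strand"].isin(["+", "-"])
        if bad_strand.any():
            row = int(np.flatnonzero(bad_strand.to_numpy())[0])
            raise ValueError(
                f"row {row}: malformed strand {df['strand'].iloc[row]!r} "
                "(expected '+' or '-')"
            )
        frag = df["fragment_length"].to_numpy()
        bad_frag = np.isfinite(frag) & (frag <= 0)
        if bad_frag.any():
            row = int(np.flatnonzero(bad_frag)[0])
            raise ValueError(f"row {row}: fragment_length must be > 0")
        if genome is not None:
            for row, (chrom, pos) in enumerate(
                zip(df["chrom"].to_numpy(), df["position"].to_numpy())
            ):
                if chrom not in genome:
                    raise ValueError(f"row {row}: unknown chromosome {chrom!r}")
                if not (0 <= pos < genome.length(chrom)):
                    raise ValueError(
                        f"row {row}: position {pos} out of bounds for {chrom} "
                        f"(length {genome.length(chrom)}; positions are 0-based, "
                        "half-open)"
                    )
        elif (df["position"].to_numpy() < 0).any():
            raise ValueError("positions must be non-negative")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_sites(
        cls,
        sites: list[InsertionSite],
        label: str = "",
        genome: GenomeIndex | None = None,
    ) -> "InsertionSet":
        df = pd.DataFrame([s.__dict__ for s in sites], columns=COLUMNS)
        return cls(df, label=label, genome=genome)

    @classmethod
    def from_arrays(
        cls,
        chrom,
        position,
        strand,
        label: str = "",
        genome: GenomeIndex | None = None,
        **extra,
    ) -> "InsertionSet":
        df = pd.DataFrame({"chrom": chrom, "position": position, "strand": strand})
        for key, val in extra.items():
            df[key] = val
        return cls(df, label=label, genome=genome)

    # -- accessors --------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def vector(self) -> str:
        return self.metadata.get("vector", "custom")

    def sites(self) -> Iterator[InsertionSite]:
        for row in self.df.itertuples(index=False):
            frag = row.fragment_length
            yield InsertionSite(
                chrom=row.chrom,
                position=int(row.position),
                strand=row.strand,
                vector=row.vector,
                replicate=str(row.replicate),
                selection=row.selection,
                platform=row.platform,
                fragment_length=None if pd.isna(frag) else float(frag),
            )

    def positions_by_chrom(self, sort: bool = True) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            pos = sub["position"].to_numpy()
            out[chrom] = np.sort(pos) if sort else pos
        return out

    def subset(self, index) -> "InsertionSet":
        return InsertionSet(
            self.df.iloc[index], label=self.label, metadata=self.metadata
        )


def read_insertion_table(
    path, genome: GenomeIndex | None = None, one_based: bool = False
) -> InsertionSet:
    """Read a tab-separated insertion table (header: chrom, position, strand,
    vector, replicate, selection, platform, fragment_length).

    ``one_based=True`` shifts input positions down by one on read, for
    deposited tables whose coordinate convention is 1-based.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "replicate": str})
    missing = [c for c in COLUMNS if c not in df.columns and c != "fragment_length"]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if one_based:
        df["position"] = df["position"] - 1
    try:
        return InsertionSet(df, label=str(path), genome=genome)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_insertion_table(iset: InsertionSet, path) -> None:
    df = iset.df.copy()
    frag = df["fragment_length"]
    df["fragment_length"] = frag.map(
        lambda v: "" if pd.isna(v) else (f"{int(v)}" if float(v).is_integer() else f"{v}")
    )
    df.to_csv(path, sep="\t", index=False)
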