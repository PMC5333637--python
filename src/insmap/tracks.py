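"""Gene models, interval tracks (BED), and fixed-step density tracks.

Interval tracks hold half-open 0-based intervals sorted by start per
chromosome, the natural container for peak sets, enhancer catalogues, and
HMM-derived histone-modification regions.  Density tracks hold fixed-step
numeric values (origin 0), the container for ChIP-seq density pileups read
from bedGraph or fixed-step wiggle files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeIndex

__all__ = [
    "GeneModel",
    "IntervalTrack",
    "DensityTrack",
    "load_interval_track",
    "write_interval_track",
    "load_density_track",
    "read_gene_models",
    "write_gene_bed12",
    "read_expression_table",
]


@dataclass
class GeneModel:
    """One transcript/gene: body interval, sorted exons, expression level."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    expression: float = 0.0

    def __post_init__(self):
        if self.tx_start >= self.tx_end:
            raise ValueError(f"{self.gene_id}: txStart must be < txEnd")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.expression < 0:
            raise ValueError(f"{self.gene_id}: expression must be non-negative")
        exons = sorted(self.exons)
        last = self.tx_start
        for s, e in exons:
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) outside gene body")
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon [{s},{e})")
            if s < last:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            last = e
        self.exons = exons

    @property
    def tss(self) -> int:
        """Transcription start: tx_start on '+', tx_end - 1 on '-'."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def size(self) -> int:
        return self.tx_end - self.tx_start


class IntervalTrack:
    """Named, per-chromosome sorted half-open intervals with optional scores."""

    def __init__(
        self,
        name: str,
        intervals: dict[str, np.ndarray],
        scores: dict[str, np.ndarray] | None = None,
    ):
        self.name = name
        self.intervals: dict[str, np.ndarray] = {}
        self.scores: dict[str, np.ndarray] = {}
        for chrom, arr in intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if len(arr) and (arr[:, 0] >= arr[:, 1]).any():
                raise ValueError(f"{name}/{chrom}: interval with start >= end")
            order = np.lexsort((arr[:, 1], arr[:, 0]))
            self.intervals[chrom] = arr[order]
            if scores is not None and chrom in scores:
                self.scores[chrom] = np.asarray(scores[chrom], float)[order]

    def __len__(self) -> int:
        return sum(len(v) for v in self.intervals.values())

    def total_bp(self) -> int:
        merged = self.merged()
        return int(
            sum((a[:, 1] - a[:, 0]).sum() for a in merged.intervals.values())
        )

    def merged(self, flank: int = 0) -> "IntervalTrack":
        """Union of intervals, each expanded by ``flank`` on both sides."""
        out: dict[str, np.ndarray] = {}
        for chrom, arr in self.intervals.items():
            if not len(arr):
                out[chrom] = arr
                continue
            starts = np.maximum(arr[:, 0] - flank, 0)
            ends = arr[:, 1] + flank
            merged: list[list[int]] = []
            for s, e in zip(starts, ends):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], int(e))
                else:
                    merged.append([int(s), int(e)])
            out[chrom] = np.asarray(merged, dtype=np.int64)
        return IntervalTrack(self.name, out)

    def contains(self, chrom: str, positions: np.ndarray, flank: int = 0) -> np.ndarray:
        """Boolean mask: does each position fall in any (flank-expanded) interval?"""
        arr = self.merged(flank).intervals.get(chrom)
        positions = np.asarray(positions)
        if arr is None or not len(arr):
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(arr[:, 0], positions, side="right") - 1
        ok = idx >= 0
        res = np.zeros(len(positions), dtype=bool)
        res[ok] = positions[ok] < arr[idx[ok], 1]
        return res

    def coverage_bp(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Covered bp of each query window [start, end) (vectorised)."""
        arr = self.merged().intervals.get(chrom)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if arr is None or not len(arr):
            return np.zeros(len(starts), dtype=np.int64)
        # prefix coverage up to each interval start
        lengths = arr[:, 1] - arr[:, 0]
        prefix = np.concatenate([[0], np.cumsum(lengths)])

        def cov_upto(x):
            i = np.searchsorted(arr[:, 0], x, side="right")
            base = prefix[i]
            j = i - 1
            inside = (j >= 0) & (x < arr[np.maximum(j, 0), 1])
            adj = np.where(inside, arr[np.maximum(j, 0), 1] - x, 0)
            return base - adj

        return cov_upto(ends) - cov_upto(starts)


def intersect_tracks(a: IntervalTrack, b: IntervalTrack, name: str | None = None) -> IntervalTrack:
    """Half-open intersection of two interval tracks (sorted, merged)."""
    am, bm = a.merged(), b.merged()
    out: dict[str, np.ndarray] = {}
    for chrom in set(am.intervals) | set(bm.intervals):
        ia = am.intervals.get(chrom, np.empty((0, 2), np.int64))
        ib = bm.intervals.get(chrom, np.empty((0, 2), np.int64))
        res = []
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i, 0], ib[j, 0])
            e = min(ia[i, 1], ib[j, 1])
            if s < e:
                res.append((s, e))
            if ia[i, 1] <= ib[j, 1]:
                i += 1
            else:
                j += 1
        out[chrom] = np.asarray(res, dtype=np.int64).reshape(-1, 2)
    return IntervalTrack(name or f"{a.name}&{b.name}", out)


class DensityTrack:
    """Fixed-step numeric values per chromosome (step bp, origin 0)."""

    def __init__(self, name: str, step: int, values: dict[str, np.ndarray]):
        if step <= 0:
            raise ValueError("step must be positive")
        self.name = name
        self.step = int(step)
        self.values: dict[str, np.ndarray] = {}
        self._cum: dict[str, np.ndarray] = {}
        for chrom, vals in values.items():
            vals = np.asarray(vals, dtype=float)
            if not np.isfinite(vals).all():
                raise ValueError(f"{name}/{chrom}: non-finite density values")
            self.values[chrom] = vals

    def _cumulative(self, chrom: str) -> np.ndarray:
        if chrom not in self._cum:
            self._cum[chrom] = np.concatenate([[0.0], np.cumsum(self.values[chrom])])
        return self._cum[chrom]

    def integral(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Integral of the step function over [0, x) in value*bp, vectorised."""
        vals = self.values.get(chrom)
        if vals is None:
            return np.zeros(np.shape(x), dtype=float)
        x = np.clip(np.asarray(x, dtype=np.int64), 0, len(vals) * self.step)
        cum = self._cumulative(chrom)
        full = x // self.step
        rem = x - full * self.step
        return cum[full] * self.step + rem * vals[np.minimum(full, len(vals) - 1)]

    def window_mean(self, chrom: str, starts, ends) -> np.ndarray:
        """Mean density over each [start, end) window (0 beyond the track)."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        width = np.maximum(ends - starts, 1)
        return (self.integral(chrom, ends) - self.integral(chrom, starts)) / width


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def load_interval_track(path, name: str | None = None) -> IntervalTrack:
    """Read BED3/BED6 into a sorted, validated :class:`IntervalTrack`."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            score = float(parts[4]) if len(parts) >= 5 and parts[4] != "." else np.nan
            rows.append((chrom, start, end, score))
    intervals: dict[str, list] = {}
    scores: dict[str, list] = {}
    for chrom, s, e, sc in rows:
        intervals.setdefault(chrom, []).append((s, e))
        scores.setdefault(chrom, []).append(sc)
    return IntervalTrack(
        name or str(path),
        {c: np.asarray(v, np.int64) for c, v in intervals.items()},
        {c: np.asarray(v, float) for c, v in scores.items()},
    )


def write_interval_track(track: IntervalTrack, path, scores: bool = False) -> None:
    with open(path, "w") as fh:
        for chrom, arr in track.intervals.items():
            sc = track.scores.get(chrom)
            for i, (s, e) in enumerate(arr):
                if scores and sc is not None and np.isfinite(sc[i]):
                    fh.write(f"{chrom}\t{s}\t{e}\t.\t{sc[i]:g}\n")
                else:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def load_density_track(
    path, step: int = 25, genome: GenomeIndex | None = None, name: str | None = None
) -> DensityTrack:
    """Read a bedGraph or fixed-step wiggle file into a fixed-step track.

    bedGraph intervals are averaged into ``step``-bp cells; gaps read as 0.
    Overlapping bedGraph intervals are ambiguous and rejected.  For wiggle
    input the declared step is used directly.
    """
    with open(path) as fh:
        first = ""
        for first in fh:
            if first.strip() and not first.startswith(("#", "track", "browser")):
                break
    if first.startswith("fixedStep"):
        return _load_fixed_step_wig(path, genome=genome, name=name or str(path))
    return _load_bedgraph(path, step=step, genome=genome, name=name or str(path))


def _chrom_sizes(
    genome: GenomeIndex | None, seen: dict[str, int]
) -> dict[str, int]:
    if genome is not None:
        return {c: genome.length(c) for c in seen}
    return seen


def _load_bedgraph(path, step, genome, name) -> DensityTrack:
    rows: dict[str, list] = {}
    maxend: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns")
            chrom, s, e = parts[0], int(parts[1]), int(parts[2])
            if s >= e:
                raise ValueError(f"{path}:{lineno}: start >= end")
            try:
                v = float(parts[3])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric bedGraph value {parts[3]!r}"
                ) from None
            rows.setdefault(chrom, []).append((s, e, v))
            maxend[chrom] = max(maxend.get(chrom, 0), e)
    sizes = _chrom_sizes(genome, maxend)
    values: dict[str, np.ndarray] = {}
    for chrom, ivals in rows.items():
        ivals.sort()
        last = -1
        for s, e, _ in ivals:
            if s < last:
                raise ValueError(f"{path}: overlapping bedGraph intervals on {chrom}")
            last = e
        n = -(-sizes[chrom] // step)
        acc = np.zeros(n, dtype=float)
        for s, e, v in ivals:
            e = min(e, sizes[chrom])
            c0, c1 = s // step, -(-e // step)
            for c in range(c0, c1):
                lo, hi = max(s, c * step), min(e, (c + 1) * step)
                acc[c] += v * (hi - lo)
        cell = np.full(n, step, dtype=float)
        cell[-1] = sizes[chrom] - (n - 1) * step
        values[chrom] = acc / cell
    return DensityTrack(name, step, values)


def _load_fixed_step_wig(path, genome, name) -> DensityTrack:
    values: dict[str, np.ndarray] = {}
    chrom, start, step, buf = None, 0, None, []

    def flush():
        if chrom is None or not buf:
            return
        offset_cells = start // step
        arr = values.get(chrom, np.zeros(0))
        need = offset_cells + len(buf)
        if len(arr) < need:
            arr = np.concatenate([arr, np.zeros(need - len(arr))])
        arr[offset_cells : offset_cells + len(buf)] = buf
        values[chrom] = arr

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                flush()
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                start = int(fields["start"]) - 1  # wiggle declares 1-based starts
                this_step = int(fields.get("step", 1))
                if step is not None and this_step != step:
                    raise ValueError(f"{path}: mixed step sizes in fixed-step wig")
                step = this_step
                if start % step:
                    raise ValueError(
                        f"{path}:{lineno}: fixedStep start not aligned to step"
                    )
                buf = []
            else:
                try:
                    buf.append(float(line))
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric wig value {line!r}"
                    ) from None
    flush()
    if step is None:
        raise ValueError(f"{path}: no fixedStep declaration found")
    return DensityTrack(name, step, values)


# -- gene models ------------------------------------------------------------

def read_gene_models(
    path, expression_path=None, fmt: str | None = None
) -> list[GeneModel]:
    """Read gene models from BED12 or GTF (converted to 0-based half-open).

    ``expression_path`` is a two-column TSV (gene_id, expression); genes
    absent from it keep expression 0.
    """
    fmt = fmt or ("gtf" if str(path).endswith((".gtf", ".gff")) else "bed12")
    genes = _read_gtf(path) if fmt == "gtf" else _read_bed12(path)
    if expression_path is not None:
        expr = read_expression_table(expression_path)
        for g in genes:
            g.expression = expr.get(g.gene_id, 0.0)
    return genes


def read_expression_table(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expression table needs (gene_id, expression)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def _read_bed12(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            p = line.split()
            if len(p) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 columns")
            chrom, start, name, strand = p[0], int(p[1]), p[3], p[5]
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            offsets = [int(x) for x in p[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=int(p[2]),
                    exons=exons,
                )
            )
    return genes


def _read_gtf(path) -> list[GeneModel]:
    by_gene: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) < 9:
                continue
            chrom, _, feature, start, end, _, strand = p[0], p[1], p[2], p[3], p[4], p[5], p[6]
            attrs = {}
            for item in p[8].strip().split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                attrs[key] = val.strip('"')
            gid = attrs.get("gene_id", "")
            rec = by_gene.setdefault(
                gid, {"chrom": chrom, "strand": strand, "exons": [], "span": None}
            )
            iv = (int(start) - 1, int(end))  # GTF is 1-based closed
            if feature == "exon":
                rec["exons"].append(iv)
            elif feature in ("transcript", "gene"):
                rec["span"] = iv
    genes = []
    for gid, rec in by_gene.items():
        exons = sorted(rec["exons"])
        span = rec["span"] or (
            min(s for s, _ in exons),
            max(e for _, e in exons),
        )
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                tx_start=span[0],
                tx_end=span[1],
                exons=exons,
            )
        )
    return genes


def write_gene_bed12(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.tx_start) for s, e in g.exons)
            fh.write(
                f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.tx_start}\t{g.tx_end}\t0\t{len(g.exons)}\t{sizes},\t{offsets},\n"
            )


def write_expression_table(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\texpression\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.expression:g}\n")
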