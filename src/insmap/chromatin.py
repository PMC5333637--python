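"""Feature-centric chromatin-context analyses.

Control-subtracted ChIP density meta-profiles around insertion sites,
region-overlap enrichment with binomial significance, bivalent-region
construction (H3K4me3 x H3K27me3 intersection), signed peak-distance
histograms, binary overlap rasters, and frequently-inserted gene sets for
GSEA export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .controls import ControlCollection
from .sites import InsertionSet
from .stats import TestResult, attach_fdr, binomial_enrichment_test
from .tracks import DensityTrack, GeneModel, IntervalTrack, intersect_tracks

__all__ = [
    "ProfileResult",
    "EnrichmentResult",
    "RasterMatrix",
    "density_profile",
    "region_overlap_enrichment",
    "enrichment_table",
    "bivalent_regions",
    "peak_relative_distances",
    "overlap_raster",
    "frequent_insertion_gene_sets",
    "write_gmt",
]


# ---------------------------------------------------------------------------
# Density meta-profiles
# ---------------------------------------------------------------------------

@dataclass
class ProfileResult:
    half: int
    bin: int
    offsets: np.ndarray  # bin start offsets relative to the site
    observed: np.ndarray  # mean density per bin over sites
    control: np.ndarray | None
    difference: np.ndarray | None
    observed_denominators: np.ndarray = field(default=None)

    @property
    def n_bins(self) -> int:
        return len(self.offsets)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"offset": self.offsets, "observed": self.observed})
        if self.control is not None:
            df["control"] = self.control
            df["difference"] = self.difference
        return df


def _mean_profile(
    positions_by_chrom: dict[str, np.ndarray],
    track: DensityTrack,
    lengths: dict[str, int],
    half: int,
    bin: int,
):
    n_bins = 2 * half // bin
    total = np.zeros(n_bins)
    denom = np.zeros(n_bins)
    rel_edges = np.arange(n_bins + 1) * bin - half
    for chrom, pos in positions_by_chrom.items():
        if not len(pos):
            continue
        edges = pos[:, None] + rel_edges[None, :]
        ints = track.integral(chrom, np.clip(edges, 0, None))
        vals = np.diff(ints, axis=1) / bin
        L = lengths.get(chrom)
        in_bounds = (edges[:, :-1] >= 0) & (edges[:, 1:] <= (L if L else edges.max()))
        total += np.where(in_bounds, vals, 0.0).sum(axis=0)
        denom += in_bounds.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = total / denom
    return mean, denom


def density_profile(
    sites: InsertionSet,
    track: DensityTrack,
    controls: ControlCollection | None = None,
    half: int = 5_000,
    bin: int = 25,
    genome=None,
) -> ProfileResult:
    """Mean ChIP density per ``bin``-bp cell across +/- ``half`` bp of the
    insertion sites (400 cells at the defaults), with the pooled-control
    mean subtracted.  Sites within ``half`` of a chromosome end
    contribute only their in-bounds bins; per-bin denominators are kept.
    """
    if len(sites) == 0:
        raise ValueError("empty insertion set")
    if (2 * half) % bin:
        raise ValueError("bin size must divide the window")
    lengths = (
        {name: length for name, length in genome.chromosomes}
        if genome is not None
        else {c: len(v) * track.step for c, v in track.values.items()}
    )
    observed, denom = _mean_profile(
        sites.positions_by_chrom(), track, lengths, half, bin
    )
    control = difference = None
    if controls is not None:
        control, _ = _mean_profile(
            controls.pooled_positions(), track, lengths, half, bin
        )
        difference = observed - control
    offsets = np.arange(2 * half // bin) * bin - half
    return ProfileResult(half, bin, offsets, observed, control, difference, denom)


# ---------------------------------------------------------------------------
# Region-overlap enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    feature: str
    k: int
    n: int
    control_k: int
    control_n: int
    flank: int
    ratio: float
    test: TestResult

    @property
    def observed_rate(self) -> float:
        return self.k / self.n if self.n else float("nan")

    @property
    def control_rate(self) -> float:
        return self.control_k / self.control_n if self.control_n else float("nan")


def _count_in_regions(
    positions_by_chrom: dict[str, np.ndarray], regions: IntervalTrack, flank: int
):
    merged = regions.merged(flank)
    k = 0
    n = 0
    for chrom, pos in positions_by_chrom.items():
        n += len(pos)
        k += int(merged.contains(chrom, pos).sum())
    return k, n


def region_overlap_enrichment(
    sites: InsertionSet,
    regions: IntervalTrack,
    controls: ControlCollection,
    flank: int = 0,
    name: str | None = None,
) -> EnrichmentResult:
    """Fraction of sites inside the (flank-expanded) regions versus the
    pooled control rate, with an exact binomial p.  A site counts by its
    single insertion coordinate, not its fragment."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if len(regions) == 0:
        raise ValueError("regions track is empty")
    k, n = _count_in_regions(sites.positions_by_chrom(), regions, flank)
    ck, cn = _count_in_regions(controls.pooled_positions(), regions, flank)
    test = binomial_enrichment_test(
        k, n, ck, max(cn, 1), name=name or regions.name
    )
    ratio = (k / n) / (ck / cn) if cn and ck else float("nan")
    return EnrichmentResult(
        name or regions.name, k, n, ck, cn, flank, ratio, test
    )


def enrichment_table(
    sites: InsertionSet,
    feature_tracks: dict[str, IntervalTrack],
    controls: ControlCollection,
    flank: int = 0,
) -> pd.DataFrame:
    """Batch enrichment over several feature tracks, BH-corrected together."""
    results = [
        region_overlap_enrichment(sites, track, controls, flank=flank, name=name)
        for name, track in feature_tracks.items()
    ]
    attach_fdr([r.test for r in results])
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "observed_k": [r.k for r in results],
            "observed_n": [r.n for r in results],
            "observed_rate": [r.observed_rate for r in results],
            "control_rate": [r.control_rate for r in results],
            "ratio": [r.ratio for r in results],
            "p": [r.test.p for r in results],
            "q": [r.test.q for r in results],
        }
    )


def bivalent_regions(
    h3k4me3: IntervalTrack, h3k27me3: IntervalTrack
) -> IntervalTrack:
    """Regions carrying both marks: sorted, merged half-open intersection."""
    return intersect_tracks(h3k4me3, h3k27me3, name="bivalent")


# ---------------------------------------------------------------------------
# Peak-relative distances
# ---------------------------------------------------------------------------

def _signed_peak_distances(
    positions_by_chrom: dict[str, np.ndarray], peaks: IntervalTrack, half: int
) -> np.ndarray:
    """Signed bp from each site to the nearest edge of the nearest peak;
    0 inside a peak, positive when the peak lies 3' (right) of the site,
    negative when it lies 5' (left).  Sites with no peak within
    +/- ``half`` are excluded."""
    merged = peaks.merged()
    out = []
    for chrom, pos in positions_by_chrom.items():
        arr = merged.intervals.get(chrom)
        if arr is None or not len(arr) or not len(pos):
            continue
        starts, ends = arr[:, 0], arr[:, 1]
        idx = np.searchsorted(starts, pos, side="right") - 1
        prev_ok = idx >= 0
        inside = prev_ok & (pos < ends[np.maximum(idx, 0)])
        far = np.int64(1) << 62  # finite sentinel (|.| stays positive)
        # distance to previous peak (peak left of site -> negative)
        d_prev = np.where(prev_ok, (ends[np.maximum(idx, 0)] - 1) - pos, -far)
        nxt = idx + 1
        nxt_ok = nxt < len(starts)
        d_next = np.where(nxt_ok, starts[np.minimum(nxt, len(starts) - 1)] - pos, far)
        pick_next = np.abs(d_next) < np.abs(d_prev)
        d = np.where(inside, 0, np.where(pick_next, d_next, d_prev)).astype(float)
        d = d[np.abs(d) <= half]
        out.append(d)
    return np.concatenate(out) if out else np.empty(0)


def peak_relative_distances(
    sites: InsertionSet,
    peaks: IntervalTrack,
    half: int = 5_000,
    bin: int = 100,
    controls: ControlCollection | None = None,
) -> pd.DataFrame:
    """Histogram of signed distances from sites to the nearest peak edge
    within +/- ``half`` bp (``bin``-bp cells), for observed and pooled
    control sites."""
    edges = np.arange(-half, half + bin, bin, dtype=float)
    obs_d = _signed_peak_distances(sites.positions_by_chrom(), peaks, half)
    obs_counts, _ = np.histogram(obs_d, bins=edges)
    df = pd.DataFrame(
        {
            "bin_start": edges[:-1].astype(int),
            "observed_count": obs_counts,
            "observed_freq": obs_counts / max(len(sites), 1),
        }
    )
    if controls is not None:
        ctrl_d = _signed_peak_distances(controls.pooled_positions(), peaks, half)
        ctrl_counts, _ = np.histogram(ctrl_d, bins=edges)
        df["control_count"] = ctrl_counts
        df["control_freq"] = ctrl_counts / max(controls.n_pooled, 1)
    return df


# ---------------------------------------------------------------------------
# Overlap rasters
# ---------------------------------------------------------------------------

@dataclass
class RasterMatrix:
    factor: str
    matrix: np.ndarray  # (n_sites, n_bins) binary
    row_sites: np.ndarray  # original site indices, sorted by the sort key
    sort_widths: np.ndarray  # sort-factor peak bp within the window, per row

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix.astype(int))
        df.insert(0, "site", self.row_sites)
        return df


def overlap_raster(
    sites: InsertionSet,
    factor_tracks,
    sort_factor: str,
    half: int = 5_000,
    bin: int = 25,
) -> dict[str, RasterMatrix]:
    """Binary site-by-bin overlap matrices, one per factor: a cell is 1
    iff the bin interval intersects any peak of that factor.  Rows are
    ordered by the total ``sort_factor`` peak width within +/- ``half``
    of the site, descending."""
    if isinstance(factor_tracks, dict):
        tracks = factor_tracks
    else:
        tracks = {}
        for t in factor_tracks:
            if t.name in tracks:
                raise ValueError(f"duplicate track name {t.name!r}")
            tracks[t.name] = t
    if sort_factor not in tracks:
        raise ValueError(f"sort factor {sort_factor!r} not among the tracks")

    chroms = sites.df["chrom"].to_numpy()
    pos = sites.df["position"].to_numpy()
    n_bins = 2 * half // bin
    rel = np.arange(n_bins + 1) * bin - half

    widths = np.zeros(len(sites))
    sorter = tracks[sort_factor].merged()
    for chrom in np.unique(chroms):
        m = chroms == chrom
        widths[m] = sorter.coverage_bp(chrom, pos[m] - half, pos[m] + half)
    row_order = np.argsort(-widths, kind="stable")

    out: dict[str, RasterMatrix] = {}
    for name, track in tracks.items():
        merged = track.merged()
        mat = np.zeros((len(sites), n_bins), dtype=np.uint8)
        for chrom in np.unique(chroms):
            m = np.flatnonzero(chroms == chrom)
            arr = merged.intervals.get(chrom)
            if arr is None or not len(arr):
                continue
            starts, ends = arr[:, 0], arr[:, 1]
            x0 = pos[m][:, None] + rel[None, :-1]
            x1 = x0 + bin
            idx = np.searchsorted(starts, x1, side="left")
            hit = (idx > 0) & (ends[np.maximum(idx - 1, 0)] > x0)
            mat[m] = hit
        out[name] = RasterMatrix(
            factor=name,
            matrix=mat[row_order],
            row_sites=row_order,
            sort_widths=widths[row_order],
        )
    return out


# ---------------------------------------------------------------------------
# Frequent-insertion gene sets
# ---------------------------------------------------------------------------

def frequent_insertion_gene_sets(
    sites: InsertionSet,
    genes: list[GeneModel],
    flank: int = 50_000,
    thresholds=(3, 4, 5),
    label: str | None = None,
) -> dict[str, list[str]]:
    """Genes with >= t insertions within the flank-expanded gene body,
    for each threshold t.  The sets are nested by construction."""
    by_chrom = sites.positions_by_chrom()
    counts = {}
    for g in genes:
        pos = by_chrom.get(g.chrom, np.empty(0, np.int64))
        counts[g.gene_id] = int(
            np.searchsorted(pos, g.tx_end + flank, side="left")
            - np.searchsorted(pos, g.tx_start - flank, side="left")
        )
    prefix = label or sites.vector or "insertions"
    return {
        f"{prefix}_ge{t}_inserts": sorted(
            gid for gid, c in counts.items() if c >= t
        )
        for t in thresholds
    }


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, description or name, *members]) + "\n")
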