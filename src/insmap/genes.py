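"""Insertion statistics relative to gene models.

In-gene fractions against matched controls, insertion frequency by gene
expression rank, and transcription-start-site (TSS)-relative
distributions in two flavours: gene-size-scaled coordinates and a fixed
+/- 5-kb window in 100-bp bins.  Signed distances are oriented by gene
strand (negative = upstream of the TSS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .controls import ControlCollection
from .sites import InsertionSet
from .stats import TestResult, binomial_enrichment_test
from .tracks import GeneModel, IntervalTrack

__all__ = [
    "ExpressionBins",
    "TssProfile",
    "make_expression_bins",
    "in_gene_fraction_ratio",
    "expression_rank_profile",
    "tss_scaled_distribution",
    "tss_window_distribution",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Expression bins
# ---------------------------------------------------------------------------

@dataclass
class ExpressionBins:
    n_bins: int
    assignment: dict[str, int]  # gene_id -> bin (0 = top expression)
    bin_genes: list[list[str]]


def make_expression_bins(genes: list[GeneModel], n_bins: int = 8) -> ExpressionBins:
    """Sort genes by expression (descending) and split into equal-sized
    bins; bin 0 holds the top-expressed genes.  Ties break by gene id."""
    ranked = sorted(genes, key=lambda g: (-g.expression, g.gene_id))
    chunks = np.array_split(np.arange(len(ranked)), n_bins)
    assignment: dict[str, int] = {}
    bin_genes: list[list[str]] = []
    for b, chunk in enumerate(chunks):
        ids = [ranked[i].gene_id for i in chunk]
        bin_genes.append(ids)
        for gid in ids:
            assignment[gid] = b
    return ExpressionBins(n_bins, assignment, bin_genes)


# ---------------------------------------------------------------------------
# In-gene fraction
# ---------------------------------------------------------------------------

def gene_body_track(genes: list[GeneModel], flank: int = 0) -> IntervalTrack:
    intervals: dict[str, list] = {}
    for g in genes:
        intervals.setdefault(g.chrom, []).append((g.tx_start, g.tx_end))
    return IntervalTrack(
        "gene_bodies", {c: np.asarray(v, np.int64) for c, v in intervals.items()}
    ).merged(flank)


@dataclass
class InGeneResult:
    ratio: float
    observed_fraction: float
    control_fraction: float
    test: TestResult
    flags: list[str] = field(default_factory=list)


def in_gene_fraction_ratio(
    sites: InsertionSet, genes: list[GeneModel], controls: ControlCollection
) -> InGeneResult:
    """Observed in-gene rate over the pooled-control in-gene rate, with an
    exact binomial p against the control-estimated success probability.
    In-gene means position within [txStart, txEnd) of any gene."""
    bodies = gene_body_track(genes)
    k = 0
    for chrom, sub in sites.df.groupby("chrom", sort=False):
        k += int(bodies.contains(chrom, sub["position"].to_numpy()).sum())
    n = len(sites)
    ck = 0
    cn = 0
    for chrom, pos in controls.pooled_positions().items():
        ck += int(bodies.contains(chrom, pos).sum())
        cn += len(pos)
    flags: list[str] = []
    if cn == 0 or ck == 0:
        flags.append("undefined_ratio")
        ratio = float("nan")
    else:
        ratio = (k / n) / (ck / cn)
    test = binomial_enrichment_test(k, n, ck, max(cn, 1), name="in_gene_fraction")
    return InGeneResult(ratio, k / n if n else float("nan"), ck / cn if cn else float("nan"), test, flags)


# ---------------------------------------------------------------------------
# Expression-rank profile
# ---------------------------------------------------------------------------

def _per_gene_counts(
    genes: list[GeneModel],
    positions_by_chrom: dict[str, np.ndarray],
    flank: int,
    inside: bool,
) -> np.ndarray:
    """Insertion-gene pair counts: sites within the gene body (inside) or
    within the flank-expanded body (near), counted once per gene hit."""
    counts = np.zeros(len(genes), dtype=np.int64)
    for gi, g in enumerate(genes):
        pos = positions_by_chrom.get(g.chrom)
        if pos is None or not len(pos):
            continue
        lo = g.tx_start if inside else g.tx_start - flank
        hi = g.tx_end if inside else g.tx_end + flank
        counts[gi] = np.searchsorted(pos, hi, side="left") - np.searchsorted(
            pos, lo, side="left"
        )
    return counts


def expression_rank_profile(
    sites: InsertionSet,
    genes: list[GeneModel],
    expression: dict[str, float] | None = None,
    flank: int = 50_000,
    n_bins: int = 8,
    controls: ControlCollection | None = None,
    scope: str = "near",
) -> pd.DataFrame:
    """Insertion frequency per expression-rank bin, as observed/control
    ratio.

    An insertion within ``flank`` of ``k`` genes contributes one count to
    each gene's bin (pair-based totals); ``scope="inside"`` restricts to
    insertions within gene bodies.  Genes without an expression value are
    excluded (logged).
    """
    if scope not in ("near", "inside"):
        raise ValueError("scope must be 'near' or 'inside'")
    if expression is not None:
        known = [g for g in genes if g.gene_id in expression]
        skipped = len(genes) - len(known)
        if skipped:
            log.info(
                "expression_rank_profile: %d gene(s) without expression excluded",
                skipped,
            )
        genes = [
            GeneModel(
                g.gene_id, g.chrom, g.strand, g.tx_start, g.tx_end, list(g.exons),
                expression[g.gene_id],
            )
            for g in known
        ]
    bins = make_expression_bins(genes, n_bins)
    inside = scope == "inside"
    obs_counts = _per_gene_counts(genes, sites.positions_by_chrom(), flank, inside)
    gene_bin = np.array([bins.assignment[g.gene_id] for g in genes])
    obs_bin = np.bincount(gene_bin, weights=obs_counts, minlength=n_bins)
    obs_freq = obs_bin / obs_bin.sum() if obs_bin.sum() else np.full(n_bins, np.nan)
    out = pd.DataFrame(
        {
            "bin": np.arange(1, n_bins + 1),  # bin 1 = top expression
            "observed_freq": obs_freq,
        }
    )
    if controls is not None:
        ctrl_counts = _per_gene_counts(
            genes, controls.pooled_positions(), flank, inside
        )
        ctrl_bin = np.bincount(gene_bin, weights=ctrl_counts, minlength=n_bins)
        ctrl_freq = (
            ctrl_bin / ctrl_bin.sum() if ctrl_bin.sum() else np.full(n_bins, np.nan)
        )
        out["control_freq"] = ctrl_freq
        with np.errstate(divide="ignore", invalid="ignore"):
            out["ratio"] = obs_freq / ctrl_freq
    return out


# ---------------------------------------------------------------------------
# TSS-relative distributions
# ---------------------------------------------------------------------------

class _TssIndex:
    """Per-chromosome unique TSS coordinates with one representative gene
    each.  Equidistant-TSS ties break toward the higher-expressed gene,
    then lexicographic gene id -- applied both when several genes share a
    TSS coordinate and when a site sits exactly between two TSSs."""

    def __init__(self, genes: list[GeneModel]):
        per_chrom: dict[str, dict[int, GeneModel]] = {}
        for g in genes:
            best = per_chrom.setdefault(g.chrom, {})
            cur = best.get(g.tss)
            if (
                cur is None
                or g.expression > cur.expression
                or (g.expression == cur.expression and g.gene_id < cur.gene_id)
            ):
                best[g.tss] = g
        self.coords: dict[str, np.ndarray] = {}
        self.expr: dict[str, np.ndarray] = {}
        self.ids: dict[str, np.ndarray] = {}
        self.strand_plus: dict[str, np.ndarray] = {}
        self.size: dict[str, np.ndarray] = {}
        for chrom, best in per_chrom.items():
            items = sorted(best.items())
            self.coords[chrom] = np.array([t for t, _ in items], dtype=np.int64)
            self.expr[chrom] = np.array([g.expression for _, g in items])
            self.ids[chrom] = np.array([g.gene_id for _, g in items])
            self.strand_plus[chrom] = np.array(
                [g.strand == "+" for _, g in items], dtype=bool
            )
            self.size[chrom] = np.array([g.size for _, g in items], dtype=np.int64)

    def nearest(self, chrom: str, positions: np.ndarray):
        """Index of the nearest TSS per position (ties resolved), or -1 if
        the chromosome has no TSS."""
        coords = self.coords.get(chrom)
        positions = np.asarray(positions, dtype=np.int64)
        if coords is None or not len(coords):
            return np.full(len(positions), -1, dtype=np.int64)
        right = np.searchsorted(coords, positions, side="left")
        left = right - 1
        has_l, has_r = left >= 0, right < len(coords)
        dl = np.where(has_l, positions - coords[np.maximum(left, 0)], np.iinfo(np.int64).max)
        dr = np.where(
            has_r, coords[np.minimum(right, len(coords) - 1)] - positions,
            np.iinfo(np.int64).max,
        )
        pick_left = dl < dr
        tie = dl == dr
        if tie.any():
            el = self.expr[chrom][np.maximum(left, 0)]
            er = self.expr[chrom][np.minimum(right, len(coords) - 1)]
            il = self.ids[chrom][np.maximum(left, 0)]
            ir = self.ids[chrom][np.minimum(right, len(coords) - 1)]
            pick_left = np.where(
                tie, (el > er) | ((el == er) & (il <= ir)), pick_left
            )
        return np.where(pick_left, left, right)


@dataclass
class TssProfile:
    mode: str  # "scaled" or "window"
    bin_edges: np.ndarray
    observed: np.ndarray  # per-bin frequency (counts / total sites)
    control: np.ndarray | None
    difference: np.ndarray | None
    n_sites: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "observed": self.observed,
            }
        )
        if self.control is not None:
            df["control"] = self.control
            df["difference"] = self.difference
        return df


def _signed_tss_positions(
    index: _TssIndex, positions_by_chrom: dict[str, np.ndarray], scaled: bool
):
    """Signed (optionally gene-size-scaled) distance to the nearest TSS
    for every site; upstream of the TSS is negative."""
    out = []
    for chrom, pos in positions_by_chrom.items():
        if not len(pos):
            continue
        idx = index.nearest(chrom, pos)
        ok = idx >= 0
        if not ok.any():
            continue
        idx = idx[ok]
        pos_ok = pos[ok]
        raw = pos_ok - index.coords[chrom][idx]
        signed = np.where(index.strand_plus[chrom][idx], raw, -raw).astype(float)
        if scaled:
            signed = signed / index.size[chrom][idx]
        out.append(signed)
    return np.concatenate(out) if out else np.empty(0)


def _profile(
    sites: InsertionSet,
    genes: list[GeneModel],
    controls: ControlCollection | None,
    edges: np.ndarray,
    scaled: bool,
    mode: str,
) -> TssProfile:
    index = _TssIndex(genes)

    def hist(d):
        # keep every bin half-open: values on the last edge fall outside
        d = d[(d >= edges[0]) & (d < edges[-1])]
        counts, _ = np.histogram(d, bins=edges)
        return counts

    obs_d = _signed_tss_positions(index, sites.positions_by_chrom(), scaled)
    n = len(sites)
    obs_counts = hist(obs_d)
    observed = obs_counts / n if n else np.full(len(edges) - 1, np.nan)
    control = difference = None
    if controls is not None:
        ctrl_d = _signed_tss_positions(index, controls.pooled_positions(), scaled)
        cn = controls.n_pooled
        ctrl_counts = hist(ctrl_d)
        control = ctrl_counts / cn if cn else np.full(len(edges) - 1, np.nan)
        difference = observed - control
    return TssProfile(mode, edges, observed, control, difference, n)


def tss_scaled_distribution(
    sites: InsertionSet,
    genes: list[GeneModel],
    bin_width: float = 0.25,
    value_range: tuple[float, float] = (-1.0, 2.0),
    controls: ControlCollection | None = None,
) -> TssProfile:
    """Histogram of (signed distance to nearest TSS) / (gene size):
    0 = TSS, 1 = transcription end of a unit-length gene.  Control-mean
    frequency subtracted per bin when controls are given."""
    lo, hi = value_range
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    return _profile(sites, genes, controls, edges, scaled=True, mode="scaled")


def tss_window_distribution(
    sites: InsertionSet,
    genes: list[GeneModel],
    half: int = 5_000,
    bin: int = 100,
    controls: ControlCollection | None = None,
) -> TssProfile:
    """Insertion frequency in fixed bins across +/- ``half`` bp of the
    nearest TSS (default 100 bins of 100 bp); counts divided by the total
    number of sites, control series subtracted."""
    if half % bin:
        raise ValueError("bin size must divide the half-window")
    edges = np.arange(-half, half + bin, bin, dtype=float)
    return _profile(sites, genes, controls, edges, scaled=False, mode="window")
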