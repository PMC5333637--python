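"""Size-adjusted in-silico control insertion sites.

For every observed insertion a matched pseudo-insertion is drawn under the
same detectability constraints that shaped the real library:

* restriction mode (long-read libraries): the control sits a
  restriction-fragment away from a genuine primary-enzyme cut site, with
  fragment size within ``max_fragment_diff`` bp of the observed fragment,
  the same strand orientation, the vector's target-site motif (TTAA/TA) if
  it has one, and no secondary-enzyme cut strictly inside the fragment;
* shear mode (sonication libraries): the control is drawn uniformly from
  motif occurrences (motif vectors) or uniformly from the genome, with the
  observed fragment size copied over.

In both modes candidates must be uniquely mappable, realised as exact
k-mer uniqueness of the ``k`` bases starting at the candidate position
(forward and reverse-complement occurrences counted together).  The full
admissible candidate set for each observed site is enumerated up front,
and each of the ``n_sets`` control sets draws one candidate per site
uniformly from it, so the support of the generator is exactly the
admissible set and attrition (sites with no admissible candidate) is
deterministic and reported per set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeIndex, MotifIndex, RestrictionIndex
from .sites import InsertionSet

__all__ = [
    "ControlConstraints",
    "ControlCollection",
    "generate_flx_controls",
    "generate_shear_controls",
    "mappability_filter",
]

log = logging.getLogger(__name__)


@dataclass
class ControlConstraints:
    """Constraint bundle for restriction-mode control generation."""

    primary: RestrictionIndex
    secondary: list[RestrictionIndex] = field(default_factory=list)
    motif: MotifIndex | None = None
    max_fragment_diff: int = 20
    mappability_k: int | None = 36
    n_sets: int = 1000
    seed: int | None = None

    def __post_init__(self):
        if self.max_fragment_diff <= 0:
            raise ValueError("max_fragment_diff must be positive")
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")


class ControlCollection:
    """``n_sets`` matched control sets mirroring one observed set.

    Array-backed: ``positions[j, i]`` is the control position matched to
    observed site ``i`` in set ``j`` (invalid where ``valid`` is False,
    i.e. attrition).  Strands always equal the matched observed strands.
    """

    def __init__(
        self,
        observed: InsertionSet,
        chrom_names: list[str],
        chrom_idx: np.ndarray,
        positions: np.ndarray,
        fragments: np.ndarray,
        valid: np.ndarray,
        seed: int | None = None,
    ):
        self.observed = observed
        self.label = observed.label
        self.chrom_names = list(chrom_names)
        self.chrom_idx = chrom_idx
        self.positions = positions
        self.fragments = fragments
        self.valid = valid
        self.seed = seed
        self.strands = observed.df["strand"].to_numpy()

    @property
    def n_sets(self) -> int:
        return self.positions.shape[0]

    @property
    def n_sites(self) -> int:
        return self.positions.shape[1]

    @property
    def attrition(self) -> np.ndarray:
        """Observed sites without an admissible control, per set."""
        return (~self.valid).sum(axis=1)

    def set_arrays(self, j: int):
        """(chroms, positions, strands, fragments) of set ``j`` (valid only)."""
        mask = self.valid[j]
        chroms = np.asarray(self.chrom_names)[self.chrom_idx[j, mask]]
        return (
            chroms,
            self.positions[j, mask],
            self.strands[mask],
            self.fragments[j, mask],
        )

    def set_as_insertion_set(self, j: int) -> InsertionSet:
        chroms, pos, strands, frags = self.set_arrays(j)
        return InsertionSet.from_arrays(
            chroms,
            pos,
            strands,
            label=f"{self.label}::control_{j:04d}",
            fragment_length=frags,
            vector=self.observed.vector,
        )

    def pooled_positions(self) -> dict[str, np.ndarray]:
        """All valid control positions across sets, sorted per chromosome."""
        out = {}
        mask = self.valid.ravel()
        ci = self.chrom_idx.ravel()[mask]
        pos = self.positions.ravel()[mask]
        for k, name in enumerate(self.chrom_names):
            out[name] = np.sort(pos[ci == k])
        return out

    @property
    def n_pooled(self) -> int:
        return int(self.valid.sum())

    def subset_sets(self, n: int) -> "ControlCollection":
        """The first ``n`` sets as a lighter collection (array views)."""
        return ControlCollection(
            self.observed,
            self.chrom_names,
            self.chrom_idx[:n],
            self.positions[:n],
            self.fragments[:n],
            self.valid[:n],
            seed=self.seed,
        )

    def to_bed(self, directory) -> None:
        """One BED file per set plus a manifest TSV (set id, attrition, seed)."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for j in range(self.n_sets):
            chroms, pos, strands, _ = self.set_arrays(j)
            with open(directory / f"controls_{j + 1:04d}.bed", "w") as fh:
                for c, p, s in zip(chroms, pos, strands):
                    fh.write(f"{c}\t{p}\t{p + 1}\t.\t0\t{s}\n")
        with open(directory / "manifest.tsv", "w") as fh:
            fh.write("set\tattrition\tseed\n")
            for j, a in enumerate(self.attrition):
                fh.write(f"{j + 1}\t{a}\t{self.seed if self.seed is not None else ''}\n")


def _uniqueness_masks(
    genome: GenomeIndex, k: int | None
) -> dict[str, np.ndarray] | None:
    return None if k is None else genome.kmer_uniqueness(k)


def _count_strictly_inside(cuts: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Number of cut coordinates x with lower < x < upper, vectorised."""
    return np.searchsorted(cuts, upper, side="left") - np.searchsorted(
        cuts, lower, side="right"
    )


def enumerate_flx_candidates(
    observed: InsertionSet, genome: GenomeIndex, constraints: ControlConstraints
):
    """Exhaustive admissible candidate set for each observed site.

    Returns (chrom_names, cand_chrom, cand_pos, cand_frag, offsets): CSR
    layout, site ``i`` owns candidates ``offsets[i]:offsets[i+1]``.
    """
    frags = observed.df["fragment_length"].to_numpy()
    if not np.isfinite(frags).all():
        raise ValueError("restriction-mode controls require fragment_length on every site")
    strands = observed.df["strand"].to_numpy()
    if constraints.primary.count() == 0:
        raise ValueError("primary-enzyme index is empty")
    if constraints.motif is not None and constraints.motif.count() == 0:
        raise ValueError(
            f"motif {constraints.motif.motif!r} has zero occurrences genome-wide"
        )
    unique = _uniqueness_masks(genome, constraints.mappability_k)
    d = constraints.max_fragment_diff

    chrom_names = genome.names
    per_chrom = []
    for name in chrom_names:
        cuts = constraints.primary.cuts.get(name, np.empty(0, np.int64))
        if constraints.motif is not None:
            motif_pos = constraints.motif.positions.get(name, np.empty(0, np.int64))
            if unique is not None and len(motif_pos):
                motif_pos = motif_pos[unique[name][motif_pos]]
        else:
            motif_pos = None
        secs = [
            s.cuts.get(name, np.empty(0, np.int64)) for s in constraints.secondary
        ]
        per_chrom.append((name, cuts, motif_pos, secs))

    chunks_chrom, chunks_pos, chunks_frag = [], [], []
    counts_per_site = np.zeros(len(observed), dtype=np.int64)
    for i, (f, strand) in enumerate(zip(frags, strands)):
        f = int(f)
        site_chrom, site_pos, site_frag = [], [], []
        for ci, (name, cuts, motif_pos, secs) in enumerate(per_chrom):
            if not len(cuts):
                continue
            if motif_pos is not None:
                # admissible control fragments: positive length, within d of f
                lo_frag = max(f - (d - 1), 1)
                hi_frag = f + (d - 1)
                if strand == "+":
                    lo = np.searchsorted(cuts, motif_pos + lo_frag, side="left")
                    hi = np.searchsorted(cuts, motif_pos + hi_frag, side="right")
                else:
                    lo = np.searchsorted(cuts, motif_pos - hi_frag, side="left")
                    hi = np.searchsorted(cuts, motif_pos - lo_frag, side="right")
                counts = hi - lo
                sel = counts > 0
                if not sel.any():
                    continue
                m_sel, lo_sel, cnt_sel = motif_pos[sel], lo[sel], counts[sel]
                total = int(cnt_sel.sum())
                rep = np.repeat(np.arange(len(m_sel)), cnt_sel)
                within = np.arange(total) - np.repeat(
                    np.cumsum(cnt_sel) - cnt_sel, cnt_sel
                )
                P = m_sel[rep]
                C = cuts[lo_sel[rep] + within]
            else:
                P = cuts - f if strand == "+" else cuts + f
                L = genome.length(name)
                ok = (P >= 0) & (P < L)
                if unique is not None:
                    ok[ok] = unique[name][P[ok]]
                P, C = P[ok], cuts[ok]
            lower = np.minimum(P, C)
            upper = np.maximum(P, C)
            keep = np.ones(len(P), dtype=bool)
            for sec in secs:
                if len(sec):
                    keep &= _count_strictly_inside(sec, lower, upper) == 0
            P, C = P[keep], C[keep]
            site_chrom.append(np.full(len(P), ci, dtype=np.int16))
            site_pos.append(P)
            site_frag.append(np.abs(C - P).astype(np.int32))
        if site_pos:
            chunks_chrom.append(np.concatenate(site_chrom))
            chunks_pos.append(np.concatenate(site_pos))
            chunks_frag.append(np.concatenate(site_frag))
            counts_per_site[i] = len(chunks_pos[-1])

    offsets = np.concatenate([[0], np.cumsum(counts_per_site)])
    cand_chrom = (
        np.concatenate(chunks_chrom) if chunks_chrom else np.empty(0, np.int16)
    )
    cand_pos = np.concatenate(chunks_pos) if chunks_pos else np.empty(0, np.int64)
    cand_frag = np.concatenate(chunks_frag) if chunks_frag else np.empty(0, np.int32)
    return chrom_names, cand_chrom, cand_pos, cand_frag, offsets


def _sample_from_candidates(
    observed, chrom_names, cand_chrom, cand_pos, cand_frag, offsets, n_sets, seed
) -> ControlCollection:
    n_sites = len(observed)
    counts = np.diff(offsets)
    chrom_idx = np.zeros((n_sets, n_sites), dtype=np.int16)
    positions = np.zeros((n_sets, n_sites), dtype=np.int64)
    fragments = np.zeros((n_sets, n_sites), dtype=np.float64)
    valid = np.broadcast_to(counts > 0, (n_sets, n_sites)).copy()
    children = np.random.SeedSequence(seed).spawn(n_sets)
    base = offsets[:-1]
    safe_counts = np.maximum(counts, 1)
    for j in range(n_sets):
        rng = np.random.default_rng(children[j])
        pick = base + (rng.random(n_sites) * counts).astype(np.int64) % safe_counts
        pick = np.minimum(pick, np.maximum(offsets[1:] - 1, 0))
        chrom_idx[j] = cand_chrom[pick] if len(cand_chrom) else 0
        positions[j] = cand_pos[pick] if len(cand_pos) else 0
        fragments[j] = cand_frag[pick] if len(cand_frag) else 0
    attr = int((counts == 0).sum())
    if attr:
        log.log(
            logging.WARNING if attr > 0.1 * n_sites else logging.INFO,
            "control generation: %d/%d observed site(s) have no admissible "
            "candidate (attrition)",
            attr,
            n_sites,
        )
    return ControlCollection(
        observed, chrom_names, chrom_idx, positions, fragments, valid, seed=seed
    )


def generate_flx_controls(
    observed: InsertionSet, genome: GenomeIndex, constraints: ControlConstraints
) -> ControlCollection:
    """Restriction-anchored matched controls (long-read libraries)."""
    parts = enumerate_flx_candidates(observed, genome, constraints)
    return _sample_from_candidates(
        observed, *parts, constraints.n_sets, constraints.seed
    )


def generate_shear_controls(
    observed: InsertionSet,
    genome: GenomeIndex,
    motif: MotifIndex | None = None,
    n_sets: int = 1000,
    seed: int | None = None,
    mappability_k: int | None = 36,
) -> ControlCollection:
    """Shear-mode matched controls (sonication libraries).

    Controls are drawn uniformly from motif occurrences (motif vectors) or
    uniformly from the genome, restricted to uniquely mappable positions;
    fragment sizes and strands are copied from the matched observed sites.
    """
    unique = _uniqueness_masks(genome, mappability_k)
    chrom_names = genome.names
    pools = []
    for ci, name in enumerate(chrom_names):
        if motif is not None:
            pool = motif.positions.get(name, np.empty(0, np.int64))
            if unique is not None and len(pool):
                pool = pool[unique[name][pool]]
        else:
            if unique is not None:
                pool = np.flatnonzero(unique[name]).astype(np.int64)
            else:
                pool = np.arange(genome.length(name), dtype=np.int64)
        pools.append((ci, pool))
    pool_pos = np.concatenate([p for _, p in pools])
    pool_chrom = np.concatenate(
        [np.full(len(p), ci, dtype=np.int16) for ci, p in pools]
    )
    if not len(pool_pos):
        raise ValueError("no admissible control positions genome-wide")

    n_sites = len(observed)
    frags = observed.df["fragment_length"].to_numpy()
    chrom_idx = np.zeros((n_sets, n_sites), dtype=np.int16)
    positions = np.zeros((n_sets, n_sites), dtype=np.int64)
    children = np.random.SeedSequence(seed).spawn(n_sets)
    for j in range(n_sets):
        rng = np.random.default_rng(children[j])
        pick = rng.integers(0, len(pool_pos), n_sites)
        chrom_idx[j] = pool_chrom[pick]
        positions[j] = pool_pos[pick]
    fragments = np.broadcast_to(frags, (n_sets, n_sites)).copy()
    valid = np.ones((n_sets, n_sites), dtype=bool)
    return ControlCollection(
        observed, chrom_names, chrom_idx, positions, fragments, valid, seed=seed
    )


def mappability_filter(
    candidates: InsertionSet, genome: GenomeIndex, k: int = 36
) -> InsertionSet:
    """Keep candidates whose k-mer (starting at the candidate position)
    occurs exactly once in the genome, counting both strands."""
    unique = genome.kmer_uniqueness(k)
    chroms = candidates.df["chrom"].to_numpy()
    pos = candidates.df["position"].to_numpy()
    keep = np.array([unique[c][p] for c, p in zip(chroms, pos)], dtype=bool)
    return candidates.subset(np.flatnonzero(keep))
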