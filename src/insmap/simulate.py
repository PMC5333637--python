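"""Desk-scale synthetic genomes, annotations, tracks, and insertion sets.

The generator emulates the structure of a transposon/retrovirus
insertion-profiling study: a small multi-chromosome genome with the
target-site motifs (TA, TTAA) and HaeIII (GGCC) sites implied by its base
composition, non-overlapping gene models with log-normal expression,
interval tracks (factor peaks, enhancers, super-enhancers, HMM-style
histone regions with an overlapping H3K4me3/H3K27me3 subset), and
insertion sets drawn from a four-component mixture: uniform background,
TSS-proximal bias (exponential decay), feature-targeted bias, and
hotspot clusters.  Every site carries a replicate label (transfection
batch) and a ground-truth component label for recovery tests.

Bases are i.i.d. given the GC content; that is sufficient for the
motif/restriction-site frequency properties the pipeline relies on.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeIndex, MotifIndex, RestrictionIndex, decode_sequence, scan_motif_positions, index_restriction_sites
from .sites import InsertionSet
from .tracks import DensityTrack, GeneModel, IntervalTrack

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "simulate_insertions",
    "simulate_rate_multiplier_insertions",
    "simulate_density_tracks",
    "write_dataset",
]

VECTOR_MOTIF = {"PB": "TTAA", "SB": "TA", "MLV": None, "Tol2": None}


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome
    chromosome_lengths: tuple[int, ...] = (5_000_000, 5_000_000)
    gc_content: float = 0.5
    # genes
    n_genes: int = 300
    gene_mean_length: float = 10_000.0
    gene_length_sigma: float = 0.6
    exon_mean_length: float = 250.0
    expression_sigma: float = 1.5
    # interval tracks
    n_peaks: int = 400
    peak_width: tuple[int, int] = (500, 2_000)
    n_enhancers: int = 150
    enhancer_width: tuple[int, int] = (1_000, 3_000)
    n_super_enhancers: int = 25
    super_enhancer_width: tuple[int, int] = (8_000, 15_000)
    # insertion model
    n_sites: int = 6_000
    vector: str = "PB"
    platform: str = "restriction"
    selection: str = "G418"
    n_replicates: int = 3
    w_background: float = 0.5
    w_tss: float = 0.2
    tss_decay: float = 5_000.0
    w_feature: float = 0.2
    feature_track: str = "super_enhancers"
    w_hotspot: float = 0.1
    hotspot_clusters: int = 5
    hotspot_spread: float = 10_000.0

    def __post_init__(self):
        weights = (self.w_background, self.w_tss, self.w_feature, self.w_hotspot)
        if any(w < 0 for w in weights):
            raise ValueError("mixture weights must be non-negative")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(l <= 0 for l in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        if not (0 < self.gc_content < 1):
            raise ValueError("GC content must lie in (0, 1)")

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("chromosome_lengths", "peak_width", "enhancer_width", "super_enhancer_width"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# Genome, genes, tracks
# ---------------------------------------------------------------------------

def _random_sequence(rng, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
    return decode_sequence(codes)


def _place_nonoverlapping(rng, chrom_lengths, n, width_sampler, max_tries=500):
    """Random non-overlapping intervals across chromosomes (length-weighted)."""
    lengths = np.asarray(chrom_lengths, dtype=float)
    placed: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(lengths))}
    out = []
    for _ in range(n):
        for _try in range(max_tries):
            ci = int(rng.choice(len(lengths), p=lengths / lengths.sum()))
            w = int(width_sampler(rng))
            if w >= lengths[ci]:
                raise ValueError("interval length exceeds chromosome length")
            s = int(rng.integers(0, lengths[ci] - w))
            overlap = any(not (e <= s or b >= s + w) for b, e in placed[ci])
            if not overlap:
                placed[ci].append((s, s + w))
                out.append((ci, s, s + w))
                break
        else:
            raise RuntimeError("could not place non-overlapping intervals")
    return out


def simulate_genome(config: SimulationConfig):
    """Build the synthetic study: genome, gene models, and interval tracks.

    Deterministic under ``config.seed``.  Returns
    ``(genome, genes, tracks)`` with ``tracks`` holding peaks, enhancers,
    super_enhancers, H3K4me3, and H3K27me3 interval tracks.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    sequences = {
        f"chr{i + 1}": _random_sequence(rng, L, config.gc_content)
        for i, L in enumerate(config.chromosome_lengths)
    }
    genome = GenomeIndex(sequences)
    names = genome.names

    # genes: non-overlapping bodies, log-normal lengths and expression
    def gene_width(rng):
        return max(
            1_000,
            int(
                rng.lognormal(
                    np.log(config.gene_mean_length), config.gene_length_sigma
                )
            ),
        )

    genes: list[GeneModel] = []
    if config.n_genes:
        spans = _place_nonoverlapping(
            rng, config.chromosome_lengths, config.n_genes, gene_width
        )
        for gi, (ci, s, e) in enumerate(sorted(spans)):
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            cursor = s
            while cursor < e - 100:
                ex_len = max(50, int(rng.exponential(config.exon_mean_length)))
                ex_end = min(cursor + ex_len, e)
                exons.append((cursor, ex_end))
                cursor = ex_end + int(rng.exponential((e - s) / 6)) + 50
            expression = float(rng.lognormal(2.0, config.expression_sigma))
            genes.append(
                GeneModel(
                    gene_id=f"gene{gi + 1:04d}",
                    chrom=names[ci],
                    strand=strand,
                    tx_start=s,
                    tx_end=e,
                    exons=exons,
                    expression=expression,
                )
            )

    def interval_track(name, n, width_range):
        spans = _place_nonoverlapping(
            rng,
            config.chromosome_lengths,
            n,
            lambda r: r.integers(width_range[0], width_range[1] + 1),
        )
        per_chrom: dict[str, list] = {c: [] for c in names}
        for ci, s, e in spans:
            per_chrom[names[ci]].append((s, e))
        return IntervalTrack(
            name,
            {c: np.asarray(v, np.int64).reshape(-1, 2) for c, v in per_chrom.items()},
        )

    tracks = {
        "peaks": interval_track("peaks", config.n_peaks, config.peak_width),
        "enhancers": interval_track(
            "enhancers", config.n_enhancers, config.enhancer_width
        ),
        "super_enhancers": interval_track(
            "super_enhancers", config.n_super_enhancers, config.super_enhancer_width
        ),
    }

    # HMM-style histone regions: H3K4me3 at expressed promoters, H3K27me3 at
    # silent promoters, with an overlapping (bivalent) subset.
    k4: dict[str, list] = {c: [] for c in names}
    k27: dict[str, list] = {c: [] for c in names}
    if genes:
        expr = np.array([g.expression for g in genes])
        median = np.median(expr)
        for g in genes:
            lo = max(0, g.tss - 1_000)
            hi = min(genome.length(g.chrom), g.tss + 1_000)
            if g.expression >= median:
                k4[g.chrom].append((lo, hi))
                if rng.random() < 0.2:  # bivalent promoters
                    k27[g.chrom].append((max(0, lo - 500), hi + 500))
            else:
                k27[g.chrom].append((max(0, g.tss - 2_000), g.tss + 2_000))
    tracks["H3K4me3"] = IntervalTrack(
        "H3K4me3", {c: np.asarray(v, np.int64).reshape(-1, 2) for c, v in k4.items()}
    ).merged()
    tracks["H3K27me3"] = IntervalTrack(
        "H3K27me3", {c: np.asarray(v, np.int64).reshape(-1, 2) for c, v in k27.items()}
    ).merged()
    return genome, genes, tracks


# ---------------------------------------------------------------------------
# Insertions
# ---------------------------------------------------------------------------

def _snap_to_motif(motif: MotifIndex, chrom: str, positions: np.ndarray) -> np.ndarray:
    """Move each position to its nearest motif occurrence on the chromosome."""
    occ = motif.positions.get(chrom)
    if occ is None or not len(occ):
        raise ValueError(f"no motif occurrence on {chrom}")
    idx = np.searchsorted(occ, positions)
    idx = np.clip(idx, 0, len(occ) - 1)
    left = np.clip(idx - 1, 0, len(occ) - 1)
    pick_left = np.abs(positions - occ[left]) < np.abs(occ[idx] - positions)
    return occ[np.where(pick_left, left, idx)]


def _assign_fragments(
    genome: GenomeIndex,
    chroms: np.ndarray,
    positions: np.ndarray,
    strands: np.ndarray,
    platform: str,
    cuts: RestrictionIndex,
    rng,
) -> np.ndarray:
    if platform == "shear":
        return rng.integers(300, 401, size=len(positions)).astype(float)
    frags = np.zeros(len(positions), dtype=float)
    for chrom in np.unique(chroms):
        m = np.flatnonzero(chroms == chrom)
        cc = cuts.cuts.get(chrom, np.empty(0, np.int64))
        if not len(cc):
            raise ValueError(f"no primary cut sites on {chrom}")
        pos = positions[m]
        plus = strands[m] == "+"
        nxt = np.searchsorted(cc, pos, side="right")
        prv = nxt - 1
        # walk toward the cut in the sequenced direction; flip the strand
        # where the chromosome end intervenes
        has_next = nxt < len(cc)
        has_prev = prv >= 0
        use_plus = np.where(plus & has_next, True, np.where(~plus & has_prev, False, has_next))
        d = np.where(
            use_plus,
            cc[np.minimum(nxt, len(cc) - 1)] - pos,
            pos - cc[np.maximum(prv, 0)],
        )
        strands[m] = np.where(use_plus, "+", "-")
        frags[m] = np.maximum(d, 1)
    return frags


def simulate_insertions(
    genome: GenomeIndex,
    genes: list[GeneModel],
    tracks: dict[str, IntervalTrack],
    config: SimulationConfig,
    seed: int | None = None,
):
    """Draw an insertion set from the mixture model.

    Returns ``(InsertionSet, component_labels)``; labels are per-site
    strings in {background, tss, feature, hotspot} retained for recovery
    tests.  Motif-constrained vectors (PB, SB) land exactly on motif
    occurrences.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed if seed is None else seed)
    )
    if config.w_tss > 0 and not genes:
        raise ValueError("TSS-proximal component requires gene models")
    motif_seq = VECTOR_MOTIF.get(config.vector)
    motif = scan_motif_positions(genome, motif_seq) if motif_seq else None
    names = genome.names
    lengths = np.array([genome.length(c) for c in names], dtype=float)

    n = config.n_sites
    comp = rng.choice(
        4,
        size=n,
        p=[config.w_background, config.w_tss, config.w_feature, config.w_hotspot],
    )
    chroms = np.empty(n, dtype=object)
    positions = np.empty(n, dtype=np.int64)

    # background: uniform over the genome (or over motif occurrences)
    bg = np.flatnonzero(comp == 0)
    if len(bg):
        if motif is not None:
            pool_chrom = np.concatenate(
                [np.full(len(motif.positions[c]), i) for i, c in enumerate(names)]
            )
            pool_pos = np.concatenate([motif.positions[c] for c in names])
            pick = rng.integers(0, len(pool_pos), len(bg))
            chroms[bg] = np.asarray(names)[pool_chrom[pick]]
            positions[bg] = pool_pos[pick]
        else:
            ci = rng.choice(len(names), size=len(bg), p=lengths / lengths.sum())
            chroms[bg] = np.asarray(names)[ci]
            positions[bg] = (rng.random(len(bg)) * lengths[ci]).astype(np.int64)

    # TSS-proximal: random gene, signed exponential offset from its TSS
    ts = np.flatnonzero(comp == 1)
    if len(ts):
        gi = rng.integers(0, len(genes), len(ts))
        offsets = (
            rng.exponential(config.tss_decay, len(ts))
            * np.where(rng.random(len(ts)) < 0.5, -1, 1)
        ).astype(np.int64)
        for k, g_idx in enumerate(gi):
            g = genes[g_idx]
            chroms[ts[k]] = g.chrom
            positions[ts[k]] = np.clip(
                g.tss + offsets[k], 0, genome.length(g.chrom) - 10
            )

    # feature-targeted: uniform over the target track (length-weighted)
    ft = np.flatnonzero(comp == 2)
    if len(ft):
        track = tracks[config.feature_track]
        ivals = [
            (chrom, s, e)
            for chrom, arr in track.merged().intervals.items()
            for s, e in arr
        ]
        if not ivals:
            raise ValueError(f"feature track {config.feature_track!r} is empty")
        widths = np.array([e - s for _, s, e in ivals], dtype=float)
        ii = rng.choice(len(ivals), size=len(ft), p=widths / widths.sum())
        for k, iv in enumerate(ii):
            chrom, s, e = ivals[iv]
            chroms[ft[k]] = chrom
            positions[ft[k]] = rng.integers(s, e)

    # hotspot clusters: fixed centres, normal spread
    hs = np.flatnonzero(comp == 3)
    if len(hs):
        ci = rng.choice(
            len(names), size=config.hotspot_clusters, p=lengths / lengths.sum()
        )
        centres = [
            (names[c], int(rng.random() * (lengths[c] - 200_000) + 100_000))
            for c in ci
        ]
        which = rng.integers(0, len(centres), len(hs))
        jitter = rng.normal(0, config.hotspot_spread, len(hs)).astype(np.int64)
        for k, w in enumerate(which):
            chrom, centre = centres[w]
            chroms[hs[k]] = chrom
            positions[hs[k]] = np.clip(
                centre + jitter[k], 0, genome.length(chrom) - 10
            )

    if motif is not None:
        for chrom in np.unique(chroms.astype(str)):
            m = np.flatnonzero(chroms == chrom)
            positions[m] = _snap_to_motif(motif, chrom, positions[m])

    strands = np.where(rng.random(n) < 0.5, "+", "-").astype(object)
    cuts = index_restriction_sites(genome)  # HaeIII
    frags = _assign_fragments(
        genome, chroms.astype(str), positions, strands, config.platform, cuts, rng
    )
    labels = np.asarray(["background", "tss", "feature", "hotspot"])[comp]
    replicates = rng.integers(1, config.n_replicates + 1, n).astype(str)
    iset = InsertionSet.from_arrays(
        chroms.astype(str),
        positions,
        strands.astype(str),
        label="simulated",
        genome=genome,
        vector=config.vector,
        replicate=replicates,
        selection=config.selection,
        platform=config.platform,
        fragment_length=frags,
    )
    return iset, labels


def simulate_rate_multiplier_insertions(
    genome: GenomeIndex,
    track: IntervalTrack,
    multiplier: float,
    n: int,
    motif: MotifIndex | None = None,
    seed: int | None = None,
    rng=None,
) -> InsertionSet:
    """Insertions with density proportional to ``multiplier`` inside the
    track and 1 outside (exactly -- used for recovery experiments).

    With a motif, the density is over motif occurrences; otherwise over
    single bases.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    rng = rng if rng is not None else np.random.default_rng(seed)
    names = genome.names
    if motif is not None:
        pool_chrom = np.concatenate(
            [np.full(len(motif.positions[c]), i) for i, c in enumerate(names)]
        )
        pool_pos = np.concatenate([motif.positions[c] for c in names])
    else:
        pool_chrom = np.concatenate(
            [np.full(genome.length(c), i, dtype=np.int32) for i, c in enumerate(names)]
        )
        pool_pos = np.concatenate(
            [np.arange(genome.length(c), dtype=np.int64) for c in names]
        )
    inside = np.zeros(len(pool_pos), dtype=bool)
    for i, c in enumerate(names):
        m = pool_chrom == i
        inside[m] = track.contains(c, pool_pos[m])
    weights = np.where(inside, multiplier, 1.0)
    pick = rng.choice(len(pool_pos), size=n, p=weights / weights.sum())
    return InsertionSet.from_arrays(
        np.asarray(names)[pool_chrom[pick]],
        pool_pos[pick],
        np.where(rng.random(n) < 0.5, "+", "-"),
        label="multiplier_sim",
        genome=genome,
        vector="PB" if motif is not None else "Tol2",
        platform="shear",
    )


def simulate_density_tracks(
    peak_tracks: dict[str, IntervalTrack],
    genome: GenomeIndex,
    background: float = 1.0,
    gain: float = 4.0,
    noise_sd: float = 0.5,
    step: int = 25,
    seed: int | None = None,
) -> dict[str, DensityTrack]:
    """Two-level density per factor: background + gain inside peaks, plus
    Gaussian noise, floored at 0.  Deterministic under ``seed``."""
    if background < 0:
        raise ValueError("background level must be non-negative")
    if gain <= 0:
        raise ValueError("peak gain must be positive")
    rng = np.random.default_rng(seed)
    out = {}
    for name, track in peak_tracks.items():
        values = {}
        for chrom, length in genome.chromosomes:
            ncell = -(-length // step)
            centers = np.arange(ncell) * step + step // 2
            vals = np.full(ncell, background, dtype=float)
            vals += gain * track.contains(chrom, np.minimum(centers, length - 1))
            if noise_sd > 0:
                vals += rng.normal(0, noise_sd, ncell)
            values[chrom] = np.maximum(vals, 0.0)
        out[name] = DensityTrack(name, step, values)
    return out


# ---------------------------------------------------------------------------
# Dataset export
# ---------------------------------------------------------------------------

def write_dataset(directory, config: SimulationConfig) -> dict:
    """Simulate and write a self-contained dataset directory.

    Emits genome.fa, genes.bed12, expression.tsv, tracks/*.bed,
    tracks/*.bedgraph, insertions.tsv, truth.tsv, and config.yaml; all
    files parse back through the package readers.
    """
    from pathlib import Path

    from .sites import write_insertion_table
    from .tracks import write_expression_table, write_gene_bed12, write_interval_track

    directory = Path(directory)
    (directory / "tracks").mkdir(parents=True, exist_ok=True)
    genome, genes, tracks = simulate_genome(config)
    iset, labels = simulate_insertions(genome, genes, tracks, config)
    genome.to_fasta(directory / "genome.fa")
    write_gene_bed12(genes, directory / "genes.bed12")
    write_expression_table(genes, directory / "expression.tsv")
    for name, track in tracks.items():
        write_interval_track(track, directory / "tracks" / f"{name}.bed")
    densities = simulate_density_tracks(
        {"H3K4me3": tracks["H3K4me3"]}, genome, seed=config.seed
    )
    for name, dt in densities.items():
        with open(directory / "tracks" / f"{name}.bedgraph", "w") as fh:
            for chrom, vals in dt.values.items():
                for i, v in enumerate(vals):
                    if v != 0:
                        fh.write(
                            f"{chrom}\t{i * dt.step}\t{(i + 1) * dt.step}\t{v:.4f}\n"
                        )
    write_insertion_table(iset, directory / "insertions.tsv")
    with open(directory / "truth.tsv", "w") as fh:
        fh.write("site\tcomponent\n")
        for i, lab in enumerate(labels):
            fh.write(f"{i}\t{lab}\n")
    config.to_yaml(directory / "config.yaml")
    return {
        "genome": genome,
        "genes": genes,
        "tracks": tracks,
        "insertions": iset,
        "labels": labels,
    }
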