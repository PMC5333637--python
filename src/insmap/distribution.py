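"""Genome-scale distribution statistics for insertion sets.

Windowed counts with permutation sampling, exon-density quintile
enrichment, exon/insertion density correlation, inter-insertion distances,
and hotspot locus detection under the (2 hits / 30 kb, 3 / 50 kb,
4+ / 100 kb) rules.

Two hotspot clustering conventions are provided.  The default
(``method="cluster"``) scans sorted sites left to right, extends a locus
while the span from its first member stays within the window, and emits it
if it holds at least ``m`` members -- one locus per contiguous cluster,
which is how recurrently-hit regions are counted.  The alternative
(``method="max-disjoint"``) emits a locus as soon as ``m`` compatible
members accumulate, which provably maximises the number of disjoint
qualifying loci and is verified against a brute-force oracle in the test
suite; on dense clusters it counts each disjoint m-subset separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats as sps

from .controls import ControlCollection
from .genome import GenomeIndex
from .sites import InsertionSet
from .stats import TestResult, bootstrap_pvalue
from .tracks import GeneModel

__all__ = [
    "WindowProfile",
    "ExonDensityBins",
    "DistanceSummary",
    "HotspotReport",
    "window_counts",
    "exon_density_bins",
    "quintile_enrichment",
    "exon_insertion_correlation",
    "inter_insertion_distances",
    "count_hotspots",
    "hotspot_replicate_provenance",
    "DEFAULT_HOTSPOT_RULES",
]

log = logging.getLogger(__name__)

DEFAULT_HOTSPOT_RULES = ((2, 30_000), (3, 50_000), (4, 100_000))
QUINTILE_LABELS = ("lowest", "low", "mid", "high", "highest")


# ---------------------------------------------------------------------------
# Windowed counts
# ---------------------------------------------------------------------------

@dataclass
class WindowProfile:
    window_size: int
    sample_size: int
    reps: int
    chroms: list[str]
    counts: dict[str, np.ndarray]  # per-window mean insertion count

    def total(self) -> float:
        return float(sum(c.sum() for c in self.counts.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chroms:
            for w, c in enumerate(self.counts[chrom]):
                rows.append((chrom, w * self.window_size, c))
        return pd.DataFrame(rows, columns=["chrom", "window_start", "mean_count"])


def _window_layout(genome: GenomeIndex, window_size: int):
    offsets = {}
    total = 0
    for name, length in genome.chromosomes:
        n = -(-length // window_size)
        offsets[name] = (total, n)
        total += n
    return offsets, total


def window_counts(
    sites: InsertionSet,
    genome: GenomeIndex,
    window_size: int = 1_000_000,
    sample_size: int = 4_000,
    reps: int = 1_000,
    seed: int | None = None,
) -> WindowProfile:
    """Mean insertion count per genomic window over permutation samples.

    ``reps`` samples of ``sample_size`` sites are drawn without
    replacement and counted per window; ``reps=0`` gives exact counts on
    the full set.  If the set is smaller than ``sample_size`` the full set
    is used (with a warning) and the means equal the exact counts.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    offsets, total = _window_layout(genome, window_size)
    chroms = sites.df["chrom"].to_numpy()
    pos = sites.df["position"].to_numpy()
    win = np.array(
        [offsets[c][0] + p // window_size for c, p in zip(chroms, pos)],
        dtype=np.int64,
    )
    n = len(sites)
    if reps == 0 or sample_size >= n:
        if reps > 0 and sample_size > n:
            log.warning(
                "window_counts: sample_size %d > %d sites; using the full set",
                sample_size,
                n,
            )
        mean = np.bincount(win, minlength=total).astype(float)
    else:
        rng = np.random.default_rng(seed)
        acc = np.zeros(total, dtype=np.float64)
        for _ in range(reps):
            idx = rng.choice(n, sample_size, replace=False)
            acc += np.bincount(win[idx], minlength=total)
        mean = acc / reps
    counts = {
        name: mean[off : off + nwin] for name, (off, nwin) in offsets.items()
    }
    return WindowProfile(window_size, sample_size, reps, genome.names, counts)


# ---------------------------------------------------------------------------
# Exon-density bins and quintile enrichment
# ---------------------------------------------------------------------------

@dataclass
class ExonDensityBins:
    bin_size: int
    chroms: list[str]
    bin_chrom: np.ndarray  # chrom index per bin
    bin_start: np.ndarray
    exon_bp: np.ndarray
    quintile: np.ndarray  # 0 (lowest) .. 4 (highest)

    @property
    def n_bins(self) -> int:
        return len(self.exon_bp)

    def bin_of(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Global bin index per site; raises if a site misses every bin."""
        name_to_off = {}
        off = 0
        counts = np.bincount(self.bin_chrom, minlength=len(self.chroms))
        for i, name in enumerate(self.chroms):
            name_to_off[name] = (off, int(counts[i]))
            off += counts[i]
        chroms = np.asarray(chroms)
        positions = np.asarray(positions, dtype=np.int64)
        out = np.empty(len(positions), dtype=np.int64)
        for c in np.unique(chroms):
            if c not in name_to_off:
                raise ValueError(f"site on {c!r} outside the binned genome")
            start, nbin = name_to_off[c]
            m = chroms == c
            b = positions[m] // self.bin_size
            if (b >= nbin).any():
                p = positions[m][b >= nbin][0]
                raise ValueError(
                    f"site at {c}:{p} beyond the last bin (genome mismatch?)"
                )
            out[m] = start + b
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [self.chroms[i] for i in self.bin_chrom],
                "start": self.bin_start,
                "exon_bp": self.exon_bp,
                "quintile": [QUINTILE_LABELS[q] for q in self.quintile],
            }
        )


def exon_density_bins(
    genes: list[GeneModel], genome: GenomeIndex, bin_size: int = 500_000
) -> ExonDensityBins:
    """Tile the genome, accumulate exon bp per bin (pro-rata across bin
    boundaries), and rank bins into five equal-sized quintile groups.

    Ties are broken by genomic coordinate (stable sort), so identical
    densities get deterministic labels.
    """
    chrom_bins = []
    for ci, (name, length) in enumerate(genome.chromosomes):
        n = -(-length // bin_size)
        chrom_bins.append((name, ci, n))
    bin_chrom = np.concatenate(
        [np.full(n, ci, dtype=np.int32) for _, ci, n in chrom_bins]
    )
    bin_start = np.concatenate(
        [np.arange(n, dtype=np.int64) * bin_size for _, _, n in chrom_bins]
    )
    offsets = {}
    off = 0
    for name, _, n in chrom_bins:
        offsets[name] = off
        off += n
    exon_bp = np.zeros(off, dtype=np.float64)
    for g in genes:
        base = offsets[g.chrom]
        for s, e in g.exons:
            b0, b1 = s // bin_size, (e - 1) // bin_size
            for b in range(b0, b1 + 1):
                lo = max(s, b * bin_size)
                hi = min(e, (b + 1) * bin_size)
                exon_bp[base + b] += hi - lo

    order = np.argsort(exon_bp, kind="stable")
    quintile = np.empty(off, dtype=np.int8)
    for qi, chunk in enumerate(np.array_split(order, 5)):
        quintile[chunk] = qi
    return ExonDensityBins(
        bin_size, genome.names, bin_chrom, bin_start, exon_bp, quintile
    )


def quintile_enrichment(
    sites: InsertionSet,
    bins: ExonDensityBins,
    controls: ControlCollection | None = None,
) -> pd.DataFrame:
    """Observed (and pooled-control) fraction of sites per exon-density
    quintile; both fraction columns sum to 1."""
    idx = bins.bin_of(
        sites.df["chrom"].to_numpy(), sites.df["position"].to_numpy()
    )
    obs = np.bincount(bins.quintile[idx], minlength=5).astype(float)
    obs_frac = obs / obs.sum()
    out = pd.DataFrame({"quintile": QUINTILE_LABELS, "observed_fraction": obs_frac})
    if controls is not None:
        ctrl = np.zeros(5, dtype=float)
        for chrom, pos in controls.pooled_positions().items():
            if not len(pos):
                continue
            cidx = bins.bin_of(np.full(len(pos), chrom), pos)
            ctrl += np.bincount(bins.quintile[cidx], minlength=5)
        out["control_fraction"] = ctrl / ctrl.sum()
    return out


@dataclass
class CorrelationResult:
    r: float
    control_r: np.ndarray
    test: TestResult | None
    flags: list[str] = field(default_factory=list)


def exon_insertion_correlation(
    sites: InsertionSet,
    bins: ExonDensityBins,
    controls: ControlCollection | None = None,
) -> CorrelationResult:
    """Pearson r between per-bin exon bp and per-bin insertion counts,
    with a bootstrap comparison against the per-set control correlations."""
    if bins.n_bins < 3:
        raise ValueError("need at least 3 bins")
    idx = bins.bin_of(sites.df["chrom"].to_numpy(), sites.df["position"].to_numpy())
    counts = np.bincount(idx, minlength=bins.n_bins).astype(float)
    flags: list[str] = []
    if np.ptp(counts) == 0 or np.ptp(bins.exon_bp) == 0:
        return CorrelationResult(float("nan"), np.empty(0), None, ["zero_variance"])
    r = float(sps.pearsonr(bins.exon_bp, counts)[0])
    control_r = np.empty(0)
    test = None
    if controls is not None:
        vals = []
        for j in range(controls.n_sets):
            chroms, pos, _, _ = controls.set_arrays(j)
            cidx = bins.bin_of(chroms, pos)
            ccounts = np.bincount(cidx, minlength=bins.n_bins).astype(float)
            if np.ptp(ccounts) == 0:
                vals.append(0.0)
            else:
                vals.append(float(sps.pearsonr(bins.exon_bp, ccounts)[0]))
        control_r = np.asarray(vals)
        test = bootstrap_pvalue(r, control_r, name="exon_insertion_correlation")
    return CorrelationResult(r, control_r, test, flags)


# ---------------------------------------------------------------------------
# Inter-insertion distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceSummary:
    threshold: int
    sample_size: int
    reps: int
    mean_log10: float
    sd_log10: float
    mean_count_below: float
    fraction_below: float
    counts_per_rep: np.ndarray
    n_zero_excluded: int
    control_mean_count_below: float | None = None
    control_counts_per_set: np.ndarray | None = None
    fold_enrichment: float | None = None
    test: TestResult | None = None
    distances: np.ndarray | None = None  # full-set distances when reps == 0


def _global_sorted(positions_by_chrom: dict[str, np.ndarray], gap: int = 1 << 30):
    """Concatenate per-chromosome sorted positions on a gapped global axis,
    so no window or distance can bridge chromosomes."""
    parts = []
    offset = 0
    for chrom in sorted(positions_by_chrom):
        pos = positions_by_chrom[chrom]
        if len(pos):
            parts.append(pos + offset)
        offset += (int(pos[-1]) if len(pos) else 0) + gap
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(parts)


def _distances_of(gpos: np.ndarray, gap: int = 1 << 30) -> np.ndarray:
    d = np.diff(gpos)
    return d[d < gap // 2]


def inter_insertion_distances(
    sites: InsertionSet,
    sample_size: int = 4_000,
    reps: int = 1_000,
    threshold: int = 10_000,
    seed: int | None = None,
    controls: ControlCollection | None = None,
) -> DistanceSummary:
    """Distances between coordinate-adjacent sites on the same chromosome.

    ``reps`` permutation samples of ``sample_size`` sites each contribute
    sorted adjacent-pair distances; zero distances (identical coordinates)
    are excluded and counted.  The headline statistic is the mean number
    of distances below ``threshold`` (10 kb), with fold-enrichment over
    the matched controls and a bootstrap p-value when controls are given.
    """
    gpos = np.sort(_global_sorted(sites.positions_by_chrom()))
    n = len(gpos)
    rng = np.random.default_rng(seed)

    def summarise(sample: np.ndarray):
        d = _distances_of(np.sort(sample))
        zeros = int((d == 0).sum())
        d = d[d > 0]
        count_below = int((d < threshold).sum())
        return d, zeros, count_below

    if reps == 0 or sample_size >= n:
        if reps > 0 and sample_size > n:
            log.warning("inter_insertion_distances: using the full set of %d sites", n)
        d, zeros, count_below = summarise(gpos)
        logs = np.log10(d) if len(d) else np.empty(0)
        counts_per_rep = np.array([count_below], dtype=float)
        mean_log = float(logs.mean()) if len(logs) else float("nan")
        sd_log = float(logs.std(ddof=1)) if len(logs) > 1 else float("nan")
        frac = count_below / len(d) if len(d) else float("nan")
        full_d = d
        total_zeros = zeros
    else:
        counts = np.empty(reps, dtype=float)
        mlogs = np.empty(reps)
        slogs = np.empty(reps)
        fracs = np.empty(reps)
        total_zeros = 0
        for r in range(reps):
            idx = np.sort(rng.choice(n, sample_size, replace=False))
            d, zeros, count_below = summarise(gpos[idx])
            total_zeros += zeros
            counts[r] = count_below
            logs = np.log10(d)
            mlogs[r] = logs.mean()
            slogs[r] = logs.std(ddof=1)
            fracs[r] = count_below / len(d) if len(d) else np.nan
        counts_per_rep = counts
        mean_log = float(mlogs.mean())
        sd_log = float(slogs.mean())
        frac = float(np.nanmean(fracs))
        full_d = None
    if total_zeros:
        log.info(
            "inter_insertion_distances: excluded %d zero distance(s)", total_zeros
        )

    result = DistanceSummary(
        threshold=threshold,
        sample_size=sample_size,
        reps=reps,
        mean_log10=mean_log,
        sd_log10=sd_log,
        mean_count_below=float(counts_per_rep.mean()),
        fraction_below=frac,
        counts_per_rep=counts_per_rep,
        n_zero_excluded=total_zeros,
        distances=full_d,
    )
    if controls is not None:
        ctrl_counts = []
        n_use = controls.n_sets if reps == 0 else min(reps, controls.n_sets)
        for j in range(n_use):
            chroms, pos, _, _ = controls.set_arrays(j)
            by_chrom: dict[str, list] = {}
            for c, p in zip(chroms, pos):
                by_chrom.setdefault(c, []).append(p)
            cg = np.sort(
                _global_sorted({c: np.sort(np.asarray(v)) for c, v in by_chrom.items()})
            )
            if sample_size < len(cg) and reps > 0:
                idx = np.sort(rng.choice(len(cg), sample_size, replace=False))
                cg = cg[idx]
            _, _, cb = summarise(cg)
            ctrl_counts.append(cb)
        result.control_counts_per_set = np.asarray(ctrl_counts, dtype=float)
        result.control_mean_count_below = float(result.control_counts_per_set.mean())
        if result.control_mean_count_below > 0:
            result.fold_enrichment = (
                result.mean_count_below / result.control_mean_count_below
            )
        result.test = bootstrap_pvalue(
            result.mean_count_below,
            result.control_counts_per_set,
            name=f"inter_insertion_distance<{threshold}",
        )
    return result


# ---------------------------------------------------------------------------
# Hotspots
# ---------------------------------------------------------------------------

@njit(cache=False)
def _count_cluster_runs(pos, W, m):  # pragma: no cover - numba
    n = len(pos)
    i = 0
    count = 0
    while i < n:
        j = i
        while j + 1 < n and pos[j + 1] - pos[i] <= W:
            j += 1
        if j - i + 1 >= m:
            count += 1
            i = j + 1
        else:
            i += 1
    return count


@njit(cache=False)
def _count_max_disjoint(pos, W, m):  # pragma: no cover - numba
    n = len(pos)
    count = 0
    a = 0
    for i in range(n):
        if pos[i] - pos[a] > W:
            while pos[i] - pos[a] > W:
                a += 1
        if i - a + 1 == m:
            count += 1
            a = i + 1
    return count


def _cluster_loci(pos: np.ndarray, W: int, m: int, method: str):
    """Locus member index ranges on one sorted position array (python path,
    used for full-set reports)."""
    loci = []
    n = len(pos)
    if method == "cluster":
        i = 0
        while i < n:
            j = i
            while j + 1 < n and pos[j + 1] - pos[i] <= W:
                j += 1
            if j - i + 1 >= m:
                loci.append(list(range(i, j + 1)))
                i = j + 1
            else:
                i += 1
    elif method == "max-disjoint":
        a = 0
        for i in range(n):
            while pos[i] - pos[a] > W:
                a += 1
            if i - a + 1 == m:
                loci.append(list(range(a, i + 1)))
                a = i + 1
    else:
        raise ValueError(f"unknown hotspot method {method!r}")
    return loci


@dataclass
class HotspotLocus:
    chrom: str
    start: int
    end: int
    site_indices: list[int]
    replicates: list[str]

    @property
    def n_sites(self) -> int:
        return len(self.site_indices)


@dataclass
class HotspotReport:
    rules: tuple
    method: str
    sample_size: int
    reps: int
    mean_counts: dict[tuple, float]
    loci: dict[tuple, list[HotspotLocus]]
    control_mean_counts: dict[tuple, float] = field(default_factory=dict)
    tests: dict[tuple, TestResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rule in self.rules:
            rows.append(
                (
                    f"{rule[0]}hit/{rule[1] // 1000}kb",
                    self.mean_counts[rule],
                    self.control_mean_counts.get(rule, np.nan),
                    self.tests[rule].p if rule in self.tests else np.nan,
                )
            )
        return pd.DataFrame(
            rows, columns=["rule", "observed_mean", "control_mean", "bootstrap_p"]
        )


def _counts_for(gpos_sorted: np.ndarray, rules, method: str) -> list[int]:
    fn = _count_cluster_runs if method == "cluster" else _count_max_disjoint
    return [int(fn(gpos_sorted, W, m)) for m, W in rules]


def count_hotspots(
    sites: InsertionSet,
    rules=DEFAULT_HOTSPOT_RULES,
    sample_size: int = 4_000,
    reps: int = 1_000,
    seed: int | None = None,
    controls: ControlCollection | None = None,
    method: str = "cluster",
    exclusive: bool = False,
) -> HotspotReport:
    """Hotspot loci under each (m hits, window W) rule.

    With ``reps > 0``, ``sample_size`` sites are sampled without
    replacement ``reps`` times and the mean locus count reported (matched
    controls get the same treatment, one sample per control set, plus a
    bootstrap p-value).  ``reps=0`` clusters the full set and reports the
    loci with their member sites and replicate labels.  Rules are
    evaluated independently by default; ``exclusive=True`` evaluates rules
    by descending ``m`` and removes member sites of emitted loci from the
    pool before lower rules run.
    """
    for m, W in rules:
        if m < 2:
            raise ValueError("hotspot rules need m >= 2")
        if W <= 0:
            raise ValueError("hotspot windows must be positive")
    if method not in ("cluster", "max-disjoint"):
        raise ValueError(f"unknown hotspot method {method!r}")

    df = sites.df.sort_values(["chrom", "position"], kind="stable")
    order = df.index.to_numpy()
    by_chrom = {
        chrom: sub["position"].to_numpy()
        for chrom, sub in df.groupby("chrom", sort=True)
    }
    gpos = _global_sorted(by_chrom)
    n = len(gpos)

    loci: dict[tuple, list[HotspotLocus]] = {rule: [] for rule in rules}
    mean_counts: dict[tuple, float] = {}

    # full-set loci with membership (always computed; cheap)
    rule_order = sorted(rules, key=lambda r: -r[0]) if exclusive else list(rules)
    consumed: set[int] = set()
    for rule in rule_order:
        m, W = rule
        pos_idx = 0
        for chrom in sorted(by_chrom):
            pos = by_chrom[chrom]
            local_orig = order[pos_idx : pos_idx + len(pos)]
            if exclusive and consumed:
                keep = np.array([o not in consumed for o in local_orig])
                pos_f, orig_f = pos[keep], local_orig[keep]
            else:
                pos_f, orig_f = pos, local_orig
            for members in _cluster_loci(pos_f, W, m, method):
                site_ids = [int(orig_f[i]) for i in members]
                reps_lab = [
                    str(sites.df.loc[i, "replicate"]) for i in site_ids
                ]
                loci[rule].append(
                    HotspotLocus(
                        chrom=chrom,
                        start=int(pos_f[members[0]]),
                        end=int(pos_f[members[-1]]) + 1,
                        site_indices=site_ids,
                        replicates=reps_lab,
                    )
                )
                if exclusive:
                    consumed.update(site_ids)
            pos_idx += len(pos)

    if reps == 0 or sample_size >= n:
        for rule in rules:
            mean_counts[rule] = float(len(loci[rule]))
    else:
        rng = np.random.default_rng(seed)
        acc = {rule: 0.0 for rule in rules}
        for _ in range(reps):
            idx = np.sort(rng.choice(n, sample_size, replace=False))
            for rule, c in zip(rules, _counts_for(gpos[idx], rules, method)):
                acc[rule] += c
        mean_counts = {rule: acc[rule] / reps for rule in rules}

    report = HotspotReport(
        rules=tuple(rules),
        method=method,
        sample_size=sample_size,
        reps=reps,
        mean_counts=mean_counts,
        loci=loci,
    )

    if controls is not None:
        rng = np.random.default_rng(None if seed is None else seed + 1)
        per_rule: dict[tuple, list] = {rule: [] for rule in rules}
        n_use = controls.n_sets if reps == 0 else min(reps, controls.n_sets)
        for j in range(n_use):
            chroms, pos, _, _ = controls.set_arrays(j)
            by_c: dict[str, list] = {}
            for c, p in zip(chroms, pos):
                by_c.setdefault(c, []).append(p)
            cg = np.sort(
                _global_sorted({c: np.sort(np.asarray(v)) for c, v in by_c.items()})
            )
            if reps > 0 and sample_size < len(cg):
                idx = np.sort(rng.choice(len(cg), sample_size, replace=False))
                cg = cg[idx]
            for rule, c in zip(rules, _counts_for(cg, rules, method)):
                per_rule[rule].append(c)
        for rule in rules:
            vals = np.asarray(per_rule[rule], dtype=float)
            report.control_mean_counts[rule] = float(vals.mean())
            report.tests[rule] = bootstrap_pvalue(
                mean_counts[rule], vals, name=f"hotspot_{rule[0]}hit"
            )
    return report


def hotspot_replicate_provenance(report: HotspotReport) -> dict:
    """Per-rule fraction of loci whose members come from >= 2 distinct
    replicate labels (independent transfections), plus per-locus labels."""
    out = {}
    for rule, loci in report.loci.items():
        for locus in loci:
            if any(lab in ("", "nan", "None") for lab in locus.replicates):
                raise ValueError("replicate labels missing on hotspot members")
        multi = [len(set(l.replicates)) >= 2 for l in loci]
        out[rule] = {
            "fraction_multi_replicate": (
                float(np.mean(multi)) if multi else float("nan")
            ),
            "per_locus_replicates": [l.replicates for l in loci],
        }
    return out
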