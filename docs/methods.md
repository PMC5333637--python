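# Methods

This note documents the models and conventions behind `insmap`: what the
matched-control generator actually draws, how each statistic is defined,
what the synthetic data emulate, and where desk-scale simulation differs
from genome-scale data.

## Coordinates and data model

All coordinates are 0-based, half-open (BED convention); GTF input is
converted on read. An insertion's `position` is the first base of the
target-site duplication on the forward strand (the first T of piggyBac's
TTAA, the T of Sleeping Beauty's TA), regardless of which flank was
sequenced; `strand` records the sequenced-flank direction and orients
the restriction fragment. Motif and restriction-site searches are
forward-strand only by default — TA, TTAA, and GGCC are palindromic, so
nothing is lost; `both_strands=True` covers non-palindromic motifs.
Bases outside A/C/G/T never match any motif or recognition sequence.

## Read-level acceptance (site_qc)

Long-read (restriction) libraries are filtered on percent identity and
coverage (> 90 each, strict), short paired-end libraries on mapping
quality (> 30, strict), proper pairing, and uniqueness. Records at an
identical (chrom, position, strand) junction are collapsed before the
≥ 2-supporting-reads rule, since PCR duplicates of the same junction are
what that rule counts. Motif confirmation then requires the vector's
target-site motif at the insertion position (PB → TTAA, SB → TA; MLV and
Tol2 have no target-site consensus and pass unconditionally). Filtering
is idempotent and monotone in every threshold (property-tested).

## Matched in-silico controls

**Restriction mode.** For an observed site with fragment length *f* and
strand *s*, a control is a pair (motif position *P*, primary-enzyme cut
*C*) such that

1. *C* is a genuine cut coordinate (HaeIII GG^CC by default);
2. the control fragment |C − P| is positive and within
   `max_fragment_diff` (default 20 bp, exclusive) of *f*, with *C* on
   the side given by *s*;
3. *P* is an occurrence of the vector motif (skipped for MLV/Tol2, where
   *P* = *C* ∓ *f* exactly);
4. no secondary-enzyme cut lies **strictly** inside the open interval
   (*P*, *C*) — a cut at either boundary does not destroy the amplicon;
5. the *k*-mer starting at *P* occurs exactly once in the genome.

Rather than rejection-sampling with a retry budget, the generator
enumerates the full admissible set per observed site once (vectorised
over sorted motif/cut arrays) and draws each of the `n_sets` controls
uniformly from it. The support of the generator is therefore *exactly*
the admissible set (verified against a brute-force enumeration oracle),
and attrition — observed sites with an empty admissible set — is
deterministic and reported per set, never silently dropped. The draw is
uniform over admissible (motif, cut) pairs; a two-stage draw (uniform
cut, then motif) would weight motifs by their admissible-cut
multiplicity, an invisible difference at the test's resolution on
uniform genomes.

**Shear mode.** Controls are drawn uniformly from motif occurrences
(motif vectors) or uniformly from all uniquely mappable positions
(Tol2/MLV); fragment sizes and strands are copied from the matched
observed sites.

**Mappability** is exact canonical *k*-mer uniqueness (default
*k* = 36): the *k*-mer starting at a candidate position, reduced to the
lexicographic minimum of itself and its reverse complement, must occur
exactly once genome-wide. This is a deterministic, dependency-free
realisation of the "re-align and require unique high-quality placement"
contract; it has no concept of base-quality or indel tolerance, so it is
slightly stricter than an aligner-based check near repeats.

**Reproducibility.** One root seed; per-set RNG streams are spawned by
set index (`SeedSequence.spawn`), so any control set can be regenerated
independently.

## Distribution statistics

* **Window counts**: windows tile each chromosome (default 1 Mb); with
  `reps > 0`, the mean count per window over `reps` samples of
  `sample_size` sites drawn without replacement (defaults 1,000 × 4,000);
  `reps=0` gives exact counts. A set smaller than the sample size is
  used whole, with a warning.
* **Exon-density quintiles**: 500-kb bins accumulate exon bp pro-rata
  across bin boundaries, are ranked by a stable sort (coordinate order
  breaks ties deterministically), and split into five equal groups.
* **Inter-insertion distances**: adjacent-site differences per
  chromosome within each permutation sample; zero distances (identical
  coordinates) are excluded and counted rather than pseudocounted,
  because log₁₀ is taken on raw bp. The headline statistic is the mean
  count of distances < 10 kb and its fold-change over controls.
* **Hotspots**: two clustering conventions are exposed.
  `method="cluster"` (default) scans sorted sites left to right, extends
  a locus while the span from its first member stays ≤ W, and emits it
  if it holds ≥ m members — one locus per contiguous cluster, the
  natural reading of a recurrently-hit region. `method="max-disjoint"`
  emits a locus as soon as m compatible members accumulate; this greedy
  is provably count-maximising and is tested for equality with
  brute-force enumeration over all disjoint qualifying subsets. The two
  differ on dense data (a tight run of 4 sites is one cluster but two
  disjoint 2-hit loci), which is why both are kept: the first carries
  the biology, the second anchors the algorithmic guarantee. Rules are
  evaluated independently by default (`exclusive=True` consumes member
  sites by descending m). Adding a site never decreases a cluster count
  (property-tested).

## Gene and TSS context

In-gene means position ∈ [txStart, txEnd) of any gene. The expression
profile sorts genes by expression into eight equal octiles (bin 1 = top)
and counts insertion–gene pairs within ±50 kb of each gene (`scope=
"near"`) or inside gene bodies (`scope="inside"`) — both are provided
because either reading is defensible; frequencies are normalised over
pairs and reported as observed/control ratios. Nearest-TSS assignment
breaks equidistant ties toward the higher-expressed gene, then
lexicographic gene id, for determinism. Signed TSS distances are
negative upstream; the scaled profile divides by gene size (default
bins of 0.25 gene-lengths over [−1, +2]; the resolution is a config
option, chosen for legibility), and the window profile uses 100 bins of
100 bp across ±5 kb, counts divided by the total number of sites, with
the pooled-control series subtracted. Control frequencies are computed
from the pooled control sets; with (near-)equal set sizes this equals
the mean over per-set frequencies.

## Chromatin context

Density meta-profiles average track values in 400 bins of 25 bp across
±5 kb of each site, computed exactly on the fixed-step track via its
cumulative integral; sites near a chromosome end contribute only
in-bounds bins, with per-bin denominators retained. Profiles are linear
in the track (property-tested). Region-overlap enrichment counts the
single insertion coordinate (not a fragment interval) inside
flank-expanded merged regions; the flank defaults to 0 and is set
explicitly (e.g. 2 kb) where an analysis calls for it. The binomial
null rate pools successes and totals across all control sets.
Peak-relative distances are signed: negative when the peak lies 5′
(left) of the site on the forward strand, 0 inside a peak. Rasters mark
a cell 1 iff the 25-bp bin interval intersects any peak, rows ordered by
the sort-factor's peak bp within the window (descending). Gene sets
collect genes with ≥ 3/4/5 insertions within the ±50-kb-expanded body;
the sets are nested by construction and exported as GMT.

## Significance

Binomial and Fisher tests are exact (`scipy.stats`), checked in the test
suite against independent tail-summation and hypergeometric-enumeration
oracles; BH FDR is the standard step-up (statsmodels), checked against
the hand formula. Bootstrap p-values use the literal count/N convention
(the `plus_one` option gives (count+1)/(N+1)); "more extreme" is
one-sided in the direction of the observed deviation, recorded in the
result's `side` field, and a numeric 0 is rendered as "P < 1/N" in text
output. The 0.05 threshold flags results only; nothing is dropped.

## Synthetic data

The generator emulates the *structure* of an insertion-profiling study,
not any particular genome. Defaults, chosen once as desk-scale stand-ins
for the study conditions: two 5-Mb chromosomes of i.i.d. bases at GC
0.5 (dinucleotide structure is not modelled; motif and HaeIII-site
frequencies then follow base composition, which is all the pipeline
relies on); 300 non-overlapping genes (log-normal lengths, ~10 kb mean;
log-normal expression); peak/enhancer/super-enhancer interval tracks and
promoter-anchored H3K4me3/H3K27me3 regions with a bivalent overlap
subset; and 6,000 insertions — paper-scale for one vector dataset — in
3 replicate batches (mirroring three independent transfections) from
the mixture w = (0.5 background, 0.2 TSS-proximal with 5-kb exponential
decay, 0.2 super-enhancer-targeted, 0.1 hotspot in 5 clusters of 10-kb
normal spread). Motif-constrained vectors snap to the nearest motif
occurrence; restriction-platform fragment lengths are the distance to
the nearest HaeIII cut in the strand direction; shear fragments are
300–400 bp. Ground-truth component labels are emitted alongside.

A separate helper, `simulate_rate_multiplier_insertions`, draws sites
with density ∝ m inside a target track and 1 outside — the clean
construction for parameter-recovery experiments, since the enrichment
ratio then equals m/(1 + (m−1)·f) for compartment fraction f, ≈ m when
f is small (~1% in the recovery runs).

## What desk scale does and does not show

A 10-Mb genome carrying thousands of sites is ~250× denser than a
mammalian genome with the same n. Constraint contracts, oracle
equivalences, null calibration, and bias recovery are all scale-free
and transfer directly. Density-sensitive statistics do not: with mean
inter-site gaps of a few kb, the <10-kb distance count saturates and
background hotspot loci are common, so clustered observed sets can show
*fewer* loci than uniform controls (the direction is recorded per test).
On genome-scale data the same statistics measure hotspot and proximity
excess. The acceptance script therefore reports these as computed
quantities of the simulated study, while the recovery experiments pin
the quantities with known ground truth.

## Numerical choices

Exact binomial tails rather than normal approximations throughout;
interval queries via sorted-array bisection (no tree structures needed
at these scales); hotspot counting over permutation samples is compiled
with numba; chromosomes are concatenated with 2³⁰-bp gaps for global
sorted-coordinate operations so no window or distance can bridge
chromosomes. Degenerate inputs fail loudly: zero-variance correlations,
empty region tracks, all-zero contingency tables, and out-of-bounds
coordinates raise or flag rather than returning silent zeros.

## Known limitations

No PCR-amplification bias, DpnI plasmid depletion, or sequencing-error
model in the generator; no read-level (FASTQ/BAM) handling — alignment
is upstream; mappability ignores base quality and indels; the i.i.d.
base model understates repeat structure, so attrition on real genomes
will be higher than in simulation; GSEA itself (NES computation) is out
of scope — only the gene-set export is provided.
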