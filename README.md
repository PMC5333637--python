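# insmap

Insertion-site profiling for transposon and retroviral integration
datasets: matched in-silico control generation, genome-wide distribution
statistics, and chromatin-context meta-profiles.

## The problem

Gene-transfer and insertional-mutagenesis vectors — the murine leukemia
virus (MLV) and the piggyBac (PB), Tol2, and Sleeping Beauty (SB)
transposons — do not integrate uniformly across the genome. Quantifying
each vector's insertion preference (toward transcription start sites,
exon-rich regions, enhancers and super-enhancers, or recurrent "hotspot"
loci) requires separating genuine biology from the detectability
constraints of the sequencing protocol: junction libraries anchored on a
restriction digest (HaeIII) can only observe insertions at a compatible
fragment distance from a cut site, PB and SB only ever land on their
target-site duplication motifs (TTAA and TA), and only uniquely mappable
positions are recoverable at all.

`insmap` addresses this with **size-adjusted matched in-silico
controls**: for every observed insertion, pseudo-insertions drawn under
the same constraints —

* a genuine primary-enzyme cut site at a fragment distance within
  Δ < 20 bp of the observed fragment, on the matched strand
  (restriction mode), or fragment sizes copied outright (shear mode);
* the vector's target-site motif at the control position;
* no secondary-enzyme cut strictly inside the control fragment
  (the paper-trail enzymes used to suppress vector-backbone amplicons);
* unique mappability, realised as exact genome-wide *k*-mer uniqueness
  (default *k* = 36, both strands).

Repeating the draw 1,000 times yields 1,000 control sets — the empirical
null for every downstream statistic.

## Statistics

With observed set *X* (n sites) and control sets *C₁ … C_N*:

* **Windowed distributions** — mean insertion counts in 1-Mb windows over
  1,000 permutation samples of 4,000 sites.
* **Exon-density enrichment** — 500-kb bins ranked into quintiles by exon
  bp; observed vs control fractions per quintile, and Pearson *r* between
  exon density and insertion density with a bootstrap contrast.
* **Inter-insertion distances** — log₁₀ distances between
  coordinate-adjacent sites; fold-enrichment of distances < 10 kb over
  controls.
* **Hotspot loci** — greedy clustering of sorted sites under the rules
  (2 hits / 30 kb), (3 / 50 kb), (4+ / 100 kb); a count-maximising
  variant (`method="max-disjoint"`) is verified against brute-force
  enumeration.
* **Gene context** — in-gene fraction ratio, insertion frequency by
  expression-rank octile, and TSS-relative profiles (gene-size-scaled and
  ±5 kb / 100-bp bins, control-subtracted).
* **Chromatin context** — 400-point ChIP-density meta-profiles
  (±5 kb / 25 bp, control-subtracted), region-overlap enrichment with
  exact binomial tests `P(X ≥ k | n, p̂)` where `p̂ = Σk_c / Σn_c` is the
  pooled control rate, bivalent-region intersection, signed peak-distance
  histograms, binary overlap rasters, and ≥3/4/5-insertion gene sets
  (GMT export for GSEA).
* **Significance** — one-sided exact binomial tests, two-sided Fisher
  tests for vector-vs-vector contrasts, bootstrap p-values
  `p = #{ c : T(C_c) at least as extreme as T(X) } / N`, and
  Benjamini–Hochberg FDR across feature batches.

A synthetic-data module generates desk-scale genomes, gene models,
chromatin tracks, and insertion sets from a programmable mixture
(uniform background, TSS-proximal decay, feature targeting, hotspot
clusters), so the whole pipeline is testable without downloads.

## Worked example

```python
import insmap as im

cfg = im.SimulationConfig(seed=7, n_sites=2000)
genome, genes, tracks = im.simulate_genome(cfg)
observed, truth = im.simulate_insertions(genome, genes, tracks, cfg)

motif = im.scan_motif_positions(genome, "TTAA")
constraints = im.ControlConstraints(
    primary=im.index_restriction_sites(genome),                   # HaeIII GG^CC
    secondary=[im.index_restriction_sites(genome, "TCTAGA", 1)],  # XbaI
    motif=motif, n_sets=200, seed=7,
)
controls = im.generate_flx_controls(observed, genome, constraints)
print(f"{controls.n_sets} control sets, attrition {controls.attrition[0]}")

enr = im.region_overlap_enrichment(observed, tracks["super_enhancers"], controls)
print(f"super-enhancer enrichment: ratio {enr.ratio:.2f}, {enr.test.p_text()}")

hot = im.count_hotspots(observed, sample_size=1000, reps=200, seed=7,
                        controls=controls)
print(hot.to_frame().to_string(index=False))

ingene = im.in_gene_fraction_ratio(observed, genes, controls)
print(f"in-gene ratio: {ingene.ratio:.2f} ({ingene.test.p_text()})")
```

prints

```
200 control sets, attrition 0
super-enhancer enrichment: ratio 7.48, P = 8.86922e-239
      rule  observed_mean  control_mean  bootstrap_p
 2hit/30kb        203.935       235.395          0.0
 3hit/50kb        140.660       160.535          0.0
4hit/100kb         86.725        90.910          0.0
in-gene ratio: 1.16 (P = 1.25592e-06)
```

The simulated dataset targets super-enhancers at an elevated rate, and
the enrichment test recovers a 7.5-fold excess over matched controls
(exact binomial p). The in-gene ratio is modestly above 1 because a
fifth of the simulated sites are TSS-proximal. The hotspot table needs
care at desk scale: on a 10-Mb toy genome 1,000 sampled sites are so
dense that uniform controls form loci constantly, and clustering
*concentrates* the observed sites into fewer loci — the bootstrap here
flags the observed counts as extreme in the depleted direction (the
`side` field of each test records this). On genome-scale data, where
background loci are rare, the same statistic measures hotspot excess.

A `insmap` command-line interface wraps the same functions
(`simulate`, `qc`, `controls`, `windows`, `exonbins`, `distance`,
`hotspots`, `genes`, `profile`, `enrich`, `raster`, `genesets`, `run`);
`insmap run --config run.yaml --out results/` executes the whole chain
and writes TSV tables plus a JSON summary and manifest.

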