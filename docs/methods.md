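# Methods

## The problem and the model

A tagmentation-based histone-modification assay (antibody-directed Tn5)
called on a tiny sample is compared against reference ChIP-seq, peak set
versus peak set. Disagreement has three distinct sources, which the package
models separately:

1. **Contamination.** Tn5 preferentially cuts open chromatin, so the query
   set contains peaks at accessible loci that carry no true modification.
   A query peak that overlaps no reference ChIP-seq peak but overlaps an
   independent accessibility (ATAC) peak is attributed to this mechanism
   and counted as a false positive. Query-specific peaks *outside*
   accessibility regions are left unattributed — they may be noise or real
   signal the reference missed — and never enter the FPR numerator.

2. **Dropout.** A true modification domain yields no query peak at all.
   This is the quantity the FNR should estimate.

3. **Fragmentation.** Broad repressive domains are read sparsely, so a
   surviving domain is often called as several fragments with internal
   gaps. Reference ChIP-seq represents the same domain as a tiling of
   sub-peaks; sub-peaks that land wholly inside a query gap have no
   overlapping query peak and inflate the naive FNR even though the domain
   was detected. The correction re-filters the missing reference peaks
   against a broad-mode (gap-tolerant) query call and counts as false
   negatives only the peaks missing from both.

Formally, with query `Q`, reference consensus `C` (union of replicates for
the FPR direction, base-level intersection for the FNR direction),
accessibility `A`, and broad-mode query `Q_b`:

```
FPR  = |overlap(subtract(Q, C), A)| / |Q|
FNR  = |subtract(C, Q)| / |C|
FNR* = |subtract(subtract(C, Q), Q_b)| / |C|
```

where `subtract` keeps query-side entries with no ≥1 bp overlap and
`overlap` keeps those with at least one (bedtools `-v` / default
semantics). All coordinates are BED 0-based half-open; abutting intervals
do not overlap; set operations ignore strand. The two consensus modes are
deliberately different: a query peak matching *either* replicate is not
method-specific (union for FPR), while only peaks seen in *both* replicates
are trustworthy enough to be declared missed (intersection for FNR).

Reported percentages are rounded half-up to one decimal; raw ratios are
kept on the result objects and used by all tests.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| overlap threshold | ≥1 bp | what counts as overlapping (no fraction options) |
| broad-merge gap | 2400 bp | gap bridged when emulating a broad-mode call from the query itself (`merge_peaks(query, gap)`); an externally supplied broad call is preferred and used verbatim |
| correlation bin size | 10 kb | genome bin width for track correlation |
| correlation transform | ln(x+1) | natural log, applied before Pearson |
| profile flank | 4 kb | window half-width around the TSS |
| fragment extension | 200 bp | assumed fragment length if coverage were rebuilt from read starts; a no-op for true coverage, kept as provenance |
| promoter window | −3000/+1000 bp | strand-aware around the TSS, precedence promoter > genic > intergenic |
| outlier policy | none | optional MAD trim (threshold 200 scaled MADs) on paired bins before correlation; off by default because outlier rules differ between tools and versions |

The broad-merge default reflects the order of magnitude of the shift-size
used by gap-tolerant peak calling for broad marks; it is a pipeline
convenience, not part of the statistic — when a genuine broad-mode peak set
exists it should be supplied.

## The synthetic-data generator

The generator emulates the study conditions, not the sequencing process:
it plants truth at the peak level and never simulates reads.

- Genome: 3 chromosomes × 1 Mb (sharp preset) or × 10 Mb (broad preset,
  sized to hold 500 domains of ~20 kb with separation margins).
- True domains: 500 per dataset, log-normal lengths (mean ~1 kb sharp,
  ~20 kb broad, σ = 0.35), placed uniformly with enough separation that
  jittered observations and broad-mode merges can never bridge two domains
  — so planted labels stay unambiguous.
- Sharp preset: dropout 0.25, contamination 0.125 — these put the realized
  rates in the low-to-mid twenties (FNR) and 10–15% (FPR), the regime such
  assays show for promoter marks.
- Broad preset: dropout 0.35, contamination 0.2, fragmentation 0.5 with
  internal gaps uniform on 500–5000 bp. Fragmentation carves gaps out of
  the domain interior, keeping both ends, so the generator's broad-mode
  query (fragments merged across gaps up to 5000 bp, the generator's own
  maximum gap) reconstructs the domain span exactly.
- Reference replicates: jittered (±100 bp) observations of the truth with
  5% independent per-replicate domain dropout. For broad marks each
  replicate tiles a domain with ~0.8–1.4 kb sub-peaks separated by
  100–400 bp — the segmented way callers report broad ChIP-seq domains, and
  the mechanism that lets a reference sub-peak sit wholly inside a query
  fragment gap.
- Contamination peaks (500 bp) are planted inside accessibility-only
  regions, which are placed clear of the truth plus the jitter margin, so
  a planted false positive can never overlap any reference observation.
- Paired tracks: two bin-level signals built from a shared standard-normal
  latent mixed with independent noise on the ln(x+1) scale
  (`ln(x+1) = 2 + 0.6·z`), inverse-transformed and clipped at zero; the
  transformed-scale Pearson correlation targets the configured ρ (clipping
  affects ~4·10⁻⁴ of bins and is negligible).
- Expression coverage: genes cycle through planted tiers 9:3:1; read counts
  are Poisson with mean proportional to tier × length, so RPKM tertiles
  recover the tiers, and gene-body coverage equals the tier level with 25%
  multiplicative noise.
- Realized rates are always recomputed from the emitted sets (dropped
  domains / all domains; planted contaminants / emitted query peaks), so
  recovery tests compare estimates to what was actually planted, not to the
  nominal probabilities.

What the generator does *not* emulate — read-level noise, local coverage
structure inside peaks, chromatin-state-dependent contamination, copy
number, mappability — bounds what passing tests show: they validate the
estimators' logic and their bias under dropout/fragmentation/contamination,
not performance on any particular real library.

## Numerical choices and degenerate inputs

- Sorting tie-break is (start, end, name) for byte-stable round trips;
  exact duplicate intervals are collapsed on load and counted in the set's
  provenance.
- Rates with a zero denominator (empty query for FPR, empty reference for
  FNR) raise rather than returning 0 or NaN.
- Gene-body rescaling uses exact fractional binning via the cumulative
  integral, so the rescaled profile conserves total body signal to float
  precision; genes shorter than the bin count are excluded and counted.
  The gene body spans TSS..TES inclusive. Flanks are split into
  `meta_bins // 5` uniform bins by default.
- TSS windows extending past a chromosome end are NaN-padded (column means
  are NaN-aware) and counted; genes whose TSS itself is out of bounds are
  excluded and counted separately.
- RPKM tertiles: `rpkm = count × 10⁹ / (length × total)`, ranked ascending
  with gene-id tie-break; group sizes differ by at most one, extras going
  to the lower-expression groups (100 genes → 34 low / 33 medium /
  33 high).
- Correlation with zero variance in either transformed vector is an error,
  not a silent 0 or 1.
- Chromosomes present in only one input of a set operation trigger a
  warning (the classic silent chr-naming zero-overlap bug); exact string
  match, no aliasing.
- Marker-locus coordinates (e.g. *XIST*) are always supplied by the caller
  or config — they depend on the genome assembly and are never hard-coded.

## Design choices where the design was open

- Interval algebra is implemented in-package (sorted sweeps and binary
  search over numpy arrays) because the contracts — dedup reporting,
  tie-breaks, strict half-open boundary behaviour, parse errors naming line
  numbers — are the point of the module; bedtools serves as an independent
  cross-check in the test suite, and a per-base boolean-array oracle is the
  primary ground truth for every operation.
- FP attribution order is fixed (ChIP filter first, then ATAC overlap): a
  peak overlapping both ChIP and ATAC is reproducible, not a false
  positive.
- Which reference consensus feeds the FPR is configurable
  (`union`/`intersect`/`single`, default union); the FNR reference is
  always the intersect consensus.
- Bivalent domains are the base-level intersection of the activating and
  repressive peak sets — a region-level co-occurrence proxy. Same-cell
  bivalency cannot be established from bulk peak sets; the output carries
  that caveat in its provenance.
- Annotation assigns each peak exactly one category with precedence
  promoter > genic > intergenic so the percentages form a partition;
  tools that report overlapping categories will differ on peaks spanning
  category boundaries.
- Profile values are CPM-scaled mean coverage and profile comparisons are
  shape-based (peak position, group ordering), because absolute profile
  height depends on normalization conventions that vary between tools.

## Problem sizes

Tests and the acceptance script run the generators at 500 true domains per
dataset, 10–20 replicate seeds per estimate, 3000–10 000 correlation bins,
and 100-instance oracle sweeps on ≤100 kb toy genomes — sizes at which the
binomial standard error of a recovered rate is a fraction of a percentage
point, chosen so recovery claims are statistically meaningful at desk
scale.

## Known limitations

- The broad correction rescues reference peaks inside the broad-mode query
  span; it cannot distinguish a genuinely missed reference peak that
  happens to sit between two unrelated query peaks closer than the merge
  gap — with external broad-mode calls this is the caller's problem, with
  the merge emulation it is bounded by the gap parameter.
- FPR attribution is associative, not causal: a query-specific peak in open
  chromatin is *consistent with* transposase bias, not proven to be an
  artifact.
- The FNR compares peak counts, so its value depends on how the reference
  caller segments broad domains; the corrected variant reduces, but does
  not remove, that dependence.
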