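# peakconcord

Peak-set concordance evaluation for low-input, tagmentation-based histone
modification assays (CUT&Tag-style protocols run on single embryos or other
tiny samples) against reference ChIP-seq.

Tn5-based assays disagree with ChIP-seq in two characteristic ways. The
transposase prefers open chromatin, so some called peaks are accessibility
artifacts rather than true modification sites; and broad repressive domains
(H3K27me3-like) are read sparsely, so one domain is often called as several
small fragments — which wrecks any naive peak-count comparison.
`peakconcord` quantifies both effects and corrects for the second:

- **FPR** — the fraction of query peaks that do *not* overlap the reference
  ChIP-seq peaks (union consensus of two replicates) but *do* overlap an
  independent accessibility (ATAC-seq) peak set:
  `FPR = |(Q \ C) ∩ A| / |Q|`.
- **FNR** — the fraction of high-confidence reference peaks (intersect
  consensus of the replicates) with no overlapping query peak:
  `FNR = |R \ Q| / |R|`.
- **Broad-corrected FNR** — missing reference peaks are filtered a second
  time against a broad-mode (gap-tolerant) query call, rescuing reference
  peaks that fall in gaps between fragments of one underlying domain:
  `FNR* = |(R \ Q) \ Q_broad| / |R|`, always ≤ FNR.

All overlaps use bedtools semantics: BED 0-based half-open coordinates,
≥1 bp shared, abutting intervals do not overlap. Around the core statistics
the package provides the standard supporting analyses: genome-binned CPM
signal with ln(x+1) Pearson correlation, TSS and scaled gene-body
metaprofiles stratified by RPKM expression tertile, promoter/genic/
intergenic peak annotation, bivalent-domain calling (activating ∩
repressive peaks) with nearest-TSS gene lists, and presence/absence marker
calls at configured loci (e.g. H3K4me3 at *XIST* as a putative embryo-sex
marker).

Because real datasets of this kind live in external archives, the package
ships a seeded synthetic-data generator that plants the truth — dropout
(false negatives), fragmentation of broad domains, and contamination from
accessibility-only regions (false positives) — so every estimator is tested
against known rates.

## Worked example

```bash
peakconcord simulate --preset broad --seed 2 --outdir sim/
peakconcord concordance \
    --query sim/query.bed \
    --reference sim/chip_rep1.bed --reference sim/chip_rep2.bed \
    --accessibility sim/accessibility.bed \
    --broad sim/query_broad.bed
```

prints (seed 2):

```
wrote broad dataset to sim: 905 query peaks, planted FP rate 0.196, planted FN rate 0.384
{
  "sample": "query",
  "total_peaks": 905,
  "fp_n": 177,
  "fpr_percent": 19.6,
  "reference_n": 6698,
  "fn_n": 3094,
  "fnr_percent": 46.2,
  "fnr_corrected_percent": 38.7
}
```

Read: of 905 query peaks, 177 (19.6%) miss the ChIP-seq consensus but sit
in accessibility peaks — exactly the planted 19.6% contamination. The naive
FNR (46.2%) overstates the planted 38.4% dropout because fragmented broad
domains leave reference sub-peaks uncovered; filtering the missing peaks
against the broad-mode query set corrects it to 38.7%.

The same evaluation runs declaratively over many samples via
`peakconcord all --config run.yaml`, and the `analysis/` scripts
(`01_simulate.py` … `04_annotation_markers.py`) walk the full study —
simulation, concordance, signal summaries, annotation and marker calls —
writing their tables under `results/`.

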