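"""Genomic-context annotation, bivalent domains, and marker-locus calls.

Annotates the sharp-mark query peaks from 01_simulate.py against the
synthetic gene models (promoter > genic > intergenic), intersects the
sharp and broad query sets into putative bivalent domains with their
nearest-TSS gene list, and calls marker-locus presence across a planted
half/half cohort (the XIST-style sexing dichotomy). Writes
results/annotation_summary.tsv, results/bivalent.bed,
results/bivalent_genes.txt and results/marker_calls.tsv.

Run:  python analysis/04_annotation_markers.py [--seed N]
"""

import argparse
from pathlib import Path

from peakconcord import synth
from peakconcord.annotation import (
    annotate_peaks,
    bivalent_domains,
    chromosome_distribution,
    domains_to_genes,
    marker_presence,
    read_gene_table,
)
from peakconcord.intervals import GenomicInterval, read_bed, write_bed

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int) -> None:
    sharp_dir = RESULTS / "data" / "sharp"
    broad_dir = RESULTS / "data" / "broad"
    query = read_bed(sharp_dir / "query.bed", label="sharp")
    genes = read_gene_table(sharp_dir / "genes.tsv")

    summary = annotate_peaks(query, genes)
    with open(RESULTS / "annotation_summary.tsv", "w") as fh:
        fh.write("category\tcount\tpercent\n")
        for cat in ("promoter", "genic", "intergenic"):
            fh.write(f"{cat}\t{summary.per_category_counts[cat]}\t"
                     f"{summary.per_category_percent[cat]:.1f}\n")
        fh.write("#chromosome\tcount\n")
        for chrom, n in sorted(chromosome_distribution(query).items()):
            fh.write(f"#{chrom}\t{n}\n")
    print("peak annotation: " + ", ".join(
        f"{c}={summary.per_category_percent[c]:.1f}%"
        for c in ("promoter", "genic", "intergenic")))

    # bivalency: sharp and broad marks live on different toy genomes, so
    # re-generate a broad query on the sharp genome for the intersection
    cfg = synth.broad_config(seed, chrom_sizes=synth.sharp_config(seed).chrom_sizes,
                             n_true_domains=40, domain_length_mean=8000.0)
    import numpy as np

    rng = np.random.default_rng(seed)
    k27_truth = synth.generate_true_domains(cfg, rng)
    atac = synth.generate_accessibility_peaks(k27_truth, cfg, rng)
    k27_query, _, _ = synth.generate_observed_peaks(k27_truth, atac, cfg, rng)
    domains = bivalent_domains(query, k27_query)
    write_bed(domains, RESULTS / "bivalent.bed")
    gene_list = domains_to_genes(domains, genes)
    (RESULTS / "bivalent_genes.txt").write_text("".join(g + "\n" for g in gene_list))
    print(f"bivalent domains: {domains.count()} regions, "
          f"{len(gene_list)} nearest-TSS genes")

    locus = GenomicInterval("chr2", 400_000, 410_000, name="XIST")
    cohort, labels = synth.generate_marker_cohort(
        synth.sharp_config(seed), locus, n_samples=10
    )
    with open(RESULTS / "marker_calls.tsv", "w") as fh:
        fh.write("sample\tlocus\tpresent\tsupporting_peaks\tplanted\tinterpretation\n")
        n_correct = 0
        for sample, planted in zip(cohort, labels):
            call = marker_presence(sample, locus, "putative female", "putative male")
            n_correct += call.present == planted
            fh.write(f"{call.sample}\t{locus.name}\t{int(call.present)}\t"
                     f"{call.supporting_peaks}\t{int(planted)}\t"
                     f"{call.interpretation}\n")
    print(f"marker calls: {n_correct}/{len(labels)} correct on the planted cohort")


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    main(parser.parse_args().seed)
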