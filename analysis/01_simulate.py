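"""Generate the two synthetic study datasets (sharp and broad marks).

Writes a complete dataset per preset under results/data/<preset>/: query
peaks (with planted contamination, dropout and — for the broad mark —
fragmentation), broad-mode query peaks, two jittered reference ChIP-seq
replicates, accessibility peaks, the true domains, gene models, chromosome
sizes, and a truth manifest with the realized planted rates.

Run from the repository root:  python analysis/01_simulate.py [--seed N]
"""

import argparse
from pathlib import Path

import numpy as np

from peakconcord import synth
from peakconcord.annotation import write_gene_table
from peakconcord.intervals import write_bed

RESULTS = Path(__file__).resolve().parent.parent / "results"


def simulate(preset: str, seed: int) -> None:
    cfg = synth.sharp_config(seed) if preset == "sharp" else synth.broad_config(seed)
    rng = np.random.default_rng(seed)
    outdir = RESULTS / "data" / preset
    outdir.mkdir(parents=True, exist_ok=True)
    chrom_sizes, genes = synth.generate_genome(cfg, rng)
    truth = synth.generate_true_domains(cfg, rng)
    atac = synth.generate_accessibility_peaks(truth, cfg, rng)
    query, query_broad, t = synth.generate_observed_peaks(truth, atac, cfg, rng)
    rep_a, rep_b = synth.generate_reference_replicates(truth, cfg, rng)
    for name, peaks in [
        ("query", query), ("query_broad", query_broad), ("chip_rep1", rep_a),
        ("chip_rep2", rep_b), ("accessibility", atac), ("true_domains", truth),
    ]:
        write_bed(peaks, outdir / f"{name}.bed")
    write_gene_table(genes, outdir / "genes.tsv")
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom, size in sorted(chrom_sizes.items()):
            fh.write(f"{chrom}\t{size}\n")
    synth.write_truth_manifest(t, cfg, outdir / "truth.json")
    print(
        f"{preset}: {truth.count()} true domains -> {query.count()} query peaks "
        f"({t.planted_fp_peaks.count()} planted contaminants, "
        f"{t.planted_fn_domains.count()} dropped domains); "
        f"planted FP rate {100 * t.realized_fp_rate:.1f}%, "
        f"FN rate {100 * t.realized_fn_rate:.1f}%"
    )


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    for preset in ("sharp", "broad"):
        simulate(preset, args.seed)
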