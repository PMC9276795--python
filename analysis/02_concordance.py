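"""Concordance evaluation: FPR with open-chromatin attribution, FNR with the
broad-peak fragmentation correction.

Reads the datasets written by 01_simulate.py, computes each rate against
the appropriate replicate consensus (union for FPR, intersect for FNR),
and compares the estimates to the planted truth. Writes
results/concordance_summary.tsv and per-sample classification BEDs.

Run:  python analysis/02_concordance.py
"""

import json
from pathlib import Path

from peakconcord.concordance import (
    compute_fnr,
    compute_fnr_broad_corrected,
    compute_fpr,
    consensus_intersect,
    consensus_union,
)
from peakconcord.intervals import read_bed

RESULTS = Path(__file__).resolve().parent.parent / "results"


def evaluate(preset: str) -> dict:
    d = RESULTS / "data" / preset
    query = read_bed(d / "query.bed", label=preset)
    query_broad = read_bed(d / "query_broad.bed")
    rep_a = read_bed(d / "chip_rep1.bed")
    rep_b = read_bed(d / "chip_rep2.bed")
    atac = read_bed(d / "accessibility.bed")
    truth = json.loads((d / "truth.json").read_text())

    fpr = compute_fpr(query, consensus_union(rep_a, rep_b), atac)
    ref = consensus_intersect(rep_a, rep_b)
    fnr = compute_fnr(ref, query)
    fnr_c = compute_fnr_broad_corrected(ref, query, query_broad)

    with open(RESULTS / f"{preset}.classification.bed", "w") as fh:
        for iv in query:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{fpr.classification[iv.coords]}\n"
            )
    return {
        "sample": preset,
        "total_peaks": fpr.total_query_peaks,
        "fp_n": fpr.false_positive_peaks,
        "fpr_percent": fpr.fpr_percent,
        "planted_fp_percent": round(100 * truth["realized_fp_rate"], 1),
        "reference_n": fnr.reference_peak_count,
        "fn_n": fnr.false_negative_peaks,
        "fnr_percent": fnr.fnr_percent,
        "fnr_corrected_percent": fnr_c.fnr_percent,
        "planted_fn_percent": round(100 * truth["realized_fn_rate"], 1),
    }


if __name__ == "__main__":
    rows = [evaluate(p) for p in ("sharp", "broad")]
    cols = list(rows[0])
    out = RESULTS / "concordance_summary.tsv"
    with open(out, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    for row in rows:
        print(
            f"{row['sample']}: FPR {row['fpr_percent']}% "
            f"(planted {row['planted_fp_percent']}%), "
            f"FNR {row['fnr_percent']}% -> corrected "
            f"{row['fnr_corrected_percent']}% "
            f"(planted {row['planted_fn_percent']}%)"
        )
    print(f"wrote {out}")
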