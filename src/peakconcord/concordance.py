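"""Replicate consensus and false-positive / false-negative rates.

The evaluation compares a low-input assay's peak set (the *query*) against
reference ChIP-seq peaks, attributing query-specific peaks to Tn5
open-chromatin bias when they fall in accessibility (ATAC) peaks:

* **FPR** — query peaks that do **not** overlap the reference ChIP-seq set
  but **do** overlap the accessibility set, divided by the total number of
  query peaks. The reference for this direction is the *union* consensus of
  the ChIP-seq replicates (a query peak matching either replicate is not
  method-specific).

* **FNR** — reference peaks with no overlapping query peak, divided by the
  number of reference peaks. The reference here is the *intersect*
  consensus of the replicates (high-confidence peaks only).

* **Broad-corrected FNR** — broad repressive domains tend to be called as
  small fragments by tagmentation-based assays, so a reference peak can
  fall in a gap between query fragments of the same underlying domain.
  The missing reference peaks are therefore filtered a second time against
  a broad-mode query set (an externally supplied gap-tolerant call, or
  ``merge_peaks(query, gap)`` as an emulation); only peaks surviving both
  filters count as false negatives.

Percentages are rounded half-up to one decimal place, matching the
precision at which such rates are conventionally reported; raw ratios are
retained on the result object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .intervals import (
    GenomicInterval,
    PeakSet,
    intersect_regions,
    merge_peaks,
    nonoverlapping_subset,
    overlapping_subset,
)

__all__ = [
    "ConcordanceResult",
    "UndefinedRateError",
    "consensus_union",
    "consensus_intersect",
    "compute_fpr",
    "compute_fnr",
    "compute_fnr_broad_corrected",
    "rate_percent",
    "DEFAULT_BROAD_MERGE_GAP",
]

# Emulates a broad-mode re-call when no external broad peak set is given;
# same order of magnitude as the shift-size used for gap-tolerant calling.
DEFAULT_BROAD_MERGE_GAP = 2400

REPRODUCIBLE = "reproducible"
FP_OPEN_CHROMATIN = "false_positive_open_chromatin"
QUERY_SPECIFIC = "query_specific_unattributed"
MISSING = "missing"


class UndefinedRateError(ZeroDivisionError):
    """A rate was requested with a zero denominator."""


def rate_percent(numerator: int, denominator: int) -> float:
    """``100 * numerator / denominator`` rounded half-up to one decimal."""
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    if denominator <= 0:
        raise UndefinedRateError("rate undefined for non-positive denominator")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class ConcordanceResult:
    """Counts, rates, and per-peak classification for one comparison.

    Either the FPR fields or the FNR fields are populated depending on the
    computing operation; ``classification`` maps each peak's
    ``(chrom, start, end)`` to its class label.
    """

    total_query_peaks: int | None = None
    false_positive_peaks: int | None = None
    fpr_percent: float | None = None
    fpr_raw: float | None = None
    reference_peak_count: int | None = None
    false_negative_peaks: int | None = None
    fnr_percent: float | None = None
    fnr_raw: float | None = None
    classification: dict[tuple[str, int, int], str] = field(default_factory=dict)


def consensus_union(rep_a: PeakSet, rep_b: PeakSet) -> PeakSet:
    """Merged union of two replicate peak sets (permissive consensus)."""
    combined = PeakSet(
        list(rep_a) + list(rep_b),
        label=f"{rep_a.label}|{rep_b.label}",
        provenance={"consensus": "union", "parents": [rep_a.label, rep_b.label]},
    )
    return merge_peaks(combined)


def consensus_intersect(rep_a: PeakSet, rep_b: PeakSet) -> PeakSet:
    """Base-level intersection of two replicates (high-confidence consensus)."""
    out = intersect_regions(rep_a, rep_b)
    out.provenance["consensus"] = "intersect"
    return out


def compute_fpr(
    query: PeakSet, reference_chip: PeakSet, accessibility: PeakSet
) -> ConcordanceResult:
    """False-positive rate with open-chromatin attribution.

    FP peaks are query peaks that miss the ChIP-seq reference entirely yet
    overlap an accessibility peak; the filter order (ChIP first, then ATAC)
    follows the definition of the rate. Query peaks overlapping the
    reference are classified reproducible; query-specific peaks outside
    accessibility regions stay unattributed and do not count as FP.
    """
    total = query.count()
    if total == 0:
        raise UndefinedRateError("FPR undefined for an empty query peak set")
    specific = nonoverlapping_subset(query, reference_chip)
    fp = overlapping_subset(specific, accessibility)
    fp_keys = {iv.coords for iv in fp}
    specific_keys = {iv.coords for iv in specific}
    classification: dict[tuple[str, int, int], str] = {}
    for iv in query:
        if iv.coords in fp_keys:
            classification[iv.coords] = FP_OPEN_CHROMATIN
        elif iv.coords in specific_keys:
            classification[iv.coords] = QUERY_SPECIFIC
        else:
            classification[iv.coords] = REPRODUCIBLE
    n_fp = fp.count()
    return ConcordanceResult(
        total_query_peaks=total,
        false_positive_peaks=n_fp,
        fpr_percent=rate_percent(n_fp, total),
        fpr_raw=n_fp / total,
        classification=classification,
    )


def compute_fnr(reference_chip: PeakSet, query: PeakSet) -> ConcordanceResult:
    """False-negative rate: reference peaks with no query overlap."""
    n_ref = reference_chip.count()
    if n_ref == 0:
        raise UndefinedRateError("FNR undefined for an empty reference peak set")
    fn = nonoverlapping_subset(reference_chip, query)
    fn_keys = {iv.coords for iv in fn}
    classification = {
        iv.coords: (MISSING if iv.coords in fn_keys else REPRODUCIBLE)
        for iv in reference_chip
    }
    n_fn = fn.count()
    return ConcordanceResult(
        reference_peak_count=n_ref,
        false_negative_peaks=n_fn,
        fnr_percent=rate_percent(n_fn, n_ref),
        fnr_raw=n_fn / n_ref,
        classification=classification,
    )


def compute_fnr_broad_corrected(
    reference_chip: PeakSet, query: PeakSet, query_broad: PeakSet
) -> ConcordanceResult:
    """FNR with the broad-peak fragmentation correction.

    Reference peaks missing from the query are filtered a second time
    against ``query_broad`` (a gap-tolerant broad-mode call of the same
    sample): a reference peak sitting in a gap between fragments of one
    broad domain is rescued rather than counted missing. The corrected FNR
    is never above the uncorrected one.
    """
    n_ref = reference_chip.count()
    if n_ref == 0:
        raise UndefinedRateError("FNR undefined for an empty reference peak set")
    fn_first = nonoverlapping_subset(reference_chip, query)
    fn = nonoverlapping_subset(fn_first, query_broad)
    fn_keys = {iv.coords for iv in fn}
    classification = {
        iv.coords: (MISSING if iv.coords in fn_keys else REPRODUCIBLE)
        for iv in reference_chip
    }
    n_fn = fn.count()
    return ConcordanceResult(
        reference_peak_count=n_ref,
        false_negative_peaks=n_fn,
        fnr_percent=rate_percent(n_fn, n_ref),
        fnr_raw=n_fn / n_ref,
        classification=classification,
    )
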