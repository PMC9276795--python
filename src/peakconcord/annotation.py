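"""Peak annotation, bivalent-domain calling, and locus-presence marker calls.

Genes are modelled by their transcription start and end sites (TSS/TES) on
a strand; a peak is assigned to exactly one category with precedence
promoter > genic > intergenic, where the promoter is a strand-aware window
around the TSS (default 3 kb upstream / 1 kb downstream, the conventional
span for promoter-proximal annotation). Bivalent domains are the
base-level co-occurrence of an activating (H3K4me3-like) and a repressive
(H3K27me3-like) peak set — a region-level proxy; co-occurrence in the same
cells would need re-ChIP-type assays, which is recorded as a caveat in the
output provenance. Marker presence at a configured locus (e.g. XIST for
putative embryo sexing) is a simple >=1 bp overlap call.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .intervals import (
    GenomicInterval,
    PeakSet,
    intersect_regions,
    merge_peaks,
    overlapping_subset,
)

__all__ = [
    "GeneModel",
    "AnnotationSummary",
    "MarkerCall",
    "read_gene_table",
    "write_gene_table",
    "annotate_peaks",
    "chromosome_distribution",
    "bivalent_domains",
    "domains_to_genes",
    "marker_presence",
    "DEFAULT_PROMOTER_UPSTREAM",
    "DEFAULT_PROMOTER_DOWNSTREAM",
]

DEFAULT_PROMOTER_UPSTREAM = 3000
DEFAULT_PROMOTER_DOWNSTREAM = 1000


@dataclass(frozen=True)
class GeneModel:
    """A gene as strand-aware TSS/TES anchors.

    For plus-strand genes ``tss < tes``; for minus-strand genes
    ``tss > tes`` (the TSS is the 5' end in transcription direction).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        if self.tss == self.tes:
            raise ValueError(f"gene {self.gene_id!r}: tss == tes")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"gene {self.gene_id!r}: plus strand needs tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"gene {self.gene_id!r}: minus strand needs tss > tes")

    @property
    def span(self) -> GenomicInterval:
        lo, hi = min(self.tss, self.tes), max(self.tss, self.tes)
        return GenomicInterval(self.chrom, lo, hi + 1, name=self.gene_id,
                               strand=self.strand)

    def promoter(self, upstream: int, downstream: int) -> GenomicInterval | None:
        """Strand-aware promoter window ``[TSS - upstream, TSS + downstream)``.

        Mirrored for minus-strand genes; clipped at position 0. Returns
        None if the clipped window is empty.
        """
        if self.strand == "+":
            lo, hi = self.tss - upstream, self.tss + downstream
        else:
            lo, hi = self.tss + 1 - downstream, self.tss + 1 + upstream
        lo = max(lo, 0)
        if lo >= hi:
            return None
        return GenomicInterval(self.chrom, lo, hi, name=self.gene_id)


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a tab-separated gene table: gene_id, chrom, strand, tss, tes."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields")
            try:
                genes.append(
                    GeneModel(fields[0], fields[1], fields[2],
                              int(fields[3]), int(fields[4]))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.tes}\n")


@dataclass
class AnnotationSummary:
    """Category and chromosome tallies plus the per-peak category map."""

    per_category_counts: dict[str, int]
    per_category_percent: dict[str, float]
    per_chromosome_counts: dict[str, int]
    peak_categories: dict[tuple[str, int, int], str]

    @property
    def total(self) -> int:
        return sum(self.per_category_counts.values())


def annotate_peaks(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    promoter_upstream: int = DEFAULT_PROMOTER_UPSTREAM,
    promoter_downstream: int = DEFAULT_PROMOTER_DOWNSTREAM,
) -> AnnotationSummary:
    """Assign each peak one category: promoter > genic > intergenic.

    A peak overlapping (>=1 bp) any promoter window is a promoter peak
    regardless of gene-body overlaps elsewhere; otherwise overlap with any
    gene span makes it genic; the rest are intergenic.
    """
    if promoter_upstream < 0 or promoter_downstream < 0:
        raise ValueError("promoter window sizes must be non-negative")
    promoters = PeakSet(
        [p for g in genes
         if (p := g.promoter(promoter_upstream, promoter_downstream)) is not None],
        label="promoters",
    )
    spans = PeakSet([g.span for g in genes], label="gene_spans")
    # peaks on gene-less chromosomes are a legitimate intergenic case, not
    # the naming-mismatch bug the set-algebra warning guards against
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)
        prom_hits = {iv.coords for iv in overlapping_subset(peaks, promoters)}
        genic_hits = {iv.coords for iv in overlapping_subset(peaks, spans)}
    categories: dict[tuple[str, int, int], str] = {}
    counts = {"promoter": 0, "genic": 0, "intergenic": 0}
    per_chrom: dict[str, int] = {}
    for iv in peaks:
        if iv.coords in prom_hits:
            cat = "promoter"
        elif iv.coords in genic_hits:
            cat = "genic"
        else:
            cat = "intergenic"
        categories[iv.coords] = cat
        counts[cat] += 1
        per_chrom[iv.chrom] = per_chrom.get(iv.chrom, 0) + 1
    total = peaks.count()
    percent = {
        k: (100.0 * v / total if total else 0.0) for k, v in counts.items()
    }
    return AnnotationSummary(
        per_category_counts=counts,
        per_category_percent=percent,
        per_chromosome_counts=per_chrom,
        peak_categories=categories,
    )


def chromosome_distribution(peaks: PeakSet) -> dict[str, int]:
    """Peak counts per chromosome; values sum to the total peak count."""
    return {c: len(peaks.on_chrom(c)) for c in peaks.chromosomes()}


def bivalent_domains(k4: PeakSet, k27: PeakSet) -> PeakSet:
    """Regions where the activating and repressive peak sets coincide.

    Base-level intersection; a region-level co-occurrence proxy (same-cell
    bivalency is not assessable from bulk peak sets — noted in provenance).
    """
    domains = intersect_regions(k4, k27)
    domains.label = "bivalent"
    domains.provenance.update(
        {
            "parents": [k4.label, k27.label],
            "caveat": "region-level co-occurrence proxy; same-cell bivalency "
            "requires re-ChIP-type assays",
        }
    )
    return domains


def _tss_distance(g: GeneModel, iv: GenomicInterval) -> int:
    if iv.start <= g.tss < iv.end:
        return 0
    if g.tss < iv.start:
        return iv.start - g.tss
    return g.tss - (iv.end - 1)


def domains_to_genes(
    domains: PeakSet, genes: Sequence[GeneModel], max_distance: int = 100_000
) -> list[str]:
    """Nearest-TSS gene per domain within ``max_distance``; deduplicated.

    Ties on distance resolve to the lexicographically smaller gene id.
    Returns a sorted unique gene-id list (input for external enrichment
    tools).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    hits: set[str] = set()
    for iv in domains:
        best: tuple[int, str] | None = None
        for g in by_chrom.get(iv.chrom, ()):
            d = _tss_distance(g, iv)
            if d <= max_distance:
                key = (d, g.gene_id)
                if best is None or key < best:
                    best = key
        if best is not None:
            hits.add(best[1])
    return sorted(hits)


@dataclass
class MarkerCall:
    """Presence/absence of any peak at a marker locus for one sample."""

    sample: str
    locus: GenomicInterval
    present: bool
    supporting_peaks: int
    interpretation: str = ""


def marker_presence(
    peaks: PeakSet,
    locus: GenomicInterval,
    present_label: str = "",
    absent_label: str = "",
) -> MarkerCall:
    """Call a locus present when >=1 peak shares >=1 bp with it.

    For the XIST application the interpretation labels are
    "putative female" (present) / "putative male" (absent); the labels are
    metadata only and never affect the call.
    """
    locus_set = PeakSet([locus], label="locus")
    # restrict to the locus chromosome: a single-locus query against a
    # genome-wide peak set is not a chromosome-naming mismatch
    on_chrom = PeakSet(peaks.on_chrom(locus.chrom), label=peaks.label)
    supporting = (
        overlapping_subset(on_chrom, locus_set).count() if on_chrom.count() else 0
    )
    present = supporting >= 1
    return MarkerCall(
        sample=peaks.label,
        locus=locus,
        present=present,
        supporting_peaks=supporting,
        interpretation=present_label if present else absent_label,
    )
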