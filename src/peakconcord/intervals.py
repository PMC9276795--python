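"""Genomic interval model, BED I/O, and interval set algebra.

All coordinates are BED-style: 0-based, half-open ``[start, end)``. Two
intervals that merely abut (one ends where the other starts) do not
overlap. Peak sets are kept sorted per chromosome by ``(start, end, name)``
and deduplicated on construction; the set operations below reproduce the
semantics of ``bedtools intersect`` with its default (``-u``-like) and
``-v`` options, which is how method-specific and shared peaks are defined
throughout the concordance analysis.

Strand is carried but ignored by every set operation here: histone peaks
are unstranded. Strand matters only for gene anchoring in the annotation
and profile modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "BedParseError",
    "read_bed",
    "write_bed",
    "merge_peaks",
    "overlapping_subset",
    "nonoverlapping_subset",
    "intersect_regions",
]

_VALID_STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Raised for malformed BED input; carries the offending line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named chromosome.

    Empty and negative intervals are rejected: ``start`` must be a
    non-negative integer strictly below ``end``.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def coords(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def sort_key(self) -> tuple[int, int, str]:
        return (self.start, self.end, self.name or "")


class PeakSet:
    """A chromosome-keyed, sorted, deduplicated collection of intervals.

    Parameters
    ----------
    intervals
        Any iterable of :class:`GenomicInterval`. Exact duplicates
        (identical chrom/start/end/name/score/strand) are collapsed; the
        number removed is recorded as ``duplicates_removed`` in
        :attr:`provenance`.
    label
        Sample identifier, carried through reports.
    provenance
        Free-form metadata (e.g. upstream peak-caller parameters).
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        label: str = "",
        provenance: Mapping[str, object] | None = None,
    ) -> None:
        self.label = label
        self.provenance: dict[str, object] = dict(provenance or {})
        by_chrom: dict[str, list[GenomicInterval]] = {}
        n_in = 0
        for iv in intervals:
            n_in += 1
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self._by_chrom: dict[str, list[GenomicInterval]] = {}
        n_kept = 0
        for chrom in sorted(by_chrom):
            ivs = sorted(set(by_chrom[chrom]), key=GenomicInterval.sort_key)
            self._by_chrom[chrom] = ivs
            n_kept += len(ivs)
        dups = n_in - n_kept
        if dups:
            self.provenance["duplicates_removed"] = dups

    # -- container protocol -------------------------------------------------

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self._by_chrom:
            yield from self._by_chrom[chrom]

    def __len__(self) -> int:
        return self.count()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self._by_chrom == other._by_chrom

    def count(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def on_chrom(self, chrom: str) -> list[GenomicInterval]:
        return list(self._by_chrom.get(chrom, ()))

    def total_bases(self) -> int:
        """Bases covered counting overlaps once (union coverage)."""
        return merge_peaks(self).sum_of_lengths()

    def sum_of_lengths(self) -> int:
        return sum(len(iv) for iv in self)

    def _arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        ivs = self._by_chrom.get(chrom, ())
        starts = np.fromiter((iv.start for iv in ivs), dtype=np.int64, count=len(ivs))
        ends = np.fromiter((iv.end for iv in ivs), dtype=np.int64, count=len(ivs))
        return starts, ends

    def replace(self, intervals: Iterable[GenomicInterval], **prov: object) -> "PeakSet":
        """New PeakSet with these intervals, inheriting label/provenance."""
        p = dict(self.provenance)
        p.pop("duplicates_removed", None)
        p.update(prov)
        return PeakSet(intervals, label=self.label, provenance=p)

    def __repr__(self) -> str:
        return (
            f"PeakSet(label={self.label!r}, n={self.count()}, "
            f"chroms={len(self._by_chrom)})"
        )


# -- BED I/O ----------------------------------------------------------------

_SKIP_PREFIXES = ("track", "browser", "#")


def read_bed(path: str | Path, label: str | None = None) -> PeakSet:
    """Read a BED3–BED6 file into a :class:`PeakSet`.

    Coordinates are taken as 0-based half-open. ``track``/``browser``/``#``
    lines and blank lines are skipped. Malformed data lines raise
    :class:`BedParseError` naming the 1-based line number. An empty file
    yields an empty set.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[1]!r}, {fields[2]!r}"
                ) from exc
            name = fields[3] if len(fields) > 3 else None
            score: float | None = None
            if len(fields) > 4:
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}:{lineno}: non-numeric score {fields[4]!r}"
                    ) from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name, score, strand)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(intervals, label=label if label is not None else path.stem)


def _format_score(score: float) -> str:
    if float(score).is_integer():
        return str(int(score))
    return format(score, "g")


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as headerless tab-separated BED.

    Chromosomes in lexicographic order, intervals sorted; per interval the
    line extends to the last populated optional field, with ``.`` / ``0``
    placeholders for gaps so columns stay positional.
    """
    with open(path, "w") as fh:
        for iv in peaks:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.strand != ".":
                n = 6
            elif iv.score is not None:
                n = 5
            elif iv.name is not None:
                n = 4
            else:
                n = 3
            if n >= 4:
                fields.append(iv.name if iv.name is not None else ".")
            if n >= 5:
                fields.append(_format_score(iv.score) if iv.score is not None else "0")
            if n >= 6:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


# -- set algebra ------------------------------------------------------------


def _warn_chrom_mismatch(a: PeakSet, b: PeakSet) -> None:
    only_a = set(a.chromosomes()) - set(b.chromosomes())
    only_b = set(b.chromosomes()) - set(a.chromosomes())
    if a.count() and b.count() and (only_a or only_b):
        # Silent naming mismatches (chr1 vs 1) are the classic zero-overlap
        # bug; a warning is cheap insurance.
        warnings.warn(
            "chromosomes present in only one input: "
            f"{sorted(only_a)} vs {sorted(only_b)}",
            stacklevel=3,
        )


def merge_peaks(peaks: PeakSet, gap: int = 0) -> PeakSet:
    """Merge intervals separated by at most ``gap`` bp.

    With ``gap=0``, overlapping and abutting intervals join; the result is
    the minimal sorted set covering the same bases, satisfying the
    non-overlap invariant. Merged intervals drop names/scores/strands.
    """
    if gap < 0:
        raise ValueError(f"gap must be non-negative, got {gap}")
    out: list[GenomicInterval] = []
    for chrom in peaks.chromosomes():
        cur_s = cur_e = None
        for iv in peaks.on_chrom(chrom):
            if cur_s is None:
                cur_s, cur_e = iv.start, iv.end
            elif iv.start <= cur_e + gap:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        if cur_s is not None:
            out.append(GenomicInterval(chrom, cur_s, cur_e))
    return peaks.replace(out, merged_gap=gap)


def _overlap_mask(query: PeakSet, reference: PeakSet) -> dict[str, np.ndarray]:
    """Per-chromosome boolean mask: query interval shares >=1 bp with reference."""
    ref_merged = merge_peaks(reference)
    masks: dict[str, np.ndarray] = {}
    for chrom in query.chromosomes():
        q_starts, q_ends = query._arrays(chrom)
        r_starts, r_ends = ref_merged._arrays(chrom)
        if len(r_starts) == 0:
            masks[chrom] = np.zeros(len(q_starts), dtype=bool)
            continue
        # Rightmost merged reference interval starting before the query end;
        # overlap iff that interval extends past the query start.
        idx = np.searchsorted(r_starts, q_ends, side="left") - 1
        hit = idx >= 0
        hit[hit] = r_ends[idx[hit]] > q_starts[hit]
        masks[chrom] = hit
    return masks


def overlapping_subset(query: PeakSet, reference: PeakSet) -> PeakSet:
    """Query intervals sharing >=1 bp with any reference interval.

    Coordinates are reported unmodified; each query interval appears at
    most once (``bedtools intersect -u`` semantics).
    """
    _warn_chrom_mismatch(query, reference)
    masks = _overlap_mask(query, reference)
    kept = [
        iv
        for chrom in query.chromosomes()
        for iv, hit in zip(query.on_chrom(chrom), masks[chrom])
        if hit
    ]
    return query.replace(kept)


def nonoverlapping_subset(query: PeakSet, reference: PeakSet) -> PeakSet:
    """Query intervals with no overlap in reference (``bedtools -v``).

    Exact complement of :func:`overlapping_subset` within the query.
    """
    _warn_chrom_mismatch(query, reference)
    masks = _overlap_mask(query, reference)
    kept = [
        iv
        for chrom in query.chromosomes()
        for iv, hit in zip(query.on_chrom(chrom), masks[chrom])
        if not hit
    ]
    return query.replace(kept)


def intersect_regions(a: PeakSet, b: PeakSet) -> PeakSet:
    """Base-level intersection as maximal merged intervals."""
    _warn_chrom_mismatch(a, b)
    am, bm = merge_peaks(a), merge_peaks(b)
    out: list[GenomicInterval] = []
    for chrom in am.chromosomes():
        a_ivs = am.on_chrom(chrom)
        b_ivs = bm.on_chrom(chrom)
        i = j = 0
        while i < len(a_ivs) and j < len(b_ivs):
            lo = max(a_ivs[i].start, b_ivs[j].start)
            hi = min(a_ivs[i].end, b_ivs[j].end)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if a_ivs[i].end <= b_ivs[j].end:
                i += 1
            else:
                j += 1
    return PeakSet(
        out,
        label=f"{a.label}&{b.label}" if a.label and b.label else a.label or b.label,
        provenance={"operation": "intersect", "parents": [a.label, b.label]},
    )
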