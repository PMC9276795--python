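"""Seeded synthetic data with planted ground truth.

The generator emulates the two bias mechanisms that make a Tn5
(tagmentation) based assay disagree with reference ChIP-seq:

* **Contamination** — the transposase prefers open chromatin, so some
  called peaks sit in accessibility (ATAC-like) regions that carry no true
  modification. Planted contamination peaks are placed inside
  accessibility-only regions and are the ground truth for the
  false-positive rate.

* **Dropout and fragmentation** — true domains can be missed outright
  (planting false negatives), and surviving *broad* domains are called as
  several small fragments with internal gaps, which inflates a naive
  peak-count FNR. The generator carves uniform 500–5000 bp gaps out of the
  interior of a fragmented domain, keeping both domain ends, so a
  gap-tolerant broad-mode call (fragments merged across gaps up to the
  generator's maximum gap) reconstructs the domain span.

Reference replicates are jittered observations of the truth. For sharp
marks each domain is one reference peak; for broad marks each replicate
tiles a domain with ~1 kb sub-peaks separated by small gaps, the way
ChIP-seq peak callers segment broad domains — this is what lets a
reference sub-peak fall wholly inside a query fragment gap, the
overestimation the broad correction repairs.

Everything is deterministic under (config, seed); realized planted rates
are recorded from the emitted sets, not the nominal probabilities, so
recovery tests compare like with like.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .intervals import GenomicInterval, PeakSet, merge_peaks, nonoverlapping_subset
from .annotation import GeneModel
from .signal_profiles import BinnedTrack, Coverage

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "sharp_config",
    "broad_config",
    "generate_genome",
    "generate_true_domains",
    "generate_accessibility_peaks",
    "generate_observed_peaks",
    "generate_reference_replicates",
    "generate_paired_tracks",
    "generate_expression_coverage",
    "generate_marker_cohort",
]


def _default_chrom_sizes() -> dict[str, int]:
    return {"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000}


@dataclass
class SyntheticConfig:
    """Generative parameters; the defaults are the study conditions.

    Sharp-mark defaults emulate a promoter mark (short domains, FNR in the
    low twenties of percent, FPR 10–15%); broad-mark defaults emulate a
    repressive domain mark (long domains, heavier dropout and
    contamination, and fragmentation of half the surviving domains).
    """

    seed: int = 0
    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    n_genes: int = 150
    mark_type: str = "sharp"  # "sharp" or "broad"
    n_true_domains: int = 500
    # log-normal domain lengths: sharp mean ~1 kb, broad mean ~20 kb
    domain_length_mean: float = 1000.0
    domain_length_sigma: float = 0.35
    dropout_rate: float = 0.25
    fragmentation: float = 0.0  # probability a surviving broad domain splits
    fragment_gap_range: tuple[int, int] = (500, 5000)
    n_accessibility_peaks: int = 800
    accessibility_peak_length: int = 1000
    contamination_rate: float = 0.125
    boundary_jitter: int = 100
    replicate_dropout: float = 0.05
    # broad-mode call emulation: merge fragments across gaps up to the
    # generator's own maximum internal gap (a broad-mode caller recognizes
    # the pieces of one domain as one peak)
    broad_call_gap: int | None = None
    signal_noise: float = 0.25
    target_correlation: float = 0.9
    n_track_bins: int = 3000
    max_retries: int = 1000

    def __post_init__(self) -> None:
        for p in (self.dropout_rate, self.fragmentation, self.contamination_rate,
                  self.replicate_dropout):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.mark_type not in ("sharp", "broad"):
            raise ValueError(f"mark_type must be sharp or broad: {self.mark_type!r}")

    @property
    def effective_broad_gap(self) -> int:
        if self.broad_call_gap is not None:
            return self.broad_call_gap
        return self.fragment_gap_range[1]


def sharp_config(seed: int = 0, **overrides: object) -> SyntheticConfig:
    """Promoter-mark preset: short domains, no fragmentation."""
    params: dict = dict(
        seed=seed,
        mark_type="sharp",
        domain_length_mean=1000.0,
        dropout_rate=0.25,
        contamination_rate=0.125,
        fragmentation=0.0,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def broad_config(seed: int = 0, **overrides: object) -> SyntheticConfig:
    """Repressive-mark preset: ~20 kb domains, fragmentation of half of them."""
    params: dict = dict(
        seed=seed,
        mark_type="broad",
        domain_length_mean=20_000.0,
        dropout_rate=0.35,
        contamination_rate=0.2,
        fragmentation=0.5,
        n_true_domains=500,
        chrom_sizes={"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000},
    )
    params.update(overrides)
    return SyntheticConfig(**params)


@dataclass
class SyntheticTruth:
    """Planted ground truth and the rates actually realized after sampling."""

    true_domains: PeakSet
    planted_fp_peaks: PeakSet
    planted_fn_domains: PeakSet
    realized_fp_rate: float
    realized_fn_rate: float


# -- placement helpers ---------------------------------------------------------


class PlacementError(RuntimeError):
    """Rejection sampling could not place an interval collision-free."""


def _sample_length(rng: np.random.Generator, mean: float, sigma: float) -> int:
    # log-normal with the requested arithmetic mean
    mu = math.log(mean) - sigma**2 / 2
    return max(50, int(round(rng.lognormal(mu, sigma))))


def _place_nonoverlapping(
    rng: np.random.Generator,
    chrom_sizes: Mapping[str, int],
    lengths: list[int],
    forbidden: PeakSet | None = None,
    margin: int = 0,
    max_retries: int = 1000,
) -> list[GenomicInterval]:
    """Place intervals uniformly, rejecting collisions (with ``margin`` bp
    padding) against already-placed intervals and a forbidden set."""
    chroms = sorted(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    if forbidden is not None:
        for iv in forbidden:
            if iv.chrom in placed:
                placed[iv.chrom].append((iv.start, iv.end))
    out: list[GenomicInterval] = []
    for length in lengths:
        ok = False
        for _ in range(max_retries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            size = chrom_sizes[chrom]
            if size <= length:
                continue
            start = int(rng.integers(0, size - length))
            end = start + length
            if all(
                end + margin <= s or start - margin >= e
                for s, e in placed[chrom]
            ):
                placed[chrom].append((start, end))
                out.append(GenomicInterval(chrom, start, end))
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place a {length}-bp interval after {max_retries} tries"
            )
    return out


# -- generators ----------------------------------------------------------------


def generate_genome(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, int], list[GeneModel]]:
    """Chromosome sizes plus non-overlapping random genes.

    Gene lengths are uniform 2–20 kb with random strands; a density that
    cannot be placed raises :class:`PlacementError`.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lengths = [int(rng.integers(2000, 10_001)) for _ in range(config.n_genes)]
    spans = _place_nonoverlapping(
        rng, config.chrom_sizes, lengths, margin=1, max_retries=config.max_retries
    )
    genes: list[GeneModel] = []
    for i, iv in enumerate(spans):
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            tss, tes = iv.start, iv.end - 1
        else:
            tss, tes = iv.end - 1, iv.start
        genes.append(GeneModel(f"gene{i:04d}", iv.chrom, strand, tss, tes))
    return dict(config.chrom_sizes), genes


def generate_true_domains(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> PeakSet:
    """Non-overlapping true modification domains (the planted truth)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lengths = [
        _sample_length(rng, config.domain_length_mean, config.domain_length_sigma)
        for _ in range(config.n_true_domains)
    ]
    # keep domains well separated so jittered replicate observations never
    # touch a neighbour; for broad marks the gap-tolerant query merge must
    # also never bridge two distinct domains
    sep = config.effective_broad_gap if config.mark_type == "broad" else 500
    margin = 2 * config.boundary_jitter + sep + 1
    ivs = _place_nonoverlapping(
        rng, config.chrom_sizes, lengths, margin=margin,
        max_retries=config.max_retries,
    )
    named = [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=f"domain{i:04d}")
        for i, iv in enumerate(sorted(ivs, key=lambda v: (v.chrom, v.start)))
    ]
    return PeakSet(named, label="true_domains")


def generate_accessibility_peaks(
    truth_domains: PeakSet,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> PeakSet:
    """Accessibility (ATAC-like) peaks: some over true domains, most not.

    Roughly a third sit on true domains (open promoters are both modified
    and accessible); the rest are placed clear of the truth and of the
    jitter margin so planted contamination peaks inside them can never
    touch a reference observation.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    n = config.n_accessibility_peaks
    n_on_domain = n // 3
    out: list[GenomicInterval] = []
    domains = list(truth_domains)
    if domains:
        idx = rng.choice(len(domains), size=min(n_on_domain, len(domains)),
                         replace=False)
        for i in idx:
            d = domains[i]
            length = min(config.accessibility_peak_length, len(d))
            start = d.start + int(rng.integers(0, len(d) - length + 1))
            out.append(GenomicInterval(d.chrom, start, start + length))
    n_clear = n - len(out)
    margin = 2 * config.boundary_jitter + 1
    clear = _place_nonoverlapping(
        rng,
        config.chrom_sizes,
        [config.accessibility_peak_length] * n_clear,
        forbidden=truth_domains,
        margin=margin,
        max_retries=config.max_retries,
    )
    out.extend(clear)
    return PeakSet(out, label="accessibility")


def _jitter_interval(
    iv: GenomicInterval, rng: np.random.Generator, jitter: int, chrom_size: int
) -> GenomicInterval:
    ds = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
    de = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
    start = max(0, iv.start + ds)
    end = min(chrom_size, iv.end + de)
    if end - start < 50:  # keep observations non-degenerate
        start, end = iv.start, iv.end
    return GenomicInterval(iv.chrom, start, end, name=iv.name)


def _fragment_domain(
    iv: GenomicInterval, rng: np.random.Generator, gap_range: tuple[int, int]
) -> list[GenomicInterval]:
    """Carve internal gaps out of a domain, keeping both ends.

    Splits into 3–6 pieces when the domain is long enough; each internal
    gap is uniform over ``gap_range``. Short domains fall back to fewer
    pieces or stay whole.
    """
    lo_gap, hi_gap = gap_range
    min_piece = 300
    length = len(iv)
    k = int(rng.integers(3, 7))  # pieces
    while k > 1 and length < k * min_piece + (k - 1) * hi_gap:
        k -= 1
    if k == 1:
        return [iv]
    gaps = [int(rng.integers(lo_gap, hi_gap + 1)) for _ in range(k - 1)]
    remaining = length - sum(gaps)
    # split remaining coverage into k pieces of >= min_piece
    cuts = np.sort(rng.integers(0, remaining - k * min_piece + 1, size=k - 1))
    piece_lens = np.diff(np.concatenate([[0], cuts + min_piece * np.arange(1, k),
                                         [remaining]]))
    pieces: list[GenomicInterval] = []
    pos = iv.start
    for j, plen in enumerate(piece_lens):
        pieces.append(
            GenomicInterval(iv.chrom, pos, pos + int(plen),
                            name=f"{iv.name}_frag{j}" if iv.name else None)
        )
        pos += int(plen)
        if j < len(gaps):
            pos += gaps[j]
    assert pos == iv.end
    return pieces


def generate_observed_peaks(
    truth_domains: PeakSet,
    accessibility: PeakSet,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PeakSet, PeakSet, SyntheticTruth]:
    """Observed query peaks with planted dropout, fragmentation, contamination.

    Returns ``(query, query_broad, truth)`` where ``query_broad`` merges
    query fragments across gaps up to the broad-call emulation gap, and the
    realized FP/FN rates in ``truth`` are computed from the emitted sets.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    observed: list[GenomicInterval] = []
    dropped: list[GenomicInterval] = []
    for iv in truth_domains:
        if rng.random() < config.dropout_rate:
            dropped.append(iv)
            continue
        size = config.chrom_sizes[iv.chrom]
        obs = _jitter_interval(iv, rng, config.boundary_jitter, size)
        if config.mark_type == "broad" and rng.random() < config.fragmentation:
            observed.extend(_fragment_domain(obs, rng, config.fragment_gap_range))
        else:
            observed.append(obs)

    # contamination: planted FP peaks inside accessibility-only regions
    m = len(observed)
    c = config.contamination_rate
    n_fp = int(rng.binomial(m, c / (1.0 - c))) if (m and c > 0 and c < 1) else 0
    margin = 2 * config.boundary_jitter + 1
    atac_only = nonoverlapping_subset(
        merge_peaks(accessibility), merge_peaks(truth_domains, gap=margin)
    )
    fp_peaks: list[GenomicInterval] = []
    candidates = list(atac_only)
    if n_fp and not candidates:
        raise PlacementError("no accessibility-only regions to plant FP peaks in")
    if n_fp:
        chosen = rng.choice(len(candidates), size=n_fp, replace=n_fp > len(candidates))
        for j, ci in enumerate(np.atleast_1d(chosen)):
            host = candidates[int(ci)]
            length = min(500, len(host))
            start = host.start + int(rng.integers(0, len(host) - length + 1))
            fp_peaks.append(
                GenomicInterval(host.chrom, start, start + length, name=f"fp{j:04d}")
            )

    query = PeakSet(observed + fp_peaks, label="query",
                    provenance={"mark_type": config.mark_type})
    query_broad = merge_peaks(query, gap=config.effective_broad_gap)
    query_broad.label = "query_broad"
    total_q = query.count()
    truth = SyntheticTruth(
        true_domains=truth_domains,
        planted_fp_peaks=PeakSet(fp_peaks, label="planted_fp"),
        planted_fn_domains=PeakSet(dropped, label="planted_fn"),
        realized_fp_rate=(len(fp_peaks) / total_q) if total_q else 0.0,
        realized_fn_rate=(
            len(dropped) / truth_domains.count() if truth_domains.count() else 0.0
        ),
    )
    return query, query_broad, truth


def generate_reference_replicates(
    truth_domains: PeakSet,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PeakSet, PeakSet]:
    """Two jittered replicate observations of the truth.

    Each replicate drops each domain independently with
    ``replicate_dropout`` and jitters boundaries. For broad marks each
    domain is emitted as ~1 kb sub-peaks with small (100–400 bp) internal
    gaps at shared positions, jittered independently per replicate — the
    segmented way peak callers report broad ChIP-seq domains.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    if config.mark_type == "broad":
        sub_peaks: list[GenomicInterval] = []
        for iv in truth_domains:
            pos = iv.start
            j = 0
            while pos < iv.end:
                width = int(rng.integers(800, 1400))
                end = min(pos + width, iv.end)
                if end - pos >= 300:
                    sub_peaks.append(
                        GenomicInterval(iv.chrom, pos, end,
                                        name=f"{iv.name}_sub{j}" if iv.name else None)
                    )
                j += 1
                pos = end + int(rng.integers(100, 401))
        units = sub_peaks
        unit_domain = [iv.name.rsplit("_sub", 1)[0] if iv.name else str(i)
                       for i, iv in enumerate(sub_peaks)]
    else:
        units = list(truth_domains)
        unit_domain = [iv.name or str(i) for i, iv in enumerate(units)]

    domains = sorted({d for d in unit_domain})
    reps: list[PeakSet] = []
    for r in range(2):
        keep_domain = {d: rng.random() >= config.replicate_dropout for d in domains}
        ivs = []
        for iv, dom in zip(units, unit_domain):
            if not keep_domain[dom]:
                continue
            size = config.chrom_sizes[iv.chrom]
            jitter = min(config.boundary_jitter, 100)
            ivs.append(_jitter_interval(iv, rng, jitter, size))
        reps.append(PeakSet(ivs, label=f"chip_rep{r + 1}"))
    return reps[0], reps[1]


def generate_paired_tracks(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[BinnedTrack, BinnedTrack]:
    """Two binned tracks whose ln(x+1)-scale Pearson r targets the config ρ.

    A shared standard-normal latent is mixed with independent noise on the
    transformed scale (``ln(x+1) = mu + s·z``), then inverse-transformed
    and clipped at zero; with mu well above zero the clip is rare and the
    realized correlation stays near the target.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 4)
    rho = config.target_correlation
    if not -1.0 <= rho <= 1.0:
        raise ValueError("target_correlation must be in [-1, 1]")
    n = config.n_track_bins
    shared = rng.standard_normal(n)
    mu, s = 2.0, 0.6
    tracks: list[BinnedTrack] = []
    # shared-latent mixture: corr(z1, z2) = sign(rho) * |rho| on the z scale,
    # preserved by the affine ln(x+1) = mu + s*z map (up to rare clipping)
    signs = (1.0, 1.0 if rho >= 0 else -1.0)
    for sign in signs:
        noise = rng.standard_normal(n)
        z = sign * math.sqrt(abs(rho)) * shared + math.sqrt(1 - abs(rho)) * noise
        vals = np.clip(np.expm1(mu + s * z), 0.0, None)
        # slice bins across chromosomes proportionally to size
        chroms = sorted(config.chrom_sizes)
        sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
        counts = np.maximum(1, np.round(sizes / sizes.sum() * n).astype(int))
        counts[-1] = n - counts[:-1].sum()
        values: dict[str, np.ndarray] = {}
        off = 0
        for c, k in zip(chroms, counts):
            values[c] = vals[off : off + k]
            off += k
        bin_size = 10_000
        tracks.append(
            BinnedTrack(
                bin_size=bin_size,
                values=values,
                chrom_sizes={c: len(values[c]) * bin_size for c in values},
                normalization="CPM",
            )
        )
    return tracks[0], tracks[1]


def generate_expression_coverage(
    genes: list[GeneModel],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, float], dict[str, int], Coverage]:
    """Expression counts and a coverage track where gene-body signal scales
    with the planted expression tier (high : medium : low = 9 : 3 : 1)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 5)
    tiers = [9.0, 3.0, 1.0]
    counts: dict[str, float] = {}
    lengths: dict[str, int] = {}
    cov = Coverage(config.chrom_sizes)
    for i, g in enumerate(genes):
        tier = tiers[i % 3]
        lo, hi = min(g.tss, g.tes), max(g.tss, g.tes) + 1
        length = hi - lo
        lengths[g.gene_id] = length
        # read count proportional to tier x length so RPKM orders by tier
        counts[g.gene_id] = float(
            rng.poisson(tier * length / 100.0) + (1 if tier == 1.0 else 0)
        )
        base = tier * (1.0 + config.signal_noise * rng.standard_normal())
        cov.values[g.chrom][lo:hi] += max(base, 0.05 * tier)
    return counts, lengths, cov


def generate_marker_cohort(
    config: SyntheticConfig,
    locus: GenomicInterval,
    n_samples: int = 10,
    rng: np.random.Generator | None = None,
) -> tuple[list[PeakSet], list[bool]]:
    """A cohort of peak sets, half carrying a peak at the marker locus.

    Emulates the presence/absence dichotomy of an X-linked activation
    marker across embryos: even-indexed samples get a peak inside the
    locus, odd-indexed samples get none (background peaks are placed clear
    of the locus in all samples). Returns the peak sets and the planted
    truth labels.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 6)
    locus_set = PeakSet([locus])
    cohort: list[PeakSet] = []
    labels: list[bool] = []
    for i in range(n_samples):
        has_marker = i % 2 == 0
        background = _place_nonoverlapping(
            rng, config.chrom_sizes, [1000] * 20, forbidden=locus_set, margin=1,
            max_retries=config.max_retries,
        )
        ivs = list(background)
        if has_marker:
            length = max(200, len(locus) // 2)
            start = locus.start + int(rng.integers(0, max(1, len(locus) - length)))
            ivs.append(GenomicInterval(locus.chrom, start, start + length))
        cohort.append(PeakSet(ivs, label=f"embryo{i + 1:02d}"))
        labels.append(has_marker)
    return cohort, labels


def write_truth_manifest(
    truth: SyntheticTruth, config: SyntheticConfig, path: str | Path
) -> None:
    """JSON manifest: realized rates plus the config echo."""
    payload = {
        "realized_fp_rate": truth.realized_fp_rate,
        "realized_fn_rate": truth.realized_fn_rate,
        "n_true_domains": truth.true_domains.count(),
        "n_planted_fp": truth.planted_fp_peaks.count(),
        "n_planted_fn": truth.planted_fn_domains.count(),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
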