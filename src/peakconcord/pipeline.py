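"""Run-configuration validation and the end-to-end evaluation pipeline.

A run is declared in a single YAML mapping: sample peak sets, reference
replicates, an accessibility peak set, gene models, marker loci, and the
numeric parameters (all defaulted to the conventional values: 10 kb
correlation bins, 4 kb profile flanks, 200 bp fragment extension, 3 kb/1 kb
promoter windows, 2400 bp broad-merge gap emulation). Validation is
strict — every unknown key is an error, and all problems are reported at
once. The pipeline composes the library operations; every number in its
reports is reproducible by calling those operations directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .annotation import (
    DEFAULT_PROMOTER_DOWNSTREAM,
    DEFAULT_PROMOTER_UPSTREAM,
    annotate_peaks,
    bivalent_domains,
    chromosome_distribution,
    domains_to_genes,
    marker_presence,
    read_gene_table,
)
from .concordance import (
    DEFAULT_BROAD_MERGE_GAP,
    compute_fnr,
    compute_fnr_broad_corrected,
    compute_fpr,
    consensus_intersect,
    consensus_union,
)
from .intervals import PeakSet, merge_peaks, read_bed, write_bed
from .signal_profiles import (
    binned_correlation,
    compute_rpkm_tertiles,
    coverage_to_bins,
    genebody_profile,
    read_bedgraph,
    read_chrom_sizes,
    tss_profile,
)

logger = logging.getLogger("peakconcord")

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_evaluation"]


class ConfigError(ValueError):
    """Invalid run configuration; message lists every problem found."""


@dataclass
class SampleConfig:
    label: str
    peaks: str
    broad_peaks: str | None = None
    coverage: str | None = None
    k27_peaks: str | None = None  # paired repressive-mark set for bivalency


@dataclass
class RunConfig:
    samples: list[SampleConfig]
    reference_replicates: list[str]
    accessibility: str | None = None
    gene_table: str | None = None
    chrom_sizes: str | None = None
    marker_loci: str | None = None
    expression_table: str | None = None
    output_dir: str = "peakconcord_out"
    seed: int = 0
    bin_size: int = 10_000
    flank: int = 4000
    fragment_extension: int = 200
    meta_bins: int = 100
    promoter_upstream: int = DEFAULT_PROMOTER_UPSTREAM
    promoter_downstream: int = DEFAULT_PROMOTER_DOWNSTREAM
    broad_merge_gap: int = DEFAULT_BROAD_MERGE_GAP
    fpr_reference_consensus: str = "union"  # or "intersect" / "single"
    outlier_policy: str = "none"
    mad_threshold: float = 200.0

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


_SAMPLE_KEYS = {"label", "peaks", "broad_peaks", "coverage", "k27_peaks"}
_TOP_KEYS = {
    "samples", "reference_replicates", "accessibility", "gene_table",
    "chrom_sizes", "marker_loci", "expression_table", "output_dir", "seed",
    "bin_size", "flank", "fragment_extension", "meta_bins",
    "promoter_upstream", "promoter_downstream", "broad_merge_gap",
    "fpr_reference_consensus", "outlier_policy", "mad_threshold",
}
_INT_KEYS = {"seed", "bin_size", "flank", "fragment_extension", "meta_bins",
             "promoter_upstream", "promoter_downstream", "broad_merge_gap"}
_PATH_KEYS = {"accessibility", "gene_table", "chrom_sizes", "marker_loci",
              "expression_table"}


def _resolve(base: Path, p: str) -> str:
    path = Path(p)
    return str(path if path.is_absolute() else base / path)


def validate_config(path: str | Path) -> RunConfig:
    """Load, default, and validate a YAML run configuration.

    Unknown keys, wrong types, and missing referenced files are all
    collected and reported in a single :class:`ConfigError`.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError("config must be a mapping at top level")
    base = path.parent
    problems: list[str] = []
    for key in raw:
        if key not in _TOP_KEYS:
            problems.append(f"unknown key: {key!r}")
    samples: list[SampleConfig] = []
    raw_samples = raw.get("samples", [])
    if not isinstance(raw_samples, list) or not raw_samples:
        problems.append("'samples' must be a non-empty list")
        raw_samples = []
    for i, s in enumerate(raw_samples):
        if not isinstance(s, Mapping):
            problems.append(f"samples[{i}] must be a mapping")
            continue
        for key in s:
            if key not in _SAMPLE_KEYS:
                problems.append(f"samples[{i}]: unknown key {key!r}")
        if "label" not in s or "peaks" not in s:
            problems.append(f"samples[{i}]: 'label' and 'peaks' are required")
            continue
        sc = SampleConfig(
            label=str(s["label"]),
            peaks=_resolve(base, str(s["peaks"])),
            broad_peaks=_resolve(base, str(s["broad_peaks"])) if s.get("broad_peaks") else None,
            coverage=_resolve(base, str(s["coverage"])) if s.get("coverage") else None,
            k27_peaks=_resolve(base, str(s["k27_peaks"])) if s.get("k27_peaks") else None,
        )
        for p in (sc.peaks, sc.broad_peaks, sc.coverage, sc.k27_peaks):
            if p and not Path(p).exists():
                problems.append(f"samples[{i}] ({sc.label}): missing file {p}")
        samples.append(sc)
    reps_raw = raw.get("reference_replicates", [])
    if not isinstance(reps_raw, list):
        problems.append("'reference_replicates' must be a list")
        reps_raw = []
    reps = [_resolve(base, str(r)) for r in reps_raw]
    for r in reps:
        if not Path(r).exists():
            problems.append(f"missing reference replicate file: {r}")
    kwargs: dict[str, Any] = {}
    for key in _TOP_KEYS - {"samples", "reference_replicates"}:
        if key not in raw:
            continue
        val = raw[key]
        if key in _INT_KEYS:
            if not isinstance(val, int) or isinstance(val, bool):
                problems.append(f"{key!r} must be an integer, got {val!r}")
                continue
        if key == "mad_threshold":
            if not isinstance(val, (int, float)):
                problems.append(f"'mad_threshold' must be numeric, got {val!r}")
                continue
            val = float(val)
        if key in _PATH_KEYS and val is not None:
            val = _resolve(base, str(val))
            if not Path(val).exists():
                problems.append(f"missing file for {key!r}: {val}")
        kwargs[key] = val
    if kwargs.get("fpr_reference_consensus", "union") not in (
        "union", "intersect", "single",
    ):
        problems.append("'fpr_reference_consensus' must be union|intersect|single")
    if problems:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems))
    return RunConfig(samples=samples, reference_replicates=reps, **kwargs)


# -- pipeline ------------------------------------------------------------------


def _load_reference(cfg: RunConfig) -> tuple[PeakSet | None, PeakSet | None]:
    """(FPR reference, FNR reference) per the configured consensus modes."""
    if not cfg.reference_replicates:
        return None, None
    reps = [read_bed(p, label=f"chip_rep{i + 1}")
            for i, p in enumerate(cfg.reference_replicates)]
    if len(reps) == 1:
        return reps[0], reps[0]
    union = consensus_union(reps[0], reps[1])
    intersect = consensus_intersect(reps[0], reps[1])
    if cfg.fpr_reference_consensus == "union":
        fpr_ref = union
    elif cfg.fpr_reference_consensus == "intersect":
        fpr_ref = intersect
    else:
        fpr_ref = reps[0]
    return fpr_ref, intersect


def run_evaluation(cfg: RunConfig) -> dict[str, Any]:
    """Execute every applicable stage and write the report bundle.

    Stages with missing optional inputs (coverage, genes, markers) are
    skipped with a logged notice; concordance always runs when reference
    replicates are present. Returns a summary dict mirroring the files
    written under ``cfg.output_dir``.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"samples": {}, "parameters": cfg.to_dict(),
                               "version": __version__}
    stage = "setup"
    try:
        stage = "load-reference"
        fpr_ref, fnr_ref = _load_reference(cfg)
        accessibility = (
            read_bed(cfg.accessibility, label="accessibility")
            if cfg.accessibility else None
        )
        genes = read_gene_table(cfg.gene_table) if cfg.gene_table else None
        chrom_sizes = (
            read_chrom_sizes(cfg.chrom_sizes) if cfg.chrom_sizes else None
        )
        expression = None
        if cfg.expression_table:
            import pandas as pd

            df = pd.read_csv(
                cfg.expression_table, sep="\t",
                names=["gene_id", "read_count", "gene_length"], comment="#",
            )
            expression = compute_rpkm_tertiles(
                dict(zip(df.gene_id, df.read_count.astype(float))),
                dict(zip(df.gene_id, df.gene_length.astype(int))),
            )
        markers = (
            list(read_bed(cfg.marker_loci, label="markers"))
            if cfg.marker_loci else None
        )

        concordance_rows: list[dict[str, Any]] = []
        tracks: dict[str, Any] = {}
        for sample in cfg.samples:
            stage = f"concordance[{sample.label}]"
            query = read_bed(sample.peaks, label=sample.label)
            row: dict[str, Any] = {"sample": sample.label,
                                   "total_peaks": query.count()}
            if fpr_ref is not None and accessibility is not None and query.count():
                fpr_res = compute_fpr(query, fpr_ref, accessibility)
                row.update(
                    fp_n=fpr_res.false_positive_peaks,
                    fpr_percent=fpr_res.fpr_percent,
                )
                _write_classification(
                    query, fpr_res.classification,
                    outdir / f"{sample.label}.classification.bed",
                )
            if fnr_ref is not None and fnr_ref.count():
                fnr_res = compute_fnr(fnr_ref, query)
                row.update(
                    reference_n=fnr_res.reference_peak_count,
                    fn_n=fnr_res.false_negative_peaks,
                    fnr_percent=fnr_res.fnr_percent,
                )
                broad = (
                    read_bed(sample.broad_peaks, label=f"{sample.label}_broad")
                    if sample.broad_peaks
                    else merge_peaks(query, gap=cfg.broad_merge_gap)
                )
                corr_res = compute_fnr_broad_corrected(fnr_ref, query, broad)
                row["fnr_corrected_percent"] = corr_res.fnr_percent
            concordance_rows.append(row)

            if genes is not None and query.count():
                stage = f"annotation[{sample.label}]"
                ann = annotate_peaks(
                    query, genes,
                    promoter_upstream=cfg.promoter_upstream,
                    promoter_downstream=cfg.promoter_downstream,
                )
                _write_annotation(
                    ann, chromosome_distribution(query),
                    outdir / f"{sample.label}.annotation.tsv",
                )
                row["promoter_percent"] = round(
                    ann.per_category_percent["promoter"], 1
                )
                if sample.k27_peaks:
                    stage = f"bivalency[{sample.label}]"
                    k27 = read_bed(sample.k27_peaks, label=f"{sample.label}_k27")
                    domains = bivalent_domains(query, k27)
                    write_bed(domains, outdir / f"{sample.label}.bivalent.bed")
                    gene_list = domains_to_genes(domains, genes)
                    (outdir / f"{sample.label}.bivalent_genes.txt").write_text(
                        "".join(g + "\n" for g in gene_list)
                    )
                    row["bivalent_domains"] = domains.count()

            if sample.coverage and chrom_sizes:
                stage = f"profiles[{sample.label}]"
                cov = read_bedgraph(sample.coverage, chrom_sizes)
                tracks[sample.label] = coverage_to_bins(cov, cfg.bin_size)
                if genes is not None:
                    groups = expression.tertile if expression else None
                    prof = tss_profile(cov, genes, flank=cfg.flank,
                                       fragment_extension=cfg.fragment_extension,
                                       groups=groups)
                    _write_profile(prof, outdir / f"{sample.label}.tss_profile.tsv")
                    body = genebody_profile(cov, genes, meta_bins=cfg.meta_bins,
                                            groups=groups)
                    _write_profile(
                        body, outdir / f"{sample.label}.genebody_profile.tsv"
                    )
            elif sample.coverage and not chrom_sizes:
                logger.info("sample %s: coverage given without chrom_sizes; "
                            "profile stage skipped", sample.label)

            if markers:
                stage = f"markers[{sample.label}]"
                calls = [
                    marker_presence(query, locus, "putative female",
                                    "putative male")
                    for locus in markers
                ]
                row["marker_calls"] = {
                    (c.locus.name or f"{c.locus.chrom}:{c.locus.start}-{c.locus.end}"):
                    c.present
                    for c in calls
                }
            summary["samples"][sample.label] = row

        stage = "report"
        _write_concordance(concordance_rows, outdir / "concordance.tsv")
        if markers:
            _write_markers(summary["samples"], outdir / "marker_calls.tsv")
        if len(tracks) >= 2:
            stage = "correlation"
            labels = sorted(tracks)
            with open(outdir / "correlation.tsv", "w") as fh:
                fh.write("sample_a\tsample_b\tpearson_r_ln1p\n")
                for i, a in enumerate(labels):
                    for b in labels[i + 1:]:
                        r = binned_correlation(
                            tracks[a], tracks[b],
                            outlier_policy=cfg.outlier_policy,
                            mad_threshold=cfg.mad_threshold,
                        )
                        fh.write(f"{a}\t{b}\t{r:.6f}\n")
        elif not tracks:
            logger.info("no coverage tracks supplied; correlation stage skipped")
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc
    return summary


def _write_classification(query: PeakSet, classification, path: Path) -> None:
    with open(path, "w") as fh:
        for iv in query:
            cls = classification.get(iv.coords, "unclassified")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{cls}\n")


def _write_annotation(ann, per_chrom, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tcount\tpercent\n")
        for cat in ("promoter", "genic", "intergenic"):
            fh.write(
                f"{cat}\t{ann.per_category_counts[cat]}\t"
                f"{ann.per_category_percent[cat]:.1f}\n"
            )
        fh.write("#chromosome\tcount\n")
        for chrom in sorted(per_chrom):
            fh.write(f"#{chrom}\t{per_chrom[chrom]}\n")


def _write_profile(prof, path: Path) -> None:
    import numpy as np

    with open(path, "w") as fh:
        fh.write("position\tmean_signal")
        groups = sorted(set(prof.group_labels)) if prof.group_labels else []
        for g in groups:
            fh.write(f"\t{g}")
        fh.write("\n")
        overall = prof.average_profile()
        per_group = {g: prof.average_profile(group=g) for g in groups}
        for j, pos in enumerate(prof.positions):
            fh.write(f"{pos}\t{overall[j]:.6g}")
            for g in groups:
                fh.write(f"\t{per_group[g][j]:.6g}")
            fh.write("\n")


def _write_concordance(rows: list[dict[str, Any]], path: Path) -> None:
    cols = ["sample", "total_peaks", "fp_n", "fpr_percent", "reference_n",
            "fn_n", "fnr_percent", "fnr_corrected_percent"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "NA")) for c in cols) + "\n")


def _write_markers(samples: Mapping[str, Any], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tlocus\tpresent\n")
        for label, row in samples.items():
            for locus, present in row.get("marker_calls", {}).items():
                fh.write(f"{label}\t{locus}\t{int(present)}\n")
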