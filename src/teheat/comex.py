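"""COMEX: proportional expression counting of TEs from multi-mapping reads.

Short RNA-seq reads from multi-copy transposable elements often align equally
well to many genomic positions, so naive unique-read counting discards most of
the signal and naive multi-read counting inflates it. The approach implemented
here partitions reads by the families their alignments touch:

* **UM** — uniquely mapped (one reported alignment). Accepted directly.
* **SMM** — specifically multiply mapped: every TE-overlapping alignment hits
  members of one single family, with at least two TE hits. Informative about
  the family; kept.
* **NMM** — non-specifically multiply mapped: alignments hit two or more
  distinct families. Non-informative; discarded.
* **UNANNOTATED** — no alignment overlaps any catalogued TE.

Retained reads are counted proportionally: a read reported at k positions
contributes weight 1/k to each TE copy it overlaps, so no read ever adds more
than one unit of evidence in total. Copy-level counts are summed into
family-level counts, converted to RPKM (reads per kilobase of feature per
million mapped reads), and filtered at an expression threshold (default
0.55 RPKM in at least one sample).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import TECatalogue, TEFeature

__all__ = [
    "CountingConfig",
    "ReadMappingSet",
    "CountMatrix",
    "collect_mappings",
    "classify_read",
    "proportional_counts",
    "family_counts",
    "rpkm",
    "filter_expressed",
    "summarize_regulation",
    "export_deseq_matrix",
    "count_sample",
    "run_comex",
    "class_statistics",
]

UM = "UM"
SMM = "SMM"
NMM = "NMM"
UNANNOTATED = "UNANNOTATED"
READ_CLASSES = (UM, SMM, NMM, UNANNOTATED)


@dataclass(frozen=True)
class CountingConfig:
    """Tunable parameters of the counting pipeline.

    rpkm_threshold : float
        Minimum RPKM in at least one sample for a row to count as expressed
        (default 0.55).
    min_overlap_bp : int
        Minimum alignment/feature overlap (bp) to call a TE hit (default 1).
    min_mapq : int
        Minimum mapping quality; 0 disables the filter. Secondary alignments
        of multi-mappers typically carry low MAPQ, so the default keeps them.
    single_te_hit_policy : str
        Class of a multi-mapper whose alignments include exactly one TE hit:
        ``"discard"`` (default, class NMM) or ``"keep"`` (class SMM).
    library_size_definition : str
        ``"all_mapped_reads"`` (default) or ``"retained_te_reads"``.
    """

    rpkm_threshold: float = 0.55
    min_overlap_bp: int = 1
    min_mapq: int = 0
    single_te_hit_policy: str = "discard"
    library_size_definition: str = "all_mapped_reads"
    strandedness: str = "unstranded"  # fixed; library protocol is non-specific

    def __post_init__(self) -> None:
        if self.rpkm_threshold < 0:
            raise ValueError("rpkm_threshold must be >= 0")
        if self.min_overlap_bp < 1:
            raise ValueError("min_overlap_bp must be >= 1")
        if self.single_te_hit_policy not in {"discard", "keep"}:
            raise ValueError(f"bad single_te_hit_policy {self.single_te_hit_policy!r}")
        if self.library_size_definition not in {"all_mapped_reads", "retained_te_reads"}:
            raise ValueError(
                f"bad library_size_definition {self.library_size_definition!r}"
            )
        if self.strandedness != "unstranded":
            raise ValueError("only unstranded counting is supported")


@dataclass
class ReadMappingSet:
    """All reported alignments of one read plus its derived class.

    ``mappings`` holds (chrom, start, end, strand) spans, 1-based inclusive.
    ``k`` (the read's mapping multiplicity) is ``len(mappings)``.
    ``hits`` parallels ``mappings`` after classification: the te_id the
    mapping was attributed to, or None for a non-TE position.
    """

    read_id: str
    mappings: list[tuple[str, int, int, str]]
    read_class: str | None = None
    assigned_family: str | None = None
    hits: list[str | None] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.mappings)

    @property
    def is_retained(self) -> bool:
        """True for reads that contribute counts (UM with a TE hit, or SMM)."""
        return self.assigned_family is not None


def collect_mappings(
    path: str | Path,
    min_mapq: int = 0,
    drop_supplementary: bool = True,
) -> tuple[list[ReadMappingSet], Counter]:
    """Group SAM/BAM records into one :class:`ReadMappingSet` per read.

    Secondary alignments must be present in the input for multi-mapper
    multiplicity to be correct. Unmapped and vendor-failed records are
    dropped; supplementary (chimeric) records are dropped by default.

    Returns the mapping sets in order of first appearance plus a counter of
    dropped-record categories.
    """
    dropped: Counter = Counter()
    by_read: dict[str, ReadMappingSet] = {}
    with pysam.AlignmentFile(str(path), require_index=False) as af:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped:
                dropped["unmapped"] += 1
                continue
            if rec.is_qcfail:
                dropped["qc_fail"] += 1
                continue
            if drop_supplementary and rec.is_supplementary:
                dropped["supplementary"] += 1
                continue
            if min_mapq and rec.mapping_quality < min_mapq:
                dropped["low_mapq"] += 1
                continue
            # sole SAM->GFF coordinate conversion point:
            # 0-based half-open [reference_start, reference_end) ->
            # 1-based inclusive [reference_start+1, reference_end]
            span = (
                rec.reference_name,
                rec.reference_start + 1,
                rec.reference_end,
                "-" if rec.is_reverse else "+",
            )
            rms = by_read.get(rec.query_name)
            if rms is None:
                by_read[rec.query_name] = ReadMappingSet(rec.query_name, [span])
            else:
                rms.mappings.append(span)
    return list(by_read.values()), dropped


def _attribute_mapping(
    cat: TECatalogue, chrom: str, start: int, end: int, min_overlap_bp: int
) -> TEFeature | None:
    """Resolve one alignment span to at most one TE feature.

    Among features overlapping by >= min_overlap_bp, the largest overlap
    wins; ties go to the lexicographically smaller te_id.
    """
    best: TEFeature | None = None
    best_key: tuple[int, str] | None = None
    for f in cat.overlapping(chrom, start, end):
        ov = f.overlap_bp(start, end)
        if ov < min_overlap_bp:
            continue
        key = (-ov, f.te_id)
        if best_key is None or key < best_key:
            best, best_key = f, key
    return best


def classify_read(
    rms: ReadMappingSet, cat: TECatalogue, cfg: CountingConfig | None = None
) -> ReadMappingSet:
    """Assign UM/SMM/NMM/UNANNOTATED and, when informative, the family.

    Rules: UM iff k == 1 (family set when the single mapping overlaps a TE,
    else UNANNOTATED). For k >= 2: UNANNOTATED when no mapping overlaps a TE;
    NMM when hits span >= 2 families; SMM when all >= 2 TE hits fall in one
    family. A multi-mapper with exactly one TE hit follows
    ``cfg.single_te_hit_policy``.
    """
    cfg = cfg or CountingConfig()
    if rms.k < 1:
        raise ValueError(f"read {rms.read_id!r} has no mappings")
    hits = [
        (f.te_id if f is not None else None)
        for f in (
            _attribute_mapping(cat, c, s, e, cfg.min_overlap_bp)
            for c, s, e, _ in rms.mappings
        )
    ]
    families = {cat.family_of(t) for t in hits if t is not None}
    n_hit = sum(h is not None for h in hits)
    if rms.k == 1:
        if n_hit:
            cls, fam = UM, next(iter(families))
        else:
            cls, fam = UNANNOTATED, None
    elif n_hit == 0:
        cls, fam = UNANNOTATED, None
    elif len(families) >= 2:
        cls, fam = NMM, None
    elif n_hit >= 2 or cfg.single_te_hit_policy == "keep":
        cls, fam = SMM, next(iter(families))
    else:
        cls, fam = NMM, None
    return replace(rms, read_class=cls, assigned_family=fam, hits=hits)


@dataclass
class CountMatrix:
    """Fractional counts per TE copy (or family) per sample.

    counts : DataFrame
        Rows are te_ids (level ``"copy"``) or family names (level
        ``"family"``); columns are sample names; values are non-negative
        fractional read counts (or RPKM when produced by :func:`rpkm`).
    lengths : Series
        Per-row feature length in bp (family rows: total bp of members).
    library_sizes : Series
        Per-sample mapped-read totals.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    library_sizes: pd.Series
    level: str = "copy"
    units: str = "counts"

    def __post_init__(self) -> None:
        self.lengths = self.lengths.reindex(self.counts.index)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def join(self, other: "CountMatrix") -> "CountMatrix":
        """Merge sample columns of two matrices over the same rows."""
        if self.level != other.level or self.units != other.units:
            raise ValueError("cannot join matrices of different level/units")
        counts = self.counts.join(other.counts, how="outer").fillna(0.0)
        lengths = self.lengths.combine_first(other.lengths)
        lib = pd.concat([self.library_sizes, other.library_sizes])
        return CountMatrix(counts, lengths, lib, self.level, self.units)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label=self.level)


def proportional_counts(
    reads: Iterable[ReadMappingSet],
    cat: TECatalogue,
    cfg: CountingConfig | None = None,
    sample: str = "sample",
    library_size: int | None = None,
) -> CountMatrix:
    """Copy-level proportional counts for one sample.

    Each retained read (UM with a TE hit, or SMM) adds weight 1/k to every
    TE copy one of its k mappings was attributed to; NMM and UNANNOTATED
    reads contribute nothing. Total weight per read is therefore n_hits/k
    <= 1, with equality iff every mapping overlaps a TE.
    """
    cfg = cfg or CountingConfig()
    weights: dict[str, float] = {f.te_id: 0.0 for f in cat}
    n_reads = 0
    n_retained = 0
    for rms in reads:
        if rms.read_class is None:
            rms = classify_read(rms, cat, cfg)
        n_reads += 1
        if not rms.is_retained:
            continue
        n_retained += 1
        w = 1.0 / rms.k
        for te_id in rms.hits:
            if te_id is not None:
                weights[te_id] += w
    if library_size is None:
        library_size = (
            n_reads
            if cfg.library_size_definition == "all_mapped_reads"
            else n_retained
        )
    te_ids = [f.te_id for f in cat]
    counts = pd.DataFrame({sample: [weights[t] for t in te_ids]}, index=te_ids)
    lengths = pd.Series([cat.get(t).length for t in te_ids], index=te_ids, dtype=float)
    lib = pd.Series([library_size], index=[sample], dtype=float)
    return CountMatrix(counts, lengths, lib, level="copy")


def family_counts(copy_matrix: CountMatrix, cat: TECatalogue) -> CountMatrix:
    """Sum copy-level rows into family-level rows.

    Family length is the total annotated bp of its member copies (used for
    family-level RPKM).
    """
    if copy_matrix.level != "copy":
        raise ValueError("family_counts expects a copy-level matrix")
    fam_of = {}
    for te_id in copy_matrix.counts.index:
        if te_id not in cat:
            raise KeyError(f"te_id {te_id!r} not in catalogue")
        fam_of[te_id] = cat.family_of(te_id)
    fam = pd.Series(fam_of)
    counts = copy_matrix.counts.groupby(fam).sum().sort_index()
    lengths = copy_matrix.lengths.groupby(fam).sum().sort_index()
    return CountMatrix(
        counts, lengths, copy_matrix.library_sizes, level="family",
        units=copy_matrix.units,
    )


def rpkm(matrix: CountMatrix) -> CountMatrix:
    """Reads per kilobase of feature per million mapped reads.

    value = count / (length/1000) / (library_size/1e6)
    """
    if (matrix.lengths <= 0).any():
        raise ValueError("all feature lengths must be > 0")
    if (matrix.library_sizes <= 0).any():
        raise ValueError("all library sizes must be > 0")
    vals = (
        matrix.counts.div(matrix.lengths / 1e3, axis=0)
        .div(matrix.library_sizes / 1e6, axis=1)
    )
    return CountMatrix(
        vals, matrix.lengths, matrix.library_sizes, matrix.level, units="rpkm"
    )


def filter_expressed(
    rpkm_matrix: CountMatrix, cfg: CountingConfig | None = None
) -> CountMatrix:
    """Keep rows whose RPKM reaches the threshold in >= 1 sample."""
    cfg = cfg or CountingConfig()
    if not len(rpkm_matrix.samples):
        raise ValueError("matrix has no sample columns")
    keep = rpkm_matrix.counts.max(axis=1) >= cfg.rpkm_threshold
    return CountMatrix(
        rpkm_matrix.counts.loc[keep],
        rpkm_matrix.lengths.loc[keep],
        rpkm_matrix.library_sizes,
        rpkm_matrix.level,
        rpkm_matrix.units,
    )


def summarize_regulation(n_significant: int, n_total: int) -> float:
    """Percentage of regulated features, rounded half-up to one decimal.

    e.g. 7156 significantly upregulated of 32793 genes -> 21.8.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_significant <= n_total:
        raise ValueError("need 0 <= n_significant <= n_total")
    pct = Decimal(100 * n_significant) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def export_deseq_matrix(
    matrix: CountMatrix,
    path: str | Path,
    fractional_path: str | Path | None = None,
) -> tuple[Path, Path]:
    """Write an integerized count TSV for differential-expression tools.

    Fractional proportional counts are rounded half-to-even to the integers
    such tools require; the untouched fractional matrix is written alongside
    (default: ``<path>`` with a ``.fractional.tsv`` suffix).
    """
    path = Path(path)
    if fractional_path is None:
        fractional_path = path.with_suffix(".fractional.tsv")
    fractional_path = Path(fractional_path)
    ints = pd.DataFrame(
        np.rint(matrix.counts.to_numpy()).astype(int),
        index=matrix.counts.index,
        columns=matrix.counts.columns,
    )
    ints.to_csv(path, sep="\t", index_label=matrix.level)
    matrix.counts.to_csv(fractional_path, sep="\t", index_label=matrix.level)
    return path, fractional_path


def class_statistics(reads: Iterable[ReadMappingSet]) -> dict[str, int]:
    """UM/SMM/NMM/UNANNOTATED tallies plus the total."""
    stats = {c: 0 for c in READ_CLASSES}
    total = 0
    for rms in reads:
        if rms.read_class is None:
            raise ValueError("reads must be classified first")
        stats[rms.read_class] += 1
        total += 1
    stats["total"] = total
    return stats


@dataclass
class ComexResult:
    """Everything one sample's COMEX run produces."""

    sample: str
    reads: list[ReadMappingSet]
    copy_counts: CountMatrix
    family_counts: CountMatrix
    class_stats: dict[str, int]
    dropped: Counter


def count_sample(
    path: str | Path,
    cat: TECatalogue,
    cfg: CountingConfig | None = None,
    sample: str | None = None,
) -> ComexResult:
    """Run classification + proportional counting on one SAM/BAM file."""
    cfg = cfg or CountingConfig()
    if sample is None:
        sample = Path(path).stem
    raw, dropped = collect_mappings(path, min_mapq=cfg.min_mapq)
    reads = [classify_read(r, cat, cfg) for r in raw]
    copy_m = proportional_counts(reads, cat, cfg, sample=sample)
    fam_m = family_counts(copy_m, cat)
    return ComexResult(sample, reads, copy_m, fam_m, class_statistics(reads), dropped)


def run_comex(
    sample_paths: Mapping[str, str | Path],
    cat: TECatalogue,
    cfg: CountingConfig | None = None,
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame]:
    """Count several samples and return (copy, family, per-class stats)."""
    cfg = cfg or CountingConfig()
    results = [count_sample(p, cat, cfg, sample=s) for s, p in sample_paths.items()]
    copy_m = results[0].copy_counts
    fam_m = results[0].family_counts
    for r in results[1:]:
        copy_m = copy_m.join(r.copy_counts)
        fam_m = fam_m.join(r.family_counts)
    stats = pd.DataFrame({r.sample: r.class_stats for r in results}).T
    return copy_m, fam_m, stats
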