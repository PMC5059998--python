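"""Conservation shadowing of LTR sequences.

Cross-species comparison of LTR (long terminal repeat) promoter sequences
reveals conserved cis-regulatory regions: a subject sequence (typically a
species consensus) is slid along a query in windows of ungapped query
positions, per-window percent identity is recorded, and maximal
above-threshold runs are reported as conserved segments. Defaults follow the
usual shadowing setup: 20-bp window, >=70 % identity, 7-bp minimum consensus
length.

The module also builds IUPAC-ambiguity consensus sequences from aligned
sequence sets (majority base where one base dominates, ambiguity code over
the observed bases otherwise); alignment construction itself is out of scope
and pre-aligned FASTA is consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "AlignedSet",
    "ShadowConfig",
    "ConservationProfile",
    "build_consensus",
    "windowed_identity",
    "conserved_segments",
    "iupac_code",
]

GAP_CHAR = "-"

# frozenset of plain bases -> IUPAC ambiguity code (e.g. {A,G} -> R)
_IUPAC_BY_SET: dict[frozenset, str] = {
    frozenset(expansion): code
    for code, expansion in ambiguous_dna_values.items()
    if code != "X"
}


def iupac_code(bases: Iterable[str]) -> str:
    """IUPAC code covering the given set of A/C/G/T bases (N handled)."""
    expanded: set[str] = set()
    for b in bases:
        b = b.upper()
        if b not in ambiguous_dna_values:
            raise ValueError(f"not a nucleotide code: {b!r}")
        expanded.update(ambiguous_dna_values[b])
    return _IUPAC_BY_SET[frozenset(expanded)]


@dataclass(frozen=True)
class ShadowConfig:
    """window: ungapped-query bp per window; identity_cutoff: percent;
    min_consensus_len: minimum above-cutoff run span in bp."""

    window: int = 20
    identity_cutoff: float = 70.0
    min_consensus_len: int = 7

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 0 <= self.identity_cutoff <= 100:
            raise ValueError("identity_cutoff must be in [0, 100]")
        if self.min_consensus_len < 1:
            raise ValueError("min_consensus_len must be >= 1")


class AlignedSet:
    """Named gapped sequences of equal aligned length, with one query record.

    The query provides the ungapped coordinate system onto which windowed
    identities and conserved segments are projected.
    """

    def __init__(self, records: Mapping[str, str], query_name: str):
        if not records:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in records.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal aligned lengths: {sorted(lengths)}")
        if query_name not in records:
            raise KeyError(f"query {query_name!r} not in alignment")
        self.records = {n: s.upper() for n, s in records.items()}
        self.query_name = query_name
        if all(c == GAP_CHAR for c in self.records[query_name]):
            raise ValueError("query has no non-gap columns")

    @classmethod
    def from_fasta(cls, path: str | Path, query_name: str) -> "AlignedSet":
        aln = AlignIO.read(str(path), "fasta")
        return cls({rec.id: str(rec.seq) for rec in aln}, query_name)

    @property
    def aligned_length(self) -> int:
        return len(self.records[self.query_name])

    def query_columns(self) -> np.ndarray:
        """Alignment column index of each ungapped query position."""
        q = np.frombuffer(self.records[self.query_name].encode(), dtype="S1")
        return np.flatnonzero(q != GAP_CHAR.encode())

    @property
    def query_length(self) -> int:
        return len(self.query_columns())


@dataclass
class ConservationProfile:
    """Windowed identity of one subject against the query.

    positions : array of int
        Ungapped query coordinates of window left anchors (0 .. L − window).
    identity : array of float
        Percent identity of the window anchored at each position.
    """

    query_name: str
    subject_name: str
    positions: np.ndarray
    identity: np.ndarray
    window: int
    query_length: int

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tidentity\n")
            for p, v in zip(self.positions, self.identity):
                fh.write(f"{p}\t{v:.4f}\n")


def build_consensus(
    seqs: Mapping[str, str] | Sequence[str],
    majority_threshold: float = 0.5,
) -> str:
    """Column-wise IUPAC consensus of equal-length gapped sequences.

    Per column: a gap is emitted iff gaps are the strict majority of the
    column; otherwise the most frequent base (gaps excluded from the tally)
    is emitted when its frequency exceeds ``majority_threshold``, else the
    IUPAC ambiguity code covering every base observed in the column.
    """
    if not 0.5 <= majority_threshold <= 1:
        raise ValueError("majority_threshold must be in [0.5, 1]")
    seq_list = list(seqs.values()) if isinstance(seqs, Mapping) else list(seqs)
    if not seq_list:
        raise ValueError("empty sequence set")
    if len({len(s) for s in seq_list}) != 1:
        raise ValueError("sequences must have equal aligned length")
    n_cols = len(seq_list[0])
    out: list[str] = []
    for j in range(n_cols):
        col = [s[j].upper() for s in seq_list]
        n_gap = col.count(GAP_CHAR)
        if n_gap * 2 > len(col):
            out.append(GAP_CHAR)
            continue
        bases = [c for c in col if c != GAP_CHAR]
        counts: dict[str, int] = {}
        for b in bases:
            counts[b] = counts.get(b, 0) + 1
        top, top_n = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        if top_n / len(bases) > majority_threshold and top in "ACGT":
            out.append(top)
        else:
            out.append(iupac_code(counts))
    return "".join(out)


_ACGT = frozenset(b"ACGT")


def windowed_identity(
    aln: AlignedSet,
    subject: str,
    cfg: ShadowConfig | None = None,
    ambiguity_matches: bool = False,
) -> ConservationProfile:
    """Sliding-window percent identity of ``subject`` vs the query.

    Windows cover ``cfg.window`` consecutive ungapped query positions,
    anchored at their left end; subject gaps and N count as mismatches;
    alignment columns where the query is gapped carry no query coordinate
    and are skipped. Trailing windows shorter than the window size are not
    emitted, so the profile covers anchors 0 .. L − window of the ungapped
    query (empty, with a warning, when L < window).

    With ``ambiguity_matches`` a subject IUPAC code compatible with the
    query base (e.g. R vs A) counts as a match.
    """
    cfg = cfg or ShadowConfig()
    if subject == aln.query_name:
        raise ValueError("subject must differ from the query")
    cols = aln.query_columns()
    q = np.array(list(aln.records[aln.query_name]))[cols]
    s = np.array(list(aln.records[subject]))[cols]
    if ambiguity_matches:
        match = np.array(
            [
                qc in "ACGT"
                and sc in ambiguous_dna_values
                and sc != "N"
                and qc in ambiguous_dna_values[sc]
                for qc, sc in zip(q, s)
            ]
        )
    else:
        match = (q == s) & np.isin(q, list("ACGT")) & np.isin(s, list("ACGT"))
    L = len(q)
    w = cfg.window
    if L < w:
        import warnings

        warnings.warn(
            f"query ({L} bp ungapped) shorter than window ({w} bp); empty profile"
        )
        return ConservationProfile(
            aln.query_name, subject, np.empty(0, int), np.empty(0, float), w, L
        )
    csum = np.concatenate([[0], np.cumsum(match)])
    ident = 100.0 * (csum[w:] - csum[:-w]) / w
    positions = np.arange(L - w + 1)
    return ConservationProfile(aln.query_name, subject, positions, ident, w, L)


@dataclass(frozen=True)
class ConservedSegment:
    """Half-open ungapped-query interval with its mean anchor identity."""

    start: int
    end: int
    mean_identity: float

    @property
    def length(self) -> int:
        return self.end - self.start


def conserved_segments(
    profile: ConservationProfile, cfg: ShadowConfig | None = None
) -> list[ConservedSegment]:
    """Call conserved segments from a windowed-identity profile.

    Maximal runs of anchors with identity >= the cutoff are found, runs
    spanning fewer than ``min_consensus_len`` bp are discarded, and each
    surviving run [a, b] is reported as [a, b + window) clipped to the query
    length. Extended segments that overlap are merged (anchor-weighted mean
    identity), so the output is sorted and non-overlapping.
    """
    cfg = cfg or ShadowConfig()
    above = profile.identity >= cfg.identity_cutoff
    segments: list[list[float]] = []  # [start, end, sum_ident, n_anchor]
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        run_span = j - i + 1
        if run_span >= cfg.min_consensus_len:
            start = int(profile.positions[i])
            end = min(int(profile.positions[j]) + profile.window, profile.query_length)
            ident_sum = float(profile.identity[i : j + 1].sum())
            if segments and start <= segments[-1][1]:
                segments[-1][1] = max(segments[-1][1], end)
                segments[-1][2] += ident_sum
                segments[-1][3] += run_span
            else:
                segments.append([start, end, ident_sum, run_span])
        i = j + 1
    return [
        ConservedSegment(int(s), int(e), tot / cnt) for s, e, tot, cnt in segments
    ]


def segments_to_bed(
    segments: list[ConservedSegment], name: str, path: str | Path
) -> None:
    """BED3+score (score = mean window identity, 1 decimal)."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{name}\t{seg.start}\t{seg.end}\t{seg.mean_identity:.1f}\n")


def consensus_to_fasta(name: str, consensus: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(consensus), 70):
            fh.write(consensus[i : i + 70] + "\n")
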