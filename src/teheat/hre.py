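"""Heat-shock-element (HSE/HRE) scanning and classification of LTR sequences.

Heat shock factor trimers bind arrays of 5-bp nGAAn / nTTCn modules. A
cluster of such modules in an LTR constitutes a putative heat-responsive
element (HRE), whose strength depends on module number and spacing:

* **P4** — four or more head-to-tail modules; the strongest HRE, bound by two
  HSF trimers.
* **P3** — exactly three head-to-tail modules; moderate strength, one trimer.
* **GAP** / **STEP** — three or more modules with irregular or 5-bp-spaced
  arrangements; low binding efficiency.
* **PROTO** — the nTTCnnGAAn two-module precursor; not a functional HRE by
  itself but the seed from which a P4 can arise by duplication.

The classification rules (notably the GAP/STEP boundary) are concentrated in
:func:`classify_cluster` so alternative readings are one-line changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "HSEModule",
    "HREConfig",
    "HRECall",
    "find_modules",
    "cluster_modules",
    "classify_cluster",
    "scan_ltr",
    "scan_fasta",
    "calls_to_bed",
    "calls_to_tsv",
]

MODULE_LEN = 5
P4 = "P4"
P3 = "P3"
GAP = "GAP"
STEP = "STEP"
PROTO = "PROTO"
NONE = "NONE"
HRE_TYPES = (P4, P3, GAP, STEP, PROTO, NONE)


@dataclass(frozen=True)
class HSEModule:
    """One matched 5-mer: nGAAn (sense) or nTTCn (antisense).

    ``start`` is the 0-based offset of the module's first base in the scanned
    sequence; ``sequence`` is the matched 5-mer (uppercased).
    """

    start: int
    orientation: str  # "GAA" or "TTC"
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != MODULE_LEN:
            raise ValueError("module must be 5 bp")
        if self.sequence[1:4] != self.orientation:
            raise ValueError("sequence core does not match orientation")

    @property
    def end(self) -> int:
        return self.start + MODULE_LEN


@dataclass(frozen=True)
class HREConfig:
    """Scanning and classification parameters.

    max_adjacent_gap : int
        Maximum bp between consecutive modules (next.start − prev.end) for
        them to remain in one cluster; default 5.
    min_basal_modules : int
        Minimum modules for a basal (GAP/STEP-grade) HRE; default 3.
    p4_min_modules : int
        Minimum head-to-tail run length for the strongest class; default 4.
    scan_both_orientations : bool
        Match nTTCn as well as nGAAn (default True).
    overlap_policy : str
        ``"greedy"`` (default): overlapping matches resolved left-to-right,
        keeping the earlier module and rescanning after its end.
        ``"all"``: report every match.
    require_alternation : bool
        Strict mode: head-to-tail runs must alternate GAA/TTC orientation to
        qualify as P4/P3 (off by default).
    """

    max_adjacent_gap: int = 5
    min_basal_modules: int = 3
    p4_min_modules: int = 4
    scan_both_orientations: bool = True
    overlap_policy: str = "greedy"
    require_alternation: bool = False

    def __post_init__(self) -> None:
        if self.max_adjacent_gap < 0:
            raise ValueError("max_adjacent_gap must be >= 0")
        if self.p4_min_modules < self.min_basal_modules:
            raise ValueError("p4_min_modules must be >= min_basal_modules")
        if self.overlap_policy not in {"greedy", "all"}:
            raise ValueError(f"bad overlap_policy {self.overlap_policy!r}")


@dataclass(frozen=True)
class HRECall:
    """A classified module cluster; ``span`` is 0-based half-open."""

    hre_type: str
    modules: tuple[HSEModule, ...]
    span: tuple[int, int]

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]


def find_modules(seq: str, cfg: HREConfig | None = None) -> list[HSEModule]:
    """All nGAAn / nTTCn 5-mers in ``seq`` (case-insensitive; N never matches).

    Flanking `n` positions must be A/C/G/T. Under the default greedy overlap
    policy an accepted module suppresses matches starting before its end.
    """
    cfg = cfg or HREConfig()
    s = seq.upper()
    matches: list[HSEModule] = []
    for i in range(len(s) - MODULE_LEN + 1):
        w = s[i : i + MODULE_LEN]
        if any(c not in "ACGT" for c in w):
            continue
        core = w[1:4]
        if core == "GAA" or (core == "TTC" and cfg.scan_both_orientations):
            matches.append(HSEModule(i, core, w))
    if cfg.overlap_policy == "all":
        return matches
    kept: list[HSEModule] = []
    next_free = 0
    for m in matches:
        if m.start >= next_free:
            kept.append(m)
            next_free = m.end
    return kept


def cluster_modules(
    modules: Iterable[HSEModule], cfg: HREConfig | None = None
) -> list[list[HSEModule]]:
    """Greedy left-to-right clustering by inter-module gap.

    Consecutive modules share a cluster iff ``next.start − prev.end`` is at
    most ``max_adjacent_gap``; overlapping modules (negative gap, possible
    only under ``overlap_policy="all"``) always share a cluster.
    """
    cfg = cfg or HREConfig()
    mods = sorted(modules, key=lambda m: m.start)
    clusters: list[list[HSEModule]] = []
    for m in mods:
        if clusters and m.start - clusters[-1][-1].end <= cfg.max_adjacent_gap:
            clusters[-1].append(m)
        else:
            clusters.append([m])
    return clusters


def _runs(modules: list[HSEModule]) -> list[list[HSEModule]]:
    """Maximal head-to-tail runs (consecutive gap exactly 0)."""
    runs: list[list[HSEModule]] = []
    for m in modules:
        if runs and m.start == runs[-1][-1].end:
            runs[-1].append(m)
        else:
            runs.append([m])
    return runs


def _alternates(run: list[HSEModule]) -> bool:
    return all(a.orientation != b.orientation for a, b in zip(run, run[1:]))


def classify_cluster(
    cluster: list[HSEModule], cfg: HREConfig | None = None
) -> HRECall:
    """Apply the HRE rule table to one module cluster.

    Precedence P4 > P3 > GAP > STEP > PROTO > NONE:

    * P4 — longest head-to-tail run >= ``p4_min_modules``.
    * P3 — longest head-to-tail run == 3.
    * GAP — >= ``min_basal_modules`` total, longest run <= 2, at least one
      gap of exactly 5 bp between blocks, both orientations present.
    * STEP — >= ``min_basal_modules`` total, every consecutive gap exactly
      5 bp, uniform orientation.
    * PROTO — exactly two head-to-tail modules oriented (TTC, GAA), i.e. the
      nTTCnnGAAn precursor.
    """
    cfg = cfg or HREConfig()
    if not cluster:
        return HRECall(NONE, (), (0, 0))
    mods = tuple(sorted(cluster, key=lambda m: m.start))
    span = (mods[0].start, mods[-1].end)
    gaps = [b.start - a.end for a, b in zip(mods, mods[1:])]
    runs = _runs(list(mods))
    if cfg.require_alternation:
        p_runs = [r for r in runs if _alternates(r)]
    else:
        p_runs = runs
    longest_p = max((len(r) for r in p_runs), default=0)
    longest = max(len(r) for r in runs)
    orientations = {m.orientation for m in mods}
    n = len(mods)

    if longest_p >= cfg.p4_min_modules:
        hre_type = P4
    elif longest_p == 3:
        hre_type = P3
    elif (
        n >= cfg.min_basal_modules
        and longest <= 2
        and any(g == 5 for g in gaps)
        and len(orientations) == 2
    ):
        hre_type = GAP
    elif (
        n >= cfg.min_basal_modules
        and all(g == 5 for g in gaps)
        and len(orientations) == 1
    ):
        hre_type = STEP
    elif (
        n == 2
        and gaps[0] == 0
        and (mods[0].orientation, mods[1].orientation) == ("TTC", "GAA")
    ):
        hre_type = PROTO
    else:
        hre_type = NONE
    return HRECall(hre_type, mods, span)


def scan_ltr(
    seq: str, cfg: HREConfig | None = None, include_none: bool = False
) -> list[HRECall]:
    """Full scan of one sequence: find, cluster, classify.

    Calls are sorted by start; NONE-grade clusters are suppressed unless
    ``include_none`` is set.
    """
    cfg = cfg or HREConfig()
    calls = [
        classify_cluster(cl, cfg) for cl in cluster_modules(find_modules(seq, cfg), cfg)
    ]
    if not include_none:
        calls = [c for c in calls if c.hre_type != NONE]
    return sorted(calls, key=lambda c: c.start)


def scan_fasta(
    path: str | Path, cfg: HREConfig | None = None, include_none: bool = False
) -> dict[str, list[HRECall]]:
    """Scan every record of a (multi-)FASTA file."""
    return {
        rec.id: scan_ltr(str(rec.seq), cfg, include_none)
        for rec in SeqIO.parse(str(path), "fasta")
    }


def calls_to_tsv(calls_by_record: dict[str, list[HRECall]], path: str | Path) -> None:
    """TSV: record, start, end, type, n_modules, comma-joined module starts."""
    with open(path, "w") as fh:
        fh.write("record\tstart\tend\thre_type\tn_modules\tmodule_starts\n")
        for rec, calls in calls_by_record.items():
            for c in calls:
                starts = ",".join(str(m.start) for m in c.modules)
                fh.write(
                    f"{rec}\t{c.start}\t{c.end}\t{c.hre_type}\t{c.n_modules}\t{starts}\n"
                )


def calls_to_bed(calls_by_record: dict[str, list[HRECall]], path: str | Path) -> None:
    """BED6 with name = hre_type and score = n_modules."""
    with open(path, "w") as fh:
        for rec, calls in calls_by_record.items():
            for c in calls:
                fh.write(
                    f"{rec}\t{c.start}\t{c.end}\t{c.hre_type}\t{c.n_modules}\t.\n"
                )
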