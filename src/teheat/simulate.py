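"""Synthetic fixtures: genomes, TE catalogues, multi-mapping reads, and LTRs
with planted HRE module clusters.

The simulator makes the whole toolkit testable without external data:

* :func:`simulate_genome` builds a single-chromosome genome of TE copies
  (family consensus + per-base divergence) separated by random intergenic
  spacers, together with the matching GFF3 catalogue.
* :func:`simulate_reads` draws error-free reads from TE copies, enumerates
  every exact genomic occurrence of each read by exhaustive substring search
  (this defines a read's mapped positions, independent of any aligner), and
  writes them as SAM records plus a *truth table* carrying each read's
  expected class and per-copy count weights.
* :func:`plant_hre` splices a canonical module arrangement of a requested
  HRE type into a module-free background.

The truth table is produced by a deliberately separate straight-line
re-statement of the read-classification and proportional-counting rules
(linear feature scan, inline class logic) sharing no code with
:mod:`teheat.comex`, so agreement between the two is evidence of
correctness rather than a tautology. Reads are drawn from the forward strand
only: classification and counting are unstranded, so strand adds nothing to
what the fixtures must exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "SimSpec",
    "simulate_genome",
    "simulate_reads",
    "simulate_dataset",
    "plant_hre",
    "hre_background",
    "HRE_SEGMENTS",
]

BASES = "ACGT"
CHROM = "chr1"


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one synthetic dataset.

    Defaults emulate a small multi-family TE genome read at 100-bp
    single-end (the read length of the emulated libraries): a handful of
    families with several copies each, 5 % per-base copy divergence from the
    family consensus, and uniform sampling of reads within each family.

    family_weights, when given, allocates ``depth_per_family × n_families``
    reads multinomially across families instead of a fixed per-family depth
    (used to plant stochastic expression ratios).

    shared_segment_bp > 0 copies an identical segment into one copy of each
    of the first two families, engineering cross-family exact multi-mapping
    (NMM reads).
    """

    n_families: int = 3
    copies_per_family: int = 4
    copy_divergence: float = 0.05
    te_length: int = 400
    intergenic_length: int = 300
    read_length: int = 100
    depth_per_family: int = 50
    seed: int = 1729
    family_weights: tuple[float, ...] | None = None
    shared_segment_bp: int = 0

    def __post_init__(self) -> None:
        if min(self.n_families, self.copies_per_family, self.te_length,
               self.intergenic_length, self.read_length,
               self.depth_per_family) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.copy_divergence <= 0.5:
            raise ValueError("copy_divergence must be in [0, 0.5]")
        if self.read_length > self.te_length:
            raise ValueError("read_length must be <= te_length")
        if self.te_length < 30:
            raise ValueError("te_length < 30 is infeasible")
        if self.family_weights is not None:
            if len(self.family_weights) != self.n_families:
                raise ValueError("family_weights length must equal n_families")
            if min(self.family_weights) < 0 or sum(self.family_weights) <= 0:
                raise ValueError("family_weights must be non-negative, not all zero")
        if self.shared_segment_bp and self.n_families < 2:
            raise ValueError("shared_segment_bp needs >= 2 families")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _mutate(rng: np.random.Generator, seq: str, p: float) -> str:
    if p == 0:
        return seq
    chars = list(seq)
    for i in np.flatnonzero(rng.random(len(chars)) < p):
        old = chars[i]
        chars[i] = BASES[(BASES.index(old) + int(rng.integers(1, 4))) % 4]
    return "".join(chars)


@dataclass
class SimGenome:
    """In-memory result of :func:`simulate_genome`."""

    sequence: str
    features: list[dict]  # chrom/start/end/te_id/family keys, GFF coordinates
    copy_seqs: dict[str, str]
    spec: SimSpec

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{CHROM}\n")
            for i in range(0, len(self.sequence), 70):
                fh.write(self.sequence[i : i + 70] + "\n")

    def write_gff(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for f in self.features:
                attrs = f"ID={f['te_id']};Family={f['family']};Superfamily=COPIA"
                fh.write(
                    f"{CHROM}\tteheat-sim\ttransposable_element\t{f['start']}"
                    f"\t{f['end']}\t.\t+\t.\t{attrs}\n"
                )


def simulate_genome(spec: SimSpec) -> SimGenome:
    """Deterministic genome + catalogue for a :class:`SimSpec`.

    Family consensus sequences are rejection-sampled to be mutually <60 %
    identical, so exact cross-family multi-mapping cannot arise by chance;
    it can only be engineered via ``shared_segment_bp``. Copies of a family
    are the consensus mutated at rate ``copy_divergence`` per base.
    """
    rng = np.random.default_rng(spec.seed)
    consensi: list[str] = []
    while len(consensi) < spec.n_families:
        cand = _random_seq(rng, spec.te_length)
        if all(_identity(cand, c) < 0.60 for c in consensi):
            consensi.append(cand)
    copy_seqs: dict[str, str] = {}
    order: list[tuple[str, str]] = []  # (te_id, family) in genomic order
    for fi, consensus in enumerate(consensi):
        fam = f"FAM{fi}"
        for ci in range(spec.copies_per_family):
            te_id = f"{fam}_{ci}"
            copy_seqs[te_id] = _mutate(rng, consensus, spec.copy_divergence)
            order.append((te_id, fam))
    if spec.shared_segment_bp:
        seg_len = min(spec.shared_segment_bp, spec.te_length)
        seg = _random_seq(rng, seg_len)
        for fam_i in (0, 1):
            te_id = f"FAM{fam_i}_0"
            s = copy_seqs[te_id]
            copy_seqs[te_id] = seg + s[seg_len:]
    pieces: list[str] = []
    features: list[dict] = []
    pos = 0  # 0-based running offset
    for te_id, fam in order:
        spacer = _random_seq(rng, spec.intergenic_length)
        pieces.append(spacer)
        pos += len(spacer)
        seq = copy_seqs[te_id]
        features.append(
            {
                "chrom": CHROM,
                "start": pos + 1,  # GFF 1-based inclusive
                "end": pos + len(seq),
                "te_id": te_id,
                "family": fam,
            }
        )
        pieces.append(seq)
        pos += len(seq)
    pieces.append(_random_seq(rng, spec.intergenic_length))
    return SimGenome("".join(pieces), features, copy_seqs, spec)


def _find_all(haystack: str, needle: str) -> list[int]:
    """0-based offsets of every exact occurrence (overlaps included)."""
    out: list[int] = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


# ---------------------------------------------------------------------------
# Independent truth-table classifier. Deliberately straight-line and separate
# from teheat.comex: linear scan over features, inline rules.
# ---------------------------------------------------------------------------

def _truth_classify(
    positions: list[int],
    read_len: int,
    features: list[dict],
    single_te_hit_policy: str = "discard",
) -> tuple[str, str | None, dict[str, float]]:
    k = len(positions)
    hit_ids: list[str | None] = []
    for p in positions:
        a_start, a_end = p + 1, p + read_len  # 1-based inclusive span
        best_id, best_ov = None, 0
        for f in features:
            ov = min(a_end, f["end"]) - max(a_start, f["start"]) + 1
            if ov >= 1 and (
                ov > best_ov or (ov == best_ov and best_id is not None
                                 and f["te_id"] < best_id)
            ):
                best_id, best_ov = f["te_id"], ov
        hit_ids.append(best_id)
    fam_by_id = {f["te_id"]: f["family"] for f in features}
    hit_families = sorted({fam_by_id[h] for h in hit_ids if h is not None})
    n_hit = sum(h is not None for h in hit_ids)
    if k == 1:
        if n_hit == 1:
            cls, fam = "UM", hit_families[0]
        else:
            cls, fam = "UNANNOTATED", None
    else:
        if n_hit == 0:
            cls, fam = "UNANNOTATED", None
        elif len(hit_families) > 1:
            cls, fam = "NMM", None
        elif n_hit >= 2:
            cls, fam = "SMM", hit_families[0]
        elif single_te_hit_policy == "keep":
            cls, fam = "SMM", hit_families[0]
        else:
            cls, fam = "NMM", None
    weights: dict[str, float] = {}
    if fam is not None:
        for h in hit_ids:
            if h is not None:
                weights[h] = weights.get(h, 0.0) + 1.0 / k
    return cls, fam, weights


def simulate_reads(
    genome: SimGenome, out_sam: str | Path | None = None
) -> pd.DataFrame:
    """Draw error-free reads and enumerate their exact mapped positions.

    Each read's positions are all exact occurrences of its sequence on the
    genome's forward strand (exhaustive substring search); the first
    occurrence becomes the primary SAM record, the rest secondary records.
    Returns the truth table, one row per read:

    read_id, source_te, k, positions (comma-joined 0-based), expected_class,
    expected_family, expected_weights ("te_id:w" semicolon-joined).
    """
    spec = genome.spec
    rng = np.random.default_rng(spec.seed + 1)
    n_fam = spec.n_families
    te_ids_by_family = [
        [f["te_id"] for f in genome.features if f["family"] == f"FAM{i}"]
        for i in range(n_fam)
    ]
    if spec.family_weights is not None:
        total = spec.depth_per_family * n_fam
        w = np.asarray(spec.family_weights, dtype=float)
        fam_choice = rng.choice(n_fam, size=total, p=w / w.sum())
        per_family = np.bincount(fam_choice, minlength=n_fam)
    else:
        per_family = np.full(n_fam, spec.depth_per_family)
    rows = []
    read_i = 0
    for fi in range(n_fam):
        for _ in range(int(per_family[fi])):
            te_id = te_ids_by_family[fi][int(rng.integers(len(te_ids_by_family[fi])))]
            copy = genome.copy_seqs[te_id]
            off = int(rng.integers(0, len(copy) - spec.read_length + 1))
            seq = copy[off : off + spec.read_length]
            positions = _find_all(genome.sequence, seq)
            cls, fam, weights = _truth_classify(
                positions, spec.read_length, genome.features
            )
            rows.append(
                {
                    "read_id": f"read{read_i:05d}",
                    "source_te": te_id,
                    "sequence": seq,
                    "k": len(positions),
                    "positions": ",".join(map(str, positions)),
                    "expected_class": cls,
                    "expected_family": fam if fam is not None else "",
                    "expected_weights": ";".join(
                        f"{t}:{w:.17g}" for t, w in sorted(weights.items())
                    ),
                }
            )
            read_i += 1
    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id", "source_te", "sequence", "k", "positions",
            "expected_class", "expected_family", "expected_weights",
        ],
    )
    if out_sam is not None:
        _write_sam(genome, truth, out_sam)
    return truth


def _write_sam(genome: SimGenome, truth: pd.DataFrame, path: str | Path) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": CHROM, "LN": len(genome.sequence)}],
    }
    rl = genome.spec.read_length
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        for _, row in truth.iterrows():
            positions = [int(p) for p in row["positions"].split(",")]
            for j, pos in enumerate(positions):
                a = pysam.AlignedSegment(sam.header)
                a.query_name = row["read_id"]
                a.flag = 0 if j == 0 else 256
                a.reference_id = 0
                a.reference_start = pos  # SAM 0-based
                a.mapping_quality = 50 if len(positions) == 1 else 1
                a.cigarstring = f"{rl}M"
                if j == 0:
                    a.query_sequence = row["sequence"]
                    a.query_qualities = pysam.qualitystring_to_array("I" * rl)
                sam.write(a)


def simulate_dataset(spec: SimSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, catalogue GFF3, reads SAM, and truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(spec)
    paths = {
        "fasta": out / "genome.fa",
        "gff": out / "catalogue.gff3",
        "sam": out / "reads.sam",
        "truth": out / "truth.tsv",
    }
    genome.write_fasta(paths["fasta"])
    genome.write_gff(paths["gff"])
    truth = simulate_reads(genome, out_sam=paths["sam"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# HRE planting
# ---------------------------------------------------------------------------

# Canonical module arrangements. Module starts are relative to the segment;
# cores at offset+1 of each module.
HRE_SEGMENTS: dict[str, tuple[str, tuple[int, ...]]] = {
    "P4": ("cGAAccTTCccGAAccTTCc", (0, 5, 10, 15)),
    "P3": ("cGAAccTTCccGAAc", (0, 5, 10)),
    "GAP": ("cGAAccTTCcctcgccGAAc", (0, 5, 15)),
    "STEP": ("cGAAcctcgccGAAcctcgccGAAc", (0, 10, 20)),
    "PROTO": ("cTTCcaGAAc", (0, 5)),
}


def _module_starts(seq: str) -> list[int]:
    """Straight-line module finder used only for planting validation."""
    s = seq.upper()
    starts = []
    for i in range(len(s) - 4):
        w = s[i : i + 5]
        if all(c in "ACGT" for c in w) and w[1:4] in ("GAA", "TTC"):
            starts.append(i)
    return starts


def hre_background(length: int, seed: int) -> str:
    """Random sequence guaranteed free of nGAAn/nTTCn modules.

    Built base by base, resampling any base that would complete a GAA or TTC
    trigram, so no 5-mer anywhere contains a module core.
    """
    rng = np.random.default_rng(seed)
    out: list[str] = []
    while len(out) < length:
        b = BASES[int(rng.integers(0, 4))]
        tri = "".join(out[-2:]) + b
        if tri.endswith("GAA") or tri.endswith("TTC"):
            continue
        out.append(b)
    return "".join(out)


def plant_hre(
    background: str, hre_type: str, offset: int, seed: int = 0
) -> tuple[str, dict]:
    """Splice a canonical arrangement of ``hre_type`` into ``background``.

    The background must be module-free within ``offset ± 30`` bp (and the
    splice must not create junction artefacts); violations raise ValueError.
    Returns the planted sequence and the expected call as a dict with keys
    ``hre_type``, ``start``, ``end``, ``module_starts``.

    ``hre_type="NONE"`` returns the background unchanged with no expected
    call.
    """
    if hre_type == "NONE":
        return background, {"hre_type": "NONE", "start": None, "end": None,
                            "module_starts": ()}
    if hre_type not in HRE_SEGMENTS:
        raise ValueError(f"unknown HRE type {hre_type!r}")
    seg, rel_starts = HRE_SEGMENTS[hre_type]
    if offset < 0 or offset + len(seg) > len(background):
        raise ValueError("segment does not fit the background at this offset")
    lo, hi = max(0, offset - 30), min(len(background), offset + len(seg) + 30)
    if _module_starts(background[lo:hi]):
        raise ValueError("background contains modules near the planting offset")
    planted = background[:offset] + seg + background[offset + len(seg):]
    expected_starts = tuple(offset + r for r in rel_starts)
    # validate locally so several elements can be planted on one background
    local = tuple(
        lo + s for s in _module_starts(planted[lo : offset + len(seg) + 30])
    )
    if local != expected_starts:
        raise ValueError("planting created junction artefacts")
    return planted, {
        "hre_type": hre_type,
        "start": offset,
        "end": offset + len(seg),
        "module_starts": expected_starts,
    }


def plant_hre_dataset(
    hre_type: str, length: int, offset: int, seed: int, max_tries: int = 50
) -> tuple[str, dict]:
    """Seeded background generation + planting, retrying clean backgrounds."""
    for t in range(max_tries):
        bg = hre_background(length, seed + 1_000_003 * t)
        try:
            return plant_hre(bg, hre_type, offset)
        except ValueError:
            continue
    raise RuntimeError(f"could not plant {hre_type} after {max_tries} tries")
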