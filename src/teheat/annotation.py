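"""TE catalogue I/O and interval queries.

A transposable-element (TE) catalogue is a GFF3 file in which every feature is
one annotated TE copy carrying a family label (e.g. ``ONSEN``, ``COPIA37``)
and optionally a superfamily label (``COPIA``, ``GYPSY``, ``LINE``, ...).
The catalogue is the reference against which aligned RNA-seq reads are
classified, so it must be validated (unique copy identifiers, sane
coordinates) and support fast interval overlap queries.

Coordinates are GFF convention throughout this module: 1-based, inclusive on
both ends. Conversion from SAM alignment spans happens exactly once, in
:mod:`teheat.comex`.
"""

from __future__ import annotations

import io
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

__all__ = [
    "TEFeature",
    "TECatalogue",
    "GFFParseError",
    "CatalogueValidationError",
    "read_te_gff",
    "write_te_gff",
    "overlapping_features",
]


class GFFParseError(ValueError):
    """A GFF3 line could not be parsed; carries the 1-based line number."""


class CatalogueValidationError(ValueError):
    """The catalogue violates an invariant (e.g. duplicate te_id)."""


@dataclass(frozen=True)
class TEFeature:
    """One annotated TE copy.

    Attributes
    ----------
    chrom : str
        Sequence (chromosome/scaffold) name.
    start, end : int
        1-based inclusive genomic coordinates.
    strand : str
        One of ``+``, ``-``, ``.``.
    te_id : str
        Identifier, unique within a catalogue.
    family : str
        TE family name; never empty.
    superfamily : str
        Higher-level group (COPIA, GYPSY, LINE, SINE, SADHU, DNA, HELITRON,
        ...); may be empty when the annotation does not provide one.
    """

    chrom: str
    start: int
    end: int
    strand: str
    te_id: str
    family: str
    superfamily: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CatalogueValidationError(
                f"{self.te_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise CatalogueValidationError(f"{self.te_id}: start {self.start} < 1")
        if not self.family:
            raise CatalogueValidationError(f"{self.te_id}: empty family")
        if self.strand not in {"+", "-", "."}:
            raise CatalogueValidationError(
                f"{self.te_id}: bad strand {self.strand!r}"
            )

    @property
    def length(self) -> int:
        """Feature length in bp (end − start + 1)."""
        return self.end - self.start + 1

    def overlap_bp(self, start: int, end: int) -> int:
        """Overlap in bp with the 1-based inclusive interval [start, end]."""
        return max(0, min(self.end, end) - max(self.start, start) + 1)


class TECatalogue:
    """Validated, indexed collection of :class:`TEFeature`.

    Maintains a per-family member index and a per-chromosome interval tree
    for overlap queries.
    """

    def __init__(self, features: Iterable[TEFeature]):
        self.features: list[TEFeature] = list(features)
        self._by_id: dict[str, TEFeature] = {}
        self.family_index: dict[str, list[str]] = defaultdict(list)
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for f in self.features:
            if f.te_id in self._by_id:
                raise CatalogueValidationError(f"duplicate te_id {f.te_id!r}")
            self._by_id[f.te_id] = f
            self.family_index[f.family].append(f.te_id)
            # IntervalTree is half-open; [start, end] inclusive -> [start, end+1)
            self._trees[f.chrom].addi(f.start, f.end + 1, f)
        self.family_index = dict(self.family_index)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[TEFeature]:
        return iter(self.features)

    def __contains__(self, te_id: str) -> bool:
        return te_id in self._by_id

    def get(self, te_id: str) -> TEFeature:
        return self._by_id[te_id]

    @property
    def families(self) -> list[str]:
        return sorted(self.family_index)

    def overlapping(self, chrom: str, start: int, end: int) -> list[TEFeature]:
        """All features with ≥1 bp overlap of 1-based inclusive [start, end].

        An unknown chromosome yields an empty list. Results are sorted by
        (start, te_id).
        """
        if start > end:
            raise ValueError(f"start {start} > end {end}")
        if chrom not in self._trees:
            return []
        hits = [iv.data for iv in self._trees[chrom].overlap(start, end + 1)]
        return sorted(hits, key=lambda f: (f.start, f.te_id))

    def family_of(self, te_id: str) -> str:
        return self._by_id[te_id].family

    def summary(self) -> pd.DataFrame:
        """Per-family copy count and total annotated bp."""
        rows = [
            {
                "family": fam,
                "n_copies": len(ids),
                "total_bp": sum(self._by_id[i].length for i in ids),
            }
            for fam, ids in sorted(self.family_index.items())
        ]
        return pd.DataFrame(rows, columns=["family", "n_copies", "total_bp"])


def _attr_first(attrs, key: str) -> str | None:
    vals = attrs.get(key)
    if not vals:
        return None
    return vals[0]


def read_te_gff(
    path: str | Path,
    family_attribute: str = "Family",
    superfamily_attribute: str = "Superfamily",
    on_missing_family: str = "error",
    family_from_id_prefix: bool = False,
) -> TECatalogue:
    """Read a TE catalogue from GFF3.

    Parameters
    ----------
    path
        GFF3 file; every non-comment line is taken as one TE feature.
    family_attribute
        Attribute key holding the family name (default ``Family``).
    superfamily_attribute
        Attribute key for the superfamily; optional in the file.
    on_missing_family
        ``"error"`` (default), ``"skip"`` the feature, or ``"unknown"`` to
        assign family ``UNKNOWN``.
    family_from_id_prefix
        Fallback: derive the family from the te_id by stripping a trailing
        ``_<n>`` copy suffix (e.g. ``ONSEN_3`` → ``ONSEN``).

    Raises
    ------
    GFFParseError
        On a malformed GFF line (message includes the line number).
    CatalogueValidationError
        On duplicate te_id or other invariant violations.
    """
    if on_missing_family not in {"error", "skip", "unknown"}:
        raise ValueError(f"bad on_missing_family {on_missing_family!r}")
    features: list[TEFeature] = []
    skipped: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise GFFParseError(
                    f"line {lineno}: expected 9 tab-separated columns, "
                    f"got {line.count(chr(9)) + 1}"
                )
            try:
                gf = feature_from_line(line)
                int(gf.start), int(gf.end)
            except Exception as exc:  # gffutils raises assorted exceptions
                raise GFFParseError(f"line {lineno}: {exc}") from exc
            te_id = _attr_first(gf.attributes, "ID") or f"feature_{lineno}"
            family = _attr_first(gf.attributes, family_attribute)
            if family is None and family_from_id_prefix:
                family = te_id.rsplit("_", 1)[0]
            if family is None:
                if on_missing_family == "error":
                    raise CatalogueValidationError(
                        f"line {lineno}: feature {te_id!r} lacks attribute "
                        f"{family_attribute!r}"
                    )
                if on_missing_family == "skip":
                    skipped.append(te_id)
                    continue
                family = "UNKNOWN"
            superfamily = _attr_first(gf.attributes, superfamily_attribute) or ""
            features.append(
                TEFeature(
                    chrom=gf.seqid,
                    start=int(gf.start),
                    end=int(gf.end),
                    strand=gf.strand if gf.strand in "+-" else ".",
                    te_id=te_id,
                    family=family,
                    superfamily=superfamily,
                )
            )
    cat = TECatalogue(features)
    cat.skipped_missing_family = skipped  # type: ignore[attr-defined]
    return cat


def write_te_gff(
    cat: TECatalogue,
    path: str | Path,
    family_attribute: str = "Family",
    superfamily_attribute: str = "Superfamily",
    source: str = "teheat",
    feature_type: str = "transposable_element",
) -> None:
    """Write a catalogue back to GFF3 (round-trips all TEFeature fields)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in cat:
            attrs = [f"ID={f.te_id}", f"{family_attribute}={f.family}"]
            if f.superfamily:
                attrs.append(f"{superfamily_attribute}={f.superfamily}")
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        source,
                        feature_type,
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def overlapping_features(
    cat: TECatalogue, chrom: str, start: int, end: int
) -> list[TEFeature]:
    """Functional alias of :meth:`TECatalogue.overlapping`."""
    return cat.overlapping(chrom, start, end)


def catalogue_from_string(gff_text: str, **kwargs) -> TECatalogue:
    """Build a catalogue from in-memory GFF3 text (testing convenience)."""
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as tf:
        tf.write(gff_text)
        name = tf.name
    try:
        return read_te_gff(name, **kwargs)
    finally:
        Path(name).unlink(missing_ok=True)
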