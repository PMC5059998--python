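"""Run configuration and the end-to-end pipeline driver.

RunConfig merges the per-stage configurations (counting, HRE scanning,
shadowing, simulation) with file paths, a seed, and a log level. Values come
from defaults, overridden by a YAML config file, overridden by CLI flags; the
effective configuration is echoed to the log and written next to the outputs
so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .annotation import read_te_gff
from .comex import (
    CountingConfig,
    count_sample,
    export_deseq_matrix,
    filter_expressed,
    rpkm,
)
from .hre import HREConfig, calls_to_bed, calls_to_tsv, scan_fasta
from .shadow import (
    AlignedSet,
    ShadowConfig,
    build_consensus,
    conserved_segments,
    consensus_to_fasta,
    segments_to_bed,
    windowed_identity,
)
from .simulate import SimSpec

logger = logging.getLogger("teheat")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs carry a .partial suffix."""


@dataclass
class RunConfig:
    """Merged configuration for `teheat run`."""

    counting: CountingConfig = field(default_factory=CountingConfig)
    hre: HREConfig = field(default_factory=HREConfig)
    shadow: ShadowConfig = field(default_factory=ShadowConfig)
    sim: SimSpec = field(default_factory=SimSpec)
    bam: str | None = None
    gff: str | None = None
    family_attribute: str = "Family"
    ltr_fasta: str | None = None
    shadow_alignment: str | None = None
    shadow_query: str | None = None
    out_dir: str = "teheat_out"
    seed: int = 1729
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict({**data, **{k: v for k, v in overrides.items()
                                         if v is not None}})

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sections = {
            "counting": CountingConfig,
            "hre": HREConfig,
            "shadow": ShadowConfig,
            "sim": SimSpec,
        }
        kwargs: dict = {}
        for key, val in data.items():
            if key in sections:
                kwargs[key] = sections[key](**val) if isinstance(val, dict) else val
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["family_weights"] = (
            list(self.sim.family_weights) if self.sim.family_weights else None
        )
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _mark_partial(out: Path) -> None:
    for p in out.iterdir():
        if p.is_file() and not p.name.endswith(".partial"):
            p.rename(p.with_name(p.name + ".partial"))


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Chain count → RPKM → filter → export, HRE scan, and shadowing.

    Stages whose inputs are not configured are skipped. Any stage failure
    renames the partial outputs with a ``.partial`` suffix and raises
    :class:`PipelineError`.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    logger.info("effective config: %s", config.to_dict())
    config.to_yaml(out / "effective_config.yaml")
    try:
        if config.bam and config.gff:
            _stage_count(config, out)
        if config.ltr_fasta:
            _stage_hre(config, out)
        if config.shadow_alignment and config.shadow_query:
            _stage_shadow(config, out)
    except Exception as exc:
        _mark_partial(out)
        raise PipelineError(str(exc)) from exc
    return out


def _stage_count(config: RunConfig, out: Path) -> None:
    cat = read_te_gff(config.gff, family_attribute=config.family_attribute)
    res = count_sample(config.bam, cat, config.counting)
    res.copy_counts.to_tsv(out / "copy_counts.tsv")
    res.family_counts.to_tsv(out / "family_counts.tsv")
    copy_rpkm = rpkm(res.copy_counts)
    fam_rpkm = rpkm(res.family_counts)
    copy_rpkm.to_tsv(out / "copy_rpkm.tsv")
    fam_rpkm.to_tsv(out / "family_rpkm.tsv")
    filter_expressed(fam_rpkm, config.counting).to_tsv(
        out / "family_rpkm_expressed.tsv"
    )
    export_deseq_matrix(
        res.family_counts, out / "family_counts_deseq.tsv",
        out / "family_counts_deseq.fractional.tsv",
    )
    with open(out / "read_class_stats.tsv", "w") as fh:
        fh.write("class\tn_reads\n")
        for cls, n in res.class_stats.items():
            fh.write(f"{cls}\t{n}\n")
    logger.info("counted %s: %s", res.sample, res.class_stats)


def _stage_hre(config: RunConfig, out: Path) -> None:
    calls = scan_fasta(config.ltr_fasta, config.hre)
    calls_to_tsv(calls, out / "hre_calls.tsv")
    calls_to_bed(calls, out / "hre_calls.bed")
    logger.info("HRE calls: %d records", len(calls))


def _stage_shadow(config: RunConfig, out: Path) -> None:
    aln = AlignedSet.from_fasta(config.shadow_alignment, config.shadow_query)
    consensus = build_consensus(
        {n: s for n, s in aln.records.items() if n != aln.query_name}
    )
    consensus_to_fasta("consensus", consensus, out / "shadow_consensus.fa")
    for subject in aln.records:
        if subject == aln.query_name:
            continue
        prof = windowed_identity(aln, subject, config.shadow)
        prof.to_tsv(out / f"shadow_profile.{subject}.tsv")
        segs = conserved_segments(prof, config.shadow)
        segments_to_bed(segs, aln.query_name, out / f"shadow_segments.{subject}.bed")
    logger.info("shadowed %d subjects", len(aln.records) - 1)
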