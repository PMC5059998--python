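# teheat

Quantifying the transcription of transposable elements (TEs) from RNA-seq is
hard because a read from a multi-copy family aligns equally well to many
genomic positions. `teheat` implements a proportional counting pipeline for
exactly this situation, together with two companion analyses of the
cis-regulatory regions that make some TE families stress-responsive: a
heat-shock-element (HRE) scanner for LTR promoter sequences and a
sliding-window conservation ("shadowing") profiler. It is aimed at plant
genomicists studying stress-responsive LTR retrotransposons (ONSEN-like
COPIA families and relatives), but nothing in it is species-specific.

## The method

**Proportional TE counting.** Given alignments that report *all* alternative
positions per read (e.g. a spliced aligner with secondary alignments kept)
and a GFF3 TE catalogue with per-copy family labels, every read is classified
by the families its mapped positions touch:

* **UM** — uniquely mapped (k = 1): accepted directly;
* **SMM** — specifically multiply mapped: all TE-overlapping positions fall
  in copies of one family — informative, kept;
* **NMM** — non-specifically multiply mapped: positions span ≥ 2 families —
  discarded;
* **UNANNOTATED** — no position overlaps a catalogued TE.

Each retained read of multiplicity k contributes weight 1/k to every TE copy
it overlaps, so no read adds more than one unit of evidence. Copy counts are
summed per family, converted to RPKM
(count / (length/10³) / (library/10⁶)), and filtered at ≥ 0.55 RPKM in at
least one sample; integerized matrices ready for DESeq-style differential
testing are exported alongside the raw fractional counts.

**HRE scanning.** Heat shock factor trimers bind arrays of 5-bp nGAAn/nTTCn
modules. The scanner finds all modules, clusters them (consecutive modules
≤ 5 bp apart), and classifies each cluster: **4P** (≥ 4 head-to-tail modules,
strongest), **3P** (exactly 3), **gap**/**step** (≥ 3 irregular or 5-bp-spaced
modules, weak), or **proto-HRE** (the nTTCnnGAAn two-module precursor).

**Conservation shadowing.** From an aligned FASTA, per-position percent
identity of a subject vs a query LTR over 20-bp windows of ungapped query
coordinates; runs ≥ 70 % identity spanning ≥ 7 bp become conserved segments.
An IUPAC-ambiguity consensus builder prepares species consensus sequences.

A fully deterministic simulator (`teheat.simulate`) generates synthetic
genomes, TE catalogues, error-free multi-mapping reads whose mapped positions
are enumerated by exhaustive substring search, and LTRs with planted HRE
clusters — every analysis is testable without external data.

## Worked example

```python
from teheat.simulate import SimSpec, simulate_dataset, plant_hre_dataset
from teheat.annotation import read_te_gff
from teheat.comex import CountingConfig, count_sample, rpkm, filter_expressed
from teheat.hre import scan_ltr

# two families x three identical copies, 30 reads each
spec = SimSpec(n_families=2, copies_per_family=3, copy_divergence=0.0,
               depth_per_family=30, seed=7)
paths = simulate_dataset(spec, "example_out")
cat = read_te_gff(paths["gff"])
res = count_sample(paths["sam"], cat)
print("read classes:", res.class_stats)
print(res.family_counts.counts)

fam_rpkm = rpkm(res.family_counts)
kept = filter_expressed(fam_rpkm, CountingConfig(rpkm_threshold=0.55))
print("expressed families:", list(kept.counts.index))

seq, expected = plant_hre_dataset("P4", length=300, offset=120, seed=5)
for call in scan_ltr(seq):
    print(call.hre_type, call.span, call.n_modules)
```

prints

```
read classes: {'UM': 0, 'SMM': 60, 'NMM': 0, 'UNANNOTATED': 0, 'total': 60}
      reads
FAM0   30.0
FAM1   30.0
expressed families: ['FAM0', 'FAM1']
P4 (120, 140) 4
```

With identical copies every read maps three times within its own family, so
all 60 reads are SMM; the 1/3 weights sum back to exactly the 30 reads
planted per family — the proportional method loses nothing to
multi-mapping. The planted four-module head-to-tail cluster is recovered as
one P4 call at its planted offset.

The same operations are available from the shell:

```bash
teheat simulate --out sim/ --seed 7
teheat comex count --bam sim/reads.sam --gff sim/catalogue.gff3 --out counts/
teheat hre scan --fasta ltrs.fa --out hre_calls.tsv
teheat shadow --aln ltr_alignment.fa --query AlONSEN --out shadow/
teheat run --config run.yaml          # end-to-end driver
```

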