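# grnavar

Mutation-aware guide-RNA (gRNA) detection, annotation and cell assignment
for single-cell CRISPR screens, plus Cas9 edit detection in matched
transcriptome data.

## The problem

Single-cell CRISPR screens (CROP-seq, Perturb-seq and relatives) read out
which guide each cell expresses by sequencing a targeted gRNA library with
cell barcodes (CB) and unique molecular identifiers (UMI). Standard feature
barcoding analysis assumes guides match their design — it even tolerates one
mismatch — but real libraries carry *mutant* guides introduced during oligo
synthesis, cloning, virus production, lentiviral integration, and cDNA
preparation. Undetected mutants inflate the apparent fraction of
untransformed cells, hide multiplets (droplets with two or more guides),
and dilute perturbation phenotypes, because even single-base spacer or
scaffold changes can abolish guide function.

`grnavar` works from barcode/UMI-tagged alignments against artificial
per-guide contigs and:

1. **calls a consensus sequence per cDNA molecule** — all reads sharing a
   (CB, UMI) pair vote; the plurality sequence wins and molecules with
   fewer than 2 supporting reads are discarded, which removes pure
   sequencing errors from the mutant pool;
2. **itemizes deviations from the designed cassette** by walking the
   alignment CIGAR (mismatches, insertions, deletions, skips, soft clips),
   names each distinct variant `<guide>` / `<guide>.<n>`, and classifies
   the likely origin of every mutant observation (virus pool, transduction
   or sub-clone, integration duplication, cDNA preparation) from how mutant
   and intact UMIs co-occur per cell;
3. **assigns guides to cells**: per guide, per-cell UMI counts (intact and
   variants pooled) are either compared to a fixed threshold *t* (assign
   iff count > *t*) or fitted with a two-component Gaussian mixture on
   log10 counts; the in-cell component's minimum count becomes the dynamic
   threshold. Cells are labelled `none` / `single_intact` / `single_mutant`
   / `multiplet`;
4. **detects Cas9 editing** in the expression library: reads over a 51 bp
   window centred on the predicted cut (3 nt upstream of the PAM) are
   deduplicated by a per-molecule union consensus; deletions spanning the
   cutsite are Cas9-induced, other indels and mismatches are reported but
   not attributed to Cas9.

A fully ground-truthed simulator generates the complete input set (guide
library, tagged BAMs, whitelist, miniature genome) with tunable depth,
ambient contamination and mutation-scenario mix, and powers the test suite
and a depth-versus-accuracy harness.

## Worked example

Simulate a small screen and run the whole pipeline on it:

```bash
grnavar simulate --n-cells 60 --seed 3 --out sim/
# the cassette template: a FASTA whose sequence contains "[spacer]" once
python -c "from grnavar.simulate import DEFAULT_TEMPLATE as t; print('>cassette\n'+t)" > template.fa
cat > run.yaml <<EOF
grna_bam: sim/grna.bam
whitelist: sim/whitelist.txt
guides: sim/guides.tsv
template: template.fa
outdir: out/
seed: 7
expression_bam: sim/expression.bam
genes_gtf: sim/genes.gtf
target_table: sim/targets.tsv
genome_fasta: sim/genome.fa
EOF
grnavar run-all --config run.yaml
```

The run prints the summary report (also written to `out/summary.json`).
On the simulated screen above it reads, in part:

```json
{
  "cells_total": 60,
  "cells_per_label": {"single_intact": 38, "single_mutant": 12,
                       "multiplet": 9, "none": 1},
  "variants_intact": 119,
  "variants_mutant": 27,
  "pct_cells_with_mutant_grna": 31.7,
  "molecules_surviving": 3195,
  "sequencing_saturation": 0.900
}
```

meaning: of 60 whitelisted cells, 38 received exactly one intact guide and
12 exactly one mutant guide, 9 droplets carry two guides (multiplets), and
one cell got none; 27 distinct mutant guide sequences were catalogued next
to the 119 designed ones seen in the data; 31.7 % of cells carry a mutant
guide; 90 % of reads were duplicates of already-seen molecules (sequencing
saturation).
Stage outputs land next to the summary: `consensus.sequence.gRNA.txt` and
`consensus.bam`, `gRNA.mutation.txt` (variants, events, region labels,
source scenarios), `mutation.spectrum.txt`, the MatrixMarket count matrix
under `matrix/`, `cell.assignment.txt`, `umi.thresholds.txt`, and
`editing.effect.txt`.

Each step is also available separately (`grnavar build-ref / consensus /
annotate / assign / edits`), and everything is importable as a library —
see `grnavar.pipeline.assign_from_bam` for the in-memory path.

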