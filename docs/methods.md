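# Methods

This note documents the models and procedures implemented in `grnavar`,
the defaults and why they were chosen, what the synthetic screens emulate,
and the numerical choices that are not forced by the science.

## Inputs and coordinate conventions

The pipeline starts from aligner output: a coordinate-sorted BAM of the
targeted gRNA library mapped against artificial per-guide contigs, carrying
a cell barcode and UMI in SAM tags (Cell Ranger dialect CB/UB/GN or
Dropseq-tools dialect XC/XM/gn), a cell-barcode whitelist, the guide design
table, and the cassette template. Alignment itself, barcode knee-point cell
calling, and 1-Hamming barcode/UMI error correction are upstream concerns;
barcodes are only rewritten through the optional lookup table that
reconciles feature-barcoding barcodes with expression barcodes (re-running
a Hamming correction here would correct twice). All coordinates are 0-based
half-open internally; GTF emission converts to the 1-based closed dialect.

The custom reference places each guide's cassette — upstream promoter/TSO
context, the spacer, and the scaffold/capture context — on its own contig,
so a splice-aware aligner annotates guide reads by contig. How much context
flanks the spacer on each side is decided entirely by the user's template
(a FASTA whose sequence contains the literal `[spacer]` placeholder once);
`context_length` only trims context symmetrically toward the spacer, in
proportion to the template's own split. The host genome is never bundled;
users concatenate the emitted contigs onto their reference. The emitted GTF
carries gene/transcript/exon per contig plus `region` feature lines holding
the cassette annotation, which makes FASTA+GTF a lossless serialization of
the reference (aligner reference builders ignore the extra feature type).

## Consensus calling

Reads sharing a (cell barcode, UMI) pair are treated as one cDNA molecule.
Two plurality votes collapse each group: first over the guide annotations
(a tie means no guide can be confidently called and the group is dropped,
with a count kept), then over the read sequences of the annotation-
concordant reads. "Same sequence" means exact string equality over the
aligned interval (soft clips excluded): the comparison is between whole
read sequences, not per-base pileups, so reads of unequal length vote as
distinct sequences and no base-quality weighting is applied. Sequence ties
are broken by a uniform draw from a single pipeline-level RNG (`--seed`,
default 17); candidates are sorted lexicographically first, so the draw is
independent of dictionary iteration order. The representative alignment of
the winning sequence (first in input order) carries the CIGAR into the
mutation annotator and the consensus BAM.

The read-support filter keeps molecules with ≥ `min_reads` reads (default
2). Support counts only annotation-concordant reads; `--count-all-reads`
switches to the whole group size. This filter is the sequencing-error
defence: an error in one read of a multi-read molecule loses the plurality
vote, and an error that is the only read of its molecule never reaches the
variant catalog. With exactly 2 reads of which one is erroneous the vote is
a coin flip, so error immunity is guaranteed only from 3 reads per UMI —
the simulator's error-immunity conditions use a 3-read floor for exactly
this reason.

## Mutation annotation and variant naming

Each consensus molecule is compared to its designed cassette by walking the
alignment CIGAR: aligned blocks (M/=/X) are compared base by base;
insertions, deletions, skips and soft clips become events anchored at the
reference base that follows them. The aligner's CIGAR is trusted — no
re-alignment is performed. A molecule with zero events over its aligned
span is intact; any event makes it mutant. This is deliberately stricter
than the 1-Hamming tolerance common in feature-barcoding pipelines, because
single-base changes measurably impair guide function. Soft-clipped bases
are evidence of deviation but have no reference coordinates; the event
records the clip length and bases at the alignment edge. A deletion
spanning a region boundary is attributed to the region containing its
leftmost deleted base; events outside the annotated cassette span are
labelled `upstream`/`downstream`.

Events serialize as `<pos><kind>:<ref>><alt>` tokens joined by `;`
(e.g. `47D:T>-`), with kind letters M/I/D/N/S. This grammar is this
package's own design: it is lossless (the consensus sequence can be rebuilt
from the reference plus the event list, which the test suite verifies as a
round-trip property) and diffable.

Molecules with identical (guide, event list) collapse into one variant.
Intact molecules take the bare guide id; mutants get `.1`, `.2`, …
ordered by descending UMI support and then first occurrence, so names are
deterministic across runs of the same input.

## Source classification

A mutant variant's likely origin is classified per (variant, cell) from
UMI co-occurrence with intact molecules of the same guide:

| constellation | call |
|---|---|
| variant observed in > 1 cell | `virus_pool` |
| sole cell, no intact UMIs of the guide there | `transduction_or_subclone` |
| > 1 mutant UMI and > 1 intact UMI in the cell | `integration_duplication` |
| exactly 1 mutant UMI next to ≥ 1 intact UMI | `cdna_prep` |
| anything else (e.g. several mutant, one intact) | `ambiguous` |

Sequencing errors never reach this stage; they are removed at consensus.
The rules are heuristics over observational data: a pool-level mutant that
happened to land in a single cell is indistinguishable from a transduction
error, which is why the first two rows share evidence classes.

## Mutation spectra

The per-position spectrum counts each event once at its leftmost cassette
coordinate, weighted by the variant's cell support (`--weight umis`
switches to UMI weighting; whether cells or molecules are the natural unit
is a reporting choice, and cells are the default because the spectrum is
meant to describe the library cells actually received). For libraries built
with template-switching oligos, `mask_tso` zeroes positions −2, −1 and 0
relative to the spacer start, where TSO artefacts masquerade as mutations.
The per-cell mutation frequency is the number of distinct mutated cassette
positions per cell divided by the profiled cassette length, scaled per
1000 nt so libraries sequencing different cassette spans are comparable.

## Guide-to-cell assignment

Ambient (cell-free) guide molecules produce low UMI counts in cells that do
not express the guide, so per-guide thresholds are required. Fixed mode
assigns a variant iff its count is strictly greater than the user threshold
(default 3). Dynamic mode fits a two-component Gaussian mixture to log10 of
the nonzero per-cell counts, pooling the intact guide with all its mutant
variants — a mutant competes for the same capture and amplification as its
parent, so it belongs to the same expression distribution. Zeros are
excluded (cells without the guide would otherwise dominate), the
higher-mean component is in-cell, membership is posterior ≥ 0.5, and the
threshold is the minimum raw count among in-cell members; assignment in
this mode is therefore inclusive (≥). The log10 scale follows the
feature-barcoding practice this mode is modelled on; `--gmm-scale linear`
is available.

Fallbacks, all logged with their reason in `umi.thresholds.txt`: fewer than
`min_cells` (default 10) nonzero observations, degenerate (all-equal)
counts, fit failure, or component means closer than half a decade on the
log10 scale. The last guard matters in practice: when a guide has no
ambient observations at all, a two-component fit splits the unimodal
in-cell distribution down the middle and would silently drop genuine
carriers. All fallbacks use the fixed threshold with strict (>) comparison.

Cells are labelled from their assigned variant set: `none`,
`single_intact`, `single_mutant`, or `multiplet` (≥ 2 variants, including
the intact+mutant-of-the-same-guide case produced by integration
duplication).

## Editing detection

For each guide target, the predicted cut sits 3 nt upstream of the PAM
(minus strand mirrored), with a symmetric, odd-width detection window
(default 51 bp). Expression-library reads are kept when they are primary,
tagged, overlap the window, and their aligned blocks overlap exons of the
window's gene and of no other gene — an internal unambiguous exon-overlap
assigner fills the role an external gene-counting tool would play, removing
a binary dependency while honouring the same "assigned to the target gene"
contract. Because reads of one molecule start at different offsets, the
per-(CB, UMI) consensus is a *union*: every window position covered by at
least one read gets a state (base or deletion); conflicts resolve by
majority with ties resolved to the reference match; insertions require a
strict majority of the reads covering their anchor. Spliced alignments (N)
advance the reference without generating deletion states — transcript
structure is never an edit. A molecule is `cutsite_deletion` iff a deletion
interval contains the cutsite base; other insertions/deletions are
`other_indel`, base changes alone are `mismatch_only`, and a clean window
is `unedited`. All events are reported regardless of class.

## The synthetic screens

The simulator emits pre-aligned reads (CIGARs computed from planted
events): since the pipeline consumes aligner output, fixtures legitimately
begin at BAM, and no aligner is needed anywhere in the tests.

Defaults describe one deeply sequenced CROP-seq-style experiment at desk
scale: 120 guides (4 per target gene plus 20 non-targeting controls),
85 % singlet / 10 % doublet / 5 % untransformed cells (a low-MOI mix after
selection), log-normal in-cell UMI counts with mean 43 per guide per cell,
ambient counts present in 5 % of (cell, guide) pairs with mean ~1, Poisson
reads per UMI with mean 10 (saturation ≈ 90 %), and per-base read error
10⁻³. The mutant-integration mix — 20 % virus-pool mutant integrations,
0.4 % transduction mutants, 1.4 % integration duplications, and an 18.5 %
chance that an intact integration gains one cDNA-preparation mutant UMI —
is proportioned to the scenario frequencies reported for deeply sequenced
screens, and yields ~20 % of cells carrying a mutant guide. The default
cell count is 500; tests and the acceptance script set explicit sizes per
analysis (e.g. 2,000 cells for the depth sweep, chosen as the smallest
population whose concordance estimates are stable to within a percent).
One pool-mutant variant is pre-drawn per guide so it recurs across cells;
transduction/duplication/cDNA events draw fresh, per-guide-unique single
events (60 % substitutions, 40 % single-base deletions across the full
annotated cassette).

The expression simulation is a miniature genome: one synthetic chromosome,
one single-exon gene per target, one cutsite per gene attached to the
gene's first guide. Cells carrying that guide intact are edited with
probability 0.7 (a 6 bp deletion spanning the cut); backgrounds of
off-cutsite 3 bp deletions (3 %) and point mismatches (5 %) are planted in
expressing cells, two 60 bp reads tiling the window per molecule.

What passing tests show — and what they do not: the generator reproduces
the *structure* the method relies on (bimodal per-guide counts, UMI-read
hierarchies, scenario-specific co-occurrence patterns, cutsite footprints)
but not chemistry-level artefacts: no PCR chimeras, no barcode collisions
or hopping, no position-dependent error profiles, no quality-score
information, and ambient molecules are drawn intact. Results on real
libraries therefore depend on upstream alignment and barcode correction
quality in ways these tests cannot certify.

## Numerical and degenerate-input choices

- Consensus tie-break candidates are sorted before the seeded draw;
  annotation ties discard the group rather than guess.
- The GMM is fitted with 3 initializations at a fixed `random_state`
  derived from the pipeline seed; thresholds are deterministic given seed.
- Empty inputs produce valid empty outputs (headers-only tables, empty
  indexed BAM, 0×0 MatrixMarket) rather than errors.
- A CIGAR that does not account for its sequence length excludes that
  molecule with a per-molecule error record; the run continues.
- An even editing-window width is rejected (the window must be symmetric
  around the cut); a missing PAM row skips that guide.
- Downsampling keeps each read independently with probability *f* from a
  seeded RNG, so repeated runs are identical.
- The pipeline is single-threaded; `--threads` is accepted for interface
  compatibility and recorded, and results never depend on it.

## Known limitations

- Variant suffixes are stable within a run but not across datasets; merge
  catalogs on the event string, not the name.
- The source classifier is per-guide-per-cell and cannot separate pool
  mutants seen in one cell from transduction errors (both are reported
  under the constellation that matches the evidence).
- The union consensus has no base-quality model; a systematic error shared
  by most reads of a molecule will be called.
- Structural interpretation of scaffold mutations (stem/loop disruption)
  and allele-frequency estimation of edits are out of scope.
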