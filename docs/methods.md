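# Methods

This note records the statistical definitions the package implements, the
conventions chosen where the literature leaves room, and what the synthetic
data generator does and does not emulate.

## CDS screening

A CDS is kept when its length is **strictly greater than 300 bp** and
divisible by 3, it starts with ATG, ends with TGA/TAA/TAG, and contains no
internal stop codon and no ambiguity code. The 300 bp threshold is applied
to the full nucleotide length including the stop codon (the literal
reading). Internal-stop and ambiguity exclusions are our additions: neither
sequence type supports codon counting, and both are flagged in the
screening manifest rather than silently dropped. Duplicate annotations of
one gene collapse to the longest copy; gene names are matched
case-insensitively with trailing copy suffixes stripped (`nad5-1` →
`nad5`), because organelle GenBank records are annotated inconsistently
across submitters. Coordinates are taken as Biopython parses them (1-based
inclusive in the file, 0-based half-open in memory); reverse-strand and
multi-exon CDSs are extracted spliced and strand-corrected.

## Index definitions and conventions

**RSCU.** `RSCU(c) = x_c · n_fam / Σ_fam x`. Families with zero total are
absent from the result rather than zero-filled, so pooled tables show which
families were actually observed. Single-codon families (Met, Trp) report
RSCU 1 when observed.

**Stop codons** never enter RSCU, ENC, CAI, CBI, Fop, GC3s or A3s..G3s.
They enter GC1/GC2/GC3/GCall only when `include_stop` is set (off by
default). Because the literature is ambiguous about whether "GC3" includes
non-synonymous third positions, both GC3 (all counted codons) and GC3s
(synonymously variable codons only) are always computed and reported.

**ENC (Wright).** Per family with at least 2 counted codons,
`F̂ = (n Σ p̂² − 1)/(n − 1)`; F̂ values are averaged within degeneracy
classes, and `ENC = 2 + Σ_k N_k / F̄_k` with the class counts of the active
code (9 twofold, 1 threefold, 5 fourfold, 3 sixfold families for the
standard code; the 2 counts Met and Trp). Conventions:

* families with fewer than 2 codons counted are skipped;
* a class mean ≤ 0 (possible at small counts, e.g. a 1/1 split in a
  twofold family gives F̂ = 0) is treated as missing;
* a missing threefold class is imputed as the mean of the twofold and
  fourfold class means (Wright's rule for unobserved Ile);
* any other missing class term is dropped and the partial sum rescaled by
  `61 / (2 + Σ_available N_k·k)` so uniform usage still maps to 61;
* the result is clipped to [20, 61]; with no computable family it is NaN.

The test suite checks this implementation against an independently coded
first-principles version on 1,000 random count tables (1e-9 agreement) and
against exact fixtures at both limits.

**CAI/CBI/Fop reference.** All three indices need a reference set of
highly expressed genes, and published organelle studies rarely state the
one their tooling used internally. The default here is self-derived and
explicit: the lowest-ENC decile of the analysed gene set (strongest bias,
putative high expression) is pooled, Sharp–Li weights are taken as
`w = RSCU/RSCU_max` per family, and each family's weight-1 codon is the
CBI/Fop optimal codon (ties break alphabetically). Any external weight
table can be supplied via `ReferenceSet.from_table`. Consequence: CAI/CBI/
Fop values are comparable within a run but not across tools with different
internal references, and published values computed with unstated references
(e.g. CodonW defaults) cannot be reproduced exactly — the per-run report
records which reference was used. Observed codons with zero or missing
weight are floored at 1e-4 inside the CAI logarithm, with a warning.

**CBI/Fop tallies** run over synonymously variable families only;
`N_ran = Σ_fam n_fam · k_opt,fam / n_fam-size` is the optimal count expected
under uniform synonymous usage. CBI is NaN when `N_tot = N_ran`.

## Diagnostics

**Neutrality plot.** OLS of GC12 on GC3 (percent scales), slope p-value
from the two-sided t-test on the slope coefficient. The verbal
interpretation emitted in reports calls slopes ≥ 0.5 mutation-dominated and
< 0.5 selection-dominated; the threshold is only for prose, all numbers are
reported. At least 3 genes and non-constant GC3 are required.

**ENC plot.** `ENC_exp(s) = 2 + s + 29/(s² + (1 − s)²)`; deviations are
observed − expected. The x-axis defaults to GC3s (the classic choice) with
GC3 available behind a flag, since "GC3" in the applied literature often
means either.

**PR2.** Strict mode (default) tallies third-position bases over the eight
fourfold-degenerate codon boxes (CTN, GTN, TCN, CCN, ACN, GCN, CGN, GGN),
i.e. Sueoka's fourfold sites including the fourfold sub-boxes of the
sixfold families; the loose mode uses all synonymously variable codons.
Points on an axis midline (x or y exactly 0.5) get no quadrant label; zero
denominators yield NaN coordinates and a flag.

**Correlations.** Pairwise Pearson r with two-sided p over codon number,
GC1, GC2, GC3, GCall, GC3s, CAI, CBI, Fop, ENC; stars at 0.05/0.01 with
**no multiple-testing correction** (deliberately mirroring common practice
in this literature; the output notes it). Constant variables report NaN.

**RSCU clustering.** Distance `1 − Pearson r` between RSCU vectors over
the 59 synonymously variable codons (scipy's `correlation` metric), average
linkage by default. Merge heights are non-decreasing for this combination;
the Newick serialization derives branch lengths from height differences.
A zero-variance row is an error naming the offending row.

## Optimal codons

Genes are ranked ascending by ENC; the first `ceil(0.10 · N)` (minimum 1)
form the high-expression pool — low ENC = strong bias = putative high
expression, the standard orientation — and the last form the low-expression
pool, with ENC ties broken by gene name. With 21 genes the pools hold 3
genes each; the ceiling rule is stated in the output. Pool RSCU is computed
on **summed counts**, not per-gene averages. A codon is optimal iff
RSCU-H > 1 and ΔRSCU = RSCU-H − RSCU-L ≥ 0.08; the RSCU > 1 criterion is
applied to the high-expression pool's RSCU. Single-codon families are never
callable (RSCU pinned at 1, ΔRSCU at 0). The audit table always carries
RSCU-H, RSCU-L, ΔRSCU and both flags so alternative callings can be checked
against it; applying these criteria to published tables can mark more
codons than a paper's own curated calls, and the package surfaces rather
than hides such differences.

## Synthetic data generator

The generator emulates the cross-gene statistical structure the
diagnostics assume, with explicit ground truth:

* **mutation regime** — per gene, θ ~ U(gc3_range) (default 0.28–0.58, the
  span observed across Medicago mitochondrial genes); every nucleotide of
  every codon position is G/C with probability θ (G:C and A:T split
  evenly), stop codons rejected and resampled. GC12 and GC3 then share the
  θ signal and the fitted neutrality slope approaches 1; finite gene
  lengths add sampling noise to GC3 (the regression's x-variable), so the
  recovered slope sits slightly below 1 (≈ 0.93–0.96 at 300–900 codons).
* **selection regime** — amino acids uniform over the 20; each codon is
  drawn from the preferred set for its amino acid with probability
  `selection_strength` (default 0.5), otherwise from its family weighted by
  a per-gene third-position composition parameter drawn from the same
  range but independent of positions 1–2. GC3 varies across genes while
  GC12 stays flat: slope ≈ 0. The default preferred set is the 15 optimal
  codons shared across the three Medicago mitogenomes.
* **mixed** — each gene assigned one regime with probability ½.

Genes are named after the 21 shared Medicago mitochondrial CDSs (then
numbered), start ATG, end TAA, contain no internal stop, and default to
101–670 codons (303–2010 bp) so every generated gene passes the screen.
Generation is vectorized and deterministic under a fixed seed.

What the generator does **not** emulate: real amino-acid composition
(uniform, not mitochondrial), codon autocorrelation along genes, indels or
annotation noise, strand-asymmetric mutation, between-gene length/function
correlations, or evolution along a phylogeny. Passing recovery tests
therefore demonstrates that the estimators detect the intended regimes
under clean conditions, not that real organelle data are this well
behaved.

The worked fixture (`worked_fixture()`) ships four tiny CDSs whose counts,
RSCU, positional GC and (where every family homozygosity is exactly 1) ENC
were computed by hand from the definitions, as an implementation-independent
anchor.

## Problem sizes and numerical choices

Recovery analyses use 20 generator seeds × 200 genes of 300–900 codons per
regime, enough to estimate the mean slope to about ±0.01 while keeping the
full suite fast. ENC oracle cross-checks use 1,000 random count tables.
Output tables round RSCU/ΔRSCU to 4 decimals, indices to 3 and percentages
to 2; all internal computation is double precision. Undefined statistics
(GC3s with no synonymous codons, CBI at a degenerate denominator, ENC with
no computable family) propagate as NaN, never as 0.

## Known limitations

* CAI/CBI/Fop depend on the reference choice (see above); cross-study
  comparison needs the same reference.
* The ENC missing-class renormalization is a documented convention, not
  part of Wright's original formula; it only engages on extremely sparse
  inputs.
* The pipeline's species-level RSCU dendrogram clusters pooled genome
  vectors; per-gene clustering is available through the library but not a
  pipeline output.
* No phylogenetic tree building: sequence alignment and ML trees are
  external-tool territory and out of scope.
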