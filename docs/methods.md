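# Methods

## Event reconstruction on the species tree

The species tree is fixed to `((Bo,Ml),(Pb,Hc))` by default (overridable
by flag or Newick input): the stated origins of INXP (Bo+Ml ancestor)
and INXE (Pb+Hc ancestor) imply exactly this topology. Branches are
named by the node they subtend — species codes for terminal branches,
`BoMl-ancestor` / `PbHc-ancestor` for the internal ones, `stem` for the
root.

**Dollo gain/loss.** Each family's presence set (species with ≥ 1 copy)
determines a unique minimal single-gain reconstruction: the gain sits on
the branch subtending the MRCA of the presence set, and one loss is
emitted per maximal subtended clade containing no retaining species.
Placing the gain at the MRCA is optimal — moving it rootward can only
add family-free clades — and the test suite checks the loss count
against exhaustive search over all gain placements for every presence
subset on the four-species tree and on random six-species trees.

**Duplications.** Family delimitation is an input (TSV), not inferred:
the families were circumscribed by eye on a supported tree, and no
algorithmic cut rule exists to reproduce that, so the package validates
the input (`validate_family_monophyly`) instead of guessing. Each
family's induced gene subtree is reconciled by LCA mapping; node *v* is
a duplication iff `map(v) == map(c)` for some child *c*, and the event
is placed on the branch leading to `map(v)`.

**Terminal counts.** A duplication is assumed to propagate one extra
copy to every descendant species that retains the family (no per-copy
loss modelling). A species' predicted gene count is then its number of
retained families plus the duplications on branches whose clade
contains it. This replay reproduces the published per-species counts
for Pb (9), Hc (19) and Ml (12). For Bo the encoded events imply 13
genes while the published total is 12; the two statements cannot both
hold under this model, so the fixture follows the event statements and
Bo's terminal count is reported but not asserted anywhere.

**Fixture choices.** The published counts do not say which family
carries the Pb+Hc-ancestor duplication; the fixture places it in INXE
(the family that arose on that branch), which is an arbitrary but
documented choice — the per-branch duplication totals are unaffected.

**Isoform removal.** Transcriptome assemblies contribute near-identical
isoforms that appear as same-species cherries with zero-length terminal
branches. `dedup_isoforms` removes one tip per such cherry until a fixed
point; branch lengths ≤ 1e−9 count as zero, and the lexicographically
smallest tip label is kept (which isoform the original analysis kept is
unstated; the choice only needs to be deterministic). The operation is
idempotent and touches nothing else.

## Synteny

Inter-gene distance is measured boundary-to-boundary (end of the
previous gene to the start of the next), not midpoint-to-midpoint or
span-based — the natural reading of "within 40 kb" for compact
clusters — and the 40 kb default is the working threshold for the
innexin cluster. GFF3 input (1-based, inclusive) is converted to
0-based half-open coordinates internally; BED passes through; strand is
ignored throughout. Every target-family locus lands in exactly one
(possibly singleton) cluster, and intervening counts are the non-target
genes wholly inside each inter-member gap.

Microsynteny blocks are maximal sets of one-to-one orthologs occupying
consecutive gene ranks in both genomes, with order and strand free.
Detection enumerates A-side intervals with incremental min/max rank
bookkeeping (O(n²), ample for the genome sizes used here) and keeps
maximal valid intervals; validity in A implies the same in B because
the map is one-to-one. Minimum block length defaults to 2.

## Coexpression

"Expressed" means raw UMI count ≥ 1; no normalization is applied
(threshold exposed as a flag). The marker rule is inclusive: a fraction
of exactly 0.5 makes a marker. Coexpression percentages use the smaller
of the two expressing-cell counts as denominator and are undefined —
emitted as missing, never 0 — when either gene has no expressing cell.
The per-cell histogram defaults to buckets 0/1/2/≥3; the alternative
strict bucketing is exposed as 0/1/2–3/>3 so the four fractions always
sum to one (a literal ">3" fourth bucket would leave cells with exactly
three expressed targets unbucketed). Bulk expression tables (TPM) are
consumed as-is; the A:B ratio summary is the per-sample median with
median absolute deviation, over samples where B > 0.

## Electrophysiology

Cells pass QC when input resistance ≥ 300 MΩ and seal ≥ 1 GΩ, both
inclusive. Unitary amplitudes come from the all-points histogram of a
segment (≥ 50 ms): Gaussian mixtures with 1–4 components are fitted and
the count chosen by BIC. The 4-component cap accommodates occasional
short-lived subconductance levels without unbounded model growth; the
exact level-detection procedure of the original recordings is not
described, so mixture fitting plus half-amplitude idealization is this
package's stated substitute. Two post-fit rules make the estimate
robust: components with weight < 0.05 are dropped (filter-transition
samples form low-weight bridges between levels), and components closer
than twice their pooled standard deviation are merged (unresolvable
above the noise). The unitary current is the median adjacent spacing of
the remaining means, signed away from the baseline, which is taken as
the most populated level (robust when openings are sparse). One
remaining component means "no activity".

Idealization assigns each sample to level *k* when it lies within
`[k−0.5, k+0.5)·i` of baseline and merges dwells shorter than twice the
filter rise time (0.3321/f_c). The I–V fit is ordinary least squares,
`i = g·(V − V_rev)`, with the slope (pA/mV = nS) reported in pS and the
reversal potential as the x-intercept; on noiseless collinear input it
is exact to machine precision. `P_o = I/(N·i)` uses the
baseline-subtracted mean current and the idealized maximum open count;
values outside [0, 1] are clamped with the raw value retained.

Nernst potentials default to 295.15 K ("room temperature" is otherwise
unstated; flag-overridable). Extracellular chloride sums the
contributions of every chloride salt in the recipe (NaCl + 2·CaCl₂ +
2·MgCl₂ = 524.8 mM against 210 mM internal); the nonselective-cation
prediction pools Na⁺+K⁺ on each side. With the recording solutions this
gives ≈ −95.1 mV (K⁺), ≈ −23.7 mV (Cl⁻) and ≈ +21.6 mV (X⁺).

## Synthetic data

All generators are pure functions of their parameter bundle; a global
seed fans out to four independent streams (families = 1, genomes = 2,
umi = 3, traces = 4) via numpy seed sequences, and every generator
returns machine-readable ground truth.

**Family histories** gain each family at the stem and draw a loss
(p = 0.15) or duplication (p = 0.10) per branch — moderate rates that
produce a realistic mixture of complete, pruned and duplicated
families; losses prune whole clades so regain is impossible, and
all-lost families are redrawn (counted). The returned event log is
*Dollo-canonical*: gain re-placed at the MRCA of survivors, losses as
maximal extinct clades, duplications re-placed at the MRCA of their
surviving descendants and dropped when none survive. Only this
canonical form is identifiable from tip data, so it — not the raw
draws, which are also returned — is the recovery target. A
duplication's copied lineage descends as a plain single-copy clade, so
each duplication adds exactly one copy per retaining species, matching
the replay rule above.

**Gene orders** place ~30 background genes with 60–120 kb spacing (well
above the 40 kb threshold) and insert planted clusters with 5 kb
internal gaps; the "recoverable" flag enforces intra-gap < minimum
background spacing. The second genome keeps each planted run contiguous
and separates every other gene with private (non-orthologous) spacer
genes, so the planted runs are the only microsynteny present by
construction.

**UMI matrices** draw negative-binomial counts (mean 3, size 1.5 —
overdispersed, as UMI data are; Poisson would understate dropout) for
genes switched on per (metacell, gene); each metacell gets a few
high-probability program genes over a 0.15 base rate. Planted pairs
fire together on a shared latent program in a set fraction of cells,
and the truth table carries the analytic expected coexpression
percentage, 100·(1 − p₀) for equal depths where p₀ is the NB zero
probability. The generator emulates metacell structure, overdispersion
and dropout; it does not emulate ambient RNA, doublets or
depth-per-cell variation, so passing tests demonstrate correctness of
the statistics, not robustness to those artefacts.

**Gating traces** simulate independent two-state channels with exact
exponential dwell times (defaults k_open = 30 s⁻¹, k_close = 70 s⁻¹,
i.e. stationary P_o = 0.3, so the closed level dominates the histogram
as in the recordings), unitary driving force g·(V − V_rev) with
g = 340 pS and V_rev = 0 as ground truth, Gaussian noise (σ = 2 pA),
and zero-phase 4th-order Butterworth filtering at 2 kHz with 10 kHz
sampling. Zero calcium forces k_open = 0 (the high-calcium condition is
only bounded in the source, so calcium is treated as a binary gate).
Bursting, modal gating and capacitance transients are out of scope.

## Problem sizes and numerical choices

Test and analysis runs use sizes that keep the full suite under a few
minutes while leaving comfortable statistical margins: 200 simulated
families for event-log recovery; 100 random 40-gene genomes for the
synteny oracles; 5,000 cells for the planted-coexpression check (±3
percentage points); 5 × 200 ms sweeps per voltage at 9 voltages for I–V
recovery (tolerance 10 % on g, 10 mV on V_rev); 100 zero-calcium runs
for the silent-control rate (≥ 95 %). All randomness is seeded;
hypothesis-based property tests run derandomized.

## Known limitations

- Sequence-level work (similarity search, alignment, tree inference) is
  out of scope; the pipeline consumes finished trees and assignments.
- The Dollo model cannot represent regain; histories that would need it
  are reported in their canonical minimal form.
- Statistical significance of synteny conservation is not assessed.
- Metacell construction is taken from input, never computed.
- Relative ion-permeability estimation from reversal potentials is
  deliberately not implemented.
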