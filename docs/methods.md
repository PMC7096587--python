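# Methods

## Problem

Within an enzyme family whose classes act on closely related substrates —
the motivating case is the gibberellin (GA) oxidase classes of the
2-oxoglutarate-dependent dioxygenase (2ODD) superfamily — substrate
discrimination is expected to be carried by a small number of positions
that are conserved *within* each functional group but differ *between*
groups, and that sit on the substrate-binding surface. `sdpscan`
operationalizes that reasoning as a pipeline of four testable stages and
reports their intersection.

## Sequence stage

**Alignment input.** The pipeline consumes an existing aligned FASTA (the
aligner is out of scope) plus a tab-separated table assigning every
sequence a functional class (e.g. GA20OX / GA3OX / C19-GA2OX / C20-GA2OX /
non-GAOX) and optionally a clade (e.g. monocot / Brassicales).

**Pairwise alignment and similarity.** Global affine-gap alignment (Gotoh)
under BLOSUM62; a gap of length L costs `gap_open + (L-1)·gap_extend`,
defaults 10 and 0.5 (the EMBOSS-needle convention). Traceback ties are
broken diagonal → gap-in-second → gap-in-first, so output is
deterministic. A residue pair is *similar* iff its BLOSUM62 score is ≥ 1;
since the BLOSUM62 diagonal is ≥ 1 everywhere, identity implies
similarity. Percent identity/similarity support three denominators —
`alignment_length` (columns that are not gap–gap), `shorter_sequence`,
and `ungapped_columns` (default; columns with residues in both
sequences). `X` scores 0 against everything and is never identical or
similar.

## Phylogeny stage

Distances are Poisson-corrected: `p` is computed over columns where both
sequences carry residues (pairwise deletion of residual gaps) and
`d = −ln(1−p)`. Saturation (`p = 1`) is an error by default; an optional
cap at `−ln(1/ncols)` exists because real alignments occasionally contain
fragment pairs. Column filtering before distances follows the familiar
deletion policies: *complete* (gapless columns only), *partial* (coverage
≥ cutoff, default 0.95 — the conventional site-coverage default;
the exact value used by the common GUI packages cannot be inferred and is
configurable), *pairwise* (defer to the distance computation).

Neighbor joining is the Saitou–Nei algorithm; Q-ties are broken by the
lexicographically smallest label pair, and a negative branch length is
clamped to zero with the deficit moved to its sibling so path lengths are
preserved. Bootstrap resamples columns of the *post-filter* alignment with
replacement (filtering once, then resampling, keeps replicates directly
comparable and the procedure deterministic given the seed); supports are
the fraction of usable replicates containing each internal bipartition,
written as internal-node labels in newick. Replicates hitting saturation
are skipped with the denominator adjusted; more than 20% skipped is an
error. The tree container and newick I/O are dendropy's.

## Motif stage

Motifs are position-probability matrices over the 20 standard residues
(MEME minimal text format, read and written directly; the format's protein
variant is not supported by the usual parsers). Scanning scores every
window by summed log2 odds against the background with pseudocount 0.01
per letter; `X` contributes nothing. The default per-motif threshold is
75% of the consensus score — an expressly simple stand-in for E-value
thresholds, which are out of scope. The per-sequence *architecture* is the
greedy selection of non-overlapping hits by descending score (ties:
smaller start, then motif id). Per-class presence fractions classify each
motif as `ubiquitous` (≥ threshold in every class), `exclusive`
(≥ threshold inside a class set, absent outside), `predominant`
(≥ threshold inside, ≤ 1−threshold outside; the boundary is inclusive so
that e.g. 90%/20% at threshold 0.8 is predominant), or `mixed` — the
fallback the first three cannot cover. The presence threshold defaults to
0.8, mirroring the 80–100% conservation shading bin.

A single-motif ZOOPS (zero-or-one occurrence per sequence) EM is provided
for testing planted motifs. Each restart seeds the PWM from a random
window; the MAP objective (likelihood plus the Dirichlet pseudocount
prior the M-step maximizes) is asserted non-decreasing at every
iteration. Because ZOOPS EM notoriously converges to shifted registers of
the true motif, each converged restart is refined by re-running EM from
the PWM shifted by ±1..3 columns and keeping the best likelihood; 10
restarts are the default. Multi-motif discovery is delegated to external
MEME.

## Conservation stage

A group has a *consensus* at a column iff one residue's gap-excluded
frequency is ≥ threshold. The threshold defaults to 0.8, anchored to the
dark-gray 80–100% shading bin used in conservation figures; no published
numeric definition of "conserved" exists for this procedure, so the value
is configurable and echoed in every output. A column with > 50% gaps in a
group yields no consensus. Columns are classified as:

* `core_conserved` — the same residue is consensus in every class;
* `class_characteristic(c)` — class *c* has a consensus differing from
  the shared consensus of all other classes (strict mode; a
  majority-of-others mode exists but is off by default);
* `clade_polymorphic` — both designated clades have consensus residues
  and they differ (this is the specificity-candidate signal and takes
  precedence in the report);
* `unconserved` otherwise.

Shading bins follow the printed convention: 100, 80–100, 60–80, < 60 % of
pooled majority frequency. Logo information content is
`log2(20) − H(freqs)` with no small-sample correction.

**Property tables.** Five residue categorizations annotate each
polymorphism: charge, hydrophobicity, size, polarity, and sidechain
flexibility. The tables are reproduced exactly as printed in the source
figure legend, including their two gaps — cysteine carries no polarity
label and glycine no flexibility label. Those dimensions are reported
through an explicit `unclassified` channel rather than silently repaired;
fidelity to the published tables is the contract. A `repair` option can
add C→non-polar and G→high-flexibility but defaults off. A checksum over
the exact residue memberships is validated at load so any edit breaks the
build. Positions are reported both as 1-based alignment columns and as
ungapped positions in a named reference sequence.

## Structure stage

PDB files are parsed with Biopython (strict mode). First MODEL only;
altloc alternatives keep the highest occupancy (ties → earlier altloc
letter); waters are dropped; hydrogens are ignored in all distances.
HETATM groups are kept separately and the ligand site is assembled from
named groups (substrate, single Fe atom, 2OG) or explicit coordinates.

Triage criteria:

* *within*: any heavy atom ≤ 5 Å (inclusive, because the criterion is
  phrased as "within 5 Å") of any substrate atom;
* *inward*: the sidechain heavy-atom centroid is strictly closer to the
  reaction center than CA is (an angular variant — CA→centroid vs
  CA→center < 90° — is available behind a flag). Glycine has no sidechain,
  is never inward, and is flagged distinctly. The reaction center defaults
  to the Fe site, the most defensible single point for a 2ODD; the
  substrate centroid is selectable.
* *cofactor-coordinating*: flagged residues whose sidechain lies ≤ 2.6 Å
  from Fe (typical Fe–ligand coordination) or ≤ 3.5 Å from 2OG
  (H-bond/salt-bridge range). Both cutoffs are configurable and logged.

Roles partition exhaustively: within ∧ inward → flagged; flagged ∧
cofactor → `cofactor_coordinating`; flagged otherwise →
`substrate_contact`; within ∧ ¬inward → `pocket_lining_only`; else
`none`. An optional chemical filter excluding ALA/GLY "non-reactive"
sidechains exists but is off by default — the phrase "reactive sidechains"
is ambiguous and the default stays purely geometric.

Column↔residue mapping requires the reference sequence and the chain to
have equal length and ≥ 95% identity; the k-th non-gap column maps to the
k-th residue. Motif hits project through this map to label residues, which
yields the pocket-by-motif composition report.

## Synthetic data

The generators define the conditions under which the pipeline's guarantees
are measured.

**Families** evolve leaf-ward along a known newick tree under a 20-state
Jukes–Cantor-like process: along a branch of length *t* (expected
substitutions/site) a site keeps its state with probability
`e^(−20t/19)`, else becomes uniform over all 20 states; the expected
proportion of differing sites at path length *t* is
`(19/20)(1 − e^(−20t/19))`, which the tests verify at 10,000 columns.
The default tree has two clades of 10 leaves, balanced within clades,
terminal and internal branches 0.05 and a 0.2 between-clade stem —
roughly 0.3 substitutions/site root-to-leaf depth, in the range of
within-family ortholog divergence. The reference recovery experiment uses
300 columns and 5 planted clade-polymorphic columns.

Planted polymorphisms overwrite the designated column per clade and are
then flipped to a random other residue with probability `noise`. Because
drift alone occasionally fixes different residues in the two clades, the
generator *scrubs* non-planted columns: wherever two clades have
incidentally fixed different consensus residues at the scrub threshold
(default 0.8), a randomly chosen minimal subset of one clade is flipped
to the other clade's consensus so that its consensus drops below
threshold. The random choice avoids planting a systematic grouping signal;
after scrubbing, the planted columns are exactly the clade-polymorphic
columns at that threshold, which is what makes precision/recall
measurements well-defined. Planted motifs overwrite a window with the
consensus in all sequences of the given classes.

**Toy structures** place each residue as CA plus a two-atom
pseudo-sidechain. Contact residues put their nearest atom at U(3.5, 4.9) Å
from a substrate atom with the sidechain centroid nearer the reaction
center than CA; lining residues sit at the same distances with the
sidechain pointing away; cofactor residues put a sidechain atom 2.2 Å
from Fe; background residues sit with all atoms > 6 Å away. Geometry is
re-drawn (up to 100 attempts) until the triage reproduces the planted
roles exactly, so the plan *is* the ground truth.

What the generators do **not** emulate: indels (families are gapless; gap
handling is exercised by hand-written fixtures), rate heterogeneity,
realistic substitution matrices (WAG/LG), real rotamer geometry, and
crystallographic artifacts. Passing tests therefore demonstrate
correctness of the estimators under their own model assumptions, not
robustness to real-data violations of them.

## Problem sizes and numerical choices

The acceptance script measures: NJ topology recovery over 20 replicate
families; polymorphism precision/recall over 5 families × 5 planted
columns at noise 0 and 0.1; pocket-role accuracy over 200 random toy
structures (~1,100 residues); ZOOPS recovery on 20 sequences of length 50;
bootstrap support floor at 100 replicates. These sizes give stable
percentages while keeping a full run around two seconds.

Tolerances: PWM rows must sum to 1 within 1e−6; frequency vectors within
1e−12; NJ path-length checks at 1e−9; EM convergence at 1e−6 relative
objective. Degenerate inputs error loudly rather than warn: empty FASTA,
ragged alignments, unlabeled ids, saturated distance pairs, all-gap
columns (flagged), missing CA atoms, zero-length denominators.

## Known limitations

* The 23/6/17-style pocket counts on real homology models depend on the
  modeling and ligand placement pipeline that produced the input PDB;
  `sdpscan` reproduces the *procedure* and report format, not those
  specific integers.
* `class_characteristic` in strict mode requires all other classes to
  agree; families whose remaining classes are themselves split are
  reported `unconserved` unless the majority-of-others mode is enabled.
* The ZOOPS EM is a testing aid for planted motifs, not a replacement for
  MEME: one motif, no E-values, no gapped motifs.
* Percent "homology" figures quoted in older literature rarely state
  identity vs. similarity or the denominator; when comparing against such
  figures, compute all three denominators and say which one you used.
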