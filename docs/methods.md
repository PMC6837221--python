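# Methods

This note records the models implemented in `caseinevo`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
data generator does and does not emulate.

## Coordinates and the region split

All residue positions are 1-based on each species' ungapped mature chain;
alignment columns are 1-based; a cleavage site is encoded by the residue it
follows, so the bovine chymosin/pepsin site is position 105 (Phe105|Met106)
and the bovine PKC is exactly residues 1–105. The PKC/GMP split is defined
once, on a reference taxon, and propagated through alignment columns: every
column up to and including the reference's cleavage-position column is PKC,
every later column GMP. This makes each species' PKC a prefix of its mature
chain, so a site position can be assigned to a region by comparing it with
the species' PKC length. Sequences are restricted to the 20 standard amino
acids plus `-`; ambiguity codes are rejected at parse time rather than
silently recoded, since a curated alignment should contain none. Species
present in an alignment but absent from the tree are rejected unless an
explicit remap (taxon → placement leaf) is supplied — silent dropping or
substitution is too error-prone for mixed-source datasets.

## GSC tree weights

Conservation statistics weight each species by Gerstein–Sonnhammer–Chothia
weights computed on the dated species tree (branch lengths in Myr), not on
a protein tree, so the weights reflect sampled evolutionary time. The
implementation initialises each leaf with its terminal branch length and
walks internal nodes leaves-to-root, apportioning each internal branch
among the leaves below it in proportion to their current raw weights;
polytomies are handled natively by apportioning over all descendant leaves.
Two degenerate cases are fixed by convention: a branch above leaves whose
raw weights are all zero is split equally, and a tree whose branch lengths
are all zero raises an error (or yields uniform weights under an explicit
flag). Raw weights conserve total branch length — a property the test
suite checks — and are normalised to sum to 1.

Divergence times are MRCA heights above the leaves. Dated supertrees are
ultrametric up to rounding, so the implementation uses the mean height of
the two leaves above their MRCA and warns above 1e-6 relative asymmetry.

## Conservation profiles

A profile is the weighted fraction of species carrying each category at
each column. Gap mass is kept in the denominator and reported as its own
category (`gap_mode="include"`, the default), so "fraction of species" is
comparable across columns of different occupancy; an alternative mode
renormalises over non-gap weight. Class schemes: aromatic = {F,W,Y},
charged = {D,E} negative and {K,R,H} positive — histidine is grouped with
the positive charges because it titrates in the stomach-pH range that
drives micelle aggregation, not with the aromatics. Numeric tracks (e.g.
disorder scores in [0,1]) are binned with half-open bins of width 0.2,
except the top bin which is right-closed so a score of exactly 1.0 is
representable; a value on a boundary goes to the upper bin.

## Charge, hydropathy, composition

Net charge uses the Henderson–Hasselbalch form with the Bjellqvist pK set
(C-terminus 3.55, D 4.05, E 4.45, H 5.98, C 9.00, N-terminus 7.50, Y 10.00,
K 10.00, R 12.00), pinned by a checksum test. NCPR divides by ungapped
sequence length. When a region is analysed on its own it is treated by
default as a free peptide with both termini titrating (`termini="both"`),
matching how general peptide-property engines evaluate a subsequence; all
four termini modes are exposed because the choice shifts short-peptide
curves noticeably. Post-translational charge (phosphate pKa 2.2/5.8/12.4,
sialic acid pKa 2.2) is deliberately out of scope: curves describe the
primary sequence, and modification stoichiometry varies between species and
even between chains in one milk sample. GRAVY is the plain Kyte–Doolittle
mean. Composition ranges report min/max per-residue frequency across
species per region, next to Swiss-Prot average frequencies as a
configurable background.

## Site prediction

The Fam20C scanner predicts a serine when, stepping two residues at a time
toward either terminus, it reaches a glutamate through at most n chained
serines (default n = 10). This is implemented as a direct bidirectional
chain scan; because every anchoring path moves monotonically in one
direction, the scan equals the fixed point of the iterative rule "an S is
predicted if the residue two positions away on either side is E or an
already-predicted S", and the test suite verifies that equality against an
independent breadth-first closure oracle on random sequences.

Pepsin follows the PeptideCutter context rules: a bond P1|P1' is cleavable
when P1' (or P1) is F/L/W/Y — F/L only in the pH 1.3 variant — unless Pro
sits at P2 or P2', His/Lys/Arg at P3, or (for the P1' branch) Arg at P1.
Context positions outside the sequence do not block. The default is the
pH > 2 variant, since gastric pH during milk digestion is 2–5. Plasmin
cleaves after every non-terminal Lys/Arg. A protease site at the final
residue is never reported (no peptide bond follows). Cleavage densities
divide site counts by each species' ungapped region length. Glycosylation
is not predicted ab initio: externally computed per-residue scores arrive
as numeric tracks and are thresholded at ≥ 0.4 on Ser/Thr.

Disulfide scenarios per species: dimer ⇔ ≥1 cysteine, oligomer ⇔ ≥2,
intrachain ⇔ two cysteines separated by at least one residue (positions
differing by ≥2) — adjacent cysteines cannot loop back on themselves.

## Divergence and the epoch contrast

Pairwise distances use pairwise deletion (shared non-gap columns only),
because indels concentrate in the GMP and complete deletion would discard
most informative columns. The ML distance maximises the JTT likelihood with
K = 4 discrete-gamma categories (Yang's category-mean discretisation,
boundaries at gamma quantiles), over t ∈ [0, 20] by bounded scalar
optimisation with tolerance 1e-8; hitting the upper bound raises a
saturation warning and caps the estimate. The JTT exchangeabilities and
frequencies are shipped as data constants (column-major lower triangle, as
in the published matrix) and pinned by checksum; the rate matrix is
rescaled to one expected substitution per site per unit time. A single
gamma shape is shared across pairs, chosen on the coarse grid
{0.25, 0.5, 1, 2, 4} by minimising the summed minimised negative
log-likelihoods; alpha is weakly identified from pairwise data, which is
why a coarse grid (rather than a continuous optimiser) is honest here. The
implementation was cross-checked against an independent ML-distance
implementation on a frozen sequence pair and agrees to ~1e-4 relative.

The distance–time scatter is summarised by least squares on
`d = s_recent·min(T, b) + s_old·max(T − b, 0)` through the origin with
nonnegative slopes (scipy NNLS), reporting `slope_ratio = s_old/s_recent`.
The breakpoint default is 60 Ma. The fit accepts either pairwise ML
distances or patristic distances from a user-supplied tree; tree-wide
branch-length optimisation is intentionally not implemented.

## Synthetic data generator

The generator emulates the *structure* of the study data: an ultrametric
pure-birth tree rescaled to root age 166 Myr (the split between egg-laying
and therian mammals); 99 taxa; a 105-residue PKC-like region
(serine/arginine/tyrosine/proline-enriched JTT frequencies) concatenated
with a 64-residue GMP-like region (threonine/isoleucine-enriched,
leucine/aromatic/arginine-depleted, cysteine frequency exactly zero — so
the observed GMP cysteine absence holds by construction); discrete-gamma
site rates (alpha = 1, K = 4); and a clock of 0.004 substitutions/site/Myr
before 60 Ma halving to 0.002 after it, chosen once to give root-level
divergences near 1 substitution/site, the scale of the real
kappa-casein scatter. Branches spanning the breakpoint are split at it by
absolute time. Planted features — three S-x-E motifs and cysteines at
positions 11 and 88 of the PKC-like region — are written into the root
sequence and then evolve freely; the truth record reports where they
survive at the tips. Indels are modelled only as whole-block tandem
duplications confined to the GMP-like region of designated tips, realised
as inserted blocks aligned by gap columns elsewhere, which keeps the
alignment truth exact. One numpy Generator seeded once drives every draw,
so outputs are bit-reproducible.

What the generator does **not** emulate: realistic indel length
distributions, selection or site-specific constraint, PTM scores,
alignment error, or lineage-specific composition shifts. Passing tests on
synthetic data therefore demonstrate correctness of the computations and
recoverability of generating parameters — not that the biological
conclusions would replicate on any particular real alignment.

## Problem sizes in tests and the acceptance script

Monte-Carlo checks use 200 replicate cherries of 2000 sites per true
distance (0.05, 0.3, 1.0), and the epoch-contrast recovery uses 30 taxa ×
2000 sites with the gamma shape fixed at its generating value — sizes at
which the Monte-Carlo standard error is small enough for a 3-SE bias check
and a 20% ratio check to be meaningful. Oracle-equivalence checks run the
motif scanner against the closure oracle on 10,000 random S/E-rich
sequences of length ≤ 60.

## Known limitations

- The shared gamma shape is a coarse-grid profile estimate; pairwise data
  barely identify alpha, and unrelated (saturated) pairs pull it upward.
- Pairwise ML distances are noisier than a tree-wide fit, particularly at
  deep divergences; the epoch contrast inherits that noise.
- Charge curves ignore phosphate and sialic-acid charge, by design.
- The curated 99-species alignment and dated supertree of the original
  analysis are inputs, not artifacts of this package; the population-level
  summary statistics can only be recomputed when those files are supplied.
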