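# Methods

This note documents the models, definitions and numerical choices behind
`qipi`, and what the synthetic test corpus does and does not establish.

## Interface definition

A complex is partitioned into two sides by chain identifiers.  Accessible
surface area (ASA) is computed for the full complex and for each side in
isolation; the per-residue burial is

    delta_asa(r) = ASA(r | isolated side) - ASA(r | complex).

A residue is a **surface residue** of its side when its isolated-side ASA
exceeds 1 Å².  A surface residue is an **interface residue** when
`delta_asa > 1 Å²` *and* at least one of its heavy atoms lies strictly
within 5 Å of a heavy atom of the other side.  All remaining surface
residues form the **non-interface surface**.  Buried residues belong to
neither set.  Both thresholds are parameters; the defaults are the
published values and every CLI default mirrors them.

Using the non-interface surface (rather than the whole chain) as the
reference state is the point of the analysis: interface and non-interface
residues are both solvent exposed, so ratios between them are not
confounded by the burial preferences of residue types.

## Accessible surface area

ASA is computed by Shrake–Rupley sphere sampling: each atom is inflated by
the probe radius (1.4 Å water) and sampled with a deterministic Fibonacci
(golden-angle) lattice of `n_points = 960` directions; the accessible
fraction of points times the sphere area gives the atom ASA, and residue
ASA is the sum over heavy atoms.  Radii are a Chothia-style element set
(C 1.87, N 1.65, O 1.40, S 1.85, P 1.80, Se 1.90; unknown 1.80 Å).
There is no randomness: repeated runs are bit-identical, and accuracy is
controlled only by `n_points` (960 points sit within ~0.5% of a 10⁵-point
run on dense clusters; the suite also cross-checks against biopython's
independent implementation).  The engine reproduces the *contract* of
slice-based reference programs (per-residue areas to within sampling
tolerance), not their bit-exact output.

## Secondary structure

Three states H/E/C.  When a DSSP file is supplied, its eight states are
collapsed (H/G/I→H, E/B→E, else C).  Otherwise a dihedral-run assigner is
used: helix requires runs of ≥4 residues with φ∈[−100°,−30°], ψ∈[−80°,0°];
strand requires runs of ≥3 with φ∈[−180°,−40°], ψ∈[60°,180°]∪[−180°,−170°];
everything else, including residues with undefined dihedrals (termini,
missing backbone), is coil.  The built-in assigner exists to make 3-state
labels reproducible without external binaries; it is cruder than DSSP and
should be overridden with DSSP output when fidelity matters.

## Propensity statistics

With `f_i` interface counts and `F_i` non-interface surface counts of class
`i`, the frequencies are `w_i = f_i/Σf` and `W_i = F_i/ΣF`, and the
**relative interface ratio** is `RIR_i = w_i/W_i`.  Classes may be the 20
residue types (the quantitative interface propensity index), the 3
secondary-structure states, their 60 products, or ASA classes.  Cells with
`W_i = 0` are reported as undefined rather than smoothed; an optional
pseudocount adds a constant to every class before normalisation.

**ASA threshold A_t.**  For one residue type, the ASA values of interface
and of non-interface surface residues are histogrammed on shared 5 Å² bins;
`A_t` is the lower edge of the first bin at which the difference of
normalised frequencies changes sign (smallest such ASA on ties; undefined
when the histograms never cross).  The 2×2 ASA-RIR is
`(f_IL/f_IS)/(f_SL/f_SS)` with I/S = interface / non-interface surface and
S/L = ASA below / at-or-above `A_t`; it is reported only when all three
denominator cells are populated.  When the crossing coincides with a
sample's support edge one cell is empty by construction and the ratio is
flagged undefined.

**Contact preferences.**  `C_ij` counts contacting residue pairs across the
interface, one count per residue pair, unordered types, both residues
interface residues of their sides.  The reported frequency of an unordered
pair is its count over the total number of contacts.  The preference is the
log2 ratio of that frequency to the frequency expected if the two sides
paired independently; for an unordered pair {i,j} with i≠j the expected
probability is `2·w_i·w_j` (both orders), and `w_i²` on the diagonal.  This
is algebraically the textbook formula evaluated on the symmetric contact
matrix with a doubled diagonal.  Cells with zero observed contacts are NaN,
never zero.  A 4×4 aggregation over basic {H,R,K}, hydrophobic
{A,V,I,L,M,P,F,W,G,C}, polar {Y,S,T,N,Q} and acidic {D,E} pools counts
first and applies the same formulas with group frequencies.

**Sizes.**  Interface size per side is the sum of `delta_asa` over that
side's interface residues; domain size is the isolated side's total ASA.
Summaries report mean, median and a method-of-moments gamma fit
(`shape = mean²/var`, `scale = var/mean`).

## Patch prediction

Candidate interfaces on an unbound domain are built in four steps.

1. **Surface residues**: ASA > 1 Å².
2. **Distance matrix**: minimum side-chain heavy-atom distance per surface
   residue pair (Cα for glycine or missing side chains), capped at 25 Å.
3. **Growth**: one patch per seed surface residue; a neighbour at seed
   distance d joins when d falls in a bin of the packaged table and its ASA
   strictly exceeds the bin minimum — (2,5]→0, (5,7]→20, (7,9]→40,
   (9,11]→60, (11,13]→80, (13,15]→100 Å².  Bins are read half-open (lo,hi];
   d ≤ 2 Å joins unconditionally and d > 15 Å never joins (closed-world
   completion of the printed bins).
4. **Merging**: identity ratio `|P₁∩P₂| / min(|P₁|,|P₂|)` (the min
   denominator keeps the ratio symmetric and the thresholds attainable);
   patches merge when the ratio reaches the domain-ASA-dependent threshold
   (0,5000]→0.8, (5000,7500]→0.7, (7500,10000]→0.6, >10000→0.5.  The
   currently highest-ratio admissible pair merges first (ties broken by
   lexicographically smallest member sets), iterating to a fixpoint; merged
   patches are plain unions (not re-grown) and lose their seed.

Each candidate is scored

    E_patch = E_res + w1·E_hydro + w2·E_cons + w3·E_sol

* `E_res = Σ ASA_i · RIR_r / REF_r` over members, with RIR from the
  packaged propensity index and REF the average accessible surface area
  scale (AAindex JANJ780101).  `ASA_i` is the absolute residue ASA in Å²
  (the division by REF_r makes the summand a propensity-weighted relative
  exposure); a flagged alternative would use percent relative ASA, which
  only rescales the term per residue type.
* `E_hydro = Σ H_r`, the structure-derived hydrophobicity scale
  (AAindex CASG920101).
* `E_cons = Σ (C_ir − B_rr)`: per-position self-substitution score from a
  PSI-BLAST ASCII profile minus the BLOSUM62 diagonal.  Profiles are inputs
  (running PSI-BLAST is out of scope); without a profile the term is
  disabled and contributes 0, flagged on the patch.
* `E_sol = Σ V_out/(V_sphere − V_out)` per member residue: a 1.2 Å sphere
  is anchored at the centroid of the residue's solvent-exposed heavy atoms
  and sampled on a deterministic cell-centred 0.2 Å grid; `V_out` is the
  volume fraction outside every atom's solvent-accessible sphere
  (vdW + 1.4 Å).  A sphere fully outside is capped at 10⁶ and flagged.
  With the centroid anchor the term is 0 for buried residues and grows only
  where the exposed-atom centroid pokes through a concave accessible
  surface, so on compact synthetic bodies it is near zero and carries
  little signal — the shipped default weight for it is 0 accordingly.

The prediction is the top-ranked patch (ties: larger patch, then
lexicographic member order).  Nonstandard residues contribute zero to all
terms but may be patch members.

## Evaluation and training

Coverage `COV = TP/(TP+FN)`, accuracy `ACC = TP/(TP+FP)`, objective
`F = COV·ACC`.  Degenerate sets: empty truth with empty prediction counts
as perfect; empty prediction against non-empty truth scores zero; non-empty
prediction against empty truth leaves COV undefined (excluded from macro
means).  Macro aggregation averages per-case COV and ACC and multiplies;
micro pools the confusion counts.  Macro is the default.

Weights are trained by exhaustive grid search (default {0, 0.25, 0.5, 1, 2}
per weight) maximising mean per-case F; component scores per candidate are
precomputed once, so each grid point is a re-ranking.  Ties take the
lexicographically smallest weight triple.  Cross-validation permutes cases
with a seeded generator, deals them round-robin into k folds (default 10)
and reports per-fold macro COV/ACC with mean ± sd.

The packaged default weights (w1 = 2, w2 = 2, w3 = 0) are the grid optimum
from training on 40 annotated synthetic domains whose profiles carry
interface-localised conservation; they are a sensible starting point, not a
claim about any particular protein family — override them via a weights
JSON when profiles or families differ.

## Synthetic corpus

The generator builds two poly-residue bodies from ideal backbone geometry
(NeRF construction with standard bond lengths and angles; one carbon-sized
CB pseudo-atom per non-glycine residue) and docks body B as a rigid copy of
body A rotated by a small angle about the docking direction through the
mid-chain pivot.  The two chain axes are then skew lines whose closest
approach sits at both chains' midpoints: the contact face is central
(no chain end is geometrically privileged), and the crossing angle sets the
face length from the requested interface fraction.  The perpendicular gap
is the smallest clash-free offset at ~4.2 Å (3.6 Å for the curved helix and
blob geometries, whose realized faces are smaller than the requested
fraction).

Planted truth is recorded at construction time as the residues whose
backbone-frame atoms (including a virtual CB, so truth does not depend on
the drawn sequence) lie within 5 Å of the other body.  Sequences are drawn
from a typical protein-surface background composition (charged and polar
residues enriched, aromatics depleted), with planted positions enriched by
caller-specified factors — by default ×3 on the five highest-propensity
types (Met, Tyr, Arg, Phe, Trp), emulating the compositional contrast of
real interfaces.  Everything is a pure function of the spec's seed; PDB
text is byte-identical across runs.

What the corpus emulates: the interface definition's geometry (burial plus
cross-contacts), compositional enrichment against a surface background,
interface-localised conservation in toy PSSM profiles, and candidate-patch
structure on small single domains.  What it does not emulate: real packing
and side-chain geometry, ASA magnitudes of globular proteins (toy bodies
are thin, so per-residue ASA is high and domain ASA small), realistic
secondary-structure mixtures, or evolutionary profiles.  Passing tests
therefore establish the correctness and determinism of the machinery and
the recoverability of planted signals at desk scale — not benchmark
performance on crystallographic complexes.

Problem sizes in the shipped study (`scripts/acceptance.py`): 30 complexes
of 24 residues per side for the propensity statistics; 30 unbound
30-residue domains for prediction versus a random-candidate baseline;
40 annotated domains for training and 5-fold cross-validation; 16
40-residue domains for hydrophobic-weight recovery; 10⁵ draws for the
contact-preference null.  These sizes give stable statistics for every
reported quantity while keeping a full run in well under a minute per
block.

## Numerical choices and degenerate inputs

* All thresholds are strict where the definition says "more than"/"less
  than": surface ASA > 1, burial > 1, contact < 5, growth ASA > bin value.
* Altlocs resolve to the highest occupancy (ties by altloc identifier);
  hydrogens are ignored; selenomethionine maps to Met; other nonstandard
  residues are kept for geometry but excluded from propensity counts.
* Zero-count propensity and contact cells are flagged (None/NaN), never
  imputed.
* The solvation grid is cell-centred so no grid plane can sit exactly on
  an axis-aligned accessible-surface boundary.
* Merging and ranking are fully deterministic via explicit lexicographic
  tie-breaks; there is no RNG anywhere in the prediction path.

## Known limitations

* The built-in secondary-structure assigner is a coarse dihedral heuristic.
* The solvation term is nearly inert under the centroid-anchor definition;
  its weight trains to zero on the synthetic corpus.
* The A_t crossing rule can land on a support edge, leaving the ASA-RIR
  undefined for sparsely sampled residue types.
* Packaged default weights come from synthetic training and should be
  retrained for real structure collections.
* mmCIF input, hydrogen placement and multi-model ensembles beyond model
  selection are unsupported.
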