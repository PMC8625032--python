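# Methods

This note records the models, parameter choices and numerical conventions
behind `templig`, and what the synthetic test bed does and does not show.

## Hybrid 3D similarity

Each heavy atom contributes a spherical Gaussian density
`ρ_i(r) = p·exp(−α_i|r−r_i|²)` with amplitude `p = 2.7` and exponent
`α_i = π(3p / 4πR_i³)^{2/3}` chosen so the Gaussian integrates to the
atom's van-der-Waals volume (radius table in `templig.config`). The shape
overlap of two posed molecules is the first-order sum of pairwise Gaussian
product integrals

`O_AB = Σ_ij p²(π/(α_i+α_j))^{3/2} exp(−α_iα_j d_ij²/(α_i+α_j))`,

and `ShapeScore = O_AB / max(O_AA, O_BB)`. Because `O` is an inner product
of density functions, Cauchy–Schwarz bounds the score by 1, with equality
exactly at self-overlap — this normalization (rather than a
Tanimoto-style one) is what puts the self-alignment endpoints at exactly
1 and 2.

Pharmacophore features are perceived deterministically: donors
(`[#7,#8;!H0]`), acceptors (any oxygen; trivalent non-pyrrole neutral
nitrogens), hydrophobes (aliphatic carbons with no heteroatom neighbour),
one aromatic feature per fully aromatic ring at its centroid, and charge
centres from formal charges. These compact SMARTS are deliberately coarser
than a medicinal-chemistry feature factory; they are stable, explainable,
and sufficient to orient ligands in the toy systems. `FeatureScore`
mirrors the shape normalization with a Gaussian kernel of width
`σ = 1.0 Å` over same-kind feature pairs. A pair of molecules that both
lack features scores 1 (identically featureless); if only one side is
featureless the score is 0.

**Alignment.** The hybrid score is maximized over rigid motions of the
query by deterministic multi-start: 12 principal-axes orientations (3 even
axis permutations × 4 proper sign flips) with centroids matched, plus the
query's input pose; the best starts are polished by Nelder–Mead over
rotation vector + translation (xatol 1e-4), followed by up to three
restart polishes at the incumbent (xatol 1e-6) which make the final score
invariant to input-frame rotations within ~1e-3. Flexibility is handled
entirely by the conformer ensemble; the alignment itself is rigid.

## Conformer generation

Distance-geometry embedding (ETKDGv3) with MMFF94 relaxation replaces
dedicated conformer generators. The ensemble is oversampled (cap + max(cap/2,
10) embeds) and de-duplicated with symmetry-aware best-RMS at 0.5 Å,
because distinct embeddings collapse onto shared force-field minima.
Defaults: cap 200 (the study-scale ensemble size), three embedding
attempts with incremented seeds before an embed failure is raised.
Identical (SMILES, seed) pairs give bit-identical coordinates. Energy
windows and duplicate thresholds of external generators are not claimed —
the settings here are this package's own documented defaults.

## Empirical scoring and local refinement

The scoring function restates the published Vina form as the package's
contract: on heavy-atom surface distances `d = r − R_i − R_j` (interaction
radii in `templig.refine.XS_RADII`, 8 Å cutoff),

| term | formula | weight |
|---|---|---|
| gauss1 | exp(−(d/0.5)²) | −0.035579 |
| gauss2 | exp(−((d−3)/2)²) | −0.005156 |
| repulsion | d² for d<0 | 0.840245 |
| hydrophobic | linear ramp 1→0 over d∈[0.5,1.5], C/halogen pairs | −0.035069 |
| h-bond | linear ramp 1→0 over d∈[−0.7,0], donor–acceptor pairs | −0.587439 |

The total is the weighted sum divided by `(1 + 0.05846·N_rot)`; the
`PoseScore` stores the rotatable-bond-scaled *effective* weights so that
`total = weights·terms` holds to machine precision. Protein atom typing is
rule-based (N donor, O acceptor, Ser/Thr/Tyr hydroxyl oxygens also donate,
carbon hydrophobic) — adequate for the rigid-receptor regime used here.

`local_refine` optimizes 3 translation + 3 rotation + N_tor torsion
variables with bounded Powell search (defaults ±1.5 Å, ±0.4 rad, ±0.6 rad).
The bounds are deliberate: superimposition decides the binding mode and
refinement only relieves clashes; unbounded torsion search would amount to
re-docking and routinely tunnels into neighbouring minima of the rugged
piecewise score surface. A translation-only pre-step relieves initial
overlap; if atoms remain interpenetrated deeper than 1.5 Å below contact
afterwards the pose is declared an irrecoverable clash. The refined score
never exceeds the starting score (the incumbent is kept on failure). The
`bound_dock` reference mode — 20 seeded random placements in a 22 Å box
followed by local refinement — is this package's stand-in for a full
global docking search and is labelled as such.

## Symmetry-aware RMSD

Pose error is the minimum in-place heavy-atom RMSD over all atom mappings:
for two poses of one molecule, all graph automorphisms (substructure
self-matches); for chemically different molecules, all embeddings of the
maximum common substructure (element- and ring-constrained, 10 s timeout,
minimum 3 atoms). No re-fitting rotation is applied — the quantity measures
displacement in a common receptor frame, obtained where needed by sequence
alignment (BLOSUM62, gap −11/−1) and Kabsch superposition of aligned
alpha-carbons (≥8 pairs and ≥30% aligned-pair identity, else the pair is
unalignable; a global alignment of random sequences still produces aligned
columns, so coverage alone cannot reject non-homologues). Iterative
pruning of poorly fitting CA pairs is available behind a flag but off by
default. In intercomparison the RMSD is always computed on the query's own
atoms, so swapping query and template legitimately changes the value.

## Curation rules

Discards, in order: covalent ligand–protein link (< 1.9 Å heavy-atom
distance; no threshold is standard, this one sits between bonding and
close contact), a second candidate ligand centre within 8 Å (shared
pocket/cofactor), ligand within 4.0 Å of ≥2 protein chains, fewer than 7
heavy atoms, molecular weight outside [140, 800] Da (inclusive bounds —
the discard phrasing is strict), and SASA burial below 50%. SASA uses
in-package Shrake–Rupley sampling (probe 1.4 Å, 256 lattice points per
atom; quadrupling the density changes toy-system burial fractions by <2%).
Grouping clusters binding sites by single linkage on ligand centres at
8 Å, keeps the most populated site, and de-duplicates identical canonical
SMILES by lowest R-free. The geometric shared-pocket rule can disagree
with an annotation-based cofactor rule for distal cofactors; reports flag
only the geometric verdict.

## Hybrid-score re-ranking

`α = min(Vina scores)/2` is computed per run from the refined
query-on-template scores of that run — the set available in every mode,
and identical to "all ligands on the target protein" when run over a full
library. With negative binding scores α is negative, so higher similarity
*lowers* (improves) the hybrid score, and since the similarity is at most
2 the two contributions are commensurate. Final ties break toward lower
binding score, then higher similarity, then template id. Site sanity uses
a 10 Å centre-to-centre cutoff (strictly-greater distances are discarded);
success is a strict `RMSD < 2.0 Å` on the rank-1 pose.

## N_min bootstrap

For the records of one similarity bin: draw n records without replacement,
keep the minimum RMSD; repeat 500 times; increase n from 1 until
mean + SE ≤ 2.0 Å (SE = sd/√500 — the sd-only alternative would
systematically raise N_min by requiring a stricter mean). The whole search
is repeated 100 times (seeds seed+i) and N_min is reported as mean ± SE
over the repetitions. Bins follow the 0.1-wide convention on [0.8, 1.6)
with open-ended tails; bins under 100 records are "insufficient" and
reported as 0-with-flag rather than a value.

## The synthetic test bed

Toy pockets are concave shells of carbon pseudo-atoms (glycine CA records,
so they parse and match as protein chains) molded around a seed ligand:
along each of ~120 sphere directions the wall sits 3.6 Å beyond the
ligand's outermost atom (an offset support surface), with both polar caps
within 55° removed as solvent mouths. The molding cradles elongated
ligands and the two-sided aperture keeps the planted pose at a force
balance along the channel; the default geometry buries the seed ligand
well above the 50% rule, and widening the aperture lowers it below — both
sides of the rule are exercisable. Template ligands are a rigid
fused-bicyclic family (naphthalenol/quinoline variants: features without
heavy-atom rotatable bonds), placed by matching donor-atom and
ring-centroid anchors and then relaxed to a fixed point of the refinement
so planted "crystal" poses are receptor equilibria, as real ones are. The
dissimilar-shared-mode query is a hydroxy-chromenone: Tanimoto ≈ 0.2 to
the templates yet the same planar bicyclic footprint.

What passing these tests shows: the geometry, scoring, ranking and
statistics machinery is internally consistent and recovers planted ground
truth under realistic score competition. What it does not show: behaviour
under protein flexibility (receptors are rigid here and in the method's
design), real pocket chemistry (shell atoms are featureless carbons, so
feature-score discrimination inside the pocket is driven by the ligands
only), torsion-rich pose recovery at crystallographic precision, or
performance on crystallographic data volumes. The worked example on the
real BACE-1 pair (`examples/worked_example_bace1.py`) bridges to real
structures but requires the two PDB files locally.

## Problem sizes

Default test-bed sizes were chosen as the smallest that exercise each
mechanism with score competition: 3-template libraries, 10–20 conformer
ensembles, 150-record bootstrap bins, 50-seed recovery runs, 25-molecule
endpoint sweeps. All randomness flows from explicit integer seeds;
repeated runs are bit-identical.
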