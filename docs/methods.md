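# Methods

`p5crkit` analyses the pyrroline-5-carboxylate reductase (P5CR, EC 1.5.1.2)
family: the terminal enzyme of proline biosynthesis, built from an
N-terminal Rossmann-type dinucleotide-binding domain (rice frame residues
1–175) and a C-terminal dimerisation domain (176–284). The package covers
the sequence-side analytics (signature and motif fingerprinting, rule-based
cofactor and oligomer calls), alignment filtering and distance-based
phylogenetics, structural interface measurements, and SEC-based
stoichiometry inference. This note records the models, the conventions and
the genuinely open design choices.

## Coordinate frame and the synthetic reference

All motif coordinates use the rice (*Oryza sativa*) P5CR numbering
(284 residues). The bundled reference (`p5crkit.reference`) is **synthetic**:
a deterministic pseudo-random 284-residue scaffold with every annotated
window planted at its canonical rice coordinate — the Gly-rich motif B
(9–16), the adenine/2′-phosphate motif A (53–58), the V-K-P extension
(76–78), the family PA-line signature window (100–122), motif C (132–136),
the hinge motif D (188–192), the dimer–dimer determinant (202–214), the
inter-dimer bridge residues H236/K241/D242, and the proline-pocket motif E
(246–251). Everything between windows is random fill drawn from an alphabet
without His/Lys so that basic-residue counts inside motif A and the planted
bridge residues are unambiguous. The scaffold is *not* the biological rice
sequence; what the package relies on — and what tests assert — is the
coordinate frame, which is exact by construction.

Motifs A (53–58), C (132–136) and the determinant region (202–214) have
published rice spans. The remaining spans were placed from textual anchors:
motif D around its conserved serine (S189 → 188–192), motif E ending at its
conserved threonine (T251 → 246–251), motif B on the β1/α1 Gly-rich loop
(9–16), and V-K-P on the β4/α4 loop roughly 60 residues downstream of B
(76–78). Published human↔rice residue pairings are internally inconsistent
(S176↔S189 implies +13 while R264↔R251 implies −13); the package keys
everything to rice coordinates and treats the stacking arginine "R251" as a
named feature only.

## Pairwise alignment and clustering

Global Needleman–Wunsch alignment with affine gaps is delegated to
Biopython's `PairwiseAligner` (BLOSUM62, open −11, extend −1; a gap of
length L scores −(11 + (L−1))). The ambiguity residue X is re-scored to 0
against everything. Percent identity divides by both-non-gap columns by
default (a `shorter`-sequence denominator is available). Clustering is
single-linkage over a link predicate mirroring redundancy filtering for
large family sets: mutual coverage ≥ 0.95 and score per aligned column
≥ 1.5. The original thresholds were formulated for BLAST bit scores; here
the density is raw NW score per column with the threshold kept at 1.5 and
exposed as a parameter — exact replication of bit-score clustering is out
of scope.

## PA-line signature scanning

The Prosite PA grammar is compiled to element lists (classes, exclusions,
wildcards, bounded repeats, `<`/`>` anchors). Every admissible start is
reported once with the *shortest* expansion at that start — deterministic
and directly checkable against a sliding-window oracle. X in a sequence
satisfies only wildcards, never residue classes (conservative).

## Cofactor-preference call

The motif-A window provides the 2′-phosphate contact region. Arg/Lys
residues in the window are counted as phosphate anchors: ≥ 2 calls the
enzyme NADPH-preferring, exactly 1 NADPH-capable, none indeterminate.
Histidine (adenine stacking) is reported as evidence but does not count
toward the preference — binding-mode studies implicate Arg/Lys side chains,
not His, in phosphate anchoring. The interaction mode is 1 when the window
holds both Ser and Arg, else 2 for Lys, else 3 for Asn, else unassigned.

## Oligomeric-state call

Decamer-forming P5CRs carry a conserved determinant window
A-D-G-G-V-A-A-G-L-P-R-[D/R]-L at rice 202–214 plus an inter-dimer
salt-bridge network (D203–K241′, R212–D242′, H236–D242′) and, in some
members, a stacking arginine. The classifier evaluates ten named features —
D203, G204, G205, P211, R212, H236, K241, D242, R251 and a
consensus-similarity score of the whole window — resolved either through an
anchor map (from global alignment against the reference) or by fixed
offsets from the unanchored motif-D hit. The similarity score is
per-position class agreement with the critical Gly/Pro positions
(G204/G205/P211) weighted double, because their loss is what disrupts the
interface loops. Weights default to 1 (R251: 0, because at least one
confirmed decamer lacks it; it is advisory only) and the weighted mean is
thresholded: ≥ 0.5 → decamer, ≤ 0.3 → dimer, otherwise unknown. The
thresholds and weights are defaults exposed in the API: the determinant
hypothesis proposes residues, not a formal score, so the scoring scheme is
this package's own construction.

## Alignment column filter

Columns are excluded when gap fraction > 0.5 or homogeneity < 0.1 (strict
inequalities; boundary values survive). The homogeneity formula is not
uniquely fixed by prior usage, so the package adopts a min–max-normalised
mean pairwise substitution score: h = (s̄ − s_min)/(s_max − s_min) with
s_max the largest diagonal entry and s_min the smallest entry of the matrix
over the 20 standard residues (BLOSUM62: 11 and −4). It is bounded in
[0, 1] — as a 0.1 threshold presupposes — exactly 1 for all-identical
tryptophan columns, and oracle-checkable by direct pair enumeration. The
formula and matrix are embedded in exported metadata. Both `-` and `.`
count as gaps; single-residue columns score 1.

## Phylogenetics

Distances use pairwise deletion (p-distance, or Poisson-corrected
−ln(1−p) capped at 10), matching a workflow where filtered alignments
retain residual gaps. Tree building is Saitou–Nei neighbor joining with the
standard Q criterion, lowest-index tie-breaks and negative branch lengths
clamped to zero; it is exact on additive inputs, which the tests exploit.
NJ is a desk-scale stand-in for maximum-likelihood inference — the
monophyly and duplication queries only need a topology, and externally
computed trees can be imported as Newick and run through the same queries.
Monophyly uses unrooted semantics: a leaf set is monophyletic iff some edge
bipartition equals it exactly (singletons trivially so). Duplication
candidates are maximal clades of ≥ 2 leaves sharing one species; genus- or
clade-level grouping is achieved by supplying a coarser mapping. Bootstrap
supports resample columns with replacement (seeded) and score base-tree
bipartitions by replicate frequency.

## Structural measurements

The PDB reader is a small fixed-column parser with a pinned policy (first
MODEL, hydrogens and waters excluded, highest-occupancy altloc kept with
ties going to 'A', line-numbered coordinate errors). Superposition uses the
Kabsch construction via `scipy`'s `Rotation.align_vectors` (proper rotation
guaranteed); the reported RMSD is recomputed by applying the returned
transform, so it is consistent with the transform to machine precision.
Surface areas use Shrake–Rupley sampling with a deterministic golden-spiral
point set (960 points), probe 1.4 Å and radii C 1.70 / N 1.55 / O 1.52 /
S 1.80 Å (default 1.70). Buried interface area is
ASA(A) + ASA(B) − ASA(A∪B), *summed over both groups* (divide by two for a
one-sided value). Salt bridges are basic side-chain N (Arg NE/NH1/NH2,
Lys NZ, His ND1/NE2) within 4.0 Å of acidic side-chain O (Asp OD1/OD2,
Glu OE1/OE2), deduplicated per residue pair at the minimum distance; the
4.0 Å cutoff is the common convention. Arg–Arg stacking uses guanidinium
centroids (CZ/NH1/NH2/NE mean) within 6.0 Å. Hinge motion superposes one
chain onto another over an alignment span (default the C-terminal domain,
rice 176–284) and reports displacement statistics over a measurement span
(default the N-terminal domain); inter-region distances default to Cα
centroids with a minimum-atom-distance mode available, and the mode is
recorded in CLI output rather than asserted to match any published
measurement convention.

## SEC calibration and stoichiometry

Kav = (Ve − Vo)/(Vt − Vo) is fit by ordinary least squares against log10
mass (the base is recorded in output). Sequence masses use a bundled
average-residue-mass table (4 decimals) plus one water; an independent mass
table (Biopython) agrees to ~1e−4 relative. Stoichiometry snaps the mass
estimate to the candidate count minimising |n·m_subunit − m_est|. The
candidate set defaults to even counts {2,4,6,8,10,12} — only even-subunit
assemblies have been observed crystallographically in this family — and the
call is flagged ambiguous when two candidates fall within the ~10% SEC
error band, or when the best two tie exactly (a mass midway between two
candidates is inherently ambiguous regardless of the band).

## Synthetic data: what it emulates, what it does not

`simulate_family` evolves the reference scaffold along a random
coalescent-style tree (unit root-to-leaf depth) by per-site uniform
substitution; the default divergence (`rate=0.08`) keeps leaves within
~10% of the scaffold, the regime where anchored motif mapping is reliable.
Conserved windows (motifs, signature, bridge residues) mutate at one tenth
of the background rate, emulating purifying selection. After evolution each
leaf's determinant region is overwritten by its planted label: decamer
leaves receive the consensus window plus the canonical bridge residues;
dimer leaves receive one of the two printed bacterial dimer windows *and*
Asn/Glu/Ala substitutions at the bridge positions, mirroring the
observation that the inter-dimer bridge network is absent from dimer-only
members. The simulation has no indels (leaf coordinates equal scaffold
coordinates), uses a uniform substitution model rather than an empirical
one, and plants determinants exactly — so classifier-recovery results
demonstrate correctness of the decision logic under the stated determinant
hypothesis, not robustness to indels, annotation error, or determinant
variants outside the printed exemplars.

`make_alignment_with_stats` realises exact per-column gap counts and
rejection-samples residues into a requested homogeneity band.
`build_toy_assembly` produces ideal Cα helices (rise 1.5 Å, 100° turn)
with optional planted salt-bridge/stacking pseudo-side-chains at exact
distances and an optional hinge rotation whose analytic displacement
(2 sin(θ/2) × distance from axis) anchors the domain-motion test.
`simulate_sec` inverts a known calibration line (defaults: slope −0.4,
intercept 2.5 on the Kav scale; void 45 mL, bed 120 mL; standards 25, 67,
275 and 669 kDa; one decamer-type unknown with a 28,624 Da subunit) and
adds seeded Gaussian noise to elution volumes (σ = 0.5 mL by default).

## Numerical choices and degenerate inputs

Seeded `numpy` generators everywhere; identical seeds give identical
outputs. NJ ties break on the lowest index pair; negative branch estimates
clamp to 0. Kabsch rejects collinear point sets (second singular value
≤ 1e−8 of the first). SASA values are quoted with the point-set
discretisation in mind: rotation invariance holds to ~0.5%, analytic
sphere comparisons to 2% at 960 points. All-gap columns have undefined
homogeneity and are excluded before the homogeneity rule applies. Zero
surviving columns, empty regions, unmapped leaves, unknown labels and
out-of-column elution volumes raise or warn as documented per function.

## Problem sizes

The test suite and the acceptance script run synthetic problems sized for
interactive use: families of 8–12 taxa × 284 residues, trees of 5–8
leaves, toy assemblies of ~30 atoms, 960-point surfaces, and
four-standard SEC calibrations. These sizes already pin the behaviour the
larger published analyses depend on (additive-tree exactness, exact column
filtering, exact planted-geometry recovery); scaling up changes runtime,
not the logic under test.

## Known limitations

Sequence clustering approximates bit-score density with raw NW score
density. The family signature and motif spans outside the three published
rice spans are placements, not published coordinates. The classifier
encodes the printed determinant exemplars; genuinely novel dimer
determinants would be called unknown rather than dimer. NJ is not an ML
tree; deep-branch rearrangements relative to FastTree/JTT analyses are
expected. Accessible-surface areas are Cα/heavy-atom Shrake–Rupley values,
not PISA assembly energetics. Feedback inhibition and metal effects on
activity are not modelled: no sequence-level procedure for them is defined.
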