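# p5crkit

Sequence, phylogenetic, structural and size-exclusion-chromatography (SEC)
analytics for the **pyrroline-5-carboxylate reductase (P5CR)** enzyme
family — the terminal enzyme of proline biosynthesis (EC 1.5.1.2), built
from an N-terminal Rossmann dinucleotide-binding domain and a C-terminal
dimerisation domain. P5CRs occur as intertwined homodimers or as
hourglass-shaped decamers of five dimers, and which assembly forms is
encoded in a short C-terminal sequence determinant.

The package is for structural bioinformaticians and enzymologists who want
to:

* recognise P5CR sequences by their Prosite-style PA-line signature and
  locate the family fingerprint motifs A–E (adenine/2′-phosphate region,
  Gly-rich pyrophosphate loop + V-K-P extension, nicotinamide loop, hinge,
  proline-carboxylate pocket) in the rice (*Os*P5CR) coordinate frame;
* predict **cofactor preference** (NADPH-preferring / NADPH-capable) from
  the basic-residue content of motif A, and the phosphate-interaction mode
  (Ser+Arg = 1, Lys = 2, Asn = 3);
* predict **oligomeric state** (decamer / dimer) from the dimer–dimer
  determinant window (rice 202–214, consensus
  `A-D-G-G-V-A-A-G-L-P-R-[D/R]-L`) and the inter-dimer salt-bridge network
  (D203, R212, H236, K241, D242);
* filter alignment columns by gap fraction (> 0.5 excluded) and
  homogeneity (< 0.1 excluded), build neighbor-joining trees with
  bootstrap, and ask monophyly / lineage-specific-duplication questions;
* measure structures: Kabsch superposition and RMSD, Shrake–Rupley
  accessible and buried interface areas, salt bridges, Arg–Arg stacking,
  and hinge-type domain motion;
* calibrate SEC columns (Kav vs log₁₀ MW), compute sequence masses, and
  snap mass estimates to subunit stoichiometries.

A synthetic-data module generates every input class with known ground
truth (families evolved on a tree with planted determinants, alignments
with exact column statistics, toy assemblies with planted geometry, SEC
runs from a known calibration line), so the whole pipeline runs and is
testable without any downloads.

## Worked example

The central call of the package — classify the three published 13-residue
determinant windows, then check a published SEC estimate:

```python
>>> from p5crkit.fingerprint import classify_dd_window
>>> classify_dd_window("ADGGVAAGLPRDL").state   # plant/human-type window
'decamer'
>>> classify_dd_window("QNAAIRQGFDMAE").state   # Neisseria-type window
'dimer'
>>> round(classify_dd_window("ADGGVAAGLPRDL").score, 3)
1.0
>>> round(classify_dd_window("QNAAIRQGFDMAE").score, 3)
0.021

>>> from p5crkit.sec_calibration import infer_stoichiometry
>>> est = infer_stoichiometry(mw_est=275_000, subunit_mw=28_624)
>>> est.n_inferred, round(est.rel_error, 3), est.ambiguous
(10, 0.041, False)
```

The score is a weighted fraction of determinant features present
(consensus similarity plus the named Gly/Pro/bridge residues): ≥ 0.5 calls
a decamer, ≤ 0.3 a dimer. The SEC example: a 275 kDa mass estimate over a
28,624 Da subunit is 9.6 subunits, which snaps to the decamer (n = 10,
theoretical mass 286,240 Da, 4.1% from the estimate) — an unambiguous call
within the ~10% error of SEC.

End-to-end on synthetic data:

```python
>>> from p5crkit.synthetic_data import FamilyConfig, simulate_family
>>> from p5crkit.fingerprint import anchor_to_reference, classify_oligomer
>>> fam = simulate_family(FamilyConfig(n_taxa=8, seed=11))
>>> calls = {r.id: classify_oligomer(r, anchor_to_reference(r, fam.scaffold)).state
...          for r in fam.sequences}
>>> calls == fam.labels
True
```

## Command line

```bash
p5cr simulate family --n-taxa 12 --seed 1 --out-fasta fam.fasta
p5cr scan --fasta fam.fasta                 # signature + motifs + calls
p5cr filter-msa --msa aln.fasta --stats-out cols.tsv
p5cr tree --msa aln.fasta --bootstrap 100 --monophyly t1,t2
p5cr struct interface --pdb model.pdb --group-a A --group-b B
p5cr sec stoichiometry --mw-est 275000 --subunit 28624
```

All reports are JSON and embed the tool version, seeds and the formula
variants in effect (identity denominator, homogeneity formula, buried-area
convention).

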