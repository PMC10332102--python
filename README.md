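# familyscope

A toolkit for transcriptome-scale analyses of the **AP2/ERF transcription-factor
superfamily** — the plant-specific family defined by the AP2 DNA-binding
domain, whose members regulate abiotic-stress and hormone responses.  It is
aimed at researchers who assemble a transcriptome (for example from a
non-model crop such as *Trichosanthes kirilowii*), and then want a tested,
scriptable version of the standard downstream workflow instead of a chain of
point-and-click tools:

* **Family identification & classification** — proteins are scanned with
  position-specific scoring matrices for the AP2 and B3 domains (results of
  an external HMMER search can be imported instead).  Genes with two complete
  AP2 domains form the **AP2** subfamily, one AP2 plus a complete B3 is
  **RAV**, a single AP2 splits into **ERF** vs **DREB** by the residues at
  domain positions 14 and 19 (Ala/Asp vs Val/Glu), and genes without a
  complete domain are excluded.  ORF length, protein length, molecular
  weight (average masses) and isoelectric point (Bjellqvist pKa set) are
  reported per gene.
* **Selection analysis** — homologous pairs (length ≥ 300 bp, global
  alignment identity > 40 %; reciprocal best match across species) are fed
  to a from-scratch **Nei–Gojobori (1986)** implementation: fractional
  synonymous/nonsynonymous site counts, pathway-averaged difference counts
  with stop-codon path exclusion, Jukes–Cantor correction

  &nbsp;&nbsp; Ka = −¾ ln(1 − 4pN/3), Ks = −¾ ln(1 − 4pS/3),

  and the usual reading of ω = Ka/Ks (< 1 purifying, = 1 neutral, > 1
  positive selection).
* **Phylogeny** — progressive protein alignment (3-mer/UPGMA guide tree,
  profile Needleman–Wunsch, BLOSUM62, affine gaps −10/−0.5), p- or
  Poisson-corrected distances, **Saitou–Nei neighbor joining**, bootstrap
  supports by column resampling, and clan assignment (A1–A6, B1–B6, AP2,
  RAV) by nearest labelled reference.
* **Expression analysis** — FPKM filtering, DEG calling between flowering
  stages (Welch t on log2(FPKM+1), fold-change ≥ 2 by default), heatmap
  z-score matrices, and family × hormone-pathway Pearson co-expression
  networks (two-sided t test with n−2 df, p < 0.05, top-10 edges per gene
  by |r|) written as Cytoscape-ready edge lists.
* **qRT-PCR statistics** — Livak **2^−ΔΔCt** relative expression against a
  0 h calibrator, one-way ANOVA with **Duncan's multiple range test**
  letters (protection level 1−0.95^(p−1)), and co-regulatory networks with
  |PCC| > 0.5, p < 0.05.
* **Synthetic data** — every input the pipeline consumes can be simulated
  with known truth: planted domains and diagnostic residues, CDS pairs
  evolved under a controlled dN/dS, FPKM matrices with planted fold changes
  and latent-factor modules, and Ct tables with planted inductions.  This
  is first-class, tested code, not a fixture.

## Worked example

`examples/` contains one short script per capability.  Classifying a small
synthetic transcriptome (`python examples/01_identify_family.py`) prints:

```
gene       subfamily  res14/19  orf_bp    aa     MW_Da    pI
ERF001     ERF        A/D          729   242   28526.5  8.96
...
DREB001    DREB       V/E          666   221   26514.5  9.38
...
AP2-001    AP2        -            864   287   33568.1  9.16
RAV001     RAV        -            735   244   28984.4  9.70
NEG001     excluded   -            537   178   20968.9  6.57

subfamily counts: {'ERF': 6, 'DREB': 4, 'AP2': 2, 'RAV': 2, 'excluded': 5}
```

Every planted gene lands in its true subfamily — `res14/19` shows the
diagnostic residues the ERF/DREB split is based on — and the domain-free or
truncated-domain decoys are excluded.  Selection analysis
(`python examples/02_kaks_selection.py`) recovers the simulated ω and
re-checks the published paralog table:

```
simulated pairs (500 codons, dS target 0.3):
 omega       Ka       Ks    Ka/Ks  class
   0.1   0.0316   0.3109   0.1017  purifying
   0.5   0.1273   0.2944   0.4325  purifying
   1.0   0.3172   0.3132   1.0129  positive

published paralog table: 33 pairs, 2 under positive selection (TkERF9/TkERF92, TkERF14/TkERF22)
re-divided ratio for TkERF9/TkERF92: 1.049782 (printed 1.049774) -> positive
```

The whole workflow also runs end-to-end from one flat YAML config, either
from Python (`familyscope.run_all`) or the thin CLI:

```bash
familyscope run --config config.yaml        # full pipeline + manifest
familyscope identify --cds cds.fasta --out assignments.tsv
familyscope kaks --cds-a cds.fasta --out kaks.tsv
familyscope tree --proteins family.fasta --bootstrap 1000 --seed 7 --out tree.nwk
```

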