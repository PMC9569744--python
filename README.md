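# virtual2de

Sectional and semi-virtual two-dimensional electrophoresis (2DE) maps of
plasma proteoforms, reconstructed from per-section peptide
identifications.

## The problem

Classical 2DE separates proteins by isoelectric point (pI, first
dimension: isoelectric focusing in an immobilized pH gradient) and by
molecular weight (Mw, second dimension: SDS-PAGE). A single protein
rarely gives a single spot: charge-altering modifications —
phosphorylation, sialylated glycans, acetylation — spread its
proteoforms into a horizontal *spot train*. In the sectional variant of
the experiment, the gel (or just the focusing strip) is cut into
sections with known coordinates, each section is analysed by LC-MS/MS,
and the pattern is reconstructed quantitatively instead of being read
off a stained image. `virtual2de` is the desk-side counterpart of that
workflow, for proteomics researchers who want to build, compare or
simulate such pattern maps.

The toolkit covers:

* **Physical chemistry** — average/monoisotopic masses, net charge
  Q(pH), isoelectric points by bisection, and proteoform construction
  with PTM-induced pI/Mw shifts. The default pKa set is Bjellqvist
  (residue-specific terminal pKas); EMBOSS and Lehninger are available
  for sensitivity checks.
* **Digestion** — in-silico trypsin (cleave after K/R, not before P)
  with missed cleavages, and the *theoretically observable* peptide
  count N_obsbl (default window 500–4500 Da, 6–50 residues).
* **Quantification** — emPAI: PAI = N_observed / N_observable,
  emPAI = 10^PAI − 1, with the standard identification filter
  (≥ 2 unique peptides per protein above a score threshold).
* **Map building** — pI-axis calibration (piecewise-linear pH
  gradients, including nonlinear 3–11 strips), log-linear SDS-PAGE Mw
  calibration, 96-section gel grids and 36-section strip schemes,
  pattern construction, spot-extent summaries, pattern comparison with
  log2 emPAI ratios, and deterministic SVG bubble maps (circle area
  proportional to emPAI).
* **Simulation** — proteoform spot trains with binomially occupied
  phospho sites crossed with sialylated glycoforms, Poisson-sampled
  per-section peptide tables with known ground truth, and recovery
  metrics.

Eight classical plasma proteins (albumin, haptoglobin, hemoglobin
alpha/beta, transthyretin, apolipoprotein A-II, alpha-1-acid
glycoprotein 1, C-reactive protein) are packaged with their mature-chain
annotations as fixtures.

## Worked example

Theoretical pI/Mw of the packaged mature chains:

```sh
$ v2de pimw
accession   chain   pI     Mw
P02768      mature  5.67   66472
P00738      mature  6.13   43349
P00738      alpha2  5.57   15946
P00738      beta    6.32   27265
...
```

Albumin's mature chain focuses at pH 5.67 with an average mass of
66,472 Da; the haptoglobin beta chain at 6.32 / 27,265 Da.

Simulate a haptoglobin beta-chain spot train (3 phospho sites at 50 %
occupancy × 2 sialylated glycoforms), quantify it per strip section,
and build the semi-virtual map:

```sh
$ v2de simulate --seed 3 --jitter 0 --out sim.psm.tsv
47 PSM rows (8 proteoforms) -> sim.psm.tsv

$ v2de empai --psm sim.psm.tsv
accession    section  n_obs  n_obsbl  pai     empai
P00738:beta  10       11     18       0.6111  3.0842
P00738:beta  8        18     18       1.0000  9.0000
P00738:beta  9        18     18       1.0000  9.0000

$ v2de build-map --psm sim.psm.tsv --out pattern.tsv
3 spots -> pattern.tsv
```

The eight proteoforms focus into strip sections 8–10 (pH ≈ 4.8–5.3 on
the nonlinear 3–11 gradient), a contiguous chain acid-shifted from the
bare chain's pI of 6.32 — the spot-train morphology sialylated
glycoproteins show on real gels. Sections 8 and 9 observe all 18
observable tryptic peptides, so their emPAI saturates at
10^1 − 1 = 9; section 10 holds the tail of the train. `v2de render`
turns the pattern into an SVG bubble map and `v2de compare` matches two
patterns spot-by-spot.

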