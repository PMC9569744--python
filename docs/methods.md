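# Methods

## Charge model and isoelectric points

A polypeptide's net charge is the Henderson–Hasselbalch sum over its
ionizable groups:

    Q(pH) = Σ_basic n_i / (1 + 10^(pH − pKa_i)) − Σ_acidic n_i / (1 + 10^(pKa_i − pH))

with acidic side chains D, E, C, Y, basic side chains H, K, R, and both
termini. Q is strictly decreasing in pH whenever at least one group is
present, so the isoelectric point — the root of Q on [0, 14] — is
unique when it exists; it is found by bisection to 1e-4 pH units and
reported at 2 decimals when compared with published tables. A molecule
whose charge never changes sign (e.g. an acetyl-blocked amine leaving
only carboxyls) has no pI and raises an explicit error rather than
returning a boundary value.

Three pKa sets ship in `data/pka_sets.tsv` (versioned, documented in
the file header):

* **bjellqvist** (default) — the table with residue-specific N-terminal
  pKas (A 7.59, M 7.0, S 6.93, P 8.36, T 6.82, V 7.44, E 7.7, else 7.5)
  and C-terminal exceptions for D (4.55) and E (4.75). This is the set
  behind the classical theoretical pI values used in gel work, and it
  reproduces the published mature-chain values for the packaged plasma
  proteins to 2 decimals (one published outlier; see Limitations).
* **emboss** and **lehninger** — for sensitivity checks; pI values can
  differ by several tenths of a pH unit between sets, which is the
  point of exposing them.

## Masses

Residue masses on both scales are derived at import from the pyteomics
elemental tables, so average and monoisotopic arithmetic share one
source of truth. Average masses are the default for gel (Mw)
coordinates — they reproduce the published integer chain masses —
while monoisotopic masses serve peptide-level bookkeeping. Residues
U, O, B, Z, X are rejected with their position rather than
approximated: a silent placeholder mass would corrupt the Mw axis.

## Modifications

Modifications carry a mass delta on each scale plus a list of ionizable
group changes:

* **phospho** — +79.98 Da (avg); two acidic groups per phosphate,
  pKa 1.2 and 6.5 (the two phosphate ionizations).
* **glyco** — mass from monomer composition (avg: Hex 162.14,
  HexNAc 203.20, NeuAc 291.26, Fuc 146.14); each NeuAc contributes one
  acidic carboxyl, pKa 2.6; neutral sugars change mass only.
* **acetyl** — +42.04 Da and removal of one lysine basic group
  (pKa 10.0).
* **oxidation**, **carbamidomethyl** — mass only.

This is deliberately the simplest model that reproduces acidic spot
trains: it ignores local electrostatics, pKa shifts from neighbouring
charges, and site positions (only counts matter for composition-level
pI/Mw).

## Digestion and the emPAI denominator

Trypsin cleaves after K or R except before P (the Keil rule, applied by
the common search engines; a flag disables it). N_obsbl counts fully
cleaved peptides inside a closed observability window, by default
500–4500 Da and 6–50 residues — a typical Orbitrap acquisition range;
the window is configuration, not dogma, and is recorded with outputs.
Missed-cleavage variants are excluded from the denominator by default
because they double-count sequence; a flag includes them for
sensitivity analysis. emPAI = 10^(N_obs/N_obsbl) − 1; a chain with no
observable peptides makes emPAI undefined and is an error, never a
division by zero.

"Identified peptides" counts distinct sequences with modification
states collapsed, since PAI counts parent peptides and modified
variants would inflate heavily modified proteoforms; a flag counts them
separately. The identification filter is ≥ 2 distinct unique peptides
above a score threshold; "100 % confidence" is engine-specific, so the
threshold is explicit configuration.

## Axes and sections

The pI axis is a piecewise-linear monotone map between strip position
and pH through an anchor table; extrapolation is an explicit off-gel
error. A 5-point approximation of a nonlinear 3–11 gradient over 18 cm
ships as a realistic default shape (steep ends, flat middle); users
supply the manufacturer's curve for accuracy. The Mw axis is the usual
least-squares fit of log10(Mw) against relative migration; the fitted
slope must be negative.

Sections are half-open intervals [low, high) with the final interval
closed, so the calibrated range is partitioned exactly — every in-range
coordinate belongs to one section, boundaries go to the higher index.
The strip scheme is 36 equal 0.5-cm sections over 18 cm; the gel grid
default is 8 Mw-rows × 12 pI-columns (96 sections), rows equal in
log10(Mw), fully overridable with explicit edges. In strip (semi-
virtual) mode a spot's Mw coordinate is the theoretical chain mass; in
grid mode it is the row's geometric midpoint.

Pattern comparison uses greedy nearest-neighbour matching per accession
within a pI tolerance (default 0.25 pH) and relative Mw tolerance
(default 10 %), with a 0.01 pseudocount in log2 emPAI ratios so zero
spots stay comparable. Greedy matching is a documented limitation:
adequate because spot sets are small and tolerance windows rarely
overlap, not an optimal assignment.

Rendering encodes emPAI as circle **area** (the perceptually honest
reading of "ball size proportional to abundance"); a radius-
proportional mode exists because the convention is ambiguous. Output is
deterministic SVG: identical input gives byte-identical files.

## Synthetic spot trains

The generator emulates the two modification classes that dominate
plasma-protein spot trains:

* phospho occupancy — n sites each occupied with probability p, giving
  Binomial(n, p) weights over phospho counts; defaults n = 3, p = 0.5
  (a moderately phosphorylated chain with all occupancy classes
  populated);
* glycoforms — a small set of glycan complements with fixed molar
  weights; the haptoglobin-beta default models four biantennary
  disialo N-glycans (weight 0.6) versus a variant with one trisialo
  triantennary glycan (weight 0.4), i.e. 8 vs 9 NeuAc.

Each (phospho-count × glycoform) species is a proteoform with exact
model weight; weights sum to 1 by construction. Observation is
Poisson-thinned sampling: a proteoform focuses at its pI plus Gaussian
jitter (default sd 0.05 pH, emulating focusing imperfection; 0 in
noise-free analyses), and the distinct-peptide count per (protein,
section) is min(N_obsbl, Poisson(depth × weight × N_obsbl)), after
which that many peptides are drawn without replacement. Default depth
is 5 expected observations per unit abundance — deep enough that
occupied sections saturate, shallow enough that train tails remain
stochastic. All randomness flows from one `numpy` generator seeded
explicitly; no global RNG state.

What the simulation does **not** model: physical carry-over/smearing
into adjacent sections beyond pI jitter, Mw heterogeneity in strip mode
(theoretical by construction), retention-time or spectrum-level
effects, chimeric or false identifications, and shared peptides between
proteins. Passing recovery tests therefore demonstrate that the
reconstruction machinery is self-consistent under the stated noise
model — not that real-gel patterns will be recovered at these rates.

## Numerical choices

* Bisection tolerance 1e-4 pH; verified against a 1e-4-step grid scan
  of |Q| and against an independent pI implementation (pyteomics) on
  random peptides.
* Simulation sizes in tests and the acceptance script: 200 random
  sequences for the digestion oracle, 100 peptides for the pI oracle,
  50 seeded replicates for train recovery — all run in seconds.
* Pattern tables round-trip through `repr`-precision edges and
  6-decimal emPAI; a body checksum detects hand edits (warning, not
  error).

## Limitations

* pI is composition-level; sequence-context pKa shifts are out of
  scope, as are structure and binding.
* Of the eleven published mature-chain (pI, Mw) anchor pairs used to
  validate the fixtures, ten reproduce exactly (pI to 2 decimals, Mw to
  the dalton). The published transthyretin pI (5.31) is the one
  outlier: the Bjellqvist value for the 21–147 chain is 5.35, confirmed
  by an independent implementation, while its mass matches exactly —
  the published figure evidently comes from a different tool or table.
* The haptoglobin alpha-1 chain (an Hp1-allele product) is not a
  contiguous range of the canonical sequence and is therefore not
  annotatable in the chain model; alpha-2 and beta are.
* The 96-section grid's published geometry (rows × columns, physical
  coordinates) is not public; the 8 × 12 default is a convention, and
  nothing downstream depends on it.
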