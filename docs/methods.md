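# Methods

## Mass conventions

Masses are monoisotopic, computed as the sum of residue masses plus one
water, plus modification deltas (iTRAQ 4-plex tag +144.10206 Da per site,
carbamidomethyl +57.02146 Da per cysteine; proton 1.00728 Da). The constant
table ships as `data/constants.tsv` and is the single editable source of
these values. Two reporting conventions mirror the fixture tables: the
*unlabelled* mass is neutral, the *labelled* mass is singly protonated, so a
pair with *n* labelling sites differs by `n × 144.102 + 1.007` Da. Labelling
sites are the N-terminus plus every lysine; tyrosine O-acylation is ignored
(its reactivity is marginal, a few percent at most), and isoleucine/leucine
are kept distinct despite identical masses.

`mass_consistency_check` compares a fixture row's printed masses with theory
at a 0.03 Da tolerance. On the packaged tables the *labelled* column agrees
with theory to within ~5 mDa throughout, but the *unlabelled* column is
evidently instrument-observed: eleven rows deviate by 0.03–0.09 Da and one
row (SSMDAFQQILK) prints a mass ~16 Da above theory, identical to the
printed mass of SSFDAFQQILK two rows earlier. The two-column check therefore
passes 100 of 112 unflagged rows (89.3%). Rows flagged `$` carry an
unexplained extra mass shift and are excluded rather than guessed at.

## Charge model

Net charge is the standard Henderson–Hasselbalch sum over an ionizable
inventory built from the species: acids D, E, free C, Y and the C-terminus;
bases H, K, R and the N-terminal amine. A tag replaces the native amine at
its site with a single `tag_amine` group; carbamidomethylated cysteine is
non-ionizable (chemically correct, even though reference structure-drawing
calculations may or may not have included the alkylation). The default pKa
set (`data/pka_bjellqvist.tsv`) is a Bjellqvist-style table used for IPG
work: C-term 3.55, D 4.05, E 4.45, H 5.98, N-term 7.50, C 9.00, Y 10.00,
K 10.00, R 12.00. Every value is overridable via `PKaTable.override` or the
`[pka_overrides]` config section; the packaged file is never mutated.

The tag-amine pKa is fixed at **7.60**, calibrated from the analytic anchor:
for free lysine tagged on both amino groups the inventory is two tag amines
against one fully deprotonated carboxylate, so `Z = 0` exactly at the tag
pKa. Free amino acids are supported as 1-residue species; their alpha-amino
pKa defaults to the in-chain N-terminal value and should be overridden with
the free-amino-acid value (≈ 8.95 for lysine) when a free amino acid is
actually meant — a polypeptide alpha-amine and a free amino acid differ by
more than a pH unit.

pI is found by bisection on [0, 14] to 1e-4; monotonicity of `Z` makes the
root unique, and tests verify the root against an independent dense
grid scan of the charge curve. Because the model is a fixed per-group pKa
sum, it cannot reproduce structure-aware reference values exactly; the
documented agreement window is ±0.35 pH units, and for doubly tagged
peptides that retain arginine the model necessarily places the pI near the
tag pKa (the direction of the shift, not its magnitude, is the robust
prediction there). Neighbour effects, temperature and denaturant
corrections are out of scope.

## Strip geometry

The default layout is the 12-well, 12 cm pH 3–10 strip with a nominally
linear gradient: well width 0.583 pH units. Wells are half-open intervals
`[lo, hi)` with the last well closed, so a boundary pI deterministically
belongs to the more basic well. A pI outside the gradient clamps to the
edge well and is flagged rather than rejected, since computed pI values can
fall slightly off-strip.

## Shift classification

Observations are paired by sequence across label states. The labelled side
must show replicate agreement — at least `min_replicates` (default 3)
observations with the *same* fraction set — otherwise the pair is group D
(irreproducible). The consensus set is the modal set, ties broken toward
the smaller set then the more acidic wells. Reproducible pairs are
classified on consensus midpoints: `delta = mid(labelled) −
mid(unlabelled)`, basic (A) at ≥ +0.5 wells, acidic (C) at ≤ −0.5, none (B)
between. The half-well threshold is configurable; the fixture tables
contain boundary rows whose printed group assignment no single set-rule
reproduces, so fixture group labels are taken from table membership and the
classifier is validated on the unambiguous subsets plus simulated data.
Observation confidence below the cutoff (default 95%) excludes a row before
pairing. `$`/`*` flags are carried through untouched.

Composition profiles report the mean number of acidic (D+E) and basic (K+R)
residues per peptide per unlabelled fraction, a peptide counting once in
each well it was observed in. Retention deltas are per-fraction means of
(labelled − unlabelled) retention time over pairs with times on both sides.
The pI filter keeps an identification when an observed well is within
`tol_wells` (default 1) of the well predicted from the computed pI of the
appropriate label state.

## Simulator

The generator emulates the structure the analysis assumes, with defaults
chosen as the study conditions: 20 random proteins of length 300 (uniform
residue alphabet — pI diversity matters more than compositional realism),
tryptic digestion (cleave after K/R except before P, via pyteomics),
peptides shorter than 6 residues dropped as unobservable, 3 replicates,
spillover 0.15 (most peptides focus in one well, the rest in an adjacent
one; edge wells spill inward), group proportions 70:34:11:7 over A/B/C/D as
observed in the fixture cohort, offsets +2/−2 wells for A/C, and a
+6-minute labelled retention shift for well-1 peptides (zero elsewhere).
A single `numpy` generator seeded from the config drives all sampling.

Two deliberate modelling choices keep the ground truth meaningful. First,
group assignment respects strip feasibility: a peptide whose true well
leaves no room for the group's offset is never assigned that group
(renormalised sampling), mirroring the observed cohort where acidic
shifters all start at the basic end. Second, group-D wells are drawn
uniformly per replicate *conditioned on not reaching replicate agreement*:
an accidentally agreeing draw would not be an irreproducible peptide, and
the conditioning makes "zero spillover ⇒ perfect recovery" a theorem for
every seed rather than a high-probability event.

What passing the simulation tests does **not** show: real digests have
non-uniform composition, confidence-dependent identification, correlated
spillover and label-dependent ionisation efficiency; none of these are
modelled, so recovery rates here bound only the pipeline's logic, not its
field performance.

## Numerical and formatting choices

Bisection bracket [0, 14], tolerance 1e-4; grid-scan oracle step 1e-4 with
agreement asserted at 1e-3. Masses print at 2 decimals and pI at 2 decimals
in all outputs so result files diff byte-identically between runs; run
summaries echo the fully resolved configuration and seed.
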