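# Methods

## Scope and model

`glycoserum` implements the desk half of a MALDI-TOF serum N-glycomics
study of ovarian disease: relative quantification of the serum N-glycome,
derived glycan traits, three-group statistics, diagnostic evaluation with a
three-class random forest, and a synthetic cohort generator calibrated to
published group-level trait values so every stage can be exercised and
validated without patient data. The wet-lab side (PNGase F release, SPE
clean-up, methylamidation chemistry, lectin ELISA) is out of scope except
for its mass consequences.

## Mass chemistry

Compositions are written `H{hex}N{hexnac}[S{neu5ac}][F{dhex}]`. Neutral
monoisotopic mass is the sum of residue masses (Hex 162.0528, HexNAc
203.0794, dHex 146.0579, Neu5Ac 291.0954 Da) plus one water (18.0106 Da).
Methylamidation converts each sialic-acid carboxyl −COOH to −CONHCH3; the
elemental substitution −OH → −NHCH3 adds 13.031634 Da per Neu5Ac and is the
package default, matching positive-mode analysis of stabilized sialoglycans.
Ions are singly sodiated by default; the adduct mass is Na minus one
electron (22.98922 Da). The electron mass (~0.00055 Da) is far below the
matching tolerance but the convention is explicit and tested. The unit
tests verify every library mass against an independent summation over
atomic masses of the full elemental formula (tolerance 1e-4 Da).

## Structural classification

A composition does not determine a structure, so traits are driven by
`GlycanAnnotation` objects: curated entries from a library TSV always win;
otherwise fallback rules infer the class. Oligomannose requires exactly the
two core GlcNAcs, ≥5 hexoses and no decorations. Exactly three HexNAc with
≥5 hexoses is called hybrid. Two-HexNAc compositions that are not
oligomannose (paucimannose such as H4N2) are classed `other` rather than
complex so they cannot leak into the agalactosylation trait. Everything
else is complex; a bisecting GlcNAc is inferred when HexNAc ≥ 5 and
hex − 3 < hexnac − 2 (more antennary GlcNAcs than hexoses could decorate),
antennae = hexnac − 2 − bisecting, galactoses = min(max(hex − 3, 0),
antennae). The inference is deliberately conservative and is overridable
per glycan through the curated library, which is the right place to encode
orthogonal LC-MS/MS structural evidence.

The shipped library (46 entries) covers the oligomannose series Man5–Man9,
common hybrids, agalactosylated through digalactosylated neutral complex
glycans with and without core fucose and bisection, and mono- to
tetra-sialylated complex glycans. H3N2 is omitted because its sodiated ion
(m/z ≈ 933) falls below the 1000–4500 acquisition window; every shipped
glycan's [M+Na]+ lies inside that window.

## Annotation and normalization

Targeted extraction in the MassyTools spirit: internal recalibration
against known glycan masses (nearest-peak matching within 3× tolerance,
least-squares polynomial of degree ≤ 2 on the mass errors, skipped with a
warning when fewer than `min_calibrants` match), then nearest-peak matching
of each library glycan within an absolute tolerance (default 0.15 Da).
Matching is globally injective: candidate (glycan, peak) pairs are assigned
in order of ascending mass error, ties toward the lower-m/z glycan, and no
peak serves two glycans. Peaks below `sn_threshold` (default 3) times the
noise estimate are invisible; the default noise estimate is the median
intensity of peaks left unmatched by the library — in targeted extraction
the unmatched population is the natural empirical background, whereas the
median over *all* peaks would sit at a mid-abundance glycan and the filter
would throw away half the real signal. An explicit per-spectrum noise level
can be supplied instead.

Profiles are total-area normalized (each glycan as % of summed annotated
signal), so all downstream quantities are compositional. Replicate spots
are averaged on the percentage scale, which cancels spot-to-spot total-ion
yield, then renormalized.

## Derived traits

Sixteen traits: Man (oligomannose sum), G0/G1/G2 over *neutral complex*
glycans by galactose count with G total = G1 + G2, F and B traits split
into neutral/sialylated components, S1–S4 by sialic-acid count and S total.
Restricting the G traits to neutral complex glycans is deliberate:
sialylated glycans are implicitly galactosylated and hybrid hexoses are
ambiguous between mannose and galactose, and only with this restriction do
galactosylation totals in the published range (~7–11%) coexist with S total
≈ 82%. Traits are linear in abundances, groups may overlap (one glycan can
be agalactosylated, bisected and fucosylated at once), and the additivity
identities S total = ΣSk, F total = F neutral + F sialo, B total likewise,
G total = G1 + G2 hold per sample to 1e-9 by construction.

## Statistics

Each trait is routed by a one-sample Kolmogorov–Smirnov test of the pooled
within-group residuals against a fitted normal (α = 0.05): Gaussian traits
go to one-way ANOVA with pairwise contrasts on the pooled ANOVA mean-square
error, non-Gaussian traits to Kruskal–Wallis with Dunn's tie-corrected
post-hoc z tests. Pairwise p-values are Bonferroni-multiplied by the number
of contrasts (3 for three groups) and capped at 1; contrast CIs use the
Bonferroni-adjusted confidence level. Plain K-S with estimated parameters
is anticonservative; a Lilliefors-corrected variant is available but off by
default. Pearson correlation uses the exact t-distribution p (n − 2 df).
ROC AUC is computed by the rank (Mann–Whitney) formulation with ties
counting 1/2, verified in the tests against exhaustive pair counting.

## Three-class evaluation

The normal/benign/cancer model is a random forest (scikit-learn, default
500 trees) under stratified 5-fold CV with a fixed seed; every subject
receives exactly one out-of-fold probability triple, and the AUC family is
computed from the pooled out-of-fold matrix: per-label one-vs-rest AUCs
(NormalAUC, BenignAUC, CancerAUC), MacroAUC = their unweighted mean (held
as an identity in the tests), MicroAUC = AUC on the flattened 3n-long
label-indicator vector. Panel-size selection ranks features by mean
impurity importance over 20 repeats of 5-fold CV and scans a k-grid by mean
MacroAUC, ties to the smaller panel. Stratification is the package's
choice, keeping per-class counts stable at cohort sizes of 60–70. PCA
standardizes features (constant features dropped with a warning) before
decomposition; LDA uses a ridge-stabilized pooled scatter so the Fisher
direction exists when p > n.

## Synthetic cohort

The generator emulates the study design: 60 healthy controls, 70 benign
neoplasms, 70 cancers split 35/35 into early (stage I–II) and late (stage
III–IV) — the per-stage split within the cancer group is a declared
convention. Calibration targets are group-level trait means/SDs for the
benign, early and late groups; the healthy-control column is not available
at that granularity, so control targets are the benign column shifted by
one benign SD in the directions the disease groups separate from controls
(lower Man, G0 and B neutral; higher S total, spread proportionally over
S1–S4) — a synthetic convention, not a measured value. One printed benign
F-neutral value contradicts the additivity identity F neutral = F total −
F sialo and was reconciled to 6.80 (SD set to the neighbouring columns'
magnitude); component targets are authoritative wherever a printed total
disagrees with its components by a rounding unit.

Per-group mean abundance vectors are obtained by iterative proportional
fitting over the overlapping trait-group constraints, starting from a
uniform spread within each disjoint structural cell, rescaling each
constrained group to its target and its complement to 100 − target until
all residuals are below 1e-9 (500-sweep cap; infeasible targets raise with
the violated constraints listed). Subjects are logistic-normal
perturbations of the group mean: latent log-abundances get i.i.d. Gaussian
noise with one dispersion per group, found by bisection so the
across-subject SD of S total matches its target. Two calibration details
matter: latent residuals are centred within each group, and the latent
baseline is fixed-point-corrected so the realized per-glycan group means
equal the calibrated vectors — otherwise the nonlinear
closure-and-renormalize transform biases the cohort means (Jensen), by up
to ~0.9 percentage points in S total at the dispersions involved. With the
correction, group trait means are exact in the ground truth and the
generator's SD target is met by construction of the tuning.

The measurement layer mimics reflector-TOF behaviour: each spot carries a
coherent calibration scale error (default 30 ppm, 1 SD, shared by all peaks
of the spot) plus independent per-peak centroiding noise (10 ppm),
per-peak lognormal intensity scatter (CV 0.15), and 5 uniform-m/z noise
peaks per spectrum with intensities up to 0.05% of total signal. The
coherent component dominates, exactly as in real spot-to-spot drift, and is
what the internal recalibration removes; modelling the full 30 ppm as
independent per-peak noise would push high-mass glycans (m/z > 3300)
outside the 0.15 Da window in ~13% of spots and no analysis could recover
the sialylation traits to the tested tolerance — a deliberate design
choice, documented here because it decides what the round-trip tests show.

CA125 is calibrated over the combined benign + cancer subjects: the four
targeted traits (S total −0.26, Man +0.29, G0 +0.23, G1 +0.28) are
standardized, coefficients solved from their empirical correlation matrix,
and the Gaussian noise component orthogonalized against the traits, so the
empirical Pearson correlations equal the targets exactly (infeasible joint
targets — residual variance ≤ 0 — raise). The affine output scale
(150 + 120z) is arbitrary; Pearson correlation is scale-free. Controls get
independent baseline CA125; HE4 is independent of the glycome with a
benign < cancer group shift.

What the generator does *not* emulate: isotope envelopes and profile-mode
spectra, baseline/matrix clusters, real between-glycan correlation
structure beyond the compositional closure, batch effects beyond spot
noise, and real covariate distributions (CA125 is linear-Gaussian, not
log-skewed). Passing round-trip tests therefore demonstrate correctness of
the pipeline's bookkeeping and calibration, not performance on real
spectra.

## Problem sizes and numerical choices

The integration suite simulates the full designed cohort sizes (70/35/35
for recovery, 140 for the covariate checks) with triplicate spots; the
permutation-null random-forest check uses 50 replicates of n = 200 with 200
trees, and the planted-signal selection benchmark 5 informative + 50 noise
features over 120 subjects with 200 trees and a 7-point k-grid — sizes
chosen to make the Monte-Carlo conclusions stable at interactive runtimes.
Tolerances: masses 1e-4 Da against the elemental oracle; IPF residuals
1e-9; additivity identities 1e-9; trait-mean recovery ±0.30 percentage
points; covariate correlations ±0.15; type-I error 0.05 ± 0.02 over 2000
null replicates. Degenerate inputs fail loudly by design: all-zero
annotation raises "no annotated signal", constant vectors are rejected by
the correlation test and reported non-Gaussian by K-S, missing labels or
under-filled folds raise before any model is fitted.
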