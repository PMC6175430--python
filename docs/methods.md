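# Methods

`nfstoich` implements an analysis chain for plasma neurofilament (Nf)
isoform biomarkers in ALS: conversion of immunoassay mass concentrations to
particle counts, one-point stoichiometric cross-calibration, translation
cost accounting under observed versus counterfactual subunit stoichiometries,
a coarse-grained Monte Carlo model of the Nf side-arm brush, and the
accompanying cohort statistics. This note records the models, the defaults
and why they were chosen, and what the synthetic-data pipeline can and
cannot demonstrate.

## Particle counts and one-point stoichiometric calibration

Each immunoassay reports a mass concentration `c` (g/L) against an arbitrary
protein calibrator, so absolute values cannot be compared across assays.
Converting to a particle count per litre,

    N = c / M * N_A,

with molar masses M = 68, 150, 200, 210 kDa for NfL, NfM, NfH(SMI35),
NfH(SMI34) and Avogadro's number N_A = 6.0221415e23, gives a quantity whose
*ratios* across assays become meaningful once the per-assay calibrator scale
is removed. That is done by a one-point calibration against the known
physiological subunit stoichiometry NfL:NfM:NfH = 7:3:2: with control-cohort
median particle counts (m_L, m_M, m_H), the correction factors are

    x = 7 / m_L,   y = 3 / m_M,   z = 2 / m_H,

and every subject's counts are multiplied componentwise by (x, y, z).
Medians (mean of the two middle order statistics for even n) are used
because plasma Nf distributions are right-skewed. By construction the
calibrated control medians are exactly (7, 3, 2); the calibrated medians of
the patient group are then an assay-independent estimate of the in-vivo
stoichiometry. Any per-assay multiplicative distortion cancels exactly —
this is a property test in the suite.

Two NfH phosphoform assays exist (SMI35, SMI34). The analysis reports one
NfH channel; which assay feeds it is ambiguous in principle, so the channel
choice is an explicit flag (`smi35_only` default, `smi34_only` and `sum`
available) and is logged per run. Both channels use the same amino-acid
count (1020) since they quantify the same protein. NfH channels are combined
*before* calibration factors are derived.

Raw counts are kept in particles/L; calibrated counts are treated as
dimensionless stoichiometric shares. Input CSVs are in g/L; a `pg_per_ml`
flag applies the 1e-9 conversion for assay-native units.

## Translation cost model

Adding one amino acid to a growing peptide chain costs ~5 ATP on average,
and translating-plus-folding a 100-residue stretch takes ~25 s; both are
linear in residue count. With subunit lengths 543 (NfL), 916 (NfM) and 1020
(NfH) residues, a calibrated profile (n_L, n_M, n_H) costs

    ATP  = 5    * (543 n_L + 916 n_M + 1020 n_H)
    time = 0.25 * (543 n_L + 916 n_M + 1020 n_H)  seconds.

Two scenarios are compared per subject. *Adaptive* is the observed profile.
*Luxury* is the cheapest profile proportional to 7:3:2 that does not fall
below any observed component: s = max(n_L/7, n_M/3, n_H/2), counterfactual
(7s, 3s, 2s). The rationale is that "maintaining" the physiological ratio
means synthesising more of the deficient subunits, never discarding protein
already made; this makes the luxury cost a per-subject upper envelope and
guarantees luxury >= adaptive pointwise. The anchoring rule is genuinely
underdetermined, so alternatives (`nfl`: match observed NfL; `total`: match
observed total count) are selectable, and the rule in force is logged.
Hours are seconds/3600 with no further adjustment. For the reference
adaptive profile (24, 2.4, 1.6) the luxury/adaptive ATP ratio is
147240/84312 ≈ 1.75.

Absolute cohort ATP/time means depend on undeposited patient-level data;
the package therefore asserts the *structure* of the result (luxury
significantly exceeds adaptive and control on synthetic cohorts; exact cost
identities on reference profiles) rather than any printed cohort mean.

## Synthetic cohorts

No public data set carries all three Nf subunits per subject, so the
generator emulates the statistical structure the analysis needs:

* Concentrations are log-normal (right-skewed, strictly positive),
  parameterised by their median and natural-log SD. Defaults: log-SD 0.4
  for controls (geometric SD ~1.5, typical of plasma NfL in healthy adults)
  and 0.6 for ALS (wider spread in disease).
* Control medians are anchored at plasma NfL = 50 pg/mL (5e-11 g/L), with
  NfM/NfH medians chosen so the underlying particle medians sit at 7:3:2;
  ALS medians are the control medians scaled per isoform by (24/7, 2.4/3,
  1.6/2) so the calibrated ALS medians target the adaptive stoichiometry.
* Every draw is multiplied by a per-assay calibrator distortion factor
  (defaults 1.0 / 0.35 / 2.0 / 2.0 for NfL / NfM / SMI35 / SMI34). These
  are arbitrary *by design*: they emulate assays calibrated against
  unrelated standards, which is exactly what the one-point calibration must
  cancel. Their values never affect calibrated results (tested).
* Clinimetrics: ALSFRS-r baseline ~ N(34, 8) clipped to [0, 48]
  (cohort-typical mean), onset-to-baseline months log-normal around 17
  (typical diagnostic latency), onset site ~ (0.25, 0.733, 0.017) for
  bulbar/limb/both, follow-up score = baseline minus a Poisson decline
  whose mean is tied to the progression category.

Progression rate is (48 − ALSFRS-r)/months since onset; categories are
slow (< 0.5), intermediate (0.5–1.0, closed interval, since the bounding
definitions are "< 0.5" and "more than 1.0") and fast (> 1.0) points/month;
disease stages are early (40–48), intermediate (25–39), late (<= 24).

What passing tests show: the conversion/calibration/cost chain is correct
and assay-scale-invariant under the assumed distributional shape. What they
do not show: anything about real assay artefacts (cross-reactivity, hook
effects, proteolytic fragments, auto-antibody epitope masking) or about the
true in-vivo concentration distributions — the generator's medians are
model inputs, not measurements.

Because a single cohort pair at the study sizes (29 controls, 60 ALS)
carries ~13% sampling error on median ratios (the SE of a log-normal sample
median is ≈ 1.2533 σ/√n on the log scale), recovery checks of the adaptive
stoichiometry average the recovered medians over replicate cohort pairs.
This isolates pipeline correctness from single-draw sampling noise; the
replicate count (25–40) makes the residual Monte Carlo error ~2%.

## Coarse-grained side-arm brush Monte Carlo

The C-terminal Nf tails form a polyelectrolyte brush on the filament
backbone. The model is the standard coarse-grained brush construction:

* **Geometry.** Periodic box 200 x 200 x 50 nm; 1–2 hard backbone
  cylinders (radius 5 nm) parallel to z; 31 graft sites per backbone per
  50 nm axial period. The nominal 1.6 nm graft interval does not tile a
  50 nm period, so sites are spaced uniformly at 50/31 ≈ 1.613 nm — the
  integer site count takes precedence. First beads sit on the cylinder
  surface at a seeded uniform azimuth and never move.
* **Arms.** One bead per residue, bead diameter = bond length = 0.6 nm.
  Tail lengths 143/510/606 beads for NfL/NfM/NfH with net charges
  −25/−43/−44 e (dephosphorylated), laid out as uniform-charge blocks in an
  editable TSV fixture. Phosphorylation adds −2 e at each designated KSP
  serine bead (0/13/44 sites for L/M/H). Real tail sequences are not
  block-uniform; the tables are explicit model inputs chosen to carry the
  right net charges and lengths, and every value is overridable.
* **Energies** (units of kT). Hard core between non-bonded beads and
  against backbone cylinders; Debye-Hueckel screened Coulomb
  u(r) = l_B z_i z_j exp(−κr)/r with Bjerrum length l_B = 0.714 nm and
  κ [nm⁻¹] = sqrt(I[M])/0.304 (κ⁻¹ ≈ 0.785 nm at the physiological
  I = 150 mM). Implicit salt, no explicit counterions — standard for this
  model class. Interactions are truncated at 6 nm (≈ 7.6 κ⁻¹, pair energy
  < 1e-3 kT), applied consistently in total and incremental energies.
* **Sampling.** Canonical Metropolis with bond-preserving single-bead
  moves: crankshaft rotations (uniform angle about the axis through the
  flanking beads) for interior beads, free cone rotations about a random
  axis through the neighbour for terminal beads; one attempted move per
  mobile bead per sweep. Both proposals are symmetric, so acceptance is
  min(1, exp(−ΔE)). Species per graft site are drawn from the configured
  NfL:NfM:NfH mixture; initial conformations are outward-biased
  self-avoiding walks. Coordinates are stored unwrapped (periodicity enters
  through the minimum-image convention only), so the radius of gyration
  R_g = sqrt(mean |r_i − r̄|²) is computed directly.

The kernel is numba-compiled; a full two-backbone system at default arm
lengths is ~19 000 beads and ~1.4 s/sweep on one core, so production-scale
runs are an explicit compute investment. Tests and the default pipeline
stage therefore run *length-scaled* systems: beads are aggregated by an
integer factor with block-summed charges, preserving each arm's net and
phospho charge exactly. The documented test scales are 0.25 (mixture
contrast and species-ordering checks: single backbone, 1000 + 1000 sweeps)
and 0.05–0.1 (bookkeeping, determinism, phosphorylation-response checks).
At these scales the model reproduces the qualitative structure of interest:
R_g(NfH) > R_g(NfM) > R_g(NfL); the NfL-rich adaptive mixture lowers mean
NfH extension while the NfL change stays within arm-level sampling error;
and added phospho charge extends NfM/NfH arms. Reduced-sweep runs are not
fully equilibrated (the driver warns when the mean R_g still drifts over
the last half of production); directional contrasts at matched conditions
are meaningful, absolute R_g values at these scales are not comparable to
full-length equilibrium values.

Validation anchors: with interactions disabled the sampler reproduces the
freely-jointed-chain closed form <R_g²> = b²(n²−1)/(6n) within Monte Carlo
error; incremental energy bookkeeping agrees with from-scratch recomputation
to 1e-6 kT over thousands of accepted moves; two isolated charged beads
reduce to the pair potential; trajectories are bit-reproducible under the
seed.

## Statistics

Normality is screened with Shapiro-Wilk at α = 0.05; two-group comparisons
use Welch's t (Gaussian) or the two-sided Mann-Whitney U; multi-group
comparisons report a one-way fixed-effects ANOVA F with (k−1, N−k) df
("GLM" — no covariate adjustment) together with Kruskal-Wallis H. Pairwise
post hoc contrasts run only when the omnibus ANOVA is significant, at the
Bonferroni threshold α/m (stored at full precision; p-values rounded
half-even to 4 decimals only in reports). Degrees of freedom are always the
package's own; printed F statistics from the original cohort are not
reconstructible without the patient-level data and are not asserted
anywhere. The U statistic is cross-checked in the suite against brute-force
pair counting, the F against the textbook mean-square ratio, and the
omnibus test's type-I error against its nominal 5% level by null
simulation.

## Pipeline and reproducibility

Stages run in the order simulate → calibrate → cost → brush → stats. Each
stochastic stage receives a sub-seed derived by SHA-256 hashing of
(global seed, stage name), so toggling one stage never perturbs another's
stream, and a (config, seed) pair yields a byte-identical `report.json`.
All physical constants live in one versioned table echoed into every
report. Design flags with no single defensible value (NfH channel mode,
luxury anchor) are logged in the report.

## Known limitations

* The generator models no age/sex/smoking structure and no assay noise
  beyond the log-normal spread; covariate-adjusted models are out of scope.
* The cost model covers translation only — no folding energetics,
  phosphorylation cost, transport, or compartmentalisation.
* The brush model's charge tables are block-uniform stand-ins for real tail
  sequences; no explicit counterions, no aggregate formation, no
  inter-filament free-energy analysis.
* Abstract-level ATP/hour figures from the motivating analysis are mutually
  inconsistent with the stated constants (5 ATP/aa, 25 s/100 aa); this
  package reports raw seconds/hours from the stated constants only and
  makes no attempt to reproduce cohort-level ATP means, whose construction
  depends on an unrecoverable counterfactual and unpublished raw data.
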