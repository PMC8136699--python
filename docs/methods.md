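# Methods

## The stage clock and cycle-length model

The seminiferous epithelium cycles through twelve stages (Roman numerals
I–XII, periodic: after XII comes I). Because every tubule cross-section moves
through the stages at the same speed, the relative frequency of a stage among
randomly sampled cross-sections equals the fraction of one cycle the stage
lasts. `StageFrequencyTable` therefore serves double duty: a composition of
the epithelium, and the time axis for kinetics (cumulative frequency =
elapsed fraction of one cycle, stage I start = 0).

A ³H-thymidine pulse labels S-phase cells; the most advanced labeled cohort
is the preleptotene/leptotene (Pl/L) spermatocyte generation, sitting at a
species-specific stage one hour after injection (stage VII in *A. cursor*,
IX in the other three species). During a chase the cohort advances
deterministically: its germ-cell class as a function of cycles elapsed is the
**germ-cell ladder**, packaged as data (`data/germ_cell_ladder.yaml`) rather
than code because the published source for it is a stage map read off a
figure. Rows tile stages I–XII per cycle: spermatocytes (cycle 0), pachytene
through meiosis (cycle 1), round spermatids (cycle 2 through stage VIII),
elongating/elongated spermatids until spermiation at stage VII of cycle 3.
Cycles traversed between two observations is the ladder-row difference plus
the difference of within-cycle positions; cycle length = chase / cycles.

**Boundary convention.** A published observation states only (cell class,
stage). The estimator's default places the cohort at the *end* of its stage
at both times; this is the convention that reproduces the published
*A. cursor* cycles-traversed values within ~2% ("start" and "midpoint" remain
configurable). An observation may instead carry an explicit
`within_stage_fraction`, giving sub-stage resolution: this reflects the
published measurement practice of locating the cohort within a stage by
pachytene nuclear size, and it is what the synthetic generator emits, making
generator → estimator round trips exact when the true frequencies are known.

**Which quantities cannot be reproduced exactly.** The published per-animal
cycles-traversed values were computed from per-animal stage frequencies that
were never published; with species-mean frequencies the estimate for
*A. cursor* is 2.378 against printed 2.33–2.37 (≤ 2.1%). Likewise several
printed species means are means of per-animal ratios, which differ by a few
percent from the same ratios recomputed from species-mean inputs; tests
assert those values at tolerances that reflect this, never exactly.

## Stereology

Volume densities are point-count fractions: seven mutually exclusive
parenchymal leaf components (tunica propria, seminiferous epithelium, lumen,
Leydig cells, blood vessels, lymphatic space, other); the tubular and
intertubular compartments are derived sums, so the hierarchy cannot
disagree with the leaves. The tunica albuginea is scored against the whole
testis and excluded from parenchyma.

Tubule length per gram takes 1 g of testis as 1/ρ cm³ with specific gravity
ρ = 1.0 by default (the conventional assumption for fresh testis; it
reproduces the published lengths and is configurable), removes the albuginea
fraction, multiplies by the tubular volume density and divides by π r² with
r from the mean diameter of round profiles. No shrinkage correction is
applied (none was applied to the reference data). Per-gram quantities use
whole-testis grams, matching the published table rows; the Leydig-number
calculation, by contrast, uses parenchymal (albuginea-subtracted) volume,
consistent with the density being a parenchymal fraction.

## Cell counts

The Abercrombie correction N·T/(T+D) converts profile counts per section of
thickness T into object counts, since a section intersects every object
whose centre lies within D/2 of it. Object diameters are inputs, not
constants: nuclear diameter for germ cells and nucleolar diameter for Sertoli
cells (counted by their single prominent nucleolus). Whether the published
analysis corrected Sertoli counts with nucleolar or nuclear diameter is not
stated; both are supported (`AnalysisConfig.sertoli_correction`) and the
choice is echoed into result metadata. Section thickness defaults to 4 µm,
the only thickness stated for the reference material; also configurable.

Ratios (meiotic index, Sertoli efficiency) are computed per animal and then
averaged across animals — never as ratios of averaged counts — because the
mean-of-ratios convention is what the reference tables report.

DSP uses the four-factor formula Sertoli/testis × efficiency × f(VIII) /
duration(VIII). Since duration(VIII) = f(VIII) × C in this framework, the
formula reduces exactly to Sertoli × efficiency / C; the identity is enforced
by a machine-precision test. Round spermatids stand in for final sperm
output, the standard assumption that spermiogenic loss is negligible.

## Stage classifier

Templates (packaged per species in `data/stage_templates.yaml`) carry the
published numeric descriptors: acrosome-angle mean ± SD for stages III–IX and
the spermatid-head "shortest:longest longitudinal axis" descriptor for X–XII
(stored verbatim as printed, values ≥ 1, without reinterpreting the
geometry), plus boolean flags — two spermatid generations before spermiation
(stages I–VII), acrosome vesicle absent (I) or present (II), nuclear
elongation from stage IX, meiotic figures only at XII. Flags filter the
candidate stages; the nearest surviving template in z-score units wins, with
ties (scores within 1e-9) resolved to the earlier stage and flagged.

At the printed SDs, adjacent angle templates overlap in places (e.g.
*N. lasiurus* III 41 ± 3° vs IV 44 ± 2°), so per-stage accuracy there is
intrinsically below 95%; the accuracy test asserts ≥ 95% in aggregate over
draws from the *A. cursor* frequency table, which the classifier exceeds
(~98%). Misclassification is confined to adjacent stages and roughly
symmetric, so recovered frequency tables stay within multinomial bands.

## Synthetic generator

The generator emulates each observation table with the minimal noise model
its sampling design implies — multinomial over 6,615 grid points and over
250 stage tallies, Poisson per-section stage-VIII counts inflated by
(T+D)/T so correction recovers truth, Gaussian calipered diameters, binomial
Leydig nucleus points — at the study's sample sizes (15 fields, 250 tubules,
10 sections, 30 profiles, 30 nuclei, 1,000 points). Label transport is
deterministic and noise-free. Packaged truths are the published species
means with between-animal SDs back-calculated as SEM·√n (n = 6, 9, 13, 11
animals). The per-section corrected stage-VIII counts are not published;
they are back-derived from Sertoli number per testis, tubule length and
section thickness (≈ 10.3 corrected nucleoli/section for *A. cursor*) and
the printed cell ratios. Unprinted object diameters use realistic defaults:
pachytene nucleus 10 µm, round-spermatid nucleus 6 µm, Sertoli nucleolus
2.5 µm.

What the generator does **not** emulate: histological artifacts (shrinkage,
oblique profiles, staining variation), between-animal variation of stage
frequencies beyond multinomial sampling (the printed SEMs cannot separate
the two sources, so only the sampling component is modelled), autoradiographic
grain statistics, or measurement error in body/testis mass. Passing recovery
tests therefore demonstrate correctness of the estimators under the stated
sampling noise, not robustness to histological artifacts.

At these settings, 500 replicate animals recover GSI exactly (mass is not
noised), tubule length within 5% and DSP within 10% in ≈100% of replicates,
and cycle length within 3% in ≈98% — the DSP error is small because the
Sertoli count cancels between the Sertoli-number and efficiency factors when
both come from the same sections, exactly as in a real per-animal analysis.

## Numerical conventions and degenerate inputs

* Frequencies/densities accepted in percent as printed, stored as fractions;
  normalization tolerance 1e-9, hierarchy tolerance 1e-6.
* Stage arithmetic is modular; ladder lookups are validated and a
  (class, stage) pair absent from the ladder is an error naming the pair.
* A chase extending past spermiation of the labeled cohort raises
  "cohort released" rather than wrapping around.
* Degenerate guards: zero cycles, zero denominators and non-positive
  dimensions raise `ValidationError`; a meiotic index above the theoretical
  yield of 4 warns; implausible GSI magnitudes warn of unit mismatch without
  silently converting.
* CSV round trips are bit-identical: integer-valued counts stay integers and
  floats are parsed with round-trip precision.

## Design choices that were genuinely open

* **Capsule handling in tubule length**: tubule volume excludes the
  albuginea. Including it changes *O. nigripes* from 35 to ≈ 37 m/g; the
  exclusive convention reproduces the published lengths.
* **Integer-cycle resolution** comes from the ladder's cell-class ordinals,
  not from minimising distance to a prior cycle length, mirroring how a
  labeled cohort's generation is identified morphologically.
* **Species mean cycle length** is the arithmetic mean of per-animal
  estimates (reproduces the published 8.42 d from 8.49 and 8.35).
* **Chase intervals** are stored net of the 1-hour baseline; the 1-hour
  anchor observation carries interval 0.
* **Sub-stage fractions** (above) make the synthetic round trip exact while
  leaving published-table analysis on the end-of-stage convention.

## Problem sizes in tests

The recovery suite uses 500 replicate animals at the study's own sample
sizes, 10,000 sections for the Abercrombie large-n check, 1,500 draws for
classifier confusion and 250 tubules for frequency recovery; the whole suite
runs in well under a minute on one core. These sizes give binomial standard
errors comfortably inside the asserted margins.
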