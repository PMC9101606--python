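# Methods

## The assessment model

`beescreen` models a deterministic reference consumer: one person of
body weight *bw* (default 70 kg) who takes the manufacturer's
recommended daily dose of a single supplement every day of the week.
For element concentration *c* (mg/kg) and dose *d* (g/day) the weekly
intake is

    I = c · (d / 1000) · 7        [mg/week per person]

All internal arithmetic stays in mg/week per person; µg is a display
convention only (Pb, Cd, As, Hg, Ni, Co, Se are conventionally reported
in µg/week, Cr, Fe, Cu, Zn in mg/week, at 2 and 3–4 decimals
respectively). No consumption-frequency or probabilistic exposure
modelling is attempted: the package screens a worst-plausible chronic
scenario, not a population distribution.

### Dose grammar

Label dose texts ("1 ampoule = 10 mL ≈ 10 g", "45 drops ≈ 1.35 g") are
parsed with a fixed precedence: an explicit gram amount (the last one
stated) wins over a millilitre amount (1 mL ≡ 1 g for these aqueous and
honey matrices) which wins over a drop count (1 drop ≡ 0.03 g). The
bundled register also stores the resolved grams/day explicitly, which
is authoritative over re-parsing; one register entry (FS-39) keeps its
verbatim label text while its stored grams/day reflects the dose its
published intake values were actually computed with.

### Censoring

Concentrations below the LOQ are left-censored. The default policy
substitutes the LOQ itself — the most conservative (intake-maximising)
choice for safety screening — with `half_loq` and `zero` available to
bound the sensitivity of any downstream number. LOQs are taken from the
censored cells themselves (Cd 0.006, Hg 0.007, Se 0.015 mg/kg in the
fixture); elements never censored carry no LOQ. In the bundled survey
44/51 Cd, 47/51 Hg and 41/51 Se cells are censored, so for these three
elements group statistics mostly reflect dose, not concentration.

## Guidance screening

Each element has one health-based weekly limit (PTWI/TWI/PMTWI/MTWI),
published in µg or mg per kg body weight per week. Two comparison modes
are deliberate:

- **faithful** (default): the per-person weekly mass, expressed in the
  guidance value's mass unit, is compared against the numeric value —
  e.g. a Ni intake of 21.35 µg/week is counted against "19.6 µg/kg
  bw/week" as if it were a 19.6 µg cut-off. This is unit-inconsistent
  but is the convention of the survey whose published counts this
  package reproduces, and it errs conservative by a factor of *bw*.
- **strict**: weekly mass / body weight against the limit in matching
  per-kg-bw units. Under this mode no fixture sample exceeds any
  guidance value.

Exceedance is strictly greater-than (a sample exactly at the limit does
not exceed), which is required for the fixture's borderline cells (As
3.15 > 3.0 exceeds; Cd 1.75 < 2.5 does not). Every report records its
mode. Total As is screened as measured; speciation (the organic, less
toxic fraction dominating) is outside the data.

## Group statistics

Five fixture samples belong to two market groups. Summaries and
comparisons deduplicate them with a per-group policy; the default —
keep shared samples in RG and PR, exclude them from HO — is the unique
policy that reproduces the survey's published HO means (As 3.10, Pb
6.22, Ni 14.79 µg/week on the 10 unshared honey samples) together with
its RG/PR means, and it also partitions the 51 samples so each enters a
comparison exactly once. Standard deviations are sample (n−1);
single-member groups have sd 0 by convention.

Comparisons are one-way ANOVA plus all-pairs Tukey HSD at α = 0.05 on
the intake scale, with Shapiro–Wilk (per group) and Levene diagnostics
attached but not gating — mirroring the source analysis, which applied
the parametric tests directly. No multiple-testing correction is
applied across elements, again matching the source. Zero-variance
input is flagged `degenerate` rather than raised.

Pearson correlations are computed on the weekly-intake basis by
default. This was an open choice — the source table does not state its
basis — and was settled empirically: all 45 published coefficients
reproduce to ±0.0015 on intakes with LOQ substitution, and do not on
concentrations. The concentration basis remains available. Pairs are
flagged significant at p < 0.001 (two-sided); constant columns yield
undefined (NaN) pairs, flagged, not raised.

## Min–max toxicological ranking

Six criteria carry per-element limits on the scale "mg per 70-kg person
per week" (BMDL01: Pb 0.245, As 0.3381; NOAEL: Hg 112.7; BMDL10: Cr
53.9; BMDL05: Cr 98; LOAEL: Co 490; DNEL: Cd 0.49, Ni 5.39, Se 2.107,
Fe 347.9, Cu 20.09, Zn 406.7). The Cr limits are nominally for Cr(VI)
but are applied to the measured total-Cr intake, as the published
ranking does. A sample's score for one element is

    score = clamp((L − x) / (L − x_min), 0, 1)

with x = bw_scale · I (bw_scale default 70), x_min the across-sample
minimum, L the limit; a criterion's score is the equal-weight mean over
its elements. Clamping is required: several fixture samples exceed the
BMDL01 limits outright and are printed as 0.000. When L ≤ x_min the
normalization is degenerate; with clamping on, any x ≥ L still scores
an unambiguous 0, otherwise the case raises.

Three conventions in `RankingConfig` were fixed by reverse-engineering
the published table and verifying every cell:

- **quantize_ug = 2**: intakes are expressed in µg/week and rounded
  half-up to 2 decimals before scoring. Scoring exact intakes leaves a
  handful of cells ~0.0015 off the published scores, and scoring the
  published display values misses others; the µg-at-2-decimals working
  precision is the single recipe that reproduces all 306 criterion
  cells to their printed precision. `None` scores exact intakes.
- **se_faithful = True**: the DNEL Se term is evaluated on the µg
  magnitude of the intake against the mg-scale limit 2.107. Every
  sample's Se term then saturates at 0 — under consistent mg units it
  would be ≈ 1 for all samples, contradicting the entire published
  DNEL column. Both modes ship and are named in every report.
- **bw_scale = 70** matches the limits' per-70-kg-person scale; scores
  are otherwise invariant to the µg/mg display convention.

The per-sample standard score (SS) is the mean over all 11 elements of
plain min–max ranks with configurable polarity (default: lower is
better; a constant column ranks 1 for all samples, with a warning). The
survey's published SS column could not be reproduced under any tested
polarity/basis combination, so SS is reported but never asserted
against the published values.

## Synthetic panels

The generator draws a latent Gaussian vector with a configurable
correlation matrix (default: constant 0.65 within the
Pb–Cd–As–Hg–Ni–Cr block, 0.8 for Se–Cu, 0 elsewhere; validated
symmetric PSD with unit diagonal before any draw) and maps it through
element-wise log-normal marginals with additive group shifts on the log
scale. Default parameters (`default_paper_like_config`) place medians
and spreads inside the fixture's measured ranges, use group sizes
15/26/10, censor Cd/Hg/Se at the fixture LOQs, and draw doses from a
catalogue of dosage forms with realistic gram ranges. Censored draws
are stored at the LOQ with the flag set, so synthetic and measured
panels share one code path.

What the generator does *not* emulate: measurement error and
triplicate averaging, the five dual-group memberships, dose texts
beyond "N g", and any fitted relationship to the fixture (no
likelihood fitting, by design). Passing pipeline tests on synthetic
panels therefore demonstrates structural correctness and statistical
behaviour under a known model, not agreement with real market data —
that is what the fixture golden tests are for.

Power guarantee: with a designed PR-vs-RG shift of −1.0 on log-Pb, the
dose held near-constant so the effect acts on the intake scale
(log-sigma 0.55 ⇒ raw-scale effect size ≈ 1.4), Tukey HSD at n = 30
per group detects the contrast in ≥ 80% of 200 seeded replicates; the
suite runs exactly this experiment.

## Numerical and engineering choices

- Golden comparisons against published tables use half-ulp tolerances
  of the printed precision (e.g. ±0.005 for 2-decimal µg values),
  never looser internal tolerances.
- Test problem sizes: oracle-equivalence checks run on 10–12-sample
  synthetic panels; correlation recovery on one 500-sample group;
  power on 200 replicates of 90 samples — sizes chosen so each check
  is statistically meaningful while the whole suite stays interactive.
- The pipeline writes deterministic bytes for a fixed manifest (the
  timestamp lives only in `manifest.json`), records the number of
  censored substitutions, and attributes any failure to its stage.
- CSV writers emit the canonical element order (Pb, Cd, As, Hg, Cr,
  Fe, Co, Ni, Cu, Zn, Se); round-tripping a panel through write + load
  is bit-exact.

## Known limitations

- The faithful screening mode is intentionally unit-inconsistent (see
  above); strict mode is the scientifically coherent reading.
- LOQ substitution biases censored elements' means upward and their
  correlations toward dose structure; the alternatives bound but do
  not remove this.
- Guidance values and criterion limits are a snapshot of the
  registries they were taken from, not a live feed.
- The SS recipe of the source survey is unresolved; only its criterion
  columns are reproduced.
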