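# Methods

## Problem setting

High-throughput screening (HTS) campaigns report, per chemical × assay
pair, either an AC50 (concentration of half-maximal activity) or an LEC
(lowest effective concentration), in µM, with inactive pairs encoded by
a 1 M (1e6 µM) sentinel. The package turns such matrices into a
vascular-disruption prioritization: a per-chemical vascular bioactivity
score (VBS), an above-mean classification into putative vascular
disruptor compounds (pVDCs), pathway-level perturbation scores, and
species-specific toxicity signatures fitted against prenatal rat/rabbit
endpoint labels.

## Vascular bioactivity score

Six target features drive the score, in descending influence: VEGFR2
down-regulation, TIE2 enzymatic inhibition, CCL2 down-regulation, PAI-1
up/down perturbation, CXCL10 up-regulation, and uPAR up/down
perturbation. Each assay potency `c` maps to a unit score

    s(c) = clip( log10(C_inactive / c) / log10(C_inactive / C_floor), 0, 1 )

so the inactive sentinel scores 0, potencies at or below `C_floor`
saturate at 1, and the score is monotone in potency. Defaults:
`C_inactive = 1e6 µM` (the sentinel itself), `C_floor = 1e-3 µM` (1 nM,
below any realistic screening hit, so real potencies almost never
saturate). A target's score aggregates its assays with `max` by
default — the most potent direction/platform speaks for the target,
which also makes the VBS invariant to padding a target with inactive
assays. `mean` aggregation is available for assay-level weighting.

The VBS is the weighted sum over targets. The weight vector is
configurable and constrained to be non-increasing in the stated target
order; the default `(6, 5, 4, 3, 2, 1)` is the simplest strictly
descending integer profile consistent with that ordering. The printed
per-chemical scores of the original campaign depended on a proprietary
23-assay weighting that is not recoverable, so absolute VBS values here
are on the package's own scale; rankings, the above-mean rule, and all
aggregate behavior are scale-faithful. The pVDC cutoff is the
arithmetic mean of the library's VBS values and the comparison is
inclusive (`vbs ≥ mean`): a chemical printed at VBS 1.49 against a 1.48
cutoff must classify as a pVDC.

ToxPi profiles re-express the per-target evidence radially: each
target's slice has angular width proportional to its weight and radius
equal to the target score divided by the per-target maximum over the
chemical set (an all-zero slice stays zero). Profiles are ordered by
VBS, ties alphabetical.

## Pathway perturbation scores

A chemical perturbs a pathway when it is active against at least
`min_targets = 5` distinct gene symbols mapped to the pathway; the
score is then the minimum potency (µM) over all hits on pathway-mapped
assays, otherwise it is undefined. Distinctness is counted at the gene
level, not the assay level, so multi-platform coverage of one gene
counts once toward the threshold (though all its hits feed the
minimum). AC50- and LEC-measured hits are treated alike, both for the
activity count and the minimum. For discriminant features, defined
scores pass through the same unit transform as assay potencies and
undefined scores enter as 0 (no perturbation evidence), which keeps the
feature matrix complete without imputation.

## Endpoint labeling

Endpoint records (chemical, species ∈ {rat, rabbit}, category, optional
LEL in mg/kg/day) validate against a controlled vocabulary of eleven
categories (embryo fetal loss, maternal pregnancy loss, fetal weight
reduction, general fetal pathology, skeletal: axial/appendicular/
cranial, urogenital: renal/ureteric, neurosensory: eye, trunk: body
wall), extensible by argument. Labeling is chemical-level: a chemical
is species-X-positive if it has any in-vocabulary record in species X,
and X-only if additionally negative in the other species. By default
maternal pregnancy loss counts toward positivity — its maternal versus
embryonic origin is ambiguous in guideline studies — and a category
restriction (`DIRECT_EMBRYO_CATEGORIES`) implements the stricter
direct-embryo-effect convention. Prevalence summaries count each
chemical once regardless of repeated records and report whole-percent
fractions.

## Stepwise LDA signatures

The two-class discriminant is Fisher's: `w = S_pooled⁻¹ (μ₁ − μ₀)` with
ridge `ε = 1e-6` added to the pooled-covariance diagonal (rejecting
subsets that stay singular), and an intercept that puts the boundary at
the midpoint of the projected class means (equal priors). Selection is
forward-only: at each step the feature maximizing mean held-out BA over
a fixed stratified 5-fold partition joins the model; ties break to the
lowest column index (which also deduplicates identical columns);
selection stops when the improvement drops to `ε` or `max_features`
(default 10) is reached. Fold assignment shuffles within class by a
seeded generator and deals round-robin, so results are bit-identical
for a fixed seed — re-running the fitted feature set does not change
any statistic, and a `stability_check` helper verifies this and reports
the BA standard deviation across re-seeded partitions.

Reported statistics: train BA (mean in-fold training BA), test BA
(pooled held-out midpoint-threshold predictions), best sensitivity and
specificity (at the threshold maximizing Youden's J on the pooled
held-out scores — "best" reads as an optimized operating point), and
the Mann–Whitney AUC of those scores (ties credited 0.5).

Selection and evaluation share one fold partition (single-level, not
nested cross-validation). This is optimistic under the null: simulation
at n = 60 with 20 noise features centers the selected model's held-out
BA near 0.68 rather than 0.5, because the selected subset is the
CV-maximizing one. Consumers comparing signature BAs against chance
should use a permutation baseline, not 0.5.

## Synthetic data generator

The generator emulates a phase-I-like campaign: 309 chemicals × 120
assays, twelve of which (two per target feature) carry the vascular
readouts, the rest background assays with synthetic gene annotations.
A planted 40% of chemicals are active, split evenly into two mechanism
groups; an active hits the shared core targets (VEGFR2, TIE2) with
probability 0.8 each, its own mechanism pair (PAS group: PAI-1, uPAR;
chemokine group: CCL2, CXCL10) with probability 0.9, the opposite pair
with probability 0.1, topped up at random to at least 3 of the 6
features. Hit potencies are log10-uniform on [0.1, 50] µM — the span of
screening-scale AC50s — and every remaining cell turns into a false hit
at rate 0.02 with the same potency law. Endpoints follow the mechanism
groups: PAS actives receive rabbit fetal-loss records with penetrance
0.85, chemokine actives rat skeletal records with penetrance 0.8, and
5% of penetrant chemicals gain a spurious cross-species record. All
draws flow from per-stage `numpy` generators keyed on the config seed,
so every artifact is bit-reproducible.

What the generator does and does not emulate: it reproduces the
sparsity, potency spread, mechanism-feature correlation structure and
species-linked label noise that the analysis assumes, but real
screening data add assay-family correlations, chemical-class clustering,
cytotoxicity burst effects and dose-spacing artifacts that are absent
here. Passing recovery tests therefore demonstrates that the pipeline's
logic recovers planted structure under its own assumptions, not that
the same operating characteristics hold on a real campaign.

## Problem sizes and numerical choices

The recovery checks average over ten generator seeds at the full
default size (309 × 120), which keeps the whole suite under a minute on
one core. Equality tests on the discriminant use direct matrix-inverse
oracles at 1e-10; score comparisons use exact arithmetic where the
computation is closed-form (unit scores, weighted sums at 1e-12).
Degenerate inputs are defined rather than special-cased: an all-inactive
chemical has VBS 0; an empty hit set reports an undefined mean; an
all-zero ToxPi slice renders with zero radius; identical class means
yield a ridge-scale discriminant and chance-level BA.

## Known limitations

- Absolute VBS values are package-scale, not the original campaign's
  printed scale; only orderings and aggregates are comparable.
- The pathway score's "minimum over mixed AC50/LEC values" treats the
  two potency kinds as interchangeable, as the source data convention
  does; no measure-specific calibration is attempted.
- Single-level CV selection (above) inflates null BA; the paper-style
  protocol is mirrored, not corrected.
- Literature ranking operates on user-supplied corpora at fixture
  scale; it implements the counting convention (document-level,
  case-insensitive, word-boundary, synonym-aware), not retrieval or
  entity recognition.
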