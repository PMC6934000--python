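# Methods

## Study design being modelled

The analysis takes the health-system-plus-patient perspective over a
one-year horizon with no discounting. The unit of analysis is the affected
eye; bilateral patients contribute two records treated as independent
(patient identifiers are provenance only — within-patient correlation is
not modelled, and nothing in the pipeline uses it). Two prescribing
strategies are compared: all glaucoma lines preservative-free versus
preservative-containing ("non-free"). An eye counts as preservative-free
only if *every* glaucoma line is; fixed-dose combinations are entered as one
line per active class, so mono- versus combination therapy is simply the
count of distinct lines.

## Disease control

Three tear-film tests are dichotomized: Schirmer test good when above
10 mm, total meiboscore (0–6, the sum of two per-eyelid 0–3 meiboscores)
good when below 3, non-invasive break-up time good when above 14 s.
Overall effectiveness requires good control on all three at once. Two
conventions are fixed here and exposed as configuration:

* **Boundary values are poor control.** The source tables define the bands
  only as "above"/"below", so the conservative reading is the default;
  `ControlThresholds(boundary_is_good=True)` gives the inclusive one.
* **TMS direction: below threshold = good.** The source text is internally
  inconsistent on this direction; the reading consistent with the reported
  counts (23 of 64 good at "below 3") is implemented.

## Costing

Yearly line cost = doses/day × 365 / doses-per-pack × pack price, rounded
to 0.01 BGN — continuous proration, matching the multiplicative definition
of the source; a `whole_packs` dispensing mode (packs started are paid in
full) is available since real dispensing rounds up. No leap-year handling.
Each eye is costed separately even when one bottle could in practice serve
both eyes. Artificial tears are carried on the record as a flag plus yearly
cost rather than being re-priced per drop.

The payer reimburses 50% of glaucoma therapy and none of the dry-eye
therapy. Money is reconciled largest-remainder style: the reimbursed share
is rounded half-up and the co-payment absorbs the remainder, so the split
always sums exactly (e.g. 321.77 → 160.89 + 160.88). At the reported cost
medians this yields a yearly co-payment of 340.81 BGN; the source rounds
the same quantity to 339 BGN (≈ ±2 BGN printing slack). All computation is
in BGN; € conversion (×0.51) is display-only.

Published registers list pack prices, not pack sizes, so the price-list
schema requires `doses_per_pack` explicitly. In the bundled example list
the two latanoprost pack prices (50.40 / 23.50 BGN) are register values;
every other price and all pack sizes are illustrative fixtures.

## Decision tree

Branch probabilities are plain proportions n(A)/n with no smoothing;
zero-count strata are pruned with a warning and siblings renormalized.
Leaf cost is the arithmetic mean of member-eye yearly cost (glaucoma +
dry-eye): the mean — rather than the median — makes the rolled-back
strategy cost equal the arm's cohort-average cost, which is the property
the tests verify. Leaf effect, in cohort-driven mode, is the proportion of
member eyes with good control on the selected test, so strategy-level
expected effect is a probability in [0, 1].

The published per-strategy effect values (3.52, 1.40, …) are in an
unstated unit and cannot be re-derived from any printed leaf-level data.
They are therefore handled in a separate *printed-values mode* that takes
the published per-strategy costs/effects and the published (rounded) deltas
as direct inputs and recomputes the ratios. Two arithmetic inconsistencies
in the published table are reproduced *as arithmetic*, not as targets: the
printed deltas give 644.46 where the table prints 644.49 (TMS), and the
NIBUT ICER cell prints 93.48 although its own printed deltas give
59.29/0.52 = 114.02. The abstract's 744/131 values likewise disagree with
the table; the table's deltas are treated as authoritative inputs. The
reported percentages 55/45 for 34/30 of 64 eyes (exact: 53.1/46.9) and
96.8% for 62/64 (exact half-up: 96.9) are further printing artefacts; this
package always reports exact half-up one-decimal percentages.

Roll-back is validated against an independent path-enumeration oracle
(explicit product of branch probabilities over every root-to-leaf path);
the two must agree to 1e−9, and property tests assert linearity in payoffs
and leaf-bound containment.

## ICER, dominance, thresholds

Deltas are comparator (preservative-free) minus reference (non-free),
matching the published sign convention. The ICER is undefined (reported
absent, verdict `not_applicable`) when ΔE = 0. Quadrants follow the signs
of (ΔE, ΔC); a zero ΔC with positive ΔE counts as (weak) dominance. In the
NW quadrant the comparator is dominated: the negative ST ICER is reported
with its quadrant rather than as a bare number, since a negative ratio is
meaningless as a price. Verdicts follow the WHO convention against GDP per
capita (default 15,226 BGN): below 1× highly cost-effective, up to and
including 3× (closed upper bound) cost-effective, above not cost-effective;
SE/NW short-circuit to dominant/dominated. In the SW quadrant the same
thresholds are applied to the reversed comparison (identical ratio), read
as the price of buying the forgone effect back.

## Sensitivity analysis

One-way deterministic perturbation of ±30% (configurable) of one quantity
at a time, all else at base, ICER recomputed at each endpoint; the base
model is never mutated (perturbation works on deep copies). The source
varied "cost and effect", so the default parameter set is all leaf costs
and effects; probabilities are excluded by default but supported — a
perturbed branch probability is clamped to [0, 1] and its siblings rescaled
proportionally to restore the sum to one. Tornado entries are sorted by
descending width |ICER_high − ICER_low| with ties (and undefined-endpoint
entries, which sort last) broken deterministically by parameter id. The
sign-flip scan uses 61 evenly spaced grid points over [−30%, +30%] (1%
steps) by default, walks outwards from zero (negative before positive at
equal magnitude), skips undefined points with a warning, and reports the
smallest flipping perturbation.

## Synthetic cohort generator

The generator's defaults are the observed study conditions: n = 64 eyes,
P(free) = 20/64, P(mono|free) = 14/20, P(mono|non-free) = 20/44,
monotherapy class weights 25:9:0:0 (PG:BB:CAI:A2A — CAI and A2A were never
prescribed alone), combination weights 6:8:5:2:9 over PG+BB, BB+CAI,
PG+CAI, CAI+A2A, PG+BB+CAI, marginal good-control probabilities 15/64,
23/64, 2/64, demographics by the reported sex/age/side/duration weights,
and yearly costs log-normal — chosen because costs are positive and
right-skewed — with (μ, σ) solved in closed form from the reported
(median, SD) anchors: 320.97 (133.18) free, 322.14 (203.76) non-free,
179.93 (9.36) dry-eye.

Given a sampled good/poor flag, each measurement is drawn uniformly from a
config-exposed interval strictly on the corresponding side of its
threshold (e.g. ST good → U(10.5, 20), poor → U(0, 9.5)), because only
dichotomized counts were reported; re-classifying a generated eye therefore
reproduces its sampled flags exactly. Dosing regimens are back-solved
against the price list so the costing pipeline returns each eye's sampled
cost to within a cent per line.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: correlation between the three tests is off by
default (only marginals were reported); the control rates are identical in
both arms in expectation, so any cohort-driven effect difference on
synthetic defaults is sampling noise (which is why the cohort-driven
demonstration reports expected costs, not an ICER); demographics are drawn
independently per eye, so within-patient eye pairing and any
age/severity/cost dependence are absent.

A separate deterministic **reference cohort**
(`glaucoma_cea.calibration.reference_cohort`) reproduces the reported
marginal counts exactly for tabulation checks. The split of monotherapy
classes and combination types across the two arms is not identified by the
marginals; one consistent completion is fixed (free arm: 10 PG + 4 BB
mono; combinations 2/1/1/0/2), and every marginal tabulation is invariant
to that choice. Its control flags are spread evenly over the cohort order
so they are not artificially confounded with therapy assignment.

## Problem sizes and tolerances

The validation suite uses cohorts of 50–1,000 eyes for counting oracles,
200 random trees (depth ≤ 4) for the roll-back/enumeration equivalence at
1e−9, and 100,000-eye draws for parameter recovery (probabilities within
4 binomial standard errors or ±0.01, cost medians within 5%). Money is
rounded half-up to 0.01 BGN throughout; probability sums are checked to
1e−9.

## Known limitations

One-year static tree: no disease progression, no incidence of dry eye
under preserved therapy (the decision question is conditional on DED
already being present), no intraocular-pressure modelling, no indirect
costs or quality-of-life weighting, no probabilistic sensitivity analysis,
and no multi-way strategy frontier (exactly two strategies exist). Effect
units differ between the cohort-driven mode (control probability) and the
printed-values mode (the source's unstated unit), so their ICERs are not
directly comparable.
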