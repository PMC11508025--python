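# Methods

## Community model

A community model joins member models through a shared medium compartment
`m`. Member reactions are namespaced `<member>__<reaction>`; each member
boundary reaction on an extracellular metabolite becomes a member exchange
`<member>__EX_<met>_m` whose coefficient on the shared metabolite is the
member's relative abundance `a_i`, so the medium row of the stoichiometric
matrix reads `sum_i a_i v_i^ex - v^m = 0`. Member-exchange bounds constrain
the abundance-scaled flux `a_i v` (the member's population-level exchange);
internal reaction bounds are per cell and are not abundance-scaled. One
community exchange `EX_<met>_m` per shared metabolite connects the pool to
the environment; its uptake bound comes from the growth-medium definition
and secretion is open. Member growth floors `mu_i_min` default to 0 —
they appear in the formulation but no value is prescribed for them, and a
zero floor is the weakest (least committal) choice.

Fluxes are carried in mmol·cell⁻¹·h⁻¹ throughout; no unit conversion layer
exists. Exchange reactions follow the COBRA sign convention (negative flux
is uptake). Bound constraints are implemented as non-strict inequalities:
LP optima lie on bounds, so strict inequalities are not representable.

## Two-stage cooperative trade-off

Stage 1 maximizes `sum_i a_i mu_i` as an LP (scipy's HiGHS). Stage 2
minimizes `sum_i mu_i^2` subject to the same polytope plus
`sum_i a_i mu_i >= alpha * mu_c`, solved as a single joint QP over all
fluxes (OSQP, tolerance ladder 1e-9 → 1e-7 with solution polishing; only
polished solutions are accepted). The default `alpha = 1.0` (full
cooperation) is a package choice and is recorded in every solution's
metadata, as are the solver names and feasibility tolerance (1e-8).

The member growth vector of stage 2 is unique (strict convexity in the
growths), but the supporting fluxes are not. Reported fluxes therefore pass
through a parsimony pass — minimize `sum |v|` with the member growths
pinned to the QP values (±1e-7) — and are labeled
`parsimony_tiebreak: true`. They are one optimal flux pattern, not the
unique one; any statement about individual exchange fluxes in this
documentation is a statement about that canonical pattern.

Knockout and essentiality scans re-optimize with the run's trade-off
configuration; at `alpha = 1` the quadratic stage cannot change community
growth (it only reallocates it), so scans evaluate the stage-1 LP directly
in that case, which keeps a ~200-reaction scan at a few milliseconds per
knockout.

## Context extraction

The extraction step turns per-reaction confidences (1 = low, 2 = medium,
3 = high) into a flux-consistent submodel. Every confidence-3 reaction that
can carry flux in the medium-constrained base model is a target. For each
target, an LP forces the target's flux and minimizes the penalty-weighted
total |flux| through not-yet-included confidence-1/2 reactions
(`penalty_low = 100`, `penalty_mid = 1`); costs are jittered by up to 10%
over `R = 5` seeded repetitions to reveal alternative supports, and every
penalized reaction used above the flux threshold (1e-4) in any repetition
is promoted. The forcing level is the larger of the flux threshold and 10%
of the target's attainable maximum: forcing at the bare threshold would
leave supporters with small stoichiometric coefficients (biomass precursors
at coefficients 0.1–0.5) below the promotion threshold and collapse the
support set. The run finishes with a flux-consistency prune (cobrapy's
fastcc). Reactions without a gene rule default to confidence 2, so
transporters with no expression evidence are neither forced in nor out;
medium exchanges and biomass are forced to 3.

Raising a reaction's confidence to 3 can only add it to the output (it
becomes a target); it may legitimately release other reactions that were
only ever included as its supports.

## Confidence scoring

Within one cell cluster, genes are grouped by agglomerative clustering
(Euclidean metric, average linkage, exactly 3 groups) of their
log-normalized expression vectors; groups ranked by mean expression map to
confidences 1/2/3. The feature space is library-size-normalized log counts
— a package choice where raw counts would also have been defensible.
Differential expression against all other cells uses the two-sided
Mann-Whitney test on raw counts with a pseudocount-1 fold change on raw
means; the rank test runs on the same raw scale as the fold change because
library-size normalization with small gene panels induces spurious shifts
in unchanged genes. Significant genes (FC >= 2, p <= 0.05) are forced to
confidence 3 (up) or 1 (down). P-values are deliberately uncorrected — the
stated threshold rule is a raw p-value rule — and an FDR switch is not
applied by default. GPR propagation uses AND → min, OR → max, the standard
context-extraction convention.

## Synthetic study system

The toy base network (~54 reactions, 48 metabolites, 52 genes including 20
expression-only decoys) carries full elemental formulas and charges;
every internal reaction except the biomass pseudo-reaction balances
elements and charge exactly, so the structural validator's mass-balance
fraction of 1.0 is a meaningful check, not a tautology. Energetics are
integer-simple and hand-checkable: galactose fermentation to lactate nets
2 ATP; full oxidation nets 28 ATP and 6 O2 (P/O = 2 lumped respiration);
the TCA cycle has no pyruvate carboxylase, so running it requires glutamine
anaplerosis. Glutamate dehydrogenase is oxidative-only (glu → akg):
allowing the reverse, reductive amination would give the network an
anaerobic NADH sink through an alanine shuttle and blur the designed
property that anaerobic growth strictly requires lactate fermentation.
Biomass consumes ATP, glucose-6-phosphate, glutamate and three uptaken
amino acids; glucose-6-phosphate can also be made from pyruvate or lactate
by lumped gluconeogenesis, which is what lets a lactate-consuming phenotype
grow without galactose.

The growth medium (`l15_like`) follows the qualitative composition of a
Leibovitz-style, galactose-based medium: galactose 0.05, pyruvate 0.01,
glutamine 0.02, amino acids 0.05 each, choline (present but transported by
nobody — a designed non-essential), oxygen 0.16, phosphate and water; no
glucose, and no lactate, alpha-ketoglutarate, fumarate, succinate,
ammonium or alanine, so any appearance of those in the shared medium is
attributable to the community. The galactose bound is set where oxygen
(0.16), not carbon, is the binding resource, which is what makes overflow
fermentation appear at the optimum. The normoxic per-cell oxygen transport
bound of 0.16 mmol·cell⁻¹·h⁻¹ is built into the base model's O2
transporter, which makes "all strata at normoxia" exactly equivalent to the
unstratified community.

Phenotype variants differ from the base only in bounds: the proliferative
variant caps respiration (OXPHOS <= 0.05 per cell — the Warburg trait) and
runs LDH forward-only; the invasive variant runs LDH in reverse only
(lactate consumer) with weak galactose entry (GALK <= 0.005); the
reservoir variant alone may export fumarate and ATP (hydrolysis-coupled
export of an extracellular ATP equivalent). These caps are what make the
lactate shuttle strictly optimal rather than merely degenerate: growth is
linear in ATP across members, so without member-specific caps the solver
is indifferent about who burns which carbon.

The expression generator emulates a three-cluster single-cell counts
matrix at toy scale (60 cells/cluster, 52 genes): negative-binomial counts
(dispersion 2.0) around lognormal per-gene baselines, each phenotype's
marker genes multiplied by the fold change (default 4) in its own cluster
and divided by it elsewhere (giving the three-tier structure the
confidence clustering expects), then Bernoulli dropout (default 10%). It
does **not** emulate transcriptome scale (tens of thousands of genes),
ambient RNA, doublets, batch effects, or imputation artifacts — so a
passing suite shows the pipeline's logic is correct on clean, designed
signal, not that the confidence calls would be robust on real single-cell
noise.

Two dedicated micro-fixtures exist for perturbation properties: an
obligate producer/consumer pair (consumer growth requires a metabolite
only the producer makes) and an oxygen-bypass model whose biomass
precursor is either imported or synthesized by an NAD-dependent oxidation,
making it medium-essential exactly under hypoxia. Both are synthetic
by construction and labeled as such.

## Spatial layering and oxygen sweep

The spheroid's radial oxygen profile is discretized into three strata with
per-cell uptake bounds outer 0.16 / middle 0.08 / inner 0.01; the outer
value is the normoxic bound, the middle and inner values are package
defaults logged with every result. All six member-to-stratum bijections
are enumerated (labels A–F in `itertools.permutations` order over the
member list) and ranked by trade-off growth; exhaustive enumeration is its
own oracle, and ties (inevitable with identical members) are flagged. Pure
one-member-per-stratum layers are a simplification; mixed-membership
layers and continuous diffusion gradients are out of scope.

The oxygen sweep instead tightens the *community-level* oxygen exchange —
the global availability — from 0.16 in 0.01 decrements down to anoxia,
16 scenarios after the separately stored baseline, each re-optimized
independently (warm starts would be legitimate for speed but are not used,
so no scenario's result depends on another's). With the day-6 community
this reproduces the qualitative oxygen-stress story: growth declines
monotonically; lactate consumption by the oxidative members persists into
deep hypoxia but shrinks with the oxygen needed to burn lactate; the
producer-side lactate flux of the shuttle strictly increases over the
interval where oxygen scarcity first redirects galactose from direct
oxidation into fermentation; and at anoxia the reservoir switches from
lactate consumer to producer. The increase lives on the producer side: in
a well-mixed linear community every consumer's lactate burn competes for
the same shrinking oxygen pool, so consumer-side uptake cannot rise as the
pool shrinks — a structural property of this model class, documented here
rather than hidden.

## Essentiality and supplementation

A knockout closes both bounds of one reaction; a medium knockout closes
one community exchange's uptake. The lethality criterion is configurable
because "growth reaches zero or falls below its optimum" admits two
readings: the default is absolute (growth < 1e-6), the alternative
fractional (growth < f × wild type, f = 0.01 by default); both are
reported with every table so either reading can be reproduced. Medium
essentiality is evaluated under three oxygen scenarios reusing the stratum
defaults (normoxia 0.16 / mid 0.08 / hypoxia 0.01) applied at the
community oxygen exchange. Supplementation opens one community uptake and
is a pure relaxation, so growth can only rise; the tests assert this at
the 1e-6 solution tolerance rather than machine precision because the two
sides come from separate QP solves.

## Cross-feeding reports

Exchange classification uses the `EX_<met>_m` naming convention and a flux
direction tolerance of 1e-6, reported with every table. An edge exists for
each (producer, consumer) pair of one shared metabolite; edge fluxes are
abundance-scaled and come from the parsimony tie-break solution. "Top 20"
truncation is presentation-only and never applied before edge detection.
The Boolean state matrix across named conditions classifies
member-metabolite pairs as always-consumed, always-secreted, or switching;
with a single condition the switching class is empty by construction.
Because trade-off fluxes are degenerate, low-flux switching calls are
solver-dependent; the shipped tests only assert calls backed by designed
mechanisms (the reservoir's anoxic lactate switch).

## Numerical choices

- LP: scipy `linprog(method="highs")`; QP: OSQP with polishing; both
  deterministic for a fixed problem, so all pipeline randomness lives in
  two seeds (expression generation, extraction cost jitter).
- Solution-level invariants (growth identity, medium mass balance,
  `S v = 0`) hold to 1e-6; solver feasibility tolerances are 1e-8.
- Absolute-value objectives (parsimony, extraction support) use the
  standard flux-splitting LP formulation.
- Degenerate inputs: a constant expression matrix falls back to an
  all-medium-confidence tertile split with a warning; fewer than three
  distinct gene profiles is an error; an infeasible extraction reports the
  biomass precursors that cannot be produced; infeasible sweep scenarios
  are recorded and skipped, not fatal.
- Problem sizes throughout (≤ 60-reaction members, ≤ ~200-reaction
  communities, 16-scenario sweeps, tens of knockouts) were chosen so the
  full analysis and test suite complete in minutes on one CPU while every
  designed property remains hand-checkable.

## Known limitations

- The synthetic system is a designed caricature: its cross-feeding edges
  and essentiality lists validate the machinery, not any real cell line's
  metabolism. Numbers from genome-scale reconstructions will differ.
- Reported fluxes are one member of the optimal set; only member growth
  rates are unique. A flux-variability bound per edge would tighten this
  and is a natural extension.
- The community is well-mixed within each oxygen stratum; no diffusion,
  no dynamic (time-course) simulation, no abundance dynamics.
- Gene-level (GPR-aware) deletions and double knockouts are not
  implemented; knockouts are per reaction.
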