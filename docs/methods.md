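# Methods

## Data model

An information system is a table of formulations (objects) × condition
attributes with one decision attribute.  Class labels are ordinal with
class 1 best: class 1 = release profile preserved (f2 ≥ 50), class 2 =
changed.  The "at least class t" (upward) union therefore contains the
labels ≤ t and the "at most class t" (downward) union the labels ≥ t;
with two classes the non-trivial unions are exactly {class 1} and
{class 2}.

The f2 cut is a sharp ≥ 50 comparison on double-precision values, no
tolerance band.  The raw f2 column is retained as metadata after
discretization but never enters the condition attributes.

Nominal attributes (coating polymer) are replaced by one 0/1 attribute
per domain value (`Coating_1` = Eudragit NE, `Coating_2` = ethyl
cellulose, `Coating_3` = shellac); exactly one is 1 per object, and the
arg-max of the binaries reconstructs the original value.  The raw
nominal column is dropped rather than kept alongside its binaries, since
rules only ever reference the binaries.

**Two-copy transformation.**  Whether larger or smaller values of an
attribute favour class 1 is not known a priori, so every attribute of
undeclared preference is declared twice: a gain copy (≥/> conditions)
and a cost copy (≤/<).  The copies are attribute *declarations* sharing
one value column — the object × value grid is untouched, which makes the
transformation non-invasive by construction.  A consequence worth
stating explicitly: with both copies present, object x weakly dominates
y only when x equals y on that attribute, so on a fully two-copied table
the dominance relation reduces to per-attribute equality and the rough
approximations coincide with classical indiscernibility-based ones.
With declared preference directions (as the synthetic generator
provides) the full dominance machinery is exercised.

## Rough approximations

Dominating cone of x = {y : y weakly dominates x}; dominated cone dual;
ties resolve by weak inequality, so both cones contain x.  For an upward
union U: lower approximation = {x : dominating cone(x) ⊆ U}, upper =
{x : dominated cone(x) ∩ U ≠ ∅}; the downward case is dual.  Quality of
classification γ = fraction of objects outside every union boundary;
γ = 1 exactly when no dominance-inconsistent pair exists.

Object consistency (used by VC-bagging) is the fraction of the object's
relevant cone lying inside its own class union — an ε-consistency-style
measure in [0, 1], 1 for fully consistent objects.

## Rule induction

Sequential covering in the DomLEM family.  For one union at consistency
threshold θ (default 1.0, i.e. certain rules):

1. the positive region is the set of union members whose cone
   consistency is ≥ θ (at θ = 1 this is the lower approximation);
2. a rule is grown one elementary condition at a time; candidate
   conditions live on the observed-value grid of each admissible copy
   (≥ on gain copies and ≤ on cost copies for an upward union; swapped
   for a downward one).  The greedy choice maximizes precision toward
   the still-uncovered positives, ties broken by absolute covered count,
   then by candidate order (deterministic);
3. growth stops when the rule's covered set reaches confidence ≥ θ with
   respect to the union.  Because premises are dominance-monotone, a
   confidence-1 rule automatically avoids every boundary object;
4. the premise is pruned to minimality (no single condition droppable
   without breaking admissibility), then each numeric threshold is
   relaxed to the most permissive observed value that keeps the rule
   admissible.  The relaxation matters: greedy growth overshoots toward
   the pure extreme of an attribute, and walking the threshold back to
   the empirical class boundary is what makes planted thresholds
   recoverable to within one observed-grid step and markedly reduces
   rule-set fragmentation;
5. covered positives are removed and induction repeats until the
   positive region is covered.  Objects not separable at θ (identical
   descriptions across classes) are dropped from the target set with a
   warning; an empty positive region yields an empty rule set with a
   warning.

Rule metrics: support = |matching E ∧ H|, strength = support/|U|
(displayed truncated — not rounded — to 4 decimals, matching the
convention of the published rule tables, where support 32 of 180 prints
as 0.1777), confidence = support/|matching E|, and a Bayesian
confirmation measure from the 2×2 premise × conclusion contingency.
Four measures are implemented — s (difference of conditionals, default),
c (Carnap), f (Kemeny–Oppenheim), l (log-likelihood ratio) — all
positive under association, zero under independence, negative under
anti-association, NaN on degenerate margins.  The published rule tables
print confirmation values of 0.65–0.75 without identifying the measure,
so no attempt is made to reproduce that column numerically; the
implemented measures are instead held to their defining sign/zero
properties.  "Strongest rules" reports sort by confirmation descending,
then support descending.

## Ensembles and evaluation

**VC-bagging.**  Each bag is a bootstrap sample of size n drawn with
replacement with inclusion probabilities proportional to object
consistency, so boundary objects enter fewer bags; rules are induced per
bag for both unions.  Bags that degenerate to a single class are skipped
with a warning.  The bag count defaults to 30 (configurable; the
published analysis does not state its own), and `bootstrap=False` with
one bag reduces exactly to plain induction.

**Classification.**  All rules with satisfied premises vote for their
conclusion union, weighted by training strength; no match falls back to
the training-majority class; vote ties go to class 2 — the conservative
call, predicting a changed release profile.  Predictions are invariant
to rule order.

**Cross-validation.**  k-fold stratified CV (default k = 5) repeated R
times (default 100), folds built by seeded `StratifiedKFold`
(class proportions within one object per fold).  The report carries
per-repeat/per-fold counts and the summary quantities of the published
CV table: average correctly/incorrectly classified objects, average
accuracy % and average precision % (macro over the two classes; micro
available).  All randomness flows from a single root seed through
deterministic counters, so identical seeds reproduce bit-identically.

**Attribute relevance.**  Every (rule, object) pair with satisfied
premise is a suggestion event, correct when the object's class lies in
the rule's conclusion.  Per attribute the score is
P(correct | attribute in premise) − P(correct | attribute absent) over
all events, aggregated across the supplied ensembles — it rises both
when rules involving the attribute suggest correctly and when rules
omitting it suggest incorrectly.  Attributes appearing in no rule score
NaN (not applicable).  Rankings stabilize noticeably when aggregated
over several independently seeded ensembles, which is how the relevance
API is intended to be used.

## Synthetic generator

Emulates the study conditions: 180 formulations; coating ∈ {1, 2, 3},
press ∈ {1, 2}, force ∈ {6, 12, 18} kN; tablet mass, hardness, crushing
strength and friability uniform within the study's printed ranges
(516–568 mg, 11–297 N, 11–619 ×10⁴ N/m², 0–10.1%); mutually exclusive
Avicel grades and a one-filler-at-a-time one-hot pattern mirroring the
printed design; disintegrant present in 80% of formulations.  The true
class is 1 iff any planted monotone class-1 rule fires; the defaults
mirror the discovered structure (Eudragit coating ∧ force ≥ 12 ∧
hardness ≥ 42.4 → class 1; non-EC coating ∧ crushing strength ≥ 180.8 →
class 1).  Observed labels then flip at the inconsistency rate (default
0.10, a realistic level of partial inconsistency for process data of
this kind), split as evenly as class sizes allow so stratification stays
meaningful; exactly `round(rate·n)` labels flip and ground truth is
returned separately.

What passing tests on this generator do *not* show: attributes are
drawn independently, so the hardness–force–crushing correlations of
real tablets are absent, and label noise is symmetric whereas real
inconsistency concentrates near the class boundary.  Results on
synthetic data therefore bound the machinery, not the chemistry.

Dissolution-profile pairs are constructed by inverting the f2 formula:
a saturating reference curve over six hourly points minus per-point
offsets whose mean square is renormalized to the exact value solving
f2 = target, so realized f2 hits each target to machine precision
(construction tolerance 0.5 is never approached).  Targets whose
required offset cannot fit between 0 and 100% dissolved raise an error.

## Problem sizes and numerical choices

The test suite and acceptance script run CV at 1–5 repeats with 5–10
bags and n = 60–600; these sizes were chosen so the full suite completes
in about a minute while every statistical claim retains a comfortable
margin, and the pipeline defaults (100 repeats, 30 bags) remain the
recommended settings for a real analysis.  Consistency comparisons use
an absolute guard of 1e-12; strength truncation adds 1e-12 before
flooring to absorb binary-representation error (so 0.2 prints 0.2000,
not 0.1999).  Seeds derived from the root seed stay below 2³¹.

## Known limitations and red checks

Only a 20-formulation excerpt of the 180-formulation information system
is publicly printed.  Two acceptance tests — recomputing printed rule
supports (46, 42) and the published VC-bagging CV accuracy (82.72%) on
the full system — fail on their explicit size precondition and will stay
red until the complete table is available; the same checks pass in
excerpt-sized or synthetic form where a hand-derivable ground truth
exists.  The published record also does not identify its confirmation
measure, VC sampling weights or bag count; the choices made here
(measure s by default, consistency-proportional weights, 30 bags) are
documented package defaults, not reproductions.
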