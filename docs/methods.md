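# Methods

## The quantity under study

A gene's translation is summarised by the parameters `L, x, g, w, m, I,
E, e, b` (see the table in `coregulation.params`), the derived total
production `B = b·x`, externally measured protein abundance `A`, and the
protein production rate

```
R = x · b / m = x / I        (since b = m / I under transcriptional steady state)
```

in proteins per second. The steady-state assumption is that matured
transcripts appear in the cytoplasm at the same rate they are degraded, so
a transcript pool of size `x` initiating one translation every `I`
seconds yields `x/I` proteins per second. The `x/I` form is used for
derivation because `b` and `m` are typically available only for a subset
of genes; `check_rate_consistency` reports the relative deviation of the
two forms where all four inputs exist (it is advisory only — how genes
with `I` present but `m` absent should enter such a check is
underdetermined, so no hard failure is attached).

Missing values are never imputed and never treated as zero: every
analysis first restricts an interaction set to the pairs whose *both*
partners carry the parameter being analysed (`restrict_to_analyzable`),
and every output row records the resulting `n`. Units are taken at face
value; all downstream statistics are rank- or ratio-based and therefore
invariant to common scale factors.

## Pair statistics

The observational unit is an unordered heterodimeric protein pair.
Homodimers are excluded everywhere (a self-pair is perfectly
"co-regulated" by construction and carries no information), and pairs are
stored canonically (smaller identifier first) so duplicates collapse.
Because partner order is arbitrary, the default orientation policy flips
each pair by an independent fair coin (seeded); fold-change statistics
are provably orientation-invariant, and the Spearman correlation of a
symmetrically oriented sample estimates a symmetric population quantity.

* **Correlation.** Spearman's ρ with average ranks for ties. The default
  95% CI is the Fisher z-transform with the Bonett–Wright standard error
  `sqrt((1 + ρ²/2)/(n−3))`. The plain Pearson-style error `1/sqrt(n−3)`
  is selectable but measurably undercovers for rank correlations: in a
  Monte-Carlo experiment (bivariate normal, Pearson ρ = 0.4, n = 200,
  1000 replicates) the Zou difference interval built from plain-Fisher
  CIs covered the true zero difference 92.7% of the time versus 94.9%
  with Bonett–Wright; the suite enforces the latter calibration.
* **Correlation differences.** Zou's (2007) asymmetric interval,
  constructed from each correlation's own CI endpoints. It degenerates to
  a shifted copy of the wider group's CI when the other group's interval
  collapses, which the tests check explicitly.
* **Fold change.** `max/min ≥ 1` per pair; medians are compared across
  sets. The log ratio (no numerator restriction) is symmetric about zero
  and its sd is the second tightness measure. The log base is natural and
  recorded in outputs, since an sd of logs scales with the base. CIs come
  from a 2000-resample bootstrap over pairs (pairs, not proteins, are the
  sampling unit), by normal approximation (point ± z·sd of replicates,
  the default) or percentile; differences between sets resample both
  groups independently, and both orderings of the two control sets are
  reported because neither is privileged.
* **No p-values.** All inference is by interval estimates.

## Null models

* `sample_random_pairs`: distinct random pairs from the analysis
  universe, drawn with replacement and rejected if homodimeric, already
  drawn, or present in any real set, until the target count (default
  3000) accumulates; when the target exceeds half the feasible pairs the
  feasible set is enumerated and sampled without replacement instead
  (identical distribution, guaranteed termination).
* `shuffle_interactome`: a uniform random permutation of node labels — a
  graph isomorphism onto relabelled nodes, so edge count and the exact
  degree multiset are preserved while protein identity is randomized.
  This is the control for the scale-free topology that random pairs lack.
* `shuffle_operons`: the pooled operon membership is permuted and
  re-sliced to the original group sizes, then expanded to pairs.
* `hub_matched_controls`: for each hub carrying the analysis parameter,
  as many random partners (without replacement) as it has analyzable
  neighbours in the real network. True partners are *not* excluded from
  the candidate pool — the matching is on sample size, not on avoiding
  overlap — and collisions are logged.

All randomized operations take explicit integer seeds; derived seeds are
produced from a root seed via `SeedSequence` keyed by CRC32 of a
component path, so results are reproducible across processes regardless
of hash randomization.

## The synthetic world

The generator emulates the *statistical* structure of translational
parameters joined to an interactome, not the mechanistic translation
model that produces such parameters.

* **Marginals** are log-normal (all parameters are positive and
  heavy-tailed; genome-wide `R` spans orders of magnitude). Default
  log-scale locations/scales are round numbers of the right order for a
  yeast-like cell: `x ~ exp(N(log 5, 1.2²))` transcripts, `I ~
  exp(N(log 300, 0.8²))` s, `m ~ exp(N(log 1200, 0.7²))` s, `e ~
  exp(N(log 0.06, 0.3²))` s/codon, `L ~ exp(N(log 400, 0.6²))` codons
  (rounded, ≥ 1), `g ~ exp(N(log 0.8, 0.5²))` ribosomes/100 codons,
  `A ~ exp(N(log 2000, 1.5²))` molecules. The derived identities hold
  exactly: `b = m/I`, `E = e·L`, `w = g·L/100`, so the table is
  internally coherent and the two `R` formulas agree to machine
  precision.
* **Planted correlation.** For each *planted* parameter `p` (default
  `x, I, A, e`) and single-complex member `i` of complex `c`:
  `log p_i = μ_p + σ_p(√ρ_c·Z_c + √ρ_b·Y_k + c_i·ε_i)` with independent
  standard-normal complex factors `Z_c` (per parameter), binary-pair
  factors `Y_k`, and `c_i` chosen so the variance is `σ_p²`. Within-pair
  latent Pearson correlation is exactly `ρ_c` (complex) or `ρ_b`
  (binary), requiring `ρ_c + ρ_b ≤ 1`; the observable within-pair
  Spearman is the bivariate-normal closed form `(6/π)·arcsin(ρ/2)` —
  0.582 at the default `ρ_c = 0.6`, 0.288 at `ρ_b = 0.3`. Since `x` and
  `I` use independent complex factors, `log R = log x − log I` inherits
  the planted correlation exactly. Unplanted parameters are independent
  noise, so the pipeline can be checked for *absence* of spurious signal.
* **Binary edges** connect members of different complexes, at most one
  edge per protein, so the planted binary correlation is not confounded
  by shared complex factors.
* **Operons** are disjoint groups whose members copy a single drawn `x`
  and `m` verbatim (one polycistronic transcript); other parameters are
  independent. Intra-operon Spearman for `x` is therefore 1 by
  construction — the positive control bounding detectable co-regulation.
* **Hubs.** Party hubs are extra proteins appended to one large complex
  each (high degree inside a module, co-regulated with partners at
  `ρ_c`); date hubs join three complexes with independent latents (high
  degree spread across modules, uncorrelated with partners). Date-hub
  edges enter the co-complex expansion, realistically diluting the
  average co-complex correlation below the planted value.
* **Coverage thinning.** `m` and `b` are jointly removed for a quarter of
  genes, and abundance `A` is written for 70% of genes, emulating the
  partial coverage of real sources; the analyzability funnel is thereby
  exercised on every run.
* **Default scale** mirrors a yeast-sized study: 600 complexes with a
  truncated power-law size distribution (3–12, exponent 2.5; the
  exponent approximates scale-free degree structure and is a knob, not a
  claim), ~8–9k co-complex pairs, 1000 binary edges, 400 operons (sizes
  1–8), 108 party and 91 date hubs, 600 additional unattached proteins,
  3000 random control pairs, 2000 bootstrap resamples.

What the generator does **not** emulate: mechanistic coupling between
parameters beyond the identities above, measurement error structure of
any particular experimental platform, overlapping complex membership for
non-hub proteins, correlated missingness, and the false-positive/negative
profile of real interactome screens. Passing tests therefore demonstrate
that the *pipeline* recovers structure that is present and reports none
where there is none — not that any particular biological dataset has that
structure.

## Numerical and degenerate-input choices

* Ties get average ranks (matters for operons, where `x` is identical
  within a group yet ρ across operon pairs is well defined and equals 1).
* At |ρ| = 1 the z-transform is unbounded; the analytic CI degenerates
  onto the boundary and is clamped to bracket the estimate.
* Analytic CIs require n ≥ 4; a zero-variance margin is a hard error.
* Bootstrap replicates of a correlation that are degenerate (a resample
  with a constant margin) are dropped from the percentile interval.
* Random-pair feasibility is checked exactly (`C(|U|,2)` minus exclusions
  restricted to the universe) before sampling; infeasible targets report
  the maximum.
* File round-trips are exact: parameter cells are written with pandas'
  shortest-repr float formatting and parsed back with Python's `float`,
  which inverts it bit-for-bit (the default pandas fast parser does not).
* Model-level seeds: the orientation, control and bootstrap seeds of
  every output row derive from user-visible root seeds; all are recorded
  in provenance notes and the run manifest.

## Problem sizes used by the test suite

Statistical tests run at sizes chosen so Monte-Carlo error is small
relative to the asserted tolerances: planted-correlation recovery on
8000 independent dimer pairs (size-2 complexes make pairs independent, so
closed-form sampling theory applies without cluster corrections), CI
calibration over 40 replicate worlds of 5000 pairs, fold-change closed
forms at 10 000 pairs with 3-SE bands computed by the delta method,
bootstrap coverage over 500 simulations of n = 400, Zou coverage over
1000 replicates of n = 200 pairs of samples, and ordering recovery over
100 seeded default worlds. Coverage properties are asserted as
frequencies over replicates rather than single draws, since one 95%
interval either covering or missing a constant is a Bernoulli(0.95)
event by design.

## Known limitations

* The Bonett–Wright/Zou combination is asymptotic; for very small hub
  classes (n of a few dozen) the intervals are approximate and the
  pipeline reports them with their n so readers can judge.
* The correlation survey treats pairs as exchangeable; proteins appearing
  in many pairs induce dependence that the CIs ignore (the same is true
  of the analysis design being reproduced). The dimer-world tests
  quantify calibration exactly in the independent case only.
* `B = b·x` ignores degradation and is not an abundance estimate; `A` is
  the abundance quantity.
* The binary/co-complex distinction carries no mechanism here: the
  generator plants weaker correlation on binary edges by fiat, with the
  default `ρ_b = ρ_c/2` expressing only the qualitative ordering.
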