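# coregulation

Quantitative analysis of **translational co-regulation among interacting
proteins**: do the subunits of stable protein complexes (and other
interaction partners) get produced at concerted rates?

Most co-expression analyses of interactomes use mRNA abundance alone and
therefore see mainly transcriptional control. This package instead works
with per-gene **translational parameters** — transcript abundance *x*,
transcript lifetime *m*, translation initiation time *I*, elongation times
*E* and *e*, ribosome loading *g* and *w*, per-transcript protein yield
*b* — and two derived quantities:

* the **protein production rate** `R = x / I` (proteins per second per
  gene, from the transcriptional steady-state identity `R = x·b/m` with
  `b = m/I`), and
* the **total production** `B = b·x`,

plus externally measured protein abundance *A*. For each interaction set
(co-complex pairs expanded from complex membership, binary pairs, operon
pairs, and matched null controls) it asks how tightly each parameter
agrees within pairs.

## Statistics

For unordered pairs (partner order is arbitrary and randomized):

* **Spearman rank correlation** ρ between first and second partners, with
  a 95% CI from the Fisher z-transform using the Bonett–Wright standard
  error `sqrt((1 + ρ²/2)/(n−3))` (plain Fisher `1/sqrt(n−3)` and a pair
  bootstrap are selectable).
* **Zou (2007) interval** for the difference of two independent
  correlations: with CIs `(l₁,u₁)`, `(l₂,u₂)` around `r₁`, `r₂`,
  `L = r₁−r₂ − sqrt((r₁−l₁)² + (u₂−r₂)²)`,
  `U = r₁−r₂ + sqrt((u₁−r₁)² + (r₂−l₂)²)`.
* **Fold change** `max(v₁,v₂)/min(v₁,v₂) ≥ 1` per pair; its median and
  the standard deviation of the (unrestricted) log ratio are tightness
  measures, with 2000-resample bootstrap CIs (normal approximation or
  percentile) for each and for between-set differences.

Null models: 3000 random pairs excluding all real interactions and
homodimers; a **label-shuffled interactome** that keeps the network
topology (exact degree multiset) while randomizing protein identity;
shuffled operons; and degree-matched random partner sets for party/date
hubs. Interval estimates only — no p-values.

Because the real parameter tables and interactome databases are external
downloads, the package ships a **synthetic-world generator** with planted,
ground-truth co-regulation (log-normal marginals, latent per-complex
factors, polycistronic operons sharing *x* and *m* exactly, party hubs
inside one module and date hubs across modules) in the same on-disk
formats the readers consume. See `docs/methods.md`.

## Worked example

```python
from coregulation import CoregulationModel, WorldConfig, simulate_world

world = simulate_world(WorldConfig(seed=7))          # planted rho: 0.6 / 0.3
model = CoregulationModel.from_world(world, parameters=("x", "R", "m"))
model.add_controls(n_random=3000, seed=8)

survey = model.fit(seed=9)
print(survey.summary())
```

```
Spearman correlation of translational parameters within pairs
confidence level: 95%   orientation seed: 9

       set parameter    n    rho ci_low ci_high
co-complex         x 8429  0.534  0.518   0.551
co-complex         R 8429  0.519  0.502   0.535
co-complex         m 4701 -0.017 -0.045   0.012
    binary         x 1000  0.242  0.182   0.300
    binary         R 1000  0.233  0.172   0.291
    binary         m  558 -0.025 -0.107   0.059
    operon         x  673  1.000  1.000   1.000
    operon         R  673  0.656  0.605   0.701
    operon         m  372  1.000  1.000   1.000
    random         x 3000 -0.010 -0.046   0.025
    random         R 3000 -0.015 -0.051   0.021
    random         m 1634  0.009 -0.039   0.058
  shuffled         x 8429 -0.001 -0.022   0.021
  shuffled         R 8429 -0.001 -0.022   0.021
  shuffled         m 4818 -0.004 -0.032   0.024
```

Reading the table: the planted parameters (*x*, and *R* through `x/I`)
correlate strongly within co-complex pairs, weakly within binary pairs
and not at all in either control; *m* carries no planted signal and is
flat everywhere except operons, whose members share one polycistronic
transcript (ρ = 1 for *x* and *m*). Continuing:

```python
diff = survey.difference("co-complex", "random", "R")
fc = model.fit_fold_change(parameter="R", reps=2000, seed=10)
```

prints (via the obvious f-strings)

```
co-complex minus random (R): 0.534 [0.495, 0.574]
co-complex median fold change: 2.51 [2.45, 2.56]
random     median fold change: 4.00 [3.77, 4.22]
```

i.e. within a typical synthetic co-complex pair one partner's production
rate is ~2.5× the other's, versus ~4× for random pairs — the fold-change
gap that quantifies co-regulation tightness.

A CLI mirrors the library (`coregulation simulate | derive | pairs |
controls | correlate | foldchange | hubs | profile | run-all`) driven by a
YAML config; `run-all` writes tidy CSVs plus a JSON run manifest, and
reruns with the same config are byte-identical.

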