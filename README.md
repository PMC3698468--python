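# phyloherbivory

Community-phylogenetic analysis of plant herbivory: does the amount of
evolutionary history in a plant community — not just its species count —
predict how much leaf damage the community sustains?

The package is for ecologists analysing plot-based herbivory surveys.
It takes a dated community phylogeny (Newick), a plot × species
abundance table (0–4 quadrat scores) and per-plant leaf-damage counts,
and produces: abundance-weighted phylogenetic diversity (PSE) per plot,
a fitted binomial mixed model of damage with crossed species/plot/
observation random effects, species- and plot-level damage estimates,
the fitted richness-by-diversity response surface, and parametric
bootstrap p-values for the fixed effects.  A synthetic-study generator
with known ground truth makes every stage testable end to end.

## The model

Phylogenetic Species Evenness for a plot with abundances `m` over the
Brownian correlation matrix `C` of the present species
(`N = Σmᵢ`, `m̄ = N/n`):

    PSE = (N Σᵢ mᵢ Cᵢᵢ − mᵀCm) / (N² − N m̄)   ∈ [0, 1]

Per-plant damage (plant *i*, `Nᵢ` leaves):

    Damagedᵢ ~ Binomial(pᵢ, Nᵢ)
    logit(pᵢ) = α + u¹_species[i] + u²_plot[i] + u³_obs[i]
              + β_date·DATE + β_sr·SR + β_pd·PD + β_srpd·(SR·PD)
    u¹ ~ N(0, σ²_species), u² ~ N(0, σ²_plot), u³ ~ N(0, σ²_obs)

fit by Laplace approximation (penalised IRLS inner solve, bounded outer
optimisation of the variance parameters).  The observation-level effect
absorbs over-/under-dispersion.  Significance of each fixed effect comes
from a parametric bootstrap: simulate from the model refit without that
factor, refit the full model, and compare observed |z| with the
simulated distribution.

## Worked example

Generate a synthetic study shaped like a 38-plot old-field survey and
run the full pipeline:

```sh
phyloherbivory simulate --out demo --seed 3
phyloherbivory run --tree demo/tree.nwk --composition demo/composition.csv \
    --plants demo/plants.csv --dates demo/dates.csv \
    --out demo/results --bootstrap-reps 199 --seed 3
```

The first command reports `wrote synthetic study (2170 plants) to demo`.
The run log then shows the fitted fixed effects:

```
INFO phyloherbivory: fixed effect Sampling date                      estimate=0.1017 se=0.0238 z=4.267
INFO phyloherbivory: fixed effect Plant species richness             estimate=0.2723 se=0.0262 z=10.400
INFO phyloherbivory: fixed effect Plant phylogenetic diversity (PSE) estimate=-6.8365 se=3.4461 z=-1.984
INFO phyloherbivory: fixed effect Plant diversity interaction        estimate=-1.7664 se=0.7199 z=-2.454
INFO phyloherbivory: variance components: {'species': 2.1922, 'plot': 0.3127, 'obs': 0.7766}
```

Reading this: each added species raises the log-odds of a leaf being
damaged by ≈0.27 at mean phylogenetic diversity, while the negative
interaction means that richness effect weakens as the community's
species become more distantly related — this seed happens to draw an
exaggerated PSE slope (its SE is wide because PSE varies little between
plots), but the richness and interaction signs reproduce the
generator's truth (β_sr = 0.23, β_srpd = −0.28).  Species identity
dominates the variance decomposition (σ²_species ≈ 2.2 against 0.31 for
plots): which species a plant belongs to matters far more for its
damage than which plot it grows in.  `demo/results/` contains
the per-plot diversity table, fit JSON, conditional-mode tables,
species/plot damage estimates with back-transformed ±1 conditional-SD
intervals, the fitted surface grid, and bootstrap JSON.

The same stages are available as library functions
(`phyloherbivory.simulate_study`, `build_model_data`, `fit_laplace`,
`bootstrap_p`, `plot_damage`, `fitted_surface`, …); see
`docs/methods.md` for the statistical details and design choices.

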