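# Methods

This package implements a community-phylogenetic analysis of herbivore
leaf damage: plot-level phylogenetic diversity (PSE) computed from a
community phylogeny, a binomial mixed model of per-plant damage with
crossed species, plot and observation random effects, parametric
bootstrap inference on the fixed effects, and a synthetic-study generator
with known ground truth.  This note records the models, the numerical
choices, and what the tests do and do not establish.

## Diversity indices

The phylogeny enters only through the Brownian-motion trait correlation
matrix `C`: `cov(i, j)` is the root-to-MRCA path length of tips *i* and
*j*, standardised by the tip depths to a unit diagonal.  For an
ultrametric tree this is MRCA depth over tree depth.  Non-ultrametric
trees are standardised the same way with a warning, since the [0, 1]
range guarantee below is stated for the ultrametric case.  The matrix is
invariant to uniform branch-length rescaling, positive semi-definite,
and pruning a tree commutes with slicing the matrix (a retained root
edge after pruning counts as shared history, which is what makes the
commutation exact).

For the `n` species present in a plot with abundance scores `m` (0–4
quadrat counts), `N = sum(m)` and `mbar = N/n`:

    PSV = (n tr(C) − sum(C)) / (n(n−1))
    PSE = (N Σ m_i C_ii − m'Cm) / (N² − N mbar)

PSE equals PSV at equal abundances and equals the mean trait divergence
over ordered pairs of *individuals* when each species is expanded into
`m_i` zero-length-branch tips, standardised by its maximum (star
phylogeny, even abundances).  The test suite drives the quadratic form
against that brute-force expansion and against picante's reference
implementation.

**A property worth knowing:** with abundance scores drawn uniformly on
1–4, PSE acquires a weak positive association with species richness
(r ≈ 0.17 under uniform assembly of 500 plots) because the evenness
deficit of random scores shrinks like 1/n — on a star tree
PSE = (N² − Σm²)/(N² − N mbar) → 1 as n grows.  The theoretically clean
richness-independence statement — and the one the tests assert tightly —
fixes abundances equal, where E[PSE] is exactly richness-free under
uniform assembly.

## The damage model

Per plant *i* with `N_i` leaves, `Damaged_i ~ Binomial(p_i, N_i)` and

    logit(p_i) = α + u¹_species[i] + u²_plot[i] + u³_obs[i]
               + β_date DATE + β_sr SR + β_pd PD + β_srpd (SR·PD)

with independent Gaussian random effects of variances σ²_species,
σ²_plot, σ²_obs.  The observation effect has one level per plant and
absorbs extra-binomial dispersion; the binomial has no free variance
parameter of its own.  Continuous predictors are centred, and the
interaction column is the product of the *centred* mains and is not
itself re-centred, so each main effect reads as a slope at the mean of
the other variables.

### Laplace fit

The marginal likelihood is approximated by a Laplace expansion around
the joint penalised mode.  For fixed standard deviations the fixed
effects and spherical random effects are found by penalised IRLS
(Newton with step halving on the penalised binomial log-likelihood);
the Laplace log-likelihood is

    ll(y | η*) − ‖b*‖²/2 − ½ log det(Λ'Z'WZΛ + I),

with `W = diag(N_i p_i(1−p_i))` at the mode.  Profiling the fixed
effects inside the inner solve and optimising only the three standard
deviations outside is the same objective as lme4's fast Laplace variant
(`glmer(nAGQ=0)`), and the two agree to ~1e-3 on crossed designs in the
tests.  Sparsity is exploited structurally rather than through a sparse
matrix library: the observation block of the Newton system is diagonal
and eliminated analytically, the factor crossproducts are grouped sums,
and what remains is a dense system of size
(n_species + n_plots + n_fixed) ≈ 70 for a study-scale dataset.

Outer optimisation: the default is bounded Nelder–Mead on log-σ
(tolerance 1e-8, one restart).  A second, validated path does L-BFGS-B
on the *variance* scale with an analytic gradient (envelope term plus
the two log-det terms, including the implicit shift of the mode); the
variance scale matters because the objective is flat in log-σ as σ → 0,
where variance-scale scores stay informative.  The gradient is verified
against central finite differences to machine-level agreement, and the
two outer paths agree to ~1e-4 in log-likelihood.  The gradient path is
roughly 30× faster at study scale (~0.05 s per fit) and is what the
bootstrap refits and the heavy simulation tests use.

SDs estimated below 1e-6 are reported as exactly 0 with a boundary flag.
Fixed-effect SEs come from the fixed-effect block of the inverse joint
Hessian at the optimum; conditional SDs of the random effects from the
corresponding random-effect blocks (conditioning on the estimated fixed
effects and variances, as lme4 does).  |η| > 20 raises a separation
flag.  Wald z = estimate/SE is reported, but p-values are left to the
bootstrap.

### Reported quantities

Plot-level estimated proportional leaf damage:
`p_j = logit⁻¹(α + u²_j + β_pd PD_j + β_sr SR_j + β_srpd (PD·SR)_j)` —
sampling date (a no-op at its mean under centring), species and
observation effects excluded.  Species-level damage:
`p_k = logit⁻¹(α + u¹_k)`, conditioning on the species effect — the only
reading under which "herbivory of species k" is a species-level
quantity.  Display
intervals back-transform mode ± 1 conditional SD and are therefore
asymmetric on the probability scale.  The fitted surface is
fixed-effects-only over a raw-scale (SR, PD) grid, centred internally
with the stored means; its logit-scale cross-curvature has the sign of
the interaction coefficient by construction, which the tests assert
numerically via finite differences.

### Parametric bootstrap

For a factor under test, the reduced model removes *only* that factor's
column; when a main effect is tested the interaction column stays.
That is the literal reading of simulating "without the fixed factor of
interest"; it ignores marginality conventions, which callers should
weigh when interpreting a main-effect p-value in the presence of its
interaction.  Each of B simulations draws fresh random effects from
Normal(0, σ̂²), forms p through the link with the reduced β̂, draws new
binomial counts with leaf totals and predictors fixed, refits the full
model, and records the factor's z.  p = #{|z_sim| ≥ |z_obs|}/B exactly
(displayed as "< 1/B" when 0); refits that fail to converge are counted,
excluded from the denominator, and warned about above 2% of B.  Refits
warm-start from the observed full fit and use the gradient outer path
with slightly relaxed tolerances (validated: |Δz| ≤ ~2e-3 against tight
refits).  The production default is B = 1000; tests use B = 199.

Type-I calibration is genuinely scale-dependent: with ~10 plots the
reduced fit's σ̂_plot frequently collapses to the boundary, the simulated
null distribution of z for plot-level covariates is too narrow, and the
test anticonservative (measured rejection ≈ 0.12 at nominal 0.05).  At
38 plots — the study's plot count, with a reduced per-plot sampling
effort to keep runtime at desk scale — rejection and the KS distance to
uniform fall within binomial error of nominal.  The calibration test
therefore uses 38 plots, a 20-species pool, 10 phytometers, 1 plant per
species per plot and mean leaf count 9.

## Synthetic studies

The generator mirrors the field design stage by stage, all randomness
flowing from one root seed split per stage:

* **Tree** — Yule (pure-birth) tree, depth normalised to 1, simulated
  forward with an extra exponential waiting time after the last split so
  no terminal branch is zero.  Pool of 52 species by default.
* **Plots** — 38 plots; richness uniform on 3–17; members sampled
  without replacement with weight `exp(−λ · patristic distance to a
  uniformly drawn focal species)`; λ = 0 (default) is uniform assembly,
  larger λ yields phylogenetically clustered, low-PSE plots; abundance
  scores uniform on 1–4; sampling dates uniform integers on 0–13 (a
  two-week campaign).
* **Damage** — a phytometer panel of 27 species drawn uniformly from
  the pool (matching the motivating survey's realized panel occupancy,
  ~1900–2000 plants); 10 plants per phytometer species per occupied
  plot; leaf counts 1 + Poisson(15); damage drawn from the model above
  with defaults at the reported operating point: α = 0.15,
  β_date = 0.10, β_sr = 0.23, β_pd = −0.19, β_srpd = −0.28,
  σ² = 2.4 / 0.26 / 0.82 (species / plot / observation).  The implied
  mean damage fraction is ≈ 0.54 and species-level damage spans roughly
  5%–98%, matching the shape of the motivating data.

What the generator does **not** emulate: spatial structure within and
between plots, phylogenetic signal in species palatability (species
effects are exchangeable draws, not Brownian on the tree), herbivore
dynamics or diet-breadth mechanisms, leaf-count dependence on species,
and observation of the same plant over time.  Passing recovery tests
therefore shows the estimator is consistent with its own generating
model at study scale — not that the model is adequate for any
particular field system.

## Numerical choices and limitations

* Inner PIRLS tolerance 1e-10 (relative), max 60 iterations; weights
  floored at 1e-12.
* Outer log-σ bounds [log 1e-7, log 50]; variance-scale path clamps
  v ≥ 1e-8 so mode, objective and gradient stay consistent at the
  boundary.
* Degenerate inputs: plots with fewer than two present species get a
  missing PSE and are excluded from modelling with a warning; a
  rank-deficient fixed design or mismatched row counts are hard errors;
  unknown factor levels at prediction time raise rather than imputing
  zero.
* The Laplace approximation, not quadrature, is used for production
  fits: crossed factors make quadrature infeasible.  Accuracy is checked
  against 25-point adaptive Gauss–Hermite quadrature on single-factor
  models (within 0.1 nats across random datasets).
* Wald coverage at the study operating point is ≈ 93–97% per
  coefficient in 100-replicate experiments; SD recovery for the species
  and observation components has median relative error under 10%.
  Plot-variance estimates from 38 plots are noticeably noisier — a
  design property, not an implementation artefact.
* Evenness (Pielou's J on the 0–4 scores) is provided as a utility only
  and never enters the model; which evenness index the motivating
  analysis computed is not recorded, so Pielou is a documented stand-in.
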