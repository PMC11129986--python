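# Methods

## Model and assumptions

The toolkit analyzes a three-component conceptual model of the
plankton–oxygen system in the upper mixed layer: dissolved oxygen `c`,
phytoplankton `u` and zooplankton `v`, all dimensionless.  Oxygen is
produced photosynthetically at rate `A u/(c+1)` (production saturates as
oxygen accumulates), consumed by phytoplankton and zooplankton respiration
with Monod kinetics, and lost at unit rate.  Phytoplankton grows
logistically with an oxygen-limited rate `B c/(c+c₁)`, is grazed with a
Holling type-II response `u/(u+h)`, and dies at rate `σ`.  Zooplankton
converts grazing into growth with an oxygen-dependent efficiency
`η c²/(c²+c₄²)` (a sigmoidal dependence: reproduction needs well-oxygenated
water) and dies both linearly (`μ₁`) and quadratically (`μ₂ v²`).  The
quadratic term is a closure for intraspecific competition, cannibalism and
predation by unresolved higher trophic levels, and is what allows
stationary Turing patterns in the spatial model.

Two structural assumptions shape the analysis:

* **Timescale separation.**  The zooplankton equation carries the factor
  `ε ∈ (0, 1]`; for `ε ≪ 1` the system is singularly perturbed with fast
  variables `(c, u)` and slow variable `v`.  The fast-time right-hand side
  is `(F, G, εH)`; consumers needing the bare zooplankton rate use
  `rhs_unscaled_H` — the split exists to prevent silent double-scaling.
* **No oxygen-free refuge.**  Setting `c = 0` forces `u = 0` and then
  `v = 0`: the extinction state `(0,0,0)` is the only boundary attractor
  and is always locally stable, which is why collapse, once triggered, is
  irreversible in this model.

All kinetic constants are held at the reference set
`A=4, B=3, σ=0.1, c₁=0.7, c₂=c₃=c₄=1, η=0.7, δ=1, ν=0.01, h=0.1`;
the mortality rates `μ₁, μ₂`, the timescale ratio `ε` and the diffusivity
ratio `D` are the knobs every analysis varies.

## Steady states and linear stability

Zooplankton-free states `(c̄, ū, 0)` come from the closed-form quartic in
`c̄` (with `ū` from a rational expression); real positive roots with
`ū > 0` are polished by 2-D Newton iteration on `(F, G)` at `v = 0`, so
the reported states satisfy the defining residuals to ~1e-13 regardless of
conditioning of the quartic coefficients.  They are independent of `μ₁`,
`μ₂` and `ε` by construction.

Coexistence states solve `F = G = H = 0` with all components positive.
For `μ₂ > 0`, `H = 0` is solved explicitly for `v`, and a 40×40 multi-start
grid over `(c, u) ∈ [0.05, 5]²` seeds 3-D Newton iterations (for `μ₂ = 0`
a small set of `v` seeds replaces the elimination; `μ₁ = μ₂ = 0` is
rejected as degenerate because `H ∝ v` then has non-isolated zeros).
Duplicates merge at Euclidean tolerance 1e-7; residuals must be below
1e-9.  The dense grid is deliberate overkill — the model has at most two
coexistence states in the studied regimes, and the grid guarantees both
are captured, including the low-oxygen pair near `c ≈ 0.03` that collides
in a saddle-node as `μ₂` decreases (located by `saddle_node_mu2` through
bisection on the root count, with the search window refined toward small
`c` and `u` where those roots live).

Stability is double-bookkept: eigenvalues of the analytic Jacobian (row 3
carries `ε`; the closed forms were derived once symbolically and are
regression-tested against central finite differences at tolerance 1e-6)
and the Routh–Hurwitz coefficients `p₂ = −tr J`, `p₁ = Σ` principal 2×2
minors, `p₀ = −det J`.  The two verdicts must agree; disagreement or an
eigenvalue with `|Re λ| < 1e-8` is surfaced as a marginal/bifurcation
condition rather than silently labelled.

## Hopf points and criticality

A Hopf threshold is the zero of `p₁ p₂ − p₀` along an equilibrium branch,
bisected to parameter tolerance 1e-7 with natural-parameter continuation
(Newton seeded from the previous point, step 0.01 with halving) supplying
the equilibrium at each probe; `p₀ > 0` and `p₂ > 0` are verified at the
root and the Jacobian eigenvalues must independently show a conjugate pair
on the axis.  When two coexistence states exist the non-saddle
(largest-oxygen) branch is tracked.

Criticality comes from the first Lyapunov coefficient `l₁` computed with
the standard projection formula for n-dimensional systems,

    l₁ = Re[⟨p, C(q,q,q̄)⟩ − 2⟨p, B(q, A⁻¹B(q,q̄))⟩
           + ⟨p, B(q̄, (2iωI − A)⁻¹B(q,q))⟩] / (2ω),

with `Aq = iωq`, `Aᵀp = −iωp`, `⟨p,q⟩ = 1`.  The bilinear and trilinear
forms are directional second/third derivatives of the vector field taken
by central differences in complex directions (step 1e-3 and 5e-3; the
field is rational, so complex evaluation is exact in exact arithmetic and
the schemes' O(h²) truncation is far below sign resolution).  Only the
*sign* of `l₁` is contractual: its magnitude depends on eigenvector
normalization, and different continuation packages print different
magnitudes for the same bifurcation.

## Global thresholds by trajectory probing

The heteroclinic destruction of the large stable cycle and the
canard-explosion collapse have no local test function.  They are located
operationally: start at the coexistence state plus an offset of 0.01 per
component, integrate to `T = 5000` with LSODA at `rtol 1e-9 / atol 1e-11`
(trajectories skirting the repelling sheet of the critical manifold are
exponentially sensitive, hence the tight tolerances), call the outcome a
collapse when phytoplankton drops below 1e-6 and stays there for 50 time
units, and bisect the parameter on that Boolean to tolerance 1e-5.  Cycle
envelopes in branch diagrams discard a transient of 2000 time units and
record the oxygen extrema over 1000 more, doubling both automatically when
the extrema of the two half-windows drift by more than 1%; those windows
exceed the slowest timescale `1/(εμ₁)` for every `ε ≥ 0.1` studied.

## Slow–fast machinery

Freezing `v = v₀` gives the planar fast subsystem.  Its equilibria are
found by substituting the explicit oxygen nullcline `u(c)` into `G = 0`
and scanning the resulting scalar function on `c ∈ (0, 20]` (4000 points,
Brent refinement, 2-D Newton polish); the upper bound is ×10 the oxygen
range the dynamics actually visits.  The fold solves
`F = G = det J_fast = 0` by 3-D Newton seeded from the `v₀` where the
slice count drops 2 → 0; residuals below 1e-9 are required.  The manifold
sampler uses 400 uniform `v₀` points on `[0, 1.1 v_s]` with a tenfold
refinement over the last 5% before the fold, labels sheets by `u ≷ u_s`,
and confirms the labels with fast-subsystem eigenvalues at every tenth
sample.  The reduced flow on the manifold is evaluated from the implicit
differentiation formulas with the analytic partials, raising a dedicated
singularity error within 1e-10 of the fold determinant.

The jump/canard discriminants `d₁ = F_v G_u − F_u G_v` and
`d₂ = F_v G_c − F_c G_v` are evaluated at the fold with tolerance 1e-6.
At the reference constants both are O(1) nonzero, so the fold is reported
as a **jump point**; the canard-cycle phenomenology near the singular Hopf
is nonetheless present and is what the collapse-threshold analysis probes.
Both classifications are legal outputs and the verdict is robust to the
tolerance over [1e-8, 1e-4].

The drift `H` at the fold depends on the mortality rates even though the
fold itself does not.  The package quotes it at `μ₁ = 0.3, μ₂ = 0.1018`
(`FOLD_CONTEXT_MU`): the slow-fast study regime just above the singular
Hopf threshold, where the drift is small and positive so the slow flow
points toward the fold — the configuration in which the canard analysis
is meaningful.

## Turing analysis

The dispersion coefficients `p₂(k²), p₁(k²), p₀(k²)` follow the cubic
characteristic polynomial of `J − diag(1, 1, D) k²`.  The Jacobian here is
the ε-scaled one — the zooplankton row carries `ε`, so the Turing verdict
and the critical wavenumber genuinely depend on the timescale separation
even though the homogeneous equilibrium does not.  `k_T²` uses the closed
form `(J₁₁+J₂₂)/3 + (J₃₃ + √Λ)/(3D)` and is always cross-validated
against direct numerical minimization of `p₀` over `k² ∈ (0, 10]`; the two
agree to machine precision because the closed form is the exact larger
root of `dp₀/dk² = 0`, but the minimizer is preferred if they ever
disagreed beyond 1e-6.  The default dispersion grid is 2000 log-spaced
`k²` values on [1e-4, 10].  When two coexistence states exist the
temporally stable one is the relevant homogeneous background.

## Spatial scheme and diagnostics

The 1-D simulator uses the discretization of all reference computations:
forward Euler with `Δt = 0.01` and the three-point Laplacian with
`Δx = 1` on a node-centered grid `x = 0..L` inclusive (`L = 500`,
`n = 501` by default).  Zero-flux boundaries are mirrored ghost nodes,
which is second-order consistent and conserves the trapezoidal mass of
each field exactly in pure diffusion — the property the scheme oracle
tests to 1e-12 per step.  The explicit stability constraint
`max(1, D) Δt/Δx² ≤ 0.5` is enforced, values in `(−1e-8, 0)` arising from
round-off are clamped to zero with a counter, and anything more negative
aborts the run as a numerical failure.  Initial conditions perturb the
homogeneous coexistence state on `|x − L/2| < 10`: raised (`+0.1` in
oxygen, `+0.2` in phytoplankton) or lowered (`−0.5`, `−0.2`) — the latter
probes robustness of OMZ formation to the perturbation sign.

An OMZ is operationalized as a maximal run of at least two consecutive
nodes with `c < θ c*`; the threshold fraction defaults to `θ = 0.5` (the
qualitative notion is "well below the steady state"; θ is exposed in the
report so other conventions are one argument away).

Regimes are classified on the final 500 time units of a run:
`global_anoxia` if the final mean oxygen is below 0.01;
`homogeneous_steady` if the relative spatial std of oxygen and the
temporal std of its mean are both below 1e-4; `stationary_pattern` if the
spatial std is at least 1e-2 while the L2 change between the last two
snapshots is below 1e-4 per node; `localized_oscillation` if temporal
oscillation (node range exceeding 5% of `c*` over the window) is confined
to under 20% of the domain; `dynamic_irregular` otherwise.  Pattern
wavenumbers are read off a type-I cosine transform (the eigenbasis of the
Neumann Laplacian), and mode comparisons are made on mode indices
`m = k L/π`, the natural resolution of a finite domain.

Default run length is `T = 5000` with snapshots every 10 time units.  The
test suite exercises the regime taxonomy on a reduced domain
(`L = 200, T = 2000`), which reproduces the full-domain labels while
keeping the whole suite at desk scale; the saturated Turing pattern locks
about 6% below the linear `k_T` (nonlinear wavelength selection), which on
the reduced domain is one mode index.

## What the probing trajectories do and do not show

All inputs are generated programmatically from the model itself — there is
no external data and no randomness anywhere in the computational paths
(random draws appear only in tests, seeded).  The localized-perturbation
initial conditions emulate a patch disturbance of a uniform ocean state;
they do not emulate measured oceanographic fields, bathymetry, advection,
vertical structure or seasonal forcing, so passing regime tests
demonstrate internal consistency of the model's mechanisms (Turing versus
non-Turing OMZ formation, timescale-driven anoxia), not predictions for a
specific ocean region.

## Known limitations

* No continuation of unstable limit cycles: subcritical cycle branches are
  inferred from envelopes and collapse probing, not traced.
* `l₁` magnitudes are reported but normalization-dependent; only signs are
  stable contracts.
* The narrow window between the subcritical Hopf at `μ₂ ≈ 0.1577` and the
  saddle-node of cycles at `≈ 0.1578` (for `μ₁ = 0.24`) is below the
  resolution targeted here; the tri-stability inside it is acknowledged
  but not resolved as a separate threshold.
* One spatial dimension, isotropic turbulent diffusion, no advection and
  no vertical structure; the diffusivity ratio `D` is the only transport
  parameter.
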