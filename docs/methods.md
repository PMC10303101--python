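# Methods

## The problem and the pipeline

`autocmap` reconstructs, as reusable and tested code, an analysis chain used
to explore how hair trace-element burden relates to cardiometabolic risk in
adults with overweight–obesity: a cohort of subjects described by clinical
variables, a 31-element hair mineralogram, and composite indices is encoded
into a common [0,1] scale, an Auto-Contractive Map (Auto-CM) neural network
learns a full variable–variable association matrix, the minimum spanning
tree over the derived distances yields a "semantic connectivity map", and an
Activation and Competition System (ACS) probes the trained associations by
clamping one variable and watching which others respond, in what order and
how strongly.

The original subject-level data are private, so the package ships a
synthetic-cohort generator that emulates the study conditions; everything
downstream operates identically on a real cohort CSV.

## Synthetic cohort generator

Each variable has a marginal specification (family, mean, SD, truncation
bounds): truncated Gaussians for roughly symmetric clinical variables,
truncated lognormals for right-skewed analytes (CRP, triglycerides,
glycaemia, HbA1c, homocysteine) and for all 31 hair elements (concentrations
in μg/g are strongly right-skewed, with many toxic elements above their hair
reference limits), and Bernoulli for binary states. Defaults reproduce the
published cohort summary (n = 95, age 51 ± 12): per-variable mean/SD and
min/max for the 25 clinical variables and all 31 elements.

Auxiliary primitives the index formulas need but the published summary does
not report are given population-plausible defaults, documented as **not**
study-calibrated and overridable: sex ~ Bernoulli(0.5), HDL ~ N(52, 13²)
mg/dL truncated to [20, 100], GGT lognormal mean 30 SD 20 U/L, smoking
Bernoulli(0.25), antihypertensive treatment Bernoulli(0.30), age truncated
N(51, 12²) on [30, 79].

**Lognormal calibration.** A lognormal matched by the closed-form method of
moments and then truncated to the published min/max no longer has the
published mean (for Barium the truncation bias is ≈ 0.05 μg/g, several
standard errors at n = 10⁵). The generator therefore calibrates (μ, σ) so
that the *truncated* distribution has the requested mean and SD (joint
2-parameter solve); when the published SD is unattainable inside the bounds
(extremely heavy-tailed elements such as Cadmium, whose printed SD of 6.66
at mean 0.74 is close to the maximum any distribution on [0, 65] with that
mean can have), σ is kept at its closed-form value and μ alone is solved so
the truncated mean is exact. Germanium's printed mean equals its printed
minimum (rounding), which no truncated distribution can attain; its target
mean is nudged 10 % of the range inside the support.

**Truncation by inverse-CDF coupling.** Correlation is induced by latent
factors: each variable's standard-normal score is u = Σ λ_f z_f + s·ε
(unit variance), and the value is the truncated marginal's quantile at
Φ(u). This keeps the truncated marginal exact *and* monotone in u, so
factor-mates are positively rank-correlated by construction; a
rejection-resampling scheme that redrew only the idiosyncratic noise would
distort the marginal under factor coupling.

**Planted structure.** Two latent factors, default loading 0.6: a
*metabolic* factor on WC, BMI, triglycerides, insulin, glycaemia, HbA1c,
fibrinogen and uric acid, and an *exposure* factor on the 13 toxic elements.
This plants exactly the kind of two-armed association structure the map is
meant to discover.

**Derived indices are computed, never sampled**: FLI, VAI, Framingham
points, MetS, the obesity flag and the toxicity index are evaluated from
each subject's simulated primitives, so their associations with the
primitives are structural. The one exception is the Italian CUORE-project CV
risk: its charts are out of scope (a pluggable stub), so that single column
is sampled from its published marginal.

**What the generator does not emulate:** measurement error and batch
effects, the exact multivariate dependence of the real cohort (only two
planted factors plus the structural dependence of derived indices),
age/sex-conditional marginals, and missingness (simulated cohorts are
complete). Passing tests therefore demonstrate that the pipeline recovers
planted structure under realistic marginals — not that the real study's
specific map topology would be reproduced.

## Composite indices

* **FLI** (Bedogni): 100·logistic(0.953 ln TG + 0.139 BMI + 0.718 ln GGT +
  0.053 WC − 15.745), TG mg/dL, GGT U/L, WC cm; <30 excludes, ≥60 indicates
  fatty liver.
* **VAI** (Amato, sex-specific), TG/HDL in mmol/L; unit converters
  (TG ×0.01129, cholesterol ×0.02586 from mg/dL) with a guard that rejects
  TG > 30 mmol/L as a probable unit mistake. Age-banded reference cutoffs
  2.23 / 1.92 / 1.93 / 2.0; the printed bands leave the 41–42 and 65–66
  edges ambiguous, resolved here as [30,42), [42,52), [52,66), [66,∞) so the
  lookup is total.
* **Framingham**: the NCEP ATP III office-based point tables, embedded as
  data, with the published points→10-year-risk lookup ("<1 %" reads 0.5,
  "≥30 %" reads 30.0). Diabetes does not enter the point sum (ATP III treats
  it as a risk equivalent outside the score).
* **MetS**: 2005 ATP III revision, ≥3 of 5 components (WC >102/88 cm,
  TG ≥150, HDL <40/50, BP ≥130/85 or treated, glucose ≥100 mg/dL).
* **Toxicity index**: TI = Σ wᵢcᵢ / Σ wᵢ over the 13 toxic elements. The
  laboratory weighting behind the original score is proprietary; the default
  here sets wᵢ = 1/reference_upperᵢ, i.e. "relative per-gram toxicity" read
  as the inverse of the tolerated hair level. This is a reimplementation
  choice, prominently overridable; TI is homogeneous in concentrations and
  invariant to rescaling all weights.

## Pre-processing

Default encoding dichotomizes every variable at its cohort median (1 iff
value > median), the split the published description implies ("high or low"
values); min–max scaling to [0,1] is available per variable. Already-binary
variables pass through. Constant variables raise rather than being silently
encoded. Variables with >10 % missing entries are rejected; lighter
missingness is median-imputed before encoding. No variable pruning by
default — the map deliberately includes everything; subset selection exists
as an explicit option for the ACS stage.

## Auto-Contractive Map

Canonical contractive dynamics with N input/hidden/output units and
contraction parameter C (> 1, default C = N so every contraction factor
stays in (0,1]): hidden h_s = m_s(1 − v_s/C); Net_i = Σ_s h_s(1 − w_si/C);
output o_i = h_i(1 − Net_i/C); adaptation Δv_s = α(m_s − h_s)(1 − v_s/C) and
Δw_si = α(h_s − o_i)(1 − w_si/C)·h_i, applied record by record in fixed
dataset order (exact reproducibility, no shuffling). Weights start at a
small positive constant (0.001·C): v = 0 exactly is a fixed point of its own
adaptation, so a zero start would never contract. Defaults: α = 0.1,
tolerance 1e-6 on the epoch-mean |Δw|, max 2000 epochs.

As v saturates toward C the hidden signal vanishes and training freezes;
co-varying variables accumulate large positive w while unrelated pairs drift
to small or negative values. The epoch-mean |Δw| trace is not strictly
monotone — it shows small transient humps (relative size ~1e-3) while the
monoconnections saturate and negative transients unwind — but its 50-epoch
block average decays monotonically to convergence on the default cohort.

**Link strengths**: w is symmetrized by the arithmetic mean (the map is
undirected), divided by its global maximum and floored at 0, giving
strengths in [0,1] with the strongest link exactly 1; the diagonal is 1 by
convention. Distance d = 1 − s; the MST over distances (Kruskal, edges
inserted in lexicographic label order so ties break deterministically) is
the semantic map. Hubs are scored by degree then summed incident strength;
the central node maximizes that score with lexicographic tie-break.

## Activation and Competition System

The ACS probes the trained strengths: the clamped variable is pinned at 1,
all others start at the resting level (0.5). Per step, node i receives
e_i = Σ_j s_ij(a_j − rest) — nodes above rest excite their neighbours, nodes
below rest inhibit them, which is the competition — and updates by
Δa_i = γ[e_i(1 − a_i) − δ(a_i − rest)] for e_i ≥ 0 (saturating toward 1) or
γ[e_i·a_i − δ(a_i − rest)] for e_i < 0, clipped to [0,1]; γ = 0.1, δ = 1.
The run stops when the largest activation change falls below 1e-5 (default)
or after 5000 iterations (converged=False, warned, never raised).

The 2-node system with coupling s has the closed-form fixed point
a* = (e + δ·rest)/(e + δ) with e = s(1 − rest): strictly increasing in s and
above rest whenever s > 0; with zero coupling the system is inert at rest.
The activation hierarchy ranks free variables by first passage above
rest + 0.1, ties by steady intensity; variables never crossing are listed
last as non-responders. The hierarchy is reported as response order only —
no causal claim is attached.

By default the ACS reuses the Auto-CM link strengths (whether the original
analysis retrained a separate auto-associative network is not documented;
a different strength matrix can be supplied). Element pruning before the ACS
run — the design used for the published risk-probe figure — is available via
`exclude_elements` / `--exclude-elements`.

## Numerical choices and degenerate inputs

* Truncated-lognormal moment formulas are evaluated in log space to survive
  σ ≈ 2–4 (Cadmium-like tails) without overflow.
* Quantile-function inputs are clipped to [1e-15, 1 − 1e-15]; sampled values
  are clipped to the truncation bounds (guards the last double of range).
* Training rejects inputs outside [0,1] and raises on non-finite weights
  with epoch/record context; the all-zero weight matrix is a degenerate
  model, not a silent all-zero map.
* Constant encoded variables, missing MetS components, unknown element
  symbols and unknown config keys all raise immediately.
* MST distance ties (common after the strength floor at 0) are broken
  lexicographically, so repeated runs give byte-identical artifacts.

## Problem sizes used by the packaged checks

Calibration checks use n = 10⁵ marginal draws; planted-correlation recovery
n = 10⁴ cohorts; bounded-strength sweeps 20 seeded 95-subject cohorts;
structure recovery 50 replicate 12-variable two-factor cohorts (6 + 6
variables, loading 0.7, n = 2000) against a 1000-sample uniform
spanning-tree baseline; MST oracle equivalence 1000 random instances with
N ≤ 6 against exhaustive Prüfer enumeration. These sizes are the package's
own choices balancing statistical resolution against quick feedback.

## Known limitations

* The Auto-CM/ACS equation family has published variants; this package
  implements one canonical, fully documented instance with a pinned contract
  (contraction by (1 − ·/C), boundedness, determinism, clamping,
  competition). Trained weights — and hence exact link-strength values — are
  not comparable across variants, only the induced ranking structure is.
* Default toxicity weights are a documented stand-in for a proprietary
  weighting; absolute TI values are not comparable to laboratory reports.
* The Framingham implementation is the ATP III point score; other variants
  (e.g. the general CVD equation) must be plugged in by the caller.
* The CUORE-project risk charts are not implemented.
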