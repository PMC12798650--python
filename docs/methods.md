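# Methods

`nmgc` evaluates how well temporal Granger causality (GC) recovers known
directed connectivity, using a stochastic neural mass network as the
ground-truth generator. This note documents the model, the estimators, the
calibration choices, and the limits of what the package's passing tests
demonstrate.

## The neural mass model

Each region of interest (ROI) contains four lumped populations: pyramidal
cells `p`, excitatory interneurons `e`, and slow (`s`) and fast (`f`)
GABAergic interneurons. A population's average membrane potential `v` maps
to an average firing rate through the static sigmoid

    z(v) = 2 e0 / (1 + exp(r (v0 - v))),       e0 = 2.5 s^-1, r = 0.56 mV^-1, v0 = 6 mV,

which supplies the model's nonlinearity (threshold below, saturation at
`2 e0`). Every synapse is a critically damped second-order filter with
impulse response `h(t) = G omega t exp(-omega t)`; its two parameters are a
gain `G` (mV) and a rate constant `omega` (s^-1). Three synapse families
exist — glutamatergic (from `p` and `e`), slow GABAergic (from `s`) and fast
GABAergic (from `f`) — and eight internal coupling constants
(`p->e, e->p, p->s, s->p, p->f, f->p, s->f, f->f`) count the average
synaptic contacts between populations. External input (mean `m_p` plus white
noise of standard deviation `sigma_p`) drives the pyramidal population
through a glutamatergic synapse; an analogous input (`m_f`, `sigma_f`)
drives the fast interneurons.

Long-range connections originate exclusively from pyramidal populations.
An *excitatory* connection (strength `W`, delay `D`, default 10 ms) feeds
the delayed source rate `W z_p(t - D)` into the glutamatergic synapse of the
target's pyramidal population; an *inhibitory* (disynaptic) connection feeds
the target's fast interneurons instead, producing net inhibition of its
pyramidal cells. The analysis signal of each ROI is `v_p`, the pyramidal
membrane potential — a proxy for the local field potential.

### Integration

Euler–Maruyama at `dt = 1e-4 s` (the fastest synapse has
`omega <= 650 s^-1`, so `dt * omega <= 0.065`); noise enters as
`sigma / sqrt(dt)`-scaled Gaussian increments drawn once per step from a
per-trial PCG64 generator, which makes every trial bit-reproducible and
independent of how trials are batched. Delays are rounded to the nearest
integer multiple of `dt` and served from a ring buffer of pyramidal rates.
Per-connection postsynaptic-potential traces are integrated as separate
second-order filters with the target's glutamatergic kinetics; because the
synapse block is linear, these equal that connection's additive share of the
lumped membrane potential exactly. The first 1 s of every simulation is
discarded as a transient before analysis.

### Band presets and their calibration

The per-band parameter sets are *calibration-verified*: starting from the
classic four-population constant set (`C = 135` with the usual fractions;
glutamatergic `G = 3.25 mV, omega = 100 s^-1`; slow GABAergic
`G = 22 mV, omega = 50 s^-1`), each preset was tuned once so that an
isolated ROI driven by its default input (`m_p = 400`, `sigma = 10`)
produces a Welch-PSD peak of `v_p` inside its nominal band, verified over
12 seeds. Two mechanisms set the frequency:

* **theta / alpha / beta** — the resonance of the slow-inhibitory feedback
  loop. The glutamatergic and slow rate constants are rescaled by 0.55 /
  1.0 / 2.0 with gains rescaled in proportion, which moves the loop's
  resonance while preserving `G/omega` and hence the operating point.
  Their fast synapse uses `G = 20 mV, omega = 500 s^-1`.
* **gamma** — the pyramidal <-> fast-interneuron loop, whose phase
  crossover with `omega_e = 100` and `omega_f = 650 s^-1` lies near 35 Hz.
  The preset strengthens that loop (`p->f = 140`, `f->p = 160`,
  `G_f = 40 mV`) and weakens slow inhibition (`G_s = 15 mV`).

The fast interneurons additionally receive a baseline drive `m_f = 100` in
the theta/alpha/beta presets. Without it the fast pool rests ~6 mV below
its sigmoid center, where its slope is nearly zero, and disynaptic
inhibition cannot be relayed at all; a modest baseline keeps the pool inside
its sensitive range, which is what makes inhibitory connections detectable
by GC in the first place. The inhibitory-relay strength was verified on a
two-ROI sweep (gamma source, inhibitory connection, excitatory return) and
the band peaks re-verified after the change.

## Preprocessing

Raw 10 kHz traces are low-passed at 50 Hz with an order-8 Butterworth
applied forward–backward (zero phase, so lag structure is not distorted)
and decimated to 100 Hz — twice the post-filter Nyquist frequency — in
stages of at most a factor 10 to keep each anti-alias filter numerically
benign. Each channel is then mean-centered and scaled to unit sample
variance. GC is invariant to this affine normalization (verified by test);
it is applied for numerical hygiene and comparability.

## Granger causality

GC from channel *j* to channel *i* is the log-ratio of restricted to
unrestricted prediction-error variances. Both models are fitted by
per-equation ordinary least squares with intercept on the identical target
window (the first *p* samples dropped once), so the models are exactly
nested and GC >= 0 holds deterministically.

* **Unconditional (pairwise)**: restricted = *p* own lags of `x_i`;
  unrestricted adds *p* lags of `x_j`.
* **Conditional**: both models also contain the lags of every other
  channel, removing common-driver and chain confounds.

With exactly two channels the formulations coincide to machine precision —
a mathematical identity, enforced by test. Residual variances use the MLE
normalization RSS / n_obs with `n_obs = n_samples - p`. Under the null the
estimator carries a small-sample bias of about `q / n_obs` (the *q = p*
added parameters each absorb ~1/n_obs of variance), which the package uses
as the reference level when judging whether a GC value is distinguishable
from "no causality".

Significance of a single GC value comes from the nested-model F test,
`F = ((RSS_r - RSS_u)/q) / (RSS_u / dof_u)` with
`dof_u = n_obs - (regressors in the unrestricted model, intercept
included)`. The per-pair F statistic matches `statsmodels`'
`grangercausalitytests` `ssr_ftest` exactly (cross-checked in the suite).
Model order defaults to 15 for all headline runs; Akaike-criterion
selection over a common sample window is available (`select_order_aic`) and
stays at or below 15 across the basic two-ROI scenarios.

## Inference across pairs and trials

The multiple-testing family is the set of all n(n-1) directed pairs of one
trial (42 for seven ROIs). Bonferroni and Benjamini–Hochberg step-up FDR
corrections are applied via `statsmodels.stats.multitest`; rejection-set
monotonicity (Bonferroni ⊆ FDR-BH ⊆ uncorrected) is property-tested.
Across the 20 trials of a scenario the package reports mean, standard
deviation (n-1 denominator) and the fraction of trials in which each pair
is significant under each correction.

For sweep experiments that report "the weight at which a link becomes
significant", one call per grid value is made by pooling trials: a
one-sided one-sample t-test of the 20 per-trial GC values against the
null-bias level `q / n_obs` at alpha = 0.05 (the source's exact rule is not
fixed by the experimental description; a majority-of-per-trial-F-tests rule
is provided as an alternative and documented in the API).

## Experiments

All scenario runners share the operating conditions 10 s / 100 Hz /
order 15 / 10 ms delay / 20 trials / alpha 0.05; trial *t* uses seed
`base_seed + t`, recorded in each table's provenance block.

* **Two-ROI sweeps** (`run_two_roi_sweep`): reciprocal pairs of distinct
  rhythms; one weight swept over {0, 20, ..., 120} (inhibitory variants up
  to 140), the other fixed at 40; GC both directions and formulations,
  postsynaptic-potential summaries, and trial-averaged PSDs.
* **Input sweep** (`run_input_sweep`): both weights 80; the second region's
  `m_p` swept 0..3500, probing the sigmoid's threshold and saturation.
* **Common input** (`run_common_input`): an alpha ROI drives unconnected
  theta and beta ROIs with equal weight; all six directed pairs estimated
  both ways.
* **7-ROI brain network** (`run_network`): theta-L, beta-L, gamma-L, alpha
  (thalamic hub), theta-R, beta-R, gamma-R. The excitatory template (hub to
  all six cortical regions, theta->beta and reciprocal beta<->gamma chains
  per hemisphere, W = 40) is an assumption — the reference network's
  numeric weight matrix is not available — and is config-overrideable. The
  mixed variant adds reciprocal inhibitory links between the three
  homologous left/right pairs (six directed inhibitory edges).
* **4-ROI mixed fixtures** (`four_roi_variants`): six documented synthetic
  topologies (chains, rings, hubs, feedback pairs) combining excitatory and
  inhibitory edges, used for the normalized-share comparison in which every
  method's edge estimates are normalized to sum to one.
* **Sensitivity** (`run_sensitivity`): one-at-a-time sweeps of signal
  length, model order, delay and sampling rate.

The "postsynaptic current" of a connection is summarized as the standard
deviation over time of its postsynaptic-potential trace (the source does
not define the summary; the std captures the delivered *fluctuating* drive,
which is what GC can see, and is recorded in the output metadata).

## What the generator does and does not emulate

It reproduces band-specific intrinsic rhythms, nonlinear (threshold /
saturation) transmission, delayed directed coupling of excitatory and
disynaptic-inhibitory type, and trial-to-trial stochasticity — the
ingredients the GC evaluation needs. It does not model the multilayer
cortical column, spiking dynamics, volume conduction, measurement noise, or
EEG forward/inverse mapping; passing tests therefore validate estimator
behavior against this family of generative dynamics, not performance on
recorded EEG.

## Known limitations

* Absolute GC levels depend on the calibration of the presets; growth
  ratios and detection thresholds are more portable, and the acceptance
  checks are framed accordingly (factor-two bands on levels, tight
  assertions on ratios/thresholds).
* Because two-channel conditional and unconditional GC are identical, a
  reported difference between the two estimators on a two-ROI system can
  only be an implementation artifact; this package reports a single value
  for both in that case.
* In this calibration a *reciprocally inhibitory* pair can silence the
  source region (the tonic component of the long-range drive pushes the
  fast pool high enough to suppress the source's pyramidal loop), so
  mutually-inhibitory two-ROI GC stays below matched excitatory values.
  One-directional inhibitory links, and inhibitory links in networks whose
  regions also receive excitatory drive, are detected reliably.
* At `m_p = 0` a region embedded in a strongly coupled pair (W = 80) is not
  fully silenced — it remains entrained by its partner — so the low-input
  end of the input sweep shows reduced but not bias-level GC. The
  saturation collapse at high `m_p` and the interior maximum are robust.

## Problem sizes

Unit and acceptance tests run the full pipeline at the standard conditions
(20 trials where a detection percentage or trial spread is asserted);
order-selection scans use 10 trials per rhythm pair and the 4-ROI share
fixtures 5 trials per variant, sizes chosen as adequate for the quantities
asserted. The acceptance script regenerates everything from scratch with
the seed passed on the command line.
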