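# Methods

This document records the mathematical definitions, numerical choices and
estimator-calibration findings behind `laminarcfc`.  It is written so that
every quantity the package reports can be reproduced from the equations and
parameters given here.

## 1. Neural mass model

Each neuronal population `n` is a second-order neural mass: its mean
postsynaptic potential `x_n(t)` (mV) obeys

```
ẍ_n = −2 g_n b_n ẋ_n − g_n² x_n + G_n g_n [ p_n(t) + Σ_m Γ[m, n] S_m(x_m) ]
```

with synaptic gain `G_n` (mV), rate constant `g_n` (1/s), damping `b_n`
(dimensionless), external drive `p_n(t)` and the signed effective
connectivity `Γ[m, n]` (from source `m` to target `n`).  The firing-rate
nonlinearity is the population sigmoid

```
S(x) = e0 / (1 + exp(r (v0 − x)))        e0 = 2.5 /s, v0 = 6 mV, r = 0.56 /mV.
```

Excitatory populations use `G = 3.25` mV; inhibitory ones `G = 22` mV, with
sign constraints on outgoing weights enforced at model construction.  An
isolated underdamped population rings at `g·sqrt(1−b²)/(2π)` Hz, so `g` sets
the population's band.  The default column has 14 populations (excitatory and
inhibitory pairs across layers L2/3, L4, L5, L6 plus specific subtypes)
wired by a fixed laminar connectivity; the full matrix ships with the package
(`laminarcfc topology` prints its graph measures).  Setting `linear=True`
replaces `S` by the identity, a control in which the system is linear and can
produce no cross-frequency coupling.

Written in first-order form (`x_n`, `ẋ_n` per population), the default column
is a system of 28 coupled first-order SDEs.

## 2. Stochastic integration

The drive is `p_n(t) = p̄_n + σ_n ξ_n(t)` with independent white noises
`ξ_n`.  The system is integrated with the local linearization (LL) scheme:
over each step the drift is linearized at the current state and the linear
SDE is solved exactly via an augmented matrix exponential, which gives the
deterministic propagation and the exact covariance of the additive-noise
integral in one operation.  LL is A-stable on the stiff, oscillatory regimes
used here, where Euler–Maruyama at the same step either damps or detonates
the gamma-band dynamics.

Defaults: `dt = 1e-4` s, burn-in 2 s (discarded), divergence guard at
|x| > 1e6.  Seeding uses `numpy` `SeedSequence`, so every simulation is
reproducible from `(model, config)`.

The inner step loop has a compiled fast path (numba, Padé-13
scaling-and-squaring matrix exponential) with a pure-numpy fallback that is
used automatically when numba is absent.  The two paths consume the identical
pre-generated noise stream and agree to ~1e-12 over a full control
simulation; each path is exactly deterministic run-to-run from
`(model, config, seed)`.  The fast path changes wall time (~11×), not the
science.

Analyses run on the trajectory decimated to 1 kHz (factor 10 with
anti-aliasing): every spectral feature of interest lies below 120 Hz, and the
information-theoretic estimators gain nothing from oversampled, strongly
autocorrelated samples while their cost scales linearly in `T`.

## 3. Band decomposition

Band series are obtained by zero-phase FIR bandpass filtering (Hamming
window, order set from the transition bandwidth, `filtfilt`) followed by the
Hilbert analytic signal.  From the analytic signal we take instantaneous
phase, amplitude (envelope) and frequency (phase derivative).  Canonical
bands: delta 0.5–4, theta 4–8, alpha 8–12, beta 12–30, gamma 30–120 Hz.

## 4. Coupling measures

All information quantities are in bits.  For population pair `(k, l)` and a
coupling family (e.g. PAC: source theta phase → target gamma amplitude):

* **Midx (modulation index)** — mean amplitude per phase bin, measured as the
  KL divergence of the normalized profile from uniform (optionally
  normalized by `log2 n_bins`).
* **ESC (envelope-to-signal correlation)** — Pearson correlation between the
  source band series and the target amplitude envelope.
* **cMI** — conditional mutual information `I(src; tgt | M)` between
  instantaneous features.
* **cTE (conditional transfer entropy)** — lag-averaged
  `(1/|L|) Σ_τ I(src_{t−τ}; tgt_t | M_t)` with `M` at minimum the target's
  own present feature, i.e. the directed, conditioned excess information the
  source past carries about the target beyond the conditioning set.

Two cTE/cMI backends are provided:

* `histogram`: features are discretized (phases into equal circular bins,
  amplitudes into quantile bins; 8 bins by default) and plug-in entropies
  with Miller–Madow correction are combined.  Negative plug-in estimates are
  clipped to zero.
* `gaussian`: the Gaussian-copula estimator.  Each series is rank-transformed
  to uniform and mapped through the standard normal quantile function;
  phases are embedded as `(cos φ, sin φ)` column pairs.  All (conditional)
  mutual informations are then closed-form functions of covariance
  log-determinants.

### 4.1 Calibration pathology of the histogram backend (why `gaussian` exists)

Significance is assessed against circular-shift surrogates of the source
series (Section 5).  For unconditioned statistics (Midx, ESC, plain MI) this
null is well calibrated: on independent white-noise pairs the surrogate
z-scores are standard normal and the pre-FDR rejection rate of |z| > 1.96 is
~5% (this is re-measured from scratch by `scripts/acceptance.py`, key `t4`).

For the *conditioned* histogram cTE the surrogate null is structurally
miscalibrated on dependent conditioning sets.  The plug-in bias of each
entropy term depends on the number and occupancy of jointly occupied
histogram cells.  Circularly shifting the source changes the *dependence
structure* between source and conditioning variables: the aligned source
concentrates probability in fewer joint cells than any shifted copy, so the
surrogate ensemble carries a different (larger) upward bias than the observed
statistic.  The difference does not vanish with Miller–Madow correction,
fewer bins, longer series or lag thinning, and it cannot be reproduced by
any internal permutation of the observed sample (we verified that
within-stratum permutations of the source, which preserve the conditioning
margins exactly, produce a null centred far from the circular-shift null).
Empirically this produced |z| up to ~20 on *known-null* edges.  Because no
bias correction computable from the aligned sample alone can match a null
defined by re-dependencing the data, we treat the histogram backend as
unsuitable for surrogate-calibrated *conditional* inference and use it only
where its plug-in algebra is the point (the exact cascade decomposition
identity, Section 7) or where no conditioning is involved.

The Gaussian-copula backend does not have this pathology: the rank transform
commutes with circular shifts (`ranks(roll(x)) == roll(ranks(x))`), so the
observed statistic and every surrogate statistic are computed from an
identically-margined Gaussian model, and the null is exactly exchangeable.
On known-null edges its surrogate z-scores are standard normal.  The cost is
that it only detects dependence expressible through correlations of the
copula scores (including the `cos/sin` phase embedding); it is therefore a
conservative estimator, which is the right trade-off for significance
claims.

### 4.2 Conditioning sets

`estimate_cfc` supports conditioning policies: `none`, `target_past` (the
target's own present feature; the minimal transfer-entropy conditioning),
`exclude_source`, `all`, or an explicit list.  For the three-population
control analysis the cTE conditioning is the *mediation set*: the target's
own gamma amplitude plus the remaining population's theta phase.  The
target's own theta phase is deliberately **not** conditioned on: in this
model the gamma-amplitude modulation is produced locally by the target's
slow voltage component, so the target theta phase is the *mechanism* of the
coupling, not a confound; conditioning on it would explain away every
genuine edge by construction.  The remaining population's phase is the
correct confound control, because common drive is exactly the case where a
third population's phase accounts for the apparent source→target relation.

## 5. Surrogate significance

The null for every coupling statistic is built by circularly shifting the
source series: offsets are drawn uniformly from `[0.1 T, 0.9 T)`, which
preserves the source's autocorrelation and marginal exactly while destroying
its alignment with the target.  Each (pair, surrogate set) uses
`SeedSequence([seed, pair_index])`, so pairs are independent and
reproducible.  From `n` surrogate draws we form `z = (stat − μ̂)/σ̂`, a
two-sided Gaussian p-value, and control the false discovery rate across the
tested matrix with Benjamini–Hochberg at `α = 0.05`; an entry is reported
significant only if it passes both |z| > z_{α/2} and the FDR mask.

## 6. Three-population control analysis

The control model has three excitatory populations: population 2 rings in
theta (4.4 Hz) and drives populations 1 (50 Hz) and 3 (57.8 Hz); 1 and 3 are
unconnected, so any 1↔3 coupling estimate is spurious common drive.

A purely linear target cannot show phase–amplitude coupling — a slow input
superposes with, but does not modulate, the gamma response.  The driven
populations therefore carry an excitatory self-connection and are
parameterized around an operating point `x* = 3.6` mV where the sigmoid
curvature |S″| is maximal: `g` is solved per population (Brent) so the
effective damped frequency at `x*`,
`sqrt(g² − G g c S′(x*) − (g b)²)/(2π)` with `c` the self-weight, equals the
nominal band frequency, and the mean drives are solved so the coupled fixed
point sits exactly at `x*`.  The slow input then modulates the gain of the
self-loop, producing genuine theta-phase → gamma-amplitude coupling on the
anatomical edges 2→1 and 2→3.

Noise enters per population, with equal σ.  The two relayed theta
components are then near-perfect copies (phase coherence > 0.95), so the
unique information a genuine source phase carries beyond the mediating copy
is small, of order `1 − coherence²`.  Raising the driven populations' noise
to decorrelate the copies was tried and rejected: target-noise excursions
beyond the sigmoid's curved region destroy the modulation mechanism before
the coherence usefully drops.  The honest lever is analysis **duration** —
the Gaussian-copula cTE z-score of a fixed small effect grows as `sqrt(T)` —
and the control analysis therefore runs on 168 s of signal.  Because
continuing to lengthen a *single* record eventually revives the residual
common-drive bias (see the finite validity window below), the remaining
power comes from **realization averaging**: the control preset simulates
three independent 168 s realizations (seeds `seed`, `seed+1`, `seed+2`) and
averages each measure's statistic *and* each surrogate draw across them.
Since realizations are independent and share the same circular offsets per
pair, an averaged surrogate draw is itself a draw from the null of the
averaged statistic, so the z-test stays calibrated; a real effect's z grows
as `sqrt(n_realizations)` while the per-realization bias does *not*
accumulate the way it does with one longer record.

Two further design constraints follow from the same physics:

* **Lag span.**  The cTE lag average covers 200 ms (40 lags, 5 ms apart),
  about one theta cycle.  Phase can causally modulate amplitude only within
  a cycle, so longer spans dilute the true effect; worse, the
  mediator-phase conditioning blocks the common drive only over the phase's
  own coherence time, so lags beyond a cycle *accumulate* common-drive bias
  (measured: with a 1000 ms span the spurious 3→1 z reaches 2.3 at 168 s and
  7.2 at 420 s; with the matched 200 ms span the spurious entries stay
  within the null at 168 s).
* **Finite validity window.**  Because the residual common-drive bias also
  grows with `sqrt(T)` while staying bias-sized, the architecture recovery
  has a duration window: long enough for the true edges (≳ 2 min at these
  parameters), not so long that the residual reaches significance (the
  matched lag span pushes this boundary beyond 168 s; at 420 s a spurious
  entry approaches z ≈ 3).  This is a property of instantaneous-conditioning
  transfer-entropy estimation generally, not of this implementation; richer
  conditioning sets (mediator theta amplitude, lag-shifted mediator phases)
  were tested and did not improve it.

Expected pattern (and what `run_control3pop` reports): at the elevated-noise
operating point the pairwise measures (ESC, Midx) mark the genuine edges
*and* the spurious 1↔3 pairs, while the mediation-conditioned
Gaussian-copula cTE marks only 2→1 and 2→3.

**Linear control.**  `run_linear_control` rebuilds the same chain with
`S(x) = x` (g and drives re-solved with `S(x*) = x*`, `S′(x*) = 1`, so the
nominal frequencies are preserved).  A linear system superposes its inputs:
the theta drive shifts but cannot modulate the gamma response, so no PAC
measure reaches significance and the gamma carrier has no sidebands at
`f_gamma ± f_theta`.  Because the gamma resonance here is broader (~10 Hz at
damping b = 0.1) than the 4.4 Hz offset, raw-spectrum sidebands are
unresolvable even when present; the equivalent resolvable observable is the
gamma-envelope spectrum, where amplitude modulation at the driver frequency
appears as a line at 4.4 Hz.  Both contrasts are reported in dB against the
local spectral background, with a pre-registered 3 dB (factor 2) detection
limit.

## 7. Cascade decomposition

For an indirect coupling `1 ⇝ 3` relayed by `2`, the plug-in chain rule gives
the exact identity

```
TE(1→3) = TE(1→2) + TE(2→3) + R
```

when all four terms are evaluated on the same discretized sample rows and a
shared truncation; the package computes the residual `R` so the identity gap
is zero to machine precision (this is asserted in the tests and re-measured
in the acceptance run).  Ten regression models relate the indirect PAC
`theta(1) → gamma(3)` to 16 direct predictor terms across a relay-strength
sweep, scored by OLS R².  Smooth but non-monotone parameter dependencies are
summarized by the Fourier nonlinear correlation: the best K-term Fourier
series fit (seeded multi-start nonlinear least squares) and
`r_nl = |corr(Y, Ŷ)|`, with an optional permutation p-value.

## 8. Connectivity topology

On `W = |Γ|` with self-loops removed: Fagiolo's weighted directed clustering
coefficient (weights normalized by the maximum, cube-root geometric-mean
triangle intensity over all directed triangle motifs, normalized by the
degree expression), local efficiency (inverse shortest path lengths on
`1/W` via Dijkstra, averaged over each node's neighbourhood), and
betweenness centrality with fractional counting of shortest paths.  Roles of
significant couplings (direct = anatomically connected, indirect = not) are
compared on these node measures with two-sample t-tests.

## 9. Parameters chosen by this implementation

These values are implementation choices (not dictated by the model
equations) and were fixed before the corresponding confirmatory analyses:

| Parameter | Value | Rationale |
|---|---|---|
| analysis rate | 1 kHz | all features < 120 Hz; estimator cost |
| histogram bins | 8 (phase and quantile) | bias/variance balance at desk-scale T |
| cTE lag horizon (generic) | 100 lags, thinned ×10 (1 s at 1 kHz) | broadband default for `estimate_cfc` |
| cTE lag horizon (control chain) | 40 lags, 5 ms apart (200 ms) | one theta cycle: the causal timescale of phase→amplitude modulation (Section 6) |
| control analysis duration | 168 s | sqrt(T) power for the small conditional effect vs. common-drive bias window (Section 6) |
| control realizations | 3 independent × 168 s, averaged | sqrt(R) power without extending any single record into the bias window (Section 6) |
| surrogate offsets | U[0.1T, 0.9T) | avoid near-identity shifts |
| α, correction | 0.05, BH-FDR per matrix | convention |
| control chain coupling | 300 | PAC depth vs. fixed-point stability |
| control self-coupling | 400 | gamma-band effective frequency solvable and strongly curved operating point |
| control noise | σ = 2, equal per population | asymmetric noise destroys PAC before decorrelating the relay (Section 6) |
| sideband detection limit | 3 dB | factor-2 over background, fixed before measurement |
| operating point | 3.6 mV | maximum |S″| of the standard sigmoid |
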