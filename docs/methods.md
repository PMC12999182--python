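# Methods

This note documents the models, estimators and numerical choices behind
`cardionet`, and what the synthetic study conditions do and do not
establish about real recordings.

## Problem setting

Four beat-indexed variability series form the nodes of a directed network:
respiration amplitude (R), heart period (H), mean arterial pressure (M)
and arterial compliance (C).  The goal is *direct* (conditional) causality:
the information flowing from one node's past to another node's present
beyond the target's own past **and** beyond the remaining two nodes, so
that mediated pathways (e.g. R→H→M) are not mistaken for direct links.
The conditional transfer entropy from source X_i to target X_j given the
rest Z is

    T_{i→j|Z} = I(X_{j,n} ; X_{i,n}^- | X_{j,n}^-, Z_n^-)   [nats].

Because the sampling grid is one heartbeat, several physiological
interactions (respiratory gating of the same beat, the fast vagal
baroreflex arm) act *within* a beat and appear at lag 0.  Zero-lag effects
are admitted only along a fixed directed acyclic graph R→H→M→C (all six
forward pairs), which keeps the simultaneous system recursive and
identifiable and encodes the collider rule: when predicting a target, only
its DAG parents may enter at lag 0 — conditioning on a same-beat
*descendant* would open a spurious path.

## Model-based estimator (extended Granger causality)

The linear route models the four series jointly as an extended vector
autoregression whose lag counter starts at zero,

    X_n = Σ_{k=0..p} A_k X_{n−k} + U_n ,

with A_0 constrained to the DAG edges.  Each target equation is fitted by
ordinary least squares; for the link i→j the *restricted* regression drops
every term in X_i (its lags 1..p and, where DAG-permitted, its lag-0
term).  With residual variances σ²_jj (unrestricted) and λ²_jj
(restricted),

    F_{i→j|Z} = ln(λ²_jj / σ²_jj),    T_{i→j|Z} = F/2 ,

the factor 2 being exact for jointly Gaussian processes.  Implementation
choices that matter:

* **Identification.**  Per-target OLS, not a two-stage residual rotation:
  the DAG makes the zero-lag system recursive, so each equation is
  identifiable on its own.
* **Common sample window.**  All fits of one subject use rows p..N−1 and
  residual variance denominator N−p, so restricted and unrestricted
  variances are computed on identical samples and the restricted design is
  a column subset of the unrestricted one.  This guarantees F ≥ 0 on every
  dataset, and makes T = F/2 an exact identity rather than an asymptotic
  one.
* **Order selection.**  One shared order per subject and condition,
  chosen by AIC = N_eff·ln det Σ̂(p) + 2·(number of free coefficients)
  over p ∈ [1, 10] on a common window (rows p_max..N−1).  The range is
  aligned with the model-free maximum lag L = 10.  The restricted model
  inherits the selected order.

## Model-free estimator (kNN conditional transfer entropy)

The nonlinear route estimates the same quantity without a model, using
k-nearest-neighbour statistics under the maximum (Chebyshev) norm in the
Kraskov–Stögbauer–Grassberger fixed-radius scheme: for each sample the
distance ε/2 to its kth neighbour in the highest-dimensional joint space
[X_{j,n}, V_n] fixes the search radius, strictly-smaller-than range counts
are taken in the three projected spaces, and digamma terms combine them:

    T = ψ(k) + ⟨ ψ(N_{VjVz}+1) − ψ(N_{XjVjVz}+1) − ψ(N_V+1) ⟩ .

Past states are represented by a **non-uniform embedding**: candidates are
all (node, lag) pairs up to L = 10 (lag 0 offered only to DAG parents of
the target; the target's own present is never a candidate).  Greedy
selection repeatedly admits the candidate with the highest conditional
mutual information given the current embedding, *iff* that CMI exceeds the
95th percentile of Ns = 100 CMIs recomputed after independently shuffling
the candidate's and the target's samples; the first rejection stops the
search.  The transfer entropy toward a target is then the CMI between the
target's present and the admitted source components given the other
admitted components, and is exactly zero when no source component was
admitted.  Defaults k = 10, L = 10, Ns = 100, α = 0.05; series are
standardized to unit variance first.

Properties worth knowing:

* **Selection effect in admission.**  The admitted candidate is the
  *maximum* over ~40 candidates, but its threshold comes from a
  single-candidate shuffle null, so under a global null the first
  admission fires far more often than α (measured: ~88% of white-noise
  runs admit at least one component; admitted null components carry < 0.1
  nats).  This inflation does not invalidate link inference, because the
  final significance test re-runs the identical selection pipeline on
  every surrogate — the null distribution inherits the same inflation.
  It does mean a non-empty embedding alone is not evidence of coupling.
* **Bias.**  kNN entropy estimates are biased downward at N = 300; the
  model-free T systematically *underestimates* the model-based T for
  strong links (measured ≈ 0.08 nats on the strongest default link at
  N = 300, shrinking with N).  Absolute MB and MF values are therefore
  not directly comparable; agreement is qualitative (presence, ranking),
  which is exactly how the two estimators are combined here: a link
  significant under MF but not MB indicates nonlinear coupling.
* **Negative estimates** for weak couplings are reported unclipped;
  significance is delegated to the surrogate test.
* **Ties.**  After standardization a seeded uniform jitter of amplitude
  1e-10 is added to every coordinate; strict-inequality counts are then
  almost surely well defined even for discretized inputs.
* **Exactness.**  Neighbour counts are exact (brute-force Chebyshev
  distance matrices below 1500 samples, a kd-tree above); an optional
  numba kernel accelerates the matrix path without changing a single
  count, and permuted (shuffle-null) evaluations reuse the cached
  distance matrices by row/column reindexing.

## Surrogate significance and degrees

Per subject and link, the observed measure is compared with the same
measure on 100 artificially decoupled datasets and deemed significant if
it exceeds their 95th percentile (linear interpolation between order
statistics):

* **MB path** — every node column is replaced by an independent iAAFT
  surrogate (exact amplitude distribution, spectrum preserved to
  convergence tolerance 1e-8, at most 100 iterations), destroying all
  cross-links at once.
* **MF path** — the target column is circularly rotated by a uniform
  random shift of at least 20 beats, others untouched; the embedding is
  re-selected for every surrogate so that the null includes selection
  variability.  This re-selection dominates the package's runtime and is
  the reason the pipeline exposes `--mb-only` and `--n-surrogates`
  overrides for desk-scale runs.

At cohort level the degree of significance s is the percentage of
subjects passing the test, classed as none (< 25), low (25–50), medium
(50–75) and high (75–100); "low" is conventionally treated as not
statistically relevant.

Measured calibration: under a four-node independent-AR null the MB path
rejects at ≈ 0.04–0.05 (nominal 0.05), inside the binomial band.

## Cohort comparison

REST-vs-HUT contrasts use the paired Wilcoxon signed-rank test: zero
differences dropped; exact tie-aware enumeration of the signed-rank
distribution (convolution over doubled midranks) for n ≤ 25 pairs, a
continuity- and tie-corrected normal approximation beyond.  The family of
12 links per estimator is corrected by Benjamini–Hochberg step-up at
q = 0.05 (families kept separate per estimator); direction is the sign of
the median HUT−REST difference.  Time-domain markers (per-node mean and
SD, denominator N−1, computed on raw series) are compared the same way.

## Preprocessing

Slow drifts are removed with an order-4 Butterworth high-pass applied
forward and backward (`filtfilt`, reflective "even" padding), then each
column is de-meaned.  The cutoff given in Hz (default 0.0156) is converted
to cycles/beat through the subject's mean beat duration — the only
dimensionally consistent reading for beat-indexed series without
resampling (synthetic data uses 1.0 s).  Two caveats are documented
deliberately: (i) no finite-order IIR filter is exactly idempotent — a
second pass alters a broadband series by ~3% of its SD via the transition
band (pure pass/stop-band content is untouched); (ii) zero-phase edge
transients extend ~1/cutoff samples, so single-frequency attenuation is
assessed on the sinusoidal component (projection), not on edge maxima.

## Synthetic study conditions

No recordings ship with the package; the generator defines the study
conditions.  It simulates a stable four-node extended VAR with Gaussian
innovations, evaluated within each beat in DAG order so zero-lag links are
realized exactly, with a 500-sample burn-in.  The default REST topology
carries the canonical pathways (coefficients in parentheses, lag 0 / lag
1): R→H (0.4/0.3, respiratory sinus arrhythmia), M→H (–/0.3, baroreflex),
H→M (0.4/–, feedforward), R→M (–/0.3), M→C (0.4/–), H→C (0.3/0.3),
R→C (0.3/–), C→M (–/0.15, weak feedback); R is an AR(2) oscillator near
0.25 cycles/beat (poles at radius 0.8), H, M, C carry AR(1) 0.4, noise
SDs 1.0/0.8/0.8/0.8.  The HUT variant halves the vagally mediated links
(R→H, H→C) and raises the pressure-related ones (M→H 0.42, R→M 0.45,
C→M 0.22) — values chosen once for stability (companion spectral radius
0.94) and a physiologically sensible direction of change, giving the
group comparison a known answer.  The nonlinear variant replaces R→H by a
standardized quadratic coupling, which is *uncorrelated* with the source
and hence invisible to the linear estimator but visible to the kNN one.
Between-subject variability is a multiplicative jitter (SD 10%) drawn
once per coefficient per subject and applied to both conditions, so the
configured REST→HUT shift is preserved within subject; unstable draws are
redrawn (max 100).

What the generator does **not** emulate: uneven beat timing, measurement
artifacts and ectopy, non-Gaussian marginals, slow non-stationarity
within a window, and any physiologic closed-loop not in the configured
topology.  Passing tests therefore demonstrate correctness of the
estimators and pipeline under the stated conditions, not clinical
validity on human data.

## Problem sizes used by the test suite

Checks are sized to run on one CPU: long-sample estimator oracles use one
realization of N = 10^6 (model-based) and N = 10^4 (kNN closed form);
surrogate calibration uses 200 null replicates for the model-based path
and a reduced replicate count with Ns = 25 embedding shuffles for the
model-free path (whose per-replicate cost is ~100 embedding
re-selections); ground-truth recovery uses the default 20-subject cohort;
the nonlinear MB-vs-MF contrast uses 12 subjects with 50 surrogates.
These sizes are the package's own choices and are stated here so they can
be scaled up verbatim.

## Known limitations

* Instantaneous effects are *assigned*, not inferred: the zero-lag DAG is
  a modelling convention; a wrong convention redistributes within-beat
  information between links.
* The MB estimator assumes joint Gaussian stationarity; T = F/2 is exact
  only under that assumption.
* The MF admission step is anti-conservative in isolation (see above);
  interpret embeddings only through the surrogate-calibrated link test.
* Wilcoxon exact enumeration is O(n·Σrank); beyond 25 pairs the normal
  approximation is used.
* The iAAFT surrogate preserves the periodogram approximately (relative
  RMS < 5% in tests), not exactly; the time-shift surrogate assumes
  approximate circular stationarity of the target.
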