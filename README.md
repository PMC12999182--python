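# cardionet

Direct-causality analysis of beat-to-beat cardiovascular variability
networks.

Short-term cardiovascular regulation — the baroreflex, respiratory sinus
arrhythmia, mechanical feedforward, and the less explored couplings of
arterial compliance — leaves its fingerprint in the joint beat-to-beat
variability of heart period (H), mean arterial pressure (M), arterial
compliance (C) and respiration (R).  `cardionet` reconstructs the
*directed* network among these four nodes from ~300-beat stationary
segments, for physiologists and methodologists who want conditional
(direct, not mediated) coupling estimates with honest significance
testing, under resting and orthostatic-stress conditions.

## What it computes

The central quantity is the **conditional transfer entropy** from a
source X_i to a target X_j given the remaining network Z:

    T_{Xi→Xj|Z} = I(X_{j,n} ; X_{i,n}⁻ | X_{j,n}⁻, Z_n⁻)   [nats]

estimated two ways:

* **Model-based (MB)** — an extended vector autoregression
  X_n = Σ_{k=0..p} A_k X_{n−k} + U_n whose lag-0 coefficients are
  constrained to the within-beat DAG R→H→M→C.  The conditional Granger
  causality F = ln(λ²/σ²) compares restricted and unrestricted residual
  variances; for Gaussian processes T = F/2 exactly.
* **Model-free (MF)** — Kraskov-style k-nearest-neighbour entropy
  estimation (Chebyshev norm, fixed search radius from the joint space)
  on non-uniformly embedded pasts: the most informative (node, lag)
  components are admitted greedily, gated by a shuffle-surrogate test
  (k = 10, L = 10, Ns = 100, α = 0.05).

Each link is validated per subject against 100 surrogates (iAAFT for MB,
target time-shift for MF, 95th-percentile rule), aggregated into cohort
significance degrees, and paired conditions are compared with Wilcoxon
signed-rank tests under Benjamini–Hochberg FDR control.  A seeded
synthetic generator provides paired REST/HUT cohorts with known
ground-truth couplings (including zero-lag and optional quadratic links)
for validation end to end.  See `docs/methods.md` for the full model
description and design choices.

## Worked example

```python
import cardionet as cn

series = cn.generate_subject(cn.default_rest_config(), seed=7)   # 300 beats
pre = cn.standardize(cn.highpass_detrend(series), "unit_variance")
res = cn.ExtendedVAR(pre).fit()      # AIC-selected extended VAR
print(res.summary())
```

```
Extended VAR conditional causality (model-based)
  subject: S00  condition: REST
  order p = 2 (AIC), effective samples = 298

source target        F        T
     H      R   0.0004   0.0002
     M      R   0.0135   0.0067
     C      R   0.0138   0.0069
     R      H   0.3312   0.1656
     M      H   0.0579   0.0290
     C      H   0.0098   0.0049
     R      M   0.1195   0.0597
     H      M   0.1833   0.0916
     C      M   0.0186   0.0093
     R      C   0.1943   0.0971
     H      C   0.1509   0.0755
     M      C   0.2374   0.1187
```

Reading the table: F is the extended conditional Granger causality and
T = F/2 the transfer entropy in nats.  The strong entries are exactly the
couplings this synthetic subject was generated with — respiratory sinus
arrhythmia (R→H, 0.17 nats), the feedforward H→M, the pressure and
respiratory drive of compliance (M→C, R→C, H→C) and the baroreflex M→H —
while the links absent from the ground truth (e.g. H→R, C→H) stay near
zero.  Whether a small value such as C→M (0.009 nats) is real is decided
by the surrogate test (`cn.link_significance("mb", pre, "C", "M", ...)`),
not by its magnitude.

The model-free estimator has the same surface
(`cn.KnnCausality(pre).fit(seed=0)`), and a full cohort study — simulate,
preprocess, estimate MB + MF, surrogate-test every link, compare REST vs
HUT — is one call (`cn.run_pipeline(cn.PipelineConfig(...))`) or one
shell command:

```sh
cardionet run-all --n-subjects 20 --seed 12345 --mb-only --out results/
```

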