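# igsense

Pipeline for studying **infants' sensitivity to information** — the degree
to which an infant's looking time tracks the trial-by-trial information
gain of visual events — and its relation to later cognitive outcomes.

Written for developmental and computational cognitive scientists who run
probabilistic cue–target eye-tracking paradigms: 16 sequences × 15 trials
in which a stimulus reappears in one of four screen quadrants with 100%,
80% or 60% predictability. Because participant-level datasets from such
studies are usually restricted-access, the package ships a first-class
synthetic cohort generator, so every stage of the analysis can be
developed, validated and power-analyzed by parameter recovery.

## What it computes

1. **Task designs** with the standard balance constraints (equal modal
   quadrants, no consecutive repeats, exact predictability proportions).
2. **Ideal-learner trial metrics.** A Dirichlet-categorical learner with
   add-one updating assigns each trial its information gain
   IG = D_KL(posterior ‖ prior), its surprise −ln p(observed), and the
   sequence predictability ln 4 − H(predictive), all in nats. From a
   uniform 25% belief, one observation yields a 40%/20%/20%/20%
   predictive — the canonical worked example, reproduced exactly.
3. **Synthetic cohorts**: heterogeneous infant parameters, looking times
   in the 1500 ms target window, look-away truncation, saccadic latencies
   faster on predictable trials, and IQ outcomes (FSIQ + VCI/VSI/WMI)
   linked to sensitivity through linear, exponential or threshold links.
4. **Hierarchical Bayesian sensitivity estimates.** Looking time is
   regressed on z-scored IG, surprise, predictability and trial number
   with per-infant random intercepts and random IG slopes
   (collapsed-Gibbs sampler, optional right-censoring at the window
   bound; split-Rhat/ESS diagnostics). The standardized posterior-mean
   slope β_IG + u₁ᵢ is the infant's *sensitivity to information*.
5. **Outcome models** after a 3-SD outlier screen: group-level looking
   and saccade mixed models, OLS and exponential curiosity→IQ fits, a
   penalized-spline additive model FSIQ ~ s(sensitivity) + SES with exact
   REML smoothness selection, tertile-stratified fits, hierarchical
   partial-R² decomposition and per-subindex models.

See `docs/methods.md` for the models, priors, defaults and limitations.

## Worked example

```python
import igsense as ig
from igsense.hier import estimates_to_frame
from igsense.outcomes import screen_sensitivity

design  = ig.generate_design(seed=1)                  # 16 balanced sequences
metrics = ig.compute_design_metrics(design)           # 240 trials of IG/surprise/pred.

infants = ig.simulate_infants(n=90, seed=2)           # cohort with attrition
records = ig.simulate_study(design, metrics, infants, seed=3)

est, coefs, diag = ig.fit_hierarchical(records, metrics, ig.HierFitSettings(seed=5))
sens = estimates_to_frame(est)

outc = ig.simulate_outcomes(infants, ig.OutcomeConfig(link="exponential"), seed=4)
ok = {p.infant_id for p in infants if p.usable and p.followed_up}
kept, removed = screen_sensitivity(sens)
gam = ig.fit_gam_outcome(kept, outc[outc.infant_id.isin(ok)])
```

The hierarchical fit prints population coefficients on the looking-time
scale (ms per SD of each predictor):

```
              term   mean    sd   q2.5  q97.5
         intercept 931.92 16.66 898.46 964.69
information_gain_z  76.44  9.13  59.17  94.92
        surprise_z -18.92  5.38 -29.53  -8.47
  predictability_z -43.00  5.27 -53.33 -32.81
       trial_index  -7.69  1.60 -10.82  -4.62
rhat_max 1.0026  ess_min 2103
```

— trials offering more information are looked at longer (+76 ms/SD here,
generated at 66 ms/SD population mean), unpredictable sequences attract
longer looks, and looking declines over trials. Downstream, on the 58
analyzable synthetic children:

```
additive model:    F = 8.53, edf = 2.31, p = 0.0003, adj. R² = 0.226, AIC = 456.67
preregistered OLS: AIC = 458.62
exponential model: b = 2.84, t = 4.63, p < 0.001, adj. R² = 0.257
tertiles:          Low  n=19 p=0.23 | Medium n=20 p=0.52 | High n=19 p=0.056
latency advantage: 175.3 ms (SE 5.0) faster on predictable trials
```

The additive model detects the convex (exponential-link) curiosity→IQ
relation planted by the generator (edf > 1, better AIC than the linear
model), the exponential re-fit recovers a positive amplitude, and the
association concentrates in the most information-sensitive tertile —
the qualitative signature this analysis is designed to detect.

The same pipeline runs from the shell:

```bash
igsense pipeline --seed 1 --outdir out/      # design → metrics → simulate →
                                             # fit-hier → screen → fit-outcome
igsense design --seed 1 --out design.json    # ... or stage by stage
igsense metrics --design design.json --alpha 1.0 --out metrics.csv
```

`out/manifest.json` records every artifact with its stage, seed and
SHA-256 checksum; identical configurations reproduce identical checksums.

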