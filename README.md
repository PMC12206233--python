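# natpipe — network attack tolerance analysis for functional connectomes

`natpipe` implements a complete, tested pipeline for quantifying the
resilience of resting-state brain networks in early Parkinson's disease
(PD) and relating it to dopaminergic integrity, lifestyle and motor
performance. It is aimed at researchers who work with ROI-level
functional-connectivity data and want a reproducible, scriptable
implementation of **network attack tolerance (NAT)** analysis — from raw
ROI time series to the mixed-model and moderation statistics — plus a
synthetic-cohort generator so every stage can be exercised and validated
without access to clinical data.

## The quantities at the core

**Global efficiency.** For a binary undirected graph with `N` nodes and
unweighted shortest-path lengths `L_ij`,

    GE = 1 / (N (N − 1)) · Σ_{i≠j} 1 / L_ij

with disconnected pairs contributing 0 and `GE = 0` for `N ≤ 1`.

**Network attack tolerance.** Each network (whole brain, plus the
somatomotor SMN, default-mode DMN, frontoparietal FPN and attention ATN
subnetworks of a 300-ROI parcellation) is proportionally thresholded at
densities 10%–50% in 5% steps (keeping the strongest `d · N(N−1)/2` edges)
and binarized. Nodes are then removed one at a time in descending order of
degree (recomputed after every removal; ties to the lowest index), and GE
is recorded after each removal. NAT is the normalized area under this
curve — the mean GE over the `N` curve points — i.e. the fraction of the
maximum possible efficiency retained during the attack. NAT lies strictly
in (0, 1) for realistic graphs.

**Lifetime physical activity.** From an activity diary, the weekly energy
expenditure per life period is

    WEE_period = Σ_i (years_i · months_i · weekly_hours_i) / (12 · years_period) · MET_i

and lifetime PA is the mean WEE of the 19–35 and 35–50 year periods.

**Statistics.** NAT observed at 9 densities per participant is modelled
with a beta-response GLMM (logit link, participant random intercepts;
fixed effects: putaminal DaT z-score, PA, education, age, sex, density and
two fMRI-sequence contrasts — 8 slopes, 198 observations for 22
participants). Composite motor/cognitive performance (GMP/GCP;
z-standardized against 39 healthy controls, duration tests sign-inverted)
is regressed on per-network mean NAT with a lifestyle moderator, and the
Johnson–Neyman technique solves analytically for the moderator range where
the conditional NAT effect is significant.

## Worked example

```python
import numpy as np
from natpipe import (CohortConfig, synthetic_atlas, generate_cohort,
                     generate_timeseries, fisher_connectivity,
                     extract_subnetwork, density_sweep, targeted_attack,
                     nat_score)

atlas = synthetic_atlas()                    # 300 ROIs, SMN/DMN/FPN/ATN labels
cfg = CohortConfig(seed=1)                   # 22 PD + 39 HC study conditions
patient = generate_cohort(cfg)[0]
ts = generate_timeseries(patient, atlas, cfg)
cm = fisher_connectivity(ts, roi_ids=atlas.roi_ids)
smn = extract_subnetwork(cm, atlas, "SMN")   # 51×51 Fisher-z submatrix
nats = [nat_score(targeted_attack(g)) for g in density_sweep(smn)]
print(f"mean SMN NAT across 9 densities: {np.mean(nats):.3f}")
```

This prints (deterministically for seed 1):

```
mean SMN NAT across 9 densities: 0.168
```

i.e. this synthetic patient's somatomotor network retains on average 16.8%
of its maximum possible efficiency while its hubs are being removed, the
single number per (participant, network) that enters the moderation
models. At the individual densities the same run gives NAT = 0.024 at 10%
density (128 edges), 0.148 at 30% and 0.378 at 50% — denser graphs
tolerate attack better, which is why density is a covariate in the GLMM.

## End-to-end runs

The `analysis/` scripts narrate the full study-scale analysis
(`01_simulate_cohort.py` → `06_sensitivity_sequence2.py`), writing all
tables under `results/`. The same stages are available as a CLI:

```
natpipe all --out results_run --seed 1          # end-to-end bundle
natpipe simulate|connect|attack|score|fit|report ...   # staged, file-based
natpipe sensitivity --sequence 2 ...            # single-sequence subgroup refit
```

On the default synthetic cohort (seed 1) the fitted models recover the
planted structure: higher putaminal DaT integrity predicts higher SMN NAT
(β = 0.130, p = 0.006; subgroup refit β = 0.114, p = 0.024), education
predicts ATN NAT (p < 0.001), GCP is unrelated to NAT (all model F-tests
n.s.), and the NAT→GMP association is positive but unstable at n = 22 —
the moderation fit is dominated by the heavy right tail of the PA
distribution (see `docs/methods.md` for why this is expected at pilot
scale).

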