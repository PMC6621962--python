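# bearmove

Movement-ecology analysis of GPS-collared American black bears (*Ursus
americanus*): from raw collar fixes and landscape rasters to behavioral
states, diel selection ratios, multi-scale step selection functions, a
housing-density acclimation model, and spatially weighted predictive
movement surfaces.  Everything runs on synthetic studies with stored
ground truth, so each estimator in the chain is testable against the
parameters that generated its data.

Who it is for: quantitative ecologists who want a fully scripted,
reproducible reference implementation of the multi-scale SSF workflow —
and a harness for asking when its pieces (characteristic-scale
selection, stepwise AICc, individual-based surface combination, the
Boyce index) actually recover known truth.

## The models

**Behavioral segmentation.** A 3-state hidden Markov model; state *i*
emits step lengths `l_t ~ Gamma(μ_i, σ_i)` and turning angles
`θ_t ~ vonMises(m_i, κ_i)` with latent transitions `Γ`.  Fitted by
maximizing the forward log-likelihood with random restarts; decoded by
Viterbi; states ordered by gamma mean so the longest-step state is
"movement", the only state carried into selection analyses.

**Step selection.** Each observed (used) step is paired with its
availability and fitted by matched conditional logistic regression,

    L(β) = Σ_steps log [ exp(βᵀx_used) / (exp(βᵀx_used) + exp(βᵀx_avail)) ],

with used covariates from a 30 m buffer around the step and available
covariates from a Gaussian kernel over the step whose SD σ is a
candidate scale (mean distance moved over 45 min – 6 h).  Per variable,
the σ with the lowest AICc is its characteristic scale; variables
correlated |r| > 0.7 are pruned; the final per-bear model comes from
bidirectional stepwise AICc selection.

**Diel selection.** Third-order (within-home-range) selection ratios
per 45-minute bin: used fraction of the step path in a category divided
by the category's share of the bear's seasonal 95% kernel-density home
range, bootstrapped across bears.

**Acclimation.** Across bears, the standardized impervious-surface
coefficient as a function of home-range housing density (HRHD), with
logistic / linear / intercept-only shapes ranked by AICc.

**Prediction.** Per bear, `ŵ(x) = exp(β₁x₁ + … + β_p x_p)` on
standardized rasters; per-bear surfaces are min-max rescaled and
combined with per-pixel-normalized inverse-distance weights from each
home-range centroid; validated with the Boyce index (Spearman rank
correlation of habitat-class rank vs predicted-to-expected hold-out
frequency).

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

The numbered scripts under `analysis/` run the full study end to end,
writing flat-file outputs under `results/study/`:

```bash
python analysis/01_simulate.py        # 5 bears, 60 days, 45-min fixes
python analysis/02_preprocess.py
python analysis/03_segment_behavior.py
python analysis/04_identify_seasons.py
python analysis/05_diel_patterns.py
python analysis/06_fit_ssf.py
python analysis/07_hrhd_acclimation.py
python analysis/08_build_surfaces.py
```

Selected output from a run with the default seed:

```
quality filter removed 3.89% of fixes (pooled)
built 8685 steps; diel split:
day      5551
night    3134

 bear01           20.1          119.0          476.8     # gamma means (m):
 bear02           21.6          121.0          477.3     # encamped/foraging/movement
movement-state steps: 33.6% of all steps

mean selection ratio across bins (1 = use equals availability):
agriculture    0.75
forest         1.19
residential    0.26
roads          0.97
wetland        1.09

combined-surface Boyce index (Spearman, 10 classes): 0.73
```

Reading it: the quality screen loses a few percent of fixes; the HMM
recovers the generator's encamped/foraging/movement step-length means
(truth 20/120/500 m); simulated bears prefer forest and wetland and
avoid agriculture and residential areas, as configured; and the combined
predictive surface ranks hold-out bear locations far better than chance
(the Boyce index is near zero for an uninformative surface).

The same pipeline is available as a single command
(`bearmove run-all --config cfg.yaml`) or stage by stage
(`bearmove synth`, `bearmove ssf`, ...).

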