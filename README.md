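# swaywave

Wavelet-energy classification of quiet-stance postural sway for balance
research in older adults.

During quiet standing, the trajectory of the center of pressure (CoP) under
the feet reflects how the nervous system integrates vision, vestibular and
somatosensory feedback to keep the body upright.  `swaywave` analyzes the
anterior–posterior CoP signal recorded on a force plate (30 s trials at
3000 Hz, under stable/unstable surface × eyes open/closed conditions:
SEO, SEC, UEO, UEC) and classifies subjects by the *frequency strategy* of
their sway:

1. **Preprocess** — least-squares linear detrend, then a zero-phase
   Butterworth low-pass at 10 Hz.
2. **Decompose** — a 16-level maximal-overlap (undecimated) dyadic wavelet
   transform splits the signal into details D₁..D₁₆ plus an approximation;
   detail level *j* covers the nominal band [fs/2^(j+1), fs/2^j] Hz.
3. **Relative energy** — each component's share of total coefficient energy,

   E_i% = Σ_j c_ij² / Σ_k Σ_j c_kj² × 100,

   over all 17 components; the 17-vector is the subject's feature spectrum.
4. **Cluster** — k-means (best of 50 k-means++ restarts, squared Euclidean,
   k = 3; a k-medoids variant is available) on the SEO spectra.
5. **Label** — clusters map to balance-strategy archetypes:
   *group 1* (very-low-frequency dominant: mean energy of D₁₅–D₁₆ > 20%),
   *group 2* (broadband: every D₁₁..D₁₆ in 10–20%),
   *group 3* (higher-frequency dominant: mean energy of D₁₁–D₁₂ > 20%).
6. **Model** — multinomial logistic regression of group membership (group 3
   as reference) on 24 sensorimotor and fall-related-concern covariates
   (FES-I, reaction time, eyesight, touch sensation, proprioception, muscle
   strength, falls history), with Wald standard errors, p-values and 95% CIs:

   P(Yᵢ = k) = exp(β_k0 + β_k·xᵢ) / Σ_j exp(β_j0 + β_j·xᵢ).

Because force-plate recordings of this kind are rarely shareable, the
package ships a synthetic-data generator that produces CoP trials with
prescribed dyadic-band energy profiles (the three archetypes, plus
condition-dependent shifts toward higher frequencies in challenging trials)
and covariate tables with group-dependent moments, so the entire pipeline is
testable end to end.

## Worked example

```python
import warnings
import numpy as np
import swaywave as sw

warnings.simplefilter("ignore", sw.SwayWaveWarning)

# 1. synthesize a small study: 5 subjects per balance-strategy group,
#    four 30 s quiet-stance conditions each, sampled at 3000 Hz
study = sw.generate_study(sw.SimulationConfig(n_per_group=5, seed=7))

# 2. run the full analysis (detrend + 10 Hz low-pass, 16-level wavelet
#    decomposition, k-means on the SEO energy spectra, archetype labels,
#    multinomial model on two covariates)
config = sw.PipelineConfig(predictors=["x1", "x2"])
result = sw.run_pipeline(config, trials=study.trials,
                         covariates=study.covariates.drop(columns=["group"]))

print("cluster -> archetype:", result.group_labels.mapping)
truth = [study.labels[s] for s in result.subject_groups["subject_id"]]
agree = (np.array(truth) == result.subject_groups["group_label"]).mean()
print(f"label agreement with generating groups: {agree:.0%}")

seo = result.condition_profiles.query("condition == 'SEO'")
print(seo[["group", "dominant_level", "E_D12", "E_D15"]].round(1).to_string(index=False))
```

prints

```
cluster -> archetype: {2: 'group1', 1: 'group2', 0: 'group3'}
label agreement with generating groups: 100%
 group dominant_level  E_D12  E_D15
group1            D15    8.5   25.1
group2            D15   17.2   17.7
group3            D11   25.0    6.8
```

The three clusters found in energy-spectrum space are labeled by the
archetype rules and coincide exactly with the groups the generator used:
the group-1 profile concentrates a quarter of its energy at D₁₅
(0.05–0.09 Hz), the broadband group-2 profile stays between 10 and 20% on
every level D₁₁–D₁₆, and group 3 is dominated by D₁₁–D₁₂ (0.3–1.6 Hz).
`result.coef_tables["group1"]` holds the group-1-versus-group-3 coefficient
table (variable, p-value, β, SE, 95% bounds, significance flag), and
`result.manifest` records the configuration, seed and per-stage diagnostics,
including convergence warnings when the regression sits at separation.

The same workflow is available from the shell on directories of trial CSVs
(`{subject}_{condition}.csv` with columns `time,cop_ap`):

```bash
swaywave simulate --n-per-group 15 --seed 7 --out data/
swaywave run --input data/ --out results/
```

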