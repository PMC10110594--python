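# neuroentropy

Whole-brain modelling of how serotonin-2A receptor (5HT2A-R) activation —
the pharmacological hallmark of psychedelic drugs — reshapes the entropy of
regional brain activity.

The package is aimed at computational neuroscientists studying neuromodulation
with whole-brain network models. It implements, end to end:

1. **A neuromodulated dynamic mean-field (DMF) model.** Each brain region
   *n* is a pair of coupled excitatory/inhibitory neural masses with
   NMDA/GABA-A synaptic gating, coupled across regions through a weighted
   structural connectome `C` and a global coupling `G`:

   ```
   I_n^E = W_E I_0 + w_+ J_NMDA S_n^E + G J_NMDA Σ_p C_np S_p^E − J_n^FIC S_n^I
   I_n^I = W_I I_0 + J_NMDA S_n^E − S_n^I
   r_n^{E,I} = F(I_n) = g_nm g (I_n − I_thr) / (1 − exp(−d g_nm g (I_n − I_thr)))
   dS_n^E/dt = −S_n^E/τ_NMDA + (1 − S_n^E) γ r_n^E + σ v_n(t)
   dS_n^I/dt = −S_n^I/τ_GABA + r_n^I + σ v_n(t)
   g_nm,n   = 1 + s_nm · d_n^rec
   ```

   Receptor activation is a response-gain modulation of the F–I curve:
   the gain `g_nm` of region *n* grows with its receptor density
   `d_n^rec`. With `s_nm = 0` the model is in the *placebo* condition;
   with `s_nm > 0` (default 0.025) it is in the *5HT2A* condition.
   A per-region feedback inhibitory weight `J_n^FIC` is calibrated so that
   every excitatory population fires near 3 Hz at rest. Integration is
   Euler–Maruyama (numba-compiled).

2. **Entropy topography.** Each region's stationary firing-rate distribution
   is well described by a gamma distribution; its differential entropy is the
   closed form `h = k + ln θ + ln Γ(k) + (1−k) ψ(k)` (nats) evaluated at the
   maximum-likelihood `(k, θ)`, with a Kolmogorov–Smirnov goodness-of-fit
   check. Conditions are contrasted by the relative change
   `Δh_n = (h_n^5HT2A − h_n^PLA) / h_n^PLA`, a paired Wilcoxon signed-rank
   test and Cohen's *d* across regions, and bilateral anatomical /
   resting-state-network group averages.

3. **Region partition.** A residual-seeded, random-search-plus-refinement
   partition of regions into strongly strength-dependent (S1), weakly
   strength-dependent (S2) and receptor-dependent (R1) groups, scored by the
   R² of a 7-term grouped linear model of `Δh_n` (shared constant plus one
   strength and one density term per group; quadratic strength terms for the
   strength groups).

4. **Connectome null models.** Degree- and strength-preserving surrogates
   (RAND / DPR / DSPR), a machine-checked preservation audit, six nodal
   topology metrics (betweenness, eigenvector, closeness, communicability,
   PageRank, sub-graph centrality), and the surrogate entropy-change
   experiment comparing `Δh_n` across surrogate ensembles.

5. **Synthetic data.** Generators for connected, heavy-tailed, pruned
   synthetic connectomes, receptor maps with controllable correlation to
   node strength, region metadata, and planted `Δh` datasets with known
   group structure — so the entire pipeline is testable without any
   empirical download. Empirical inputs (e.g. an AAL-90 DTI connectome and
   a PET receptor map) can be supplied as plain text files instead.

## Worked example

```python
import numpy as np
from neuroentropy import (
    ModelParameters, SyntheticSpec, calibrate_fic, simulate,
    generate_connectome, generate_receptor_map,
    region_entropies, relative_change, condition_contrast,
)

spec = SyntheticSpec(n_regions=30, density=0.3, seed=42)
con = generate_connectome(spec)          # symmetric, connected, heavy-tailed
rec = generate_receptor_map(spec, con)   # densities in [0, 20]

params = ModelParameters(seed=7)         # G=2.4, s_nm=0.025, sigma=0.01 nA
cal = calibrate_fic(con, rec, params)    # placebo calibration to 3 Hz
print(np.abs(cal.achieved_rates - 3).max())   # 0.144  (Hz, worst region)

h_pla, h_2a = [], []
for rep in range(3):
    p = simulate(con, rec, params, cal.J_fic, "placebo", seed=1000 + rep)
    d = simulate(con, rec, params, cal.J_fic, "5ht2a", seed=1000 + rep)
    h_pla.append(region_entropies(p).h)
    h_2a.append(region_entropies(d).h)
h_pla, h_2a = np.array(h_pla), np.array(h_2a)

print(condition_contrast(h_pla, h_2a))
# {'mean_h_pla': 1.990, 'mean_h_5ht2a': 3.428, 'wilcoxon_p': 1.86e-09,
#  'cohens_d_mean': 3.60, 'cohens_d_sd': 0.016, ...}

delta = relative_change(h_pla, h_2a)
print((delta.delta_h > 0).mean())        # 1.0 — entropy rises in every region
print(np.corrcoef(delta.delta_h, con.strength())[0, 1])   # 0.91
print(np.corrcoef(delta.delta_h, rec.density)[0, 1])      # 0.57
```

Receptor activation raises the entropy of every region (placebo mean
≈ 1.99 nats vs ≈ 3.43 nats under activation on this synthetic system), and
the topography of the change tracks connectivity strength more closely than
receptor density — the central qualitative behaviour of the model.

A command-line interface mirrors the library
(`neuroentropy calibrate | simulate | entropy | partition | nulls | run-all |
make-synthetic`); `run-all` writes per-region TSV tables, JSON summaries and
a reproducibility manifest.

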