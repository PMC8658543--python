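# arcnet

Cultured neuronal networks respond to chemical induction of long-term
potentiation (LTP) with a counterintuitive reorganisation: the average
correlation between neurons' firing drops globally, while a small subset of
neuron pairs — enriched for cells expressing the immediate-early genes (IEGs)
Arc and c-Fos — selectively *increases* its correlated activity.  `arcnet`
implements the full single-culture analysis that detects and quantifies this
"refinement" effect, for experimenters working with calcium imaging plus
post-hoc immunostaining of dissociated cultures, and for methods developers
who want a ground-truthed benchmark of the whole chain.

The pipeline runs from raw inputs to summary statistics:

1. **Segmentation & labeling** — nuclei are segmented from the DAPI channel;
   per-ROI marker intensities (NeuN, Arc, c-Fos) are modelled as a mixture of
   two normal distributions fitted by EM, and a cell is positive when its
   intensity exceeds μ₋ + 3σ₋ (the 99.7% point of the negative population).
   Only NeuN⁺ cells enter the network analysis.
2. **Trace processing** — per-ROI fluorescence is background/photobleach
   corrected by subtracting the mean signal of the least-active tenth of
   cells at each time point, normalised to ΔF/F, and deconvolved into spike
   trains by MAP inference under an AR(1) calcium model with a sparse
   nonnegative spike prior (fast-oopsi-style).
3. **STTC networks** — pairwise correlation uses the spike time tiling
   coefficient with Δt = 50 ms,

   STTC = ½ [ (P_A − T_B)/(1 − P_A T_B) + (P_B − T_A)/(1 − P_B T_A) ],

   where T_A is the fraction of the recording within ±Δt of any spike of A
   and P_A the fraction of A's spikes within ±Δt of any spike of B.  STTC
   values (the correlation index, CI) populate per-epoch adjacency matrices,
   node "total flow" strengths, group-wise CI means, positive/negative
   correlation-change classification and distance summaries.
4. **ICD refinement** — node-strength survival curves are fitted with a
   stretched exponential d(τ) = exp(−α τ^β); the baseline-minus-after
   difference curve is summarised by peak height, peak location, width at
   half-peak height and AUC, and a culture is called *refined* when width
   and peak location both exceed calibrated thresholds.
5. **Cohort regression** — a forward/backward stepwise linear model (partial-F
   selection, p_enter = 0.05, p_remove = 0.10) explains the per-culture
   Arc-positive percentage from firing rates, CI and refinement status.

A first-class synthetic-culture generator (`arcnet.synthetic`) provides
ground truth for every stage: network-burst spike trains across three epochs
(baseline / during / after stimulation), AR(1) fluorescence, renderable
nuclear and calcium frames, bimodal marker intensities with Arc ⊂ c-Fos
overlap, and spatially clustered Arc⁺ nuclei.

## Worked example

```python
from arcnet.pipeline import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1, spike_source="true"))
print("refined:", result.refined, "| ground truth:", result.refinement_truth)
print("network mean CI:", {k: round(v, 3) for k, v in result.ci_network_mean.items()})
print("marker %:", {k: round(v, 1) for k, v in result.marker_percentages.items()})
m = result.icd_metrics
print(f"ICD width {m.width_half_peak:.3f}, peak location {m.peak_location:.3f}")
print(result.group_ci["after:neun_arc"].to_string(index=False))
```

prints

```
refined: True | ground truth: True
network mean CI: {'baseline': 0.241, 'during': 0.208, 'after': 0.034}
marker %: {'neun': 87.0, 'arc': 10.0, 'cfos': 15.0, 'arc_or_cfos': 16.0}
ICD width 0.207, peak location 0.100
 pair_set  mean_ci  n_pairs
  Arc-Arc 0.389095       45
 Arc-NeuN 0.087090      900
NeuN-NeuN 0.017635     4005
```

The culture's mean CI collapses after stimulation (0.241 → 0.034) while the
Arc⁺–Arc⁺ pair set retains a high mean CI (0.389 over 45 pairs) — the
refinement signature — and the ICD difference-curve width (0.207) and peak
location (0.100) both clear their thresholds, so the culture is classified
refined, matching the generator's ground truth.  About 16% of neurons are
Arc and/or c-Fos positive, with Arc largely a subset of c-Fos.

The same pipeline is scriptable from the shell:

```sh
arcnet simulate --seed 3 --out sim/
arcnet run --seed 1 --out results_run/
arcnet sttc --spikes sim/spikes.csv --epoch after --out adjacency_after.csv
```

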