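# neurostates

Functional brain-network analysis of mental-state EEG: phase lag index
(PLI) connectivity, sparsity-thresholded small-world graph metrics, and
group statistics — plus a synthetic generator of six evoked mental
states (resting, fatigue, attentive, inattentive, positive, negative) so
the whole chain runs end to end with no external data.

It is written for researchers who study how mental states reorganize
scalp-EEG functional networks: you either feed it your own 10-20-montage
recordings (CSV or EDF) or simulate labeled cohorts, and it returns
connectivity matrices, small-world parameters, and t / p / Cohen's d
comparison tables.

## The analysis

1. **Signal**: per-channel baseline removal and a 1-45 Hz zero-phase
   broadband filter, then zero-phase band-passes into a low band
   (theta + alpha, 4.0-13.0 Hz) and a high band (beta, 14.0-30.0 Hz).
   Instantaneous phase comes from the analytic signal
   `psi(t) = S(t) + i H[S](t) = A(t) e^{i phi(t)}`.
2. **Connectivity**: the phase lag index between channels n and m,

       PLI = | < sign(Delta phi(t)) > |,   Delta phi wrapped to (-pi, pi],

   ranges 0 (no consistent lead/lag) to 1 (perfect phase locking) and is
   blind to zero-lag, volume-conducted coupling. PLI is averaged over
   8 s epochs, with 1 s trimmed at each record end.
3. **Graphs**: proportional thresholding keeps the strongest
   `round(s * N(N-1)/2)` connections at each sparsity `s` of a 5-40%
   grid (5% steps). Per graph: clustering `C_i = 2#_i / (K_i(K_i-1))`,
   characteristic path length `L` (harmonic mean, so disconnected pairs
   stay finite), global efficiency `E_g`, nodal local efficiency
   `NE_loc`, and the small-world indices `gamma = C/C_random`,
   `lambda = L/L_random`, `sigma = gamma/lambda` against 20
   degree-preserving (Maslov-Sneppen) rewired references; `sigma > 1`
   marks small-world topology. Metrics are averaged over the grid.
4. **Statistics**: pooled-variance two-sample t-tests with Cohen's d on
   the range-averaged metrics per band, ROI aggregation of `NE_loc` by
   lobe and by the hemispheric ROIs {F3,F7,FC1,FC5,C3,T7} vs
   {F4,F8,FC2,FC6,C4,T8}, and subjective-scale state labeling
   (six indicators x five grades, fixed rule table).

## Worked example

```python
import neurostates as ns

config = ns.PipelineConfig(profile_a="resting", profile_b="fatigue",
                           n_per_group=13, duration=30.0, seed=21,
                           n_random_realizations=10)
result = ns.run_pipeline(config, write_outputs=False)
print(result.comparison_tables["low"][["metric", "mean_a", "mean_b", "t", "p", "cohens_d"]])
```

prints (low band, resting = a, fatigue = b):

```
 metric  mean_a  mean_b      t     p  cohens_d
  sigma   1.285   0.628 12.227 0.000     4.796
  gamma   1.480   0.730 10.799 0.000     4.236
 lambda   1.119   1.076  3.461 0.002     1.357
    E_g   0.498   0.505 -2.921 0.007    -1.146
  E_loc   0.431   0.183 21.984 0.000     8.623
```

Fatigue floods the low band with unstructured coupling, so its density
rises sharply while `sigma` and `gamma` collapse: the network loses its
"economic" small-world layout — the direction of effect the analysis is
designed to expose. Each `examples/*.py` script walks one capability
(simulation, connectivity, graph metrics, group comparison, scale
labeling) and prints what the numbers mean.

A thin CLI mirrors the chain:
`neurostates simulate|connectivity|metrics|compare|run`, e.g.

```bash
neurostates run --seed 1 --out out/
```

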