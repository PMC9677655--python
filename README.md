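# patsep

Single-neuron **pattern separation** analysis for dentate gyrus (DG)
slice experiments, plus the behavioral analyses that usually accompany
them — built for labs using the paired input/output spike-train
stimulation design and for anyone who wants a tested, reproducible
implementation of its metrics.

The DG is thought to decorrelate overlapping cortical inputs before
they reach CA3. In the slice version of this question, perforant-path
afferents are stimulated with five distinct 2-s, 10 Hz Poisson spike
trains whose pairwise similarity is calibrated (mean pairwise Pearson
R = 0.76 on 10 ms binned counts), each delivered 10 times while a
granule cell's output spikes are recorded — 50 output sweeps per cell.
Pattern separation is then quantified by comparing, for every pair of
input trains *i, j*, the similarity of the inputs with the mean
similarity of the outputs they evoke:

* **R** — Pearson correlation of the binned count vectors
  (decorrelation),
* **NDP** — normalized dot product, `a·b/(‖a‖‖b‖)`, the cosine between
  count vectors (orthogonalization),
* **SF** — scaling factor, `min(‖a‖,‖b‖)/max(‖a‖,‖b‖)` (rate
  scaling),

with `S_output < S_input` (below the identity line) indicating
separation. Accompanying statistics — firing rate, burst probability,
compactness, occupancy, dispersion, per-stimulus spike probability
with 30–80% QC — characterize the output code, and the inference layer
provides the designs used with such data: ANCOVA of output on input
similarity with housing group as factor, one/two-sample t-tests, and
two-way ANOVA with Tukey HSD for immediate-early-gene (cFOS/NPAS4)
cell densities. Behavioral modules compute open-field locomotion and
zone dwell, object-exploration times, and the novel-object-recognition
discrimination index `DI = novel/(novel+familiar)`.

Because raw recordings, tracking traces and histology tables from such
studies are rarely deposited, `patsep` ships first-class synthetic
generators with the same statistical structure: calibrated correlated
Poisson input sets (mother-train thinning with a closed-form
correlation oracle), a stochastic granule-cell responder, arena
trajectories (reflected Ornstein–Uhlenbeck walk), NOR cohorts and
sparse IEG count tables. See `docs/methods.md` for models, conventions
and limitations.

## Worked example

```python
from patsep import (InputGenConfig, ResponderConfig, generate_input_set,
                    simulate_granule_cell, input_output_similarity,
                    separation_summary, spike_probability)

inputs = generate_input_set(InputGenConfig(seed=7))   # 5 trains, R = 0.76 band
cell = simulate_granule_cell(inputs.trains, ResponderConfig(seed=8))
print(spike_probability(cell).probability)
for metric in ("R", "NDP", "SF"):
    ss = separation_summary(input_output_similarity(cell, metric))
    print(metric, ss.mean_s_input, ss.mean_s_output, ss.fraction_below_diagonal)
```

Running `python examples/02_pattern_separation_metrics.py` (the same
computation with formatting) prints:

```
output sweeps: 50 (10 repetitions x 5 trains)
spike probability: 0.51 (QC pass, window 30-80%)
burst probability: 0.076
  R: mean input 0.745 -> mean output 0.311; 100% of pairs below the diagonal
NDP: mean input 0.764 -> mean output 0.337; 100% of pairs below the diagonal
 SF: mean input 0.925 -> mean output 0.843; 90% of pairs below the diagonal
```

Read: the simulated cell responds to about half the stimuli (inside
the 30–80% acceptance window used to titrate stimulation intensity).
Highly similar inputs (R ≈ 0.75) evoke much less similar outputs
(R ≈ 0.31) — every input pair falls below the identity line, i.e. the
cell separates patterns by decorrelation and orthogonalization — while
SF stays high, meaning overall spike-count scaling changes far less
than the spike arrangement.

The other scripts in `examples/` cover input-set generation, the
two-group ANCOVA design, open field + NOR, IEG densities, and the full
pipeline. A thin CLI wraps the same functions:

```bash
patsep run --seed 1 --out runs/study      # full simulated study + report
patsep generate-inputs --seed 3 --out inputs.csv
```

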