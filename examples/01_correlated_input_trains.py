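"""Generate a correlated Poisson input-train set and check its similarity.

The stimulation protocol needs five distinct 2-s, 10 Hz Poisson trains
whose mean pairwise Pearson correlation on 10 ms binned counts is 0.76.
The generator thins a common mother train and rejection-samples until
the realized correlation lands in the 0.76 +/- 0.02 acceptance band.
"""

from patsep import (
    InputGenConfig,
    bin_spike_train,
    generate_input_set,
    pairwise_input_similarity,
)

result = generate_input_set(InputGenConfig(seed=42))
print(f"calibrated copy probability : {result.copy_p:.3f}")
print(f"candidate sets rejected     : {result.n_rejected}")
for train in result.trains:
    print(f"  {train.label}: {train.n_spikes} spikes ({train.rate_hz:.1f} Hz)")

binned = [bin_spike_train(t, 0.01) for t in result.trains]
sim = pairwise_input_similarity(binned, "R")
print(f"mean pairwise R at 10 ms bins: {sim.mean:.4f} (target 0.76 +/- 0.02)")
# Each of the 10 unordered train pairs contributes one correlation; the
# mean is the quantity the stimulation protocol calibrates.
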