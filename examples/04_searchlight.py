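"""Channel-searchlight decoding: which scalp regions carry the signal?

Builds triangulation neighborhoods on the 61-channel montage, then
decodes Perceptual Baseline items from each neighborhood's 0-500 ms
window average.  The early cue signal is occipital, so occipital centers
should dominate the map.
"""

import numpy as np

import tntdecode as td
from tntdecode.synth import OCCIPITAL

montage = td.Montage.standard_61()
graph = td.build_neighbors(montage)
print(f"mean neighbors/channel: {graph.mean_neighbors():.2f} +/- {graph.std_neighbors():.2f}")

cfg = td.SimulationConfig(seed=7, cue_pattern_amp=10.0)
epochs, _ = td.simulate_participant(cfg, 0)
pb = epochs.select_condition("PerceptualBaseline")
spec = td.DecodeSpec(mode="item", n_bins=3, n_folds=3, n_iterations=3)
topo = td.searchlight_decode(pb, graph, spec, window=(0.0, 500.0), seed=8)

order = np.argsort(topo.values)[::-1]
print("top 5 centers:")
for i in order[:5]:
    print(f"  {graph.channel_names[i]:>4}: {topo.values[i]:.3f}")
occ = montage.index(OCCIPITAL)
far = np.setdiff1d(np.arange(61), occ)
print(f"occipital mean {topo.values[occ].mean():.3f} vs elsewhere "
      f"{topo.values[far].mean():.3f} (chance {1/6:.3f})")
# Above-chance accuracy concentrated at occipital centers localizes the
# early item signal to visual cortex, as a cue-perception account predicts.
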