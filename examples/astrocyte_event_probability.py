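"""Astrocyte event probability and synchrony before and after a CSD wave.

Simulates a two-photon recording in which somatic Ca2+ events appear only
after the CSD passage, scores each soma with the mean + 4 SD high-Ca2+ pixel
rule, and measures the pairwise synchrony of the soma signals.
"""

import numpy as np

from csdflow.io import TimeWindow
from csdflow.synth import TwoPhotonScenario, simulate_twophoton
from csdflow import twophoton as tp

scenario = TwoPhotonScenario(grid=64, n_somata=10, soma_radius_px=2,
                             pairwise_rho=0.10, seed=0)
movie, mask, truth = simulate_twophoton(scenario)

dff, _bad = tp.pixel_dff(movie, scenario.pre_csd_window)
rois = tp.soma_rois_from_mask(mask > 0, min_px=3, max_px=100)

pre_eval = TimeWindow(40.0, 90.0)     # event-free segment of the pre-CSD period
for label, window in (("pre-CSD", pre_eval), ("post-CSD", scenario.post_csd_window)):
    probs = tp.event_probability(dff, rois, eval_window=window,
                                 ref_window=scenario.pre_csd_window, mode="per_soma")
    print(f"{label}: mean soma P(High Ca2+) = {np.mean([p.p_high for p in probs]):.2e}")

traces = tp.soma_traces(dff, rois, scenario.post_csd_window)
corr = tp.pairwise_soma_correlation(traces, aggregate="mean_per_recording")
print(f"mean pairwise soma correlation post-CSD: {corr:.3f} "
      f"(generator target {scenario.pairwise_rho})")
print("P(High Ca2+) is the fraction of pixel-frames above each pixel's "
      "pre-CSD mean + 4 SD; post-CSD activity sits orders of magnitude above "
      "the pre-CSD noise floor, with low pairwise synchrony.")
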