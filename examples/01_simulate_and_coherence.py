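"""Simulate a coupled dyad and locate the coupling with wavelet coherence.

Builds one synthetic dyadic session with a shared 0.09 Hz oscillation on
channels A1/B2, preprocesses it (modality separation + AR pre-whitening)
and prints the band-mean coherence profile of the coupled and an
uncoupled channel pair.
"""

import numpy as np

from hypercoh import coherence, preprocess, simulate

params = simulate.SimParams(
    n_channels=3,
    duration=300.0,
    coupling_pairs=(simulate.CouplingPair(1, 2, 0.09, 2.0),),
    event_spec=simulate.EventSpec(lock_mode="always"),
    seed=42,
)
hb_a, hb_b, truth = simulate.simulate_dyad(params)
hb_a = preprocess.preprocess_series(hb_a)
hb_b = preprocess.preprocess_series(hb_b)

grid = coherence.band_grid()
means = coherence.dyad_band_means(hb_a, hb_b, grid=grid)
k = grid.nearest_band(0.09)

print(f"grid: {grid.n_bands} bands, {grid.f_min}-{grid.frequencies[-1]:.4g} Hz")
print(f"band nearest 0.09 Hz: index {k} ({grid.frequencies[k]:.4f} Hz)")
# the lowest bands keep only a handful of in-COI samples in a 5-min session
# and their means are noisy; search the peak where COI support is solid
lo = 20
for pair in [(1, 2), (1, 3), (1, 1)]:
    bm = means[pair]
    peak = lo + int(np.nanargmax(bm[lo:]))
    print(f"pair A{pair[0]}-B{pair[1]}: band-mean WTC at 0.09 Hz = {bm[k]:.3f}, "
          f"peak at band {peak} ({grid.frequencies[peak]:.4f} Hz)")

# The coupled pair's coherence at the injected band should clearly exceed the
# uncoupled pairs' chance level (~0.35-0.45 for this smoothing), and its peak
# band should sit at (or next to) the injected frequency.
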