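"""Temporal cleaning: detrend, low-pass, regress nuisance, censor spikes.

Plants a motion-like artifact hitting half the voxels in a synthetic
series and shows how DVARS censoring flags the corrupted frames after
the rest of the temporal cleaning has run.
"""

import numpy as np

import softparc as sp

spec = sp.HierarchySpec(n_networks=4, voxels_per_network=40, n_frames=200, seed=5)
ts, _ = sp.simulate_bold(spec)

# a head movement displaces each voxel differently: random signed
# amplitudes, so neither the global signal nor a shared waveform can
# absorb the artifact
rng = np.random.default_rng(8)
vals = ts.values.copy()
vals[:, 60] += rng.normal(0.0, 120.0, ts.n_voxels)
vals[:, 140] += rng.normal(0.0, 120.0, ts.n_voxels)
ts = ts.with_values(vals)

ts = sp.detrend(ts)
ts = sp.lowpass(ts, cutoff=0.1)
regressors, names = sp.build_nuisance(ts, global_signal=True)
ts = sp.regress_nuisance(ts, regressors)
print("nuisance regressors:", names)

censor = sp.compute_dvars(ts)
bad = np.flatnonzero(~censor.keep)
print(f"DVARS censored frames: {bad.tolist()} "
      f"(peak DVARS {censor.dvars.max():.2f}% of the mode-1000 signal)")

features = sp.correlation_map(ts, censor)
print(f"correlation features: {features.n} x {features.n}, "
      f"computed over {int(censor.keep.sum())} kept frames")
# The zero-phase low-pass filter smears each spike over neighbouring
# frames, so DVARS flags a small window around each planted artifact; the
# correlation matrix is then estimated from the clean frames only.
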