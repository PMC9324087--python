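"""Simulate MRF fingerprints and build the dictionary + temporal subspace.

Runs the EPG simulator for two tissues, builds a small (T1, T2) dictionary
for a 128-frame train, and shows how much of the dictionary a rank-5
temporal subspace captures.
"""

import numpy as np

import stackmrf as sm

seq = sm.SequenceParams.default(128)
print(f"sequence: {seq.n_frames} frames, TR {seq.tr_ms} ms, TE {seq.te_ms} ms, "
      f"{seq.recovery_delay_ms/1000:.0f} s recovery delay")

# two representative tissues: white-matter-like and CSF-like
for name, t1, t2 in (("short", 800, 80), ("long", 2500, 800)):
    fp = sm.simulate_fingerprint(seq, t1, t2)
    print(f"{name:5s} (T1={t1}, T2={t2} ms): first echoes "
          f"{np.round(np.abs(fp[:4]), 4)}, signal energy "
          f"{np.linalg.norm(fp):.3f}")
# The inversion makes early echoes T1-sensitive; the spoiled-FISP steady
# approach and the lobe envelope encode T2.

grid = sm.DictionaryGrid(np.geomspace(50, 3000, 25), np.geomspace(10, 1500, 25))
dictionary = sm.build_dictionary(seq, grid)
subspace = sm.compute_subspace(dictionary, 5)
proj = dictionary.signals @ np.conj(subspace.basis)
resid = np.linalg.norm(dictionary.signals - proj @ subspace.basis.T)
resid /= np.linalg.norm(dictionary.signals)
print(f"dictionary: {dictionary.n_entries} entries x {dictionary.n_frames} frames")
print(f"rank-5 subspace captures all fingerprints to a relative residual of "
      f"{resid:.3%}")
# That residual is why the reconstruction can solve for 5 coefficient
# images instead of 128 contrast images.
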