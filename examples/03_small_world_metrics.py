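"""Small-world metrics of a thresholded PLI network.

Thresholds one subject's low-band connectivity over the 5-40% sparsity
grid, normalizes by degree-preserving rewired references, and prints the
per-sparsity and range-averaged parameters. sigma > 1 indicates
small-world topology: more clustered than random without proportionally
longer paths.
"""

import neurostates as ns

rec = ns.generate_state_recording("resting", duration=60.0, fs=250.0, seed=3)
banded = ns.bandpass(ns.preprocess(rec), ns.LOW_BAND)
conn = ns.pli_matrix(ns.instantaneous_phase(banded, ns.LOW_BAND))

per_sparsity, averaged = ns.sparsity_sweep(conn, n_realizations=20, seed=3)
print("sparsity     C      L   gamma  lambda  sigma    E_g  E_loc")
for m in per_sparsity:
    print(f"  {m.sparsity:4.0%}  {m.C:6.3f} {m.L:6.3f} {m.gamma:6.3f} "
          f"{m.lam:6.3f} {m.sigma:6.3f} {m.E_g:6.3f} {m.E_loc:6.3f}")
m = averaged
print(f"  mean  {m.C:6.3f} {m.L:6.3f} {m.gamma:6.3f} {m.lam:6.3f} "
      f"{m.sigma:6.3f} {m.E_g:6.3f} {m.E_loc:6.3f}")
print("\nrange-averaged sigma > 1 -> the resting-state network keeps the "
      "'economic' small-world layout")
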