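"""Equilibrium ribosome-RNAP coupling from ALEX FRET traces.

A three-state chain (uncoupled E~0, loosely coupled E~0.1, coupled E~0.3)
is simulated with alternating-laser excitation, then analysed end to end:
deinterleave, window on acceptor survival, HMM state assignment, Gaussian
mixture of the FRET histogram, coupled fraction and recoupling kinetics.
"""

import numpy as np

from expressome import pipeline as pl
from expressome import synthgen as sg

# uncoupled -> loose at 1/10.1 s^-1: mean recoupling time 10.1 s
R = np.array([[0.0, 1 / 10.1, 0.0],
              [0.04, 0.0, 0.08],
              [0.0, 0.03, 0.0]])
pi = sg.stationary_distribution(R)
print(f"configured occupancies (uncoupled/loose/coupled): {pi.round(3)}")

cfg = sg.SimConfig(kinetic_scheme="coupling_multistate", n_traces=80,
                   n_frames=3000, state_fret_means=(0.0, 0.1, 0.3),
                   state_fret_sd=0.03, rate_matrix=R, alex=True,
                   bleach_mean_frames={"donor": 4000, "acceptor": 5000},
                   seed=11)
traces, _ = sg.simulate_dataset(cfg)
res, _ = pl.run_coupling_analysis(traces, {"n_states": 3, "n_boot": 20}, seed=0)

print(f"mixture means: {[round(m, 3) for m in res['gmm']['means']]}")
print(f"fraction coupled: {res['fraction_coupled']:.2f} "
      f"+/- {res['fraction_coupled_se']:.2f}")
print(f"recoupling time constant: {res['recoupling']['tau_s']:.1f} s "
      f"(configured 10.1 s)")
print(f"median coupled lifetime: {res['median_coupled_lifetime_s']:.1f} s"
      + ("  (lower bound: censoring-dominated)"
         if res["lifetime_is_lower_bound"] else ""))
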