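"""Finding a static target: decision time across the noise axis.

A single spin-model agent (allocentric frame, with T0 = 100 equilibration
sweeps per movement step so the bump can track the target bearing) seeks a static Gaussian target at the arena
center.  Decision time — the first step within 5 distance units — is long
near the ordering transition and short in the ordered phase, where a
stable bump steers the agent almost straight at the target.
"""

import numpy as np

import ringflock as rf

def decision_time(beta, seed):
    cfg = rf.SimulationConfig(
        model="spin", frame_policy="allo", N=1, Ns=100, beta=beta, T0=100,
        steps=3000, seed=seed, stop_at_target_distance=5.0, record_every=50,
        targets=[rf.TargetSpec(position=(500.0, 500.0), amplitude=0.0025)])
    rec = rf.run_simulation(cfg)
    return rec.reached_step


for beta in (5.0, 20.0):
    times = [decision_time(beta, s) for s in range(8)]
    finite = [t for t in times if t is not None]
    print(f"beta={beta:5.1f}: median decision time = "
          f"{np.median(finite):6.0f} steps "
          f"({len(times) - len(finite)}/8 runs censored at 3000)")

print("\nSmaller median in the ordered phase (larger beta) = faster, more "
      "direct target finding.")
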