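"""Stationary law of the stochastic spin updates vs exact enumeration.

On a small ring (Ns = 8) every one of the 256 network states can be
enumerated, so the chain's empirical occupancy can be compared with the
Boltzmann weights exp(-beta * H) directly.  The total-variation distance
should be close to zero.
"""

import numpy as np

import ringflock as rf

NS, BETA = 8, 0.5
net = rf.SpinRingNetwork(NS, beta=BETA)
rng = np.random.default_rng(1)
counts = net.state_histogram(None, rng, n_samples=200_000,
                             burn_in_sweeps=1000)

energy = np.empty(2**NS)
for code in range(2**NS):
    s = np.array([1 if code >> i & 1 else -1 for i in range(NS)])
    energy[code] = rf.SpinRingNetwork(NS, BETA, states=s).hamiltonian()
weights = np.exp(-BETA * (energy - energy.min()))
p_exact = weights / weights.sum()
p_chain = counts / counts.sum()
tv = 0.5 * np.abs(p_exact - p_chain).sum()

print(f"Ns={NS}, beta={BETA}: total-variation distance chain vs exact "
      f"Boltzmann = {tv:.4f}")
print("Values near 0 confirm the single-spin update rule samples the "
      "intended equilibrium distribution.")
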