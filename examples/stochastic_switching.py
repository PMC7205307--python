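"""Sample the endpoint distribution of the stochastic switch at three
inducer levels: unimodal-low, bimodal, and unimodal-high.

Each run starts a cell with zero mRNA/protein/xanthosine molecules and
lets the discrete reaction network evolve for 10^6 s of simulated time
(tau = 500 at gamma_p = 5e-4 1/s) with the hybrid SSA/tau-leap solver.
"""

from xapswitch import (CellGeometry, build_network, find_fixed_points,
                       run_ensemble, split_bimodal, table1)

geom = CellGeometry()
N_RUNS = 100  # scaled-down ensemble; raise for smoother histograms

for c_a in (12.0, 18.5, 25.0):
    params = table1(c_a=c_a)
    net = build_network(params, geom)
    ens = run_ensemble(net, (0, 0, 0), 500.0, N_RUNS, base_seed=2020)
    sp = split_bimodal(ens.endpoints[:, 1])
    fps = find_fixed_points(params)
    det = ", ".join(f"{fp.state.p_a * geom.omega:.0f}({fp.stability[0]})"
                    for fp in fps)
    modes = " and ".join(f"{m:.1f}" for m in sp.means)
    print(f"c_a = {c_a:5.1f}: protein mode(s) at {modes} molecules "
          f"(weights {[round(w, 2) for w in sp.weights]})")
    print(f"           deterministic branches: {det}")

print()
print("Inside the bistable window (18.5) the population splits between the")
print("uninduced and induced states; outside it every cell ends up on the")
print("single deterministic branch. Mode positions track the fixed points.")
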