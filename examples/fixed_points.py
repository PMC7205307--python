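"""Find the steady states of the reference scenario and read off the switch.

The circuit's two stable states are the 'off' (uninduced) and 'on'
(induced) expression levels; the middle unstable state is the switch
point between their basins of attraction.
"""

from xapswitch import CellGeometry, find_fixed_points, table1

params = table1()            # reference parameter set, c_a = 13
geom = CellGeometry()        # 1 fL cytoplasm, K_a = 5e-5 M

print(f"extracellular xanthosine c_a = {params.c_a} (x K_a = 5e-5 M)")
print(f"{'#':>2} {'stability':>9} {'mRNA':>8} {'protein':>9} {'xanthosine':>12}")
for fp in find_fixed_points(params):
    m, p, x = (fp.state.m_a * geom.omega, fp.state.p_a * geom.omega,
               fp.state.x_a * geom.omega)
    print(f"{fp.index:>2} {fp.stability:>9} {m:8.2f} {p:9.1f} {x:12.3g}")

print()
print("Counts are molecules per cell. The outer two states are stable:")
print("an uninduced cell holds ~5 transporter/enzyme copies, an induced")
print("one ~250, with intracellular xanthosine piled up ~1e7 molecules.")
print("The middle (unstable) state carries ~1 mRNA: the switch point.")
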