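"""Peak power production and efficiency across kinesin species.

For each packaged motor the power W = v F / kBT is maximized over backward
force between zero and stall, and the efficiency eta = W / [(k+ + k-) dG]
is evaluated at the optimum with dG = 20 kBT per ATP.  Wild-type motors
outperform the neck-linker mutants because the mutants waste hydrolyses on
futile cycles (escape probability < 1).
"""

from kinstep import efficiency, max_power, nl_docking_energy, preset, preset_names, stall_force

print(f"{'motor':12s} {'stall_pN':>8s} {'F_opt_pN':>9s} {'W_max_kBT/s':>12s} "
      f"{'eta_at_opt_%':>12s} {'ED_kBT':>7s}")
rows = []
for name in preset_names():
    p = preset(name)
    F_opt, W = max_power(p)
    rows.append((name, stall_force(p), F_opt, W,
                 100 * efficiency(F_opt, p), nl_docking_energy(p)))
for name, fs, fo, w, eta, ed in sorted(rows, key=lambda r: -r[3]):
    print(f"{name:12s} {fs:8.2f} {fo:9.2f} {w:12.1f} {eta:12.1f} {ed:7.2f}")

print("\nW_max is the peak of the power-force curve; ED is the neck-linker")
print("docking energy inferred from the zero-force stepping ratio.")
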