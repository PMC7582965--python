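"""Arrival-time binning and the corrected-red melanin signature.

Builds the standard 80 MHz / 16-bin pulse train, maps the red and green gate
windows onto bins, and compares the gate-mass difference (the analytic
corrected-red fraction) across endogenous fluorophores: only short-lifetime
melanin is strongly positive, which is the basis of the virtual stain.
"""

import numpy as np

from skinmpm.timetag import (
    GateWindows,
    Irf,
    PulseTrainConfig,
    bin_edges,
    decay_bin_probs,
    window_to_bins,
)

cfg = PulseTrainConfig()
windows = GateWindows()

print(f"pulse period  : {cfg.period_ns:.3f} ns at {cfg.rep_rate/1e6:.0f} MHz")
print(f"bin width     : {cfg.bin_width_ns*1000:.0f} ps x {cfg.n_bins} bins")
edges = bin_edges(cfg)
print(f"bin edges     : {edges[0]:.3f} .. {edges[-1]:.3f} ns")

red = sorted(window_to_bins(windows.red, cfg))
green = sorted(window_to_bins(windows.green, cfg))
print(f"red window  {windows.red} ns -> bins {red}")
print(f"green window {windows.green} ns -> bins {green}")
print(f"shared (overlap) bins: {sorted(set(red) & set(green))}")
print()

print("gate-mass difference (red - green), the analytic corrected-red "
      "fraction per detected photon:")
emitters = {
    "melanin (0.2 ns)": [(0.2, 1.0)],
    "NAD(P)H (0.4/2.5 ns)": [(0.4, 0.75), (2.5, 0.25)],
    "keratin (1.4 ns)": [(1.4, 1.0)],
    "elastin (1.7 ns)": [(1.7, 1.0)],
    "FAD (2.3 ns)": [(2.3, 1.0)],
}
for name, lifetimes in emitters.items():
    p = decay_bin_probs(lifetimes, Irf(), cfg)
    diff = p[red].sum() - p[green].sum()
    print(f"  {name:22s} {diff:+.3f}")
print()
print("A positive value means the emitter survives the green-from-red "
      "subtraction; only melanin is strongly positive, so the corrected-red "
      "channel is melanin-selective.")
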