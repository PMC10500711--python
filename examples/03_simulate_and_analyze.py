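"""Simulate a four-pulse DEER dataset and run the full analysis pipeline.

Builds the 80 µM study conditions (doubly labelled ligand, 5.1 nm Gaussian
distance distribution), simulates one trace per pump pulse, then recovers
the modulation depth, background decay constant, noise level and MNR from
the trace alone — the generating parameters are never shown to the
analyzer.
"""

from deerwave.fixtures import synthetic_dataset
from deerwave.sensitivity import mnr

traces, manifest = synthetic_dataset("high_c", seed=42)

print(f"spin concentration: {manifest['spin_concentration_M']*1e6:.0f} uM, "
      f"sigma0 = {manifest['sigma0']}")
print(f"{'pulse':12s}  {'lam true':>8s} {'lam_hat':>8s}  {'k true':>7s} {'k_hat':>7s}"
      f"  {'noise':>7s}  {'MNR':>5s}")
for name, trace in traces.items():
    true = manifest["pulses"][name]
    res = mnr(trace, tau_trunc=7.0)
    print(f"{name:12s}  {true['lambda']:8.3f} {res.lambda_hat:8.3f} "
          f" {true['k_per_us']:7.4f} {res.k_hat:7.4f}  {res.noise:7.4f}  {res.mnr:5.0f}")

print("\nBroadband pumps roughly double the modulation depth of the 16 ns")
print("rectangular reference — and with it the MNR at this trace length.")
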