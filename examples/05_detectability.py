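"""Rare-event detectability: reference value versus acquisition depth.

With the >=20-event minimum population size, a subpopulation barely
exceeding a reference of r % of CD45+ needs ceil(20 / (r/100)) CD45+
events.  At the targeted acquisition of 500,000 events, subpopulations
with references below 0.004% cannot be reliably evaluated.
"""

from mrdflow import min_cd45_required

print("reference (%CD45+)   minimum CD45+ events for >=20 events")
for ref in (0.001, 0.002, 0.004, 0.01, 0.1, 1.992):
    req = min_cd45_required(ref, min_events=20)
    flag = "  <- not evaluable at 500,000 events" if req > 500_000 else ""
    print(f"  {ref:8.3f}           {req:>12,}{flag}")

print("\nA reference of 0.001% needs 2,000,000 CD45+ events; deep references "
      "only pay off with deep acquisition.")
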