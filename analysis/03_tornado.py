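#!/usr/bin/env python
"""One-way deterministic sensitivity (tornado) for both iCBT formats:
each parameter is pushed to mean ± 1.96 SE (± 20% without an SE) and the
ICUR versus the waitlist recorded; rows are ranked by the ICUR swing."""

from menocea import default_parameters
from menocea.reporting import cmd_tornado

params = default_parameters()
for strategy in ("guided", "self_managed"):
    rows = cmd_tornado(params, strategy=strategy, output_dir="results/tornado")
    print(f"\nTornado, {strategy} vs waitlist (top 5 of {len(rows)}):")
    for _, r in rows.head(5).iterrows():
        print(f"  {r['parameter']:38s} swing {r['swing']:12.1f}")
print("\nState utilities and state costs dominate; a swing of 'inf' marks a")
print("range whose extreme flips the comparison into dominance (the published")
print("finding that an unfavorable reduced-state utility is the one change")
print("that can push the comparison past acceptability).")
print("Tables written to results/tornado/.")
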