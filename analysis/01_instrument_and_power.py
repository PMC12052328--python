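#!/usr/bin/env python
"""Stage 1 — the instrument and the study's planning numbers.

Writes the bundled 12-item instrument as a table and JSON document, and
computes the per-group sample size for the two-student discriminant
comparison: detecting a 0.5-point score difference (SDs 0.8 and 1.2) with a
Mann-Whitney test at 80% power and alpha 5%, using the 0.864 worst-case
relative-efficiency divisor.
"""

import json
from pathlib import Path

import pandas as pd

from novascore import default_instrument
from novascore.pipeline import power_report

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

instrument = default_instrument()
items = pd.DataFrame(
    [
        {"category": it.category, "nova_group": it.nova_group.value,
         "item_id": it.item_id, "label": it.label}
        for it in instrument.items
    ]
)
items.to_csv(OUT / "instrument_items.csv", index=False)
instrument.to_json(OUT / "instrument.json")

plan = power_report(delta=0.5, sd1=0.8, sd2=1.2)
(OUT / "power.json").write_text(json.dumps(plan, indent=2) + "\n")

print(f"{instrument.name}: {len(instrument.items)} items, "
      f"{len(instrument.categories)} categories, scale "
      f"{instrument.scale.min}-{instrument.scale.max}")
print(items.to_string(index=False))
print(f"\nplanned sample size: {plan['n_per_group']} per group "
      f"(delta=0.5, SDs 0.8/1.2, power 0.80, alpha 0.05, ARE 0.864)")
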