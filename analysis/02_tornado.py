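#!/usr/bin/env python
"""One-way (tornado) sensitivity analysis.

Varies every scalar input over its published range (±20% where none is
published) and ranks the bars by their excursion of the incremental net
monetary benefit at the willingness-to-pay threshold.  Writes the bar table
and a tornado plot.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from milkcea.params import load_parameters
from milkcea.sensitivity import tornado

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

params = load_parameters()
bars = tornado(params)
df = pd.DataFrame([dataclasses.asdict(b) for b in bars])
df.to_csv(OUT / "tornado.csv", index=False)

print("=== tornado: widest bars (incremental NMB excursion, int$) ===")
print(df.head(12).to_string(index=False,
                            formatters={"width": "{:.1f}".format,
                                        "ev_low": "{:.1f}".format,
                                        "ev_high": "{:.1f}".format}))

try:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    top = df.head(12).iloc[::-1]
    mid = (top.ev_low + top.ev_high) / 2
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.barh(top.parameter, top.ev_high - top.ev_low,
            left=top.ev_low, color="#4878b0")
    ax.set_xlabel("incremental net monetary benefit (int$)")
    ax.set_title("one-way sensitivity of the base case")
    fig.tight_layout()
    fig.savefig(OUT / "tornado.png", dpi=120)
    print(f"plot written to {OUT / 'tornado.png'}")
except ImportError:
    print("matplotlib not available; skipped the plot")
print(f"bar table written to {OUT / 'tornado.csv'}")
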