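"""Group-level summary: mean attention index with within-subject error bars.

Simulates a small sample of participants with a common injected gain,
aggregates the per-participant attention indices and reports condition means
with Cousineau-Morey within-subject standard errors (the error bars suited
to repeated-measures contrasts: between-participant level differences are
removed before the SE is computed).
"""

import pandas as pd

from tagattn.pipeline import simulate_participant_ai
from tagattn.report import make_summary

tables = []
for p in range(4):
    t = simulate_participant_ai("exp3", 96, gain=1.3, seed=40 + p)
    t["participant"] = f"p{p}"
    tables.append(t)
ai = pd.concat(tables, ignore_index=True)

summary = make_summary(ai, participant="participant",
                       condition=["focus", "location"], value="ai",
                       plot_path="scratch_ai_summary.png")
print(summary.round(3).to_string(index=False))
print("\nMeans above 1 reflect the injected attentional gain (1.3); the"
      "\nwithin-subject SE discounts stable participant-level offsets."
      "\nBar chart written to scratch_ai_summary.png.")
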