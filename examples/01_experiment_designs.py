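"""Generate the three experiments' trial structures.

Builds a counterbalanced session for each experiment and prints the design
constants the generators guarantee: probe-placement probabilities, arc
geometry, frame-locked flicker frequencies, block structure, and the
Experiment 2 dimming-event timing constraints.
"""

import numpy as np

from tagattn.design import (
    EXP1_LAYOUT,
    EXP2_FREQS,
    EXP3_FREQS,
    LOCATIONS,
    build_session,
    make_probability_table,
    merged_region_span,
)

# --- geometry and probabilities -----------------------------------------
print("Exp 1 arc: %.1f deg segments, %.1f deg gaps; 3 merged -> %.1f deg"
      % (EXP1_LAYOUT.segment_span, EXP1_LAYOUT.gap, merged_region_span(EXP1_LAYOUT, 3)))
for focus in ("narrow", "split", "broad"):
    t = make_probability_table(focus)
    cued = sum(t.probs[c] for c in t.cued)
    print(f"{focus:>6}: cued mass {cued:.2f}, table {t.probs}")

# --- flicker frequencies -------------------------------------------------
print("\nExp 2 tags:", {l: EXP2_FREQS[l].freq_display for l in LOCATIONS})
print("Exp 3 tags (clockwise):", [f.freq_display for f in EXP3_FREQS])

# --- sessions ------------------------------------------------------------
d1 = build_session("exp1", 720, seed=1)
print(f"\nExp 1 session: {d1.n_trials} trials in {d1.trials.block.nunique()} blocks of 10; "
      f"cued-probe fraction {d1.trials.probe_cued.mean():.3f} (target 0.75)")

d2 = build_session("exp2", 480, seed=1)
gaps = [np.diff(np.sort(g.onset)).min() for _, g in d2.events.groupby("trial")
        if len(g) > 1]
print(f"Exp 2 session: {d2.n_trials} trials, {len(d2.events)} dimming events, "
      f"min onset gap {min(gaps):.2f} s (constraint 1.1 s)")

d3 = build_session("exp3", 480, seed=1)
print("Exp 3 session: focus counts", d3.trials.focus.value_counts().to_dict(),
      "(240 per condition, sides collapsed)")
left_inner = d3.trials.query("side == 'left'").freq_innermost.value_counts().to_dict()
print("  innermost-left frequency counts (layout flips):", left_inner)
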