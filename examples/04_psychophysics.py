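"""Adaptive staircases, response matching and d' on simulated observers.

Runs the two thresholding procedures against known Weibull observers (QUEST
for the contrast task, 3-down-1-up for dimming depth), then simulates a
continuous-report trial and scores it with window-based response-event
matching and the log-linear-corrected d'.
"""

import numpy as np

from tagattn.behavior import (
    ObserverModel,
    ResponseLog,
    dprime_loglinear,
    match_responses,
    observer_respond,
    quest_run,
    run_staircase_3d1u,
)

# --- QUEST: estimate the 75%-correct contrast ---------------------------
obs = ObserverModel(threshold=0.12, slope=3.0, guess=0.5, lapse=0.01)
true75 = obs.intensity_at(0.75)
est = quest_run(0.05, obs, 120, target_p=0.75, seed=1)
rng = np.random.default_rng(2)
acc = np.mean([observer_respond(obs, est, rng) for _ in range(720)])
print(f"QUEST: true 75%-point {true75:.4f}, estimate {est:.4f} "
      f"({100 * abs(est - true75) / true75:.1f}% off); "
      f"accuracy at estimate over 720 trials: {100 * acc:.1f}%")

# --- 3-down-1-up: converges near 79.4% correct --------------------------
det_obs = ObserverModel(threshold=0.3, slope=3.0, guess=0.0, lapse=0.0)
state = run_staircase_3d1u(det_obs, start=0.8, step=0.02, n_trials=3000, seed=4)
tail_acc = np.mean([ok for _, ok in state.history[1000:]])
print(f"3-down-1-up: long-run accuracy {tail_acc:.3f} "
      f"(theoretical convergence point 0.5^(1/3) = {0.5 ** (1/3):.3f})")

# --- matching and d' -----------------------------------------------------
log = ResponseLog(
    trial_duration=5.0,
    events=[(0.9, "target"), (2.2, "nontarget"), (3.6, "target")],
    responses=[1.4, 4.1, 4.9],  # hits the 1st and 3rd events; 4.9 unpaired
)
m = match_responses(log, window=(0.0, 1.0))
print(f"matching: {m['hit']} hits, {m['miss']} misses, {m['false_alarm']} FAs, "
      f"{m['correct_rejection']} CRs, {m['unpaired']} unpaired (discarded)")

d = dprime_loglinear(hits=45, n_targets=50, fas=5, n_nontargets=50)
print(f"d' (log-linear) for 45/50 hits vs 5/50 FAs: {d:.2f}")
print(f"d' stays finite even at ceiling: {dprime_loglinear(50, 50, 0, 50):.2f}")
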