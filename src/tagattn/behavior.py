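"""Simulated observers, adaptive staircases and behavioral analyses.

Covers the psychophysical machinery of the three tasks: a Weibull observer
model standing in for participants, the Bayesian QUEST staircase used to set
probe contrast at ~75% correct, the 3-down-1-up staircase used to threshold
dimming depth (converging near 79.4% correct), continuous-report matching of
responses to events, log-linear-corrected d-prime, accuracy tables, and the
gaze-based trial/participant exclusion rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import SessionDesign, make_probability_table

__all__ = [
    "ObserverModel",
    "StaircaseState",
    "ResponseLog",
    "observer_respond",
    "quest_run",
    "staircase_3d1u_step",
    "run_staircase_3d1u",
    "match_responses",
    "dprime_loglinear",
    "exclude_trials_by_gaze",
    "exclude_participants",
    "accuracy_table",
    "simulate_exp1_session",
]


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# observer model


@dataclass(frozen=True)
class ObserverModel:
    """Weibull psychometric observer.

    P(correct | x) = guess + (1 - guess - lapse) * (1 - exp(-(x / threshold)^slope))

    ``threshold`` is the Weibull scale (the ~63% point of the rescaled curve),
    in stimulus units (contrast fraction, dimming depth, or 1/switch-rate
    scaled difficulty). ``guess`` is 0.5 for 2AFC orientation discrimination,
    near 0 for detection.
    """

    threshold: float
    slope: float = 3.0
    guess: float = 0.5
    lapse: float = 0.01

    def __post_init__(self):
        if self.threshold <= 0 or self.slope <= 0:
            raise ValueError("threshold and slope must be positive")
        if not 0 <= self.guess < 1:
            raise ValueError("guess must be in [0, 1)")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must be in [0, 0.1]")

    def p_correct(self, x) -> float:
        x = np.asarray(x, float)
        if np.any(x < 0):
            raise ValueError("intensity must be non-negative")
        p = self.guess + (1 - self.guess - self.lapse) * (1 - np.exp(-((x / self.threshold) ** self.slope)))
        return float(p) if p.ndim == 0 else p

    def intensity_at(self, p: float) -> float:
        """Invert the psychometric function: intensity giving P(correct)=p."""
        if not self.guess < p < 1 - self.lapse:
            raise ValueError(f"p={p} outside the attainable range "
                             f"({self.guess}, {1 - self.lapse})")
        frac = (p - self.guess) / (1 - self.guess - self.lapse)
        return self.threshold * (-math.log(1 - frac)) ** (1 / self.slope)


def observer_respond(model: ObserverModel, intensity: float, seed) -> bool:
    """One Bernoulli trial outcome at the given intensity (True = correct)."""
    if intensity < 0:
        raise ValueError("intensity must be non-negative")
    return bool(_rng(seed).random() < model.p_correct(intensity))


# ---------------------------------------------------------------------------
# QUEST


def quest_run(prior_mode: float, observer: ObserverModel, n_trials: int,
              target_p: float = 0.75, seed=None, *, slope: float = 3.0,
              guess: float = None, lapse: float = None,
              grid_lo: float = 1e-3, grid_hi: float = 1.0, n_grid: int = 200,
              prior_sd_log10: float = 1.0, estimate: str = "mean") -> float:
    """Bayesian adaptive threshold estimation (QUEST).

    Maintains a posterior over the *target-p* intensity T (the intensity at
    which the assumed Weibull observer is correct with probability
    ``target_p``) on a log-spaced grid. Each trial is placed at the current
    posterior mode ("updated after every response") and the outcome updates
    the posterior via the Weibull likelihood.

    The returned estimate is the posterior mean in log intensity
    (``estimate="mean"``, the default): the mode is jumpy under the
    occasional lucky-streak posterior and its heavy low tail biases realized
    accuracy below the target; the mean is the lower-variance, unbiased
    summary. ``estimate="mode"`` returns the classic posterior mode instead.

    Assumed psychometric parameters (``slope``, ``guess``, ``lapse``) default
    to the observer's own; the prior is Gaussian in log10 intensity around
    ``prior_mode`` with SD ``prior_sd_log10``.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    if estimate not in ("mean", "mode"):
        raise ValueError("estimate must be 'mean' or 'mode'")
    guess = observer.guess if guess is None else guess
    lapse = observer.lapse if lapse is None else lapse
    if not guess < target_p < 1 - lapse:
        raise ValueError("target_p must lie strictly between guess and 1 - lapse")
    rng = _rng(seed)

    grid = np.logspace(math.log10(grid_lo), math.log10(grid_hi), n_grid)
    log_post = -0.5 * ((np.log10(grid) - math.log10(prior_mode)) / prior_sd_log10) ** 2
    if not np.any(np.isfinite(log_post)):
        raise ValueError("degenerate prior: no mass on the intensity grid")

    # scale so that p(correct | x = T) = target_p for threshold parameter T
    frac = (target_p - guess) / (1 - guess - lapse)
    c = (-math.log(1 - frac)) ** (1 / slope)  # T = c * weibull_scale

    def p_correct(x, T):
        scale = T / c
        return guess + (1 - guess - lapse) * (1 - np.exp(-((x / scale) ** slope)))

    for _ in range(n_trials):
        x = grid[np.argmax(log_post)]
        correct = observer_respond(observer, x, rng)
        p = np.clip(p_correct(x, grid), 1e-12, 1 - 1e-12)
        log_post += np.log(p if correct else 1 - p)
        log_post -= log_post.max()  # numerical stability
    if estimate == "mode":
        return float(grid[np.argmax(log_post)])
    w = np.exp(log_post)
    w /= w.sum()
    return float(10 ** np.sum(w * np.log10(grid)))


# ---------------------------------------------------------------------------
# 3-down-1-up staircase


@dataclass
class StaircaseState:
    """State of a transformed up-down (3-down-1-up) staircase.

    ``intensity`` is on a scale where larger = easier (deeper dimming).
    Three consecutive correct responses step toward harder (intensity down);
    any error steps toward easier (intensity up) and resets the counter.
    The asymptotic convergence point is the intensity where
    p(correct)^3 = 0.5, i.e. p = 0.5^(1/3) ~ 0.794.
    """

    intensity: float
    step: float
    bounds: tuple = (0.0, 1.0)
    correct_streak: int = 0
    history: list = field(default_factory=list)  # (intensity, outcome)

    def __post_init__(self):
        lo, hi = self.bounds
        if not lo <= self.intensity <= hi:
            raise ValueError("intensity outside declared bounds")


def staircase_3d1u_step(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the staircase by one target-event outcome."""
    lo, hi = state.bounds
    intensity = state.intensity
    streak = state.correct_streak
    history = state.history + [(state.intensity, bool(correct))]
    if correct:
        streak += 1
        if streak == 3:
            intensity = max(lo, intensity - state.step)
            streak = 0
    else:
        intensity = min(hi, intensity + state.step)
        streak = 0
    return StaircaseState(intensity, state.step, state.bounds, streak, history)


def run_staircase_3d1u(observer: ObserverModel, start: float, step: float,
                       n_trials: int, seed, bounds=(0.0, 1.0)) -> StaircaseState:
    """Run a seeded 3-down-1-up staircase against a simulated observer."""
    rng = _rng(seed)
    state = StaircaseState(start, step, bounds)
    for _ in range(n_trials):
        correct = observer_respond(observer, state.intensity, rng)
        state = staircase_3d1u_step(state, correct)
    return state


# ---------------------------------------------------------------------------
# response-event matching


@dataclass
class ResponseLog:
    """Per-trial continuous-report record.

    ``events``: list of (onset s, kind) with kind in {target, nontarget};
    ``responses``: response times in s from trial start; ``gaze``: optional
    (t, eccentricity dva) array sampled at a fixed rate.
    """

    trial_duration: float
    events: list
    responses: list
    gaze: np.ndarray = None

    def __post_init__(self):
        for t, _ in self.events:
            if not 0 <= t <= self.trial_duration:
                raise ValueError("event onset outside trial")
        for r in self.responses:
            if not 0 <= r <= self.trial_duration:
                raise ValueError("response time outside trial")


def match_responses(log: ResponseLog, window=(0.0, 1.0),
                    lo_inclusive: bool = False) -> dict:
    """Assign responses to events and count signal-detection outcomes.

    A response at time r matches event onset t when lo < r - t <= hi
    (``lo_inclusive=True`` makes the lower bound inclusive, as in the
    0.1-1 s window). Each response goes to the most recent matching event
    that has not yet consumed a response; responses matching no event are
    "unpaired" and excluded from the rates. Events: target+response = hit,
    target unanswered = miss, nontarget+response = false alarm, nontarget
    unanswered = correct rejection.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("window lower bound must be below upper bound")
    events = sorted(log.events, key=lambda e: e[0])
    consumed = [False] * len(events)
    outcomes = [None] * len(events)
    unpaired = 0
    for r in sorted(log.responses):
        best = None
        for i, (t, _kind) in enumerate(events):
            dt = r - t
            in_win = (dt >= lo if lo_inclusive else dt > lo) and dt <= hi
            if in_win and not consumed[i]:
                best = i  # events sorted by onset: last match = most recent
        if best is None:
            unpaired += 1
        else:
            consumed[best] = True
    for i, (t, kind) in enumerate(events):
        if kind == "target":
            outcomes[i] = "hit" if consumed[i] else "miss"
        else:
            outcomes[i] = "false_alarm" if consumed[i] else "correct_rejection"
    counts = {k: outcomes.count(k) for k in
              ("hit", "miss", "false_alarm", "correct_rejection")}
    counts["unpaired"] = unpaired
    counts["per_event"] = outcomes
    return counts


# ---------------------------------------------------------------------------
# d-prime with log-linear correction


def dprime_loglinear(hits: int, n_targets: int, fas: int, n_nontargets: int) -> float:
    """Signal-detection d' with the log-linear correction.

    H = (hits + 0.5) / (n_targets + 1), F = (fas + 0.5) / (n_nontargets + 1),
    d' = PHI^-1(H) - PHI^-1(F). The correction keeps d' finite at ceiling and
    floor rates.
    """
    for v in (hits, n_targets, fas, n_nontargets):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if hits > n_targets or fas > n_nontargets:
        raise ValueError("hits/false alarms cannot exceed their trial counts")
    h = (hits + 0.5) / (n_targets + 1)
    f = (fas + 0.5) / (n_nontargets + 1)
    return float(norm.ppf(h) - norm.ppf(f))


# ---------------------------------------------------------------------------
# gaze exclusions


def exclude_trials_by_gaze(gaze: np.ndarray, ecc_limit: float = 0.75,
                           dur_limit: float = 0.05) -> bool:
    """True (exclude the trial) iff gaze left the fixation zone too long.

    ``gaze`` is an (n, 2) array of (time s, eccentricity dva) at a uniform
    sampling rate. A trial is excluded when any contiguous run of samples
    with eccentricity > ecc_limit (missing samples, e.g. blinks, count as
    excursions) lasts longer than dur_limit seconds.
    """
    gaze = np.asarray(gaze, float)
    if gaze.ndim != 2 or gaze.shape[0] == 0:
        raise ValueError("empty or malformed gaze trace")
    t, ecc = gaze[:, 0], gaze[:, 1]
    if np.any(ecc[~np.isnan(ecc)] < 0):
        raise ValueError("eccentricity must be non-negative")
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    out = np.isnan(ecc) | (ecc > ecc_limit)
    run = 0
    for flag in out:
        run = run + 1 if flag else 0
        if run * dt > dur_limit:
            return True
    return False


def exclude_participants(exclusion_fractions, thresholds=None,
                         frac_limit: float = 0.25, z_limit: float = 3.0) -> pd.DataFrame:
    """Participant-level exclusion and outlier flags.

    A participant is excluded when their gaze-based trial-exclusion fraction
    strictly exceeds ``frac_limit`` (0.25). If per-participant thresholds are
    supplied, values more than ``z_limit`` sample SDs from the sample mean are
    flagged as outliers (flag only; not auto-excluded).
    """
    frac = np.asarray(exclusion_fractions, float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("exclusion fractions must be in [0, 1]")
    out = pd.DataFrame({"exclusion_fraction": frac})
    out["excluded"] = frac > frac_limit
    if thresholds is not None:
        th = np.asarray(thresholds, float)
        sd = th.std(ddof=1) if len(th) > 1 else 0.0
        z = (th - th.mean()) / sd if sd > 0 else np.zeros_like(th)
        out["threshold"] = th
        out["threshold_outlier"] = np.abs(z) > z_limit
    return out


# ---------------------------------------------------------------------------
# Experiment 1 accuracy


def simulate_exp1_session(design: SessionDesign, observer: ObserverModel,
                          contrast: float, seed, gain: dict = None) -> pd.DataFrame:
    """Simulate 2AFC outcomes for an Experiment 1 session at fixed contrast.

    ``gain`` optionally maps probe type ("cued"/"uncued") to a multiplicative
    effective-contrast factor, modeling a cue-validity benefit; default is no
    modulation.
    """
    rng = _rng(seed)
    gain = gain or {}
    rows = []
    for _, tr in design.trials.iterrows():
        kind = "cued" if tr["probe_cued"] else "uncued"
        eff = contrast * gain.get(kind, 1.0)
        rows.append({
            "trial": tr["trial"], "focus": tr["focus"],
            "probe_location": tr["probe_location"], "probe_cued": tr["probe_cued"],
            "correct": observer_respond(observer, eff, rng),
        })
    return pd.DataFrame(rows)


def accuracy_table(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Proportion correct per focus condition x probe type.

    Probe types are cued vs uncued; in the split condition the uncued probes
    are separated into the intermediate versus the outer uncued locations.
    Cells with no trials are emitted with NaN accuracy and n = 0 rather than
    fabricated.
    """
    df = outcomes.copy()

    def probe_type(row):
        if row["probe_cued"]:
            return "cued"
        if row["focus"] == "split" and row["probe_location"] == "intermediate":
            return "uncued_intermediate"
        if row["focus"] == "split":
            return "uncued_outer"
        return "uncued"

    df["probe_type"] = df.apply(probe_type, axis=1)
    cells = []
    for focus in df["focus"].unique():
        types = (("cued", "uncued_intermediate", "uncued_outer") if focus == "split"
                 else ("cued", "uncued"))
        sub = df[df["focus"] == focus]
        for pt in types:
            cell = sub[sub["probe_type"] == pt]
            cells.append({
                "focus": focus, "probe_type": pt, "n": len(cell),
                "accuracy": cell["correct"].mean() if len(cell) else np.nan,
            })
    return pd.DataFrame(cells)
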