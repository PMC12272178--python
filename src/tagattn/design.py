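"""Experiment-design generators for the covert spatial-attention studies.

Three experiments share a common geometry: arc segments in the lower visual
field, a subset of which is cued on each block. Experiment 1 is a cued
orientation-discrimination task with probabilistic probe placement;
Experiment 2 adds frequency tagging (three flicker frequencies per hemifield)
and a dimming-detection task; Experiment 3 tags all six locations and replaces
dimming with an RSVP letter-conjunction task.

All randomized constructions take a :class:`numpy.random.Generator` (or a seed)
and are reproducible: identical seeds yield identical session tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ArcLayout",
    "ProbabilityTable",
    "FrequencyAssignment",
    "Event",
    "EventSchedule",
    "DimmingProfile",
    "RsvpStream",
    "SessionDesign",
    "EXP1_LAYOUT",
    "EXP2_LAYOUT",
    "EXP3_LAYOUT",
    "EXP2_FREQS",
    "EXP3_FREQS",
    "RSVP_ALPHABET",
    "LOCATIONS",
    "make_probability_table",
    "merged_region_span",
    "frame_locked_frequency",
    "schedule_dimming_events",
    "assign_event_kinds",
    "make_rsvp_stream",
    "adjust_switch_rate",
    "build_session",
]

#: Canonical within-hemifield location labels, innermost = nearest the
#: vertical meridian.
LOCATIONS = ("innermost", "intermediate", "outermost")

#: The 15 consonants used in the RSVP streams.
RSVP_ALPHABET = ("B", "C", "D", "F", "G", "J", "K", "L", "N", "P", "R", "T", "X", "Y", "V")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class ArcLayout:
    """Polar-arc segment geometry of the stimulus display.

    Angles are degrees of polar angle around fixation; radii are degrees of
    visual angle (dva). Segments within a quadrant are disjoint by
    construction (positive span, non-negative gap).
    """

    n_segments_per_quadrant: int
    segment_span: float  # degrees of polar angle
    gap: float  # degrees between neighboring segments
    meridian_offset: float  # degrees from the vertical/horizontal meridians
    inner_radius: float  # dva
    outer_radius: float  # dva

    def __post_init__(self):
        if self.segment_span <= 0:
            raise ValueError("segment_span must be positive")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError("need 0 < inner_radius < outer_radius")


#: Experiment 1: ten segments along a circle, five per lower quadrant.
EXP1_LAYOUT = ArcLayout(5, 14.7, 3.0, 1.5, 8.0, 14.0)
#: Experiment 2: six segments in the lower hemifield, three per quadrant.
EXP2_LAYOUT = ArcLayout(3, 25.33, 4.0, 2.0, 6.0, 10.0)
#: Experiment 3: same partition as Experiment 2, closer to fixation.
EXP3_LAYOUT = ArcLayout(3, 25.33, 4.0, 2.0, 4.0, 8.0)


def merged_region_span(layout: ArcLayout, k: int) -> float:
    """Polar-angle span of ``k`` neighboring segments merged into one region.

    Merging removes the boundaries but keeps the gaps' extent, so the merged
    region spans ``k * segment_span + (k - 1) * gap`` degrees (e.g. three
    14.7-degree segments with 3-degree gaps merge into 50.1 degrees).
    """
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValueError("k must be a positive integer")
    if k > layout.n_segments_per_quadrant:
        raise ValueError(
            f"cannot merge {k} segments: only {layout.n_segments_per_quadrant} per quadrant"
        )
    return k * layout.segment_span + (k - 1) * layout.gap


# ---------------------------------------------------------------------------
# probe probabilities (Experiment 1)


@dataclass(frozen=True)
class ProbabilityTable:
    """Per-location probe probabilities for one cue (focus) condition.

    The cued locations jointly carry probability 0.75 in every condition; the
    remaining 0.25 is spread over the adjacent uncued locations.
    """

    focus: str
    probs: dict  # location label -> probability
    cued: frozenset  # labels of cued locations

    def __post_init__(self):
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")
        cued_total = sum(self.probs[c] for c in self.cued)
        if abs(cued_total - 0.75) > 1e-9:
            raise ValueError(f"cued probability mass is {cued_total}, not 0.75")

    @property
    def locations(self):
        return tuple(self.probs)

    def sample(self, rng, size=None):
        """Draw probe location label(s)."""
        labels = list(self.probs)
        p = [self.probs[k] for k in labels]
        return _rng(rng).choice(labels, size=size, p=p)


_FOCI = ("narrow", "split", "broad")


def make_probability_table(focus: str, experiment: str = "exp1") -> ProbabilityTable:
    """Printed probe-placement probabilities for an Experiment 1 cue condition.

    narrow: one cued location at 0.75, two flanking locations at 0.125 each.
    split: two cued locations at 0.375 each; the intermediate location and the
    two outer flankers at 1/12 each. broad: five equidistant positions inside
    the merged cued region at 0.15 each, two flankers at 0.125 each.
    """
    if experiment != "exp1":
        raise ValueError(f"probability tables are defined for exp1, not {experiment!r}")
    if focus == "narrow":
        probs = {"cued": 0.75, "neighbor_1": 0.125, "neighbor_2": 0.125}
        cued = frozenset({"cued"})
    elif focus == "split":
        probs = {
            "cued_1": 0.375,
            "cued_2": 0.375,
            "intermediate": 1 / 12,
            "outer_1": 1 / 12,
            "outer_2": 1 / 12,
        }
        cued = frozenset({"cued_1", "cued_2"})
    elif focus == "broad":
        probs = {f"cued_{i}": 0.15 for i in range(1, 6)}
        probs.update({"neighbor_1": 0.125, "neighbor_2": 0.125})
        cued = frozenset(f"cued_{i}" for i in range(1, 6))
    else:
        raise ValueError(f"unknown focus condition {focus!r}; expected one of {_FOCI}")
    return ProbabilityTable(focus=focus, probs=probs, cued=cued)


# ---------------------------------------------------------------------------
# frame-locked flicker frequencies


@dataclass(frozen=True)
class FrequencyAssignment:
    """Flicker frequency realized as an integer number of frames per cycle."""

    refresh_rate: float  # Hz
    frames_per_cycle: int
    side_flipped: bool = False

    @property
    def freq(self) -> float:
        return self.refresh_rate / self.frames_per_cycle

    @property
    def freq_display(self) -> float:
        """Frequency rounded to 2 decimals, as conventionally reported."""
        return round(self.freq, 2)


def frame_locked_frequency(refresh: float, frames_per_cycle: int) -> FrequencyAssignment:
    """Flicker frequency achievable on a display: refresh / frames_per_cycle.

    At 120 Hz this yields the tag set used here: 120/11 = 10.91, 120/10 = 12,
    120/9 = 13.33, 120/13 = 9.23, 120/15 = 8, 120/17 = 7.06 (2-decimal
    display convention; full precision via ``.freq``).
    """
    if refresh <= 0:
        raise ValueError("refresh rate must be positive")
    if not isinstance(frames_per_cycle, (int, np.integer)) or isinstance(frames_per_cycle, bool):
        raise ValueError("frames_per_cycle must be an integer")
    if frames_per_cycle < 1:
        raise ValueError("frames_per_cycle must be >= 1")
    return FrequencyAssignment(float(refresh), int(frames_per_cycle))


#: Experiment 2 tag frequencies, innermost to outermost (120 Hz refresh).
EXP2_FREQS = {
    "innermost": frame_locked_frequency(120, 11),  # 10.91 Hz
    "intermediate": frame_locked_frequency(120, 10),  # 12 Hz
    "outermost": frame_locked_frequency(120, 9),  # 13.33 Hz
}

#: Experiment 3 tag frequencies in clockwise order from the right-most
#: location (the outermost right segment), on unflipped trials.
EXP3_FREQS = [frame_locked_frequency(120, n) for n in (17, 15, 13, 11, 10, 9)]
# 7.06, 8, 9.23 (right side, outer->inner), 10.91, 12, 13.33 (left, inner->outer)


def adjust_switch_rate(rate: float, tag_freqs, refresh: float = 120.0) -> float:
    """Snap an RSVP switch rate to the frame grid, dodging tag harmonics.

    The nearest frame-realizable rate is ``refresh / round(refresh / rate)``.
    If that rate coincides (within 1e-6 Hz) with any tag frequency or an
    integer harmonic of one, the cycle length is shifted by one frame
    (preferring +1 frame, i.e. a slightly slower stream; -1 as fallback).
    """
    if rate <= 0:
        raise ValueError("switch rate must be positive")
    freqs = [f.freq if isinstance(f, FrequencyAssignment) else float(f) for f in tag_freqs]

    def collides(r):
        for f in freqs:
            k = round(r / f)
            if k >= 1 and abs(r - k * f) < 1e-6:
                return True
        return False

    frames = max(1, round(refresh / rate))
    snapped = refresh / frames
    if not collides(snapped):
        return snapped
    slower = refresh / (frames + 1)
    if not collides(slower):
        return slower
    if frames > 1 and not collides(refresh / (frames - 1)):
        return refresh / (frames - 1)
    raise ValueError("no collision-free rate within one frame of the request")


# ---------------------------------------------------------------------------
# dimming events (Experiment 2)


@dataclass(frozen=True)
class Event:
    onset: float  # s from trial start
    kind: str = "unassigned"  # target | nontarget
    configuration: str = "unassigned"  # singular | adjacent | disjoint | all-cued
    locations: frozenset = frozenset()


@dataclass(frozen=True)
class EventSchedule:
    trial_duration: float  # s
    events: tuple  # of Event, sorted by onset

    # timing-constraint constants
    MIN_GAP = 1.1  # s between consecutive onsets
    START_MARGIN = 0.5  # no event in the first 0.5 s
    END_MARGIN = 0.7  # none in the last 0.7 s

    def __post_init__(self):
        onsets = [e.onset for e in self.events]
        if any(b - a < self.MIN_GAP - 1e-12 for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets closer than the 1.1 s minimum gap")
        if onsets and (onsets[0] < self.START_MARGIN - 1e-12
                       or onsets[-1] > self.trial_duration - self.END_MARGIN + 1e-12):
            raise ValueError("event onset outside the allowed trial window")

    @property
    def onsets(self):
        return tuple(e.onset for e in self.events)


def schedule_dimming_events(trial_duration: float, n_events: int, seed) -> EventSchedule:
    """Randomize 0-3 dimming-event onsets within a trial, honoring the
    timing constraints (>= 1.1 s between onsets, none in the first 0.5 s or
    the last 0.7 s), by rejection sampling.

    Raises if the constraints are analytically infeasible for the request, or
    if the attempt cap (10,000) is exhausted.
    """
    if not 0 <= n_events <= 3:
        raise ValueError("n_events must be in {0, 1, 2, 3}")
    lo, hi = EventSchedule.START_MARGIN, trial_duration - EventSchedule.END_MARGIN
    if n_events == 0:
        return EventSchedule(trial_duration, ())
    needed = (n_events - 1) * EventSchedule.MIN_GAP
    if hi - lo < needed or hi < lo:
        raise ValueError(
            f"{n_events} events with 1.1 s gaps cannot fit in the usable "
            f"window [{lo:.2f}, {hi:.2f}] s of a {trial_duration} s trial"
        )
    rng = _rng(seed)
    for _ in range(10_000):
        onsets = np.sort(rng.uniform(lo, hi, size=n_events))
        if n_events == 1 or np.all(np.diff(onsets) >= EventSchedule.MIN_GAP):
            return EventSchedule(trial_duration, tuple(Event(float(t)) for t in onsets))
    raise RuntimeError(
        f"rejection sampling failed after 10000 attempts "
        f"(duration={trial_duration}, n_events={n_events})"
    )


# cued location sets per focus condition in Experiment 2
_EXP2_CUED = {
    "narrow_innermost": frozenset({"innermost"}),
    "narrow_intermediate": frozenset({"intermediate"}),
    "split": frozenset({"innermost", "outermost"}),
    "broad": frozenset(LOCATIONS),
}


def _config_label(locs: frozenset) -> str:
    if len(locs) == 1:
        return "singular"
    if len(locs) == 3:
        return "all-cued"
    return "adjacent" if "intermediate" in locs else "disjoint"


def assign_event_kinds(focus: str, schedule: EventSchedule, seed,
                       stratified: bool = False) -> EventSchedule:
    """Label scheduled dimming events as targets or nontargets.

    Each event is independently a target with p = 0.5 ("half of them at the
    cued locations"); ``stratified=True`` instead fixes the target count to
    ``round(n/2)`` exactly. Target/nontarget dimming configurations depend on
    the focus condition:

    - narrow (cue innermost or intermediate): target = the cued location dims;
      nontarget = one of the two uncued locations dims (equally probable).
    - split (cue innermost + outermost): target = both cued locations dim
      synchronously (disjoint); nontarget = singular (any one location) or
      adjacent (the intermediate plus one cued location), equally probable at
      the configuration level.
    - broad (all three cued): target = any two of the three locations dim
      synchronously; nontarget = any single location dims.
    """
    key = focus
    if focus == "narrow":
        raise ValueError(
            "narrow focus must specify the cued location: "
            "use 'narrow_innermost' or 'narrow_intermediate'"
        )
    if key not in _EXP2_CUED:
        raise ValueError(f"unknown focus condition {focus!r}")
    cued = _EXP2_CUED[key]
    rng = _rng(seed)
    n = len(schedule.events)
    if stratified and n:
        n_targets = round(n / 2)
        is_target = np.zeros(n, bool)
        is_target[rng.choice(n, size=n_targets, replace=False)] = True
    else:
        is_target = rng.random(n) < 0.5

    pairs = [frozenset(p) for p in
             (("innermost", "intermediate"), ("intermediate", "outermost"),
              ("innermost", "outermost"))]
    uncued = [l for l in LOCATIONS if l not in cued]

    events = []
    for ev, tgt in zip(schedule.events, is_target):
        if tgt:
            if key.startswith("narrow"):
                locs = cued
            elif key == "split":
                locs = frozenset({"innermost", "outermost"})
            else:  # broad: any two of the three
                locs = pairs[rng.integers(3)]
        else:
            if key.startswith("narrow"):
                locs = frozenset({uncued[rng.integers(2)]})
            elif key == "split":
                if rng.integers(2) == 0:  # singular: any one location
                    locs = frozenset({LOCATIONS[rng.integers(3)]})
                else:  # adjacent: intermediate + one cued
                    c = ("innermost", "outermost")[rng.integers(2)]
                    locs = frozenset({c, "intermediate"})
            else:  # broad
                locs = frozenset({LOCATIONS[rng.integers(3)]})
        events.append(replace(ev, kind="target" if tgt else "nontarget",
                              configuration=_config_label(locs), locations=locs))
    return EventSchedule(schedule.trial_duration, tuple(events))


@dataclass(frozen=True)
class DimmingProfile:
    """Transient transparency (alpha) trajectory of a dimming event.

    Alpha follows a Gaussian bump over the event duration, peaking at ``mu``
    (the halfway point by default). With sigma = 1 s over a 0.4 s event the
    bump is nearly linear up and down. The trajectory is normalized so alpha
    starts and ends at 0 and peaks at ``depth``.
    """

    duration: float = 0.4  # s
    mu: float = 0.2  # s, peak time
    sigma: float = 1.0  # s
    depth: float = 1.0  # peak alpha, in [0, 1]

    def trajectory(self, refresh: float = 120.0) -> np.ndarray:
        t = np.arange(0, self.duration + 1e-9, 1.0 / refresh)
        g = np.exp(-0.5 * ((t - self.mu) / self.sigma) ** 2)
        base = min(g[0], g[-1])
        traj = (g - base) / (g.max() - base) * self.depth
        return np.clip(traj, 0.0, 1.0)


# ---------------------------------------------------------------------------
# RSVP streams (Experiment 3)

_EXP3_CUED = {
    "split": frozenset({"innermost", "outermost"}),
    "broad": frozenset(LOCATIONS),
}


@dataclass(frozen=True)
class RsvpStream:
    """A per-location letter stream with scheduled target/nontarget frames."""

    focus: str
    switch_rate: float  # Hz
    letters: tuple  # letters[frame] = dict location -> letter
    target_onsets: tuple  # s
    nontarget_onsets: tuple  # s

    @property
    def n_frames(self):
        return len(self.letters)


def _frame_config(frame: dict, cued: frozenset) -> str:
    """Classify a letter frame: 'target', 'nontarget' or 'none'."""
    letters = [frame[l] for l in LOCATIONS]
    if len(cued) == 3:  # broad
        same = sum(a == b for a, b in
                   ((letters[0], letters[1]), (letters[1], letters[2]), (letters[0], letters[2])))
        if letters[0] == letters[1] == letters[2]:
            return "target"
        if same >= 1:
            return "nontarget"
        return "none"
    # split: cued = innermost + outermost
    if frame["innermost"] == frame["outermost"]:
        return "target"
    if frame["intermediate"] in (frame["innermost"], frame["outermost"]):
        return "nontarget"
    return "none"


def make_rsvp_stream(focus: str, switch_rate: float, trial_duration: float,
                     n_targets: int, seed, n_nontargets: int = 0,
                     pretest: float = 0.5) -> RsvpStream:
    """Build an RSVP letter stream with exactly the scheduled events.

    Letters are drawn uniformly from the 15-consonant alphabet per location
    and frame. Target frames show the same letter at every cued location
    (split: the intermediate letter differs); nontarget frames show the
    condition's distractor conjunction (split: the intermediate location
    matches exactly one cued location; broad: exactly two of three match).
    All other frames are re-drawn until they contain neither configuration,
    so the scheduled onsets are the complete event list. No event lands in
    the pretest interval; event onsets keep a 1.1 s minimum separation.
    """
    if focus not in _EXP3_CUED:
        raise ValueError(f"unknown focus condition {focus!r}; expected split or broad")
    if not 0 <= n_targets <= 2:
        raise ValueError("n_targets must be in {0, 1, 2}")
    if switch_rate <= 0:
        raise ValueError("switch rate must be positive")
    rng = _rng(seed)
    cued = _EXP3_CUED[focus]
    n_frames = int(math.floor(trial_duration * switch_rate))
    frame_dur = 1.0 / switch_rate
    n_events = n_targets + n_nontargets

    # eligible frames: onset >= pretest, event fully inside the trial
    eligible = [i for i in range(n_frames) if i * frame_dur >= pretest - 1e-9]
    if n_events > len(eligible):
        raise ValueError("switch rate too low to fit the requested events")

    # pick event frames with >= 1.1 s onset separation (rejection sampling)
    min_gap_frames = math.ceil(1.1 * switch_rate)
    for _ in range(10_000):
        picked = sorted(rng.choice(eligible, size=n_events, replace=False)) if n_events else []
        if all(b - a >= min_gap_frames for a, b in zip(picked, picked[1:])):
            break
    else:
        raise RuntimeError("could not place events with 1.1 s separation; "
                           "lower n_targets/n_nontargets or raise trial_duration")
    kinds = ["target"] * n_targets + ["nontarget"] * n_nontargets
    rng.shuffle(kinds)
    event_frames = dict(zip(picked, kinds))

    def draw_letter():
        return RSVP_ALPHABET[rng.integers(len(RSVP_ALPHABET))]

    frames = []
    for i in range(n_frames):
        kind = event_frames.get(i, "none")
        for _ in range(1000):
            frame = {l: draw_letter() for l in LOCATIONS}
            if kind == "target":
                common = draw_letter()
                for l in cued:
                    frame[l] = common
                if focus == "split":
                    while frame["intermediate"] == common:
                        frame["intermediate"] = draw_letter()
            elif kind == "nontarget":
                common = draw_letter()
                if focus == "split":
                    c = ("innermost", "outermost")[rng.integers(2)]
                    other = "outermost" if c == "innermost" else "innermost"
                    frame[c] = common
                    frame["intermediate"] = common
                    while frame[other] == common:
                        frame[other] = draw_letter()
                else:  # broad: exactly two of three share
                    pair = [["innermost", "intermediate"], ["intermediate", "outermost"],
                            ["innermost", "outermost"]][rng.integers(3)]
                    odd = next(l for l in LOCATIONS if l not in pair)
                    frame[pair[0]] = frame[pair[1]] = common
                    while frame[odd] == common:
                        frame[odd] = draw_letter()
            if _frame_config(frame, cued) == (kind if kind != "none" else "none"):
                break
        else:  # pragma: no cover - 15 letters make collisions vanishingly rare
            raise RuntimeError("could not draw a conforming letter frame")
        frames.append(frame)

    t_on = tuple(i * frame_dur for i, k in sorted(event_frames.items()) if k == "target")
    nt_on = tuple(i * frame_dur for i, k in sorted(event_frames.items()) if k == "nontarget")
    return RsvpStream(focus, switch_rate, tuple(frames), t_on, nt_on)


# ---------------------------------------------------------------------------
# full sessions


@dataclass
class SessionDesign:
    """A full session: one row per trial, plus (Exp 2/3) one row per event."""

    experiment: str
    trials: pd.DataFrame
    events: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_trials(self):
        return len(self.trials)

    def to_tsv(self, trials_path, events_path=None):
        self.trials.to_csv(trials_path, sep="\t", index=False)
        if events_path is not None and len(self.events):
            self.events.to_csv(events_path, sep="\t", index=False)


def _balanced_block_order(conditions, n_blocks, rng):
    """Balanced random order: each condition equally often, shuffled in
    balanced chunks (a pragmatic stand-in for Latin-square sequencing)."""
    if n_blocks % len(conditions):
        raise ValueError(f"{n_blocks} blocks not divisible by {len(conditions)} conditions")
    order = []
    for _ in range(n_blocks // len(conditions)):
        chunk = list(conditions)
        rng.shuffle(chunk)
        order.extend(chunk)
    return order


def build_session(experiment: str, n_trials: int, seed) -> SessionDesign:
    """Generate a counterbalanced single-participant session.

    Block sizes follow each experiment's design (Exp 1: 10, Exp 2: 5,
    Exp 3: 3). Cued sides alternate across blocks; focus conditions are
    balanced within a session. Experiment 3 flips the frequency layout every
    block so each frequency appears on each side equally often.
    """
    rng = _rng(seed)
    if experiment == "exp1":
        return _build_exp1(n_trials, rng)
    if experiment == "exp2":
        return _build_exp2(n_trials, rng)
    if experiment == "exp3":
        return _build_exp3(n_trials, rng)
    raise ValueError(f"unknown experiment {experiment!r}")


def _sides(n_blocks, rng, abba=False):
    """Alternating cued sides; ``abba`` uses an L,R,R,L period-4 pattern so a
    quantity that itself alternates every block (the Exp 3 layout flip) stays
    balanced within each side."""
    first = ("left", "right")[rng.integers(2)]
    other = "right" if first == "left" else "left"
    if abba:
        return [first if i % 4 in (0, 3) else other for i in range(n_blocks)]
    return [first if i % 2 == 0 else other for i in range(n_blocks)]


def _build_exp1(n_trials, rng):
    block = 10
    if n_trials % (block * 6):
        raise ValueError(f"exp1 trial count must be divisible by {block * 6}")
    n_blocks = n_trials // block
    sides = _sides(n_blocks, rng)
    # balance focus within each side's block sequence so focus x side is exact
    per_side_order = {
        s: _balanced_block_order(_FOCI, n_blocks // 2, rng) for s in ("left", "right")
    }
    counters = {"left": 0, "right": 0}
    tables = {f: make_probability_table(f) for f in _FOCI}
    rows = []
    trial = 0
    for b in range(n_blocks):
        side = sides[b]
        focus = per_side_order[side][counters[side]]
        counters[side] += 1
        locs = tables[focus].sample(rng, size=block)
        for loc in locs:
            rows.append({
                "trial": trial, "block": b, "focus": focus, "side": side,
                "probe_location": loc,
                "probe_cued": loc in tables[focus].cued,
            })
            trial += 1
    return SessionDesign("exp1", pd.DataFrame(rows))


_EXP2_CONDITIONS = ("narrow_innermost", "narrow_intermediate", "split", "broad")


def _build_exp2(n_trials, rng):
    block = 5
    if n_trials % (block * len(_EXP2_CONDITIONS) * 2):
        raise ValueError(f"exp2 trial count must be divisible by {block * 8}")
    n_blocks = n_trials // block
    sides = _sides(n_blocks, rng)
    per_side_order = {
        s: _balanced_block_order(_EXP2_CONDITIONS, n_blocks // 2, rng)
        for s in ("left", "right")
    }
    counters = {"left": 0, "right": 0}
    trial_rows, event_rows = [], []
    trial = 0
    for b in range(n_blocks):
        side = sides[b]
        cond = per_side_order[side][counters[side]]
        counters[side] += 1
        cued = _EXP2_CUED[cond]
        for _ in range(block):
            dur = float(rng.uniform(4.5, 5.0))
            n_ev = int(rng.integers(1, 4))
            sched = assign_event_kinds(cond, schedule_dimming_events(dur, n_ev, rng), rng)
            row = {
                "trial": trial, "block": b, "focus": cond, "side": side,
                "trial_duration": dur, "n_events": n_ev,
            }
            for loc in LOCATIONS:
                row[f"freq_{loc}"] = EXP2_FREQS[loc].freq_display
            row["attended_freqs"] = ",".join(
                str(EXP2_FREQS[l].freq_display) for l in LOCATIONS if l in cued)
            trial_rows.append(row)
            for ev in sched.events:
                event_rows.append({
                    "trial": trial, "onset": ev.onset, "kind": ev.kind,
                    "configuration": ev.configuration,
                    "locations": ",".join(sorted(ev.locations)),
                })
            trial += 1
    return SessionDesign("exp2", pd.DataFrame(trial_rows), pd.DataFrame(event_rows))


def exp3_frequency_map(flipped: bool) -> dict:
    """Location -> display frequency for both hemifields.

    Unflipped: the low-frequency triplet (7.06, 8, 9.23 Hz; outer->inner) sits
    on the right side and the high triplet (10.91, 12, 13.33; inner->outer) on
    the left. Flipping mirrors the layout about the vertical meridian.
    """
    lows = [f.freq_display for f in EXP3_FREQS[:3]]  # 7.06, 8, 9.23 outer->inner
    highs = [f.freq_display for f in EXP3_FREQS[3:]]  # 10.91, 12, 13.33 inner->outer
    right = {"outermost": lows[0], "intermediate": lows[1], "innermost": lows[2]}
    left = {"innermost": highs[0], "intermediate": highs[1], "outermost": highs[2]}
    if flipped:
        left, right = right, left
    return {"left": left, "right": right}


def _build_exp3(n_trials, rng):
    block = 3
    cell = block * 2 * 2 * 2  # focus x side x layout
    if n_trials % cell:
        raise ValueError(f"exp3 trial count must be divisible by {cell}")
    n_blocks = n_trials // block
    sides = _sides(n_blocks, rng, abba=True)
    per_side_order = {
        s: _balanced_block_order(("split", "broad"), n_blocks // 2, rng)
        for s in ("left", "right")
    }
    counters = {"left": 0, "right": 0}
    trial_rows, event_rows = [], []
    trial = 0
    for b in range(n_blocks):
        side = sides[b]
        focus = per_side_order[side][counters[side]]
        counters[side] += 1
        flipped = bool(b % 2)  # layout flips every block
        fmap = exp3_frequency_map(flipped)
        for _ in range(block):
            dur = float(rng.uniform(4.5, 5.0))
            n_t = int(rng.integers(0, 3))
            # distractor count unstated in the source design; uniform up to a
            # total of 3 events so the 1.1 s separations always fit
            n_nt = int(rng.integers(0, min(2, 3 - n_t) + 1))
            stream = make_rsvp_stream(focus, 2.5, dur, n_t, rng, n_nontargets=n_nt)
            row = {
                "trial": trial, "block": b, "focus": focus, "side": side,
                "layout_flipped": flipped, "trial_duration": dur,
                "n_targets": n_t, "n_nontargets": n_nt,
            }
            uncued_side = "right" if side == "left" else "left"
            for loc in LOCATIONS:
                row[f"freq_{loc}"] = fmap[side][loc]
                row[f"freq_{loc}_uncued"] = fmap[uncued_side][loc]
            trial_rows.append(row)
            for t in stream.target_onsets:
                event_rows.append({"trial": trial, "onset": t, "kind": "target"})
            for t in stream.nontarget_onsets:
                event_rows.append({"trial": trial, "onset": t, "kind": "nontarget"})
            trial += 1
    return SessionDesign("exp3", pd.DataFrame(trial_rows), pd.DataFrame(event_rows))
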