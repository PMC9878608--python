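"""Behavioural trial lists, naturalness-boundary aggregation and run schedules.

The behavioural session measures, by method of adjustment, where along
each principal component a face stops looking natural; the mean boundary
(and its between-participant SD) anchors the five caricature levels used
in the scanner: boundary - 1 SD, boundary, +1, +3 and +6 SD beyond it.
Schedules are BIDS-style event tables (onset, duration, trial_type, ...)
for the event-related caricature runs and the blocked localiser runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: level offsets (in between-participant boundary SDs) used in the scanner
LEVEL_OFFSETS = (-1, 0, 1, 3, 6)
#: offsets that are additionally shown picture-plane inverted
INVERTED_OFFSETS = (-1, 6)

EVENT_COLUMNS = ["onset", "duration", "trial_type", "component", "level_sd", "orientation"]


def condition_label(component: int, offset: int, orientation: str = "upright") -> str:
    sign = f"+{offset}" if offset >= 0 else str(offset)
    suffix = "_inv" if orientation == "inverted" else ""
    return f"pc{component}_{sign}sd{suffix}"


def level_label(offset: int, orientation: str = "upright") -> str:
    """Label of a level-pooled analysis condition (components collapsed)."""
    sign = f"+{offset}" if offset >= 0 else str(offset)
    suffix = "_inv" if orientation == "inverted" else ""
    return f"{sign}sd{suffix}"


@dataclass
class RunSchedule:
    """Ordered stimulus events plus rest padding and attention events."""

    events: pd.DataFrame  # EVENT_COLUMNS
    total_duration: float
    tr: float = 2.0
    attention_onsets: np.ndarray = field(default_factory=lambda: np.array([]))
    kind: str = "event_related"

    def __post_init__(self) -> None:
        ev = self.events
        onsets = ev["onset"].to_numpy()
        if len(onsets) > 1:
            if not np.all(np.diff(onsets) > 0):
                raise ValueError("event onsets must be strictly increasing")
            ends = onsets + ev["duration"].to_numpy()
            if np.any(ends[:-1] > onsets[1:] + 1e-9):
                raise ValueError("events must not overlap")
        if len(onsets) and onsets[-1] + ev["duration"].iloc[-1] > self.total_duration + 1e-9:
            raise ValueError("events extend past total duration")

    @property
    def n_volumes(self) -> int:
        n = self.total_duration / self.tr
        if abs(n - round(n)) > 1e-9:
            raise ValueError("total duration is not a whole number of TRs")
        return int(round(n))

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.events["trial_type"]))

    def to_tsv(self, path: str | Path) -> None:
        self.events.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, total_duration: float, tr: float = 2.0, kind: str = "event_related"
    ) -> "RunSchedule":
        ev = pd.read_csv(path, sep="\t")
        return cls(events=ev, total_duration=total_duration, tr=tr, kind=kind)


def behavioural_trial_list(
    classes: int = 2,
    components: int = 5,
    directions: int = 2,
    repetitions: int = 6,
    max_caricature_bounds: tuple[float, float] = (8.0, 14.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Shuffled method-of-adjustment trial list.

    Every (class, component, direction) cell appears exactly
    ``repetitions`` times — the canonical 2 classes x 5 components x 2
    directions x 6 repeats gives 120 trials.  The slider's maximal
    caricature is drawn uniformly per trial so its endpoint cannot cue
    the boundary.
    """
    if min(classes, components, directions, repetitions) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    rows = [
        {"class": c, "component": pc + 1, "direction": d}
        for c in range(classes)
        for pc in range(components)
        for d in (+1, -1)[:directions]
        for _ in range(repetitions)
    ]
    df = pd.DataFrame(rows)
    df = df.sample(frac=1.0, random_state=np.random.RandomState(seed)).reset_index(drop=True)
    lo, hi = max_caricature_bounds
    df["max_caricature_sd"] = rng.uniform(lo, hi, size=len(df))
    df.index.name = "trial"
    return df


def aggregate_boundaries(table: pd.DataFrame, expected_repetitions: int = 6) -> pd.DataFrame:
    """Per-direction naturalness boundaries: participant means, group mean/SD.

    ``table`` is long format with columns participant, class, component,
    direction, transition_sd.  Group SD uses denominator n-1 over the
    participant means; with a single participant the SD is undefined and
    flagged.  Directions with missing repetitions are flagged too.
    """
    required = {"participant", "class", "component", "direction", "transition_sd"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if (table["transition_sd"] < 0).any():
        raise ValueError("transition points must be >= 0")
    keys = ["class", "component", "direction"]
    out = []
    for dir_key, grp in table.groupby(keys):
        per_part = grp.groupby("participant")["transition_sd"].agg(["mean", "count"])
        n = len(per_part)
        flags = []
        if (per_part["count"] != expected_repetitions).any():
            flags.append("missing_repetitions")
        if n < 2:
            flags.append("single_participant")
        out.append(
            {
                **dict(zip(keys, dir_key)),
                "n_participants": n,
                "group_mean": per_part["mean"].mean(),
                "group_sd": per_part["mean"].std(ddof=1) if n >= 2 else np.nan,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(out)


def participant_boundary_means(table: pd.DataFrame) -> pd.DataFrame:
    """Mean transition point per participant per direction (over repetitions)."""
    keys = ["participant", "class", "component", "direction"]
    return table.groupby(keys, as_index=False)["transition_sd"].mean()


def caricature_condition_set(
    boundary_mean: float | np.ndarray,
    boundary_sd: float | np.ndarray,
    components: int = 3,
) -> pd.DataFrame:
    """The scanner condition set: 5 upright levels + 2 inverted per component.

    Absolute positions are boundary_mean + offset * boundary_sd; the
    canonical 3 components give 21 conditions (15 upright, 6 inverted).
    Negative absolute positions are clipped to 0 with a warning flag.
    """
    means = np.broadcast_to(np.asarray(boundary_mean, float), (components,))
    sds = np.broadcast_to(np.asarray(boundary_sd, float), (components,))
    if np.any(sds <= 0):
        raise ValueError("boundary_sd must be positive")
    rows = []
    for pc in range(1, components + 1):
        for off in LEVEL_OFFSETS:
            pos = means[pc - 1] + off * sds[pc - 1]
            clipped = pos < 0
            pos = max(pos, 0.0)
            orientations = ["upright"] + (["inverted"] if off in INVERTED_OFFSETS else [])
            for ori in orientations:
                rows.append(
                    {
                        "trial_type": condition_label(pc, off, ori),
                        "level_label": level_label(off, ori),
                        "component": pc,
                        "level_offset": off,
                        "level_sd": pos,
                        "orientation": ori,
                        "clipped": clipped,
                    }
                )
    return pd.DataFrame(rows)


def upright_labels(condition_set: pd.DataFrame) -> list[str]:
    return condition_set.loc[condition_set["orientation"] == "upright", "trial_type"].tolist()


def _place_attention_events(
    rng: np.random.Generator, n: int, total: float, duration: float = 0.05, min_gap: float = 1.0
) -> np.ndarray:
    """Uniform attention-event onsets with a minimum gap between them."""
    if n == 0:
        return np.array([])
    lo, hi = 0.5, total - 1.0
    slack = (hi - lo) - (n - 1) * min_gap
    if slack <= 0:
        raise ValueError(f"cannot place {n} events {min_gap} s apart in {total} s")
    # uniform order statistics in the slack, shifted by the guaranteed gaps
    base = np.sort(rng.uniform(0.0, slack, size=n))
    return lo + base + min_gap * np.arange(n)


def event_related_schedule(
    conditions: pd.DataFrame,
    repeats: int = 3,
    isi_menu: tuple[float, ...] = (3.0, 5.0, 7.0),
    stim_dur: float = 1.0,
    lead_in: float = 8.0,
    trailing_rest: float = 8.0,
    tr: float = 2.0,
    n_attention: int = 42,
    seed: int = 0,
) -> RunSchedule:
    """Event-related caricature run: jittered ISIs with exact per-ISI counts.

    Each condition repeats ``repeats`` times; the ISI menu is balanced
    exactly (trial count must divide by the menu size).  The run starts
    with ``lead_in`` s of rest and the final stimulus is followed by its
    ISI plus ``trailing_rest`` s, so the canonical 63-trial run lasts
    lead_in + sum(stim + ISI) + trailing_rest = 394 s (197 volumes at
    TR 2 s).
    """
    rng = np.random.default_rng(seed)
    trial_rows = pd.concat([conditions] * repeats, ignore_index=True)
    n_trials = len(trial_rows)
    if n_trials == 0:
        return RunSchedule(
            events=pd.DataFrame(columns=EVENT_COLUMNS),
            total_duration=lead_in + trailing_rest,
            tr=tr,
            attention_onsets=_place_attention_events(
                rng, min(n_attention, 2), lead_in + trailing_rest
            ),
        )
    if n_trials % len(isi_menu) != 0:
        raise ValueError(
            f"{n_trials} trials not divisible by {len(isi_menu)} ISI durations"
        )
    order = rng.permutation(n_trials)
    trial_rows = trial_rows.iloc[order].reset_index(drop=True)
    isis = np.repeat(isi_menu, n_trials // len(isi_menu)).astype(float)
    rng.shuffle(isis)

    onsets = lead_in + np.concatenate([[0.0], np.cumsum(stim_dur + isis[:-1])])
    total = lead_in + float(np.sum(stim_dur + isis)) + trailing_rest
    events = pd.DataFrame({"onset": onsets, "duration": stim_dur})
    carried = [
        c
        for c in ("trial_type", "level_label", "component", "level_offset", "level_sd", "orientation")
        if c in trial_rows.columns
    ]
    for c in carried:
        events[c] = trial_rows[c].to_numpy()
    events["isi"] = isis
    attention = _place_attention_events(rng, n_attention, total)
    return RunSchedule(
        events=events, total_duration=total, tr=tr, attention_onsets=attention
    )


def pool_by_level(schedule: RunSchedule) -> RunSchedule:
    """Relabel events by caricature level, collapsing across components.

    The scanner analyses treat the stimulus set as 7 types — the 5
    upright caricature levels plus the 2 inverted extremes — regardless
    of which component was modulated.
    """
    if "level_label" not in schedule.events.columns:
        raise ValueError("schedule events carry no level labels")
    ev = schedule.events.copy()
    ev["trial_type"] = ev["level_label"]
    return RunSchedule(
        events=ev,
        total_duration=schedule.total_duration,
        tr=schedule.tr,
        attention_onsets=schedule.attention_onsets,
        kind=schedule.kind,
    )


def localiser_schedule(
    categories: tuple[str, ...] = ("faces", "objects", "scenes"),
    blocks_per_category: int = 8,
    images_per_block: int = 8,
    image_dur: float = 1.0,
    off_dur: float = 8.0,
    tr: float = 2.0,
    n_attention: int = 130,
    seed: int = 0,
) -> RunSchedule:
    """Blocked localiser run: 8 s ON (8 x 1 s images), 8 s OFF, OFF at both ends.

    Duration = off + n_blocks * (block + off); the canonical 24 blocks
    give 392 s (196 volumes at TR 2 s).
    """
    if blocks_per_category < 1 or images_per_block < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    block_order = np.repeat(categories, blocks_per_category)
    rng.shuffle(block_order)
    block_len = images_per_block * image_dur
    rows = []
    t = off_dur
    for cat in block_order:
        for i in range(images_per_block):
            rows.append(
                {
                    "onset": t + i * image_dur,
                    "duration": image_dur,
                    "trial_type": cat,
                    "component": np.nan,
                    "level_sd": np.nan,
                    "orientation": "upright",
                }
            )
        t += block_len + off_dur
    total = off_dur + len(block_order) * (block_len + off_dur)
    events = pd.DataFrame(rows)
    attention = _place_attention_events(rng, n_attention, total, min_gap=0.5)
    return RunSchedule(
        events=events,
        total_duration=total,
        tr=tr,
        attention_onsets=attention,
        kind="localiser",
    )


def block_onsets(schedule: RunSchedule, block_len: float = 8.0) -> pd.DataFrame:
    """Collapse a localiser image-event table into (onset, duration, category) blocks."""
    ev = schedule.events.sort_values("onset")
    blocks = []
    for cat, grp in ev.groupby("trial_type"):
        onsets = grp["onset"].to_numpy()
        start = onsets[0]
        prev = onsets[0]
        for o in onsets[1:]:
            if o - prev > grp["duration"].iloc[0] + 1e-9:
                blocks.append({"onset": start, "duration": prev - start + grp["duration"].iloc[0], "trial_type": cat})
                start = o
            prev = o
        blocks.append({"onset": start, "duration": prev - start + grp["duration"].iloc[0], "trial_type": cat})
    return pd.DataFrame(blocks).sort_values("onset").reset_index(drop=True)
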