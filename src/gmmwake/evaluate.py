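"""Ictal-state labeling, alarm-based metrics, and the wake-up power model.

A recording is annotated with seizure intervals; every analysis window is
assigned exactly one of four states: ictal (during a seizure), pre-ictal
(the hour before onset), post-ictal (the hour after offset), or
inter-ictal (everything else).  Where periods overlap, precedence is
ictal > pre-ictal > post-ictal > inter-ictal, so an imminent seizure
always wins.

Sensitivity is alarm-based: a seizure counts as predicted when at least
one alarm is raised in its pre-ictal period.  Specificity is
window-based over inter-ictal windows only — it equals the fraction of
no-risk time the digital back-end stays asleep — and ictal/post-ictal
windows are excluded from both metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INTER_ICTAL",
    "PRE_ICTAL",
    "ICTAL",
    "POST_ICTAL",
    "SeizureTimeline",
    "EvalReport",
    "label_timeline",
    "alarms_from_predictions",
    "sensitivity",
    "specificity",
    "system_power",
    "evaluate_alarms",
    "read_timeline_csv",
    "write_timeline_csv",
]

INTER_ICTAL = "inter_ictal"
PRE_ICTAL = "pre_ictal"
ICTAL = "ictal"
POST_ICTAL = "post_ictal"

#: default pre-/post-ictal horizon, seconds (one hour each side)
DEFAULT_PRE_DUR = 3600.0
DEFAULT_POST_DUR = 3600.0


@dataclass
class SeizureTimeline:
    """Seizure annotations over a recording of ``duration`` seconds.

    ``seizures`` is a sorted list of non-overlapping (onset, offset)
    intervals in seconds, all inside (0, duration].
    """

    duration: float
    seizures: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        self.seizures = [(float(a), float(b)) for a, b in self.seizures]
        prev_end = 0.0
        for onset, offset in self.seizures:
            if not (0.0 <= onset < offset <= self.duration):
                raise ValueError(f"seizure ({onset}, {offset}) outside (0, {self.duration}]")
            if onset < prev_end:
                raise ValueError("seizures must be sorted and non-overlapping")
            prev_end = offset

    @property
    def n_seizures(self) -> int:
        return len(self.seizures)


@dataclass
class EvalReport:
    """Summary of one evaluation run."""

    sensitivity: float | None
    specificity: float | None
    n_predicted: int
    n_missed: int
    n_true_negative: int
    n_false_positive: int
    duty_cycle: float | None = None
    system_power_w: float | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    def to_text(self) -> str:
        lines = [
            f"sensitivity       : {self.sensitivity if self.sensitivity is not None else 'NA'}",
            f"specificity       : {self.specificity if self.specificity is not None else 'NA'}",
            f"predicted seizures: {self.n_predicted}",
            f"missed seizures   : {self.n_missed}",
            f"true negatives    : {self.n_true_negative}",
            f"false positives   : {self.n_false_positive}",
        ]
        if self.duty_cycle is not None:
            lines.append(f"back-end duty     : {self.duty_cycle:.4f}")
        if self.system_power_w is not None:
            lines.append(f"system power      : {self.system_power_w * 1e6:.4f} uW")
        return "\n".join(lines)


def label_timeline(
    tl: SeizureTimeline,
    window_starts: Sequence[float],
    pre_dur: float = DEFAULT_PRE_DUR,
    post_dur: float = DEFAULT_POST_DUR,
) -> np.ndarray:
    """Assign each window (by its start time) one of the four ictal states.

    Pre-ictal of a seizure spans [onset - pre_dur, onset); post-ictal
    spans [offset, offset + post_dur).  Precedence on overlap:
    ictal > pre-ictal > post-ictal > inter-ictal.
    """
    if pre_dur < 0 or post_dur < 0:
        raise ValueError("pre_dur and post_dur must be nonnegative")
    t = np.asarray(window_starts, dtype=float)
    labels = np.full(t.shape, INTER_ICTAL, dtype=object)
    # ascending precedence: later assignments overwrite earlier ones
    for onset, offset in tl.seizures:
        labels[(t >= offset) & (t < offset + post_dur)] = POST_ICTAL
    for onset, offset in tl.seizures:
        labels[(t >= onset - pre_dur) & (t < onset)] = PRE_ICTAL
    for onset, offset in tl.seizures:
        labels[(t >= onset) & (t < offset)] = ICTAL
    return labels


def alarms_from_predictions(predictions: Sequence[int], positive_class: int = 0,
                            smoothing: int = 1) -> np.ndarray:
    """Turn per-window class predictions into binary alarms.

    An alarm is raised at window i when the last ``smoothing`` consecutive
    windows (default 1, i.e. no debouncing) were all classified as the
    positive (pre-ictal) class.
    """
    if smoothing < 1:
        raise ValueError("smoothing must be >= 1")
    pos = np.asarray(predictions) == positive_class
    if smoothing == 1:
        return pos
    alarms = pos.copy()
    for k in range(1, smoothing):
        alarms[k:] &= pos[:-k]
        alarms[:k] = False
    return alarms


def sensitivity(
    alarms: Sequence[bool],
    window_starts: Sequence[float],
    tl: SeizureTimeline,
    pre_dur: float = DEFAULT_PRE_DUR,
    post_dur: float = DEFAULT_POST_DUR,
) -> tuple[float | None, int, int]:
    """Alarm-based sensitivity: predicted seizures over all seizures.

    A seizure is predicted when at least one alarm window is labeled
    pre-ictal and falls inside that seizure's pre-ictal interval.
    Returns (sensitivity, n_predicted, n_missed); sensitivity is None
    (NA) when the timeline holds no seizures.
    """
    alarms = np.asarray(alarms, dtype=bool)
    t = np.asarray(window_starts, dtype=float)
    if alarms.shape != t.shape:
        raise ValueError("alarms and window_starts must be aligned")
    if tl.n_seizures == 0:
        return None, 0, 0
    labels = label_timeline(tl, t, pre_dur=pre_dur, post_dur=post_dur)
    predicted = 0
    for onset, _ in tl.seizures:
        in_pre = (t >= onset - pre_dur) & (t < onset) & (labels == PRE_ICTAL)
        if np.any(alarms & in_pre):
            predicted += 1
    missed = tl.n_seizures - predicted
    return predicted / tl.n_seizures, predicted, missed


def specificity(alarms: Sequence[bool],
                labels: Sequence[str]) -> tuple[float | None, int, int]:
    """Window-based specificity over inter-ictal windows only.

    Returns (specificity, n_true_negative, n_false_positive); specificity
    is None (NA) when there are no inter-ictal windows.
    """
    alarms = np.asarray(alarms, dtype=bool)
    labels = np.asarray(labels, dtype=object)
    if alarms.shape != labels.shape:
        raise ValueError("alarms and labels must be aligned")
    inter = labels == INTER_ICTAL
    if not inter.any():
        return None, 0, 0
    fp = int(np.sum(alarms & inter))
    tn = int(np.sum(~alarms & inter))
    return tn / (tn + fp), tn, fp


def system_power(p_analog: float, p_digital: float, spec: float,
                 pre_frac: float) -> tuple[float, float]:
    """Wake-up power model.

    The digital back-end runs during all pre-ictal time plus the
    false-positive fraction of the remaining time:
    duty = pre_frac + (1 - pre_frac) * (1 - spec);
    total power = p_analog + duty * p_digital (watts).
    """
    if not 0.0 <= spec <= 1.0 or not 0.0 <= pre_frac <= 1.0:
        raise ValueError("spec and pre_frac must lie in [0, 1]")
    duty = pre_frac + (1.0 - pre_frac) * (1.0 - spec)
    return duty, p_analog + duty * p_digital


def evaluate_alarms(
    alarms: Sequence[bool],
    window_starts: Sequence[float],
    tl: SeizureTimeline,
    pre_dur: float = DEFAULT_PRE_DUR,
    post_dur: float = DEFAULT_POST_DUR,
    p_analog: float | None = None,
    p_digital: float | None = None,
) -> EvalReport:
    """Full alarm-based evaluation of one recording."""
    labels = label_timeline(tl, window_starts, pre_dur=pre_dur, post_dur=post_dur)
    sens, n_pred, n_miss = sensitivity(alarms, window_starts, tl, pre_dur, post_dur)
    spec, tn, fp = specificity(alarms, labels)
    duty = power = None
    if p_analog is not None and p_digital is not None and spec is not None:
        pre_frac = float(np.mean(labels == PRE_ICTAL))
        duty, power = system_power(p_analog, p_digital, spec, pre_frac)
    return EvalReport(
        sensitivity=sens,
        specificity=spec,
        n_predicted=n_pred,
        n_missed=n_miss,
        n_true_negative=tn,
        n_false_positive=fp,
        duty_cycle=duty,
        system_power_w=power,
    )


# ---------------------------------------------------------------------------
# I/O


def read_timeline_csv(path: str | Path, duration: float) -> SeizureTimeline:
    """Read a timeline CSV with columns (onset_s, offset_s)."""
    df = pd.read_csv(path)
    seizures = list(zip(df["onset_s"].astype(float), df["offset_s"].astype(float)))
    return SeizureTimeline(duration=duration, seizures=seizures)


def write_timeline_csv(path: str | Path, tl: SeizureTimeline) -> None:
    pd.DataFrame(tl.seizures, columns=["onset_s", "offset_s"]).to_csv(path, index=False)
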