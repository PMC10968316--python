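"""Rigid-body motion schedules and moved volume states.

A schedule lists the movement events that happen while one slice's k-space
is acquired line by line: each event has an onset (the phase-encode line
index at which it occurs), a rotation triple in degrees and a translation
triple in pixels. Movements are never undone — the subject stays in the new
pose — so the sequence of "motion states" is cumulative.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi

from .volume_io import Volume

__all__ = [
    "MotionEvent",
    "MotionSchedule",
    "SimulationParams",
    "sample_motion_schedule",
    "apply_rigid_transform",
    "generate_motion_states",
    "rotation_matrix",
]


@dataclass(frozen=True)
class MotionEvent:
    onset_line: int
    rotation: tuple[float, float, float]  # degrees about x, y, z
    translation: tuple[float, float, float]  # pixels along x, y, z


@dataclass
class MotionSchedule:
    events: list[MotionEvent]
    n_lines: int

    def __post_init__(self) -> None:
        onsets = [e.onset_line for e in self.events]
        if any(o2 <= o1 for o1, o2 in zip(onsets, onsets[1:])):
            raise ValueError(f"onset lines must be strictly increasing, got {onsets}")
        if onsets and not (0 <= onsets[0] and onsets[-1] < self.n_lines):
            raise ValueError(f"onset lines {onsets} outside [0, {self.n_lines})")

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset_line for e in self.events], dtype=np.int64)

    def to_json(self) -> str:
        return json.dumps({"n_lines": self.n_lines,
                           "events": [asdict(e) for e in self.events]})

    @classmethod
    def from_json(cls, text: str) -> "MotionSchedule":
        d = json.loads(text)
        events = [MotionEvent(int(e["onset_line"]), tuple(e["rotation"]),
                              tuple(e["translation"])) for e in d["events"]]
        return cls(events=events, n_lines=int(d["n_lines"]))


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the motion-artifact simulation.

    Defaults encode the reference protocol: rotations up to ±5°,
    translations up to ±10 px, two to four cumulative movements per slice,
    the first movement only after half of k-space has been acquired, an
    independent random schedule for every slice, and each new pose obtained
    by transforming the previous (already interpolated) pose.
    """

    max_rotation_deg: float = 5.0
    max_translation_px: float = 10.0
    n_movements_range: tuple[int, int] = (2, 4)
    min_onset_fraction: float = 0.5
    per_slice_independent: bool = True
    cumulative_resampling: bool = True
    interpolation_order: int = 1
    ordering: str = "linear"
    echo_train_length: int = 1
    reconstruction: str = "magnitude"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_rotation_deg <= 0 or self.max_translation_px <= 0:
            raise ValueError("motion amplitude bounds must be positive")
        lo, hi = self.n_movements_range
        if not (0 <= lo <= hi):
            raise ValueError(f"invalid n_movements_range {self.n_movements_range}")
        if not 0.0 <= self.min_onset_fraction < 1.0:
            raise ValueError("min_onset_fraction must lie in [0, 1)")
        if self.echo_train_length < 1:
            raise ValueError("echo_train_length must be >= 1")


def sample_motion_schedule(
    params: SimulationParams, n_lines: int, rng: np.random.Generator
) -> MotionSchedule:
    """Draw one random motion schedule.

    The event count is uniform on ``n_movements_range``; onsets are drawn
    without replacement from the lines strictly after
    ``floor(min_onset_fraction * n_lines)`` (snapped to echo-train
    boundaries when ``echo_train_length > 1``) and sorted; rotation and
    translation components are uniform on ±max.
    """
    if n_lines < 4:
        raise ValueError("need at least 4 phase-encode lines")
    lo, hi = params.n_movements_range
    n_events = int(rng.integers(lo, hi + 1))
    first_allowed = int(math.floor(params.min_onset_fraction * n_lines)) + 1
    candidates = np.arange(first_allowed, n_lines)
    if params.echo_train_length > 1:
        # movements can only happen between echo trains
        candidates = candidates[candidates % params.echo_train_length == 0]
    if len(candidates) < n_events:
        raise ValueError(
            f"cannot place {n_events} events on {len(candidates)} candidate lines"
        )
    onsets = np.sort(rng.choice(candidates, size=n_events, replace=False))
    events = []
    for onset in onsets:
        rot = rng.uniform(-params.max_rotation_deg, params.max_rotation_deg, 3)
        tra = rng.uniform(-params.max_translation_px, params.max_translation_px, 3)
        events.append(MotionEvent(int(onset), tuple(rot.tolist()), tuple(tra.tolist())))
    return MotionSchedule(events=events, n_lines=n_lines)


def rotation_matrix(rotation_deg: Sequence[float]) -> np.ndarray:
    """Combined rotation matrix for rotations applied in fixed order x→y→z."""
    ax, ay, az = (math.radians(a) for a in rotation_deg)
    rx = np.array([[1, 0, 0],
                   [0, math.cos(ax), -math.sin(ax)],
                   [0, math.sin(ax), math.cos(ax)]])
    ry = np.array([[math.cos(ay), 0, math.sin(ay)],
                   [0, 1, 0],
                   [-math.sin(ay), 0, math.cos(ay)]])
    rz = np.array([[math.cos(az), -math.sin(az), 0],
                   [math.sin(az), math.cos(az), 0],
                   [0, 0, 1]])
    return rz @ ry @ rx


def _apply_affine(v: Volume, rot: np.ndarray, translation: Sequence[float],
                  order: int) -> Volume:
    """Resample ``v`` under: rotate about the geometric centre, then translate."""
    data = v.data
    center = (np.array(data.shape, dtype=np.float64) - 1.0) / 2.0
    t = np.asarray(translation, dtype=np.float64)
    # output[p] = input[R^T @ p + offset]  with  offset = c - R^T @ (c + t)
    matrix = rot.T
    offset = center - matrix @ (center + t)
    moved = ndi.affine_transform(
        data, matrix, offset=offset, order=order,
        mode="constant", cval=0.0, prefilter=order > 1,
    )
    if order > 1:
        moved = np.clip(moved, 0.0, None)  # spline overshoot is unphysical
    return Volume(data=moved, voxel_size=v.voxel_size,
                  provenance=v.provenance, signed=v.signed)


def apply_rigid_transform(
    v: Volume,
    rotation: Sequence[float],
    translation: Sequence[float],
    order: int = 1,
) -> Volume:
    """Rigidly move a volume: rotation (degrees, x→y→z about the centre)
    followed by a pixel translation; zero fill outside the field of view."""
    return _apply_affine(v, rotation_matrix(rotation), translation, order)


def generate_motion_states(
    v: Volume, schedule: MotionSchedule, params: SimulationParams
) -> list[Volume]:
    """The sequence of poses implied by a schedule, one volume per event.

    In cumulative mode (default) state ``k`` is obtained by transforming
    state ``k-1``, so interpolation error compounds exactly as repeated
    physical resampling would. In composed mode each state is resampled
    once from the original volume under the algebraically composed rigid
    transform, which is sharper but not literally sequential.
    """
    states: list[Volume] = []
    if params.cumulative_resampling:
        current = v
        for ev in schedule.events:
            current = apply_rigid_transform(current, ev.rotation, ev.translation,
                                            params.interpolation_order)
            states.append(current)
    else:
        rot = np.eye(3)
        tra = np.zeros(3)
        for ev in schedule.events:
            r = rotation_matrix(ev.rotation)
            # (R2,t2)∘(R1,t1): x → R2 R1 (x−c) + c + R2 t1 + t2
            rot = r @ rot
            tra = r @ tra + np.asarray(ev.translation, dtype=np.float64)
            states.append(_apply_affine(v, rot, tra, params.interpolation_order))
    return states
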