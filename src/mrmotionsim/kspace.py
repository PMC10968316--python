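"""Centered 2D k-space transforms and phase-encode line replacement.

The simulation mimics what happens physically during a line-by-line spin-echo
acquisition: lines acquired before the subject moved come from the still
image, lines acquired afterwards come from the moved image, and the inverse
transform of the mixed k-space carries ghosting along the phase-encode axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motion import MotionSchedule, SimulationParams, sample_motion_schedule, \
    generate_motion_states
from .volume_io import Volume

__all__ = [
    "KSpace",
    "slice_to_kspace",
    "kspace_to_image",
    "acquisition_line_order",
    "compose_kspace",
    "simulate_artifact_slice",
    "simulate_artifact_volume",
]

PHASE_AXIS = 0  # in-plane axis whose lines are acquired one per TR


@dataclass
class KSpace:
    """Zero-frequency-centred 2D spatial-frequency data of one slice."""

    data: np.ndarray  # complex
    phase_axis: int = PHASE_AXIS

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("k-space data must be 2D")
        if self.phase_axis not in (0, 1):
            raise ValueError("phase_axis must be 0 or 1")

    @property
    def n_lines(self) -> int:
        return self.data.shape[self.phase_axis]


def slice_to_kspace(s: np.ndarray, phase_axis: int = PHASE_AXIS) -> KSpace:
    """Centred 2D DFT of an image slice."""
    s = np.asarray(s)
    if s.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {s.shape}")
    if not np.all(np.isfinite(s)):
        raise ValueError("slice contains non-finite values")
    k = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(s)))
    return KSpace(data=k, phase_axis=phase_axis)


def kspace_to_image(k: KSpace, reconstruction: str = "magnitude") -> np.ndarray:
    """Inverse centred DFT followed by magnitude (default) or clipped real part.

    Composed k-space is generally not conjugate-symmetric, so the inverse
    transform is complex; MR images are magnitude images, hence the default.
    """
    img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k.data)))
    if reconstruction == "magnitude":
        return np.abs(img)
    if reconstruction == "real":
        return np.clip(img.real, 0.0, None)
    raise ValueError(f"unknown reconstruction {reconstruction!r}")


def acquisition_line_order(n_lines: int, ordering: str = "linear") -> np.ndarray:
    """Map acquisition time index -> phase-encode line index.

    ``linear`` acquires lines top to bottom through the centred layout;
    ``centric`` starts at the centre line and alternates outwards.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be positive")
    if ordering == "linear":
        return np.arange(n_lines)
    if ordering == "centric":
        center = n_lines // 2
        out = [center]
        for off in range(1, n_lines):
            for line in (center - off, center + off):
                if 0 <= line < n_lines:
                    out.append(line)
        return np.array(out[:n_lines])
    raise ValueError(f"unknown acquisition ordering {ordering!r}")


def compose_kspace(
    clean: KSpace,
    states: list[KSpace],
    schedule: MotionSchedule,
    ordering: str = "linear",
) -> tuple[KSpace, np.ndarray]:
    """Replace phase-encode lines of the motion-free k-space with lines from
    the motion states that were active when each line was acquired.

    Walking lines in acquisition order, a line acquired at time ``t`` is
    taken from motion state ``k`` where ``k`` counts the events with onset
    ``<= t`` (state 0 is the motion-free slice). Returns the composite
    k-space and the per-line provenance array (indexed by line, not time).
    """
    if len(states) != schedule.n_events:
        raise ValueError(
            f"{schedule.n_events} events but {len(states)} motion states"
        )
    n_lines = clean.n_lines
    if schedule.n_lines != n_lines:
        raise ValueError(
            f"schedule covers {schedule.n_lines} lines, k-space has {n_lines}"
        )
    for st in states:
        if st.data.shape != clean.data.shape:
            raise ValueError("all k-space arrays must share one shape")

    order = acquisition_line_order(n_lines, ordering)
    times = np.arange(n_lines)
    active = np.searchsorted(schedule.onsets, times, side="right")
    provenance = np.empty(n_lines, dtype=np.int64)
    provenance[order] = active

    out = np.array(clean.data, copy=True)
    src = np.moveaxis(out, clean.phase_axis, 0)
    for k, st in enumerate(states, start=1):
        lines = provenance == k
        src[lines] = np.moveaxis(st.data, clean.phase_axis, 0)[lines]
    return KSpace(data=out, phase_axis=clean.phase_axis), provenance


def simulate_artifact_slice(
    v: Volume,
    z: int,
    params: SimulationParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, MotionSchedule]:
    """Produce one motion-corrupted slice and its signed residual map.

    Samples a schedule, builds the full-volume motion states (so in-plane
    and through-plane motion both leak into the slice), composes k-space
    line by line, and inverse-transforms. ``residual = artifact - clean``.
    """
    clean_slice = v.get_slice(z)
    n_lines = clean_slice.shape[PHASE_AXIS]
    schedule = sample_motion_schedule(params, n_lines, rng)
    states = generate_motion_states(v, schedule, params)

    ks_clean = slice_to_kspace(clean_slice)
    ks_states = [slice_to_kspace(s.get_slice(z)) for s in states]
    composite, _ = compose_kspace(ks_clean, ks_states, schedule, params.ordering)
    artifact = kspace_to_image(composite, params.reconstruction)
    residual = artifact - clean_slice
    # re-derive the artifact from the residual (changes it by at most one
    # ulp) so that clean + residual == artifact holds bit-exactly
    artifact = clean_slice + residual
    return artifact, residual, schedule


def _as_seed_tuple(seed: int | tuple[int, ...]) -> tuple[int, ...]:
    return tuple(seed) if isinstance(seed, (tuple, list)) else (int(seed),)


def simulate_artifact_volume(
    v: Volume,
    params: SimulationParams,
    seed: int | tuple[int, ...] = 0,
) -> tuple[Volume, Volume, list[MotionSchedule]]:
    """Corrupt every slice of a volume.

    With ``per_slice_independent`` (default) each slice gets its own random
    schedule from an rng stream derived from ``(seed, slice index)``, so a
    single-slice run and a whole-volume run agree slice for slice.
    Otherwise one schedule (and one set of motion states) is shared by all
    slices. Returns artifact volume, signed residual volume, and one
    schedule per slice (a single shared schedule repeated, in shared mode).
    """
    base = _as_seed_tuple(seed)
    artifact = np.empty_like(v.data, dtype=np.float64)
    residual = np.empty_like(v.data, dtype=np.float64)
    schedules: list[MotionSchedule] = []

    if params.per_slice_independent:
        for z in range(v.n_slices):
            rng = np.random.default_rng((*base, z))
            a, r, sched = simulate_artifact_slice(v, z, params, rng)
            artifact[:, :, z] = a
            residual[:, :, z] = r
            schedules.append(sched)
    else:
        rng = np.random.default_rng(base)
        n_lines = v.data.shape[PHASE_AXIS]
        schedule = sample_motion_schedule(params, n_lines, rng)
        states = generate_motion_states(v, schedule, params)
        for z in range(v.n_slices):
            clean_slice = v.get_slice(z)
            ks_clean = slice_to_kspace(clean_slice)
            ks_states = [slice_to_kspace(s.get_slice(z)) for s in states]
            composite, _ = compose_kspace(ks_clean, ks_states, schedule,
                                          params.ordering)
            a = kspace_to_image(composite, params.reconstruction)
            artifact[:, :, z] = a
            residual[:, :, z] = a - clean_slice
            schedules.append(schedule)

    art_vol = Volume(data=artifact, voxel_size=v.voxel_size,
                     provenance={**v.provenance, "simulated": True})
    res_vol = Volume(data=residual, voxel_size=v.voxel_size,
                     provenance={**v.provenance, "residual": True}, signed=True)
    return art_vol, res_vol, schedules
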