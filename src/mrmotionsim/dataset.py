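"""Paired-sample assembly, train/validation/test splitting, HDF5 persistence.

A paired sample is one slice in three views: the motion-free image, the
motion-corrupted image, and their signed residual. The stored artifact is
recomputed as ``clean + residual`` at storage precision, so the identity
``clean + residual == artifact`` holds bit-exactly for every sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import h5py
import numpy as np

from .kspace import simulate_artifact_volume
from .motion import MotionSchedule, SimulationParams
from .volume_io import Volume

__all__ = [
    "PairedSample",
    "DatasetSplit",
    "build_pairs",
    "split_dataset",
    "save_dataset",
    "load_dataset",
    "DatasetError",
]

STORAGE_DTYPE = np.float32


class DatasetError(IOError):
    """Raised when a dataset container is unreadable or incomplete."""


@dataclass
class PairedSample:
    clean: np.ndarray
    artifact: np.ndarray
    residual: np.ndarray
    subject_id: str
    slice_index: int
    schedule: MotionSchedule | None = None

    @classmethod
    def from_simulation(
        cls,
        clean: np.ndarray,
        artifact: np.ndarray,
        subject_id: str,
        slice_index: int,
        schedule: MotionSchedule | None = None,
    ) -> "PairedSample":
        clean = np.asarray(clean, dtype=STORAGE_DTYPE)
        residual = (np.asarray(artifact, dtype=STORAGE_DTYPE) - clean).astype(STORAGE_DTYPE)
        # re-derive the artifact so clean + residual == artifact exactly
        artifact = clean + residual
        return cls(clean=clean, artifact=artifact, residual=residual,
                   subject_id=subject_id, slice_index=slice_index,
                   schedule=schedule)

    def __post_init__(self) -> None:
        if not (self.clean.shape == self.artifact.shape == self.residual.shape):
            raise ValueError("clean, artifact and residual must share one shape")


@dataclass
class DatasetSplit:
    train: list[int]
    validation: list[int]
    test: list[int]
    fractions: tuple[float, float, float]
    seed: int

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.validation), len(self.test)


def build_pairs(
    clean_volumes: Sequence[Volume],
    params: SimulationParams,
    seed: int = 0,
    subject_ids: Sequence[str] | None = None,
) -> list[PairedSample]:
    """Simulate artifacts for every slice of every volume; one sample per slice.

    Volume ``i`` uses the derived seed ``(seed, i)`` so the result does not
    depend on how volumes are batched across calls.
    """
    if subject_ids is None:
        subject_ids = [f"subj{i:04d}" for i in range(len(clean_volumes))]
    samples: list[PairedSample] = []
    for i, vol in enumerate(clean_volumes):
        artifact, _, schedules = simulate_artifact_volume(vol, params, seed=(seed, i))
        for z in range(vol.n_slices):
            samples.append(PairedSample.from_simulation(
                clean=vol.data[:, :, z],
                artifact=artifact.data[:, :, z],
                subject_id=str(subject_ids[i]),
                slice_index=z,
                schedule=schedules[z],
            ))
    return samples


def split_dataset(
    samples: Sequence[PairedSample],
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
    by_subject: bool = False,
) -> DatasetSplit:
    """Deterministic shuffle then partition into train/validation/test.

    Partition sizes are ``floor(fraction * N)`` with any remainder assigned
    to the training partition. With ``by_subject``, subjects (not slices)
    are partitioned, so no subject contributes to two partitions.
    """
    f_train, f_val, f_test = fractions
    if min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be positive and sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)

    def partition(items: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = len(items)
        n_val = int(np.floor(f_val * n))
        n_test = int(np.floor(f_test * n))
        n_train = n - n_val - n_test  # floor(f_train*n) + remainder
        shuffled = rng.permutation(items)
        return (shuffled[:n_train], shuffled[n_train:n_train + n_val],
                shuffled[n_train + n_val:])

    if by_subject:
        subjects = sorted({s.subject_id for s in samples})
        tr_s, va_s, te_s = partition(np.array(subjects))
        tr_s, va_s, te_s = set(tr_s), set(va_s), set(te_s)
        train = [i for i, s in enumerate(samples) if s.subject_id in tr_s]
        val = [i for i, s in enumerate(samples) if s.subject_id in va_s]
        test = [i for i, s in enumerate(samples) if s.subject_id in te_s]
    else:
        tr, va, te = partition(np.arange(len(samples)))
        train, val, test = tr.tolist(), va.tolist(), te.tolist()

    return DatasetSplit(train=list(map(int, train)), validation=list(map(int, val)),
                        test=list(map(int, test)), fractions=tuple(fractions),
                        seed=seed)


_REQUIRED_MEMBERS = ("clean", "artifact", "residual", "subject_id",
                     "slice_index", "split/train", "split/validation",
                     "split/test")


def save_dataset(samples: Sequence[PairedSample], split: DatasetSplit,
                 path: str) -> None:
    """Write all pairs plus the split manifest into one HDF5 container."""
    clean = np.stack([s.clean for s in samples]).astype(STORAGE_DTYPE)
    artifact = np.stack([s.artifact for s in samples]).astype(STORAGE_DTYPE)
    residual = np.stack([s.residual for s in samples]).astype(STORAGE_DTYPE)
    with h5py.File(path, "w") as f:
        f.create_dataset("clean", data=clean)
        f.create_dataset("artifact", data=artifact)
        f.create_dataset("residual", data=residual)
        f.create_dataset("subject_id",
                         data=np.array([s.subject_id for s in samples], dtype="S32"))
        f.create_dataset("slice_index",
                         data=np.array([s.slice_index for s in samples], dtype=np.int64))
        f.create_dataset(
            "schedule_json",
            data=np.array([(s.schedule.to_json() if s.schedule else "").encode()
                           for s in samples]))
        g = f.create_group("split")
        g.create_dataset("train", data=np.array(split.train, dtype=np.int64))
        g.create_dataset("validation", data=np.array(split.validation, dtype=np.int64))
        g.create_dataset("test", data=np.array(split.test, dtype=np.int64))
        g.attrs["fractions"] = list(split.fractions)
        g.attrs["seed"] = split.seed


def load_dataset(path: str) -> tuple[list[PairedSample], DatasetSplit]:
    """Load a container written by :func:`save_dataset`; bit-exact round trip."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise DatasetError(f"cannot open dataset container {path}: {exc}") from exc
    with f:
        for member in _REQUIRED_MEMBERS:
            if member not in f:
                raise DatasetError(f"dataset container {path} is missing member {member!r}")
        clean = f["clean"][...]
        artifact = f["artifact"][...]
        residual = f["residual"][...]
        subj = [s.decode() for s in f["subject_id"][...]]
        slc = f["slice_index"][...]
        sched = [s.decode() for s in f["schedule_json"][...]] \
            if "schedule_json" in f else [""] * len(subj)
        samples = [
            PairedSample(
                clean=clean[i], artifact=artifact[i], residual=residual[i],
                subject_id=subj[i], slice_index=int(slc[i]),
                schedule=MotionSchedule.from_json(sched[i]) if sched[i] else None,
            )
            for i in range(len(subj))
        ]
        g = f["split"]
        split = DatasetSplit(
            train=g["train"][...].tolist(),
            validation=g["validation"][...].tolist(),
            test=g["test"][...].tolist(),
            fractions=tuple(g.attrs["fractions"]),
            seed=int(g.attrs["seed"]),
        )
    return samples, split
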