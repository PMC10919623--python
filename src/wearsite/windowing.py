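"""Segmentation of recordings into labeled 1-second windows and splits.

Windows are 100 consecutive samples (1 s at 100 Hz), never cross a bout
boundary, and inherit the bout's intensity label and the recording's
wear-site.  The first and final minute of each bout are trimmed so windows
come from the metabolically steady portion.  The default split scheme
partitions windows at random (90/10, the study's scheme — note that it
places windows from the same participant, even the same bout, on both
sides); a leakage-safe by-participant scheme is offered and recommended for
generalization claims.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .groundtruth import BoutResult
from .synthdata import ParticipantProfile, TriaxialRecording

COVARIATE_NAMES = ("age", "height", "weight")


@dataclass
class LabeledWindowSet:
    """Fixed-length windows with per-window labels, as parallel arrays."""

    windows: np.ndarray            # (n, window_len, 3) float32, units of g
    site: np.ndarray               # (n,) str
    intensity: np.ndarray          # (n,) str
    participant_id: np.ndarray     # (n,) str
    group: np.ndarray              # (n,) str
    covariates: np.ndarray | None = None   # (n, 3): age, height, weight
    covariate_stats: dict | None = None    # standardization means/sds

    def __post_init__(self) -> None:
        n = self.windows.shape[0]
        for name in ("site", "intensity", "participant_id", "group"):
            arr = getattr(self, name)
            if arr.shape[0] != n:
                raise ValueError(f"{name} length {arr.shape[0]} != {n} windows")
        if self.covariates is not None and self.covariates.shape != (n, 3):
            raise ValueError("covariates must be (n, 3)")

    def __len__(self) -> int:
        return self.windows.shape[0]

    def subset(self, idx: np.ndarray) -> "LabeledWindowSet":
        return LabeledWindowSet(
            windows=self.windows[idx], site=self.site[idx],
            intensity=self.intensity[idx],
            participant_id=self.participant_id[idx], group=self.group[idx],
            covariates=None if self.covariates is None else self.covariates[idx],
            covariate_stats=self.covariate_stats)

    @staticmethod
    def concatenate(sets: list["LabeledWindowSet"]) -> "LabeledWindowSet":
        sets = [s for s in sets if len(s) > 0]
        if not sets:
            raise ValueError("nothing to concatenate")
        cov = None
        if all(s.covariates is not None for s in sets):
            cov = np.concatenate([s.covariates for s in sets])
        return LabeledWindowSet(
            windows=np.concatenate([s.windows for s in sets]),
            site=np.concatenate([s.site for s in sets]),
            intensity=np.concatenate([s.intensity for s in sets]),
            participant_id=np.concatenate([s.participant_id for s in sets]),
            group=np.concatenate([s.group for s in sets]),
            covariates=cov)


def expected_window_count(bout_duration_s: float, sample_rate: float = 100.0,
                          window_len: int = 100, stride: int = 100,
                          trim_s: float = 60.0) -> int:
    """floor((trimmed_samples - window_len)/stride) + 1, or 0 if over-trimmed."""
    trimmed = int(round((bout_duration_s - 2 * trim_s) * sample_rate))
    if trimmed < window_len:
        return 0
    return (trimmed - window_len) // stride + 1


def segment(recording: TriaxialRecording, bouts: list[BoutResult],
            participant: ParticipantProfile, window_len: int = 100,
            stride: int = 100, trim_s: float = 60.0) -> LabeledWindowSet:
    """Tile each non-excluded, trimmed bout with labeled windows.

    Excluded bouts and bouts shorter than one window after trimming
    contribute nothing.  No window crosses a bout boundary.
    """
    fs = recording.sample_rate
    results_by_index = {b.bout_index: b for b in bouts}
    wins, intensity = [], []
    for bout_index, start_s, end_s in recording.bout_annotations:
        res = results_by_index.get(bout_index)
        if res is None or res.excluded:
            continue
        i0 = int(round((start_s + trim_s) * fs))
        i1 = int(round((end_s - trim_s) * fs))
        if i1 - i0 < window_len:
            continue
        n_w = (i1 - i0 - window_len) // stride + 1
        for k in range(n_w):
            a = i0 + k * stride
            wins.append(recording.xyz[a:a + window_len])
            intensity.append(res.intensity)
    n = len(wins)
    windows = (np.stack(wins).astype(np.float32) if n
               else np.empty((0, window_len, 3), dtype=np.float32))
    return LabeledWindowSet(
        windows=windows,
        site=np.full(n, recording.site, dtype=object),
        intensity=np.asarray(intensity, dtype=object),
        participant_id=np.full(n, participant.id, dtype=object),
        group=np.full(n, participant.group, dtype=object))


def split(window_set: LabeledWindowSet, train_fraction: float = 0.9,
          seed: int = 0, scheme: str = "window_random"
          ) -> tuple[LabeledWindowSet, LabeledWindowSet]:
    """Partition into train/validation sets.

    ``window_random`` partitions individual windows uniformly at random;
    ``by_participant`` assigns whole participants to one side (no id appears
    on both sides), targeting the requested window fraction greedily.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(window_set)
    rng = np.random.default_rng(seed)
    if scheme == "window_random":
        perm = rng.permutation(n)
        n_train = int(round(n * train_fraction))
        train_idx, val_idx = perm[:n_train], perm[n_train:]
    elif scheme == "by_participant":
        pids = np.asarray(window_set.participant_id)
        unique = rng.permutation(np.unique(pids))
        target = n * train_fraction
        train_ids, total = [], 0
        for pid in unique:
            # keep at least one participant on the validation side
            if total >= target or len(train_ids) == len(unique) - 1:
                break
            train_ids.append(pid)
            total += int((pids == pid).sum())
        mask = np.isin(pids, train_ids)
        train_idx, val_idx = np.where(mask)[0], np.where(~mask)[0]
    else:
        raise ValueError(f"unknown split scheme {scheme!r}")
    if train_idx.size == 0 or val_idx.size == 0:
        raise ValueError("split produced an empty side")
    return window_set.subset(train_idx), window_set.subset(val_idx)


def attach_covariates(window_set: LabeledWindowSet,
                      profiles: list[ParticipantProfile],
                      standardize: bool = False,
                      stats: dict | None = None) -> LabeledWindowSet:
    """Join per-participant age/height/weight onto every window.

    With ``standardize``, covariates are z-scored.  Pass the training set
    first (stats=None: its own statistics are computed and stored on the
    result as ``covariate_stats``); then pass those stats when attaching to
    the validation set, so validation never standardizes with its own
    statistics.
    """
    by_id = {p.id: p for p in profiles}
    missing = set(np.unique(window_set.participant_id)) - set(by_id)
    if missing:
        raise ValueError(f"no profile for participant(s): {sorted(missing)}")
    cov = np.array([[by_id[pid].age, by_id[pid].height, by_id[pid].weight]
                    for pid in window_set.participant_id], dtype=np.float64)
    used_stats = None
    if standardize:
        if stats is None:
            mean = cov.mean(axis=0)
            sd = cov.std(axis=0)
            sd[sd == 0] = 1.0
            used_stats = {"mean": mean, "sd": sd}
        else:
            used_stats = stats
        cov = (cov - used_stats["mean"]) / used_stats["sd"]
    out = LabeledWindowSet(
        windows=window_set.windows, site=window_set.site,
        intensity=window_set.intensity,
        participant_id=window_set.participant_id, group=window_set.group,
        covariates=cov.astype(np.float32), covariate_stats=used_stats)
    return out
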