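"""Gamma-plane trajectories, speed profiles, and per-person signatures.

The acquisition-ordered (a, b) estimates form a stochastic trajectory on
the Gamma plane.  Its "speed" is the Euclidean shift between consecutive
points, with entry index as the clock (one unit step per estimated entry).
Shifts below the stochastic-motion cutoff (default 0.002) are treated as
rest and excluded; shifts above 1 — the Exponential range of the plane —
are the relevant peaks.  The per-person distribution of those peaks is
itself Gamma-fitted; its scale equals the Fano factor (variance-to-mean
ratio) and is the dispersion index the cohort stage compares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .signatures import GammaEstimate, fit_gamma_mle

__all__ = [
    "StochasticTrajectory",
    "SpeedProfile",
    "PersonSignature",
    "build_trajectory",
    "shift_magnitudes",
    "extract_peaks",
    "person_signature",
    "fano_factor",
    "DEFAULT_SPEED_CUTOFF",
    "DEFAULT_PEAK_THRESHOLD",
    "MIN_PEAKS",
]

DEFAULT_SPEED_CUTOFF = 0.002
DEFAULT_PEAK_THRESHOLD = 1.0
MIN_PEAKS = 10


class InsufficientTrajectoryError(ValueError):
    """Fewer than two Gamma-plane points: no shift can be computed."""


class InsufficientPeaksError(ValueError):
    """Too few speed peaks for a per-person distribution fit."""


@dataclass
class StochasticTrajectory:
    """Time-ordered (a, b) points for one person, days concatenated."""

    participant_id: str
    points: np.ndarray  # (n, 2) columns (a, b)
    entry_indices: np.ndarray
    day_tags: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.entry_indices = np.asarray(self.entry_indices, dtype=int)
        self.day_tags = np.asarray(self.day_tags, dtype=int)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if self.points.shape[0] < 2:
            raise InsufficientTrajectoryError(
                "a trajectory needs >= 2 Gamma-plane points"
            )
        if len(self.entry_indices) != len(self.points) or len(self.day_tags) != len(
            self.points
        ):
            raise ValueError("per-point tags must match the number of points")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class SpeedProfile:
    """Consecutive-point shift magnitudes with sub-cutoff rest flags."""

    shifts: np.ndarray
    sub_cutoff_mask: np.ndarray
    cutoff: float

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.sub_cutoff_mask = np.asarray(self.sub_cutoff_mask, dtype=bool)
        if self.shifts.shape != self.sub_cutoff_mask.shape:
            raise ValueError("mask must match shifts")
        if np.any(self.shifts < 0):
            raise ValueError("shifts are magnitudes, must be >= 0")

    @property
    def moving_shifts(self) -> np.ndarray:
        """Shifts at or above the stochastic-motion cutoff."""
        return self.shifts[~self.sub_cutoff_mask]


@dataclass(frozen=True)
class PersonSignature:
    """One person's Gamma fit of speed peaks plus summary shift statistics."""

    participant_id: str
    peak_fit: GammaEstimate
    max_shift: float
    median_shift: float
    n_peaks: int
    n_entries: int = 0
    n_discarded: int = 0

    @property
    def fano(self) -> float:
        return fano_factor(self.peak_fit)


def build_trajectory(
    signatures: list[GammaEstimate],
    participant_id: str = "",
    day_tags=None,
    entry_indices=None,
) -> StochasticTrajectory:
    """Assemble acquisition-ordered estimates into one trajectory.

    Day boundaries are tagged but do not break the path: trajectories from
    consecutive days are pieced together into one longitudinal curve.
    """
    if len(signatures) < 2:
        raise InsufficientTrajectoryError(
            f"got {len(signatures)} point(s); need >= 2"
        )
    pts = np.array([[s.a, s.b] for s in signatures], dtype=float)
    if day_tags is None:
        day_tags = np.ones(len(pts), dtype=int)
    if entry_indices is None:
        entry_indices = np.arange(1, len(pts) + 1)
    return StochasticTrajectory(
        participant_id=participant_id,
        points=pts,
        entry_indices=entry_indices,
        day_tags=day_tags,
    )


def shift_magnitudes(
    traj: StochasticTrajectory, cutoff: float = DEFAULT_SPEED_CUTOFF
) -> SpeedProfile:
    """Euclidean shift between consecutive (a, b) points, one per unit step.

    Shifts below ``cutoff`` are flagged as stochastic rest and excluded
    from peak and median statistics downstream.
    """
    deltas = np.diff(traj.points, axis=0)
    shifts = np.sqrt((deltas**2).sum(axis=1))
    return SpeedProfile(
        shifts=shifts, sub_cutoff_mask=shifts < cutoff, cutoff=cutoff
    )


def extract_peaks(
    profile: SpeedProfile, threshold: float = DEFAULT_PEAK_THRESHOLD
) -> np.ndarray:
    """All unflagged shifts strictly above ``threshold``, order preserved."""
    peaks = profile.shifts[(~profile.sub_cutoff_mask) & (profile.shifts > threshold)]
    if peaks.size == 0:
        warnings.warn(
            "no speed peaks above threshold; participant needs more data",
            stacklevel=2,
        )
    return peaks


def person_signature(
    participant_id: str,
    peaks,
    profile: SpeedProfile,
    n_entries: int = 0,
    n_discarded: int = 0,
    min_peaks: int = MIN_PEAKS,
) -> PersonSignature:
    """Gamma-fit the peak distribution and summarize the shift profile."""
    peaks = np.asarray(peaks, dtype=float)
    floor = max(min_peaks, MIN_PEAKS)  # the Gamma fit itself needs >= 10
    if peaks.size < floor:
        raise InsufficientPeaksError(
            f"{participant_id}: {peaks.size} peaks < {floor}; excluded"
        )
    moving = profile.moving_shifts
    return PersonSignature(
        participant_id=participant_id,
        peak_fit=fit_gamma_mle(peaks),
        max_shift=float(moving.max()),
        median_shift=float(np.median(moving)),
        n_peaks=int(peaks.size),
        n_entries=n_entries,
        n_discarded=n_discarded,
    )


def fano_factor(est: GammaEstimate) -> float:
    """Variance-to-mean ratio of a Gamma(a, b): (a b^2)/(a b) = b."""
    return est.variance / est.mean
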