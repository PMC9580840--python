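"""Sliding-window hydropathy profiles and the window-width sweep.

A hydropathy profile replaces each residue by its scale value and smooths
with a centered moving average of odd width W, producing the "water wave"
curve whose interior maxima are hydrophobic peaks.  W = 9 means +/-4
residues about the center (the L = 2N + 1 convention); edges are
truncated rather than padded, so no values are emitted for centers whose
window would overrun the analyzed region — padding would fabricate
extrema.

All reported positions are 1-based indices into the full original
sequence, even when analysis is restricted to a sub-region (e.g. a
kinesin motor domain), so peak positions line up across species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .scales import HydropathyScale

__all__ = [
    "SequenceRecord",
    "HydropathyProfile",
    "SweepResult",
    "compute_profile",
    "window_sweep",
    "DEFAULT_WINDOWS",
]

logger = logging.getLogger("hydrolevel")

#: Default window sweep: odd widths 7 through 21.
DEFAULT_WINDOWS: tuple[int, ...] = tuple(range(7, 22, 2))


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with optional species/protein labels and region.

    ``region`` is a 1-based inclusive interval restricting analysis, e.g.
    a ~350-residue motor domain inside a full-length kinesin.
    """

    id: str
    residues: str
    species: str = ""
    protein: str = ""
    region: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.region is not None:
            start, end = self.region
            if not (1 <= start <= end <= len(self.residues)):
                raise ValueError(
                    f"record {self.id!r}: region {self.region} outside "
                    f"[1, {len(self.residues)}]"
                )

    @property
    def analyzed(self) -> tuple[int, str]:
        """(1-based start, residue substring) of the analyzed region."""
        if self.region is None:
            return 1, self.residues
        start, end = self.region
        return start, self.residues[start - 1:end]

    def label(self) -> str:
        parts = [p for p in (self.species, self.protein) if p]
        return " ".join(parts) if parts else self.id


@dataclass(frozen=True)
class HydropathyProfile:
    """Windowed hydropathy values over a sequence region.

    ``positions[i]`` is the 1-based center of the i-th window in the
    original sequence; ``values[i]`` the arithmetic mean of the scale
    values over the W residues around it.  Length is
    ``region_length - window + 1``.
    """

    sequence_id: str
    scale_name: str
    window: int
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values differ in length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def start_position(self) -> int:
        """1-based center of the first window."""
        return int(self.positions[0])

    def value_at(self, position: int) -> float:
        idx = int(position) - self.start_position
        if not 0 <= idx < len(self.values):
            raise IndexError(f"position {position} outside profile")
        return float(self.values[idx])


def _check_window(window: int, region_len: int) -> None:
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if window > region_len:
        raise ValueError(
            f"window {window} exceeds analyzed region length {region_len}"
        )


def compute_profile(record: SequenceRecord, scale: HydropathyScale,
                    window: int, unknown: str = "error") -> HydropathyProfile:
    """Centered moving-average hydropathy profile of ``record``.

    The value at center i is the mean of scale values over positions
    i-(W-1)/2 ... i+(W-1)/2 of the analyzed region; edge centers whose
    window would overrun the region are omitted.

    ``unknown`` is the nonstandard-residue policy passed to the scale
    (``"error"`` or ``"mean"``).
    """
    start, residues = record.analyzed
    _check_window(window, len(residues))
    raw = scale.encode(residues, unknown=unknown)
    # window sums first, one division after: for integer-valued scales the
    # sums are exact in float64, so equal windows give bit-identical means
    values = np.convolve(raw, np.ones(window), mode="valid") / window
    half = (window - 1) // 2
    positions = np.arange(start + half, start + half + len(values))
    logger.debug(
        "profile id=%s scale=%s W=%d region_start=%d n=%d",
        record.id, scale.name, window, start, len(values),
    )
    return HydropathyProfile(
        sequence_id=record.id, scale_name=scale.name, window=window,
        positions=positions, values=values,
    )


@dataclass(frozen=True)
class SweepResult:
    """Outcome of a window sweep.

    ``per_window`` maps each window to ``(profile, LevelStat | None)``;
    the statistic is None when the profile has too few peaks to score.
    ``best_window`` is the statistic minimizer (ties toward the smaller
    window) or None when no window could be scored — e.g. a constant
    sequence has no peaks at any width, which is reported rather than
    silently assigned a W*.
    """

    per_window: Mapping[int, tuple[HydropathyProfile, Optional["LevelStat"]]]
    best_window: Optional[int]

    @property
    def best_stat(self):
        if self.best_window is None:
            return None
        return self.per_window[self.best_window][1]


def window_sweep(record: SequenceRecord, scale: HydropathyScale,
                 windows: Sequence[int] = DEFAULT_WINDOWS, k: int = 5,
                 definition: str = "mad", min_separation: int = 10,
                 polarity: str = "peaks",
                 unknown: str = "error") -> SweepResult:
    """Profile ``record`` at each window width and score the k-peak level
    statistic, locating the family-optimal width W*.

    W* is defined operationally as the window minimizing the deviation
    statistic (smallest deviation = most level peak set), ties broken
    toward the smaller window.  Windows with fewer than 2 detected peaks
    carry no statistic and cannot win.
    """
    from .levelsets import find_extrema, level_deviation, top_k_peaks

    windows = list(windows)
    if not windows:
        raise ValueError("empty window list")
    for w in windows:
        _check_window(w, len(record.analyzed[1]))

    per_window: dict[int, tuple[HydropathyProfile, Optional[object]]] = {}
    best: Optional[int] = None
    for w in sorted(windows):
        profile = compute_profile(record, scale, w, unknown=unknown)
        stat = None
        try:
            extrema = find_extrema(profile, min_separation=min_separation)
            peaks = top_k_peaks(extrema, k=k, polarity=polarity)
            if len(peaks.peaks) >= 2:
                stat = level_deviation(peaks, definition=definition)
        except ValueError:
            stat = None
        per_window[w] = (profile, stat)
        if stat is not None:
            if best is None:
                best = w
            else:
                best_dev = per_window[best][1].deviation
                # strictly better beyond numerical noise; ties keep the
                # smaller window (windows are visited in ascending order)
                tol = 1e-9 * max(1.0, abs(best_dev))
                if stat.deviation < best_dev - tol:
                    best = w
    logger.info(
        "sweep id=%s scale=%s windows=%s k=%d definition=%s min_sep=%d -> W*=%s",
        record.id, scale.name, sorted(windows), k, definition,
        min_separation, best,
    )
    return SweepResult(per_window=per_window, best_window=best)
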