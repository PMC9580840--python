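"""Extrema detection and level-set synchronization statistics.

Evolution can "level" the highest hydrophobic peaks of a hydropathy
profile so they sit at nearly equal heights — a level set, interpreted as
synchronized domain dynamics.  The machinery here operationalizes that
idea: detect interior extrema of a profile, keep the k highest
hydrophobic peaks, and score how level they are by their deviation from
the mean (mean absolute deviation by default, sample SD as an
alternative).  Small deviations mean a well-synchronized level set;
`compare_species` ranks orthologs by that score, smallest first.

Hydrophilic minima are handled by the same machinery with the polarity
flag set to ``"valleys"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .profiling import HydropathyProfile, SequenceRecord, compute_profile
from .scales import HydropathyScale

__all__ = [
    "Extremum",
    "PeakSet",
    "LevelStat",
    "LevelMembers",
    "ComparisonRow",
    "SpeciesComparison",
    "find_extrema",
    "top_k_peaks",
    "level_deviation",
    "level_members",
    "compare_species",
    "match_peaks",
    "score_record",
]

logger = logging.getLogger("hydrolevel")


@dataclass(frozen=True)
class Extremum:
    """An interior local extremum of a profile (1-based center position)."""

    position: int
    value: float
    kind: str  # "peak" | "valley"


@dataclass(frozen=True)
class PeakSet:
    """The selected k most extreme peaks (or valleys) of a profile.

    ``peaks`` is ordered most-extreme first (descending value for peaks,
    ascending for valleys).  ``short`` flags that fewer than the requested
    k extrema existed.
    """

    peaks: Tuple[Extremum, ...]
    k: int
    polarity: str = "peaks"
    min_separation: Optional[int] = None
    short: bool = False

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def values(self) -> np.ndarray:
        return np.array([p.value for p in self.peaks])

    @property
    def positions(self) -> Tuple[int, ...]:
        return tuple(p.position for p in self.peaks)


@dataclass(frozen=True)
class LevelStat:
    """Deviation-from-mean synchronization score of a peak set.

    ``deviation`` is zero iff all peak values are equal (a perfect level
    set) and grows as the peaks spread apart; it is in the units of the
    hydropathy scale used.
    """

    mean_level: float
    deviation: float
    definition: str  # "mad" | "sd"
    n_peaks: int


def _runs(values: np.ndarray) -> Iterable[tuple[int, int]]:
    """Maximal runs [s, e] (inclusive indices) of equal consecutive values."""
    n = len(values)
    s = 0
    for i in range(1, n + 1):
        if i == n or values[i] != values[s]:
            yield s, i - 1
            s = i


def _enforce_separation(cands: List[Extremum], min_separation: int,
                        prefer_high: bool) -> List[Extremum]:
    """Among extrema closer than ``min_separation``, keep only the more
    extreme one, iteratively most-extreme first (ties to smaller position)."""
    key = (lambda e: (-e.value, e.position)) if prefer_high else \
          (lambda e: (e.value, e.position))
    kept: List[Extremum] = []
    for cand in sorted(cands, key=key):
        if all(abs(cand.position - k.position) >= min_separation for k in kept):
            kept.append(cand)
    kept.sort(key=lambda e: e.position)
    return kept


def find_extrema(profile: HydropathyProfile,
                 min_separation: int = 10) -> List[Extremum]:
    """Interior local maxima and minima of a profile, position-ordered.

    An interior extremum is strictly greater (peak) or less (valley) than
    its nearest unequal neighbors; a flat plateau is reduced to its center
    point (ties toward the smaller index).  Extrema of the same kind
    closer than ``min_separation`` residues are thinned, keeping the more
    extreme one.
    """
    if len(profile) < 3:
        raise ValueError(
            f"profile has {len(profile)} values; need at least 3 to "
            "define interior extrema"
        )
    v = profile.values
    n = len(v)
    peaks: List[Extremum] = []
    valleys: List[Extremum] = []
    for s, e in _runs(v):
        if s == 0 or e == n - 1:
            continue  # touches an edge: not interior
        center = int(profile.positions[(s + e) // 2])
        left, right = v[s - 1], v[e + 1]
        if left < v[s] and right < v[s]:
            peaks.append(Extremum(center, float(v[s]), "peak"))
        elif left > v[s] and right > v[s]:
            valleys.append(Extremum(center, float(v[s]), "valley"))
    out = _enforce_separation(peaks, min_separation, prefer_high=True)
    out += _enforce_separation(valleys, min_separation, prefer_high=False)
    out.sort(key=lambda x: x.position)
    return out


def top_k_peaks(extrema: Sequence[Extremum], k: int = 5,
                polarity: str = "peaks",
                min_separation: Optional[int] = None) -> PeakSet:
    """The k highest hydrophobic peaks (or, with ``polarity="valleys"``,
    the k lowest hydrophilic minima).

    Ties at the cutoff are broken toward the smaller position.  If fewer
    than k qualifying extrema exist, all are returned with the ``short``
    flag raised; none at all is an error (an empty level set is reported,
    not silently scored).
    """
    if k < 2:
        raise ValueError(f"k must be at least 2, got {k}")
    if polarity not in ("peaks", "valleys"):
        raise ValueError(f"polarity must be 'peaks' or 'valleys', got {polarity!r}")
    kind = "peak" if polarity == "peaks" else "valley"
    pool = [e for e in extrema if e.kind == kind]
    if not pool:
        raise ValueError(f"no {polarity} found: practically an empty level set")
    sign = -1.0 if polarity == "peaks" else 1.0
    pool.sort(key=lambda e: (sign * e.value, e.position))
    chosen = tuple(pool[:k])
    return PeakSet(peaks=chosen, k=k, polarity=polarity,
                   min_separation=min_separation, short=len(chosen) < k)


def level_deviation(peaks: PeakSet, definition: str = "mad") -> LevelStat:
    """Deviation of the peak heights from their mean.

    ``"mad"`` (default) is the mean absolute deviation about the mean;
    ``"sd"`` the sample standard deviation (ddof=1).  Both are zero
    exactly when the peaks form a perfect level set.
    """
    if len(peaks) < 2:
        raise ValueError(f"need at least 2 peaks to score, got {len(peaks)}")
    values = peaks.values
    mean = float(values.mean())
    if definition == "mad":
        dev = float(np.abs(values - mean).mean())
    elif definition == "sd":
        dev = float(values.std(ddof=1))
    else:
        raise ValueError(f"definition must be 'mad' or 'sd', got {definition!r}")
    return LevelStat(mean_level=mean, deviation=dev, definition=definition,
                     n_peaks=len(peaks))


@dataclass(frozen=True)
class LevelMembers:
    """Largest subset of peaks lying in a band of half-width epsilon."""

    count: int
    members: Tuple[Extremum, ...]
    epsilon: float


def level_members(peaks: PeakSet, epsilon: Optional[float] = None) -> LevelMembers:
    """Largest subset of peaks whose values all lie within ``epsilon`` of
    the subset's own mean (a band of total width 2*epsilon).

    Found exactly by scanning contiguous windows of the value-sorted
    peaks.  ``epsilon`` defaults to the peak set's mean absolute
    deviation (self-scaling); when that is zero all peaks are already
    level and every one is a member.
    """
    if len(peaks) < 1:
        raise ValueError("need at least 1 peak")
    if epsilon is None:
        values = peaks.values
        epsilon = float(np.abs(values - values.mean()).mean())
        if epsilon == 0.0:
            return LevelMembers(len(peaks), tuple(
                sorted(peaks.peaks, key=lambda e: e.position)), 0.0)
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")

    by_value = sorted(peaks.peaks, key=lambda e: (e.value, e.position))
    vals = [e.value for e in by_value]
    n = len(vals)
    slack = 1e-12 * max(1.0, max(abs(v) for v in vals))
    best: Optional[tuple[int, int]] = None  # (i, j) inclusive window
    for i in range(n):
        for j in range(i, n):
            window = vals[i:j + 1]
            mean = sum(window) / len(window)
            if (window[-1] - mean <= epsilon + slack
                    and mean - window[0] <= epsilon + slack):
                if best is None or (j - i) > (best[1] - best[0]):
                    best = (i, j)
    assert best is not None  # singletons always qualify
    members = tuple(sorted(by_value[best[0]:best[1] + 1],
                           key=lambda e: e.position))
    return LevelMembers(len(members), members, float(epsilon))


def score_record(record: SequenceRecord, scale: HydropathyScale,
                 window: int = 9, k: int = 5, definition: str = "mad",
                 min_separation: int = 10, polarity: str = "peaks",
                 unknown: str = "error",
                 ) -> tuple[Optional[PeakSet], Optional[LevelStat], str]:
    """Full pipeline for one record: profile, extrema, top-k, deviation.

    Returns ``(peak_set, stat, status)`` where status is ``"ok"``,
    ``"short set"`` (scored, but fewer than k peaks) or a failure note
    with no score.
    """
    profile = compute_profile(record, scale, window, unknown=unknown)
    try:
        extrema = find_extrema(profile, min_separation=min_separation)
        peaks = top_k_peaks(extrema, k=k, polarity=polarity,
                            min_separation=min_separation)
    except ValueError as exc:
        return None, None, str(exc)
    if len(peaks) < 2:
        return peaks, None, f"only {len(peaks)} peak(s); too few to score"
    stat = level_deviation(peaks, definition=definition)
    status = "short set" if peaks.short else "ok"
    logger.info(
        "score id=%s scale=%s W=%d k=%d definition=%s min_sep=%d polarity=%s "
        "-> deviation=%.4f status=%s",
        record.id, scale.name, window, k, definition, min_separation,
        polarity, stat.deviation, status,
    )
    return peaks, stat, status


@dataclass(frozen=True)
class ComparisonRow:
    label: str
    sequence_id: str
    deviation: Optional[float]
    mean_level: Optional[float]
    n_peaks: int
    window: int
    scale_name: str
    definition: str
    status: str


@dataclass(frozen=True)
class SpeciesComparison:
    """Per-species level statistics, ranked most-level (smallest) first.

    ``ranking`` lists scored rows in ascending deviation order; rows that
    could not be scored (too few peaks) follow at the end with their
    status note.
    """

    rows: Tuple[ComparisonRow, ...]

    @property
    def ranking(self) -> Tuple[ComparisonRow, ...]:
        scored = [r for r in self.rows if r.deviation is not None]
        unscored = [r for r in self.rows if r.deviation is None]
        scored.sort(key=lambda r: (r.deviation, r.label))
        return tuple(scored + unscored)


def compare_species(records: Sequence[SequenceRecord],
                    scale: HydropathyScale, window: int = 9, k: int = 5,
                    definition: str = "mad", min_separation: int = 10,
                    polarity: str = "peaks",
                    unknown: str = "error") -> SpeciesComparison:
    """Run the level-set pipeline on each record with shared parameters.

    One row per record; the comparison's ``ranking`` orders species by
    ascending deviation (most level first).  Records whose profiles have
    too few peaks appear with a status note instead of a score.
    """
    if not records:
        raise ValueError("compare_species needs at least one record")
    rows = []
    for rec in records:
        peaks, stat, status = score_record(
            rec, scale, window=window, k=k, definition=definition,
            min_separation=min_separation, polarity=polarity, unknown=unknown,
        )
        rows.append(ComparisonRow(
            label=rec.label(), sequence_id=rec.id,
            deviation=None if stat is None else stat.deviation,
            mean_level=None if stat is None else stat.mean_level,
            n_peaks=0 if peaks is None else len(peaks),
            window=window, scale_name=scale.name, definition=definition,
            status=status,
        ))
    return SpeciesComparison(rows=tuple(rows))


def match_peaks(a: HydropathyProfile, b: HydropathyProfile,
                max_shift: int = 10, min_separation: int = 10,
                ) -> List[Tuple[Extremum, Optional[Extremum]]]:
    """Greedily pair the peaks of profile ``a`` with the nearest peaks of
    profile ``b`` within ``max_shift`` residues.

    Supports numbered-peak comparisons across species: closest pairs are
    matched first; each peak is used at most once; a's unmatched peaks
    are paired with None.  Both profiles must share window and scale.
    """
    if a.window != b.window or a.scale_name != b.scale_name:
        raise ValueError(
            f"profiles differ in window/scale: "
            f"({a.window}, {a.scale_name!r}) vs ({b.window}, {b.scale_name!r})"
        )
    peaks_a = [e for e in find_extrema(a, min_separation) if e.kind == "peak"]
    peaks_b = [e for e in find_extrema(b, min_separation) if e.kind == "peak"]
    candidates = sorted(
        ((abs(pa.position - pb.position), ia, ib)
         for ia, pa in enumerate(peaks_a)
         for ib, pb in enumerate(peaks_b)
         if abs(pa.position - pb.position) <= max_shift),
        key=lambda t: (t[0], peaks_a[t[1]].position, peaks_b[t[2]].position),
    )
    matched_a: dict[int, int] = {}
    used_b: set[int] = set()
    for _, ia, ib in candidates:
        if ia not in matched_a and ib not in used_b:
            matched_a[ia] = ib
            used_b.add(ib)
    return [
        (pa, peaks_b[matched_a[ia]] if ia in matched_a else None)
        for ia, pa in enumerate(peaks_a)
    ]
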