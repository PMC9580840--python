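"""Synthetic sequences with planted hydrophobic peaks of known heights.

The generator emulates the situation the level-set statistic is designed
to detect: a windowed hydropathy profile with k well-separated
hydrophobic peaks whose heights share a common level (up to a
controllable spread sigma) above a stochastic hydrophilic background.
Because the true peak centers and achieved heights are returned
alongside the sequence, every pipeline stage can be tested end to end
without downloading real orthologs.

Construction.  The scale's residues are split at the midpoint between
``background_level`` and ``target_level``: motif residues come from the
target side, background residues from a small pool nearest the
background level on the other side.  This guarantees every motif residue
outvalues every background residue, so each planted motif produces a
clean local maximum and spurious background peaks stay below the planted
ones.  Within a motif, residues are chosen greedily so that every
running partial sum tracks ``j * h`` — hence any window contained in the
motif has mean close to the drawn height ``h ~ Normal(target_level,
sigma^2)``.

Scale values are discrete, so requested heights are quantized; the truth
object records the *achieved* height of each motif (its mean scale
value, i.e. the profile value at the motif center for a window equal to
``motif_width``), which makes the truth usable as an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .profiling import SequenceRecord
from .scales import HydropathyScale, load_scale

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-peak sequence generator.

    Defaults emulate a ~360-residue kinesin-motor-sized region with five
    planted hydrophobic peaks, analysis window 9, on the MZ scale (whose
    milli-exponent values run from 69 to 246): peaks target level 220
    over a hydrophilic background near 120.  ``motif_width`` must be at
    least the window width intended for analysis, so the analyzing window
    fits inside each motif.
    """

    length: int = 360
    k: int = 5
    motif_width: int = 9
    target_level: float = 220.0
    level_spread: float = 0.0     # sigma of peak heights, scale units
    background_level: float = 120.0
    min_spacing: int = 40         # background gap between motifs, residues
    seed: int = 0
    scale_name: str = "MZ"
    background_pool_size: int = 6

    def __post_init__(self) -> None:
        if self.length < 1 or self.k < 0:
            raise ValueError("length must be >= 1 and k >= 0")
        if self.motif_width < 1 or self.motif_width % 2 == 0:
            raise ValueError(
                f"motif_width must be a positive odd integer, got {self.motif_width}"
            )
        if self.level_spread < 0:
            raise ValueError("level_spread (sigma) must be nonnegative")
        if self.min_spacing < 0:
            raise ValueError("min_spacing must be nonnegative")
        if self.k * (self.motif_width + self.min_spacing) > self.length:
            raise ValueError(
                f"infeasible packing: k*(motif_width+min_spacing) = "
                f"{self.k * (self.motif_width + self.min_spacing)} exceeds "
                f"length {self.length}"
            )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated sequence: where the peaks are and the
    heights actually achieved after residue quantization."""

    planted_centers: Tuple[int, ...]   # 1-based motif centers
    planted_heights: Tuple[float, ...]  # achieved motif-mean hydropathicity
    requested_heights: Tuple[float, ...]


def _split_pools(scale: HydropathyScale, spec: SyntheticSpec,
                 ) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """(motif_pool, background_pool) as (aa, value) lists.

    Motif residues sit on the target side of the background/target
    midpoint; the background pool is the ``background_pool_size`` residues
    nearest the background level on the other side, which keeps extreme
    residues out of the background so spurious peaks are rare.
    """
    if spec.target_level == spec.background_level:
        raise ValueError("target_level must differ from background_level")
    if not scale.vmin <= spec.target_level <= scale.vmax:
        raise ValueError(
            f"target_level {spec.target_level} outside the attainable range "
            f"of window means [{scale.vmin}, {scale.vmax}] on scale "
            f"{scale.name!r}"
        )
    mid = 0.5 * (spec.target_level + spec.background_level)
    hydrophobic = spec.target_level > spec.background_level
    items = sorted(scale.values.items())  # alphabetical: deterministic ties
    if hydrophobic:
        motif = [(aa, v) for aa, v in items if v >= mid]
        backgr = [(aa, v) for aa, v in items if v < mid]
    else:
        motif = [(aa, v) for aa, v in items if v <= mid]
        backgr = [(aa, v) for aa, v in items if v > mid]
    if not motif:
        raise ValueError(
            f"no residues on the target side of {mid:.3g} on scale "
            f"{scale.name!r}"
        )
    if not backgr:
        raise ValueError(
            f"no residues available for the background on scale {scale.name!r}"
        )
    lo = min(v for _, v in motif)
    hi = max(v for _, v in motif)
    if not lo <= spec.target_level <= hi:
        raise ValueError(
            f"target_level {spec.target_level} outside the attainable range "
            f"of window means [{lo}, {hi}] on scale {scale.name!r}"
        )
    backgr.sort(key=lambda p: (abs(p[1] - spec.background_level), p[0]))
    backgr = sorted(backgr[:spec.background_pool_size])
    return motif, backgr


def _greedy_motif(pool: list[tuple[str, float]], h: float,
                  width: int) -> tuple[str, float]:
    """Pick ``width`` residues so every partial sum tracks ``j*h``.

    Deterministic (ties broken alphabetically); returns the motif string
    and its achieved mean value.
    """
    seq: list[str] = []
    total = 0.0
    for j in range(1, width + 1):
        aa, v = min(pool, key=lambda p: (abs(total + p[1] - j * h), p[0]))
        seq.append(aa)
        total += v
    return "".join(seq), total / width


def generate(spec: SyntheticSpec) -> tuple[SequenceRecord, SyntheticTruth]:
    """Generate a sequence with ``spec.k`` planted hydrophobic peaks.

    Deterministic under a fixed seed.  Returns the sequence record and
    the ground truth (1-based planted centers, achieved heights).
    """
    scale = load_scale(spec.scale_name)
    motif_pool, backgr_pool = _split_pools(scale, spec)
    rng = np.random.default_rng(spec.seed)

    # background everywhere, motifs spliced in afterwards
    letters = [aa for aa, _ in backgr_pool]
    seq = list(rng.choice(letters, size=spec.length))

    centers: list[int] = []
    achieved: list[float] = []
    requested: list[float] = []
    if spec.k > 0:
        margin = spec.motif_width  # keeps windows up to motif_width interior
        stride = spec.motif_width + spec.min_spacing
        lo, hi = margin, spec.length - 1 - margin
        slack = (hi - lo) - (spec.k - 1) * stride
        if slack < 0:
            raise ValueError(
                f"infeasible packing: cannot place {spec.k} motifs of width "
                f"{spec.motif_width} with spacing {spec.min_spacing} and "
                f"edge margin {margin} in length {spec.length}"
            )
        offsets = np.sort(rng.integers(0, slack + 1, size=spec.k))
        half = spec.motif_width // 2
        for i in range(spec.k):
            center0 = lo + i * stride + int(offsets[i])  # 0-based
            h = float(rng.normal(spec.target_level, spec.level_spread))
            motif, got = _greedy_motif(motif_pool, h, spec.motif_width)
            seq[center0 - half:center0 + half + 1] = list(motif)
            centers.append(center0 + 1)
            achieved.append(got)
            requested.append(h)

    record = SequenceRecord(
        id=f"synthetic-k{spec.k}-s{spec.level_spread:g}-seed{spec.seed}",
        residues="".join(seq),
        species="synthetic",
        protein="planted",
    )
    truth = SyntheticTruth(
        planted_centers=tuple(centers),
        planted_heights=tuple(achieved),
        requested_heights=tuple(requested),
    )
    return record, truth
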