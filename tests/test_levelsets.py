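import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrolevel import (
    Extremum,
    PeakSet,
    SequenceRecord,
    compare_species,
    compute_profile,
    find_extrema,
    level_deviation,
    level_members,
    load_scale,
    match_peaks,
    rescale,
    score_record,
    top_k_peaks,
)
from hydrolevel.synthetic import SyntheticSpec, generate

from conftest import make_profile

MZ = load_scale("MZ")


# ---------------------------------------------------------------- oracles

def oracle_extrema(values, positions, min_separation):
    """Naive re-statement of the extremum rules, independent of the
    implementation: strict interior extrema with plateau centers, then
    iterative most-extreme-first thinning."""
    n = len(values)
    cands = {"peak": [], "valley": []}
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        if i > 0 and j < n - 1:
            center = positions[(i + j) // 2]
            if values[i - 1] < values[i] > values[j + 1]:
                cands["peak"].append((center, values[i]))
            if values[i - 1] > values[i] < values[j + 1]:
                cands["valley"].append((center, values[i]))
        i = j + 1
    out = []
    for kind, sign in (("peak", -1), ("valley", 1)):
        kept = []
        for pos, val in sorted(cands[kind], key=lambda c: (sign * c[1], c[0])):
            if all(abs(pos - kp) >= min_separation for kp, _ in kept):
                kept.append((pos, val))
        out += [(pos, val, kind) for pos, val in kept]
    return sorted(out)


def oracle_level_members(values, epsilon):
    """Exhaustive subset scan: largest subset within +/- epsilon of its mean."""
    best = 0
    idx = range(len(values))
    for r in range(1, len(values) + 1):
        for subset in itertools.combinations(idx, r):
            sub = [values[i] for i in subset]
            mean = sum(sub) / len(sub)
            if all(abs(v - mean) <= epsilon + 1e-12 for v in sub):
                best = max(best, r)
    return best


# ------------------------------------------------------------ find_extrema

def test_toy_profile_extrema():
    prof = make_profile([1, 3, 2, 4, 2, 5, 1])
    found = find_extrema(prof, min_separation=1)
    peaks = [(e.position, e.value) for e in found if e.kind == "peak"]
    valleys = [(e.position, e.value) for e in found if e.kind == "valley"]
    assert peaks == [(2, 3.0), (4, 4.0), (6, 5.0)]
    assert valleys == [(3, 2.0), (5, 2.0)]


def test_monotone_profile_has_no_extrema():
    assert find_extrema(make_profile([1, 2, 3, 4, 5]), 1) == []


def test_triangle_has_single_apex_peak():
    found = find_extrema(make_profile([0, 1, 2, 3, 2, 1, 0]), 1)
    assert [(e.position, e.kind) for e in found] == [(4, "peak")]


def test_plateau_reduces_to_center():
    found = find_extrema(make_profile([0, 2, 2, 2, 0]), 1)
    assert [(e.position, e.value, e.kind) for e in found] == [(3, 2.0, "peak")]
    # even-length plateau: center ties toward the smaller index
    found = make_profile([0, 2, 2, 0]), 1
    assert [(e.position,) for e in find_extrema(*found)] == [(2,)]


def test_min_separation_keeps_the_higher_peak():
    prof = make_profile([0, 5, 0, 4, 0, 9, 0, 3, 0])
    found = [e for e in find_extrema(prof, min_separation=3) if e.kind == "peak"]
    assert [(e.position, e.value) for e in found] == [(2, 5.0), (6, 9.0)]


def test_short_profile_rejected():
    with pytest.raises(ValueError, match="at least 3"):
        find_extrema(make_profile([1, 2]), 1)


@pytest.mark.parametrize("min_separation", [1, 3])
def test_extrema_agree_with_bruteforce_enumeration(min_separation):
    """Every profile of length <= 9 over a 3-letter value alphabet."""
    for n in range(3, 10):
        for values in itertools.product((0.0, 1.0, 2.0), repeat=n):
            prof = make_profile(values)
            got = sorted((e.position, e.value, e.kind)
                         for e in find_extrema(prof, min_separation))
            want = oracle_extrema(list(values), list(range(1, n + 1)),
                                  min_separation)
            assert got == want, f"values={values} min_sep={min_separation}"


# ------------------------------------------------------------- top_k_peaks

def _peaks(pairs):
    return [Extremum(pos, float(val), "peak") for pos, val in pairs]


def test_top_k_selects_largest_values():
    extrema = _peaks([(10, 5), (30, 9), (50, 2), (70, 7), (90, 8),
                      (110, 1), (130, 6)])
    ps = top_k_peaks(extrema, k=5)
    assert [p.value for p in ps.peaks] == [9, 8, 7, 6, 5]
    assert not ps.short


def test_top_k_short_set_flagged():
    ps = top_k_peaks(_peaks([(1, 3), (9, 2), (20, 1)]), k=5)
    assert len(ps) == 3 and ps.short


def test_tie_at_cutoff_prefers_smaller_position():
    extrema = _peaks([(10, 9), (20, 8), (30, 7), (40, 6),
                      (200, 5), (100, 5)])
    ps = top_k_peaks(extrema, k=5)
    assert ps.peaks[-1].position == 100


def test_no_peaks_is_an_error():
    valleys = [Extremum(5, 1.0, "valley")]
    with pytest.raises(ValueError, match="empty level set"):
        top_k_peaks(valleys, k=5)


def test_k_below_two_rejected():
    with pytest.raises(ValueError, match="k must be"):
        top_k_peaks(_peaks([(1, 1), (5, 2)]), k=1)


def test_valley_polarity_selects_lowest_minima():
    extrema = [Extremum(p, float(v), "valley")
               for p, v in [(10, 4), (30, 1), (50, 3), (70, 2), (90, 5)]]
    ps = top_k_peaks(extrema, k=3, polarity="valleys")
    assert [p.value for p in ps.peaks] == [1, 2, 3]


# --------------------------------------------------------- level_deviation

def test_equal_peaks_have_zero_deviation():
    ps = top_k_peaks(_peaks([(i * 20, 7.0) for i in range(1, 6)]), k=5)
    for definition in ("mad", "sd"):
        assert level_deviation(ps, definition).deviation == 0.0


def test_hand_computed_mad_and_sd():
    ps = top_k_peaks(_peaks([(10, 1), (30, 2), (50, 3), (70, 4), (90, 5)]), k=5)
    mad = level_deviation(ps, "mad")
    sd = level_deviation(ps, "sd")
    assert mad.mean_level == pytest.approx(3.0)
    assert mad.deviation == pytest.approx(1.2)
    assert sd.deviation == pytest.approx(1.5811, abs=1e-4)


def test_fewer_than_two_peaks_cannot_be_scored():
    ps = PeakSet(peaks=(Extremum(5, 1.0, "peak"),), k=5, short=True)
    with pytest.raises(ValueError, match="at least 2"):
        level_deviation(ps)


@settings(deadline=None, max_examples=100)
@given(st.lists(st.floats(-100, 100), min_size=2, max_size=8))
def test_mad_never_exceeds_sample_sd(values):
    ps = PeakSet(peaks=tuple(
        Extremum((i + 1) * 20, v, "peak") for i, v in enumerate(values)), k=8)
    assert level_deviation(ps, "mad").deviation <= \
        level_deviation(ps, "sd").deviation + 1e-9


# ----------------------------------------------------------- level_members

def test_all_equal_peaks_are_all_members():
    ps = top_k_peaks(_peaks([(i * 20, 4.0) for i in range(1, 6)]), k=5)
    assert level_members(ps, epsilon=0.01).count == 5
    assert level_members(ps).count == 5  # default epsilon, mad == 0


def test_three_of_five_within_band():
    ps = top_k_peaks(_peaks([(10, 10), (30, 10.1), (50, 9.9),
                             (70, 5), (90, 15)]), k=5)
    members = level_members(ps, epsilon=0.2)
    assert members.count == 3
    assert sorted(e.value for e in members.members) == [9.9, 10, 10.1]


def test_huge_epsilon_admits_everyone():
    ps = top_k_peaks(_peaks([(10, -50), (30, 0), (50, 80), (70, 3),
                             (90, 12)]), k=5)
    assert level_members(ps, epsilon=1e9).count == 5


def test_nonpositive_epsilon_rejected():
    ps = top_k_peaks(_peaks([(10, 1), (30, 2)]), k=2)
    with pytest.raises(ValueError, match="positive"):
        level_members(ps, epsilon=0.0)


@settings(deadline=None, max_examples=150)
@given(
    values=st.lists(st.integers(0, 20), min_size=1, max_size=8),
    epsilon=st.floats(0.25, 6.0),
)
def test_level_members_agree_with_subset_bruteforce(values, epsilon):
    peaks = tuple(Extremum((i + 1) * 30, float(v), "peak")
                  for i, v in enumerate(values))
    ps = PeakSet(peaks=peaks, k=len(peaks))
    got = level_members(ps, epsilon=epsilon).count
    assert got == oracle_level_members([float(v) for v in values], epsilon)


# ------------------------------------------------ pipeline-level properties

def test_affine_equivariance_of_the_pipeline():
    rec, _ = generate(SyntheticSpec(level_spread=1.5, seed=5))
    base_peaks, base_stat, _ = score_record(rec, MZ, window=9)
    mapped = rescale(MZ, 2.0, 1.0)
    new_peaks, new_stat, _ = score_record(rec, mapped, window=9)
    assert new_peaks.positions == base_peaks.positions
    assert new_stat.deviation == pytest.approx(2.0 * base_stat.deviation,
                                               rel=1e-9)
    assert new_stat.mean_level == pytest.approx(
        2.0 * base_stat.mean_level + 1.0, rel=1e-9)


# ---------------------------------------------------------- compare_species

def test_smaller_planted_spread_ranks_first():
    recs = []
    for sigma in (0.1, 1.0):
        rec, _ = generate(SyntheticSpec(level_spread=sigma, seed=21))
        recs.append(SequenceRecord(id=f"s{sigma}", residues=rec.residues,
                                   species=f"sigma={sigma}"))
    comparison = compare_species(recs, MZ, window=9)
    ranking = comparison.ranking
    assert ranking[0].label == "sigma=0.1"
    assert ranking[0].deviation < ranking[1].deviation


def test_single_record_ranks_first():
    rec, _ = generate(SyntheticSpec(seed=2))
    comparison = compare_species([rec], MZ)
    assert len(comparison.ranking) == 1
    assert comparison.ranking[0].status == "ok"


def test_empty_input_rejected():
    with pytest.raises(ValueError, match="at least one"):
        compare_species([], MZ)


def test_record_without_peaks_gets_status_note_not_score():
    flat = SequenceRecord(id="flat", residues="A" * 60, species="flatliner")
    rec, _ = generate(SyntheticSpec(seed=3))
    comparison = compare_species([rec, flat], MZ, window=9)
    ranking = comparison.ranking
    assert ranking[-1].label == "flatliner"
    assert ranking[-1].deviation is None
    assert "empty level set" in ranking[-1].status


# --------------------------------------------------------------- match_peaks

def test_profile_matches_itself_identically():
    rec, truth = generate(SyntheticSpec(seed=9))
    prof = compute_profile(rec, MZ, 9)
    pairs = match_peaks(prof, prof, max_shift=5)
    assert pairs and all(a.position == b.position for a, b in pairs)


def test_shifted_profile_matches_at_constant_offset():
    rec, _ = generate(SyntheticSpec(seed=13, level_spread=1.0))
    prof = compute_profile(rec, MZ, 9)
    shifted = make_profile(prof.values, start=prof.start_position + 3,
                           window=9)
    pairs = match_peaks(prof, shifted, max_shift=10)
    offsets = {b.position - a.position for a, b in pairs if b is not None}
    assert offsets == {3}
    assert all(b is not None for _, b in pairs)


def test_peaks_beyond_max_shift_stay_unmatched():
    a = make_profile([0, 5, 0, 0, 0, 0, 0, 0, 0, 0], window=3)
    b = make_profile([0, 0, 0, 0, 0, 0, 0, 0, 5, 0], window=3)
    pairs = match_peaks(a, b, max_shift=2, min_separation=1)
    assert all(pb is None for _, pb in pairs)


def test_mismatched_window_or_scale_rejected():
    rec, _ = generate(SyntheticSpec(seed=4))
    p9 = compute_profile(rec, MZ, 9)
    p7 = compute_profile(rec, MZ, 7)
    with pytest.raises(ValueError, match="window/scale"):
        match_peaks(p9, p7, max_shift=5)
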