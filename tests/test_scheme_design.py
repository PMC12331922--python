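import csv
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stagdia as sd
from stagdia.scheme_design import AVERAGINE_SPACING


@pytest.mark.parametrize(
    "mz_min,mz_max,width,expected",
    [
        (400, 1000, 24, 52),  # standard staggered method
        (400, 500, 4, 52),  # one gas-phase fraction segment
        (400, 412, 12, 4),  # smallest staggered scheme
    ],
)
def test_window_counts(mz_min, mz_max, width, expected):
    scheme = sd.build_staggered_scheme(mz_min, mz_max, width)
    assert len(scheme.windows) == expected


def test_smallest_scheme_demux_bins(tiny_scheme):
    assert tiny_scheme.demux_bins == [(400.0, 406.0), (406.0, 412.0)]


@pytest.mark.parametrize("args", [(400, 1000, 24), (400, 500, 4), (500, 700, 20)])
def test_bin_tiling_and_double_coverage(args):
    """Demux bins tile the range gap-free; every in-range bin is sampled by
    exactly two windows, one per bank."""
    scheme = sd.build_staggered_scheme(*args)
    bins = scheme.demux_bins
    assert bins[0][0] == scheme.mz_min
    assert math.isclose(bins[-1][1], scheme.mz_max)
    for (_, hi), (lo, _) in zip(bins, bins[1:]):
        assert math.isclose(hi, lo)
    for lo, hi in bins:
        covering = scheme.windows_covering((lo + hi) / 2)
        assert len(covering) == 2
        assert {w.bank for w in covering} == {0, 1}


def test_edge_windows(scheme52):
    """Exactly two windows cover a single in-range bin; the top edge window
    covers none; banks alternate window-by-window in acquisition order."""
    bmap = sd.build_bin_map(scheme52)
    n_covered = sorted(len(v) for v in bmap.values())
    assert n_covered.count(1) == 2
    assert n_covered.count(0) == 1
    assert n_covered.count(2) == len(scheme52.windows) - 3
    orders = [w.order for w in scheme52.windows]
    assert orders == sorted(orders)
    banks = [w.bank for w in scheme52.windows]
    assert banks == [k % 2 for k in range(len(banks))]
    lowers = [w.lower_mz for w in scheme52.windows]
    assert np.allclose(np.diff(lowers), scheme52.stagger)


@pytest.mark.parametrize(
    "args,err",
    [
        ((400, 1000, -2), "positive"),
        ((400, 410, 24), "degenerate"),
        ((400, 1000.5, 24), "divisible"),
        ((1000, 400, 24), "exceed"),
    ],
)
def test_build_errors(args, err):
    with pytest.raises(ValueError, match=err):
        sd.build_staggered_scheme(*args)


# -- forbidden-zone snapping ----------------------------------------------


def test_snap_fixed_point():
    pitch = AVERAGINE_SPACING / 2
    x = (997 + 0.25) * pitch
    assert sd.snap_to_forbidden_zone(x, 2) == pytest.approx(x, abs=1e-12)


def test_snap_matches_exhaustive_grid_search():
    boundary = 500.0
    pitch = AVERAGINE_SPACING / 2
    ks = range(int((boundary - 1) / pitch), int((boundary + 1) / pitch) + 1)
    grid = [(k + 0.25) * pitch for k in ks]
    best = min(grid, key=lambda g: abs(g - boundary))
    assert sd.snap_to_forbidden_zone(boundary, 2) == pytest.approx(best, abs=1e-9)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.floats(min_value=300.0, max_value=1500.0), st.sampled_from([2, 3]))
def test_snap_bound_and_idempotence(boundary, z):
    snapped = sd.snap_to_forbidden_zone(boundary, z)
    assert abs(snapped - boundary) <= AVERAGINE_SPACING / (2 * z) + 1e-9
    assert sd.snap_to_forbidden_zone(snapped, z) == pytest.approx(snapped, abs=1e-9)


def test_snapped_scheme_keeps_count_and_nominal_bins(scheme52):
    snapped = sd.build_staggered_scheme(400, 1000, 24, snap_boundaries=True)
    assert len(snapped.windows) == 52
    assert snapped.demux_bins == scheme52.demux_bins
    for w, v in zip(snapped.windows, scheme52.windows):
        assert abs(w.lower_mz - v.lower_mz) <= 0.2501


# -- gas-phase fractionation plan -----------------------------------------


def test_gpf_plan_segments():
    plan = sd.build_gpf_plan(400, 1000, 6, 2, 4)
    assert plan.n_segments == 6
    assert plan.segments[0][0] == (400.0, 502.0)
    for (lo, hi), scheme in plan.segments:
        assert hi - lo == pytest.approx(102.0)
        assert len(scheme.windows) == 52
    # adjacent segments overlap by exactly the stated overlap
    for ((_, hi), _), ((lo2, _), _) in zip(plan.segments, plan.segments[1:]):
        assert hi - lo2 == pytest.approx(2.0)


def test_gpf_overlap_regions_in_two_segments():
    plan = sd.build_gpf_plan(400, 1000, 6, 2, 4)
    assert plan.segment_for(501.0) == [0, 1]
    assert plan.segment_for(450.0) == [0]
    # union of unique spans covers the global range
    assert plan.segments[0][1].mz_min == 400.0
    assert plan.segments[-1][1].mz_max == 1000.0
    uniq = [(s.mz_min, s.mz_max) for _, s in plan.segments]
    for (_, hi), (lo, _) in zip(uniq, uniq[1:]):
        assert hi == pytest.approx(lo)


def test_gpf_degenerate_single_segment(scheme52):
    plan = sd.build_gpf_plan(400, 1000, 1, 0, 24)
    scheme = plan.segments[0][1]
    assert [(w.lower_mz, w.upper_mz, w.bank) for w in scheme.windows] == [
        (w.lower_mz, w.upper_mz, w.bank) for w in scheme52.windows
    ]


@pytest.mark.parametrize(
    "args",
    [(400, 1000, 6, 150, 4), (400, 1000, 6, 2, 150), (400, 1000, 0, 2, 4)],
)
def test_gpf_errors(args):
    with pytest.raises(ValueError):
        sd.build_gpf_plan(*args)


# -- concatenation and fraction counting ----------------------------------


def test_concatenation_cases():
    plan = sd.plan_concatenation(18, 6)
    pools = plan.pools()
    assert pools[0] == [0, 6, 12]
    assert all(len(p) == 3 for p in pools)
    assert sd.plan_concatenation(6, 6).pools() == [[i] for i in range(6)]
    assert sorted(len(p) for p in sd.plan_concatenation(7, 3).pools()) == [2, 2, 3]
    with pytest.raises(ValueError):
        sd.plan_concatenation(5, 6)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.integers(min_value=1, max_value=60), st.integers(min_value=1, max_value=60))
def test_concatenation_is_balanced_partition(n_fractions, n_pools):
    if n_pools > n_fractions:
        return
    plan = sd.plan_concatenation(n_fractions, n_pools)
    pools = plan.pools()
    recovered = sorted(f for p in pools for f in p)
    assert recovered == list(range(n_fractions))
    sizes = [len(p) for p in pools]
    assert max(sizes) - min(sizes) <= 1


@pytest.mark.parametrize(
    "minutes,interval,expected", [(42, 140, 18), (0, 140, 0), (10, 140, 4)]
)
def test_fraction_count(minutes, interval, expected):
    assert sd.fraction_count(minutes, interval) == expected


def test_fraction_count_zero_interval():
    with pytest.raises(ValueError):
        sd.fraction_count(42, 0)


# -- serialization ---------------------------------------------------------


def test_isolation_list_roundtrip(scheme52, tmp_path):
    path = tmp_path / "windows.csv"
    sd.export_isolation_list(scheme52, path)
    with open(path) as fh:
        rows = list(csv.DictReader(fh))
    assert len(rows) == len(scheme52.windows)
    for row, w in zip(rows, scheme52.windows):
        assert float(row["center_mz"]) == pytest.approx(
            (w.lower_mz + w.upper_mz) / 2, abs=1e-6
        )
    back = sd.read_isolation_list(path)
    assert back.mz_min == scheme52.mz_min
    assert back.mz_max == scheme52.mz_max
    assert [(w.lower_mz, w.upper_mz, w.bank, w.order) for w in back.windows] == [
        (w.lower_mz, w.upper_mz, w.bank, w.order) for w in scheme52.windows
    ]


def test_scheme_json_roundtrip(scheme52, tmp_path):
    path = tmp_path / "scheme.json"
    scheme52.save(path)
    back = sd.WindowScheme.load(path)
    assert back.to_dict() == scheme52.to_dict()
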