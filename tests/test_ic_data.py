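"""QC rules, grid mapping and table IO for indirect-calorimetry profiles."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import circascreen as cs
from circascreen.errors import (
    DegenerateCurveError,
    EmptyInputError,
    FormatError,
    InsufficientCoverageError,
)
from circascreen.ic_data import (
    CANONICAL_ZT,
    QCThresholds,
    RULE_OUT_OF_RANGE,
    RULE_PULSE,
    RULE_ZT12,
)

from conftest import make_profile

THR = QCThresholds()


def table(rows, header="subject_id,genotype,centre,modality,time,value"):
    return io.StringIO(header + "\n" + "\n".join(rows))


class TestReadTable:
    def test_one_profile_per_subject_modality(self):
        rows = [
            f"m{s},WT,ICS,activity,{7 + h},100" for s in (1, 2) for h in range(21)
        ]
        profiles = cs.read_ic_table(table(rows))
        assert len(profiles) == 2
        assert all(p.zt.size == 21 for p in profiles)

    def test_clock_time_maps_lights_on_to_zt0(self):
        rows = ["m1,WT,ICS,activity,07:00,5", "m1,WT,ICS,activity,08:30,6"]
        (p,) = cs.read_ic_table(table(rows), time_format="clock")
        assert p.zt[0] == pytest.approx(0.0)   # ICS lights on 7:00
        assert p.zt[1] == pytest.approx(1.5)

    def test_missing_value_column_is_format_error(self):
        bad = io.StringIO("subject_id,genotype,centre,modality,time\nm1,WT,ICS,activity,7\n")
        with pytest.raises(FormatError, match="value"):
            cs.read_ic_table(bad)

    def test_empty_file_is_empty_input_error(self):
        with pytest.raises(EmptyInputError):
            cs.read_ic_table(io.StringIO("subject_id,genotype,centre,modality,time,value\n"))

    def test_unparseable_values_become_missing(self):
        rows = ["m1,WT,ICS,activity,7,100", "m1,WT,ICS,activity,8,broken"]
        (p,) = cs.read_ic_table(table(rows))
        assert p.n_observed == 1 and np.isnan(p.values[1])


class TestCanonicalGrid:
    def test_canonical_input_is_identity(self):
        vals = np.linspace(1, 25, 25)
        out = cs.to_canonical_grid(make_profile(vals))
        np.testing.assert_array_equal(out.zt, CANONICAL_ZT)
        np.testing.assert_array_equal(out.values, vals)

    def test_partial_coverage_marks_missing_bins(self):
        # ZT7..ZT28 = 22 observed hourly points -> 3 canonical bins missing
        zt = np.arange(7.0, 29.0)
        p = make_profile(np.ones(22), zt=zt)
        out = cs.to_canonical_grid(p)
        assert out.n_observed == 22
        assert int(np.isnan(out.values).sum()) == 3

    def test_wrap_past_midnight(self):
        # ZT0..ZT4 recorded the next morning land in bins 24..28
        p = make_profile([1, 2], zt=[0.0, 3.0])
        # relax coverage by combining with a full day
        zt = np.concatenate([np.arange(6.0, 24.0), [0.0, 3.0]])
        p = make_profile(np.arange(20.0), zt=np.sort(zt))
        out = cs.to_canonical_grid(p)
        assert not np.isnan(out.values[24 - 6])  # bin ZT24 fed by ZT0

    def test_subhourly_samples_average_within_bin(self):
        zt = np.concatenate([np.arange(6.0, 17.0), [17.0, 17.5]])
        vals = np.concatenate([np.ones(11), [2.0, 4.0]])
        out = cs.to_canonical_grid(make_profile(vals, zt=zt))
        assert out.values[int(17 - 6)] == pytest.approx(3.0)

    def test_insufficient_coverage_raises(self):
        p = make_profile(np.ones(5), zt=np.arange(6.0, 11.0))
        with pytest.raises(InsufficientCoverageError):
            cs.to_canonical_grid(p)


class TestOutOfRange:
    def test_food_above_065_removed_anywhere(self):
        vals = np.full(25, 0.2)
        vals[4] = 0.70  # ZT10
        p, report = cs.remove_out_of_range(make_profile(vals, modality="food_intake"), THR)
        assert np.isnan(p.values[4])
        assert report.removals == [(10.0, RULE_OUT_OF_RANGE, 0.70)]

    def test_night_activity_spike_retained(self):
        vals = np.full(25, 100.0)
        vals[14] = 4500.0  # ZT20, dark phase
        p, report = cs.remove_out_of_range(make_profile(vals), THR)
        assert len(report) == 0 and p.values[14] == 4500.0

    def test_daytime_activity_spike_removed_and_logged(self):
        zt = np.arange(4.0, 29.0)
        vals = np.full(25, 100.0)
        vals[0] = 4500.0  # ZT4, light phase
        p, report = cs.remove_out_of_range(make_profile(vals, zt=zt), THR)
        assert np.isnan(p.values[0])
        assert report.removals == [(4.0, RULE_OUT_OF_RANGE, 4500.0)]

    def test_boundary_is_strict(self):
        vals = np.full(25, 0.2)
        vals[3] = 0.65
        _, report = cs.remove_out_of_range(make_profile(vals, modality="food_intake"), THR)
        assert len(report) == 0


def _zt12_profile(y12, bump14=None):
    """Rising curve peaking at ZT20 (max 1000) with a configurable ZT12 value."""
    vals = np.full(25, 100.0)
    ramp = np.linspace(200, 1000, 8)          # ZT13..ZT20 monotone
    vals[7:15] = ramp
    vals[6] = y12                              # ZT12 bin
    if bump14 is not None:
        vals[8] = bump14                       # make ZT14 a local max
        vals[9] = min(vals[9], bump14 - 200)
    return make_profile(vals)


class TestZT12Artifact:
    def test_transient_removed(self):
        p, report = cs.remove_zt12_artifact(_zt12_profile(900.0), THR)
        assert np.isnan(p.values[6])
        assert report.removals[0][:2] == (12.0, RULE_ZT12)

    def test_low_zt12_retained(self):
        _, report = cs.remove_zt12_artifact(_zt12_profile(500.0), THR)
        assert len(report) == 0

    def test_second_local_max_in_window_blocks_removal(self):
        _, report = cs.remove_zt12_artifact(_zt12_profile(900.0, bump14=600.0), THR)
        assert len(report) == 0

    def test_non_local_max_retained(self):
        # ZT12 high but neighbours higher -> not a local maximum
        vals = np.full(25, 100.0)
        vals[5:9] = [850, 900, 950, 1000]
        _, report = cs.remove_zt12_artifact(make_profile(vals), THR)
        assert len(report) == 0


class TestPulseBreakup:
    def test_flat_series_untouched(self):
        _, report = cs.remove_pulse_breakup(make_profile(np.full(25, 5.0)), THR)
        assert len(report) == 0

    def test_spike_with_both_gaps_above_threshold_removed(self):
        vals = np.full(25, 400.0)
        vals[10] = 1000.0  # gaps 600 both sides; threshold 0.57*1000 = 570
        p, report = cs.remove_pulse_breakup(make_profile(vals), THR)
        assert np.isnan(p.values[10])
        assert report.removals == [(16.0, RULE_PULSE, 1000.0)]

    def test_min_gap_rule_spares_shouldered_spike(self):
        vals = np.full(25, 400.0)
        vals[10] = 1000.0
        vals[9] = 900.0    # left gap 100 -> min(100, 600) < 570
        _, report = cs.remove_pulse_breakup(make_profile(vals), THR)
        assert all(z != 16.0 for z, _, _ in report.removals)

    def test_endpoint_uses_single_neighbour(self):
        vals = np.full(25, 400.0)
        vals[0] = 1000.0
        p, report = cs.remove_pulse_breakup(make_profile(vals), THR)
        assert np.isnan(p.values[0])


class TestImputeNormalize:
    def test_minmax_definition(self):
        vals = np.linspace(0, 100, 25)
        out = cs.impute_and_normalize(make_profile(vals))
        assert out[12] == pytest.approx(0.5)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_interior_gap_linear_midpoint(self):
        vals = np.arange(25.0) + 2.0
        vals[10] = np.nan  # neighbours 11 and 13 -> imputed 12
        p = make_profile(vals)
        full = np.interp(p.zt, p.zt[p.observed_mask()], p.values[p.observed_mask()])
        assert full[10] == pytest.approx(12.0)
        out = cs.impute_and_normalize(p)
        assert np.all((out >= 0) & (out <= 1))

    def test_edge_gap_nearest_extension(self):
        vals = np.linspace(10, 34, 25)
        vals[0] = np.nan
        out = cs.impute_and_normalize(make_profile(vals))
        assert out[0] == out[1] == 0.0

    def test_constant_curve_is_degenerate(self):
        with pytest.raises(DegenerateCurveError):
            cs.impute_and_normalize(make_profile(np.full(25, 7.0)))

    def test_too_few_observed_bins(self):
        vals = np.full(25, np.nan)
        vals[:11] = np.arange(11.0)
        with pytest.raises(InsufficientCoverageError):
            cs.impute_and_normalize(make_profile(vals))


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

def _random_profile(seed, modality="activity"):
    rng = np.random.default_rng(seed)
    scale = 5000.0 if modality == "activity" else 1.0
    vals = rng.uniform(0, scale, 25)
    vals[rng.random(25) < 0.08] = np.nan
    if np.sum(~np.isnan(vals)) < 12:
        vals[:12] = rng.uniform(0, scale, 12)
    return make_profile(vals, modality=modality)


@settings(max_examples=60, derandomize=True)
@given(seed=st.integers(0, 10**6), modality=st.sampled_from(["activity", "food_intake"]))
def test_conservation_per_rule(seed, modality):
    """retained + removed = observed, for every rule in the pass."""
    profile = _random_profile(seed, modality)
    n0 = profile.n_observed
    for rule in (cs.remove_out_of_range, cs.remove_zt12_artifact, cs.remove_pulse_breakup):
        out, report = rule(profile, THR)
        assert out.n_observed + len(report) == profile.n_observed
        profile = out
    cleaned, full_report = cs.apply_qc(_random_profile(seed, modality), THR)
    assert cleaned.n_observed + len(full_report) == n0
    zts = [z for z, _, _ in full_report.removals]
    assert len(zts) == len(set(zts))  # each point removed exactly once


@settings(max_examples=60, derandomize=True)
@given(seed=st.integers(0, 10**6), modality=st.sampled_from(["activity", "food_intake"]))
def test_out_of_range_matches_bruteforce_scan(seed, modality):
    profile = _random_profile(seed, modality)
    _, report = cs.remove_out_of_range(profile, THR)
    expected = set()
    for z, v in zip(profile.zt, profile.values):
        if np.isnan(v):
            continue
        if modality == "food_intake" and v > THR.food_max:
            expected.add(z)
        if modality == "activity" and v > THR.activity_max and (z % 24) < 12:
            expected.add(z)
    assert {z for z, _, _ in report.removals} == expected


@settings(max_examples=60, derandomize=True)
@given(seed=st.integers(0, 10**6))
def test_pulse_breakup_matches_bruteforce_scan(seed):
    profile = _random_profile(seed)
    _, report = cs.remove_pulse_breakup(profile, THR)
    idx = np.flatnonzero(profile.observed_mask())
    seq = profile.values[idx]
    expected = set()
    for pos in range(seq.size):
        gaps = []
        if pos > 0:
            gaps.append(abs(seq[pos] - seq[pos - 1]))
        if pos < seq.size - 1:
            gaps.append(abs(seq[pos] - seq[pos + 1]))
        if gaps and min(gaps) >= THR.alpha1 * seq.max():
            expected.add(profile.zt[idx[pos]])
    assert {z for z, _, _ in report.removals} == expected


@settings(max_examples=40, derandomize=True)
@given(seed=st.integers(0, 10**6))
def test_normalized_curves_span_unit_interval(seed):
    profile = _random_profile(seed)
    try:
        out = cs.impute_and_normalize(profile)
    except (InsufficientCoverageError, DegenerateCurveError):
        return
    assert out.min() == pytest.approx(0.0)
    assert out.max() == pytest.approx(1.0)


def test_rule_order_out_of_range_before_zt12():
    """An out-of-range daytime spike is removed before y_max is computed,
    changing whether ZT12 qualifies as 4/5 of the maximum."""
    vals = np.full(25, 100.0)
    vals[6] = 900.0          # ZT12 candidate transient
    vals[7:15] = np.linspace(200, 1000, 8)
    vals[2] = 4500.0         # ZT8 daytime artefact, would inflate y_max
    _, report = cs.apply_qc(make_profile(vals), THR)
    rules = {z: r for z, r, _ in report.removals}
    assert rules.get(8.0) == RULE_OUT_OF_RANGE
    assert rules.get(12.0) == RULE_ZT12  # evaluated against post-removal y_max
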