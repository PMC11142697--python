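"""Yield-gap ratios, stage classification and top-country tallies."""
import pytest

import graincast as gc

# published distribution intensities over 1961-2021 (61 years)
EXPECTED_TALLIES = {
    "rice": {"Australia": (22, 36.1), "Puerto Rico": (15, 24.6),
             "Egypt": (13, 21.3), "Swaziland": (6, 9.8), "Syria": (2, 3.3),
             "Dominica": (1, 1.6), "North Korea": (1, 1.6), "Uzbekistan": (1, 1.6)},
    "wheat": {"Netherlands": (27, 44.3), "Ireland": (19, 31.1),
              "Denmark": (5, 8.2), "New Zealand": (5, 8.2), "Belgium": (2, 3.3),
              "France": (1, 1.6), "Luxembourg": (1, 1.6), "Zambia": (1, 1.6)},
    "maize": {"United Arab Emirates": (20, 32.8), "New Zealand": (11, 18.0),
              "France": (8, 13.1), "Israel": (6, 9.8), "Jordan": (6, 9.8),
              "Kuwait": (3, 4.9), "Greece": (2, 3.3), "Netherlands": (2, 3.3),
              "Saint Vincent and the Grenadines": (2, 3.3), "Qatar": (1, 1.6)},
    "soybean": {"Italy": (19, 31.1), "Turkey": (17, 27.9),
                "Ethiopia PDR": (12, 19.7), "Paraguay": (4, 6.6),
                "Mexico": (3, 4.9), "New Zealand": (3, 4.9), "Canada": (1, 1.6),
                "Egypt": (1, 1.6), "Switzerland": (1, 1.6)},
}


def test_ratio_series_reference_values():
    """2030 ratios from the published equations: rice 50.6%, soybean 72.5%."""
    assert gc.ratio_series({2030: 5194.8}, {2030: 10269.5})[2030] == 50.6
    assert gc.ratio_series({2030: 3070.6}, {2030: 4237.0})[2030] == 72.5
    assert gc.ratio_series({2030: 4000.0}, {2030: 4000.0})[2030] == 100.0


def test_ratio_series_is_scale_invariant():
    avg = {y: 100.0 + y for y in range(2020, 2031)}
    top = {y: 300.0 + 2 * y for y in range(2020, 2031)}
    lam = 17.0
    assert gc.ratio_series(avg, top) == gc.ratio_series(
        {y: lam * v for y, v in avg.items()}, {y: lam * v for y, v in top.items()})


def test_classify_gap_labels():
    assert gc.classify_gap({2020: 15.4, 2030: 14.7})[0] == "widening"
    assert gc.classify_gap({2020: 50.2, 2030: 50.6})[0] == "narrowing"
    assert gc.classify_gap({2020: 40.0, 2030: 40.0})[0] == "stable"
    label, change = gc.classify_gap({2020: 70.2, 2025: 71.0, 2030: 72.5})
    assert (label, change) == ("narrowing", 2.3)


@pytest.mark.parametrize("ratio, stage, priority", [
    (14.7, "low", "high-yield countries"),
    (50.6, "mid", "both"),
    (72.5, "high", "low-yield countries"),
    (30.0, "mid", "both"),     # boundaries fall in the mid band
    (70.0, "mid", "both"),
])
def test_stage_and_priority(ratio, stage, priority):
    assert gc.stage_and_priority(ratio) == (stage, priority)


def test_stage_rejects_out_of_band_ratio():
    with pytest.raises(ValueError):
        gc.stage_and_priority(0.0)
    with pytest.raises(ValueError):
        gc.stage_and_priority(120.0)


@pytest.mark.parametrize("crop", sorted(EXPECTED_TALLIES))
def test_tallies_match_the_documented_record(reference_fixture, crop):
    """Counts and percentages for every country match the published
    distribution intensities."""
    tally = gc.tally_top_countries(reference_fixture[(crop, "top")])
    assert tally.n_years == 61
    expected = EXPECTED_TALLIES[crop]
    assert set(tally.counts) == set(expected)
    for country, (n, pct) in expected.items():
        assert tally.counts[country] == n
        assert tally.percentages[country] == pct
    assert sum(tally.counts.values()) == 61  # the years partition


def test_tally_single_country():
    s = gc.YieldSeries(crop="rice", kind="top",
                       values={y: 100.0 for y in range(2000, 2010)},
                       top_country={y: "Australia" for y in range(2000, 2010)})
    tally = gc.tally_top_countries(s)
    assert tally.counts == {"Australia": 10}
    assert tally.percentages == {"Australia": 100.0}


def test_tally_requires_complete_labels():
    s = gc.YieldSeries(crop="rice", kind="top",
                       values={2000: 1.0, 2001: 2.0, 2002: 2.0},
                       top_country={2000: "A", 2001: "B"})
    with pytest.raises(ValueError, match="2002"):
        gc.tally_top_countries(s)


def test_build_gap_report_from_reference_projections():
    from graincast.reference import REFERENCE_TRENDS
    horizon = range(2020, 2031)
    avg = REFERENCE_TRENDS[("maize", "average")].predict(horizon)
    top = REFERENCE_TRENDS[("maize", "top")].predict(horizon)
    rep = gc.build_gap_report("maize", avg, top)
    assert rep.ratio_by_year[2030] == 14.7
    assert rep.trend_label == "widening"
    assert rep.stage == "low"
    assert rep.priority == "high-yield countries"
    assert round(rep.potential_limit_2030) == 46022
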