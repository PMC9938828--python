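import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ptew.errors import NoDataError, ValidationError
from ptew.indices import (
    classify_cd,
    classify_hpi,
    contamination_factor,
    degree_of_contamination,
    hpi,
    index_report,
    sub_index,
    unit_weight,
)

conc = st.floats(min_value=0.0, max_value=1e4, allow_nan=False)
std = st.floats(min_value=1e-3, max_value=1e4, allow_nan=False)


@pytest.mark.parametrize(
    "c, s, expected",
    [
        (0.36, 15.0, -0.98),  # winter mean Pb against the EPA standard
        (5.0, 5.0, 0.0),
        (0.0, 5.0, -1.0),
    ],
)
def test_contamination_factor_examples(c, s, expected):
    assert contamination_factor(c, s) == pytest.approx(expected, abs=5e-3)


def test_contamination_factor_domain_errors():
    with pytest.raises(ValidationError):
        contamination_factor(1.0, 0.0)
    with pytest.raises(ValidationError):
        contamination_factor(-1.0, 5.0)


@given(c1=conc, c2=conc, s1=std, s2=std)
def test_contamination_factor_monotonicity(c1, c2, s1, s2):
    # strictness only where the ratio difference is resolvable in float64
    if c1 < c2 and (c2 - c1) / s1 > 1e-12:
        assert contamination_factor(c1, s1) < contamination_factor(c2, s1)
    if s1 < s2 and c1 / s1 - c1 / s2 > 1e-12:
        assert contamination_factor(c1, s1) > contamination_factor(c1, s2)


def test_degree_of_contamination_epa_seasonal_values(study, metals):
    for season, expected in (("winter", -3.74), ("summer", -3.82)):
        cfs = [
            contamination_factor(c, metals[m].standards["EPA"])
            for m, c in study.mean_concentrations(season).items()
        ]
        assert round(degree_of_contamination(cfs), 2) == expected


def test_degree_of_contamination_zero_and_empty():
    assert degree_of_contamination([0.0, 0.0, 0.0]) == 0.0
    with pytest.raises(NoDataError):
        degree_of_contamination([])


@given(st.lists(st.floats(-1, 100, allow_nan=False), min_size=1, max_size=30))
def test_degree_of_contamination_equals_left_fold(cfs):
    total = 0.0
    for v in cfs:
        total += v
    assert degree_of_contamination(cfs) == pytest.approx(total, abs=1e-9)


@pytest.mark.parametrize(
    "cd, label",
    [(-3.74, "significantly_low"), (2.0, "moderate"), (3.5, "high"),
     (1.0, "significantly_low"), (3.0, "moderate")],
)
def test_classify_cd(cd, label):
    assert classify_cd(cd) == label


@pytest.mark.parametrize(
    "s, k, expected", [(2.0, 1.0, 0.5), (6.0, 1.0, 1 / 6), (1.0, 1.0, 1.0)]
)
def test_unit_weight(s, k, expected):
    assert unit_weight(s, k) == pytest.approx(expected)


@pytest.mark.parametrize(
    "c, s, i, expected",
    [
        (2.28, 50.0, 100.0, 195.44),  # Mn: ideal above the standard
        (0.32, 2.0, 0.0, 16.00),
        (5.0, 5.0, 0.0, 100.0),
    ],
)
def test_sub_index_examples(c, s, i, expected):
    assert sub_index(c, s, i) == pytest.approx(expected, abs=5e-3)


def test_sub_index_degenerate_standard():
    with pytest.raises(ValidationError):
        sub_index(1.0, 5.0, 5.0)


def _epa_winter_inputs(study, metals):
    means = study.mean_concentrations("winter")
    w = {m: unit_weight(metals[m].standards["EPA"]) for m in means}
    q = {m: sub_index(c, metals[m].standards["EPA"], metals[m].ideal)
         for m, c in means.items()}
    return w, q


def test_hpi_table2_mode_reproduces_printed_value(study, metals):
    w, q = _epa_winter_inputs(study, metals)
    assert hpi(w, q, rounding="table2") == pytest.approx(20.82, abs=0.01)


def test_hpi_full_precision_differs_from_tabulated(study, metals):
    w, q = _epa_winter_inputs(study, metals)
    assert hpi(w, q, rounding="full") == pytest.approx(20.47, abs=0.02)


def test_hpi_of_constant_subindices_is_that_constant():
    w = {"a": 0.3, "b": 0.01, "c": 5.0}
    q = {m: 42.0 for m in w}
    assert hpi(w, q) == pytest.approx(42.0)


def test_hpi_metal_set_mismatch_lists_difference():
    with pytest.raises(ValidationError, match="Fe"):
        hpi({"Pb": 0.1}, {"Pb": 5.0, "Fe": 2.0})


@given(
    data=st.dictionaries(
        st.sampled_from(["Pb", "Hg", "Mn", "Fe", "As", "Cd"]),
        st.tuples(st.floats(1e-3, 10.0), st.floats(0.0, 500.0)),
        min_size=1,
        max_size=6,
    ),
    scale=st.floats(1e-3, 1e3),
)
def test_hpi_scale_invariance_and_bounds(data, scale):
    w = {m: wq[0] for m, wq in data.items()}
    q = {m: wq[1] for m, wq in data.items()}
    value = hpi(w, q)
    scaled = hpi({m: v * scale for m, v in w.items()}, q)
    assert scaled == pytest.approx(value, rel=1e-9)
    assert min(q.values()) - 1e-9 <= value <= max(q.values()) + 1e-9


@pytest.mark.parametrize(
    "value, label",
    [(20.82, "excellent"), (75.0, "good"), (310.0, "unsuitable"),
     (50.0, "good"), (100.0, "poor"), (200.0, "very_poor"), (300.0, "unsuitable")],
)
def test_classify_hpi(value, label):
    assert classify_hpi(value) == label


@given(st.floats(-50, 50, allow_nan=False))
def test_cd_classification_is_total_and_exclusive(x):
    assert classify_cd(x) in {"significantly_low", "moderate", "high"}


@given(st.floats(0, 1000, allow_nan=False))
def test_hpi_classification_is_total_and_exclusive(x):
    assert classify_hpi(x) in {"excellent", "good", "poor", "very_poor", "unsuitable"}


def test_index_report_consistency(study, metals):
    res = index_report(study.mean_concentrations("winter"), metals, "EPA", "winter")
    assert res.cd == pytest.approx(math.fsum(res.cf.values()))
    assert all(0 < w <= 1 for w in res.w.values())
    assert res.cd_class == "significantly_low"
    assert res.hpi_class == "excellent"
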