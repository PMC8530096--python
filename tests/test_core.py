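"""Unit and property tests for the entropy computation stages."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist

from mmdisten import (
    DistanceHistogram,
    EntropyParams,
    MultichannelSeries,
    as_series,
    coarse_grain,
    distance_epdf,
    embed,
    embed_nested,
    mm_mdisten,
    mm_mdisten_curve,
    normalized_entropy,
    template_distances,
)
from mmdisten.core import (
    DegenerateToleranceError,
    EmbeddingError,
    InvalidBinCountError,
    InvalidScaleError,
    TemplateSet,
)


# ---------------------------------------------------------------------------
# coarse-graining
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "values, s, expected",
    [
        ([1, 2, 3, 4, 5, 6], 2, [1.5, 3.5, 5.5]),
        ([1, 2, 3, 4, 5], 2, [1.5, 3.5]),  # 5th sample discarded
        ([1, 2, 3, 4, 5, 6], 3, [2.0, 5.0]),
    ],
)
def test_coarse_grain_window_means(values, s, expected):
    cg = coarse_grain(as_series(values), s)
    assert cg.scale == s
    np.testing.assert_allclose(cg.values[0], expected)


def test_coarse_grain_scale_one_is_identity(random_series):
    cg = coarse_grain(random_series, 1)
    np.testing.assert_array_equal(cg.values, random_series.values)


def test_coarse_grain_invalid_scale_names_s_and_n():
    series = as_series([1.0, 2.0, 3.0])
    with pytest.raises(InvalidScaleError, match="s=4.*N=3"):
        coarse_grain(series, 4)
    with pytest.raises(InvalidScaleError):
        coarse_grain(series, 0)


@given(n=st.integers(2, 200), s=st.integers(1, 15))
@settings(max_examples=60, deadline=None)
def test_coarse_grain_floor_law(n, s):
    if s > n:
        return
    series = as_series(np.arange(n, dtype=float))
    cg = coarse_grain(series, s)
    assert cg.n_samples == n // s


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def test_embed_single_channel_enumeration():
    cg = coarse_grain(as_series([1, 2, 3, 4, 5]), 1)
    ts = embed(cg, m=3, tau=1)
    assert ts.count == 3
    np.testing.assert_array_equal(
        ts.templates[:, 0, :], [[1, 2, 3], [2, 3, 4], [3, 4, 5]]
    )


def test_embed_two_channels():
    cg = coarse_grain(as_series([[1, 2, 3], [10, 20, 30]]), 1)
    ts = embed(cg, m=2, tau=1)
    assert ts.count == 2
    np.testing.assert_array_equal(ts.templates[0], [[1, 2], [10, 20]])


def test_embed_matches_index_enumeration_oracle():
    # c=1, N_s=10, m=3, tau=2: count must be 10 - (3-1)*2 = 6
    values = np.arange(10, dtype=float)
    cg = coarse_grain(as_series(values), 1)
    ts = embed(cg, m=3, tau=2)
    assert ts.count == 6
    for j in range(6):  # brute-force index enumeration
        expected = [values[j + k * 2] for k in range(3)]
        np.testing.assert_array_equal(ts.templates[j, 0], expected)


def test_embed_too_short_reports_minimum():
    cg = coarse_grain(as_series([1.0, 2.0]), 1)
    with pytest.raises(EmbeddingError, match="at least 5"):
        embed(cg, m=3, tau=2)


def test_embed_nested_stacks_consecutive_templates(rng):
    values = rng.standard_normal((2, 12))
    cg = coarse_grain(MultichannelSeries(values=values), 1)
    m, tau = 3, 1
    nested = embed_nested(cg, m, tau)
    single = embed(cg, m, tau)
    assert nested.count == single.count - (m - 1) * tau
    for j in range(nested.count):
        expected = np.concatenate(
            [single.templates[j + k * tau] for k in range(m)], axis=1
        )
        np.testing.assert_array_equal(nested.templates[j], expected)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_template_distance_3_4_5_triangle():
    ts = TemplateSet(templates=np.array([[[0.0, 0.0, 0.0]], [[3.0, 4.0, 0.0]]]))
    dm = template_distances(ts, r=1.0, n=1.0)
    assert dm.raw[0, 1] == pytest.approx(5.0)
    assert dm.scaled[0, 1] == pytest.approx(5.0)
    assert dm.raw[0, 0] == 0.0


def test_identical_templates_zero_distance():
    t = np.ones((1, 2, 3))
    ts = TemplateSet(templates=np.repeat(t, 3, axis=0))
    dm = template_distances(ts, r=0.5, n=2.0)
    np.testing.assert_array_equal(dm.raw, 0.0)


def test_distances_match_double_loop_oracle(rng):
    templates = rng.standard_normal((8, 2, 3))
    r, n = 0.37, 2.0
    dm = template_distances(TemplateSet(templates=templates), r=r, n=n)
    for i in range(8):
        for j in range(8):
            d = np.sqrt(((templates[i] - templates[j]) ** 2).sum())
            assert dm.raw[i, j] == pytest.approx(d, abs=1e-12)
            assert dm.scaled[i, j] == pytest.approx((d / r) ** n, abs=1e-9)


def test_nonpositive_tolerance_rejected(rng):
    ts = TemplateSet(templates=rng.standard_normal((4, 1, 3)))
    with pytest.raises(DegenerateToleranceError):
        template_distances(ts, r=0.0, n=2.0)


# ---------------------------------------------------------------------------
# histogram / entropy
# ---------------------------------------------------------------------------

def test_epdf_degenerate_range_is_one_hot():
    dm = template_distances(
        TemplateSet(templates=np.zeros((3, 1, 2)) + [[0.0, 1.0]]), r=1.0, n=2.0
    )
    h = distance_epdf(dm, B=8)
    np.testing.assert_array_equal(h.probabilities, [1, 0, 0, 0, 0, 0, 0, 0])


def test_epdf_uniform_four_values():
    # distances {0,1,2,3} with B=4 -> each value in its own bin
    raw = np.zeros((4, 4))
    vals = {(0, 1): 0.0, (0, 2): 1.0, (0, 3): 2.0, (1, 2): 3.0, (1, 3): 3.0, (2, 3): 3.0}
    # construct a symmetric matrix whose upper triangle is {0,1,2,3,3,3}
    for (i, j), v in vals.items():
        raw[i, j] = raw[j, i] = v
    from mmdisten.core import DistanceMatrix

    dm = DistanceMatrix(raw=raw, scaled=raw)
    h = distance_epdf(dm, B=4)
    np.testing.assert_allclose(h.probabilities, [1 / 6, 1 / 6, 1 / 6, 3 / 6])
    assert h.probabilities.sum() == pytest.approx(1.0, abs=1e-12)


def test_epdf_matches_counting_oracle(rng):
    templates = rng.standard_normal((11, 1, 3))  # 55 pairwise distances
    dm = template_distances(TemplateSet(templates=templates), r=0.2, n=2.0)
    B = 8
    h = distance_epdf(dm, B=B)
    iu = np.triu_indices(11, k=1)
    dists = dm.scaled[iu]
    lo, hi = dists.min(), dists.max()
    width = (hi - lo) / B
    counts = np.zeros(B)
    for d in dists:  # independent per-value bin assignment
        t = min(int((d - lo) / width), B - 1)
        counts[t] += 1
    np.testing.assert_allclose(h.probabilities, counts / dists.size)
    assert h.probabilities.sum() == pytest.approx(1.0, abs=1e-12)


def test_epdf_rejects_small_bin_count(rng):
    dm = template_distances(TemplateSet(templates=rng.standard_normal((4, 1, 2))), 1.0, 2.0)
    with pytest.raises(InvalidBinCountError):
        distance_epdf(dm, B=1)


@pytest.mark.parametrize(
    "probs, expected",
    [
        (np.eye(8)[0], 0.0),  # one-hot
        (np.full(8, 1 / 8), 1.0),  # uniform
        (np.array([0.5, 0.5] + [0.0] * 62), 1 / 6),  # 1/log2(64)
    ],
)
def test_normalized_entropy_closed_forms(probs, expected):
    h = DistanceHistogram(probabilities=probs, bin_edges=np.arange(len(probs) + 1.0))
    assert normalized_entropy(h) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# composed entropy
# ---------------------------------------------------------------------------

def test_constant_series_zero_at_all_scales():
    series = MultichannelSeries(values=np.full((3, 200), 7.5))
    params = EntropyParams()
    for s in range(1, 16):
        assert mm_mdisten(series, params, s) == 0.0


def test_channel_permutation_invariance(rng):
    values = rng.standard_normal((4, 250))
    params = EntropyParams(scales=(1, 2, 5))
    base = MultichannelSeries(values=values)
    permuted = MultichannelSeries(values=values[[2, 0, 3, 1]])
    for s in params.scales:
        assert mm_mdisten(base, params, s) == pytest.approx(
            mm_mdisten(permuted, params, s), abs=1e-12
        )


def test_curve_matches_per_scale_calls(random_series, default_params):
    curve = mm_mdisten_curve(random_series, default_params)
    assert curve.scale_values == default_params.scales
    for s, e in zip(curve.scale_values, curve.entropy_values):
        assert e == mm_mdisten(random_series, default_params, s)


def test_curve_rejects_infeasible_scale_by_name():
    series = as_series(np.sin(np.arange(30)))
    params = EntropyParams(scales=(1, 29))
    with pytest.raises(EmbeddingError, match="s=29"):
        mm_mdisten_curve(series, params)


def test_determinism(random_series, default_params):
    a = mm_mdisten(random_series, default_params, 3)
    b = mm_mdisten(random_series, default_params, 3)
    assert a == b


def test_full_pipeline_matches_nested_loop_reference(rng):
    """Composed stages agree with an unoptimized loop reference on a tiny case."""
    values = rng.standard_normal((2, 14))  # <= 12 templates
    series = MultichannelSeries(values=values)
    params = EntropyParams(scales=(1,), B=8)
    result = mm_mdisten(series, params, 1)

    # reference: all loops, no shared helpers
    m, tau, B = params.m, params.tau, params.B
    r = params.r_coef * np.std(values)
    count = values.shape[1] - (m - 1) * tau
    templates = [values[:, j : j + (m - 1) * tau + 1 : tau] for j in range(count)]
    dists = []
    for i in range(count):
        for j in range(i + 1, count):
            acc = 0.0
            for c in range(2):
                for k in range(m):
                    acc += (templates[i][c][k] - templates[j][c][k]) ** 2
            dists.append(np.sqrt(acc) / r)
    dists = [d ** params.n for d in dists]
    lo, hi = min(dists), max(dists)
    counts = [0] * B
    for d in dists:
        t = min(int((d - lo) / ((hi - lo) / B)), B - 1)
        counts[t] += 1
    p = [cnt / len(dists) for cnt in counts if cnt > 0]
    expected = -sum(q * np.log2(q) for q in p) / np.log2(B)
    assert result == pytest.approx(expected, abs=1e-12)


@given(
    n=st.integers(50, 400),
    c=st.sampled_from([1, 2, 4]),
    s=st.integers(1, 15),
    seed=st.integers(0, 2**16),
)
@settings(max_examples=40, deadline=None)
def test_entropy_always_in_unit_interval(n, c, s, seed):
    rng = np.random.default_rng(seed)
    series = MultichannelSeries(values=rng.standard_normal((c, n)))
    params = EntropyParams()
    if n // s < (params.m - 1) * params.tau + 2:
        return
    e = mm_mdisten(series, params, s)
    assert 0.0 <= e <= 1.0


def test_nested_mode_end_to_end(rng):
    series = MultichannelSeries(values=rng.standard_normal((2, 100)))
    e = mm_mdisten(series, EntropyParams(mode="nested"), 2)
    assert 0.0 <= e <= 1.0


def test_series_validation():
    with pytest.raises(ValueError):
        MultichannelSeries(values=np.array([[np.nan, 1.0]]))
    with pytest.raises(ValueError):
        MultichannelSeries(values=np.ones((1, 2)), sampling_rate=-5.0)
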