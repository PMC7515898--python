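import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pyroage import (
    MetricSet,
    ModelSpec,
    PredictorCombination,
    SearchRecord,
    ValidationError,
    average_model_predictions,
    compute_mad,
    compute_pearson_r,
    compute_rmse,
    compute_vif,
    default_cohort_config,
    enumerate_combinations,
    evaluate_all_schemes,
    evaluate_replicate_scheme,
    fit_model,
    generate_cohort,
    generate_replicate_grids,
    make_linear_model,
    predict,
    random_split,
    run_exhaustive_search,
    search_plan,
    select_best_combination,
    summarize_best,
    zp1_combination,
)
from pyroage.search import (
    REPLICATE_SCHEMES,
    SCHEME_ORDER,
    frame_to_records,
    records_to_frame,
)
from pyroage.synthetic import GRID_CELLS, SyntheticConfig


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_mad_hand_example():
    assert compute_mad([30, 40, 50], [28, 44, 50]) == pytest.approx(2.0)


def test_rmse_hand_example():
    assert compute_rmse([30, 40, 50], [28, 44, 50]) == pytest.approx(math.sqrt(20 / 3))


def test_metrics_zero_on_identical():
    v = [1.0, 2.0, 3.0]
    assert compute_mad(v, v) == 0.0
    assert compute_rmse(v, v) == 0.0


def test_metric_length_mismatch():
    for fn in (compute_mad, compute_rmse, compute_pearson_r):
        with pytest.raises(ValidationError):
            fn([1.0, 2.0], [1.0])


def test_mad_rmse_elementwise_oracle():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = rng.integers(2, 40)
        p = rng.normal(50, 20, size=n)
        o = rng.normal(50, 20, size=n)
        mad_oracle = sum(abs(a - b) for a, b in zip(p, o)) / n
        rmse_oracle = math.sqrt(sum((a - b) ** 2 for a, b in zip(p, o)) / n)
        assert abs(compute_mad(p, o) - mad_oracle) <= 1e-12
        assert abs(compute_rmse(p, o) - rmse_oracle) <= 1e-12


def test_pearson_perfect_and_oracle():
    x = np.array([1.0, 2.0, 5.0, 9.0])
    assert compute_pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
    assert compute_pearson_r(x, -x) == pytest.approx(-1.0)
    rng = np.random.default_rng(1)
    for _ in range(50):
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        assert abs(compute_pearson_r(a, b) - stats.pearsonr(a, b)[0]) <= 1e-12


def test_pearson_zero_variance_rejected():
    with pytest.raises(ValidationError):
        compute_pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_metricset_power_mean_guard():
    with pytest.raises(ValidationError):
        MetricSet(pearson_r=0.9, mad=5.0, rmse=4.0, n=10)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.floats(min_value=-100, max_value=100), min_size=2, max_size=30),
    st.integers(min_value=0, max_value=1000),
)
def test_rmse_ge_mad_property(observed, seed):
    rng = np.random.default_rng(seed)
    o = np.array(observed)
    p = o + rng.normal(size=o.size)
    assert compute_rmse(p, o) >= compute_mad(p, o) >= 0


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def test_enumeration_counts():
    assert len(enumerate_combinations("cpg7")) == 127
    assert len(enumerate_combinations("mqr14")) == 16_383


def test_enumeration_unique_and_ordered():
    combos = enumerate_combinations("cpg7")
    labels = [c.label for c in combos]
    assert len(set(labels)) == 127
    sizes = [c.n_variables for c in combos]
    assert sizes == sorted(sizes)
    # 2^n - 1 identity on both scopes
    assert len(enumerate_combinations("mqr14")) == 2**14 - 1
    assert len({c.label for c in enumerate_combinations("mqr14")}) == 2**14 - 1


def test_six_family_plan_totals_17018():
    specs = [ModelSpec(f) for f in ("mqr", "svm_r", "svm_l", "svm_p", "gbr", "mmda")]
    plan = search_plan(specs)
    assert plan["mqr"] == 16_383
    assert all(plan[f] == 127 for f in ("svm_r", "svm_l", "svm_p", "gbr", "mmda"))
    assert plan["total"] == 17_018


# ---------------------------------------------------------------------------
# exhaustive search
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_split():
    cohort = generate_cohort(default_cohort_config(n_samples=150, seed=8))
    return random_split(cohort, 100, seed=1)


def test_single_family_search_127_records(small_split):
    training, testing = small_split
    records = run_exhaustive_search(training, testing, [ModelSpec("svm_r")])
    assert len(records) == 127
    assert not any(r.failed for r in records)
    assert all(r.metrics_training and r.metrics_testing for r in records)


def test_search_count_matches_plan(small_split):
    training, testing = small_split
    specs = [ModelSpec("svm_l"), ModelSpec("mmda")]
    records = run_exhaustive_search(training, testing, specs)
    assert len(records) == search_plan(specs)["total"]


def test_overlapping_sets_rejected(small_split):
    training, _ = small_split
    with pytest.raises(ValidationError, match="overlap"):
        run_exhaustive_search(training, training, [ModelSpec("svm_r")])


def test_best_mqr_beats_zp1_baseline(small_split):
    training, testing = small_split
    records = run_exhaustive_search(
        training, testing, [ModelSpec("zp1_mlr"), ModelSpec("mqr")]
    )
    zp1 = next(r for r in records if r.family == "zp1_mlr")
    best_mqr = select_best_combination(records, "mqr", reference="testing")
    assert best_mqr.metrics_testing.mad < zp1.metrics_testing.mad


def test_search_checkpoint_resume(small_split, tmp_path):
    training, testing = small_split
    specs = [ModelSpec("svm_r")]
    r1 = run_exhaustive_search(training, testing, specs, checkpoint_dir=tmp_path)
    # second run must load every record from the checkpoint, not refit
    r2 = run_exhaustive_search(training, testing, specs, checkpoint_dir=tmp_path)
    assert len(r1) == len(r2) == 127
    assert [r.combination_label for r in r1] == [r.combination_label for r in r2]
    m1 = {r.combination_label: r.metrics_testing.mad for r in r1}
    m2 = {r.combination_label: r.metrics_testing.mad for r in r2}
    assert m1 == m2


def test_records_frame_roundtrip(small_split):
    training, testing = small_split
    records = run_exhaustive_search(training, testing, [ModelSpec("zp1_mlr")])
    frame = records_to_frame(records)
    back = frame_to_records(frame)
    assert back[0].combination_label == records[0].combination_label
    assert back[0].metrics_testing.mad == pytest.approx(records[0].metrics_testing.mad)


def test_failed_fit_recorded_not_raised(small_split):
    training, testing = small_split
    # degenerate hyperparameter: negative tree count fails every fit
    records = run_exhaustive_search(
        training, testing, [ModelSpec("gbr", {"n_estimators": -1})]
    )
    assert len(records) == 127
    assert all(r.failed for r in records)
    with pytest.raises(ValidationError):
        select_best_combination(records, "gbr", reference="testing")


def test_summarize_best_layout(small_split):
    training, testing = small_split
    specs = [ModelSpec("svm_r"), ModelSpec("mmda")]
    records = run_exhaustive_search(training, testing, specs)
    summary = summarize_best(records, [s.family for s in specs])
    assert len(summary) == 4  # 2 families x (T, V) reference rows
    assert set(summary["reference"]) == {"T", "V"}


# ---------------------------------------------------------------------------
# best-combination selection
# ---------------------------------------------------------------------------

def _record(family, label, nvars, mad):
    m = MetricSet(pearson_r=0.9, mad=mad, rmse=mad + 1, n=50)
    return SearchRecord(
        family=family, combination_label=label, n_variables=nvars,
        metrics_training=m, metrics_testing=m, hyperparameter_fingerprint="hp",
    )


def test_tie_break_prefers_fewer_variables():
    records = [
        _record("mqr", "CpG_1-5", 5, 4.4),
        _record("mqr", "CpG_6-7", 2, 4.4),
        _record("mqr", "CpG_1", 1, 5.0),
    ]
    best = select_best_combination(records, "mqr", reference="testing")
    assert best.combination_label == "CpG_6-7"


def test_single_record_selected():
    records = [_record("gbr", "CpG_1", 1, 9.0)]
    assert select_best_combination(records, "gbr", "training") is records[0]


def test_selection_invariant_to_order():
    rng = np.random.default_rng(0)
    records = [
        _record("svm_r", f"CpG_{i}", 1, float(m))
        for i, m in enumerate(rng.uniform(3, 8, size=20), start=1)
    ]
    baseline = select_best_combination(records, "svm_r", "testing").combination_label
    for seed in range(5):
        shuffled = list(records)
        np.random.default_rng(seed).shuffle(shuffled)
        assert select_best_combination(shuffled, "svm_r", "testing").combination_label == baseline


# ---------------------------------------------------------------------------
# model averaging
# ---------------------------------------------------------------------------

def test_average_two_members(tiny_table):
    m1 = make_linear_model(zp1_combination(), intercept=40.0, coef=[0.0, 0.0])
    m2 = make_linear_model(zp1_combination(), intercept=44.0, coef=[0.0, 0.0])
    np.testing.assert_allclose(average_model_predictions([m1, m2], tiny_table), 42.0)


def test_average_single_member_identity(tiny_table):
    m = make_linear_model(zp1_combination(), intercept=3.0, coef=[0.5, 0.25])
    np.testing.assert_array_equal(
        average_model_predictions([m], tiny_table), predict(m, tiny_table)
    )


def test_average_elementwise_oracle(cohort300):
    rng = np.random.default_rng(5)
    models = [
        make_linear_model(zp1_combination(), intercept=rng.normal(), coef=rng.normal(size=2))
        for _ in range(3)
    ]
    oracle = np.mean([predict(m, cohort300) for m in models], axis=0)
    np.testing.assert_allclose(average_model_predictions(models, cohort300), oracle, atol=1e-12)


def test_average_empty_rejected(tiny_table):
    with pytest.raises(ValidationError):
        average_model_predictions([], tiny_table)


# ---------------------------------------------------------------------------
# replicate schemes
# ---------------------------------------------------------------------------

def test_five_schemes_with_expected_counts():
    assert len(REPLICATE_SCHEMES) == 5
    counts = sorted(s.n_measurements for s in REPLICATE_SCHEMES.values())
    assert counts == [1, 2, 2, 3, 6]
    assert REPLICATE_SCHEMES["S6_3pcr2psq"].choices == (tuple(GRID_CELLS),)
    # symmetric choice counts over the 3x2 grid
    n_choices = {sid: len(s.choices) for sid, s in REPLICATE_SCHEMES.items()}
    assert n_choices == {
        "S1_1pcr1psq": 6, "S2_1pcr2psq": 3, "S2_2pcr1psq": 12,
        "S3_3pcr1psq": 8, "S6_3pcr2psq": 1,
    }


def test_constant_grids_equal_single_replicate(split300):
    training, testing = split300
    model = fit_model(training, ModelSpec("svm_r"), PredictorCombination("cpg7", (5, 6, 7)))
    noiseless = SyntheticConfig(n_samples=1, pcr_sd=0.0, psq_sd=0.0, seed=0)
    sub = testing.subset([True] * 40 + [False] * (testing.n_samples - 40))
    grids = generate_replicate_grids(sub, noiseless)
    metrics = {
        sid: evaluate_replicate_scheme(grids, sub.ages, model, sid)
        for sid in SCHEME_ORDER
    }
    base = metrics["S1_1pcr1psq"]
    for m in metrics.values():
        assert m.mad == pytest.approx(base.mad, abs=1e-9)
        assert m.rmse == pytest.approx(base.rmse, abs=1e-9)


def test_scheme_variance_reduction_in_expectation():
    mads = {sid: [] for sid in ("S1_1pcr1psq", "S6_3pcr2psq")}
    for seed in range(5):
        cfg = SyntheticConfig(n_samples=120, pcr_sd=3.0, psq_sd=2.0, seed=seed)
        cohort = generate_cohort(cfg)
        training, testing = random_split(cohort, 80, seed=seed)
        model = fit_model(
            training, ModelSpec("mqr"),
            PredictorCombination("mqr14", [(5, 1), (6, 1), (7, 1), (6, 2)]),
        )
        grids = generate_replicate_grids(testing, cfg)
        for sid in mads:
            mads[sid].append(
                evaluate_replicate_scheme(grids, testing.ages, model, sid).mad
            )
    assert np.mean(mads["S6_3pcr2psq"]) <= np.mean(mads["S1_1pcr1psq"])


def test_random_assignment_seeded(split300):
    training, testing = split300
    model = fit_model(training, ModelSpec("svm_r"), PredictorCombination("cpg7", (6, 7)))
    cfg = SyntheticConfig(n_samples=1, pcr_sd=2.0, psq_sd=1.0, seed=0)
    sub = testing.subset([True] * 30 + [False] * (testing.n_samples - 30))
    grids = generate_replicate_grids(sub, cfg)
    m1 = evaluate_replicate_scheme(grids, sub.ages, model, "S1_1pcr1psq",
                                   assignment="random", seed=4)
    m2 = evaluate_replicate_scheme(grids, sub.ages, model, "S1_1pcr1psq",
                                   assignment="random", seed=4)
    m3 = evaluate_replicate_scheme(grids, sub.ages, model, "S1_1pcr1psq",
                                   assignment="random", seed=5)
    assert m1 == m2
    assert m1 != m3


def test_average_predictions_flag_matches_for_linear(split300):
    # averaging methylation before prediction == averaging predictions for
    # a linear model; the flag exposes the alternative route
    training, testing = split300
    model = fit_model(
        training, ModelSpec("mqr"), PredictorCombination("mqr14", [(5, 1), (7, 1)])
    )
    cfg = SyntheticConfig(n_samples=1, pcr_sd=2.0, psq_sd=1.0, seed=1)
    sub = testing.subset([True] * 10 + [False] * (testing.n_samples - 10))
    grids = generate_replicate_grids(sub, cfg)
    a = evaluate_replicate_scheme(grids, sub.ages, model, "S2_1pcr2psq")
    b = evaluate_replicate_scheme(grids, sub.ages, model, "S2_1pcr2psq",
                                  average_predictions=True)
    assert a.mad == pytest.approx(b.mad, abs=1e-9)


def test_evaluate_all_schemes_table(split300):
    training, testing = split300
    model = fit_model(training, ModelSpec("svm_r"), PredictorCombination("cpg7", (6, 7)))
    cfg = SyntheticConfig(n_samples=1, pcr_sd=2.0, psq_sd=1.0, seed=2)
    sub = testing.subset([True] * 20 + [False] * (testing.n_samples - 20))
    grids = generate_replicate_grids(sub, cfg)
    table = evaluate_all_schemes(grids, sub.ages, model)
    assert list(table["scheme"]) == list(SCHEME_ORDER)
    assert list(table["n_measurements"]) == [1, 2, 2, 3, 6]


# ---------------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------------

def test_vif_orthogonal_columns():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(200, 3))
    Q, _ = np.linalg.qr(X - X.mean(axis=0))
    vifs, flags = compute_vif(Q)
    np.testing.assert_allclose(vifs, 1.0, atol=1e-9)
    assert not flags.any()


def test_vif_known_correlation():
    # exact empirical correlation 0.9 built by Gram-Schmidt
    rng = np.random.default_rng(1)
    u = rng.normal(size=100)
    u = (u - u.mean()) / np.linalg.norm(u - u.mean())
    w = rng.normal(size=100)
    w = w - w.mean() - (w @ u) * u
    w /= np.linalg.norm(w)
    x2 = 0.9 * u + math.sqrt(1 - 0.81) * w
    vifs, flags = compute_vif(np.column_stack([u, x2]))
    np.testing.assert_allclose(vifs, 1 / (1 - 0.81), rtol=1e-6)
    assert not flags.any()


def test_vif_duplicated_column_infinite():
    rng = np.random.default_rng(2)
    x = rng.normal(size=50)
    vifs, flags = compute_vif(np.column_stack([x, x, rng.normal(size=50)]))
    assert np.isinf(vifs[0]) and np.isinf(vifs[1])
    assert flags[0] and flags[1] and not flags[2]


def test_vif_shape_guards():
    with pytest.raises(ValidationError):
        compute_vif(np.ones((10, 1)))
    with pytest.raises(ValidationError):
        compute_vif(np.ones((3, 4)))
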