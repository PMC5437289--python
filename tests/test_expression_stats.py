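"""ΔΔCt folds, the F-test-gated t-test, Grubbs outliers and the depiction filter."""

import numpy as np
import pandas as pd
import pytest

from tracermet.expression_stats import (
    CtTable,
    FilterThresholds,
    ddct_fold_change,
    differential_filter,
    grubbs_outlier,
    variance_gated_ttest,
    variance_gated_ttest_batch,
)


def make_ct(dct_control, dct_treated, gene="PRODH", ref_ct=18.0):
    rows = []
    for cond, dcts in (("ctrl", dct_control), ("treat", dct_treated)):
        for i, dct in enumerate(dcts):
            sample = f"{cond}{i}"
            rows.append({"sample": sample, "condition": cond, "gene": "RPL19", "ct": ref_ct})
            rows.append({"sample": sample, "condition": cond, "gene": gene, "ct": ref_ct + dct})
    return CtTable(pd.DataFrame(rows))


def test_ddct_identity():
    ct = make_ct([4.0, 4.0], [4.0, 4.0])
    assert ddct_fold_change(ct, "PRODH", "treat", "ctrl") == pytest.approx(1.0)


def test_ddct_two_cycle_advantage_and_reciprocity():
    assert ddct_fold_change(make_ct([5.0], [3.0]), "PRODH", "treat", "ctrl") == pytest.approx(4.0)
    assert ddct_fold_change(make_ct([3.0], [5.0]), "PRODH", "treat", "ctrl") == pytest.approx(0.25)


def test_ddct_invariant_to_global_sample_shift():
    """A per-sample Ct offset hitting target and reference alike cancels."""
    rows = []
    for cond, dct, shift in (("ctrl", 5.0, 0.0), ("treat", 3.0, 2.5)):
        rows.append({"sample": cond, "condition": cond, "gene": "RPL19", "ct": 18.0 + shift})
        rows.append({"sample": cond, "condition": cond, "gene": "PRODH", "ct": 18.0 + dct + shift})
    fold = ddct_fold_change(CtTable(pd.DataFrame(rows)), "PRODH", "treat", "ctrl")
    assert fold == pytest.approx(4.0)


def test_ct_table_requires_reference_and_range():
    bad = pd.DataFrame(
        [{"sample": "s1", "condition": "c", "gene": "PRODH", "ct": 22.0}]
    )
    with pytest.raises(ValueError, match="reference"):
        CtTable(bad)
    out_of_range = pd.DataFrame(
        [{"sample": "s1", "condition": "c", "gene": "RPL19", "ct": 50.0}]
    )
    with pytest.raises(ValueError, match="45"):
        CtTable(out_of_range)


def test_gated_ttest_identical_groups():
    result = variance_gated_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert result.p_value == pytest.approx(1.0)
    assert result.test_used == "student"


def test_gated_ttest_large_shift_is_significant():
    result = variance_gated_ttest([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
    assert result.p_value < 1e-6
    assert result.test_used == "student"


def test_gated_ttest_routes_to_welch_on_unequal_variance():
    rng = np.random.default_rng(3)
    a = rng.normal(0, 1, 8)
    b = rng.normal(0, 10, 8) * 10  # 100× the spread of a
    result = variance_gated_ttest(a, b)
    assert result.f_test_p < 0.05
    assert result.test_used == "welch"


def test_gated_ttest_degenerate_conventions():
    equal = variance_gated_ttest([2.0, 2.0], [2.0, 2.0])
    assert equal.p_value == 1.0 and not equal.degenerate
    unequal = variance_gated_ttest([2.0, 2.0], [3.0, 3.0])
    assert unequal.p_value == 0.0 and unequal.degenerate


def test_gated_ttest_batch_matches_scalar(rng):
    a = rng.normal(0, 1, size=(50, 5))
    b = rng.normal(0.3, 2, size=(50, 4))
    p_batch, welch_batch = variance_gated_ttest_batch(a, b)
    for i in range(50):
        scalar = variance_gated_ttest(a[i], b[i])
        assert p_batch[i] == pytest.approx(scalar.p_value, abs=1e-12)
        assert welch_batch[i] == (scalar.test_used == "welch")


def test_grubbs_flags_planted_outlier():
    assert grubbs_outlier([10, 11, 9, 10, 11, 50]) == 5


def test_grubbs_clean_sample_not_flagged():
    assert grubbs_outlier([10, 11, 9, 10, 11, 12]) is None
    assert grubbs_outlier([1.0, 1.0, 1.0, 1.0]) is None  # zero spread convention


def test_grubbs_needs_three():
    with pytest.raises(ValueError):
        grubbs_outlier([1.0, 2.0])


def make_effect_table(control_vals, treated_vals, metabolite="m1"):
    rows = [
        {"metabolite": metabolite, "condition": cond, "value": v}
        for cond, vals in (("ctrl", control_vals), ("treat", treated_vals))
        for v in vals
    ]
    return pd.DataFrame(rows)


def test_filter_retains_large_significant_change():
    table = make_effect_table([1.0, 1.02, 0.98], [1.30, 1.32, 1.28])
    out = differential_filter(table, "contribution", "ctrl", "treat")
    row = out.iloc[0]
    assert row["change"] == pytest.approx(0.30, abs=1e-9)
    assert row["p_value"] < 0.05
    assert row["retained"] and row["direction"] == 1


def test_filter_rejects_noisy_change():
    table = make_effect_table([1.0, 1.02, 0.98], [0.8, 1.3, 1.8])  # ~30% but noisy
    out = differential_filter(table, "contribution", "ctrl", "treat")
    assert out.iloc[0]["p_value"] > 0.05
    assert not out.iloc[0]["retained"]


def test_filter_rejects_small_change():
    table = make_effect_table([1.0, 1.001, 0.999], [1.10, 1.101, 1.099])
    out = differential_filter(table, "contribution", "ctrl", "treat")
    assert out.iloc[0]["p_value"] < 0.001
    assert not out.iloc[0]["retained"]  # 10% < 25% magnitude gate


def test_filter_level_kind_uses_27_percent_gate():
    table = make_effect_table([1.0, 1.02, 0.98], [1.26, 1.262, 1.258])
    assert not differential_filter(table, "level", "ctrl", "treat").iloc[0]["retained"]
    table2 = make_effect_table([1.0, 1.02, 0.98], [1.30, 1.302, 1.298])
    assert differential_filter(table2, "level", "ctrl", "treat").iloc[0]["retained"]


def test_filter_zero_baseline_skipped():
    table = make_effect_table([0.0, 0.0], [1.0, 1.1])
    out = differential_filter(table, "level", "ctrl", "treat")
    assert len(out) == 0


def test_filter_absolute_change_dialect():
    # contribution 0.10 → 0.40: relative change 300%, absolute 0.30
    table = make_effect_table([0.10, 0.101, 0.099], [0.40, 0.401, 0.399])
    rel = differential_filter(table, "contribution", "ctrl", "treat")
    absd = differential_filter(
        table, "contribution", "ctrl", "treat", change_definition="absolute"
    )
    assert rel.iloc[0]["change"] == pytest.approx(3.0, abs=1e-6)
    assert absd.iloc[0]["change"] == pytest.approx(0.30, abs=1e-6)


def test_bh_column_is_supplementary_only():
    table = pd.concat(
        [
            make_effect_table([1.0, 1.02, 0.98], [1.30, 1.32, 1.28], "hit"),
            make_effect_table([1.0, 1.01, 0.99], [1.0, 1.02, 0.98], "null"),
        ]
    )
    out = differential_filter(table, "contribution", "ctrl", "treat")
    assert "bh_q_supplementary" in out.columns
    # the retained flag agrees with raw p and magnitude gates alone
    thresholds = FilterThresholds()
    expected = (out["change"] > thresholds.contribution_change) & (
        out["p_value"] <= thresholds.alpha
    )
    assert (out["retained"] == expected).all()


def test_thresholds_validation():
    with pytest.raises(ValueError):
        FilterThresholds(alpha=0.0)
    with pytest.raises(ValueError):
        FilterThresholds(contribution_change=1.5)
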