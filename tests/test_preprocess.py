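"""Exclusion rules, serum cell filters, and MRI transforms."""

import numpy as np
import pandas as pd
import pytest

from lcsem.cohort import default_config, generate_cohort
from lcsem.preprocess import (exclude_participants, filter_s100b,
                              transform_mri, average_bilateral)


def _frame(**cols):
    n = max(len(v) for v in cols.values())
    base = {"participant_id": np.arange(1, n + 1)}
    base.update({k: np.asarray(v, dtype=float) for k, v in cols.items()})
    return pd.DataFrame(base)


def test_mmse_below_cutoff_removed_at_either_wave():
    df = _frame(mmse_2=[23, 29, 30], mmse_3=[29, 22, 30],
                dementia_2=[0, 0, 0], dementia_3=[0, 0, 0],
                melanoma_2=[0, 0, 0], melanoma_3=[0, 0, 0])
    out, log = exclude_participants(df)
    assert list(out["participant_id"]) == [3]
    assert log.count("dementia_or_mmse") == 2


def test_melanoma_either_wave_removed_and_counts_match():
    df = _frame(mmse_2=[29] * 4, mmse_3=[29] * 4,
                dementia_2=[0] * 4, dementia_3=[1, 0, 0, 0],
                melanoma_2=[0, 0, 1, 0], melanoma_3=[0, 1, 0, 0])
    out, log = exclude_participants(df)
    assert list(out["participant_id"]) == [4]
    assert log.count("dementia_or_mmse") == 1
    assert log.count("melanoma") == 2
    assert len(df) - log.count() == len(out)


def test_no_flags_passthrough_empty_log():
    df = _frame(mmse_2=[29, 30], mmse_3=[28, 29], dementia_2=[0, 0],
                dementia_3=[0, 0], melanoma_2=[0, 0], melanoma_3=[0, 0])
    out, log = exclude_participants(df)
    pd.testing.assert_frame_equal(out, df)
    assert log.count() == 0


def test_missing_flags_treated_as_not_flagged():
    df = _frame(mmse_2=[np.nan, 29], mmse_3=[29, np.nan],
                dementia_2=[np.nan, np.nan], dementia_3=[0, np.nan],
                melanoma_2=[np.nan, 0], melanoma_3=[0, np.nan])
    out, _ = exclude_participants(df)
    assert len(out) == 2


def test_outlier_rule_exact_cutoff():
    vals = [0.08] * 99 + [0.50]
    df = _frame(s100b_2=vals, s100b_3=[0.09] * 100)
    x = pd.Series(vals)
    cut = x.mean() + 4 * x.std()
    out, log = filter_s100b(df)
    if 0.50 > cut:
        assert np.isnan(out["s100b_2"].iloc[-1])
        assert log.count("outlier_4sd_wave2") == 1
        assert log.rules[0]["values"] == [0.50]
    else:
        assert out["s100b_2"].iloc[-1] == 0.50


def test_outlier_rule_is_one_sided_and_noniterative():
    # extreme LOW value must be retained; mean/SD computed pre-removal
    vals = [0.08] * 98 + [0.0005, 0.60]
    df = _frame(s100b_2=vals, s100b_3=[0.09] * 100)
    out, log = filter_s100b(df)
    assert out["s100b_2"].iloc[-2] == 0.0005
    x = pd.Series(vals)
    assert (0.60 > x.mean() + 4 * x.std()) == np.isnan(out["s100b_2"].iloc[-1])


def test_wave3_floor_rule():
    df = _frame(s100b_2=[0.08] * 5, s100b_3=[0.09, 0.015, 0.09, 0.019, 0.025])
    out, log = filter_s100b(df)
    assert out["s100b_3"].isna().sum() == 2
    assert log.count("assay_floor_wave3") == 2
    # wave-2 values below the floor are untouched (filter is wave-3 only)
    df2 = _frame(s100b_2=[0.08, 0.01, 0.08], s100b_3=[0.09, 0.09, 0.09])
    out2, _ = filter_s100b(df2)
    assert out2["s100b_2"].iloc[1] == 0.01


def test_filter_inlier_table_unchanged():
    df = _frame(s100b_2=np.linspace(0.06, 0.1, 50),
                s100b_3=np.linspace(0.07, 0.11, 50))
    out, log = filter_s100b(df)
    pd.testing.assert_frame_equal(out, df)
    assert log.count() == 0


def test_filter_skipped_with_warning_when_sparse():
    df = _frame(s100b_2=[0.08] + [np.nan] * 4, s100b_3=[np.nan] * 5)
    out, log = filter_s100b(df)
    warned = [r for r in log.rules if r.get("warning")]
    assert warned
    assert out["s100b_2"].iloc[0] == 0.08


def test_filter_row_order_invariance():
    rng = np.random.default_rng(0)
    vals = np.concatenate([rng.normal(0.085, 0.02, 98), [0.9, 0.85]])
    df = _frame(s100b_2=vals, s100b_3=np.full(100, 0.09))
    out1, _ = filter_s100b(df)
    perm = rng.permutation(100)
    out2, _ = filter_s100b(df.iloc[perm].reset_index(drop=True))
    removed1 = set(df["participant_id"][out1["s100b_2"].isna()])
    removed2 = set(df.iloc[perm].reset_index(drop=True)
                   ["participant_id"][out2["s100b_2"].isna()])
    assert removed1 == removed2 != set()


def test_transform_log_and_icv_proportion():
    df = _frame(wmh_2=[1.0], wmh_3=[2.0], tb_2=[991.176], tb_3=[980.0],
                gm_2=[470.0], gm_3=[465.0], icv=[1450.0])
    out = transform_mri(df, icv_correct=False)
    assert out["wmh_2"].iloc[0] == pytest.approx(0.0)
    assert out["tb_2"].iloc[0] == 991.176  # volumes untouched without ICV
    out2 = transform_mri(df, icv_correct=True)
    assert out2["tb_2"].iloc[0] == pytest.approx(991.176 / 1450, abs=1e-5)
    assert out2["wmh_2"].iloc[0] == pytest.approx(np.log(1.0 / 1450))


def test_transform_idempotency_guard_and_errors():
    df = _frame(wmh_2=[1.0], wmh_3=[1.0], tb_2=[990.0], tb_3=[980.0],
                gm_2=[470.0], gm_3=[465.0], icv=[1450.0])
    out = transform_mri(df, icv_correct=False)
    with pytest.raises(ValueError, match="already transformed"):
        transform_mri(out)
    zero = _frame(wmh_2=[0.0], wmh_3=[1.0], tb_2=[990.0], tb_3=[980.0],
                  gm_2=[470.0], gm_3=[465.0], icv=[1450.0])
    assert np.isnan(transform_mri(zero, icv_correct=False)["wmh_2"].iloc[0])
    neg = _frame(wmh_2=[-1.0], wmh_3=[1.0], tb_2=[990.0], tb_3=[980.0],
                 gm_2=[470.0], gm_3=[465.0], icv=[1450.0])
    with pytest.raises(ValueError, match="negative volume"):
        transform_mri(neg, icv_correct=False)


def test_transform_touches_only_volumetrics(small_cohort):
    out = transform_mri(small_cohort, icv_correct=True)
    for c in small_cohort.columns:
        if c.startswith(("fa_", "md_")) or c in ("s100b_2", "s100b_3", "sex"):
            pd.testing.assert_series_equal(out[c], small_cohort[c])


def test_average_bilateral_uses_available_side():
    cfg = default_config(n_participants=5, seed=1)
    df = generate_cohort(cfg)
    df.loc[0, "fa_atr_r_2"] = np.nan
    out = average_bilateral(df)
    assert out["fa_atr_2"].iloc[0] == df["fa_atr_l_2"].iloc[0]
    assert out["fa_atr_2"].iloc[1] == pytest.approx(
        (df["fa_atr_l_2"].iloc[1] + df["fa_atr_r_2"].iloc[1]) / 2)


def test_full_preprocessing_row_accounting():
    cfg = default_config(n_participants=2000, seed=55)
    df = generate_cohort(cfg)
    out, log = exclude_participants(df)
    assert len(out) == len(df) - log.count()
    # every removed id appears exactly once across rules
    removed = [i for r in log.rules for i in r["participant_ids"]]
    assert len(removed) == len(set(removed))
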