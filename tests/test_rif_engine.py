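import numpy as np
import pandas as pd
import pytest

from rifnet.core_io import ValidationError
from rifnet.de_screen import select_de_targets, summarize_targets
from rifnet.rif_engine import (
    coexpression_links,
    condition_correlations,
    export_ma_plot,
    export_rif_scatter,
    rif1,
    rif2,
    score_regulators,
)

from _oracles import naive_rif, pearson_r
from conftest import make_study, random_study


def _summaries_for(study):
    return summarize_targets(study)


def test_self_link_is_exact():
    """A regulator that is its own target: r=1 both sides, DC=0."""
    study = random_study(np.random.default_rng(0), n_genes=5, n_s=4, n_c=4)
    g = study.gene_ids[0]
    corr = condition_correlations(study, [g], [g])
    assert corr["r_S"][0, 0] == 1.0 and corr["r_C"][0, 0] == 1.0
    links = coexpression_links(study, [g], pd.DataFrame({"gene_id": [g]}))
    assert links.dc.iloc[0] == 0.0


def test_perfect_anticorrelation_extremes():
    """Regulator = target in S, = -target in C: r_S=1, r_C=-1, DC=2."""
    tgt_s = np.array([1.0, 2.0, 3.0, 4.0])
    tgt_c = np.array([2.0, 4.0, 1.0, 3.0])
    vals = np.vstack(
        [
            np.concatenate([tgt_s, -tgt_c]),
            np.concatenate([tgt_s, tgt_c]),
        ]
    )
    study = make_study(vals, gene_ids=["reg", "tgt"], n_s=4)
    corr = condition_correlations(study, ["reg"], ["tgt"])
    assert corr["r_S"][0, 0] == pytest.approx(1.0)
    assert corr["r_C"][0, 0] == pytest.approx(-1.0)
    dc = corr["r_S"][0, 0] - corr["r_C"][0, 0]
    assert dc == pytest.approx(2.0)


def test_correlations_match_scalar_oracle(rng):
    """All pairwise per-condition correlations equal the covariance-formula oracle."""
    study = random_study(rng, n_genes=20, n_s=10, n_c=10)
    regs = study.gene_ids[:8]
    tgts = study.gene_ids[8:]
    corr = condition_correlations(study, regs, tgts)
    for i, r in enumerate(regs):
        for j, t in enumerate(tgts):
            for role, key in (("S", "r_S"), ("C", "r_C")):
                cols = study.samples(role)
                expected = pearson_r(
                    study.values.loc[r, cols].tolist(), study.values.loc[t, cols].tolist()
                )
                assert corr[key][i, j] == pytest.approx(expected, abs=1e-12)


def test_zero_variance_regulator_flagged_not_dropped():
    vals = np.array([[3.0] * 8, [1, 2, 3, 4, 5, 6, 7, 8], [2, 1, 4, 3, 6, 5, 8, 7]])
    study = make_study(vals, gene_ids=["flat", "a", "b"], n_s=4)
    corr = condition_correlations(study, ["flat", "a"], ["b"])
    assert corr["r_S"][0, 0] == 0.0 and corr["r_C"][0, 0] == 0.0
    assert corr["flagged"][0, 0] and not corr["flagged"][1, 0]


def test_rif_hand_examples():
    """Single-target hand evaluations: RIF1 = x*d*DC^2, RIF2 = (xS rS)^2-(xC rC)^2."""
    de = pd.DataFrame({"gene_id": ["t"], "x_j": [2.0], "x_jS": [2.0], "x_jC": [1.0], "d_j": [1.0]})
    links = pd.DataFrame(
        {"regulator_id": ["r"], "target_id": ["t"], "r_S": [1.0], "r_C": [1.0], "dc": [1.0]}
    )
    assert rif1(de, links) == pytest.approx(2.0)
    assert rif2(de, links) == pytest.approx(3.0)  # (2*1)^2 - (1*1)^2
    # all-zero differential co-expression forces RIF1 = 0
    links0 = links.assign(dc=0.0)
    assert rif1(de, links0) == 0.0
    # symmetric case forces RIF2 = 0
    de_sym = de.assign(x_jC=2.0)
    assert rif2(de_sym, links) == 0.0


def test_rif_missing_link_is_contract_violation():
    de = pd.DataFrame({"gene_id": ["t", "u"], "x_j": 1.0, "x_jS": 1.0, "x_jC": 1.0, "d_j": 0.0})
    links = pd.DataFrame(
        {"regulator_id": ["r"], "target_id": ["t"], "r_S": [0.5], "r_C": [0.5], "dc": [0.0]}
    )
    with pytest.raises(ValidationError, match="missing link"):
        rif1(de, links)


def test_scores_match_naive_loop_oracle(rng):
    """Vectorized RIF1/RIF2 equal the term-by-term loop oracle to 1e-12."""
    study = random_study(rng, n_genes=30, n_s=8, n_c=8)
    summaries = _summaries_for(study)
    de = summaries.iloc[:10]  # any target set works for the identity
    regs = study.gene_ids
    scores = score_regulators(study, regs, de)
    for reg in regs[:6] + [de.gene_id.iloc[0]]:
        o1, o2 = naive_rif(study, reg, de.to_dict("records"))
        row = scores.loc[scores.regulator_id == reg].iloc[0]
        assert row.rif1_raw == pytest.approx(o1, abs=1e-12)
        assert row.rif2_raw == pytest.approx(o2, abs=1e-12)


def test_standardized_scores_mean0_sd1(rng):
    study = random_study(rng, n_genes=40, n_s=6, n_c=6)
    summaries = _summaries_for(study)
    scores = score_regulators(study, study.gene_ids, summaries.iloc[:15])
    for col in ("rif1_z", "rif2_z"):
        assert scores[col].mean() == pytest.approx(0.0, abs=1e-10)
        assert scores[col].std(ddof=1) == pytest.approx(1.0, abs=1e-10)
    np.testing.assert_allclose(
        scores.combined, np.abs(scores.rif1_z) + np.abs(scores.rif2_z), atol=1e-12
    )
    assert sorted(scores["rank"]) == list(range(1, len(scores) + 1))


def test_condition_swap_invariance(rng):
    """Swapping S and C negates both raw RIFs; combined scores and ranks persist."""
    study = random_study(rng, n_genes=30, n_s=7, n_c=7)
    summaries = _summaries_for(study)
    de = summaries.iloc[:12]
    swapped = study.swap_conditions()
    de_swapped = summarize_targets(swapped).iloc[:12]
    scores = score_regulators(study, study.gene_ids, de)
    scores_sw = score_regulators(swapped, study.gene_ids, de_swapped)
    merged = scores.merge(scores_sw, on="regulator_id", suffixes=("", "_sw"))
    np.testing.assert_allclose(merged.rif1_raw_sw, -merged.rif1_raw, atol=1e-10)
    np.testing.assert_allclose(merged.rif2_raw_sw, -merged.rif2_raw, atol=1e-10)
    np.testing.assert_allclose(merged.combined_sw, merged.combined, atol=1e-10)
    assert (merged["rank_sw"] == merged["rank"]).all()


def test_regulator_scale_invariance(rng):
    """Rescaling a regulator's expression by a positive constant changes nothing."""
    study = random_study(rng, n_genes=20, n_s=6, n_c=6)
    summaries = _summaries_for(study)
    de = summaries.iloc[5:15]
    reg = study.gene_ids[0]
    scores = score_regulators(study, study.gene_ids[:5], de)
    study.values.loc[reg] *= 7.3
    scores2 = score_regulators(study, study.gene_ids[:5], de)
    row = scores.loc[scores.regulator_id == reg].iloc[0]
    row2 = scores2.loc[scores2.regulator_id == reg].iloc[0]
    assert row2.rif1_raw == pytest.approx(row.rif1_raw, rel=1e-10)
    assert row2.rif2_raw == pytest.approx(row.rif2_raw, rel=1e-10)


def test_null_regulator_raw_scores_vanish():
    """A regulator with DC = 0 to every target (flat profile: r = 0 both sides)
    has rif1_raw = rif2_raw = 0 exactly."""
    rng = np.random.default_rng(3)
    n = 12
    base = rng.normal(8, 1, size=(6, n))
    null_row = np.full(n, 8.0)
    vals = np.vstack([null_row, base])
    study = make_study(vals, n_s=n // 2)
    summaries = summarize_targets(study)
    de = summaries.iloc[1:]
    scores = score_regulators(study, study.gene_ids[:4], de)
    row = scores.loc[scores.regulator_id == study.gene_ids[0]].iloc[0]
    assert row.rif1_raw == 0.0 and row.rif2_raw == 0.0


def test_too_few_regulators_error(rng):
    study = random_study(rng, n_genes=5, n_s=4, n_c=4)
    with pytest.raises(ValidationError, match=">= 2 regulators"):
        score_regulators(study, [study.gene_ids[0]], _summaries_for(study).iloc[:2])


def test_exports_are_pure_projections(rng):
    study = random_study(rng, n_genes=10, n_s=4, n_c=4)
    summaries = _summaries_for(study)
    summaries["is_DE"] = summaries.p_value < 0.5
    scores = score_regulators(study, study.gene_ids, summaries.iloc[:4])
    scatter = export_rif_scatter(scores)
    assert len(scatter) == len(scores)
    np.testing.assert_array_equal(scatter.rif1_z, scores.rif1_z)
    ma = export_ma_plot(summaries)
    assert list(ma.columns) == ["gene_id", "x_j", "d_j", "is_DE"]
    np.testing.assert_array_equal(ma.x_j, summaries.x_j)
    empty = export_rif_scatter(pd.DataFrame(columns=scores.columns))
    assert empty.empty and list(empty.columns) == ["rif1_z", "rif2_z", "label"]


def test_spearman_option_runs(rng):
    study = random_study(rng, n_genes=10, n_s=5, n_c=5)
    summaries = _summaries_for(study)
    s1 = score_regulators(study, study.gene_ids, summaries.iloc[:5], method="spearman")
    assert len(s1) == 10
    # monotone transformation of a regulator leaves Spearman scores unchanged
    reg = study.gene_ids[0]
    study.values.loc[reg] = np.exp(study.values.loc[reg] / 4.0)
    s2 = score_regulators(study, study.gene_ids, summaries.iloc[:5], method="spearman")
    a = s1.loc[s1.regulator_id == reg].iloc[0]
    b = s2.loc[s2.regulator_id == reg].iloc[0]
    assert b.rif1_raw == pytest.approx(a.rif1_raw, rel=1e-10)
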