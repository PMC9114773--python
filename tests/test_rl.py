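"""Prior loading, score arithmetic, the all-samples consistency filter,
and ground-truth recovery of the end-to-end communication pipeline."""

import numpy as np
import pandas as pd
import pytest

from tmekit.rl import (
    GROUP_AGGREGATE,
    FilterConfig,
    flag_significant,
    load_interaction_prior,
    run_rl_pipeline,
    score_interactions,
)
from tmekit.simulate import simulate_counts
from tmekit.study import STUDY_QC, rl_precision_recall, standard_study_config


def write_prior(tmp_path, rows):
    path = tmp_path / "prior.tsv"
    pd.DataFrame(rows, columns=["ligand", "receptor", "directed", "mode"]).to_csv(
        path, sep="\t", index=False
    )
    return path


class TestPriorLoading:
    def test_subsets_to_directed_known_mode(self, tmp_path):
        rows = [("l1", "r1", 1, "stimulation"), ("l2", "r2", 1, "inhibition"),
                ("l3", "r3", 0, "stimulation"), ("l4", "r4", 1, ""),
                ("l5", "r5", 1, "stimulation")]
        prior = load_interaction_prior(write_prior(tmp_path, rows))
        assert set(prior["ligand"]) == {"l1", "l2", "l5"}

    def test_duplicates_collapsed(self, tmp_path):
        rows = [("l1", "r1", 1, "stimulation"), ("l1", "r1", 1, "stimulation")]
        prior = load_interaction_prior(write_prior(tmp_path, rows))
        assert len(prior) == 1

    def test_missing_columns_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"ligand": ["a"], "receptor": ["b"]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="directed"):
            load_interaction_prior(path)

    def test_empty_result_warns(self, tmp_path):
        with pytest.warns(UserWarning, match="empty"):
            load_interaction_prior(write_prior(tmp_path, [("l", "r", 0, "")]))


def de_table(entries):
    """Build a DE table from (gene, cell_type, sample, log2fc, p_adj) tuples."""
    rows = [
        {"gene": g, "cell_type": ct, "sample_id": s, "group_id": "G",
         "log2fc": fc, "pct_fg": 0.5, "pct_bg": 0.4, "lrt_stat": 1.0,
         "df": 2, "p": p, "p_adj": p, "status": "ok"}
        for (g, ct, s, fc, p) in entries
    ]
    return pd.DataFrame(rows)


def simple_prior():
    return pd.DataFrame(
        [{"ligand": "L", "receptor": "R", "directed": 1, "mode": "stimulation"}]
    )


class TestScoring:
    def test_score_is_sum_of_log2fcs(self):
        de = de_table([("L", "CAF", "s1", 0.7, 0.001), ("R", "Tumor", "s1", 0.3, 0.001)])
        rec = score_interactions(de, simple_prior(), "CAF", "Tumor", "G", ["s1"])
        per_sample = rec[rec.sample_id == "s1"]
        assert per_sample["rl_score"].iloc[0] == pytest.approx(1.0)

    def test_linear_fc_formula(self):
        # ligand and receptor both linear FC 2 -> log2(4) = 2; FC 1 -> 0
        de = de_table([("L", "CAF", "s1", 1.0, 0.001), ("R", "Tumor", "s1", 1.0, 0.001)])
        rec = score_interactions(de, simple_prior(), "CAF", "Tumor", "G", ["s1"])
        assert rec[rec.sample_id == "s1"]["rl_score"].iloc[0] == pytest.approx(2.0)
        de0 = de_table([("L", "CAF", "s1", 0.0, 0.5), ("R", "Tumor", "s1", 0.0, 0.5)])
        rec0 = score_interactions(de0, simple_prior(), "CAF", "Tumor", "G", ["s1"])
        assert rec0[rec0.sample_id == "s1"]["rl_score"].iloc[0] == pytest.approx(0.0)

    def test_group_aggregate_is_mean(self):
        de = de_table(
            [("L", "CAF", "s1", 1.0, 0.001), ("R", "Tumor", "s1", 1.0, 0.001),
             ("L", "CAF", "s2", 2.0, 0.001), ("R", "Tumor", "s2", 2.0, 0.001)]
        )
        rec = score_interactions(de, simple_prior(), "CAF", "Tumor", "G", ["s1", "s2"])
        agg = rec[rec.sample_id == GROUP_AGGREGATE]
        assert agg["rl_score"].iloc[0] == pytest.approx(3.0)

    def test_absent_gene_skipped(self):
        de = de_table([("L", "CAF", "s1", 1.0, 0.001)])  # receptor missing
        rec = score_interactions(de, simple_prior(), "CAF", "Tumor", "G", ["s1"])
        assert rec.empty


def records_three_samples(lig_fcs=(1.0, 1.0, 1.0), rec_fcs=(1.0, 1.0, 1.0),
                          lig_ps=(0.001,) * 3, rec_ps=(0.001,) * 3):
    entries = []
    for s, lf, rf, lp, rp in zip(["s1", "s2", "s3"], lig_fcs, rec_fcs, lig_ps, rec_ps):
        entries += [("L", "CAF", s, lf, lp), ("R", "Tumor", s, rf, rp)]
    de = de_table(entries)
    return score_interactions(de, simple_prior(), "CAF", "Tumor", "G", ["s1", "s2", "s3"])


class TestConsistencyFilter:
    def test_all_samples_pass_flags_significant(self):
        out = flag_significant(records_three_samples())
        assert out["significant"].all()

    def test_ligand_below_half_log2fc_in_one_sample_blocks(self):
        out = flag_significant(records_three_samples(lig_fcs=(1.0, 0.49, 1.0)))
        assert not out["significant"].any()

    def test_receptor_cutoff_is_exclusive_zero(self):
        out = flag_significant(records_three_samples(rec_fcs=(1.0, 0.0, 1.0)))
        assert not out["significant"].any()

    def test_padj_threshold_strict(self):
        out = flag_significant(records_three_samples(rec_ps=(0.001, 0.01, 0.001)))
        assert not out["significant"].any()

    def test_missing_sample_record_blocks(self):
        rec = records_three_samples()
        rec = rec[rec.sample_id != "s2"]
        out = flag_significant(rec, samples=["s1", "s2", "s3"])
        assert not out["significant"].any()

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(0)
        rec = records_three_samples(
            lig_fcs=rng.uniform(0, 1.5, 3), rec_fcs=rng.uniform(-0.5, 1, 3),
            lig_ps=rng.uniform(0, 0.05, 3), rec_ps=rng.uniform(0, 0.05, 3),
        )
        strict = flag_significant(rec, FilterConfig(0.01, 0.5, 0.0))
        relaxed = flag_significant(rec, FilterConfig(0.2, 0.0, -1.0))
        assert (relaxed["significant"] | ~strict["significant"]).all()


@pytest.fixture(scope="module")
def pipeline_run(study_data):
    config, gt, counts, prior = study_data
    results = run_rl_pipeline(
        counts, prior, "CAF2", ["Tumor"], "AOMDSS", qc=STUDY_QC
    )
    return gt, results


class TestPipeline:
    def test_precision_and_recall(self, pipeline_run):
        gt, results = pipeline_run
        precision, recall = rl_precision_recall(results["Tumor"], gt)
        assert precision >= 0.9
        assert recall >= 0.9

    def test_additivity_identity_every_record(self, pipeline_run):
        _, results = pipeline_run
        rec = results["Tumor"]
        per_sample = rec[rec.sample_id != GROUP_AGGREGATE]
        np.testing.assert_allclose(
            per_sample["rl_score"],
            per_sample["ligand_log2fc"] + per_sample["receptor_log2fc"],
        )

    def test_one_sample_without_effect_unsets_flag(self):
        config, gt = standard_study_config(seed=21, cells_per_type_per_sample=250)
        # drop the planting of ligand g0000 in sample s3 only
        config.planted_effects = [
            (g, ct, "all" if g != "g0000" else s, fc)
            for (g, ct, s, fc) in config.planted_effects
            for s in (["s1", "s2"] if g == "g0000" else ["all"])
        ]
        counts, gt_counts = simulate_counts(config)
        gt.planted_log2fc = gt_counts.planted_log2fc
        from tmekit.simulate import simulate_interaction_prior

        prior = simulate_interaction_prior(config, gt, n_decoys=5, seed=22)
        results = run_rl_pipeline(counts, prior, "CAF2", ["Tumor"], "AOMDSS", qc=STUDY_QC)
        rec = results["Tumor"]
        affected = rec[(rec.ligand == "g0000") & (rec.sample_id == GROUP_AGGREGATE)]
        intact = rec[(rec.ligand == "g0001") & (rec.sample_id == GROUP_AGGREGATE)]
        assert not affected["significant"].any()
        assert intact["significant"].all()

    def test_label_permutation_destroys_flags(self):
        hits = 0
        for seed in range(5):
            config, gt = standard_study_config(seed=30 + seed, cells_per_type_per_sample=150)
            counts, gt_counts = simulate_counts(config)
            gt.planted_log2fc = gt_counts.planted_log2fc
            from tmekit.simulate import simulate_interaction_prior

            prior = simulate_interaction_prior(config, gt, n_decoys=5, seed=40 + seed)
            rng = np.random.default_rng(50 + seed)
            obs = counts.obs.copy()
            for s in obs["sample_id"].unique():
                idx = obs.index[obs["sample_id"] == s]
                obs.loc[idx, "cell_type"] = rng.permutation(obs.loc[idx, "cell_type"].to_numpy())
            counts.obs = obs
            results = run_rl_pipeline(counts, prior, "CAF2", ["Tumor"], "AOMDSS", qc=STUDY_QC)
            if not results["Tumor"]["significant"].any():
                hits += 1
        assert hits >= 5 * 0.95 - 1e-9  # all five shuffled runs lose every flag

    def test_empty_prior_empty_report(self, study_data):
        _, _, counts, _ = study_data
        empty = pd.DataFrame(columns=["ligand", "receptor", "directed", "mode"])
        with pytest.warns(UserWarning, match="empty"):
            results = run_rl_pipeline(counts, empty, "CAF2", ["Tumor"], "AOMDSS", qc=STUDY_QC)
        assert results == {}
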