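"""Synthetic screen generator: determinism, truth recovery, noise effects."""

import numpy as np
import pandas as pd
import pytest

import sirnascreen as ss


def _pipeline(run, cfg=None):
    cfg = cfg or ss.ScreenConfig()
    norm = ss.normalize_run(run.measurements, run.layouts, run.annotation, cfg)
    scores = ss.build_oligo_scores(norm, "normal", "tumor")
    stats = ss.fit_d_distribution(scores["d"])
    return ss.call_phenotypes(scores, stats, config=cfg)


class TestGeneration:
    def test_deterministic_under_seed(self):
        cfg = ss.SimConfig(n_plates=3, n_oligos=200, n_genes=70, seed=11)
        a = ss.simulate_screen(cfg)
        b = ss.simulate_screen(cfg)
        pd.testing.assert_frame_equal(a.measurements, b.measurements)
        pd.testing.assert_frame_equal(a.truth.oligos, b.truth.oligos)

    def test_seed_changes_noise_not_marginals(self):
        cfg = ss.SimConfig(n_plates=3, n_oligos=200, n_genes=70)
        a = ss.simulate_screen(cfg, seed=1)
        b = ss.simulate_screen(cfg, seed=2)
        assert not a.measurements["FI"].equals(b.measurements["FI"])
        va = a.truth.genes["gene_class"].value_counts().to_dict()
        vb = b.truth.genes["gene_class"].value_counts().to_dict()
        assert va == vb

    def test_record_and_library_counts(self):
        cfg = ss.SimConfig(n_plates=4, n_oligos=300, n_genes=110, seed=0)
        run = ss.simulate_screen(cfg)
        assert len(run.measurements) == 4 * 96 * 2 * 2
        assert run.annotation["oligo_id"].nunique() == 300
        per_gene = run.truth.oligos.groupby("gene_symbol").size()
        assert per_gene.between(1, 4).all()
        assert per_gene.sum() == 300

    def test_unrepresentable_library_rejected(self):
        with pytest.raises(ss.SimulationError, match="do not fit"):
            ss.simulate_screen(ss.SimConfig(n_plates=1, n_oligos=100, n_genes=40))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ss.SimulationError):
            ss.SimConfig(frac_tumor_selective=0.8, frac_lethal=0.5)

    def test_effects_within_bounds(self):
        run = ss.simulate_screen(ss.SimConfig(n_plates=3, n_oligos=200,
                                              n_genes=70, seed=5))
        t = run.truth.oligos
        assert t["effect_normal"].between(0, 150).all()
        assert t["effect_tumor"].between(0, 150).all()


class TestZeroNoise:
    def test_normalization_reproduces_planted_effects(self, zero_noise_sim):
        """With the noise off, the %NT read out of the pipeline equals the
        planted per-line expected %NT for every oligo."""
        run = zero_noise_sim["run"]
        scores = zero_noise_sim["scores"].set_index("oligo_id")
        truth = run.truth.oligos.set_index("oligo_id")
        np.testing.assert_allclose(
            scores["pct_nt_normal"], truth.loc[scores.index, "effect_normal"],
            atol=1e-9,
        )
        np.testing.assert_allclose(
            scores["pct_nt_tumor"], truth.loc[scores.index, "effect_tumor"],
            atol=1e-9,
        )

    def test_nt_wells_read_100_in_both_lines(self, zero_noise_sim):
        per_well = ss.normalize_measurements(
            zero_noise_sim["run"].measurements, zero_noise_sim["run"].layouts
        )
        nt = per_well[per_well["role"] == "control_nt"]
        np.testing.assert_allclose(nt["pct_nt"], 100.0, atol=1e-9)

    def test_calls_match_truth_exactly(self, zero_noise_sim):
        """No stochastic misses: every effective oligo whose planted effect
        clears the thresholds is called as its class."""
        calls = zero_noise_sim["calls"]
        truth = zero_noise_sim["run"].truth
        expected = truth.expected_calls().set_index("oligo_id")["call"]
        got = calls.set_index("oligo_id")["call"]
        assert (got.loc[expected.index] == expected).all()


class TestConfirmationRuns:
    def test_subset_measurement_size(self, small_sim):
        truth = small_sim["run"].truth
        subset = truth.oligos["oligo_id"].iloc[:84].tolist()
        conf = ss.simulate_confirmation(truth, subset, small_sim["sim_cfg"], seed=3)
        lib = conf.measurements.merge(
            ss.screen_model.layouts_to_frame(conf.layouts),
            on=["plate_id", "row", "column"],
        )
        oligos = lib.loc[lib["role"] == "library", "oligo_id"].nunique()
        assert oligos == 84
        # 3 replicates per line by default in confirmation runs
        assert sorted(conf.measurements["replicate"].unique()) == [1, 2, 3]

    def test_deterministic_under_seed(self, small_sim):
        truth = small_sim["run"].truth
        subset = truth.oligos["oligo_id"].iloc[:10].tolist()
        a = ss.simulate_confirmation(truth, subset, small_sim["sim_cfg"], seed=9)
        b = ss.simulate_confirmation(truth, subset, small_sim["sim_cfg"], seed=9)
        pd.testing.assert_frame_equal(a.measurements, b.measurements)

    def test_empty_subset_rejected(self, small_sim):
        with pytest.raises(ss.SimulationError, match="empty"):
            ss.simulate_confirmation(small_sim["run"].truth, [],
                                     small_sim["sim_cfg"])

    def test_unknown_oligo_rejected(self, small_sim):
        with pytest.raises(ss.SimulationError, match="not in the library"):
            ss.simulate_confirmation(small_sim["run"].truth, ["nope"],
                                     small_sim["sim_cfg"])


class TestRecoveryMetrics:
    def test_perfect_caller(self, zero_noise_sim):
        truth = zero_noise_sim["run"].truth
        metrics = ss.evaluate_recovery(truth.expected_calls(), truth)
        assert (metrics["sensitivity"] == 1.0).all()
        assert (metrics["specificity"] == 1.0).all()

    def test_all_inactive_caller(self, zero_noise_sim):
        truth = zero_noise_sim["run"].truth
        calls = truth.expected_calls().assign(call="inactive")
        metrics = ss.evaluate_recovery(calls, truth).set_index(
            ["level", "gene_class"]
        )
        row = metrics.loc[("oligo", "tumor_selective")]
        assert row["sensitivity"] == 0.0
        assert row["specificity"] == 1.0

    def test_mismatched_sets_rejected(self, zero_noise_sim):
        truth = zero_noise_sim["run"].truth
        calls = truth.expected_calls().iloc[:-1]
        with pytest.raises(ss.SimulationError, match="different oligo sets"):
            ss.evaluate_recovery(calls, truth)


class TestNoiseDegradesRecovery:
    def test_differential_sensitivity_falls_with_cv(self):
        """Averaged over 10 seeds, more FI noise can only blunt recovery
        of tumor-selective oligos."""
        def mean_sens(cv):
            vals = []
            for seed in range(10):
                cfg = ss.SimConfig(n_plates=10, n_oligos=800, n_genes=280,
                                   noise_cv=cv, seed=seed)
                run = ss.simulate_screen(cfg)
                calls = _pipeline(run)
                m = ss.evaluate_recovery(calls[["oligo_id", "call"]], run.truth)
                row = m[(m["level"] == "oligo")
                        & (m["gene_class"] == "tumor_selective")]
                vals.append(float(row["sensitivity"].iloc[0]))
            return np.mean(vals)

        s_low, s_mid, s_high = mean_sens(0.1), mean_sens(0.35), mean_sens(0.6)
        assert s_low >= s_mid >= s_high
        assert s_low > s_high
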