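"""Simulator: library construction, selection dynamics, measurement."""

import numpy as np
import pandas as pd
import pytest

from hypoxiascreen import (
    ConfigError,
    HitBlock,
    PopulationState,
    ShRNALibrary,
    SimConfig,
    build_library,
    closed_form_ratio,
    run_screen,
    simulate_growth_assay,
    simulate_qpcr,
    simulate_screen,
    step_passage,
)
from hypoxiascreen.screen_sim import HYPOXIA, NORMOXIA


def make_library(specs):
    """specs: list of (gene_id, efficacy, s_normoxia, s_hypoxia) per probe."""
    probes = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(len(specs))],
            "gene_id": [s[0] for s in specs],
            "efficacy": [s[1] for s in specs],
        }
    )
    truth = (
        pd.DataFrame(
            {
                "gene_id": [s[0] for s in specs],
                "expressed": 1,
                "s_normoxia": [s[2] for s in specs],
                "s_hypoxia": [s[3] for s in specs],
            }
        )
        .drop_duplicates("gene_id")
        .reset_index(drop=True)
    )
    return ShRNALibrary(probes), truth


class TestBuildLibrary:
    def test_scale_and_coverage(self, rng):
        cfg = SimConfig(n_genes=1000, probes_per_gene_mean=4.0)
        lib, truth = build_library(cfg, rng)
        assert 3600 < lib.n_probes < 4400  # ~4 probes/gene
        per_gene = lib.probes.groupby("gene_id").size()
        assert len(per_gene) == 1000  # no orphan genes
        assert per_gene.min() >= 1
        assert lib.probes["efficacy"].between(0.7, 1.0).all()

    def test_expression_flags_and_neutral_silent_genes(self, rng):
        cfg = SimConfig(n_genes=1000, fraction_expressed=0.8)
        _, truth = build_library(cfg, rng)
        n_silent = (truth["expressed"] == 0).sum()
        assert 150 < n_silent < 250  # ~200 of 1000
        silent = truth[truth["expressed"] == 0]
        assert (silent["s_normoxia"] == 0).all()
        assert (silent["s_hypoxia"] == 0).all()

    def test_empty_hit_spec_is_all_neutral(self, rng):
        _, truth = build_library(SimConfig(n_genes=200, hit_spec=()), rng)
        assert (truth[["s_normoxia", "s_hypoxia"]] == 0).all().all()

    def test_hits_only_in_expressed_well_covered_genes(self, rng):
        cfg = SimConfig(
            n_genes=500, hit_spec=(HitBlock(n_genes=15, s_hypoxia=-0.5),)
        )
        lib, truth = build_library(cfg, rng)
        hits = truth[truth["s_hypoxia"] != 0]
        assert len(hits) == 15
        assert (hits["expressed"] == 1).all()
        per_gene = lib.probes.groupby("gene_id").size()
        assert per_gene[hits["gene_id"]].min() >= cfg.min_shrnas

    def test_oversized_hit_spec_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(
                n_genes=100,
                fraction_expressed=0.1,
                hit_spec=(HitBlock(n_genes=50, s_hypoxia=-0.5),),
            )


class TestStepPassage:
    def test_deterministic_limit_preserves_neutral_frequencies(self, rng):
        lib, truth = make_library([("g0", 1.0, 0, 0), ("g1", 1.0, 0, 0)])
        cfg = SimConfig(n_genes=2, bottleneck=None)
        state = PopulationState(NORMOXIA, 0, np.array([100.0, 300.0]))
        out = step_passage(state, lib, truth, cfg, rng)
        np.testing.assert_allclose(out.frequencies(), [0.25, 0.75])
        assert out.passage_index == 1

    def test_neutral_frequency_is_martingale_under_bottleneck(self):
        # mean frequency over many resampled passages stays at the start value
        lib, truth = make_library([("g0", 1.0, 0, 0), ("g1", 1.0, 0, 0)])
        cfg = SimConfig(n_genes=2, bottleneck=2000)
        freqs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            state = PopulationState(NORMOXIA, 0, np.array([500.0, 1500.0]))
            freqs.append(step_passage(state, lib, truth, cfg, rng).frequencies()[0])
        se = np.std(freqs, ddof=1) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - 0.25) < 3 * se

    def test_lethal_knockdown_changes_relative_abundance_eightfold(self, rng):
        # s=-1, efficacy=1, d=3: clone A stalls while B doubles 3x -> 1/8 per passage
        lib, truth = make_library([("A", 1.0, -1.0, -1.0), ("B", 1.0, 0, 0)])
        cfg = SimConfig(n_genes=2, bottleneck=None, doublings_per_passage=3.0)
        state = PopulationState(NORMOXIA, 0, np.array([1.0, 1.0]))
        out = step_passage(state, lib, truth, cfg, rng)
        assert out.counts[0] / out.counts[1] == pytest.approx(1 / 8)

    def test_frequency_conservation_across_passages(self, rng):
        lib, truth = make_library(
            [("A", 0.9, 0, -0.5), ("B", 0.8, 0, 0), ("C", 1.0, -0.3, 0)]
        )
        cfg = SimConfig(n_genes=3, bottleneck=10_000)
        state = PopulationState(HYPOXIA, 0, np.full(3, 1000.0))
        for _ in range(5):
            state = step_passage(state, lib, truth, cfg, rng)
            assert state.frequencies().sum() == pytest.approx(1.0)


class TestSimulateScreen:
    def test_same_seed_identical_tables(self, demo_cfg):
        a1, _, t1 = simulate_screen(demo_cfg)
        a2, _, t2 = simulate_screen(demo_cfg)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_neutral_probes_stay_inside_fold_threshold(self):
        # large bottleneck + no measurement noise: drift alone never
        # pushes a neutral probe past 5-fold
        cfg = SimConfig(
            n_genes=1000, measurement_cv=0.0, bottleneck=4_000_000, seed=5
        )
        abundance, _, _ = simulate_screen(cfg)
        ratio = abundance["signal_hypoxia"] / abundance["signal_normoxia"]
        assert ratio.between(1 / 5, 5).all()

    def test_planted_dropout_matches_closed_form_direction(self):
        cfg = SimConfig(
            n_genes=50,
            hit_spec=(HitBlock(n_genes=2, s_hypoxia=-0.5),),
            measurement_cv=0.0,
            bottleneck=None,
            seed=3,
        )
        abundance, lib, truth = simulate_screen(cfg)
        hits = set(truth.loc[truth["s_hypoxia"] != 0, "gene_id"])
        merged = abundance.merge(lib.probes[["probe_id", "efficacy"]], on="probe_id")
        sub = merged[merged["gene_id"].isin(hits)]
        ratio = sub["signal_hypoxia"] / sub["signal_normoxia"]
        # every hit probe below 2^(-0.7*0.5*3*10) = 2^-10.5 times the
        # compositional factor; certainly below the 1/5 call threshold
        assert (ratio < 1 / 5).all()

    def test_effect_size_monotonicity_noise_free(self):
        ratios = []
        for s in (-0.1, -0.3, -0.6, -0.9):
            lib, truth = make_library([("A", 1.0, 0.0, s), ("B", 1.0, 0, 0)])
            cfg = SimConfig(n_genes=2, measurement_cv=0.0, bottleneck=None)
            ab = run_screen(lib, truth, cfg, np.random.default_rng(0))
            r = ab["signal_hypoxia"] / ab["signal_normoxia"]
            ratios.append(r.iloc[0])
        assert all(a > b for a, b in zip(ratios, ratios[1:]))

    def test_mean_null_log_ratio_centred_on_zero(self):
        # neutrality: over 100 seeded mini-screens the per-probe mean
        # log-ratio is within 3 standard errors of 0
        logs = []
        for seed in range(100):
            cfg = SimConfig(
                n_genes=20, probes_per_gene_mean=2.0, bottleneck=50_000,
                measurement_cv=0.1, seed=seed,
            )
            ab, _, _ = simulate_screen(cfg)
            logs.append(np.log(ab["signal_hypoxia"] / ab["signal_normoxia"]).mean())
        se = np.std(logs, ddof=1) / np.sqrt(len(logs))
        assert abs(np.mean(logs)) < 3 * se


class TestGrowthAssaySim:
    def test_noise_free_neutral_gene_equals_control(self, noise_free_growth, rng):
        df = simulate_growth_assay("X", 0.0, 0.0, (1.0, 0.8), noise_free_growth, rng)
        assert df["cell_count"].nunique() == 1  # all cells of the design identical

    def test_noise_free_hypoxia_effect_closed_form(self, noise_free_growth, rng):
        df = simulate_growth_assay("X", 0.0, -0.2, (1.0, 1.0), noise_free_growth, rng)
        by = df.groupby(["shrna", "condition"])["cell_count"].mean()
        ctrl_h = by[("control", HYPOXIA)]
        assert by[("1", HYPOXIA)] / ctrl_h == pytest.approx(2.0 ** (-0.2 * 7))
        assert by[("1", NORMOXIA)] == pytest.approx(by[("control", NORMOXIA)])

    def test_design_is_three_replicates_per_cell(self, noise_free_growth, rng):
        df = simulate_growth_assay("X", 0.0, -0.5, (0.9, 0.8), noise_free_growth, rng)
        sizes = df.groupby(["shrna", "condition"]).size()
        assert (sizes == 3).all() and len(sizes) == 6


class TestQpcrSim:
    def test_noise_free_fold_encoding_on_ct_scale(self, noise_free_qpcr, rng):
        ct = simulate_qpcr({"T": 2.0}, noise_free_qpcr, rng)
        by = ct[ct["gene_id"] == "T"].groupby("condition")["ct"].mean()
        assert by[NORMOXIA] - by[HYPOXIA] == pytest.approx(1.0)  # log2(2)

    def test_controls_always_on_plate(self, noise_free_qpcr, rng):
        ct = simulate_qpcr({}, noise_free_qpcr, rng)
        assert {"ACTB", "GLUT1", "PDK1"} <= set(ct["gene_id"])

    def test_non_positive_fold_rejected(self, noise_free_qpcr, rng):
        with pytest.raises(ValueError, match="non-positive"):
            simulate_qpcr({"T": 0.0}, noise_free_qpcr, rng)


def test_closed_form_helper_matches_hand_value():
    # efficacy 1, s_hyp -0.5, d 3, 10 passages -> 2^-15
    assert closed_form_ratio(1.0, 0.0, -0.5, 3.0, 10) == pytest.approx(2.0**-15)
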