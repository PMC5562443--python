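"""Planted-truth recovery and reproducibility of the synthetic generators."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exitscape.dynamics import detect_transient
from exitscape.intervals import te_fraction
from exitscape.methylation import region_percent
from exitscape.mirna import check_escape, fold_repression, scan_seed_sites
from exitscape.screen import derive_signatures, score_perturbation
from exitscape.synthetic import (
    SimulationConfig,
    simulate_clone_panel,
    simulate_genome,
    simulate_knockdown_panel,
    simulate_luciferase,
    simulate_timecourse,
    simulate_two_state,
    simulate_utr,
)


class TestReproducibility:
    def test_generators_bitwise_reproducible(self, small_config):
        a, b = simulate_two_state(small_config), simulate_two_state(small_config)
        pd.testing.assert_frame_equal(a.comparison, b.comparison)
        pd.testing.assert_frame_equal(
            simulate_clone_panel(small_config).panel,
            simulate_clone_panel(small_config).panel,
        )
        assert simulate_utr(small_config).sequences == simulate_utr(small_config).sequences

    def test_substreams_independent(self, small_config):
        # changing a parameter consumed by one generator leaves others untouched
        other = dataclasses.replace(small_config, n_clones=30, utr_length=600)
        pd.testing.assert_frame_equal(
            simulate_two_state(small_config).comparison,
            simulate_two_state(other).comparison,
        )

    def test_different_seeds_differ(self, small_config):
        a = simulate_two_state(small_config)
        b = simulate_two_state(small_config.with_seed(small_config.seed + 1))
        assert not a.comparison.equals(b.comparison)


class TestTwoState:
    def test_noiseless_recovery_exact(self, small_config):
        cfg = dataclasses.replace(small_config, noise_sd=0.0)
        sim = simulate_two_state(cfg)
        sigs = derive_signatures(sim.comparison, cfg.signature_fold)
        assert sigs.set_a == sim.truth.set_a
        assert sigs.set_b == sim.truth.set_b

    def test_noisy_recovery_quantified_against_truth(self, small_config):
        sim = simulate_two_state(small_config)
        sigs = derive_signatures(sim.comparison, small_config.signature_fold)
        recall = len(sigs.set_a & sim.truth.set_a) / len(sim.truth.set_a)
        precision = len(sigs.set_a & sim.truth.set_a) / max(len(sigs.set_a), 1)
        assert recall > 0.5 and precision > 0.9

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=10, n_signature_a=8, n_signature_b=8)


class TestKnockdownPanel:
    def test_archetypes_land_in_planted_quadrants(self, small_config):
        sim = simulate_two_state(small_config)
        panel = simulate_knockdown_panel(small_config, sim.truth)
        for label, profile in panel.profiles.items():
            score = score_perturbation(profile, sim.truth)
            assert score.quadrant == panel.expected_quadrants[label], label

    def test_null_archetype_near_origin(self, small_config):
        sim = simulate_two_state(small_config)
        panel = simulate_knockdown_panel(small_config, sim.truth)
        score = score_perturbation(panel.profiles["null"], sim.truth)
        assert abs(score.esc_axis) <= 10 and abs(score.epi_axis) <= 10

    def test_off_signature_genes_unshifted(self, small_config):
        sim = simulate_two_state(small_config)
        panel = simulate_knockdown_panel(small_config, sim.truth)
        prof = panel.profiles["exit_facilitator"]
        off = prof[~prof["gene_id"].isin(sim.truth.set_a | sim.truth.set_b)]
        # no planted effect: median |log fc| stays well under the 2x gate
        assert np.median(np.abs(np.log2(off["fold_change"]))) < 0.5


class TestTimecourse:
    def test_noiseless_transient_detected_and_decoys_rejected(self, small_config):
        cfg = dataclasses.replace(small_config, noise_sd=0.0)
        sim = simulate_timecourse(cfg)
        t = np.array(sim.courses.columns, dtype=float)
        for cid in sim.courses.index:
            call = detect_transient(t, sim.courses.loc[cid].to_numpy())
            assert call.is_transient == (cid in sim.transient_ids)

    def test_low_noise_isolates_planted_transient(self, small_config):
        # stated bound for exact isolation: sigma <= 0.05
        hits = 0
        for seed in range(50):
            cfg = dataclasses.replace(small_config, seed=seed, noise_sd=0.05)
            sim = simulate_timecourse(cfg)
            t = np.array(sim.courses.columns, dtype=float)
            found = {
                cid
                for cid in sim.courses.index
                if detect_transient(t, sim.courses.loc[cid].to_numpy()).is_transient
            }
            hits += found == sim.transient_ids
        assert hits >= 48

    def test_fractions_emitted_for_every_candidate(self, small_config):
        sim = simulate_timecourse(small_config)
        assert set(sim.fractions.index) == set(sim.courses.index)
        assert sim.fraction_hour in set(np.array(sim.courses.columns, dtype=float))


class TestClonePanel:
    def test_zero_probability_gives_zero_percent(self, small_config):
        cfg = dataclasses.replace(
            small_config, clone_regions=(("r", 10, 0.0),)
        )
        sim = simulate_clone_panel(cfg)
        assert region_percent(sim.panel, sim.regions["r"]) == 0.0

    def test_estimates_within_binomial_interval(self, small_config):
        cfg = dataclasses.replace(
            small_config, n_clones=20, clone_regions=(("r", 10, 0.4),)
        )
        covered = 0
        n_panels = 100
        for seed in range(n_panels):
            sim = simulate_clone_panel(cfg.with_seed(seed))
            pct = region_percent(sim.panel, sim.regions["r"])
            n = 20 * 10
            lo = stats.binom.ppf(0.025, n, 0.4) / n * 100
            hi = stats.binom.ppf(0.975, n, 0.4) / n * 100
            covered += lo <= pct <= hi
        assert covered >= 0.93 * n_panels

    def test_missing_rate_masks_calls(self, small_config):
        cfg = dataclasses.replace(small_config, missing_rate=0.3)
        sim = simulate_clone_panel(cfg)
        assert sim.panel.isna().to_numpy().mean() == pytest.approx(0.3, abs=0.1)


class TestGenome:
    def test_te_truth_recovered_exactly(self, small_config):
        sim = simulate_genome(small_config)
        comp = te_fraction(sim.exons, sim.repeats)
        assert comp.fraction == pytest.approx(sim.truth["te_fraction"], abs=1e-12)

    def test_no_te_overlap_config(self, small_config):
        cfg = dataclasses.replace(small_config, te_overlap_fraction=0.0)
        sim = simulate_genome(cfg)
        assert te_fraction(sim.exons, sim.repeats).fraction == 0.0

    def test_cpg_table_valid_and_regions_separate(self, small_config):
        sim = simulate_genome(small_config)
        t = sim.cpg_table
        assert (t["total_count"] >= t["meth_count"]).all()
        assert (t["meth_count"] >= 0).all()
        assert not t.duplicated(["chrom", "pos"]).any()


class TestUtr:
    def test_planted_sites_recovered_at_recorded_positions(self, small_config):
        sim = simulate_utr(small_config)
        found = []
        for utr_id, seq in sim.sequences.items():
            found += [
                (s.utr_id, s.start, s.end, s.site_type)
                for s in scan_seed_sites(seq, sim.mirna, utr_id)
            ]
        want = [(s.utr_id, s.start, s.end, s.site_type) for s in sim.truth]
        assert sorted(found) == sorted(want)

    def test_empty_plant_spec_scans_empty(self, small_config):
        sim = simulate_utr(small_config)
        assert scan_seed_sites(sim.sequences["utr_empty"], sim.mirna) == []

    def test_mutants_escape(self, small_config):
        sim = simulate_utr(small_config)
        assert sim.mutants  # at least one UTR carried sites
        for utr_id, mut in sim.mutants.items():
            res = check_escape(sim.sequences[utr_id], mut, sim.mirna)
            assert res.escape, utr_id


class TestLuciferase:
    def test_planted_fold_recovered(self, small_config):
        table = simulate_luciferase(small_config)
        out = fold_repression(table)
        for construct, fold in small_config.luciferase_fold:
            assert out.loc[construct, "fold_repression"] == pytest.approx(
                fold, rel=0.25
            )
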