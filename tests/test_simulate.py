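"""Generator contracts: determinism, planted effects, conservation."""

import numpy as np
import pandas as pd
import pytest

from bacterivory import SimulationConfig, simulate_all
from bacterivory.community import pool_kos, sample_columns
from bacterivory.errors import ConfigError
from bacterivory.simulate import (simulate_alignments, simulate_growth_curves,
                                  simulate_species_counts, simulate_transcript_table)

from conftest import small_config


class TestConfig:
    def test_peak_ranges_must_exceed_init(self):
        with pytest.raises(ConfigError):
            SimulationConfig(hf_init=(5e2, 1e3), hf_peak=(8e2, 1.3e4))

    def test_duration_too_short_for_both_peaks(self):
        with pytest.raises(ConfigError, match="duration too short"):
            SimulationConfig(duration=6.0, hf_peak_day=(5.0, 6.5))

    def test_trophic_proportions_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            SimulationConfig(trophic_mode_proportions=(0.5, 0.5, 0.5))

    def test_yaml_roundtrip(self, tmp_path):
        cfg = small_config(noise_cv=0.17)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert SimulationConfig.from_yaml(tmp_path / "c.yaml") == cfg


class TestDeterminism:
    def test_same_seed_identical_different_seed_differs(self, config):
        a = simulate_all(config, seed=7)
        b = simulate_all(config, seed=7)
        c = simulate_all(config, seed=8)
        for attr in ("curves", "samples", "transcripts", "protein_hits",
                     "nucleotide_hits", "species_counts"):
            pd.testing.assert_frame_equal(getattr(a, attr), getattr(b, attr))
        assert not a.curves.equals(c.curves)
        assert not a.transcripts.equals(c.transcripts)


class TestGrowthCurves:
    def test_zero_noise_curve_follows_template(self):
        cfg = small_config(noise_cv=0.0, count_noise_cv=0.0)
        curves, _ = simulate_growth_curves(cfg, seed=3)
        for _, grp in curves[curves["population"] == "hf"].groupby("incubation"):
            n = grp.sort_values("time_days")["cells_per_ml"].to_numpy()
            peak = int(np.argmax(n))
            assert (np.diff(n[:peak + 1]) >= 0).all()          # rise to the peak
            post = n[peak + 1:]  # grid points fully past the analytic peak
            ratios = post[1:] / post[:-1]
            assert np.allclose(ratios, ratios[0])              # exponential decline
            assert n.max() / n[0] >= 7.0                       # >= 7x increase
        # PF decays monotonically without noise
        for _, grp in curves[curves["population"] == "pf"].groupby("incubation"):
            n = grp.sort_values("time_days")["cells_per_ml"].to_numpy()
            assert (np.diff(n) < 0).all()

    def test_bacterial_peak_precedes_hf_peak(self):
        cfg = small_config(noise_cv=0.0, count_noise_cv=0.0)
        curves, _ = simulate_growth_curves(cfg, seed=11)
        for _, grp in curves.groupby("incubation"):
            t_b = grp[grp["population"] == "bacteria"].sort_values("time_days")
            t_h = grp[grp["population"] == "hf"].sort_values("time_days")
            peak_b = t_b["time_days"].iloc[int(np.argmax(t_b["cells_per_ml"]))]
            peak_h = t_h["time_days"].iloc[int(np.argmax(t_h["cells_per_ml"]))]
            assert peak_b < peak_h

    def test_every_incubation_has_all_three_states(self, experiment):
        for _, grp in experiment.samples.groupby("incubation"):
            assert set(grp["state"]) == {"lag", "growth", "decline"}


class TestTranscriptTable:
    def test_tpm_columns_sum_to_one_million(self, experiment):
        cols = sample_columns(experiment.transcripts)
        sums = experiment.transcripts[cols].sum(axis=0)
        assert np.allclose(sums, 1e6, atol=1.0)

    def test_marker_and_hk_sets_disjoint(self, experiment):
        truth = experiment.truth
        assert not truth.marker_ko_ids & truth.hk_ko_ids
        assert not truth.marker_ko_ids & truth.photo_ko_ids

    def test_annotation_fraction_close_to_configured(self, config, experiment):
        frac = (experiment.transcripts["ko_ids"] != "").mean()
        assert frac == pytest.approx(config.ko_annotation_fraction, abs=0.01)

    def test_realized_marker_fold_change_matches_plant(self):
        """Mean growth/lag TPM ratio over planted markers stays in the
        Monte-Carlo band of the generative model ([3.2, 4.8] for a 4x plant
        at CV 0.3, derived by direct simulation of the noise model)."""
        cfg = small_config(n_marker_kos=50, noise_cv=0.3)
        _, samples = simulate_growth_curves(cfg, seed=5)
        table, truth = simulate_transcript_table(cfg, samples, seed=5)
        ko, _ = pool_kos(table)
        lag_cols = samples.loc[samples["state"] == "lag", "sample_id"]
        gro_cols = samples.loc[samples["state"] == "growth", "sample_id"]
        fc = ko[list(gro_cols)].mean(axis=1) / ko[list(lag_cols)].mean(axis=1)
        mean_fc = fc.loc[sorted(truth.marker_ko_ids)].mean()
        assert 3.2 <= mean_fc <= 4.8

    def test_null_plant_gives_marker_fc_at_housekeeping_level(self):
        cfg = small_config(marker_fold_change=1.0, noise_cv=0.2)
        _, samples = simulate_growth_curves(cfg, seed=5)
        table, truth = simulate_transcript_table(cfg, samples, seed=5)
        ko, _ = pool_kos(table)
        lag_cols = list(samples.loc[samples["state"] == "lag", "sample_id"])
        gro_cols = list(samples.loc[samples["state"] == "growth", "sample_id"])
        fc = ko[gro_cols].mean(axis=1) / ko[lag_cols].mean(axis=1)
        mk = fc.loc[sorted(truth.marker_ko_ids)].mean()
        hk = fc.loc[sorted(truth.hk_ko_ids)].mean()
        assert mk == pytest.approx(hk, rel=0.1)

    def test_photosynthesis_transcripts_collapse_by_decline(self, experiment):
        truth = experiment.truth
        ko, _ = pool_kos(experiment.transcripts)
        samples = experiment.samples
        lag = list(samples.loc[samples["state"] == "lag", "sample_id"])
        dec = list(samples.loc[samples["state"] == "decline", "sample_id"])
        photo = ko.loc[sorted(truth.photo_ko_ids)]
        assert photo[dec].mean().mean() < 0.05 * photo[lag].mean().mean()

    def test_two_ko_transcripts_planted(self, config, experiment):
        n_two = (experiment.transcripts["ko_ids"].str.contains(";")).sum()
        n_annot = (experiment.transcripts["ko_ids"] != "").sum()
        assert n_two == pytest.approx(config.two_ko_fraction * n_annot, rel=0.15)


class TestAlignments:
    def test_present_species_median_identity_above_99(self, experiment):
        truth = experiment.truth
        nt = experiment.nucleotide_hits.copy()
        nt["species"] = nt["sseqid"].str.split("_cds").str[0]
        for sp, status in truth.species_status.items():
            sub = nt[nt["species"] == sp]
            if status == "present":
                assert sub["pident"].median() > 99
            elif status == "relative":
                assert 90 <= sub["pident"].median() <= 95
            else:
                assert sub.empty

    def test_absent_species_emit_no_hits(self, experiment):
        truth = experiment.truth
        absent = {sp for sp, st in truth.species_status.items() if st == "absent"}
        mapped = experiment.species_map["species_id"].unique()
        assert not absent & set(mapped)
        prot_species = set(experiment.protein_hits["sseqid"].str.split("_p").str[0])
        assert not absent & prot_species

    def test_present_species_have_enough_transcripts_somewhere(self, config, experiment):
        prot = experiment.protein_hits.copy()
        q = prot[["qseqid"]].drop_duplicates()
        parts = q["qseqid"].str.split("_")
        q["inc"], q["sp"] = parts.str[0], parts.str[2]
        counts = q.groupby(["sp", "inc"]).size().groupby("sp").max()
        for sp, status in experiment.truth.species_status.items():
            if status != "absent":
                assert counts[sp] >= 100

    def test_tie_fraction_binomial(self):
        cfg = small_config(tie_fraction=0.1)
        prot, _, _, _ = simulate_alignments(cfg, seed=2)
        dup = prot.groupby(["qseqid", "bitscore"]).size()
        n_tied_queries = (dup[dup >= 2].reset_index()
                          .groupby("qseqid").size().shape[0])
        n_queries = prot["qseqid"].nunique()
        expected = 0.1 * n_queries
        sd = np.sqrt(n_queries * 0.1 * 0.9)
        assert abs(n_tied_queries - expected) < 5 * sd


class TestSpeciesCounts:
    def test_marker_share_ratio_matches_effect(self):
        """Heterotroph/phototroph mean relative-expression ratio of planted
        genes lands in the Monte-Carlo band [3, 5.3] for a 4x effect at CV 0.5."""
        cfg = small_config(noise_cv=0.5, relative_expression_effect=4.0)
        exp = simulate_all(cfg, seed=4)
        counts = exp.species_counts
        lc = counts.assign(expr=counts["read_count"] / counts["effective_length"])
        tot = lc.groupby(["species", "sample"])["expr"].sum()
        gmap = dict(zip(exp.gene_map["cds_id"], exp.gene_map["gene"]))
        lc["gene"] = lc["cds_id"].map(gmap)
        gene_expr = (lc.dropna(subset=["gene"])
                     .groupby(["gene", "species", "sample"])["expr"].sum())
        shares = (gene_expr / tot).reset_index(name="share")
        mode = exp.truth.trophic_mode
        shares["mode"] = shares["species"].map(mode)
        common = [g for g in exp.truth.species_marker_genes
                  if g not in exp.truth.genes_absent_in_phototrophs]
        sub = shares[shares["gene"].isin(common)]
        het = sub.loc[sub["mode"] == "heterotroph", "share"]
        pho = sub.loc[sub["mode"] == "phototroph", "share"]
        assert len(het) >= 20 and len(pho) >= 20
        assert 3.0 <= het.mean() / pho.mean() <= 5.3

    def test_null_effect_gives_equal_shares(self):
        cfg = small_config(relative_expression_effect=1.0, noise_cv=0.3)
        exp = simulate_all(cfg, seed=4)
        counts = exp.species_counts
        lc = counts.assign(expr=counts["read_count"] / counts["effective_length"])
        tot = lc.groupby(["species", "sample"])["expr"].sum()
        gmap = dict(zip(exp.gene_map["cds_id"], exp.gene_map["gene"]))
        lc["gene"] = lc["cds_id"].map(gmap)
        gene_expr = (lc.dropna(subset=["gene"])
                     .groupby(["gene", "species", "sample"])["expr"].sum())
        shares = (gene_expr / tot).reset_index(name="share")
        shares["mode"] = shares["species"].map(exp.truth.trophic_mode)
        common = [g for g in exp.truth.species_marker_genes
                  if g not in exp.truth.genes_absent_in_phototrophs]
        sub = shares[shares["gene"].isin(common)]
        het = sub.loc[sub["mode"] == "heterotroph", "share"].mean()
        pho = sub.loc[sub["mode"] == "phototroph", "share"].mean()
        assert het / pho == pytest.approx(1.0, abs=0.25)

    def test_requires_transcript_truth_first(self, config, experiment):
        from bacterivory.simulate import SyntheticTruth
        bare = SyntheticTruth(species_status={"sp01": "present"},
                              trophic_mode={"sp01": "heterotroph"})
        with pytest.raises(ConfigError):
            simulate_species_counts(config, experiment.samples, bare, seed=0)
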