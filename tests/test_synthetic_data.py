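"""Synthetic-data generator: planted truth, noise model, determinism."""

import dataclasses
import filecmp
import json

import numpy as np
import pandas as pd
import pytest

from peonymir.smallrna_catalog import GenomeIndex, revcomp
from peonymir.synthetic_data import (
    SimulationConfig,
    _nb_draw,
    _rngs,
    audit_outputs,
    simulate_counts,
    simulate_degradome,
    simulate_genome,
    simulate_mirbase,
    simulate_all,
)


class TestConfigValidation:
    def test_bad_dispersion_and_mean(self):
        with pytest.raises(ValueError, match="dispersion"):
            SimulationConfig(dispersion=0)
        with pytest.raises(ValueError, match="mean_count"):
            SimulationConfig(mean_count=-1)

    def test_peak_fraction_bounds(self):
        with pytest.raises(ValueError, match="peak_fraction"):
            SimulationConfig(degradome_peak_fraction=1.5)
        SimulationConfig(degradome_peak_fraction=1.0)  # boundary is legal


@pytest.fixture(scope="module")
def small_config():
    return SimulationConfig(
        seed=7,
        n_contigs=3,
        contig_length=4000,
        n_planted_mir={"gp1": 3, "gp2a": 2, "gp2b": 3, "gp3": 3, "gp4": 2},
        n_decoy_tags=30,
        n_transcripts=40,
        n_planted_modules=4,
        n_extra_de_mirnas=2,
        n_extra_de_genes=2,
    )


@pytest.fixture(scope="module")
def small_sim(small_config):
    rngs = _rngs(small_config.seed)
    genome, gff, truth = simulate_genome(small_config, rngs["genome"])
    return small_config, genome, gff, truth


class TestGenome:
    def test_gp3_matures_absent_from_genome(self, small_sim):
        _, genome, _, truth = small_sim
        joined = list(genome.values())
        for m in truth.planted_mirnas:
            if m.group == "gp3":
                assert all(
                    m.sequence not in c and revcomp(m.sequence) not in c
                    for c in joined
                )

    def test_hairpin_group_loci_pass_independent_recheck(self, small_sim):
        from peonymir.mirna_discovery import fold_back

        _, genome, _, truth = small_sim
        gi = GenomeIndex(genome)
        for m in truth.planted_mirnas:
            if m.group in ("gp1", "gp2a", "gp4"):
                res = fold_back(gi, (*m.locus,))
                assert res.accepted, m.id
            if m.group == "gp2b":
                assert not fold_back(gi, (*m.locus,)).accepted, m.id

    def test_gff_rows_carry_every_genomic_locus(self, small_sim):
        cfg, _, gff, truth = small_sim
        with_locus = [m for m in truth.planted_mirnas if m.locus is not None]
        assert len(gff) == len(with_locus)
        ids = {r["attributes"].split(";")[0].removeprefix("ID=") for r in gff}
        assert ids == {m.id for m in with_locus}


class TestReference:
    def test_reference_membership_by_group(self, small_sim):
        cfg, genome, _, truth = small_sim
        mature, precursor = simulate_mirbase(cfg, truth, genome, _rngs(cfg.seed)["mirbase"])
        n_known = sum(1 for m in truth.planted_mirnas if m.group != "gp4")
        assert len(mature) == n_known == len(precursor)
        for m in truth.planted_mirnas:
            if m.group == "gp4":
                assert m.id not in mature and m.id not in precursor
            else:
                assert mature[m.id] == m.sequence
                assert m.sequence in precursor[m.id]

    def test_gp1_precursors_map_to_genome_gp2_gp3_do_not(self, small_sim):
        cfg, genome, _, truth = small_sim
        _, precursor = simulate_mirbase(cfg, truth, genome, _rngs(cfg.seed)["mirbase"])
        gi = GenomeIndex(genome)
        for m in truth.planted_mirnas:
            if m.group == "gp4":
                continue
            hits = gi.map_tag(precursor[m.id], 0)
            if m.group == "gp1":
                assert len(hits) >= 1
            else:
                assert hits == []


class TestCounts:
    def test_planted_effect_shifts_mean_by_factor_four(self):
        """+2 log2 effect at (FD, DE): empirical mean ratio across many
        features approaches 4 within NB standard error."""
        cfg = SimulationConfig(seed=3)
        from peonymir.synthetic_data import SyntheticTruth

        truth = SyntheticTruth()
        n = 600
        transcripts = {f"T{i:04d}": "A" * 100 for i in range(n)}
        truth.effect_cells = {t: {("FD", "DE"): 2.0} for t in transcripts}
        rngs = _rngs(cfg.seed)
        _, mrna, _ = simulate_counts(cfg, truth, transcripts, rngs["srna"], rngs["mrna"])
        de_cols = [c for c in mrna.columns if c.startswith("FD_DE")]
        bs_cols = [c for c in mrna.columns if c.startswith("FD_BS")]
        ratio = mrna[de_cols].to_numpy().mean() / mrna[bs_cols].to_numpy().mean()
        assert ratio == pytest.approx(4.0, rel=0.1)

    def test_null_config_plants_no_de(self, small_config):
        cfg = dataclasses.replace(
            small_config, effect_log2fc=0.0, n_planted_modules=0,
            n_extra_de_mirnas=0, n_extra_de_genes=0,
        )
        rngs = _rngs(cfg.seed)
        _, _, truth = simulate_genome(cfg, rngs["genome"])
        from peonymir.synthetic_data import simulate_transcripts

        simulate_transcripts(cfg, truth, rngs["transcripts"], rngs["modules"])
        assert truth.planted_de_features == []
        assert truth.effect_cells == {}

    def test_decoy_out_of_range_fraction(self, small_sim):
        cfg, genome, _, truth = small_sim
        cfg2 = dataclasses.replace(cfg, n_decoy_tags=1000,
                                   decoy_out_of_range_fraction=0.2)
        transcripts = {"T0001": "A" * 500}
        rngs = _rngs(cfg2.seed)
        srna, _, _ = simulate_counts(cfg2, truth, transcripts, rngs["srna"], rngs["mrna"])
        lengths = srna["sequence"].str.len()
        planted = len(truth.planted_mirnas)
        out = ((lengths < 18) | (lengths > 26)).sum()
        assert out == round(0.2 * 1000)
        assert (lengths[:planted].between(18, 26)).all()

    def test_nb_dispersion_matches_parameterization(self):
        rng = np.random.default_rng(0)
        mu, disp = 100.0, 0.2
        draws = _nb_draw(rng, np.full(200_000, mu), disp)
        assert draws.mean() == pytest.approx(mu, rel=0.02)
        assert draws.var() == pytest.approx(mu + disp * mu**2, rel=0.05)


class TestDegradome:
    def test_peak_fraction_one_concentrates_all_tags(self, small_sim):
        cfg, genome, _, truth0 = small_sim
        from peonymir.synthetic_data import SyntheticTruth, simulate_transcripts

        cfg2 = dataclasses.replace(cfg, degradome_peak_fraction=1.0)
        truth = SyntheticTruth()
        truth.planted_mirnas = truth0.planted_mirnas
        transcripts, _ = simulate_transcripts(
            cfg2, truth, _rngs(cfg2.seed)["transcripts"], _rngs(cfg2.seed)["modules"]
        )
        deg = simulate_degradome(cfg2, truth, transcripts, _rngs(cfg2.seed)["degradome"])
        for _, tid, pos in truth.planted_cleavage_sites:
            rows = deg["FD"][deg["FD"]["transcript_id"] == tid]
            assert rows["count"].max() == rows.set_index("position").loc[pos, "count"]
            assert rows["count"].sum() == cfg2.degradome_cleaved_tags

    def test_background_transcripts_stay_sparse(self, run_dir, truth, transcripts):
        deg = pd.read_csv(run_dir / "degradome_MU.tsv", sep="\t")
        cleaved = {tid for _, tid, _ in truth.planted_cleavage_sites}
        background = deg[~deg["transcript_id"].isin(cleaved)]
        assert background["count"].max() <= 3  # uniform singles, rare collisions

    def test_planted_position_out_of_bounds_is_an_error(self, small_sim):
        cfg, _, _, truth0 = small_sim
        from peonymir.synthetic_data import GenerationError, SyntheticTruth

        truth = SyntheticTruth()
        truth.planted_cleavage_sites = [("m", "T0001", 999)]
        with pytest.raises(GenerationError, match="outside"):
            simulate_degradome(cfg, truth, {"T0001": "A" * 100}, _rngs(0)["degradome"])


class TestDeterminismAndAudit:
    def test_same_seed_twice_is_byte_identical(self, tmp_path, small_config):
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_all(small_config, a)
        simulate_all(small_config, b)
        names = sorted(p.name for p in a.iterdir())
        assert names == sorted(p.name for p in b.iterdir())
        for name in names:
            assert (a / name).read_bytes() == (b / name).read_bytes(), name

    def test_cross_file_audit_is_clean(self, tmp_path, small_config):
        simulate_all(small_config, tmp_path / "bundle")
        assert audit_outputs(tmp_path / "bundle") == []

    def test_audit_detects_tampering(self, tmp_path, small_config):
        out = tmp_path / "bundle"
        simulate_all(small_config, out)
        srna = pd.read_csv(out / "srna_counts.tsv", sep="\t")
        srna = srna.iloc[5:]  # drop planted tags
        srna.to_csv(out / "srna_counts.tsv", sep="\t", index=False)
        assert audit_outputs(out) != []
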