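import dataclasses
import json

import numpy as np
import pytest

from sescreen import (
    SyntheticConfig,
    simulate_dataset,
    stitch,
    write_dataset,
)
from sescreen import io as sio
from sescreen.simulate import generate_landscape, synthesize_sequences


class TestConfigValidation:
    def test_defaults_valid(self):
        SyntheticConfig()

    def test_rejects_too_few_lines(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_lines=3, n_target_lines=2)

    def test_rejects_tiny_lineage_groups(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_lines=10, n_target_lines=1)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_typical=-1)

    def test_infeasible_packing_reported(self):
        cfg = SyntheticConfig(
            seed=1, n_chromosomes=1, chrom_length=100_000, n_typical=50, n_super=5
        )
        with pytest.raises(ValueError, match="infeasible packing"):
            generate_landscape(cfg)


class TestLandscapeInvariants:
    def test_deterministic(self, small_config):
        a = generate_landscape(small_config)
        b = generate_landscape(small_config)
        assert a.to_dict() == b.to_dict()

    def test_counts_match_config(self, small_config, small_dataset):
        truth = small_dataset.truth
        assert len(truth.super_enhancers) == small_config.n_super
        assert len(truth.typical_enhancers) == small_config.n_typical
        assert len(truth.genes) == small_config.n_genes

    def test_spacing_at_least_configured(self, small_config, small_dataset):
        by_chrom = {}
        for e in small_dataset.truth.enhancers:
            by_chrom.setdefault(e.chrom, []).append(e)
        for enhancers in by_chrom.values():
            enhancers.sort(key=lambda e: e.start)
            for prev, cur in zip(enhancers, enhancers[1:]):
                assert cur.start - prev.end >= small_config.spacing_bp

    def test_constituents_tile_the_region(self, small_dataset):
        for e in small_dataset.truth.enhancers:
            cons = sorted(e.constituents)
            assert cons[0][0] == e.start
            assert cons[-1][1] == e.end
            for (s1, e1), (s2, e2) in zip(cons, cons[1:]):
                assert e1 <= s2

    def test_truth_stitch_bijection(self, small_dataset):
        """After promoter filtering, stitching at the default distance
        recovers exactly the planted enhancer hulls (spacing is 2x stitch)."""
        from sescreen import define_candidates

        candidates = define_candidates(
            small_dataset.k27ac_peaks,
            small_dataset.genes,
            small_dataset.k4me3_peaks,
        )
        stitched = stitch(candidates)
        planted = {(e.chrom, e.start, e.end) for e in small_dataset.truth.enhancers}
        recovered = {
            (e.region.chrom, e.region.start, e.region.end) for e in stitched
        }
        assert planted == recovered

    def test_msat_means_match_planted_distributions(self):
        # pool several seeds so the sample means are stable
        in_counts, out_counts = [], []
        for seed in (1, 2, 3):
            truth = generate_landscape(SyntheticConfig(seed=seed))
            for m in truth.microsatellites:
                (in_counts if m.in_fli1_peak else out_counts).append(m.repeat_count)
        cfg = SyntheticConfig()
        assert np.mean(in_counts) == pytest.approx(cfg.msat_mean_repeats_in_fli1, rel=0.1)
        assert np.mean(out_counts) == pytest.approx(cfg.msat_mean_repeats_outside, rel=0.1)

    def test_substream_isolation(self, small_config):
        """Changing the screen size must not perturb the landscape draws."""
        other = dataclasses.replace(small_config, n_lines=20, n_target_lines=6)
        assert (
            generate_landscape(small_config).to_dict()
            == generate_landscape(other).to_dict()
        )


class TestSequences:
    def test_planted_runs_present_verbatim(self, small_config, small_dataset):
        seqs = small_dataset.sequences
        for m in small_dataset.truth.microsatellites:
            run = m.unit * m.repeat_count
            assert seqs[m.chrom][m.start : m.start + len(run)] == run

    def test_lengths_and_alphabet(self, small_config, small_dataset):
        for chrom, seq in small_dataset.sequences.items():
            assert len(seq) == small_config.chrom_length
            assert set(seq) <= set("ACGT")

    def test_deterministic(self, small_config):
        truth = generate_landscape(small_config)
        assert synthesize_sequences(truth, small_config) == synthesize_sequences(
            truth, small_config
        )


class TestScreens:
    def test_planted_labels_and_genes(self, small_config, small_dataset):
        truth = small_dataset.truth
        assert len(truth.selective_genes) == small_config.n_selective_genes
        assert len(truth.driver_genes) == small_config.n_driver_genes
        assert set(truth.driver_genes) <= set(truth.selective_genes)
        labels = list(truth.line_labels.values())
        assert labels.count(small_config.target_lineage) == small_config.n_target_lines

    def test_matrix_shape(self, small_config, small_dataset):
        dep = small_dataset.dependency
        assert dep.scores.shape == (small_config.n_screen_genes, small_config.n_lines)

    def test_planted_dependency_effect_visible(self, small_dataset):
        dep = small_dataset.dependency
        target_mask = (dep.lineages == "EWING").to_numpy()
        for gid in small_dataset.truth.selective_genes:
            row = dep.scores.loc[gid].to_numpy()
            assert row[target_mask].mean() < row[~target_mask].mean() - 1.0

    def test_ic50_shift_direction(self, small_dataset):
        df = small_dataset.drug_table.table
        target = df[df["lineage"] == "EWING"]["ic50"]
        other = df[df["lineage"] != "EWING"]["ic50"]
        assert np.exp(np.mean(np.log(target))) < np.exp(np.mean(np.log(other)))


class TestWriteDataset:
    def test_all_files_parse_back(self, small_dataset, tmp_path):
        paths = write_dataset(small_dataset, tmp_path)
        expected = {
            "genome",
            "genes",
            "k27ac_track",
            "k27ac_peaks",
            "k4me3_peaks",
            "fli1_peaks",
            "expression",
            "dependency",
            "labels",
            "ic50",
            "truth",
        }
        assert set(paths) == expected
        genes = sio.read_genes_tsv(paths["genes"])
        assert len(genes) == len(small_dataset.genes)
        track = sio.read_bedgraph(paths["k27ac_track"])
        assert set(track.chroms) == set(small_dataset.track.chroms)
        peaks = sio.read_bed(paths["k27ac_peaks"])
        assert len(peaks) == len(small_dataset.k27ac_peaks)
        dep = sio.read_dependency_tsv(paths["dependency"], paths["labels"])
        assert dep.scores.shape == small_dataset.dependency.scores.shape
        drug = sio.read_ic50_tsv(paths["ic50"])
        assert len(drug.table) == len(small_dataset.drug_table.table)
        fasta = sio.FastaSource(paths["genome"])
        assert set(fasta.chroms()) == set(small_dataset.sequences)
        truth = json.loads(paths["truth"].read_text())
        assert truth["seed"] == small_dataset.config.seed

    def test_expected_density_recovered_from_track(self, small_dataset):
        """Poisson noise averages out: mean density over a planted super's
        constituents approximates background + strength."""
        cfg = small_dataset.config
        track = small_dataset.track
        from sescreen import GenomicInterval

        for enh in small_dataset.truth.super_enhancers:
            total = sum(
                track.region_signal(GenomicInterval(enh.chrom, s, e))
                for s, e in enh.constituents
            )
            length = sum(e - s for s, e in enh.constituents)
            expected = cfg.background_density + enh.strength
            assert total / length == pytest.approx(expected, rel=0.15)
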