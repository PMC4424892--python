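"""Generator determinism, planted-truth consistency and moment checks."""

import json

import numpy as np
import pytest

from ersplice.annotation import load_annotation, write_annotation
from ersplice.binding import annotate_dsg_binding, gene_window
from ersplice.splice_events import enumerate_events
from ersplice.synthetic import (
    ConfigurationError,
    ConsistencyError,
    GroundTruth,
    SimulationConfig,
    generate_annotation,
    plant_truth,
    simulate,
    simulate_counts,
    write_fixture,
)


class TestConfigValidation:
    def test_bad_isoform_range(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(isoforms_per_gene=(0, 3))
        with pytest.raises(ConfigurationError):
            SimulationConfig(isoforms_per_gene=(2, 12))

    def test_event_mix_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(event_mix={"SE": 0.5, "RI": 0.4})

    def test_single_replicate_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_replicates=1)


class TestAnnotationGeneration:
    def test_single_isoform_gene_has_no_events(self):
        cfg = SimulationConfig(n_genes=1, isoforms_per_gene=(1, 1), seed=4)
        ann = generate_annotation(cfg)
        (gene,) = ann.genes.values()
        assert len(gene.transcripts) == 1
        assert enumerate_events(ann) == {}

    def test_same_seed_gives_byte_identical_gtf(self, tmp_path):
        cfg = SimulationConfig(n_genes=25, seed=99)
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_annotation(generate_annotation(cfg), p1)
        write_annotation(generate_annotation(SimulationConfig(
            n_genes=25, seed=99)), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_genes_span_chromosomes_and_strands_without_overlap(self):
        ann = generate_annotation(SimulationConfig(n_genes=30, seed=5))
        assert len(ann.chroms()) >= 2
        assert {g.strand for g in ann.genes.values()} == {"+", "-"}
        by_chrom = {}
        for g in ann.genes.values():
            by_chrom.setdefault(g.chrom, []).append(g.span)
        for spans in by_chrom.values():
            spans.sort()
            for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
                assert e0 < s1

    def test_every_multi_isoform_gene_has_an_event(self):
        ann = generate_annotation(SimulationConfig(n_genes=50, seed=6))
        events = enumerate_events(ann)
        genes_with_events = {ev.gene_id for ev in events.values()}
        for g in ann.genes.values():
            if len(g.transcripts) >= 2:
                assert g.gene_id in genes_with_events

    def test_planted_cassette_exons_lie_inside_reparsed_transcripts(self, tmp_path):
        # write the GTF, re-parse it, and check every SE event's skipped
        # exon sits strictly between exons of the inclusion transcript
        cfg = SimulationConfig(n_genes=50, seed=7)
        path = tmp_path / "x.gtf"
        write_annotation(generate_annotation(cfg), path)
        ann = load_annotation(path)
        events = enumerate_events(ann)
        se = [ev for ev in events.values() if ev.event_type == "SE"]
        assert se, "expected planted cassette exons"
        for ev in se:
            up_end, ex_start, ex_end, dn_start = ev.coords
            gene = ann.genes[ev.gene_id]
            carriers = [
                t for t in gene.transcripts.values()
                if (ex_start, ex_end) in set(t.exons)
            ]
            assert carriers
            for t in carriers:
                assert t.start < ex_start and ex_end < t.end


class TestCountSimulation:
    def test_empty_truth_under_null_config(self):
        cfg = SimulationConfig(n_genes=20, de_fraction=0, ds_fraction=0,
                               switch_fraction=0, promoter_switch_fraction=0,
                               delta_psi_effect=0, seed=8)
        ds = simulate(cfg)
        assert ds.truth.is_empty()

    def test_truth_annotation_mismatch_rejected(self):
        cfg = SimulationConfig(n_genes=5, seed=9)
        ann = generate_annotation(cfg)
        bad = GroundTruth()
        bad.de_genes["wt"]["NOPE"] = 1
        with pytest.raises(ConsistencyError):
            simulate_counts(ann, bad, cfg)

    def test_planted_fold_change_is_recovered_in_the_mean(self):
        # FC=2 genes at depth 1000: the E2/vehicle mean-count ratio across
        # many seeds concentrates near the planted value
        ratios = []
        for seed in range(40):
            cfg = SimulationConfig(n_genes=6, isoforms_per_gene=(1, 1),
                                   depth=1000, de_fraction=1.0,
                                   de_fold_change=2.0, seed=100 + seed)
            ds = simulate(cfg)
            wt = ds.gene_counts.query("cell_line == 'wt'")
            for g, sign in ds.truth.de_genes["wt"].items():
                if sign != 1:
                    continue
                sub = wt[wt["feature_id"] == g]
                veh = sub.loc[sub["condition"] == "vehicle", "count"].mean()
                e2 = sub.loc[sub["condition"] == "E2", "count"].mean()
                ratios.append(e2 / veh)
        assert ratios
        assert 1.5 <= np.mean(ratios) <= 2.5

    def test_pooled_psi_estimates_track_planted_values(self):
        from ersplice.splice_events import EFFECTIVE_LENGTHS, psi

        cfg = SimulationConfig(n_genes=30, ds_fraction=0.5,
                               delta_psi_effect=0.3, junction_depth=500,
                               seed=11)
        ds = simulate(cfg)
        junc = ds.junction_counts.query("cell_line == 'wt'")
        checked = 0
        for key, dpsi in ds.truth.ds_events["wt"].items():
            sub = junc[junc["event_key"] == key]
            if sub.empty:
                continue
            li, ls = EFFECTIVE_LENGTHS[sub["event_type"].iloc[0]]
            by_cond = sub.groupby("condition")[["ijc", "sjc"]].sum()
            psi_v = psi(by_cond.loc["vehicle", "ijc"],
                        by_cond.loc["vehicle", "sjc"], li, ls)
            psi_e = psi(by_cond.loc["E2", "ijc"], by_cond.loc["E2", "sjc"],
                        li, ls)
            assert abs((psi_e - psi_v) - dpsi) <= 0.12
            checked += 1
        assert checked >= 5

    def test_switch_genes_have_opposite_planted_signs(self, small_dataset):
        truth = small_dataset.truth
        assert truth.switch_genes
        for g, info in truth.switch_genes.items():
            signs = info["signs"]
            assert signs["ct_erb"] == signs["nt_erb"] == -signs["wt"]
            gene = small_dataset.annotation.genes[g]
            assert len(gene.transcripts) >= 2


class TestFixtureIO:
    def test_all_fixture_files_written_and_parseable(self, tmp_path,
                                                     small_dataset):
        from ersplice.annotation import load_peaks

        paths = write_fixture(small_dataset, tmp_path / "fix")
        ann = load_annotation(paths["gtf"])
        assert ann == small_dataset.annotation
        load_peaks(paths["era_peaks"], "era")
        load_peaks(paths["erb_peaks"], "erb")
        truth = json.loads(paths["truth"].read_text())
        assert set(truth) == {"de_genes", "ds_events", "switch_genes",
                              "promoter_switch_genes", "peak_groups"}

    def test_peak_placement_both_puts_peaks_in_every_window(self):
        cfg = SimulationConfig(
            n_genes=30, ds_fraction=0.5, seed=12,
            peak_placement={"both": 1.0, "era_only": 0.0, "erb_only": 0.0},
        )
        ds = simulate(cfg)
        dsg_genes = [ds.annotation.genes[g] for g in ds.truth.peak_groups]
        assert dsg_genes
        table = annotate_dsg_binding(dsg_genes, ds.era_peaks, ds.erb_peaks)
        assert (table["group"] == "1").all()

    def test_empty_truth_yields_valid_empty_bed(self, tmp_path):
        cfg = SimulationConfig(n_genes=4, de_fraction=0, ds_fraction=0,
                               switch_fraction=0, promoter_switch_fraction=0,
                               delta_psi_effect=0, seed=13)
        ds = simulate(cfg)
        paths = write_fixture(ds, tmp_path / "nullfix")
        from ersplice.annotation import load_peaks

        peaks = load_peaks(paths["era_peaks"], "era")
        for gene in ds.annotation.genes.values():
            chrom, lo, hi = gene_window(gene)
            for s, e in peaks.intervals.get(chrom, []):
                assert min(e, hi) - max(s, lo) < 1  # background stays outside
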