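import json
from dataclasses import replace

import numpy as np
import pytest

from ercross.expression_de import call_regulated, classify_regulation
from ercross.interval_algebra import classify_six, extend, merge, partition_subtypes
from ercross.motif_scan import classify_sites
from ercross.synthetic_data import (
    PAPER_SCALE,
    TINY,
    SimConfig,
    simulate_all,
    simulate_expression,
    simulate_genes,
    simulate_mirna,
    simulate_peaks,
    simulate_sequences,
    write_bundle,
)
from ercross.target_linking import link


def region_sets(sim, config):
    return (
        merge(extend(sim.beta, config.flank, config.chrom_sizes)),
        merge(extend(sim.alpha_tap, config.flank, config.chrom_sizes)),
        merge(extend(sim.alpha_wt, config.flank, config.chrom_sizes)),
    )


class TestConfig:
    def test_defaults_valid(self):
        SimConfig().validate()
        TINY.validate()
        PAPER_SCALE.validate()

    @pytest.mark.parametrize(
        "kw",
        [
            {"class_probs": (0.5, 0.5, 0.5, 0.5)},
            {"ere_fraction": 0.8, "here_fraction": 0.5},
            {"gc_content": 0.0},
            {"ere_mismatches": 3},
            {"group_props": (0.5, 0.5, 0.5, 0.1)},
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            replace(TINY, **kw).validate()


class TestSimulatePeaks:
    def test_deterministic(self):
        a = simulate_peaks(TINY, np.random.default_rng(5))
        b = simulate_peaks(TINY, np.random.default_rng(5))
        assert a == b

    def test_counts(self):
        sim = simulate_peaks(TINY, np.random.default_rng(1))
        assert len(sim.beta) == TINY.n_beta
        n56 = TINY.n_alpha_class5 + TINY.n_alpha_class6
        assert len(sim.alpha_tap) >= n56
        assert len(sim.truth) == len(sim.beta) + len(sim.alpha_tap)

    def test_infeasible_design_rejected(self):
        tiny_genome = replace(TINY, chrom_sizes={"sim1": 50_000}, n_beta=1000)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_peaks(tiny_genome, np.random.default_rng(0))

    def test_zero_overlap_design_gives_no_heterodimers(self):
        config = replace(
            TINY, class_probs=(0.0, 0.0, 1.0, 0.0), n_alpha_class5=0, n_alpha_class6=0
        )
        sim = simulate_peaks(config, np.random.default_rng(2))
        br, tr, _ = region_sets(sim, config)
        part = partition_subtypes(br, tr)
        assert part.heterodimer == ()

    def test_full_overlap_design_all_heterodimer(self):
        config = replace(
            TINY, class_probs=(0.0, 1.0, 0.0, 0.0), n_alpha_class5=0, n_alpha_class6=0
        )
        sim = simulate_peaks(config, np.random.default_rng(3))
        br, tr, _ = region_sets(sim, config)
        part = partition_subtypes(br, tr)
        assert len(part.heterodimer) == len(br)

    def test_realized_class_fractions_within_3se(self):
        config = replace(TINY, n_beta=400,
                         chrom_sizes={"sim1": 4_000_000, "sim2": 4_000_000})
        sim = simulate_peaks(config, np.random.default_rng(4))
        counts = {f"CLASS{k}": 0 for k in range(1, 7)}
        for pid in (p.id for p in sim.beta):
            counts[sim.truth[pid]] += 1
        for cls, p in zip(("CLASS1", "CLASS2", "CLASS3", "CLASS4"), config.class_probs):
            se = np.sqrt(p * (1 - p) / config.n_beta)
            assert abs(counts[cls] / config.n_beta - p) <= 3 * se + 1e-9

    def test_truth_labels_recovered_by_classifier(self):
        sim = simulate_peaks(TINY, np.random.default_rng(6))
        br, tr, wr = region_sets(sim, TINY)
        labels = classify_six(sim.beta, br, tr, wr, sim.alpha_tap)
        assert all(labels[k].name.startswith(v) for k, v in sim.truth.items())


class TestSimulateSequences:
    def test_all_full_elements(self):
        config = replace(TINY, ere_fraction=1.0, here_fraction=0.0, ere_mismatches=0)
        sim = simulate_peaks(TINY, np.random.default_rng(7))
        seqs, truth = simulate_sequences(sim.beta[:30], config, np.random.default_rng(7))
        labels, fractions = classify_sites(seqs)
        assert fractions["ERE+"] == 1.0
        assert all(v == "ERE+" for v in truth.values())

    def test_no_planting_gives_no_false_positives(self):
        config = replace(TINY, ere_fraction=0.0, here_fraction=0.0)
        sim = simulate_peaks(TINY, np.random.default_rng(8))
        seqs, _ = simulate_sequences(sim.beta[:30], config, np.random.default_rng(8))
        _, fractions = classify_sites(seqs)
        assert fractions["ERE+"] <= 0.05  # scrubbed background: should be 0
        assert fractions["none"] == 1.0

    def test_truth_recovered_exactly(self):
        sim = simulate_peaks(TINY, np.random.default_rng(9))
        seqs, truth = simulate_sequences(sim.beta, TINY, np.random.default_rng(9))
        labels, _ = classify_sites(seqs)
        assert {k: v.value for k, v in labels.items()} == truth

    def test_with_one_mismatch_still_recovered(self):
        config = replace(TINY, ere_mismatches=1)
        sim = simulate_peaks(TINY, np.random.default_rng(10))
        seqs, truth = simulate_sequences(sim.beta, config, np.random.default_rng(10))
        labels, _ = classify_sites(seqs)
        assert {k: v.value for k, v in labels.items()} == truth

    def test_site_shorter_than_motif_rejected(self):
        from ercross.genomic_io import GenomicInterval

        config = replace(TINY, ere_fraction=1.0, here_fraction=0.0)
        short = [GenomicInterval("sim1", 0, 10, id="tiny")]
        with pytest.raises(ValueError, match="shorter"):
            simulate_sequences(short, config, np.random.default_rng(0))


class TestSimulateExpression:
    def test_zero_noise_exact_recovery(self):
        genes = [f"g{i}" for i in range(300)]
        table, truth = simulate_expression(genes, TINY, np.random.default_rng(11))
        groups = classify_regulation(call_regulated(table))
        assert {g: v for g, v in truth.items() if v is not None} == {
            g: grp.value for g, grp in groups.items()
        }

    def test_proportions_echoed(self):
        config = replace(TINY, group_props=(0.25, 0.17, 0.52, 0.02))
        genes = [f"g{i}" for i in range(1000)]
        table, truth = simulate_expression(genes, config, np.random.default_rng(12))
        groups = classify_regulation(call_regulated(table))
        counts = {k: 0 for k in ("wt_only", "both_concordant", "beta_only", "opposite")}
        for grp in groups.values():
            counts[grp.value] += 1
        for key, p in zip(counts, config.group_props):
            se = np.sqrt(p * (1 - p) / 1000)
            assert abs(counts[key] / 1000 - p) <= 3 * se + 1e-9

    def test_timepoint_zero_anchored(self):
        table, _ = simulate_expression(["g"], TINY, np.random.default_rng(13))
        t0 = table[table.time_h == 0]
        assert (t0.log2fc == 0).all() and (t0.diffscore == 0).all()


class TestSimulateGenesAndMirna:
    def test_gene_link_truth(self):
        bundle = simulate_all(TINY, seed=14)
        links = link(bundle["genes"], bundle["beta_regions"], TINY.window)
        for gene_id, planted in bundle["gene_truth"].items():
            assert (gene_id in links) == planted

    def test_mirna_count_and_planting(self):
        config = replace(TINY, mirna_near_fraction=0.5, n_mirna=30)
        sim = simulate_peaks(config, np.random.default_rng(15))
        loci, truth = simulate_mirna(config, np.random.default_rng(15), sim.beta)
        assert len(loci) == 30
        assert sum(truth.values()) == 15

    def test_planting_without_sites_rejected(self):
        config = replace(TINY, mirna_near_fraction=0.5)
        with pytest.raises(ValueError):
            simulate_mirna(config, np.random.default_rng(0), sites=())


class TestBundle:
    def test_deterministic_bundle(self):
        a = simulate_all(TINY, seed=20)
        b = simulate_all(TINY, seed=20)
        assert a["peaks"] == b["peaks"]
        assert a["sequences"] == b["sequences"]
        assert a["expression"].equals(b["expression"])
        assert a["mirna_loci"] == b["mirna_loci"]

    def test_write_bundle_files(self, tmp_path):
        bundle = simulate_all(TINY, seed=21)
        write_bundle(bundle, tmp_path)
        expected = {
            "beta_peaks.bed", "alpha_tap_peaks.bed", "alpha_wt_peaks.bed",
            "chrom.sizes", "site_sequences.fa", "genes.tsv", "expression.tsv",
            "mirna_loci.bed", "truth.json",
        }
        assert expected <= {p.name for p in tmp_path.iterdir()}
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert set(truth) == {
            "peak_classes", "sequence_classes", "gene_linked",
            "expression_groups", "mirna_planted_near",
        }
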