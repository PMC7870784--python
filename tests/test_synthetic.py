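"""The generator: determinism, noise-free limits, planted guarantees, feasibility."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from pmsnet import AxisSpec, SynthConfig, generate, plant_axis, run_pipeline
from pmsnet.io import read_gene_list, read_gmt, read_mirsnp_table, read_predictions


class TestDeterminism:
    def test_same_seed_gives_byte_identical_bundles(self, small_config, tmp_path):
        a = generate(small_config)
        b = generate(small_config)
        pd.testing.assert_frame_equal(a.predictions.table, b.predictions.table)
        pd.testing.assert_frame_equal(a.mirsnps.table, b.mirsnps.table)
        assert a.risk_genes.genes == b.risk_genes.genes
        assert a.truth.to_json() == b.truth.to_json()
        dir_a, dir_b = tmp_path / "a", tmp_path / "b"
        a.write(dir_a)
        b.write(dir_b)
        for f in sorted(p.relative_to(dir_a) for p in dir_a.rglob("*") if p.is_file()):
            assert (dir_a / f).read_bytes() == (dir_b / f).read_bytes(), f

    def test_different_seeds_differ(self, small_config):
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        assert generate(small_config).risk_genes.genes != generate(other).risk_genes.genes


class TestNoiseFreeLimit:
    def test_perfect_sources_reproduce_true_target_map(self, small_config):
        cfg = dataclasses.replace(
            small_config, source_sensitivity=1.0, source_fp_rate=0.0
        )
        bundle = generate(cfg)
        from pmsnet import build_consensus

        cons = build_consensus(bundle.predictions, k=4)
        assert set(cons.targets) == set(bundle.truth.true_targets)
        for mirna, genes in bundle.truth.true_targets.items():
            assert cons.targets[mirna] == genes


class TestSourceNoiseModel:
    def test_support_counts_follow_the_binomial_envelope(self, default_bundle):
        """Per-pair source support is Binomial(N, sensitivity) for unforced pairs."""
        cfg = default_bundle.config
        forced = {
            (m, default_bundle.truth.axes[i]["gene"])
            for i, t in enumerate(default_bundle.truth.axes)
            for m in t["mirnas"]
        }
        support = default_bundle.predictions.table.groupby(["mirna", "gene"])["source"].nunique()
        truth_pairs = {
            (m, g) for m, genes in default_bundle.truth.true_targets.items() for g in genes
        }
        rng = np.random.default_rng(1)
        keys = [k for k in support.index if k in truth_pairs and k not in forced]
        sample = [support[keys[i]] for i in rng.choice(len(keys), size=200, replace=False)]
        mean = np.mean(sample)
        # 99% envelope for the mean of 200 Binomial(10, 0.7) draws
        mu = cfg.n_sources * cfg.source_sensitivity
        se = np.sqrt(cfg.n_sources * cfg.source_sensitivity * (1 - cfg.source_sensitivity) / 200)
        assert abs(mean - mu) < 2.576 * se
        # and no unforced support count strays outside the distribution's 99% band
        lo, hi = binom.ppf(0.005, 10, 0.7), binom.ppf(0.995, 10, 0.7)
        frac_outside = np.mean([not lo <= s <= hi for s in sample])
        assert frac_outside <= 0.05


class TestFeasibility:
    def test_risk_genes_beyond_universe_rejected(self):
        with pytest.raises(ValueError, match="risk genes"):
            generate(SynthConfig(seed=1, universe_size=10, n_risk_genes=20))

    def test_axis_needing_more_pathways_than_planted_rejected(self):
        with pytest.raises(ValueError, match="planted"):
            SynthConfig(seed=1, n_planted_pathways=2, axes=(AxisSpec(n_pathways=3),)).validate()

    def test_consensus_threshold_beyond_roster_rejected(self):
        with pytest.raises(ValueError, match="roster"):
            SynthConfig(seed=1, n_sources=3, consensus_k=4).validate()

    def test_plant_axis_rejects_zero_pathways(self, small_config):
        with pytest.raises(ValueError, match="at least one pathway"):
            plant_axis(small_config, AxisSpec(n_mirnas=2, n_pathways=0))

    def test_errors_raised_before_any_file_is_written(self, tmp_path):
        bad = SynthConfig(seed=1, universe_size=10, n_risk_genes=20)
        with pytest.raises(ValueError):
            generate(bad)
        assert list(tmp_path.iterdir()) == []


class TestPlantedAxes:
    def test_two_disjoint_axes_recovered_with_no_spurious_third(self):
        cfg = plant_axis(SynthConfig(seed=7), AxisSpec(n_mirnas=3, n_pathways=2))
        bundle = generate(cfg)
        result = run_pipeline(
            bundle.risk_genes, bundle.pathways, bundle.predictions, bundle.mirsnps
        )
        got = sorted(
            (a.rsid, a.gene, tuple(sorted(a.mirnas)), tuple(sorted(a.pathways)))
            for a in result.axes
        )
        expected = sorted(
            (t["rsid"], t["gene"], tuple(sorted(t["mirnas"])), tuple(sorted(t["pathways"])))
            for t in bundle.truth.axes
        )
        assert len(expected) == 2
        assert got == expected


class TestRoundTrip:
    def test_emitted_files_reload_through_the_readers(self, small_config, tmp_path):
        bundle = generate(small_config)
        paths = bundle.write(tmp_path / "bundle")
        coll = read_gmt(paths["gmt"])
        assert coll.ids() == bundle.pathways.ids()
        for pid in coll.ids():
            assert coll.genes(pid) == bundle.pathways.genes(pid)
        genes = read_gene_list(paths["genes"])
        assert genes.genes == bundle.risk_genes.genes
        pred = read_predictions(sorted(paths["predictions"].glob("*.tsv")))
        pd.testing.assert_frame_equal(pred.table, bundle.predictions.table)
        snps = read_mirsnp_table(paths["mirsnps"])
        pd.testing.assert_frame_equal(snps.table, bundle.mirsnps.table)
        truth = json.loads(paths["truth"].read_text())
        assert truth["planted_pathways"] == list(bundle.truth.planted_pathways)
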