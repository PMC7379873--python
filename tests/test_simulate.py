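"""Synthetic-data generator: determinism, expectations, caps, truth labels."""

import math

import numpy as np
import pandas as pd
import pysam
import pytest

from radploidy.reduce import iupac_expand
from radploidy.simulate import (
    SimulationConfig,
    emit_files,
    simulate_allotetraploid,
    simulate_dataset,
    simulate_parents,
    simulate_quartet_sites,
)


def discriminating_sites(parent1, parent2) -> int:
    """Sites whose allele sets differ between the two parents."""
    n = 0
    for lid in parent1.sequences:
        for a, b in zip(parent1.sequences[lid], parent2.sequences[lid]):
            if iupac_expand(a) != iupac_expand(b):
                n += 1
    return n


class TestSimulationConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"parent_divergence": -0.1},
            {"parent_divergence": 1.5},
            {"backcross_fraction": 2.0},
            {"missing_rate": -1e-9},
            {"n_loci": 0},
            {"locus_length": 0},
            {"depth_mean": 0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestSimulateParents:
    def test_divergence_count_matches_closed_form(self):
        """Observed parent-discriminating sites within 3σ of n·L·divergence."""
        config = SimulationConfig(n_loci=1000, parent_divergence=0.01, seed=1)
        _, parent1, parent2 = simulate_parents(config)
        n_sites = config.n_loci * config.locus_length
        expected = n_sites * config.parent_divergence
        sigma = math.sqrt(n_sites * 0.01 * 0.99)
        observed = discriminating_sites(parent1, parent2)
        assert abs(observed - expected) <= 3 * sigma

    def test_zero_divergence_identity(self):
        config = SimulationConfig(n_loci=50, parent_divergence=0.0, seed=2)
        _, parent1, parent2 = simulate_parents(config)
        assert parent1.sequences == parent2.sequences

    def test_determinism_byte_identical_fasta(self, tmp_path):
        config = SimulationConfig(n_loci=100, seed=3)
        for run in ("a", "b"):
            _, parent1, _ = simulate_parents(config)
            parent1.to_fasta(tmp_path / f"{run}.fasta")
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()

    def test_parental_heterozygosity_produces_ambiguity_codes(self):
        config = SimulationConfig(n_loci=200, parental_heterozygosity=0.01, seed=4)
        _, parent1, _ = simulate_parents(config)
        symbols = set("".join(parent1.sequences.values()))
        assert symbols - set("ACGT"), "expected IUPAC codes at heterozygous sites"

    def test_snp_cap_respected_at_high_divergence(self):
        config = SimulationConfig(n_loci=100, parent_divergence=0.25, seed=5)
        _, parent1, parent2 = simulate_parents(config)
        for lid in parent1.sequences:
            n = sum(
                iupac_expand(a) != iupac_expand(b)
                for a, b in zip(parent1.sequences[lid], parent2.sequences[lid])
            )
            assert n <= 20


class TestSimulateAllotetraploid:
    def test_f1_truth_is_all_cat5(self, f1_dataset):
        counts = f1_dataset["truth"].counts()
        assert set(counts) == {"CAT5"}
        assert counts["CAT5"] > 0

    def test_full_backcross_removes_cat5(self):
        config = SimulationConfig(n_loci=200, backcross_fraction=1.0, seed=6)
        _, parent1, parent2 = simulate_parents(config)
        _, truth = simulate_allotetraploid(parent1, parent2, config)
        assert truth.counts().get("CAT5", 0) == 0
        assert truth.counts().get("CAT1", 0) > 0

    def test_post_origin_count_matches_closed_form(self):
        """CAT34 truth count within 3σ of n·L·post_origin_rate."""
        config = SimulationConfig(n_loci=1000, post_origin_rate=0.002, seed=7)
        _, parent1, parent2 = simulate_parents(config)
        _, truth = simulate_allotetraploid(parent1, parent2, config)
        n_sites = config.n_loci * config.locus_length
        expected = n_sites * config.post_origin_rate
        sigma = math.sqrt(n_sites * 0.002 * 0.998)
        assert abs(truth.counts().get("CAT34", 0) - expected) <= 3 * sigma

    def test_mismatched_locus_sets_rejected(self):
        config = SimulationConfig(n_loci=10, seed=8)
        _, parent1, parent2 = simulate_parents(config)
        del parent2.sequences[sorted(parent2.sequences)[0]]
        with pytest.raises(ValueError, match="locus ids"):
            simulate_allotetraploid(parent1, parent2, config)

    def test_truth_conservation(self, mixed_dataset):
        """Category truth counts sum to the number of polymorphic sites."""
        truth = mixed_dataset["truth"]
        counts = truth.counts()
        assert sum(counts.values()) == len(truth)
        assert set(counts) <= {"CAT1", "CAT2", "CAT34", "CAT5", "OTHER"}
        # exactly one record per site
        keys = truth.records[["locus_id", "offset"]]
        assert not keys.duplicated().any()

    @pytest.mark.parametrize("param,categories", [
        ("backcross_fraction", ("CAT1", "CAT5")),
        ("post_origin_rate", ("CAT34", None)),
    ])
    def test_monotone_trends_over_seeds(self, param, categories):
        """Expected truth composition moves monotonically with the rate.

        Over 20 seeds: more backcrossing -> more CAT1+CAT2, fewer CAT5;
        a higher post-origin rate -> more CAT34.
        """
        up_cat, down_cat = categories
        if param == "backcross_fraction":
            values = [0.0, 0.25, 0.5]
        else:
            values = [0.0, 0.002, 0.004]
        mean_up, mean_down = [], []
        for value in values:
            ups, downs = [], []
            for seed in range(20):
                config = SimulationConfig(n_loci=120, seed=seed, **{param: value})
                _, parent1, parent2 = simulate_parents(config)
                _, truth = simulate_allotetraploid(parent1, parent2, config)
                counts = truth.counts()
                ups.append(counts.get(up_cat, 0) + counts.get("CAT2", 0) * (up_cat == "CAT1"))
                downs.append(counts.get(down_cat, 0) if down_cat else 0)
            mean_up.append(np.mean(ups))
            mean_down.append(np.mean(downs))
        assert mean_up == sorted(mean_up)
        if down_cat:
            assert mean_down == sorted(mean_down, reverse=True)


class TestEmitFiles:
    def test_depth_mean_within_3_sigma(self, tmp_path):
        config = SimulationConfig(n_loci=400, depth_mean=50.0, seed=9)
        files, _ = simulate_dataset(config, tmp_path)
        depths = pd.read_csv(
            files.tetraploid_depth, sep="\t", header=None,
            names=["contig", "pos", "depth"],
        )
        per_locus = depths["depth"].to_numpy()[:: config.locus_length]
        var = config.depth_mean + config.depth_mean**2 / config.depth_dispersion
        sigma_mean = math.sqrt(var / len(per_locus))
        assert abs(per_locus.mean() - 50.0) <= 3 * sigma_mean

    def test_no_dropout_means_full_presence(self, f1_dataset):
        config = f1_dataset["config"]
        files = f1_dataset["files"]
        n_positions = config.n_loci * config.locus_length
        for depth_file in (files.parent2_depth, files.tetraploid_depth):
            df = pd.read_csv(depth_file, sep="\t", header=None)
            assert len(df) == n_positions

    def test_dropout_rate_applied(self, tmp_path):
        config = SimulationConfig(n_loci=500, missing_rate=0.3, seed=10)
        files, _ = simulate_dataset(config, tmp_path)
        df = pd.read_csv(files.parent2_depth, sep="\t", header=None)
        present = len(df) / config.locus_length
        sigma = math.sqrt(500 * 0.3 * 0.7)
        assert abs(present - 500 * 0.7) <= 3 * sigma

    def test_cat5_sites_have_two_alleles_dosage_2_2(self, f1_dataset):
        """Tetraploid VCF genotypes at homeo-SNP truth sites are 2+2."""
        files = f1_dataset["files"]
        truth = f1_dataset["truth"]
        ref_offsets = pd.read_csv(files.offsets_tsv, sep="\t")
        start_of = dict(zip(ref_offsets["locus_id"], ref_offsets["start0"]))
        cat5_positions = {
            start_of[r.locus_id] + r.offset
            for r in truth.records.itertuples()
            if r.true_category == "CAT5"
        }
        checked = 0
        with pysam.VariantFile(str(files.tetraploid_vcf)) as vcf:
            sample = list(vcf.header.samples)[0]
            for rec in vcf:
                if rec.pos not in cat5_positions:
                    continue
                gt = rec.samples[sample]["GT"]
                alleles = [rec.alleles[i] for i in gt]
                assert len(set(alleles)) == 2
                counts = sorted(alleles.count(a) for a in set(alleles))
                assert counts == [2, 2]
                checked += 1
        assert checked > 100

    def test_determinism_byte_identical_outputs(self, tmp_path):
        config = SimulationConfig(n_loci=60, seed=12, missing_rate=0.1)
        files_a, _ = simulate_dataset(config, tmp_path / "a")
        files_b, _ = simulate_dataset(config, tmp_path / "b")
        for name in ("ref_fasta", "parent2_vcf", "tetraploid_vcf",
                     "parent2_depth", "truth_tsv"):
            a = getattr(files_a, name).read_bytes()
            b = getattr(files_b, name).read_bytes()
            assert a == b, name


class TestSimulateQuartetSites:
    def test_gamma_zero_hybrid_equals_p1(self):
        q = simulate_quartet_sites(0.0, 500, seed=1)
        assert q.hybrid == q.p1

    def test_gamma_one_hybrid_equals_p2(self):
        q = simulate_quartet_sites(1.0, 500, seed=2)
        assert q.hybrid == q.p2

    def test_gamma_half_binomial(self):
        q = simulate_quartet_sites(0.5, 10_000, seed=3)
        matches_p2 = sum(h == b for h, b in zip(q.hybrid, q.p2))
        sigma = math.sqrt(10_000 * 0.25)
        assert abs(matches_p2 - 5_000) <= 3 * sigma

    def test_invalid_gamma_rejected(self):
        for gamma in (-0.1, 1.1):
            with pytest.raises(ValueError):
                simulate_quartet_sites(gamma, 100, seed=0)

    def test_uninformative_padding(self):
        q = simulate_quartet_sites(0.5, 100, seed=4, n_uninformative=50)
        assert len(q.outgroup) == 150
        tail = zip(q.outgroup[100:], q.p1[100:], q.hybrid[100:], q.p2[100:])
        assert all(o == a == h == b for o, a, h, b in tail)
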