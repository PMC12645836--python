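"""Fixture generator: determinism, arithmetic contracts, statistical calibration,
and serialization round trips."""

import hashlib

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfselect import codonsites as cs
from tfselect import synthetic_data as sd
from tfselect.regions import ALLGENES, BD, CRM, NONBD, TFBS


def md5s(paths: dict) -> dict:
    return {k: hashlib.md5(open(p, "rb").read()).hexdigest() for k, p in paths.items()}


class TestGenerateFixture:
    def test_coding_span_arithmetic(self):
        cfg = sd.FixtureConfig(seed=0, n_genes=10, codons_per_gene=100, n_crms=0)
        fx = sd.generate_fixture(cfg)
        total_coding = sum(t.end - t.start for t in fx.gene_models)
        assert total_coding == 3000 and len(fx.gene_models) == 10

    def test_bd_nonbd_partition(self):
        cfg = sd.FixtureConfig(seed=1, n_genes=4, n_tf_genes=2, codons_per_gene=100, bd_fraction=0.3, n_crms=0)
        fx = sd.generate_fixture(cfg)
        bd = fx.region_catalog.intervals[BD]
        assert all(len(iv) == 90 for iv in bd)
        for t in fx.gene_models:
            if not t.is_tf:
                continue
            bd_len = sum(len(iv) for iv in bd if t.start <= iv.start < t.end)
            nonbd_len = sum(
                len(iv) for iv in fx.region_catalog.intervals[NONBD] if t.start <= iv.start < t.end
            )
            assert bd_len + nonbd_len == t.end - t.start
            assert nonbd_len == 210

    def test_reference_transcripts_have_no_internal_stops(self, small_fixture):
        fixture, _ = small_fixture
        for t in fixture.gene_models:
            cds = fixture.reference[t.contig][t.start : t.end]
            counts = cs.ng_site_counts(cds)  # raises on internal stop
            assert counts.total == pytest.approx(t.end - t.start)

    def test_planted_motifs_match_their_consensus(self, small_fixture):
        fixture, _ = small_fixture
        consensi = {p.consensus for p in fixture.pwms}
        for iv in fixture.tfbs_all:
            word = fixture.reference[iv.contig][iv.start : iv.end]
            assert word in consensi

    def test_every_catalog_tfbs_inside_a_retained_crm(self, small_fixture):
        fixture, _ = small_fixture
        crms = fixture.region_catalog.intervals[CRM]
        for site in fixture.region_catalog.intervals[TFBS]:
            assert any(c.start <= site.start and site.end <= c.end for c in crms)

    def test_impossible_packing_rejected(self):
        with pytest.raises(ValueError, match="packing"):
            sd.FixtureConfig(flank_len=100, crm_len=800)

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            sd.FixtureConfig(sel_mix=(0.5, 0.2, 0.1))


class TestGeneratePopulation:
    def test_sample_size_floor(self):
        with pytest.raises(ValueError):
            sd.FixtureConfig(sample_size=1)

    def test_variants_are_biallelic_snps_within_reference(self, small_fixture):
        fixture, pop = small_fixture
        ref = fixture.reference["chr1"]
        v = pop.variants
        assert (v["ref"] != v["alt"]).all()
        assert v["pos"].between(0, len(ref) - 1).all()
        assert (v["ref"] == [ref[p] for p in v["pos"]]).all()
        assert v["k"].between(1, pop.sample_size - 1).all()
        assert v["pos"].is_unique

    def test_carriers_match_counts(self, small_fixture):
        _, pop = small_fixture
        for k, carr in zip(pop.variants["k"], pop.carriers):
            assert len(carr) == k and len(set(carr.tolist())) == k

    def test_neutral_mix_diversity_matches_theta(self):
        """Mean per-site diversity over seeds within 3 SE of theta_per_site."""
        theta = 0.01
        pis = []
        for seed in range(20):
            cfg = sd.FixtureConfig(
                seed=seed, n_genes=6, codons_per_gene=100, n_tf_genes=0, flank_len=0,
                n_crms=0, sample_size=20, theta_per_site=theta, sel_mix=(1.0, 0.0, 0.0),
            )
            fx = sd.generate_fixture(cfg)
            pop = sd.generate_population(fx, cfg)
            k = pop.variants["k"].to_numpy(float)
            n = cfg.sample_size
            L = sum(t.end - t.start for t in fx.gene_models)
            pis.append((2 * k * (n - k) / (n * (n - 1))).sum() / L)
        se = np.std(pis, ddof=1) / np.sqrt(len(pis))
        assert abs(np.mean(pis) - theta) < 3 * se

    def test_neutral_sfs_matches_one_over_i(self):
        """Aggregated neutral SFS passes a chi-square test against 1/i."""
        n = 20
        counts = np.zeros(n - 1)
        for seed in range(15):
            cfg = sd.FixtureConfig(
                seed=100 + seed, n_genes=6, codons_per_gene=150, n_tf_genes=0,
                flank_len=500, n_crms=0, sample_size=n, theta_per_site=0.01,
                sel_mix=(1.0, 0.0, 0.0),
            )
            fx = sd.generate_fixture(cfg)
            pop = sd.generate_population(fx, cfg)
            counts += np.bincount(pop.variants["k"], minlength=n)[1:n]
        expected = (1.0 / np.arange(1, n)) / (1.0 / np.arange(1, n)).sum() * counts.sum()
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=n - 2)

    def test_deleterious_mix_skews_sfs_and_depresses_pin_pis(self):
        """A strongly deleterious nonsynonymous class lowers pin/pis and
        shifts the generated nonsynonymous SFS toward rare classes, matching
        the closed-form spectrum used by the generator."""
        cfg = sd.FixtureConfig(
            seed=3, n_genes=20, codons_per_gene=200, n_tf_genes=0, flank_len=0,
            n_crms=0, sample_size=30, theta_per_site=0.02,
            sel_mix=(0.0, 1.0, 0.0), sel_coeffs=(0.0, -20.0, 10.0),
        )
        fx = sd.generate_fixture(cfg)
        pop = sd.generate_population(fx, cfg)
        v = pop.variants
        ref = fx.reference["chr1"]
        Ls = Ln = 0.0
        for t in fx.gene_models:
            c = cs.ng_site_counts(ref[t.start : t.end])
            Ls, Ln = Ls + c.L_syn, Ln + c.L_nonsyn
        Pn = (v["var_class"] == "nonsynonymous").sum()
        Ps = (v["var_class"] == "synonymous").sum()
        assert (Pn / Ln) / (Ps / Ls) < 1.0
        # singleton excess vs the neutral synonymous class
        k_non = v.loc[v["var_class"] == "nonsynonymous", "k"]
        k_syn = v.loc[v["var_class"] == "synonymous", "k"]
        assert (k_non == 1).mean() > (k_syn == 1).mean()
        # and the class counts match the generator's closed-form spectrum
        e_k = sd.sfs_class_expectations(-20.0, 30) * cfg.theta_per_site * Ln
        obs = np.bincount(k_non, minlength=30)[1:30]
        mask = e_k >= 5
        chi2 = ((obs[mask] - e_k[mask]) ** 2 / e_k[mask]).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=int(mask.sum()))

    def test_null_pathogenic_enrichment_balances_proportions(self):
        """With enrichment multiplier 1, BD and non-BD pathogenic proportions
        are statistically indistinguishable when aggregated over seeds."""
        table = np.zeros(4)
        for seed in range(10):
            cfg = sd.FixtureConfig(
                seed=200 + seed, n_genes=8, n_tf_genes=8, flank_len=0, n_crms=0,
                theta_per_site=0.01, pathogenic_enrichment_bd=1.0, sample_size=20,
            )
            fx = sd.generate_fixture(cfg)
            pop = sd.generate_population(fx, cfg)
            v = pop.variants
            labeled = v[v["clinical"].isin(["pathogenic", "benign"])]
            cat = fx.region_catalog
            for _, row in labeled.iterrows():
                in_bd = BD in cat.labels_at("chr1", row["pos"])
                i = (0 if row["clinical"] == "pathogenic" else 1) + (0 if in_bd else 2)
                table[i] += 1
        _, p = stats.fisher_exact(table.reshape(2, 2).T)
        assert p > 0.01

    def test_expected_alpha_neutral_and_mixture(self):
        assert sd.FixtureConfig(sel_mix=(1.0, 0.0, 0.0)).expected_alpha() == 0.0
        cfg = sd.FixtureConfig(sel_mix=(0.6, 0.35, 0.05), sel_coeffs=(0.0, -9.0, 10.0))
        u = sd.relative_fixation
        expected = 0.05 * u(10.0) / (0.6 + 0.35 * u(-9.0) + 0.05 * u(10.0))
        assert cfg.expected_alpha() == pytest.approx(expected)


class TestWriteFixture:
    def test_same_seed_gives_byte_identical_outputs(self, tmp_path, small_fixture_config):
        hashes = []
        for sub in ("a", "b"):
            fx = sd.generate_fixture(small_fixture_config)
            pop = sd.generate_population(fx, small_fixture_config)
            paths = sd.write_fixture(fx, pop, tmp_path / sub)
            hashes.append(md5s(paths))
        assert hashes[0] == hashes[1]

    def test_round_trip_reconstructs_everything(self, tmp_path, small_fixture):
        fixture, pop = small_fixture
        paths = sd.write_fixture(fixture, pop, tmp_path / "rt")
        assert sd.read_fasta(paths["reference"]) == fixture.reference
        assert sd.read_fasta(paths["outgroup"]) == pop.outgroup
        genes = sd.read_gff3_transcripts(paths["genes"])
        assert [(t.gene_id, t.start, t.end, t.is_tf) for t in genes] == [
            (t.gene_id, t.start, t.end, t.is_tf) for t in fixture.gene_models
        ]
        for name, label in (("bd", BD), ("crm", CRM), ("tfbs", TFBS)):
            got = sd.read_bed(paths[name])
            want = sorted(
                fixture.crm_intervals if name == "crm" else fixture.region_catalog.intervals[label],
                key=lambda iv: (iv.contig, iv.start, iv.end),
            )
            assert [(iv.start, iv.end, iv.score) for iv in got] == [
                (iv.start, iv.end, iv.score if name == "crm" else 0) for iv in want
            ]
        vdf, carriers = sd.read_vcf(paths["vcf"])
        assert len(vdf) == len(pop.variants)
        assert (vdf["k"].to_numpy() == pop.variants["k"].to_numpy()).all()
        for mine, theirs in zip(pop.carriers, carriers):
            assert np.array_equal(mine, theirs)
        pwms = sd.read_jaspar(paths["pwms"])
        assert [p.consensus for p in pwms] == [p.consensus for p in fixture.pwms]

    def test_vcf_one_based_bed_zero_based_cross_check(self, tmp_path, small_fixture):
        """The same planted coordinate appears 1-based in VCF, 0-based in BED."""
        fixture, pop = small_fixture
        paths = sd.write_fixture(fixture, pop, tmp_path / "conv")
        vcf_pos = [
            int(line.split("\t")[1])
            for line in open(paths["vcf"])
            if not line.startswith("#")
        ]
        assert vcf_pos == [p + 1 for p in pop.variants["pos"]]
        bed_rows = [line.split("\t") for line in open(paths["crm"])]
        ref = fixture.reference["chr1"]
        for row in bed_rows:
            start, end = int(row[1]), int(row[2])
            assert 0 <= start < end <= len(ref)

    def test_truth_row_count_equals_vcf_record_count(self, tmp_path, small_fixture):
        fixture, pop = small_fixture
        paths = sd.write_fixture(fixture, pop, tmp_path / "truth")
        truth = pd.read_csv(paths["truth"], sep="\t")
        n_vcf = sum(1 for line in open(paths["vcf"]) if not line.startswith("#"))
        assert len(truth) == n_vcf
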