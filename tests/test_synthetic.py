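"""Synthetic study generator: determinism, round-trips, recovery."""

import filecmp

import numpy as np
import pandas as pd
import pytest

import dupscape as d


SMALL = dict(n_chromosomes=4, mean_chrom_length=2_000_000, n_loci=80)


class TestDeterminism:
    def test_byte_identical_outputs_for_fixed_seed(self, tmp_path):
        cfg = d.SimConfig(seed=42, **SMALL)
        d.simulate_all(cfg, out_dir=tmp_path / "a")
        d.simulate_all(d.SimConfig(seed=42, **SMALL), out_dir=tmp_path / "b")
        names = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert names == sorted(p.name for p in (tmp_path / "b").iterdir())
        for name in names:
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_different_seed_different_truth(self):
        t1, _ = d.gen_truth_and_genotypes(
            d.SimConfig(seed=1, **SMALL),
            d.gen_genome_and_annotation(d.SimConfig(seed=1, **SMALL))[0],
        )
        t2, _ = d.gen_truth_and_genotypes(
            d.SimConfig(seed=2, **SMALL),
            d.gen_genome_and_annotation(d.SimConfig(seed=2, **SMALL))[0],
        )
        assert [(l.chrom, l.start) for l in t1.loci] != [
            (l.chrom, l.start) for l in t2.loci
        ]


class TestGenomeAnnotation:
    def test_zero_gene_density_unsupported_but_tiny_density_near_empty(self):
        cfg = d.SimConfig(seed=1, **SMALL, gene_density=0.01)
        genome, ann = d.gen_genome_and_annotation(cfg)
        occupied = sum(g.end - g.start for g in ann.genes)
        assert occupied / genome.total_length < 0.05

    def test_gene_density_matches_configuration(self):
        cfg = d.SimConfig(seed=2, n_chromosomes=2, mean_chrom_length=5_000_000,
                          gene_density=0.3)
        genome, ann = d.gen_genome_and_annotation(cfg)
        occupied = sum(g.end - g.start for g in ann.genes)
        assert occupied / genome.total_length == pytest.approx(0.3, rel=0.10)

    def test_gene_children_within_span_and_introns_disjoint_from_cds(self):
        cfg = d.SimConfig(seed=3, **SMALL)
        _, ann = d.gen_genome_and_annotation(cfg)
        for g in ann.genes[:300]:
            for s, e in g.introns:
                for cs, ce in g.cds:
                    assert e <= cs or s >= ce

    def test_intergenic_interval_classifies_empty(self):
        cfg = d.SimConfig(seed=4, **SMALL, gene_density=0.05)
        genome, ann = d.gen_genome_and_annotation(cfg)
        rng = np.random.default_rng(0)
        for iv in d.gen_intergenic_loci(ann, genome, rng, n=20, size=200):
            assert d.classify_feature_overlap(iv, ann) == frozenset()


@pytest.fixture(scope="module")
def truth_ev():
    cfg = d.SimConfig(seed=6, **SMALL)
    genome, _ = d.gen_genome_and_annotation(cfg)
    truth, ev = d.gen_truth_and_genotypes(cfg, genome)
    return cfg, genome, truth, ev


class TestTruthAndGenotypes:
    def test_loci_within_genome_and_disjoint(self, truth_ev):
        cfg, genome, truth, _ = truth_ev
        for l in truth.loci:
            genome.validate_interval(l.chrom, l.start, l.end)

    def test_divergent_loci_near_fixed_difference(self, truth_ev):
        cfg, _, truth, _ = truth_ev
        a_ids = [s.id for s in truth.samples if s.species == cfg.species_a]
        b_ids = [s.id for s in truth.samples if s.species == cfg.species_b]
        for lid in truth.divergent_ids:
            pa = truth.presence.loc[lid, a_ids].mean()
            pb = truth.presence.loc[lid, b_ids].mean()
            assert pa == 0.0
            assert pb >= 0.8
            assert d.fst_dominant(pa, len(a_ids), pb, len(b_ids)) > 0.75

    def test_every_locus_has_a_carrier(self, truth_ev):
        _, _, truth, _ = truth_ev
        assert (truth.presence.sum(axis=1) >= 1).all()

    def test_singleton_fraction_matches_spectrum_oracle(self):
        """Observed singleton fraction falls inside a Monte-Carlo envelope of
        the configured 1/i frequency spectrum."""
        cfg = d.SimConfig(seed=7, n_chromosomes=4, mean_chrom_length=3_000_000,
                          n_loci=400, n_divergent=0, location_effect=0.0,
                          high_support_rate=0.0)
        genome, _ = d.gen_genome_and_annotation(cfg)
        truth, _ = d.gen_truth_and_genotypes(cfg, genome)
        n_tot = len(truth.samples)
        a_ids = [s.id for s in truth.samples if s.species == cfg.species_a]
        counts = (truth.presence[a_ids] == 1).sum(axis=1)
        observed = (counts == 1).mean()
        # independent oracle: simulate the same spectrum directly
        rng = np.random.default_rng(123)
        w = 1.0 / np.arange(1, n_tot + 1)
        w /= w.sum()
        sims = []
        for _ in range(400):
            p = rng.choice(np.arange(1, n_tot + 1), size=cfg.n_loci, p=w) / n_tot
            draws = rng.random((cfg.n_loci, n_tot)) < p[:, None]
            keep = draws.sum(axis=1) > 0
            # emulate the forced single carrier for all-absent draws
            forced = (~keep).sum()
            frac = ((draws[:, : len(a_ids)].sum(axis=1) == 1).sum()
                    + forced * len(a_ids) / n_tot) / cfg.n_loci
            sims.append(frac)
        lo, hi = np.quantile(sims, [0.001, 0.999])
        assert lo - 0.02 <= observed <= hi + 0.02

    def test_sample_plan_is_two_species_three_locations(self, truth_ev):
        cfg, _, truth, _ = truth_ev
        meta = pd.DataFrame([(s.species, s.location) for s in truth.samples],
                            columns=["species", "location"])
        assert meta["species"].value_counts()[cfg.species_a] == 20
        assert meta["species"].value_counts()[cfg.species_b] == 14
        assert set(meta["location"]) == {"CostaRica", "Panama", "FrenchGuiana"}


class TestCallerEmulation:
    def test_zero_noise_consensus_recovers_truth_exactly(self):
        cfg = d.SimConfig(
            seed=8, **SMALL,
            jitter_sd={m: 0.0 for m in d.METHODS},
            fn_rate={m: 0.0 for m in d.METHODS},
            fp_rate=0.0, low_support_rate=0.0, ubiquitous_rate=0.0,
        )
        genome, _ = d.gen_genome_and_annotation(cfg)
        truth, _ = d.gen_truth_and_genotypes(cfg, genome)
        calls = d.gen_caller_calls(cfg, truth, genome, cfg.species_a)
        disc = d.discovery_set(calls, genome)
        focal = cfg.focal_samples(cfg.species_a)
        expected = {
            (t.chrom, t.start, t.end)
            for t in truth.loci if t.id in set(truth.discoverable_ids(focal))
        }
        assert {(l.chrom, l.start, l.end) for l in disc} == expected

    def test_two_methods_fully_blind_empties_consensus(self):
        cfg = d.SimConfig(seed=9, **SMALL,
                          fn_rate={"PE_SR": 0.0, "SR": 1.0, "RD": 1.0},
                          fp_rate=0.0, ubiquitous_rate=0.0)
        genome, _ = d.gen_genome_and_annotation(cfg)
        truth, _ = d.gen_truth_and_genotypes(cfg, genome)
        calls = d.gen_caller_calls(cfg, truth, genome, cfg.species_a)
        assert d.discovery_set(calls, genome) == []

    def test_within_tool_merge_reunites_jittered_duplicates(self):
        cfg = d.SimConfig(seed=10, **SMALL, fp_rate=0.0, ubiquitous_rate=0.0)
        genome, _ = d.gen_genome_and_annotation(cfg)
        truth, _ = d.gen_truth_and_genotypes(cfg, genome)
        calls = d.gen_caller_calls(cfg, truth, genome, cfg.species_a)
        sr_calls = [d.assign_breakpoint_ci(c, genome) for c in calls["SR"]]
        loci = d.merge_within_tool(sr_calls)
        focal = cfg.focal_samples(cfg.species_a)
        n_events = len(truth.discoverable_ids(focal))
        # jitter sd 3 bp << +/-10 bp CI: per-sample duplicates collapse
        assert len(loci) <= n_events + 2

    def test_artifact_loci_removed_by_ubiquitous_filter(self):
        cfg = d.SimConfig(seed=12, **SMALL, ubiquitous_rate=0.05, fp_rate=0.0)
        genome, _ = d.gen_genome_and_annotation(cfg)
        truth, _ = d.gen_truth_and_genotypes(cfg, genome)
        calls = d.gen_caller_calls(cfg, truth, genome, cfg.species_a)
        focal = cfg.focal_samples(cfg.species_a)
        with_filter = d.discovery_set(calls, genome, reference_samples=focal)
        without = d.discovery_set(calls, genome)
        assert len(truth.artifact_loci) > 0
        assert len(with_filter) < len(without)
        # every artifact locus survives without the filter ...
        for a in truth.artifact_loci:
            assert any(d.reciprocal_overlap(a, l) >= 0.9 for l in without)
        # ... and none survives with it
        for a in truth.artifact_loci:
            for l in with_filter:
                assert d.reciprocal_overlap(a, l) < 0.9


class TestEndToEndRecovery:
    def test_discovery_recovers_truth_with_study_noise(self, sim_small):
        data = sim_small
        cfg = data.config
        focal = cfg.focal_samples(cfg.species_a)
        disc = d.discovery_set(
            data.calls[cfg.species_a], data.genome, reference_samples=focal
        )
        ids = set(data.truth.discoverable_ids(focal))
        truth_loci = [l for l in data.truth.loci if l.id in ids]
        ev = d.evaluate_discovery(truth_loci, disc)
        assert ev["sensitivity"] >= 0.90
        assert ev["precision"] >= 0.95


class TestFileRoundTrips:
    def test_calls_tsv_and_vcf_round_trip(self, sim_small, tmp_path):
        from dupscape import io as dio

        data = sim_small
        calls = data.calls[data.config.species_a]["PE_SR"][:50]
        tsv = tmp_path / "c.tsv"
        vcf = tmp_path / "c.vcf"
        dio.write_calls_tsv(calls, tsv)
        dio.write_calls_vcf(calls, data.genome, vcf)
        t = dio.read_calls_tsv(tsv)
        v = dio.read_calls_vcf(vcf)
        key = lambda c: (c.chrom, c.start, c.end, c.sample)
        for back in (t, v):
            assert sorted(map(key, back)) == sorted(map(key, calls))
            assert {c.method for c in back} == {"PE_SR"}
            assert all(c.support_pairs is not None for c in back)

    def test_vcf_reader_skips_non_dup_records(self, tmp_path, genome):
        import pysam

        header = pysam.VariantHeader()
        header.contigs.add("chr1", length=1_000_000)
        header.info.add("END", 1, "Integer", "End")
        header.info.add("SVTYPE", 1, "String", "Type")
        path = str(tmp_path / "mix.vcf")
        with pysam.VariantFile(path, "w", header=header) as out:
            for i, svtype in enumerate(["DUP", "DEL", "INV", "DUP"]):
                rec = out.new_record(contig="chr1", start=1000 * (i + 1),
                                     stop=1000 * (i + 1) + 500,
                                     alleles=("N", f"<{svtype}>"), id=f"v{i}")
                rec.info["SVTYPE"] = svtype
                out.write(rec)
        from dupscape import io as dio

        calls = dio.read_calls_vcf(path, method="SR", sample="s1")
        assert [c.id for c in calls] == ["v0", "v3"]

    def test_loci_tsv_round_trip(self, sim_small, tmp_path):
        from dupscape import io as dio

        data = sim_small
        disc = d.discovery_set(data.calls[data.config.species_a], data.genome)
        path = tmp_path / "loci.tsv"
        dio.write_loci_tsv(disc, path)
        back = dio.read_loci_tsv(path)
        assert [(l.chrom, l.start, l.end, l.methods) for l in back] == [
            (l.chrom, l.start, l.end, l.methods) for l in disc
        ]
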