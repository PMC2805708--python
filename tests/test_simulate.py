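"""Synthetic-data generator: digestion, variant planting, read simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rrlsnp as r
from rrlsnp.simulate import (
    READ_LEN,
    ErrorProfile,
    default_samples,
    read_fasta,
    read_sam,
    read_truth,
    emit_outputs,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=300)


class TestDigest:
    def test_enumerated_example(self):
        frags = r.digest("AACCGGTTCCGGAA")
        assert [(f.start, f.end) for f in frags] == [(0, 3), (3, 9), (9, 14)]
        seq = "AACCGGTTCCGGAA"
        assert [seq[f.start : f.end] for f in frags] == ["AAC", "CGGTTC", "CGGAA"]
        assert [f.length for f in frags] == [3, 6, 5]

    def test_no_site_returns_whole_sequence(self):
        assert [(f.start, f.end) for f in r.digest("AAAA")] == [(0, 4)]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            r.digest("")

    @given(dna)
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_conservation_and_tags(self, seq):
        frags = r.digest(seq)
        assert sum(f.length for f in frags) == len(seq)
        assert frags[0].start == 0 and frags[-1].end == len(seq)
        for prev, nxt in zip(frags, frags[1:]):
            assert prev.end == nxt.start
            assert seq[nxt.start : nxt.start + 3] == "CGG"
            assert seq[prev.end - 1] == "C"


class TestGenerateGenome:
    def test_deterministic_and_site_density(self):
        g1 = r.generate_genome(2, 100_000, 0.45, 5.0, seed=7)
        g2 = r.generate_genome(2, 100_000, 0.45, 5.0, seed=7)
        assert g1.chromosomes == g2.chromosomes
        for seq in g1.chromosomes.values():
            n = seq.count("CCGG")
            assert 450 <= n <= 550  # ~500 planted sites
        g3 = r.generate_genome(2, 100_000, 0.45, 5.0, seed=8)
        assert g3.chromosomes != g1.chromosomes

    def test_zero_density_gives_single_fragment(self):
        g = r.generate_genome(2, 5_000, 0.5, 0.0, seed=1)
        for name, seq in g.chromosomes.items():
            assert len(r.digest(seq, name)) == 1

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_chroms": 1},
            {"chrom_length": 500},
            {"gc_fraction": 0.0},
            {"site_density": -1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        defaults = dict(n_chroms=2, chrom_length=10_000, gc_fraction=0.45,
                        site_density=5.0, seed=0)
        defaults.update(kwargs)
        with pytest.raises(ValueError):
            r.generate_genome(**defaults)


@pytest.fixture(scope="module")
def planted():
    genome = r.generate_genome(2, 50_000, 0.45, 5.0, seed=4)
    panel = r.plant_variants(genome, n_snps=200, seed=4)
    return genome, panel


class TestPlantVariants:

    def test_biallelic_and_unique_positions(self, planted):
        genome, panel = planted
        seen = set()
        for v in panel.variants:
            assert v.ref != v.alt and v.ref in "ACGT" and v.alt in "ACGT"
            assert genome.chromosomes[v.chrom][v.pos] == v.ref
            assert (v.chrom, v.pos) not in seen
            seen.add((v.chrom, v.pos))
            assert set(np.unique(v.genotypes)) <= {0, 1, 2}

    def test_class_structure_of_genotypes(self, planted):
        _, panel = planted
        groups = np.array(panel.groups)
        for v in panel.variants:
            cult = v.genotypes[groups == "cultivated"]
            wild = v.genotypes[groups == "wild"]
            if v.klass == "vinifera_only":
                assert 0 < cult.sum() < 2 * len(cult) and wild.sum() == 0
            elif v.klass == "wild_only":
                assert 0 < wild.sum() < 2 * len(wild) and cult.sum() == 0
            elif v.klass == "shared":
                assert 0 < cult.sum() < 2 * len(cult)
                assert 0 < wild.sum() < 2 * len(wild)
            elif v.klass == "fixed":
                assert {cult.sum(), wild.sum()} == {0, 2 * len(wild)} or {
                    cult.sum(), wild.sum()
                } == {2 * len(cult), 0}

    def test_disruption_rate_and_site_overlap(self, planted):
        genome, panel = planted
        n_disrupt = sum(v.disrupts_site for v in panel.variants)
        assert n_disrupt == round(0.05 * 200)
        for v in panel.variants:
            seq = genome.chromosomes[v.chrom]
            in_site = "CCGG" in seq[max(0, v.pos - 3) : v.pos + 4]
            assert in_site == v.disrupts_site

    def test_zero_disruption_avoids_all_sites(self):
        genome = r.generate_genome(2, 30_000, 0.45, 5.0, seed=5)
        panel = r.plant_variants(
            genome, n_snps=50, restriction_disruption_rate=0.0, seed=5
        )
        for v in panel.variants:
            seq = genome.chromosomes[v.chrom]
            assert "CCGG" not in seq[max(0, v.pos - 3) : v.pos + 4]

    def test_all_fixed_mixture_forces_fixed_truth(self):
        genome = r.generate_genome(2, 30_000, 0.45, 5.0, seed=6)
        panel = r.plant_variants(
            genome, n_snps=30,
            class_mix={"fixed": 1.0},
            restriction_disruption_rate=0.0, seed=6,
        )
        groups = np.array(panel.groups)
        for v in panel.variants:
            cult, wild = v.genotypes[groups == "cultivated"], v.genotypes[groups == "wild"]
            assert len(set(cult)) == 1 and len(set(wild)) == 1
            assert abs(int(cult[0]) - int(wild[0])) == 2

    def test_bad_mixture_rejected(self):
        genome = r.generate_genome(2, 30_000, 0.45, 5.0, seed=6)
        with pytest.raises(ValueError):
            r.plant_variants(genome, n_snps=10, class_mix={"shared": 0.9, "fixed": 0.9})

    def test_truth_classes_recovered_from_perfect_counts(self, planted):
        """Segregation classification on error-free genotype-derived read
        counts round-trips the planted class of every variant."""
        _, panel = planted
        groups = np.array(panel.groups)
        for v in panel.variants:
            alt = v.genotypes.astype(int)
            ref = 2 - alt
            seg = r.classify_segregation(ref, alt, groups)
            expected = {
                "vinifera_only": "vinifera_polymorphic",
                "wild_only": "wild_polymorphic",
                "shared": "shared_polymorphic",
                "fixed": "fixed_difference",
            }[v.klass]
            assert seg.value == expected


@pytest.fixture(scope="module")
def clean_run():
    """High-depth, error-free run on a small genome."""
    genome = r.generate_genome(2, 30_000, 0.45, 5.0, seed=9)
    panel = r.plant_variants(genome, n_snps=80, seed=9)
    readset = r.simulate_reads(
        genome, panel, mean_depth=30.0,
        error_profile=ErrorProfile.flat(0.0), seed=9,
    )
    return genome, panel, readset


class TestSimulateReads:

    def test_reads_are_32bp_and_tagged(self, clean_run):
        _, _, readset = clean_run
        assert readset.seq.shape[1] == READ_LEN
        # without sequencing error every read begins with the HpaII tag
        assert readset.tag_fraction() == 1.0

    def test_error_free_mismatches_are_planted_variants(self, clean_run):
        genome, panel, readset = clean_run
        truth = {(v.chrom, v.pos) for v in panel.variants}
        observed = {
            (s.chrom, s.pos) for s in r.aggregate_pileup(readset, genome)
        }
        assert observed <= truth

    def test_size_window_enrichment(self):
        """Fragments inside the preferred size window receive ~10x the
        per-end read share of fragments outside it."""
        genome = r.generate_genome(2, 100_000, 0.45, 5.0, seed=10)
        panel = r.plant_variants(genome, n_snps=10, seed=10)
        readset = r.simulate_reads(genome, panel, mean_depth=5.0, seed=10)
        from rrlsnp.simulate import digest

        depth_in, depth_out, n_in, n_out = 0, 0, 0, 0
        for ci, chrom in enumerate(readset.chroms):
            frags = [
                f for f in digest(genome.chromosomes[chrom], chrom)
                if f.length >= READ_LEN
            ]
            starts = readset.start[readset.chrom_idx == ci]
            counts = np.bincount(starts, minlength=len(genome.chromosomes[chrom]))
            for f in frags[1:-1]:
                reads_here = counts[f.start] + counts[f.end - 30]
                if 40 <= f.length <= 250:
                    depth_in += reads_here
                    n_in += 1
                else:
                    depth_out += reads_here
                    n_out += 1
        assert n_in > 50 and n_out > 20
        ratio = (depth_in / n_in) / (depth_out / n_out)
        assert 5 < ratio < 20

    def test_seed_determinism(self):
        genome = r.generate_genome(2, 20_000, 0.45, 5.0, seed=11)
        panel = r.plant_variants(genome, n_snps=40, seed=11)
        a = r.simulate_reads(genome, panel, mean_depth=5.0, seed=11)
        b = r.simulate_reads(genome, panel, mean_depth=5.0, seed=11)
        assert np.array_equal(a.seq, b.seq)
        assert np.array_equal(a.qual, b.qual)
        assert np.array_equal(a.start, b.start)

    def test_allele_dropout_at_disrupted_sites(self):
        """A haplotype whose variant abolishes the cut is never sequenced
        from that cut.  When both flanking fragments are long, the merged
        fragment's other ends cannot reach the site either, so heterozygous
        carriers show zero alternative-allele reads (with error turned off);
        the reference haplotype is still sequenced."""
        from rrlsnp.simulate import _cut_positions

        genome = r.generate_genome(2, 60_000, 0.45, 5.0, seed=9)
        panel = r.plant_variants(genome, n_snps=160, seed=9)
        readset = r.simulate_reads(
            genome, panel, mean_depth=30.0,
            error_profile=ErrorProfile.flat(0.0), seed=9,
        )
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

        def raw_counts(v, sample_idx):
            """Allele counts at v.pos for one sample, from the reads."""
            ci = readset.chroms.index(v.chrom)
            sel = np.flatnonzero(
                (readset.chrom_idx == ci)
                & (readset.sample_idx == sample_idx)
                & (readset.start <= v.pos)
                & (readset.start + READ_LEN > v.pos)
            )
            out = {}
            for k in sel:
                if readset.strand[k]:
                    base = comp[chr(readset.seq[k][readset.start[k] + READ_LEN - 1 - v.pos])]
                else:
                    base = chr(readset.seq[k][v.pos - readset.start[k]])
                out[base] = out.get(base, 0) + 1
            return out

        het_ref = het_alt = n_checked = 0
        for v in panel.variants:
            if not v.disrupts_site:
                continue
            cuts = np.array(_cut_positions(genome.sequence_bytes(v.chrom)))
            cut = cuts[(cuts >= v.pos - 2) & (cuts <= v.pos + 1)][0]
            others = cuts[cuts != cut]
            if np.min(np.abs(others - cut)) <= 34:
                continue  # a short flank lets the merged fragment leak reads
            n_checked += 1
            for i in np.flatnonzero(v.genotypes == 1):
                per = raw_counts(v, i)
                het_ref += per.get(v.ref, 0)
                het_alt += per.get(v.alt, 0)
        assert n_checked >= 2
        assert het_ref > 20  # reference haplotype is still sequenced
        assert het_alt == 0  # carrying haplotype never sequenced here

    def test_mean_depth_must_be_positive(self):
        genome = r.generate_genome(2, 20_000, 0.45, 5.0, seed=1)
        panel = r.plant_variants(genome, n_snps=10, seed=1)
        with pytest.raises(ValueError):
            r.simulate_reads(genome, panel, mean_depth=0.0)


class TestErrorProfile:
    def test_default_is_nondecreasing_and_bounded(self):
        p = ErrorProfile.default()
        assert np.all(np.diff(p.rates) >= 0)
        assert p.rates.min() >= 0 and p.rates.max() <= 0.25

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            ErrorProfile(rates=np.full(32, 0.5), quality_means=np.full(32, 30.0))
        with pytest.raises(ValueError):
            ErrorProfile(rates=np.full(10, 0.01), quality_means=np.full(10, 30.0))


class TestEmitOutputs:
    def test_round_trips(self, tmp_path):
        genome = r.generate_genome(2, 15_000, 0.45, 5.0, seed=3)
        panel = r.plant_variants(genome, n_snps=40, seed=3)
        readset = r.simulate_reads(genome, panel, mean_depth=8.0, seed=3)
        paths = emit_outputs(readset, panel, genome, tmp_path)

        assert read_fasta(paths["fasta"]) == genome.chromosomes

        rs2 = read_sam(paths["sam"])
        assert len(rs2) == len(readset)
        key = lambda rs, i: (
            rs.samples[rs.sample_idx[i]], int(rs.chrom_idx[i]), int(rs.start[i]),
            int(rs.strand[i]), rs.seq[i].tobytes(),
        )
        assert sorted(key(readset, i) for i in range(len(readset))) == sorted(
            key(rs2, i) for i in range(len(rs2))
        )

        sites1 = list(r.aggregate_pileup(readset, genome))
        sites2 = list(r.read_pileup(paths["pileup"]))
        assert sites1 == sites2

        panel2 = read_truth(paths["truth"])
        assert panel2.samples == panel.samples
        assert len(panel2.variants) == len(panel.variants)
        for v1, v2 in zip(panel.variants, panel2.variants):
            assert (v1.chrom, v1.pos, v1.ref, v1.alt) == (v2.chrom, v2.pos, v2.ref, v2.alt)
            assert np.array_equal(v1.genotypes, v2.genotypes)
            assert v1.disrupts_site == v2.disrupts_site

    def test_empty_readset_gives_valid_files(self, tmp_path):
        genome = r.generate_genome(2, 5_000, 0.45, 0.0, seed=1)
        panel = r.TruthPanel(samples=default_samples(), variants=[])
        empty = r.ReadSet(
            samples=panel.sample_ids, chroms=genome.names,
            sample_idx=np.empty(0, dtype=np.int32),
            chrom_idx=np.empty(0, dtype=np.int32),
            start=np.empty(0, dtype=np.int64),
            strand=np.empty(0, dtype=np.int8),
            seq=np.empty((0, READ_LEN), dtype=np.uint8),
            qual=np.empty((0, READ_LEN), dtype=np.uint8),
        )
        paths = emit_outputs(empty, panel, genome, tmp_path)
        assert list(r.read_pileup(paths["pileup"])) == []
        assert len(read_sam(paths["sam"])) == 0
        assert read_truth(paths["truth"]).variants == []


class TestBlockGenotypes:
    def test_blocks_are_internally_identical_without_noise(self):
        m = r.simulate_block_genotypes(
            n_samples=10, n_sites_per_chrom=60, block_length=5_000,
            site_noise=0.0, seed=2,
        )
        by_block = {}
        for j, (chrom, pos) in enumerate(m.sites):
            by_block.setdefault((chrom, pos // 5_000), []).append(j)
        for idx in by_block.values():
            cols = m.calls[:, idx]
            assert np.all(cols == cols[:, :1])

    def test_no_fixed_or_singleton_blocks(self):
        m = r.simulate_block_genotypes(
            n_samples=10, n_sites_per_chrom=60, site_noise=0.0, seed=3
        )
        alt = m.calls.sum(axis=0)
        assert np.all(alt >= 2) and np.all(alt <= 2 * m.n_samples - 2)

    def test_within_block_ld_stays_high_with_noise(self):
        m = r.simulate_block_genotypes(n_samples=10, n_sites_per_chrom=60, seed=3)
        by_block = {}
        for j, (chrom, pos) in enumerate(m.sites):
            by_block.setdefault((chrom, pos // 5_000), []).append(j)
        r2s = []
        for idx in by_block.values():
            for a, b in zip(idx, idx[1:]):
                v = r.r2_pair(m.calls[:, a], m.calls[:, b])
                if v is not None:
                    r2s.append(v)
        assert np.median(r2s) > 0.5
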