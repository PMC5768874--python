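"""Library simulator: reference generation, capture geometry, damage model."""

import numpy as np
import pytest
from scipy.stats import binom

from osseq import readqc, simlib, varbench
from osseq.simlib import (
    CnaSpec, FfpeModel, VariantSpec,
    make_reference, simulate_library, simulate_roi_coverage,
)


class TestMakeReference:
    def test_seed_determinism(self):
        g1, r1 = make_reference(130, 2, 300, seed=7)
        g2, r2 = make_reference(130, 2, 300, seed=7)
        assert g1 == g2 and r1 == r2

    def test_single_gene_layout(self):
        genome, rois = make_reference(1, 1, 500, seed=0)
        assert list(genome) == ["chr1"]
        assert len(rois) == 1 and rois[0].gene == "GENE001"

    def test_zero_roi_len_rejected(self):
        with pytest.raises(ValueError):
            make_reference(1, 1, 0, seed=0)

    def test_fasta_roundtrip(self, tmp_path):
        genome, _ = make_reference(2, 1, 300, seed=1)
        simlib.write_fasta(genome, tmp_path / "ref.fa")
        assert simlib.read_fasta(tmp_path / "ref.fa") == genome


class TestSpecValidation:
    def test_vaf_bounds(self):
        with pytest.raises(ValueError):
            VariantSpec("chr1", 1, "A", "T", vaf=0.0)
        with pytest.raises(ValueError):
            VariantSpec("chr1", 1, "A", "T", vaf=1.5)

    def test_copy_ratio_positive(self):
        with pytest.raises(ValueError):
            CnaSpec("G", 0.0)

    def test_variant_ref_must_match_reference(self, small_fixture):
        genome, rois, probes = (small_fixture["genome"],
                                small_fixture["rois"],
                                small_fixture["probes"])
        pos = rois[0].start + 50
        wrong = "ACGT"[("ACGT".find(genome["chr1"][pos]) + 1) % 4]
        with pytest.raises(ValueError, match="does not match"):
            simulate_library(genome, rois=rois, probes=probes,
                             variants=[VariantSpec("chr1", pos, wrong, "A",
                                                   vaf=0.5)])

    def test_probe_off_reference_rejected(self, small_fixture):
        from osseq.panel import Probe

        genome, rois = small_fixture["genome"], small_fixture["rois"]
        bogus = Probe("PBAD", "chr1", 2000, "+", "A" * 25,
                      rois[0].roi_id, 9.0, 60.0)
        with pytest.raises(ValueError, match="PBAD"):
            simulate_library(genome, [bogus], rois)


class TestReadEmission:
    def test_clean_reads_match_reference(self, small_fixture):
        lib = simulate_library(
            small_fixture["genome"], small_fixture["probes"],
            small_fixture["rois"], depth_target=100, seed=4,
            seq_error_rate=0.0)
        genome = small_fixture["genome"]
        for r in lib.reads1 + lib.reads2:
            assert genome[r.chrom][r.start:r.end].upper() == r.bases

    def test_read1_begins_with_probe_sequence(self, small_fixture):
        lib = simulate_library(
            small_fixture["genome"], small_fixture["probes"],
            small_fixture["rois"], depth_target=30, seed=4,
            seq_error_rate=0.0)
        for rec, (rid, seq, qual) in zip(lib.truth, lib.fastq1):
            assert rec.pair_id == rid
            assert seq.startswith(lib.probes[rec.probe_id].sequence)
            assert len(seq) == len(qual)

    def test_pair_count_conservation(self, small_fixture, tmp_path):
        lib = simulate_library(
            small_fixture["genome"], small_fixture["probes"],
            small_fixture["rois"], depth_target=50, seed=9,
            duplicate_rate=0.1)
        assert len(lib.fastq1) == len(lib.fastq2) == len(lib.truth)
        lib.write_fastq(tmp_path / "r1.fastq", tmp_path / "r2.fastq")
        n_lines = sum(1 for _ in open(tmp_path / "r1.fastq"))
        assert n_lines == 4 * lib.n_pairs

    def test_full_deamination_without_repair_forces_transitions(
            self, small_fixture):
        genome = small_fixture["genome"]
        lib = simulate_library(
            genome, small_fixture["probes"], small_fixture["rois"],
            depth_target=30, seed=1, seq_error_rate=0.0,
            ffpe_model=FfpeModel(deamination_rate=1.0, repair="off"))
        for rec, r1 in zip(lib.truth, lib.reads1):
            strand = lib.probes[rec.probe_id].strand
            template_c, read_as = (("G", "A") if strand == "+"
                                   else ("C", "T"))
            ref = genome[r1.chrom][r1.start:r1.end].upper()
            for got, want in zip(r1.bases, ref):
                assert got == (read_as if want == template_c else want)

    def test_excision_repair_truncates_instead_of_substituting(
            self, small_fixture):
        genome = small_fixture["genome"]
        lib = simulate_library(
            genome, small_fixture["probes"], small_fixture["rois"],
            depth_target=30, seed=1, seq_error_rate=0.0,
            ffpe_model=FfpeModel(deamination_rate=0.3, repair="excision_on"))
        for r in lib.reads1 + lib.reads2:
            assert genome[r.chrom][r.start:r.end].upper() == r.bases
        # truncation shortens inserts relative to the undamaged library
        clean = simulate_library(
            genome, small_fixture["probes"], small_fixture["rois"],
            depth_target=30, seed=1, seq_error_rate=0.0)
        assert lib.truth_inserts().mean() < clean.truth_inserts().mean()


class TestCaptureGeometry:
    def test_mean_insert_near_100_max_under_fragment_cap(self, small_fixture):
        lib = simulate_library(
            small_fixture["genome"], small_fixture["probes"],
            small_fixture["rois"], n_pairs=30_000, seed=11)
        ins = lib.truth_inserts()
        assert abs(ins.mean() - 100.0) < 5.0
        assert ins.max() <= 700

    def test_insert_truth_reproducible_from_alignments(self, small_fixture,
                                                       tmp_path):
        lib = simulate_library(
            small_fixture["genome"], small_fixture["probes"],
            small_fixture["rois"], depth_target=80, seed=5)
        lib.write_truth_sam(tmp_path / "t.sam")
        pairs = readqc.pairs_from_sam(tmp_path / "t.sam")
        truth = {t.pair_id: t.insert for t in lib.truth}
        assert pairs and all(truth[p.pair_id] == p.insert for p in pairs)

    def test_indel_specs_rejected_at_read_level(self, small_fixture):
        genome, rois = small_fixture["genome"], small_fixture["rois"]
        pos = rois[0].start + 40
        ref = genome["chr1"][pos]
        spec = VariantSpec("chr1", pos, ref, ref + "AA", vaf=0.3,
                           kind="insertion")
        with pytest.raises(ValueError, match="SNV"):
            simulate_library(genome, small_fixture["probes"], rois,
                             variants=[spec])


class TestVafRecovery:
    @pytest.mark.parametrize("vaf", [0.05, 0.25, 0.5])
    def test_observed_alt_fraction_in_99pct_binomial_interval(
            self, small_fixture, vaf):
        genome, rois = small_fixture["genome"], small_fixture["rois"]
        roi = rois[0]
        pos = roi.start + 77
        ref = genome["chr1"][pos]
        alt = "ACGT"[("ACGT".find(ref) + 1) % 4]
        lib = simulate_library(
            genome, small_fixture["probes"], rois,
            variants=[VariantSpec("chr1", pos, ref, alt, vaf=vaf)],
            depth_target=1500, seed=int(vaf * 100), seq_error_rate=0.0)
        piles = varbench.RoiPileups(rois, genome)
        for r in lib.reads1 + lib.reads2:
            piles.add_read(r.chrom, r.start, r.bases)
        site = piles.site("chr1", pos)
        assert site.depth >= 1000
        k = site.counts[alt]
        lo = binom.ppf(0.005, site.depth, vaf)
        hi = binom.ppf(0.995, site.depth, vaf)
        assert lo <= k <= hi


class TestRoiCoverageSim:
    def test_poisson_limit_mean(self):
        df = simulate_roi_coverage(20, 8, mean_depth=1000,
                                   dispersion=np.inf, seed=0,
                                   roi_bias_sd=0.0)
        se = np.sqrt(1000 / len(df))
        assert abs(df["test"].mean() - 1000) < 3 * se

    def test_copy_ratio_scales_gene_mean(self):
        df = simulate_roi_coverage(
            50, 16, cnas=[CnaSpec("GENE001", 4.90)], seed=3)
        amp = df[df.gene == "GENE001"]
        rest = df[df.gene != "GENE001"]
        observed = (amp["test"] / amp["control"]).mean()
        baseline = (rest["test"] / rest["control"]).mean()
        assert observed / baseline == pytest.approx(4.90, rel=0.08)

    def test_seed_changes_matrix(self):
        a = simulate_roi_coverage(5, 4, seed=1)
        b = simulate_roi_coverage(5, 4, seed=2)
        assert not a.equals(b)
        assert a.equals(simulate_roi_coverage(5, 4, seed=1))

    def test_coverage_tsv_roundtrip(self, tmp_path):
        df = simulate_roi_coverage(3, 2, seed=5)
        simlib.write_coverage_tsv(df, tmp_path / "cov.tsv")
        back = simlib.read_coverage_tsv(tmp_path / "cov.tsv")
        assert back["test"].tolist() == df["test"].tolist()


def test_repair_off_has_higher_ct_ag_ratio_at_equal_seed(small_fixture,
                                                         tmp_path):
    """The deamination signature (C>T/G>A fraction of SNVs) must drop when
    excision repair removes the damaged bases."""
    genome, rois, probes = (small_fixture["genome"], small_fixture["rois"],
                            small_fixture["probes"])
    # spike a couple of non-signature somatic variants so the denominator
    # is never empty
    specs = []
    for roi in rois:
        for off in (60, 160):
            pos = roi.start + off
            ref = genome["chr1"][pos]
            alt = {"A": "C", "C": "G", "G": "C", "T": "G"}[ref]
            specs.append(VariantSpec("chr1", pos, ref, alt, vaf=0.4))

    def signature(repair):
        lib = simulate_library(
            genome, probes, rois, variants=specs, depth_target=400,
            seed=23, seq_error_rate=0.0,
            ffpe_model=FfpeModel(deamination_rate=0.05, repair=repair))
        piles = varbench.RoiPileups(rois, genome)
        for r in lib.reads1 + lib.reads2:
            piles.add_read(r.chrom, r.start, r.bases)
        snvs = [(s.ref, s.alt_allele()[0])
                for s in piles.candidate_sites(min_alt_reads=3)]
        return varbench.ct_ag_ratio(snvs)

    off_ratio = signature("off")
    on_ratio = signature("excision_on")
    assert off_ratio is not None and on_ratio is not None
    assert off_ratio > on_ratio
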