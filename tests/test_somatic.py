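"""MAF parsing, flanking windows, candidate set difference, neomer extraction."""

import numpy as np
import pytest

from neomerkit import (
    DataIntegrityError,
    FormatError,
    Genome,
    build_kmer_index,
    build_windows,
    candidate_kmers,
    extract_neomers,
    read_maf,
)
from neomerkit.fixtures import brute_force_neomers
from neomerkit.kmers import kmer_strings
from neomerkit.somatic import SomaticMutation, read_neomer_tsv, write_neomer_tsv
from tests.conftest import random_sequence

MAF_HEADER = (
    "Tumor_Sample_Barcode\tChromosome\tStart_Position\tEnd_Position\t"
    "Reference_Allele\tTumor_Seq_Allele2\tVariant_Type\tVariant_Classification"
)


def _maf(tmp_path, rows, header=MAF_HEADER):
    p = tmp_path / "test.maf"
    p.write_text("#version test\n" + header + "\n" + "\n".join(rows) + "\n")
    return p


def _snp(sample="s1", chrom="chr1", pos=5, ref="A", alt="G", **kw):
    return SomaticMutation(sample, chrom, pos, pos, ref, alt, "SNP", "Missense_Mutation", **kw)


class TestReadMaf:
    def test_rows_in_order(self, tmp_path):
        p = _maf(
            tmp_path,
            [
                "s1\tchr1\t5\t5\tA\tG\tSNP\tMissense_Mutation",
                "s2\tchr1\t7\t7\tT\tC\tSNP\tSilent",
                "s1\tchr2\t3\t4\tAC\tGT\tDNP\tMissense_Mutation",
            ],
        )
        muts = read_maf(p)
        assert [m.sample_id for m in muts] == ["s1", "s2", "s1"]
        m = muts[0]
        assert (m.start, m.end, m.ref_allele, m.alt_allele, m.variant_type) == (
            5, 5, "A", "G", "SNP",
        )

    def test_missing_required_column_named(self, tmp_path):
        header = MAF_HEADER.replace("\tVariant_Type", "")
        p = _maf(tmp_path, ["s1\tchr1\t5\t5\tA\tG\tSilent"], header=header)
        with pytest.raises(FormatError, match="Variant_Type"):
            read_maf(p)

    def test_bad_position_row_skipped(self, tmp_path):
        p = _maf(
            tmp_path,
            [
                "s1\tchr1\tfive\t5\tA\tG\tSNP\tSilent",
                "s2\tchr1\t7\t7\tT\tC\tSNP\tSilent",
            ],
        )
        muts = read_maf(p)
        assert len(muts) == 1 and muts[0].sample_id == "s2"

    def test_extra_columns_preserved(self, tmp_path):
        p = _maf(
            tmp_path,
            ["s1\tchr1\t5\t5\tA\tG\tSNP\tSilent\tx"],
            header=MAF_HEADER + "\tCustom",
        )
        assert read_maf(p)[0].extra == {"Custom": "x"}


class TestBuildWindows:
    # genome chr1="ACGTACGTAA"; with k=4 the k+30 flank clips to the contig
    def test_snp_substitution(self, toy_genome):
        w = build_windows(toy_genome, _snp(), k=4)
        assert w.ref_seq == "ACGTACGTAA"
        assert w.alt_seq == "ACGTGCGTAA"
        assert (w.window_start, w.window_end) == (1, 10)

    def test_insertion_between_start_and_end(self, toy_genome):
        mut = SomaticMutation("s1", "chr1", 4, 5, "-", "TT", "INS", "")
        w = build_windows(toy_genome, mut, k=4)
        assert w.alt_seq == "ACGTTTACGTAA"

    def test_deletion(self, toy_genome):
        mut = SomaticMutation("s1", "chr1", 5, 5, "A", "-", "DEL", "")
        w = build_windows(toy_genome, mut, k=4)
        assert w.alt_seq == "ACGTCGTAA"

    def test_ref_mismatch_reports_position(self, toy_genome):
        with pytest.raises(DataIntegrityError, match="chr1:5"):
            build_windows(toy_genome, _snp(ref="C"), k=4)

    def test_unknown_contig(self, toy_genome):
        with pytest.raises(DataIntegrityError, match="chrX"):
            build_windows(toy_genome, _snp(chrom="chrX"), k=4)

    def test_flank_is_k_plus_30(self):
        seq = "A" * 200 + "C" + "A" * 200
        genome = Genome({"c": seq})
        mut = SomaticMutation("s", "c", 201, 201, "C", "G", "SNP", "")
        w = build_windows(genome, mut, k=6)
        assert len(w.ref_seq) == 2 * 36 + 1  # k+30 flanks around 1-base edit
        assert w.ref_seq[w.edit_offset] == "C"


class TestCandidateKmers:
    def test_snp_candidates_by_set_difference(self, toy_genome):
        w = build_windows(toy_genome, _snp(), k=4)
        expected = kmer_strings(w.alt_seq, 4) - kmer_strings(w.ref_seq, 4)
        assert candidate_kmers(w, 4, canonical=False) == expected
        assert expected == {"CGTG", "GTGC", "TGCG", "GCGT"}

    def test_identity_edit_yields_nothing(self, toy_genome):
        w = build_windows(toy_genome, _snp(ref="A", alt="A"), k=4)
        assert candidate_kmers(w, 4, canonical=False) == set()

    def test_insertion_candidates(self, toy_genome):
        mut = SomaticMutation("s1", "chr1", 4, 5, "-", "TT", "INS", "")
        w = build_windows(toy_genome, mut, k=4)
        expected = kmer_strings("ACGTTTACGTAA", 4) - kmer_strings("ACGTACGTAA", 4)
        assert candidate_kmers(w, 4, canonical=False) == expected


class TestExtractNeomers:
    def test_toy_snp_against_brute_force(self, toy_genome):
        idx = build_kmer_index(toy_genome, 4, canonical=False)
        records = extract_neomers([_snp()], toy_genome, idx, 4)
        expected = brute_force_neomers(toy_genome, _snp(), 4, canonical=False)
        assert {r.kmer for r in records} == expected
        assert all(not idx.contains(r.kmer) for r in records)
        assert all(r.sample_id == "s1" for r in records)

    def test_membership_veto(self):
        # the mutated sequence only creates k-mers already in the genome
        genome = Genome({"c": "AAAAAAACAAAAAAA" + "T" * 20})
        idx = build_kmer_index(genome, 4, canonical=False)
        mut = SomaticMutation("s", "c", 8, 8, "C", "A", "SNP", "")
        assert extract_neomers([mut], genome, idx, 4) == []

    def test_empty_input(self, toy_genome, toy_index_forward):
        assert extract_neomers([], toy_genome, toy_index_forward, 4) == []

    def test_duplicate_flagging_within_sample(self, rng):
        # two mutations in one sample engineered to create one shared k-mer
        seq = random_sequence(rng, 400)
        genome = Genome({"c": seq})
        idx = build_kmer_index(genome, 5, canonical=False)
        m1 = SomaticMutation("s", "c", 100, 100, seq[99], _flip(seq[99]), "SNP", "")
        records = extract_neomers([m1, m1], genome, idx, 5)
        kmers1 = {r.kmer for r in records if not r.duplicate}
        dup = {r.kmer for r in records if r.duplicate}
        assert dup == kmers1  # second pass re-emits every k-mer, flagged

    def test_mismatch_skip_flag(self, toy_genome, toy_index_forward):
        bad = _snp(ref="C")
        with pytest.raises(DataIntegrityError):
            extract_neomers([bad], toy_genome, toy_index_forward, 4)
        assert extract_neomers(
            [bad], toy_genome, toy_index_forward, 4, skip_mismatch=True
        ) == []


def _flip(base):
    return {"A": "G", "C": "T", "G": "A", "T": "C"}[base]


class TestOracleEquivalence:
    @pytest.mark.parametrize("canonical", [False, True])
    def test_windowed_pipeline_matches_whole_genome_difference(self, canonical):
        """Spot-check of the somatic oracle; the full 200-instance sweep runs
        in the acceptance suite."""
        rng = np.random.default_rng(7)
        for trial in range(20):
            seq = random_sequence(rng, int(rng.integers(300, 1500)))
            genome = Genome({"c": seq})
            k = int(rng.integers(5, 9))
            pos = int(rng.integers(k + 35, len(seq) - k - 35))
            mut = SomaticMutation(
                "s", "c", pos, pos, seq[pos - 1], _flip(seq[pos - 1]), "SNP", ""
            )
            idx = build_kmer_index(genome, k, canonical=canonical)
            got = {r.kmer for r in extract_neomers([mut], genome, idx, k)}
            assert got == brute_force_neomers(genome, mut, k, canonical)

    def test_monotone_edit_null(self, rng):
        """A 'mutation' whose alt equals its ref yields zero records."""
        seq = random_sequence(rng, 500)
        genome = Genome({"c": seq})
        idx = build_kmer_index(genome, 6)
        for pos in (50, 250, 450):
            mut = SomaticMutation("s", "c", pos, pos, seq[pos - 1], seq[pos - 1], "SNP", "")
            assert extract_neomers([mut], genome, idx, 6) == []


def test_neomer_tsv_roundtrip(tmp_path, toy_genome):
    idx = build_kmer_index(toy_genome, 4, canonical=False)
    records = extract_neomers(
        [_snp(cancer_type="GBM", organ="Brain", stage="II")], toy_genome, idx, 4
    )
    assert records
    path = tmp_path / "neomers.tsv"
    write_neomer_tsv(records, path, {"note": "test"})
    assert path.read_text().startswith("#neomerkit=")
    assert read_neomer_tsv(path) == records
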