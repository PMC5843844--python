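"""Filtering-cascade semantics: quality, merging, barcodes, isotype, consensus."""

import numpy as np
import pytest

from igpipe import (
    PipelineConfig,
    assign_isotype,
    barcode_consensus,
    extract_barcode,
    median_phred_filter,
    merge_pairs,
    orient_read,
    process_read_pairs,
    revcomp,
    trim_primers,
)
from igpipe.readproc import MergedRead, TrimmedRead

from conftest import make_read
from oracles import group_certainty, longest_exact_overlap


def _rand_dna(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


class TestMedianPhredFilter:
    def test_high_quality_read_passes(self, config):
        assert median_phred_filter(make_read("ACGT" * 10, qual=40), config)

    def test_median_exactly_34_fails(self, config):
        # the filter is a strict inequality
        assert not median_phred_filter(make_read("ACGT" * 10, qual=34), config)

    def test_even_length_median_is_mean_of_central_pair(self, config):
        read = make_read("ACGT")
        read.quals = np.array([30, 33, 35, 40])
        assert float(np.median(read.quals)) == 34.0
        assert not median_phred_filter(read, config)

    def test_empty_read_raises(self, config):
        with pytest.raises(ValueError):
            median_phred_filter(make_read(""), config)


class TestMergePairs:
    def _pair(self, mol, l1, l2, q1=38, q2=38):
        fwd = make_read(mol[:l1], qual=q1, rid="p")
        rev = make_read(revcomp(mol[len(mol) - l2:]), qual=q2, rid="p")
        return fwd, rev

    def test_sixty_base_overlap_yields_expected_length(self, config):
        mol = _rand_dna(240, seed=0)
        fwd, rev = self._pair(mol, 150, 150)  # true overlap 60
        merged = merge_pairs(fwd, rev, config)
        assert merged is not None
        assert merged.bases == mol
        assert merged.overlap_length == 60
        assert len(merged.bases) == 150 + 150 - 60

    def test_exactly_fifty_base_overlap_discarded(self, config):
        mol = _rand_dna(250, seed=1)
        fwd, rev = self._pair(mol, 150, 150)  # true overlap 50: fails strict > 50
        assert merge_pairs(fwd, rev, config) is None

    def test_single_mismatch_in_overlap_discards(self, config):
        mol = _rand_dna(240, seed=2)
        fwd, rev = self._pair(mol, 150, 150)
        bases = list(rev.bases)
        # rev position 120 sits inside the 60 nt overlap after reverse complement
        bases[120] = {"A": "C", "C": "A", "G": "T", "T": "G"}[bases[120]]
        rev.bases = "".join(bases)
        # the exhaustive scan confirms no qualifying exact overlap remains
        assert longest_exact_overlap(fwd.bases, revcomp(rev.bases)) <= 50
        assert merge_pairs(fwd, rev, config) is None

    def test_overlap_quality_takes_per_position_maximum(self, config):
        mol = _rand_dna(240, seed=3)
        fwd, rev = self._pair(mol, 150, 150, q1=30, q2=40)
        merged = merge_pairs(fwd, rev, config)
        assert list(np.unique(merged.quals[:90])) == [30]     # fwd-only
        assert list(np.unique(merged.quals[90:150])) == [40]  # overlap max
        assert list(np.unique(merged.quals[150:])) == [40]    # rev-only


def _as_merged(bases, qual=38):
    return MergedRead(id="m", bases=bases, quals=np.full(len(bases), qual,
                      dtype=np.int16), overlap_length=60, source_ids=("m", "m"))


class TestOrientRead:
    def test_sense_read_unchanged(self, clean_run, scheme):
        amplicon = clean_run["molecules"][0].sequence
        oriented, status = orient_read(_as_merged(amplicon), scheme)
        assert status == "oriented"
        assert oriented.bases == amplicon

    def test_orientation_is_involutive(self, clean_run, scheme):
        amplicon = clean_run["molecules"][0].sequence
        o1, _ = orient_read(_as_merged(amplicon), scheme)
        o2, _ = orient_read(_as_merged(revcomp(amplicon)), scheme)
        assert o1.bases == o2.bases
        assert np.array_equal(o1.quals, o2.quals)

    def test_handle_free_read_unassigned(self, scheme):
        oriented, status = orient_read(_as_merged(_rand_dna(200, seed=4)), scheme)
        assert oriented is None and status == "unassigned"

    def test_handle_on_both_strands_is_chimeric(self, scheme):
        bases = scheme.handle + _rand_dna(50, seed=5) + revcomp(scheme.handle)
        oriented, status = orient_read(_as_merged(bases), scheme)
        assert oriented is None and status == "chimeric"


class TestExtractBarcode:
    def test_template_conformant_barcode_extracted(self, scheme):
        read = _as_merged(scheme.handle + "ACGTTGGGGTAAAA" + _rand_dna(40, seed=6))
        bc, status = extract_barcode(read, scheme)
        assert status == "ok" and bc == "ACGTTGGGGTAAAA"

    def test_non_T_at_conserved_position_rejected(self, scheme):
        read = _as_merged(scheme.handle + "ACGTAGGGGTAAAA" + _rand_dna(40, seed=6))
        bc, status = extract_barcode(read, scheme)
        assert bc is None and status == "conserved_base"

    def test_truncated_barcode_rejected(self, scheme):
        read = _as_merged(scheme.handle + "ACGTTGGGGTAAA")  # 13 nt then EOF
        bc, status = extract_barcode(read, scheme)
        assert bc is None and status == "truncated_barcode"

    def test_extraction_from_oriented_three_prime_end(self, clean_run, scheme):
        mol = clean_run["molecules"][0]
        bc, status = extract_barcode(_as_merged(mol.sequence), scheme)
        assert status == "ok" and bc == mol.barcode


class TestAssignIsotype:
    def test_exact_constant_prefix_scores_41_shared_kmers(self, toy, config):
        refs, _ = toy
        allele_id = next(a for a, (iso, _) in refs.constants.items() if iso == "IGHM")
        c50 = refs.constants[allele_id][1][:50]
        read = _rand_dna(30, seed=7) + c50 + _rand_dna(20, seed=8)
        call = assign_isotype(read, refs.constants, config)
        assert call is not None
        assert call.isotype == "IGHM"
        assert call.kmer_score == 50 - 10 + 1
        assert call.margin > 0

    def test_unrelated_sequence_is_ambiguous(self, toy, config):
        refs, _ = toy
        assert assign_isotype("A" * 120, refs.constants, config) is None

    def test_read_shorter_than_k_raises(self, toy, config):
        refs, _ = toy
        with pytest.raises(ValueError):
            assign_isotype("ACGTACGT", refs.constants, config)

    def test_error_free_mixture_fully_recovered(self, clean_run, toy, config):
        refs, _ = toy
        for mol in clean_run["molecules"]:
            call = assign_isotype(mol.sequence, refs.constants, config)
            assert call is not None and call.isotype == mol.isotype


class TestTrimPrimers:
    def test_round_trip_recovers_true_insert(self, clean_run, toy, config):
        refs, scheme = toy
        for mol in clean_run["molecules"][:10]:
            call = assign_isotype(mol.sequence, refs.constants, config)
            trimmed, status = trim_primers(_as_merged(mol.sequence), scheme, call,
                                           mol.barcode, config)
            assert status == "ok"
            assert trimmed.bases == mol.insert

    def test_three_fr1_mismatches_rejected(self, clean_run, toy, config):
        refs, scheme = toy
        mol = clean_run["molecules"][0]
        call = assign_isotype(mol.sequence, refs.constants, config)
        bases = list(mol.sequence)
        for i in (2, 7, 12):
            bases[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[bases[i]]
        trimmed, status = trim_primers(_as_merged("".join(bases)), scheme, call,
                                       mol.barcode, config)
        assert trimmed is None and status == "no_fr1_primer"

    def test_empty_insert_rejected(self, toy, config):
        refs, scheme = toy
        primer = scheme.vh_fr1_primers["VH1-FR1"]
        allele_id = next(iter(refs.constants))
        c50 = refs.constants[allele_id][1][:50]
        call = assign_isotype("A" * 30 + c50, refs.constants, config)
        bases = primer + c50 + revcomp("ACGTTGGGGTAAAA") + revcomp(scheme.handle)
        trimmed, status = trim_primers(_as_merged(bases), scheme, call,
                                       "ACGTTGGGGTAAAA", config)
        assert trimmed is None and status == "empty_insert"


def _member(bases, qual=38):
    return TrimmedRead(id="t", bases=bases, quals=np.full(len(bases), qual,
                       dtype=np.int16), fr1_primer="VH1-FR1",
                       barcode="ACGTTGGGGTAAAA", isotype="IGHM")


class TestBarcodeConsensus:
    def test_identical_members_certainty_one(self, config):
        seq = _rand_dna(90, seed=9)
        rec, status = barcode_consensus([_member(seq)] * 3, config)
        assert status == "ok"
        assert rec.certainty == 1.0 and rec.consensus == seq and rec.support == 3

    def test_singleton_retained_with_vacuous_agreement(self, config):
        seq = _rand_dna(90, seed=10)
        rec, status = barcode_consensus([_member(seq)], config)
        assert status == "ok" and rec.certainty == 1.0 and rec.support == 1

    def test_divergent_member_certainty_matches_tally_oracle(self, config):
        seq = _rand_dna(100, seed=11)
        div = list(seq)
        rng = np.random.default_rng(12)
        for i in rng.choice(100, size=30, replace=False):
            div[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[div[i]]
        members = [_member(seq)] * 3 + [_member("".join(div))]
        rec, status = barcode_consensus(members, config)
        expected = group_certainty([seq, seq, seq, "".join(div)])
        assert status == "ok"
        assert rec.certainty == pytest.approx(expected, rel=1e-12)
        assert rec.consensus == seq  # 3-vs-1 plurality restores the majority

    def test_low_certainty_group_discarded(self, config):
        seq = _rand_dna(100, seed=13)
        div = list(seq)
        rng = np.random.default_rng(14)
        for i in rng.choice(100, size=50, replace=False):
            div[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[div[i]]
        rec, status = barcode_consensus([_member(seq), _member("".join(div))], config)
        assert rec is None and status == "low_certainty"
        assert group_certainty([seq, "".join(div)]) <= 0.80

    def test_off_length_members_dropped_before_scoring(self, config):
        seq = _rand_dna(90, seed=15)
        members = [_member(seq)] * 2 + [_member(seq[:60])]
        rec, status = barcode_consensus(members, config)
        assert status == "ok"
        assert rec.support == 2 and rec.n_members == 3

    def test_empty_group_raises(self, config):
        with pytest.raises(ValueError):
            barcode_consensus([], config)


class TestCascadeConservation:
    def test_zero_error_run_has_no_rejects(self, clean_run):
        ledger = clean_run["ledger"]
        assert (ledger["stage_reached"] == "retained").all()
        assert (ledger["reject_reason"] == "").all()

    def test_ledger_conserves_input_count(self, toy):
        from igpipe import RepertoireSimParams, simulate_reads, simulate_repertoire

        refs, scheme = toy
        params = RepertoireSimParams(seed=21, n_clones=20, molecules_per_clone=2,
                                     seq_error_rate=0.005, reads_per_molecule=4)
        mols, _ = simulate_repertoire(params, refs, scheme)
        pairs, _ = simulate_reads(mols, params)
        records, ledger, counts = process_read_pairs(pairs, scheme, refs.constants)
        assert len(ledger) == len(pairs)
        retained = (ledger["stage_reached"] == "retained").sum()
        rejected = (ledger["reject_reason"] != "").sum()
        assert retained + rejected == len(pairs)
        # reads reaching grouping equal reads entering the consensus stage
        assert counts["consensus"]["in"] == counts["trim"]["out"]

    def test_each_retained_read_in_exactly_one_group(self, clean_run):
        ledger = clean_run["ledger"]
        retained = ledger[ledger["stage_reached"] == "retained"]
        support = sum(r.n_members for r in clean_run["records"])
        assert support == len(retained)
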