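"""Amplicon alignment, indel calling and protein consequences."""

import re

import numpy as np
import pytest
from Bio.Seq import Seq

import crisprtile as ct
from crisprtile.alleles import (
    AlleleError,
    AlleleRecord,
    ReadAlignment,
    UnalignableReadError,
    _alignment_events,
    align_read,
    allele_table,
    call_indel,
    frame_group_compare,
    left_normalize,
    protein_consequence,
)
from crisprtile.simulate import apply_descriptor

from conftest import gene_for

D = ct.IndelDescriptor


@pytest.fixture(scope="module")
def locus():
    """20-residue gene with an amplicon spanning the whole CDS, cut at nt 30."""
    gene = gene_for("MKTAYIAKQRLEHGFDSWVC")
    amp = ct.Amplicon(gene.cds_seq, cds_offset=0, frame_anchor=0,
                      cut_pos_amplicon=30)
    return gene, amp


class TestAlignRead:
    def test_identical_read_has_no_gaps(self, locus):
        _, amp = locus
        aln = align_read(amp, amp.seq)
        assert "-" not in aln.ref_aln and "-" not in aln.read_aln
        assert aln.score == 2 * len(amp.seq)

    def test_three_nt_deletion_single_gap(self, locus):
        _, amp = locus
        read = amp.seq[:30] + amp.seq[33:]
        aln = align_read(amp, read)
        assert aln.read_aln.count("-") == 3
        # one contiguous gap
        assert re.search(r"-+", aln.read_aln).group() == "---"

    def test_deletion_in_repeat_left_normalized(self):
        # AAA run: gap placement is ambiguous; events must come out leftmost
        seq = "CGTCTGAAAAAGTCTGGTCTACTGATC"
        amp = ct.Amplicon(seq, 0, 0, 10)
        read = seq[:7] + seq[10:]  # remove 3 of the 5 As
        aln = align_read(amp, read)
        events = _alignment_events(amp, aln)
        assert len(events) == 1
        assert events[0].kind == "del"
        assert events[0].ref_start == 6  # leftmost A of the run
        assert seq[6] == "A" and seq[5] != "A"

    def test_garbage_read_rejected(self, locus):
        _, amp = locus
        with pytest.raises(UnalignableReadError):
            align_read(amp, "TTTTAAAATTTTAAAATTTTAAAATTTTAAAA" * 2)

    def test_wrong_length_rejected(self, locus):
        _, amp = locus
        with pytest.raises(UnalignableReadError):
            align_read(amp, amp.seq[:10])


class TestCallIndel:
    def test_deletion_at_cut(self, locus):
        _, amp = locus
        # delete [29, 32); flanks differ so this is already left-normal
        read = amp.seq[:29] + amp.seq[32:]
        desc = call_indel(amp, align_read(amp, read))
        assert (desc.start, desc.ref_len, desc.alt) == (29, 3, "")

    def test_distant_mismatch_is_noise(self, locus):
        _, amp = locus
        pos = amp.cut_pos_amplicon - 30
        base = "A" if amp.seq[pos] != "A" else "C"
        read = amp.seq[:pos] + base + amp.seq[pos + 1 :]
        assert call_indel(amp, align_read(amp, read), window_halfwidth=20) is None

    def test_mismatch_inside_window_is_substitution(self, locus):
        _, amp = locus
        pos = amp.cut_pos_amplicon + 2
        base = "A" if amp.seq[pos] != "A" else "C"
        read = amp.seq[:pos] + base + amp.seq[pos + 1 :]
        desc = call_indel(amp, align_read(amp, read))
        assert (desc.start, desc.ref_len, desc.alt) == (pos, 1, base)

    def test_compound_event_flagged(self, locus):
        _, amp = locus
        cut = amp.cut_pos_amplicon
        # deletion at the cut plus a mismatch 6 nt downstream
        read = amp.seq[:cut] + amp.seq[cut + 3 :]
        mpos = cut + 6 - 3  # coordinates after the deletion
        base = "A" if read[mpos] != "A" else "C"
        read = read[:mpos] + base + read[mpos + 1 :]
        desc = call_indel(amp, align_read(amp, read))
        assert desc is not None and desc.compound

    def test_insertion_at_cut(self, locus):
        _, amp = locus
        cut = amp.cut_pos_amplicon
        read = amp.seq[:cut] + "T" + amp.seq[cut:]
        desc = call_indel(amp, align_read(amp, read))
        norm = left_normalize(amp, desc)
        assert norm.ref_len == 0 and len(norm.alt) == 1


class TestProteinConsequence:
    @pytest.mark.parametrize(
        "desc,expected",
        [
            (D(12, 3, ""), ("Y5del", "in_frame")),          # drop codon 5
            (D(12, 6, "GAATAT"), ("Y5_I6delinsEY", "in_frame")),
            (D(12, 6, "GAAATT"), ("Y5E", "in_frame")),      # I6 re-created
            (D(30, 3, "CTG"), ("L11=", "synonymous")),      # CTT -> CTG
            (D(18, 3, "GTT"), ("A7V", "in_frame")),
            (D(24, 1, ""), ("Q9fs", "frameshift")),
            (D(25, 0, "G"), ("Q9fs", "frameshift")),
            (D(9, 0, "GAA"), ("T3_A4insE", "in_frame")),
            (D(9, 6, ""), ("A4_Y5del", "in_frame")),
            (None, ("WT", "WT")),
        ],
    )
    def test_named_consequences(self, locus, desc, expected):
        gene, amp = locus
        assert protein_consequence(gene, amp, desc) == expected

    def test_outside_cds_is_noncoding(self, locus):
        gene, _ = locus
        padded = ct.Amplicon("ACGTACGTAC" + gene.cds_seq, cds_offset=10,
                             frame_anchor=0, cut_pos_amplicon=40)
        assert protein_consequence(gene, padded, D(2, 3, ""))[0] == "noncoding"

    def test_frame_class_follows_net_length_mod_three(self, locus):
        gene, amp = locus
        rng = np.random.default_rng(21)
        for _ in range(60):
            start = int(rng.integers(3, 40))
            ref_len = int(rng.integers(0, 7))
            alt = "".join(rng.choice(list("ACGT"), rng.integers(0, 7)))
            cons, fclass = protein_consequence(gene, amp, D(start, ref_len, alt))
            if (len(alt) - ref_len) % 3 != 0:
                assert fclass == "frameshift" and cons.endswith("fs")

    def test_left_normalized_descriptor_same_consequence(self, locus):
        gene, amp = locus
        rng = np.random.default_rng(22)
        checked = 0
        for _ in range(80):
            start = int(rng.integers(3, 40))
            if rng.random() < 0.5:
                desc = D(start, 3, "")
            else:
                desc = D(start, 0, "".join(rng.choice(list("ACGT"), 3)))
            norm = left_normalize(amp, desc)
            if norm != desc:
                checked += 1
                assert protein_consequence(gene, amp, desc) == \
                    protein_consequence(gene, amp, norm)
        assert checked > 5


def apply_hgvs(protein: str, hgvs: str) -> str:
    """Independent applier: alternate protein implied by the HGVS string."""
    if hgvs in ("WT",) or hgvs.endswith("="):
        return protein
    m = re.fullmatch(r"([A-Z])(\d+)_([A-Z])(\d+)delins([A-Z]+)", hgvs)
    if m:
        a, b = int(m.group(2)), int(m.group(4))
        return protein[: a - 1] + m.group(5) + protein[b:]
    m = re.fullmatch(r"([A-Z])(\d+)delins([A-Z]+)", hgvs)
    if m:
        a = int(m.group(2))
        return protein[: a - 1] + m.group(3) + protein[a:]
    m = re.fullmatch(r"([A-Z])(\d+)_([A-Z])(\d+)del", hgvs)
    if m:
        a, b = int(m.group(2)), int(m.group(4))
        return protein[: a - 1] + protein[b:]
    m = re.fullmatch(r"([A-Z])(\d+)del", hgvs)
    if m:
        a = int(m.group(2))
        return protein[: a - 1] + protein[a:]
    m = re.fullmatch(r"([A-Z])(\d+)_([A-Z])(\d+)ins([A-Z]+)", hgvs)
    if m:
        a = int(m.group(2))
        return protein[:a] + m.group(5) + protein[a:]
    m = re.fullmatch(r"([A-Z])(\d+)([A-Z])", hgvs)
    if m:
        a = int(m.group(2))
        return protein[: a - 1] + m.group(3) + protein[a:]
    raise ValueError(f"unparsed consequence {hgvs!r}")


def test_in_frame_retranslation_self_consistency(locus):
    """Translating the alternate CDS reproduces the protein the HGVS-like
    string implies, for random in-frame descriptors."""
    gene, amp = locus
    rng = np.random.default_rng(23)
    checked = 0
    for _ in range(120):
        start = int(rng.integers(3, 45))
        ref_len = int(rng.choice([0, 3, 6]))
        alt_len = max(0, ref_len + int(rng.choice([-3, 0, 3])))
        alt = "".join(rng.choice(list("ACGT"), alt_len))
        if ref_len == 0 and not alt:
            continue
        desc = D(start, ref_len, alt)
        cons, fclass = protein_consequence(gene, amp, desc)
        if fclass not in ("in_frame", "synonymous", "WT"):
            continue
        alt_cds = apply_descriptor(gene.cds_seq, desc)
        translated = str(Seq(alt_cds).translate(to_stop=True))
        if len(translated) != len(gene.protein_seq) + desc.net // 3:
            continue  # premature stop: name refers to the truncated product
        assert translated == apply_hgvs(gene.protein_seq, cons)
        checked += 1
    assert checked >= 40


class TestAlleleTable:
    def _reads(self, amp, spec):
        return [apply_descriptor(amp.seq, d) for d in spec]

    def test_rpm_sums_and_lfc_formula(self, locus):
        gene, amp = locus
        del3 = D(29, 3, "")
        reads = {
            1: self._reads(amp, [None, None, del3, del3]),
            9: self._reads(amp, [None, None, None, del3]),
        }
        recs = allele_table(reads, amp, gene)
        by = {r.consequence: r for r in recs}
        for day in (1, 9):
            assert sum(r.rpm_by_timepoint[day] for r in recs) == pytest.approx(1e6)
        wt = by["WT"]
        assert wt.lfc_vs_day1[9] == pytest.approx(
            np.log2(7.5e5 + 1) - np.log2(5e5 + 1)
        )
        assert by["WT"].lfc_vs_day1[1] == 0.0

    def test_equal_rpm_gives_zero_lfc(self, locus):
        gene, amp = locus
        reads = {1: [amp.seq] * 3, 9: [amp.seq] * 5}
        recs = allele_table(reads, amp, gene)
        assert recs[0].lfc_vs_day1[9] == 0.0

    def test_allele_absent_at_reference_excluded(self, locus):
        gene, amp = locus
        del3 = D(29, 3, "")
        reads = {1: [amp.seq] * 3, 9: [apply_descriptor(amp.seq, del3)] * 3}
        recs = allele_table(reads, amp, gene)
        assert [r.consequence for r in recs] == ["WT"]

    def test_missing_reference_day_rejected(self, locus):
        gene, amp = locus
        with pytest.raises(AlleleError):
            allele_table({9: [amp.seq]}, amp, gene, reference_day=1)

    def test_sorted_by_reference_abundance(self, locus):
        gene, amp = locus
        del3 = D(29, 3, "")
        reads = {1: [apply_descriptor(amp.seq, del3)] * 3 + [amp.seq]}
        recs = allele_table(reads, amp, gene)
        assert recs[0].consequence != "WT"


def _record(cons, fclass, lfc):
    rec = AlleleRecord(cons, fclass, None)
    rec.lfc_vs_day1 = {9: lfc}
    rec.rpm_by_timepoint = {9: 0.0, 1: 0.0}
    return rec


class TestFrameGroupCompare:
    def test_identical_distributions_not_significant(self):
        recs = [_record(f"A{i}fs", "frameshift", v)
                for i, v in enumerate([-1, -2, -3, -4])]
        recs += [_record(f"A{i}del", "in_frame", v)
                 for i, v in enumerate([-1, -2, -3, -4])]
        out = frame_group_compare(recs)
        assert out.pvalue > 0.9

    def test_separated_groups_significant(self):
        recs = [_record(f"A{i}fs", "frameshift", -4 - 0.1 * i) for i in range(5)]
        recs += [_record(f"A{i}del", "in_frame", 0.1 * i) for i in range(5)]
        out = frame_group_compare(recs)
        assert out.statistic == 0.0  # frameshift uniformly lower
        assert out.pvalue < 0.05
        assert out.median_frameshift < out.median_in_frame

    def test_missing_class_informative_error(self):
        recs = [_record(f"A{i}fs", "frameshift", -1.0) for i in range(4)]
        with pytest.raises(AlleleError, match="in-frame"):
            frame_group_compare(recs)


def test_simulated_fraction_recovery_within_binomial_ci(locus):
    """50/50 WT / 3-nt deletion at 1000 reads: recovered day-1 fractions
    fall inside the binomial 99% CI."""
    gene, amp = locus
    specs = [
        ct.AlleleSpec(None, 0.5, 1.0),
        ct.AlleleSpec(D(29, 3, ""), 0.5, 1.0),
    ]
    reads, truth = ct.simulate_amplicon_reads(
        gene, amp, specs, days=(1,), n_reads=1000,
        rng=np.random.default_rng(31),
    )
    recs = allele_table(reads, amp, gene)
    frac = {r.consequence: r.rpm_by_timepoint[1] / 1e6 for r in recs}
    half = 2.576 * np.sqrt(0.25 / 1000)
    for cons in truth["consequence"]:
        assert abs(frac[cons] - 0.5) < half
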