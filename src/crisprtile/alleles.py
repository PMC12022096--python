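"""Single-locus editing analysis: indel calling and allele tracking.

Amplicon reads are globally aligned to the reference (match +2, mismatch
-4, gap open -12, gap extend -1); indels are left-normalized so that
equivalent gap placements yield one canonical descriptor.  Edits are only
trusted inside an editing window around the Cas9 cut (Cas9 repair outcomes
concentrate there); isolated events outside the window are treated as
sequencing noise.  Alleles are keyed by their protein-level consequence in
an HGVS-like notation (A372del, I141_C142delinsEI, L235=, G237V, Q236fs),
and tracked over timepoints as RPM and LFC versus the reference day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .library_io import GeneModel
from . import qc


class AlleleError(ValueError):
    pass


class UnalignableReadError(AlleleError):
    pass


@dataclass(frozen=True)
class Amplicon:
    """A PCR amplicon anchored to the gene model.

    ``cds_offset`` is the amplicon position where CDS coordinate
    ``frame_anchor`` begins; ``cut_pos_amplicon`` is the blunt-cut
    position in amplicon coordinates.
    """

    seq: str
    cds_offset: int
    frame_anchor: int
    cut_pos_amplicon: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not 0 <= self.cut_pos_amplicon <= len(self.seq):
            raise AlleleError("cut position outside the amplicon")
        if self.cds_offset < 0 or self.frame_anchor < 0:
            raise AlleleError("negative anchor coordinates")

    def to_cds(self, amplicon_pos: int) -> int:
        return self.frame_anchor + (amplicon_pos - self.cds_offset)


@dataclass(frozen=True)
class IndelDescriptor:
    """A replacement of ``ref_len`` reference bases at ``start`` by ``alt``.

    Coordinates are 0-based on the amplicon.  Pure deletions have
    ``alt == ''``; pure insertions have ``ref_len == 0``; substitutions
    have ``len(alt) == ref_len``.
    """

    start: int
    ref_len: int
    alt: str
    compound: bool = False

    @property
    def net(self) -> int:
        return len(self.alt) - self.ref_len


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -4
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


@dataclass
class ReadAlignment:
    """Gapped reference/read pair with score."""

    ref_aln: str
    read_aln: str
    score: float


def align_read(
    amplicon: Amplicon, read: str, min_score_frac: float = 0.4
) -> ReadAlignment:
    """Global alignment of a read to the amplicon.

    Reads scoring below ``min_score_frac * 2 * len(read)`` are rejected as
    unalignable.  Among equal-scoring alignments the first reported is
    taken; indels are left-normalized downstream, so the choice does not
    affect called descriptors.
    """
    read = read.upper()
    if not 0.5 * len(amplicon.seq) <= len(read) <= 1.5 * len(amplicon.seq):
        raise UnalignableReadError(
            f"read length {len(read)} outside [0.5, 1.5] x amplicon length"
        )
    alns = _ALIGNER.align(amplicon.seq, read)
    aln = alns[0]
    if aln.score < min_score_frac * 2 * len(read):
        raise UnalignableReadError(
            f"alignment score {aln.score} below floor "
            f"{min_score_frac * 2 * len(read):.1f}"
        )
    return ReadAlignment(str(aln[0]), str(aln[1]), float(aln.score))


def _left_normalize_deletion(ref: str, start: int, length: int) -> int:
    while start > 0 and ref[start - 1] == ref[start + length - 1]:
        start -= 1
    return start


def _left_normalize_insertion(ref: str, pos: int, alt: str) -> tuple[int, str]:
    while pos > 0 and alt and ref[pos - 1] == alt[-1]:
        alt = ref[pos - 1] + alt[:-1]
        pos -= 1
    return pos, alt


@dataclass(frozen=True)
class _Event:
    kind: str  # "del", "ins", "sub"
    ref_start: int
    ref_end: int  # half-open; == ref_start for insertions
    alt: str


def _alignment_events(amplicon: Amplicon, alignment: ReadAlignment) -> list[_Event]:
    """Extract left-normalized mismatch/indel events from a gapped pair."""
    ref_aln, read_aln = alignment.ref_aln, alignment.read_aln
    ref = amplicon.seq
    events: list[_Event] = []
    rpos = 0  # reference coordinate
    i = 0
    n = len(ref_aln)
    while i < n:
        a, b = ref_aln[i], read_aln[i]
        if a != "-" and b != "-":
            if a != b:
                events.append(_Event("sub", rpos, rpos + 1, b))
            rpos += 1
            i += 1
        elif b == "-":  # deletion from the reference
            j = i
            while j < n and read_aln[j] == "-":
                j += 1
            length = j - i
            start = _left_normalize_deletion(ref, rpos, length)
            events.append(_Event("del", start, start + length, ""))
            rpos += length
            i = j
        else:  # insertion into the reference
            j = i
            while j < n and ref_aln[j] == "-":
                j += 1
            alt = read_aln[i:j]
            pos, alt = _left_normalize_insertion(ref, rpos, alt)
            events.append(_Event("ins", pos, pos, alt))
            i = j
    return events


def call_indel(
    amplicon: Amplicon,
    alignment: ReadAlignment,
    window_halfwidth: int = 20,
) -> IndelDescriptor | None:
    """Merge edit events near the cut into one descriptor.

    Events overlapping [cut - w, cut + w] merge into a single replacement
    descriptor; events wholly outside are ignored as sequencing noise.
    Returns None for a (window-)wild-type read.  Multiple disjoint events
    inside the window produce a compound-flagged descriptor.
    """
    cut = amplicon.cut_pos_amplicon
    lo, hi = cut - window_halfwidth, cut + window_halfwidth
    events = [
        e
        for e in _alignment_events(amplicon, alignment)
        if (e.ref_start < hi and e.ref_end > lo)
        or (e.kind == "ins" and lo <= e.ref_start <= hi)
    ]
    if not events:
        return None
    ref = amplicon.seq
    start = min(e.ref_start for e in events)
    end = max(e.ref_end for e in events)
    # rebuild the alternate segment by applying events right-to-left
    alt = ref[start:end]
    for e in sorted(events, key=lambda e: e.ref_start, reverse=True):
        s, t = e.ref_start - start, e.ref_end - start
        alt = alt[:s] + e.alt + alt[t:]
    desc = IndelDescriptor(start, end - start, alt, compound=len(events) > 1)
    # re-left-normalize the merged descriptor when it is a pure indel
    if desc.ref_len and not desc.alt:
        s = _left_normalize_deletion(ref, desc.start, desc.ref_len)
        desc = IndelDescriptor(s, desc.ref_len, "", desc.compound)
    elif desc.alt and not desc.ref_len:
        p, a = _left_normalize_insertion(ref, desc.start, desc.alt)
        desc = IndelDescriptor(p, 0, a, desc.compound)
    return desc


def left_normalize(amplicon: Amplicon, desc: IndelDescriptor) -> IndelDescriptor:
    """Canonical leftmost placement of a pure-indel descriptor."""
    ref = amplicon.seq
    # trim shared flanks so equivalent replacements compare equal
    start, ref_len, alt = desc.start, desc.ref_len, desc.alt
    ref_seg = ref[start : start + ref_len]
    while ref_seg and alt and ref_seg[0] == alt[0]:
        ref_seg, alt, start, ref_len = ref_seg[1:], alt[1:], start + 1, ref_len - 1
    while ref_seg and alt and ref_seg[-1] == alt[-1]:
        ref_seg, alt, ref_len = ref_seg[:-1], alt[:-1], ref_len - 1
    if ref_len and not alt:
        start = _left_normalize_deletion(ref, start, ref_len)
    elif alt and not ref_len:
        start, alt = _left_normalize_insertion(ref, start, alt)
    return IndelDescriptor(start, ref_len, alt, desc.compound)


def protein_consequence(
    gene_model: GeneModel,
    amplicon: Amplicon,
    descriptor: IndelDescriptor | None,
) -> tuple[str, str]:
    """HGVS-like protein consequence and frame class for one descriptor.

    Returns e.g. ('A372del', 'in_frame'), ('I141_C142delinsEI', 'in_frame'),
    ('L235=', 'synonymous'), ('G237V', 'in_frame'), ('Q236fs', 'frameshift'),
    ('WT', 'WT').  A descriptor outside the CDS yields ('noncoding', 'WT').
    """
    if descriptor is None:
        return "WT", "WT"
    cds = gene_model.cds_seq
    prot = gene_model.protein_seq
    s = amplicon.to_cds(descriptor.start)
    e = s + descriptor.ref_len
    if e <= 0 or s >= len(cds):
        return "noncoding", "WT"
    if s < 0 or e > len(cds):
        return "noncoding", "WT"
    if descriptor.net % 3 != 0:
        first = min(s // 3, len(prot) - 1)
        return f"{prot[first]}{first + 1}fs", "frameshift"
    alt_cds = cds[:s] + descriptor.alt + cds[e:]
    alt_prot = str(Seq(alt_cds).translate(to_stop=True))
    # trim the longest common prefix, then suffix
    a = 0
    while a < min(len(prot), len(alt_prot)) and prot[a] == alt_prot[a]:
        a += 1
    b = 0
    while (
        b < min(len(prot), len(alt_prot)) - a
        and prot[len(prot) - 1 - b] == alt_prot[len(alt_prot) - 1 - b]
    ):
        b += 1
    deleted = prot[a : len(prot) - b]
    inserted = alt_prot[a : len(alt_prot) - b]
    if not deleted and not inserted:
        if alt_cds == cds:
            return "WT", "WT"
        pos = min(s // 3 + 1, len(prot))
        return f"{prot[pos - 1]}{pos}=", "synonymous"
    if not inserted:
        if len(deleted) == 1:
            return f"{deleted}{a + 1}del", "in_frame"
        return (
            f"{deleted[0]}{a + 1}_{deleted[-1]}{a + len(deleted)}del",
            "in_frame",
        )
    if not deleted:
        # insertion between residues a and a+1
        left = f"{prot[a - 1]}{a}" if a >= 1 else "N0"
        right = f"{prot[a]}{a + 1}" if a < len(prot) else "C*"
        return f"{left}_{right}ins{inserted}", "in_frame"
    if len(deleted) == 1 and len(inserted) == 1:
        return f"{deleted}{a + 1}{inserted}", "in_frame"
    if len(deleted) == 1:
        return f"{deleted}{a + 1}delins{inserted}", "in_frame"
    return (
        f"{deleted[0]}{a + 1}_{deleted[-1]}{a + len(deleted)}delins{inserted}",
        "in_frame",
    )


@dataclass
class AlleleRecord:
    """One allele (keyed by protein consequence) tracked over timepoints."""

    consequence: str
    frame_class: str
    descriptor: IndelDescriptor | None
    counts_by_day: dict[int, int] = field(default_factory=dict)
    rpm_by_timepoint: dict[int, float] = field(default_factory=dict)
    lfc_vs_day1: dict[int, float] = field(default_factory=dict)


def classify_read(
    read: str,
    amplicon: Amplicon,
    gene_model: GeneModel,
    window_halfwidth: int = 20,
) -> tuple[str, str, IndelDescriptor | None]:
    """Align one read and return (consequence, frame_class, descriptor)."""
    aln = align_read(amplicon, read)
    desc = call_indel(amplicon, aln, window_halfwidth)
    consequence, frame_class = protein_consequence(gene_model, amplicon, desc)
    return consequence, frame_class, desc


def allele_table(
    reads_by_day: Mapping[int, Sequence[str]],
    amplicon: Amplicon,
    gene_model: GeneModel,
    reference_day: int = 1,
    min_reads: int = 1,
    window_halfwidth: int = 20,
) -> list[AlleleRecord]:
    """Per-allele RPM and LFC-vs-reference-day from timepoint read sets.

    RPM is per million aligned reads; unalignable reads are dropped.
    Alleles with fewer than ``min_reads`` reads at the reference day are
    excluded.  Records are sorted by reference-day abundance, descending.
    """
    if reference_day not in reads_by_day:
        raise AlleleError(f"reference day {reference_day} has no reads")
    records: dict[str, AlleleRecord] = {}
    aligned_totals: dict[int, int] = {}
    for day, reads in sorted(reads_by_day.items()):
        n_aligned = 0
        for read in reads:
            try:
                cons, fclass, desc = classify_read(
                    read, amplicon, gene_model, window_halfwidth
                )
            except UnalignableReadError:
                continue
            n_aligned += 1
            rec = records.setdefault(cons, AlleleRecord(cons, fclass, desc))
            rec.counts_by_day[day] = rec.counts_by_day.get(day, 0) + 1
        aligned_totals[day] = n_aligned
    if aligned_totals[reference_day] == 0:
        raise AlleleError("no alignable reads at the reference day")
    out: list[AlleleRecord] = []
    for rec in records.values():
        if rec.counts_by_day.get(reference_day, 0) < min_reads:
            continue
        for day, total in aligned_totals.items():
            c = rec.counts_by_day.get(day, 0)
            rec.rpm_by_timepoint[day] = c / total * 1e6 if total else 0.0
        ref_rpm = rec.rpm_by_timepoint[reference_day]
        for day in aligned_totals:
            rec.lfc_vs_day1[day] = float(
                np.log2(rec.rpm_by_timepoint[day] + 1) - np.log2(ref_rpm + 1)
            )
        out.append(rec)
    out.sort(key=lambda r: -r.rpm_by_timepoint[reference_day])
    return out


def allele_frame(records: Sequence[AlleleRecord]) -> pd.DataFrame:
    """Allele records as a tidy DataFrame (one row per allele)."""
    days = sorted({d for r in records for d in r.rpm_by_timepoint})
    data: dict[str, list] = {
        "consequence": [r.consequence for r in records],
        "frame_class": [r.frame_class for r in records],
    }
    for d in days:
        data[f"rpm_d{d}"] = [r.rpm_by_timepoint.get(d, 0.0) for r in records]
    for d in days:
        data[f"lfc_d{d}"] = [r.lfc_vs_day1.get(d, np.nan) for r in records]
    return pd.DataFrame(data)


@dataclass(frozen=True)
class FrameComparison:
    statistic: float
    pvalue: float
    median_frameshift: float
    median_in_frame: float
    day: int


def frame_group_compare(
    records: Sequence[AlleleRecord], day: int | None = None
) -> FrameComparison:
    """Rank-sum comparison of frameshift vs in-frame allele LFCs at a day."""
    days = sorted({d for r in records for d in r.lfc_vs_day1})
    if day is None:
        day = days[-1]
    fs = [r.lfc_vs_day1[day] for r in records if r.frame_class == "frameshift"]
    inf = [r.lfc_vs_day1[day] for r in records if r.frame_class == "in_frame"]
    if len(fs) < 3 or len(inf) < 3:
        raise AlleleError(
            f"need >=3 alleles per class, got {len(fs)} frameshift / "
            f"{len(inf)} in-frame"
        )
    u, p = qc.rank_sum_compare(fs, inf)
    return FrameComparison(
        u, p, float(np.median(fs)), float(np.median(inf)), day
    )
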