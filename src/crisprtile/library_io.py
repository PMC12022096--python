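"""Gene models and sgRNA tiling libraries.

Coordinate conventions
----------------------
CDS coordinates are 0-based half-open internally; protein positions are
1-based in all user-facing output.  ``cut_pos`` counts the number of CDS
nucleotides 5' of the blunt SpCas9 cut, which falls between protospacer
positions 17 and 18 (3 bp 5' of the NGG PAM).

Multi-exon genes are out of scope: the CDS must be supplied pre-spliced.
Guides whose protospacer matches the CDS in more than one place cannot be
given a unique cut site and are rejected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

CATEGORIES = ("CDS", "NEG", "POS", "NT")
_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
_NT = set("ACGT")


class LibraryError(ValueError):
    """Malformed library or gene model input."""


class UnmappedGuideError(LibraryError):
    """A CDS-category protospacer with no exact match on either strand."""


class AmbiguousGuideError(LibraryError):
    """A protospacer matching the CDS at more than one site."""


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GeneModel:
    """A single-gene coding model: spliced CDS plus its protein sequence.

    ``cds_seq`` is the coding strand 5'->3' and includes the stop codon;
    ``protein_seq`` excludes the stop.
    """

    gene_id: str
    cds_seq: str
    protein_seq: str

    def __post_init__(self) -> None:
        cds = self.cds_seq.upper()
        prot = self.protein_seq.upper()
        object.__setattr__(self, "cds_seq", cds)
        object.__setattr__(self, "protein_seq", prot)
        if set(cds) - _NT:
            raise LibraryError(
                f"{self.gene_id}: CDS contains non-ACGT characters: "
                f"{sorted(set(cds) - _NT)}"
            )
        if set(prot) - _STANDARD_AA:
            raise LibraryError(
                f"{self.gene_id}: protein contains non-standard residues: "
                f"{sorted(set(prot) - _STANDARD_AA)}"
            )
        if len(cds) != 3 * (len(prot) + 1):
            raise LibraryError(
                f"{self.gene_id}: CDS length {len(cds)} != 3*(n_residues+1) "
                f"= {3 * (len(prot) + 1)}"
            )
        translated = str(Seq(cds).translate())
        if translated != prot + "*":
            raise LibraryError(
                f"{self.gene_id}: CDS does not translate to protein followed "
                "by a single stop"
            )

    @property
    def n_residues(self) -> int:
        return len(self.protein_seq)

    @classmethod
    def from_cds(cls, gene_id: str, cds_seq: str) -> "GeneModel":
        """Build a model from a CDS alone, translating internally."""
        prot = str(Seq(cds_seq.upper()).translate())
        if not prot.endswith("*"):
            raise LibraryError(f"{gene_id}: CDS does not end in a stop codon")
        return cls(gene_id, cds_seq, prot[:-1])

    @classmethod
    def from_fasta(cls, path: str | Path, gene_id: str | None = None) -> "GeneModel":
        """Load from FASTA: one CDS record, optionally one protein record.

        With a single record the protein is obtained by translation.  With
        two records the nucleotide one is taken as the CDS and the other as
        the protein, and consistency is checked.
        """
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise LibraryError(f"{path}: no FASTA records")
        nts = [r for r in records if not set(str(r.seq).upper()) - _NT]
        if len(nts) != 1:
            raise LibraryError(f"{path}: expected exactly one nucleotide record")
        cds = str(nts[0].seq)
        gid = gene_id or nts[0].id
        others = [r for r in records if r is not nts[0]]
        if not others:
            return cls.from_cds(gid, cds)
        if len(others) > 1:
            raise LibraryError(f"{path}: more than one protein record")
        return cls(gid, cds, str(others[0].seq))


@dataclass(frozen=True)
class SgRNA:
    """One guide: 20-nt protospacer plus placement on the gene model.

    ``residues`` are the 1-based protein positions flanking the cut (one or
    two consecutive positions); empty for control guides.
    """

    sgrna_id: str
    protospacer: str
    category: str
    strand: str | None = None
    cut_pos: int | None = None
    residues: tuple[int, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise LibraryError(
                f"{self.sgrna_id}: protospacer must be 20 nt, got "
                f"{len(self.protospacer)}"
            )
        if set(self.protospacer.upper()) - _NT:
            raise LibraryError(f"{self.sgrna_id}: non-ACGT protospacer")
        if self.category not in CATEGORIES:
            raise LibraryError(
                f"{self.sgrna_id}: category {self.category!r} not one of "
                f"{CATEGORIES}"
            )
        if self.category == "CDS":
            if self.cut_pos is None or not self.residues:
                raise LibraryError(
                    f"{self.sgrna_id}: CDS guide must have cut_pos and residues"
                )
        elif self.cut_pos is not None or self.residues:
            raise LibraryError(
                f"{self.sgrna_id}: control guide must not carry a placement"
            )


@dataclass
class Library:
    """A tiling library over one gene, controls included."""

    sgrnas: list[SgRNA]
    gene: GeneModel
    _by_id: dict[str, SgRNA] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [g.sgrna_id for g in self.sgrnas]
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise LibraryError(f"duplicate sgrna_ids: {dups}")
        self._by_id = {g.sgrna_id: g for g in self.sgrnas}

    def __len__(self) -> int:
        return len(self.sgrnas)

    def __getitem__(self, sgrna_id: str) -> SgRNA:
        return self._by_id[sgrna_id]

    @property
    def sgrna_ids(self) -> list[str]:
        return [g.sgrna_id for g in self.sgrnas]

    def category_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.sgrnas:
            out[g.category] = out.get(g.category, 0) + 1
        return out

    def cds_sgrnas(self) -> list[SgRNA]:
        return [g for g in self.sgrnas if g.category == "CDS"]

    def to_frame(self) -> pd.DataFrame:
        """Guide annotation as a DataFrame indexed by sgrna_id."""
        return pd.DataFrame(
            {
                "protospacer": [g.protospacer for g in self.sgrnas],
                "category": [g.category for g in self.sgrnas],
                "strand": [g.strand or "NA" for g in self.sgrnas],
                "cut_pos": [g.cut_pos for g in self.sgrnas],
                "residues": [";".join(map(str, g.residues)) for g in self.sgrnas],
                "label": [g.label for g in self.sgrnas],
            },
            index=pd.Index(self.sgrna_ids, name="sgrna_id"),
        )


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def map_protospacer(gene_model: GeneModel, protospacer: str) -> tuple[str, int]:
    """Locate a 20-nt protospacer on the CDS and return (strand, cut_pos).

    The protospacer is searched exactly on the coding strand ('+') and as
    its reverse complement ('-').  The blunt cut sits between protospacer
    nt 17 and 18, so cut_pos = match_start + 17 on '+' and match_start + 3
    on '-' (all coordinates on the coding strand, 0-based).
    """
    proto = protospacer.upper()
    if len(proto) != 20:
        raise LibraryError(f"protospacer must be 20 nt, got {len(proto)}")
    if set(proto) - _NT:
        raise LibraryError("non-ACGT protospacer")
    rc = revcomp(proto)
    hits = [("+", s) for s in _find_all(gene_model.cds_seq, proto)]
    if rc != proto:
        hits += [("-", s) for s in _find_all(gene_model.cds_seq, rc)]
    if not hits:
        raise UnmappedGuideError(f"protospacer {proto} not found on the CDS")
    if rc == proto:  # palindromic: strand, hence cut site, is ambiguous
        raise AmbiguousGuideError(
            f"protospacer {proto} is its own reverse complement"
        )
    if len(hits) > 1:
        raise AmbiguousGuideError(
            f"protospacer {proto} matches the CDS at {len(hits)} sites; "
            "cannot assign a unique cut site"
        )
    strand, start = hits[0]
    cut_pos = start + 17 if strand == "+" else start + 3
    return strand, cut_pos


def assign_residues(gene_model: GeneModel, cut_pos: int) -> tuple[int, ...]:
    """1-based codon indices of the two nucleotides flanking the cut.

    {floor((cut_pos-1)/3)+1, floor(cut_pos/3)+1}, clipped to the protein:
    two consecutive residues when the cut neighbourhood spans a codon
    boundary, one residue when both flanking nucleotides share a codon.
    """
    if not 0 <= cut_pos <= len(gene_model.cds_seq):
        raise LibraryError(f"cut_pos {cut_pos} outside the CDS")
    n = gene_model.n_residues
    cands = {(cut_pos - 1) // 3 + 1, cut_pos // 3 + 1}
    residues = tuple(sorted(r for r in cands if 1 <= r <= n))
    if len(residues) < len(cands):
        warnings.warn(
            f"cut_pos {cut_pos} flanks nucleotides outside residues 1..{n} "
            "(stop codon region); clipped",
            stacklevel=2,
        )
    return residues


def guide_label(gene_model: GeneModel, residues: tuple[int, ...]) -> str:
    """Guide name of the form 'sgQ58/K59' (or 'sgT7' for one residue)."""
    parts = [f"{gene_model.protein_seq[r - 1]}{r}" for r in residues]
    return "sg" + "/".join(parts)


def parse_library(path: str | Path, gene_model: GeneModel) -> Library:
    """Load a guide table (TSV/CSV: sgrna_id, protospacer, category[, label]).

    CDS guides are placed on the gene model via exact protospacer matching;
    control guides (NEG/POS/NT) pass through without placement.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"sgrna_id", "protospacer", "category"}
    missing = required - set(df.columns)
    if missing:
        raise LibraryError(f"{path}: missing columns {sorted(missing)}")
    protos = df["protospacer"].str.upper()
    dup_mask = protos.duplicated(keep=False)
    if dup_mask.any():
        groups = df[dup_mask].groupby(protos[dup_mask])["sgrna_id"].agg(list)
        detail = "; ".join(f"{p}: {ids}" for p, ids in groups.items())
        raise LibraryError(f"{path}: duplicate protospacers ({detail})")
    sgrnas = []
    unmapped = []
    for row in df.itertuples(index=False):
        cat = row.category.strip().upper()
        proto = row.protospacer.strip().upper()
        if cat == "CDS":
            try:
                strand, cut_pos = map_protospacer(gene_model, proto)
            except UnmappedGuideError:
                unmapped.append(row.sgrna_id)
                continue
            residues = assign_residues(gene_model, cut_pos)
            label = getattr(row, "label", "") or guide_label(gene_model, residues)
            sgrnas.append(
                SgRNA(row.sgrna_id, proto, cat, strand, cut_pos, residues, label)
            )
        else:
            label = getattr(row, "label", "") or ""
            sgrnas.append(SgRNA(row.sgrna_id, proto, cat, label=label))
    if unmapped:
        raise UnmappedGuideError(
            f"{path}: CDS guides with no exact CDS match: {unmapped}"
        )
    lib = Library(sgrnas, gene_model)
    logger.info("loaded %d sgRNAs: %s", len(lib), lib.category_counts())
    return lib


def write_library(library: Library, path: str | Path) -> None:
    library.to_frame().to_csv(path, sep="\t")


def residue_coverage(library: Library, gene_model: GeneModel | None = None) -> float:
    """Fraction of protein positions assigned to at least one CDS guide."""
    gene = gene_model or library.gene
    covered: set[int] = set()
    for g in library.cds_sgrnas():
        covered.update(g.residues)
    return len(covered & set(range(1, gene.n_residues + 1))) / gene.n_residues
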