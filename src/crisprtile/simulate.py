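"""Synthetic tiling screens with known truth.

The generator emulates the statistical structure of a single-gene CRISPR
tiling screen: a random coding gene, an NGG-constrained guide library with
positive/negative/non-targeting controls, multi-arm count matrices and
single-locus amplicon read sets.

Model
-----
Guide abundances start lognormal (one plasmid pool shared by every arm and
replicate).  Depletion is exponential in population doublings: after D
doublings a Cas9-arm guide's expected abundance is multiplied by
2^(-D * activity * effect), where ``effect`` is the per-doubling log2
depletion of the targeted residues and ``activity`` the guide's on-target
editing efficiency (Beta-distributed).  Drug arms additionally multiply
guides in resistance regions by 2^(+D * enrich_effect * in_frame_prob *
activity).  Parental (Cas9-negative) arms are untouched.  Observed counts
are negative binomial around depth x relative abundance.  Every draw is
reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .library_io import (
    GeneModel,
    Library,
    SgRNA,
    assign_residues,
    guide_label,
    map_protospacer,
    revcomp,
    AmbiguousGuideError,
    UnmappedGuideError,
)
from .quant import CountMatrix, SampleMeta
from .alleles import Amplicon, IndelDescriptor, left_normalize, protein_consequence

_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOPS = ("TAA", "TAG", "TGA")

# Human coding sequence is GC3-rich; weighting codons by GC content gives a
# realistic NGG (PAM) density, without which a tiling library cannot reach
# the ~0.475 residue coverage an NGG-restricted design attains on a real
# kinase CDS.
_CODON_WEIGHTS = np.array(
    [1.8 ** sum(ch in "GC" for ch in c) for c in _CODONS]
)
_CODON_WEIGHTS = _CODON_WEIGHTS / _CODON_WEIGHTS.sum()


@dataclass(frozen=True)
class ArmSpec:
    """One screen arm: which cell line, treatment and sampling days."""

    cell_line: str = "CAS9"
    treatment: str = "none"
    days: tuple[int, ...] = (0, 14)
    doublings_per_day: float = 1.0


@dataclass(frozen=True)
class RegionSpec:
    """An essential residue window with per-doubling log2 depletion."""

    start: int
    end: int
    effect: float


@dataclass(frozen=True)
class ResistanceSpec:
    """A residue window whose in-frame edits enrich under drug."""

    start: int
    end: int
    enrich_effect: float
    in_frame_prob: float = 0.66


@dataclass(frozen=True)
class NoiseSpec:
    """Count-noise model: NB dispersion, depth, initial-abundance spread."""

    nb_dispersion: float = 0.008
    depth: int = 1_000_000
    initial_sigma: float = 0.5


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a full-scale simulated tiling screen.

    Defaults mirror the screened system: a 393-residue kinase, ~0.475 of
    residues covered by NGG-placable guides, 24 negative / 18 positive /
    10 non-targeting controls, two replicates, 14 doublings at one per
    day, sequenced at 1e6 reads per sample.
    """

    seed: int = 0
    n_residues: int = 393
    n_neg: int = 24
    n_pos: int = 18
    n_nt: int = 10
    pos_effect: float = 0.5
    activity_alpha: float = 5.0
    activity_beta: float = 2.0
    target_coverage: float | None = 0.475
    n_replicates: int = 2
    arms: tuple[ArmSpec, ...] = (
        ArmSpec("PAR", "none", (0, 14)),
        ArmSpec("CAS9", "none", (0, 7, 14)),
    )
    essential_regions: tuple[RegionSpec, ...] = ()
    resistance_regions: tuple[ResistanceSpec, ...] = ()
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        for r in self.essential_regions:
            if not 1 <= r.start <= r.end <= self.n_residues:
                raise ValueError(f"region {r} outside 1..{self.n_residues}")
            if r.effect < 0:
                raise ValueError("effects must be >= 0")
        if self.noise.nb_dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_gene(
    config: SimulationConfig | None = None,
    n_residues: int | None = None,
    rng: np.random.Generator | None = None,
    gene_id: str = "SIMGENE",
) -> GeneModel:
    """A random coding gene: ATG start, no internal stops, one final stop."""
    config = config or SimulationConfig()
    n = n_residues or config.n_residues
    if n < 30:
        raise ValueError("need at least 30 residues")
    rng = rng if rng is not None else config.rng()
    body = rng.choice(_CODONS, size=n - 1, p=_CODON_WEIGHTS)
    stop = _STOPS[rng.integers(len(_STOPS))]
    cds = "ATG" + "".join(body) + stop
    return GeneModel.from_cds(gene_id, cds)


def _pam_candidates(gene: GeneModel) -> list[str]:
    """All 20-mers with an NGG immediately 3' on either strand of the CDS."""
    cds = gene.cds_seq
    protos = []
    for s in range(0, len(cds) - 22):
        if cds[s + 21 : s + 23] == "GG":
            protos.append(cds[s : s + 20])
    for s in range(3, len(cds) - 19):
        if cds[s - 3 : s - 1] == "CC":
            protos.append(revcomp(cds[s : s + 20]))
    return protos


def design_library(
    gene_model: GeneModel,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
    min_cds_guides: int = 30,
) -> tuple[Library, pd.Series]:
    """NGG-constrained tiling library plus per-guide activity draws.

    Duplicate and multi-mapping protospacers are dropped; when
    ``target_coverage`` is set the CDS guides are randomly subsampled to
    just reach that residue coverage.  Control protospacers are random
    20-mers absent from the CDS.
    """
    config = config or SimulationConfig()
    rng = rng if rng is not None else config.rng()
    cds = gene_model.cds_seq
    placed = []
    seen: set[str] = set()
    for proto in _pam_candidates(gene_model):
        if proto in seen:
            continue
        seen.add(proto)
        try:
            strand, cut = map_protospacer(gene_model, proto)
        except (AmbiguousGuideError, UnmappedGuideError):
            continue
        residues = assign_residues(gene_model, cut)
        if residues:
            placed.append((proto, strand, cut, residues))
    if len(placed) < min_cds_guides:
        raise ValueError(
            f"only {len(placed)} placable guides; gene too short or GG-poor"
        )
    if config.target_coverage is not None:
        order = rng.permutation(len(placed))
        covered: set[int] = set()
        goal = config.target_coverage * gene_model.n_residues
        chosen = []
        for i in order:
            chosen.append(placed[i])
            covered.update(placed[i][3])
            if len(covered) >= goal:
                break
        placed = sorted(chosen, key=lambda t: t[2])
    sgrnas = [
        SgRNA(
            f"CDS_{i:03d}",
            proto,
            "CDS",
            strand,
            cut,
            residues,
            guide_label(gene_model, residues),
        )
        for i, (proto, strand, cut, residues) in enumerate(placed)
    ]
    forbidden = set(seen) | {revcomp(p) for p in seen}
    for cat, n_ctrl in (("NEG", config.n_neg), ("POS", config.n_pos),
                        ("NT", config.n_nt)):
        made = 0
        while made < n_ctrl:
            proto = "".join(rng.choice(list("ACGT"), size=20))
            if proto in forbidden or proto in cds or revcomp(proto) in cds:
                continue
            forbidden.add(proto)
            forbidden.add(revcomp(proto))
            sgrnas.append(SgRNA(f"{cat}_{made:02d}", proto, cat))
            made += 1
    lib = Library(sgrnas, gene_model)
    activities = pd.Series(
        rng.beta(config.activity_alpha, config.activity_beta, size=len(lib)),
        index=lib.sgrna_ids,
        name="activity",
    )
    return lib, activities


def _guide_effects(
    library: Library, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-guide (essential effect, enrich effect, in-frame prob)."""
    ess = np.zeros(len(library))
    enr = np.zeros(len(library))
    ifp = np.zeros(len(library))
    for i, g in enumerate(library.sgrnas):
        if g.category == "POS":
            ess[i] = config.pos_effect
        elif g.category == "CDS":
            for r in config.essential_regions:
                if any(r.start <= x <= r.end for x in g.residues):
                    ess[i] = max(ess[i], r.effect)
            for r in config.resistance_regions:
                if any(r.start <= x <= r.end for x in g.residues):
                    if r.enrich_effect > enr[i]:
                        enr[i] = r.enrich_effect
                        ifp[i] = r.in_frame_prob
    return ess, enr, ifp


def simulate_screen(
    library: Library,
    activities: pd.Series,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Multi-arm NB count matrix plus a per-guide truth table.

    The truth table records activity, effects, and expected RPM per
    (arm, day) as columns ``rpm:<cell_line>:<treatment>:d<day>``; use
    :func:`expected_lfc` to turn those into expected contrast LFCs.
    """
    config = config or SimulationConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    act = activities.reindex(library.sgrna_ids).to_numpy()
    ess, enr, ifp = _guide_effects(library, config)
    a0 = rng.lognormal(0.0, config.noise.initial_sigma, size=len(library))
    truth = pd.DataFrame(
        {
            "activity": act,
            "essential_effect": ess,
            "enrich_effect": enr,
            "in_frame_prob": ifp,
            "initial_abundance": a0,
        },
        index=pd.Index(library.sgrna_ids, name="sgrna_id"),
    )
    metas: list[SampleMeta] = []
    vectors: dict[str, np.ndarray] = {}
    for arm in config.arms:
        for day in arm.days:
            doublings = arm.doublings_per_day * day
            mult = np.ones(len(library))
            if arm.cell_line == "CAS9":
                mult = 2.0 ** (-doublings * act * ess)
                if arm.treatment not in ("none", "DMSO", ""):
                    mult *= 2.0 ** (doublings * enr * ifp * act)
            rel = a0 * mult
            p = rel / rel.sum()
            truth[f"rpm:{arm.cell_line}:{arm.treatment}:d{day}"] = p * 1e6
            mean = config.noise.depth * p
            for rep in range(1, config.n_replicates + 1):
                sid = f"{arm.cell_line}_{arm.treatment}_d{day}_r{rep}"
                if config.noise.nb_dispersion == 0:
                    counts = rng.poisson(mean)
                else:
                    shape = 1.0 / config.noise.nb_dispersion
                    lam = rng.gamma(shape, mean / shape)
                    counts = rng.poisson(lam)
                vectors[sid] = counts
                metas.append(
                    SampleMeta(sid, arm.cell_line, day, arm.treatment, rep)
                )
    counts = pd.DataFrame(
        vectors, index=pd.Index(library.sgrna_ids, name="sgrna_id"), dtype=np.int64
    )
    cm = CountMatrix(counts, metas, {m.sample_id: 0 for m in metas})
    return cm, truth


def expected_lfc(
    truth: pd.DataFrame, numerator_col: str, denominator_col: str
) -> pd.Series:
    """Noise-free LFC implied by the truth table's expected RPM columns."""
    return np.log2(truth[numerator_col] + 1) - np.log2(truth[denominator_col] + 1)


def simulate_reads(
    library: Library,
    proportions: Sequence[float],
    n_reads: int,
    rng: np.random.Generator,
    flank: int = 10,
) -> tuple[list[str], pd.Series]:
    """Cassette reads embedding protospacers at random offsets.

    Returns the reads and the per-guide truth counts drawn from the
    mixture.
    """
    p = np.asarray(proportions, dtype=float)
    p = p / p.sum()
    draws = rng.multinomial(n_reads, p)
    reads: list[str] = []
    for g, n in zip(library.sgrnas, draws):
        for _ in range(n):
            left = "".join(rng.choice(list("ACGT"), size=flank))
            right = "".join(rng.choice(list("ACGT"), size=flank))
            reads.append(left + g.protospacer + right)
    rng.shuffle(reads)
    return reads, pd.Series(draws, index=library.sgrna_ids, name="truth_count")


# ---------------------------------------------------------------- amplicons


@dataclass(frozen=True)
class AlleleSpec:
    """One allele of the edited locus and its per-day dynamics.

    ``per_day_multiplier`` scales the allele's expected abundance for each
    day past the reference day; 1.0 is neutral, <1 depleting.
    """

    descriptor: IndelDescriptor | None
    day1_fraction: float
    per_day_multiplier: float = 1.0


def make_amplicon(
    gene_model: GeneModel, cut_pos: int, flank: int = 100
) -> Amplicon:
    """An amplicon window of the CDS centred on a cut site."""
    start = max(0, cut_pos - flank)
    end = min(len(gene_model.cds_seq), cut_pos + flank)
    return Amplicon(
        seq=gene_model.cds_seq[start:end],
        cds_offset=0,
        frame_anchor=start,
        cut_pos_amplicon=cut_pos - start,
    )


def apply_descriptor(seq: str, desc: IndelDescriptor | None) -> str:
    if desc is None:
        return seq
    return seq[: desc.start] + desc.alt + seq[desc.start + desc.ref_len :]


def simulate_amplicon_reads(
    gene_model: GeneModel,
    amplicon: Amplicon,
    allele_spec: Sequence[AlleleSpec],
    days: Sequence[int] = (1, 2, 5, 9),
    n_reads: int = 1000,
    base_error: float = 0.0,
    rng: np.random.Generator | None = None,
    reference_day: int = 1,
) -> tuple[dict[int, list[str]], pd.DataFrame]:
    """Amplicon read sets per timepoint from an evolving allele mixture.

    Day-1 fractions must sum to 1; each allele's weight at day d is
    fraction x multiplier^(d - reference_day), renormalized.  The truth
    table lists each allele's left-normalized descriptor, protein
    consequence and expected fraction per day.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    fracs = np.array([a.day1_fraction for a in allele_spec], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-6:
        raise ValueError(f"day-1 fractions sum to {fracs.sum()}, not 1")
    seqs = [apply_descriptor(amplicon.seq, a.descriptor) for a in allele_spec]
    reads_by_day: dict[int, list[str]] = {}
    truth_rows = []
    frac_cols: dict[int, np.ndarray] = {}
    for day in days:
        mult = np.array(
            [a.per_day_multiplier ** (day - reference_day) for a in allele_spec]
        )
        w = fracs * mult
        w = w / w.sum()
        frac_cols[day] = w
        draws = rng.multinomial(n_reads, w)
        reads: list[str] = []
        for seq, n in zip(seqs, draws):
            for _ in range(n):
                if base_error > 0:
                    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                    hit = rng.random(len(arr)) < base_error
                    if hit.any():
                        subs = rng.choice(
                            np.frombuffer(b"ACGT", dtype=np.uint8), size=hit.sum()
                        )
                        arr[hit] = subs
                    reads.append(arr.tobytes().decode())
                else:
                    reads.append(seq)
        rng.shuffle(reads)
        reads_by_day[day] = reads
    for i, a in enumerate(allele_spec):
        desc = (
            left_normalize(amplicon, a.descriptor)
            if a.descriptor is not None
            else None
        )
        cons, fclass = protein_consequence(gene_model, amplicon, desc)
        row = {
            "consequence": cons,
            "frame_class": fclass,
            "desc_start": desc.start if desc else -1,
            "desc_ref_len": desc.ref_len if desc else 0,
            "desc_alt": desc.alt if desc else "",
            "day1_fraction": fracs[i],
            "per_day_multiplier": a.per_day_multiplier,
        }
        for day in days:
            row[f"frac_d{day}"] = frac_cols[day][i]
        truth_rows.append(row)
    return reads_by_day, pd.DataFrame(truth_rows)
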