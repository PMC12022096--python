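"""Depth normalization and per-sgRNA log2 fold-change contrasts.

RPM = counts / column total x 1e6; LFC is computed on RPM + 1 (pseudocount
on RPM, not on raw counts), per replicate pair, then averaged.  The
canonical drop-out contrast divides the Cas9 arm at day 14 by the parental
(Cas9-negative) arm at day 0, which retains the full depletion signal while
cancelling library-composition effects shared by the two arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .library_io import Library
from .quant import CountMatrix, SampleMeta


class ContrastError(ValueError):
    """Contrast does not resolve to usable sample pairs."""


REPLICATE_POLICIES = ("pairwise_then_mean", "mean_of_pairs_listed")


@dataclass(frozen=True)
class Contrast:
    """A named numerator/denominator sample selection.

    Selectors are field->value mappings over SampleMeta (cell_line, day,
    treatment); replicates are paired by replicate index.
    """

    name: str
    numerator: Mapping[str, object]
    denominator: Mapping[str, object]
    replicate_policy: str = "pairwise_then_mean"

    def __post_init__(self) -> None:
        if self.replicate_policy not in REPLICATE_POLICIES:
            raise ContrastError(
                f"replicate_policy must be one of {REPLICATE_POLICIES}"
            )


# The canonical screen contrasts, for convenience.
def paired_dropout_contrast(day: int = 14) -> Contrast:
    return Contrast(
        f"PAR/Cas9-D{day}",
        numerator={"cell_line": "CAS9", "day": day},
        denominator={"cell_line": "PAR", "day": 0},
    )


def within_line_contrast(day: int = 14, cell_line: str = "CAS9") -> Contrast:
    return Contrast(
        f"{cell_line.title()}/{cell_line.title()}-D{day}",
        numerator={"cell_line": cell_line, "day": day},
        denominator={"cell_line": cell_line, "day": 0},
    )


def drug_contrast(treatment: str, day: int = 18, control: str = "DMSO") -> Contrast:
    return Contrast(
        f"{treatment}/{control}-D{day}",
        numerator={"cell_line": "CAS9", "day": day, "treatment": treatment},
        denominator={"cell_line": "CAS9", "day": day, "treatment": control},
    )


def rpm(count_matrix: CountMatrix) -> pd.DataFrame:
    """Reads-per-million normalization; every column sums to 1e6."""
    counts = count_matrix.counts
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ContrastError(
            f"zero-total sample(s): {list(zero.index)}; cannot normalize"
        )
    return counts / totals * 1e6


def _pair_samples(
    samples: list[SampleMeta], contrast: Contrast
) -> list[tuple[SampleMeta, SampleMeta]]:
    def match(s: SampleMeta, sel: Mapping[str, object]) -> bool:
        return all(getattr(s, k) == v for k, v in sel.items())

    num = [s for s in samples if match(s, contrast.numerator)]
    den = [s for s in samples if match(s, contrast.denominator)]
    if not num or not den:
        raise ContrastError(
            f"{contrast.name}: selector matched {len(num)} numerator and "
            f"{len(den)} denominator samples"
        )
    if contrast.replicate_policy == "mean_of_pairs_listed":
        if len(num) != len(den):
            raise ContrastError(
                f"{contrast.name}: listed pairs differ in length"
            )
        return list(zip(num, den))
    by_rep_num = {s.replicate: s for s in num}
    by_rep_den = {s.replicate: s for s in den}
    common = sorted(set(by_rep_num) & set(by_rep_den))
    if not common:
        raise ContrastError(
            f"{contrast.name}: no replicate indices shared between "
            "numerator and denominator"
        )
    return [(by_rep_num[r], by_rep_den[r]) for r in common]


def compute_lfc(
    rpm_matrix: pd.DataFrame,
    samples: list[SampleMeta],
    contrast: Contrast,
    library: Library | None = None,
) -> pd.DataFrame:
    """Per-sgRNA LFC table for one contrast.

    Per replicate pair r: lfc_r = log2(rpm_num_r + 1) - log2(rpm_den_r + 1);
    lfc_mean is the arithmetic mean over pairs.  Guide annotation (category,
    residues) is joined in from the library when given.
    """
    pairs = _pair_samples(samples, contrast)
    out = pd.DataFrame(index=rpm_matrix.index.copy())
    rep_cols = []
    for i, (ns, ds) in enumerate(pairs, start=1):
        col = f"lfc_rep{i}"
        out[col] = np.log2(rpm_matrix[ns.sample_id] + 1.0) - np.log2(
            rpm_matrix[ds.sample_id] + 1.0
        )
        rep_cols.append(col)
    out["lfc_mean"] = out[rep_cols].mean(axis=1)
    if library is not None:
        ann = library.to_frame()
        out = out.join(ann[["category", "residues"]])
    else:
        out["category"] = "CDS"
        out["residues"] = ""
    out["filtered"] = False
    out["filter_reason"] = ""
    out["corrected_lfc"] = np.nan
    out.attrs["contrast"] = contrast.name
    return out


def filter_low_counts(
    lfc_table: pd.DataFrame,
    count_matrix: CountMatrix,
    reference_sample: str,
    min_count: int = 300,
) -> pd.DataFrame:
    """Flag guides with reference-sample counts below ``min_count``.

    Flagged rows carry reason 'low_count' and are excluded from residue
    mapping downstream, but remain in the table.
    """
    if reference_sample not in count_matrix.counts.columns:
        raise ContrastError(f"reference sample {reference_sample!r} not found")
    out = lfc_table.copy()
    low = count_matrix.counts[reference_sample].reindex(out.index) < min_count
    out.loc[low, "filtered"] = True
    out.loc[low, "filter_reason"] = "low_count"
    return out


def activity_correct(
    lfc_table: pd.DataFrame,
    activity_scores: Mapping[str, float] | pd.Series,
    floor: float = 0.2,
) -> pd.DataFrame:
    """Divide lfc_mean by on-target activity (floored) into corrected_lfc.

    Scores on (0, 100] are rescaled to (0, 1].  Division by a positive
    floored activity never flips the LFC sign; guides without a score keep
    corrected_lfc unset.
    """
    act = pd.Series(activity_scores, dtype=float)
    if (act <= 0).any():
        bad = list(act.index[act <= 0])
        raise ValueError(f"non-positive activity scores for {bad}")
    if act.max() > 1.0:
        act = act / 100.0
    if act.max() > 1.0:
        raise ValueError("activity scores exceed 100")
    out = lfc_table.copy()
    aligned = act.reindex(out.index)
    out["corrected_lfc"] = out["lfc_mean"] / aligned.clip(lower=floor)
    missing = out.index[
        aligned.isna() & (out["category"] == "CDS") & ~out["filtered"]
    ]
    if len(missing):
        import warnings

        warnings.warn(
            f"no activity score for {len(missing)} unfiltered CDS guide(s); "
            "corrected_lfc left unset",
            stacklevel=2,
        )
    return out


def write_lfc(lfc_table: pd.DataFrame, path) -> None:
    cols = [c for c in lfc_table.columns if c.startswith("lfc_rep")]
    order = ["category", "residues", *cols, "lfc_mean", "corrected_lfc",
             "filtered", "filter_reason"]
    lfc_table[order].to_csv(path, sep="\t", index_label="sgrna_id")
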