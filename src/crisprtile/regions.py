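"""Rank binning, residue projection, region calling and structure export.

Scored guides are ranked by mean LFC (most enriched first) and split into
17 contiguous rank bins of near-equal size: bin 1 holds the most enriched
guides, bin 17 the most depleted.  Guide scores project onto protein
residues through the cut-site assignment; contiguous runs of residues in
the extreme bins become called regions, optionally gated by an absolute
LFC cutoff, and per-residue scores can be written into the B-factor column
of a PDB file for heat-map rendering in any structure viewer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .library_io import GeneModel

logger = logging.getLogger(__name__)

DIRECTIONS = ("depleted", "enriched")


class RegionError(ValueError):
    pass


def bin_sgrnas(
    lfc_table: pd.DataFrame,
    n_bins: int = 17,
    categories: tuple[str, ...] = ("CDS",),
    column: str = "lfc_mean",
) -> pd.Series:
    """Assign unfiltered guides of the given categories to rank bins.

    Guides are sorted by ``column`` descending (ties broken by sgrna_id for
    determinism) and split into ``n_bins`` contiguous groups as equal as
    possible; the first N mod n_bins bins get one extra guide.
    """
    if "filtered" in lfc_table.columns:
        sub = lfc_table[~lfc_table["filtered"]]
    else:
        sub = lfc_table
    sub = sub[sub["category"].isin(categories)]
    n = len(sub)
    if n < n_bins:
        raise RegionError(f"{n} scored guides < {n_bins} bins")
    # descending LFC, ties broken by sgrna_id (the index) ascending
    keys = np.lexsort((sub.index.to_numpy(), -sub[column].to_numpy()))
    order = sub.iloc[keys]
    base, extra = divmod(n, n_bins)
    sizes = [base + 1] * extra + [base] * (n_bins - extra)
    labels = np.repeat(np.arange(1, n_bins + 1), sizes)
    return pd.Series(labels, index=order.index, name="bin")


def residue_track(
    lfc_table: pd.DataFrame,
    bins: pd.Series,
    gene_model: GeneModel,
    direction: str | None = None,
    column: str = "lfc_mean",
) -> pd.DataFrame:
    """Project guide LFCs onto residues 1..n.

    mean_lfc averages ``column`` (raw or activity-corrected LFC) over all
    guides assigned to a residue;
    best_bin is the extreme bin among them (max index for 'depleted'
    tracks, min for 'enriched').
    """
    if direction not in DIRECTIONS:
        raise RegionError(f"direction must be one of {DIRECTIONS}")
    n = gene_model.n_residues
    per_res_lfc: dict[int, list[float]] = {}
    per_res_bin: dict[int, list[int]] = {}
    per_res_guides: dict[int, list[str]] = {}
    scored = lfc_table.loc[bins.index]
    for gid, row in scored.iterrows():
        res_str = row.get("residues", "")
        if not res_str:
            continue
        for r in map(int, str(res_str).split(";")):
            per_res_lfc.setdefault(r, []).append(row[column])
            per_res_bin.setdefault(r, []).append(int(bins[gid]))
            per_res_guides.setdefault(r, []).append(gid)
    idx = pd.RangeIndex(1, n + 1, name="residue")
    agg = max if direction == "depleted" else min
    track = pd.DataFrame(
        {
            "aa": list(gene_model.protein_seq),
            "n_guides": [len(per_res_lfc.get(r, [])) for r in idx],
            "mean_lfc": [
                float(np.mean(per_res_lfc[r])) if r in per_res_lfc else np.nan
                for r in idx
            ],
            "best_bin": [
                agg(per_res_bin[r]) if r in per_res_bin else np.nan for r in idx
            ],
            "guides": [";".join(per_res_guides.get(r, [])) for r in idx],
        },
        index=idx,
    )
    track["covered"] = track["n_guides"] >= 1
    track.attrs["direction"] = direction
    return track


@dataclass(frozen=True)
class RegionCall:
    """A contiguous residue span called from the extreme bins."""

    start_res: int
    end_res: int
    direction: str
    label: str
    extreme_lfc: float
    supporting_sgrnas: tuple[str, ...]

    @property
    def span(self) -> range:
        return range(self.start_res, self.end_res + 1)


def _region_label(track: pd.DataFrame, start: int, end: int) -> str:
    aa = track["aa"]
    if start == end:
        return f"{aa[start]}{start}"
    if end == start + 1:
        return f"{aa[start]}{start}/{aa[end]}{end}"
    return f"{aa[start]}{start}_{aa[end]}{end}"


def call_regions(
    track: pd.DataFrame,
    qualifying_bins: set[int],
    direction: str | None = None,
    max_gap: int = 1,
    lfc_threshold: float | None = None,
) -> list[RegionCall]:
    """Merge residues whose best_bin qualifies into maximal regions.

    Seed residues within ``max_gap`` nonqualifying residues of each other
    merge into one region.  ``lfc_threshold`` optionally adds an absolute
    gate: a depleted seed must also have mean_lfc <= threshold (>= for
    enriched).
    """
    if not qualifying_bins:
        raise RegionError("empty qualifying bin set")
    direction = direction or track.attrs.get("direction")
    if direction not in DIRECTIONS:
        raise RegionError(f"direction must be one of {DIRECTIONS}")
    qual = track["best_bin"].isin(qualifying_bins)
    if lfc_threshold is not None:
        if direction == "depleted":
            qual &= track["mean_lfc"] <= lfc_threshold
        else:
            qual &= track["mean_lfc"] >= lfc_threshold
    seeds = sorted(track.index[qual.fillna(False)])
    calls: list[RegionCall] = []
    if not seeds:
        return calls
    groups: list[list[int]] = [[seeds[0]]]
    for r in seeds[1:]:
        if r - groups[-1][-1] - 1 <= max_gap:
            groups[-1].append(r)
        else:
            groups.append([r])
    pick = min if direction == "depleted" else max
    for grp in groups:
        start, end = grp[0], grp[-1]
        lfcs = track.loc[grp, "mean_lfc"]
        guides: list[str] = []
        for r in grp:
            guides.extend(g for g in track.loc[r, "guides"].split(";") if g)
        calls.append(
            RegionCall(
                start_res=start,
                end_res=end,
                direction=direction,
                label=_region_label(track, start, end),
                extreme_lfc=float(pick(lfcs)),
                supporting_sgrnas=tuple(dict.fromkeys(guides)),
            )
        )
    return calls


def regions_frame(calls: list[RegionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start": [c.start_res for c in calls],
            "end": [c.end_res for c in calls],
            "label": [c.label for c in calls],
            "direction": [c.direction for c in calls],
            "extreme_lfc": [c.extreme_lfc for c in calls],
            "supporting_sgrnas": [";".join(c.supporting_sgrnas) for c in calls],
        }
    )


def write_track(track: pd.DataFrame, path) -> None:
    track[["aa", "n_guides", "mean_lfc", "best_bin", "covered"]].to_csv(
        path, sep="\t"
    )


def export_bfactor(
    pdb_path: str | Path,
    track: pd.DataFrame,
    chain_id: str,
    out_path: str | Path,
    field: str = "mean_lfc",
) -> Path:
    """Write a per-residue track field into a PDB B-factor column.

    Operates on the text of the fixed-column PDB format so every byte
    outside the B-factor field (columns 61-66) of matching-chain ATOM /
    HETATM records is preserved.  Residues absent from the track (or with
    NA values) get B = 0.00.
    """
    if field not in track.columns:
        raise RegionError(f"track has no field {field!r}")
    values = track[field]
    pdb_path, out_path = Path(pdb_path), Path(out_path)
    lines = pdb_path.read_text().splitlines(keepends=True)
    matched = 0
    n_na = 0
    out_lines = []
    for line in lines:
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 66:
            if line[21] == chain_id:
                try:
                    resseq = int(line[22:26])
                except ValueError:
                    out_lines.append(line)
                    continue
                if resseq in values.index and pd.notna(values[resseq]):
                    b = float(values[resseq])
                    matched += 1
                else:
                    b = 0.0
                    n_na += 1
                out_lines.append(f"{line[:60]}{b:6.2f}{line[66:]}")
                continue
        out_lines.append(line)
    if matched == 0:
        raise RegionError(
            f"no residue numbers of chain {chain_id!r} in {pdb_path} "
            "overlap the track"
        )
    if n_na:
        logger.info("%d atoms without a track value set to B=0.00", n_na)
    out_path.write_text("".join(out_lines))
    return out_path
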