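"""Enrichment statistics: per-peptide EF, ranking, position EF heatmaps.

The enrichment factor (EF) of a sequence class x is the quotient of its
total-normalized read frequencies after vs before selection::

    EF(x) = (c_after(x) / N_after) / (c_before(x) / N_before)

EF > 1 means enriched.  The same formula applied to the class "residue a at
Gln-relative position rel" gives the position EF matrix rendered as the
heatmap, and the per-position maxima give the heatmap-derived consensus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .library_design import AMINO_ACIDS, LibraryDesign, rel_to_abs

__all__ = [
    "CountTable",
    "PositionEF",
    "heatmap_consensus",
    "logo_matrix",
    "normalize",
    "peptide_ef",
    "position_aa_ef",
    "rank_top",
]


class EmptySampleError(ValueError):
    pass


@dataclass(frozen=True)
class CountTable:
    """Peptide counts before and after selection.

    ``df`` is indexed by peptide with integer columns ``c_before`` and
    ``c_after``; totals are the column sums.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"c_before", "c_after"} - set(self.df.columns)
        if missing:
            raise ValueError(f"count table lacks columns {sorted(missing)}")
        if (self.df[["c_before", "c_after"]] < 0).any().any():
            raise ValueError("counts must be >= 0")

    @classmethod
    def from_counts(cls, before: dict, after: dict) -> "CountTable":
        peptides = sorted(set(before) | set(after))
        df = pd.DataFrame(
            {
                "c_before": [before.get(p, 0) for p in peptides],
                "c_after": [after.get(p, 0) for p in peptides],
            },
            index=pd.Index(peptides, name="peptide"),
        )
        return cls(df)

    @classmethod
    def from_tsv(
        cls, path, before_sample: str = "before", after_sample: str = "after"
    ) -> "CountTable":
        """Build from a long-format TSV with columns sample/peptide/count."""
        long = pd.read_csv(path, sep="\t")
        wide = (
            long.pivot_table(
                index="peptide", columns="sample", values="count", fill_value=0
            )
            .astype(int)
        )
        for s in (before_sample, after_sample):
            if s not in wide.columns:
                raise ValueError(f"{path}: sample {s!r} missing")
        df = wide[[before_sample, after_sample]].copy()
        df.columns = ["c_before", "c_after"]
        df.index.name = "peptide"
        return cls(df.sort_index())

    @property
    def n_before(self) -> int:
        return int(self.df["c_before"].sum())

    @property
    def n_after(self) -> int:
        return int(self.df["c_after"].sum())


def normalize(counts: pd.Series) -> pd.Series:
    """Counts -> frequencies summing to 1."""
    total = counts.sum()
    if total <= 0:
        raise EmptySampleError("sample total is zero")
    return counts / total


def peptide_ef(table: CountTable, pseudocount: float = 0.0) -> pd.DataFrame:
    """Per-peptide EF = (c_after/N_after) / (c_before/N_before).

    An optional pseudocount is added to both counts of every peptide (the
    totals are adjusted accordingly).  With pseudocount 0, peptides absent
    before selection get EF = NaN and the ``zero_before`` flag; they are
    excluded from ranking rather than reported as infinite.
    """
    df = table.df.copy()
    cb = df["c_before"].astype(float) + pseudocount
    ca = df["c_after"].astype(float) + pseudocount
    nb, na = cb.sum(), ca.sum()
    if nb <= 0 or na <= 0:
        raise EmptySampleError("a sample total is zero")
    with np.errstate(divide="ignore", invalid="ignore"):
        ef = (ca / na) / (cb / nb)
    df["ef"] = ef.where(cb > 0)
    df["zero_before"] = table.df["c_before"] == 0
    return df


def rank_top(
    ef_table: pd.DataFrame,
    min_count_after: int = 100,
    top_n: int | None = 100,
) -> pd.DataFrame:
    """Rank peptides by EF, highest first.

    Peptides with ``c_after < min_count_after`` (not considered significant)
    or with no defined EF are dropped.  Ties are broken by higher
    ``c_after``, then lexicographically by peptide.  Returns the first
    ``top_n`` rows with a 1-based ``rank`` column (all rows when ``top_n``
    is None).
    """
    eligible = ef_table[
        (ef_table["c_after"] >= min_count_after) & ef_table["ef"].notna()
    ].reset_index()
    eligible = eligible.sort_values(
        by=["ef", "c_after", "peptide"],
        ascending=[False, False, True],
        kind="mergesort",
    ).set_index("peptide")
    eligible["rank"] = np.arange(1, len(eligible) + 1)
    return eligible.head(top_n) if top_n is not None else eligible


@dataclass(frozen=True)
class PositionEF:
    """Position EF matrix with its companion count matrices.

    ``ef`` is residues (20, alphabetical) x Gln-relative positions; cells
    whose residue was unseen before selection are NaN and flagged in
    ``undefined`` rather than reported as infinite.
    """

    ef: pd.DataFrame
    counts_before: pd.DataFrame
    counts_after: pd.DataFrame

    @property
    def undefined(self) -> pd.DataFrame:
        return self.counts_before == 0


def position_aa_ef(table: CountTable, design: LibraryDesign) -> PositionEF:
    """Per-position, per-residue EF over the design's randomized positions.

    For residue a at relative position rel, the class counts are the summed
    counts of all peptides carrying a at rel; the EF is the quotient of
    their normalized frequencies after vs before selection.
    """
    if table.df.empty:
        raise EmptySampleError("count table is empty")
    nb, na = table.n_before, table.n_after
    if nb <= 0 or na <= 0:
        raise EmptySampleError("a sample total is zero")
    rels = design.randomized_rel
    residues = list(AMINO_ACIDS)
    peptides = table.df.index
    cb = table.df["c_before"].to_numpy()
    ca = table.df["c_after"].to_numpy()

    ef = pd.DataFrame(index=residues, columns=list(rels), dtype=float)
    counts_b = pd.DataFrame(0, index=residues, columns=list(rels))
    counts_a = pd.DataFrame(0, index=residues, columns=list(rels))
    for rel in rels:
        pos = rel_to_abs(design, rel)
        res_at = np.asarray(peptides.str[pos])
        for a in residues:
            mask = res_at == a
            b = int(cb[mask].sum())
            c = int(ca[mask].sum())
            counts_b.loc[a, rel] = b
            counts_a.loc[a, rel] = c
            ef.loc[a, rel] = (c / na) / (b / nb) if b > 0 else np.nan
    ef.index.name = "residue"
    ef.columns.name = "rel_position"
    return PositionEF(ef=ef, counts_before=counts_b, counts_after=counts_a)


def heatmap_consensus(matrix: pd.DataFrame) -> tuple[dict[int, str], dict[int, bool]]:
    """Per-position residue with maximal EF (the heatmap-derived consensus).

    Returns ``(consensus, tie_flags)`` keyed by relative position; ties are
    broken alphabetically and flagged.  A column with no defined entry is an
    error.
    """
    consensus: dict[int, str] = {}
    ties: dict[int, bool] = {}
    for rel in matrix.columns:
        col = matrix[rel].dropna()
        if col.empty:
            raise ValueError(f"position {rel:+d}: no defined EF entries")
        top = col.max()
        winners = sorted(col.index[col == top])
        consensus[int(rel)] = winners[0]
        ties[int(rel)] = len(winners) > 1
    return consensus, ties


def render_consensus(design: LibraryDesign, consensus: dict[int, str]) -> str:
    """Consensus over randomized positions merged with the fixed backbone,
    over the contiguous span they cover (e.g. ``Q-Q-C-Y-I``)."""
    abs_pos = sorted(rel_to_abs(design, r) for r in consensus)
    span = range(min(abs_pos), max(max(abs_pos), design.reactive_index) + 1)
    rel_of = {rel_to_abs(design, r): r for r in consensus}
    out = [
        consensus[rel_of[i]] if i in rel_of else design.backbone_peptide[i]
        for i in span
    ]
    return "-".join(out)


def logo_matrix(peptides, weights=None) -> pd.DataFrame:
    """Per-position residue frequencies (20 x L, columns sum to 1).

    ``peptides`` is any iterable of equal-length sequences (e.g. the top-100
    ranked peptides); optional ``weights`` (e.g. read counts) weight each
    sequence.  Intended for export to sequence-logo tools.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("no peptides")
    L = len(peptides[0])
    if any(len(p) != L for p in peptides):
        raise ValueError("peptides have mixed lengths")
    w = np.ones(len(peptides)) if weights is None else np.asarray(weights, float)
    arr = np.frombuffer("".join(peptides).encode(), np.uint8).reshape(-1, L)
    mat = np.zeros((len(AMINO_ACIDS), L))
    for i, aa in enumerate(AMINO_ACIDS):
        mat[i] = ((arr == ord(aa)) * w[:, None]).sum(axis=0)
    totals = mat.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("a position has no residues from the 20-letter alphabet")
    out = pd.DataFrame(mat / totals, index=list(AMINO_ACIDS), columns=range(L))
    out.index.name = "residue"
    out.columns.name = "position"
    return out


def write_consensus_json(
    design: LibraryDesign,
    consensus: dict[int, str],
    ties: dict[int, bool],
    path,
) -> None:
    doc = {
        "per_position": {f"{k:+d}": v for k, v in sorted(consensus.items())},
        "ties": {f"{k:+d}": bool(v) for k, v in sorted(ties.items())},
        "rendered": render_consensus(design, consensus),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
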