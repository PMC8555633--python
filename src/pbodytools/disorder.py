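"""Intrinsic-disorder enrichment testing against size-matched random sets.

IDRs are called from per-residue consensus predictor counts: a region counts
as disordered where at least ``min_predictors`` predictors agree, and only
maximal runs of at least ``min_len`` residues (default 25) are kept.  Each
protein's fraction disordered is its IDR residues over its length.

The enrichment question — is a given protein set (e.g. the 17 condensate-
associated proteins) more disordered than chance? — is answered by resampling:
draw many random sets of the same cardinality uniformly without replacement
from the whole proteome, compute the same disorder statistic for each, and
report the percentile of the observed statistic in that null (strictly-below
convention).  Two statistics are supported: the protein-averaged mean of
per-protein fractions, and the residue-weighted total IDR residues over total
residues.  For small proteomes the null can be enumerated exhaustively.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STAT_KINDS = ("protein_averaged", "residue_weighted")


def call_idrs(
    consensus_counts: Sequence[int], min_len: int = 25, min_predictors: int = 3
) -> list[tuple[int, int]]:
    """Maximal runs with predictor count ≥ min_predictors and length ≥ min_len.

    Returns 1-based closed intervals, sorted and disjoint.  An empty sequence
    yields no IDRs.
    """
    counts = np.asarray(consensus_counts)
    if counts.size == 0:
        return []
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        counts = counts.astype(int)
        if np.any(counts < 0):
            raise ValueError("predictor counts must be non-negative integers")
    hit = counts >= min_predictors
    out: list[tuple[int, int]] = []
    start = None
    for i, h in enumerate(hit):
        if h and start is None:
            start = i
        elif not h and start is not None:
            if i - start >= min_len:
                out.append((start + 1, i))
            start = None
    if start is not None and len(hit) - start >= min_len:
        out.append((start + 1, len(hit)))
    return out


def _check_intervals(intervals: Iterable[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    prev_end = 0
    for a, b in ivs:
        if a < 1 or b > length or b < a:
            raise ValueError(f"interval ({a}, {b}) outside [1, {length}]")
        if a <= prev_end:
            raise ValueError("IDR intervals must be non-overlapping")
        prev_end = b
    return ivs


def fraction_disordered(intervals: Iterable[tuple[int, int]], length: int) -> float:
    """IDR residues over protein length, from 1-based closed intervals."""
    if length < 1:
        raise ValueError("protein length must be positive")
    ivs = _check_intervals(intervals, length)
    return sum(b - a + 1 for a, b in ivs) / length


class ProteomeTable:
    """Per-protein length and disorder annotation for enrichment testing."""

    def __init__(self, table: pd.DataFrame, intervals: dict[str, list[tuple[int, int]]] | None = None):
        required = {"protein_id", "length", "fraction_disordered"}
        if not required.issubset(table.columns):
            raise ValueError(f"proteome table needs columns {sorted(required)}")
        if table["protein_id"].duplicated().any():
            raise ValueError("duplicate protein identifiers")
        if ((table["fraction_disordered"] < 0) | (table["fraction_disordered"] > 1)).any():
            raise ValueError("fractions must lie in [0, 1]")
        self.table = table.reset_index(drop=True)
        self.intervals = intervals or {}
        self._index = {pid: i for i, pid in enumerate(self.table["protein_id"])}

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._index

    @property
    def ids(self) -> list[str]:
        return list(self.table["protein_id"])

    @property
    def fractions(self) -> np.ndarray:
        return self.table["fraction_disordered"].to_numpy(dtype=float)

    @property
    def lengths(self) -> np.ndarray:
        return self.table["length"].to_numpy(dtype=float)

    def rows_for(self, protein_ids: Sequence[str]) -> np.ndarray:
        missing = [p for p in protein_ids if p not in self._index]
        if missing:
            raise KeyError(f"proteins not in proteome: {missing[:5]}")
        return np.asarray([self._index[p] for p in protein_ids])

    @classmethod
    def from_intervals(cls, interval_table: pd.DataFrame, lengths: pd.DataFrame) -> "ProteomeTable":
        """Build from TSV-shaped tables: (protein_id, start, end) + (protein_id, length).

        Intervals are 1-based closed; proteins absent from the interval table
        get fraction 0.  This is the shape of deposited disorder-region files
        after trivial reshaping.
        """
        ivmap: dict[str, list[tuple[int, int]]] = {}
        for pid, grp in interval_table.groupby("protein_id"):
            ivmap[pid] = [(int(a), int(b)) for a, b in zip(grp["start"], grp["end"])]
        rows = []
        for pid, length in zip(lengths["protein_id"], lengths["length"]):
            ivs = ivmap.get(pid, [])
            rows.append(
                {
                    "protein_id": pid,
                    "length": int(length),
                    "fraction_disordered": fraction_disordered(ivs, int(length)),
                }
            )
        return cls(pd.DataFrame(rows), ivmap)

    @classmethod
    def from_consensus_counts(
        cls,
        counts: dict[str, Sequence[int]],
        min_len: int = 25,
        min_predictors: int = 3,
    ) -> "ProteomeTable":
        rows, ivmap = [], {}
        for pid, c in counts.items():
            ivs = call_idrs(c, min_len=min_len, min_predictors=min_predictors)
            ivmap[pid] = ivs
            rows.append(
                {
                    "protein_id": pid,
                    "length": len(c),
                    "fraction_disordered": fraction_disordered(ivs, len(c)) if len(c) else 0.0,
                }
            )
        return cls(pd.DataFrame(rows), ivmap)


def set_statistic(
    proteome: ProteomeTable, protein_ids: Sequence[str], kind: str = "protein_averaged"
) -> float:
    """Disorder statistic of a protein set.

    protein_averaged: mean of per-protein fractions.  residue_weighted:
    total IDR residues over total residues across the set.
    """
    if kind not in STAT_KINDS:
        raise ValueError(f"kind must be one of {STAT_KINDS}")
    # canonical (sorted) row order so identical sets give bit-identical floats
    rows = np.sort(proteome.rows_for(protein_ids))
    frac = proteome.fractions[rows]
    if kind == "protein_averaged":
        return float(frac.mean())
    lens = proteome.lengths[rows]
    return float(np.sum(frac * lens) / np.sum(lens))


@dataclass(frozen=True)
class EnrichmentResult:
    observed: float
    n_draws: int
    percentile: float        # in [0, 100], strictly-below convention
    kind: str
    n_ties: int
    null_sample: np.ndarray  # the null statistics actually drawn

    def __post_init__(self):
        below = int(np.sum(self.null_sample < self.observed))
        if abs(self.percentile - 100.0 * below / len(self.null_sample)) > 1e-9:
            raise ValueError("percentile inconsistent with stored null sample")


def _null_statistics(
    fractions: np.ndarray,
    lengths: np.ndarray,
    set_size: int,
    n_draws: int,
    rng: np.random.Generator,
    kind: str,
    length_matched: bool,
    observed_rows: np.ndarray | None,
) -> np.ndarray:
    n = len(fractions)
    if length_matched:
        if observed_rows is None:
            raise ValueError("length-matched draws need the observed set")
        # bin proteome into length quartiles; draw matching bin counts
        bins = np.quantile(lengths, [0.25, 0.5, 0.75])
        bin_of = np.digitize(lengths, bins)
        need = np.bincount(bin_of[observed_rows], minlength=4)
        members = [np.flatnonzero(bin_of == b) for b in range(4)]
        draws = np.empty((n_draws, set_size), dtype=np.int64)
        for d in range(n_draws):
            parts = [rng.choice(members[b], size=need[b], replace=False) for b in range(4)]
            draws[d] = np.concatenate(parts)
    else:
        draws = np.empty((n_draws, set_size), dtype=np.int64)
        for d in range(n_draws):
            draws[d] = rng.choice(n, size=set_size, replace=False)
    draws = np.sort(draws, axis=1)  # canonical order: ties are exact
    if kind == "protein_averaged":
        return fractions[draws].mean(axis=1)
    w = lengths[draws]
    return np.sum(fractions[draws] * w, axis=1) / np.sum(w, axis=1)


def enrichment_percentile(
    proteome: ProteomeTable,
    protein_ids: Sequence[str],
    n_draws: int = 10_000,
    rng: np.random.Generator | int | None = None,
    kind: str = "protein_averaged",
    length_matched: bool = False,
) -> EnrichmentResult:
    """Percentile of the observed set statistic among size-matched random sets.

    Draws ``n_draws`` sets of the same cardinality uniformly without
    replacement from the whole proteome (members of the observed set are not
    excluded) and returns 100·(#draws strictly below observed)/n_draws.
    Ties are counted separately in ``n_ties``.
    """
    if kind not in STAT_KINDS:
        raise ValueError(f"kind must be one of {STAT_KINDS}")
    rows = proteome.rows_for(protein_ids)
    if len(set(protein_ids)) != len(protein_ids):
        raise ValueError("protein set contains duplicates")
    if len(rows) > len(proteome):
        raise ValueError("protein set larger than the proteome")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    observed = set_statistic(proteome, protein_ids, kind)
    null = _null_statistics(
        proteome.fractions, proteome.lengths, len(rows), n_draws, rng, kind,
        length_matched, rows,
    )
    below = int(np.sum(null < observed))
    ties = int(np.sum(null == observed))
    return EnrichmentResult(
        observed=observed,
        n_draws=n_draws,
        percentile=100.0 * below / n_draws,
        kind=kind,
        n_ties=ties,
        null_sample=null,
    )


def enrichment_percentile_exhaustive(
    proteome: ProteomeTable,
    protein_ids: Sequence[str],
    kind: str = "protein_averaged",
    max_subsets: int = 2_000_000,
) -> EnrichmentResult:
    """Exact percentile by full enumeration of all same-size subsets."""
    rows = proteome.rows_for(protein_ids)
    k = len(rows)
    n = len(proteome)
    n_subsets = math.comb(n, k)
    if n_subsets > max_subsets:
        raise ValueError(f"{n_subsets} subsets exceed the enumeration limit")
    fractions, lengths = proteome.fractions, proteome.lengths
    observed = set_statistic(proteome, protein_ids, kind)
    null = np.empty(n_subsets)
    for i, comb in enumerate(itertools.combinations(range(n), k)):
        idx = np.asarray(comb)
        if kind == "protein_averaged":
            null[i] = fractions[idx].mean()
        else:
            w = lengths[idx]
            null[i] = np.sum(fractions[idx] * w) / np.sum(w)
    below = int(np.sum(null < observed))
    return EnrichmentResult(
        observed=observed,
        n_draws=n_subsets,
        percentile=100.0 * below / n_subsets,
        kind=kind,
        n_ties=int(np.sum(null == observed)),
        null_sample=null,
    )
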