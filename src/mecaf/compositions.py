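"""Compositional data containers and transforms.

Microbiome sequencing observes *relative* abundances: each sample is a
vector of proportions on the simplex, carrying no information about total
microbial load. The containers here track the three representations used
throughout the package:

``AbundanceTable``
    nonnegative counts or abundances (samples x taxa), with per-sample
    group labels and optional rank-prefixed taxonomic lineages;
``CompositionMatrix``
    strictly positive rows summing to one (relative abundances);
``CLRMatrix``
    centered log-ratio coordinates, ``x_ij = log r_ij - mean_j log r_ij``,
    whose rows sum to zero. Mean comparison of CLR vectors is the
    hypothesis the max-type tests in :mod:`mecaf.dtest` address.

Zeros must be imputed (pseudo-count) before ratios and logs are taken;
:func:`impute_zeros` implements the conventional additive pseudo-count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "AbundanceTable",
    "CompositionMatrix",
    "CLRMatrix",
    "impute_zeros",
    "to_composition",
    "clr_transform",
    "aggregate_to_rank",
    "clr_pipeline",
    "RANKS",
]

#: Recognized taxonomic ranks, coarsest to finest, with their lineage prefixes.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species", "strain")
RANK_PREFIXES = dict(
    zip(RANKS, ("k__", "p__", "c__", "o__", "f__", "g__", "s__", "t__"))
)

COMPOSITION_ROWSUM_TOL = 1e-10
CLR_ROWSUM_TOL = 1e-8


class CompositionError(ValueError):
    """Invalid compositional input (negative, zero, or inconsistent data)."""


def _as_2d_float(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise CompositionError(f"expected a 2-D samples x taxa matrix, got ndim={arr.ndim}")
    return arr


def _check_ids(arr: np.ndarray, sample_ids, taxon_ids) -> tuple[list[str], list[str]]:
    n, p = arr.shape
    sample_ids = [str(s) for s in sample_ids] if sample_ids is not None else [f"S{i}" for i in range(n)]
    taxon_ids = [str(t) for t in taxon_ids] if taxon_ids is not None else [f"T{j}" for j in range(p)]
    if len(sample_ids) != n:
        raise CompositionError(f"{len(sample_ids)} sample ids for {n} rows")
    if len(taxon_ids) != p:
        raise CompositionError(f"{len(taxon_ids)} taxon ids for {p} columns")
    if len(set(taxon_ids)) != p:
        raise CompositionError("duplicate taxon ids")
    return sample_ids, taxon_ids


@dataclass
class AbundanceTable:
    """Nonnegative samples x taxa abundance matrix with metadata.

    Parameters
    ----------
    values : array-like, shape (n_samples, n_taxa)
        Counts or abundances; all entries must be >= 0.
    sample_ids, taxon_ids : sequences of str, optional
        Generated (``S0..``, ``T0..``) when omitted.
    group : sequence, optional
        Per-sample group label. Two-level designs are required by the
        two-sample tests; a single level is allowed (e.g. for mock-split
        type I error studies).
    lineages : sequence of str, optional
        Rank-prefixed, semicolon-delimited lineage per taxon, e.g.
        ``"k__Bacteria;p__Firmicutes;...;s__..."``.
    """

    values: np.ndarray
    sample_ids: list[str] = None
    taxon_ids: list[str] = None
    group: np.ndarray | None = None
    lineages: list[str] | None = None

    def __post_init__(self):
        self.values = _as_2d_float(self.values)
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise CompositionError(f"negative abundance at sample {i}, taxon {j}")
        if not np.all(np.isfinite(self.values)):
            raise CompositionError("non-finite abundance values")
        self.sample_ids, self.taxon_ids = _check_ids(self.values, self.sample_ids, self.taxon_ids)
        if self.group is not None:
            self.group = np.asarray(self.group)
            if self.group.shape != (self.values.shape[0],):
                raise CompositionError("group labels must align with samples")
            levels, counts = np.unique(self.group, return_counts=True)
            if len(levels) > 2:
                raise CompositionError(f"group must have at most two levels, found {len(levels)}")
            if len(levels) == 2 and counts.min() < 2:
                raise CompositionError("each group level needs at least 2 samples")
        if self.lineages is not None:
            self.lineages = [str(x) for x in self.lineages]
            if len(self.lineages) != self.values.shape[1]:
                raise CompositionError("lineages must align with taxa")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def group_levels(self) -> np.ndarray:
        if self.group is None:
            raise CompositionError("table carries no group labels")
        return np.unique(self.group)

    def split_groups(self, levels: Sequence | None = None):
        """Return (table_1, table_2) split by group label.

        ``levels`` fixes which label is group 1; default is sorted order
        (lexicographically smaller label first).
        """
        obs = self.group_levels()
        if len(obs) != 2:
            raise CompositionError("two-sample split requires exactly two group levels")
        if levels is None:
            levels = list(obs)
        if sorted(map(str, levels)) != sorted(map(str, obs)):
            raise CompositionError(f"group levels {levels} do not match observed {list(obs)}")
        out = []
        for lev in levels:
            mask = self.group == lev
            out.append(
                AbundanceTable(
                    self.values[mask],
                    [s for s, m in zip(self.sample_ids, mask) if m],
                    self.taxon_ids,
                    group=self.group[mask],
                    lineages=self.lineages,
                )
            )
        return tuple(out)


@dataclass
class CompositionMatrix:
    """Strictly positive samples x taxa matrix; every row sums to 1."""

    values: np.ndarray
    sample_ids: list[str] = None
    taxon_ids: list[str] = None
    group: np.ndarray | None = None
    lineages: list[str] | None = None

    def __post_init__(self):
        self.values = _as_2d_float(self.values)
        if np.any(self.values <= 0):
            raise CompositionError("compositions must be strictly positive")
        if np.any(self.values >= 1):
            raise CompositionError("composition entries must lie in (0, 1)")
        rowsums = self.values.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > COMPOSITION_ROWSUM_TOL * max(1, self.values.shape[1])):
            raise CompositionError("composition rows must sum to 1")
        self.sample_ids, self.taxon_ids = _check_ids(self.values, self.sample_ids, self.taxon_ids)
        if self.group is not None:
            self.group = np.asarray(self.group)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]


@dataclass
class CLRMatrix:
    """Centered log-ratio coordinates; every row sums to 0."""

    values: np.ndarray
    sample_ids: list[str] = None
    taxon_ids: list[str] = None
    group: np.ndarray | None = None
    lineages: list[str] | None = None

    def __post_init__(self):
        self.values = _as_2d_float(self.values)
        rowsums = self.values.sum(axis=1)
        if np.any(np.abs(rowsums) > CLR_ROWSUM_TOL * max(1, self.values.shape[1])):
            raise CompositionError("CLR rows must sum to 0")
        self.sample_ids, self.taxon_ids = _check_ids(self.values, self.sample_ids, self.taxon_ids)
        if self.group is not None:
            self.group = np.asarray(self.group)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]


def impute_zeros(table: AbundanceTable, pseudo: float = 0.5) -> AbundanceTable:
    """Replace exact zeros with a positive pseudo-count.

    The default 0.5 is the customary half-count for count tables. For
    tables already on the relative-abundance scale the caller must supply
    a pseudo on that scale (e.g. half the smallest nonzero proportion);
    the function is scale-agnostic.
    """
    if not pseudo > 0:
        raise CompositionError("pseudo-count must be > 0")
    vals = table.values.copy()
    vals[vals == 0] = pseudo
    return replace(table, values=vals)


def to_composition(table: AbundanceTable) -> CompositionMatrix:
    """Close each sample to the unit simplex (divide by its row sum)."""
    if np.any(table.values <= 0):
        raise CompositionError(
            "table has nonpositive entries; impute zeros (impute_zeros) before closing to the simplex"
        )
    vals = table.values / table.values.sum(axis=1, keepdims=True)
    return CompositionMatrix(
        vals, table.sample_ids, table.taxon_ids, group=table.group, lineages=table.lineages
    )


def clr_transform(comp: CompositionMatrix) -> CLRMatrix:
    """Centered log-ratio transform: log r_ij minus the row mean of logs.

    Equivalent to ``log(r_ij / geometric_mean_j(r_i.))``. Because closing
    to the simplex only rescales rows, CLR of the closed table equals the
    row-centered log of the original positive abundances.
    """
    if np.any(comp.values <= 0):
        raise CompositionError("CLR requires strictly positive entries")
    logs = np.log(comp.values)
    vals = logs - logs.mean(axis=1, keepdims=True)
    return CLRMatrix(
        vals, comp.sample_ids, comp.taxon_ids, group=comp.group, lineages=comp.lineages
    )


def _lineage_key(lineage: str, rank: str) -> str:
    """Lineage truncated at `rank`, or 'unclassified' when the rank field is absent/empty."""
    idx = RANKS.index(rank)
    fields = [f.strip() for f in lineage.split(";")]
    by_prefix = {}
    for f in fields:
        for r, pref in RANK_PREFIXES.items():
            if f.startswith(pref):
                by_prefix[r] = f
                break
    target = by_prefix.get(rank, "")
    if target == "" or target == RANK_PREFIXES[rank]:
        return "unclassified"
    prefix_chain = [by_prefix.get(r, RANK_PREFIXES[r]) for r in RANKS[: idx + 1]]
    return ";".join(prefix_chain)


def aggregate_to_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum taxa sharing a lineage up to ``rank``; per-sample totals are conserved.

    Taxa whose lineage lacks the requested rank fall into a single
    ``"unclassified"`` bucket, so no abundance is ever dropped.
    """
    if table.lineages is None:
        raise CompositionError("aggregation requires per-taxon lineages")
    if rank not in RANKS:
        raise CompositionError(f"unknown rank {rank!r}; choose one of {RANKS}")
    keys = [_lineage_key(lin, rank) for lin in table.lineages]
    order: list[str] = []
    seen = set()
    for k in keys:
        if k not in seen:
            seen.add(k)
            order.append(k)
    key_idx = {k: i for i, k in enumerate(order)}
    out = np.zeros((table.n_samples, len(order)))
    for j, k in enumerate(keys):
        out[:, key_idx[k]] += table.values[:, j]
    return AbundanceTable(
        out,
        table.sample_ids,
        order,
        group=table.group,
        lineages=[k if k != "unclassified" else "unclassified" for k in order],
    )


def clr_pipeline(table: AbundanceTable, pseudo: float = 0.5) -> CLRMatrix:
    """Convenience: impute zeros, close to the simplex, CLR-transform."""
    return clr_transform(to_composition(impute_zeros(table, pseudo)))
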