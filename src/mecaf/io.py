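"""Feature-table and metadata readers/writers (TSV/CSV, text only).

External files follow the dominant feature-table convention: taxa as
rows, samples as columns, first column the taxon id (optionally a full
rank-prefixed lineage string). Internally everything is samples x taxa.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .compositions import AbundanceTable, CompositionError

__all__ = [
    "read_feature_table",
    "read_metadata",
    "attach_groups",
    "write_feature_table",
    "write_report",
]


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _looks_like_lineage(name: str) -> bool:
    return "__" in name


def read_feature_table(path) -> AbundanceTable:
    """Parse a taxa-by-samples TSV/CSV into an :class:`AbundanceTable`.

    Lineage-style row ids (``k__...;p__...``) are kept as per-taxon
    lineages so the table can be aggregated by rank.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise CompositionError(f"empty feature table: {path}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise CompositionError(f"duplicate taxon id {dup!r} in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        j, i = np.argwhere(numeric.isna().values)[0]
        raise CompositionError(
            f"non-numeric cell at taxon {df.index[j]!r}, sample {df.columns[i]!r} in {path}"
        )
    values = numeric.values.T  # file is taxa x samples; internal is samples x taxa
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise CompositionError(
            f"negative abundance at taxon {df.index[j]!r}, sample {df.columns[i]!r} in {path}"
        )
    taxon_ids = [str(t) for t in df.index]
    lineages = taxon_ids if all(_looks_like_lineage(t) for t in taxon_ids) else None
    return AbundanceTable(
        values, sample_ids=[str(c) for c in df.columns], taxon_ids=taxon_ids, lineages=lineages
    )


def read_metadata(path, group_col: str = "group") -> pd.DataFrame:
    """Read a sample metadata table with columns ``sample_id`` and ``group_col``."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if "sample_id" not in df.columns:
        raise CompositionError(f"metadata {path} lacks a 'sample_id' column")
    if group_col not in df.columns:
        raise CompositionError(f"metadata {path} lacks the group column {group_col!r}")
    if df["sample_id"].duplicated().any():
        raise CompositionError(f"duplicate sample_id in metadata {path}")
    return df.astype({"sample_id": str})


def attach_groups(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    group_col: str = "group",
    levels=None,
) -> AbundanceTable:
    """Attach group labels; samples absent from the metadata are dropped.

    ``levels`` restricts and orders the two labels (first label = group
    1); by default the lexicographically smaller observed label is group 1.
    """
    meta = metadata.set_index("sample_id")[group_col]
    if levels is not None:
        meta = meta[meta.isin(levels)]
    keep = [i for i, s in enumerate(table.sample_ids) if s in meta.index]
    if not keep:
        raise CompositionError("no sample ids shared between table and metadata")
    sample_ids = [table.sample_ids[i] for i in keep]
    group = np.asarray([str(meta.loc[s]) for s in sample_ids])
    observed = sorted(set(group))
    if len(observed) != 2:
        raise CompositionError(
            f"exactly two group levels required after filtering, found {observed}"
        )
    if levels is not None and sorted(map(str, levels)) != observed:
        raise CompositionError(f"requested levels {levels} not both present in data")
    return AbundanceTable(
        table.values[keep],
        sample_ids,
        table.taxon_ids,
        group=group,
        lineages=table.lineages,
    )


def write_feature_table(table: AbundanceTable, path) -> None:
    """Write taxa-by-samples TSV/CSV (inverse of :func:`read_feature_table`)."""
    ids = table.lineages if table.lineages is not None else table.taxon_ids
    df = pd.DataFrame(table.values.T, index=ids, columns=table.sample_ids)
    df.index.name = "taxon"
    df.to_csv(path, sep=_sep_for(path))


def write_report(results, path) -> None:
    """Write test results as a long-format TSV report."""
    rows = []
    for rank, res in results:
        rows.append(
            {
                "method": res.method,
                "rank": rank,
                "p": res.p,
                "n1": res.n1,
                "n2": res.n2,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "reject": res.reject,
                "alpha": res.alpha,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
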