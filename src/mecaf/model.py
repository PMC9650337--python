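"""Model/results layer for two-group differential-abundance testing.

`DifferentialAbundanceModel` wraps an :class:`AbundanceTable` with group
labels and runs the transform pipeline (pseudo-count -> optional rank
aggregation -> composition -> representation per method) once; ``fit``
evaluates a chosen test and returns a results object with the
per-component standardized statistics, the global p-value and a
``summary()`` table, in the spirit of statsmodels' Model/Results split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import dtest
from .compositions import (
    AbundanceTable,
    aggregate_to_rank,
    clr_transform,
    impute_zeros,
    to_composition,
)

__all__ = ["DifferentialAbundanceModel", "DifferentialAbundanceResults"]


class DifferentialAbundanceModel:
    """Two-group comparison of mean microbiome compositions.

    Parameters
    ----------
    table : AbundanceTable
        Counts or abundances with a two-level group label.
    pseudo : float
        Pseudo-count replacing zeros before closure (default 0.5).
    rank : str, optional
        Aggregate to this taxonomic rank first (requires lineages).
    levels : sequence, optional
        Orders the two group labels (first = group 1); default is
        lexicographic.
    """

    def __init__(self, table: AbundanceTable, pseudo: float = 0.5, rank: str | None = None,
                 levels: Sequence | None = None):
        if rank is not None:
            table = aggregate_to_rank(table, rank)
        self.table = table
        self.pseudo = pseudo
        self.rank = rank
        self.levels = levels
        t1, t2 = table.split_groups(levels)
        self.comp1 = to_composition(impute_zeros(t1, pseudo))
        self.comp2 = to_composition(impute_zeros(t2, pseudo))
        self.clr1 = clr_transform(self.comp1)
        self.clr2 = clr_transform(self.comp2)

    @classmethod
    def from_dataframe(
        cls,
        counts: pd.DataFrame,
        metadata: pd.DataFrame,
        group_col: str = "group",
        **kwargs,
    ) -> "DifferentialAbundanceModel":
        """Build from a taxa-by-samples DataFrame plus sample metadata.

        ``counts`` rows are taxa (index = taxon id or lineage string),
        columns are samples; ``metadata`` needs ``sample_id`` and
        ``group_col`` columns.
        """
        from .io import attach_groups

        ids = [str(t) for t in counts.index]
        lineages = ids if all("__" in t for t in ids) else None
        table = AbundanceTable(
            counts.values.T,
            sample_ids=[str(c) for c in counts.columns],
            taxon_ids=ids,
            lineages=lineages,
        )
        meta = metadata.astype({"sample_id": str}) if "sample_id" in metadata else metadata
        table = attach_groups(table, meta, group_col=group_col, levels=kwargs.pop("levels", None))
        return cls(table, **kwargs)

    def fit(
        self,
        method: str = "mecaf",
        alpha: float = 0.05,
        n_perm: int = 999,
        seed=None,
        **kwargs,
    ) -> "DifferentialAbundanceResults":
        """Run one test; ``method`` in {mecaf, mec, mec-log, mec-raw, permanova}."""
        m = method.lower()
        if m == "mecaf":
            res = dtest.mecaf_test(self.clr1, self.clr2, alpha=alpha, **kwargs)
        elif m == "mec":
            res = dtest.mec_test(self.clr1, self.clr2, alpha=alpha, seed=seed,
                                 n_perm=n_perm, **kwargs)
        elif m in ("mec-log", "mec-raw"):
            res = dtest.mec_variant_test(
                self.comp1, self.comp2, m.split("-")[1], alpha=alpha,
                n_perm=n_perm, seed=seed, simulation=False, **kwargs,
            )
        elif m == "mec-oracle":
            raise ValueError(
                "MEC-Oracle needs absolute abundances, unobservable in real data"
            )
        elif m == "permanova":
            res = dtest.permanova_test(
                self.comp1, self.comp2, n_perm=n_perm, seed=seed, alpha=alpha, **kwargs
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        return DifferentialAbundanceResults(self, res)


@dataclass
class DifferentialAbundanceResults:
    """Fitted test with per-taxon diagnostics and a summary table."""

    model: DifferentialAbundanceModel
    test: dtest.TestResult

    @property
    def statistic(self) -> float:
        return self.test.statistic

    @property
    def pvalue(self) -> float:
        return self.test.p_value

    @property
    def reject(self) -> bool:
        return self.test.reject

    def component_frame(self) -> pd.DataFrame:
        """Per-taxon CLR mean differences and squared standardized statistics.

        Components the max ran over carry the test's ``component_stat``;
        the dropped (last) CLR component is NaN there for MECAF.
        """
        c1, c2 = self.model.clr1, self.model.clr2
        diff = c1.values.mean(axis=0) - c2.values.mean(axis=0)
        frame = pd.DataFrame(
            {
                "taxon": c1.taxon_ids,
                "clr_mean_1": c1.values.mean(axis=0),
                "clr_mean_2": c2.values.mean(axis=0),
                "clr_mean_diff": diff,
            }
        ).set_index("taxon")
        if self.test.per_component is not None:
            stats = np.full(len(frame), np.nan)
            stats[: len(self.test.per_component)] = self.test.per_component
            frame["component_stat"] = stats
        return frame

    def top_taxa(self, k: int = 10) -> pd.DataFrame:
        """The k taxa with the largest per-component statistics."""
        frame = self.component_frame()
        if "component_stat" not in frame:
            raise ValueError("per-component statistics unavailable for this method")
        return frame.sort_values("component_stat", ascending=False).head(k)

    def summary(self) -> str:
        t = self.test
        lines = [
            f"Two-sample differential abundance test ({t.method})",
            "=" * 52,
            f"taxa (p):           {t.p}",
            f"group sizes:        n1 = {t.n1}, n2 = {t.n2}",
            f"statistic:          {t.statistic:.4f}",
        ]
        if t.standardized is not None:
            lines.append(f"standardized:       {t.standardized:.4f}")
        lines += [
            f"p-value:            {t.p_value:.4g}",
            f"reject at alpha={t.alpha:g}: {t.reject}",
        ]
        if t.per_component is not None:
            top = self.top_taxa(min(5, len(t.per_component)))
            lines.append("")
            lines.append("largest per-component statistics:")
            for taxon, row in top.iterrows():
                lines.append(
                    f"  {str(taxon)[:40]:<42} {row['component_stat']:8.3f}"
                    f"  (CLR mean diff {row['clr_mean_diff']:+.3f})"
                )
        return "\n".join(lines)

    def plot_components(self, ax=None, k: int | None = None):
        """Bar plot of the per-component squared standardized differences."""
        import matplotlib.pyplot as plt

        if self.test.per_component is None:
            raise ValueError("per-component statistics unavailable for this method")
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        vals = self.test.per_component
        order = np.argsort(vals)[::-1]
        if k is not None:
            order = order[:k]
        ax.bar(range(len(order)), vals[order])
        ax.set_xticks(range(len(order)))
        ax.set_xticklabels(
            [self.model.clr1.taxon_ids[i] for i in order], rotation=90, fontsize=6
        )
        ax.set_ylabel("squared standardized diff")
        ax.set_title(f"{self.test.method}: per-component statistics")
        return ax
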