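"""Cross-strain, cross-omics and cross-tissue convergence rules.

The integrative layer operates on a contrast grid — a mapping
(dataset, strain, contrast) -> result table; the canonical grid of the
analysis is 2 strains x 3 phenotype contrasts x 2 omics layers = 12
comparisons. Its rules are deliberately simple set/threshold operations:

* direction concordance of DE features shared between two strains, with an
  exact binomial test of the same-direction count against 0.5;
* pathway convergence: a pathway is selected when it is FDR-significant in
  at least 2 of the 12 comparisons and nominally significant in at least 4;
* regulator selection: FDR-significant in at least 25% of comparisons;
* cross-omics overlap: molecules DE in the same (strain, contrast) cell in
  at least two data sets, joined case-insensitively on gene symbol;
* miRNA-target pairing: interaction-table pairs with more than two evidence
  sources whose miRNA and target mRNA are DE in the same direction;
* cross-tissue correlation of fold changes over a gene subset;
* a multi-comparison GSEA summary keeping sets FDR-significant (at an
  exploratory 25% FDR) in at least half of the comparisons.

Missing comparisons in any grid count as non-significant, never as errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "ConcordanceSummary",
    "cross_strain_concordance",
    "pathway_convergence",
    "regulator_selection",
    "cross_omics_overlap",
    "mirna_target_pairs",
    "cross_tissue_correlation",
    "gsea_summary_filter",
    "union_heatmap_table",
]


@dataclass
class ConcordanceSummary:
    """Direction agreement of DE features common to two comparisons."""

    common: list[str]
    n_same: int
    n_opposite: int
    p_binomial: float  # two-sided vs 0.5; NaN when no common features

    @property
    def opposite_fraction(self) -> float:
        total = self.n_same + self.n_opposite
        return self.n_opposite / total if total else float("nan")


def cross_strain_concordance(de_a: pd.DataFrame, de_b: pd.DataFrame) -> ConcordanceSummary:
    """Compare DE directions of features flagged in both input tables.

    Inputs are flagged DE tables (``de_flag`` output) from the same contrast
    in two strains. Directions are compared by sign(logFC); the two-sided
    binomial P tests the same-direction count against chance (0.5). An
    empty intersection yields an empty summary with P = NaN.
    """
    a = de_a.set_index("feature_id")["logFC"]
    b = de_b.set_index("feature_id")["logFC"]
    common = sorted(set(a.index) & set(b.index))
    if not common:
        return ConcordanceSummary([], 0, 0, float("nan"))
    same = int((np.sign(a[common]).to_numpy() == np.sign(b[common]).to_numpy()).sum())
    n = len(common)
    p = float(stats.binomtest(same, n, 0.5, alternative="two-sided").pvalue)
    return ConcordanceSummary(common, same, n - same, p)


def _grid_key(key) -> str:
    return "/".join(map(str, key)) if isinstance(key, tuple) else str(key)


def _stack_grid(grid: Mapping, value_cols: Sequence[str], key_col: str) -> pd.DataFrame:
    if not grid:
        raise InvalidInputError("empty contrast grid")
    frames = []
    for key, table in grid.items():
        t = table[[key_col, *value_cols]].copy()
        t["comparison"] = _grid_key(key)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def pathway_convergence(
    grid: Mapping,
    fdr_hits: int = 2,
    nominal_hits: int = 4,
    fdr: float = 0.05,
    nominal: float = 0.05,
    name_col: str = "set_name",
) -> pd.DataFrame:
    """Select pathways recurrently significant across the comparison grid.

    A pathway is selected when it reaches PFDR < ``fdr`` in at least
    ``fdr_hits`` comparisons AND P < ``nominal`` in at least
    ``nominal_hits`` comparisons. Missing (pathway, comparison) cells count
    as non-significant. Returns a per-pathway table with hit counts and the
    selection flag.
    """
    stacked = _stack_grid(grid, ["P", "PFDR"], name_col)
    agg = stacked.groupby(name_col).agg(
        n_fdr=("PFDR", lambda s: int((s < fdr).sum())),
        n_nominal=("P", lambda s: int((s < nominal).sum())),
        n_tested=("P", "size"),
    )
    agg["selected"] = (agg["n_fdr"] >= fdr_hits) & (agg["n_nominal"] >= nominal_hits)
    return agg.reset_index().sort_values(name_col, kind="mergesort").reset_index(drop=True)


def regulator_selection(
    grid: Mapping,
    fraction: float = 0.25,
    fdr: float = 0.05,
    name_col: str = "regulator",
) -> pd.DataFrame:
    """Select regulators FDR-significant in at least ``fraction`` of comparisons.

    The threshold count is ceil(fraction x n_comparisons) over the grid's
    comparisons (not only those where the regulator was scored); missing
    cells count as non-significant.
    """
    if not grid:
        raise InvalidInputError("empty contrast grid")
    n_comparisons = len(grid)
    need = ceil(fraction * n_comparisons)
    stacked = _stack_grid(grid, ["PFDR"], name_col)
    agg = stacked.groupby(name_col).agg(n_fdr=("PFDR", lambda s: int((s < fdr).sum())))
    agg["n_comparisons"] = n_comparisons
    agg["selected"] = agg["n_fdr"] >= need
    return agg.reset_index().sort_values(name_col, kind="mergesort").reset_index(drop=True)


def cross_omics_overlap(
    grid: Mapping[tuple[str, str, str], pd.DataFrame],
    display_p: float = 0.01,
    p_thresh: float = 0.05,
    fc_thresh: float = 1.2,
    categories: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Molecules DE in the same (strain, contrast) cell in >= 2 data sets.

    Grid keys are (dataset, strain, contrast); tables are full DE tables.
    Identifiers are harmonized case-insensitively (gene-symbol join); the
    reported symbol is the first-seen casing. Each overlapping molecule is
    annotated with its pathway-category membership (via ``categories``,
    symbol -> label) and whether it passes the ``display_p`` nominal filter
    in at least one comparison.
    """
    if not grid:
        raise InvalidInputError("empty contrast grid")
    lfc_floor = np.log2(fc_thresh)
    seen_casing: dict[str, str] = {}
    hits: dict[tuple[str, str, str], set[str]] = {}  # (symbol, strain, contrast) -> datasets
    display_ok: set[str] = set()
    for (dataset, strain, contrast), table in grid.items():
        flagged = table.loc[
            (table["P"] < p_thresh) & (table["logFC"].abs() >= lfc_floor)
        ]
        for fid, p in zip(flagged["feature_id"], flagged["P"]):
            sym = str(fid).lower()
            seen_casing.setdefault(sym, str(fid))
            hits.setdefault((sym, strain, contrast), set()).add(dataset)
            if p < display_p:
                display_ok.add(sym)

    rows = []
    for (sym, strain, contrast), datasets in sorted(hits.items()):
        if len(datasets) < 2:
            continue
        symbol = seen_casing[sym]
        rows.append(
            {
                "feature_id": symbol,
                "strain": strain,
                "contrast": contrast,
                "n_datasets": len(datasets),
                "datasets": ",".join(sorted(datasets)),
                "category": (categories or {}).get(symbol, "unassigned"),
                "passes_display_p": sym in display_ok,
            }
        )
    cols = [
        "feature_id", "strain", "contrast", "n_datasets", "datasets",
        "category", "passes_display_p",
    ]
    return pd.DataFrame(rows, columns=cols)


def mirna_target_pairs(
    de_mirna: pd.DataFrame,
    de_mrna: pd.DataFrame,
    interactions: pd.DataFrame,
    min_sources: int = 3,
) -> pd.DataFrame:
    """Same-direction miRNA-mRNA pairs with enough interaction evidence.

    Retains interaction-table pairs with at least ``min_sources`` evidence
    sources (the "more than two sources" rule, since curated pairs list
    exactly three tools) whose miRNA and target mRNA are both flagged DE in
    the queried comparison with matching direction signs.
    """
    if interactions.empty:
        raise InvalidInputError("empty interaction table")
    required = {"mirna", "target", "n_sources"}
    missing = required - set(interactions.columns)
    if missing:
        raise InvalidInputError(f"interaction table missing columns: {sorted(missing)}")
    mir_dir = dict(zip(de_mirna["feature_id"], de_mirna["direction"]))
    mrna_dir = dict(zip(de_mrna["feature_id"], de_mrna["direction"]))
    keep = []
    for row in interactions.sort_values(["mirna", "target"], kind="mergesort").itertuples():
        if row.n_sources < min_sources:
            continue
        dm, dt = mir_dir.get(row.mirna), mrna_dir.get(row.target)
        if dm is None or dt is None or dm != dt:
            continue
        keep.append(
            {
                "mirna": row.mirna,
                "target": row.target,
                "n_sources": int(row.n_sources),
                "direction": int(dm),
            }
        )
    return pd.DataFrame(keep, columns=["mirna", "target", "n_sources", "direction"])


def cross_tissue_correlation(
    fc_tissue1: pd.DataFrame,
    fc_tissue2: pd.DataFrame,
    subset: Sequence[str] | None = None,
    on: str = "logFC",
) -> tuple[float, float, int]:
    """Pearson correlation of per-gene fold changes between two tissues.

    ``subset`` restricts to a gene list (e.g. genes nominally DE in tissue 1
    and expressed in tissue 2); None uses all shared genes. ``on`` selects
    the correlated column — "logFC" (default) or any other shared numeric
    column such as a mean-expression column. Returns ``(r, p, n)`` with the
    P-value from the t-transform with n-2 degrees of freedom.
    """
    a = fc_tissue1.set_index("feature_id")[on]
    b = fc_tissue2.set_index("feature_id")[on]
    genes = set(a.index) & set(b.index)
    if subset is not None:
        genes &= set(subset)
    genes = sorted(genes)
    if len(genes) < 3:
        raise InsufficientDataError(f"need >= 3 shared genes, got {len(genes)}")
    res = stats.pearsonr(a[genes].to_numpy(), b[genes].to_numpy())
    return float(res.statistic), float(res.pvalue), len(genes)


def gsea_summary_filter(
    grid: Mapping, fdr: float = 0.25, fraction: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep gene sets FDR-significant in at least ``fraction`` of comparisons.

    Grid values are enrichment tables (``set_name, NES, PFDR, ...``). A set
    passes when PFDR < ``fdr`` in at least ceil(fraction x n_comparisons)
    comparisons; missing cells count as non-significant. Returns
    ``(summary, nes_matrix)`` — the per-set hit counts with selection flags,
    and the sets x comparisons NES matrix with NaN marking unavailable or
    non-significant cells (the display convention of the summary heatmap).
    """
    if not grid:
        raise InvalidInputError("empty enrichment grid")
    n_comparisons = len(grid)
    need = ceil(fraction * n_comparisons)
    stacked = _stack_grid(grid, ["NES", "PFDR"], "set_name")
    agg = stacked.groupby("set_name").agg(
        n_fdr=("PFDR", lambda s: int((s < fdr).sum())),
    )
    agg["n_comparisons"] = n_comparisons
    agg["selected"] = agg["n_fdr"] >= need
    summary = agg.reset_index().sort_values("set_name", kind="mergesort").reset_index(drop=True)

    selected = summary.loc[summary["selected"], "set_name"]
    sig = stacked.loc[
        stacked["set_name"].isin(selected) & (stacked["PFDR"] < fdr)
    ]
    nes = sig.pivot_table(index="set_name", columns="comparison", values="NES", aggfunc="first")
    # make sure every grid comparison appears as a column, NA where absent
    nes = nes.reindex(columns=[_grid_key(k) for k in grid.keys()], index=sorted(selected))
    return summary, nes


def union_heatmap_table(
    de_tables: Sequence[pd.DataFrame], order_by: str
) -> pd.DataFrame:
    """Fold-change matrix over the union of flagged features, rank-ordered.

    ``de_tables`` are flagged DE tables (each one comparison); rows are the
    union of their features ordered by FC in the ``order_by`` contrast
    (descending, ties broken by feature id), with NaN where a feature was
    not flagged in a comparison. Columns are labeled dataset/contrast.
    """
    if not de_tables:
        raise InvalidInputError("no DE tables supplied")
    cols = {}
    order_fc = None
    for t in de_tables:
        label = f"{t['dataset'].iloc[0]}/{t['contrast'].iloc[0]}" if len(t) else "empty"
        cols[label] = t.set_index("feature_id")["FC"]
        if len(t) and t["contrast"].iloc[0] == order_by:
            order_fc = cols[label]
    mat = pd.DataFrame(cols)
    if order_fc is None:
        raise InvalidInputError(f"no input table has contrast {order_by!r}")
    key = order_fc.reindex(mat.index)
    mat = mat.loc[
        pd.DataFrame({"fc": -key, "id": mat.index}).sort_values(
            ["fc", "id"], kind="mergesort", na_position="last"
        ).index
    ]
    mat.index.name = "feature_id"
    return mat
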