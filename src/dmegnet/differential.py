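"""Differential methylation/expression calling and quadrant integration.

Two-group Welch tests produce per-feature effect sizes (delta-beta for
methylation on the [0,1] beta scale, log2 fold-change for expression) with
Benjamini-Hochberg adjusted p-values. Threshold rules then call
differentially methylated sites/genes (DMS/DMG) and differentially
expressed genes (DEG), and genes that pass both filters (DMEGs) are placed
into the four methylation x expression quadrants (HyperUp, HyperDown,
HypoUp, HypoDown). A one-sided hypergeometric test provides gene-set
over-representation against user-supplied collections.

Default thresholds: DMS |delta-beta| > 0.3 at FDR < 0.05; DMG delta-beta
beyond +/-0.3 at FDR < 0.01; DEG |log2FC| > 1 at FDR < 0.01. All
inequalities are strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DMEGRecord",
    "two_group_test",
    "bh_adjust",
    "call_dms",
    "call_dmg",
    "call_deg",
    "classify_dmeg",
    "region_union",
    "gene_set_enrichment",
]

#: quadrant label implied by (methylation direction, expression direction)
QUADRANT = {
    ("hyper", "up"): "HyperUp",
    ("hyper", "down"): "HyperDown",
    ("hypo", "up"): "HypoUp",
    ("hypo", "down"): "HypoDown",
}


@dataclass(frozen=True)
class DMEGRecord:
    """A gene that is both differentially methylated and expressed in one region."""

    gene: str
    region: str
    methylation: str  # hyper | hypo
    expression: str  # up | down
    meth_fdr: float = float("nan")

    @property
    def group(self) -> str:
        return QUADRANT[(self.methylation, self.expression)]


def two_group_test(
    matrix: pd.DataFrame,
    group_a: set[str] | list[str],
    group_b: set[str] | list[str],
    statistic: str = "welch",
) -> pd.DataFrame:
    """Per-feature two-sample test of group B against group A.

    Returns a table with columns (effect, p, fdr) indexed by feature, where
    effect = mean(B) - mean(A) on the matrix scale. ``statistic`` is
    "welch" (default), "student" (pooled variance) or "mannwhitney";
    the effect column is the mean difference in every case. Features with
    zero variance in both groups get p = 1. The FDR column is BH-adjusted
    over all tested features.
    """
    group_a, group_b = sorted(set(group_a)), sorted(set(group_b))
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = matrix[group_a].to_numpy(dtype=float)
    b = matrix[group_b].to_numpy(dtype=float)
    effect = np.nanmean(b, axis=1) - np.nanmean(a, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        if statistic == "welch":
            result = stats.ttest_ind(b, a, axis=1, equal_var=False, nan_policy="omit")
        elif statistic == "student":
            result = stats.ttest_ind(b, a, axis=1, equal_var=True, nan_policy="omit")
        elif statistic == "mannwhitney":
            result = stats.mannwhitneyu(b, a, axis=1, nan_policy="omit")
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    p = np.asarray(result.pvalue, dtype=float)
    degenerate = (np.nanvar(a, axis=1) == 0) & (np.nanvar(b, axis=1) == 0)
    p[degenerate] = 1.0
    p[np.isnan(p)] = 1.0
    return pd.DataFrame({"effect": effect, "p": p, "fdr": bh_adjust(p)}, index=matrix.index)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dms(table: pd.DataFrame, fdr_max: float = 0.05, abs_delta_min: float = 0.3) -> set[str]:
    """Differentially methylated sites: |delta-beta| > threshold and FDR < cut (strict)."""
    keep = (table["effect"].abs() > abs_delta_min) & (table["fdr"] < fdr_max)
    return set(table.index[keep])


def call_dmg(
    table: pd.DataFrame, fdr_max: float = 0.01, delta_min: float = 0.3
) -> tuple[set[str], set[str]]:
    """Differentially methylated genes as (hyper, hypo) sets.

    hyper: delta-beta > delta_min; hypo: delta-beta < -delta_min; both at
    FDR < fdr_max, all strict.
    """
    sig = table["fdr"] < fdr_max
    hyper = set(table.index[sig & (table["effect"] > delta_min)])
    hypo = set(table.index[sig & (table["effect"] < -delta_min)])
    return hyper, hypo


def call_deg(
    table: pd.DataFrame, fdr_max: float = 0.01, lfc_min: float = 1.0
) -> tuple[set[str], set[str]]:
    """Differentially expressed genes as (up, down) sets at |log2FC| > lfc_min, FDR < fdr_max."""
    sig = table["fdr"] < fdr_max
    up = set(table.index[sig & (table["effect"] > lfc_min)])
    down = set(table.index[sig & (table["effect"] < -lfc_min)])
    return up, down


def classify_dmeg(
    dmg_by_region: dict[str, tuple[set[str], set[str]]],
    deg: tuple[set[str], set[str]],
    meth_fdr: dict[tuple[str, str], float] | None = None,
) -> list[DMEGRecord]:
    """Assign each per-region DMG that is also a DEG to its quadrant.

    ``dmg_by_region`` maps region -> (hyper set, hypo set); ``deg`` is
    (up set, down set). ``meth_fdr`` optionally supplies the methylation FDR
    per (gene, region) so cross-region conflicts can later be resolved by
    smallest FDR.
    """
    up, down = deg
    records: list[DMEGRecord] = []
    for region in sorted(dmg_by_region):
        hyper, hypo = dmg_by_region[region]
        clash = hyper & hypo
        if clash:
            raise ValueError(f"genes both hyper and hypo in {region}: {sorted(clash)}")
        for meth_dir, gene_set in (("hyper", hyper), ("hypo", hypo)):
            for gene in sorted(gene_set):
                for expr_dir, expr_set in (("up", up), ("down", down)):
                    if gene in expr_set:
                        fdr = meth_fdr.get((gene, region), float("nan")) if meth_fdr else float("nan")
                        records.append(
                            DMEGRecord(gene, region, meth_dir, expr_dir, meth_fdr=fdr)
                        )
    return records


def region_union(records: list[DMEGRecord]) -> dict:
    """Summarise DMEG records across regions.

    Returns a dict with: ``genes`` (the union, each gene once),
    ``group_counts`` (quadrant tally on the union), ``region_counts``
    (records per region), ``genes_by_n_regions`` (Venn-style 1/2/3-region
    buckets), and ``conflicts`` (genes whose quadrant differs across
    regions). A conflicted gene keeps the quadrant of its smallest
    methylation-FDR record (ties: lexicographic region order).
    """
    by_gene: dict[str, list[DMEGRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene, []).append(rec)

    group_counts = {g: 0 for g in ("HyperUp", "HyperDown", "HypoUp", "HypoDown")}
    genes_by_n_regions: dict[int, set[str]] = {}
    conflicts: dict[str, str] = {}
    for gene, recs in by_gene.items():
        n_regions = len({r.region for r in recs})
        genes_by_n_regions.setdefault(n_regions, set()).add(gene)
        groups = {r.group for r in recs}
        best = min(
            recs,
            key=lambda r: (r.meth_fdr if np.isfinite(r.meth_fdr) else np.inf, r.region),
        )
        if len(groups) > 1:
            conflicts[gene] = best.group
        group_counts[best.group] += 1

    region_counts: dict[str, int] = {}
    for rec in records:
        region_counts[rec.region] = region_counts.get(rec.region, 0) + 1
    return {
        "genes": set(by_gene),
        "group_counts": group_counts,
        "region_counts": region_counts,
        "genes_by_n_regions": {k: sorted(v) for k, v in sorted(genes_by_n_regions.items())},
        "conflicts": conflicts,
    }


def gene_set_enrichment(
    query: set[str], universe: set[str], sets: dict[str, set[str]]
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each set.

    All sets are intersected with ``universe`` first. p is the upper-tail
    probability of drawing at least the observed overlap when |query| genes
    are sampled from the universe without replacement; FDR is BH over sets.
    """
    query, universe = set(query), set(universe)
    if not query:
        raise ValueError("query gene set is empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    m = len(universe)
    n = len(query)
    rows = []
    for name in sorted(sets):
        members = sets[name] & universe
        if not members:
            continue
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, m, len(members), n))
        rows.append((name, k, len(members), p))
    table = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"]).set_index("set")
    table["fdr"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return table.sort_values("p")
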