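"""Sample stratification and probe-to-gene-region aggregation.

Tumour samples are split into marker-negative / marker-positive classes by
comparing the marker gene (PD-1 in the motivating application) against the
mean of the normal samples. Probe-level methylation beta values are averaged
into gene-region-level values using a probe annotation table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ALLOWED_REGIONS", "SampleGroups", "stratify_by_reference_mean", "aggregate_probe_beta"]

ALLOWED_REGIONS = frozenset(
    {"Body", "TSS200", "TSS1500", "5'UTR", "3'UTR", "1stExon", "Intergenic"}
)


@dataclass
class SampleGroups:
    """Tissue labels for all samples and marker labels for tumour samples."""

    tissue: dict[str, str]  # sample -> normal | tumor
    marker: dict[str, str]  # tumour sample -> negative | positive
    reference_mean: float

    @property
    def negative(self) -> set[str]:
        return {s for s, lab in self.marker.items() if lab == "negative"}

    @property
    def positive(self) -> set[str]:
        return {s for s, lab in self.marker.items() if lab == "positive"}

    def counts(self) -> dict[str, int]:
        return {
            "normal": sum(v == "normal" for v in self.tissue.values()),
            "tumor": sum(v == "tumor" for v in self.tissue.values()),
            "negative": len(self.negative),
            "positive": len(self.positive),
        }


def stratify_by_reference_mean(
    expr: pd.DataFrame,
    marker_gene: str,
    normal_ids: set[str] | list[str],
    tumor_ids: set[str] | list[str],
) -> SampleGroups:
    """Label tumour samples negative/positive against the normal-sample mean.

    A tumour sample is *negative* iff its marker expression is strictly
    lower than the mean marker expression over ``normal_ids``; samples at or
    above the mean are *positive*. Samples outside the two id sets are
    ignored.
    """
    if marker_gene not in expr.index:
        raise KeyError(f"marker gene {marker_gene!r} not in expression matrix")
    normal_ids, tumor_ids = set(normal_ids), set(tumor_ids)
    if not normal_ids:
        raise ValueError("normal sample set is empty")
    if normal_ids & tumor_ids:
        raise ValueError("normal and tumour id sets overlap")
    missing = (normal_ids | tumor_ids) - set(expr.columns)
    if missing:
        raise KeyError(f"sample ids absent from matrix: {sorted(missing)}")

    marker = expr.loc[marker_gene]
    ref_mean = float(marker[sorted(normal_ids)].mean())
    tissue = {s: "normal" for s in normal_ids}
    tissue.update({s: "tumor" for s in tumor_ids})
    labels = {
        s: ("negative" if float(marker[s]) < ref_mean else "positive") for s in sorted(tumor_ids)
    }
    return SampleGroups(tissue=tissue, marker=labels, reference_mean=ref_mean)


def aggregate_probe_beta(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    regions: set[str] | list[str] = ("Body", "TSS200", "TSS1500"),
) -> pd.DataFrame:
    """Average probe beta values into (gene, region) rows.

    The value for (gene, region, sample) is the arithmetic mean of the
    non-missing beta values over the probes annotated to that pair; a probe
    annotated to several pairs contributes to all of them. Pairs with no
    probe in the beta matrix are not emitted; a sample whose probes are all
    missing stays missing.
    """
    regions = set(regions)
    unknown = regions - ALLOWED_REGIONS
    if unknown:
        raise ValueError(f"unknown region tags {sorted(unknown)}; allowed: {sorted(ALLOWED_REGIONS)}")
    ann = annotation[annotation["region"].isin(regions)]
    ann = ann[ann["probe"].isin(beta.index)]
    if ann.empty:
        warnings.warn("no probe maps to any requested region; empty output", stacklevel=2)
        empty = pd.DataFrame(
            index=pd.MultiIndex.from_tuples([], names=["gene", "region"]), columns=beta.columns
        )
        return empty.astype(float)

    values = beta.loc[ann["probe"]].to_numpy(dtype=float)
    frame = pd.DataFrame(values, columns=beta.columns)
    frame["gene"] = ann["gene"].to_numpy()
    frame["region"] = ann["region"].to_numpy()
    agg = frame.groupby(["gene", "region"], sort=True).mean()  # skips NaN per cell
    return agg
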