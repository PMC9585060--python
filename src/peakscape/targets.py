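"""Direct-target calling: intersect differential expression with binding.

Sign convention (important): log2fc is mutant relative to control, so a
gene that the TF *activates* is LOWER in the mutant and has log2fc <= -0.5;
a repressed gene has log2fc >= +0.5. Genes whose expression is below the
minimum mean count in both genotypes are filtered before direction calls.

A gene is "bound" when it is the assigned (nearest-promoter) gene of at
least one peak; a direct target is a bound gene called activated or
repressed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import PeakAnnotation

__all__ = [
    "TargetSummary",
    "classify_de",
    "classify_de_table",
    "call_direct_targets",
    "direct_pct",
]

DIRECTIONS = ("activated", "repressed", "unchanged", "filtered")


@dataclass(frozen=True)
class TargetSummary:
    n_activated: int
    n_repressed: int
    n_direct_activated: int
    n_direct_repressed: int
    pct_direct_activated: float
    pct_direct_repressed: float

    def to_dict(self) -> dict:
        return asdict(self)


def direct_pct(n_direct: int, n_total: int) -> float:
    """Percentage of direct targets among DE genes, 1-decimal rounded."""
    if n_direct > n_total:
        raise ValueError("direct count exceeds total")
    if n_total == 0:
        return 0.0
    return round(100.0 * n_direct / n_total, 1)


def classify_de(log2fc: float, fdr: float, mean_count_control: float,
                mean_count_mutant: float, lfc_threshold: float = 0.5,
                fdr_threshold: float = 0.05,
                min_mean_count: float = 25.0) -> str:
    """Direction call for one DE row.

    filtered when neither genotype reaches ``min_mean_count``; activated
    when log2fc <= -lfc_threshold and fdr < fdr_threshold (lower in the
    mutant means the TF was driving expression); repressed mirrored;
    otherwise unchanged. The log2fc threshold is inclusive, the fdr
    threshold strict.
    """
    for v, name in ((log2fc, "log2fc"), (fdr, "fdr"),
                    (mean_count_control, "mean_count_control"),
                    (mean_count_mutant, "mean_count_mutant")):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"missing DE field {name}")
    if max(mean_count_control, mean_count_mutant) < min_mean_count:
        return "filtered"
    if fdr < fdr_threshold:
        if log2fc <= -lfc_threshold:
            return "activated"
        if log2fc >= lfc_threshold:
            return "repressed"
    return "unchanged"


def classify_de_table(de: pd.DataFrame, lfc_threshold: float = 0.5,
                      fdr_threshold: float = 0.05,
                      min_mean_count: float = 25.0) -> pd.Series:
    """Vectorized direction call for a whole DE table."""
    if de[["log2fc", "fdr", "mean_count_control", "mean_count_mutant"]].isna().any().any():
        raise ValueError("DE table contains missing values")
    expressed = de[["mean_count_control", "mean_count_mutant"]].max(axis=1) >= min_mean_count
    sig = de["fdr"] < fdr_threshold
    direction = pd.Series("unchanged", index=de.index)
    direction[sig & (de["log2fc"] <= -lfc_threshold)] = "activated"
    direction[sig & (de["log2fc"] >= lfc_threshold)] = "repressed"
    direction[~expressed] = "filtered"
    return direction


def call_direct_targets(de: pd.DataFrame,
                        annotations: Sequence[PeakAnnotation],
                        lfc_threshold: float = 0.5,
                        fdr_threshold: float = 0.05,
                        min_mean_count: float = 25.0,
                        max_tss_distance: int | None = None
                        ) -> tuple[pd.DataFrame, TargetSummary]:
    """Per-gene target calls plus the summary fractions.

    Returns a DataFrame with columns gene_id, direction, bound, direct.
    ``max_tss_distance`` optionally restricts "bound" to assignments whose
    |distance to TSS| is within the cap; by default any assignment counts.
    """
    bound_genes: set[str] = set()
    for a in annotations:
        if a.assigned_gene is None:
            continue
        if max_tss_distance is not None and (
            a.distance_to_tss is None or abs(a.distance_to_tss) > max_tss_distance
        ):
            continue
        bound_genes.add(a.assigned_gene)

    calls = de[["gene_id"]].copy()
    calls["direction"] = classify_de_table(de, lfc_threshold, fdr_threshold,
                                           min_mean_count)
    calls["bound"] = calls["gene_id"].isin(bound_genes)
    calls["direct"] = calls["bound"] & calls["direction"].isin(["activated",
                                                                "repressed"])
    calls = calls.sort_values("gene_id", kind="stable").reset_index(drop=True)

    n_act = int((calls["direction"] == "activated").sum())
    n_rep = int((calls["direction"] == "repressed").sum())
    n_da = int((calls["direct"] & (calls["direction"] == "activated")).sum())
    n_dr = int((calls["direct"] & (calls["direction"] == "repressed")).sum())
    summary = TargetSummary(n_act, n_rep, n_da, n_dr,
                            direct_pct(n_da, n_act), direct_pct(n_dr, n_rep))
    return calls, summary
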