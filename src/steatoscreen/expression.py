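"""qPCR relative quantification (delta-delta-Cq) and DEG set arithmetic.

Relative expression follows the classic comparative-Cq method with an
assumed amplification efficiency of 2: per sample,
``dCq = Cq_target - mean(Cq_reference)``; per gene and treatment group,
``ddCq = mean(dCq_treated) - mean(dCq_control)`` and the fold change versus
control is ``2 ** (-ddCq)`` (control = 1). Group comparisons use a
two-sample t-test for two groups and one-way ANOVA with Tukey's post hoc for
three or more.

The module also provides the fold-change/p-value filter used to define
differentially expressed gene (DEG) sets from an external DE table, and
3-set Venn arithmetic over gene-id sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FoldChangeResult",
    "ddcq",
    "DEGSet",
    "filter_degs",
    "venn3",
]


@dataclass
class FoldChangeResult:
    gene: str
    group: str
    fold_change: float  # vs control; control == 1
    dcq_mean: float
    ddcq: float
    n: int
    p_value: float


def _sample_dcq(table: pd.DataFrame, reference_genes: list[str]) -> pd.DataFrame:
    """Per (sample, gene) replicate-mean Cq minus the sample's reference mean."""
    mean_cq = (
        table.groupby(["sample", "group", "gene"])["cq"].mean().reset_index()
    )
    refs = mean_cq[mean_cq["gene"].isin(reference_genes)]
    ref_mean = refs.groupby("sample")["cq"].mean().rename("ref_cq")
    for sample in mean_cq["sample"].unique():
        present = set(refs.loc[refs["sample"] == sample, "gene"])
        missing = set(reference_genes) - present
        if missing:
            raise ValueError(
                f"sample {sample!r} is missing reference gene(s): {sorted(missing)}"
            )
    out = mean_cq[~mean_cq["gene"].isin(reference_genes)].merge(ref_mean, on="sample")
    out["dcq"] = out["cq"] - out["ref_cq"]
    return out


def ddcq(
    cq_table: pd.DataFrame,
    control_group: str,
    reference_genes: list[str],
) -> list[FoldChangeResult]:
    """Comparative-Cq relative expression of every target gene and group.

    ``cq_table`` needs columns (sample, group, gene, cq); replicate rows per
    (sample, gene) are averaged first. Cq values far outside the usual
    instrument range trigger a warning. Returns one result per
    (gene, non-control group).
    """
    required = {"sample", "group", "gene", "cq"}
    missing = required - set(cq_table.columns)
    if missing:
        raise ValueError(f"Cq table missing columns: {sorted(missing)}")
    if control_group not in set(cq_table["group"]):
        raise ValueError(f"control group {control_group!r} not in table")
    cq = cq_table["cq"].to_numpy(dtype=float)
    if not np.all(np.isfinite(cq)):
        raise ValueError("Cq values must be finite")
    if np.any((cq < 5) | (cq > 45)):
        warnings.warn("Cq values outside the typical 5-45 cycle range", stacklevel=2)

    dcq = _sample_dcq(cq_table, reference_genes)
    groups = [g for g in dcq["group"].unique() if g != control_group]
    results: list[FoldChangeResult] = []
    for gene, sub in dcq.groupby("gene"):
        ctrl = sub.loc[sub["group"] == control_group, "dcq"].to_numpy()
        by_group = {
            g: sub.loc[sub["group"] == g, "dcq"].to_numpy() for g in groups
        }
        pvals = _group_pvalues(ctrl, by_group)
        for g in groups:
            vals = by_group[g]
            if vals.size == 0:
                continue
            delta = float(vals.mean() - ctrl.mean())
            results.append(
                FoldChangeResult(
                    gene=gene,
                    group=g,
                    fold_change=float(2.0 ** (-delta)),
                    dcq_mean=float(vals.mean()),
                    ddcq=delta,
                    n=int(vals.size),
                    p_value=pvals.get(g, float("nan")),
                )
            )
    return results


def _group_pvalues(ctrl: np.ndarray, by_group: dict[str, np.ndarray]) -> dict[str, float]:
    """t-test vs control for one treated group; ANOVA + Tukey for several."""
    groups = [g for g, v in by_group.items() if v.size > 0]
    if not groups or ctrl.size < 2:
        return {}
    if len(groups) == 1:
        g = groups[0]
        if by_group[g].size < 2 or (np.ptp(ctrl) == 0 and np.ptp(by_group[g]) == 0):
            return {g: float("nan")}
        return {g: float(stats.ttest_ind(by_group[g], ctrl).pvalue)}
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate([ctrl] + [by_group[g] for g in groups])
    labels = np.concatenate(
        [np.repeat("__control__", ctrl.size)]
        + [np.repeat(g, by_group[g].size) for g in groups]
    )
    if np.ptp(values) == 0:
        return {g: float("nan") for g in groups}
    tk = pairwise_tukeyhsd(values, labels)
    out: dict[str, float] = {}
    summary = np.array(tk.summary().data[1:], dtype=object)
    for row in summary:
        g1, g2, pv = str(row[0]), str(row[1]), float(row[3])
        if g1 == "__control__":
            out[g2] = pv
        elif g2 == "__control__":
            out[g1] = pv
    return out


@dataclass
class DEGSet:
    """Genes passing a fold-change/p-value filter for one comparison."""

    comparison: str
    genes: frozenset[str]
    fc_threshold: float
    p_threshold: float

    def __len__(self) -> int:
        return len(self.genes)


def filter_degs(
    de_table: pd.DataFrame,
    fc_threshold: float = 3.0,
    p_threshold: float = 0.05,
    comparison: str = "",
) -> DEGSet:
    """Keep genes with |fold change| beyond the threshold and p below it.

    ``de_table`` needs columns (gene, fold_change, p); fold changes are
    positive ratios, and a gene passes when ``fc >= fc_threshold`` (up) or
    ``fc <= 1 / fc_threshold`` (down, the "-fold" direction) with
    ``p < p_threshold``.
    """
    required = {"gene", "fold_change", "p"}
    missing = required - set(de_table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    fc = de_table["fold_change"].to_numpy(dtype=float)
    if np.any(fc <= 0):
        raise ValueError("fold changes must be positive ratios")
    keep = ((fc >= fc_threshold) | (fc <= 1.0 / fc_threshold)) & (
        de_table["p"].to_numpy(dtype=float) < p_threshold
    )
    return DEGSet(
        comparison=comparison,
        genes=frozenset(de_table.loc[keep, "gene"]),
        fc_threshold=fc_threshold,
        p_threshold=p_threshold,
    )


def venn3(set_a, set_b, set_c) -> dict[str, int]:
    """Counts of the 7 disjoint regions of three sets (plus per-set totals).

    Region keys are membership patterns over (A, B, C): '100' is A only,
    '110' is A and B but not C, '111' is the triple intersection. The seven
    region counts sum to ``|A | B | C|``.
    """
    a, b, c = set(set_a), set(set_b), set(set_c)
    regions = {
        "100": len(a - b - c),
        "010": len(b - a - c),
        "001": len(c - a - b),
        "110": len((a & b) - c),
        "101": len((a & c) - b),
        "011": len((b & c) - a),
        "111": len(a & b & c),
    }
    regions.update({"A": len(a), "B": len(b), "C": len(c), "union": len(a | b | c)})
    return regions
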