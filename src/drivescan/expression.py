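"""Carrier/noncarrier expression divergence and its genomic context.

Per gene, divergence is |mean(carrier TPM) - mean(noncarrier TPM)| /
mean(noncarrier TPM), in percent, over genes whose noncarrier mean exceeds
10 TPM.  A 20-gene sliding mean (genes ordered by start coordinate) gives
the positional track.  Genes are labelled by recombination class (the class
covering at least 80% of the 5-kb windows they overlap) and by CNV-mask
overlap (any overlap counts); group contrasts use the two-sided
Mann-Whitney rank test (exact below a combined n of 12 when untied,
normal approximation otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import merge_intervals

EXPRESSION_FLOOR = 10.0
TRACK_WINDOW_GENES = 20
CLASS_COVER_FRACTION = 0.80


@dataclass
class DivergenceResult:
    per_gene: pd.DataFrame       # gene_id, start, end, carrier_mean, noncarrier_mean, divergence_pct
    track: pd.DataFrame          # window index, center gene, mean divergence over 20 genes


def gene_divergence_track(
    matrix: pd.DataFrame,
    roles: dict[str, str],
    gene_intervals: dict[str, tuple[int, int]],
    expression_floor: float = EXPRESSION_FLOOR,
    window_genes: int = TRACK_WINDOW_GENES,
) -> DivergenceResult:
    """Per-gene divergence (%) plus the sliding 20-gene positional track."""
    carriers = [s for s in matrix.columns if roles.get(s) == "carrier"]
    controls = [s for s in matrix.columns if roles.get(s) == "noncarrier"]
    if not carriers or not controls:
        raise ValueError("both carrier and noncarrier samples are required")

    rows = []
    for gid in matrix.index:
        if gid not in gene_intervals:
            continue
        nc_mean = float(matrix.loc[gid, controls].mean())
        if nc_mean <= expression_floor:
            continue
        ca_mean = float(matrix.loc[gid, carriers].mean())
        a, b = gene_intervals[gid]
        rows.append(
            {
                "gene_id": gid,
                "start": a,
                "end": b,
                "carrier_mean": ca_mean,
                "noncarrier_mean": nc_mean,
                "divergence_pct": 100.0 * abs(ca_mean - nc_mean) / nc_mean,
            }
        )
    per_gene = pd.DataFrame(rows).sort_values(["start", "gene_id"]).reset_index(drop=True)

    if len(per_gene) >= window_genes:
        div = per_gene["divergence_pct"].to_numpy()
        starts = per_gene["start"].to_numpy()
        n_windows = len(div) - window_genes + 1
        track = pd.DataFrame(
            {
                "window_index": np.arange(n_windows),
                "center_start": starts[window_genes // 2 : window_genes // 2 + n_windows],
                "mean_divergence_pct": np.convolve(div, np.ones(window_genes) / window_genes, "valid"),
            }
        )
    else:
        track = pd.DataFrame(columns=["window_index", "center_start", "mean_divergence_pct"])
    return DivergenceResult(per_gene, track)


def classify_genes_by_context(
    gene_intervals: dict[str, tuple[int, int]],
    window_classes: pd.DataFrame,
    cnv_mask: list[tuple[int, int]],
    population: str,
    cover_fraction: float = CLASS_COVER_FRACTION,
) -> pd.DataFrame:
    """Label each gene with its dominant recombination class and CNV overlap.

    *window_classes* holds start/end plus one column per population (the
    per-window topology classes).  The recombination label is the class
    covering >= *cover_fraction* of the windows the gene overlaps
    ('unlabeled' otherwise, including genes outside the classified region);
    the CNV flag is any overlap with the merged mask.
    """
    mask = merge_intervals(cnv_mask) if cnv_mask else []
    ws = window_classes["start"].to_numpy()
    we = window_classes["end"].to_numpy()
    cls = window_classes[population].to_numpy()

    rows = []
    for gid, (a, b) in sorted(gene_intervals.items()):
        overlap = (ws < b) & (we > a)
        label = "unlabeled"
        n_over = int(overlap.sum())
        if n_over > 0:
            vals, counts = np.unique(cls[overlap], return_counts=True)
            best = int(np.argmax(counts))
            if counts[best] / n_over >= cover_fraction and vals[best] != "U":
                label = {"A": "very_recent", "B": "recent", "C": "nonrecombined"}[str(vals[best])]
        in_cnv = any(min(b, e) - max(a, s) > 0 for s, e in mask)
        rows.append(
            {
                "gene_id": gid,
                "start": a,
                "end": b,
                "recombination_label": label,
                "cnv_overlap": in_cnv,
            }
        )
    return pd.DataFrame(rows)


def rank_test(x, y, exact_threshold: int = 12) -> float:
    """Two-sided Mann-Whitney p (exact when small and untied)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need at least 2 observations")
    pooled = np.concatenate([x, y])
    method = (
        "exact"
        if (len(pooled) < exact_threshold and len(np.unique(pooled)) == len(pooled))
        else "asymptotic"
    )
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def compare_divergence_groups(
    divergences: pd.DataFrame, labels: pd.DataFrame
) -> pd.DataFrame:
    """Group medians and rank-test p-values for the standard contrasts.

    Contrasts: CNV-overlapping vs non-overlapping genes, and each pair of
    recombination classes.  Groups with fewer than 2 genes skip the contrast
    (recorded with NaN p).
    """
    df = divergences.merge(labels, on=["gene_id", "start", "end"])
    out = []

    def contrast(name, sel_a, sel_b, label_a, label_b):
        a = df.loc[sel_a, "divergence_pct"]
        b = df.loc[sel_b, "divergence_pct"]
        rec = {
            "contrast": name,
            "group_a": label_a,
            "group_b": label_b,
            "n_a": len(a),
            "n_b": len(b),
            "median_a": float(a.median()) if len(a) else np.nan,
            "median_b": float(b.median()) if len(b) else np.nan,
            "p_value": np.nan,
        }
        if len(a) >= 2 and len(b) >= 2:
            rec["p_value"] = rank_test(a, b)
        out.append(rec)

    contrast("cnv_vs_other", df["cnv_overlap"], ~df["cnv_overlap"], "cnv", "non_cnv")
    classes = ["nonrecombined", "recent", "very_recent"]
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            contrast(
                f"{classes[i]}_vs_{classes[j]}",
                df["recombination_label"] == classes[i],
                df["recombination_label"] == classes[j],
                classes[i],
                classes[j],
            )
    return pd.DataFrame(out)
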