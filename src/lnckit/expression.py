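"""Count normalization and differential expression.

Normalization is the median-of-ratios method: each sample's size factor is
the median, over genes with no zero count, of that sample's count divided by
the gene's geometric mean across samples. Differential expression is a
two-sided Welch t-test on log2(normalized count + 1), with Benjamini-Hochberg
adjustment across all tested genes. The default significance filter keeps
genes with |log2FC| > 0.75, P < 0.05 and BH-adjusted P < 0.45 — a deliberately
permissive FDR cut-off suited to small-cohort RNA-Seq candidate screening,
where the P-value carries the primary stringency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Raw gene x sample counts with a two-group condition labelling."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_genes, n_samples) non-negative ints
    condition: list[str]  # per-sample label, exactly two distinct groups

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match gene/sample ids")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.condition) != len(self.sample_ids):
            raise ValueError("one condition label per sample required")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if len(self.groups) != 2:
            raise ValueError(f"exactly two condition groups required, got {self.groups}")

    @property
    def groups(self) -> list[str]:
        """The two condition labels, control group first (sorted order)."""
        return sorted(set(self.condition))

    def group_columns(self, group: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.condition) if c == group])

    @classmethod
    def from_tsv(cls, counts_path: str | Path, conditions_path: str | Path) -> "CountMatrix":
        """Load counts (genes x samples TSV, first column gene ids) and a
        two-column sample/condition table."""
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        cond = pd.read_csv(conditions_path, sep="\t", index_col=0).iloc[:, 0]
        missing = [s for s in df.columns if s not in cond.index]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        return cls(
            gene_ids=list(df.index),
            sample_ids=list(df.columns),
            counts=df.to_numpy(),
            condition=[cond[s] for s in df.columns],
        )

    def to_tsv(self, counts_path: str | Path, conditions_path: str | Path) -> None:
        pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids).to_csv(
            counts_path, sep="\t", index_label="gene_id"
        )
        pd.DataFrame(
            {"sample_id": self.sample_ids, "condition": self.condition}
        ).to_csv(conditions_path, sep="\t", index=False)


@dataclass(frozen=True)
class DEThresholds:
    """Significance cut-offs for the differential-expression filter."""

    lfc_threshold: float = 0.75
    p_threshold: float = 0.05
    fdr_threshold: float = 0.45

    def __post_init__(self) -> None:
        if min(self.lfc_threshold, self.p_threshold, self.fdr_threshold) <= 0:
            raise ValueError("all thresholds must be strictly positive")
        if self.p_threshold > 1 or self.fdr_threshold > 1:
            raise ValueError("p/fdr thresholds must be <= 1")


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2fc: float  # group2 - group1 (case minus control) on log2 scale
    p_value: float
    fdr: float
    mean_norm_g1: float
    mean_norm_g2: float
    significant: bool
    degenerate: bool = False  # zero variance in both groups with unequal means


def size_factors(cm: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors, one per sample.

    Only genes with strictly positive counts in every sample enter the
    median. Raises if no gene is eligible, in which case normalization is
    undefined for this matrix.
    """
    counts = cm.counts.astype(float)
    eligible = (counts > 0).all(axis=1)
    if not eligible.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "median-of-ratios normalization is undefined for this matrix"
        )
    sub = counts[eligible]
    log_geomean = np.mean(np.log(sub), axis=1)
    # ratios[i, j] = counts[i, j] / geomean_i
    ratios = np.exp(np.log(sub) - log_geomean[:, None])
    return np.median(ratios, axis=0)


def normalize(cm: CountMatrix, sf: np.ndarray) -> np.ndarray:
    """Divide each sample's counts by its size factor."""
    sf = np.asarray(sf, dtype=float)
    if sf.shape != (len(cm.sample_ids),):
        raise ValueError(
            f"size factor vector length {sf.shape} does not match "
            f"{len(cm.sample_ids)} samples"
        )
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    return cm.counts / sf[None, :]


def differential_expression(
    cm: CountMatrix, thresholds: DEThresholds = DEThresholds()
) -> list[DEResult]:
    """Per-gene Welch t-test on log2(normalized + 1) with BH adjustment.

    log2fc is group2 minus group1, where group1 is the alphabetically first
    condition label (the control in a case/control design labelled e.g.
    "control"/"disease"). Degenerate genes (all-zero, or zero variance in
    both groups) are handled deterministically: equal means give p = 1,
    unequal means with zero variance give the smallest positive float and a
    degenerate flag.
    """
    g1_cols = cm.group_columns(cm.groups[0])
    g2_cols = cm.group_columns(cm.groups[1])
    if len(g1_cols) < 2 or len(g2_cols) < 2:
        raise ValueError("each condition group needs >= 2 samples for a t-test")

    sf = size_factors(cm)
    x = np.log2(normalize(cm, sf) + 1.0)
    x1, x2 = x[:, g1_cols], x[:, g2_cols]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
    log2fc = m2 - m1

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat, pvals = stats.ttest_ind(x2, x1, axis=1, equal_var=False)
    pvals = np.asarray(pvals)

    zero_var = (v1 == 0) & (v2 == 0)
    equal_means = np.isclose(m1, m2)
    degenerate = zero_var & ~equal_means
    pvals[zero_var & equal_means] = 1.0
    pvals[degenerate] = np.finfo(float).tiny
    log2fc = np.where(zero_var & equal_means, 0.0, log2fc)
    pvals = np.nan_to_num(pvals, nan=1.0)

    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")

    norm = normalize(cm, sf)
    mean1 = norm[:, g1_cols].mean(axis=1)
    mean2 = norm[:, g2_cols].mean(axis=1)

    results = []
    for i, gene in enumerate(cm.gene_ids):
        sig = (
            abs(log2fc[i]) > thresholds.lfc_threshold
            and pvals[i] < thresholds.p_threshold
            and fdr[i] < thresholds.fdr_threshold
        )
        results.append(
            DEResult(
                gene_id=gene,
                log2fc=float(log2fc[i]),
                p_value=float(pvals[i]),
                fdr=float(fdr[i]),
                mean_norm_g1=float(mean1[i]),
                mean_norm_g2=float(mean2[i]),
                significant=bool(sig),
                degenerate=bool(degenerate[i]),
            )
        )
    return results


def filter_significant(
    results: list[DEResult],
    thresholds: DEThresholds = DEThresholds(),
    biotype_filter: str | None = None,
    biotypes: dict[str, str] | None = None,
) -> list[DEResult]:
    """Keep significant rows, optionally restricted to one biotype.

    ``biotypes`` maps gene_id to biotype (e.g. from the gene model); it is
    required when ``biotype_filter`` is given.
    """
    kept = [r for r in results if r.significant]
    if biotype_filter is not None:
        if biotypes is None:
            raise ValueError("biotype_filter requires a gene->biotype mapping")
        kept = [r for r in kept if biotypes.get(r.gene_id) == biotype_filter]
    return kept


def results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results]).set_index("gene_id")


def write_results(results: list[DEResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t")


def plot_heatmap(
    cm: CountMatrix, results: list[DEResult], path: str | Path, max_genes: int = 50
) -> None:
    """Static heatmap of the most significant genes (log2 normalized counts),
    a visual overview companion to the result table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sig = sorted((r for r in results if r.significant), key=lambda r: r.p_value)[:max_genes]
    if not sig:
        logger.warning("no significant genes; heatmap not drawn")
        return
    idx = [cm.gene_ids.index(r.gene_id) for r in sig]
    x = np.log2(normalize(cm, size_factors(cm)) + 1.0)[idx]
    fig, ax = plt.subplots(figsize=(8, max(2, 0.2 * len(idx))))
    im = ax.imshow(x, aspect="auto", cmap="RdBu_r")
    ax.set_yticks(range(len(idx)), [r.gene_id for r in sig], fontsize=6)
    ax.set_xticks(range(len(cm.sample_ids)), cm.sample_ids, rotation=90, fontsize=6)
    fig.colorbar(im, label="log2(normalized + 1)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
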