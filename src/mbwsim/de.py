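"""Small-replicate differential expression and knockdown-study summaries.

A deliberately simple, fully documented pipeline for 3-vs-3 count designs:

1. median-of-ratios size factors (each sample's median ratio to the
   per-gene geometric-mean reference);
2. per-gene negative-binomial dispersion by the method of moments, shrunk
   toward the panel-wide mean to stabilize tiny-replicate estimates;
3. a Wald test on the log2 ratio of normalized group means, with a
   delta-method standard error from the NB mean-variance relation;
4. Benjamini-Hochberg FDR control, with the study's significance rule:
   |log2FC| >= 1 and adjusted p < 0.05.

Plus the study-specific readouts: RPKM, the early/late biosynthetic-gene
dichotomy, the regulator fold-change table, and the exact binomial test for
transgene segregation ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .transcriptome import (
    ENZYME_CLASSES,
    LBG_CLASSES,
    REGULATOR_SUBROLES,
    RNAI,
    WILD_TYPE,
    GenePanel,
)

__all__ = [
    "DE_COLUMNS",
    "size_factors",
    "estimate_dispersion",
    "bh_adjust",
    "wald_test",
    "rpkm",
    "pathway_summary",
    "regulator_table",
    "segregation_binomial",
    "SegregationResult",
]

logger = logging.getLogger(__name__)

#: Column contract of a differential-expression result table.
DE_COLUMNS = ["base_mean", "log2FC", "se", "pvalue", "padj", "significant"]

#: Pseudocount added to both normalized group means, but only for genes
#: where one of the means is zero.  Conditional application keeps the log2
#: fold change of expressed genes an exact ratio of normalized means, which
#: makes it exactly invariant to rescaling any sample's column.
PSEUDOCOUNT = 0.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios sequencing-depth factors.

    Each sample's factor is the median, over genes expressed in every
    sample, of the ratio between its count and the gene's geometric mean
    across samples.  Factors are defined relative to that common reference,
    so rescaling one sample's column by ``c`` multiplies its factor by
    ``c`` relative to the others (between-sample ratios are equivariant).
    If no gene is nonzero in all samples, total-count ratios are used
    instead (with a logged warning).
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if all_nonzero.any():
        logref = np.log(mat[all_nonzero]).mean(axis=1, keepdims=True)
        factors = np.exp(np.median(np.log(mat[all_nonzero]) - logref, axis=0))
    else:
        logger.warning(
            "no gene has nonzero counts in every sample; "
            "falling back to total-count size factors"
        )
        totals = mat.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("cannot compute size factors: some sample has zero total counts")
        factors = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    groups: pd.Series,
    factors: pd.Series | None = None,
    shrinkage_weight: float = 0.3,
) -> pd.Series:
    """Per-gene NB dispersion ``alpha`` with shrinkage toward the panel mean.

    The raw estimate is the within-group method of moments on normalized
    counts, ``alpha = (var - mean) / mean**2`` pooled over groups by degrees
    of freedom and clipped at zero.  The returned value is
    ``(1 - w) * alpha_gene + w * mean(alpha)`` with ``w`` =
    ``shrinkage_weight``, which stabilizes the tiny-replicate estimates
    the study design (n = 3 per group) would otherwise produce.

    All-zero genes get NaN (excluded from testing).
    """
    if not 0 <= shrinkage_weight <= 1:
        raise ValueError("shrinkage_weight must lie in [0, 1]")
    if factors is None:
        factors = size_factors(counts)
    norm = counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    labels = groups.to_numpy()
    num = np.zeros(norm.shape[0])
    den = 0.0
    mean_all = norm.mean(axis=1)
    for g in pd.unique(labels):
        sub = norm[:, labels == g]
        n = sub.shape[1]
        if n < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = (v - m) / (m * m)
        num += np.where(np.isfinite(raw), raw, 0.0) * (n - 1)
        den += n - 1
    alpha_raw = np.maximum(num / den, 0.0)
    alpha_raw[mean_all == 0] = np.nan
    panel_mean = float(np.nanmean(alpha_raw)) if np.isfinite(alpha_raw).any() else 0.0
    alpha = (1.0 - shrinkage_weight) * alpha_raw + shrinkage_weight * panel_mean
    return pd.Series(alpha, index=counts.index, name="alpha")


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``padj_(i) = min_{j >= i} p_(j) * m / j`` over the ascending order,
    capped at 1; NaNs are passed through and do not count toward ``m``.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return out
    order = np.argsort(p[ok], kind="mergesort")
    ranked = p[ok][order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.minimum(adj, 1.0)
    out[ok] = vals
    return out


def wald_test(
    counts: pd.DataFrame,
    groups: pd.Series,
    factors: pd.Series | None = None,
    alphas: pd.Series | None = None,
    lfc_threshold: float = 1.0,
    padj_threshold: float = 0.05,
    reference: str = WILD_TYPE,
    treatment: str = RNAI,
) -> pd.DataFrame:
    """Wald differential-expression test (treatment vs reference).

    ``log2FC`` is the log2 ratio of normalized group means (a 0.5
    pseudocount is added to both means when either is zero), with the
    delta-method standard error from
    ``Var(count_s / sf_s) = m / sf_s + alpha * m**2``.  Two-sided p-values
    come from the standard normal reference for ``log2FC / SE``; BH
    adjustment and the significance rule (|log2FC| >= 1, padj < 0.05 by
    default) follow.

    Genes with zero counts everywhere (or a degenerate zero SE) get NaN
    p-values and are never called significant.
    """
    if factors is None:
        factors = size_factors(counts)
    if alphas is None:
        alphas = estimate_dispersion(counts, groups, factors)
    sf = factors.to_numpy()
    labels = groups.to_numpy()
    norm = counts.to_numpy(dtype=float) / sf[None, :]
    alpha = alphas.to_numpy(dtype=float)

    def group_stats(name):
        idx = labels == name
        if not idx.any():
            raise ValueError(f"group {name!r} not present")
        m = norm[:, idx].mean(axis=1)
        n = int(idx.sum())
        # delta-method variance of the normalized group mean under NB noise
        inv_sf_sum = float(np.sum(1.0 / sf[idx]))
        a = np.where(np.isfinite(alpha), alpha, 0.0)
        var = (m * inv_sf_sum + n * a * m * m) / (n * n)
        return m, var

    m_ref, var_ref = group_stats(reference)
    m_trt, var_trt = group_stats(treatment)

    pc = np.where((m_ref == 0) | (m_trt == 0), PSEUDOCOUNT, 0.0)
    log2fc = np.log2((m_trt + pc) / (m_ref + pc))
    ln2 = math.log(2.0)
    se = np.sqrt(
        var_trt / ((m_trt + pc) ** 2) + var_ref / ((m_ref + pc) ** 2)
    ) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    degenerate = ~np.isfinite(se) | (se == 0) | ~np.isfinite(alpha)
    pvalue = np.where(degenerate, np.nan, pvalue)
    padj = bh_adjust(pvalue)
    significant = (np.abs(log2fc) >= lfc_threshold) & (padj < padj_threshold)
    significant = np.where(np.isnan(padj), False, significant)
    return pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "log2FC": log2fc,
            "se": se,
            "pvalue": pvalue,
            "padj": padj,
            "significant": significant.astype(bool),
        },
        index=counts.index,
    )


def rpkm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    ``RPKM = count * 1e9 / (length_bases * total counts of the sample)``.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("gene_lengths missing entries for some genes")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero-depth sample(s): {bad}")
    return counts * 1e9 / np.outer(lengths.to_numpy(), totals.to_numpy())


def pathway_summary(de: pd.DataFrame, panel: GenePanel) -> pd.DataFrame:
    """Early/late biosynthetic-gene response dichotomy.

    One row per enzyme class with the copies tested, the significant down-
    and up-regulated tallies, whether every copy is significantly down, and
    the resulting call: ``LBG-like coordinate-down`` when all copies fall
    together, else ``EBG-like mixed``.
    """
    rows = []
    for cls_name in ENZYME_CLASSES:
        genes = panel.table.loc[panel.table["subrole"] == cls_name, "gene_id"]
        genes = [g for g in genes if g in de.index]
        if not genes:
            logger.warning("enzyme class %s absent from panel/DE table; omitted", cls_name)
            continue
        sub = de.loc[genes]
        down = int((sub["significant"] & (sub["log2FC"] < 0)).sum())
        up = int((sub["significant"] & (sub["log2FC"] > 0)).sum())
        all_down = down == len(genes)
        rows.append({
            "enzyme_class": cls_name,
            "pathway_position": "LBG" if cls_name in LBG_CLASSES else "EBG",
            "copies_tested": len(genes),
            "copies_down": down,
            "copies_up": up,
            "all_copies_down": all_down,
            "dichotomy_call": "LBG-like coordinate-down" if all_down else "EBG-like mixed",
        })
    return pd.DataFrame(rows)


def regulator_table(de: pd.DataFrame, panel: GenePanel) -> pd.DataFrame:
    """Fold-change table for the six anthocyanin regulators.

    Fold change is reported on the linear fold-down scale
    (``2**(-log2FC)``; values > 1 mean lower in the knockdown).  Missing
    subroles yield rows with null estimates.
    """
    reg = panel.genes_with_role("regulator").set_index("subrole")
    rows = []
    for subrole in REGULATOR_SUBROLES:
        gene_id = reg.loc[subrole, "gene_id"] if subrole in reg.index else None
        if gene_id is None or gene_id not in de.index:
            rows.append({"subrole": subrole, "gene_id": gene_id, "fold_down": np.nan,
                         "log2FC": np.nan, "padj": np.nan, "significant": False})
            continue
        r = de.loc[gene_id]
        rows.append({
            "subrole": subrole, "gene_id": gene_id,
            "fold_down": float(2.0 ** (-r["log2FC"])),
            "log2FC": float(r["log2FC"]), "padj": float(r["padj"]),
            "significant": bool(r["significant"]),
        })
    return pd.DataFrame(rows)


def volcano_plot(de: pd.DataFrame, path, highlight: list[str] | None = None) -> None:
    """Save a volcano plot (log2FC vs -log10 padj) to ``path``.

    Genes listed in ``highlight`` (e.g. the six regulators) are marked.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = de.dropna(subset=["padj"])
    neglog = -np.log10(np.maximum(sub["padj"], 1e-300))
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(sub["log2FC"], neglog, s=6, c=np.where(sub["significant"], "crimson", "grey"),
               alpha=0.6, linewidths=0)
    if highlight:
        hl = sub.loc[sub.index.intersection(highlight)]
        ax.scatter(hl["log2FC"], -np.log10(np.maximum(hl["padj"], 1e-300)),
                   s=30, facecolors="none", edgecolors="black")
    ax.axhline(-math.log10(0.05), ls="--", lw=0.8, c="black")
    for x in (-1, 1):
        ax.axvline(x, ls="--", lw=0.8, c="black")
    ax.set_xlabel("log2 fold change (RNAi vs wild type)")
    ax.set_ylabel("-log10 adjusted p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class SegregationResult:
    """Exact binomial test of an offspring segregation ratio."""

    pmf: np.ndarray
    modal_count: int
    p_two_sided: float
    expected_count: float


def segregation_binomial(
    n_offspring: int, n_dominant: int, ratio: tuple[int, int] = (3, 1)
) -> SegregationResult:
    """Exact two-sided binomial test of an r:1 segregation ratio.

    The dominant-phenotype count is Binomial(n, r / (r + 1)); the two-sided
    p-value sums the probabilities of all outcomes no more likely than the
    observed one (minimum-likelihood convention).
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    if not 0 <= n_dominant <= n_offspring:
        raise ValueError("n_dominant must lie in [0, n_offspring]")
    r, one = ratio
    if one != 1 or r <= 0:
        raise ValueError(f"ratio must be (r, 1) with r > 0, got {ratio}")
    p_succ = r / (r + 1.0)
    ks = np.arange(n_offspring + 1)
    pmf = stats.binom.pmf(ks, n_offspring, p_succ)
    observed = pmf[n_dominant]
    p_two = float(pmf[pmf <= observed * (1 + 1e-9)].sum())
    return SegregationResult(
        pmf=pmf,
        modal_count=int(np.argmax(pmf)),
        p_two_sided=min(p_two, 1.0),
        expected_count=n_offspring * p_succ,
    )
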