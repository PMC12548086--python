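"""Joint correlation + partial-least-squares pairing of regions with genes.

The central integration step: significant epigenomic regions (DMRs or
DARs) are paired with significant genes (DEGs) by combining sample-wise
Pearson correlation with a multivariate PLS2 regression of the gene
block on the region block. Both views are computed on standardized
samples x features matrices restricted to the samples shared by the two
assays; group labels play no role here — pairing is across-sample
covariation, with the exposure contrast entering only through which
features were called significant upstream.

Pairs are typed *homologous* (cis: the gene is a candidate target of
the region via a +-2 kb promoter window or an annotated enhancer) or
*heterologous* (trans: any other gene). Because homologous pairs are
vastly outnumbered, significance is asymmetric: homologous pairs need
only one criterion (|r| or |beta| beyond its threshold), heterologous
pairs need both. Thresholds are (1-alpha) quantiles of |r| and |beta|
under row permutations of the gene block, which breaks the region-gene
linkage while preserving both marginal structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import GenomeAnnotation, candidate_targets, region_midpoint, tss_distance
from .diffcall import log_cpm
from .io import CountMatrix, MethylSiteMatrix

PAIR_COLUMNS = [
    "region_id", "gene_id", "region_chrom", "region_start", "region_end",
    "region_mid", "r", "beta", "type", "sig_r", "sig_beta", "significant",
    "sign", "sign_inconsistent", "tss_distance", "region_status", "gene_status",
]

__all__ = [
    "PAIR_COLUMNS",
    "region_signal_matrix",
    "gene_signal_matrix",
    "fit_mpls",
    "permutation_thresholds",
    "classify_pairs",
    "PairThresholds",
    "pair_category_tallies",
]


@dataclass
class PairThresholds:
    """Permutation-derived significance thresholds for |r| and |beta|."""

    r_star: float
    beta_star: float
    alpha: float
    n_permutations: int
    seed: int


def _standardize(df: pd.DataFrame, what: str) -> pd.DataFrame:
    sd = df.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {(~keep).sum()} constant {what} column(s) before standardization",
            stacklevel=3,
        )
        df = df.loc[:, keep]
        sd = sd[keep]
    return (df - df.mean(axis=0)) / sd


def region_signal_matrix(
    calls: pd.DataFrame,
    omics: MethylSiteMatrix | CountMatrix,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Samples x regions signal matrix for called regions, standardized.

    DMR signal is the pooled methylation fraction over the region per
    sample; DAR signal is log2(CPM+1) of the peak. Regions with zero
    coverage in any sample (methylation) or zero variance are dropped
    with a warning. Columns are keyed by ``region_id``.
    """
    if isinstance(omics, MethylSiteMatrix):
        cols = {}
        dropped = []
        starts = omics.sites["start"].to_numpy()
        chroms = omics.sites["chrom"].to_numpy()
        for row in calls.itertuples(index=False):
            sel = (chroms == row.chrom) & (starts >= row.start) & (starts < row.end)
            meth = omics.meth.loc[sel].sum(axis=0)
            total = omics.total.loc[sel].sum(axis=0)
            if (total == 0).any() or not sel.any():
                dropped.append(row.region_id)
                continue
            cols[row.region_id] = meth / total
        if dropped:
            warnings.warn(
                f"dropping {len(dropped)} region(s) with zero coverage in some sample",
                stacklevel=2,
            )
        signal = pd.DataFrame(cols)
        signal.index = omics.meth.columns
    else:
        signal = log_cpm(omics.counts).loc[calls["region_id"]].T
    if samples is not None:
        signal = signal.loc[samples]
    return _standardize(signal, "region")


def gene_signal_matrix(
    calls: pd.DataFrame, gc: CountMatrix, samples: list[str] | None = None
) -> pd.DataFrame:
    """Samples x genes standardized log2(CPM+1) for significant genes."""
    signal = log_cpm(gc.counts).loc[calls["gene_id"]].T
    if samples is not None:
        signal = signal.loc[samples]
    return _standardize(signal, "gene")


def shared_samples(a: pd.DataFrame, b: pd.DataFrame) -> list[str]:
    """Sample ids present in both sample sheets, in first-sheet order."""
    other = set(b["sample_id"])
    return [s for s in a["sample_id"] if s in other]


# ---------------------------------------------------------------------------
# PLS2 (NIPALS)
# ---------------------------------------------------------------------------


def fit_mpls(X: pd.DataFrame, Y: pd.DataFrame, K: int | None = None) -> pd.DataFrame:
    """PLS2 regression coefficients of Y (genes) on X (regions), NIPALS.

    ``K`` latent components are extracted jointly over all regions and
    genes (default min(2, n-1, p)); the returned beta maps standardized
    region signal to standardized expression, regions x genes. The
    deflation order is fixed (the starting score is the current Y column
    with the largest sum of squares, lowest index on ties) so the fit is
    deterministic. With K = rank(X) and n > p, beta equals the
    multivariate OLS solution; in the 1x1 standardized case it equals
    the Pearson correlation.
    """
    Xm = np.asarray(X, dtype=float).copy()
    Ym = np.asarray(Y, dtype=float).copy()
    if np.isnan(Xm).any() or np.isnan(Ym).any():
        raise ValueError("NaN in PLS inputs")
    n, p = Xm.shape
    q = Ym.shape[1]
    if Ym.shape[0] != n:
        raise ValueError("X and Y must share the sample axis")
    if K is None:
        K = min(2, n - 1, p)
    if K < 1 or K > min(n - 1, p):
        raise ValueError(f"K={K} out of range 1..min(n-1, p)={min(n - 1, p)}")

    W = np.zeros((p, K))
    P = np.zeros((p, K))
    C = np.zeros((q, K))
    n_comp = 0
    for k in range(K):
        j = int(np.argmax((Ym**2).sum(axis=0)))
        u = Ym[:, j].copy()
        if not np.any(u):
            break
        t = np.zeros(n)
        for _ in range(500):
            w = Xm.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                break
            w /= norm
            t_new = Xm @ w
            c = Ym.T @ t_new / (t_new @ t_new)
            u = Ym @ c / (c @ c)
            if np.linalg.norm(t_new - t) <= 1e-12 * max(1.0, np.linalg.norm(t_new)):
                t = t_new
                break
            t = t_new
        tt = t @ t
        if tt <= 1e-300:
            break
        # fixed sign convention: largest-|w| entry positive
        pivot = int(np.argmax(np.abs(w)))
        if w[pivot] < 0:
            w, t = -w, -t
        pvec = Xm.T @ t / tt
        c = Ym.T @ t / tt
        Xm -= np.outer(t, pvec)
        Ym -= np.outer(t, c)
        W[:, k], P[:, k], C[:, k] = w, pvec, c
        n_comp += 1
    W, P, C = W[:, :n_comp], P[:, :n_comp], C[:, :n_comp]
    if n_comp == 0:
        beta = np.zeros((p, q))
    else:
        beta = W @ np.linalg.solve(P.T @ W, C.T)
    return pd.DataFrame(beta, index=X.columns, columns=Y.columns)


def pairwise_correlation(X: pd.DataFrame, Y: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between every X column and every Y column (standardized inputs)."""
    n = len(X)
    r = np.asarray(X, dtype=float).T @ np.asarray(Y, dtype=float) / (n - 1)
    return pd.DataFrame(np.clip(r, -1.0, 1.0), index=X.columns, columns=Y.columns)


def permutation_thresholds(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    alpha: float = 0.05,
    B: int = 200,
    seed: int = 0,
    K: int | None = None,
) -> PairThresholds:
    """(1-alpha) quantiles of |r| and |beta| under row permutations of Y."""
    if B < 50:
        raise ValueError("need at least 50 permutations")
    rng = np.random.default_rng(seed)
    n = len(X)
    r_null, b_null = [], []
    for _ in range(B):
        perm = rng.permutation(n)
        Yp = pd.DataFrame(np.asarray(Y)[perm], index=Y.index, columns=Y.columns)
        r_null.append(np.abs(pairwise_correlation(X, Yp).to_numpy()).ravel())
        b_null.append(np.abs(fit_mpls(X, Yp, K=K).to_numpy()).ravel())
    if alpha >= 1.0:
        r_star = beta_star = 0.0
    else:
        r_star = float(np.quantile(np.concatenate(r_null), 1.0 - alpha))
        beta_star = float(np.quantile(np.concatenate(b_null), 1.0 - alpha))
    return PairThresholds(
        r_star=r_star, beta_star=beta_star, alpha=alpha, n_permutations=B, seed=seed
    )


# ---------------------------------------------------------------------------
# Pair classification
# ---------------------------------------------------------------------------


def classify_pairs(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    beta: pd.DataFrame,
    thresholds: PairThresholds,
    annotation: GenomeAnnotation,
    region_calls: pd.DataFrame,
    gene_calls: pd.DataFrame | None = None,
    promoter_bp: int = 2_000,
) -> pd.DataFrame:
    """Type and score every region-gene pair.

    homologous = the gene is a candidate target of the region (promoter
    window or enhancer); significance is |r| >= r_star OR |beta| >=
    beta_star for homologous pairs, AND for heterologous pairs. The
    recorded sign is the correlation sign, with a flag when the
    regression coefficient disagrees. Output is sorted by significance,
    then |r| descending.
    """
    r = pairwise_correlation(X, Y)
    regions = region_calls.set_index("region_id").loc[list(X.columns)]
    gene_rows = annotation.genes.set_index("gene_id")

    rows = []
    for region_id, reg in regions.iterrows():
        region = (reg["chrom"], int(reg["start"]), int(reg["end"]))
        cand = {g for g, _ in candidate_targets(region, annotation, promoter_bp)}
        mid = region_midpoint(region[1], region[2])
        for gene_id in Y.columns:
            rv = float(r.loc[region_id, gene_id])
            bv = float(beta.loc[region_id, gene_id])
            homologous = gene_id in cand
            sig_r = abs(rv) >= thresholds.r_star
            sig_b = abs(bv) >= thresholds.beta_star
            significant = (sig_r or sig_b) if homologous else (sig_r and sig_b)
            gene = gene_rows.loc[gene_id] if gene_id in gene_rows.index else None
            if gene is not None and gene["chrom"] == region[0]:
                dist = float(tss_distance(region, gene))
            else:
                dist = float("nan")
            rows.append(
                {
                    "region_id": region_id,
                    "gene_id": gene_id,
                    "region_chrom": region[0],
                    "region_start": region[1],
                    "region_end": region[2],
                    "region_mid": mid,
                    "r": rv,
                    "beta": bv,
                    "type": "homologous" if homologous else "heterologous",
                    "sig_r": sig_r,
                    "sig_beta": sig_b,
                    "significant": significant,
                    "sign": "+" if rv >= 0 else "-",
                    "sign_inconsistent": (rv != 0 and bv != 0 and np.sign(rv) != np.sign(bv)),
                    "tss_distance": dist,
                }
            )
    pairs = pd.DataFrame(rows, columns=None if rows else PAIR_COLUMNS)
    if len(pairs):
        pairs["region_status"] = pairs["region_id"].map(
            region_calls.set_index("region_id")["status"]
        )
        if gene_calls is not None:
            pairs["gene_status"] = pairs["gene_id"].map(gene_calls.set_index("gene_id")["status"])
        pairs = pairs.sort_values(
            ["significant", "r"],
            key=lambda s: s.abs() if s.name == "r" else s,
            ascending=[False, False],
            ignore_index=True,
        )
    return pairs


def pair_category_tallies(pairs: pd.DataFrame) -> dict[str, int]:
    """Counts of significant pairs by (type, region status, gene status, sign)."""
    sig = pairs[pairs["significant"]]
    if not len(sig):
        return {}
    cols = ["type"]
    if "region_status" in sig.columns:
        cols.append("region_status")
    if "gene_status" in sig.columns:
        cols.append("gene_status")
    cols.append("sign")
    grouped = sig.groupby(cols, observed=True).size()
    return {"|".join(map(str, k if isinstance(k, tuple) else (k,))): int(v) for k, v in grouped.items()}
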