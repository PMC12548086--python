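"""Gene-level intersections and dependence/overlap statistics.

Three operations close the integration:

* exact three-set Venn algebra over per-assay gene sets, nominating the
  triple intersection ("triple-regulated" genes hit in methylation,
  accessibility and expression);
* a chi-square test of independence between the direction of the
  epigenomic change and the direction of the expression change over
  significant proximal pairs (Pearson chi-square, no continuity
  correction; odds ratio with 0.5 added to zero cells);
* a distance-binned hypergeometric overlap test between two region ->
  target predictions over an explicit finite universe of (region,
  target) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VennSummary",
    "venn_genes",
    "ContingencyResult",
    "dependence_chi2",
    "chi2_independence",
    "chi2_upper_p",
    "binned_overlap_test",
]


@dataclass
class VennSummary:
    """Counts of the 7 intersection cells of three gene sets.

    Cell keys are membership masks in (A, B, C) order: "101" = in A and
    C but not B.
    """

    cells: dict[str, int]
    triple: list[str]
    sets: dict[str, set]

    @property
    def union_size(self) -> int:
        return sum(self.cells.values())


def venn_genes(dmr_genes, dar_genes, deg_genes) -> VennSummary:
    """Exact set algebra over the three per-assay gene sets."""
    a, b, c = set(dmr_genes), set(dar_genes), set(deg_genes)
    cells = {}
    for mask in ("100", "010", "001", "110", "101", "011", "111"):
        ia, ib, ic = (m == "1" for m in mask)
        members = (a if ia else (a | b | c) - a)
        members = members & (b if ib else (a | b | c) - b)
        members = members & (c if ic else (a | b | c) - c)
        cells[mask] = len(members)
    return VennSummary(
        cells=cells,
        triple=sorted(a & b & c),
        sets={"dmr": a, "dar": b, "deg": c},
    )


@dataclass
class ContingencyResult:
    table: pd.DataFrame
    chi2: float
    df: int
    p: float
    odds_ratio: float
    n: int


def chi2_independence(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction: sum (O-E)^2/E."""
    obs = np.asarray(table, dtype=float)
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("contingency table entries must be nonnegative integers")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("chi-square undefined: a margin of the table is zero")
    expected = np.outer(row, col) / total
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return chi2, df, chi2_upper_p(chi2, df)


def chi2_upper_p(chi2: float, df: int) -> float:
    """Upper-tail p of the chi-square distribution."""
    return float(stats.chi2.sf(chi2, df))


def dependence_chi2(
    pairs: pd.DataFrame,
    proximal_bp: float = 2_000,
) -> ContingencyResult:
    """Direction-of-change dependence between assays over significant pairs.

    Restricted to significant pairs within the promoter/enhancer scope:
    homologous pairs, plus any pair whose |TSS distance| is below
    ``proximal_bp``. Rows = sign of the region effect (from
    region_status), columns = sign of the gene change (gene_status).
    """
    need = {"significant", "type", "tss_distance", "region_status", "gene_status"}
    missing = need - set(pairs.columns)
    if missing:
        raise ValueError(f"pairs frame is missing columns: {sorted(missing)}")
    scope = pairs[
        pairs["significant"]
        & ((pairs["type"] == "homologous") | (pairs["tss_distance"].abs() < proximal_bp))
    ]
    if not len(scope):
        raise ValueError("no significant proximal pairs to test")
    up_region = {"hyper", "GA", "up"}
    up_gene = {"up", "hyper", "GA"}
    rows = np.where(scope["region_status"].isin(up_region), "region+", "region-")
    cols = np.where(scope["gene_status"].isin(up_gene), "gene+", "gene-")
    table = pd.crosstab(pd.Series(rows, name="region"), pd.Series(cols, name="gene"))
    table = table.reindex(index=["region+", "region-"], columns=["gene+", "gene-"], fill_value=0)
    chi2, df, p = chi2_independence(table.to_numpy())
    t = table.to_numpy(dtype=float)
    t = np.where(t == 0, t + 0.5, t)
    odds = float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))
    return ContingencyResult(
        table=table, chi2=chi2, df=df, p=p, odds_ratio=odds, n=int(len(scope))
    )


def binned_overlap_test(
    pred_a: set[tuple[str, str]],
    pred_b: set[tuple[str, str]],
    universe_bins: pd.DataFrame,
) -> pd.DataFrame:
    """Per-bin upper-tail hypergeometric overlap of two target predictions.

    ``universe_bins`` has columns (region_id, gene_id, bin); the universe
    of each bin is its set of (region, target) pairs. Within a bin with
    population M, |A| successes and |B| draws, the reported p is
    P(X >= k) for the observed overlap k.
    """
    need = {"region_id", "gene_id", "bin"}
    if need - set(universe_bins.columns):
        raise ValueError("universe_bins needs columns region_id, gene_id, bin")
    out = []
    for bin_label, sub in universe_bins.groupby("bin"):
        universe = set(zip(sub["region_id"], sub["gene_id"]))
        a = pred_a & universe
        b = pred_b & universe
        k = len(a & b)
        if k > min(len(a), len(b)):
            raise ValueError("overlap larger than the smaller prediction set")
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(a), len(b)))
        out.append(
            {
                "bin": bin_label,
                "universe": len(universe),
                "n_a": len(a),
                "n_b": len(b),
                "overlap": k,
                "p": min(p, 1.0),
            }
        )
    return pd.DataFrame(out)
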