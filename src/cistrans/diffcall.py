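"""Differential calling: binned DMRs, and moderated DARs/DEGs.

Differentially methylated regions are found by pooling CpG counts into
fixed-width bins (100 bp by default), Welch-testing the arcsine-square-
root-transformed per-sample methylation levels, adjusting with
Benjamini-Hochberg, and merging adjacent significant bins of the same
sign into regions.

Accessible regions and expressed genes share one empirical-Bayes
moderated two-group test on log2(CPM+1): the per-feature sample variance
is shrunk towards a prior estimated from the whole ensemble by matching
the moments of log-variances (a scaled-inverse-chi-square prior), giving
a "posterior variance" s2_post and a moderated statistic

    z = (mean2 - mean1) / sqrt(s2_post * (1/n1 + 1/n2))

referred to a t distribution with d0 + d degrees of freedom. No
fold-change filter is applied on top of the FDR cut: small but
consistent shifts are exactly what variance shrinkage is meant to keep.

Direction conventions: effects are group2 - group1 (exposed minus
control), so hyper/GA/up all mean "higher in group 2".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq

from .io import CountMatrix, MethylSiteMatrix

__all__ = [
    "bh_adjust",
    "bin_methylation",
    "call_dmrs",
    "moderated_test",
    "call_dars",
    "call_degs",
    "curate_annotated",
    "BinnedMethylation",
]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in the
    input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# DMRs
# ---------------------------------------------------------------------------


@dataclass
class BinnedMethylation:
    """Pooled methylation counts per fixed-width genomic bin."""

    bins: pd.DataFrame  # chrom, start, end, n_sites
    meth: pd.DataFrame  # bins x samples
    total: pd.DataFrame
    samples: pd.DataFrame
    tested: pd.Series  # passes min_cov in every sample

    @property
    def levels(self) -> pd.DataFrame:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.meth / self.total.replace(0, np.nan)


def bin_methylation(
    m: MethylSiteMatrix, bin_bp: int = 100, min_cov: int = 10
) -> BinnedMethylation:
    """Pool site counts into half-open bins of ``bin_bp``.

    Bins whose pooled coverage falls below ``min_cov`` in any sample are
    flagged (``tested=False``) and excluded from downstream testing.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    key = pd.DataFrame(
        {"chrom": m.sites["chrom"], "bin_start": (m.sites["start"] // bin_bp) * bin_bp}
    )
    grouped_meth = m.meth.groupby([key["chrom"], key["bin_start"]]).sum()
    grouped_total = m.total.groupby([key["chrom"], key["bin_start"]]).sum()
    n_sites = m.sites.groupby([key["chrom"], key["bin_start"]]).size()
    bins = grouped_meth.index.to_frame(index=False)
    bins.columns = ["chrom", "start"]
    bins["end"] = bins["start"] + bin_bp
    bins["n_sites"] = n_sites.to_numpy()
    tested = pd.Series((grouped_total >= min_cov).all(axis=1).to_numpy(), name="tested")
    return BinnedMethylation(
        bins=bins,
        meth=grouped_meth.reset_index(drop=True),
        total=grouped_total.reset_index(drop=True),
        samples=m.samples,
        tested=tested,
    )


def _group_columns(samples: pd.DataFrame, group_labels) -> tuple[list[str], list[str]]:
    g1, g2 = group_labels
    c1 = list(samples.loc[samples["group"] == g1, "sample_id"])
    c2 = list(samples.loc[samples["group"] == g2, "sample_id"])
    if len(c1) < 2 or len(c2) < 2:
        raise ValueError(
            f"need >=2 samples per group for a variance estimate; got "
            f"{len(c1)} ({g1}) and {len(c2)} ({g2})"
        )
    return c1, c2


def call_dmrs(
    binned: BinnedMethylation,
    group_labels: tuple[str, str] = ("FA", "PM"),
    alpha: float = 0.05,
    delta_min: float = 0.10,
    merge_gap: int = 100,
    min_bins: int = 2,
    method: str = "moderated",
) -> pd.DataFrame:
    """Two-group test on arcsine-sqrt bin levels; BH; merge significant bins.

    The default test is the same empirical-Bayes moderated statistic used
    for DARs/DEGs, applied to the arcsine-square-root-transformed
    per-sample bin levels: at the few replicates typical of these designs
    a per-bin Welch t has so few degrees of freedom that its attainable
    p-values cannot survive an FDR adjustment over tens of thousands of
    bins, whereas the ensemble-shrunk variance restores power at
    essentially no calibration cost (the transform makes bin variances
    comparable). ``method="welch"`` switches to a plain per-bin Welch t.

    A bin is significant when q < alpha and |delta| >= delta_min, delta
    being the plain difference of group-mean methylation fractions
    (group2 - group1). Adjacent significant bins of the same sign with a
    gap <= merge_gap are merged; the merged effect is the coverage-
    weighted mean delta and the reported statistics come from the most
    significant member bin. A region must rest on at least ``min_bins``
    significant bins — an isolated significant bin is not a region.
    """
    c1, c2 = _group_columns(binned.samples, group_labels)
    tested = binned.tested.to_numpy()
    levels = binned.levels.loc[tested]
    y = np.arcsin(np.sqrt(levels.to_numpy(dtype=float)))
    delta = levels[c2].mean(axis=1).to_numpy() - levels[c1].mean(axis=1).to_numpy()
    if method == "moderated":
        res = moderated_test(
            pd.DataFrame(y, columns=levels.columns),
            binned.samples["group"],
            group_labels,
        )
        t = res["z"].to_numpy()
        p = res["p"].to_numpy()
    elif method == "welch":
        y1 = y[:, [levels.columns.get_loc(c) for c in c1]]
        y2 = y[:, [levels.columns.get_loc(c) for c in c2]]
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(y2, y1, axis=1, equal_var=False)
        t = np.asarray(t, dtype=float)
        p = np.asarray(p, dtype=float)
        tdiff = y2.mean(axis=1) - y1.mean(axis=1)
        zero_var = np.isnan(p)
        p[zero_var & (tdiff == 0)] = 1.0
        t[zero_var & (tdiff == 0)] = 0.0
        p[zero_var & (tdiff != 0)] = 0.0  # no within-group variance but a mean shift
    else:
        raise ValueError(f"unknown DMR test method {method!r}")
    q = bh_adjust(p)
    sig = (q < alpha) & (np.abs(delta) >= delta_min)

    bins = binned.bins.loc[tested].reset_index(drop=True)
    cov_w = binned.total.loc[tested].sum(axis=1).to_numpy()
    sig_tab = bins.loc[sig].assign(
        delta=delta[sig], t=t[sig], p=p[sig], q=q[sig], w=cov_w[sig]
    )
    sig_tab = sig_tab.sort_values(["chrom", "start"], ignore_index=True)

    regions = []
    current: list[pd.Series] = []

    def flush():
        if not current:
            return
        sub = pd.DataFrame(current)
        best = sub.loc[sub["q"].idxmin()]
        effect = float(np.average(sub["delta"], weights=sub["w"]))
        regions.append(
            {
                "chrom": sub["chrom"].iloc[0],
                "start": int(sub["start"].min()),
                "end": int(sub["end"].max()),
                "n_bins": len(sub),
                "n_sites": int(sub["n_sites"].sum()),
                "effect": effect,
                "z": float(best["t"]),
                "p": float(best["p"]),
                "q": float(best["q"]),
                "status": "hyper" if effect > 0 else "hypo",
            }
        )

    for row in sig_tab.itertuples(index=False):
        if current and (
            row.chrom == current[-1]["chrom"]
            and np.sign(row.delta) == np.sign(current[-1]["delta"])
            and row.start - current[-1]["end"] <= merge_gap
        ):
            current.append(pd.Series(row._asdict()))
        else:
            flush()
            current = [pd.Series(row._asdict())]
    flush()

    out = pd.DataFrame(
        regions,
        columns=["chrom", "start", "end", "n_bins", "n_sites", "effect", "z", "p", "q", "status"],
    )
    out = out[out["n_bins"] >= min_bins].reset_index(drop=True)
    out["region_id"] = [
        f"{c}:{s}-{e}" for c, s, e in zip(out["chrom"], out["start"], out["end"])
    ]
    return out


# ---------------------------------------------------------------------------
# Moderated two-group test (DARs / DEGs)
# ---------------------------------------------------------------------------


def _fit_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Scaled-inverse-chi-square prior (d0, s0^2) by log-variance moments.

    Marginally s2/s0^2 ~ F(d, d0), so Var[log s2] = psi'(d/2) + psi'(d0/2)
    and E[log s2] = log s0^2 + psi(d/2) - log(d/2) - psi(d0/2) + log(d0/2).
    """
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 3:
        raise ValueError(
            "too few features with positive variance to estimate the shrinkage prior"
        )
    e = np.log(s2)
    evar = float(np.var(e, ddof=1))
    target = evar - float(special.polygamma(1, d / 2.0))
    if target <= float(special.polygamma(1, 1e7 / 2.0)):
        d0 = np.inf
        s02 = float(np.exp(e.mean() - special.digamma(d / 2.0) + np.log(d / 2.0)))
        return d0, s02
    half_d0 = brentq(lambda x: float(special.polygamma(1, x)) - target, 1e-8, 1e7 / 2.0)
    d0 = 2.0 * half_d0
    s02 = float(
        np.exp(
            e.mean()
            - special.digamma(d / 2.0)
            + np.log(d / 2.0)
            + special.digamma(d0 / 2.0)
            - np.log(d0 / 2.0)
        )
    )
    return d0, s02


def moderated_test(
    log_signal: pd.DataFrame,
    groups,
    group_labels: tuple[str, str] = ("FA", "PM"),
    prior: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group test on a features x samples matrix.

    ``groups`` is the per-column group label sequence. ``prior`` fixes
    (d0, s0^2) instead of estimating them (useful for studying limits).
    Returns a frame with delta, z, s2_post, p and attrs d0, s02, df.
    """
    groups = pd.Series(list(groups))
    samples = pd.DataFrame({"sample_id": log_signal.columns, "group": groups.to_numpy()})
    c1, c2 = _group_columns(samples, group_labels)
    x1 = log_signal[c1].to_numpy(dtype=float)
    x2 = log_signal[c2].to_numpy(dtype=float)
    if np.isnan(x1).any() or np.isnan(x2).any():
        raise ValueError("NaN in input signal matrix")
    n1, n2 = x1.shape[1], x2.shape[1]
    d = n1 + n2 - 2
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    rss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = rss / d
    delta0 = m2 - m1
    if prior is None:
        if (s2 > 0).sum() < 3 and np.all(delta0 == 0):
            # degenerate but unambiguous: identical data carry no evidence
            out = pd.DataFrame(
                {"delta": delta0, "z": 0.0, "s2_post": 0.0, "p": 1.0},
                index=log_signal.index,
            )
            out.attrs.update({"d0": np.inf, "s02": 0.0, "df": np.inf, "n1": n1, "n2": n2})
            return out
        d0, s02 = _fit_variance_prior(s2, d)
    else:
        d0, s02 = prior
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df = np.inf
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df = d0 + d
    delta = m2 - m1
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    z = delta / se
    if np.isinf(df):
        p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        p = 2.0 * stats.t.sf(np.abs(z), df)
    out = pd.DataFrame(
        {"delta": delta, "z": z, "s2_post": s2_post, "p": p}, index=log_signal.index
    )
    out.attrs.update({"d0": d0, "s02": s02, "df": df, "n1": n1, "n2": n2})
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (relative depth per sample).

    Each sample's factor is the median, over features observed in every
    sample, of its counts divided by the feature's geometric mean. This
    is robust to composition: a handful of strongly shifted features
    cannot drag the scale of the remaining ones, which a plain
    total-count library size does when up- and down-shifts are
    unbalanced in linear space.
    """
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        zero = lib.index[lib == 0][0]
        raise ValueError(f"library size of sample {zero!r} is zero")
    vals = counts.to_numpy(dtype=float)
    positive = (vals > 0).all(axis=1)
    if positive.sum() < 10:  # too few all-observed features: fall back to depth
        sf = lib / np.exp(np.mean(np.log(lib)))
        return pd.Series(sf, index=counts.columns)
    logv = np.log(vals[positive])
    ratios = logv - logv.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns)


def log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) with median-of-ratios effective library sizes."""
    sf = size_factors(counts)
    scaled = counts.div(sf, axis=1)
    eff_lib = float(scaled.sum(axis=0).mean())
    return np.log2(scaled / eff_lib * 1e6 + 1.0)


def _call_counts(
    cm: CountMatrix, group_labels, alpha, status_labels: tuple[str, str]
) -> pd.DataFrame:
    signal = log_cpm(cm.counts)
    res = moderated_test(signal, cm.samples["group"], group_labels)
    res["q"] = bh_adjust(res["p"].to_numpy())
    res["status"] = np.where(res["delta"] > 0, status_labels[0], status_labels[1])
    res.loc[res["delta"] == 0, "status"] = "flat"
    sig = res[res["q"] < alpha].copy()
    zcut = float(np.min(np.abs(sig["z"]))) if len(sig) else float("nan")
    sig = sig.rename(columns={"delta": "effect"})
    sig.attrs.update(res.attrs)
    sig.attrs["zcut"] = zcut
    return sig


def call_dars(
    pc: CountMatrix,
    group_labels: tuple[str, str] = ("FA", "PM"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Moderated test on log2(CPM+1) peak counts; q < alpha, no fold-change cut.

    The smallest |z| among significant peaks is recorded in
    ``attrs['zcut']`` (the boundary of the calls in the shrinkage plot).
    Status GA = more accessible in group 2, LA = less.
    """
    sig = _call_counts(pc, group_labels, alpha, ("GA", "LA"))
    out = sig.reset_index(names="feature_id")
    if pc.regions is not None:
        coords = pc.regions.loc[out["feature_id"]]
        out["chrom"] = coords["chrom"].to_numpy()
        out["start"] = coords["start"].to_numpy()
        out["end"] = coords["end"].to_numpy()
        out["region_id"] = out["feature_id"]
    out.attrs.update(sig.attrs)
    return out


def call_degs(
    gc: CountMatrix,
    group_labels: tuple[str, str] = ("FA", "PM"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Moderated test on log2(CPM+1) gene counts; status up/down."""
    sig = _call_counts(gc, group_labels, alpha, ("up", "down"))
    out = sig.reset_index(names="gene_id")
    out = out.rename(columns={"effect": "log2fc"})
    out.attrs.update(sig.attrs)
    return out


def curate_annotated(calls: pd.DataFrame) -> pd.DataFrame:
    """Reduce annotated calls to unique (target gene, status) representatives.

    Calls without a target gene are dropped; among calls sharing a
    (target_gene, status) pair the smallest q wins, ties broken by
    smaller |TSS distance| then genomic position.
    """
    if "target_gene" not in calls.columns:
        raise ValueError("calls must be annotated (run annotate_regions first)")
    out = calls[calls["target_gene"].notna()].copy()
    out["_absd"] = out["tss_distance"].abs()
    out = out.sort_values(["q", "_absd", "chrom", "start"], kind="stable")
    out = out.drop_duplicates(subset=["target_gene", "status"], keep="first")
    out = out.drop(columns="_absd").sort_values(["chrom", "start"], ignore_index=True)
    return out
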