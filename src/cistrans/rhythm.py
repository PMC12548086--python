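"""Single-cosinor fitting of 24-h expression series and group comparison.

The cosinor model is linear least squares on the design
[1, cos(wt), sin(wt)], w = 2*pi/period:

    y(t) = M + A*cos(w*(t - phi)) + e,   A >= 0,  phi in [0, period)

with mesor M (rhythm-adjusted mean), amplitude A (half the peak-to-
trough swing; the full swing is also reported) and acrophase phi (hour
of the rhythm's peak, anchored to the cosine maximum). Standard errors
for A and phi come from the delta method; a zero-amplitude F test (2
numerator df) screens for rhythmicity. Group comparisons are Wald tests
on the mesor, amplitude and circular acrophase differences, BH-adjusted
across genes x parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffcall import bh_adjust

__all__ = ["CosinorFit", "cosinor_fit", "compare_cosinor", "fit_rhythms"]

_DEGENERATE_TOL = 1e-9


@dataclass
class CosinorFit:
    mesor: float
    amplitude: float
    acrophase: float  # hours in [0, period); NaN when degenerate
    se_mesor: float
    se_amplitude: float
    se_acrophase: float
    peak_to_trough: float
    resid_sd: float
    n: int
    p_rhythm: float
    degenerate: bool
    period: float


def cosinor_fit(times, values, period: float = 24.0) -> CosinorFit:
    """Least-squares single cosinor fit of one series."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if period <= 0:
        raise ValueError("period must be > 0")
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be matching 1-d arrays")
    if len(np.unique(t)) < 4:
        raise ValueError("need at least 4 distinct timepoints for a cosinor fit")
    w = 2.0 * np.pi / period
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("collinear cosinor design (timepoints do not span the period)")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    mesor, bc, bs = coef
    resid = y - X @ coef
    n = len(y)
    dof = n - 3
    rss = float(resid @ resid)
    sigma2 = rss / dof if dof > 0 else float("nan")
    cov = sigma2 * np.linalg.inv(X.T @ X)

    amplitude = float(np.hypot(bc, bs))
    scale = max(1.0, abs(mesor))
    degenerate = amplitude < _DEGENERATE_TOL * scale
    if degenerate:
        acrophase = float("nan")
        se_amp = float(np.sqrt(max(cov[1, 1], cov[2, 2]))) if dof > 0 else float("nan")
        se_phi = float("nan")
    else:
        acrophase = float((period / (2.0 * np.pi)) * np.arctan2(bs, bc) % period)
        g_amp = np.array([0.0, bc / amplitude, bs / amplitude])
        g_phi = (period / (2.0 * np.pi)) * np.array(
            [0.0, -bs / amplitude**2, bc / amplitude**2]
        )
        se_amp = float(np.sqrt(g_amp @ cov @ g_amp))
        se_phi = float(np.sqrt(g_phi @ cov @ g_phi))
    # zero-amplitude F test against the intercept-only model
    rss0 = float(((y - y.mean()) ** 2).sum())
    if dof > 0 and rss > 0:
        f = ((rss0 - rss) / 2.0) / (rss / dof)
        p_rhythm = float(stats.f.sf(f, 2, dof))
    elif dof > 0 and rss0 > rss:
        p_rhythm = 0.0  # perfect rhythmic fit
    else:
        p_rhythm = 1.0
    return CosinorFit(
        mesor=float(mesor),
        amplitude=amplitude,
        acrophase=acrophase,
        se_mesor=float(np.sqrt(cov[0, 0])) if dof > 0 else float("nan"),
        se_amplitude=se_amp,
        se_acrophase=se_phi,
        peak_to_trough=2.0 * amplitude,
        resid_sd=float(np.sqrt(sigma2)) if dof > 0 else float("nan"),
        n=n,
        p_rhythm=p_rhythm,
        degenerate=degenerate,
        period=period,
    )


def wrap_phase_difference(dphi: float, period: float = 24.0) -> float:
    """Wrap a circular difference to (-period/2, period/2]."""
    x = (dphi + period / 2.0) % period - period / 2.0
    return period / 2.0 if x == -period / 2.0 else x


def fit_rhythms(series: pd.DataFrame, period: float = 24.0) -> pd.DataFrame:
    """Per (gene, group) cosinor fits of a long-format series."""
    rows = []
    for (gene, group), sub in series.groupby(["gene", "group"], sort=True):
        fit = cosinor_fit(sub["zt"], sub["value"], period=period)
        rows.append({"gene": gene, "group": group, **fit.__dict__})
    return pd.DataFrame(rows)


def _wald(delta: float, se: float) -> float:
    if not np.isfinite(se) or se == 0:
        return float("nan")
    return float(2.0 * stats.norm.sf(abs(delta) / se))


def compare_cosinor(
    series: pd.DataFrame,
    group_labels: tuple[str, str] = ("FA", "PM"),
    period: float = 24.0,
) -> pd.DataFrame:
    """Per-gene group differences in mesor, amplitude and acrophase.

    Wald tests on each parameter difference (group2 - group1); the
    acrophase difference is wrapped to (-period/2, period/2] and its
    test is skipped (flagged) when either fit is degenerate. p-values
    are BH-adjusted jointly across genes x parameters.
    """
    g1, g2 = group_labels
    fits = fit_rhythms(series[series["group"].isin(group_labels)], period=period)
    rows = []
    for gene, sub in fits.groupby("gene"):
        by = sub.set_index("group")
        if not {g1, g2}.issubset(by.index):
            raise ValueError(f"gene {gene!r} lacks one of the groups {group_labels}")
        f1, f2 = by.loc[g1], by.loc[g2]
        d_mesor = float(f2["mesor"] - f1["mesor"])
        d_amp = float(f2["amplitude"] - f1["amplitude"])
        degenerate = bool(f1["degenerate"] or f2["degenerate"])
        if degenerate:
            d_phi, p_phi = float("nan"), float("nan")
        else:
            d_phi = wrap_phase_difference(
                float(f2["acrophase"] - f1["acrophase"]), period=period
            )
            p_phi = _wald(d_phi, np.hypot(f1["se_acrophase"], f2["se_acrophase"]))
        rows.append(
            {
                "gene": gene,
                "d_mesor": d_mesor,
                "p_mesor": _wald(d_mesor, np.hypot(f1["se_mesor"], f2["se_mesor"])),
                "d_amplitude": d_amp,
                "p_amplitude": _wald(d_amp, np.hypot(f1["se_amplitude"], f2["se_amplitude"])),
                "d_acrophase": d_phi,
                "p_acrophase": p_phi,
                "acrophase_skipped": degenerate,
            }
        )
    out = pd.DataFrame(rows)
    # joint BH over genes x parameters, leaving skipped tests missing
    pcols = ["p_mesor", "p_amplitude", "p_acrophase"]
    stacked = out[pcols].to_numpy().ravel()
    mask = np.isfinite(stacked)
    q = np.full_like(stacked, np.nan)
    if mask.any():
        q[mask] = bh_adjust(stacked[mask])
    qmat = q.reshape(out[pcols].shape)
    for i, col in enumerate(pcols):
        out[col.replace("p_", "q_")] = qmat[:, i]
    return out
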