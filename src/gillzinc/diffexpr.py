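"""Per-time-point differential-expression calling and temporal summaries.

At each sampling time the zinc-depleted group is compared against the
time-matched control with a t-test per reporter, Benjamini-Hochberg
correction across reporters within that time point, and a conjunction
call: |signed fold change| > 1.8 AND adjusted P < 0.1 (10% FDR), both
strict.  Fold changes follow the signed convention used for two-colour
ratio data: a linear ratio r maps to +r when r >= 1 and to -1/r when
r < 1, so the 1.8-fold threshold is symmetric for induction and
repression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ConfigurationError, ExpressionDataset

DEFAULT_FC_THRESHOLD = 1.8
DEFAULT_FDR_THRESHOLD = 0.1


def welch_t_test(
    group_a: np.ndarray, group_b: np.ndarray, pooled: bool = False
) -> tuple[float, float, float]:
    """Two-sample t-test of mean(a) - mean(b).

    Welch's unequal-variance form with Welch-Satterthwaite degrees of
    freedom by default; ``pooled=True`` gives the classic equal-variance
    Student test.  Degenerate inputs follow a stated convention: both
    groups constant with equal means -> (0, 1); both constant with
    unequal means -> (inf, 0).

    Returns
    -------
    (t, two-sided p, df)
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ConfigurationError("each group needs >= 2 non-missing values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            return 0.0, 1.0, float(na + nb - 2)
        return float(np.sign(diff) * np.inf), 0.0, float(na + nb - 2)
    if pooled:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = float(na + nb - 2)
    else:
        sea2, seb2 = va / na, vb / nb
        se = np.sqrt(sea2 + seb2)
        df = (sea2 + seb2) ** 2 / (sea2**2 / (na - 1) + seb2**2 / (nb - 1))
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), float(df)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Missing p-values propagate as NaN without entering the family size.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        if (p[ok] < 0).any() or (p[ok] > 1).any():
            raise ConfigurationError("p-values must lie in [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def signed_fold_change(depleted, control) -> float:
    """Signed linear fold change from two groups of log2 ratios.

    r = 2**(mean(depleted) - mean(control)); returns +r for r >= 1 and
    -1/r otherwise, so identical means give +1 and a halving gives -2.
    """
    d = np.asarray(depleted, dtype=float)
    c = np.asarray(control, dtype=float)
    d, c = d[np.isfinite(d)], c[np.isfinite(c)]
    if len(d) == 0 or len(c) == 0:
        raise ConfigurationError("fold change needs >= 1 value per group")
    r = 2.0 ** (d.mean() - c.mean())
    return float(r) if r >= 1.0 else float(-1.0 / r)


def _signed_from_log2(diff: np.ndarray) -> np.ndarray:
    r = 2.0**diff
    return np.where(r >= 1.0, r, -1.0 / r)


@dataclass
class TemporalSummary:
    """Per-time-point regulation counts plus direction-persistent genes."""

    per_time: pd.DataFrame  # index time, columns n_up, n_down, n_total
    pct_up: float  # over all (reporter, time) called events; NaN if none
    pct_down: float
    persistent: list  # reporters called with one constant direction at every time


def call_regulated(
    dataset: ExpressionDataset,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    pooled: bool = False,
) -> pd.DataFrame:
    """Call differential expression per reporter per time point.

    Expects a dataset that went through ``filter_expressed`` (uses its
    ``retained`` sets).  BH correction is applied within each time point
    across the reporters tested there.  Returns the long-form call table
    with columns reporter, time, fc, p, q, direction, called.
    """
    if not dataset.retained:
        raise ConfigurationError("dataset has no retained sets; run filter_expressed first")
    rows = []
    for t in dataset.time_points:
        keep = dataset.retained[t]
        if len(keep) == 0:
            continue
        dep = dataset.M.loc[keep, dataset.arrays_for("depleted", t)].to_numpy()
        ctl = dataset.M.loc[keep, dataset.arrays_for("control", t)].to_numpy()
        tstat, p = _vector_welch(dep, ctl, pooled=pooled)
        q = bh_adjust(p)
        fc = _signed_from_log2(np.nanmean(dep, axis=1) - np.nanmean(ctl, axis=1))
        called = (np.abs(fc) > fc_threshold) & (q < fdr_threshold)
        direction = np.where(~called, "none", np.where(fc > 0, "up", "down"))
        rows.append(
            pd.DataFrame(
                {
                    "reporter": keep,
                    "time": t,
                    "fc": fc,
                    "p": p,
                    "q": q,
                    "direction": direction,
                    "called": called,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["reporter", "time", "fc", "p", "q", "direction", "called"]
        )
    return pd.concat(rows, ignore_index=True)


def _vector_welch(
    dep: np.ndarray, ctl: np.ndarray, pooled: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch (or pooled) t-test with NaN-aware group sizes."""
    na = np.isfinite(dep).sum(axis=1).astype(float)
    nb = np.isfinite(ctl).sum(axis=1).astype(float)
    if (na < 2).any() or (nb < 2).any():
        raise ConfigurationError("every tested reporter needs >= 2 values per group")
    ma, mb = np.nanmean(dep, axis=1), np.nanmean(ctl, axis=1)
    va = np.nanvar(dep, axis=1, ddof=1)
    vb = np.nanvar(ctl, axis=1, ddof=1)
    diff = ma - mb
    if pooled:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = na + nb - 2
    else:
        sea2, seb2 = va / na, vb / nb
        se2 = sea2 + seb2
        with np.errstate(invalid="ignore", divide="ignore"):
            df = se2**2 / (sea2**2 / (na - 1) + seb2**2 / (nb - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # degenerate rows: both groups constant
    degen = se2 == 0.0
    if degen.any():
        equal = degen & (diff == 0.0)
        t[equal], p[equal] = 0.0, 1.0
        unequal = degen & (diff != 0.0)
        t[unequal] = np.sign(diff[unequal]) * np.inf
        p[unequal] = 0.0
    return t, p


def temporal_summary(calls: pd.DataFrame) -> TemporalSummary:
    """Summarise a call table: per-time counts, overall up/down %, persistence.

    A reporter is direction-persistent when it is called at every time
    point present in the table with the same nonzero direction throughout.
    Percentages are over all called (reporter, time) events and NaN when
    nothing was called.
    """
    times = sorted(calls["time"].unique()) if len(calls) else []
    hit = calls[calls["called"]] if len(calls) else calls
    per = pd.DataFrame(index=pd.Index(times, name="time"))
    if len(times):
        g = hit.groupby("time")["direction"]
        per["n_up"] = g.apply(lambda s: int((s == "up").sum())).reindex(times, fill_value=0)
        per["n_down"] = g.apply(lambda s: int((s == "down").sum())).reindex(
            times, fill_value=0
        )
        per["n_total"] = per["n_up"] + per["n_down"]
    else:
        per["n_up"] = per["n_down"] = per["n_total"] = []
    n_events = len(hit)
    pct_up = 100.0 * (hit["direction"] == "up").sum() / n_events if n_events else np.nan
    pct_down = 100.0 * (hit["direction"] == "down").sum() / n_events if n_events else np.nan
    persistent = []
    if n_events and len(times):
        counts = hit.groupby("reporter")["direction"].agg(["nunique", "count", "first"])
        sel = counts[(counts["count"] == len(times)) & (counts["nunique"] == 1)]
        persistent = sorted(sel.index)
    return TemporalSummary(
        per_time=per, pct_up=float(pct_up), pct_down=float(pct_down), persistent=persistent
    )


def collapse_to_genes(calls: pd.DataFrame, reporter_to_gene: dict) -> pd.DataFrame:
    """Collapse reporter-level calls to genes, keeping the most significant reporter.

    Arrays carry several reporters per gene; for reporting, each
    (gene, time) keeps the row with the smallest q (ties: largest |fc|).
    """
    out = calls.copy()
    out["gene"] = out["reporter"].map(reporter_to_gene).fillna(out["reporter"])
    out = out.sort_values(["q", "fc"], key=lambda s: s if s.name == "q" else -s.abs())
    return out.groupby(["gene", "time"], as_index=False).first()
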