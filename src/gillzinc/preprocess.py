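"""Two-channel array preprocessing: MA transform, lowess normalization, filters.

Each hybridisation compares one sample (Cy5) against a common reference
(Cy3), so the per-spot measurement is the log ratio M = log2(R/G) and the
average log intensity A = (log2 R + log2 G)/2.  Dye incorporation bias is
intensity-dependent, which shows up as a smooth trend of M on A; it is
removed per array by subtracting a lowess fit of M on A.  Downstream
testing only uses spots that pass the scanner's per-spot confidence call
and reporters with enough surviving replicates in both groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

CONDITIONS = ("depleted", "control")

#: sampling times in days (8 h = 0.3 d)
DEFAULT_TIME_POINTS = (0.3, 1.0, 4.0, 7.0, 14.0)

DEFAULT_LOWESS_SPAN = 0.3
DEFAULT_LOWESS_ITER = 3
DEFAULT_MIN_REPLICATES = 3


class ConfigurationError(ValueError):
    """Raised when an input table or parameter violates a contract."""


@dataclass
class ExpressionDataset:
    """Reporter-by-array log-ratio data with its sample design.

    Attributes
    ----------
    M : DataFrame, reporters x arrays
        log2(sample/reference) per spot; NaN where missing or filtered.
    A : DataFrame, reporters x arrays
        mean log2 spot intensity; NaN where missing.
    confidence : DataFrame of bool, reporters x arrays
        True where the spot passed the quantification confidence call.
    design : DataFrame indexed by array id
        columns ``condition`` (depleted/control), ``time`` (days),
        ``replicate`` (int).
    """

    M: pd.DataFrame
    A: pd.DataFrame
    confidence: pd.DataFrame
    design: pd.DataFrame
    normalized: bool = False
    #: reporters retained per (time point) comparison, filled by filter_expressed
    retained: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.M.shape != self.A.shape or self.M.shape != self.confidence.shape:
            raise ConfigurationError("M, A and confidence must share shape")
        if not self.M.columns.equals(self.A.columns):
            raise ConfigurationError("M and A must share array ids")
        if set(self.M.columns) != set(self.design.index):
            raise ConfigurationError("every array id must appear exactly once in the design")
        if self.design.index.has_duplicates:
            raise ConfigurationError("duplicate array id in design")
        bad = set(self.design["condition"]) - set(CONDITIONS)
        if bad:
            raise ConfigurationError(f"unknown condition labels: {sorted(bad)}")

    @property
    def reporters(self) -> pd.Index:
        return self.M.index

    @property
    def time_points(self) -> list[float]:
        return sorted(self.design["time"].unique())

    def arrays_for(self, condition: str, time: float) -> list[str]:
        d = self.design
        sel = d.index[(d["condition"] == condition) & (d["time"] == time)]
        return list(sel)

    def copy(self) -> "ExpressionDataset":
        return replace(
            self,
            M=self.M.copy(),
            A=self.A.copy(),
            confidence=self.confidence.copy(),
            design=self.design.copy(),
            retained=dict(self.retained),
        )


def compute_ma(red: pd.DataFrame, green: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MA transform of two-channel intensities, sample in the red channel.

    M = log2(R/G), A = (log2 R + log2 G)/2.  Spots where either channel is
    missing or non-positive become NaN in both outputs rather than raising.
    """
    if red.shape != green.shape:
        raise ConfigurationError(
            f"channel shape mismatch: red {red.shape} vs green {green.shape}"
        )
    r = red.to_numpy(dtype=float).copy()
    g = green.to_numpy(dtype=float).copy()
    bad = ~(np.isfinite(r) & np.isfinite(g) & (r > 0) & (g > 0))
    r[bad] = np.nan
    g[bad] = np.nan
    with np.errstate(invalid="ignore"):
        lr, lg = np.log2(r), np.log2(g)
    M = pd.DataFrame(lr - lg, index=red.index, columns=red.columns)
    A = pd.DataFrame((lr + lg) / 2.0, index=red.index, columns=red.columns)
    return M, A


def lowess_normalize(
    m: np.ndarray,
    a: np.ndarray,
    span: float = DEFAULT_LOWESS_SPAN,
    iterations: int = DEFAULT_LOWESS_ITER,
) -> np.ndarray:
    """Subtract the lowess trend of M on A for a single array.

    Returns M minus the locally weighted fit evaluated at each spot's A.
    Missing values propagate untouched; the fit uses only complete spots.
    """
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    if m.shape != a.shape:
        raise ConfigurationError("M and A vectors must have equal length")
    if not 0 < span <= 1:
        raise ConfigurationError(f"span must be in (0, 1], got {span}")
    ok = np.isfinite(m) & np.isfinite(a)
    if ok.sum() < 10:
        raise ConfigurationError(
            "fewer than 10 complete spots; rerun with normalization skipped"
        )
    # delta collapses near-duplicate A values; pure speed knob
    delta = 0.005 * (np.nanmax(a[ok]) - np.nanmin(a[ok]))
    fitted = _sm_lowess(
        m[ok], a[ok], frac=span, it=iterations, delta=delta, return_sorted=False
    )
    # spots with missing M or A cannot be corrected and stay missing;
    # MA-transformed data shares missingness between the two, so the
    # pattern is unchanged in practice
    out = np.full(m.shape, np.nan)
    out[ok] = m[ok] - fitted
    return out


def normalize_dataset(
    dataset: ExpressionDataset,
    span: float = DEFAULT_LOWESS_SPAN,
    iterations: int = DEFAULT_LOWESS_ITER,
) -> ExpressionDataset:
    """Apply per-array lowess normalization to every array of a dataset."""
    out = dataset.copy()
    for array_id in out.M.columns:
        out.M[array_id] = lowess_normalize(
            out.M[array_id].to_numpy(), out.A[array_id].to_numpy(), span, iterations
        )
    out.normalized = True
    return out


def filter_expressed(
    dataset: ExpressionDataset,
    min_replicates: int = DEFAULT_MIN_REPLICATES,
) -> ExpressionDataset:
    """Apply the confidence filter and the replicate rule.

    Spots failing the per-spot confidence call are set missing.  A reporter
    enters the depleted-vs-control comparison at a given time point only if
    both groups retain at least ``min_replicates`` non-missing values there;
    the retained reporter set is recorded per time point in ``retained``.
    """
    if min_replicates < 2:
        raise ConfigurationError("min_replicates must be >= 2 (t-test needs two values)")
    out = dataset.copy()
    out.M = out.M.where(out.confidence)
    out.A = out.A.where(out.confidence)
    retained: dict[float, pd.Index] = {}
    for t in out.time_points:
        ok = None
        for condition in CONDITIONS:
            cols = out.arrays_for(condition, t)
            counts = out.M[cols].notna().sum(axis=1)
            this = counts >= min_replicates
            ok = this if ok is None else (ok & this)
        retained[t] = out.M.index[ok]
    out.retained = retained
    return out
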