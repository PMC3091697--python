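"""Closed-form physiology: unidirectional zinc influx and qPCR quantification.

Influx across the gill is measured by whole-body accumulation of a 65Zn
tracer: J_in = cpm / (SA * bw * t) in pmol g^-1 h^-1, where SA is the
specific activity of the tracer in the water (cpm pmol^-1), bw the fish
body weight (g) and t the flux duration (h).

qPCR abundance comes off a per-gene standard curve Ct = slope * log10(copies)
+ intercept fitted on serial dilutions; relative copies are then divided
by the relative copies of the 18s rRNA reference gene.
"""

from __future__ import annotations

import numpy as np

from .diffexpr import welch_t_test
from .preprocess import ConfigurationError


def zinc_influx(cpm: float, sa: float, bw: float, t: float) -> float:
    """Unidirectional influx J_in = cpm / (SA * bw * t), pmol g^-1 h^-1."""
    if sa <= 0 or bw <= 0 or t <= 0:
        raise ConfigurationError("SA, bw and t must all be positive")
    if cpm < 0:
        raise ConfigurationError("cpm cannot be negative")
    return cpm / (sa * bw * t)


def specific_activity(label_cpm_per_l: float, total_zn_pmol_per_l: float) -> float:
    """Tracer specific activity SA = [65Zn] / [Zn total], cpm pmol^-1."""
    if total_zn_pmol_per_l <= 0:
        raise ConfigurationError("total zinc concentration must be positive")
    if label_cpm_per_l < 0:
        raise ConfigurationError("label activity cannot be negative")
    return label_cpm_per_l / total_zn_pmol_per_l


def fit_standard_curve(log10_copies, ct_values) -> tuple[float, float, float]:
    """Least-squares standard curve Ct = slope*log10(copies) + intercept.

    Returns (slope, intercept, efficiency) where the amplification
    efficiency is E = 10**(-1/slope) - 1 (E = 1 for perfect doubling,
    slope about -3.32).
    """
    x = np.asarray(log10_copies, dtype=float)
    y = np.asarray(ct_values, dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise ConfigurationError("need >= 2 matching (dilution, Ct) pairs")
    slope, intercept = np.polyfit(x, y, 1)
    if slope == 0:
        raise ConfigurationError("degenerate standard curve (zero slope)")
    efficiency = 10.0 ** (-1.0 / slope) - 1.0
    return float(slope), float(intercept), float(efficiency)


def qpcr_copies(ct: float, slope: float, intercept: float) -> float:
    """Relative copy number from a Ct value via the standard curve inverse."""
    if slope == 0:
        raise ConfigurationError("slope must be nonzero")
    return 10.0 ** ((ct - intercept) / slope)


def qpcr_relative_expression(
    ct: float, slope: float, intercept: float, reference_copies: float
) -> float:
    """Copies off the standard curve, normalised to 18s reference copies."""
    if reference_copies <= 0:
        raise ConfigurationError("reference copies must be positive")
    return qpcr_copies(ct, slope, intercept) / reference_copies


def compare_groups(group_a, group_b, alpha: float = 0.05) -> dict:
    """Two-tailed unpaired Student's t-test between measurement groups."""
    t, p, df = welch_t_test(group_a, group_b, pooled=True)
    return {"t": t, "p": p, "df": df, "significant": bool(p < alpha)}
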