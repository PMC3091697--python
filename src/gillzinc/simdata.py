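"""Synthetic data with the statistical structure of the gill time-course study.

The expression generator emulates a two-channel (sample vs common
reference) oligonucleotide array experiment: ~16K reporters measured for
two conditions (zinc depleted vs control) at five time points (0.3, 1, 4,
7, 14 days) in quintuplicate, with one control replicate missing at Day 4.
Each spot carries a log ratio

    M = beta_g + effect(g, t)*[depleted] + b(A) + eps,   eps ~ N(0, noise_sd)

where beta_g is a reporter baseline shared by both conditions, b(A) is a
smooth intensity-dependent dye bias (a cubic in the spot's average log
intensity A) that lowess normalization is expected to remove, and the
planted effects hit a small minority of reporters (~3% at one or more
time points) with down-regulation dominating from Day 4 onwards.  One
designated reporter is persistently down-regulated at every time point
(the metallothionein-like pattern).  Every planted quantity is returned
in a ground-truth table so recovery can be checked by direct enumeration.

Companion generators produce promoter sets with planted motif sites,
gene->term annotation tables with planted overlaps, and random curated
edge tables, covering the remaining pipeline stages.

All randomness flows from a single seed through named child streams, so
identical configurations give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import (
    DEFAULT_TIME_POINTS,
    ConfigurationError,
    ExpressionDataset,
)
from .network import EDGE_TYPES
from .tfbs import IUPAC, MotifPattern, PromoterSet

_STREAMS = (
    "baseline", "intensity", "noise", "confidence", "effects",
    "promoters", "annotation", "edges",
)


def _rngs(seed: int) -> dict:
    """Named, independent generator streams derived from one seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for the expression generator.

    Defaults reproduce the design of the source experiment: 16,000
    reporters, depleted vs control at 0.3/1/4/7/14 days, five replicates
    each with one Day-4 control replicate dropped, 3% of reporters
    regulated at one or more time points with planted |log2 FC| = 1.5,
    measurement noise SD 0.4, and a cubic dye bias bounded by ~0.35 log2
    units.
    """

    n_reporters: int = 16000
    time_points: tuple = DEFAULT_TIME_POINTS
    n_replicates: int = 5
    #: (condition, time) pairs that lose one replicate
    dropout: tuple = (("control", 4.0),)
    #: fraction of reporters carrying a nonzero effect at >= 1 time point
    frac_regulated: float = 0.03
    #: P(activation) per time point for a regulated reporter; peaks at Day 7
    activation_weights: tuple = (0.12, 0.18, 0.32, 0.42, 0.07)
    #: P(down | active) at time points >= late_from days; earlier times are 50/50
    frac_down_late: float = 0.75
    late_from: float = 4.0
    effect_log2: float = 1.5
    noise_sd: float = 0.4
    baseline_sd: float = 0.3
    #: dye-bias polynomial coefficients in z = (A - 11)/5, low order first
    bias_coeffs: tuple = (0.1, -0.4, 0.15, 0.3)
    low_confidence_rate: float = 0.02
    #: plant one reporter down-regulated at every time point; the
    #: metallothionein-like response is strong, so it gets its own magnitude
    plant_persistent: bool = True
    persistent_effect_log2: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_regulated", "frac_down_late", "low_confidence_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_reporters < 1:
            raise ConfigurationError(f"n_reporters must be >= 1, got {self.n_reporters}")
        if self.n_replicates < 1:
            raise ConfigurationError(f"n_replicates must be >= 1, got {self.n_replicates}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.effect_log2 <= 0:
            raise ConfigurationError(f"effect_log2 must be > 0, got {self.effect_log2}")
        if len(self.activation_weights) != len(self.time_points):
            raise ConfigurationError(
                "activation_weights must match time_points in length"
            )
        for cond, t in self.dropout:
            if cond not in ("depleted", "control") or t not in self.time_points:
                raise ConfigurationError(f"dropout refers to unknown cell ({cond}, {t})")


def _bias(a: np.ndarray, coeffs) -> np.ndarray:
    z = (a - 11.0) / 5.0
    return np.polynomial.polynomial.polyval(z, np.asarray(coeffs, dtype=float))


def simulate_expression_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Draw one synthetic experiment plus its planted ground truth.

    Returns the dataset (M/A/confidence matrices with the sample design)
    and a truth table indexed by reporter with one ``effect_<t>`` column
    per time point (0 where unregulated), a ``regulated`` flag and a
    ``persistent`` flag (same nonzero sign at every time point).
    """
    config.validate()
    rng = _rngs(config.seed)
    tps = tuple(float(t) for t in config.time_points)
    reporters = pd.Index([f"rep{i:05d}" for i in range(config.n_reporters)], name="reporter")

    # --- design ---------------------------------------------------------
    rows = []
    dropout = {(c, float(t)) for c, t in config.dropout}
    for cond in ("depleted", "control"):
        for t in tps:
            n = config.n_replicates - ((cond, t) in dropout)
            for r in range(1, n + 1):
                rows.append((f"{cond[:3]}_d{t:g}_r{r}", cond, t, r))
    design = pd.DataFrame(
        rows, columns=["array", "condition", "time", "replicate"]
    ).set_index("array")

    # --- planted effects ------------------------------------------------
    n_reg = int(round(config.frac_regulated * config.n_reporters))
    er = rng["effects"]
    reg_idx = np.sort(er.choice(config.n_reporters, size=n_reg, replace=False))
    effects = np.zeros((config.n_reporters, len(tps)))
    if n_reg:
        active = er.random((n_reg, len(tps))) < np.asarray(config.activation_weights)
        silent = ~active.any(axis=1)
        active[silent, er.integers(0, len(tps), size=int(silent.sum()))] = True
        p_down = np.where(np.asarray(tps) >= config.late_from, config.frac_down_late, 0.5)
        down = er.random((n_reg, len(tps))) < p_down
        sign = np.where(down, -1.0, 1.0)
        effects[reg_idx] = np.where(active, sign * config.effect_log2, 0.0)
        if config.plant_persistent:
            effects[reg_idx[0]] = -config.persistent_effect_log2
    truth = pd.DataFrame(
        effects, index=reporters, columns=[f"effect_{t:g}" for t in tps]
    )
    truth["regulated"] = (effects != 0.0).any(axis=1)
    sign_const = np.all(effects > 0, axis=1) | np.all(effects < 0, axis=1)
    truth["persistent"] = sign_const

    # --- measurements ---------------------------------------------------
    n_arrays = len(design)
    shape = (config.n_reporters, n_arrays)
    beta = rng["baseline"].normal(0.0, config.baseline_sd, size=config.n_reporters)
    A = np.clip(rng["intensity"].normal(10.0, 1.7, size=shape), 6.0, 16.0)
    eps = (
        rng["noise"].normal(0.0, config.noise_sd, size=shape)
        if config.noise_sd > 0
        else np.zeros(shape)
    )
    tcol = {t: j for j, t in enumerate(tps)}
    mu = np.tile(beta[:, None], (1, n_arrays))
    for j, (aid, row) in enumerate(design.iterrows()):
        if row["condition"] == "depleted":
            mu[:, j] += effects[:, tcol[row["time"]]]
    M = mu + _bias(A, config.bias_coeffs) + eps
    confident = rng["confidence"].random(shape) >= config.low_confidence_rate

    dataset = ExpressionDataset(
        M=pd.DataFrame(M, index=reporters, columns=design.index),
        A=pd.DataFrame(A, index=reporters, columns=design.index),
        confidence=pd.DataFrame(confident, index=reporters, columns=design.index),
        design=design,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# promoters


def _random_sequences(rng, ids, length: int, gc: float) -> dict:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    draws = rng.choice(4, size=(len(ids), length), p=p)
    return {g: "".join(bases[row]) for g, row in zip(ids, draws)}


def _realize(rng, consensus: str) -> str:
    return "".join(rng.choice(list(IUPAC[ch])) for ch in consensus.upper())


def simulate_promoter_set(
    foreground_ids,
    n_background: int,
    planted,
    length: int = 2000,
    gc: float = 0.5,
    seed: int = 0,
) -> tuple[PromoterSet, pd.DataFrame]:
    """Random promoters with motif sites planted at known positions.

    Parameters
    ----------
    foreground_ids : gene ids of the regulated list.
    n_background : number of additional control-cohort promoters
        (ids ``bg00000``...).
    planted : iterable of (motif, foreground presence fraction, background
        presence fraction); each selected gene receives one concrete
        realisation of the IUPAC consensus at a uniform plus-strand
        position.  ``round(frac * n)`` genes are selected per cohort.
    gc : GC content of the random background sequence.

    Returns the promoter set and a truth table (gene, motif, position,
    strand) of planted sites; random background matches are of course not
    listed there.
    """
    fg = list(foreground_ids)
    bg = [f"bg{i:05d}" for i in range(n_background)]
    rng = _rngs(seed)["promoters"]
    planted = [
        (m if isinstance(m, MotifPattern) else MotifPattern(*m), f1, f2)
        for m, f1, f2 in planted
    ]
    for motif, f1, f2 in planted:
        if len(motif.consensus) > length:
            raise ConfigurationError(
                f"motif {motif.name!r} longer than promoter length {length}"
            )
        if not (0 <= f1 <= 1 and 0 <= f2 <= 1):
            raise ConfigurationError("presence fractions must be in [0, 1]")
    seqs = _random_sequences(rng, fg + bg, length, gc)
    truth_rows = []
    for motif, f_fg, f_bg in planted:
        w = len(motif.consensus)
        for cohort, frac in ((fg, f_fg), (bg, f_bg)):
            n_plant = int(round(frac * len(cohort)))
            chosen = rng.choice(len(cohort), size=n_plant, replace=False)
            for i in chosen:
                g = cohort[i]
                pos = int(rng.integers(0, length - w + 1))
                site = _realize(rng, motif.consensus)
                s = seqs[g]
                seqs[g] = s[:pos] + site + s[pos + w :]
                truth_rows.append((g, motif.name, pos + 1, "+"))
    truth = pd.DataFrame(truth_rows, columns=["gene", "motif", "position", "strand"])
    return PromoterSet(sequences=seqs, window=length), truth


# ---------------------------------------------------------------------------
# annotation terms


def simulate_annotation_table(
    n_genes: int,
    n_terms: int,
    planted=(),
    term_size_range: tuple = (5, 50),
    seed: int = 0,
) -> tuple[dict, list]:
    """Random gene->term table with exactly reproduced planted overlaps.

    ``planted`` entries are (term name, term size, gene list, overlap):
    the emitted term contains exactly ``overlap`` genes drawn from the
    gene list and ``term size - overlap`` genes from outside it.  Random
    terms draw their members uniformly, so under the null every
    list/term overlap is hypergeometric.

    Returns (term_map, universe) where universe is the gene-id list.
    """
    universe = [f"g{i:05d}" for i in range(n_genes)]
    rng = _rngs(seed)["annotation"]
    lo, hi = term_size_range
    if n_terms > 0 and not 1 <= lo <= hi <= n_genes:
        raise ConfigurationError(f"term_size_range {term_size_range} invalid for {n_genes} genes")
    term_map: dict[str, set] = {}
    for j in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(n_genes, size=size, replace=False)
        term_map[f"term{j:04d}"] = {universe[i] for i in members}
    for name, size, gene_list, overlap in planted:
        gene_list = list(gene_list)
        outside = sorted(set(universe) - set(gene_list))
        if overlap > len(gene_list) or overlap > size or size - overlap > len(outside):
            raise ConfigurationError(
                f"planted term {name!r}: overlap {overlap} impossible for size {size}"
            )
        inside = rng.choice(gene_list, size=overlap, replace=False)
        rest = rng.choice(outside, size=size - overlap, replace=False)
        term_map[name] = set(inside) | set(rest)
    return term_map, universe


# ---------------------------------------------------------------------------
# interaction edges


def simulate_interaction_table(
    nodes,
    extra_nodes: int = 0,
    edge_density: float = 0.1,
    directed_fraction: float = 0.5,
    allow_self_loops: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Random curated-style edge table over ``nodes`` plus decoys.

    Each unordered node pair receives an edge with probability
    ``edge_density``; edges get a uniform interaction type and are
    directed with probability ``directed_fraction``.
    """
    if not 0.0 <= edge_density <= 1.0:
        raise ConfigurationError(f"edge_density must be in [0, 1], got {edge_density}")
    all_nodes = list(nodes) + [f"decoy{i:04d}" for i in range(extra_nodes)]
    rng = _rngs(seed)["edges"]
    rows = []
    for i, u in enumerate(all_nodes):
        start = i if allow_self_loops else i + 1
        for v in all_nodes[start:]:
            if rng.random() < edge_density:
                etype = EDGE_TYPES[rng.integers(0, len(EDGE_TYPES))]
                directed = bool(rng.random() < directed_fraction)
                rows.append((u, v, etype, directed))
    return pd.DataFrame(rows, columns=["source", "target", "type", "directed"])
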