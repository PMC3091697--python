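"""Promoter windows, IUPAC motif scanning, and TFBS frequency testing.

The question asked here: among genes regulated by zinc depletion, is the
fraction of promoters (2000 bp upstream of the translation start) that
carry at least one binding-site motif for a given transcription factor
different from that fraction in a cohort of never-regulated genes?  The
comparison is a pooled two-proportion z-test, two-sided, at alpha 0.05.

Motifs are IUPAC consensus strings supplied by the user (binding-site
collections such as Transfac are proprietary and are not shipped; a
demonstration motif file, including a synthetic MRE-like consensus, is
packaged for the examples).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .preprocess import ConfigurationError

DEFAULT_WINDOW = 2000
DEFAULT_CONTROL_COHORT_SIZE = 198
DEFAULT_ALPHA = 0.05

#: IUPAC nucleotide codes -> the explicit base set each matches.  A subject
#: base outside ACGT (an N in the assembly) matches nothing, not even
#: pattern N, so the subject side is never expanded.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/IUPAC string (case-insensitive, upper out)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """A named transcription-factor binding-site consensus."""

    name: str
    consensus: str

    def __post_init__(self) -> None:
        c = self.consensus.upper()
        if not c or any(ch not in IUPAC for ch in c):
            raise ConfigurationError(
                f"motif {self.name!r}: consensus must be non-empty IUPAC, got {self.consensus!r}"
            )
        object.__setattr__(self, "consensus", c)

    def regex(self) -> re.Pattern:
        # lookahead so overlapping occurrences are all counted
        body = "".join(f"[{IUPAC[ch]}]" for ch in self.consensus)
        return re.compile(f"(?=({body}))")


@dataclass
class PromoterSet:
    """Upstream sequences keyed by gene id, 5'->3' relative to each gene."""

    sequences: dict  # gene id -> str
    window: int = DEFAULT_WINDOW
    truncated: dict = field(default_factory=dict)  # gene id -> bool
    errors: dict = field(default_factory=dict)  # gene id -> message

    def __post_init__(self) -> None:
        for g, s in self.sequences.items():
            if len(s) > self.window:
                raise ConfigurationError(f"{g}: sequence longer than window")
            self.truncated.setdefault(g, len(s) < self.window)


def extract_upstream(genes: pd.DataFrame, genome, window: int = DEFAULT_WINDOW) -> PromoterSet:
    """Extract the upstream window for each gene from a genome.

    Parameters
    ----------
    genes : DataFrame with columns gene, contig, start, strand; ``start``
        is the 1-based first base of the translation start codon and
        strand is '+' or '-'.
    genome : mapping contig -> sequence (plain dict of strings or a
        ``pyfaidx.Fasta``).

    A plus-strand gene with start s yields genomic bases [s-window, s-1];
    a minus-strand gene yields [s+1, s+window] reverse-complemented.
    Windows are truncated at contig edges (flagged); per-gene problems are
    recorded in ``errors`` instead of raising.
    """
    seqs: dict[str, str] = {}
    errors: dict[str, str] = {}
    truncated: dict[str, bool] = {}
    for row in genes.itertuples(index=False):
        gid, contig, start, strand = row.gene, row.contig, int(row.start), row.strand
        try:
            if contig not in genome:
                raise KeyError(f"contig {contig!r} not in genome")
            contig_seq = str(genome[contig][:]).upper()
            L = len(contig_seq)
            if not 1 <= start <= L:
                raise ValueError(f"start {start} outside contig of length {L}")
            if strand == "+":
                lo = max(1, start - window)
                seq = contig_seq[lo - 1 : start - 1]
            elif strand == "-":
                hi = min(L, start + window)
                seq = reverse_complement(contig_seq[start : hi])
            else:
                raise ValueError(f"strand must be + or -, got {strand!r}")
            seqs[gid] = seq
            truncated[gid] = len(seq) < window
        except (KeyError, ValueError) as exc:
            errors[gid] = str(exc)
    return PromoterSet(sequences=seqs, window=window, truncated=truncated, errors=errors)


@dataclass
class ScanResult:
    """Per-gene match counts and 1-based positions for one motif.

    Minus-strand positions are on the reverse-complemented promoter.
    """

    motif: str
    plus: dict  # gene -> count
    minus: dict
    positions: dict  # gene -> {'+': [pos...], '-': [pos...]}

    def presence(self, gene) -> bool:
        return self.plus.get(gene, 0) + self.minus.get(gene, 0) > 0

    @property
    def genes_with_site(self) -> set:
        return {g for g in self.plus if self.presence(g)}


def scan_promoters(
    promoters: PromoterSet, motif: MotifPattern, strands: str = "both"
) -> ScanResult:
    """Count all (overlapping) IUPAC-consensus matches per promoter.

    ``strands`` is 'both', '+', or '-'; the minus strand is scanned as the
    reverse complement of the promoter sequence.
    """
    if strands not in ("both", "+", "-"):
        raise ConfigurationError(f"strands must be both/+/-, got {strands!r}")
    rx = motif.regex()
    plus: dict = {}
    minus: dict = {}
    positions: dict = {}
    for gene, seq in promoters.sequences.items():
        seq = seq.upper()
        pos: dict[str, list[int]] = {"+": [], "-": []}
        if strands in ("both", "+"):
            pos["+"] = [m.start() + 1 for m in rx.finditer(seq)]
        if strands in ("both", "-"):
            pos["-"] = [m.start() + 1 for m in rx.finditer(reverse_complement(seq))]
        plus[gene], minus[gene] = len(pos["+"]), len(pos["-"])
        positions[gene] = pos
    return ScanResult(motif=motif.name, plus=plus, minus=minus, positions=positions)


@dataclass
class TfbsComparison:
    """Foreground-vs-background presence comparison for one motif."""

    motif: str
    n1: int
    x1: int
    n2: int
    x2: int
    p1: float
    p2: float
    z: float
    p: float
    significant: bool
    alpha: float = DEFAULT_ALPHA


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z statistic and two-sided normal p.

    z = (p1 - p2) / sqrt(pbar (1-pbar) (1/n1 + 1/n2)), no continuity
    correction.  Degenerate pooled proportion (0 or 1) gives z=0, p=1.
    """
    if n1 < 1 or n2 < 1:
        raise ConfigurationError("cohort sizes must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ConfigurationError("counts must satisfy 0 <= x <= n")
    pbar = (x1 + x2) / (n1 + n2)
    if pbar in (0.0, 1.0):
        return 0.0, 1.0
    se = np.sqrt(pbar * (1.0 - pbar) * (1.0 / n1 + 1.0 / n2))
    z = (x1 / n1 - x2 / n2) / se
    return float(z), float(2.0 * norm.sf(abs(z)))


def compare_tfbs_frequency(
    foreground: ScanResult,
    background: ScanResult,
    alpha: float = DEFAULT_ALPHA,
) -> TfbsComparison:
    """Test whether motif presence differs between regulated and control genes.

    Presence means >= 1 site on either scanned strand; the tested quantity
    is the fraction of genes with presence, not the site count.
    """
    n1, n2 = len(foreground.plus), len(background.plus)
    if n1 == 0 or n2 == 0:
        raise ConfigurationError("both cohorts must be non-empty")
    x1 = sum(foreground.presence(g) for g in foreground.plus)
    x2 = sum(background.presence(g) for g in background.plus)
    z, p = two_proportion_z(x1, n1, x2, n2)
    return TfbsComparison(
        motif=foreground.motif,
        n1=n1, x1=x1, n2=n2, x2=x2,
        p1=x1 / n1, p2=x2 / n2,
        z=z, p=p, significant=bool(p < alpha), alpha=alpha,
    )


def select_control_cohort(
    all_genes, regulated, size: int = DEFAULT_CONTROL_COHORT_SIZE, seed: int = 0
) -> set:
    """Uniform sample (without replacement) of never-regulated genes."""
    pool = sorted(set(all_genes) - set(regulated))
    if len(pool) < size:
        raise ConfigurationError(
            f"only {len(pool)} never-regulated genes available, need {size}"
        )
    rng = np.random.default_rng(seed)
    return set(rng.choice(pool, size=size, replace=False)) if size else set()
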