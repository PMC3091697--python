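"""Promoter extraction coordinates, IUPAC scanning, and the z comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from gillzinc.preprocess import ConfigurationError
from gillzinc.tfbs import (
    IUPAC,
    MotifPattern,
    PromoterSet,
    ScanResult,
    compare_tfbs_frequency,
    extract_upstream,
    reverse_complement,
    scan_promoters,
    select_control_cohort,
    two_proportion_z,
)


def naive_scan(seq: str, consensus: str) -> list:
    """Oracle: slide a window and compare each position against the
    explicit character sets of the pattern."""
    seq = seq.upper()
    w = len(consensus)
    hits = []
    for i in range(len(seq) - w + 1):
        if all(seq[i + j] in IUPAC[c] for j, c in enumerate(consensus.upper())):
            hits.append(i + 1)
    return hits


def _genome():
    rng = np.random.default_rng(0)
    chrom = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=8000)])
    return {"chr1": chrom}


def _gene_table(rows):
    return pd.DataFrame(rows, columns=["gene", "contig", "start", "strand"])


class TestExtractUpstream:
    def test_plus_strand_window(self):
        genome = _genome()
        out = extract_upstream(_gene_table([("g", "chr1", 5001, "+")]), genome)
        assert out.sequences["g"] == genome["chr1"][3000:5000]
        assert not out.truncated["g"]

    def test_minus_strand_window_is_reverse_complement(self):
        genome = _genome()
        out = extract_upstream(_gene_table([("g", "chr1", 5000, "-")]), genome)
        assert out.sequences["g"] == reverse_complement(genome["chr1"][5000:7000])

    def test_left_truncation_at_contig_start(self):
        genome = _genome()
        out = extract_upstream(_gene_table([("g", "chr1", 1500, "+")]), genome)
        assert out.sequences["g"] == genome["chr1"][:1499]
        assert out.truncated["g"]

    def test_bad_rows_become_error_records_not_crashes(self):
        out = extract_upstream(
            _gene_table(
                [("a", "chrX", 100, "+"), ("b", "chr1", 999999, "+"), ("c", "chr1", 3000, "+")]
            ),
            _genome(),
        )
        assert set(out.errors) == {"a", "b"}
        assert "c" in out.sequences

    def test_pyfaidx_genome_accepted(self, tmp_path):
        import pyfaidx

        from gillzinc.io import write_genome_fasta

        genome = _genome()
        path = tmp_path / "genome.fa"
        write_genome_fasta(genome, path)
        fa = pyfaidx.Fasta(str(path))
        out = extract_upstream(_gene_table([("g", "chr1", 5001, "+")]), fa)
        assert out.sequences["g"] == genome["chr1"][3000:5000]


class TestScanner:
    def test_direct_inspection_example(self):
        res = scan_promoters(PromoterSet({"g": "TTGCATGCA"}, window=9),
                             MotifPattern("m", "TGCA"), strands="+")
        assert res.positions["g"]["+"] == [2, 6]

    def test_overlapping_matches_counted(self):
        res = scan_promoters(PromoterSet({"g": "AAA"}, window=3),
                             MotifPattern("m", "AA"), strands="+")
        assert res.plus["g"] == 2

    def test_iupac_expansion(self):
        res = scan_promoters(PromoterSet({"g": "TGCACTC"}, window=7),
                             MotifPattern("m", "TGCRCNC"), strands="+")
        assert res.plus["g"] == 1

    def test_subject_n_never_matches(self):
        res = scan_promoters(PromoterSet({"g": "ANA"}, window=3),
                             MotifPattern("m", "ANA"), strands="+")
        assert res.plus["g"] == 0

    def test_strand_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=80)])
            motif = "".join(
                np.array(list(IUPAC))[rng.integers(0, len(IUPAC), size=6)]
            )
            fwd = scan_promoters(PromoterSet({"g": seq}, window=80),
                                 MotifPattern("m", motif), strands="+")
            rc = scan_promoters(
                PromoterSet({"g": reverse_complement(seq)}, window=80),
                MotifPattern("m", reverse_complement(motif)), strands="+",
            )
            assert fwd.plus["g"] == rc.plus["g"]

    def test_matches_naive_oracle_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            seq = "".join(np.array(list("ACGTN"))[rng.integers(0, 5, size=120)])
            motif = "".join(np.array(list(IUPAC))[rng.integers(0, 15, size=5)])
            res = scan_promoters(PromoterSet({"g": seq}, window=120),
                                 MotifPattern("m", motif))
            assert res.positions["g"]["+"] == naive_scan(seq, motif)
            assert res.positions["g"]["-"] == naive_scan(reverse_complement(seq), motif)

    def test_invalid_consensus_rejected(self):
        with pytest.raises(ConfigurationError):
            MotifPattern("m", "ACGU")
        with pytest.raises(ConfigurationError):
            MotifPattern("m", "")


class TestTwoProportionZ:
    def test_hand_evaluated_cohort_example(self):
        z, p = two_proportion_z(3, 26, 3, 198)
        assert z == pytest.approx(2.98, abs=0.01)
        assert p == pytest.approx(0.003, abs=5e-4)

    def test_equal_proportions(self):
        z, p = two_proportion_z(5, 10, 10, 20)
        assert z == 0.0 and p == 1.0

    def test_degenerate_pooled_proportion(self):
        assert two_proportion_z(26, 26, 198, 198) == (0.0, 1.0)
        assert two_proportion_z(0, 26, 0, 198) == (0.0, 1.0)

    def test_z_squared_equals_pearson_chi_square(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n1, n2 = int(rng.integers(5, 200)), int(rng.integers(5, 200))
            x1, x2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            if x1 + x2 in (0, n1 + n2):
                continue
            z, _ = two_proportion_z(x1, n1, x2, n2)
            table = [[x1, n1 - x1], [x2, n2 - x2]]
            chi2 = chi2_contingency(table, correction=False)[0]
            assert z**2 == pytest.approx(chi2, abs=1e-10)

    def test_zero_cohort_errors(self):
        with pytest.raises(ConfigurationError):
            two_proportion_z(0, 0, 1, 10)


class TestComparison:
    @staticmethod
    def _scan(counts):
        return ScanResult(
            motif="m",
            plus=dict(counts),
            minus={g: 0 for g in counts},
            positions={g: {"+": [], "-": []} for g in counts},
        )

    def test_presence_not_count_is_compared(self):
        fg = self._scan({"a": 7, "b": 0})
        bg = self._scan({"c": 1, "d": 0})
        cmp_ = compare_tfbs_frequency(fg, bg)
        assert (cmp_.x1, cmp_.n1, cmp_.x2, cmp_.n2) == (1, 2, 1, 2)
        assert not cmp_.significant

    def test_significance_at_alpha(self):
        fg = self._scan({f"f{i}": 1 for i in range(20)})
        bg = self._scan({f"b{i}": (1 if i < 2 else 0) for i in range(100)})
        cmp_ = compare_tfbs_frequency(fg, bg, alpha=0.05)
        assert cmp_.significant and cmp_.p < 0.05


class TestControlCohort:
    def test_pool_exactly_size_returns_whole_pool(self):
        pool = {f"g{i}" for i in range(10)}
        out = select_control_cohort(pool | {"reg"}, {"reg"}, size=10, seed=1)
        assert out == pool

    def test_size_zero_is_empty(self):
        assert select_control_cohort({"a", "b"}, set(), size=0, seed=1) == set()

    def test_seeded_reproducibility_and_exclusion(self):
        genes = {f"g{i}" for i in range(300)}
        reg = {f"g{i}" for i in range(50)}
        a = select_control_cohort(genes, reg, size=198, seed=4)
        b = select_control_cohort(genes, reg, size=198, seed=4)
        assert a == b and len(a) == 198 and not (a & reg)

    def test_insufficient_pool_errors(self):
        with pytest.raises(ConfigurationError):
            select_control_cohort({"a", "b"}, {"a"}, size=5, seed=0)
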