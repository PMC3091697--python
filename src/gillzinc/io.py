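"""Readers and writers for the pipeline's plain-text formats.

Canonical dialects: TSV with a header row for all tables (empty field or
"NA" both read as missing), FASTA at 60 columns for promoters, GMT-like
text (term TAB description TAB gene...) for annotation tables, one
"name TAB IUPAC" line per motif, and JSON for summaries.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .preprocess import ConfigurationError, ExpressionDataset
from .tfbs import MotifPattern, PromoterSet

_NA = ["", "NA"]


def _read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=_NA, keep_default_na=True)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA")


def write_expression_dataset(dataset: ExpressionDataset, outdir, prefix: str = "sim") -> dict:
    """Write M/A/confidence/design TSVs; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "m": outdir / f"{prefix}_log_ratios.tsv",
        "a": outdir / f"{prefix}_intensities.tsv",
        "confidence": outdir / f"{prefix}_confidence.tsv",
        "design": outdir / f"{prefix}_design.tsv",
    }
    write_matrix(dataset.M, paths["m"])
    write_matrix(dataset.A, paths["a"])
    write_matrix(dataset.confidence.astype(int), paths["confidence"])
    dataset.design.to_csv(paths["design"], sep="\t")
    return {k: str(v) for k, v in paths.items()}


def read_expression_dataset(m_path, a_path, confidence_path, design_path) -> ExpressionDataset:
    M = _read_matrix(m_path)
    A = _read_matrix(a_path)
    conf = _read_matrix(confidence_path).astype(bool)
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    design["time"] = design["time"].astype(float)
    return ExpressionDataset(M=M, A=A, confidence=conf, design=design)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    out = pd.read_csv(path, sep="\t", na_values=_NA)
    out["called"] = out["called"].astype(bool)
    return out


def write_promoters(promoters: PromoterSet, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene, description="")
        for gene, seq in promoters.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_promoters(path, window: int) -> PromoterSet:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return PromoterSet(sequences=seqs, window=window)


def write_genome_fasta(contigs: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def demo_motifs_path() -> Path:
    """Path of the packaged synthetic demonstration motif file."""
    return Path(__file__).parent / "data" / "demo_motifs.tsv"


def read_motifs(path) -> list:
    """Parse a motif file: one 'name TAB IUPAC-consensus' per line, # comments."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ConfigurationError(f"{path}:{lineno}: expected 'name<TAB>consensus'")
        out.append(MotifPattern(parts[0], parts[1]))
    return out


def write_motifs(motifs, path) -> None:
    Path(path).write_text("".join(f"{m.name}\t{m.consensus}\n" for m in motifs))


def write_gmt(term_map: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for term in sorted(term_map):
            desc = (descriptions or {}).get(term, "na")
            genes = "\t".join(sorted(term_map[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


def read_gmt(path) -> dict:
    term_map: dict[str, set] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ConfigurationError(f"{path}:{lineno}: GMT rows need term, description, genes")
        term_map[parts[0]] = set(parts[2:])
    return term_map


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(set(genes))))


def read_gene_list(path) -> set:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_edges(path) -> pd.DataFrame:
    out = pd.read_csv(path, sep="\t", na_values=_NA)
    out["directed"] = out["directed"].astype(bool)
    return out


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, tuple)):
            return sorted(o) if isinstance(o, set) else list(o)
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="index")
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
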