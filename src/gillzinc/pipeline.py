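"""End-to-end driver: preprocess -> DE -> enrichment -> TFBS -> network.

The pipeline reads the plain-text inputs, runs each enabled stage in the
order the analysis dictates, and writes a report bundle (call table,
temporal summary, enrichment table, TFBS comparison table, network files,
run log) into one output directory.  Any stage failure aborts with a
stage-named error and the run log marked incomplete.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__, diffexpr, enrich, io, network, preprocess, tfbs

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and toggles for one pipeline run.

    Threshold defaults are the study's constants: fold change 1.8,
    FDR 0.1, alpha 0.05, 2000 bp promoter window, 198 control genes,
    3 replicates minimum.
    """

    # expression inputs (required)
    m_path: str = ""
    a_path: str = ""
    confidence_path: str = ""
    design_path: str = ""
    # optional stage inputs
    term_table_path: str | None = None
    promoters_path: str | None = None
    motifs_path: str | None = None
    edges_path: str | None = None
    seed_nodes: tuple = ("Zn", "Mtf1")
    # thresholds
    fc_threshold: float = diffexpr.DEFAULT_FC_THRESHOLD
    fdr_threshold: float = diffexpr.DEFAULT_FDR_THRESHOLD
    alpha: float = tfbs.DEFAULT_ALPHA
    window: int = tfbs.DEFAULT_WINDOW
    control_cohort_size: int = tfbs.DEFAULT_CONTROL_COHORT_SIZE
    min_replicates: int = preprocess.DEFAULT_MIN_REPLICATES
    lowess_span: float = preprocess.DEFAULT_LOWESS_SPAN
    skip_lowess: bool = False
    enrichment_mode: str = "ease"
    seed: int = 0
    outdir: str = "results"
    # stage toggles; None = run iff inputs provided
    run_enrich: bool | None = None
    run_tfbs: bool | None = None
    run_network: bool | None = None

    def validate(self) -> None:
        for thr in ("fc_threshold", "fdr_threshold", "alpha", "lowess_span"):
            if getattr(self, thr) <= 0:
                raise PipelineError(f"stage config: {thr} must be positive")
        for stage, paths in {
            "preprocess": [self.m_path, self.a_path, self.confidence_path, self.design_path],
            "enrich": [self.term_table_path] if self._enabled("enrich") else [],
            "tfbs": [self.promoters_path, self.motifs_path] if self._enabled("tfbs") else [],
            "network": [self.edges_path] if self._enabled("network") else [],
        }.items():
            for p in paths:
                if not p or not Path(p).exists():
                    raise PipelineError(f"stage {stage}: required input missing ({p!r})")

    def _enabled(self, stage: str) -> bool:
        toggle = getattr(self, f"run_{stage}")
        if toggle is not None:
            return toggle
        inputs = {
            "enrich": [self.term_table_path],
            "tfbs": [self.promoters_path, self.motifs_path],
            "network": [self.edges_path],
        }[stage]
        return all(inputs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every enabled stage; returns the report-bundle path map."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"outdir": str(outdir)}
    runlog: dict = {
        "tool": "gillzinc",
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": {},
        "complete": False,
    }
    logpath = outdir / "run_log.json"

    def _stage(name, fn):
        try:
            result = fn()
        except Exception as exc:
            runlog["stages"][name] = f"failed: {exc}"
            io.write_json(runlog, logpath)
            raise PipelineError(f"stage {name}: {exc}") from exc
        runlog["stages"][name] = "ok"
        return result

    # --- preprocess -----------------------------------------------------
    def _preprocess():
        ds = io.read_expression_dataset(
            config.m_path, config.a_path, config.confidence_path, config.design_path
        )
        if not config.skip_lowess:
            ds = preprocess.normalize_dataset(ds, span=config.lowess_span)
            for aid in ds.M.columns:
                log.info("array %s: lowess-normalized, median M %.4f", aid, ds.M[aid].median())
        return preprocess.filter_expressed(ds, min_replicates=config.min_replicates)

    dataset = _stage("preprocess", _preprocess)

    # --- differential expression ---------------------------------------
    def _de():
        calls = diffexpr.call_regulated(
            dataset, fc_threshold=config.fc_threshold, fdr_threshold=config.fdr_threshold
        )
        summary = diffexpr.temporal_summary(calls)
        io.write_calls(calls, outdir / "de_calls.tsv")
        io.write_json(
            {
                "per_time": summary.per_time,
                "pct_up": summary.pct_up,
                "pct_down": summary.pct_down,
                "persistent": summary.persistent,
            },
            outdir / "temporal_summary.json",
        )
        return calls, summary

    calls, summary = _stage("diffexpr", _de)
    bundle["calls"] = str(outdir / "de_calls.tsv")
    bundle["summary"] = str(outdir / "temporal_summary.json")
    regulated = sorted(calls.loc[calls["called"], "reporter"].unique())
    io.write_gene_list(regulated, outdir / "regulated_genes.txt")

    # --- enrichment -----------------------------------------------------
    if config._enabled("enrich"):
        def _enrich():
            term_map = io.read_gmt(config.term_table_path)
            background = sorted(set().union(*(set(v) for v in dataset.retained.values())))
            genes = sorted(set(regulated) & set(background))
            table = enrich.fisher_enrichment(
                genes, background, term_map, mode=config.enrichment_mode
            )
            table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            return table

        _stage("enrich", _enrich)
        bundle["enrichment"] = str(outdir / "enrichment.tsv")

    # --- TFBS -----------------------------------------------------------
    if config._enabled("tfbs"):
        def _tfbs():
            promoters = io.read_promoters(config.promoters_path, window=config.window)
            motifs = io.read_motifs(config.motifs_path)
            fg_ids = [g for g in regulated if g in promoters.sequences]
            if not fg_ids:
                raise ValueError("no regulated gene has a promoter sequence")
            cohort = tfbs.select_control_cohort(
                promoters.sequences, regulated,
                size=config.control_cohort_size, seed=config.seed,
            )
            fg = tfbs.PromoterSet(
                {g: promoters.sequences[g] for g in fg_ids}, window=config.window
            )
            bg = tfbs.PromoterSet(
                {g: promoters.sequences[g] for g in sorted(cohort)}, window=config.window
            )
            rows, scan_rows = [], []
            for motif in motifs:
                fg_scan = tfbs.scan_promoters(fg, motif)
                bg_scan = tfbs.scan_promoters(bg, motif)
                cmp_ = tfbs.compare_tfbs_frequency(fg_scan, bg_scan, alpha=config.alpha)
                rows.append(asdict(cmp_))
                for cohort_name, scan in (("regulated", fg_scan), ("control", bg_scan)):
                    for g in scan.plus:
                        scan_rows.append(
                            (motif.name, cohort_name, g, scan.plus[g], scan.minus[g])
                        )
            pd.DataFrame(rows).to_csv(outdir / "tfbs_comparison.tsv", sep="\t", index=False)
            pd.DataFrame(
                scan_rows, columns=["motif", "cohort", "gene", "plus", "minus"]
            ).to_csv(outdir / "tfbs_scans.tsv", sep="\t", index=False)

        _stage("tfbs", _tfbs)
        bundle["tfbs"] = str(outdir / "tfbs_comparison.tsv")

    # --- network --------------------------------------------------------
    if config._enabled("network"):
        def _network():
            edges = io.read_edges(config.edges_path)
            net = network.build_direct_interaction_network(
                regulated, config.seed_nodes, edges
            )
            hubs = network.rank_hubs(net)
            hubs.to_csv(outdir / "network_hubs.tsv", sep="\t", index=False)
            pd.DataFrame(
                net.edges, columns=["source", "target", "type", "directed"]
            ).to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
            pd.DataFrame(
                {"node": sorted(net.nodes), "isolated": [n in net.isolated for n in sorted(net.nodes)]}
            ).to_csv(outdir / "network_nodes.tsv", sep="\t", index=False)
            network.export_graphml(net, outdir / "network.graphml")

        _stage("network", _network)
        bundle["network"] = str(outdir / "network_hubs.tsv")

    runlog["complete"] = True
    io.write_json(runlog, logpath)
    bundle["run_log"] = str(logpath)
    return bundle
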