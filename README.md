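# gillzinc

Time-course transcriptomics of the zebrafish gill under zinc depletion, as a
tested, reusable pipeline.  The gill is the tissue through which fish take up
zinc directly from water, and its response to a zinc-depleted environment is
a time-resolved cascade: two-channel (sample vs common reference) 16K
oligonucleotide arrays measured at 0.3, 1, 4, 7 and 14 days in quintuplicate,
in both depleted and control fish.  `gillzinc` implements the full analysis
chain for such data, for bioinformaticians who want each step as a tested
library function rather than a chain of GUI tools:

- **preprocess** — MA transform (M = log₂ R/G, A = ½(log₂ R + log₂ G)),
  per-array lowess normalization of M on A, per-spot confidence filtering,
  and the ≥ 3-replicates-per-group rule.
- **diffexpr** — per-time-point Welch t-tests, Benjamini–Hochberg adjustment
  within each time point, signed fold change (FC = +r for r ≥ 1, −1/r
  otherwise), the calling rule |FC| > 1.8 ∧ q < 0.1, and temporal summaries
  (up/down counts per day, direction-persistent genes).
- **enrich** — one-sided hypergeometric term enrichment with the
  conservative EASE (k−1) variant and BH correction across terms.
- **tfbs** — 2000 bp upstream-of-ATG promoter extraction, overlapping IUPAC
  consensus scanning on both strands, and the pooled two-proportion z-test
  of motif presence in regulated genes vs a 198-gene never-regulated cohort.
- **network** — direct-interaction network as the induced subgraph of a
  curated edge table on regulated genes plus seed nodes (Zn, Mtf1), with
  unique-neighbour hub ranking.
- **physiology** — unidirectional zinc influx J_in = cpm/(SA·bw·t) and
  standard-curve qPCR quantification normalised to 18s rRNA.
- **simdata** — a seeded generator that reproduces the study design (16,000
  reporters, 2 × 5 × 5 with one missing Day-4 control replicate, ~3%
  regulated, intensity-dependent dye bias) together with planted ground
  truth, so every stage is verifiable without any download.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data.  From the repository root:

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_normalize_filter.py
python analysis/03_differential_expression.py
```

which prints (seed 1):

```
dye-bias trend (worst per-A-decile |median M|, 6 arrays): 0.364 before lowess -> 0.035 after
      n_up  n_down  n_total
time
0.3      4       7       11
1.0     11       8       19
4.0      9      28       37
7.0     38     110      148
14.0     1       6        7
198 reporters called at >= 1 time point; 28.4% of called events up, 71.6% down
recovery vs planted truth: sensitivity 0.34, FDP 0.005 (222 called events, 654 planted)
```

Reading this: the cubic dye bias planted by the simulator (up to 0.36 log₂
units) is flattened to the noise floor by lowess; the calls rise to a Day-7
peak and subside by Day 14 with down-regulation dominating, mirroring the
design; and at the study's sparsity a planted 1.5-log₂ effect is a genuinely
hard target — about a third of planted events are recovered while the
false-discovery proportion stays well under the 10% the BH procedure
controls.  `04_enrichment.py` then lifts the planted annotation term to the
top of the EASE ranking (p ≈ 7 × 10⁻¹³), and `05_tfbs.py` flags exactly the
motif with a planted presence imbalance:

```
 * Hnf4a_fixture       12.7% vs   1.5%  z= +4.33  p=1.51e-05
```

i.e. 12.7% of regulated promoters carry the site against 1.5% of the
198-gene control cohort.  `06_network.py` and `07_physiology.py` complete
the chain (hub table; J_in and qPCR arithmetic).

The same operations are available as a CLI (`gillzinc simulate|normalize|
de|enrich|tfbs|network|influx|run`); `gillzinc run --config pipeline.cfg`
executes every stage from one key=value config file and writes a report
bundle with a machine-readable run log.

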