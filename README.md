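# famchar — gene-family characterization pipeline

`famchar` re-implements, as a tested Python library with a CLI, the standard
workflow for genome-wide characterization of a plant stress-protein gene
family — here the late embryogenesis-abundant (LEA) family of potato
(*Solanum tuberosum*), 74 genes in nine groups (LEA1–LEA6, ASR, DHN, SMP).
It is aimed at researchers who want each step of such a survey to be a
reproducible, unit-tested function rather than a chain of web tools:

* **Family assignment** — Pfam domain hits (PF03760, PF03168, PF03242,
  PF02987, PF00477, PF10714, PF02496, PF00257, PF04927 → the nine groups)
  filtered at e-value < 0.05; best hit wins, ties surfaced for curation.
* **Physicochemical profiling** — the five ProtParam descriptors per protein:
  average molecular weight, theoretical pI (bisection on the Bjellqvist
  charge model), instability index `(10/L)·Σ DIWV(x_i, x_{i+1})`, aliphatic
  index `X_A + 2.9·X_V + 3.9·(X_I + X_L)`, and GRAVY (mean Kyte–Doolittle
  hydropathy), plus family summaries.
* **Phylogeny** — p-distances with pairwise gap deletion, Poisson correction
  `d = −ln(1 − p)`, Saitou–Nei neighbour joining, bootstrap supports from
  column resampling (default 1000 replicates), and sister-pair (cherry)
  detection at support > 90%.
* **Duplication classification** — within-group pairs above 75% global
  alignment identity are *tandem* when on one chromosome within 100 kb with
  fewer than 10 intervening non-family genes, else *segmental* when the
  alignment covers > 80% of the longer sequence at > 70% identity.
* **Gene structure** — exon–intron models from exact-match spliced mapping of
  CDS onto genomic sequence; intron-count distributions.
* **Expression** — FPKM + 1e-5 pseudocount, `log2(treatment/control)` fold
  changes, square-root display transform, CV%, induced/inhibited calls at
  |log2FC| ≥ 1.
* **qPCR** — 2^−ΔCt relative quantification against a reference gene
  (default `StEF1a`), replicate mean ± sample SD.
* **Synthetic data** — seeded generators for family genomes (group-specific
  motifs including the dehydrin K-segment `EKGMMEKIKEKLPGHH`, planted tandem
  arrays and segmental pairs, planted introns), FPKM matrices and Ct tables,
  each with a machine-readable truth table.

The package ships `fixtures/table1.tsv` (also installed as
`famchar/data/table1.tsv`), a verbatim transcription of the published
74-member descriptor table, which drives the desk-scale reproduction of the
survey's summary statistics. Recomputing per-protein descriptors from raw
sequences additionally requires downloading them from Spud DB / Phytozome by
the accessions in that table (a manual step; see
`famchar.physchem.validate_against_table`).

## Worked example

```bash
python analysis/01_family_overview.py
```

prints

```
74 family genes in 9 groups; largest LEA2 = 45
mean MW 22.5 kDa (range 8.5-53.3)
mean pI 8.33; 73.0% above pH 7.0
10 proteins with GRAVY > 0, all in LEA2; 7 above 30 kDa
```

i.e. the family is small-protein (mean 22.5 kDa), predominantly basic
(mean pI 8.33; 73% above pH 7) and hydrophilic (only 10 of 74 GRAVY-positive,
all in LEA2). The remaining drivers exercise the inference stages on
synthetic genomes with known truth and report recovery:

```bash
python analysis/02_synthetic_genome_characterization.py  # classify + dupscan + introns
python analysis/03_phylogeny_sister_pairs.py             # NJ + 1000 bootstraps + cherries
python analysis/04_expression_qpcr_recovery.py           # fold changes + 2^-dCt
```

Each writes its tables and a JSON summary under `results/`. The same stages
are available as a CLI (`famchar classify|physchem|phylo|dupscan|structure|
expr|qpcr|simulate|run`); `famchar run --config run.cfg` executes the whole
characterization from one YAML config and writes a deterministic
`report.json`.

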