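# tcrshare

Analysis of **public T-cell receptor (TCR) CDR3 clones** shared within and
across species, for immunologists studying tumor-associated repertoire
convergence. The package implements the full chain from AIRR-style
clonotype tables to the headline questions:

- **Publicness** — a CDR3 amino-acid (AA) junction seen in ≥ 2 subjects is
  *public*; public clones found in both study groups are *inclusive*, those
  confined to one group *exclusive*. Do tumor-developing animals carry more
  exclusive public clones?
- **Convergent recombination (CR)** — the *CR level* of an AA junction is
  the number of distinct nucleotide (NT) junctions encoding it,
  CR(a) = |{n : translate(n) = a}|. Does public sharing rise with CR, and
  differently per group (likelihood-ratio test on nested Gaussian GLMs)?
- **Repertoire overlap** — Morisita–Horn index
  2·Σxᵢyᵢ / ((Σxᵢ²/X² + Σyᵢ²/Y²)·X·Y) between samples, and the weighted
  (Ruzicka) Jaccard Σmin(fₐ,f_b)/Σmax(fₐ,f_b) between mouse exclusive sets
  and human cohorts.
- **Cross-species metrics** — the rank-area metric
  1/(rank_mouse × rank_human) for clones ranked by copy number in both
  species; stage similarity = shared clones / (clones in sample × cases in
  stage); NT-origin bipartite graphs showing that the two species build the
  same AA junction from disjoint NT recombinations.
- **Sequence networks** — Levenshtein-distance neighborhoods and networks
  (≤ 2 edits for single chains, ≤ 3 summed edits for α-β pairs).
- **Single-cell pairing** — one α-β CDR3 pair per cell (multichain and
  incomplete cells dropped); a pair is shared with a bulk sample when both
  chains occur in that sample.

Because the underlying mouse sequencing data are not public, the package
ships a first-class synthetic-repertoire generator (`tcrshare.simulate`)
with planted ground truth — group-exclusive public clones, synonymous-codon
CR variants, cross-species AAs with species-disjoint NT encodings, a staged
human cohort with a stage-1-enriched sharing gradient, and plantable
single-cell pairs — so every pipeline stage is exercised against a known
answer.

## Layout

- `src/tcrshare/` — the library: `io` (AIRR TSV, pooling, subsampling),
  `simulate`, `publicness`, `cross_species`, `networks`, `single_cell`,
  `pipeline`, `cli`.
- `analysis/01…05_*.py` — numbered narrative drivers that run each stage on
  the synthetic study and write tables under `results/`.
- `tcrshare` console script — `simulate`, `classify`, `cr`, `run-all`
  subcommands over the same library.

## Worked example

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_publicness_cr.py --seed 1
```

prints (seed 1):

```
mouse samples: 160 (5 control + 5 case subjects, 8 timepoints, chains ('alpha', 'beta'))
planted public AAs: 222; cross-species AAs: 33
[beta] subsampled depth per subject: 9152 reads
[beta] mean exclusive-case fraction: case 0.084 vs control 0.000 (Welch p = 4.52e-05)
```

Each of the ten subjects was pooled across its eight timepoints and
subsampled to the same depth (9,152 β reads). On average 8.4 % of a
tumor-developing subject's unique clones are public clones exclusive to the
tumor group, versus 0 % in controls — recovering the planted 10 % vs 2 %
world (control-exclusive clones planted at 2 % of 300 ≈ 6 AAs mostly fall
below 2 carriers after the carrier draw). The Welch t-test puts the group
gap at p ≈ 5 × 10⁻⁵. Continuing with `analysis/03_cross_species.py` reports
33 cross-species AAs, a rank-area profile dominated by a clone ranked 1
(mouse) × 3 (human), and mean stage similarities 0.064 > 0.048 > 0.039 >
0.024 for stages i–iv, the planted monotone gradient.

## Acceptance script

`scripts/acceptance.py` recomputes, from freshly constructed samples, the
two self-contained worked-example values of the rank-area metric: a clone
with the top copy number in both species (ranks 1 × 1) and a clone ranked
last of 258 shared clones in both species, ranking each sample with
`rank_clones` and evaluating `cross_rank_area`:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
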