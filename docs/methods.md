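# Methods

## Data model and identity conventions

A clonotype (`Clone`) is keyed **by its nucleotide junction alone** within
a sample: rows sharing an NT junction are merged with summed copy numbers,
and V/J calls are kept as annotation sets. This matches the analytical
stance that a CDR3 AA sequence is the unit of biology while V-J context is
provenance — the same AA (and even the same NT) junction can arise from
several V-J pairings. The stored AA junction is the full IMGT junction
(conserved C…F included); nothing is trimmed.

Nonproductive rows — junction length not divisible by 3, or any stop codon
— are dropped at load time and tallied in a skip report, because every
downstream statistic is defined on productive AA junctions. Translation
uses the standard genetic code (Biopython).

## Pooling, subsampling, presence

Subject pools combine all timepoints of one subject and chain
(count-summed union). Equal-depth normalisation draws reads **without
replacement** (multivariate hypergeometric) — the standard rarefaction
model; sampling with replacement would inflate singleton loss. "Presence"
of an AA in a subject means summed copy number ≥ `min_count` (default 1)
in the subsampled pool. The subsample depth in the analysis drivers is 80 %
of the shallowest subject pool, keeping every subject while still
normalising; the depth is a parameter, not a constant.

## Publicness and convergent recombination

Labels partition all AAs exhaustively: *private* (1 subject),
*public-inclusive* (≥ 1 subject in each group), *public-exclusive* (≥ 2
subjects, one group only). Per-subject label fractions are reported under
two weightings — `unique` (each AA once; the default used in the figures
of record) and `total_reads` (copy-number weighted) — because both views
are informative and the choice changes the percentages.

The CR level of an AA is the count of distinct NT junctions encoding it in
the scope of interest (a sample, a subject pool, or a group of pools).
Conservation holds by construction: Σ over AAs of CR level = number of
distinct NT junctions in scope.

The sharing-vs-CR comparison builds, per group, the mean sharing level
(subjects carrying the AA) at each CR level and compares nested Gaussian
models `sharing ~ CR` vs `sharing ~ CR + group + CR×group` with a
likelihood-ratio statistic 2(ℓ₁−ℓ₀) against χ²(2). The model family is a
pragmatic choice: the response is a per-cell mean, not a count, and the
original description says only that generalized linear models were
compared. OLS log-likelihoods are exact for the Gaussian family.

## Overlap indices

- **Morisita–Horn** (abundance-based, bounded [0, 1], self = 1) is used for
  sample-sample overlap; the original count-based Morisita index is
  unbounded for small samples and was not chosen.
- **Weighted (Ruzicka) Jaccard** Σmin/Σmax over clone frequency vectors is
  the frequency-aware Jaccard generalisation used for mouse-exclusive-set
  vs human-cohort sharing at equal subsampled depth.
- Young/old epoch structure: timepoints 1–4 vs 5–8 (configurable); group ×
  epoch cells average all cross-bin sample pairs, excluding self-pairs.

## Cross-species metrics

- Ranking is competition ranking on descending copy number with
  **lexicographic tie-break**, so ranks are a deterministic dense
  permutation — required for reproducible rank areas.
- Rank-area metric: 1/(rank_mouse × rank_human) ∈ (0, 1], equal to 1 iff a
  clone tops both species; per-timepoint shares are areas normalised to
  sum to 1.
- Stage similarity: |AA(sample) ∩ AA(stage pool)| / (clones in sample ×
  cases in stage); stages with zero cases are excluded (division by zero).
- Highly abundant young/old selection: candidates must be present in
  ≥ `min_samples` samples of each epoch; significance is a two-sided Welch
  test on per-sample copy numbers **including zeros** for samples not
  carrying the clone (the alternative — conditioning on presence — biases
  against clones whose shift is partly in prevalence). α defaults to 0.05
  and is exposed.
- Resampling null: mean cohort frequency ("frequency" = summed copies of
  the AA across cohort samples / summed cohort depth) of the selected set
  vs `n_iter` uniform draws of equal size from the candidates; empirical
  p uses the +1 correction and is never exactly 0.
- The TCR-peptide binding scorer is an interface (callable or lookup
  table); no binding model is trained or shipped.

## Sequence networks

Levenshtein distance (unit-cost insert/delete/substitute, two-row DP,
oracle-checked against a full-matrix DP). Neighborhoods count pool
sequences within `d_max` edits of a focal, excluding the focal itself;
random baselines draw uniformly from the pool excluding the focal set.
Distance networks connect nodes at distance ∈ [1, d_max]; copy numbers are
node attributes, never edge weights. For α-β pairs the default distance is
the **sum** of the per-chain distances with d_max = 3 (a per-chain mode is
available; the summed reading was chosen as the stricter interpretation of
"up to 3 different AA between two pairs").

## Synthetic world

Defaults state the emulated design: 5 control + 5 case subjects × 8
timepoints × 2 chains, 300 clones per sample, Zipf(2.0) copy numbers
(heavy-tailed, distribution unspecified in the source data, capped at
10⁴), planted fractions 10 % exclusive-case / 2 % exclusive-control / 25 %
inclusive (public clones occupying ~35–40 % of a repertoire), CR variants
per public AA ~ 1 + Poisson(cr_variants_mean − 1) synonymous-codon
re-encodings (mean 1.5), and a per-subject carrier probability of 0.8
re-drawn so exclusives always reach ≥ 2 carriers in their group (this is
what makes per-subject fractions vary, so group tests have variance; set
1.0 for noiseless exact recovery). Human cohorts inject 30 % of the public
mouse β AAs through freshly drawn NT encodings rejected against the mouse
NT set — cross-species AAs therefore have **exactly disjoint** NT origins.
The staged cohort shares a geometric gradient of the mouse public pool,
stage i 4× stage iv. Single-cell tables plant matchable pairs from the
inclusive pools and a configurable multichain fraction.

What the generator does **not** emulate: V-D-J recombination statistics
(junctions are uniform random AA cores, so edit-distance neighborhoods are
empty at realistic lengths — network tests plant their own clusters),
thymic selection, sequencing error, and chance AA collisions between
private clones (junction strings are globally unique by construction). A
green recovery test therefore establishes that the pipeline detects the
planted structure at the stated rates, not that real repertoires have that
structure.

## Numerical conventions

- Clonality = 1 − H/ln(richness) (1 − Pielou evenness), 0 for a single
  clone by convention; Shannon H in nats.
- Welch (unequal-variance) t-test everywhere a two-group mean comparison
  is called for; two constant equal groups return p = 1 by convention.
- Empirical p-values use the +1 correction: (1 + #{null ≥ obs})/(n + 1).
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); pipeline reruns with the same config are
  byte-identical.
- Ties anywhere ranking or truncation occurs (top-N pools, clone ranks)
  break lexicographically on the AA string.

## Known limitations

- Publicness presence is binary at `min_count`; no abundance-weighted or
  probabilistic publicness model.
- The LR test treats per-CR-level means as independent Gaussian
  observations; with few CR levels the χ² reference is approximate.
- Whether equal-depth subsampling should count reads or unique clones is
  ambiguous in the emulated design; reads were chosen (rarefaction
  standard) and the depth is exposed for sensitivity analysis.
- The 582-style shared-pair count is reported both as pair-sample
  occurrences and as unique pairs, since either reading is defensible.
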