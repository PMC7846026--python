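"""Cross-species clone sets and the metrics defined over them.

Covers: construction of the mouse/human shared-AA set under a presence
quantifier, the tumor-vs-normal association filter, the rank-area metric
(1 / (mouse rank x human rank)) and its per-timepoint profile, the
frequency-weighted (Ruzicka) Jaccard overlap, breast-cancer stage
similarity, selection of highly abundant young/old clones with a
resampling null, CDR3-peptide pair enumeration with a pluggable scorer,
and V/J gene-usage correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    CoverageError,
    DataError,
    EmptyInputError,
    TcrShareError,
)
from .io import RepertoireSample, StudyDesign, subsample_repertoire
from .publicness import welch_ttest

logger = logging.getLogger(__name__)


@dataclass
class Quantifier:
    """Presence requirements a cross-species AA must satisfy.

    ``min_mouse_samples``: minimum number of mouse samples carrying the AA.
    ``require_all_mouse_timepoints``: the AA must appear at every mouse
    timepoint (the construction behind the 258-style set).
    ``human_requirement``: ``all`` = present in every human dataset (the
    7513-style set); ``any`` = present in at least one.
    """

    min_mouse_samples: int = 1
    require_all_mouse_timepoints: bool = False
    human_requirement: str = "all"
    datasets: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.human_requirement not in ("any", "all"):
            raise ConfigError(
                f"human_requirement must be 'any' or 'all', got {self.human_requirement!r}"
            )


@dataclass
class CrossSpeciesSet:
    members: set[str]
    quantifier: Quantifier
    provenance: pd.DataFrame = field(repr=False, default=None)


@dataclass
class RankedArea:
    junction_aa: str
    rank_mouse: int
    rank_human: int

    @property
    def area(self) -> float:
        return cross_rank_area(self.rank_mouse, self.rank_human)


@dataclass
class StageSimilarity:
    sample_id: str
    stage: str
    shared_count: int
    n_clones_sample: int
    n_cases_stage: int

    @property
    def similarity(self) -> float:
        return self.shared_count / (self.n_clones_sample * self.n_cases_stage)


def build_cross_species_set(
    mouse_samples: list[RepertoireSample],
    human_datasets: dict[str, list[RepertoireSample]],
    quantifier: Quantifier | None = None,
) -> CrossSpeciesSet:
    """AA sequences satisfying the presence quantifier over mouse samples
    and named human datasets, with per-dataset provenance flags."""
    if not mouse_samples or not human_datasets:
        raise EmptyInputError("need mouse samples and at least one human dataset")
    quantifier = quantifier or Quantifier()
    names = quantifier.datasets or tuple(sorted(human_datasets))
    unknown = set(names) - set(human_datasets)
    if unknown:
        raise ConfigError(f"quantifier names unknown datasets: {sorted(unknown)}")

    mouse_presence: dict[str, int] = {}
    tp_presence: dict[str, set[int]] = {}
    all_tps = {s.timepoint for s in mouse_samples if s.timepoint is not None}
    for s in mouse_samples:
        for aa in s.aa_set():
            mouse_presence[aa] = mouse_presence.get(aa, 0) + 1
            if s.timepoint is not None:
                tp_presence.setdefault(aa, set()).add(s.timepoint)
    human_presence = {
        name: set().union(*(s.aa_set() for s in human_datasets[name]))
        for name in names
    }

    rows = []
    members = set()
    for aa, n_mouse in sorted(mouse_presence.items()):
        in_datasets = {name: aa in human_presence[name] for name in names}
        ok = n_mouse >= quantifier.min_mouse_samples
        if quantifier.require_all_mouse_timepoints:
            ok = ok and tp_presence.get(aa, set()) >= all_tps
        flags = list(in_datasets.values())
        ok = ok and (all(flags) if quantifier.human_requirement == "all" else any(flags))
        if ok:
            members.add(aa)
        rows.append(
            {"junction_aa": aa, "n_mouse_samples": n_mouse, "member": ok, **in_datasets}
        )
    return CrossSpeciesSet(
        members=members, quantifier=quantifier, provenance=pd.DataFrame(rows)
    )


def tumor_associated_filter(
    aa_candidates: set[str],
    tumor_samples: list[RepertoireSample],
    normal_samples: list[RepertoireSample],
) -> set[str]:
    """AAs present in at least one tumor sample and in no normal sample."""
    if not normal_samples:
        logger.warning(
            "no normal samples supplied; filter degenerates to tumor presence"
        )
    in_tumor = set().union(*(s.aa_set() for s in tumor_samples)) if tumor_samples else set()
    in_normal = (
        set().union(*(s.aa_set() for s in normal_samples)) if normal_samples else set()
    )
    return {aa for aa in aa_candidates if aa in in_tumor and aa not in in_normal}


def rank_clones(sample: RepertoireSample) -> dict[str, int]:
    """Rank AAs by descending summed copy number; highest copy number is 1.

    Ties are broken lexicographically so ranks are a deterministic dense
    permutation 1..k.
    """
    if not sample.clones:
        raise EmptyInputError(f"cannot rank empty sample {sample.sample_id}")
    counts = sample.aa_counts()
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return {aa: i + 1 for i, (aa, _) in enumerate(ordered)}


def cross_rank_area(rank_mouse: int, rank_human: int) -> float:
    """The rank-area metric 1 / (mouse rank x human rank); 1 iff both ranks are 1."""
    if rank_mouse < 1 or rank_human < 1:
        raise TcrShareError(f"ranks must be >= 1, got ({rank_mouse}, {rank_human})")
    return 1.0 / (rank_mouse * rank_human)


def rank_area_profile(
    cross_set: CrossSpeciesSet | set[str],
    mouse_by_timepoint: dict[int, RepertoireSample],
    human_reference: RepertoireSample,
) -> pd.DataFrame:
    """Stacked-bar data: one RankedArea per cross-set member per timepoint.

    Members are ranked (restricted to the set) in the human reference and
    in each timepoint's mouse sample; shares are areas normalised to sum
    to 1 within each timepoint.
    """
    members = cross_set.members if isinstance(cross_set, CrossSpeciesSet) else cross_set
    members = sorted(members)

    def restricted_ranks(sample: RepertoireSample) -> dict[str, int]:
        counts = sample.aa_counts()
        missing = [aa for aa in members if aa not in counts]
        if missing:
            raise CoverageError(
                f"cross-set members absent from {sample.sample_id}: {missing[:5]}"
            )
        ordered = sorted(members, key=lambda aa: (-counts[aa], aa))
        return {aa: i + 1 for i, aa in enumerate(ordered)}

    human_ranks = restricted_ranks(human_reference)
    rows = []
    for tp in sorted(mouse_by_timepoint):
        mouse_ranks = restricted_ranks(mouse_by_timepoint[tp])
        areas = {
            aa: cross_rank_area(mouse_ranks[aa], human_ranks[aa]) for aa in members
        }
        total = sum(areas.values())
        for aa in members:
            rows.append(
                {
                    "timepoint": tp,
                    "junction_aa": aa,
                    "rank_mouse": mouse_ranks[aa],
                    "rank_human": human_ranks[aa],
                    "area": areas[aa],
                    "share": areas[aa] / total,
                }
            )
    return pd.DataFrame(rows)


def weighted_jaccard(freqs_a: dict[str, float], freqs_b: dict[str, float]) -> float:
    """Frequency-weighted (Ruzicka) Jaccard: sum(min) / sum(max) over the union."""
    if not any(v > 0 for v in freqs_a.values()) or not any(
        v > 0 for v in freqs_b.values()
    ):
        raise EmptyInputError("weighted Jaccard undefined when a side is all zero")
    num = den = 0.0
    for key in set(freqs_a) | set(freqs_b):
        fa = freqs_a.get(key, 0.0)
        fb = freqs_b.get(key, 0.0)
        num += min(fa, fb)
        den += max(fa, fb)
    return num / den


def exclusive_vs_cohort_overlap(
    exclusive_sets: dict[str, set[str]],
    mouse_samples: list[RepertoireSample],
    human_cohorts: dict[str, list[RepertoireSample]],
    subsample_n: int,
    seed: int,
) -> dict:
    """Mean weighted Jaccard between mouse samples and each human cohort,
    restricted to each exclusive AA set, at equal subsampled depth.

    Returns per-(set, cohort) means, the pairwise values, and Welch tests
    comparing the exclusive sets within each cohort.
    """
    rng = np.random.default_rng(seed)
    mice = [subsample_repertoire(s, subsample_n, rng) for s in mouse_samples]
    cohorts = {
        name: [subsample_repertoire(s, subsample_n, rng) for s in cohort]
        for name, cohort in sorted(human_cohorts.items())
    }
    values: dict[tuple[str, str], list[float]] = {}
    for set_name, aa_set in sorted(exclusive_sets.items()):
        for cohort_name, cohort in cohorts.items():
            vals = []
            for m in mice:
                fm = {
                    aa: f for aa, f in m.aa_frequencies().items() if aa in aa_set
                }
                for h in cohort:
                    fh = {
                        aa: f
                        for aa, f in h.aa_frequencies().items()
                        if aa in aa_set
                    }
                    if not fm or not fh:
                        vals.append(0.0)
                    else:
                        vals.append(weighted_jaccard(fm, fh))
            values[(set_name, cohort_name)] = vals
    means = {k: float(np.mean(v)) for k, v in values.items()}
    tests = {}
    set_names = sorted(exclusive_sets)
    if len(set_names) == 2:
        for cohort_name in cohorts:
            a = values[(set_names[0], cohort_name)]
            b = values[(set_names[1], cohort_name)]
            if len(a) < 2 or len(b) < 2:
                tests[cohort_name] = None  # too few pairs for a t-test
                continue
            t, df, p = welch_ttest(a, b)
            tests[cohort_name] = {"t": t, "df": df, "p_value": p}
    return {"means": means, "values": values, "tests": tests}


def stage_similarity(
    sample: RepertoireSample,
    staged_cohort: dict[str, list[set[str]]],
) -> list[StageSimilarity]:
    """Similarity of one sample to each disease stage.

    similarity = |AA(sample) ∩ AA(stage pool)| /
                 (clones in sample x cases in stage).
    """
    if not staged_cohort:
        raise EmptyInputError("staged cohort is empty")
    sample_aas = sample.aa_set()
    out = []
    for stage, cases in sorted(staged_cohort.items()):
        if not cases:
            logger.warning("stage %s has no cases; excluded", stage)
            continue
        pool = set().union(*cases)
        out.append(
            StageSimilarity(
                sample_id=sample.sample_id,
                stage=stage,
                shared_count=len(sample_aas & pool),
                n_clones_sample=len(sample_aas),
                n_cases_stage=len(cases),
            )
        )
    return out


def select_highly_abundant(
    young_samples: list[RepertoireSample],
    old_samples: list[RepertoireSample],
    min_samples: int = 10,
    alpha: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Clones present in >= ``min_samples`` samples of each epoch whose
    per-sample copy numbers differ between epochs (two-sided Welch).

    Copy number is 0 in samples not carrying the clone.
    """
    if min_samples > len(young_samples) or min_samples > len(old_samples):
        raise ConfigError(
            f"min_samples={min_samples} exceeds epoch size "
            f"({len(young_samples)} young, {len(old_samples)} old)"
        )
    young_counts = [s.aa_counts() for s in young_samples]
    old_counts = [s.aa_counts() for s in old_samples]
    candidates = set()
    universe = set().union(*young_counts, *old_counts)
    for aa in universe:
        ny = sum(1 for c in young_counts if aa in c)
        no = sum(1 for c in old_counts if aa in c)
        if ny >= min_samples and no >= min_samples:
            candidates.add(aa)
    significant = set()
    for aa in candidates:
        a = [c.get(aa, 0) for c in young_counts]
        b = [c.get(aa, 0) for c in old_counts]
        _, _, p = welch_ttest(a, b)
        if p < alpha:
            significant.add(aa)
    return candidates, significant


def cohort_mean_frequency(
    aa_set: set[str], cohort_samples: list[RepertoireSample]
) -> float:
    """Summed copy number of the AAs across the cohort / summed cohort depth,
    averaged over the AAs."""
    if not cohort_samples:
        raise DataError("cohort is empty")
    depth = sum(s.total_reads for s in cohort_samples)
    total: dict[str, int] = {}
    for s in cohort_samples:
        for aa, cnt in s.aa_counts().items():
            total[aa] = total.get(aa, 0) + cnt
    return float(np.mean([total.get(aa, 0) / depth for aa in sorted(aa_set)]))


def resampling_null(
    selected: set[str],
    candidates: set[str],
    cohort_samples: list[RepertoireSample],
    n_iter: int = 1000,
    seed: int = 0,
) -> dict:
    """Resampling null for the mean cohort frequency of a selected AA set.

    Draws ``n_iter`` random subsets of |selected| from the candidates and
    recomputes the mean frequency; empirical p uses the +1 correction so
    it is never exactly zero.
    """
    if len(selected) > len(candidates):
        raise ConfigError("selected set larger than candidate set")
    if not cohort_samples:
        raise DataError("cohort is empty")
    rng = np.random.default_rng(seed)
    observed = cohort_mean_frequency(selected, cohort_samples)
    pool = sorted(candidates)
    null = np.empty(n_iter)
    for i in range(n_iter):
        draw = rng.choice(len(pool), size=len(selected), replace=False)
        null[i] = cohort_mean_frequency({pool[j] for j in draw}, cohort_samples)
    p = (1 + int((null >= observed).sum())) / (n_iter + 1)
    return {"observed": observed, "null": null, "p_value": p}


def enumerate_peptide_pairs(
    cdr3s: list[str],
    peptides: list[str],
    scorer=None,
) -> pd.DataFrame:
    """All CDR3 x peptide pairs, with scores attached when a scorer is given.

    ``scorer`` may be a callable (cdr3, peptide) -> score or a DataFrame
    with columns (cdr3, peptide, score); missing pairs score null.
    """
    if len(set(cdr3s)) != len(cdr3s):
        logger.warning("duplicate CDR3s deduplicated")
        cdr3s = list(dict.fromkeys(cdr3s))
    if len(set(peptides)) != len(peptides):
        logger.warning("duplicate peptides deduplicated")
        peptides = list(dict.fromkeys(peptides))
    rows = [(c, p) for c in cdr3s for p in peptides]
    df = pd.DataFrame(rows, columns=["cdr3", "peptide"])
    if scorer is None:
        df["score"] = np.nan
    elif callable(scorer):
        df["score"] = [scorer(c, p) for c, p in rows]
    else:
        lookup = {
            (r.cdr3, r.peptide): r.score for r in scorer.itertuples(index=False)
        }
        df["score"] = [lookup.get(pair, np.nan) for pair in rows]
    return df


def vj_usage_correlation(
    samples: list[RepertoireSample], which: str = "v"
) -> pd.DataFrame:
    """Pearson correlation matrix of per-gene usage-frequency vectors
    across samples; genes used in fewer than 2 samples are excluded."""
    if which not in ("v", "j"):
        raise ConfigError("which must be 'v' or 'j'")
    usage: dict[str, dict[str, float]] = {}
    for s in samples:
        counts: dict[str, int] = {}
        for clone in s.clones.values():
            calls = clone.v_calls if which == "v" else clone.j_calls
            for gene in calls:
                counts[gene] = counts.get(gene, 0) + clone.duplicate_count
        total = sum(counts.values())
        usage[s.sample_id] = (
            {g: c / total for g, c in counts.items()} if total else {}
        )
    genes = sorted(set().union(*usage.values())) if usage else []
    mat = pd.DataFrame(
        {g: [usage[sid].get(g, 0.0) for sid in sorted(usage)] for g in genes},
        index=sorted(usage),
    )
    keep = [g for g in genes if (mat[g] > 0).sum() >= 2]
    dropped = set(genes) - set(keep)
    if dropped:
        logger.warning("genes used in <2 samples excluded: %s", sorted(dropped))
    if not keep:
        raise DataError("no gene used in >= 2 samples")
    return mat[keep].corr(method="pearson")
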