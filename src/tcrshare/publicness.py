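"""Publicness classification, convergent recombination, overlap indices,
repertoire summaries, and the group-comparison tests.

Definitions
-----------
A CDR3 amino-acid sequence is *private* when it appears in exactly one
subject and *public* when it appears in at least two.  Public sequences
are *inclusive* when both study groups carry them and *exclusive* when
only one group does.  The *CR level* of an AA sequence is the number of
distinct nucleotide sequences encoding it in the data in scope —
convergent recombination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .errors import DataError, DesignError, EmptyInputError, TcrShareError
from .io import RepertoireSample, StudyDesign

LABELS = (
    "private",
    "public_inclusive",
    "public_exclusive_control",
    "public_exclusive_case",
)


@dataclass
class PublicnessRecord:
    junction_aa: str
    n_control_subjects: int
    n_case_subjects: int

    @property
    def n_subjects_total(self) -> int:
        return self.n_control_subjects + self.n_case_subjects

    @property
    def label(self) -> str:
        total = self.n_subjects_total
        if total == 1:
            return "private"
        if self.n_control_subjects >= 1 and self.n_case_subjects >= 1:
            return "public_inclusive"
        if self.n_control_subjects >= 2:
            return "public_exclusive_control"
        return "public_exclusive_case"


@dataclass
class CRRecord:
    junction_aa: str
    nt_set: frozenset[str]

    @property
    def cr_level(self) -> int:
        return len(self.nt_set)


@dataclass
class RepertoireSummary:
    unique_clones: int
    shannon_diversity: float
    clonality: float
    cdr3_length_histogram: dict[int, int]


def classify_publicness(
    pooled_samples: list[RepertoireSample],
    design: StudyDesign,
    min_count: int = 1,
) -> list[PublicnessRecord]:
    """One record per distinct AA across subject pools.

    Presence in a subject means the AA appears with summed copy number
    >= ``min_count`` in that subject's (subsampled) pool.
    """
    groups = {design.group_of(s.subject_id) for s in pooled_samples}
    if len(groups) < 2:
        raise DesignError(
            "publicness labels need subjects from both groups; "
            f"got only {sorted(groups)}"
        )
    counts: dict[str, list[int]] = {}  # aa -> [n_control, n_case]
    for sample in pooled_samples:
        is_case = design.group_of(sample.subject_id) == "case"
        for aa, cnt in sample.aa_counts().items():
            if cnt >= min_count:
                entry = counts.setdefault(aa, [0, 0])
                entry[1 if is_case else 0] += 1
    return [
        PublicnessRecord(aa, n_control_subjects=c, n_case_subjects=k)
        for aa, (c, k) in sorted(counts.items())
    ]


def publicness_fractions(
    records: list[PublicnessRecord],
    pooled_samples: list[RepertoireSample],
    weighting: str = "unique",
) -> pd.DataFrame:
    """Per-subject fraction of each publicness label; rows sum to 1.

    ``unique`` counts each AA once; ``total_reads`` weights by summed
    copy number.
    """
    if weighting not in ("unique", "total_reads"):
        raise TcrShareError(f"unknown weighting {weighting!r}")
    label_of = {r.junction_aa: r.label for r in records}
    rows = []
    for sample in pooled_samples:
        weights = dict.fromkeys(LABELS, 0.0)
        for aa, cnt in sample.aa_counts().items():
            try:
                label = label_of[aa]
            except KeyError:
                raise TcrShareError(
                    f"AA {aa} in sample {sample.sample_id} has no publicness record"
                ) from None
            weights[label] += 1.0 if weighting == "unique" else float(cnt)
        total = sum(weights.values())
        rows.append(
            {
                "subject_id": sample.subject_id,
                "group": sample.group,
                **{lab: (weights[lab] / total if total else 0.0) for lab in LABELS},
            }
        )
    return pd.DataFrame(rows)


def cr_levels(samples: RepertoireSample | list[RepertoireSample]) -> list[CRRecord]:
    """CR level per AA: distinct NT junctions mapping to it in scope."""
    if isinstance(samples, RepertoireSample):
        samples = [samples]
    nt_by_aa: dict[str, set[str]] = {}
    for sample in samples:
        for clone in sample.clones.values():
            if not clone.junction_nt:
                raise DataError(
                    f"clone {clone.junction_aa} in {sample.sample_id} lacks junction_nt"
                )
            nt_by_aa.setdefault(clone.junction_aa, set()).add(clone.junction_nt)
    return [
        CRRecord(aa, frozenset(nts)) for aa, nts in sorted(nt_by_aa.items())
    ]


def cr_publicness_association(
    pooled_samples: list[RepertoireSample],
    design: StudyDesign,
) -> dict:
    """Does sharing rise with CR level differently between the groups?

    Per group, each AA contributes its within-group CR level (distinct NT
    encodings over that group's pools) and its sharing level (number of
    group subjects carrying it); points are averaged per CR level.  Nested
    Gaussian models — mean sharing ~ CR versus mean sharing ~ CR + group +
    CR x group — are compared by a likelihood-ratio test against chi2(df).
    """
    groups = sorted({design.group_of(s.subject_id) for s in pooled_samples})
    if len(groups) < 2:
        raise DesignError("need both groups for the CR-sharing comparison")
    points = []
    for grp in groups:
        grp_samples = [
            s for s in pooled_samples if design.group_of(s.subject_id) == grp
        ]
        sharing: dict[str, int] = {}
        for s in grp_samples:
            for aa in s.aa_set():
                sharing[aa] = sharing.get(aa, 0) + 1
        for rec in cr_levels(grp_samples):
            points.append(
                {
                    "group": grp,
                    "cr_level": rec.cr_level,
                    "sharing": sharing[rec.junction_aa],
                }
            )
    df = pd.DataFrame(points)
    table = (
        df.groupby(["group", "cr_level"])["sharing"].mean().reset_index()
        .rename(columns={"sharing": "mean_sharing"})
    )
    y = table["mean_sharing"].to_numpy(float)
    x = table["cr_level"].to_numpy(float)
    g = (table["group"] == groups[1]).to_numpy(float)
    X0 = sm.add_constant(np.column_stack([x]))
    X1 = sm.add_constant(np.column_stack([x, g, x * g]))
    ll0 = sm.OLS(y, X0).fit().llf
    ll1 = sm.OLS(y, X1).fit().llf
    lr = max(2.0 * (ll1 - ll0), 0.0)
    dof = X1.shape[1] - X0.shape[1]
    p = float(stats.chi2.sf(lr, dof))
    return {"table": table, "lr_statistic": float(lr), "df": dof, "p_value": p}


# ---------------------------------------------------------------------------
# overlap indices


def morisita_overlap(a: RepertoireSample, b: RepertoireSample) -> float:
    """Morisita-Horn overlap of two samples' AA abundance vectors, in [0, 1]."""
    if not a.clones or not b.clones:
        raise EmptyInputError("Morisita-Horn overlap undefined for empty samples")
    ca, cb = a.aa_counts(), b.aa_counts()
    X = sum(ca.values())
    Y = sum(cb.values())
    cross = sum(ca[aa] * cb.get(aa, 0) for aa in ca)
    sum_a2 = sum(v * v for v in ca.values())
    sum_b2 = sum(v * v for v in cb.values())
    return 2.0 * cross / ((sum_a2 / X**2 + sum_b2 / Y**2) * X * Y)


def grouped_overlap_matrix(
    samples: list[RepertoireSample], design: StudyDesign
) -> pd.DataFrame:
    """Mean pairwise Morisita-Horn between group x young/old epoch cells.

    Samples are binned by (group, epoch of their timepoint); each matrix
    cell averages all cross-bin (or within-bin, excluding self) pairs.
    """
    bins: dict[str, list[RepertoireSample]] = {}
    for s in samples:
        if s.timepoint is None:
            continue
        key = f"{s.group}_{design.epoch_of(s.timepoint)}"
        bins.setdefault(key, []).append(s)
    names = sorted(bins)
    mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for i, gi in enumerate(names):
        for gj in names[i:]:
            vals = []
            for a in bins[gi]:
                for b in bins[gj]:
                    if a is b:
                        continue
                    vals.append(morisita_overlap(a, b))
            # within-bin loops see each unordered pair twice; the mean is unchanged
            mean = float(np.mean(vals)) if vals else np.nan
            mat.loc[gi, gj] = mean
            mat.loc[gj, gi] = mean
    return mat


def repertoire_summary(sample: RepertoireSample) -> RepertoireSummary:
    """Shannon diversity (nats), clonality (1 - Pielou evenness), and the
    AA-length histogram of one sample."""
    counts = np.array(list(sample.aa_counts().values()), dtype=float)
    if counts.size == 0:
        raise EmptyInputError("summary undefined for empty sample")
    p = counts / counts.sum()
    shannon = float(-(p * np.log(p)).sum())
    richness = counts.size
    clonality = 1.0 - shannon / math.log(richness) if richness > 1 else 0.0
    hist: dict[int, int] = {}
    for aa in sample.aa_counts():
        hist[len(aa)] = hist.get(len(aa), 0) + 1
    return RepertoireSummary(
        unique_clones=richness,
        shannon_diversity=shannon,
        clonality=clonality,
        cdr3_length_histogram=dict(sorted(hist.items())),
    )


# ---------------------------------------------------------------------------
# statistical tests


def welch_ttest(a, b) -> tuple[float, float, float]:
    """Two-sided Welch t-test; returns (t, df, p).

    When both groups are constant with equal means the test is vacuous
    and (0, n-2, 1) is returned by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("each group needs at least 2 values")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return math.inf, float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def ks_compare(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise DataError("each sample needs at least 1 value")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
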