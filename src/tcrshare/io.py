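"""Clonotype data model and AIRR Rearrangement-style TSV input/output.

A *clone* is keyed by its nucleotide junction alone; rows that share a
nucleotide junction within a sample are merged (copy numbers summed) and
their V/J calls are kept as annotation sets, since the same CDR3 can arise
from multiple V-J pairings.  Nonproductive rows (out-of-frame junctions or
in-frame stop codons) are dropped at load time and tallied in a skip
report, because all downstream analyses operate on amino-acid CDR3s.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import (
    AlphabetError,
    ConsistencyError,
    DepthError,
    EmptyInputError,
    FormatError,
)

logger = logging.getLogger(__name__)

_NT_ALPHABET = frozenset("ACGT")

#: AIRR core columns required on input.
REQUIRED_COLUMNS = ("junction", "junction_aa", "duplicate_count")
#: Metadata columns written (and recognised) alongside the AIRR core.
METADATA_COLUMNS = (
    "repertoire_id",
    "subject_id",
    "group",
    "timepoint",
    "chain",
    "tissue",
)


def translate_junction(junction_nt: str) -> str | None:
    """Translate a nucleotide junction under the standard genetic code.

    Returns the amino-acid string, or ``None`` when the junction is
    nonproductive (length not divisible by 3, or any stop codon).

    Raises
    ------
    AlphabetError
        If the string contains characters outside A/C/G/T.
    """
    bad = set(junction_nt) - _NT_ALPHABET
    if bad:
        raise AlphabetError(
            f"junction contains non-ACGT characters: {sorted(bad)}"
        )
    if len(junction_nt) % 3 != 0:
        return None
    aa = str(Seq(junction_nt).translate())
    if "*" in aa:
        return None
    return aa


@dataclass
class Clone:
    """One clonotype: NT junction, AA junction, V/J annotation, copy number."""

    junction_nt: str
    junction_aa: str
    duplicate_count: int
    v_calls: frozenset[str] = frozenset()
    j_calls: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.duplicate_count < 1:
            raise ValueError(
                f"duplicate_count must be >= 1, got {self.duplicate_count}"
            )


@dataclass
class RepertoireSample:
    """A bag of clones with subject/group/timepoint/chain/tissue metadata.

    ``clones`` maps ``junction_nt`` -> :class:`Clone`; identity within a
    sample is the nucleotide junction alone.
    """

    sample_id: str
    subject_id: str
    group: str = "control"
    timepoint: int | None = None
    chain: str = "beta"
    tissue: str = "blood"
    clones: dict[str, Clone] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(c.duplicate_count for c in self.clones.values())

    @property
    def unique_clones(self) -> int:
        return len(self.clones)

    def aa_set(self) -> set[str]:
        """Distinct amino-acid junctions present in the sample."""
        return {c.junction_aa for c in self.clones.values()}

    def aa_counts(self) -> dict[str, int]:
        """Copy number summed per amino-acid junction."""
        counts: dict[str, int] = {}
        for c in self.clones.values():
            counts[c.junction_aa] = counts.get(c.junction_aa, 0) + c.duplicate_count
        return counts

    def aa_frequencies(self) -> dict[str, float]:
        total = self.total_reads
        return {aa: n / total for aa, n in self.aa_counts().items()}

    def add_clone(self, clone: Clone) -> None:
        """Merge ``clone`` into the sample under the NT-identity rule."""
        existing = self.clones.get(clone.junction_nt)
        if existing is None:
            self.clones[clone.junction_nt] = replace(clone)
        else:
            existing.duplicate_count += clone.duplicate_count
            existing.v_calls = existing.v_calls | clone.v_calls
            existing.j_calls = existing.j_calls | clone.j_calls


@dataclass
class StudyDesign:
    """Subjects with group labels plus the young/old timepoint partition."""

    subjects: list[tuple[str, str]]
    timepoints: list[int] = field(default_factory=lambda: list(range(1, 9)))
    young_timepoints: frozenset[int] = frozenset({1, 2, 3, 4})
    old_timepoints: frozenset[int] = frozenset({5, 6, 7, 8})

    def __post_init__(self) -> None:
        if self.young_timepoints & self.old_timepoints:
            raise ValueError("young and old timepoint sets must be disjoint")

    def group_of(self, subject_id: str) -> str:
        for sid, grp in self.subjects:
            if sid == subject_id:
                return grp
        raise KeyError(subject_id)

    def epoch_of(self, timepoint: int) -> str:
        if timepoint in self.young_timepoints:
            return "young"
        if timepoint in self.old_timepoints:
            return "old"
        raise KeyError(timepoint)


# ---------------------------------------------------------------------------
# TSV reading / writing


def _row_metadata(row: pd.Series, col: str, default):
    val = row.get(col)
    if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
        return default
    return val


def read_airr_table(
    path: str | Path,
    metadata: Mapping[str, str] | None = None,
    return_skips: bool = False,
):
    """Read an AIRR-style TSV into a list of :class:`RepertoireSample`.

    One sample per distinct ``repertoire_id`` (falling back to a single
    anonymous sample when the column is absent).  Rows with the same
    nucleotide junction are merged with summed counts.  Nonproductive rows
    are excluded and tallied.

    Parameters
    ----------
    path
        TSV file with a header row; must contain ``junction``,
        ``junction_aa`` and ``duplicate_count``.
    metadata
        Optional mapping from the AIRR column names used here to the
        column names actually present in the file.
    return_skips
        When true, also return a ``Counter`` of skip reasons.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    if df.empty and len(df.columns) == 0:
        raise EmptyInputError(f"{path} has no rows")
    if metadata:
        df = df.rename(columns={v: k for k, v in metadata.items()})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"required column {col!r} missing from {path}")

    skips: Counter[str] = Counter()
    samples: dict[str, RepertoireSample] = {}
    for _, row in df.iterrows():
        nt = row["junction"]
        try:
            aa = translate_junction(nt)
        except AlphabetError:
            skips["bad_alphabet"] += 1
            continue
        if aa is None:
            skips["nonproductive"] += 1
            continue
        sample_id = str(_row_metadata(row, "repertoire_id", "sample"))
        if sample_id not in samples:
            tp = _row_metadata(row, "timepoint", None)
            samples[sample_id] = RepertoireSample(
                sample_id=sample_id,
                subject_id=str(_row_metadata(row, "subject_id", sample_id)),
                group=str(_row_metadata(row, "group", "control")),
                timepoint=int(tp) if tp is not None else None,
                chain=str(_row_metadata(row, "chain", "beta")),
                tissue=str(_row_metadata(row, "tissue", "blood")),
            )
        v = row.get("v_call", "") or ""
        j = row.get("j_call", "") or ""
        samples[sample_id].add_clone(
            Clone(
                junction_nt=nt,
                junction_aa=aa,
                duplicate_count=int(row["duplicate_count"]),
                v_calls=frozenset({v} if v else ()),
                j_calls=frozenset({j} if j else ()),
            )
        )
    out = list(samples.values())
    if return_skips:
        return out, skips
    return out


def write_airr_table(samples: Iterable[RepertoireSample], path: str | Path) -> None:
    """Write samples as an AIRR-style TSV (round-trips with :func:`read_airr_table`)."""
    samples = list(samples)
    if not samples:
        raise EmptyInputError("no samples to write")
    rows = []
    for s in samples:
        if not s.clones:
            logger.warning("sample %s has no clones; writing no rows", s.sample_id)
        for clone in s.clones.values():
            rows.append(
                {
                    "junction": clone.junction_nt,
                    "junction_aa": clone.junction_aa,
                    "v_call": ",".join(sorted(clone.v_calls)),
                    "j_call": ",".join(sorted(clone.j_calls)),
                    "duplicate_count": clone.duplicate_count,
                    "repertoire_id": s.sample_id,
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "timepoint": "" if s.timepoint is None else s.timepoint,
                    "chain": s.chain,
                    "tissue": s.tissue,
                }
            )
    cols = ["junction", "junction_aa", "v_call", "j_call", "duplicate_count"]
    cols += list(METADATA_COLUMNS)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_skip_report(skips: Counter, path: str | Path) -> None:
    pd.DataFrame(
        sorted(skips.items()), columns=["reason", "count"]
    ).to_csv(path, sep="\t", index=False)


def write_run_manifest(path: str | Path, *, inputs, seed: int, parameters: dict) -> None:
    Path(path).write_text(
        json.dumps(
            {"inputs": inputs, "seed": seed, "parameters": parameters},
            indent=2,
            default=str,
        )
    )


# ---------------------------------------------------------------------------
# Pooling and subsampling


def pool_subject(samples: list[RepertoireSample]) -> RepertoireSample:
    """Combine all timepoint samples of one subject into a single pool.

    The pooled clone multiset is the count-summed union; ``timepoint`` is
    cleared.  All inputs must share subject and chain.
    """
    if not samples:
        raise EmptyInputError("pool_subject needs at least one sample")
    chains = {s.chain for s in samples}
    if len(chains) > 1:
        raise ConsistencyError(f"mixed chains in pool: {sorted(chains)}")
    subjects = {s.subject_id for s in samples}
    if len(subjects) > 1:
        raise ConsistencyError(f"mixed subjects in pool: {sorted(subjects)}")
    first = samples[0]
    pooled = RepertoireSample(
        sample_id=f"{first.subject_id}_pooled_{first.chain}",
        subject_id=first.subject_id,
        group=first.group,
        timepoint=None,
        chain=first.chain,
        tissue=first.tissue,
    )
    for s in samples:
        for clone in s.clones.values():
            pooled.add_clone(clone)
    return pooled


def subsample_repertoire(
    sample: RepertoireSample, n: int, seed: int | np.random.Generator
) -> RepertoireSample:
    """Draw ``n`` reads without replacement (multivariate hypergeometric).

    Each clone is expanded to ``duplicate_count`` copies; the returned
    sample has ``total_reads == n`` exactly and is reproducible given the
    seed.
    """
    total = sample.total_reads
    if n > total:
        raise DepthError(
            f"requested {n} reads but sample {sample.sample_id} has {total}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    keys = list(sample.clones)
    counts = np.array([sample.clones[k].duplicate_count for k in keys], dtype=np.int64)
    drawn = rng.multivariate_hypergeometric(counts, n)
    out = replace(sample, clones={})
    for key, k in zip(keys, drawn):
        if k > 0:
            out.clones[key] = replace(sample.clones[key], duplicate_count=int(k))
    return out
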