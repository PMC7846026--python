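"""Single-cell alpha-beta pair assembly and matching against bulk samples.

Each cell barcode yields an alpha-beta CDR3 pair only when it carries
exactly one alpha and exactly one beta call; cells with more than one
call of a chain are dropped (multichain), cells missing a chain are
dropped (incomplete).  A pair is *shared* with a bulk mouse sample when
its alpha appears in the sample's alpha repertoire and its beta in the
beta repertoire of the same sample.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import FormatError
from .io import RepertoireSample
from .networks import DistanceNetwork, build_distance_network
from .publicness import welch_ttest

logger = logging.getLogger(__name__)

CHAINS = ("alpha", "beta")


@dataclass(frozen=True)
class AlphaBetaPair:
    cell_id: str
    alpha_aa: str
    beta_aa: str

    def __post_init__(self) -> None:
        if not self.alpha_aa or not self.beta_aa:
            raise ValueError("both chains must be non-empty")

    @property
    def key(self) -> tuple[str, str]:
        return (self.alpha_aa, self.beta_aa)


def assemble_pairs(
    cell_calls: pd.DataFrame,
) -> tuple[list[AlphaBetaPair], Counter]:
    """Build one pair per cell with exactly one alpha and one beta call.

    Duplicate (cell_id, chain, junction_aa) rows are collapsed before
    chains are counted.  Drop reasons: ``multichain`` (>=2 distinct calls
    of a chain; checked first), ``incomplete`` (a chain missing).
    """
    required = {"cell_id", "chain", "junction_aa"}
    missing = required - set(cell_calls.columns)
    if missing:
        raise FormatError(f"cell-call table missing columns: {sorted(missing)}")
    bad = set(cell_calls["chain"]) - set(CHAINS)
    if bad:
        raise FormatError(f"unknown chain values: {sorted(bad)}")
    deduped = cell_calls.drop_duplicates(["cell_id", "chain", "junction_aa"])
    if len(deduped) < len(cell_calls):
        logger.warning(
            "collapsed %d duplicate cell-call rows", len(cell_calls) - len(deduped)
        )
    pairs: list[AlphaBetaPair] = []
    dropped: Counter[str] = Counter()
    for cell_id, grp in deduped.groupby("cell_id", sort=True):
        alphas = sorted(grp.loc[grp["chain"] == "alpha", "junction_aa"])
        betas = sorted(grp.loc[grp["chain"] == "beta", "junction_aa"])
        if len(alphas) > 1 or len(betas) > 1:
            dropped["multichain"] += 1
        elif not alphas or not betas:
            dropped["incomplete"] += 1
        else:
            pairs.append(AlphaBetaPair(str(cell_id), alphas[0], betas[0]))
    return pairs, dropped


def unique_pairs(pairs: list[AlphaBetaPair]) -> set[tuple[str, str]]:
    """Deduplicated (alpha_aa, beta_aa) set across cells."""
    return {p.key for p in pairs}


def match_pairs_to_samples(
    pairs: list[AlphaBetaPair],
    alpha_samples: list[RepertoireSample],
    beta_samples: list[RepertoireSample],
) -> dict:
    """Which pairs are shared with which bulk samples, plus group means.

    Alpha and beta samples are joined on ``sample_id``-less identity:
    the subject they belong to (``subject_id``); a subject missing one
    chain is excluded with a warning.  Returns per-sample shared-pair
    lists, per-sample counts (both pair-occurrence and unique-pair
    views), and a Welch comparison of control vs case per-sample counts.
    """
    alpha_by = {s.subject_id: s for s in alpha_samples}
    beta_by = {s.subject_id: s for s in beta_samples}
    keys = sorted(set(alpha_by) & set(beta_by))
    for missing in sorted(set(alpha_by) ^ set(beta_by)):
        logger.warning("subject %s lacks one chain; excluded from matching", missing)
    pair_keys = sorted(unique_pairs(pairs))
    shared: dict[str, list[tuple[str, str]]] = {}
    groups: dict[str, str] = {}
    for key in keys:
        a_set = alpha_by[key].aa_set()
        b_set = beta_by[key].aa_set()
        shared[key] = [p for p in pair_keys if p[0] in a_set and p[1] in b_set]
        groups[key] = alpha_by[key].group
    counts = {k: len(v) for k, v in shared.items()}
    shared_union = set().union(*shared.values()) if shared else set()
    result = {
        "shared": shared,
        "groups": groups,
        "counts_per_sample": counts,
        "n_shared_pair_occurrences": int(sum(counts.values())),
        "n_unique_shared_pairs": len(shared_union),
        "group_means": {},
        "welch": None,
    }
    by_group: dict[str, list[int]] = {}
    for key, grp in groups.items():
        by_group.setdefault(grp, []).append(counts[key])
    result["group_means"] = {g: sum(v) / len(v) for g, v in by_group.items()}
    if len(by_group) == 2 and all(len(v) >= 2 for v in by_group.values()):
        names = sorted(by_group)
        t, df, p = welch_ttest(by_group[names[0]], by_group[names[1]])
        result["welch"] = {"groups": names, "t": t, "df": df, "p_value": p}
    return result


def pair_group_partition(
    shared: dict[str, list[tuple[str, str]]],
    groups: dict[str, str],
    d_max: int = 3,
) -> dict:
    """Partition shared pairs into control-only / case-only / both and
    build a summed-chain distance network (d <= ``d_max``) per subset."""
    seen_in: dict[tuple[str, str], set[str]] = {}
    for key, plist in shared.items():
        for p in plist:
            seen_in.setdefault(p, set()).add(groups[key])
    partition: dict[str, list[tuple[str, str]]] = {
        "control_only": [],
        "case_only": [],
        "both": [],
    }
    for p in sorted(seen_in):
        gs = seen_in[p]
        if gs == {"control"}:
            partition["control_only"].append(p)
        elif gs == {"case"}:
            partition["case_only"].append(p)
        else:
            partition["both"].append(p)
    networks: dict[str, DistanceNetwork] = {}
    for name, plist in partition.items():
        if plist:
            networks[name] = build_distance_network(
                plist, d_max=d_max, pair_distance="summed_chains"
            )
        else:
            networks[name] = DistanceNetwork(graph=nx.Graph(), d_max=d_max)
    return {"partition": partition, "networks": networks}
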