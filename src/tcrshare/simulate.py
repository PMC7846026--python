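"""Synthetic repertoire generator with planted ground truth.

Emulates the statistical structure the downstream analyses assume: two
groups of mice (control and tumor-developing) sampled at monthly
timepoints, heavy-tailed (Zipf) clone abundances, public amino-acid
clones realised through several synonymous nucleotide encodings
(convergent recombination), group-exclusive shared clones, human bulk
and staged cohorts sharing amino-acid sequences with the mice through
disjoint nucleotide encodings, and single-cell chain calls with
plantable alpha-beta pairs.

Every planted feature is recorded in a :class:`TruthManifest` so that
recovery by the analysis stages can be checked exactly (noiseless
settings) or statistically (Monte-Carlo rates).  Generation is a pure
function of the configuration, including its seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import ConfigError
from .io import Clone, RepertoireSample, StudyDesign

# Reverse codon table (standard code, stops removed), built once.
_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
CODON_TO_AA = {c: str(Seq(c).translate()) for c in _CODONS}
AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in CODON_TO_AA.items():
    if aa != "*":
        AA_TO_CODONS.setdefault(aa, []).append(codon)

AA_LETTERS = sorted(AA_TO_CODONS)  # the 20 standard amino acids

BULK_DATASET_NAMES = ("cohort_a", "cohort_b", "cohort_c")
STAGES = ("i", "ii", "iii", "iv")


@dataclass
class SimulationConfig:
    """Parameters of the stated synthetic world.

    Fractions partition each sample's clonotypes into planted publicness
    classes; the remainder are subject-private.  ``carrier_prob`` is the
    per-subject probability of carrying a given planted public clone
    (re-drawn so exclusives always reach >=2 carriers in their group and
    inclusives >=1 in each group); set to 1.0 for noiseless recovery.
    """

    n_control: int = 5
    n_case: int = 5
    timepoints: int = 8
    clones_per_sample: int = 300
    abundance_exponent: float = 2.0
    planted_exclusive_case_frac: float = 0.10
    planted_exclusive_control_frac: float = 0.02
    planted_inclusive_frac: float = 0.25
    cr_variants_mean: float = 1.5
    cross_species_frac: float = 0.3
    seed: int = 0
    # world details the analyses exercise
    chains: tuple[str, ...] = ("alpha", "beta")
    carrier_prob: float = 0.8
    young_shared_frac: float = 0.0
    cr_case_boost: float = 0.0
    max_clone_count: int = 10_000
    # human cohorts
    n_human_samples: int = 3
    human_clones_per_sample: int = 200
    stage_cases: tuple[int, ...] = (4, 4, 4, 4)
    stage_share_max: float = 0.4
    stage_gradient: float = 4.0
    binding_shift: float = 1.0
    # single cell
    sc_cells: int = 100
    sc_matchable_frac: float = 0.2
    sc_multichain_frac: float = 0.1

    def validate(self) -> None:
        fracs = (
            self.planted_exclusive_case_frac
            + self.planted_exclusive_control_frac
            + self.planted_inclusive_frac
            + self.young_shared_frac
        )
        if fracs > 1.0 + 1e-12:
            raise ConfigError(f"planted fractions sum to {fracs} > 1")
        if min(
            self.n_control,
            self.n_case,
            self.timepoints,
            self.clones_per_sample,
        ) < 0:
            raise ConfigError("counts must be non-negative")
        if self.abundance_exponent <= 1.0:
            raise ConfigError("abundance_exponent must exceed 1 (Zipf)")
        if self.cr_variants_mean < 1.0:
            raise ConfigError("cr_variants_mean must be >= 1")
        if not 0.0 <= self.cross_species_frac <= 1.0:
            raise ConfigError("cross_species_frac must lie in [0, 1]")


@dataclass
class TruthManifest:
    """Planted ground truth: per-AA labels, NT encodings, pools, pairs."""

    labels: dict[str, str] = field(default_factory=dict)
    nt_sets: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    cross_species: list[str] = field(default_factory=list)
    pools: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)

    def mouse_nt(self, aa: str) -> set[str]:
        return set(self.nt_sets.get(aa, {}).get("mouse", []))

    def human_nt(self, aa: str) -> set[str]:
        return set(self.nt_sets.get(aa, {}).get("human", []))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


# ---------------------------------------------------------------------------
# low-level draws


def _random_aa(rng: np.random.Generator, used: set[str]) -> str:
    """A fresh IMGT-style junction: conserved C ... F around a random core."""
    while True:
        length = int(rng.integers(6, 13))
        core = "".join(rng.choice(AA_LETTERS, size=length))
        aa = f"C{core}F"
        if aa not in used:
            used.add(aa)
            return aa


def _encode_nt(rng: np.random.Generator, aa: str) -> str:
    return "".join(
        AA_TO_CODONS[letter][rng.integers(len(AA_TO_CODONS[letter]))]
        for letter in aa
    )


def _nt_variants(
    rng: np.random.Generator, aa: str, k: int, forbidden: set[str] | None = None
) -> list[str]:
    """``k`` distinct NT encodings of ``aa``, avoiding ``forbidden``."""
    forbidden = forbidden or set()
    out: list[str] = []
    seen: set[str] = set(forbidden)
    for _ in range(200 * k):
        nt = _encode_nt(rng, aa)
        if nt not in seen:
            seen.add(nt)
            out.append(nt)
            if len(out) == k:
                return out
    raise ConfigError(f"could not find {k} distinct encodings for {aa}")


def _n_variants(rng: np.random.Generator, mean: float) -> int:
    # shifted Poisson: 1 + Poisson(mean - 1), so the mean is `mean`
    return 1 + int(rng.poisson(max(mean - 1.0, 0.0)))


def _zipf_counts(rng: np.random.Generator, n: int, a: float, cap: int) -> np.ndarray:
    return np.minimum(rng.zipf(a, size=n), cap)


def _draw_carriers(
    rng: np.random.Generator,
    subjects: list[str],
    p: float,
    min_carriers: int,
) -> list[str]:
    """Bernoulli carrier draw conditioned on at least ``min_carriers``."""
    for _ in range(10_000):
        mask = rng.random(len(subjects)) < p
        if mask.sum() >= min_carriers:
            return [s for s, m in zip(subjects, mask) if m]
    return list(subjects)  # p so low conditioning failed; carry everyone


# ---------------------------------------------------------------------------
# mouse study


def default_design(config: SimulationConfig) -> StudyDesign:
    subjects = [(f"C{i + 1}", "control") for i in range(config.n_control)]
    subjects += [(f"T{i + 1}", "case") for i in range(config.n_case)]
    tps = list(range(1, config.timepoints + 1))
    half = max(1, config.timepoints // 2)
    return StudyDesign(
        subjects=subjects,
        timepoints=tps,
        young_timepoints=frozenset(tps[:half]),
        old_timepoints=frozenset(tps[half:]),
    )


def generate_mouse_study(
    config: SimulationConfig,
) -> tuple[list[RepertoireSample], TruthManifest]:
    """Generate the two-group longitudinal mouse study.

    One sample per subject x timepoint x chain.  Planted public AA
    clones carry several synonymous NT encodings; exclusives are carried
    by >=2 subjects of exactly one group, inclusives by >=1 of each.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = default_design(config)
    control_ids = [s for s, g in design.subjects if g == "control"]
    case_ids = [s for s, g in design.subjects if g == "case"]

    n = config.clones_per_sample
    k_case = round(config.planted_exclusive_case_frac * n)
    k_ctrl = round(config.planted_exclusive_control_frac * n)
    k_incl = round(config.planted_inclusive_frac * n)
    k_young = round(config.young_shared_frac * n)
    if k_case + k_ctrl + k_incl + k_young > n:
        raise ConfigError("more planted public clones than clones per sample")

    truth = TruthManifest()
    used_aa: set[str] = set()

    def make_pool(chain: str, label: str, k: int, cr_mean: float) -> list[str]:
        pool = []
        for _ in range(k):
            aa = _random_aa(rng, used_aa)
            variants = _nt_variants(rng, aa, _n_variants(rng, cr_mean))
            truth.labels[aa] = label
            truth.nt_sets[aa] = {"mouse": variants, "human": []}
            pool.append(aa)
        return pool

    # carriers per public AA, fixed across timepoints
    carriers: dict[str, list[str]] = {}
    pools: dict[str, dict[str, list[str]]] = {}
    for chain in config.chains:
        pools[chain] = {
            "exclusive_case": make_pool(
                chain, "exclusive-case", k_case,
                config.cr_variants_mean + config.cr_case_boost,
            ),
            "exclusive_control": make_pool(
                chain, "exclusive-control", k_ctrl, config.cr_variants_mean
            ),
            "inclusive": make_pool(
                chain, "inclusive", k_incl, config.cr_variants_mean
            ),
            "young_shared": make_pool(
                chain, "inclusive", k_young, config.cr_variants_mean
            ),
        }
        p = config.carrier_prob
        for aa in pools[chain]["exclusive_case"]:
            carriers[aa] = _draw_carriers(rng, case_ids, p, 2)
        for aa in pools[chain]["exclusive_control"]:
            carriers[aa] = _draw_carriers(rng, control_ids, p, 2)
        for aa in pools[chain]["inclusive"] + pools[chain]["young_shared"]:
            carriers[aa] = _draw_carriers(rng, control_ids, p, 1) + _draw_carriers(
                rng, case_ids, p, 1
            )
    truth.pools = pools

    # subject-private clones, persistent across that subject's timepoints
    n_private = n - k_case - k_ctrl - k_incl - k_young
    privates: dict[tuple[str, str], list[str]] = {}
    for chain in config.chains:
        for sid, _ in design.subjects:
            plist = []
            for _ in range(n_private):
                aa = _random_aa(rng, used_aa)
                variants = _nt_variants(rng, aa, 1)
                truth.labels[aa] = "private"
                truth.nt_sets[aa] = {"mouse": variants, "human": []}
                plist.append(aa)
            privates[(chain, sid)] = plist

    samples: list[RepertoireSample] = []
    for chain in config.chains:
        for sid, grp in design.subjects:
            sample_aas = [
                aa
                for pool_name in ("exclusive_case", "exclusive_control", "inclusive")
                for aa in pools[chain][pool_name]
                if sid in carriers[aa]
            ]
            young_aas = [
                aa for aa in pools[chain]["young_shared"] if sid in carriers[aa]
            ]
            for tp in design.timepoints:
                aas = list(sample_aas)
                if tp in design.young_timepoints:
                    aas += young_aas
                aas += privates[(chain, sid)]
                sample = RepertoireSample(
                    sample_id=f"{sid}_t{tp}_{chain}",
                    subject_id=sid,
                    group=grp,
                    timepoint=tp,
                    chain=chain,
                )
                clone_rows: list[tuple[str, str]] = []
                for aa in aas:
                    for nt in truth.nt_sets[aa]["mouse"]:
                        clone_rows.append((nt, aa))
                counts = _zipf_counts(
                    rng,
                    len(clone_rows),
                    config.abundance_exponent,
                    config.max_clone_count,
                )
                for (nt, aa), cnt in zip(clone_rows, counts):
                    sample.add_clone(
                        Clone(junction_nt=nt, junction_aa=aa, duplicate_count=int(cnt))
                    )
                samples.append(sample)
    return samples, truth


# ---------------------------------------------------------------------------
# human cohorts


def _fresh_human_aa(
    rng: np.random.Generator, truth: TruthManifest, used: set[str]
) -> str:
    aa = _random_aa(rng, used)
    nt = _nt_variants(rng, aa, 1)
    truth.labels.setdefault(aa, "human-private")
    truth.nt_sets[aa] = {"mouse": [], "human": nt}
    return aa


def generate_human_cohorts(
    config: SimulationConfig, truth: TruthManifest
) -> tuple[dict[str, list[RepertoireSample]], dict[str, list[RepertoireSample]], dict[str, pd.DataFrame]]:
    """Generate bulk human datasets, a staged cohort, and score tables.

    A ``cross_species_frac`` share of the planted public mouse beta AAs
    is injected into every human sample through freshly drawn NT
    encodings disjoint from the mouse encodings.  The staged cohort
    carries stage labels i-iv with a stage-1-enriched sharing gradient
    (stage i shares ``stage_gradient`` times more than stage iv).
    """
    if truth is None or not truth.pools:
        raise ConfigError("truth manifest from generate_mouse_study required")
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    chain = "beta" if "beta" in config.chains else config.chains[0]
    mouse_public = [
        aa
        for pool_name in ("exclusive_case", "exclusive_control", "inclusive")
        for aa in truth.pools[chain][pool_name]
    ]
    n_cross = round(config.cross_species_frac * len(mouse_public))
    cross = [mouse_public[i] for i in rng.permutation(len(mouse_public))[:n_cross]]
    truth.cross_species = sorted(cross)
    for aa in cross:
        if aa not in truth.labels or truth.labels[aa] == "private":
            truth.labels[aa] = "cross-species"
        k = _n_variants(rng, config.cr_variants_mean)
        truth.nt_sets[aa]["human"] = _nt_variants(
            rng, aa, k, forbidden=set(truth.nt_sets[aa]["mouse"])
        )

    used_aa = set(truth.labels)

    def build_sample(sample_id: str, shared_aas: list[str], tissue: str = "tumor"):
        sample = RepertoireSample(
            sample_id=sample_id,
            subject_id=sample_id,
            group="case",
            timepoint=None,
            chain=chain,
            tissue=tissue,
        )
        n_fill = max(config.human_clones_per_sample - len(shared_aas), 0)
        aas = list(shared_aas) + [
            _fresh_human_aa(rng, truth, used_aa) for _ in range(n_fill)
        ]
        rows = [(nt, aa) for aa in aas for nt in truth.nt_sets[aa]["human"]]
        counts = _zipf_counts(
            rng, len(rows), config.abundance_exponent, config.max_clone_count
        )
        for (nt, aa), cnt in zip(rows, counts):
            sample.add_clone(
                Clone(junction_nt=nt, junction_aa=aa, duplicate_count=int(cnt))
            )
        return sample

    bulk = {
        name: [
            build_sample(f"{name}_s{i + 1}", cross)
            for i in range(config.n_human_samples)
        ]
        for name in BULK_DATASET_NAMES
    }

    # staged cohort with a monotone stage-1-enriched sharing gradient
    staged: dict[str, list[RepertoireSample]] = {}
    g = config.stage_gradient
    shares = [
        config.stage_share_max * g ** (-i / (len(STAGES) - 1)) for i in range(len(STAGES))
    ]
    for stage, n_cases, share in zip(STAGES, config.stage_cases, shares):
        cases = []
        for i in range(n_cases):
            k = round(share * len(mouse_public))
            idx = rng.permutation(len(mouse_public))[:k]
            shared = [mouse_public[j] for j in idx]
            for aa in shared:  # human encodings for stage-shared AAs on demand
                if not truth.nt_sets[aa]["human"]:
                    truth.nt_sets[aa]["human"] = _nt_variants(
                        rng, aa, 1, forbidden=set(truth.nt_sets[aa]["mouse"])
                    )
            cases.append(build_sample(f"stage{stage}_case{i + 1}", shared))
        staged[stage] = cases

    # per-sequence score tables: generation probability (log-normal) and a
    # binding-style score shifted upward for the cross-species set
    all_aas = sorted(used_aa)
    pgen = pd.DataFrame(
        {
            "sequence": all_aas,
            "score": np.exp(rng.normal(-25.0, 3.0, size=len(all_aas))),
        }
    )
    cross_set = set(cross)
    binding = pd.DataFrame(
        {
            "sequence": all_aas,
            "score": rng.normal(0.0, 1.0, size=len(all_aas))
            + np.array(
                [config.binding_shift if a in cross_set else 0.0 for a in all_aas]
            ),
        }
    )
    return bulk, staged, {"pgen": pgen, "binding": binding}


# ---------------------------------------------------------------------------
# single cell


def generate_single_cell(
    config: SimulationConfig,
    truth: TruthManifest,
    mouse_samples: list[RepertoireSample] | None = None,
) -> pd.DataFrame:
    """Per-cell chain-call table (cell_id, chain, junction_aa, junction_nt).

    ``sc_matchable_frac`` of the cells carry an alpha-beta pair whose two
    chains are both present in the planted inclusive pools (hence in the
    mouse samples); ``sc_multichain_frac`` carry a second alpha call to
    exercise the multichain filter.  Planted matchable pairs are recorded
    in ``truth.planted_pairs``.
    """
    config.validate()
    if truth is None or not truth.pools:
        raise ConfigError("truth manifest from generate_mouse_study required")
    rng = np.random.default_rng(config.seed + 2)
    alpha_pool = truth.pools.get("alpha", {}).get("inclusive", [])
    beta_pool = truth.pools.get("beta", {}).get("inclusive", [])
    n_match = round(config.sc_matchable_frac * config.sc_cells)
    if n_match > 0 and (not alpha_pool or not beta_pool):
        raise ConfigError("matchable pairs need alpha and beta inclusive pools")

    used_aa = set(truth.labels)
    rows: list[dict] = []
    truth.planted_pairs = []
    n_multi = round(config.sc_multichain_frac * config.sc_cells)
    for i in range(config.sc_cells):
        cell = f"cell{i + 1:04d}"
        if i < n_match:
            a = alpha_pool[int(rng.integers(len(alpha_pool)))]
            b = beta_pool[int(rng.integers(len(beta_pool)))]
            truth.planted_pairs.append((a, b))
        else:
            a = _random_aa(rng, used_aa)
            b = _random_aa(rng, used_aa)
            truth.nt_sets[a] = {"mouse": [], "human": _nt_variants(rng, a, 1)}
            truth.nt_sets[b] = {"mouse": [], "human": _nt_variants(rng, b, 1)}
            truth.labels[a] = truth.labels[b] = "human-private"
        nt_a = truth.nt_sets[a]["human"] or truth.nt_sets[a]["mouse"]
        nt_b = truth.nt_sets[b]["human"] or truth.nt_sets[b]["mouse"]
        rows.append(
            {"cell_id": cell, "chain": "alpha", "junction_aa": a, "junction_nt": nt_a[0]}
        )
        rows.append(
            {"cell_id": cell, "chain": "beta", "junction_aa": b, "junction_nt": nt_b[0]}
        )
        if i >= n_match and i < n_match + n_multi:
            extra = _random_aa(rng, used_aa)
            truth.nt_sets[extra] = {"mouse": [], "human": _nt_variants(rng, extra, 1)}
            truth.labels[extra] = "human-private"
            rows.append(
                {
                    "cell_id": cell,
                    "chain": "alpha",
                    "junction_aa": extra,
                    "junction_nt": truth.nt_sets[extra]["human"][0],
                }
            )
    return pd.DataFrame(rows, columns=["cell_id", "chain", "junction_aa", "junction_nt"])
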