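"""End-to-end orchestration: simulate -> load -> pool -> subsample ->
publicness/CR -> cross-species -> networks -> single cell -> report.

The pipeline is a pure function of (inputs, config, seed): rerunning
with an identical configuration produces byte-identical outputs.  Each
stage writes its tables under the output directory and contributes to a
JSON summary.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import cross_species as xs
from . import io as rio
from . import networks as nets
from . import publicness as pub
from . import simulate as sim
from . import single_cell as sc
from .errors import TcrShareError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "results/pipeline"
    seed: int = 0
    sim: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    subsample_frac: float = 0.8  # of the shallowest subject pool, per chain
    min_count: int = 1
    weighting: str = "unique"
    min_samples: int = 4
    alpha: float = 0.05
    d_max: int = 2
    sc_d_max: int = 3
    n_random: int = 100
    n_iter: int = 200
    top_n: int = 10_000

    def __post_init__(self) -> None:
        if not 0 < self.subsample_frac <= 1:
            raise TcrShareError("subsample_frac must lie in (0, 1]")
        if self.alpha < 0 or self.alpha > 1:
            raise TcrShareError("alpha must lie in [0, 1]")


def _stage(report: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            report.setdefault("stages", {}).setdefault(name, {})
            logger.info("stage %s started", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                report["stages"][name]["seconds"] = round(dt, 3)
                logger.info("stage %s finished in %.2fs", name, dt)
            else:
                logger.error("stage %s failed: %s", name, exc)
            return False

    return _Timer()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on a synthetic study and write all outputs.

    Returns the report dictionary (also written to ``summary.json``).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.sim.seed = config.seed
    report: dict = {"config": {"seed": config.seed, "outdir": str(out)}}

    with _stage(report, "simulate"):
        mouse_samples, truth = sim.generate_mouse_study(config.sim)
        bulk, staged, scores = sim.generate_human_cohorts(config.sim, truth)
        sc_table = sim.generate_single_cell(config.sim, truth, mouse_samples)
        rio.write_airr_table(mouse_samples, out / "mouse_repertoires.tsv")
        truth.to_json(out / "truth_manifest.json")
        sc_table.to_csv(out / "single_cell_calls.tsv", sep="\t", index=False)
        design = sim.default_design(config.sim)
        report["stages"]["simulate"].update(
            n_mouse_samples=len(mouse_samples),
            n_human_datasets=len(bulk),
            n_cells=int(sc_table["cell_id"].nunique()),
        )

    with _stage(report, "pool_subsample"):
        pools: dict[str, list[rio.RepertoireSample]] = {}
        for chain in config.sim.chains:
            chain_pools = []
            for sid, _grp in design.subjects:
                subject_samples = [
                    s
                    for s in mouse_samples
                    if s.subject_id == sid and s.chain == chain
                ]
                chain_pools.append(rio.pool_subject(subject_samples))
            depth = int(
                config.subsample_frac * min(p.total_reads for p in chain_pools)
            )
            pools[chain] = [
                rio.subsample_repertoire(p, depth, config.seed + i)
                for i, p in enumerate(chain_pools)
            ]
            report["stages"]["pool_subsample"][f"depth_{chain}"] = depth

    with _stage(report, "publicness_cr"):
        for chain in config.sim.chains:
            records = pub.classify_publicness(
                pools[chain], design, min_count=config.min_count
            )
            fractions = pub.publicness_fractions(
                records, pools[chain], weighting=config.weighting
            )
            fractions.to_csv(
                out / f"publicness_fractions_{chain}.tsv", sep="\t", index=False
            )
            pd.DataFrame(
                [
                    {
                        "junction_aa": r.junction_aa,
                        "n_control_subjects": r.n_control_subjects,
                        "n_case_subjects": r.n_case_subjects,
                        "label": r.label,
                    }
                    for r in records
                ]
            ).to_csv(out / f"publicness_{chain}.tsv", sep="\t", index=False)
            crs = pub.cr_levels(pools[chain])
            pd.DataFrame(
                [
                    {"junction_aa": r.junction_aa, "cr_level": r.cr_level}
                    for r in crs
                ]
            ).to_csv(out / f"cr_levels_{chain}.tsv", sep="\t", index=False)
            case_frac = fractions.loc[
                fractions["group"] == "case", "public_exclusive_case"
            ]
            ctrl_frac = fractions.loc[
                fractions["group"] == "control", "public_exclusive_case"
            ]
            t, dof, p = pub.welch_ttest(ctrl_frac, case_frac)
            assoc = pub.cr_publicness_association(pools[chain], design)
            report["stages"]["publicness_cr"][chain] = {
                "exclusive_case_fraction_case": float(case_frac.mean()),
                "exclusive_case_fraction_control": float(ctrl_frac.mean()),
                "welch_p": p,
                "cr_sharing_lr_p": assoc["p_value"],
            }
        overlap = pub.grouped_overlap_matrix(
            [s for s in mouse_samples if s.chain == config.sim.chains[-1]], design
        )
        overlap.to_csv(out / "grouped_overlap.tsv", sep="\t")

    with _stage(report, "cross_species"):
        chain = "beta" if "beta" in config.sim.chains else config.sim.chains[0]
        quantifier = xs.Quantifier(min_mouse_samples=1, human_requirement="all")
        cross = xs.build_cross_species_set(pools[chain], bulk, quantifier)
        cross.provenance.to_csv(out / "cross_species_set.tsv", sep="\t", index=False)
        staged_sets = {
            stage: [s.aa_set() for s in cases] for stage, cases in staged.items()
        }
        stage_rows = []
        for p in pools[chain]:
            for rec in xs.stage_similarity(p, staged_sets):
                stage_rows.append(
                    {
                        "sample_id": rec.sample_id,
                        "stage": rec.stage,
                        "shared_count": rec.shared_count,
                        "similarity": rec.similarity,
                    }
                )
        pd.DataFrame(stage_rows).to_csv(
            out / "stage_similarity.tsv", sep="\t", index=False
        )
        case_tp = [
            s for s in mouse_samples if s.chain == chain and s.group == "case"
        ]
        young = [s for s in case_tp if s.timepoint in design.young_timepoints]
        old = [s for s in case_tp if s.timepoint in design.old_timepoints]
        candidates, significant = xs.select_highly_abundant(
            young, old, min_samples=config.min_samples, alpha=config.alpha
        )
        null_p = None
        if significant:
            null = xs.resampling_null(
                significant,
                candidates,
                [s for cohort in bulk.values() for s in cohort],
                n_iter=config.n_iter,
                seed=config.seed,
            )
            null_p = null["p_value"]
        report["stages"]["cross_species"].update(
            n_members=len(cross.members),
            n_abundant_candidates=len(candidates),
            n_abundant_significant=len(significant),
            abundant_null_p=null_p,
            stage_mean_similarity={
                stage: float(
                    pd.DataFrame(stage_rows)
                    .query("stage == @stage")["similarity"]
                    .mean()
                )
                for stage in staged_sets
            },
        )

    with _stage(report, "networks"):
        chain = "beta" if "beta" in config.sim.chains else config.sim.chains[0]
        case_samples = [
            s for s in mouse_samples if s.chain == chain and s.group == "case"
        ]
        pool_seqs = nets.top_n_pool(case_samples, n=config.top_n)
        focal = sorted(cross.members)[:2] if cross.members else pool_seqs[:2]
        nbr = nets.neighborhood_vs_random(
            focal,
            pool_seqs,
            n_random=config.n_random,
            d_max=config.d_max,
            seed=config.seed,
        )
        network = nets.build_distance_network(pool_seqs[:200], d_max=config.d_max)
        network.edge_table().to_csv(
            out / "distance_network_edges.tsv", sep="\t", index=False
        )
        report["stages"]["networks"].update(
            focal=focal,
            focal_counts=nbr["focal_counts"],
            baseline_mean=nbr["baseline_mean"],
            n_components=len(network.components),
        )

    with _stage(report, "single_cell"):
        pairs, dropped = sc.assemble_pairs(sc_table)
        match = sc.match_pairs_to_samples(
            pairs, pools.get("alpha", []), pools.get("beta", [])
        )
        part = sc.pair_group_partition(
            match["shared"], match["groups"], d_max=config.sc_d_max
        )
        pd.DataFrame(
            [
                {"subset": name, "alpha_aa": a, "beta_aa": b}
                for name, plist in part["partition"].items()
                for a, b in plist
            ]
        ).to_csv(out / "pair_partition.tsv", sep="\t", index=False)
        report["stages"]["single_cell"].update(
            n_pairs=len(pairs),
            n_unique_pairs=len(sc.unique_pairs(pairs)),
            dropped=dict(dropped),
            n_unique_shared_pairs=match["n_unique_shared_pairs"],
            group_means=match["group_means"],
            partition_sizes={k: len(v) for k, v in part["partition"].items()},
        )

    (out / "summary.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def config_from_dict(d: dict) -> RunConfig:
    sim_cfg = sim.SimulationConfig(**d.pop("sim", {}))
    cfg = RunConfig(sim=sim_cfg, **d)
    return cfg


def load_config(path: str | Path) -> RunConfig:
    return config_from_dict(json.loads(Path(path).read_text()))


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    d = asdict(cfg)
    Path(path).write_text(json.dumps(d, indent=2, default=str))
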