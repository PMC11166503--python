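"""Seed-reproducible orchestration: simulate -> decode -> stats -> RSA.

A :class:`RunConfig` fully determines a run; every stochastic stage
receives a seed derived from the master seed, stage outputs are written
under the run directory, and a manifest records per-stage seeds, outputs
and checksums so that re-running an identical config is byte-verifiable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import behavior as bh
from . import cluster_stats as cs
from .decoding import (
    DecodeSpec,
    condition_spec,
    decode_timecourse,
    item_spec,
    pairwise_item_decode,
    pca_reduce,
)
from .epochs import save_behavior, subsample_to_match
from .rsa import average_subjective_rdm, rsa_timecourse
from .searchlight import build_neighbors, searchlight_decode
from .synth import (
    SimulationConfig,
    simulate_behavior,
    simulate_participant,
    simulate_subjective_ratings,
)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on (round-trips through YAML)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_perm: int = 200
    cluster_alpha: float = 0.05
    step_ms: float = 40.0
    n_iterations: int = 3
    n_components: int = 15
    stats_window: tuple[float, float] = (0.0, 3000.0)
    do_behavior: bool = True
    do_condition: bool = True
    do_item: bool = True
    do_searchlight: bool = False
    do_rsa: bool = True
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["simulation"]["epoch_window"] = list(self.simulation.epoch_window)
        d["stats_window"] = list(self.stats_window)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim = d.pop("simulation", {})
        sim["epoch_window"] = tuple(sim.get("epoch_window", (-1000.0, 3500.0)))
        d["stats_window"] = tuple(d.get("stats_window", (0.0, 3000.0)))
        return cls(simulation=SimulationConfig(**sim), **d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the enabled stages in dependency order.

    Writes per-stage outputs, ``manifest.json`` (stage, seed, outputs with
    SHA-256 checksums, wall time) and a human-readable ``report.md`` of
    the headline statistics.  Returns the run directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest, report = [], []
    sim = config.simulation

    def record(stage, seed, outputs, t0):
        manifest.append(
            {
                "stage": stage,
                "seed": seed,
                "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
                "wall_s": round(time.perf_counter() - t0, 3),
            }
        )

    def run_stage(stage, fn):
        t0 = time.perf_counter()
        seed = _stage_seed(config.seed, stage)
        try:
            outputs = fn(seed)
        except Exception as err:
            raise PipelineError(f"stage {stage!r} failed: {err}") from err
        record(stage, seed, outputs, t0)

    # -- simulate ----------------------------------------------------------
    state: dict = {}

    def stage_simulate(seed):
        sim_seeded = replace(sim, seed=seed)
        pairs = [
            simulate_participant(sim_seeded, pid)
            for pid in range(sim.n_participants)
        ]
        state["epochs"] = [p[0] for p in pairs]
        state["truths"] = [p[1] for p in pairs]
        state["sim_seeded"] = sim_seeded
        paths = []
        for pid, truth in enumerate(state["truths"]):
            p = out / f"truth_p{pid:02d}.json"
            truth.to_json(p)
            paths.append(p)
        return paths

    run_stage("simulate", stage_simulate)

    # -- behavior ----------------------------------------------------------
    if config.do_behavior:

        def stage_behavior(seed):
            table = simulate_behavior(state["truths"], state["sim_seeded"])
            state["behavior"] = table
            path = out / "behavior.csv"
            save_behavior(table, path)
            wide = table.pivot(index="participant", columns="condition", values="detail")
            anova = bh.rm_anova_gg(wide[["Think", "NoThink", "Baseline"]].to_numpy())
            contrast = bh.paired_t_dz(
                wide["NoThink"].to_numpy(), wide["Baseline"].to_numpy()
            )
            report.append(f"Detail ANOVA: {anova}")
            report.append(f"No-Think vs Baseline Detail: {contrast}")
            stats_path = out / "behavior_stats.json"
            stats_path.write_text(
                json.dumps({"anova": asdict(anova), "nt_vs_bl": asdict(contrast)})
            )
            return [path, stats_path]

        run_stage("behavior", stage_behavior)

    # -- features ----------------------------------------------------------
    features = [
        pca_reduce(e, n_components=config.n_components) for e in state["epochs"]
    ]

    def _report_clusters(label, res):
        sig = res.significant()
        if not sig:
            report.append(f"{label}: no significant clusters")
        for c in sig:
            t0c, t1c = res.times[c.indices.min()], res.times[c.indices.max()]
            report.append(
                f"{label}: cluster {t0c:.0f}-{t1c:.0f} ms, mass {c.mass:.1f}, p = {c.p:.4f}"
            )

    # -- condition decoding ------------------------------------------------
    if config.do_condition:

        def stage_condition(seed):
            spec = condition_spec(
                step_ms=config.step_ms, n_iterations=config.n_iterations
            )
            results = []
            for pid, epo in enumerate(state["epochs"]):
                sub = subsample_to_match(
                    epo, "Think", "PerceptualBaseline", seed=[seed, 2, pid]
                )
                sub = subsample_to_match(
                    sub, "NoThink", "PerceptualBaseline", seed=[seed, 3, pid]
                )
                feats = pca_reduce(sub, n_components=config.n_components)
                keep = feats.trial_table["condition"].isin(["Think", "PerceptualBaseline"]).to_numpy()
                feats_tp = replace(
                    feats,
                    data=feats.data[keep],
                    trial_table=feats.trial_table[keep].reset_index(drop=True),
                )
                results.append(
                    decode_timecourse(feats_tp, spec, seed=[seed, 1, pid])
                )
            res = cs.perm_test_vs_chance(
                results, n_perm=config.n_perm,
                cluster_alpha=config.cluster_alpha, window=config.stats_window,
                seed=[seed, 99],
            )
            _report_clusters("Think vs PerceptualBaseline decoding vs 50%", res)
            path = out / "condition_clusters.json"
            path.write_text(_clusters_json(res))
            return [path]

        run_stage("condition_decoding", stage_condition)

    # -- item decoding -----------------------------------------------------
    item_results: dict[str, list] = {}
    if config.do_item or config.do_rsa:

        def stage_item(seed):
            spec = item_spec(step_ms=config.step_ms, n_iterations=config.n_iterations)
            paths = []
            for cond in ("Think", "NoThink", "PerceptualBaseline"):
                results = []
                for pid, feats in enumerate(features):
                    keep = (feats.trial_table["condition"] == cond).to_numpy()
                    f_c = replace(
                        feats,
                        data=feats.data[keep],
                        trial_table=feats.trial_table[keep].reset_index(drop=True),
                    )
                    results.append(decode_timecourse(f_c, spec, seed=[seed, 1, pid]))
                item_results[cond] = results
                res = cs.perm_test_vs_chance(
                    results, n_perm=config.n_perm,
                    cluster_alpha=config.cluster_alpha,
                    window=config.stats_window, seed=[seed, 98],
                )
                state[f"item_clusters_{cond}"] = res
                _report_clusters(f"{cond} item decoding vs chance", res)
                path = out / f"item_clusters_{cond}.json"
                path.write_text(_clusters_json(res))
                paths.append(path)
            return paths

        run_stage("item_decoding", stage_item)

    # -- searchlight -------------------------------------------------------
    if config.do_searchlight:

        def stage_searchlight(seed):
            graph = build_neighbors(state["epochs"][0].montage)
            spec = item_spec(n_iterations=config.n_iterations)
            paths = []
            for window, tag in (((0.0, 500.0), "early"), ((500.0, 3000.0), "late")):
                maps = []
                for pid, epo in enumerate(state["epochs"]):
                    think = epo.select_condition("Think")
                    maps.append(
                        searchlight_decode(
                            think, graph, spec, window=window, seed=[seed, 1, pid]
                        ).values
                    )
                arr = np.stack(maps)
                path = out / f"searchlight_think_{tag}.csv"
                np.savetxt(path, arr, delimiter=",")
                report.append(
                    f"Think searchlight {tag}: peak channel "
                    f"{graph.channel_names[int(arr.mean(0).argmax())]}"
                )
                paths.append(path)
            return paths

        run_stage("searchlight", stage_searchlight)

    # -- RSA ---------------------------------------------------------------
    if config.do_rsa:

        def stage_rsa(seed):
            spec = item_spec(step_ms=config.step_ms, n_iterations=config.n_iterations)
            _, conceptual = simulate_subjective_ratings(
                state["truths"][0], state["sim_seeded"], condition="Think"
            )
            sub_rdm = average_subjective_rdm(conceptual, direction="similarity")
            rhos = []
            for pid, feats in enumerate(features):
                keep = (feats.trial_table["condition"] == "Think").to_numpy()
                f_c = replace(
                    feats,
                    data=feats.data[keep],
                    trial_table=feats.trial_table[keep].reset_index(drop=True),
                )
                series = pairwise_item_decode(f_c, spec, seed=[seed, 1, pid])
                tc = rsa_timecourse(series.rdm, sub_rdm, series.times)
                rhos.append(tc.rho)
            mean_rho = np.nanmean(np.stack(rhos), axis=0)
            path = out / "rsa_think_conceptual.csv"
            np.savetxt(path, np.column_stack([series.times, mean_rho]), delimiter=",")
            late = (series.times >= 500) & (series.times < 3000)
            report.append(
                f"Think conceptual RSA, mean rho 500-3000 ms: {np.nanmean(mean_rho[late]):.3f}"
            )
            return [path]

        run_stage("rsa", stage_rsa)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "report.md").write_text(
        "# Pipeline report\n\n" + "\n".join(f"- {line}" for line in report) + "\n"
    )
    return out


def _clusters_json(res) -> str:
    return json.dumps(
        {
            "n_permutations": res.n_permutations,
            "cluster_alpha": res.cluster_alpha,
            "threshold": res.threshold,
            "clusters": [
                {
                    "indices": np.asarray(c.indices).ravel().tolist(),
                    "mass": c.mass,
                    "p": c.p,
                    "sign": c.sign,
                }
                for c in res.clusters
            ],
        }
    )
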