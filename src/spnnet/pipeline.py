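"""End-to-end orchestration: epochs -> connectivity -> exclusion ->
group networks -> thresholding -> metrics -> communities -> hubs ->
group comparisons, with every artifact written to disk and a run log
tying all numbers to the config and master seed."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .community import (
    match_partitions,
    optimize_modularity,
    partition_distance,
)
from .connectivity import (
    build_connectivity_matrix,
    mean_connectivity_strength,
    tukey_fence_outliers,
)
from .exports import (
    brainnet_exports,
    write_graph_bundle,
    write_matrix_tsv,
    write_node_metrics_tsv,
    write_partition_tsv,
    write_profiles_tsv,
)
from .hubs import classify_nodes, hub_census, hub_homogeneity_test
from .io import (
    CONDITIONS,
    extract_condition_epochs,
    read_atlas,
    read_events,
    read_timeseries,
)
from .metrics import network_summary, node_metrics
from .network import group_average, percolation_threshold
from .stats import compare_networks
from .synthetic import Cohort

logger = logging.getLogger(__name__)

GROUPS = ("groupA", "groupB")


@dataclass
class PipelineConfig:
    """All tunable parameters of one pipeline run.

    Round-trips losslessly through YAML. Defaults follow the analysis
    conventions the pipeline implements: 20,000 permutation
    randomizations, 100 modularity restarts, 1 / 1.5 SD hub and pillar
    cutoffs, a 30% high-influence band and a 10%-of-maximum connector
    cutoff.
    """

    data_dir: str = ""
    atlas_path: str = ""
    out_dir: str = "out"
    n_bins: int | None = None
    trs_per_trial: int = 4
    hub_sd: float = 1.0
    pillar_sd: float = 1.5
    top_pct: float = 30.0
    connector_frac: float = 0.10
    n_modularity_runs: int = 100
    n_permutations: int = 20000
    n_subject_permutations: int = 200
    n_partition_permutations: int = 0
    permutation_unit: str = "node"
    tukey_k: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trs_per_trial < 1 or self.n_modularity_runs < 1:
            raise ValueError("trs_per_trial and n_modularity_runs must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.top_pct <= 100:
            raise ValueError("top_pct must lie in (0, 100]")
        if not 0 <= self.connector_frac <= 1:
            raise ValueError("connector_frac must lie in [0, 1]")
        if self.tukey_k < 0 or self.hub_sd < 0 or self.pillar_sd < 0:
            raise ValueError("SD multipliers and tukey_k must be nonnegative")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_subjects(data_dir: str | Path) -> Cohort:
    """Read a cohort from disk.

    Subject files follow ``<id>_timeseries.tsv`` / ``<id>_events.tsv`` /
    optional ``<id>_censor.txt``; ids beginning ``g0``/``g1`` assign the
    two groups (the convention the synthetic writer uses).
    """
    data_dir = Path(data_dir)
    groups: tuple[list, list] = ([], [])
    for ts_path in sorted(data_dir.glob("*_timeseries.tsv")):
        sid = ts_path.name[: -len("_timeseries.tsv")]
        censor = data_dir / f"{sid}_censor.txt"
        ts = read_timeseries(
            ts_path, censor_path=censor if censor.exists() else None, subject_id=sid
        )
        events = read_events(data_dir / f"{sid}_events.tsv")
        if sid.startswith("g0"):
            groups[0].append((ts, events))
        elif sid.startswith("g1"):
            groups[1].append((ts, events))
        else:
            raise ValueError(
                f"cannot infer group for subject {sid!r}: id must start with g0/g1"
            )
    if not groups[0] or not groups[1]:
        raise ValueError(f"{data_dir}: need subjects in both groups")
    manifest_path = data_dir / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    return Cohort(group_a=groups[0], group_b=groups[1], manifest=manifest)


def subject_connectivity(cohort: Cohort, config: PipelineConfig) -> dict:
    """Per-subject, per-condition NMI matrices, keyed (group, condition)."""
    out: dict[tuple[str, str], list] = {}
    for gname, subjects in zip(GROUPS, (cohort.group_a, cohort.group_b)):
        for condition in CONDITIONS:
            mats = []
            for ts, events in subjects:
                epochs = extract_condition_epochs(
                    ts, events, condition, trs_per_trial=config.trs_per_trial
                )
                mats.append(
                    build_connectivity_matrix(
                        epochs,
                        n_bins=config.n_bins,
                        label=ts.subject_id,
                        condition=condition,
                        node_ids=list(ts.roi_ids),
                    )
                )
            out[(gname, condition)] = mats
    return out


def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None) -> dict:
    """Execute every stage and write the output bundle.

    Returns a results dictionary holding the thresholded graphs, metric
    summaries, partitions, hub censuses and statistical comparisons; the
    same content is persisted under ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort = load_subjects(config.data_dir)
    atlas = read_atlas(config.atlas_path) if config.atlas_path else None

    ss = np.random.SeedSequence(config.seed)
    seeds = iter(int(s) for s in ss.generate_state(64))

    matrices = subject_connectivity(cohort, config)

    from . import __version__ as pkg_version

    log: dict = {
        "spnnet_version": pkg_version,
        "config_digest": config.digest(),
        "master_seed": config.seed,
        "exclusions": {},
        "thresholds": {},
    }
    results: dict = {"config": config, "log": log}
    graphs, summaries, partitions, profiles, censuses = {}, {}, {}, {}, {}

    ref_key = (GROUPS[0], CONDITIONS[0])
    for key, mats in matrices.items():
        gname, condition = key
        strengths = [mean_connectivity_strength(m) for m in mats]
        excluded_idx = (
            tukey_fence_outliers(np.array(strengths), k=config.tukey_k)
            if len(strengths) >= 4
            else set()
        )
        excluded = {mats[i].label for i in excluded_idx}
        if excluded:
            logger.info("%s/%s: excluding outlier subjects %s", gname, condition,
                        sorted(excluded))
        log["exclusions"]["/".join(key)] = sorted(excluded)
        avg = group_average(mats, excluded=excluded, label=gname, condition=condition)
        graph = percolation_threshold(avg)
        log["thresholds"]["/".join(key)] = {
            "tau": graph.provenance["threshold"],
            "density": graph.density,
        }
        graphs[key] = graph
        summaries[key] = network_summary(graph)
        partitions[key] = optimize_modularity(
            graph, n_runs=config.n_modularity_runs, seed=next(seeds)
        )

    for key in matrices:
        if key != ref_key:
            partitions[key] = match_partitions(partitions[ref_key], partitions[key])
        profiles[key] = classify_nodes(
            graphs[key],
            partitions[key],
            hub_sd=config.hub_sd,
            top_pct=config.top_pct,
            connector_frac=config.connector_frac,
            pillar_sd=config.pillar_sd,
        )
        censuses[key] = hub_census(profiles[key], provenance={"network": "/".join(key)})

    # Pairwise contrasts: between groups per condition, between conditions per group.
    pairs = [
        ((GROUPS[0], c), (GROUPS[1], c)) for c in CONDITIONS
    ] + [
        ((g, CONDITIONS[0]), (g, CONDITIONS[1])) for g in GROUPS
    ]
    comparisons, distances, chi2_tests = {}, {}, {}
    for ka, kb in pairs:
        name = "/".join(ka) + "_vs_" + "/".join(kb)
        comparisons[name] = compare_networks(
            graphs[ka], graphs[kb],
            unit="node", n_perm=config.n_permutations, seed=next(seeds),
        )
        comparisons[name] += compare_networks(
            graphs[ka], graphs[kb],
            metrics=("density", "global_efficiency"),
            unit="subject",
            n_perm=config.n_subject_permutations,
            seed=next(seeds),
            matrices_a=matrices[ka],
            matrices_b=matrices[kb],
        )
        distances[name] = partition_distance(partitions[ka], partitions[kb])
        try:
            chi2_tests[name] = hub_homogeneity_test(censuses[ka], censuses[kb])
        except ValueError as exc:
            chi2_tests[name] = ("degenerate", str(exc))

    results.update(
        graphs=graphs, summaries=summaries, partitions=partitions,
        profiles=profiles, censuses=censuses, comparisons=comparisons,
        partition_distances=distances, hub_tests=chi2_tests,
    )

    # ---- persist -------------------------------------------------------
    for key in matrices:
        stem = out_dir / ("_".join(key))
        write_matrix_tsv(graphs[key], stem.with_suffix(".weights.tsv"))
        write_graph_bundle(graphs[key], stem)
        write_node_metrics_tsv(node_metrics(graphs[key]), f"{stem}_node_metrics.tsv")
        write_partition_tsv(partitions[key], f"{stem}_partition.tsv")
        write_profiles_tsv(profiles[key], f"{stem}_profiles.tsv")
        (out_dir / f"{'_'.join(key)}_summary.json").write_text(
            json.dumps(summaries[key], indent=2)
        )
        if atlas is not None:
            brainnet_exports(atlas, graphs[key], partitions[key], profiles[key],
                             out_dir / ("_".join(key) + "_brainnet"))
    report = {
        "comparisons": {
            name: [dataclasses.asdict(c) for c in comps]
            for name, comps in comparisons.items()
        },
        "partition_distances": distances,
        "hub_homogeneity": {
            k: (list(v) if not isinstance(v, tuple) or v[0] != "degenerate" else v)
            for k, v in chi2_tests.items()
        },
        "hub_censuses": {"/".join(k): c.counts for k, c in censuses.items()},
    }
    (out_dir / "comparisons.json").write_text(json.dumps(report, indent=2, default=str))
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    config.to_yaml(out_dir / "config.yaml")
    return results
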