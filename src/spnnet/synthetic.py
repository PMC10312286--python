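"""Synthetic cohort generator with planted modular covariance and hub roles.

Subjects are simulated with a latent-factor linear-Gaussian model: each
module carries an independent latent signal per TR, and every node mixes
its own module's latent (within-module loading), a small shared leak of
the other latents (between-module loading) and white noise. Designated
connector nodes additionally load on several foreign modules, giving
them genuinely distributed connectivity; designated provincial-role
nodes carry only their own module's signal. A group-level attenuation
factor scales the second group's loadings down, mimicking a patient
cohort with globally weakened task connectivity.

The generator emits exactly the objects and on-disk formats the rest of
the pipeline consumes (ROI time series plus trial event tables on the
task's TR grid), so every stage — epoching, NMI estimation, thresholding,
community detection, hub classification, statistics — is exercised
end-to-end on data whose ground truth is known.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import CONDITIONS, EventTable, RoiTimeSeries, write_events, write_timeseries


@dataclass
class SyntheticSpec:
    """Parameters of the simulated study.

    Defaults emulate the study design the pipeline targets: 212 atlas
    ROIs in five covariance modules, a 23 + 14 subject cohort, two runs
    of 30 trials per condition on a 5-TR trial grid (TR = 2 s: 300 ms
    prime + 1,000 ms object + 8,700 ms interstimulus interval), and a
    4-TR analysis window per trial.
    """

    n_nodes: int = 212
    module_sizes: tuple[int, ...] = (45, 45, 42, 40, 40)
    n_subjects: tuple[int, int] = (23, 14)
    trials_per_condition: int = 30  # per run
    n_runs: int = 2
    trs_per_trial: int = 4
    trial_len_trs: int = 5
    latent_sd: float = 1.0
    noise_sd: float = 0.6
    within_loading: float = 1.0
    between_loading: float = 0.05
    connector_loading: float = 0.5
    n_connectors_per_module: int = 2
    n_cross_modules: int = 3
    group_attenuation: float = 0.0
    censor_fraction: float = 0.0
    p_correct: float = 1.0
    tr_seconds: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) != self.n_nodes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)}, not n_nodes={self.n_nodes}"
            )
        if any(m <= 0 for m in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if not 0 <= self.group_attenuation <= 1:
            raise ValueError("group_attenuation must lie in [0, 1]")
        for name in ("latent_sd", "noise_sd", "within_loading",
                     "between_loading", "connector_loading"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def trs_per_run(self) -> int:
        return 2 * self.trials_per_condition * self.trial_len_trs

    @property
    def total_trs(self) -> int:
        return self.n_runs * self.trs_per_run

    def module_labels(self) -> np.ndarray:
        """Planted module assignment, node index -> module index."""
        return np.repeat(np.arange(self.n_modules), self.module_sizes)

    def module_starts(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(self.module_sizes)[:-1]])

    def connector_nodes(self) -> np.ndarray:
        """Planted connector nodes: the first ``n_connectors_per_module``
        nodes of each module, which load on ``n_cross_modules`` foreign
        modules."""
        starts = self.module_starts()
        return np.concatenate(
            [np.arange(s, s + min(self.n_connectors_per_module, sz))
             for s, sz in zip(starts, self.module_sizes)]
        )

    def provincial_nodes(self) -> np.ndarray:
        """Planted provincial-role nodes: the block after the connectors
        in each module, carrying only their own module's latent."""
        starts = self.module_starts()
        out = []
        for s, sz in zip(starts, self.module_sizes):
            lo = s + min(self.n_connectors_per_module, sz)
            hi = min(s + 2 * self.n_connectors_per_module, s + sz)
            out.append(np.arange(lo, hi))
        return np.concatenate(out)

    def loading_matrix(self) -> np.ndarray:
        """(n_modules, n_nodes) latent-to-node loading matrix, group 1."""
        labels = self.module_labels()
        load = np.full((self.n_modules, self.n_nodes), self.between_loading)
        load[labels, np.arange(self.n_nodes)] = self.within_loading
        for i in self.provincial_nodes():
            load[:, i] = 0.0
            load[labels[i], i] = self.within_loading
        for i in self.connector_nodes():
            own = labels[i]
            cross = [(own + k) % self.n_modules
                     for k in range(1, self.n_cross_modules + 1)]
            load[cross, i] = self.connector_loading
        return load


def _make_events(spec: SyntheticSpec, rng: np.random.Generator) -> EventTable:
    """Trial grid: conditions alternate within each run, runs concatenated."""
    trials = []
    for run in range(spec.n_runs):
        offset = run * spec.trs_per_run
        for t in range(2 * spec.trials_per_condition):
            onset = offset + t * spec.trial_len_trs
            condition = CONDITIONS[t % 2]
            correct = bool(rng.random() < spec.p_correct)
            trials.append((onset, condition, correct))
    return EventTable(trials=trials)


def generate_subject(
    spec: SyntheticSpec, subject_index: int, group: int
) -> tuple[RoiTimeSeries, EventTable]:
    """Simulate one subject, reproducibly from (seed, group, subject index).

    Group 1 (index 1) has all loadings scaled by ``1 - group_attenuation``,
    which lowers its signal-to-noise ratio and hence its NMI connectivity.
    """
    if group not in (0, 1):
        raise ValueError("group must be 0 or 1")
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(group, subject_index))
    )
    t = spec.total_trs
    latents = rng.normal(0.0, spec.latent_sd, size=(t, spec.n_modules))
    load = spec.loading_matrix()
    if group == 1:
        load = load * (1.0 - spec.group_attenuation)
    noise = rng.normal(0.0, spec.noise_sd, size=(t, spec.n_nodes))
    data = latents @ load + noise
    censored: frozenset[int] = frozenset()
    if spec.censor_fraction > 0:
        n_censor = int(spec.censor_fraction * t)
        censored = frozenset(
            rng.choice(t, size=n_censor, replace=False).tolist()
        )
    events = _make_events(spec, rng)
    ts = RoiTimeSeries(
        subject_id=f"g{group}_s{subject_index:02d}",
        data=data,
        tr_seconds=spec.tr_seconds,
        roi_ids=[f"roi{j:03d}" for j in range(spec.n_nodes)],
        censored_trs=censored,
    )
    return ts, events


@dataclass
class Cohort:
    """Two simulated subject groups plus the generating manifest."""

    group_a: list[tuple[RoiTimeSeries, EventTable]]
    group_b: list[tuple[RoiTimeSeries, EventTable]]
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        """Write all subjects in the TSV formats the readers consume."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for subjects in (self.group_a, self.group_b):
            for ts, events in subjects:
                write_timeseries(ts, out / f"{ts.subject_id}_timeseries.tsv")
                write_events(events, out / f"{ts.subject_id}_events.tsv")
                if ts.censored_trs:
                    (out / f"{ts.subject_id}_censor.txt").write_text(
                        "\n".join(str(i) for i in sorted(ts.censored_trs)) + "\n"
                    )
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def generate_cohort(spec: SyntheticSpec) -> Cohort:
    """Simulate both groups; everything reproducible from ``spec.seed``."""
    group_a = [generate_subject(spec, i, 0) for i in range(spec.n_subjects[0])]
    group_b = [generate_subject(spec, i, 1) for i in range(spec.n_subjects[1])]
    manifest = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(spec).items()},
        "planted_modules": spec.module_labels().tolist(),
        "connector_nodes": spec.connector_nodes().tolist(),
        "provincial_nodes": spec.provincial_nodes().tolist(),
    }
    return Cohort(group_a=group_a, group_b=group_b, manifest=manifest)


def desk_spec(**overrides) -> SyntheticSpec:
    """Small preset for fast end-to-end runs: 60 nodes, 4 modules,
    8 subjects per group, one run of 24 trials per condition (240 TRs)."""
    params = dict(
        n_nodes=60,
        module_sizes=(15, 15, 15, 15),
        n_subjects=(8, 8),
        trials_per_condition=24,
        n_runs=1,
    )
    params.update(overrides)
    return SyntheticSpec(**params)
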