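"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates, at the matrix level, what the upstream imaging
pipeline would deliver: per-subject symmetric integer fiber-count networks
with small-world topology, subject-level weight variation partly explained
by nuisance covariates, and a planted disease effect — connections incident
to the affected regions (and any explicitly listed edges) are weakened by a
multiplicative factor in the patient group only.

Defaults mirror the study conditions the analysis is meant for: 26 patients
("AD") vs 16 controls ("NC"), 90 nodes, a ring-lattice topology with 10%
random rewiring at roughly 40% connection density, and integer weights of
mean ~40 floored at the 4-fiber presence threshold so that thresholding
never interacts with noise in effect-free cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .construction import DEFAULT_MIN_FIBERS, FiberRecord
from .cohort import Subject
from .matrices import ConnectivityMatrix

__all__ = [
    "CohortConfig",
    "generate_base_topology",
    "generate_cohort",
    "cohort_to_fiber_records",
]

#: Population centers used when applying covariate slopes (age yr,
#: education yr, intracranial volume mm^3, gender indicator).
_COVARIATE_CENTERS = {
    "age": 70.0,
    "gender": 0.5,
    "education": 10.0,
    "icv": 1.45e6,
}

_DEFAULT_COVARIATE_EFFECT = {
    "age": -0.004,  # log-weight units per year
    "gender": 0.0,
    "education": 0.005,  # per year of schooling
    "icv": 2.0e-7,  # per mm^3
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    ``effect_multiplier`` scales the weights of connections incident to
    ``affected_nodes`` (plus any ``affected_edges``) in the patient group;
    1.0 means no planted effect.  ``covariate_effect`` maps covariate names
    to slopes on log-weights, applied as a global per-subject scaling so
    the nuisance regression has real structure to remove.
    """

    n_ad: int = 26
    n_nc: int = 16
    n_nodes: int = 90
    topology: str = "smallworld"  # smallworld | random
    lattice_k: int = 36  # ring-lattice neighbors (even), ~40% density
    rewire_prob: float = 0.1
    base_weight_mean: float = 40.0
    weight_dispersion: float = 8.0  # negative-binomial size parameter
    noise_sd: float = 0.1  # per-edge lognormal sigma per subject
    min_fibers: int = DEFAULT_MIN_FIBERS
    affected_nodes: tuple[int, ...] = ()
    affected_edges: tuple[tuple[int, int], ...] = ()
    effect_multiplier: float = 1.0
    covariate_effect: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATE_EFFECT)
    )
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("an explicit integer seed is required")
        if self.n_ad < 2 or self.n_nc < 2:
            raise ValueError("each group needs at least 2 subjects")
        if not 0.0 < self.effect_multiplier <= 1.0:
            raise ValueError("effect_multiplier must be in (0, 1]")
        if self.topology not in ("smallworld", "random"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.lattice_k >= self.n_nodes:
            raise ValueError("lattice_k must be smaller than n_nodes")
        for idx in self.affected_nodes:
            if not 1 <= idx <= self.n_nodes:
                raise ValueError(f"affected node {idx} outside 1..{self.n_nodes}")
        for i, j in self.affected_edges:
            if not (1 <= i <= self.n_nodes and 1 <= j <= self.n_nodes):
                raise ValueError(
                    f"affected edge ({i}, {j}) outside 1..{self.n_nodes}"
                )


def generate_base_topology(config: CohortConfig) -> ConnectivityMatrix:
    """Template network shared by all subjects of a cohort.

    ``smallworld`` builds a ring lattice (``lattice_k`` neighbors) with
    random rewiring probability ``rewire_prob``; ``random`` builds a
    density-matched uniform random graph.  Present edges get integer
    weights from a negative-binomial count distribution with the
    configured mean and dispersion, floored at the presence threshold.
    """
    ss = np.random.SeedSequence(config.seed)
    topo_seed, weight_seed = (int(s) for s in ss.generate_state(2))
    n, k = config.n_nodes, config.lattice_k
    if config.topology == "smallworld":
        g = nx.watts_strogatz_graph(n, k, config.rewire_prob, seed=topo_seed)
    else:
        m = n * k // 2
        g = nx.gnm_random_graph(n, m, seed=topo_seed)
    rng = np.random.default_rng(weight_seed)
    w = np.zeros((n, n))
    mu, size = config.base_weight_mean, config.weight_dispersion
    prob = size / (size + mu)
    for i, j in g.edges():
        weight = max(config.min_fibers, int(rng.negative_binomial(size, prob)))
        w[i, j] = weight
        w[j, i] = weight
    return ConnectivityMatrix(w)


def _subject_covariates(rng: np.random.Generator) -> dict:
    return {
        "age": float(max(40.0, rng.normal(70.0, 7.0))),
        "gender": int(rng.integers(0, 2)),
        "education": float(max(1.0, rng.normal(10.0, 3.0))),
        "icv": float(max(9e5, rng.normal(1.45e6, 1.3e5))),
    }


def _effect_mask(config: CohortConfig) -> np.ndarray:
    """Boolean mask of weight entries scaled in the patient group."""
    n = config.n_nodes
    mask = np.zeros((n, n), dtype=bool)
    for idx in config.affected_nodes:
        mask[idx - 1, :] = True
        mask[:, idx - 1] = True
    for i, j in config.affected_edges:
        mask[i - 1, j - 1] = True
        mask[j - 1, i - 1] = True
    np.fill_diagonal(mask, False)
    return mask


def generate_cohort(config: CohortConfig) -> list[Subject]:
    """Full synthetic cohort: patients first, then controls.

    Each subject's matrix is the template with per-edge lognormal noise, a
    global covariate-driven scaling, and — for patients — the planted
    weakening of affected connections; weights are re-rounded and present
    edges floored at the threshold so group membership never changes the
    binary topology.
    """
    template = generate_base_topology(config).weights
    present = template > 0
    effect = _effect_mask(config)
    ss = np.random.SeedSequence(config.seed)
    cohort_rng = np.random.default_rng(int(ss.generate_state(3)[2]))
    n = config.n_nodes
    iu = np.triu_indices(n, k=1)
    subjects = []
    groups = ["AD"] * config.n_ad + ["NC"] * config.n_nc
    counters = {"AD": 0, "NC": 0}
    for group in groups:
        counters[group] += 1
        sid = f"{group.lower()}{counters[group]:03d}"
        covs = _subject_covariates(cohort_rng)
        log_scale = sum(
            config.covariate_effect.get(name, 0.0)
            * (covs[name] - _COVARIATE_CENTERS[name])
            for name in covs
        )
        noise = np.zeros((n, n))
        noise_upper = cohort_rng.normal(0.0, config.noise_sd, size=iu[0].size)
        noise[iu] = noise_upper
        noise = noise + noise.T
        w = template * np.exp(noise + log_scale)
        if group == "AD" and config.effect_multiplier < 1.0:
            w = np.where(effect, w * config.effect_multiplier, w)
        w = np.round(w)
        w[present] = np.maximum(w[present], config.min_fibers)
        w[~present] = 0.0
        subjects.append(
            Subject(
                id=sid,
                group=group,
                matrix=ConnectivityMatrix(w),
                **covs,
            )
        )
    return subjects


def cohort_to_fiber_records(subject: Subject) -> list[FiberRecord]:
    """Expand an integer count matrix into one record per streamline.

    Tallying the output with the network-construction module reproduces the
    matrix exactly.
    """
    if not subject.matrix.is_integer:
        raise ValueError("fiber records require an integer-weight matrix")
    w = subject.matrix.weights
    records = []
    iu, jv = np.nonzero(np.triu(w, k=1))
    for i, j in zip(iu, jv):
        records.extend([FiberRecord(int(i) + 1, int(j) + 1)] * int(w[i, j]))
    return records
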