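"""Synthetic datasets with the structure the method assumes.

Gene groups contain latent subclusters: every subcluster has a
standard-normal factor per sample and member genes load on it with
within-cluster correlation ``rho`` (optionally sign-flipped to create
anti-correlated members).  Survival times are exponential draws from a
proportional-hazards model on the cluster factors plus clinical
covariates, with independent exponential censoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from gosurv.data import (
    ClinicalCovariates,
    Dataset,
    ExpressionMatrix,
    GeneGroupMap,
    SurvivalResponse,
)

PRESETS = ("tiny", "null", "clustered_signal", "anticorrelated")


@dataclass
class SimulationStructure:
    """Group membership, latent cluster labels, and per-gene sign flips."""

    groups: GeneGroupMap
    gene_cluster: dict[str, tuple[str, int]]       # gene -> (primary group, cluster index)
    cluster_genes: dict[str, list[str]]            # "group|c<k>" -> member genes
    sign_flip: dict[str, int] = field(default_factory=dict)  # gene -> +1/-1

    @property
    def factor_ids(self) -> list[str]:
        return sorted(self.cluster_genes)


@dataclass
class SimulationTruth:
    structure: SimulationStructure
    true_beta: dict[str, float]                    # factor id -> coefficient
    true_gamma: dict[str, float]
    baseline_rate: float
    censoring_rate: float
    within_cluster_rho: float
    seed: int
    factors: dict[str, list[float]] = field(default_factory=dict)  # factor id -> per-sample values

    def factor_matrix(self, factor_ids: list[str] | None = None) -> np.ndarray:
        ids = factor_ids or sorted(self.factors)
        return np.column_stack([np.asarray(self.factors[f]) for f in ids])

    def to_json(self, path) -> None:
        payload = {
            "groups": {g: sorted(m) for g, m in self.structure.groups.groups.items()},
            "gene_cluster": {g: list(v) for g, v in self.structure.gene_cluster.items()},
            "cluster_genes": self.structure.cluster_genes,
            "sign_flip": self.structure.sign_flip,
            "true_beta": self.true_beta,
            "true_gamma": self.true_gamma,
            "baseline_rate": self.baseline_rate,
            "censoring_rate": self.censoring_rate,
            "within_cluster_rho": self.within_cluster_rho,
            "seed": self.seed,
            "factors": self.factors,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            payload = json.load(fh)
        structure = SimulationStructure(
            groups=GeneGroupMap({g: frozenset(m) for g, m in payload["groups"].items()}),
            gene_cluster={g: (v[0], int(v[1])) for g, v in payload["gene_cluster"].items()},
            cluster_genes=payload["cluster_genes"],
            sign_flip={g: int(v) for g, v in payload["sign_flip"].items()},
        )
        return cls(
            structure=structure,
            true_beta=payload["true_beta"],
            true_gamma=payload["true_gamma"],
            baseline_rate=payload["baseline_rate"],
            censoring_rate=payload["censoring_rate"],
            within_cluster_rho=payload["within_cluster_rho"],
            seed=payload["seed"],
            factors=payload["factors"],
        )


def simulate_structure(
    n_groups: int,
    genes_per_group: tuple[int, int],
    clusters_per_group: tuple[int, int],
    overlap_fraction: float = 0.0,
    seed: int = 0,
) -> SimulationStructure:
    """Disjoint base groups with latent subclusters, plus optional overlap.

    ``overlap_fraction`` of all genes receive a second, purely
    annotational membership in another group (their expression is still
    generated by the primary cluster's factor).
    """
    if n_groups < 1 or genes_per_group[0] < 1:
        raise ValueError("counts must be positive")
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    if overlap_fraction > 0 and n_groups < 2:
        raise ValueError("overlap requires at least 2 groups")
    rng = np.random.default_rng(seed)
    groups: dict[str, set[str]] = {}
    gene_cluster: dict[str, tuple[str, int]] = {}
    cluster_genes: dict[str, list[str]] = {}
    counter = 0
    for g in range(n_groups):
        gid = f"GO:{g:07d}"
        size = int(rng.integers(genes_per_group[0], genes_per_group[1] + 1))
        k = int(rng.integers(clusters_per_group[0], clusters_per_group[1] + 1))
        k = min(k, size)
        genes = [f"g{counter + i:05d}" for i in range(size)]
        counter += size
        labels = np.sort(np.arange(size) % k)
        groups[gid] = set(genes)
        for gene, lab in zip(genes, labels):
            gene_cluster[gene] = (gid, int(lab) + 1)
            cluster_genes.setdefault(f"{gid}|c{int(lab) + 1}", []).append(gene)
    all_genes = sorted(gene_cluster)
    n_overlap = int(round(overlap_fraction * len(all_genes)))
    if n_overlap:
        chosen = rng.choice(len(all_genes), size=n_overlap, replace=False)
        gids = sorted(groups)
        for i in chosen:
            gene = all_genes[i]
            home = gene_cluster[gene][0]
            others = [g for g in gids if g != home]
            groups[others[int(rng.integers(len(others)))]].add(gene)
    return SimulationStructure(
        groups=GeneGroupMap({g: frozenset(m) for g, m in groups.items()}),
        gene_cluster=gene_cluster,
        cluster_genes=cluster_genes,
    )


def simulate_expression(
    structure: SimulationStructure,
    n_samples: int,
    within_cluster_rho: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    sign_flip_fraction: float = 0.0,
) -> tuple[ExpressionMatrix, dict[str, np.ndarray]]:
    """Factor-model expression: gene = sqrt(rho)*factor + sqrt(1-rho)*noise.

    Each latent cluster gets an independent standard-normal factor per
    sample, so the expected within-cluster correlation is ``rho`` and
    across-cluster correlations vanish.  ``sign_flip_fraction`` of genes
    load negatively, producing anti-correlated members.  Returns the
    matrix and the per-cluster factor vectors.
    """
    if not 0 <= within_cluster_rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    factors = {cid: rng.standard_normal(n_samples) for cid in sorted(structure.cluster_genes)}
    genes = sorted(structure.gene_cluster)
    flips = dict(structure.sign_flip)
    if sign_flip_fraction > 0:
        for gene in genes:
            if gene not in flips and rng.random() < sign_flip_fraction:
                flips[gene] = -1
    structure.sign_flip = {g: s for g, s in flips.items() if s == -1}
    rows = np.empty((len(genes), n_samples))
    a = np.sqrt(within_cluster_rho)
    b = np.sqrt(1.0 - within_cluster_rho)
    for i, gene in enumerate(genes):
        gid, k = structure.gene_cluster[gene]
        f = factors[f"{gid}|c{k}"]
        s = flips.get(gene, 1)
        rows[i] = s * a * f + b * rng.standard_normal(n_samples)
        if noise_sd > 0:
            rows[i] = rows[i] + noise_sd * rng.standard_normal(n_samples)
    sample_ids = [f"s{i:04d}" for i in range(n_samples)]
    return ExpressionMatrix(genes, sample_ids, rows), factors


def simulate_survival(
    factors: np.ndarray,
    true_beta: np.ndarray,
    Z: np.ndarray,
    true_gamma: np.ndarray,
    baseline_rate: float,
    censoring_rate: float,
    seed: int = 0,
) -> SurvivalResponse:
    """Exponential event times with rate baseline_rate * exp(eta), exponential censoring.

    ``censoring_rate`` = 0 disables censoring.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    if censoring_rate < 0:
        raise ValueError("censoring_rate must be nonnegative")
    rng = np.random.default_rng(seed)
    factors = np.atleast_2d(np.asarray(factors, float))
    n = factors.shape[0]
    eta = factors @ np.asarray(true_beta, float)
    if np.asarray(Z).size:
        eta = eta + np.asarray(Z, float) @ np.asarray(true_gamma, float)
    rate = baseline_rate * np.exp(eta)
    t_event = rng.exponential(1.0 / rate)
    if censoring_rate > 0:
        t_cens = rng.exponential(1.0 / censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-9)
    return SurvivalResponse(time, event)


def _simulate_clinical(n: int, rng: np.random.Generator) -> ClinicalCovariates:
    binary = (rng.random(n) < 0.5).astype(float)
    cont = rng.standard_normal(n)
    return ClinicalCovariates(["z_bin", "z_cont"], np.column_stack([binary, cont]))


def _assemble(
    structure: SimulationStructure,
    expr: ExpressionMatrix,
    factors: dict[str, np.ndarray],
    true_beta: dict[str, float],
    true_gamma: dict[str, float],
    baseline_rate: float,
    censoring_rate: float,
    rho: float,
    seed: int,
    surv_seed: int,
    clin_seed: int,
) -> tuple[Dataset, SimulationTruth]:
    n = expr.n_samples
    clinical = _simulate_clinical(n, np.random.default_rng(clin_seed))
    factor_ids = sorted(factors)
    F = np.column_stack([factors[f] for f in factor_ids])
    beta_vec = np.asarray([true_beta.get(f, 0.0) for f in factor_ids])
    gamma_vec = np.asarray([true_gamma.get(c, 0.0) for c in clinical.covariate_names])
    survival = simulate_survival(
        F, beta_vec, clinical.values, gamma_vec, baseline_rate, censoring_rate, seed=surv_seed
    )
    survival.sample_ids = list(expr.sample_ids)
    clinical.sample_ids = list(expr.sample_ids)
    dataset = Dataset(expr, survival, clinical, structure.groups.restrict_to_genes(expr.gene_ids))
    truth = SimulationTruth(
        structure=structure,
        true_beta=dict(true_beta),
        true_gamma=dict(true_gamma),
        baseline_rate=baseline_rate,
        censoring_rate=censoring_rate,
        within_cluster_rho=rho,
        seed=seed,
        factors={f: factors[f].tolist() for f in factor_ids},
    )
    return dataset, truth


def make_benchmark_dataset(preset: str, seed: int = 0) -> tuple[Dataset, SimulationTruth]:
    """Named benchmark scenarios.

    tiny: 20 genes / 4 groups / 40 samples, one modest signal cluster.
    null: no survival association at all.
    clustered_signal: 3 signal-bearing groups hidden among 50 noise groups,
    n = 200, roughly 25% events.
    anticorrelated: each signal group buries a small survival-relevant
    subcluster among stronger decoy subclusters (some members
    sign-flipped), so a whole-group first PC misses the signal that
    cluster-level summarization isolates.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of {PRESETS}")
    rho = 0.8

    if preset == "tiny":
        structure = simulate_structure(4, (5, 5), (2, 2), 0.0, seed=seed)
        expr, factors = simulate_expression(structure, 40, rho, seed=seed + 1)
        beta = {sorted(structure.cluster_genes)[0]: 0.8}
        gamma = {"z_bin": 0.5, "z_cont": 0.3}
        return _assemble(structure, expr, factors, beta, gamma, 0.1, 0.1, rho, seed, seed + 2, seed + 3)

    if preset == "null":
        structure = simulate_structure(10, (8, 12), (2, 3), 0.1, seed=seed)
        expr, factors = simulate_expression(structure, 120, rho, seed=seed + 1)
        return _assemble(structure, expr, factors, {}, {}, 0.1, 0.1, rho, seed, seed + 2, seed + 3)

    if preset == "clustered_signal":
        structure = simulate_structure(53, (8, 12), (2, 2), 0.05, seed=seed)
        expr, factors = simulate_expression(structure, 200, rho, seed=seed + 1)
        gids = structure.groups.group_ids
        beta = {}
        for gid, coef in zip(gids[:3], (1.0, -1.0, 0.8)):
            beta[f"{gid}|c1"] = coef
        gamma = {"z_bin": 0.4, "z_cont": 0.3}
        # censoring_rate ~3x baseline gives roughly a quarter observed events
        return _assemble(structure, expr, factors, beta, gamma, 0.03, 0.09, rho, seed, seed + 2, seed + 3)

    # anticorrelated: 4 signal groups of 33 genes (1 signal subcluster of 5,
    # 4 decoy subclusters of 7) + 8 small noise groups
    rho = 0.9
    rng = np.random.default_rng(seed)
    groups: dict[str, set[str]] = {}
    gene_cluster: dict[str, tuple[str, int]] = {}
    cluster_genes: dict[str, list[str]] = {}
    sign_flip: dict[str, int] = {}
    counter = 0

    def add_group(gid: str, sizes: list[int], flip_in: set[int]):
        nonlocal counter
        members = []
        for k, size in enumerate(sizes, start=1):
            genes = [f"g{counter + i:05d}" for i in range(size)]
            counter += size
            members.extend(genes)
            cluster_genes[f"{gid}|c{k}"] = genes
            for j, gene in enumerate(genes):
                gene_cluster[gene] = (gid, k)
                if k in flip_in and j % 2 == 1:
                    sign_flip[gene] = -1
        groups[gid] = set(members)

    signal_factors = []
    for g in range(4):
        gid = f"GO:{g:07d}"
        add_group(gid, [5, 7, 7, 7, 7], flip_in={2, 3, 4, 5})
        signal_factors.append(f"{gid}|c1")
    for g in range(4, 12):
        add_group(f"GO:{g:07d}", [int(rng.integers(8, 13))], flip_in=set())

    structure = SimulationStructure(
        groups=GeneGroupMap({g: frozenset(m) for g, m in groups.items()}),
        gene_cluster=gene_cluster,
        cluster_genes=cluster_genes,
        sign_flip=sign_flip,
    )
    expr, factors = simulate_expression(structure, 300, rho, seed=seed + 1)
    beta = {f: coef for f, coef in zip(signal_factors, (1.0, -1.0, 0.9, -0.9))}
    gamma = {"z_bin": 0.3, "z_cont": 0.2}
    return _assemble(structure, expr, factors, beta, gamma, 0.05, 0.05, rho, seed, seed + 2, seed + 3)
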