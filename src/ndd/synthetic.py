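"""Self-contained synthetic benchmarks with the structure the pipeline assumes.

The generator plants the premise of similarity-based DDI prediction —
similar drugs tend to share interactions — in its simplest form: drugs
belong to latent clusters, a symmetric compatibility relation over clusters
decides which cluster pairs interact often (probability ``p_within``) versus
rarely (``p_between``), and each *informative* similarity view exposes the
cluster structure: same-cluster similarity peaks at 0.9 and decays
geometrically with distance along a view-specific random ordering of the
cluster members (views agree on the clusters but disagree on the detail,
like similarity types derived from different data sources), zero between
clusters, with multiplicative Gaussian perturbation so zeros stay zero.
The decay concentrates each row's mass on a handful of neighbours, keeping
informative views below the c1 = 0.6 entropy cutoff that a row spread
uniformly over a whole 15-drug cluster would already exceed.
Two adversarial views exercise the
selection stage: a near-uniform noise view whose row entropy is at the
log(m-1) scale, guaranteed above the c1 = 0.6 cutoff, and a near-duplicate
of the first informative view whose affinity with it is far above c2.

The compatibility relation is drawn so that compatible cluster pairs cover
10–22% of all drug pairs, putting interaction prevalence near 6–14% — the
class-imbalance regime of curated DDI datasets. The default rates
(``p_within`` 0.6, ``p_between`` 0.005) keep the label noise low enough
that a well-trained classifier can separate the planted structure cleanly;
with much noisier rates even the Bayes-optimal scorer, which can only
assign one score level per cluster pair, is capped well below an AUC of
0.9 by the mass of tied pairs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .data_model import DrugIndex, InteractionMatrix, SimilarityMatrix, write_matrix
from .exceptions import ParameterError


@dataclass(frozen=True)
class SyntheticSpec:
    """Benchmark shape and noise levels; defaults give a 60-drug, 4-cluster
    panel with three informative views plus the two adversarial ones."""

    m: int = 60
    n_clusters: int = 4
    p_within: float = 0.6
    p_between: float = 0.005
    n_informative_views: int = 3
    view_noise_sd: float = 0.05
    within_peak: float = 0.9
    within_decay: float = 0.5
    include_uniform_view: bool = True
    include_duplicate_view: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2 * self.n_clusters:
            raise ParameterError("need m >= 2 * n_clusters")
        if not 0 <= self.p_between < self.p_within <= 1:
            raise ParameterError("need 0 <= p_between < p_within <= 1")
        if self.n_informative_views < 1:
            raise ParameterError("need at least one informative view")
        if self.view_noise_sd < 0:
            raise ParameterError("view_noise_sd must be non-negative")
        if not (0 < self.within_peak <= 1 and 0 < self.within_decay < 1):
            raise ParameterError("need 0 < within_peak <= 1 and 0 < within_decay < 1")


def _symmetric_noise(rng: np.random.Generator, m: int, sd: float) -> np.ndarray:
    E = rng.normal(0.0, sd, size=(m, m))
    return np.triu(E, 1) + np.triu(E, 1).T


def _draw_compatibility(rng: np.random.Generator, clusters: np.ndarray) -> np.ndarray:
    """Symmetric boolean relation over clusters whose compatible cluster pairs
    (incl. self-pairs) cover 10–22% of the drug-pair universe.

    The mass window keeps interaction prevalence in the imbalance regime of
    curated DDI data and leaves the frequently-interacting pairs a clear
    minority, so that ranking them first is both hard enough and rewarded.
    """
    n_clusters = int(clusters.max()) + 1
    sizes = np.bincount(clusters, minlength=n_clusters)
    cluster_pairs = list(itertools.combinations_with_replacement(range(n_clusters), 2))
    mass = np.array(
        [sizes[a] * (sizes[a] - 1) // 2 if a == b else sizes[a] * sizes[b]
         for a, b in cluster_pairs],
        dtype=float,
    )
    total = mass.sum()
    for _ in range(10_000):
        on = rng.random(len(cluster_pairs)) < 0.35
        frac = mass[on].sum() / total
        if on.sum() >= 2 and 0.10 <= frac <= 0.22:
            C = np.zeros((n_clusters, n_clusters), dtype=bool)
            for (a, b), flag in zip(cluster_pairs, on):
                C[a, b] = C[b, a] = flag
            return C
    raise ParameterError("could not draw a non-trivial compatibility relation")


def generate_benchmark(
    spec: SyntheticSpec = SyntheticSpec(),
) -> tuple[list[SimilarityMatrix], InteractionMatrix, dict]:
    """Return (views, Y, truth); bit-reproducible given ``spec.seed``.

    ``truth`` records the cluster assignment and the cluster-compatibility
    matrix that generated the interactions.
    """
    rng = np.random.default_rng(spec.seed)
    m, nc = spec.m, spec.n_clusters

    clusters = np.sort(np.arange(m) % nc)  # near-equal sizes
    clusters = clusters[rng.permutation(m)]
    C = _draw_compatibility(rng, clusters)

    # interactions: Bernoulli by cluster-pair compatibility, symmetric, zero diag
    compat = C[clusters[:, None], clusters[None, :]]
    prob = np.where(compat, spec.p_within, spec.p_between)
    U = rng.random((m, m))
    Y = np.triu((U < prob), 1)
    Y = (Y | Y.T).astype(np.int8)
    np.fill_diagonal(Y, 0)
    if Y.sum() == 0:  # vanishingly unlikely at default sizes
        cand = np.argwhere(np.triu(compat, 1))
        a, b = cand[0] if len(cand) else (0, 1)
        Y[a, b] = Y[b, a] = 1

    views: list[SimilarityMatrix] = []
    for v in range(spec.n_informative_views):
        base = np.zeros((m, m))
        for c in range(nc):
            members = np.flatnonzero(clusters == c)
            order = rng.permutation(len(members))  # view-specific arrangement
            size = len(members)
            pos = np.empty(size, dtype=int)
            pos[order] = np.arange(size)
            gap = np.abs(pos[:, None] - pos[None, :])
            dist = np.minimum(gap, size - gap)  # circular rank distance
            block = spec.within_peak * spec.within_decay ** (dist - 1.0)
            base[np.ix_(members, members)] = np.where(dist > 0, block, 0.0)
        noise = _symmetric_noise(rng, m, spec.view_noise_sd)
        A = np.clip(base * (1.0 + noise), 0.0, 1.0)
        np.fill_diagonal(A, 1.0)
        views.append(SimilarityMatrix(name=f"informative_{v + 1}", A=A))

    if spec.include_duplicate_view:
        noise = _symmetric_noise(rng, m, 0.001)
        A = np.clip(views[0].A + noise, 0.0, 1.0)
        np.fill_diagonal(A, 1.0)
        views.append(SimilarityMatrix(name="near_duplicate", A=A))

    if spec.include_uniform_view:
        A = np.full((m, m), 1.0 / m)
        np.fill_diagonal(A, 0.0)
        views.append(SimilarityMatrix(name="uniform_noise", A=A))

    truth = {
        "clusters": clusters.tolist(),
        "compatibility": C.astype(int).tolist(),
        "spec": asdict(spec),
    }
    return views, InteractionMatrix(Y=Y), truth


def default_index(m: int) -> DrugIndex:
    return DrugIndex(tuple(f"D{i:04d}" for i in range(m)))


def write_benchmark(
    out_dir: str | Path, spec: SyntheticSpec = SyntheticSpec()
) -> dict[str, str]:
    """Materialize a benchmark as the CSV formats the loaders read.

    Returns a name→path map covering the drug list, the interaction matrix
    and every similarity view, plus the truth JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    views, Y, truth = generate_benchmark(spec)
    index = default_index(spec.m)
    paths = {"drugs": str(out / "drugs.txt")}
    index.to_file(paths["drugs"])
    paths["interactions"] = str(out / "interactions.csv")
    write_matrix(Y.Y, paths["interactions"], index)
    for v in views:
        p = str(out / f"similarity_{v.name}.csv")
        write_matrix(v.A, p, index)
        paths[v.name] = p
    paths["truth"] = str(out / "truth.json")
    Path(paths["truth"]).write_text(json.dumps(truth, indent=2))
    return paths
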