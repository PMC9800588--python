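"""Synthetic study generator with planted ground truth.

Emulates every input class of a two-phase (estrus vs diestrus),
multi-tissue bulk RNA-seq comparison: negative-binomial replicate counts
with planted differentially expressed genes, log2FC signature libraries
with planted rank correlations and beneficial/deleterious outcome labels,
directed signaling networks with planted high-centrality genes, signed
TF->target regulons with planted directionally active TFs, and gene-set
collections with planted enriched terms.  Every generator is a pure
function of its configuration and seed, and every planted id resolves in
the generated objects, so downstream inference can be scored against known
truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import stage_rng
from .deg import ExpressionProfile, TrendVector
from .enrich import GeneSet
from .errors import InvalidConfigError
from .tfact import Regulon
from .tascomp import TAS

#: the 15 tissues profiled in the emulated study design
TISSUES = (
    "aorta",
    "vein",
    "brown_adipose",
    "white_adipose",
    "heart",
    "kidney",
    "liver",
    "skeletal_muscle",
    "stomach",
    "duodenum",
    "cerebrum",
    "hypothalamus",
    "ovary",
    "uterus",
    "spleen",
)

#: tissues whose DEG burden is oriented toward down-regulation in the
#: two-module trend structure (the rest lean up-regulated)
DOWN_MODULE = ("aorta", "brown_adipose", "kidney", "skeletal_muscle")

#: fixed 3-level outcome/experiment-type label hierarchy for library members
LABEL_HIERARCHY: dict[str, tuple[str, ...]] = {
    "disease": ("cancer", "cardiovascular", "metabolic", "inflammation"),
    "chemical treatment": ("hormone", "drug"),
    "lifestyle": ("diet", "exercise"),
}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for all generators.

    Defaults emulate the study design: three biological replicates per
    tissue-phase group across 15 tissues, replicate depth scaled to about
    one million reads, a planted effect size of |log2FC| = 2, mild
    negative-binomial overdispersion, and a per-tissue signature library of
    84 members (a curation effort of ~1,300 signatures over 15 tissues).
    """

    seed: int = 0
    n_genes: int = 2000
    n_replicates: int = 3
    lib_size_mean: float = 1e6
    nb_dispersion: float = 0.05
    deg_fraction: float = 0.1
    deg_log2fc: float = 2.0
    n_tissues: int = 15
    tas_library_size: int = 84
    tas_rho: float = 0.3
    tas_correlated_fraction: float = 0.5
    label_balance: float = 0.5
    n_tfs: int = 30
    targets_per_tf: int = 20
    tf_consistency: float = 0.9
    tf_active_fraction: float = 0.3
    net_nodes: int = 2000
    net_edges: int = 6000
    n_hubs: int = 20

    def validate(self) -> None:
        fractions = {
            "deg_fraction": self.deg_fraction,
            "tas_correlated_fraction": self.tas_correlated_fraction,
            "label_balance": self.label_balance,
            "tf_consistency": self.tf_consistency,
            "tf_active_fraction": self.tf_active_fraction,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {value}")
        if self.nb_dispersion < 0:
            raise InvalidConfigError("nb_dispersion must be >= 0")
        if self.lib_size_mean <= 0:
            raise InvalidConfigError("lib_size_mean must be positive")
        if self.n_genes < 10:
            raise InvalidConfigError("n_genes must be >= 10")
        if self.n_replicates < 1:
            raise InvalidConfigError("n_replicates must be >= 1")
        if not -1.0 < self.tas_rho < 1.0:
            raise InvalidConfigError("tas_rho must lie in (-1, 1)")
        if self.targets_per_tf < 3:
            raise InvalidConfigError("targets_per_tf must be >= 3")
        if self.net_nodes < 10:
            raise InvalidConfigError("net_nodes must be >= 10")
        if self.net_edges < self.net_nodes - 1:
            raise InvalidConfigError("net_edges must be >= net_nodes - 1")
        if not 1 <= self.n_tissues <= len(TISSUES):
            raise InvalidConfigError(f"n_tissues must be in [1, {len(TISSUES)}]")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators.

    ``deg_signs`` maps planted DEG gene ids to their trend sign,
    ``correlated_tas`` maps planted library member ids to (rho, outcome),
    ``active_tfs`` maps planted TF ids to their activity direction sign,
    ``hub_ids`` lists the planted high-centrality genes, and
    ``protective_phase`` records which phase was planted as protective.
    """

    deg_signs: dict[str, int] = field(default_factory=dict)
    correlated_tas: dict[str, tuple[float, str]] = field(default_factory=dict)
    active_tfs: dict[str, int] = field(default_factory=dict)
    hub_ids: tuple[str, ...] = ()
    protective_phase: str = ""


def gene_ids(n_genes: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n_genes)]


def _nb_draws(rng: np.random.Generator, mu: np.ndarray, dispersion: float, n_reps: int) -> np.ndarray:
    """Gene x replicate counts with variance mu + dispersion * mu^2.

    Gamma-Poisson mixture; dispersion 0 is the Poisson limit.
    """
    shape = (mu.shape[0], n_reps)
    mu_mat = np.broadcast_to(mu[:, None], shape)
    if dispersion == 0:
        return rng.poisson(mu_mat)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu_mat * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    config: SimConfig,
    tissue: str = "tissue",
    deg_signs: Mapping[str, int] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionProfile, ExpressionProfile, PlantedTruth]:
    """Simulate an estrus/diestrus count-matrix pair with planted DEGs.

    Baseline per-gene means are log-normal, rescaled so each replicate's
    expected total equals ``lib_size_mean``.  Planted DEGs have their
    estrus-phase mean multiplied by ``2**(sign * deg_log2fc)``.  When
    ``deg_signs`` is given it fixes the planted genes and directions
    (shared-structure studies); otherwise they are drawn at random.
    """
    config.validate()
    if rng is None:
        rng = stage_rng(config.seed, f"counts:{tissue}")
    genes = gene_ids(config.n_genes)
    weights = rng.lognormal(mean=0.0, sigma=1.5, size=config.n_genes)
    base = config.lib_size_mean * weights / weights.sum()

    if deg_signs is None:
        n_deg = int(round(config.deg_fraction * config.n_genes))
        planted = rng.choice(config.n_genes, size=n_deg, replace=False)
        signs = rng.choice([-1, 1], size=n_deg)
        deg_signs = {genes[i]: int(s) for i, s in zip(planted, signs)}
    else:
        missing = set(deg_signs) - set(genes)
        if missing:
            raise InvalidConfigError(f"planted DEG ids not in gene universe: {sorted(missing)[:3]}")

    fold = np.ones(config.n_genes)
    index = {g: i for i, g in enumerate(genes)}
    for g, s in deg_signs.items():
        fold[index[g]] = 2.0 ** (s * config.deg_log2fc)

    counts_a = _nb_draws(rng, base * fold, config.nb_dispersion, config.n_replicates)
    counts_b = _nb_draws(rng, base, config.nb_dispersion, config.n_replicates)

    def frame(arr: np.ndarray, phase: str) -> pd.DataFrame:
        cols = [f"{tissue}_{phase}_rep{r + 1}" for r in range(config.n_replicates)]
        return pd.DataFrame(arr, index=pd.Index(genes, name="gene"), columns=cols)

    profile_a = ExpressionProfile(tissue=tissue, phase="estrus", counts=frame(counts_a, "estrus"))
    profile_b = ExpressionProfile(tissue=tissue, phase="diestrus", counts=frame(counts_b, "diestrus"))
    truth = PlantedTruth(deg_signs=dict(deg_signs))
    return profile_a, profile_b, truth


def _label_path(rng: np.random.Generator, outcome: str) -> tuple[str, ...]:
    """Draw a 1-3 level label path rooted at the outcome label."""
    depth = rng.choice([1, 2, 3], p=[0.1, 0.3, 0.6])
    if depth == 1:
        return (outcome,)
    kind = list(LABEL_HIERARCHY)[rng.integers(len(LABEL_HIERARCHY))]
    if depth == 2:
        return (outcome, kind)
    sub = LABEL_HIERARCHY[kind][rng.integers(len(LABEL_HIERARCHY[kind]))]
    return (outcome, kind, sub)


def simulate_tas_library(
    config: SimConfig,
    query: TAS,
    protective_phase: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[TAS], PlantedTruth]:
    """Simulate a labelled signature library around a query signature.

    Correlated members are built through a Gaussian copula: the query
    values are rank-transformed to normal scores ``z`` and a member is
    ``s * rho_P * z + sqrt(1 - rho_P^2) * noise`` with ``rho_P = 2
    sin(pi * rho_S / 6)``, the exact Pearson counterpart of the target
    Spearman ``rho_S`` under bivariate normality, so the population
    Spearman correlation with the query is ``s * tas_rho``.  The sign ``s``
    couples to the outcome label: when estrus is the planted protective
    phase, beneficial members correlate positively with the estrus-induced
    query (and deleterious negatively); when diestrus protects, the
    coupling flips.  Uncorrelated members are independent noise.
    """
    config.validate()
    if len(query) < 100:
        raise InvalidConfigError("query signature must have >= 100 genes")
    if rng is None:
        rng = stage_rng(config.seed, f"tas:{query.tissue}")
    if protective_phase is None:
        protective_phase = ["estrus", "diestrus"][rng.integers(2)]
    if protective_phase not in ("estrus", "diestrus"):
        raise InvalidConfigError("protective_phase must be 'estrus' or 'diestrus'")

    n = len(query)
    ranks = stats.rankdata(query.values)
    z = stats.norm.ppf(ranks / (n + 1))
    rho_p = 2.0 * np.sin(np.pi * config.tas_rho / 6.0)
    n_corr = int(round(config.tas_correlated_fraction * config.tas_library_size))

    members: list[TAS] = []
    truth = PlantedTruth(protective_phase=protective_phase)
    for i in range(config.tas_library_size):
        member_id = f"{query.tissue}_tas{i:03d}"
        outcome = "beneficial" if rng.random() < config.label_balance else "deleterious"
        if i < n_corr:
            positive = (outcome == "beneficial") == (protective_phase == "estrus")
            s = 1.0 if positive else -1.0
            values = s * rho_p * z + np.sqrt(1.0 - rho_p**2) * rng.standard_normal(n)
            truth.correlated_tas[member_id] = (float(s * config.tas_rho), outcome)
        else:
            values = rng.standard_normal(n)
        members.append(
            TAS(
                id=member_id,
                tissue=query.tissue,
                genes=query.genes.copy(),
                values=values,
                outcome=outcome,
                label_path=_label_path(rng, outcome),
            )
        )
    return members, truth


def simulate_network(
    config: SimConfig,
    deg_ids: Sequence[str],
    genes: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[nx.DiGraph, tuple[str, ...]]:
    """Grow a directed scale-free network and plant high-centrality DEGs.

    Preferential-attachment growth over the full node universe (the
    measured genes when ``genes`` is given, else ``net_nodes`` synthetic
    ids); each edge is oriented at random.  Up to ``n_hubs`` nodes sampled
    from ``deg_ids`` then receive extra edges until their total degree
    exceeds the 95th percentile of the non-hub degree distribution.
    Returns the graph and the planted hub ids.
    """
    config.validate()
    nodes = list(genes) if genes is not None else gene_ids(config.net_nodes)
    if len(nodes) < 10:
        raise InvalidConfigError("need at least 10 network nodes")
    if config.net_edges < len(nodes) - 1:
        raise InvalidConfigError("net_edges must be >= number of nodes - 1")
    if rng is None:
        rng = stage_rng(config.seed, "network")

    n = len(nodes)
    degree = np.zeros(n, dtype=float)
    edges: set[tuple[int, int]] = set()

    def add_edge(i: int, j: int) -> None:
        if i == j:
            return
        pair = (i, j) if rng.random() < 0.5 else (j, i)
        if pair not in edges and (pair[1], pair[0]) not in edges:
            edges.add(pair)
            degree[pair[0]] += 1
            degree[pair[1]] += 1

    per_node = max(1, config.net_edges // max(n - 1, 1))
    for j in range(1, n):
        m = min(per_node, j)
        weights = degree[:j] + 1.0
        partners = rng.choice(j, size=m, replace=False, p=weights / weights.sum())
        for i in partners:
            add_edge(int(i), j)
    # top up to the requested edge count with degree-weighted endpoints
    while len(edges) < config.net_edges:
        weights = degree + 1.0
        i, j = rng.choice(n, size=2, replace=False, p=weights / weights.sum())
        add_edge(int(i), int(j))

    index = {node: k for k, node in enumerate(nodes)}
    hub_ids: tuple[str, ...] = ()
    candidates = [g for g in deg_ids if g in index]
    if config.n_hubs > 0 and candidates:
        n_hubs = min(config.n_hubs, len(candidates))
        hubs = list(rng.choice(sorted(candidates), size=n_hubs, replace=False))
        hub_pos = {index[h] for h in hubs}
        background = degree[[k for k in range(n) if k not in hub_pos]]
        target = int(np.ceil(np.percentile(background, 95))) + 3
        for h in hubs:
            k = index[h]
            while degree[k] <= target:
                add_edge(k, int(rng.integers(n)))
        hub_ids = tuple(sorted(hubs))

    graph = nx.DiGraph()
    graph.add_nodes_from(nodes)
    graph.add_edges_from((nodes[i], nodes[j]) for i, j in edges)
    return graph, hub_ids


def simulate_regulons(
    config: SimConfig,
    trend: TrendVector,
    rng: np.random.Generator | None = None,
) -> tuple[list[Regulon], dict[str, int]]:
    """Simulate signed TF->target regulons with planted active TFs.

    Active TFs are drawn from the measured DEG genes so that their own
    expression trend matches their planted activity direction (as a real
    auto-consistent TF would); a fraction ``tf_consistency`` of their
    targets receive an edge sign consistent with (direction x trend), the
    rest the contradicting sign.  Inactive TFs take uniformly sampled
    targets with random signs, so their target trends follow the global
    trend distribution.  Returns the regulons and the planted
    TF -> direction map.
    """
    config.validate()
    if rng is None:
        rng = stage_rng(config.seed, f"regulons:{trend.tissue}")
    measured = sorted(trend.trend)
    if len(measured) < config.targets_per_tf + 1:
        raise InvalidConfigError("trend domain too small for requested regulon size")
    if config.n_tfs > len(measured):
        raise InvalidConfigError(
            f"n_tfs={config.n_tfs} exceeds the {len(measured)} measured trend genes"
        )
    n_active = int(round(config.tf_active_fraction * config.n_tfs))
    tf_pool = list(rng.choice(measured, size=config.n_tfs, replace=False))

    regulons: list[Regulon] = []
    active: dict[str, int] = {}
    for k, tf in enumerate(tf_pool):
        choices = [g for g in measured if g != tf]
        targets = list(rng.choice(choices, size=config.targets_per_tf, replace=False))
        if k < n_active:
            direction = trend.trend[tf]
            active[tf] = direction
            signed = []
            for g in targets:
                consistent = rng.random() < config.tf_consistency
                sign = direction * trend.trend[g] * (1 if consistent else -1)
                signed.append((g, int(sign)))
        else:
            signed = [(g, int(rng.choice([-1, 1]))) for g in targets]
        regulons.append(Regulon(tf=tf, targets=tuple(signed)))
    return regulons, active


def simulate_genesets(
    config: SimConfig,
    deg_ids: Sequence[str],
    collections: Sequence[str] = ("KEGG", "Hallmark", "GAD"),
    n_terms: int = 15,
    term_size: int = 40,
    planted_per_collection: int = 3,
    rng: np.random.Generator | None = None,
) -> tuple[list[GeneSet], list[str]]:
    """Simulate gene-set collections with a few planted enriched terms.

    Planted terms draw 80% of their members from the planted DEG ids and
    the rest from the background; other terms are uniform draws from the
    gene universe.  Returns the sets and the planted term ids.
    """
    config.validate()
    if rng is None:
        rng = stage_rng(config.seed, "genesets")
    genes = gene_ids(config.n_genes)
    deg_list = sorted(set(deg_ids))
    sets: list[GeneSet] = []
    planted_ids: list[str] = []
    for collection in collections:
        for t in range(n_terms):
            term_id = f"{collection}_term{t:02d}"
            if t < planted_per_collection and len(deg_list) >= term_size:
                n_deg = int(round(0.8 * term_size))
                members = set(rng.choice(deg_list, size=n_deg, replace=False))
                members |= set(rng.choice(genes, size=term_size - n_deg, replace=False))
                planted_ids.append(term_id)
            else:
                members = set(rng.choice(genes, size=term_size, replace=False))
            sets.append(
                GeneSet(id=term_id, name=term_id.replace("_", " "), collection=collection, members=frozenset(members))
            )
    return sets, planted_ids


@dataclass
class StudyBundle:
    """A complete synthetic study: all inputs plus per-tissue planted truth."""

    config: SimConfig
    tissues: tuple[str, ...]
    profiles: dict[str, tuple[ExpressionProfile, ExpressionProfile]]
    queries: dict[str, TAS]
    libraries: dict[str, list[TAS]]
    genesets: list[GeneSet]
    planted_terms: list[str]
    network: nx.DiGraph
    regulons: list[Regulon]
    regulon_reference_tissue: str
    truth: dict[str, PlantedTruth]
    global_deg_signs: dict[str, int]


def simulate_study(config: SimConfig) -> StudyBundle:
    """Generate a full multi-tissue synthetic study with shared trend structure.

    A global planted DEG sign map is shared across tissues: each tissue
    keeps a random 80% subset of the planted genes, and tissues in the
    down-leaning module flip all signs, producing the two-module trend
    structure a cross-tissue cosine map should recover.  One signaling
    network and one regulon database (planted against the up-module
    orientation) serve all tissues, as a curated resource would.
    """
    config.validate()
    tissues = TISSUES[: config.n_tissues]
    rng = stage_rng(config.seed, "study")
    genes = gene_ids(config.n_genes)
    n_deg = int(round(config.deg_fraction * config.n_genes))
    planted = rng.choice(config.n_genes, size=n_deg, replace=False)
    base_signs = {genes[i]: int(s) for i, s in zip(planted, rng.choice([-1, 1], size=n_deg))}

    from . import tascomp

    profiles = {}
    queries = {}
    libraries = {}
    truth = {}
    for tissue in tissues:
        t_rng = stage_rng(config.seed, f"tissue:{tissue}")
        module = -1 if tissue in DOWN_MODULE else +1
        kept = {g: module * s for g, s in base_signs.items() if t_rng.random() < 0.8}
        prof_a, prof_b, t_truth = simulate_counts(config, tissue=tissue, deg_signs=kept, rng=t_rng)
        profiles[tissue] = (prof_a, prof_b)
        query = tascomp.build_tas(prof_a, prof_b, tas_id=f"{tissue}_estrus_induced")
        queries[tissue] = query
        library, lib_truth = simulate_tas_library(config, query, rng=t_rng)
        libraries[tissue] = library
        t_truth.correlated_tas = lib_truth.correlated_tas
        t_truth.protective_phase = lib_truth.protective_phase
        truth[tissue] = t_truth

    reference = tissues[0]
    ref_trend = TrendVector(tissue=reference, trend=truth[reference].deg_signs)
    # clamp regulon dimensions to the planted trend domain at small scales
    n_meas = len(ref_trend.trend)
    reg_config = dataclasses.replace(
        config,
        n_tfs=max(1, min(config.n_tfs, n_meas // 2)),
        targets_per_tf=max(3, min(config.targets_per_tf, n_meas // 2)),
    )
    regulons, active = simulate_regulons(reg_config, ref_trend)
    truth[reference].active_tfs = active

    network, hub_ids = simulate_network(config, sorted(base_signs), genes=genes)
    truth[reference].hub_ids = hub_ids

    # planted terms must fit inside the planted DEG pool at small scales
    term_size = min(40, max(10, n_deg))
    genesets, planted_terms = simulate_genesets(config, sorted(base_signs), term_size=term_size)
    return StudyBundle(
        config=config,
        tissues=tuple(tissues),
        profiles=profiles,
        queries=queries,
        libraries=libraries,
        genesets=genesets,
        planted_terms=planted_terms,
        network=network,
        regulons=regulons,
        regulon_reference_tissue=reference,
        truth=truth,
        global_deg_signs=base_signs,
    )
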