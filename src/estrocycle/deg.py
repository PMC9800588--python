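"""Differential expression between estrous-cycle phases and trend encoding.

For each tissue, gene counts from the two phases (estrus vs diestrus) are
compared with a pooled two-proportion z-test on library-size-normalised
counts; genes passing ``|log2FC| >= 1`` and BH ``q <= 0.05`` are called
differentially expressed (DEGs).  DEG directions are encoded as +1/-1 trend
vectors, tissues are compared by the cosine similarity of their shared-DEG
trends, and the tissues carrying the largest DEG burden are prioritised as
estrous-cycle target tissues (ECTTs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

PHASES = ("estrus", "diestrus")


@dataclass
class ExpressionProfile:
    """Gene-level counts for one tissue-phase group with replicate columns.

    ``counts`` is a genes x replicates DataFrame of non-negative integers;
    ``lib_sizes`` are the per-replicate column totals (recomputed on
    construction so that the invariant holds by definition).
    """

    tissue: str
    phase: str
    counts: pd.DataFrame
    lib_sizes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise InputError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.counts.index.has_duplicates:
            raise InputError("gene ids must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise InputError("counts must be non-negative")
        self.lib_sizes = self.counts.to_numpy().sum(axis=0).astype(float)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index


@dataclass(frozen=True)
class TrendVector:
    """Per-tissue map from DEG gene id to its direction (+1 up, -1 down)."""

    tissue: str
    trend: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = {g: t for g, t in self.trend.items() if t not in (+1, -1)}
        if bad:
            raise InputError(f"trend values must be +1 or -1, got {bad}")


def pooled_log2fc(counts_a, counts_b, lib_a, lib_b, pseudocount: float = 1.0):
    """Log2 fold change of pooled normalised counts, phase A over phase B.

    Replicates are pooled per gene (``K = sum over replicates``) and rates
    are normalised by the total library size ``N``::

        log2( ((K_A + c) / N_A) / ((K_B + c) / N_B) )

    with pseudocount ``c`` keeping the estimate finite at zero counts.
    Accepts per-gene pooled vectors or genes x replicates matrices.
    """
    K_a = _pool(counts_a)
    K_b = _pool(counts_b)
    N_a = float(np.sum(lib_a))
    N_b = float(np.sum(lib_b))
    if N_a <= 0 or N_b <= 0:
        raise InputError("library totals must be positive")
    if (K_a < 0).any() or (K_b < 0).any():
        raise InputError("counts must be non-negative")
    return np.log2(((K_a + pseudocount) / N_a) / ((K_b + pseudocount) / N_b))


def _pool(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    return arr.sum(axis=1) if arr.ndim == 2 else arr


def deg_ztest(K_a, N_a, K_b, N_b):
    """Two-proportion z-test on pooled counts against total library sizes.

    Under the null the per-gene read rate is equal in the two phases; with
    ``p_hat = (K_a + K_b) / (N_a + N_b)`` the statistic is

        z = (K_a/N_a - K_b/N_b) / sqrt(p_hat (1 - p_hat) (1/N_a + 1/N_b))

    and the p-value is two-sided normal.  Degenerate genes (no reads at all,
    or p_hat = 1) return ``z = 0, p = 1``.  Vectorised over genes.

    Returns ``(z, p)``.
    """
    K_a = np.asarray(K_a, dtype=float)
    K_b = np.asarray(K_b, dtype=float)
    N_a = float(N_a)
    N_b = float(N_b)
    if N_a <= 0 or N_b <= 0:
        raise InputError("library totals must be positive")
    if (K_a < 0).any() or (K_b < 0).any():
        raise InputError("counts must be non-negative")
    if (K_a > N_a).any() or (K_b > N_b).any():
        raise InputError("pooled count exceeds library total")
    p_hat = (K_a + K_b) / (N_a + N_b)
    var = p_hat * (1.0 - p_hat) * (1.0 / N_a + 1.0 / N_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (K_a / N_a - K_b / N_b) / np.sqrt(var), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    profile_a: ExpressionProfile,
    profile_b: ExpressionProfile,
    fc_min: float = 1.0,
    q_max: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Full per-tissue DEG table: gene, log2fc, p, q, call.

    Genes with zero pooled counts in both phases are excluded before testing
    (their fold change is undefined).  BH adjustment is applied per tissue
    over all tested genes; calls use inclusive thresholds
    ``|log2FC| >= fc_min`` and ``q <= q_max``.
    """
    shared = profile_a.genes.intersection(profile_b.genes)
    if len(shared) == 0:
        raise InputError("profiles share no genes")
    K_a = profile_a.counts.loc[shared].to_numpy().sum(axis=1).astype(float)
    K_b = profile_b.counts.loc[shared].to_numpy().sum(axis=1).astype(float)
    N_a = profile_a.lib_sizes.sum()
    N_b = profile_b.lib_sizes.sum()
    keep = (K_a + K_b) > 0
    genes = shared[keep]
    K_a, K_b = K_a[keep], K_b[keep]
    lfc = np.log2(((K_a + pseudocount) / N_a) / ((K_b + pseudocount) / N_b))
    _, p = deg_ztest(K_a, N_a, K_b, N_b)
    q = bh_adjust(p)
    table = pd.DataFrame({"gene": genes, "log2fc": lfc, "p": p, "q": q})
    return call_degs(table, fc_min=fc_min, q_max=q_max)


def call_degs(table: pd.DataFrame, fc_min: float = 1.0, q_max: float = 0.05) -> pd.DataFrame:
    """Assign up/down/none calls at inclusive |log2FC| and q thresholds."""
    out = table.copy()
    up = (out["log2fc"] >= fc_min) & (out["q"] <= q_max)
    down = (out["log2fc"] <= -fc_min) & (out["q"] <= q_max)
    out["call"] = np.select([up, down], ["up", "down"], default="none")
    return out


def apply_ortholog_map(table: pd.DataFrame, mapping: Mapping[str, str]) -> pd.DataFrame:
    """Translate a called DEG table to orthologous gene ids.

    Genes without a mapping are dropped (logged); when several source genes
    map to one ortholog, the most significant record (smallest q, then
    largest |log2fc|) is kept.  Applied after calling, so thresholds refer
    to the measured species.
    """
    import logging

    log = logging.getLogger(__name__)
    mapped = table[table["gene"].isin(mapping)].copy()
    dropped = len(table) - len(mapped)
    if dropped:
        log.info("%d of %d genes without ortholog mapping dropped", dropped, len(table))
    mapped["gene"] = mapped["gene"].map(mapping)
    mapped = mapped.sort_values(["q", "log2fc"], ascending=[True, False], key=abs)
    return mapped.drop_duplicates("gene", keep="first").sort_index().reset_index(drop=True)


def trend_vector(table: pd.DataFrame, tissue: str) -> TrendVector:
    """Encode a called DEG table as a +1/-1 trend map over its DEGs."""
    trend = {}
    for gene, call in zip(table["gene"], table["call"]):
        if call == "up":
            trend[gene] = +1
        elif call == "down":
            trend[gene] = -1
    return TrendVector(tissue=tissue, trend=trend)


def tissue_cosine_matrix(trends: Sequence[TrendVector]) -> pd.DataFrame:
    """Cosine similarity between tissues on the trends of their shared DEGs.

    For each pair the trend vectors are restricted to genes that are DEGs in
    both tissues; because entries are +-1 the cosine reduces to the mean of
    the elementwise product.  Pairs sharing no DEG get NaN (undefined); the
    diagonal is 1 by convention.
    """
    if len(trends) < 2:
        raise InputError("need at least two tissues")
    names = [t.tissue for t in trends]
    mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for i, ti in enumerate(trends):
        mat.iloc[i, i] = 1.0
        for j in range(i + 1, len(trends)):
            tj = trends[j]
            shared = set(ti.trend) & set(tj.trend)
            if shared:
                prod = [ti.trend[g] * tj.trend[g] for g in shared]
                mat.iloc[i, j] = mat.iloc[j, i] = float(np.mean(prod))
    return mat


def select_ectts(deg_counts: Mapping[str, int], k: int = 6) -> list[str]:
    """Top-k tissues by total DEG count (ties broken by tissue id)."""
    if k > len(deg_counts):
        raise InputError(f"k={k} exceeds the number of tissues ({len(deg_counts)})")
    ranked = sorted(deg_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [tissue for tissue, _ in ranked[:k]]
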