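"""Transcriptomic alteration signature (TAS) comparative engine.

A TAS is a gene-indexed log2 fold-change vector contrasting an experimental
state with its control.  The estrus-induced TAS of a tissue (estrus vs
diestrus) is matched by Spearman correlation against a labelled library of
same-tissue signatures; significant matches (|SCC| >= 0.1) vote, through
their beneficial/deleterious outcome labels, on whether estrus or diestrus
is the protective phase for that tissue (phase-to-tissue specific
protection, PTSP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .deg import ExpressionProfile, pooled_log2fc
from .errors import InputError

log = logging.getLogger(__name__)

OUTCOMES = ("beneficial", "deleterious", "none")
#: reproductive tissues whose deleterious matches may reflect normal cycle
#: physiology rather than harm; excluded from protection verdicts by default
REPRODUCTIVE_TISSUES = ("ovary", "uterus")


@dataclass
class TAS:
    """One log2FC signature with tissue origin and outcome annotation.

    ``label_path`` is the ordered multi-level annotation of the source
    experiment, e.g. ``("deleterious", "disease", "cancer")``.
    """

    id: str
    tissue: str
    genes: np.ndarray
    values: np.ndarray
    outcome: str = "none"
    label_path: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes)
        self.values = np.asarray(self.values, dtype=float)
        if self.genes.shape[0] != self.values.shape[0]:
            raise InputError("genes and values must have equal length")
        if not np.isfinite(self.values).all():
            raise InputError("signature values must be finite")
        if self.outcome not in OUTCOMES:
            raise InputError(f"outcome must be one of {OUTCOMES}")

    def __len__(self) -> int:
        return int(self.genes.shape[0])


@dataclass(frozen=True)
class PTSPCall:
    """Aggregated protective-phase verdict for one tissue."""

    tissue: str
    protective_votes: int
    harmful_votes: int
    verdict: str  # estrus-protective | diestrus-protective | indeterminate
    sign_test_p: float


def build_tas(
    profile_a: ExpressionProfile,
    profile_b: ExpressionProfile,
    pseudocount: float = 1.0,
    tas_id: str | None = None,
) -> TAS:
    """Build the phase-A-vs-phase-B signature from two expression profiles.

    Uses the same pooled-rate log2FC estimator as the DEG caller; genes with
    zero pooled counts in both profiles are dropped.
    """
    shared = profile_a.genes.intersection(profile_b.genes)
    if len(shared) == 0:
        raise InputError("profiles share no genes")
    K_a = profile_a.counts.loc[shared].to_numpy().sum(axis=1).astype(float)
    K_b = profile_b.counts.loc[shared].to_numpy().sum(axis=1).astype(float)
    keep = (K_a + K_b) > 0
    values = pooled_log2fc(
        K_a[keep], K_b[keep], profile_a.lib_sizes, profile_b.lib_sizes, pseudocount
    )
    name = tas_id or f"{profile_a.tissue}_{profile_a.phase}_vs_{profile_b.phase}"
    return TAS(id=name, tissue=profile_a.tissue, genes=shared[keep].to_numpy(), values=values)


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson on average (midrank) ranks.

    Returns NaN when either vector has zero rank variance (all values tied),
    where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("inputs must be equal-length 1-D vectors")
    if x.size < 3:
        raise InputError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def scc_pvalue(scc: float, n: int) -> float:
    """Two-sided p-value for a Spearman coefficient via the t approximation.

    ``t = scc * sqrt((n - 2) / (1 - scc^2))`` on n - 2 degrees of freedom;
    |scc| = 1 maps to p = 0.  Standard at transcriptome-scale n.
    """
    if n < 3:
        raise InputError("need n >= 3")
    if np.isnan(scc):
        return float("nan")
    if abs(scc) >= 1.0:
        return 0.0
    t = scc * np.sqrt((n - 2) / (1.0 - scc**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _aligned_scc(a: TAS, b: TAS) -> tuple[float, int]:
    """SCC of two signatures over their gene intersection."""
    shared, ia, ib = np.intersect1d(a.genes, b.genes, return_indices=True)
    if shared.size < 3:
        return float("nan"), int(shared.size)
    return spearman(a.values[ia], b.values[ib]), int(shared.size)


def prune_redundant(
    library: Sequence[TAS], scc_cut: float = 0.5, min_overlap: int = 100
) -> list[TAS]:
    """Remove redundant library members (same-tissue SCC >= scc_cut).

    Greedy single pass in input (curation) order: a member is retained iff
    its SCC with every already-retained member of the same tissue is below
    the cut.  Pairs sharing fewer than ``min_overlap`` genes cannot be
    assessed and are treated as non-redundant.  Deterministic.
    """
    if not library:
        raise InputError("library is empty")
    retained: list[TAS] = []
    for member in library:
        redundant = False
        for kept in retained:
            if kept.tissue != member.tissue:
                continue
            scc, n = _aligned_scc(member, kept)
            if n >= min_overlap and not np.isnan(scc) and scc >= scc_cut:
                redundant = True
                break
        if not redundant:
            retained.append(member)
    return retained


def is_hit(scc: float, threshold: float = 0.1) -> bool:
    """Match rule: a correlation is a significant hit iff |SCC| >= threshold."""
    return bool(not np.isnan(scc) and abs(scc) >= threshold)


def match_library(
    query: TAS,
    library: Sequence[TAS],
    scc_threshold: float = 0.1,
    min_overlap: int = 100,
) -> pd.DataFrame:
    """Correlate a query signature against same-tissue library members.

    SCC is computed over the gene-space intersection of each pair; pairs
    with fewer than ``min_overlap`` shared genes are skipped (logged).
    Returns one row per evaluated member with columns ``library_id,
    n_shared, scc, p, significant, outcome, label_path``.
    """
    same_tissue = [m for m in library if m.tissue == query.tissue]
    if not same_tissue:
        log.warning("no library members for tissue %r", query.tissue)
    rows = []
    n_skipped = 0
    for member in same_tissue:
        scc, n_shared = _aligned_scc(query, member)
        if n_shared < min_overlap:
            n_skipped += 1
            continue
        rows.append(
            {
                "query_id": query.id,
                "library_id": member.id,
                "n_shared": n_shared,
                "scc": scc,
                "p": scc_pvalue(scc, n_shared),
                "significant": is_hit(scc, scc_threshold),
                "outcome": member.outcome,
                "label_path": "/".join(member.label_path),
            }
        )
    if n_skipped:
        log.info("skipped %d members below min_overlap=%d", n_skipped, min_overlap)
    cols = ["query_id", "library_id", "n_shared", "scc", "p", "significant", "outcome", "label_path"]
    return pd.DataFrame(rows, columns=cols)


def ptsp_aggregate(hits: pd.DataFrame, tissue: str) -> PTSPCall:
    """Aggregate labelled significant hits into a protective-phase verdict.

    Each significant hit with a beneficial/deleterious label votes:
    positive correlation with a beneficial state, or negative correlation
    with a deleterious state, is evidence that estrus protects the tissue;
    the converse is evidence for diestrus.  The verdict is the majority
    vote, reported with a two-sided exact binomial sign test against an
    even split; ties or no labelled hits give ``indeterminate``.
    """
    if hits.empty:
        voters = hits
    else:
        voters = hits[hits["significant"].astype(bool) & (hits["outcome"] != "none")]
    protective = int(
        (
            ((voters["scc"] > 0) & (voters["outcome"] == "beneficial"))
            | ((voters["scc"] < 0) & (voters["outcome"] == "deleterious"))
        ).sum()
    )
    harmful = len(voters) - protective
    total = protective + harmful
    if total == 0 or protective == harmful:
        verdict = "indeterminate"
    elif protective > harmful:
        verdict = "estrus-protective"
    else:
        verdict = "diestrus-protective"
    p = float("nan") if total == 0 else stats.binomtest(protective, total, 0.5).pvalue
    return PTSPCall(
        tissue=tissue,
        protective_votes=protective,
        harmful_votes=harmful,
        verdict=verdict,
        sign_test_p=float(p),
    )


def label_hierarchy_summary(
    hits: pd.DataFrame, library: Sequence[TAS]
) -> dict[str, dict[str, int]]:
    """Counts per label-path prefix for positive hits, negative hits, background.

    The background is the full library; prefixes are slash-joined so a hit
    labelled ``deleterious/disease/cancer`` increments three prefixes.
    """

    def count(paths) -> dict[str, int]:
        out: dict[str, int] = {}
        for path in paths:
            parts = [p for p in path if p]
            for depth in range(1, len(parts) + 1):
                key = "/".join(parts[:depth])
                out[key] = out.get(key, 0) + 1
        return out

    sig = hits if hits.empty else hits[hits["significant"].astype(bool)]
    pos = [tuple(s.split("/")) for s in sig.loc[sig["scc"] > 0, "label_path"]] if not sig.empty else []
    neg = [tuple(s.split("/")) for s in sig.loc[sig["scc"] < 0, "label_path"]] if not sig.empty else []
    background = [m.label_path for m in library]
    return {"positive": count(pos), "negative": count(neg), "background": count(background)}


def ptsp_calls(
    hits_by_tissue: Mapping[str, pd.DataFrame],
    exclude_tissues: Sequence[str] = REPRODUCTIVE_TISSUES,
) -> dict[str, PTSPCall]:
    """PTSP verdicts for each tissue, skipping reproductive tissues by default.

    In reproductive tissues (ovary, uterus) deleterious-labelled matches can
    simply reflect the physiological estrus/diestrus difference, so verdicts
    there are suppressed unless ``exclude_tissues`` is overridden.
    """
    return {
        tissue: ptsp_aggregate(hits, tissue)
        for tissue, hits in hits_by_tissue.items()
        if tissue not in set(exclude_tissues)
    }
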