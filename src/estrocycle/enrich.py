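"""Gene-set over-representation analysis of DEG sets.

One-sided Fisher exact (hypergeometric tail) tests of up-regulated,
down-regulated, and combined DEG sets against GMT collections, with BH
correction within each tissue x collection x direction family, plus the
cross-tissue reporting rules: terms shared by several tissues and
term-term links by member overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .deg import TrendVector, bh_adjust
from .errors import InputError

log = logging.getLogger(__name__)

DIRECTIONS = ("up", "down", "both")


@dataclass(frozen=True)
class GeneSet:
    """One annotated gene set from a collection such as KEGG or Hallmark."""

    id: str
    name: str
    collection: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise InputError(f"gene set {self.id!r} has no members")


def read_gmt(path, collection: str = "custom") -> list[GeneSet]:
    """Read a standard GMT file (id <tab> description <tab> members...)."""
    sets = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: GMT line needs id, description and >=1 member")
            sets.append(
                GeneSet(
                    id=fields[0],
                    name=fields[1],
                    collection=collection,
                    members=frozenset(fields[2:]),
                )
            )
    return sets


def write_gmt(sets: Sequence[GeneSet], path) -> None:
    with open(path, "w") as handle:
        for gs in sets:
            handle.write("\t".join([gs.id, gs.name, *sorted(gs.members)]) + "\n")


def fisher_enrich(
    deg_set: Iterable[str], term: Iterable[str], universe: Iterable[str]
) -> tuple[int, float]:
    """One-sided enrichment test for a DEG set against one term.

    Builds the 2x2 table within the universe and returns the hypergeometric
    upper tail P(X >= overlap), i.e. the one-sided Fisher exact p-value.
    Returns ``(overlap, p)``.
    """
    universe = set(universe)
    if not universe:
        raise InputError("universe is empty")
    degs = set(deg_set) & universe
    members = set(term) & universe
    overlap = len(degs & members)
    # P(X >= k) for X ~ Hypergeom(M=|U|, n=|term|, N=|degs|)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(degs)))
    return overlap, min(p, 1.0)


def run_enrichment(
    trends: Sequence[TrendVector],
    genesets: Sequence[GeneSet],
    universe: Mapping[str, set] | Iterable[str],
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Test up/down/both DEG sets of every tissue against every term.

    ``universe`` is the per-tissue background of genes tested for
    differential expression (a mapping tissue -> gene set, or one shared
    set).  BH adjustment is applied within each tissue x collection x
    direction family.  DEG ids absent from the universe are dropped with a
    logged count.  Returns one row per (term, tissue, direction) with the
    overlapping genes retained for downstream overlap reporting.
    """
    rows = []
    for trend in trends:
        if isinstance(universe, Mapping):
            background = set(universe[trend.tissue])
        else:
            background = set(universe)
        degs = set(trend.trend)
        dropped = degs - background
        if dropped:
            log.info("%s: %d DEG ids outside the universe dropped", trend.tissue, len(dropped))
            degs &= background
        if not degs:
            continue
        sets_by_direction = {
            "up": {g for g in degs if trend.trend[g] == +1},
            "down": {g for g in degs if trend.trend[g] == -1},
            "both": degs,
        }
        for direction, deg_set in sets_by_direction.items():
            if not deg_set:
                continue
            for gs in genesets:
                overlap, p = fisher_enrich(deg_set, gs.members, background)
                rows.append(
                    {
                        "term": gs.id,
                        "name": gs.name,
                        "collection": gs.collection,
                        "tissue": trend.tissue,
                        "direction": direction,
                        "overlap": overlap,
                        "overlap_genes": "|".join(sorted(deg_set & gs.members & background)),
                        "p": p,
                    }
                )
    results = pd.DataFrame(
        rows,
        columns=["term", "name", "collection", "tissue", "direction", "overlap", "overlap_genes", "p"],
    )
    if results.empty:
        results["q"] = pd.Series(dtype=float)
        results["significant"] = pd.Series(dtype=bool)
        return results
    results["q"] = np.nan
    for _, idx in results.groupby(["tissue", "collection", "direction"]).groups.items():
        results.loc[idx, "q"] = bh_adjust(results.loc[idx, "p"].to_numpy())
    results["significant"] = results["q"] <= q_max
    return results


def shared_terms(results: pd.DataFrame, min_tissues: int = 5) -> list[str]:
    """Terms significant (any direction) in at least ``min_tissues`` tissues."""
    if results.empty:
        return []
    sig = results[results["significant"]]
    counts = sig.groupby("term")["tissue"].nunique()
    return sorted(counts.index[counts >= min_tissues])


def term_deg_unions(results: pd.DataFrame, terms: Sequence[str]) -> dict[str, set]:
    """Union of contributing DEG overlaps per term across significant rows."""
    unions: dict[str, set] = {t: set() for t in terms}
    sig = results[results["significant"] & results["term"].isin(terms)]
    for term, genes in zip(sig["term"], sig["overlap_genes"]):
        if genes:
            unions[term] |= set(genes.split("|"))
    return unions


def term_overlap_links(
    term_genes: Mapping[str, set],
    min_frac: float = 0.25,
    collections: Mapping[str, str] | None = None,
    hide_within: Sequence[str] = (),
) -> list[tuple[str, str, float]]:
    """Link two terms when they share enough contributing DEGs.

    The overlap fraction is ``|A & B| / min(|A|, |B|)`` (symmetric and
    conservative for nested sets); terms are linked at fraction >=
    ``min_frac``.  With ``collections`` given, links internal to any
    collection named in ``hide_within`` are suppressed (a reporting
    option for link-dense collections).
    """
    names = sorted(term_genes)
    links = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            set_a, set_b = term_genes[a], term_genes[b]
            if not set_a or not set_b:
                continue
            if collections is not None and hide_within:
                if collections.get(a) == collections.get(b) and collections.get(a) in hide_within:
                    continue
            frac = len(set_a & set_b) / min(len(set_a), len(set_b))
            if frac >= min_frac:
                links.append((a, b, frac))
    return links
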