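"""Causal inference of functional transcription factors from signed regulons.

Each TF's signed target set (regulon) is scored against the observed DEG
trend of a tissue: an activity direction is supported when targets move the
way the signed edges predict.  Significance comes from a permutation null
that shuffles trend labels over the measured-gene universe, with BH
correction across all (TF, direction) tests per tissue and a one-sided
q <= 0.05 call.  Activity scores are signed, shrunk -log10(q) values; key
TFs are those significant across several estrous-cycle target tissues, and
the expression-activity correlation checks that significant TFs' own fold
changes track their inferred regulatory activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import stage_rng
from .deg import TrendVector, bh_adjust
from .errors import InputError
from . import tascomp

log = logging.getLogger(__name__)

#: floor on q before -log10 shrinkage, capping activity scores at 16
ACTIVITY_CAP = 16.0


@dataclass(frozen=True)
class Regulon:
    """Signed target set of one TF: (gene, sign) with sign in {+1, -1, 0}.

    Sign 0 marks regulation of unknown direction.
    """

    tf: str
    targets: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.targets]
        if len(genes) != len(set(genes)):
            raise InputError(f"regulon {self.tf!r} has duplicate target ids")
        bad = {s for _, s in self.targets if s not in (-1, 0, 1)}
        if bad:
            raise InputError(f"edge signs must be -1, 0 or +1; got {bad}")


def consistency_score(
    regulon: Regulon, trend: TrendVector, direction: str
) -> tuple[int, int] | None:
    """Correct-minus-incorrect consistency of a regulon with a trend.

    For a hypothesised TF direction (up = +1, down = -1), each signed edge
    predicts its target's trend as ``direction_sign * edge_sign``; matching
    targets add +1 and contradicting targets -1.  Unsigned (sign 0) edges
    add +1 for any measured target, as responsiveness evidence without a
    direction.  Only targets in the trend domain are counted.  Returns
    ``(score, n_measured)``, or None when no target is measured
    (not testable).
    """
    if direction not in ("up", "down"):
        raise InputError("direction must be 'up' or 'down'")
    dir_sign = 1 if direction == "up" else -1
    score = 0
    n_measured = 0
    for gene, sign in regulon.targets:
        t = trend.trend.get(gene)
        if t is None:
            continue
        n_measured += 1
        score += 1 if sign == 0 else dir_sign * sign * t
    if n_measured == 0:
        return None
    return score, n_measured


def permutation_null(
    regulon: Regulon,
    trend: TrendVector,
    direction: str,
    B: int = 1000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> float | None:
    """One-sided permutation p-value for a regulon's consistency score.

    Trend labels are permuted over the measured-gene universe ``B`` times
    with the regulon fixed; ``p = (1 + #{S_perm >= S_obs}) / (B + 1)``.
    Returns None for a not-testable regulon.
    """
    if B < 100:
        raise InputError("need B >= 100 permutations")
    observed = consistency_score(regulon, trend, direction)
    if observed is None:
        return None
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    score_obs, _ = observed
    dir_sign = 1 if direction == "up" else -1
    domain = np.fromiter(trend.trend.values(), dtype=np.int64)
    measured = [(g, s) for g, s in regulon.targets if g in trend.trend]
    weights = np.array([dir_sign * s for _, s in measured if s != 0], dtype=np.int64)
    n_zero = sum(1 for _, s in measured if s == 0)
    n_signed = weights.size
    if n_signed == 0:
        # only unsigned edges: score is invariant under permutation
        exceed = B
    else:
        # drawing labels without replacement == permuting then reading the
        # target positions; vectorised via random-key argpartition
        keys = rng.random((B, domain.size))
        idx = np.argpartition(keys, n_signed - 1, axis=1)[:, :n_signed]
        perm_scores = (domain[idx] * weights).sum(axis=1) + n_zero
        exceed = int((perm_scores >= score_obs).sum())
    return (1.0 + exceed) / (B + 1.0)


def infer_tf_activity(
    regulons: Sequence[Regulon],
    trend: TrendVector,
    tissue: str,
    B: int = 1000,
    seed: int = 0,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Directional TF activity calls for one tissue.

    Both directions are tested per testable TF; BH adjustment runs across
    all (TF, direction) pairs of the tissue, then each TF keeps its better
    direction (smaller q, ties by larger |score|, then 'up') so no TF is
    called active in both directions at once.  The activity score is the
    signed, shrunk significance ``sign(direction) * min(-log10(q), 16)``.
    """
    rng = stage_rng(seed, f"tfact:{tissue}")
    rows = []
    for regulon in regulons:
        for direction in ("up", "down"):
            scored = consistency_score(regulon, trend, direction)
            if scored is None:
                continue
            score, n_measured = scored
            p = permutation_null(regulon, trend, direction, B=B, rng=rng)
            rows.append(
                {
                    "tf": regulon.tf,
                    "tissue": tissue,
                    "direction": direction,
                    "score": score,
                    "n_measured": n_measured,
                    "p": p,
                }
            )
    columns = ["tf", "tissue", "direction", "score", "n_measured", "p", "q", "significant", "activity_score"]
    if not rows:
        log.warning("%s: no testable regulon", tissue)
        return pd.DataFrame(columns=columns)
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    # one direction per TF: smaller q, then larger |score|, then 'up'
    table["_rank"] = list(zip(table["q"], -table["score"].abs(), table["direction"] != "up"))
    table = (
        table.sort_values(["tf", "_rank"]).groupby("tf", as_index=False).first().drop(columns="_rank")
    )
    table["significant"] = table["q"] <= q_max
    dir_sign = np.where(table["direction"] == "up", 1.0, -1.0)
    table["activity_score"] = dir_sign * np.minimum(
        -np.log10(np.maximum(table["q"], 10.0**-ACTIVITY_CAP)), ACTIVITY_CAP
    )
    return table[columns]


def key_tf_selection(
    results_by_tissue: Mapping[str, pd.DataFrame],
    ectts: Sequence[str],
    min_share: int = 4,
) -> list[str]:
    """TFs significant (either direction) in at least ``min_share`` ECTTs."""
    counts: dict[str, int] = {}
    for tissue in ectts:
        table = results_by_tissue.get(tissue)
        if table is None or table.empty:
            continue
        for tf in table.loc[table["significant"], "tf"].unique():
            counts[tf] = counts.get(tf, 0) + 1
    return sorted(tf for tf, c in counts.items() if c >= min_share)


def expression_activity_correlation(
    results_by_tissue: Mapping[str, pd.DataFrame],
    deg_tables: Mapping[str, pd.DataFrame],
) -> tuple[float, float]:
    """Spearman correlation of TF log2FC with signed activity score.

    Pools all significant (TF, tissue) pairs whose TF has a fold change in
    that tissue's DEG table (others are dropped and logged).  Returns
    ``(scc, p)``; fewer than 3 pairs gives ``(nan, nan)``.
    """
    lfc = []
    activity = []
    dropped = 0
    for tissue, table in results_by_tissue.items():
        degs = deg_tables.get(tissue)
        if degs is None or table.empty:
            continue
        fc = dict(zip(degs["gene"], degs["log2fc"]))
        for _, row in table[table["significant"]].iterrows():
            if row["tf"] in fc:
                lfc.append(fc[row["tf"]])
                activity.append(row["activity_score"])
            else:
                dropped += 1
    if dropped:
        log.info("%d significant TFs without a fold change; dropped", dropped)
    if len(lfc) < 3:
        return float("nan"), float("nan")
    scc = tascomp.spearman(lfc, activity)
    return scc, tascomp.scc_pvalue(scc, len(lfc))
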