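"""Plain-text readers and writers for all pipeline inputs and outputs.

Formats: count matrices as TSV (rows = genes, columns = ``TISSUE_PHASE_repN``
sample ids), signatures as per-member TSV (gene, log2fc) plus one metadata
TSV, networks as 3-column edge lists (source, target, sign), regulons as
(tf, target, sign) TSV, gene sets as GMT.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .deg import ExpressionProfile
from .errors import InputError
from .tascomp import TAS
from .tfact import Regulon


def write_counts(profile_a: ExpressionProfile, profile_b: ExpressionProfile, path) -> None:
    """Write an estrus/diestrus profile pair as one TSV per tissue."""
    merged = profile_a.counts.join(profile_b.counts)
    merged.to_csv(path, sep="\t")


def read_counts(path) -> tuple[ExpressionProfile, ExpressionProfile]:
    """Read a per-tissue count TSV back into its two phase profiles.

    Sample columns must follow ``TISSUE_PHASE_repN``; the phase token is
    parsed from the right so tissue names may contain underscores.
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    by_phase: dict[str, list[str]] = {"estrus": [], "diestrus": []}
    tissue = None
    for col in table.columns:
        parts = col.rsplit("_", 2)
        if len(parts) != 3 or parts[1] not in by_phase:
            raise InputError(f"{path}: sample column {col!r} is not TISSUE_PHASE_repN")
        tissue = parts[0]
        by_phase[parts[1]].append(col)
    if not by_phase["estrus"] or not by_phase["diestrus"]:
        raise InputError(f"{path}: need replicates for both phases")
    prof_a = ExpressionProfile(tissue=tissue, phase="estrus", counts=table[by_phase["estrus"]])
    prof_b = ExpressionProfile(tissue=tissue, phase="diestrus", counts=table[by_phase["diestrus"]])
    return prof_a, prof_b


def write_tas(tas: TAS, path) -> None:
    pd.DataFrame({"gene": tas.genes, "log2fc": tas.values}).to_csv(path, sep="\t", index=False)


def read_tas(path, tas_id: str, tissue: str, outcome: str = "none", label_path=()) -> TAS:
    table = pd.read_csv(path, sep="\t")
    if not {"gene", "log2fc"} <= set(table.columns):
        raise InputError(f"{path}: signature TSV needs 'gene' and 'log2fc' columns")
    return TAS(
        id=tas_id,
        tissue=tissue,
        genes=table["gene"].to_numpy(),
        values=table["log2fc"].to_numpy(),
        outcome=outcome,
        label_path=tuple(label_path),
    )


def write_tas_library(members: Sequence[TAS], directory) -> Path:
    """Write one TSV per member plus a metadata table; returns metadata path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for tas in members:
        filename = f"{tas.id}.tsv"
        write_tas(tas, directory / filename)
        rows.append(
            {
                "id": tas.id,
                "tissue": tas.tissue,
                "outcome": tas.outcome,
                "label_path": "/".join(tas.label_path),
                "file": filename,
            }
        )
    meta_path = directory / "library_metadata.tsv"
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)
    return meta_path


def read_tas_library(metadata_path) -> list[TAS]:
    metadata_path = Path(metadata_path)
    meta = pd.read_csv(metadata_path, sep="\t", keep_default_na=False)
    members = []
    for _, row in meta.iterrows():
        label_path = tuple(p for p in str(row["label_path"]).split("/") if p)
        members.append(
            read_tas(
                metadata_path.parent / row["file"],
                tas_id=row["id"],
                tissue=row["tissue"],
                outcome=row["outcome"] or "none",
                label_path=label_path,
            )
        )
    return members


def write_network(graph: nx.DiGraph, path) -> None:
    with open(path, "w") as handle:
        handle.write("source\ttarget\tsign\n")
        for source, target in sorted(graph.edges()):
            sign = graph.edges[source, target].get("sign", 1)
            handle.write(f"{source}\t{target}\t{sign}\n")


def read_network(path) -> nx.DiGraph:
    graph = nx.DiGraph()
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise InputError(f"{path}: edge list needs at least source and target columns")
    for row in table.itertuples(index=False):
        source, target = str(row[0]), str(row[1])
        if source != target:
            graph.add_edge(source, target)
    return graph


def write_regulons(regulons: Sequence[Regulon], path) -> None:
    rows = [
        {"tf": reg.tf, "target": gene, "sign": sign}
        for reg in regulons
        for gene, sign in reg.targets
    ]
    pd.DataFrame(rows, columns=["tf", "target", "sign"]).to_csv(path, sep="\t", index=False)


def read_regulons(path) -> list[Regulon]:
    table = pd.read_csv(path, sep="\t")
    if not {"tf", "target", "sign"} <= set(table.columns):
        raise InputError(f"{path}: regulon TSV needs tf, target and sign columns")
    regulons = []
    for tf, group in table.groupby("tf", sort=True):
        targets = tuple((str(g), int(s)) for g, s in zip(group["target"], group["sign"]))
        regulons.append(Regulon(tf=str(tf), targets=targets))
    return regulons


def read_ortholog_map(path) -> dict[str, str]:
    """Read a 2-column TSV mapping measured gene ids to ortholog ids."""
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise InputError(f"{path}: ortholog map needs source and target columns")
    return dict(zip(table.iloc[:, 0].astype(str), table.iloc[:, 1].astype(str)))


def list_count_files(directory) -> list[Path]:
    directory = Path(directory)
    files = sorted(p for p in directory.glob("counts_*.tsv"))
    if not files:
        raise InputError(f"no counts_*.tsv files under {os.fspath(directory)}")
    return files
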