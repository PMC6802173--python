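"""Transcriptional regulatory network construction and circuitry motifs.

Edges are TF → target gene, with "regulator binding near a gene implies
regulatory control" as the edge semantics: every peak of a factor is
assigned to target gene(s) under the ±20 kb + gene-body rule (nearest-gene
fallback included), and an edge exists when at least one peak supports it.
Circuitry motifs are enumerated on the TF-restricted subgraph:
autoregulation (A→A), feedback (A→B and B→A), and feed-forward loops as
ordered triples (A,B,C) of distinct TFs with A→B, B→C, A→C.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .annotation import assign_target_gene
from .config import PipelineConfig
from .errors import ConfigurationError
from .io import GeneModel, PeakSet

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatoryNetwork",
    "CircuitrySummary",
    "build_trn",
    "find_circuitry",
    "coregulated_gene_set",
    "export_edge_list",
    "read_edge_list",
]


@dataclass
class RegulatoryNetwork:
    """Directed TF → gene edge set with supporting peak evidence."""

    tfs: list[str]
    edges: dict[tuple[str, str], tuple[str, ...]]  # (tf, gene) -> peak ids
    tf_gene_map: dict[str, str]

    def targets_of(self, tf: str) -> set[str]:
        return {g for (t, g) in self.edges if t == tf}

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.tfs)
        for (tf, gene), ev in self.edges.items():
            g.add_edge(tf, gene, n_peaks=len(ev))
        return g


@dataclass(frozen=True)
class CircuitrySummary:
    autoregulators: frozenset[str]
    feedback_pairs: frozenset[frozenset[str]]
    feedforward_triads: frozenset[tuple[str, str, str]]


def build_trn(
    peaksets: Sequence[PeakSet],
    genes: Iterable[GeneModel],
    tf_gene_map: Mapping[str, str],
    config: PipelineConfig,
) -> RegulatoryNetwork:
    """Assign every factor's peaks to target genes and collect the edge set.

    ``tf_gene_map`` names each factor's own gene so that self-edges can be
    detected without relying on factor/gene string equality.
    """
    gene_list = list(genes)
    missing = [ps.factor for ps in peaksets if ps.factor not in tf_gene_map]
    if missing:
        raise ConfigurationError(f"factors missing from tf_gene_map: {missing}")
    gene_chroms = {g.chrom for g in gene_list}
    edges: dict[tuple[str, str], list[str]] = {}
    skipped = 0
    for ps in peaksets:
        for i, peak in enumerate(ps):
            if peak.chrom not in gene_chroms:
                skipped += 1
                continue
            peak_id = f"{ps.factor}:{i}"
            for target in assign_target_gene(peak, gene_list, config):
                edges.setdefault((ps.factor, target), []).append(peak_id)
    if skipped:
        logger.warning("skipped %d peaks on chromosomes without genes", skipped)
    return RegulatoryNetwork(
        tfs=[ps.factor for ps in peaksets],
        edges={k: tuple(v) for k, v in edges.items()},
        tf_gene_map=dict(tf_gene_map),
    )


def find_circuitry(network: RegulatoryNetwork) -> CircuitrySummary:
    """Enumerate autoregulation, feedback pairs, and feed-forward triads.

    The network is first restricted to TF nodes: an edge A→B between TFs
    exists when factor A targets the gene of factor B (via
    ``tf_gene_map``).  Self-loops count only toward autoregulation.
    """
    gene_to_tfs: dict[str, list[str]] = {}
    for tf, gene in network.tf_gene_map.items():
        gene_to_tfs.setdefault(gene, []).append(tf)

    g = nx.DiGraph()
    g.add_nodes_from(network.tfs)
    for (tf, gene) in network.edges:
        for target_tf in gene_to_tfs.get(gene, ()):
            if target_tf in g:
                g.add_edge(tf, target_tf)

    auto = frozenset(a for a in g.nodes if g.has_edge(a, a))
    feedback = frozenset(
        frozenset((a, b))
        for a, b in g.edges
        if a != b and g.has_edge(b, a)
    )
    ffl = set()
    for a in g.nodes:
        for b in g.successors(a):
            if b == a:
                continue
            for c in g.successors(b):
                if c != a and c != b and g.has_edge(a, c):
                    ffl.add((a, b, c))
    return CircuitrySummary(auto, feedback, frozenset(ffl))


def coregulated_gene_set(
    peaksets: Sequence[PeakSet],
    genes: Iterable[GeneModel],
    threshold: int,
    config: PipelineConfig,
    network: RegulatoryNetwork | None = None,
    tf_gene_map: Mapping[str, str] | None = None,
) -> set[str]:
    """Genes targeted by strictly more than ``threshold`` distinct factors."""
    if network is None:
        n_factors = len(peaksets)
        if threshold > n_factors:
            raise ConfigurationError(
                f"threshold {threshold} exceeds factor count {n_factors}"
            )
        tf_map = dict(tf_gene_map) if tf_gene_map else {ps.factor: ps.factor for ps in peaksets}
        network = build_trn(peaksets, genes, tf_map, config)
    elif threshold > len(network.tfs):
        raise ConfigurationError(
            f"threshold {threshold} exceeds factor count {len(network.tfs)}"
        )
    counts: dict[str, set[str]] = {}
    for (tf, gene) in network.edges:
        counts.setdefault(gene, set()).add(tf)
    return {g for g, tfs in counts.items() if len(tfs) > threshold}


def export_edge_list(network: RegulatoryNetwork, path: str | Path) -> None:
    """Write a deterministic TSV edge list (source, target, n_peaks)."""
    rows = sorted(
        (tf, gene, len(ev)) for (tf, gene), ev in network.edges.items()
    )
    with open(path, "w") as fh:
        fh.write("source\ttarget\tn_peaks\n")
        for tf, gene, n in rows:
            fh.write(f"{tf}\t{gene}\t{n}\n")


def read_edge_list(
    path: str | Path, tf_gene_map: Mapping[str, str]
) -> RegulatoryNetwork:
    """Round-trip loader for :func:`export_edge_list` output.

    Evidence peak identities are not stored in the file; synthetic ids are
    rebuilt so evidence *counts* survive the round trip.
    """
    edges: dict[tuple[str, str], tuple[str, ...]] = {}
    tfs: list[str] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("source\ttarget"):
            raise ConfigurationError(f"{path}: not an edge-list file")
        for line in fh:
            tf, gene, n = line.rstrip("\n").split("\t")
            if tf not in tfs:
                tfs.append(tf)
            edges[(tf, gene)] = tuple(f"{tf}:{i}" for i in range(int(n)))
    return RegulatoryNetwork(tfs, edges, dict(tf_gene_map))
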