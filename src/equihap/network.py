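"""Minimum-spanning haplotype networks and phylogeographic summaries.

Haplotype networks connect the unique variant profiles of a dataset by
a spanning tree of minimum total Hamming distance, the construction
used for control-region phylogeography.  Because many distinct minimum
spanning trees usually exist under tied distances, edges are chosen by
Kruskal's algorithm with a fixed tie-break — (distance, smaller node id,
larger node id), node ids assigned by sorted canonical key — so the
output is bit-reproducible.

On top of the network this module derives the standard cohort
summaries: counts of haplotypes unique to a cohort and the F% statistic
(percentage of a haplogroup's haplotypes that are unique to a cohort),
dominant (high-frequency) haplotypes, and a ranked list of candidate
ancestral haplotypes per haplogroup.  The ancestral ranking — degree
within the haplogroup, then carrier count — is an operational
convention, not an inference of ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

from .window import CollapsedHaplotype


@dataclass(frozen=True)
class HaplotypeNode:
    node_id: int
    canonical_key: str
    total_count: int
    region_counts: dict[str, int] = field(compare=False)
    haplogroup: str = ""

    def __post_init__(self) -> None:
        if self.total_count < 1:
            raise ValueError("total_count must be >= 1")
        if self.region_counts and sum(self.region_counts.values()) != self.total_count:
            raise ValueError("region_counts must sum to total_count")


@dataclass(frozen=True)
class NetworkEdge:
    a: int
    b: int
    distance: int

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("self-loop edge")
        if self.distance < 1:
            raise ValueError("edge distance must be >= 1")


@dataclass
class HaplotypeNetwork:
    nodes: list[HaplotypeNode]
    edges: list[NetworkEdge]

    @property
    def total_weight(self) -> int:
        return sum(e.distance for e in self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n.node_id, canonical_key=n.canonical_key,
                       total_count=n.total_count, haplogroup=n.haplogroup)
        for e in self.edges:
            g.add_edge(e.a, e.b, distance=e.distance)
        return g


def _hamming_labels(a: frozenset[str], b: frozenset[str]) -> int:
    return len(a ^ b)


def build_mst(haplotypes: list[CollapsedHaplotype]) -> HaplotypeNetwork:
    """Build the minimum spanning tree over unique haplotypes.

    Kruskal over edges sorted by (distance, a, b); node ids follow the
    sorted canonical keys, so the tree is deterministic.
    """
    if not haplotypes:
        raise ValueError("empty haplotype table")
    ordered = sorted(haplotypes, key=lambda h: h.canonical_key)
    nodes = [HaplotypeNode(i, h.canonical_key, h.total_count,
                           dict(h.region_counts), h.haplogroup or "")
             for i, h in enumerate(ordered)]
    all_edges = sorted(
        (( _hamming_labels(ordered[i].labels, ordered[j].labels), i, j)
         for i, j in combinations(range(len(ordered)), 2)),
    )
    parent = list(range(len(ordered)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[NetworkEdge] = []
    for d, i, j in all_edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append(NetworkEdge(i, j, d))
            if len(edges) == len(ordered) - 1:
                break
    return HaplotypeNetwork(nodes=nodes, edges=edges)


def unique_haplotype_stats(haplotypes: list[CollapsedHaplotype],
                           partition: dict[str, set[str] | list[str]]) -> pd.DataFrame:
    """Per-(haplogroup, cohort) haplotype counts, unique counts and F%.

    ``partition`` maps cohort names to the regions they cover; it must
    cover every region appearing in the data.  A haplotype counts for a
    cohort when it has at least one carrier there, and is *unique* to
    the cohort when all its carriers fall inside it.  F% is
    100 * n_unique / n_haplotypes.
    """
    region_to_cohort: dict[str, str] = {}
    for cohort, regions in partition.items():
        for r in regions:
            region_to_cohort[r] = cohort
    seen_regions = {r for h in haplotypes for r in h.region_counts}
    uncovered = seen_regions - set(region_to_cohort)
    if uncovered:
        raise ValueError(f"regions outside partition: {sorted(uncovered)}")

    rows = []
    haplogroups = sorted({h.haplogroup or "" for h in haplotypes})
    for hg in haplogroups:
        members = [h for h in haplotypes if (h.haplogroup or "") == hg]
        for cohort in sorted(partition):
            present = [h for h in members if any(
                region_to_cohort[r] == cohort for r in h.region_counts)]
            unique = [h for h in present if all(
                region_to_cohort[r] == cohort for r in h.region_counts)]
            n_hap = len(present)
            rows.append({
                "haplogroup": hg,
                "cohort": cohort,
                "n_haplotypes": n_hap,
                "n_unique": len(unique),
                "f_percent": 100.0 * len(unique) / n_hap if n_hap else 0.0,
            })
    return pd.DataFrame(rows, columns=["haplogroup", "cohort", "n_haplotypes",
                                       "n_unique", "f_percent"])


def dominant_haplotypes(haplotypes: list[CollapsedHaplotype],
                        min_count: int) -> list[CollapsedHaplotype]:
    """Haplotypes carried by at least ``min_count`` samples, most frequent first."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    kept = [h for h in haplotypes if h.total_count >= min_count]
    return sorted(kept, key=lambda h: (-h.total_count, h.canonical_key))


def candidate_ancestral(network: HaplotypeNetwork, haplogroup: str) -> list[HaplotypeNode]:
    """Rank a haplogroup's nodes as candidate ancestral haplotypes.

    Ordering: degree within the haplogroup's induced subtree (desc),
    then total carrier count (desc), then canonical key.  The rank-1
    node is the operational candidate; no claim of ancestry is made.
    """
    members = [n for n in network.nodes if n.haplogroup == haplogroup]
    if not members:
        raise ValueError(f"haplogroup {haplogroup!r} absent from network")
    ids = {n.node_id for n in members}
    degree: dict[int, int] = {i: 0 for i in ids}
    for e in network.edges:
        if e.a in ids and e.b in ids:
            degree[e.a] += 1
            degree[e.b] += 1
    return sorted(members, key=lambda n: (-degree[n.node_id], -n.total_count,
                                          n.canonical_key))


def write_network(network: HaplotypeNetwork, outdir: str | Path,
                  prefix: str = "network") -> dict[str, Path]:
    """Write nodes TSV, edges TSV and a GML file; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nodes_path = outdir / f"{prefix}_nodes.tsv"
    edges_path = outdir / f"{prefix}_edges.tsv"
    gml_path = outdir / f"{prefix}.gml"
    pd.DataFrame(
        [{"node_id": n.node_id, "canonical_key": n.canonical_key,
          "count": n.total_count, "haplogroup": n.haplogroup,
          "region_counts": ";".join(f"{r}:{c}" for r, c in sorted(n.region_counts.items()))}
         for n in network.nodes]
    ).to_csv(nodes_path, sep="\t", index=False)
    pd.DataFrame(
        [{"a": e.a, "b": e.b, "distance": e.distance} for e in network.edges],
        columns=["a", "b", "distance"],
    ).to_csv(edges_path, sep="\t", index=False)
    nx.write_gml(network.to_networkx(), gml_path)
    return {"nodes": nodes_path, "edges": edges_path, "gml": gml_path}
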