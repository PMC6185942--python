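"""Gene-network inference from top-ranked SNP-SNP interactions.

Each SNP of a top-ranked interaction is mapped to its nearest gene; the
SNP-SNP interaction is then lifted to a gene-gene edge between those two
genes.  Edges supported by several SNP pairs collapse into one edge with
a support list.  Self-loops (both SNPs nearest to the same gene) are
flagged and excluded from exports by default.  Networks from different
datasets can be intersected to retain only edges replicated in both.

Gene annotations are accepted as BED (0-based half-open) and converted
to 1-based inclusive intervals internally; SNP positions are 1-based
throughout (MAP/VCF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .stats import AssociationResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene intervals, 1-based inclusive, with unique gene ids."""

    table: pd.DataFrame  # columns: gene_id, chrom, start, end

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "start", "end"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"annotation requires columns {sorted(required)}")
        if self.table["gene_id"].duplicated().any():
            dup = self.table.loc[self.table["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if (self.table["start"] > self.table["end"]).any():
            raise ValueError("gene interval with start > end")

    @classmethod
    def from_records(cls, records: list[tuple[str, str, int, int]]) -> "GeneAnnotation":
        """From (gene_id, chrom, start, end) tuples, 1-based inclusive."""
        return cls(pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end"]))

    @classmethod
    def read_bed(cls, path) -> "GeneAnnotation":
        """Read a BED file (chrom, start, end, name); 0-based half-open."""
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                tok = line.split("\t")
                if len(tok) < 4:
                    raise ValueError(f"{path}: line {ln}: BED needs >=4 columns (name required)")
                chrom, start, end, name = tok[0], int(tok[1]), int(tok[2]), tok[3]
                rows.append((name, chrom, start + 1, end))  # to 1-based inclusive
        return cls.from_records(rows)


def nearest_gene(
    chrom: str, pos: int, annotation: GeneAnnotation
) -> tuple[str, int] | None:
    """Nearest gene to a 1-based position, with its distance.

    Distance 0 inside a gene; otherwise the gap to the nearer interval
    endpoint.  Ties go to the gene with the smaller start, then the
    lexicographically smaller id.  ``None`` when the chromosome carries
    no gene.
    """
    sub = annotation.table[annotation.table["chrom"] == chrom]
    if sub.empty:
        return None
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    # gap is 0 inside an interval, else distance to the nearer endpoint
    gap = np.where(pos < starts, starts - pos, np.where(pos > ends, pos - ends, 0))
    order = sorted(
        range(len(sub)),
        key=lambda r: (gap[r], starts[r], sub["gene_id"].iloc[r]),
    )
    best = order[0]
    return str(sub["gene_id"].iloc[best]), int(gap[best])


@dataclass
class GeneNetwork:
    """Undirected gene-gene network with per-edge SNP-pair support.

    Edge attributes: ``supports`` (list of dicts with snp_i, snp_j,
    pattern_id, p_pair, improvement), ``best_p``, ``best_improvement``,
    ``self_loop``.
    """

    graph: nx.Graph

    @classmethod
    def empty(cls) -> "GeneNetwork":
        return cls(nx.Graph())

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_keys(self, include_self_loops: bool = True) -> set[tuple[str, str]]:
        keys = {tuple(sorted((u, v))) for u, v in self.graph.edges}
        if not include_self_loops:
            keys = {k for k in keys if k[0] != k[1]}
        return keys

    def self_loops(self) -> set[tuple[str, str]]:
        return {k for k in self.edge_keys() if k[0] == k[1]}

    def add_support(self, gene_a: str, gene_b: str, support: dict) -> None:
        u, v = sorted((gene_a, gene_b))
        if self.graph.has_edge(u, v):
            data = self.graph.edges[u, v]
            data["supports"].append(support)
            data["best_p"] = min(data["best_p"], support["p_pair"])
            data["best_improvement"] = max(
                data["best_improvement"], support["improvement"]
            )
        else:
            self.graph.add_edge(
                u,
                v,
                supports=[support],
                best_p=support["p_pair"],
                best_improvement=support["improvement"],
                self_loop=(u == v),
            )


def infer_network(
    results: list[AssociationResult],
    loci: dict[str, tuple[str, int]],
    annotation: GeneAnnotation,
    max_distance: int | None = None,
) -> GeneNetwork:
    """Lift SNP-pair interactions to a gene-gene network.

    ``loci`` maps SNP ids to (chromosome, 1-based position).  SNPs with
    no mappable gene (no gene on the chromosome, or farther than
    ``max_distance`` when given) drop their interactions with a logged
    count.
    """
    net = GeneNetwork.empty()
    n_dropped = 0
    for r in results:
        mapped = []
        for snp in (r.snp_i, r.snp_j):
            if snp not in loci:
                mapped = None
                break
            hit = nearest_gene(*loci[snp], annotation)
            if hit is None or (max_distance is not None and hit[1] > max_distance):
                mapped = None
                break
            mapped.append(hit[0])
        if mapped is None:
            n_dropped += 1
            continue
        net.add_support(
            mapped[0],
            mapped[1],
            {
                "snp_i": r.snp_i,
                "snp_j": r.snp_j,
                "pattern_id": r.pattern_id,
                "p_pair": r.p_pair,
                "improvement": r.improvement,
            },
        )
    if n_dropped:
        logger.info("dropped %d interaction(s) with unmappable SNPs", n_dropped)
    return net


def intersect_networks(
    net_a: GeneNetwork, net_b: GeneNetwork, drop_self_loops: bool = True
) -> GeneNetwork:
    """Edges present in both networks (unordered match), supports merged."""
    common = net_a.edge_keys() & net_b.edge_keys()
    if drop_self_loops:
        common = {k for k in common if k[0] != k[1]}
    out = GeneNetwork.empty()
    for u, v in sorted(common):
        for src in (net_a, net_b):
            for s in src.graph.edges[u, v]["supports"]:
                out.add_support(u, v, s)
    return out


def export_network(
    net: GeneNetwork, path, fmt: str = "edge-tsv", include_self_loops: bool = False
) -> None:
    """Write the network as an edge TSV or SIF file, lexicographically ordered."""
    keys = sorted(net.edge_keys(include_self_loops=include_self_loops))
    if fmt == "edge-tsv":
        with open(path, "w") as fh:
            fh.write(
                "gene_a\tgene_b\tn_supports\tbest_p\tbest_improvement\tself_loop\tsupports\n"
            )
            for u, v in keys:
                d = net.graph.edges[u, v]
                supports = ";".join(
                    f"{s['snp_i']}|{s['snp_j']}|{s['pattern_id']}|{s['p_pair']!r}|{s['improvement']!r}"
                    for s in d["supports"]
                )
                fh.write(
                    f"{u}\t{v}\t{len(d['supports'])}\t{d['best_p']!r}"
                    f"\t{d['best_improvement']!r}\t{int(d['self_loop'])}\t{supports}\n"
                )
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v in keys:
                fh.write(f"{u}\tinteracts\t{v}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_network_tsv(path) -> GeneNetwork:
    """Read back an edge TSV written by :func:`export_network`."""
    net = GeneNetwork.empty()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_a\tgene_b"):
            raise ValueError(f"{path}: not a network edge TSV")
        for line in fh:
            tok = line.rstrip("\n").split("\t")
            u, v = tok[0], tok[1]
            for s in tok[6].split(";") if tok[6] else []:
                si, sj, pid, p, imp = s.split("|")
                net.add_support(
                    u,
                    v,
                    {
                        "snp_i": si,
                        "snp_j": sj,
                        "pattern_id": int(pid),
                        "p_pair": float(p),
                        "improvement": float(imp),
                    },
                )
    return net
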