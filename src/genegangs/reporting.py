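"""Per-gang topology metrics and plot-ready exports.

For each finalized gang this module reports, per genome set: the maximum
and modal (consensus) per-genome member count, how many genomes are *ruly*
(carry every gang cluster), how many maintain *synteny* (gang cluster order
equal to the consensus order or its full reversal, ignoring aliens,
duplicates, and clusters absent from that genome), how many conserve
*strandedness* (strand pattern equal to the consensus pattern or its global
inversion), and how many are *infiltrated* by alien genes — features inside
the gang's genomic span that carry no gang cluster ID (unclustered features
included).

Exports are plain TSV-shaped DataFrames: a topology table (one row per
gang), per-genome classifications, per-genome gene tracks with homology
connector lines for gang-alignment figures, and cluster-based dot-plot
points for any genome pair. No figures are rendered here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .gangs import GeneGang
from .model import GeneFeature, Genome, GenomeSet

__all__ = [
    "GangTopology",
    "consensus_order",
    "topology_metrics",
    "topology_table",
    "per_genome_table",
    "export_gang_alignment",
    "dotplot_points",
]


@dataclass
class GangTopology:
    """Topology summary of one gang across a genome set."""

    gang_id: str
    max_members: int
    consensus_members: int
    n_ruly_genomes: int
    n_syntenic_genomes: int
    n_strand_conserved_genomes: int
    n_infiltrated_genomes: int
    n_genomes_evaluated: int
    per_genome: dict[str, dict] = field(default_factory=dict)


def _genome_cluster_order(
    gang: GeneGang, genome_id: str
) -> tuple[list[str], dict[str, str]]:
    """Left-to-right order of gang cluster IDs in one genome (duplicates
    collapsed to first occurrence) plus each cluster's strand there."""
    members = sorted(
        gang.member_features_in(genome_id),
        key=lambda f: (f.contig_id, f.start, f.feature_id),
    )
    order: list[str] = []
    strand: dict[str, str] = {}
    for f in members:
        if f.cluster_id not in order:
            order.append(f.cluster_id)
            strand[f.cluster_id] = f.strand
    return order, strand


def consensus_order(gang: GeneGang) -> list[str]:
    """Modal left-to-right order of the gang's cluster IDs across genomes.

    An order and its reversal are the same arrangement; the modal class is
    chosen on their combined count, represented by its more frequent
    orientation (ties broken lexicographically). Genomes carrying fewer
    than two gang clusters are uninformative and skipped.
    """
    raw = Counter()
    for gid in gang.groupings:
        order, _ = _genome_cluster_order(gang, gid)
        if len(order) >= 2:
            raw[tuple(order)] += 1
    if not raw:
        return sorted(gang.cluster_ids)
    combined = Counter()
    for order, n in raw.items():
        key = min(order, order[::-1])
        combined[key] += n
    best = max(combined, key=lambda k: (combined[k], k[::-1]))  # ties: lex smallest
    fwd, rev = raw[best], raw[best[::-1]]
    if rev > fwd or (rev == fwd and best[::-1] < best):
        return list(best[::-1])
    return list(best)


def _matches_up_to_reversal(order: list[str], consensus: list[str]) -> bool:
    ref = [c for c in consensus if c in order]
    return order == ref or order == ref[::-1]


def topology_metrics(gang: GeneGang, gs: GenomeSet) -> GangTopology:
    """Compute the gang's topology counts over the genomes it occurs in.

    Genomes without any gang member are excluded from all denominators.
    Alien infiltration scans the full genome annotation between the gang's
    outermost member centers on each contig the gang occupies.
    """
    cons = consensus_order(gang)
    cids = gang.cluster_ids

    # consensus strand per cluster: modal raw strand across genomes
    strand_votes: dict[str, Counter] = {c: Counter() for c in cids}
    per_genome_data: dict[str, tuple[list[str], dict[str, str]]] = {}
    for gid in gs.genome_ids:
        members = gang.member_features_in(gid)
        if not members:
            continue
        order, strands = _genome_cluster_order(gang, gid)
        per_genome_data[gid] = (order, strands)
        for c, s in strands.items():
            strand_votes[c][s] += 1
    cons_strand = {
        c: ("+" if votes.get("+", 0) >= votes.get("-", 0) else "-")
        for c, votes in strand_votes.items()
        if votes
    }

    counts = []
    n_ruly = n_syn = n_strand = n_infil = 0
    per_genome: dict[str, dict] = {}
    for gid, (order, strands) in per_genome_data.items():
        members = gang.member_features_in(gid)
        counts.append(len(members))
        ruly = cids <= {f.cluster_id for f in members}
        syntenic = _matches_up_to_reversal(order, cons)
        agree = [strands[c] == cons_strand[c] for c in order if c in cons_strand]
        strand_ok = bool(agree) and (all(agree) or not any(agree))
        infiltrated = _is_infiltrated(gang, gs.genome(gid))
        n_ruly += ruly
        n_syn += syntenic
        n_strand += strand_ok
        n_infil += infiltrated
        per_genome[gid] = {
            "n_members": len(members),
            "ruly": ruly,
            "syntenic": syntenic,
            "strand_conserved": strand_ok,
            "infiltrated": infiltrated,
        }

    modal = Counter(counts)
    top = max(modal.values()) if modal else 0
    consensus_members = min(c for c, n in modal.items() if n == top) if modal else 0
    return GangTopology(
        gang_id=gang.gang_id or "",
        max_members=max(counts) if counts else 0,
        consensus_members=consensus_members,
        n_ruly_genomes=n_ruly,
        n_syntenic_genomes=n_syn,
        n_strand_conserved_genomes=n_strand,
        n_infiltrated_genomes=n_infil,
        n_genomes_evaluated=len(per_genome_data),
        per_genome=per_genome,
    )


def _is_infiltrated(gang: GeneGang, genome: Genome) -> bool:
    members = gang.member_features_in(genome.genome_id)
    if len(members) < 2:
        return False
    keys = {f.key for f in members}
    by_contig: dict[str, list[GeneFeature]] = {}
    for f in members:
        by_contig.setdefault(f.contig_id, []).append(f)
    for contig, feats in by_contig.items():
        if len(feats) < 2:
            continue
        lo = min(f.center for f in feats)
        hi = max(f.center for f in feats)
        for f in genome.features:
            if f.contig_id != contig or f.key in keys:
                continue
            if lo <= f.center <= hi:
                return True
    return False


def topology_table(gangs: list[GeneGang], gs: GenomeSet) -> pd.DataFrame:
    """One row per gang: member counts and conservation counts."""
    rows = []
    for gang in gangs:
        t = topology_metrics(gang, gs)
        rows.append(
            {
                "gang_id": t.gang_id,
                "n_clusters": len(gang.cluster_ids),
                "max_members": t.max_members,
                "consensus_members": t.consensus_members,
                "gang_ruliness": round(gang.gang_ruliness, 4),
                "n_ruly_genomes": t.n_ruly_genomes,
                "n_syntenic_genomes": t.n_syntenic_genomes,
                "n_strand_conserved_genomes": t.n_strand_conserved_genomes,
                "n_infiltrated_genomes": t.n_infiltrated_genomes,
            }
        )
    return pd.DataFrame(rows)


def per_genome_table(gangs: list[GeneGang], gs: GenomeSet) -> pd.DataFrame:
    """Per gang x genome classification rows (type-specific structure stays
    visible downstream instead of being special-cased here)."""
    rows = []
    for gang in gangs:
        t = topology_metrics(gang, gs)
        for gid, d in t.per_genome.items():
            rows.append({"gang_id": t.gang_id, "genome_id": gid, **d})
    return pd.DataFrame(rows)


def export_gang_alignment(
    gs: GenomeSet, gangs: list[GeneGang]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene tracks plus homology connector lines for alignment figures.

    Returns ``(tracks, connectors)``: tracks holds one row per feature with
    its gang tag (empty for non-members); connectors links features of the
    same cluster in consecutive genomes (as listed in the set), one row per
    connected pair.
    """
    gang_of_key: dict[tuple[str, str], str] = {}
    for gang in gangs:
        for gid in gang.groupings:
            for f in gang.member_features_in(gid):
                gang_of_key[f.key] = gang.gang_id or ""
    track_rows = []
    for g in gs:
        for f in g.features:
            track_rows.append(
                {
                    "genome_id": g.genome_id,
                    "contig_id": f.contig_id,
                    "feature_id": f.feature_id,
                    "start": f.start,
                    "end": f.end,
                    "strand": f.strand,
                    "cluster_id": f.cluster_id or "",
                    "gang_id": gang_of_key.get(f.key, ""),
                }
            )
    conn_rows = []
    for ga, gb in zip(gs.genomes, gs.genomes[1:]):
        feats_b: dict[str, list[GeneFeature]] = {}
        for f in gb.features:
            if f.cluster_id:
                feats_b.setdefault(f.cluster_id, []).append(f)
        for fa in ga.features:
            if not fa.cluster_id:
                continue
            for fb in feats_b.get(fa.cluster_id, []):
                conn_rows.append(
                    {
                        "cluster_id": fa.cluster_id,
                        "genome_a": ga.genome_id,
                        "center_a": fa.center,
                        "genome_b": gb.genome_id,
                        "center_b": fb.center,
                        "gang_id": gang_of_key.get(fa.key, ""),
                    }
                )
    return pd.DataFrame(track_rows), pd.DataFrame(conn_rows)


def dotplot_points(ga: Genome, gb: Genome) -> pd.DataFrame:
    """Cluster-based dot plot: one point per shared-cluster feature pair.

    Coordinates are feature centers; ``same_strand`` distinguishes common
    from opposite orientation. A genome against itself yields the exact
    diagonal plus paralog off-diagonals.
    """
    by_cluster: dict[str, list[GeneFeature]] = {}
    for f in gb.features:
        if f.cluster_id:
            by_cluster.setdefault(f.cluster_id, []).append(f)
    rows = []
    for fa in ga.features:
        if not fa.cluster_id:
            continue
        for fb in by_cluster.get(fa.cluster_id, []):
            rows.append(
                {
                    "cluster_id": fa.cluster_id,
                    "x": fa.center,
                    "y": fb.center,
                    "feature_a": fa.feature_id,
                    "feature_b": fb.feature_id,
                    "same_strand": fa.strand == fb.strand,
                }
            )
    return pd.DataFrame(rows)
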