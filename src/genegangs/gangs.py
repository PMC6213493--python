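"""Gene-gang detection.

A *gene gang* is a group of three or more monocistronic genes whose members
stay within a short center-to-center distance of one another in all (or
nearly all) genomes of a set, irrespective of gene order, strand, or
intervening genes. Detection proceeds through a fixed pipeline:

1. classify homology clusters into highly paralogous **large clusters**
   (excluded from seeding) and **seed clusters**;
2. around every occurrence of every seed cluster, collect the **genomic
   grouping**: the seed feature(s) plus all features within the
   collinearity window (center-to-center distance at most
   ``max_genomic_distance``, either strand, either side);
3. collect each seed's per-genome groupings into a **cluster gang**, drop
   gangs whose seed is too rare (``min_genome_prevalence``), and prune each
   retained gang's windows to their *conserved* content: collinear features
   whose cluster recurs in the window in fewer than
   ``min_genome_prevalence`` genomes are dropped (without this step,
   merging would chain along one-off adjacencies and collapse any coherent
   genome set into a single all-encompassing gang);
4. merge cluster gangs that share any homology cluster among their
   (conserved) member features, repeating to a fixpoint (computed as
   connected components of the cluster-overlap relation), yielding
   feature-disjoint **gene gangs**;
5. re-admit paralogs that sit at the edge of groupings and were missed
   because large clusters never seed (**paralog correction**);
6. drop gangs with fewer than ``min_gang_clusters`` clusters or missing
   from any genome (**final filter**), after pruning clusters whose
   **ruliness** (fraction of genomes carrying the cluster inside the gang)
   falls below ``min_genome_prevalence / n_genomes``.

A gang's ruliness is the minimum ruliness over its clusters; a gang is
*ruly* at 1.00. The optional ruliness filter removes clusters (and their
features) below a chosen threshold, giving strict or unruly views of the
same gangs.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import GeneFeature, Genome, GenomeSet

logger = logging.getLogger("genegangs")

__all__ = [
    "GangParams",
    "GenomicGrouping",
    "ClusterGang",
    "GeneGang",
    "classify_clusters",
    "build_grouping",
    "build_cluster_gangs",
    "prevalence_filter",
    "prune_unconserved",
    "merge_to_gene_gangs",
    "paralog_correction",
    "final_filter",
    "compute_ruliness",
    "ruliness_filter",
    "detect_gene_gangs",
    "gangs_to_records",
    "gangs_to_json",
]


@dataclass
class GangParams:
    """Tunable parameters of gang detection.

    Defaults are calibrated for a 41-genome chlorovirus-sized corpus:
    collinearity window 3500 bp center-to-center, seed prevalence 34 of 41
    genomes, paralog-correction prevalence 15 genomes, large-cluster size
    strictly above 80 members, and at least 3 clusters per gang.
    """

    max_genomic_distance: float = 3500.0
    min_genome_prevalence: int = 34
    paralog_correction_threshold: int = 15
    large_cluster_threshold: int = 80
    min_gang_clusters: int = 3

    def __post_init__(self) -> None:
        if self.max_genomic_distance <= 0:
            raise ValueError("max_genomic_distance must be positive")
        for name in (
            "paralog_correction_threshold",
            "large_cluster_threshold",
            "min_gang_clusters",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_genome_prevalence < 0:
            raise ValueError("min_genome_prevalence must be >= 0")

    def validate_for(self, gs: GenomeSet) -> None:
        if self.min_genome_prevalence > gs.n_genomes:
            raise ValueError(
                f"min_genome_prevalence ({self.min_genome_prevalence}) exceeds "
                f"the number of genomes ({gs.n_genomes})"
            )


@dataclass
class GenomicGrouping:
    """A seed's neighborhood in one genome.

    ``features`` holds the seed feature(s) plus every feature within the
    collinearity window of any seed feature (either strand, either side,
    same contig), deduplicated and coordinate-sorted.
    """

    genome_id: str
    seed_features: list[GeneFeature]
    features: list[GeneFeature]

    @property
    def collinear_features(self) -> list[GeneFeature]:
        return self.features


@dataclass
class ClusterGang:
    """One seed cluster's genomic groupings across the genomes where it occurs."""

    seed_cluster: str
    groupings: dict[str, GenomicGrouping]

    @property
    def prevalence(self) -> int:
        return len(self.groupings)

    def cluster_ids(self) -> set[str]:
        return {
            f.cluster_id
            for gr in self.groupings.values()
            for f in gr.features
            if f.cluster_id is not None
        }

    def feature_keys(self) -> set[tuple[str, str]]:
        return {f.key for gr in self.groupings.values() for f in gr.features}


@dataclass
class GeneGang:
    """A merged, cross-genome, feature-disjoint set of genomic groupings."""

    groupings: dict[str, GenomicGrouping]
    gang_id: Optional[str] = None
    seed_clusters: set[str] = field(default_factory=set)
    ruliness: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False

    @property
    def cluster_ids(self) -> set[str]:
        """The gang cluster IDs: clusters of all member features, all genomes."""
        return {
            f.cluster_id
            for gr in self.groupings.values()
            for f in gr.features
            if f.cluster_id is not None
        }

    def features_in(self, genome_id: str) -> list[GeneFeature]:
        gr = self.groupings.get(genome_id)
        return list(gr.features) if gr else []

    def member_features_in(self, genome_id: str) -> list[GeneFeature]:
        """Features whose cluster belongs to the gang (aliens excluded)."""
        cids = self.cluster_ids
        return [f for f in self.features_in(genome_id) if f.cluster_id in cids]

    def all_features(self) -> list[GeneFeature]:
        return [f for gr in self.groupings.values() for f in gr.features]

    def feature_keys(self) -> set[tuple[str, str]]:
        return {f.key for f in self.all_features()}

    def genomes_covered(self) -> set[str]:
        cids = self.cluster_ids
        return {
            gid
            for gid, gr in self.groupings.items()
            if any(f.cluster_id in cids for f in gr.features)
        }

    @property
    def gang_ruliness(self) -> float:
        if not self.ruliness:
            return math.nan
        return min(self.ruliness.values())

    def canonical_key(self) -> tuple:
        cids = tuple(sorted(self.cluster_ids))
        starts = []
        for gid in sorted(self.groupings):
            feats = self.groupings[gid].features
            if feats:
                starts.append((gid, min(f.start for f in feats)))
        first = starts[0] if starts else ("", 0)
        return (first[0], first[1], cids)


class _NeighborIndex:
    """Per-contig center-sorted feature index for window queries."""

    def __init__(self, genome: Genome):
        self._by_contig: dict[str, tuple[list[float], list[GeneFeature]]] = {}
        for f in genome.features:
            self._by_contig.setdefault(f.contig_id, ([], []))
        tmp: dict[str, list[GeneFeature]] = {}
        for f in genome.features:
            tmp.setdefault(f.contig_id, []).append(f)
        for contig, feats in tmp.items():
            feats = sorted(feats, key=lambda f: (f.center, f.feature_id))
            self._by_contig[contig] = ([f.center for f in feats], feats)

    def within(self, anchor: GeneFeature, max_dist: float) -> list[GeneFeature]:
        """All features with center-to-center distance <= max_dist of anchor
        on the anchor's contig (the anchor itself included)."""
        if anchor.contig_id not in self._by_contig:
            return []
        centers, feats = self._by_contig[anchor.contig_id]
        lo = bisect_left(centers, anchor.center - max_dist)
        hi = bisect_right(centers, anchor.center + max_dist)
        return feats[lo:hi]


def _sorted_dedup(features: Iterable[GeneFeature]) -> list[GeneFeature]:
    seen: dict[tuple[str, str], GeneFeature] = {}
    for f in features:
        seen.setdefault(f.key, f)
    return sorted(
        seen.values(), key=lambda f: (f.contig_id, f.start, f.end, f.feature_id)
    )


def classify_clusters(
    gs: GenomeSet, p: GangParams
) -> tuple[set[str], set[str]]:
    """Partition clusters into (seed_clusters, large_clusters).

    A cluster is *large* iff its total member count across the set is
    strictly greater than ``large_cluster_threshold``; every other cluster
    is a seed cluster.
    """
    seeds, large = set(), set()
    for cid, members in gs.cluster_map.items():
        (large if len(members) > p.large_cluster_threshold else seeds).add(cid)
    return seeds, large


def build_grouping(
    g: Genome,
    seed_cluster: str,
    p: GangParams,
    index: Optional[_NeighborIndex] = None,
) -> Optional[GenomicGrouping]:
    """The genomic grouping of a seed cluster in one genome, or None.

    All features of ``seed_cluster`` in the genome act as seed features
    (the split-gene case: a seed annotated as several proximal genes); the
    grouping is the union over seed features of all features within
    ``max_genomic_distance`` (inclusive), plus the seeds themselves.
    """
    seed_feats = [f for f in g.features if f.cluster_id == seed_cluster]
    if not seed_feats:
        return None
    if index is None:
        index = _NeighborIndex(g)
    collected: list[GeneFeature] = []
    for s in seed_feats:
        collected.extend(index.within(s, p.max_genomic_distance))
    return GenomicGrouping(
        genome_id=g.genome_id,
        seed_features=_sorted_dedup(seed_feats),
        features=_sorted_dedup(collected + seed_feats),
    )


def build_cluster_gangs(
    gs: GenomeSet,
    seeds: Iterable[str],
    p: GangParams,
    indexes: Optional[dict[str, _NeighborIndex]] = None,
) -> list[ClusterGang]:
    """One cluster gang per seed cluster, over the genomes where it occurs."""
    if indexes is None:
        indexes = {g.genome_id: _NeighborIndex(g) for g in gs}
    gangs = []
    for cid in sorted(seeds):
        groupings: dict[str, GenomicGrouping] = {}
        for g in gs:
            gr = build_grouping(g, cid, p, indexes[g.genome_id])
            if gr is not None:
                groupings[g.genome_id] = gr
        if groupings:
            gangs.append(ClusterGang(seed_cluster=cid, groupings=groupings))
    return gangs


def prevalence_filter(gangs: Sequence[ClusterGang], p: GangParams) -> list[ClusterGang]:
    """Keep cluster gangs whose seed occurs in >= min_genome_prevalence genomes."""
    return [cg for cg in gangs if cg.prevalence >= p.min_genome_prevalence]


def prune_unconserved(
    gangs: Sequence[ClusterGang], p: GangParams
) -> list[ClusterGang]:
    """Restrict each cluster gang's windows to their conserved content.

    A collinear cluster is conserved within a cluster gang when at least
    ``min_genome_prevalence`` of the gang's groupings contain a feature of
    it. Features of unconserved clusters, and unclustered features, are
    removed from the groupings; seed features always stay (the seed recurs
    in every grouping by construction). This keeps the merge step anchored
    to consistently co-located clusters rather than one-off adjacencies.
    """
    out = []
    for cg in gangs:
        genomes_with: dict[str, set[str]] = {}
        for gid, gr in cg.groupings.items():
            for f in gr.features:
                if f.cluster_id is not None:
                    genomes_with.setdefault(f.cluster_id, set()).add(gid)
        keep = {
            cid
            for cid, gids in genomes_with.items()
            if len(gids) >= p.min_genome_prevalence
        }
        keep.add(cg.seed_cluster)
        groupings = {
            gid: GenomicGrouping(
                genome_id=gid,
                seed_features=list(gr.seed_features),
                features=[f for f in gr.features if f.cluster_id in keep],
            )
            for gid, gr in cg.groupings.items()
        }
        out.append(ClusterGang(seed_cluster=cg.seed_cluster, groupings=groupings))
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def merge_to_gene_gangs(gangs: Sequence[ClusterGang]) -> list[GeneGang]:
    """Merge cluster gangs sharing any cluster ID into disjoint gene gangs.

    Equivalent to the iterate-until-fixpoint merging of overlapping gangs:
    the result is the connected components of the "shares a cluster ID
    among member features" relation, with each component's groupings
    unioned per genome and features deduplicated. Unclustered features
    cannot trigger merges; if one lands in several components' groupings it
    is kept only in the canonically first gang (logged), so the resulting
    gangs are pairwise disjoint in both features and cluster IDs.
    """
    gangs = sorted(gangs, key=lambda cg: cg.seed_cluster)
    if not gangs:
        return []
    uf = _UnionFind(len(gangs))
    owner: dict[str, int] = {}
    for i, cg in enumerate(gangs):
        for cid in sorted(cg.cluster_ids()):
            if cid in owner:
                uf.union(owner[cid], i)
            else:
                owner[cid] = i
    components: dict[int, list[ClusterGang]] = {}
    for i, cg in enumerate(gangs):
        components.setdefault(uf.find(i), []).append(cg)

    merged: list[GeneGang] = []
    for root in sorted(components):
        comp = components[root]
        groupings: dict[str, GenomicGrouping] = {}
        genome_ids = sorted({gid for cg in comp for gid in cg.groupings})
        for gid in genome_ids:
            seeds: list[GeneFeature] = []
            feats: list[GeneFeature] = []
            for cg in comp:
                gr = cg.groupings.get(gid)
                if gr is not None:
                    seeds.extend(gr.seed_features)
                    feats.extend(gr.features)
            groupings[gid] = GenomicGrouping(
                genome_id=gid,
                seed_features=_sorted_dedup(seeds),
                features=_sorted_dedup(feats),
            )
        merged.append(
            GeneGang(
                groupings=groupings,
                seed_clusters={cg.seed_cluster for cg in comp},
            )
        )
    merged.sort(key=lambda g: g.canonical_key())

    # resolve unclustered features shared between components
    claimed: dict[tuple[str, str], int] = {}
    for i, gang in enumerate(merged):
        for gid, gr in gang.groupings.items():
            kept = []
            for f in gr.features:
                if f.cluster_id is None:
                    if f.key in claimed and claimed[f.key] != i:
                        logger.info(
                            "unclustered feature %s contested between gangs; "
                            "kept in the first",
                            f.key,
                        )
                        continue
                    claimed[f.key] = i
                kept.append(f)
            gr.features = kept
    return merged


def paralog_correction(
    gangs: Sequence[GeneGang],
    gs: GenomeSet,
    p: GangParams,
    indexes: Optional[dict[str, _NeighborIndex]] = None,
) -> list[GeneGang]:
    """Re-admit edge paralogs of gang clusters missed by seeding.

    Around every member feature of every gang, in every genome the gang
    covers, features within the collinearity window whose cluster is
    already a gang cluster ID but which are not yet members are noted as
    candidates. A cluster's candidates are admitted only when candidates
    were found in at least ``paralog_correction_threshold`` genomes; the
    admitted features join the groupings where they were discovered.
    Features belonging to another gang are never stolen (logged instead).
    Runs as a single pass; never moves features between gangs.
    """
    if indexes is None:
        indexes = {g.genome_id: _NeighborIndex(g) for g in gs}
    membership: dict[tuple[str, str], int] = {}
    for i, gang in enumerate(gangs):
        for key in gang.feature_keys():
            membership[key] = i

    out = list(gangs)
    for i, gang in enumerate(out):
        gang_cids = gang.cluster_ids
        member_keys = gang.feature_keys()
        # cluster_id -> genomes where candidates were found; and the candidates
        cand_genomes: dict[str, set[str]] = {}
        candidates: dict[str, list[GeneFeature]] = {}
        for gid in sorted(gang.groupings):
            idx = indexes[gid]
            for m in gang.groupings[gid].features:
                for f in idx.within(m, p.max_genomic_distance):
                    if (
                        f.cluster_id is not None
                        and f.cluster_id in gang_cids
                        and f.key not in member_keys
                    ):
                        cand_genomes.setdefault(f.cluster_id, set()).add(gid)
                        candidates.setdefault(f.cluster_id, []).append(f)
        for cid in sorted(candidates):
            if len(cand_genomes[cid]) < p.paralog_correction_threshold:
                continue
            for f in _sorted_dedup(candidates[cid]):
                other = membership.get(f.key)
                if other is not None and other != i:
                    logger.info(
                        "paralog correction: feature %s already belongs to "
                        "another gang; not moved",
                        f.key,
                    )
                    continue
                gr = gang.groupings[f.genome_id]
                gr.features = _sorted_dedup(gr.features + [f])
                membership[f.key] = i
                member_keys.add(f.key)
    return out


def final_filter(
    gangs: Sequence[GeneGang], gs: GenomeSet, p: GangParams
) -> list[GeneGang]:
    """Keep gangs with >= min_gang_clusters cluster IDs and member features
    in every genome of the set."""
    all_ids = set(gs.genome_ids)
    kept = []
    for gang in gangs:
        if len(gang.cluster_ids) < p.min_gang_clusters:
            continue
        if not all_ids.issubset(gang.genomes_covered()):
            continue
        kept.append(gang)
    return kept


def compute_ruliness(gang: GeneGang, gs: GenomeSet) -> dict[str, float]:
    """Per-cluster ruliness: the fraction of genomes holding >= 1 gang
    feature of that cluster. Stored on the gang; the gang's own ruliness is
    the minimum over its clusters."""
    counts: dict[str, set[str]] = {cid: set() for cid in gang.cluster_ids}
    for gid, gr in gang.groupings.items():
        for f in gr.features:
            if f.cluster_id in counts:
                counts[f.cluster_id].add(gid)
    gang.ruliness = {
        cid: len(genomes) / gs.n_genomes for cid, genomes in counts.items()
    }
    return gang.ruliness


def ruliness_filter(
    gang: GeneGang,
    gs: GenomeSet,
    threshold: float,
    min_gang_clusters: int = 3,
    warn_degenerate: bool = True,
) -> GeneGang:
    """Remove clusters (and their features) with ruliness below threshold.

    Returns a new gang; unclustered context features are untouched. If the
    filter leaves fewer than ``min_gang_clusters`` clusters the gang is
    flagged degenerate and retained with a warning.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("ruliness threshold must be in [0, 1]")
    rul = compute_ruliness(gang, gs)
    drop = {cid for cid, r in rul.items() if r < threshold - 1e-12}
    groupings = {}
    for gid, gr in gang.groupings.items():
        groupings[gid] = GenomicGrouping(
            genome_id=gid,
            seed_features=[f for f in gr.seed_features if f.cluster_id not in drop],
            features=[f for f in gr.features if f.cluster_id not in drop],
        )
    new = GeneGang(
        groupings=groupings,
        gang_id=gang.gang_id,
        seed_clusters=set(gang.seed_clusters) - drop,
    )
    compute_ruliness(new, gs)
    if len(new.cluster_ids) < min_gang_clusters:
        new.degenerate = True
        if not warn_degenerate:
            return new
        logger.warning(
            "ruliness filter at %.3f left gang %s with %d cluster IDs "
            "(< %d); flagged degenerate, retained",
            threshold,
            gang.gang_id,
            len(new.cluster_ids),
            min_gang_clusters,
        )
    return new


def detect_gene_gangs(
    gs: GenomeSet,
    p: Optional[GangParams] = None,
    ruliness_threshold: Optional[float] = None,
) -> list[GeneGang]:
    """Run the full gang-detection pipeline on a genome set.

    classify -> build cluster gangs -> prevalence filter -> conservation
    pruning -> merge -> paralog correction -> base ruliness pruning at
    ``min_genome_prevalence / n_genomes`` -> final filter -> (optional)
    user ruliness filter. Deterministic given inputs and parameters;
    genome input order and cluster iteration order do not affect the
    result. Emits a hard warning if detection converges to a single
    all-encompassing gang (a sign the parameters need recalibration for
    the corpus's collinear similarity).
    """
    if p is None:
        p = GangParams()
    if gs.n_genomes == 0 or not gs.cluster_map:
        return []
    p.validate_for(gs)

    indexes = {g.genome_id: _NeighborIndex(g) for g in gs}
    seeds, _large = classify_clusters(gs, p)
    cluster_gangs = build_cluster_gangs(gs, seeds, p, indexes)
    cluster_gangs = prevalence_filter(cluster_gangs, p)
    cluster_gangs = prune_unconserved(cluster_gangs, p)
    gangs = merge_to_gene_gangs(cluster_gangs)
    gangs = paralog_correction(gangs, gs, p, indexes)
    base = p.min_genome_prevalence / gs.n_genomes
    gangs = [
        ruliness_filter(
            g, gs, base, min_gang_clusters=p.min_gang_clusters, warn_degenerate=False
        )
        for g in gangs
    ]
    gangs = final_filter(gangs, gs, p)
    if ruliness_threshold is not None:
        gangs = [
            ruliness_filter(
                g, gs, ruliness_threshold, min_gang_clusters=p.min_gang_clusters
            )
            for g in gangs
        ]

    gangs.sort(key=lambda g: g.canonical_key())
    for i, gang in enumerate(gangs, 1):
        gang.gang_id = f"gang_{i:02d}"
        compute_ruliness(gang, gs)

    n_seed_total = len(seeds)
    if (
        len(gangs) == 1
        and n_seed_total >= 10
        and len(gangs[0].cluster_ids) > 0.5 * n_seed_total
    ):
        logger.warning(
            "detection converged to a single gang holding %d of %d seed "
            "clusters; max_genomic_distance / min_genome_prevalence likely "
            "need recalibration for this genome set",
            len(gangs[0].cluster_ids),
            n_seed_total,
        )
    return gangs


def gangs_to_records(gangs: Sequence[GeneGang]) -> list[dict]:
    """JSON-friendly structure: gangs -> genomes -> groupings -> features."""
    records = []
    for gang in gangs:
        rec = {
            "gang_id": gang.gang_id,
            "cluster_ids": sorted(gang.cluster_ids),
            "seed_clusters": sorted(gang.seed_clusters),
            "ruliness": {c: round(r, 6) for c, r in sorted(gang.ruliness.items())},
            "gang_ruliness": round(gang.gang_ruliness, 6)
            if gang.ruliness
            else None,
            "degenerate": gang.degenerate,
            "genomes": {},
        }
        for gid in sorted(gang.groupings):
            gr = gang.groupings[gid]
            rec["genomes"][gid] = {
                "seed_features": [f.feature_id for f in gr.seed_features],
                "features": [
                    {
                        "feature_id": f.feature_id,
                        "contig_id": f.contig_id,
                        "start": f.start,
                        "end": f.end,
                        "strand": f.strand,
                        "cluster_id": f.cluster_id,
                    }
                    for f in gr.features
                ],
            }
        records.append(rec)
    return records


def gangs_to_json(gangs: Sequence[GeneGang], path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(gangs_to_records(gangs), fh, indent=1, sort_keys=True)
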