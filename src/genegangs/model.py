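"""Core data model: gene features, genomes, genome sets, phylogenies.

Coordinates are 1-based inclusive throughout (GenBank/GFF3 native). Gene
centers ``(start + end) / 2`` may be half-integral and are kept as floats;
they are never rounded before distance comparison, because the proximity
thresholds of the downstream analyses are defined on center-to-center
distances. Genomes are treated as linear: distances never wrap, and the
center-to-center distance between features on different contigs is
undefined (treated as infinite by every analysis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "GeneFeature",
    "Genome",
    "GenomeSet",
    "Phylogeny",
    "center_distance",
]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated coding region.

    Attributes
    ----------
    feature_id:
        Identifier unique within a :class:`GenomeSet` for its genome
        (typically a locus_tag).
    genome_id, contig_id:
        Genome and contig of origin.
    start, end:
        1-based inclusive coordinates, ``start <= end``.
    strand:
        ``"+"`` or ``"-"``.
    cluster_id:
        Homology-cluster assignment; ``None`` for unclustered ("alien")
        genes, which are legal and required downstream.
    product:
        Optional free-text annotation.
    """

    feature_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    cluster_id: Optional[str] = None
    product: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) < start ({self.start}) for {self.feature_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def center(self) -> float:
        """Midpoint of the feature; invariant under strand flip."""
        return (self.start + self.end) / 2.0

    def with_cluster(self, cluster_id: Optional[str]) -> "GeneFeature":
        return GeneFeature(
            self.feature_id,
            self.genome_id,
            self.contig_id,
            self.start,
            self.end,
            self.strand,
            cluster_id,
            self.product,
        )

    @property
    def key(self) -> tuple[str, str]:
        """Identity key ``(genome_id, feature_id)``."""
        return (self.genome_id, self.feature_id)


def center_distance(a: GeneFeature, b: GeneFeature) -> float:
    """Center-to-center distance in bp; ``inf`` across contigs or genomes."""
    if a.genome_id != b.genome_id or a.contig_id != b.contig_id:
        return math.inf
    return abs(a.center - b.center)


@dataclass
class Genome:
    """One annotated genome: ordered contigs and coordinate-sorted features."""

    genome_id: str
    contigs: list[tuple[str, int]] = field(default_factory=list)
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sort_features()
        lengths = dict(self.contigs)
        for f in self.features:
            if f.genome_id != self.genome_id:
                raise ValueError(
                    f"feature {f.feature_id} belongs to {f.genome_id}, "
                    f"not {self.genome_id}"
                )
            if f.contig_id in lengths and f.end > lengths[f.contig_id]:
                raise ValueError(
                    f"feature {f.feature_id} ({f.start}..{f.end}) exceeds "
                    f"contig {f.contig_id} length {lengths[f.contig_id]}"
                )

    def sort_features(self) -> None:
        self.features.sort(key=lambda f: (f.contig_id, f.start, f.end, f.feature_id))

    @property
    def n_features(self) -> int:
        return len(self.features)

    def features_on(self, contig_id: str) -> list[GeneFeature]:
        return [f for f in self.features if f.contig_id == contig_id]

    def feature_by_id(self, feature_id: str) -> GeneFeature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)


class GenomeSet:
    """A collection of genomes plus the homology-cluster map.

    This is the unit every analysis runs on. ``cluster_map`` maps each
    cluster_id to the list of member features across all genomes; it is
    rebuilt from the features, so the two views can never disagree.
    """

    def __init__(self, genomes: Iterable[Genome]):
        self.genomes: list[Genome] = list(genomes)
        ids = [g.genome_id for g in self.genomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genome_id in GenomeSet")
        self._by_id = {g.genome_id: g for g in self.genomes}
        seen: set[tuple[str, str]] = set()
        for g in self.genomes:
            for f in g.features:
                if f.key in seen:
                    raise ValueError(f"duplicate feature key {f.key}")
                seen.add(f.key)
        self.rebuild_cluster_map()

    def rebuild_cluster_map(self) -> None:
        cmap: dict[str, list[GeneFeature]] = {}
        for g in self.genomes:
            for f in g.features:
                if f.cluster_id is not None:
                    cmap.setdefault(f.cluster_id, []).append(f)
        self.cluster_map: dict[str, list[GeneFeature]] = cmap

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    @property
    def genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes]

    def __iter__(self) -> Iterator[Genome]:
        return iter(self.genomes)

    def __len__(self) -> int:
        return len(self.genomes)

    def genome(self, genome_id: str) -> Genome:
        return self._by_id[genome_id]

    def cluster_members_in(self, cluster_id: str, genome_id: str) -> list[GeneFeature]:
        return [
            f
            for f in self.cluster_map.get(cluster_id, [])
            if f.genome_id == genome_id
        ]

    def cluster_prevalence(self, cluster_id: str) -> int:
        """Number of genomes containing at least one member of the cluster."""
        return len({f.genome_id for f in self.cluster_map.get(cluster_id, [])})


class Phylogeny:
    """A phylogeny with branch lengths, backed by a dendropy tree."""

    def __init__(self, tree) -> None:
        import dendropy

        if not isinstance(tree, dendropy.Tree):
            raise TypeError("Phylogeny wraps a dendropy.Tree")
        for edge in tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            if edge.length is None:
                raise ValueError("phylogeny has edges without branch lengths")
            if edge.length < 0:
                raise ValueError("negative branch length")
        self.tree = tree
        self._pdm = tree.phylogenetic_distance_matrix()
        self._taxa = {t.label: t for t in tree.taxon_namespace}

    @property
    def tip_ids(self) -> set[str]:
        return set(self._taxa)

    @property
    def newick_text(self) -> str:
        return self.tree.as_string(schema="newick")

    def distance(self, a: str, b: str) -> float:
        """Patristic distance: sum of branch lengths on the tip-to-tip path."""
        if a not in self._taxa:
            raise KeyError(f"unknown tip {a!r}")
        if b not in self._taxa:
            raise KeyError(f"unknown tip {b!r}")
        if a == b:
            return 0.0
        return float(self._pdm.patristic_distance(self._taxa[a], self._taxa[b]))
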