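"""Shared fixtures: hand-built genome sets and one simulated corpus."""

from __future__ import annotations

import pytest

from genegangs.model import GeneFeature, Genome, GenomeSet
from genegangs.simulate import PlantedGangSpec, SimConfig, simulate


def make_genome(
    genome_id: str,
    feats: list[tuple],
    length: int = 500_000,
    contig_id: str | None = None,
) -> Genome:
    """Build a one-contig genome from (fid, start, end, strand, cluster) tuples."""
    contig = contig_id or f"{genome_id}_c1"
    features = [
        GeneFeature(
            feature_id=fid,
            genome_id=genome_id,
            contig_id=contig,
            start=start,
            end=end,
            strand=strand,
            cluster_id=cluster,
        )
        for fid, start, end, strand, cluster in feats
    ]
    return Genome(genome_id=genome_id, contigs=[(contig, length)], features=features)


@pytest.fixture
def worked_example_gs() -> GenomeSet:
    """Ten genomes with an A-B-C neighborhood; C is absent from the last one.

    Centers sit at 1500/3500/5500, so consecutive pairs are 2000 bp apart
    (inside the 3500 bp window) while A and C are 4000 bp apart. The
    resulting gang has cluster ruliness <A, B, C> = <1.00, 1.00, 0.90>.
    """
    genomes = []
    for i in range(10):
        gid = f"V{i + 1:02d}"
        feats = [
            (f"{gid}_a", 1000, 2000, "+", "A"),
            (f"{gid}_b", 3000, 4000, "-", "B"),
        ]
        if i < 9:
            feats.append((f"{gid}_c", 5000, 6000, "+", "C"))
        genomes.append(make_genome(gid, feats, length=10_000))
    return GenomeSet(genomes)


@pytest.fixture(scope="session")
def corpus():
    """One corpus-scale simulated set with five planted gangs (fixed seed)."""
    cfg = SimConfig(
        planted_gangs=[PlantedGangSpec(s) for s in (3, 5, 7, 10, 4)],
        rng_seed=20180576,
    )
    return simulate(cfg)
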