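"""Synthetic genome sets with known structure for end-to-end validation.

The generator emulates a chlorovirus-scale corpus: ~41 linear genomes of
~330 kbp carrying 319–416 non-overlapping genes each, a core set of 155
single-copy clusters present in every genome, optional highly paralogous
"large" families, and planted gene gangs whose members stay within a
bounded center-to-center span. An ancestor genome is generated first and
every genome derives from it by block inversions and translocations
(Poisson-distributed event counts), so orthologs share clusters and a
phylogenetic signal exists; a star phylogeny with branch lengths
proportional to the number of applied events is emitted alongside.

Planted gangs are moved as atomic units with fixed internal spacing and a
buffer gap on both flanks wider than the detection window, so that with
zero disruption their members — and only their members — are mutually
collinear in every genome. Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .io import write_fasta, write_gff3
from .model import GeneFeature, Genome, GenomeSet

__all__ = ["PlantedGangSpec", "SimConfig", "SyntheticTruth", "simulate", "degrade_ruliness"]


@dataclass
class PlantedGangSpec:
    """One planted gang: member count, max consecutive-center span, target ruliness."""

    size: int
    max_span_bp: float = 3500.0
    ruliness: float = 1.0

    def __post_init__(self) -> None:
        if not 3 <= self.size <= 10:
            raise ValueError("planted gang size must be in 3..10")
        if not 0.0 < self.ruliness <= 1.0:
            raise ValueError("ruliness must be in (0, 1]")


@dataclass
class SimConfig:
    """Study conditions of the synthetic corpus (defaults: chlorovirus scale)."""

    n_genomes: int = 41
    genome_length: int = 330_000
    n_genes_min: int = 319
    n_genes_max: int = 416
    n_core_clusters: int = 155
    planted_gangs: list[PlantedGangSpec] = field(default_factory=list)
    large_families: tuple[int, ...] = ()  # total members per family, each > 80
    shuffle_intensity: float = 20.0  # expected block events per genome
    gang_disruption_rate: float = 0.0  # P(a planted gang loses a member) per genome
    unclustered_fraction: float = 0.05  # accessory genes left without a cluster
    gene_len_min: int = 300
    gene_len_max: int = 900
    min_gap: int = 50
    gang_flank_gap: int = 4000  # buffer outside planted gangs, > detection window
    max_block_genes: int = 25  # shuffled blocks span 1..this many units
    rng_seed: int = 0


@dataclass
class SyntheticTruth:
    """Manifest of what was planted; exactly describes the emitted genome set."""

    gangs: list[dict]  # {"gang_index", "cluster_ids", "features": {genome: [ids]}}
    events: dict[str, list[dict]]  # per-genome inversion/translocation/deletion log
    core_clusters: list[str]
    large_clusters: list[str]

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


@dataclass
class _Slot:
    """One ancestor gene slot."""

    slot: int
    length: int
    strand: str
    cluster_id: Optional[str]
    core: bool = False
    gang: Optional[int] = None  # planted gang index
    deletable: bool = True


@dataclass
class _Unit:
    """A shuffling unit: a single gene, or a whole planted gang with fixed
    internal gaps and flanking buffers."""

    slots: list[_Slot]
    internal_gaps: list[int]
    gang: Optional[int] = None

    def invert(self) -> None:
        self.slots = [
            _Slot(s.slot, s.length, "-" if s.strand == "+" else "+", s.cluster_id,
                  s.core, s.gang, s.deletable)
            for s in reversed(self.slots)
        ]
        self.internal_gaps = list(reversed(self.internal_gaps))


def _plan_ancestor(cfg: SimConfig, rng: np.random.Generator) -> list[_Unit]:
    n = cfg.n_genes_max
    lengths = rng.integers(cfg.gene_len_min, cfg.gene_len_max + 1, size=n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    gang_sizes = [sp.size for sp in cfg.planted_gangs]
    if sum(gang_sizes) > cfg.n_core_clusters:
        raise ValueError("planted gang members exceed the core-cluster budget")
    # choose disjoint contiguous slot runs for gangs, well separated
    sep = 12  # slots between gang runs: > window at typical gene density
    runs: list[tuple[int, int]] = []
    for size in gang_sizes:
        for _ in range(10_000):
            start = int(rng.integers(sep, n - size - sep))
            if all(start + size + sep <= s or e + sep <= start for s, e in runs):
                runs.append((start, start + size))
                break
        else:
            raise ValueError("cannot place planted gangs; too many for the genome")

    gang_of_slot: dict[int, int] = {}
    for gi, (s, e) in enumerate(runs):
        for i in range(s, e):
            gang_of_slot[i] = gi

    slots: list[_Slot] = []
    for i in range(n):
        slots.append(
            _Slot(
                slot=i,
                length=int(lengths[i]),
                strand=str(strands[i]),
                cluster_id=None,
                gang=gang_of_slot.get(i),
            )
        )

    # large paralog families: k slots each, all sharing one cluster id
    large_slots: set[int] = set()
    free = [i for i in range(n) if slots[i].gang is None]
    for fi, total in enumerate(cfg.large_families):
        if total <= 80:
            raise ValueError("large families must have > 80 total members")
        k = math.ceil(total / cfg.n_genomes)
        chosen = rng.choice([i for i in free if i not in large_slots], size=k, replace=False)
        for i in chosen:
            slots[i].cluster_id = f"L{fi:02d}"
            slots[i].deletable = False
            large_slots.add(int(i))

    # core clusters: every planted gang member plus random fill, single copy
    core_slots = set(gang_of_slot)
    pool = [i for i in range(n) if i not in core_slots and i not in large_slots]
    fill = cfg.n_core_clusters - len(core_slots)
    core_slots |= {int(i) for i in rng.choice(pool, size=fill, replace=False)}
    for i in sorted(core_slots):
        slots[i].core = True
        slots[i].deletable = False
        slots[i].cluster_id = f"C{i:04d}"

    # accessory genes: own singleton clusters, a fraction left unclustered
    for i in range(n):
        if slots[i].cluster_id is None and slots[i].gang is None:
            if rng.random() >= cfg.unclustered_fraction:
                slots[i].cluster_id = f"A{i:04d}"

    # ancestor gap plan; intra-gang gaps are tight so consecutive centers
    # respect the planted span
    intra: dict[int, list[int]] = {}
    for gi, (s, e) in enumerate(runs):
        gaps = []
        for i in range(s, e - 1):
            span = cfg.planted_gangs[gi].max_span_bp
            cap = int(span - (slots[i].length + slots[i + 1].length) / 2)
            if cap < cfg.min_gap:
                raise ValueError("planted span too tight for the gene lengths")
            gaps.append(int(rng.integers(cfg.min_gap, min(cap, 200) + 1)))
        intra[gi] = gaps

    # assemble shuffling units in ancestor order
    units: list[_Unit] = []
    i = 0
    run_start = {s: (s, e) for s, e in runs}
    while i < n:
        if i in run_start:
            s, e = run_start[i]
            gi = gang_of_slot[i]
            units.append(_Unit(slots=slots[s:e], internal_gaps=intra[gi], gang=gi))
            i = e
        else:
            units.append(_Unit(slots=[slots[i]], internal_gaps=[]))
            i += 1

    # feasibility of the packing
    total_len = int(sum(s.length for s in slots))
    n_gaps = len(units) + 1
    flank = 2 * cfg.gang_flank_gap * len(runs)
    if total_len + flank + n_gaps * cfg.min_gap > cfg.genome_length:
        raise ValueError(
            f"infeasible packing: {cfg.n_genes_max} genes do not fit in "
            f"{cfg.genome_length} bp"
        )
    return units


def _layout(
    units: list[_Unit],
    cfg: SimConfig,
    rng: np.random.Generator,
    genome_id: str,
    contig_id: str,
) -> Genome:
    """Place units left to right, redrawing inter-unit gaps."""
    total_len = sum(s.length for u in units for s in u.slots)
    n_inter = len(units) + 1
    flank = 2 * cfg.gang_flank_gap * sum(1 for u in units if u.gang is not None)
    budget = cfg.genome_length - total_len - flank - sum(
        g for u in units for g in u.internal_gaps
    )
    mean_extra = max(0, budget // n_inter - cfg.min_gap)
    feats: list[GeneFeature] = []
    pos = 1
    prev_gang = False
    for u in units:
        gap = int(rng.integers(cfg.min_gap, cfg.min_gap + 2 * mean_extra + 1))
        if u.gang is not None or prev_gang:
            gap = max(gap, cfg.gang_flank_gap)
        pos += gap
        for k, s in enumerate(u.slots):
            start = pos
            end = pos + s.length - 1
            feats.append(
                GeneFeature(
                    feature_id=f"{genome_id}_g{s.slot:04d}",
                    genome_id=genome_id,
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    strand=s.strand,
                    cluster_id=s.cluster_id,
                )
            )
            pos = end + 1
            if k < len(u.internal_gaps):
                pos += u.internal_gaps[k]
        prev_gang = u.gang is not None
    tail = int(rng.integers(cfg.min_gap, cfg.min_gap + 2 * mean_extra + 1))
    length = pos + tail
    return Genome(genome_id=genome_id, contigs=[(contig_id, length)], features=feats)


def _shuffle(
    units: list[_Unit], cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[_Unit], list[dict]]:
    units = [
        _Unit(slots=list(u.slots), internal_gaps=list(u.internal_gaps), gang=u.gang)
        for u in units
    ]
    events: list[dict] = []
    n_events = int(rng.poisson(cfg.shuffle_intensity))
    for _ in range(n_events):
        if len(units) < 2:
            break
        block_len = int(rng.integers(1, min(cfg.max_block_genes, len(units)) + 1))
        start = int(rng.integers(0, len(units) - block_len + 1))
        block = units[start : start + block_len]
        if rng.random() < 0.5:
            for u in block:
                u.invert()
            units[start : start + block_len] = list(reversed(block))
            events.append({"type": "inversion", "start_unit": start, "n_units": block_len})
        else:
            rest = units[:start] + units[start + block_len :]
            at = int(rng.integers(0, len(rest) + 1))
            units = rest[:at] + block + rest[at:]
            events.append(
                {"type": "translocation", "start_unit": start, "n_units": block_len,
                 "insert_at": at}
            )
    return units, events


def simulate(
    cfg: SimConfig, out_dir: Optional[str | os.PathLike] = None
) -> tuple[GenomeSet, SyntheticTruth]:
    """Generate a genome set plus its truth manifest; optionally write files.

    When ``out_dir`` is given, one GFF3+FASTA pair per genome, a cluster
    table TSV, the truth JSON, and a star-phylogeny Newick are written;
    re-loading them through the I/O module reproduces the in-memory set.
    Deterministic (byte-identical files) for a fixed ``rng_seed``.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    if cfg.n_genes_min > cfg.n_genes_max:
        raise ValueError("n_genes_min > n_genes_max")
    ancestor = _plan_ancestor(cfg, rng)

    width = max(2, len(str(cfg.n_genomes)))
    genome_ids = [f"G{i + 1:0{width}d}" for i in range(cfg.n_genomes)]

    # pre-draw which genomes lose a member of each sub-ruly planted gang
    degraded: dict[int, tuple[int, set[str]]] = {}  # gang -> (victim slot, genomes)
    for gi, sp in enumerate(cfg.planted_gangs):
        if sp.ruliness < 1.0:
            k = round((1.0 - sp.ruliness) * cfg.n_genomes)
            victims = rng.choice(cfg.n_genomes, size=k, replace=False)
            gang_slots = [s.slot for u in ancestor if u.gang == gi for s in u.slots]
            victim_slot = int(rng.choice(gang_slots))
            degraded[gi] = (victim_slot, {genome_ids[v] for v in victims})

    genomes: list[Genome] = []
    events_log: dict[str, list[dict]] = {}
    for gid in genome_ids:
        events: list[dict] = []
        units = [
            _Unit(slots=list(u.slots), internal_gaps=list(u.internal_gaps), gang=u.gang)
            for u in ancestor
        ]

        drop_slots: set[int] = set()
        target = int(rng.integers(cfg.n_genes_min, cfg.n_genes_max + 1))
        deletable = [u.slots[0].slot for u in units if u.gang is None and u.slots[0].deletable]
        n_del = min(cfg.n_genes_max - target, len(deletable))
        if n_del > 0:
            drop_slots |= {int(i) for i in rng.choice(deletable, size=n_del, replace=False)}
        for gi, (victim, gset) in degraded.items():
            if gid in gset:
                drop_slots.add(victim)
        for gi in range(len(cfg.planted_gangs)):
            if rng.random() < cfg.gang_disruption_rate:
                gang_slots = [s.slot for u in units if u.gang == gi for s in u.slots]
                drop_slots.add(int(rng.choice(gang_slots)))

        if drop_slots:
            pruned: list[_Unit] = []
            for u in units:
                kept = [s for s in u.slots if s.slot not in drop_slots]
                removed = [s for s in u.slots if s.slot in drop_slots]
                for s in removed:
                    events.append({"type": "deletion", "slot": s.slot})
                if not kept:
                    continue
                gaps = u.internal_gaps[: max(0, len(kept) - 1)]
                pruned.append(_Unit(slots=kept, internal_gaps=gaps, gang=u.gang))
            units = pruned

        units, shuffle_events = _shuffle(units, cfg, rng)
        events.extend(shuffle_events)
        genomes.append(_layout(units, cfg, rng, gid, f"{gid}_c1"))
        events_log[gid] = events

    gs = GenomeSet(genomes)
    gang_truth = []
    for gi, sp in enumerate(cfg.planted_gangs):
        slots_of_gang = [s.slot for u in ancestor if u.gang == gi for s in u.slots]
        cluster_ids = sorted(f"C{i:04d}" for i in slots_of_gang)
        feats = {}
        for g in gs:
            present = [
                f.feature_id for f in g.features if f.cluster_id in cluster_ids
            ]
            feats[g.genome_id] = sorted(present)
        gang_truth.append(
            {"gang_index": gi, "cluster_ids": cluster_ids, "features": feats}
        )
    truth = SyntheticTruth(
        gangs=gang_truth,
        events=events_log,
        core_clusters=sorted(
            {s.cluster_id for u in ancestor for s in u.slots if s.core}
        ),
        large_clusters=sorted(
            {
                s.cluster_id
                for u in ancestor
                for s in u.slots
                if s.cluster_id and s.cluster_id.startswith("L")
            }
        ),
    )

    if out_dir is not None:
        _write_files(gs, truth, cfg, Path(out_dir), rng)
    return gs, truth


_BASES = np.array(list("ACGT"))


def _write_files(
    gs: GenomeSet,
    truth: SyntheticTruth,
    cfg: SimConfig,
    out_dir: Path,
    rng: np.random.Generator,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for g in gs:
        write_gff3(g, out_dir / f"{g.genome_id}.gff3")
        contigs = []
        for cid, length in g.contigs:
            seq = "".join(_BASES[rng.integers(0, 4, size=length)])
            contigs.append((cid, seq))
        write_fasta(contigs, out_dir / f"{g.genome_id}.fa")
    with open(out_dir / "clusters.tsv", "w") as fh:
        fh.write("#genome_id\tfeature_id\tcluster_id\n")
        for g in gs:
            for f in g.features:
                if f.cluster_id is not None:
                    fh.write(f"{g.genome_id}\t{f.feature_id}\t{f.cluster_id}\n")
    truth.to_json(out_dir / "truth.json")
    # star phylogeny, branch length proportional to applied events
    tips = []
    for g in gs:
        n_ev = sum(1 for e in truth.events[g.genome_id] if e["type"] != "deletion")
        tips.append(f"{g.genome_id}:{0.001 + 0.01 * n_ev:.5f}")
    with open(out_dir / "tree.nwk", "w") as fh:
        fh.write("(" + ",".join(tips) + ");\n")


def degrade_ruliness(
    gs: GenomeSet,
    truth: SyntheticTruth,
    cluster_id: str,
    k_genomes: int,
    seed: int,
) -> tuple[GenomeSet, SyntheticTruth]:
    """Delete a cluster's features from k randomly chosen genomes.

    Creates unruly variants of an existing set: the cluster's resulting
    ruliness is exactly ``(n - k) / n``. The truth manifest is updated in
    kind. ``k_genomes`` must be smaller than the number of genomes and not
    exceed the cluster's current prevalence.
    """
    if k_genomes >= gs.n_genomes:
        raise ValueError("k_genomes must be < n_genomes")
    rng = np.random.default_rng(seed)
    have = sorted(
        {f.genome_id for f in gs.cluster_map.get(cluster_id, [])}
    )
    if len(have) < k_genomes:
        raise ValueError(
            f"cluster {cluster_id} present in only {len(have)} genomes"
        )
    victims = set(rng.choice(have, size=k_genomes, replace=False)) if k_genomes else set()

    new_genomes = []
    events = {gid: list(ev) for gid, ev in truth.events.items()}
    for g in gs:
        if g.genome_id in victims:
            feats = [f for f in g.features if f.cluster_id != cluster_id]
            for f in g.features:
                if f.cluster_id == cluster_id:
                    events[g.genome_id].append(
                        {"type": "deletion", "feature_id": f.feature_id}
                    )
            new_genomes.append(Genome(g.genome_id, list(g.contigs), feats))
        else:
            new_genomes.append(g)
    new_gs = GenomeSet(new_genomes)
    new_gangs = []
    for gang in truth.gangs:
        gang = dict(gang)
        if cluster_id in gang["cluster_ids"]:
            gang["features"] = {
                gid: [
                    fid
                    for fid in fids
                    if gid not in victims
                    or any(
                        f.feature_id == fid
                        for f in new_gs.genome(gid).features
                    )
                ]
                for gid, fids in gang["features"].items()
            }
        new_gangs.append(gang)
    new_truth = SyntheticTruth(
        gangs=new_gangs,
        events=events,
        core_clusters=list(truth.core_clusters),
        large_clusters=list(truth.large_clusters),
    )
    return new_gs, new_truth
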