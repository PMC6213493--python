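"""Single-copy core genes and conservation of pairwise gene distances.

Single-copy core genes (SCCGs) are homology clusters present exactly once in
every genome of a set. Two complementary analyses quantify how well the
center-to-center distance between SCCG pairs is conserved across genomes:

* the **strictly constrained bin analysis** asks how often the analogous
  pair in other genomes sits at roughly the *same* distance (within the
  seed pair's 1-kbp bin widened by a small buffer);
* the **growing bin analysis** asks how often the analogous pair stays
  within a *maximum* distance (bins growing from 0–1 kbp to 0–280 kbp),
  compared against a random-shuffle background in which genes shuffle
  independently while preserving the genome's overall pairwise distance
  distribution (the empirical CDF of all gene-pair distances).

The half-maximal crossing of the background-subtracted growing-bin curve
gives the largest bin size at which non-random distance conservation is
still detectable for a genome pair.

All distances are center-to-center in bp; pairs on different contigs have
undefined (infinite) distance and can never fall inside a bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import GeneFeature, Genome, GenomeSet, Phylogeny

__all__ = [
    "SCCGSet",
    "ConstrainedBinCurve",
    "GrowingBinCurve",
    "HalfMaxResult",
    "identify_sccgs",
    "pairwise_center_distances",
    "constrained_bin_analysis",
    "growing_bin_analysis",
    "random_shuffle_null",
    "half_max_threshold",
    "phylo_distance",
]

DEFAULT_BIN_BP = 1_000
DEFAULT_MAX_BP = 280_000
DEFAULT_BUFFER_BP = 250
DEFAULT_THRESHOLDS = (1.00, 0.90, 0.80, 0.70)

_EPS = 1e-12


@dataclass
class SCCGSet:
    """The single-copy core genes of a genome set."""

    cluster_ids: list[str]
    per_genome_feature: dict[tuple[str, str], GeneFeature]
    genome_ids: list[str]

    def __len__(self) -> int:
        return len(self.cluster_ids)

    def feature(self, genome_id: str, cluster_id: str) -> GeneFeature:
        return self.per_genome_feature[(genome_id, cluster_id)]

    def features_in(self, genome_id: str) -> list[GeneFeature]:
        return [self.feature(genome_id, c) for c in self.cluster_ids]


def identify_sccgs(gs: GenomeSet) -> SCCGSet:
    """Return the clusters with exactly one member in every genome."""
    sccg_ids = []
    per_genome: dict[tuple[str, str], GeneFeature] = {}
    for cid in sorted(gs.cluster_map):
        members = gs.cluster_map[cid]
        by_genome: dict[str, list[GeneFeature]] = {}
        for f in members:
            by_genome.setdefault(f.genome_id, []).append(f)
        if len(by_genome) == gs.n_genomes and all(
            len(v) == 1 for v in by_genome.values()
        ):
            sccg_ids.append(cid)
            for gid, (feat,) in by_genome.items():
                per_genome[(gid, cid)] = feat
    return SCCGSet(sccg_ids, per_genome, gs.genome_ids)


def pairwise_center_distances(
    g: Genome, features: Sequence[GeneFeature]
) -> list[tuple[tuple[GeneFeature, GeneFeature], float]]:
    """All unordered same-contig pairs with their center-to-center distance.

    Pairs spanning different contigs are omitted (their distance is
    undefined on a linear, possibly fragmented assembly).
    """
    out = []
    feats = list(features)
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            a, b = feats[i], feats[j]
            if a.contig_id != b.contig_id:
                continue
            out.append(((a, b), abs(a.center - b.center)))
    return out


def _sccg_distance_matrix(gs: GenomeSet, sccg: SCCGSet, genome_id: str) -> np.ndarray:
    """Distance matrix over SCCG clusters (sccg.cluster_ids order) in one
    genome; ``inf`` across contigs."""
    feats = sccg.features_in(genome_id)
    centers = np.array([f.center for f in feats], dtype=float)
    contigs = np.array([f.contig_id for f in feats])
    d = np.abs(centers[:, None] - centers[None, :])
    d[contigs[:, None] != contigs[None, :]] = np.inf
    return d


def _upper_triangle(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


@dataclass
class ConstrainedBinCurve:
    """Pooled result of the strictly constrained bin analysis.

    ``conserved_fraction[t]`` gives, per 1-kbp seed-distance bin, the
    fraction of seed pairs whose distance was conserved (within the bin
    widened by ``buffer_bp`` on each side) in at least a fraction ``t`` of
    the other genomes. Bins containing no seed pair hold NaN, never 0.
    """

    bin_upper_bp: np.ndarray
    bin_bp: int
    buffer_bp: int
    thresholds: tuple[float, ...]
    conserved_fraction: dict[float, np.ndarray]
    n_seed_pairs: np.ndarray

    def occupied(self) -> np.ndarray:
        return self.n_seed_pairs > 0


def constrained_bin_analysis(
    gs: GenomeSet,
    sccg: SCCGSet,
    bin_bp: int = DEFAULT_BIN_BP,
    buffer_bp: int = DEFAULT_BUFFER_BP,
    max_bp: int = DEFAULT_MAX_BP,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> ConstrainedBinCurve:
    """Strict conservation of SCCG pair distances, pooled over seed genomes.

    Every genome serves as the seed in turn. Each same-contig SCCG pair in
    the seed genome is assigned to the 1-kbp bin holding its distance; the
    analogous pair in another genome counts as conserved when its distance
    lies within ``[bin_low - buffer, bin_high + buffer]``. A pair absent
    from one contig in a comparison genome counts as not conserved there.
    """
    if gs.n_genomes < 2:
        raise ValueError("constrained bin analysis needs >= 2 genomes")
    n_bins = max_bp // bin_bp
    edges = np.arange(1, n_bins + 1) * bin_bp
    n_pairs_total = np.zeros(n_bins, dtype=int)
    n_conserved = {t: np.zeros(n_bins, dtype=int) for t in thresholds}

    dmats = {gid: _upper_triangle(_sccg_distance_matrix(gs, sccg, gid)) for gid in gs.genome_ids}
    n_other = gs.n_genomes - 1
    for seed_id in gs.genome_ids:
        d_seed = dmats[seed_id]
        in_range = np.isfinite(d_seed) & (d_seed < max_bp)
        if not in_range.any():
            continue
        bins = np.floor(d_seed[in_range] / bin_bp).astype(int)
        lo = bins * bin_bp - buffer_bp
        hi = (bins + 1) * bin_bp + buffer_bp
        conserved_count = np.zeros(in_range.sum(), dtype=int)
        for other_id in gs.genome_ids:
            if other_id == seed_id:
                continue
            d_other = dmats[other_id][in_range]
            conserved_count += ((d_other >= lo) & (d_other <= hi)).astype(int)
        frac = conserved_count / n_other
        np.add.at(n_pairs_total, bins, 1)
        for t in thresholds:
            np.add.at(n_conserved[t], bins, (frac >= t - _EPS).astype(int))

    curve = {}
    for t in thresholds:
        with np.errstate(invalid="ignore"):
            vals = np.where(
                n_pairs_total > 0, n_conserved[t] / np.maximum(n_pairs_total, 1), np.nan
            )
        curve[t] = vals
    return ConstrainedBinCurve(
        bin_upper_bp=edges,
        bin_bp=bin_bp,
        buffer_bp=buffer_bp,
        thresholds=thresholds,
        conserved_fraction=curve,
        n_seed_pairs=n_pairs_total,
    )


@dataclass
class GrowingBinCurve:
    """Growing-bin conservation curve for one ordered genome pair.

    ``observed_fraction[b]`` is the fraction of SCCG pairs within the bin
    ``[0, edge_b]`` in the first genome that are also within it in the
    second; bins with no eligible pair hold NaN. ``null_cdf_a``/``null_cdf_b``
    are the random-shuffle background CDFs of each genome, and
    ``subtracted`` is observed minus the second genome's background.
    """

    genome_pair: tuple[str, str]
    bin_upper_bp: np.ndarray
    observed_fraction: np.ndarray
    null_cdf_a: np.ndarray
    null_cdf_b: np.ndarray
    n_eligible: np.ndarray
    phylo_distance: Optional[float] = None

    @property
    def subtracted(self) -> np.ndarray:
        return self.observed_fraction - self.null_cdf_b

    def occupied(self) -> np.ndarray:
        return self.n_eligible > 0


def random_shuffle_null(
    g: Genome, bin_bp: int = DEFAULT_BIN_BP, max_bp: int = DEFAULT_MAX_BP
) -> np.ndarray:
    """Random-shuffle background: empirical CDF of all gene-pair distances.

    Uses every gene of the genome (not only SCCGs), same-contig pairs only.
    This is the conserved fraction expected at each bin size if genes
    shuffled independently while preserving the genome's internal distance
    distribution.
    """
    if g.n_features < 2:
        raise ValueError("random shuffle null needs >= 2 features")
    dists = np.array(
        [d for _, d in pairwise_center_distances(g, g.features)], dtype=float
    )
    if dists.size == 0:
        raise ValueError(f"{g.genome_id}: no same-contig gene pair")
    dists.sort()
    edges = np.arange(1, max_bp // bin_bp + 1) * bin_bp
    return np.searchsorted(dists, edges, side="right") / dists.size


def growing_bin_analysis(
    ga: Genome,
    gb: Genome,
    sccg: SCCGSet,
    bin_bp: int = DEFAULT_BIN_BP,
    max_bp: int = DEFAULT_MAX_BP,
    phylogeny: Optional[Phylogeny] = None,
) -> GrowingBinCurve:
    """Growing-bin conservation of SCCG distances for an ordered genome pair.

    For each bin ``[0, b]`` (b growing by ``bin_bp`` up to ``max_bp``), the
    observed fraction is ``#{pairs with distance <= b in both genomes} /
    #{pairs with distance <= b in ga}``. The denominator is taken from the
    first genome of the ordered pair; both orders of a comparison are
    computed on demand.
    """
    if ga.genome_id not in sccg.genome_ids or gb.genome_id not in sccg.genome_ids:
        raise ValueError("both genomes must belong to the SCCG set's genome set")
    feats_a = sccg.features_in(ga.genome_id)
    feats_b = sccg.features_in(gb.genome_id)
    ca = np.array([f.center for f in feats_a])
    cb = np.array([f.center for f in feats_b])
    ta = np.array([f.contig_id for f in feats_a])
    tb = np.array([f.contig_id for f in feats_b])
    da = np.abs(ca[:, None] - ca[None, :])
    da[ta[:, None] != ta[None, :]] = np.inf
    db = np.abs(cb[:, None] - cb[None, :])
    db[tb[:, None] != tb[None, :]] = np.inf
    da = _upper_triangle(da)
    db = _upper_triangle(db)

    edges = np.arange(1, max_bp // bin_bp + 1) * bin_bp
    da_sorted = np.sort(da)
    dmax_sorted = np.sort(np.maximum(da, db))
    den = np.searchsorted(da_sorted, edges, side="right").astype(float)
    num = np.searchsorted(dmax_sorted, edges, side="right").astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        observed = np.where(den > 0, num / np.maximum(den, 1), np.nan)

    pd = None
    if phylogeny is not None:
        pd = phylogeny.distance(ga.genome_id, gb.genome_id)
    return GrowingBinCurve(
        genome_pair=(ga.genome_id, gb.genome_id),
        bin_upper_bp=edges,
        observed_fraction=observed,
        null_cdf_a=random_shuffle_null(ga, bin_bp, max_bp),
        null_cdf_b=random_shuffle_null(gb, bin_bp, max_bp),
        n_eligible=den.astype(int),
        phylo_distance=pd,
    )


@dataclass
class HalfMaxResult:
    """Half-maximal detectability threshold of a subtracted growing-bin curve."""

    threshold_bp: int
    initial_conservation: float
    half_max: float
    reached: bool  # False when the curve never drops to half of its start


def half_max_threshold(curve: GrowingBinCurve) -> HalfMaxResult:
    """Largest bin size with reliably non-random distance conservation.

    The initial conservation is the subtracted curve's value at the first
    occupied bin; the threshold is the smallest bin upper edge at which the
    subtracted curve first drops to at most half of it. If the curve never
    reaches half-max the maximum bin is returned with ``reached=False``.
    """
    sub = curve.subtracted
    valid = curve.occupied() & np.isfinite(sub)
    if not valid.any():
        raise ValueError("no occupied bin in curve")
    first = int(np.flatnonzero(valid)[0])
    initial = float(sub[first])
    half = initial / 2.0
    for i in range(first, len(sub)):
        if valid[i] and sub[i] <= half + _EPS:
            return HalfMaxResult(int(curve.bin_upper_bp[i]), initial, half, True)
    return HalfMaxResult(int(curve.bin_upper_bp[-1]), initial, half, False)


def phylo_distance(p: Phylogeny, a: str, b: str) -> float:
    """Patristic distance between two tips (sum of path branch lengths)."""
    return p.distance(a, b)
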