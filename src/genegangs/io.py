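"""Readers and writers: GenBank, GFF3+FASTA, cluster tables, Newick trees.

GenBank parsing goes through Biopython, GFF3 through gffutils, FASTA through
Biopython, Newick through dendropy. All coordinates are kept 1-based
inclusive as the formats define them.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Optional

from .model import GeneFeature, Genome, GenomeSet, Phylogeny

logger = logging.getLogger("genegangs")

__all__ = [
    "read_genbank",
    "read_gff3_fasta",
    "read_cluster_table",
    "read_newick",
    "write_gff3",
    "write_fasta",
    "load_genome_dir",
]


def _feature_id_from_qualifiers(feat, ordinal: int) -> str:
    for key in ("locus_tag", "protein_id"):
        vals = feat.qualifiers.get(key)
        if vals:
            return str(vals[0])
    return f"cds_{ordinal:05d}"


def read_genbank(path: str | os.PathLike, genome_id: Optional[str] = None) -> Genome:
    """Load a GenBank flat file into a :class:`Genome`.

    One :class:`GeneFeature` is created per CDS. The feature_id is the
    locus_tag, falling back to protein_id and then to a synthesized ordinal
    ID. A CDS with a ``join()`` location is collapsed to its outermost span
    with a logged warning.
    """
    from Bio import SeqIO

    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    contigs: list[tuple[str, int]] = []
    features: list[GeneFeature] = []
    n = 0
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise ValueError(f"{path}: no GenBank records found")
    for rec in records:
        contigs.append((rec.id, len(rec.seq)))
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            n += 1
            loc = feat.location
            if len(getattr(loc, "parts", [loc])) > 1:
                logger.warning(
                    "%s: CDS %s has a compound (join) location; using the "
                    "outermost span",
                    path.name,
                    _feature_id_from_qualifiers(feat, n),
                )
            # Biopython locations are 0-based half-open; convert back.
            start = int(loc.start) + 1
            end = int(loc.end)
            strand = "-" if loc.strand == -1 else "+"
            product = feat.qualifiers.get("product", [None])[0]
            features.append(
                GeneFeature(
                    feature_id=_feature_id_from_qualifiers(feat, n),
                    genome_id=genome_id,
                    contig_id=rec.id,
                    start=start,
                    end=end,
                    strand=strand,
                    product=product,
                )
            )
    return Genome(genome_id=genome_id, contigs=contigs, features=features)


def _fasta_lengths(fasta_path: str | os.PathLike) -> list[tuple[str, int]]:
    from Bio import SeqIO

    return [(rec.id, len(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")]


def read_gff3_fasta(
    gff_path: str | os.PathLike,
    fasta_path: str | os.PathLike,
    genome_id: Optional[str] = None,
) -> Genome:
    """Load a GFF3 annotation plus its FASTA into a :class:`Genome`.

    CDS features are used when present, otherwise gene features. GFF3
    coordinates are 1-based inclusive and used as-is; multi-segment CDS
    sharing one ID are collapsed to the outermost span with a warning. A
    feature referencing a contig absent from the FASTA is a hard error.
    """
    import gffutils

    gff_path = Path(gff_path)
    if genome_id is None:
        genome_id = gff_path.stem
    contigs = _fasta_lengths(fasta_path)
    contig_ids = {c for c, _ in contigs}

    try:
        db = gffutils.create_db(
            str(gff_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # empty annotation is a legal degenerate input
        text = gff_path.read_text()
        if not any(
            line.strip() and not line.startswith("#") for line in text.splitlines()
        ):
            return Genome(genome_id=genome_id, contigs=contigs, features=[])
        raise ValueError(f"{gff_path}: cannot parse GFF3") from exc

    ftypes = {f.featuretype for f in db.all_features()}
    use_type = "CDS" if "CDS" in ftypes else "gene"
    # collapse multi-segment features sharing an ID to the outermost span
    spans: dict[str, list] = {}
    order: list[str] = []
    for feat in db.features_of_type(use_type, order_by=("seqid", "start")):
        fid = feat.attributes.get("ID", [f"{use_type}_{feat.start}_{feat.end}"])[0]
        # gffutils' create_unique suffixes duplicate IDs with "_1", "_2", ...
        base = fid
        if "_" in fid and fid.rsplit("_", 1)[1].isdigit() and fid.rsplit("_", 1)[0] in spans:
            base = fid.rsplit("_", 1)[0]
        if base not in spans:
            spans[base] = [feat]
            order.append(base)
        else:
            spans[base].append(feat)
    features: list[GeneFeature] = []
    for fid in order:
        parts = spans[fid]
        seqids = {p.seqid for p in parts}
        if len(seqids) > 1:
            raise ValueError(f"{gff_path}: feature {fid} spans multiple contigs")
        seqid = parts[0].seqid
        if seqid not in contig_ids:
            raise ValueError(
                f"{gff_path}: feature {fid} references contig {seqid!r} "
                f"absent from {fasta_path}"
            )
        if len(parts) > 1:
            logger.warning(
                "%s: feature %s has %d segments; using the outermost span",
                gff_path.name,
                fid,
                len(parts),
            )
        start = min(p.start for p in parts)
        end = max(p.end for p in parts)
        strand = "-" if parts[0].strand == "-" else "+"
        attrs = parts[0].attributes
        product = attrs.get("product", [None])[0]
        cluster = attrs.get("cluster_id", [None])[0]
        features.append(
            GeneFeature(
                feature_id=fid,
                genome_id=genome_id,
                contig_id=seqid,
                start=start,
                end=end,
                strand=strand,
                cluster_id=cluster,
                product=product,
            )
        )
    return Genome(genome_id=genome_id, contigs=contigs, features=features)


def read_cluster_table(path: str | os.PathLike, gs: GenomeSet) -> GenomeSet:
    """Attach homology-cluster IDs from a TSV to a :class:`GenomeSet`.

    The table has three tab-separated columns ``genome_id``, ``feature_id``,
    ``cluster_id``; a header line is optional and ``#`` comment lines are
    ignored. Rows referencing unknown features are skipped with a warning;
    duplicate rows assigning conflicting clusters to one feature are a hard
    error. Features absent from the table keep ``cluster_id = None``. The
    returned set has its cluster map rebuilt.
    """
    known: dict[tuple[str, str], GeneFeature] = {}
    for g in gs:
        for f in g.features:
            known[f.key] = f

    assigned: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                logger.warning("cluster table line %d: <3 columns, skipped", lineno)
                continue
            genome_id, feature_id, cluster_id = (p.strip() for p in parts[:3])
            key = (genome_id, feature_id)
            if key not in known:
                logger.warning(
                    "cluster table line %d: unknown feature %s, skipped",
                    lineno,
                    key,
                )
                continue
            if key in assigned and assigned[key] != cluster_id:
                raise ValueError(
                    f"cluster table line {lineno}: feature {key} assigned "
                    f"both {assigned[key]!r} and {cluster_id!r}"
                )
            assigned[key] = cluster_id

    new_genomes = []
    for g in gs:
        feats = [f.with_cluster(assigned.get(f.key)) for f in g.features]
        new_genomes.append(Genome(g.genome_id, list(g.contigs), feats))
    return GenomeSet(new_genomes)


def read_newick(path: str | os.PathLike) -> Phylogeny:
    """Load a Newick phylogeny; edges without branch lengths are an error."""
    import dendropy

    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return Phylogeny(tree)


def write_gff3(genome: Genome, path: str | os.PathLike, source: str = "genegangs") -> None:
    """Write a genome's features as GFF3 (``gene`` records).

    cluster_id and product are carried as attributes, so a written genome
    re-read with :func:`read_gff3_fasta` reproduces identical
    ``(start, end, strand, feature_id, cluster_id)`` tuples.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig_id, length in genome.contigs:
            fh.write(f"##sequence-region {contig_id} 1 {length}\n")
        for f in genome.features:
            attrs = [f"ID={f.feature_id}"]
            if f.cluster_id is not None:
                attrs.append(f"cluster_id={f.cluster_id}")
            if f.product is not None:
                attrs.append(f"product={f.product}")
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        source,
                        "gene",
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def write_fasta(
    contigs: list[tuple[str, str]], path: str | os.PathLike, width: int = 70
) -> None:
    """Write ``(contig_id, sequence)`` pairs as FASTA."""
    with open(path, "w") as fh:
        for contig_id, seq in contigs:
            fh.write(f">{contig_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_genome_dir(directory: str | os.PathLike) -> GenomeSet:
    """Load every genome in a directory into one :class:`GenomeSet`.

    ``*.gb``/``*.gbk``/``*.gbff`` files are read as GenBank; ``*.gff3``/
    ``*.gff`` files are read with the same-stem ``.fa``/``.fasta`` file.
    """
    directory = Path(directory)
    genomes: list[Genome] = []
    for p in sorted(directory.iterdir()):
        if p.suffix in (".gb", ".gbk", ".gbff"):
            genomes.append(read_genbank(p))
        elif p.suffix in (".gff3", ".gff"):
            fasta = None
            for ext in (".fa", ".fasta", ".fna"):
                cand = p.with_suffix(ext)
                if cand.exists():
                    fasta = cand
                    break
            if fasta is None:
                raise FileNotFoundError(f"no FASTA found for {p}")
            genomes.append(read_gff3_fasta(p, fasta))
    if not genomes:
        raise ValueError(f"no genomes found in {directory}")
    return GenomeSet(genomes)
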