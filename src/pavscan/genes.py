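"""Gene models and GFF3 input/output.

A :class:`GeneModel` is the unit of presence/absence calling and of sweep-region
annotation: a gene's chromosome, strand and its (merged, non-overlapping) exon
intervals. Coordinates are 0-based half-open internally; GFF3 (1-based,
inclusive) is converted on ingestion and on export.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass
from typing import Iterable, Sequence

import gffutils

__all__ = ["GeneModel", "merge_intervals", "read_gff3", "write_gff3"]


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Sort 0-based half-open intervals and merge overlapping/abutting ones."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    if not ivs:
        return ()
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


@dataclass(frozen=True)
class GeneModel:
    """A gene with merged exon intervals on a single chromosome.

    Parameters
    ----------
    gene_id : str
        Unique gene identifier.
    chromosome : str
        Chromosome (sequence) name.
    strand : str
        ``"+"`` or ``"-"``. Coverage statistics are strand-independent; the
        strand is carried for export only.
    exons : tuple of (start, end)
        0-based half-open exon intervals, non-overlapping and sorted.
        Overlapping input exons are merged so shared bases are not counted
        twice. Total exon length must be >= 1.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        merged = merge_intervals(self.exons)
        if not merged:
            raise ValueError(f"gene {self.gene_id}: at least one exon is required")
        for s, e in merged:
            if s < 0 or e <= s:
                raise ValueError(f"gene {self.gene_id}: invalid exon interval ({s}, {e})")
        object.__setattr__(self, "exons", merged)

    @property
    def start(self) -> int:
        """0-based start of the gene body (first exon start)."""
        return self.exons[0][0]

    @property
    def end(self) -> int:
        """0-based half-open end of the gene body (last exon end)."""
        return self.exons[-1][1]

    @property
    def exon_length(self) -> int:
        """Total number of exonic bases (overlaps merged)."""
        return sum(e - s for s, e in self.exons)


def write_gff3(models: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as GFF3 (gene + exon features, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            fh.write(
                f"{g.chromosome}\tpavscan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chromosome}\tpavscan\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def _top_level_gene_id(db: "gffutils.FeatureDB", feature: "gffutils.Feature") -> str:
    """Climb the Parent chain of an exon to the top-level feature id."""
    current = feature
    seen = set()
    while True:
        parents = current.attributes.get("Parent")
        if not parents:
            return current.id
        pid = parents[0]
        if pid in seen:  # defensive: malformed circular Parent chain
            return pid
        seen.add(pid)
        try:
            current = db[pid]
        except gffutils.FeatureNotFoundError:
            return pid


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from a GFF3 file.

    Exon features are grouped by their (transitively resolved) Parent gene;
    gene features without exon children fall back to a single exon spanning
    the gene body. Coordinates are converted to 0-based half-open. Gene order
    follows first appearance in the file.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    order: list[str] = []

    for feat in db.all_features():
        if feat.featuretype == "gene":
            gid = feat.id
            if gid not in meta:
                meta[gid] = (feat.seqid, feat.strand if feat.strand in "+-" else "+")
                order.append(gid)
                exons.setdefault(gid, [])
        elif feat.featuretype == "exon":
            gid = _top_level_gene_id(db, feat)
            if gid not in meta:
                meta[gid] = (feat.seqid, feat.strand if feat.strand in "+-" else "+")
                order.append(gid)
            exons.setdefault(gid, []).append((feat.start - 1, feat.end))

    models = []
    for gid in order:
        chrom, strand = meta[gid]
        ivs = exons.get(gid)
        if not ivs:
            gene = db[gid]
            ivs = [(gene.start - 1, gene.end)]
        models.append(GeneModel(gene_id=gid, chromosome=chrom, strand=strand, exons=tuple(ivs)))
    return models
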