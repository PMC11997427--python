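"""Coverage-based gene presence/absence (PAV) calling.

A gene is called *present* in a sample when at least a fraction
``lost_cutoff`` (default 0.2) of its exonic bases have read depth of at least
``min_depth`` (default 2), and *absent* otherwise — the SGSGeneLoss-style
``minCov = 2, lostCutoff = 0.2`` rule. The boundary is inclusive: a covered
fraction exactly equal to the cutoff is a presence call ("at least 20%").

Depth input follows the samtools-depth dialect: a TSV of
``(chromosome, 1-based position, depth)`` with zero-depth rows omitted, so any
position missing from the file reads as depth 0.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genes import GeneModel

__all__ = [
    "CoverageTrack",
    "PAVMatrix",
    "covered_fraction",
    "call_gene",
    "build_pav_matrix",
    "read_populations_tsv",
    "write_populations_tsv",
]

UNASSIGNED = "unassigned"


@dataclass
class CoverageTrack:
    """Sparse per-base read depth for one sample.

    ``data`` maps chromosome -> (sorted positions, depths), both 0-based numpy
    arrays. Positions not present read as depth 0.
    """

    sample_id: str
    data: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_arrays(
        cls, sample_id: str, chroms: Sequence[str], positions: np.ndarray, depths: np.ndarray
    ) -> "CoverageTrack":
        """Build from parallel per-row arrays of chrom / 0-based position / depth."""
        chroms = np.asarray(chroms)
        positions = np.asarray(positions, dtype=np.int64)
        depths = np.asarray(depths, dtype=np.int64)
        if np.any(depths < 0):
            raise ValueError("depths must be non-negative")
        data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in pd.unique(chroms):
            mask = chroms == chrom
            pos = positions[mask]
            dep = depths[mask]
            order = np.argsort(pos, kind="stable")
            data[str(chrom)] = (pos[order], dep[order])
        return cls(sample_id=sample_id, data=data)

    @classmethod
    def from_depth_tsv(cls, path: str | os.PathLike, sample_id: str | None = None) -> "CoverageTrack":
        """Read a samtools-depth TSV (chrom, 1-based pos, depth); '.gz' accepted."""
        path = Path(path)
        if sample_id is None:
            sample_id = path.name
            for suffix in (".gz", ".tsv", ".txt", ".depth"):
                if sample_id.endswith(suffix):
                    sample_id = sample_id[: -len(suffix)]
        try:
            df = pd.read_csv(
                path, sep="\t", header=None, names=["chrom", "pos", "depth"],
                dtype={"chrom": str, "pos": np.int64, "depth": np.int64},
            )
        except pd.errors.EmptyDataError:
            return cls(sample_id=sample_id, data={})
        return cls.from_arrays(sample_id, df["chrom"].to_numpy(), df["pos"].to_numpy() - 1, df["depth"].to_numpy())

    def to_depth_tsv(self, path: str | os.PathLike) -> None:
        """Write 1-based depth TSV, omitting zero-depth rows."""
        with open(path, "w") as fh:
            for chrom in self.data:
                pos, dep = self.data[chrom]
                keep = dep > 0
                for p, d in zip(pos[keep] + 1, dep[keep]):
                    fh.write(f"{chrom}\t{p}\t{d}\n")

    def depth_at(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense depth over a 0-based half-open interval (missing rows -> 0)."""
        out = np.zeros(end - start, dtype=np.int64)
        if chrom not in self.data:
            return out
        pos, dep = self.data[chrom]
        lo, hi = np.searchsorted(pos, (start, end))
        out[pos[lo:hi] - start] = dep[lo:hi]
        return out

    def chromosomes(self) -> set[str]:
        return set(self.data)


def covered_fraction(gene: GeneModel, track: CoverageTrack, min_depth: int = 2) -> float:
    """Fraction of a gene's exonic bases with depth >= ``min_depth``.

    Returns a value in [0, 1]: covered exonic base count over total exonic
    base count. Strand-independent.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    total = gene.exon_length
    if total < 1:
        raise ValueError(f"gene {gene.gene_id} has zero exon length")
    if gene.chromosome not in track.data:
        return 0.0
    pos, dep = track.data[gene.chromosome]
    covered = 0
    for s, e in gene.exons:
        lo, hi = np.searchsorted(pos, (s, e))
        covered += int(np.count_nonzero(dep[lo:hi] >= min_depth))
    return covered / total


def call_gene(fraction: float, lost_cutoff: float = 0.2) -> int:
    """Binary presence call: 1 iff ``fraction >= lost_cutoff`` (inclusive)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if not 0.0 <= lost_cutoff <= 1.0:
        raise ValueError("lost_cutoff must be in [0, 1]")
    return 1 if fraction >= lost_cutoff else 0


@dataclass
class PAVMatrix:
    """Binary genes x samples presence/absence matrix with population labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    calls: np.ndarray  # shape (n_genes, n_samples), values in {0, 1}
    populations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("calls shape does not match gene/sample id lists")
        if not np.isin(self.calls, (0, 1)).all():
            raise ValueError("calls must be binary")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.populations = {
            s: self.populations.get(s, UNASSIGNED) for s in self.sample_ids
        }

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def population_labels(self) -> list[str]:
        """Distinct population labels in sample order of first appearance."""
        return list(dict.fromkeys(self.populations[s] for s in self.sample_ids))

    def sample_indices(self, population: str | None = None) -> np.ndarray:
        if population is None:
            return np.arange(self.n_samples)
        idx = np.array(
            [i for i, s in enumerate(self.sample_ids) if self.populations[s] == population],
            dtype=np.int64,
        )
        if idx.size == 0:
            raise ValueError(f"no samples carry population label {population!r}")
        return idx

    def to_tsv(self, path: str | os.PathLike) -> None:
        df = pd.DataFrame(self.calls, index=self.gene_ids, columns=self.sample_ids)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls, path: str | os.PathLike, populations: Mapping[str, str] | None = None
    ) -> "PAVMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            calls=df.to_numpy(),
            populations=dict(populations or {}),
        )


def build_pav_matrix(
    models: Sequence[GeneModel],
    tracks: Sequence[CoverageTrack],
    populations: Mapping[str, str] | None = None,
    min_depth: int = 2,
    lost_cutoff: float = 0.2,
) -> PAVMatrix:
    """Call presence/absence for every gene in every sample.

    Rows follow gene input order, columns sample input order. Tracks whose
    chromosomes are never referenced by any gene trigger a warning (and
    contribute depth 0 everywhere they are not looked up).
    """
    if not tracks:
        raise ValueError("at least one coverage track is required")
    sample_ids = [t.sample_id for t in tracks]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids among coverage tracks")
    gene_chroms = {g.chromosome for g in models}
    for t in tracks:
        unknown = t.chromosomes() - gene_chroms
        if unknown:
            warnings.warn(
                f"track {t.sample_id}: chromosomes {sorted(unknown)} not present in "
                "gene models; their depth is ignored",
                stacklevel=2,
            )
    calls = np.zeros((len(models), len(tracks)), dtype=np.int8)
    for j, track in enumerate(tracks):
        for i, gene in enumerate(models):
            calls[i, j] = call_gene(covered_fraction(gene, track, min_depth), lost_cutoff)
    return PAVMatrix(
        gene_ids=[g.gene_id for g in models],
        sample_ids=sample_ids,
        calls=calls,
        populations=dict(populations or {}),
    )


def read_populations_tsv(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column (sample_id, population) TSV with header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("population table needs columns sample_id, population")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_populations_tsv(populations: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for s, p in populations.items():
            fh.write(f"{s}\t{p}\n")
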