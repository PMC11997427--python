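"""SNP filters, nucleotide diversity, Weir-Cockerham Fst, and sweep regions.

Implements the resequencing-side statistics of the pipeline: locus filtering
(depth 2x-50x, missing rate <= 90%, minor-allele frequency >= 5%), windowed
nucleotide diversity pi (interval-length denominator, the vcftools windowed-pi
convention), the Weir & Cockerham (1984) two-population Fst estimator
(per-site variance components summed before the ratio), per-gene statistics
with 4-kb flanks, 10-kb window aggregation of per-site sweep scores,
top-quantile window selection (nearest-rank) and the adjacent-or-one-
intervening merge rule for sweep regions.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genes import GeneModel

__all__ = [
    "UndefinedStatisticError",
    "GenotypeMatrix",
    "read_vcf",
    "write_vcf",
    "filter_snps",
    "nucleotide_diversity",
    "fst_weir_cockerham",
    "gene_flank_stats",
    "window_aggregate",
    "merge_window_runs",
    "select_and_merge",
    "annotate_regions",
]

MISSING = -1


class UndefinedStatisticError(ValueError):
    """A statistic has no defined value on the requested data (signalled, never 0)."""


@dataclass
class GenotypeMatrix:
    """Biallelic diploid SNP genotypes as alternate-allele dosage.

    ``genotypes`` has shape (n_snps, n_samples) with values 0/1/2 or -1 for
    missing. Positions are 1-based (VCF convention) and sorted within each
    chromosome.
    """

    sample_ids: list[str]
    chromosomes: np.ndarray  # per-SNP chromosome name
    positions: np.ndarray  # per-SNP 1-based position
    genotypes: np.ndarray  # (n_snps, n_samples) int8
    populations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (self.positions.size, len(self.sample_ids)):
            raise ValueError("genotypes shape does not match positions/samples")
        if not np.isin(self.genotypes, (MISSING, 0, 1, 2)).all():
            raise ValueError("genotypes must be dosage 0/1/2 or -1 (missing)")
        for chrom in pd.unique(self.chromosomes):
            pos = self.positions[self.chromosomes == chrom]
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions not sorted on {chrom}")

    @property
    def n_snps(self) -> int:
        return int(self.positions.size)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def take_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            chromosomes=self.chromosomes[mask],
            positions=self.positions[mask],
            genotypes=self.genotypes[mask],
            populations=dict(self.populations),
        )

    def region_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Sites whose 0-based coordinate lies in [start, end)."""
        return (
            (self.chromosomes == chrom)
            & (self.positions - 1 >= start)
            & (self.positions - 1 < end)
        )

    def sample_indices(self, samples: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in samples], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None

    def population_samples(self, population: str) -> list[str]:
        out = [s for s in self.sample_ids if self.populations.get(s) == population]
        if not out:
            raise ValueError(f"no samples carry population label {population!r}")
        return out


def read_vcf(path: str | os.PathLike, populations: Mapping[str, str] | None = None) -> tuple[GenotypeMatrix, int]:
    """Read biallelic SNPs from a VCF via cyvcf2.

    Returns the matrix and the number of non-biallelic/non-SNP records
    skipped.
    """
    from cyvcf2 import VCF  # deferred: cyvcf2 import is comparatively slow

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms: list[str] = []
    positions: list[int] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped += 1
            continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types, dtype=np.int8)
        dosage = np.where(gt == 3, 2, np.where(gt == 2, MISSING, gt))
        chroms.append(var.CHROM)
        positions.append(var.POS)
        rows.append(dosage.astype(np.int8))
    geno = np.vstack(rows) if rows else np.zeros((0, len(samples)), dtype=np.int8)
    gm = GenotypeMatrix(
        sample_ids=samples,
        chromosomes=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        genotypes=geno,
        populations=dict(populations or {}),
    )
    return gm, skipped


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike, contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a minimal deterministic VCF 4.2 (GT only, ref A / alt G)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.sample_ids) + "\n")
        for i in range(gm.n_snps):
            gts = "\t".join(_GT_STR[int(g)] for g in gm.genotypes[i])
            fh.write(
                f"{gm.chromosomes[i]}\t{gm.positions[i]}\tsnp{i + 1}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def filter_snps(
    gm: GenotypeMatrix,
    mean_depth: np.ndarray | None = None,
    min_depth: float = 2.0,
    max_depth: float = 50.0,
    max_missing_rate: float = 0.9,
    min_af: float = 0.05,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply the locus filters in order: depth, missingness, allele frequency.

    Retains loci with mean depth in [min_depth, max_depth] (when depths are
    supplied), missing rate <= max_missing_rate, and minor-allele frequency
    >= min_af computed on non-missing calls. Returns the surviving matrix and
    a report of loci removed by each filter. The composition is idempotent.
    """
    if gm.n_snps == 0:
        warnings.warn("filter_snps: matrix has zero loci; returned unchanged", stacklevel=2)
        return gm, {"removed_depth": 0, "removed_missing": 0, "removed_af": 0, "retained": 0}

    keep = np.ones(gm.n_snps, dtype=bool)
    report: dict[str, int] = {}

    if mean_depth is not None:
        depth = np.asarray(mean_depth, dtype=float)
        if depth.shape != (gm.n_snps,):
            raise ValueError("mean_depth must have one value per locus")
        ok = (depth >= min_depth) & (depth <= max_depth)
        report["removed_depth"] = int((keep & ~ok).sum())
        keep &= ok
    else:
        report["removed_depth"] = 0

    missing = (gm.genotypes == MISSING).mean(axis=1)
    ok = missing <= max_missing_rate
    report["removed_missing"] = int((keep & ~ok).sum())
    keep &= ok

    nonmiss = (gm.genotypes != MISSING).sum(axis=1)
    alt = np.where(gm.genotypes == MISSING, 0, gm.genotypes).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = alt / (2 * nonmiss)
    maf = np.minimum(af, 1 - af)
    ok = (nonmiss > 0) & (maf >= min_af)
    report["removed_af"] = int((keep & ~ok).sum())
    keep &= ok

    report["retained"] = int(keep.sum())
    return gm.take_sites(keep), report


def _allele_counts(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (total non-missing allele count, alt allele count)."""
    nonmiss = geno != MISSING
    n = 2 * nonmiss.sum(axis=1)
    alt = np.where(nonmiss, geno, 0).sum(axis=1)
    return n, alt


def nucleotide_diversity(
    gm: GenotypeMatrix,
    chrom: str,
    start: int,
    end: int,
    samples: Sequence[str] | None = None,
) -> float:
    """Nucleotide diversity pi per bp over [start, end) (0-based half-open).

    Per SNP, pi_site = (pairwise allele differences among non-missing haploid
    alleles) / C(n_alleles, 2); the region value sums pi_site over contained
    SNPs and divides by the full interval length in bp, so monomorphic and
    non-SNP positions contribute zero to the numerator but full weight to the
    denominator. A region whose every SNP has fewer than 2 non-missing
    alleles raises :class:`UndefinedStatisticError`.
    """
    if end - start < 1:
        raise ValueError("region length must be >= 1")
    mask = gm.region_mask(chrom, start, end)
    geno = gm.genotypes[mask]
    if samples is not None:
        geno = geno[:, gm.sample_indices(samples)]
    if geno.shape[0] == 0:
        return 0.0
    n, alt = _allele_counts(geno)
    usable = n >= 2
    if not usable.any():
        raise UndefinedStatisticError(
            f"pi undefined on {chrom}:{start}-{end}: no site with >= 2 non-missing alleles"
        )
    nn, aa = n[usable].astype(float), alt[usable].astype(float)
    pi_site = aa * (nn - aa) / (nn * (nn - 1) / 2.0)
    return float(pi_site.sum() / (end - start))


def _wc_components(
    geno_a: np.ndarray, geno_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir & Cockerham (1984) variance components a, b, c (r = 2)."""
    r = 2.0
    parts = []
    for geno in (geno_a, geno_b):
        nonmiss = geno != MISSING
        n_i = nonmiss.sum(axis=1).astype(float)  # individuals
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(nonmiss, geno, 0).sum(axis=1) / (2 * n_i)
            h_i = (geno == 1).sum(axis=1) / n_i
        parts.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = parts

    valid = (n1 >= 1) & (n2 >= 1)
    nbar = (n1 + n2) / r
    valid &= nbar > 1
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    valid &= nc > 0
    zero = np.zeros_like(nbar)
    return (
        np.where(valid, a, zero),
        np.where(valid, b, zero),
        np.where(valid, c, zero),
    )


def fst_weir_cockerham(
    gm: GenotypeMatrix,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    chrom: str | None = None,
    start: int | None = None,
    end: int | None = None,
) -> float:
    """Weir & Cockerham (1984) Fst between two sample sets.

    Per-site variance components are summed over sites before taking the
    ratio (the "ratio of averages"); negative estimates are reported as
    computed. With no polymorphic (informative) site in the region the
    estimate is undefined and :class:`UndefinedStatisticError` is raised.
    """
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each population needs at least 2 samples")
    if set(samples_a) & set(samples_b):
        raise ValueError("populations share samples")
    if chrom is not None:
        mask = gm.region_mask(chrom, start if start is not None else 0, end if end is not None else np.iinfo(np.int64).max)
        geno = gm.genotypes[mask]
    else:
        geno = gm.genotypes
    ga = geno[:, gm.sample_indices(samples_a)]
    gb = geno[:, gm.sample_indices(samples_b)]
    if geno.shape[0] == 0:
        raise UndefinedStatisticError("Fst undefined: no site in region")
    a, b, c = _wc_components(ga, gb)
    denom = (a + b + c).sum()
    if denom == 0:
        raise UndefinedStatisticError("Fst undefined: no polymorphic site in region")
    return float(a.sum() / denom)


def gene_flank_stats(
    gene: GeneModel,
    gm: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    flank: int = 4000,
    chromosome_length: int | None = None,
) -> pd.DataFrame:
    """pi (per population) and Fst for a gene body and its flanks.

    Three genomic intervals are summarised: upstream ``[start - flank,
    start)``, gene body ``[start, end)`` and downstream ``[end, end + flank)``
    in genomic orientation (strand-independent). Flanks clipped at chromosome
    bounds are flagged ``truncated``; undefined statistics are reported as
    NaN.
    """
    sa = gm.population_samples(pop_a)
    sb = gm.population_samples(pop_b)
    bounds_hi = chromosome_length if chromosome_length is not None else None
    intervals = {
        "upstream": (max(0, gene.start - flank), gene.start),
        "gene_body": (gene.start, gene.end),
        "downstream": (gene.end, gene.end + flank if bounds_hi is None else min(gene.end + flank, bounds_hi)),
    }
    rows = []
    for part, (s, e) in intervals.items():
        truncated = (part == "upstream" and e - s < flank) or (
            part == "downstream" and e - s < flank
        )
        row: dict[str, object] = {
            "part": part,
            "start": s,
            "end": e,
            "truncated": truncated,
        }
        if e - s < 1:
            row.update({f"pi_{pop_a}": np.nan, f"pi_{pop_b}": np.nan, "fst": np.nan})
        else:
            for pop, ss in ((pop_a, sa), (pop_b, sb)):
                try:
                    row[f"pi_{pop}"] = nucleotide_diversity(gm, gene.chromosome, s, e, ss)
                except UndefinedStatisticError:
                    row[f"pi_{pop}"] = np.nan
            try:
                row["fst"] = fst_weir_cockerham(gm, sa, sb, gene.chromosome, s, e)
            except UndefinedStatisticError:
                row["fst"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def window_aggregate(
    chroms: Sequence[str],
    positions: np.ndarray,
    scores: np.ndarray,
    chromosome_lengths: Mapping[str, int],
    window: int = 10_000,
) -> pd.DataFrame:
    """Average per-site scores in fixed non-overlapping windows.

    Positions are 0-based bp coordinates; windows are fixed-origin half-open
    ``[k*window, (k+1)*window)``, so a site exactly on a boundary belongs to
    the right-hand window. Terminal windows shorter than ``window`` are kept
    and flagged. Windows containing no site are omitted (and so never enter
    quantile computation downstream).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    chroms = np.asarray(chroms, dtype=object)
    positions = np.asarray(positions, dtype=np.int64)
    scores = np.asarray(scores, dtype=float)
    rows = []
    for chrom in pd.unique(chroms):
        if chrom not in chromosome_lengths:
            raise ValueError(f"no declared length for chromosome {chrom!r}")
        length = int(chromosome_lengths[chrom])
        mask = chroms == chrom
        pos = positions[mask]
        sc = scores[mask]
        if np.any((pos < 0) | (pos >= length)):
            raise ValueError(f"site beyond declared length of {chrom!r}")
        widx = pos // window
        for k in np.unique(widx):
            sel = widx == k
            start = int(k) * window
            end = min(start + window, length)
            rows.append(
                {
                    "chromosome": chrom,
                    "start": start,
                    "end": end,
                    "score": float(sc[sel].mean()),
                    "n_sites": int(sel.sum()),
                    "terminal": end - start < window,
                }
            )
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "score", "n_sites", "terminal"])


def merge_window_runs(indexes: Sequence[int]) -> list[tuple[int, int]]:
    """Merge sorted window indexes separated by at most one intervening window.

    Returns inclusive (first, last) index runs. Idempotent: merging the
    indexes covered by a run reproduces the run.
    """
    idx = sorted(set(int(i) for i in indexes))
    if not idx:
        return []
    runs = [[idx[0], idx[0]]]
    for i in idx[1:]:
        if i - runs[-1][1] <= 2:  # adjacent, or exactly one window between
            runs[-1][1] = i
        else:
            runs.append([i, i])
    return [(a, b) for a, b in runs]


def select_and_merge(
    windows: pd.DataFrame, quantile: float = 0.95, window: int = 10_000
) -> pd.DataFrame:
    """Select top-quantile windows and merge them into sweep regions.

    The score threshold is the nearest-rank empirical ``quantile`` over all
    scored windows (rank ``ceil(q * n)`` of the ascending scores); windows
    with score >= threshold are selected. Within a chromosome, selected
    windows separated by at most one intervening window on the fixed grid are
    merged; a region spans the first window start to the last window end and
    its score is the maximum member score.
    """
    if windows.empty:
        raise ValueError("at least one scored window is required")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    scores = np.sort(windows["score"].to_numpy(dtype=float))
    rank = max(1, math.ceil(quantile * scores.size))
    threshold = scores[rank - 1]
    selected = windows[windows["score"] >= threshold]
    rows = []
    for chrom, grp in selected.groupby("chromosome", sort=False):
        grp = grp.sort_values("start")
        by_index = {int(s) // window: r for s, r in zip(grp["start"], grp.to_dict("records"))}
        for first, last in merge_window_runs(list(by_index)):
            members = [by_index[i] for i in range(first, last + 1) if i in by_index]
            rows.append(
                {
                    "chromosome": chrom,
                    "start": members[0]["start"],
                    "end": members[-1]["end"],
                    "n_windows": len(members),
                    "member_starts": [m["start"] for m in members],
                    "region_score": max(m["score"] for m in members),
                }
            )
    out = pd.DataFrame(rows, columns=["chromosome", "start", "end", "n_windows", "member_starts", "region_score"])
    out.attrs["threshold"] = float(threshold)
    return out


def annotate_regions(regions: pd.DataFrame, models: Sequence[GeneModel]) -> pd.DataFrame:
    """Attach to each region the genes whose body overlaps it by >= 1 bp.

    Gene body = [first exon start, last exon end), half-open on both the gene
    and the region, so a gene abutting a region end is not assigned. Regions
    on chromosomes absent from the gene models get an empty list with a
    warning.
    """
    regions = regions.copy()
    model_chroms = {g.chromosome for g in models}
    gene_lists = []
    for _, row in regions.iterrows():
        chrom = row["chromosome"]
        if chrom not in model_chroms:
            warnings.warn(f"region chromosome {chrom!r} absent from gene models", stacklevel=2)
            gene_lists.append([])
            continue
        hits = [
            g.gene_id
            for g in models
            if g.chromosome == chrom and g.start < row["end"] and g.end > row["start"]
        ]
        gene_lists.append(hits)
    regions["genes"] = gene_lists
    regions["n_genes"] = [len(g) for g in gene_lists]
    return regions
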