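"""Synthetic cohorts with known ground truth for every pipeline stage.

The generators emulate the statistical structure of a two-population
resequencing cohort of a domesticated crop: by default 152 cultivated and 49
wild accessions, gene presence frequencies with planted between-group fold
differences (> 2), Poisson per-base exon coverage for present genes,
Balding-Nichols allele frequencies at a target Fst, an expression atlas with
genes of planted tissue specificity, and per-window sweep scores with planted
high-score runs.

Reproducibility: one global seed fans out to per-generator child seeds via
``numpy.random.SeedSequence(seed, spawn_key=(k,))`` with a fixed generator
index k, so adding a generator never perturbs the draws of another. Every
generator is byte-deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genes import GeneModel, write_gff3
from .calling import CoverageTrack, PAVMatrix, write_populations_tsv
from .expression import ExpressionMatrix
from .popgen import GenotypeMatrix, write_vcf

__all__ = ["SimulationConfig", "GroundTruth", "simulate_gene_models",
           "simulate_pav_cohort", "simulate_coverage", "simulate_genotypes",
           "simulate_expression", "simulate_window_scores", "simulate_all"]

# fixed generator -> child-seed index; append-only so existing draws are stable
_CHILD_INDEX = {
    "gene_models": 0,
    "pav": 1,
    "coverage": 2,
    "genotypes": 3,
    "expression": 4,
    "window_scores": 5,
}

_TISSUE_NAMES = ["leaf", "root", "stem", "flower", "fruit", "seed", "peel", "bud"]


def _rng(seed: int, generator: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_CHILD_INDEX[generator],))
    )


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the real cohort the pipeline targets: 152 cultivated vs
    49 wild accessions, nine chromosomes, mean exon depth 10x for present
    genes on a zero background, 50 genes planted with a > 2-fold
    between-population presence-frequency difference, genotypes at target
    Fst 0.3, and an eight-tissue expression atlas with 20 planted
    tissue-specific genes.
    """

    seed: int = 0
    n_genes: int = 200
    n_chromosomes: int = 9
    chromosome_length: int = 1_000_000
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"cultivated": 152, "wild": 49}
    )
    depth_present: float = 10.0
    depth_absent: float = 0.0
    n_selected: int = 50
    target_fst: float = 0.3
    n_snps: int = 5000
    n_tissues: int = 8
    n_specific_genes: int = 20
    n_replicates: int = 3  # expression replicates per tissue
    expression_noise_sd: float = 0.2  # log-normal sigma on replicates

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes, "n_chromosomes": self.n_chromosomes,
            "chromosome_length": self.chromosome_length, "n_selected": self.n_selected,
            "n_snps": self.n_snps, "n_tissues": self.n_tissues,
            "n_specific_genes": self.n_specific_genes, "n_replicates": self.n_replicates,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if not self.group_sizes:
            raise ValueError("group_sizes must be non-empty")
        if any(v < 0 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if not (self.depth_present > self.depth_absent >= 0):
            raise ValueError("require depth_present > depth_absent >= 0")
        if not 0 <= self.target_fst < 1:
            raise ValueError("target_fst must be in [0, 1)")
        if self.n_selected > self.n_genes:
            raise ValueError("n_selected cannot exceed n_genes")
        if self.n_specific_genes > self.n_genes:
            raise ValueError("n_specific_genes cannot exceed n_genes")

    def sample_ids(self) -> tuple[list[str], dict[str, str]]:
        """Deterministic sample ids and their population map."""
        ids, pops = [], {}
        for pop, n in self.group_sizes.items():
            for i in range(1, n + 1):
                sid = f"{pop}_{i:03d}"
                ids.append(sid)
                pops[sid] = pop
        return ids, pops


@dataclass
class GroundTruth:
    """Planted truth sufficient to score every downstream stage."""

    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    pav_truth: np.ndarray | None = None  # genes x samples, {0,1}
    selected_gene_ids: set[str] = field(default_factory=set)
    planted_frequencies: dict[str, dict[str, float]] = field(default_factory=dict)
    tau_truth: dict[str, float] = field(default_factory=dict)
    specific_tissue_truth: dict[str, str] = field(default_factory=dict)
    ancestral_freqs: np.ndarray | None = None
    planted_window_indexes: set[int] = field(default_factory=set)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "gene_ids": self.gene_ids,
            "sample_ids": self.sample_ids,
            "pav_truth": None if self.pav_truth is None else self.pav_truth.tolist(),
            "selected_gene_ids": sorted(self.selected_gene_ids),
            "planted_frequencies": self.planted_frequencies,
            "tau_truth": self.tau_truth,
            "specific_tissue_truth": self.specific_tissue_truth,
            "ancestral_freqs": None if self.ancestral_freqs is None else self.ancestral_freqs.tolist(),
            "planted_window_indexes": sorted(self.planted_window_indexes),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def simulate_gene_models(config: SimulationConfig) -> list[GeneModel]:
    """Non-overlapping gene models, assigned round-robin to chromosomes.

    Each gene has 1-10 exons of 100-600 bp (padded so total exon length is
    >= 300 bp) separated by 50-300 bp introns, and consecutive genes on a
    chromosome are separated by 200-1000 bp. Raises when a chromosome cannot
    hold its share of genes.
    """
    config.validate()
    rng = _rng(config.seed, "gene_models")
    cursors = {f"chr{i + 1}": 0 for i in range(config.n_chromosomes)}
    chrom_names = list(cursors)
    models: list[GeneModel] = []
    for i in range(config.n_genes):
        chrom = chrom_names[i % config.n_chromosomes]
        n_exons = int(rng.integers(1, 11))
        lens = rng.integers(100, 601, size=n_exons)
        deficit = 300 - int(lens.sum())
        if deficit > 0:
            lens[-1] += deficit
        gaps = rng.integers(50, 301, size=n_exons - 1) if n_exons > 1 else np.array([], dtype=int)
        start = cursors[chrom] + int(rng.integers(200, 1001))
        exons = []
        pos = start
        for j, ln in enumerate(lens):
            exons.append((pos, pos + int(ln)))
            pos += int(ln)
            if j < gaps.size:
                pos += int(gaps[j])
        if exons[-1][1] > config.chromosome_length:
            raise ValueError(
                f"chromosome {chrom} (length {config.chromosome_length}) too short "
                f"to place gene {i + 1} of {config.n_genes}"
            )
        cursors[chrom] = exons[-1][1]
        models.append(
            GeneModel(
                gene_id=f"gene{i + 1:05d}",
                chromosome=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                exons=tuple(exons),
            )
        )
    return models


def simulate_pav_cohort(
    models: Sequence[GeneModel],
    config: SimulationConfig,
    shared_frequency: float | None = None,
) -> tuple[PAVMatrix, GroundTruth]:
    """Draw a presence/absence cohort with planted frequency contrasts.

    ``n_selected`` genes get the frequency pair (0.9, 0.1) between the first
    two populations (direction randomised per gene; fold difference 9 > 2).
    The remaining genes share one frequency across populations: the fixed
    ``shared_frequency`` when given, otherwise a draw from a pan-genome-like
    mixture — 80% at 1.0 (core-like), 10% near-core on (0.95, 1), 10%
    variable on (0.05, 0.95). Per-sample presence is an independent
    Bernoulli draw per gene.
    """
    if shared_frequency is not None and not 0 <= shared_frequency <= 1:
        raise ValueError("shared_frequency must be in [0, 1]")
    config.validate()
    if len(config.group_sizes) < 2:
        raise ValueError("at least 2 populations are required")
    rng = _rng(config.seed, "pav")
    gene_ids = [g.gene_id for g in models]
    n_genes = len(gene_ids)
    if config.n_selected > n_genes:
        raise ValueError("n_selected cannot exceed the number of gene models")
    sample_ids, populations = config.sample_ids()
    pops = list(config.group_sizes)
    pop_a, pop_b = pops[0], pops[1]

    selected_idx = rng.choice(n_genes, size=config.n_selected, replace=False)
    selected_set = set(int(i) for i in selected_idx)

    # per-gene, per-population presence frequency
    freqs = {pop: np.empty(n_genes) for pop in pops}
    planted: dict[str, dict[str, float]] = {}
    for i in range(n_genes):
        if i in selected_set:
            hi_first = rng.random() < 0.5
            fa, fb = (0.9, 0.1) if hi_first else (0.1, 0.9)
            for pop in pops:
                if pop == pop_a:
                    freqs[pop][i] = fa
                elif pop == pop_b:
                    freqs[pop][i] = fb
                else:
                    freqs[pop][i] = (fa + fb) / 2
            planted[gene_ids[i]] = {pop_a: fa, pop_b: fb}
        else:
            if shared_frequency is not None:
                f = shared_frequency
            else:
                u = rng.random()
                if u < 0.8:
                    f = 1.0
                elif u < 0.9:
                    f = rng.uniform(0.95, 1.0)
                else:
                    f = rng.uniform(0.05, 0.95)
            for pop in pops:
                freqs[pop][i] = f

    calls = np.zeros((n_genes, len(sample_ids)), dtype=np.int8)
    col = 0
    for pop, n in config.group_sizes.items():
        block = (rng.random((n_genes, n)) < freqs[pop][:, None]).astype(np.int8)
        calls[:, col : col + n] = block
        col += n

    pav = PAVMatrix(gene_ids=gene_ids, sample_ids=sample_ids, calls=calls, populations=populations)
    truth = GroundTruth(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        pav_truth=calls.copy(),
        selected_gene_ids={gene_ids[i] for i in selected_set},
        planted_frequencies=planted,
    )
    return pav, truth


def simulate_coverage(
    models: Sequence[GeneModel],
    pav_truth: PAVMatrix,
    config: SimulationConfig,
    out_dir: str | os.PathLike | None = None,
) -> dict[str, CoverageTrack]:
    """Per-sample exon depth tracks consistent with a PAV truth matrix.

    Exonic bases of present genes draw depth ~ Poisson(depth_present);
    absent genes draw Poisson(depth_absent) (all-zero when depth_absent = 0).
    Non-exonic positions carry no rows, matching the samtools-depth sparse
    dialect (zero-depth rows omitted, 1-based positions on disk). When
    ``out_dir`` is given, one ``<sample>.depth.tsv`` is written per sample.
    """
    config.validate()
    if list(pav_truth.gene_ids) != [g.gene_id for g in models]:
        raise ValueError("pav_truth gene ids must match the gene models")
    rng = _rng(config.seed, "coverage")
    exon_pos = {
        g.gene_id: (
            g.chromosome,
            np.concatenate([np.arange(s, e) for s, e in g.exons]),
        )
        for g in models
    }
    tracks: dict[str, CoverageTrack] = {}
    for j, sample in enumerate(pav_truth.sample_ids):
        chroms: list[np.ndarray] = []
        poss: list[np.ndarray] = []
        deps: list[np.ndarray] = []
        for i, g in enumerate(models):
            present = pav_truth.calls[i, j] == 1
            mean = config.depth_present if present else config.depth_absent
            if mean == 0:
                continue
            chrom, pos = exon_pos[g.gene_id]
            depth = rng.poisson(mean, size=pos.size)
            keep = depth > 0
            if keep.any():
                chroms.append(np.full(keep.sum(), chrom, dtype=object))
                poss.append(pos[keep])
                deps.append(depth[keep])
        if chroms:
            track = CoverageTrack.from_arrays(
                sample,
                np.concatenate(chroms),
                np.concatenate(poss),
                np.concatenate(deps),
            )
        else:
            track = CoverageTrack(sample_id=sample, data={})
        tracks[sample] = track
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sample, track in tracks.items():
            track.to_depth_tsv(out_dir / f"{sample}.depth.tsv")
    return tracks


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, GroundTruth]:
    """Balding-Nichols diploid genotypes at a target Fst for two populations.

    Ancestral frequencies p ~ Uniform(0.1, 0.9); each population's frequency
    ~ Beta(p(1-F)/F, (1-p)(1-F)/F) with F = target_fst (taken equal to p when
    F = 0); genotypes Binomial(2, p_pop); distinct sorted positions uniform
    on chr1.
    """
    config.validate()
    if len(config.group_sizes) != 2:
        raise ValueError("genotype simulation requires exactly 2 populations")
    rng = _rng(config.seed, "genotypes")
    n_snps = config.n_snps
    p = rng.uniform(0.1, 0.9, size=n_snps)
    F = config.target_fst
    pop_freqs = []
    for _ in config.group_sizes:
        if F == 0:
            pop_freqs.append(p.copy())
        else:
            pop_freqs.append(rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F))
    sample_ids, populations = config.sample_ids()
    geno_blocks = []
    for freq, n in zip(pop_freqs, config.group_sizes.values()):
        geno_blocks.append(rng.binomial(2, freq[:, None], size=(n_snps, n)).astype(np.int8))
    genotypes = np.concatenate(geno_blocks, axis=1)
    positions = np.sort(rng.choice(config.chromosome_length, size=n_snps, replace=False)) + 1
    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        chromosomes=np.array(["chr1"] * n_snps, dtype=object),
        positions=positions,
        genotypes=genotypes,
        populations=populations,
    )
    truth = GroundTruth(sample_ids=sample_ids, ancestral_freqs=p)
    return gm, truth


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """An expression atlas with planted tissue-specific genes.

    ``n_specific_genes`` genes are expressed at mean 100 in exactly one
    tissue and at a fraction rho ~ Uniform(0, 0.1) of that elsewhere, so the
    noiseless tau = 1 - rho >= 0.9. Remaining genes have near-uniform tissue
    means m * Uniform(0.9, 1.1) (m log-uniform on [1, 100]), bounding their
    noiseless tau below ~0.21. Replicate values add multiplicative
    log-normal noise with sigma ``expression_noise_sd``. ``tau_truth``
    records tau of the noiseless tissue means.
    """
    config.validate()
    if config.n_tissues < 2:
        raise ValueError("at least 2 tissues are required")
    if config.n_replicates < 2:
        raise ValueError("at least 2 replicates per tissue are required")
    from .expression import tau as _tau

    rng = _rng(config.seed, "expression")
    n_genes, n_tissues = config.n_genes, config.n_tissues
    tissues = (_TISSUE_NAMES + [f"tissue{i}" for i in range(9, n_tissues + 1)])[:n_tissues]
    gene_ids = [f"gene{i + 1:05d}" for i in range(n_genes)]

    specific_idx = rng.choice(n_genes, size=config.n_specific_genes, replace=False)
    specific_tissue = {int(i): int(rng.integers(n_tissues)) for i in specific_idx}

    means = np.empty((n_genes, n_tissues))
    for i in range(n_genes):
        if i in specific_tissue:
            rho = rng.uniform(0.0, 0.1)
            means[i] = 100.0 * rho
            means[i, specific_tissue[i]] = 100.0
        else:
            m = 10 ** rng.uniform(0, 2)
            means[i] = m * rng.uniform(0.9, 1.1, size=n_tissues)

    sample_ids = [f"{t}_rep{r}" for t in tissues for r in range(1, config.n_replicates + 1)]
    tissue_of = {s: s.rsplit("_rep", 1)[0] for s in sample_ids}
    noise = rng.lognormal(0.0, config.expression_noise_sd, size=(n_genes, len(sample_ids)))
    tissue_cols = np.repeat(np.arange(n_tissues), config.n_replicates)
    values = means[:, tissue_cols] * noise

    em = ExpressionMatrix(
        gene_ids=gene_ids, sample_ids=sample_ids, values=values,
        tissues=tissue_of, unit="fpkm",
    )
    truth = GroundTruth(
        gene_ids=gene_ids,
        tau_truth={gene_ids[i]: _tau(means[i]) for i in range(n_genes)},
        specific_tissue_truth={gene_ids[i]: tissues[t] for i, t in specific_tissue.items()},
    )
    return em, truth


def simulate_window_scores(
    config: SimulationConfig, n_windows: int = 2000, n_planted: int = 12, window: int = 10_000
) -> tuple["pd.DataFrame", GroundTruth]:
    """Per-window sweep scores with planted high-score runs on one chromosome.

    Background scores ~ Exponential(1). Planted windows come in runs of 1-3
    consecutive windows whose scores exceed the empirical 99th percentile of
    the background; runs are separated by at least 4 background windows so
    distinct runs never merge. ``n_planted`` counts planted windows in total
    and must stay below 5% of ``n_windows``.
    """
    import pandas as pd

    config.validate()
    if n_planted >= 0.05 * n_windows:
        raise ValueError("n_planted must be below 5% of n_windows")
    rng = _rng(config.seed, "window_scores")
    scores = rng.exponential(1.0, size=n_windows)
    hi = float(np.quantile(scores, 0.99))
    planted: set[int] = set()
    blocked: set[int] = set()
    while len(planted) < n_planted:
        run_len = min(int(rng.integers(1, 4)), n_planted - len(planted))
        start = int(rng.integers(0, n_windows - run_len))
        run = range(start, start + run_len)
        if any(i in blocked for i in run):
            continue
        planted.update(run)
        blocked.update(range(start - 4, start + run_len + 4))
    for i in sorted(planted):
        scores[i] = hi + 0.5 + rng.exponential(1.0)
    df = pd.DataFrame(
        {
            "chromosome": ["chr1"] * n_windows,
            "start": np.arange(n_windows) * window,
            "end": (np.arange(n_windows) + 1) * window,
            "score": scores,
            "n_sites": np.full(n_windows, 1),
            "terminal": np.full(n_windows, False),
        }
    )
    truth = GroundTruth(planted_window_indexes=planted)
    return df, truth


def simulate_all(config: SimulationConfig, out_dir: str | os.PathLike) -> GroundTruth:
    """Run every generator and write the full fixture cohort to ``out_dir``.

    Writes genes.gff3, depth/<sample>.depth.tsv, populations.tsv,
    genotypes.vcf, expression.tsv, sample_tissues.tsv, window_scores.tsv and
    truth.json; returns the combined ground truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    models = simulate_gene_models(config)
    write_gff3(models, out / "genes.gff3")
    pav, truth = simulate_pav_cohort(models, config)
    write_populations_tsv(pav.populations, out / "populations.tsv")
    simulate_coverage(models, pav, config, out_dir=out / "depth")
    if len(config.group_sizes) == 2 and config.n_snps > 0:
        gm, gt = simulate_genotypes(config)
        write_vcf(gm, out / "genotypes.vcf", {"chr1": config.chromosome_length})
        truth.ancestral_freqs = gt.ancestral_freqs
    em, et = simulate_expression(config)
    em.to_tsv(out / "expression.tsv")
    with open(out / "sample_tissues.tsv", "w") as fh:
        fh.write("sample_id\ttissue\n")
        for s in em.sample_ids:
            fh.write(f"{s}\t{em.tissues[s]}\n")
    truth.tau_truth = et.tau_truth
    truth.specific_tissue_truth = et.specific_tissue_truth
    wdf, wt = simulate_window_scores(config)
    wdf.to_csv(out / "window_scores.tsv", sep="\t", index=False)
    truth.planted_window_indexes = wt.planted_window_indexes
    truth.to_json(out / "truth.json")
    return truth
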