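"""Expression normalisation, tissue-specificity index tau, and retention analysis.

tau summarises expression breadth from per-tissue mean expression x_1..x_n:

    tau = n/(n-1) - sum_i(x_i) / ((n-1) * max_i(x_i))

which equals sum_i(1 - x_i/max)/(n-1) and ranges from 0 (uniform across
tissues) to 1 (restricted to one tissue). tau is undefined (NaN) when every
tissue mean is zero. A gene is called tissue-specific when tau >= a threshold
(default 0.8) and its maximal tissue mean clears an expression floor
(default 1 FPKM); it is then assigned to its argmax tissue.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import PAVMatrix

__all__ = [
    "ExpressionMatrix",
    "counts_to_fpkm",
    "tissue_means",
    "tau",
    "specificity_table",
    "call_specific_genes",
    "retention_crosstab",
    "specific_gene_frequency_distribution",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix with tissue labels.

    ``unit`` tags whether ``values`` are raw counts or FPKM; ``gene_lengths``
    (bp) are required only for the counts -> FPKM conversion.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    tissues: dict[str, str]
    gene_lengths: dict[str, float] | None = None
    unit: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match gene/sample id lists")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        missing = [s for s in self.sample_ids if s not in self.tissues]
        if missing:
            raise ValueError(f"samples without tissue label: {missing[:5]}")
        if self.gene_lengths is not None:
            bad = [g for g in self.gene_ids if self.gene_lengths.get(g, 0) < 1]
            if bad:
                raise ValueError(f"gene lengths must be >= 1 bp (offenders: {bad[:5]})")

    def to_tsv(self, path: str | os.PathLike) -> None:
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        path: str | os.PathLike,
        tissues: Mapping[str, str],
        gene_lengths: Mapping[str, float] | None = None,
        unit: str = "counts",
    ) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
            tissues=dict(tissues),
            gene_lengths=dict(gene_lengths) if gene_lengths is not None else None,
            unit=unit,
        )


def counts_to_fpkm(
    em: ExpressionMatrix,
    gene_lengths: Mapping[str, float] | None = None,
    library_sizes: Mapping[str, float] | None = None,
) -> ExpressionMatrix:
    """FPKM[g, s] = counts[g, s] * 1e9 / (length[g] * library_size[s]).

    Library sizes default to column sums of the count matrix (total assigned
    counts, featureCounts-style).
    """
    lengths = gene_lengths if gene_lengths is not None else em.gene_lengths
    if lengths is None:
        raise ValueError("gene lengths are required for FPKM conversion")
    lvec = np.array([float(lengths[g]) for g in em.gene_ids])
    if np.any(lvec <= 0):
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        lib = em.values.sum(axis=0)
    else:
        lib = np.array([float(library_sizes[s]) for s in em.sample_ids])
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    fpkm = em.values * 1e9 / (lvec[:, None] * lib[None, :])
    return ExpressionMatrix(
        gene_ids=list(em.gene_ids),
        sample_ids=list(em.sample_ids),
        values=fpkm,
        tissues=dict(em.tissues),
        gene_lengths=dict(lengths),
        unit="fpkm",
    )


def tissue_means(em: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene arithmetic mean over samples sharing a tissue label.

    Columns are tissues in sorted order; requires >= 1 sample per tissue by
    construction (every tissue label comes from some sample).
    """
    labels = [em.tissues[s] for s in em.sample_ids]
    tissues = sorted(set(labels))
    out = np.empty((len(em.gene_ids), len(tissues)))
    for j, t in enumerate(tissues):
        cols = [i for i, lab in enumerate(labels) if lab == t]
        out[:, j] = em.values[:, cols].mean(axis=1)
    return pd.DataFrame(out, index=em.gene_ids, columns=tissues)


def tau(x: Sequence[float]) -> float:
    """Tissue-specificity index of a vector of per-tissue means.

    Returns a value in [0, 1]; NaN (undefined) when the maximum is zero.
    Raises on fewer than 2 tissues or on negative input.
    """
    arr = np.asarray(x, dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError("tau requires at least 2 tissues")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("tissue means must be finite and non-negative")
    m = arr.max()
    if m == 0:
        return float("nan")
    # summation form of the index, algebraically equal to
    # n/(n-1) - sum(x)/((n-1)*max) but exact at the 0 and 1 limits
    return float(np.sum(1.0 - arr / m) / (n - 1))


def specificity_table(means: pd.DataFrame) -> pd.DataFrame:
    """tau, argmax tissue, and max mean for every gene of a tissue-mean table.

    Argmax ties are broken by first tissue in sorted column order and flagged
    in ``ambiguous_argmax``.
    """
    tissues = sorted(means.columns)
    vals = means[tissues].to_numpy(dtype=float)
    n = len(tissues)
    if n < 2:
        raise ValueError("at least 2 tissues are required")
    maxv = vals.max(axis=1)
    argmax = vals.argmax(axis=1)  # numpy: first index on ties
    n_at_max = (vals == maxv[:, None]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.sum(1.0 - vals / maxv[:, None], axis=1) / (n - 1)
    t = np.where(maxv == 0, np.nan, t)
    return pd.DataFrame(
        {
            "gene_id": list(means.index),
            "tau": t,
            "argmax_tissue": [tissues[i] for i in argmax],
            "max_mean": maxv,
            "n_tissues": n,
            "ambiguous_argmax": n_at_max > 1,
        }
    )


def call_specific_genes(
    records: pd.DataFrame,
    tau_threshold: float = 0.8,
    min_max_expression: float = 1.0,
) -> dict[str, list[str]]:
    """Per-tissue lists of tissue-specific genes.

    A gene is specific to its argmax tissue iff tau >= ``tau_threshold`` and
    its maximal tissue mean >= ``min_max_expression``; genes with undefined
    tau are excluded. Each specific gene lands in exactly one tissue.
    """
    ok = (
        records["tau"].notna()
        & (records["tau"] >= tau_threshold)
        & (records["max_mean"] >= min_max_expression)
    )
    out: dict[str, list[str]] = {}
    for _, row in records[ok].iterrows():
        out.setdefault(row["argmax_tissue"], []).append(row["gene_id"])
    return out


def retention_crosstab(
    specific: Mapping[str, Sequence[str]], categories: pd.DataFrame
) -> pd.DataFrame:
    """Per-tissue proportions of pan-genome categories among specific genes.

    ``categories`` is the classify_genes output (gene_id, category). Genes
    without a category are counted as ``unclassified``; proportions sum to 1
    per tissue. Tissues with zero specific genes yield an all-NaN row.
    """
    cat_map = dict(zip(categories["gene_id"], categories["category"]))
    cols = list(dict.fromkeys(list(pd.unique(categories["category"])) + ["unclassified"]))
    rows = {}
    for tissue, genes in specific.items():
        counts = {c: 0 for c in cols}
        for g in genes:
            counts[cat_map.get(g, "unclassified")] += 1
        total = len(genes)
        rows[tissue] = {c: (counts[c] / total if total else np.nan) for c in cols}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "tissue"
    return out


def specific_gene_frequency_distribution(
    specific: Mapping[str, Sequence[str]],
    pav: PAVMatrix,
    populations: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PAV frequencies of tissue-specific genes, per tissue and population.

    Returns a long table (tissue, population, gene_id, frequency) over the
    genes covered by the PAV matrix, and a per-(tissue, population) summary
    with quartiles, mean and the count of specific genes missing from the
    matrix.
    """
    from .analytics import gene_frequency

    pops = list(populations) if populations is not None else pav.population_labels()
    freq_by_pop = {p: gene_frequency(pav, p) for p in pops}
    long_rows = []
    summary_rows = []
    for tissue, genes in specific.items():
        covered = [g for g in genes if g in set(pav.gene_ids)]
        n_uncovered = len(genes) - len(covered)
        for p in pops:
            freqs = [freq_by_pop[p][g] for g in covered]
            for g, f in zip(covered, freqs):
                long_rows.append(
                    {"tissue": tissue, "population": p, "gene_id": g, "frequency": f}
                )
            arr = np.array(freqs, dtype=float)
            summary_rows.append(
                {
                    "tissue": tissue,
                    "population": p,
                    "n_genes": len(covered),
                    "n_uncovered": n_uncovered,
                    "q25": float(np.quantile(arr, 0.25)) if arr.size else np.nan,
                    "median": float(np.quantile(arr, 0.5)) if arr.size else np.nan,
                    "q75": float(np.quantile(arr, 0.75)) if arr.size else np.nan,
                    "mean": float(arr.mean()) if arr.size else np.nan,
                }
            )
    return pd.DataFrame(long_rows), pd.DataFrame(summary_rows)
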