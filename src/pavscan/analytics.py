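"""Pan-genome analytics on a PAV matrix.

Gene-frequency summaries, core/softcore/shell/cloud classification,
pan/core rarefaction curves, PAV distance matrices, an internal
neighbor-joining tree, and export of the binary matrix as an alignment for
external maximum-likelihood tree software.

Classification intervals (carrier frequency f over the chosen denominator):

* ``core``      f = 1 exactly (present in 100% of individuals)
* ``softcore``  0.99 <= f < 1
* ``shell``     0.01 <= f < 0.99
* ``cloud``     0 < f < 0.01
* ``absent``    f = 0 (absent from every sample; reported separately so the
  five buckets always partition the gene set)

Boundaries are evaluated on integer presence counts, so e.g. 199/200 is
softcore and 2/200 (= 0.01) is shell.
"""

from __future__ import annotations

import io
import os
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix
from skbio.tree import nj

from .calling import PAVMatrix

__all__ = [
    "gene_frequency",
    "classify_genes",
    "rarefaction",
    "pav_distance",
    "neighbor_joining",
    "export_binary_alignment",
    "read_binary_alignment",
]

CATEGORIES = ("core", "softcore", "shell", "cloud", "absent")


def gene_frequency(pav: PAVMatrix, population: str | None = None) -> dict[str, float]:
    """Per-gene presence frequency, over all samples or one population."""
    idx = pav.sample_indices(population)
    counts = pav.calls[:, idx].sum(axis=1)
    n = idx.size
    return {g: c / n for g, c in zip(pav.gene_ids, counts.tolist())}


def _categorise(count: int, n: int) -> str:
    # integer arithmetic avoids float-boundary surprises at f = 0.99 / 0.01
    if count == n:
        return "core"
    if 100 * count >= 99 * n:
        return "softcore"
    if count == 0:
        return "absent"
    if 100 * count < n:
        return "cloud"
    return "shell"


def classify_genes(pav: PAVMatrix, population: str | None = None) -> pd.DataFrame:
    """Classify every gene by carrier frequency.

    Returns a DataFrame with columns ``gene_id, frequency, category``; the
    category counts always partition the gene total.
    """
    idx = pav.sample_indices(population)
    n = idx.size
    counts = pav.calls[:, idx].sum(axis=1)
    return pd.DataFrame(
        {
            "gene_id": pav.gene_ids,
            "frequency": counts / n,
            "category": [_categorise(int(c), n) for c in counts],
        }
    )


def rarefaction(
    pav: PAVMatrix, replicates: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Pan/core gene-count rarefaction by repeated random subsampling.

    For each sample size k in 1..N, draws ``replicates`` subsets of k samples
    without replacement; *pan* counts genes present in at least one sampled
    sample and *core* genes present in all of them. Means and standard
    deviations (ddof=1; 0 when replicates == 1) are reported per k. At k = N
    every draw is the full cohort, so sd = 0 and the values equal the
    full-cohort pan and core counts.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    n = pav.n_samples
    calls = pav.calls
    root = np.random.SeedSequence(seed)
    rows = []
    for k, child in zip(range(1, n + 1), root.spawn(n)):
        rng = np.random.default_rng(child)
        pan = np.empty(replicates, dtype=np.int64)
        core = np.empty(replicates, dtype=np.int64)
        for r in range(replicates):
            cols = rng.choice(n, size=k, replace=False)
            sub = calls[:, cols]
            pan[r] = int((sub.any(axis=1)).sum())
            core[r] = int((sub.all(axis=1)).sum())
        ddof = 1 if replicates > 1 else 0
        rows.append(
            {
                "k": k,
                "pan_mean": float(pan.mean()),
                "pan_sd": float(pan.std(ddof=ddof)),
                "core_mean": float(core.mean()),
                "core_sd": float(core.std(ddof=ddof)),
                "replicates": replicates,
            }
        )
    return pd.DataFrame(rows)


def pav_distance(pav: PAVMatrix, metric: str = "hamming") -> pd.DataFrame:
    """Pairwise sample distances from the binary PAV profile.

    ``hamming``: fraction of genes with differing calls. ``jaccard``:
    1 - |intersection| / |union| over present-gene sets; two samples with no
    present genes at all are at distance 0 by convention.
    """
    if pav.n_samples < 2:
        raise ValueError("at least 2 samples are required")
    x = pav.calls.astype(np.float64).T  # samples x genes
    if metric == "hamming":
        d = np.abs(x[:, None, :] - x[None, :, :]).mean(axis=2)
    elif metric == "jaccard":
        inter = x @ x.T
        totals = x.sum(axis=1)
        union = totals[:, None] + totals[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - inter / union
        d[union == 0] = 0.0
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=pav.sample_ids, columns=pav.sample_ids)


def neighbor_joining(distances: pd.DataFrame) -> str:
    """Neighbor-joining tree (newick, with branch lengths) from a distance matrix.

    Samples are sorted into canonical (lexicographic) order before
    agglomeration, so the topology does not depend on input row order.
    """
    ids = list(distances.index)
    if len(ids) < 3:
        raise ValueError("neighbor joining requires at least 3 samples")
    if list(distances.columns) != ids:
        raise ValueError("distance matrix rows and columns must match")
    order = sorted(ids)
    d = distances.loc[order, order].to_numpy(dtype=float)
    tree = nj(DistanceMatrix(d, order))
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def _alignment(pav: PAVMatrix) -> MultipleSeqAlignment:
    records = []
    for j, s in enumerate(pav.sample_ids):
        seq = "".join(str(int(v)) for v in pav.calls[:, j])
        records.append(SeqRecord(Seq(seq), id=s, description=""))
    return MultipleSeqAlignment(records)


def export_binary_alignment(
    pav: PAVMatrix, path: str | os.PathLike, fmt: str = "phylip-relaxed"
) -> None:
    """Export the PAV matrix as a 0/1 character alignment.

    One sequence per sample, character order = gene order. Relaxed PHYLIP is
    the default because sample ids routinely exceed the strict 10-character
    limit; FASTA is available via ``fmt="fasta"``.
    """
    if fmt not in ("phylip-relaxed", "fasta"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    AlignIO.write(_alignment(pav), str(path), fmt)


def read_binary_alignment(path: str | os.PathLike, fmt: str = "phylip-relaxed") -> pd.DataFrame:
    """Read a 0/1 alignment back into a samples x genes DataFrame of ints."""
    aln = AlignIO.read(str(path), fmt)
    return pd.DataFrame(
        [[int(c) for c in str(rec.seq)] for rec in aln],
        index=[rec.id for rec in aln],
    )
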