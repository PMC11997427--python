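"""Gene-frequency selection scan and gene-set enrichment.

Contrasts per-gene presence frequencies between two populations with a
two-sided Fisher's exact test on the 2x2 presence/absence table, adjusts
p-values with Benjamini-Hochberg, and flags genes under selection when
q < 0.001 and the frequency fold difference exceeds 2 (both strict). Term
enrichment of gene sets uses an upper-tail hypergeometric test.

Conventions where the rule leaves room:

* The two-sided Fisher p sums the probabilities of all tables (fixed margins)
  no more likely than the observed one (minimum-likelihood convention).
* Fold with one zero frequency is +infinity, which qualifies as > 2 only when
  the nonzero side has at least 2 carriers; single-carrier genes are reported
  with ``low_support=True`` and are never flagged.
* Genes absent from both contrasted populations are untestable: excluded from
  the BH family (shrinking m) but still reported with NaN p/q.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calling import PAVMatrix

__all__ = [
    "fisher_exact_two_sided",
    "bh_adjust",
    "frequency_scan",
    "hypergeometric_enrichment",
]


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]]."""
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("table cells must be non-negative")
    if sum(cells) == 0:
        raise ValueError("all-zero table has no defined test")
    p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    return float(min(p, 1.0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def frequency_scan(
    pav: PAVMatrix,
    pop_a: str,
    pop_b: str,
    p_adj_threshold: float = 1e-3,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-gene presence-frequency contrast between two populations.

    Returns one row per gene with counts, frequencies, fold difference,
    Fisher p, BH q, and a direction call: ``high_in_A`` / ``low_in_A`` when
    q < ``p_adj_threshold`` and fold > ``fold_threshold`` (both strict),
    otherwise ``none``.
    """
    if pop_a == pop_b:
        raise ValueError("the two populations must differ")
    ia = pav.sample_indices(pop_a)
    ib = pav.sample_indices(pop_b)
    if ia.size < 2 or ib.size < 2:
        raise ValueError("each population needs at least 2 samples")
    if set(ia) & set(ib):
        raise ValueError("populations share samples")
    n_a, n_b = int(ia.size), int(ib.size)
    pres_a = pav.calls[:, ia].sum(axis=1).astype(int)
    pres_b = pav.calls[:, ib].sum(axis=1).astype(int)

    freq_a = pres_a / n_a
    freq_b = pres_b / n_b
    tested = (pres_a + pres_b) > 0

    # identical count pairs share a p-value; cache to avoid redundant tests
    cache: dict[tuple[int, int], float] = {}
    p = np.full(pav.n_genes, np.nan)
    for i in np.flatnonzero(tested):
        key = (int(pres_a[i]), int(pres_b[i]))
        if key not in cache:
            cache[key] = fisher_exact_two_sided(
                key[0], n_a - key[0], key[1], n_b - key[1]
            )
        p[i] = cache[key]
    q = np.full(pav.n_genes, np.nan)
    if tested.any():
        q[tested] = bh_adjust(p[tested])

    hi = np.maximum(freq_a, freq_b)
    lo = np.minimum(freq_a, freq_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(lo > 0, hi / lo, np.inf)
    fold[~tested] = np.nan

    hi_count = np.maximum(pres_a, pres_b)
    low_support = tested & (lo == 0) & (hi_count < 2)
    fold_ok = tested & (fold > fold_threshold) & ~low_support
    sig = tested & (q < p_adj_threshold) & fold_ok
    direction = np.where(
        sig & (freq_a > freq_b), "high_in_A", np.where(sig & (freq_b > freq_a), "low_in_A", "none")
    )

    return pd.DataFrame(
        {
            "gene_id": pav.gene_ids,
            "count_present_A": pres_a,
            "count_absent_A": n_a - pres_a,
            "count_present_B": pres_b,
            "count_absent_B": n_b - pres_b,
            "freq_A": freq_a,
            "freq_B": freq_b,
            "fold": fold,
            "p_value": p,
            "q_value": q,
            "direction": direction,
            "low_support": low_support,
            "tested": tested,
        }
    )


def hypergeometric_enrichment(
    gene_set: Iterable[str],
    universe: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric term enrichment of a gene set.

    For each term, p = P(X >= hits) with population size = |universe|,
    successes = term genes in the universe, draws = |gene_set|. Terms with no
    universe genes are skipped; q is BH across tested terms; rows are sorted
    by (q, p, term).
    """
    universe_set = set(universe)
    genes = set(gene_set)
    if not genes <= universe_set:
        raise ValueError("gene_set must be a subset of the universe")
    if not genes:
        return pd.DataFrame(
            columns=[
                "term_id", "term_size_in_universe", "hits_in_set", "set_size",
                "universe_size", "p_value", "q_value", "significant",
            ]
        )
    m, n_draw = len(universe_set), len(genes)
    rows = []
    for term, term_genes in annotation.items():
        tg = set(term_genes) & universe_set
        if not tg:
            continue
        hits = len(tg & genes)
        p = float(stats.hypergeom.sf(hits - 1, m, len(tg), n_draw))
        rows.append(
            {
                "term_id": term,
                "term_size_in_universe": len(tg),
                "hits_in_set": hits,
                "set_size": n_draw,
                "universe_size": m,
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df["q_value"] = []
        df["significant"] = []
        return df
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    df["significant"] = df["q_value"] < q_threshold
    return df.sort_values(["q_value", "p_value", "term_id"], kind="stable").reset_index(drop=True)
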