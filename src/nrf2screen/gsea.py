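"""Signal-to-noise ranked gene-set enrichment with a gene-permutation null.

The per-gene ranking statistic is the signal-to-noise ratio between two
sample groups: (mean_a - mean_b) / (sd_a* + sd_b*), with each sd floored at
20% of the group mean's magnitude (0.2 when the mean is zero) so that genes
with tiny within-group spread do not dominate the ranking.

The enrichment score (ES) is the signed maximum deviation of the weighted
running-sum statistic over the ranked list: genes in the set increment the
sum by |score|^p (normalized over set members), genes outside decrement by
1/(N - n_hits).  Significance comes from a gene-permutation null — random
same-size gene sets drawn from the ranked universe — with the normalized
enrichment score (NES) scaling ES by the mean same-sign null |ES|, as in the
original GSEA convention.  The permutation p-value is a plain Monte-Carlo
estimate with the +1 correction; its floor is 1/(n_perm + 1).  Nulls are
shared across sets of the same size for a given seed, so duplicated sets
receive identical statistics.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cohort_io import GeneSetCollection

logger = logging.getLogger("nrf2screen")


@dataclass
class RankedList:
    """Gene symbols with scores, strictly ordered (score desc, symbol asc)."""

    genes: np.ndarray  # str array
    scores: np.ndarray  # float, aligned with genes
    group_labels: tuple[str, str] = ("group_a", "group_b")

    @classmethod
    def from_scores(
        cls, scores: pd.Series, group_labels: tuple[str, str] = ("group_a", "group_b")
    ) -> "RankedList":
        if scores.index.has_duplicates:
            raise ValueError("duplicate genes in ranked list")
        df = pd.DataFrame({"gene": scores.index.astype(str), "score": scores.values})
        df = df.sort_values(
            ["score", "gene"], ascending=[False, True], kind="mergesort"
        )
        return cls(
            genes=df["gene"].to_numpy(),
            scores=df["score"].to_numpy(dtype=float),
            group_labels=group_labels,
        )

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GseaSetResult:
    """Enrichment statistics for one gene set against one ranked list."""

    set_name: str
    size: int  # after intersection with the ranked universe
    es: float
    nes: float  # NaN when no same-sign null exists (flagged)
    p: float
    padj: float
    leading_edge: list[str] = field(default_factory=list)
    flag: str = ""


def signal_to_noise(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Signal-to-noise ratio with the GSEA sd floor convention."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >=2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values")
    mu_a, mu_b = a.mean(), b.mean()
    sd_a = _floored_sd(a.std(ddof=1), mu_a)
    sd_b = _floored_sd(b.std(ddof=1), mu_b)
    return float((mu_a - mu_b) / (sd_a + sd_b))


def _floored_sd(sd: float, mu: float) -> float:
    floor = 0.2 * abs(mu) if mu != 0 else 0.2
    return max(sd, floor)


def rank_by_signal_to_noise(
    values: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
) -> RankedList:
    """Per-gene signal-to-noise scores (group A minus group B), ranked."""
    a = values[list(group_a)].to_numpy()
    b = values[list(group_b)].to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >=2 samples")
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = np.maximum(a.std(axis=1, ddof=1), np.where(mu_a != 0, 0.2 * np.abs(mu_a), 0.2))
    sd_b = np.maximum(b.std(axis=1, ddof=1), np.where(mu_b != 0, 0.2 * np.abs(mu_b), 0.2))
    s2n = (mu_a - mu_b) / (sd_a + sd_b)
    return RankedList.from_scores(
        pd.Series(s2n, index=values.index), group_labels=("mutant", "control")
    )


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------

def enrichment_score(
    ranked: RankedList,
    gene_set: list[str] | set[str],
    weight_p: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted running-sum ES with its full profile and leading edge.

    Returns (ES, running profile of length N, leading-edge genes).  The
    leading edge is the set members at or before the extremum for positive
    ES, at or after it for negative ES.  When the positive and negative
    extrema of the profile tie in magnitude exactly, the positive one is
    taken (deterministic tie-break).
    """
    n = len(ranked)
    in_set = np.isin(ranked.genes, list(gene_set))
    n_hits = int(in_set.sum())
    if n_hits == 0:
        raise ValueError("gene set disjoint from the ranked universe")
    if n_hits == n:
        raise ValueError("gene set equals the ranked universe")
    w = np.abs(ranked.scores) ** weight_p
    hit_w = np.where(in_set, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit scores zero: fall back to equal steps
        hit_w = in_set.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~in_set) / (n - n_hits)
    profile = np.cumsum(steps)
    i_max = int(np.argmax(profile))
    i_min = int(np.argmin(profile))
    # positive extremum wins ties, with a small tolerance so float summation
    # order cannot flip the sign on symmetric profiles
    es = profile[i_max] if profile[i_max] >= -profile[i_min] - 1e-12 else profile[i_min]
    if es >= 0:
        leading = list(ranked.genes[: i_max + 1][in_set[: i_max + 1]])
    else:
        leading = list(ranked.genes[i_min:][in_set[i_min:]])
    return float(es), profile, leading


def _null_es(
    scores: np.ndarray,
    set_size: int,
    n_perm: int,
    rng: np.random.Generator,
    weight_p: float = 1.0,
) -> np.ndarray:
    """ES of ``n_perm`` uniform random same-size gene sets, vectorized.

    Only hit positions matter: between hits the running sum decreases
    linearly, so its extrema sit immediately after (max) or before (min)
    each hit.
    """
    n = len(scores)
    if set_size >= n:
        raise ValueError("set size must be smaller than the universe")
    w = np.abs(scores) ** weight_p
    # sorted hit positions per permutation, shape (n_perm, k); drawn in
    # chunks (random keys, k smallest) to bound memory at chunk x n floats
    chunk = max(1, min(n_perm, 4_000_000 // max(n, 1)))
    blocks = []
    for start in range(0, n_perm, chunk):
        b = min(chunk, n_perm - start)
        keys = rng.random((b, n))
        blocks.append(np.argpartition(keys, set_size - 1, axis=1)[:, :set_size])
    pos = np.sort(np.concatenate(blocks, axis=0), axis=1)
    hw = w[pos]
    denom = hw.sum(axis=1, keepdims=True)
    zero = denom[:, 0] == 0
    if zero.any():
        hw[zero] = 1.0
        denom = hw.sum(axis=1, keepdims=True)
    cw = np.cumsum(hw, axis=1) / denom
    k = set_size
    m = 1.0 / (n - k)
    idx = np.arange(1, k + 1)
    after = cw - (pos + 1 - idx) * m  # profile just after each hit
    before = np.concatenate(
        [np.zeros((n_perm, 1)), cw[:, :-1]], axis=1
    ) - (pos - (idx - 1)) * m  # just before each hit
    top = after.max(axis=1)
    bottom = before.min(axis=1)
    return np.where(top >= -bottom - 1e-12, top, bottom)


def permutation_null(
    ranked: RankedList,
    set_size: int,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> np.ndarray:
    """Null ES sample from uniform random same-size gene sets."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng([seed, set_size])
    return _null_es(ranked.scores, set_size, n_perm, rng, weight_p)


def gsea_batch(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_perm: int = 10_000,
    seed: int = 0,
    weight_p: float = 1.0,
    min_size: int = 5,
) -> list[GseaSetResult]:
    """ES/NES/permutation-p for every set in a collection, BH-adjusted.

    Sets with fewer than ``min_size`` genes after intersection with the
    ranked universe are skipped with a flag.  The null is shared across
    sets of equal post-intersection size under the given seed.
    """
    if len(collection) == 0:
        raise ValueError("empty collection")
    universe = set(ranked.genes)
    null_cache: dict[int, np.ndarray] = {}
    results: list[GseaSetResult] = []
    for name in collection.names():
        genes = [g for g in collection.genes(name) if g in universe]
        size = len(genes)
        if size < min_size:
            results.append(
                GseaSetResult(
                    set_name=name, size=size, es=np.nan, nes=np.nan,
                    p=np.nan, padj=np.nan, flag="undersized",
                )
            )
            continue
        if size == len(universe):
            results.append(
                GseaSetResult(
                    set_name=name, size=size, es=np.nan, nes=np.nan,
                    p=np.nan, padj=np.nan, flag="set_equals_universe",
                )
            )
            continue
        es, _, leading = enrichment_score(ranked, genes, weight_p)
        if size not in null_cache:
            null_cache[size] = permutation_null(
                ranked, size, n_perm=n_perm, seed=seed, weight_p=weight_p
            )
        null = null_cache[size]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same_sign) == 0:
            results.append(
                GseaSetResult(
                    set_name=name, size=size, es=es, nes=np.nan,
                    p=1.0 / (n_perm + 1), padj=np.nan,
                    leading_edge=leading, flag="no_same_sign_null",
                )
            )
            continue
        p = (1 + int((np.abs(same_sign) >= abs(es)).sum())) / (1 + len(same_sign))
        nes = es / np.mean(np.abs(same_sign))
        results.append(
            GseaSetResult(
                set_name=name, size=size, es=es, nes=float(nes), p=float(p),
                padj=np.nan, leading_edge=leading,
            )
        )
    tested = [r for r in results if not r.flag or r.flag == "no_same_sign_null"]
    if not tested:
        raise ValueError("all sets skipped (undersized or degenerate)")
    scored = [r for r in tested if np.isfinite(r.p)]
    if scored:
        padj = multipletests([r.p for r in scored], method="fdr_bh")[1]
        for r, q in zip(scored, padj):
            r.padj = float(q)
    return results


def results_to_frame(results: list[GseaSetResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "size": [r.size for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p": [r.p for r in results],
            "padj": [r.padj for r in results],
            "flag": [r.flag for r in results],
        }
    )


def volcano_table(
    results_by_collection: dict[str, list[GseaSetResult]],
    highlight_patterns: list[str] | None = None,
) -> pd.DataFrame:
    """Long-format table for volcano plots over one or more collections.

    Rows are sorted by adjusted p then |NES| descending (stable); sets whose
    name matches any highlight regex (e.g. the reactive-oxygen hallmark or
    the NFE2L2 oncogenic signature) are flagged.
    """
    if not results_by_collection or all(
        not v for v in results_by_collection.values()
    ):
        raise ValueError("no results to tabulate")
    patterns = [re.compile(p) for p in (highlight_patterns or [])]
    rows = []
    for coll_name, results in results_by_collection.items():
        for r in results:
            rows.append(
                {
                    "collection": coll_name,
                    "set_name": r.set_name,
                    "nes": r.nes,
                    "padj": r.padj,
                    "flag": r.flag,
                    "highlight": any(p.search(r.set_name) for p in patterns),
                }
            )
    df = pd.DataFrame(rows)
    df["_absnes"] = df["nes"].abs()
    df = df.sort_values(
        ["padj", "_absnes"], ascending=[True, False], kind="mergesort"
    ).drop(columns="_absnes")
    return df.reset_index(drop=True)
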