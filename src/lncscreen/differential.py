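"""Two built-in differential-expression callers and the caller-agnostic
intersection rule.

The final DE list is defined as the genes significant (BH-adjusted q <=
threshold) in *every* supplied caller's output — the intersection operator is
agnostic to where the calls came from. Two native callers are provided so
the operator has independent inputs:

* ``exact_count_test`` — counts are aggregated per group and the exposed
  total is tested against a conditional binomial (success probability =
  exposed library fraction), two-sided by the minimum-likelihood rule.
  Aggregation tests a rate difference, not biological variability: with
  overdispersed replicates its type-I error exceeds the nominal level
  (reported, not hidden; see docs/methods.md).
* ``rate_lrt_test`` — the asymptotic likelihood-ratio (G) test of the same
  two-rate null, chi-square with 1 df. A distinct second count-based caller
  with different small-sample behaviour; shares the exact test's documented
  anti-conservativeness under biological dispersion.
* ``permutation_caller`` — exhaustive label permutation (462 relabelings for
  6 vs 5) of a moderated t on log2(CPM + 1). Distribution-free and robust,
  but per-gene exhaustive p-values have granularity 1/462, so after BH
  adjustment over ~15,000 genes q <= 0.05 is unreachable; the default pools
  the permutation null across genes (SAM-style), refining granularity to
  1/(462 x genes). Even pooled, a per-sample location statistic carries far
  less information than the count aggregates for near-absent genes, so this
  caller is not part of the default intersection (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .expression import CountMatrix, ExpressionMatrix

__all__ = [
    "DECallSet",
    "DEIntersection",
    "exact_count_test",
    "exact_count_test_many",
    "rate_lrt_test",
    "bh_adjust",
    "fold_change",
    "exact_test_caller",
    "rate_lrt_caller",
    "permutation_caller",
    "intersect_calls",
]


@dataclass
class DECallSet:
    """Per-gene calls from one caller: log2 fold change, p and BH q."""

    caller_id: str
    calls: pd.DataFrame  # index gene_id; columns log2fc, p, q

    def significant(self, q_threshold: float = 0.05) -> set[str]:
        return set(self.calls.index[self.calls["q"] <= q_threshold])


@dataclass
class DEIntersection:
    """Genes significant in every supplied call set, with per-caller q."""

    gene_ids: list[str]
    q_values: pd.DataFrame  # genes x callers
    q_threshold: float


def exact_count_test(counts_A, counts_B, lib_A, lib_B) -> float:
    """Two-sided exact test of equal expression rate between two groups.

    Counts and library sizes are summed within groups; under the null the
    exposed total k_A given k = k_A + k_B is Binomial(k, L_A / (L_A + L_B)).
    The two-sided p sums the probabilities of all outcomes no more likely
    than the observed one (minimum-likelihood rule, ties included), capped
    at 1. k = 0 returns p = 1 by convention.
    """
    counts_A = np.atleast_1d(np.asarray(counts_A))
    counts_B = np.atleast_1d(np.asarray(counts_B))
    lib_A = np.atleast_1d(np.asarray(lib_A, dtype=float))
    lib_B = np.atleast_1d(np.asarray(lib_B, dtype=float))
    if len(counts_A) == 0 or len(counts_B) == 0:
        raise ValueError("each group needs at least one sample")
    if (lib_A <= 0).any() or (lib_B <= 0).any():
        raise ValueError("library sizes must be positive")
    kA = int(counts_A.sum())
    kB = int(counts_B.sum())
    return float(
        exact_count_test_many(
            np.array([kA]), np.array([kB]), lib_A.sum(), lib_B.sum()
        )[0]
    )


def exact_count_test_many(kA: np.ndarray, kB: np.ndarray, LA: float, LB: float) -> np.ndarray:
    """Vectorized minimum-likelihood binomial p-values for many genes that
    share the same library totals. Enumerates all k + 1 outcomes per gene."""
    kA = np.asarray(kA, dtype=np.int64)
    kB = np.asarray(kB, dtype=np.int64)
    p0 = LA / (LA + LB)
    k = kA + kB
    out = np.ones(len(k), dtype=float)
    nonzero = k > 0
    if not nonzero.any():
        return out
    kz = k[nonzero]
    kAz = kA[nonzero]
    # flat enumeration of outcomes 0..k per gene
    sizes = kz + 1
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    flat_i = np.arange(offsets[-1]) - np.repeat(offsets[:-1], sizes)
    flat_k = np.repeat(kz, sizes)
    # binomial pmf in log space (much faster than scipy's frozen pmf on
    # millions of outcomes; agrees to ~1e-14 relative)
    log_pmf = (
        gammaln(flat_k + 1)
        - gammaln(flat_i + 1)
        - gammaln(flat_k - flat_i + 1)
        + flat_i * np.log(p0)
        + (flat_k - flat_i) * np.log1p(-p0)
    )
    pmf = np.exp(log_pmf)
    p_obs = pmf[offsets[:-1] + kAz]
    # relative tolerance guards against pmf ties broken by roundoff
    include = pmf <= np.repeat(p_obs, sizes) * (1.0 + 1e-7)
    sums = np.add.reduceat(np.where(include, pmf, 0.0), offsets[:-1])
    out[nonzero] = np.minimum(sums, 1.0)
    return out


def rate_lrt_test(kA: np.ndarray, kB: np.ndarray, LA: float, LB: float) -> np.ndarray:
    """Likelihood-ratio (G) test of equal expression rate on aggregated
    group counts; p from chi-square with 1 df.

    G = 2 [ k_A ln(k_A / E_A) + k_B ln(k_B / E_B) ] with E_A = k L_A /
    (L_A + L_B). Zero counts contribute nothing; k = 0 gives p = 1.
    """
    kA = np.asarray(kA, dtype=float)
    kB = np.asarray(kB, dtype=float)
    if LA <= 0 or LB <= 0:
        raise ValueError("library totals must be positive")
    k = kA + kB
    p0 = LA / (LA + LB)
    with np.errstate(divide="ignore", invalid="ignore"):
        tA = np.where(kA > 0, kA * np.log(kA / (k * p0)), 0.0)
        tB = np.where(kB > 0, kB * np.log(kB / (k * (1 - p0))), 0.0)
    G = 2.0 * (tA + tB)
    return np.where(k == 0, 1.0, stats.chi2.sf(G, 1))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1, monotone
    in p-rank)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(
    expr: ExpressionMatrix,
    gene: str,
    group_a: str,
    group_b: str,
    pseudocount: float = 0.01,
) -> tuple[float, float]:
    """Ratio of group mean CPM (A over B) with a pseudocount, plus log2.

    The pseudocount (default 0.01 CPM) keeps near-absent genes finite; it is
    added to both group means.
    """
    a = expr.samples_in_group(group_a)
    b = expr.samples_in_group(group_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    mean_a = float(expr.values.loc[gene, a].mean())
    mean_b = float(expr.values.loc[gene, b].mean())
    ratio = (mean_a + pseudocount) / (mean_b + pseudocount)
    return ratio, float(np.log2(ratio))


def _group_fold_changes(
    expr: ExpressionMatrix, genes: list[str], group_a: str, group_b: str, pseudocount: float
) -> np.ndarray:
    a = expr.samples_in_group(group_a)
    b = expr.samples_in_group(group_b)
    mean_a = expr.values.loc[genes, a].mean(axis=1).to_numpy()
    mean_b = expr.values.loc[genes, b].mean(axis=1).to_numpy()
    return np.log2((mean_a + pseudocount) / (mean_b + pseudocount))


def _group_aggregates(m: CountMatrix, genes: list[str], group_a: str, group_b: str):
    a = m.samples_in_group(group_a)
    b = m.samples_in_group(group_b)
    kA = m.counts.loc[genes, a].sum(axis=1).to_numpy()
    kB = m.counts.loc[genes, b].sum(axis=1).to_numpy()
    return kA, kB, float(m.library_sizes[a].sum()), float(m.library_sizes[b].sum())


def _call_set(caller_id, genes, p, expr, group_a, group_b, pseudocount) -> DECallSet:
    calls = pd.DataFrame(
        {
            "log2fc": _group_fold_changes(expr, genes, group_a, group_b, pseudocount),
            "p": p,
            "q": bh_adjust(p),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return DECallSet(caller_id, calls)


def exact_test_caller(
    m: CountMatrix,
    expr: ExpressionMatrix,
    genes: list[str],
    group_a: str,
    group_b: str,
    pseudocount: float = 0.01,
) -> DECallSet:
    """DE calls from the aggregate exact conditional-binomial test."""
    kA, kB, LA, LB = _group_aggregates(m, genes, group_a, group_b)
    p = exact_count_test_many(kA, kB, LA, LB)
    return _call_set("exact_binomial", genes, p, expr, group_a, group_b, pseudocount)


def rate_lrt_caller(
    m: CountMatrix,
    expr: ExpressionMatrix,
    genes: list[str],
    group_a: str,
    group_b: str,
    pseudocount: float = 0.01,
) -> DECallSet:
    """DE calls from the aggregate likelihood-ratio (G) test."""
    kA, kB, LA, LB = _group_aggregates(m, genes, group_a, group_b)
    p = rate_lrt_test(kA, kB, LA, LB)
    return _call_set("rate_lrt", genes, p, expr, group_a, group_b, pseudocount)


def _labelings(n_a: int, n_b: int) -> np.ndarray:
    """All distinct assignments of n_a + n_b samples to group A; the first
    row is the identity labeling (observed grouping)."""
    n = n_a + n_b
    combos = list(combinations(range(n), n_a))
    rows = np.zeros((len(combos), n), dtype=float)
    for i, c in enumerate(combos):
        rows[i, list(c)] = 1.0
    return rows


def permutation_caller(
    expr: ExpressionMatrix,
    genes: list[str],
    group_a: str,
    group_b: str,
    pool_null: bool = True,
    pseudocount: float = 0.01,
) -> DECallSet:
    """DE calls from exhaustive label permutation of a moderated t on
    log2(CPM + 1).

    The statistic is the group-mean difference divided by (pooled SE + s0),
    with s0 the median SE over genes at the observed labeling — the usual
    fudge keeping near-zero-variance genes off the top of the null. With
    ``pool_null=True`` (default) a gene's p-value is the fraction of all
    genes x relabelings whose |statistic| reaches its observed value; with
    ``pool_null=False`` only the gene's own relabelings are used
    (granularity 1/462 for 6 vs 5).
    """
    a = expr.samples_in_group(group_a)
    b = expr.samples_in_group(group_b)
    n_a, n_b = len(a), len(b)
    if min(n_a, n_b) < 2:
        raise ValueError("permutation caller needs >= 2 samples per group")
    L = np.log2(expr.values.loc[genes, a + b].to_numpy() + 1.0)
    W = _labelings(n_a, n_b).T  # samples x relabelings
    mean_a = L @ W / n_a
    mean_b = L @ (1.0 - W) / n_b
    # per-labeling within-group variances (clip guards roundoff negatives)
    sq_a = (L**2) @ W / n_a
    sq_b = (L**2) @ (1.0 - W) / n_b
    var_a = np.clip(sq_a - mean_a**2, 0.0, None) * n_a / (n_a - 1)
    var_b = np.clip(sq_b - mean_b**2, 0.0, None) * n_b / (n_b - 1)
    se = np.sqrt(var_a / n_a + var_b / n_b)
    s0 = float(np.median(se[:, 0])) or 1e-8  # degenerate all-constant input
    T = (mean_a - mean_b) / (se + s0)
    obs = np.abs(T[:, 0])
    if pool_null:
        pool = np.sort(np.abs(T).ravel())
        exceed = pool.size - np.searchsorted(pool, obs, side="left")
        p = np.maximum(exceed, 1) / pool.size
    else:
        p = (np.abs(T) >= obs[:, None]).sum(axis=1) / T.shape[1]
    return _call_set("permutation", genes, p, expr, group_a, group_b, pseudocount)


def intersect_calls(call_sets: list[DECallSet], q_threshold: float = 0.05) -> DEIntersection:
    """Genes with q <= threshold in every supplied call set."""
    if not call_sets:
        raise ValueError("need at least one call set")
    universe = set(call_sets[0].calls.index)
    for cs in call_sets[1:]:
        if set(cs.calls.index) != universe:
            raise ValueError("call sets must share a gene universe")
    sig = set.intersection(*(cs.significant(q_threshold) for cs in call_sets))
    genes = sorted(sig)
    q = pd.DataFrame(
        {cs.caller_id: cs.calls.loc[genes, "q"] for cs in call_sets},
        index=pd.Index(genes, name="gene_id"),
    )
    return DEIntersection(gene_ids=genes, q_values=q, q_threshold=q_threshold)
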