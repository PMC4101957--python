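"""Self-contained gene set statistics and the subject-permutation engine.

Three set-level statistics are implemented, all tested by permuting sample
labels (the self-contained null: no gene in the set is associated with the
phenotype):

* O'Brien's OLS statistic ``T_ols`` — standardized sum of per-gene group
  mean differences; one-sided and direction-sensitive (c = 2 only).
* Hotelling's ``T^2`` — two-group multivariate mean-difference statistic
  with a shrinkage-regularised pooled covariance.
* Wilks' lambda — MANOVA statistic for c >= 2 groups,
  ``det(E) / det(E + H)`` with the within-matrix ``E`` built from the same
  shrinkage estimate; small values indicate separation.

``run_gsa`` is the top-level driver: per-set permutation P-values with a
shared permutation stream, BH-FDR and permutation-FWER adjustment across
sets, post hoc pairwise comparisons for c > 2, and per-gene detail for
significant sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .data_model import ExpressionDataset, GeneSetCollection, Phenotype
from .multiplicity import bh_adjust, permutation_fwer
from .shrinkage import shrink_covariance, within_group_residuals

__all__ = [
    "StandardizedData",
    "PermutationResult",
    "GeneLevelStats",
    "GSAResultTable",
    "standardize",
    "ols_statistic",
    "hotelling_t2",
    "wilks_lambda",
    "permutation_pvalue",
    "gene_level_stats",
    "run_gsa",
]


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizedData:
    """Per-gene standardized expression y* = (y - ybar_k) / s_k."""

    values: np.ndarray       # (m, N)
    pooled_sd: np.ndarray    # s_k, pooled within-group SD, denominator N - c
    overall_mean: np.ndarray # ybar_k, grand mean over all N samples


def _group_indices_from_labels(labels: np.ndarray) -> dict[str, np.ndarray]:
    labs = np.asarray([str(x) for x in labels])
    seen: dict[str, None] = {}
    for lab in labs:
        seen.setdefault(lab)
    return {g: np.flatnonzero(labs == g) for g in seen}


def _standardize_values(values: np.ndarray, group_idx: dict[str, np.ndarray]) -> StandardizedData:
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    c = len(group_idx)
    grand = values.mean(axis=1)
    pooled_ss = np.zeros(values.shape[0])
    for idx in group_idx.values():
        sub = values[:, idx]
        pooled_ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    sd = np.sqrt(pooled_ss / (n - c))
    if np.any(sd == 0):
        raise ValueError("zero pooled standard deviation; drop zero-variance genes first")
    std = (values - grand[:, None]) / sd[:, None]
    return StandardizedData(values=std, pooled_sd=sd, overall_mean=grand)


def standardize(data: ExpressionDataset) -> StandardizedData:
    """Standardize each gene by grand mean and pooled within-group SD."""
    if data.phenotype.kind != "categorical":
        raise ValueError("standardization requires a categorical phenotype")
    return _standardize_values(data.values, data.phenotype.group_indices())


# ---------------------------------------------------------------------------
# set-level statistics
# ---------------------------------------------------------------------------

def _ols_from_std(std_values: np.ndarray, set_members, idx1: np.ndarray, idx2: np.ndarray) -> float:
    sub = std_values[np.asarray(set_members, dtype=int)]
    z1 = sub[:, idx1].mean(axis=1)
    z2 = sub[:, idx2].mean(axis=1)
    d = z1 - z2
    n1, n2 = len(idx1), len(idx2)
    resid = np.concatenate(
        [sub[:, idx1] - z1[:, None], sub[:, idx2] - z2[:, None]], axis=1
    )
    s_pooled = (resid @ resid.T) / (n1 + n2 - 2)
    denom = float(s_pooled.sum()) * (1.0 / n1 + 1.0 / n2)
    if denom <= 0:
        raise ValueError("singular covariance: 1'V1 <= 0 in the OLS statistic")
    return float(d.sum() / np.sqrt(denom))


def ols_statistic(std: StandardizedData, set_members, groups: Phenotype) -> float:
    """O'Brien's OLS statistic 1'd / sqrt(1'V1) for two conditions.

    ``d`` is the vector of per-gene differences of standardized group means
    (group 1 minus group 2, order of first appearance), and
    ``V = S_pooled (1/n1 + 1/n2)`` with ``S_pooled`` the pooled within-group
    covariance of the standardized values on the set's genes.  The sign
    reports direction: positive means group 1 higher.
    """
    gi = groups.group_indices()
    if len(gi) != 2:
        raise ValueError("the OLS statistic is defined for exactly 2 conditions")
    idx1, idx2 = gi.values()
    return _ols_from_std(std.values, set_members, idx1, idx2)


def _shrunk_pooled_cov(values: np.ndarray, set_members, group_idx: dict[str, np.ndarray]):
    sub = values[np.asarray(set_members, dtype=int)]
    resid = within_group_residuals(sub, group_idx)
    return shrink_covariance(resid, n_groups=len(group_idx))


def _t2_from_values(values: np.ndarray, set_members, group_idx: dict[str, np.ndarray]) -> float:
    (idx1, idx2) = group_idx.values()
    sub = values[np.asarray(set_members, dtype=int)]
    d = sub[:, idx1].mean(axis=1) - sub[:, idx2].mean(axis=1)
    est = _shrunk_pooled_cov(values, set_members, group_idx)
    n1, n2 = len(idx1), len(idx2)
    try:
        sol = scipy.linalg.solve(est.covariance, d, assume_a="pos")
    except np.linalg.LinAlgError:
        raise ValueError(
            "shrunk pooled covariance is numerically singular; "
            "consider a shrinkage floor for m > N - 2 sets"
        ) from None
    return float(n1 * n2 / (n1 + n2) * d @ sol)


def hotelling_t2(data: ExpressionDataset, set_members) -> float:
    """Hotelling's T^2 = (n1 n2 / N) d' S_p^{-1} d with shrunk pooled S_p."""
    gi = data.phenotype.group_indices()
    if len(gi) != 2:
        raise ValueError("Hotelling's T^2 requires exactly 2 conditions")
    return _t2_from_values(data.values, set_members, gi)


def _wilks_from_values(values: np.ndarray, set_members, group_idx: dict[str, np.ndarray]) -> float:
    sub = values[np.asarray(set_members, dtype=int)]
    m = sub.shape[0]
    c = len(group_idx)
    n = sub.shape[1]
    grand = sub.mean(axis=1)
    H = np.zeros((m, m))
    for idx in group_idx.values():
        diff = sub[:, idx].mean(axis=1) - grand
        H += len(idx) * np.outer(diff, diff)
    est = _shrunk_pooled_cov(values, set_members, group_idx)
    E = (n - c) * est.covariance
    # generalized symmetric-definite problem: eigenvalues of E^{-1} H
    eigvals = scipy.linalg.eigh(H, E, eigvals_only=True)
    if not np.all(np.isfinite(eigvals)):
        raise ValueError("non-finite eigenvalues in Wilks' lambda")
    eigvals = np.clip(eigvals, 0.0, None)
    r = min(m, c - 1)
    top = np.sort(eigvals)[::-1][:r]
    return float(np.prod(1.0 / (1.0 + top)))


def wilks_lambda(data: ExpressionDataset, set_members) -> float:
    """Wilks' lambda = prod 1/(1 + lambda_k) over eigenvalues of E^{-1} H.

    ``H`` is the between-group sum-of-squares-and-products matrix and
    ``E = (N - c) x`` the shrunk pooled within-group covariance, so the
    value equals ``det(E) / det(E + H)``.  Smaller values mean stronger
    separation of the group mean vectors.
    """
    gi = data.phenotype.group_indices()
    if len(gi) < 2:
        raise ValueError("Wilks' lambda requires at least 2 conditions")
    return _wilks_from_values(data.values, set_members, gi)


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed: float
    null_draws: np.ndarray
    pvalue: float
    tail: str
    seed: int | None = None


def _tail_pvalue(observed: float, null_draws: np.ndarray, tail: str, plus_one: bool = False) -> float:
    null_draws = np.asarray(null_draws, dtype=float)
    if tail == "upper":
        count = int(np.sum(null_draws >= observed))
    elif tail == "lower":
        count = int(np.sum(null_draws <= observed))
    elif tail == "two_sided":
        count = int(np.sum(np.abs(null_draws) >= abs(observed)))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    n = len(null_draws)
    if plus_one:
        return (1 + count) / (1 + n)
    return count / n


def permutation_pvalue(
    stat_fn,
    data: ExpressionDataset,
    nb_perm: int,
    tail: str = "upper",
    seed: int | None = None,
    plus_one: bool = False,
    permutations: np.ndarray | None = None,
) -> PermutationResult:
    """Subject-permutation P-value for an arbitrary statistic.

    ``stat_fn(data, labels)`` must return the statistic for the given
    per-sample labels.  Sample labels are permuted uniformly at random
    ``nb_perm`` times and the P-value is the fraction of permuted statistics
    at least as extreme as the observed one (no +1 correction unless
    ``plus_one``; a null that never reaches the observed value yields P = 0).
    A precomputed permutation index matrix can be supplied to share one
    stream across statistics.
    """
    if nb_perm < 1:
        raise ValueError("nb_perm must be at least 1")
    labels = data.phenotype.labels
    n = len(labels)
    if permutations is None:
        rng = np.random.default_rng(seed)
        permutations = np.array([rng.permutation(n) for _ in range(nb_perm)])
    observed = float(stat_fn(data, labels))
    null = np.array([stat_fn(data, labels[perm]) for perm in permutations[:nb_perm]])
    p = _tail_pvalue(observed, null, tail, plus_one)
    return PermutationResult(observed=observed, null_draws=null, pvalue=p, tail=tail, seed=seed)


# ---------------------------------------------------------------------------
# per-gene statistics
# ---------------------------------------------------------------------------

@dataclass
class GeneLevelStats:
    """Per-gene two-sample t (c = 2) or one-way F (c > 2) with ranks."""

    statistic: np.ndarray
    pvalue: np.ndarray
    rank: np.ndarray       # 1..m_total, ascending in the statistic
    kind: str              # "t" | "F"
    gene_ids: list[str] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "statistic": self.statistic,
                "pvalue": self.pvalue,
                "rank": self.rank,
            }
        )


def gene_level_stats(data: ExpressionDataset) -> GeneLevelStats:
    """Pooled-variance t statistics (2 groups) or ANOVA F (> 2 groups)."""
    ph = data.phenotype
    if ph.kind != "categorical":
        raise ValueError("gene-level statistics require a categorical phenotype")
    gi = ph.group_indices()
    c = len(gi)
    n = data.n_samples
    if c == 2:
        idx1, idx2 = gi.values()
        n1, n2 = len(idx1), len(idx2)
        m1 = data.values[:, idx1].mean(axis=1)
        m2 = data.values[:, idx2].mean(axis=1)
        ss = sum(
            ((data.values[:, idx] - data.values[:, idx].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            for idx in (idx1, idx2)
        )
        sp2 = ss / (n - 2)
        stat = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        pval = 2 * scipy.stats.t.sf(np.abs(stat), df=n - 2)
        kind = "t"
    else:
        grand = data.values.mean(axis=1)
        ss_between = np.zeros(data.n_genes)
        ss_within = np.zeros(data.n_genes)
        for idx in gi.values():
            sub = data.values[:, idx]
            gm = sub.mean(axis=1)
            ss_between += len(idx) * (gm - grand) ** 2
            ss_within += ((sub - gm[:, None]) ** 2).sum(axis=1)
        stat = (ss_between / (c - 1)) / (ss_within / (n - c))
        pval = scipy.stats.f.sf(stat, c - 1, n - c)
        kind = "F"
    order = np.argsort(stat, kind="stable")
    rank = np.empty(len(stat), dtype=int)
    rank[order] = np.arange(1, len(stat) + 1)
    return GeneLevelStats(statistic=stat, pvalue=pval, rank=rank, kind=kind, gene_ids=list(data.gene_ids))


# ---------------------------------------------------------------------------
# top-level driver
# ---------------------------------------------------------------------------

@dataclass
class GSAResultTable:
    """Per-set statistics, raw and adjusted P-values, and per-gene detail."""

    table: pd.DataFrame
    gene_stats: GeneLevelStats
    significant_sets: dict[str, pd.DataFrame]
    alpha: float
    nb_perm: int
    n_groups: int
    posthoc: "pd.DataFrame | None" = None

    def write(self, path, per_gene_path=None) -> None:
        self.table.to_csv(path, sep="\t", index=False)
        if per_gene_path is not None:
            frames = []
            for name, df in self.significant_sets.items():
                df = df.copy()
                df.insert(0, "set", name)
                frames.append(df)
            detail = pd.concat(frames) if frames else pd.DataFrame(
                columns=["set", "gene", "statistic", "pvalue", "rank"]
            )
            detail.to_csv(per_gene_path, sep="\t", index=False)


MCP_NAMES = {1: "dunnett", 2: "tukey", 3: "sequential"}


def run_gsa(
    data: ExpressionDataset,
    sets: GeneSetCollection,
    alpha: float = 0.05,
    nb_perm: int = 5000,
    mcp: "int | str | None" = None,
    seed: int | None = None,
    tail: str = "upper",
    plus_one: bool = False,
) -> GSAResultTable:
    """Permutation GSA over a collection of sets with a shared null stream.

    For two conditions, each set gets a one-sided OLS P-value (``tail``
    chooses which direction counts as extreme) and an upper-tail Hotelling
    T^2 P-value.  For more than two conditions each set gets a lower-tail
    Wilks' lambda MANOVA P-value, and sets significant at ``alpha`` are
    followed up with the post hoc scheme ``mcp`` (1 = Dunnett, 2 = Tukey,
    3 = sequential; names accepted).  BH-FDR and single-step permutation
    FWER adjustments are attached per test family.  One permutation index
    matrix, keyed by ``seed``, is reused across every set and statistic, so
    results are reproducible bit-for-bit and adding a set does not perturb
    the others.
    """
    from .posthoc import comparison_pairs, posthoc_test  # circular-safe

    ph = data.phenotype
    if ph.kind != "categorical":
        raise ValueError("run_gsa requires a categorical phenotype (use the RF test for continuous)")
    c = ph.n_groups
    if c > 2 and mcp is None:
        raise ValueError("a multiple-comparison scheme (mcp) is required when c > 2")
    if c == 2 and mcp is not None:
        import warnings

        warnings.warn("mcp is ignored with 2 conditions", stacklevel=2)

    rng = np.random.default_rng(seed)
    n = data.n_samples
    permutations = np.array([rng.permutation(n) for _ in range(nb_perm)])
    labels = ph.labels
    member_lists = [sets.members(j) for j in range(sets.n_sets)]
    gstats = gene_level_stats(data)

    if c == 2:
        def all_stats(labs):
            gi = _group_indices_from_labels(labs)
            std = _standardize_values(data.values, gi)
            idx1, idx2 = gi.values()
            ols = np.array([_ols_from_std(std.values, mem, idx1, idx2) for mem in member_lists])
            t2 = np.array([_t2_from_values(data.values, mem, gi) for mem in member_lists])
            return ols, t2

        obs_ols, obs_t2 = all_stats(labels)
        null_ols = np.empty((nb_perm, sets.n_sets))
        null_t2 = np.empty((nb_perm, sets.n_sets))
        for k, perm in enumerate(permutations):
            null_ols[k], null_t2[k] = all_stats(labels[perm])
        p_ols = np.array(
            [_tail_pvalue(obs_ols[j], null_ols[:, j], tail, plus_one) for j in range(sets.n_sets)]
        )
        p_t2 = np.array(
            [_tail_pvalue(obs_t2[j], null_t2[:, j], "upper", plus_one) for j in range(sets.n_sets)]
        )
        table = pd.DataFrame(
            {
                "set": sets.set_names,
                "size": sets.sizes,
                "ols_stat": obs_ols,
                "ols_p": p_ols,
                "ols_fdr": bh_adjust(p_ols),
                "ols_fwe": permutation_fwer(obs_ols, null_ols, tail=tail),
                "t2_stat": obs_t2,
                "t2_p": p_t2,
                "t2_fdr": bh_adjust(p_t2),
                "t2_fwe": permutation_fwer(obs_t2, null_t2, tail="upper"),
            }
        )
        sig_mask = (p_ols <= alpha) | (p_t2 <= alpha)
        posthoc_table = None
    else:
        def all_stats(labs):
            gi = _group_indices_from_labels(labs)
            return np.array([_wilks_from_values(data.values, mem, gi) for mem in member_lists])

        obs_w = all_stats(labels)
        null_w = np.empty((nb_perm, sets.n_sets))
        for k, perm in enumerate(permutations):
            null_w[k] = all_stats(labels[perm])
        p_w = np.array(
            [_tail_pvalue(obs_w[j], null_w[:, j], "lower", plus_one) for j in range(sets.n_sets)]
        )
        table = pd.DataFrame(
            {
                "set": sets.set_names,
                "size": sets.sizes,
                "wilks_stat": obs_w,
                "manova_p": p_w,
                "manova_fdr": bh_adjust(p_w),
                "manova_fwe": permutation_fwer(obs_w, null_w, tail="lower"),
            }
        )
        sig_mask = p_w <= alpha
        mcp_kind = MCP_NAMES.get(mcp, mcp)
        scheme = comparison_pairs(ph.groups, mcp_kind)
        rows = []
        pair_cols = [f"{b} - {a}" for (b, a) in scheme.pairs]
        for j in np.flatnonzero(sig_mask):
            res = posthoc_test(data, member_lists[j], scheme, nb_perm=nb_perm, seed=_spawn_seed(seed, j))
            rows.append([sets.set_names[j]] + list(res.adjusted_pvalues))
        posthoc_table = pd.DataFrame(rows, columns=["set"] + pair_cols)

    significant = {}
    for j in np.flatnonzero(sig_mask):
        mem = member_lists[j]
        significant[sets.set_names[j]] = pd.DataFrame(
            {
                "gene": [data.gene_ids[i] for i in mem],
                "statistic": gstats.statistic[mem],
                "pvalue": gstats.pvalue[mem],
                "rank": gstats.rank[mem],
            }
        )
    return GSAResultTable(
        table=table,
        gene_stats=gstats,
        significant_sets=significant,
        alpha=alpha,
        nb_perm=nb_perm,
        n_groups=c,
        posthoc=posthoc_table,
    )


def _spawn_seed(seed: int | None, index: int) -> int:
    """Stable child seed for substreams (posthoc per set, etc.)."""
    ss = np.random.SeedSequence(0 if seed is None else seed)
    return int(ss.spawn(index + 1)[index].generate_state(1)[0] % (2**31))
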