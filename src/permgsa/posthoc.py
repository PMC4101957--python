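"""Post hoc multiple comparisons among c > 2 conditions.

When a set's MANOVA is significant, pairwise follow-up identifies which
conditions differ.  Three pair-selection schemes are offered: Dunnett
(every group against the reference, the first group in order of
appearance), Tukey (all pairs), and sequential (each condition against the
previous one).  Each pair is tested with a pairwise Hotelling T^2 on the
two groups' samples (shrunk pooled covariance) and a subject-permutation
raw P restricted to those samples; the family is adjusted single-step by
max-T over the scheme's pairs using a shared permutation stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ExpressionDataset

__all__ = ["ComparisonScheme", "PosthocResult", "comparison_pairs", "posthoc_test"]

_KINDS = {"dunnett": 1, "tukey": 2, "sequential": 3}


@dataclass
class ComparisonScheme:
    kind: str
    pairs: list[tuple[str, str]]  # (group_b, group_a) reported as "b - a"
    reference_group: str | None = None


@dataclass
class PosthocResult:
    scheme: ComparisonScheme
    statistics: np.ndarray
    raw_pvalues: np.ndarray
    adjusted_pvalues: np.ndarray


def comparison_pairs(groups: list[str], mcp) -> ComparisonScheme:
    """Build the pair list for a scheme (1/dunnett, 2/tukey, 3/sequential).

    Group order is order of first appearance in the data; Dunnett compares
    every later group against the first.
    """
    if isinstance(mcp, str):
        kind = mcp.lower()
        if kind not in _KINDS:
            raise ValueError(f"unknown comparison scheme {mcp!r}")
    else:
        names = {v: k for k, v in _KINDS.items()}
        if mcp not in names:
            raise ValueError(f"mcp must be 1 (dunnett), 2 (tukey) or 3 (sequential), got {mcp!r}")
        kind = names[mcp]
    groups = list(map(str, groups))
    c = len(groups)
    if c < 3:
        raise ValueError("post hoc comparisons require at least 3 conditions")
    if kind == "dunnett":
        ref = groups[0]
        pairs = [(g, ref) for g in groups[1:]]
        return ComparisonScheme(kind, pairs, reference_group=ref)
    if kind == "tukey":
        pairs = [(groups[j], groups[i]) for i in range(c) for j in range(i + 1, c)]
        return ComparisonScheme(kind, pairs)
    pairs = [(groups[i + 1], groups[i]) for i in range(c - 1)]
    return ComparisonScheme(kind, pairs)


def posthoc_test(
    data: ExpressionDataset,
    set_members,
    scheme: ComparisonScheme,
    nb_perm: int = 1000,
    seed: int | None = None,
) -> PosthocResult:
    """Pairwise permutation T^2 tests with single-step max-T adjustment.

    Permutations for a pair shuffle labels only within that pair's samples
    (the pairwise null concerns those two groups alone); one stream of
    permutation draws is shared across the family so the max-T adjustment
    is coherent.
    """
    from .gsa import _t2_from_values  # shared statistic kernel

    gi = data.phenotype.group_indices()
    for b, a in scheme.pairs:
        for g in (a, b):
            if g not in gi:
                raise ValueError(f"group {g!r} not present in the data")
            if len(gi[g]) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")

    groups = list(gi)
    n_pairs = len(scheme.pairs)
    observed = np.empty(n_pairs)
    null = np.empty((nb_perm, n_pairs))
    for j, (b, a) in enumerate(scheme.pairs):
        # stream keyed by the pair itself, so a pair's null draws are
        # identical whichever scheme (family) it appears in
        key = (min(groups.index(a), groups.index(b)), max(groups.index(a), groups.index(b)))
        rng = np.random.default_rng(np.random.SeedSequence(0 if seed is None else seed, spawn_key=key))
        cols = np.concatenate([gi[a], gi[b]])
        sub_values = data.values[:, cols]
        na = len(gi[a])
        split = {a: np.arange(na), b: np.arange(na, len(cols))}
        observed[j] = _t2_from_values(sub_values, set_members, split)
        for k in range(nb_perm):
            perm = rng.permutation(len(cols))
            psplit = {a: perm[:na], b: perm[na:]}
            null[k, j] = _t2_from_values(sub_values, set_members, psplit)
    raw = (null >= observed).mean(axis=0)
    max_t = null.max(axis=1)
    adjusted = np.array([np.mean(max_t >= o) for o in observed])
    adjusted = np.maximum(adjusted, raw)
    return PosthocResult(scheme=scheme, statistics=observed, raw_pvalues=raw, adjusted_pvalues=adjusted)
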