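"""Decision support: marginal factor effects and significance-gated trees.

The marginal analysis fits a one-way linear model per design factor and
reports level means with 95% quantile ranges and a compact letter display at
a given significance level. The tree recursively partitions the records: at
each node every factor is tested with a permutation F-test, p-values are
Bonferroni-adjusted across the factors tested at that node
(conditional-inference style), and the most significant factor is split into
the two level groups maximizing the between-group sum of squares. Ordinal
factors split only at order-respecting cutpoints.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TreeNode", "DecisionTree", "marginal_effects", "build_tree", "render_tree", "parse_tree"]

MAX_FACTOR_LEVELS = 12


# --------------------------------------------------------------------------
# marginal one-way analysis


def _pairwise_p(values: pd.Series, levels: list, groups: pd.Series) -> dict:
    """Two-sided p-values for all level pairs from the one-way model
    (pooled residual variance, t reference)."""
    n = len(values)
    k = len(levels)
    means = {lv: values[groups == lv].mean() for lv in levels}
    counts = {lv: int((groups == lv).sum()) for lv in levels}
    sse = sum(
        ((values[groups == lv] - means[lv]) ** 2).sum() for lv in levels
    )
    df = n - k
    if df <= 0 or sse <= 0:
        return {pair: 1.0 for pair in itertools.combinations(levels, 2)}
    mse = sse / df
    out = {}
    for a, b in itertools.combinations(levels, 2):
        se = np.sqrt(mse * (1 / counts[a] + 1 / counts[b]))
        t = (means[a] - means[b]) / se if se > 0 else 0.0
        out[(a, b)] = 2 * stats.t.sf(abs(t), df)
    return out


def _letters(levels_sorted: list, sig: dict) -> dict:
    """Compact letter display: maximal runs of mutually non-significant levels
    (levels ordered by mean) share a letter."""

    def significant(a, b) -> bool:
        return sig.get((a, b), sig.get((b, a), False))

    k = len(levels_sorted)
    intervals = []
    for lo in range(k):
        hi = lo
        while hi + 1 < k and not any(
            significant(levels_sorted[i], levels_sorted[hi + 1])
            for i in range(lo, hi + 1)
        ):
            hi += 1
        intervals.append((lo, hi))
    maximal = [
        iv
        for iv in set(intervals)
        if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in set(intervals))
    ]
    maximal.sort()
    letters = {lv: "" for lv in levels_sorted}
    for letter, (lo, hi) in zip("abcdefghijklmnopqrstuvwxyz", maximal):
        for i in range(lo, hi + 1):
            letters[levels_sorted[i]] += letter
    return letters


def marginal_effects(
    records: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-factor level means, 95% quantiles over scenarios x replicates, and
    significance letters (levels sharing no letter differ at p < alpha)."""
    if records.empty:
        raise ValueError("empty record set (check the filter)")
    rows = []
    for factor in factors:
        levels = sorted(records[factor].unique().tolist())
        if len(levels) < 2:
            raise ValueError(f"factor {factor!r} has fewer than 2 levels")
        pp = _pairwise_p(records[response], levels, records[factor])
        sig = {pair: p < alpha for pair, p in pp.items()}
        order = sorted(levels, key=lambda lv: records.loc[records[factor] == lv, response].mean())
        letters = _letters(order, sig)
        for lv in levels:
            vals = records.loc[records[factor] == lv, response]
            rows.append(
                {
                    "factor": factor,
                    "level": lv,
                    "mean": vals.mean(),
                    "q2.5": vals.quantile(0.025),
                    "q97.5": vals.quantile(0.975),
                    "n": len(vals),
                    "letters": letters[lv],
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# regression tree


@dataclass
class TreeNode:
    n: int
    mean: float
    q_low: float
    q_high: float
    factor: str | None = None
    left_levels: list = field(default_factory=list)
    right_levels: list = field(default_factory=list)
    p_value: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.factor is None


@dataclass
class DecisionTree:
    root: TreeNode
    response: str
    factors: list
    alpha: float
    min_leaf: int

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def n_nodes(self) -> int:
        def walk(node: TreeNode) -> int:
            if node.is_leaf:
                return 1
            return 1 + walk(node.left) + walk(node.right)

        return walk(self.root)


def _f_statistic(y: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = y.size
    sums = np.bincount(codes, weights=y, minlength=k)
    counts = np.bincount(codes, minlength=k)
    nz = counts > 0
    gm = y.mean()
    ssb = float(np.sum(sums[nz] ** 2 / counts[nz]) - n * gm**2)
    sst = float(np.sum(y**2) - n * gm**2)
    ssw = sst - ssb
    k_eff = int(nz.sum())
    if k_eff < 2 or n - k_eff <= 0:
        return 0.0
    if ssw <= 1e-12 * max(sst, 1.0):
        return np.inf if ssb > 0 else 0.0
    return (ssb / (k_eff - 1)) / (ssw / (n - k_eff))


def _perm_p(
    y: np.ndarray, codes: np.ndarray, k: int, n_perm: int, rng: np.random.Generator
) -> float:
    """Permutation p-value of the one-way F statistic (vectorized)."""
    f_obs = _f_statistic(y, codes, k)
    if f_obs == 0.0:
        return 1.0
    Y = rng.permuted(np.broadcast_to(y, (n_perm, y.size)).copy(), axis=1)
    onehot = np.zeros((y.size, k))
    onehot[np.arange(y.size), codes] = 1.0
    counts = onehot.sum(axis=0)
    nz = counts > 0
    sums = Y @ onehot
    n = y.size
    gm = y.mean()
    ssb = (sums[:, nz] ** 2 / counts[nz]).sum(axis=1) - n * gm**2
    sst = float(np.sum(y**2) - n * gm**2)
    ssw = sst - ssb
    k_eff = int(nz.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ssb / (k_eff - 1)) / np.maximum(ssw, 1e-300) / (1.0 / (n - k_eff))
    return float((1 + np.sum(f_perm >= f_obs)) / (1 + n_perm))


def _best_binary_split(
    y: np.ndarray, values: np.ndarray, levels: list
) -> tuple[list, list]:
    """Two level groups maximizing the between-group sum of squares.

    Numeric (ordinal) factors split only at cutpoints in level order;
    categorical factors consider every 2-group partition.
    """
    ordinal = all(isinstance(lv, (int, float, np.integer, np.floating)) for lv in levels)
    if ordinal:
        partitions = [
            (levels[: i + 1], levels[i + 1 :]) for i in range(len(levels) - 1)
        ]
    else:
        partitions = []
        others = levels[1:]
        for r in range(len(others) + 1):
            for combo in itertools.combinations(others, r):
                left = [levels[0], *combo]
                right = [lv for lv in levels if lv not in left]
                if right:
                    partitions.append((left, right))
    best, best_ssb = None, -np.inf
    for left, right in partitions:
        mask = np.isin(values, left)
        n_l, n_r = int(mask.sum()), int((~mask).sum())
        if n_l == 0 or n_r == 0:
            continue
        ssb = n_l * (y[mask].mean() - y.mean()) ** 2 + n_r * (
            y[~mask].mean() - y.mean()
        ) ** 2
        if ssb > best_ssb:
            best, best_ssb = (list(left), list(right)), ssb
    return best


def build_tree(
    records: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    alpha: float = 0.01,
    min_leaf: int = 20,
    n_permutations: int = 1000,
    seed: int = 0,
) -> DecisionTree:
    """Recursive partitioning with a permutation F-test split gate.

    At each node, each factor with >= 2 observed levels is tested; the factor
    with the smallest Bonferroni-adjusted permutation p-value splits the node
    if p_adj < alpha and the node holds at least ``min_leaf`` records.
    """
    for factor in factors:
        n_lv = records[factor].nunique()
        if n_lv > MAX_FACTOR_LEVELS:
            raise ValueError(
                f"factor {factor!r} has {n_lv} levels; design factors are small "
                f"categorical sets (max {MAX_FACTOR_LEVELS})"
            )
    y_all = records[response].to_numpy(dtype=float)

    def grow(idx: np.ndarray, seed_seq: np.random.SeedSequence) -> TreeNode:
        y = y_all[idx]
        node = TreeNode(
            n=idx.size,
            mean=float(y.mean()),
            q_low=float(np.quantile(y, 0.025)),
            q_high=float(np.quantile(y, 0.975)),
        )
        if idx.size < min_leaf or np.ptp(y) == 0:
            return node
        rng = np.random.default_rng(seed_seq)
        best_factor, best_p, best_levels, best_values = None, np.inf, None, None
        n_tested = 0
        for factor in factors:
            values = records[factor].to_numpy()[idx]
            levels = sorted(pd.unique(values).tolist())
            if len(levels) < 2:
                continue
            n_tested += 1
            codes = np.searchsorted(np.array(levels, dtype=object), values) if not all(
                isinstance(lv, (int, float, np.integer, np.floating)) for lv in levels
            ) else np.searchsorted(np.array(levels), values)
            p = _perm_p(y, codes.astype(int), len(levels), n_permutations, rng)
            if p < best_p:
                best_factor, best_p, best_levels, best_values = factor, p, levels, values
        if best_factor is None:
            return node
        p_adj = min(1.0, best_p * n_tested)
        if p_adj >= alpha:
            return node
        split = _best_binary_split(y, best_values, best_levels)
        if split is None:
            return node
        left_levels, right_levels = split
        mask = np.isin(best_values, left_levels)
        node.factor = best_factor
        node.left_levels = left_levels
        node.right_levels = right_levels
        node.p_value = p_adj
        child_seeds = seed_seq.spawn(2)
        node.left = grow(idx[mask], child_seeds[0])
        node.right = grow(idx[~mask], child_seeds[1])
        return node

    root = grow(np.arange(len(records)), np.random.SeedSequence(seed))
    return DecisionTree(
        root=root,
        response=response,
        factors=list(factors),
        alpha=alpha,
        min_leaf=min_leaf,
    )


# --------------------------------------------------------------------------
# rendering and round-tripping


def _node_to_dict(node: TreeNode) -> dict:
    d = {
        "n": node.n,
        "mean": node.mean,
        "q_low": node.q_low,
        "q_high": node.q_high,
    }
    if not node.is_leaf:
        d.update(
            factor=node.factor,
            left_levels=node.left_levels,
            right_levels=node.right_levels,
            p_value=node.p_value,
            left=_node_to_dict(node.left),
            right=_node_to_dict(node.right),
        )
    return d


def _node_from_dict(d: dict) -> TreeNode:
    node = TreeNode(
        n=d["n"], mean=d["mean"], q_low=d["q_low"], q_high=d["q_high"]
    )
    if "factor" in d:
        node.factor = d["factor"]
        node.left_levels = d["left_levels"]
        node.right_levels = d["right_levels"]
        node.p_value = d["p_value"]
        node.left = _node_from_dict(d["left"])
        node.right = _node_from_dict(d["right"])
    return node


def render_tree(tree: DecisionTree) -> tuple[str, str]:
    """Deterministic (text, json) renderings of a tree."""

    lines: list[str] = [
        f"response: {tree.response}  alpha={tree.alpha}  min_leaf={tree.min_leaf}"
    ]

    def walk(node: TreeNode, indent: int, label: str) -> None:
        pad = "  " * indent
        if node.is_leaf:
            lines.append(
                f"{pad}{label}leaf: mean={node.mean:.4f} "
                f"[{node.q_low:.4f}, {node.q_high:.4f}] n={node.n}"
            )
        else:
            lines.append(
                f"{pad}{label}split on {node.factor} (p={node.p_value:.4g}, n={node.n})"
            )
            walk(node.left, indent + 1, f"{node.factor} in {node.left_levels}: ")
            walk(node.right, indent + 1, f"{node.factor} in {node.right_levels}: ")

    walk(tree.root, 0, "")
    payload = {
        "response": tree.response,
        "factors": tree.factors,
        "alpha": tree.alpha,
        "min_leaf": tree.min_leaf,
        "root": _node_to_dict(tree.root),
    }
    return "\n".join(lines), json.dumps(payload, sort_keys=True)


def parse_tree(source: str | Path) -> DecisionTree:
    """Rebuild a tree from its JSON rendering (string or file path)."""
    if isinstance(source, Path):
        text = source.read_text()
    elif source.lstrip().startswith("{"):
        text = source
    else:
        text = Path(source).read_text()
    d = json.loads(text)
    return DecisionTree(
        root=_node_from_dict(d["root"]),
        response=d["response"],
        factors=d["factors"],
        alpha=d["alpha"],
        min_leaf=d["min_leaf"],
    )
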