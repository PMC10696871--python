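"""Regional cell-type scoring (ssGSEA) and gene-list overlap tests."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError
from .transcriptomics import bh_fdr


def ssgsea_score(expression: np.ndarray, in_set: np.ndarray, alpha: float = 0.25) -> float:
    """Single-sample rank-weighted running-sum enrichment score.

    Genes are ranked by expression descending (rank N for the most
    expressed); walking down the ranking, P_in accumulates |rank|^alpha
    mass over in-set genes, P_out uniform mass over out-set genes, and the
    score is the sum of (P_in - P_out) over all positions.
    """
    expression = np.asarray(expression, dtype=float)
    in_set = np.asarray(in_set, dtype=bool)
    n = expression.size
    n_in = int(in_set.sum())
    if n_in < 1:
        raise ConfigError("empty effective gene set")
    if n_in >= n:
        raise ConfigError("gene set covers all genes; out-of-set mass undefined")
    order = np.argsort(-expression, kind="mergesort")
    ranks = np.arange(n, 0, -1, dtype=float)  # rank N first (highest expression)
    members = in_set[order]
    w = np.where(members, ranks**alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~members) / float(n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_region_scores(
    expr: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
    alpha: float = 0.25,
    znormalize: bool = False,
) -> pd.DataFrame:
    """ssGSEA score of each gene set in each region.

    ``expr`` is region x gene.  Sets are intersected with the matrix's
    genes and must retain at least 2 members.  Scores are reported raw
    unless ``znormalize`` (z-score per cell type across regions).
    """
    genes = expr.columns
    masks = {}
    for name, members in gene_sets.items():
        mask = np.asarray(genes.isin(set(members)))
        if mask.sum() < 2:
            raise ConfigError(f"gene set {name!r} overlaps fewer than 2 matrix genes")
        masks[name] = mask
    values = expr.to_numpy(float)
    out = pd.DataFrame(
        {
            name: [ssgsea_score(values[r], mask, alpha=alpha) for r in range(len(expr))]
            for name, mask in masks.items()
        },
        index=expr.index,
    )
    if znormalize:
        out = (out - out.mean()) / out.std(ddof=1)
    return out


def overlap_permutation_test(
    gene_list: Sequence[str],
    gene_set: Sequence[str],
    background: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Permutation p for the overlap of a gene list with a marker set.

    The null redraws |list| genes uniformly from the background and counts
    the overlap with the set; p = (1 + #{null >= observed}) / (n_perm + 1).
    Also reports the exact hypergeometric upper-tail probability for
    reference.
    """
    bg = np.asarray(list(dict.fromkeys(background)))
    gl = set(gene_list)
    gs = set(gene_set)
    if not gl <= set(bg) or not gs <= set(bg):
        raise ConfigError("list and set must be subsets of the background")
    if len(gl) > len(bg):
        raise ConfigError("list larger than background")
    observed = len(gl & gs)
    in_set = np.isin(bg, list(gs))
    rng = np.random.default_rng(seed)
    k = len(gl)
    null = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        null[i] = in_set[rng.choice(len(bg), size=k, replace=False)].sum()
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    p_hyper = float(stats.hypergeom.sf(observed - 1, len(bg), len(gs), k))
    return {
        "overlap": observed,
        "p_perm": float(p),
        "p_hypergeom": p_hyper,
        "n_list": k,
        "n_set": len(gs),
        "n_background": len(bg),
    }


def overlap_table(
    gene_list: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    background: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Overlap test of one gene list against every cell-type set, with BH q
    across cell types."""
    rows = []
    for i, (name, members) in enumerate(gene_sets.items()):
        res = overlap_permutation_test(
            gene_list, members, background, n_perm=n_perm, seed=seed + i
        )
        res["cell_type"] = name
        rows.append(res)
    out = pd.DataFrame(rows).set_index("cell_type")
    out["q"] = bh_fdr(out["p_perm"].to_numpy())
    return out
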