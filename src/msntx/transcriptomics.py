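"""PLS1 imaging-transcriptomics, spatial permutation inference and gene lists.

For a univariate response map the first PLS component has weight vector
proportional to X'y (X standardized per gene), so it is computed in closed
form; inference uses spatial (spin) or naive permutations of the response
and region-bootstrap standard errors for per-gene Z scores.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, DegenerateInputError

Z_THRESHOLD = 5.0


# ---------------------------------------------------------------------------
# PLS1
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PLSResult:
    """First PLS component of region x gene expression against a region map."""

    scores: pd.Series  # PLS1 score per region
    weights: pd.Series  # unit-norm gene weight vector
    explained_variance: float  # R^2 of the response on the scores
    gene_table: pd.DataFrame | None = None  # weight, se, z after bootstrap
    p_perm: float | None = None
    spatial_rho: float | None = None
    p_spin: float | None = None


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if not (sd > 0).all():
        raise DegenerateInputError("a gene column has zero variance across regions")
    return (X - X.mean(axis=0)) / sd


def pls1(X: pd.DataFrame | np.ndarray, y, standardize: bool = True) -> PLSResult:
    """First PLS component: weights ∝ X'y (unit norm), scores = Xw.

    The sign is fixed so that corr(scores, y) >= 0.  Explained variance is
    the squared Pearson correlation between scores and the response.
    """
    if isinstance(X, pd.DataFrame):
        genes = X.columns
        regions = X.index
        Xv = X.to_numpy(float)
    else:
        Xv = np.asarray(X, dtype=float)
        genes = pd.RangeIndex(Xv.shape[1], name="gene")
        regions = pd.RangeIndex(Xv.shape[0], name="region")
    yv = np.asarray(y, dtype=float)
    if yv.shape != (Xv.shape[0],):
        raise ValueError("response must have one value per region of X")
    if yv.std(ddof=1) == 0:
        raise DegenerateInputError("response map has zero variance")
    if standardize:
        Xv = _standardize_columns(Xv)
    yc = yv - yv.mean()
    w = Xv.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise DegenerateInputError("X'y is identically zero")
    w = w / norm
    scores = Xv @ w
    r = np.corrcoef(scores, yv)[0, 1]
    if r < 0:
        w, scores, r = -w, -scores, -r
    return PLSResult(
        scores=pd.Series(scores, index=regions, name="pls1_score"),
        weights=pd.Series(w, index=genes, name="pls1_weight"),
        explained_variance=float(r**2),
    )


# ---------------------------------------------------------------------------
# spin permutations
# ---------------------------------------------------------------------------


def _random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 3, 3) rotation matrices uniform over SO(3) (QR of Gaussians)."""
    a = rng.normal(size=(n, 3, 3))
    q, r = np.linalg.qr(a)
    d = np.sign(np.einsum("nii->ni", r))
    q = q * d[:, None, :]
    det = np.linalg.det(q)
    q[det < 0, :, 0] *= -1.0
    return q


def generate_spins(
    xyz: np.ndarray,
    n_rot: int,
    seed: int = 0,
    hemispheres: np.ndarray | None = None,
) -> np.ndarray:
    """Region permutations induced by random sphere rotations.

    Each rotation is applied to the centroids and every region is relabelled
    by the nearest rotated centroid.  If ``hemispheres`` is given (array of
    'left'/'right'), the left and right blocks are rotated by mirrored
    rotations (x -> -x conjugation) and matched within hemisphere.
    Returns an (n_rot, R) integer array of source indices.
    """
    xyz = np.asarray(xyz, dtype=float)
    rng = np.random.default_rng(seed)
    rots = _random_rotations(n_rot, rng)
    R = len(xyz)
    perms = np.empty((n_rot, R), dtype=int)

    def _fill(idx, block_rots):
        block = xyz[idx]
        rotated = np.einsum("nij,rj->nri", block_rots, block)
        cos = np.einsum("nri,qi->nrq", rotated, block)
        for n in range(n_rot):
            perms[n, idx] = idx[_greedy_assignment(cos[n])]

    if hemispheres is None:
        _fill(np.arange(R), rots)
    else:
        hemispheres = np.asarray(hemispheres)
        mirror = np.diag([-1.0, 1.0, 1.0])
        _fill(np.flatnonzero(hemispheres == "left"), rots)
        idx_r = np.flatnonzero(hemispheres == "right")
        if idx_r.size:
            _fill(idx_r, mirror @ rots @ mirror)
    return perms


def _greedy_assignment(cos: np.ndarray) -> np.ndarray:
    """One-to-one matching of rotated regions to originals.

    perm[i] is the original region whose value region i takes after the
    rotation.  Regions claim their nearest unclaimed original in order of
    decreasing best-match similarity, so the relabelling is a bijection and
    preserves the multiset of map values.
    """
    n = cos.shape[0]
    perm = np.empty(n, dtype=int)
    used = np.zeros(n, dtype=bool)
    for i in np.argsort(-cos.max(axis=1)):
        row = np.where(used, -np.inf, cos[i])
        q = int(row.argmax())
        perm[i] = q
        used[q] = True
    return perm


def spin_test(
    map_a,
    map_b,
    xyz: np.ndarray,
    n_rot: int = 10_000,
    seed: int = 0,
    hemispheres: np.ndarray | None = None,
) -> tuple[float, float]:
    """Spearman correlation of two region maps with a spin-permutation p.

    The null rotates ``map_a``'s regions by uniformly random rotations
    (mirrored across hemispheres when given) and recomputes rho;
    p = (1 + #{|rho_null| >= |rho|}) / (n_rot + 1), two-sided.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share the region index")
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise DegenerateInputError("constant map: spin test undefined")
    rho = stats.spearmanr(a, b).statistic
    perms = generate_spins(xyz, n_rot, seed=seed, hemispheres=hemispheres)
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    null_rho = _pearson_rows(ra[perms], rb)
    p = (1.0 + np.sum(np.abs(null_rho) >= abs(rho))) / (n_rot + 1.0)
    return float(rho), float(p)


def _pearson_rows(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of A with vector b."""
    Ac = A - A.mean(axis=1, keepdims=True)
    bc = b - b.mean()
    denom = np.sqrt((Ac**2).sum(axis=1) * (bc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Ac @ bc) / denom


# ---------------------------------------------------------------------------
# permutation test on the PLS1 explained variance
# ---------------------------------------------------------------------------


def pls_permutation_p(
    X,
    y,
    n_perm: int = 10_000,
    mode: str = "spin",
    xyz: np.ndarray | None = None,
    hemispheres: np.ndarray | None = None,
    seed: int = 0,
) -> float:
    """Permutation p-value for the PLS1 explained variance.

    mode='spin' permutes the response by random sphere rotations
    (requires ``xyz``); mode='shuffle' uses plain permutations.
    p = (1 + #{null EV >= observed EV}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ConfigError("n_perm must be at least 100")
    res = pls1(X, y)
    observed = res.explained_variance
    yv = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    if mode == "spin":
        if xyz is None:
            raise ConfigError("spin mode requires region coordinates")
        perms = generate_spins(xyz, n_perm, seed=seed, hemispheres=hemispheres)
    elif mode == "shuffle":
        perms = np.array([rng.permutation(len(yv)) for _ in range(n_perm)])
    else:
        raise ConfigError(f"unknown mode {mode!r}")
    Xv = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Xs = _standardize_columns(Xv)
    count = 0
    for p in perms:
        yp = yv[p]
        if yp.std(ddof=1) == 0:
            continue
        yc = yp - yp.mean()
        w = Xs.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            continue
        scores = Xs @ (w / nw)
        ev = np.corrcoef(scores, yp)[0, 1] ** 2
        if ev >= observed:
            count += 1
    return float((1.0 + count) / (n_perm + 1.0))


# ---------------------------------------------------------------------------
# bootstrap gene Z scores
# ---------------------------------------------------------------------------


def bootstrap_gene_z(X, y, B: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Region-bootstrap variability of PLS1 gene weights.

    Regions are resampled with replacement B times; each refit weight vector
    is sign-aligned to the original (flipped when its correlation with the
    original weights is negative).  SE is the SD over bootstraps (ddof=1)
    and Z = weight / SE.  Returns a DataFrame indexed by gene with columns
    ``weight, se, z``, sorted by weight descending.  Genes with SE == 0 get
    a signed-infinity Z (with a warning).
    """
    if isinstance(X, pd.DataFrame):
        genes = X.columns
        Xv = X.to_numpy(float)
    else:
        Xv = np.asarray(X, dtype=float)
        genes = pd.RangeIndex(Xv.shape[1], name="gene")
    yv = np.asarray(y, dtype=float)
    R = Xv.shape[0]
    if R < 10:
        raise ValueError("need at least 10 regions to bootstrap")
    base = pls1(Xv, yv)
    w0 = base.weights.to_numpy()

    rng = np.random.default_rng(seed)
    boots = np.empty((B, Xv.shape[1]))
    got = 0
    while got < B:
        idx = rng.integers(0, R, size=R)
        Xb, yb = Xv[idx], yv[idx]
        if yb.std(ddof=1) == 0 or not (Xb.std(axis=0, ddof=1) > 0).all():
            continue  # degenerate resample: redraw
        wb = pls1(Xb, yb).weights.to_numpy()
        if wb @ w0 < 0:
            wb = -wb
        boots[got] = wb
        got += 1
    se = boots.std(axis=0, ddof=1)
    degenerate = se <= 1e-12 * np.maximum(np.abs(w0), 1e-30)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(~degenerate, w0 / np.where(degenerate, 1.0, se), np.sign(w0) * np.inf)
    if degenerate.any():
        warnings.warn("some genes have zero bootstrap SE; Z set to signed infinity")
    out = pd.DataFrame({"weight": w0, "se": se, "z": z}, index=genes)
    return out.sort_values("weight", ascending=False)


def threshold_gene_lists(
    z: pd.Series, threshold: float = Z_THRESHOLD
) -> tuple[list[str], list[str]]:
    """Split genes into (Z > threshold) and (Z < -threshold) lists, each
    sorted by |Z| descending.  The threshold is strict."""
    z = z.dropna()
    pos = z[z > threshold]
    neg = z[z < -threshold]
    return (
        pos.reindex(pos.abs().sort_values(ascending=False).index).index.tolist(),
        neg.reindex(neg.abs().sort_values(ascending=False).index).index.tolist(),
    )


# ---------------------------------------------------------------------------
# ISH gene screen
# ---------------------------------------------------------------------------


def ish_gene_screen(
    expr: pd.DataFrame,
    tmap,
    gene_list,
    xyz: np.ndarray,
    n_rot: int = 1_000,
    rho_threshold: float = 0.35,
    seed: int = 0,
) -> pd.DataFrame:
    """Spatial correlation screen of candidate genes against a t-map.

    For each candidate gene present in ``expr``: Spearman rho with the
    t-map and a spin p-value; q is Benjamini-Hochberg across the screened
    list; significant iff |rho| > ``rho_threshold`` and q < 0.05.
    """
    overlap = [g for g in gene_list if g in expr.columns]
    if not overlap:
        raise ValueError("gene list has no overlap with the expression matrix")
    tv = np.asarray(tmap, dtype=float)
    rows = []
    for i, g in enumerate(overlap):
        rho, p = spin_test(
            expr[g].to_numpy(float), tv, xyz, n_rot=n_rot, seed=seed + i
        )
        rows.append({"gene": g, "rho": rho, "p_spin": p})
    out = pd.DataFrame(rows).set_index("gene")
    out["q"] = bh_fdr(out["p_spin"].to_numpy())
    out["significant"] = (out["rho"].abs() > rho_threshold) & (out["q"] < 0.05)
    return out


# ---------------------------------------------------------------------------
# cross-disorder DGE correlation
# ---------------------------------------------------------------------------


def dge_weight_correlation(
    list_weights: pd.Series,
    background_weights: pd.Series,
    dge: pd.DataFrame,
    direction: str = "upregulated",
    n_perm: int = 10_000,
    min_overlap: int = 5,
    seed: int = 0,
) -> dict:
    """Correlate PLS gene weights with a disorder's differential expression.

    ``list_weights`` holds the weights of the thresholded PLS gene list;
    ``dge`` has columns ``gene`` and ``log2fc``.  The overlap is restricted
    to upregulated (log2fc > 0; or downregulated with log2fc < 0) DGE genes
    present in the list.  The permutation null redraws |overlap| weights
    from the full background weight vector; p is two-sided on |rho|.
    Overlaps below ``min_overlap`` are flagged and get no p-value.
    """
    if direction == "upregulated":
        dysregulated = dge.loc[dge["log2fc"] > 0]
    elif direction == "downregulated":
        dysregulated = dge.loc[dge["log2fc"] < 0]
    else:
        raise ConfigError(f"unknown direction {direction!r}")
    lfc = dysregulated.set_index("gene")["log2fc"]
    overlap = [g for g in list_weights.index if g in lfc.index]
    result = {"overlap_genes": overlap, "n_overlap": len(overlap)}
    if len(overlap) < min_overlap:
        result.update({"rho": None, "p_perm": None, "flag": "insufficient overlap"})
        return result
    w = list_weights.loc[overlap].to_numpy(float)
    f = lfc.loc[overlap].to_numpy(float)
    if np.unique(w).size < 2 or np.unique(f).size < 2:
        result.update({"rho": None, "p_perm": None, "flag": "degenerate overlap values"})
        return result
    rho = stats.spearmanr(w, f).statistic
    rng = np.random.default_rng(seed)
    bg = background_weights.to_numpy(float)
    rf = stats.rankdata(f)
    null = np.empty(n_perm)
    for i in range(n_perm):
        sample = bg[rng.choice(len(bg), size=len(overlap), replace=False)]
        null[i] = _pearson_rows(stats.rankdata(sample)[None, :], rf)[0]
    p = (1.0 + np.sum(np.abs(null) >= abs(rho))) / (n_perm + 1.0)
    result.update({"rho": float(rho), "p_perm": float(p), "flag": None})
    return result


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
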