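"""Morphometric similarity networks (MSN) and regional strength maps.

The MSN of a subject is the region-by-region Pearson correlation matrix of
z-normalized morphometric feature vectors, built without any thresholding.
A region's strength is its mean off-diagonal correlation.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError


def znormalize_features(table: np.ndarray | pd.DataFrame) -> np.ndarray:
    """z-score each feature column across regions (mean 0, SD 1, ddof=1).

    Raises :class:`DegenerateInputError` naming the offending feature if a
    column is constant across regions.
    """
    if isinstance(table, pd.DataFrame):
        names = list(table.columns)
        values = table.to_numpy(float)
    else:
        values = np.asarray(table, dtype=float)
        names = [f"feature_{j}" for j in range(values.shape[1])]
    if values.ndim != 2:
        raise ValueError("expected a 2-D region x feature table")
    sd = values.std(axis=0, ddof=1)
    bad = np.flatnonzero(~(sd > 0))
    if bad.size:
        raise DegenerateInputError(
            f"feature {names[bad[0]]!r} has zero variance across regions"
        )
    return (values - values.mean(axis=0)) / sd


def build_msn(ztable: np.ndarray) -> np.ndarray:
    """Pearson correlations between all pairs of region feature vectors.

    Input is a z-scored region x feature table (>= 2 features).  Entry
    (i, j) correlates region i's and region j's feature vectors over the
    features.  The diagonal is set to exactly 1; no thresholding is applied.
    """
    z = np.asarray(ztable, dtype=float)
    if z.ndim != 2 or z.shape[1] < 2:
        raise ValueError("need a 2-D table with at least 2 features")
    rows = z - z.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rows, axis=1)
    bad = np.flatnonzero(~(norms > 0))
    if bad.size:
        raise DegenerateInputError(
            f"region {bad[0]} has a constant feature vector; correlation undefined"
        )
    net = (rows / norms[:, None]) @ (rows / norms[:, None]).T
    np.clip(net, -1.0, 1.0, out=net)
    np.fill_diagonal(net, 1.0)
    # enforce exact symmetry against floating-point drift
    return (net + net.T) / 2.0


def msn_strength(net: np.ndarray) -> tuple[np.ndarray, float]:
    """Regional strength map and its global mean.

    strength(i) = mean over j != i of net[i, j]; global = mean over regions.
    """
    net = np.asarray(net, dtype=float)
    r = net.shape[0]
    if net.ndim != 2 or net.shape[0] != net.shape[1] or r < 2:
        raise ValueError("need a square matrix with at least 2 regions")
    strength = (net.sum(axis=1) - np.diag(net)) / (r - 1)
    return strength, float(strength.mean())


def cohort_strengths(features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pipeline: features -> MSN -> strength for a whole cohort.

    Parameters
    ----------
    features : (n_subjects, n_regions, n_features) raw feature array.

    Returns
    -------
    strengths : (n_subjects, n_regions) regional strength matrix.
    global_strength : (n_subjects,) per-subject global mean strength.

    Numerically identical (to ~1e-12) to looping znormalize_features /
    build_msn / msn_strength per subject, but batched for Monte-Carlo use.
    """
    f = np.asarray(features, dtype=float)
    if f.ndim != 3:
        raise ValueError("expected (subjects, regions, features)")
    n_sub, n_reg, _ = f.shape
    sd = f.std(axis=1, ddof=1, keepdims=True)
    if not (sd > 0).all():
        raise DegenerateInputError("a feature is constant across regions for some subject")
    z = (f - f.mean(axis=1, keepdims=True)) / sd
    rows = z - z.mean(axis=2, keepdims=True)
    rows /= np.linalg.norm(rows, axis=2, keepdims=True)
    nets = np.einsum("srf,stf->srt", rows, rows)
    strengths = (nets.sum(axis=2) - 1.0) / (n_reg - 1)
    return strengths, strengths.mean(axis=1)


def network_aggregate(
    strengths: np.ndarray | pd.DataFrame, labels: Sequence
) -> pd.DataFrame:
    """Average regional strengths within label groups (Yeo-7 / von Economo).

    ``strengths`` is subject x region; ``labels`` gives one label per
    region.  Returns a subject x network DataFrame of unweighted means.
    """
    if isinstance(strengths, pd.DataFrame):
        values = strengths.to_numpy(float)
        index = strengths.index
    else:
        values = np.atleast_2d(np.asarray(strengths, dtype=float))
        index = pd.RangeIndex(values.shape[0])
    labels = np.asarray(labels)
    if labels.shape[0] != values.shape[1]:
        raise ValueError("one label required per region")
    out = {}
    for lab in pd.unique(labels):
        members = labels == lab
        if not members.any():
            raise ValueError(f"network label {lab!r} has no member regions")
        out[lab] = values[:, members].mean(axis=1)
    return pd.DataFrame(out, index=index)
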