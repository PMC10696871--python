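"""Probe-level expression preprocessing to a region x gene matrix.

Mirrors the standard atlas workflow: background filtering of probes,
collapsing multi-probe genes to the most representative probe, assigning
tissue samples to parcellation regions by distance to the region boundary,
averaging per region, and scaled-robust-sigmoid (SRS) normalization of each
gene across regions.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import DegenerateInputError

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ProbeMatrix:
    """Probe x sample expression with annotation.

    expression: DataFrame probes x samples;
    probe_gene: Series mapping probe id -> gene symbol (one gene per probe);
    above_background: boolean DataFrame, same shape as expression;
    sample_coords: DataFrame samples x (x, y, z) in mm, optional 'donor'.
    """

    expression: pd.DataFrame
    probe_gene: pd.Series
    above_background: pd.DataFrame
    sample_coords: pd.DataFrame

    def __post_init__(self):
        if not self.expression.index.equals(self.above_background.index):
            raise ValueError("expression and flags must share the probe index")
        if not self.expression.columns.equals(self.above_background.columns):
            raise ValueError("expression and flags must share the sample index")


def filter_probes(pm: ProbeMatrix) -> ProbeMatrix:
    """Drop low-intensity probes below background in over 50% of samples.

    A probe is kept iff its fraction of below-background samples is <= 0.5
    (the exclusion rule is strict: strictly more than half below background).
    """
    frac_below = 1.0 - pm.above_background.mean(axis=1)
    keep = frac_below <= 0.5
    if not keep.any():
        logger.warning("all probes removed by the background filter")
    return ProbeMatrix(
        expression=pm.expression.loc[keep],
        probe_gene=pm.probe_gene.loc[keep[keep].index],
        above_background=pm.above_background.loc[keep],
        sample_coords=pm.sample_coords,
    )


def collapse_probes_to_genes(pm: ProbeMatrix) -> pd.DataFrame:
    """Collapse to one probe per gene; returns a gene x sample DataFrame.

    For genes with multiple probes the probe with the highest homogeneity
    score — mean Pearson correlation of its sample profile with the gene's
    other probes — is retained.  Genes whose probes are all constant are
    dropped (logged).
    """
    rows = {}
    for gene, probe_ids in pm.probe_gene.groupby(pm.probe_gene).groups.items():
        sub = pm.expression.loc[probe_ids].to_numpy(float)
        sds = sub.std(axis=1)
        if not (sds > 0).any():
            logger.warning("gene %s dropped: all probes constant", gene)
            continue
        if len(probe_ids) == 1:
            rows[gene] = sub[0]
            continue
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub)
        np.fill_diagonal(corr, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            homogeneity = np.nanmean(corr, axis=1)
        homogeneity[~np.isfinite(homogeneity)] = -np.inf
        homogeneity[~(sds > 0)] = -np.inf
        if np.all(np.isinf(homogeneity)):
            # no informative inter-probe correlations: fall back to the
            # most variable non-constant probe
            rows[gene] = sub[int(np.argmax(sds))]
        else:
            rows[gene] = sub[int(np.argmax(homogeneity))]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=pm.expression.columns)
    out.index.name = "gene"
    return out.sort_index()


def assign_samples(
    sample_coords: pd.DataFrame,
    region_centers: np.ndarray,
    region_radius: float | np.ndarray,
    region_ids: np.ndarray | None = None,
    max_dist: float = 2.0,
) -> pd.Series:
    """Assign each sample to the nearest region boundary within ``max_dist``.

    Region geometry is a ball of radius ``region_radius`` around each
    center; the distance of a sample to a region is the Euclidean distance
    to its boundary sphere from outside, ``max(0, ||p - c|| - r)`` (zero
    anywhere inside the region).  Samples farther than ``max_dist`` from
    every boundary are unassigned (value -1).
    """
    pts = sample_coords[["x", "y", "z"]].to_numpy(float)
    centers = np.asarray(region_centers, dtype=float)
    radius = np.broadcast_to(np.asarray(region_radius, dtype=float), (len(centers),))
    if region_ids is None:
        region_ids = np.arange(len(centers))
    d_center = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
    d_boundary = np.maximum(0.0, d_center - radius[None, :])
    nearest = d_boundary.argmin(axis=1)
    ok = d_boundary[np.arange(len(pts)), nearest] <= max_dist
    assigned = np.where(ok, np.asarray(region_ids)[nearest], -1)
    n_un = int((~ok).sum())
    if n_un:
        logger.info("%d/%d samples unassigned (> %.1f mm from any boundary)",
                    n_un, len(pts), max_dist)
    return pd.Series(assigned, index=sample_coords.index, name="region_id")


def srs_normalize(values: np.ndarray) -> np.ndarray:
    """Scaled robust sigmoid: sigmoid((x - median) / (IQR / 1.35)), rescaled
    to span [0, 1] exactly.  IQR uses linear-interpolation quantiles."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    if iqr <= 0:
        raise DegenerateInputError("zero IQR: values too concentrated for SRS")
    # expit is the overflow-safe sigmoid
    s = expit((x - np.median(x)) / (iqr / 1.35))
    return (s - s.min()) / (s.max() - s.min())


def build_region_gene_matrix(
    gene_sample: pd.DataFrame,
    sample_region: pd.Series,
    parcellation: pd.DataFrame,
) -> pd.DataFrame:
    """Aggregate samples to left-hemisphere regions and SRS-normalize.

    Region value = mean over assigned samples; right-hemisphere regions and
    unassigned samples are dropped; each gene is then SRS-normalized across
    regions.  Genes constant across regions are dropped (logged).
    """
    left_ids = set(
        parcellation.loc[parcellation["hemisphere"] == "left", "region_id"].tolist()
    )
    keep = sample_region[sample_region.isin(left_ids)]
    if keep.empty or keep.nunique() < 2:
        raise ValueError("need assigned samples in at least 2 left-hemisphere regions")
    by_region = gene_sample[keep.index].T.groupby(keep).mean()
    by_region.index.name = "region_id"
    out = {}
    for gene in by_region.columns:
        col = by_region[gene].to_numpy(float)
        try:
            out[gene] = srs_normalize(col)
        except DegenerateInputError:
            logger.warning("gene %s dropped: constant across regions", gene)
    return pd.DataFrame(out, index=by_region.index).sort_index()
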