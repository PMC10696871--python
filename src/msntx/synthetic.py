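"""Synthetic cohort, parcellation, expression and gene-resource generators.

Everything here is a pure function of ``(config, seed)``: calling a generator
twice with the same arguments returns identical outputs.  Each generator also
returns (or fills in) a :class:`GroundTruth` record so that downstream
recovery tests can compare estimated quantities against what was planted.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DegenerateInputError

#: canonical morphometric feature names, in column order
FEATURES = (
    "surface_area",
    "cortical_thickness",
    "gray_matter_volume",
    "gaussian_curvature",
    "mean_curvature",
)

#: native-unit affine maps per feature (scale, offset); absorbed by
#: z-normalization downstream but keeps raw tables in plausible units
_FEATURE_SCALE = np.array([180.0, 0.25, 450.0, 0.04, 0.05])
_FEATURE_OFFSET = np.array([900.0, 2.6, 2400.0, 0.12, 0.14])

_CELL_TYPE_NAMES = (
    "astrocytes",
    "endothelial",
    "microglia",
    "oligodendrocytes",
    "opcs",
    "excitatory_neurons",
    "inhibitory_neurons",
)

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclasses.dataclass
class GroundTruth:
    """Record of what a generator planted, for recovery tests.

    ``affected_regions`` maps subtype id (1-based) to ``{region_id: signed
    effect magnitude}``; ``associated_genes`` maps gene symbol to its planted
    loading (signed beta on the standardized target map).
    """

    seed: int
    planted_n_subtypes: int = 0
    affected_regions: dict[int, dict[int, float]] = dataclasses.field(default_factory=dict)
    associated_genes: dict[str, float] = dataclasses.field(default_factory=dict)

    def gene_sign(self, gene: str) -> int:
        beta = self.associated_genes.get(gene, 0.0)
        return int(np.sign(beta))


# ---------------------------------------------------------------------------
# parcellation
# ---------------------------------------------------------------------------


def _hemisphere_lattice(n: int, axis_sign: float) -> np.ndarray:
    """Quasi-uniform Fibonacci lattice of ``n`` unit vectors on the
    hemisphere ``sign(x) == axis_sign``."""
    i = np.arange(n)
    # cos(theta) uniform in (0, 1): polar angle measured from the +-x axis
    cos_t = (i + 0.5) / n
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = i * _GOLDEN_ANGLE
    x = axis_sign * cos_t
    y = sin_t * np.cos(phi)
    z = sin_t * np.sin(phi)
    return np.column_stack([x, y, z])


def _block_labels(n: int, n_labels: int) -> np.ndarray:
    """Assign labels 1..n_labels in contiguous blocks over n items."""
    edges = np.linspace(0, n, n_labels + 1)
    return np.searchsorted(edges, np.arange(n), side="right").clip(1, n_labels)


def make_parcellation(n_regions: int = 308, n_left: int = 152, seed: int = 0) -> pd.DataFrame:
    """Build a synthetic spherical parcellation table.

    Returns a DataFrame with one row per region and columns ``region_id``
    (0..n_regions-1), ``name``, ``hemisphere`` ('left'/'right'), unit-sphere
    centroid coordinates ``x, y, z``, ``yeo7_label`` and ``voneconomo_label``
    (1..7, contiguous blocks within hemisphere) and ``parent_dk``.

    Centroids are laid out on per-hemisphere Fibonacci lattices (left
    hemisphere occupies x < 0) and rotated about the x-axis by a
    seed-dependent angle, so distinct seeds give distinct but equally
    well-spread geometries.
    """
    n_right = n_regions - n_left
    if not (2 <= n_left < n_regions) or n_right < 1:
        raise ConfigError(
            f"need 2 <= n_left < n_regions with both hemispheres non-empty, "
            f"got n_regions={n_regions}, n_left={n_left}"
        )
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * math.pi)
    c, s = math.cos(theta), math.sin(theta)
    rot_x = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])

    rows = []
    for hemi, sign, n_h in (("left", -1.0, n_left), ("right", 1.0, n_right)):
        pts = _hemisphere_lattice(n_h, sign) @ rot_x.T
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        yeo = _block_labels(n_h, 7)
        veco = _block_labels(n_h, 7)
        n_dk = max(1, min(34, n_h // 2))
        dk = _block_labels(n_h, n_dk)
        prefix = "L" if hemi == "left" else "R"
        for k in range(n_h):
            rows.append(
                {
                    "name": f"{prefix}_region_{k:03d}",
                    "hemisphere": hemi,
                    "x": pts[k, 0],
                    "y": pts[k, 1],
                    "z": pts[k, 2],
                    "yeo7_label": int(yeo[k]),
                    "voneconomo_label": int(veco[k]),
                    "parent_dk": f"{prefix}_dk{dk[k]:02d}",
                }
            )
    parc = pd.DataFrame(rows)
    parc.insert(0, "region_id", np.arange(n_regions))
    return parc


def centroids(parcellation: pd.DataFrame) -> np.ndarray:
    """(R, 3) unit-sphere centroid array in region_id order."""
    p = parcellation.sort_values("region_id")
    return p[["x", "y", "z"]].to_numpy(float)


def validate_parcellation(parcellation: pd.DataFrame) -> None:
    """Raise ConfigError if the parcellation violates its invariants."""
    rid = parcellation["region_id"].to_numpy()
    if len(np.unique(rid)) != len(rid) or not np.array_equal(np.sort(rid), np.arange(len(rid))):
        raise ConfigError("region_ids must be unique and contiguous from 0")
    norms = np.linalg.norm(parcellation[["x", "y", "z"]].to_numpy(float), axis=1)
    if not np.allclose(norms, 1.0, atol=1e-9):
        raise ConfigError("centroids must lie on the unit sphere")
    for hemi in ("left", "right"):
        if not (parcellation["hemisphere"] == hemi).any():
            raise ConfigError(f"hemisphere {hemi!r} is empty")


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def default_covariate_config() -> dict:
    return {
        "age_range": (7.0, 17.0),
        "tiv_mean": 1450.0,
        "tiv_sd": 130.0,
        "frac_male": 0.65,
        "age_effect": 0.15,
        "sex_effect": 0.15,
        "tiv_effect": 0.15,
    }


def _normalize_subtype_config(subtype_config: Sequence[Mapping]) -> list[dict]:
    if not subtype_config:
        raise ConfigError("subtype_config must list at least one subtype")
    out = []
    total = 0.0
    for cfg in subtype_config:
        cfg = dict(cfg)
        total += float(cfg["proportion"])
        effects = []
        for eff in cfg.get("effects", []):
            regions = np.asarray(eff["regions"], dtype=int)
            if regions.size == 0:
                raise ConfigError("subtype effect has an empty region set")
            effects.append({"regions": regions, "magnitude": float(eff["magnitude"])})
        cfg["effects"] = effects
        out.append(cfg)
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"subtype proportions must sum to 1, got {total}")
    return out


def simulate_cohort(
    parcellation: pd.DataFrame,
    n_control: int,
    n_patient: int,
    subtype_config: Sequence[Mapping],
    covariate_config: Mapping | None = None,
    noise_sd: float = 0.6,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame, GroundTruth]:
    """Simulate per-subject morphometric tables and subject metadata.

    Parameters
    ----------
    subtype_config:
        Sequence of ``{"proportion": p, "effects": [{"regions": ids,
        "magnitude": m}, ...]}`` dicts; proportions must sum to 1.  A
        positive magnitude pushes the affected regions' feature vectors
        toward the cohort-mean baseline direction (raising downstream MSN
        strength), a negative one pushes away from it.  Magnitudes are in
        units of the baseline feature SD.
    covariate_config:
        Sampling ranges for age/sex/TIV plus effect scales; see
        :func:`default_covariate_config`.  Covariate effects load on
        region-by-feature gradient matrices drawn once per cohort so they
        survive the per-subject z-normalization.

    Returns
    -------
    features : (n_subjects, n_regions, 5) float array in native units,
        subjects ordered controls first then patients.
    meta : DataFrame with subject_id, group, subtype_truth, age, sex
        ('M'/'F'), tiv and PANSS columns (patients only).
    ground_truth : GroundTruth with the planted subtype map.
    """
    cov = dict(default_covariate_config())
    cov.update(covariate_config or {})
    subtypes = _normalize_subtype_config(subtype_config)
    rng = np.random.default_rng(seed)

    R = len(parcellation)
    n_sub = n_control + n_patient

    # baseline: hub gradient h_r along a shared feature direction u, plus
    # region idiosyncrasy; h is smooth over the sphere and left-skewed
    # (most regions sit above its mean), so after per-subject z-scoring the
    # bulk of regions share an alignment direction and MSN strength responds
    # monotonically to a region's projection onto the cohort-mean direction
    u = rng.normal(size=len(FEATURES))
    u /= np.linalg.norm(u)
    xyz = centroids(parcellation)
    gram = np.clip(xyz @ xyz.T, -1.0, 1.0)
    ang = np.arccos(gram)
    cov_h = np.exp(-ang / 0.5) + 1e-8 * np.eye(R)
    smooth = np.linalg.cholesky(cov_h) @ rng.normal(size=R)
    hub_cut = np.quantile(smooth, 0.8)
    h = np.where(smooth < hub_cut, 1.0, -2.0) + 0.15 * smooth
    baseline = np.outer(h, u) + 0.6 * rng.normal(size=(R, len(FEATURES)))
    baseline_sd = float(np.mean(np.std(baseline, axis=0, ddof=1)))
    mean_dir = baseline.mean(axis=0)
    mean_dir = mean_dir / np.linalg.norm(mean_dir)

    # covariate gradients (region x feature), shared across subjects
    g_age = rng.normal(size=(R, len(FEATURES)))
    g_sex = rng.normal(size=(R, len(FEATURES)))
    g_tiv = rng.normal(size=(R, len(FEATURES)))

    lo, hi = cov["age_range"]
    age = rng.uniform(lo, hi, size=n_sub)
    sex = (rng.random(n_sub) > cov["frac_male"]).astype(int)  # 0=M, 1=F
    tiv = rng.normal(cov["tiv_mean"], cov["tiv_sd"], size=n_sub)

    # patient subtype assignment by configured proportions
    props = np.array([c["proportion"] for c in subtypes])
    counts = np.floor(props * n_patient).astype(int)
    for k in np.argsort(-(props * n_patient - counts)):
        if counts.sum() >= n_patient:
            break
        counts[k] += 1
    subtype_of_patient = rng.permutation(np.repeat(np.arange(1, len(subtypes) + 1), counts))

    truth = GroundTruth(seed=seed, planted_n_subtypes=len(subtypes))
    for k, cfg in enumerate(subtypes, start=1):
        reg_eff: dict[int, float] = {}
        for eff in cfg["effects"]:
            bad = set(eff["regions"]) - set(parcellation["region_id"])
            if bad:
                raise ConfigError(f"effect regions not in parcellation: {sorted(bad)}")
            for r in eff["regions"]:
                reg_eff[int(r)] = reg_eff.get(int(r), 0.0) + eff["magnitude"]
        truth.affected_regions[k] = reg_eff

    def _perturb_region(vec: np.ndarray, mag: float) -> np.ndarray:
        """Move a region's feature vector toward (+) / away from (-) the
        cohort-mean direction.

        Positive magnitudes saturate: the aligned component is boosted by
        up to 1.5 baseline SDs while the orthogonal (idiosyncratic) content
        shrinks, so the induced strength gain grows monotonically to the
        correlation ceiling.  Negative magnitudes subtract ``mag`` SDs of
        the aligned component and inflate the idiosyncratic content, which
        monotonically lowers strength.
        """
        d = vec @ mean_dir
        ortho = vec - d * mean_dir
        if mag >= 0:
            boost = 1.5 * baseline_sd * (1.0 - math.exp(-0.4 * mag))
            return (d + boost) * mean_dir + math.exp(-0.3 * mag) * ortho
        return (d + mag * baseline_sd) * mean_dir + (1.0 + 0.15 * abs(mag)) * ortho

    features = np.empty((n_sub, R, len(FEATURES)))
    age_c = (age - age.mean()) / max(age.std(), 1e-12)
    tiv_c = (tiv - tiv.mean()) / max(tiv.std(), 1e-12)
    for s in range(n_sub):
        f = baseline.copy()
        f += cov["age_effect"] * age_c[s] * g_age
        f += cov["sex_effect"] * sex[s] * g_sex
        f += cov["tiv_effect"] * tiv_c[s] * g_tiv
        if s >= n_control:
            k = int(subtype_of_patient[s - n_control])
            for r, mag in truth.affected_regions[k].items():
                f[r] = _perturb_region(f[r], mag)
        f += rng.normal(scale=noise_sd, size=f.shape)
        features[s] = _FEATURE_OFFSET + _FEATURE_SCALE * f

    panss_mu = np.array([60.0, 15.0, 14.0, 32.0])
    panss_sd = np.array([15.0, 5.0, 6.0, 8.0])
    panss = np.full((n_sub, 4), np.nan)
    panss[n_control:] = np.clip(
        panss_mu + panss_sd * rng.normal(size=(n_patient, 4)), 1.0, None
    )

    meta = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n_sub)],
            "group": ["control"] * n_control + ["patient"] * n_patient,
            "subtype_truth": [pd.NA] * n_control + list(subtype_of_patient),
            "age": age,
            "sex": np.where(sex == 0, "M", "F"),
            "tiv": tiv,
            "panss_total": panss[:, 0],
            "panss_positive": panss[:, 1],
            "panss_negative": panss[:, 2],
            "panss_general": panss[:, 3],
        }
    )
    meta["subtype_truth"] = meta["subtype_truth"].astype("Int64")
    return features, meta, truth


def paper_default_config(parcellation: pd.DataFrame, effect: float = 4.5) -> dict:
    """Default study-emulating cohort configuration.

    Cohort sizes mirror the study scale (106 controls, 100 patients split
    53/47 between two subtypes with oppositely signed strength effects on
    disjoint region sets).  ``effect`` scales the planted magnitudes.
    """
    rng = np.random.default_rng(20231205)
    rids = parcellation["region_id"].to_numpy()
    n_aff = max(2, len(rids) // 5)
    picked = rng.choice(rids, size=2 * n_aff, replace=False)
    set_a, set_b = picked[:n_aff], picked[n_aff:]
    # mirrored signed patterns: each subtype shows decreased strength where
    # the other shows increased strength, on two disjoint region sets
    return {
        "n_control": 106,
        "n_patient": 100,
        "subtype_config": [
            {
                "proportion": 0.53,
                "effects": [
                    {"regions": set_a, "magnitude": -effect},
                    {"regions": set_b, "magnitude": +effect},
                ],
            },
            {
                "proportion": 0.47,
                "effects": [
                    {"regions": set_a, "magnitude": +effect},
                    {"regions": set_b, "magnitude": -effect},
                ],
            },
        ],
        "noise_sd": 0.6,
    }


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def angular_distance(xyz: np.ndarray) -> np.ndarray:
    """Pairwise great-circle (angular) distance matrix for unit vectors."""
    return np.arccos(np.clip(xyz @ xyz.T, -1.0, 1.0))


def simulate_expression(
    parcellation_left: pd.DataFrame,
    target_map: np.ndarray,
    n_genes: int = 500,
    frac_pos: float = 0.05,
    frac_neg: float = 0.05,
    spatial_corr_length: float = 0.3,
    noise_sd: float = 1.0,
    beta_scale: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a region x gene expression matrix with planted gradient genes.

    Associated genes follow ``beta_g * standardized(target_map) + field``
    where ``field`` is a zero-mean Gaussian process on the sphere with
    covariance ``noise_sd^2 * exp(-angular distance / spatial_corr_length)``;
    the remaining genes are pure field noise.  ``frac_pos`` / ``frac_neg``
    of genes get positive / negative betas (magnitudes in
    ``[0.5, 1.5] * beta_scale``).
    """
    if frac_pos + frac_neg > 1.0 + 1e-12:
        raise ConfigError("frac_pos + frac_neg must be <= 1")
    target_map = np.asarray(target_map, dtype=float)
    R = len(parcellation_left)
    if target_map.shape != (R,):
        raise ConfigError("target_map must have one value per left-hemisphere region")
    sd = target_map.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("target_map has zero variance")
    t_std = (target_map - target_map.mean()) / sd

    rng = np.random.default_rng(seed)
    xyz = centroids(parcellation_left)
    if spatial_corr_length > 0:
        k = np.exp(-angular_distance(xyz) / spatial_corr_length)
        chol = np.linalg.cholesky(k + 1e-9 * np.eye(R))
    else:
        chol = np.eye(R)

    n_pos = int(round(frac_pos * n_genes))
    n_neg = int(round(frac_neg * n_genes))
    genes = [f"G{i:05d}" for i in range(n_genes)]
    signs = np.zeros(n_genes)
    signs[:n_pos] = 1.0
    signs[n_pos : n_pos + n_neg] = -1.0

    truth = GroundTruth(seed=seed)
    expr = np.empty((R, n_genes))
    for g in range(n_genes):
        field = noise_sd * (chol @ rng.normal(size=R))
        if signs[g] != 0:
            beta = signs[g] * beta_scale * rng.uniform(0.5, 1.5)
            expr[:, g] = beta * t_std + field
            truth.associated_genes[genes[g]] = float(beta)
        else:
            expr[:, g] = field

    df = pd.DataFrame(expr, index=parcellation_left["region_id"].to_numpy(), columns=genes)
    df.index.name = "region_id"
    return df, truth


# ---------------------------------------------------------------------------
# gene resources: cell-type sets, ISH set, DGE tables
# ---------------------------------------------------------------------------


def _weighted_sample_without_replacement(
    rng: np.random.Generator, items: np.ndarray, weights: np.ndarray, size: int
) -> np.ndarray:
    """Efraimidis–Spirakis weighted reservoir draw without replacement."""
    keys = rng.random(len(items)) ** (1.0 / weights)
    return items[np.argsort(-keys)[:size]]


def simulate_gene_resources(
    gene_names: Sequence[str],
    ground_truth: GroundTruth,
    n_cell_types: int = 7,
    set_size: int = 50,
    dge_config: Sequence[Mapping] | None = None,
    enrichment_odds: float = 1.0,
    ish_size: int = 40,
    ish_frac_planted: float = 0.5,
    seed: int = 0,
) -> tuple[dict[str, list[str]], list[str], dict[str, pd.DataFrame]]:
    """Generate cell-type marker sets, an ISH disease-gene set and DGE tables.

    Cell-type sets are drawn without replacement; set ``k`` is enriched for
    planted genes whose loading sign alternates (+, -, +, ...) with odds
    ``enrichment_odds`` (1.0 = unbiased hypergeometric draw).  DGE tables
    follow ``dge_config`` entries ``{"disorder": str, "n_genes": int,
    "frac_planted": float, "slope": float, "noise_sd": float}``: genes that
    overlap the planted set get ``log2fc = slope * loading + noise``.
    """
    genes = np.asarray(list(gene_names))
    if set_size >= len(genes):
        raise ConfigError("set_size must be smaller than the gene pool")
    rng = np.random.default_rng(seed)
    loading = np.array([ground_truth.associated_genes.get(g, 0.0) for g in genes])

    cell_sets: dict[str, list[str]] = {}
    for k in range(n_cell_types):
        name = _CELL_TYPE_NAMES[k % len(_CELL_TYPE_NAMES)]
        if k >= len(_CELL_TYPE_NAMES):
            name = f"{name}_{k // len(_CELL_TYPE_NAMES) + 1}"
        target_sign = 1.0 if k % 2 == 0 else -1.0
        w = np.where(np.sign(loading) == target_sign, enrichment_odds, 1.0)
        members = _weighted_sample_without_replacement(rng, genes, w, set_size)
        cell_sets[name] = sorted(members.tolist())

    planted = np.array([g for g in genes if g in ground_truth.associated_genes])
    n_pl = min(int(round(ish_frac_planted * ish_size)), len(planted))
    others = np.array([g for g in genes if g not in ground_truth.associated_genes])
    ish = np.concatenate(
        [
            rng.choice(planted, size=n_pl, replace=False) if n_pl else planted[:0],
            rng.choice(others, size=ish_size - n_pl, replace=False),
        ]
    )
    ish_set = sorted(ish.tolist())

    dge_tables: dict[str, pd.DataFrame] = {}
    for cfg in dge_config or []:
        n_g = int(cfg["n_genes"])
        frac_pl = float(cfg.get("frac_planted", 0.5))
        slope = float(cfg.get("slope", 1.0))
        nsd = float(cfg.get("noise_sd", 0.1))
        n_pl = min(int(round(frac_pl * n_g)), len(planted))
        chosen = np.concatenate(
            [
                rng.choice(planted, size=n_pl, replace=False) if n_pl else planted[:0],
                rng.choice(others, size=n_g - n_pl, replace=False),
            ]
        )
        lfc = np.empty(n_g)
        for i, g in enumerate(chosen):
            base = ground_truth.associated_genes.get(g)
            if base is not None:
                lfc[i] = slope * base + nsd * rng.normal()
            else:
                lfc[i] = rng.normal(scale=max(nsd, 0.25))
        dge_tables[str(cfg["disorder"])] = pd.DataFrame(
            {"gene": chosen, "log2fc": lfc}
        ).drop_duplicates("gene", ignore_index=True)
    return cell_sets, ish_set, dge_tables
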