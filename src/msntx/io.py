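"""Plain-text readers and writers (tidy TSV, GMT gene sets)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import FEATURES


def write_features_tsv(path, features: np.ndarray, subject_ids, region_ids) -> None:
    """Write a (subjects, regions, features) array as tidy TSV
    (subject_id, region_id, feature, value)."""
    n_sub, n_reg, n_feat = features.shape
    df = pd.DataFrame(
        {
            "subject_id": np.repeat(subject_ids, n_reg * n_feat),
            "region_id": np.tile(np.repeat(region_ids, n_feat), n_sub),
            "feature": np.tile(list(FEATURES[:n_feat]), n_sub * n_reg),
            "value": features.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_features_tsv(path) -> tuple[np.ndarray, list, list]:
    """Read tidy features back into ((subjects, regions, features), subject_ids,
    region_ids); feature order follows the canonical FEATURES order."""
    df = pd.read_csv(path, sep="\t")
    subjects = df["subject_id"].drop_duplicates().tolist()
    regions = sorted(df["region_id"].drop_duplicates().tolist())
    feats = [f for f in FEATURES if f in set(df["feature"])]
    cube = (
        df.pivot_table(
            index=["subject_id", "region_id"], columns="feature", values="value", sort=False
        )
        .reindex(pd.MultiIndex.from_product([subjects, regions]))[list(feats)]
        .to_numpy()
        .reshape(len(subjects), len(regions), len(feats))
    )
    return cube, subjects, regions


def write_gmt(path, gene_sets: Mapping[str, Sequence[str]], description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = list(dict.fromkeys(fields[2:]))
    return sets
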