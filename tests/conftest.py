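import numpy as np
import pytest

from msntx import msn, subtyping, synthetic


@pytest.fixture(scope="session")
def parcellation_small():
    return synthetic.make_parcellation(n_regions=40, n_left=20, seed=1)


@pytest.fixture(scope="session")
def parcellation_left(parcellation_small):
    return parcellation_small[parcellation_small["hemisphere"] == "left"].reset_index(
        drop=True
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """Small two-subtype cohort with strong opposite-sign planted effects."""
    parc = synthetic.make_parcellation(n_regions=64, n_left=32, seed=1)
    set_a = list(range(0, 12))
    set_b = list(range(12, 24))
    cfg = [
        {
            "proportion": 0.5,
            "effects": [
                {"regions": set_a, "magnitude": -5.0},
                {"regions": set_b, "magnitude": +5.0},
            ],
        },
        {
            "proportion": 0.5,
            "effects": [
                {"regions": set_a, "magnitude": +5.0},
                {"regions": set_b, "magnitude": -5.0},
            ],
        },
    ]
    features, meta, truth = synthetic.simulate_cohort(parc, 50, 50, cfg, seed=11)
    strengths, global_strength = msn.cohort_strengths(features)
    return {
        "parcellation": parc,
        "features": features,
        "meta": meta,
        "truth": truth,
        "strengths": strengths,
        "global_strength": global_strength,
        "set_a": set_a,
        "set_b": set_b,
    }


@pytest.fixture(scope="session")
def residualized(planted_cohort):
    X = subtyping.residualize_strengths(
        planted_cohort["strengths"], planted_cohort["meta"]
    )
    y = (planted_cohort["meta"]["group"] == "patient").astype(int).to_numpy()
    truth = (
        planted_cohort["meta"]
        .loc[y == 1, "subtype_truth"]
        .to_numpy()
        .astype(int)
    )
    return X, y, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def expression_with_gradient(parcellation_left):
    """Left-hemisphere expression with planted positive and negative genes."""
    rng = np.random.default_rng(7)
    target = np.sin(np.linspace(0, 3, len(parcellation_left))) + 0.1 * rng.normal(
        size=len(parcellation_left)
    )
    expr, truth = synthetic.simulate_expression(
        parcellation_left,
        target,
        n_genes=120,
        frac_pos=0.1,
        frac_neg=0.1,
        noise_sd=0.4,
        beta_scale=1.5,
        seed=5,
    )
    return expr, truth, target
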