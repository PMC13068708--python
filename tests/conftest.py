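import numpy as np
import pytest

from durdisc import designs, estimation, models, synthetic_data


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_design():
    return designs.ConstantStimuliDesign(
        standard=80.0, c_levels=designs.c_grid(80.0)
    )


@pytest.fixture
def long_design():
    return designs.ConstantStimuliDesign(
        standard=500.0, c_levels=designs.c_grid(500.0)
    )


def simulate_type_b(
    model: str,
    params: dict,
    n_observers: int,
    seed: int,
    standard: float = 80.0,
):
    """Per-observer constant-stimuli Type B effects (delta DL) for a cohort."""
    rng = np.random.default_rng(seed)
    design = designs.ConstantStimuliDesign(
        standard=standard, c_levels=designs.c_grid(standard)
    )
    lo, hi = estimation.default_anchors(standard)
    out = []
    for _ in range(n_observers):
        observer = synthetic_data.make_observer(model, params, standard)
        records = designs.run_constant_stimuli(
            designs.build_design(design, rng), observer, rng, keep_latents=False
        )
        table = estimation.aggregate(records)
        est_sc = estimation.spearman_karber(table, lo, hi, "sc")
        est_cs = estimation.spearman_karber(table, lo, hi, "cs")
        out.append(est_sc.dl - est_cs.dl)
    return np.asarray(out)
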