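import numpy as np
import pytest

import falffmap as fm
from falffmap.io import BrainMask
from falffmap.simulate import _grid_affine, gen_parcellation, gen_reference_map


@pytest.fixture(scope="session")
def small_cohort():
    """A 10+10-subject cohort with a planted amplitude effect on a 12^3 grid."""
    cfg = fm.SimulationConfig(
        grid_dims=(12, 12, 12), n_timepoints=120, n_per_group=10, seed=3
    )
    vols, mask, parc, recs = fm.gen_bold_cohort(cfg)
    return cfg, vols, mask, parc, recs


@pytest.fixture(scope="session")
def small_cohort_maps(small_cohort):
    cfg, vols, mask, parc, recs = small_cohort
    maps = [fm.fisher_z_standardize(fm.falff_map(v, mask)) for v in vols]
    return cfg, maps, mask, parc, recs


@pytest.fixture(scope="session")
def grid_mask():
    dims = (12, 12, 12)
    return BrainMask(data=np.ones(dims, dtype=bool), affine=_grid_affine(dims))


@pytest.fixture(scope="session")
def atlas90(grid_mask):
    return gen_parcellation((12, 12, 12))


@pytest.fixture(scope="session")
def reference_map(grid_mask):
    return gen_reference_map(grid_mask, seed=100)


@pytest.fixture(scope="session")
def expression_setup(grid_mask, atlas90, reference_map):
    """Bundle -> processed matrix -> samples/scores on the smooth reference."""
    cfg = fm.ExpressionSimConfig(n_samples=200, n_genes=400, seed=4)
    bundle, annotations, planted = fm.gen_expression_bundle(cfg, reference_map, grid_mask)
    expr = fm.process_expression(bundle, atlas90)
    samples = fm.extract_values_at_samples(
        reference_map,
        expr.sample_mni[["x", "y", "z"]].to_numpy(),
        sample_ids=list(expr.values.index),
    )
    scores = fm.gene_scores(expr, samples)
    return cfg, bundle, annotations, planted, expr, samples, scores
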