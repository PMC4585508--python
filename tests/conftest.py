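import numpy as np
import pytest

from langmorph import CohortSpec, generate_cohort, relative_cohort_matrix
from langmorph.cohort import EffectBlob, records_to_table


def small_spec(**overrides) -> CohortSpec:
    """A fast two-subgroup cohort on a 12³ grid; override fields as needed."""
    kwargs = dict(
        n_per_group={"ASC_delay": 10, "ASC_nodelay": 10},
        grid_shape=(12, 12, 12),
        voxel_size=(2.0, 2.0, 2.0),
        global_gm_offset=0.0,
        seed=7,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


def prepared_cohort(spec: CohortSpec, tissues=("GM",)):
    """Generate a cohort and return (table, {tissue: relative CohortMatrix}).

    All tissues share the first tissue's template mask so that multi-condition
    analyses operate on a common voxel register.
    """
    records, maps = generate_cohort(spec)
    table = records_to_table(records)
    matrices = {}
    mask = None
    for t in tissues:
        matrices[t] = relative_cohort_matrix(maps[t], t, mask_index=mask)
        mask = matrices[t].mask_index
    return table, matrices


@pytest.fixture(scope="session")
def null_cohort():
    """A signal-free cohort shared by read-only tests."""
    return prepared_cohort(small_spec())


@pytest.fixture(scope="session")
def latent_cohort():
    """A cohort with one embedded latent language factor expressed in GM.

    The spatial pattern is a volume-balanced blob pair (+/−) so the factor
    redistributes regional volume without moving the subject's total GM —
    the structure that survives relative-volume scaling.
    """
    spec = small_spec(
        n_per_group={"ASC_delay": 15, "ASC_nodelay": 15},
        grid_shape=(16, 16, 16),
        latent_loadings={"VIQ": 0.7, "FAS": 0.7, "NWR": 0.7, "ADIR-S": 0.0},
        latent_spatial_pattern=[
            EffectBlob((0.0, 0.0, 0.0), 8.0, 0.08, tissue="GM"),
            EffectBlob((-10.0, 10.0, -8.0), 8.0, -0.08, tissue="GM"),
        ],
        seed=11,
    )
    return spec, prepared_cohort(spec, tissues=("GM", "WM"))
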