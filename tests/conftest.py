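import numpy as np
import pandas as pd
import pytest

from qcpop.data import GenotypeDataset
from qcpop.simulate import PedigreeSpec, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Shared desk-scale cohort with families, artifacts and aneuploidies."""
    cfg = SimConfig(
        n_regions=4,
        samples_per_region=50,
        n_variants=300,
        n_x_variants=120,
        pedigree_spec=PedigreeSpec(trios=1, sib_pairs=2, half_sib_pairs=1,
                                   parent_offspring_pairs=1,
                                   consanguineous_pairs=1, duplicate_pairs=2),
        aneuploidy_counts={"XO": 2, "XO_mosaic": 2, "XXX": 3, "XXY": 2},
        lrld_blocks=[("1", 10_000_000, 12_000_000, 4)],
        plate_effects=[(0, [0, 1, 2], 0.5)],
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def tiny_dataset():
    """Hand-built 4-sample x 6-variant dataset with a missing call."""
    calls = np.array(
        [
            [0, 1, 2, 0, 1, 2],
            [2, 1, 0, 1, 1, 2],
            [1, 1, 1, -1, 0, 2],
            [0, 0, 2, 2, 1, 2],
        ],
        dtype=np.int8,
    )
    variants = pd.DataFrame({
        "id": [f"v{i}" for i in range(6)],
        "chrom": ["1", "1", "1", "2", "2", "X"],
        "pos": [100, 200, 300, 100, 250, 500],
        "allele1": list("AACGTA"),
        "allele2": list("GGTACG"),
    })
    samples = pd.DataFrame({
        "id": ["s1", "s2", "s3", "s4"],
        "sex": ["M", "F", "F", "M"],
        "region": ["north", "north", "south", "south"],
    })
    return GenotypeDataset(calls=calls, variants=variants, samples=samples)
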