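import numpy as np
import pandas as pd
import pytest

from gxepipe import simulate as sim
from gxepipe.datatypes import GenotypeMatrix


@pytest.fixture(scope="session")
def small_study():
    """120 genes x 60 lines x 2 reps x 2 envs with known components."""
    truth = sim.make_truth(120, sigma2_G=1.0, sigma2_GE=0.5, sigma2_e=0.5, seed=10)
    design = sim.StudyDesign(n_lines=60, n_reps=2, seed=11)
    return sim.generate_expression(design, truth), truth


@pytest.fixture(scope="session")
def small_genotypes():
    return sim.generate_genotypes(n_lines=80, n_variants=60, maf_low=0.1,
                                  ld_block_size=1, seed=12)


def make_genotypes(calls_rows, line_names=None, positions=None, chrom="2L"):
    """Hand-built genotype panel from a list of 0/1 rows."""
    arr = np.asarray(calls_rows, dtype=np.int8)
    n_var, n_lines = arr.shape
    lines = line_names or [f"l{i}" for i in range(n_lines)]
    pos = positions or list(range(100, 100 + 10 * n_var, 10))
    vids = [f"v{i}" for i in range(n_var)]
    calls = pd.DataFrame(arr, index=vids, columns=lines)
    variants = pd.DataFrame({"chrom": chrom, "pos": pos}, index=vids)
    return GenotypeMatrix(calls, variants)
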