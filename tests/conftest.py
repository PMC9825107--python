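import numpy as np
import pandas as pd
import pytest

from niptsr.evaluate import run_simulated_case
from niptsr.families import GenotypeSet, Pedigree, Rearrangement, Breakpoint
from niptsr.simulate import SimConfig, simulate_family, simulate_plasma


@pytest.fixture(scope="session")
def default_case():
    """One deeply sequenced simulated case shared across tests.

    Grandparent-referenced maternal reciprocal translocation at the
    desk-scale defaults with the true ff supplied to the model.
    """
    cfg = SimConfig(seed=11, mean_depth=1000, ff=0.2)
    truth, results = run_simulated_case(cfg, ff=0.2)
    return cfg, truth, results


@pytest.fixture(scope="session")
def sibling_case():
    """A sibling-referenced case (both parents phased)."""
    cfg = SimConfig(seed=12, mean_depth=1000, ff=0.2,
                    reference_role="sibling", reference_carrier_status="auto")
    truth, results = run_simulated_case(cfg, ff=0.2)
    return cfg, truth, results


@pytest.fixture
def tiny_rearrangement():
    return Rearrangement(
        kind="reciprocal_translocation",
        breakpoints=(
            Breakpoint("bp1", "chr1", 500, 600),
            Breakpoint("bp2", "chr2", 500, 600),
        ),
        carrier_parent="mother",
    )


def make_genotypes(mother, father, reference, chrom="chr1", spacing=100):
    """GenotypeSet over evenly spaced SNPs on one chromosome."""
    n = len(mother)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(n) * spacing,
            "mother": np.asarray(mother),
            "father": np.asarray(father),
            "reference": np.asarray(reference),
        }
    )
    return GenotypeSet(df)


@pytest.fixture
def grandparent_pedigree():
    return Pedigree("M", "F", "GM", "grandparent", "carrier")


@pytest.fixture
def child_pedigree():
    return Pedigree("M", "F", "C", "child", "carrier")
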