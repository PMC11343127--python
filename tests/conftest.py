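import numpy as np
import pandas as pd
import pytest

from proteoflux.abundance import AbundanceMatrix
from proteoflux.kinetics import PeptideTimeCourse, fraction_new
from proteoflux.synthdata import SynthConfig

PAPER_TIMEPOINTS = (0.0, 0.25, 1.0, 4.0, 16.0, 32.0)


def noiseless_courses(kdeg, n_peptides=3, protein_id="P1", cohort="control",
                      timepoints=PAPER_TIMEPOINTS, n_value=20.0):
    """Exact single-exponential time courses for one protein."""
    return [
        PeptideTimeCourse(
            peptide_sequence=f"PEPTIDEK{i}",
            protein_id=protein_id,
            n_value=n_value,
            observations=[(t, float(fraction_new(kdeg, t))) for t in timepoints],
            cohort=cohort,
        )
        for i in range(n_peptides)
    ]


@pytest.fixture
def small_config():
    """Small but fully featured study configuration for fast end-to-end runs."""
    return SynthConfig(
        seed=11,
        n_proteins=100,
        n_ontologies=10,
        proteins_per_ontology=10,
        peptides_per_protein=3,
    )


@pytest.fixture
def simple_matrix():
    """4+4 replicate area matrix with a clean 2-fold change for P2."""
    rng = np.random.default_rng(5)
    samples = [f"c{i}" for i in range(4)] + [f"e{i}" for i in range(4)]
    genotype_of = {s: ("control" if s.startswith("c") else "experimental")
                   for s in samples}
    base = rng.uniform(1e5, 1e7, size=(10, 1))
    values = pd.DataFrame(
        np.repeat(base, 8, axis=1),
        index=[f"P{i}" for i in range(10)],
        columns=samples,
    )
    values.loc["P2", [s for s in samples if s.startswith("e")]] *= 2.0
    return AbundanceMatrix(values=values, genotype_of=genotype_of)
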