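import numpy as np
import pandas as pd
import pytest

from aeroflux import (
    AbundanceMatrix,
    Compartment,
    Mode,
    SampleDescriptor,
    SizeFraction,
    TaxonInfo,
)


def make_samples(days=(1, 2), compartments=("bulk", "ssml", "aerosol"),
                 size_fraction=SizeFraction.F3000_200):
    out = []
    for d in days:
        for c in compartments:
            sid = f"d{d}_{c}"
            out.append(
                SampleDescriptor(
                    sample_id=sid,
                    day=d,
                    compartment=Compartment(c),
                    size_fraction=size_fraction,
                )
            )
    return out


def make_matrix(values, samples=None, taxa=None, mode=Mode.COUNTS):
    """values: dict sample_id -> column list, or DataFrame."""
    if isinstance(values, dict):
        values = pd.DataFrame(values)
        if taxa is not None:
            values.index = [t.taxon_id if isinstance(t, TaxonInfo) else t for t in taxa]
        else:
            values.index = [f"t{i}" for i in range(len(values))]
    if samples is None:
        samples = [
            SampleDescriptor(sample_id=c, day=i, compartment=Compartment.BULK,
                             size_fraction=SizeFraction.F3000_200)
            for i, c in enumerate(values.columns)
        ]
    taxa_infos = tuple(
        t if isinstance(t, TaxonInfo) else TaxonInfo(taxon_id=str(t))
        for t in (taxa or values.index)
    )
    return AbundanceMatrix(values=values, samples=tuple(samples),
                           taxa=taxa_infos, mode=mode)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def three_compartment_matrix():
    """2 days x 3 compartments, 3 taxa, counts mode."""
    samples = make_samples()
    data = {
        s.sample_id: [10 * (i + 1) + j for j in range(3)]
        for i, s in enumerate(samples)
    }
    return make_matrix(data, samples=samples)
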