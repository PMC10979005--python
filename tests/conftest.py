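import numpy as np
import pandas as pd
import pytest

from forensicstr.markers import (
    AlleleFrequencySpectrum,
    GenotypeTable,
    Linkage,
    MarkerDef,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


def make_table(panel, rows):
    """Build a GenotypeTable from [(sample, sex, pop, {locus: (a, b)})]."""
    panel = tuple(panel)
    recs = []
    for sid, sex, pop, calls in rows:
        rec = {"SampleID": sid, "Sex": sex, "Population": pop}
        for m in panel:
            a, b = calls.get(m.name, (None, None))
            rec[f"{m.name}_1"] = a
            rec[f"{m.name}_2"] = b
        recs.append(rec)
    cols = ["SampleID", "Sex", "Population"]
    for m in panel:
        cols += [f"{m.name}_1", f"{m.name}_2"]
    return GenotypeTable(panel, pd.DataFrame(recs, columns=cols))


def random_freqs(rng, k, concentration=1.0):
    """Dirichlet frequency vector with no zero entries."""
    p = rng.dirichlet(np.full(k, concentration))
    p = np.maximum(p, 1e-6)
    return p / p.sum()


def spectrum_from_freqs(p, n_chrom=10000, locus="SIM"):
    """Turn a frequency vector into an integer-count spectrum close to p."""
    counts = np.maximum(np.round(np.asarray(p) * n_chrom).astype(int), 1)
    labels = [str(8 + i) for i in range(len(counts))]
    return AlleleFrequencySpectrum(locus, dict(zip(labels, counts.tolist())))
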