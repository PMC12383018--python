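import numpy as np
import pandas as pd
import pytest

from stepgen.io import GenotypeSet, TraitTable
from stepgen.pedigree import Pedigree


def make_snp_map(m, chrom="1", spacing=1000):
    return pd.DataFrame({
        "snp": [f"s{j + 1}" for j in range(m)],
        "chrom": str(chrom),
        "pos": np.arange(1, m + 1) * spacing,
    })


def random_pedigree(rng, n_founders=10, n_total=80):
    """Random pedigree with matings among existing animals (loops allowed)."""
    recs = [(f"X{i}", "0", "0") for i in range(n_founders)]
    ids = [f"X{i}" for i in range(n_founders)]
    for i in range(n_founders, n_total):
        s, d = rng.choice(len(ids), 2, replace=False)
        recs.append((f"X{i}", ids[s], ids[d]))
        ids.append(f"X{i}")
    return Pedigree.from_records(recs)


def random_genotypes(rng, n=30, m=50, maf=(0.1, 0.5), missing=0.0, ids=None):
    p = rng.uniform(*maf, m)
    calls = rng.binomial(2, p, size=(n, m)).astype(float)
    # avoid monomorphic columns
    for j in np.nonzero(calls.std(axis=0) == 0)[0]:
        calls[rng.integers(n), j] = 1.0
    if missing > 0:
        calls[rng.random(calls.shape) < missing] = np.nan
    if ids is None:
        ids = [f"G{i + 1}" for i in range(n)]
    return GenotypeSet(ids, make_snp_map(m), calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def trio_pedigree():
    return Pedigree.from_records([("A", "0", "0"), ("B", "0", "0"),
                                  ("C", "A", "B")])


def make_traits(ids, y, cg=None, names=("t1",)):
    """TraitTable from an (n, T) array (NaN = missing)."""
    y = np.atleast_2d(np.asarray(y, float))
    if y.shape[0] != len(ids):
        y = y.T
    df = pd.DataFrame({"animal": list(ids)})
    for t, name in enumerate(names):
        df[name] = y[:, t]
    df["cg"] = cg if cg is not None else "g1"
    return TraitTable(df, tuple(names))
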