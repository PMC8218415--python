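import numpy as np
import pytest

from ampliconmeth import (
    AmpliconDef,
    AssayType,
    CpGSite,
    ReadCallMatrix,
    build_locus_map,
)

# small synthetic reference with a handful of CpGs and non-CpG cytosines
REFERENCE = ("TTAACGTTACGGATCACGTTGGCATTCCGGATACGATT" * 3)
CHROM = "chrSyn"


@pytest.fixture
def reference():
    return {CHROM: REFERENCE}


@pytest.fixture
def amplicon():
    return AmpliconDef("amp1", CHROM, 5, 100)


@pytest.fixture
def locus(reference, amplicon):
    return build_locus_map([amplicon], reference)


def make_matrix(rows, assay=AssayType.BS, positions=None):
    """Build a ReadCallMatrix from a list of call strings like 'CTN'."""
    n_sites = len(rows[0]) if rows else (len(positions) if positions else 0)
    if positions is None:
        positions = [100 + 10 * k for k in range(n_sites)]
    sites = [
        CpGSite(chrom="chrT", pos=p, amplicon="ampT", global_index=k + 1)
        for k, p in enumerate(positions)
    ]
    calls = (
        np.array([list(r) for r in rows], dtype="<U1")
        if rows
        else np.empty((0, n_sites), dtype="<U1")
    )
    ids = [f"r{k}" for k in range(len(rows))]
    return ReadCallMatrix(assay=assay, sites=sites, calls=calls, read_ids=ids)
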