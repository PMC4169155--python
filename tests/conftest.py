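import numpy as np
import pytest

from qtlsweep.alignment import (
    AlignedSampleSet,
    OutgroupSequence,
    SiteFilterConfig,
    SiteRecord,
)


@pytest.fixture
def default_filter():
    return SiteFilterConfig()


def make_alignment(rows, population="pop", start_coord=1, quality=None, ids=None):
    """Alignment from a list of sequence strings."""
    matrix = np.array([list(r.upper()) for r in rows], dtype="<U1")
    ids = ids or [f"s{k}" for k in range(len(rows))]
    pops = [population] * len(rows) if isinstance(population, str) else population
    return AlignedSampleSet(ids, pops, matrix, start_coord=start_coord, quality=quality)


def make_site(coord, counts_by_pop, outgroup="A", status=None):
    """SiteRecord from {pop: {base: count}} with inferred status."""
    if status is None:
        distinct = {b for c in counts_by_pop.values() for b in c}
        status = {1: "monomorphic", 2: "biallelic"}.get(len(distinct), "multiallelic")
    return SiteRecord(
        coord=coord,
        allele_counts={p: dict(c) for p, c in counts_by_pop.items()},
        n_valid={p: sum(c.values()) for p, c in counts_by_pop.items()},
        outgroup_base=outgroup,
        status=status,
    )


@pytest.fixture
def small_alignment():
    return make_alignment(["ACGTACGTAC", "ACGTACGTAC"])


@pytest.fixture
def outgroup10():
    return OutgroupSequence("ACGTACGTAC", "sim_outgroup")
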