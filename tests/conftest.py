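import numpy as np
import pytest

from coselect.catalog import EventMatrix, LineageMap
from coselect.response import ResponseCall


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """4 cell lines x 3 loci with a known event pattern."""
    values = np.array(
        [
            [1, 0, 1],
            [1, 1, 0],
            [0, 1, 1],
            [0, 0, 1],
        ],
        dtype=bool,
    )
    lineage = LineageMap({"L1": "colon", "L2": "colon", "L3": "melanoma", "L4": "lung"})
    return EventMatrix(["L1", "L2", "L3", "L4"], ["APC", "KRAS", "TP53"], values, lineage)


def random_event_matrix(rng, n=40, g=8, freq_lo=0.1, freq_hi=0.5, lineages=None):
    f = rng.uniform(freq_lo, freq_hi, g)
    values = rng.random((n, g)) < f
    cells = [f"CL{i:03d}" for i in range(n)]
    loci = [f"G{j:03d}" for j in range(g)]
    lin = LineageMap()
    if lineages:
        labels = rng.choice(lineages, size=n)
        lin = LineageMap(dict(zip(cells, (str(x) for x in labels))))
    return EventMatrix(cells, loci, values, lin)


def manual_call(matrix_cells, sensitive, drug="drugX", assay_mode="gic50_nm"):
    """A ResponseCall built directly from a chosen S set (for tests that
    need a fixed partition rather than a fitted curve)."""
    sensitive = set(sensitive)
    cells = sorted(matrix_cells)
    gi = np.array([0.0 if c in sensitive else 1.0 for c in cells])
    order = sorted(cells, key=lambda c: (c not in sensitive, c))
    return ResponseCall(
        drug=drug,
        assay_mode=assay_mode,
        ordered_cell_lines=order,
        ordered_gi=np.sort(gi),
        inflection_index=len(sensitive),
        cutoff_gi=0.5,
        sensitive=sensitive,
        resistant=set(cells) - sensitive,
        degenerate=False,
    )
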