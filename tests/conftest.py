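import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

from icpnm.srs_data import ContingencyTable, Report, ReportDatabase
from icpnm.pnm import BipartiteGraph, DrugAttributes

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def toy_db() -> ReportDatabase:
    """Five-report database with hand-enumerable contingency counts."""
    mk = lambda rid, day, drugs, ades: Report(
        rid, dt.date(2004, 1, day), frozenset(drugs), frozenset(ades))
    return ReportDatabase([
        mk("R1", 1, {"D1"}, {"A1"}),
        mk("R2", 2, {"D1", "D2"}, {"A1", "A2"}),
        mk("R3", 3, {"D2"}, {"A2"}),
        mk("R4", 4, {"D1"}, {"A2"}),
        mk("R5", 5, {"D3"}, {"A1"}),
    ])


@pytest.fixture
def toy_graph():
    """Four-drug bipartite graph whose link features are hand-computable."""
    return BipartiteGraph([("D1", "A1"), ("D1", "A2"), ("D2", "A1"),
                           ("D3", "A2")])


@pytest.fixture
def toy_attrs():
    return {
        "D1": DrugAttributes((1, 1, 0, 0), frozenset({"T1", "T2"}), "AX1"),
        "D2": DrugAttributes((1, 1, 0, 0), frozenset({"T1", "T3"}), "AX2"),
        "D3": DrugAttributes((0, 0, 1, 1), frozenset({"T4"}), "BY1"),
        "D4": DrugAttributes((1, 0, 0, 0), frozenset({"T2", "T3"}), "AZ9"),
    }


def random_table(rng: np.random.Generator, n_max: int = 10 ** 6,
                 all_cells_positive: bool = True) -> ContingencyTable:
    """A random valid 2x2 report table (optionally with every cell >= 1)."""
    while True:
        n = int(rng.integers(1_000, n_max))
        ci = int(rng.integers(1, n // 2))
        cj = int(rng.integers(1, n // 2))
        lo = max(0, ci + cj - n)
        hi = min(ci, cj)
        c = int(rng.integers(lo, hi + 1))
        t = ContingencyTable(c, ci, cj, n)
        if not all_cells_positive or min(t.cells()) >= 1:
            return t
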