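import numpy as np
import pytest

from aedscreen import fixtures, germline, screensim
from aedscreen.library import design_library
from aedscreen.tracking import AmpliconLayout


@pytest.fixture(scope="session")
def traj_genes():
    return fixtures.traj_like_genes()


@pytest.fixture(scope="session")
def traj_alignment(traj_genes):
    return germline.align_sequences(traj_genes)


@pytest.fixture(scope="session")
def traj_profile(traj_alignment):
    return germline.conservation_profile(traj_alignment)


@pytest.fixture(scope="session")
def nnk_library():
    return design_library("FEQWT", [1, 3], "NNK")


@pytest.fixture(scope="session")
def amplicon():
    template, span = screensim.default_template("FEQWT")
    layout = AmpliconLayout(template, span, [1, 3])
    return template, span, layout


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def brute_force_global_score(
    a: str, b: str, matrix, gap_open: float = -10.0, gap_extend: float = -1.0
) -> float:
    """Independent affine-gap global alignment optimum by memoised recursion.

    A gap of length L scores gap_open + (L - 1) * gap_extend.  States: 0 =
    free to do anything, 1 = currently extending a gap in b, 2 = extending a
    gap in a.
    """
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(matrix[a[i], b[j]] + best(i + 1, j + 1, 0))
        if i < len(a):
            cost = gap_extend if state == 1 else gap_open
            options.append(cost + best(i + 1, j, 1))
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open
            options.append(cost + best(i, j + 1, 2))
        return max(options)

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(10000)
    try:
        return best(0, 0, 0)
    finally:
        sys.setrecursionlimit(old)
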