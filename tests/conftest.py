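"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pytest

from llpsminer.records import ExperimentRecord, Provenance, Quantity, RecordSet


# ---------------------------------------------------------------------------
# record factories
# ---------------------------------------------------------------------------

def make_record(
    paper="P01",
    fig="Fig1",
    name="FUS",
    pc=None,
    rc=None,
    ph=None,
    temp=None,
    phase=None,
    **kwargs,
):
    """Terse ExperimentRecord builder; bare floats become µM/°C quantities."""
    if isinstance(pc, (int, float)):
        pc = Quantity(float(pc), "µM", True)
    if isinstance(rc, (int, float)):
        rc = Quantity(float(rc), "µM", True)
    if isinstance(temp, (int, float)):
        temp = Quantity(float(temp), "°C", True)
    return ExperimentRecord(
        provenance=Provenance(paper, fig),
        protein_name=name,
        protein_conc=pc,
        rna_conc=rc,
        ph=ph,
        temperature=temp,
        phase_status=phase,
        **kwargs,
    )


def make_set(records, origin="label"):
    first = records[0].provenance
    return RecordSet(first.paper_id, first.figure_id, tuple(records), origin=origin)


@pytest.fixture
def grid_labels():
    """A small hand-built figure: 2x2 concentration grid, both phases."""
    recs = [
        make_record(pc=1.0, rc=0.1, ph=7.4, temp=25, phase=0),
        make_record(pc=1.0, rc=10.0, ph=7.4, temp=25, phase=0),
        make_record(pc=100.0, rc=0.1, ph=7.4, temp=25, phase=1),
        make_record(pc=100.0, rc=10.0, ph=7.4, temp=25, phase=1),
    ]
    return make_set(recs)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def ro_similarity(a: str, b: str) -> float:
    """Brute-force Ratcliff-Obershelp gestalt similarity 2M/(|a|+|b|).

    Finds the longest matching block by naive O(n^3) scan (ties resolved to
    the earliest start in a, then in b) and recurses on both flanks.
    Independent of difflib's dict-based implementation.
    """

    def matching_chars(x: str, y: str) -> int:
        best_size, best_i, best_j = 0, 0, 0
        for i in range(len(x)):
            for j in range(len(y)):
                k = 0
                while i + k < len(x) and j + k < len(y) and x[i + k] == y[j + k]:
                    k += 1
                if k > best_size:
                    best_size, best_i, best_j = k, i, j
        if best_size == 0:
            return 0
        return (
            best_size
            + matching_chars(x[:best_i], y[:best_j])
            + matching_chars(x[best_i + best_size:], y[best_j + best_size:])
        )

    if not a and not b:
        return 1.0
    return 2.0 * matching_chars(a, b) / (len(a) + len(b))


def brute_force_assignment_cost(C: np.ndarray) -> float:
    """Exhaustive minimum assignment cost for small rectangular matrices."""
    C = np.asarray(C, dtype=float)
    m, n = C.shape
    if m == 0 or n == 0:
        return 0.0
    if m <= n:
        return min(
            sum(C[i, p[i]] for i in range(m)) for p in permutations(range(n), m)
        )
    return min(sum(C[p[j], j] for j in range(n)) for p in permutations(range(m), n))


def exact_signed_rank_p(diffs) -> float:
    """Two-sided exact signed-rank p-value by full sign enumeration.

    Uses midranks of |d| (so it handles tied magnitudes); zero differences
    must already be removed.  Exponential in n: for tiny fixtures only.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_abs[j] == sorted_abs[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # midrank over the tie run
        i = j
    w_neg_obs = ranks[d < 0].sum()
    w_pos_obs = ranks[d > 0].sum()
    count = 0
    for mask in range(2**n):
        w_neg = sum(ranks[k] for k in range(n) if mask >> k & 1)
        if w_neg <= min(w_neg_obs, w_pos_obs) or w_neg >= max(w_neg_obs, w_pos_obs):
            count += 1
    return min(count / 2.0**n, 1.0)
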