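"""Independent numerical oracles used only by the test suite.

These deliberately avoid the package's own solution paths: the pure
delays are approximated by long Erlang chains and the system is
integrated by matrix exponentials, and plasma-visit statistics come from
a direct absorbing-Markov-chain linear solve.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm


def erlang_chain_solution(params, times, n_stages=256, dose=1.0):
    """Approximate each pure delay by an ``n_stages``-stage Erlang chain
    (stage rate n/DT) and propagate the full linear system with matrix
    exponentials.

    Returns (fd5, fa, total_accounted) arrays over ``times``.
    """
    l = params.l
    n3 = n8 = n_stages
    r3 = n3 / params.dt3
    r8 = n8 / params.dt8
    N = 2 + n3 + 4 + n8 + 3
    i1, i2 = 0, 1
    c3 = 2
    i4 = c3 + n3
    i5, i6, i7 = i4 + 1, i4 + 2, i4 + 3
    c8 = i4 + 4
    iL1, iL6, iL8 = c8 + n8, c8 + n8 + 1, c8 + n8 + 2

    A = np.zeros((N, N))
    A[i1, i1] = -(l[(2, 1)] + l[(0, 1)])
    A[i2, i1] = l[(2, 1)]
    A[iL1, i1] = l[(0, 1)]
    A[i2, i2] = -(l[(3, 2)] + l[(5, 2)])
    A[c3, i2] = l[(3, 2)]
    A[i5, i2] = l[(5, 2)]
    for s in range(n3):
        A[c3 + s, c3 + s] = -r3
        if s + 1 < n3:
            A[c3 + s + 1, c3 + s] = r3
    A[i4, c3 + n3 - 1] = r3
    A[i4, i4] = -l[(5, 4)]
    A[i5, i4] = l[(5, 4)]
    k5 = l[(6, 5)] + l[(7, 5)] + l[(8, 5)]
    A[i5, i5] = -k5
    A[i6, i5] = l[(6, 5)]
    A[i7, i5] = l[(7, 5)]
    A[c8, i5] = l[(8, 5)]
    A[i5, i6] = l[(5, 6)]
    A[i6, i6] = -(l[(5, 6)] + l[(0, 6)])
    A[iL6, i6] = l[(0, 6)]
    A[i5, i7] = l[(5, 7)]
    A[i7, i7] = -l[(5, 7)]
    for s in range(n8):
        A[c8 + s, c8 + s] = -r8
        if s + 1 < n8:
            A[c8 + s + 1, c8 + s] = r8
    A[iL8, c8 + n8 - 1] = r8

    x = np.zeros(N)
    x[i1] = dose
    fd5, fa, total = [], [], []
    prev_t = 0.0
    for t in np.asarray(times, dtype=float):
        dt = t - prev_t
        if dt > 0:
            x = expm(A * dt) @ x
            prev_t = t
        fd5.append(x[i5])
        fa.append(x[i6] + x[i7])
        total.append(x.sum())
    return np.asarray(fd5), np.asarray(fa), np.asarray(total)


def markov_expected_plasma_visits(params):
    """Expected number of visits to plasma before irreversible exit.

    Solves the absorbing-chain fundamental matrix N = (I - Q)^-1 on the
    embedded jump chain over transient states {plasma, store 6, store 7}
    (delay 8 and the loss from 6 are absorbing) and reads off N[plasma,
    plasma] for a chain started in plasma.
    """
    l = params.l
    k5 = l[(6, 5)] + l[(7, 5)] + l[(8, 5)]
    k6 = l[(5, 6)] + l[(0, 6)]
    # transient order: 5, 6, 7
    Q = np.array(
        [
            [0.0, l[(6, 5)] / k5, l[(7, 5)] / k5],
            [l[(5, 6)] / k6, 0.0, 0.0],
            [1.0, 0.0, 0.0],
        ]
    )
    N = np.linalg.inv(np.eye(3) - Q)
    return N[0, 0]
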