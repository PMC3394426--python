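"""Numba-compiled dynamic-programming kernels.

These inner loops dominate the runtime of threshold sweeps and of the
coordinate-descent weight search, which rescales every candidate pair
hundreds of times.  Strings are passed as int64 arrays of code points.
"""

import numpy as np
from numba import njit

_NEG = -1.0e18


@njit(cache=False)
def levenshtein_kernel(a, b):
    """Unit-cost Levenshtein distance between two code-point arrays."""
    n1 = a.shape[0]
    n2 = b.shape[0]
    if n1 == 0:
        return n2
    if n2 == 0:
        return n1
    prev = np.empty(n2 + 1, np.int64)
    curr = np.empty(n2 + 1, np.int64)
    for j in range(n2 + 1):
        prev[j] = j
    for i in range(1, n1 + 1):
        curr[0] = i
        ai = a[i - 1]
        for j in range(1, n2 + 1):
            m = prev[j - 1] + (0 if ai == b[j - 1] else 1)
            d = prev[j] + 1
            if d < m:
                m = d
            ins = curr[j - 1] + 1
            if ins < m:
                m = ins
            curr[j] = m
        prev, curr = curr, prev
    return prev[n2]


@njit(cache=False)
def weighted_edit_kernel(a, b, w):
    """Minimum-cost edit script with per-character insertion/deletion costs.

    ``w`` holds 26 costs for 'a'..'z'; any other code point costs 1.0 to
    insert or delete.  Substitution always costs 1.0.
    """
    n1 = a.shape[0]
    n2 = b.shape[0]
    prev = np.empty(n2 + 1, np.float64)
    curr = np.empty(n2 + 1, np.float64)
    prev[0] = 0.0
    for j in range(1, n2 + 1):
        c = b[j - 1]
        prev[j] = prev[j - 1] + (w[c - 97] if 97 <= c <= 122 else 1.0)
    for i in range(1, n1 + 1):
        ca = a[i - 1]
        del_cost = w[ca - 97] if 97 <= ca <= 122 else 1.0
        curr[0] = prev[0] + del_cost
        for j in range(1, n2 + 1):
            cb = b[j - 1]
            ins_cost = w[cb - 97] if 97 <= cb <= 122 else 1.0
            m = prev[j - 1] + (0.0 if ca == cb else 1.0)
            d = prev[j] + del_cost
            if d < m:
                m = d
            ins = curr[j - 1] + ins_cost
            if ins < m:
                m = ins
            curr[j] = m
        prev, curr = curr, prev
    return prev[n2]


@njit(cache=False)
def affine_local_kernel(a, b, ca, cb, match, klass, mismatch, alpha, beta):
    """Best local alignment score with affine gaps g(k) = alpha + beta*k.

    ``ca``/``cb`` carry the equivalence-class id of each character (-1 if
    none).  A column scores ``match`` on equal characters, ``klass`` when
    both characters sit in the same class, ``mismatch`` otherwise.  A gap
    run of length k costs alpha + beta*k.  Alignments may start and end
    anywhere; the empty alignment scores 0.
    """
    n1 = a.shape[0]
    n2 = b.shape[0]
    open_ = alpha + beta
    m_prev = np.full(n2 + 1, _NEG)
    x_prev = np.full(n2 + 1, _NEG)
    y_prev = np.full(n2 + 1, _NEG)
    m_cur = np.full(n2 + 1, _NEG)
    x_cur = np.full(n2 + 1, _NEG)
    y_cur = np.full(n2 + 1, _NEG)
    best = 0.0
    for i in range(1, n1 + 1):
        m_cur[0] = _NEG
        x_cur[0] = _NEG
        y_cur[0] = _NEG
        for j in range(1, n2 + 1):
            if a[i - 1] == b[j - 1]:
                s = match
            elif ca[i - 1] >= 0 and ca[i - 1] == cb[j - 1]:
                s = klass
            else:
                s = mismatch
            d = 0.0
            if m_prev[j - 1] > d:
                d = m_prev[j - 1]
            if x_prev[j - 1] > d:
                d = x_prev[j - 1]
            if y_prev[j - 1] > d:
                d = y_prev[j - 1]
            mm = s + d
            m_cur[j] = mm
            if mm > best:
                best = mm
            # gap in b (consumes a[i-1]); opened from M, extended in X
            x = m_prev[j] - open_
            t = x_prev[j] - beta
            if t > x:
                x = t
            x_cur[j] = x
            # gap in a (consumes b[j-1]); may follow a gap in b
            y = m_cur[j - 1] - open_
            t = x_cur[j - 1] - open_
            if t > y:
                y = t
            t = y_cur[j - 1] - beta
            if t > y:
                y = t
            y_cur[j] = y
        m_prev, m_cur = m_cur, m_prev
        x_prev, x_cur = x_cur, x_prev
        y_prev, y_cur = y_cur, y_prev
    return best
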