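"""Independent reference implementations used only to check the package.

These deliberately do not share code with atacedit: the alignment oracle
is a direct dynamic-programming transcription of the affine-gap
recurrences, and the Welch oracle is the textbook formula.
"""

from __future__ import annotations

import math

import numpy as np

NEG = -1e18


def affine_glocal_score(ref: str, read: str, match: int = 4, mismatch: int = 16,
                        gap_open: int = 24, gap_extend: int = 1) -> float:
    """Brute-force affine-gap DP score: read global, reference local.

    A gap of length k costs ``gap_open + k * gap_extend``; unaligned
    reference flanks are free.  Row-vectorized over the reference axis;
    the horizontal (deletion) state uses the running-maximum identity
    D[j] = max_{k<j} (open_state[k] - gap_open - (j-k)·gap_extend).
    """
    n, m = len(read), len(ref)
    ref_a = np.frombuffer(ref.encode(), dtype=np.uint8)
    j_ext = np.arange(m + 1) * gap_extend

    H_prev = np.zeros(m + 1)          # row 0: leading reference skip is free
    V_prev = np.full(m + 1, NEG)
    for i in range(1, n + 1):
        sub = np.where(ref_a == ord(read[i - 1]), match, -mismatch)
        V = np.maximum(V_prev, H_prev - gap_open) - gap_extend
        H = np.empty(m + 1)
        H[0] = -(gap_open + i * gap_extend)
        G = np.empty(m + 1)           # states a deletion may open from
        G[0] = H[0]
        G[1:] = np.maximum(H_prev[:-1] + sub, V[1:])
        run = np.maximum.accumulate(G + j_ext)
        H[1:] = np.maximum(G[1:], run[:-1] - gap_open - j_ext[1:])
        H_prev, V_prev = H, V
    return float(H_prev.max())


def welch_reference(x, y) -> tuple[float, float, float]:
    """Textbook Welch statistic, Welch–Satterthwaite df and two-tailed p."""
    from scipy.special import stdtr

    x = list(map(float, x))
    y = list(map(float, y))
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stdtr(df, -abs(t))
    return t, df, p


def deletion_in_window(del_start: int, del_len: int, snp_pos: int,
                       window: int) -> bool:
    """Set-containment check: every deleted offset inside snp_pos ± window."""
    deleted = set(range(del_start, del_start + del_len))
    allowed = set(range(snp_pos - window, snp_pos + window + 1))
    return deleted <= allowed
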