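"""Numba kernel for maximum-weight nested base pairing.

The dynamic program is the classic O(n^3) recursion over a precomputed
pair-weight matrix W (W[i,j] <= 0 means i,j may not pair):

    dp[i,j] = max( dp[i+1,j],
                   max_{k: W[i,k]>0, k>i+minloop} W[i,k] + dp[i+1,k-1] + dp[k+1,j] )
"""

import numpy as np
from numba import njit


@njit(cache=True)
def nussinov_dp(W, minloop):
    n = W.shape[0]
    # admissible partners per opening index, in increasing order
    nc = np.zeros(n, dtype=np.int32)
    cand = np.empty((n, n), dtype=np.int32)
    for i in range(n):
        c = 0
        for k in range(i + minloop + 1, n):
            if W[i, k] > 0.0:
                cand[i, c] = k
                c += 1
        nc[i] = c
    dp = np.zeros((n, n), dtype=np.float64)
    for l in range(minloop + 1, n):
        for i in range(0, n - l):
            j = i + l
            best = dp[i + 1, j]
            for ci in range(nc[i]):
                k = cand[i, ci]
                if k > j:
                    break
                c = W[i, k] + dp[i + 1, k - 1]
                if k < j:
                    c += dp[k + 1, j]
                if c > best:
                    best = c
            dp[i, j] = best
    return dp


def traceback(dp, W, minloop):
    """One optimal structure; ties broken by pairing the smallest opening
    index with its smallest admissible partner, recursively."""
    n = dp.shape[0]
    struct = ["."] * n
    stack = [(0, n - 1)]
    eps = 1e-9
    while stack:
        i, j = stack.pop()
        while i < j:
            if dp[i, j] <= eps:
                break
            paired = False
            target = dp[i, j]
            for k in range(i + minloop + 1, j + 1):
                if W[i, k] > 0.0:
                    cand = W[i, k] + dp[i + 1, k - 1]
                    if k < j:
                        cand += dp[k + 1, j]
                    if abs(cand - target) < eps:
                        struct[i] = "("
                        struct[k] = ")"
                        if k < j:
                            stack.append((k + 1, j))
                        i, j = i + 1, k - 1
                        paired = True
                        break
            if not paired:
                i += 1
    return "".join(struct)
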