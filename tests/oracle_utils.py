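"""Independent brute-force oracles kept deliberately separate from the
implementation paths they check."""

import math

import numpy as np


def rv_bruteforce(X, Y, modified=False):
    """RV coefficient via explicit element-wise double sums over the
    cross-product matrices (no trace/norm shortcuts)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not modified:  # the modified variant uses the tables as given
        X = X - X.mean(axis=0)
        Y = Y - Y.mean(axis=0)
    n = X.shape[0]
    Sx = [[sum(X[i, k] * X[j, k] for k in range(X.shape[1])) for j in range(n)] for i in range(n)]
    Sy = [[sum(Y[i, k] * Y[j, k] for k in range(Y.shape[1])) for j in range(n)] for i in range(n)]
    if modified:
        for i in range(n):
            Sx[i][i] = 0.0
            Sy[i][i] = 0.0
    num = sum(Sx[i][j] * Sy[i][j] for i in range(n) for j in range(n))
    dx = sum(Sx[i][j] ** 2 for i in range(n) for j in range(n))
    dy = sum(Sy[i][j] ** 2 for i in range(n) for j in range(n))
    return num / math.sqrt(dx * dy)
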