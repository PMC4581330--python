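"""Numba kernels for the BRNN hidden chains.

The forward chain runs left-to-right, each state computed by a two-layer
subnet from the current input and the previous S states; the backward chain
mirrors it right-to-left.  States beyond the chain ends are zero vectors.
The adjoint kernels implement backpropagation through structure: gradients
on each hidden state accumulate contributions from the output network and
from the S downstream transition evaluations that consumed it.

Layout: the forward chain stores position j (0-based) at ``hpad[j + S]`` with
``hpad[0:S]`` the zero boundary; the backward chain stores position j at
``hpad[j]`` with ``hpad[N:N+S]`` the zero boundary.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def chain_forward(X, W1, b1, W2, b2, S, reverse):
    """Run one hidden chain; returns (hpad, A1) with A1 the subnet hidden
    activations per position."""
    N, d = X.shape
    C = W1.shape[1]
    H = W2.shape[1]
    din = d + S * H
    hpad = np.zeros((N + S, H))
    A1 = np.empty((N, C))
    uf = np.empty(din)
    if not reverse:
        for j in range(N):
            for t in range(d):
                uf[t] = X[j, t]
            for s in range(1, S + 1):
                base = d + (s - 1) * H
                for t in range(H):
                    uf[base + t] = hpad[j + S - s, t]
            a1 = np.tanh(np.dot(uf, W1) + b1)
            for t in range(C):
                A1[j, t] = a1[t]
            h = np.tanh(np.dot(a1, W2) + b2)
            for t in range(H):
                hpad[j + S, t] = h[t]
    else:
        for j in range(N - 1, -1, -1):
            for t in range(d):
                uf[t] = X[j, t]
            for s in range(1, S + 1):
                base = d + (s - 1) * H
                for t in range(H):
                    uf[base + t] = hpad[j + s, t]
            a1 = np.tanh(np.dot(uf, W1) + b1)
            for t in range(C):
                A1[j, t] = a1[t]
            h = np.tanh(np.dot(a1, W2) + b2)
            for t in range(H):
                hpad[j, t] = h[t]
    return hpad, A1


@njit(cache=True)
def chain_backward(X, W1, W2, hpad, A1, dh, S, reverse):
    """Adjoint of :func:`chain_forward`.

    ``dh`` (N x H) is the external gradient on each hidden state (from the
    output network).  Returns (dW1, db1, dW2, db2, dX).
    """
    N, d = X.shape
    C = W1.shape[1]
    H = W2.shape[1]
    din = d + S * H
    dW1 = np.zeros_like(W1)
    db1 = np.zeros(C)
    dW2 = np.zeros_like(W2)
    db2 = np.zeros(H)
    dX = np.zeros((N, d))
    dhpad = np.zeros((N + S, H))
    uf = np.empty(din)
    dz2 = np.empty(H)
    if not reverse:
        for j in range(N):
            for t in range(H):
                dhpad[j + S, t] += dh[j, t]
        for j in range(N - 1, -1, -1):
            for t in range(d):
                uf[t] = X[j, t]
            for s in range(1, S + 1):
                base = d + (s - 1) * H
                for t in range(H):
                    uf[base + t] = hpad[j + S - s, t]
            for t in range(H):
                h = hpad[j + S, t]
                dz2[t] = dhpad[j + S, t] * (1.0 - h * h)
                db2[t] += dz2[t]
            for a in range(C):
                av = A1[j, a]
                for t in range(H):
                    dW2[a, t] += av * dz2[t]
            da1 = np.dot(W2, dz2)
            dz1 = da1 * (1.0 - A1[j] * A1[j])
            for t in range(C):
                db1[t] += dz1[t]
            for a in range(din):
                uv = uf[a]
                for t in range(C):
                    dW1[a, t] += uv * dz1[t]
            duf = np.dot(W1, dz1)
            for t in range(d):
                dX[j, t] += duf[t]
            for s in range(1, S + 1):
                if j - s >= 0:
                    base = d + (s - 1) * H
                    for t in range(H):
                        dhpad[j + S - s, t] += duf[base + t]
    else:
        for j in range(N):
            for t in range(H):
                dhpad[j, t] += dh[j, t]
        for j in range(N):
            for t in range(d):
                uf[t] = X[j, t]
            for s in range(1, S + 1):
                base = d + (s - 1) * H
                for t in range(H):
                    uf[base + t] = hpad[j + s, t]
            for t in range(H):
                h = hpad[j, t]
                dz2[t] = dhpad[j, t] * (1.0 - h * h)
                db2[t] += dz2[t]
            for a in range(C):
                av = A1[j, a]
                for t in range(H):
                    dW2[a, t] += av * dz2[t]
            da1 = np.dot(W2, dz2)
            dz1 = da1 * (1.0 - A1[j] * A1[j])
            for t in range(C):
                db1[t] += dz1[t]
            for a in range(din):
                uv = uf[a]
                for t in range(C):
                    dW1[a, t] += uv * dz1[t]
            duf = np.dot(W1, dz1)
            for t in range(d):
                dX[j, t] += duf[t]
            for s in range(1, S + 1):
                if j + s < N:
                    base = d + (s - 1) * H
                    for t in range(H):
                        dhpad[j + s, t] += duf[base + t]
    return dW1, db1, dW2, db2, dX
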