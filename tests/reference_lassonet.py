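"""Independent plain-LassoNet reference used as a cross-check.

A deliberately simple, separately written implementation of the standard
(single-modality) LassoNet objective and training loop: residual net,
binary cross-entropy, full-batch momentum gradient descent, and a
per-feature scalar-loop hierarchical prox.  It shares no code with the
package; the regression test compares per-step path objectives against
the package with the structural multiplier set to 1.
"""

import numpy as np


def ref_forward(theta, W1, b1, w2, b2, X):
    hidden = np.maximum(X.dot(W1) + b1, 0.0)
    return X.dot(theta) + hidden.dot(w2) + b2


def ref_loss(theta, W1, b1, w2, b2, X, y):
    s = ref_forward(theta, W1, b1, w2, b2, X)
    return float(np.mean(np.logaddexp(0.0, s) - y * s))


def ref_objective(theta, W1, b1, w2, b2, X, y, lam):
    return ref_loss(theta, W1, b1, w2, b2, X, y) + lam * float(np.sum(np.abs(theta)))


def ref_grads(theta, W1, b1, w2, b2, X, y):
    n = X.shape[0]
    z = X.dot(W1) + b1
    h = np.maximum(z, 0.0)
    s = X.dot(theta) + h.dot(w2) + b2
    p = 1.0 / (1.0 + np.exp(-s))
    g = (p - y) / n
    dz = np.outer(g, w2) * (z > 0)
    return X.T.dot(g), X.T.dot(dz), dz.sum(axis=0), h.T.dot(g), g.sum()


def ref_prox_single(theta_j, w_row, lam, M):
    """Scalar-loop hierarchical prox for one feature."""
    K = w_row.shape[0]
    absw = np.sort(np.abs(w_row))[::-1]
    best = None
    for n in range(K + 1):
        s_n = absw[:n].sum()
        u = abs(theta_j) + M * s_n - lam
        if u < 0.0:
            u = 0.0
        w_n = M / (1.0 + n * M * M) * u
        upper = np.inf if n == 0 else absw[n - 1]
        lower = 0.0 if n == K else absw[n]
        if lower <= w_n <= upper:
            best = w_n
            break
    if best is None:
        best = 0.0
    sgn = 1.0 if theta_j >= 0 else -1.0
    theta_out = sgn * best / M
    w_out = np.sign(w_row) * np.minimum(best, np.abs(w_row))
    return theta_out, w_out


def ref_prox(theta, W1, lam, M):
    theta_out = np.empty_like(theta)
    W_out = np.empty_like(W1)
    for j in range(theta.shape[0]):
        theta_out[j], W_out[j] = ref_prox_single(theta[j], W1[j], lam, M)
    return theta_out, W_out


def ref_fit_path(X, y, init, lr, mu, B, lam_start, eps, n_steps, M):
    """Dense warm start then a multiplicative path; returns per-step
    (lambda, objective) pairs.  ``init`` is (theta, W1, b1, w2, b2)."""
    theta, W1, b1, w2, b2 = [np.array(a, dtype=float) for a in init[:4]] + [float(init[4])]
    vth = np.zeros_like(theta); vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1); vw2 = np.zeros_like(w2); vb2 = 0.0
    for _ in range(B):
        dth, dW1, db1, dw2, db2 = ref_grads(theta, W1, b1, w2, b2, X, y)
        vth = mu * vth - lr * dth; vW1 = mu * vW1 - lr * dW1
        vb1 = mu * vb1 - lr * db1; vw2 = mu * vw2 - lr * dw2; vb2 = mu * vb2 - lr * db2
        theta = theta + vth; W1 = W1 + vW1; b1 = b1 + vb1; w2 = w2 + vw2; b2 = b2 + vb2

    out = []
    lam = lam_start
    for _ in range(n_steps):
        vth = np.zeros_like(theta); vW1 = np.zeros_like(W1)
        vb1 = np.zeros_like(b1); vw2 = np.zeros_like(w2); vb2 = 0.0
        for _ in range(B):
            dth, dW1, db1, dw2, db2 = ref_grads(theta, W1, b1, w2, b2, X, y)
            vth = mu * vth - lr * dth; vW1 = mu * vW1 - lr * dW1
            vb1 = mu * vb1 - lr * db1; vw2 = mu * vw2 - lr * dw2; vb2 = mu * vb2 - lr * db2
            theta = theta + vth; W1 = W1 + vW1; b1 = b1 + vb1; w2 = w2 + vw2; b2 = b2 + vb2
            theta, W1 = ref_prox(theta, W1, lr * lam, M)
        out.append((lam, ref_objective(theta, W1, b1, w2, b2, X, y, lam)))
        if np.count_nonzero(theta) == 0:
            break
        lam = (1.0 + eps) * lam
    return out
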