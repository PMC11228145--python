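"""Independent oracles for the attentive network, used only by tests.

``brute_force_simplex_projection`` solves the sparsemax quadratic program by
exhaustive support enumeration; ``reference_forward_per_feature`` is a plain
NumPy re-implementation of the eval-mode forward pass with per-feature
(singleton) attention, written directly from the layer definitions and using
scipy's scalar root finder for the capped projection threshold.
"""

from itertools import combinations

import numpy as np
from scipy.optimize import brentq

BN_EPS = 1e-5
SQRT_HALF = float(np.sqrt(0.5))


def brute_force_simplex_projection(z: np.ndarray) -> np.ndarray:
    """argmin ||p - z||^2 over the probability simplex, by trying every
    support set (feasible only for small dimension)."""
    z = np.asarray(z, dtype=float)
    d = len(z)
    best, best_obj = None, np.inf
    for k in range(1, d + 1):
        for support in combinations(range(d), k):
            s = list(support)
            tau = (z[s].sum() - 1.0) / k
            p = np.zeros(d)
            p[s] = z[s] - tau
            if (p[s] <= -1e-12).any():
                continue
            obj = ((p - z) ** 2).sum()
            if obj < best_obj - 1e-15:
                best_obj, best = obj, p
    return best


def _capped_projection_row(z: np.ndarray, cap: np.ndarray) -> np.ndarray:
    """Projection onto {0 <= p <= cap, sum p = 1} via a scalar root find on
    the threshold."""
    if cap.sum() < 1.0 - 1e-12:
        s = cap.sum()
        return cap / s if s > 0 else np.full_like(z, 1.0 / len(z))

    def f(tau):
        return np.clip(z - tau, 0.0, cap).sum() - 1.0

    lo = float((z - cap).min()) - 1.0
    hi = float(z.max())
    tau = brentq(f, lo, hi, xtol=1e-14)
    return np.clip(z - tau, 0.0, cap)


def _bn_eval(bn, x):
    xn = (x - bn.running_mean) / np.sqrt(bn.running_var + BN_EPS)
    return xn * bn.gamma.data + bn.beta.data


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


def _glu(blk, x):
    y = _bn_eval(blk.bn, x @ blk.W.data + blk.b.data)
    h = blk.n_out
    return y[:, :h] * _sigmoid(y[:, h:])


def _transform(model, x, step_set):
    h = None
    for k, blk in enumerate(model.shared):
        y = _glu(blk, x if k == 0 else h)
        h = y if k == 0 else (y + h) * SQRT_HALF
    for blk in model.independent[step_set]:
        h = (_glu(blk, h) + h) * SQRT_HALF
    return h


def reference_forward_per_feature(model, X):
    """Eval-mode forward pass with singleton (per-feature) attention.

    Returns (prediction, masks list) and assumes the model was built with an
    all-singleton partition in natural column order.
    """
    cfg = model.config
    X = np.asarray(X, dtype=float)
    base = X.copy()
    for j, emb in model.embeddings.items():
        codes = np.clip(X[:, j], 0, 1).astype(int)
        base[:, j] = emb.data[codes, 0]
    x_bn = _bn_eval(model.input_bn, base)

    feat = _transform(model, x_bn, 0)
    a = feat[:, cfg.n_d:]
    prior = np.ones((len(X), X.shape[1]))
    masks = []
    d_sum = np.zeros((len(X), cfg.n_d))
    for i in range(cfg.n_steps):
        scores = _bn_eval(model.att_bn[i], a @ model.att_W[i].data + model.att_b[i].data)
        z = prior * scores
        cap = np.minimum(prior, 1.0)
        q = np.stack([_capped_projection_row(z[r], cap[r]) for r in range(len(z))])
        masks.append(q)
        feat = _transform(model, q * x_bn, i + 1)
        d_sum += np.maximum(feat[:, :cfg.n_d], 0.0)
        a = feat[:, cfg.n_d:]
        prior = prior * (cfg.gamma - q)
    pred = d_sum @ model.W_out.data + model.b_out.data
    return pred.ravel(), masks
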