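"""Binary cross-entropy, in probability and logit form.

The probability form is the textbook loss
``H(y, yhat) = -(y log yhat + (1 - y) log(1 - yhat))``;
the logit form is used inside training loops for numerical stability and
yields the well-known gradient ``sigmoid(z) - y``.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-7


def sigmoid(z):
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(y, y_hat) -> np.ndarray:
    """Binary cross-entropy of predicted probability ``y_hat`` against the
    true binary label ``y``. Probabilities are clamped to [EPS, 1 - EPS]."""
    y = np.asarray(y, dtype=np.float64)
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("true labels must be 0 or 1")
    p = np.clip(np.asarray(y_hat, dtype=np.float64), EPS, 1.0 - EPS)
    return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


def bce_grad(y, y_hat) -> np.ndarray:
    """Analytic d loss / d y_hat = (y_hat - y) / (y_hat (1 - y_hat))."""
    y = np.asarray(y, dtype=np.float64)
    p = np.clip(np.asarray(y_hat, dtype=np.float64), EPS, 1.0 - EPS)
    return (p - y) / (p * (1.0 - p))


def bce_from_logits(y, z):
    """Mean BCE and its gradient w.r.t. the logit ``z`` (stable form)."""
    y = np.asarray(y, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    return float(loss.mean()), (sigmoid(z) - y) / y.size
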