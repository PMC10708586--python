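"""Loss functions returning (scalar loss, gradient w.r.t. network output)."""

from __future__ import annotations

import numpy as np

PROB_EPS = 1e-7  # clamp for probabilities entering a logarithm


def nll_loss(log_probs, labels):
    """Cross-entropy on log-softmax outputs (mean over the batch)."""
    n = log_probs.shape[0]
    labels = np.asarray(labels)
    loss = -log_probs[np.arange(n), labels].mean()
    grad = np.zeros_like(log_probs)
    grad[np.arange(n), labels] = -1.0 / n
    return float(loss), grad


def bce_loss(probs, targets):
    """Binary cross-entropy on probabilities (mean), with clamping."""
    p = np.clip(probs, PROB_EPS, 1.0 - PROB_EPS)
    t = np.asarray(targets, dtype=p.dtype)
    loss = -(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean()
    grad = (-(t / p) + (1.0 - t) / (1.0 - p)) / p.size
    return float(loss), grad
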