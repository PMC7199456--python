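"""Training objectives: cross-entropy, PU risk decomposition, nnPU clamp.

Vocabulary (fixed throughout the package): label 0 marks voxels outside the
bounding box — the *positive* class of the PU problem, known background —
and label 1 marks voxels inside the box, which are *unlabeled* (tumor or
background).  With sigmoid probability sigma(logit) interpreted as P(tumor),
the per-voxel losses are

    L(logit, 1) = -log sigma(logit)        (negative/tumor target)
    L(logit, 0) = -log(1 - sigma(logit))   (positive/background target)

From a batch the three empirical risk terms are formed:

    r_p_plus  = mean over label-0 voxels of L(., 0)
    r_u_minus = mean over label-1 voxels of L(., 1)
    r_p_minus = mean over label-0 voxels of L(., 1)

The unbiased PU risk is  pi_p * r_p_plus + (r_u_minus - pi_p * r_p_minus),
an unbiased estimate of the fully supervised risk when the class prior
pi_p is correct.  Its correction term in parentheses can go negative with a
flexible model, which signals overfitting to the unlabeled region; the
non-negative variant clamps it at zero, and the trainer additionally
switches to a defensive gradient step when the term falls below -beta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PULossConfig:
    """Hyperparameters of the PU objective.

    pi_p is the positive-class (background) prior, 0.75 at the operating
    point; beta >= 0 widens the tolerance of the gradient-switching rule;
    gamma in (0, 1] discounts the defensive step; eta scales every ADAM
    step.  ``shared_n`` divides each empirical term by the full batch size
    instead of its own label-group size.
    """

    pi_p: float = 0.75
    beta: float = 0.0
    gamma: float = 1.0
    eta: float = 0.5
    shared_n: bool = False

    def __post_init__(self):
        if not 0.0 < self.pi_p < 1.0:
            raise ValueError(f"pi_p must lie in (0, 1), got {self.pi_p}")
        if not 0.0 <= self.beta <= self.pi_p:
            raise ValueError(f"need 0 <= beta <= pi_p, got beta={self.beta}")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in (0, 1], got {self.gamma}")
        if self.eta <= 0:
            raise ValueError("eta must be positive")


@dataclass(frozen=True)
class RiskComponents:
    """The three empirical risk terms of one batch, in nats."""

    r_p_plus: float
    r_u_minus: float
    r_p_minus: float
    n_pos: int
    n_unl: int


def _softplus(z: np.ndarray) -> np.ndarray:
    # log(1 + exp(z)) without overflow for large |z|
    z = np.asarray(z, dtype=np.float64)
    return np.logaddexp(0.0, z)


def sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def voxel_ce(logit, target_class) -> np.ndarray:
    """Stable sigmoid cross-entropy of a logit against a {0, 1} target.

    Vectorized; scalar inputs return a scalar.  Target 1 gives
    -log sigma(logit) = softplus(-logit); target 0 gives
    -log(1 - sigma(logit)) = softplus(logit).
    """
    logit = np.asarray(logit, dtype=np.float64)
    target = np.asarray(target_class)
    loss = np.where(target == 1, _softplus(-logit), _softplus(logit))
    return loss if loss.ndim else float(loss)


def risk_components(
    logits: np.ndarray, labels: np.ndarray, shared_n: bool = False
) -> RiskComponents:
    """Decompose a voxel batch into the three empirical PU risk terms.

    By default each term averages over its own label group; with
    ``shared_n`` every sum is divided by the total voxel count instead.
    """
    logits = np.asarray(logits, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    pos = labels == 0
    unl = labels == 1
    n_pos, n_unl = int(pos.sum()), int(unl.sum())
    if n_pos == 0 or n_unl == 0:
        raise ValueError(
            "batch contains a single label class; mix S1 and S0 patches "
            "at the sampler level so every batch carries both"
        )
    div_pos = logits.size if shared_n else n_pos
    div_unl = logits.size if shared_n else n_unl
    lp = logits[pos]
    return RiskComponents(
        r_p_plus=float(_softplus(lp).sum() / div_pos),
        r_u_minus=float(_softplus(-logits[unl]).sum() / div_unl),
        r_p_minus=float(_softplus(-lp).sum() / div_pos),
        n_pos=n_pos,
        n_unl=n_unl,
    )


def pu_risk(c: RiskComponents, cfg: PULossConfig) -> float:
    """Unbiased PU risk: pi_p*r_p_plus + r_u_minus - pi_p*r_p_minus (may be < 0)."""
    return cfg.pi_p * c.r_p_plus + c.r_u_minus - cfg.pi_p * c.r_p_minus


def nn_pu_risk(c: RiskComponents, cfg: PULossConfig) -> tuple[float, bool]:
    """Non-negative PU risk and the gradient-switch flag.

    Returns ``pi_p*r_p_plus + max(0, r_u_minus - pi_p*r_p_minus)`` and a
    flag that is True iff the correction term fell below -beta, i.e. the
    trainer should take the discounted defensive step.
    """
    correction = c.r_u_minus - cfg.pi_p * c.r_p_minus
    risk = cfg.pi_p * c.r_p_plus + max(0.0, correction)
    return risk, bool(correction < -cfg.beta)


def naive_risk(logits: np.ndarray, labels: np.ndarray) -> float:
    """Plain mean cross-entropy treating box labels as voxel ground truth."""
    logits = np.asarray(logits, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    return float(voxel_ce(logits, labels).mean())


# ---------------------------------------------------------------------------
# gradients with respect to the logits (used by the trainer's backward pass)

def _group_divisors(labels, shared_n):
    n = labels.size
    n_pos = int((labels == 0).sum())
    n_unl = n - n_pos
    if shared_n:
        return n, n
    return n_pos, n_unl


def pu_risk_gradient(logits: np.ndarray, labels: np.ndarray, cfg: PULossConfig) -> np.ndarray:
    """d(pu_risk)/d(logits) for the unclamped objective (normal branch)."""
    shape = np.shape(logits)
    logits = np.asarray(logits, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    div_pos, div_unl = _group_divisors(labels, cfg.shared_n)
    s = sigmoid(logits)
    g = np.zeros_like(s)
    pos = labels == 0
    unl = ~pos
    # pi_p * r_p_plus term: d softplus(z)/dz = sigma(z)
    g[pos] += cfg.pi_p * s[pos] / div_pos
    # r_u_minus: d softplus(-z)/dz = sigma(z) - 1
    g[unl] += (s[unl] - 1.0) / div_unl
    # - pi_p * r_p_minus
    g[pos] -= cfg.pi_p * (s[pos] - 1.0) / div_pos
    return g.reshape(shape)


def defensive_gradient(logits: np.ndarray, labels: np.ndarray, cfg: PULossConfig) -> np.ndarray:
    """d(pi_p*r_p_minus - r_u_minus)/d(logits): pushes the correction term up."""
    shape = np.shape(logits)
    logits = np.asarray(logits, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    div_pos, div_unl = _group_divisors(labels, cfg.shared_n)
    s = sigmoid(logits)
    g = np.zeros_like(s)
    pos = labels == 0
    unl = ~pos
    g[pos] += cfg.pi_p * (s[pos] - 1.0) / div_pos
    g[unl] -= (s[unl] - 1.0) / div_unl
    return g.reshape(shape)


def naive_gradient(logits: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """d(naive_risk)/d(logits) = (sigma(logit) - label) / n."""
    shape = np.shape(logits)
    logits = np.asarray(logits, dtype=np.float64).ravel()
    labels = np.asarray(labels, dtype=np.float64).ravel()
    return ((sigmoid(logits) - labels) / logits.size).reshape(shape)
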