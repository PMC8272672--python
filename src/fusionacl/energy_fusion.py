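"""Energy-based multimodal fusion classifier.

The concatenated multimodal vector m = (c, o) — handcrafted features c and
deep features o, both min-max scaled to [0, 1] — is the visible layer of a
restricted Boltzmann machine (RBM): a bipartite energy model with visible
biases t_i, hidden biases beta_e and interaction weights theta_ie.  The
joint energy of binary states (x, y) is

    E(x, y) = - sum_i t_i x_i - sum_e beta_e y_e - sum_ie x_i theta_ie y_e

and the model assigns a visible vector the marginal probability
p(x) = Z^-1 sum_y exp(-E(x, y)).  Training maximizes the data log-likelihood
sum_j log p(x_j) by contrastive divergence (CD-k); real-valued features in
[0, 1] are treated as Bernoulli expectations (mean-field visible units).
A logistic output unit on the hidden activations, fine-tuned with
cross-entropy, turns the fused representation into a tear probability W;
W >= 0.5 is called positive.

A nonstandard formulation sometimes seen in print places the visible bias
inside the activation and the interaction term; that variant is available
via ``variant="printed"`` for comparison, but the standard form above is
the default (the printed form counts the visible bias twice and is
inconsistent with the likelihood objective).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp

from .errors import ConfigurationError, ExactModeError, UntrainedModelError

#: exact enumeration is refused above this many total units
EXACT_UNIT_LIMIT = 20


@dataclass
class FusedSample:
    """One multimodal feature vector in [0,1]^d with its binary label."""

    m: np.ndarray
    label: int

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, float)
        if self.m.ndim != 1:
            raise ConfigurationError("FusedSample.m must be 1-D")
        if self.m.min() < -1e-9 or self.m.max() > 1 + 1e-9:
            raise ConfigurationError("FusedSample.m entries must lie in [0, 1]")
        self.m = np.clip(self.m, 0.0, 1.0)
        if self.label not in (0, 1):
            raise ConfigurationError("FusedSample.label must be 0 or 1")


@dataclass
class RBMParams:
    """Parameters of the fusion RBM plus the logistic output unit."""

    visible_bias: np.ndarray  # t_i
    hidden_bias: np.ndarray  # beta_e
    weights: np.ndarray  # theta_ie, (n_visible, n_hidden)
    output_weights: np.ndarray = None  # type: ignore[assignment]
    output_bias: float = 0.0
    trained: bool = False
    history: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.visible_bias = np.asarray(self.visible_bias, float)
        self.hidden_bias = np.asarray(self.hidden_bias, float)
        self.weights = np.asarray(self.weights, float)
        nv, nh = self.weights.shape
        if self.visible_bias.shape != (nv,) or self.hidden_bias.shape != (nh,):
            raise ConfigurationError("RBM bias/weight shapes are inconsistent")
        if nh >= nv:
            raise ConfigurationError(
                f"hidden layer ({nh}) must be smaller than the visible layer ({nv})"
            )
        if self.output_weights is None:
            self.output_weights = np.zeros(nh)
        for arr in (self.visible_bias, self.hidden_bias, self.weights):
            if not np.all(np.isfinite(arr)):
                raise ConfigurationError("RBM parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.weights.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class TrainConfig:
    cd_steps: int = 1
    learning_rate: float = 0.05
    epochs: int = 30
    batch_size: int = 16
    seed: int = 0
    finetune_epochs: int = 1000
    finetune_lr: float = 0.5
    finetune_l2: float = 1.0
    n_hidden: int | None = None
    log_exact_likelihood: bool = True

    def __post_init__(self) -> None:
        for name in ("cd_steps", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"train.{name} must be >= 1")
        for name in ("learning_rate", "finetune_lr"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"train.{name} must be > 0")
        if self.finetune_epochs < 0:
            raise ConfigurationError("train.finetune_epochs must be >= 0")
        if self.finetune_l2 < 0:
            raise ConfigurationError("train.finetune_l2 must be >= 0")


def sigmoid(k):
    """Logistic function 1 / (1 + e^-k)."""
    return expit(k)


def _as_matrix(samples) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([s.m for s in samples])
    y = np.array([s.label for s in samples], dtype=float)
    return X, y


def hidden_forward(m, params: RBMParams, variant: str = "standard") -> np.ndarray:
    """Hidden activation p_e = sigma(sum_i m_i theta_ie + beta_e)."""
    x = m.m if isinstance(m, FusedSample) else np.asarray(m, float)
    if x.shape[-1] != params.n_visible:
        raise ConfigurationError(
            f"sample length {x.shape[-1]} != visible units {params.n_visible}"
        )
    if variant == "standard":
        return sigmoid(x @ params.weights + params.hidden_bias)
    if variant == "printed":
        return sigmoid((x + params.visible_bias) @ params.weights + params.hidden_bias)
    raise ConfigurationError(f"unknown variant {variant!r}")


def energy(x, y, params: RBMParams, variant: str = "standard") -> float:
    """Joint energy of visible state x and hidden state y."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    bias_terms = -float(params.visible_bias @ x) - float(params.hidden_bias @ y)
    if variant == "standard":
        interaction = -float(x @ params.weights @ y)
    elif variant == "printed":
        # bias enters the interaction in place of the visible state
        interaction = -float(params.visible_bias @ params.weights @ y)
    else:
        raise ConfigurationError(f"unknown variant {variant!r}")
    return bias_terms + interaction


def enumerate_states(n: int) -> np.ndarray:
    """All 2^n binary vectors of length n, lexicographic order."""
    idx = np.arange(2 ** n)
    return ((idx[:, None] >> np.arange(n - 1, -1, -1)) & 1).astype(float)


def _check_exact(params: RBMParams) -> None:
    total = params.n_visible + params.n_hidden
    if total > EXACT_UNIT_LIMIT:
        raise ExactModeError(
            f"exact enumeration limited to {EXACT_UNIT_LIMIT} total units, "
            f"model has {total}"
        )


def _neg_energy_table(params: RBMParams) -> np.ndarray:
    """-E(x, y) for every joint state, shape (2^nv, 2^nh)."""
    X = enumerate_states(params.n_visible)
    Y = enumerate_states(params.n_hidden)
    return (X @ params.visible_bias)[:, None] + (Y @ params.hidden_bias)[None, :] \
        + X @ params.weights @ Y.T


def exact_marginals(params: RBMParams) -> tuple[np.ndarray, np.ndarray]:
    """Exact marginals p(x) and p(y) by joint enumeration.

    Rows follow :func:`enumerate_states` order.  Refuses models with more
    than ``EXACT_UNIT_LIMIT`` total units.
    """
    _check_exact(params)
    neg_e = _neg_energy_table(params)
    log_z = logsumexp(neg_e)
    px = np.exp(logsumexp(neg_e, axis=1) - log_z)
    py = np.exp(logsumexp(neg_e, axis=0) - log_z)
    return px, py


def free_energy(X: np.ndarray, params: RBMParams) -> np.ndarray:
    """F(v) = -t.v - sum_e softplus(beta_e + v.theta_e); log p = -F - log Z."""
    X = np.atleast_2d(np.asarray(X, float))
    act = X @ params.weights + params.hidden_bias
    return -(X @ params.visible_bias) - np.logaddexp(0.0, act).sum(axis=1)


def exact_log_likelihood(X, params: RBMParams) -> float:
    """Mean log p(x) over rows of X, with log Z by visible enumeration."""
    if params.n_visible > EXACT_UNIT_LIMIT:
        raise ExactModeError(
            f"exact log-likelihood needs <= {EXACT_UNIT_LIMIT} visible units"
        )
    all_v = enumerate_states(params.n_visible)
    log_z = logsumexp(-free_energy(all_v, params))
    return float(np.mean(-free_energy(X, params) - log_z))


def sample_from_model(params: RBMParams, n: int, seed: int = 0) -> np.ndarray:
    """Draw exact i.i.d. binary visible samples (small models only)."""
    _check_exact(params)
    px, _ = exact_marginals(params)
    rng = np.random.default_rng(seed)
    idx = rng.choice(px.shape[0], size=n, p=px)
    return enumerate_states(params.n_visible)[idx]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _cd_update(X: np.ndarray, params: RBMParams, lr: float, k: int,
               rng: np.random.Generator) -> None:
    """One CD-k gradient ascent step on a minibatch (in place)."""
    n = X.shape[0]
    ph0 = sigmoid(X @ params.weights + params.hidden_bias)
    v = X
    ph = ph0
    for _ in range(k):
        h = (rng.random(ph.shape) < ph).astype(float)
        v = sigmoid(h @ params.weights.T + params.visible_bias)
        ph = sigmoid(v @ params.weights + params.hidden_bias)
    params.weights += lr * (X.T @ ph0 - v.T @ ph) / n
    params.visible_bias += lr * (X - v).mean(axis=0)
    params.hidden_bias += lr * (ph0 - ph).mean(axis=0)


def train(samples, config: TrainConfig) -> RBMParams:
    """Two-phase training: unsupervised CD, then supervised logistic head.

    Phase 1 ascends the RBM log-likelihood of the visible vectors with
    contrastive divergence; labels are not used.  Phase 2 fits the
    hidden-to-output logistic unit by full-batch cross-entropy gradient
    descent.  Fully deterministic given ``config.seed``.  When the model is
    small enough for exact enumeration, the exact mean log-likelihood per
    epoch is recorded in ``params.history['log_likelihood']``.
    """
    if len(samples) < 2:
        raise ConfigurationError("training needs at least 2 samples")
    X, y = _as_matrix(samples)
    nv = X.shape[1]
    nh = config.n_hidden if config.n_hidden is not None else max(2, min(32, nv - 1))
    if nh >= nv:
        raise ConfigurationError(
            f"n_hidden ({nh}) must be less than the feature dimension ({nv})"
        )
    rng = np.random.default_rng(config.seed)
    params = RBMParams(
        visible_bias=np.zeros(nv),
        hidden_bias=np.zeros(nh),
        # 1/sqrt(nv) keeps initial hidden activations in the responsive
        # part of the sigmoid for [0,1]-valued visibles
        weights=rng.normal(0.0, 1.0 / np.sqrt(nv), size=(nv, nh)),
    )
    track = config.log_exact_likelihood and nv + nh <= EXACT_UNIT_LIMIT
    ll_log: list[float] = []
    if track:
        ll_log.append(exact_log_likelihood(X, params))
    for _ in range(config.epochs):
        order = rng.permutation(X.shape[0])
        for start in range(0, X.shape[0], config.batch_size):
            batch = X[order[start:start + config.batch_size]]
            _cd_update(batch, params, config.learning_rate, config.cd_steps, rng)
        if track:
            ll_log.append(exact_log_likelihood(X, params))
    params.history["log_likelihood"] = ll_log

    # Phase 2: supervised logistic head on the hidden activations.
    if config.finetune_epochs > 0:
        classes = set(int(v) for v in y)
        if classes != {0, 1}:
            raise ConfigurationError(
                "supervised fine-tune needs both classes present in the labels"
            )
        H = sigmoid(X @ params.weights + params.hidden_bias)
        # standardize hidden activations for the fit (so the L2 penalty acts
        # on a common scale), then fold the standardization back into w, b
        mu = H.mean(axis=0)
        sd = H.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Hs = (H - mu) / sd
        w = np.zeros(nh)
        b = 0.0
        n = Hs.shape[0]
        # mean cross-entropy + (l2 / 2n) ||w||^2, full-batch gradient descent
        for _ in range(config.finetune_epochs):
            p = sigmoid(Hs @ w + b)
            err = p - y
            w -= config.finetune_lr * ((Hs.T @ err) + config.finetune_l2 * w) / n
            b -= config.finetune_lr * float(err.mean())
        params.output_weights = w / sd
        params.output_bias = b - float((w * mu / sd).sum())
    params.trained = True
    return params


def predict(m, params: RBMParams) -> tuple[float, int]:
    """Tear probability W and the binary call (positive iff W >= 0.5)."""
    if not params.trained:
        raise UntrainedModelError("predict called with untrained RBM parameters")
    p_e = hidden_forward(m, params)
    w = float(sigmoid(p_e @ params.output_weights + params.output_bias))
    return w, int(w >= 0.5)


def predict_batch(X: np.ndarray, params: RBMParams) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`predict` over rows of X."""
    if not params.trained:
        raise UntrainedModelError("predict called with untrained RBM parameters")
    H = sigmoid(np.atleast_2d(X) @ params.weights + params.hidden_bias)
    probs = sigmoid(H @ params.output_weights + params.output_bias)
    return probs, (probs >= 0.5).astype(int)
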