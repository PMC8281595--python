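"""Per-omic nonlinear dimension reduction with a one-hidden-layer autoencoder.

Each omic layer's distance-feature matrix (values in [0, 1]) is compressed
through a bottleneck of ``hidden_size`` units (default 100):

    reconstruction(v) = tanh(W' . s(W v + b) + b')

with ``s = tanh`` by default. Because the output activation lives on
[-1, 1] while inputs live on [0, 1], the reconstruction is mapped through
``(y + 1) / 2`` and trained against an element-wise binary cross-entropy
(mean squared error available behind ``loss="mse"``). Training uses Adam,
10 epochs, 50% dropout on the hidden layer (weight dropout — zeroing 50%
of W and W' entries each step — behind ``weight_dropout=True``), gradient
clipping at global norm 5, and is bit-reproducible given a seed.

The network is intentionally tiny: its input dimension equals the number of
training samples (a few hundred), so full-batch numpy training is fast and
has no framework dependency. A linear PCA projector with the same encoding
contract is provided as an alternative backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .normalization import DistanceFeatureMatrix

DEFAULT_HIDDEN = 100
DEFAULT_EPOCHS = 10
DEFAULT_DROPOUT = 0.5

_ACTIVATIONS = {
    "tanh": (np.tanh, lambda a: 1.0 - a**2),
    "sigmoid": (
        lambda z: 1.0 / (1.0 + np.exp(-z)),
        lambda a: a * (1.0 - a),
    ),
    "relu": (
        lambda z: np.maximum(z, 0.0),
        lambda a: (a > 0).astype(float),
    ),
}


@dataclass
class EncoderState:
    """Fitted autoencoder weights plus the training log."""

    omic_tag: str
    W: np.ndarray  # hidden x input
    W_prime: np.ndarray  # input x hidden
    b: np.ndarray  # hidden
    b_prime: np.ndarray  # input
    hidden_size: int
    input_dim: int
    hidden_activation: str
    loss_history: list[float] = field(default_factory=list)
    seed: int = 0


@dataclass
class LatentMatrix:
    """Bottleneck representation: samples x hidden latent features."""

    sample_ids: list[str]
    latent_ids: list[str]  # "<omic_tag>.<index>", unique across omics
    values: np.ndarray


def _as_array(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, DistanceFeatureMatrix):
        return np.asarray(X.values, dtype=float), list(X.sample_ids)
    arr = np.asarray(X, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


def _clip_gradients(grads: list[np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g**2).sum()) for g in grads))
    if total > max_norm:
        scale = max_norm / total
        for g in grads:
            g *= scale


def fit_autoencoder(
    X,
    omic_tag: str = "",
    hidden_size: int = DEFAULT_HIDDEN,
    epochs: int = DEFAULT_EPOCHS,
    dropout: float = DEFAULT_DROPOUT,
    seed: int = 0,
    learning_rate: float = 1e-3,
    activation: str = "tanh",
    loss: str = "bce",
    weight_dropout: bool = False,
    clip_norm: float = 5.0,
) -> EncoderState:
    """Train the autoencoder on a [0, 1]-valued matrix (samples x features).

    Full batch for n <= 512 samples, mini-batches of 128 otherwise. The fit
    is a pure function of ``(X, hyperparameters, seed)``.
    """
    values, _ = _as_array(X)
    if not (0 <= dropout < 1):
        raise ValueError("dropout must be in [0, 1)")
    if hidden_size < 1:
        raise ValueError("hidden_size must be >= 1")
    if not np.all(np.isfinite(values)):
        raise ValueError("input contains non-finite values")
    act, act_grad = _ACTIVATIONS[activation]
    n, m = values.shape
    rng = np.random.default_rng(seed)

    lim1 = np.sqrt(6.0 / (m + hidden_size))
    lim2 = np.sqrt(6.0 / (hidden_size + m))
    W = rng.uniform(-lim1, lim1, size=(hidden_size, m))
    Wp = rng.uniform(-lim2, lim2, size=(m, hidden_size))
    b = np.zeros(hidden_size)
    bp = np.zeros(m)

    params = [W, Wp, b, bp]
    adam_m = [np.zeros_like(p) for p in params]
    adam_v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    batch = n if n <= 512 else 128
    history: list[float] = []

    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch):
            xb = values[order[start : start + batch]]
            nb = xb.shape[0]
            if weight_dropout and dropout > 0:
                mask_W = (rng.random(W.shape) >= dropout).astype(float)
                mask_Wp = (rng.random(Wp.shape) >= dropout).astype(float)
                W_eff, Wp_eff = W * mask_W, Wp * mask_Wp
            else:
                mask_W = mask_Wp = None
                W_eff, Wp_eff = W, Wp

            hidden = act(xb @ W_eff.T + b)
            if not weight_dropout and dropout > 0:
                drop = (rng.random(hidden.shape) >= dropout).astype(float)
                hidden = hidden * drop / (1.0 - dropout)
            z_out = hidden @ Wp_eff.T + bp
            yhat = (np.tanh(z_out) + 1.0) / 2.0
            yc = np.clip(yhat, 1e-7, 1.0 - 1e-7)
            if loss == "bce":
                batch_loss = float(
                    -np.mean(xb * np.log(yc) + (1.0 - xb) * np.log(1.0 - yc))
                )
                # d/dz of BCE with y = (tanh(z)+1)/2 collapses to 2(y - x)
                dz = 2.0 * (yhat - xb) / (nb * m)
            elif loss == "mse":
                batch_loss = float(np.mean((yhat - xb) ** 2))
                dz = (yhat - xb) * 4.0 * yhat * (1.0 - yhat) / (nb * m)
            else:
                raise ValueError(f"unknown loss '{loss}'")
            epoch_loss += batch_loss * nb

            g_Wp = dz.T @ hidden
            g_bp = dz.sum(axis=0)
            dh = dz @ Wp_eff
            if not weight_dropout and dropout > 0:
                dh = dh * drop / (1.0 - dropout)
            dzh = dh * act_grad(hidden)
            g_W = dzh.T @ xb
            g_b = dzh.sum(axis=0)
            if mask_W is not None:
                g_W *= mask_W
                g_Wp *= mask_Wp

            grads = [g_W, g_Wp, g_b, g_bp]
            _clip_gradients(grads, clip_norm)
            step += 1
            for p, g, mo, vo in zip(params, grads, adam_m, adam_v):
                mo += (1 - beta1) * (g - mo)
                vo += (1 - beta2) * (g**2 - vo)
                m_hat = mo / (1 - beta1**step)
                v_hat = vo / (1 - beta2**step)
                p -= learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        history.append(epoch_loss / n)

    return EncoderState(
        omic_tag=omic_tag,
        W=W,
        W_prime=Wp,
        b=b,
        b_prime=bp,
        hidden_size=hidden_size,
        input_dim=m,
        hidden_activation=activation,
        loss_history=history,
        seed=seed,
    )


def encode(state: EncoderState, X) -> LatentMatrix:
    """Bottleneck activations ``s(W x + b)`` (dropout off at inference)."""
    values, sample_ids = _as_array(X)
    if values.shape[1] != state.input_dim:
        raise ValueError(
            f"input has {values.shape[1]} features, encoder expects {state.input_dim}"
        )
    act, _ = _ACTIVATIONS[state.hidden_activation]
    latent = act(values @ state.W.T + state.b)
    ids = [f"{state.omic_tag}.{i}" for i in range(state.hidden_size)]
    return LatentMatrix(sample_ids=sample_ids, latent_ids=ids, values=latent)


def reconstruct(state: EncoderState, X) -> np.ndarray:
    """Full forward pass mapped back to [0, 1]; used for loss diagnostics."""
    values, _ = _as_array(X)
    act, _ = _ACTIVATIONS[state.hidden_activation]
    hidden = act(values @ state.W.T + state.b)
    return (np.tanh(hidden @ state.W_prime.T + state.b_prime) + 1.0) / 2.0


@dataclass
class PCAProjector:
    """Linear stand-in for the autoencoder with the same encoding contract."""

    omic_tag: str
    model: PCA
    hidden_size: int
    input_dim: int

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.model.explained_variance_ratio_


def fit_pca_embedding(X, k: int, omic_tag: str = "") -> PCAProjector:
    values, _ = _as_array(X)
    n, m = values.shape
    if k > min(n - 1, m):
        raise ValueError(f"k={k} exceeds min(n_samples - 1, n_features) = {min(n - 1, m)}")
    model = PCA(n_components=k, svd_solver="full").fit(values)
    return PCAProjector(omic_tag=omic_tag, model=model, hidden_size=k, input_dim=m)


def encode_pca(state: PCAProjector, X) -> LatentMatrix:
    values, sample_ids = _as_array(X)
    latent = state.model.transform(values)
    ids = [f"{state.omic_tag}.{i}" for i in range(state.hidden_size)]
    return LatentMatrix(sample_ids=sample_ids, latent_ids=ids, values=latent)
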