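"""Multimodal contrastive alignment into a shared latent space.

Three modality encoders -- morphology (aggregated slide bag), clinico-
molecular, and AI-inferred transcriptomic -- project each patient into a
common ``embed_dim``-dimensional space (512 by default).  Training minimises
a symmetric InfoNCE objective summed over the three modality pairs: within a
mini-batch, the embeddings of the *same* patient across two modalities are
the positive pair and all other patients are negatives, under a temperature-
scaled cosine-similarity softmax.  No outcome labels enter this stage; the
API has no label parameter.

The per-patient unified embedding is the L2-normalised average of the
available modality projections (re-normalised), which degrades gracefully to
image-only inference where the molecular modality is absent.

Everything here is plain NumPy: the encoders are small MLPs with explicit
forward/backward passes and an Adam optimiser, sized for CPU training on
desk-scale cohorts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

MODALITIES = ("morphology", "molecular", "transcriptomic")
#: Unordered modality pairs, in the fixed order used by ``pair_weights``.
MODALITY_PAIRS = (
    ("morphology", "molecular"),
    ("morphology", "transcriptomic"),
    ("molecular", "transcriptomic"),
)
DEFAULT_EMBED_DIM = 512


@dataclass
class EncoderSpec:
    modality: str
    input_dim: int
    hidden_dims: list[int] = field(default_factory=list)
    embed_dim: int = DEFAULT_EMBED_DIM
    activation: str = "relu"
    dropout: float = 0.0


@dataclass
class AlignmentConfig:
    temperature: float = 0.07
    learnable_temperature: bool = True
    batch_size: int = 128
    epochs: int = 100
    learning_rate: float = 1e-2
    weight_decay: float = 0.1
    optimizer: str = "adam"
    pair_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    fusion: str = "average"  # or "concat_linear"
    seed: int = 0

    def validate(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature!r}")
        w = np.asarray(self.pair_weights, dtype=float)
        if w.shape != (3,) or (w < 0).any() or not w.any():
            raise ValueError(
                "pair_weights must be three non-negative weights, not all zero"
            )
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (contrastive loss degenerate)")


@dataclass
class TrinityEmbedding:
    """Unified fused patient vector in the shared latent space (unit norm)."""

    patient_id: str
    vector: np.ndarray
    modalities_used: tuple[str, ...]


# ---------------------------------------------------------------------------
# InfoNCE
# ---------------------------------------------------------------------------


def _row_normalize(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    norms = np.maximum(norms, 1e-12)
    return Z / norms, norms


def _softmax(S: np.ndarray, axis: int) -> np.ndarray:
    e = np.exp(S - S.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def _info_nce_pair_grad(
    Za: np.ndarray, Zb: np.ndarray, temperature: float
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Symmetric InfoNCE loss plus gradients w.r.t. Za, Zb and temperature."""
    Za = np.asarray(Za, dtype=float)
    Zb = np.asarray(Zb, dtype=float)
    if Za.shape != Zb.shape or Za.ndim != 2:
        raise ValueError(f"shape mismatch: {Za.shape} vs {Zb.shape}")
    if not (np.isfinite(Za).all() and np.isfinite(Zb).all()):
        raise ValueError("non-finite embedding input")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    N = Za.shape[0]
    An, na = _row_normalize(Za)
    Bn, nb = _row_normalize(Zb)
    C = An @ Bn.T  # cosine similarities
    S = C / temperature
    P = _softmax(S, axis=1)  # a -> b retrieval
    Q = _softmax(S, axis=0)  # b -> a retrieval
    diag = np.arange(N)
    loss = -0.5 / N * (
        np.log(np.maximum(P[diag, diag], 1e-300)).sum()
        + np.log(np.maximum(Q[diag, diag], 1e-300)).sum()
    )
    eye = np.eye(N)
    dS = 0.5 / N * ((P - eye) + (Q - eye))
    dAn = (dS @ Bn) / temperature
    dBn = (dS.T @ An) / temperature
    # back through row normalisation: d(z/|z|) = (I - zz^T/|z|^2)/|z|
    dZa = (dAn - (dAn * An).sum(axis=1, keepdims=True) * An) / na
    dZb = (dBn - (dBn * Bn).sum(axis=1, keepdims=True) * Bn) / nb
    # dL/dtau = sum_ij dL/dS_ij * dS_ij/dtau with S = C / tau
    dtau = float((dS * (-C / temperature**2)).sum())
    return float(loss), dZa, dZb, dtau


def info_nce_pair(Za: np.ndarray, Zb: np.ndarray, temperature: float = 0.07) -> float:
    """Symmetric InfoNCE loss between two patient-aligned embedding matrices.

    Rows are L2-normalised internally; similarity is cosine over
    ``temperature``; the loss is the average of the a->b and b->a softmax
    cross-entropies with the matching row as the target.  Always >= 0;
    equals 0 at N = 1 and ln N when every row is identical in both views.
    """
    loss, _, _, _ = _info_nce_pair_grad(Za, Zb, temperature)
    return loss


def multimodal_loss(
    Zm: np.ndarray,
    Zc: np.ndarray,
    Zt: np.ndarray,
    config: AlignmentConfig | None = None,
) -> float:
    """Weighted sum of the pairwise InfoNCE losses over the three pairs."""
    config = config if config is not None else AlignmentConfig()
    config.validate()
    views = {"morphology": Zm, "molecular": Zc, "transcriptomic": Zt}
    total = 0.0
    for w, (a, b) in zip(config.pair_weights, MODALITY_PAIRS):
        if w:
            total += w * info_nce_pair(views[a], views[b], config.temperature)
    return total


# ---------------------------------------------------------------------------
# MLP encoder with explicit backprop
# ---------------------------------------------------------------------------


class MLPEncoder:
    """Small fully connected encoder with manual forward/backward passes."""

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        self.spec = spec
        dims = [spec.input_dim, *spec.hidden_dims, spec.embed_dim]
        self.W = []
        self.b = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            # He-style initialisation for ReLU layers
            self.W.append(rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in))
            self.b.append(np.zeros(d_out))
        self._cache: list[np.ndarray] = []
        self._masks: list[np.ndarray | None] = []

    @property
    def params(self) -> list[np.ndarray]:
        return [*self.W, *self.b]

    def _act(self, x: np.ndarray) -> np.ndarray:
        if self.spec.activation == "relu":
            return np.maximum(x, 0.0)
        if self.spec.activation == "tanh":
            return np.tanh(x)
        raise ValueError(f"unknown activation {self.spec.activation!r}")

    def _act_grad(self, h: np.ndarray) -> np.ndarray:
        if self.spec.activation == "relu":
            return (h > 0).astype(float)
        return 1.0 - h**2  # tanh

    def forward(
        self, X: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        self._cache = [np.asarray(X, dtype=float)]
        self._masks = []
        h = self._cache[0]
        n_layers = len(self.W)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if i < n_layers - 1:
                h = self._act(z)
                if train and self.spec.dropout > 0:
                    mask = (rng.random(h.shape) >= self.spec.dropout) / (
                        1.0 - self.spec.dropout
                    )
                    h = h * mask
                    self._masks.append(mask)
                else:
                    self._masks.append(None)
            else:
                h = z
            self._cache.append(h)
        return h

    def backward(self, dout: np.ndarray) -> list[np.ndarray]:
        """Gradients for [W..., b...] given dL/d(output); uses cached forward."""
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.b)
        d = dout
        for i in reversed(range(len(self.W))):
            h_in = self._cache[i]
            if i < len(self.W) - 1:
                h_out = self._cache[i + 1]
                mask = self._masks[i]
                if mask is not None:
                    d = d * mask
                    h_out = h_out / np.where(mask == 0, 1.0, mask)  # pre-dropout
                d = d * self._act_grad(h_out)
            grads_W[i] = h_in.T @ d
            grads_b[i] = d.sum(axis=0)
            if i > 0:
                d = d @ self.W[i].T
        return [*grads_W, *grads_b]


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class EncoderBundle:
    """Trained encoders plus input standardisation and the alignment config."""

    encoders: dict[str, MLPEncoder]
    config: AlignmentConfig
    input_means: dict[str, np.ndarray]
    input_sds: dict[str, np.ndarray]
    temperature: float
    loss_curve: list[float] = field(default_factory=list)

    @property
    def embed_dim(self) -> int:
        return next(iter(self.encoders.values())).spec.embed_dim

    def project(self, modality: str, X: np.ndarray) -> np.ndarray:
        """Project raw modality features into the shared space (unit rows)."""
        Xz = (np.asarray(X, float) - self.input_means[modality]) / self.input_sds[
            modality
        ]
        Z = self.encoders[modality].forward(Xz, train=False)
        Zn, _ = _row_normalize(Z)
        return Zn

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays: dict[str, np.ndarray] = {}
        for mod, enc in self.encoders.items():
            for i, W in enumerate(enc.W):
                arrays[f"{mod}_W{i}"] = W
            for i, b in enumerate(enc.b):
                arrays[f"{mod}_b{i}"] = b
            arrays[f"{mod}_mean"] = self.input_means[mod]
            arrays[f"{mod}_sd"] = self.input_sds[mod]
        np.savez(path, **arrays)
        sidecar = {
            "config": {**asdict(self.config), "pair_weights": list(self.config.pair_weights)},
            "temperature": self.temperature,
            "loss_curve": self.loss_curve,
            "specs": {m: asdict(e.spec) for m, e in self.encoders.items()},
        }
        Path(str(path) + ".json").write_text(
            json.dumps(sidecar, indent=2) + "\n", encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "EncoderBundle":
        sidecar = json.loads(Path(str(path) + ".json").read_text(encoding="utf-8"))
        cfg = sidecar["config"]
        cfg["pair_weights"] = tuple(cfg["pair_weights"])
        config = AlignmentConfig(**cfg)
        data = np.load(path)
        encoders, means, sds = {}, {}, {}
        rng = np.random.default_rng(0)
        for mod, spec_dict in sidecar["specs"].items():
            spec = EncoderSpec(**spec_dict)
            enc = MLPEncoder(spec, rng)
            enc.W = [data[f"{mod}_W{i}"] for i in range(len(enc.W))]
            enc.b = [data[f"{mod}_b{i}"] for i in range(len(enc.b))]
            encoders[mod] = enc
            means[mod] = data[f"{mod}_mean"]
            sds[mod] = data[f"{mod}_sd"]
        return cls(
            encoders=encoders,
            config=config,
            input_means=means,
            input_sds=sds,
            temperature=sidecar["temperature"],
            loss_curve=sidecar["loss_curve"],
        )


def train_alignment(
    views: dict[str, np.ndarray],
    specs: dict[str, EncoderSpec] | None = None,
    config: AlignmentConfig | None = None,
) -> EncoderBundle:
    """Train the three encoders contrastively on patient-aligned views.

    ``views`` maps each modality name to an ``n_patients x input_dim`` matrix
    with rows aligned across modalities (same patient order).  There is
    deliberately no label argument: this stage never sees HRD status.

    Mini-batches are sampled without replacement each epoch with the last
    short batch dropped (contrastive quality depends on batch size); the
    temperature is learnable (via its log) unless disabled.  Deterministic
    given ``config.seed``.  Returns the bundle with the per-epoch mean loss
    curve attached.
    """
    config = config if config is not None else AlignmentConfig()
    config.validate()
    if set(views) != set(MODALITIES):
        raise ValueError(f"views must cover exactly {MODALITIES}, got {set(views)}")
    n = next(iter(views.values())).shape[0]
    for mod, X in views.items():
        if X.shape[0] != n:
            raise ValueError("modality views are not patient-aligned")
    if specs is None:
        specs = {
            mod: EncoderSpec(modality=mod, input_dim=views[mod].shape[1])
            for mod in MODALITIES
        }
    embed_dims = {s.embed_dim for s in specs.values()}
    if len(embed_dims) != 1:
        raise ValueError(f"embed_dim must be identical across encoders: {embed_dims}")

    rng = np.random.default_rng(config.seed)
    means = {m: views[m].mean(axis=0) for m in MODALITIES}
    sds = {
        m: np.where(views[m].std(axis=0) > 0, views[m].std(axis=0), 1.0)
        for m in MODALITIES
    }
    Xz = {m: (views[m] - means[m]) / sds[m] for m in MODALITIES}
    encoders = {m: MLPEncoder(specs[m], rng) for m in MODALITIES}
    opt = {
        m: Adam(encoders[m].params, config.learning_rate) for m in MODALITIES
    }
    log_tau = np.log(config.temperature)
    tau_state = [0.0, 0.0]  # Adam moments for log-temperature

    batch = min(config.batch_size, n)
    if batch < 2:
        raise ValueError("need at least 2 patients for contrastive training")
    loss_curve: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n - batch + 1, batch):
            idx = order[start : start + batch]
            tau = float(np.exp(log_tau))
            Z = {
                m: encoders[m].forward(Xz[m][idx], train=True, rng=rng)
                for m in MODALITIES
            }
            dZ = {m: np.zeros_like(Z[m]) for m in MODALITIES}
            batch_loss, dtau_total = 0.0, 0.0
            for w, (a, b) in zip(config.pair_weights, MODALITY_PAIRS):
                if not w:
                    continue
                loss, dZa, dZb, dtau = _info_nce_pair_grad(Z[a], Z[b], tau)
                batch_loss += w * loss
                dZ[a] += w * dZa
                dZ[b] += w * dZb
                dtau_total += w * dtau
            for m in MODALITIES:
                grads = encoders[m].backward(dZ[m])
                if config.weight_decay:
                    n_w = len(encoders[m].W)
                    for j in range(n_w):  # decay weights, not biases
                        grads[j] = grads[j] + config.weight_decay * encoders[m].W[j]
                opt[m].step(encoders[m].params, grads)
            if config.learnable_temperature:
                g = dtau_total * tau  # d/d(log tau)
                tau_state[0] = 0.9 * tau_state[0] + 0.1 * g
                tau_state[1] = 0.999 * tau_state[1] + 0.001 * g**2
                log_tau -= (
                    config.learning_rate
                    * tau_state[0]
                    / (np.sqrt(tau_state[1]) + 1e-8)
                )
                log_tau = float(np.clip(log_tau, np.log(1e-3), np.log(10.0)))
            epoch_losses.append(batch_loss)
        mean_loss = float(np.mean(epoch_losses)) if epoch_losses else float("nan")
        loss_curve.append(mean_loss)
        logger.debug("alignment epoch %d: loss %.4f", epoch, mean_loss)

    return EncoderBundle(
        encoders=encoders,
        config=config,
        input_means=means,
        input_sds=sds,
        temperature=float(np.exp(log_tau)),
        loss_curve=loss_curve,
    )


# ---------------------------------------------------------------------------
# Fusion and cohort embedding
# ---------------------------------------------------------------------------


def fuse(
    projections: dict[str, np.ndarray],
    patient_id: str = "",
    available: tuple[str, ...] | None = None,
) -> TrinityEmbedding:
    """Fuse per-modality projections into one unit-norm patient vector.

    Each available projection is L2-normalised, the normalised vectors are
    averaged, and the average is re-normalised.  With one modality this is
    that modality's normalised projection.  Antipodal inputs whose average
    vanishes cannot be normalised and raise.
    """
    mods = tuple(available) if available is not None else tuple(sorted(projections))
    if not mods:
        raise ValueError("at least one modality is required")
    vecs = []
    for m in mods:
        v = np.asarray(projections[m], dtype=float).ravel()
        norm = np.linalg.norm(v)
        if norm <= 0:
            raise ValueError(f"zero-length projection for modality {m!r}")
        vecs.append(v / norm)
    avg = np.mean(vecs, axis=0)
    norm = np.linalg.norm(avg)
    if norm < 1e-12:
        raise ValueError("modality projections cancel; cannot normalise fusion")
    return TrinityEmbedding(
        patient_id=patient_id, vector=avg / norm, modalities_used=mods
    )


def embed_cohort(
    bundle: EncoderBundle,
    views: dict[str, np.ndarray],
    patient_ids: list[str],
    required: tuple[str, ...] = ("morphology", "transcriptomic"),
) -> list[TrinityEmbedding]:
    """Project and fuse a cohort; supports image-only inference.

    ``views`` may omit modalities (e.g. ``molecular`` absent when classifying
    from a slide image alone); the modalities listed in ``required`` must be
    present, otherwise an error names the absences.
    """
    missing = [m for m in required if m not in views]
    if missing:
        raise ValueError(f"missing mandatory modalities: {missing}")
    available = tuple(m for m in MODALITIES if m in views)
    proj = {m: bundle.project(m, views[m]) for m in available}
    out = []
    for i, pid in enumerate(patient_ids):
        out.append(
            fuse({m: proj[m][i] for m in available}, patient_id=pid, available=available)
        )
    return out


def embeddings_to_matrix(embeddings: list[TrinityEmbedding]) -> np.ndarray:
    return np.vstack([e.vector for e in embeddings])


def retrieval_top1_accuracy(Za: np.ndarray, Zb: np.ndarray) -> float:
    """Fraction of rows of Za whose nearest Zb row (cosine) is the same patient."""
    An, _ = _row_normalize(np.asarray(Za, float))
    Bn, _ = _row_normalize(np.asarray(Zb, float))
    nearest = (An @ Bn.T).argmax(axis=1)
    return float((nearest == np.arange(len(nearest))).mean())
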