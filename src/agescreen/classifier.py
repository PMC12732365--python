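"""Cell-age classifiers behind a uniform P(old) contract.

Two backends are provided:

``mlp_head``
    A trainable surrogate encoder plus the classification head used for
    fine-tuning. Each (gene, expression-bin) pair is embedded as

        e(g, b) = gene_emb[g] + bin_emb[b] + gene_mod[g] * bin_value[b]

    and cell embeddings are the average of e(g, token[g]) over genes. The
    multiplicative value-modulation term is essential under mean pooling:
    a purely additive gene table contributes a constant to every cell, so
    without modulation the pooled embedding would collapse to the token
    histogram and lose which gene carries which token. ``bin_value`` is
    initialized as a monotone ramp in the bin index (a pretrained encoder
    represents expression magnitude smoothly), making the pooled vector a
    random linear sketch of the cell's expression profile from the start.
    The head is: layer normalization, then five 1024-unit linear layers
    interleaved with GELU and dropout 0.4, then a single logit. Training
    minimizes class-weighted binary cross-entropy on logits with AdamW
    (lr 1e-4, weight decay 1e-7) for 20 epochs at batch size 256. The
    classifier contract is backend-agnostic, so a richer pretrained
    encoder can be slotted in behind the same interface.

``logistic``
    The linear baseline: per-gene token values standardized with training
    statistics, then L1-penalized logistic regression at the default
    regularization strength (C = 1).

Both backends expose ``predict_old_prob`` returning one probability in
(0, 1) per cell (clamped away from exact 0/1 so downstream log-ratios are
finite) and a vectorized ``perturbation_probs`` used by the screen.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erf, expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .preprocess import BinnedMatrix

__all__ = [
    "TrainConfig",
    "AgeClassifier",
    "MLPHeadClassifier",
    "LogisticClassifier",
    "class_weights",
    "fit_mlp_head",
    "fit_logistic_baseline",
    "predict_old_prob",
    "evaluate_auc",
    "save_model",
    "load_model",
]

PROB_CLAMP = 1e-12
_LN_EPS = 1e-5
_PREDICT_CHUNK = 8192


@dataclass
class TrainConfig:
    """Hyperparameters of the MLP-head backend (defaults are the training
    recipe used throughout: 5 x 1024 GELU head, dropout 0.4, 20 epochs,
    batch 256, AdamW lr 1e-4 / weight decay 1e-7)."""

    embed_dim: int = 256
    n_hidden_layers: int = 5
    hidden_units: int = 1024
    dropout: float = 0.4
    gene_bag_drop: float = 0.0
    epochs: int = 20
    batch_size: int = 256
    learning_rate: float = 1e-4
    weight_decay: float = 1e-7
    seed: int = 0

    def __post_init__(self):
        if min(self.embed_dim, self.n_hidden_layers, self.hidden_units, self.epochs,
               self.batch_size) <= 0 or self.learning_rate <= 0:
            raise ValueError("architecture and optimizer sizes must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if not 0 <= self.gene_bag_drop < 1:
            raise ValueError("gene_bag_drop must be in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")


def class_weights(labels) -> tuple[float, float]:
    """Inverse-frequency class weights ``w_c = n_total / (2 n_c)`` for the
    (mid, old) classes; with these, per-class weighted loss contributions
    are balanced regardless of label imbalance."""
    labels = np.asarray(labels, dtype=object).astype(str)
    n_mid = int((labels == "mid").sum())
    n_old = int((labels == "old").sum())
    if n_mid == 0 or n_old == 0:
        raise ValueError("both classes must be present to compute class weights")
    n = n_mid + n_old
    return n / (2.0 * n_mid), n / (2.0 * n_old)


def _gelu(x):
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0, dtype=x.dtype)))


def _gelu_grad(x):
    cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0, dtype=x.dtype)))
    pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi).astype(x.dtype)
    return cdf + x * pdf


class AgeClassifier:
    """Fitted cell-age model: maps binned expression to P(old) per cell."""

    backend: str

    def __init__(self, gene_symbols: pd.Index, n_bins: int):
        self.gene_symbols = pd.Index(gene_symbols)
        self.n_bins = int(n_bins)

    # -- contract ---------------------------------------------------------
    def _check_genes(self, binned: BinnedMatrix):
        if list(binned.gene_symbols) == list(self.gene_symbols):
            return
        diff = set(binned.gene_symbols).symmetric_difference(self.gene_symbols)
        if diff:
            raise ValueError(f"gene set differs from training genes; symmetric difference: {sorted(diff)[:20]}")
        raise ValueError("gene order differs from training gene order")

    def predict_old_prob(self, binned: BinnedMatrix) -> np.ndarray:
        """One P(old) per cell, clamped to (0, 1); deterministic."""
        self._check_genes(binned)
        if binned.tokens.max(initial=0) >= self.n_bins:
            raise ValueError("token value >= n_bins")
        p = self._predict_tokens(binned.tokens)
        return np.clip(p, PROB_CLAMP, 1.0 - PROB_CLAMP)

    def perturbation_probs(self, tokens: np.ndarray, gene_idx: np.ndarray, token_value: int) -> np.ndarray:
        """P(old) after writing ``token_value`` into each gene of
        ``gene_idx`` in turn; returns an array (len(gene_idx), n_cells).

        The base implementation perturbs and predicts gene by gene;
        backends override it with an algebraically identical vectorized
        path.
        """
        out = np.empty((len(gene_idx), tokens.shape[0]))
        for j, g in enumerate(gene_idx):
            pert = tokens.copy()
            pert[:, g] = token_value
            out[j] = self._predict_tokens(pert)
        return np.clip(out, PROB_CLAMP, 1.0 - PROB_CLAMP)

    def _predict_tokens(self, tokens: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class MLPHeadClassifier(AgeClassifier):
    backend = "mlp_head"

    def __init__(self, gene_symbols, n_bins, cfg: TrainConfig, params: dict):
        super().__init__(gene_symbols, n_bins)
        self.cfg = cfg
        self.params = params  # float32 arrays

    # -- architecture -----------------------------------------------------
    @property
    def n_parameters(self) -> int:
        total = 0
        for value in self.params.values():
            arrays = value if isinstance(value, list) else [value]
            total += sum(a.size for a in arrays)
        return int(total)

    def _token_bin_counts(self, tokens: np.ndarray) -> np.ndarray:
        n, g = tokens.shape
        flat = tokens.astype(np.int64) + self.n_bins * np.arange(n)[:, None]
        counts = np.bincount(flat.ravel(), minlength=n * self.n_bins)
        return counts.reshape(n, self.n_bins).astype(np.float32)

    def _pool(self, tokens: np.ndarray) -> np.ndarray:
        """Cell embedding: mean over genes of the additive gene/bin
        embeddings plus the gene-specific value modulation."""
        p = self.params
        n_genes = tokens.shape[1]
        counts = self._token_bin_counts(tokens)
        pooled = counts @ p["bin_emb"] / np.float32(n_genes)
        pooled += p["gene_emb"].mean(axis=0)
        values = p["bin_value"][tokens]                      # (N, G, D)
        pooled += np.einsum("ngd,gd->nd", values, p["gene_mod"]) / np.float32(n_genes)
        return pooled

    def _forward_pooled(self, pooled: np.ndarray, rng=None, dropout=0.0, cache=None):
        p = self.params
        mu = pooled.mean(axis=1, keepdims=True)
        var = pooled.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + np.float32(_LN_EPS))
        xhat = (pooled - mu) * inv
        x = xhat * p["ln_gamma"] + p["ln_beta"]
        if cache is not None:
            cache["xhat"], cache["inv"] = xhat, inv
            cache["pre"], cache["act"], cache["mask"] = [], [], []
        for layer in range(len(p["hidden_w"])):
            pre = x @ p["hidden_w"][layer] + p["hidden_b"][layer]
            x = _gelu(pre)
            mask = None
            if rng is not None and dropout > 0:
                mask = (rng.random(x.shape) >= dropout).astype(np.float32) / np.float32(1 - dropout)
                x = x * mask
            if cache is not None:
                cache["pre"].append(pre)
                cache["act"].append(x)
                cache["mask"].append(mask)
        logit = x @ p["out_w"][:, 0] + p["out_b"][0]
        if cache is not None:
            cache["last"] = x
        return logit

    def _predict_tokens(self, tokens: np.ndarray) -> np.ndarray:
        pooled = self._pool(tokens)
        out = np.empty(pooled.shape[0], dtype=np.float64)
        for start in range(0, pooled.shape[0], _PREDICT_CHUNK):
            sl = slice(start, start + _PREDICT_CHUNK)
            out[sl] = expit(self._forward_pooled(pooled[sl]))
        return out

    def perturbation_probs(self, tokens, gene_idx, token_value):
        """Vectorized screen path: a single-gene token edit shifts the
        pooled cell embedding by the gene's embedding delta
        (bin_emb[new] - bin_emb[old] plus its value-modulation term) over
        n_genes, so all perturbed embeddings are formed in one pass and
        pushed through the head in large chunks."""
        if tokens.max(initial=0) >= self.n_bins:
            raise ValueError("token value >= n_bins")
        p = self.params
        n_cells, n_genes = tokens.shape
        pooled = self._pool(tokens)  # (N, D)
        out = np.empty((len(gene_idx), n_cells))
        new_emb = p["bin_emb"][token_value]
        new_val = p["bin_value"][token_value]
        # chunk over genes to bound memory at ~ chunk * N * D floats
        gene_chunk = max(1, int(4_000_000 // max(1, n_cells)))
        gene_idx = np.asarray(gene_idx)
        for start in range(0, len(gene_idx), gene_chunk):
            idx = gene_idx[start:start + gene_chunk]
            old_emb = p["bin_emb"][tokens[:, idx]]            # (N, k, D)
            old_val = p["bin_value"][tokens[:, idx]]          # (N, k, D)
            delta = (new_emb[None, None, :] - old_emb
                     + p["gene_mod"][idx][None, :, :] * (new_val[None, None, :] - old_val)
                     ) / np.float32(n_genes)
            batch = pooled[:, None, :] + delta                # (N, k, D)
            batch = np.ascontiguousarray(batch.transpose(1, 0, 2)).reshape(-1, pooled.shape[1])
            probs = np.empty(batch.shape[0])
            for s in range(0, batch.shape[0], _PREDICT_CHUNK):
                sl = slice(s, s + _PREDICT_CHUNK)
                probs[sl] = expit(self._forward_pooled(batch[sl]))
            out[start:start + len(idx)] = probs.reshape(len(idx), n_cells)
        return np.clip(out, PROB_CLAMP, 1.0 - PROB_CLAMP)


def _init_params(n_genes: int, cfg: TrainConfig, n_bins: int, rng) -> dict:
    d, h = cfg.embed_dim, cfg.hidden_units
    f32 = np.float32
    # the value-modulation sketch carries the gene-specific signal, so it
    # starts dominant; the additive tables begin as small perturbations
    ramp = (np.arange(n_bins) / max(1, n_bins - 1) - 0.5).astype(f32)
    params = {
        "gene_emb": rng.normal(0, 0.02, (n_genes, d)).astype(f32),
        "bin_emb": rng.normal(0, 0.02, (n_bins, d)).astype(f32),
        "gene_mod": rng.normal(0, 1.0, (n_genes, d)).astype(f32),
        "bin_value": (ramp[:, None] + rng.normal(0, 0.02, (n_bins, d))).astype(f32),
        "ln_gamma": np.ones(d, dtype=f32),
        "ln_beta": np.zeros(d, dtype=f32),
        "hidden_w": [],
        "hidden_b": [],
        # zero-init final layer: the logit starts at 0 and the readout is
        # built coherently by the optimizer, which matters at small step
        # budgets (standard fine-tuning-head practice)
        "out_w": np.zeros((h, 1), dtype=f32),
        "out_b": np.zeros(1, dtype=f32),
    }
    fan_in = d
    for _ in range(cfg.n_hidden_layers):
        params["hidden_w"].append(rng.normal(0, np.sqrt(2 / fan_in), (fan_in, h)).astype(f32))
        params["hidden_b"].append(np.zeros(h, dtype=f32))
        fan_in = h
    return params


class _AdamW:
    def __init__(self, lr, wd, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.wd, self.b1, self.b2, self.eps = lr, wd, beta1, beta2, eps
        self.t = 0
        self.m, self.v = {}, {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for key, g in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            m = self.m[key]
            v = self.v[key]
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p = params[key]
            p *= np.float32(1 - self.lr * self.wd)  # decoupled weight decay
            p -= np.float32(self.lr) * (m / b1t) / (np.sqrt(v / b2t) + np.float32(self.eps))


def fit_mlp_head(train: BinnedMatrix, labels, cfg: TrainConfig | None = None) -> MLPHeadClassifier:
    """Train the embedding + MLP-head backend.

    ``labels`` must contain both "mid" and "old". The loss is the mean of
    per-sample binary cross-entropy terms weighted by ``class_weights`` of
    the full training labels, which makes it invariant to replicating all
    members of one class. Fully deterministic given ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    labels = np.asarray(labels).astype(str)
    if len(labels) != train.n_cells:
        raise ValueError("labels must align with cells")
    if train.tokens.max(initial=0) >= train.n_bins:
        raise ValueError("token value >= n_bins")
    y = (labels == "old").astype(np.float32)
    w_mid, w_old = class_weights(labels)
    sample_w = np.where(y == 1, w_old, w_mid).astype(np.float32)

    rng = np.random.default_rng(cfg.seed)
    n_genes = train.tokens.shape[1]
    model = MLPHeadClassifier(train.gene_symbols, train.n_bins, cfg,
                              _init_params(n_genes, cfg, train.n_bins, rng))
    p = model.params
    # flatten list params for the optimizer
    flat = {"gene_emb": p["gene_emb"], "bin_emb": p["bin_emb"],
            "gene_mod": p["gene_mod"], "bin_value": p["bin_value"],
            "ln_gamma": p["ln_gamma"], "ln_beta": p["ln_beta"],
            "out_w": p["out_w"], "out_b": p["out_b"]}
    for i in range(cfg.n_hidden_layers):
        flat[f"hidden_w{i}"] = p["hidden_w"][i]
        flat[f"hidden_b{i}"] = p["hidden_b"][i]
    opt = _AdamW(cfg.learning_rate, cfg.weight_decay)

    n = train.n_cells
    tokens = train.tokens
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            kept = None
            if cfg.gene_bag_drop > 0:
                # per-minibatch gene bagging: pool over a random gene subset
                # so mutually redundant informative genes all acquire
                # reliance (a frozen pretrained encoder cannot specialize
                # to a few panel genes; the trainable surrogate can, and
                # bagging removes that artifact)
                mask = rng.random(n_genes) >= cfg.gene_bag_drop
                if not mask.any():
                    mask[rng.integers(n_genes)] = True
                kept = np.flatnonzero(mask)
            grads = _backward_batch(model, tokens[idx], y[idx], sample_w[idx], rng, kept)
            opt.step(flat, grads)
    return model


def _backward_batch(model: MLPHeadClassifier, tokens, y, w, rng, kept=None) -> dict:
    cfg, p = model.cfg, model.params
    nb = tokens.shape[0]
    full_genes = tokens.shape[1]
    if kept is None:
        kept = np.arange(full_genes)
    sub = tokens[:, kept]
    gene_emb = p["gene_emb"][kept]
    gene_mod = p["gene_mod"][kept]
    n_genes = len(kept)
    counts = model._token_bin_counts(sub)
    values = p["bin_value"][sub]  # (N, Gk, D)
    pooled = (counts @ p["bin_emb"] / np.float32(n_genes)
              + gene_emb.mean(axis=0)
              + np.einsum("ngd,gd->nd", values, gene_mod) / np.float32(n_genes))
    cache: dict = {}
    logit = model._forward_pooled(pooled, rng=rng, dropout=cfg.dropout, cache=cache)
    # weighted BCE-with-logits; gradient wrt logit
    dlogit = (w * (expit(logit).astype(np.float32) - y) / np.float32(nb)).astype(np.float32)

    grads: dict = {}
    x_last = cache["last"].astype(np.float32)
    grads["out_w"] = (x_last.T @ dlogit)[:, None]
    grads["out_b"] = np.array([dlogit.sum()], dtype=np.float32)
    dx = dlogit[:, None] @ p["out_w"].T.astype(np.float32)
    for layer in range(cfg.n_hidden_layers - 1, -1, -1):
        mask = cache["mask"][layer]
        if mask is not None:
            dx = dx * mask
        pre = cache["pre"][layer]
        dpre = (dx * _gelu_grad(pre)).astype(np.float32)
        x_in = cache["act"][layer - 1] if layer > 0 else (cache["xhat"] * p["ln_gamma"] + p["ln_beta"])
        grads[f"hidden_w{layer}"] = x_in.T.astype(np.float32) @ dpre
        grads[f"hidden_b{layer}"] = dpre.sum(axis=0)
        dx = dpre @ p["hidden_w"][layer].T
    # layer norm backward
    xhat, inv = cache["xhat"], cache["inv"]
    grads["ln_gamma"] = (dx * xhat).sum(axis=0).astype(np.float32)
    grads["ln_beta"] = dx.sum(axis=0).astype(np.float32)
    dxhat = dx * p["ln_gamma"]
    d = xhat.shape[1]
    dpooled = inv * (dxhat - dxhat.mean(axis=1, keepdims=True)
                     - xhat * (dxhat * xhat).mean(axis=1, keepdims=True))
    dpooled = dpooled.astype(np.float32)
    grads["bin_emb"] = counts.T @ dpooled / np.float32(n_genes)
    ge = np.zeros_like(p["gene_emb"])
    ge[kept] = dpooled.sum(axis=0) / np.float32(n_genes)
    grads["gene_emb"] = ge
    gm = np.zeros_like(p["gene_mod"])
    gm[kept] = np.einsum("nd,ngd->gd", dpooled, values) / np.float32(n_genes)
    grads["gene_mod"] = gm
    contrib = dpooled[:, None, :] * gene_mod[None, :, :] / np.float32(n_genes)
    gb = np.zeros_like(p["bin_value"])
    np.add.at(gb, sub.ravel().astype(np.int64), contrib.reshape(-1, d))
    grads["bin_value"] = gb
    return grads


class LogisticClassifier(AgeClassifier):
    backend = "logistic"

    def __init__(self, gene_symbols, n_bins, pipeline: Pipeline):
        super().__init__(gene_symbols, n_bins)
        self.pipeline = pipeline
        self._old_col = int(np.flatnonzero(pipeline.classes_ == "old")[0])

    def _predict_tokens(self, tokens: np.ndarray) -> np.ndarray:
        return self.pipeline.predict_proba(tokens.astype(np.float64))[:, self._old_col]

    def perturbation_probs(self, tokens, gene_idx, token_value):
        """Vectorized: a token edit moves the linear decision value by
        coef_g * (z_new - z_old) for the edited gene only."""
        scaler: StandardScaler = self.pipeline.named_steps["scale"]
        lr: LogisticRegression = self.pipeline.named_steps["logreg"]
        x = tokens.astype(np.float64)
        z = (x - scaler.mean_) / scaler.scale_
        base = z @ lr.coef_[0] + lr.intercept_[0]
        gene_idx = np.asarray(gene_idx)
        z_new = (token_value - scaler.mean_[gene_idx]) / scaler.scale_[gene_idx]
        shift = lr.coef_[0][gene_idx][None, :] * (z_new[None, :] - z[:, gene_idx])
        dec = base[:, None] + shift  # (N, k)
        sign = 1.0 if self._old_col == 1 else -1.0
        probs = expit(sign * dec.T)
        return np.clip(probs, PROB_CLAMP, 1.0 - PROB_CLAMP)


def fit_logistic_baseline(train: BinnedMatrix, labels, seed: int = 0) -> LogisticClassifier:
    """Fit the standardized L1 logistic-regression baseline (C = 1)."""
    labels = np.asarray(labels).astype(str)
    if len(labels) != train.n_cells:
        raise ValueError("labels must align with cells")
    class_weights(labels)  # raises if a class is absent
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("logreg", LogisticRegression(l1_ratio=1.0, C=1.0, solver="liblinear",
                                      max_iter=1000, random_state=seed)),
    ])
    pipe.fit(train.tokens.astype(np.float64), labels)
    return LogisticClassifier(train.gene_symbols, train.n_bins, pipe)


def predict_old_prob(model: AgeClassifier, cells: BinnedMatrix) -> np.ndarray:
    return model.predict_old_prob(cells)


def evaluate_auc(model: AgeClassifier, cells: BinnedMatrix, labels) -> float:
    """Held-out ROC-AUC of P(old) against the age-group labels, i.e. the
    rank statistic P(score_old > score_mid) + 0.5 P(tie)."""
    labels = np.asarray(labels).astype(str)
    if len(set(labels)) < 2:
        raise ValueError("both classes must be present to compute ROC-AUC")
    scores = model.predict_old_prob(cells)
    return float(roc_auc_score((labels == "old").astype(int), scores))


def save_model(model: AgeClassifier, path) -> None:
    """Serialize a fitted classifier (architecture, weights, training gene
    list, n_bins) to a single file; ``load_model`` restores bit-identical
    predictions."""
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path) -> AgeClassifier:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, AgeClassifier):
        raise TypeError("file does not contain a fitted AgeClassifier")
    return model
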