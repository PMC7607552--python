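"""Variational autoencoder over expression compendia.

Architecture: genes -> intermediate (ReLU) -> latent mean mu and latent
log-variance; decoder mirrors the encoder (latent -> intermediate (ReLU)
-> genes, sigmoid output).  The loss is per-sample binary cross-entropy
reconstruction (summed over genes) plus kappa * KL(q(z|x) || N(0, I))
(summed over latent dimensions), both averaged over the batch.  kappa
starts at 0 and ramps by ``kl_warmup_step`` per epoch, capped at 1, so the
latent code is regularized toward the standard-normal prior only gradually
(KL warmup avoids posterior collapse).

The implementation is self-contained numpy: forward pass, analytic
gradients and Adam updates, deterministic under a seed on a single thread.
Follows the statsmodels convention: :class:`ExpressionVAE` is the model,
``fit()`` returns a :class:`VAEResults` carrying parameters, history and
diagnostics, and downstream simulation operates on the results object.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_io import ExpressionCompendium, split_train_validation

__all__ = ["VAEConfig", "ExpressionVAE", "VAEResults", "LatentMatrix",
           "train_vae", "load_model"]

_FORMAT_VERSION = 1


@dataclass
class VAEConfig:
    """Hyperparameters of the two-layer VAE.

    Defaults follow the compendium-scale setting: intermediate width 2,500,
    30 latent features, Adam at learning rate 0.001, batch size 100, KL
    warmup step 0.01 per epoch, 100 epochs.  Small synthetic compendia use
    proportionally smaller widths via explicit overrides.
    """

    input_dim: int
    intermediate_dim: int = 2500
    latent_dim: int = 30
    learning_rate: float = 0.001
    batch_size: int = 100
    epochs: int = 100
    kl_warmup_step: float = 0.01
    seed: int = 0
    # How the validation KL is weighted: "current" uses the epoch's kappa,
    # "one" always uses kappa = 1.
    validation_kl_weight: str = "current"

    def __post_init__(self):
        if not (self.latent_dim < self.intermediate_dim < self.input_dim):
            raise ValueError(
                "require latent_dim < intermediate_dim < input_dim, got "
                f"{self.latent_dim} / {self.intermediate_dim} / {self.input_dim}"
            )
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("learning_rate > 0, batch_size >= 1, epochs >= 0 required")
        if self.kl_warmup_step <= 0:
            raise ValueError("kl_warmup_step must be > 0")
        if self.validation_kl_weight not in ("current", "one"):
            raise ValueError("validation_kl_weight must be 'current' or 'one'")


@dataclass
class LatentMatrix:
    """Samples x latent_dim matrix of latent coordinates (encoder means)."""

    values: np.ndarray
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("latent matrix must be 2-D")
        if self.sample_ids and len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length must match row count")

    @property
    def latent_dim(self) -> int:
        return self.values.shape[1]


def _glorot(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _init_params(cfg: VAEConfig, rng) -> dict:
    g, h, d = cfg.input_dim, cfg.intermediate_dim, cfg.latent_dim
    return {
        "W1": _glorot(rng, g, h), "b1": np.zeros(h),
        "Wm": _glorot(rng, h, d), "bm": np.zeros(d),
        "Wv": _glorot(rng, h, d), "bv": np.zeros(d),
        "W3": _glorot(rng, d, h), "b3": np.zeros(h),
        "W4": _glorot(rng, h, g), "b4": np.zeros(g),
    }


_LOGVAR_CLIP = 15.0  # keeps exp(logvar) finite early in training


def _forward(params, X, rng=None, sample_z=True):
    """Forward pass. Returns a cache of intermediates for backprop."""
    h1_pre = X @ params["W1"] + params["b1"]
    h1 = np.maximum(h1_pre, 0.0)
    mu = h1 @ params["Wm"] + params["bm"]
    logvar = np.clip(h1 @ params["Wv"] + params["bv"], -_LOGVAR_CLIP, _LOGVAR_CLIP)
    if sample_z:
        eps = rng.standard_normal(mu.shape)
        z = mu + np.exp(0.5 * logvar) * eps
    else:
        eps = np.zeros_like(mu)
        z = mu
    h2_pre = z @ params["W3"] + params["b3"]
    h2 = np.maximum(h2_pre, 0.0)
    logits = h2 @ params["W4"] + params["b4"]
    return {"X": X, "h1": h1, "mu": mu, "logvar": logvar, "eps": eps,
            "z": z, "h2": h2, "logits": logits}


def _losses(cache):
    """(reconstruction BCE, KL), each averaged over the batch.

    BCE is computed from logits in the numerically stable softplus form and
    summed over genes; KL is summed over latent dimensions.  Every per-
    dimension KL term 0.5 * (e^l + mu^2 - 1 - l) is >= 0, so the KL is
    non-negative by construction.
    """
    X, logits = cache["X"], cache["logits"]
    bce = np.maximum(logits, 0.0) - logits * X + np.log1p(np.exp(-np.abs(logits)))
    bce = bce.sum(axis=1).mean()
    mu, lv = cache["mu"], cache["logvar"]
    kl = 0.5 * (np.exp(lv) + mu ** 2 - 1.0 - lv).sum(axis=1).mean()
    return bce, kl


def _backward(params, cache, kappa):
    """Analytic gradients of BCE + kappa * KL w.r.t. all parameters."""
    X, h1, mu, lv = cache["X"], cache["h1"], cache["mu"], cache["logvar"]
    eps, z, h2, logits = cache["eps"], cache["z"], cache["h2"], cache["logits"]
    B = X.shape[0]

    xhat = expit(logits)
    dlogits = (xhat - X) / B
    grads = {
        "W4": h2.T @ dlogits, "b4": dlogits.sum(axis=0),
    }
    dh2 = dlogits @ params["W4"].T
    dh2_pre = dh2 * (h2 > 0)
    grads["W3"] = z.T @ dh2_pre
    grads["b3"] = dh2_pre.sum(axis=0)
    dz = dh2_pre @ params["W3"].T

    dmu = dz + kappa * mu / B
    # d z / d logvar = eps * 0.5 * exp(logvar / 2); KL term adds 0.5(e^l - 1)
    dlv = dz * eps * 0.5 * np.exp(0.5 * lv) + kappa * 0.5 * (np.exp(lv) - 1.0) / B
    clipped = (lv <= -_LOGVAR_CLIP) | (lv >= _LOGVAR_CLIP)
    dlv[clipped] = 0.0

    grads["Wm"] = h1.T @ dmu
    grads["bm"] = dmu.sum(axis=0)
    grads["Wv"] = h1.T @ dlv
    grads["bv"] = dlv.sum(axis=0)
    dh1 = dmu @ params["Wm"].T + dlv @ params["Wv"].T
    dh1_pre = dh1 * (h1 > 0)
    grads["W1"] = X.T @ dh1_pre
    grads["b1"] = dh1_pre.sum(axis=0)
    return grads


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _check_scaled(values):
    if values.size and (values.min() < 0 or values.max() > 1):
        raise ValueError(
            "VAE input must be scaled to [0, 1]; found values in "
            f"[{values.min():.4g}, {values.max():.4g}]"
        )


class ExpressionVAE:
    """VAE model over a scaled (0-1) expression compendium.

    Parameters
    ----------
    compendium : ExpressionCompendium
        Training data, values in [0, 1].
    config : VAEConfig, optional
        Hyperparameters; ``input_dim`` is inferred from the compendium if a
        config is not supplied.
    validation_fraction : float
        Fraction held out as a validation set (default 0.1, i.e. a 90/10
        split); ignored when an explicit ``validation`` compendium is passed
        to :meth:`fit`.
    """

    def __init__(self, compendium: ExpressionCompendium, config: VAEConfig | None = None,
                 validation_fraction: float = 0.1):
        _check_scaled(compendium.values)
        if config is None:
            config = VAEConfig(input_dim=compendium.n_genes)
        if config.input_dim != compendium.n_genes:
            raise ValueError(
                f"config.input_dim {config.input_dim} != n_genes {compendium.n_genes}"
            )
        self.compendium = compendium
        self.config = config
        self.validation_fraction = validation_fraction

    def fit(self, validation: ExpressionCompendium | None = None,
            kl_weight_max: float = 1.0) -> "VAEResults":
        """Train and return a :class:`VAEResults`.

        ``kl_weight_max`` caps kappa (0 turns the model into a plain
        autoencoder, useful as a diagnostic).
        """
        cfg = self.config
        if validation is None:
            train, val = split_train_validation(
                self.compendium, 1.0 - self.validation_fraction, cfg.seed
            )
        else:
            train, val = self.compendium, validation
        Xtr, Xval = train.values, val.values

        rng = np.random.default_rng(cfg.seed)
        params = _init_params(cfg, rng)
        opt = _Adam(params, cfg.learning_rate)

        history, kl_steps = [], []
        n = Xtr.shape[0]
        for epoch in range(cfg.epochs):
            kappa = min(kl_weight_max, epoch * cfg.kl_warmup_step)
            order = rng.permutation(n)
            ep_loss, n_batches = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                batch = Xtr[order[start:start + cfg.batch_size]]
                cache = _forward(params, batch, rng=rng, sample_z=True)
                bce, kl = _losses(cache)
                loss = bce + kappa * kl
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"NaN/inf loss at epoch {epoch}, batch {n_batches} "
                        f"(bce={bce:.4g}, kl={kl:.4g}); training aborted"
                    )
                kl_steps.append(kl)
                grads = _backward(params, cache, kappa)
                opt.step(params, grads)
                ep_loss += loss
                n_batches += 1
            val_kappa = 1.0 if cfg.validation_kl_weight == "one" else kappa
            vcache = _forward(params, Xval, sample_z=False)
            vbce, vkl = _losses(vcache)
            history.append({
                "epoch": epoch, "train_loss": ep_loss / max(n_batches, 1),
                "val_loss": vbce + val_kappa * vkl, "kl_weight": kappa,
                "val_bce": vbce, "val_kl": vkl,
            })

        return VAEResults(
            params=params, config=cfg, gene_ids=list(self.compendium.gene_ids),
            history=pd.DataFrame(history,
                                 columns=["epoch", "train_loss", "val_loss",
                                          "kl_weight", "val_bce", "val_kl"]),
            kl_per_step=np.asarray(kl_steps),
            trained=cfg.epochs > 0,
        )


@dataclass
class VAEResults:
    """Fitted VAE: parameters, training history and encode/decode."""

    params: dict
    config: VAEConfig
    gene_ids: list
    history: pd.DataFrame
    kl_per_step: np.ndarray
    trained: bool = True

    # -- inference ---------------------------------------------------------

    def _require_trained(self):
        if not self.trained:
            raise RuntimeError("model is untrained (epochs=0); fit before encoding")

    def _check_genes(self, comp: ExpressionCompendium):
        if list(comp.gene_ids) != list(self.gene_ids):
            mismatched = [g for g in comp.gene_ids if g not in set(self.gene_ids)]
            extra = [g for g in self.gene_ids if g not in set(comp.gene_ids)]
            raise ValueError(
                "gene identifiers do not match the training genes "
                f"(order-sensitive); unknown: {mismatched[:5]}, missing: {extra[:5]}"
            )

    def encode(self, comp: ExpressionCompendium) -> LatentMatrix:
        """Latent mean mu per sample (deterministic; no sampling)."""
        self._require_trained()
        self._check_genes(comp)
        _check_scaled(comp.values)
        h1 = np.maximum(comp.values @ self.params["W1"] + self.params["b1"], 0.0)
        mu = h1 @ self.params["Wm"] + self.params["bm"]
        return LatentMatrix(mu, list(comp.sample_ids))

    def decode(self, z, sample_ids=None) -> ExpressionCompendium:
        """Decode latent coordinates to expression values in (0, 1)."""
        self._require_trained()
        if isinstance(z, LatentMatrix):
            if sample_ids is None and z.sample_ids:
                sample_ids = z.sample_ids
            z = z.values
        z = np.asarray(z, dtype=float)
        if z.ndim != 2 or z.shape[1] != self.config.latent_dim:
            raise ValueError(
                f"latent width {z.shape[-1] if z.ndim == 2 else z.ndim} != "
                f"latent_dim {self.config.latent_dim}"
            )
        h2 = np.maximum(z @ self.params["W3"] + self.params["b3"], 0.0)
        values = expit(h2 @ self.params["W4"] + self.params["b4"])
        if sample_ids is None:
            sample_ids = [f"s{i}" for i in range(z.shape[0])]
        return ExpressionCompendium(values, sample_ids, list(self.gene_ids), scaled=True)

    def reconstruct(self, comp: ExpressionCompendium) -> ExpressionCompendium:
        return self.decode(self.encode(comp))

    def reconstruction_bce(self, comp: ExpressionCompendium) -> float:
        """Mean per-sample binary cross-entropy of decode(encode(comp))."""
        xhat = np.clip(self.reconstruct(comp).values, 1e-12, 1 - 1e-12)
        x = comp.values
        return float(-(x * np.log(xhat) + (1 - x) * np.log(1 - xhat)).sum(axis=1).mean())

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Expression VAE results",
            "=" * 56,
            f"architecture        {cfg.input_dim} -> {cfg.intermediate_dim} -> "
            f"{cfg.latent_dim} (mu, logvar) -> mirrored decoder",
            f"epochs              {cfg.epochs}",
            f"batch size          {cfg.batch_size}",
            f"learning rate       {cfg.learning_rate}",
            f"KL warmup step      {cfg.kl_warmup_step}",
            f"seed                {cfg.seed}",
        ]
        if len(self.history):
            first, last = self.history.iloc[0], self.history.iloc[-1]
            lines += [
                f"train loss          {first.train_loss:.3f} (epoch 0) -> "
                f"{last.train_loss:.3f} (epoch {int(last.epoch)})",
                f"validation loss     {first.val_loss:.3f} -> {last.val_loss:.3f}",
                f"final KL weight     {last.kl_weight:.3f}",
            ]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Save to a directory: weights.npz + model.json + history.tsv."""
        os.makedirs(path, exist_ok=True)
        np.savez(os.path.join(path, "weights.npz"), **self.params,
                 kl_per_step=self.kl_per_step)
        meta = {
            "format_version": _FORMAT_VERSION,
            "config": asdict(self.config),
            "gene_ids": list(self.gene_ids),
            "trained": bool(self.trained),
        }
        with open(os.path.join(path, "model.json"), "w") as fh:
            json.dump(meta, fh, indent=1)
        self.history.to_csv(os.path.join(path, "history.tsv"), sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "VAEResults":
        meta_path = os.path.join(path, "model.json")
        if not os.path.exists(meta_path):
            raise FileNotFoundError(f"no model archive at {path}")
        with open(meta_path) as fh:
            meta = json.load(fh)
        if meta.get("format_version") != _FORMAT_VERSION:
            raise ValueError(
                f"model archive version {meta.get('format_version')} "
                f"incompatible with reader version {_FORMAT_VERSION}"
            )
        archive = np.load(os.path.join(path, "weights.npz"))
        params = {k: archive[k] for k in archive.files if k != "kl_per_step"}
        history = pd.read_csv(os.path.join(path, "history.tsv"), sep="\t")
        return cls(params=params, config=VAEConfig(**meta["config"]),
                   gene_ids=meta["gene_ids"], history=history,
                   kl_per_step=archive["kl_per_step"], trained=meta["trained"])


def train_vae(comp: ExpressionCompendium, config: VAEConfig,
              validation: ExpressionCompendium | None = None,
              validation_fraction: float = 0.1) -> VAEResults:
    """Functional wrapper: build :class:`ExpressionVAE` and fit it."""
    return ExpressionVAE(comp, config, validation_fraction).fit(validation=validation)


def load_model(path) -> VAEResults:
    return VAEResults.load(path)
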