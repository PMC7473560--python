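"""Min–max optimization loop for the supervised CycleGAN.

Each training step first updates the two critics on their Wasserstein-plus-
gradient-penalty objective (optionally several critic steps per generator
step), then updates both generators on the combined objective

    L_G = L_adv^gen + alpha * L_cyclic + beta * L_identity + gamma * L_sup.

Defaults follow the reference training protocol: Adam(beta1=0.5,
beta2=0.999), learning rate 2e-4, batch 16, up to 200 epochs with early
stopping at patience 5 on the validation criterion (supervised L1 by
default — the one component that directly measures recovery fidelity).
Runs are bit-reproducible given (seed, config, dataset) on one device.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .core_io import PETVolume
from .patch_pipeline import PatchSet, unscale
from .sgan_model import (
    Critic,
    CriticSpec,
    Generator,
    GeneratorSpec,
    LossWeights,
    adversarial_loss,
    cycle_loss,
    identity_loss,
    supervised_loss,
)

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    learning_rate: float = 2e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    batch_size: int = 16
    max_epochs: int = 200
    early_stop_patience: int = 5
    critic_steps_per_gen_step: int = 1
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("invalid training configuration")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")


class Adam:
    """Adam optimizer over a fixed list of parameter tensors."""

    def __init__(self, params, lr, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, ad.Tensor) else g
            m *= self.b1
            m += (1 - self.b1) * gd
            v *= self.b2
            v += (1 - self.b2) * gd * gd
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class ModelBundle:
    """The four networks plus their optimizers."""

    g_ab: Generator
    g_ba: Generator
    d_a: Critic
    d_b: Critic
    opt_gen: Adam | None = None
    opt_critic: Adam | None = None

    @classmethod
    def create(
        cls,
        gen_spec: GeneratorSpec | None = None,
        critic_spec: CriticSpec | None = None,
        config: "TrainConfig | None" = None,
        seed: int = 0,
    ) -> "ModelBundle":
        gen_spec = gen_spec or GeneratorSpec()
        critic_spec = critic_spec or CriticSpec()
        config = config or TrainConfig()
        b = cls(
            g_ab=Generator(gen_spec, seed),
            g_ba=Generator(gen_spec, seed + 1),
            d_a=Critic(critic_spec, seed + 2),
            d_b=Critic(critic_spec, seed + 3),
        )
        b.attach_optimizers(config)
        return b

    def attach_optimizers(self, config: TrainConfig):
        self.opt_gen = Adam(
            self.g_ab.params() + self.g_ba.params(),
            config.learning_rate,
            config.adam_beta1,
            config.adam_beta2,
        )
        self.opt_critic = Adam(
            self.d_a.params() + self.d_b.params(),
            config.learning_rate,
            config.adam_beta1,
            config.adam_beta2,
        )

    def all_params(self):
        return (
            self.g_ab.params()
            + self.g_ba.params()
            + self.d_a.params()
            + self.d_b.params()
        )

    def checkpoint(self) -> dict:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.all_params())}

    def load_checkpoint(self, ckpt: dict):
        params = self.all_params()
        if len(ckpt) != len(params):
            raise ValueError("checkpoint does not match model parameterization")
        for i, p in enumerate(params):
            p.data[...] = ckpt[f"p{i}"]


def save_checkpoint(ckpt: dict, path):
    np.savez_compressed(path, **ckpt)


def load_checkpoint(path) -> dict:
    with np.load(path) as z:
        return {k: z[k].copy() for k in z.files}


def _check_finite(record: dict):
    for k, v in record.items():
        if not np.isfinite(v):
            raise FloatingPointError(
                f"non-finite loss component {k!r}: {record}"
            )


def train_step(models: ModelBundle, batch, config: TrainConfig, seed: int = 0) -> dict:
    """One critic phase (``critic_steps_per_gen_step`` updates) + one
    generator update on a batch of paired scaled patches ``(x_a, x_b)``.

    Returns the loss components of the generator phase plus the last critic
    objective; the supervised term is present only when gamma > 0, so an
    ablated run's history carries no trace of the removed component.
    """
    x_a, x_b = batch
    w = config.weights
    record: dict = {}

    # --- critic phase: minimize E[D(fake)] - E[D(real)] + GP ------------
    for k in range(config.critic_steps_per_gen_step):
        critic_obj, _ = adversarial_loss(
            models.g_ab,
            models.g_ba,
            models.d_a,
            models.d_b,
            x_a,
            x_b,
            w.lambda_gp,
            seed * 1000 + k,
        )
        grads = ad.grad(critic_obj, models.opt_critic.params)
        models.opt_critic.step(grads)
        record["critic"] = critic_obj.item()

    # --- generator phase -------------------------------------------------
    _, gen_adv = adversarial_loss(
        models.g_ab,
        models.g_ba,
        models.d_a,
        models.d_b,
        x_a,
        x_b,
        w.lambda_gp,
        seed * 1000 + 500,
    )
    total = gen_adv
    record["adv"] = gen_adv.item()
    cyc = cycle_loss(models.g_ab, models.g_ba, x_a, x_b)
    record["cyclic"] = cyc.item()
    total = total + ad.Tensor(np.float64(w.alpha)) * cyc
    ident = identity_loss(models.g_ab, models.g_ba, x_a, x_b)
    record["identity"] = ident.item()
    total = total + ad.Tensor(np.float64(w.beta)) * ident
    if w.gamma > 0:
        sup = supervised_loss(models.g_ab, models.g_ba, x_a, x_b)
        record["sup"] = sup.item()
        total = total + ad.Tensor(np.float64(w.gamma)) * sup
    record["total"] = total.item()
    _check_finite(record)
    grads = ad.grad(total, models.opt_gen.params)
    models.opt_gen.step(grads)
    return record


def validation_loss(models: ModelBundle, val_set: PatchSet, batch_size: int = 16) -> float:
    """Supervised L1 on validation pairs (forward passes only)."""
    losses, weights = [], []
    for i in range(0, len(val_set), batch_size):
        x_a = val_set.ld[i : i + batch_size]
        x_b = val_set.fd[i : i + batch_size]
        losses.append(supervised_loss(models.g_ab, models.g_ba, x_a, x_b).item())
        weights.append(len(x_a))
    return float(np.average(losses, weights=weights))


def early_stop_index(val_losses, patience: int) -> tuple[int, bool]:
    """(index of the best epoch so far, whether to stop now).

    Stops once the best value has not improved for ``patience`` consecutive
    epochs.
    """
    best = int(np.argmin(val_losses))
    return best, (len(val_losses) - 1 - best) >= patience


def fit(
    models: ModelBundle,
    train_set: PatchSet,
    val_set: PatchSet,
    config: TrainConfig,
) -> tuple[dict, list[dict]]:
    """Epoch loop with per-epoch reshuffling and early stopping.

    Returns ``(best checkpoint, history)`` where history has one record per
    epoch holding the epoch-averaged loss components and the validation
    criterion.  The returned checkpoint is always the epoch with the best
    (lowest) validation loss.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("training and validation sets must be non-empty")
    if models.opt_gen is None:
        models.attach_optimizers(config)
    history: list[dict] = []
    val_losses: list[float] = []
    best_ckpt = models.checkpoint()
    master = np.random.default_rng(config.seed)
    epoch_seeds = master.integers(0, 2**31 - 1, size=config.max_epochs)
    for epoch in range(config.max_epochs):
        rng = np.random.default_rng(int(epoch_seeds[epoch]))
        order = rng.permutation(len(train_set))
        sums: dict = {}
        n_batches = 0
        for bi, start in enumerate(range(0, len(train_set), config.batch_size)):
            idx = order[start : start + config.batch_size]
            batch = (train_set.ld[idx], train_set.fd[idx])
            rec = train_step(models, batch, config, seed=epoch * 100000 + bi)
            for k, v in rec.items():
                sums[k] = sums.get(k, 0.0) + v
            n_batches += 1
        record = {k: v / n_batches for k, v in sums.items()}
        record["epoch"] = epoch
        record["val"] = validation_loss(models, val_set, config.batch_size)
        history.append(record)
        val_losses.append(record["val"])
        best, stop = early_stop_index(val_losses, config.early_stop_patience)
        if best == epoch:
            best_ckpt = models.checkpoint()
        log.info(
            "epoch %d: total %.4g val %.4g (best %d)",
            epoch,
            record.get("total", float("nan")),
            record["val"],
            best,
        )
        if stop:
            break
    return best_ckpt, history


def recover(
    g_ab: Generator, ld: PETVolume, scale_factor: float, batch_slices: int = 4
) -> PETVolume:
    """Pass each transverse slice whole through G_AB and return to kBq/ml.

    The input volume is divided by ``scale_factor`` (the training-time joint
    scale), mapped slice by slice, and multiplied back; output is
    non-negative by the generator's closing rectifier.
    """
    if scale_factor <= 0:
        raise ValueError("scale factor must be positive")
    vals = ld.values / scale_factor
    out = np.empty_like(vals)
    nz = vals.shape[2]
    for start in range(0, nz, batch_slices):
        sl = vals[:, :, start : start + batch_slices]
        x = np.moveaxis(sl, 2, 0)[:, None, :, :]
        y = g_ab(x)
        out[:, :, start : start + batch_slices] = np.moveaxis(y.data[:, 0], 0, 2)
    rec = PETVolume(out, ld.voxel_size_mm, domain_role="recovered")
    return unscale(rec, scale_factor)
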