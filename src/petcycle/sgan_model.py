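"""S-CycleGAN computation core: generators, Wasserstein critics, losses.

The framework couples two generators (G_AB: low-dose -> full-dose and G_BA
for the reverse direction) with two Wasserstein critics (D_A, D_B) and
trains them under the combined objective

    L = L_adv + alpha * L_cyclic + beta * L_identity + gamma * L_sup

with default weights alpha=10, beta=5, gamma=5 and gradient-penalty weight
lambda=10.  Setting gamma=0 (and optionally beta=0) degrades the objective
to a plain cycle-consistent adversarial model, the standard ablation.

Architectures
-------------
Generator: two 3x3/64 stem convolutions, six residual modules (each three
conv -> batch-norm -> ReLU blocks plus an additive skip followed by ReLU),
a concatenation of every module input plus the last module output, two 64-
filter fusion convolutions, and a final 3x3 convolution joined to an
end-to-end additive bypass with a closing ReLU — so outputs are
non-negative and any H x W input maps to an H x W output.

Critic: four 4x4 stride-2 convolutions with 64/128/256/512 filters and
leaky-ReLU (slope 0.2), then dense layers of 1024 and 1 output.  There is no
final squashing (Wasserstein critic) and no batch normalization, which
would couple samples and break the per-sample gradient penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

def _init_std(init, fan_in: int) -> float:
    """Gaussian init scale: fan-in-scaled by default, or a fixed std.

    ``"fan_in"`` uses std sqrt(2/fan_in), which keeps activation variance
    roughly constant through rectified conv stacks and so keeps deep
    gradients healthy; a float pins the std directly.
    """
    if init == "fan_in":
        return float(np.sqrt(2.0 / fan_in))
    return float(init)


@dataclass
class GeneratorSpec:
    base_filters: int = 64
    kernel: int = 3
    n_residual_modules: int = 6
    convs_per_module: int = 3
    include_raw_input_in_concat: bool = False  # alternative fan-in reading
    in_channels: int = 1

    def concat_channels(self) -> int:
        c = (self.n_residual_modules + 1) * self.base_filters
        if self.include_raw_input_in_concat:
            c += self.in_channels
        return c


@dataclass
class CriticSpec:
    filters: tuple[int, ...] = (64, 128, 256, 512)
    kernel: int = 4
    stride: int = 2
    pad: int = 1
    leaky_slope: float = 0.2
    dense_units: int = 1024
    input_size: int = 56
    in_channels: int = 1


@dataclass
class LossWeights:
    alpha: float = 10.0  # cycle-consistency
    beta: float = 5.0  # identity
    gamma: float = 5.0  # supervised L1
    lambda_gp: float = 10.0  # gradient penalty

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma, self.lambda_gp) < 0:
            raise ValueError("loss weights must be non-negative")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv2d:
    """3x3-style convolution via im2col; weight shape (C*k*k, F)."""

    def __init__(self, cin, cout, k, stride=1, pad=0, rng=None, init="fan_in"):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout
        std = _init_std(init, cin * k * k)
        self.W = Tensor(
            rng.normal(0.0, std, size=(cin * k * k, cout)), requires_grad=True
        )
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if h + 2 * self.pad < self.k or w + 2 * self.pad < self.k:
            raise ValueError("input smaller than convolution kernel")
        oh = (h + 2 * self.pad - self.k) // self.stride + 1
        ow = (w + 2 * self.pad - self.k) // self.stride + 1
        cols = ad.im2col(x, self.k, self.stride, self.pad)
        out = ad.matmul(cols, self.W) + self.b
        out = ad.reshape(out, (n, oh, ow, self.cout))
        return ad.transpose(out, (0, 3, 1, 2))

    def params(self):
        return [self.W, self.b]


class BatchNorm2d:
    """Normalization over (batch, H, W) per channel with learned scale/shift.

    Statistics always come from the tensor being processed (no running
    averages), so single-image inference behaves like instance
    normalization.
    """

    def __init__(self, channels, eps=1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = ad.tmean(x, axis=(0, 2, 3), keepdims=True)
        xc = x - mu
        var = ad.tmean(xc * xc, axis=(0, 2, 3), keepdims=True)
        return self.gamma * (xc / ad.sqrt(var + self.eps)) + self.beta

    def params(self):
        return [self.gamma, self.beta]


class Dense:
    def __init__(self, nin, nout, rng=None, init="fan_in"):
        rng = rng or np.random.default_rng(0)
        std = _init_std(init, nin)
        self.W = Tensor(rng.normal(0.0, std, size=(nin, nout)), requires_grad=True)
        self.b = Tensor(np.zeros(nout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.W) + self.b

    def params(self):
        return [self.W, self.b]


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

class Generator:
    """Dense-residual image-to-image generator; preserves spatial size."""

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        f, k = spec.base_filters, spec.kernel
        pad = k // 2
        self.stem = [
            Conv2d(spec.in_channels, f, k, pad=pad, rng=rng),
            Conv2d(f, f, k, pad=pad, rng=rng),
        ]
        self.modules = []
        for _ in range(spec.n_residual_modules):
            block = [
                (Conv2d(f, f, k, pad=pad, rng=rng), BatchNorm2d(f))
                for _ in range(spec.convs_per_module)
            ]
            self.modules.append(block)
        self.fuse = [
            Conv2d(spec.concat_channels(), f, k, pad=pad, rng=rng),
            Conv2d(f, f, k, pad=pad, rng=rng),
        ]
        # near-zero final conv: the end-to-end bypass then dominates at
        # initialization, so the generator starts close to the identity map
        self.out_conv = Conv2d(f, spec.in_channels, k, pad=pad, rng=rng, init=1e-3)

    def __call__(self, x) -> Tensor:
        x = ad.as_tensor(x)
        h = ad.relu(self.stem[0](x))
        h = ad.relu(self.stem[1](h))
        module_inputs = []
        for block in self.modules:
            module_inputs.append(h)
            t = h
            for conv, bn in block:
                t = ad.relu(bn(conv(t)))
            h = ad.relu(t + h)
        cat_items = module_inputs + [h]
        if self.spec.include_raw_input_in_concat:
            cat_items = [x] + cat_items
        h = ad.concat(cat_items, axis=1)
        h = ad.relu(self.fuse[0](h))
        h = ad.relu(self.fuse[1](h))
        return ad.relu(self.out_conv(h) + x)

    def params(self):
        ps = []
        for c in self.stem + self.fuse + [self.out_conv]:
            ps += c.params()
        for block in self.modules:
            for conv, bn in block:
                ps += conv.params() + bn.params()
        return ps

    def n_params(self) -> int:
        return sum(p.size for p in self.params())


class Critic:
    """Wasserstein critic mapping a patch batch to per-sample scores."""

    def __init__(self, spec: CriticSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.convs = []
        cin = spec.in_channels
        size = spec.input_size
        for f in spec.filters:
            self.convs.append(Conv2d(cin, f, spec.kernel, spec.stride, spec.pad, rng))
            size = (size + 2 * spec.pad - spec.kernel) // spec.stride + 1
            if size < 1:
                raise ValueError("critic input too small for its conv stack")
            cin = f
        self.flat_dim = cin * size * size
        self.dense = [
            Dense(self.flat_dim, spec.dense_units, rng),
            Dense(spec.dense_units, 1, rng),
        ]

    def __call__(self, x) -> Tensor:
        x = ad.as_tensor(x)
        n = x.shape[0]
        h = x
        for conv in self.convs:
            h = ad.leaky_relu(conv(h), self.spec.leaky_slope)
        h = ad.reshape(h, (n, self.flat_dim))
        h = ad.leaky_relu(self.dense[0](h), self.spec.leaky_slope)
        return ad.reshape(self.dense[1](h), (n,))

    def params(self):
        ps = []
        for c in self.convs + self.dense:
            ps += c.params()
        return ps

    def n_params(self) -> int:
        return sum(p.size for p in self.params())


def build_generator(spec: GeneratorSpec, seed: int = 0) -> Generator:
    return Generator(spec, seed)


def build_critic(spec: CriticSpec, seed: int = 0) -> Critic:
    return Critic(spec, seed)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _batch(x) -> Tensor:
    """Coerce (N,H,W) or (N,1,H,W) arrays to 4-D tensors."""
    t = ad.as_tensor(x)
    if t.data.ndim == 3:
        n, h, w = t.shape
        t = ad.reshape(t, (n, 1, h, w))
    return t


def l1(a: Tensor, b: Tensor) -> Tensor:
    return ad.tmean(ad.absolute(a - b))


def supervised_loss(g_ab, g_ba, x_a, x_b) -> Tensor:
    """L1 of G_AB(x_A) vs x_B plus L1 of G_BA(x_B) vs x_A (paired data)."""
    x_a, x_b = _batch(x_a), _batch(x_b)
    if x_a.shape != x_b.shape:
        raise ValueError("paired batches must share shapes")
    return l1(g_ab(x_a), x_b) + l1(g_ba(x_b), x_a)


def cycle_loss(g_ab, g_ba, x_a, x_b) -> Tensor:
    """L1 reconstruction error around both A->B->A and B->A->B cycles."""
    x_a, x_b = _batch(x_a), _batch(x_b)
    return l1(g_ba(g_ab(x_a)), x_a) + l1(g_ab(g_ba(x_b)), x_b)


def identity_loss(g_ab, g_ba, x_a, x_b) -> Tensor:
    """Penalty for altering an image already in the generator's target domain."""
    x_a, x_b = _batch(x_a), _batch(x_b)
    return l1(g_ba(x_a), x_a) + l1(g_ab(x_b), x_b)


def gradient_penalty(critic, real, fake, lambda_gp: float = 10.0, seed: int = 0) -> Tensor:
    """lambda * E[(||grad_y critic(y)||_2 - 1)^2] at random interpolates.

    Interpolates are y = eps*real + (1-eps)*fake with eps ~ U(0,1) per
    sample under ``seed``; the per-sample input gradient comes from a traced
    backward pass, so the penalty itself remains differentiable with respect
    to the critic weights.
    """
    real, fake = _batch(real), _batch(fake)
    if real.shape != fake.shape:
        raise ValueError("real and fake batches must share shapes")
    n = real.shape[0]
    eps = np.random.default_rng(seed).uniform(size=(n, 1, 1, 1))
    # leaf node: the interpolate is the differentiation point, not the
    # endpoints (which the critic update treats as constants anyway)
    interp = Tensor(eps * real.data + (1.0 - eps) * fake.data, requires_grad=True)
    scores = critic(interp)
    (g,) = ad.grad(ad.tsum(scores), [interp])
    sq = ad.tsum(g * g, axis=(1, 2, 3))
    norm = ad.sqrt(sq + 1e-12)
    return Tensor(np.float64(lambda_gp)) * ad.tmean((norm - 1.0) ** 2)


def critic_pair_loss(critic, real, fake, lambda_gp: float = 10.0, seed: int = 0) -> Tensor:
    """One direction's critic objective: E[D(fake)] - E[D(real)] + penalty.

    Minimizing this drives the critic toward the 1-Wasserstein witness
    function; the gradient penalty keeps it near 1-Lipschitz.
    """
    real, fake = _batch(real), _batch(fake)
    wasserstein = ad.tmean(critic(fake)) - ad.tmean(critic(real))
    return wasserstein + gradient_penalty(critic, real, fake, lambda_gp, seed)


def adversarial_loss(
    g_ab, g_ba, d_a, d_b, x_a, x_b, lambda_gp: float = 10.0, seed: int = 0
) -> tuple[Tensor, Tensor]:
    """Both directions' adversarial terms, averaged with factor 1/2.

    Returns ``(critic objective, generator objective)``.  The gradient
    penalty enters the critic objective only; generated samples are detached
    there so critic gradients do not flow into the generators.  The
    generator objective is the negated fake-score term.
    """
    x_a, x_b = _batch(x_a), _batch(x_b)
    fake_b = g_ab(x_a)
    fake_a = g_ba(x_b)
    half = Tensor(np.float64(0.5))
    critic_obj = half * (
        critic_pair_loss(d_b, x_b, fake_b.detach(), lambda_gp, seed)
        + critic_pair_loss(d_a, x_a, fake_a.detach(), lambda_gp, seed + 1)
    )
    gen_obj = half * (-ad.tmean(d_b(fake_b)) - ad.tmean(d_a(fake_a)))
    return critic_obj, gen_obj


def total_loss(components: dict, weights: LossWeights) -> float:
    """Weighted combination L = L_adv + alpha*L_cyc + beta*L_id + gamma*L_sup.

    ``components`` maps names in {"adv", "cyclic", "identity", "sup"} to
    scalars; a term whose weight is zero may be absent entirely (ablation).
    """
    def get(name):
        v = components.get(name)
        if v is None:
            return 0.0
        v = v.item() if isinstance(v, Tensor) else float(v)
        if not np.isfinite(v):
            raise ValueError(f"loss component {name!r} is not finite")
        return v

    return (
        get("adv")
        + weights.alpha * get("cyclic")
        + weights.beta * get("identity")
        + weights.gamma * get("sup")
    )
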