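"""Clebsch-Gordan equivariant classifier for amino-acid microenvironments.

The network consumes Zernike coefficient blocks grouped by spherical degree l.
Each layer applies three operations, all of which commute with rotations of the
input point cloud:

* **linearity** -- mixes channels within each degree l (never across l or m);
* **Clebsch-Gordan nonlinearity** -- forms pairwise products of activation rows
  and decomposes them back into degrees l3 via the real coupling tensors.  In
  ``simply`` mode only a row with itself (l1 = l2, same channel); in ``fully``
  mode all (l1, l2) and channel pairs;
* **spherical batch norm** -- divides each (l, channel) row by a running mean
  of its rotation-invariant Euclidean norm.

The degree-0 (invariant) channels of every layer are concatenated and fed to a
feed-forward head that outputs 20 logits, termed pseudoenergies: they equal
log-probabilities up to an additive constant.  Because only invariants reach
the head, predictions are exactly rotation invariant.

Implementation note: forward and backward passes are written directly in numpy
(explicit vector-Jacobian products per operation); the batch-norm divisor is
treated as a constant during backpropagation.  Training uses Adam on a softmax
cross-entropy loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .basis import BasisSpec
from .cg import real_coupling
from .holograms import HologramCoefficients
from .wigner import real_wigner_d

__all__ = [
    "AA_ALPHABET",
    "AAProfile",
    "EquivariantTensor",
    "NetworkConfig",
    "CGNetwork",
    "TrainLog",
    "linear_layer",
    "cg_nonlinearity",
    "spherical_batch_norm",
    "collect_invariants",
    "train",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


@dataclass
class AAProfile:
    """Pseudoenergies (logits) and probabilities over the 20 amino acids.

    Order is fixed alphabetically by 1-letter code: ``ACDEFGHIKLMNPQRSTVWY``.
    """

    pseudoenergies: np.ndarray
    alphabet: str = AA_ALPHABET

    def __post_init__(self):
        self.pseudoenergies = np.asarray(self.pseudoenergies, dtype=float).reshape(-1)
        if self.pseudoenergies.shape != (len(self.alphabet),):
            raise ValueError("profile must have one pseudoenergy per amino acid")

    @property
    def probabilities(self) -> np.ndarray:
        return softmax(self.pseudoenergies)

    def pseudoenergy(self, aa: str) -> float:
        return float(self.pseudoenergies[self.alphabet.index(aa)])

    def log_probability(self, aa: str) -> float:
        logp = self.pseudoenergies - _logsumexp(self.pseudoenergies)
        return float(logp[self.alphabet.index(aa)])

    def argmax(self) -> str:
        # ties broken toward the alphabetically first amino acid (np.argmax does)
        return self.alphabet[int(np.argmax(self.pseudoenergies))]


def _logsumexp(x):
    m = np.max(x)
    return m + np.log(np.sum(np.exp(x - m)))


@dataclass
class EquivariantTensor:
    """Activations grouped by degree l: blocks[l] has shape (channels_l, 2l+1).

    ``metadata[l]`` optionally records per-channel provenance (e.g. the (channel
    name, radial index) of input rows, or a learned-channel index).
    """

    blocks: dict[int, np.ndarray]
    metadata: dict[int, list] | None = None

    def __post_init__(self):
        for l, b in self.blocks.items():
            b = np.asarray(b, dtype=float)
            if b.ndim != 2 or b.shape[1] != 2 * l + 1:
                raise ValueError(f"block for l={l} must have shape (channels, {2*l+1})")
            self.blocks[l] = b

    @classmethod
    def from_coefficients(cls, coeffs: HologramCoefficients, l_max: int | None = None):
        l_hi = coeffs.basis.l_max if l_max is None else min(l_max, coeffs.basis.l_max)
        blocks = {l: coeffs.blocks[l].copy() for l in range(l_hi + 1)}
        meta = {l: coeffs.row_labels(l) for l in range(l_hi + 1)}
        return cls(blocks=blocks, metadata=meta)

    def rotated(self, rotation: np.ndarray) -> "EquivariantTensor":
        return EquivariantTensor(
            {l: b @ real_wigner_d(l, rotation).T for l, b in self.blocks.items()},
            metadata=self.metadata,
        )


# ---------------------------------------------------------------------------
# the three layer operations (public, single-sample / batched forms)
# ---------------------------------------------------------------------------

def linear_layer(tensor: EquivariantTensor, weights: dict[int, np.ndarray]) -> EquivariantTensor:
    """Per-degree channel mixing: out[l] = W_l @ x[l].  Never mixes l or m."""
    out = {}
    for l, b in tensor.blocks.items():
        w = weights[l]
        if w.shape[1] != b.shape[0]:
            raise ValueError(
                f"weight for l={l} has in-dim {w.shape[1]}, block has {b.shape[0]} channels"
            )
        out[l] = w @ b
    return EquivariantTensor(out)


def _product_plan(in_degrees_channels: dict[int, int], mode: str, l_max: int):
    """Enumerate the CG product segments for one nonlinearity application.

    Returns a list of (l1, l2, l3, pairing) where pairing is 'diag' (same
    channel with itself) or 'outer' (all channel pairs), plus the resulting
    channel count per l3.
    """
    if mode not in ("simply", "fully"):
        raise ValueError("mode must be 'simply' or 'fully'")
    degrees = sorted(in_degrees_channels)
    plan = []
    if mode == "simply":
        for l in degrees:
            for l3 in range(0, min(2 * l, l_max) + 1):
                plan.append((l, l, l3, "diag"))
    else:
        for i1, l1 in enumerate(degrees):
            for l2 in degrees[i1:]:
                for l3 in range(abs(l1 - l2), min(l1 + l2, l_max) + 1):
                    plan.append((l1, l2, l3, "outer"))
    return plan


def cg_nonlinearity(tensor: EquivariantTensor, mode: str, l_max: int) -> EquivariantTensor:
    """Pairwise CG products of activation rows, decomposed into degrees <= l_max."""
    x = {l: b[None] for l, b in tensor.blocks.items()}  # add batch axis
    out, _ = _cg_forward(x, mode, l_max)
    return EquivariantTensor({l: b[0] for l, b in out.items()})


def _cg_forward(x: dict[int, np.ndarray], mode: str, l_max: int):
    """Batched CG nonlinearity.  x[l]: (B, C_l, 2l+1).  Returns (out, cache)."""
    chans = {l: b.shape[1] for l, b in x.items()}
    plan = _product_plan(chans, mode, l_max)
    pieces: dict[int, list[np.ndarray]] = {}
    cache = []
    for l1, l2, l3, pairing in plan:
        t = real_coupling(l1, l2, l3)
        if not t.any():
            continue
        a1, a2 = x[l1], x[l2]
        if pairing == "diag":
            p = np.einsum("pqr,biq,bir->bip", t, a1, a2, optimize=True)
        else:
            b_, c1, c2 = a1.shape[0], a1.shape[1], a2.shape[1]
            p = np.einsum("pqr,biq,bjr->bijp", t, a1, a2, optimize=True)
            p = p.reshape(b_, c1 * c2, 2 * l3 + 1)
        pieces.setdefault(l3, []).append(p)
        cache.append((l1, l2, l3, pairing, t))
    out = {l3: np.concatenate(ps, axis=1) for l3, ps in sorted(pieces.items())}
    return out, cache


def _cg_backward(dout: dict[int, np.ndarray], x: dict[int, np.ndarray], cache):
    """VJP of _cg_forward.  dout[l3]: (B, C_out_l3, 2l3+1)."""
    dx = {l: np.zeros_like(b) for l, b in x.items()}
    offset = {l3: 0 for l3 in dout}
    for l1, l2, l3, pairing, t in cache:
        a1, a2 = x[l1], x[l2]
        if pairing == "diag":
            c = a1.shape[1]
            dp = dout[l3][:, offset[l3]: offset[l3] + c]
            offset[l3] += c
            dx[l1] += np.einsum("bip,pqr,bir->biq", dp, t, a2, optimize=True)
            dx[l2] += np.einsum("bip,pqr,biq->bir", dp, t, a1, optimize=True)
        else:
            c1, c2 = a1.shape[1], a2.shape[1]
            dp = dout[l3][:, offset[l3]: offset[l3] + c1 * c2]
            offset[l3] += c1 * c2
            dp = dp.reshape(dp.shape[0], c1, c2, 2 * l3 + 1)
            dx[l1] += np.einsum("bijp,pqr,bjr->biq", dp, t, a2, optimize=True)
            dx[l2] += np.einsum("bijp,pqr,biq->bjr", dp, t, a1, optimize=True)
    return dx


def spherical_batch_norm(
    batch: dict[int, np.ndarray],
    running_stats: dict[int, np.ndarray],
    train_flag: bool,
    momentum: float = 0.1,
    eps: float = 1e-6,
):
    """Normalise each (l, channel) row by the mean rotation-invariant row norm.

    ``batch[l]``: (B, C_l, 2l+1).  In train mode the statistic is the batch
    mean of the Euclidean row norms and the running statistic is updated; in
    eval mode the stored running statistic is used.  Returns (normalised batch,
    divisors used).
    """
    out, divisors = {}, {}
    for l, y in batch.items():
        norms = np.linalg.norm(y, axis=2)          # (B, C)
        if train_flag:
            stat = norms.mean(axis=0)              # (C,)
            if l in running_stats:
                running_stats[l] = (1 - momentum) * running_stats[l] + momentum * stat
            else:
                running_stats[l] = stat.copy()
            div = stat + eps
        else:
            div = running_stats.get(l, np.ones(y.shape[1])) + eps
        out[l] = y / div[None, :, None]
        divisors[l] = div
    return out, divisors


def collect_invariants(per_layer: list[EquivariantTensor]) -> np.ndarray:
    """Concatenate the degree-0 channels of every layer output, in layer order."""
    parts = []
    for t in per_layer:
        if 0 not in t.blocks:
            raise ValueError("tensor lacks a degree-0 block")
        parts.append(np.asarray(t.blocks[0])[..., 0].reshape(-1))
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``hidden_channels`` is the per-degree channel width maintained between
    layers; ``l_max`` caps the degrees carried through the network (it may be
    lower than the encoding's l_max); ``head_widths`` are the hidden widths of
    the feed-forward head.
    """

    n_layers: int = 2
    mode: str = "fully"
    hidden_channels: int = 8
    l_max: int = 3
    head_widths: tuple[int, ...] = (64,)
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("simply", "fully"):
            raise ValueError("mode must be 'simply' or 'fully'")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        self.head_widths = tuple(self.head_widths)


@dataclass
class TrainLog:
    epochs: list[int] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


class CGNetwork:
    """The equivariant classifier: stacked CG layers + invariant head."""

    def __init__(self, config: NetworkConfig, basis: BasisSpec,
                 channels: tuple[str, ...], n_classes: int = 20,
                 alphabet: str = AA_ALPHABET):
        if n_classes == len(alphabet):
            pass
        elif n_classes < len(alphabet):
            alphabet = alphabet[:n_classes]
        else:
            raise ValueError("n_classes may not exceed the alphabet size")
        self.config = config
        self.basis = basis
        self.channels = tuple(channels)
        self.n_classes = n_classes
        self.alphabet = alphabet
        self._build()

    # -- architecture ---------------------------------------------------
    def _build(self):
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        l_net = min(cfg.l_max, self.basis.l_max)
        in_ch = {
            l: len(self.channels) * len(self.basis.n_list(l)) for l in range(l_net + 1)
        }
        self.l_net = l_net
        self.layers = []
        self.running_stats: list[dict[int, np.ndarray]] = []
        h = cfg.hidden_channels
        cur = in_ch
        inv_dim = 0
        for _ in range(cfg.n_layers):
            w_in = {l: rng.standard_normal((h, cur[l])) / np.sqrt(cur[l])
                    for l in cur}
            plan = _product_plan({l: h for l in cur}, cfg.mode, l_net)
            mid_ch: dict[int, int] = {}
            for l1, l2, l3, pairing in plan:
                if not real_coupling(l1, l2, l3).any():
                    continue
                mid_ch[l3] = mid_ch.get(l3, 0) + (h if pairing == "diag" else h * h)
            w_out = {l: rng.standard_normal((h, mid_ch[l])) / np.sqrt(mid_ch[l])
                     for l in sorted(mid_ch)}
            self.layers.append({"w_in": w_in, "w_out": w_out})
            self.running_stats.append({})
            cur = {l: h for l in sorted(mid_ch)}
            inv_dim += h  # each layer contributes its l=0 channels
        widths = [inv_dim, *cfg.head_widths, self.n_classes]
        self.head = []
        for d_in, d_out in zip(widths[:-1], widths[1:]):
            w = rng.standard_normal((d_out, d_in)) * np.sqrt(2.0 / d_in)
            b = np.zeros(d_out)
            self.head.append({"w": w, "b": b})
        self.invariant_dim = inv_dim

    @property
    def n_parameters(self) -> int:
        n = 0
        for layer in self.layers:
            for w in (*layer["w_in"].values(), *layer["w_out"].values()):
                n += w.size
        for lin in self.head:
            n += lin["w"].size + lin["b"].size
        return n

    # -- forward --------------------------------------------------------
    def _check_basis(self, coeffs: HologramCoefficients):
        if (coeffs.basis.l_max, coeffs.basis.n_max) != (self.basis.l_max, self.basis.n_max) \
                or coeffs.basis.r_max != self.basis.r_max:
            raise ValueError("coefficient basis does not match model basis")
        if tuple(coeffs.channels) != self.channels:
            raise ValueError("coefficient channels do not match model channels")

    def _stack(self, dataset: list[HologramCoefficients]) -> dict[int, np.ndarray]:
        for c in dataset:
            self._check_basis(c)
        return {
            l: np.stack([c.blocks[l] for c in dataset])
            for l in range(self.l_net + 1)
        }

    def _forward_batch(self, x: dict[int, np.ndarray], train: bool, cache_out=None):
        """Batched forward pass.  x[l]: (B, C_l, 2l+1) -> logits (B, n_classes)."""
        cfg = self.config
        inv_parts = []
        caches = []
        for k, layer in enumerate(self.layers):
            a = {l: np.einsum("oc,bcm->bom", layer["w_in"][l], x[l]) for l in x}
            mid, cg_cache = _cg_forward(a, cfg.mode, self.l_net)
            y = {l: np.einsum("oc,bcm->bom", layer["w_out"][l], mid[l]) for l in mid}
            z, div = spherical_batch_norm(y, self.running_stats[k], train)
            inv_parts.append(z[0][:, :, 0])
            caches.append({"x": x, "a": a, "mid": mid, "cg": cg_cache,
                           "div": div, "z": z})
            x = z
        hvec = np.concatenate(inv_parts, axis=1)
        acts = [hvec]
        h = hvec
        for j, lin in enumerate(self.head):
            h = h @ lin["w"].T + lin["b"]
            if j < len(self.head) - 1:
                h = np.maximum(h, 0.0)
            acts.append(h)
        if cache_out is not None:
            cache_out["layers"] = caches
            cache_out["acts"] = acts
        return h

    def forward(self, coeffs: HologramCoefficients) -> AAProfile:
        """Predict the amino-acid profile for one encoded neighborhood."""
        self._check_basis(coeffs)
        x = {l: coeffs.blocks[l][None] for l in range(self.l_net + 1)}
        logits = self._forward_batch(x, train=False)
        return AAProfile(logits[0], alphabet=self.alphabet)

    def predict_batch(self, dataset: list[HologramCoefficients]) -> np.ndarray:
        """Logits for a list of encoded neighborhoods, shape (B, n_classes)."""
        return self._forward_batch(self._stack(dataset), train=False)

    # -- backward -------------------------------------------------------
    def _backward_batch(self, cache, dlogits: np.ndarray):
        grads = {"layers": [], "head": []}
        acts = cache["acts"]
        dh = dlogits
        head_grads = [None] * len(self.head)
        for j in range(len(self.head) - 1, -1, -1):
            a_in = acts[j]
            head_grads[j] = {
                "w": dh.T @ a_in,
                "b": dh.sum(axis=0),
            }
            dh = dh @ self.head[j]["w"]
            if j > 0:
                dh = dh * (acts[j] > 0)
        grads["head"] = head_grads
        d_inv = dh  # gradient w.r.t. the concatenated invariants
        h = self.config.hidden_channels
        layer_grads = [None] * len(self.layers)
        dz_next: dict[int, np.ndarray] | None = None
        for k in range(len(self.layers) - 1, -1, -1):
            c = cache["layers"][k]
            z = c["z"]
            dz = {l: np.zeros_like(z[l]) for l in z}
            seg = d_inv[:, k * h:(k + 1) * h]
            dz[0][:, :, 0] += seg
            if dz_next is not None:
                for l in dz_next:
                    dz[l] += dz_next[l]
            dy = {l: dz[l] / c["div"][l][None, :, None] for l in dz}
            w_out_g = {
                l: np.einsum("bom,bcm->oc", dy[l], c["mid"][l]) for l in dy
            }
            dmid = {
                l: np.einsum("oc,bom->bcm", self.layers[k]["w_out"][l], dy[l])
                for l in dy
            }
            da = _cg_backward(dmid, c["a"], c["cg"])
            w_in_g = {
                l: np.einsum("bom,bcm->oc", da[l], c["x"][l]) for l in da
            }
            dx = {
                l: np.einsum("oc,bom->bcm", self.layers[k]["w_in"][l], da[l])
                for l in da
            }
            layer_grads[k] = {"w_in": w_in_g, "w_out": w_out_g}
            dz_next = dx
        grads["layers"] = layer_grads
        return grads

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        arrays = {}
        for k, layer in enumerate(self.layers):
            for l, w in layer["w_in"].items():
                arrays[f"layer{k}_w_in_{l}"] = w
            for l, w in layer["w_out"].items():
                arrays[f"layer{k}_w_out_{l}"] = w
            for l, s in self.running_stats[k].items():
                arrays[f"layer{k}_stat_{l}"] = s
        for j, lin in enumerate(self.head):
            arrays[f"head{j}_w"] = lin["w"]
            arrays[f"head{j}_b"] = lin["b"]
        meta = {
            "config": asdict(self.config),
            "basis": {"l_max": self.basis.l_max, "n_max": self.basis.n_max,
                      "r_max": self.basis.r_max},
            "channels": list(self.channels),
            "n_classes": self.n_classes,
            "alphabet": self.alphabet,
        }
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "CGNetwork":
        data = np.load(path)
        meta = json.loads(bytes(data["meta_json"]).decode())
        cfg = NetworkConfig(**{**meta["config"],
                               "head_widths": tuple(meta["config"]["head_widths"])})
        model = cls(cfg, BasisSpec(**meta["basis"]), tuple(meta["channels"]),
                    n_classes=meta["n_classes"], alphabet=meta["alphabet"])
        for k, layer in enumerate(model.layers):
            for l in layer["w_in"]:
                layer["w_in"][l] = data[f"layer{k}_w_in_{l}"]
            for l in layer["w_out"]:
                layer["w_out"][l] = data[f"layer{k}_w_out_{l}"]
            for l in layer["w_out"]:
                key = f"layer{k}_stat_{l}"
                if key in data:
                    model.running_stats[k][l] = data[key]
        for j, lin in enumerate(model.head):
            lin["w"] = data[f"head{j}_w"]
            lin["b"] = data[f"head{j}_b"]
        return model

    # parameter flattening for the optimizer -----------------------------
    def _param_items(self):
        for k, layer in enumerate(self.layers):
            for l in sorted(layer["w_in"]):
                yield ("layers", k, "w_in", l)
            for l in sorted(layer["w_out"]):
                yield ("layers", k, "w_out", l)
        for j in range(len(self.head)):
            yield ("head", j, "w", None)
            yield ("head", j, "b", None)

    def _get_param(self, item):
        group, k, name, l = item
        if group == "layers":
            return self.layers[k][name][l]
        return self.head[k][name]

    def _set_param(self, item, value):
        group, k, name, l = item
        if group == "layers":
            self.layers[k][name][l] = value
        else:
            self.head[k][name] = value

    @staticmethod
    def _get_grad(grads, item):
        group, k, name, l = item
        if group == "layers":
            return grads["layers"][k][name][l]
        return grads["head"][k][name]


def _cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean softmax cross-entropy and its gradient w.r.t. logits."""
    b = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -logp[np.arange(b), labels].mean()
    p = np.exp(logp)
    dlogits = p
    dlogits[np.arange(b), labels] -= 1.0
    return loss, dlogits / b


def train(
    dataset: list[tuple[HologramCoefficients, str]],
    config: NetworkConfig,
    epochs: int = 200,
    lr: float = 1e-3,
    seed: int = 0,
    batch_size: int = 32,
    validation: list[tuple[HologramCoefficients, str]] | None = None,
    alphabet: str | None = None,
) -> tuple[CGNetwork, TrainLog]:
    """Train a :class:`CGNetwork` with Adam on softmax cross-entropy.

    Deterministic given ``seed``.  If a validation set is supplied the
    checkpoint with the best validation accuracy is returned, otherwise the
    final model.  Raises on a non-finite loss with a diagnostic.
    """
    if alphabet is None:
        alphabet = "".join(sorted({lab for _, lab in dataset}))
    if len({lab for _, lab in dataset}) < 2:
        raise ValueError("training requires at least 2 classes")
    coeffs = [c for c, _ in dataset]
    y = np.array([alphabet.index(lab) for _, lab in dataset])
    model = CGNetwork(config, coeffs[0].basis, tuple(coeffs[0].channels),
                      n_classes=len(alphabet), alphabet=alphabet)
    x_all = model._stack(coeffs)
    if validation is not None:
        xv = model._stack([c for c, _ in validation])
        yv = np.array([alphabet.index(lab) for _, lab in validation])

    rng = np.random.default_rng(seed)
    items = list(model._param_items())
    mom = {i: np.zeros_like(model._get_param(it)) for i, it in enumerate(items)}
    vel = {i: np.zeros_like(model._get_param(it)) for i, it in enumerate(items)}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t_step = 0
    log = TrainLog()
    n = len(coeffs)
    best_val, best_state = -np.inf, None

    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb = {l: x_all[l][idx] for l in x_all}
            cache: dict = {}
            logits = model._forward_batch(xb, train=True, cache_out=cache)
            loss, dlogits = _cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (batch starting {start}); "
                    "try a lower learning rate or check input scaling"
                )
            grads = model._backward_batch(cache, dlogits)
            t_step += 1
            for i, it in enumerate(items):
                g = CGNetwork._get_grad(grads, it)
                mom[i] = beta1 * mom[i] + (1 - beta1) * g
                vel[i] = beta2 * vel[i] + (1 - beta2) * g * g
                m_hat = mom[i] / (1 - beta1**t_step)
                v_hat = vel[i] / (1 - beta2**t_step)
                model._set_param(it, model._get_param(it) - lr * m_hat / (np.sqrt(v_hat) + eps))
            ep_loss += loss * len(idx)
            ep_correct += int((logits.argmax(axis=1) == y[idx]).sum())
        log.epochs.append(epoch)
        log.loss.append(ep_loss / n)
        log.accuracy.append(ep_correct / n)
        if validation is not None:
            lv = model._forward_batch(xv, train=False)
            vloss, _ = _cross_entropy(lv, yv)
            vacc = float((lv.argmax(axis=1) == yv).mean())
            log.val_loss.append(vloss)
            log.val_accuracy.append(vacc)
            if vacc > best_val:
                best_val = vacc
                best_state = _snapshot(model)
    if best_state is not None:
        _restore(model, best_state)
    return model, log


def _snapshot(model: CGNetwork):
    return (
        [{n: {l: w.copy() for l, w in layer[n].items()} for n in ("w_in", "w_out")}
         for layer in model.layers],
        [{"w": lin["w"].copy(), "b": lin["b"].copy()} for lin in model.head],
        [{l: s.copy() for l, s in st.items()} for st in model.running_stats],
    )


def _restore(model: CGNetwork, state):
    layers, head, stats = state
    model.layers = layers
    model.head = head
    model.running_stats = stats
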