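"""Band-selecting attention network for spectral trait regression.

The forward pass composes, in order:

1. a *mask* stage — gated convolution followed by a U-shaped
   encoder/LSTM-bottleneck/decoder — that re-weights the input spectrum
   while a cosine loss keeps its shape (see ``training.mask_similarity_loss``);
2. ten *band-attention heads* that each emit one hard one-hot band choice
   per channel via cosine similarity, an adaptive cosine scale, and a
   uniform-noise Gumbel softmax (straight-through in hard mode);
3. three *vegetation-index branches* (double-difference, add-multiply,
   ratio) computed elementwise on the selected, sigmoid-squashed
   reflectance; and
4. a *gated fusion head* that softmax-scores the three index forms and
   regresses the trait from the weighted sum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import autograd.numpy as anp
from autograd.tracer import getval

from . import nn
from .nn import DTYPE

# branch -> number of band roles in its formula; head order follows this dict
BRANCH_ROLES = {"double_diff": 4, "add_mul": 4, "ratio": 2}
BRANCH_NAMES = tuple(BRANCH_ROLES)
N_HEADS = sum(BRANCH_ROLES.values())
INDEX_EPS = 1e-6


@dataclass
class ModelConfig:
    n_bands: int = 204
    gconv_channels: int = 128          # pre-split; halves into feature + gate
    ucrn_channels: int = 64
    ucrn_stages: int = 4
    ucrn_kernel: int = 5
    ucrn_dilation: int = 2
    pool_kernel: int = 2
    recurrent_hidden: int = 64
    attn_channels: int = 64
    attn_kernel: int = 5
    attn_dilation: int = 2
    gumbel_temperature: float = 1.0
    gumbel_shrink: float = 10.0
    dropout_rate: float = 0.2
    head_hidden: int = 128
    index_eps: float = INDEX_EPS
    # numerical guard: the difference/product denominators make branch values
    # unbounded (R3≈R4 crosses zero despite ε); clip keeps float32 finite
    branch_clip: float = 50.0
    # divide attention logits by the band count before the Gumbel softmax.
    # Off by default: with the adaptive cosine scale already normalising the
    # logit range, the extra 1/204 collapses logits to ~±0.05, the softmax
    # goes uniform and band selection cannot learn.
    scale_logits_by_bands: bool = False
    # replicate edge values when padding the attention convolutions; zero
    # padding makes the first/last bands artificially distinctive and the
    # argmax selection locks onto the spectrum ends
    attn_edge_pad: bool = True
    # multiply the gathered reflectance by the adaptive cosine factor before
    # the sigmoid ("the weights were scaled, multiplied with the reflectance,
    # then passed through a sigmoid"); without it the sigmoid of raw [0,1]
    # reflectance collapses every activation into (0.5, 0.73)
    scale_selected: bool = True

    def __post_init__(self):
        if self.gconv_channels % 2:
            raise ValueError("gconv_channels must be even")
        if self.n_bands < 2 ** self.ucrn_stages:
            raise ValueError("n_bands too small for the encoder poolings")
        for name in ("n_bands", "gconv_channels", "ucrn_channels", "recurrent_hidden",
                     "attn_channels", "head_hidden"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gumbel_temperature <= 0 or self.gumbel_shrink <= 0:
            raise ValueError("gumbel temperature and shrink must be positive")

    @property
    def attn_padding(self) -> int:
        # length-preserving padding for the dilated attention convs
        return self.attn_dilation * (self.attn_kernel - 1) // 2

    @property
    def ucrn_padding(self) -> int:
        return self.ucrn_dilation * (self.ucrn_kernel - 1) // 2


@dataclass
class BandSelection:
    """One hard band choice: which branch/role/channel picked which band."""

    branch: str
    role: str
    channel: int
    band_index: int
    wavelength: float


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def init_model(config: ModelConfig, seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    half = config.gconv_channels // 2
    if half != config.ucrn_channels:
        raise ValueError("gconv feature half must match ucrn_channels")
    c = config.ucrn_channels
    k, d = config.ucrn_kernel, config.ucrn_dilation

    params = {
        "gconv": {
            "feature": nn.conv_init(rng, 1, half, 5),
            "gate": nn.conv_init(rng, 1, half, 5),
        },
        "ucrn": {
            "pre1": nn.conv_init(rng, c, c, k),
            "pre2": nn.conv_init(rng, c, c, k),
            "enc": [{"conv": nn.conv_init(rng, c, c, k), "bn": nn.batchnorm_init(c)}
                    for _ in range(config.ucrn_stages)],
            "bott_in": nn.linear_init(rng, c, config.recurrent_hidden),
            "lstm": nn.lstm_init(rng, config.recurrent_hidden, config.recurrent_hidden),
            "bott_out": nn.linear_init(rng, config.recurrent_hidden, c),
            "dec": [nn.conv_init(rng, c, c, k) for _ in range(config.ucrn_stages)],
            # bias 1 starts the mask near identity so early features keep the
            # input's scale (the cosine mask loss is scale-free)
            "final": {**nn.conv_init(rng, c, 1, 1),
                      "b": np.ones(1, dtype=DTYPE)},
        },
        "heads": [
            {
                "q": nn.conv_init(rng, 1, config.attn_channels, config.attn_kernel),
                "v": nn.conv_init(rng, config.attn_channels, config.attn_channels,
                                  config.attn_kernel),
                "wl": rng.normal(scale=0.5, size=(config.attn_channels,
                                                  config.attn_channels)).astype(DTYPE),
            }
            for _ in range(N_HEADS)
        ],
        "fusion": {
            "score": nn.conv_init(rng, len(BRANCH_NAMES), len(BRANCH_NAMES), 1),
            "fc1": nn.linear_init(rng, config.attn_channels, config.head_hidden),
            "fc2": nn.linear_init(rng, config.head_hidden, 1),
        },
    }
    return params


def count_parameters(params: dict) -> int:
    return nn.count_parameters(params)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def gated_conv_forward(params: dict, x):
    """x: (B, 1, L) -> ReLU(feature ⊙ sigmoid(gate)), (B, C/2, L)."""
    feature = nn.conv1d(params["feature"], x, dilation=1, padding=2)
    gate = nn.conv1d(params["gate"], x, dilation=1, padding=2)
    return nn.relu(feature * nn.sigmoid(gate))


def ucrn_forward(params: dict, x, config: ModelConfig):
    """Encoder/bottleneck/decoder over the band axis: (B, C, L) -> (B, 1, L)."""
    pad = config.ucrn_padding
    d = config.ucrn_dilation
    h = nn.conv1d(params["pre1"], x, dilation=d, padding=pad)
    h = nn.conv1d(params["pre2"], h, dilation=d, padding=pad)
    pre = h

    skips = []
    for stage in params["enc"]:
        h = nn.maxpool1d(h, config.pool_kernel)
        h = nn.relu(nn.batchnorm1d(stage["bn"], nn.conv1d(stage["conv"], h,
                                                          dilation=d, padding=pad)))
        skips.append(h)

    # bottleneck: channel compression -> LSTM over band positions -> expansion
    t = anp.transpose(h, (0, 2, 1))
    t = nn.linear(params["bott_in"], t)
    t = nn.lstm(params["lstm"], t)
    t = nn.linear(params["bott_out"], t)
    h = anp.transpose(t, (0, 2, 1))

    # decoder: upsample, add matching encoder features, convolve
    targets = [s.shape[2] for s in skips[-2::-1]] + [pre.shape[2]]
    skip_feats = skips[-2::-1] + [pre]
    for conv, target, skip in zip(params["dec"], targets, skip_feats):
        h = nn.upsample_nearest(h, target)
        h = nn.relu(nn.conv1d(conv, h + skip, dilation=d, padding=pad))

    return nn.relu(nn.conv1d(params["final"], h))


def mask_forward(params: dict, x, config: ModelConfig):
    """O = I × Mask(I); returns (masked spectrum, mask map)."""
    mask = ucrn_forward(params["ucrn"], gated_conv_forward(params["gconv"], x), config)
    return x * mask, mask


def adacos_scale(x, bandnum: int):
    """Adaptive cosine scale over the last axis of x.

    S = 2·ln(bandnum); B_i = exp(S·x_i − max(S·x)); α = max(S·x) + ln(mean B)/cos(π/4).
    """
    if bandnum < 2:
        raise ValueError("bandnum must be >= 2")
    if np.size(x) == 0:
        raise ValueError("empty input")
    s = 2.0 * anp.log(float(bandnum))
    sx = s * x
    m = anp.max(sx, axis=-1, keepdims=True)
    b = anp.exp(sx - m)
    b_avg = anp.mean(b, axis=-1)
    return anp.squeeze(m, axis=-1) + anp.log(b_avg) / np.cos(np.pi / 4.0)


def uniform_gumbel_softmax(logits, tau: float, shrink: float, hard: bool = False,
                           rng: np.random.Generator | None = None):
    """Softmax over the last axis of (noise + logits)/tau, with uniform [0,1)
    noise divided by ``shrink``; rng=None means noise-free (evaluation).

    Hard mode returns exact one-hots at the argmax with straight-through
    gradients (the backward pass sees the soft distribution).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if shrink <= 0:
        raise ValueError("shrink must be positive")
    if rng is not None:
        noise = (rng.random(np.shape(logits)) / shrink).astype(DTYPE)
        logits = logits + noise
    soft = nn.softmax(logits / DTYPE(tau), axis=-1)
    if not hard:
        return soft
    soft_val = getval(soft)
    idx = np.argmax(soft_val, axis=-1)
    onehot = np.zeros(soft_val.shape, dtype=DTYPE)
    np.put_along_axis(onehot, np.asarray(idx)[..., None], 1.0, axis=-1)
    return soft + nn.stop_gradient(onehot - soft)


from autograd.extend import primitive, defvjp


def _adacos_select_core(cos, refl, noise, tau, n_bands, logit_div=1.0):
    """Shared forward math: cos (B,H,A,L), refl (B,L) -> intermediates."""
    s2 = 2.0 * np.log(float(n_bands))
    c45 = np.cos(np.pi / 4.0)
    sx = s2 * cos
    m = sx.max(axis=-1, keepdims=True)
    b_mat = np.exp(sx - m)
    b_avg = b_mat.mean(axis=-1, keepdims=True)
    alpha = m + np.log(b_avg) / c45
    logits = alpha * cos / np.float32(logit_div)
    z = logits if noise is None else logits + noise
    z = z / np.float32(tau)
    zmax = z.max(axis=-1, keepdims=True)
    ez = np.exp(z - zmax)
    soft = ez / ez.sum(axis=-1, keepdims=True)
    return s2, c45, sx, m, b_mat, b_avg, alpha, z, soft


@primitive
def _attention_select(cos, refl, noise=None, tau=1.0, n_bands=204, hard=True,
                      out_idx=None, logit_div=1.0, scale_selected=False):
    """Fused adacos-scale → uniform-Gumbel softmax → band gather.

    cos: (B, H, A, L) cosine similarities; refl: (B, L) reflectance.
    Returns the selected (pre-sigmoid) reflectance (B, H, A); in hard mode
    the forward value is an exact gather at the argmax while the VJP is the
    straight-through soft expectation.  ``out_idx`` (int array (B, H, A)),
    when given, receives the argmax band indices as a side channel.

    One taped op replacing ~20 large elementwise intermediates; asserted
    equivalent to the composable ops in the test suite.
    """
    _, _, _, _, _, _, alpha, z, soft = _adacos_select_core(cos, refl, noise, tau,
                                                           n_bands, logit_div)
    idx = np.argmax(z, axis=-1)
    if out_idx is not None:
        out_idx[...] = idx
    if hard:
        sel = np.take_along_axis(
            np.broadcast_to(refl[:, None, None, :], z.shape), idx[..., None], -1
        )[..., 0]
    else:
        sel = np.einsum("bhal,bl->bha", soft, refl)
    return alpha[..., 0] * sel if scale_selected else sel


def _attention_select_vjp_cos(ans, cos, refl, noise=None, tau=1.0, n_bands=204,
                              hard=True, out_idx=None, logit_div=1.0,
                              scale_selected=False):
    def vjp(gout):
        s2, c45, sx, m, b_mat, b_avg, alpha, z, soft = _adacos_select_core(
            cos, refl, noise, tau, n_bands, logit_div)
        a2 = alpha[..., 0]
        if scale_selected:
            if hard:
                idx = np.argmax(z, axis=-1)
                sel = np.take_along_axis(
                    np.broadcast_to(refl[:, None, None, :], z.shape),
                    idx[..., None], -1)[..., 0]
            else:
                sel = np.einsum("bhal,bl->bha", soft, refl)
            gsel = gout * a2
            galpha_out = (gout * sel)[..., None]
        else:
            gsel = gout
            galpha_out = 0.0
        gsoft = gsel[..., None] * refl[:, None, None, :]
        gz = soft * (gsoft - np.sum(gsoft * soft, axis=-1, keepdims=True))
        glogit = gz / np.float32(tau)
        n = np.float32(logit_div)
        galpha = np.sum(glogit * cos, axis=-1, keepdims=True) / n + galpha_out
        e_max = (sx == m)
        e_max = e_max / e_max.sum(axis=-1, keepdims=True)     # split ties
        dalpha = s2 * (e_max * (1.0 - 1.0 / c45)
                       + b_mat / (cos.shape[-1] * b_avg * c45))
        return glogit * alpha / n + galpha * dalpha
    return vjp


def _attention_select_vjp_refl(ans, cos, refl, noise=None, tau=1.0, n_bands=204,
                               hard=True, out_idx=None, logit_div=1.0,
                               scale_selected=False):
    def vjp(gsel):
        _, _, _, _, _, _, alpha, z, soft = _adacos_select_core(cos, refl, noise, tau,
                                                               n_bands, logit_div)
        if scale_selected:
            gsel = gsel * alpha[..., 0]
        if hard:
            # forward gathered at the argmax, so the gather is what refl sees
            idx = np.argmax(z, axis=-1)
            out = np.zeros_like(refl)
            batch = np.broadcast_to(
                np.arange(refl.shape[0])[:, None, None], idx.shape)
            np.add.at(out, (batch.ravel(), idx.ravel()), gsel.ravel())
            return out
        return np.einsum("bha,bhal->bl", gsel, soft)
    return vjp


defvjp(_attention_select, _attention_select_vjp_cos, _attention_select_vjp_refl)


def _edge_pad(x, pad: int):
    """Replicate-pad the last axis (works on 3- and 4-D maps)."""
    left = anp.repeat(x[..., :1], pad, axis=-1)
    right = anp.repeat(x[..., -1:], pad, axis=-1)
    return anp.concatenate([left, x, right], axis=-1)


def band_attention_forward(params: dict, features, reflectance, config: ModelConfig,
                           hard: bool = True, rng: np.random.Generator | None = None):
    """One attention head.

    features, reflectance: (B, 1, L).  Returns (activations (B, A), alignment
    rows (B, A, L), band indices (B, A)).
    """
    pad = config.attn_padding
    d = config.attn_dilation
    if config.attn_edge_pad:
        q = nn.relu(nn.conv1d(params["q"], _edge_pad(features, pad), dilation=d))
        v = nn.relu(nn.conv1d(params["v"], _edge_pad(q, pad), dilation=d))
    else:
        q = nn.relu(nn.conv1d(params["q"], features, dilation=d, padding=pad))
        v = nn.relu(nn.conv1d(params["v"], q, dilation=d, padding=pad))

    v_norm = v / anp.sqrt(anp.sum(v * v, axis=1, keepdims=True) + 1e-12)
    w = params["wl"]
    w_norm = w / anp.sqrt(anp.sum(w * w, axis=1, keepdims=True) + 1e-12)
    cos = anp.matmul(w_norm, v_norm)                       # (B, A, L), in [-1, 1]

    alpha = adacos_scale(cos, config.n_bands)              # (B, A)
    div = DTYPE(config.n_bands if config.scale_logits_by_bands else 1.0)
    logits = alpha[:, :, None] * cos / div

    align = uniform_gumbel_softmax(logits, config.gumbel_temperature,
                                   config.gumbel_shrink, hard=hard, rng=rng)
    selected = anp.sum(align * reflectance, axis=2)        # (B, A)
    if config.scale_selected:
        selected = alpha * selected
    activations = nn.sigmoid(selected)
    band_idx = np.argmax(getval(align), axis=-1)
    return activations, align, band_idx


def multi_head_attention_forward(head_params: list, features, reflectance,
                                 config: ModelConfig, hard: bool = True,
                                 rng: np.random.Generator | None = None):
    """All attention heads in one pass via grouped GEMMs.

    Numerically identical to running :func:`band_attention_forward` per head
    (asserted in the test suite) but ~an order of magnitude cheaper on CPU,
    since one traced op replaces each per-head op.

    Returns (activations (B, H, A), band indices (B, H, A)).
    """
    n_heads = len(head_params)
    a = config.attn_channels
    pad, d = config.attn_padding, config.attn_dilation
    batch = features.shape[0]

    q_w = anp.concatenate([p["q"]["w"] for p in head_params], axis=0)   # (H*A, K)
    q_b = anp.concatenate([p["q"]["b"] for p in head_params], axis=0)
    v_w = anp.stack([p["v"]["w"] for p in head_params], axis=0)         # (H, A, A*K)
    v_b = anp.stack([p["v"]["b"] for p in head_params], axis=0)
    wl = anp.stack([p["wl"] for p in head_params], axis=0)              # (H, A, A)

    if config.attn_edge_pad:
        q = nn._conv1d_gemm(q_w, q_b, _edge_pad(features, pad), dilation=d,
                            relu=True)
        q = anp.reshape(q, (batch, n_heads, a, config.n_bands))
        v = nn.grouped_conv1d(v_w, v_b, _edge_pad(q, pad), dilation=d, relu=True)
    else:
        q = nn._conv1d_gemm(q_w, q_b, features, dilation=d, padding=pad, relu=True)
        q = anp.reshape(q, (batch, n_heads, a, config.n_bands))
        v = nn.grouped_conv1d(v_w, v_b, q, dilation=d, padding=pad, relu=True)

    v_norm = nn.unit_normalize(v, axis=2)
    w_norm = nn.unit_normalize(wl, axis=2)
    cos = anp.matmul(w_norm, v_norm)                                    # (B, H, A, L)

    noise = None
    if rng is not None:
        noise = (rng.random((batch, n_heads, a, config.n_bands))
                 / config.gumbel_shrink).astype(DTYPE)
    band_idx = np.empty((batch, n_heads, a), dtype=np.int64)
    refl2d = anp.reshape(reflectance, (batch, config.n_bands))
    selected = _attention_select(
        cos, refl2d, noise=noise, tau=config.gumbel_temperature,
        n_bands=config.n_bands, hard=hard, out_idx=band_idx,
        logit_div=float(config.n_bands) if config.scale_logits_by_bands else 1.0,
        scale_selected=config.scale_selected)
    activations = nn.sigmoid(selected)
    return activations, band_idx


def index_branch_forward(selected: dict, branch: str, eps: float = INDEX_EPS):
    """Elementwise index form on per-role (B, A) activations."""
    if branch == "double_diff":
        need = ("R1", "R2", "R3", "R4")
    elif branch == "add_mul":
        need = ("R1", "R2", "R3", "R4")
    elif branch == "ratio":
        need = ("R1", "R2")
    else:
        raise ValueError(f"unknown branch {branch!r}")
    missing = [r for r in need if r not in selected]
    if missing:
        raise ValueError(f"branch {branch} missing roles {missing}")
    r = selected
    if branch == "double_diff":
        return (r["R1"] - r["R2"]) / (r["R3"] - r["R4"] + eps)
    if branch == "add_mul":
        return (r["R1"] + r["R2"]) / (r["R3"] * r["R4"] + eps)
    return r["R1"] / (r["R2"] + eps)


def fusion_head_forward(params: dict, branch_features, config: ModelConfig,
                        rng: np.random.Generator | None = None, train: bool = False):
    """branch_features: (B, 3, A) -> (prediction (B,), form scores (B, 3, A))."""
    if branch_features.shape[1] != len(BRANCH_NAMES):
        raise ValueError(f"expected {len(BRANCH_NAMES)} branch feature vectors")
    raw = nn.conv1d(params["score"], branch_features)       # 1x1 conv over form axis
    scores = nn.softmax(raw, axis=1)
    fused = anp.sum(scores * branch_features, axis=1)       # (B, A)
    h = nn.relu(nn.linear(params["fc1"], fused))
    h = nn.dropout(h, config.dropout_rate, rng, train)
    out = nn.linear(params["fc2"], h)
    return anp.reshape(out, (-1,)), scores


# ---------------------------------------------------------------------------
# full forward
# ---------------------------------------------------------------------------

def iter_head_roles():
    """Yield (head_index, branch, role) in the fixed head order."""
    i = 0
    for branch, n_roles in BRANCH_ROLES.items():
        for r in range(n_roles):
            yield i, branch, f"R{r + 1}"
            i += 1


def model_forward(params: dict, config: ModelConfig, x, hard: bool = True,
                  rng: np.random.Generator | None = None, train: bool = False):
    """Full forward pass.

    x: (B, L) reflectance on the config grid.  Returns a dict with keys
    ``pred`` (B,), ``form_scores`` (B, 3, A), ``band_idx`` {head: (B, A)},
    ``mask_in``/``mask_out`` (B, 1, L).
    """
    if isinstance(x, np.ndarray):
        x = np.ascontiguousarray(x, dtype=DTYPE)
    x = anp.reshape(x, (x.shape[0], 1, config.n_bands))
    masked, mask = mask_forward(params, x, config)

    acts, all_idx = multi_head_attention_forward(params["heads"], masked, x, config,
                                                 hard=hard, rng=rng)
    role_maps = {b: {} for b in BRANCH_NAMES}
    band_idx = {}
    for i, branch, role in iter_head_roles():
        role_maps[branch][role] = acts[:, i, :]
        band_idx[i] = all_idx[:, i, :]

    branch_feats = anp.stack(
        [index_branch_forward(role_maps[b], b, config.index_eps) for b in BRANCH_NAMES],
        axis=1)                                            # (B, 3, A)
    if config.branch_clip:
        branch_feats = anp.clip(branch_feats, -config.branch_clip, config.branch_clip)
    pred, scores = fusion_head_forward(params["fusion"], branch_feats, config,
                                       rng=rng, train=train)
    return {"pred": pred, "form_scores": scores, "band_idx": band_idx,
            "mask_in": x, "mask_out": masked}


def selections_from_band_idx(band_idx: dict, wavelengths: np.ndarray) -> list[BandSelection]:
    """Flatten per-head argmax indices into BandSelection records.

    Selections are input-dependent; when the index arrays carry several
    samples, one record per (sample, head, channel) is emitted so frequency
    reports aggregate over the whole probe set.
    """
    out = []
    for i, branch, role in iter_head_roles():
        rows = np.atleast_2d(band_idx[i])
        for row in rows:
            for channel, b in enumerate(row):
                out.append(BandSelection(branch, role, channel, int(b),
                                         float(wavelengths[int(b)])))
    return out


# ---------------------------------------------------------------------------
# checkpoint I/O: npz weights + json sidecar (config + wavelength grid)
# ---------------------------------------------------------------------------

def _flatten_tree(tree, prefix="", out=None):
    out = {} if out is None else out
    if isinstance(tree, dict):
        for k, v in tree.items():
            _flatten_tree(v, f"{prefix}{k}.", out)
    elif isinstance(tree, (list, tuple)):
        for i, v in enumerate(tree):
            _flatten_tree(v, f"{prefix}{i}.", out)
    else:
        out[prefix[:-1]] = tree
    return out


def _set_path(tree, path, value):
    keys = path.split(".")
    node = tree
    for k in keys[:-1]:
        node = node[int(k)] if isinstance(node, (list, tuple)) else node[k]
    last = keys[-1]
    if isinstance(node, (list, tuple)):
        node[int(last)] = value
    else:
        node[last] = value


def save_model(params: dict, config: ModelConfig, wavelengths: np.ndarray, path) -> None:
    path = str(path)
    np.savez(path if path.endswith(".npz") else path + ".npz",
             **_flatten_tree(params))
    sidecar = path[:-4] if path.endswith(".npz") else path
    with open(sidecar + ".json", "w") as fh:
        json.dump({"config": asdict(config),
                   "wavelengths": np.asarray(wavelengths).tolist()}, fh, indent=2)


def load_model(path) -> tuple[dict, ModelConfig, np.ndarray]:
    path = str(path)
    npz_path = path if path.endswith(".npz") else path + ".npz"
    sidecar = npz_path[:-4] + ".json"
    with open(sidecar) as fh:
        meta = json.load(fh)
    config = ModelConfig(**meta["config"])
    params = init_model(config, seed=0)
    data = np.load(npz_path)
    for key in data.files:
        _set_path(params, key, data[key])
    return params, config, np.asarray(meta["wavelengths"])
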