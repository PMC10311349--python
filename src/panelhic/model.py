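"""The reference-panel attention U-net as a pure computation graph.

The network enhances one scaled ``w x w`` contact-map patch of a study
sample, guided by the same genomic region extracted from ``n`` reference
samples:

* ``F`` lifts the 1-channel patch to ``d`` channels with one ReLU 9x9 conv.
* ``E1``/``E2``/``E3`` are consecutive encoding blocks linked by 2x2 max
  pooling; ``E1``/``E2`` are two ReLU 3x3 convs with dropout in between,
  ``E3`` (batch norm, convs, pool, flatten) emits a flat ``(w/8)^2`` vector
  used as the attention query (study) and keys (references).
* Attention weights ``alpha = softmax(Q K^T)`` combine the references'
  ``E1``/``E2`` feature maps (values ``V1``/``V2``) into ``s1``/``s2``; the
  attention outputs are ``a_k = s_k + A_k(s_k)`` where ``A1``/``A2`` mirror
  ``E1``/``E2`` but are preceded by layer normalization.
* The U-net skip connections are replaced by concatenations of the study
  embedding with the attention output at the same scale, projected back to
  ``d`` channels by ``P1``/``P2``; the decoder ``D1``/``D2`` (layouts of
  ``E2``/``E1``, nearest-neighbour 2x upsampling) and the output block ``O``
  (ReLU 3x3 conv then ReLU 9x9 conv to one channel) produce the enhanced
  nonnegative ``w x w`` patch.

No batch normalization appears in ``F``/``E1``/``E2`` (it introduces
artifacts in enhanced maps); dot-product attention is unscaled. The output
patch is not symmetrized here — symmetrization happens at stitch time.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .nn import Parameter, Tensor

__all__ = ["ModelConfig", "MultiscaleEmbedding", "AttentionOutput", "RefPanelUNet"]


@dataclass
class ModelConfig:
    w: int = 200              # window size in bins; divisible by 8
    d: int = 24               # embedding channels
    outer_filter: int = 9     # first (F) and last (O) conv filter size
    inner_filter: int = 3     # all internal conv filter sizes
    dropout: float = 0.2

    def __post_init__(self):
        if self.w % 8 != 0:
            raise ValueError(f"w={self.w} must be divisible by 8")
        if self.d < 1:
            raise ValueError("d must be >= 1")


@dataclass
class MultiscaleEmbedding:
    """Per-sample encoder outputs (batched along axis 0)."""

    f: Tensor     # (B, d, w, w)      F output (study copy feeds O)
    v1: Tensor    # (B, d, w, w)      E1 output (attention value, level 1)
    v2: Tensor    # (B, d, w/2, w/2)  E2 output (attention value, level 2)
    key: Tensor   # (B, (w/8)^2)      E3 output (query for study, key for refs)


@dataclass
class AttentionOutput:
    alpha: Tensor  # (n, 1) simplex weights over references
    a1: Tensor     # (1, d, w, w)
    a2: Tensor     # (1, d, w/2, w/2)


class RefPanelUNet:
    """Panel-attention U-net; parameters live in a flat name -> Parameter dict."""

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0,
                 use_panel: bool = True):
        self.cfg = cfg or ModelConfig()
        self.use_panel = use_panel
        self.training = True
        self.rng = np.random.default_rng(seed)  # dropout noise
        self.params: dict[str, Parameter] = {}
        self.bn_running = {"mean": np.zeros((1, self.cfg.d, 1, 1)),
                           "var": np.ones((1, self.cfg.d, 1, 1))}
        self._init_params(np.random.default_rng(np.random.SeedSequence([seed, 0x1417])))

    # -- parameter setup ----------------------------------------------------

    def _conv_param(self, rng, name: str, c_in: int, c_out: int, k: int):
        std = np.sqrt(2.0 / (c_in * k * k))
        self.params[f"{name}.w"] = Parameter(rng.normal(0.0, std, (c_out, c_in, k, k)))
        self.params[f"{name}.b"] = Parameter(np.zeros(c_out))

    def _init_params(self, rng):
        d, ko, ki = self.cfg.d, self.cfg.outer_filter, self.cfg.inner_filter
        self._conv_param(rng, "F", 1, d, ko)
        for blk in ("E1", "E2", "A1", "A2", "D1"):
            self._conv_param(rng, f"{blk}.c1", d, d, ki)
            self._conv_param(rng, f"{blk}.c2", d, d, ki)
        self._conv_param(rng, "E3.c1", d, d, ki)
        self._conv_param(rng, "E3.c2", d, d, ki)
        self._conv_param(rng, "E3.c3", d, 1, ki)
        self._conv_param(rng, "P1", 2 * d, d, ki)
        self._conv_param(rng, "P2", 2 * d, d, ki)
        self._conv_param(rng, "D2.c1", 2 * d, d, ki)
        self._conv_param(rng, "D2.c2", d, d, ki)
        self._conv_param(rng, "O.c1", 2 * d, d, ki)
        self._conv_param(rng, "O.c2", d, 1, ko)
        self.params["E3.bn.g"] = Parameter(np.ones(d))
        self.params["E3.bn.b"] = Parameter(np.zeros(d))
        for blk in ("A1", "A2"):
            self.params[f"{blk}.ln.g"] = Parameter(np.ones(d))
            self.params[f"{blk}.ln.b"] = Parameter(np.zeros(d))

    # -- mode handling ------------------------------------------------------

    def train(self):
        self.training = True
        return self

    def eval(self):
        self.training = False
        return self

    def encoder_param_names(self) -> list[str]:
        """Parameters of F and E1-E3 (the contrastively pretrained subset)."""
        return [k for k in self.params
                if k.split(".")[0] in ("F", "E1", "E2", "E3")]

    # -- building blocks ----------------------------------------------------

    def _conv(self, name: str, x: Tensor) -> Tensor:
        return nn.conv2d(x, self.params[f"{name}.w"], self.params[f"{name}.b"])

    def _two_conv_block(self, name: str, x: Tensor) -> Tensor:
        """conv-ReLU, dropout, conv-ReLU (the E1/E2/A1/A2/D1 layout)."""
        h = nn.relu(self._conv(f"{name}.c1", x))
        h = nn.dropout(h, self.cfg.dropout, self.rng, self.training)
        return nn.relu(self._conv(f"{name}.c2", h))

    # -- public operations --------------------------------------------------

    def encode(self, patches: np.ndarray) -> MultiscaleEmbedding:
        """Run F and E1-E3 on a batch of scaled patches (B, w, w) or (B, 1, w, w)."""
        x = np.asarray(patches, dtype=float)
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[2] != self.cfg.w or x.shape[3] != self.cfg.w:
            raise ValueError(
                f"encode: patch shape {x.shape[2:]} does not match w={self.cfg.w}")
        t = Tensor(x, requires_grad=False)
        f = nn.relu(self._conv("F", t))
        v1 = self._two_conv_block("E1", f)
        p1 = nn.maxpool2x2(v1)
        v2 = self._two_conv_block("E2", p1)
        p2 = nn.maxpool2x2(v2)
        h = nn.batchnorm2d(p2, self.params["E3.bn.g"], self.params["E3.bn.b"],
                           self.bn_running, self.training)
        h = nn.relu(self._conv("E3.c1", h))
        h = nn.dropout(h, self.cfg.dropout, self.rng, self.training)
        h = nn.maxpool2x2(h)
        h = nn.relu(self._conv("E3.c2", h))
        h = nn.relu(self._conv("E3.c3", h))
        key = nn.flatten(h)
        if key.shape[1] != (self.cfg.w // 8) ** 2:
            raise AssertionError("E3 produced a key of unexpected length")
        return MultiscaleEmbedding(f=f, v1=v1, v2=v2, key=key)

    def _attention_block(self, name: str, s: Tensor) -> Tensor:
        h = nn.layernorm(s, self.params[f"{name}.ln.g"], self.params[f"{name}.ln.b"])
        return self._two_conv_block(name, h)

    def attend(self, query: Tensor, ref_keys: Tensor, ref_v1: Tensor,
               ref_v2: Tensor) -> AttentionOutput:
        """Unscaled dot-product attention over the reference samples."""
        if ref_keys.shape[0] < 1:
            raise ValueError("attend requires at least one reference sample")
        logits = nn.matmul(ref_keys, nn.transpose2d(query))   # (n, 1)
        alpha = nn.softmax_vec(logits)
        s1 = nn.attend_combine(alpha, ref_v1)
        s2 = nn.attend_combine(alpha, ref_v2)
        a1 = nn.add(s1, self._attention_block("A1", s1))
        a2 = nn.add(s2, self._attention_block("A2", s2))
        return AttentionOutput(alpha=alpha, a1=a1, a2=a2)

    def forward(self, study: np.ndarray, refs: np.ndarray | None) -> Tensor:
        """Enhance one scaled study patch given reference patches at the region.

        ``study``: (w, w); ``refs``: (n, w, w) or None for the no-panel
        ablation. Returns a (1, 1, w, w) tensor of nonnegative scaled values.
        """
        study = np.asarray(study, dtype=float)
        if study.shape != (self.cfg.w, self.cfg.w):
            raise ValueError(f"study patch shape {study.shape} != ({self.cfg.w}, {self.cfg.w})")
        w2, d = self.cfg.w // 2, self.cfg.d
        if self.use_panel:
            if refs is None or len(refs) == 0:
                raise ValueError("panel model requires at least one reference patch")
            refs = np.asarray(refs, dtype=float)
            if refs.shape[1:] != (self.cfg.w, self.cfg.w):
                raise ValueError("reference patches must share the study window size")
            emb = self.encode(np.concatenate([study[None], refs], axis=0))
            f_s = nn.slice_batch(emb.f, 0, 1)
            v1_s = nn.slice_batch(emb.v1, 0, 1)
            v2_s = nn.slice_batch(emb.v2, 0, 1)
            q = nn.slice_batch(emb.key, 0, 1)
            att = self.attend(q, nn.slice_batch(emb.key, 1, None),
                              nn.slice_batch(emb.v1, 1, None),
                              nn.slice_batch(emb.v2, 1, None))
            a1, a2 = att.a1, att.a2
        else:
            emb = self.encode(study[None])
            f_s, v1_s, v2_s = emb.f, emb.v1, emb.v2
            a1 = Tensor(np.zeros((1, d, self.cfg.w, self.cfg.w)), requires_grad=False)
            a2 = Tensor(np.zeros((1, d, w2, w2)), requires_grad=False)

        p1 = nn.relu(self._conv("P1", nn.concat_channels(v1_s, a1)))
        p2 = nn.relu(self._conv("P2", nn.concat_channels(v2_s, a2)))
        d1 = self._two_conv_block("D1", p2)
        d2 = self._two_conv_block("D2", nn.concat_channels(p1, nn.upsample2x(d1)))
        o = nn.relu(self._conv("O.c1", nn.concat_channels(f_s, d2)))
        return nn.relu(self._conv("O.c2", o))

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"param:{k}": p.data for k, p in self.params.items()}
        arrays["bn:mean"] = self.bn_running["mean"]
        arrays["bn:var"] = self.bn_running["var"]
        meta = json.dumps({"cfg": asdict(self.cfg), "use_panel": self.use_panel})
        arrays["meta"] = np.frombuffer(meta.encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path) -> "RefPanelUNet":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            model = cls(ModelConfig(**meta["cfg"]), use_panel=meta["use_panel"])
            for k in model.params:
                model.params[k].data = z[f"param:{k}"].copy()
            model.bn_running = {"mean": z["bn:mean"].copy(), "var": z["bn:var"].copy()}
        return model.eval()

    def load_encoder(self, path) -> None:
        """Initialize F/E1-E3 (and batch-norm state) from a pretrained checkpoint."""
        with np.load(path) as z:
            for k in self.encoder_param_names():
                self.params[k].data = z[f"param:{k}"].copy()
            self.bn_running = {"mean": z["bn:mean"].copy(), "var": z["bn:var"].copy()}
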