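"""Two-headed convolutional network: shared trunk, diagnosis and prognosis heads."""

from __future__ import annotations

import numpy as np

from dxprog.config import BackboneConfig
from dxprog.nn import layers as L

TRUNK_PREFIXES = ("conv", "fc")


class TwoHeadCNN:
    """Small CNN trunk with a multi-class diagnosis head and a single-logit
    prognosis head. Forward returns logits for both heads; backward accepts
    gradients for either head (pass ``None`` to detach a head's loss).
    """

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        cfg.validate()
        self.cfg = cfg
        self.params: dict[str, np.ndarray] = {}
        k = cfg.kernel_size
        c_in = 1
        for i, c_out in enumerate(cfg.conv_channels):
            fan_in = c_in * k * k
            self.params[f"conv{i}_W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
            self.params[f"conv{i}_b"] = np.zeros(c_out)
            c_in = c_out
        self.params["fc_W"] = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(cfg.embedding_dim, c_in))
        self.params["fc_b"] = np.zeros(cfg.embedding_dim)
        d = cfg.embedding_dim
        # zero-initialized heads: training starts as a linear probe (no trunk
        # gradient until the head moves), which protects pretrained features
        self.params["head_diag_W"] = np.zeros((cfg.diagnosis_classes, d))
        self.params["head_diag_b"] = np.zeros(cfg.diagnosis_classes)
        self.params["head_prog_W"] = np.zeros((1, d))
        self.params["head_prog_b"] = np.zeros(1)

    # -- weight management ---------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, value in state.items():
            self.params[key] = value.copy()

    def copy_trunk_and_diag_from(self, other: "TwoHeadCNN") -> None:
        """Phase-1 -> Phase-2 transfer: trunk + diagnosis head copied, prognosis head kept fresh."""
        for key, value in other.params.items():
            if key.startswith(TRUNK_PREFIXES) or key.startswith("head_diag"):
                self.params[key] = value.copy()

    # -- forward / backward --------------------------------------------------

    def forward(self, x: np.ndarray):
        """x: (B, H, W) float images; returns (diag_logits, prog_logits, cache).

        Full-resolution input is average-pooled by ``cfg.input_downsample``
        and centered before the first convolution.
        """
        n_conv = len(self.cfg.conv_channels)
        d = self.cfg.input_downsample
        if d > 1:
            B, H, W = x.shape
            x = x.reshape(B, H // d, d, W // d, d).mean(axis=(2, 4))
        h = (x[:, None, :, :].astype(np.float64) - 0.5) * 2.0
        caches = []
        for i in range(n_conv):
            h, c_conv = L.conv2d_forward(h, self.params[f"conv{i}_W"], self.params[f"conv{i}_b"])
            h, c_relu = L.relu_forward(h)
            if i < n_conv - 1:
                h, c_pool = L.avgpool2_forward(h)
            else:
                h, c_pool = L.global_avgpool_forward(h)
            caches.append((c_conv, c_relu, c_pool))
        emb, c_fc = L.linear_forward(h, self.params["fc_W"], self.params["fc_b"])
        emb, c_erelu = L.relu_forward(emb)
        diag, c_diag = L.linear_forward(emb, self.params["head_diag_W"], self.params["head_diag_b"])
        prog, c_prog = L.linear_forward(emb, self.params["head_prog_W"], self.params["head_prog_b"])
        return diag, prog, (caches, c_fc, c_erelu, c_diag, c_prog)

    def backward(self, cache, d_diag: np.ndarray | None, d_prog: np.ndarray | None) -> dict[str, np.ndarray]:
        caches, c_fc, c_erelu, c_diag, c_prog = cache
        grads: dict[str, np.ndarray] = {}
        demb = 0.0
        if d_diag is not None:
            dd, grads["head_diag_W"], grads["head_diag_b"] = L.linear_backward(
                d_diag, self.params["head_diag_W"], c_diag
            )
            demb = demb + dd
        if d_prog is not None:
            dp, grads["head_prog_W"], grads["head_prog_b"] = L.linear_backward(
                d_prog, self.params["head_prog_W"], c_prog
            )
            demb = demb + dp
        demb = L.relu_backward(demb, c_erelu)
        dh, grads["fc_W"], grads["fc_b"] = L.linear_backward(demb, self.params["fc_W"], c_fc)
        n_conv = len(self.cfg.conv_channels)
        for i in reversed(range(n_conv)):
            c_conv, c_relu, c_pool = caches[i]
            if i < n_conv - 1:
                dh = L.avgpool2_backward(dh, c_pool)
            else:
                dh = L.global_avgpool_backward(dh, c_pool)
            dh = L.relu_backward(dh, c_relu)
            dh, grads[f"conv{i}_W"], grads[f"conv{i}_b"] = L.conv2d_backward(
                dh, self.params[f"conv{i}_W"], c_conv
            )
        return grads

    # -- inference -----------------------------------------------------------

    def predict(self, x: np.ndarray, batch_size: int = 256):
        """Returns (diagnosis probability matrix, prognosis scores in [0,1])."""
        diag_probs, prog_scores = [], []
        for start in range(0, len(x), batch_size):
            d, p, _ = self.forward(x[start : start + batch_size])
            diag_probs.append(L.softmax(d))
            prog_scores.append(L.sigmoid(p.ravel()))
        return np.concatenate(diag_probs), np.concatenate(prog_scores)
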