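"""Minimal numpy neural-network stack for the expression classifier.

The fundamental unit is a peephole LSTM cell:

    i_t = sigmoid(W_xi x_t + W_hi h_{t-1} + W_ci c_{t-1} + b_i)
    f_t = sigmoid(W_xf x_t + W_hf h_{t-1} + W_cf c_{t-1} + b_f)
    c_t = f_t * c_{t-1} + i_t * tanh(W_xc x_t + W_hc h_{t-1} + b_c)
    o_t = sigmoid(W_xo x_t + W_ho h_{t-1} + W_co c_t + b_o)
    h_t = o_t * tanh(c_t)

Peephole weights are full matrices (the diagonal variant is a special case)
and are zero when the peephole switch is off, which recovers the standard
LSTM.  The network is two LSTM layers, inverted dropout after each during
training, a fully connected layer on the final hidden state, and softmax.
Gradients are exact backpropagation through time; the optimizer is Adam.

Everything here is deterministic given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTMCellParams", "LSTMLayer", "LSTMNetwork", "lstm_cell_step",
           "softmax", "AdamOptimizer"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class LSTMCellParams:
    """All weight matrices and biases of one LSTM cell.

    Shapes: ``W_x*`` are (hidden, input); ``W_h*`` and peephole ``W_c*`` are
    (hidden, hidden); biases are (hidden,).
    """

    GATE_NAMES = ("W_xi", "W_hi", "W_ci", "b_i",
                  "W_xf", "W_hf", "W_cf", "b_f",
                  "W_xc", "W_hc", "b_c",
                  "W_xo", "W_ho", "W_co", "b_o")

    def __init__(self, input_size: int, hidden_size: int,
                 peephole: bool = True,
                 rng: np.random.Generator | None = None):
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.peephole = peephole
        H, F = hidden_size, input_size

        def init(shape, fan_in):
            if rng is None:
                return np.zeros(shape)
            bound = np.sqrt(6.0 / (fan_in + shape[0]))
            return rng.uniform(-bound, bound, size=shape)

        for gate in "ifco":
            setattr(self, f"W_x{gate}", init((H, F), F))
            setattr(self, f"W_h{gate}", init((H, H), H))
            setattr(self, f"b_{gate}", np.zeros(H))
        for gate in "ifo":
            w = init((H, H), H) * 0.1 if peephole else np.zeros((H, H))
            setattr(self, f"W_c{gate}", w)
        # forget-gate bias 1: remember by default, standard LSTM practice
        self.b_f = self.b_f + 1.0 if rng is not None else self.b_f

    def check_shapes(self) -> None:
        H, F = self.hidden_size, self.input_size
        expected = {"W_xi": (H, F), "W_xf": (H, F), "W_xc": (H, F),
                    "W_xo": (H, F)}
        for name in self.GATE_NAMES:
            arr = getattr(self, name)
            want = expected.get(name, (H,) if name.startswith("b") else (H, H))
            if arr.shape != want:
                raise ValueError(f"{name} has shape {arr.shape}, want {want}")


def lstm_cell_step(p: LSTMCellParams, x_t: np.ndarray, h_prev: np.ndarray,
                   c_prev: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One cell update; accepts vectors or (batch, dim) arrays."""
    x_t, h_prev, c_prev = (np.atleast_2d(np.asarray(a, dtype=float))
                           for a in (x_t, h_prev, c_prev))
    if x_t.shape[-1] != p.input_size or h_prev.shape[-1] != p.hidden_size:
        raise ValueError(
            f"input/hidden sizes {x_t.shape[-1]}/{h_prev.shape[-1]} do not "
            f"match cell ({p.input_size}/{p.hidden_size})"
        )
    i = sigmoid(x_t @ p.W_xi.T + h_prev @ p.W_hi.T + c_prev @ p.W_ci.T + p.b_i)
    f = sigmoid(x_t @ p.W_xf.T + h_prev @ p.W_hf.T + c_prev @ p.W_cf.T + p.b_f)
    g = np.tanh(x_t @ p.W_xc.T + h_prev @ p.W_hc.T + p.b_c)
    c_t = f * c_prev + i * g
    o = sigmoid(x_t @ p.W_xo.T + h_prev @ p.W_ho.T + c_t @ p.W_co.T + p.b_o)
    h_t = o * np.tanh(c_t)
    return h_t, c_t


class LSTMLayer:
    """One LSTM layer unrolled over time, returning the full hidden sequence."""

    def __init__(self, input_size: int, hidden_size: int, peephole: bool = True,
                 rng: np.random.Generator | None = None):
        self.params = LSTMCellParams(input_size, hidden_size, peephole, rng)

    def forward(self, X: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """X is (batch, time, input); returns (batch, time, hidden)."""
        p = self.params
        B, T, _ = X.shape
        H = p.hidden_size
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        Hs = np.empty((B, T, H))
        if cache is not None:
            cache.update(X=X, i=[], f=[], g=[], o=[], c=[], tc=[],
                         h_prev=[], c_prev=[])
        for t in range(T):
            x_t = X[:, t, :]
            i = sigmoid(x_t @ p.W_xi.T + h @ p.W_hi.T + c @ p.W_ci.T + p.b_i)
            f = sigmoid(x_t @ p.W_xf.T + h @ p.W_hf.T + c @ p.W_cf.T + p.b_f)
            g = np.tanh(x_t @ p.W_xc.T + h @ p.W_hc.T + p.b_c)
            c_new = f * c + i * g
            o = sigmoid(x_t @ p.W_xo.T + h @ p.W_ho.T + c_new @ p.W_co.T + p.b_o)
            tc = np.tanh(c_new)
            h_new = o * tc
            if cache is not None:
                cache["h_prev"].append(h)
                cache["c_prev"].append(c)
                for k, v in zip("ifgoc", (i, f, g, o, c_new)):
                    cache[k].append(v)
                cache["tc"].append(tc)
            h, c = h_new, c_new
            Hs[:, t, :] = h
        return Hs

    def backward(self, cache: dict, dHs: np.ndarray) -> tuple[np.ndarray, dict]:
        """Backprop through time.

        ``dHs`` is the upstream gradient on the full hidden sequence
        (batch, time, hidden).  Returns (dX, parameter gradients).
        """
        p = self.params
        X = cache["X"]
        B, T, F = X.shape
        H = p.hidden_size
        grads = {name: np.zeros_like(getattr(p, name))
                 for name in p.GATE_NAMES}
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        dX = np.empty_like(X)
        for t in range(T - 1, -1, -1):
            i, f, g, o = (cache[k][t] for k in "ifgo")
            c_t, tc = cache["c"][t], cache["tc"][t]
            h_prev, c_prev = cache["h_prev"][t], cache["c_prev"][t]
            x_t = X[:, t, :]

            dh = dHs[:, t, :] + dh_next
            do = dh * tc
            da_o = do * o * (1 - o)
            dc = dc_next + dh * o * (1 - tc * tc) + da_o @ p.W_co
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da_i = di * i * (1 - i)
            da_f = df * f * (1 - f)
            da_g = dg * (1 - g * g)

            grads["W_xi"] += da_i.T @ x_t
            grads["W_hi"] += da_i.T @ h_prev
            grads["W_ci"] += da_i.T @ c_prev
            grads["b_i"] += da_i.sum(0)
            grads["W_xf"] += da_f.T @ x_t
            grads["W_hf"] += da_f.T @ h_prev
            grads["W_cf"] += da_f.T @ c_prev
            grads["b_f"] += da_f.sum(0)
            grads["W_xc"] += da_g.T @ x_t
            grads["W_hc"] += da_g.T @ h_prev
            grads["b_c"] += da_g.sum(0)
            grads["W_xo"] += da_o.T @ x_t
            grads["W_ho"] += da_o.T @ h_prev
            grads["W_co"] += da_o.T @ c_t
            grads["b_o"] += da_o.sum(0)

            dX[:, t, :] = (da_i @ p.W_xi + da_f @ p.W_xf
                           + da_g @ p.W_xc + da_o @ p.W_xo)
            dh_next = (da_i @ p.W_hi + da_f @ p.W_hf
                       + da_g @ p.W_hc + da_o @ p.W_ho)
            dc_next = dc * f + da_i @ p.W_ci + da_f @ p.W_cf
        if not p.peephole:
            # peephole matrices stay identically zero in the standard cell
            for name in ("W_ci", "W_cf", "W_co"):
                grads[name] = np.zeros_like(grads[name])
        return dX, grads


class LSTMNetwork:
    """Two stacked LSTM layers + dropout + fully connected softmax head."""

    def __init__(self, input_size: int, hidden_sizes: tuple[int, ...],
                 n_classes: int, peephole: bool = True, dropout: float = 0.3,
                 rng: np.random.Generator | None = None):
        if not 0 <= dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        self.input_size = input_size
        self.hidden_sizes = tuple(hidden_sizes)
        self.n_classes = n_classes
        self.peephole = peephole
        self.dropout = dropout
        self.layers: list[LSTMLayer] = []
        size = input_size
        for h in self.hidden_sizes:
            self.layers.append(LSTMLayer(size, h, peephole, rng))
            size = h
        if rng is None:
            self.W_fc = np.zeros((n_classes, size))
        else:
            bound = np.sqrt(6.0 / (size + n_classes))
            self.W_fc = rng.uniform(-bound, bound, (n_classes, size))
        self.b_fc = np.zeros(n_classes)

    # -- forward ------------------------------------------------------------

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Inference pass (dropout off).  X (batch, time, features) -> probs."""
        H = X
        for layer in self.layers:
            H = layer.forward(H)
        logits = H[:, -1, :] @ self.W_fc.T + self.b_fc
        return softmax(logits)

    def loss_and_grads(self, X: np.ndarray, y_onehot: np.ndarray,
                       rng: np.random.Generator | None = None
                       ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean cross-entropy + full gradient dict (training pass)."""
        B = X.shape[0]
        caches, masks = [], []
        H = X
        for layer in self.layers:
            cache: dict = {}
            H = layer.forward(H, cache)
            caches.append(cache)
            if self.dropout > 0 and rng is not None:
                mask = (rng.random(H.shape) >= self.dropout) / (1 - self.dropout)
                H = H * mask
            else:
                mask = None
            masks.append(mask)
        h_last = H[:, -1, :]
        logits = h_last @ self.W_fc.T + self.b_fc
        probs = softmax(logits)
        eps = 1e-12
        loss = -np.mean(np.log(np.sum(probs * y_onehot, axis=1) + eps))

        dlogits = (probs - y_onehot) / B
        grads = {"fc/W": dlogits.T @ h_last, "fc/b": dlogits.sum(0)}
        dH = np.zeros_like(H)
        dH[:, -1, :] = dlogits @ self.W_fc
        for li in range(len(self.layers) - 1, -1, -1):
            if masks[li] is not None:
                dH = dH * masks[li]
            dH, layer_grads = self.layers[li].backward(caches[li], dH)
            for name, g in layer_grads.items():
                grads[f"layer{li}/{name}"] = g
        return float(loss), grads

    # -- parameter plumbing --------------------------------------------------

    def parameter_dict(self) -> dict[str, np.ndarray]:
        out = {"fc/W": self.W_fc, "fc/b": self.b_fc}
        for li, layer in enumerate(self.layers):
            for name in LSTMCellParams.GATE_NAMES:
                out[f"layer{li}/{name}"] = getattr(layer.params, name)
        return out

    def set_parameter(self, key: str, value: np.ndarray) -> None:
        if key == "fc/W":
            self.W_fc = value
        elif key == "fc/b":
            self.b_fc = value
        else:
            prefix, name = key.split("/")
            li = int(prefix.removeprefix("layer"))
            setattr(self.layers[li].params, name, value)

    @classmethod
    def from_parameter_dict(cls, weights: dict[str, np.ndarray],
                            peephole: bool = True) -> "LSTMNetwork":
        n_layers = len({k.split("/")[0] for k in weights
                        if k.startswith("layer")})
        if n_layers == 0 or "fc/W" not in weights:
            raise ValueError("parameter dict lacks layers or FC head")
        hidden = tuple(weights[f"layer{li}/W_xi"].shape[0]
                       for li in range(n_layers))
        input_size = weights["layer0/W_xi"].shape[1]
        n_classes = weights["fc/W"].shape[0]
        net = cls(input_size, hidden, n_classes, peephole=peephole, rng=None)
        for key, value in weights.items():
            net.set_parameter(key, np.asarray(value, dtype=float))
        for layer in net.layers:
            layer.params.check_shapes()
        return net


class AdamOptimizer:
    """Plain Adam; state keyed by parameter name."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, net: LSTMNetwork, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        params = net.parameter_dict()
        for key, g in grads.items():
            if self.weight_decay and not key.endswith(("b_i", "b_f", "b_c",
                                                       "b_o", "/b")):
                g = g + self.weight_decay * params[key]
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            mhat = self.m[key] / (1 - self.beta1 ** self.t)
            vhat = self.v[key] / (1 - self.beta2 ** self.t)
            net.set_parameter(
                key, params[key] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            )
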