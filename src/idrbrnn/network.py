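"""The two-stage bidirectional recurrent network and the windowed NN baseline.

Stage architecture.  For a sequence of input vectors i_1..i_N, three
two-layer feed-forward subnets implement the output, forward-transition and
backward-transition functions:

    o_j     = N_O(i_j, hF_j, hB_j)
    hF_j    = N_F(i_j, hF_{j-1}, ..., hF_{j-S})
    hB_j    = N_B(i_j, hB_{j+1}, ..., hB_{j+S})

with zero boundary states, tanh hidden layers, tanh hidden-chain states and
softmax outputs (m = 2 classes: ordered, disordered).  S is the shortcut
span: each transition sees the previous/next S states, shortening gradient
paths along the chain.

Two-stage filtering.  A second, identical-architecture BRNN consumes
"semi-global" evidence: at position j its input is the first-stage output
c_j followed by 2p+1 window averages of first-stage outputs, the f-th window
centred at k_f = j + f(2w+1) and spanning k_f - w .. k_f + w.  Window
positions outside the sequence are excluded from both the sum and the
divisor.  Defaults w = 7, p = 10, giving a second-stage input of
m(2p + 2) values per position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels

PARAM_FIELDS = (
    "Wf1", "bf1", "Wf2", "bf2",
    "Wb1", "bb1", "Wb2", "bb2",
    "Wo1", "bo1", "Wo2", "bo2",
)

_PROB_FLOOR = 1e-12


@dataclass
class FilterGeometry:
    """Geometry of the second-stage filter: half-window w, half-count of
    windows p, number of classes m."""

    w: int = 7
    p: int = 10
    m: int = 2

    def __post_init__(self) -> None:
        if self.w < 0 or self.p < 0 or self.m < 2:
            raise ValueError("require w >= 0, p >= 0, m >= 2")

    @property
    def input_width(self) -> int:
        return self.m * (2 * self.p + 2)


@dataclass
class StageParams:
    """Parameters of one BRNN stage: forward/backward transition subnets and
    the output subnet, all two-layered."""

    Wf1: np.ndarray
    bf1: np.ndarray
    Wf2: np.ndarray
    bf2: np.ndarray
    Wb1: np.ndarray
    bb1: np.ndarray
    Wb2: np.ndarray
    bb2: np.ndarray
    Wo1: np.ndarray
    bo1: np.ndarray
    Wo2: np.ndarray
    bo2: np.ndarray
    span: int = 2

    @property
    def hidden_chain(self) -> int:
        return self.Wf2.shape[1]

    @property
    def subnet_hidden(self) -> int:
        return self.Wf1.shape[1]

    @property
    def n_classes(self) -> int:
        return self.Wo2.shape[1]

    @property
    def d(self) -> int:
        return self.Wf1.shape[0] - self.span * self.hidden_chain

    def arrays(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in PARAM_FIELDS}

    def copy(self) -> "StageParams":
        return StageParams(
            **{k: v.copy() for k, v in self.arrays().items()}, span=self.span
        )


def init_stage(
    d: int,
    hidden_chain: int = 11,
    subnet_hidden: int = 11,
    span: int = 2,
    m: int = 2,
    rng: np.random.Generator | None = None,
) -> StageParams:
    """Weights uniform in +-1/sqrt(fan_in), biases zero."""
    rng = rng or np.random.default_rng()
    if span < 1:
        raise ValueError("span must be >= 1")

    def mat(rows, cols):
        b = 1.0 / np.sqrt(rows)
        return rng.uniform(-b, b, size=(rows, cols))

    din_t = d + span * hidden_chain
    din_o = d + 2 * hidden_chain
    return StageParams(
        Wf1=mat(din_t, subnet_hidden), bf1=np.zeros(subnet_hidden),
        Wf2=mat(subnet_hidden, hidden_chain), bf2=np.zeros(hidden_chain),
        Wb1=mat(din_t, subnet_hidden), bb1=np.zeros(subnet_hidden),
        Wb2=mat(subnet_hidden, hidden_chain), bb2=np.zeros(hidden_chain),
        Wo1=mat(din_o, subnet_hidden), bo1=np.zeros(subnet_hidden),
        Wo2=mat(subnet_hidden, m), bo2=np.zeros(m),
        span=span,
    )


@dataclass
class TwoStageModel:
    stage1: StageParams
    stage2: StageParams
    geometry: FilterGeometry = field(default_factory=FilterGeometry)

    def __post_init__(self) -> None:
        if self.stage2.d != self.geometry.input_width:
            raise ValueError(
                f"stage-2 input width {self.stage2.d} != filter width "
                f"{self.geometry.input_width}"
            )

    def copy(self) -> "TwoStageModel":
        return TwoStageModel(
            self.stage1.copy(), self.stage2.copy(), replace(self.geometry)
        )


def init_two_stage(
    d: int,
    geometry: FilterGeometry | None = None,
    hidden_chain: int = 11,
    subnet_hidden: int = 11,
    span: int = 2,
    rng: np.random.Generator | None = None,
) -> TwoStageModel:
    rng = rng or np.random.default_rng()
    geometry = geometry or FilterGeometry()
    s1 = init_stage(d, hidden_chain, subnet_hidden, span, geometry.m, rng)
    s2 = init_stage(
        geometry.input_width, hidden_chain, subnet_hidden, span, geometry.m, rng
    )
    return TwoStageModel(s1, s2, geometry)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def stage_forward(
    params: StageParams, X: np.ndarray, return_cache: bool = False
):
    """Per-position class probabilities for one stage (rows sum to 1)."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != params.d:
        raise ValueError(
            f"input width {X.shape[1] if X.ndim == 2 else None} != "
            f"stage width {params.d}"
        )
    S = params.span
    hFpad, AF1 = _kernels.chain_forward(
        X, params.Wf1, params.bf1, params.Wf2, params.bf2, S, False
    )
    hBpad, AB1 = _kernels.chain_forward(
        X, params.Wb1, params.bb1, params.Wb2, params.bb2, S, True
    )
    n = X.shape[0]
    hF = hFpad[S : S + n]
    hB = hBpad[:n]
    UO = np.concatenate([X, hF, hB], axis=1)
    AO1 = np.tanh(UO @ params.Wo1 + params.bo1)
    logits = AO1 @ params.Wo2 + params.bo2
    probs = softmax(logits)
    if not return_cache:
        return probs
    cache = dict(
        X=X, hFpad=hFpad, hBpad=hBpad, AF1=AF1, AB1=AB1, UO=UO, AO1=AO1,
        probs=probs,
    )
    return probs, cache


def stage_backward(
    params: StageParams, cache: dict, dlogits: np.ndarray
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Gradients of a scalar loss wrt stage parameters and inputs, given the
    gradient on the pre-softmax logits."""
    X = cache["X"]
    n, d = X.shape
    H = params.hidden_chain
    AO1, UO = cache["AO1"], cache["UO"]
    dWo2 = AO1.T @ dlogits
    dbo2 = dlogits.sum(axis=0)
    dAO1 = dlogits @ params.Wo2.T
    dZO1 = dAO1 * (1.0 - AO1 * AO1)
    dWo1 = UO.T @ dZO1
    dbo1 = dZO1.sum(axis=0)
    dUO = dZO1 @ params.Wo1.T
    dX = np.ascontiguousarray(dUO[:, :d])
    dhF = np.ascontiguousarray(dUO[:, d : d + H])
    dhB = np.ascontiguousarray(dUO[:, d + H :])
    dWf1, dbf1, dWf2, dbf2, dXf = _kernels.chain_backward(
        X, params.Wf1, params.Wf2, cache["hFpad"], cache["AF1"], dhF,
        params.span, False,
    )
    dWb1, dbb1, dWb2, dbb2, dXb = _kernels.chain_backward(
        X, params.Wb1, params.Wb2, cache["hBpad"], cache["AB1"], dhB,
        params.span, True,
    )
    dX += dXf + dXb
    grads = dict(
        Wf1=dWf1, bf1=dbf1, Wf2=dWf2, bf2=dbf2,
        Wb1=dWb1, bb1=dbb1, Wb2=dWb2, bb2=dbb2,
        Wo1=dWo1, bo1=dbo1, Wo2=dWo2, bo2=dbo2,
    )
    return grads, dX


def _filter_indices(n: int, geom: FilterGeometry):
    width = 2 * geom.w + 1
    f = np.arange(-geom.p, geom.p + 1)
    j = np.arange(n)
    kf = j[:, None] + f[None, :] * width
    lo, hi = kf - geom.w, kf + geom.w
    lo_c = np.clip(lo, 0, n - 1)
    hi_c = np.clip(hi, 0, n - 1)
    valid = (hi >= 0) & (lo <= n - 1)
    counts = np.where(valid, hi_c - lo_c + 1, 1)
    return lo_c, hi_c, valid, counts


def build_filter_inputs(stage1_out: np.ndarray, geom: FilterGeometry) -> np.ndarray:
    """Second-stage input: first-stage output at j followed by 2p+1 window
    averages; out-of-range positions excluded from sum and divisor."""
    P = np.asarray(stage1_out, dtype=np.float64)
    n, m = P.shape
    if m != geom.m:
        raise ValueError(f"stage-1 output has {m} classes, geometry expects {geom.m}")
    lo_c, hi_c, valid, counts = _filter_indices(n, geom)
    cs = np.vstack([np.zeros((1, m)), np.cumsum(P, axis=0)])
    sums = cs[hi_c + 1] - cs[lo_c]  # n x (2p+1) x m
    avg = np.where(valid[..., None], sums / counts[..., None], 0.0)
    return np.concatenate([P, avg.reshape(n, -1)], axis=1)


def filter_inputs_adjoint(
    dF: np.ndarray, geom: FilterGeometry, n: int
) -> np.ndarray:
    """Adjoint of :func:`build_filter_inputs`: maps a gradient on the filter
    inputs back to a gradient on the stage-1 outputs."""
    m = geom.m
    dP = dF[:, :m].copy()
    davg = dF[:, m:].reshape(n, 2 * geom.p + 1, m)
    lo_c, hi_c, valid, counts = _filter_indices(n, geom)
    g = np.where(valid[..., None], davg / counts[..., None], 0.0)
    diff = np.zeros((n + 1, m))
    np.add.at(diff, lo_c.ravel(), g.reshape(-1, m))
    np.add.at(diff, (hi_c + 1).ravel(), -g.reshape(-1, m))
    dP += np.cumsum(diff, axis=0)[:n]
    return dP


def two_stage_forward(
    model: TwoStageModel, X: np.ndarray, return_cache: bool = False
):
    if return_cache:
        p1, c1 = stage_forward(model.stage1, X, return_cache=True)
        F = build_filter_inputs(p1, model.geometry)
        p2, c2 = stage_forward(model.stage2, F, return_cache=True)
        return p2, dict(p1=p1, c1=c1, F=F, c2=c2)
    p1 = stage_forward(model.stage1, X)
    F = build_filter_inputs(p1, model.geometry)
    return stage_forward(model.stage2, F)


def two_stage_predict(model: TwoStageModel, X: np.ndarray) -> np.ndarray:
    """N x m probabilities from the full two-stage network."""
    return two_stage_forward(model, X)


def two_stage_loss_grad(
    model: TwoStageModel, X: np.ndarray, y: np.ndarray
) -> tuple[float, int, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Summed cross-entropy of both stages against the labels, with gradients.

    Both stages are supervised with the same targets; the second-stage
    gradient additionally flows back through the filter into stage 1.
    Returns (loss_sum, n_residues, grads_stage1, grads_stage2).
    """
    y = np.asarray(y, dtype=np.intp)
    n = X.shape[0]
    if y.shape[0] != n:
        raise ValueError(f"labels length {y.shape[0]} != sequence length {n}")
    p2, cache = two_stage_forward(model, X, return_cache=True)
    p1 = cache["p1"]
    idx = np.arange(n)
    loss = -np.log(np.maximum(p2[idx, y], _PROB_FLOOR)).sum()
    loss += -np.log(np.maximum(p1[idx, y], _PROB_FLOOR)).sum()
    Y = np.zeros_like(p2)
    Y[idx, y] = 1.0
    dlogits2 = p2 - Y
    g2, dF = stage_backward(model.stage2, cache["c2"], dlogits2)
    dP1 = filter_inputs_adjoint(dF, model.geometry, n)
    # softmax adjoint for the gradient arriving on stage-1 probabilities,
    # plus the stage-1 cross-entropy term directly on the logits
    dlogits1 = p1 * (dP1 - (dP1 * p1).sum(axis=1, keepdims=True)) + (p1 - Y)
    g1, _ = stage_backward(model.stage1, cache["c1"], dlogits1)
    return float(loss), n, g1, g2


# ---------------------------------------------------------------------------
# windowed feed-forward baseline

@dataclass
class NNBaselineParams:
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    window: int = 21


def init_nn_baseline(
    d: int,
    window: int = 21,
    hidden: int = 20,
    m: int = 2,
    rng: np.random.Generator | None = None,
) -> NNBaselineParams:
    if window % 2 == 0:
        raise ValueError("window must be odd")
    rng = rng or np.random.default_rng()
    fan_in = window * d
    b = 1.0 / np.sqrt(fan_in)
    return NNBaselineParams(
        W1=rng.uniform(-b, b, size=(fan_in, hidden)),
        b1=np.zeros(hidden),
        W2=rng.uniform(-1.0 / np.sqrt(hidden), 1.0 / np.sqrt(hidden),
                       size=(hidden, m)),
        b2=np.zeros(m),
        window=window,
    )


def nn_baseline_forward(params: NNBaselineParams, X: np.ndarray) -> np.ndarray:
    """Single-hidden-layer network on a flattened sliding window of input
    rows, zero-padded at the termini; softmax output per position."""
    if params.window % 2 == 0:
        raise ValueError("window must be odd")
    X = np.asarray(X, dtype=np.float64)
    n, d = X.shape
    half = params.window // 2
    padded = np.vstack([np.zeros((half, d)), X, np.zeros((half, d))])
    win = np.lib.stride_tricks.sliding_window_view(padded, (params.window, d))
    flat = win.reshape(n, params.window * d)
    A1 = np.tanh(flat @ params.W1 + params.b1)
    return softmax(A1 @ params.W2 + params.b2)


# ---------------------------------------------------------------------------
# serialization: a single .npz container with named keys; bit-exact round trip

def _stage_to_dict(prefix: str, s: StageParams) -> dict[str, np.ndarray]:
    out = {f"{prefix}{k}": v for k, v in s.arrays().items()}
    out[f"{prefix}span"] = np.array(s.span)
    return out


def _stage_from_dict(prefix: str, d: dict) -> StageParams:
    return StageParams(
        **{k: d[f"{prefix}{k}"] for k in PARAM_FIELDS},
        span=int(d[f"{prefix}span"]),
    )


def save_model(model: TwoStageModel, path) -> None:
    arrays = dict(
        geometry=np.array([model.geometry.w, model.geometry.p, model.geometry.m])
    )
    arrays.update(_stage_to_dict("stage1_", model.stage1))
    arrays.update(_stage_to_dict("stage2_", model.stage2))
    np.savez(path, **arrays)


def load_model(path) -> TwoStageModel:
    with np.load(path) as d:
        data = dict(d)
    w, p, m = (int(v) for v in data["geometry"])
    return TwoStageModel(
        stage1=_stage_from_dict("stage1_", data),
        stage2=_stage_from_dict("stage2_", data),
        geometry=FilterGeometry(w=w, p=p, m=m),
    )
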