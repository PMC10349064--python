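"""Differentiable cell-based architecture search (DARTS) over recurrence images.

A cell is a small DAG with two input nodes (the outputs of the two
previous cells), four intermediate nodes and a depth-wise-concatenation
output node — seven nodes in all.  Every edge into an intermediate node
carries a *mixed operation*: the softmax-weighted sum of a fixed
operator set

    {separable conv 3x3, separable conv 5x5, dilated conv 3x3,
     dilated conv 5x5, max pool 3x3, avg pool 3x3, identity}

whose architectural weights (alpha) are learned jointly with the
network weights (omega): in each search iteration omega takes a
gradient step on the training half and alpha on the validation half
(first-order alternation).  Convolutional operators use the
Convolution + BatchNorm + ReLU order.  After search, the operator with
the maximal weight is preserved per edge and each intermediate node
keeps its two strongest incoming edges, yielding a discrete genotype
with exactly 8 edges per cell.

The full-scale assembly stacks 18 normal cells with a reduction cell
after every 6; the desk-scale presets here use 2-3 cells and 8 initial
channels so that search and retraining run on one CPU in minutes.
Reference hyper-parameters: 50 search epochs, batch size 6, SGD with
learning rate 0.025, momentum 0.9, weight decay 3e-4; fine-tuning 200
epochs at batch size 10.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .types import InvalidParameterError

__all__ = ["OPS", "NASConfig", "NetworkSpec", "Genotype", "Alpha",
           "mixed_op_weights", "SearchNetwork", "search",
           "derive_genotype", "assemble_network", "FixedNetwork", "retrain"]

OPS = ("sep_conv_3x3", "sep_conv_5x5", "dil_conv_3x3", "dil_conv_5x5",
       "max_pool_3x3", "avg_pool_3x3", "identity")
N_NODES = 4                      # intermediate nodes per cell
N_EDGES = sum(i + 2 for i in range(N_NODES))   # 14 mixed edges per cell


class DivergenceError(RuntimeError):
    """Raised when a training loss becomes non-finite."""


@dataclass
class NASConfig:
    """Search / retraining hyper-parameters (desk-scale defaults)."""

    epochs: int = 5
    batch_size: int = 6
    learning_rate: float = 0.025
    momentum: float = 0.9
    weight_decay: float = 3e-4
    alpha_lr: float = 3e-4
    alpha_warmup_epochs: int = 0  # train only weights for the first epochs
    cosine_lr: bool = False      # anneal the learning rate to 0 over epochs
    augment_noise_std: float = 0.0   # input-noise augmentation (retraining)
    augment_time_flip: bool = False  # reverse-time recurrence-image flip
    augment_diag_crop: int = 0       # diagonal sub-window crop margin (px)
    dtype: str = "float32"           # array dtype for parameters/training
    seed: int = 0


@dataclass
class NetworkSpec:
    """Macro-architecture: how many cells, where reductions go."""

    n_normal_cells: int = 2
    n_reduction_cells: int = 1
    init_channels: int = 8
    nodes_per_cell: int = 7     # 2 inputs + 4 intermediate + 1 concat output

    def cell_sequence(self) -> list[bool]:
        """True entries mark reduction cells.

        A reduction cell follows every ``n_normal / (n_reduction+... )``
        normal cells; for the full-scale 18+2 design this places one
        after cells 6 and 12.
        """
        if self.n_reduction_cells == 0:
            return [False] * self.n_normal_cells
        per = max(1, self.n_normal_cells // (self.n_reduction_cells + 1))
        seq: list[bool] = []
        normals = reductions = 0
        while normals < self.n_normal_cells or reductions < self.n_reduction_cells:
            if normals and normals % per == 0 and reductions < self.n_reduction_cells \
                    and (not seq or not seq[-1]):
                seq.append(True)
                reductions += 1
                normals += 0
            if normals < self.n_normal_cells:
                seq.append(False)
                normals += 1
            elif reductions < self.n_reduction_cells:
                seq.append(True)
                reductions += 1
        return seq


@dataclass
class Alpha:
    """Architectural weights: one (edges x operators) matrix per cell type."""

    normal: np.ndarray
    reduce: np.ndarray

    def copy(self) -> "Alpha":
        return Alpha(self.normal.copy(), self.reduce.copy())


@dataclass
class Genotype:
    """Discrete cell description: per node, two (op, input-state) pairs.

    States are numbered 0 (prev-prev cell), 1 (prev cell), 2..5
    (intermediate nodes).
    """

    normal: list[list[tuple[str, int]]]
    reduce: list[list[tuple[str, int]]]

    def to_json(self) -> str:
        return json.dumps({"normal": self.normal, "reduce": self.reduce})

    @classmethod
    def from_json(cls, text: str) -> "Genotype":
        doc = json.loads(text)
        conv = lambda cell: [[(str(o), int(i)) for o, i in node]
                             for node in cell]
        return cls(normal=conv(doc["normal"]), reduce=conv(doc["reduce"]))


def mixed_op_weights(alpha_edge: np.ndarray) -> np.ndarray:
    """Softmax over one edge's operator weights (sums to 1)."""
    a = np.asarray(alpha_edge, dtype=np.float64)
    if a.shape != (len(OPS),):
        raise InvalidParameterError(f"alpha edge must have {len(OPS)} entries")
    e = np.exp(a - a.max())
    return e / e.sum()


# ---------------------------------------------------------------------------
# operator implementations

class _BN:
    def __init__(self, c: int, params: list):
        self.gamma = ad.Parameter(np.ones(c))
        self.beta = ad.Parameter(np.zeros(c))
        self.running: dict = {}
        params += [self.gamma, self.beta]

    def __call__(self, x: ad.Tensor, training: bool) -> ad.Tensor:
        return ad.batch_norm(x, self.gamma, self.beta, self.running, training)


class _ConvBNReLU:
    """Plain conv -> BN -> ReLU (used for stems and preprocessing)."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int,
                 rng: np.random.Generator, params: list):
        self.w = ad.Parameter(ad.kaiming_init((c_out, c_in, k, k),
                                              c_in * k * k, rng))
        self.stride = stride
        self.pad = k // 2
        self.bn = _BN(c_out, params)
        params.append(self.w)

    def __call__(self, x: ad.Tensor, training: bool) -> ad.Tensor:
        x = ad.conv2d(x, self.w, stride=self.stride, padding=self.pad)
        return ad.relu(self.bn(x, training))


class _SepConv:
    """Depthwise k x k + pointwise 1x1, then BN + ReLU."""

    def __init__(self, c: int, k: int, stride: int, dilation: int,
                 rng: np.random.Generator, params: list):
        self.dw = ad.Parameter(ad.kaiming_init((c, 1, k, k), k * k, rng))
        self.pw = ad.Parameter(ad.kaiming_init((c, c, 1, 1), c, rng))
        self.stride = stride
        self.dilation = dilation
        self.pad = dilation * (k - 1) // 2
        self.c = c
        self.bn = _BN(c, params)
        params += [self.dw, self.pw]

    def __call__(self, x: ad.Tensor, training: bool) -> ad.Tensor:
        x = ad.conv2d(x, self.dw, stride=self.stride, padding=self.pad,
                      dilation=self.dilation, groups=self.c)
        x = ad.conv2d(x, self.pw)
        return ad.relu(self.bn(x, training))


class _FactorizedReduce:
    """1x1 stride-2 conv + BN: 'identity' across a reduction edge."""

    def __init__(self, c: int, rng: np.random.Generator, params: list):
        self.w = ad.Parameter(ad.kaiming_init((c, c, 1, 1), c, rng))
        self.bn = _BN(c, params)
        params.append(self.w)

    def __call__(self, x: ad.Tensor, training: bool) -> ad.Tensor:
        return self.bn(ad.conv2d(x, self.w, stride=2), training)


def _make_op(name: str, c: int, stride: int, rng: np.random.Generator,
             params: list):
    if name == "sep_conv_3x3":
        return _SepConv(c, 3, stride, 1, rng, params)
    if name == "sep_conv_5x5":
        return _SepConv(c, 5, stride, 1, rng, params)
    if name == "dil_conv_3x3":
        return _SepConv(c, 3, stride, 2, rng, params)
    if name == "dil_conv_5x5":
        return _SepConv(c, 5, stride, 2, rng, params)
    if name == "max_pool_3x3":
        return lambda x, training: ad.max_pool2d(x, 3, stride, 1)
    if name == "avg_pool_3x3":
        return lambda x, training: ad.avg_pool2d(x, 3, stride, 1)
    if name == "identity":
        if stride == 1:
            return lambda x, training: x
        return _FactorizedReduce(c, rng, params)
    raise InvalidParameterError(f"unknown operator {name!r}")


def _edge_list() -> list[tuple[int, int]]:
    """(node, input_state) pairs in canonical order; 14 entries."""
    edges = []
    for j in range(N_NODES):
        for i in range(j + 2):
            edges.append((j, i))
    return edges


# ---------------------------------------------------------------------------
# supernet (search) cells

class _MixedCell:
    def __init__(self, c_pp: int, c_p: int, c: int, reduction: bool,
                 reduction_prev: bool, rng: np.random.Generator, params: list):
        self.reduction = reduction
        # when the previous cell reduced, s0 is twice the spatial size of
        # s1: bring it down with a stride-2 1x1 preprocessing conv
        self.pre0 = _ConvBNReLU(c_pp, c, 1, 2 if reduction_prev else 1,
                                rng, params)
        self.pre1 = _ConvBNReLU(c_p, c, 1, 1, rng, params)
        self.ops: list[list] = []
        for (j, i) in _edge_list():
            stride = 2 if reduction and i < 2 else 1
            self.ops.append([_make_op(name, c, stride, rng, params)
                             for name in OPS])

    def __call__(self, s0: ad.Tensor, s1: ad.Tensor, alpha: np.ndarray,
                 training: bool) -> ad.Tensor:
        s0 = self.pre0(s0, training)
        s1 = self.pre1(s1, training)
        states = [s0, s1]
        edge_idx = 0
        for j in range(N_NODES):
            acc = None
            for i in range(j + 2):
                w = mixed_op_weights(alpha[edge_idx])
                contrib = None
                for o, op in enumerate(self.ops[edge_idx]):
                    term = op(states[i], training) * ad.Tensor(w[o])
                    contrib = term if contrib is None else contrib + term
                acc = contrib if acc is None else acc + contrib
                edge_idx += 1
            states.append(acc)
        return ad.concat(states[2:], axis=1)


class SearchNetwork:
    """Supernet: stem, mixed cells, global pooling, 2-class head."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator,
                 dtype: str = "float32"):
        self.spec = spec
        with ad.using_dtype(np.dtype(dtype)):
            self._build(rng)

    def _build(self, rng: np.random.Generator) -> None:
        spec = self.spec
        self.params: list[ad.Parameter] = []
        c = spec.init_channels
        self.stem = _ConvBNReLU(1, c, 3, 1, rng, self.params)
        self.cells: list[_MixedCell] = []
        self.sequence = spec.cell_sequence()
        c_pp = c_p = c
        cur = c
        red_prev = False
        for is_red in self.sequence:
            if is_red:
                cur *= 2
            cell = _MixedCell(c_pp, c_p, cur, is_red, red_prev,
                              rng, self.params)
            self.cells.append(cell)
            red_prev = is_red
            c_pp, c_p = c_p, cur * N_NODES
        self.alpha = Alpha(
            normal=0.01 * rng.standard_normal((N_EDGES, len(OPS))),
            reduce=0.01 * rng.standard_normal((N_EDGES, len(OPS))),
        )
        feat = c_p
        self.w_cls = ad.Parameter(ad.kaiming_init((feat, 2), feat, rng,
                                                  gain=1.0))
        self.b_cls = ad.Parameter(np.zeros(2))
        self.params += [self.w_cls, self.b_cls]
        self._alpha_normal = ad.Parameter(self.alpha.normal)
        self._alpha_reduce = ad.Parameter(self.alpha.reduce)

    def forward(self, x: ad.Tensor, training: bool = True) -> ad.Tensor:
        s0 = s1 = self.stem(x, training)
        for cell, is_red in zip(self.cells, self.sequence):
            alpha = (self._alpha_reduce if is_red else self._alpha_normal)
            s0, s1 = s1, cell(s0, s1, alpha.data, training)
        pooled = s1.mean(axis=(2, 3))
        return ad.linear(pooled, self.w_cls, self.b_cls)

    def forward_with_alpha_grad(self, x: ad.Tensor) -> ad.Tensor:
        """Forward pass where the mixing weights are graph nodes, so the
        loss differentiates w.r.t. alpha."""
        s0 = s1 = self.stem(x, True)
        for cell, is_red in zip(self.cells, self.sequence):
            alpha_t = self._alpha_reduce if is_red else self._alpha_normal
            s0, s1 = s1, _mixed_cell_alpha(cell, s0, s1, alpha_t)
        pooled = s1.mean(axis=(2, 3))
        return ad.linear(pooled, self.w_cls, self.b_cls)


def _softmax_rows(a: ad.Tensor) -> list[list[ad.Tensor]]:
    """Row-wise softmax of an alpha matrix as scalar graph nodes."""
    rows = []
    for e in range(a.shape[0]):
        row = _row(a, e)
        mx = float(row.data.max())
        exps = [ _exp_scalar(_index(row, o), mx) for o in range(a.shape[1])]
        total = exps[0]
        for t in exps[1:]:
            total = total + t
        rows.append([e_i / total for e_i in exps])
    return rows


def _row(a: ad.Tensor, e: int) -> ad.Tensor:
    out = ad.Tensor(a.data[e], parents=(a,))

    def bw(g):
        full = np.zeros_like(a.data)
        full[e] = g
        a._accum(full)
    out._backward = bw
    return out


def _index(v: ad.Tensor, i: int) -> ad.Tensor:
    out = ad.Tensor(v.data[i], parents=(v,))

    def bw(g):
        full = np.zeros_like(v.data)
        full[i] = g
        v._accum(full)
    out._backward = bw
    return out


def _exp_scalar(x: ad.Tensor, shift: float) -> ad.Tensor:
    val = np.exp(x.data - shift)
    out = ad.Tensor(val, parents=(x,))
    out._backward = lambda g: x._accum(g * val)
    return out


def _mixed_cell_alpha(cell: _MixedCell, s0: ad.Tensor, s1: ad.Tensor,
                      alpha_t: ad.Parameter) -> ad.Tensor:
    weights = _softmax_rows(alpha_t)
    s0 = cell.pre0(s0, True)
    s1 = cell.pre1(s1, True)
    states = [s0, s1]
    edge_idx = 0
    for j in range(N_NODES):
        acc = None
        for i in range(j + 2):
            contrib = None
            for o, op in enumerate(cell.ops[edge_idx]):
                term = op(states[i], True) * weights[edge_idx][o]
                contrib = term if contrib is None else contrib + term
            acc = contrib if acc is None else acc + contrib
            edge_idx += 1
        states.append(acc)
    return ad.concat(states[2:], axis=1)


# ---------------------------------------------------------------------------
# search loop

def search(train_images: np.ndarray, train_labels: np.ndarray,
           val_images: np.ndarray, val_labels: np.ndarray,
           spec: NetworkSpec | None = None, cfg: NASConfig | None = None
           ) -> tuple[SearchNetwork, list[Alpha], Genotype]:
    """Alternating bilevel-style optimization of weights and alphas.

    ``*_images`` are (N, H, W) recurrence images with binary labels.
    Network weights step on training batches (SGD with momentum and
    weight decay), architectural weights on validation batches (Adam).
    Returns the supernet, the per-epoch alpha history and the final
    derived genotype.  ``epochs=0`` derives the genotype from the
    initialized alphas.
    """
    spec = spec or NetworkSpec()
    cfg = cfg or NASConfig()
    rng = np.random.default_rng(cfg.seed)
    net = SearchNetwork(spec, rng, cfg.dtype)
    opt_w = ad.SGD(net.params, lr=cfg.learning_rate, momentum=cfg.momentum,
                   weight_decay=cfg.weight_decay)
    opt_a = ad.Adam([net._alpha_normal, net._alpha_reduce], lr=cfg.alpha_lr,
                    weight_decay=1e-3)
    dt = np.dtype(cfg.dtype)
    x_tr = np.asarray(train_images, dt)[:, None]
    x_va = np.asarray(val_images, dt)[:, None]
    y_tr = np.asarray(train_labels, int)
    y_va = np.asarray(val_labels, int)
    history: list[Alpha] = []

    with ad.using_dtype(dt):
        _search_loop(cfg, net, opt_w, opt_a, x_tr, y_tr, x_va, y_va,
                     rng, history)
    net.alpha = Alpha(net._alpha_normal.data.copy(),
                      net._alpha_reduce.data.copy())
    return net, history, derive_genotype(net.alpha)


def _search_loop(cfg, net, opt_w, opt_a, x_tr, y_tr, x_va, y_va,
                 rng, history) -> None:
    for epoch in range(cfg.epochs):
        tr_order = rng.permutation(len(x_tr))
        va_order = rng.permutation(len(x_va))
        vi = 0
        for start in range(0, len(x_tr), cfg.batch_size):
            bt = tr_order[start:start + cfg.batch_size]
            # alpha step on a validation batch (skipped during warm-up:
            # letting the weights mature first counters the early bias of
            # the search toward parameter-free operators)
            bv = va_order[vi:vi + cfg.batch_size]
            vi = (vi + cfg.batch_size) % max(1, len(x_va) - cfg.batch_size + 1)
            if len(bv) and epoch >= cfg.alpha_warmup_epochs:
                logits = net.forward_with_alpha_grad(ad.Tensor(x_va[bv]))
                loss_a = ad.softmax_cross_entropy(logits, y_va[bv])
                opt_a.zero_grad()
                for p in net.params:
                    p.grad = None
                loss_a.backward()
                opt_a.step()
                if not np.isfinite(loss_a.item()):
                    raise DivergenceError(f"alpha loss diverged at epoch {epoch}")
            # weight step on a training batch
            logits = net.forward(ad.Tensor(x_tr[bt]), training=True)
            loss_w = ad.softmax_cross_entropy(logits, y_tr[bt])
            opt_w.zero_grad()
            net._alpha_normal.grad = None
            net._alpha_reduce.grad = None
            loss_w.backward()
            opt_w.step()
            if not np.isfinite(loss_w.item()):
                raise DivergenceError(f"weight loss diverged at epoch {epoch}")
        net.alpha = Alpha(net._alpha_normal.data.copy(),
                          net._alpha_reduce.data.copy())
        history.append(net.alpha.copy())


PARAM_FREE_OPS = frozenset({"max_pool_3x3", "avg_pool_3x3", "identity"})


def derive_genotype(alpha: Alpha, max_param_free: int = 2) -> Genotype:
    """Discretize: per intermediate node keep the two incoming edges with
    the largest maximal softmaxed non-identity weight, each carrying its
    argmax operator (ties break toward the lower operator index).

    At small search budgets differentiable search is known to collapse
    toward parameter-free operators (pooling/identity), which perform
    well in an under-trained supernet but generalize poorly once
    discretized.  ``max_param_free`` caps how many parameter-free
    operators a cell may retain: beyond the cap, the weakest such
    selections fall back to the edge's strongest convolutional operator.
    Set it to ``len(OPS) * N_NODES`` to disable the cap.
    """
    conv_ops = [o for o in range(len(OPS)) if OPS[o] not in PARAM_FREE_OPS]

    def one(mat: np.ndarray) -> list[list[tuple[str, int]]]:
        if not np.isfinite(mat).all():
            raise InvalidParameterError("alpha contains non-finite values")
        soft = np.stack([mixed_op_weights(row) for row in mat])
        edges = _edge_list()
        id_idx = OPS.index("identity")
        cell = []
        chosen = []   # (node_j, slot, edge, op, weight)
        for j in range(N_NODES):
            rows = [(e, i) for e, (jj, i) in enumerate(edges) if jj == j]
            non_id = [o for o in range(len(OPS)) if o != id_idx]
            strength = {e: soft[e, non_id].max() for e, _ in rows}
            top2 = sorted(rows, key=lambda r: (-strength[r[0]], r[1]))[:2]
            node = []
            for slot, (e, i) in enumerate(sorted(top2, key=lambda r: r[1])):
                op = int(np.argmax(soft[e]))  # argmax; ties -> lowest index
                node.append([OPS[op], i])
                chosen.append((j, slot, e, op, float(soft[e, op])))
            cell.append(node)
        # enforce the parameter-free cap, weakest selections first
        pf = sorted((c for c in chosen if OPS[c[3]] in PARAM_FREE_OPS),
                    key=lambda c: -c[4])
        for j, slot, e, op, _w in pf[max_param_free:]:
            best_conv = max(conv_ops, key=lambda o: (soft[e, o], -o))
            cell[j][slot][0] = OPS[best_conv]
        return [[(op, i) for op, i in node] for node in cell]

    return Genotype(normal=one(alpha.normal), reduce=one(alpha.reduce))


# ---------------------------------------------------------------------------
# discrete network

class _FixedCell:
    def __init__(self, geno_cell: list[list[tuple[str, int]]], c_pp: int,
                 c_p: int, c: int, reduction: bool, reduction_prev: bool,
                 rng: np.random.Generator, params: list):
        self.geno = geno_cell
        self.pre0 = _ConvBNReLU(c_pp, c, 1, 2 if reduction_prev else 1,
                                rng, params)
        self.pre1 = _ConvBNReLU(c_p, c, 1, 1, rng, params)
        self.ops: list[list] = []
        for node in geno_cell:
            node_ops = []
            for name, i in node:
                stride = 2 if reduction and i < 2 else 1
                node_ops.append(_make_op(name, c, stride, rng, params))
            self.ops.append(node_ops)

    def __call__(self, s0: ad.Tensor, s1: ad.Tensor,
                 training: bool) -> ad.Tensor:
        s0 = self.pre0(s0, training)
        s1 = self.pre1(s1, training)
        states = [s0, s1]
        for node, node_ops in zip(self.geno, self.ops):
            acc = None
            for (name, i), op in zip(node, node_ops):
                term = op(states[i], training)
                acc = term if acc is None else acc + term
            states.append(acc)
        return ad.concat(states[2:], axis=1)


class FixedNetwork:
    """The discrete network assembled from a genotype."""

    def __init__(self, genotype: Genotype, spec: NetworkSpec,
                 rng: np.random.Generator, dtype: str = "float32"):
        self.spec = spec
        self.genotype = genotype
        with ad.using_dtype(np.dtype(dtype)):
            self._build(rng)

    def _build(self, rng: np.random.Generator) -> None:
        spec = self.spec
        genotype = self.genotype
        self.params: list[ad.Parameter] = []
        c = spec.init_channels
        self.stem = _ConvBNReLU(1, c, 3, 1, rng, self.params)
        self.sequence = spec.cell_sequence()
        self.cells: list[_FixedCell] = []
        c_pp = c_p = c
        cur = c
        red_prev = False
        for is_red in self.sequence:
            if is_red:
                cur *= 2
            cell = _FixedCell(genotype.reduce if is_red else genotype.normal,
                              c_pp, c_p, cur, is_red, red_prev, rng,
                              self.params)
            self.cells.append(cell)
            red_prev = is_red
            c_pp, c_p = c_p, cur * N_NODES
        feat = c_p
        self.w_cls = ad.Parameter(ad.kaiming_init((feat, 2), feat, rng,
                                                  gain=1.0))
        self.b_cls = ad.Parameter(np.zeros(2))
        self.params += [self.w_cls, self.b_cls]

    def forward(self, x: ad.Tensor, training: bool = False) -> ad.Tensor:
        s0 = s1 = self.stem(x, training)
        for cell in self.cells:
            s0, s1 = s1, cell(s0, s1, training)
        pooled = s1.mean(axis=(2, 3))
        return ad.linear(pooled, self.w_cls, self.b_cls)

    def _logits(self, images: np.ndarray, chunk: int = 32) -> np.ndarray:
        """Eval-mode logits, computed without a graph and in chunks."""
        dt = self.params[0].data.dtype
        x = np.asarray(images, dt)[:, None]
        out = []
        with ad.no_grad(), ad.using_dtype(dt):
            for start in range(0, len(x), chunk):
                out.append(self.forward(ad.Tensor(x[start:start + chunk]),
                                        training=False).data)
        return np.concatenate(out, axis=0)

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Class predictions for (N, H, W) images (eval mode)."""
        return self._logits(images).argmax(axis=1)

    def scores(self, images: np.ndarray) -> np.ndarray:
        """PxAF-class logit margin per image (eval mode)."""
        logits = self._logits(images)
        return logits[:, 1] - logits[:, 0]


def assemble_network(genotype: Genotype, spec: NetworkSpec | None = None,
                     seed: int = 0, dtype: str = "float32") -> FixedNetwork:
    """Build the discrete classifier from a genotype and a macro spec."""
    spec = spec or NetworkSpec()
    return FixedNetwork(genotype, spec, np.random.default_rng(seed), dtype)


def retrain(model: FixedNetwork, train_images: np.ndarray,
            train_labels: np.ndarray, cfg: NASConfig | None = None
            ) -> dict:
    """Supervised training of the assembled network from scratch.

    Returns per-epoch mean loss and training accuracy.  Uses the
    fine-tuning hyper-parameters (SGD, momentum, weight decay) scaled by
    ``cfg``; with ``epochs=0`` the model is returned untouched.
    """
    cfg = cfg or NASConfig(batch_size=10)
    rng = np.random.default_rng(cfg.seed)
    opt = ad.SGD(model.params, lr=cfg.learning_rate, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)
    dt = model.params[0].data.dtype
    x = np.asarray(train_images, dt)[:, None]
    y = np.asarray(train_labels, int)
    history = {"loss": [], "accuracy": []}
    with ad.using_dtype(dt):
        _retrain_loop(cfg, model, opt, x, y, rng, history)
    return history


def _retrain_loop(cfg, model, opt, x, y, rng, history) -> None:
    for epoch in range(cfg.epochs):
        if cfg.cosine_lr and cfg.epochs > 1:
            opt.lr = cfg.learning_rate * 0.5 * (
                1 + np.cos(np.pi * epoch / cfg.epochs))
        order = rng.permutation(len(x))
        losses, correct, seen = [], 0, 0
        for start in range(0, len(x), cfg.batch_size):
            b = order[start:start + cfg.batch_size]
            xb = x[b]
            if cfg.augment_diag_crop > 0:
                # a diagonal sub-matrix of a recurrence plot is itself the
                # recurrence image of a shorter time window: on-manifold,
                # label-preserving augmentation
                m = cfg.augment_diag_crop
                side = xb.shape[2] - m
                offs = rng.integers(0, m + 1, size=len(xb))
                xb = np.stack([xb[i, :, t:t + side, t:t + side]
                               for i, t in enumerate(offs)])
            if cfg.augment_time_flip:
                # reversing time permutes the envelope, flipping the
                # recurrence matrix along both axes: label-preserving
                flip = rng.random(len(xb)) < 0.5
                xb = xb.copy()
                xb[flip] = xb[flip, :, ::-1, ::-1]
            if cfg.augment_noise_std > 0:
                xb = xb + rng.normal(0.0, cfg.augment_noise_std, xb.shape)
            logits = model.forward(ad.Tensor(xb), training=True)
            loss = ad.softmax_cross_entropy(logits, y[b])
            opt.zero_grad()
            loss.backward()
            opt.step()
            if not np.isfinite(loss.item()):
                raise DivergenceError(f"loss diverged at epoch {epoch}")
            losses.append(loss.item())
            correct += int((logits.data.argmax(axis=1) == y[b]).sum())
            seen += len(b)
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(correct / seen)


def save_genotype(genotype: Genotype, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(genotype.to_json())
    return path


def load_genotype(path: str | Path) -> Genotype:
    return Genotype.from_json(Path(path).read_text())
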