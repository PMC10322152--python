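"""Coevolution-filtered contact-map classifier and signed contact relevance.

A deliberately small network classifies soft contact maps into the five
conformational states: the input map is hard-masked to the top coevolving
pairs, neighboring retained pairs are average-pooled on the residue-pair grid
(contacts between adjacent positions serve similar roles), and two dense
sigmoid layers map the pooled features through a 30-dimensional hidden layer
to one output node per state.  The loss sum((e - d)^2) + sum(e^2) regularizes
the outputs themselves.  The model is an analysis device trained to saturation
on the labeled maps — it is never used for prediction on unseen proteins.

Layer-wise relevance propagation (epsilon rule) then redistributes each state
output back onto the retained residue pairs.  Positive relevance marks a
contact characteristically present in the state (encouraged), negative marks
one characteristically absent (discouraged).  Two architecture details keep
the attribution exact rather than approximate: the dense layers carry no
bias terms (all relevance reaches the inputs, conserving the output
activation up to the epsilon slack), and the hidden sigmoid is the
zero-centered tanh.  With a logistic hidden unit, a unit receiving no input
still outputs 1/2 — an unattributable constant whose relevance the epsilon
rule smears onto arbitrary near-zero weights; tanh(z) vanishes with z and
satisfies tanh(z)/z > 0, so dead units carry no relevance and the
redistribution never flips the sign of a contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact_maps import SoftContactMap
from .errors import DataError, LabelError, MappingError

__all__ = [
    "StateNetConfig", "TrainedStateNet", "StateSignature", "train_statenet",
    "lrp_relevance", "extract_signatures", "region_fractions", "eq6_loss",
]


@dataclass
class StateNetConfig:
    """Architecture and training hyper-parameters of the state network."""

    filter_pairs: list[tuple[int, int]]
    n_states: int = 5
    pool_size: int = 4
    hidden_dim: int = 30
    output_penalty: float = 1.0     # coefficient of the sum(e^2) loss term
    weight_decay: float = 0.0       # optional explicit weight decay (off)
    learning_rate: float = 0.5
    epochs: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.pool_size < 1 or self.hidden_dim < 1:
            raise ValueError("pool_size and hidden_dim must be >= 1")
        if not self.filter_pairs:
            raise ValueError("filter_pairs must be non-empty")
        self.filter_pairs = [(min(i, j), max(i, j)) for i, j in self.filter_pairs]


@dataclass
class StateSignature:
    """Encouraged/discouraged residue pairs of one state with signed relevance."""

    state: str
    contacts: list[tuple[tuple[int, int], float, str]]  # (pair, relevance, direction)
    pooled_bundles: list[tuple[tuple[int, int], float]] = field(default_factory=list)
    threshold: float = 0.1
    metadata: dict = field(default_factory=dict)

    @property
    def encouraged(self):
        return [(p, r) for p, r, d in self.contacts if d == "encouraged"]

    @property
    def discouraged(self):
        return [(p, r) for p, r, d in self.contacts if d == "discouraged"]

    def to_dict(self) -> dict:
        return {
            "state": self.state,
            "threshold": self.threshold,
            "contacts": [{"i": int(p[0]), "j": int(p[1]), "relevance": float(r),
                          "direction": d} for p, r, d in self.contacts],
            "pooled_bundles": [{"block": list(map(int, b)), "relevance": float(r)}
                               for b, r in self.pooled_bundles],
            "config": self.metadata,
        }


def eq6_loss(e: np.ndarray, d: np.ndarray, output_penalty: float = 1.0) -> float:
    """sum((e - d)^2) + sum(e^2): squared error plus an output-magnitude
    penalty that keeps the sigmoid outputs away from saturation."""
    e = np.asarray(e, dtype=float)
    d = np.asarray(d, dtype=float)
    return float(((e - d) ** 2).sum() + output_penalty * (e ** 2).sum())


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class TrainedStateNet:
    config: StateNetConfig
    states: tuple[str, ...]
    pair_block: np.ndarray          # block id (flattened pooled grid) per pair
    blocks: list[tuple[int, int]]   # (bi, bj) grid coordinates per pooled unit
    block_counts: np.ndarray        # retained pairs per pooled unit
    W1: np.ndarray                  # (n_blocks, hidden)
    W2: np.ndarray                  # (hidden, n_states)
    loss_history: np.ndarray = None
    final_loss: float = 0.0

    # -- forward pieces -----------------------------------------------------
    def pair_values(self, cmap: SoftContactMap) -> np.ndarray:
        idx = np.array(self.config.filter_pairs)
        return cmap.values[idx[:, 0], idx[:, 1]]

    def pooled(self, x_pairs: np.ndarray) -> np.ndarray:
        """Mean of retained pair values within each pool_size x pool_size
        block of the residue-pair grid."""
        single = x_pairs.ndim == 1
        x2 = np.atleast_2d(x_pairs)
        acc = np.zeros((x2.shape[0], len(self.blocks)))
        np.add.at(acc, (slice(None), self.pair_block), x2)
        acc /= self.block_counts
        return acc[0] if single else acc

    def forward(self, x_pairs: np.ndarray):
        h0 = self.pooled(x_pairs)
        z1 = h0 @ self.W1
        a1 = np.tanh(z1)            # zero-centered sigmoid (see module docs)
        z2 = a1 @ self.W2
        e = _sigmoid(z2)
        return h0, z1, a1, z2, e

    def predict_state(self, cmap: SoftContactMap) -> str:
        *_, e = self.forward(self.pair_values(cmap)[None, :])
        return self.states[int(np.argmax(e[0]))]


def _build_pooling(filter_pairs, pool_size):
    blocks = {}
    pair_block = np.empty(len(filter_pairs), dtype=int)
    for k, (i, j) in enumerate(filter_pairs):
        key = (i // pool_size, j // pool_size)
        if key not in blocks:
            blocks[key] = len(blocks)
        pair_block[k] = blocks[key]
    ordered = sorted(blocks, key=blocks.get)
    counts = np.bincount(pair_block, minlength=len(ordered)).astype(float)
    return pair_block, ordered, counts


def train_statenet(maps: list[SoftContactMap], cfg: StateNetConfig,
                   states: tuple[str, ...] | None = None) -> TrainedStateNet:
    """Full-batch gradient descent on the output loss; deterministic for a
    fixed seed.  Raises LabelError when a requested state has no examples and
    DataError on divergence (NaN loss).

    Hidden units use tanh, the zero-centered sigmoid, so that relevance
    propagation stays sign-consistent and dead units carry no relevance
    (see the module docstring).
    """
    if states is None:
        states = tuple(dict.fromkeys(m.state for m in maps))
    if len(states) != cfg.n_states:
        cfg.n_states = len(states)
    counts = {s: sum(m.state == s for m in maps) for s in states}
    empty = [s for s, c in counts.items() if c == 0]
    if empty:
        raise LabelError(f"states with zero training examples: {empty}")

    pair_block, blocks, block_counts = _build_pooling(cfg.filter_pairs, cfg.pool_size)
    net = TrainedStateNet(config=cfg, states=states, pair_block=pair_block,
                          blocks=blocks, block_counts=block_counts,
                          W1=None, W2=None)
    rng = np.random.default_rng(cfg.seed)
    n_blocks = len(blocks)
    net.W1 = rng.normal(0.0, 1.0 / np.sqrt(n_blocks), (n_blocks, cfg.hidden_dim))
    net.W2 = rng.normal(0.0, 1.0 / np.sqrt(cfg.hidden_dim),
                        (cfg.hidden_dim, cfg.n_states))

    X = np.stack([net.pair_values(m) for m in maps])
    D = np.zeros((len(maps), cfg.n_states))
    for r, m in enumerate(maps):
        D[r, states.index(m.state)] = 1.0
    H0 = net.pooled(X)
    n = len(maps)

    losses = np.empty(cfg.epochs)
    for epoch in range(cfg.epochs):
        z1 = H0 @ net.W1
        a1 = np.tanh(z1)
        z2 = a1 @ net.W2
        e = _sigmoid(z2)
        loss = (((e - D) ** 2).sum() + cfg.output_penalty * (e ** 2).sum()) / n
        if cfg.weight_decay:
            loss += cfg.weight_decay * ((net.W1 ** 2).sum() + (net.W2 ** 2).sum())
        if not np.isfinite(loss):
            raise DataError(f"training diverged at epoch {epoch} (loss {loss})")
        losses[epoch] = loss
        dz2 = (2.0 * (e - D) + 2.0 * cfg.output_penalty * e) * e * (1.0 - e) / n
        gW2 = a1.T @ dz2
        da1 = dz2 @ net.W2.T
        dz1 = da1 * (1.0 - a1 ** 2)
        gW1 = H0.T @ dz1
        if cfg.weight_decay:
            gW1 += 2.0 * cfg.weight_decay * net.W1
            gW2 += 2.0 * cfg.weight_decay * net.W2
        net.W1 -= cfg.learning_rate * gW1
        net.W2 -= cfg.learning_rate * gW2

    net.loss_history = losses
    net.final_loss = float(losses[-1])
    return net


# ---------------------------------------------------------------------------
# Layer-wise relevance propagation (epsilon rule)


def _lrp_dense(R_out: np.ndarray, inputs: np.ndarray, W: np.ndarray,
               z_out: np.ndarray, eps: float) -> np.ndarray:
    """Redistribute relevance through inputs @ W = z_out with the
    epsilon-stabilized z-rule."""
    denom = z_out + eps * np.sign(z_out)
    denom = np.where(denom == 0.0, eps, denom)
    s = R_out / denom
    return inputs * (W @ s)


def lrp_relevance(net: TrainedStateNet, cmap: SoftContactMap,
                  target_state: str, eps: float = 1e-6) -> np.ndarray:
    """Signed relevance of every retained pair for ``target_state``.

    Starts from the pre-sigmoid activation of the target output node and
    applies the epsilon rule through both dense layers and the pooling layer;
    the bias-free layers conserve the total relevance up to the epsilon
    slack.  Returns an array aligned with ``net.config.filter_pairs``.
    """
    if target_state not in net.states:
        raise LabelError(f"unknown state {target_state!r}; net knows {net.states}")
    x = net.pair_values(cmap)
    h0, z1, a1, z2, e = net.forward(x[None, :])
    h0, z1, a1, z2 = h0[0], z1[0], a1[0], z2[0]
    k = net.states.index(target_state)

    R_out = z2[k]
    R_hidden = _lrp_dense(np.array([R_out]), a1, net.W2[:, [k]], z2[[k]], eps)
    R_blocks = _lrp_dense(R_hidden, h0, net.W1, z1, eps)
    # pooling: each block's relevance goes back to its member pairs in
    # proportion to their (equal-share) contributions x / count.
    contrib = x / net.block_counts[net.pair_block]
    denom = h0[net.pair_block]
    denom = np.where(np.abs(denom) < eps, eps, denom)
    R_pairs = contrib / denom * R_blocks[net.pair_block]
    return R_pairs


def extract_signatures(net: TrainedStateNet, maps: list[SoftContactMap],
                       threshold: float = 0.1,
                       eps: float = 1e-6) -> list[StateSignature]:
    """Per state: mean relevance over that state's maps; keep pairs with
    |relevance| > threshold; positive sign = encouraged, negative =
    discouraged; pooled-block aggregates retained alongside."""
    signatures = []
    pairs = net.config.filter_pairs
    for state in net.states:
        state_maps = [m for m in maps if m.state == state]
        if not state_maps:
            raise LabelError(f"no maps with state {state!r}")
        rel = np.mean([lrp_relevance(net, m, state, eps=eps) for m in state_maps],
                      axis=0)
        contacts = []
        for k in np.argsort(-np.abs(rel)):
            if abs(rel[k]) <= threshold:
                break
            direction = "encouraged" if rel[k] > 0 else "discouraged"
            contacts.append((pairs[k], float(rel[k]), direction))
        block_rel = np.zeros(len(net.blocks))
        np.add.at(block_rel, net.pair_block, rel)
        bundles = [(net.blocks[b], float(block_rel[b]))
                   for b in np.argsort(-np.abs(block_rel)) if abs(block_rel[b]) > threshold]
        signatures.append(StateSignature(
            state=state, contacts=contacts, pooled_bundles=bundles,
            threshold=threshold,
            metadata={"pool_size": net.config.pool_size,
                      "hidden_dim": net.config.hidden_dim,
                      "seed": net.config.seed}))
    return signatures


def region_fractions(signatures: list[StateSignature],
                     regions: dict[int, str],
                     total_contacts: int | None = None) -> dict:
    """Fractions of signed signature contacts per (state, region pair, sign).

    Every residue must be assigned a region.  Fractions are denominated by
    ``total_contacts`` (e.g. all observed contacts across the training set);
    by default the total number of stored signature contacts across states.
    """
    if total_contacts is None:
        total_contacts = sum(len(s.contacts) for s in signatures) or 1
    table = {}
    for sig in signatures:
        tally = {}
        for (i, j), _r, direction in sig.contacts:
            for res in (i, j):
                if res not in regions:
                    raise MappingError(f"residue {res} has no region assignment")
            key = (tuple(sorted((regions[i], regions[j]))),
                   "+" if direction == "encouraged" else "-")
            tally[key] = tally.get(key, 0) + 1
        table[sig.state] = {k: v / total_contacts for k, v in tally.items()}
    return table
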