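"""Pseudolikelihood Potts model fitting and coevolution-map construction.

The Potts model assigns each alignment column a field vector v_i and each
column pair a coupling block w_ij over the residue alphabet.  Parameters are
fitted by maximizing the weighted, L2-regularized pseudolikelihood: the sum
over sequences and columns of the log conditional probability of the observed
residue given the rest of the sequence.  Couplings are pair-symmetric
(w[i,j,a,b] = w[j,i,b,a]) and fitted jointly.

Coupling blocks are reduced to a single score per column pair after fixing
the zero-sum gauge (the coupling-score degeneracy otherwise makes the plain
double sum over the block gauge-dependent), then standardized to zero mean
and unit variance over the off-diagonal upper triangle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from . import msa as msa_mod
from .errors import ConvergenceError, FrameMismatchError
from .msa import MultipleAlignment

__all__ = [
    "PottsModel", "CoevolutionMap", "fit_potts", "pseudolikelihood_value_grad",
    "zero_sum_gauge", "coupling_scores", "combine_maps", "top_pairs",
    "precision_vs_structure", "write_map", "read_map",
]


@dataclass
class PottsModel:
    """Fields ``v`` (L, q), couplings ``w`` (L, L, q, q) and fit metadata."""

    v: np.ndarray
    w: np.ndarray
    regularization: tuple[float, float]
    alphabet: str
    converged: bool = True
    grad_norm: float = 0.0
    n_iter: int = 0

    @property
    def length(self) -> int:
        return self.v.shape[0]

    @property
    def q(self) -> int:
        return self.v.shape[1]

    def validate(self) -> None:
        assert np.allclose(self.w, self.w.transpose(1, 0, 3, 2)), "w not pair-symmetric"
        L = self.length
        assert np.allclose(self.w[np.arange(L), np.arange(L)], 0.0), "diagonal blocks nonzero"


@dataclass
class CoevolutionMap:
    """Symmetric L x L pair-score matrix; diagonal fixed at zero."""

    scores: np.ndarray
    standardized: bool = False
    source: str = ""

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] != self.scores.shape[1]:
            raise FrameMismatchError("scores must be a square matrix")
        if not np.allclose(self.scores, self.scores.T, atol=1e-9):
            raise FrameMismatchError("scores must be symmetric")
        np.fill_diagonal(self.scores, 0.0)

    @property
    def length(self) -> int:
        return self.scores.shape[0]


# ---------------------------------------------------------------------------
# Pseudolikelihood objective


def _pair_index(L: int) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(L, k=1)
    return iu, ju


def _unpack(theta: np.ndarray, L: int, q: int):
    nv = L * q
    v = theta[:nv].reshape(L, q)
    wu = theta[nv:].reshape(-1, q, q)
    return v, wu


def _full_coupling_matrix(wu: np.ndarray, L: int, q: int) -> np.ndarray:
    """Assemble the symmetric (L q, L q) block coupling matrix from the
    upper-triangle pair blocks."""
    iu, ju = _pair_index(L)
    W = np.zeros((L, q, L, q))
    W[iu, :, ju, :] = wu
    W[ju, :, iu, :] = wu.transpose(0, 2, 1)
    return W.reshape(L * q, L * q)


def pseudolikelihood_value_grad(theta, X_onehot, x_idx, seq_weights,
                                lam_v, lam_w, L, q):
    """Weighted negative log pseudolikelihood and its gradient.

    ``X_onehot`` is (N, L*q); ``x_idx`` the (N, L) residue indices.
    Regularization: lam_v * sum v^2 + lam_w * sum_{i<j} w^2.
    """
    N = X_onehot.shape[0]
    v, wu = _unpack(theta, L, q)
    W = _full_coupling_matrix(wu, L, q)
    A = X_onehot @ W                      # (N, L*q)
    logits = A.reshape(N, L, q) + v[None, :, :]
    lse = logsumexp(logits, axis=2)       # (N, L)
    obs = np.take_along_axis(logits, x_idx[:, :, None], axis=2)[:, :, 0]
    nll = float(np.sum(seq_weights[:, None] * (lse - obs)))

    P = softmax(logits, axis=2)
    D = P.copy()
    np.put_along_axis(D, x_idx[:, :, None], np.take_along_axis(D, x_idx[:, :, None], axis=2) - 1.0, axis=2)
    D *= seq_weights[:, None, None]
    grad_v = D.sum(axis=0)

    Df = D.reshape(N, L * q)
    G = X_onehot.T @ Df                   # (L*q, L*q), unconstrained
    Gb = G.reshape(L, q, L, q)
    iu, ju = _pair_index(L)
    grad_wu = Gb[iu, :, ju, :] + Gb[ju, :, iu, :].transpose(0, 2, 1)

    nll += lam_v * float(np.sum(v * v)) + lam_w * float(np.sum(wu * wu))
    grad_v = grad_v + 2.0 * lam_v * v
    grad_wu = grad_wu + 2.0 * lam_w * wu
    return nll, np.concatenate([grad_v.ravel(), grad_wu.ravel()])


def fit_potts(aln: MultipleAlignment,
              reg: tuple[float, float] | None = None,
              alphabet: str | None = None,
              tol: float = 1e-5,
              maxiter: int = 2000) -> PottsModel:
    """Fit the symmetric Potts model by weighted pseudolikelihood maximization.

    Parameters
    ----------
    aln : gap-filtered, weighted alignment (kept columns are used).
    reg : (lam_v, lam_w); defaults to (0.01, 0.01 * (L - 1)).
    alphabet : residue alphabet; default the full 21-letter alphabet.  Pass a
        reduced alphabet for alignments known to use fewer symbols.
    tol : gradient max-norm tolerance of the quasi-Newton optimizer.

    Raises
    ------
    ConvergenceError if the optimizer stops without satisfying ``tol``;
    the exception carries the final gradient norm.
    """
    alphabet = alphabet or msa_mod.ALPHABET
    q = len(alphabet)
    if alphabet == msa_mod.ALPHABET:
        x_idx = aln.encoded(masked=True)
    else:
        x_idx = msa_mod.encode_sequences(
            [''.join(np.array(list(s))[aln.column_mask]) for s in aln.sequences],
            alphabet=alphabet)
    N, L = x_idx.shape
    if L < 2:
        raise FrameMismatchError("need at least 2 kept columns")
    lam_v, lam_w = reg if reg is not None else (0.01, 0.01 * (L - 1))

    X_onehot = np.zeros((N, L, q))
    np.put_along_axis(X_onehot, x_idx[:, :, None].astype(np.int64), 1.0, axis=2)
    X_onehot = X_onehot.reshape(N, L * q)
    x_idx = x_idx.astype(np.int64)
    seq_weights = np.asarray(aln.weights, dtype=float)

    n_pairs = L * (L - 1) // 2
    theta0 = np.zeros(L * q + n_pairs * q * q)
    res = minimize(
        pseudolikelihood_value_grad, theta0, jac=True, method="L-BFGS-B",
        args=(X_onehot, x_idx, seq_weights, lam_v, lam_w, L, q),
        options={"maxiter": maxiter, "gtol": tol, "ftol": 1e-12, "maxcor": 20},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = grad_norm <= tol * 10  # L-BFGS projected-gradient slack
    if not converged and not res.success:
        raise ConvergenceError(
            f"pseudolikelihood optimizer stopped after {res.nit} iterations "
            f"with gradient max-norm {grad_norm:.3g} > {tol:.3g}",
            grad_norm=grad_norm)

    v, wu = _unpack(res.x, L, q)
    iu, ju = _pair_index(L)
    w = np.zeros((L, L, q, q))
    w[iu, ju] = wu
    w[ju, iu] = wu.transpose(0, 2, 1)
    return PottsModel(v=v, w=w, regularization=(lam_v, lam_w), alphabet=alphabet,
                      converged=converged, grad_norm=grad_norm, n_iter=res.nit)


# ---------------------------------------------------------------------------
# Scoring


def zero_sum_gauge(w: np.ndarray) -> np.ndarray:
    """Shift every coupling block to the zero-sum (Ising) gauge.

    Row means, column means and the block mean of each q x q block become
    zero; pair scores computed afterwards are invariant under gauge shifts
    applied to the raw model.
    """
    row_mean = w.mean(axis=3, keepdims=True)
    col_mean = w.mean(axis=2, keepdims=True)
    all_mean = w.mean(axis=(2, 3), keepdims=True)
    return w - row_mean - col_mean + all_mean


def _standardize(scores: np.ndarray) -> np.ndarray:
    L = scores.shape[0]
    iu, ju = np.triu_indices(L, k=1)
    vals = scores[iu, ju]
    sd = vals.std()
    if sd < 1e-30:  # constant map: standardization degenerates to zeros
        out = np.zeros_like(scores)
        return out
    z = (vals - vals.mean()) / sd
    out = np.zeros_like(scores)
    out[iu, ju] = z
    out[ju, iu] = z
    return out


def coupling_scores(model: PottsModel, mode: str = "frobenius") -> CoevolutionMap:
    """Reduce gauge-fixed coupling blocks to one standardized score per pair.

    ``paper_sum`` sums the absolute gauge-fixed couplings over the block;
    ``frobenius`` (default) takes the Frobenius norm.  Scores are then
    standardized to zero mean / unit variance over the upper triangle.
    """
    wg = zero_sum_gauge(model.w)
    if mode == "paper_sum":
        raw = np.abs(wg).sum(axis=(2, 3))
    elif mode == "frobenius":
        raw = np.sqrt((wg ** 2).sum(axis=(2, 3)))
    else:
        raise ValueError(f"unknown scoring mode {mode!r}")
    np.fill_diagonal(raw, 0.0)
    return CoevolutionMap(scores=_standardize(raw), standardized=True, source=mode)


def combine_maps(maps: list[CoevolutionMap],
                 weights: list[float] | None = None) -> CoevolutionMap:
    """Element-wise weighted mean of per-subfamily maps (equal weights by
    default), so family-wide pairs outrank subfamily-specific ones."""
    if not maps:
        raise ValueError("no maps to combine")
    L = maps[0].length
    for m in maps:
        if m.length != L:
            raise FrameMismatchError(
                f"map length {m.length} != {L}; maps must share the column frame")
    if weights is None:
        weights = np.ones(len(maps))
    weights = np.asarray(weights, dtype=float)
    combined = np.tensordot(weights / weights.sum(),
                            np.stack([m.scores for m in maps]), axes=1)
    return CoevolutionMap(scores=combined, standardized=False, source="global")


def top_pairs(cmap: CoevolutionMap, t: int,
              min_separation: int = 5) -> list[tuple[int, int]]:
    """The t highest-scoring pairs with |i - j| >= min_separation.

    Sorted by descending score, ties broken by (i, j) lexicographic order.
    Sequence-local pairs are excluded because they reflect secondary
    structure, not tertiary contacts.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    L = cmap.length
    iu, ju = np.triu_indices(L, k=1)
    keep = (ju - iu) >= min_separation
    iu, ju, s = iu[keep], ju[keep], cmap.scores[iu[keep], ju[keep]]
    order = sorted(range(len(s)), key=lambda k: (-s[k], iu[k], ju[k]))
    if t > len(order):
        warnings.warn(
            f"requested t={t} but only {len(order)} pairs available; truncating")
        t = len(order)
    return [(int(iu[k]), int(ju[k])) for k in order[:t]]


def precision_vs_structure(pairs, structures, contact_cutoff: float = 4.0):
    """False-positive rate of predicted pairs against an ensemble of structures.

    A pair is a true contact if its minimum residue distance is within
    ``contact_cutoff`` (Angstrom) in ANY provided structure; structures may be
    ResidueDistanceMatrix or SoftContactMap objects (the sigmoid is inverted
    for the latter).  Returns (false_positive_rate, n_false).
    """
    if not pairs:
        return 0.0, 0
    n_false = 0
    soft_cut = 1.0 / (1.0 + np.exp(2.0 * contact_cutoff - 8.0))
    for i, j in pairs:
        is_contact = False
        for s in structures:
            if hasattr(s, "distances"):
                if s.distances[i, j] <= contact_cutoff:
                    is_contact = True
                    break
            else:
                if s.values[i, j] >= soft_cut:
                    is_contact = True
                    break
        n_false += not is_contact
    return n_false / len(pairs), n_false


# ---------------------------------------------------------------------------
# Map I/O: tab-separated (i, j, score), 1-based indices


def write_map(cmap: CoevolutionMap, path, header: str | None = None) -> None:
    L = cmap.length
    iu, ju = np.triu_indices(L, k=1)
    with open(path, "w") as fh:
        fh.write(f"# L={L}\tstandardized={int(cmap.standardized)}\tsource={cmap.source}\n")
        if header:
            fh.write(f"# {header}\n")
        for i, j in zip(iu, ju):
            fh.write(f"{i + 1}\t{j + 1}\t{cmap.scores[i, j]:.10g}\n")


def read_map(path) -> CoevolutionMap:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                for tokens in line[1:].strip().split("\t"):
                    if "=" in tokens:
                        k, v = tokens.split("=", 1)
                        meta[k.strip()] = v.strip()
                continue
            i, j, s = line.split()
            rows.append((int(i) - 1, int(j) - 1, float(s)))
    L = int(meta.get("L", max(max(i, j) for i, j, _ in rows) + 1))
    scores = np.zeros((L, L))
    for i, j, s in rows:
        scores[i, j] = scores[j, i] = s
    return CoevolutionMap(scores=scores,
                          standardized=bool(int(meta.get("standardized", 0))),
                          source=meta.get("source", ""))
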