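"""Soft contact maps, state similarity in coevolution-filtered contact space,
and the discriminative contact count t.

A structure is reduced to the matrix of minimum heavy-atom inter-residue
distances r, then softened into M(A, B) = 1 / (1 + exp(2 r - 8)) — a sigmoid
switching around 4 A.  Similarity between two structures x and y, seen
through a coevolution map C, is the inner product of the element-wise
products <C (x) M_x, C (x) M_y>.  Restricting this similarity to the top-t
coevolving pairs and asking for which t the five conformational states are
best separated in a 1D embedding selects the number of state-discriminative
contacts.

Also hosts the structure-comparison plumbing: Kabsch C-alpha RMSD, BLOSUM62
sequence distances, PCA projection, and structure-to-alignment column maps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .coevolution import CoevolutionMap, top_pairs
from .errors import DataError, FrameMismatchError, InsufficientDataError

__all__ = [
    "STATES", "ResidueDistanceMatrix", "SoftContactMap", "soft_contact_map",
    "map_similarity", "optimize_t", "ca_rmsd", "blosum_distance",
    "pca_project", "PCAResult", "read_structure_distances",
    "map_structure_to_columns", "save_distance_matrix", "load_distance_matrix",
]

STATES = ("outward_open", "outward_occluded", "occluded",
          "inward_occluded", "inward_open")


@dataclass
class ResidueDistanceMatrix:
    """Minimum inter-residue distances (A) with a conformational-state label."""

    distances: np.ndarray
    structure_id: str = ""
    state: str = "unknown"
    column_map: dict[int, int] | None = None  # structure residue -> MSA column

    def __post_init__(self):
        d = np.asarray(self.distances, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise DataError("distance matrix must be square")
        if (d < 0).any():
            raise DataError("negative inter-residue distance")
        if not np.allclose(d, d.T, atol=1e-6):
            raise DataError("distance matrix must be symmetric")
        self.distances = d

    @property
    def length(self) -> int:
        return self.distances.shape[0]


@dataclass
class SoftContactMap:
    """Sigmoid-filtered contact matrix, values in (0, 1)."""

    values: np.ndarray
    state: str = "unknown"
    structure_id: str = ""

    @property
    def length(self) -> int:
        return self.values.shape[0]


def soft_contact_map(dm: ResidueDistanceMatrix) -> SoftContactMap:
    """M(A, B) = 1 / (1 + exp(2 r_AB - 8)): 0.5 at 4 A, ~1 when formed,
    ~0 when far apart.  Strictly decreasing in r."""
    values = 1.0 / (1.0 + np.exp(2.0 * dm.distances - 8.0))
    return SoftContactMap(values=values, state=dm.state, structure_id=dm.structure_id)


def map_similarity(C: CoevolutionMap, mx: SoftContactMap, my: SoftContactMap,
                   pairs: list[tuple[int, int]] | None = None) -> float:
    """d_xy = <C (x) M_x, C (x) M_y>, optionally restricted to given pairs.

    Symmetric in x and y.  When ``pairs`` is given, only those (i, j) entries
    (both triangles) contribute.
    """
    if not (C.length == mx.length == my.length):
        raise FrameMismatchError("coevolution map and contact maps must share L")
    prod = (C.scores * mx.values) * (C.scores * my.values)
    if pairs is None:
        return float(prod.sum())
    idx = np.array(pairs)
    return float(2.0 * prod[idx[:, 0], idx[:, 1]].sum())


# ---------------------------------------------------------------------------
# t optimization


def _classical_mds_1d(D: np.ndarray) -> np.ndarray:
    """Deterministic 1D embedding (Torgerson classical MDS): the leading
    eigenvector of the double-centered squared-distance matrix."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    v = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
    # fix the sign so embeddings are reproducible
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return v


def _umap_1d(D: np.ndarray, seed: int) -> np.ndarray:
    import umap

    emb = umap.UMAP(n_components=1, metric="precomputed", random_state=seed,
                    n_neighbors=min(5, D.shape[0] - 1))
    return emb.fit_transform(D)[:, 0]


def _symmetric_kl(samples_by_state: dict[str, np.ndarray],
                  floor: float = 1e-12,
                  min_bandwidth_fraction: float = 0.05) -> float:
    """Sum of symmetric KL divergences between Gaussian KDEs (Silverman
    bandwidth) of the per-state 1D embeddings, on a shared grid.

    The bandwidth is floored at a fraction of the overall data span:
    a state cloud collapsed to (near-)identical embedding values carries no
    separability information, and an unfloored kernel would turn it into a
    spuriously sharp density with inflated divergence.
    """
    all_vals = np.concatenate(list(samples_by_state.values()))
    span = all_vals.max() - all_vals.min()
    if span < 1e-12:
        return 0.0
    grid = np.linspace(all_vals.min() - 0.2 * span, all_vals.max() + 0.2 * span, 512)
    dens = {}
    for s, vals in samples_by_state.items():
        n = vals.size
        silverman = np.std(vals) * (4.0 / (3.0 * n)) ** 0.2
        h = max(silverman, min_bandwidth_fraction * span)
        p = np.exp(-0.5 * ((grid[:, None] - vals[None, :]) / h) ** 2).mean(axis=1)
        p = np.maximum(p, floor)
        dens[s] = p / np.trapezoid(p, grid)
    states = list(dens)
    total = 0.0
    for a in range(len(states)):
        for b in range(a + 1, len(states)):
            pa, pb = dens[states[a]], dens[states[b]]
            total += float(np.trapezoid(pa * np.log(pa / pb), grid)
                           + np.trapezoid(pb * np.log(pb / pa), grid))
    return total


def optimize_t(maps: list[SoftContactMap], C_global: CoevolutionMap,
               t_grid: list[int], direction: str = "maximize",
               embedding: str = "mds", seed: int = 0,
               min_separation: int = 5, sufficiency_tol: float = 0.005):
    """Select the number of coevolving contacts sufficient to distinguish
    conformational states.

    For each t: keep the top-t coevolving pairs, compute the pairwise
    similarity matrix between structures restricted to those pairs, turn it
    into a kernel-induced distance, embed to 1D (deterministic classical MDS
    by default, UMAP pluggable via ``embedding='umap'``), fit one smoothed
    density per state and sum the symmetric KL divergence over state pairs.

    With ``direction='maximize'`` (default), t is chosen as the SMALLEST
    grid value whose divergence is within ``sufficiency_tol`` (relative) of
    the curve maximum: t is defined as the contact count sufficient for
    distinguishing the states, so among statistically indistinguishable
    divergences the most parsimonious contact set wins.
    ``direction='minimize'`` selects the least discriminative t instead; the
    full objective curve is always returned so either convention is
    recoverable.

    Returns (t_best, curve) where curve is a dict t -> objective; a
    ``degenerate`` key is set when the objective is flat.
    """
    states = {}
    for m in maps:
        states.setdefault(m.state, []).append(m)
    if len(states) < 2:
        raise InsufficientDataError("need at least 2 states")
    for s, ms in states.items():
        if len(ms) < 2:
            raise InsufficientDataError(f"state {s!r} has fewer than 2 maps")
    if direction not in ("maximize", "minimize"):
        raise ValueError("direction must be 'maximize' or 'minimize'")

    n = len(maps)
    curve = {}
    for t in t_grid:
        pairs = top_pairs(C_global, t, min_separation=min_separation)
        idx = np.array(pairs)
        feats = np.stack([
            C_global.scores[idx[:, 0], idx[:, 1]] * m.values[idx[:, 0], idx[:, 1]]
            for m in maps])                       # (n, t): C (x) M on the pairs
        S = 2.0 * feats @ feats.T                 # similarity (both triangles)
        diag = np.diag(S)
        D = np.sqrt(np.maximum(diag[:, None] + diag[None, :] - 2.0 * S, 0.0))
        emb = (_umap_1d(D, seed) if embedding == "umap" else _classical_mds_1d(D))
        by_state = {s: np.array([emb[k] for k in range(n) if maps[k].state == s])
                    for s in states}
        curve[t] = _symmetric_kl(by_state)

    values = np.array([curve[t] for t in t_grid])
    degenerate = bool(len(t_grid) > 1 and values.max() - values.min() < 1e-12)
    if degenerate:
        warnings.warn("objective is flat in t; state ensembles may be identical")
    if direction == "maximize":
        cutoff = values.max() - sufficiency_tol * abs(values.max())
        pick = int(np.argmax(values >= cutoff))  # smallest sufficient t
    else:
        pick = int(np.argmin(values))
    t_best = int(t_grid[pick])
    curve = dict(curve)
    curve["degenerate"] = degenerate  # type: ignore[index]
    return t_best, curve


# ---------------------------------------------------------------------------
# Structure-comparison plumbing


def ca_rmsd(a: np.ndarray, b: np.ndarray,
            pairing: list[tuple[int, int]] | None = None) -> float:
    """C-alpha RMSD (A) after optimal least-squares rigid superposition
    (Kabsch).  ``pairing`` maps indices of a to indices of b; identity when
    omitted."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if pairing is not None:
        pa = np.array([p[0] for p in pairing])
        pb = np.array([p[1] for p in pairing])
        a, b = a[pa], b[pb]
    if a.shape != b.shape or a.shape[0] < 3:
        raise DataError("need at least 3 paired residues with matching shapes")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    H = bc.T @ ac
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    S = np.diag([1.0, 1.0, d])
    R = U @ S @ Vt
    diff = (bc @ R) - ac
    return float(np.sqrt((diff ** 2).sum() / a.shape[0]))


_BLOSUM62 = None


def _blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        from Bio.Align import substitution_matrices
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


def blosum_distance(seq_a: str, seq_b: str) -> float:
    """Normalized BLOSUM62 distance on the shared alignment frame.

    d = 1 - S(a, b) / sqrt(S(a, a) S(b, b)) summed over mutually non-gap
    columns; 0 for identical sequences, larger for diverged ones.
    """
    if len(seq_a) != len(seq_b):
        raise FrameMismatchError("sequences must be on the same alignment frame")
    mat = _blosum62()
    s_ab = s_aa = s_bb = 0.0
    n = 0
    for ca, cb in zip(seq_a.upper(), seq_b.upper()):
        if ca in ("-", ".") or cb in ("-", "."):
            continue
        if ca not in mat.alphabet or cb not in mat.alphabet:
            continue
        s_ab += mat[ca, cb]
        s_aa += mat[ca, ca]
        s_bb += mat[cb, cb]
        n += 1
    if n == 0:
        raise InsufficientDataError("no comparable (mutually non-gap) columns")
    denom = np.sqrt(max(s_aa, 1e-12) * max(s_bb, 1e-12))
    return float(1.0 - s_ab / denom)


@dataclass
class PCAResult:
    coordinates: np.ndarray
    components: np.ndarray
    mean: np.ndarray
    explained_variance: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return self.coordinates @ self.components + self.mean


def pca_project(features: np.ndarray, n_components: int | None = 2) -> PCAResult:
    """PCA of mean-centered feature vectors, deterministic up to a fixed sign
    convention (largest-magnitude loading of each component positive)."""
    from sklearn.decomposition import PCA

    X = np.asarray(features, dtype=float)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    comps = pca.components_
    for k in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[k]))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
            coords[:, k] = -coords[:, k]
    return PCAResult(coordinates=coords, components=comps, mean=pca.mean_,
                     explained_variance=pca.explained_variance_)


# ---------------------------------------------------------------------------
# Structure file reading and caching


def read_structure_distances(path, structure_id: str | None = None,
                             state: str = "unknown") -> ResidueDistanceMatrix:
    """Minimum heavy-atom inter-residue distance matrix from a PDB/mmCIF file
    (first model, amino-acid residues, hydrogens excluded)."""
    import biotite.structure as struc
    import biotite.structure.io as strucio

    path = Path(path)
    atoms = strucio.load_structure(str(path), model=1)
    atoms = atoms[struc.filter_amino_acids(atoms) & (atoms.element != "H")]
    res_ids, res_start = np.unique(atoms.res_id, return_index=True)
    order = np.argsort(res_start)
    res_ids = res_ids[order]
    n = len(res_ids)
    coords_by_res = [atoms.coord[atoms.res_id == r] for r in res_ids]
    dist = np.zeros((n, n))
    for i in range(n):
        ci = coords_by_res[i]
        for j in range(i + 1, n):
            cj = coords_by_res[j]
            d2 = ((ci[:, None, :] - cj[None, :, :]) ** 2).sum(axis=2)
            dist[i, j] = dist[j, i] = np.sqrt(d2.min())
    return ResidueDistanceMatrix(distances=dist,
                                 structure_id=structure_id or path.stem,
                                 state=state)


def map_structure_to_columns(structure_seq: str, alignment_row: str,
                             kept_columns: np.ndarray | None = None) -> dict[int, int]:
    """Map structure residue indices (0-based) to MSA columns by global
    alignment of the structure sequence against the (ungapped) alignment row
    (Needleman-Wunsch, BLOSUM62, gap open 10 / extend 0.5)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _blosum62()
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"

    row_positions = [k for k, c in enumerate(alignment_row) if c not in ("-", ".")]
    row_seq = "".join(alignment_row[k] for k in row_positions).upper()
    aln = aligner.align(structure_seq.upper(), row_seq)[0]
    column_map = {}
    kept = set(kept_columns.tolist()) if kept_columns is not None else None
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for off in range(a_end - a_start):
            col = row_positions[b_start + off]
            if kept is None or col in kept:
                column_map[a_start + off] = col
    return column_map


def save_distance_matrix(dm: ResidueDistanceMatrix, prefix) -> None:
    """Cache as a text matrix plus a JSON sidecar (id, state, column map)."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".dist.tsv"), dm.distances, fmt="%.6g", delimiter="\t")
    sidecar = {"structure_id": dm.structure_id, "state": dm.state,
               "column_map": dm.column_map}
    prefix.with_suffix(".dist.json").write_text(json.dumps(sidecar, indent=1))


def load_distance_matrix(prefix) -> ResidueDistanceMatrix:
    prefix = Path(prefix)
    d = np.loadtxt(prefix.with_suffix(".dist.tsv"), delimiter="\t")
    meta = json.loads(prefix.with_suffix(".dist.json").read_text())
    cmap = meta.get("column_map")
    if cmap is not None:
        cmap = {int(k): v for k, v in cmap.items()}
    return ResidueDistanceMatrix(distances=d, structure_id=meta["structure_id"],
                                 state=meta["state"], column_map=cmap)
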