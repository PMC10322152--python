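"""Ground-truth generators for every pipeline stage.

Three kinds of fixtures are produced, each with a machine-readable record of
its planted truth:

* MSAs Gibbs-sampled from a Potts model with a small set of strongly coupled
  column pairs (the truth for contact recovery);
* multi-state toy "structures": residue distance matrices in which each
  conformational state is defined by its own exclusive contacts on top of a
  shared background, plus decorative bead-chain 3D coordinates (the truth for
  state classification, signatures and CVs);
* biased 1D/2D trajectories Metropolis-sampled from exp(-(F - U)/RT) for an
  analytic free-energy surface F and bias U (the truth for reweighting).

The distance matrices are constructed directly (planted contacts at 3.5 A,
broken contacts at 12 A) rather than derived from the bead coordinates: an
arbitrary planted contact set is generally not realizable by a 3D chain, and
the tests consume distances.  The coordinates serve rigid-motion and
superposition checks only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact_maps import ResidueDistanceMatrix, soft_contact_map
from .coevolution import CoevolutionMap, PottsModel
from .errors import DataError
from .msa import MultipleAlignment

__all__ = [
    "PlantedWorld", "make_planted_potts", "sample_potts_msa",
    "make_state_defs", "make_state_ensembles", "planted_coevolution_map",
    "double_well", "make_biased_trajectory", "STATE_CYCLE",
]

#: Conformational cycle order of the five transporter states.
STATE_CYCLE = ("outward_open", "outward_occluded", "occluded",
               "inward_occluded", "inward_open")

R_GAS = 8.314462618e-3  # kJ/mol/K
CONTACT_DISTANCE = 3.5  # A, planted formed contact
BROKEN_DISTANCE = 12.0  # A, planted broken contact


@dataclass
class PlantedWorld:
    """Bundle of ground truths consumed by tests and the acceptance script."""

    potts: PottsModel | None = None
    planted_pairs: list[tuple[int, int]] = field(default_factory=list)
    state_defs: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    background_pairs: list[tuple[int, int]] = field(default_factory=list)
    noise_pairs: list[tuple[int, int]] = field(default_factory=list)
    surface: object = None
    surface_info: dict = field(default_factory=dict)
    seed: int = 0

    def sidecar(self) -> dict:
        """JSON-serializable record of the planted truth."""
        return {
            "seed": self.seed,
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "state_defs": {s: [list(p) for p in ps] for s, ps in self.state_defs.items()},
            "background_pairs": [list(p) for p in self.background_pairs],
            "noise_pairs": [list(p) for p in self.noise_pairs],
            "surface_info": self.surface_info,
        }


# ---------------------------------------------------------------------------
# Potts fixtures


def _draw_separated_pairs(rng, L, k, min_separation=5, exclude=(),
                          used_blocks=None, block_size=4):
    """k distinct pairs with |i - j| >= min_separation, residue-disjoint where
    possible so planted couplings do not interact.

    When ``used_blocks`` is given, pairs additionally occupy distinct
    ``block_size x block_size`` cells of the residue-pair grid: contact-map
    pooling assumes grid-adjacent contacts serve the same function, so
    planted contacts with different roles must not land in one pooled cell.
    """
    pairs, used = [], set()
    forbidden = set(exclude)
    attempts = 0
    while len(pairs) < k:
        i = int(rng.integers(0, L - min_separation))
        j = int(rng.integers(i + min_separation, L))
        attempts += 1
        if (i, j) in forbidden:
            continue
        if attempts < 200 * k and (i in used or j in used):
            continue  # prefer residue-disjoint pairs; relax if space runs out
        block = (i // block_size, j // block_size)
        if used_blocks is not None:
            if block in used_blocks and attempts < 500 * k:
                continue
            used_blocks.add(block)
        pairs.append((i, j))
        used.update((i, j))
        forbidden.add((i, j))
    return pairs


def make_planted_potts(L: int = 30, q: int = 8, k: int = 10,
                       coupling_strength: float = 1.2,
                       seed: int = 0) -> PlantedWorld:
    """Potts model with k strongly coupled pairs (diagonal couplings that
    favor identical letters) and weak random fields."""
    rng = np.random.default_rng(seed)
    from .msa import ALPHABET
    alphabet = ALPHABET[1:q + 1]  # q standard residues, no gap
    v = 0.1 * rng.standard_normal((L, q))
    w = np.zeros((L, L, q, q))
    pairs = _draw_separated_pairs(rng, L, k)
    for i, j in pairs:
        block = coupling_strength * np.eye(q)
        w[i, j] = block
        w[j, i] = block.T
    model = PottsModel(v=v, w=w, regularization=(0.0, 0.0), alphabet=alphabet)
    return PlantedWorld(potts=model, planted_pairs=pairs, seed=seed)


def sample_potts_msa(model: PottsModel, n: int, seed: int = 0,
                     burn_in: int = 150, thin: int = 1) -> MultipleAlignment:
    """Gibbs-sample n sequences from the Potts model.

    n independent chains are run in parallel; each full sweep resamples every
    column from its conditional given the rest of the chain.  ``burn_in``
    sweeps are discarded, then every ``thin``-th sweep state is the final one
    (chains are independent, so a single post-burn-in state per chain
    suffices; thinning only adds decorrelation margin).  Independent chains
    started from uniform noise mix quickly at the coupling strengths used
    here, so the default burn-in is generous rather than minimal.
    """
    rng = np.random.default_rng(seed)
    L, q = model.length, model.q
    x = rng.integers(0, q, size=(n, L))
    onehot = np.zeros((n, L, q))
    np.put_along_axis(onehot, x[:, :, None], 1.0, axis=2)
    onehot_flat = onehot.reshape(n, L * q)
    # per-site coupling matrices for BLAS: logits = X_flat @ Wi + v_i
    W_site = [model.w[i].transpose(0, 2, 1).reshape(L * q, q) for i in range(L)]
    rows = np.arange(n)

    total_sweeps = burn_in + thin
    for _ in range(total_sweeps):
        for i in range(L):
            logits = model.v[i] + onehot_flat @ W_site[i]
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            new = (p.cumsum(axis=1) > rng.random((n, 1))).argmax(axis=1)
            onehot_flat[rows, i * q + x[:, i]] = 0.0
            x[:, i] = new
            onehot_flat[rows, i * q + new] = 1.0

    seqs = ["".join(model.alphabet[a] for a in row) for row in x]
    ids = [f"synth{k:05d}" for k in range(n)]
    return MultipleAlignment(sequences=seqs, ids=ids, subfamily="synthetic")


# ---------------------------------------------------------------------------
# Multi-state structure fixtures


def make_state_defs(L: int = 60, n_exclusive: int = 6, n_background: int = 8,
                    n_noise: int = 20, states=STATE_CYCLE,
                    seed: int = 0, block_size: int = 4) -> PlantedWorld:
    """Per-state exclusive contact sets (pairwise disjoint), shared background
    contacts formed in every state, and non-structural noise pairs.

    All drawn pairs occupy distinct ``block_size``-cells of the residue-pair
    grid, mirroring the biology the contact-map pooling assumes: grid-adjacent
    contacts belong to the same structural element and share their
    state-dependence, so contacts with different roles live in different
    neighborhoods.
    """
    rng = np.random.default_rng(seed)
    world = PlantedWorld(seed=seed)
    taken: list[tuple[int, int]] = []
    used_blocks: set = set()
    for s in states:
        ps = _draw_separated_pairs(rng, L, n_exclusive, exclude=taken,
                                   used_blocks=used_blocks, block_size=block_size)
        world.state_defs[s] = ps
        taken += ps
    world.background_pairs = _draw_separated_pairs(
        rng, L, n_background, exclude=taken,
        used_blocks=used_blocks, block_size=block_size)
    taken += world.background_pairs
    world.noise_pairs = _draw_separated_pairs(
        rng, L, n_noise, exclude=taken,
        used_blocks=used_blocks, block_size=block_size)
    world.planted_pairs = taken[:len(taken) - len(world.noise_pairs)]
    return world


def _chain_coordinates(L: int, rng, noise_sd: float) -> np.ndarray:
    """Decorative helical bead chain (one bead per residue, ~3.8 A rise)."""
    tt = np.arange(L) * 0.6
    coords = np.stack([6.0 * np.cos(tt), 6.0 * np.sin(tt), 1.5 * np.arange(L)], axis=1)
    return coords + noise_sd * rng.standard_normal((L, 3))


NEIGHBOR_DISTANCE = 4.75  # A, partially formed contact in cycle-adjacent states


def make_state_ensembles(world: PlantedWorld, L: int = 60, n_per_state: int = 4,
                         noise_sd: float = 0.5, seed: int = 1,
                         neighbor_distance: float = NEIGHBOR_DISTANCE,
                         noise_range: tuple[float, float] = (3.0, 8.0)):
    """Labeled soft contact maps plus toy coordinates for every state.

    A state's exclusive pairs and the shared background sit at 3.5 A in that
    state's members; exclusive pairs of other states are broken (12 A).
    Because conformational states lie on a cycle, the breaking is graded:
    contacts of a cycle-adjacent state are only partially opened
    (``neighbor_distance``, default 4.75 A, on the steep flank of the
    contact sigmoid) before reaching the fully broken distance two or more
    steps away.  This gives the ensemble the sequential contact-space
    geometry of a real conformational pathway instead of five mutually
    equidistant clusters.  ``neighbor_distance=BROKEN_DISTANCE`` recovers
    strictly binary (exclusive) contacts.  Noise pairs fluctuate uniformly
    in ``noise_range`` per member — non-structural flexible pairs; the
    default 3-8 A range keeps them on the sensitive flank of the contact
    sigmoid.  Gaussian distance noise of sd ``noise_sd`` (A) is added
    symmetrically everywhere.

    Returns (soft_maps, distance_matrices, coords_by_structure).
    """
    if n_per_state < 2:
        raise DataError("need at least 2 members per state")
    rng = np.random.default_rng(seed)
    idx = np.arange(L)
    sep = np.abs(idx[:, None] - idx[None, :])
    baseline = np.minimum(3.8 * sep, 25.0).astype(float)
    states = list(world.state_defs)

    maps, dms, coords = [], [], {}
    for k, state in enumerate(states):
        for member in range(n_per_state):
            d = baseline.copy()
            for k2, s2 in enumerate(states):
                cycle_sep = abs(k - k2)
                if cycle_sep == 0:
                    dist = CONTACT_DISTANCE
                elif cycle_sep == 1:
                    dist = neighbor_distance
                else:
                    dist = BROKEN_DISTANCE
                for i, j in world.state_defs[s2]:
                    d[i, j] = d[j, i] = dist
            for i, j in world.background_pairs:
                d[i, j] = d[j, i] = CONTACT_DISTANCE
            for i, j in world.noise_pairs:
                val = rng.uniform(*noise_range)
                d[i, j] = d[j, i] = val
            noise = rng.standard_normal((L, L)) * noise_sd
            d += np.triu(noise, 1) + np.triu(noise, 1).T
            np.fill_diagonal(d, 0.0)
            np.clip(d, 0.1, None, out=d)
            np.fill_diagonal(d, 0.0)
            sid = f"{state}_{member}"
            dm = ResidueDistanceMatrix(distances=d, structure_id=sid, state=state)
            dms.append(dm)
            maps.append(soft_contact_map(dm))
            coords[sid] = _chain_coordinates(L, rng, noise_sd)
    return maps, dms, coords


def planted_coevolution_map(world: PlantedWorld, L: int = 60,
                            seed: int = 2) -> CoevolutionMap:
    """Coevolution map consistent with the planted world.

    State-exclusive pairs score highest (they are the conserved,
    state-defining couplings), noise pairs score next — coevolving pairs
    that are not persistent structural contacts, the false-positive class
    real coevolution maps contain — then shared background contacts, then a
    weak random floor.
    """
    rng = np.random.default_rng(seed)
    scores = np.abs(rng.normal(0.0, 0.2, size=(L, L)))
    scores = np.triu(scores, 1)
    # coupling strength graded along the cycle: contacts of the central
    # (occluded-like) states are under the strongest evolutionary constraint,
    # cycle-end states' contacts the weakest, so end-state contacts rank last
    # within the discriminative band.
    n_states = len(world.state_defs)
    mid = (n_states - 1) / 2.0
    for k, ps in enumerate(world.state_defs.values()):
        lo = float(np.interp(abs(k - mid), [0.0, 1.0, 2.0], [4.15, 3.95, 3.70]))
        for i, j in ps:
            scores[min(i, j), max(i, j)] = rng.uniform(lo, lo + 0.15)
    for i, j in world.noise_pairs:
        scores[min(i, j), max(i, j)] = rng.uniform(3.3, 3.6)
    for i, j in world.background_pairs:
        scores[min(i, j), max(i, j)] = rng.uniform(2.0, 2.6)
    scores = scores + scores.T
    return CoevolutionMap(scores=scores, standardized=False, source="planted")


# ---------------------------------------------------------------------------
# Biased trajectories


def double_well(barrier: float = 10.0):
    """1D double well F(x) = barrier * (x^2 - 1)^2: minima at +-1 (F = 0),
    barrier of height ``barrier`` kJ/mol at x = 0."""
    def F(x):
        return barrier * (np.asarray(x) ** 2 - 1.0) ** 2
    F.info = {"kind": "double_well", "barrier": barrier, "minima": [-1.0, 1.0]}
    return F


def make_biased_trajectory(surface, bias, n_frames: int, n_walkers: int = 4,
                           seed: int = 0, domain=(-1.8, 1.8), step: float = 0.35,
                           temperature: float = 298.0, burn_in: int = 500,
                           start: np.ndarray | None = None):
    """Metropolis-sample per-walker chains from exp(-(F - U)/RT).

    ``surface`` (F) and ``bias`` (U) are callables of the 1D coordinate, in
    kJ/mol.  Returns a BiasedEnsemble whose frames carry the bias estimate
    U(xi_t); the true surface stays available through ``surface``.
    """
    from .free_energy import BiasedEnsemble  # local import: avoid cycle

    rng = np.random.default_rng(seed)
    rt = R_GAS * temperature
    lo, hi = domain

    if start is None:
        x = rng.uniform(lo, hi, size=n_walkers)
    else:
        x = np.array(start, dtype=float)
    steps_per_walker = burn_in + int(np.ceil(n_frames / n_walkers))

    def neg_log_p(xx):
        return (surface(xx) - bias(xx)) / rt

    e = neg_log_p(x)
    samples = np.empty((steps_per_walker, n_walkers))
    accepted = 0
    for t in range(steps_per_walker):
        prop = x + rng.normal(0.0, step, size=n_walkers)
        inside = (prop >= lo) & (prop <= hi)
        e_prop = np.where(inside, neg_log_p(np.clip(prop, lo, hi)), np.inf)
        accept = rng.random(n_walkers) < np.exp(np.minimum(0.0, e - e_prop))
        accept &= inside
        x = np.where(accept, prop, x)
        e = np.where(accept, e_prop, e)
        accepted += int(accept.sum())
        samples[t] = x
    rate = accepted / (steps_per_walker * n_walkers)
    if rate < 0.01:
        raise DataError(f"Metropolis acceptance rate {rate:.3%} < 1%; reduce step")

    samples = samples[burn_in:]
    fpw = min(samples.shape[0], int(np.ceil(n_frames / n_walkers)))
    xi = samples[:fpw].T.reshape(-1)                      # walker-major blocks
    walkers = np.repeat(np.arange(n_walkers), fpw)
    times = np.tile(np.arange(fpw, dtype=float), n_walkers)
    return BiasedEnsemble(
        time=times,
        walker=walkers,
        xi=xi,
        bias=np.asarray(bias(xi), dtype=float),
        process="synthetic",
        temperature=temperature,
        acceptance_rate=rate,
    )
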