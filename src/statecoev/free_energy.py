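"""Reweighting of adaptively biased ensembles into 1D free-energy profiles.

Frames sampled under an adaptive bias (whose converged estimate U(xi) flattens
the sampled marginal) are reweighted by w(t) = exp(-U(xi_t)/RT) / n(bin(xi_t)),
i.e. a Boltzmann factor of the bias normalized by the occupancy of the frame's
bin.  Projected onto any per-frame scalar coordinate x, the free energy of bin
i is E(x_i) = -RT ln( sum_t u(i,t) w(t) / sum_t w(t) ), gauged to min E = 0.

The global 1D coordinate is an order-constrained discriminant projection: the
canonical LDA ratio is augmented with (i - j)^2 weights between class pairs so
that the five conformational states fall in cycle order along the axis; the
ratio is non-convex, so it is maximized from many random restarts and only
correctly ordered solutions are accepted.

Diagnostics: per-bin error from the imbalance of directed transitions between
adjacent bins (a converged adaptive bias makes transitions symmetric), walker
overlap counts, segment alignment by inverse-variance-weighted offsets, and
convergence criteria on profile time series.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .errors import (AlignmentGapError, BinningError, DataError,
                     InsufficientDataError, OrderingError)

__all__ = [
    "R_GAS", "BinGrid", "BiasedEnsemble", "FreeEnergyProfile",
    "OrderedLdaModel", "fit_ordered_lda", "frame_weights",
    "project_free_energy", "align_profiles", "transition_imbalance_error",
    "walker_overlap", "convergence_check", "write_ensemble", "read_ensemble",
    "write_profile", "read_profile",
]

R_GAS = 8.314462618e-3  # kJ/mol/K


@dataclass
class BinGrid:
    """Uniform 1D grid with half-open intervals [lo, hi)."""

    lo: float
    hi: float
    n_bins: int = 100

    @classmethod
    def spanning(cls, values: np.ndarray, n_bins: int = 100, pad: float = 0.05):
        vmin, vmax = float(np.min(values)), float(np.max(values))
        span = max(vmax - vmin, 1e-12)
        return cls(vmin - pad * span, vmax + pad * span, n_bins)

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    def assign(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if (values < self.lo).any() or (values >= self.hi).any():
            bad = values[(values < self.lo) | (values >= self.hi)]
            raise BinningError(
                f"{bad.size} frame(s) outside grid [{self.lo}, {self.hi}) "
                f"(first offending value {bad[0]:.4g})")
        idx = np.floor((values - self.lo) / (self.hi - self.lo) * self.n_bins)
        return np.clip(idx.astype(int), 0, self.n_bins - 1)


@dataclass
class BiasedEnsemble:
    """Per-frame records of a biased simulation.

    ``xi`` is the biased CV value (1D here; the coordinate used for
    reweighting may differ), ``bias`` the adaptive free-energy estimate
    U(xi_t) in kJ/mol.  ``features`` optionally carries per-frame contact
    distances for discriminant projections.
    """

    time: np.ndarray
    walker: np.ndarray
    xi: np.ndarray
    bias: np.ndarray
    process: str = ""
    temperature: float = 298.0
    bin_spec: BinGrid | None = None
    features: np.ndarray | None = None
    acceptance_rate: float | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.walker = np.asarray(self.walker, dtype=int)
        self.xi = np.asarray(self.xi, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if not (self.time.shape == self.walker.shape == self.xi.shape == self.bias.shape):
            raise DataError("frame arrays must have equal lengths")
        wids = np.unique(self.walker)
        if wids.size and not np.array_equal(wids, np.arange(wids.min(), wids.min() + wids.size)):
            raise DataError("walker ids must form a contiguous set")
        for w in wids:
            tw = self.time[self.walker == w]
            if (np.diff(tw) < 0).any():
                raise DataError(f"times not non-decreasing for walker {w}")

    @property
    def n_frames(self) -> int:
        return self.xi.size

    @property
    def rt(self) -> float:
        return R_GAS * self.temperature

    def grid(self, n_bins: int = 100) -> BinGrid:
        if self.bin_spec is not None:
            return self.bin_spec
        return BinGrid.spanning(self.xi, n_bins=n_bins)


@dataclass
class FreeEnergyProfile:
    """Binned 1D free energies with point-wise standard errors.

    Bins never visited carry E = nan and occupied = False; occupied E are
    gauged so that min E = 0 (plus ``offset`` if the profile was aligned).
    """

    centers: np.ndarray
    E: np.ndarray
    se: np.ndarray
    n_eff: np.ndarray
    offset: float = 0.0
    label: str = ""

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.E)

    def shifted(self, delta: float) -> "FreeEnergyProfile":
        return replace(self, E=self.E + delta, offset=self.offset + delta)


# ---------------------------------------------------------------------------
# Ordered discriminant projection


@dataclass
class OrderedLdaModel:
    w: np.ndarray
    state_order: tuple[str, ...]
    l2: float
    n_restarts: int
    seed: int
    objective: float = 0.0
    ordered_fraction: float = 0.0

    def project(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w


def _order_weighted_scatter(X_by_class):
    """Quadratic forms of the order-weighted discriminant ratio.

    Numerator matrix A = sum_ij (i - j)^2 (mu_i - mu_j)(mu_i - mu_j)^T;
    denominator matrix B = within-class scatter.  The ratio
    (w^T A w)/(w^T B w) equals the order-weighted LDA objective.
    """
    mus = [Xc.mean(axis=0) for Xc in X_by_class]
    dim = mus[0].size
    A = np.zeros((dim, dim))
    nc = len(X_by_class)
    for i in range(nc):
        for j in range(nc):
            d = mus[i] - mus[j]
            A += (i - j) ** 2 * np.outer(d, d)
    B = sum((Xc - m).T @ (Xc - m) for Xc, m in zip(X_by_class, mus))
    return A, B


def ordered_lda_objective(w: np.ndarray, X_by_class: list[np.ndarray]) -> float:
    """(sum_ij (i-j)^2 (mu_i - mu_j)^2) / (within-class scatter); the ratio
    is scale-invariant in w."""
    A, B = _order_weighted_scatter(X_by_class)
    den = float(w @ B @ w)
    num = float(w @ A @ w)
    if den < 1e-300:
        return np.inf if num > 0 else 0.0
    return num / den


def _two_class_closed_form(X_by_class):
    """Classical two-class discriminant S_W^-1 (mu_1 - mu_0)."""
    mu = [Xc.mean(axis=0) for Xc in X_by_class]
    Sw = sum((Xc - m).T @ (Xc - m) for Xc, m in zip(X_by_class, mu))
    Sw = Sw + 1e-9 * np.eye(Sw.shape[0])
    return np.linalg.solve(Sw, mu[1] - mu[0])


def fit_ordered_lda(X: np.ndarray, labels, state_order,
                    l2: float = 1e-3, n_restarts: int = 1000,
                    seed: int = 0, maxiter: int = 200) -> OrderedLdaModel:
    """Maximize the order-weighted discriminant ratio over unit directions.

    Runs local ascent from ``n_restarts`` random unit initializations and
    keeps the best direction whose projected class means are strictly
    monotone in ``state_order`` (directions giving the reversed order are
    flipped).  ``l2`` softly penalizes departure of the raw vector from unit
    norm; the reported direction is unit-normalized.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    state_order = tuple(state_order)
    X_by_class = []
    for s in state_order:
        Xc = X[labels == s]
        if Xc.shape[0] < 2:
            raise InsufficientDataError(f"state {s!r} has fewer than 2 examples")
        X_by_class.append(Xc)
    if len(X_by_class) < 2:
        raise InsufficientDataError("need at least 2 states")
    dim = X.shape[1]
    rng = np.random.default_rng(seed)
    A, B = _order_weighted_scatter(X_by_class)
    mus = np.stack([Xc.mean(axis=0) for Xc in X_by_class])

    def neg_obj_grad(w):
        Bw = B @ w
        Aw = A @ w
        den = float(w @ Bw)
        num = float(w @ Aw)
        ratio = num / den
        g_ratio = 2.0 * (Aw - ratio * Bw) / den
        nrm = np.linalg.norm(w)
        pen = l2 * (nrm - 1.0) ** 2
        g_pen = 2.0 * l2 * (nrm - 1.0) * w / max(nrm, 1e-300)
        return -(ratio - pen), -(g_ratio - g_pen)

    best_w, best_obj = None, -np.inf
    n_ordered = 0
    for _ in range(n_restarts):
        w0 = rng.standard_normal(dim)
        w0 /= np.linalg.norm(w0)
        res = minimize(neg_obj_grad, w0, jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-10})
        w = res.x / max(np.linalg.norm(res.x), 1e-300)
        means = mus @ w
        d = np.diff(means)
        if (d < 0).all():
            w, means, d = -w, -means, -d
        # strict order at the scale of the projections, not float dust
        scale = max(float(np.std(X @ w)), 1e-300)
        if not (d > 1e-9 * scale).all():
            continue
        n_ordered += 1
        obj = float(w @ A @ w) / float(w @ B @ w)
        if obj > best_obj:
            best_obj, best_w = obj, w
    if best_w is None:
        raise OrderingError(
            "no restart produced strictly ordered projected state means",
            diagnostics={"n_restarts": n_restarts, "state_order": state_order})
    return OrderedLdaModel(w=best_w, state_order=state_order, l2=l2,
                           n_restarts=n_restarts, seed=seed,
                           objective=float(best_obj),
                           ordered_fraction=n_ordered / n_restarts)


# ---------------------------------------------------------------------------
# Reweighting


def frame_weights(ens: BiasedEnsemble, grid: BinGrid | None = None) -> np.ndarray:
    """w(t) = exp(-U(xi_t)/RT) / n(bin(xi_t)): Boltzmann factor of the bias
    estimate divided by the occupancy count of the frame's bin."""
    grid = grid or ens.grid()
    idx = grid.assign(ens.xi)
    counts = np.bincount(idx, minlength=grid.n_bins)
    log_w = -ens.bias / ens.rt
    log_w -= log_w.max()  # overflow guard; weights are relative
    w = np.exp(log_w) / counts[idx]
    return w


def project_free_energy(ens: BiasedEnsemble, weights: np.ndarray,
                        coordinate, bins: BinGrid,
                        label: str = "") -> FreeEnergyProfile:
    """E(x_i) = -RT ln( sum_{t in bin i} w(t) / sum_t w(t) ), gauged to
    min E = 0; unvisited bins are flagged (E = nan), not errors.

    ``coordinate`` is a per-frame scalar array or an OrderedLdaModel (applied
    to ``ens.features``).
    """
    if isinstance(coordinate, OrderedLdaModel):
        if ens.features is None:
            raise DataError("ensemble carries no features to project")
        coord = coordinate.project(ens.features)
    else:
        coord = np.asarray(coordinate, dtype=float)
    weights = np.asarray(weights, dtype=float)
    idx = bins.assign(coord)
    wsum = np.bincount(idx, weights=weights, minlength=bins.n_bins)
    w2sum = np.bincount(idx, weights=weights ** 2, minlength=bins.n_bins)
    p = wsum / weights.sum()
    with np.errstate(divide="ignore"):
        E = -ens.rt * np.log(p)
    E[wsum <= 0] = np.nan
    occ = np.isfinite(E)
    E[occ] -= np.nanmin(E)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_eff = np.where(w2sum > 0, wsum ** 2 / w2sum, 0.0)
    se = np.full(bins.n_bins, np.nan)
    se[occ] = ens.rt / np.sqrt(np.maximum(n_eff[occ], 1.0))
    return FreeEnergyProfile(centers=bins.centers, E=E, se=se, n_eff=n_eff,
                             label=label or ens.process)


# ---------------------------------------------------------------------------
# Profile alignment


def align_profiles(profiles: list[FreeEnergyProfile],
                   min_overlap: int = 3):
    """Additive offsets (first profile fixed at 0) minimizing the
    inverse-variance-weighted squared disagreement on overlapping bins, then
    an inverse-variance-weighted combination.

    Returns (combined_profile, offsets).
    """
    if not profiles:
        raise InsufficientDataError("no profiles to align")
    if len(profiles) == 1:
        return profiles[0], [0.0]
    n = len(profiles)
    centers = profiles[0].centers
    for p in profiles:
        if p.centers.shape != centers.shape or not np.allclose(p.centers, centers):
            raise AlignmentGapError("profiles must share the coordinate grid")

    # overlap graph connectivity
    pairs = []
    for a in range(n):
        for b in range(a + 1, n):
            ov = profiles[a].occupied & profiles[b].occupied
            if ov.sum() >= min_overlap:
                pairs.append((a, b, ov))
    adj = {k: set() for k in range(n)}
    for a, b, _ in pairs:
        adj[a].add(b)
        adj[b].add(a)
    seen = {0}
    stack = [0]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    if len(seen) != n:
        missing = sorted(set(range(n)) - seen)
        raise AlignmentGapError(
            f"profiles {missing} share no sufficient bin overlap with profile 0",
            gap=missing)

    # quadratic in the offsets: solve the (n-1)-dim normal equations
    A = np.zeros((n, n))
    rhs = np.zeros(n)
    for a, b, ov in pairs:
        wgt = 1.0 / (profiles[a].se[ov] ** 2 + profiles[b].se[ov] ** 2)
        diff = profiles[a].E[ov] - profiles[b].E[ov]
        s = wgt.sum()
        A[a, a] += s
        A[b, b] += s
        A[a, b] -= s
        A[b, a] -= s
        rhs[a] -= (wgt * diff).sum()
        rhs[b] += (wgt * diff).sum()
    offsets = np.zeros(n)
    offsets[1:] = np.linalg.solve(A[1:, 1:], rhs[1:])

    shifted = [p.shifted(d) for p, d in zip(profiles, offsets)]
    E = np.full(centers.shape, np.nan)
    se = np.full(centers.shape, np.nan)
    n_eff = np.zeros(centers.shape)
    for k in range(centers.size):
        vals = [(p.E[k], p.se[k]) for p in shifted if p.occupied[k]]
        if not vals:
            continue
        wgt = np.array([1.0 / (s ** 2) for _, s in vals])
        E[k] = np.sum([v * g for (v, _), g in zip(vals, wgt)]) / wgt.sum()
        se[k] = 1.0 / np.sqrt(wgt.sum())
        n_eff[k] = sum(p.n_eff[k] for p in shifted if p.occupied[k])
    occ = np.isfinite(E)
    gauge = np.nanmin(E)
    E[occ] -= gauge
    combined = FreeEnergyProfile(centers=centers, E=E, se=se, n_eff=n_eff,
                                 label="combined")
    return combined, [float(d) for d in offsets]


# ---------------------------------------------------------------------------
# Error and overlap diagnostics


def transition_imbalance_error(ens: BiasedEnsemble,
                               bins: BinGrid,
                               coordinate: np.ndarray | None = None,
                               gauge_bin: int | None = None) -> np.ndarray:
    """Per-bin free-energy error (kJ/mol) from directed-transition imbalance.

    Consecutive frames of each walker landing in adjacent bins contribute a
    directed count; each adjacent-bin edge carries an imbalance
    delta = RT |ln(N_ij / N_ji)| (add-one smoothed).  Per-bin errors
    accumulate edge imbalances in quadrature along the bin axis from the
    gauge bin (default: the most occupied bin).  Flat, well-sampled regions
    approach zero error.
    """
    coord = ens.xi if coordinate is None else np.asarray(coordinate, dtype=float)
    idx = bins.assign(coord)
    up = np.zeros(bins.n_bins - 1)
    down = np.zeros(bins.n_bins - 1)
    for w in np.unique(ens.walker):
        sel = ens.walker == w
        if sel.sum() < 2:
            raise InsufficientDataError(f"walker {w} has fewer than 2 frames")
        order = np.argsort(ens.time[sel], kind="stable")
        b = idx[sel][order]
        steps = np.diff(b)
        src = b[:-1]
        np.add.at(up, src[steps == 1], 1)
        np.add.at(down, src[steps == -1] - 1, 1)
    rt = ens.rt
    edge_err = rt * np.abs(np.log((up + 1.0) / (down + 1.0)))
    if gauge_bin is None:
        gauge_bin = int(np.argmax(np.bincount(idx, minlength=bins.n_bins)))
    err = np.zeros(bins.n_bins)
    var = edge_err ** 2
    for k in range(gauge_bin + 1, bins.n_bins):
        err[k] = np.sqrt(err[k - 1] ** 2 + var[k - 1])
    for k in range(gauge_bin - 1, -1, -1):
        err[k] = np.sqrt(err[k + 1] ** 2 + var[k])
    return err


def walker_overlap(ens: BiasedEnsemble, bins: BinGrid,
                   threshold: float = 0.1,
                   coordinate: np.ndarray | None = None,
                   normalize_by_mean: bool = True) -> np.ndarray:
    """O(x): number of walkers whose unbiased per-walker distribution at bin
    x reaches ``threshold`` of the across-walker mean distribution there.

    ``normalize_by_mean=False`` applies the threshold to the raw per-walker
    probability instead.
    """
    coord = ens.xi if coordinate is None else np.asarray(coordinate, dtype=float)
    idx = bins.assign(coord)
    weights = frame_weights(ens, ens.grid())
    walkers = np.unique(ens.walker)
    P = np.zeros((walkers.size, bins.n_bins))
    for k, w in enumerate(walkers):
        sel = ens.walker == w
        pw = np.bincount(idx[sel], weights=weights[sel], minlength=bins.n_bins)
        tot = pw.sum()
        P[k] = pw / tot if tot > 0 else 0.0
    if normalize_by_mean:
        mean = P.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(mean > 0, P / mean, 0.0)
        return (ratio >= threshold).sum(axis=0).astype(int)
    return (P >= threshold).sum(axis=0).astype(int)


def convergence_check(snapshots: list[FreeEnergyProfile],
                      fe_cutoff: float = 40.0,
                      dF_tol: float = 0.5,
                      dist_snapshots: list[np.ndarray] | None = None,
                      dist_tol: float = 0.1) -> dict:
    """Convergence report over a time series of profile snapshots.

    Criteria, evaluated only on bins below ``fe_cutoff`` (kJ/mol):
      * stability: the 2-norm series of successive profile differences;
      * ``dF``: last successive change below ``dF_tol`` per bin (max-norm);
      * ``distribution``: std of the last coordinate distribution around the
        mean distribution below ``dist_tol`` (skipped when no distributions
        are given).
    """
    if len(snapshots) < 2:
        raise InsufficientDataError("need at least 2 profile snapshots")
    norms = []
    max_diffs = []
    for a, b in zip(snapshots[:-1], snapshots[1:]):
        sel = a.occupied & b.occupied & (a.E < fe_cutoff) & (b.E < fe_cutoff)
        d = b.E[sel] - a.E[sel]
        norms.append(float(np.linalg.norm(d)))
        max_diffs.append(float(np.max(np.abs(d))) if d.size else 0.0)
    report = {
        "norm_series": norms,
        "max_diff_series": max_diffs,
        "dF_converged": max_diffs[-1] < dF_tol,
        "stable": all(m < dF_tol for m in max_diffs[-1:]),
        "first_passing_index": next(
            (k for k, m in enumerate(max_diffs) if m < dF_tol), None),
    }
    if dist_snapshots is not None:
        last = np.asarray(dist_snapshots[-1], dtype=float)
        mean = last.mean()
        report["distribution_std"] = float(last.std() / mean) if mean > 0 else np.inf
        report["distribution_converged"] = report["distribution_std"] < dist_tol
    report["converged"] = report["dF_converged"] and report.get(
        "distribution_converged", True)
    return report


# ---------------------------------------------------------------------------
# Plain-text I/O


def write_ensemble(ens: BiasedEnsemble, path) -> None:
    """Whitespace-separated table: time walker xi U (xvg-like, '#' comments)."""
    with open(path, "w") as fh:
        fh.write(f"# process={ens.process} temperature={ens.temperature}\n")
        fh.write("# time walker xi U\n")
        for t, w, x, u in zip(ens.time, ens.walker, ens.xi, ens.bias):
            fh.write(f"{t:.6g} {w:d} {x:.10g} {u:.10g}\n")


def read_ensemble(path) -> BiasedEnsemble:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "@")):
                if line.startswith("#"):
                    for tok in line[1:].split():
                        if "=" in tok:
                            k, v = tok.split("=", 1)
                            meta[k] = v
                continue
            rows.append(line.split())
    if not rows:
        raise InsufficientDataError(f"no frames in {path}")
    arr = np.array(rows, dtype=float)
    return BiasedEnsemble(time=arr[:, 0], walker=arr[:, 1].astype(int),
                          xi=arr[:, 2], bias=arr[:, 3],
                          process=meta.get("process", ""),
                          temperature=float(meta.get("temperature", 298.0)))


def write_profile(profile: FreeEnergyProfile, path,
                  overlap: np.ndarray | None = None) -> None:
    """TSV: bin center, E, se, n_eff[, O]."""
    with open(path, "w") as fh:
        fh.write(f"# label={profile.label} offset={profile.offset:.10g}\n")
        cols = "center\tE\tse\tn_eff" + ("\tO" if overlap is not None else "")
        fh.write(f"# {cols}\n")
        for k in range(profile.centers.size):
            row = (f"{profile.centers[k]:.10g}\t{profile.E[k]:.10g}\t"
                   f"{profile.se[k]:.10g}\t{profile.n_eff[k]:.10g}")
            if overlap is not None:
                row += f"\t{int(overlap[k])}"
            fh.write(row + "\n")


def read_profile(path) -> FreeEnergyProfile:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                continue
            rows.append(line.split()[:4])
    arr = np.array(rows, dtype=float)
    return FreeEnergyProfile(centers=arr[:, 0], E=arr[:, 1], se=arr[:, 2],
                             n_eff=arr[:, 3],
                             offset=float(meta.get("offset", 0.0)),
                             label=meta.get("label", ""))
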