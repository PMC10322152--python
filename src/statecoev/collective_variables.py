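"""State-discriminating collective variables from maximum-margin contacts.

A linear SVM separates the contact-distance features of two adjacent
conformational states; the coefficients with the largest magnitudes (above
the first clear gap in their sorted histogram) select the state-specific
contacts.  Positive-coefficient contacts define CV1 and negated
negative-coefficient contacts define CV2, each a weighted mean of minimum
residue-residue distances:

    CV_1 = (1 / sum_i max(0, c_i)) * sum_i max(0, c_i) x_i
    CV_2 = (1 / sum_i -min(0, c_i)) * sum_i -min(0, c_i) x_i

with x_i in nm.  Because each CV is a convex combination of distances to
contacts specific to one state, a high CV_j value means few contacts of
state j are formed.  Sampling parameters for the adaptive-bias engine are
exported per conformational process.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, ConstructionError, DataError, FrameMismatchError

__all__ = [
    "ANGSTROM_PER_NM", "CVDefinition", "fit_state_svm", "select_coefficients",
    "build_cv_pair", "evaluate_cv", "min_residue_distance",
    "export_sampling_config", "AWH_PROCESS_DEFAULTS", "write_cv_definition",
    "read_cv_definition",
]

ANGSTROM_PER_NM = 10.0

#: Adaptive-bias sampling defaults per conformational process:
#: per-CV diffusion constants (nm^2/ps), harmonic force constants
#: (kJ/mol/nm^2), cover diameter (nm) and free-energy cutoff (kJ/mol).
AWH_PROCESS_DEFAULTS = {
    "outward opening": {
        "diffusion_cv1": 0.0005, "diffusion_cv2": 0.001,
        "force_constant_cv1": 10000.0, "force_constant_cv2": 50000.0,
        "cover_diameter": 0.4, "fe_cutoff": 60.0,
    },
    "rocker switch": {
        "diffusion_cv1": 0.001, "diffusion_cv2": 0.001,
        "force_constant_cv1": 50000.0, "force_constant_cv2": 50000.0,
        "cover_diameter": 0.4, "fe_cutoff": 60.0,
    },
    "inward opening": {
        "diffusion_cv1": 0.0005, "diffusion_cv2": 0.0005,
        "force_constant_cv1": 30000.0, "force_constant_cv2": 30000.0,
        "cover_diameter": 0.4, "fe_cutoff": 40.0,
    },
}
AWH_COMMON = {"n_walkers": 4, "initial_error": 10.0, "target": "cutoff"}


@dataclass
class CVDefinition:
    """Weighted-distance collective variable over residue pairs (nm)."""

    terms: list[tuple[tuple[int, int], float]]   # (pair, weight > 0)
    side: str = "state1_specific"
    units: str = "nm"

    def __post_init__(self):
        if not self.terms:
            raise ConstructionError("a CV needs at least one term")
        if any(w <= 0 for _, w in self.terms):
            raise ConstructionError("CV weights must be strictly positive")

    @property
    def normalization(self) -> float:
        return float(sum(w for _, w in self.terms))

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [p for p, _ in self.terms]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.terms])

    def evaluate_distances(self, distances: np.ndarray) -> float:
        """Normalized weighted mean of per-term distances (same units in
        and out); always inside [min(distances), max(distances)]."""
        d = np.asarray(distances, dtype=float)
        if d.shape[0] != len(self.terms):
            raise FrameMismatchError("one distance per CV term required")
        w = self.weights
        return float((w * d).sum() / w.sum())


def fit_state_svm(frames_a: np.ndarray, frames_b: np.ndarray,
                  C: float = 1.0) -> np.ndarray:
    """Linear maximum-margin coefficients separating two state ensembles.

    Features are standardized before fitting and the coefficients mapped back
    to the original distance scale.  Positive coefficients push toward class
    B.  Near-degenerate margins (indistinguishable ensembles) produce a
    warning, never an exception.
    """
    from sklearn.svm import SVC

    A = np.atleast_2d(np.asarray(frames_a, dtype=float))
    B = np.atleast_2d(np.asarray(frames_b, dtype=float))
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise DataError("need at least 2 examples per state")
    X = np.vstack([A, B])
    y = np.r_[np.zeros(A.shape[0]), np.ones(B.shape[0])]
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale < 1e-12] = 1.0
    svm = SVC(kernel="linear", C=C, tol=1e-8)
    svm.fit((X - mean) / scale, y)
    coeffs = svm.coef_[0] / scale
    if np.linalg.norm(coeffs) < 1e-8:
        warnings.warn("degenerate margin: state ensembles are indistinguishable")
    return coeffs


def select_coefficients(coeffs: np.ndarray, gap_factor: float = 5.0,
                        top_k: int = 20):
    """Threshold at the first clear gap in the sorted |coefficient| spectrum.

    |coefficients| are sorted descending; the first adjacent gap wider than
    ``gap_factor`` times the median adjacent spacing sets the threshold at
    its midpoint.  Without such a gap the top ``top_k`` coefficients are kept
    with a warning.  Returns (threshold, selected indices).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size < 2:
        raise DataError("need at least 2 coefficients")
    mags = np.abs(coeffs)
    order = np.argsort(-mags)
    sorted_mags = mags[order]
    gaps = -np.diff(sorted_mags)
    median_gap = float(np.median(gaps))
    big = np.flatnonzero(gaps > gap_factor * max(median_gap, 1e-300))
    if big.size == 0:
        warnings.warn(
            f"no coefficient gap wider than {gap_factor} x median spacing; "
            f"falling back to the top {top_k}")
        k = min(top_k, coeffs.size)
        threshold = sorted_mags[k - 1]
        return float(threshold), [int(i) for i in order[:k]]
    first = int(big[0])
    threshold = 0.5 * (sorted_mags[first] + sorted_mags[first + 1])
    return float(threshold), [int(i) for i in order[:first + 1]]


def build_cv_pair(coeffs: np.ndarray, selected: list[int],
                  pairs: list[tuple[int, int]]):
    """Split selected coefficients by sign into the two per-process CVs.

    Positive coefficients weight CV1 (contacts specific to state 1),
    negated negative coefficients weight CV2.  Raises when either side is
    empty, naming it.
    """
    if not selected:
        raise ConstructionError("no selected coefficients")
    coeffs = np.asarray(coeffs, dtype=float)
    pos = [(pairs[i], float(coeffs[i])) for i in selected if coeffs[i] > 0]
    neg = [(pairs[i], float(-coeffs[i])) for i in selected if coeffs[i] < 0]
    if not pos:
        raise ConstructionError("no positive coefficients: CV1 side is empty")
    if not neg:
        raise ConstructionError("no negative coefficients: CV2 side is empty")
    cv1 = CVDefinition(terms=pos, side="state1_specific")
    cv2 = CVDefinition(terms=neg, side="state2_specific")
    return cv1, cv2


def min_residue_distance(frame: dict[int, np.ndarray], i: int, j: int) -> float:
    """Minimum heavy-atom distance between residues i and j of a frame
    (mapping residue -> (n_atoms, 3) coordinates), in the frame's units."""
    for r in (i, j):
        if r not in frame:
            raise FrameMismatchError(f"residue {r} missing from frame")
    a = np.atleast_2d(np.asarray(frame[i], dtype=float))
    b = np.atleast_2d(np.asarray(frame[j], dtype=float))
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def evaluate_cv(cv: CVDefinition, frame: dict[int, np.ndarray],
                coordinates_in: str = "nm") -> float:
    """Evaluate the CV on a coordinate frame (nm).

    The frame maps residue index to heavy-atom coordinates; Angstrom input is
    converted explicitly.  Linear in the distances, hence equivariant under
    uniform scaling and invariant under rigid motion.
    """
    factor = 1.0 if coordinates_in == "nm" else 1.0 / ANGSTROM_PER_NM
    if coordinates_in not in ("nm", "angstrom"):
        raise ValueError("coordinates_in must be 'nm' or 'angstrom'")
    d = np.array([min_residue_distance(frame, i, j) for i, j in cv.pairs])
    return cv.evaluate_distances(d * factor)


def export_sampling_config(cv_pair, process: str, path=None,
                           overrides: dict | None = None) -> str:
    """Flat key=value sampling configuration for the named process.

    Embeds the residue pairs and weights of both CVs plus the per-process
    adaptive-bias defaults; ``overrides`` are emitted verbatim with a
    provenance note.  Unknown process names raise ConfigError.
    """
    if process not in AWH_PROCESS_DEFAULTS:
        raise ConfigError(
            f"unknown process {process!r}; known: {sorted(AWH_PROCESS_DEFAULTS)}")
    params = {**AWH_COMMON, **AWH_PROCESS_DEFAULTS[process]}
    overridden = set()
    if overrides:
        overridden = set(overrides)
        params.update(overrides)
    cv1, cv2 = cv_pair
    lines = [f"process = {process}"]
    for key in sorted(params):
        note = "  # user override" if key in overridden else ""
        lines.append(f"{key} = {params[key]:g}{note}" if isinstance(params[key], float)
                     else f"{key} = {params[key]}{note}")
    for name, cv in (("cv1", cv1), ("cv2", cv2)):
        lines.append(f"{name}_pairs = " + ";".join(f"{i}-{j}" for i, j in cv.pairs))
        lines.append(f"{name}_weights = " + ";".join(f"{w:.8g}" for w in cv.weights))
        lines.append(f"{name}_normalization = {cv.normalization:.8g}")
        lines.append(f"{name}_units = {cv.units}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def write_cv_definition(cv: CVDefinition, path) -> None:
    payload = {"pairs": [list(p) for p in cv.pairs],
               "weights": [float(w) for w in cv.weights],
               "side": cv.side, "units": cv.units}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_cv_definition(path) -> CVDefinition:
    with open(path) as fh:
        payload = json.load(fh)
    terms = [((int(i), int(j)), float(w))
             for (i, j), w in zip(payload["pairs"], payload["weights"])]
    return CVDefinition(terms=terms, side=payload.get("side", "state1_specific"),
                        units=payload.get("units", "nm"))
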