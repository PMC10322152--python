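"""Translate state signatures into Rosetta-dialect constraint files.

Encouraged contacts become attractive flat-bottomed harmonics inside
``AmbiguousConstraint`` blocks; discouraged contacts become repulsive fade
functions inside ``MultiConstraint`` blocks.  The constraints are written for
an external relaxation engine to consume — nothing here executes it.  All
biases are deliberately weak (force-constant ceiling of 20) and carry a small
overall weight so they steer rather than overwhelm the physical energy
function of the downstream minimizer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from .errors import DataError
from .state_classifier import StateSignature

__all__ = [
    "FORCE_CONSTANT_CEILING", "ConstraintSpec", "map_signature_to_target",
    "write_constraints", "read_constraints", "write_relax_flags",
]

logger = logging.getLogger(__name__)

#: Biases stronger than this (in the engine's standard units) would compete
#: with the native energetics; the writer refuses them.
FORCE_CONSTANT_CEILING = 20.0

DEFAULT_WEIGHT = 0.1
DEFAULT_FLAT_HARMONIC = {"x0": 4.0, "sd": 1.0, "tol": 1.0}
DEFAULT_FADE = {"zmin": 0.0, "zmax": 8.0, "fade_zone": 2.0, "well_depth": 5.0}


@dataclass
class ConstraintSpec:
    """One residue-pair bias in target-protein (1-based) numbering."""

    pair: tuple[int, int]
    direction: str                      # encouraged | discouraged
    functional_form: dict = field(default_factory=dict)
    weight: float = DEFAULT_WEIGHT
    atom: str = "CA"

    def __post_init__(self):
        if self.direction not in ("encouraged", "discouraged"):
            raise DataError(f"unknown direction {self.direction!r}")
        if self.weight <= 0:
            raise DataError("constraint weight must be positive")
        if not self.functional_form:
            self.functional_form = dict(
                DEFAULT_FLAT_HARMONIC if self.direction == "encouraged"
                else DEFAULT_FADE)
        f = self.functional_form
        if self.direction == "encouraged":
            if f["x0"] <= 0:
                raise DataError("flat_harmonic x0 must be positive")
            if 1.0 / f["sd"] ** 2 > FORCE_CONSTANT_CEILING:
                raise DataError(
                    f"flat_harmonic stiffness 1/sd^2 = {1.0 / f['sd'] ** 2:.3g} "
                    f"exceeds the ceiling of {FORCE_CONSTANT_CEILING}")
        else:
            if f["zmin"] >= f["zmax"]:
                raise DataError("fade requires zmin < zmax")
            if abs(f["well_depth"]) > FORCE_CONSTANT_CEILING:
                raise DataError(
                    f"fade well depth {f['well_depth']:.3g} exceeds the "
                    f"ceiling of {FORCE_CONSTANT_CEILING}")


def map_signature_to_target(sig: StateSignature,
                            column_map: dict[int, int],
                            weight: float = DEFAULT_WEIGHT,
                            flat_harmonic: dict | None = None,
                            fade: dict | None = None) -> list[ConstraintSpec]:
    """Translate a signature into constraint specs on the target protein.

    ``column_map`` maps alignment columns (0-based) to target residue numbers
    (1-based); signature pairs whose columns are absent from the map (gaps in
    the target) are dropped and counted in the log.  An empty signature
    yields an empty list with a warning.
    """
    if not sig.contacts:
        warnings.warn(f"signature for state {sig.state!r} is empty")
        return []
    specs = []
    n_dropped = 0
    for (ci, cj), _relevance, direction in sig.contacts:
        ri, rj = column_map.get(ci), column_map.get(cj)
        if ri is None or rj is None:
            n_dropped += 1
            continue
        form = dict((flat_harmonic or DEFAULT_FLAT_HARMONIC)
                    if direction == "encouraged" else (fade or DEFAULT_FADE))
        specs.append(ConstraintSpec(pair=(int(ri), int(rj)), direction=direction,
                                    functional_form=form, weight=weight))
    if n_dropped:
        logger.info("state %s: dropped %d unmappable signature pair(s)",
                    sig.state, n_dropped)
    return specs


def _spec_lines(spec: ConstraintSpec) -> list[str]:
    i, j = spec.pair
    f = spec.functional_form
    if spec.direction == "encouraged":
        body = (f"AtomPair {spec.atom} {i} {spec.atom} {j} "
                f"FLAT_HARMONIC {f['x0']:g} {f['sd']:g} {f['tol']:g}")
        return [f"#WEIGHT {spec.weight:g}", "AmbiguousConstraint", body, "END"]
    body = (f"AtomPair {spec.atom} {i} {spec.atom} {j} "
            f"FADE {f['zmin']:g} {f['zmax']:g} {f['fade_zone']:g} {f['well_depth']:g}")
    return [f"#WEIGHT {spec.weight:g}", "MultiConstraint", body, "END"]


def write_constraints(specs: list[ConstraintSpec], path) -> None:
    """Emit the constraint file; byte-stable for a fixed input order.

    The per-block ``#WEIGHT`` comment records the bias weight (comments are
    ignored by the downstream engine but let the package round-trip its own
    files losslessly).
    """
    if not specs:
        warnings.warn("no constraints to write; emitting an empty file")
    lines = []
    for spec in specs:
        lines += _spec_lines(spec)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_constraints(path) -> list[ConstraintSpec]:
    """Parse a constraint file written by :func:`write_constraints`."""
    specs = []
    weight = DEFAULT_WEIGHT
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line in ("AmbiguousConstraint", "MultiConstraint", "END"):
                continue
            if line.startswith("#WEIGHT"):
                weight = float(line.split()[1])
                continue
            if line.startswith("#"):
                continue
            tok = line.split()
            if tok[0] != "AtomPair":
                raise DataError(f"unsupported constraint line: {line}")
            atom, i, _atom2, j, func = tok[1], int(tok[2]), tok[3], int(tok[4]), tok[5]
            params = [float(x) for x in tok[6:]]
            if func == "FLAT_HARMONIC":
                specs.append(ConstraintSpec(
                    pair=(i, j), direction="encouraged", atom=atom, weight=weight,
                    functional_form={"x0": params[0], "sd": params[1],
                                     "tol": params[2]}))
            elif func == "FADE":
                specs.append(ConstraintSpec(
                    pair=(i, j), direction="discouraged", atom=atom, weight=weight,
                    functional_form={"zmin": params[0], "zmax": params[1],
                                     "fade_zone": params[2],
                                     "well_depth": params[3]}))
            else:
                raise DataError(f"unknown functional form {func!r}")
    return specs


def write_relax_flags(path) -> None:
    """Companion flags file recording the cartesian-relax settings the
    constraints are designed for, as comments for the user."""
    text = (
        "# Cartesian fastrelax settings recommended for these constraints:\n"
        "# pro_close weight 0.0\n"
        "# cart_bonded weight 0.5\n"
        "# constraint weight 0.1 (also recorded per block in the .cst file)\n"
    )
    with open(path, "w") as fh:
        fh.write(text)
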