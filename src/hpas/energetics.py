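"""Electronic-property formulas, geometry validity filters, and RMSD.

The package does not run quantum-chemistry engines; it consumes their
outputs.  An :class:`EnergyRecord` holds the per-charge-state quantities an
external calculator produces (orbital energies in eV, dispersion-corrected
total energy in Hartree), from which the frontier gap and the adiabatic
ionization potential / electron affinity follow:

    Gap = LUMO - HOMO
    AIP = E_tot(cation) - E_tot(neutral)
    AEA = E_tot(anion)  - E_tot(neutral)

Total energies are in Hartree; AIP/AEA are reported in eV using the CODATA
conversion constant.  The validity filter rejects geometries whose
optimization failed, that have imaginary frequencies, a declared bond longer
than 2.0 A, or any atom pair closer than 0.1 A.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .errors import ContractError

logger = logging.getLogger(__name__)

#: CODATA Hartree -> eV conversion.
HARTREE_TO_EV = 27.211386245988

#: Maximum accepted length of a declared bond, in Angstrom.
MAX_BOND_LENGTH = 2.0

#: Minimum accepted distance between any two atoms, in Angstrom.
MIN_ATOM_DISTANCE = 0.1


@dataclass(frozen=True)
class EnergyRecord:
    """Calculator output for one charge state of one molecule.

    Orbital energies are in eV, ``e_tot``/``zpe``/``dispersion`` in Hartree.
    ``homo_minus1 <= homo`` and ``lumo <= lumo_plus1`` are enforced when
    present; ``homo <= lumo`` is *not* (some methods invert them).
    """

    charge: int
    homo: float | None = None
    homo_minus1: float | None = None
    lumo: float | None = None
    lumo_plus1: float | None = None
    e_tot: float | None = None
    zpe: float | None = None
    dispersion: float | None = None
    converged: bool = True
    n_imag: int = 0

    def __post_init__(self):
        if self.charge not in (-1, 0, 1):
            raise ContractError(f"unsupported charge state {self.charge}")
        if (
            self.homo is not None
            and self.homo_minus1 is not None
            and self.homo_minus1 > self.homo
        ):
            raise ContractError("homo_minus1 must not exceed homo")
        if (
            self.lumo is not None
            and self.lumo_plus1 is not None
            and self.lumo > self.lumo_plus1
        ):
            raise ContractError("lumo must not exceed lumo_plus1")


@dataclass(frozen=True)
class Geometry:
    """Cartesian structure: element symbols, coordinates (A), declared bonds."""

    symbols: tuple[str, ...]
    coords: np.ndarray
    bonds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.shape != (len(self.symbols), 3):
            raise ContractError(
                f"coords shape {coords.shape} does not match {len(self.symbols)} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise ContractError("coordinates must be finite")
        n = len(self.symbols)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ContractError(f"invalid bond ({i}, {j}) for {n} atoms")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class ValidationVerdict:
    """Outcome of the geometry validity filter."""

    passed: bool
    reasons: frozenset[str] = field(default_factory=frozenset)

    def __bool__(self) -> bool:
        return self.passed


def homo_lumo_gap(record: EnergyRecord) -> float:
    """Frontier gap, LUMO - HOMO, in eV; defined for neutral records only."""
    if record.charge != 0:
        raise ContractError("the gap is defined only for the neutral state")
    if record.homo is None or record.lumo is None:
        raise ContractError("gap requires both homo and lumo")
    gap = record.lumo - record.homo
    if gap < 0:
        logger.warning("negative HOMO-LUMO gap (%.4f eV)", gap)
    return gap


def _adiabatic_difference(
    neutral: EnergyRecord, charged: EnergyRecord, expected_charge: int
) -> float:
    if neutral.charge != 0 or charged.charge != expected_charge:
        raise ContractError(
            f"expected charges (0, {expected_charge:+d}), got "
            f"({neutral.charge}, {charged.charge})"
        )
    if not (neutral.converged and charged.converged):
        raise ContractError("both charge states must be converged")
    if neutral.e_tot is None or charged.e_tot is None:
        raise ContractError("both records need e_tot")
    return (charged.e_tot - neutral.e_tot) * HARTREE_TO_EV


def adiabatic_ip(neutral: EnergyRecord, cation: EnergyRecord) -> float:
    """Adiabatic ionization potential, E_tot(cation) - E_tot(neutral), in eV."""
    return _adiabatic_difference(neutral, cation, +1)


def adiabatic_ea(neutral: EnergyRecord, anion: EnergyRecord) -> float:
    """Adiabatic electron affinity, E_tot(anion) - E_tot(neutral), in eV."""
    return _adiabatic_difference(neutral, anion, -1)


def validate_geometry(geometry: Geometry, record: EnergyRecord) -> ValidationVerdict:
    """Apply the four validity filters; always returns a verdict.

    Reason codes: ``not_converged``, ``imaginary_freq``, ``long_bond``
    (a declared bond longer than 2.0 A) and ``clash`` (any atom pair closer
    than 0.1 A).  The bond filter applies only to the declared bond list; the
    clash filter applies to all atom pairs.
    """
    reasons = set()
    if not record.converged:
        reasons.add("not_converged")
    if record.n_imag > 0:
        reasons.add("imaginary_freq")
    coords = geometry.coords
    for i, j in geometry.bonds:
        if np.linalg.norm(coords[i] - coords[j]) > MAX_BOND_LENGTH:
            reasons.add("long_bond")
            break
    if len(geometry) >= 2 and pdist(coords).min() < MIN_ATOM_DISTANCE:
        reasons.add("clash")
    return ValidationVerdict(passed=not reasons, reasons=frozenset(reasons))


def kabsch_rmsd(a: Geometry, b: Geometry, heavy_only: bool = False) -> float:
    """Minimal RMSD between two conformations after optimal superposition.

    Atom correspondence is by index; the element sequences must match.  The
    optimal proper rotation is found with the SVD-based construction
    (as implemented by :func:`scipy.spatial.transform.Rotation.align_vectors`)
    after centering both structures.  ``heavy_only`` drops hydrogens before
    superposition.
    """
    if a.symbols != b.symbols:
        raise ContractError("element sequences differ")
    mask = np.ones(len(a), dtype=bool)
    if heavy_only:
        mask = np.array([s != "H" for s in a.symbols])
        if not mask.any():
            raise ContractError("no heavy atoms to superpose")
    pa = a.coords[mask] - a.coords[mask].mean(axis=0)
    pb = b.coords[mask] - b.coords[mask].mean(axis=0)
    _, rssd = Rotation.align_vectors(pa, pb)
    return float(rssd / np.sqrt(mask.sum()))


def rmsd_fraction_below(rmsds, threshold: float = 0.2) -> float:
    """Fraction of RMSD values strictly below ``threshold`` (default 0.2 A).

    The bulk summary used to judge agreement between two geometry sets.
    """
    values = np.asarray(list(rmsds), dtype=float)
    if values.size == 0:
        raise ContractError("no RMSD values given")
    return float(np.mean(values < threshold))
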