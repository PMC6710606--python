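"""Thermodynamic conversions and per-fragment efficiency metrics.

Ligand efficiency (LE) is the binding free energy of a ligand normalized by
its heavy-atom count, LE = ΔG/N; group efficiency (GE) is the same ratio for
the *difference* between two structurally related molecules, GE = ΔΔG/ΔN.

Internally the signed thermodynamic convention is used throughout:
ΔG = RT·ln(Kd) in kcal/mol, negative for binders (Kd < 1 M).  Efficiency
values are reported by default in magnitude convention — positive numbers on
the familiar ~0.3 kcal·mol⁻¹·HA⁻¹ scale — with ``convention="signed"``
available everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from rdkit import Chem
from rdkit import RDLogger

from .errors import (
    DegenerateComparisonError,
    InvalidInputError,
    SmilesParseError,
)

# RDKit logs parse failures to stderr on its own; we raise instead.
RDLogger.DisableLog("rdApp.error")

Convention = Literal["magnitude", "signed"]

#: Gas constant in kcal·mol⁻¹·K⁻¹.
GAS_CONSTANT_KCAL: float = 1.987e-3

#: Standard laboratory temperature in kelvin.
STANDARD_TEMPERATURE_K: float = 298.15


@dataclass(frozen=True)
class ThermoParams:
    """Temperature and gas constant used for Kd ↔ ΔG conversions.

    Parameters
    ----------
    temperature
        Absolute temperature in kelvin.  Defaults to 298.15 K.
    gas_constant
        Gas constant in kcal·mol⁻¹·K⁻¹.  Defaults to 1.987e-3.
    """

    temperature: float = STANDARD_TEMPERATURE_K
    gas_constant: float = GAS_CONSTANT_KCAL

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise InvalidInputError(f"temperature must be > 0 K, got {self.temperature}")
        if not (self.gas_constant > 0):
            raise InvalidInputError(f"gas_constant must be > 0, got {self.gas_constant}")

    @property
    def rt(self) -> float:
        """R·T in kcal/mol."""
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class EfficiencyValue:
    """An efficiency number (kcal·mol⁻¹ per heavy atom) tagged with its sign convention."""

    value: float
    convention: Convention = "magnitude"

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class Fragment:
    """One candidate fragment: affinity, size, and pocket assignment.

    ``delta_g`` is the signed binding free energy in kcal/mol (negative for
    binders).  ``n_heavy`` is the heavy-atom count N (a.k.a. HAC).  If a
    SMILES string is supplied it must agree with ``n_heavy``.
    """

    fragment_id: str
    pocket_id: str
    delta_g: float
    n_heavy: int
    smiles: str | None = None

    def __post_init__(self) -> None:
        if self.n_heavy < 1:
            raise InvalidInputError(
                f"fragment {self.fragment_id!r}: n_heavy must be >= 1, got {self.n_heavy}"
            )
        if not math.isfinite(self.delta_g):
            raise InvalidInputError(
                f"fragment {self.fragment_id!r}: delta_g must be finite, got {self.delta_g}"
            )
        if self.smiles is not None:
            n = heavy_atom_count(self.smiles)
            if n != self.n_heavy:
                raise InvalidInputError(
                    f"fragment {self.fragment_id!r}: n_heavy={self.n_heavy} disagrees "
                    f"with SMILES {self.smiles!r} ({n} heavy atoms)"
                )

    @property
    def is_binder(self) -> bool:
        """True when ΔG < 0 under the signed convention."""
        return self.delta_g < 0

    @property
    def key(self) -> str:
        """Globally unique handle: the same fragment_id in two pockets is two entities."""
        return f"{self.pocket_id}:{self.fragment_id}"

    def le(self, convention: Convention = "magnitude") -> float:
        """Shorthand for ``ligand_efficiency(self, convention).value``."""
        return ligand_efficiency(self, convention).value


def delta_g_from_kd(kd: float, params: ThermoParams | None = None) -> float:
    """Binding free energy ΔG = RT·ln(Kd) in kcal/mol from a dissociation constant.

    Parameters
    ----------
    kd
        Equilibrium dissociation constant in molar.  Must be positive.
    params
        Temperature/gas-constant bundle; defaults to 298.15 K.

    Returns
    -------
    float
        Signed ΔG in kcal/mol — negative for binders (Kd < 1 M).
    """
    if params is None:
        params = ThermoParams()
    if not (kd > 0) or not math.isfinite(kd):
        raise InvalidInputError(f"Kd must be a positive finite molar concentration, got {kd}")
    return params.rt * math.log(kd)


def kd_from_delta_g(delta_g: float, params: ThermoParams | None = None) -> float:
    """Inverse of :func:`delta_g_from_kd`: Kd = exp(ΔG / RT) in molar."""
    if params is None:
        params = ThermoParams()
    if not math.isfinite(delta_g):
        raise InvalidInputError(f"delta_g must be finite, got {delta_g}")
    return math.exp(delta_g / params.rt)


def ligand_efficiency(frag: Fragment, convention: Convention = "magnitude") -> EfficiencyValue:
    """LE = ΔG/N, the average free-energy contribution per heavy atom.

    In magnitude convention the absolute value is returned, so a typical
    fragment hit scores ~0.3 kcal·mol⁻¹·HA⁻¹ positive.
    """
    # Fragment.__post_init__ guarantees n_heavy >= 1; guard anyway for duck-typed input.
    if frag.n_heavy < 1:
        raise InvalidInputError(f"n_heavy must be >= 1, got {frag.n_heavy}")
    signed = frag.delta_g / frag.n_heavy
    if convention == "signed":
        return EfficiencyValue(signed, "signed")
    return EfficiencyValue(abs(signed), "magnitude")


def group_efficiency(
    frag_a: Fragment, frag_b: Fragment, convention: Convention = "magnitude"
) -> EfficiencyValue:
    """GE = (ΔG_B − ΔG_A) / (N_B − N_A): efficiency of the atoms added from A to B.

    Raises
    ------
    DegenerateComparisonError
        When both molecules have the same heavy-atom count (ΔN = 0).
    """
    d_n = frag_b.n_heavy - frag_a.n_heavy
    if d_n == 0:
        raise DegenerateComparisonError(
            f"group efficiency undefined: {frag_a.fragment_id!r} and "
            f"{frag_b.fragment_id!r} have equal heavy-atom count ({frag_a.n_heavy})"
        )
    signed = (frag_b.delta_g - frag_a.delta_g) / d_n
    if convention == "signed":
        return EfficiencyValue(signed, "signed")
    return EfficiencyValue(abs(signed), "magnitude")


def heavy_atom_count(smiles: str) -> int:
    """Number of non-hydrogen atoms in a SMILES string, implicit aromatics included.

    Raises
    ------
    SmilesParseError
        Naming the offending string when RDKit cannot parse it.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return mol.GetNumHeavyAtoms()
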