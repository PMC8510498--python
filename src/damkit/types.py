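"""Domain records for the descriptor pipeline.

Plain dataclasses with eager validation: a record that constructs is a record
the numerical layer can trust (finite energies, consistent units, I > A where
a denominator needs it).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

from .constants import normalize_unit, to_ev


def _require_finite(name: str, value: float, compound_id: str) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} of compound {compound_id!r} is not finite: {value!r}")


@dataclass(frozen=True)
class SpeciesEnergies:
    """Total energies of the neutral, cationic and anionic species of one compound.

    All three energies must carry the same unit (``hartree`` or ``eV``); the
    vertical ionization potential and electron affinity are energy differences
    between the charged and neutral forms.
    """

    compound_id: str
    e_neutral: float
    e_cation: float
    e_anion: float
    unit: str = "eV"

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit", normalize_unit(self.unit))
        for name in ("e_neutral", "e_cation", "e_anion"):
            object.__setattr__(self, name, float(getattr(self, name)))
            _require_finite(name, getattr(self, name), self.compound_id)

    def in_ev(self) -> "SpeciesEnergies":
        """Return an equivalent record with all energies converted to eV."""
        if self.unit == "eV":
            return self
        return SpeciesEnergies(
            compound_id=self.compound_id,
            e_neutral=to_ev(self.e_neutral, self.unit),
            e_cation=to_ev(self.e_cation, self.unit),
            e_anion=to_ev(self.e_anion, self.unit),
            unit="eV",
        )


@dataclass(frozen=True)
class OrbitalPair:
    """HOMO and LUMO eigenvalues (eV) of one compound.

    An inverted ordering (HOMO above LUMO) is unphysical for a closed shell
    and triggers a warning, but the record is kept — the gap is still a
    well-defined difference.
    """

    compound_id: str
    e_homo: float
    e_lumo: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "e_homo", float(self.e_homo))
        object.__setattr__(self, "e_lumo", float(self.e_lumo))
        _require_finite("e_homo", self.e_homo, self.compound_id)
        _require_finite("e_lumo", self.e_lumo, self.compound_id)
        if self.e_homo > self.e_lumo:
            warnings.warn(
                f"compound {self.compound_id!r}: HOMO ({self.e_homo}) above LUMO "
                f"({self.e_lumo}) — unphysical closed-shell ordering",
                stacklevel=2,
            )


@dataclass(frozen=True)
class GlobalDescriptors:
    """Global reactivity descriptors of one compound, all in eV.

    ``gap`` is present only when frontier-orbital data were supplied;
    ``omega_minus``/``omega_plus`` only when (I, A) were available with I > A.
    """

    compound_id: str
    i_pot: Optional[float] = None
    e_aff: Optional[float] = None
    gap: Optional[float] = None
    omega_minus: Optional[float] = None
    omega_plus: Optional[float] = None

    def __post_init__(self) -> None:
        if self.omega_minus is not None or self.omega_plus is not None:
            if self.i_pot is None or self.e_aff is None:
                raise ValueError(
                    f"compound {self.compound_id!r}: omega values populated "
                    "without (I, A)"
                )
            if not self.i_pot > self.e_aff:
                raise ValueError(
                    f"compound {self.compound_id!r}: I ({self.i_pot}) must exceed "
                    f"A ({self.e_aff}) when omega values are populated"
                )
            if self.omega_minus < 0 or self.omega_plus < 0:
                raise ValueError(
                    f"compound {self.compound_id!r}: omega values must be nonnegative"
                )


@dataclass(frozen=True)
class ReferenceSet:
    """Donor-acceptor map anchors: fluorine (acceptor) and sodium (donor).

    Only the ionization potentials and electron affinities are stored; the
    anchor omega values are always recomputed from them at full precision,
    never entered independently.
    """

    i_f: float
    a_f: float
    i_na: float
    a_na: float

    def __post_init__(self) -> None:
        if not self.i_f > self.a_f:
            raise ValueError(f"acceptor reference requires I > A, got ({self.i_f}, {self.a_f})")
        if not self.i_na > self.a_na:
            raise ValueError(f"donor reference requires I > A, got ({self.i_na}, {self.a_na})")

    @property
    def omega_plus_f(self) -> float:
        from .descriptors import electroaccepting_power

        return electroaccepting_power(self.i_f, self.a_f)

    @property
    def omega_minus_na(self) -> float:
        from .descriptors import electrodonating_power

        return electrodonating_power(self.i_na, self.a_na)


#: Region labels of the donor-acceptor map. First token: accepting character
#: versus the F anchor (Ra vs 1); second token: donating character versus the
#: Na anchor (Rd vs 1, where Rd < 1 means a better donor than Na because lower
#: omega_minus donates more readily). Points exactly on an anchor line get the
#: token "boundary".
DAM_REGIONS = (
    "donor-donor",
    "donor-acceptor",
    "acceptor-donor",
    "acceptor-acceptor",
)


@dataclass(frozen=True)
class DAMPoint:
    """A compound's coordinates on the donor-acceptor map."""

    compound_id: str
    ra: float
    rd: float
    region_label: str

    def __post_init__(self) -> None:
        if self.ra <= 0 or self.rd <= 0:
            raise ValueError(
                f"compound {self.compound_id!r}: DAM coordinates must be positive"
            )


@dataclass(frozen=True)
class CompoundRecord:
    """One compound's full descriptor row (a row of the report tables)."""

    compound_id: str
    descriptors: GlobalDescriptors
    dam: Optional[DAMPoint] = None
    substituent: str = ""
    metadata: dict = field(default_factory=dict)
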