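"""Global reactivity descriptors from energies and frontier orbitals.

The scalar layer implements the conceptual-DFT working equations:

    I           = E(cation)  - E(neutral)          (vertical ionization potential)
    A           = E(neutral) - E(anion)            (vertical electron affinity)
    gap         = E(LUMO)    - E(HOMO)
    omega_minus = (3I + A)^2 / (16 (I - A))        (electrodonating power)
    omega_plus  = (I + 3A)^2 / (16 (I - A))        (electroaccepting power)

All descriptor outputs are in eV; species energies may be supplied in Hartree
and are converted with the CODATA factor. ``ReactivityDescriptors`` wraps the
same math as a scikit-learn transformer over pandas DataFrames, and
``descriptor_pipeline`` composes it with the donor-acceptor map into the
record list the reporting layer consumes.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .types import (
    CompoundRecord,
    DAMPoint,
    GlobalDescriptors,
    OrbitalPair,
    ReferenceSet,
    SpeciesEnergies,
)

logger = logging.getLogger(__name__)

RANK_KEYS = ("i_pot", "e_aff", "gap", "omega_minus", "omega_plus", "ra", "rd")


def ionization_potential(e: SpeciesEnergies) -> float:
    """Vertical ionization potential I = E(cation) - E(neutral), in eV."""
    ev = e.in_ev()
    return ev.e_cation - ev.e_neutral


def electron_affinity(e: SpeciesEnergies) -> float:
    """Vertical electron affinity A = E(neutral) - E(anion), in eV.

    A is negative when the anion lies above the neutral (the extra electron is
    unbound), as for dapsone and the BHT / ascorbic-acid standards.
    """
    ev = e.in_ev()
    return ev.e_neutral - ev.e_anion


def gap(o: OrbitalPair) -> float:
    """HOMO-LUMO gap = E(LUMO) - E(HOMO), in eV. Smaller gap, higher reactivity."""
    return o.e_lumo - o.e_homo


def _check_i_a(i_pot: float, e_aff: float, compound_id: str = "<anonymous>") -> None:
    if not np.all(np.isfinite([i_pot, e_aff])):
        raise ValueError(f"compound {compound_id!r}: non-finite (I, A)")
    if not i_pot > e_aff:
        raise ValueError(
            f"compound {compound_id!r}: electrodonating/accepting powers require "
            f"I > A (degenerate denominator 16(I - A) with I={i_pot}, A={e_aff})"
        )


def electrodonating_power(i_pot: float, e_aff: float, compound_id: str = "<anonymous>") -> float:
    """Electrodonating power omega_minus = (3I + A)^2 / (16 (I - A)), in eV.

    Lower values mean a smaller energetic cost to donate fractional charge —
    a better electron donor and, in the donor-acceptor map reading, a better
    antioxidant.
    """
    i_pot, e_aff = float(i_pot), float(e_aff)
    _check_i_a(i_pot, e_aff, compound_id)
    return (3.0 * i_pot + e_aff) ** 2 / (16.0 * (i_pot - e_aff))


def electroaccepting_power(i_pot: float, e_aff: float, compound_id: str = "<anonymous>") -> float:
    """Electroaccepting power omega_plus = (I + 3A)^2 / (16 (I - A)), in eV.

    Higher values mean a larger energetic gain on accepting fractional charge —
    a better electron acceptor (antireductant character).
    """
    i_pot, e_aff = float(i_pot), float(e_aff)
    _check_i_a(i_pot, e_aff, compound_id)
    return (i_pot + 3.0 * e_aff) ** 2 / (16.0 * (i_pot - e_aff))


class ReactivityDescriptors(BaseEstimator, TransformerMixin):
    """Transformer from per-compound inputs to global reactivity descriptors.

    The transformer is stateless (``fit`` only validates parameters); it maps
    a DataFrame with one row per compound onto the descriptor columns
    ``i_pot``, ``e_aff``, ``gap``, ``omega_minus``, ``omega_plus`` (eV).

    Parameters
    ----------
    input_kind : {"auto", "energies", "orbitals", "direct"}
        How to interpret the input columns:

        * ``energies`` — columns ``e_neutral``, ``e_cation``, ``e_anion`` and
          optionally ``unit`` (default eV); I and A are energy differences.
        * ``direct`` — columns ``i_pot``, ``e_aff`` already in eV (the entry
          path for published descriptor tables).
        * ``orbitals`` — columns ``e_homo``, ``e_lumo`` in eV; only the gap is
          derivable.
        * ``auto`` — pick whichever of the above matches the columns present.
    strict : bool
        When True (default), any compound with I <= A raises; when False such
        rows get NaN omega values and a logged warning.

    Examples
    --------
    >>> import pandas as pd
    >>> X = pd.DataFrame({"compound_id": ["DDS"], "i_pot": [7.78], "e_aff": [-1.10]})
    >>> ReactivityDescriptors(input_kind="direct").fit_transform(X).round(2)
      compound_id  i_pot  e_aff  omega_minus  omega_plus
    0         DDS   7.78   -1.1         3.48        0.14
    """

    _ENERGY_COLS = ("e_neutral", "e_cation", "e_anion")
    _ORBITAL_COLS = ("e_homo", "e_lumo")
    _DIRECT_COLS = ("i_pot", "e_aff")

    def __init__(self, input_kind: str = "auto", strict: bool = True):
        self.input_kind = input_kind
        self.strict = strict

    def fit(self, X: pd.DataFrame, y=None) -> "ReactivityDescriptors":
        if self.input_kind not in ("auto", "energies", "orbitals", "direct"):
            raise ValueError(f"unknown input_kind {self.input_kind!r}")
        self._validate(X)
        self.n_features_in_ = X.shape[1]
        return self

    def _resolve_kind(self, X: pd.DataFrame) -> str:
        if self.input_kind != "auto":
            return self.input_kind
        cols = set(X.columns)
        if set(self._ENERGY_COLS) <= cols:
            return "energies"
        if set(self._DIRECT_COLS) <= cols:
            return "direct"
        if set(self._ORBITAL_COLS) <= cols:
            return "orbitals"
        raise ValueError(
            "could not infer input kind: need columns "
            f"{self._ENERGY_COLS}, {self._DIRECT_COLS} or {self._ORBITAL_COLS}, "
            f"got {sorted(cols)}"
        )

    def _validate(self, X: pd.DataFrame) -> str:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a pandas DataFrame with a compound_id column")
        if "compound_id" not in X.columns:
            raise ValueError("input is missing the compound_id column")
        dup = X["compound_id"][X["compound_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate compound_id values: {sorted(set(dup))}")
        kind = self._resolve_kind(X)
        needed = {
            "energies": self._ENERGY_COLS,
            "orbitals": self._ORBITAL_COLS,
            "direct": self._DIRECT_COLS,
        }[kind]
        missing = [c for c in needed if c not in X.columns]
        if missing:
            raise ValueError(f"input kind {kind!r} is missing columns {missing}")
        return kind

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        kind = self._validate(X)
        out = pd.DataFrame({"compound_id": X["compound_id"].to_numpy()})
        if kind == "orbitals":
            pairs = [
                OrbitalPair(str(r.compound_id), float(r.e_homo), float(r.e_lumo))
                for r in X.itertuples()
            ]
            out["gap"] = [gap(p) for p in pairs]
            return out

        if kind == "energies":
            records = [
                SpeciesEnergies(
                    str(r.compound_id),
                    float(r.e_neutral),
                    float(r.e_cation),
                    float(r.e_anion),
                    unit=str(getattr(r, "unit", "eV")),
                )
                for r in X.itertuples()
            ]
            i_pot = np.array([ionization_potential(e) for e in records])
            e_aff = np.array([electron_affinity(e) for e in records])
        else:  # direct (I, A) in eV
            i_pot = X["i_pot"].to_numpy(dtype=float)
            e_aff = X["e_aff"].to_numpy(dtype=float)

        out["i_pot"] = i_pot
        out["e_aff"] = e_aff
        wm = np.full(len(out), np.nan)
        wp = np.full(len(out), np.nan)
        for k, (cid, i, a) in enumerate(zip(out["compound_id"], i_pot, e_aff)):
            try:
                wm[k] = electrodonating_power(i, a, cid)
                wp[k] = electroaccepting_power(i, a, cid)
            except ValueError:
                if self.strict:
                    raise
                logger.warning("compound %r: I <= A, omega values set to NaN", cid)
        out["omega_minus"] = wm
        out["omega_plus"] = wp
        return out


def descriptor_pipeline(
    energies: Optional[Sequence[SpeciesEnergies]] = None,
    orbitals: Optional[Sequence[OrbitalPair]] = None,
    ref: Optional[ReferenceSet] = None,
    direct: Optional[Sequence[tuple]] = None,
) -> list[CompoundRecord]:
    """Compose the descriptor transforms into one record list.

    Energy-only compounds get (I, A, omega) but no gap; orbital-only compounds
    get only the gap; a compound in both inputs gets everything. ``direct``
    accepts ``(compound_id, I, A)`` triples in eV for descriptor tables whose
    energies are not available — those are merged with the energy-derived rows
    (a compound may appear in only one of the two). DAM points are attached
    iff ``ref`` is given and the compound has omega values.
    """
    from .dam import dam_indices

    energies = list(energies or [])
    orbitals = list(orbitals or [])
    direct = list(direct or [])

    ia: dict[str, tuple[float, float]] = {}
    order: list[str] = []

    for e in energies:
        if e.compound_id in ia:
            raise ValueError(f"duplicate compound_id {e.compound_id!r} in energies")
        ia[e.compound_id] = (ionization_potential(e), electron_affinity(e))
        order.append(e.compound_id)
    for cid, i, a in direct:
        if cid in ia:
            raise ValueError(f"duplicate compound_id {cid!r} between energies and direct table")
        ia[cid] = (float(i), float(a))
        order.append(cid)

    gaps: dict[str, float] = {}
    for o in orbitals:
        if o.compound_id in gaps:
            raise ValueError(f"duplicate compound_id {o.compound_id!r} in orbitals")
        gaps[o.compound_id] = gap(o)
        if o.compound_id not in ia:
            order.append(o.compound_id)

    records = []
    for cid in order:
        i_pot = e_aff = wm = wp = None
        if cid in ia:
            i_pot, e_aff = ia[cid]
            wm = electrodonating_power(i_pot, e_aff, cid)
            wp = electroaccepting_power(i_pot, e_aff, cid)
        d = GlobalDescriptors(
            compound_id=cid,
            i_pot=i_pot,
            e_aff=e_aff,
            gap=gaps.get(cid),
            omega_minus=wm,
            omega_plus=wp,
        )
        dam = dam_indices(d, ref) if (ref is not None and wm is not None) else None
        records.append(CompoundRecord(compound_id=cid, descriptors=d, dam=dam))
    return records


def _record_key(record: CompoundRecord, key: str) -> float:
    if key in ("ra", "rd"):
        if record.dam is None:
            raise ValueError(
                f"compound {record.compound_id!r} carries no DAM point for key {key!r}"
            )
        return getattr(record.dam, key)
    value = getattr(record.descriptors, key)
    if value is None:
        raise ValueError(
            f"compound {record.compound_id!r} carries no value for key {key!r}"
        )
    return value


def rank_by(
    records: Iterable[CompoundRecord],
    key: str,
    direction: str = "ascending",
    printed_precision: int = 2,
) -> list[str]:
    """Order compound ids by a descriptor at full precision.

    Ties at full precision (exact float equality) break lexicographically on
    compound_id; groups that are tied only at *printed* precision (default two
    decimals, as in the published tables) are reported through the module
    logger so printed-table comparisons stay auditable.
    """
    records = list(records)
    if key not in RANK_KEYS:
        raise ValueError(f"unknown ranking key {key!r}; expected one of {RANK_KEYS}")
    if direction not in ("ascending", "descending"):
        raise ValueError(f"direction must be ascending or descending, got {direction!r}")
    keyed = [(_record_key(r, key), r.compound_id) for r in records]

    printed = {}
    for v, cid in keyed:
        printed.setdefault(round(v, printed_precision), []).append(cid)
    for pv, ids in printed.items():
        if len(ids) > 1:
            logger.info(
                "key %s: compounds %s tie at printed precision (%s); resolved at full precision",
                key,
                sorted(ids),
                pv,
            )

    keyed.sort(key=lambda t: (t[0], t[1]), reverse=(direction == "descending"))
    return [cid for _, cid in keyed]
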