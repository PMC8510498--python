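"""Physical constants and shared unit handling."""

# CODATA 2018 Hartree-electronvolt relationship.
HARTREE_TO_EV: float = 27.211386245988

#: Unit tokens accepted for energy tables (case-insensitive on read).
VALID_UNITS = ("hartree", "eV")


def normalize_unit(token: str) -> str:
    """Map a unit token to its canonical form, rejecting unknown units.

    Accepts ``hartree``/``ha``/``au`` and ``ev`` in any case.
    """
    t = token.strip().lower()
    if t in ("hartree", "ha", "au", "a.u."):
        return "hartree"
    if t == "ev":
        return "eV"
    raise ValueError(
        f"unknown energy unit {token!r}; expected one of {VALID_UNITS}"
    )


def to_ev(value: float, unit: str) -> float:
    """Convert an energy to eV from a canonical unit tag."""
    if unit == "eV":
        return value
    if unit == "hartree":
        return value * HARTREE_TO_EV
    raise ValueError(f"unknown canonical unit {unit!r}")
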