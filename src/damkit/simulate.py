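"""Synthetic inputs with known ground truth.

Three generators cover the package's input surface:

* ``panel_generate`` — species-energy triples whose hidden (I, A) are drawn
  uniformly with a guaranteed separation, so the descriptor pipeline can be
  checked by exact round trip (energies are built as e_cation = e_neutral + I,
  e_anion = e_neutral - A).
* ``huckel_orbitals`` — a Hueckel pi-system solver (eigenvalues of
  alpha*I + beta*Adjacency) serving as an independent oracle for the
  HOMO/LUMO/gap path: paths and cycles have closed-form spectra.
* ``assay_simulate`` — replicate absorbances whose expected percentages follow
  a stated monotone logistic link from a reactivity descriptor, so
  pipeline-level rank recovery can be tested. The link is openly synthetic:
  its defaults map the electrodonating-power range of the dapsone panel
  (about 3-7 eV) onto the observed DPPH percentage range, with lower
  omega_minus giving higher true capture.

All randomness flows through ``numpy.random.default_rng(seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .assay import AssayPanel, AssayReplicate
from .types import CompoundRecord, OrbitalPair, SpeciesEnergies


@dataclass(frozen=True)
class PanelSpec:
    """Specification for a synthetic species-energy panel.

    ``min_separation`` enforces I - A >= that many eV, keeping the
    omega denominators away from zero (the dapsone panel itself spans
    separations of roughly 5-9 eV).
    """

    n_compounds: int
    i_range: tuple = (7.5, 9.0)
    a_range: tuple = (-1.7, 1.7)
    min_separation: float = 0.5
    seed: int = 0
    e_neutral_anchor: float = -1000.0
    unit: str = "eV"

    def __post_init__(self) -> None:
        if self.n_compounds < 0:
            raise ValueError("n_compounds must be nonnegative")
        for lo, hi in (self.i_range, self.a_range):
            if not lo < hi:
                raise ValueError("ranges must satisfy lo < hi")
        if not self.min_separation > 0:
            raise ValueError("min_separation must be positive")
        if self.i_range[1] - self.a_range[0] < self.min_separation:
            raise ValueError(
                "infeasible ranges: no (I, A) pair can satisfy the separation"
            )


def panel_generate(spec: PanelSpec) -> tuple[list[SpeciesEnergies], "np.recarray"]:
    """Draw a panel of energy triples with controlled (I, A) structure.

    Returns the energy records plus a hidden truth table (record array with
    fields compound_id, i_pot, e_aff) for round-trip tests. (I, A) pairs are
    drawn uniformly within their ranges by rejection until I - A meets the
    separation; deterministic under ``spec.seed``.
    """
    from .constants import HARTREE_TO_EV

    rng = np.random.default_rng(spec.seed)
    ids, i_list, a_list = [], [], []
    for k in range(spec.n_compounds):
        for _ in range(10_000):
            i_pot = rng.uniform(*spec.i_range)
            e_aff = rng.uniform(*spec.a_range)
            if i_pot - e_aff >= spec.min_separation:
                break
        else:  # pragma: no cover - guarded by PanelSpec feasibility check
            raise RuntimeError("rejection sampling failed to satisfy the separation")
        ids.append(f"S{k + 1:04d}")
        i_list.append(i_pot)
        a_list.append(e_aff)

    scale = 1.0 / HARTREE_TO_EV if spec.unit.lower() in ("hartree", "ha", "au") else 1.0
    records = [
        SpeciesEnergies(
            compound_id=cid,
            e_neutral=spec.e_neutral_anchor * scale,
            e_cation=(spec.e_neutral_anchor + i_pot) * scale,
            e_anion=(spec.e_neutral_anchor - e_aff) * scale,
            unit=spec.unit,
        )
        for cid, i_pot, e_aff in zip(ids, i_list, a_list)
    ]
    truth = np.rec.fromarrays(
        [np.array(ids), np.array(i_list, dtype=float), np.array(a_list, dtype=float)],
        names=("compound_id", "i_pot", "e_aff"),
    )
    return records, truth


@dataclass(frozen=True)
class PiSystem:
    """A Hueckel pi system: 0/1 adjacency plus Coulomb/resonance integrals.

    ``alpha`` shifts the whole spectrum; ``beta`` (negative by convention)
    scales the splitting. The default electron count is one pi electron per
    center and must be even (closed shell).
    """

    adjacency: np.ndarray
    alpha: float = 0.0
    beta: float = -1.0
    n_electrons: Optional[int] = None

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=float)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        if not np.isin(adj, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        object.__setattr__(self, "adjacency", adj)
        n_e = self.n_electrons if self.n_electrons is not None else adj.shape[0]
        if n_e % 2 != 0:
            raise ValueError("open-shell pi systems (odd electron count) are not supported")
        if not 0 < n_e < 2 * adj.shape[0]:
            raise ValueError("electron count must leave both occupied and virtual orbitals")
        object.__setattr__(self, "n_electrons", n_e)

    @property
    def n_centers(self) -> int:
        return self.adjacency.shape[0]


def path_system(n: int, alpha: float = 0.0, beta: float = -1.0, **kw) -> PiSystem:
    """Linear polyene chain of n centers (ethylene n=2, butadiene n=4...)."""
    adj = np.zeros((n, n))
    idx = np.arange(n - 1)
    adj[idx, idx + 1] = adj[idx + 1, idx] = 1
    return PiSystem(adjacency=adj, alpha=alpha, beta=beta, **kw)


def cycle_system(n: int, alpha: float = 0.0, beta: float = -1.0, **kw) -> PiSystem:
    """Monocyclic pi system of n centers (benzene n=6)."""
    ps = path_system(n, alpha=alpha, beta=beta, **kw)
    adj = ps.adjacency.copy()
    adj[0, n - 1] = adj[n - 1, 0] = 1
    return PiSystem(adjacency=adj, alpha=alpha, beta=beta, **kw)


def huckel_eigenvalues(ps: PiSystem) -> np.ndarray:
    """Sorted eigenvalues of the Hueckel Hamiltonian alpha*I + beta*A."""
    h = ps.alpha * np.eye(ps.n_centers) + ps.beta * ps.adjacency
    return np.linalg.eigvalsh(h)


def path_eigenvalues(n: int, alpha: float = 0.0, beta: float = -1.0) -> np.ndarray:
    """Closed-form spectrum of a chain: alpha + 2 beta cos(k pi / (n+1))."""
    k = np.arange(1, n + 1)
    return np.sort(alpha + 2.0 * beta * np.cos(k * np.pi / (n + 1)))


def cycle_eigenvalues(n: int, alpha: float = 0.0, beta: float = -1.0) -> np.ndarray:
    """Closed-form spectrum of a ring: alpha + 2 beta cos(2 pi k / n)."""
    k = np.arange(n)
    return np.sort(alpha + 2.0 * beta * np.cos(2.0 * np.pi * k / n))


def huckel_orbitals(ps: PiSystem, compound_id: str = "pi-system") -> tuple[OrbitalPair, np.ndarray]:
    """Frontier orbitals of a closed-shell pi system.

    Fills the sorted spectrum with electron pairs; HOMO is the highest filled
    level, LUMO the next one. A degenerate HOMO (benzene's e1g pair) simply
    reports the shared eigenvalue. Returns the pair plus the full spectrum.
    """
    eigenvalues = huckel_eigenvalues(ps)
    n_pairs = ps.n_electrons // 2
    homo = float(eigenvalues[n_pairs - 1])
    lumo = float(eigenvalues[n_pairs])
    return OrbitalPair(compound_id=compound_id, e_homo=homo, e_lumo=lumo), eigenvalues


@dataclass(frozen=True)
class AssaySimSpec:
    """Logistic descriptor-to-activity link plus replicate noise.

    ``true% = max_percent / (1 + exp(sign * slope * (omega - midpoint)))``
    with sign fixed so that for the donor link (omega_minus) lower values give
    higher capture and for the acceptor link (omega_plus) higher values give
    higher reduction. Defaults place the midpoint inside the dapsone panel's
    omega_minus range so the simulated percentages span the observed 0-90%.
    """

    link_descriptor: str = "omega_minus"
    midpoint: float = 5.0
    slope: float = 1.5
    max_percent: float = 95.0
    noise_sd: float = 1.0
    n_replicates: int = 3
    seed: int = 0
    assay_type: str = "DPPH"
    control_absorbance: float = 0.80

    def __post_init__(self) -> None:
        if self.link_descriptor not in ("omega_minus", "omega_plus"):
            raise ValueError("link_descriptor must be omega_minus or omega_plus")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.slope <= 0:
            raise ValueError("slope must be positive; the sign convention is fixed")
        if self.assay_type not in ("DPPH", "FRAP"):
            raise ValueError("assay_type must be DPPH or FRAP")


def link_percent(omega: float, spec: AssaySimSpec) -> float:
    """The noiseless logistic link from a descriptor value to true percent."""
    sign = 1.0 if spec.link_descriptor == "omega_minus" else -1.0
    return spec.max_percent / (1.0 + np.exp(sign * spec.slope * (omega - spec.midpoint)))


def assay_simulate(
    records: Sequence[CompoundRecord], spec: AssaySimSpec
) -> tuple[AssayPanel, "np.recarray"]:
    """Simulate a replicate assay panel from descriptor records.

    Per replicate, Gaussian noise (SD ``spec.noise_sd`` percentage points) is
    added to the link output and the absorbance is back-computed so that the
    percentage formulas recover exactly the noisy percent. Returns the panel
    plus a truth table of noiseless link percentages.
    """
    rng = np.random.default_rng(spec.seed)
    control_id = "CONTROL"
    a_control = spec.control_absorbance

    replicates = [
        AssayReplicate(control_id, j + 1, a_control) for j in range(spec.n_replicates)
    ]
    ids, true_pct = [], []
    for rec in records:
        omega = getattr(rec.descriptors, spec.link_descriptor)
        if omega is None:
            raise ValueError(
                f"compound {rec.compound_id!r} lacks {spec.link_descriptor}; cannot link"
            )
        truth = float(link_percent(omega, spec))
        ids.append(rec.compound_id)
        true_pct.append(truth)
        noisy = truth + rng.normal(0.0, spec.noise_sd, size=spec.n_replicates)
        for j, pct in enumerate(noisy):
            if spec.assay_type == "DPPH":
                absorbance = a_control * (1.0 - pct / 100.0)
            else:
                absorbance = a_control * pct / 100.0
            replicates.append(AssayReplicate(rec.compound_id, j + 1, max(absorbance, 0.0)))

    panel = AssayPanel(
        assay_type=spec.assay_type, replicates=tuple(replicates), control_id=control_id
    )
    truth_table = np.rec.fromarrays(
        [np.array(ids), np.array(true_pct, dtype=float)],
        names=("compound_id", "true_percent"),
    )
    return panel, truth_table
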