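"""Excitonic Hamiltonian assembly, adiabatic states and gradients.

The electronic Hamiltonian of a multichromophoric system is approximated
in the Frenkel picture: the basis consists of the global ground state
``|gs>`` plus quasi-diabatic states ``|ai>`` in which chromophore ``a``
carries its ``i``-th localized excitation while every other chromophore
sits in its ground state.  In this basis the Hamiltonian is

    H = E_gs |gs><gs| + sum_ai (E_gs + dE_ai) |ai><ai|
        + sum_{ai != bj} V_ai,bj |ai><bj|

where ``dE_ai`` are the site energies (vertical excitation energies of
the monomers) and ``V_ai,bj`` the excitonic couplings.  Couplings
between excitations on the same chromophore vanish identically because
the localized states are eigenstates of the monomer problem, and the
ground state is uncoupled by construction, so it passes through the
diagonalization unchanged.

All quantities in this module are in Hartree atomic units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BasisLabel",
    "SiteStateResult",
    "EnergyLedger",
    "ExcitonHamiltonian",
    "AdiabaticSet",
    "GradientSet",
    "assemble_hamiltonian",
    "ground_state_energy",
    "adiabatize",
    "adiabatic_gradient",
]

#: (chromophore_id, state_index) with state_index >= 1; the ground state
#: carries the distinguished label ``("gs", 0)`` in serialized tables.
BasisLabel = tuple[int, int]

_SYMMETRY_TOL = 1e-12


@dataclass(frozen=True)
class SiteStateResult:
    """Energy, gradient and transition data for one monomer state.

    Parameters
    ----------
    chromophore_id : int
        Index of the chromophore this state lives on.
    state_index : int
        0 for the monomer ground state, >= 1 for localized excitations.
    energy : float
        Total monomer (QM/MM) energy, hartree.
    gradient : ndarray
        Gradient over this chromophore's own nuclear coordinates,
        hartree/bohr (or hartree/radian for torsional models).
    transition_dipole : ndarray, shape (3,)
        Transition dipole <0|r|i> in au; zeros for the ground state.
    transition_charges : object, optional
        A ``TransitionChargeSet`` or ``TransitionDensityCloud`` used by
        the coupling schemes; ``None`` for the ground state.
    """

    chromophore_id: int
    state_index: int
    energy: float
    gradient: np.ndarray
    transition_dipole: np.ndarray = field(default_factory=lambda: np.zeros(3))
    transition_charges: object | None = None

    def __post_init__(self):
        if self.state_index < 0:
            raise ValueError("state_index must be >= 0")


@dataclass
class EnergyLedger:
    """Bookkeeping of QM/MM and MM energy components for the ground state.

    Each per-site calculation treats all other chromophores as its MM
    region, so the per-site energy ``E_0^(a)`` contains the MM energies
    of the other monomers, their mutual MM interactions, and the QM/MM
    interaction of site ``a`` with each of them.

    Attributes
    ----------
    per_site_qmmm_energy : dict
        ``a -> E_0^(a)``, the QM/MM ground-state energy of monomer ``a``.
    full_mm_energy : float
        MM energy of the full system, ``E_MM``.
    per_site_mm_energy : dict
        ``a -> E(MM, a)``.
    pairwise_mm_interaction : dict
        ``(a, b) with a < b -> E(MM, ab)`` interaction term.
    per_pair_qmmm_interaction : dict
        ordered ``(a, b) -> E(QM/MM, ab)``: QM monomer ``a`` with MM
        monomer ``b``.
    """

    per_site_qmmm_energy: dict[int, float]
    full_mm_energy: float
    per_site_mm_energy: dict[int, float] = field(default_factory=dict)
    pairwise_mm_interaction: dict[tuple[int, int], float] = field(default_factory=dict)
    per_pair_qmmm_interaction: dict[tuple[int, int], float] = field(default_factory=dict)

    @classmethod
    def from_components(
        cls,
        qm_energies: Mapping[int, float],
        mm_energies: Mapping[int, float],
        mm_pair_interactions: Mapping[tuple[int, int], float],
        qmmm_pair_interactions: Mapping[tuple[int, int], float],
    ) -> "EnergyLedger":
        """Build a consistent ledger from elementary components.

        ``mm_pair_interactions`` is keyed by unordered pairs ``(a, b)``
        with ``a < b``; ``qmmm_pair_interactions`` by ordered pairs.
        """
        sites = sorted(qm_energies)
        mm_pairs = {tuple(sorted(k)): v for k, v in mm_pair_interactions.items()}
        per_site_qmmm = {}
        for a in sites:
            e = qm_energies[a]
            for b in sites:
                if b == a:
                    continue
                e += mm_energies[b]
                e += qmmm_pair_interactions.get((a, b), 0.0)
            # mutual MM interactions among the *other* chromophores are
            # part of site a's MM region
            for (b, c), v in mm_pairs.items():
                if a not in (b, c):
                    e += v
            per_site_qmmm[a] = e
        full_mm = sum(mm_energies[a] for a in sites) + sum(mm_pairs.values())
        return cls(
            per_site_qmmm_energy=per_site_qmmm,
            full_mm_energy=full_mm,
            per_site_mm_energy=dict(mm_energies),
            pairwise_mm_interaction=mm_pairs,
            per_pair_qmmm_interaction=dict(qmmm_pair_interactions),
        )

    def validate(self, tol: float = 1e-10) -> None:
        """Check the decomposition of the full MM energy, if available."""
        if not self.per_site_mm_energy:
            return
        total = sum(self.per_site_mm_energy.values()) + sum(
            self.pairwise_mm_interaction.values()
        )
        if abs(total - self.full_mm_energy) > tol:
            raise ValueError(
                f"full MM energy {self.full_mm_energy} does not match the "
                f"sum of per-site and pairwise terms {total}"
            )


def ground_state_energy(ledger: EnergyLedger, n_chromophores: int) -> float:
    """Ground-state energy with the MM double-counting correction.

    ``E_gs = sum_a E_0^(a) - (N_C - 1) * E_MM``.  Subtracting ``E_MM``
    from every per-site QM/MM energy removes the unwanted MM description
    of the other monomers; the surviving single ``E_MM`` compensates for
    what would otherwise be erased entirely.  For two chromophores this
    reduces exactly to

        E_gs = E(QM,a) + E(QM,b) + E(QM/MM,ab) + E(QM/MM,ba) - E(MM,ab)

    where the last term removes the double-counted a-b interaction.
    """
    sites = sorted(ledger.per_site_qmmm_energy)
    if len(sites) != n_chromophores:
        raise ValueError(
            f"ledger covers {len(sites)} chromophores, expected {n_chromophores}"
        )
    ledger.validate()
    return sum(ledger.per_site_qmmm_energy.values()) - (
        n_chromophores - 1
    ) * ledger.full_mm_energy


@dataclass
class ExcitonHamiltonian:
    """Assembled excitonic Hamiltonian.

    Attributes
    ----------
    ground_energy : float
        ``E_gs`` in hartree.
    site_energies : ndarray, shape (n,)
        Site energies ``dE_ai`` in basis-label order, hartree.  No sign
        assumption is made: site energies may become negative where a
        monomer's excited surface dips below its ground surface.
    couplings : ndarray, shape (n, n)
        Symmetric coupling matrix with exactly zero diagonal and zero
        intra-chromophore blocks.
    basis_labels : list of (chromophore_id, state_index)
    """

    ground_energy: float
    site_energies: np.ndarray
    couplings: np.ndarray
    basis_labels: list[BasisLabel]

    @property
    def n_excitons(self) -> int:
        return len(self.basis_labels)

    def excitonic_block(self) -> np.ndarray:
        """The excitonic block ``diag(E_gs + dE_ai) + V``."""
        return (
            np.diag(self.ground_energy + self.site_energies) + self.couplings
        )

    def full_matrix(self) -> np.ndarray:
        """Full (n+1) x (n+1) Hamiltonian with the ground state first."""
        n = self.n_excitons
        h = np.zeros((n + 1, n + 1))
        h[0, 0] = self.ground_energy
        h[1:, 1:] = self.excitonic_block()
        return h

    def to_frame(self) -> pd.DataFrame:
        """Serialize to a tabular form: one row per basis label.

        Columns: chromophore, state, site_energy, then one coupling
        column per basis label.  The ground energy is stored in the
        frame's ``attrs``.
        """
        cols = [f"V_{a}_{i}" for a, i in self.basis_labels]
        df = pd.DataFrame(self.couplings, columns=cols)
        df.insert(0, "chromophore", [a for a, _ in self.basis_labels])
        df.insert(1, "state", [i for _, i in self.basis_labels])
        df.insert(2, "site_energy", self.site_energies)
        df.attrs["ground_energy"] = self.ground_energy
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, ground_energy: float | None = None) -> "ExcitonHamiltonian":
        labels = list(zip(df["chromophore"].astype(int), df["state"].astype(int)))
        v = df[[f"V_{a}_{i}" for a, i in labels]].to_numpy(float)
        e0 = df.attrs.get("ground_energy", 0.0) if ground_energy is None else ground_energy
        return cls(
            ground_energy=float(e0),
            site_energies=df["site_energy"].to_numpy(float),
            couplings=v,
            basis_labels=labels,
        )


@dataclass
class AdiabaticSet:
    """Adiabatic states from diagonalizing the excitonic block.

    ``energies[0]`` is the (untouched) ground-state energy; the
    remaining entries are the excitonic eigenvalues in ascending order.
    ``coefficients[:, K-1]`` gives the excitonic-basis expansion of
    adiabatic state ``K`` (K >= 1).  ``label_map[K]`` is the dominant
    excitonic label of state K.
    """

    energies: np.ndarray
    coefficients: np.ndarray
    basis_labels: list[BasisLabel]
    label_map: dict[int, BasisLabel]

    @property
    def n_states(self) -> int:
        """Number of states including the ground state."""
        return len(self.energies)

    def excitation_energies(self) -> np.ndarray:
        """``E_K - E_gs`` for the excitonic adiabats, hartree."""
        return self.energies[1:] - self.energies[0]

    def full_coefficients(self) -> np.ndarray:
        """(n+1) x (n+1) block-diagonal coefficient matrix incl. ground."""
        n = self.coefficients.shape[0]
        c = np.zeros((n + 1, n + 1))
        c[0, 0] = 1.0
        c[1:, 1:] = self.coefficients
        return c

    def to_frame(self) -> pd.DataFrame:
        cols = [f"C_{a}_{i}" for a, i in self.basis_labels]
        df = pd.DataFrame(self.coefficients.T, columns=cols)
        df.insert(0, "state", np.arange(1, len(self.energies)))
        df.insert(1, "energy", self.energies[1:])
        df.attrs["ground_energy"] = self.energies[0]
        return df


@dataclass
class GradientSet:
    """Gradients of the Hamiltonian matrix elements.

    All arrays span the system's full nuclear coordinate vector
    (dimension D): ``grad_ground`` has shape (D,), ``grad_site`` shape
    (n, D) and ``grad_coupling`` shape (n, n, D) with
    ``grad_coupling[i, j] == grad_coupling[j, i]``.
    """

    grad_ground: np.ndarray
    grad_site: np.ndarray
    grad_coupling: np.ndarray

    def __post_init__(self):
        d = len(self.grad_ground)
        n = self.grad_site.shape[0]
        if self.grad_site.shape != (n, d) or self.grad_coupling.shape != (n, n, d):
            raise ValueError("inconsistent gradient dimensions")


def assemble_hamiltonian(
    site_results: Sequence[Sequence[SiteStateResult]],
    couplings: np.ndarray,
    ledger: EnergyLedger | None = None,
) -> ExcitonHamiltonian:
    """Assemble the excitonic Hamiltonian from per-monomer results.

    Parameters
    ----------
    site_results : sequence of sequences
        One inner sequence per chromophore, containing its ground state
        (state_index 0) and at least one excited state.
    couplings : ndarray
        Symmetric matrix indexed by the excitonic basis labels in
        (chromophore, state) order.  Intra-chromophore entries are
        forced to exactly zero.
    ledger : EnergyLedger, optional
        When given, the ground energy comes from
        :func:`ground_state_energy`; otherwise it is the sum of the
        monomer ground-state energies (no MM environment).

    Raises
    ------
    ValueError
        On missing ground states, mismatched label sets, or a coupling
        matrix that is non-symmetric beyond 1e-12.
    """
    labels: list[BasisLabel] = []
    site_e: list[float] = []
    for results in site_results:
        by_index = {r.state_index: r for r in results}
        if 0 not in by_index:
            raise ValueError(
                f"chromophore {results[0].chromophore_id} is missing its ground state"
            )
        if len(by_index) < 2:
            raise ValueError(
                f"chromophore {results[0].chromophore_id} contributes no excited state"
            )
        ground = by_index[0]
        for i in sorted(by_index):
            if i == 0:
                continue
            r = by_index[i]
            if r.chromophore_id != ground.chromophore_id:
                raise ValueError("mixed chromophore ids within one site block")
            labels.append((r.chromophore_id, r.state_index))
            site_e.append(r.energy - ground.energy)

    n = len(labels)
    couplings = np.asarray(couplings, float)
    if couplings.shape != (n, n):
        raise ValueError(
            f"coupling matrix shape {couplings.shape} does not match the "
            f"{n} basis labels"
        )
    if np.max(np.abs(couplings - couplings.T)) > _SYMMETRY_TOL:
        raise ValueError("coupling matrix is not symmetric within 1e-12")

    v = 0.5 * (couplings + couplings.T)
    chrom = np.array([a for a, _ in labels])
    same_site = chrom[:, None] == chrom[None, :]
    v[same_site] = 0.0

    if ledger is not None:
        e_gs = ground_state_energy(ledger, len(site_results))
    else:
        e_gs = sum(
            r.energy for results in site_results for r in results if r.state_index == 0
        )
    return ExcitonHamiltonian(
        ground_energy=float(e_gs),
        site_energies=np.array(site_e),
        couplings=v,
        basis_labels=labels,
    )


def adiabatize(h: ExcitonHamiltonian) -> AdiabaticSet:
    """Diagonalize the excitonic block of the Hamiltonian.

    The ground state is an eigenstate by construction and passes
    through unchanged.  Eigenvalues are returned in ascending order
    within the excitonic block; each eigenvector's sign is fixed so its
    largest-magnitude component is positive, which makes the dominant
    label assignment reproducible.
    """
    evals, evecs = np.linalg.eigh(h.excitonic_block())
    for k in range(evecs.shape[1]):
        imax = int(np.argmax(np.abs(evecs[:, k])))
        if evecs[imax, k] < 0:
            evecs[:, k] = -evecs[:, k]
    label_map = {}
    for k in range(evecs.shape[1]):
        # ties broken by the lowest basis index (argmax picks the first)
        label_map[k + 1] = h.basis_labels[int(np.argmax(np.abs(evecs[:, k])))]
    return AdiabaticSet(
        energies=np.concatenate(([h.ground_energy], evals)),
        coefficients=evecs,
        basis_labels=list(h.basis_labels),
        label_map=label_map,
    )


def adiabatic_gradient(k: int, aset: AdiabaticSet, grads: GradientSet) -> np.ndarray:
    """Gradient of adiabatic energy ``E_K`` with frozen coefficients.

    The expansion coefficients are variationally optimal, so their
    derivatives give a null (Hellmann-Feynman) contribution:

        grad E_K = grad E_gs + sum_ai C_ai,K^2 grad dE_ai
                   + sum_{ai != bj} C_ai,K C_bj,K grad V_ai,bj

    Parameters
    ----------
    k : int
        Adiabatic index, 1-based over the excitonic adiabats; the
        ground state (k = 0) is not handled here — its gradient is
        ``grads.grad_ground`` directly.
    """
    n = aset.coefficients.shape[0]
    if not 1 <= k <= n:
        raise IndexError(f"adiabatic index {k} out of range 1..{n}")
    c = aset.coefficients[:, k - 1]
    g = grads.grad_ground.copy()
    g += np.einsum("i,id->d", c**2, grads.grad_site)
    # diagonal and intra-site coupling gradients are identically zero,
    # so summing over all pairs is safe
    g += np.einsum("i,j,ijd->d", c, c, grads.grad_coupling) - np.einsum(
        "i,iid->d", c**2, grads.grad_coupling
    )
    return g
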