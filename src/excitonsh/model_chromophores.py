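"""Analytic model chromophores: the synthetic electronic-structure backend.

Each chromophore is a one-dimensional torsional unit patterned on
azobenzene-like photoisomerization: a single dihedral-like angle theta
with a double-well ground-state surface (minima at theta = 0, cis-like,
and theta = pi, trans-like) and excited surfaces with their minimum at
the perpendicular geometry theta = pi/2, where the isomerization funnel
sits.  The default surfaces are

    E_0(theta) = (W/2) (1 - cos 2 theta) + (D_cis/2) (1 + cos theta)
    E_i(theta) = A_i - (D_i/2) (1 - cos 2 theta)

with W = 0.06, D_cis = 0.02, A_1 = 0.10, D_1 = 0.05 hartree.  Every
backend quantity — energies, gradients, interstate overlaps between
successive geometries, transition dipoles and transition charges — is
analytic, so finite-difference and composition checks hold to machine
precision and no quantum-chemistry package is needed anywhere.

A dimer of such units reproduces the phenomenology of a bichromophoric
photoswitch: a weakly coupled ("n-pi*-like", dark) exciton manifold and
a strongly coupled ("pi-pi*-like", bright) manifold coexist at the
stacked reference geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import couplings as cpl
from .exciton_core import (
    ExcitonHamiltonian,
    GradientSet,
    SiteStateResult,
    assemble_hamiltonian,
)
from .units import ANGSTROM_TO_BOHR

__all__ = [
    "ExcitedStateParams",
    "TorsionalSite",
    "DimerSystem",
    "LinearCrossingSystem",
    "make_default_dimer",
    "make_trivial_crossing_system",
]


@dataclass(frozen=True)
class ExcitedStateParams:
    """Parameters of one excited surface of a torsional site.

    vertical : float
        Vertical excitation energy A_i at the ground minima, hartree.
    well_depth : float
        Depth D_i of the funnel well at theta = pi/2, hartree.
    bright : bool
        Strongly coupled (pi-pi*-like) manifolds carry the full
        torsion-dependent transition charge; weakly coupled
        (n-pi*-like) manifolds carry a small constant fraction of it.
    """

    vertical: float
    well_depth: float
    bright: bool


@dataclass
class TorsionalSite:
    """One azobenzene-like torsional chromophore.

    The double-well ground curve and the funnel-shaped excited curves
    quoted in the class notes are *diabatic* reference curves: they
    retain their electronic character and cross near the funnel.  The
    states the site actually exports — the monomer adiabats that enter
    the excitonic basis — come from coupling each adjacent diabat pair
    (i-1, i) by a seam-localized interaction

        v_i(theta) = V_i exp(-dD_i(theta)^2 / (2 (3 V_i)^2)),
        V_i = (c / 2) |d(dD_i)/dtheta| at the seam,

    where ``dD_i`` is the diabatic gap and ``c`` (``funnel_softness``,
    radians) sets the angular width of the resulting avoided crossing.
    Energies are the smooth two-level branch functions composed along
    the chain, gradients their exact derivatives, and the interstate
    overlaps come from the same model's mixing angles
    ``alpha_i = 0.5 atan2(2 v_i, dD_i)`` through an orthogonal
    character frame ``U(theta)``; the overlap block is
    ``S = U(theta_t)^T U(theta_next)``, so overlaps compose exactly.
    Because energies, gradients and overlaps all derive from one
    analytic model, the adiabatic surfaces are smooth (no trivial
    crossings within a site) and the character swap happens exactly at
    the seam, where the local-diabatization dynamics transfers
    amplitude.

    The transition density of each state is represented by a pair of
    opposite charges +/- q at the two ends of a rigid arm of length
    ``arm_length`` through the site center, so every transition is
    charge-neutral by construction.  The charge magnitude is
    ``q0 |sin(theta/2)|`` for bright manifolds — maximal at the
    trans-like geometry and vanishing at the cis-like one — and the
    constant ``q0 * dark_scale`` for dark manifolds.
    """

    site_id: int = 0
    barrier: float = 0.06  # W, hartree
    cis_offset: float = 0.02  # D_cis, hartree
    excited: tuple[ExcitedStateParams, ...] = (
        ExcitedStateParams(vertical=0.10, well_depth=0.05, bright=False),
        ExcitedStateParams(vertical=0.16, well_depth=0.04, bright=True),
    )
    inertia: float = 1.0e5  # reduced torsional inertia, m_e * bohr^2 (CNNC-like scale)
    q0: float = 0.46  # transition charge magnitude, e
    dark_scale: float = 0.05
    arm_length: float = 5.0  # bohr
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    funnel_softness: float = 0.05  # c in alpha_i(theta), radians
    freeze_charges_at: float | None = None  # evaluate q(theta) at a fixed angle

    def __post_init__(self):
        self.center = np.asarray(self.center, float)
        self.axis = np.asarray(self.axis, float)
        self.axis = self.axis / np.linalg.norm(self.axis)

    @property
    def n_excited(self) -> int:
        return len(self.excited)

    # -- diabatic reference curves ------------------------------------

    def diabatic_energy(self, i: int, theta: float) -> float:
        """Character-retaining reference curve of state i, hartree."""
        if i == 0:
            return 0.5 * self.barrier * (1.0 - np.cos(2.0 * theta)) + (
                0.5 * self.cis_offset * (1.0 + np.cos(theta))
            )
        p = self.excited[i - 1]
        return p.vertical - 0.5 * p.well_depth * (1.0 - np.cos(2.0 * theta))

    def diabatic_gradient(self, i: int, theta: float) -> float:
        if i == 0:
            return self.barrier * np.sin(2.0 * theta) - 0.5 * self.cis_offset * np.sin(
                theta
            )
        return -self.excited[i - 1].well_depth * np.sin(2.0 * theta)

    # -- seam couplings and adiabatic surfaces ------------------------

    def seam_amplitude(self, k: int) -> float:
        """Peak interaction V_k of the diabat pair (k-1, k).

        ``V_k = (c/2) |d(dD_k)/dtheta|`` at the trans-side seam, which
        makes the angular width of the avoided crossing equal to the
        funnel softness c.  Zero when the pair never crosses.
        """
        tx = self.crossing_angle(k)
        if tx is None:
            return 0.0
        dslope = self.diabatic_gradient(k, tx) - self.diabatic_gradient(k - 1, tx)
        return 0.5 * self.funnel_softness * abs(dslope)

    def _pair_gap_coupling(self, k: int, theta: float) -> tuple[float, float]:
        """Diabatic gap dD_k and seam-localized coupling v_k at theta."""
        dd = self.diabatic_energy(k, theta) - self.diabatic_energy(k - 1, theta)
        v_peak = self.seam_amplitude(k)
        if v_peak == 0.0:
            return dd, 0.0
        sig = 3.0 * v_peak
        return dd, v_peak * np.exp(-dd * dd / (2.0 * sig * sig))

    def _pair_branches(self, k: int, theta: float) -> tuple[float, float]:
        """Lower and upper adiabatic branch of the diabat pair (k-1, k)."""
        dd, v = self._pair_gap_coupling(k, theta)
        mean = 0.5 * (
            self.diabatic_energy(k - 1, theta) + self.diabatic_energy(k, theta)
        )
        half = 0.5 * np.sqrt(dd * dd + 4.0 * v * v)
        return mean - half, mean + half

    def site_energies(self, theta: float) -> np.ndarray:
        """Monomer adiabatic energies [E_0, ..., E_n] at theta, hartree.

        Smooth chain composition of the pairwise branch functions: the
        bottom state is the lower branch of pair (0, 1), the top state
        the upper branch of the last pair, and each middle state k
        combines the upper branch of pair (k-1, k) with the lower
        branch of pair (k, k+1).  Away from the seams (where the
        couplings vanish) these reduce exactly to the diabatic curves.
        """
        n = self.n_excited
        e = np.empty(n + 1)
        lo1, _ = self._pair_branches(1, theta)
        e[0] = lo1
        for k in range(1, n):
            _, up_k = self._pair_branches(k, theta)
            lo_next, _ = self._pair_branches(k + 1, theta)
            e[k] = up_k + lo_next - self.diabatic_energy(k, theta)
        _, up_n = self._pair_branches(n, theta)
        e[n] = up_n
        return e

    def ground_energy(self, theta: float) -> float:
        return self.site_energies(theta)[0]

    def excited_energy(self, i: int, theta: float) -> float:
        return self.site_energies(theta)[i]

    def _pair_branch_gradients(self, k: int, theta: float) -> tuple[float, float]:
        """d/dtheta of the lower and upper branch of pair (k-1, k)."""
        dd, v = self._pair_gap_coupling(k, theta)
        g_lo = self.diabatic_gradient(k - 1, theta)
        g_hi = self.diabatic_gradient(k, theta)
        ddp = g_hi - g_lo
        mean_p = 0.5 * (g_lo + g_hi)
        s = np.sqrt(dd * dd + 4.0 * v * v)
        if s < 1e-300:
            half_p = 0.0
        else:
            v_peak = self.seam_amplitude(k)
            vp = 0.0 if v_peak == 0.0 else v * (-dd * ddp) / (3.0 * v_peak) ** 2
            half_p = 0.5 * (dd * ddp + 4.0 * v * vp) / s
        return mean_p - half_p, mean_p + half_p

    def site_gradient(self, theta: float, state: int) -> float:
        """Analytic dE_state/dtheta of the adiabatic energies, hartree/rad."""
        n = self.n_excited
        if state == 0:
            return self._pair_branch_gradients(1, theta)[0]
        if state == n:
            return self._pair_branch_gradients(n, theta)[1]
        _, up_p = self._pair_branch_gradients(state, theta)
        lo_p, _ = self._pair_branch_gradients(state + 1, theta)
        return up_p + lo_p - self.diabatic_gradient(state, theta)

    # -- overlaps ------------------------------------------------------

    def crossing_angle(self, i: int) -> float | None:
        """Trans-side angle where surfaces i-1 and i cross, if they do.

        For i = 1 (ground/first-excited) the condition is a quadratic
        in cos(theta); for i >= 2 the two funnel surfaces cross where
        ``1 - cos 2 theta = 2 (A_i - A_{i-1}) / (D_i - D_{i-1})``.
        Returns the crossing with theta > pi/2 (the one reached first
        coming from the trans well), or ``None`` if the surfaces never
        cross.
        """
        if i == 1:
            w, dc, p = self.barrier, self.cis_offset, self.excited[0]
            # (W + D)(1 - u^2) + (dc/2)(1 + u) - A = 0 with u = cos(theta)
            a2 = -(w + p.well_depth)
            a1 = 0.5 * dc
            a0 = w + p.well_depth + 0.5 * dc - p.vertical
            disc = a1**2 - 4.0 * a2 * a0
            if disc < 0:
                return None
            roots = [(-a1 + s * np.sqrt(disc)) / (2.0 * a2) for s in (+1.0, -1.0)]
            us = [u for u in roots if -1.0 <= u <= 1.0]
            if not us:
                return None
            # theta > pi/2 means cos(theta) < 0; prefer that branch
            neg = [u for u in us if u < 0]
            return float(np.arccos(max(neg) if neg else min(us)))
        lo, hi = self.excited[i - 2], self.excited[i - 1]
        dd = hi.well_depth - lo.well_depth
        if dd == 0.0:
            return None
        val = 2.0 * (hi.vertical - lo.vertical) / dd
        if not 0.0 <= val <= 2.0:
            return None
        two_theta = np.arccos(1.0 - val)
        return float(np.pi - 0.5 * two_theta)  # trans-side solution

    def mixing_angle(self, theta: float, plane: int = 1) -> float:
        """Character-exchange angle of the (plane-1, plane) state pair.

        The two-level mixing angle ``0.5 atan2(2 v, dD)`` of the same
        gap/coupling model that defines the adiabatic energies: 0 where
        the diabats are normally ordered, pi/2 where they are inverted,
        sweeping through pi/4 at each seam over an angular width of
        about the funnel softness.
        """
        dd, v = self._pair_gap_coupling(plane, theta)
        if v == 0.0 and dd >= 0.0:
            return 0.0
        return 0.5 * np.arctan2(2.0 * v, dd)

    def frame(self, theta: float) -> np.ndarray:
        """Orthogonal character frame U(theta) over ground + excited states."""
        n = self.n_excited + 1
        u = np.eye(n)
        for plane in range(1, n):
            a = self.mixing_angle(theta, plane)
            rot = np.eye(n)
            c, s = np.cos(a), np.sin(a)
            rot[plane - 1, plane - 1] = c
            rot[plane, plane] = c
            rot[plane - 1, plane] = s
            rot[plane, plane - 1] = -s
            u = u @ rot
        return u

    def site_overlap(self, theta_t: float, theta_next: float) -> np.ndarray:
        """Overlap block ``S_ij = <phi_i(theta_t)|phi_j(theta_next)>``.

        ``S = U(theta_t)^T U(theta_next)``: exactly orthogonal, identity
        for equal angles, and exactly composing,
        S(t1->t2) S(t2->t3) = S(t1->t3).  For a site with a single
        excited state this reduces to a rotation by
        ``alpha(theta_next) - alpha(theta_t)`` in the (ground, excited)
        plane.
        """
        return self.frame(theta_t).T @ self.frame(theta_next)

    # -- transition properties ----------------------------------------

    def _charge_magnitude(self, theta: float, state: int) -> float:
        p = self.excited[state - 1]
        if not p.bright:
            return self.q0 * self.dark_scale
        th = theta if self.freeze_charges_at is None else self.freeze_charges_at
        return self.q0 * abs(np.sin(0.5 * th))

    def _charge_magnitude_deriv(self, theta: float, state: int) -> float:
        p = self.excited[state - 1]
        if not p.bright or self.freeze_charges_at is not None:
            return 0.0
        s = np.sin(0.5 * theta)
        return 0.5 * self.q0 * np.cos(0.5 * theta) * np.sign(s) if s != 0.0 else 0.0

    def end_positions(self) -> np.ndarray:
        half = 0.5 * self.arm_length * self.axis
        return np.array([self.center + half, self.center - half])

    def transition_charges(self, theta: float, state: int) -> cpl.TransitionChargeSet:
        """Two-point +/- q(theta) transition charges at the arm ends."""
        q = self._charge_magnitude(theta, state)
        return cpl.TransitionChargeSet(
            atom_positions=self.end_positions(),
            charges=np.array([q, -q]),
            chromophore_id=self.site_id,
            state_pair=(0, state),
        )

    def transition_cloud(
        self, theta: float, state: int, width: float = 1.0
    ) -> cpl.TransitionDensityCloud:
        """Gaussian-cloud representation of the same transition density."""
        q = self._charge_magnitude(theta, state)
        return cpl.TransitionDensityCloud(
            centers=self.end_positions(),
            widths=np.array([width, width]),
            weights=np.array([q, -q]),
            chromophore_id=self.site_id,
            state_pair=(0, state),
        )

    def transition_dipole(self, theta: float, state: int) -> np.ndarray:
        """Transition dipole mu_0i = q(theta) * arm vector, au."""
        q = self._charge_magnitude(theta, state)
        return q * self.arm_length * self.axis


class DimerSystem:
    """A rigid stack of torsional chromophores with excitonic couplings.

    Site ``k`` is centered at ``k * stack_distance`` along z with its
    arm along x, so all transition dipoles are parallel and
    perpendicular to the stack axis (an H-aggregate: the symmetric,
    bright combination lies above the antisymmetric, dark one).  The
    nuclear coordinate vector is the concatenation of the site torsions
    in declared order; the inter-site geometry is frozen.

    Because the charge positions are geometry-independent and only the
    charge magnitudes depend on the torsions, every coupling factorizes
    as ``V_ai,bj = q_ai(theta_a) q_bj(theta_b) G_ab`` with a fixed
    geometric kernel ``G_ab`` per scheme (EC, TC or point-dipole),
    which is precomputed once.

    Parameters
    ----------
    sites : sequence of TorsionalSite
    stack_distance : float
        Inter-site spacing, angstrom (converted internally to bohr).
    scheme : str
        "TC", "EC" or "dipole".
    cloud_width : float
        Gaussian width (bohr) used by the EC scheme.
    gradient_mode : str
        "full" differentiates the couplings exactly, including the
        torsion dependence of the transition charges (default: keeps
        the dynamics exactly energy-conserving on this analytic
        backend); "static" freezes the charges, mirroring the
        approximation used with fitted charges in production codes.
    """

    def __init__(
        self,
        sites: Sequence[TorsionalSite],
        stack_distance: float = 6.0,
        scheme: str = "TC",
        cloud_width: float = 1.0,
        gradient_mode: str = "full",
    ):
        if scheme not in ("TC", "EC", "dipole"):
            raise ValueError(f"unknown coupling scheme {scheme!r}")
        if gradient_mode not in ("full", "static"):
            raise ValueError(f"unknown gradient mode {gradient_mode!r}")
        self.sites = list(sites)
        self.stack_distance = stack_distance * ANGSTROM_TO_BOHR
        self.scheme = scheme
        self.cloud_width = cloud_width
        self.gradient_mode = gradient_mode
        for k, site in enumerate(self.sites):
            site.site_id = k
            site.center = np.array([0.0, 0.0, k * self.stack_distance])
        self.basis_labels = [
            (a, i)
            for a, site in enumerate(self.sites)
            for i in range(1, site.n_excited + 1)
        ]
        self._kernel = self._geometric_kernels()

    # -- system protocol ----------------------------------------------

    @property
    def n_coords(self) -> int:
        return len(self.sites)

    @property
    def masses(self) -> np.ndarray:
        return np.array([s.inertia for s in self.sites])

    def _geometric_kernels(self) -> dict[tuple[int, int], float]:
        """Coupling of unit +/- 1 charge pairs for every site pair."""
        kern = {}
        for a in range(len(self.sites)):
            for b in range(a + 1, len(self.sites)):
                sa, sb = self.sites[a], self.sites[b]
                if self.scheme == "TC":
                    ua = cpl.TransitionChargeSet(
                        sa.end_positions(), np.array([1.0, -1.0]), chromophore_id=a
                    )
                    ub = cpl.TransitionChargeSet(
                        sb.end_positions(), np.array([1.0, -1.0]), chromophore_id=b
                    )
                    g = cpl.tc_coupling(ua, ub)
                elif self.scheme == "EC":
                    ua = cpl.TransitionDensityCloud(
                        sa.end_positions(),
                        np.full(2, self.cloud_width),
                        np.array([1.0, -1.0]),
                        chromophore_id=a,
                    )
                    ub = cpl.TransitionDensityCloud(
                        sb.end_positions(),
                        np.full(2, self.cloud_width),
                        np.array([1.0, -1.0]),
                        chromophore_id=b,
                    )
                    g = cpl.exact_coulomb(ua, ub)
                else:  # point-dipole
                    mu_a = sa.arm_length * sa.axis
                    mu_b = sb.arm_length * sb.axis
                    g = cpl.dipole_coupling(mu_a, mu_b, sb.center - sa.center)
                kern[(a, b)] = g
                kern[(b, a)] = g
        return kern

    def _charges(self, x: np.ndarray) -> np.ndarray:
        return np.array(
            [self.sites[a]._charge_magnitude(x[a], i) for a, i in self.basis_labels]
        )

    def hamiltonian(self, x: np.ndarray) -> ExcitonHamiltonian:
        """Excitonic Hamiltonian at torsion angles ``x``."""
        x = np.asarray(x, float)
        site_results = []
        for a, site in enumerate(self.sites):
            energies = site.site_energies(x[a])
            block = [
                SiteStateResult(
                    chromophore_id=a,
                    state_index=i,
                    energy=energies[i],
                    gradient=np.array([site.site_gradient(x[a], i)]),
                    transition_dipole=(
                        np.zeros(3) if i == 0 else site.transition_dipole(x[a], i)
                    ),
                )
                for i in range(site.n_excited + 1)
            ]
            site_results.append(block)
        q = self._charges(x)
        n = len(self.basis_labels)
        v = np.zeros((n, n))
        for p in range(n):
            a, _ = self.basis_labels[p]
            for r in range(p + 1, n):
                b, _ = self.basis_labels[r]
                if a == b:
                    continue
                v[p, r] = v[r, p] = q[p] * q[r] * self._kernel[(a, b)]
        return assemble_hamiltonian(site_results, v)

    def gradients(self, x: np.ndarray) -> GradientSet:
        """Gradients of E_gs, site energies and couplings w.r.t. all torsions."""
        x = np.asarray(x, float)
        d = self.n_coords
        n = len(self.basis_labels)
        gg = np.array([s.site_gradient(x[a], 0) for a, s in enumerate(self.sites)])
        gs = np.zeros((n, d))
        for p, (a, i) in enumerate(self.basis_labels):
            # site energy dE_ai = E_i - E_0 depends only on theta_a
            gs[p, a] = self.sites[a].site_gradient(x[a], i) - self.sites[
                a
            ].site_gradient(x[a], 0)
        gv = np.zeros((n, n, d))
        if self.gradient_mode == "full":
            q = self._charges(x)
            dq = np.array(
                [
                    self.sites[a]._charge_magnitude_deriv(x[a], i)
                    for a, i in self.basis_labels
                ]
            )
            for p in range(n):
                a, _ = self.basis_labels[p]
                for r in range(n):
                    b, _ = self.basis_labels[r]
                    if a == b or p == r:
                        continue
                    g = self._kernel[(a, b)]
                    gv[p, r, a] = dq[p] * q[r] * g
                    gv[p, r, b] += q[p] * dq[r] * g
        # static mode: charge positions are rigid, so grad V vanishes
        return GradientSet(grad_ground=gg, grad_site=gs, grad_coupling=gv)

    def ground_gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return np.array([s.site_gradient(x[a], 0) for a, s in enumerate(self.sites)])

    def site_overlaps(self, x_t: np.ndarray, x_next: np.ndarray) -> list[np.ndarray]:
        return [
            site.site_overlap(x_t[a], x_next[a]) for a, site in enumerate(self.sites)
        ]

    def transition_dipoles(self, x: np.ndarray) -> np.ndarray:
        """(n_basis, 3) transition dipoles of the excitonic basis states."""
        return np.array(
            [self.sites[a].transition_dipole(x[a], i) for a, i in self.basis_labels]
        )


class LinearCrossingSystem:
    """Two one-exciton sites whose site energies cross linearly.

    A minimal system for trivial-crossing and Landau-Zener tests: one
    shared nuclear coordinate x, site energies ``e0 +/- slope * x``, a
    constant coupling V and a flat ground surface.  Site overlaps are
    identity blocks (the localized states never change character), so
    the diabatic states are exactly the excitonic basis states.
    """

    def __init__(
        self,
        coupling: float,
        slope: float,
        e0: float = 0.1,
        mass: float = 2000.0,
    ):
        if coupling < 0:
            raise ValueError("coupling must be >= 0")
        self.coupling = coupling
        self.slope = slope
        self.e0 = e0
        self.mass = mass
        self.basis_labels = [(0, 1), (1, 1)]

    @property
    def n_coords(self) -> int:
        return 1

    @property
    def masses(self) -> np.ndarray:
        return np.array([self.mass])

    def hamiltonian(self, x: np.ndarray) -> ExcitonHamiltonian:
        xv = float(np.asarray(x, float).ravel()[0])
        site_results = []
        for a, sign in enumerate((+1.0, -1.0)):
            site_results.append(
                [
                    SiteStateResult(a, 0, 0.0, np.zeros(1)),
                    SiteStateResult(
                        a,
                        1,
                        self.e0 + sign * self.slope * xv,
                        np.array([sign * self.slope]),
                        transition_dipole=np.array([1.0, 0.0, 0.0]),
                    ),
                ]
            )
        v = np.array([[0.0, self.coupling], [self.coupling, 0.0]])
        return assemble_hamiltonian(site_results, v)

    def gradients(self, x: np.ndarray) -> GradientSet:
        gs = np.array([[self.slope], [-self.slope]])
        return GradientSet(
            grad_ground=np.zeros(1),
            grad_site=gs,
            grad_coupling=np.zeros((2, 2, 1)),
        )

    def ground_gradient(self, x: np.ndarray) -> np.ndarray:
        return np.zeros(1)

    def site_overlaps(self, x_t, x_next) -> list[np.ndarray]:
        return [np.eye(2), np.eye(2)]

    def transition_dipoles(self, x: np.ndarray) -> np.ndarray:
        return np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])


def make_default_dimer(
    scheme: str = "TC",
    stack_distance: float = 6.0,
    asymmetry: float = 0.0,
    gradient_mode: str = "full",
) -> DimerSystem:
    """The reference bichromophoric system.

    Two identical torsional sites stacked ``stack_distance`` angstrom
    apart.  ``asymmetry`` shifts the vertical energies of the second
    site by the given amount (hartree) to break the homodimer symmetry.
    At the trans-like reference geometry the bright (pi-pi*-like)
    manifold couples by tens of meV and the dark (n-pi*-like) manifold
    by well under 5 meV.
    """
    site_a = TorsionalSite(site_id=0)
    excited_b = tuple(
        ExcitedStateParams(p.vertical + asymmetry, p.well_depth, p.bright)
        for p in site_a.excited
    )
    site_b = TorsionalSite(site_id=1, excited=excited_b)
    return DimerSystem(
        [site_a, site_b],
        stack_distance=stack_distance,
        scheme=scheme,
        gradient_mode=gradient_mode,
    )


def make_trivial_crossing_system(
    coupling: float, slope: float = 0.01, **kwargs
) -> LinearCrossingSystem:
    """Two one-exciton sites with linearly crossing site energies.

    With ``coupling = 0`` the diabats cross exactly; any ``V > 0``
    opens an avoided crossing with minimum adiabatic gap ``2 V``.
    """
    return LinearCrossingSystem(coupling=coupling, slope=slope, **kwargs)
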