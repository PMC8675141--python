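"""Fewest-switches surface hopping with local diabatization.

Nuclei move classically on one adiabatic surface of the excitonic
Hamiltonian (velocity Verlet); the electronic amplitudes are propagated
in the locally diabatic representation: at each step the overlap matrix
``S_KL = <K(t)|L(t+dt)>`` between successive adiabatic states is
assembled from single-chromophore overlaps, symmetrically
(Loewdin-)orthogonalized into the closest orthogonal matrix T, and the
amplitudes advanced as ``c(t+dt) = T^T exp(-i Ebar dt) c(t)``.  Because
T is exactly orthogonal the electronic norm is conserved to machine
precision, and because the propagation follows the overlaps rather than
nonadiabatic coupling vectors, trivial (unavoided) crossings between
essentially uncoupled states are handled without any special care: the
amplitudes simply follow the diabatic character.

Hops are drawn from the fewest-switches prescription realized as
population-flux apportionment; after an accepted hop all velocities are
rescaled by a common factor to conserve total energy (no nonadiabatic
coupling direction exists in this scheme), and energetically forbidden
hops are frustrated, leaving the velocities unchanged.  Decoherence is
imposed by an overlap-based correction (ODC): each non-active amplitude
is damped by the overlap of frozen Gaussians following the respective
surfaces and collapsed to zero once that overlap falls below a
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exciton_core import AdiabaticSet, GradientSet, adiabatic_gradient, adiabatize
from .units import FS_TO_AU, KB_HARTREE, HARTREE_TO_EV

__all__ = [
    "SHConfig",
    "HopEvent",
    "TrajectoryState",
    "InitialCondition",
    "TrajectoryResult",
    "EnsembleResult",
    "excitonic_overlap",
    "assemble_overlap_matrix",
    "lowdin_orthogonalize",
    "ld_propagate",
    "hop_probabilities",
    "attempt_hop",
    "rescale_after_hop",
    "ODCTracker",
    "sample_initial_conditions",
    "thermalize_andersen",
    "thermalize_rescale",
    "run_trajectory",
    "run_ensemble",
]


@dataclass
class SHConfig:
    """Surface-hopping run parameters.

    dt_fs : nuclear and electronic time step (one LD step per nuclear
        step), fs.
    odc_sigma : frozen-Gaussian width of the decoherence correction,
        in coordinate units (au).
    odc_smin : minimum wavepacket overlap below which a non-active
        amplitude is collapsed to zero.
    ground_stop_fs : a trajectory stops after running on the ground
        state for at least this long.
    excitation_window : (low, high) vertical excitation window in eV
        used by initial-condition sampling.
    energy_tol : total-energy drift between hops above which the
        trajectory is flagged (and excluded from ensembles), hartree.
    """

    dt_fs: float = 0.1
    max_time_fs: float = 1000.0
    odc_sigma: float = 1.0
    odc_smin: float = 0.005
    ground_stop_fs: float = 100.0
    excitation_window: tuple[float, float] | None = None
    seed: int = 0
    energy_tol: float = 1e-4
    decoherence: bool = True

    def __post_init__(self):
        if self.dt_fs <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 < self.odc_smin < 1.0:
            raise ValueError("odc_smin must lie in (0, 1)")


@dataclass
class HopEvent:
    time_fs: float
    from_state: int
    to_state: int
    kinetic_adjustment: float  # hartree added to the kinetic energy
    frustrated: bool = False


@dataclass
class TrajectoryState:
    """Full dynamical state of one trajectory at one instant."""

    coordinates: np.ndarray
    velocities: np.ndarray
    time_fs: float
    active_state: int
    amplitudes: np.ndarray  # complex, over ground + excitonic adiabats
    adiabatic: AdiabaticSet
    rng_state: object | None = None

    def check(self) -> None:
        norm = float(np.sum(np.abs(self.amplitudes) ** 2))
        if abs(norm - 1.0) > 1e-10:
            raise ValueError(f"electronic norm {norm} deviates from 1")
        if not 0 <= self.active_state < len(self.amplitudes):
            raise ValueError("active state out of range")


@dataclass
class InitialCondition:
    coordinates: np.ndarray
    velocities: np.ndarray
    state: int  # adiabatic index, 0 = ground


# ---------------------------------------------------------------------
# overlap machinery
# ---------------------------------------------------------------------


def excitonic_overlap(site_blocks: Sequence[np.ndarray]) -> np.ndarray:
    """Overlap matrix in the excitonic basis from per-chromophore blocks.

    ``site_blocks[a][i, j]`` holds the single-chromophore overlaps
    ``S_ij^(a) = <phi_i^(a)(t)|phi_j^(a)(t+dt)>`` including the ground
    row/column.  Because the monomer orbitals of different chromophores
    are orthogonal, the overlap of two excitonic product states
    factorizes into one non-ground factor per involved chromophore
    times ``S_00^(c)`` for every uninvolved chromophore:

        <ai|bj'> = S_i0^(a) S_0j^(b) prod_{c != a,b} S_00^(c)   (a != b)
        <ai|aj'> = S_ij^(a) prod_{c != a} S_00^(c)
        <gs|bj'> = S_0j^(b) prod_{c != b} S_00^(c)
        <gs|gs'> = prod_c S_00^(c)

    Returns the (n+1) x (n+1) matrix with the ground state first.
    """
    n_sites = len(site_blocks)
    dims = [b.shape[0] - 1 for b in site_blocks]
    for a, b in enumerate(site_blocks):
        if b.ndim != 2 or b.shape[0] != b.shape[1]:
            raise ValueError(f"site block {a} is not square")
    labels = [(a, i) for a in range(n_sites) for i in range(1, dims[a] + 1)]
    s00 = np.array([b[0, 0] for b in site_blocks])

    def prod_except(*exclude: int) -> float:
        out = 1.0
        for c in range(n_sites):
            if c not in exclude:
                out *= s00[c]
        return out

    n = len(labels)
    sig = np.zeros((n + 1, n + 1))
    sig[0, 0] = prod_except()
    for col, (b, j) in enumerate(labels, start=1):
        sig[0, col] = site_blocks[b][0, j] * prod_except(b)
    for row, (a, i) in enumerate(labels, start=1):
        sig[row, 0] = site_blocks[a][i, 0] * prod_except(a)
        for col, (b, j) in enumerate(labels, start=1):
            if a == b:
                sig[row, col] = site_blocks[a][i, j] * prod_except(a)
            else:
                sig[row, col] = (
                    site_blocks[a][i, 0] * site_blocks[b][0, j] * prod_except(a, b)
                )
    return sig


def assemble_overlap_matrix(
    site_overlaps: Sequence[np.ndarray],
    c_t: AdiabaticSet | np.ndarray,
    c_next: AdiabaticSet | np.ndarray,
) -> np.ndarray:
    """Adiabatic-basis overlap ``S_KL = <K(t)|L(t+dt)>``.

    The excitonic-basis overlaps are transformed by the coefficient
    matrix of time t on the bra side and of time t+dt on the ket side;
    the ground row/column is included (the ground state participates in
    the transformation trivially).
    """
    sig = excitonic_overlap(site_overlaps)
    ct = c_t.full_coefficients() if isinstance(c_t, AdiabaticSet) else np.asarray(c_t)
    cn = (
        c_next.full_coefficients()
        if isinstance(c_next, AdiabaticSet)
        else np.asarray(c_next)
    )
    if ct.shape != sig.shape or cn.shape != sig.shape:
        raise ValueError("coefficient matrices inconsistent with overlap dimension")
    return ct.T @ sig @ cn


def lowdin_orthogonalize(s: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Closest orthogonal matrix to S in the Frobenius norm.

    ``T = S (S^T S)^(-1/2)``, computed via the SVD ``S = U Sig V^T`` as
    ``T = U V^T``.  A singular value below ``tol`` signals a
    numerically rank-deficient overlap (states appearing/disappearing
    from the propagated space) and aborts the trajectory.
    """
    s = np.asarray(s, float)
    u, sv, vt = np.linalg.svd(s)
    if sv.min() < tol:
        raise RuntimeError(
            f"overlap matrix numerically rank deficient (min singular value "
            f"{sv.min():.2e}); aborting trajectory"
        )
    return u @ vt


def ld_propagate(
    c_t: np.ndarray,
    e_t: np.ndarray,
    e_next: np.ndarray,
    t_mat: np.ndarray,
    dt_au: float,
) -> np.ndarray:
    """One local-diabatization step of the electronic amplitudes.

    ``c(t+dt) = T^T diag(exp(-i Ebar_K dt)) c(t)`` with
    ``Ebar = (E(t) + E(t+dt)) / 2``.  Exactly norm-preserving for
    orthogonal T.
    """
    ebar = 0.5 * (np.asarray(e_t, float) + np.asarray(e_next, float))
    return t_mat.T @ (np.exp(-1j * ebar * dt_au) * np.asarray(c_t, complex))


# ---------------------------------------------------------------------
# hopping
# ---------------------------------------------------------------------


def hop_probabilities(
    c_t: np.ndarray, c_next: np.ndarray, t_mat: np.ndarray, active: int
) -> np.ndarray:
    """Fewest-switches probabilities via population-flux apportionment.

    The total hop probability out of the active state K equals its
    fractional population loss over the step (zero if the population
    did not decrease) and is shared among the other states in
    proportion to their population gain.  Returns a vector over all
    states with ``P[K] = 0``.
    """
    p_t = np.abs(np.asarray(c_t)) ** 2
    p_n = np.abs(np.asarray(c_next)) ** 2
    probs = np.zeros(len(p_t))
    loss = p_t[active] - p_n[active]
    if loss <= 0.0 or p_t[active] <= 0.0:
        return probs
    total = loss / p_t[active]
    gains = np.clip(p_n - p_t, 0.0, None)
    gains[active] = 0.0
    gsum = gains.sum()
    if gsum <= 0.0:
        return probs
    probs = total * gains / gsum
    probs[active] = 0.0
    return probs


def attempt_hop(probs: np.ndarray, rng: np.random.Generator) -> int | None:
    """Cumulative-interval selection against one uniform draw."""
    draw = rng.random()
    cum = 0.0
    for state in range(len(probs)):
        cum += probs[state]
        if draw < cum:
            return state
    return None


def rescale_after_hop(
    velocities: np.ndarray,
    masses: np.ndarray,
    e_old: float,
    e_new: float,
) -> np.ndarray | None:
    """Uniformly rescale velocities to conserve total energy.

    Returns the rescaled velocities, or ``None`` if the required
    kinetic energy is unavailable (frustrated hop: velocities must be
    left unchanged by the caller).
    """
    ke = 0.5 * float(np.sum(masses * velocities**2))
    ke_new = ke + (e_old - e_new)
    if ke_new < 0.0 or (ke == 0.0 and ke_new != ke):
        return None
    if ke == 0.0:
        return velocities.copy()
    return velocities * np.sqrt(ke_new / ke)


# ---------------------------------------------------------------------
# decoherence (ODC)
# ---------------------------------------------------------------------


class ODCTracker:
    """Overlap-based decoherence correction bookkeeping.

    For every non-active state carrying amplitude, an auxiliary frozen
    Gaussian (width sigma per nuclear coordinate) is propagated
    classically on that state's surface, starting from the geometry at
    which the state last acquired amplitude (or the last hop).  The
    amplitude is damped each step by the change of its overlap with the
    wavepacket following the active surface; once the overlap falls
    below ``smin`` the amplitude is collapsed to zero.  The norm defect
    is absorbed by the active state, whose amplitude is never reduced.

    The auxiliary force is evaluated at the main trajectory's geometry
    (first-order treatment of the divergence), which is exact for the
    constant-force situations the correction is meant to resolve.
    """

    def __init__(self, sigma: float, smin: float):
        self.sigma = sigma
        self.smin = smin
        self.aux: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self.o_prev: dict[int, float] = {}

    def reset(self, x: np.ndarray, v: np.ndarray) -> None:
        """Drop all auxiliary trajectories (call at t=0 and after hops)."""
        self.aux.clear()
        self.o_prev.clear()
        self._x0 = x.copy()
        self._v0 = v.copy()

    def step(
        self,
        c: np.ndarray,
        active: int,
        x: np.ndarray,
        v: np.ndarray,
        accel_of: Callable[[int], np.ndarray],
        dt_au: float,
    ) -> np.ndarray:
        """Damp non-active amplitudes; returns the corrected amplitudes."""
        c = np.array(c, complex)
        for k in range(len(c)):
            if k == active:
                continue
            pop = abs(c[k]) ** 2
            if pop < 1e-14:
                self.aux.pop(k, None)
                self.o_prev.pop(k, None)
                continue
            if k not in self.aux:
                self.aux[k] = (x.copy(), v.copy())
                self.o_prev[k] = 1.0
                continue
            xk, vk = self.aux[k]
            vk = vk + accel_of(k) * dt_au
            xk = xk + vk * dt_au
            self.aux[k] = (xk, vk)
            overlap = float(
                np.exp(-np.sum((xk - x) ** 2) / (4.0 * self.sigma**2))
            )
            if overlap < self.smin:
                c[k] = 0.0
                self.aux.pop(k)
                self.o_prev.pop(k, None)
                continue
            factor = min(1.0, overlap / self.o_prev[k])
            c[k] *= factor
            self.o_prev[k] = overlap
        # renormalize: the active state absorbs the norm defect
        other = sum(abs(c[k]) ** 2 for k in range(len(c)) if k != active)
        act = abs(c[active]) ** 2
        if act > 0.0:
            c[active] *= np.sqrt(max(0.0, 1.0 - other) / act)
        else:
            norm = np.sqrt(other)
            if norm > 0:
                c /= norm
        return c


# ---------------------------------------------------------------------
# initial conditions and thermalization
# ---------------------------------------------------------------------


def thermalize_andersen(
    system,
    x0: np.ndarray,
    v0: np.ndarray,
    temperature: float,
    collision_rate_fs: float,
    dt_fs: float,
    n_steps: int,
    rng: np.random.Generator,
    sample_every: int | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Ground-state MD with the Andersen thermostat.

    Each nuclear coordinate independently suffers collisions at rate
    ``collision_rate_fs`` (per fs); on collision its velocity is
    redrawn from the Maxwell distribution at ``temperature``.  With a
    zero collision rate this is plain NVE velocity Verlet on the
    ground surface.  Returns snapshots ``(x, v)`` every
    ``sample_every`` steps (default: only the final one).
    """
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    dt = dt_fs * FS_TO_AU
    masses = system.masses
    sig_v = np.sqrt(KB_HARTREE * temperature / masses)
    p_coll = collision_rate_fs * dt_fs
    x = np.array(x0, float)
    v = np.array(v0, float)
    a = -system.ground_gradient(x) / masses
    out = []
    for step in range(1, n_steps + 1):
        x = x + v * dt + 0.5 * a * dt**2
        a_new = -system.ground_gradient(x) / masses
        v = v + 0.5 * (a + a_new) * dt
        a = a_new
        if p_coll > 0.0:
            hit = rng.random(len(v)) < p_coll
            if np.any(hit):
                v[hit] = sig_v[hit] * rng.standard_normal(int(hit.sum()))
        if sample_every and step % sample_every == 0:
            out.append((x.copy(), v.copy()))
    if not sample_every:
        out.append((x.copy(), v.copy()))
    return out


def thermalize_rescale(
    system,
    x0: np.ndarray,
    v0: np.ndarray,
    temperature: float,
    collision_rate_fs: float,
    dt_fs: float,
    n_steps: int,
    rng: np.random.Generator,
    sample_every: int | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Global-rescale stochastic thermostat (all velocities share one factor).

    At collision events the total kinetic energy is redrawn from its
    canonical (chi-squared) distribution and all velocities are scaled
    by a common factor — a simple stand-in for global-rescaling
    thermostats.
    """
    dt = dt_fs * FS_TO_AU
    masses = system.masses
    ndof = len(masses)
    p_coll = collision_rate_fs * dt_fs
    x = np.array(x0, float)
    v = np.array(v0, float)
    a = -system.ground_gradient(x) / masses
    out = []
    for step in range(1, n_steps + 1):
        x = x + v * dt + 0.5 * a * dt**2
        a_new = -system.ground_gradient(x) / masses
        v = v + 0.5 * (a + a_new) * dt
        a = a_new
        if p_coll > 0.0 and rng.random() < p_coll:
            ke = 0.5 * float(np.sum(masses * v**2))
            ke_target = rng.gamma(0.5 * ndof, KB_HARTREE * temperature)
            if ke > 0:
                v *= np.sqrt(ke_target / ke)
        if sample_every and step % sample_every == 0:
            out.append((x.copy(), v.copy()))
    if not sample_every:
        out.append((x.copy(), v.copy()))
    return out


def sample_initial_conditions(
    system,
    snapshots: Sequence[tuple[np.ndarray, np.ndarray]],
    window_ev: tuple[float, float],
    n_samples: int,
    rng: np.random.Generator,
) -> list[InitialCondition]:
    """Dipole-weighted sampling of (snapshot, starting state) pairs.

    A pair is selectable iff the vertical excitation energy of the
    state lies inside the window; among selectable pairs the acceptance
    probability is ``|mu_0K|^2`` normalized to the ensemble maximum, so
    bright states are excited in proportion to their radiative
    transition probability and dark states (mu = 0) are never selected.
    """
    lo, hi = window_ev
    candidates = []
    all_energies = []
    for x, v in snapshots:
        aset = adiabatize(system.hamiltonian(x))
        de = aset.excitation_energies() * HARTREE_TO_EV
        mu_basis = system.transition_dipoles(x)
        mu_ad = aset.coefficients.T @ mu_basis  # (n_adiabats, 3)
        w = np.sum(mu_ad**2, axis=1)
        all_energies.extend(de.tolist())
        for k in range(len(de)):
            if lo <= de[k] <= hi:
                candidates.append((x, v, k + 1, w[k]))
    if not candidates:
        emin, emax = (min(all_energies), max(all_energies)) if all_energies else (np.nan, np.nan)
        raise ValueError(
            f"no excitation inside the window [{lo}, {hi}] eV; available "
            f"energies span [{emin:.3f}, {emax:.3f}] eV"
        )
    wmax = max(w for *_, w in candidates)
    if wmax <= 0.0:
        raise ValueError("all in-window states are dark (zero transition dipole)")
    out: list[InitialCondition] = []
    while len(out) < n_samples:
        x, v, k, w = candidates[rng.integers(len(candidates))]
        if rng.random() < w / wmax:
            out.append(InitialCondition(x.copy(), v.copy(), k))
    return out


# ---------------------------------------------------------------------
# trajectory driver
# ---------------------------------------------------------------------


@dataclass
class TrajectoryResult:
    frame: pd.DataFrame
    hops: list[HopEvent]
    basis_labels: list[tuple[int, int]]
    seed: int | None = None
    flagged: bool = False
    max_drift: float = 0.0
    aborted: str | None = None

    @property
    def final_coordinates(self) -> np.ndarray:
        cols = [c for c in self.frame.columns if c.startswith("q")]
        return self.frame.iloc[-1][cols].to_numpy(float)

    @property
    def final_state(self) -> int:
        return int(self.frame.iloc[-1]["active"])


@dataclass
class EnsembleResult:
    trajectories: list[TrajectoryResult]
    discarded: list[TrajectoryResult] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return len(self.trajectories) + len(self.discarded)


def _active_gradient(k: int, aset: AdiabaticSet, grads: GradientSet) -> np.ndarray:
    if k == 0:
        return grads.grad_ground
    return adiabatic_gradient(k, aset, grads)


def run_trajectory(
    system,
    initial: InitialCondition,
    config: SHConfig,
    rng: np.random.Generator | None = None,
    init_amplitudes: np.ndarray | None = None,
    record_every: int = 1,
) -> TrajectoryResult:
    """Propagate one surface-hopping trajectory.

    The nuclear step (velocity Verlet on the active surface) and the
    electronic LD step share the same time step.  Per recorded step the
    result frame holds: time, coordinates, active state and its
    dominant excitonic label, all adiabatic energies, adiabatic
    amplitude populations ``|c_K|^2``, the active state's excitonic
    weights ``|C_ai,K|^2`` (zero when on the ground state) and the
    amplitude-derived excitonic populations.

    A total-energy drift between hops larger than ``config.energy_tol``
    flags the trajectory; ensembles exclude flagged trajectories.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dt = config.dt_fs * FS_TO_AU
    masses = system.masses
    labels = list(system.basis_labels)
    n_basis = len(labels)

    x = np.array(initial.coordinates, float)
    v = np.array(initial.velocities, float)
    active = int(initial.state)
    aset = adiabatize(system.hamiltonian(x))
    grads = system.gradients(x)
    if init_amplitudes is None:
        c = np.zeros(n_basis + 1, complex)
        c[active] = 1.0
    else:
        c = np.asarray(init_amplitudes, complex).copy()
        c /= np.linalg.norm(c)

    odc = ODCTracker(config.odc_sigma, config.odc_smin)
    odc.reset(x, v)

    hops: list[HopEvent] = []
    records: list[dict] = []
    time_fs = 0.0
    ground_time = 0.0
    e_ref = aset.energies[active] + 0.5 * float(np.sum(masses * v**2))
    max_drift = 0.0
    aborted = None

    def label_of(k: int) -> str:
        if k == 0:
            return "gs"
        a, i = aset.label_map[k]
        return f"{a}:{i}"

    def record():
        rec = {"time_fs": time_fs}
        for d in range(len(x)):
            rec[f"q{d}"] = x[d]
        for d in range(len(v)):
            rec[f"v{d}"] = v[d]
        rec["active"] = active
        rec["label"] = label_of(active)
        for k in range(n_basis + 1):
            rec[f"E{k}"] = aset.energies[k]
        pops = np.abs(c) ** 2
        for k in range(n_basis + 1):
            rec[f"pop{k}"] = pops[k]
        if active == 0:
            w = np.zeros(n_basis)
        else:
            w = aset.coefficients[:, active - 1] ** 2
        for p, (a, i) in enumerate(labels):
            rec[f"w_{a}_{i}"] = w[p]
        d_amp = aset.full_coefficients() @ c
        rec["damp_gs"] = abs(d_amp[0]) ** 2
        for p, (a, i) in enumerate(labels):
            rec[f"damp_{a}_{i}"] = abs(d_amp[p + 1]) ** 2
        records.append(rec)

    record()
    g_act = _active_gradient(active, aset, grads)
    n_steps = int(round(config.max_time_fs / config.dt_fs))
    for step in range(1, n_steps + 1):
        a_vec = -g_act / masses
        x1 = x + v * dt + 0.5 * a_vec * dt**2
        aset1 = adiabatize(system.hamiltonian(x1))
        grads1 = system.gradients(x1)

        # adiabatic-basis overlap with sign alignment of the new columns
        sig = excitonic_overlap(system.site_overlaps(x, x1))
        s_ad = aset.full_coefficients().T @ sig @ aset1.full_coefficients()
        flips = np.ones(n_basis + 1)
        for k in range(1, n_basis + 1):
            if s_ad[k, k] < 0.0:
                flips[k] = -1.0
        if np.any(flips < 0):
            s_ad = s_ad * flips[None, :]
            aset1.coefficients *= flips[1:][None, :]
        try:
            t_mat = lowdin_orthogonalize(s_ad)
        except RuntimeError as err:
            aborted = str(err)
            break

        c1 = ld_propagate(c, aset.energies, aset1.energies, t_mat, dt)
        probs = hop_probabilities(c, c1, t_mat, active)

        # velocity update on the pre-hop active surface
        g1 = _active_gradient(active, aset1, grads1)
        v1 = v + 0.5 * (a_vec + (-g1 / masses)) * dt

        target = attempt_hop(probs, rng)
        if target is not None and target != active:
            e_old = aset1.energies[active]
            e_new = aset1.energies[target]
            v_res = rescale_after_hop(v1, masses, e_old, e_new)
            if v_res is None:
                hops.append(
                    HopEvent(time_fs + config.dt_fs, active, active, 0.0, True)
                )
            else:
                hops.append(
                    HopEvent(
                        time_fs + config.dt_fs, active, target, e_old - e_new, False
                    )
                )
                v1 = v_res
                active = target
                g1 = _active_gradient(active, aset1, grads1)
                odc.reset(x1, v1)
                e_ref = aset1.energies[active] + 0.5 * float(
                    np.sum(masses * v1**2)
                )

        if config.decoherence:

            def accel_of(k: int) -> np.ndarray:
                return -_active_gradient(k, aset1, grads1) / masses

            c1 = odc.step(c1, active, x1, v1, accel_of, dt)

        x, v, c, aset, g_act = x1, v1, c1, aset1, g1
        time_fs += config.dt_fs

        e_tot = aset.energies[active] + 0.5 * float(np.sum(masses * v**2))
        drift = abs(e_tot - e_ref)
        max_drift = max(max_drift, drift)

        if step % record_every == 0:
            record()

        if active == 0:
            ground_time += config.dt_fs
            if ground_time >= config.ground_stop_fs:
                break
        else:
            ground_time = 0.0

    frame = pd.DataFrame(records)
    return TrajectoryResult(
        frame=frame,
        hops=hops,
        basis_labels=labels,
        seed=config.seed,
        flagged=max_drift > config.energy_tol or aborted is not None,
        max_drift=max_drift,
        aborted=aborted,
    )


def run_ensemble(
    system,
    initials: Sequence[InitialCondition],
    config: SHConfig,
    base_seed: int | None = None,
    record_every: int = 1,
) -> EnsembleResult:
    """Run a swarm of trajectories with independent, logged seeds.

    Flagged trajectories (energy-conservation breach or aborted LD
    step) are excluded from the analysis set but kept in ``discarded``.
    """
    seed_seq = np.random.SeedSequence(config.seed if base_seed is None else base_seed)
    children = seed_seq.spawn(len(initials))
    kept, dropped = [], []
    for ic, child in zip(initials, children):
        rng = np.random.default_rng(child)
        traj = run_trajectory(system, ic, config, rng=rng, record_every=record_every)
        traj.seed = int(child.generate_state(1)[0] % (2**31))
        (dropped if traj.flagged else kept).append(traj)
    return EnsembleResult(trajectories=kept, discarded=dropped)
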