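"""Interchromophore Coulomb couplings and transition-charge fitting.

Two states of the same spin manifold on chromophores that are not in
contact couple predominantly through the Coulomb interaction of their
transition densities,

    V_ai,bj = integral rho_0i^(a)(r) rho_0j^(b)(r') / |r - r'| dr dr'.

Here transition densities are modeled as sums of spherical Gaussians
centered on atoms — the analytic analog of the one-center AO-pair
structure that survives in neglect-of-differential-overlap schemes.
For two spherical Gaussians of widths sigma_p, sigma_q the Coulomb
kernel is closed-form, ``erf(r / (sqrt(2) s)) / r`` with
``s = sqrt(sigma_p^2 + sigma_q^2)``, so the "exact Coulomb" (EC)
coupling is an analytic double sum.  The cheaper "transition charges"
(TC) scheme replaces each density by atomic monopoles fitted to its
electrostatic potential (TrESP) and couples the two charge sets by
plain Coulomb sums.  The exchange contribution is omitted entirely: it
vanishes in the NDO framework this model mirrors.

All quantities in atomic units: bohr, hartree, electron charge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .units import BOHR_TO_ANGSTROM, ANGSTROM_TO_BOHR

__all__ = [
    "TransitionDensityCloud",
    "TransitionChargeSet",
    "ESPGrid",
    "exact_coulomb",
    "build_esp_grid",
    "fit_tresp",
    "tc_coupling",
    "dipole_coupling",
    "coupling_gradient_static",
    "distance_scan",
    "write_xyz",
    "read_xyz",
]

_NEUTRALITY_TOL = 1e-10
_SQRT_2_OVER_PI = np.sqrt(2.0 / np.pi)


def _gaussian_coulomb(r: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Coulomb kernel between unit spherical Gaussians.

    ``erf(r / (sqrt(2) s)) / r`` with the analytic r -> 0 limit
    ``sqrt(2/pi) / s``.
    """
    r = np.asarray(r, float)
    s = np.broadcast_to(np.asarray(s, float), r.shape)
    out = np.empty_like(r)
    small = r < 1e-12
    out[small] = _SQRT_2_OVER_PI / s[small]
    rn = r[~small]
    out[~small] = erf(rn / (np.sqrt(2.0) * s[~small])) / rn
    return out


def _gaussian_coulomb_deriv(r: np.ndarray, s: np.ndarray) -> np.ndarray:
    """d/dr of :func:`_gaussian_coulomb`; 0 at r = 0 by symmetry."""
    r = np.asarray(r, float)
    s = np.broadcast_to(np.asarray(s, float), r.shape)
    out = np.zeros_like(r)
    ok = r >= 1e-12
    rn, sn = r[ok], s[ok]
    a = np.sqrt(2.0) * sn
    out[ok] = (2.0 / (np.sqrt(np.pi) * a)) * np.exp(-((rn / a) ** 2)) / rn - erf(
        rn / a
    ) / rn**2
    return out


@dataclass
class TransitionDensityCloud:
    """Atom-centered Gaussian model of a transition density.

    Parameters
    ----------
    centers : ndarray, shape (N, 3)
        Gaussian centers, bohr.
    widths : ndarray, shape (N,)
        Gaussian standard deviations, bohr; must be positive.
    weights : ndarray, shape (N,)
        Signed amplitudes in units of e.  For a genuine transition
        density between orthogonal states (``state_pair`` set) the
        weights must integrate to zero.
    chromophore_id : int
    state_pair : tuple or None
        ``(0, i)`` for the 0 -> i transition; ``None`` for generic test
        charge distributions, for which neutrality is not enforced.
    """

    centers: np.ndarray
    widths: np.ndarray
    weights: np.ndarray
    chromophore_id: int = 0
    state_pair: tuple[int, int] | None = None

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, float))
        self.widths = np.atleast_1d(np.asarray(self.widths, float))
        self.weights = np.atleast_1d(np.asarray(self.weights, float))
        if self.widths.shape == (1,) and len(self.centers) > 1:
            self.widths = np.full(len(self.centers), self.widths[0])
        if not (len(self.centers) == len(self.widths) == len(self.weights)):
            raise ValueError("centers, widths and weights must have equal length")
        if np.any(self.widths <= 0):
            raise ValueError("Gaussian widths must be positive")
        if self.state_pair is not None and abs(self.weights.sum()) > _NEUTRALITY_TOL:
            raise ValueError(
                "transition density must integrate to zero "
                f"(sum of weights = {self.weights.sum():.3e})"
            )

    def potential(self, points: np.ndarray) -> np.ndarray:
        """Electrostatic potential of the cloud at ``points`` (hartree/e)."""
        points = np.atleast_2d(np.asarray(points, float))
        r = np.linalg.norm(points[:, None, :] - self.centers[None, :, :], axis=-1)
        kern = _gaussian_coulomb(r, self.widths[None, :])
        return kern @ self.weights

    def dipole(self) -> np.ndarray:
        """Dipole moment of the cloud (au); origin-independent if neutral."""
        return self.weights @ self.centers

    def extent(self) -> float:
        """Radius of the cloud: max center distance from centroid plus 3 sigma."""
        centroid = self.centers.mean(axis=0)
        r = np.linalg.norm(self.centers - centroid, axis=1)
        return float(np.max(r + 3.0 * self.widths))


@dataclass
class TransitionChargeSet:
    """Atomic transition charges (TrESP) for one 0 -> i transition."""

    atom_positions: np.ndarray
    charges: np.ndarray
    chromophore_id: int = 0
    state_pair: tuple[int, int] | None = None

    def __post_init__(self):
        self.atom_positions = np.atleast_2d(np.asarray(self.atom_positions, float))
        self.charges = np.atleast_1d(np.asarray(self.charges, float))
        if len(self.atom_positions) != len(self.charges):
            raise ValueError("positions and charges must have equal length")

    def potential(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        r = np.linalg.norm(
            points[:, None, :] - self.atom_positions[None, :, :], axis=-1
        )
        return (1.0 / r) @ self.charges

    def dipole(self) -> np.ndarray:
        return self.charges @ self.atom_positions


@dataclass
class ESPGrid:
    """Grid points and reference potential for TrESP fitting."""

    points: np.ndarray
    reference_potential: np.ndarray

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, float))
        self.reference_potential = np.asarray(self.reference_potential, float)
        if len(self.points) != len(self.reference_potential):
            raise ValueError("points and potential values must have equal length")

    def __len__(self) -> int:
        return len(self.points)


def exact_coulomb(
    cloud_a: TransitionDensityCloud, cloud_b: TransitionDensityCloud
) -> float:
    """Exact Coulomb (EC) coupling between two transition-density clouds.

    Analytic double sum over Gaussian pairs; symmetric in A <-> B to
    machine precision.  Intra-chromophore couplings are zero by
    construction and are refused rather than computed.
    """
    if cloud_a.chromophore_id == cloud_b.chromophore_id:
        raise ValueError(
            "intra-chromophore couplings are zero by construction; "
            f"got two clouds on chromophore {cloud_a.chromophore_id}"
        )
    r = np.linalg.norm(
        cloud_a.centers[:, None, :] - cloud_b.centers[None, :, :], axis=-1
    )
    s = np.sqrt(cloud_a.widths[:, None] ** 2 + cloud_b.widths[None, :] ** 2)
    kern = _gaussian_coulomb(r, s)
    return float(cloud_a.weights @ kern @ cloud_b.weights)


def tc_coupling(qa: TransitionChargeSet, qb: TransitionChargeSet) -> float:
    """Transition-charge (TC) coupling: ``sum_AB q_A q_B / R_AB``."""
    if qa.chromophore_id == qb.chromophore_id:
        raise ValueError(
            "intra-chromophore couplings are zero by construction; "
            f"got two charge sets on chromophore {qa.chromophore_id}"
        )
    r = np.linalg.norm(
        qa.atom_positions[:, None, :] - qb.atom_positions[None, :, :], axis=-1
    )
    if np.any(r < 1e-9):
        ia, ib = np.unravel_index(int(np.argmin(r)), r.shape)
        raise ZeroDivisionError(
            f"coincident atoms: atom {ia} of chromophore {qa.chromophore_id} "
            f"and atom {ib} of chromophore {qb.chromophore_id}"
        )
    return float(qa.charges @ (1.0 / r) @ qb.charges)


def dipole_coupling(
    mu_a: np.ndarray, mu_b: np.ndarray, r_vec: np.ndarray
) -> float:
    """Point-dipole coupling ``[mu_a.mu_b - 3 (mu_a.R)(mu_b.R)] / R^3``.

    ``r_vec`` points from chromophore a to b.  The leading far-field
    term of both EC and TC couplings for dipole-allowed transitions.
    """
    mu_a = np.asarray(mu_a, float)
    mu_b = np.asarray(mu_b, float)
    r_vec = np.asarray(r_vec, float)
    dist = np.linalg.norm(r_vec)
    if dist == 0.0:
        raise ValueError("zero separation between dipoles")
    rh = r_vec / dist
    return float((mu_a @ mu_b - 3.0 * (mu_a @ rh) * (mu_b @ rh)) / dist**3)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def build_esp_grid(
    charge_model: TransitionDensityCloud,
    centers: np.ndarray | None = None,
    shells: Sequence[float] = (1.4, 1.6, 1.8, 2.0),
    density: float = 1.0,
    exclusion_radius: float = 3.0,
) -> ESPGrid:
    """Nested merged-sphere grid around a chromophore, with the cloud's
    potential as the fit reference.

    For each shell multiplier ``m``, points are laid on spheres of
    radius ``m * exclusion_radius`` around every center (about
    ``density`` points per bohr^2) and kept only where they are at least
    that far from *every* center, which merges the spheres into a single
    molecular surface.  No point is closer than ``exclusion_radius`` to
    any atom.
    """
    if any(m <= 0 for m in shells):
        raise ValueError("shell multipliers must be positive")
    centers = (
        charge_model.centers if centers is None else np.atleast_2d(np.asarray(centers, float))
    )
    pts = []
    for m in shells:
        radius = m * exclusion_radius
        n_pts = max(8, int(np.ceil(density * 4.0 * np.pi * radius**2)))
        sphere = _fibonacci_sphere(n_pts) * radius
        for c in centers:
            cand = sphere + c
            d = np.linalg.norm(cand[:, None, :] - centers[None, :, :], axis=-1)
            keep = np.all(d >= radius - 1e-9, axis=1)
            pts.append(cand[keep])
    points = np.vstack(pts)
    if len(points) == 0:
        raise ValueError("ESP grid is empty; check shells and exclusion radius")
    return ESPGrid(points=points, reference_potential=charge_model.potential(points))


def fit_tresp(
    cloud: TransitionDensityCloud,
    atoms: np.ndarray,
    grid: ESPGrid | None = None,
    constrain_total: bool = True,
    constrain_dipole: bool = False,
) -> TransitionChargeSet:
    """Fit atomic transition charges to the cloud's electrostatic potential.

    Linear least squares of the atomic-monopole potential against the
    reference potential on the grid, with Lagrange-multiplier equality
    constraints: total charge zero (default on) and, optionally, exact
    reproduction of the cloud's dipole moment.

    Raises
    ------
    ValueError
        If the grid has no more points than atoms, or the constrained
        normal equations are singular (fewer independent points than
        unknowns plus constraints).
    """
    atoms = np.atleast_2d(np.asarray(atoms, float))
    if grid is None:
        grid = build_esp_grid(cloud, centers=atoms)
    n_atoms = len(atoms)
    if len(grid) <= n_atoms:
        raise ValueError(
            f"need more grid points ({len(grid)}) than atoms ({n_atoms})"
        )
    r = np.linalg.norm(grid.points[:, None, :] - atoms[None, :, :], axis=-1)
    if np.any(r < 1e-9):
        raise ValueError("grid point coincides with an atom")
    design = 1.0 / r

    cons_rows = []
    cons_rhs = []
    if constrain_total:
        cons_rows.append(np.ones(n_atoms))
        cons_rhs.append(0.0)
    if constrain_dipole:
        mu = cloud.dipole()
        for k in range(3):
            cons_rows.append(atoms[:, k])
            cons_rhs.append(mu[k])
    n_cons = len(cons_rows)

    ata = design.T @ design
    atb = design.T @ grid.reference_potential
    kkt = np.zeros((n_atoms + n_cons, n_atoms + n_cons))
    kkt[:n_atoms, :n_atoms] = 2.0 * ata
    rhs = np.zeros(n_atoms + n_cons)
    rhs[:n_atoms] = 2.0 * atb
    for m, (row, b) in enumerate(zip(cons_rows, cons_rhs)):
        kkt[n_atoms + m, :n_atoms] = row
        kkt[:n_atoms, n_atoms + m] = row
        rhs[n_atoms + m] = b
    if np.linalg.cond(kkt) > 1e12:
        raise ValueError("rank-deficient TrESP fit: grid does not determine charges")
    sol = np.linalg.solve(kkt, rhs)
    return TransitionChargeSet(
        atom_positions=atoms,
        charges=sol[:n_atoms],
        chromophore_id=cloud.chromophore_id,
        state_pair=cloud.state_pair,
    )


def _as_points(obj) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """(positions, weights, widths-or-None) view of a set or cloud."""
    if isinstance(obj, TransitionChargeSet):
        return obj.atom_positions, obj.charges, None
    if isinstance(obj, TransitionDensityCloud):
        return obj.centers, obj.weights, obj.widths
    raise TypeError(f"unsupported coupling object {type(obj)!r}")


def coupling_gradient_static(set_a, set_b) -> np.ndarray:
    """Static gradient of the coupling w.r.t. all center positions.

    Differentiates the Coulomb sum (TC) or Gaussian Coulomb sum (EC)
    with the charges/weights held frozen — i.e. neglecting their
    dependence on the nuclear coordinates.  Returns an array of shape
    (N_A + N_B, 3); A's centers first.  Mixed pairs (one cloud, one
    charge set) are supported by treating point charges as zero-width.
    """
    pa, wa, sa = _as_points(set_a)
    pb, wb, sb = _as_points(set_b)
    diff = pa[:, None, :] - pb[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    if sa is None and sb is None:
        if np.any(r < 1e-9):
            raise ZeroDivisionError("coincident centers across the two sets")
        dk = -1.0 / r**2
    else:
        za = np.zeros(len(pa)) if sa is None else sa
        zb = np.zeros(len(pb)) if sb is None else sb
        s = np.sqrt(za[:, None] ** 2 + zb[None, :] ** 2)
        if np.any((r < 1e-9) & (s < 1e-12)):
            raise ZeroDivisionError("coincident point centers across the two sets")
        dk = _gaussian_coulomb_deriv(r, s)
    with np.errstate(invalid="ignore"):
        unit = np.where(r[..., None] > 1e-12, diff / np.maximum(r, 1e-300)[..., None], 0.0)
    pair = (wa[:, None] * wb[None, :] * dk)[..., None] * unit
    grad_a = pair.sum(axis=1)
    grad_b = -pair.sum(axis=0)
    return np.vstack([grad_a, grad_b])


def distance_scan(
    system_a: TransitionDensityCloud,
    system_b: TransitionDensityCloud,
    axis: np.ndarray = (0.0, 0.0, 1.0),
    distances: Sequence[float] = (),
) -> pd.DataFrame:
    """Scan the TC and EC couplings along a separation axis.

    ``system_b`` is rigidly translated so its centroid sits at each
    requested distance from ``system_a``'s centroid along ``axis``.
    TrESP charges are fitted once per system (atoms at the Gaussian
    centers) and reused at every separation, mirroring how transition
    charges are used in practice.  Geometries where the clouds overlap
    are flagged in the ``overlapping`` column, not refused.

    Returns a DataFrame with columns R (bohr), V_EC, V_TC (hartree),
    rel_dev = |V_TC - V_EC| / |V_EC| and overlapping.
    """
    distances = np.asarray(list(distances), float)
    if len(distances) == 0:
        raise ValueError("no scan distances given")
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)

    qa = fit_tresp(system_a, system_a.centers)
    qb = fit_tresp(system_b, system_b.centers)
    cent_a = system_a.centers.mean(axis=0)
    cent_b = system_b.centers.mean(axis=0)
    contact = system_a.extent() + system_b.extent()

    rows = []
    for dist in distances:
        shift = cent_a + dist * axis - cent_b
        cloud_b = TransitionDensityCloud(
            centers=system_b.centers + shift,
            widths=system_b.widths,
            weights=system_b.weights,
            chromophore_id=system_b.chromophore_id,
            state_pair=system_b.state_pair,
        )
        set_b = TransitionChargeSet(
            atom_positions=qb.atom_positions + shift,
            charges=qb.charges,
            chromophore_id=qb.chromophore_id,
            state_pair=qb.state_pair,
        )
        v_ec = exact_coulomb(system_a, cloud_b)
        v_tc = tc_coupling(qa, set_b)
        rel = abs(v_tc - v_ec) / abs(v_ec) if v_ec != 0.0 else np.inf
        rows.append(
            {
                "R": dist,
                "V_EC": v_ec,
                "V_TC": v_tc,
                "rel_dev": rel,
                "overlapping": bool(dist < contact),
            }
        )
    return pd.DataFrame(rows)


def write_xyz(path, obj, comment: str = "") -> None:
    """Write a cloud or charge set in an extended-XYZ dialect.

    Columns: element placeholder X, x, y, z in angstrom, charge/weight
    in e, and width in angstrom (0 for point charges).
    """
    pos, w, widths = _as_points(obj)
    sp = "None" if obj.state_pair is None else ",".join(str(v) for v in obj.state_pair)
    with open(path, "w") as fh:
        fh.write(f"{len(pos)}\n")
        fh.write(f"chromophore={obj.chromophore_id} state_pair={sp} {comment}\n")
        for k in range(len(pos)):
            x, y, z = pos[k] * BOHR_TO_ANGSTROM
            width = 0.0 if widths is None else widths[k] * BOHR_TO_ANGSTROM
            fh.write(f"X {x:18.10f} {y:18.10f} {z:18.10f} {w[k]:16.10f} {width:12.6f}\n")


def read_xyz(path):
    """Read the extended-XYZ dialect written by :func:`write_xyz`.

    Returns a :class:`TransitionChargeSet` when all widths are zero,
    otherwise a :class:`TransitionDensityCloud`.
    """
    with open(path) as fh:
        n = int(fh.readline())
        header = fh.readline().split()
        meta = dict(item.split("=", 1) for item in header if "=" in item)
        rows = [fh.readline().split() for _ in range(n)]
    pos = np.array([[float(v) for v in r[1:4]] for r in rows]) * ANGSTROM_TO_BOHR
    w = np.array([float(r[4]) for r in rows])
    widths = np.array([float(r[5]) for r in rows]) * ANGSTROM_TO_BOHR
    chrom = int(meta.get("chromophore", 0))
    sp = meta.get("state_pair", "None")
    state_pair = None if sp == "None" else tuple(int(v) for v in sp.split(","))
    if np.all(widths == 0.0):
        return TransitionChargeSet(pos, w, chromophore_id=chrom, state_pair=state_pair)
    return TransitionDensityCloud(
        pos, widths, w, chromophore_id=chrom, state_pair=state_pair
    )
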