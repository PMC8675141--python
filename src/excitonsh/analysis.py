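"""Ensemble post-processing: populations, EET counts, yields, kinetics, spectra.

Populations of the excitonic (quasi-diabatic) states are estimated by
the standard surface-hopping trajectory count: at each time the active
adiabatic state of every trajectory contributes its squared excitonic
coefficients ``|C_ai,K|^2`` to the label populations, and trajectories
on the ground state contribute to the ground label.  Photoproduct
quantum yields come with their binomial standard deviation
``sigma = sqrt(Phi (1 - Phi) / N)``.  Excited-state decay is summarized
by a first-order irreversible kinetic model: the upper (pi-pi*-like)
population decays as ``exp(-t / tau2)`` and the lower (n-pi*-like)
population as a delayed exponential ``exp(-(t - t0) / tau1~)`` — no
decay to the ground state can occur before enough torsional twisting
has built up, hence the delay — with the overall lifetime
``tau1 = t0 + tau1~``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dynamics import EnsembleResult, TrajectoryResult
from .units import HARTREE_TO_EV

__all__ = [
    "PopulationTrace",
    "KineticFitResult",
    "YieldResult",
    "excitonic_populations",
    "count_eet_transitions",
    "quantum_yield",
    "cis_trans_classifier",
    "fit_kinetics",
    "absorption_spectrum",
]


@dataclass
class PopulationTrace:
    """Time-resolved label populations averaged over an ensemble.

    ``data`` has a ``time_fs`` column plus one column per label
    (``gs`` and ``a:i`` strings); every time slice sums to one.
    """

    data: pd.DataFrame

    @property
    def time_fs(self) -> np.ndarray:
        return self.data["time_fs"].to_numpy()

    def population(self, label: str) -> np.ndarray:
        return self.data[label].to_numpy()

    def combined(self, labels: Sequence[str]) -> np.ndarray:
        return sum(self.data[lab].to_numpy() for lab in labels)


@dataclass
class KineticFitResult:
    """Delayed-exponential decay parameters, all in ps."""

    tau1: float
    tau2: float | None
    t0: float
    tau1_tilde: float
    residual: float

    def __post_init__(self):
        if abs(self.tau1 - (self.t0 + self.tau1_tilde)) > 1e-9 * max(1.0, self.tau1):
            raise ValueError("tau1 must equal t0 + tau1_tilde")


@dataclass
class YieldResult:
    """Photoproduct quantum yield with binomial uncertainty."""

    phi: float
    sigma_phi: float
    n: int
    excluded: int


def _pad_active_labels(traj: TrajectoryResult, n_steps: int) -> pd.DataFrame:
    """Trajectory frame extended to a common grid by repeating the last row.

    Trajectories stop once they have relaxed to the ground state; for
    ensemble averages they are held in their final state afterwards.
    """
    frame = traj.frame
    if len(frame) >= n_steps:
        return frame.iloc[:n_steps]
    pad = pd.concat([frame.iloc[[-1]]] * (n_steps - len(frame)), ignore_index=True)
    return pd.concat([frame, pad], ignore_index=True)


def excitonic_populations(ensemble: EnsembleResult) -> PopulationTrace:
    """Excitonic-state populations from the active-state coefficients.

    The population of label ``ai`` at time t is the ensemble average of
    ``|C_ai,K_active(t)|^2``; the ground label collects the fraction of
    trajectories whose active state is the ground state.  Trajectories
    with ragged time grids are extended to the longest grid by holding
    their final state.
    """
    trajs = ensemble.trajectories
    if not trajs:
        raise ValueError("empty ensemble")
    labels = trajs[0].basis_labels
    n_steps = max(len(t.frame) for t in trajs)
    time = max((t.frame for t in trajs), key=len)["time_fs"].to_numpy()[:n_steps]
    cols = {f"w_{a}_{i}": f"{a}:{i}" for a, i in labels}

    acc = {lab: np.zeros(n_steps) for lab in cols.values()}
    ground = np.zeros(n_steps)
    for traj in trajs:
        frame = _pad_active_labels(traj, n_steps)
        ground += (frame["active"].to_numpy() == 0).astype(float)
        for col, lab in cols.items():
            acc[lab] += frame[col].to_numpy()
    n = len(trajs)
    data = pd.DataFrame({"time_fs": time, "gs": ground / n})
    for lab, vals in acc.items():
        data[lab] = vals / n
    return PopulationTrace(data=data)


def count_eet_transitions(
    traj: TrajectoryResult, label_pair: tuple[str, str]
) -> int:
    """Count dominant-label switches between the two members of a pair.

    The dominant excitonic label of the active state is the argmax of
    ``|C_ai,K|^2`` (ties broken by the lowest label index); only direct,
    consecutive switches between the two labels are counted.
    """
    w_cols = [f"w_{a}_{i}" for a, i in traj.basis_labels]
    missing = [lab for lab in label_pair if lab not in
               {f"{a}:{i}" for a, i in traj.basis_labels}]
    if missing:
        import warnings

        warnings.warn(f"labels {missing} absent from trajectory basis")
        return 0
    w = traj.frame[w_cols].to_numpy()
    idx = np.argmax(w, axis=1)  # argmax takes the first maximum: lowest index
    names = [f"{a}:{i}" for a, i in traj.basis_labels]
    dominant = np.array([names[i] for i in idx], dtype=object)
    on_ground = traj.frame["active"].to_numpy() == 0
    dominant[on_ground] = "gs"
    a, b = label_pair
    count = 0
    for prev, cur in zip(dominant[:-1], dominant[1:]):
        if (prev == a and cur == b) or (prev == b and cur == a):
            count += 1
    return count


def cis_trans_classifier(threshold: float = np.pi / 4) -> Callable:
    """Default photoproduct classifier for torsional chromophores.

    A trajectory is a (cis) photoproduct when any site torsion ends
    within ``threshold`` of 0 modulo 2 pi; otherwise it is a reactant.
    """

    def classify(traj: TrajectoryResult) -> str:
        theta = traj.final_coordinates
        folded = np.abs((theta + np.pi) % (2.0 * np.pi) - np.pi)
        return "product" if np.any(folded < threshold) else "reactant"

    return classify


def quantum_yield(
    ensemble: EnsembleResult, classifier: Callable | None = None
) -> YieldResult:
    """Photoisomerization quantum yield with binomial standard deviation.

    ``classifier(traj)`` returns "product", "reactant" or "excluded";
    excluded trajectories are removed from the denominator.
    ``Phi = N_product / (N - N_excluded)`` and
    ``sigma_Phi = sqrt(Phi (1 - Phi) / N)`` with N the number of
    trajectories actually counted.
    """
    if classifier is None:
        classifier = cis_trans_classifier()
    outcomes = [classifier(t) for t in ensemble.trajectories]
    excluded = sum(1 for o in outcomes if o == "excluded")
    n = len(outcomes) - excluded
    if n == 0:
        raise ValueError("all trajectories excluded; no yield defined")
    reactive = sum(1 for o in outcomes if o == "product")
    phi = reactive / n
    sigma = float(np.sqrt(phi * (1.0 - phi) / n))
    return YieldResult(phi=phi, sigma_phi=sigma, n=n, excluded=excluded)


def binomial_sigma(phi: float, n: int) -> float:
    """Binomial standard deviation ``sqrt(phi (1 - phi) / n)``."""
    return float(np.sqrt(phi * (1.0 - phi) / n))


def _delayed_exp(t: np.ndarray, t0: float, tau: float) -> np.ndarray:
    out = np.ones_like(t)
    late = t >= t0
    out[late] = np.exp(-(t[late] - t0) / tau)
    return out


def _sequential_lower(
    t: np.ndarray, t0: float, tau1t: float, tau2: float
) -> np.ndarray:
    """Lower-state population of the irreversible chain upper -> lower -> ground.

    The upper state feeds the lower one with rate 1/tau2 from t = 0;
    the lower state starts decaying (rate 1/tau1~) only after the delay
    t0.  Closed form from piecewise integration.
    """
    k1 = 1.0 / tau1t
    k2 = 1.0 / tau2
    out = np.empty_like(t)
    early = t < t0
    out[early] = 1.0 - np.exp(-k2 * t[early])
    tl = t[~early]
    p_t0 = 1.0 - np.exp(-k2 * t0)
    if abs(k1 - k2) < 1e-12:
        feed = k2 * np.exp(-k1 * (tl - t0) - k2 * t0) * (tl - t0)
    else:
        feed = (
            k2
            / (k1 - k2)
            * (np.exp(-k2 * tl) - np.exp(-k1 * (tl - t0) - k2 * t0))
        )
    out[~early] = np.exp(-k1 * (tl - t0)) * p_t0 + feed
    return out


def fit_kinetics(
    trace: PopulationTrace,
    lower_labels: Sequence[str],
    upper_labels: Sequence[str] | None = None,
    mode: str = "lower-only",
) -> KineticFitResult:
    """Fit the first-order irreversible kinetic model to population traces.

    Parameters
    ----------
    trace : PopulationTrace
    lower_labels : labels whose summed population is the lower
        (n-pi*-like) excited population, e.g. ["0:1", "1:1"].
    upper_labels : labels of the upper (pi-pi*-like) manifold; required
        in "sequential" mode.
    mode : "lower-only" fits the delayed exponential
        ``P(t) = exp(-(t - t0)/tau1~)`` (P = 1 for t < t0) to the lower
        trace, as after direct excitation of the lower states.
        "sequential" jointly fits ``P_upper = exp(-t/tau2)`` and the
        corresponding chain-with-delay form of the lower trace, as
        after excitation of the upper states.

    Returns times in ps; ``tau1 = t0 + tau1~`` exactly.

    Raises
    ------
    RuntimeError if the fit does not converge, reporting the initial
    guess used.
    """
    t_ps = trace.time_fs / 1000.0
    p_low = trace.combined(lower_labels)

    if mode == "lower-only":
        guess = np.array([0.1 * t_ps[-1], max(t_ps[-1] / 3.0, 1e-3)])

        def resid(params):
            t0, tau = np.abs(params)
            return _delayed_exp(t_ps, t0, tau) - p_low

    elif mode == "sequential":
        if upper_labels is None:
            raise ValueError("sequential mode requires upper_labels")
        p_up = trace.combined(upper_labels)
        guess = np.array(
            [0.1 * t_ps[-1], max(t_ps[-1] / 3.0, 1e-3), max(t_ps[-1] / 3.0, 1e-3)]
        )

        def resid(params):
            t0, tau1t, tau2 = np.abs(params)
            r1 = np.exp(-t_ps / tau2) - p_up
            r2 = _sequential_lower(t_ps, t0, tau1t, tau2) - p_low
            return np.concatenate([r1, r2])

    else:
        raise ValueError(f"unknown mode {mode!r}")

    sol = least_squares(resid, guess, method="lm", max_nfev=10000)
    if not sol.success:
        raise RuntimeError(
            f"kinetic fit did not converge from initial guess {guess}: {sol.message}"
        )
    params = np.abs(sol.x)
    t0, tau1t = params[0], params[1]
    tau2 = float(params[2]) if mode == "sequential" else None
    return KineticFitResult(
        tau1=float(t0 + tau1t),
        tau2=tau2,
        t0=float(t0),
        tau1_tilde=float(tau1t),
        residual=float(np.sqrt(np.mean(sol.fun**2))),
    )


def absorption_spectrum(
    snapshot_sets: Sequence,
    broadening_ev: float = 0.15,
    grid_ev: np.ndarray | None = None,
) -> pd.DataFrame:
    """Gaussian-broadened absorption spectrum from a snapshot ensemble.

    ``snapshot_sets`` is a sequence of (excitation_energies_hartree,
    transition_dipoles_au) pairs, one per snapshot, with one row per
    adiabatic state.  Stick intensities are the oscillator strengths
    ``f_K = (2/3) dE_K |mu_K|^2`` accumulated per adiabatic state and
    broadened with a Gaussian of width ``broadening_ev``.  The total
    spectrum is exactly the sum of the per-state contributions.

    Returns a DataFrame with columns energy_ev, state_1..state_n, total.
    """
    energies = []
    strengths = []
    for de, mu in snapshot_sets:
        de = np.asarray(de, float)
        mu = np.atleast_2d(np.asarray(mu, float))
        energies.append(de * HARTREE_TO_EV)
        strengths.append((2.0 / 3.0) * de * np.sum(mu**2, axis=1))
    energies = np.array(energies)  # (n_snap, n_states)
    strengths = np.array(strengths)
    n_states = energies.shape[1]
    if grid_ev is None:
        lo = energies.min() - 4.0 * broadening_ev
        hi = energies.max() + 4.0 * broadening_ev
        grid_ev = np.linspace(lo, hi, 400)
    norm = 1.0 / (broadening_ev * np.sqrt(2.0 * np.pi) * len(energies))
    out = pd.DataFrame({"energy_ev": grid_ev})
    total = np.zeros_like(grid_ev)
    for k in range(n_states):
        contrib = norm * np.sum(
            strengths[:, k, None]
            * np.exp(-((grid_ev[None, :] - energies[:, k, None]) ** 2)
                     / (2.0 * broadening_ev**2)),
            axis=0,
        )
        out[f"state_{k + 1}"] = contrib
        total += contrib
    out["total"] = total
    return out
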