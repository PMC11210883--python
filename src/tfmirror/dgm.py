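"""Benchmark simulators: a negative-binomial autoregressive factor model with
phylogenetic noise and uneven sequencing depth, plus a perturbed
predator-prey (Lotka-Volterra) toy system.

The count model draws, per subject i and time t,

    y_t ~ NB(b exp(theta_t), phi)        (mean-dispersion: var = mu + mu^2/phi)
    theta_t = sum_p A_p theta_{t-p} + sum_q (B_q + C_q . z) w_{t-q} + eps_t
    b ~ Gamma(shape 10, scale lambda),   eps_t ~ N(0, Sigma)

with low-rank A/B/C, Sigma_{jj'} = (1 + d_{jj'})^{-alpha} from cophenetic
distances on a balanced binary tree, and exact-zero intervention rows for
null taxa so ground truth is known by construction.
"""

from __future__ import annotations

import dataclasses
import json
import logging

import numpy as np
from scipy.integrate import solve_ivp

from .ts_data import StudyCollection

logger = logging.getLogger(__name__)

__all__ = [
    "DGMParams",
    "TruthLabels",
    "LVParams",
    "phylo_covariance",
    "generate_params",
    "simulate_dataset",
    "pulse_schedule",
    "truth_labels",
    "lv_simulate",
]

_ZERO_TOL = 1e-10


# ---------------------------------------------------------------------------
# phylogenetic covariance
# ---------------------------------------------------------------------------

def phylo_covariance(n_leaves: int, alpha: float, J: int | None = None) -> np.ndarray:
    """Sigma_{jj'} = (1 + d_{jj'})^{-alpha} on a balanced binary tree.

    Branch lengths are 1, so the cophenetic distance between leaves j and j'
    is twice the number of levels up to their lowest common ancestor.
    ``n_leaves`` must be a power of 2; ``J`` (default ``n_leaves``) keeps the
    first J leaves, a principal submatrix and therefore still PSD.
    """
    if n_leaves < 2 or (n_leaves & (n_leaves - 1)) != 0:
        raise ValueError(f"n_leaves must be a power of 2 >= 2, got {n_leaves}")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    J = n_leaves if J is None else J
    if J > n_leaves:
        raise ValueError("J cannot exceed n_leaves")
    idx = np.arange(J)
    xor = idx[:, None] ^ idx[None, :]
    levels = np.zeros((J, J), dtype=int)
    nz = xor > 0
    levels[nz] = np.floor(np.log2(xor[nz])).astype(int) + 1
    d = 2 * levels
    return (1.0 + d) ** (-alpha)


# ---------------------------------------------------------------------------
# parameter generation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DGMParams:
    """Full parameterization of the count simulator."""

    J: int
    D: int
    S: int
    P: int                       # autoregressive lags
    Q: int                       # intervention lags
    A: np.ndarray                # (P, J, J)
    B: np.ndarray                # (Q, J, D)
    C: np.ndarray                # (Q, S, J, D); empty when S == 0
    phi: float
    depth_shape: float
    depth_scale: float           # lambda
    alpha: float
    nonnull_taxa: np.ndarray     # sorted indices of directly affected taxa
    pi_nonnull: float
    signal_strength: float
    rank: int
    seed: int
    sigma_scale: float = 1.0  # multiplies Sigma; 0 disables latent noise

    def sigma(self) -> np.ndarray:
        n_leaves = 1 << max(1, int(np.ceil(np.log2(self.J))))
        return self.sigma_scale * phylo_covariance(n_leaves, self.alpha, J=self.J)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("A", "B", "C", "nonnull_taxa"):
            d[key] = getattr(self, key).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DGMParams":
        d = dict(d)
        for key in ("A", "B", "C"):
            d[key] = np.asarray(d[key], dtype=float)
        d["nonnull_taxa"] = np.asarray(d["nonnull_taxa"], dtype=int)
        return cls(**d)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)


@dataclasses.dataclass
class TruthLabels:
    """Per-lag nonnull indicators, ``labels[h-1, j]`` for lags 1..h_max."""

    labels: np.ndarray  # (h_max, J) bool

    @property
    def h_max(self) -> int:
        return self.labels.shape[0]

    def nonnull(self, h: int) -> np.ndarray:
        return self.labels[h - 1]


def _companion_radius(A: np.ndarray) -> float:
    P, J, _ = A.shape
    comp = np.zeros((P * J, P * J))
    comp[:J] = A.transpose(1, 0, 2).reshape(J, P * J)
    if P > 1:
        comp[J:, : (P - 1) * J] = np.eye((P - 1) * J)
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def generate_params(
    J: int,
    D: int = 1,
    S: int = 0,
    rank: int = 2,
    pi_nonnull: float = 0.2,
    signal_strength: float = 1.0,
    P: int = 1,
    Q: int = 1,
    alpha: float = 10.0,
    lam: float = 0.1,
    phi: float = 1.0,
    seed: int = 0,
    target_radius: float = 0.8,
    sigma_scale: float = 1.0,
) -> DGMParams:
    """Draw a low-rank, stationary parameter set with exact ground truth.

    Each A_p is a rank-``rank`` Gaussian factor product rescaled (shrinking in
    bounded steps) until the companion-form spectral radius falls below
    ``target_radius``.  B_q and C_q are low-rank with rows outside the
    nonnull set zeroed exactly, then multiplied by ``signal_strength``.
    """
    if not 0 <= pi_nonnull <= 1:
        raise ValueError("pi_nonnull must lie in [0, 1]")
    if rank > J or (D and rank > max(J, D)):
        raise ValueError("rank exceeds matrix dimensions")
    rng = np.random.default_rng(seed)

    A = np.stack(
        [rng.normal(size=(J, rank)) @ rng.normal(size=(rank, J)) / np.sqrt(J * rank)
         for _ in range(P)]
    )
    for _ in range(100):
        if _companion_radius(A) < target_radius:
            break
        A *= 0.7
    else:
        raise RuntimeError("could not rescale A to a stationary regime")

    n_nonnull = int(np.ceil(pi_nonnull * J))
    nonnull = np.sort(rng.choice(J, size=n_nonnull, replace=False)) if n_nonnull else np.array([], dtype=int)
    null_mask = np.ones(J, dtype=bool)
    null_mask[nonnull] = False

    def low_rank_effect(shape_cols: int) -> np.ndarray:
        r = min(rank, shape_cols, J)
        M = rng.normal(size=(J, r)) @ rng.normal(size=(r, shape_cols)) / np.sqrt(r)
        M[null_mask] = 0.0
        return signal_strength * M

    B = np.stack([low_rank_effect(D) for _ in range(Q)])
    if S:
        C = np.stack([np.stack([low_rank_effect(D) for _ in range(S)]) for _ in range(Q)])
    else:
        C = np.zeros((Q, 0, J, D))
    return DGMParams(
        J=J, D=D, S=S, P=P, Q=Q, A=A, B=B, C=C, phi=phi,
        depth_shape=10.0, depth_scale=lam, alpha=alpha,
        nonnull_taxa=nonnull, pi_nonnull=pi_nonnull,
        signal_strength=signal_strength, rank=rank, seed=seed,
        sigma_scale=sigma_scale,
    )


def truth_labels(params: DGMParams, h_max: int) -> TruthLabels:
    """Lag-budgeted reachability: taxon j is nonnull at lag h when it has a
    nonzero row of B_q (or C_q) for some q <= h, or is reachable from such a
    taxon through A_p links with total lag <= h."""
    J = params.J
    direct_at = np.zeros((h_max + 1, J), dtype=bool)  # effect arriving exactly at lag q
    for q in range(1, min(params.Q, h_max) + 1):
        hit = np.abs(params.B[q - 1]).max(axis=1) > _ZERO_TOL
        if params.S:
            hit |= np.abs(params.C[q - 1]).max(axis=(0, 2)) > _ZERO_TOL
        direct_at[q] |= hit
    adj = [np.abs(params.A[p - 1]) > _ZERO_TOL for p in range(1, params.P + 1)]

    # reach[h] = taxa whose latent state is shifted at exactly lag h (or earlier
    # propagation arriving at h); build cumulatively
    reach = np.zeros((h_max + 1, J), dtype=bool)
    for h in range(1, h_max + 1):
        r = direct_at[h].copy()
        for p in range(1, min(params.P, h) + 1):
            src = reach[h - p]
            if src.any():
                r |= adj[p - 1][:, src].any(axis=1)
        reach[h] = r
    labels = np.zeros((h_max, J), dtype=bool)
    acc = np.zeros(J, dtype=bool)
    for h in range(1, h_max + 1):
        acc |= reach[h]
        labels[h - 1] = acc
    return TruthLabels(labels=labels)


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------

def pulse_schedule(
    n_subjects: int, T: int, D: int = 1, onset: int = 10, duration: int = 5
) -> np.ndarray:
    """One contiguous intervention pulse per subject, ``(n, D, T)``."""
    w = np.zeros((n_subjects, D, T))
    w[:, :, onset : onset + duration] = 1.0
    return w


def simulate_dataset(
    params: DGMParams,
    n_subjects: int,
    T: int,
    schedule: np.ndarray | None = None,
    z: np.ndarray | None = None,
    burn_in: int = 20,
    h_max: int = 5,
    seed: int = 0,
) -> tuple[StudyCollection, TruthLabels]:
    """Simulate counts for ``n_subjects`` subjects over ``T`` timepoints.

    The latent recursion starts at 0 and a ``burn_in`` prefix (with the
    intervention off) is discarded.  ``schedule`` is ``(n, D, T)`` (default:
    one pulse per subject); ``z`` is ``(n, S)``.
    """
    rng = np.random.default_rng(seed)
    J, D, S = params.J, params.D, params.S
    if schedule is None:
        schedule = pulse_schedule(n_subjects, T, D=D, onset=max(1, T // 3), duration=max(1, T // 6))
    schedule = np.asarray(schedule, dtype=float)
    if schedule.shape != (n_subjects, D, T):
        raise ValueError(f"schedule must have shape {(n_subjects, D, T)}, got {schedule.shape}")
    if S:
        if z is None:
            z = rng.integers(0, 2, size=(n_subjects, S)).astype(float)
        z = np.asarray(z, dtype=float)
        if z.shape != (n_subjects, S):
            raise ValueError(f"z must have shape {(n_subjects, S)}")
    else:
        z = np.zeros((n_subjects, 0))

    sigma = params.sigma()
    if np.allclose(sigma, 0):
        L = np.zeros_like(sigma)
    else:
        # tiny jitter keeps Cholesky defined in the near-singular alpha regimes
        L = np.linalg.cholesky(sigma + 1e-10 * np.eye(J))

    total = burn_in + T
    subjects = [f"S{i + 1}" for i in range(n_subjects)]
    abundances, interventions, covariates, time_grid = {}, {}, {}, {}
    maxlag = max(params.P, params.Q)
    for i, subj in enumerate(subjects):
        w_full = np.zeros((D, total))
        w_full[:, burn_in:] = schedule[i]
        theta = np.zeros((J, total + maxlag))  # leading zeros = pre-history
        eps = L @ rng.standard_normal(size=(J, total))
        for t in range(total):
            tt = t + maxlag
            th = eps[:, t].copy()
            for p in range(1, params.P + 1):
                th += params.A[p - 1] @ theta[:, tt - p]
            for q in range(1, params.Q + 1):
                if t - q >= 0:
                    w_lag = w_full[:, t - q]
                    eff = params.B[q - 1]
                    if S:
                        eff = eff + np.tensordot(z[i], params.C[q - 1], axes=(0, 0))
                    th += eff @ w_lag
            theta[:, tt] = th
        theta_kept = theta[:, maxlag + burn_in :]
        if np.max(theta_kept) > 50:
            raise OverflowError(
                "exp(theta) overflow; reduce signal strength or noise scale"
            )
        b = rng.gamma(shape=params.depth_shape, scale=params.depth_scale)
        mu = b * np.exp(theta_kept)
        p_nb = params.phi / (params.phi + mu)
        counts = rng.negative_binomial(params.phi, p_nb).astype(float)
        abundances[subj] = counts
        interventions[subj] = schedule[i].copy()
        covariates[subj] = z[i]
        time_grid[subj] = np.arange(T, dtype=float)

    collection = StudyCollection(
        subjects=subjects,
        abundances=abundances,
        interventions=interventions,
        covariates=covariates,
        taxa=[f"tax{j + 1}" for j in range(J)],
        intervention_names=[f"w{d + 1}" for d in range(D)],
        covariate_names=[f"z{s + 1}" for s in range(S)],
        time_grid=time_grid,
    )
    return collection, truth_labels(params, h_max)


# ---------------------------------------------------------------------------
# Lotka-Volterra toy
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LVParams:
    """Predator-prey system with a switched prey growth rate.

    Inside the perturbation windows the prey growth rate ``b1`` is replaced
    by ``b1_perturbed``.
    """

    b1: float = 2.0
    b2: float = 1.0
    a12: float = 1.0
    a21: float = 1.0
    delta: float = 0.2
    horizon: float = 10.0
    perturbations: tuple[tuple[float, float], ...] = ((3.0, 4.0), (8.0, 9.0))
    b1_perturbed: float = 1.0
    init_low: float = 0.0
    init_high: float = 4.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        for lo, hi in self.perturbations:
            if not (0 <= lo < hi <= self.horizon):
                raise ValueError(f"perturbation window ({lo}, {hi}) outside [0, horizon]")

    def perturbed(self, t: float) -> bool:
        return any(lo <= t < hi for lo, hi in self.perturbations)

    def b1_at(self, t: float) -> float:
        return self.b1_perturbed if self.perturbed(t) else self.b1


def lv_step(params: LVParams, y1: float, y2: float, t: float) -> tuple[float, float]:
    """One discrete Euler update of the perturbed system."""
    b1 = params.b1_at(t)
    d = params.delta
    y1_next = (1 + d * b1 - d * params.a12 * y2) * y1
    y2_next = (1 - d * params.b2 + d * params.a21 * y1) * y2
    return y1_next, y2_next


def lv_invariant(params: LVParams, y1: np.ndarray, y2: np.ndarray) -> np.ndarray:
    """Conserved quantity of the unperturbed continuous system."""
    return (
        params.a21 * y1 - params.b2 * np.log(y1)
        + params.a12 * y2 - params.b1 * np.log(y2)
    )


def lv_simulate(
    params: LVParams,
    n_subjects: int,
    seed: int = 0,
    mode: str = "discrete",
    rtol: float = 1e-10,
) -> StudyCollection:
    """Simulate prey/predator trajectories plus the binary perturbation series.

    ``discrete`` iterates the Euler recursion at step ``delta``; ``continuous``
    integrates the ODE segment-wise (the growth rate switches at window
    boundaries) and samples the solution on the same grid.
    """
    if mode not in ("discrete", "continuous"):
        raise ValueError("mode must be 'discrete' or 'continuous'")
    rng = np.random.default_rng(seed)
    n_steps = int(round(params.horizon / params.delta))
    times = params.delta * np.arange(n_steps + 1)
    w_series = np.array([1.0 if params.perturbed(t) else 0.0 for t in times])[None, :]

    subjects = [f"S{i + 1}" for i in range(n_subjects)]
    abundances, interventions, covariates, time_grid = {}, {}, {}, {}
    for subj in subjects:
        y0 = rng.uniform(params.init_low, params.init_high, size=2)
        traj = np.empty((2, n_steps + 1))
        traj[:, 0] = y0
        if mode == "discrete":
            y1, y2 = float(y0[0]), float(y0[1])
            for k in range(n_steps):
                y1, y2 = lv_step(params, y1, y2, float(times[k]))
                traj[:, k + 1] = (y1, y2)
        else:
            def rhs(t, y):
                b1 = params.b1_at(t)
                return [
                    b1 * y[0] - params.a12 * y[0] * y[1],
                    -params.b2 * y[1] + params.a21 * y[0] * y[1],
                ]

            breaks = sorted({0.0, params.horizon}
                            | {b for w in params.perturbations for b in w
                               if 0 < b < params.horizon})
            y = np.array(y0, dtype=float)
            for lo, hi in zip(breaks[:-1], breaks[1:]):
                mask = (times >= lo - 1e-12) & (times <= hi + 1e-12)
                sol = solve_ivp(
                    rhs, (lo, hi), y, t_eval=times[mask],
                    rtol=rtol, atol=1e-12, dense_output=False, method="RK45",
                )
                traj[:, mask] = sol.y
                y = sol.y[:, -1]
        abundances[subj] = traj
        interventions[subj] = w_series.copy()
        covariates[subj] = np.zeros(0)
        time_grid[subj] = times.copy()
    return StudyCollection(
        subjects=subjects,
        abundances=abundances,
        interventions=interventions,
        covariates=covariates,
        taxa=["prey", "predator"],
        intervention_names=["perturbation"],
        covariate_names=[],
        time_grid=time_grid,
    )
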