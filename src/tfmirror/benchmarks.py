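"""Reusable benchmark experiments over the synthetic data generator.

These drive both the acceptance test suite and ``scripts/acceptance.py``:
each function regenerates its data from scratch, runs the full pipeline, and
measures the outcome against the simulator's ground truth.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import stats

from .dgm import DGMParams, generate_params, simulate_dataset, truth_labels
from .mirrors import lagged_mirrors, mirror_statistics, multi_split_select, pd_effects, split_and_fit
from .normalize import NormalizationSpec, apply_normalization
from .transfer_model import BoostingConfig

logger = logging.getLogger(__name__)

__all__ = ["fdr_control_benchmark", "null_symmetry_benchmark", "lagged_chain_benchmark"]

# The headline inferential setting: many taxa, 20% directly affected with a
# strong intervention shift, near-diagonal phylogenetic covariance
# (alpha = 10), dispersed sequencing depth (lambda = 0.1), asinh-transformed
# size-factor normalized counts, 25-split mirror selection at q = 0.2.
T1_SETTINGS = dict(
    J=200, pi_nonnull=0.2, signal_strength=3.0, alpha=10.0, lam=0.1, phi=1.0,
    n_subjects=12, T=30, P=2, Q=2, q=0.2, n_splits=25, n_iterations=300,
)


def _boost_config(n_iterations: int, seed: int) -> BoostingConfig:
    return BoostingConfig(
        n_iterations=n_iterations,
        learning_rate=0.1,
        max_interactions=0,
        screen_method="none",
        random_seed=seed,
    )


@dataclasses.dataclass
class FDRBenchmarkResult:
    fdp: list[float]
    power: list[float]
    n_selected: list[int]

    @property
    def mean_fdp(self) -> float:
        return float(np.mean(self.fdp))

    @property
    def mean_power(self) -> float:
        return float(np.mean(self.power))


def fdr_control_benchmark(
    seed: int = 1, n_replicates: int = 10, **overrides
) -> FDRBenchmarkResult:
    """Mean false-discovery proportion of multi-split mirror selection.

    For each replicate: generate a dataset (replicate r uses parameter seed
    ``seed + r`` and independent simulation/selection seeds), size-factor +
    asinh normalize, run 25-split selection at the target level, and score
    the selection against the lag-1 ground truth.
    """
    s = {**T1_SETTINGS, **overrides}
    fdps, powers, sizes = [], [], []
    for r in range(n_replicates):
        rep_seed = seed + r
        params = generate_params(
            J=s["J"], pi_nonnull=s["pi_nonnull"], signal_strength=s["signal_strength"],
            P=1, Q=1, alpha=s["alpha"], lam=s["lam"], phi=s["phi"], seed=rep_seed,
        )
        coll, truth = simulate_dataset(
            params, n_subjects=s["n_subjects"], T=s["T"], seed=rep_seed + 10_000
        )
        coll, _ = apply_normalization(coll, NormalizationSpec(method="size_factor_asinh"))
        config = _boost_config(s["n_iterations"], rep_seed)
        res = multi_split_select(
            coll, config, P=s["P"], Q=s["Q"], q=s["q"],
            n_splits=s["n_splits"], seed=rep_seed + 20_000,
        )
        sel = res.selected
        nonnull = truth.nonnull(1)
        fdps.append(float((sel & ~nonnull).sum() / max(int(sel.sum()), 1)))
        powers.append(float((sel & nonnull).sum() / max(int(nonnull.sum()), 1)))
        sizes.append(int(sel.sum()))
        logger.info("replicate %d: %d selected, FDP %.3f, power %.3f",
                    r + 1, sizes[-1], fdps[-1], powers[-1])
    return FDRBenchmarkResult(fdp=fdps, power=powers, n_selected=sizes)


def null_symmetry_benchmark(
    seed: int = 1, n_replicates: int = 20, J: int = 200,
    n_subjects: int = 12, T: int = 30, n_iterations: int = 300,
) -> list[float]:
    """Two-sided binomial p-values for sign fairness of null mirrors.

    Each replicate simulates with the intervention effect switched off
    (B = C = 0 via zero signal strength), computes one split's mirror vector,
    and tests whether positive signs occur at the fair-coin rate.
    """
    pvals = []
    for r in range(n_replicates):
        rep_seed = seed + r
        params = generate_params(
            J=J, pi_nonnull=0.2, signal_strength=0.0, P=1, Q=1,
            alpha=10.0, lam=0.1, phi=1.0, seed=rep_seed,
        )
        coll, _ = simulate_dataset(params, n_subjects=n_subjects, T=T, seed=rep_seed + 10_000)
        coll, _ = apply_normalization(coll, NormalizationSpec(method="size_factor_asinh"))
        config = _boost_config(n_iterations, rep_seed)
        pair = split_and_fit(coll, config, P=2, Q=2, seed=rep_seed + 20_000)
        W_on, W_off = np.ones((coll.D, 2)), np.zeros((coll.D, 2))
        M = mirror_statistics(
            pd_effects(pair.model1, pair.design1, W_on, W_off),
            pd_effects(pair.model2, pair.design2, W_on, W_off),
        )
        nz = M[M != 0]
        k = int((nz > 0).sum())
        pvals.append(float(stats.binomtest(k, len(nz), 0.5).pvalue))
    return pvals


def chain_params(J: int = 10, b_effect: float = 3.0, a_link: float = 0.8,
                 phi: float = 10.0, lam: float = 10.0) -> DGMParams:
    """A sparse linear-chain parameterization: the intervention shifts taxon 1
    at lag 1 and taxon 2 only through taxon 1's lag-1 autoregressive link."""
    A = np.zeros((1, J, J))
    A[0, 1, 0] = a_link
    B = np.zeros((1, J, 1))
    B[0, 0, 0] = b_effect
    return DGMParams(
        J=J, D=1, S=0, P=1, Q=1, A=A, B=B, C=np.zeros((1, 0, J, 1)),
        phi=phi, depth_shape=10.0, depth_scale=lam, alpha=10.0,
        nonnull_taxa=np.array([0]), pi_nonnull=1 / J, signal_strength=b_effect,
        rank=1, seed=0,
    )


def lagged_chain_benchmark(
    seed: int = 1, n_runs: int = 10, J: int = 10, n_subjects: int = 30,
    T: int = 30, n_splits: int = 15, n_iterations: int = 300, q: float = 0.2,
) -> dict:
    """Fraction of runs in which the indirectly-affected chain taxon is
    selected at lag 2 but not at lag 1."""
    params = chain_params(J=J)
    truth = truth_labels(params, h_max=2)
    assert list(np.flatnonzero(truth.nonnull(1))) == [0]
    assert list(np.flatnonzero(truth.nonnull(2))) == [0, 1]

    lag1_hits, lag2_hits, successes = 0, 0, 0
    for r in range(n_runs):
        rep_seed = seed + r
        coll, _ = simulate_dataset(params, n_subjects=n_subjects, T=T, seed=rep_seed + 10_000)
        coll, _ = apply_normalization(coll, NormalizationSpec(method="size_factor_asinh"))
        config = _boost_config(n_iterations, rep_seed)
        results = lagged_mirrors(
            coll, config, P=2, Q=2, q=q, h_max=2,
            n_splits=n_splits, seed=rep_seed + 20_000,
        )
        in_lag1 = bool(results[0].selected[1])
        in_lag2 = bool(results[1].selected[1])
        lag1_hits += in_lag1
        lag2_hits += in_lag2
        successes += (in_lag2 and not in_lag1)
    return {
        "success_rate": successes / n_runs,
        "lag1_rate": lag1_hits / n_runs,
        "lag2_rate": lag2_hits / n_runs,
    }
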