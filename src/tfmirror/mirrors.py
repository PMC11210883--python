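"""Selective inference via data splitting and mirror statistics.

Subjects are split in half, a transfer-function model is fitted on each half
from nonoverlapping trajectory segments, and the per-taxon intervention
effect is estimated on each half as a partial-dependence contrast between an
"on" and an "off" intervention path.  The mirror statistic rewards
sign-agreement across splits; a threshold is chosen so that an empirical FDR
estimate stays below the target level, and evidence is aggregated over many
random splits through inclusion rates.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .transfer_model import (
    BoostingConfig,
    TransferFunctionModel,
    fit,
    screen_interactions,
)
from .ts_data import LaggedDesign, StudyCollection, tile_windows

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPair",
    "MirrorResult",
    "split_and_fit",
    "pd_effect",
    "pd_effects",
    "mirror_statistics",
    "fdr_hat",
    "select_taxa",
    "multi_split_select",
    "lagged_mirrors",
]


@dataclasses.dataclass
class SplitPair:
    """Two disjoint subject halves with their fitted models and designs."""

    subjects1: list[str]
    subjects2: list[str]
    model1: TransferFunctionModel
    model2: TransferFunctionModel
    design1: LaggedDesign
    design2: LaggedDesign
    seed: int


@dataclasses.dataclass
class MirrorResult:
    """Mirror statistics, FDR curve, threshold and selection for one run."""

    taxa: list[str]
    mirrors: np.ndarray
    threshold: float
    selected: np.ndarray  # bool (J,)
    q: float
    fdr_curve: list[tuple[float, float]]
    pd1: np.ndarray | None = None
    pd2: np.ndarray | None = None
    lag: int = 1
    per_split_selected: list[np.ndarray] | None = None
    per_split_mirrors: list[np.ndarray] | None = None
    inclusion_rates: np.ndarray | None = None
    n_splits: int = 1
    seed: int | None = None

    @property
    def selection_set(self) -> list[str]:
        return [t for t, s in zip(self.taxa, self.selected) if s]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "taxon": self.taxa,
                "mirror": self.mirrors,
                "selected": self.selected,
                "lag": self.lag,
            }
        )
        if self.pd1 is not None:
            df.insert(1, "pd1", self.pd1)
            df.insert(2, "pd2", self.pd2)
        if self.inclusion_rates is not None:
            df["inclusion_rate"] = self.inclusion_rates
        return df


# ---------------------------------------------------------------------------
# split construction
# ---------------------------------------------------------------------------

def split_and_fit(
    collection: StudyCollection,
    config: BoostingConfig,
    P: int,
    Q: int,
    seed: int,
    stride: int | None = None,
) -> SplitPair:
    """Randomly halve the subjects and fit one model per half.

    Fits use fully disjoint trajectory segments (default stride
    ``max(P, Q) + 1``).  Interaction screening follows ``config`` on each
    half's own design.
    """
    if collection.n_subjects < 2:
        raise ValueError("data splitting requires at least 2 subjects")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(collection.n_subjects)
    half = collection.n_subjects // 2
    s1 = [collection.subjects[i] for i in sorted(perm[:half])]
    s2 = [collection.subjects[i] for i in sorted(perm[half:])]
    stride = stride if stride is not None else max(P, Q) + 1

    halves = []
    for subset in (s1, s2):
        sub = collection.subset_subjects(subset)
        base = tile_windows(sub, P, Q, stride=stride)
        pairs = screen_interactions(base, config=config)
        design = tile_windows(sub, P, Q, stride=stride, interactions=pairs)
        model = fit(
            design,
            config=config,
            taxa=sub.taxa,
            intervention_names=sub.intervention_names,
            covariate_names=sub.covariate_names,
        )
        halves.append((model, design))
    return SplitPair(
        subjects1=s1,
        subjects2=s2,
        model1=halves[0][0],
        model2=halves[1][0],
        design1=halves[0][1],
        design2=halves[1][1],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# partial-dependence effects
# ---------------------------------------------------------------------------

def _override_intervention_block(
    model: TransferFunctionModel, X_base: np.ndarray, W: np.ndarray
) -> np.ndarray:
    """Replace the intervention block of base rows by a fixed (D, Q) path
    (columns oldest -> newest)."""
    out = X_base.copy()
    J, D, P, Q = model.J, model.D, model.P, model.Q
    for q in range(Q):
        cols = P * J + q * D + np.arange(D)
        out[:, cols] = W[:, Q - 1 - q][None, :]
    return out


def pd_effects(
    model: TransferFunctionModel,
    design: LaggedDesign,
    W_on: np.ndarray,
    W_off: np.ndarray,
) -> np.ndarray:
    """Per-taxon average prediction contrast between two intervention paths.

    Abundance histories, covariates and recomputed interaction products are
    taken from the design's windows; only the ``(D, Q)`` intervention block is
    replaced.  Returns a length-J vector.
    """
    if design.n_rows == 0:
        raise ValueError("empty design")
    W_on = np.asarray(W_on, dtype=float)
    W_off = np.asarray(W_off, dtype=float)
    for name, W in (("W_on", W_on), ("W_off", W_off)):
        if W.shape != (model.D, model.Q):
            raise ValueError(f"{name} must have shape {(model.D, model.Q)}, got {W.shape}")
    X_base = design.X[:, : design.n_base]
    pred_on = model.predict_base_rows(_override_intervention_block(model, X_base, W_on))
    pred_off = model.predict_base_rows(_override_intervention_block(model, X_base, W_off))
    return (pred_on - pred_off).mean(axis=0)


def pd_effect(
    model: TransferFunctionModel,
    design: LaggedDesign,
    W_on: np.ndarray,
    W_off: np.ndarray,
    taxon: int | str,
) -> float:
    """Single-taxon convenience wrapper around :func:`pd_effects`."""
    j = model.taxa.index(taxon) if isinstance(taxon, str) else int(taxon)
    return float(pd_effects(model, design, W_on, W_off)[j])


def pd_effects_lagged(
    model: TransferFunctionModel,
    design: LaggedDesign,
    W_on_series: np.ndarray,
    W_off_series: np.ndarray,
    h_max: int,
) -> np.ndarray:
    """Per-lag PD effects from h-step substitution forecasts, ``(h_max, J)``.

    ``W_*_series`` are hypothetical intervention series of shape
    ``(D, Q + h_max - 1)`` spanning times t-Q+1 .. t+h_max-1 relative to each
    window's response time t; step k of the recursion uses columns
    ``k-1 .. k-1+Q-1`` as its intervention block.  Lag 1 equals
    :func:`pd_effects` on the corresponding ``(D, Q)`` block.
    """
    if design.n_rows == 0:
        raise ValueError("empty design")
    J, D, P, Q, S = model.J, model.D, model.P, model.Q, model.S
    need = Q + h_max - 1
    W_on_series = np.asarray(W_on_series, dtype=float)
    W_off_series = np.asarray(W_off_series, dtype=float)
    for name, W in (("W_on_series", W_on_series), ("W_off_series", W_off_series)):
        if W.shape != (D, need):
            raise ValueError(f"{name} must have shape {(D, need)}, got {W.shape}")
    X_base = design.X[:, : design.n_base]
    n = X_base.shape[0]
    # reconstruct the (n, J, P) history tensor, columns oldest -> newest
    H0 = np.empty((n, J, P))
    for p in range(1, P + 1):
        H0[:, :, P - p] = X_base[:, (p - 1) * J : p * J]
    Z = X_base[:, P * J + Q * D :]

    out = np.empty((h_max, J))
    preds = {}
    for arm, series in (("on", W_on_series), ("off", W_off_series)):
        H = H0.copy()
        arm_preds = np.empty((h_max, n, J))
        for k in range(1, h_max + 1):
            block = series[:, k - 1 : k - 1 + Q]  # oldest -> newest
            parts = [H[:, :, P - p] for p in range(1, P + 1)]
            for q in range(Q):
                parts.append(np.tile(block[:, Q - 1 - q], (n, 1)))
            if S:
                parts.append(Z)
            Xb = np.concatenate(parts, axis=1)
            pred = model.predict_base_rows(Xb)
            arm_preds[k - 1] = pred
            H = np.concatenate([H[:, :, 1:], pred[:, :, None]], axis=2)
        preds[arm] = arm_preds
    for h in range(h_max):
        out[h] = (preds["on"][h] - preds["off"][h]).mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# mirror statistics and thresholding
# ---------------------------------------------------------------------------

def mirror_statistics(pd1: np.ndarray, pd2: np.ndarray) -> np.ndarray:
    """M_j = sign(pd1_j * pd2_j) * (|pd1_j| + |pd2_j|); sign(0) = 0."""
    pd1 = np.asarray(pd1, dtype=float)
    pd2 = np.asarray(pd2, dtype=float)
    if pd1.shape != pd2.shape:
        raise ValueError("pd1 and pd2 must have equal length")
    return np.sign(pd1 * pd2) * (np.abs(pd1) + np.abs(pd2))


def fdr_hat(M: np.ndarray, t: float, plus_one: bool = False) -> float:
    """Estimated FDR at threshold t: |{M < -t}| / |{M > t}|.

    A zero denominator gives 0 when the numerator is also 0 and +inf
    otherwise (no selection possible at that threshold).  The optional
    ``plus_one`` adds a conservative +1 to the numerator.
    """
    if t <= 0:
        raise ValueError("threshold t must be positive")
    M = np.asarray(M, dtype=float)
    num = int(np.sum(M < -t)) + (1 if plus_one else 0)
    den = int(np.sum(M > t))
    if den == 0:
        return 0.0 if num == 0 else float("inf")
    return num / den


def select_taxa(
    M: np.ndarray,
    q: float,
    taxa: Sequence[str] | None = None,
    plus_one: bool = False,
    candidate_M: np.ndarray | None = None,
) -> MirrorResult:
    """Smallest threshold t* among candidate |M| values with FDR_hat <= q;
    selection is {j : M_j > t*}.

    ``candidate_M`` optionally supplies a pooled mirror vector from which both
    the candidate thresholds and the FDR_hat counts are taken (used by the
    lag-pooling variant); selection is always applied to ``M`` itself.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    M = np.asarray(M, dtype=float)
    pool = M if candidate_M is None else np.asarray(candidate_M, dtype=float)
    candidates = np.unique(np.abs(pool))
    candidates = candidates[candidates > 0]
    curve = [(float(t), fdr_hat(pool, t, plus_one=plus_one)) for t in candidates]
    t_star = float("inf")
    for t, f in curve:
        if f <= q:
            t_star = t
            break
    selected = M > t_star if np.isfinite(t_star) else np.zeros_like(M, dtype=bool)
    taxa = list(taxa) if taxa is not None else [f"tax{j + 1}" for j in range(len(M))]
    return MirrorResult(
        taxa=taxa,
        mirrors=M,
        threshold=t_star,
        selected=selected,
        q=q,
        fdr_curve=curve,
    )


def aggregate_inclusion(
    per_split_selected: Sequence[np.ndarray], q: float
) -> tuple[np.ndarray, np.ndarray]:
    """Multi-split aggregation by inclusion rates.

    I_j = mean over splits of 1{j selected} / |selection|; splits with empty
    selections contribute 0.  Rates are sorted ascending and the largest
    prefix whose cumulative sum stays <= q is discarded; the remaining taxa
    are selected.  Returns (rates, selected_mask).
    """
    K = len(per_split_selected)
    J = len(per_split_selected[0])
    rates = np.zeros(J)
    for sel in per_split_selected:
        size = int(sel.sum())
        if size > 0:
            rates += sel.astype(float) / size
    rates /= K
    order = np.argsort(rates, kind="stable")
    csum = np.cumsum(rates[order])
    drop = csum <= q
    selected = np.ones(J, dtype=bool)
    selected[order[drop]] = False
    selected &= rates > 0
    return rates, selected


def _split_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32)]


def multi_split_select(
    collection: StudyCollection,
    config: BoostingConfig,
    P: int,
    Q: int,
    q: float,
    n_splits: int = 25,
    seed: int = 0,
    W_on: np.ndarray | None = None,
    W_off: np.ndarray | None = None,
    plus_one: bool = False,
) -> MirrorResult:
    """Run the full split -> PD -> mirror -> threshold pipeline ``n_splits``
    times and aggregate selections through inclusion rates."""
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    D = collection.D
    W_on = np.ones((D, Q)) if W_on is None else np.asarray(W_on, dtype=float)
    W_off = np.zeros((D, Q)) if W_off is None else np.asarray(W_off, dtype=float)

    seeds = _split_seeds(seed, n_splits)
    per_sel, per_M = [], []
    last = None
    for k, sk in enumerate(seeds):
        pair = split_and_fit(collection, config, P, Q, seed=sk)
        pd1 = pd_effects(pair.model1, pair.design1, W_on, W_off)
        pd2 = pd_effects(pair.model2, pair.design2, W_on, W_off)
        M = mirror_statistics(pd1, pd2)
        res = select_taxa(M, q, taxa=collection.taxa, plus_one=plus_one)
        res.pd1, res.pd2 = pd1, pd2
        per_sel.append(res.selected)
        per_M.append(M)
        last = res
    if n_splits == 1:
        last.n_splits = 1
        last.seed = seed
        last.per_split_selected = per_sel
        last.per_split_mirrors = per_M
        last.inclusion_rates, _ = aggregate_inclusion(per_sel, q)
        return last
    rates, selected = aggregate_inclusion(per_sel, q)
    return MirrorResult(
        taxa=list(collection.taxa),
        mirrors=np.mean(per_M, axis=0),
        threshold=float("nan"),
        selected=selected,
        q=q,
        fdr_curve=[],
        pd1=last.pd1,
        pd2=last.pd2,
        per_split_selected=per_sel,
        per_split_mirrors=per_M,
        inclusion_rates=rates,
        n_splits=n_splits,
        seed=seed,
    )


def lagged_mirrors(
    collection: StudyCollection,
    config: BoostingConfig,
    P: int,
    Q: int,
    q: float,
    h_max: int,
    n_splits: int = 25,
    seed: int = 0,
    pool_lags: bool = True,
    plus_one: bool = False,
) -> list[MirrorResult]:
    """Per-lag mirror selection from h-step substitution forecasts.

    For each split, one recursive forecast pass under the all-on and all-off
    hypothetical intervention series yields PD effects for every lag
    h' <= h_max.  When ``pool_lags`` is set, the lag-h threshold is chosen
    from the mirrors of all lags h' <= h pooled together (selection still
    applies to the lag-h mirrors); otherwise each lag is thresholded on its
    own mirrors.
    """
    if h_max < 1:
        raise ValueError("h_max must be >= 1")
    D = collection.D
    need = Q + h_max - 1
    on_series = np.ones((D, need))
    off_series = np.zeros((D, need))

    seeds = _split_seeds(seed, n_splits)
    # per split: (h_max, J) mirrors
    split_mirrors = []
    for sk in seeds:
        pair = split_and_fit(collection, config, P, Q, seed=sk)
        pd1 = pd_effects_lagged(pair.model1, pair.design1, on_series, off_series, h_max)
        pd2 = pd_effects_lagged(pair.model2, pair.design2, on_series, off_series, h_max)
        split_mirrors.append(mirror_statistics(pd1, pd2))

    results = []
    for h in range(1, h_max + 1):
        per_sel, per_M = [], []
        for Mk in split_mirrors:
            M_h = Mk[h - 1]
            pooled = Mk[:h].ravel() if pool_lags else M_h
            res = select_taxa(M_h, q, taxa=collection.taxa, plus_one=plus_one,
                              candidate_M=pooled)
            per_sel.append(res.selected)
            per_M.append(M_h)
        if n_splits == 1:
            rates, selected = aggregate_inclusion(per_sel, q)
            selected = per_sel[0]
        else:
            rates, selected = aggregate_inclusion(per_sel, q)
        results.append(
            MirrorResult(
                taxa=list(collection.taxa),
                mirrors=np.mean(per_M, axis=0),
                threshold=float("nan"),
                selected=selected,
                q=q,
                fdr_curve=[],
                lag=h,
                per_split_selected=per_sel,
                per_split_mirrors=per_M,
                inclusion_rates=rates,
                n_splits=n_splits,
                seed=seed,
            )
        )
    return results
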