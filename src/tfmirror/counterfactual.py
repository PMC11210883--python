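"""Counterfactual trajectory simulation under contrasting intervention paths."""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .transfer_model import TransferFunctionModel, forecast
from .ts_data import StudyCollection

logger = logging.getLogger(__name__)

__all__ = [
    "CounterfactualResult",
    "simulate_counterfactuals",
    "summarize_differences",
    "select_representative_taxa",
]


@dataclasses.dataclass
class CounterfactualResult:
    """Per subject x taxon x horizon forecasts under two intervention arms."""

    subjects: list[str]
    taxa: list[str]
    horizon: int
    y_on: np.ndarray   # (n_subjects, J, horizon)
    y_off: np.ndarray
    W_on: np.ndarray   # (D, horizon)
    W_off: np.ndarray
    z_override: np.ndarray | None = None

    @property
    def diff(self) -> np.ndarray:
        return self.y_on - self.y_off

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, subj in enumerate(self.subjects):
            for j, tax in enumerate(self.taxa):
                for h in range(self.horizon):
                    rows.append(
                        (subj, tax, h + 1, self.y_on[i, j, h], self.y_off[i, j, h],
                         self.y_on[i, j, h] - self.y_off[i, j, h])
                    )
        return pd.DataFrame(rows, columns=["subject", "taxon", "horizon", "y_on", "y_off", "diff"])


def _default_anchor(collection: StudyCollection, subj: str, P: int) -> int:
    """Index of the launch time: intervention onset (first active time) when
    present and preceded by >= P history, otherwise the last observed time."""
    w = collection.interventions[subj]
    active = np.flatnonzero((w > 0).any(axis=0))
    T = w.shape[1]
    if len(active) and active[0] >= P:
        return int(active[0])
    return T - 1


def simulate_counterfactuals(
    model: TransferFunctionModel,
    collection: StudyCollection,
    W_on: np.ndarray,
    W_off: np.ndarray,
    horizon: int,
    z_override: np.ndarray | None = None,
    anchor: dict[str, int] | int | None = None,
) -> CounterfactualResult:
    """Forecast each subject under two hypothetical intervention paths.

    Both arms share the subject's observed history up to the anchor time
    (default: intervention onset when present, else the last observation).
    ``W_on`` / ``W_off`` are ``(D, horizon)``.  A covariate override, when
    supplied, replaces z in both arms.
    """
    W_on = np.asarray(W_on, dtype=float)
    W_off = np.asarray(W_off, dtype=float)
    for name, W in (("W_on", W_on), ("W_off", W_off)):
        if W.shape != (model.D, horizon):
            raise ValueError(f"{name} must have shape {(model.D, horizon)}, got {W.shape}")
    if z_override is not None:
        z_override = np.asarray(z_override, dtype=float)
        if model.S == 0 or z_override.shape != (model.S,):
            raise ValueError(
                f"z_override shape {z_override.shape} incompatible with model S={model.S}"
            )

    y_on = np.empty((collection.n_subjects, model.J, horizon))
    y_off = np.empty_like(y_on)
    for i, subj in enumerate(collection.subjects):
        if anchor is None:
            a = _default_anchor(collection, subj, model.P)
        elif isinstance(anchor, dict):
            a = anchor[subj]
        else:
            a = int(anchor)
        if a < model.P - 1:
            raise ValueError(
                f"anchor {a} for subject {subj!r} leaves fewer than P={model.P} observations"
            )
        sub = collection.subset_subjects([subj]).truncate(a + 1)
        if z_override is not None:
            sub.covariates[subj] = z_override.copy()
        y_on[i] = forecast(model, sub, W_on, horizon)[subj]
        y_off[i] = forecast(model, sub, W_off, horizon)[subj]
    return CounterfactualResult(
        subjects=list(collection.subjects),
        taxa=list(model.taxa),
        horizon=horizon,
        y_on=y_on,
        y_off=y_off,
        W_on=W_on,
        W_off=W_off,
        z_override=z_override,
    )


def summarize_differences(
    result: CounterfactualResult,
    quantiles: tuple[float, float, float] = (0.25, 0.5, 0.75),
    group_by: tuple[StudyCollection, str] | None = None,
) -> pd.DataFrame:
    """Quantile bands of subject-level counterfactual differences.

    Returns a tidy frame with per-taxon, per-horizon linear-interpolation
    (type-7) quantiles; when ``group_by = (collection, covariate_name)`` is
    given, bands are computed separately per level of a binary covariate.
    """
    if result.y_on.size == 0:
        raise ValueError("empty counterfactual result")
    q_lo, q_mid, q_hi = quantiles
    diff = result.diff  # (n, J, h)

    groups: dict[str, np.ndarray] = {"all": np.arange(len(result.subjects))}
    if group_by is not None:
        coll, cov = group_by
        s = coll.covariate_names.index(cov)
        values = np.array([coll.covariates[subj][s] for subj in result.subjects])
        levels = np.unique(values)
        if len(levels) > 2:
            raise ValueError(f"grouping covariate {cov!r} is not binary: levels {levels}")
        groups = {f"{cov}={lv:g}": np.flatnonzero(values == lv) for lv in levels}

    rows = []
    for label, idx in groups.items():
        sub = diff[idx]  # (n_g, J, h)
        lo = np.quantile(sub, q_lo, axis=0, method="linear")
        mid = np.quantile(sub, q_mid, axis=0, method="linear")
        hi = np.quantile(sub, q_hi, axis=0, method="linear")
        for j, tax in enumerate(result.taxa):
            for h in range(result.horizon):
                rows.append((label, tax, h + 1, lo[j, h], mid[j, h], hi[j, h]))
    return pd.DataFrame(rows, columns=["group", "taxon", "horizon", "q_lo", "q_mid", "q_hi"])


def select_representative_taxa(
    result: CounterfactualResult, every_kth: int
) -> list[str]:
    """Order taxa by their score on the first principal component of the
    taxon-by-(subject x horizon) difference matrix and return every k-th.

    The PC sign is fixed by forcing the loading with largest absolute value
    to be positive, so the ordering is deterministic.
    """
    if every_kth < 1:
        raise ValueError("every_kth must be a positive integer")
    J = len(result.taxa)
    if J < every_kth:
        raise ValueError(f"need at least {every_kth} taxa, have {J}")
    M = result.diff.transpose(1, 0, 2).reshape(J, -1)  # taxa as observations
    if np.allclose(M, 0):
        logger.warning("all counterfactual differences are zero; returning input order")
        return list(result.taxa)[::every_kth]
    Mc = M - M.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Mc, full_matrices=False)
    loading = Vt[0]
    if loading[np.argmax(np.abs(loading))] < 0:
        loading = -loading
    scores = Mc @ loading
    order = np.argsort(-scores, kind="stable")
    ordered = [result.taxa[k] for k in order]
    return ordered[::every_kth]


def plot_bands(summary: pd.DataFrame, taxa: Sequence[str] | None = None, ax=None):
    """Minimal quantile-band plot of summarize_differences output."""
    import matplotlib.pyplot as plt  # optional dependency, imported lazily

    taxa = list(taxa) if taxa is not None else sorted(summary["taxon"].unique())
    if ax is None:
        _, ax = plt.subplots()
    for tax in taxa:
        for label, grp in summary[summary["taxon"] == tax].groupby("group"):
            grp = grp.sort_values("horizon")
            ax.fill_between(grp["horizon"], grp["q_lo"], grp["q_hi"], alpha=0.3)
            ax.plot(grp["horizon"], grp["q_mid"], label=f"{tax} ({label})")
    ax.set_xlabel("horizon")
    ax.set_ylabel("counterfactual difference")
    ax.legend(fontsize="small")
    return ax
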