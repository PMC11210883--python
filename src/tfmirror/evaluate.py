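"""Forecasting and inference metrics: cross-validated MAE by horizon, FDP and
power by lag against simulator ground truth, and a pre/post t-test + BH
baseline."""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dgm import TruthLabels
from .transfer_model import BoostingConfig, fit_collection, forecast
from .ts_data import StudyCollection

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "cv_forecast_mae",
    "fdp_power_by_lag",
    "prepost_ttest",
]


@dataclasses.dataclass
class EvaluationReport:
    """Per-fold, per-horizon MAE plus fold assignments."""

    mae: np.ndarray                  # (n_folds, h_max), NaN where no forecast
    fold_subjects: list[list[str]]
    h_max: int
    seed: int

    @property
    def mae_by_horizon(self) -> np.ndarray:
        return np.nanmean(self.mae, axis=0)

    @property
    def mae_overall(self) -> float:
        return float(np.nanmean(self.mae))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (k, h + 1, self.mae[k, h])
            for k in range(self.mae.shape[0])
            for h in range(self.h_max)
        ]
        return pd.DataFrame(rows, columns=["fold", "horizon", "mae"])


def cv_forecast_mae(
    collection: StudyCollection,
    P: int,
    Q: int,
    config: BoostingConfig | None = None,
    n_folds: int = 4,
    h_max: int = 5,
    seed: int = 0,
    anchor_stride: int = 1,
) -> EvaluationReport:
    """Subject-level cross-validated mean absolute forecasting error.

    Per fold, a model is fitted on the training subjects; each held-out
    subject is forecast from every admissible anchor time (stepping by
    ``anchor_stride``) using the true future interventions, and
    ``|y_hat - y|`` is averaged over taxa, anchors and subjects per horizon.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if collection.n_subjects < n_folds:
        raise ValueError("need at least as many subjects as folds")
    config = config or BoostingConfig()
    rng = np.random.default_rng(seed)
    perm = rng.permutation(collection.n_subjects)
    folds = [sorted(perm[k::n_folds]) for k in range(n_folds)]
    fold_subjects = [[collection.subjects[i] for i in f] for f in folds]

    mae = np.full((n_folds, h_max), np.nan)
    for k, test_subjects in enumerate(fold_subjects):
        train = [s for s in collection.subjects if s not in test_subjects]
        model = fit_collection(collection.subset_subjects(train), P, Q, config=config)
        errs: list[list[float]] = [[] for _ in range(h_max)]
        for subj in test_subjects:
            y = collection.abundances[subj]
            w = collection.interventions[subj]
            T = y.shape[1]
            if T < P + 1:
                logger.warning("held-out subject %r too short for any forecast; skipped", subj)
                continue
            sub_all = collection.subset_subjects([subj])
            for t0 in range(P - 1, T - 1, anchor_stride):
                h_avail = min(h_max, T - 1 - t0)
                if h_avail < 1:
                    continue
                truncated = sub_all.truncate(t0 + 1)
                W_fut = w[:, t0 + 1 : t0 + 1 + h_avail]
                pred = forecast(model, truncated, W_fut, h_avail)[subj]
                for h in range(h_avail):
                    errs[h].append(float(np.mean(np.abs(pred[:, h] - y[:, t0 + 1 + h]))))
        for h in range(h_max):
            if errs[h]:
                mae[k, h] = float(np.mean(errs[h]))
    return EvaluationReport(mae=mae, fold_subjects=fold_subjects, h_max=h_max, seed=seed)


def fdp_power_by_lag(
    selections: dict[int, np.ndarray] | Sequence[np.ndarray],
    truth: TruthLabels,
) -> pd.DataFrame:
    """False-discovery proportion and power of per-lag selections.

    FDP = |selected & null_h| / max(|selected|, 1);
    power = |selected & nonnull_h| / max(|nonnull_h|, 1).
    """
    if isinstance(selections, dict):
        items = sorted(selections.items())
    else:
        items = list(enumerate(selections, start=1))
    rows = []
    for h, sel in items:
        sel = np.asarray(sel, dtype=bool)
        nonnull = truth.nonnull(h)
        if sel.shape != nonnull.shape:
            raise ValueError(f"selection at lag {h} has wrong length")
        n_sel = int(sel.sum())
        fd = int((sel & ~nonnull).sum())
        td = int((sel & nonnull).sum())
        fdp = fd / max(n_sel, 1)
        power = td / max(int(nonnull.sum()), 1)
        rows.append((h, n_sel, fdp, power))
    return pd.DataFrame(rows, columns=["lag", "n_selected", "fdp", "power"])


def prepost_ttest(
    collection: StudyCollection,
    onset: dict[str, int] | None = None,
    window: int = 4,
    q: float = 0.2,
) -> pd.DataFrame:
    """Welch two-sample t-test of pre- vs post-intervention means per taxon,
    with Benjamini-Hochberg adjustment across taxa.

    The ``window`` samples before and after each subject's intervention onset
    are pooled across subjects (shorter subjects contribute what they have).
    Onset defaults to the first time any intervention exceeds 0.5.
    """
    pre_cols, post_cols = [], []
    for subj in collection.subjects:
        y = collection.abundances[subj]
        if onset is not None:
            o = onset[subj]
        else:
            active = np.flatnonzero((collection.interventions[subj] > 0.5).any(axis=0))
            if len(active) == 0:
                logger.warning("subject %r has no active intervention; skipped", subj)
                continue
            o = int(active[0])
        lo = max(0, o - window)
        if lo == o or o >= y.shape[1]:
            logger.warning("subject %r has no usable pre/post window; skipped", subj)
            continue
        pre_cols.append(y[:, lo:o])
        post_cols.append(y[:, o : o + window])
    if not pre_cols:
        raise ValueError("no subject contributed pre/post samples")
    pre = np.concatenate(pre_cols, axis=1)
    post = np.concatenate(post_cols, axis=1)

    J = collection.J
    pvals = np.ones(J)
    tstats = np.zeros(J)
    for j in range(J):
        a, b = pre[j], post[j]
        if a.std() < 1e-12 and b.std() < 1e-12:
            if not np.isclose(a.mean(), b.mean()):
                pvals[j] = 0.0
            else:
                logger.warning("taxon %s has zero variance in both windows; p = 1",
                               collection.taxa[j])
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        tstats[j], pvals[j] = t, p
    reject, padj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return pd.DataFrame(
        {
            "taxon": collection.taxa,
            "t_stat": tstats,
            "p_value": pvals,
            "p_adjusted": padj,
            "selected": reject,
        }
    )
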