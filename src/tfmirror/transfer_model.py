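"""Per-taxon transfer-function estimation and forecasting.

Each taxon's next-step response is predicted from flattened lagged abundances
of *all* taxa, lagged intervention strengths (including the current time),
static covariates, and screened interaction products.  Estimation is
componentwise L2 boosting (stagewise forward selection with shrinkage), which
collapses to a sparse linear predictor per taxon; the boosting loop is
vectorized across taxa.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Sequence

import numpy as np

from .normalize import NormalizationSpec
from .ts_data import (
    LaggedDesign,
    StudyCollection,
    flatten_history,
    interaction_columns,
    intervention_column_indices,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BoostingConfig",
    "TransferFunctionModel",
    "screen_interactions",
    "fit",
    "predict_one_step",
    "forecast",
    "partial_dependence_profile",
]

_EXHAUSTIVE_CAP = 500  # base-design width above which exhaustive screening is refused


@dataclasses.dataclass
class BoostingConfig:
    """Hyperparameters for interaction screening and componentwise boosting."""

    n_iterations: int = 500
    learning_rate: float = 0.1
    max_interactions: int = 20
    screen_method: str = "xyz_random_projection"  # or "exhaustive" / "none"
    n_projections: int = 50
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must lie in (0, 1]")
        if self.max_interactions < 0:
            raise ValueError("max_interactions must be >= 0")
        if self.screen_method not in ("xyz_random_projection", "exhaustive", "none"):
            raise ValueError(f"unknown screen_method {self.screen_method!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BoostingConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# interaction screening
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    ok = sd > 1e-12
    Xs = np.zeros_like(X)
    Xs[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    return Xs, mu, sd


def _exact_pair_scores(
    X_base: np.ndarray, Ys: np.ndarray, pairs: Sequence[tuple[int, int]]
) -> np.ndarray:
    """max over responses of |corr(x_a * x_b, y_j)| for the given pairs."""
    scores = np.zeros(len(pairs))
    n = X_base.shape[0]
    for k, (a, b) in enumerate(pairs):
        prod = X_base[:, a] * X_base[:, b]
        sd = prod.std()
        if sd < 1e-12:
            continue
        prod = (prod - prod.mean()) / sd
        scores[k] = np.max(np.abs(prod @ Ys)) / n
    return scores


def screen_interactions(
    design: LaggedDesign,
    responses: np.ndarray | None = None,
    config: BoostingConfig | None = None,
) -> list[tuple[int, int]]:
    """Rank candidate interaction pairs (a, b), a <= b, of base-design columns.

    ``exhaustive`` scores every pair by the maximum over taxa of the absolute
    correlation between the product column and the response.  The randomized
    mode approximates the same covariance scan with sign projections: for each
    of R repetitions draw r in {-1, +1}^n and accumulate the outer product of
    X'(y o r) and X'r, whose expectation is X' diag(y) X; a shortlist of top
    candidates is then re-scored exactly.
    """
    config = config or BoostingConfig()
    if config.screen_method == "none" or config.max_interactions == 0:
        return []
    Y = design.Y_response if responses is None else np.asarray(responses, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X_base = design.X[:, : design.n_base]
    if X_base.shape[0] != Y.shape[0]:
        raise ValueError("responses are not row-aligned with the design")
    n, d = X_base.shape
    Xs, _, sd = _standardize(X_base)
    usable = np.flatnonzero(sd > 1e-12)

    Ys = np.empty_like(Y)
    resp_sd = Y.std(axis=0)
    const = resp_sd < 1e-12
    if const.any():
        logger.warning("%d constant response columns skipped in screening", int(const.sum()))
    Ys[:, ~const] = (Y[:, ~const] - Y[:, ~const].mean(axis=0)) / resp_sd[~const]
    Ys[:, const] = 0.0
    if (~const).sum() == 0:
        return []

    if config.screen_method == "exhaustive":
        if d > _EXHAUSTIVE_CAP:
            raise ValueError(
                f"exhaustive screening refused for base design wider than {_EXHAUSTIVE_CAP}"
            )
        pairs = [(a, b) for a in usable for b in usable if a <= b]
        scores = _exact_pair_scores(Xs, Ys, pairs)
    else:
        rng = np.random.default_rng(config.random_seed)
        S = np.zeros((d, d))
        R = config.n_projections
        for j in np.flatnonzero(~const):
            y = Ys[:, j]
            acc = np.zeros((d, d))
            for _ in range(R):
                r = rng.choice([-1.0, 1.0], size=n)
                acc += np.outer(Xs.T @ (y * r), Xs.T @ r)
            np.maximum(S, np.abs(acc) / (R * n), out=S)
        S = np.maximum(S, S.T)
        iu = np.triu_indices(d)
        order = np.argsort(S[iu])[::-1]
        shortlist = min(len(order), max(5 * config.max_interactions, 50))
        cand = [(int(iu[0][k]), int(iu[1][k])) for k in order[:shortlist]]
        cand = [(a, b) for a, b in cand if sd[a] > 1e-12 and sd[b] > 1e-12]
        pairs = cand
        scores = _exact_pair_scores(Xs, Ys, pairs)

    keep = np.argsort(scores)[::-1]
    out = []
    for k in keep:
        if scores[k] <= 1e-12:
            break
        out.append(tuple(pairs[k]))
        if len(out) >= config.max_interactions:
            break
    return out


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

_MODEL_FORMAT_VERSION = 1


@dataclasses.dataclass
class TransferFunctionModel:
    """J fitted additive linear predictors plus the metadata to apply them.

    ``coefficients`` has one column per taxon, rows aligned with the design's
    feature layout (base columns then interaction products), on the original
    feature scale.  Prediction is ``X @ coefficients + intercepts``.
    """

    intercepts: np.ndarray
    coefficients: np.ndarray
    P: int
    Q: int
    interactions: list[tuple[int, int]]
    feature_names: list[str]
    n_base: int
    taxa: list[str]
    intervention_names: list[str]
    covariate_names: list[str]
    normalization: NormalizationSpec | None = None
    config: BoostingConfig | None = None
    clip_at_zero: bool = False

    def __post_init__(self) -> None:
        J = len(self.taxa)
        d = self.n_base + len(self.interactions)
        if self.intercepts.shape != (J,):
            raise ValueError("intercepts must have one entry per taxon")
        if self.coefficients.shape != (d, J):
            raise ValueError(
                f"coefficients shape {self.coefficients.shape} != {(d, J)}"
            )

    @property
    def J(self) -> int:
        return len(self.taxa)

    @property
    def D(self) -> int:
        return len(self.intervention_names)

    @property
    def S(self) -> int:
        return len(self.covariate_names)

    # -- prediction ---------------------------------------------------------
    def expand_base(self, X_base: np.ndarray) -> np.ndarray:
        """Append interaction product columns to base feature rows."""
        return np.hstack([X_base, interaction_columns(X_base, self.interactions)])

    def predict_design(self, X: np.ndarray) -> np.ndarray:
        """Predict all taxa for rows already in full (base + interaction) layout."""
        out = X @ self.coefficients + self.intercepts[None, :]
        if self.clip_at_zero:
            out = np.clip(out, 0.0, None)
        return out

    def predict_base_rows(self, X_base: np.ndarray) -> np.ndarray:
        return self.predict_design(self.expand_base(X_base))

    def intervention_columns(self) -> np.ndarray:
        return intervention_column_indices(self.J, self.D, self.P, self.Q)

    # -- serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format_version": _MODEL_FORMAT_VERSION,
            "P": self.P,
            "Q": self.Q,
            "n_base": self.n_base,
            "taxa": self.taxa,
            "intervention_names": self.intervention_names,
            "covariate_names": self.covariate_names,
            "interactions": [list(p) for p in self.interactions],
            "feature_names": self.feature_names,
            "intercepts": self.intercepts.tolist(),
            "coefficients": self.coefficients.tolist(),
            "normalization": None if self.normalization is None else self.normalization.to_dict(),
            "config": None if self.config is None else self.config.to_dict(),
            "clip_at_zero": self.clip_at_zero,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransferFunctionModel":
        if d.get("format_version") != _MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {d.get('format_version')}")
        return cls(
            intercepts=np.asarray(d["intercepts"], dtype=float),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            P=d["P"],
            Q=d["Q"],
            interactions=[tuple(p) for p in d["interactions"]],
            feature_names=list(d["feature_names"]),
            n_base=d["n_base"],
            taxa=list(d["taxa"]),
            intervention_names=list(d["intervention_names"]),
            covariate_names=list(d["covariate_names"]),
            normalization=None
            if d.get("normalization") is None
            else NormalizationSpec.from_dict(d["normalization"]),
            config=None if d.get("config") is None else BoostingConfig.from_dict(d["config"]),
            clip_at_zero=d.get("clip_at_zero", False),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str) -> "TransferFunctionModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit(
    design: LaggedDesign,
    responses: np.ndarray | None = None,
    config: BoostingConfig | None = None,
    taxa: Sequence[str] | None = None,
    intervention_names: Sequence[str] | None = None,
    covariate_names: Sequence[str] | None = None,
    normalization: NormalizationSpec | None = None,
) -> TransferFunctionModel:
    """Componentwise L2 boosting of every taxon's predictor, vectorized.

    Columns are standardized; each iteration selects, per taxon, the single
    column whose least-squares fit most reduces the squared residual, and adds
    ``learning_rate`` times that coefficient.  The result is collapsed to an
    intercept plus sparse coefficient vector on the original feature scale.
    """
    config = config or BoostingConfig()
    Y = design.Y_response if responses is None else np.asarray(responses, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.X
    n, d = X.shape
    if n < 2:
        raise ValueError("fitting requires at least 2 rows")
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("design or responses contain missing values")
    J = Y.shape[1]

    Xs, mu, sd = _standardize(X)
    usable = sd > 1e-12  # constant columns are never selected

    ybar = Y.mean(axis=0)
    resid = Y - ybar[None, :]
    beta_std = np.zeros((d, J))
    lr = config.learning_rate
    for _ in range(config.n_iterations):
        # per-(column, taxon) OLS slope on current residuals; columns have
        # variance 1 so the slope is the inner product / n
        C = (Xs.T @ resid) / n
        C[~usable, :] = 0.0
        best = np.argmax(np.abs(C), axis=0)
        cb = C[best, np.arange(J)]
        beta_std[best, np.arange(J)] += lr * cb
        resid -= lr * cb[None, :] * Xs[:, best]

    # collapse to the original scale
    beta = np.zeros((d, J))
    beta[usable] = beta_std[usable] / sd[usable, None]
    intercepts = ybar - mu @ beta

    n_tax = Y.shape[1]
    taxa = list(taxa) if taxa is not None else [f"tax{j + 1}" for j in range(n_tax)]
    # recover names by parsing the design's feature labels when not given
    if intervention_names is None or covariate_names is None:
        iv, cv = [], []
        for name in design.feature_names[: design.n_base]:
            if name.startswith("w[") and name.endswith(".lag0"):
                iv.append(name[2 : name.rindex("]")])
            elif name.startswith("z["):
                cv.append(name[2:-1])
        intervention_names = intervention_names or iv
        covariate_names = covariate_names if covariate_names is not None else cv
    return TransferFunctionModel(
        intercepts=intercepts,
        coefficients=beta,
        P=design.P,
        Q=design.Q,
        interactions=list(design.interactions),
        feature_names=list(design.feature_names),
        n_base=design.n_base,
        taxa=taxa,
        intervention_names=list(intervention_names),
        covariate_names=list(covariate_names),
        normalization=normalization,
        config=config,
    )


def fit_collection(
    collection: StudyCollection,
    P: int,
    Q: int,
    config: BoostingConfig | None = None,
    stride: int = 1,
    normalization: NormalizationSpec | None = None,
) -> TransferFunctionModel:
    """Tile, screen interactions, and fit in one call."""
    from .ts_data import tile_windows

    config = config or BoostingConfig()
    base = tile_windows(collection, P, Q, stride=stride)
    pairs = screen_interactions(base, config=config)
    design = tile_windows(collection, P, Q, stride=stride, interactions=pairs)
    return fit(
        design,
        config=config,
        taxa=collection.taxa,
        intervention_names=collection.intervention_names,
        covariate_names=collection.covariate_names,
        normalization=normalization,
    )


# ---------------------------------------------------------------------------
# prediction / forecasting
# ---------------------------------------------------------------------------

def predict_one_step(
    model: TransferFunctionModel,
    Y_hist: np.ndarray,
    W_hist: np.ndarray,
    z: np.ndarray | None = None,
) -> np.ndarray:
    """Evaluate all J predictors on one history.

    ``Y_hist`` is ``(J, P)`` with columns oldest to newest; ``W_hist`` is
    ``(D, Q)`` including the current time as its last column; ``z`` has
    length S.
    """
    Y_hist = np.asarray(Y_hist, dtype=float)
    W_hist = np.asarray(W_hist, dtype=float)
    z = np.zeros(model.S) if z is None else np.asarray(z, dtype=float)
    if Y_hist.shape != (model.J, model.P):
        raise ValueError(
            f"Y_hist shape {Y_hist.shape} does not match model (J={model.J}, P={model.P})"
        )
    if W_hist.shape != (model.D, model.Q):
        raise ValueError(
            f"W_hist shape {W_hist.shape} does not match model (D={model.D}, Q={model.Q})"
        )
    if z.shape != (model.S,):
        raise ValueError(f"z shape {z.shape} does not match model (S={model.S})")
    x = flatten_history(Y_hist, W_hist, z)[None, :]
    return model.predict_base_rows(x)[0]


def forecast(
    model: TransferFunctionModel,
    observed: StudyCollection,
    future_interventions: dict[str, np.ndarray] | np.ndarray,
    horizon: int,
) -> dict[str, np.ndarray]:
    """h-step forecasts with observed-value substitution.

    For each subject the forecast launches from the last observed time; at
    step k the abundance history mixes observed values (times at or before
    the launch point) with earlier predictions, and the intervention history
    mixes observed columns with the supplied future path (``(D, horizon)``
    per subject, or one array shared by all).  Returns per-subject
    ``(J, horizon)`` prediction matrices on the model's normalization scale.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    out: dict[str, np.ndarray] = {}
    for subj in observed.subjects:
        if isinstance(future_interventions, dict):
            if subj not in future_interventions:
                raise ValueError(f"missing future interventions for subject {subj!r}")
            W_fut = np.asarray(future_interventions[subj], dtype=float)
        else:
            W_fut = np.asarray(future_interventions, dtype=float)
        if W_fut.shape != (model.D, horizon):
            raise ValueError(
                f"future interventions for {subj!r} have shape {W_fut.shape}, "
                f"expected {(model.D, horizon)}"
            )
        y_obs = observed.abundances[subj]
        w_obs = observed.interventions[subj]
        z = observed.covariates[subj]
        T = y_obs.shape[1]
        if T < model.P:
            raise ValueError(
                f"subject {subj!r} has {T} observed timepoints, fewer than P={model.P}"
            )
        y_ext = np.concatenate([y_obs, np.zeros((model.J, horizon))], axis=1)
        w_ext = np.concatenate([w_obs, W_fut], axis=1)
        for k in range(1, horizon + 1):
            t = T - 1 + k  # index of the time being predicted
            Y_hist = y_ext[:, t - model.P : t]
            lo = t - model.Q + 1
            if lo < 0:
                W_hist = np.concatenate(
                    [np.zeros((model.D, -lo)), w_ext[:, : t + 1]], axis=1
                )
            else:
                W_hist = w_ext[:, lo : t + 1]
            y_ext[:, t] = predict_one_step(model, Y_hist, W_hist, z)
        out[subj] = y_ext[:, T:]
    return out


def partial_dependence_profile(
    model: TransferFunctionModel,
    taxon: int | str,
    feature: int,
    grid: Sequence[float],
    design: LaggedDesign,
) -> np.ndarray:
    """Mean prediction for one taxon as a base feature sweeps over ``grid``.

    Interaction columns involving the swept feature are recomputed for each
    grid value.
    """
    if design.n_rows == 0:
        raise ValueError("empty design")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    if not 0 <= feature < model.n_base:
        raise ValueError(f"feature index {feature} outside base design of width {model.n_base}")
    j = model.taxa.index(taxon) if isinstance(taxon, str) else int(taxon)
    X_base = design.X[:, : design.n_base].copy()
    out = np.empty(len(grid))
    for g, v in enumerate(grid):
        X_base[:, feature] = v
        out[g] = model.predict_base_rows(X_base)[:, j].mean()
    return out
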