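"""Containers for multi-subject intervention time series and lagged design matrices.

The central object is :class:`StudyCollection`, which holds per-subject
taxon-by-time abundance matrices, intervention-by-time matrices, static
covariates, and the per-subject time grids.  Downstream modeling requires a
regular time grid; :func:`interpolate_to_grid` is the single sanctioned path
from irregular data.  :func:`tile_windows` tiles trajectories into lagged
feature rows paired with per-taxon responses.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

__all__ = [
    "StudyCollection",
    "LaggedDesign",
    "interpolate_to_grid",
    "filter_prevalence",
    "tile_windows",
    "read_collection",
    "write_collection",
]


@dataclasses.dataclass
class StudyCollection:
    """Aligned abundance, intervention and covariate series for a cohort.

    Parameters
    ----------
    subjects
        Ordered subject identifiers.
    abundances
        Per subject, a ``(J, T_i)`` float array of taxon abundances over that
        subject's time grid (raw counts or normalized values).
    interventions
        Per subject, a ``(D, T_i)`` float array of intervention strengths,
        typically in ``[0, 1]``.
    covariates
        Per subject, a length-``S`` static covariate vector (``S`` may be 0).
    taxa, intervention_names, covariate_names
        Identifier lists of lengths ``J``, ``D`` and ``S``.
    time_grid
        Per subject, strictly increasing observation times.
    """

    subjects: list[str]
    abundances: dict[str, np.ndarray]
    interventions: dict[str, np.ndarray]
    covariates: dict[str, np.ndarray]
    taxa: list[str]
    intervention_names: list[str]
    covariate_names: list[str]
    time_grid: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.subjects = list(self.subjects)
        self.taxa = list(self.taxa)
        self.intervention_names = list(self.intervention_names)
        self.covariate_names = list(self.covariate_names)
        J, D, S = len(self.taxa), len(self.intervention_names), len(self.covariate_names)
        for subj in self.subjects:
            t = np.asarray(self.time_grid[subj], dtype=float)
            if t.ndim != 1 or (len(t) > 1 and np.any(np.diff(t) <= 0)):
                raise ValueError(f"time grid for subject {subj!r} is not strictly increasing")
            self.time_grid[subj] = t
            y = np.asarray(self.abundances[subj], dtype=float)
            w = np.asarray(self.interventions[subj], dtype=float)
            if y.shape != (J, len(t)):
                raise ValueError(
                    f"abundances for subject {subj!r} have shape {y.shape}, "
                    f"expected {(J, len(t))}"
                )
            if w.shape != (D, len(t)):
                raise ValueError(
                    f"interventions for subject {subj!r} have shape {w.shape}, "
                    f"expected {(D, len(t))}"
                )
            if np.isnan(y).any() or np.isnan(w).any():
                raise ValueError(f"missing values in series for subject {subj!r}")
            z = np.asarray(self.covariates.get(subj, np.zeros(S)), dtype=float)
            if z.shape != (S,):
                raise ValueError(
                    f"covariates for subject {subj!r} have shape {z.shape}, expected {(S,)}"
                )
            self.abundances[subj] = y
            self.interventions[subj] = w
            self.covariates[subj] = z

    # -- basic dimensions ---------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def J(self) -> int:
        return len(self.taxa)

    @property
    def D(self) -> int:
        return len(self.intervention_names)

    @property
    def S(self) -> int:
        return len(self.covariate_names)

    # -- derived views ------------------------------------------------------
    def pooled_abundances(self) -> tuple[np.ndarray, list[tuple[str, float]]]:
        """Concatenate all subjects' samples into one ``(J, N)`` matrix.

        Returns the matrix and a list of ``(subject, time)`` sample keys in
        column order.
        """
        cols, keys = [], []
        for subj in self.subjects:
            cols.append(self.abundances[subj])
            keys.extend((subj, float(t)) for t in self.time_grid[subj])
        return np.concatenate(cols, axis=1), keys

    def subset_subjects(self, subjects: Iterable[str]) -> "StudyCollection":
        subjects = list(subjects)
        missing = [s for s in subjects if s not in self.abundances]
        if missing:
            raise KeyError(f"unknown subjects: {missing}")
        return StudyCollection(
            subjects=subjects,
            abundances={s: self.abundances[s].copy() for s in subjects},
            interventions={s: self.interventions[s].copy() for s in subjects},
            covariates={s: self.covariates[s].copy() for s in subjects},
            taxa=list(self.taxa),
            intervention_names=list(self.intervention_names),
            covariate_names=list(self.covariate_names),
            time_grid={s: self.time_grid[s].copy() for s in subjects},
        )

    def subset_taxa(self, taxa: Sequence[str]) -> "StudyCollection":
        idx = [self.taxa.index(t) for t in taxa]
        return StudyCollection(
            subjects=list(self.subjects),
            abundances={s: self.abundances[s][idx, :].copy() for s in self.subjects},
            interventions={s: self.interventions[s].copy() for s in self.subjects},
            covariates={s: self.covariates[s].copy() for s in self.subjects},
            taxa=list(taxa),
            intervention_names=list(self.intervention_names),
            covariate_names=list(self.covariate_names),
            time_grid={s: self.time_grid[s].copy() for s in self.subjects},
        )

    def truncate(self, n_timepoints: int) -> "StudyCollection":
        """Keep only the first ``n_timepoints`` observations of every subject."""
        if n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        return StudyCollection(
            subjects=list(self.subjects),
            abundances={s: self.abundances[s][:, :n_timepoints].copy() for s in self.subjects},
            interventions={
                s: self.interventions[s][:, :n_timepoints].copy() for s in self.subjects
            },
            covariates={s: self.covariates[s].copy() for s in self.subjects},
            taxa=list(self.taxa),
            intervention_names=list(self.intervention_names),
            covariate_names=list(self.covariate_names),
            time_grid={s: self.time_grid[s][:n_timepoints].copy() for s in self.subjects},
        )

    def is_regular(self, rtol: float = 1e-8) -> bool:
        """True when every subject's grid has constant spacing."""
        for subj in self.subjects:
            t = self.time_grid[subj]
            if len(t) < 2:
                continue
            d = np.diff(t)
            if not np.allclose(d, d[0], rtol=rtol, atol=1e-12):
                return False
        return True


@dataclasses.dataclass
class LaggedDesign:
    """Flattened lagged feature rows and aligned per-taxon responses.

    ``X`` columns are ordered: abundance lags 1..P (all taxa per lag),
    intervention lags 0..Q-1 (all interventions per lag), covariates, then
    screened interaction product columns.  ``window_index`` records the
    ``(subject, response_time)`` pair for every row.
    """

    X: np.ndarray
    Y_response: np.ndarray
    window_index: list[tuple[str, float]]
    P: int
    Q: int
    feature_names: list[str]
    n_base: int
    interactions: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.Y_response.shape[0]:
            raise ValueError("X and Y_response row counts differ")
        if self.X.shape[0] != len(self.window_index):
            raise ValueError("window_index length does not match X")
        if len(set(self.window_index)) != len(self.window_index):
            raise ValueError("window_index rows are not unique")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


# ---------------------------------------------------------------------------
# feature layout helpers (shared with transfer_model)
# ---------------------------------------------------------------------------

def base_feature_names(
    taxa: Sequence[str],
    intervention_names: Sequence[str],
    covariate_names: Sequence[str],
    P: int,
    Q: int,
) -> list[str]:
    names = []
    for p in range(1, P + 1):
        names.extend(f"y[{t}].lag{p}" for t in taxa)
    for q in range(Q):
        names.extend(f"w[{w}].lag{q}" for w in intervention_names)
    names.extend(f"z[{c}]" for c in covariate_names)
    return names


def intervention_column_indices(J: int, D: int, P: int, Q: int) -> np.ndarray:
    """Base-design column indices of the intervention block (lags 0..Q-1)."""
    return np.arange(P * J, P * J + Q * D)


def flatten_history(Y_hist: np.ndarray, W_hist: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Flatten ``(J, P)`` abundance history (columns oldest -> newest),
    ``(D, Q)`` intervention history, and covariates into the base feature
    layout used by :func:`tile_windows`.

    Abundance lag ``p`` is column ``P - p`` of ``Y_hist``; intervention lag
    ``q`` is column ``Q - 1 - q`` of ``W_hist`` (lag 0 = current time).
    """
    J, P = Y_hist.shape
    D, Q = W_hist.shape
    parts = [Y_hist[:, P - p] for p in range(1, P + 1)]
    parts.extend(W_hist[:, Q - 1 - q] for q in range(Q))
    if len(z):
        parts.append(np.asarray(z, dtype=float))
    return np.concatenate([np.atleast_1d(p) for p in parts])


def interaction_columns(X_base: np.ndarray, pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    """Product columns for interaction pairs, given base feature rows."""
    if not pairs:
        return np.empty((X_base.shape[0], 0))
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    return X_base[:, a] * X_base[:, b]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def interpolate_to_grid(collection: StudyCollection, step: float) -> StudyCollection:
    """Resample every subject onto an arithmetic grid with spacing ``step``.

    Natural cubic splines are fitted per taxon / per intervention channel and
    evaluated on ``arange(first, last, step)`` (endpoint included).
    Abundances are clipped at 0 after interpolation; intervention channels
    whose raw values lie in ``[0, 1]`` are clipped back to ``[0, 1]``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    new_ab, new_iv, new_tg = {}, {}, {}
    for subj in collection.subjects:
        t = collection.time_grid[subj]
        if len(t) < 4:
            raise ValueError(
                f"subject {subj!r} has only {len(t)} timepoints; "
                "cubic spline interpolation requires at least 4"
            )
        n_steps = int(np.floor((t[-1] - t[0]) / step + 1e-9))
        grid = t[0] + step * np.arange(n_steps + 1)
        y = collection.abundances[subj]
        w = collection.interventions[subj]
        y_new = CubicSpline(t, y.T, bc_type="natural")(grid).T
        y_new = np.clip(y_new, 0.0, None)
        w_new = CubicSpline(t, w.T, bc_type="natural")(grid).T
        for d in range(w.shape[0]):
            if w[d].min() >= 0.0 and w[d].max() <= 1.0:
                w_new[d] = np.clip(w_new[d], 0.0, 1.0)
        new_ab[subj] = y_new
        new_iv[subj] = w_new
        new_tg[subj] = grid
    return StudyCollection(
        subjects=list(collection.subjects),
        abundances=new_ab,
        interventions=new_iv,
        covariates={s: collection.covariates[s].copy() for s in collection.subjects},
        taxa=list(collection.taxa),
        intervention_names=list(collection.intervention_names),
        covariate_names=list(collection.covariate_names),
        time_grid=new_tg,
    )


def filter_prevalence(collection: StudyCollection, min_fraction: float) -> StudyCollection:
    """Keep taxa present (abundance > 0) in at least ``min_fraction`` of all
    samples pooled over subjects and times.  Taxon order is preserved."""
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in [0, 1]")
    pooled, _ = collection.pooled_abundances()
    frac = (pooled > 0).mean(axis=1)
    keep = frac >= min_fraction
    if not keep.any():
        raise ValueError(
            "prevalence filter removed every taxon; lower min_fraction "
            f"(max observed prevalence is {frac.max():.3f})"
        )
    kept_taxa = [t for t, k in zip(collection.taxa, keep) if k]
    return collection.subset_taxa(kept_taxa)


def tile_windows(
    collection: StudyCollection,
    P: int,
    Q: int,
    stride: int = 1,
    interactions: Sequence[tuple[int, int]] | None = None,
) -> LaggedDesign:
    """Tile trajectories into lagged feature rows.

    For every subject on a regular grid, response times are taken at indices
    ``t = max(P, Q), max(P, Q) + stride, ...`` (0-based).  Each row packs
    abundance lags 1..P, intervention lags 0..Q-1 (lag 0 is the response
    time itself), covariates, and interaction products.
    """
    if P < 1 or Q < 1:
        raise ValueError("P and Q must both be >= 1")
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    if not collection.is_regular():
        raise ValueError("tile_windows requires a regular time grid; interpolate first")
    interactions = list(interactions or [])
    J, D, S = collection.J, collection.D, collection.S
    n_base = P * J + Q * D + S
    for a, b in interactions:
        if not (0 <= a <= b < n_base):
            raise ValueError(f"interaction pair ({a}, {b}) outside base design of width {n_base}")

    start = max(P, Q)
    rows, resp, index = [], [], []
    for subj in collection.subjects:
        t_grid = collection.time_grid[subj]
        T = len(t_grid)
        if T < max(P, Q) + 1:
            logger.warning(
                "subject %r has %d timepoints, fewer than max(P, Q) + 1 = %d; skipped",
                subj, T, max(P, Q) + 1,
            )
            continue
        y = collection.abundances[subj]
        w = collection.interventions[subj]
        z = collection.covariates[subj]
        for t in range(start, T, stride):
            Y_hist = y[:, t - P : t]          # columns oldest -> newest
            W_hist = w[:, t - Q + 1 : t + 1]  # includes current time (lag 0)
            rows.append(flatten_history(Y_hist, W_hist, z))
            resp.append(y[:, t])
            index.append((subj, float(t_grid[t])))
    if not rows:
        raise ValueError("no subject long enough to tile any window")
    X_base = np.asarray(rows)
    X = np.hstack([X_base, interaction_columns(X_base, interactions)])
    names = base_feature_names(
        collection.taxa, collection.intervention_names, collection.covariate_names, P, Q
    )
    names += [f"({names[a]})*({names[b]})" for a, b in interactions]
    return LaggedDesign(
        X=X,
        Y_response=np.asarray(resp),
        window_index=index,
        P=P,
        Q=Q,
        feature_names=names,
        n_base=n_base,
        interactions=interactions,
    )


# ---------------------------------------------------------------------------
# file I/O (plain TSV/CSV)
# ---------------------------------------------------------------------------

def _read_table(path: str) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, comment="#")


def read_collection(
    counts_path: str,
    samples_path: str,
    interventions_path: str,
    covariates_path: str | None = None,
) -> StudyCollection:
    """Assemble a :class:`StudyCollection` from the standard flat files.

    ``counts``: taxa as rows (first column taxon id), samples as columns.
    ``samples``: columns sample_id, subject_id, time.
    ``interventions``: long format with subject_id, time, intervention, value.
    ``covariates``: optional, subject_id plus one column per covariate.
    """
    counts = _read_table(counts_path)
    taxa = counts.iloc[:, 0].astype(str).tolist()
    count_mat = counts.iloc[:, 1:]
    samples = _read_table(samples_path)
    required = {"sample_id", "subject_id", "time"}
    if not required.issubset(samples.columns):
        raise ValueError(f"samples file must have columns {sorted(required)}")
    iv = _read_table(interventions_path)
    if not {"subject_id", "time", "intervention", "value"}.issubset(iv.columns):
        raise ValueError(
            "interventions file must have columns subject_id, time, intervention, value"
        )
    intervention_names = sorted(iv["intervention"].astype(str).unique())

    cov_names: list[str] = []
    cov_table = None
    if covariates_path is not None:
        cov_table = _read_table(covariates_path)
        cov_table["subject_id"] = cov_table["subject_id"].astype(str)
        cov_table = cov_table.set_index("subject_id")
        cov_names = [c for c in cov_table.columns]

    subjects = []
    abundances, interventions, covariates, time_grid = {}, {}, {}, {}
    samples["subject_id"] = samples["subject_id"].astype(str)
    for subj, grp in samples.groupby("subject_id", sort=True):
        grp = grp.sort_values("time")
        sample_ids = grp["sample_id"].astype(str).tolist()
        missing = [s for s in sample_ids if s not in count_mat.columns]
        if missing:
            raise ValueError(f"samples missing from counts table: {missing}")
        t = grp["time"].to_numpy(dtype=float)
        y = count_mat[sample_ids].to_numpy(dtype=float)
        w = np.zeros((len(intervention_names), len(t)))
        sub_iv = iv[iv["subject_id"].astype(str) == subj]
        for d, name in enumerate(intervention_names):
            rows = sub_iv[sub_iv["intervention"].astype(str) == name]
            lookup = dict(zip(rows["time"].astype(float), rows["value"].astype(float)))
            w[d] = [lookup.get(float(tt), 0.0) for tt in t]
        subjects.append(subj)
        abundances[subj] = y
        interventions[subj] = w
        time_grid[subj] = t
        if cov_table is not None:
            covariates[subj] = cov_table.loc[subj].to_numpy(dtype=float)
        else:
            covariates[subj] = np.zeros(0)
    return StudyCollection(
        subjects=subjects,
        abundances=abundances,
        interventions=interventions,
        covariates=covariates,
        taxa=taxa,
        intervention_names=intervention_names,
        covariate_names=cov_names,
        time_grid=time_grid,
    )


def write_collection(collection: StudyCollection, outdir: str, header: str | None = None) -> dict:
    """Write counts/samples/interventions/covariates TSVs; returns file paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    pooled, keys = collection.pooled_abundances()
    sample_ids = [f"{s}_t{t:g}" for s, t in keys]
    paths = {}

    def _write(df: pd.DataFrame, name: str) -> None:
        path = os.path.join(outdir, name)
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            df.to_csv(fh, sep="\t", index=False)
        paths[name] = path

    counts = pd.DataFrame(pooled, columns=sample_ids)
    counts.insert(0, "taxon", collection.taxa)
    _write(counts, "counts.tsv")

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subject_id": [s for s, _ in keys],
            "time": [t for _, t in keys],
        }
    )
    _write(samples, "samples.tsv")

    rows = []
    for subj in collection.subjects:
        for d, name in enumerate(collection.intervention_names):
            for t, v in zip(collection.time_grid[subj], collection.interventions[subj][d]):
                rows.append((subj, float(t), name, float(v)))
    _write(
        pd.DataFrame(rows, columns=["subject_id", "time", "intervention", "value"]),
        "interventions.tsv",
    )

    if collection.S:
        cov = pd.DataFrame(
            {name: [collection.covariates[s][i] for s in collection.subjects]
             for i, name in enumerate(collection.covariate_names)}
        )
        cov.insert(0, "subject_id", collection.subjects)
        _write(cov, "covariates.tsv")
    return paths
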