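"""Sample-depth normalization: median-of-ratios size factors, asinh, TSS, CLR."""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .ts_data import StudyCollection

logger = logging.getLogger(__name__)

__all__ = ["NormalizationSpec", "size_factors", "apply_normalization", "METHODS"]

METHODS = ("none", "size_factor", "size_factor_asinh", "tss", "clr")


@dataclasses.dataclass
class NormalizationSpec:
    """Normalization method plus fitted per-sample size factors.

    ``pseudocount`` is used by ``clr`` only.  ``renormalize`` rescales fitted
    size factors to unit geometric mean (off by default).
    """

    method: str = "none"
    pseudocount: float = 0.5
    renormalize: bool = False
    size_factors_: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown normalization method {self.method!r}; choose from {METHODS}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "pseudocount": self.pseudocount,
            "renormalize": self.renormalize,
            "size_factors": None
            if self.size_factors_ is None
            else [float(s) for s in self.size_factors_],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationSpec":
        sf = d.get("size_factors")
        return cls(
            method=d["method"],
            pseudocount=d.get("pseudocount", 0.5),
            renormalize=d.get("renormalize", False),
            size_factors_=None if sf is None else np.asarray(sf, dtype=float),
        )


def size_factors(counts: np.ndarray, renormalize: bool = False) -> np.ndarray:
    """Median-of-ratios size factors of a taxa-by-sample count matrix.

    s_i = median over reference taxa j of k_{ji} / geomean(k_{j.}).  Reference
    taxa are those with strictly positive counts in every sample; when none
    exist, geometric means are computed over positive entries only and the
    per-sample median is taken over the sample's positive counts (a
    poscounts-style fallback, logged).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D taxa-by-sample matrix")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    col_sums = counts.sum(axis=0)
    if (col_sums == 0).any():
        bad = int(np.flatnonzero(col_sums == 0)[0])
        raise ValueError(f"sample {bad} is all-zero; size factors undefined")

    all_positive = (counts > 0).all(axis=1)
    if all_positive.any():
        ref = counts[all_positive]
        log_gm = np.mean(np.log(ref), axis=1)
        s = np.median(ref / np.exp(log_gm)[:, None], axis=0)
    else:
        logger.warning(
            "no taxon is positive in all samples; falling back to geometric "
            "means over positive entries only"
        )
        logs = np.zeros_like(counts)
        pos_mask = counts > 0
        logs[pos_mask] = np.log(counts[pos_mask])
        n_pos = (counts > 0).sum(axis=1)
        keep = n_pos > 0
        gm = np.exp(logs[keep].sum(axis=1) / n_pos[keep])
        ratios = counts[keep] / gm[:, None]
        s = np.empty(counts.shape[1])
        pos = counts[keep] > 0
        for i in range(counts.shape[1]):
            vals = ratios[pos[:, i], i]
            if len(vals) == 0:
                raise ValueError(f"sample {i} has no positive counts among usable taxa")
            s[i] = np.median(vals)
    if (s <= 0).any():
        # medians can hit 0 on extremely sparse columns; guard with the
        # smallest positive ratio so downstream division stays defined
        floor = s[s > 0].min() if (s > 0).any() else 1.0
        logger.warning("%d size factors were <= 0; floored to %g", int((s <= 0).sum()), floor)
        s = np.where(s > 0, s, floor)
    if renormalize:
        s = s / np.exp(np.mean(np.log(s)))
    return s


def _transform_matrix(y: np.ndarray, spec: NormalizationSpec, s: np.ndarray) -> np.ndarray:
    if spec.method == "none":
        return y.copy()
    if spec.method == "size_factor":
        return y / s[None, :]
    if spec.method == "size_factor_asinh":
        return np.arcsinh(y / s[None, :])
    if spec.method == "tss":
        totals = y.sum(axis=0)
        if (totals == 0).any():
            bad = int(np.flatnonzero(totals == 0)[0])
            raise ValueError(f"tss undefined: sample {bad} is all-zero")
        return y / totals[None, :]
    if spec.method == "clr":
        shifted = y + spec.pseudocount
        if (shifted <= 0).any():
            raise ValueError("clr requires a positive pseudocount when zeros are present")
        logs = np.log(shifted)
        return logs - logs.mean(axis=0, keepdims=True)
    raise AssertionError(spec.method)


def apply_normalization(
    collection: StudyCollection, spec: NormalizationSpec
) -> tuple[StudyCollection, NormalizationSpec]:
    """Return a transformed copy of the collection plus the fitted spec.

    Size factors are estimated on the matrix of all samples pooled across
    subjects, then applied per sample; the fitted factors are recorded on the
    returned spec so forecasts can declare their scale.
    """
    pooled, keys = collection.pooled_abundances()
    s_all = None
    if spec.method in ("size_factor", "size_factor_asinh"):
        s_all = size_factors(pooled, renormalize=spec.renormalize)
    fitted = NormalizationSpec(
        method=spec.method,
        pseudocount=spec.pseudocount,
        renormalize=spec.renormalize,
        size_factors_=s_all,
    )
    new_ab = {}
    offset = 0
    for subj in collection.subjects:
        T = len(collection.time_grid[subj])
        y = collection.abundances[subj]
        s = s_all[offset : offset + T] if s_all is not None else np.ones(T)
        new_ab[subj] = _transform_matrix(y, spec, s)
        offset += T
    out = StudyCollection(
        subjects=list(collection.subjects),
        abundances=new_ab,
        interventions={s_: collection.interventions[s_].copy() for s_ in collection.subjects},
        covariates={s_: collection.covariates[s_].copy() for s_ in collection.subjects},
        taxa=list(collection.taxa),
        intervention_names=list(collection.intervention_names),
        covariate_names=list(collection.covariate_names),
        time_grid={s_: collection.time_grid[s_].copy() for s_ in collection.subjects},
    )
    return out, fitted
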