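"""Prediction probability (Pk) and correlation analyses.

Pk measures how well a continuous indicator ranks ordinal anesthetic states:
over all unordered observation pairs belonging to *different* states, a pair
is concordant when the indicator ordering matches the state ordering,
discordant when reversed, and tied when the indicator values are equal;

    Pk = (C + T/2) / (C + D + T).

Pk = 1 means the indicator ranks every cross-state pair correctly; Pk = 0.5
is chance.  Pairs tied on state are ignored.  Pk is computed on observations
pooled across patients.

The standard error is a delete-one jackknife over observations.  Because the
published Pk tables report values >= 0.5 even for negatively correlated
indicators, a direction-folded variant max(Pk, 1-Pk) is also provided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _stats

__all__ = [
    "PairedOrdinalData",
    "PkResult",
    "prediction_probability",
    "pk_se_jackknife",
    "directionless_pk",
    "correlation",
    "pk_table",
]


@dataclass(frozen=True)
class PairedOrdinalData:
    """(indicator, ordinal class) observations.

    ``classes`` are numeric labels whose natural ordering is the state
    ordering (for aRASS: 0 is the most awake, −5 the deepest, so larger
    class value = more awake).
    """

    indicator: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicator, dtype=float)
        cls = np.asarray(self.classes, dtype=float)
        object.__setattr__(self, "indicator", ind)
        object.__setattr__(self, "classes", cls)
        if len(ind) != len(cls):
            raise ValueError("indicator and classes must have equal length")
        if len(ind) < 2:
            raise ValueError("need at least 2 observations")

    @property
    def n(self) -> int:
        return len(self.indicator)


@dataclass(frozen=True)
class PkResult:
    pk: float
    se: float
    n_concordant: int
    n_discordant: int
    n_tied_indicator: int

    @property
    def n_pairs(self) -> int:
        return self.n_concordant + self.n_discordant + self.n_tied_indicator


def _pair_counts(ind: np.ndarray, cls: np.ndarray):
    """Per-observation concordant/discordant/tied pair counts (each pair once).

    Row i of the returned arrays counts the pairs involving observation i;
    totals are half the row sums.
    """
    di = np.sign(np.subtract.outer(ind, ind))
    dc = np.sign(np.subtract.outer(cls, cls))
    cross = dc != 0
    conc = cross & (di * dc > 0)
    disc = cross & (di * dc < 0)
    tied = cross & (di == 0)
    return conc.sum(axis=1), disc.sum(axis=1), tied.sum(axis=1)


def _pk_from_counts(c: float, d: float, t: float) -> float:
    denom = c + d + t
    if denom == 0:
        raise ValueError("Pk undefined: no cross-class pairs")
    return (c + t / 2.0) / denom


def prediction_probability(data: PairedOrdinalData, se: bool = True) -> PkResult:
    """Pk by exhaustive cross-class pair counting, with jackknife SE.

    Raises
    ------
    ValueError
        If all observations share one class (Pk undefined).
    """
    ind, cls = data.indicator, data.classes
    if len(np.unique(cls)) < 2:
        raise ValueError("Pk undefined: all observations are in one class")
    ci, di_, ti = _pair_counts(ind, cls)
    c, d, t = int(ci.sum()) // 2, int(di_.sum()) // 2, int(ti.sum()) // 2
    pk = _pk_from_counts(c, d, t)
    se_val = pk_se_jackknife(data) if se and data.n >= 3 else float("nan")
    return PkResult(pk=pk, se=se_val, n_concordant=c, n_discordant=d,
                    n_tied_indicator=t)


def pk_se_jackknife(data: PairedOrdinalData) -> float:
    """Delete-one jackknife standard error of Pk.

    Leave-one-out replicates whose remaining observations fall in a single
    class (Pk undefined) are skipped with a warning; if every replicate is
    skipped an error is raised.
    """
    if data.n < 3:
        raise ValueError("jackknife needs n >= 3")
    ind, cls = data.indicator, data.classes
    ci, di_, ti = _pair_counts(ind, cls)
    c = int(ci.sum()) // 2
    d = int(di_.sum()) // 2
    t = int(ti.sum()) // 2

    # class counts to detect single-class leave-one-out subsets
    _, inverse, counts = np.unique(cls, return_inverse=True, return_counts=True)
    n_classes = len(counts)

    reps = []
    skipped = 0
    for i in range(data.n):
        if n_classes == 2 and counts[inverse[i]] == 1:
            skipped += 1
            continue
        try:
            reps.append(_pk_from_counts(c - ci[i], d - di_[i], t - ti[i]))
        except ValueError:
            skipped += 1
    if skipped:
        warnings.warn(
            f"{skipped} jackknife replicate(s) skipped: leave-one-out subset "
            "had a single class", stacklevel=2,
        )
    if not reps:
        raise ValueError("all jackknife replicates degenerate; SE undefined")
    reps = np.asarray(reps)
    m = len(reps)
    return float(math.sqrt((m - 1) / m * ((reps - reps.mean()) ** 2).sum()))


def directionless_pk(data: PairedOrdinalData | float) -> float:
    """Direction-folded Pk: max(Pk, 1 − Pk).

    Accepts either a dataset or an already-computed raw Pk value.
    """
    pk = data if isinstance(data, float) else prediction_probability(data, se=False).pk
    return max(pk, 1.0 - pk)


def correlation(x: Sequence[float], y: Sequence[float],
                method: str = "auto") -> tuple[float, float, str]:
    """Correlation coefficient and p-value, Pearson or Spearman.

    In ``auto`` mode a Kolmogorov-Smirnov normality test (against a normal
    with the sample's moments) runs on both variables; Pearson is used only
    when both pass at the 0.05 level, Spearman otherwise.

    Returns (R, p, method_used).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    if method == "auto":
        def _normal(v):
            return _stats.kstest(v, "norm", args=(v.mean(), v.std(ddof=1))).pvalue > 0.05
        method = "pearson" if (_normal(x) and _normal(y)) else "spearman"
    if method == "pearson":
        r, p = _stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = _stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), method


def pk_table(features_frame, feature_columns: Sequence[str],
             class_col: str = "arass", ce_col: str = "ce_ug_ml",
             window_col: str = "window"):
    """Pooled Pk/SE and correlation table, one row per (window, feature).

    Mirrors the published layout: raw and direction-folded Pk with jackknife
    SE, plus the correlation of each feature with the sedation score and with
    the propofol effect-site concentration (auto Pearson/Spearman).
    """
    import pandas as pd

    rows = []
    for window, grp in features_frame.groupby(window_col, sort=True):
        cls = grp[class_col].to_numpy(dtype=float)
        ce = grp[ce_col].to_numpy(dtype=float)
        for feat in feature_columns:
            vals = grp[feat].to_numpy(dtype=float)
            res = prediction_probability(PairedOrdinalData(vals, cls))
            r_cls, p_cls, m_cls = correlation(vals, cls)
            r_ce, p_ce, m_ce = correlation(vals, ce)
            rows.append({
                "window": window, "feature": feat,
                "pk_raw": res.pk, "pk": directionless_pk(res.pk), "se": res.se,
                "r_arass": r_cls, "p_arass": p_cls, "method_arass": m_cls,
                "r_ce": r_ce, "p_ce": p_ce, "method_ce": m_ce,
            })
    return pd.DataFrame(rows)
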