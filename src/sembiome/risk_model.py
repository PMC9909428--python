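"""Logistic disease-risk model on latent scores: split, SMOTE, fit, ROC.

The scored cohort is split 80/20 stratified by the four analysis groups, the
training fold is class-balanced with SMOTE (synthetic minority points
interpolated between nearest minority neighbors), a plain maximum-likelihood
logistic regression is fitted, and accuracy is read off the verification
fold as the ROC AUC with a DeLong confidence interval.  Balancing happens
strictly after the split and only ever sees training rows, so verification
data never leaks into model construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "SplitResult",
    "RiskConfig",
    "RocResult",
    "stratified_split",
    "smote_balance",
    "fit_logistic",
    "roc_auc",
]

log = logging.getLogger(__name__)


@dataclass
class SplitResult:
    training: list[str]
    verification: list[str]
    strata: dict[str, str]


@dataclass
class RiskConfig:
    """SMOTE and model settings for the risk stage."""

    smote_k: int = 5
    over_pct: float = 200.0
    under_pct: float = 200.0
    seed: int = 1234
    features: tuple[str, ...] = ("lv2",)

    def __post_init__(self) -> None:
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")
        if self.over_pct <= 0 or self.under_pct <= 0:
            raise ValueError("over/under percentages must be positive")


@dataclass
class RocResult:
    auc: float
    ci: tuple[float, float]
    curve: pd.DataFrame = field(repr=False)  # columns fpr, tpr


def stratified_split(
    strata: dict[str, str], frac: float = 0.8, seed: int = 1234
) -> SplitResult:
    """Random stratified split: round(frac * n) of each stratum to training.

    Rounding is round-half-even.  Strata with fewer than 2 members go wholly
    to training with a warning.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    by_stratum: dict[str, list[str]] = {}
    for sid, g in strata.items():
        by_stratum.setdefault(g, []).append(sid)
    train: list[str] = []
    verif: list[str] = []
    for g in sorted(by_stratum):
        ids = sorted(by_stratum[g])
        if len(ids) < 2:
            log.warning("stratum %r has <2 samples; assigning all to training", g)
            train.extend(ids)
            continue
        perm = rng.permutation(len(ids))
        n_train = int(np.round(frac * len(ids)))
        train.extend(ids[i] for i in perm[:n_train])
        verif.extend(ids[i] for i in perm[n_train:])
    return SplitResult(train, verif, dict(strata))


def smote_balance(
    features: pd.DataFrame, labels: pd.Series, cfg: RiskConfig
) -> tuple[pd.DataFrame, pd.Series]:
    """SMOTE class balancing of a training table.

    For each minority point, ``over_pct/100`` synthetic points are created by
    interpolating toward one of its ``smote_k`` nearest minority neighbors
    with a Uniform(0,1) weight; the majority class is then subsampled to
    ``under_pct/100`` times the number of synthetic points.  Original
    minority rows are always preserved.
    """
    y = labels.astype(int)
    counts = y.value_counts()
    if len(counts) != 2:
        raise ValueError("labels must contain both classes")
    minority = counts.idxmin()
    minor = features[y == minority]
    major = features[y != minority]
    n_min = len(minor)
    if n_min < cfg.smote_k + 1:
        raise ValueError(
            f"minority class needs at least smote_k+1 = {cfg.smote_k + 1} samples, "
            f"got {n_min}"
        )
    rng = np.random.default_rng(cfg.seed)
    per_point = cfg.over_pct / 100.0
    n_syn = int(round(per_point * n_min))
    xm = minor.to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=cfg.smote_k + 1).fit(xm)
    _, neigh = nn.kneighbors(xm)
    neigh = neigh[:, 1:]  # drop self
    base = np.repeat(np.arange(n_min), int(np.ceil(per_point)) or 1)
    base = rng.permutation(base)[:n_syn] if len(base) >= n_syn else rng.integers(0, n_min, n_syn)
    pick = neigh[base, rng.integers(0, cfg.smote_k, size=n_syn)]
    u = rng.uniform(size=(n_syn, 1))
    synthetic = xm[base] + u * (xm[pick] - xm[base])
    syn_df = pd.DataFrame(synthetic, columns=features.columns,
                          index=[f"synthetic_{i}" for i in range(n_syn)])
    n_major = int(round(cfg.under_pct / 100.0 * n_syn))
    if n_major >= len(major):
        maj_sel = major
    else:
        sel = rng.choice(len(major), size=n_major, replace=False)
        maj_sel = major.iloc[sel]
    out_x = pd.concat([minor, syn_df, maj_sel])
    out_y = pd.Series(
        [minority] * (n_min + n_syn) + [counts.idxmax()] * len(maj_sel),
        index=out_x.index,
    )
    return out_x, out_y


def fit_logistic(
    features: pd.DataFrame, labels: pd.Series, max_iter: int = 1000
) -> tuple[LogisticRegression, pd.Series, float]:
    """Maximum-likelihood logistic regression (no penalty).

    Returns the fitted model, the coefficient vector (indexed by feature)
    and the intercept.  Constant features and non-convergence (e.g. under
    complete separation) produce warnings, a single class an error.
    """
    if features.shape[1] < 1:
        raise ValueError("need at least one feature")
    y = labels.astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    const = [c for c in features.columns if features[c].nunique() <= 1]
    if const:
        log.warning("constant feature(s): %s", const)
    model = LogisticRegression(penalty=None, max_iter=max_iter, solver="lbfgs")
    with warnings.catch_warnings():
        warnings.simplefilter("always", ConvergenceWarning)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model.fit(features.to_numpy(dtype=float), y)
        for wmsg in caught:
            if issubclass(wmsg.category, ConvergenceWarning):
                log.warning("logistic fit hit the iteration cap "
                            "(possible separation): %s", wmsg.message)
    coefs = pd.Series(model.coef_[0], index=features.columns)
    return model, coefs, float(model.intercept_[0])


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the empirical AUC."""
    m, n = len(pos), len(neg)
    # placement values via mid-ranks (ties count one half)
    all_vals = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_vals)
    rpos = stats.rankdata(pos)
    rneg = stats.rankdata(neg)
    v10 = (ranks[:m] - rpos) / n  # P(neg < pos_i) with half-ties
    v01 = 1.0 - (ranks[m:] - rneg) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(probabilities: np.ndarray, labels: np.ndarray) -> RocResult:
    """AUC (ties count one half) with a DeLong 95% confidence interval."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    pos = p[y == 1]
    neg = p[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("labels contain a single class")
    ranks = stats.rankdata(p)
    auc = (ranks[y == 1].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))
    var = _delong_variance(pos, neg)
    half = 1.96 * np.sqrt(max(var, 0.0))
    lo, hi = max(auc - half, 0.0), min(auc + half, 1.0)
    fpr, tpr, _ = roc_curve(y, p)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return RocResult(float(auc), (float(lo), float(hi)), curve)
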