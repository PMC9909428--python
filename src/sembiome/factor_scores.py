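"""Bartlett factor scores from a frozen measurement model, plus group tests.

After the structural model is accepted, its measurement part (loadings,
residual variances, latent covariance) is frozen and used to score any
sample — in particular samples whose disease status is unknown, which is the
whole point of a risk biomarker.  Scores use the Bartlett (generalized
least squares) estimator

    f_hat = (L' Th^-1 L)^-1 L' Th^-1 x

with ``L`` the loading matrix, ``Th`` the diagonal residual variances and
``x`` the indicator vector standardized with the *training* population
moments.  Bartlett scores are conditionally unbiased for the true factor
values and do not involve the latent covariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .sem_core import LATENTS, FittedSem

__all__ = [
    "MeasurementModel",
    "ScoreTable",
    "WilcoxonResult",
    "extract_measurement_model",
    "bartlett_scores",
    "mann_whitney",
    "compare_groups",
]


@dataclass
class MeasurementModel:
    """Measurement-equation submodel with all parameters fixed."""

    indicators: dict[str, list[str]]  # latent -> indicator names
    loadings: pd.Series  # indexed by indicator
    residual_variances: pd.Series  # indexed by indicator
    latent_covariance: float
    train_means: pd.Series
    train_sds: pd.Series

    def __post_init__(self) -> None:
        if not -1 < self.latent_covariance < 1:
            raise ValueError("latent covariance must lie in (-1, 1)")

    @property
    def all_indicators(self) -> list[str]:
        return [g for lv in LATENTS for g in self.indicators[lv]]

    def loading_matrix(self) -> np.ndarray:
        names = self.all_indicators
        lam = np.zeros((len(names), len(LATENTS)))
        for f, lv in enumerate(LATENTS):
            for g in self.indicators[lv]:
                lam[names.index(g), f] = self.loadings[g]
        return lam

    def to_text(self) -> str:
        lines = []
        for lv in LATENTS:
            terms = " + ".join(
                f"{self.loadings[g]:g}*{g}" for g in self.indicators[lv]
            )
            lines.append(f"{lv} =~ {terms}")
        lines.append(f"lv1 ~~ {self.latent_covariance:g}*lv2")
        for g in self.all_indicators:
            lines.append(f"{g} ~~ {self.residual_variances[g]:g}*{g}")
        return "\n".join(lines)

    def to_json(self) -> str:
        import json

        return json.dumps({
            "indicators": self.indicators,
            "loadings": self.loadings.to_dict(),
            "residual_variances": self.residual_variances.to_dict(),
            "latent_covariance": self.latent_covariance,
            "train_means": self.train_means.to_dict(),
            "train_sds": self.train_sds.to_dict(),
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MeasurementModel":
        import json

        d = json.loads(text)
        return cls(
            indicators={lv: list(v) for lv, v in d["indicators"].items()},
            loadings=pd.Series(d["loadings"]),
            residual_variances=pd.Series(d["residual_variances"]),
            latent_covariance=float(d["latent_covariance"]),
            train_means=pd.Series(d["train_means"]),
            train_sds=pd.Series(d["train_sds"]),
        )


@dataclass
class ScoreTable:
    """Per-sample latent variable scores with group labels."""

    table: pd.DataFrame  # index sample id; columns lv1, lv2, group

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index_label="sample_id")


@dataclass
class WilcoxonResult:
    pair: tuple[str, str]
    u_statistic: float
    p_value: float
    n1: int
    n2: int
    exact: bool


def extract_measurement_model(f: FittedSem) -> MeasurementModel:
    """Freeze the measurement part of a fitted SEM, dropping the outcome.

    Extraction is idempotent in the sense that the parameters are copied
    verbatim: loadings, residual variances and the latent covariance equal
    the fitted values exactly.
    """
    return MeasurementModel(
        indicators={lv: list(f.spec.indicators[lv]) for lv in LATENTS},
        loadings=f.loadings().copy(),
        residual_variances=f.residual_variances().copy(),
        latent_covariance=f.latent_correlation(),
        train_means=f.train_means.copy(),
        train_sds=f.train_sds.copy(),
    )


def bartlett_scores(
    m: MeasurementModel,
    clr: pd.DataFrame,
    groups: dict[str, str] | None = None,
) -> ScoreTable:
    """Bartlett latent scores for every row of a sample x genus matrix.

    Indicators are standardized with the training-set moments stored in the
    model; disease status is never consulted, so held-out samples score
    identically to training samples.
    """
    names = m.all_indicators
    missing = [g for g in names if g not in clr.columns]
    if missing:
        raise ValueError(f"missing genus columns: {missing}")
    theta = m.residual_variances[names].to_numpy(dtype=float)
    if (theta <= 0).any():
        bad = names[int(np.argmin(theta))]
        raise ValueError(f"non-positive residual variance for {bad!r}")
    lam = m.loading_matrix()
    x = clr[names].to_numpy(dtype=float)
    z = (x - m.train_means[names].to_numpy()) / m.train_sds[names].to_numpy()
    lt = lam.T / theta  # L' Th^-1
    scores = np.linalg.solve(lt @ lam, lt @ z.T).T
    tab = pd.DataFrame(scores, index=clr.index, columns=list(LATENTS))
    tab["group"] = [groups.get(s) if groups else None for s in clr.index]
    return ScoreTable(tab)


def mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of all label assignments (tie-safe) when
    ``n1 + n2 <= 10``; otherwise the normal approximation with continuity
    and tie correction.  Returns (U of the first sample, p, exact?).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")

    def u_of(first_idx: tuple[int, ...], values: np.ndarray) -> float:
        mask = np.zeros(len(values), dtype=bool)
        mask[list(first_idx)] = True
        ranks = stats.rankdata(values)
        return ranks[mask].sum() - n1 * (n1 + 1) / 2

    if n1 + n2 <= 10:
        values = np.concatenate([a, b])
        u_obs = u_of(tuple(range(n1)), values)
        ext_obs = min(u_obs, n1 * n2 - u_obs)
        count = total = 0
        for comb in combinations(range(n1 + n2), n1):
            u = u_of(comb, values)
            total += 1
            if min(u, n1 * n2 - u) <= ext_obs + 1e-9:
                count += 1
        return float(u_obs), count / total, True
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), False


def compare_groups(
    s: ScoreTable, pairs: list[tuple[str, str]], variable: str = "lv2"
) -> list[WilcoxonResult]:
    """Wilcoxon-Mann-Whitney comparisons of a score between group pairs."""
    out = []
    for g1, g2 in pairs:
        a = s.table.loc[s.table.group == g1, variable].to_numpy()
        b = s.table.loc[s.table.group == g2, variable].to_numpy()
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"empty group in pair ({g1}, {g2})")
        u, p, exact = mann_whitney(a, b)
        out.append(WilcoxonResult((g1, g2), u, p, len(a), len(b), exact))
    return out
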