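"""Synthetic cohort generator with the latent-factor structure the SEM assumes.

The generative model inverts the analysis model.  Per sample:

* latent factors ``(F1, F2)`` ~ bivariate standard normal, correlation ``c``;
* marker genus log2-scale signal ``x_ij = a_ij * F_i + e_ij`` with
  ``e_ij ~ N(0, 1 - a_ij^2)`` so each marker has unit variance and loading
  ``a_ij`` on the CLR-like scale;
* background genera are independent normals around genus-specific baseline
  offsets drawn from ``N(0, background_sigma^2)``, giving the heavy-tailed
  abundance spectrum real genus tables show;
* the log2 vector maps to a composition by softmax (base 2) and counts are
  multinomial at fixed depth ``D`` (Dirichlet-multinomial when
  ``overdispersion > 0``);
* the binary disease label is a probit threshold model
  ``y = 1  iff  b1*F1 + b2*F2 + eps > tau`` with
  ``eps ~ N(0, 1 - b1^2 - b2^2 - 2*b1*b2*c)``, so the latent response has
  unit variance and ``tau`` fixes the population prevalence.

Questionnaire metadata is filled so that group assignment reproduces the
requested NC/AS/AM/OD sizes exactly: diseased samples become AS or AM (the
latter with an additional other-disease marker), healthy samples become NC
or OD.  Cohort composition is therefore fixed by design (as in a defined
study population) while the label itself still follows the threshold model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CountTable, MetadataTable, REQUIRED_METADATA_COLUMNS

__all__ = [
    "SimConfig",
    "SimTruth",
    "generate_population",
    "generate_community",
    "published_female_scenario",
]

#: Published standardized solution of the female two-latent-variable model.
FEMALE_SOLUTION = {
    "loadings_lv1": {"Alistipes": 0.54, "Butyricimonas": 0.53, "Coprobacter": 0.44},
    "loadings_lv2": {"Fusicatenibacter": 0.58, "Agathobacter": 0.42,
                     "Streptococcus": 0.20},
    "latent_corr": 0.07,
    "b1": 0.32,
    "b2": -0.41,
    "group_sizes": {"NC": 321, "AS": 45, "AM": 75, "OD": 1669},
}


@dataclass
class SimConfig:
    """Ground-truth parameters of a simulated cohort."""

    n_nc: int = 321
    n_as: int = 45
    n_am: int = 75
    n_od: int = 1669
    loadings_lv1: tuple[float, ...] = (0.54, 0.53, 0.44)
    loadings_lv2: tuple[float, ...] = (0.58, 0.42, 0.20)
    latent_corr: float = 0.07
    b1: float = 0.32
    b2: float = -0.41
    prevalence: float | None = None  # population disease prevalence; sets tau
    n_background: int = 150
    background_sigma: float = 3.0
    depth: int = 20_000
    overdispersion: float = 0.0
    sex: str = "female"
    marker_names_lv1: tuple[str, ...] | None = None
    marker_names_lv2: tuple[str, ...] | None = None
    seed: int = 1234

    def __post_init__(self) -> None:
        if not -1 < self.latent_corr < 1:
            raise ValueError("latent correlation must lie in (-1, 1)")
        for a in (*self.loadings_lv1, *self.loadings_lv2):
            if not -1 < a < 1:
                raise ValueError("loadings must lie in (-1, 1)")
        if self.depth < 1000:
            raise ValueError("read depth must be >= 1000")
        if min(self.n_nc, self.n_as, self.n_am, self.n_od) < 0:
            raise ValueError("group sizes must be non-negative")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        if self.outcome_residual_variance <= 0:
            raise ValueError("outcome variance exhausted: b1^2 + b2^2 + "
                             "2*b1*b2*c must be < 1")
        if self.prevalence is None:
            n_total = self.n_nc + self.n_as + self.n_am + self.n_od
            n_pos = self.n_as + self.n_am
            self.prevalence = n_pos / n_total if n_total and n_pos else 0.5

    @property
    def outcome_residual_variance(self) -> float:
        b1, b2, c = self.b1, self.b2, self.latent_corr
        return 1.0 - (b1**2 + b2**2 + 2 * b1 * b2 * c)

    @property
    def tau(self) -> float:
        return float(stats.norm.ppf(1 - self.prevalence))

    @property
    def genus_names(self) -> list[str]:
        m1 = list(self.marker_names_lv1 or
                  [f"MarkerLv1_{i+1}" for i in range(len(self.loadings_lv1))])
        m2 = list(self.marker_names_lv2 or
                  [f"MarkerLv2_{i+1}" for i in range(len(self.loadings_lv2))])
        bg = [f"Genus_{i+1:03d}" for i in range(self.n_background)]
        return m1 + m2 + bg

    @property
    def marker_names(self) -> list[str]:
        return self.genus_names[: len(self.loadings_lv1) + len(self.loadings_lv2)]


@dataclass
class SimTruth:
    """Per-sample ground truth of a simulated cohort."""

    table: pd.DataFrame  # index sample id; F1, F2, y_star, label, group
    config: SimConfig

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index_label="sample_id")


def _draw_samples(cfg: SimConfig, n: int, rng: np.random.Generator,
                  offsets: np.ndarray) -> dict:
    c = cfg.latent_corr
    chol = np.linalg.cholesky(np.array([[1.0, c], [c, 1.0]]))
    F = rng.standard_normal((n, 2)) @ chol.T
    a1 = np.asarray(cfg.loadings_lv1)
    a2 = np.asarray(cfg.loadings_lv2)
    x1 = F[:, [0]] * a1 + rng.standard_normal((n, len(a1))) * np.sqrt(1 - a1**2)
    x2 = F[:, [1]] * a2 + rng.standard_normal((n, len(a2))) * np.sqrt(1 - a2**2)
    bg = offsets + rng.standard_normal((n, cfg.n_background))
    z = np.hstack([x1, x2, bg])  # log2-scale abundances
    comp = np.exp2(z)
    comp /= comp.sum(axis=1, keepdims=True)
    if cfg.overdispersion > 0:
        conc = comp / cfg.overdispersion
        gam = rng.standard_gamma(conc)
        comp = gam / gam.sum(axis=1, keepdims=True)
    counts = rng.multinomial(cfg.depth, comp)
    eps = rng.standard_normal(n) * np.sqrt(cfg.outcome_residual_variance)
    y_star = cfg.b1 * F[:, 0] + cfg.b2 * F[:, 1] + eps
    label = (y_star > cfg.tau).astype(int)
    return {"F": F, "counts": counts, "y_star": y_star, "label": label}


def generate_population(cfg: SimConfig, n: int, rng: np.random.Generator | None = None):
    """Prospective draw of ``n`` samples (no group conditioning).

    Returns (counts array n x genera, truth DataFrame); the disease label is
    binomial with the configured prevalence.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    offsets = rng.normal(0.0, cfg.background_sigma, size=cfg.n_background)
    d = _draw_samples(cfg, n, rng, offsets)
    truth = pd.DataFrame({
        "F1": d["F"][:, 0], "F2": d["F"][:, 1],
        "y_star": d["y_star"], "label": d["label"],
    })
    return d["counts"], truth


_NC_BASE = {
    "atopic_dermatitis": False, "other_disease": False, "medication": False,
    "hospitalization_or_surgery": False, "helicobacter_treatment": False,
    "insomnia_consultation": False, "smoking_history": False,
    "menstruating_now": False, "pregnant_or_breastfeeding": False,
    "colorectal_surgery_history": False,
}


def _metadata_row(group: str, sex: str, rng: np.random.Generator) -> dict:
    """Questionnaire answers that place a sample in exactly ``group``."""
    row = dict(_NC_BASE)
    row["sex"] = sex
    row["bmi"] = float(np.round(rng.uniform(18.6, 24.5), 1))
    row["cesd"] = int(rng.integers(0, 15))
    row["age"] = int(rng.integers(20, 79))
    row["defecation_frequency"] = rng.choice(["1-2_per_day", "4-6_per_week"])
    row["alcohol"] = rng.choice(["none", "moderate_le5_per_week"])
    row["menstrual_status"] = "regular" if sex == "female" else None
    if group in ("AS", "AM"):
        row["atopic_dermatitis"] = True
    if group in ("AM", "OD"):
        # pick which marker makes this an "other disease" case
        marker = rng.choice(["flag", "bmi_high", "bmi_low", "cesd", "surgery"])
        if marker == "flag":
            row["other_disease"] = True
        elif marker == "bmi_high":
            row["bmi"] = float(np.round(rng.uniform(25.0, 35.0), 1))
        elif marker == "bmi_low":
            row["bmi"] = float(np.round(rng.uniform(15.0, 18.4), 1))
        elif marker == "cesd":
            row["cesd"] = int(rng.integers(16, 40))
        else:
            row["colorectal_surgery_history"] = True
        # non-NC lifestyle answers are unconstrained for AS/AM/OD
        row["smoking_history"] = bool(rng.uniform() < 0.3)
        row["alcohol"] = rng.choice(list(("none", "moderate_le5_per_week",
                                          "heavy_or_gt5_per_week")))
    return row


def generate_community(cfg: SimConfig):
    """Generate a cohort with exact NC/AS/AM/OD sizes plus ground truth.

    Samples are drawn prospectively from the latent-factor model and then
    retrospectively assembled: threshold-positive draws fill the AS and AM
    quotas, negative draws fill NC and OD, and metadata is written so group
    assignment recovers exactly the requested sizes.

    Returns ``(CountTable, MetadataTable, SimTruth)``.
    """
    rng = np.random.default_rng(cfg.seed)
    offsets = rng.normal(0.0, cfg.background_sigma, size=cfg.n_background)
    n_pos_need = cfg.n_as + cfg.n_am
    n_neg_need = cfg.n_nc + cfg.n_od
    pos_rows: list[int] = []
    neg_rows: list[int] = []
    counts_parts: list[np.ndarray] = []
    truth_parts: list[pd.DataFrame] = []
    total = 0
    guard = 0
    while len(pos_rows) < n_pos_need or len(neg_rows) < n_neg_need:
        guard += 1
        if guard > 200:
            raise RuntimeError("could not fill group quotas; prevalence too extreme")
        remaining_pos = max(n_pos_need - len(pos_rows), 0)
        batch = max(
            2 * n_neg_need,
            int(remaining_pos / max(cfg.prevalence, 1e-6) * 1.5) + 100,
        )
        d = _draw_samples(cfg, batch, rng, offsets)
        counts_parts.append(d["counts"])
        truth_parts.append(pd.DataFrame({
            "F1": d["F"][:, 0], "F2": d["F"][:, 1],
            "y_star": d["y_star"], "label": d["label"],
        }))
        for i, lab in enumerate(d["label"]):
            (pos_rows if lab else neg_rows).append(total + i)
        total += batch
    counts_all = np.vstack(counts_parts)
    truth_all = pd.concat(truth_parts, ignore_index=True)

    chosen = pos_rows[:n_pos_need] + neg_rows[:n_neg_need]
    group_seq = (["AS"] * cfg.n_as + ["AM"] * cfg.n_am
                 + ["NC"] * cfg.n_nc + ["OD"] * cfg.n_od)
    order = rng.permutation(len(chosen))
    sample_ids = [f"S{i+1:05d}" for i in range(len(chosen))]
    rows = []
    meta_rows = []
    for new_pos, k in enumerate(order):
        src = chosen[k]
        grp = group_seq[k]
        sid = sample_ids[new_pos]
        rows.append((sid, src, grp))
        meta = _metadata_row(grp, cfg.sex, rng)
        meta["sample_id"] = sid
        meta_rows.append(meta)

    idx = [src for _, src, _ in rows]
    counts = counts_all[idx].T  # genus x sample
    table = CountTable(cfg.genus_names, [sid for sid, _, _ in rows], counts)

    meta_df = pd.DataFrame(meta_rows).set_index("sample_id")
    for col in REQUIRED_METADATA_COLUMNS:
        if col != "sample_id" and col not in meta_df.columns:
            meta_df[col] = pd.NA
    bool_cols = [c for c in meta_df.columns
                 if meta_df[c].dropna().map(lambda v: isinstance(v, (bool, np.bool_))).all()
                 and meta_df[c].notna().any()]
    for c in set(bool_cols) & set(_NC_BASE):
        meta_df[c] = meta_df[c].astype("boolean")
    for c in ("menstruating_now", "pregnant_or_breastfeeding"):
        meta_df[c] = meta_df[c].astype("boolean")
    meta = MetadataTable(meta_df)

    truth = truth_all.iloc[idx].reset_index(drop=True)
    truth.index = pd.Index([sid for sid, _, _ in rows], name="sample_id")
    truth["group"] = [grp for _, _, grp in rows]
    return table, meta, SimTruth(truth, cfg)


def published_female_scenario(n_scale: float = 1.0, seed: int = 1234, **overrides) -> SimConfig:
    """SimConfig preset matching the published female standardized solution.

    Group sizes (321, 45, 75, 1669) are scaled by ``n_scale`` with ordinary
    rounding; loadings, paths and the latent correlation echo the printed
    female solution.
    """
    if n_scale <= 0:
        raise ValueError("n_scale must be positive")
    sol = FEMALE_SOLUTION
    sizes = {k: int(np.round(v * n_scale)) for k, v in sol["group_sizes"].items()}
    cfg = SimConfig(
        n_nc=sizes["NC"], n_as=sizes["AS"], n_am=sizes["AM"], n_od=sizes["OD"],
        loadings_lv1=tuple(sol["loadings_lv1"].values()),
        loadings_lv2=tuple(sol["loadings_lv2"].values()),
        latent_corr=sol["latent_corr"], b1=sol["b1"], b2=sol["b2"],
        marker_names_lv1=tuple(sol["loadings_lv1"]),
        marker_names_lv2=tuple(sol["loadings_lv2"]),
        # The printed solution describes the NC+AS population the SEM was fit
        # to, so the threshold reproduces that population's disease rate.
        prevalence=sol["group_sizes"]["AS"]
        / (sol["group_sizes"]["NC"] + sol["group_sizes"]["AS"]),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg
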