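"""Compositional effect sizes and top-k stability selection of marker genera.

For two groups of samples the per-genus effect size is a standardized median
difference computed on the Dirichlet Monte-Carlo CLR ensemble: between-group
differences are formed by randomly pairing samples across groups in every
instance, within-group dispersions by random pairings within each group, and

    effect = median(between differences)
             / max(median |within A|, median |within B|).

Positive effects mean higher CLR abundance in the second-listed group.  The
statistic is deliberately robust (medians of pairwise differences) and
scale-free.

Because the Monte-Carlo draws and pairings inject randomness, the whole
calculation is repeated many times with fresh seeds and only the genera that
land in the top-k (by absolute effect) of *every* repetition are retained as
stable markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clr_transform import ClrConfig, ClrEnsemble, clr_ensemble
from .data_model import CountTable

__all__ = [
    "EffectTable",
    "StableMarkers",
    "effect_sizes",
    "top_k_by_abs_effect",
    "stable_marker_selection",
]

log = logging.getLogger(__name__)


@dataclass
class EffectTable:
    """Per-genus standardized effects with their components."""

    table: pd.DataFrame  # index genus; columns effect, diff_btw, dispersion

    @property
    def effects(self) -> pd.Series:
        return self.table["effect"]


@dataclass
class StableMarkers:
    """Genera intersecting the top-k list of every repetition."""

    genera: list[str]
    mean_effect: pd.Series  # indexed by genus, mean over repetitions
    reps: int
    k: int

    def signed(self) -> dict[str, float]:
        return {g: float(self.mean_effect[g]) for g in self.genera}

    def to_frame(self) -> pd.DataFrame:
        eff = self.mean_effect.reindex(self.genera)
        return pd.DataFrame(
            {"genus": self.genera, "mean_effect": eff.to_numpy(),
             "sign": np.sign(eff.to_numpy()).astype(int)}
        )


def _group_indices(
    samples: list[str], groups: dict[str, str], labels: tuple[str, str] | None
) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    present = [groups[s] for s in samples if groups.get(s) is not None]
    uniq = list(dict.fromkeys(present))
    if labels is None:
        if len(uniq) != 2:
            raise ValueError(f"need exactly two group labels, got {uniq}")
        labels = (uniq[0], uniq[1])
    elif set(labels) != set(uniq):
        raise ValueError(f"labels {labels} do not match data labels {uniq}")
    a, b = labels
    ia = np.array([i for i, s in enumerate(samples) if groups.get(s) == a])
    ib = np.array([i for i, s in enumerate(samples) if groups.get(s) == b])
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("each group needs at least 2 samples")
    return ia, ib, (a, b)


def effect_sizes(
    ens: ClrEnsemble,
    groups: dict[str, str],
    seed: int = 1234,
    labels: tuple[str, str] | None = None,
) -> EffectTable:
    """Standardized two-group effect per genus on a CLR ensemble.

    ``groups`` maps sample id -> one of exactly two labels; ``labels`` gives
    the (reference, comparison) order — positive effects mean higher
    abundance in the second-listed group.  Without ``labels`` the first
    label encountered in ensemble order is the reference.
    """
    ia, ib, _ = _group_indices(ens.samples, groups, labels)
    x = ens.values  # (n, g, k)
    n_inst = x.shape[2]
    n_pairs = max(len(ia), len(ib))

    def draw(pool: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(pool, size=(n_inst, n_pairs), replace=True)

    # per-group streams keyed by group membership (not by group role), so
    # swapping the two labels negates the effects exactly
    rng_a = np.random.default_rng([seed, *map(int, ia)])
    rng_b = np.random.default_rng([seed, *map(int, ib)])
    sel_a, sel_b = draw(ia, rng_a), draw(ib, rng_b)
    wa1, wa2 = draw(ia, rng_a), draw(ia, rng_a)
    wb1, wb2 = draw(ib, rng_b), draw(ib, rng_b)
    inst = np.arange(n_inst)[:, None]
    btw = _paired(x, sel_b, inst) - _paired(x, sel_a, inst)
    win_a = np.abs(_paired(x, wa1, inst) - _paired(x, wa2, inst))
    win_b = np.abs(_paired(x, wb1, inst) - _paired(x, wb2, inst))
    med_btw = np.median(btw, axis=(0, 1))
    disp = np.maximum(np.median(win_a, axis=(0, 1)), np.median(win_b, axis=(0, 1)))
    disp = np.where(disp <= 0, np.finfo(float).tiny, disp)
    eff = med_btw / disp
    tab = pd.DataFrame(
        {"effect": eff, "diff_btw": med_btw, "dispersion": disp}, index=ens.genera
    )
    return EffectTable(tab)


def _paired(x: np.ndarray, sel: np.ndarray, inst: np.ndarray) -> np.ndarray:
    """Gather CLR values for per-instance sample selections.

    ``sel`` has shape (n_inst, n_pairs); the result has shape
    (n_inst, n_pairs, n_genera) where entry [t, p, g] = x[sel[t, p], g, t].
    """
    return x.transpose(2, 0, 1)[inst, sel, :]


def top_k_by_abs_effect(t: EffectTable, k: int) -> list[str]:
    """Top-k genera by |effect|, descending; ties broken lexicographically."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(t.table):
        raise ValueError("k exceeds the number of genera")
    order = sorted(
        t.table.index, key=lambda g: (-abs(t.table.at[g, "effect"]), g)
    )
    return order[:k]


def stable_marker_selection(
    counts: CountTable,
    groups: dict[str, str],
    reps: int = 500,
    k: int = 20,
    base_seed: int = 1234,
    clr_cfg: ClrConfig | None = None,
    labels: tuple[str, str] | None = None,
) -> StableMarkers:
    """Intersection of the top-k effect lists over ``reps`` re-randomized runs.

    Each repetition rebuilds the Dirichlet CLR ensemble *and* re-draws the
    random pairings with seed ``base_seed + r`` (r = 1..reps).  An empty
    intersection is a valid result (logged as a warning).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    clr_cfg = clr_cfg or ClrConfig()
    surviving: set[str] | None = None
    sums: pd.Series | None = None
    for r in range(1, reps + 1):
        seed = base_seed + r
        cfg = ClrConfig(
            n_instances=clr_cfg.n_instances, prior=clr_cfg.prior,
            seed=seed, expected=clr_cfg.expected,
        )
        ens = clr_ensemble(counts, cfg)
        eff = effect_sizes(ens, groups, seed=seed, labels=labels)
        top = set(top_k_by_abs_effect(eff, k))
        surviving = top if surviving is None else (surviving & top)
        sums = eff.effects if sums is None else (sums + eff.effects)
        if not surviving:
            log.warning("stable marker intersection empty after %d repetitions", r)
            break
    mean_eff = sums / min(reps, r)
    genera = sorted(surviving, key=lambda g: (-abs(mean_eff[g]), g))
    return StableMarkers(genera, mean_eff, reps=reps, k=k)
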