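"""Monte-Carlo Dirichlet centered log-ratio (CLR) transformation.

Read counts are compositional: only relative abundances are informative, and
low counts carry large uncertainty.  Both issues are handled by drawing, for
every sample, ``n_instances`` composition vectors from a
``Dirichlet(counts + prior)`` posterior and applying the CLR transform

    clr(p)_j = log2 p_j - mean_j log2 p_j

to each draw, centering over all genera.  Downstream statistics (effect
sizes, the SEM input matrix) then aggregate over the instance dimension, so
count uncertainty propagates instead of being discarded.

A deterministic "expected-proportion" mode replaces the Dirichlet draws with
the posterior mean ``(counts + prior) / sum`` and is used for exact tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CountTable

__all__ = ["ClrConfig", "ClrEnsemble", "clr_ensemble", "clr_point_estimate"]

#: Default seed for the Monte-Carlo draws, kept as the conventional 1234.
DEFAULT_SEED = 1234


@dataclass
class ClrConfig:
    """Settings for the Monte-Carlo CLR ensemble.

    Parameters
    ----------
    n_instances : int
        Number of Dirichlet Monte-Carlo instances per sample (default 128).
    prior : float
        Uniform pseudo-count added to every cell (default 0.5), which keeps
        zero counts finite on the log scale.
    seed : int
        Seed for the Dirichlet draws.
    expected : bool
        If True, suppress Monte-Carlo variance and use posterior-mean
        proportions (n_instances collapses to identical instances).
    """

    n_instances: int = 128
    prior: float = 0.5
    seed: int = DEFAULT_SEED
    expected: bool = False

    def __post_init__(self) -> None:
        if self.n_instances < 1:
            raise ValueError("n_instances must be >= 1")
        if self.prior <= 0:
            raise ValueError("prior must be > 0")


@dataclass
class ClrEnsemble:
    """sample x genus x instance array of CLR values (log2 units)."""

    samples: list[str]
    genera: list[str]
    values: np.ndarray  # shape (n_samples, n_genera, n_instances)

    def __post_init__(self) -> None:
        expected = (len(self.samples), len(self.genera))
        if self.values.shape[:2] != expected:
            raise ValueError(
                f"value array shape {self.values.shape} does not match labels {expected}"
            )

    @property
    def n_instances(self) -> int:
        return self.values.shape[2]


def clr_ensemble(counts: CountTable, cfg: ClrConfig | None = None) -> ClrEnsemble:
    """Dirichlet Monte-Carlo CLR ensemble of a count table.

    Reproducible for a fixed ``cfg.seed``; raises if any sample column is
    all zeros.
    """
    cfg = cfg or ClrConfig()
    mat = counts.counts.T.astype(float)  # samples x genera
    totals = mat.sum(axis=1)
    if (totals <= 0).any():
        bad = counts.samples[int(np.argmin(totals))]
        raise ValueError(f"sample {bad!r} has zero total count")
    alpha = mat + cfg.prior
    n, g = alpha.shape
    if cfg.expected:
        p = alpha / alpha.sum(axis=1, keepdims=True)
        draws = np.repeat(p[:, :, None], cfg.n_instances, axis=2)
    else:
        rng = np.random.default_rng(cfg.seed)
        # draw gammas in a canonical (sorted-label) genus order so the
        # ensemble is invariant to the row order of the input table
        order = np.argsort(np.asarray(counts.genera, dtype=object))
        inverse = np.argsort(order)
        gam = rng.standard_gamma(
            alpha[:, order, None], size=(n, g, cfg.n_instances)
        )[:, inverse, :]
        draws = gam / gam.sum(axis=1, keepdims=True)
    logd = np.log2(draws)
    clr = logd - logd.mean(axis=1, keepdims=True)
    return ClrEnsemble(list(counts.samples), list(counts.genera), clr)


def clr_point_estimate(ens: ClrEnsemble) -> pd.DataFrame:
    """Element-wise median across instances, rows re-centered to sum zero.

    Returns a sample x genus DataFrame usable as the SEM input matrix.
    """
    med = np.median(ens.values, axis=2)
    med -= med.mean(axis=1, keepdims=True)
    return pd.DataFrame(med, index=ens.samples, columns=ens.genera)
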