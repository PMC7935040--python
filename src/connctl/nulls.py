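"""Degree-preserving null networks and the gray-matter coefficient null test.

Randomization uses Maslov–Sneppen double-edge swaps with weights carried on
their edges: the *binary* degree sequence, the edge count and the multiset of
edge weights are preserved exactly. Node strength (weighted degree) is NOT
preserved — only the binary degree distribution is, which is precisely what
the swap move conserves.

The null test rewires every subject's (thresholded) connectome, recomputes
controllability and strength, refits the mixed model and records the rGM
coefficient, yielding an empirical one-sided p-value for the observed
coefficient against the null distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .connectome import ConnectivityMatrix, threshold_proportional
from .control import control_profile
from .lme import ModelSpec, fit_lme
from .table import SubjectVolumetrics, assemble, center_and_scale

__all__ = ["NullDistribution", "rewire_preserving_degree", "null_beta_test"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NullDistribution:
    """Observed rGM coefficient against its randomized-network distribution."""

    original_beta: float
    null_betas: np.ndarray
    n_replicates: int
    seed: int
    n_failures: int = 0
    alternative: str = "greater"

    def __post_init__(self) -> None:
        betas = np.asarray(self.null_betas, dtype=float)
        object.__setattr__(self, "null_betas", betas)
        if betas.size == 0:
            raise ValueError("empty null distribution")

    @property
    def p_value(self) -> float:
        r = self.null_betas.size
        if self.alternative == "greater":
            extreme = np.sum(self.null_betas >= self.original_beta)
        elif self.alternative == "two-sided":
            extreme = np.sum(np.abs(self.null_betas) >= abs(self.original_beta))
        else:
            raise ValueError(f"unknown alternative {self.alternative!r}")
        return float((1 + extreme) / (r + 1))

    def summary(self) -> dict:
        return {
            "original_beta": self.original_beta,
            "p_value": self.p_value,
            "n_replicates": self.n_replicates,
            "n_used": int(self.null_betas.size),
            "n_failures": self.n_failures,
            "seed": self.seed,
            "alternative": self.alternative,
        }


def rewire_preserving_degree(
    C: ConnectivityMatrix,
    swaps_per_edge: int = 10,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
) -> ConnectivityMatrix:
    """Randomize topology by weighted Maslov–Sneppen double-edge swaps.

    Attempts ``swaps_per_edge × edge_count`` swaps; each picks two disjoint
    edges (a,b), (c,d) and rewires to (a,d), (c,b) when neither exists,
    carrying each edge's weight with it. Deterministic for a given seed.
    """
    if swaps_per_edge < 1:
        raise ValueError("swaps_per_edge must be >= 1")
    rng = np.random.default_rng(seed)
    w = C.weights.copy()
    n = w.shape[0]
    iu, ju = np.nonzero(np.triu(w, k=1))
    m = iu.size
    if m < 4:
        raise ValueError(f"graph has only {m} edges; need >= 4 to rewire")
    edges = np.stack([iu, ju], axis=1)
    weights = w[iu, ju].copy()
    present = {(int(i), int(j)) for i, j in edges}

    attempts = swaps_per_edge * m
    successes = 0
    for _ in range(attempts):
        e1, e2 = rng.choice(m, size=2, replace=False)
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        # proposed: (a,d) and (c,b)
        if len({a, b, c, d}) < 4:
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if new1 in present or new2 in present:
            continue
        present.discard((min(a, b), max(a, b)))
        present.discard((min(c, d), max(c, d)))
        present.add(new1)
        present.add(new2)
        edges[e1] = new1
        edges[e2] = new2
        successes += 1
    if successes == 0:
        logger.warning(
            "rewiring achieved 0/%d successful swaps; graph too constrained",
            attempts,
        )
        warnings.warn(
            f"no legal double-edge swap found in {attempts} attempts",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.zeros_like(w)
    out[edges[:, 0], edges[:, 1]] = weights
    out = out + out.T
    return C.with_weights(out)


def null_beta_test(
    connectomes: Sequence[ConnectivityMatrix],
    volumetrics: Sequence[SubjectVolumetrics],
    atlas: RegionAtlas,
    model_spec: ModelSpec,
    n_replicates: int,
    seed: int,
    *,
    threshold: float | None = 0.10,
    scheme: str = "singular_value",
    sd_mode: str = "pooled",
    swaps_per_edge: int = 10,
    alternative: str = "greater",
    beta_term: str = "rgm",
) -> NullDistribution:
    """Empirical null test of the gray-matter coefficient.

    Fits the model on the observed (thresholded) connectomes, then on
    ``n_replicates`` cohorts in which every subject's network is rewired
    degree-preservingly, and compares the ``beta_term`` coefficient.
    Replicates whose fit does not converge are excluded (and counted);
    more than 10% failures aborts.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    def _pipeline(mats: Sequence[ConnectivityMatrix]) -> float:
        profiles = [control_profile(c, scheme=scheme) for c in mats]
        table = center_and_scale(
            assemble(profiles, volumetrics, atlas), sd_mode=sd_mode
        )
        result = fit_lme(table, model_spec, method="ML")
        if not result.converged:
            raise RuntimeError("LME did not converge")
        return result.coefficients[beta_term].beta

    observed = [
        threshold_proportional(c, threshold) if threshold is not None else c
        for c in connectomes
    ]
    original_beta = _pipeline(observed)

    root = np.random.SeedSequence(seed)
    replicate_seeds = root.spawn(n_replicates)
    null_betas: list[float] = []
    failures = 0
    max_failures = max(1, int(0.10 * n_replicates))
    for rep, rep_seq in enumerate(replicate_seeds):
        subject_seeds = rep_seq.spawn(len(observed))
        try:
            rewired = [
                rewire_preserving_degree(
                    c, swaps_per_edge=swaps_per_edge,
                    seed=np.random.default_rng(sseq),
                )
                for c, sseq in zip(observed, subject_seeds)
            ]
            null_betas.append(_pipeline(rewired))
        except RuntimeError as exc:
            failures += 1
            logger.warning("replicate %d excluded: %s", rep, exc)
            if failures > max_failures:
                raise RuntimeError(
                    f"{failures} of {rep + 1} null replicates failed to "
                    f"converge (> 10% of {n_replicates}); aborting"
                ) from exc
    return NullDistribution(
        original_beta=original_beta,
        null_betas=np.array(null_betas),
        n_replicates=n_replicates,
        seed=seed,
        n_failures=failures,
        alternative=alternative,
    )


def null_distribution_frame(dist: NullDistribution) -> pd.DataFrame:
    """Tidy (replicate, beta) table for serialization."""
    return pd.DataFrame(
        {"replicate": np.arange(dist.null_betas.size), "beta": dist.null_betas}
    )
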