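"""Synthetic cohorts and model fixtures with known ground truth.

``generate_cohort`` builds a heavy-tailed group-template connectome, per-
subject matrices with multiplicative lognormal edge noise, regional gray-
matter volumes whose across-region correlation with template strength is set
*exactly* per subject (Gram–Schmidt construction, then a positive affine map
to volume units, which preserves Pearson correlation), and truncated-normal
TIV. ``generate_lme_fixture`` builds a long table whose response is exactly
X·beta + subject intercept + noise, so mixed-model estimates can be checked
against the generating coefficients.

All randomness flows from one seed through named substreams (template,
subjects, volumetrics) so components can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, default_atlas
from .connectome import ConnectivityMatrix
from .table import StudyTable, SubjectVolumetrics

__all__ = ["CohortConfig", "LmeFixtureConfig", "generate_cohort", "generate_lme_fixture"]


@dataclass(frozen=True)
class CohortConfig:
    """Knobs for synthetic cohort generation; defaults mirror a 65×120 study."""

    n_subjects: int = 65
    n_regions: int = 120
    template_degree_exponent: float = 2.5
    subject_noise_sd: float = 0.2
    rgm_topology_coupling: float = 0.0
    tiv_mean: float = 1.5e6
    tiv_sd: float = 1.2e5
    seed: int = 0
    edge_density: float = 0.6
    rgm_mean: float = 4000.0
    rgm_rel_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_regions <= 1:
            raise ValueError("n_subjects must be >=1 and n_regions >= 2")
        if not -1.0 <= self.rgm_topology_coupling <= 1.0:
            raise ValueError("rgm_topology_coupling must lie in [-1, 1]")
        if self.subject_noise_sd < 0 or self.tiv_sd <= 0 or self.tiv_mean <= 0:
            raise ValueError("noise and TIV parameters must be positive")
        if self.template_degree_exponent <= 1.0:
            raise ValueError("template_degree_exponent must exceed 1")


@dataclass(frozen=True)
class LmeFixtureConfig:
    """Ground-truth coefficients for a mixed-model recovery fixture."""

    true_betas: dict = field(default_factory=dict)
    random_intercept_sd: float = 0.5
    residual_sd: float = 1.0
    n_subjects: int = 65
    n_regions: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_sd <= 0 or self.random_intercept_sd < 0:
            raise ValueError("residual_sd must be > 0 and random_intercept_sd >= 0")
        if self.n_subjects < 2 or self.n_regions < 2:
            raise ValueError("need at least 2 subjects and 2 regions")
        unknown = set(self.true_betas) - {"tiv", "degree", "strength", "rgm",
                                          "degree:rgm", "strength:rgm"}
        if unknown:
            raise ValueError(f"unknown terms in true_betas: {sorted(unknown)}")


def _template_matrix(n: int, exponent: float, density: float, rng) -> np.ndarray:
    """Symmetric weighted template with heavy-tailed strength distribution."""
    # Pareto-tailed strength propensities, capped for numerical sanity
    u = rng.uniform(size=n)
    s = (1.0 - u) ** (-1.0 / (exponent - 1.0))
    s = np.clip(s, None, 50.0 * np.median(s))
    w = np.outer(s, s) / s.sum()
    w *= rng.lognormal(mean=0.0, sigma=0.5, size=(n, n))
    w = np.triu(w, k=1)
    # sparsify: keep a random fraction of edges, guaranteeing connectivity is
    # not required — only heterogeneous positive strengths are
    if density < 1.0:
        mask = rng.uniform(size=w.shape) < density
        w = w * mask
    w = w + w.T
    np.fill_diagonal(w, 0.0)
    # avoid isolated nodes: give any empty row one weak edge
    strengths = w.sum(axis=1)
    for i in np.flatnonzero(strengths == 0):
        j = (i + 1) % n
        w[i, j] = w[j, i] = np.median(w[w > 0]) if (w > 0).any() else 1.0
    return 100.0 * w / w.mean()  # streamline-count-like scale


def _exact_corr_mix(target: np.ndarray, rho: float, rng) -> np.ndarray:
    """Standardized vector whose sample correlation with ``target`` is exactly rho."""
    z = (target - target.mean()) / target.std()
    eps = rng.normal(size=target.size)
    eps = eps - eps.mean()
    eps = eps - z * (eps @ z) / (z @ z)  # residualize against z
    norm = eps.std()
    if norm == 0:
        raise ValueError("degenerate noise vector")
    eps = eps / norm
    return rho * z + np.sqrt(1.0 - rho**2) * eps


def generate_cohort(
    cfg: CohortConfig, atlas: RegionAtlas | None = None
) -> tuple[list[ConnectivityMatrix], list[SubjectVolumetrics], RegionAtlas]:
    """Simulate subject connectomes, regional volumes and TIV."""
    if atlas is None:
        atlas = (
            default_atlas()
            if cfg.n_regions == 120
            else RegionAtlas.synthetic(cfg.n_regions)
        )
    if atlas.n_regions != cfg.n_regions:
        raise ValueError("atlas size does not match n_regions")
    root = np.random.SeedSequence(cfg.seed)
    streams = dict(zip(("template", "subjects", "volumetrics"), root.spawn(3)))

    n = cfg.n_regions
    template = _template_matrix(
        n, cfg.template_degree_exponent, cfg.edge_density,
        np.random.default_rng(streams["template"]),
    )
    template_strength = template.sum(axis=1)

    subj_rng = np.random.default_rng(streams["subjects"])
    connectomes = []
    for s in range(cfg.n_subjects):
        noise = subj_rng.lognormal(mean=0.0, sigma=cfg.subject_noise_sd, size=(n, n))
        noise = np.triu(noise, k=1)
        noise = noise + noise.T
        w = template * noise
        np.fill_diagonal(w, 0.0)
        connectomes.append(
            ConnectivityMatrix(
                weights=w, atlas=atlas, subject_id=f"sub-{s + 1:03d}"
            )
        )

    vol_rng = np.random.default_rng(streams["volumetrics"])
    volumetrics = []
    for s in range(cfg.n_subjects):
        x = _exact_corr_mix(template_strength, cfg.rgm_topology_coupling, vol_rng)
        scale = cfg.rgm_rel_sd
        # shrink until strictly positive; positive affine map keeps the
        # correlation exact
        while np.any(1.0 + scale * x <= 0):
            scale *= 0.5
        rgm = cfg.rgm_mean * (1.0 + scale * x)
        tiv = 0.0
        while tiv <= 0:
            tiv = vol_rng.normal(cfg.tiv_mean, cfg.tiv_sd)
        if rgm.sum() > tiv:
            rgm *= 0.8 * tiv / rgm.sum()
        volumetrics.append(
            SubjectVolumetrics(subject_id=f"sub-{s + 1:03d}", tiv=float(tiv), rgm=rgm)
        )
    return connectomes, volumetrics, atlas


def generate_lme_fixture(cfg: LmeFixtureConfig, atlas: RegionAtlas | None = None) -> StudyTable:
    """Long table with response = X·beta + subject intercept + residual noise.

    Predictors (degree, rgm, tiv and an unused mc column) are simulated
    standardized, so the returned StudyTable's scaled view equals its raw
    view and can be fed straight to the model fitter.
    """
    if atlas is None:
        atlas = (
            default_atlas()
            if cfg.n_regions == 120
            else RegionAtlas.synthetic(cfg.n_regions)
        )
    rng = np.random.default_rng(cfg.seed)
    ns, nr = cfg.n_subjects, cfg.n_regions
    subjects = [f"sub-{i + 1:03d}" for i in range(ns)]
    regions = list(atlas.names[:nr])

    degree = rng.normal(size=ns * nr)
    rgm = rng.normal(size=ns * nr)
    tiv_subj = rng.normal(size=ns)
    tiv = np.repeat(tiv_subj, nr)

    betas = {k.replace("strength", "degree"): v for k, v in cfg.true_betas.items()}
    response = (
        betas.get("tiv", 0.0) * tiv
        + betas.get("degree", 0.0) * degree
        + betas.get("rgm", 0.0) * rgm
        + betas.get("degree:rgm", 0.0) * degree * rgm
    )
    response = response + np.repeat(
        rng.normal(scale=cfg.random_intercept_sd, size=ns), nr
    )
    response = response + rng.normal(scale=cfg.residual_sd, size=ns * nr)

    df = pd.DataFrame(
        {
            "subject_id": np.repeat(subjects, nr),
            "region_name": np.tile(regions, ns),
            "ac": response,
            "mc": rng.normal(size=ns * nr),
            "strength": degree,
            "rgm": rgm,
            "tiv": tiv,
        }
    )
    return StudyTable(data=df, scaled=df.copy(), scaling={"pre_standardized": True})
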