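"""Long-format subject × region observation table for the mixed models.

Joins per-subject control profiles with regional gray-matter volumes and
total intracranial volume, then applies the modeling transform: each regional
variable is centered to mean zero within subject and z-scaled; TIV, constant
within subject, is centered and scaled across subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .control import ControlProfile

__all__ = [
    "SubjectVolumetrics",
    "StudyTable",
    "assemble",
    "center_and_scale",
    "read_volumetrics",
    "write_volumetrics",
]

logger = logging.getLogger(__name__)

#: columns transformed within subject
REGIONAL_COLUMNS = ("ac", "mc", "strength", "rgm")


@dataclass(frozen=True)
class SubjectVolumetrics:
    """Regional gray-matter volumes (mm³, atlas order) and TIV for one subject."""

    subject_id: str
    tiv: float
    rgm: np.ndarray

    def __post_init__(self) -> None:
        rgm = np.asarray(self.rgm, dtype=float)
        object.__setattr__(self, "rgm", rgm)
        if not np.isfinite(self.tiv) or self.tiv <= 0:
            raise ValueError(f"{self.subject_id}: TIV must be positive and finite")
        if rgm.ndim != 1:
            raise ValueError("rgm must be a 1-D vector")
        if not np.all(np.isfinite(rgm)) or np.any(rgm <= 0):
            raise ValueError(f"{self.subject_id}: rgm values must be positive and finite")
        if rgm.sum() > self.tiv:
            raise ValueError(
                f"{self.subject_id}: total rGM {rgm.sum():.4g} exceeds TIV {self.tiv:.4g}"
            )


@dataclass
class StudyTable:
    """Raw and (optionally) scaled long-format observations.

    ``data`` has one row per (subject_id, region_name) with columns
    ac, mc, strength, rgm, tiv. ``scaled`` mirrors it after the modeling
    transform; ``scaling`` records the constants used.
    """

    data: pd.DataFrame
    scaled: pd.DataFrame | None = None
    scaling: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def n_regions(self) -> int:
        return self.data["region_name"].nunique()


def write_volumetrics(
    volumetrics: Iterable[SubjectVolumetrics], atlas: RegionAtlas, path
) -> None:
    """Tidy TSV: one row per (subject, region) plus the subject's TIV."""
    rows = []
    for v in volumetrics:
        for name, value in zip(atlas.names, v.rgm):
            rows.append(
                {"subject_id": v.subject_id, "region_name": name,
                 "rgm": value, "tiv": v.tiv}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_volumetrics(path, atlas: RegionAtlas) -> list[SubjectVolumetrics]:
    """Inverse of :func:`write_volumetrics` (atlas region order enforced)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"subject_id", "region_name", "rgm", "tiv"}
    if not required.issubset(df.columns):
        raise ValueError(f"volumetrics table needs columns {sorted(required)}")
    out = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.set_index("region_name")
        missing = set(atlas.names) - set(grp.index)
        if missing:
            raise ValueError(f"{sid}: missing regions {sorted(missing)[:5]}...")
        rgm = grp.loc[list(atlas.names), "rgm"].to_numpy(dtype=float)
        tiv = float(grp["tiv"].iloc[0])
        out.append(SubjectVolumetrics(subject_id=str(sid), tiv=tiv, rgm=rgm))
    return out


def assemble(
    profiles: Iterable[ControlProfile],
    volumetrics: Iterable[SubjectVolumetrics],
    atlas: RegionAtlas,
) -> StudyTable:
    """Inner-join control profiles and volumetrics into a StudyTable.

    Subjects present in only one input are dropped with a warning; rows with
    any missing value are dropped with the count logged.
    """
    prof_frames = {p.subject_id: p for p in profiles}
    vol_map = {v.subject_id: v for v in volumetrics}
    if len(prof_frames) == 0 or len(vol_map) == 0:
        raise ValueError("profiles and volumetrics must be non-empty")
    common = sorted(set(prof_frames) & set(vol_map))
    if not common:
        raise ValueError("no subjects shared between profiles and volumetrics")
    dropped = sorted((set(prof_frames) | set(vol_map)) - set(common))
    if dropped:
        logger.warning("dropping subjects missing from one input: %s", dropped)

    rows = []
    for sid in common:
        p = prof_frames[sid]
        v = vol_map[sid]
        if len(v.rgm) != atlas.n_regions or len(p.region_names) != atlas.n_regions:
            raise ValueError(f"{sid}: region count does not match atlas")
        df = p.to_frame()
        df["rgm"] = np.asarray(v.rgm, float)
        df["tiv"] = v.tiv
        rows.append(df)
    data = pd.concat(rows, ignore_index=True)
    if data.duplicated(["subject_id", "region_name"]).any():
        raise ValueError("duplicate (subject, region) pairs")
    n_before = len(data)
    data = data.dropna().reset_index(drop=True)
    if len(data) < n_before:
        logger.warning("dropped %d incomplete rows", n_before - len(data))
    return StudyTable(data=data)


def center_and_scale(T: StudyTable, sd_mode: str = "pooled") -> StudyTable:
    """Populate the scaled view with the modeling transform.

    ac, mc, strength and rgm are centered to mean zero within each subject,
    then divided by a standard deviation: with ``sd_mode="pooled"`` (default)
    the pooled SD of the centered column over all rows, with ``"within"`` each
    subject's own SD of its centered values. TIV is centered and scaled across
    subjects. Zero-variance regional columns raise; a zero-variance TIV is set
    to zero with a warning (constant covariate).
    """
    if sd_mode not in ("pooled", "within"):
        raise ValueError(f"sd_mode must be 'pooled' or 'within', got {sd_mode!r}")
    df = T.data.copy()
    counts = df.groupby("subject_id")["region_name"].count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"subjects with fewer than 2 regions: {bad}")

    scaled = df.copy()
    scaling: dict = {"sd_mode": sd_mode, "columns": {}}
    grouped = df.groupby("subject_id")
    for col in REGIONAL_COLUMNS:
        centered = df[col] - grouped[col].transform("mean")
        if sd_mode == "pooled":
            sd = float(centered.std(ddof=1))
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"zero pooled variance in column {col!r}")
            scaled[col] = centered / sd
            scaling["columns"][col] = {"pooled_sd": sd}
        else:
            sds = centered.groupby(df["subject_id"]).transform("std")
            if (sds == 0).any() or sds.isna().any():
                raise ValueError(f"zero within-subject variance in column {col!r}")
            scaled[col] = centered / sds
            scaling["columns"][col] = {
                "within_sd": centered.groupby(df["subject_id"]).std().to_dict()
            }

    subj_tiv = df.groupby("subject_id")["tiv"].first()
    tiv_mean = float(subj_tiv.mean())
    tiv_sd = float(subj_tiv.std(ddof=1)) if len(subj_tiv) > 1 else 0.0
    if tiv_sd == 0:
        logger.warning("TIV has zero variance across subjects; scaled TIV set to 0")
        scaled["tiv"] = 0.0
    else:
        scaled["tiv"] = (df["tiv"] - tiv_mean) / tiv_sd
    scaling["columns"]["tiv"] = {"mean": tiv_mean, "sd": tiv_sd}

    return StudyTable(data=T.data, scaled=scaled, scaling=scaling)
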