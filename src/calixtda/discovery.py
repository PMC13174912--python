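"""Screen-validate-augment discovery loop and structure post-processing.

Workflow: rank a candidate pool by predicted adsorption enthalpy (most
negative = strongest physisorption first), draw a stratified validation
sample biased toward favorable predictions, obtain reference enthalpies for
the sample, fold them back into the training set and re-run the
hyperparameter search (dataset augmentation).  Also provides the Hess-law
enthalpy difference, a geometric cone/partial-cone/alternate conformation
classifier, and box-plot-style group summaries by (family, conformation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chemio import MoleculePointCloud
from .fixtures import ScaffoldAtomMap
from .surrogate import (
    FoldMetrics,
    Hyperparams,
    SurrogateModel,
    cross_validate,
    fit,
    grid_search_one_se,
)

__all__ = [
    "EnthalpyComponents",
    "CandidateRecord",
    "TrainingSet",
    "GroupSummary",
    "ConfigHashMismatch",
    "adsorption_enthalpy",
    "rank_candidates",
    "stratified_validation_sample",
    "augment_and_retrain",
    "classify_conformation",
    "summarize_by_group",
    "write_screening_report",
]


class ConfigHashMismatch(ValueError):
    """Pool descriptors were built with a different ImageConfig than the model."""


@dataclass(frozen=True)
class EnthalpyComponents:
    """Component enthalpies at 298.15 K, kcal/mol."""

    h_complex: float  # host + CO2
    h_host: float
    h_guest: float

    def __post_init__(self) -> None:
        for v in (self.h_complex, self.h_host, self.h_guest):
            if not math.isfinite(v):
                raise ValueError("enthalpy components must be finite")


def adsorption_enthalpy(components: EnthalpyComponents) -> float:
    """dH = H(host+CO2) - H(host) - H(CO2); negative favors binding."""
    return components.h_complex - components.h_host - components.h_guest


@dataclass
class CandidateRecord:
    """One candidate flowing through the discovery loop."""

    candidate_id: str
    predicted_dh: float | None = None
    computed_dh: float | None = None
    conformation: str = ""
    provenance: str = "screened"  # initial | augmentation_1 | augmentation_2 | screened


@dataclass
class TrainingSet:
    """Labelled descriptor matrix with per-row identity and provenance."""

    ids: list[str]
    X: np.ndarray
    y: np.ndarray
    provenance: list[str]
    config_hash: str

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.X) == len(self.y) == len(self.provenance)):
            raise ValueError("training-set fields disagree in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate structure ids in training set")

    @property
    def n(self) -> int:
        return len(self.ids)


def rank_candidates(
    model: SurrogateModel,
    candidate_ids: Sequence[str],
    X_pool: np.ndarray,
    config_hash: str,
) -> list[CandidateRecord]:
    """Predict and sort ascending (most negative dH first; ties by id)."""
    if config_hash != model.config_hash:
        raise ConfigHashMismatch(
            f"pool featurized with config {config_hash!r} but model expects "
            f"{model.config_hash!r}; refusing to mix descriptors"
        )
    if len(candidate_ids) != len(X_pool):
        raise ValueError("id/descriptor count mismatch")
    preds = model.predict(np.atleast_2d(X_pool))
    records = [
        CandidateRecord(candidate_id=cid, predicted_dh=float(p))
        for cid, p in zip(candidate_ids, preds)
    ]
    records.sort(key=lambda r: (r.predicted_dh, r.candidate_id))
    return records


def _stratum_of(dh: float, boundaries: tuple[float, float]) -> int:
    """0: weakest (dH > hi), 1: middle, 2: strongest (dH < lo)."""
    hi, lo = boundaries  # e.g. (-5.0, -7.0)
    if dh > hi:
        return 0
    if dh < lo:
        return 2
    return 1


STRATUM_NAMES = ("weak", "mid", "strong")


def stratified_validation_sample(
    ranked: Sequence[CandidateRecord],
    boundaries: tuple[float, float] = (-5.0, -7.0),
    counts: tuple[int, int, int] = (3, 3, 5),
    seed: int = 0,
    families: Sequence[str] | None = None,
) -> list[CandidateRecord]:
    """Seeded uniform sampling without replacement within enthalpy strata.

    Strata on predicted dH (kcal/mol): above the first boundary, between the
    two, and below the second; default (3, 3, 5) draws 11 validation
    structures biased toward strong binders.  ``families`` optionally
    restricts the pool to candidates whose id starts with one of the given
    family prefixes.
    """
    pool = list(ranked)
    if families is not None:
        pool = [r for r in pool if any(r.candidate_id.startswith(f) for f in families)]
    strata: list[list[CandidateRecord]] = [[], [], []]
    for r in pool:
        if r.predicted_dh is None:
            raise ValueError(f"{r.candidate_id}: screened record lacks a prediction")
        strata[_stratum_of(r.predicted_dh, boundaries)].append(r)
    rng = np.random.default_rng(seed)
    selected: list[CandidateRecord] = []
    for name, bucket, want in zip(STRATUM_NAMES, strata, counts):
        if len(bucket) < want:
            raise ValueError(
                f"stratum {name!r} has {len(bucket)} candidates, need {want}"
            )
        idx = rng.choice(len(bucket), size=want, replace=False)
        selected.extend(bucket[i] for i in sorted(idx))
    return selected


def augment_and_retrain(
    training_set: TrainingSet,
    new_ids: Sequence[str],
    X_new: np.ndarray,
    y_new: Sequence[float],
    provenance: str = "augmentation_1",
    alpha_grid: Sequence[float] | None = None,
    gamma_grid: Sequence[float] | None = None,
    k: int = 3,
    seed: int = 0,
) -> tuple[SurrogateModel, FoldMetrics, TrainingSet, Hyperparams]:
    """Union the datasets, redo the grid search, refit on everything.

    Ids must not collide with existing rows.  Returns the refitted model,
    its CV metrics at the newly selected hyperparameters, the merged
    training set and the hyperparameters themselves.
    """
    clash = set(new_ids) & set(training_set.ids)
    if clash:
        raise ValueError(f"duplicate structure ids in augmentation: {sorted(clash)}")
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    merged = TrainingSet(
        ids=list(training_set.ids) + list(new_ids),
        X=np.vstack([training_set.X, X_new]) if len(X_new) else training_set.X,
        y=np.concatenate([training_set.y, np.asarray(y_new, dtype=float)]),
        provenance=list(training_set.provenance) + [provenance] * len(new_ids),
        config_hash=training_set.config_hash,
    )
    from .surrogate import DEFAULT_ALPHA_GRID, DEFAULT_GAMMA_GRID

    hp, _ = grid_search_one_se(
        merged.X,
        merged.y,
        alpha_grid if alpha_grid is not None else DEFAULT_ALPHA_GRID,
        gamma_grid if gamma_grid is not None else DEFAULT_GAMMA_GRID,
        k=k,
        seed=seed,
    )
    fm = cross_validate(merged.X, merged.y, hp, k=k, seed=seed)
    model = fit(merged.X, merged.y, hp, config_hash=merged.config_hash)
    return model, fm, merged, hp


def _fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through the points."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[-1]


def classify_conformation(
    cloud: MoleculePointCloud,
    atom_map: ScaffoldAtomMap,
    cos_threshold: float = 0.1,
) -> str:
    """Label the macrocycle conformation from ring orientations.

    A least-squares plane is fitted through the four bridge atoms.  Each
    aryl ring's orientation is the sign of the dot product between the
    bridge-plane normal and the ring's para axis (midpoint of the two
    bridge-attached carbons to the para carbon) — the direction the ring
    "points".  The cyclic sign pattern maps to cone (all same), partial cone
    (3-1), 1,2-alternate (adjacent pairs) or 1,3-alternate (alternating).
    Any ring whose axis is within ``cos_threshold`` of coplanarity leaves
    the conformation undetermined.
    """
    coords = np.asarray(cloud.coords, dtype=float)
    for idx in atom_map.bridge_atoms:
        if idx >= len(coords):
            raise ValueError("atom map references atoms beyond the cloud")
    normal = _fit_plane_normal(coords[list(atom_map.bridge_atoms)])
    signs: list[int] = []
    for ring_idx in range(4):
        ring = atom_map.rings[ring_idx]
        if any(i >= len(coords) for i in ring):
            raise ValueError("atom map references atoms beyond the cloud")
        a, b = atom_map.attach_atoms(ring_idx)
        para = atom_map.para_atom(ring_idx)
        axis = coords[para] - (coords[a] + coords[b]) / 2.0
        nrm = np.linalg.norm(axis)
        if nrm == 0:
            return "undetermined"
        cos = float(np.dot(axis / nrm, normal))
        if abs(cos) < cos_threshold:
            return "undetermined"
        signs.append(1 if cos > 0 else -1)
    total = sum(signs)
    if abs(total) == 4:
        return "cone"
    if abs(total) == 2:
        return "partial_cone"
    # two up, two down: adjacent vs alternating
    if signs[0] == signs[1] or signs[1] == signs[2]:
        return "alt12"
    return "alt13"


@dataclass(frozen=True)
class GroupSummary:
    """Box-plot statistics of computed dH within one (family, conformation)."""

    family: str
    conformation: str
    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outlier_ids: tuple[str, ...]


def summarize_by_group(
    records: Sequence[tuple[str, str, str, float]] | pd.DataFrame,
) -> list[GroupSummary]:
    """Quartiles (linear interpolation), 1.5*IQR whiskers and outliers.

    Accepts either a DataFrame with columns (structure_id, family,
    conformation, delta_h) or an iterable of such tuples.  Whiskers extend
    to the most extreme data point within Q1 - 1.5*IQR / Q3 + 1.5*IQR;
    values beyond are listed as outliers.  Empty groups are omitted.
    """
    if isinstance(records, pd.DataFrame):
        df = records[["structure_id", "family", "conformation", "delta_h"]].copy()
    else:
        df = pd.DataFrame(
            records, columns=["structure_id", "family", "conformation", "delta_h"]
        )
    out: list[GroupSummary] = []
    for (fam, conf), grp in df.groupby(["family", "conformation"], sort=True):
        vals = grp["delta_h"].to_numpy(dtype=float)
        if len(vals) == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        outliers = grp.loc[
            (grp["delta_h"] < lo_fence) | (grp["delta_h"] > hi_fence), "structure_id"
        ]
        out.append(
            GroupSummary(
                family=str(fam),
                conformation=str(conf),
                n=len(vals),
                median=float(med),
                q1=float(q1),
                q3=float(q3),
                whisker_low=float(inside.min()),
                whisker_high=float(inside.max()),
                outlier_ids=tuple(sorted(outliers)),
            )
        )
    return out


def write_screening_report(
    ranked: Sequence[CandidateRecord],
    selected: Sequence[CandidateRecord],
    path: str | Path,
    boundaries: tuple[float, float] = (-5.0, -7.0),
) -> None:
    """Deterministic CSV: id, predicted dH, rank, stratum, selected flag."""
    chosen = {r.candidate_id for r in selected}
    lines = ["candidate_id,predicted_dh,rank,stratum,selected"]
    for rank, r in enumerate(ranked, start=1):
        stratum = STRATUM_NAMES[_stratum_of(r.predicted_dh, boundaries)]
        lines.append(
            f"{r.candidate_id},{r.predicted_dh:.6f},{rank},{stratum},"
            f"{int(r.candidate_id in chosen)}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
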