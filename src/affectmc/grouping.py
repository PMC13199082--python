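"""Trait-based participant grouping by emotional stability.

Participants answer a five-dimension emotional-stability scale
(pessimism/optimism, anxiety/calmness, aggression/tolerance,
dependence/autonomy, indifference/empathy).  Grouping is data-driven:
the (optionally standardized) dimension matrix is projected onto its top
right-singular vectors, K-means with K=2 clusters the projected scores,
and the cluster with the lower mean total score is labelled the
low-stability group.  A published normative threshold (181 on the total
score) flags individuals below the "normal" stability range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core_io import ParseError, StabilityGroup

logger = logging.getLogger("affectmc")

#: scale dimensions in the canonical reporting order
DIMENSIONS = (
    "pessimism_optimism",
    "anxiety_calmness",
    "aggression_tolerance",
    "dependence_autonomy",
    "indifference_empathy",
)

#: normative minimum total score for "normal" emotional stability
NORMATIVE_THRESHOLD = 181.0


class NormativeFlag(Enum):
    BELOW_NORMAL = "below_normal"
    NORMAL_OR_ABOVE = "normal_or_above"


@dataclass
class ScaleResponse:
    """One participant's five dimension scores; the total is recomputed
    as their plain sum, never stored."""

    participant_id: str
    dims: dict[str, float]

    def __post_init__(self) -> None:
        missing = [d for d in DIMENSIONS if d not in self.dims]
        if missing:
            raise ValueError(f"missing scale dimensions: {missing}")

    @property
    def total(self) -> float:
        return float(sum(self.dims[d] for d in DIMENSIONS))

    def vector(self) -> np.ndarray:
        return np.array([self.dims[d] for d in DIMENSIONS], dtype=float)


@dataclass
class ClusterResult:
    """Output of the SVD + K-means grouping."""

    labels: dict[str, StabilityGroup]
    scores: np.ndarray  # (n_participants, n_components)
    variance_explained: np.ndarray
    centroids: np.ndarray
    seed: int
    inertia: float
    participant_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ve = np.asarray(self.variance_explained)
        if np.any(ve < -1e-12) or np.any(ve > 1 + 1e-12):
            raise ValueError("variance_explained entries must lie in [0, 1]")
        if np.any(np.diff(ve) > 1e-12):
            raise ValueError("variance_explained must be non-increasing")
        if ve.sum() > 1 + 1e-12:
            raise ValueError("variance_explained must sum to <= 1")
        if len(set(self.labels.values())) != 2:
            raise ValueError("exactly two stability groups must be populated")


def read_scale_responses(source: str | Path | IO[str]) -> list[ScaleResponse]:
    """Read a scale CSV (participant_id + the five dimension columns)."""
    try:
        frame = pd.read_csv(source)
    except pd.errors.EmptyDataError:
        raise ParseError("empty scale file") from None
    missing = [c for c in ("participant_id",) + DIMENSIONS if c not in frame.columns]
    if missing:
        raise ParseError(f"scale file missing columns: {missing}")
    out = []
    for _, row in frame.iterrows():
        out.append(ScaleResponse(
            participant_id=str(row["participant_id"]),
            dims={d: float(row[d]) for d in DIMENSIONS},
        ))
    return out


def write_scale_responses(
    responses: Sequence[ScaleResponse], sink: str | Path | IO[str]
) -> None:
    rows = [
        {"participant_id": r.participant_id, **{d: r.dims[d] for d in DIMENSIONS}}
        for r in responses
    ]
    pd.DataFrame(rows).to_csv(sink, index=False)


def svd_project(
    responses: Sequence[ScaleResponse],
    n_components: int = 3,
    standardize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Project scale responses onto their top right-singular vectors.

    Columns are centered and (by default) scaled to unit sample variance;
    ``variance_explained[i]`` is ``sigma_i^2 / sum(sigma^2)`` on the
    processed matrix.  Each component is oriented so that its loading on
    the total score (the sum of its dimension loadings) is non-negative,
    making the sign convention reproducible across linear-algebra
    backends.

    Returns ``(scores, variance_explained)`` where ``scores`` has shape
    ``(n_participants, n_components)`` and ``variance_explained`` covers
    the requested components.
    """
    M = np.vstack([r.vector() for r in responses])
    n, d = M.shape
    if n < n_components + 1:
        raise ValueError(
            f"need at least n_components + 1 = {n_components + 1} participants, got {n}"
        )
    Z = M - M.mean(axis=0)
    if standardize:
        sd = Z.std(axis=0, ddof=1)
        const = np.where(sd == 0)[0]
        if const.size:
            raise ValueError(
                f"constant column(s) cannot be standardized: "
                f"{[DIMENSIONS[i] for i in const]}"
            )
        Z = Z / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    # orient: loading on the total score (sum over dimensions) >= 0
    for i in range(Vt.shape[0]):
        load = Vt[i].sum()
        if load == 0 and np.any(Vt[i] != 0):
            load = Vt[i][np.nonzero(Vt[i])[0][0]]
        if load < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    var = s**2
    variance_explained = var / var.sum()
    scores = U[:, :n_components] * s[:n_components]
    return scores, variance_explained[:n_components]


def kmeans_cluster(
    scores: np.ndarray, k: int = 2, seed: int = 0, restarts: int = 10
) -> tuple[np.ndarray, np.ndarray, float]:
    """K-means (k-means++ seeding, Lloyd iterations, best of ``restarts``).

    Deterministic given ``seed``; raises if ``k`` exceeds the number of
    distinct points (scikit-learn's empty-cluster re-seeding handles
    duplicated points short of that).
    """
    scores = np.asarray(scores, dtype=float)
    distinct = np.unique(scores, axis=0).shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > distinct:
        raise ValueError(f"k={k} exceeds the {distinct} distinct points")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=restarts,
        random_state=seed, algorithm="lloyd",
    ).fit(scores)
    return km.labels_, km.cluster_centers_, float(km.inertia_)


def assign_stability_labels(
    raw_labels: Sequence[int], responses: Sequence[ScaleResponse]
) -> dict[str, StabilityGroup]:
    """Map two raw cluster indices to Low/High stability by mean total score.

    The cluster with the lower mean total becomes the low-stability group,
    so the mapping is invariant to permutations of the raw indices.  Equal
    means fall back to cluster size (larger cluster = high stability) with
    a logged warning.
    """
    raw_labels = np.asarray(raw_labels)
    uniq = np.unique(raw_labels)
    if uniq.size != 2:
        raise ValueError(f"expected exactly 2 clusters, got {uniq.size}")
    totals = np.array([r.total for r in responses], dtype=float)
    means = {c: totals[raw_labels == c].mean() for c in uniq}
    sizes = {c: int((raw_labels == c).sum()) for c in uniq}
    if min(sizes.values()) == 1:
        logger.warning("a stability cluster contains a single participant")
    a, b = uniq
    if means[a] == means[b]:
        logger.warning(
            "equal cluster mean totals; breaking tie by size (larger = high)"
        )
        low = a if sizes[a] <= sizes[b] else b
    else:
        low = a if means[a] < means[b] else b
    return {
        r.participant_id: (
            StabilityGroup.LOW if raw_labels[i] == low else StabilityGroup.HIGH
        )
        for i, r in enumerate(responses)
    }


def normative_flag(total: float, threshold: float = NORMATIVE_THRESHOLD) -> NormativeFlag:
    """Flag a total score against the normative minimum for "normal"
    stability; the threshold itself counts as normal."""
    if not np.isfinite(total):
        raise ValueError("total must be finite")
    return NormativeFlag.BELOW_NORMAL if total < threshold else NormativeFlag.NORMAL_OR_ABOVE


def cluster_participants(
    responses: Sequence[ScaleResponse],
    n_components: int = 3,
    seed: int = 0,
    restarts: int = 10,
    standardize: bool = True,
) -> ClusterResult:
    """End-to-end grouping: standardize -> SVD -> K-means(2) -> label."""
    scores, variance_explained = svd_project(
        responses, n_components=n_components, standardize=standardize
    )
    raw, centroids, inertia = kmeans_cluster(scores, k=2, seed=seed, restarts=restarts)
    labels = assign_stability_labels(raw, responses)
    return ClusterResult(
        labels=labels, scores=scores, variance_explained=variance_explained,
        centroids=centroids, seed=seed, inertia=inertia,
        participant_ids=[r.participant_id for r in responses],
    )


def elbow_curve(
    scores: np.ndarray, k_range: Sequence[int] = range(1, 7), seed: int = 0,
    restarts: int = 10,
) -> pd.DataFrame:
    """Within-cluster sum of squares for a range of K (report only; K is
    fixed at 2 in the analysis)."""
    scores = np.asarray(scores, dtype=float)
    rows = []
    for k in k_range:
        if k == 1:
            inertia = float(((scores - scores.mean(axis=0)) ** 2).sum())
        else:
            km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(scores)
            inertia = float(km.inertia_)
        rows.append({"k": k, "inertia": inertia})
    return pd.DataFrame(rows)
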