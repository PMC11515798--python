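"""Per-subject dysbiosis trajectories, clustering, and response categories.

Subjects are summarised by their dysbiosis score at each visit, clustered
by agglomerative hierarchical clustering on the (imputed) score vectors,
and each cluster is mapped to one of four ordinal microbial treatment
response categories defined by where its mean trajectory sits relative to
a normobiosis cut (default 0.5, the midpoint of the two-topic proportion):

* 0 non-responder — dysbiotic at baseline, at the first post-treatment
  visit and at the final visit;
* 3 responder — normobiotic at the first post-treatment visit and still
  normobiotic at the final visit;
* 2 short-term responder — normobiotic at the first post-treatment visit
  but dysbiotic again at the final visit;
* 1 indifferent — any other pattern.

The numeric codes are ordinal in clinical response (0 worst, 3 best).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

from .cohort import CATEGORY_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "ClusterResult",
    "ResponsePattern",
    "build_trajectories",
    "cluster_trajectories",
    "assign_categories",
]


@dataclass
class Trajectory:
    subject_id: str
    visit_months: tuple[int, ...]
    scores: np.ndarray      # aligned to visits; NaN where missing
    missing: np.ndarray     # boolean mask, True where missing

    def __post_init__(self) -> None:
        months = list(self.visit_months)
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError("visit_months must be strictly increasing")
        if months[0] != 0 or self.missing[0]:
            raise ValueError("baseline (month 0) must be present")
        present = self.scores[~self.missing]
        if np.any((present < 0) | (present > 1)):
            raise ValueError("scores must lie in [0, 1]")


@dataclass
class ClusterResult:
    subject_ids: list[str]
    cluster_ids: np.ndarray          # 1-based cluster labels per subject
    merge_heights: np.ndarray        # dendrogram merge heights
    imputed: np.ndarray              # subjects x visits matrix used for clustering
    visit_months: tuple[int, ...]


@dataclass
class ResponsePattern:
    subject_id: str
    category: int
    name: str
    cluster_id: int

    def __post_init__(self) -> None:
        if CATEGORY_NAMES[self.category] != self.name:
            raise ValueError("category code and name disagree")


def build_trajectories(scores: pd.Series, metadata: pd.DataFrame) -> list[Trajectory]:
    """Assemble one trajectory per subject from per-sample scores.

    ``scores`` is indexed by sample id; ``metadata`` maps sample id to
    subject_id and visit_month. Missing visits are masked; subjects
    lacking a baseline (month 0) sample are excluded and logged.
    """
    if len(scores) == 0:
        raise ValueError("no scores provided")
    joined = metadata.loc[scores.index, ["subject_id", "visit_month"]].copy()
    joined["score"] = scores.to_numpy()
    months = tuple(sorted(joined["visit_month"].unique()))
    trajectories, excluded = [], []
    for subject, grp in joined.groupby("subject_id", sort=True):
        by_visit = grp.set_index("visit_month")["score"]
        if 0 not in by_visit.index:
            excluded.append(subject)
            continue
        vals = np.array([by_visit.get(m, np.nan) for m in months])
        trajectories.append(Trajectory(
            subject_id=str(subject), visit_months=months, scores=vals,
            missing=np.isnan(vals),
        ))
    if excluded:
        logger.warning("excluded %d subjects lacking a baseline sample: %s",
                       len(excluded), excluded)
    if not trajectories:
        raise ValueError("no subjects with baseline samples")
    return trajectories


def _impute_locf(matrix: np.ndarray) -> np.ndarray:
    out = matrix.copy()
    for j in range(1, out.shape[1]):
        nan = np.isnan(out[:, j])
        out[nan, j] = out[nan, j - 1]
    return out


def cluster_trajectories(
    trajectories: list[Trajectory],
    k: int = 4,
    linkage: str = "ward",
    distance: str = "euclidean",
    impute: str = "locf",
) -> ClusterResult:
    """Agglomerative clustering of score trajectories cut at ``k`` clusters.

    Missing visits are imputed by last observation carried forward
    (``impute="locf"``, default) or incomplete subjects are dropped
    (``impute="drop"``). Deterministic.
    """
    if linkage not in ("ward", "average", "complete"):
        raise ValueError(f"unsupported linkage: {linkage!r}")
    if distance != "euclidean":
        raise ValueError("only euclidean distance is supported")
    subjects = [t.subject_id for t in trajectories]
    matrix = np.vstack([t.scores for t in trajectories])
    if impute == "locf":
        matrix = _impute_locf(matrix)
    elif impute == "drop":
        keep = ~np.isnan(matrix).any(axis=1)
        matrix, subjects = matrix[keep], [s for s, k_ in zip(subjects, keep) if k_]
    else:
        raise ValueError(f"unknown imputation mode: {impute!r}")
    if len(subjects) < k:
        raise ValueError(f"need at least k={k} subjects, have {len(subjects)}")
    Z = scipy_linkage(matrix, method=linkage, metric=distance)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(
        subject_ids=list(subjects), cluster_ids=labels,
        merge_heights=Z[:, 2].copy(), imputed=matrix,
        visit_months=trajectories[0].visit_months,
    )


def assign_categories(
    clusters: ClusterResult,
    normo_cut: float = 0.5,
) -> list[ResponsePattern]:
    """Map each cluster to a response category from its mean trajectory.

    The decision uses the cluster mean score at baseline, at the first
    post-treatment visit and at the final visit, against ``normo_cut``.
    Two clusters may map to the same category (a warning is logged);
    categories label clusters, they are not forced to be unique.
    """
    if clusters.imputed.shape[1] < 3:
        raise ValueError("need baseline, one post-treatment and a final visit")
    patterns: list[ResponsePattern] = []
    seen: dict[int, list[int]] = {}
    for cid in np.unique(clusters.cluster_ids):
        mean = clusters.imputed[clusters.cluster_ids == cid].mean(axis=0)
        base, first_post, final = mean[0], mean[1], mean[-1]
        if first_post < normo_cut and final < normo_cut:
            cat = 3
        elif first_post < normo_cut and final >= normo_cut:
            cat = 2
        elif base >= normo_cut and first_post >= normo_cut and final >= normo_cut:
            cat = 0
        else:
            cat = 1
        seen.setdefault(cat, []).append(int(cid))
        for subject, c in zip(clusters.subject_ids, clusters.cluster_ids):
            if c == cid:
                patterns.append(ResponsePattern(
                    subject_id=subject, category=cat,
                    name=CATEGORY_NAMES[cat], cluster_id=int(cid),
                ))
    for cat, cids in seen.items():
        if len(cids) > 1:
            logger.warning("clusters %s all mapped to category %d (%s)",
                           cids, cat, CATEGORY_NAMES[cat])
    order = {s: i for i, s in enumerate(clusters.subject_ids)}
    patterns.sort(key=lambda p: order[p.subject_id])
    return patterns


def patterns_frame(patterns: list[ResponsePattern]) -> pd.DataFrame:
    """Tidy table of subject, cluster and category assignments."""
    return pd.DataFrame(
        [
            {"subject_id": p.subject_id, "cluster_id": p.cluster_id,
             "category_code": p.category, "category_name": p.name}
            for p in patterns
        ]
    ).set_index("subject_id")
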