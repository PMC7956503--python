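"""Unsupervised subject stratification by hierarchical clustering.

Subjects are clustered on their protein profiles with Ward's
minimum-variance linkage on Euclidean distances — the standard pairing
for stratifying omics cohorts. Cutting the dendrogram at k clusters
yields the proteome-defined groups; labels (A, B, C, ...) are assigned
canonically by decreasing cluster size (ties broken by the smallest
member subject id) so results do not depend on input order.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy

from .errors import ValidationError
from .matrix import SpcMatrix

K_DEFAULT = 3


@dataclass
class Dendrogram:
    """Ward/Euclidean merge tree over subjects.

    ``linkage_matrix`` is the (n-1) x 4 scipy linkage encoding; heights
    are non-decreasing (checked at construction, a guarantee of Ward's
    criterion).
    """

    linkage_matrix: np.ndarray
    subject_ids: list[str]
    method: str = "ward"
    metric: str = "euclidean"
    transform: str = "none"

    def __post_init__(self):
        heights = self.linkage_matrix[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValidationError("non-monotone merge heights in Ward linkage")

    @property
    def n_leaves(self) -> int:
        return len(self.subject_ids)

    def leaf_order(self) -> list[str]:
        """Leaves in standard recursive left-to-right dendrogram order."""
        return [self.subject_ids[i] for i in hierarchy.leaves_list(self.linkage_matrix)]

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        z = self.linkage_matrix
        n = self.n_leaves

        def height(node: int) -> float:
            return 0.0 if node < n else float(z[node - n, 2])

        def emit(node: int, parent_h: float) -> str:
            bl = parent_h - height(node)
            if node < n:
                return f"{self.subject_ids[node]}:{bl:.6g}"
            left, right = int(z[node - n, 0]), int(z[node - n, 1])
            h = height(node)
            return f"({emit(left, h)},{emit(right, h)}):{bl:.6g}"

        root = 2 * n - 2
        h = height(root)
        left, right = int(z[root - n, 0]), int(z[root - n, 1])
        return f"({emit(left, h)},{emit(right, h)});"


@dataclass
class GroupAssignment:
    """Canonical subject -> group-label mapping with k non-empty labels."""

    labels: dict[str, str]
    k: int

    def members(self, label: str) -> list[str]:
        return sorted(s for s, g in self.labels.items() if g == label)

    def group_names(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def as_dict(self) -> dict[str, str]:
        return dict(self.labels)


def _group_label(i: int) -> str:
    letters = string.ascii_uppercase
    return letters[i] if i < 26 else f"G{i + 1}"


def cluster_subjects(m: SpcMatrix, transform: str = "none") -> Dendrogram:
    """Ward-linkage dendrogram over subject columns.

    ``transform="log2p1"`` applies log2(x + 1) before computing Euclidean
    distances; on raw spectral counts the distance is dominated by the
    handful of most abundant proteins, so the log transform is the
    variance-stabilized alternative.
    """
    if m.n_columns < 2:
        raise ValidationError("clustering requires at least 2 subjects")
    x = m.values.T.to_numpy(dtype=float)
    if transform == "log2p1":
        x = np.log2(x + 1.0)
    elif transform != "none":
        raise ValidationError(f"unknown transform {transform!r}")
    z = hierarchy.linkage(x, method="ward", metric="euclidean")
    return Dendrogram(linkage_matrix=z, subject_ids=list(m.values.columns), transform=transform)


def cut_tree(d: Dendrogram, k: int = K_DEFAULT) -> GroupAssignment:
    """Cut the dendrogram into k groups with canonical A/B/C labels.

    Clusters are labeled in decreasing size; equal-sized clusters order
    by their smallest subject id, making the labeling reproducible and
    independent of subject input order.
    """
    if not (1 <= k <= d.n_leaves):
        raise ValidationError(f"k must be in [1, {d.n_leaves}], got {k}")
    flat = hierarchy.fcluster(d.linkage_matrix, t=k, criterion="maxclust")
    clusters: dict[int, list[str]] = {}
    for sid, c in zip(d.subject_ids, flat):
        clusters.setdefault(int(c), []).append(sid)
    ordered = sorted(clusters.values(), key=lambda ms: (-len(ms), min(ms)))
    labels = {}
    for i, ms in enumerate(ordered):
        for s in ms:
            labels[s] = _group_label(i)
    return GroupAssignment(labels=labels, k=len(ordered))
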