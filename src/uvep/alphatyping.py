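"""Alpha-value subject typing on a compact marker panel.

The alpha-value of a panel protein in one subject is its share of the
subject's total panel abundance:

    alpha_i(p) = aSpC_i(p) / sum over panel q of aSpC_i(q)

so each subject gets a composition vector on the simplex (entries sum to
1). This makes typing a simple monitoring rule: compare a subject's
composition to per-group reference compositions and assign the nearest
one in Euclidean distance. Because alpha is a ratio, it is invariant to
any global rescaling of the subject's counts (loading, depth).

A subject in which no panel protein was detected carries no
compositional information; it is flagged degenerate and given the
uniform profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .markers import MarkerPanel
from .matrix import SpcMatrix
from .stratify import GroupAssignment

logger = logging.getLogger(__name__)


@dataclass
class AlphaProfile:
    """Per-subject normalized marker abundances and group assignment."""

    subject_id: str
    alpha: dict[str, float]
    degenerate: bool = False
    assigned: str | None = None
    margin: float = float("nan")


def _panel_submatrix(m: SpcMatrix, panel: MarkerPanel) -> pd.DataFrame:
    if not panel.proteins:
        raise ValidationError("marker panel is empty")
    missing = [p for p in panel.proteins if p not in m.values.index]
    if missing:
        raise ValidationError(f"panel protein(s) missing from matrix: {missing}")
    return m.values.loc[panel.proteins]


def alpha_profile(m: SpcMatrix, panel: MarkerPanel) -> list[AlphaProfile]:
    """Compute each subject's alpha composition over the panel."""
    sub = _panel_submatrix(m, panel)
    k = len(panel.proteins)
    profiles = []
    for sid in sub.columns:
        col = sub[sid].to_numpy(dtype=float)
        total = col.sum()
        if total <= 0:
            profiles.append(
                AlphaProfile(sid, dict(zip(panel.proteins, [1.0 / k] * k)), degenerate=True)
            )
        else:
            profiles.append(AlphaProfile(sid, dict(zip(panel.proteins, col / total))))
    return profiles


def alpha_centroids(
    m: SpcMatrix, panel: MarkerPanel, groups: GroupAssignment | dict[str, str]
) -> dict[str, dict[str, float]]:
    """Per-group mean alpha profile, renormalized to sum 1.

    Degenerate subjects are excluded from the averages; a group whose
    subjects are all degenerate has no defined centroid and is an error.
    """
    labels = groups.as_dict() if isinstance(groups, GroupAssignment) else dict(groups)
    profiles = {p.subject_id: p for p in alpha_profile(m, panel)}
    unknown = [s for s in labels if s not in profiles]
    if unknown:
        raise ValidationError(f"grouped subject(s) missing from matrix: {unknown}")
    centroids = {}
    for g in sorted(set(labels.values())):
        members = [profiles[s] for s, lab in labels.items() if lab == g and not profiles[s].degenerate]
        if not members:
            raise ValidationError(f"group {g!r} has no non-degenerate subject")
        mean = np.mean([[p.alpha[q] for q in panel.proteins] for p in members], axis=0)
        mean = mean / mean.sum()
        centroids[g] = dict(zip(panel.proteins, mean))
    return centroids


def assign_by_alpha(
    profiles: list[AlphaProfile], reference: dict[str, dict[str, float]]
) -> GroupAssignment:
    """Nearest-centroid typing in alpha space.

    Each subject goes to the reference group whose centroid is closest in
    Euclidean distance; the margin (runner-up distance minus best) is
    stored on the profile. Exact ties take the first group in canonical
    label order, with a log message.
    """
    if not reference:
        raise ValidationError("no reference centroids")
    groups = sorted(reference)
    panel = list(profiles[0].alpha) if profiles else []
    for g in groups:
        if set(reference[g]) != set(panel):
            raise ValidationError(f"centroid for group {g!r} is on a different panel")
    labels = {}
    for prof in profiles:
        v = np.array([prof.alpha[p] for p in panel])
        dists = {g: float(np.linalg.norm(v - np.array([reference[g][p] for p in panel])))
                 for g in groups}
        best = min(dists.values())
        tied = [g for g in groups if dists[g] == best]
        if len(tied) > 1:
            logger.warning("subject %s equidistant from groups %s; taking %s",
                           prof.subject_id, tied, tied[0])
        prof.assigned = tied[0]
        others = [dists[g] for g in groups if g != tied[0]]
        prof.margin = float(min(others) - best) if others else float("nan")
        labels[prof.subject_id] = tied[0]
    return GroupAssignment(labels=labels, k=len(set(labels.values())))


def alpha_table(profiles: list[AlphaProfile]) -> pd.DataFrame:
    """Report table: one row per subject, one alpha column per panel protein."""
    panel = list(profiles[0].alpha) if profiles else []
    rows = []
    for p in profiles:
        row = {"subject_id": p.subject_id}
        row.update({f"alpha_{q}": p.alpha[q] for q in panel})
        row.update({"assigned": p.assigned, "margin": p.margin, "degenerate": p.degenerate})
        rows.append(row)
    return pd.DataFrame(rows)
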