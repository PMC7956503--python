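"""Discriminant-protein selection and linear discriminant analysis.

The marker workflow mirrors a classic discriminant pipeline: a univariate
screen first (per-protein one-way ANOVA F-ratio across the stratified
subject groups, with the F-distribution p-value), then a multivariate
linear discriminant analysis fitted on the surviving proteins with a
common (pooled) within-group covariance and Mahalanobis-distance
assignment. Because the protein count far exceeds the subject count, the
pooled covariance is singular; it is regularized by shrinkage toward its
own diagonal with a configurable mixing weight.

Discriminants are finally intersected with the DAve/DCI DEP set, and a
compact monitoring panel is nominated by ranking the intersection by the
largest |DAve| over all pairwise comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import DepSet, group_mean_aspc
from .errors import ValidationError
from .matrix import SpcMatrix

logger = logging.getLogger(__name__)

#: Univariate screen defaults: F >= 5 and p <= 0.01 (non-strict).
F_MIN = 5.0
P_MAX = 0.01
#: Shrinkage weight toward the diagonal of the pooled covariance.
LDA_SHRINKAGE = 0.5
#: Default size of the nominated monitoring panel.
PANEL_SIZE = 6


@dataclass(frozen=True)
class DiscriminantRecord:
    """Per-protein univariate screen result."""

    accession: str
    f_ratio: float
    p_value: float
    group_means: dict[str, float]
    selected: bool


def _group_members(groups: dict[str, str]) -> dict[str, list[str]]:
    members: dict[str, list[str]] = {}
    for s in groups:
        members.setdefault(groups[s], []).append(s)
    return {g: members[g] for g in sorted(members)}


def f_ratio_select(
    m: SpcMatrix,
    groups: dict[str, str],
    f_min: float = F_MIN,
    p_max: float = P_MAX,
) -> list[DiscriminantRecord]:
    """Screen proteins by one-way ANOVA F across subject groups.

    A protein is selected when F >= ``f_min`` and p <= ``p_max``
    (p from the F distribution with G-1 and N-G degrees of freedom).
    A protein constant within and between groups has an undefined F and
    is never selected. Requires >= 2 subjects per group so the
    within-group variance is defined.
    """
    if m.level != "subject":
        raise ValidationError("f_ratio_select expects the subject-level aSpC matrix")
    members = _group_members(groups)
    if len(members) < 2:
        raise ValidationError("need at least 2 groups")
    small = [g for g, ms in members.items() if len(ms) < 2]
    if small:
        raise ValidationError(f"group(s) with <2 subjects: {small}")
    samples = [m.values[ms].to_numpy(dtype=float) for ms in members.values()]
    with np.errstate(divide="ignore", invalid="ignore"):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")  # constant rows produce expected NaNs
            f, p = stats.f_oneway(*samples, axis=1)
    means = {g: m.values[ms].mean(axis=1) for g, ms in members.items()}
    records = []
    for i, accession in enumerate(m.values.index):
        fi, pi = float(f[i]), float(p[i])
        selected = bool(np.isfinite(fi) and np.isfinite(pi) and fi >= f_min and pi <= p_max)
        records.append(
            DiscriminantRecord(
                accession=accession,
                f_ratio=fi,
                p_value=pi,
                group_means={g: float(means[g].iloc[i]) for g in means},
                selected=selected,
            )
        )
    return records


def discriminant_table(records: list[DiscriminantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"accession": r.accession, "f_ratio": r.f_ratio, "p_value": r.p_value,
               "selected": r.selected}
        row.update({f"mean_{g}": v for g, v in r.group_means.items()})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class LdaModel:
    """Linear discriminant model with common (pooled, shrunk) covariance.

    ``precision`` is the inverse of the regularized pooled within-group
    covariance; Mahalanobis distances to the group centroids use it
    directly. ``scalings`` are the canonical discriminant axes
    (eigenvectors of precision @ between-group scatter), at most
    min(G - 1, n_proteins) of them, for low-dimensional score plots.
    """

    proteins: list[str]
    labels: list[str]
    centroids: pd.DataFrame  # groups x proteins
    precision: np.ndarray
    scalings: np.ndarray  # proteins x n_axes
    shrinkage: float
    training_scores: pd.DataFrame = field(default=None)

    @property
    def n_axes(self) -> int:
        return self.scalings.shape[1]

    def transform(self, m: SpcMatrix) -> pd.DataFrame:
        """Canonical discriminant scores for each subject column."""
        x = _subject_matrix(m, self.proteins)
        scores = x.to_numpy() @ self.scalings
        return pd.DataFrame(
            scores, index=x.index, columns=[f"score_{i + 1}" for i in range(self.n_axes)]
        )


def _subject_matrix(m: SpcMatrix, proteins: list[str]) -> pd.DataFrame:
    missing = [p for p in proteins if p not in m.values.index]
    if missing:
        raise ValidationError(f"matrix lacks model protein(s): {missing[:5]}")
    # subjects as rows, proteins as features
    return m.values.loc[proteins].T


def fit_lda(m: SpcMatrix, groups: dict[str, str], shrinkage: float = LDA_SHRINKAGE) -> LdaModel:
    """Fit LDA with a pooled within-group covariance shared by all groups.

    The pooled covariance is shrunk toward its diagonal:
    ``S = (1 - shrinkage) * S_pooled + shrinkage * diag(S_pooled)``,
    plus a tiny ridge so duplicated or constant proteins cannot make it
    singular. Requires more subjects than groups.
    """
    if not (0 <= shrinkage <= 1):
        raise ValidationError(f"shrinkage must be in [0, 1], got {shrinkage}")
    proteins = list(m.values.index)
    if len(proteins) < 2:
        raise ValidationError("LDA requires at least 2 proteins")
    members = _group_members(groups)
    labels = list(members)
    if len(labels) < 2:
        raise ValidationError("LDA requires at least 2 groups")
    x = _subject_matrix(m, proteins)
    n, p = x.shape
    if n <= len(labels):
        raise ValidationError(f"need more subjects ({n}) than groups ({len(labels)})")
    centroids = pd.DataFrame(
        {g: x.loc[ms].mean(axis=0) for g, ms in members.items()}
    ).T.loc[labels]
    # pooled within-group scatter
    sw = np.zeros((p, p))
    for g, ms in members.items():
        xc = x.loc[ms].to_numpy() - centroids.loc[g].to_numpy()
        sw += xc.T @ xc
    sw /= n - len(labels)
    diag = np.diag(np.diag(sw))
    cov = (1.0 - shrinkage) * sw + shrinkage * diag
    ridge = 1e-8 * (np.trace(cov) / p if np.trace(cov) > 0 else 1.0)
    cov[np.diag_indices_from(cov)] += ridge
    precision = np.linalg.inv(cov)
    # between-group scatter (weighted by group size) around the grand mean
    grand = x.mean(axis=0).to_numpy()
    sb = np.zeros((p, p))
    for g, ms in members.items():
        d = (centroids.loc[g].to_numpy() - grand)[:, None]
        sb += len(ms) * (d @ d.T)
    eigval, eigvec = np.linalg.eig(precision @ sb)
    order = np.argsort(eigval.real)[::-1]
    n_axes = min(len(labels) - 1, p)
    scalings = eigvec.real[:, order[:n_axes]]
    model = LdaModel(
        proteins=proteins,
        labels=labels,
        centroids=centroids,
        precision=precision,
        scalings=scalings,
        shrinkage=shrinkage,
    )
    model.training_scores = model.transform(m)
    return model


def mahalanobis_distances(model: LdaModel, m: SpcMatrix) -> pd.DataFrame:
    """Mahalanobis distance from every subject to every group centroid."""
    x = _subject_matrix(m, model.proteins)
    out = {}
    for g in model.labels:
        d = x.to_numpy() - model.centroids.loc[g].to_numpy()
        out[g] = np.sqrt(np.einsum("ij,jk,ik->i", d, model.precision, d))
    return pd.DataFrame(out, index=x.index)


def classify_lda(model: LdaModel, m: SpcMatrix) -> dict[str, str]:
    """Assign each subject to the nearest centroid in Mahalanobis distance.

    Exact ties go to the first group in canonical (sorted) label order and
    are logged.
    """
    dist = mahalanobis_distances(model, m)
    assignment = {}
    for subject in dist.index:
        row = dist.loc[subject]
        best = row.min()
        tied = [g for g in model.labels if row[g] == best]
        if len(tied) > 1:
            logger.warning("subject %s equidistant from groups %s; taking %s",
                           subject, tied, tied[0])
        assignment[subject] = tied[0]
    return assignment


@dataclass
class MarkerPanel:
    """An ordered set of candidate marker proteins with group-mean aSpC."""

    proteins: list[str]
    source: str  # lda_only | dep_only | intersection
    group_means: pd.DataFrame
    n_lda_only: int = 0
    n_dep_only: int = 0


def intersect_panels(lda_selected: set[str], deps: DepSet, m: SpcMatrix,
                     groups: dict[str, str]) -> MarkerPanel:
    """Intersect LDA-screen discriminants with the DAve/DCI DEP set."""
    inter = sorted(str(p) for p in lda_selected & deps.proteins)
    means = group_mean_aspc(m, groups)
    gm = means.loc[[p for p in inter if p in means.index]]
    return MarkerPanel(
        proteins=inter,
        source="intersection",
        group_means=gm,
        n_lda_only=len(lda_selected - deps.proteins),
        n_dep_only=len(deps.proteins - lda_selected),
    )


def select_top_markers(panel: MarkerPanel, deps: DepSet, k: int = PANEL_SIZE) -> MarkerPanel:
    """Nominate a compact monitoring panel: top |DAve| proteins, group-balanced.

    Proteins are scored by their largest |DAve| over all pairwise
    comparisons, then drawn round-robin across their characteristic group
    (the group with the highest mean aSpC) so every stratified group is
    represented — a panel describing only one group cannot type subjects
    of the others. Ties in |DAve| break by accession so the panel is
    reproducible.
    """
    if k < 1:
        raise ValidationError("panel size must be >= 1")
    score: dict[str, float] = {p: 0.0 for p in panel.proteins}
    for df in deps.comparisons.values():
        sub = df[df["accession"].isin(score)]
        for acc, val in zip(sub["accession"], sub["dave"].abs()):
            if val > score[acc]:
                score[acc] = float(val)
    gm = panel.group_means
    if gm is None or len(gm) == 0:
        ranked = sorted(score, key=lambda a: (-score[a], a))[:k]
    else:
        by_group: dict[str, list[str]] = {g: [] for g in gm.columns}
        for acc in panel.proteins:
            by_group[gm.loc[acc].idxmax()].append(acc)
        for g in by_group:
            by_group[g].sort(key=lambda a: (-score[a], a))
        ranked = []
        while len(ranked) < min(k, len(panel.proteins)):
            for g in sorted(by_group):
                if by_group[g] and len(ranked) < k:
                    ranked.append(by_group[g].pop(0))
    return MarkerPanel(
        proteins=ranked,
        source=panel.source,
        group_means=panel.group_means.loc[[p for p in ranked if p in panel.group_means.index]],
        n_lda_only=panel.n_lda_only,
        n_dep_only=panel.n_dep_only,
    )
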