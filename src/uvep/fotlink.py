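"""Linking proteome-defined groups to respiratory-impedance phenotype.

Respiratory impedance is measured by the forced oscillation technique
(FOT): resistance (Rrs) and reactance (Xrs) of the respiratory system at
6, 8 and 10 Hz plus AX, the area under the reactance curve, all
expressed as reference-equation Z-scores. This module provides the
statistics that connect those Z-scores to the proteome groups:

* Kruskal–Wallis rank test (tie-corrected) per FOT variable across
  groups, with Dunn's post-hoc pairwise z tests and Holm adjustment;
* the 2x2 chi-squared test with Yates continuity correction (truncated
  at zero) for categorical cohort characteristics;
* a cohort characteristics table comparing a binary split (e.g.
  late-preterm vs term birth) across all covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .stratify import GroupAssignment

#: The seven impedance Z-score variables, in reporting order.
FOT_VARIABLES = ["z_rrs6", "z_rrs8", "z_rrs10", "z_xrs6", "z_xrs8", "z_xrs10", "z_ax"]


@dataclass
class FotRecord:
    """One subject's impedance Z-scores plus free-form covariates."""

    subject_id: str
    z_scores: dict[str, float]
    covariates: dict[str, object] = field(default_factory=dict)
    birth_group: str | None = None  # "LP" | "T"

    def __post_init__(self):
        missing = [v for v in FOT_VARIABLES if v not in self.z_scores]
        if missing:
            raise ValidationError(f"FOT record {self.subject_id}: missing {missing}")
        bad = [v for v in FOT_VARIABLES if not np.isfinite(self.z_scores[v])]
        if bad:
            raise ValidationError(f"FOT record {self.subject_id}: non-finite Z-score {bad}")


def read_fot_table(path) -> list[FotRecord]:
    """Read the per-subject FOT TSV: subject_id, z_* columns, free covariates."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing = [c for c in ["subject_id", *FOT_VARIABLES] if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in ("subject_id", *FOT_VARIABLES)]
    records = []
    for _, row in df.iterrows():
        cov = {c: row[c] for c in extra if c != "birth_group" and pd.notna(row[c])}
        records.append(
            FotRecord(
                subject_id=row["subject_id"],
                z_scores={v: float(row[v]) for v in FOT_VARIABLES},
                covariates=cov,
                birth_group=row.get("birth_group") if "birth_group" in df.columns else None,
            )
        )
    return records


def fot_frame(records: list[FotRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, **r.z_scores}
        if r.birth_group is not None:
            row["birth_group"] = r.birth_group
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def kruskal_wallis(values: list[tuple[str, float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-squared p (df = G - 1)."""
    groups: dict[str, list[float]] = {}
    for g, v in values:
        groups.setdefault(g, []).append(v)
    if len(groups) < 2:
        raise ValidationError("Kruskal–Wallis needs at least 2 groups")
    if sum(len(v) for v in groups.values()) < 2:
        raise ValidationError("Kruskal–Wallis needs at least 2 observations")
    samples = [np.asarray(v, dtype=float) for v in groups.values()]
    if np.ptp(np.concatenate(samples)) == 0:
        return 0.0, 1.0  # all values identical: no rank information
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control).

    Sorted ascending, p_(i) is multiplied by (m - i), a running maximum is
    enforced so the adjusted sequence is monotone, and values cap at 1.
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    stepped = np.maximum.accumulate(p[order] * (m - np.arange(m)))
    out = np.empty(m)
    out[order] = np.minimum(stepped, 1.0)
    return out


def dunn_posthoc(values: list[tuple[str, float]], method: str = "dunn_holm") -> dict[tuple[str, str], float]:
    """Dunn's pairwise z tests on pooled ranks, Holm-adjusted p per pair.

    The z statistic for groups i, j is the mean-rank difference divided by
    sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)) where
    T = sum(t^3 - t) / (12 (N - 1)) corrects for ties; two-sided normal
    p-values are then Holm-adjusted over the G(G-1)/2 pairs.
    """
    if method != "dunn_holm":
        raise ValidationError(f"unknown post-hoc method {method!r}")
    groups: dict[str, list[float]] = {}
    for g, v in values:
        groups.setdefault(g, []).append(v)
    if len(groups) < 2:
        raise ValidationError("post-hoc comparison needs at least 2 groups")
    labels = sorted(groups)
    pooled = np.concatenate([groups[g] for g in labels]).astype(float)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_rank, sizes, start = {}, {}, 0
    for g in labels:
        n = len(groups[g])
        mean_rank[g] = float(ranks[start:start + n].mean())
        sizes[g] = n
        start += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1))) if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(combinations(labels, 2))
    raw = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = 0.0 if se == 0 else (mean_rank[a] - mean_rank[b]) / se
        raw.append(2.0 * stats.norm.sf(abs(z)))
    adjusted = holm_adjust(raw)
    return {pair: float(p) for pair, p in zip(pairs, adjusted)}


def chi2_yates(table) -> tuple[float, float]:
    """2x2 chi-squared with Yates continuity correction, truncated at zero.

    chi2 = sum over cells of max(|O - E| - 0.5, 0)^2 / E, with expected
    counts from the margins; p from chi-squared with 1 df. The truncation
    means deviations smaller than the half-count correction give
    chi2 = 0, p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValidationError("contingency table has negative counts")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValidationError("zero row/column margin: expected count undefined")
    expected = np.outer(rows, cols) / t.sum()
    chi2 = float((np.maximum(np.abs(t - expected) - 0.5, 0.0) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def compare_groups_fot(
    records: list[FotRecord],
    groups: GroupAssignment | dict[str, str],
    alpha: float = 0.05,
) -> dict:
    """Per-variable Kruskal–Wallis + Dunn/Holm report across proteome groups.

    Returns a dict with a summary DataFrame (``table``: group medians and
    IQRs, H, p per variable) and a nested dict (``pairwise``: variable ->
    pair -> Holm-adjusted p). Every grouped subject must have a record.
    """
    labels = groups.as_dict() if isinstance(groups, GroupAssignment) else dict(groups)
    if len(set(labels.values())) < 2:
        raise ValidationError("FOT comparison needs at least 2 groups")
    by_id = {r.subject_id: r for r in records}
    missing = [s for s in labels if s not in by_id]
    if missing:
        raise ValidationError(f"subjects without FOT record: {missing}")
    group_names = sorted(set(labels.values()))
    rows, pairwise = [], {}
    for var in FOT_VARIABLES:
        values = [(labels[s], by_id[s].z_scores[var]) for s in labels]
        h, p = kruskal_wallis(values)
        row = {"variable": var, "H": h, "p": p, "significant": p < alpha}
        for g in group_names:
            vals = np.array([v for lab, v in values if lab == g])
            row[f"median_{g}"] = float(np.median(vals))
            q1, q3 = np.percentile(vals, [25, 75])
            row[f"iqr_{g}"] = float(q3 - q1)
        rows.append(row)
        pairwise[var] = dunn_posthoc(values)
    return {"table": pd.DataFrame(rows), "pairwise": pairwise, "alpha": alpha}


def cohort_table(records: list[FotRecord], split: str = "birth_group") -> pd.DataFrame:
    """Cohort characteristics compared across a binary split.

    Categorical covariates get counts, percentages (of each arm's
    non-missing denominator) and the Yates chi-squared p; quantitative
    covariates and the FOT Z-scores get mean (SD) and the Kruskal–Wallis
    p. Missing covariate values are allowed; each row uses its own
    pairwise-complete denominators, which are reported.
    """
    df = fot_frame(records)
    if split not in df.columns:
        raise ValidationError(f"split covariate {split!r} not found")
    arms = [a for a in df[split].dropna().unique()]
    if len(arms) != 2:
        raise ValidationError(f"split {split!r} must be binary, found {len(arms)} levels")
    arms = sorted(map(str, arms))
    df[split] = df[split].astype(str)
    variables = [c for c in df.columns if c not in ("subject_id", split)]
    rows = []
    for var in variables:
        sub = df[[split, var]].dropna()
        a = sub.loc[sub[split] == arms[0], var]
        b = sub.loc[sub[split] == arms[1], var]
        if pd.api.types.is_numeric_dtype(sub[var]) and sub[var].nunique() > 2:
            if a.nunique() <= 1 and b.nunique() <= 1 and set(a) == set(b):
                p = 1.0
            else:
                _, p = kruskal_wallis(
                    [(arms[0], float(v)) for v in a] + [(arms[1], float(v)) for v in b]
                )
            rows.append(
                {"variable": var, "kind": "quantitative",
                 arms[0]: f"{a.mean():.2f} ({a.std(ddof=1):.2f})",
                 arms[1]: f"{b.mean():.2f} ({b.std(ddof=1):.2f})",
                 "n_" + arms[0]: len(a), "n_" + arms[1]: len(b), "p": round(float(p), 3)}
            )
        else:
            pos = _positive_level(sub[var])
            ka, kb = int((a == pos).sum()), int((b == pos).sum())
            na, nb = len(a), len(b)
            table = [[ka, na - ka], [kb, nb - kb]]
            try:
                _, p = chi2_yates(table)
            except ValidationError:
                p = 1.0  # constant in both arms: no association testable
            rows.append(
                {"variable": var, "kind": "categorical",
                 arms[0]: f"{ka} ({100 * ka / na:.2f})",
                 arms[1]: f"{kb} ({100 * kb / nb:.2f})",
                 "n_" + arms[0]: na, "n_" + arms[1]: nb, "p": round(float(p), 3)}
            )
    return pd.DataFrame(rows)


def _positive_level(col: pd.Series):
    """The level counted in a categorical row: True/1/'yes' if present, else max."""
    levels = set(col.dropna().unique())
    for candidate in (True, 1, "1", "yes", "Y", "true", "True"):
        if candidate in levels:
            return candidate
    return max(levels, key=str)
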