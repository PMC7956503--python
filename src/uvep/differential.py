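"""DAve/DCI label-free differential expression on spectral counts.

Two semiquantitative indices compare the average spectral count (aSpC) of
a protein between two conditions X and Y:

* DAve (differential average) — the difference scaled by the mean,
  ``2(X - Y) / (X + Y)``, bounded in [-2, 2]; +-2 means the protein is
  absent on one side.
* DCI (differential confidence index) — the difference weighted by total
  abundance, ``(X + Y)(X - Y) / 2``; it separates confident changes of
  abundant proteins from noise-level flips of rare ones.

A protein is a differentially expressed protein (DEP) for a pairwise
group comparison when |DAve| and |DCI| both strictly exceed their
thresholds (defaults 0.2 and 5); the pooled DEP set is the union over all
pairwise comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrix import SpcMatrix

#: Default thresholds for calling a protein differentially expressed.
DAVE_THRESHOLD = 0.2
DCI_THRESHOLD = 5.0
#: Stricter DCI cut used when reporting cluster-of-differentiation markers.
CD_DCI_THRESHOLD = 10.0


def dave(x, y):
    """Differential average: 2(x - y)/(x + y), with dave(0, 0) = 0.

    Accepts scalars or arrays of non-negative aSpC values; antisymmetric
    and invariant under common positive scaling of both arguments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("DAve requires non-negative spectral counts")
    total = x + y
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total > 0, 2.0 * (x - y) / np.where(total > 0, total, 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


def dci(x, y):
    """Differential confidence index: (x + y)(x - y)/2.

    Same sign as DAve; magnitude grows with total abundance, so it
    down-weights differences among barely-detected proteins.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("DCI requires non-negative spectral counts")
    out = (x + y) * (x - y) / 2.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DiffResult:
    """Per-protein result of one pairwise group comparison."""

    accession: str
    comparison: tuple[str, str]
    aspc_x: float
    aspc_y: float
    dave: float
    dci: float
    passed: bool


@dataclass
class DepSet:
    """Pooled differentially-expressed-protein set over all pairwise comparisons."""

    proteins: set[str]
    comparisons: dict[tuple[str, str], pd.DataFrame]
    dave_threshold: float
    dci_threshold: float

    def table(self) -> pd.DataFrame:
        """All comparisons stacked into one long report table."""
        frames = []
        for (x, y), df in self.comparisons.items():
            out = df.copy()
            out.insert(0, "comparison", f"{x}_vs_{y}")
            frames.append(out)
        return pd.concat(frames, ignore_index=True)

    def to_tsv(self, path) -> None:
        self.table().to_csv(path, sep="\t", index=False)


def group_mean_aspc(m: SpcMatrix, groups: dict[str, str]) -> pd.DataFrame:
    """Per-protein mean aSpC for each group (columns = sorted group labels)."""
    unknown = [s for s in groups if s not in m.values.columns]
    if unknown:
        raise ValidationError(f"subjects not in matrix: {unknown}")
    labels = sorted(set(groups.values()))
    cols = {}
    for g in labels:
        members = [s for s, lab in groups.items() if lab == g]
        cols[g] = m.values[members].mean(axis=1)
    return pd.DataFrame(cols)


def pairwise_deps(
    m: SpcMatrix,
    groups: dict[str, str],
    dave_threshold: float = DAVE_THRESHOLD,
    dci_threshold: float = DCI_THRESHOLD,
) -> DepSet:
    """Extract DEPs from every pairwise comparison of group-mean aSpC.

    For each unordered pair of groups (in canonical sorted label order),
    computes per-protein DAve and DCI on the group means and flags
    proteins with |DAve| > dave_threshold and |DCI| > dci_threshold
    (strict). Returns the pooled union with full per-comparison tables.
    """
    if m.level != "subject":
        raise ValidationError("pairwise_deps expects the subject-level aSpC matrix")
    means = group_mean_aspc(m, groups)
    labels = list(means.columns)
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups for differential expression")
    comparisons: dict[tuple[str, str], pd.DataFrame] = {}
    passing: set[str] = set()
    for x, y in combinations(labels, 2):
        mx = means[x].to_numpy()
        my = means[y].to_numpy()
        d_ave = dave(mx, my)
        d_ci = dci(mx, my)
        ok = (np.abs(d_ave) > dave_threshold) & (np.abs(d_ci) > dci_threshold)
        df = pd.DataFrame(
            {
                "accession": means.index,
                "aspc_x": mx,
                "aspc_y": my,
                "dave": d_ave,
                "dci": d_ci,
                "passed": ok,
            }
        )
        comparisons[(x, y)] = df
        passing.update(df.loc[df["passed"], "accession"])
    return DepSet(
        proteins=passing,
        comparisons=comparisons,
        dave_threshold=dave_threshold,
        dci_threshold=dci_threshold,
    )


def cd_marker_table(
    deps: DepSet,
    cd_accessions: set[str],
    group_means: pd.DataFrame,
    dci_threshold: float = CD_DCI_THRESHOLD,
) -> pd.DataFrame:
    """Report cluster-of-differentiation markers at a stricter DCI cut.

    Restricts the differential results to the supplied CD accession list,
    re-evaluates the pass flag with the stricter |DCI| threshold (default
    10 instead of the global 5), and attaches per-group mean aSpC. CD
    accessions absent from the analyzed matrix are omitted with a warning.
    """
    present = [a for a in sorted(cd_accessions) if a in group_means.index]
    absent = sorted(set(cd_accessions) - set(present))
    if absent:
        warnings.warn(f"CD accession(s) not in matrix, omitted: {absent}", stacklevel=2)
    rows = []
    for (x, y), df in deps.comparisons.items():
        sub = df[df["accession"].isin(present)]
        for _, r in sub.iterrows():
            rows.append(
                {
                    "accession": r["accession"],
                    "comparison": f"{x}_vs_{y}",
                    "aspc_x": r["aspc_x"],
                    "aspc_y": r["aspc_y"],
                    "dave": r["dave"],
                    "dci": r["dci"],
                    "passed": bool(
                        abs(r["dave"]) > deps.dave_threshold and abs(r["dci"]) > dci_threshold
                    ),
                }
            )
    out = pd.DataFrame(
        rows, columns=["accession", "comparison", "aspc_x", "aspc_y", "dave", "dci", "passed"]
    )
    if len(out):
        gm = group_means.loc[out["accession"]].reset_index(drop=True)
        gm.columns = [f"aspc_{g}" for g in gm.columns]
        out = pd.concat([out, gm], axis=1)
    return out


def read_accession_list(path) -> set[str]:
    """Read a plain-text accession list, one per line, '#' comments allowed."""
    out = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.add(line)
    return out
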