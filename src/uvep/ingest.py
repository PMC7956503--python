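"""Reading, aligning, normalizing and replicate-averaging protein lists.

The raw inputs are per-run protein identification lists. This module turns
them into the analysis-ready subject-level aSpC matrix:

1. :func:`read_run_table` — parse and validate the long-TSV (or wide-CSV)
   run table;
2. :func:`align_runs` — union the per-run protein lists into one matrix,
   absent identifications becoming structural zeros;
3. :func:`normalize_total_spc` — per-run total-count scaling to the grand
   mean run total, correcting for injection/acquisition depth;
4. :func:`filter_by_frequency` — keep proteins detected in more than a
   given fraction of runs (detection judged on pre-normalization counts);
5. :func:`replicate_qc` — per-subject correlation/slope check between the
   two technical replicates (flag-only; nothing is dropped);
6. :func:`average_replicates` — collapse replicate pairs to per-subject
   average spectral counts (aSpC).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, ValidationError
from .matrix import RUN_COLUMNS, RunTable, SpcMatrix

logger = logging.getLogger(__name__)

#: Replicate QC acceptance window; flag-only defaults (see replicate_qc).
QC_MIN_CORRELATION = 0.8
QC_SLOPE_LO = 0.8
QC_SLOPE_HI = 1.25


@dataclass(frozen=True)
class ReplicateQc:
    """Quality summary for one subject's technical replicate pair."""

    subject_id: str
    correlation: float
    slope: float
    n_shared_proteins: int
    passed: bool


def _read_long_tsv(path: Path) -> RunTable:
    df = pd.read_csv(path, sep="\t", dtype={"run_id": str, "subject_id": str, "accession": str})
    required = [c for c in RUN_COLUMNS if c != "gene_symbol"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if "gene_symbol" not in df.columns:
        df["gene_symbol"] = pd.NA
    neg = df.index[pd.to_numeric(df["spc"], errors="coerce") < 0]
    if len(neg):
        # +2: header line and 1-based numbering, so the message points at the file line
        raise ValidationError(f"{path}: negative spc at file line {neg[0] + 2}")
    df["replicate"] = df["replicate"].astype(int)
    df["spc"] = df["spc"].astype(float)
    return RunTable(records=df[RUN_COLUMNS].copy(), provenance=[f"read long TSV {path}"])


def _read_wide_csv(path: Path, sidecar: Path) -> RunTable:
    wide = pd.read_csv(path, index_col=0)
    meta = pd.read_csv(sidecar, sep="\t", dtype=str)
    for col in ("run_id", "subject_id", "replicate"):
        if col not in meta.columns:
            raise FormatError(f"{sidecar}: missing required column(s) ['{col}']")
    meta = meta.set_index("run_id")
    unknown = [r for r in wide.columns if r not in meta.index]
    if unknown:
        raise FormatError(f"{path}: run id(s) {unknown} absent from sidecar {sidecar}")
    n_empty = int(wide.isna().to_numpy().sum())
    wide = wide.fillna(0.0)
    rows = []
    for run_id in wide.columns:
        for accession, spc in wide[run_id].items():
            rows.append(
                (run_id, meta.loc[run_id, "subject_id"], int(meta.loc[run_id, "replicate"]),
                 str(accession), pd.NA, float(spc))
            )
    df = pd.DataFrame(rows, columns=RUN_COLUMNS)
    if (df["spc"] < 0).any():
        row = df.index[df["spc"] < 0][0]
        raise ValidationError(f"{path}: negative spc for {df.loc[row, 'accession']}")
    prov = [f"read wide CSV {path} with sidecar {sidecar}"]
    if n_empty:
        prov.append(f"treated {n_empty} empty cell(s) as 0")
    return RunTable(records=df, provenance=prov)


def read_run_table(path, format: str = "long_tsv", sidecar=None) -> RunTable:
    """Read a run-level protein table.

    Parameters
    ----------
    path
        Input file. ``long_tsv`` expects columns run_id, subject_id,
        replicate, accession, gene_symbol (optional), spc. ``wide_csv``
        expects proteins as rows and run ids as columns, with a sidecar
        TSV mapping run_id -> (subject_id, replicate); empty cells are
        read as explicit zeros.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    if format == "long_tsv":
        return _read_long_tsv(path)
    if format == "wide_csv":
        if sidecar is None:
            raise FormatError("wide_csv format requires a sidecar run-metadata TSV")
        return _read_wide_csv(path, Path(sidecar))
    raise FormatError(f"unknown run-table format {format!r}")


def align_runs(runs: RunTable) -> SpcMatrix:
    """Align per-run protein lists into one proteins x runs matrix.

    The protein index is the sorted union of accessions over all runs;
    a protein not identified in a run gets a structural zero (no
    imputation). Column order follows input run order, so permuting the
    input runs permutes columns without changing any value.
    """
    run_ids = runs.run_ids
    if len(run_ids) < 2:
        raise ValidationError("alignment requires at least 2 runs")
    values = (
        runs.records.pivot(index="accession", columns="run_id", values="spc")
        .reindex(columns=run_ids)
        .sort_index()
        .fillna(0.0)
    )
    values.columns.name = None
    values.index.name = None
    detection = values > 0
    return SpcMatrix(
        values=values,
        level="run",
        provenance=[*runs.provenance,
                    f"aligned {len(run_ids)} runs, {values.shape[0]} proteins (union)"],
        detection=detection,
        gene_symbols=runs.gene_symbols(),
    )


def normalize_total_spc(m: SpcMatrix) -> SpcMatrix:
    """Scale each column so its total equals the grand mean column total.

    Column j is multiplied by mean(totals)/totals[j]; totals are equalized
    across runs while within-column protein ratios (and ranks) are
    untouched. Idempotent: a second application is a no-op.
    """
    totals = m.values.sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValidationError(f"zero-total column(s): {list(zero)}")
    target = float(totals.mean())
    scaled = m.values * (target / totals)
    return m.with_values(
        scaled,
        f"total-SpC normalization to grand mean column total {target:.6g}",
        normalized=True,
    )


def filter_by_frequency(m: SpcMatrix, min_frac: float = 0.25) -> SpcMatrix:
    """Keep proteins detected in strictly more than ``min_frac`` of runs.

    Detection means raw (pre-normalization) count > 0; with 42 runs and
    the default 0.25 this keeps proteins seen in >= 11 runs. An empty
    result is a warning, not an error.
    """
    if m.level != "run":
        raise ValidationError("frequency filter applies to the run-level matrix")
    if not (0 <= min_frac < 1):
        raise ValidationError(f"min_frac must be in [0, 1), got {min_frac}")
    detection = m.detection if m.detection is not None else (m.values > 0)
    frac = detection.sum(axis=1) / detection.shape[1]
    keep = frac > min_frac
    if not keep.any():
        warnings.warn("frequency filter removed every protein", stacklevel=2)
    out = m.values.loc[keep]
    return m.with_values(
        out,
        f"frequency filter >{min_frac:.0%}: kept {int(keep.sum())}/{len(keep)} proteins",
    )


def replicate_qc(
    m: SpcMatrix,
    pairing: dict[str, tuple[str, str]],
    min_correlation: float = QC_MIN_CORRELATION,
    slope_lo: float = QC_SLOPE_LO,
    slope_hi: float = QC_SLOPE_HI,
) -> list[ReplicateQc]:
    """Per-subject technical-replicate agreement check.

    Over proteins detected in either replicate, computes the Pearson
    correlation and the least-squares slope of replicate 2 regressed on
    replicate 1. Good technical replicates show correlation near 1 and
    slope near the theoretical value of 1. Degenerate inputs (no shared
    detections, or a constant replicate) yield NaN and fail. Flag-only:
    callers decide what to do with failing subjects.
    """
    results = []
    for subject_id, (run1, run2) in pairing.items():
        for run in (run1, run2):
            if run not in m.values.columns:
                raise ValidationError(f"run {run!r} for subject {subject_id!r} not in matrix")
        x = m.values[run1].to_numpy(dtype=float)
        y = m.values[run2].to_numpy(dtype=float)
        either = (x > 0) | (y > 0)
        x, y = x[either], y[either]
        n = int(either.sum())
        if n < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
            corr, slope = float("nan"), float("nan")
        else:
            fit = stats.linregress(x, y)
            corr, slope = float(fit.rvalue), float(fit.slope)
        ok = (
            np.isfinite(corr)
            and np.isfinite(slope)
            and corr >= min_correlation
            and slope_lo <= slope <= slope_hi
        )
        if not ok:
            logger.warning(
                "replicate QC failed for %s: r=%.3f slope=%.3f (n=%d)",
                subject_id, corr, slope, n,
            )
        results.append(ReplicateQc(subject_id, corr, slope, n, bool(ok)))
    return results


def average_replicates(m: SpcMatrix, pairing: dict[str, tuple[str, str]]) -> SpcMatrix:
    """Collapse replicate runs to per-subject average spectral counts (aSpC).

    Each subject's column is the arithmetic mean of its two replicate
    columns; the result is the subject-level matrix used by clustering,
    the discriminant screen and differential expression.
    """
    if m.level != "run":
        raise ValidationError("average_replicates expects a run-level matrix")
    used = [r for pair in pairing.values() for r in pair]
    missing = [r for r in used if r not in m.values.columns]
    if missing:
        raise ValidationError(f"pairing references runs absent from matrix: {missing}")
    cols = {}
    for subject_id, (run1, run2) in pairing.items():
        cols[subject_id] = (m.values[run1] + m.values[run2]) / 2.0
    values = pd.DataFrame(cols)
    values.columns.name = None
    return SpcMatrix(
        values=values,
        level="subject",
        normalized=m.normalized,
        provenance=[*m.provenance, f"averaged replicates into {len(cols)} subject aSpC columns"],
        detection=None,
        gene_symbols=m.gene_symbols,
    )
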