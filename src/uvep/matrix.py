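"""Core containers: run-level spectral-count records and the aligned matrix.

A label-free shotgun-proteomics experiment produces, per LC-MS/MS run, a
list of identified proteins with their spectral counts (SpC, the number of
MS/MS spectra matched to each protein — a proxy for relative abundance).
:class:`RunTable` holds these records in long form; :class:`SpcMatrix` is
the aligned proteins x columns matrix the downstream statistics operate on,
first at *run* level (one column per LC-MS/MS run) and, after technical
replicates are averaged, at *subject* level (aSpC).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

RUN_COLUMNS = ["run_id", "subject_id", "replicate", "accession", "gene_symbol", "spc"]


@dataclass(frozen=True)
class RunRecord:
    """One protein identification in one LC-MS/MS run."""

    run_id: str
    subject_id: str
    replicate: int
    accession: str
    gene_symbol: str | None
    spc: float

    def __post_init__(self):
        if self.spc < 0:
            raise ValidationError(
                f"negative spectral count {self.spc} for {self.accession} in run {self.run_id}"
            )


@dataclass
class RunTable:
    """Validated long-form table of :class:`RunRecord` rows.

    Invariants enforced at construction: spc >= 0; (run_id, accession)
    unique; each run_id maps to exactly one (subject_id, replicate) pair.
    """

    records: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        df = self.records
        missing = [c for c in RUN_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"run table missing columns: {missing}")
        neg = df.index[df["spc"] < 0]
        if len(neg):
            raise ValidationError(f"negative spc at row(s) {list(neg[:5])}")
        dup = df.duplicated(subset=["run_id", "accession"])
        if dup.any():
            r = df.loc[dup, ["run_id", "accession"]].iloc[0]
            raise ValidationError(
                f"duplicate (run_id, accession) pair: ({r['run_id']}, {r['accession']})"
            )
        meta = df[["run_id", "subject_id", "replicate"]].drop_duplicates()
        bad = meta["run_id"].duplicated()
        if bad.any():
            raise ValidationError(
                f"run_id {meta.loc[bad, 'run_id'].iloc[0]!r} maps to more than one "
                "(subject_id, replicate) pair"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def run_ids(self) -> list[str]:
        """Run ids in order of first appearance."""
        return list(self.records["run_id"].drop_duplicates())

    def run_meta(self) -> pd.DataFrame:
        """One row per run: run_id, subject_id, replicate (input order)."""
        return (
            self.records[["run_id", "subject_id", "replicate"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def pairing(self) -> dict[str, tuple[str, str]]:
        """Map subject_id -> (replicate-1 run, replicate-2 run).

        Raises :class:`ValidationError` if any subject does not have
        exactly two replicate runs.
        """
        meta = self.run_meta()
        out: dict[str, tuple[str, str]] = {}
        for sid, grp in meta.groupby("subject_id", sort=False):
            if len(grp) != 2:
                raise ValidationError(
                    f"subject {sid!r} has {len(grp)} runs; exactly 2 replicates required"
                )
            grp = grp.sort_values("replicate")
            out[sid] = (grp["run_id"].iloc[0], grp["run_id"].iloc[1])
        return out

    def gene_symbols(self) -> dict[str, str]:
        sym = self.records.dropna(subset=["gene_symbol"])
        return dict(zip(sym["accession"], sym["gene_symbol"]))


@dataclass
class SpcMatrix:
    """Aligned spectral-count matrix (proteins x runs, or proteins x subjects).

    ``values`` is a DataFrame indexed by accession with run ids (level
    ``"run"``) or subject ids (level ``"subject"``) as columns.
    ``detection`` is the boolean raw-count > 0 mask captured at alignment
    time; the detection-frequency filter always consults it, so the filter
    outcome does not depend on whether normalization ran first.
    ``provenance`` is an append-only log of the transforms applied.
    """

    values: pd.DataFrame
    level: str  # "run" | "subject"
    normalized: bool = False
    provenance: list[str] = field(default_factory=list)
    detection: pd.DataFrame | None = None
    gene_symbols: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.level not in ("run", "subject"):
            raise ValidationError(f"invalid matrix level {self.level!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("spectral-count matrix contains negative entries")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate accessions in protein index")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate column ids in matrix")

    @property
    def protein_index(self) -> list[str]:
        return list(self.values.index)

    @property
    def column_index(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, note: str, **kw) -> "SpcMatrix":
        """Derived matrix sharing metadata, with ``note`` appended to provenance."""
        det = self.detection
        if det is not None and not values.index.equals(self.values.index):
            det = det.loc[values.index] if set(values.index) <= set(det.index) else None
        fields = dict(
            values=values,
            level=self.level,
            normalized=self.normalized,
            provenance=[*self.provenance, note],
            detection=det,
            gene_symbols=self.gene_symbols,
        )
        fields.update(kw)
        return SpcMatrix(**fields)

    def to_tsv(self, path) -> None:
        """Write the matrix as TSV, provenance as '#'-prefixed header lines."""
        with open(path, "w", encoding="utf-8") as fh:
            for line in self.provenance:
                fh.write(f"# {line}\n")
            fh.write(f"# level={self.level} normalized={self.normalized}\n")
            out = self.values.copy()
            out.index.name = "accession"
            out.to_csv(fh, sep="\t")


def read_matrix_tsv(path) -> SpcMatrix:
    """Read a matrix written by :meth:`SpcMatrix.to_tsv`."""
    provenance: list[str] = []
    level, normalized = "run", False
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            text = line[1:].strip()
            if text.startswith("level="):
                parts = dict(p.split("=") for p in text.split())
                level = parts.get("level", "run")
                normalized = parts.get("normalized") == "True"
            else:
                provenance.append(text)
            pos = fh.tell()
        values = pd.read_csv(fh, sep="\t", index_col="accession")
    return SpcMatrix(values=values, level=level, normalized=normalized, provenance=provenance)


def matrix_mass(m: SpcMatrix) -> float:
    """Total spectral-count mass (sum of all entries)."""
    return float(np.asarray(m.values).sum())
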