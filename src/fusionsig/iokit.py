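"""File formats and validation shared by all pipeline stages.

Expression matrices are plain pandas DataFrames (rows = genes, columns =
samples) read from tab-delimited text or GCT 1.2.  Clinical tables are
DataFrames indexed by sample id.  Signatures are small value objects with
signed weights in [-1, 1].

All readers validate and reject malformed input rather than coercing it.
The TSV dialect is fixed: tab-separated, UTF-8, ``.`` decimal separator,
no quoting.  Missing values are permitted (as ``NA``) only in clinical
tables; expression must be complete because rank-based scoring is
undefined on missing values.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("fusionsig")

#: Controlled vocabulary for the fusion-status column.  ``erg_other``
#: marks samples whose ERG locus is fused to a partner other than
#: TMPRSS2; such samples carry TMPRSS2-ERG-negative labels but similar
#: downstream pathway activity.
FUSION_STATUSES = ("positive", "negative", "erg_other")

CLINICAL_REQUIRED_COLUMNS = ("fusion_status", "age", "gleason", "time", "event")


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates a contract."""


@dataclasses.dataclass(frozen=True)
class Signature:
    """A signed, weighted gene signature.

    Parameters
    ----------
    genes
        Unique gene identifiers, in signature order.
    weights
        One weight per gene, each in ``[-1, 1]`` and nonzero.  The sign
        encodes the direction of regulation in fusion-positive tumors
        (positive = upregulated); the largest magnitude is exactly 1.
    name
        Optional identifier carried through to score metadata.
    """

    genes: tuple[str, ...]
    weights: tuple[float, ...]
    name: str = "signature"

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValidationError("empty signature")
        if len(self.genes) != len(self.weights):
            raise ValidationError(
                f"signature has {len(self.genes)} genes but "
                f"{len(self.weights)} weights"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene ids in signature")
        w = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValidationError("non-finite signature weight")
        if np.any(w == 0.0):
            raise ValidationError("zero signature weight (weights must be in [-1,1] \\ {0})")
        if np.any(np.abs(w) > 1.0):
            bad = [g for g, x in zip(self.genes, w) if abs(x) > 1.0]
            raise ValidationError(f"weight outside [-1, 1] for gene(s): {bad[:5]}")
        if not np.isclose(np.max(np.abs(w)), 1.0):
            raise ValidationError("max |weight| must equal 1 (normalization anchor)")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def up_genes(self) -> tuple[str, ...]:
        return tuple(g for g, w in zip(self.genes, self.weights) if w > 0)

    @property
    def down_genes(self) -> tuple[str, ...]:
        return tuple(g for g, w in zip(self.genes, self.weights) if w < 0)

    def as_series(self) -> pd.Series:
        return pd.Series(list(self.weights), index=list(self.genes), name="weight")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check an in-memory expression matrix (genes x samples)."""
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene id(s): {dups[:5]}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample id(s): {dups[:5]}")
    values = expr.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("expression matrix contains non-numeric cells")
    if not np.all(np.isfinite(values)):
        n_bad = int((~np.isfinite(values)).sum())
        raise ValidationError(f"expression matrix contains {n_bad} missing/non-finite cells")
    return expr


def read_expression(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a genes-x-samples expression matrix from TSV or GCT 1.2.

    ``format`` may be ``"tsv"`` or ``"gct"``; when omitted it is inferred
    from the file suffix (``.gct`` -> GCT, anything else -> TSV).
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        return _read_gct(path)
    if format == "tsv":
        try:
            expr = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ValidationError(f"{path}: cannot parse TSV expression matrix: {exc}") from exc
        try:
            expr = expr.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: non-numeric expression cell: {exc}") from exc
        expr.index = expr.index.astype(str)
        expr.columns = expr.columns.astype(str)
        return validate_expression(expr)
    raise ValidationError(f"unknown expression format {format!r} (expected 'tsv' or 'gct')")


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise ValidationError(f"{path}: truncated GCT file")
    if lines[0].strip() != "#1.2":
        raise ValidationError(f"{path}: line 1: expected GCT version header '#1.2', got {lines[0]!r}")
    dims = lines[1].split("\t")
    if len(dims) < 2:
        raise ValidationError(f"{path}: line 2: expected '<n_genes>\\t<n_samples>'")
    try:
        n_genes, n_samples = int(dims[0]), int(dims[1])
    except ValueError as exc:
        raise ValidationError(f"{path}: line 2: non-integer dimensions") from exc
    header = lines[2].split("\t")
    if len(header) != n_samples + 2:
        raise ValidationError(
            f"{path}: line 3: header has {len(header) - 2} sample columns, "
            f"line 2 declares {n_samples}"
        )
    data_lines = [ln for ln in lines[3:] if ln.strip() != ""]
    if len(data_lines) != n_genes:
        raise ValidationError(
            f"{path}: line 2 declares {n_genes} genes but file has {len(data_lines)} data rows"
        )
    genes, rows = [], []
    for offset, ln in enumerate(data_lines, start=4):
        fields = ln.split("\t")
        if len(fields) != n_samples + 2:
            raise ValidationError(f"{path}: line {offset}: expected {n_samples + 2} fields, got {len(fields)}")
        genes.append(fields[0])
        try:
            rows.append([float(x) for x in fields[2:]])
        except ValueError as exc:
            raise ValidationError(f"{path}: line {offset}: non-numeric expression cell") from exc
    expr = pd.DataFrame(rows, index=pd.Index(genes, name="gene"), columns=header[2:], dtype=float)
    return validate_expression(expr)


def write_expression(expr: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    """Write an expression matrix as TSV (default) or GCT 1.2."""
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    validate_expression(expr)
    if format == "tsv":
        out = expr.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.6g")
    elif format == "gct":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.shape[0]}\t{expr.shape[1]}\n")
            fh.write("NAME\tDescription\t" + "\t".join(map(str, expr.columns)) + "\n")
            for gene, row in zip(expr.index, expr.to_numpy()):
                fh.write(str(gene) + "\tNA\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")
    else:
        raise ValidationError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Check a clinical table indexed by sample id."""
    if clinical.index.has_duplicates:
        dups = clinical.index[clinical.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample id(s): {dups[:5]}")
    missing = [c for c in CLINICAL_REQUIRED_COLUMNS if c not in clinical.columns]
    if missing:
        raise ValidationError(f"clinical table missing required column(s): {missing}")
    bad_status = set(clinical["fusion_status"].dropna()) - set(FUSION_STATUSES)
    if bad_status:
        raise ValidationError(
            f"unknown fusion_status value(s) {sorted(bad_status)}; expected one of {FUSION_STATUSES}"
        )
    ev = clinical["event"].dropna()
    if not np.isin(ev.to_numpy(), (0, 1)).all():
        raise ValidationError("event column must be 0/1")
    tm = clinical["time"].dropna()
    if (tm.to_numpy() < 0).any():
        raise ValidationError("negative survival time")
    return clinical


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited clinical table; first column is ``sample_id``."""
    path = Path(path)
    clinical = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False, dtype={0: str})
    if "sample_id" not in clinical.columns:
        raise ValidationError(f"{path}: first column must be 'sample_id'")
    clinical = clinical.set_index("sample_id")
    return validate_clinical(clinical)


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    validate_clinical(clinical)
    out = clinical.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


# ---------------------------------------------------------------------------
# Signatures
# ---------------------------------------------------------------------------


def read_signature(path: str | Path, header: bool = False, name: str | None = None) -> Signature:
    """Read a two-column ``gene<TAB>weight`` signature file."""
    path = Path(path)
    genes: list[str] = []
    weights: list[float] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    start = 1 if header else 0
    for lineno, ln in enumerate(lines[start:], start=start + 1):
        if ln.strip() == "":
            continue
        fields = ln.split("\t")
        if len(fields) != 2:
            raise ValidationError(f"{path}: row {lineno}: expected 2 tab-separated fields")
        try:
            w = float(fields[1])
        except ValueError as exc:
            raise ValidationError(f"{path}: row {lineno}: non-numeric weight {fields[1]!r}") from exc
        if not (-1.0 <= w <= 1.0) or w == 0.0:
            raise ValidationError(
                f"{path}: row {lineno}: weight {w} outside [-1, 1] or zero for gene {fields[0]!r}"
            )
        genes.append(fields[0])
        weights.append(w)
    if not genes:
        raise ValidationError(f"{path}: empty signature")
    return Signature(tuple(genes), tuple(weights), name=name or path.stem)


def write_signature(signature: Signature, path: str | Path, header: bool = False) -> None:
    """Write ``gene<TAB>weight`` rows, weights with 6 decimals."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write("gene\tweight\n")
        for gene, w in zip(signature.genes, signature.weights):
            fh.write(f"{gene}\t{w:.6f}\n")


def write_json(obj: object, path: str | Path) -> None:
    """Serialize a report/manifest/truth object as indented JSON."""

    def _default(o: object):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def align_samples(expr: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Return clinical rows for the matrix samples, in matrix column order.

    Raises if any scored sample lacks a clinical row.
    """
    missing = [s for s in expr.columns if s not in clinical.index]
    if missing:
        raise ValidationError(f"clinical table missing sample(s): {missing[:5]}")
    return clinical.loc[list(expr.columns)]
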