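"""Readers and writers for expression matrices, sample annotations and signatures.

All formats are plain UTF-8 tab-delimited text. Lines starting with ``#`` are
treated as metadata comments and skipped on read; writers use them to embed
run provenance (config hash, RNG seed).

Conventions
-----------
* Expression: genes in rows, samples in columns; first column holds the gene
  symbol, first row the sample identifiers. Values are log-scale expression.
  Empty cells or ``NA`` denote missing values.
* Annotation: one row per sample with the columns listed in
  :data:`ANNOTATION_COLUMNS`.
* Signatures: three-column TSV (gene, direction, fold_change) or standard GMT
  (name, description, genes...; all genes treated as upregulated).
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError
from .signature import GeneSignature, SignatureEntry

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = (
    "sample_id",
    "subject_id",
    "parity",
    "tissue",
    "er_status",
    "menopausal",
    "age_first_birth_years",
    "years_since_last_birth",
)

PARITY_LEVELS = ("parous", "nulliparous")
TISSUE_LEVELS = ("normal", "adjacent_normal", "tumor")
ER_LEVELS = ("positive", "negative", "unknown")
MENOPAUSAL_LEVELS = ("pre", "post", "unknown")

_MISSING_TOKENS = {"", "na", "nan", "null", "none"}


def _read_lines(path: str | os.PathLike) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]


def _metadata_header(metadata: Mapping[str, object] | None) -> str:
    if not metadata:
        return ""
    return "".join(f"# {key}={value}\n" for key, value in metadata.items())


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes-in-rows expression TSV into a genes x samples DataFrame.

    Duplicate gene rows are retained (probe-level data); collapse them with
    :func:`paritysig.preprocess.collapse_probes`. Duplicate sample identifiers
    are an error. Ragged rows are an error.
    """
    lines = _read_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty expression file")
    header = lines[0].split("\t")
    samples = header[1:]
    if not samples:
        raise FormatError(f"{path}: no sample columns in header")
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise FormatError(f"{path}: duplicate sample ids {dupes}")
    width = len(header)
    genes: list[str] = []
    raw: list[list[str]] = []
    for i, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != width:
            raise FormatError(
                f"{path}: ragged row at line {i} ({len(fields)} fields, expected {width})"
            )
        genes.append(fields[0])
        raw.append(fields[1:])
    values = np.empty((len(raw), len(samples)), dtype=float)
    for i, row in enumerate(raw):
        for j, tok in enumerate(row):
            if tok.strip().lower() in _MISSING_TOKENS:
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(tok)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: non-numeric value {tok!r} at line {i + 2}"
                    ) from exc
    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    n_dup = int(matrix.index.duplicated().sum())
    if n_dup:
        logger.warning("%s: %d duplicate gene rows (probe-level data?)", path, n_dup)
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        logger.info("%s: %d missing expression values", path, n_missing)
    return matrix


def write_expression(
    matrix: pd.DataFrame,
    path: str | os.PathLike,
    metadata: Mapping[str, object] | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_header(metadata))
        matrix.to_csv(fh, sep="\t", index_label="gene", na_rep="NA", lineterminator="\n")


def read_annotation(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sample annotation TSV, indexed by unique sample_id.

    Categorical columns are validated against their allowed levels; missing
    ``er_status`` / ``menopausal`` entries become ``"unknown"``.
    """
    ann = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "sample_id" not in ann.columns:
        raise FormatError(f"{path}: annotation must have a sample_id column")
    if ann["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id values")
    ann = ann.set_index("sample_id", drop=False)
    ann.index.name = None
    for col, levels in (
        ("parity", PARITY_LEVELS),
        ("tissue", TISSUE_LEVELS),
        ("er_status", ER_LEVELS),
        ("menopausal", MENOPAUSAL_LEVELS),
    ):
        if col not in ann.columns:
            if col in ("er_status", "menopausal"):
                ann[col] = "unknown"
                continue
            raise FormatError(f"{path}: missing required column {col!r}")
        vals = ann[col].fillna("unknown" if "unknown" in levels else "")
        bad = sorted(set(vals) - set(levels))
        if bad:
            raise FormatError(f"{path}: invalid {col} values {bad}; allowed {levels}")
        ann[col] = vals
    for col in ("age_first_birth_years", "years_since_last_birth"):
        if col in ann.columns:
            ann[col] = pd.to_numeric(ann[col], errors="coerce")
        else:
            ann[col] = np.nan
    if "subject_id" not in ann.columns:
        ann["subject_id"] = ann["sample_id"]
    return ann


def write_annotation(
    ann: pd.DataFrame,
    path: str | os.PathLike,
    metadata: Mapping[str, object] | None = None,
) -> None:
    cols = [c for c in ANNOTATION_COLUMNS if c in ann.columns]
    cols += [c for c in ann.columns if c not in cols]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_header(metadata))
        ann.to_csv(fh, sep="\t", index=False, columns=cols, na_rep="NA", lineterminator="\n")


def _infer_signature_format(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "gmt" if str(path).lower().endswith(".gmt") else "tsv"


def read_signature(
    path: str | os.PathLike, fmt: str | None = None, name: str | None = None
) -> GeneSignature:
    """Read a signature from TSV (gene/direction/fold_change) or GMT.

    For GMT files with several gene sets, ``name`` selects one; the default is
    the first line. GMT entries have direction ``up`` and no fold change.
    """
    fmt = _infer_signature_format(path, fmt)
    lines = _read_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty signature file")
    if fmt == "gmt":
        for ln in lines:
            fields = ln.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: GMT line needs name, description and >=1 gene")
            if name is None or fields[0] == name:
                entries = tuple(SignatureEntry(g, "up", None) for g in fields[2:] if g)
                return GeneSignature(fields[0], entries)
        raise FormatError(f"{path}: gene set {name!r} not found")
    if fmt != "tsv":
        raise ValueError(f"unknown signature format {fmt!r}")
    header = lines[0].split("\t")
    if header[0] != "gene":
        raise FormatError(f"{path}: signature TSV must start with a 'gene' header column")
    entries = []
    for i, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        gene = fields[0]
        direction = fields[1] if len(fields) > 1 and fields[1] else "up"
        if direction not in ("up", "down"):
            raise FormatError(f"{path}: unknown direction token {direction!r} at line {i}")
        fc: float | None = None
        if len(fields) > 2 and fields[2].strip().lower() not in _MISSING_TOKENS:
            try:
                fc = float(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: bad fold change {fields[2]!r} at line {i}") from exc
        try:
            entries.append(SignatureEntry(gene, direction, fc))
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
    sig_name = name if name is not None else os.path.splitext(os.path.basename(path))[0]
    return GeneSignature(sig_name, tuple(entries))


def write_signature(
    sig: GeneSignature,
    path: str | os.PathLike,
    fmt: str | None = None,
    metadata: Mapping[str, object] | None = None,
) -> None:
    fmt = _infer_signature_format(path, fmt)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_header(metadata))
        if fmt == "gmt":
            fh.write("\t".join([sig.name, "paritysig"] + sig.genes) + "\n")
            return
        if fmt != "tsv":
            raise ValueError(f"unknown signature format {fmt!r}")
        fh.write("gene\tdirection\tfold_change\n")
        for e in sig.entries:
            fc = "" if e.fold_change is None else repr(float(e.fold_change))
            fh.write(f"{e.gene}\t{e.direction}\t{fc}\n")


def parity_labels(ann: pd.DataFrame, sample_ids: Iterable[str]) -> np.ndarray:
    """Return the parity label of each sample id, in order; error on gaps."""
    sample_ids = list(sample_ids)
    missing = [s for s in sample_ids if s not in ann.index]
    if missing:
        raise ValueError(f"samples missing from annotation: {missing[:10]}")
    labels = ann.loc[sample_ids, "parity"].to_numpy()
    bad = sorted(set(labels) - set(PARITY_LEVELS))
    if bad:
        raise ValueError(f"invalid parity labels {bad}")
    return labels
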