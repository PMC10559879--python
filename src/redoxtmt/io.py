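"""Readers and writers for the pipeline's tabular formats.

All files are UTF-8 TSV without quoting; decimal point is "."; missing
values are empty cells.  Gene sets use the standard GMT dialect (set name,
description, tab-separated member symbols).
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from .model import (
    DESIGN_COLUMNS,
    PEPTIDE_META_COLUMNS,
    GeneSetCollection,
    PeptideTable,
    SampleDesign,
    SiteAnnotationTable,
    SiteId,
    ValidationError,
)

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.9g"


def _read_tsv(path: str, **kw) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, **kw)


def read_design(path: str) -> SampleDesign:
    """Read and validate a sample-design TSV.

    Raises :class:`ValidationError` for duplicate (mix, channel) pairs,
    redox samples missing their TMT1/TMT2 twin, unknown treatment/layer
    tokens, or an empty file.
    """
    frame = _read_tsv(path)
    if len(frame) == 0:
        raise ValidationError("no design rows")
    return SampleDesign(frame)


def read_peptide_table(path: str, design: SampleDesign) -> PeptideTable:
    """Read a peptide-isoform quantification TSV for one physical layer.

    Layout: the :data:`PEPTIDE_META_COLUMNS` followed by one intensity
    column per channel id.  Blank intensity cells become missing (NaN),
    never zero.  Hard errors: an intensity column with no design entry, a
    negative intensity, or an unparseable site id (reported with its row
    number).
    """
    raw = _read_tsv(path)
    missing = [c for c in PEPTIDE_META_COLUMNS if c not in raw.columns]
    if missing:
        raise ValidationError(f"peptide table {path} missing columns {missing}")
    channel_cols = [c for c in raw.columns if c not in PEPTIDE_META_COLUMNS]
    unknown = set(channel_cols) - set(design.channels)
    if unknown:
        raise ValidationError(
            f"intensity column(s) {sorted(unknown)} have no design entry"
        )
    frame = raw.copy()
    for ch in channel_cols:
        frame[ch] = pd.to_numeric(frame[ch].mask(frame[ch] == "", np.nan), errors="raise")
        neg = frame.index[frame[ch] < 0]
        if len(neg):
            raise ValidationError(
                f"negative intensity in column {ch}, data row {neg[0] + 1}"
            )
    for i, text in enumerate(frame["sites"]):
        for token in str(text).split(";"):
            if token:
                try:
                    SiteId.parse(token)
                except ValidationError as exc:
                    raise ValidationError(f"data row {i + 1}: {exc}") from exc
    # a row may only carry intensities for channels of its own mix
    mix_channels = {m: set(design.channels_of(m)) for m in design.mixes}
    unknown_mix = set(frame["mix_id"]) - set(mix_channels)
    if unknown_mix:
        raise ValidationError(f"mix id(s) {sorted(unknown_mix)} not in design")
    for mix, grp in frame.groupby("mix_id", sort=False):
        foreign = [c for c in channel_cols if c not in mix_channels[mix]]
        for c in foreign:
            if grp[c].notna().any():
                raise ValidationError(
                    f"mix {mix} has intensities in channel {c} "
                    "which is not part of that mix's design"
                )
    return PeptideTable(frame, channel_cols)


def write_table(result: pd.DataFrame, path: str) -> None:
    """Write a tabular result as TSV with deterministic column order.

    Floats are rendered at 9 significant digits, so write/read round-trips
    are exact to that precision.  An empty result produces a header-only
    file.
    """
    if len(result.columns) == 0:
        raise ValidationError("refusing to write a table with no columns")
    result.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`, inferring dtypes."""
    return pd.read_csv(path, sep="\t")


def write_design(design: SampleDesign, path: str) -> None:
    write_table(design.frame[DESIGN_COLUMNS], path)


def write_peptide_table(table: PeptideTable, path: str) -> None:
    write_table(table.frame, path)


def read_gmt(path: str, name: str | None = None) -> GeneSetCollection:
    """Read a GMT gene-set file (set name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path} line {i + 1}: GMT rows need name, description "
                    "and at least one member"
                )
            sets[parts[0]] = [m for m in parts[2:] if m]
    if not sets:
        raise ValidationError(f"no gene sets in {path}")
    return GeneSetCollection(name=name or os.path.basename(path), sets=sets)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_name, members in collection.sets.items():
            fh.write("\t".join([set_name, "na", *members]) + "\n")


def read_mapping(path: str) -> dict[str, str]:
    """Read a 2-column accession -> gene symbol TSV (with header)."""
    frame = _read_tsv(path)
    if frame.shape[1] < 2:
        raise ValidationError(f"mapping file {path} needs 2 columns")
    acc, sym = frame.columns[:2]
    return dict(zip(frame[acc], frame[sym]))


def write_mapping(mapping: dict[str, str], path: str) -> None:
    frame = pd.DataFrame(
        sorted(mapping.items()), columns=["protein_accession", "gene_symbol"]
    )
    write_table(frame, path)


def read_annotations(path: str) -> SiteAnnotationTable:
    return SiteAnnotationTable(_read_tsv(path).replace("", np.nan))


def write_annotations(ann: SiteAnnotationTable, path: str) -> None:
    write_table(ann.frame, path)
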