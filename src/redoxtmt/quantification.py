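"""Reporter-ion impurity correction and peptide-to-site rollup.

TMT reagents carry isotopic impurities: a fraction of each channel's true
signal is observed in neighbouring channels.  Vendors ship a correction
matrix; correction is the corresponding linear solve.  Site rollup turns
peptide-isoform intensities into modification-site intensities by summing
all isoforms that contain the site; a peptide carrying k sites contributes
its full intensity to each of them (no stoichiometric splitting — the data
do not resolve which cysteine of a two-cysteine peptide changed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    ANALYSIS_LAYERS,
    PEPTIDE_META_COLUMNS,
    SAMPLE_LEVELS,
    PeptideTable,
    SampleDesign,
    SiteQuantMatrix,
    ValidationError,
)

log = logging.getLogger(__name__)

_MAX_CONDITION = 1e12


@dataclass
class ImpurityMatrix:
    """Channel cross-contamination matrix.

    ``matrix[i, j]`` is the fraction of channel j's true signal observed in
    channel i, so observed = matrix @ true.  Columns must not over-account
    signal (column sums <= 1) and the matrix must be well conditioned for
    the correction solve to run.
    """

    channels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        k = len(self.channels)
        if m.shape != (k, k):
            raise ValidationError(f"impurity matrix must be {k}x{k}, got {m.shape}")
        if (m < 0).any():
            raise ValidationError("impurity matrix entries must be non-negative")
        if (np.diag(m) <= 0).any():
            raise ValidationError("impurity matrix diagonal must be positive")
        if (m.sum(axis=0) > 1 + 1e-6).any():
            raise ValidationError("impurity matrix column sums exceed 1")
        if np.linalg.cond(m) > _MAX_CONDITION:
            raise ValidationError("impurity matrix is ill-conditioned; refusing")
        self.matrix = m

    @classmethod
    def identity(cls, channels: Sequence[str]) -> "ImpurityMatrix":
        return cls(list(channels), np.eye(len(channels)))

    @classmethod
    def from_tsv(cls, path: str) -> "ImpurityMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        if list(frame.index) != list(frame.columns):
            raise ValidationError("impurity matrix row/column headers differ")
        return cls(list(frame.columns), frame.to_numpy(dtype=float))

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.matrix, index=self.channels, columns=self.channels).to_csv(
            path, sep="\t", float_format="%.9g"
        )

    def mix(self, true_values: np.ndarray) -> np.ndarray:
        """Forward mixing: rows of true channel vectors -> observed."""
        return np.asarray(true_values, dtype=float) @ self.matrix.T


def correct_impurities(table: PeptideTable, m: ImpurityMatrix) -> PeptideTable:
    """Invert reporter-ion isotope impurity mixing on a peptide table.

    Per record the observed vector o is replaced by the solution x of
    ``m @ x = o``, restricted to the record's observed channels (missing
    channels stay missing; their bleed-through is not modelled).  Negative
    solutions are clipped to 0 and counted in the log.
    """
    absent = [c for c in table.channels if c not in m.channels]
    if absent:
        raise ValidationError(f"channel(s) {absent} absent from impurity matrix")
    idx = [m.channels.index(c) for c in table.channels]
    values = table.frame[table.channels].to_numpy(dtype=float)
    observed = ~np.isnan(values)
    corrected = np.full_like(values, np.nan)
    n_clipped = 0
    # solve once per missingness pattern, vectorized over its rows
    patterns = {}
    for row, pat in enumerate(map(tuple, observed)):
        patterns.setdefault(pat, []).append(row)
    for pat, rows in patterns.items():
        cols = [i for i, obs in enumerate(pat) if obs]
        if not cols:
            continue
        sub = m.matrix[np.ix_([idx[i] for i in cols], [idx[i] for i in cols])]
        if np.linalg.cond(sub) > _MAX_CONDITION:
            raise ValidationError(
                f"singular impurity submatrix for record(s) starting at "
                f"data row {rows[0] + 1}"
            )
        sol = np.linalg.solve(sub, values[np.ix_(rows, cols)].T).T
        n_clipped += int((sol < 0).sum())
        np.clip(sol, 0.0, None, out=sol)
        corrected[np.ix_(rows, cols)] = sol
    if n_clipped:
        log.info("impurity correction clipped %d negative solutions to 0", n_clipped)
    frame = table.frame.copy()
    frame[table.channels] = corrected
    return PeptideTable(frame, table.channels)


def rollup_sites(
    table: PeptideTable, design: SampleDesign, layer: str
) -> SiteQuantMatrix:
    """Sum peptide-isoform intensities into entity intensities for one
    analysis layer.

    Entities are protein accessions for the proteome (all peptides of a
    protein are summed) and ``accession_site`` keys for the PTM layers.
    For the redoxome, ``ox_all`` reads only TMT1 (free-thiol) channels and
    ``ox_rev`` only TMT2 channels.  Missing channel values are skipped in
    the sum; an entity with no observed peptide in a sample stays missing.
    """
    if layer not in ANALYSIS_LAYERS:
        raise ValidationError(f"unknown analysis layer {layer!r}")
    rows = design.for_layer(layer)
    mix_set = set(rows["mix_id"])
    frame = table.frame
    in_layer = frame["mix_id"].isin(mix_set)
    n_skipped = int((~in_layer).sum())
    if n_skipped:
        log.info(
            "rollup %s: skipped %d records whose mix has no %s channels",
            layer, n_skipped, layer,
        )
    frame = frame[in_layer]
    if len(frame) == 0:
        raise ValidationError(f"no records for layer {layer}")

    long = frame.melt(
        id_vars=PEPTIDE_META_COLUMNS,
        value_vars=table.channels,
        var_name="channel_id",
        value_name="intensity",
    )
    long = long.merge(
        rows[["mix_id", "channel_id", *SAMPLE_LEVELS]],
        on=["mix_id", "channel_id"],
        how="inner",
    )
    if layer == "proteome":
        long["entity"] = long["protein_accession"]
    else:
        long = long[long["sites"] != ""]
        if len(long) == 0:
            raise ValidationError(f"no modified peptides for layer {layer}")
        long = long.assign(site=long["sites"].str.split(";")).explode("site")
        long["entity"] = long["protein_accession"] + "_" + long["site"]
    grouped = (
        long.groupby(["entity", *SAMPLE_LEVELS], sort=True)["intensity"]
        .sum(min_count=1)
    )
    matrix = grouped.unstack(SAMPLE_LEVELS)
    matrix.columns = pd.MultiIndex.from_tuples(matrix.columns, names=SAMPLE_LEVELS)
    matrix = matrix.sort_index(axis=1)
    return SiteQuantMatrix(layer=layer, values=matrix)
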