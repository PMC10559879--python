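"""Core data model for the multi-layer TMT experiment.

The experiment quantifies three omics layers from the same biological
samples: a proteome (protein abundance), a redoxome (sequential iodoTMT
labeling of cysteines: the TMT1 stage labels free thiols, the TMT2 stage
labels reversibly oxidized thiols after reduction) and a phosphoproteome.
Samples are multiplexed into TMT mixes; every treated (+LPS) sample shares
a mix with its paired untreated control, so all fold changes downstream are
mix-internal.

Analysis layers are ``proteome``, ``ox_all`` (overall oxidation, from TMT1
channels), ``ox_rev`` (reversible oxidation, from TMT2 channels) and
``phospho``.  Physical table layers (what a quant export contains) are
``proteome``, ``redoxome`` and ``phospho``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TABLE_LAYERS = ("proteome", "redoxome", "phospho")
ANALYSIS_LAYERS = ("proteome", "ox_all", "ox_rev", "phospho")
PTM_LAYERS = ("ox_all", "ox_rev", "phospho")
TREATMENTS = ("treated", "control")
LABEL_STAGES = ("TMT1", "TMT2", "NA")

#: analysis layer -> (physical table layer, label stage or None)
LAYER_SOURCE = {
    "proteome": ("proteome", None),
    "ox_all": ("redoxome", "TMT1"),
    "ox_rev": ("redoxome", "TMT2"),
    "phospho": ("phospho", None),
}

_SITE_RE = re.compile(r"^([CSTYM])(\d+)$")


class ValidationError(ValueError):
    """Raised when an input table violates a model invariant."""


@dataclass(frozen=True, order=True)
class SiteId:
    """A modification site on a protein's canonical sequence (1-based)."""

    residue: str
    position: int

    def __post_init__(self) -> None:
        if self.residue not in "CSTYM":
            raise ValidationError(f"invalid site residue {self.residue!r}")
        if self.position < 1:
            raise ValidationError(f"site position must be >= 1, got {self.position}")

    @classmethod
    def parse(cls, text: str) -> "SiteId":
        m = _SITE_RE.match(text.strip())
        if not m:
            raise ValidationError(f"unparseable site id {text!r}")
        return cls(m.group(1), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.residue}{self.position}"


def site_entity(accession: str, site: SiteId | str) -> str:
    """Entity key of a modification site, e.g. ``P10599_C32``."""
    return f"{accession}_{site}"


def split_site_entity(entity: str) -> tuple[str, str]:
    """Split ``P10599_C32`` into accession and site string."""
    acc, _, site = entity.rpartition("_")
    if not acc:
        raise ValidationError(f"not a site entity key: {entity!r}")
    return acc, site


DESIGN_COLUMNS = [
    "mix_id",
    "channel_id",
    "run",
    "replicate",
    "timepoint",
    "treatment",
    "label_stage",
    "layer",
]


class SampleDesign:
    """Maps every (mix, channel) to its biological sample.

    A biological sample is (run, replicate, timepoint, treatment); redoxome
    mixes additionally carry the label stage (TMT1 = free thiols, TMT2 =
    reversibly oxidized thiols), so each redox sample occupies two channels
    of its mix.
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = self._validate(frame)

    @staticmethod
    def _validate(frame: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in DESIGN_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"design is missing columns {missing}")
        if len(frame) == 0:
            raise ValidationError("no design rows")
        frame = frame[DESIGN_COLUMNS].copy()
        frame["run"] = frame["run"].astype(int)
        frame["replicate"] = frame["replicate"].astype(int)
        for col, allowed in [
            ("treatment", TREATMENTS),
            ("label_stage", LABEL_STAGES),
            ("layer", TABLE_LAYERS),
        ]:
            bad = set(frame[col]) - set(allowed)
            if bad:
                raise ValidationError(
                    f"unknown {col} token(s) {sorted(bad)}; allowed: {allowed}"
                )
        dup = frame.duplicated(["mix_id", "channel_id"])
        if dup.any():
            row = frame[dup].iloc[0]
            raise ValidationError(
                f"duplicate (mix, channel) pair ({row.mix_id}, {row.channel_id})"
            )
        redox = frame[frame["layer"] == "redoxome"]
        if len(redox):
            if (redox["label_stage"] == "NA").any():
                raise ValidationError("redoxome design rows must set label_stage")
            stages = redox.groupby(
                ["mix_id", "run", "replicate", "timepoint", "treatment"]
            )["label_stage"].agg(lambda s: tuple(sorted(s)))
            bad = stages[stages != ("TMT1", "TMT2")]
            if len(bad):
                key = bad.index[0]
                raise ValidationError(
                    f"redoxome sample {key} lacks its TMT1/TMT2 twin "
                    f"(found stages {bad.iloc[0]})"
                )
        nonredox = frame[frame["layer"] != "redoxome"]
        if len(nonredox) and (nonredox["label_stage"] != "NA").any():
            raise ValidationError("label_stage must be NA outside the redoxome layer")
        # mix-internal treated/control pairing per timepoint (and stage)
        pair_cols = ["mix_id", "timepoint", "label_stage"]
        pairing = frame.groupby(pair_cols)["treatment"].agg(set)
        unpaired = pairing[pairing.map(lambda s: s != {"treated", "control"})]
        if len(unpaired):
            key = unpaired.index[0]
            raise ValidationError(
                f"mix {key[0]} timepoint {key[1]}: treated/control pairing "
                f"incomplete (treatments present: {sorted(unpaired.iloc[0])})"
            )
        return frame.reset_index(drop=True)

    # -- convenience views -------------------------------------------------

    def channels_of(self, mix_id: str) -> list[str]:
        return self.frame.loc[self.frame["mix_id"] == mix_id, "channel_id"].tolist()

    @property
    def mixes(self) -> list[str]:
        return list(dict.fromkeys(self.frame["mix_id"]))

    @property
    def channels(self) -> list[str]:
        return list(dict.fromkeys(self.frame["channel_id"]))

    @property
    def timepoints(self) -> list[str]:
        return list(dict.fromkeys(self.frame["timepoint"]))

    def replicates(self) -> list[tuple[int, int]]:
        """Distinct global biological replicates as (run, replicate)."""
        reps = self.frame[["run", "replicate"]].drop_duplicates()
        return sorted(map(tuple, reps.to_numpy()))

    def for_layer(self, layer: str) -> pd.DataFrame:
        """Design rows feeding one analysis layer (stage-filtered for redox)."""
        if layer not in ANALYSIS_LAYERS:
            raise ValidationError(f"unknown analysis layer {layer!r}")
        table_layer, stage = LAYER_SOURCE[layer]
        rows = self.frame[self.frame["layer"] == table_layer]
        if stage is not None:
            rows = rows[rows["label_stage"] == stage]
        return rows

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleDesign) and self.frame.equals(other.frame)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class PeptideIsoformRecord:
    """One quantified peptide isoform in one TMT mix.

    ``channel_intensities`` maps channel id to a non-negative reporter-ion
    intensity; a channel absent from the map is *missing*, which is distinct
    from a measured zero.
    """

    mix_id: str
    protein_accession: str
    peptide_sequence: str
    sites: tuple[SiteId, ...]
    channel_intensities: dict[str, float]

    def __post_init__(self) -> None:
        for v in self.channel_intensities.values():
            if v < 0:
                raise ValidationError(
                    f"negative intensity {v} for peptide {self.peptide_sequence} "
                    f"in mix {self.mix_id}"
                )


PEPTIDE_META_COLUMNS = ["mix_id", "protein_accession", "peptide_sequence", "sites"]


class PeptideTable:
    """A layer's peptide-isoform quantification table.

    Wide frame: one row per (mix, peptide isoform); the metadata columns of
    :data:`PEPTIDE_META_COLUMNS` plus one float column per channel id, with
    NaN for missing intensities.  ``sites`` is the semicolon-joined site
    list ("" for proteome rows).
    """

    def __init__(self, frame: pd.DataFrame, channels: Sequence[str]):
        self.channels = list(channels)
        missing = [c for c in PEPTIDE_META_COLUMNS + self.channels if c not in frame.columns]
        if missing:
            raise ValidationError(f"peptide table missing columns {missing}")
        frame = frame[PEPTIDE_META_COLUMNS + self.channels].copy()
        frame["sites"] = frame["sites"].fillna("")
        vals = frame[self.channels].to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("negative reporter intensity in peptide table")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def to_records(self) -> list[PeptideIsoformRecord]:
        records = []
        for row in self.frame.itertuples(index=False):
            # itertuples mangles non-identifier column names; go positional
            vals = list(row)[len(PEPTIDE_META_COLUMNS):]
            intensities = {
                ch: float(v) for ch, v in zip(self.channels, vals) if pd.notna(v)
            }
            sites = tuple(
                SiteId.parse(s) for s in str(row.sites).split(";") if s
            )
            records.append(
                PeptideIsoformRecord(
                    mix_id=row.mix_id,
                    protein_accession=row.protein_accession,
                    peptide_sequence=row.peptide_sequence,
                    sites=sites,
                    channel_intensities=intensities,
                )
            )
        return records

    @classmethod
    def from_records(
        cls, records: Iterable[PeptideIsoformRecord], channels: Sequence[str]
    ) -> "PeptideTable":
        rows = []
        for r in records:
            row = {
                "mix_id": r.mix_id,
                "protein_accession": r.protein_accession,
                "peptide_sequence": r.peptide_sequence,
                "sites": ";".join(str(s) for s in r.sites),
            }
            for ch in channels:
                row[ch] = r.channel_intensities.get(ch, np.nan)
            rows.append(row)
        frame = pd.DataFrame(rows, columns=PEPTIDE_META_COLUMNS + list(channels))
        return cls(frame, channels)


SAMPLE_LEVELS = ["run", "replicate", "timepoint", "treatment"]


@dataclass
class SiteQuantMatrix:
    """Entity x sample intensity matrix for one analysis layer.

    ``values``: DataFrame indexed by entity key (accession for the proteome,
    ``accession_SiteId`` for PTM layers) with a 4-level column MultiIndex
    (run, replicate, timepoint, treatment).  NaN encodes missing.  For
    ``ox_all`` the values derive only from TMT1 channels, for ``ox_rev``
    only from TMT2; the layer tag carries that provenance so downstream
    contrasts never mix label stages.
    """

    layer: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.layer not in ANALYSIS_LAYERS:
            raise ValidationError(f"unknown analysis layer {self.layer!r}")
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate entity keys in quant matrix")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample keys in quant matrix")


@dataclass
class FoldChangeMatrix:
    """Replicate-level log2 fold changes (treated vs control) for one layer
    and time point.

    ``values``: DataFrame entity x (run, replicate) of log2 ratios, NaN
    where either side of the mix-internal pair was missing or zero.  The
    provenance flags record which normalization steps have been applied;
    ``invert_overall_oxidation`` refuses to run twice while they are
    enforced.
    """

    layer: str
    timepoint: str
    values: pd.DataFrame
    median_normalized: bool = False
    protein_normalized: bool = False
    inverted: bool = False

    def copy_with(self, values: pd.DataFrame, **flags) -> "FoldChangeMatrix":
        state = dict(
            layer=self.layer,
            timepoint=self.timepoint,
            median_normalized=self.median_normalized,
            protein_normalized=self.protein_normalized,
            inverted=self.inverted,
        )
        state.update(flags)
        return FoldChangeMatrix(values=values, **state)


DIFFERENTIAL_COLUMNS = [
    "entity",
    "layer",
    "timepoint",
    "n",
    "log2fc_mean",
    "t_stat",
    "p",
    "fdr",
    "significant",
    "direction",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) plus an accession -> gene symbol map."""

    name: str
    sets: dict[str, list[str]]
    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for set_name, members in self.sets.items():
            dedup = list(dict.fromkeys(members))
            if not dedup:
                raise ValidationError(f"gene set {set_name!r} is empty")
            clean[set_name] = dedup
        self.sets = clean


ANNOTATION_KINDS = ("known_modified", "disulfide_partner")


class SiteAnnotationTable:
    """Known cysteine modifications / disulfide partners for sites.

    Columns: protein_accession, site, annotation, partner.  A
    ``disulfide_partner`` row carries the partner site; a ``known_modified``
    row does not.
    """

    COLUMNS = ["protein_accession", "site", "annotation", "partner"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"annotation table missing columns {missing}")
        frame = frame[self.COLUMNS].copy()
        frame["partner"] = frame["partner"].fillna("")
        for row in frame.itertuples(index=False):
            SiteId.parse(row.site)
            if row.annotation not in ANNOTATION_KINDS:
                raise ValidationError(f"unknown annotation kind {row.annotation!r}")
            if row.annotation == "disulfide_partner":
                if not row.partner:
                    raise ValidationError(
                        f"disulfide_partner row for {row.protein_accession} "
                        f"{row.site} lacks a partner site"
                    )
                SiteId.parse(row.partner)
            elif row.partner:
                raise ValidationError(
                    f"known_modified row for {row.protein_accession} {row.site} "
                    "must not carry a partner"
                )
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)
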