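"""Join differential oxidation sites against known-site annotations.

The annotation table is a user-exported flat file (e.g. from UniProtKB)
listing cysteines known to be modified and disulfide-bond partners; the
join lets the analyst see which significantly altered oxidation sites are
already described and which are novel.
"""

from __future__ import annotations

import pandas as pd

from .model import SiteAnnotationTable, ValidationError, split_site_entity


def annotate_sites(res: pd.DataFrame, ann: SiteAnnotationTable) -> pd.DataFrame:
    """Left-join an oxidation differential result with site annotations.

    Lossless on ``res`` (row count preserved).  Sites absent from the
    annotation table get ``known_modified = False`` and no partner.
    """
    layers = set(res["layer"])
    if not layers <= {"ox_all", "ox_rev"}:
        raise ValidationError(
            f"annotate_sites expects oxidation layers, got {sorted(layers)}"
        )
    parts = [split_site_entity(e) for e in res["entity"]]
    keyed = res.copy()
    keyed["protein_accession"] = [p[0] for p in parts]
    keyed["site"] = [p[1] for p in parts]
    ann_frame = ann.frame.copy()
    ann_frame["known_modified"] = True
    ann_frame = (
        ann_frame.sort_values("annotation", kind="mergesort")
        .drop_duplicates(["protein_accession", "site"], keep="first")  # disulfide rows win
    )
    out = keyed.merge(
        ann_frame[["protein_accession", "site", "known_modified", "partner"]],
        on=["protein_accession", "site"],
        how="left",
    )
    out["known_modified"] = out["known_modified"].notna() & out["known_modified"].eq(True)
    out = out.rename(columns={"partner": "disulfide_partner"})
    out["disulfide_partner"] = out["disulfide_partner"].fillna("")
    return out
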