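"""Cross-timepoint dynamics and multiply-modified-protein overlap.

Compares each entity's mean log2 fold change between the early (4 h) and
late (24 h) LPS contrasts: Pearson correlation with its t-transform
significance and a least-squares trendline, separately for entities
significant at >= 1 time point and for unaffected entities.  The overlap
analysis classifies proteins by which layers (protein level, oxidation,
phosphorylation) carry significant changes; a "multiply modified" protein
has both a significant oxidation site and a significant phosphorylation
site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import ValidationError, split_site_entity

VENN_CLASSES = [
    "protein",
    "ox",
    "phospho",
    "protein+ox",
    "protein+phospho",
    "ox+phospho",
    "protein+ox+phospho",
]


@dataclass
class DynamicsResult:
    """Pearson correlation of an entity subset between two time points."""

    layer: str
    subset: str
    n: int
    r: float
    p: float
    slope: float
    intercept: float
    computable: bool = True


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """r, p (two-sided, t transform with df = n-2), slope, intercept."""
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    if sxx == 0 or syy == 0:
        raise ValidationError("zero variance on one axis; correlation undefined")
    r = sxy / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    return r, p, float(slope), intercept


def correlate_timepoints(
    res_early: pd.DataFrame,
    res_late: pd.DataFrame,
    subset: str = "significant",
    significant_rule: str = "either",
) -> DynamicsResult:
    """Correlate mean log2FCs between the two time points.

    ``subset`` is "significant" (entities significant at >= 1 time point,
    or at both with ``significant_rule='both'``) or "not_affected"
    (significant at neither).  Fewer than 3 shared entities yields a
    not-computable result.
    """
    layers = set(res_early["layer"]) | set(res_late["layer"])
    if len(layers) != 1:
        raise ValidationError(f"results must share one layer, got {sorted(layers)}")
    layer = layers.pop()
    if subset not in ("significant", "not_affected"):
        raise ValidationError(f"unknown subset {subset!r}")
    if significant_rule not in ("either", "both"):
        raise ValidationError(f"unknown significant_rule {significant_rule!r}")
    early = res_early.set_index("entity")
    late = res_late.set_index("entity")
    shared = early.index.intersection(late.index)
    sig_e = early.loc[shared, "significant"].to_numpy(dtype=bool)
    sig_l = late.loc[shared, "significant"].to_numpy(dtype=bool)
    if subset == "significant":
        mask = (sig_e | sig_l) if significant_rule == "either" else (sig_e & sig_l)
    else:
        mask = ~(sig_e | sig_l)
    x = early.loc[shared, "log2fc_mean"].to_numpy(dtype=float)[mask]
    y = late.loc[shared, "log2fc_mean"].to_numpy(dtype=float)[mask]
    if x.size < 3:
        return DynamicsResult(
            layer=layer, subset=subset, n=int(x.size),
            r=np.nan, p=np.nan, slope=np.nan, intercept=np.nan, computable=False,
        )
    r, p, slope, intercept = _pearson(x, y)
    return DynamicsResult(
        layer=layer, subset=subset, n=int(x.size),
        r=r, p=p, slope=slope, intercept=intercept,
    )


def dynamics_table(results: list[DynamicsResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "layer": d.layer,
                "subset": d.subset,
                "n": d.n,
                "r": d.r,
                "p": d.p,
                "slope": d.slope,
                "intercept": d.intercept,
                "computable": d.computable,
            }
            for d in results
        ]
    )


def _significant_proteins(res: pd.DataFrame, site_level: bool) -> set[str]:
    sig = res.loc[res["significant"], "entity"]
    if site_level:
        return {split_site_entity(e)[0] for e in sig}
    return set(sig)


def overlap_multiply_modified(
    prot: pd.DataFrame, ox: pd.DataFrame, phos: pd.DataFrame
) -> pd.DataFrame:
    """Per-protein significance flags across the three layers.

    ``ox`` is the concatenation of the ox_all and ox_rev differential
    results (a protein counts as oxidation-significant if any site in
    either redox readout is significant).  Returns one row per protein in
    the union of significant proteins with the three membership flags, the
    Venn class label and the multiply-modified call (significant oxidation
    AND phosphorylation sites).
    """
    sig_prot = _significant_proteins(prot, site_level=False)
    sig_ox = _significant_proteins(ox, site_level=True)
    sig_phos = _significant_proteins(phos, site_level=True)
    union = sorted(sig_prot | sig_ox | sig_phos)
    rows = []
    for protein in union:
        flags = (protein in sig_prot, protein in sig_ox, protein in sig_phos)
        label = "+".join(
            name for name, f in zip(("protein", "ox", "phospho"), flags) if f
        )
        rows.append(
            {
                "protein": protein,
                "sig_protein": flags[0],
                "sig_ox": flags[1],
                "sig_phospho": flags[2],
                "venn_class": label,
                "multiply_modified": flags[1] and flags[2],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein",
            "sig_protein",
            "sig_ox",
            "sig_phospho",
            "venn_class",
            "multiply_modified",
        ],
    )


def venn_counts(overlap: pd.DataFrame) -> pd.DataFrame:
    """Counts of the 7 non-empty Venn classes (they partition the union)."""
    counts = overlap["venn_class"].value_counts() if len(overlap) else {}
    return pd.DataFrame(
        [{"venn_class": c, "count": int(counts.get(c, 0))} for c in VENN_CLASSES]
    )
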