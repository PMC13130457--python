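"""Three-contrast classification of differentially expressed genes.

A gene is observed in three contrasts: DEN (denervated vs innervated,
control muscle), SH_IN (knockdown vs control, innervated) and SH_DE
(knockdown vs control, denervated).  A contrast is "DE" when the linear
fold change is at least ``fc_thresh`` up or down (|log2fc| >= log2(1.5),
boundary inclusive) with p strictly below 0.05.  The DE flag pattern plus
the signs of the log2 fold changes partition the genes into
activity-independent (AIN: knockdown effect without a denervation
effect) and activity-dependent (AD) classes, the latter subdivided by
the condition showing the knockdown effect (In / De / InDe) and by
whether the knockdown effect agrees in sign with the denervation effect
(pos / neg), or, when both knockdown contrasts respond, whether the two
knockdown effects agree with each other (AD_InDe vs AD_InDe_inverse).

This module consumes (log2fc, p) triples from any upstream DE fit; no
count modeling or multiple-testing correction is performed here (the
filter operates on raw p-values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UnresolvedSignError, ValidationError
from .synthetic import DEG_CLASSES

__all__ = [
    "CONTRASTS",
    "GeneClassAssignment",
    "flag_de",
    "classify_gene",
    "classify_table",
    "zscore_matrix",
    "venn_region",
]

CONTRASTS = ("DEN", "SH_IN", "SH_DE")

VENN_REGIONS = (
    "DEN_only",
    "SH_IN_only",
    "SH_DE_only",
    "DEN_SH_IN",
    "DEN_SH_DE",
    "SH_IN_SH_DE",
    "DEN_SH_IN_SH_DE",
)


@dataclass(frozen=True)
class GeneClassAssignment:
    """One gene's DE flags and assigned class."""

    gene: str
    de_den: bool
    de_sh_in: bool
    de_sh_de: bool
    gene_class: str
    sign_unresolved: bool = False

    def __post_init__(self):
        if self.gene_class not in DEG_CLASSES:
            raise ValidationError(f"unknown class {self.gene_class!r}")


def flag_de(
    log2fc: float, p: float, fc_thresh: float = 1.5, p_thresh: float = 0.05
) -> bool:
    """DE filter: |log2fc| >= log2(fc_thresh) (inclusive) and p < p_thresh (strict)."""
    if not 0 <= p <= 1:
        raise ValidationError(f"p-value must be in [0, 1], got {p}")
    if fc_thresh <= 1:
        raise ValidationError("fc_thresh must exceed 1")
    if not 0 < p_thresh <= 1:
        raise ValidationError("p_thresh must be in (0, 1]")
    return bool(abs(log2fc) >= math.log2(fc_thresh) and p < p_thresh)


def _sign(x: float, contrast: str, gene: str) -> float:
    if x == 0:
        raise UnresolvedSignError(
            f"gene {gene}: zero log2fc on sign-determining contrast {contrast}"
        )
    return math.copysign(1.0, x)


def classify_gene(
    record: pd.Series | dict,
    fc_thresh: float = 1.5,
    p_thresh: float = 0.05,
) -> GeneClassAssignment:
    """Assign one gene to its class from its three-contrast statistics.

    ``record`` must carry ``gene`` plus ``log2fc_<c>`` / ``p_<c>`` for each
    contrast.  With D/I/E the DE flags of DEN / SH_IN / SH_DE:

    * no flags at all -> ``none``; D only -> ``AD_untouched``
    * not D with knockdown effects -> ``AIN_InDe`` / ``AIN_In`` / ``AIN_De``
    * D and I only -> ``AD_In_pos``/``AD_In_neg`` by sign agreement of
      SH_IN with DEN; D and E only -> ``AD_De_pos``/``AD_De_neg`` likewise
    * all three -> ``AD_InDe``, or ``AD_InDe_inverse`` when the two
      knockdown effects have opposite signs.

    A zero fold change on a contrast whose sign the class depends on
    raises :class:`UnresolvedSignError` (unreachable for genes that pass
    the DE filter, since the filter requires a nonzero fold change).
    """
    rec = dict(record)
    gene = str(rec["gene"])
    d = flag_de(rec["log2fc_DEN"], rec["p_DEN"], fc_thresh, p_thresh)
    i = flag_de(rec["log2fc_SH_IN"], rec["p_SH_IN"], fc_thresh, p_thresh)
    e = flag_de(rec["log2fc_SH_DE"], rec["p_SH_DE"], fc_thresh, p_thresh)

    cls = "none"
    unresolved = False
    try:
        if not d:
            if i and e:
                cls = "AIN_InDe"
            elif i:
                cls = "AIN_In"
            elif e:
                cls = "AIN_De"
        elif i and e:
            same = _sign(rec["log2fc_SH_IN"], "SH_IN", gene) == _sign(
                rec["log2fc_SH_DE"], "SH_DE", gene
            )
            cls = "AD_InDe" if same else "AD_InDe_inverse"
        elif i:
            same = _sign(rec["log2fc_SH_IN"], "SH_IN", gene) == _sign(
                rec["log2fc_DEN"], "DEN", gene
            )
            cls = "AD_In_pos" if same else "AD_In_neg"
        elif e:
            same = _sign(rec["log2fc_SH_DE"], "SH_DE", gene) == _sign(
                rec["log2fc_DEN"], "DEN", gene
            )
            cls = "AD_De_pos" if same else "AD_De_neg"
        else:
            cls = "AD_untouched"
    except UnresolvedSignError:
        cls, unresolved = "none", True

    return GeneClassAssignment(gene, d, i, e, cls, unresolved)


def venn_region(d: bool, i: bool, e: bool) -> str | None:
    """Name of the Venn region for a DE flag triple (None if no flag)."""
    members = [name for name, flag in zip(CONTRASTS, (d, i, e)) if flag]
    if not members:
        return None
    return "_".join(members) + ("_only" if len(members) == 1 else "")


def classify_table(
    records: pd.DataFrame,
    fc_thresh: float = 1.5,
    p_thresh: float = 0.05,
) -> tuple[pd.DataFrame, dict, dict]:
    """Classify every gene; return assignments, class counts and Venn counts.

    Returns ``(assignments, class_counts, summary)`` where ``summary``
    holds the 7 Venn region counts of the three DE sets plus, per
    knockdown contrast, the fraction of its DE genes that are
    up-regulated (log2fc > 0).
    """
    if records["gene"].duplicated().any():
        dupes = records.loc[records["gene"].duplicated(), "gene"].unique()
        raise ValidationError(f"duplicate gene id(s): {list(dupes[:5])}")

    assignments = [
        classify_gene(row, fc_thresh, p_thresh) for _, row in records.iterrows()
    ]
    out = pd.DataFrame(
        [
            {
                "gene": a.gene,
                "de_DEN": a.de_den,
                "de_SH_IN": a.de_sh_in,
                "de_SH_DE": a.de_sh_de,
                "gene_class": a.gene_class,
                "sign_unresolved": a.sign_unresolved,
            }
            for a in assignments
        ],
        columns=[
            "gene", "de_DEN", "de_SH_IN", "de_SH_DE", "gene_class", "sign_unresolved",
        ],
    )

    class_counts = {cls: 0 for cls in DEG_CLASSES}
    for a in assignments:
        class_counts[a.gene_class] += 1

    venn = {region: 0 for region in VENN_REGIONS}
    for a in assignments:
        region = venn_region(a.de_den, a.de_sh_in, a.de_sh_de)
        if region is not None:
            venn[region] += 1

    summary = {"venn": venn}
    for contrast in ("SH_IN", "SH_DE"):
        de = out[f"de_{contrast}"].to_numpy()
        if de.any():
            fc = records[f"log2fc_{contrast}"].to_numpy()[de]
            summary[f"up_fraction_{contrast}"] = float(np.mean(fc > 0))
        else:
            summary[f"up_fraction_{contrast}"] = float("nan")
    return out, class_counts, summary


def zscore_matrix(
    records: pd.DataFrame, gene_list
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene z-scores of log2 fold change across the three contrasts.

    Population-SD convention: z = (x - row mean) / row SD with ddof=0.
    Rows with zero variance become all-zero and are returned in the
    flagged list.  Unknown genes raise a lookup error.
    """
    genes = list(gene_list)
    table = records.set_index("gene")
    missing = [g for g in genes if g not in table.index]
    if missing:
        raise KeyError(f"gene(s) not in table: {missing[:5]}")
    fc = table.loc[genes, [f"log2fc_{c}" for c in CONTRASTS]].to_numpy(dtype=float)
    mean = fc.mean(axis=1, keepdims=True)
    sd = fc.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    z = (fc - mean) / sd
    z[constant] = 0.0
    out = pd.DataFrame(z, index=pd.Index(genes, name="gene"), columns=list(CONTRASTS))
    return out, [g for g, c in zip(genes, constant) if c]
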