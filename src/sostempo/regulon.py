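"""SOS regulon calling and early/late temporal classification.

A gene enters the regulon when it satisfies three expression criteria plus a
binding requirement: (1) induced in wild type under damage at 40 min,
(2) derepressed in the repressor-deletion strain without damage, (3) its
damage induction is RecA-dependent (not induced in the *recA* deletion under
damage), and (4) the repressor binds its promoter (ChIP).  Member genes are
collapsed to transcription units, and each TU's promoter is classified early
(induced by 20 min) or late (induced only at 40 min).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .annotation import Annotation


def call_sos_regulon(
    de_wt40: pd.DataFrame,
    de_dlexa: pd.DataFrame,
    de_dreca40: pd.DataFrame,
    lexa_bound,
    overrides: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Evaluate the three criteria plus binding for every gene.

    ``lexa_bound`` is the set of genes with a repressor ChIP peak at their
    promoter.  ``overrides`` maps gene id -> reason and forces the
    derepression criterion true (e.g. genes deleted in the repressor-deletion
    strain, whose coverage there is degenerate).  Returns a per-gene table
    with the criteria vector, membership, and any override reason.
    """
    overrides = overrides or {}
    idx = de_wt40.index
    for name, de in (("derepression", de_dlexa), ("recA-dependence", de_dreca40)):
        if set(de.index) != set(idx):
            only_a = sorted(set(idx) - set(de.index))[:10]
            only_b = sorted(set(de.index) - set(idx))[:10]
            raise ValueError(
                f"gene universes differ between contrasts ({name}): "
                f"missing {only_a}, extra {only_b}"
            )
    bound = set(lexa_bound)
    c1 = de_wt40["induced"].astype(bool)
    c2 = de_dlexa.loc[idx, "induced"].astype(bool).copy()
    reason = pd.Series([None] * len(idx), index=idx, dtype=object)
    for gid, why in overrides.items():
        if gid in c2.index:
            c2.loc[gid] = True
            reason.loc[gid] = why
    c3 = ~de_dreca40.loc[idx, "induced"].astype(bool)
    lb = pd.Series([g in bound for g in idx], index=idx)
    member = c1 & c2 & c3 & lb
    return pd.DataFrame(
        {
            "c1_induced_wt40": c1,
            "c2_derepressed_dlexa": c2,
            "c3_recA_dependent": c3,
            "lexa_bound": lb,
            "member": member,
            "override_reason": reason,
        }
    )


def collapse_to_tus(calls: pd.DataFrame, annotation: Annotation) -> pd.DataFrame:
    """One record per TU containing at least one member gene.

    The promoter gene is the TU's first gene in the direction of
    transcription (promoter-proximal operator placement).  Raises on TUs
    with genes on both strands.
    """
    members = calls.index[calls["member"]]
    tus = annotation.tus()
    by_tu: dict[str, list[str]] = {}
    for gid in members:
        by_tu.setdefault(annotation.get(gid).tu_id, []).append(gid)
    rows = []
    for tu_id, mem in sorted(by_tu.items()):
        promoter = tus[tu_id][0].gene_id
        rows.append(
            {
                "tu_id": tu_id,
                "promoter_gene": promoter,
                "member_genes": ",".join(sorted(mem)),
                "n_members": len(mem),
            }
        )
    return pd.DataFrame(rows, columns=["tu_id", "promoter_gene", "member_genes",
                                       "n_members"]).set_index("tu_id")


def classify_temporal(
    tus: pd.DataFrame,
    de_wt20: pd.DataFrame,
    de_wt40: pd.DataFrame,
) -> pd.DataFrame:
    """Label each member TU early (induced at 20 min) or late (40 min only).

    Induction of any member gene counts for the TU.  TUs induced at neither
    timepoint are excluded with a warning.
    """
    rows = []
    for tu_id, rec in tus.iterrows():
        genes = rec["member_genes"].split(",")
        at20 = any(bool(de_wt20.loc[g, "induced"]) for g in genes if g in de_wt20.index)
        at40 = any(bool(de_wt40.loc[g, "induced"]) for g in genes if g in de_wt40.index)
        if at20:
            cls, first = "early", 20
        elif at40:
            cls, first = "late", 40
        else:
            warnings.warn(
                f"TU {tu_id} is a member but induced at neither timepoint; excluded"
            )
            continue
        rows.append(
            {
                "tu_id": tu_id,
                "promoter_gene": rec["promoter_gene"],
                "temporal_class": cls,
                "first_induced_timepoint": first,
            }
        )
    return pd.DataFrame(
        rows, columns=["tu_id", "promoter_gene", "temporal_class",
                       "first_induced_timepoint"]
    ).set_index("tu_id")
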