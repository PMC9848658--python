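"""Horizontal-gene-transfer candidate screening from homology hit tables.

Each query gene carries a set of protein-homology hits (subject, taxon
label, bit score, E-value).  Hits are classified into taxonomic groups
(plant, archaea, bacteria, fungi, virus, metazoan, other), the recipient's
own lineage is excluded, and two per-query indices contrast the best
in-group hit with the best out-group hit:

* alien index  AI = ln(E_ingroup + ε) − ln(E_outgroup + ε), ε = 1e-200 —
  large positive AI means the query is far closer to out-group sequences;
* h index      h = bit_outgroup − bit_ingroup, the bit-score analogue.

A query is an HGT candidate only when both indices agree (AI ≥ 45 and
h ≥ 30 by default); the putative donor is the group of the best out-group
hit.  A GC-content flag marks candidates whose composition departs from the
genome background, a classic secondary signature of foreign DNA.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: closed taxon-group vocabulary
GROUPS = ("plant", "archaea", "bacteria", "fungi", "virus", "metazoan", "other")

#: pseudo-count keeping log E-values finite
AI_EPSILON = 1e-200


@dataclass
class TaxonomyMap:
    """Maps subject taxonomy labels/lineages to taxon groups.

    ``mapping`` keys are matched as case-insensitive substrings of the hit's
    taxon label (so a lineage string containing "Viruses" maps to ``virus``);
    unmatched labels fall through to ``other``.  ``self_patterns`` name the
    recipient's own taxa — matching hits are discarded before scoring.
    ``fold_metazoan`` collapses the metazoan bucket into ``other`` for the
    stricter six-group vocabulary.
    """

    mapping: Mapping[str, str]
    ingroup: str = "plant"
    self_patterns: tuple[str, ...] = ()
    fold_metazoan: bool = False

    def __post_init__(self) -> None:
        for grp in self.mapping.values():
            if grp not in GROUPS:
                raise ValueError(f"unknown taxon group {grp!r}")
        if self.ingroup not in GROUPS:
            raise ValueError(f"unknown ingroup {self.ingroup!r}")

    def group_for(self, label: str) -> str:
        low = label.lower()
        for key, grp in self.mapping.items():
            if key.lower() in low:
                return "other" if (self.fold_metazoan and grp == "metazoan") else grp
        return "other"

    def is_self(self, label: str) -> bool:
        low = label.lower()
        return any(p.lower() in low for p in self.self_patterns)


#: default lineage keywords for synthetic and NCBI-style labels
DEFAULT_TAXONOMY = TaxonomyMap(mapping={
    "viridiplantae": "plant", "plant": "plant",
    "archaea": "archaea",
    "bacteria": "bacteria",
    "fungi": "fungi",
    "virus": "virus", "viruses": "virus",
    "metazoa": "metazoan", "metazoan": "metazoan",
})


@dataclass
class HGTThresholds:
    """Consensus thresholds: a candidate needs both AI and h above cutoff."""

    ai: float = 45.0
    h: float = 30.0
    missing_ingroup_evalue: float = 1.0
    missing_ingroup_bitscore: float = 0.0
    gc_delta: float = 0.10


def read_hit_table(path, *, columns: Sequence[str] = ("query", "subject", "taxon",
                                                      "bitscore", "evalue")
                   ) -> pd.DataFrame:
    """Read a tab-separated homology hit table.

    The default layout is five named columns; tables with more columns (for
    example 12-column tabular alignment output plus a taxon column) can be
    handled by passing the column names in file order — only the five
    canonical names are kept.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=list(columns),
                     comment="#")
    need = {"query", "subject", "taxon", "bitscore", "evalue"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"hit table lacks columns: {sorted(missing)}")
    return df[["query", "subject", "taxon", "bitscore", "evalue"]]


def assign_groups(hits: pd.DataFrame, taxmap: TaxonomyMap | None = None
                  ) -> pd.DataFrame:
    """Label every hit with its taxon group; drop self-hits."""
    taxmap = taxmap or DEFAULT_TAXONOMY
    labels = hits["taxon"].astype(str)
    is_self = labels.map(taxmap.is_self)
    n_self = int(is_self.sum())
    if n_self:
        logger.info("assign_groups: dropped %d self-lineage hits", n_self)
    out = hits.loc[~is_self].copy()
    out["group"] = out["taxon"].astype(str).map(taxmap.group_for)
    return out


def best_hits(hits: pd.DataFrame, *, truncate_top: int | None = None
              ) -> pd.DataFrame:
    """Per-query, per-group extrema: minimum E-value and maximum bit score.

    ``truncate_top`` optionally restricts each query to its N
    smallest-E-value hits before taking extrema.
    """
    df = hits
    if truncate_top is not None:
        df = (df.sort_values(["query", "evalue"], kind="stable")
                .groupby("query", sort=False).head(truncate_top))
    if df.empty:
        return pd.DataFrame(columns=["query", "group", "evalue", "bitscore"])
    agg = (df.groupby(["query", "group"], sort=False)
             .agg(evalue=("evalue", "min"), bitscore=("bitscore", "max"))
             .reset_index())
    return agg


def alien_index(best_ingroup_evalue: float | None,
                best_outgroup_evalue: float,
                *, epsilon: float = AI_EPSILON,
                missing_ingroup_evalue: float = 1.0) -> float:
    """AI = ln(E_in + ε) − ln(E_out + ε); absent in-group hits count as E=1."""
    e_in = (missing_ingroup_evalue if best_ingroup_evalue is None
            else best_ingroup_evalue)
    return math.log(e_in + epsilon) - math.log(best_outgroup_evalue + epsilon)


def h_index(best_ingroup_bitscore: float | None,
            best_outgroup_bitscore: float,
            *, missing_ingroup_bitscore: float = 0.0) -> float:
    """h = best out-group bit score − best in-group bit score."""
    b_in = (missing_ingroup_bitscore if best_ingroup_bitscore is None
            else best_ingroup_bitscore)
    return best_outgroup_bitscore - b_in


def call_hgt(ai: float, h: float, thresholds: HGTThresholds | None = None
             ) -> bool:
    """Candidate iff both indices reach their cutoff (the consensus rule)."""
    t = thresholds or HGTThresholds()
    return ai >= t.ai and h >= t.h


def gc_content(sequence: str) -> float:
    """G+C fraction over unambiguous bases; NaN if none."""
    seq = sequence.upper()
    gc = sum(seq.count(b) for b in "GC")
    at = sum(seq.count(b) for b in "AT")
    if gc + at == 0:
        return math.nan
    return gc / (gc + at)


def gc_flag(gene_gc: float, background_gc: float, delta: float = 0.10) -> bool:
    """Flag a gene whose GC exceeds the genome background by ≥ delta."""
    return gene_gc - background_gc >= delta


def screen(hits: pd.DataFrame, taxmap: TaxonomyMap | None = None, *,
           sequences: Mapping[str, str] | None = None,
           background_gc: float | None = None,
           thresholds: HGTThresholds | None = None,
           truncate_top: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Run the full HGT screen over a hit table.

    Returns a per-query call table (best in/out-group E-values and bit
    scores, AI, h, donor group, candidate flag, optional GC columns) plus a
    summary dict with candidate counts and the taxonomic distribution of
    best hits across all queries.
    """
    taxmap = taxmap or DEFAULT_TAXONOMY
    thresholds = thresholds or HGTThresholds()
    labeled = assign_groups(hits, taxmap)
    extrema = best_hits(labeled, truncate_top=truncate_top)

    rows = []
    best_hit_groups: dict[str, int] = {}
    for query, grp_df in extrema.groupby("query", sort=False):
        ing = grp_df[grp_df["group"] == taxmap.ingroup]
        outg = grp_df[grp_df["group"] != taxmap.ingroup]
        top = grp_df.loc[grp_df["bitscore"].idxmax()]
        best_hit_groups[top["group"]] = best_hit_groups.get(top["group"], 0) + 1
        if outg.empty:
            continue  # nothing to contrast against
        e_in = float(ing["evalue"].min()) if not ing.empty else None
        b_in = float(ing["bitscore"].max()) if not ing.empty else None
        donor_row = outg.loc[outg["bitscore"].idxmax()]
        e_out = float(outg["evalue"].min())
        b_out = float(donor_row["bitscore"])
        ai = alien_index(e_in, e_out,
                         missing_ingroup_evalue=thresholds.missing_ingroup_evalue)
        h = h_index(b_in, b_out,
                    missing_ingroup_bitscore=thresholds.missing_ingroup_bitscore)
        row = {
            "query": query,
            "best_ingroup_evalue": math.nan if e_in is None else e_in,
            "best_outgroup_evalue": e_out,
            "best_ingroup_bitscore": math.nan if b_in is None else b_in,
            "best_outgroup_bitscore": b_out,
            "AI": ai,
            "h": h,
            "donor_group": donor_row["group"],
            "is_candidate": call_hgt(ai, h, thresholds),
        }
        if sequences is not None and query in sequences:
            gc = gc_content(sequences[query])
            row["gc_content"] = gc
            if background_gc is not None:
                row["gc_flag"] = gc_flag(gc, background_gc, thresholds.gc_delta)
        rows.append(row)

    calls = pd.DataFrame(rows)
    n_candidates = int(calls["is_candidate"].sum()) if len(calls) else 0
    summary = {
        "n_queries": int(hits["query"].nunique()),
        "n_scored": len(calls),
        "n_candidates": n_candidates,
        "candidates": (calls.loc[calls["is_candidate"], "query"].tolist()
                       if len(calls) else []),
        "donor_groups": (calls.loc[calls["is_candidate"], "donor_group"]
                         .value_counts().to_dict() if len(calls) else {}),
        "best_hit_group_distribution": best_hit_groups,
    }
    return calls, summary


def write_screen(calls: pd.DataFrame, summary: dict, out_tsv, out_json) -> None:
    calls.to_csv(out_tsv, sep="\t", index=False)
    with open(out_json, "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
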