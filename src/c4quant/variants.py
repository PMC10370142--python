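"""The overall C4 SNP table: allele calls, copy estimates, consequences.

Positions below the minimum depth (6 for WGS, 20 for targeted data) are
no-calls.  At called positions an allele is reported when its depth ratio
reaches 0.5 normalised by the overall gene copy number — i.e. at least
half of one copy's expected share, so a variant on one of four copies
(ratio 0.25) is detectable.  Allele copy is the ratio times the overall
copy, rounded.  Exonic substitutions are annotated as synonymous or
non-synonymous (p.<ref><aa></alt> with signal-peptide-inclusive
numbering); single-base indel alleles are frameshifts (the premature
termination class).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .copynum import MIN_DEPTH, round_half_away
from .depth import COLUMNS, DepthTable
from .genemodel import GeneModel, translate_codon
from .reference import AlignmentReference

__all__ = [
    "call_snps",
    "annotate_consequence",
    "summarize_cohort",
    "CohortSummary",
]

SNP_COLUMNS = [
    "pos", "feature_coord", "region", "ref", "allele", "allele_depth",
    "total_depth", "ratio", "copy", "non_ref", "consequence", "hgvs_p",
]


def annotate_consequence(
    pos: int,
    allele: str,
    model: GeneModel,
    ref: AlignmentReference,
) -> tuple:
    """(consequence, p-label) of an allele at a 1-based overall position.

    Substitutions in exons are synonymous or non-synonymous; ``del``/``ins``
    alleles in exons are frameshifts.  Non-exonic alleles are non-coding.
    """
    cds = model.cds_of_absolute(pos)
    if cds is None:
        return "non-coding", None
    if allele in ("del", "ins"):
        return "frameshift", None
    aa_pos = model.aa_of_cds(cds)
    lo, hi = model.codon_cds_span(aa_pos)
    seq = ref.sequences[ref.c4a_name]
    codon = "".join(seq[model.absolute_of_cds(i) - 1] for i in range(lo, hi + 1))
    ref_aa = translate_codon(codon)
    alt_codon = list(codon)
    alt_codon[cds - lo] = allele
    alt_aa = translate_codon("".join(alt_codon))
    label = f"p.{ref_aa}{aa_pos}{alt_aa}"
    if alt_aa == ref_aa:
        return "synonymous", label
    if alt_aa == "*":
        return "stop-gained", label
    return "non-synonymous", label


def call_snps(
    table: DepthTable,
    overall: int,
    mode: str = "wgs",
    model: Optional[GeneModel] = None,
    ref: Optional[AlignmentReference] = None,
    min_depth: Optional[int] = None,
) -> pd.DataFrame:
    """Build the overall C4 SNP table for one sample.

    Returns a DataFrame (columns :data:`SNP_COLUMNS`) with one row per
    passing allele per position.  The frame carries ``attrs['n_no_call']``
    (covered positions failing the depth threshold) and, for
    ``overall == 0``, ``attrs['note']`` explaining the empty table.
    """
    if model is None:
        model = table.model
    if min_depth is None:
        min_depth = MIN_DEPTH[mode]

    empty = pd.DataFrame(columns=SNP_COLUMNS)
    if overall == 0:
        empty.attrs["note"] = "overall C4 copy number is 0; no C4 sequence to call"
        empty.attrs["n_no_call"] = 0
        return empty

    totals = table.total
    called = totals >= min_depth
    thr = 0.5 / overall
    refseq = ref.sequences[ref.c4a_name] if ref is not None else None

    rows = []
    for col, allele in enumerate(COLUMNS):
        counts = table.c4[:, col]
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
        hit = called & (ratio >= thr) & (counts > 0)
        for idx in np.nonzero(hit)[0]:
            pos = int(idx) + 1
            r = float(ratio[idx])
            ref_base = refseq[idx] if refseq is not None else None
            non_ref = (allele != ref_base) if ref_base is not None else None
            consequence = hgvs = None
            if refseq is not None and (non_ref or allele in ("del", "ins")):
                consequence, hgvs = annotate_consequence(pos, allele, model, ref)
            rows.append((
                pos, str(model.from_absolute(pos)), model.region_of(pos),
                ref_base, allele, int(counts[idx]), int(totals[idx]), r,
                min(round_half_away(r * overall), overall), non_ref,
                consequence, hgvs,
            ))
    df = pd.DataFrame(rows, columns=SNP_COLUMNS)
    df.sort_values(["pos", "allele"], inplace=True, kind="mergesort")
    df.reset_index(drop=True, inplace=True)
    df.attrs["n_no_call"] = int(((totals > 0) & ~called).sum())
    df.attrs["min_depth"] = min_depth
    df.attrs["overall"] = overall
    return df


@dataclass
class CohortSummary:
    """Cohort-level variant summary."""

    variants: pd.DataFrame       # per (pos, allele): copies, frequencies, carriers
    region_table: pd.DataFrame   # per region: variant positions / total positions
    carrier_curve: pd.DataFrame  # carrier fraction vs allele-frequency threshold
    n_samples: int
    min_total_copy: int


def summarize_cohort(
    sample_tables: Sequence[pd.DataFrame],
    overall_copies: Sequence[int],
    model: GeneModel,
    populations: Optional[Sequence[str]] = None,
    min_total_copy: int = 10,
    af_thresholds: Optional[Sequence[float]] = None,
) -> CohortSummary:
    """Summarise non-reference variation across a cohort.

    Global allele frequency of a variant is its summed copy over the
    summed overall C4 copy of the cohort; carrier counts are samples with
    at least one copy.  Variant positions are filtered to a total
    non-reference copy of at least ``min_total_copy``.  The carrier curve
    gives, per region class, the fraction of samples carrying at least one
    non-reference allele at or below each global-frequency threshold.
    """
    if len(sample_tables) < 1:
        raise ValueError("need at least one sample")
    if populations is None:
        populations = ["ALL"] * len(sample_tables)
    if af_thresholds is None:
        af_thresholds = np.round(np.arange(0.0, 0.0525, 0.0025), 4)

    total_overall = int(sum(overall_copies))
    per_variant = {}
    carriers = {}
    for i, df in enumerate(sample_tables):
        if len(df) == 0:
            continue
        nr = df[df["non_ref"] == True]  # noqa: E712
        for row in nr.itertuples():
            key = (row.pos, row.allele)
            rec = per_variant.setdefault(
                key, {"pos": row.pos, "allele": row.allele, "region": row.region,
                      "consequence": row.consequence, "hgvs_p": row.hgvs_p,
                      "total_copy": 0, "carriers": 0, "by_pop": {}})
            rec["total_copy"] += int(row.copy)
            if row.copy >= 1:
                rec["carriers"] += 1
                carriers.setdefault(key, set()).add(i)
            pop = populations[i]
            bp = rec["by_pop"].setdefault(pop, [0, 0])
            bp[0] += int(row.copy)

    pop_overall = {}
    for i, n in enumerate(overall_copies):
        pop_overall[populations[i]] = pop_overall.get(populations[i], 0) + int(n)

    rows = []
    for key, rec in sorted(per_variant.items()):
        gaf = rec["total_copy"] / total_overall if total_overall else float("nan")
        row = {
            "pos": rec["pos"], "allele": rec["allele"], "region": rec["region"],
            "consequence": rec["consequence"], "hgvs_p": rec["hgvs_p"],
            "total_copy": rec["total_copy"], "global_af": gaf,
            "carriers": rec["carriers"],
        }
        for pop, (cp, _) in rec["by_pop"].items():
            row[f"af_{pop}"] = cp / pop_overall[pop] if pop_overall[pop] else float("nan")
        rows.append(row)
    variants = pd.DataFrame(rows)
    if len(variants):
        variants_f = variants[variants["total_copy"] >= min_total_copy].reset_index(drop=True)
    else:
        variants_f = variants

    region_totals = model.region_counts()
    reg_rows = []
    for region in ("exon", "intron", "herv"):
        npos = (variants_f[variants_f["region"] == region]["pos"].nunique()
                if len(variants_f) else 0)
        total = region_totals[region]
        reg_rows.append({"region": region, "variant_positions": int(npos),
                         "total_positions": int(total),
                         "fraction": npos / total if total else float("nan")})
    region_table = pd.DataFrame(reg_rows)

    # carrier curve over all (unfiltered) non-reference variants
    curve_rows = []
    n = len(sample_tables)
    for thr in af_thresholds:
        row = {"threshold": float(thr)}
        for region in ("exon", "intron", "herv"):
            hit = set()
            for key, rec in per_variant.items():
                if rec["region"] != region:
                    continue
                gaf = rec["total_copy"] / total_overall if total_overall else 0.0
                if gaf <= thr + 1e-12:
                    hit |= carriers.get(key, set())
            row[region] = len(hit) / n
        curve_rows.append(row)
    carrier_curve = pd.DataFrame(curve_rows)

    return CohortSummary(
        variants=variants_f, region_table=region_table,
        carrier_curve=carrier_curve, n_samples=n, min_total_copy=min_total_copy,
    )
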