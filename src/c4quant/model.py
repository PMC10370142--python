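"""Model/Results interface tying the pipeline stages together.

:class:`C4Model` is built from one sample's evidence (a merged depth
table, plus optionally the merged reads for phasing) and ``fit()`` returns
a :class:`C4Results` carrying the copy-number profile, the SNP table, the
recombinant assessment and a ``summary()`` table, in the spirit of the
model/results split used by statistical modelling packages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import copynum, phase, variants
from .depth import (DepthTable, MergedReadSet, build_depth_table,
                    build_depth_table_fast, merge_blocks,
                    merge_paralog_alignments)
from .genemodel import GeneModel
from .reference import AlignmentReference

__all__ = ["C4Model", "C4Results"]


class C4Model:
    """Per-sample C4 characterisation model.

    Parameters
    ----------
    depth_table
        Merged allele depth table over the overall frame and TNXB.
    reference
        The three-sequence alignment reference (supplies reference bases).
    phase_source
        Optional read-level evidence for phasing: a
        :class:`~c4quant.depth.MergedReadSet` or merged read blocks.
    mode
        ``"wgs"`` or ``"targeted"``; fixes the default minimum depth
        (6 / 20).
    """

    def __init__(
        self,
        depth_table: DepthTable,
        reference: AlignmentReference,
        phase_source=None,
        mode: str = "wgs",
        min_depth: Optional[int] = None,
        min_pairs: int = 3,
        min_fraction: float = 0.05,
        borderline_window=copynum.BORDERLINE_WINDOW,
    ):
        if mode not in copynum.MIN_DEPTH:
            raise ValueError(f"mode must be one of {sorted(copynum.MIN_DEPTH)}")
        self.depth_table = depth_table
        self.gene_model = depth_table.model
        self.reference = reference
        self.phase_source = phase_source
        self.mode = mode
        self.min_depth = copynum.MIN_DEPTH[mode] if min_depth is None else min_depth
        self.min_pairs = min_pairs
        self.min_fraction = min_fraction
        self.borderline_window = borderline_window

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_sam(cls, sam_path, reference: AlignmentReference,
                 gene_model: GeneModel, **kwargs) -> "C4Model":
        """Build from a SAM/BAM alignment against the three-contig reference."""
        merged = merge_paralog_alignments(sam_path, reference, gene_model)
        table = build_depth_table(merged, gene_model)
        return cls(table, reference, phase_source=merged, **kwargs)

    @classmethod
    def from_sample(cls, bundle, **kwargs) -> "C4Model":
        """Build from a simulated :class:`~c4quant.simulate.SampleBundle`."""
        blocks = merge_blocks(bundle.blocks, bundle.reference)
        table = build_depth_table_fast(blocks, bundle.model)
        return cls(table, bundle.reference, phase_source=blocks, **kwargs)

    # -- fitting ---------------------------------------------------------
    def fit(self, call_variants: bool = True) -> "C4Results":
        profile = copynum.call_profile(
            self.depth_table, self.gene_model, mode=self.mode,
            min_depth=self.min_depth, borderline_window=self.borderline_window)

        snp_table = None
        if call_variants:
            snp_table = variants.call_snps(
                self.depth_table, profile.overall, mode=self.mode,
                model=self.gene_model, ref=self.reference,
                min_depth=self.min_depth)

        evidence = recombinants = e26 = None
        if self.phase_source is not None:
            evidence = phase.collect_phase_evidence(self.phase_source, self.gene_model)
            recombinants = phase.call_recombinants(
                evidence, profile, min_pairs=self.min_pairs,
                min_fraction=self.min_fraction)
            e26 = phase.classify_e26_extended_variants(
                self.phase_source, self.gene_model, profile.overall)
        return C4Results(
            model=self, profile=profile, snp_table=snp_table,
            phase_evidence=evidence, recombinants=recombinants,
            e26_variants=e26,
        )


@dataclass
class C4Results:
    """Fitted per-sample results."""

    model: C4Model
    profile: copynum.CopyNumberProfile
    snp_table: Optional[pd.DataFrame] = None
    phase_evidence: Optional[list] = None
    recombinants: Optional[phase.RecombinantCall] = None
    e26_variants: Optional[pd.DataFrame] = None

    # -- presentation ----------------------------------------------------
    def profile_frame(self) -> pd.DataFrame:
        p = self.profile
        rows = []
        for cat, copy in p.as_dict().items():
            key = {"overall": "overall", "A": "A", "Rg": "Rg", "L": "L"}.get(cat)
            rows.append({
                "category": cat, "copy": copy,
                "raw_ratio": p.ratios.get(key) if key else None,
                "flag": p.flags.get(key) if key else None,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        p = self.profile
        lines = []
        lines.append("C4 copy-number and sequence profile")
        lines.append("=" * 48)
        lines.append(f"mode: {self.model.mode}   min depth: {self.model.min_depth}")
        lines.append("")
        lines.append(f"{'category':<14}{'copy':>6}  {'ratio':>8}  flag")
        lines.append("-" * 48)
        for row in self.profile_frame().itertuples():
            ratio = "" if row.raw_ratio is None or pd.isna(row.raw_ratio) \
                else f"{row.raw_ratio:.3f}"
            copy = "NA" if row.copy is None else str(row.copy)
            flag = row.flag or ""
            lines.append(f"{row.category:<14}{copy:>6}  {ratio:>8}  {flag}")
        if self.snp_table is not None:
            non_ref = int((self.snp_table["non_ref"] == True).sum())  # noqa: E712
            lines.append("")
            lines.append(f"SNP table: {len(self.snp_table)} allele calls, "
                         f"{non_ref} non-reference")
        if self.recombinants is not None:
            r = self.recombinants
            lines.append("")
            lines.append(f"phase evidence: {r.informative_pairs} informative pairs "
                         f"({', '.join(f'{k}={v}' for k, v in r.counts.items())})")
            flagged = [k for k, v in r.flags.items() if v]
            lines.append("recombinants: " + (", ".join(flagged) if flagged else "none"))
        for w in p.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    # -- output ----------------------------------------------------------
    def write(self, outdir, sample_id: str = "sample") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.model.depth_table.to_tsv(outdir / f"{sample_id}.depth.tsv",
                                      outdir / f"{sample_id}.tnxb_depth.tsv")
        self.profile_frame().to_csv(outdir / f"{sample_id}.copy_profile.tsv",
                                    sep="\t", index=False)
        if self.snp_table is not None:
            self.snp_table.to_csv(outdir / f"{sample_id}.snps.tsv",
                                  sep="\t", index=False)
        if self.recombinants is not None:
            r = self.recombinants
            rows = [{"class": c, "pairs": r.counts[c],
                     "flag": r.flags.get(c, False), "phased": r.phased[c]}
                    for c in phase.CLASSES]
            pd.DataFrame(rows).to_csv(outdir / f"{sample_id}.phase.tsv",
                                      sep="\t", index=False)
        if self.e26_variants is not None and len(self.e26_variants):
            self.e26_variants.to_csv(outdir / f"{sample_id}.e26_variants.tsv",
                                     sep="\t", index=False)
        meta = {
            "sample_id": sample_id,
            "mode": self.model.mode,
            "min_depth": self.model.min_depth,
            "min_pairs": self.model.min_pairs,
            "min_fraction": self.model.min_fraction,
            "borderline_window": list(self.model.borderline_window),
            "profile": self.profile.as_dict(),
            "warnings": self.profile.warnings,
        }
        with open(outdir / f"{sample_id}.metadata.json", "w") as fh:
            json.dump(meta, fh, indent=1)
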