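"""Integer copy-number calls from the merged C4 depth table.

Overall C4 copy number is twice the ratio of the median non-HERV C4 depth
to the median TNXB depth (TNXB is taken to be diploid).  Category copy
numbers (C4A/C4B, Rodgers/Chido, long/short form, functional copies after
loss-of-function adjustment) multiply the relevant depth ratios by the
overall copy number and round to the nearest integer (half away from
zero).  Scaled ratios whose fractional part falls in the configurable
borderline window [0.35, 0.65] are flagged "borderline"; diagnostic sites
below the minimum depth (6 for WGS, 20 for targeted data) yield no-calls
rather than zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .depth import DepthTable, NormalizerMissingError
from .genemodel import GeneModel

__all__ = [
    "CopyNumberProfile",
    "call_overall_copy",
    "call_snp_ratio_copies",
    "call_herv_copies",
    "call_functional_copies",
    "call_profile",
    "MIN_DEPTH",
    "round_half_away",
]

MIN_DEPTH = {"wgs": 6, "targeted": 20}
BORDERLINE_WINDOW = (0.35, 0.65)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _flag(scaled: float, window=BORDERLINE_WINDOW) -> str:
    frac = scaled - math.floor(scaled)
    return "borderline" if window[0] <= frac <= window[1] else "clear"


@dataclass
class CopyNumberProfile:
    """Called integer copies per category with raw ratios and flags."""

    overall: int
    a: Optional[int] = None
    b: Optional[int] = None
    rg: Optional[int] = None
    ch: Optional[int] = None
    l: Optional[int] = None
    s: Optional[int] = None
    lof_a: Optional[int] = None
    lof_b: Optional[int] = None
    functional_a: Optional[int] = None
    functional_b: Optional[int] = None
    ratios: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "overall": self.overall, "A": self.a, "B": self.b,
            "Rg": self.rg, "Ch": self.ch, "L": self.l, "S": self.s,
            "lof_a": self.lof_a, "lof_b": self.lof_b,
            "functional_A": self.functional_a, "functional_B": self.functional_b,
        }


def _herv_mask(model: GeneModel) -> np.ndarray:
    mask = np.zeros(model.total_length, dtype=bool)
    h0, h1 = model.herv_span
    mask[h0 - 1:h1] = True
    return mask


def call_overall_copy(
    table: DepthTable,
    model: GeneModel,
    use_mean: bool = False,
    borderline_window=BORDERLINE_WINDOW,
):
    """Overall C4 copy from the C4/TNXB depth ratio.

    The C4 median is taken over non-HERV frame positions only, so the
    long/short mixture cannot bias the overall estimate.  Returns
    ``(ratio, copy, flag)``.
    """
    agg = np.mean if use_mean else np.median
    tnxb_med = float(agg(table.tnxb_total))
    if tnxb_med <= 0:
        raise NormalizerMissingError("TNXB normalizer has no coverage")
    c4_med = float(agg(table.total[~_herv_mask(model)]))
    ratio = c4_med / tnxb_med
    scaled = 2.0 * ratio
    return ratio, round_half_away(scaled), _flag(scaled, borderline_window)


def call_snp_ratio_copies(
    table: DepthTable,
    sites,
    overall: int,
    label_x: str,
    label_y: str,
    min_depth: int = MIN_DEPTH["wgs"],
    model: Optional[GeneModel] = None,
    borderline_window=BORDERLINE_WINDOW,
):
    """Copy split of a diagnostic SNP group (isotype or epitope).

    ``sites`` are :class:`DiagnosticSite` objects whose ``alleles`` map
    contains ``label_x`` and ``label_y``.  Per-site ratios of the
    ``label_x`` base over total depth are averaged and scaled by the
    overall copy.  Any site below ``min_depth`` renders the whole category
    a no-call (``(None, None, nan, "no_call")``).
    """
    if overall == 0:
        return 0, 0, float("nan"), "clear"
    if model is None:
        model = table.model
    ratios = []
    for site in sites:
        pos = model.site_absolute(site)
        row = table.c4[pos - 1]
        total = int(row[:5].sum())
        if total < min_depth:
            return None, None, float("nan"), "no_call"
        base = site.alleles[label_x]
        ratios.append(row["ACGT".index(base)] / total)
    mean_ratio = float(np.mean(ratios))
    scaled = mean_ratio * overall
    copy_x = min(max(round_half_away(scaled), 0), overall)
    return copy_x, overall - copy_x, mean_ratio, _flag(scaled, borderline_window)


def call_herv_copies(
    table: DepthTable,
    model: GeneModel,
    overall: int,
    borderline_window=BORDERLINE_WINDOW,
):
    """Long/short-form copy split from the HERV-interval depth ratio."""
    if overall == 0:
        return 0, 0, float("nan"), "clear"
    herv = _herv_mask(model)
    nonherv_med = float(np.median(table.total[~herv]))
    if nonherv_med <= 0:
        return None, None, float("nan"), "no_call"
    ratio = float(np.median(table.total[herv])) / nonherv_med
    scaled = ratio * overall
    l_copy = min(max(round_half_away(scaled), 0), overall)
    return l_copy, overall - l_copy, ratio, _flag(scaled, borderline_window)


def call_functional_copies(
    table: DepthTable,
    model: GeneModel,
    overall: int,
    a_copies: Optional[int],
    b_copies: Optional[int],
    min_depth: int = MIN_DEPTH["wgs"],
):
    """Functional copies after subtracting loss-of-function alleles.

    The exon-29 TC-insertion depth ratio times the overall copy gives the
    LoF-A copy count, subtracted from C4A; likewise the exon-13 C-deletion
    for C4B.  Negative results clamp to zero with a warning.
    Returns ``(functional_a, functional_b, lof_a, lof_b, warnings)``.
    """
    warnings = []
    if overall == 0:
        return (0 if a_copies is not None else None,
                0 if b_copies is not None else None, 0, 0, warnings)

    def _lof(pos: int, col: int) -> int:
        row = table.c4[pos - 1]
        total = int(row[:5].sum())
        if total < min_depth:
            warnings.append(f"LoF site at {pos} below minimum depth")
            return 0
        return min(max(round_half_away(row[col] / total * overall), 0), overall)

    ins_anchor = model.to_absolute(model.tc_ins_anchor)
    del_site = model.to_absolute(model.c_del_site)
    lof_a = _lof(ins_anchor, 5)
    lof_b = _lof(del_site, 4)

    functional_a = functional_b = None
    if a_copies is not None:
        functional_a = a_copies - lof_a
        if functional_a < 0:
            warnings.append("LoF-A copies exceed C4A copies; clamped to 0")
            functional_a = 0
    if b_copies is not None:
        functional_b = b_copies - lof_b
        if functional_b < 0:
            warnings.append("LoF-B copies exceed C4B copies; clamped to 0")
            functional_b = 0
    return functional_a, functional_b, lof_a, lof_b, warnings


def call_profile(
    table: DepthTable,
    model: GeneModel,
    mode: str = "wgs",
    min_depth: Optional[int] = None,
    use_mean: bool = False,
    borderline_window=BORDERLINE_WINDOW,
) -> CopyNumberProfile:
    """Full copy-number profile from one sample's depth table."""
    if min_depth is None:
        min_depth = MIN_DEPTH[mode]
    ratio, overall, flag = call_overall_copy(
        table, model, use_mean=use_mean, borderline_window=borderline_window)
    profile = CopyNumberProfile(overall=overall)
    profile.ratios["overall"] = ratio
    profile.flags["overall"] = flag

    a, b, r_ab, f_ab = call_snp_ratio_copies(
        table, model.isotype_sites, overall, "A", "B",
        min_depth=min_depth, model=model, borderline_window=borderline_window)
    rg, ch, r_rc, f_rc = call_snp_ratio_copies(
        table, model.epitope_sites, overall, "Rg", "Ch",
        min_depth=min_depth, model=model, borderline_window=borderline_window)
    l, s, r_ls, f_ls = call_herv_copies(
        table, model, overall, borderline_window=borderline_window)
    profile.a, profile.b = a, b
    profile.rg, profile.ch = rg, ch
    profile.l, profile.s = l, s
    profile.ratios.update({"A": r_ab, "Rg": r_rc, "L": r_ls})
    profile.flags.update({"A": f_ab, "Rg": f_rc, "L": f_ls})

    fa, fb, lof_a, lof_b, warnings = call_functional_copies(
        table, model, overall, a, b, min_depth=min_depth)
    profile.functional_a, profile.functional_b = fa, fb
    profile.lof_a, profile.lof_b = lof_a, lof_b
    profile.warnings.extend(warnings)
    return profile
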