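"""Read-backed phasing between the isotype (E26) and epitope (E28) SNP groups.

The five C4A/C4B SNPs in exon 26 and the four Rodgers/Chido SNPs in exon
28 are 440 bp apart — farther than one 150 bp read but within reach of a
sequenced fragment — so a read *pair* (or a single long read) can observe
alleles from both groups on one molecule.  Pairs with a definite call in
each group count towards one of the four classes A-Rg, A-Ch, B-Rg, B-Ch;
the non-canonical pairings A-Ch and B-Rg are recombinants.

The E26 extended-variant analysis instead demands a single read spanning
all five isotype SNPs (positions E26.128-E26.145), and reports in-phase
allele strings that are neither all-C4A nor all-C4B.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .copynum import CopyNumberProfile, round_half_away
from .depth import (MergedReadSet, _walk_read, fragment_site_bases,
                    fragment_window_strings)
from .genemodel import FeatureCoordinate, GeneModel

__all__ = [
    "PhaseEvidence",
    "RecombinantCall",
    "collect_phase_evidence",
    "call_recombinants",
    "classify_e26_extended_variants",
    "phasing_completeness",
    "E26_WINDOW",
]

E26_WINDOW = (FeatureCoordinate("E26", 128), FeatureCoordinate("E26", 145))

CLASSES = ("A-Rg", "A-Ch", "B-Rg", "B-Ch")


@dataclass
class PhaseEvidence:
    """Isotype/epitope calls observed on one fragment."""

    fragment: str
    isotype: Optional[str]   # "A", "B", "ambiguous" or None (no site covered)
    epitope: Optional[str]   # "Rg", "Ch", "ambiguous" or None

    @property
    def informative(self) -> bool:
        return self.isotype in ("A", "B") and self.epitope in ("Rg", "Ch")


@dataclass
class RecombinantCall:
    """Per-sample recombinant assessment."""

    counts: dict                     # pairs per class
    informative_pairs: int
    flags: dict                      # class -> bool (A-Ch / B-Rg recombinants)
    phased: dict                     # class -> bool (read-backed support)
    suppressed: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    min_pairs: int = 3
    min_fraction: float = 0.05


def _group_call(bases: Sequence[int], covered: Sequence[bool], site_alleles) -> Optional[str]:
    """Majority call over the covered sites of one group; ties are ambiguous."""
    votes = Counter()
    any_covered = False
    for base, cov, alleles in zip(bases, covered, site_alleles):
        if not cov:
            continue
        any_covered = True
        for label, allele in alleles.items():
            if base == ord(allele):
                votes[label] += 1
    if not any_covered:
        return None
    if not votes:
        return "ambiguous"
    top = votes.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return "ambiguous"
    return top[0][0]


def collect_phase_evidence(
    source,
    model: GeneModel,
    min_base_quality: int = 10,
) -> List[PhaseEvidence]:
    """Per-fragment isotype/epitope evidence.

    ``source`` is either a :class:`~c4quant.depth.MergedReadSet` (SAM
    path) or an iterable of merged read blocks (simulator fast path).
    Only fragments covering at least one site in *each* group are
    returned.
    """
    iso_pos = [model.site_absolute(s) for s in model.isotype_sites]
    epi_pos = [model.site_absolute(s) for s in model.epitope_sites]
    iso_alleles = [s.alleles for s in model.isotype_sites]
    epi_alleles = [s.alleles for s in model.epitope_sites]
    n_iso = len(iso_pos)

    out = []
    if isinstance(source, MergedReadSet):
        frags = {}
        for read in source.reads:
            if read.contig != "C4":
                continue
            frags.setdefault(read.qname, []).append(read)
        targets = {p - 1 for p in iso_pos + epi_pos}
        for qname, reads in sorted(frags.items()):
            reads.sort(key=lambda r: r.mate)
            seen = {}
            for read in reads:
                for r0, kind, base in _walk_read(read, min_base_quality):
                    if kind != "base":
                        continue
                    if read.from_short and r0 >= source.herv_start0:
                        r0 += source.herv_length
                    if r0 in targets and r0 not in seen:
                        seen[r0] = ord(base)
            bases = [seen.get(p - 1, 0) for p in iso_pos + epi_pos]
            covered = [(p - 1) in seen for p in iso_pos + epi_pos]
            iso = _group_call(bases[:n_iso], covered[:n_iso], iso_alleles)
            epi = _group_call(bases[n_iso:], covered[n_iso:], epi_alleles)
            if iso is not None and epi is not None:
                out.append(PhaseEvidence(qname, iso, epi))
    else:
        bases, covered = fragment_site_bases(source, iso_pos + epi_pos)
        for i in range(len(bases)):
            iso = _group_call(bases[i, :n_iso], covered[i, :n_iso], iso_alleles)
            epi = _group_call(bases[i, n_iso:], covered[i, n_iso:], epi_alleles)
            if iso is not None and epi is not None:
                out.append(PhaseEvidence(f"frag{i}", iso, epi))
    return out


def call_recombinants(
    evidence: Iterable[PhaseEvidence],
    profile: CopyNumberProfile,
    min_pairs: int = 3,
    min_fraction: float = 0.05,
) -> RecombinantCall:
    """Flag A-Ch / B-Rg recombinants from phase evidence.

    A recombinant class is flagged when it is supported by at least
    ``min_pairs`` informative pairs making up at least ``min_fraction`` of
    all informative pairs; classes impossible under the copy profile are
    suppressed with a warning.
    """
    counts = {c: 0 for c in CLASSES}
    for ev in evidence:
        if ev.informative:
            counts[f"{ev.isotype}-{ev.epitope}"] += 1
    informative = sum(counts.values())

    category = {"A-Rg": ("a", "rg"), "A-Ch": ("a", "ch"),
                "B-Rg": ("b", "rg"), "B-Ch": ("b", "ch")}
    flags = {}
    phased = {}
    suppressed = []
    warnings = []
    for cls in CLASSES:
        n = counts[cls]
        supported = (n >= min_pairs
                     and informative > 0
                     and n >= min_fraction * informative)
        iso_attr, epi_attr = category[cls]
        iso_copies = getattr(profile, iso_attr)
        epi_copies = getattr(profile, epi_attr)
        possible = not (iso_copies == 0 or epi_copies == 0)
        if supported and not possible:
            suppressed.append(cls)
            warnings.append(
                f"{cls} support ({n} pairs) is inconsistent with the copy "
                f"profile ({iso_attr.upper()}={iso_copies}, {epi_attr}={epi_copies})")
            supported = False
        phased[cls] = supported
        if cls in ("A-Ch", "B-Rg"):
            flags[cls] = supported
    return RecombinantCall(
        counts=counts, informative_pairs=informative, flags=flags,
        phased=phased, suppressed=suppressed, warnings=warnings,
        min_pairs=min_pairs, min_fraction=min_fraction,
    )


def classify_e26_extended_variants(
    source,
    model: GeneModel,
    overall: int,
    min_base_quality: int = 10,
) -> pd.DataFrame:
    """In-phase allele strings over the five isotype SNPs.

    Only single reads spanning the whole E26.128-E26.145 window are used,
    so the phase of all five sites is directly observed.  Returns a
    DataFrame of observed strings with estimated copy numbers
    (``round(relative depth x overall)``); the canonical all-C4A and
    all-C4B strings are marked.  ``attrs['status']`` is ``"ok"`` or
    ``"no_coverage"``.
    """
    site_pos = [model.site_absolute(s) for s in model.isotype_sites]
    a_string = "".join(s.alleles["A"] for s in model.isotype_sites)
    b_string = "".join(s.alleles["B"] for s in model.isotype_sites)

    if isinstance(source, MergedReadSet):
        w0 = model.to_absolute(E26_WINDOW[0]) - 1
        w1 = model.to_absolute(E26_WINDOW[1]) - 1
        strings = []
        frags = {}
        for read in source.reads:
            if read.contig == "C4":
                frags.setdefault(read.qname, []).append(read)
        for qname, reads in sorted(frags.items()):
            reads.sort(key=lambda r: r.mate)
            got = None
            for read in reads:
                cover = {}
                for r0, kind, base in _walk_read(read, min_base_quality):
                    if kind != "base":
                        continue
                    if read.from_short and r0 >= source.herv_start0:
                        r0 += source.herv_length
                    cover[r0] = base
                if all(p in cover for p in range(w0, w1 + 1)):
                    got = "".join(cover[p - 1] for p in site_pos)
                    break
            if got is not None:
                strings.append(got)
    else:
        strings = fragment_window_strings(
            source, [model.to_absolute(E26_WINDOW[0]),
                     model.to_absolute(E26_WINDOW[1])] + site_pos)
        # the helper returns bases in the order given; strip the two
        # window-bound columns
        strings = [s[2:] for s in strings]

    counts = Counter(strings)
    total = sum(counts.values())
    rows = []
    for string, n in counts.most_common():
        canonical = ("A" if string == a_string
                     else "B" if string == b_string else None)
        copy = round_half_away(n / total * overall) if total else None
        rows.append({"alleles": string, "reads": n, "fraction": n / total,
                     "copy": copy, "canonical": canonical})
    df = pd.DataFrame(rows, columns=["alleles", "reads", "fraction", "copy",
                                     "canonical"])
    df.attrs["status"] = "ok" if total else "no_coverage"
    df.attrs["spanning_reads"] = total
    return df


def phasing_completeness(
    calls: Sequence[RecombinantCall],
    profiles: Sequence[CopyNumberProfile],
) -> dict:
    """Cohort phasing completeness for the non-recombinant pairings.

    For each of A-Rg and B-Ch: the number of samples with read-backed
    phasing of that combination over the number of samples whose copy
    profile carries it.
    """
    if len(calls) != len(profiles) or len(calls) == 0:
        raise ValueError("need matching, non-empty call and profile lists")
    out = {"warnings": []}
    for cls, iso_attr, epi_attr in (("A-Rg", "a", "rg"), ("B-Ch", "b", "ch")):
        carriers = 0
        phased = 0
        for call, prof in zip(calls, profiles):
            iso = getattr(prof, iso_attr)
            epi = getattr(prof, epi_attr)
            if iso is None or epi is None or iso == 0 or epi == 0:
                continue
            carriers += 1
            if call.phased.get(cls, False):
                phased += 1
        key = f"completeness_{cls.replace('-', '_')}"
        if carriers == 0:
            out[key] = None
            out["warnings"].append(f"no {cls} carriers in cohort")
        else:
            out[key] = phased / carriers
            if phased == 0:
                out["warnings"].append(f"no read-backed phasing for any {cls} carrier")
        out[f"carriers_{cls.replace('-', '_')}"] = carriers
        out[f"phased_{cls.replace('-', '_')}"] = phased
    return out
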