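"""Coordinate frame and gene model for the overall C4 alignment reference.

The C4 genes are described in a single "overall" coordinate frame spanning
the long-form gene from 5'UTR position -285 through 3'UTR position +341.
Positions are named feature-locally (e.g. ``E26.129`` is the 129th base of
exon 26, ``I9.276`` the 276th base of intron 9), with 1-based offsets for
exons, introns and the 3'UTR and negative offsets (-285..-1) for the 5'UTR.
Amino-acid numbering over the CDS includes the 19-residue signal peptide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "FeatureCoordinate",
    "DiagnosticSite",
    "GeneModel",
]

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon.upper()]


@dataclass(frozen=True, order=True)
class FeatureCoordinate:
    """A feature-local position, e.g. ``E26.129`` or ``U5.-285``."""

    feature: str
    offset: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.feature}.{self.offset}"

    @classmethod
    def parse(cls, text: str) -> "FeatureCoordinate":
        feature, _, off = text.partition(".")
        return cls(feature, int(off))


@dataclass(frozen=True)
class DiagnosticSite:
    """A single diagnostic SNP with the two allele bases it distinguishes.

    ``alleles`` maps category labels (``A``/``B`` for the isotype group,
    ``Rg``/``Ch`` for the epitope group) to the base carried by that
    category at this site.
    """

    coord: FeatureCoordinate
    alleles: dict


class GeneModel:
    """Ordered feature layout of the overall C4 frame plus annotations.

    Parameters
    ----------
    features
        Ordered ``(name, length)`` pairs covering the whole frame:
        ``U5``, ``E1``, ``I1``, ..., ``E<n>``, ``U3``.
    herv
        Inclusive feature-local interval of the HERV-K(C4) insertion; must
        lie strictly inside intron 9.
    isotype_sites, epitope_sites
        Diagnostic SNP groups distinguishing C4A/C4B and Rodgers/Chido.
    tc_ins_anchor
        Exon-29 position after which the loss-of-function ``TC`` dinucleotide
        inserts (frameshift, typically on C4A copies).
    c_del_site
        Exon-13 position whose single-base deletion is the C4B
        loss-of-function frameshift.
    """

    def __init__(
        self,
        features: Iterable[tuple],
        herv: tuple,
        isotype_sites: list,
        epitope_sites: list,
        tc_ins_anchor: FeatureCoordinate,
        c_del_site: FeatureCoordinate,
        known_variants: Optional[list] = None,
        protein_features: Optional[dict] = None,
        tnxb_name: str = "TNXB",
        tnxb_length: int = 21059,
        signal_peptide_length: int = 19,
    ):
        self.features = [(str(n), int(l)) for n, l in features]
        self._starts = {}
        pos = 1
        for name, length in self.features:
            if length <= 0:
                raise ValueError(f"feature {name} has non-positive length {length}")
            if name in self._starts:
                raise ValueError(f"duplicate feature {name}")
            self._starts[name] = pos
            pos += length
        self.total_length = pos - 1
        self._lengths = dict(self.features)

        self.herv = (herv[0], herv[1])
        self.isotype_sites = list(isotype_sites)
        self.epitope_sites = list(epitope_sites)
        self.tc_ins_anchor = tc_ins_anchor
        self.tc_ins_seq = "TC"
        self.c_del_site = c_del_site
        self.known_variants = list(known_variants or [])
        self.protein_features = dict(protein_features or {})
        self.tnxb_name = tnxb_name
        self.tnxb_length = int(tnxb_length)
        self.signal_peptide_length = int(signal_peptide_length)

        self.exon_names = [n for n, _ in self.features if n.startswith("E")]
        self._cds_start = {}
        c = 1
        for name in self.exon_names:
            self._cds_start[name] = c
            c += self._lengths[name]
        self.cds_length = c - 1
        self._validate()

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        if self.cds_length % 3 != 0:
            raise ValueError(f"CDS length {self.cds_length} not divisible by 3")
        h0, h1 = self.herv
        if h0.feature != "I9" or h1.feature != "I9":
            raise ValueError("HERV interval must lie within intron 9")
        i9 = self._lengths.get("I9", 0)
        if not (1 < h0.offset and h1.offset < i9 and h0.offset <= h1.offset):
            raise ValueError("HERV interval must lie strictly within intron 9")
        for site in self.isotype_sites + self.epitope_sites:
            feat = site.coord.feature
            if not feat.startswith("E"):
                raise ValueError(f"diagnostic site {site.coord} not exonic")
            if not (1 <= site.coord.offset <= self._lengths[feat]):
                raise ValueError(f"diagnostic site {site.coord} outside {feat}")

    # -- coordinate conversion -----------------------------------------
    def feature_start(self, name: str) -> int:
        return self._starts[name]

    def feature_length(self, name: str) -> int:
        return self._lengths[name]

    def to_absolute(self, coord: FeatureCoordinate) -> int:
        """Map a feature-local coordinate to the 1-based overall frame."""
        name = coord.feature
        if name not in self._starts:
            raise KeyError(f"unknown feature {name!r}")
        length = self._lengths[name]
        if name == "U5":
            if not (-length <= coord.offset <= -1):
                raise ValueError(f"5'UTR offset {coord.offset} out of range")
            return self._starts[name] + (coord.offset + length)
        if not (1 <= coord.offset <= length):
            raise ValueError(f"offset {coord.offset} out of range for {name}")
        return self._starts[name] + coord.offset - 1

    def from_absolute(self, pos: int) -> FeatureCoordinate:
        if not (1 <= pos <= self.total_length):
            raise ValueError(f"absolute position {pos} outside frame")
        for name, length in self.features:
            start = self._starts[name]
            if start <= pos < start + length:
                if name == "U5":
                    return FeatureCoordinate(name, pos - start - length)
                return FeatureCoordinate(name, pos - start + 1)
        raise AssertionError("unreachable")

    # -- region classes -------------------------------------------------
    @property
    def herv_span(self) -> tuple:
        """Inclusive absolute (start, end) of the HERV interval."""
        return (self.to_absolute(self.herv[0]), self.to_absolute(self.herv[1]))

    def region_of(self, pos: int) -> str:
        coord = self.from_absolute(pos)
        h0, h1 = self.herv_span
        if h0 <= pos <= h1:
            return "herv"
        if coord.feature == "U5":
            return "utr5"
        if coord.feature == "U3":
            return "utr3"
        if coord.feature.startswith("E"):
            return "exon"
        return "intron"

    def region_counts(self) -> dict:
        """Number of frame positions per region class."""
        h0, h1 = self.herv_span
        n_herv = h1 - h0 + 1
        counts = {"utr5": 0, "exon": 0, "intron": 0, "herv": n_herv, "utr3": 0}
        for name, length in self.features:
            if name == "U5":
                counts["utr5"] += length
            elif name == "U3":
                counts["utr3"] += length
            elif name.startswith("E"):
                counts["exon"] += length
            else:
                counts["intron"] += length
        counts["intron"] -= n_herv
        return counts

    # -- CDS machinery ---------------------------------------------------
    def cds_of_absolute(self, pos: int) -> Optional[int]:
        """1-based CDS index of an absolute position, or None if not exonic."""
        coord = self.from_absolute(pos)
        if not coord.feature.startswith("E"):
            return None
        return self._cds_start[coord.feature] + coord.offset - 1

    def absolute_of_cds(self, cds_pos: int) -> int:
        if not (1 <= cds_pos <= self.cds_length):
            raise ValueError(f"CDS position {cds_pos} out of range")
        for name in self.exon_names:
            start = self._cds_start[name]
            if start <= cds_pos < start + self._lengths[name]:
                return self.to_absolute(FeatureCoordinate(name, cds_pos - start + 1))
        raise AssertionError("unreachable")

    @staticmethod
    def aa_of_cds(cds_pos: int) -> int:
        """Signal-peptide-inclusive amino-acid number of a CDS position."""
        return (cds_pos + 2) // 3

    def codon_cds_span(self, aa_pos: int) -> tuple:
        return (3 * aa_pos - 2, 3 * aa_pos)

    def site_absolute(self, site: DiagnosticSite) -> int:
        return self.to_absolute(site.coord)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def _site(s):
            return {"coord": str(s.coord), "alleles": s.alleles}

        return {
            "features": [[n, l] for n, l in self.features],
            "herv": [str(self.herv[0]), str(self.herv[1])],
            "isotype_sites": [_site(s) for s in self.isotype_sites],
            "epitope_sites": [_site(s) for s in self.epitope_sites],
            "tc_ins_anchor": str(self.tc_ins_anchor),
            "c_del_site": str(self.c_del_site),
            "known_variants": self.known_variants,
            "protein_features": self.protein_features,
            "tnxb_name": self.tnxb_name,
            "tnxb_length": self.tnxb_length,
            "signal_peptide_length": self.signal_peptide_length,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneModel":
        def _site(s):
            return DiagnosticSite(FeatureCoordinate.parse(s["coord"]), dict(s["alleles"]))

        return cls(
            features=[(n, l) for n, l in d["features"]],
            herv=(FeatureCoordinate.parse(d["herv"][0]), FeatureCoordinate.parse(d["herv"][1])),
            isotype_sites=[_site(s) for s in d["isotype_sites"]],
            epitope_sites=[_site(s) for s in d["epitope_sites"]],
            tc_ins_anchor=FeatureCoordinate.parse(d["tc_ins_anchor"]),
            c_del_site=FeatureCoordinate.parse(d["c_del_site"]),
            known_variants=d.get("known_variants"),
            protein_features=d.get("protein_features"),
            tnxb_name=d.get("tnxb_name", "TNXB"),
            tnxb_length=d.get("tnxb_length", 21059),
            signal_peptide_length=d.get("signal_peptide_length", 19),
        )

    @classmethod
    def from_json(cls, path) -> "GeneModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
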