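"""Three-sequence alignment reference (C4A long, C4B short, TNXB).

The default synthetic build reproduces the geometry of the real locus:
5235 exonic positions over 41 exons, 8831 non-HERV intronic positions,
a 6367 bp HERV-K(C4) insertion at I9.276-I9.6642, UTRs of 285/341 bp,
the five C4A/C4B isotype SNPs in exon 26 encoding the PCPVLD/LSPVIH
hexapeptide at amino acids 1120-1125, the four Rodgers/Chido epitope SNPs
in exon 28 (nonsynonymous at amino acids 1207 and 1210, VDLL vs ADLR),
and a 440 bp gap between the last isotype SNP and the first epitope SNP.
Exon lengths are additionally pinned so that a panel of known
nonsynonymous variant positions (e.g. E13.122 -> p.H549P,
E33.6 -> p.A1413P, E36.4 -> p.P1530S) lands on the documented codons.
"""

from __future__ import annotations

import numpy as np

from .genemodel import DiagnosticSite, FeatureCoordinate, GeneModel, translate_codon

__all__ = [
    "AlignmentReference",
    "build_synthetic_reference",
    "classify_isotype_motif",
    "default_gene_model",
    "C4A_MOTIF",
    "C4B_MOTIF",
]

C4A_MOTIF = "PCPVLD"
C4B_MOTIF = "LSPVIH"

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")

# 41 exons totalling 5235 coding bases (1744 residues + stop).
DEFAULT_EXON_LENGTHS = [
    132, 132, 200, 80, 82, 100, 90, 96, 130, 150,
    149, 183, 150, 130, 130, 137, 198, 140, 90, 93,
    180, 82, 76, 150, 150, 150, 124, 172, 200, 120,
    120, 115, 120, 116, 117, 150, 110, 110, 100, 100, 81,
]

# 40 introns; I9 carries the 6367 bp HERV at I9.276-I9.6642; I26+I27 fix the
# 440 bp spacing between the isotype and epitope SNP groups.
DEFAULT_INTRON_LENGTHS = (
    [239] + [222] * 7 + [6767] + [222] * 16 + [100, 100] + [222] * 13
)

UTR5_LENGTH = 285
UTR3_LENGTH = 341
HERV_START_I9 = 276
HERV_END_I9 = 6642

# Isotype group: exon-26 SNPs toggling PCPVLD (C4A) <-> LSPVIH (C4B).
ISOTYPE_SITES = [
    ("E26.129", "C", "T"),
    ("E26.132", "G", "C"),
    ("E26.140", "C", "A"),
    ("E26.143", "G", "C"),
    ("E26.145", "T", "C"),
]
# Epitope group: exon-28 SNPs toggling Rodgers (VDLL) <-> Chido (ADLR).
EPITOPE_SITES = [
    ("E28.111", "T", "C"),
    ("E28.116", "T", "C"),
    ("E28.125", "T", "G"),
    ("E28.126", "T", "A"),
]

# aa -> codon carried by the reference (major allele); fixed so that the
# known-variant panel below annotates onto the documented residues.
_FIXED_CODONS = {
    141: "CTC", 229: "ACC", 325: "AAG", 328: "ATG", 478: "CCT",
    549: "CAT", 726: "CCG", 791: "CGC", 916: "CGA", 959: "GAA",
    1286: "GCA", 1413: "GCC", 1530: "CCA",
    # isotype motif, aa 1120-1125 (C4A allele)
    1120: "CCT", 1121: "TGT", 1122: "CCA", 1123: "GTG", 1124: "CTC", 1125: "GAT",
    # epitope region, aa 1205-1210 (Rodgers allele; VDLL at 1207-1210)
    1205: "GGT", 1206: "AAC", 1207: "GTT", 1208: "GAT", 1209: "CTG", 1210: "CTT",
}

# Known nonsynonymous variant panel: (site, major, minor, p-label).
KNOWN_VARIANTS = [
    ("E3.157", "C", "G", "p.L141V"),
    ("E6.60", "C", "T", "p.T229I"),
    ("E9.62", "A", "T", "p.K325M"),
    ("E9.72", "G", "A", "p.M328I"),
    ("E12.92", "C", "T", "p.P478L"),
    ("E13.122", "A", "C", "p.H549P"),
    ("E17.106", "C", "T", "p.P726L"),
    ("E18.103", "G", "A", "p.R791H"),
    ("E21.155", "G", "A", "p.R916Q"),
    ("E23.23", "A", "C", "p.E959D"),
    ("E29.180", "G", "T", "p.A1286S"),
    ("E33.6", "G", "C", "p.A1413P"),
    ("E36.4", "C", "T", "p.P1530S"),
]

PROTEIN_FEATURES = {
    "isotype_motif": [1120, 1125],
    "rg_ch_epitope": [1207, 1210],
    "c5_convertase": [477, 478],
    "c1_masp2_cleavage": [756, 757],
    "c2a_binding": [763, 770],
    "c3b_binding_1236": [1236, 1236],
    "c3b_binding_1238": [1238, 1238],
    "c1_masp2_binding_1": [1405, 1427],
    "c1_masp2_binding_2": [1716, 1732],
}

TC_INS_ANCHOR = "E29.55"
C_DEL_SITE = "E13.70"

_SENSE_CODONS = sorted(
    a + b + d
    for a in "ACGT" for b in "ACGT" for d in "ACGT"
    if translate_codon(a + b + d) != "*"
)


def classify_isotype_motif(hexapeptide: str) -> str:
    """Classify a 6-residue peptide as ``C4A``, ``C4B`` or ``other``.

    The isotypes are distinguished by the hexapeptide at amino acids
    1120-1125: PCPVLD for C4A, LSPVIH for C4B.
    """
    if len(hexapeptide) != 6:
        raise ValueError("isotype motif must be a 6 amino-acid string")
    pep = hexapeptide.upper()
    if not set(pep) <= _AA_LETTERS:
        raise ValueError(f"non-amino-acid characters in {hexapeptide!r}")
    if pep == C4A_MOTIF:
        return "C4A"
    if pep == C4B_MOTIF:
        return "C4B"
    return "other"


class AlignmentReference:
    """The three-contig alignment reference plus the short->overall liftover.

    The C4A contig carries the full overall frame (long form); the C4B
    contig is the short form, i.e. the same frame with the HERV interval
    absent and the C4B/Chido alleles at the diagnostic sites.  The liftover
    from C4B-short coordinates into the overall frame is the identity below
    the HERV start and a shift by the HERV length above it.
    """

    def __init__(self, c4a_seq: str, c4b_seq: str, tnxb_seq: str,
                 herv_start: int, herv_length: int,
                 c4a_name: str = "C4A", c4b_name: str = "C4B",
                 tnxb_name: str = "TNXB"):
        self.sequences = {c4a_name: c4a_seq, c4b_name: c4b_seq, tnxb_name: tnxb_seq}
        self.c4a_name = c4a_name
        self.c4b_name = c4b_name
        self.tnxb_name = tnxb_name
        self.herv_start = int(herv_start)      # 1-based, overall frame
        self.herv_length = int(herv_length)
        if len(c4a_seq) - len(c4b_seq) != herv_length:
            raise ValueError("short form must differ from long form by the HERV length")

    @property
    def herv_end(self) -> int:
        return self.herv_start + self.herv_length - 1

    def short_to_overall(self, pos: int) -> int:
        """Lift a 1-based C4B-short position into the overall frame."""
        if not (1 <= pos <= len(self.sequences[self.c4b_name])):
            raise ValueError(f"short-form position {pos} out of range")
        return pos if pos < self.herv_start else pos + self.herv_length

    def overall_to_short(self, pos: int) -> int | None:
        """Inverse liftover; None inside the HERV gap."""
        if pos < self.herv_start:
            return pos
        if pos <= self.herv_end:
            return None
        return pos - self.herv_length

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")

    @classmethod
    def from_fasta(cls, path, model: GeneModel) -> "AlignmentReference":
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        h0, h1 = model.herv_span
        return cls(seqs["C4A"], seqs["C4B"], seqs[model.tnxb_name],
                   herv_start=h0, herv_length=h1 - h0 + 1)


def default_gene_model(
    cds_exon_lengths=None,
    intron_lengths=None,
    tnxb_length: int = 21059,
) -> GeneModel:
    """Construct the gene model for the (default) synthetic locus layout."""
    exons = list(cds_exon_lengths or DEFAULT_EXON_LENGTHS)
    introns = list(intron_lengths or DEFAULT_INTRON_LENGTHS)
    if len(introns) != len(exons) - 1:
        raise ValueError("need exactly one fewer intron than exons")
    if any(l <= 0 for l in exons) or any(l <= 0 for l in introns):
        raise ValueError("feature lengths must be positive")
    if sum(exons) % 3 != 0:
        raise ValueError(f"CDS total {sum(exons)} not divisible by 3")

    features = [("U5", UTR5_LENGTH)]
    for i, exon_len in enumerate(exons, start=1):
        features.append((f"E{i}", exon_len))
        if i <= len(introns):
            features.append((f"I{i}", introns[i - 1]))
    features.append(("U3", UTR3_LENGTH))

    isotype = [DiagnosticSite(FeatureCoordinate.parse(c), {"A": a, "B": b})
               for c, a, b in ISOTYPE_SITES]
    epitope = [DiagnosticSite(FeatureCoordinate.parse(c), {"Rg": r, "Ch": ch})
               for c, r, ch in EPITOPE_SITES]

    return GeneModel(
        features=features,
        herv=(FeatureCoordinate("I9", HERV_START_I9), FeatureCoordinate("I9", HERV_END_I9)),
        isotype_sites=isotype,
        epitope_sites=epitope,
        tc_ins_anchor=FeatureCoordinate.parse(TC_INS_ANCHOR),
        c_del_site=FeatureCoordinate.parse(C_DEL_SITE),
        known_variants=[list(v) for v in KNOWN_VARIANTS],
        protein_features=PROTEIN_FEATURES,
        tnxb_length=tnxb_length,
    )


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def build_synthetic_reference(
    seed: int = 1,
    cds_exon_lengths=None,
    intron_lengths=None,
    tnxb_length: int = 21059,
):
    """Build the deterministic synthetic gene model and three-sequence reference.

    Returns ``(model, reference)``.  Same seed (and lengths) always yields
    byte-identical sequences.  The CDS is random sense codons with the
    diagnostic/known-variant codons pinned; introns, UTRs, the HERV insert
    and TNXB are random sequence.
    """
    model = default_gene_model(cds_exon_lengths, intron_lengths, tnxb_length)
    rng = np.random.default_rng(seed)

    n_codons = model.cds_length // 3
    codon_arr = rng.integers(0, len(_SENSE_CODONS), n_codons)
    codons = [_SENSE_CODONS[i] for i in codon_arr]
    if cds_exon_lengths is None:
        for aa_pos, codon in _FIXED_CODONS.items():
            codons[aa_pos - 1] = codon
    codons[-1] = "TAA"  # single terminal stop
    cds = "".join(codons)

    # assemble the overall (long-form) frame
    parts = []
    for name, length in model.features:
        if name.startswith("E"):
            start = model._cds_start[name]
            parts.append(cds[start - 1:start - 1 + length])
        else:
            parts.append(_random_sequence(rng, length))
    overall = "".join(parts)
    assert len(overall) == model.total_length

    # sanity: reference carries the C4A / Rodgers alleles
    if cds_exon_lengths is None:
        for site in model.isotype_sites:
            assert overall[model.site_absolute(site) - 1] == site.alleles["A"]
        for site in model.epitope_sites:
            assert overall[model.site_absolute(site) - 1] == site.alleles["Rg"]

    h0, h1 = model.herv_span
    short = bytearray((overall[:h0 - 1] + overall[h1:]).encode())

    def _short_index(abs_pos: int) -> int:
        return abs_pos - 1 if abs_pos < h0 else abs_pos - 1 - (h1 - h0 + 1)

    for site in model.isotype_sites:
        short[_short_index(model.site_absolute(site))] = ord(site.alleles["B"])
    for site in model.epitope_sites:
        short[_short_index(model.site_absolute(site))] = ord(site.alleles["Ch"])

    tnxb = _random_sequence(rng, model.tnxb_length)

    ref = AlignmentReference(overall, short.decode(), tnxb,
                             herv_start=h0, herv_length=h1 - h0 + 1)
    return model, ref
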