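"""Synthetic diploid C4 samples: genotypes, paired-end reads, truth files.

A sample is a pair of haplotypes, each carrying 0-5 C4 gene copies.  Every
copy has an isotype (A/B, the exon-26 SNP group), a form (L/S, presence of
the intron-9 HERV), an epitope (Rg/Ch, the exon-28 SNP group; defaults to
the canonical pairing A-Rg / B-Ch), optionally one loss-of-function allele
(exon-29 TC insertion or exon-13 C deletion) and a list of injected SNVs.
Two TNXB copies are always present and provide the diploid depth
normalizer.

Reads are 150 bp paired-end with Gaussian insert sizes, uniform fragment
starts within each copy, and independent substitution errors.  The default
insert size (600 +/- 100 bp) emulates long-insert short-read libraries, so
that fragments can span the 440 bp gap between the isotype and epitope SNP
groups and read-backed phasing is possible.

Each copy's reads are held in a :class:`ReadBlock`: a vectorised container
(fragment starts, insert sizes, the copy sequence, a copy->contig position
map, and the materialised sequencing errors) that the depth module can
pile up without any per-read Python loop.  The same blocks serialise to
FASTQ and to a truth SAM against the three-contig reference.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .genemodel import GeneModel
from .reference import AlignmentReference

__all__ = [
    "GeneCopy",
    "HaplotypeSpec",
    "SimConfig",
    "ReadBlock",
    "SampleBundle",
    "simulate_sample",
    "simulate_cohort",
    "genotype_from_counts",
]

_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP[a] = b

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GeneCopy:
    """One C4 gene copy on a haplotype."""

    isotype: str = "A"              # "A" or "B"
    form: str = "L"                 # "L" (HERV present) or "S"
    epitope: Optional[str] = None   # "Rg"/"Ch"; None = canonical for isotype
    lof: Optional[str] = None       # None, "tc_ins" or "c_del"
    snvs: list = field(default_factory=list)  # [(abs_pos 1-based, alt_base)]

    def __post_init__(self):
        if self.isotype not in ("A", "B"):
            raise ValueError(f"isotype must be A or B, got {self.isotype!r}")
        if self.form not in ("L", "S"):
            raise ValueError(f"form must be L or S, got {self.form!r}")
        if self.epitope not in (None, "Rg", "Ch"):
            raise ValueError(f"epitope must be Rg/Ch, got {self.epitope!r}")
        if self.lof not in (None, "tc_ins", "c_del"):
            raise ValueError(f"unknown LoF allele {self.lof!r}")

    @property
    def effective_epitope(self) -> str:
        if self.epitope is not None:
            return self.epitope
        return "Rg" if self.isotype == "A" else "Ch"


@dataclass
class HaplotypeSpec:
    copies: List[GeneCopy] = field(default_factory=list)

    def __post_init__(self):
        if not (0 <= len(self.copies) <= 5):
            raise ValueError("0-5 C4 copies per haplotype")


@dataclass
class SimConfig:
    hap1: HaplotypeSpec = field(default_factory=HaplotypeSpec)
    hap2: HaplotypeSpec = field(default_factory=HaplotypeSpec)
    coverage: float = 30.0          # mean read depth per haploid copy
    read_length: int = 150
    insert_mean: float = 600.0
    insert_sd: float = 100.0
    error_rate: float = 0.0
    seed: int = 1

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_length < 50:
            raise ValueError("read length must be >= 50")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error rate must be in [0, 1)")

    @property
    def copies(self) -> List[GeneCopy]:
        return list(self.hap1.copies) + list(self.hap2.copies)


@dataclass
class ReadBlock:
    """All read pairs sampled from a single gene (or TNXB) copy.

    ``posmap`` maps 0-based copy positions to 0-based positions on
    ``contig`` (-1 for bases inserted relative to the contig).  Error
    offsets are in reference-forward orientation of each mate's span.
    """

    contig: str
    copy_id: str
    seq: np.ndarray            # uint8 ASCII copy sequence
    posmap: np.ndarray         # int64
    starts: np.ndarray         # int64, fragment starts (copy space)
    inserts: np.ndarray        # int64
    read_length: int
    err_frag: np.ndarray
    err_mate: np.ndarray
    err_off: np.ndarray
    err_base: np.ndarray       # uint8
    indel: Optional[tuple] = None  # ("ins", ref_anchor0, copy_anchor0) /
                                   # ("del", ref_del0, copy_junction0)
    name_prefix: str = "sim"

    @property
    def n_fragments(self) -> int:
        return len(self.starts)

    def mate_span_starts(self, mate: int) -> np.ndarray:
        if mate == 0:
            return self.starts
        return self.starts + self.inserts - self.read_length


def _build_copy(copy: GeneCopy, model: GeneModel, ref: AlignmentReference):
    """Return (seq uint8, posmap into origin contig, contig name, indel)."""
    overall = np.frombuffer(
        ref.sequences[ref.c4a_name].encode(), dtype=np.uint8
    ).copy()
    for site in model.isotype_sites:
        overall[model.site_absolute(site) - 1] = ord(site.alleles[copy.isotype])
    for site in model.epitope_sites:
        overall[model.site_absolute(site) - 1] = ord(site.alleles[copy.effective_epitope])

    h0, h1 = model.herv_span  # 1-based inclusive
    for pos, alt in copy.snvs:
        if copy.form == "S" and h0 <= pos <= h1:
            raise ValueError(f"SNV at {pos} lies in the HERV absent from a short-form copy")
        overall[pos - 1] = ord(alt)

    idx = np.arange(model.total_length, dtype=np.int64)
    if copy.form == "S":
        keep = (idx < h0 - 1) | (idx > h1 - 1)
        idx = idx[keep]
        contig = ref.c4b_name
        # origin contig coordinates are short-form coordinates
        refpos = np.where(idx >= h1, idx - (h1 - h0 + 1), idx)
    else:
        contig = ref.c4a_name
        refpos = idx.copy()
    seq = overall[idx]

    indel = None
    if copy.lof == "tc_ins":
        anchor_abs = model.to_absolute(model.tc_ins_anchor)  # 1-based overall
        j = int(np.searchsorted(idx, anchor_abs - 1))
        ins = np.frombuffer(model.tc_ins_seq.encode(), dtype=np.uint8)
        seq = np.concatenate([seq[:j + 1], ins, seq[j + 1:]])
        refpos = np.concatenate(
            [refpos[:j + 1], np.full(len(ins), -1, dtype=np.int64), refpos[j + 1:]]
        )
        indel = ("ins", int(refpos[j]), j)
    elif copy.lof == "c_del":
        del_abs = model.to_absolute(model.c_del_site)
        j = int(np.searchsorted(idx, del_abs - 1))
        ref_del0 = int(refpos[j])
        seq = np.delete(seq, j)
        refpos = np.delete(refpos, j)
        indel = ("del", ref_del0, j)  # copy position j now holds the base after the deletion

    return seq, refpos, contig, indel


def _sample_block(rng, seq, refpos, contig, indel, copy_id, config) -> ReadBlock:
    rl = config.read_length
    n = len(seq)
    n_frags = int(round(config.coverage * n / (2 * rl)))
    inserts = np.clip(
        np.rint(rng.normal(config.insert_mean, config.insert_sd, n_frags)),
        rl, n,
    ).astype(np.int64)
    starts = rng.integers(0, n - inserts + 1).astype(np.int64)

    total_bases = n_frags * 2 * rl
    if config.error_rate > 0 and total_bases > 0:
        n_err = rng.binomial(total_bases, config.error_rate)
        flat = rng.integers(0, total_bases, n_err)
        err_frag = (flat // (2 * rl)).astype(np.int64)
        rem = flat % (2 * rl)
        err_mate = (rem // rl).astype(np.int8)
        err_off = (rem % rl).astype(np.int64)
        span0 = np.where(err_mate == 0, starts[err_frag],
                         starts[err_frag] + inserts[err_frag] - rl)
        orig = seq[span0 + err_off]
        code = np.searchsorted(_BASES, orig)  # ACGT are sorted ASCII
        new_code = (code + rng.integers(1, 4, n_err)) % 4
        err_base = _BASES[new_code]
    else:
        err_frag = np.empty(0, dtype=np.int64)
        err_mate = np.empty(0, dtype=np.int8)
        err_off = np.empty(0, dtype=np.int64)
        err_base = np.empty(0, dtype=np.uint8)

    return ReadBlock(
        contig=contig, copy_id=copy_id, seq=seq, posmap=refpos,
        starts=starts, inserts=inserts, read_length=rl,
        err_frag=err_frag, err_mate=err_mate, err_off=err_off,
        err_base=err_base, indel=indel,
    )


def _truth(config: SimConfig, model: GeneModel, ref: AlignmentReference) -> dict:
    copies = config.copies
    truth = {
        "overall": len(copies),
        "A": sum(c.isotype == "A" for c in copies),
        "B": sum(c.isotype == "B" for c in copies),
        "Rg": sum(c.effective_epitope == "Rg" for c in copies),
        "Ch": sum(c.effective_epitope == "Ch" for c in copies),
        "L": sum(c.form == "L" for c in copies),
        "S": sum(c.form == "S" for c in copies),
        "lof_a": sum(c.lof == "tc_ins" for c in copies),
        "lof_b": sum(c.lof == "c_del" for c in copies),
    }
    truth["functional_A"] = truth["A"] - truth["lof_a"]
    truth["functional_B"] = truth["B"] - truth["lof_b"]
    variants = {}
    c4a = ref.sequences[ref.c4a_name]
    for c in copies:
        for pos, alt in c.snvs:
            key = (int(pos), str(alt))
            variants[key] = variants.get(key, 0) + 1
    truth["variants"] = [
        {"pos": p, "ref": c4a[p - 1], "alt": a, "copies": n}
        for (p, a), n in sorted(variants.items())
    ]
    return truth


@dataclass
class SampleBundle:
    """A simulated sample: read blocks plus ground truth."""

    sample_id: str
    config: SimConfig
    model: GeneModel
    reference: AlignmentReference
    blocks: List[ReadBlock]
    truth: dict

    # -- FASTQ ----------------------------------------------------------
    def _mate_matrix(self, block: ReadBlock, mate: int) -> np.ndarray:
        rl = block.read_length
        span = block.mate_span_starts(mate)
        mat = block.seq[span[:, None] + np.arange(rl)]
        sel = block.err_mate == mate
        mat[block.err_frag[sel], block.err_off[sel]] = block.err_base[sel]
        return mat

    def write_fastq(self, r1_path, r2_path) -> None:
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
            for block in self.blocks:
                rl = block.read_length
                qual = "I" * rl
                m1 = self._mate_matrix(block, 0)
                m2 = _COMP[self._mate_matrix(block, 1)[:, ::-1]]
                for i in range(block.n_fragments):
                    name = f"{self.sample_id}:{block.copy_id}:{i}"
                    f1.write(f"@{name}/1\n{m1[i].tobytes().decode()}\n+\n{qual}\n")
                    f2.write(f"@{name}/2\n{m2[i].tobytes().decode()}\n+\n{qual}\n")

    # -- truth SAM ------------------------------------------------------
    def write_sam(self, path, multimap: bool = True) -> None:
        """Write the truth alignment against the three-contig reference.

        Every read is placed at its sampled origin.  With ``multimap``,
        C4-derived reads additionally get a secondary record on the other
        paralog wherever the sequence permits (outside the HERV interval
        and away from LoF indels), mimicking a real aligner's multi-mapping
        of the near-identical paralogs.
        """
        ref = self.reference
        herv_len = ref.herv_length
        h0_0 = ref.herv_start - 1  # 0-based junction position in the overall frame
        lines = []
        lines.append("@HD\tVN:1.6\tSO:unsorted")
        for name, seq in ref.sequences.items():
            lines.append(f"@SQ\tSN:{name}\tLN:{len(seq)}")
        lines.append("@PG\tID:c4quant-sim\tPN:c4quant-sim")

        for block in self.blocks:
            rl = block.read_length
            qual = "I" * rl
            m1 = self._mate_matrix(block, 0)
            m2 = self._mate_matrix(block, 1)  # reference-forward orientation
            s1 = block.mate_span_starts(0)
            s2 = block.mate_span_starts(1)
            for i in range(block.n_fragments):
                name = f"{self.sample_id}:{block.copy_id}:{i}"
                recs = []
                for mate, (mat, spans) in enumerate(((m1, s1), (m2, s2))):
                    pos0, cigar, covers_indel = _alignment_of(
                        block, int(spans[i]))
                    recs.append(
                        dict(mate=mate, pos0=pos0, cigar=cigar, seq=mat[i],
                             covers_indel=covers_indel)
                    )
                tlen = int(block.inserts[i])
                for r, other in ((recs[0], recs[1]), (recs[1], recs[0])):
                    flag = 99 if r["mate"] == 0 else 147
                    sl = tlen if r["mate"] == 0 else -tlen
                    lines.append("\t".join((
                        name, str(flag), block.contig, str(r["pos0"] + 1), "60",
                        r["cigar"], "=", str(other["pos0"] + 1), str(sl),
                        r["seq"].tobytes().decode(), qual,
                        f"tO:Z:{block.copy_id}", "AS:i:100",
                    )))
                if multimap and block.contig in (ref.c4a_name, ref.c4b_name):
                    for r, other in ((recs[0], recs[1]), (recs[1], recs[0])):
                        if r["covers_indel"] or other["covers_indel"]:
                            continue
                        alt = _paralog_position(
                            block.contig, r["pos0"], rl, ref.c4a_name,
                            ref.c4b_name, h0_0, herv_len)
                        alt_mate = _paralog_position(
                            block.contig, other["pos0"], rl, ref.c4a_name,
                            ref.c4b_name, h0_0, herv_len)
                        if alt is None or alt_mate is None:
                            continue
                        other_contig = (ref.c4b_name
                                        if block.contig == ref.c4a_name
                                        else ref.c4a_name)
                        flag = (99 if r["mate"] == 0 else 147) | 0x100
                        sl = tlen if r["mate"] == 0 else -tlen
                        lines.append("\t".join((
                            name, str(flag), other_contig, str(alt + 1), "0",
                            f"{rl}M", "=", str(alt_mate + 1), str(sl),
                            r["seq"].tobytes().decode(), qual,
                            f"tO:Z:{block.copy_id}", "AS:i:90",
                        )))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    # -- truth tables ---------------------------------------------------
    def write_truth(self, copy_path, variants_path=None) -> None:
        with open(copy_path, "w") as fh:
            fh.write("category\tcopy\n")
            for key in ("overall", "A", "B", "Rg", "Ch", "L", "S",
                        "lof_a", "lof_b", "functional_A", "functional_B"):
                fh.write(f"{key}\t{self.truth[key]}\n")
        if variants_path is not None:
            with open(variants_path, "w") as fh:
                fh.write("pos\tref\talt\tcopies\n")
                for v in self.truth["variants"]:
                    fh.write(f"{v['pos']}\t{v['ref']}\t{v['alt']}\t{v['copies']}\n")


def _alignment_of(block: ReadBlock, start: int):
    """(pos0, cigar, covers_indel) of a read spanning copy positions [start, start+rl)."""
    rl = block.read_length
    refs = block.posmap[start:start + rl]
    if block.indel is None:
        return int(refs[0]), f"{rl}M", False
    lead = 0
    while lead < rl and refs[lead] < 0:
        lead += 1
    if lead == rl:  # read entirely inside the insertion (impossible for 2 bp)
        raise AssertionError("read contained in insertion")
    ops = []
    if lead:
        ops.append([lead, "S"])
    prev = refs[lead]
    pos0 = int(prev)
    ops.append([1, "M"])
    touched = lead > 0
    for r in refs[lead + 1:]:
        if r < 0:
            if ops[-1][1] == "I":
                ops[-1][0] += 1
            else:
                ops.append([1, "I"])
            touched = True
        else:
            if ops[-1][1] == "M" and r == prev + 1:
                ops[-1][0] += 1
            else:
                if r != prev + 1:
                    ops.append([int(r - prev - 1), "D"])
                    touched = True
                ops.append([1, "M"])
            prev = r
    if ops[-1][1] == "I":  # trailing insertion becomes a soft clip
        ops[-1][1] = "S"
    cigar = "".join(f"{n}{op}" for n, op in ops)
    return pos0, cigar, touched


def _paralog_position(contig, pos0, rl, c4a_name, c4b_name, h0_0, herv_len):
    """Position of a plain-M read on the other paralog, or None."""
    if contig == c4a_name:  # long-form origin; drop reads touching the HERV
        if pos0 + rl <= h0_0:
            return pos0
        if pos0 >= h0_0 + herv_len:
            return pos0 - herv_len
        return None
    # short-form origin; drop reads crossing the HERV junction
    if pos0 + rl <= h0_0:
        return pos0
    if pos0 >= h0_0:
        return pos0 + herv_len
    return None


def simulate_sample(
    config: SimConfig,
    model: GeneModel,
    ref: AlignmentReference,
    sample_id: str = "sample",
) -> SampleBundle:
    """Simulate one diploid sample (C4 copies plus exactly two TNXB copies)."""
    rng = np.random.default_rng(config.seed)
    blocks = []
    for k, copy in enumerate(config.copies):
        seq, refpos, contig, indel = _build_copy(copy, model, ref)
        cid = f"C4_{k + 1}_{copy.isotype}{copy.form}"
        blocks.append(_sample_block(rng, seq, refpos, contig, indel, cid, config))
    tnxb = np.frombuffer(ref.sequences[ref.tnxb_name].encode(), dtype=np.uint8)
    tnxb_map = np.arange(len(tnxb), dtype=np.int64)
    for k in range(2):
        blocks.append(_sample_block(
            rng, tnxb, tnxb_map, ref.tnxb_name, None, f"TNXB_{k + 1}", config))
    return SampleBundle(
        sample_id=sample_id, config=config, model=model, reference=ref,
        blocks=blocks, truth=_truth(config, model, ref),
    )


def genotype_from_counts(
    overall: int,
    a_copies: int,
    l_copies: int,
    lof: Optional[str] = None,
    recombinant: Optional[str] = None,
    snvs: Optional[dict] = None,
) -> Tuple[HaplotypeSpec, HaplotypeSpec]:
    """Build a diploid genotype from category counts.

    Forms are assigned to copies independently of isotype (the first
    ``l_copies`` copies are long).  ``lof='auto'`` puts a TC insertion on
    the first A copy if any, else a C deletion on the first B copy.
    ``recombinant`` ('A-Ch' or 'B-Rg') swaps the epitope of one copy.
    ``snvs`` maps copy index -> list of (abs_pos, alt).
    """
    if not (0 <= a_copies <= overall and 0 <= l_copies <= overall):
        raise ValueError("category counts must lie within the overall copy number")
    if overall > 10:
        raise ValueError("at most 10 copies (5 per haplotype)")
    copies = []
    for k in range(overall):
        iso = "A" if k < a_copies else "B"
        form = "L" if k < l_copies else "S"
        copies.append(GeneCopy(isotype=iso, form=form))
    if lof == "auto":
        lof = "tc_ins" if a_copies >= 1 else ("c_del" if overall >= 1 else None)
    if lof == "tc_ins":
        idx = next(i for i, c in enumerate(copies) if c.isotype == "A")
        copies[idx].lof = "tc_ins"
    elif lof == "c_del":
        idx = next(i for i, c in enumerate(copies) if c.isotype == "B")
        copies[idx].lof = "c_del"
    if recombinant == "A-Ch":
        idx = next(i for i, c in enumerate(copies) if c.isotype == "A")
        copies[idx].epitope = "Ch"
    elif recombinant == "B-Rg":
        idx = next(i for i, c in enumerate(copies) if c.isotype == "B")
        copies[idx].epitope = "Rg"
    elif recombinant is not None:
        raise ValueError(f"unknown recombinant class {recombinant!r}")
    for i, sv in (snvs or {}).items():
        copies[i].snvs = list(sv)
    h1 = HaplotypeSpec(copies[:5])
    h2 = HaplotypeSpec(copies[5:])
    return h1, h2


def simulate_cohort(
    n: int,
    genotypes: Sequence[tuple],
    seed: int,
    model: GeneModel,
    ref: AlignmentReference,
    probs: Optional[Sequence[float]] = None,
    **config_kwargs,
) -> List[SampleBundle]:
    """Simulate ``n`` samples drawing diploid genotypes from a distribution.

    ``genotypes`` is a sequence of ``(hap1, hap2)`` pairs; ``probs`` the
    sampling weights (uniform if omitted).  Per-sample seeds derive
    deterministically from the master seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    genotypes = list(genotypes)
    if probs is not None:
        probs = np.asarray(probs, dtype=float)
        if len(probs) != len(genotypes) or probs.min() < 0 or probs.sum() <= 0:
            raise ValueError("malformed genotype distribution")
        probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    choices = rng.choice(len(genotypes), size=n, p=probs)
    bundles = []
    for i, g in enumerate(choices):
        h1, h2 = genotypes[g]
        cfg = SimConfig(hap1=h1, hap2=h2,
                        seed=int((seed * 1_000_003 + 7919 * i + 1) % (2 ** 31)),
                        **config_kwargs)
        bundles.append(simulate_sample(cfg, model, ref, sample_id=f"s{i:04d}"))
    return bundles
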