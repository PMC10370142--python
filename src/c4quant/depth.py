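"""Paralog-merged depth tables over the overall C4 frame and TNXB.

The aligner reports C4-derived reads against both the C4A (long-form) and
C4B (short-form) contigs.  Merging keeps one placement per read (highest
alignment score; ties resolve to the C4A frame), lifts C4B-short
coordinates into the overall frame through the HERV liftover, and passes
TNXB reads through unchanged.  The depth table counts A, C, G, T,
deletions and insertions per position; an insertion at position p means
reads supporting inserted sequence immediately after p.

Counting rules: soft-clipped bases are ignored, bases below the
base-quality floor (default Q10) are ignored, duplicate-flagged reads are
dropped, mapping quality is deliberately not filtered (multi-mapping
between the near-identical paralogs is the point), and overlapping mates
of one fragment are counted once per position.

Two ingestion fronts produce identical tables: :func:`merge_paralog_alignments`
plus :func:`build_depth_table` for SAM/BAM input, and
:func:`merge_blocks` plus :func:`build_depth_table_fast` for the
simulator's in-memory read blocks (vectorised; used for large validation
grids).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
import pysam

from .genemodel import GeneModel
from .reference import AlignmentReference
from .simulate import ReadBlock

__all__ = [
    "DepthTable",
    "MergedRead",
    "MergedReadSet",
    "merge_paralog_alignments",
    "build_depth_table",
    "merge_blocks",
    "build_depth_table_fast",
    "fragment_site_bases",
    "fragment_window_strings",
]

COLUMNS = ("A", "C", "G", "T", "del", "ins")
_BASE_COL = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T


class NormalizerMissingError(RuntimeError):
    """Raised when the TNXB normalizer has no coverage."""


@dataclass
class MergedRead:
    qname: str
    mate: int                  # 0 = first of pair, 1 = second
    contig: str                # "C4" (overall frame) or the TNXB name
    pos0: int                  # 0-based start on the *source* frame
    cigar: tuple               # pysam-style (op, len) tuples
    seq: str
    quals: Optional[np.ndarray]
    from_short: bool = False   # positions need the short->overall lift


@dataclass
class MergedReadSet:
    reads: List[MergedRead]
    herv_start0: int
    herv_length: int
    tnxb_name: str
    stats: Dict[str, int] = field(default_factory=dict)
    merged: bool = True

    def lift(self, pos: np.ndarray) -> np.ndarray:
        """Element-wise short->overall lift (0-based)."""
        return np.where(pos >= self.herv_start0, pos + self.herv_length, pos)


def merge_paralog_alignments(
    sam,
    ref: AlignmentReference,
    model: GeneModel,
) -> MergedReadSet:
    """Merge a three-contig alignment into one read set on the overall frame.

    ``sam`` is a path to a SAM/BAM file or an already-merged
    :class:`MergedReadSet` (in which case it is returned unchanged —
    merging is idempotent).  Each read contributes exactly once: among a
    read's C4A/C4B placements the highest alignment score wins, with ties
    going to the C4A frame.
    """
    if isinstance(sam, MergedReadSet):
        return sam

    h0_0 = ref.herv_start - 1
    known = set(ref.sequences)
    stats = defaultdict(int)
    candidates: Dict[tuple, list] = defaultdict(list)
    tnxb_reads: List[MergedRead] = []

    with pysam.AlignmentFile(str(sam), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                stats["unmapped"] += 1
                continue
            contig = rec.reference_name
            if contig not in known:
                stats["unknown_contig"] += 1
                continue
            if rec.is_duplicate:
                stats["duplicate"] += 1
                continue
            if rec.query_sequence is None or rec.cigartuples is None:
                stats["missing_seq"] += 1
                continue
            mate = 1 if rec.is_read2 else 0
            quals = (np.asarray(rec.query_qualities, dtype=np.int16)
                     if rec.query_qualities is not None else None)
            mr = MergedRead(
                qname=rec.query_name, mate=mate, contig=contig,
                pos0=rec.reference_start, cigar=tuple(rec.cigartuples),
                seq=rec.query_sequence, quals=quals,
            )
            if contig == ref.tnxb_name:
                if not rec.is_secondary:
                    tnxb_reads.append(mr)
                continue
            score = rec.get_tag("AS") if rec.has_tag("AS") else 0
            candidates[(rec.query_name, mate)].append((score, contig, mr))

    merged: List[MergedRead] = []
    for key, cands in candidates.items():
        cands.sort(key=lambda t: (-t[0], t[1] != ref.c4a_name))
        score, contig, best = cands[0]
        best.from_short = contig == ref.c4b_name
        best.contig = "C4"
        merged.append(best)
        stats["c4_reads"] += 1
        stats["c4_extra_alignments"] += len(cands) - 1
    stats["tnxb_reads"] = len(tnxb_reads)

    return MergedReadSet(
        reads=merged + tnxb_reads,
        herv_start0=h0_0,
        herv_length=ref.herv_length,
        tnxb_name=ref.tnxb_name,
        stats=dict(stats),
    )


def _walk_read(read: MergedRead, floor: int):
    """Yield per-position evidence of one read as (refpos0, kind, base).

    kind is "base" (with the base character), "del" or "ins" (insertion
    anchored immediately after refpos0).  Soft clips and sub-floor bases
    are skipped.  Positions are on the read's source frame (pre-lift).
    """
    r = read.pos0
    q = 0
    out = []
    for op, ln in read.cigar:
        if op in (0, 7, 8):  # M / = / X
            for k in range(ln):
                if read.quals is None or read.quals[q + k] >= floor:
                    out.append((r + k, "base", read.seq[q + k]))
            r += ln
            q += ln
        elif op == 1:  # I
            if r > read.pos0:
                out.append((r - 1, "ins", None))
            q += ln
        elif op == 2:  # D
            for k in range(ln):
                out.append((r + k, "del", None))
            r += ln
        elif op == 3:  # N
            r += ln
        elif op == 4:  # S
            q += ln
        elif op == 5:  # H
            pass
        else:
            raise ValueError(f"unsupported CIGAR op {op}")
    return out


class DepthTable:
    """Per-position six-way counts for the overall C4 frame and TNXB."""

    def __init__(self, c4: np.ndarray, tnxb: np.ndarray, model: GeneModel):
        self.c4 = np.asarray(c4, dtype=np.int64)
        self.tnxb = np.asarray(tnxb, dtype=np.int64)
        self.model = model
        if self.c4.shape != (model.total_length, 6):
            raise ValueError("C4 count array does not span the overall frame")

    # totals exclude the insertion column: an insertion is evidence of
    # extra sequence after a position, not of coverage at it
    @property
    def total(self) -> np.ndarray:
        return self.c4[:, :5].sum(axis=1)

    @property
    def tnxb_total(self) -> np.ndarray:
        return self.tnxb[:, :5].sum(axis=1)

    def counts_at(self, pos: int) -> dict:
        """Counts at a 1-based overall-frame position."""
        row = self.c4[pos - 1]
        return dict(zip(COLUMNS, (int(x) for x in row)))

    def to_frame(self) -> pd.DataFrame:
        model = self.model
        pos = np.arange(1, model.total_length + 1)
        feats = [str(model.from_absolute(int(p))) for p in pos]
        df = pd.DataFrame(self.c4, columns=list(COLUMNS))
        df.insert(0, "feature_coord", feats)
        df.insert(0, "pos", pos)
        df["total"] = self.total
        return df

    def to_tsv(self, path, tnxb_path=None) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        if tnxb_path is not None:
            df = pd.DataFrame(self.tnxb, columns=list(COLUMNS))
            df.insert(0, "pos", np.arange(1, len(self.tnxb) + 1))
            df["total"] = self.tnxb_total
            df.to_csv(tnxb_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, tnxb_path, model: GeneModel) -> "DepthTable":
        c4 = pd.read_csv(path, sep="\t")[list(COLUMNS)].to_numpy()
        tnxb = pd.read_csv(tnxb_path, sep="\t")[list(COLUMNS)].to_numpy()
        return cls(c4, tnxb, model)


def build_depth_table(
    merged: MergedReadSet,
    model: GeneModel,
    min_base_quality: int = 10,
) -> DepthTable:
    """Pile the merged read set into a :class:`DepthTable`.

    Overlapping mates of one fragment contribute once per position (the
    first mate wins where both cover a position).
    """
    L = model.total_length
    c4 = np.zeros((L, 6), dtype=np.int64)
    tnxb = np.zeros((model.tnxb_length, 6), dtype=np.int64)

    fragments: Dict[tuple, list] = defaultdict(list)
    for read in merged.reads:
        fragments[(read.qname, read.contig == merged.tnxb_name)].append(read)

    for (qname, is_tnxb), reads in fragments.items():
        target = tnxb if is_tnxb else c4
        reads.sort(key=lambda r: r.mate)
        seen: Dict[int, tuple] = {}
        ins_seen = set()
        for read in reads:
            try:
                events = _walk_read(read, min_base_quality)
            except (ValueError, IndexError):
                continue  # malformed CIGAR/sequence: skip the read
            for r0, kind, base in events:
                if read.from_short and kind != "ins":
                    r0 = r0 + merged.herv_length if r0 >= merged.herv_start0 else r0
                if kind == "ins":
                    a0 = (r0 + merged.herv_length
                          if read.from_short and r0 >= merged.herv_start0 else r0)
                    if a0 not in ins_seen:
                        ins_seen.add(a0)
                        target[a0, 5] += 1
                    continue
                if r0 in seen:
                    continue
                seen[r0] = (kind, base)
        for r0, (kind, base) in seen.items():
            if kind == "del":
                target[r0, 4] += 1
            else:
                col = _BASE_COL.get(ord(base))
                if col is not None:
                    target[r0, col] += 1
    return DepthTable(c4, tnxb, model)


# ----------------------------------------------------------------------
# fast path over simulator read blocks
# ----------------------------------------------------------------------

def merge_blocks(blocks: Iterable[ReadBlock], ref: AlignmentReference) -> List[ReadBlock]:
    """Lift each block's position map into the overall frame.

    C4A-origin maps are already overall coordinates; C4B-short maps are
    lifted through the HERV liftover.  TNXB blocks pass through.  Each
    read appears exactly once (the simulator's in-memory representation
    has no secondary placements to deduplicate).
    """
    h0_0 = ref.herv_start - 1
    out = []
    for b in blocks:
        if b.contig == ref.c4b_name:
            pm = b.posmap
            lifted = np.where((pm >= 0) & (pm >= h0_0), pm + ref.herv_length, pm)
            indel = b.indel
            if indel is not None:
                kind, rpos, cpos = indel
                if rpos >= h0_0:
                    rpos += ref.herv_length
                indel = (kind, rpos, cpos)
            b = ReadBlock(**{**b.__dict__, "contig": "C4", "posmap": lifted,
                             "indel": indel})
        elif b.contig == ref.c4a_name:
            b = ReadBlock(**{**b.__dict__, "contig": "C4"})
        out.append(b)
    return out


def _mate_positions(block: ReadBlock, mate: int):
    """(copy positions, validity mask) for one mate, with overlap clipping."""
    rl = block.read_length
    span = block.mate_span_starts(mate)
    pos = span[:, None] + np.arange(rl)
    if mate == 0:
        mask = np.ones_like(pos, dtype=bool)
    else:
        # count R2 only beyond the end of R1
        mask = pos >= (block.starts + rl)[:, None]
    return pos, mask


def _mate_bases(block: ReadBlock, mate: int, pos: np.ndarray) -> np.ndarray:
    bases = block.seq[pos]
    sel = block.err_mate == mate
    bases[block.err_frag[sel], block.err_off[sel]] = block.err_base[sel]
    return bases


def _covers(block: ReadBlock, cpos: int) -> tuple:
    """Masks of fragments whose R1 (resp. clipped R2) covers copy position cpos."""
    rl = block.read_length
    s1 = block.starts
    c1 = (s1 <= cpos) & (cpos < s1 + rl)
    s2 = block.mate_span_starts(1)
    lo2 = np.maximum(s2, s1 + rl)
    c2 = (lo2 <= cpos) & (cpos < s2 + rl)
    return c1, c2


def _covers_range(block: ReadBlock, lo: int, hi: int) -> tuple:
    """Masks of fragments with one mate spanning copy positions [lo, hi]."""
    rl = block.read_length
    s1 = block.starts
    c1 = (s1 <= lo) & (hi < s1 + rl)
    s2 = block.mate_span_starts(1)
    lo2 = np.maximum(s2, s1 + rl)
    c2 = (lo2 <= lo) & (hi < s2 + rl)
    return c1, c2


def build_depth_table_fast(
    blocks: Iterable[ReadBlock],
    model: GeneModel,
) -> DepthTable:
    """Vectorised pileup of merged read blocks (overall frame + TNXB)."""
    L = model.total_length
    c4 = np.zeros((L, 6), dtype=np.int64)
    tnxb = np.zeros((model.tnxb_length, 6), dtype=np.int64)

    for block in blocks:
        if block.n_fragments == 0:
            continue
        if block.contig == model.tnxb_name:
            target, n = tnxb, model.tnxb_length
        elif block.contig == "C4":
            target, n = c4, L
        else:
            raise ValueError(
                f"block on contig {block.contig!r}: merge blocks before piling up")
        for mate in (0, 1):
            pos, mask = _mate_positions(block, mate)
            bases = _mate_bases(block, mate, pos)
            refs = block.posmap[pos]
            valid = mask & (refs >= 0)
            rp = refs[valid]
            bb = bases[valid]
            for code, col in _BASE_COL.items():
                target[:, col] += np.bincount(rp[bb == code], minlength=n)

        if block.indel is not None:
            kind, rpos, cpos = block.indel
            if kind == "ins":
                # a read shows the insertion only if it extends through it:
                # anchor, the inserted bases, and one aligned base beyond
                # (an insertion at a read edge is soft-clipped, not evidence)
                ins_len = int((block.posmap < 0).sum())
                c1a, c2a = _covers_range(block, cpos, cpos + ins_len + 1)
                target[rpos, 5] += int(c1a.sum() + (c2a & ~c1a).sum())
            else:
                # a read shows the deletion if it spans the junction
                c1a, c2a = _covers_range(block, cpos - 1, cpos)
                target[rpos, 4] += int(c1a.sum() + (c2a & ~c1a).sum())
    return DepthTable(c4, tnxb, model)


def _copy_index_of(block: ReadBlock, refpos0: int) -> Optional[int]:
    """Copy-space index mapping to overall-frame position refpos0, if any."""
    pm = block.posmap
    if block.indel is None:
        i = int(np.searchsorted(pm, refpos0))
        if i < len(pm) and pm[i] == refpos0:
            return i
        return None
    valid = np.nonzero(pm >= 0)[0]
    vals = pm[valid]
    i = int(np.searchsorted(vals, refpos0))
    if i < len(vals) and vals[i] == refpos0:
        return int(valid[i])
    return None


def fragment_site_bases(
    blocks: Iterable[ReadBlock],
    positions,
) -> tuple:
    """Per-fragment observed bases at the given overall-frame positions.

    ``positions`` are 1-based overall-frame coordinates.  Returns
    ``(bases, covered)``: uint8 / bool arrays of shape
    ``(n_fragments_total, n_sites)`` over all C4 blocks, with sequencing
    errors applied and overlapping mates counted once (first mate wins).
    Fragments covering no site are omitted.
    """
    positions = [int(p) - 1 for p in positions]
    mats = []
    covs = []
    for block in blocks:
        if block.contig != "C4" or block.n_fragments == 0:
            continue
        nf = block.n_fragments
        bases = np.zeros((nf, len(positions)), dtype=np.uint8)
        cover = np.zeros((nf, len(positions)), dtype=bool)
        for j, p0 in enumerate(positions):
            cpos = _copy_index_of(block, p0)
            if cpos is None:
                continue
            c1, c2 = _covers(block, cpos)
            base = np.full(nf, block.seq[cpos], dtype=np.uint8)
            for mate, cm in ((0, c1), (1, c2 & ~c1)):
                sel = ((block.err_mate == mate)
                       & (block.mate_span_starts(mate)[block.err_frag]
                          + block.err_off == cpos))
                if sel.any():
                    frags = block.err_frag[sel]
                    hit = cm[frags]
                    base[frags[hit]] = block.err_base[sel][hit]
            cov = c1 | c2
            bases[cov, j] = base[cov]
            cover[:, j] = cov
        keep = cover.any(axis=1)
        mats.append(bases[keep])
        covs.append(cover[keep])
    if not mats:
        z = np.zeros((0, len(positions)))
        return z.astype(np.uint8), z.astype(bool)
    return np.concatenate(mats), np.concatenate(covs)


def fragment_window_strings(
    blocks: Iterable[ReadBlock],
    window_positions,
) -> list:
    """Allele strings over ``window_positions`` from single spanning reads.

    Only fragments with one read covering the *entire* window contribute
    (phase across all positions must be directly observed on one
    molecule); returns one string per such fragment.
    """
    positions = [int(p) - 1 for p in window_positions]
    lo_ref, hi_ref = min(positions), max(positions)
    out = []
    for block in blocks:
        if block.contig != "C4" or block.n_fragments == 0:
            continue
        cps = [_copy_index_of(block, p) for p in positions]
        if any(c is None for c in cps):
            continue  # window disrupted on this copy (e.g. indel)
        lo, hi = min(cps), max(cps)
        c1, c2 = _covers_range(block, lo, hi)
        use2 = c2 & ~c1
        nf = block.n_fragments
        bases = np.zeros((nf, len(cps)), dtype=np.uint8)
        for j, cpos in enumerate(cps):
            base = np.full(nf, block.seq[cpos], dtype=np.uint8)
            for mate, cm in ((0, c1), (1, use2)):
                sel = ((block.err_mate == mate)
                       & (block.mate_span_starts(mate)[block.err_frag]
                          + block.err_off == cpos))
                if sel.any():
                    frags = block.err_frag[sel]
                    hit = cm[frags]
                    base[frags[hit]] = block.err_base[sel][hit]
            bases[:, j] = base
        for i in np.nonzero(c1 | use2)[0]:
            out.append(bases[i].tobytes().decode())
    return out
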