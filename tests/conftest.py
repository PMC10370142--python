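import numpy as np
import pysam
import pytest

import c4quant as cq


@pytest.fixture(scope="session")
def model_ref():
    return cq.build_synthetic_reference(seed=1)


@pytest.fixture(scope="session")
def model(model_ref):
    return model_ref[0]


@pytest.fixture(scope="session")
def reference(model_ref):
    return model_ref[1]


@pytest.fixture(scope="session")
def standard_bundle(model_ref):
    """Error-free 4-copy sample (2 A-long, 2 B-short) at 30x per copy."""
    model, ref = model_ref
    h1, h2 = cq.genotype_from_counts(4, 2, 2)
    cfg = cq.SimConfig(hap1=h1, hap2=h2, coverage=30.0, error_rate=0.0, seed=7)
    return cq.simulate_sample(cfg, model, ref)


@pytest.fixture(scope="session")
def standard_sam(standard_bundle, tmp_path_factory):
    path = tmp_path_factory.mktemp("sam") / "standard.sam"
    standard_bundle.write_sam(path)
    return path


def naive_pileup(sam_path, ref, model, min_base_quality=10):
    """Independent brute-force pileup oracle over true-origin records.

    Walks pysam aligned pairs read by read, lifts C4B-short coordinates
    per base, keeps the first mate's evidence where mates overlap, and
    counts bases (at/above the quality floor), deletions, and internal
    insertion events.
    """
    from collections import defaultdict

    L = model.total_length
    c4 = np.zeros((L, 6), dtype=np.int64)
    tnxb = np.zeros((model.tnxb_length, 6), dtype=np.int64)
    col = {"A": 0, "C": 1, "G": 2, "T": 3}
    h0 = ref.herv_start - 1
    hl = ref.herv_length

    frags = defaultdict(list)
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_duplicate:
                continue
            frags[(rec.query_name, rec.reference_name == ref.tnxb_name)].append(rec)

    def lift(r, short):
        return r + hl if short and r >= h0 else r

    for (qname, is_tnxb), recs in frags.items():
        target = tnxb if is_tnxb else c4
        recs.sort(key=lambda r: r.is_read2)
        seen = {}
        ins_seen = set()
        for rec in recs:
            short = rec.reference_name == ref.c4b_name
            seq = rec.query_sequence
            quals = rec.query_qualities
            pairs = rec.get_aligned_pairs()
            last_ref = None
            pending_ins = False
            for qpos, rpos in pairs:
                if rpos is None:
                    # insertion or soft clip: an insertion only if flanked
                    # by aligned bases on both sides
                    if last_ref is not None:
                        pending_ins = True
                    continue
                if qpos is None:  # deletion
                    r = lift(rpos, short)
                    if r not in seen:
                        seen[r] = ("del", None)
                    last_ref = rpos
                    pending_ins = False
                    continue
                if pending_ins:
                    a = lift(last_ref, short)
                    if a not in ins_seen:
                        ins_seen.add(a)
                        target[a, 5] += 1
                    pending_ins = False
                last_ref = rpos
                if quals is not None and quals[qpos] < min_base_quality:
                    continue
                r = lift(rpos, short)
                if r not in seen:
                    seen[r] = ("base", seq[qpos])
        for r, (kind, base) in seen.items():
            if kind == "del":
                target[r, 4] += 1
            elif base in col:
                target[r, col[base]] += 1
    return c4, tnxb
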