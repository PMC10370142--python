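"""End-to-end parameter-recovery panels run against the simulator.

These routines drive the full pipeline (simulate -> merge -> depth table
-> calls) over seeded genotype grids and report recovery statistics.
They back both the acceptance test-suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .copynum import call_profile
from .depth import build_depth_table_fast, merge_blocks, fragment_site_bases
from .model import C4Model
from .phase import call_recombinants, collect_phase_evidence
from .reference import build_synthetic_reference
from .simulate import SimConfig, genotype_from_counts, simulate_sample
from .variants import call_snps

__all__ = [
    "copy_grid",
    "grid_concordance",
    "snp_recovery",
    "recombinant_panel",
    "phasing_completeness_panel",
]

CATEGORIES = ("overall", "A", "B", "Rg", "Ch", "L", "S",
              "functional_A", "functional_B")


def _derive_seed(master: int, *parts: int) -> int:
    x = int(master) & 0xFFFFFFFFFFFFFFFF
    for p in parts:
        x = (x * 6364136223846793005 + int(p) + 1442695040888963407) % 2 ** 64
    return int(x % (2 ** 31 - 1)) + 1


def _fit_profile(bundle, mode="wgs"):
    blocks = merge_blocks(bundle.blocks, bundle.reference)
    table = build_depth_table_fast(blocks, bundle.model)
    return call_profile(table, bundle.model, mode=mode), table, blocks


def copy_grid(
    seed: int = 1,
    overall_range: Sequence[int] = range(0, 9),
    seeds_per: int = 3,
    coverage: float = 30.0,
    error_rate: float = 0.01,
    include_lof: bool = True,
    reference_seed: int = 1,
) -> pd.DataFrame:
    """Copy-number recovery over the full genotype grid.

    For every overall copy number, every C4A/C4B split, every long/short
    split, with and without one loss-of-function allele, ``seeds_per``
    replicates are simulated and called; one row per sample per category
    records truth vs. call.
    """
    model, ref = build_synthetic_reference(seed=reference_seed)
    rows = []
    for n in overall_range:
        lof_opts = [None] + (["auto"] if include_lof and n >= 1 else [])
        for a in range(n + 1):
            for l in range(n + 1):
                for lof in lof_opts:
                    for rep in range(seeds_per):
                        h1, h2 = genotype_from_counts(n, a, l, lof=lof)
                        cfg = SimConfig(
                            hap1=h1, hap2=h2, coverage=coverage,
                            error_rate=error_rate,
                            seed=_derive_seed(seed, n, a, l,
                                              0 if lof is None else 1, rep),
                        )
                        bundle = simulate_sample(cfg, model, ref)
                        profile, _, _ = _fit_profile(bundle)
                        called = profile.as_dict()
                        for cat in CATEGORIES:
                            rows.append({
                                "overall": n, "a": a, "l": l,
                                "lof": lof or "none", "rep": rep,
                                "category": cat,
                                "truth": bundle.truth[cat],
                                "called": called[cat],
                            })
    df = pd.DataFrame(rows)
    df["match"] = df["truth"] == df["called"]
    return df


def grid_concordance(grid: pd.DataFrame) -> float:
    """Fraction of integer calls matching truth (in percent)."""
    return 100.0 * float(grid["match"].mean())


def snp_recovery(
    seed: int = 1,
    n_sites: int = 50,
    overall: int = 4,
    a_copies: int = 2,
    coverage: float = 100.0,
    error_rate: float = 0.0,
    reference_seed: int = 1,
) -> dict:
    """Recovery of randomly injected SNVs at error-free coverage.

    ``n_sites`` variants are injected at random frame positions, each on
    a random subset of 1..overall copies (all copies long, so HERV
    positions are fair game).  Positions within one insert length of the
    frame edge are excluded: the simulator samples fragments from the
    finite segment only, so edge positions lack the coverage that
    flanking reads provide in real data.  Returns sensitivity, the count
    of false positive non-reference calls, and whether all allele-copy
    estimates were exact.
    """
    model, ref = build_synthetic_reference(seed=reference_seed)
    rng = np.random.default_rng(_derive_seed(seed, 91))

    site_abs = {model.site_absolute(s) for s in model.isotype_sites}
    site_abs |= {model.site_absolute(s) for s in model.epitope_sites}
    c4a = ref.sequences[ref.c4a_name]

    margin = 700  # insert mean + sd
    positions = []
    while len(positions) < n_sites:
        p = int(rng.integers(margin + 1, model.total_length - margin + 1))
        if p in site_abs or p in positions:
            continue
        positions.append(p)
    injected = {}
    snvs = {i: [] for i in range(overall)}
    for p in positions:
        ref_base = c4a[p - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref_base])
        n_copies = int(rng.integers(1, overall + 1))
        which = rng.choice(overall, size=n_copies, replace=False)
        for i in which:
            snvs[int(i)].append((p, str(alt)))
        injected[(p, str(alt))] = n_copies

    h1, h2 = genotype_from_counts(overall, a_copies, overall, snvs=snvs)
    cfg = SimConfig(hap1=h1, hap2=h2, coverage=coverage,
                    error_rate=error_rate, seed=_derive_seed(seed, 17))
    bundle = simulate_sample(cfg, model, ref)
    profile, table, _ = _fit_profile(bundle)
    snp = call_snps(table, profile.overall, mode="wgs", model=model, ref=ref)

    # expected non-reference calls: injected SNVs plus the C4B/Chido
    # alleles carried by the B copies at the diagnostic sites
    expected = dict(injected)
    b_copies = overall - a_copies
    if b_copies:
        for s in model.isotype_sites:
            expected[(model.site_absolute(s), s.alleles["B"])] = b_copies
        for s in model.epitope_sites:
            expected[(model.site_absolute(s), s.alleles["Ch"])] = b_copies

    calls = {(int(r.pos), r.allele): int(r.copy)
             for r in snp.itertuples() if r.non_ref}
    detected = sum(1 for k in injected if k in calls)
    copies_exact = all(calls.get(k) == v for k, v in expected.items() if k in calls)
    false_pos = sum(1 for k in calls if k not in expected)
    missed = [k for k in expected if k not in calls]
    return {
        "sensitivity": detected / n_sites,
        "false_positives": false_pos,
        "copies_exact": bool(copies_exact and not missed),
        "n_injected": n_sites,
        "n_detected": detected,
        "overall": profile.overall,
    }


def recombinant_panel(
    seed: int = 1,
    n_replicates: int = 100,
    coverage: float = 30.0,
    error_rate: float = 0.01,
    reference_seed: int = 1,
) -> dict:
    """Recombinant detection and specificity over seeded replicates.

    Simulates ``n_replicates`` carriers each of A-Ch and B-Rg (one
    recombinant copy among overall four) plus ``n_replicates``
    non-recombinant samples, and counts detections and false flags.
    """
    model, ref = build_synthetic_reference(seed=reference_seed)

    def _run(recombinant: Optional[str], rep: int):
        h1, h2 = genotype_from_counts(4, 2, 2, recombinant=recombinant)
        cfg = SimConfig(hap1=h1, hap2=h2, coverage=coverage,
                        error_rate=error_rate,
                        seed=_derive_seed(seed, rep,
                                          {"A-Ch": 1, "B-Rg": 2, None: 3}[recombinant]))
        bundle = simulate_sample(cfg, model, ref)
        profile, _, blocks = _fit_profile(bundle)
        evidence = collect_phase_evidence(blocks, model)
        return call_recombinants(evidence, profile)

    detected = {"A-Ch": 0, "B-Rg": 0}
    for cls in ("A-Ch", "B-Rg"):
        for rep in range(n_replicates):
            call = _run(cls, rep)
            if call.flags[cls]:
                detected[cls] += 1
    false_flags = 0
    for rep in range(n_replicates):
        call = _run(None, rep)
        false_flags += int(call.flags["A-Ch"] or call.flags["B-Rg"])
    return {
        "detected_A_Ch": detected["A-Ch"],
        "detected_B_Rg": detected["B-Rg"],
        "n_replicates": n_replicates,
        "false_flags": false_flags,
    }


def phasing_completeness_panel(
    seed: int = 1,
    n_samples: int = 20,
    coverage: float = 30.0,
    error_rate: float = 0.01,
    reference_seed: int = 1,
) -> dict:
    """Phasing completeness for the canonical pairings on a clean cohort."""
    from .phase import phasing_completeness

    model, ref = build_synthetic_reference(seed=reference_seed)
    calls, profiles = [], []
    for i in range(n_samples):
        h1, h2 = genotype_from_counts(4, 2, 2)
        cfg = SimConfig(hap1=h1, hap2=h2, coverage=coverage,
                        error_rate=error_rate, seed=_derive_seed(seed, 5, i))
        bundle = simulate_sample(cfg, model, ref)
        profile, _, blocks = _fit_profile(bundle)
        evidence = collect_phase_evidence(blocks, model)
        calls.append(call_recombinants(evidence, profile))
        profiles.append(profile)
    return phasing_completeness(calls, profiles)
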