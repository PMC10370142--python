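"""Cohort-level orchestration and reporting.

Aggregates per-sample results into population-stratified copy-number
histograms, an allele-frequency table, a recombinant carrier-frequency
table (carriers / N per population) and the phasing-completeness summary.
Every run also emits a machine-readable metadata record (version, config
hash, thresholds) sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd

from . import __version__
from .model import C4Results
from .phase import phasing_completeness
from .variants import CohortSummary, summarize_cohort

__all__ = ["RunConfig", "CohortTables", "build_cohort_tables", "write_cohort_tables"]

HIST_CATEGORIES = ("overall", "A", "B", "L", "S")


@dataclass
class RunConfig:
    """Serializable run configuration."""

    mode: str = "wgs"
    min_depth: Optional[int] = None
    min_pairs: int = 3
    min_fraction: float = 0.05
    borderline_window: tuple = (0.35, 0.65)
    min_total_copy: int = 10
    reference_fasta: Optional[str] = None
    gene_model_json: Optional[str] = None
    output_dir: Optional[str] = None
    seed: int = 1

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a run configuration from a YAML or JSON file."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)  # JSON is a YAML subset
        if not isinstance(data, dict):
            raise ValueError(f"malformed run config in {path}")
        if "borderline_window" in data:
            data["borderline_window"] = tuple(data["borderline_window"])
        return cls(**data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)

    def metadata(self) -> dict:
        return {"version": __version__, "config_hash": self.config_hash(),
                "config": asdict(self)}


@dataclass
class CohortTables:
    copy_histograms: pd.DataFrame
    summary: Optional[CohortSummary]
    recombinant_carriers: pd.DataFrame
    completeness: dict
    metadata: dict = field(default_factory=dict)


def build_cohort_tables(
    results: Sequence[C4Results],
    populations: Optional[Sequence[str]] = None,
    config: Optional[RunConfig] = None,
) -> CohortTables:
    """Aggregate fitted per-sample results into cohort tables.

    Samples without a population label collapse into a single ``ALL``
    group.  Tables are invariant to sample ordering.
    """
    if len(results) == 0:
        raise ValueError("no samples")
    if populations is None:
        populations = ["ALL"] * len(results)
    config = config or RunConfig()

    order = sorted(range(len(results)),
                   key=lambda i: (populations[i], results[i].profile.overall))
    results = [results[i] for i in order]
    populations = [populations[i] for i in order]

    hist_rows = []
    for pop in sorted(set(populations)):
        idx = [i for i, p in enumerate(populations) if p == pop]
        for cat in HIST_CATEGORIES:
            attr = cat.lower() if cat != "overall" else "overall"
            counts = {}
            for i in idx:
                copy = getattr(results[i].profile, attr)
                key = "no_call" if copy is None else int(copy)
                counts[key] = counts.get(key, 0) + 1
            for copy, n in sorted(counts.items(), key=lambda kv: str(kv[0])):
                hist_rows.append({"population": pop, "category": cat,
                                  "copy": copy, "count": n,
                                  "fraction": n / len(idx)})
    hist = pd.DataFrame(hist_rows)

    summary = None
    if all(r.snp_table is not None for r in results):
        summary = summarize_cohort(
            [r.snp_table for r in results],
            [r.profile.overall for r in results],
            results[0].model.gene_model,
            populations=populations,
            min_total_copy=config.min_total_copy,
        )

    rec_rows = []
    have_phase = [r for r in results if r.recombinants is not None]
    for pop in sorted(set(populations)):
        idx = [i for i, p in enumerate(populations) if p == pop]
        n = len(idx)
        ach = sum(1 for i in idx if results[i].recombinants is not None
                  and results[i].recombinants.flags.get("A-Ch"))
        brg = sum(1 for i in idx if results[i].recombinants is not None
                  and results[i].recombinants.flags.get("B-Rg"))
        rec_rows.append({"population": pop, "A-Ch_carriers": ach,
                         "B-Rg_carriers": brg, "N": n,
                         "A-Ch_carrier_freq": ach / n,
                         "B-Rg_carrier_freq": brg / n})
    recombinants = pd.DataFrame(rec_rows)

    completeness = {}
    if have_phase:
        completeness = phasing_completeness(
            [r.recombinants for r in have_phase],
            [r.profile for r in have_phase])

    return CohortTables(
        copy_histograms=hist, summary=summary,
        recombinant_carriers=recombinants, completeness=completeness,
        metadata=config.metadata(),
    )


def write_cohort_tables(tables: CohortTables, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables.copy_histograms.to_csv(outdir / "copy_histograms.tsv", sep="\t", index=False)
    tables.recombinant_carriers.to_csv(outdir / "recombinant_carriers.tsv",
                                       sep="\t", index=False)
    if tables.summary is not None:
        tables.summary.variants.to_csv(outdir / "variant_frequencies.tsv",
                                       sep="\t", index=False)
        tables.summary.region_table.to_csv(outdir / "variant_regions.tsv",
                                           sep="\t", index=False)
        tables.summary.carrier_curve.to_csv(outdir / "carrier_curve.tsv",
                                            sep="\t", index=False)
    meta = dict(tables.metadata)
    meta["completeness"] = tables.completeness
    with open(outdir / "cohort_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1, default=str)
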