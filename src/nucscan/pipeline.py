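"""End-to-end two-condition comparison runs with a manifest of outputs.

``compare`` does the whole analysis in memory from loaded objects;
``run_compare`` wraps it with file I/O: it loads the genome, annotation
and two fragment BEDs, writes every table/track/gene list to the output
directory and records parameters, input checksums and output paths in a
JSON manifest. Every number in the written report is re-derivable from
the exported machine-readable tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import differential, occupancy, profiles
from .fragments import FragmentSet, coverage_rate, read_fragments
from .genome import (GeneAnnotation, GenomeAssembly, compute_genome_ratios,
                     derive_feature_partition, load_annotation)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one comparison run.

    ``fragments`` maps exactly two condition labels to BED3 paths; the
    first label is condition A throughout the outputs. Defaults: 10-kb
    categorical view at 1.5-fold, 500-bp differential scan at 2-fold,
    1-kb promoters, TSS profile over +/-1 kb in 10-bp bins.
    """

    genome_fasta: str
    annotation: str
    fragments: dict[str, str]
    outdir: str
    coarse_width: int = 10_000
    fine_width: int = 500
    coarse_fold: float = 1.5
    fine_fold: float = 2.0
    promoter_span: int = 1000
    flank: int = 1000
    profile_bin: int = 10
    min_fpkm: float | None = None
    rule: str = "midpoint"
    seed: int = 0

    def __post_init__(self):
        if len(self.fragments) != 2:
            raise ValueError("exactly two conditions required")
        for name in ("coarse_width", "fine_width", "promoter_span", "flank",
                     "profile_bin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.coarse_fold <= 0 or self.fine_fold <= 0:
            raise ValueError("fold thresholds must be positive")

    @property
    def conditions(self) -> tuple[str, str]:
        labels = tuple(self.fragments)
        return labels  # insertion order: first = A, second = B

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _md5(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def compare(genome: GenomeAssembly, ann: GeneAnnotation,
            frags: dict[str, FragmentSet], cfg: RunConfig) -> dict:
    """Run the full comparison in memory; returns a dict of results.

    Keys: coverage, classified (10-kb table) and category_counts,
    diff_windows (500-bp table), genome_ratios, region_ratios,
    gc_quintiles, tss_profiles, landmarks, genes_genic, genes_promoter,
    tracks (fine-grid OccupancyTrack per condition).
    """
    la, lb = cfg.conditions
    results: dict = {"conditions": (la, lb)}

    results["coverage"] = {lab: coverage_rate(fs, genome)
                           for lab, fs in frags.items()}

    coarse_grid = occupancy.make_windows(genome, cfg.coarse_width)
    fine_grid = occupancy.make_windows(genome, cfg.fine_width)
    coarse = {lab: occupancy.occupancy_track(fs, coarse_grid, cfg.rule, lab)
              for lab, fs in frags.items()}
    fine = {lab: occupancy.occupancy_track(fs, fine_grid, cfg.rule, lab)
            for lab, fs in frags.items()}
    results["tracks"] = fine

    classified = differential.classify_bins(coarse[la], coarse[lb], cfg.coarse_fold)
    results["classified"] = classified
    results["category_counts"] = differential.category_counts(classified)

    wins = differential.differential_windows(fine[la], fine[lb], cfg.fine_fold,
                                             cfg.min_fpkm)
    results["diff_windows"] = wins
    results["genes_genic"] = differential.map_windows_to_genes(
        wins, ann, "genic", cfg.promoter_span)
    results["genes_promoter"] = differential.map_windows_to_genes(
        wins, ann, "promoter", cfg.promoter_span)

    partition = derive_feature_partition(ann, genome, cfg.promoter_span)
    genome_ratios = compute_genome_ratios(partition)
    region = genome_ratios.rename(columns={"percent": "genome_percent"})
    for lab, fs in frags.items():
        rr = occupancy.region_occupancy_ratio(fs, partition, cfg.rule)
        region[f"percent_{lab}"] = rr["percent"]
    results["genome_ratios"] = genome_ratios
    results["region_ratios"] = region

    results["gc_quintiles"] = profiles.gc_quintile_summary(fine, genome)

    tss = {lab: profiles.tss_metaprofile(fs, ann, genome, cfg.flank,
                                         cfg.profile_bin)
           for lab, fs in frags.items()}
    results["tss_profiles"] = tss
    results["landmarks"] = {lab: profiles.profile_landmarks(p)
                            for lab, p in tss.items()}
    return results


def run_compare(cfg: RunConfig) -> dict:
    """Load inputs, run :func:`compare`, write all outputs plus a manifest.

    Deterministic given the inputs. Any stage error aborts the run with
    the stage name and cause; outputs written before the failure are
    flagged as partial in the manifest.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {k: v for k, v in vars(cfg).items()},
        "inputs": {},
        "outputs": {},
        "complete": False,
    }
    stage = "load inputs"
    try:
        genome = GenomeAssembly.from_fasta(cfg.genome_fasta)
        ann = load_annotation(cfg.annotation, genome)
        frags = {lab: read_fragments(path, genome)
                 for lab, path in cfg.fragments.items()}
        manifest["inputs"] = {
            "genome": {"path": cfg.genome_fasta, "md5": _md5(cfg.genome_fasta)},
            "annotation": {"path": cfg.annotation, "md5": _md5(cfg.annotation)},
            **{f"fragments_{lab}": {"path": p, "md5": _md5(p),
                                    "n_fragments": frags[lab].total}
               for lab, p in cfg.fragments.items()},
        }

        stage = "compare"
        res = compare(genome, ann, frags, cfg)
        la, lb = res["conditions"]

        stage = "write outputs"
        def _save(name: str, writer) -> None:
            path = outdir / name
            writer(path)
            manifest["outputs"][name] = str(path)

        _save("coverage.tsv", lambda p: pd.DataFrame(
            [{"condition": lab, "coverage_rate": rate,
              "definition": "per-base union fraction"}
             for lab, rate in res["coverage"].items()]).to_csv(p, sep="\t", index=False))
        _save("bins_coarse_classified.tsv",
              lambda p: res["classified"].to_csv(p, sep="\t", index=False))
        _save("bins_coarse_category_counts.tsv", lambda p: pd.Series(
            res["category_counts"]).rename_axis("category").rename("n_windows")
            .to_csv(p, sep="\t"))
        _save("differential_windows.tsv",
              lambda p: res["diff_windows"].to_csv(p, sep="\t", index=False))
        _save("differential_windows.bed",
              lambda p: differential.write_windows_bed(res["diff_windows"], p))
        _save("region_ratios.tsv",
              lambda p: res["region_ratios"].to_csv(p, sep="\t", index=False))
        _save("gc_quintiles.tsv",
              lambda p: res["gc_quintiles"].to_csv(p, sep="\t", index=False))
        for lab in (la, lb):
            _save(f"tss_profile_{lab}.tsv", res["tss_profiles"][lab].to_tsv)
            _save(f"occupancy_fine_{lab}.bedgraph", res["tracks"][lab].to_bedgraph)
        _save("tss_landmarks.json", lambda p: Path(p).write_text(
            json.dumps(res["landmarks"], indent=2) + "\n"))
        _save("genes_genic.tsv",
              lambda p: res["genes_genic"].to_csv(p, sep="\t", index=False))
        _save("genes_promoter.tsv",
              lambda p: res["genes_promoter"].to_csv(p, sep="\t", index=False))
        manifest["complete"] = True
    except Exception as exc:
        manifest["error"] = {"stage": stage, "cause": str(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         default=str) + "\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str) + "\n")
    return manifest
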