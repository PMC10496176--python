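"""End-to-end orchestration: exclude -> classify -> prune -> per-site QC,
PCs and association -> meta -> locus survey, with per-stage artifacts and a
JSON manifest whose counts reconcile exactly with the input cohort size."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import io as cio
from .association import CONTRASTS, ContrastInfeasibleError, run_site_gwas
from .enrichment import enrichment_summary, harmonize_and_match
from .meta import flag_significance, meta_analyze
from .sample_qc import (
    DUPLICATE_KINSHIP_THRESHOLD,
    FIRST_DEGREE_KINSHIP_THRESHOLD,
    exclude_ineligible,
    prune_relatives,
)
from .schemes import CATEGORIES, classify_frame, resolve_scheme

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    phenotypes: str
    genotypes: str  # .vcf or dosage .tsv
    out_dir: str
    kinship: Optional[str] = None
    scheme: str = "current"
    literature_loci: Optional[str] = None
    contrasts: Sequence[str] = ("ADLB_vs_ctrl", "AD_vs_ctrl", "LB_vs_ctrl", "ADLB_vs_AD")
    maf_min: float = 0.01
    hwe_p_min: float = 1e-5
    miss_max: float = 0.20
    r2_min: float = 0.8
    gw_threshold: float = 5e-8
    nominal_alpha: float = 0.05
    dup_threshold: float = DUPLICATE_KINSHIP_THRESHOLD
    first_degree_threshold: float = FIRST_DEGREE_KINSHIP_THRESHOLD
    n_pcs: int = 10
    hwe_controls_only: bool = True
    firth_fallback: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> None:
        for name in ("phenotypes", "genotypes"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise PipelineError("config", "missing_path", f"{name}: {p} not found")
        for name in ("kinship", "literature_loci"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError("config", "missing_path", f"{name}: {p} not found")
        for name, lo, hi in [
            ("maf_min", 0.0, 0.5), ("hwe_p_min", 0.0, 1.0),
            ("miss_max", 0.0, 1.0), ("r2_min", 0.0, 1.0),
            ("gw_threshold", 0.0, 1.0), ("nominal_alpha", 0.0, 1.0),
        ]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise PipelineError(
                    "config", "bad_threshold", f"{name}={v} outside [{lo}, {hi}]"
                )
        unknown = [c for c in self.contrasts if c not in CONTRASTS]
        if unknown:
            raise PipelineError("config", "unknown_contrast", f"{unknown}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, write artifacts under config.out_dir, and return
    the manifest (also written as manifest.json)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()},
        "stages": {},
        "warnings": [],
    }

    # --- read inputs
    records, parse_errors = cio.read_phenotypes(config.phenotypes)
    if len(parse_errors):
        parse_errors.to_csv(out / "parse_errors.tsv", sep="\t", index=False)
    gpath = str(config.genotypes)
    try:
        gm = cio.read_vcf(gpath) if gpath.endswith(".vcf") else cio.read_dosage_tsv(gpath)
    except Exception as exc:
        raise PipelineError("read_genotypes", "read_failed", str(exc)) from exc
    manifest["stages"]["input"] = {
        "n_individuals": int(len(records)),
        "n_variants": int(gm.n_variants),
        "n_parse_errors": int(len(parse_errors)),
    }

    # --- exclude
    bad_ids = set(parse_errors["id"]) if len(parse_errors) else set()
    unparseable = records["id"].isin(bad_ids)
    parse_excluded = records[unparseable]
    kept, exclusions = exclude_ineligible(records[~unparseable])
    if len(parse_excluded):
        exclusions = pd.concat(
            [exclusions,
             pd.DataFrame({"id": parse_excluded["id"], "reason": "parse_error"})],
            ignore_index=True,
        )
    exclusions.to_csv(out / "exclusions.tsv", sep="\t", index=False)
    manifest["stages"]["exclude"] = {
        "n_excluded": int(len(exclusions)),
        "n_kept": int(len(kept)),
        "reasons": exclusions["reason"].value_counts().to_dict()
        if len(exclusions) else {},
    }

    # --- classify
    scheme = resolve_scheme(config.scheme)
    kept = kept.copy()
    kept["category"] = classify_frame(kept, scheme)
    counts = kept["category"].value_counts().reindex(CATEGORIES, fill_value=0)
    counts.rename_axis("category").reset_index(name="n").to_csv(
        out / "category_counts.tsv", sep="\t", index=False
    )
    manifest["stages"]["classify"] = {
        "scheme": scheme.name,
        "counts": {k: int(v) for k, v in counts.items()},
        "n_classified": int(
            counts[["AD+LB+", "AD+LB-", "AD-LB+", "AD-LB-"]].sum()
        ),
    }

    # --- prune relatives
    analyzed = kept[~kept["category"].isin(["unclassified", "excluded"])]
    if config.kinship is None:
        manifest["warnings"].append("no kinship table supplied; pruning skipped")
        manifest["stages"]["prune"] = {"skipped": True, "n_removed": 0,
                                       "n_kept": int(len(analyzed))}
    else:
        kinship = cio.read_kinship(config.kinship)
        present = set(analyzed["id"])
        pairs = [
            tuple(row) for row in kinship.itertuples(index=False, name=None)
            if row[0] in present and row[1] in present
        ]
        keep_ids = prune_relatives(
            analyzed,
            pairs,
            dict(zip(analyzed["id"], analyzed["category"])),
            dup_threshold=config.dup_threshold,
            first_degree_threshold=config.first_degree_threshold,
        )
        removed = sorted(present - set(keep_ids))
        pd.DataFrame({"id": removed, "reason": "relative_pruned"}).to_csv(
            out / "pruned.tsv", sep="\t", index=False
        )
        analyzed = analyzed[analyzed["id"].isin(keep_ids)]
        manifest["stages"]["prune"] = {
            "skipped": False,
            "n_removed": len(removed),
            "n_kept": int(len(analyzed)),
        }

    # --- per-site association per contrast
    sites = list(pd.unique(analyzed["site"]))
    meta_tables: dict = {}
    infeasible: list = []
    for cname in config.contrasts:
        site_tables = []
        for site in sites:
            try:
                res = run_site_gwas(
                    analyzed,
                    gm,
                    cname,
                    site=site,
                    n_pcs=config.n_pcs,
                    maf_min=config.maf_min,
                    hwe_p_min=config.hwe_p_min,
                    miss_max=config.miss_max,
                    r2_min=config.r2_min,
                    hwe_controls_only=config.hwe_controls_only,
                    firth_fallback=config.firth_fallback,
                )
            except ContrastInfeasibleError as exc:
                infeasible.append({"contrast": cname, "site": str(site),
                                   "message": str(exc)})
                continue
            cio.write_summary_stats(res, out / f"gwas_{cname}_{site}.tsv")
            site_tables.append(res)
        if not site_tables:
            continue
        meta = flag_significance(
            meta_analyze(site_tables),
            gw_threshold=config.gw_threshold,
            nominal=config.nominal_alpha,
        )
        cio.write_summary_stats(meta, out / f"meta_{cname}.tsv")
        meta_tables[cname] = meta
    manifest["stages"]["association"] = {
        "sites": [str(s) for s in sites],
        "contrasts_run": sorted(meta_tables),
        "infeasible": infeasible,
    }

    # --- locus survey
    if config.literature_loci is not None and meta_tables:
        loci = cio.read_literature_loci(config.literature_loci)
        survey_rows = []
        for cname, meta in meta_tables.items():
            matched = harmonize_and_match(loci, meta)
            matched.insert(0, "contrast", cname)
            survey_rows.append(matched)
            for source, group in matched.groupby("source"):
                tested = group[group["match_status"] == "matched"]
                if len(tested) == 0:
                    continue
                summary = enrichment_summary(
                    tested, alpha=config.nominal_alpha, contrast=cname
                )
                manifest.setdefault("enrichment", []).append(
                    {
                        "contrast": cname,
                        "source": source,
                        "n_tested": summary.n_tested,
                        "n_hits": summary.n_hits,
                        "fraction_pct": summary.fraction_pct,
                        "chance_level_pct": summary.chance_level_pct,
                        "binomial_p": summary.binomial_p,
                    }
                )
        pd.concat(survey_rows, ignore_index=True).to_csv(
            out / "locus_survey.tsv", sep="\t", index=False
        )

    # --- reconciliation: every input individual is accounted for
    n_input = manifest["stages"]["input"]["n_individuals"]
    n_excluded = manifest["stages"]["exclude"]["n_excluded"]
    counts = manifest["stages"]["classify"]["counts"]
    n_unclassified = counts["unclassified"] + counts["excluded"]
    n_pruned = manifest["stages"]["prune"]["n_removed"]
    n_analyzed = manifest["stages"]["prune"]["n_kept"]
    manifest["reconciliation"] = {
        "n_input": n_input,
        "n_excluded": n_excluded,
        "n_unclassified": n_unclassified,
        "n_pruned": n_pruned,
        "n_analyzed": n_analyzed,
        "balanced": bool(
            n_excluded + n_unclassified + n_pruned + n_analyzed == n_input
        ),
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
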