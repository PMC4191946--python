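"""End-to-end orchestration: io -> quality filter -> functional restriction
-> classification -> shared exclusion -> burden test -> prevalence tables ->
SNP tests -> category enrichment -> APOE analyses.

The run is deterministic given its inputs: re-running on identical files
produces byte-identical result tables.  Every removal of a record is
accounted for in the stage counts (inputs equal the sum of stage outcomes),
and any cross-validation failure aborts with a named-stage error after
removing partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
import shutil
from dataclasses import asdict
from typing import Optional

import pandas as pd
import yaml

from .model import (
    AnalysisConfig,
    CohortData,
    DataError,
    Group,
    RunReport,
    VariantStatus,
)
from . import io as rio
from .classify import classify_cohort
from .burden import burden_test
from .association import (
    category_enrichment,
    gene_prevalence,
    prevalence_total,
)
from .apoe import call_apoe, apoe_strata_tests

log = logging.getLogger("raveburden")

__all__ = ["run_pipeline", "load_config", "analyze_cohort"]

_APOE_SNPS = {"rs429358": "d130", "rs7412": "d176"}


def load_config(path: str) -> dict:
    """Read a YAML or JSON pipeline configuration."""
    with open(path) as fh:
        text = fh.read()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise DataError(f"config {path} is not a mapping")
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _fisher_row(name: str, fr) -> dict:
    return {
        "test": name,
        "a": fr.table[0][0], "b": fr.table[0][1],
        "c": fr.table[1][0], "d": fr.table[1][1],
        "p_two_sided": float(f"{fr.p_two_sided:.4g}"),
        "or_cmle": "inf" if math.isinf(fr.or_cmle) else round(fr.or_cmle, 4),
        "ci_low": round(fr.ci_low, 4),
        "ci_high": "inf" if math.isinf(fr.ci_high) else round(fr.ci_high, 4),
        "method": fr.method.value,
        "degenerate": int(fr.degenerate),
    }


def analyze_cohort(
    data: CohortData,
    panel,
    cfg: Optional[AnalysisConfig] = None,
) -> tuple[list, dict]:
    """Run every analysis stage on an in-memory cohort.

    Returns (classifications, results dict).  The pipeline file runner wraps
    this with IO, bookkeeping and output writing.
    """
    cfg = cfg or AnalysisConfig()
    classifications = classify_cohort(data, cfg)

    results: dict = {}
    br = burden_test(data, classifications, panel=panel, cfg=cfg)
    results["burden"] = {
        "gene_set": br.gene_set,
        "case_carriers": br.case_carriers,
        "control_carriers": br.control_carriers,
        "fisher": _fisher_row("burden", br.fisher),
    }
    results["_burden_scores"] = br.scores

    # per-gene prevalence over genes with >=1 qualifying variant
    qual_genes = sorted(
        {
            v.gene
            for v, c in zip(data.variants, classifications)
            if c.status in (VariantStatus.NOVEL, VariantStatus.RARE)
        }
    )
    prev_rows = []
    for gene in qual_genes:
        for group in (Group.CASE, Group.CONTROL):
            row = gene_prevalence(data, classifications, gene, group)
            prev_rows.append(
                {
                    "gene": gene, "group": group.value,
                    "carriers": row.carriers, "cohort_n": row.cohort_n,
                    "prevalence_pct": round(row.prevalence, 2),
                }
            )
    results["prevalence"] = prev_rows
    known = [g.gene for g in panel if "known_als" in g.categories]
    tot = prevalence_total(data, classifications, known, Group.CASE)
    results["prevalence_total_known_cases"] = {
        "carriers": tot.carriers, "cohort_n": tot.cohort_n,
        "prevalence_pct": round(tot.prevalence, 2),
    }

    # category enrichment for every subset tag in the panel
    tags = sorted({t for g in panel for t in g.subsets})
    results["category_enrichment"] = []
    for tag in tags:
        fr, pct = category_enrichment(data, classifications, panel, tag, cfg)
        row = _fisher_row(f"subset:{tag}", fr)
        row.update(pct)
        results["category_enrichment"].append(row)

    # APOE diplotypes and stratified tests, when both tag SNPs are present
    rs_cols = {}
    for j, v in enumerate(data.variants):
        if v.dbsnp_id in _APOE_SNPS:
            rs_cols[_APOE_SNPS[v.dbsnp_id]] = j
    if set(rs_cols) == {"d130", "d176"}:
        dips = [
            call_apoe(
                int(data.genotypes[i, rs_cols["d130"]]),
                int(data.genotypes[i, rs_cols["d176"]]),
                sample_id=s.sample_id,
            )
            for i, s in enumerate(data.samples)
        ]
        results["_apoe_diplotypes"] = dips
        results["apoe"] = [
            dict(_fisher_row(name, fr))
            for name, fr in apoe_strata_tests(dips, data.samples, method=cfg.test_method).items()
        ]
    return classifications, results


def run_pipeline(config: str | dict, outdir: Optional[str] = None) -> RunReport:
    """Execute the full pipeline from a config file or mapping.

    Config keys: ``vcf``, ``annotations``, ``manifest``, ``panel`` (input
    paths), ``outdir`` (output directory, overridable by the argument), and
    optionally ``analysis`` (a mapping of :class:`AnalysisConfig` overrides).
    """
    cfg_dict = load_config(config) if isinstance(config, str) else dict(config)
    outdir = outdir or cfg_dict.get("outdir")
    if not outdir:
        raise DataError("no output directory configured")
    acfg = AnalysisConfig(**cfg_dict.get("analysis", {}))

    report = RunReport(config=cfg_dict)
    report.config_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()

    created = not os.path.isdir(outdir)
    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []
    try:
        inputs = {k: cfg_dict[k] for k in ("vcf", "annotations", "manifest", "panel")}
        for name, path in inputs.items():
            if not os.path.exists(path):
                raise DataError(f"stage io: input {name} not found at {path}")
            report.input_digests[name] = _sha256(path)

        log.info("stage io: reading inputs")
        vcf_data = rio.read_vcf(inputs["vcf"])
        annotations = rio.read_annotations(inputs["annotations"])
        manifest = rio.read_manifest(inputs["manifest"])
        panel = rio.read_panel(inputs["panel"])
        data = rio.assemble_cohort(vcf_data, annotations, manifest)

        report.stage_counts["sites_read"] = len(data.variants)
        report.stage_counts["n_cases"] = data.n_cases
        report.stage_counts["n_controls"] = data.n_controls

        classifications, results = analyze_cohort(data, panel, acfg)
        counts = {s: 0 for s in VariantStatus}
        for c in classifications:
            counts[c.status] += 1
        for status, k in counts.items():
            report.stage_counts[status.value] = k
        for group, key in ((Group.CASE, "novel_case"), (Group.CONTROL, "novel_control")):
            report.stage_counts[key] = sum(
                1
                for c in classifications
                if c.status is VariantStatus.NOVEL and c.attributed_to is group
            )
        if sum(counts.values()) != len(data.variants):
            raise DataError("stage classify: stage counts do not sum to input sites")

        log.info("stage write: emitting result tables")

        def _write(name: str, df: pd.DataFrame) -> None:
            path = os.path.join(outdir, name)
            df.to_csv(path, sep="\t", index=False)
            written.append(path)

        rio.write_variant_table(
            data, classifications, os.path.join(outdir, "classification.tsv")
        )
        written.append(os.path.join(outdir, "classification.tsv"))

        scores = results.pop("_burden_scores")
        _write(
            "burden_scores.tsv",
            pd.DataFrame(
                {"sample_id": list(scores), "score": [round(v, 4) for v in scores.values()]}
            ),
        )
        _write("burden_summary.tsv", pd.DataFrame([results["burden"]["fisher"]]))
        _write("prevalence.tsv", pd.DataFrame(results["prevalence"]))
        _write("category_enrichment.tsv", pd.DataFrame(results["category_enrichment"]))
        dips = results.pop("_apoe_diplotypes", None)
        if dips is not None:
            _write(
                "apoe_diplotypes.tsv",
                pd.DataFrame(
                    [
                        {
                            "sample_id": d.sample_id,
                            "allele1": d.allele1 or ".",
                            "allele2": d.allele2 or ".",
                            "ambiguous": int(d.ambiguous),
                            "called": int(d.called),
                        }
                        for d in dips
                    ]
                ),
            )
            _write("apoe_tests.tsv", pd.DataFrame(results["apoe"]))

        report.results = results
        report.outputs = sorted(os.path.relpath(p, outdir) for p in written)
        report_path = os.path.join(outdir, "run_report.json")
        with open(report_path, "w") as fh:
            json.dump(asdict(report), fh, indent=2, sort_keys=True, default=str)
        report.outputs.append("run_report.json")
        return report
    except Exception:
        # remove partial outputs so a failed run leaves no half-written state
        for p in written:
            if os.path.exists(p):
                os.remove(p)
        if created and os.path.isdir(outdir) and not os.listdir(outdir):
            shutil.rmtree(outdir)
        raise
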