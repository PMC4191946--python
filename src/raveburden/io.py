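"""Readers and writers for the pipeline's external file formats.

Formats (all UTF-8, tab-separated unless noted; ``.`` or an empty cell
means *absent*):

* multi-sample VCFv4 with GT genotypes and the site-level INFO keys
  DP, QD, FS, HaplotypeScore, MQ, MQRankSum, ReadPosRankSum (parsed with
  cyvcf2; multi-allelic records are decomposed into one record per
  alternate allele);
* annotation table: one row per decomposed variant with gene, protein
  change, functional class, database memberships/frequencies and
  in-silico pathogenicity columns;
* population-frequency database: variant key plus dbSNP/ESP6500/1000G
  membership and frequencies;
* sample manifest: case/control status and phenotype fields;
* gene panel: gene with comma-separated category labels and sub-set tags;
* classification table: the analysis output, round-trip stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    MISSING,
    AnnotatedVariant,
    Classification,
    CohortData,
    DataError,
    FunctionalClass,
    Group,
    OnsetSite,
    PanelGene,
    Sample,
    Sex,
    SiteQuality,
)

__all__ = [
    "VcfData",
    "read_vcf",
    "write_vcf",
    "read_annotations",
    "write_annotations",
    "read_manifest",
    "write_manifest",
    "read_panel",
    "write_panel",
    "read_freqdb",
    "write_freqdb",
    "assemble_cohort",
    "write_variant_table",
    "read_variant_table",
]

_NA = ["", "."]

_INFO_KEYS = {
    "qd": "QD",
    "fs": "FS",
    "haplotype_score": "HaplotypeScore",
    "mq": "MQ",
    "mq_rank_sum": "MQRankSum",
    "read_pos_rank_sum": "ReadPosRankSum",
}


@dataclass
class VcfData:
    """Pre-annotation fragment of a cohort: genotypes plus site quality."""

    sample_ids: list[str]
    keys: list[tuple[str, int, str, str]]  # (chrom, pos, ref, alt), 1-based
    genotypes: np.ndarray  # int8 (samples x variants); MISSING = -1
    site_quality: list[SiteQuality]


def read_vcf(path: str) -> VcfData:
    """Read a multi-sample VCF, decomposing multi-allelic records.

    Each alternate allele becomes its own variant; a sample's dosage for
    that variant is the number of copies of that allele in its GT.  A GT
    containing any missing allele yields a missing dosage.  Absent INFO
    keys yield absent site-quality fields.
    """
    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    keys: list[tuple[str, int, str, str]] = []
    cols: list[np.ndarray] = []
    quals: list[SiteQuality] = []
    seen: set[tuple[str, int, str, str]] = set()
    for rec in vcf:
        gts = np.array([g[:2] for g in rec.genotypes], dtype=np.int16)
        any_missing = (gts < 0).any(axis=1)
        info = dict(rec.INFO)
        qfields = {f: info.get(k) for f, k in _INFO_KEYS.items()}
        dp = info.get("DP")
        sq = SiteQuality(
            dp=int(dp) if dp is not None else None,
            qual=float(rec.QUAL) if rec.QUAL is not None else None,
            **{f: (float(v) if v is not None else None) for f, v in qfields.items()},
        )
        for j, alt in enumerate(rec.ALT):
            key = (rec.CHROM, rec.POS, rec.REF, alt)
            if key in seen:
                raise DataError(f"duplicate site {key} in {path}")
            seen.add(key)
            dosage = (gts == (j + 1)).sum(axis=1).astype(np.int8)
            dosage[any_missing] = MISSING
            keys.append(key)
            cols.append(dosage)
            quals.append(sq)
    geno = (
        np.stack(cols, axis=1)
        if cols
        else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    return VcfData(sample_ids=sample_ids, keys=keys, genotypes=geno, site_quality=quals)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _fmt(v, nd=6) -> str:
    if v is None:
        return "."
    if isinstance(v, float):
        return f"{v:.{nd}g}"
    return str(v)


def write_vcf(data: VcfData, path: str) -> None:
    """Write a decomposed cohort fragment as a biallelic-record VCF."""
    lines = ["##fileformat=VCFv4.2"]
    seen_contigs: list[str] = []
    for chrom, _, _, _ in data.keys:
        if chrom not in seen_contigs:
            seen_contigs.append(chrom)
    lines.extend(f"##contig=<ID={c}>" for c in seen_contigs)
    for key, desc in [
        ("DP", "Approximate read depth"),
        ("QD", "Variant confidence normalized by depth"),
        ("FS", "Phred-scaled strand bias"),
        ("HaplotypeScore", "Consistency with at most two haplotypes"),
        ("MQ", "RMS mapping quality"),
        ("MQRankSum", "Mapping-quality rank-sum Z"),
        ("ReadPosRankSum", "Read-position rank-sum Z"),
    ]:
        num_type = "Integer" if key == "DP" else "Float"
        lines.append(
            f'##INFO=<ID={key},Number=1,Type={num_type},Description="{desc}">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(data.sample_ids)
    )
    for j, (chrom, pos, ref, alt) in enumerate(data.keys):
        q = data.site_quality[j]
        info_items = []
        if q.dp is not None:
            info_items.append(f"DP={q.dp}")
        for f, k in _INFO_KEYS.items():
            v = getattr(q, f)
            if v is not None:
                info_items.append(f"{k}={_fmt(v)}")
        info = ";".join(info_items) or "."
        gts = "\t".join(_GT_STR[int(d)] for d in data.genotypes[:, j])
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{_fmt(q.qual)}\t.\t{info}\tGT\t{gts}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# tabular readers/writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=_NA
    )


def _opt_float(v) -> Optional[float]:
    return None if pd.isna(v) else float(v)


def _bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes")
    return bool(v)


ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "protein_change", "functional_class",
    "in_dbsnp", "dbsnp_id", "dbsnp_has_freq", "esp6500_freq", "kg_freq",
    "polyphen_score", "polyphen_label", "sift_label", "mutationtaster_label",
    "phylop_label",
]


def read_annotations(path: str) -> list[AnnotatedVariant]:
    """Read the variant annotation table.

    Empty frequency cells mean absent from that database, never frequency 0.
    """
    df = _read_tsv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"annotation table {path} lacks columns {sorted(missing)}")
    out = []
    valid_classes = {fc.value for fc in FunctionalClass}
    for _, row in df.iterrows():
        fc = row["functional_class"]
        if fc not in valid_classes:
            raise DataError(
                f"unknown functional class {fc!r} (valid: {sorted(valid_classes)})"
            )
        out.append(
            AnnotatedVariant(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                gene=row["gene"],
                protein_change=None if pd.isna(row["protein_change"]) else row["protein_change"],
                functional_class=FunctionalClass(fc),
                in_dbsnp=_bool(row["in_dbsnp"]),
                dbsnp_id=None if pd.isna(row["dbsnp_id"]) else row["dbsnp_id"],
                dbsnp_has_freq=_bool(row["dbsnp_has_freq"]),
                esp_freq=_opt_float(row["esp6500_freq"]),
                kg_freq=_opt_float(row["kg_freq"]),
                polyphen_score=_opt_float(row["polyphen_score"]),
                polyphen_label=None if pd.isna(row["polyphen_label"]) else row["polyphen_label"],
                sift_label=None if pd.isna(row["sift_label"]) else row["sift_label"],
                mutationtaster_label=None if pd.isna(row["mutationtaster_label"]) else row["mutationtaster_label"],
                phylop_label=None if pd.isna(row["phylop_label"]) else row["phylop_label"],
            )
        )
    return out


def write_annotations(variants: Sequence[AnnotatedVariant], path: str) -> None:
    rows = []
    for v in variants:
        rows.append(
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "gene": v.gene,
                "protein_change": v.protein_change or ".",
                "functional_class": v.functional_class.value,
                "in_dbsnp": int(v.in_dbsnp),
                "dbsnp_id": v.dbsnp_id or ".",
                "dbsnp_has_freq": int(v.dbsnp_has_freq),
                "esp6500_freq": _fmt(v.esp_freq),
                "kg_freq": _fmt(v.kg_freq),
                "polyphen_score": _fmt(v.polyphen_score),
                "polyphen_label": v.polyphen_label or ".",
                "sift_label": v.sift_label or ".",
                "mutationtaster_label": v.mutationtaster_label or ".",
                "phylop_label": v.phylop_label or ".",
            }
        )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_manifest(path: str) -> list[Sample]:
    df = _read_tsv(path)
    required = {"sample_id", "group", "sex", "onset_site", "age_of_onset", "long_survivor"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"manifest {path} lacks columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        try:
            group = Group(row["group"])
        except ValueError:
            raise DataError(f"unknown group {row['group']!r} for {row['sample_id']}")
        sex = Sex(row["sex"]) if not pd.isna(row["sex"]) else Sex.UNKNOWN
        onset = (
            OnsetSite(row["onset_site"])
            if not pd.isna(row["onset_site"])
            else OnsetSite.UNKNOWN
        )
        out.append(
            Sample(
                sample_id=row["sample_id"],
                group=group,
                sex=sex,
                onset_site=onset,
                age_of_onset=_opt_float(row["age_of_onset"]),
                long_survivor=_bool(row["long_survivor"]),
            )
        )
    return out


def write_manifest(samples: Sequence[Sample], path: str) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "group": s.group.value,
            "sex": s.sex.value,
            "onset_site": s.onset_site.value,
            "age_of_onset": _fmt(s.age_of_onset),
            "long_survivor": int(s.long_survivor),
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_panel(path: str) -> list[PanelGene]:
    df = _read_tsv(path)
    required = {"gene", "categories"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"panel {path} lacks columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        cats = frozenset(
            c.strip() for c in str(row["categories"]).split(",") if c.strip()
        )
        subsets = frozenset()
        if "subsets" in df.columns and not pd.isna(row.get("subsets")):
            subsets = frozenset(
                t.strip() for t in str(row["subsets"]).split(",") if t.strip()
            )
        rvis = _opt_float(row["rvis"]) if "rvis" in df.columns else None
        out.append(
            PanelGene(gene=row["gene"], categories=cats, subsets=subsets, rvis=rvis)
        )
    if not out:
        raise DataError(f"panel {path} is empty")
    return out


def write_panel(panel: Sequence[PanelGene], path: str) -> None:
    rows = [
        {
            "gene": g.gene,
            "categories": ",".join(sorted(g.categories)),
            "subsets": ",".join(sorted(g.subsets)) or ".",
            "rvis": _fmt(g.rvis),
        }
        for g in panel
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


FREQDB_COLUMNS = [
    "chrom", "pos", "ref", "alt", "dbsnp_id", "in_dbsnp", "dbsnp_has_freq",
    "esp6500_freq", "kg_freq",
]


def read_freqdb(path: str) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = set(FREQDB_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"frequency database {path} lacks columns {sorted(missing)}")
    df["pos"] = df["pos"].astype(int)
    for col in ("esp6500_freq", "kg_freq"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("in_dbsnp", "dbsnp_has_freq"):
        df[col] = df[col].map(_bool)
    return df


def write_freqdb(df: pd.DataFrame, path: str) -> None:
    out = df.copy()
    for col in ("esp6500_freq", "kg_freq"):
        out[col] = out[col].map(lambda v: _fmt(None if pd.isna(v) else float(v)))
    for col in ("in_dbsnp", "dbsnp_has_freq"):
        out[col] = out[col].astype(int)
    out["dbsnp_id"] = out["dbsnp_id"].fillna(".")
    out[FREQDB_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# assembly and result tables
# ---------------------------------------------------------------------------

def assemble_cohort(
    vcf_data: VcfData,
    annotations: Sequence[AnnotatedVariant],
    manifest: Sequence[Sample],
) -> CohortData:
    """Join VCF genotypes, annotations and manifest into a CohortData.

    Every VCF sample must appear in the manifest and every decomposed VCF
    variant must have an annotation row (joined on chrom, pos, ref, alt).
    Sample order follows the manifest; variant order follows the VCF.
    """
    by_id = {s.sample_id: s for s in manifest}
    for sid in vcf_data.sample_ids:
        if sid not in by_id:
            raise DataError(f"sample {sid!r} present in VCF but missing from manifest")
    ann_by_key = {v.key: v for v in annotations}
    variants = []
    for key in vcf_data.keys:
        if key not in ann_by_key:
            raise DataError(f"variant {key} has no annotation row")
        variants.append(ann_by_key[key])
    manifest_order = [s.sample_id for s in manifest if s.sample_id in set(vcf_data.sample_ids)]
    idx = [vcf_data.sample_ids.index(sid) for sid in manifest_order]
    return CohortData(
        samples=[by_id[sid] for sid in manifest_order],
        variants=variants,
        genotypes=vcf_data.genotypes[idx, :],
        site_quality=list(vcf_data.site_quality),
    )


VARIANT_TABLE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "protein_change", "functional_class",
    "status", "reasons", "case_carriers", "control_carriers",
    "polyphen_score", "polyphen_label",
]


def write_variant_table(
    data: CohortData,
    classifications: Sequence[Classification],
    path: str,
) -> None:
    """Emit the per-variant classification table (one row per variant)."""
    rows = []
    for v, c in zip(data.variants, classifications):
        rows.append(
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "gene": v.gene,
                "protein_change": v.protein_change or ".",
                "functional_class": v.functional_class.value,
                "status": c.status.value,
                "reasons": ";".join(c.reasons) or ".",
                "case_carriers": c.case_carriers,
                "control_carriers": c.control_carriers,
                "polyphen_score": _fmt(v.polyphen_score),
                "polyphen_label": v.polyphen_label or ".",
            }
        )
    pd.DataFrame(rows, columns=VARIANT_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variant_table(path: str) -> pd.DataFrame:
    df = _read_tsv(path)
    df["pos"] = df["pos"].astype(int)
    df["case_carriers"] = df["case_carriers"].astype(int)
    df["control_carriers"] = df["control_carriers"].astype(int)
    return df
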