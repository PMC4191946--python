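"""Synthetic case/control cohort generator.

Generates a gene panel, a population-frequency database, and a genotyped
case/control cohort with the statistical structure the analysis assumes,
so every pipeline stage runs without external data:

* a panel of 169 genes over the four categories (known ALS, associated,
  trios, RRM), with some genes in several categories and sub-set tags
  (stress granule, hnRNP, chromatin);
* database sites per gene: common variants (drawn under Hardy-Weinberg
  equilibrium from their database frequency, identically in both groups),
  rare ESP6500 sites at or below the 0.000538 cutoff — including an anchor
  variant at exactly that frequency (the pathogenic SOD1 p.D91A pattern)
  and a just-above-cutoff site — and 1000 Genomes-only dbSNP entries that
  exercise the unfrequencied-dbSNP rarity rule;
* planted deleterious carriers: each carrier receives a private (singleton)
  novel variant with a probably-damaging PolyPhen-2 score in the burden
  gene set; the case/control carrier odds ratio is the planted theta;
* a planted stress-granule enrichment with the study's carrier rates;
* a two-SNP APOE locus under HWE with planted onset-site and sex effects
  (carrier-phenotype odds ratios are exact by construction: diplotypes are
  drawn with phenotype-dependent reweighting of carrier odds);
* site-quality annotations with a configured fraction of database sites
  violating each hard filter, and a configured missing-genotype rate.

Planted private variants always carry passing quality annotations:
they model confirmed calls, and random quality failures are a property of
background sites.  All randomness flows through one
``numpy.random.Generator`` stream, so a fixed seed reproduces the cohort
bit for bit on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    MISSING,
    AnnotatedVariant,
    CohortData,
    ConfigError,
    FunctionalClass,
    Group,
    OnsetSite,
    PanelGene,
    Sample,
    Sex,
    SiteQuality,
)
from . import io as rio

__all__ = ["SimConfig", "simulate_panel", "simulate_freqdb", "simulate_cohort",
           "simulate_study", "write_study"]

_KNOWN_GENES = [
    "SOD1", "FUS", "ANG", "OPTN", "SETX", "ALS2", "ATXN2", "TAF15", "EWSR1",
    "VAPB", "VCP", "DCTN1", "FIG4", "PRPH", "NEFH", "FGGY", "ERBB4", "SS18L1",
    "UBQLN2", "PFN1", "C9ORF72", "SQSTM1",
]
_ASSOCIATED_GENES = [
    "SPG11", "HFE", "ALAD", "APEX1", "OGG1", "PON1", "PON2", "PON3", "PVR",
    "SOD2", "APOE", "UNC13A", "DPP6", "ITPR2", "ELP3", "GRN", "MAPT",
    "CHMP2B", "SIGMAR1", "PSEN1", "CST3",
]
_TRIO_GENES = ["SRCAP", "AIM1L", "EHMT1", "FOXA1", "HDAC10", "CDH13"]
_RRM_GENES = [
    "HNRNPA1", "HNRNPA2B1", "HNRNPA0", "HNRNPAB", "HNRNPD", "HNRNPDL",
    "TIA1", "RBM33", "CELF4", "SFPQ", "CNOT1",
]

_STRESS_GRANULE = ["TIA1", "TAF15", "EWSR1", "FUS", "ANG", "ATXN2", "PFN1",
                   "RBM33", "CELF4", "SFPQ"]
_HNRNP = [g for g in _RRM_GENES if g.startswith("HNRNP")]
_CHROMATIN = ["SRCAP", "EHMT1", "FOXA1", "HDAC10", "SS18L1"]

_AA = "ARNDCQEGHILKMFPSTWYV"


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the sequenced study: 242 cases (111 female) and 129
    controls (69 female) over a 169-gene panel; planted deleterious-carrier
    odds ratio 1.93 in the known+associated gene set over a control carrier
    probability of 0.22; stress-granule carrier rates 4.13% / 0.78%; APOE
    allele frequencies (e2, e3, e4) = (0.08, 0.78, 0.14) with planted
    e2-upper-limb-onset OR 5.22 and e4-female (limb onset) OR 4.13; the
    ESP6500 anchor variant at frequency exactly 0.000538.
    """

    n_cases: int = 242
    n_controls: int = 129
    n_cases_female: int = 111
    n_controls_female: int = 69
    n_genes: int = 169
    n_known: int = 22
    n_associated: int = 87
    n_trios: int = 30
    n_rrm: int = 30
    common_sites_per_gene: int = 2
    rare_sites_per_gene: int = 1
    kgonly_gene_fraction: float = 0.25
    benign_novel_rate: float = 0.25  # mean benign private novel variants/sample
    control_deleterious_rate: float = 0.22
    burden_or: float = 1.93  # planted theta for deleterious carriers in cases
    burden_gene_categories: tuple[str, ...] = ("known_als", "associated")
    deleterious_stopgain_fraction: float = 0.05
    sg_case_rate: float = 0.0413
    sg_control_rate: float = 0.0078
    apoe_freqs: tuple[float, float, float] = (0.08, 0.78, 0.14)  # e2, e3, e4
    apoe_e2_upper_limb_or: float = 5.22
    apoe_e4_female_limb_or: float = 4.13
    onset_probs: tuple[float, float, float] = (0.35, 0.35, 0.30)  # bulbar, upper_limb, limb
    long_survivor_fraction: float = 1 / 3
    quality_fail_fraction: float = 0.02  # per hard filter, background sites
    missing_rate: float = 0.01
    include_near_cutoff_site: bool = True
    force_shared_variant: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes != self.n_known + self.n_associated + self.n_trios + self.n_rrm:
            raise ConfigError(
                "n_genes must equal the sum of the four category counts"
            )
        for name in (
            "kgonly_gene_fraction", "control_deleterious_rate", "sg_case_rate",
            "sg_control_rate", "quality_fail_fraction", "missing_rate",
            "long_survivor_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name in ("burden_or", "apoe_e2_upper_limb_or", "apoe_e4_female_limb_or"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if abs(sum(self.apoe_freqs) - 1.0) > 1e-9:
            raise ConfigError("APOE allele frequencies must sum to 1")
        if abs(sum(self.onset_probs) - 1.0) > 1e-9:
            raise ConfigError("onset-site probabilities must sum to 1")
        if self.n_cases_female > self.n_cases or self.n_controls_female > self.n_controls:
            raise ConfigError("female counts exceed cohort sizes")
        # implied case carrier probability must be a probability
        if self.case_rate(self.control_deleterious_rate, self.burden_or) >= 1.0:
            raise ConfigError("infeasible theta/control-rate combination")

    @staticmethod
    def case_rate(p0: float, theta: float) -> float:
        """Case carrier probability implied by control rate p0 and odds ratio."""
        if p0 >= 1.0:
            return 1.0
        odds = theta * p0 / (1.0 - p0)
        return odds / (1.0 + odds)

    @classmethod
    def reduced(cls, **overrides) -> "SimConfig":
        """A small-panel configuration for replicated simulations.

        Cohort sizes and planted rates keep their study defaults; only the
        panel and per-gene site counts shrink.
        """
        base = dict(
            n_genes=16, n_known=6, n_associated=6, n_trios=2, n_rrm=2,
            common_sites_per_gene=1, rare_sites_per_gene=0,
            kgonly_gene_fraction=0.0, benign_novel_rate=0.05,
            quality_fail_fraction=0.0, missing_rate=0.0,
            sg_case_rate=0.0, sg_control_rate=0.0,
        )
        base.update(overrides)
        return cls(**base)


def _names(real: list[str], n: int, prefix: str) -> list[str]:
    if n <= len(real):
        return real[:n]
    return real + [f"{prefix}{i:03d}" for i in range(1, n - len(real) + 1)]


def simulate_panel(cfg: SimConfig, seed: Optional[int] = None) -> list[PanelGene]:
    """Build the gene panel: four categories, overlaps, sub-set tags, RVIS."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    groups = {
        "known_als": _names(_KNOWN_GENES, cfg.n_known, "KALS"),
        "associated": _names(_ASSOCIATED_GENES, cfg.n_associated, "ASG"),
        "trios": _names(_TRIO_GENES, cfg.n_trios, "TRI"),
        "rrm": _names(_RRM_GENES, cfg.n_rrm, "RRM"),
    }
    cats: dict[str, set[str]] = {}
    for cat, genes in groups.items():
        for g in genes:
            cats.setdefault(g, set()).add(cat)
    # multi-category overlaps: the FET-family pattern (known genes that also
    # contain an RRM)
    for g in ("FUS", "TAF15", "EWSR1", "ATXN2"):
        if g in cats:
            cats[g].add("rrm")
    panel = []
    for g in sorted(cats):
        subsets = set()
        if g in _STRESS_GRANULE:
            subsets.add("stress_granule")
        if g in _HNRNP:
            subsets.add("hnrnp")
        if g in _CHROMATIN:
            subsets.add("chromatin")
        rvis = float(np.round(rng.normal(-0.5, 1.0), 2))
        if g == "SRCAP":
            rvis = -4.14
        elif g == "SOD1":
            rvis = -0.08
        panel.append(
            PanelGene(
                gene=g,
                categories=frozenset(cats[g]),
                subsets=frozenset(subsets),
                rvis=rvis,
            )
        )
    return panel


def _gene_layout(panel: Sequence[PanelGene]) -> dict[str, tuple[str, int]]:
    """Deterministic (chrom, base position) per gene."""
    layout = {}
    for i, g in enumerate(panel):
        layout[g.gene] = (f"chr{i % 22 + 1}", 1_000_000 + i * 100_000)
    return layout


def _protein_change(rng: np.random.Generator, pos: int) -> str:
    a, b = rng.choice(list(_AA), size=2)
    return f"p.{a}{pos % 997 + 1}{b}"


def simulate_freqdb(
    panel: Sequence[PanelGene], cfg: SimConfig, seed: Optional[int] = None
) -> tuple[pd.DataFrame, list[AnnotatedVariant]]:
    """Population-frequency database plus annotation rows for its sites.

    Returns the frequency table and matching annotation records.  Includes
    the ESP6500 anchor site at frequency exactly 0.000538 in SOD1 (or the
    first known gene), a just-above-cutoff site, 1000G-only dbSNP entries,
    and common sites in every gene.  Novel-designated positions never
    appear here.
    """
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1)
    layout = _gene_layout(panel)
    rows = []
    annotations = []
    rsid = 10_000

    def add_site(gene, pos_offset, *, esp, kg, in_dbsnp, dbsnp_has_freq,
                 polyphen, dbsnp_id=None, protein_change=None,
                 functional_class=FunctionalClass.NONSYNONYMOUS):
        nonlocal rsid
        chrom, base = layout[gene]
        pos = base + pos_offset
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        if in_dbsnp and dbsnp_id is None:
            rsid += 1
            dbsnp_id = f"rs{rsid}"
        rows.append(
            {
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "dbsnp_id": dbsnp_id or ".", "in_dbsnp": in_dbsnp,
                "dbsnp_has_freq": dbsnp_has_freq,
                "esp6500_freq": esp, "kg_freq": kg,
            }
        )
        label = "D" if (polyphen or 0) >= 0.85 else ("P" if (polyphen or 0) >= 0.5 else "B")
        annotations.append(
            AnnotatedVariant(
                chrom=chrom, pos=pos, ref=str(ref), alt=str(alt), gene=gene,
                protein_change=protein_change or _protein_change(rng, pos),
                functional_class=functional_class,
                in_dbsnp=in_dbsnp, dbsnp_id=dbsnp_id,
                dbsnp_has_freq=dbsnp_has_freq,
                esp_freq=esp, kg_freq=kg,
                polyphen_score=polyphen,
                polyphen_label=label if polyphen is not None else None,
            )
        )

    anchor_gene = "SOD1" if any(g.gene == "SOD1" for g in panel) else panel[0].gene
    add_site(
        anchor_gene, 91, esp=0.000538, kg=None, in_dbsnp=True,
        dbsnp_has_freq=True, polyphen=0.99, dbsnp_id="rs80265967",
        protein_change="p.D91A",
    )
    if cfg.include_near_cutoff_site:
        near_gene = "HNRNPA0" if any(g.gene == "HNRNPA0" for g in panel) else panel[-1].gene
        add_site(
            near_gene, 187, esp=0.000625, kg=None, in_dbsnp=True,
            dbsnp_has_freq=True, polyphen=float(np.round(rng.beta(2, 5), 4)),
            dbsnp_id="rs201091840", protein_change="p.G187S",
        )
    for i, g in enumerate(panel):
        for s in range(cfg.common_sites_per_gene):
            f = float(np.round(rng.uniform(0.01, 0.5), 4))
            add_site(
                g.gene, 200 + s * 100,
                esp=f, kg=float(np.round(min(0.999, f * rng.uniform(0.8, 1.2)), 4)),
                in_dbsnp=True, dbsnp_has_freq=True,
                polyphen=float(np.round(rng.beta(1, 8), 4)),
            )
        for s in range(cfg.rare_sites_per_gene):
            f = float(np.round(rng.uniform(0.0001, 0.000538), 6))
            damaging = rng.random() < 0.3
            score = rng.uniform(0.85, 1.0) if damaging else rng.beta(2, 5)
            add_site(
                g.gene, 500 + s * 100, esp=f, kg=None,
                in_dbsnp=True, dbsnp_has_freq=True,
                polyphen=float(np.round(score, 4)),
            )
        if rng.random() < cfg.kgonly_gene_fraction:
            add_site(
                g.gene, 800, esp=None,
                kg=float(np.round(rng.uniform(0.001, 0.009), 4)),
                in_dbsnp=True, dbsnp_has_freq=False,
                polyphen=float(np.round(rng.beta(2, 5), 4)),
            )
    return pd.DataFrame(rows, columns=rio.FREQDB_COLUMNS), annotations


# APOE locus constants (GRCh37-like coordinates; the analysis only needs
# two distinct keyed sites)
_APOE_130 = ("chr19", 45411941, "T", "C")  # rs429358, dosage counts e4
_APOE_176 = ("chr19", 45412079, "C", "T")  # rs7412, dosage counts e2

_DIPLOTYPES = [("e2", "e2"), ("e2", "e3"), ("e2", "e4"),
               ("e3", "e3"), ("e3", "e4"), ("e4", "e4")]


def _apoe_diplotype_probs(freqs: tuple[float, float, float]) -> np.ndarray:
    f = {"e2": freqs[0], "e3": freqs[1], "e4": freqs[2]}
    probs = []
    for a, b in _DIPLOTYPES:
        p = f[a] * f[b] * (1 if a == b else 2)
        probs.append(p)
    return np.array(probs)


def _passing_quality(rng: np.random.Generator) -> SiteQuality:
    return SiteQuality(
        dp=int(rng.integers(30, 100)),
        qual=float(np.round(rng.uniform(100, 2000), 1)),
        qd=float(np.round(rng.uniform(5, 30), 2)),
        fs=float(np.round(rng.uniform(0, 20), 2)),
        haplotype_score=float(np.round(rng.uniform(0, 5), 2)),
        mq=float(np.round(rng.uniform(40, 60), 1)),
        mq_rank_sum=float(np.round(rng.normal(0, 2), 2)),
        read_pos_rank_sum=float(np.round(rng.normal(0, 2), 2)),
    )


def _background_quality(rng: np.random.Generator, fail_frac: float) -> SiteQuality:
    q = _passing_quality(rng)
    fails = rng.random(8) < fail_frac
    kw = dict(
        dp=q.dp, qual=q.qual, qd=q.qd, fs=q.fs,
        haplotype_score=q.haplotype_score, mq=q.mq,
        mq_rank_sum=q.mq_rank_sum, read_pos_rank_sum=q.read_pos_rank_sum,
    )
    if fails[0]:
        kw["dp"] = int(rng.integers(0, 5))
    if fails[1]:
        kw["qual"] = float(np.round(rng.uniform(0, 29.9), 1))
    if fails[2]:
        kw["qd"] = float(np.round(rng.uniform(0, 1.9), 2))
    if fails[3]:
        kw["fs"] = float(np.round(rng.uniform(50.1, 200), 1))
    if fails[4]:
        kw["haplotype_score"] = float(np.round(rng.uniform(13.1, 30), 1))
    if fails[5]:
        kw["mq"] = float(np.round(rng.uniform(0, 29.9), 1))
    if fails[6]:
        kw["mq_rank_sum"] = float(np.round(rng.uniform(-20, -12.6), 2))
    if fails[7]:
        kw["read_pos_rank_sum"] = float(np.round(rng.uniform(-15, -8.1), 2))
    return SiteQuality(**kw)


def simulate_cohort(
    panel: Sequence[PanelGene],
    freqdb: pd.DataFrame,
    cfg: SimConfig,
    seed: Optional[int] = None,
    db_annotations: Optional[list[AnnotatedVariant]] = None,
) -> CohortData:
    """Draw a full genotyped cohort with the configured planted structure."""
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 2)
    n_case, n_control = cfg.n_cases, cfg.n_controls
    n = n_case + n_control

    # --- samples -----------------------------------------------------------
    sexes_case = [Sex.FEMALE] * cfg.n_cases_female + [Sex.MALE] * (n_case - cfg.n_cases_female)
    sexes_ctrl = [Sex.FEMALE] * cfg.n_controls_female + [Sex.MALE] * (n_control - cfg.n_controls_female)
    rng.shuffle(sexes_case)
    rng.shuffle(sexes_ctrl)
    onset_levels = [OnsetSite.BULBAR, OnsetSite.UPPER_LIMB, OnsetSite.LIMB]
    onsets = [onset_levels[i] for i in rng.choice(3, size=n_case, p=cfg.onset_probs)]
    n_long = int(round(cfg.long_survivor_fraction * n_case))
    long_flags = np.zeros(n_case, dtype=bool)
    long_flags[rng.choice(n_case, size=n_long, replace=False)] = True
    ages = np.clip(np.round(rng.normal(60, 8, size=n_case)), 44, 82)
    samples = [
        Sample(
            sample_id=f"CASE{i + 1:04d}", group=Group.CASE, sex=sexes_case[i],
            onset_site=onsets[i], age_of_onset=float(ages[i]),
            long_survivor=bool(long_flags[i]),
        )
        for i in range(n_case)
    ] + [
        Sample(sample_id=f"CTRL{i + 1:04d}", group=Group.CONTROL, sex=sexes_ctrl[i])
        for i in range(n_control)
    ]
    case_idx = np.arange(n_case)
    is_case = np.zeros(n, dtype=bool)
    is_case[:n_case] = True

    # --- database sites under HWE, identical in both groups ----------------
    if db_annotations is None:
        raise ConfigError("simulate_cohort needs the annotations from simulate_freqdb")
    db_ann = list(db_annotations)
    freqs = np.array(
        [
            a.esp_freq if a.esp_freq is not None else (a.kg_freq or 0.0)
            for a in db_ann
        ]
    )
    geno_db = rng.binomial(2, freqs[None, :], size=(n, len(db_ann))).astype(np.int8)
    if cfg.missing_rate > 0 and len(db_ann):
        miss = rng.random(geno_db.shape) < cfg.missing_rate
        geno_db[miss] = MISSING

    variants: list[AnnotatedVariant] = list(db_ann)
    columns: list[np.ndarray] = [geno_db[:, j] for j in range(len(db_ann))]
    quality: list[SiteQuality] = [
        _background_quality(rng, cfg.quality_fail_fraction) for _ in db_ann
    ]

    layout = _gene_layout(panel)
    novel_counter: dict[str, int] = {}

    def add_private(gene: str, carriers: Sequence[int], polyphen: Optional[float],
                    functional_class=FunctionalClass.NONSYNONYMOUS) -> None:
        c = novel_counter.get(gene, 0)
        novel_counter[gene] = c + 1
        chrom, base = layout[gene]
        pos = base + 50_000 + c
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        label = None
        if polyphen is not None:
            label = "D" if polyphen >= 0.85 else ("P" if polyphen >= 0.5 else "B")
        variants.append(
            AnnotatedVariant(
                chrom=chrom, pos=pos, ref=str(ref), alt=str(alt), gene=gene,
                protein_change=_protein_change(rng, pos),
                functional_class=functional_class,
                polyphen_score=polyphen, polyphen_label=label,
            )
        )
        col = np.zeros(n, dtype=np.int8)
        col[list(carriers)] = 1
        columns.append(col)
        quality.append(_passing_quality(rng))

    # --- planted deleterious carriers (the burden signal) ------------------
    burden_genes = [
        g.gene for g in panel if g.categories & set(cfg.burden_gene_categories)
    ]
    if not burden_genes:
        raise ConfigError("no panel gene matches burden_gene_categories")
    p0 = cfg.control_deleterious_rate
    p1 = cfg.case_rate(p0, cfg.burden_or)
    carrier = rng.random(n) < np.where(is_case, p1, p0)
    for i in np.flatnonzero(carrier):
        gene = burden_genes[rng.integers(len(burden_genes))]
        if rng.random() < cfg.deleterious_stopgain_fraction:
            add_private(gene, [i], None, functional_class=FunctionalClass.STOPGAIN)
        else:
            add_private(gene, [i], float(np.round(rng.uniform(0.85, 1.0), 4)))

    # --- benign private novel background ------------------------------------
    all_genes = [g.gene for g in panel]
    counts = rng.poisson(cfg.benign_novel_rate, size=n)
    for i in np.flatnonzero(counts):
        for _ in range(int(counts[i])):
            gene = all_genes[rng.integers(len(all_genes))]
            add_private(gene, [i], float(np.round(rng.beta(1, 8), 4)))

    # --- planted stress-granule enrichment ----------------------------------
    sg_genes = [g.gene for g in panel if "stress_granule" in g.subsets]
    if sg_genes and (cfg.sg_case_rate > 0 or cfg.sg_control_rate > 0):
        sg_carrier = rng.random(n) < np.where(is_case, cfg.sg_case_rate, cfg.sg_control_rate)
        for i in np.flatnonzero(sg_carrier):
            gene = sg_genes[rng.integers(len(sg_genes))]
            add_private(gene, [i], float(np.round(rng.beta(2, 2), 4)))

    # --- forced case-and-control shared novel variant ------------------------
    if cfg.force_shared_variant:
        gene = all_genes[0]
        shared = [0, 1, n_case]  # two cases and one control
        add_private(gene, shared, float(np.round(rng.beta(2, 2), 4)))

    # --- APOE locus ----------------------------------------------------------
    dip_probs = _apoe_diplotype_probs(cfg.apoe_freqs)
    dip_idx = np.empty(n, dtype=int)
    for i in range(n):
        w = dip_probs.copy()
        if is_case[i]:
            s = samples[i]
            for j, (a, b) in enumerate(_DIPLOTYPES):
                if s.onset_site is OnsetSite.UPPER_LIMB and "e2" in (a, b):
                    w[j] *= cfg.apoe_e2_upper_limb_or
                if (
                    s.onset_site is OnsetSite.LIMB
                    and s.sex is Sex.FEMALE
                    and "e4" in (a, b)
                ):
                    w[j] *= cfg.apoe_e4_female_limb_or
        dip_idx[i] = rng.choice(6, p=w / w.sum())
    d130 = np.array(
        [sum(a == "e4" for a in _DIPLOTYPES[k]) for k in dip_idx], dtype=np.int8
    )
    d176 = np.array(
        [sum(a == "e2" for a in _DIPLOTYPES[k]) for k in dip_idx], dtype=np.int8
    )
    e2f, _, e4f = cfg.apoe_freqs
    for (chrom, pos, ref, alt), dos, f, rsid, pc in (
        (_APOE_130, d130, e4f, "rs429358", "p.C130R"),
        (_APOE_176, d176, e2f, "rs7412", "p.R176C"),
    ):
        variants.append(
            AnnotatedVariant(
                chrom=chrom, pos=pos, ref=ref, alt=alt, gene="APOE",
                protein_change=pc, functional_class=FunctionalClass.NONSYNONYMOUS,
                in_dbsnp=True, dbsnp_id=rsid, dbsnp_has_freq=True,
                esp_freq=round(f, 4), kg_freq=round(f, 4),
                polyphen_score=None,
            )
        )
        columns.append(dos.copy())
        quality.append(_passing_quality(rng))

    return CohortData(
        samples=samples,
        variants=variants,
        genotypes=np.stack(columns, axis=1),
        site_quality=quality,
    )


@dataclass
class SimulatedStudy:
    panel: list[PanelGene]
    freqdb: pd.DataFrame
    cohort: CohortData


def simulate_study(cfg: Optional[SimConfig] = None, seed: Optional[int] = None) -> SimulatedStudy:
    """Panel + frequency database + cohort in one call."""
    cfg = cfg or SimConfig()
    panel = simulate_panel(cfg, seed)
    freqdb, annotations = simulate_freqdb(panel, cfg, seed)
    cohort = simulate_cohort(panel, freqdb, cfg, seed, db_annotations=annotations)
    return SimulatedStudy(panel=panel, freqdb=freqdb, cohort=cohort)


def write_study(study: SimulatedStudy, outdir: str) -> dict[str, str]:
    """Write VCF + annotation + frequency + panel + manifest files."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "cohort.vcf"),
        "annotations": os.path.join(outdir, "annotations.tsv"),
        "freqdb": os.path.join(outdir, "freqdb.tsv"),
        "panel": os.path.join(outdir, "panel.tsv"),
        "manifest": os.path.join(outdir, "manifest.tsv"),
    }
    cohort = study.cohort
    vcf_data = rio.VcfData(
        sample_ids=[s.sample_id for s in cohort.samples],
        keys=[v.key for v in cohort.variants],
        genotypes=cohort.genotypes,
        site_quality=cohort.site_quality,
    )
    rio.write_vcf(vcf_data, paths["vcf"])
    rio.write_annotations(cohort.variants, paths["annotations"])
    rio.write_freqdb(study.freqdb, paths["freqdb"])
    rio.write_panel(study.panel, paths["panel"])
    rio.write_manifest(cohort.samples, paths["manifest"])
    return paths
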