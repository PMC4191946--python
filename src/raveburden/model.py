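"""Shared data model for the targeted case/control rare-variant analysis.

The types here mirror the artifacts of a candidate-gene sequencing study:
annotated variant calls joined to a sample manifest, a gene panel with
category labels, and a configuration object holding every numeric threshold
of the analysis (site-quality hard filters, the population-frequency rarity
cutoff, and the PolyPhen-2 carrier threshold).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

MISSING = -1  # sentinel dosage for an uncalled genotype


class RaveBurdenError(Exception):
    """Base class for package errors."""


class DataError(RaveBurdenError):
    """Malformed or contradictory input data."""


class ConfigError(RaveBurdenError):
    """Invalid analysis or simulation configuration."""


class FunctionalClass(str, enum.Enum):
    NONSYNONYMOUS = "nonsynonymous"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    FRAMESHIFT = "frameshift"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: classes retained by the nonsynonymous-only restriction
FUNCTIONAL_CLASSES = frozenset(
    {
        FunctionalClass.NONSYNONYMOUS,
        FunctionalClass.STOPGAIN,
        FunctionalClass.STOPLOSS,
        FunctionalClass.FRAMESHIFT,
    }
)

#: loss-of-function classes that never receive a PolyPhen-2 score
LOF_CLASSES = frozenset({FunctionalClass.STOPGAIN, FunctionalClass.FRAMESHIFT})


class Group(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class OnsetSite(str, enum.Enum):
    BULBAR = "bulbar"
    UPPER_LIMB = "upper_limb"
    LIMB = "limb"
    UNKNOWN = "unknown"


class VariantStatus(str, enum.Enum):
    NOVEL = "novel"
    RARE = "rare"
    EXCLUDED_SHARED = "excluded_shared"
    COMMON = "common"
    FILTERED_QUALITY = "filtered_quality"
    NON_FUNCTIONAL = "non_functional"


class TestMethod(str, enum.Enum):
    MINLIKE = "minlike"
    CENTRAL = "central"


class AggregationMode(str, enum.Enum):
    MAX = "max"
    SUM = "sum"


@dataclass(frozen=True)
class AnnotatedVariant:
    """A decomposed site+allele with gene annotation and database context.

    ``esp_freq``/``kg_freq`` of ``None`` mean *absent from that database*,
    which is distinct from a listed frequency of 0 (a database entry with
    frequency 0 still counts as database membership).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    functional_class: FunctionalClass = FunctionalClass.NONSYNONYMOUS
    protein_change: Optional[str] = None
    in_dbsnp: bool = False
    dbsnp_id: Optional[str] = None
    dbsnp_has_freq: bool = False
    esp_freq: Optional[float] = None
    kg_freq: Optional[float] = None
    polyphen_score: Optional[float] = None
    polyphen_label: Optional[str] = None
    sift_label: Optional[str] = None
    mutationtaster_label: Optional[str] = None
    phylop_label: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("esp_freq", "kg_freq", "polyphen_score"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise DataError(f"{name}={v!r} outside [0, 1] for {self.key}")
        if self.dbsnp_has_freq and not self.in_dbsnp:
            raise DataError(f"dbsnp_has_freq without in_dbsnp for {self.key}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SiteQuality:
    """Site-level quality annotations consumed by the hard filters.

    Absent fields (``None``) never fail their rule.
    """

    dp: Optional[int] = None
    qual: Optional[float] = None
    qd: Optional[float] = None
    fs: Optional[float] = None
    haplotype_score: Optional[float] = None
    mq: Optional[float] = None
    mq_rank_sum: Optional[float] = None
    read_pos_rank_sum: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dp is not None and self.dp < 0:
            raise DataError(f"negative read depth {self.dp}")
        if self.qual is not None and self.qual < 0:
            raise DataError(f"negative QUAL {self.qual}")


@dataclass(frozen=True)
class Sample:
    sample_id: str
    group: Group
    sex: Sex = Sex.UNKNOWN
    onset_site: OnsetSite = OnsetSite.UNKNOWN
    age_of_onset: Optional[float] = None
    long_survivor: bool = False

    def __post_init__(self) -> None:
        if self.group is Group.CONTROL:
            if self.onset_site is not OnsetSite.UNKNOWN or self.age_of_onset is not None:
                raise DataError(
                    f"control sample {self.sample_id} carries phenotype fields"
                )


@dataclass(frozen=True)
class PanelGene:
    """A panel gene with one or more category labels and optional sub-set tags."""

    gene: str
    categories: frozenset[str]
    subsets: frozenset[str] = frozenset()
    rvis: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.categories:
            raise DataError(f"panel gene {self.gene} has no category")


#: the four panel categories
PANEL_CATEGORIES = ("known_als", "associated", "trios", "rrm")


@dataclass
class CohortData:
    """Genotype matrix (samples x variants) joined to manifest and annotation."""

    samples: list[Sample]
    variants: list[AnnotatedVariant]
    genotypes: np.ndarray  # int8, shape (n_samples, n_variants), MISSING = -1
    site_quality: list[SiteQuality]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        ns, nv = self.genotypes.shape
        if ns != len(self.samples) or nv != len(self.variants):
            raise DataError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(self.site_quality) != nv:
            raise DataError("site_quality length does not match variants")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise DataError("dosages must be in {0,1,2,missing}")
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            dup = sorted(k for k in keys if keys.count(k) > 1)[0]
            raise DataError(f"duplicate variant site {dup}")

    @property
    def n_cases(self) -> int:
        return sum(1 for s in self.samples if s.group is Group.CASE)

    @property
    def n_controls(self) -> int:
        return sum(1 for s in self.samples if s.group is Group.CONTROL)

    def group_mask(self, group: Group) -> np.ndarray:
        return np.array([s.group is group for s in self.samples], dtype=bool)


@dataclass
class AnalysisConfig:
    """All thresholds of the analysis; defaults are the study's constants.

    * ``rarity_cutoff`` — ESP6500 frequency at or below which a database-known
      variant counts as rare (the frequency of the pathogenic SOD1 p.D91A allele).
    * ``kg_cutoff`` — 1000 Genomes frequency bound (strict ``<``) for dbSNP
      entries without a listed frequency.
    * ``polyphen_threshold`` — per-individual score at or above which a sample
      counts as a deleterious-variant carrier ("probably damaging").
    * quality thresholds — GATK-style hard filters applied to site records.
    """

    rarity_cutoff: float = 0.000538
    kg_cutoff: float = 0.01
    polyphen_threshold: float = 0.85
    aggregation_mode: AggregationMode = AggregationMode.MAX
    test_method: TestMethod = TestMethod.MINLIKE
    # score policies for the allele-binning step
    missing_score_policy: str = "zero"  # "zero" | "exclude"
    lof_score_policy: str = "one"  # "one" | "zero": stopgain/frameshift score
    # hard-filter thresholds (a site fails if any strict comparison holds)
    dp_min: float = 5.0
    qual_min: float = 30.0
    qd_min: float = 2.0
    fs_max: float = 50.0
    haplotype_score_max: float = 13.0
    mq_min: float = 30.0
    mq_rank_sum_min: float = -12.5
    read_pos_rank_sum_min: float = -8.0
    n_cases: int = 242
    n_controls: int = 129
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rarity_cutoff", "kg_cutoff", "polyphen_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ConfigError("cohort sizes must be positive")
        if self.missing_score_policy not in ("zero", "exclude"):
            raise ConfigError(f"missing_score_policy {self.missing_score_policy!r}")
        if self.lof_score_policy not in ("one", "zero"):
            raise ConfigError(f"lof_score_policy {self.lof_score_policy!r}")
        if isinstance(self.aggregation_mode, str):
            self.aggregation_mode = AggregationMode(self.aggregation_mode)
        if isinstance(self.test_method, str):
            self.test_method = TestMethod(self.test_method)


@dataclass(frozen=True)
class Classification:
    """Final status of one variant plus the rule identifiers that produced it."""

    status: VariantStatus
    reasons: tuple[str, ...] = ()
    case_carriers: int = 0
    control_carriers: int = 0
    attributed_to: Optional[Group] = None


@dataclass(frozen=True)
class FisherResult:
    """Exact 2x2 inference result in the conditional (fixed-margins) framework."""

    table: tuple[tuple[int, int], tuple[int, int]]
    p_two_sided: float
    method: TestMethod
    or_cmle: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


@dataclass(frozen=True)
class PrevalenceRow:
    gene: str
    carriers: int
    cohort_n: int

    @property
    def prevalence(self) -> float:
        """Carrier percentage, 100 * carriers / cohort_n."""
        return 100.0 * self.carriers / self.cohort_n


@dataclass(frozen=True)
class BurdenResult:
    gene_set: str
    scores: dict[str, float]  # sample_id -> aggregated deleteriousness score
    case_carriers: int
    control_carriers: int
    n_cases: int
    n_controls: int
    fisher: FisherResult


@dataclass(frozen=True)
class ApoeDiplotype:
    """An unordered pair of APOE epsilon alleles for one sample."""

    sample_id: str
    allele1: Optional[str]  # "e2" | "e3" | "e4"; None when uncallable
    allele2: Optional[str]
    ambiguous: bool = False
    called: bool = True

    def carries(self, allele: str) -> bool:
        return self.called and allele in (self.allele1, self.allele2)


@dataclass
class RunReport:
    """Bookkeeping of one end-to-end pipeline run."""

    config: dict = field(default_factory=dict)
    config_hash: str = ""
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
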