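"""Risk-association catalog: ingestion, harmonization, selection, pruning.

A catalog row is one study-level SNP-disease association (alleles, odds
ratio, p-value, case/control genotype counts, sample size) of the kind
curated from the genetic-association literature.  This module turns rows
into :class:`RiskAssociation` records, puts study alleles on the reference
strand, selects *cross-ethnic* SNPs (discovered at genome-wide significance
and independently supported in several distinct populations) and
*replicated* SNPs (genome-wide significant in several independent papers),
ranks them by strength of replication, prunes linkage disequilibrium
greedily from the top of that ranking, and quantifies between-study
heterogeneity of allelic odds ratios with Cochran's Q / I².
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    IncompatibleAllelesError,
    InsufficientDataError,
    MissingDataError,
    ParameterError,
    SchemaError,
)
from .frequencies import VALID_BASES, FrequencyTable

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

CATALOG_COLUMNS = [
    "rsid",
    "disease",
    "study_id",
    "population",
    "study_class",
    "risk_allele",
    "other_allele",
    "p_value",
    "odds_ratio",
    "ci_low",
    "ci_high",
    "case_hom_risk",
    "case_het",
    "case_hom_other",
    "control_hom_risk",
    "control_het",
    "control_hom_other",
    "n_total",
]

LD_COLUMNS = ["rsid_a", "rsid_b", "population", "r2"]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclasses.dataclass
class RiskAssociation:
    """One study-level SNP-disease association record."""

    rsid: str
    disease: str
    study_id: str
    population: str
    risk_allele: str
    other_allele: str
    p_value: float
    odds_ratio: float
    ci_low: float | None = None
    ci_high: float | None = None
    case_genotype_counts: tuple[int, int, int] | None = None  # (hom-risk, het, hom-other)
    control_genotype_counts: tuple[int, int, int] | None = None
    n_total: int = 1
    study_class: str = "GWAS"
    ambiguous_strand: bool = False

    def __post_init__(self) -> None:
        if self.risk_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            raise ParameterError(
                f"{self.rsid}: invalid allele(s) ({self.risk_allele}, {self.other_allele})"
            )
        if self.risk_allele == self.other_allele:
            raise ParameterError(f"{self.rsid}: risk and other allele identical")
        if not (0 < self.p_value <= 1):
            raise ParameterError(f"{self.rsid}: p-value {self.p_value} outside (0, 1]")
        if self.odds_ratio <= 0:
            raise ParameterError(f"{self.rsid}: odds ratio {self.odds_ratio} <= 0")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.odds_ratio <= self.ci_high):
                raise ParameterError(
                    f"{self.rsid}: OR {self.odds_ratio} outside CI "
                    f"[{self.ci_low}, {self.ci_high}]"
                )
        for counts in (self.case_genotype_counts, self.control_genotype_counts):
            if counts is not None:
                if len(counts) != 3 or any(c < 0 for c in counts):
                    raise ParameterError(f"{self.rsid}: malformed genotype counts {counts}")
                if sum(counts) < 1:
                    raise ParameterError(f"{self.rsid}: genotype counts sum to 0")
        if self.n_total < 1:
            raise ParameterError(f"{self.rsid}: n_total {self.n_total} < 1")

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.risk_allele] == self.other_allele

    def control_risk_freq(self) -> float | None:
        """Risk-allele frequency in the study's control group, if counts exist."""
        if self.control_genotype_counts is None:
            return None
        hr, het, ho = self.control_genotype_counts
        tot = 2 * (hr + het + ho)
        return (2 * hr + het) / tot if tot else None


@dataclasses.dataclass(frozen=True)
class LDRecord:
    """Pairwise linkage disequilibrium (R²) in one reference panel."""

    rsid_a: str
    rsid_b: str
    population: str
    r2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ParameterError(f"LD r2 {self.r2} outside [0, 1]")


@dataclasses.dataclass
class HeterogeneityResult:
    """Cochran's Q and I² for one SNP across studies."""

    rsid: str
    q_statistic: float
    df: int
    i_squared: float  # percentage in [0, 100]


@dataclasses.dataclass
class EvidenceSummary:
    """Replication evidence for one retained risk allele."""

    rsid: str
    risk_allele: str
    n_studies: int
    n_populations: int
    total_n: int


@dataclasses.dataclass
class LoadReport:
    records: list[RiskAssociation]
    warnings: list[str]

    @property
    def n_loaded(self) -> int:
        return len(self.records)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_counts(row, prefix: str) -> tuple[int, int, int] | None:
    vals = [_opt_float(row.get(f"{prefix}_{g}")) for g in ("hom_risk", "het", "hom_other")]
    if any(v is None for v in vals):
        return None
    return tuple(int(v) for v in vals)  # type: ignore[return-value]


def parse_catalog(path, schema: dict[str, str] | None = None) -> LoadReport:
    """Parse a catalog TSV into records, reporting malformed rows by line.

    ``schema`` optionally maps file column names onto the canonical names in
    :data:`CATALOG_COLUMNS`.  Empty strings denote absent optional fields.
    Rows whose mandatory fields cannot be parsed are skipped with a warning
    carrying the 1-based file line number; a missing required column is
    fatal.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if schema:
        df = df.rename(columns=schema)
    required = [
        "rsid", "disease", "study_id", "population", "risk_allele",
        "other_allele", "p_value", "odds_ratio", "n_total",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"catalog missing required column(s): {missing}")
    records: list[RiskAssociation] = []
    warns: list[str] = []
    for i, row in enumerate(df.to_dict("records")):
        line = i + 2  # 1-based, after the header line
        try:
            rec = RiskAssociation(
                rsid=row["rsid"],
                disease=row["disease"],
                study_id=row["study_id"],
                population=row["population"],
                risk_allele=row["risk_allele"].upper(),
                other_allele=row["other_allele"].upper(),
                p_value=float(row["p_value"]),
                odds_ratio=float(row["odds_ratio"]),
                ci_low=_opt_float(row.get("ci_low")),
                ci_high=_opt_float(row.get("ci_high")),
                case_genotype_counts=_opt_counts(row, "case"),
                control_genotype_counts=_opt_counts(row, "control"),
                n_total=int(float(row["n_total"])),
                study_class=row.get("study_class") or "GWAS",
            )
        except (ValueError, ParameterError) as exc:
            warns.append(f"line {line}: skipped ({exc})")
            continue
        records.append(rec)
    return LoadReport(records=records, warnings=warns)


def load_ld_records(path) -> list[LDRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"LD table missing column(s): {missing}")
    return [
        LDRecord(str(r.rsid_a), str(r.rsid_b), str(r.population), float(r.r2))
        for r in df.itertuples()
    ]


def harmonize_strand(
    assoc: RiskAssociation,
    ref: FrequencyTable,
    ref_population: str,
    maf_margin: float = 0.1,
) -> RiskAssociation:
    """Put the study alleles of one record on the reference (positive) strand.

    Non-palindromic SNPs are resolved by set comparison: if the study alleles
    match the reference alleles they are left unchanged, if they match only
    after complementation both are complemented, otherwise an
    incompatible-alleles error names the rsid.

    Palindromic (A/T, C/G) SNPs are flagged ``ambiguous_strand``; when the
    study's control risk-allele frequency and the reference frequency
    distinguish the two orientations by more than ``maf_margin`` the closer
    orientation is adopted (possibly relabelling which base is the risk
    allele), otherwise the record is left as-is with the flag set so callers
    can exclude it from frequency-based analyses.
    """
    ref_alleles = set(ref.alleles(assoc.rsid))
    study = {assoc.risk_allele, assoc.other_allele}
    comp = {COMPLEMENT[assoc.risk_allele], COMPLEMENT[assoc.other_allele]}

    if assoc.is_palindromic:
        if study != ref_alleles:
            raise IncompatibleAllelesError(
                f"{assoc.rsid}: study alleles {sorted(study)} do not match "
                f"reference alleles {sorted(ref_alleles)}"
            )
        out = dataclasses.replace(assoc, ambiguous_strand=True)
        f_study = assoc.control_risk_freq()
        if f_study is not None:
            f_ref = ref.raf(assoc.rsid, assoc.risk_allele, ref_population)
            d_asis = abs(f_study - f_ref)
            d_flip = abs(f_study - (1.0 - f_ref))
            if abs(d_asis - d_flip) > maf_margin and d_flip < d_asis:
                out = dataclasses.replace(
                    out,
                    risk_allele=COMPLEMENT[assoc.risk_allele],
                    other_allele=COMPLEMENT[assoc.other_allele],
                )
        return out

    if study == ref_alleles:
        return assoc
    if comp == ref_alleles:
        return dataclasses.replace(
            assoc,
            risk_allele=COMPLEMENT[assoc.risk_allele],
            other_allele=COMPLEMENT[assoc.other_allele],
        )
    raise IncompatibleAllelesError(
        f"{assoc.rsid}: study alleles {sorted(study)} match reference alleles "
        f"{sorted(ref_alleles)} neither directly nor via complement"
    )


def _single_disease(assocs: Sequence[RiskAssociation]) -> None:
    diseases = {a.disease for a in assocs}
    if len(diseases) > 1:
        raise ParameterError(f"records span multiple diseases: {sorted(diseases)}")


def _study_significant(a: RiskAssociation, p_gwas: float, p_candidate: float) -> bool:
    thr = p_candidate if a.study_class == "candidate" else p_gwas
    return a.p_value < thr


def select_cross_ethnic(
    assocs: Sequence[RiskAssociation],
    min_populations: int = 5,
    p_discovery: float = 1e-6,
    p_gwas: float = 1e-6,
    p_candidate: float = 0.01,
) -> list[EvidenceSummary]:
    """Select SNPs with cross-ethnic support for one disease.

    A SNP is retained when, for a consistent risk allele, (i) at least one
    association reaches ``p < p_discovery`` and (ii) significant support
    (``p < p_gwas`` for GWAS, ``p < p_candidate`` for candidate studies)
    exists in at least ``min_populations`` *distinct* populations.  Studies
    reporting a different risk allele at the same rsid do not count as
    support.
    """
    _single_disease(assocs)
    by_key: dict[tuple[str, str], list[RiskAssociation]] = {}
    for a in assocs:
        by_key.setdefault((a.rsid, a.risk_allele), []).append(a)

    out: list[EvidenceSummary] = []
    seen: set[str] = set()
    for (rsid, risk_allele), group in by_key.items():
        sig = [a for a in group if _study_significant(a, p_gwas, p_candidate)]
        if not any(a.p_value < p_discovery for a in group):
            continue
        pops = {a.population for a in sig}
        if len(pops) < min_populations:
            continue
        if rsid in seen:  # two alleles both qualifying would be contradictory
            raise ParameterError(f"{rsid}: conflicting risk alleles both pass selection")
        seen.add(rsid)
        studies = {a.study_id for a in sig}
        total_n = sum(
            next(a.n_total for a in sig if a.study_id == s) for s in studies
        )
        out.append(
            EvidenceSummary(
                rsid=rsid,
                risk_allele=risk_allele,
                n_studies=len(studies),
                n_populations=len(pops),
                total_n=total_n,
            )
        )
    return out


def select_replicated(
    assocs: Sequence[RiskAssociation],
    p_threshold: float = 5e-8,
    min_papers: int = 2,
) -> list[EvidenceSummary]:
    """SNPs significant at ``p < p_threshold`` in >= ``min_papers`` distinct papers."""
    _single_disease(assocs)
    by_key: dict[tuple[str, str], list[RiskAssociation]] = {}
    for a in assocs:
        by_key.setdefault((a.rsid, a.risk_allele), []).append(a)
    out: list[EvidenceSummary] = []
    for (rsid, risk_allele), group in by_key.items():
        sig = [a for a in group if a.p_value < p_threshold]
        papers = {a.study_id for a in sig}
        if len(papers) < min_papers:
            continue
        out.append(
            EvidenceSummary(
                rsid=rsid,
                risk_allele=risk_allele,
                n_studies=len(papers),
                n_populations=len({a.population for a in sig}),
                total_n=sum(next(a.n_total for a in sig if a.study_id == s) for s in papers),
            )
        )
    return out


def rank_evidence(summaries: Iterable[EvidenceSummary]) -> list[EvidenceSummary]:
    """Order by replication strength; ties break lexicographically by rsid.

    Sort key: number of studies, then total sample size, then number of
    populations (all descending), then rsid ascending — a total order.
    """
    return sorted(
        summaries,
        key=lambda s: (-s.n_studies, -s.total_n, -s.n_populations, s.rsid),
    )


def ld_prune(
    snps: Sequence[str],
    ld: Iterable[LDRecord],
    r2_threshold: float,
    panel: str,
    strict: bool = True,
) -> list[str]:
    """Greedy LD pruning of a pre-ranked (strongest-first) SNP list.

    Scanning from the top, a SNP is kept unless its R² with an
    already-kept SNP violates the threshold: ``R² > r2_threshold`` when
    ``strict`` (catalog pruning at 0.7), ``R² >= r2_threshold`` otherwise
    (risk-score pruning at 0.3).  Pairs absent from the LD table are
    treated as unlinked.
    """
    if not (0 < r2_threshold <= 1):
        raise ParameterError(f"r2_threshold {r2_threshold} outside (0, 1]")
    pair_r2: dict[frozenset, float] = {}
    for rec in ld:
        if rec.population != panel:
            continue
        key = frozenset((rec.rsid_a, rec.rsid_b))
        pair_r2[key] = max(pair_r2.get(key, 0.0), rec.r2)

    kept: list[str] = []
    for snp in snps:
        linked = False
        for prev in kept:
            r2 = pair_r2.get(frozenset((snp, prev)), 0.0)
            if (r2 > r2_threshold) if strict else (r2 >= r2_threshold):
                linked = True
                break
        if not linked:
            kept.append(snp)
    return kept


def _log_or_se(a: RiskAssociation) -> float | None:
    """Standard error of ln(OR): from the 95% CI, else Woolf's formula."""
    if a.ci_low is not None and a.ci_high is not None and a.ci_low > 0:
        return (math.log(a.ci_high) - math.log(a.ci_low)) / (2 * Z_95)
    if a.case_genotype_counts is None or a.control_genotype_counts is None:
        return None
    chr_, che, cho = a.case_genotype_counts
    tr, te, to = a.control_genotype_counts
    cells = [
        2 * chr_ + che,  # case risk alleles
        2 * cho + che,  # case other alleles
        2 * tr + te,  # control risk alleles
        2 * to + te,  # control other alleles
    ]
    if any(c == 0 for c in cells):
        cells = [c + 0.5 for c in cells]
    return math.sqrt(sum(1.0 / c for c in cells))


def heterogeneity_i2(assocs: Sequence[RiskAssociation]) -> HeterogeneityResult:
    """Between-study heterogeneity of allelic odds ratios for one SNP.

    Fixed-effect Cochran's Q on ln(OR) with inverse-variance weights;
    I² = max(0, (Q - df) / Q) x 100.  The ln(OR) standard error comes from
    the reported 95% CI when present, otherwise from the 2x2 allele counts
    via Woolf's formula (0.5 added to every cell when any cell is zero).
    """
    rsids = {a.rsid for a in assocs}
    if len(rsids) != 1:
        raise ParameterError(f"heterogeneity_i2 expects one rsid, got {sorted(rsids)}")
    rsid = rsids.pop()
    usable = [(math.log(a.odds_ratio), _log_or_se(a)) for a in assocs]
    usable = [(y, se) for y, se in usable if se is not None and se > 0]
    if len(usable) < 2:
        raise InsufficientDataError(
            f"{rsid}: need >= 2 studies with OR and CI (or genotype counts), "
            f"have {len(usable)}"
        )
    y = np.array([u[0] for u in usable])
    w = np.array([1.0 / u[1] ** 2 for u in usable])
    pooled = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - pooled) ** 2))
    df = len(usable) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityResult(rsid=rsid, q_statistic=q, df=df, i_squared=i2)
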