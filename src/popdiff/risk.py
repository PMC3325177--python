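"""Likelihood-ratio genetic risk (PGR), additive risk scores (GRS), and
permutation calibration of inter-population risk contrasts.

The Predicted Genetic Risk of an individual multiplies, over LD-independent
risk loci, the genotype likelihood ratio LR(g) = Pr(g | case) / Pr(g | control)
estimated from published case/control genotype counts (study LRs are combined
with square-root-of-sample-size weights).  The additive Genetic Risk Score
sums risk-allele dosage x ln(OR) instead.

Whether the *population distribution* of PGR is unusually differentiated is
decided by permutation: each permutation swaps every risk locus for a
genomic locus matched on global allele frequency, redraws genotypes for all
individuals from that locus's population-specific frequencies under
Hardy-Weinberg equilibrium, recomputes log PGR with the original LRs, and
records the mean log-PGR contrast of each continental group against all
other individuals.  Because matched loci carry ordinary genome-wide drift,
the permutation p-value asks whether the risk loci are *more* differentiated
than frequency-matched genome SNPs, not whether drift exists at all.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import LDRecord, ld_prune
from .errors import (
    DataError,
    MissingDataError,
    ParameterError,
    SchemaError,
)
from .frequencies import FrequencyTable, RegionMap

GENOTYPES = ("hom_other", "het", "hom_risk")  # index == risk-allele dosage


@dataclasses.dataclass
class LocusRiskModel:
    """Per-genotype likelihood ratios for one risk SNP.

    ``lr_by_genotype`` maps ``hom_risk`` / ``het`` / ``hom_other`` to LR > 0.
    ``ln_or`` (natural-log allelic odds ratio) feeds the additive GRS.
    """

    rsid: str
    risk_allele: str
    lr_by_genotype: dict[str, float]
    n_effective: float = 0.0
    source_populations: tuple[str, ...] = ()
    ln_or: float | None = None
    fallback: bool = False
    continuity_corrected: bool = False

    def __post_init__(self) -> None:
        missing = [g for g in GENOTYPES if g not in self.lr_by_genotype]
        if missing:
            raise ParameterError(f"{self.rsid}: LR missing for genotype(s) {missing}")
        if any(v <= 0 for v in self.lr_by_genotype.values()):
            raise ParameterError(f"{self.rsid}: all LRs must be > 0")

    def ln_lr_by_dosage(self) -> np.ndarray:
        """ln LR indexed by risk-allele dosage 0, 1, 2."""
        return np.log([self.lr_by_genotype[g] for g in GENOTYPES])


@dataclasses.dataclass
class StudyLR:
    """Per-study genotype LRs prior to cross-study combination."""

    rsid: str
    risk_allele: str
    lr_by_genotype: dict[str, float]
    n_total: int
    population: str = ""
    ln_or: float | None = None


@dataclasses.dataclass
class RiskScoreResult:
    individual: str
    population: str
    log_pgr: float
    n_loci_used: int
    grs: float | None = None


def genotype_lr(
    case_counts: tuple[int, int, int],
    control_counts: tuple[int, int, int],
) -> dict[str, float]:
    """Genotype likelihood ratios from case/control genotype counts.

    Counts are ordered (hom-risk, het, hom-other).  LR(g) is the case
    genotype fraction over the control genotype fraction; when any of the
    six cells is zero, 0.5 is added to all six (keeping the LRs finite and
    order-consistent).
    """
    case = np.asarray(case_counts, dtype=float)
    ctrl = np.asarray(control_counts, dtype=float)
    if case.shape != (3,) or ctrl.shape != (3,):
        raise ParameterError("genotype counts must be triples (hom-risk, het, hom-other)")
    if case.sum() < 1 or ctrl.sum() < 1:
        raise DataError("genotype counts sum to zero")
    if np.any(case < 0) or np.any(ctrl < 0):
        raise ParameterError("genotype counts must be non-negative")
    if np.any(case == 0) or np.any(ctrl == 0):
        case = case + 0.5
        ctrl = ctrl + 0.5
    lr = (case / case.sum()) / (ctrl / ctrl.sum())
    return {"hom_risk": float(lr[0]), "het": float(lr[1]), "hom_other": float(lr[2])}


def combine_study_lrs(studies: Sequence[StudyLR]) -> LocusRiskModel:
    """Average per-genotype LRs across studies with sqrt(sample size) weights.

    LR(g) = Σ_s sqrt(n_s) LR_s(g) / Σ_s sqrt(n_s).  All studies must agree
    on the (harmonized) risk allele.  The combined ln(OR) uses the same
    weights over studies that report one.
    """
    if not studies:
        raise ParameterError("no studies to combine")
    rsids = {s.rsid for s in studies}
    if len(rsids) != 1:
        raise ParameterError(f"studies span multiple rsids: {sorted(rsids)}")
    alleles = {s.risk_allele for s in studies}
    if len(alleles) != 1:
        raise DataError(
            f"{studies[0].rsid}: conflicting risk alleles after harmonization: "
            f"{sorted(alleles)}"
        )
    w = np.sqrt([s.n_total for s in studies])
    lrs = {
        g: float(np.sum(w * [s.lr_by_genotype[g] for s in studies]) / w.sum())
        for g in GENOTYPES
    }
    with_or = [(wi, s.ln_or) for wi, s in zip(w, studies) if s.ln_or is not None]
    ln_or = (
        float(sum(wi * v for wi, v in with_or) / sum(wi for wi, _ in with_or))
        if with_or
        else None
    )
    return LocusRiskModel(
        rsid=studies[0].rsid,
        risk_allele=alleles.pop(),
        lr_by_genotype=lrs,
        n_effective=float(sum(s.n_total for s in studies)),
        source_populations=tuple(sorted({s.population for s in studies if s.population})),
        ln_or=ln_or,
    )


def hwe_fallback_model(raf_control: float, odds_ratio: float) -> dict[str, float]:
    """Per-genotype LRs from an allelic OR when genotype counts are absent.

    Control genotype frequencies follow Hardy-Weinberg at ``raf_control``;
    case frequencies follow a multiplicative allelic model (each risk allele
    multiplies the odds by ``odds_ratio``), i.e. case(g) ∝ control(g)·OR^g
    renormalized.  The LR is then OR^g divided by the normalizer — callers
    should mark models built this way as ``fallback``.
    """
    if not (0.0 < raf_control < 1.0):
        raise ParameterError(f"raf_control {raf_control} must be inside (0, 1)")
    if odds_ratio <= 0:
        raise ParameterError(f"odds_ratio {odds_ratio} must be > 0")
    p = raf_control
    control = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])  # dosage 0,1,2
    case = control * odds_ratio ** np.arange(3)
    case /= case.sum()
    lr = case / control
    return {"hom_risk": float(lr[2]), "het": float(lr[1]), "hom_other": float(lr[0])}


# ---------------------------------------------------------------------------
# genotype container


class GenotypeMatrix:
    """Individuals x SNPs risk-allele dosage matrix with population labels.

    ``dosages`` is a DataFrame (individuals x rsids) of 0/1/2 with NaN for
    missing calls; the counted allele per SNP is the harmonized risk allele.
    """

    def __init__(
        self,
        dosages: pd.DataFrame,
        populations: pd.Series,
        counted_allele: Mapping[str, str] | None = None,
    ):
        vals = dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise SchemaError("dosages must be 0, 1, 2 or missing")
        if not dosages.index.equals(populations.index):
            populations = populations.reindex(dosages.index)
            if populations.isna().any():
                missing = list(populations.index[populations.isna()])
                raise SchemaError(f"no population label for individual(s): {missing}")
        self.dosages = dosages.astype(float)
        self.populations = populations.astype(str)
        self.counted_allele = dict(counted_allele or {})

    @property
    def individuals(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def rsids(self) -> list[str]:
        return list(self.dosages.columns)

    @classmethod
    def from_tsv(cls, genotype_path, sample_path) -> "GenotypeMatrix":
        """Long-format TSV: ``individual, rsid, dosage`` + ``individual, population``."""
        geno = pd.read_csv(genotype_path, sep="\t", dtype={"individual": str, "rsid": str})
        for col in ("individual", "rsid", "dosage"):
            if col not in geno.columns:
                raise SchemaError(f"genotype TSV missing column {col!r}")
        wide = geno.pivot(index="individual", columns="rsid", values="dosage")
        samples = _read_sample_map(sample_path)
        return cls(wide, samples.reindex(wide.index))

    @classmethod
    def from_vcf(cls, path, sample_path) -> "GenotypeMatrix":
        """Read dosages of the ALT allele from the GT field of a VCF."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        inds = list(vcf.samples)
        cols: dict[str, np.ndarray] = {}
        counted: dict[str, str] = {}
        for v in vcf:
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            types = v.gt_types
            dos = np.where(types == 3, 2.0, np.where(types == 1, 1.0, 0.0))
            dos = np.where(types == 2, np.nan, dos)
            cols[v.ID] = dos
            counted[v.ID] = v.ALT[0]
        wide = pd.DataFrame(cols, index=inds)
        samples = _read_sample_map(sample_path)
        return cls(wide, samples.reindex(wide.index), counted)


def _read_sample_map(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("individual", "population"):
        if col not in df.columns:
            raise SchemaError(f"sample map missing column {col!r}")
    return df.set_index("individual")["population"]


# ---------------------------------------------------------------------------
# scores


def prune_models(
    models: Sequence[LocusRiskModel],
    ld: Sequence[LDRecord],
    panel: str,
    r2_threshold: float = 0.3,
    strict: bool = False,
) -> list[LocusRiskModel]:
    """LD-prune a list of models (assumed ranked strongest-first).

    Risk-score pruning removes the weaker SNP of any pair with R² >= 0.3 in
    the panel matched to the scored individual's population group.
    """
    kept = set(ld_prune([m.rsid for m in models], ld, r2_threshold, panel, strict=strict))
    return [m for m in models if m.rsid in kept]


def pgr(
    dosages: Mapping[str, float | None],
    models: Sequence[LocusRiskModel],
) -> tuple[float, int]:
    """Log Predicted Genetic Risk of one individual.

    log PGR = Σ over usable loci of ln LR(genotype); loci with missing
    dosage are skipped.  Returns ``(log_pgr, n_loci_used)``.  Models are
    expected to be LD-pruned already (see :func:`prune_models`).
    """
    total, used = 0.0, 0
    for m in models:
        d = dosages.get(m.rsid)
        if d is None or (isinstance(d, float) and math.isnan(d)):
            continue
        total += float(m.ln_lr_by_dosage()[int(d)])
        used += 1
    if used == 0:
        raise DataError("no usable locus: every model SNP is missing a dosage")
    return total, used


def grs(
    dosages: Mapping[str, float | None],
    models: Sequence[LocusRiskModel],
) -> float:
    """Additive Genetic Risk Score: Σ dosage x ln(OR); missing loci skipped."""
    if not models:
        raise ParameterError("no model loci")
    total = 0.0
    for m in models:
        if m.ln_or is None:
            raise ParameterError(f"{m.rsid}: model has no ln(OR) for GRS")
        d = dosages.get(m.rsid)
        if d is None or (isinstance(d, float) and math.isnan(d)):
            continue
        total += float(d) * m.ln_or
    return total


def score_matrix(
    matrix: GenotypeMatrix,
    models: Sequence[LocusRiskModel],
    with_grs: bool = False,
) -> list[RiskScoreResult]:
    """PGR (and optionally GRS) for every individual in a genotype matrix."""
    log_pgr, used = _batch_log_pgr(matrix, models)
    out = []
    for i, ind in enumerate(matrix.individuals):
        if used[i] == 0:
            raise DataError(f"{ind}: no usable locus")
        g = None
        if with_grs:
            g = grs(matrix.dosages.loc[ind].to_dict(), models)
        out.append(
            RiskScoreResult(
                individual=ind,
                population=str(matrix.populations.loc[ind]),
                log_pgr=float(log_pgr[i]),
                n_loci_used=int(used[i]),
                grs=g,
            )
        )
    return out


def _batch_log_pgr(
    matrix: GenotypeMatrix, models: Sequence[LocusRiskModel]
) -> tuple[np.ndarray, np.ndarray]:
    missing = [m.rsid for m in models if m.rsid not in matrix.dosages.columns]
    if missing:
        raise MissingDataError(f"genotype matrix lacks model SNP(s): {missing}")
    D = matrix.dosages[[m.rsid for m in models]].to_numpy(dtype=float)  # n x k
    L = np.stack([m.ln_lr_by_dosage() for m in models])  # k x 3
    mask = ~np.isnan(D)
    idx = np.where(mask, D, 0).astype(int)
    lnlr = np.take_along_axis(L[None, :, :], idx[:, :, None], axis=2)[:, :, 0]
    return np.where(mask, lnlr, 0.0).sum(axis=1), mask.sum(axis=1)


def build_locus_models(records) -> list[LocusRiskModel]:
    """Combine catalog records into one :class:`LocusRiskModel` per rsid.

    Studies with case and control genotype counts contribute
    :func:`genotype_lr` estimates; studies without counts but with a control
    risk-allele frequency are filled in by :func:`hwe_fallback_model` (the
    model is then marked ``fallback``).  Studies providing neither are
    skipped.  Per-study LRs are combined with sqrt(n) weights.
    """
    by_rsid: dict[str, list] = {}
    for rec in records:
        by_rsid.setdefault(rec.rsid, []).append(rec)
    models = []
    for rsid, recs in by_rsid.items():
        studies, fallback = [], False
        for rec in recs:
            if rec.case_genotype_counts and rec.control_genotype_counts:
                lrs = genotype_lr(rec.case_genotype_counts, rec.control_genotype_counts)
            else:
                raf = rec.control_risk_freq()
                if raf is None or not (0 < raf < 1):
                    continue
                lrs = hwe_fallback_model(raf, rec.odds_ratio)
                fallback = True
            studies.append(
                StudyLR(
                    rsid=rsid,
                    risk_allele=rec.risk_allele,
                    lr_by_genotype=lrs,
                    n_total=rec.n_total,
                    population=rec.population,
                    ln_or=math.log(rec.odds_ratio),
                )
            )
        if not studies:
            continue
        model = combine_study_lrs(studies)
        model.fallback = fallback
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# permutation contrast test


@dataclasses.dataclass
class PermutationResult:
    """Observed group contrasts of mean log PGR and their permutation p-values."""

    observed: dict[str, float]  # group -> mean log PGR(group) - mean log PGR(others)
    p_values: dict[str, float]
    null: dict[str, np.ndarray]
    group_means: dict[str, float]
    n_perm: int
    seed: int
    pool_sizes: dict[str, int]  # model rsid -> matched-control pool size


def permutation_contrast_test(
    matrix: GenotypeMatrix,
    models: Sequence[LocusRiskModel],
    region_map: RegionMap,
    table: FrequencyTable,
    groups: Sequence[str] = ("African", "Asian", "European"),
    n_perm: int = 100_000,
    tolerance: float = 0.05,
    seed: int = 0,
    exclusions: Sequence[str] = (),
) -> PermutationResult:
    """Permutation calibration of inter-population log-PGR contrasts.

    Observed statistic per group g: mean log PGR of individuals in g minus
    the mean over all other individuals.  Each permutation replaces every
    model locus with a genomic locus matched on its global mean frequency
    (unweighted mean over the matrix's populations, ± ``tolerance``), draws
    each individual's genotype from the matched locus's population-specific
    frequency under HWE, recomputes log PGR with the ORIGINAL locus LRs,
    and records the three contrasts.  Two-sided p doubles the smaller
    continuity-corrected tail.
    """
    from .differentiation import empirical_two_sided_p

    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; p-values will be coarse", stacklevel=2)
    rng = np.random.default_rng(seed)

    obs_log_pgr, _ = _batch_log_pgr(matrix, models)
    pops = matrix.populations.to_numpy(dtype=object)
    group_of = np.array([region_map.region_of(p) or "" for p in pops], dtype=object)
    in_group = {g: group_of == g for g in groups}
    for g in groups:
        if not in_group[g].any():
            raise DataError(f"no individual belongs to group {g!r}")
    observed = {
        g: float(obs_log_pgr[m].mean() - obs_log_pgr[~m].mean())
        for g, m in in_group.items()
    }
    group_means = {g: float(obs_log_pgr[m].mean()) for g, m in in_group.items()}

    # population-specific frequency matrix over the populations in play
    mat_pops = [p for p in dict.fromkeys(pops)]  # preserve order, unique
    freq = table.freq_matrix()
    absent = [p for p in mat_pops if p not in freq.columns]
    if absent:
        raise MissingDataError(f"frequency table lacks population(s): {absent}")
    F = freq[mat_pops].to_numpy(dtype=float)  # n_snps x n_pops
    complete = ~np.isnan(F).any(axis=1)
    rsid_arr = freq.index.to_numpy(dtype=object)
    model_rsids = {m.rsid for m in models}
    eligible = complete & ~np.isin(rsid_arr, list(model_rsids | set(exclusions)))
    global_a = F.mean(axis=1)  # unweighted global mean frequency of allele_a

    # matched pools, allele-level: either orientation of an eligible SNP
    pop_index = np.array([mat_pops.index(p) for p in pops])
    pool_freqs: list[np.ndarray] = []  # each: m_j x n_pops oriented frequencies
    pool_sizes: dict[str, int] = {}
    for m in models:
        t_rows = np.where(rsid_arr == m.rsid)[0]
        if t_rows.size == 0 or not complete[t_rows[0]]:
            raise MissingDataError(f"{m.rsid}: no complete frequency profile in table")
        fa_t = F[t_rows[0]]
        a, _b = table.alleles(m.rsid)
        target = global_a[t_rows[0]] if m.risk_allele == a else 1.0 - global_a[t_rows[0]]
        match_a = eligible & (np.abs(global_a - target) <= tolerance)
        match_b = eligible & (np.abs(1.0 - global_a - target) <= tolerance)
        both = match_a & match_b
        use_a = match_a & (~both | (np.abs(global_a - target) <= np.abs(1 - global_a - target)))
        use_b = match_b & ~use_a
        stacked = np.vstack([F[use_a], 1.0 - F[use_b]])
        if stacked.shape[0] == 0:
            raise DataError(
                f"{m.rsid}: no control locus matches global frequency "
                f"{target:.3f} ± {tolerance}"
            )
        pool_freqs.append(stacked)
        pool_sizes[m.rsid] = stacked.shape[0]

    L = np.stack([m.ln_lr_by_dosage() for m in models])  # k x 3
    k, n_ind = len(models), len(pops)
    null = {g: np.empty(n_perm) for g in groups}
    chunk = max(1, int(5_000_000 // max(1, k * n_ind)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        # matched locus per (perm, model): population frequencies of risk-role allele
        pmat = np.empty((b, k, n_ind))
        for j, fr in enumerate(pool_freqs):
            pick = rng.integers(0, fr.shape[0], size=b)
            pmat[:, j, :] = fr[pick][:, pop_index]
        dos = rng.binomial(2, pmat)  # b x k x n_ind
        lnlr = np.take_along_axis(L[None, :, :], dos, axis=2)  # b x k x n_ind
        log_pgr = lnlr.sum(axis=1)  # b x n_ind
        for g, m in in_group.items():
            null[g][done : done + b] = log_pgr[:, m].mean(axis=1) - log_pgr[:, ~m].mean(axis=1)
        done += b

    p_values = {g: empirical_two_sided_p(null[g], observed[g]) for g in groups}
    return PermutationResult(
        observed=observed,
        p_values=p_values,
        null=null,
        group_means=group_means,
        n_perm=n_perm,
        seed=seed,
        pool_sizes=pool_sizes,
    )
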