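"""Synthetic multi-population corpus generator.

Emulates, with a known generative model, every input the analysis consumes:

* a genome-wide per-population allele-frequency table under the
  Balding-Nichols model (each population's frequency is Beta-distributed
  around an ancestral frequency, with variance governed by a drift
  parameter F);
* an injectable directional cline at designated "disease" loci — risk-allele
  frequencies raised in a high region (Africa-like) and lowered in a low
  region (East-Asia-like) while reference-region (Europe-like) frequencies
  are left untouched so frequency matching stays valid;
* Hardy-Weinberg genotypes (dosage ~ Binomial(2, population RAF), loci in
  linkage equilibrium);
* case/control association studies whose genotype counts are multinomial
  draws consistent with a stated allelic odds ratio under a multiplicative
  model;
* a risk-association catalog with construction-guaranteed positives and
  decoys for each selection rule, plus a small LD table with planted linked
  pairs.

Defaults mirror the study conditions the analysis targets: an
11-population HapMap-like panel (African/European/Asian regions plus two
unassigned populations), F = 0.05 per-population drift, 10 disease loci
with a ±0.10 injected cline, odds ratios in [1.1, 1.5], and case/control
studies of 2,000 + 2,000 individuals.

The whole corpus is a pure function of :class:`SimulationConfig` (equal
seeds give byte-identical files).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import RiskAssociation, Z_95
from .errors import MissingDataError, ParameterError
from .frequencies import FrequencyTable, RegionMap
from .risk import GenotypeMatrix

HAPMAP_POPULATIONS = (
    "ASW", "MKK", "LWK", "YRI",  # African region
    "TSI", "CEU",  # European region
    "JPT", "CHB", "CHD",  # Asian region
    "GIH", "MEX",  # unassigned to a contrast region
)


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic corpus (defaults = study conditions)."""

    n_genome_snps: int = 5_000
    populations: tuple[str, ...] = HAPMAP_POPULATIONS
    f_drift: float = 0.05
    n_disease_snps: int = 10
    delta_high: float = 0.10
    delta_low: float = -0.10
    or_range: tuple[float, float] = (1.1, 1.5)
    n_individuals_per_pop: int = 50
    n_case: int = 2_000
    n_control: int = 2_000
    n_studies_per_snp: int = 6
    seed: int = 0
    serial_founder: bool = False
    region_scheme: str = "hapmap"
    region_high: str = "African"
    region_low: str = "Asian"
    region_ref: str = "European"

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_drift < 1.0):
            raise ParameterError(f"f_drift {self.f_drift} outside [0, 1)")
        if self.n_disease_snps > self.n_genome_snps:
            raise ParameterError("more disease SNPs than genome SNPs")

    def region_map(self) -> RegionMap:
        return RegionMap.default(self.region_scheme)

    def disease_rsids(self) -> list[str]:
        """Disease loci are the first n_disease_snps of the genome table."""
        return [f"rs{i + 1}" for i in range(self.n_disease_snps)]


def _balding_nichols(rng, ancestral: np.ndarray, f: float) -> np.ndarray:
    """One population's frequencies drifted from ``ancestral`` with parameter F."""
    if f == 0.0:
        return ancestral.copy()
    out = ancestral.copy()
    interior = (ancestral > 0.0) & (ancestral < 1.0)  # fixation is absorbing
    scale = (1.0 - f) / f
    p = ancestral[interior]
    out[interior] = rng.beta(p * scale, (1.0 - p) * scale)
    return out


def simulate_frequency_table(config: SimulationConfig) -> FrequencyTable:
    """Genome-wide per-population frequency table under Balding-Nichols drift.

    Ancestral frequencies are Uniform(0.05, 0.95).  By default every
    population drifts independently from the ancestral frequency (a star
    topology, under which the FST of the panel estimates F directly); with
    ``serial_founder=True`` each population instead drifts from its
    predecessor in ``config.populations``, accumulating differentiation
    along the list to mimic a serial-founder migration cline.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genome_snps
    anc = rng.uniform(0.05, 0.95, size=n)
    rsids = [f"rs{i + 1}" for i in range(n)]
    bases = np.array(list("ACGT"))
    ia = rng.integers(0, 4, size=n)
    ib = (ia + rng.integers(1, 4, size=n)) % 4
    n_chrom = 2 * config.n_individuals_per_pop

    frames = []
    prev = anc
    for pop in config.populations:
        base = prev if config.serial_founder else anc
        f_pop = _balding_nichols(rng, base, config.f_drift)
        frames.append(
            pd.DataFrame(
                {
                    "rsid": rsids,
                    "chrom": "1",
                    "pos": np.arange(1, n + 1) * 1000,
                    "allele_a": bases[ia],
                    "allele_b": bases[ib],
                    "population": pop,
                    "freq_a": f_pop,
                    "n_chromosomes": n_chrom,
                }
            )
        )
        prev = f_pop
    return FrequencyTable(pd.concat(frames, ignore_index=True))


def inject_cline(
    table: FrequencyTable,
    disease_rsids: list[str],
    delta_high: float,
    delta_low: float,
    region_map: RegionMap,
    region_high: str,
    region_low: str,
) -> FrequencyTable:
    """Shift risk-allele (``allele_a``) frequencies at disease loci.

    Adds ``delta_high`` in every high-region population and ``delta_low``
    (typically negative) in every low-region population, clamping to
    [0.01, 0.99]; reference-region frequencies are untouched so European
    frequency matching remains valid.  Warns when clamping hits more than
    10% of the shifted loci.
    """
    df = table.df.copy()
    present = set(df["rsid"])
    absent = [r for r in disease_rsids if r not in present]
    if absent:
        raise MissingDataError(f"disease rsid(s) not in table: {absent}")
    high = set(region_map.populations_in(region_high))
    low = set(region_map.populations_in(region_low))
    is_disease = df["rsid"].isin(disease_rsids)
    shift = np.zeros(len(df))
    shift[is_disease & df["population"].isin(high)] = delta_high
    shift[is_disease & df["population"].isin(low)] = delta_low
    raw = df["freq_a"].to_numpy() + shift
    clipped = np.clip(raw, 0.01, 0.99)
    moved = shift != 0
    n_clamped_loci = df.loc[moved & (raw != clipped), "rsid"].nunique()
    if disease_rsids and n_clamped_loci > 0.10 * len(disease_rsids):
        warnings.warn(
            f"clamping applied at {n_clamped_loci}/{len(disease_rsids)} disease "
            f"loci; the injected shift may be too aggressive",
            stacklevel=2,
        )
    df["freq_a"] = clipped
    return FrequencyTable(df)


def simulate_genotypes(
    table: FrequencyTable,
    n_per_pop: int,
    seed: int,
    rsids: list[str] | None = None,
    populations: list[str] | None = None,
) -> GenotypeMatrix:
    """HWE genotypes: dosage ~ Binomial(2, population frequency of allele_a).

    Loci are drawn independently (linkage equilibrium).  Individuals are
    named ``<POP>_<i>``.
    """
    rng = np.random.default_rng(seed)
    pops = populations or table.populations
    freq = table.freq_matrix()
    if rsids is None:
        rsids = list(freq.index)
    sub = freq.loc[rsids, pops]
    inds, labels, blocks = [], [], []
    for pop in pops:
        p = sub[pop].to_numpy(dtype=float)
        dos = rng.binomial(2, np.broadcast_to(p, (n_per_pop, len(rsids)))).astype(float)
        dos[:, np.isnan(p)] = np.nan
        blocks.append(dos)
        inds.extend(f"{pop}_{i + 1}" for i in range(n_per_pop))
        labels.extend([pop] * n_per_pop)
    dosages = pd.DataFrame(np.vstack(blocks), index=inds, columns=rsids)
    counted = {r: table.alleles(r)[0] for r in rsids}
    return GenotypeMatrix(dosages, pd.Series(labels, index=inds), counted)


def simulate_case_control_study(
    raf_control: float,
    odds_ratio: float,
    n_case: int,
    n_control: int,
    seed: int,
    rsid: str = "rs1",
    disease: str = "disease",
    study_id: str = "study1",
    population: str = "POP",
    risk_allele: str = "A",
    other_allele: str = "G",
) -> RiskAssociation:
    """One case/control study with genotype counts consistent with an OR.

    Control genotype frequencies follow HWE at ``raf_control``; case
    frequencies follow the multiplicative allelic model
    case(g) ∝ control(g)·OR^g.  Counts are multinomial draws; the reported
    p-value is the chi-square test of the resulting 2x2 allele table and
    the reported OR (with Woolf 95% CI) is recomputed from the sampled
    counts.
    """
    if not (0.0 < raf_control < 1.0):
        raise ParameterError("raf_control must be inside (0, 1)")
    rng = np.random.default_rng(seed)
    p = raf_control
    control = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])  # dosage 0,1,2
    case = control * odds_ratio ** np.arange(3)
    case /= case.sum()
    if (np.concatenate([case * n_case, control * n_control]) < 1).any():
        warnings.warn("expected genotype cell < 1; counts will be noisy", stacklevel=2)
    c_case = rng.multinomial(n_case, case)
    c_ctrl = rng.multinomial(n_control, control)
    # 2x2 allele table
    a = 2 * c_case[2] + c_case[1]  # case risk alleles
    b = 2 * c_case[0] + c_case[1]
    c = 2 * c_ctrl[2] + c_ctrl[1]
    d = 2 * c_ctrl[0] + c_ctrl[1]
    p_value = stats.chi2_contingency([[a, b], [c, d]], correction=False)[1]
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    or_hat = (cells[0] * cells[3]) / (cells[1] * cells[2])
    se = float(np.sqrt((1.0 / cells).sum()))
    p_value = max(float(p_value), 1e-300)
    return RiskAssociation(
        rsid=rsid,
        disease=disease,
        study_id=study_id,
        population=population,
        risk_allele=risk_allele,
        other_allele=other_allele,
        p_value=min(1.0, p_value),
        odds_ratio=float(or_hat),
        ci_low=float(or_hat * np.exp(-Z_95 * se)),
        ci_high=float(or_hat * np.exp(Z_95 * se)),
        case_genotype_counts=(int(c_case[2]), int(c_case[1]), int(c_case[0])),
        control_genotype_counts=(int(c_ctrl[2]), int(c_ctrl[1]), int(c_ctrl[0])),
        n_total=n_case + n_control,
    )


def simulate_catalog(
    config: SimulationConfig, table: FrequencyTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Catalog + LD tables with construction-guaranteed positives and decoys.

    Every disease SNP gets ``n_studies_per_snp`` GWAS studies in distinct
    populations with reported p = 1e-8, so cross-ethnic selection retains
    it.  Decoys exercise each exclusion rule: too few populations, weak
    p-values, and a single paper.  The LD table plants a pair at R² = 0.9
    (so pruning at > 0.7 removes the weaker twin), and an independent pair
    at R² = 0.512 that must survive.
    """
    rng = np.random.default_rng(config.seed + 1)
    region_map = config.region_map()
    pooled_ref, _, _ = table.pooled(region_map, config.region_ref)
    disease = config.disease_rsids()
    pops = list(config.populations)

    rows: list[RiskAssociation] = []

    def studies_for(rsid, n_studies, p_reported, study_class="GWAS", n_total=None,
                    tag=""):
        a, b = table.alleles(rsid)
        raf = float(np.clip(pooled_ref.get(rsid, 0.5), 0.05, 0.95))
        or_true = float(rng.uniform(*config.or_range))
        for s in range(n_studies):
            rec = simulate_case_control_study(
                raf,
                or_true,
                config.n_case,
                config.n_control,
                seed=int(rng.integers(0, 2**31 - 1)),
                rsid=rsid,
                disease="disease_main",
                study_id=f"pmid_{tag}{rsid}_{s}",
                population=pops[s % len(pops)],
                risk_allele=a,
                other_allele=b,
            )
            rec = dataclasses.replace(
                rec,
                p_value=p_reported,
                study_class=study_class,
                n_total=n_total or rec.n_total,
            )
            rows.append(rec)

    for rsid in disease:
        studies_for(rsid, config.n_studies_per_snp, 1e-8)

    # decoys, taken from the genome tail so they never collide with disease loci
    genome = [r for r in table.rsids if r not in disease]
    decoy_few, decoy_weak, decoy_single, ld_twin, ld_free_a = genome[-5:]
    studies_for(decoy_few, 4, 1e-8, tag="few_")  # only 4 populations
    studies_for(decoy_weak, 6, 1e-4, tag="weak_")  # never significant
    studies_for(decoy_single, 1, 1e-9, tag="single_")  # one paper only
    # a linked twin of the first disease SNP with weaker evidence (fewer studies)
    studies_for(ld_twin, max(5, config.n_studies_per_snp - 1), 1e-8, tag="twin_")
    # an independent SNP correlated at R²=0.512 (must survive pruning at >0.7)
    studies_for(ld_free_a, config.n_studies_per_snp, 1e-8, tag="free_")

    catalog = pd.DataFrame(
        {
            "rsid": [r.rsid for r in rows],
            "disease": [r.disease for r in rows],
            "study_id": [r.study_id for r in rows],
            "population": [r.population for r in rows],
            "study_class": [r.study_class for r in rows],
            "risk_allele": [r.risk_allele for r in rows],
            "other_allele": [r.other_allele for r in rows],
            "p_value": [r.p_value for r in rows],
            "odds_ratio": [r.odds_ratio for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "case_hom_risk": [r.case_genotype_counts[0] for r in rows],
            "case_het": [r.case_genotype_counts[1] for r in rows],
            "case_hom_other": [r.case_genotype_counts[2] for r in rows],
            "control_hom_risk": [r.control_genotype_counts[0] for r in rows],
            "control_het": [r.control_genotype_counts[1] for r in rows],
            "control_hom_other": [r.control_genotype_counts[2] for r in rows],
            "n_total": [r.n_total for r in rows],
        }
    )
    ld = pd.DataFrame(
        {
            "rsid_a": [disease[0], ld_free_a, disease[1]],
            "rsid_b": [ld_twin, disease[0], disease[2]],
            "population": ["CEU", "CEU", "CEU"],
            "r2": [0.9, 0.512, 0.1],
        }
    )
    return catalog, ld


@dataclasses.dataclass
class SyntheticCorpus:
    """The full generated input set for one configuration."""

    config: SimulationConfig
    frequencies: FrequencyTable
    disease_rsids: list[str]
    genotypes: GenotypeMatrix
    catalog: pd.DataFrame
    ld: pd.DataFrame


def simulate_corpus(config: SimulationConfig, genotype_rsids: list[str] | None = None) -> SyntheticCorpus:
    """Generate the full corpus: frequencies with cline, genotypes, catalog, LD.

    ``genotype_rsids`` limits the genotype matrix (default: disease loci
    only, which is what the risk-score analyses consume).
    """
    table = simulate_frequency_table(config)
    disease = config.disease_rsids()
    table = inject_cline(
        table,
        disease,
        config.delta_high,
        config.delta_low,
        config.region_map(),
        config.region_high,
        config.region_low,
    )
    geno = simulate_genotypes(
        table,
        config.n_individuals_per_pop,
        seed=config.seed + 2,
        rsids=genotype_rsids or disease,
    )
    cat, ld = simulate_catalog(config, table)
    return SyntheticCorpus(
        config=config,
        frequencies=table,
        disease_rsids=disease,
        genotypes=geno,
        catalog=cat,
        ld=ld,
    )


# ---------------------------------------------------------------------------
# writers


def write_frequency_vcf(table: FrequencyTable, path) -> None:
    """Write per-population frequencies as a sites-only VCF with AF_/AN_ tags.

    REF = ``allele_b``, ALT = ``allele_a`` so that the AF convention (ALT
    frequency) carries ``freq_a``.
    """
    pops = table.populations
    lines = ["##fileformat=VCFv4.2"]
    for pop in pops:
        lines.append(
            f'##INFO=<ID=AF_{pop},Number=1,Type=Float,Description="Allele frequency in {pop}">'
        )
        lines.append(
            f'##INFO=<ID=AN_{pop},Number=1,Type=Integer,Description="Chromosome count in {pop}">'
        )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    freq = table.freq_matrix()
    counts = table.count_matrix()
    meta = table._allele_frame()
    for rsid in freq.index:
        info = []
        for pop in pops:
            v = freq.at[rsid, pop]
            if pd.isna(v):
                continue
            info.append(f"AF_{pop}={v:.6g}")
            info.append(f"AN_{pop}={int(counts.at[rsid, pop])}")
        row = meta.loc[rsid]
        lines.append(
            f"{row['chrom']}\t{int(row['pos'])}\t{rsid}\t{row['allele_b']}"
            f"\t{row['allele_a']}\t.\t.\t{';'.join(info)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_genotype_vcf(matrix: GenotypeMatrix, table: FrequencyTable, path) -> None:
    """Write a GT-only VCF; ALT is each SNP's counted (risk) allele."""
    inds = matrix.individuals
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(inds),
    ]
    meta = table._allele_frame()
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for rsid in matrix.rsids:
        row = meta.loc[rsid]
        counted = matrix.counted_allele.get(rsid, row["allele_a"])
        ref = row["allele_b"] if counted == row["allele_a"] else row["allele_a"]
        dosages = matrix.dosages[rsid]
        gts = [gt_code.get(float(d), "./.") if pd.notna(d) else "./." for d in dosages]
        lines.append(
            f"{row['chrom']}\t{int(row['pos'])}\t{rsid}\t{ref}\t{counted}\t.\t.\t.\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_corpus(corpus: SyntheticCorpus, outdir) -> dict[str, str]:
    """Write the corpus as plain-text files and a manifest; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "frequencies": str(out / "frequencies.tsv"),
        "genotypes_vcf": str(out / "genotypes.vcf"),
        "samples": str(out / "samples.tsv"),
        "catalog": str(out / "catalog.tsv"),
        "ld": str(out / "ld.tsv"),
        "manifest": str(out / "manifest.json"),
    }
    corpus.frequencies.df.to_csv(paths["frequencies"], sep="\t", index=False)
    write_genotype_vcf(corpus.genotypes, corpus.frequencies, paths["genotypes_vcf"])
    pd.DataFrame(
        {
            "individual": corpus.genotypes.individuals,
            "population": corpus.genotypes.populations.to_numpy(),
        }
    ).to_csv(paths["samples"], sep="\t", index=False)
    corpus.catalog.to_csv(paths["catalog"], sep="\t", index=False)
    corpus.ld.to_csv(paths["ld"], sep="\t", index=False)
    manifest = {
        "config": dataclasses.asdict(corpus.config),
        "disease_rsids": corpus.disease_rsids,
        "files": {k: v for k, v in paths.items() if k != "manifest"},
    }
    Path(paths["manifest"]).write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
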