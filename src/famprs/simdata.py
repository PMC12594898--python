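"""Synthetic multi-generation cohort generator.

The generator emulates an unselected family-based cohort: three-generation
families (a founder couple, their children with married-in spouses, and
grandchildren), unlinked biallelic variants gene-dropped from founders in
Hardy-Weinberg proportions, and disease assigned by a liability-threshold
model

    L = b1 * z(PRS) + b2 * z(age) + c * u_family + e,    Var(L) = 1,
    affected  iff  L > Phi^{-1}(1 - K),

with K the target prevalence among females (default 0.0122, i.e. 1.22%).
``liability_slope_for_or`` converts a desired per-SD disease odds ratio
(default 1.24) into the liability slope b1 by numerical search against
simulated logistic fits.  Rare loss-of-function variants with allele
frequencies in a configurable band (default 0.00037-0.026) can be injected
with synthetic gene/consequence annotations for the monogenic arm.

Everything is driven by one numpy Generator, so a fixed seed reproduces the
pedigree, panel and roster bit-for-bit.
"""

from __future__ import annotations

import functools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit, logit

from .pedigree import Individual, Pedigree, write_fam
from .scoring import GenotypePanel, PRSTable, ScoreFile

logger = logging.getLogger(__name__)

#: fictional candidate-gene symbols for the monogenic arm (synthetic stand-in
#: for a curated breast-cancer gene list; 41 symbols, LOF variants drawn from
#: the first 24)
CANDIDATE_GENES = [f"BCG{i:02d}" for i in range(1, 42)]

# ordered, non-palindromic allele pairs (effect, other); A/T and C/G pairs
# are excluded so simulated variants never need frequency-based strand calls
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("G", "T"),
    ("C", "A"), ("C", "T"), ("T", "G"), ("T", "C"),
]


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults echo the target cohort: ~200 three-generation families,
    female disease prevalence 1.22%, per-SD odds ratio 1.24, a 313-variant
    score with centered-normal weights (sd 0.05, typical GWAS per-allele
    log-OR magnitudes), and 21 rare LOF variants with frequencies between
    0.00037 and 0.026.
    """

    n_families: int = 200
    generations: int = 3
    sibship_sizes: tuple[int, ...] = (1, 2, 3, 4)
    sibship_probs: tuple[float, ...] = (0.2, 0.35, 0.3, 0.15)
    spouse_prob: float = 0.8  # chance a second-generation child founds a branch
    n_prs_variants: int = 313
    freq_range: tuple[float, float] = (0.05, 0.5)
    weight_sd: float = 0.05
    weights: np.ndarray | None = None
    or_per_sd: float | None = 1.24  # converted to beta_prs when beta_prs is None
    beta_prs: float | None = None  # liability slope per PRS SD
    beta_age: float = 0.3  # liability slope per age SD; disease risk accrues with age
    shared_env_sd: float = 0.0  # per-family shared-environment liability sd
    target_prevalence: float = 0.0122
    n_lof_variants: int = 21
    lof_freq_range: tuple[float, float] = (0.00037, 0.026)
    lof_pathogenic_prob: float = 0.7  # chance an injected LOF carries a ClinVar flag
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must lie in (0, 1)")
        lo, hi = self.freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("freq_range must lie in (0, 1)")
        llo, lhi = self.lof_freq_range
        if not (0 < llo <= lhi <= 0.05):
            raise ValueError("lof_freq_range must lie in (0, 0.05]")
        if self.generations not in (2, 3):
            raise ValueError("template supports 2 or 3 generations")
        if len(self.sibship_sizes) != len(self.sibship_probs):
            raise ValueError("sibship size/probability lengths differ")


@dataclass
class SimCohort:
    """A fully materialised synthetic cohort plus its generating truth."""

    config: SimConfig
    pedigree: Pedigree
    score: ScoreFile
    panel: GenotypePanel
    roster: pd.DataFrame
    truth: pd.DataFrame  # sample_id-indexed: raw_prs, z_prs, liability
    lof_panel: GenotypePanel | None = None
    lof_annotations: pd.DataFrame | None = None
    candidate_genes: list[str] = field(default_factory=lambda: list(CANDIDATE_GENES))

    def write(self, outdir) -> dict[str, str]:
        """Emit every file dialect the analysis modules read."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "weights": out / "weights.tsv",
            "dosages": out / "dosages.tsv",
            "variants": out / "variants.tsv",
            "fam": out / "pedigree.fam",
            "roster": out / "roster.tsv",
        }
        write_weight_table(self.score, paths["weights"])
        self.panel.to_dosage_tsv(paths["dosages"], paths["variants"])
        write_fam(self.pedigree, paths["fam"])
        self.roster.to_csv(paths["roster"], sep="\t", index=False)
        if self.lof_panel is not None:
            paths["lof_dosages"] = out / "lof_dosages.tsv"
            paths["lof_variants"] = out / "lof_variants.tsv"
            paths["annotations"] = out / "annotations.tsv"
            paths["candidate_genes"] = out / "candidate_genes.txt"
            self.lof_panel.to_dosage_tsv(paths["lof_dosages"], paths["lof_variants"])
            self.lof_annotations.to_csv(paths["annotations"], sep="\t", index=False)
            paths["candidate_genes"].write_text(
                "\n".join(self.candidate_genes) + "\n"
            )
        return {k: str(v) for k, v in paths.items()}


# --------------------------------------------------------------------------
# pedigree templates


def _age(rng: np.random.Generator, mean: float, sd: float) -> float:
    return float(np.clip(np.round(rng.normal(mean, sd), 1), 18.0, 100.0))


def simulate_pedigrees(config: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Independent families from the template: founder couple, their
    children (each with a married-in spouse with probability
    ``spouse_prob``), and grandchildren when ``generations == 3``.

    Ages follow generation bands (70+/-8, 47+/-6, 25+/-5 years).  Each
    sibship is guaranteed at least one daughter so the female relative
    classes (mother, sister, daughter) are populated.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ped = Pedigree()
    probs = np.asarray(config.sibship_probs, float)
    probs = probs / probs.sum()
    for f in range(config.n_families):
        fam = f"F{f:04d}"
        gf, gm = f"{fam}_G1M", f"{fam}_G1F"
        ped.add(Individual(fam, gf, sex="male", age=_age(rng, 70, 8)))
        ped.add(Individual(fam, gm, sex="female", age=_age(rng, 70, 8)))
        nsib = int(rng.choice(config.sibship_sizes, p=probs))
        sexes = ["female" if rng.random() < 0.5 else "male" for _ in range(nsib)]
        if "female" not in sexes:
            sexes[int(rng.integers(nsib))] = "female"
        for s in range(nsib):
            child = f"{fam}_G2C{s}"
            ped.add(
                Individual(
                    fam, child, father_id=gf, mother_id=gm,
                    sex=sexes[s], age=_age(rng, 47, 6),
                )
            )
            if config.generations < 3 or rng.random() >= config.spouse_prob:
                continue
            spouse = f"{fam}_G2S{s}"
            spouse_sex = "male" if sexes[s] == "female" else "female"
            ped.add(Individual(fam, spouse, sex=spouse_sex, age=_age(rng, 47, 6)))
            father, mother = (spouse, child) if sexes[s] == "female" else (child, spouse)
            nkids = int(rng.choice((0, 1, 2, 3), p=(0.15, 0.3, 0.35, 0.2)))
            ksexes = ["female" if rng.random() < 0.5 else "male" for _ in range(nkids)]
            if nkids and "female" not in ksexes:
                ksexes[int(rng.integers(nkids))] = "female"
            for k in range(nkids):
                ped.add(
                    Individual(
                        fam, f"{fam}_G3C{s}_{k}", father_id=father, mother_id=mother,
                        sex=ksexes[k], age=_age(rng, 25, 5),
                    )
                )
    ped.validate()
    return ped


# --------------------------------------------------------------------------
# gene dropping


def _variant_metadata(n: int, prefix: str, rng: np.random.Generator) -> pd.DataFrame:
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(len(_ALLELE_PAIRS), size=n)]
    return pd.DataFrame(
        {
            "variant_id": [f"{prefix}{i:04d}" for i in range(n)],
            "counted_allele": [p[0] for p in pairs],
            "alternate_allele": [p[1] for p in pairs],
            "chromosome": [str(1 + i % 22) for i in range(n)],
            "position": [1_000_000 + 10_000 * i for i in range(n)],
        }
    )


def gene_drop(
    ped: Pedigree,
    freqs: np.ndarray,
    rng: np.random.Generator,
    prefix: str = "var",
    metadata: pd.DataFrame | None = None,
) -> GenotypePanel:
    """Drop unlinked biallelic variants through the pedigree.

    Founders draw two alleles i.i.d. Bernoulli(freq) (Hardy-Weinberg);
    every non-founder inherits one uniformly chosen allele from each
    parent.  Dosage counts the effect allele.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    order = sorted(ped.members, key=lambda i: ped._compute_depths()[i])
    idx = {iid: k for k, iid in enumerate(order)}
    n, m = len(order), freqs.size
    h1 = np.zeros((n, m), dtype=np.int8)
    h2 = np.zeros((n, m), dtype=np.int8)
    for iid in order:
        k = idx[iid]
        fa, mo = ped.parents(iid)
        if fa is None and mo is None:
            h1[k] = rng.random(m) < freqs
            h2[k] = rng.random(m) < freqs
        elif fa is None or mo is None:
            raise ValueError(f"{iid}: exactly one known parent; template forbids")
        else:
            pick_f = rng.random(m) < 0.5
            pick_m = rng.random(m) < 0.5
            h1[k] = np.where(pick_f, h1[idx[fa]], h2[idx[fa]])
            h2[k] = np.where(pick_m, h1[idx[mo]], h2[idx[mo]])
    if metadata is None:
        metadata = _variant_metadata(m, prefix, rng)
    dosages = pd.DataFrame(
        (h1 + h2).astype(float),
        index=pd.Index(order, name="sample_id"),
        columns=metadata["variant_id"].tolist(),
    )
    return GenotypePanel(dosages, metadata.set_index("variant_id"))


def check_mendelian(ped: Pedigree, panel: GenotypePanel) -> None:
    """Raise if any non-founder's dosage is unattainable from its parents.

    A parent with dosage 2 must transmit the allele (minimum contribution
    1); a parent with dosage 0 cannot (maximum contribution 0).
    """
    D = panel.dosages
    for iid in panel.sample_ids:
        fa, mo = ped.parents(iid)
        if fa is None or mo is None:
            continue
        child = D.loc[iid].to_numpy()
        lo = hi = np.zeros_like(child)
        for p in (fa, mo):
            pd_ = D.loc[p].to_numpy()
            lo = lo + (pd_ == 2)
            hi = hi + (pd_ > 0)
        bad = (child < lo) | (child > hi)
        if bad.any():
            j = int(np.argmax(bad))
            raise AssertionError(
                f"Mendelian violation: {iid} dosage {child[j]} at "
                f"{D.columns[j]} with parents {D.loc[fa].iloc[j]}, {D.loc[mo].iloc[j]}"
            )


# --------------------------------------------------------------------------
# liability-threshold phenotypes


def liability_threshold(prevalence: float) -> float:
    """Phi^{-1}(1 - K): the liability cut above which disease occurs."""
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    return float(stats.norm.isf(prevalence))


def liability_status(
    z_prs: np.ndarray,
    z_age: np.ndarray,
    beta_prs: float,
    beta_age: float,
    prevalence: float,
    rng: np.random.Generator,
    shared: np.ndarray | None = None,
    shared_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Liability draw and threshold call; returns (liability, affected).

    The residual variance is set so Var(L) = 1, which pins the threshold
    at Phi^{-1}(1 - K).
    """
    var_expl = beta_prs**2 + beta_age**2 + shared_sd**2
    if var_expl >= 1:
        raise ValueError("liability slopes explain >= 100% of variance")
    z_prs = np.asarray(z_prs, float)
    liab = beta_prs * z_prs + beta_age * np.asarray(z_age, float)
    if shared_sd > 0 and shared is not None:
        liab = liab + shared_sd * shared
    liab = liab + math.sqrt(1 - var_expl) * rng.standard_normal(z_prs.size)
    return liab, liab > liability_threshold(prevalence)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def assign_phenotypes(
    ped: Pedigree,
    panel: GenotypePanel,
    score: ScoreFile,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disease status from the liability model; returns (roster, truth).

    The threshold applies to females only (the disease modeled is breast
    cancer); males are unaffected and roster-ineligible.  The roster
    carries the flags the selection cascade consumes; affected females get
    ``age_at_onset`` equal to their recorded age (the cohort is a
    retrospective snapshot; onset-age dynamics are out of scope).
    """
    beta_prs = config.beta_prs
    if beta_prs is None:
        beta_prs = (
            liability_slope_for_or(config.or_per_sd, config.target_prevalence)
            if config.or_per_sd is not None
            else 0.0
        )
    samples = panel.sample_ids
    raw = panel.dosages.to_numpy(float) @ score.weights.loc[panel.variant_ids].to_numpy()
    z_prs = _zscore(raw)
    ages = np.array([ped[i].age if ped[i].age is not None else 50.0 for i in samples])
    z_age = _zscore(ages)
    fam_ids = [ped[i].family_id for i in samples]
    if config.shared_env_sd > 0:
        fams = {f: rng.standard_normal() for f in dict.fromkeys(fam_ids)}
        shared = np.array([fams[f] for f in fam_ids])
    else:
        shared = None
    liab, hit = liability_status(
        z_prs, z_age, beta_prs, config.beta_age, config.target_prevalence,
        rng, shared=shared, shared_sd=config.shared_env_sd,
    )
    female = np.array([ped[i].sex == "female" for i in samples])
    affected = hit & female
    fam_has_other_case = pd.Series(affected, index=fam_ids).groupby(level=0).sum()
    roster = pd.DataFrame(
        {
            "sample_id": samples,
            "family_id": fam_ids,
            "sex": ["female" if f else "male" for f in female],
            "age": ages,
            "affection": np.where(~female, "unaffected", np.where(affected, "affected", "unaffected")),
            "bc_status": np.where(
                ~female, "ineligible", np.where(affected, "case", "control_eligible")
            ),
            "age_at_onset": np.where(affected, ages, np.nan),
            "personal_history": affected,
            "family_history": [
                bool(fam_has_other_case[f] - int(a)) for f, a in zip(fam_ids, affected)
            ],
            "genotyped": True,
            "phenotype_complete": True,
        }
    )
    for iid, aff, onset in zip(samples, affected, roster["age_at_onset"]):
        ped[iid].affection = "affected" if aff else "unaffected"
        if aff:
            ped[iid].age_at_onset = float(onset)
    truth = pd.DataFrame(
        {"raw_prs": raw, "z_prs": z_prs, "liability": liab},
        index=pd.Index(samples, name="sample_id"),
    )
    return roster, truth


# --------------------------------------------------------------------------
# effect-size calibration


@functools.lru_cache(maxsize=16)
def liability_slope_for_or(
    or_per_sd: float,
    prevalence: float,
    n: int = 200_000,
    seed: int = 20_240_101,
) -> float:
    """Liability slope b1 whose induced per-SD disease odds ratio matches
    ``or_per_sd``, found by root search against logistic fits on one large
    simulated sample (common random numbers keep the objective smooth)."""
    if or_per_sd <= 0:
        raise ValueError("odds ratio must be positive")
    if abs(or_per_sd - 1.0) < 1e-9:
        return 0.0
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    thr = liability_threshold(prevalence)
    target = math.log(or_per_sd)

    def fitted_log_or(b: float) -> float:
        y = (b * z + math.sqrt(1 - b * b) * eps > thr).astype(float)
        import statsmodels.api as sm

        fit = sm.Logit(y, sm.add_constant(z)).fit(disp=0)
        return float(fit.params[1])

    lo, hi = 1e-4, 0.8
    b = brentq(lambda b: fitted_log_or(b) - target, lo, hi, xtol=1e-4)
    logger.info("per-SD OR %.3f at K=%.4f -> liability slope %.4f", or_per_sd, prevalence, b)
    return float(b)


def simulate_case_control(
    n_cases: int,
    n_controls: int,
    or_per_sd: float,
    rng: np.random.Generator,
    prevalence: float = 0.0122,
) -> tuple[np.ndarray, np.ndarray]:
    """Case-control sample of standardized scores under a logistic model.

    Draws a population with P(case | z) = expit(logit(K) + ln(OR) * z),
    z ~ N(0, 1), then samples the requested numbers of cases and controls.
    Retrospective sampling leaves the odds ratio intact.
    """
    beta = math.log(or_per_sd)
    alpha = float(logit(prevalence))
    z_cases: list[np.ndarray] = []
    z_controls: list[np.ndarray] = []
    nc = nk = 0
    while nc < n_cases or nk < n_controls:
        block = max(20_000, int(1.5 * (n_cases - nc) / max(prevalence, 1e-4)))
        z = rng.standard_normal(block)
        y = rng.random(block) < expit(alpha + beta * z)
        z_cases.append(z[y])
        z_controls.append(z[~y])
        nc += int(y.sum())
        nk += int((~y).sum())
    zc = np.concatenate(z_cases)[:n_cases]
    zk = np.concatenate(z_controls)[:n_controls]
    return (
        np.concatenate([zc, zk]),
        np.concatenate([np.ones(n_cases, int), np.zeros(n_controls, int)]),
    )


# --------------------------------------------------------------------------
# LOF injection and top-level assembly


def inject_lof(
    ped: Pedigree,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Gene-drop rare LOF variants and emit a synthetic annotation table.

    Frequencies are log-uniform within ``lof_freq_range``; genes come from
    the fictional candidate list (first 24 symbols, echoing a candidate
    set where a subset of genes harbours LOF variation); each variant gets
    a LOF consequence class and a ClinVar-pathogenic flag with probability
    ``lof_pathogenic_prob``.
    """
    n = config.n_lof_variants
    lo, hi = config.lof_freq_range
    freqs = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    meta = _variant_metadata(n, "lof", rng)
    panel = gene_drop(ped, freqs, rng, metadata=meta)
    lof_classes = sorted(
        ("stop_gained", "frameshift", "splice_donor", "splice_acceptor", "start_lost")
    )
    annotations = pd.DataFrame(
        {
            "variant_id": meta["variant_id"],
            "gene": [CANDIDATE_GENES[i % 24] for i in range(n)],
            "consequence": [lof_classes[i] for i in rng.integers(len(lof_classes), size=n)],
            "clinvar_pathogenic": rng.random(n) < config.lof_pathogenic_prob,
            "af": freqs,
        }
    )
    return panel, annotations


def make_score_file(config: SimConfig, rng: np.random.Generator, panel: GenotypePanel) -> ScoreFile:
    """Weight file matching the simulated panel (effect allele = counted)."""
    n = config.n_prs_variants
    w = (
        np.asarray(config.weights, float)
        if config.weights is not None
        else rng.normal(0.0, config.weight_sd, size=n)
    )
    if w.size != n:
        raise ValueError("weights length differs from n_prs_variants")
    al = panel.alleles
    table = pd.DataFrame(
        {
            "variant_id": panel.variant_ids,
            "chromosome": al["chromosome"].to_numpy(),
            "position": al["position"].to_numpy(),
            "effect_allele": al["counted_allele"].to_numpy(),
            "other_allele": al["alternate_allele"].to_numpy(),
            "weight": w,
        }
    )
    return ScoreFile(table, name="simPRS")


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Full gene-drop cohort: pedigree, PRS panel + weights, liability
    phenotypes, and injected LOF variants with annotations."""
    rng = np.random.default_rng(config.seed)
    ped = simulate_pedigrees(config, rng)
    freqs = rng.uniform(*config.freq_range, size=config.n_prs_variants)
    panel = gene_drop(ped, freqs, rng)
    score = make_score_file(config, rng, panel)
    roster, truth = assign_phenotypes(ped, panel, score, config, rng)
    lof_panel, annotations = (
        inject_lof(ped, config, rng) if config.n_lof_variants > 0 else (None, None)
    )
    return SimCohort(
        config=config,
        pedigree=ped,
        score=score,
        panel=panel,
        roster=roster,
        truth=truth,
        lof_panel=lof_panel,
        lof_annotations=annotations,
    )


# --------------------------------------------------------------------------
# file emitters in the dialects the analysis modules read


def write_weight_table(score: ScoreFile, path) -> None:
    """PGS-Catalog-style tab-separated weight file."""
    df = score.variants.rename(
        columns={
            "variant_id": "rsID",
            "chromosome": "chr_name",
            "position": "chr_position",
            "weight": "effect_weight",
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# score file: {score.name}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_vcf(panel: GenotypePanel, path) -> None:
    """Minimal VCF 4.2 with hard GT calls (REF = alternate allele, ALT =
    counted allele, mirroring the loader's ALT-dosage convention)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    samples = panel.sample_ids
    al = panel.alleles
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(al["chromosome"].astype(str).unique(), key=str):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for vid in panel.variant_ids:
            rec = al.loc[vid]
            gts = [
                gt_map.get(d, "./.") if not np.isnan(d) else "./."
                for d in panel.dosages[vid].to_numpy(float)
            ]
            fh.write(
                f"{rec['chromosome']}\t{rec['position']}\t{vid}\t"
                f"{rec['alternate_allele']}\t{rec['counted_allele']}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )
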