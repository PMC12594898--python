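"""Polygenic risk score computation.

A PRS weight file lists variants with an effect allele and a per-allele
log-odds weight (natural log scale).  Given a genotype panel holding
effect-allele dosages (0, 1, 2 or missing) the raw score of an individual is

    raw_i = sum_j d_ij * w_j

over the variants that survive allele harmonization.  Scores are
standardized to z-scores against a reference set of samples (all samples by
default) using the n-1 denominator.

Harmonization reconciles the weight file's allele labels with the panel's:
a panel variant may count the weight file's effect allele directly
(``matched``), count the other allele (``allele_swapped``; dosage is
complemented as ``2 - d`` at scoring time), sit on the opposite strand
(``strand_flipped``), or be undecidable (palindromic A/T and C/G pairs and
label mismatches are ``ambiguous_dropped``).  Variants missing from the
panel are ``absent_from_panel``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: harmonization statuses that contribute dosages to the score
CONTRIBUTING_STATUSES = ("matched", "allele_swapped", "strand_flipped")

SCORE_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "weight",
]

# accepted header aliases for the tab-separated weight-file dialect
_COLUMN_ALIASES = {
    "rsID": "variant_id",
    "rsid": "variant_id",
    "variant_id": "variant_id",
    "chr_name": "chromosome",
    "chromosome": "chromosome",
    "chr_position": "position",
    "position": "position",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "reference_allele": "other_allele",
    "effect_weight": "weight",
    "weight": "weight",
    "OR": "OR",
    "odds_ratio": "OR",
}


@dataclass(frozen=True)
class ScoreVariant:
    """One weighted variant of a PRS model."""

    variant_id: str
    effect_allele: str
    other_allele: str
    weight: float
    chromosome: str | None = None
    position: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(
                f"{self.variant_id}: effect and other allele are identical"
            )
        if not math.isfinite(self.weight):
            raise ValueError(f"{self.variant_id}: non-finite weight")


@dataclass
class ScoreFile:
    """An ordered collection of weighted variants defining a PRS.

    ``variants`` is a DataFrame with columns ``variant_id, chromosome,
    position, effect_allele, other_allele, weight`` in file order.
    """

    variants: pd.DataFrame
    name: str = "PRS"

    def __post_init__(self) -> None:
        missing = [c for c in SCORE_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"score table lacks columns: {missing}")
        if len(self.variants) == 0:
            raise ValueError("empty score file")
        dup = self.variants["variant_id"].duplicated()
        if dup.any():
            ids = self.variants.loc[dup, "variant_id"].tolist()
            raise ValueError(f"duplicate variant ids in score file: {ids[:5]}")
        same = self.variants["effect_allele"] == self.variants["other_allele"]
        if same.any():
            raise ValueError("effect allele equals other allele for some variants")
        if not np.isfinite(self.variants["weight"].to_numpy(float)).all():
            raise ValueError("non-finite weights in score file")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["variant_id"].tolist()

    @property
    def weights(self) -> pd.Series:
        return self.variants.set_index("variant_id")["weight"]


def load_score_file(source, name: str = "PRS") -> ScoreFile:
    """Read a tab-separated PRS weight table.

    Requires a variant id, effect allele and other allele column plus either
    a log-odds ``effect_weight`` column or an ``OR`` column (in which case
    the weight is ``ln(OR)``).  ``#`` comment lines are ignored.
    """
    df = pd.read_csv(source, sep="\t", comment="#", dtype={"rsID": str})
    df = df.rename(columns={c: _COLUMN_ALIASES[c] for c in df.columns if c in _COLUMN_ALIASES})
    for col in ("variant_id", "effect_allele", "other_allele"):
        if col not in df.columns:
            raise ValueError(f"weight file is missing mandatory column '{col}'")
    if "weight" not in df.columns:
        if "OR" not in df.columns:
            raise ValueError("weight file needs an effect_weight or OR column")
        ors = df["OR"].to_numpy(float)
        if np.any(ors <= 0):
            raise ValueError("odds ratios must be positive to take ln(OR)")
        df["weight"] = np.log(ors)
    out = pd.DataFrame(
        {
            "variant_id": df["variant_id"].astype(str),
            "chromosome": df["chromosome"].astype(str) if "chromosome" in df else None,
            "position": df["position"].astype("Int64") if "position" in df else None,
            "effect_allele": df["effect_allele"].astype(str).str.upper(),
            "other_allele": df["other_allele"].astype(str).str.upper(),
            "weight": df["weight"].astype(float),
        }
    )
    return ScoreFile(out, name=name)


@dataclass
class GenotypePanel:
    """Sample-by-variant dosages of a counted allele.

    ``dosages``: DataFrame indexed by sample_id, one column per variant,
    values in {0, 1, 2} or NaN for missing.  ``alleles``: DataFrame indexed
    by variant_id with ``counted_allele`` (the allele the dosage counts),
    ``alternate_allele`` and optional ``chromosome``/``position``.
    """

    dosages: pd.DataFrame
    alleles: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosages.index.duplicated().any():
            raise ValueError("duplicate sample ids in genotype panel")
        vals = self.dosages.to_numpy(float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        missing_meta = set(self.dosages.columns) - set(self.alleles.index)
        if missing_meta:
            raise ValueError(f"variants without allele metadata: {sorted(missing_meta)[:5]}")
        same = self.alleles["counted_allele"] == self.alleles["alternate_allele"]
        if same.any():
            raise ValueError("counted allele equals alternate allele for some variants")

    @property
    def sample_ids(self) -> list[str]:
        return self.dosages.index.tolist()

    @property
    def variant_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_samples(self) -> int:
        return len(self.dosages)

    @classmethod
    def from_vcf(cls, path) -> "GenotypePanel":
        """Load hard GT calls from a VCF; dosage = count of the first ALT allele.

        ``./.`` genotypes and calls involving further ALT alleles become
        missing.  The counted allele is ALT, the alternate is REF.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        cols: dict[str, np.ndarray] = {}
        meta: list[dict] = []
        for var in vcf:
            alts = var.ALT
            if not alts:
                continue
            vid = var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{alts[0]}"
            dos = np.full(len(samples), np.nan)
            for i, gt in enumerate(var.genotypes):
                a, b = gt[0], gt[1]
                if a < 0 or b < 0 or a > 1 or b > 1:
                    continue
                dos[i] = (a == 1) + (b == 1)
            cols[vid] = dos
            meta.append(
                {
                    "variant_id": vid,
                    "counted_allele": alts[0].upper(),
                    "alternate_allele": var.REF.upper(),
                    "chromosome": var.CHROM,
                    "position": var.POS,
                }
            )
        dosages = pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"))
        alleles = pd.DataFrame(meta).set_index("variant_id")
        return cls(dosages, alleles)

    @classmethod
    def from_dosage_tsv(cls, dosage_path, variant_info) -> "GenotypePanel":
        """Load a TSV dosage matrix (samples as rows, variants as columns, NA
        for missing) plus a variant-info TSV with columns ``variant_id,
        counted_allele, alternate_allele`` (and optional coordinates)."""
        dosages = pd.read_csv(dosage_path, sep="\t", index_col=0)
        dosages.index = dosages.index.astype(str)
        dosages.index.name = "sample_id"
        info = pd.read_csv(variant_info, sep="\t", dtype={"variant_id": str})
        alleles = info.set_index("variant_id")
        for col in ("counted_allele", "alternate_allele"):
            alleles[col] = alleles[col].astype(str).str.upper()
        return cls(dosages.astype(float), alleles)

    def to_dosage_tsv(self, dosage_path, variant_info_path) -> None:
        self.dosages.to_csv(dosage_path, sep="\t", na_rep="NA")
        self.alleles.to_csv(variant_info_path, sep="\t")


@dataclass
class HarmonizationReport:
    """Per-variant reconciliation of a score file against a panel.

    ``table`` columns: variant_id, status, complement_dosage.  A True
    ``complement_dosage`` means the panel counts the non-effect allele and
    the effective dosage is ``2 - d``.
    """

    table: pd.DataFrame
    score_name: str = "PRS"

    @property
    def counts(self) -> dict[str, int]:
        base = {
            "matched": 0,
            "allele_swapped": 0,
            "strand_flipped": 0,
            "ambiguous_dropped": 0,
            "absent_from_panel": 0,
        }
        base.update(self.table["status"].value_counts().to_dict())
        return base

    @property
    def n_contributing(self) -> int:
        return int(self.table["status"].isin(CONTRIBUTING_STATUSES).sum())

    def contributing(self) -> pd.DataFrame:
        return self.table[self.table["status"].isin(CONTRIBUTING_STATUSES)]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "score": self.score_name,
            "n_score_variants": int(len(self.table)),
            "n_contributing": self.n_contributing,
            "counts": self.counts,
        }


def _revcomp_pair(a: str, b: str) -> tuple[str, str] | None:
    try:
        return COMPLEMENT[a], COMPLEMENT[b]
    except KeyError:
        return None


def is_strand_ambiguous(a: str, b: str) -> bool:
    """True for palindromic allele pairs (A/T, C/G) whose strand cannot be
    resolved without frequency information."""
    return COMPLEMENT.get(a) == b


def harmonize(score: ScoreFile, panel: GenotypePanel) -> HarmonizationReport:
    """Classify each score variant against the panel's counted alleles."""
    if len(score) == 0 or panel.n_samples == 0:
        raise ValueError("harmonize requires a non-empty score file and panel")
    rows = []
    n_ambiguous = 0
    allele_map: Mapping = panel.alleles[["counted_allele", "alternate_allele"]].to_dict("index")
    present = set(panel.variant_ids)
    for rec in score.variants.itertuples(index=False):
        vid, eff, oth = rec.variant_id, rec.effect_allele, rec.other_allele
        if vid not in present:
            rows.append((vid, "absent_from_panel", False))
            continue
        if is_strand_ambiguous(eff, oth):
            rows.append((vid, "ambiguous_dropped", False))
            n_ambiguous += 1
            continue
        counted = allele_map[vid]["counted_allele"]
        alt = allele_map[vid]["alternate_allele"]
        rc = _revcomp_pair(counted, alt)
        if (eff, oth) == (counted, alt):
            rows.append((vid, "matched", False))
        elif (eff, oth) == (alt, counted):
            rows.append((vid, "allele_swapped", True))
        elif rc is not None and (eff, oth) == rc:
            rows.append((vid, "strand_flipped", False))
        elif rc is not None and (eff, oth) == rc[::-1]:
            rows.append((vid, "strand_flipped", True))
        else:
            # allele labels irreconcilable under any orientation
            rows.append((vid, "ambiguous_dropped", False))
            n_ambiguous += 1
    if n_ambiguous:
        logger.warning(
            "%d score variant(s) dropped as strand-ambiguous or allele-mismatched",
            n_ambiguous,
        )
    table = pd.DataFrame(rows, columns=["variant_id", "status", "complement_dosage"])
    return HarmonizationReport(table, score_name=score.name)


@dataclass
class PRSTable:
    """Per-sample raw and standardized scores.

    ``table``: DataFrame indexed by sample_id with columns ``raw_score``,
    ``n_variants_used`` and ``z_score`` (NaN until :func:`standardize`).
    """

    table: pd.DataFrame
    score_name: str = "PRS"

    @property
    def raw(self) -> pd.Series:
        return self.table["raw_score"]

    @property
    def z(self) -> pd.Series:
        return self.table["z_score"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path, score_name: str = "PRS") -> "PRSTable":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        df.index = df.index.astype(str)
        return cls(df, score_name=score_name)


def compute_prs(
    score: ScoreFile,
    panel: GenotypePanel,
    report: HarmonizationReport | None = None,
    missing_policy: str = "skip",
) -> PRSTable:
    """Sum effect-allele dosage times ln(OR) weight per sample.

    ``missing_policy='skip'`` omits a variant from a sample's sum when its
    dosage is missing (``n_variants_used`` reflects this, mirroring scoring
    on the markers actually available).  ``'mean_dosage'`` substitutes the
    variant's mean effective dosage over non-missing samples.
    """
    if missing_policy not in ("skip", "mean_dosage"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if report is None:
        report = harmonize(score, panel)
    contrib = report.contributing()
    if len(contrib) == 0:
        raise ValueError("no score variants contribute after harmonization")
    ids = contrib["variant_id"].tolist()
    D = panel.dosages[ids].to_numpy(float).copy()
    comp = contrib["complement_dosage"].to_numpy(bool)
    D[:, comp] = 2.0 - D[:, comp]
    w = score.weights.loc[ids].to_numpy(float)

    observed = ~np.isnan(D)
    if missing_policy == "mean_dosage":
        col_mean = np.nanmean(np.where(observed, D, np.nan), axis=0)
        col_mean = np.nan_to_num(col_mean)  # variant missing everywhere contributes 0
        D = np.where(observed, D, col_mean)
        raw = D @ w
        n_used = np.full(len(D), len(ids))
    else:
        raw = np.nansum(np.where(observed, D, 0.0) * w, axis=1)
        n_used = observed.sum(axis=1)
    out = pd.DataFrame(
        {
            "raw_score": raw,
            "n_variants_used": n_used.astype(int),
            "z_score": np.nan,
        },
        index=pd.Index(panel.sample_ids, name="sample_id"),
    )
    return PRSTable(out, score_name=score.name)


def standardize(prs: PRSTable, reference: Sequence[str] | None = None) -> PRSTable:
    """Fill z-scores as (raw - mean_ref) / sd_ref with the n-1 denominator.

    ``reference`` selects the samples defining mean/sd (default: all
    samples); the transform is applied to every sample.
    """
    table = prs.table.copy()
    ref = table.loc[list(reference)] if reference is not None else table
    if len(ref) < 2:
        raise ValueError("standardization reference needs at least 2 samples")
    mu = ref["raw_score"].mean()
    sd = ref["raw_score"].std(ddof=1)
    if sd == 0 or not math.isfinite(sd):
        raise ValueError("zero raw-score variance in standardization reference")
    table["z_score"] = (table["raw_score"] - mu) / sd
    return PRSTable(table, score_name=prs.score_name)
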