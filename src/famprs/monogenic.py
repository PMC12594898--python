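"""Rare pathogenic-variant screening in candidate disease genes.

Two evidence streams flag a variant: membership of a curated candidate-gene
list combined with a loss-of-function consequence, and a pathogenic
assertion from a clinical database.  ``merge_mode='shared'`` demands both
(the default coding rule); ``'union'`` accepts either.  Flagged variants
are then screened across the genotype panel: dosage 1 marks a heterozygous
carrier, dosage 2 a homozygous one, and the allele frequency is recomputed
from the called genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .cohort import SelectionResult
from .scoring import GenotypePanel

logger = logging.getLogger(__name__)

#: consequence classes treated as loss-of-function
LOF_CLASSES = frozenset(
    {"stop_gained", "frameshift", "splice_donor", "splice_acceptor", "start_lost"}
)

ANNOTATION_COLUMNS = ["variant_id", "gene", "consequence"]


def _clinvar_flag(annotations: pd.DataFrame) -> pd.Series:
    if "clinvar_pathogenic" in annotations.columns:
        return annotations["clinvar_pathogenic"].astype(bool)
    if "clinvar_significance" in annotations.columns:
        sig = annotations["clinvar_significance"].astype(str).str.lower()
        return sig.str.contains("pathogenic") & ~sig.str.contains("conflicting")
    raise ValueError(
        "annotations need a clinvar_pathogenic or clinvar_significance column"
    )


def build_pathogenic_set(
    candidate_genes: Iterable[str],
    annotations: pd.DataFrame,
    merge_mode: str = "shared",
) -> pd.DataFrame:
    """Merge candidate-gene LOF evidence with clinical pathogenicity calls.

    Returns the flagged subset of ``annotations`` with a ``provenance``
    column in {candidate_lof, clinvar_pathogenic, both}.
    """
    if merge_mode not in ("shared", "union"):
        raise ValueError(f"unknown merge_mode {merge_mode!r}")
    genes = set(candidate_genes)
    if not genes:
        raise ValueError("candidate gene list is empty")
    if len(annotations) == 0:
        raise ValueError("empty annotation table")
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValueError(f"annotation table lacks columns: {missing}")
    df = annotations.copy()
    cand_lof = df["gene"].isin(genes) & df["consequence"].isin(LOF_CLASSES)
    clinvar = _clinvar_flag(df)
    keep = (cand_lof & clinvar) if merge_mode == "shared" else (cand_lof | clinvar)
    out = df[keep].copy()
    prov = np.where(
        cand_lof[keep] & clinvar[keep],
        "both",
        np.where(cand_lof[keep], "candidate_lof", "clinvar_pathogenic"),
    )
    out["provenance"] = prov
    return out.reset_index(drop=True)


@dataclass
class CarrierTable:
    """Per-variant carrier listing with recomputed allele frequencies.

    ``table`` columns: variant_id, gene, status (present/absent), n_het,
    n_hom, n_case_carriers, n_control_carriers, allele_frequency,
    het_carriers and hom_carriers (comma-joined sample ids).
    """

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def gene_summary(self) -> dict:
        present = self.table[self.table["status"] == "present"]
        out = {}
        for gene, grp in present.groupby("gene"):
            out[str(gene)] = {
                "n_variants": int(len(grp)),
                "n_het_carriers": int(grp["n_het"].sum()),
                "n_hom_carriers": int(grp["n_hom"].sum()),
                "max_allele_frequency": float(grp["allele_frequency"].max()),
            }
        return out


def flag_carriers(
    panel: GenotypePanel,
    flagged: pd.DataFrame,
    selection: SelectionResult | None = None,
) -> CarrierTable:
    """Screen the panel for carriers of each flagged variant.

    Dosage counts the pathogenic allele: 1 = heterozygous, 2 = homozygous.
    Allele frequency = (het + 2*hom) / (2 * n_called).  Variants absent
    from the panel are reported with status 'absent', never fatally.
    Case/control carrier counts use the selection result when given.
    """
    cases = set(selection.case_ids) if selection is not None else set()
    controls = set(selection.control_ids) if selection is not None else set()
    samples = np.asarray(panel.sample_ids)
    rows = []
    for rec in flagged.itertuples(index=False):
        vid = rec.variant_id
        gene = getattr(rec, "gene", "")
        if vid not in panel.dosages.columns:
            logger.info("flagged variant %s absent from panel", vid)
            rows.append(
                dict(
                    variant_id=vid, gene=gene, status="absent", n_het=0, n_hom=0,
                    n_case_carriers=0, n_control_carriers=0,
                    allele_frequency=np.nan, het_carriers="", hom_carriers="",
                )
            )
            continue
        d = panel.dosages[vid].to_numpy(float)
        called = ~np.isnan(d)
        het = samples[called & (d == 1)]
        hom = samples[called & (d == 2)]
        carriers = set(het) | set(hom)
        n_called = int(called.sum())
        freq = (len(het) + 2 * len(hom)) / (2 * n_called) if n_called else np.nan
        rows.append(
            dict(
                variant_id=vid,
                gene=gene,
                status="present",
                n_het=len(het),
                n_hom=len(hom),
                n_case_carriers=len(carriers & cases),
                n_control_carriers=len(carriers & controls),
                allele_frequency=freq,
                het_carriers=",".join(sorted(het)),
                hom_carriers=",".join(sorted(hom)),
            )
        )
    return CarrierTable(pd.DataFrame(rows))


def load_candidate_genes(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return [
            line.strip()
            for line in fh
            if line.strip() and not line.lstrip().startswith("#")
        ]
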