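"""GWAS-catalog parsing and construction of disease-specific SNP panels.

Builds unweighted risk-score panels from an association table in the 2014
GWAS Catalog tab-separated dialect: filter to genome-wide-significant,
risk-allele-annotated, biallelic records; merge supplemental
literature-review SNPs; collapse each panel to approximately independent
SNPs by iterative LD pruning; and intersect with published risk scores.

Every stage is bookkept: a provenance log accounts for each input SNP as
kept or removed with a reason, so panel sizes are auditable end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix, stage_rng

__all__ = [
    "DISEASE_GROUPS",
    "DEFAULT_GROUP_KEYWORDS",
    "CATALOG_COLUMNS",
    "SNPPanel",
    "CatalogFormatError",
    "parse_catalog",
    "classify_trait",
    "filter_records",
    "merge_supplemental",
    "panels_from_records",
    "ld_prune",
    "published_grs_subset",
    "write_panel_tsv",
    "read_panel_tsv",
]

DISEASE_GROUPS = ("alzheimers", "cvd_stroke", "t2d", "cancer", "other")

#: Keyword table mapping free-text trait names to disease groups.  This is a
#: user-editable default: pass your own mapping to parse_catalog/classify_trait
#: to change the grouping.
DEFAULT_GROUP_KEYWORDS: dict[str, tuple[str, ...]] = {
    "alzheimers": ("alzheimer",),
    "cvd_stroke": (
        "cardiovascular",
        "coronary",
        "myocardial",
        "stroke",
        "heart disease",
        "heart failure",
        "atrial fibrillation",
    ),
    "t2d": ("type 2 diabetes", "type ii diabetes"),
    "cancer": (
        "cancer",
        "carcinoma",
        "melanoma",
        "leukemia",
        "leukaemia",
        "lymphoma",
        "glioma",
        "neuroblastoma",
        "myeloma",
    ),
}

CATALOG_COLUMNS = {
    "snps": "SNPS",
    "trait": "DISEASE/TRAIT",
    "p_value": "P-VALUE",
    "risk_allele": "STRONGEST SNP-RISK ALLELE",
}
#: Optional column listing the SNP's common alleles (e.g. "A/G"); when absent
#: every record is assumed biallelic.
ALLELES_COLUMN = "ALLELES"

RECORD_COLUMNS = [
    "snp_id",
    "trait",
    "disease_group",
    "p_value",
    "risk_allele",
    "allele_list",
    "source",
]


class CatalogFormatError(ValueError):
    """A required catalog column is missing or malformed."""


@dataclass
class SNPPanel:
    """An ordered, risk-allele-annotated SNP panel for one disease group.

    ``snps`` has columns ``snp_id`` and ``risk_allele`` (one row per SNP, no
    duplicates); ``provenance`` accumulates ``(snp_id, action, reason)``
    triples across the pipeline stages that produced the panel.
    """

    disease_group: str
    snps: pd.DataFrame
    provenance: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.snps.duplicated("snp_id").any():
            dups = self.snps.loc[self.snps.duplicated("snp_id"), "snp_id"].tolist()
            raise ValueError(f"duplicate SNPs in panel: {dups}")

    def __len__(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["snp_id"])

    def risk_allele_map(self) -> dict[str, str]:
        return dict(zip(self.snps["snp_id"], self.snps["risk_allele"]))

    def provenance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.provenance, columns=["snp_id", "action", "reason"])


def classify_trait(trait: str, keywords: dict[str, tuple[str, ...]] | None = None) -> str:
    """Map a free-text trait name to a disease group via keyword matching."""
    kw = keywords if keywords is not None else DEFAULT_GROUP_KEYWORDS
    low = trait.lower()
    for group, words in kw.items():
        if any(w in low for w in words):
            return group
    return "other"


def _parse_risk_allele(cell: object) -> tuple[str | None, str | None]:
    """Split the "rs12345-A" convention; returns (rsid_from_cell, allele)."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None, None
    text = str(cell).strip()
    if "-" not in text:
        return (text or None), None
    rsid, _, allele = text.rpartition("-")
    allele = allele.strip().upper()
    if allele in {"A", "C", "G", "T"}:
        return rsid.strip(), allele
    return rsid.strip(), None  # "?" or other unparseable codes


def _parse_alleles(cell: object) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return ()
    text = str(cell).strip()
    if not text:
        return ()
    for sep in ("/", ",", ";"):
        if sep in text:
            return tuple(a.strip().upper() for a in text.split(sep) if a.strip())
    return (text.upper(),)


def parse_catalog(
    path,
    keywords: dict[str, tuple[str, ...]] | None = None,
    source: str = "catalog",
) -> pd.DataFrame:
    """Read a GWAS-catalog-dialect TSV into an association-record table.

    Expects tab-separated columns ``SNPS``, ``DISEASE/TRAIT``, ``P-VALUE``
    and ``STRONGEST SNP-RISK ALLELE`` (risk allele in the ``rsID-A``
    convention; ``rsID-?`` yields a record with no risk allele, retained and
    flagged).  An optional ``ALLELES`` column gives the SNP's common alleles;
    without it records are assumed biallelic.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CATALOG_COLUMNS.values() if c not in raw.columns]
    if missing:
        raise CatalogFormatError(f"catalog file lacks required column(s): {missing}")

    records = []
    for _, row in raw.iterrows():
        snp_id = str(row[CATALOG_COLUMNS["snps"]]).strip()
        trait = str(row[CATALOG_COLUMNS["trait"]]).strip()
        try:
            p_value = float(row[CATALOG_COLUMNS["p_value"]])
        except (TypeError, ValueError):
            p_value = np.nan
        _, allele = _parse_risk_allele(row[CATALOG_COLUMNS["risk_allele"]])
        alleles = (
            _parse_alleles(row[ALLELES_COLUMN]) if ALLELES_COLUMN in raw.columns else ()
        )
        records.append(
            {
                "snp_id": snp_id,
                "trait": trait,
                "disease_group": classify_trait(trait, keywords),
                "p_value": p_value,
                "risk_allele": allele,
                "allele_list": alleles,
                "source": source,
            }
        )
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


def filter_records(
    records: pd.DataFrame,
    p_threshold: float = 5e-8,
    allow_multiallelic: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the significance / risk-allele / biallelic filters.

    Keeps records with ``p_value < p_threshold`` (strict), a parsed risk
    allele, and at most two listed alleles (unless ``allow_multiallelic``).
    Duplicate rsIDs within a disease group collapse to the smallest p-value.
    Returns ``(kept, log)`` where the log accounts for every input record.
    """
    if p_threshold <= 0:
        raise ValueError("p_threshold must be positive")
    if len(records) == 0:
        empty = pd.DataFrame(columns=RECORD_COLUMNS)
        return empty, pd.DataFrame(columns=["snp_id", "disease_group", "action", "reason"])
    log_rows = []
    keep_mask = []
    for _, row in records.iterrows():
        reason = None
        if not np.isfinite(row["p_value"]) or not row["p_value"] < p_threshold:
            reason = "not genome-wide significant"
        elif row["risk_allele"] is None or (
            isinstance(row["risk_allele"], float) and np.isnan(row["risk_allele"])
        ):
            reason = "no risk allele"
        elif not allow_multiallelic and len(row["allele_list"]) > 2:
            reason = "multiallelic"
        keep_mask.append(reason is None)
        log_rows.append(
            {
                "snp_id": row["snp_id"],
                "disease_group": row["disease_group"],
                "action": "kept" if reason is None else "removed",
                "reason": reason or "passed filters",
            }
        )
    kept = records.loc[keep_mask].copy()

    # deduplicate within disease group, smallest p wins
    kept = kept.sort_values(["disease_group", "snp_id", "p_value"], kind="stable")
    dup = kept.duplicated(["disease_group", "snp_id"], keep="first")
    for _, row in kept.loc[dup].iterrows():
        log_rows.append(
            {
                "snp_id": row["snp_id"],
                "disease_group": row["disease_group"],
                "action": "removed",
                "reason": "duplicate rsID (kept smallest p)",
            }
        )
    kept = kept.loc[~dup].reset_index(drop=True)
    return kept, pd.DataFrame(log_rows)


def merge_supplemental(
    records: pd.DataFrame, literature_records: pd.DataFrame
) -> pd.DataFrame:
    """Union catalog records with literature-review SNPs.

    Duplicated rsIDs within a disease group resolve in favour of the catalog
    entry; a duplicate carrying a different risk allele is a contradiction
    and raises.
    """
    lit = literature_records.copy()
    lit["source"] = "literature"
    merged = pd.concat([records, lit], ignore_index=True)
    conflicts = []
    for (group, snp), sub in merged.groupby(["disease_group", "snp_id"]):
        if sub["risk_allele"].nunique(dropna=False) > 1:
            conflicts.append(snp)
    if conflicts:
        raise ValueError(
            f"conflicting risk alleles between catalog and literature for: {sorted(set(conflicts))}"
        )
    merged["_src_rank"] = (merged["source"] != "catalog").astype(int)
    merged = merged.sort_values(["disease_group", "snp_id", "_src_rank"], kind="stable")
    merged = merged.drop_duplicates(["disease_group", "snp_id"], keep="first")
    return merged.drop(columns="_src_rank").reset_index(drop=True)


def panels_from_records(records: pd.DataFrame) -> dict[str, SNPPanel]:
    """Split filtered records into one risk-allele-annotated panel per group."""
    panels = {}
    for group, sub in records.groupby("disease_group"):
        if group == "other":
            continue
        snps = sub[["snp_id", "risk_allele"]].reset_index(drop=True)
        prov = [(s, "kept", "panel member") for s in snps["snp_id"]]
        panels[group] = SNPPanel(disease_group=group, snps=snps, provenance=prov)
    return panels


def _pairwise_r2(dosage: pd.DataFrame) -> pd.DataFrame:
    """Squared Pearson correlation of dosages, pairwise-complete over calls."""
    zero_var = dosage.std(skipna=True) == 0
    if zero_var.any():
        warnings.warn(
            f"zero-variance SNP(s) treated as r^2 = 0: {list(dosage.columns[zero_var])}",
            stacklevel=3,
        )
    r = dosage.corr(method="pearson", min_periods=2)
    r2 = r.pow(2).fillna(0.0)
    np.fill_diagonal(r2.values, 0.0)
    return r2


def ld_prune(
    panel: SNPPanel,
    genotypes: GenotypeMatrix,
    r2_threshold: float = 0.8,
    seed: int = 0,
) -> SNPPanel:
    """Iteratively remove one member of each SNP pair in LD above threshold.

    Pairwise r-squared is the squared Pearson correlation of risk-allele
    dosages over individuals with calls at both SNPs.  While any pair exceeds
    the threshold, the first violating pair in rsID order is resolved by a
    seeded uniform choice of which member to drop, which makes the pruned
    panel deterministic for a fixed seed and guarantees the output contains
    no pair above threshold (chains A-B-C are pruned to closure).
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must be in (0, 1]")
    missing = [s for s in panel.snp_ids if s not in set(genotypes.snps)]
    if missing:
        raise KeyError(f"panel SNP(s) absent from genotypes: {missing}")

    rng = stage_rng(seed, "ld-prune")
    dosage = genotypes.to_frame()[panel.snp_ids]
    r2 = _pairwise_r2(dosage)
    alive = {s: True for s in panel.snp_ids}
    provenance = list(panel.provenance)

    while True:
        live = [s for s in panel.snp_ids if alive[s]]
        sub = r2.loc[live, live]
        viol = np.argwhere(np.triu(sub.to_numpy() > r2_threshold, k=1))
        if len(viol) == 0:
            break
        pairs = sorted((live[i], live[j]) for i, j in viol)
        a, b = pairs[0]
        drop = a if rng.random() < 0.5 else b
        other = b if drop == a else a
        alive[drop] = False
        provenance.append(
            (drop, "removed", f"LD r^2 > {r2_threshold} with {other}")
        )

    kept = panel.snps.loc[panel.snps["snp_id"].map(alive)].reset_index(drop=True)
    return SNPPanel(disease_group=panel.disease_group, snps=kept, provenance=provenance)


def published_grs_subset(panel: SNPPanel, published_list: pd.DataFrame) -> SNPPanel:
    """Restrict a panel to the SNPs of a published genetic risk score.

    ``published_list`` has columns ``snp_id`` and ``exclude_reason`` (empty
    for usable SNPs; otherwise e.g. "no risk allele", "ambiguous coding",
    "multiple risk alleles", "poor imputation quality").  The result is the
    intersection of the panel with the usable published SNPs; the provenance
    log records the disposition of every published SNP.
    """
    provenance = list(panel.provenance)
    in_panel = set(panel.snp_ids)
    keep = []
    for _, row in published_list.iterrows():
        snp = row["snp_id"]
        reason = row.get("exclude_reason")
        if isinstance(reason, str) and reason.strip():
            provenance.append((snp, "removed", reason.strip()))
        elif snp not in in_panel:
            provenance.append((snp, "removed", "not in panel"))
        else:
            provenance.append((snp, "kept", "published GRS member"))
            keep.append(snp)
    kept = panel.snps.loc[panel.snps["snp_id"].isin(keep)].reset_index(drop=True)
    return SNPPanel(disease_group=panel.disease_group, snps=kept, provenance=provenance)


def write_panel_tsv(panel: SNPPanel, path, provenance_path=None) -> None:
    out = panel.snps.copy()
    out["disease_group"] = panel.disease_group
    out.to_csv(path, sep="\t", index=False)
    if provenance_path is not None:
        panel.provenance_frame().to_csv(provenance_path, sep="\t", index=False)


def read_panel_tsv(path) -> SNPPanel:
    df = pd.read_csv(path, sep="\t")
    group = df["disease_group"].iloc[0] if len(df) else "other"
    return SNPPanel(
        disease_group=group, snps=df[["snp_id", "risk_allele"]].reset_index(drop=True)
    )
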