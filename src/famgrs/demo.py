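"""Engineered demonstration inputs with auditable panel bookkeeping.

Builds a synthetic GWAS-catalog table and matching genotype LD structure in
which every filtering stage has a known, exact outcome:

* four disease groups whose catalogs contain 1143 genome-wide-significant,
  risk-allele-annotated records (12 of them multiallelic and hence dropped),
  plus 10 supplemental literature SNPs for the Alzheimer's group;
* per group, a set of engineered perfect-LD pairs so pruning at r^2 > 0.8
  removes exactly 20 / 90 / 55 / 58 SNPs, yielding panels of
  93 / 239 / 155 / 431 SNPs (918 total);
* a second tier of moderate-LD pairs (r^2 ~ 0.45) so re-pruning the panels
  at r^2 > 0.2 yields the stricter 83 / 218 / 137 / 386 panels;
* published risk-score lists with per-SNP exclusion flags reproducing the
  11 -> 8 (Alzheimer's), 18 -> 14 (type 2 diabetes) and 29 -> 20 / 13 -> 12
  (cardiovascular) subset sizes.

All ids, traits and genotypes are synthetic; the structure, not the content,
mirrors the real inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import CohortConfig, GenotypeMatrix, generate_genotypes, stage_rng
from .panel import ALLELES_COLUMN, CATALOG_COLUMNS, RECORD_COLUMNS

__all__ = ["DemoInputs", "make_demo_inputs", "make_demo_genotypes", "GROUP_DESIGN"]

#: Per-group design: (trait name, catalog kept, strong pairs, moderate pairs,
#: literature SNPs).  catalog_kept counts significant biallelic records with
#: risk alleles; strong pairs lose one member at r^2 > 0.8; moderate pairs
#: lose one member at r^2 > 0.2.
GROUP_DESIGN = {
    "alzheimers": {"trait": "Alzheimer's disease", "catalog_kept": 103, "strong_pairs": 20, "moderate_pairs": 10, "literature": 10},
    "cvd_stroke": {"trait": "Coronary heart disease", "catalog_kept": 329, "strong_pairs": 90, "moderate_pairs": 21, "literature": 0},
    "t2d": {"trait": "Type 2 diabetes", "catalog_kept": 210, "strong_pairs": 55, "moderate_pairs": 18, "literature": 0},
    "cancer": {"trait": "Breast cancer", "catalog_kept": 489, "strong_pairs": 58, "moderate_pairs": 45, "literature": 0},
}

_N_MULTIALLELIC_PER_GROUP = 3  # 12 total; significant but > 2 alleles
_RISK_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}  # never strand-ambiguous


@dataclass
class DemoInputs:
    """Synthetic catalog, literature and published-GRS fixtures plus the
    LD layout needed to generate matching genotypes."""

    catalog: pd.DataFrame  # GWAS-catalog TSV dialect
    literature: pd.DataFrame  # parsed record format, source="literature"
    published_lists: dict[str, pd.DataFrame]
    strong_pairs: dict[str, list[tuple[str, str]]]
    moderate_pairs: dict[str, list[tuple[str, str]]]
    risk_alleles: dict[str, str]
    group_snps: dict[str, list[str]]  # all kept SNPs per group (pre-pruning)

    @property
    def all_snps(self) -> list[str]:
        out: list[str] = []
        for group in GROUP_DESIGN:
            out.extend(self.group_snps[group])
        return out


def make_demo_inputs(seed: int = 0) -> DemoInputs:
    """Construct the engineered catalog/literature/published fixtures."""
    rng = stage_rng(seed, "demo-catalog")
    next_rs = 1000001
    catalog_rows = []
    literature_rows = []
    strong_pairs: dict[str, list[tuple[str, str]]] = {}
    moderate_pairs: dict[str, list[tuple[str, str]]] = {}
    risk_alleles: dict[str, str] = {}
    group_snps: dict[str, list[str]] = {}
    published_lists: dict[str, pd.DataFrame] = {}

    def new_rs() -> str:
        nonlocal next_rs
        rs = f"rs{next_rs}"
        next_rs += 1
        return rs

    def sig_p() -> float:
        return float(10.0 ** rng.uniform(-30, -8.5))

    for group, design in GROUP_DESIGN.items():
        trait = design["trait"]
        n_strong = design["strong_pairs"]
        n_mod = design["moderate_pairs"]
        n_lit = design["literature"]
        n_catalog = design["catalog_kept"]

        snps = [new_rs() for _ in range(n_catalog + n_lit)]
        group_snps[group] = snps
        for s in snps:
            risk_alleles[s] = str(rng.choice(["A", "C", "G", "T"]))

        # layout: moderate pairs first, then strong-pair bases + partners,
        # then free singletons; literature SNPs are the last n_lit singletons.
        mod = [(snps[2 * k], snps[2 * k + 1]) for k in range(n_mod)]
        strong_start = 2 * n_mod
        strong = [
            (snps[strong_start + 2 * k], snps[strong_start + 2 * k + 1])
            for k in range(n_strong)
        ]
        moderate_pairs[group] = mod
        strong_pairs[group] = strong

        catalog_snps = snps[: n_catalog] if n_lit else snps
        lit_snps = snps[n_catalog:]
        for s in catalog_snps:
            r = risk_alleles[s]
            catalog_rows.append(
                {
                    CATALOG_COLUMNS["snps"]: s,
                    CATALOG_COLUMNS["trait"]: trait,
                    CATALOG_COLUMNS["p_value"]: f"{sig_p():.3e}",
                    CATALOG_COLUMNS["risk_allele"]: f"{s}-{r}",
                    ALLELES_COLUMN: f"{r}/{_RISK_PARTNER[r]}",
                }
            )
        for s in lit_snps:
            r = risk_alleles[s]
            literature_rows.append(
                {
                    "snp_id": s,
                    "trait": trait,
                    "disease_group": group,
                    "p_value": 1e-10,
                    "risk_allele": r,
                    "allele_list": (r, _RISK_PARTNER[r]),
                    "source": "literature",
                }
            )

        # significant but multiallelic records: removed by the biallelic filter
        for _ in range(_N_MULTIALLELIC_PER_GROUP):
            s = new_rs()
            catalog_rows.append(
                {
                    CATALOG_COLUMNS["snps"]: s,
                    CATALOG_COLUMNS["trait"]: trait,
                    CATALOG_COLUMNS["p_value"]: f"{sig_p():.3e}",
                    CATALOG_COLUMNS["risk_allele"]: f"{s}-A",
                    ALLELES_COLUMN: "A/G/T",
                }
            )
        # sub-threshold and unannotated records: removed by the other filters
        for _ in range(2):
            s = new_rs()
            catalog_rows.append(
                {
                    CATALOG_COLUMNS["snps"]: s,
                    CATALOG_COLUMNS["trait"]: trait,
                    CATALOG_COLUMNS["p_value"]: "2.0e-06",
                    CATALOG_COLUMNS["risk_allele"]: f"{s}-C",
                    ALLELES_COLUMN: "C/T",
                }
            )
        s = new_rs()
        catalog_rows.append(
            {
                CATALOG_COLUMNS["snps"]: s,
                CATALOG_COLUMNS["trait"]: trait,
                CATALOG_COLUMNS["p_value"]: f"{sig_p():.3e}",
                CATALOG_COLUMNS["risk_allele"]: f"{s}-?",
                ALLELES_COLUMN: "A/G",
            }
        )

    # published GRS lists: usable members are free singletons of each panel
    # (always retained by LD pruning), exclusions are flagged extra rsIDs.
    def free_singles(group: str) -> list[str]:
        d = GROUP_DESIGN[group]
        start = 2 * d["moderate_pairs"] + 2 * d["strong_pairs"]
        return group_snps[group][start:]

    def published(group: str, n_usable: int, exclusions: list[str]) -> pd.DataFrame:
        usable = free_singles(group)[:n_usable]
        rows = [{"snp_id": s, "exclude_reason": ""} for s in usable]
        rows += [
            {"snp_id": new_rs(), "exclude_reason": reason} for reason in exclusions
        ]
        return pd.DataFrame(rows, columns=["snp_id", "exclude_reason"])

    published_lists["alzheimers_11snp"] = published(
        "alzheimers", 8, ["no risk allele", "no risk allele", "ambiguous coding"]
    )
    published_lists["t2d_18snp"] = published(
        "t2d",
        14,
        ["no risk allele", "ambiguous coding", "ambiguous coding", "ambiguous coding"],
    )
    published_lists["cvd_29snp"] = published(
        "cvd_stroke",
        20,
        ["multiple risk alleles"] * 6
        + ["poor imputation quality", "poor imputation quality", "ambiguous coding"],
    )
    published_lists["cvd_13snp"] = published("cvd_stroke", 12, ["no risk allele"])

    catalog = pd.DataFrame(catalog_rows)
    literature = pd.DataFrame(literature_rows, columns=RECORD_COLUMNS)
    return DemoInputs(
        catalog=catalog,
        literature=literature,
        published_lists=published_lists,
        strong_pairs=strong_pairs,
        moderate_pairs=moderate_pairs,
        risk_alleles=risk_alleles,
        group_snps=group_snps,
    )


def make_demo_genotypes(
    pedigree: pd.DataFrame,
    inputs: DemoInputs,
    config: CohortConfig,
    moderate_r2: float = 0.45,
) -> GenotypeMatrix:
    """Genotypes for every kept catalog/literature SNP with the engineered LD.

    Moderate pairs are generated as two-SNP founder LD blocks at
    ``moderate_r2``; strong pairs are exact dosage duplicates (r^2 = 1);
    everything else is independent.  Ref/alt orientation is aligned with the
    catalog's risk alleles so a VCF round trip reproduces the dosages.
    """
    mod_pairs = [p for g in GROUP_DESIGN for p in inputs.moderate_pairs[g]]
    strong = [p for g in GROUP_DESIGN for p in inputs.strong_pairs[g]]
    dup_of = {b: a for a, b in strong}
    base_order: list[str] = []
    for a, b in mod_pairs:
        base_order += [a, b]
    for s in inputs.all_snps:
        if s in dup_of or s in set(base_order):
            continue
        base_order.append(s)

    block_sizes = tuple([2] * len(mod_pairs) + [1] * (len(base_order) - 2 * len(mod_pairs)))
    gen_cfg = replace(
        config, ld_block_sizes=block_sizes, within_block_r2=moderate_r2
    )
    gm = generate_genotypes(pedigree, len(base_order), gen_cfg, snp_ids=base_order)

    # append exact duplicates for the strong pairs
    col = {s: j for j, s in enumerate(gm.snps)}
    dup_ids = [b for _, b in strong]
    dup_cols = np.column_stack([gm.dosage[:, col[dup_of[b]]] for b in dup_ids])
    dosage = np.hstack([gm.dosage, dup_cols])
    snps = gm.snps + dup_ids

    # orient ref/alt to the catalog risk alleles
    rng = stage_rng(config.seed, "demo-orientation")
    ref, alt, risk = [], [], []
    for s in snps:
        r = inputs.risk_alleles[s]
        other = _RISK_PARTNER[r]
        if rng.random() < 0.5:
            ref.append(r)
            alt.append(other)
        else:
            ref.append(other)
            alt.append(r)
        risk.append(r)

    return GenotypeMatrix(
        individuals=gm.individuals,
        snps=snps,
        dosage=dosage,
        ref=np.array(ref),
        alt=np.array(alt),
        risk_allele=np.array(risk),
    )
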