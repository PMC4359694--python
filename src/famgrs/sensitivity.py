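"""Robustness battery: SNP removals, stricter LD pruning, published panels,
and substitution of the generation-one controls with an external cohort.

Each scenario changes exactly one thing about the primary analysis — the
panel composition, the LD threshold, or the control group — recomputes the
scores and offsets, and refits the models, so results tables are directly
comparable row-for-row with the primary results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix, stage_rng
from .grs import compute_grs
from .models import run_analysis_suite
from .panel import SNPPanel, ld_prune, published_grs_subset

__all__ = [
    "SensitivityScenario",
    "remove_snps",
    "remove_snps_and_refit",
    "make_external_controls",
    "substitute_controls",
    "run_scenarios",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SensitivityScenario:
    """One robustness re-analysis; exactly one modification axis is active."""

    name: str
    snps_removed: tuple[str, ...] = ()
    ld_threshold_override: float | None = None
    panel_override: pd.DataFrame | None = None  # published GRS list
    control_substitution: object | None = None  # (individuals, GenotypeMatrix)

    def __post_init__(self) -> None:
        axes = [
            bool(self.snps_removed),
            self.ld_threshold_override is not None,
            self.panel_override is not None,
            self.control_substitution is not None,
        ]
        if sum(axes) != 1:
            raise ValueError(
                f"scenario {self.name!r} must activate exactly one modification axis"
            )


def remove_snps(panel: SNPPanel, snp_list: Sequence[str]) -> SNPPanel:
    """Drop the given SNPs from a panel (absent SNPs warn and are skipped)."""
    present = set(panel.snp_ids)
    provenance = list(panel.provenance)
    to_drop = []
    for snp in snp_list:
        if snp not in present:
            logger.warning("SNP %s not in %s panel; skipped", snp, panel.disease_group)
            continue
        to_drop.append(snp)
        provenance.append((snp, "removed", "sensitivity removal"))
    kept = panel.snps.loc[~panel.snps["snp_id"].isin(to_drop)].reset_index(drop=True)
    if len(kept) == 0:
        raise ValueError("empty panel after SNP removal")
    return SNPPanel(disease_group=panel.disease_group, snps=kept, provenance=provenance)


def remove_snps_and_refit(
    panel: SNPPanel,
    genotypes: GenotypeMatrix,
    individuals: pd.DataFrame,
    snp_list: Sequence[str],
    models: Sequence[str] = ("poisson_glmm",),
    strata: Sequence[str] = ("generation1", "generation2", "both"),
    n_quad: int = 9,
) -> pd.DataFrame:
    """Refit all strata after removing SNPs from the panel.

    Counts and offsets are recomputed on the reduced panel, so every
    individual's offset shrinks to log(2 * remaining calls).
    """
    reduced = remove_snps(panel, snp_list)
    grs = compute_grs(genotypes, reduced)
    return run_analysis_suite(
        individuals, {reduced.disease_group: grs}, models=models, strata=strata, n_quad=n_quad
    )


def make_external_controls(
    n: int,
    template: GenotypeMatrix,
    seed: int = 0,
    id_prefix: str = "EXT",
    missing_rate: float = 0.0,
    drop_snps: Sequence[str] = (),
) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Synthesize an unrelated external control cohort.

    Draws Hardy-Weinberg genotypes at the empirical risk-allele frequencies
    of the template matrix — a stand-in for an external referent cohort
    genotyped on an overlapping SNP set (``drop_snps`` removes SNPs the
    external platform lacks).  Returns a pedigree-style table of singleton
    individuals and their genotypes.
    """
    rng = stage_rng(seed, "external-controls")
    keep = [s for s in template.snps if s not in set(drop_snps)]
    tpl = template.subset_snps(keep)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(tpl.dosage, axis=0) / 2.0
    dosage = rng.binomial(2, p, size=(n, len(keep))).astype(float)
    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = np.nan
    ids = [f"{id_prefix}{k + 1:05d}" for k in range(n)]
    gm = GenotypeMatrix(
        individuals=ids,
        snps=keep,
        dosage=dosage,
        ref=tpl.ref.copy(),
        alt=tpl.alt.copy(),
        risk_allele=tpl.risk_allele.copy(),
    )
    indiv = pd.DataFrame(
        {
            "family_id": [f"{id_prefix}F{k + 1:05d}" for k in range(n)],
            "individual_id": ids,
            "father_id": "0",
            "mother_id": "0",
            "sex": rng.choice(["M", "F"], size=n),
            "generation": 1,
            "role": "spouse_g1",
            "longevity_member": 0,
        }
    )
    return indiv, gm


def substitute_controls(
    individuals: pd.DataFrame,
    genotypes: GenotypeMatrix,
    external_individuals: pd.DataFrame,
    external_genotypes: GenotypeMatrix,
    shared_snps_only: bool = True,
) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Replace generation-one married-in controls with an external cohort.

    The original G1 controls are dropped; external individuals enter as
    singleton families with longevity_member = 0 and generation = 1 (so they
    contribute no within-family correlation, like any married-in control).
    With ``shared_snps_only`` the genotypes are intersected to the SNPs both
    cohorts carry; zero shared SNPs is an error.
    """
    shared = [s for s in genotypes.snps if s in set(external_genotypes.snps)]
    if not shared:
        raise ValueError("no SNPs shared between cohort and external controls")
    if not shared_snps_only and len(shared) != len(genotypes.snps):
        raise ValueError("external cohort lacks cohort SNPs and shared_snps_only=False")

    drop_mask = (individuals["generation"] == 1) & (individuals["longevity_member"] == 0)
    kept_ind = individuals.loc[~drop_mask].reset_index(drop=True)
    new_ind = pd.concat([kept_ind, external_individuals], ignore_index=True)

    g_main = genotypes.subset_snps(shared)
    g_ext = external_genotypes.subset_snps(shared)
    keep_rows = [i for i, ind in enumerate(g_main.individuals) if ind in set(kept_ind["individual_id"])]
    merged = GenotypeMatrix(
        individuals=[g_main.individuals[i] for i in keep_rows] + list(g_ext.individuals),
        snps=shared,
        dosage=np.vstack([g_main.dosage[keep_rows], g_ext.dosage]),
        ref=g_main.ref.copy(),
        alt=g_main.alt.copy(),
        risk_allele=g_main.risk_allele.copy(),
    )
    return new_ind, merged


def run_scenarios(
    scenarios: Sequence[SensitivityScenario],
    panel: SNPPanel,
    genotypes: GenotypeMatrix,
    individuals: pd.DataFrame,
    models: Sequence[str] = ("poisson_glmm",),
    strata: Sequence[str] = ("generation1", "generation2", "both"),
    seed: int = 0,
    n_quad: int = 9,
) -> pd.DataFrame:
    """Run each scenario and return a union-safe results table.

    Every output row carries a ``scenario`` column and is otherwise
    column-compatible with the primary results table.
    """
    frames = []
    for sc in scenarios:
        if sc.snps_removed:
            out = remove_snps_and_refit(
                panel, genotypes, individuals, sc.snps_removed,
                models=models, strata=strata, n_quad=n_quad,
            )
        elif sc.ld_threshold_override is not None:
            pruned = ld_prune(panel, genotypes, sc.ld_threshold_override, seed=seed)
            grs = compute_grs(genotypes, pruned)
            out = run_analysis_suite(
                individuals, {pruned.disease_group: grs},
                models=models, strata=strata, n_quad=n_quad,
            )
        elif sc.panel_override is not None:
            sub = published_grs_subset(panel, sc.panel_override)
            grs = compute_grs(genotypes, sub)
            out = run_analysis_suite(
                individuals, {sub.disease_group: grs},
                models=models, strata=strata, n_quad=n_quad,
            )
        else:
            ext_ind, ext_gm = sc.control_substitution  # type: ignore[misc]
            new_ind, new_gm = substitute_controls(individuals, genotypes, ext_ind, ext_gm)
            grs = compute_grs(new_gm, _restrict_panel(panel, new_gm))
            out = run_analysis_suite(
                new_ind, {panel.disease_group: grs},
                models=models, strata=strata, n_quad=n_quad,
            )
        out.insert(0, "scenario", sc.name)
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def _restrict_panel(panel: SNPPanel, genotypes: GenotypeMatrix) -> SNPPanel:
    present = set(genotypes.snps)
    kept = panel.snps.loc[panel.snps["snp_id"].isin(present)].reset_index(drop=True)
    prov = list(panel.provenance) + [
        (s, "removed", "not shared with external cohort")
        for s in panel.snp_ids
        if s not in present
    ]
    return SNPPanel(disease_group=panel.disease_group, snps=kept, provenance=prov)
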