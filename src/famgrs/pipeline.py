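"""End-to-end orchestration: simulate -> panels -> scores -> models ->
sensitivity -> power, from one config and one root seed.

Every stage writes plain-text outputs (TSV / VCF / JSON) into the output
directory and registers them in a manifest with row counts, so a rerun with
the same seed is byte-identical and auditable.  Stage seeds are derived from
the root seed by the documented crc32 split (see :func:`famgrs.cohort.stage_rng`),
so no two stages share a random stream.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortConfig,
    GenotypeMatrix,
    generate_pedigrees,
    inject_longevity_effect,
    kinship_matrix,
    read_pedigree_tsv,
    stage_rng,
    write_dosage_tsv,
    write_pedigree_tsv,
    write_vcf,
)
from .demo import GROUP_DESIGN, DemoInputs, make_demo_genotypes, make_demo_inputs
from .grs import compute_grs, orient_to_risk_allele
from .models import run_analysis_suite
from .panel import (
    SNPPanel,
    filter_records,
    ld_prune,
    merge_supplemental,
    panels_from_records,
    parse_catalog,
    read_panel_tsv,
    write_panel_tsv,
)
from .power import estimate_power
from .sensitivity import (
    SensitivityScenario,
    make_external_controls,
    run_scenarios,
)

__all__ = ["RunConfig", "PowerGrid", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "build-panels", "score", "fit", "sensitivity", "power")


@dataclass(frozen=True)
class PowerGrid:
    strata: tuple[str, ...] = ("generation1", "generation2", "both")
    panel_sizes: tuple[int, ...] = (93, 239, 155, 431)
    effects_percent: tuple[float, ...] = (1.0,)
    n_reps: int = 100


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run; one root seed drives all stages."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    models: tuple[str, ...] = ("poisson_glmm",)
    ld_threshold: float = 0.8
    strict_ld_threshold: float = 0.2
    ambiguous_policy: str = "keep"
    moderate_r2: float = 0.45
    n_external_controls: int = 300
    power: PowerGrid = field(default_factory=PowerGrid)
    n_quad: int = 9
    output_dir: str = "famgrs_run"
    seed: int = 0


def load_config(path) -> RunConfig:
    """Read a YAML run configuration (missing keys fall back to defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort = CohortConfig(**raw.get("cohort", {}))
    power_kw = raw.get("power", {})
    for key in ("strata", "panel_sizes", "effects_percent"):
        if key in power_kw:
            power_kw[key] = tuple(power_kw[key])
    power = PowerGrid(**power_kw)
    top = {
        k: v
        for k, v in raw.items()
        if k not in {"cohort", "power"}
    }
    if "models" in top:
        top["models"] = tuple(top["models"])
    return RunConfig(cohort=cohort, power=power, **top)


def _stage_seed(root: int, stage: str) -> int:
    return int(stage_rng(root, f"stage:{stage}").integers(0, 2**31 - 1))


class _State:
    """Holds in-memory intermediates and the output manifest for one run."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "package": "famgrs",
            "version": __version__,
            "seed": config.seed,
            "stage_seeds": {},
            "files": {},
        }
        self.pedigree: pd.DataFrame | None = None
        self.genotypes: GenotypeMatrix | None = None
        self.inputs: DemoInputs | None = None
        self.panels: dict[str, SNPPanel] | None = None
        self.grs_tables: dict[str, pd.DataFrame] | None = None

    def register(self, name: str, path: Path, rows: int | None = None) -> None:
        if rows is None:
            with open(path) as fh:
                rows = sum(1 for _ in fh)
        self.manifest["files"][name] = {"path": path.name, "rows": int(rows)}

    # -- lazy loading for stage-by-stage CLI use ---------------------------

    def get_pedigree(self) -> pd.DataFrame:
        if self.pedigree is None:
            self.pedigree = read_pedigree_tsv(self.out / "pedigree.tsv")
        return self.pedigree

    def get_inputs(self) -> DemoInputs:
        if self.inputs is None:
            self.inputs = make_demo_inputs(_stage_seed(self.config.seed, "demo"))
        return self.inputs

    def get_panels(self) -> dict[str, SNPPanel]:
        if self.panels is None:
            self.panels = {
                g: read_panel_tsv(self.out / f"panel_{g}.tsv") for g in GROUP_DESIGN
            }
        return self.panels

    def get_genotypes(self) -> GenotypeMatrix:
        if self.genotypes is None:
            # re-orient the VCF with the union of all panel risk alleles
            inputs = self.get_inputs()
            union = SNPPanel(
                disease_group="other",
                snps=pd.DataFrame(
                    {
                        "snp_id": list(inputs.risk_alleles),
                        "risk_allele": list(inputs.risk_alleles.values()),
                    }
                ),
            )
            self.genotypes = orient_to_risk_allele(
                self.out / "genotypes.vcf", union, self.config.ambiguous_policy
            )
        return self.genotypes

    def get_grs_tables(self) -> dict[str, pd.DataFrame]:
        if self.grs_tables is None:
            self.grs_tables = {
                g: pd.read_csv(self.out / f"grs_{g}.tsv", sep="\t") for g in GROUP_DESIGN
            }
        return self.grs_tables


def _stage_simulate(state: _State) -> None:
    cfg = state.config
    cohort = replace(cfg.cohort, seed=_stage_seed(cfg.seed, "cohort"))
    state.manifest["stage_seeds"]["cohort"] = cohort.seed
    ped = generate_pedigrees(cohort)
    inputs = state.get_inputs()
    gm = make_demo_genotypes(ped, inputs, cohort, moderate_r2=cfg.moderate_r2)
    gm = inject_longevity_effect(
        gm,
        ped,
        cohort.longevity_rate_ratio,
        cohort.family_intercept_sd,
        seed=_stage_seed(cfg.seed, "longevity"),
    )
    write_pedigree_tsv(ped, state.out / "pedigree.tsv")
    write_vcf(gm, state.out / "genotypes.vcf")
    write_dosage_tsv(gm, state.out / "dosages.tsv")
    inputs.catalog.to_csv(state.out / "catalog.tsv", sep="\t", index=False)
    state.pedigree, state.genotypes = ped, gm
    state.register("pedigree", state.out / "pedigree.tsv", rows=len(ped))
    state.register("genotypes_vcf", state.out / "genotypes.vcf", rows=gm.n_snps)
    state.register("dosages", state.out / "dosages.tsv", rows=gm.n_individuals)
    state.register("catalog", state.out / "catalog.tsv", rows=len(inputs.catalog))


def _stage_build_panels(state: _State) -> None:
    cfg = state.config
    inputs = state.get_inputs()
    records = parse_catalog(state.out / "catalog.tsv")
    kept, _log = filter_records(records)
    merged = merge_supplemental(kept, inputs.literature)
    panels = panels_from_records(merged)
    gm = state.get_genotypes()
    prune_seed = _stage_seed(cfg.seed, "ld-prune")
    state.manifest["stage_seeds"]["ld_prune"] = prune_seed
    pruned = {}
    for group, panel in panels.items():
        pruned[group] = ld_prune(panel, gm, cfg.ld_threshold, seed=prune_seed)
        write_panel_tsv(
            pruned[group],
            state.out / f"panel_{group}.tsv",
            state.out / f"provenance_{group}.tsv",
        )
        state.register(f"panel_{group}", state.out / f"panel_{group}.tsv", rows=len(pruned[group]))
        state.register(
            f"provenance_{group}",
            state.out / f"provenance_{group}.tsv",
            rows=len(pruned[group].provenance),
        )
    state.panels = pruned
    state.manifest["total_panel_snps"] = int(sum(len(p) for p in pruned.values()))


def _stage_score(state: _State) -> None:
    gm = state.get_genotypes()
    tables = {}
    for group, panel in state.get_panels().items():
        grs = compute_grs(gm, panel)
        grs.to_csv(state.out / f"grs_{group}.tsv", sep="\t", index=False)
        state.register(f"grs_{group}", state.out / f"grs_{group}.tsv", rows=len(grs))
        tables[group] = grs
    state.grs_tables = tables


def _stage_fit(state: _State) -> None:
    cfg = state.config
    ped = state.get_pedigree()
    kin = None
    if "lmm_kinship" in cfg.models:
        kin = kinship_matrix(ped)
    results = run_analysis_suite(
        ped,
        state.get_grs_tables(),
        models=cfg.models,
        kinship=kin,
        n_quad=cfg.n_quad,
    )
    results.to_csv(state.out / "results_primary.tsv", sep="\t", index=False)
    state.register("results_primary", state.out / "results_primary.tsv", rows=len(results))


def _stage_sensitivity(state: _State) -> None:
    cfg = state.config
    ped = state.get_pedigree()
    gm = state.get_genotypes()
    panels = state.get_panels()
    inputs = state.get_inputs()
    seed = _stage_seed(cfg.seed, "sensitivity")
    frames = []

    # targeted SNP removals from the Alzheimer's panel (top pair, single, all)
    ad = panels["alzheimers"]
    s = ad.snp_ids
    removal_sets = {
        "ad_remove_pair": tuple(s[:2]),
        "ad_remove_single": (s[2],),
        "ad_remove_all3": tuple(s[:3]),
    }
    scenarios = [
        SensitivityScenario(name=name, snps_removed=snps)
        for name, snps in removal_sets.items()
    ]
    frames.append(
        run_scenarios(scenarios, ad, gm, ped, models=cfg.models, seed=seed, n_quad=cfg.n_quad)
    )

    # stricter LD threshold, every disease group
    for group, panel in panels.items():
        sc = SensitivityScenario(
            name=f"{group}_ld{cfg.strict_ld_threshold}",
            ld_threshold_override=cfg.strict_ld_threshold,
        )
        frames.append(
            run_scenarios([sc], panel, gm, ped, models=cfg.models, seed=seed, n_quad=cfg.n_quad)
        )

    # published-GRS subsets
    published_groups = {
        "alzheimers_11snp": "alzheimers",
        "t2d_18snp": "t2d",
        "cvd_29snp": "cvd_stroke",
        "cvd_13snp": "cvd_stroke",
    }
    for name, group in published_groups.items():
        sc = SensitivityScenario(
            name=f"published_{name}", panel_override=inputs.published_lists[name]
        )
        frames.append(
            run_scenarios([sc], panels[group], gm, ped, models=cfg.models, seed=seed, n_quad=cfg.n_quad)
        )

    # external-control substitution (younger unrelated controls)
    ext_ind, ext_gm = make_external_controls(
        cfg.n_external_controls, gm, seed=_stage_seed(cfg.seed, "external")
    )
    sc = SensitivityScenario(
        name="external_controls", control_substitution=(ext_ind, ext_gm)
    )
    frames.append(
        run_scenarios([sc], panels["alzheimers"], gm, ped, models=cfg.models, seed=seed, n_quad=cfg.n_quad)
    )

    out = pd.concat(frames, ignore_index=True)
    out.to_csv(state.out / "results_sensitivity.tsv", sep="\t", index=False)
    state.register("results_sensitivity", state.out / "results_sensitivity.tsv", rows=len(out))


def _stage_power(state: _State) -> None:
    cfg = state.config
    grid = cfg.power
    table = estimate_power(
        strata=grid.strata,
        panel_sizes=grid.panel_sizes,
        effects_percent=grid.effects_percent,
        n_reps=grid.n_reps,
        seed=_stage_seed(cfg.seed, "power"),
        n_quad=cfg.n_quad,
        cohort=replace(cfg.cohort, seed=_stage_seed(cfg.seed, "cohort")),
    )
    table.to_csv(state.out / "power.tsv", sep="\t", index=False)
    state.register("power", state.out / "power.tsv", rows=len(table))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "build-panels": _stage_build_panels,
    "score": _stage_score,
    "fit": _stage_fit,
    "sensitivity": _stage_sensitivity,
    "power": _stage_power,
}


def run_pipeline(config: RunConfig, stages: Sequence[str] | None = None) -> dict:
    """Run the requested stages (default: all) and write the manifest.

    Returns the manifest dict.  Any stage failure raises with the stage name
    so shell callers can exit non-zero.
    """
    state = _State(config)
    manifest_path = state.out / "manifest.json"
    if manifest_path.exists():
        with open(manifest_path) as fh:
            state.manifest = json.load(fh)
        state.manifest["seed"] = config.seed
    for stage in stages or ALL_STAGES:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.time()
        logger.info("stage %s ...", stage)
        try:
            _STAGE_FUNCS[stage](state)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)
    with open(manifest_path, "w") as fh:
        json.dump(state.manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return state.manifest
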