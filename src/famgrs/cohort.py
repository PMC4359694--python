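"""Synthetic family cohorts for genetic risk score burden analyses.

This module emulates the structure of a two-generation familial-longevity
study: a set of families each ascertained through a long-lived proband, the
proband's siblings, spouses who married into the family (the controls), the
offspring of generation one, and the offspring's spouses.  Genotypes for a
panel of biallelic SNPs are produced by drawing founder haplotypes from a
block-structured Gaussian-copula model (so linkage disequilibrium within a
block hits a configurable r-squared target) and dropping them through the
pedigree by Mendelian segregation, one whole block per gamete.

A multiplicative "familial longevity" effect on the per-allele-slot
risk-allele rate can then be injected by binomial thinning (rate ratio < 1)
or boosting (rate ratio > 1) of the dosages of longevity members, leaving
the married-in controls untouched.

All randomness flows from a single integer seed; every public generator is
byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CohortConfig",
    "ConfigError",
    "GenotypeMatrix",
    "BLOOD_ROLES",
    "ROLES",
    "stage_rng",
    "generate_pedigrees",
    "generate_genotypes",
    "inject_longevity_effect",
    "kinship_matrix",
    "write_pedigree_tsv",
    "read_pedigree_tsv",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_vcf",
]

ROLES = ("proband", "sibling", "spouse_g1", "offspring", "spouse_g2")
BLOOD_ROLES = frozenset({"proband", "sibling", "offspring"})

PEDIGREE_COLUMNS = [
    "family_id",
    "individual_id",
    "father_id",
    "mother_id",
    "sex",
    "generation",
    "role",
    "longevity_member",
]


class ConfigError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Derive a stage-specific generator from one root seed.

    The split scheme is ``SeedSequence([seed, crc32(stage)])``: deterministic,
    documented, and independent across stage names.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode("utf8"))])
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: A count-distribution spec: {"kind": "fixed", "value": k} gives every family
#: exactly k; {"kind": "poisson", "mean": m} draws iid Poisson counts;
#: {"kind": "multinomial_total", "total": t} scatters exactly t individuals
#: uniformly across families (used by the defaults so cohort totals are exact).
DistSpec = Mapping[str, object]


def _draw_counts(spec: DistSpec, n_families: int, rng: np.random.Generator) -> np.ndarray:
    if not isinstance(spec, Mapping) or "kind" not in spec:
        raise ConfigError(f"invalid distribution spec: {spec!r}")
    kind = spec["kind"]
    if kind == "fixed":
        k = int(spec["value"])  # type: ignore[arg-type]
        if k < 0:
            raise ConfigError("fixed count must be >= 0")
        return np.full(n_families, k, dtype=int)
    if kind == "poisson":
        mean = float(spec["mean"])  # type: ignore[arg-type]
        if mean < 0:
            raise ConfigError("poisson mean must be >= 0")
        return rng.poisson(mean, size=n_families)
    if kind == "multinomial_total":
        total = int(spec["total"])  # type: ignore[arg-type]
        if total < 0:
            raise ConfigError("multinomial total must be >= 0")
        return rng.multinomial(total, np.full(n_families, 1.0 / n_families))
    raise ConfigError(f"unknown distribution kind {kind!r}")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the emulated study cohort.

    The defaults reproduce the published generation sizes: 583 families,
    1562 generation-one participants of whom 175 are married-in controls,
    and 3102 generation-two participants with a 0.40 spouse fraction.
    """

    n_families: int = 583
    g1_sibs_per_family: DistSpec = field(
        default_factory=lambda: {"kind": "multinomial_total", "total": 804}
    )
    g1_spouses_total: int = 175
    g2_offspring_per_family: DistSpec = field(
        default_factory=lambda: {"kind": "multinomial_total", "total": 1861}
    )
    spouse_fraction_g2: float = 0.40
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    ld_block_sizes: tuple[int, ...] = (1, 2, 1, 3)
    within_block_r2: float = 0.5
    longevity_rate_ratio: float = 1.0
    family_intercept_sd: float = 0.01
    missing_rate: float = 0.01
    seed: int = 2014

    def validate(self) -> None:
        if self.n_families < 1:
            raise ConfigError("n_families must be >= 1")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError("allele_freq_range must lie strictly inside (0, 1)")
        if not 0.0 <= self.within_block_r2 <= 1.0:
            raise ConfigError("within_block_r2 must be in [0, 1]")
        if self.longevity_rate_ratio <= 0:
            raise ConfigError("longevity_rate_ratio must be positive")
        if self.family_intercept_sd < 0:
            raise ConfigError("family_intercept_sd must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.spouse_fraction_g2 < 1.0:
            raise ConfigError("spouse_fraction_g2 must be in [0, 1)")
        if any(s < 1 for s in self.ld_block_sizes):
            raise ConfigError("ld_block_sizes entries must be >= 1")


# ---------------------------------------------------------------------------
# pedigree generation
# ---------------------------------------------------------------------------


def generate_pedigrees(config: CohortConfig) -> pd.DataFrame:
    """Generate a two-generation cohort of families.

    Returns a pedigree table with one row per study participant and columns
    ``family_id, individual_id, father_id, mother_id, sex, generation, role,
    longevity_member`` plus an internal ``partner_id`` column recording
    marriages.  Parents of generation-one siblings are latent founders whose
    ids appear in the parent columns but have no row of their own (the
    convention used by .fam files when parents were not sampled); a missing
    parent is coded ``"0"``.
    """
    config.validate()
    rng = stage_rng(config.seed, "pedigree")
    fam_ids = [f"F{k + 1:04d}" for k in range(config.n_families)]
    sib_counts = _draw_counts(config.g1_sibs_per_family, config.n_families, rng)
    off_counts = _draw_counts(config.g2_offspring_per_family, config.n_families, rng)

    rows: list[dict] = []
    blood_g1: list[int] = []  # row indices of G1 blood members

    def add_row(**kw) -> int:
        kw.setdefault("partner_id", "0")
        rows.append(kw)
        return len(rows) - 1

    for f, fam in enumerate(fam_ids):
        father, mother = f"{fam}_GP1", f"{fam}_GP2"
        idx = add_row(
            family_id=fam,
            individual_id=f"{fam}_P1",
            father_id=father,
            mother_id=mother,
            sex="M" if rng.random() < 0.5 else "F",
            generation=1,
            role="proband",
            longevity_member=1,
        )
        blood_g1.append(idx)
        for s in range(sib_counts[f]):
            idx = add_row(
                family_id=fam,
                individual_id=f"{fam}_S{s + 1}",
                father_id=father,
                mother_id=mother,
                sex="M" if rng.random() < 0.5 else "F",
                generation=1,
                role="sibling",
                longevity_member=1,
            )
            blood_g1.append(idx)

    # married-in G1 controls: spouses of distinct blood members
    n_spouse_g1 = min(config.g1_spouses_total, len(blood_g1))
    married_g1 = rng.choice(len(blood_g1), size=n_spouse_g1, replace=False)
    for k, bi in enumerate(sorted(blood_g1[j] for j in married_g1)):
        partner = rows[bi]
        sp_id = f"{partner['individual_id']}_SP"
        partner["partner_id"] = sp_id
        add_row(
            family_id=partner["family_id"],
            individual_id=sp_id,
            father_id="0",
            mother_id="0",
            sex="F" if partner["sex"] == "M" else "M",
            generation=1,
            role="spouse_g1",
            longevity_member=0,
            partner_id=partner["individual_id"],
        )

    # generation-two offspring: each assigned to a G1 blood parent in the
    # same family; the co-parent is the recorded spouse when one exists,
    # otherwise a latent (unsampled) founder shared by full siblings.
    fam_blood = {}
    for bi in blood_g1:
        fam_blood.setdefault(rows[bi]["family_id"], []).append(bi)
    offspring_rows: list[int] = []
    for f, fam in enumerate(fam_ids):
        candidates = fam_blood[fam]
        for o in range(off_counts[f]):
            bi = candidates[rng.integers(len(candidates))]
            parent = rows[bi]
            if parent["partner_id"] != "0":
                co_parent = parent["partner_id"]
            else:
                co_parent = f"{parent['individual_id']}_X"
            if parent["sex"] == "M":
                father_id, mother_id = parent["individual_id"], co_parent
            else:
                father_id, mother_id = co_parent, parent["individual_id"]
            idx = add_row(
                family_id=fam,
                individual_id=f"{fam}_O{o + 1}",
                father_id=father_id,
                mother_id=mother_id,
                sex="M" if rng.random() < 0.5 else "F",
                generation=2,
                role="offspring",
                longevity_member=1,
            )
            offspring_rows.append(idx)

    # generation-two spouses at the configured fraction of generation two
    frac = config.spouse_fraction_g2
    n_spouse_g2 = int(round(len(offspring_rows) * frac / (1.0 - frac))) if frac > 0 else 0
    n_spouse_g2 = min(n_spouse_g2, len(offspring_rows))
    married_g2 = rng.choice(len(offspring_rows), size=n_spouse_g2, replace=False)
    for oi in sorted(offspring_rows[j] for j in married_g2):
        partner = rows[oi]
        sp_id = f"{partner['individual_id']}_SP"
        partner["partner_id"] = sp_id
        add_row(
            family_id=partner["family_id"],
            individual_id=sp_id,
            father_id="0",
            mother_id="0",
            sex="F" if partner["sex"] == "M" else "M",
            generation=2,
            role="spouse_g2",
            longevity_member=0,
            partner_id=partner["individual_id"],
        )

    ped = pd.DataFrame(rows, columns=PEDIGREE_COLUMNS + ["partner_id"])
    ped = ped.sort_values(["family_id", "generation", "individual_id"], kind="stable")
    return ped.reset_index(drop=True)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Risk-allele dosage matrix for a set of individuals and biallelic SNPs.

    ``dosage`` is float with values {0, 1, 2} and NaN for a missing call and
    always counts copies of ``risk_allele``.  ``ref``/``alt`` record the VCF
    orientation chosen for each SNP (the risk allele may be either).
    """

    individuals: list[str]
    snps: list[str]
    dosage: np.ndarray  # shape (n_individuals, n_snps), float, NaN = missing
    ref: np.ndarray
    alt: np.ndarray
    risk_allele: np.ndarray

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.individuals) or m != len(self.snps):
            raise ValueError("dosage dimensions do not match id lists")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snps.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in genotype matrix") from None

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.snp_index(s) for s in snp_ids]
        return GenotypeMatrix(
            individuals=list(self.individuals),
            snps=[self.snps[i] for i in idx],
            dosage=self.dosage[:, idx].copy(),
            ref=self.ref[idx].copy(),
            alt=self.alt[idx].copy(),
            risk_allele=self.risk_allele[idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.individuals, columns=self.snps)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            individuals=list(self.individuals),
            snps=list(self.snps),
            dosage=self.dosage.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            risk_allele=self.risk_allele.copy(),
        )


def _latent_equicorrelation(p: float, r2: float) -> float:
    """Latent Gaussian correlation giving binary (allelic) correlation sqrt(r2).

    Solves the tetrachoric equation P(Z1<=t, Z2<=t; rho) = p^2 + r*p*(1-p)
    with t = Phi^-1(p) and r = sqrt(r2); for equal allele frequencies the
    squared dosage correlation then equals r2.
    """
    if r2 <= 0:
        return 0.0
    r_target = float(np.sqrt(r2))
    if r_target >= 1.0:
        return 1.0
    t = stats.norm.ppf(p)

    def binary_corr(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf(
            [t, t], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
        return (p11 - p * p) / (p * (1.0 - p))

    return float(optimize.brentq(lambda r: binary_corr(r) - r_target, 0.0, 0.999999, xtol=1e-8))


def _block_plan(panel_size: int, block_sizes: Sequence[int]) -> list[int]:
    """Cycle the configured block sizes to cover exactly panel_size SNPs."""
    plan: list[int] = []
    total, k = 0, 0
    while total < panel_size:
        s = min(int(block_sizes[k % len(block_sizes)]), panel_size - total)
        plan.append(s)
        total += s
        k += 1
    return plan


_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


def generate_genotypes(
    pedigree: pd.DataFrame,
    panel_size: int,
    config: CohortConfig,
    snp_ids: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Simulate biallelic dosages for every pedigree member.

    Founder haplotypes are drawn per LD block from an equicorrelated
    Gaussian copula with one allele frequency per block (uniform on
    ``allele_freq_range``), so the expected pairwise dosage r-squared inside
    a block equals ``within_block_r2`` and blocks are independent.
    Non-founders receive one whole-block gamete from each parent (free
    recombination between blocks, none within).  Parents referenced in the
    pedigree but absent from it (latent founders) are simulated internally
    and discarded.
    """
    config.validate()
    if panel_size < 1:
        raise ConfigError("panel_size must be >= 1")
    rng = stage_rng(config.seed, "genotypes")

    if snp_ids is None:
        snp_ids = [f"rs{9000001 + j}" for j in range(panel_size)]
    elif len(snp_ids) != panel_size:
        raise ConfigError("snp_ids length must equal panel_size")

    members = list(pedigree["individual_id"])
    parents = {
        r.individual_id: (r.father_id, r.mother_id)
        for r in pedigree.itertuples()
    }
    # latent ids: referenced as a parent, not a row, not "0"
    referenced = set(pedigree["father_id"]) | set(pedigree["mother_id"])
    latent = sorted(referenced - set(members) - {"0"})
    all_ids = latent + members
    founders = [i for i in all_ids if parents.get(i, ("0", "0")) == ("0", "0") or i in latent]
    n_all = len(all_ids)
    pos = {ind: k for k, ind in enumerate(all_ids)}

    blocks = _block_plan(panel_size, config.ld_block_sizes)
    lo, hi = config.allele_freq_range

    hap = np.zeros((n_all, 2, panel_size), dtype=np.int8)
    founder_pos = np.array([pos[i] for i in founders])
    n_f = len(founders)

    # founder haplotypes, block by block
    rho_cache: dict[tuple[float, float], float] = {}
    col = 0
    block_slices: list[slice] = []
    for size in blocks:
        sl = slice(col, col + size)
        block_slices.append(sl)
        p_b = rng.uniform(lo, hi)
        if size == 1 or config.within_block_r2 == 0.0:
            z = rng.standard_normal((n_f, 2, size))
        else:
            key = (round(p_b, 6), config.within_block_r2)
            if key not in rho_cache:
                rho_cache[key] = _latent_equicorrelation(p_b, config.within_block_r2)
            rho = rho_cache[key]
            shared = rng.standard_normal((n_f, 2, 1))
            noise = rng.standard_normal((n_f, 2, size))
            z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
        hap[founder_pos, :, sl] = (z <= stats.norm.ppf(p_b)).astype(np.int8)
        col += size

    # Mendelian drop: children in pedigree row order (parents are either
    # latent founders or earlier rows; offspring rows follow their G1 parents
    # because generations sort ascending within a family).
    order = [i for i in all_ids if i not in set(founders)]
    n_blocks = len(blocks)
    for ind in order:
        fa, mo = parents[ind]
        k = pos[ind]
        for side, par in enumerate((fa, mo)):
            choice = rng.integers(0, 2, size=n_blocks)
            gam = np.empty(panel_size, dtype=np.int8)
            prow = hap[pos[par]]
            for b, sl in enumerate(block_slices):
                gam[sl] = prow[choice[b], sl]
            hap[k, side] = gam

    member_pos = np.array([pos[i] for i in members])
    dosage = hap[member_pos].sum(axis=1).astype(float)

    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=panel_size)
    risk_is_alt = rng.random(panel_size) < 0.5
    ref = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    alt = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    risk = np.where(risk_is_alt, alt, ref)

    return GenotypeMatrix(
        individuals=members,
        snps=list(snp_ids),
        dosage=dosage,
        ref=ref,
        alt=alt,
        risk_allele=risk,
    )


# ---------------------------------------------------------------------------
# longevity effect
# ---------------------------------------------------------------------------


def inject_longevity_effect(
    genotypes: GenotypeMatrix,
    individuals: pd.DataFrame,
    rate_ratio: float,
    family_intercept_sd: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Impose a multiplicative familial-longevity effect on risk-allele rates.

    Longevity members' dosages are binomially thinned (rate ratio < 1: each
    carried risk allele kept with probability ``rate_ratio * exp(u_f)``) or
    boosted (rate ratio > 1: empty allele slots filled so the per-slot rate
    multiplies), where ``u_f ~ N(0, family_intercept_sd^2)`` is a shared
    log-scale family intercept modulating the injected effect.  Married-in
    controls are never modified, and with ``rate_ratio = 1`` there is no
    effect to modulate, so the matrix is returned unchanged (the null case
    is an exact no-op).
    """
    if rate_ratio <= 0:
        raise ValueError("rate_ratio must be positive")
    if rate_ratio == 1.0:
        return genotypes.copy()

    rng = stage_rng(seed, "longevity-effect")
    info = individuals.set_index("individual_id").loc[genotypes.individuals]
    member = info["longevity_member"].to_numpy().astype(bool)
    fams = info["family_id"].to_numpy()
    fam_codes, fam_index = pd.factorize(fams)
    u = rng.normal(0.0, family_intercept_sd, size=len(fam_index))
    factor = rate_ratio * np.exp(u)[fam_codes]  # per individual

    dosage = genotypes.dosage.copy()
    with np.errstate(invalid="ignore"):
        p_hat = np.nanmean(dosage, axis=0) / 2.0  # per-SNP risk allele rate

    for i in np.nonzero(member)[0]:
        f = factor[i]
        row = dosage[i]
        called = ~np.isnan(row)
        if abs(f - 1.0) < 1e-15:
            continue
        if f <= 1.0:
            x = row[called].astype(int)
            dosage[i, called] = rng.binomial(x, f).astype(float)
        else:
            q = (f - 1.0) * p_hat[called] / (1.0 - p_hat[called])
            if np.any(q > 1.0):
                raise ValueError(
                    "rate_ratio pushes the per-slot risk-allele rate above 1"
                )
            x = row[called].astype(int)
            dosage[i, called] = (x + rng.binomial(2 - x, q)).astype(float)

    out = genotypes.copy()
    out.dosage = dosage
    return out


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


def kinship_matrix(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Kinship coefficients phi for every pair of pedigree members.

    Uses the standard tabular recursion (phi(i,i) = (1 + phi(f,m))/2,
    phi(i,j) = (phi(f,j) + phi(m,j))/2 with parents processed first).
    Parents referenced but not listed are treated as unrelated, non-inbred
    latent founders; the returned square DataFrame covers only listed
    individuals.  Raises on a cyclic pedigree.
    """
    members = list(pedigree["individual_id"])
    parents = {
        r.individual_id: (r.father_id, r.mother_id) for r in pedigree.itertuples()
    }
    referenced = set(pedigree["father_id"]) | set(pedigree["mother_id"])
    latent = sorted(referenced - set(members) - {"0"})
    for l in latent:
        parents[l] = ("0", "0")
    all_ids = latent + members

    # topological order (Kahn); cycle -> error
    children: dict[str, list[str]] = {i: [] for i in all_ids}
    indeg = {i: 0 for i in all_ids}
    for i in all_ids:
        for p in parents[i]:
            if p != "0":
                if p not in parents:
                    raise ValueError(f"parent {p!r} is not a known individual")
                children[p].append(i)
                indeg[i] += 1
    queue = [i for i in all_ids if indeg[i] == 0]
    topo: list[str] = []
    while queue:
        i = queue.pop()
        topo.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(topo) != len(all_ids):
        raise ValueError("pedigree contains a cycle")

    n = len(all_ids)
    pos = {ind: k for k, ind in enumerate(topo)}
    K = np.zeros((n, n))
    for ind in topo:
        k = pos[ind]
        fa, mo = parents[ind]
        if fa == "0" and mo == "0":
            K[k, k] = 0.5
            continue
        row = np.zeros(n)
        for p in (fa, mo):
            if p != "0":
                row += 0.5 * K[pos[p]]
        K[k, :] = row
        K[:, k] = row
        phi_fm = K[pos[fa], pos[mo]] if fa != "0" and mo != "0" else 0.0
        K[k, k] = 0.5 * (1.0 + phi_fm)

    idx = [pos[m] for m in members]
    return pd.DataFrame(K[np.ix_(idx, idx)], index=members, columns=members)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def write_pedigree_tsv(pedigree: pd.DataFrame, path) -> None:
    pedigree[PEDIGREE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", dtype={"father_id": str, "mother_id": str})
    missing = set(PEDIGREE_COLUMNS) - set(ped.columns)
    if missing:
        raise ValueError(f"pedigree file lacks columns: {sorted(missing)}")
    return ped


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    """Plain risk-allele dosage table: rows = individuals, columns = SNPs."""
    df = genotypes.to_frame()
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_dosage_tsv(path, risk_alleles: Mapping[str, str] | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="individual_id", na_values=["NA"])
    m = df.shape[1]
    risk = np.array([risk_alleles.get(s, "A") if risk_alleles else "A" for s in df.columns])
    return GenotypeMatrix(
        individuals=list(df.index),
        snps=list(df.columns),
        dosage=df.to_numpy(dtype=float),
        ref=np.array(["A"] * m),
        alt=np.array(["G"] * m),
        risk_allele=risk,
    )


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write hard-call genotypes as uncompressed VCF 4.2 (GT only).

    Dosages count the risk allele, which may be REF or ALT for a given SNP;
    genotype codes are oriented accordingly so a VCF round trip through
    risk-allele re-orientation recovers the dosage matrix.
    """
    gt_when_alt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    gt_when_ref = {0.0: "1/1", 1.0: "0/1", 2.0: "0/0"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individuals)
            + "\n"
        )
        for j, snp in enumerate(genotypes.snps):
            table = (
                gt_when_alt
                if genotypes.risk_allele[j] == genotypes.alt[j]
                else gt_when_ref
            )
            calls = [
                "./." if np.isnan(d) else table[float(d)]
                for d in genotypes.dosage[:, j]
            ]
            fh.write(
                f"1\t{j + 1}\t{snp}\t{genotypes.ref[j]}\t{genotypes.alt[j]}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )
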