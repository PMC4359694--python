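"""Unweighted genetic risk scores and Poisson offsets.

The score for individual *i* over a panel of *m* SNPs is the plain sum of
risk-allele dosages, GRS_i = sum_j x_ij with x_ij in {0, 1, 2}, counted over
the SNPs with a genotype call.  Each allele counts one — no per-SNP effect
weights — so the score is the absolute number of disease alleles carried.
To compare carriers with different amounts of missingness on a rate scale,
each record carries the offset log(2 * n_nonmissing), the log of the number
of allele slots actually observed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix
from .panel import SNPPanel

__all__ = ["compute_grs", "orient_to_risk_allele", "read_vcf_genotypes", "GRS_COLUMNS"]

logger = logging.getLogger(__name__)

GRS_COLUMNS = ["individual_id", "disease_group", "count", "n_nonmissing", "offset"]

#: Strand-ambiguous base pairs (indistinguishable under strand flip).
AMBIGUOUS_PAIRS = frozenset({frozenset({"A", "T"}), frozenset({"C", "G"})})


def compute_grs(genotypes: GenotypeMatrix, panel: SNPPanel) -> pd.DataFrame:
    """Per-individual risk-allele counts, call counts and offsets for a panel.

    Returns a table with one row per individual: ``count`` (sum of non-missing
    dosages), ``n_nonmissing`` (SNPs with a call) and ``offset``
    = log(2 * n_nonmissing).  Individuals with no called panel SNP have no
    defined rate and are dropped with a warning.
    """
    missing = [s for s in panel.snp_ids if s not in set(genotypes.snps)]
    if missing:
        raise KeyError(f"panel SNP(s) absent from genotypes: {missing}")
    sub = genotypes.subset_snps(panel.snp_ids)
    called = ~np.isnan(sub.dosage)
    counts = np.nansum(sub.dosage, axis=1)
    n_nonmissing = called.sum(axis=1)

    ok = n_nonmissing > 0
    if not ok.all():
        dropped = [sub.individuals[i] for i in np.nonzero(~ok)[0]]
        logger.warning(
            "dropping %d individual(s) with no called panel SNP: %s",
            len(dropped),
            dropped[:10],
        )
    out = pd.DataFrame(
        {
            "individual_id": np.asarray(sub.individuals)[ok],
            "disease_group": panel.disease_group,
            "count": counts[ok].astype(int),
            "n_nonmissing": n_nonmissing[ok].astype(int),
            "offset": np.log(2.0 * n_nonmissing[ok]),
        },
        columns=GRS_COLUMNS,
    )
    return out


def read_vcf_genotypes(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read GT hard calls from a VCF via cyvcf2.

    Returns ``(alt_dosage, sites)``: ALT-allele dosage per individual x SNP
    (NaN for missing calls) and a per-SNP table with ``snp_id, ref, alt``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, sites = [], []
    for var in vcf:
        gts = np.asarray(var.genotype.array())[:, :2]
        dos = np.where((gts < 0).any(axis=1), np.nan, (gts == 1).sum(axis=1))
        sites.append({"snp_id": var.ID, "ref": var.REF, "alt": var.ALT[0]})
        rows.append(dos.astype(float))
    vcf.close()
    alt_dosage = pd.DataFrame(
        np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0)),
        index=samples,
        columns=[s["snp_id"] for s in sites],
    )
    return alt_dosage, pd.DataFrame(sites)


def orient_to_risk_allele(
    vcf_path,
    panel: SNPPanel,
    ambiguous_policy: str = "keep",
) -> GenotypeMatrix:
    """Convert VCF GT calls into risk-allele dosages for a panel.

    For each panel SNP the dosage is the number of copies of the panel's
    risk allele: the ALT count when the risk allele is ALT, or 2 - ALT count
    when it is REF.  Strand-ambiguous SNPs (A/T or C/G) are kept as-is or
    excluded according to ``ambiguous_policy`` ("keep" or "drop"); a risk
    allele matching neither REF nor ALT raises.
    """
    if ambiguous_policy not in {"keep", "drop"}:
        raise ValueError("ambiguous_policy must be 'keep' or 'drop'")
    alt_dosage, sites = read_vcf_genotypes(vcf_path)
    site_map = sites.set_index("snp_id")
    risk_map = panel.risk_allele_map()

    keep_ids: list[str] = []
    cols: list[np.ndarray] = []
    refs, alts, risks = [], [], []
    for snp in panel.snp_ids:
        if snp not in site_map.index:
            raise KeyError(f"panel SNP {snp!r} not found in VCF")
        ref, alt = site_map.loc[snp, "ref"], site_map.loc[snp, "alt"]
        risk = risk_map[snp]
        if frozenset({ref, alt}) in AMBIGUOUS_PAIRS and ambiguous_policy == "drop":
            logger.warning("dropping strand-ambiguous SNP %s (%s/%s)", snp, ref, alt)
            continue
        if risk == alt:
            d = alt_dosage[snp].to_numpy(dtype=float)
        elif risk == ref:
            d = 2.0 - alt_dosage[snp].to_numpy(dtype=float)
        else:
            raise ValueError(
                f"risk allele {risk!r} of SNP {snp} matches neither REF {ref!r} nor ALT {alt!r}"
            )
        keep_ids.append(snp)
        cols.append(d)
        refs.append(ref)
        alts.append(alt)
        risks.append(risk)

    return GenotypeMatrix(
        individuals=list(alt_dosage.index),
        snps=keep_ids,
        dosage=np.column_stack(cols) if cols else np.empty((len(alt_dosage), 0)),
        ref=np.array(refs),
        alt=np.array(alts),
        risk_allele=np.array(risks),
    )
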