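"""SNP- and family-level quality control for trio genotype data.

The filters are the ones routinely applied to family-based SNP panels
before transmission testing:

* Mendelian masking — any (family, SNP) genotype triple that is impossible
  under Mendelian inheritance is set to missing for all three members.
* Per-SNP call rate, computed over all individuals (parents and children)
  after masking.
* Minor allele frequency and an exact Hardy-Weinberg equilibrium test,
  both computed in the parents only (the children are ascertained and would
  distort both).

Masking is applied first; call rate, MAF and HWE are then evaluated on the
masked data.  The order matters marginally (masking lowers call rates) and
is fixed here for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import MISSING, SnpRecord, TrioGenotypes, trios_to_array

__all__ = [
    "QcThresholds",
    "QcReport",
    "mendelian_consistent",
    "hwe_exact_p",
    "apply_qc",
]


@dataclass(frozen=True)
class QcThresholds:
    """Exclusion thresholds: a SNP is kept only if its call rate is at least
    ``min_call_rate``, its parental HWE exact p is at least ``hwe_alpha`` and
    its parental MAF is at least ``min_maf``."""

    min_call_rate: float = 0.95
    hwe_alpha: float = 0.001
    min_maf: float = 0.01

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "hwe_alpha", "min_maf"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class QcReport:
    """Per-SNP metrics plus the list of masked Mendelian errors.

    ``snp_table`` columns: snp_id, call_rate, maf_parents, hwe_p_parents,
    passed, reasons (comma-joined, empty when passed).
    ``mendelian_errors`` columns: family_id, snp_id.
    """

    snp_table: pd.DataFrame
    mendelian_errors: pd.DataFrame


def mendelian_consistent(father_gt, mother_gt, child_gt) -> bool:
    """True iff the child genotype can arise from one allele of each parent.

    Genotypes are length-2 sequences of allele codes; any missing member
    makes the triple unassessable and therefore consistent.
    """
    f = np.asarray(father_gt)
    m = np.asarray(mother_gt)
    c = np.asarray(child_gt)
    if (f == MISSING).any() or (m == MISSING).any() or (c == MISSING).any():
        return True
    child = tuple(sorted(c.tolist()))
    for a in f:
        for b in m:
            if tuple(sorted((int(a), int(b)))) == child:
                return True
    return False


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact test of Hardy-Weinberg proportions.

    Conditions on the total sample size and the minor-allele count and sums
    the probabilities of every heterozygote count that is no more probable
    than the observed one (the standard exact HWE convention).
    """
    counts = (int(n_AA), int(n_Aa), int(n_aa))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n == 0:
        raise ValueError("no data: all genotype counts are zero")
    n_minor = min(2 * counts[0] + counts[1], 2 * counts[2] + counts[1])
    # P(n_het | n, n_minor) ∝ n! / (n_AA! n_Aa! n_aa!) * 2^n_Aa, normalised
    # over all feasible heterozygote counts of the right parity.
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    rare_hom = (n_minor - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        hets * np.log(2.0)
        - gammaln(rare_hom + 1)
        - gammaln(hets + 1)
        - gammaln(common_hom + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[hets == counts[1]][0]
    return float(prob[prob <= p_obs * (1 + 1e-12)].sum())


def _genotype_counts_parents(G: np.ndarray, j: int) -> tuple[int, int, int]:
    """(hom allele-a, het, hom allele-b) counts among parents at SNP j."""
    g = G[:, :2, j, :]  # (n, 2, 2)
    ok = (g != MISSING).all(axis=-1)
    dos = g.sum(axis=-1)  # number of allele-b copies, 0/1/2
    dos = dos[ok]
    return int((dos == 0).sum()), int((dos == 1).sum()), int((dos == 2).sum())


def apply_qc(
    snps: list[SnpRecord],
    trios: list[TrioGenotypes],
    thresholds: QcThresholds | None = None,
) -> tuple[list[SnpRecord], list[TrioGenotypes], QcReport]:
    """Mask Mendelian errors, then drop SNPs failing call-rate/MAF/HWE.

    Returns the passing SNPs, new trios restricted to those SNPs (with
    masked genotypes), and a :class:`QcReport` covering every input SNP.
    The operation is idempotent.
    """
    thresholds = thresholds or QcThresholds()
    G = trios_to_array(trios).copy()
    n_fam, _, m, _ = G.shape

    mend_rows = []
    for i, trio in enumerate(trios):
        for j in range(m):
            if not mendelian_consistent(G[i, 0, j], G[i, 1, j], G[i, 2, j]):
                G[i, :, j, :] = MISSING
                mend_rows.append({"family_id": trio.family_id, "snp_id": snps[j].snp_id})

    rows = []
    keep = []
    for j, snp in enumerate(snps):
        called = (G[:, :, j, :] != MISSING).all(axis=-1)
        call_rate = float(called.mean()) if n_fam else 0.0
        n0, n1, n2 = _genotype_counts_parents(G, j)
        n_par = n0 + n1 + n2
        if n_par:
            maf = (min(2 * n0 + n1, 2 * n2 + n1)) / (2 * n_par)
            hwe_p = hwe_exact_p(n0, n1, n2)
        else:
            maf, hwe_p = 0.0, 1.0
        reasons = []
        if call_rate < thresholds.min_call_rate:
            reasons.append("call_rate")
        if maf < thresholds.min_maf:
            reasons.append("maf")
        if hwe_p < thresholds.hwe_alpha:
            reasons.append("hwe")
        passed = not reasons
        keep.append(passed)
        rows.append({
            "snp_id": snp.snp_id,
            "call_rate": call_rate,
            "maf_parents": maf,
            "hwe_p_parents": hwe_p,
            "passed": passed,
            "reasons": ",".join(reasons),
        })

    keep = np.array(keep, dtype=bool)
    snps_out = [s for s, k in zip(snps, keep) if k]
    trios_out = [
        TrioGenotypes(t.family_id, G[i][:, keep, :]) for i, t in enumerate(trios)
    ]
    report = QcReport(
        snp_table=pd.DataFrame(
            rows, columns=["snp_id", "call_rate", "maf_parents",
                           "hwe_p_parents", "passed", "reasons"]),
        mendelian_errors=pd.DataFrame(mend_rows, columns=["family_id", "snp_id"]),
    )
    return snps_out, trios_out, report
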