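"""Single-marker transmission disequilibrium tests for case-parent trios.

The TDT compares, over heterozygous parents, how often an allele is
transmitted to the affected child versus withheld.  Under the null of no
association (or no linkage) each heterozygous meiosis transmits either
allele with probability 1/2, independently of population structure, which
makes the test robust to stratification.

For a single biallelic SNP under a multiplicative (log-additive) risk model
the conditional-logistic maximum-likelihood estimate of the per-allele
relative risk equals the transmission ratio T/U, so the point estimate and
Wald interval here are closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, SnpRecord, TrioGenotypes, trios_to_array

__all__ = [
    "TransmissionCount",
    "TdtResult",
    "RelativeRisk",
    "count_transmissions",
    "tdt_rr",
    "tdt_exact_p",
    "tdt_permutation_p",
    "tdt_test",
    "conditional_scan",
    "ConditionalScanResult",
]


@dataclass(frozen=True)
class TransmissionCount:
    """Transmitted (T) and untransmitted (U) counts of the effect allele
    over informative parental meioses at one SNP."""

    snp_id: str
    effect_allele: str
    T: int
    U: int

    @property
    def n_informative(self) -> int:
        return self.T + self.U


@dataclass(frozen=True)
class RelativeRisk:
    """Multiplicative per-allele relative risk with a Wald 95% CI on the
    log scale.  ``corrected`` flags a +0.5 continuity correction applied to
    both counts when one of them was zero."""

    rr: float
    ci_low: float
    ci_high: float
    corrected: bool = False

    def __iter__(self):
        return iter((self.rr, self.ci_low, self.ci_high))


@dataclass(frozen=True)
class TdtResult:
    counts: TransmissionCount
    rr: RelativeRisk
    p_exact: float
    eaf_parents: float
    p_perm: float | None = None


def _resolve_snp(snps: list[SnpRecord], snp) -> tuple[int, SnpRecord]:
    if isinstance(snp, SnpRecord):
        idx = next(i for i, s in enumerate(snps) if s.snp_id == snp.snp_id)
        return idx, snp
    if isinstance(snp, int):
        return snp, snps[snp]
    idx = next((i for i, s in enumerate(snps) if s.snp_id == snp), None)
    if idx is None:
        raise KeyError(f"SNP {snp!r} not in map")
    return idx, snps[idx]


def _count_tu(G: np.ndarray, j: int, eff_code: int) -> tuple[int, int]:
    """Vectorised T/U counting at SNP column ``j`` for effect-allele code."""
    g = G[:, :, j, :]  # (n, 3, 2)
    ok = (g != MISSING).all(axis=(1, 2))
    dos = (g == eff_code).sum(axis=-1)  # (n, 3) effect-allele dosage
    het = g[:, :, 0] != g[:, :, 1]  # (n, 3)
    het_f, het_m = het[:, 0], het[:, 1]
    k = het_f.astype(int) + het_m.astype(int)
    forced = (~het_f) * dos[:, 0] // 2 + (~het_m) * dos[:, 1] // 2
    t = dos[:, 2] - forced
    valid = ok & (k > 0) & (t >= 0) & (t <= k)
    T = int(t[valid].sum())
    U = int((k - t)[valid].sum())
    return T, U


def count_transmissions(
    trios: list[TrioGenotypes],
    snps: list[SnpRecord],
    snp,
    effect_allele: str,
) -> TransmissionCount:
    """Count effect-allele transmissions from heterozygous parents.

    A meiosis is informative when the parent is heterozygous and all three
    genotypes of the family at the SNP are non-missing.  When both parents
    are heterozygous and the child is heterozygous, the per-allele counts
    are still determined: one parent transmitted each allele, crediting one
    T and one U.
    """
    j, rec = _resolve_snp(snps, snp)
    if effect_allele == rec.allele_a:
        eff = 0
    elif effect_allele == rec.allele_b:
        eff = 1
    else:
        raise ValueError(
            f"effect allele {effect_allele!r} is not an allele of {rec.snp_id} "
            f"({rec.allele_a}/{rec.allele_b})"
        )
    T, U = _count_tu(trios_to_array(trios), j, eff)
    return TransmissionCount(rec.snp_id, effect_allele, T, U)


def tdt_rr(T: float, U: float) -> RelativeRisk:
    """Relative risk T/U with 95% Wald CI ``exp(ln(T/U) ± 1.96 √(1/T+1/U))``."""
    if T + U <= 0:
        raise ValueError("no informative transmissions")
    corrected = False
    if T == 0 or U == 0:
        T, U = T + 0.5, U + 0.5
        corrected = True
    log_rr = np.log(T / U)
    se = np.sqrt(1.0 / T + 1.0 / U)
    z = stats.norm.ppf(0.975)
    return RelativeRisk(
        rr=float(np.exp(log_rr)),
        ci_low=float(np.exp(log_rr - z * se)),
        ci_high=float(np.exp(log_rr + z * se)),
        corrected=corrected,
    )


def tdt_exact_p(T: int, U: int) -> float:
    """Two-sided exact binomial p for T successes in T+U Bernoulli(1/2)
    trials (sum of outcome probabilities no larger than the observed one)."""
    if T + U <= 0:
        raise ValueError("no informative transmissions")
    return float(stats.binomtest(int(T), int(T) + int(U), 0.5).pvalue)


def exact_p_vectorized(T: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided exact binomial p at p0=1/2 for arrays of counts.

    Exploits the symmetry of Binomial(n, 1/2): outcomes no more probable
    than T are exactly those at least as extreme as max(T, n-T).
    """
    T = np.asarray(T, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    m = np.maximum(T, n - T)
    p = np.where(2 * m == n, 1.0, np.minimum(1.0, 2.0 * stats.binom.sf(m - 1, n, 0.5)))
    return p


def tdt_permutation_p(
    T: int,
    U: int,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    adaptive: bool = False,
    alpha: float = 0.05,
) -> float:
    """Permutation p for the TDT chi-square statistic (T-U)^2/(T+U).

    Each permutation independently flips every informative meiosis's
    transmitted/untransmitted label with probability 1/2, so the permuted
    T is Binomial(T+U, 1/2).  p = (1 + exceedances) / (1 + n_perm).

    With ``adaptive=True`` permutation proceeds in blocks of 1000 and stops
    early once the Wilson 99% interval of the p estimate lies entirely above
    ``alpha`` (the SNP is then clearly non-significant); this trades
    precision of large p-values for speed, as adaptive permutation schemes
    in standard GWAS toolkits do.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = T + U
    obs = (T - U) ** 2 / n if n else 0.0
    block = 1000 if adaptive else n_perm
    done = 0
    exceed = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        t_star = rng.binomial(n, 0.5, size=b)
        stat = (2 * t_star - n) ** 2 / n if n else np.zeros(b)
        exceed += int((stat >= obs - 1e-12).sum())
        done += b
        if adaptive and done < n_perm:
            lo, _ = _wilson(exceed + 1, done + 1, z=2.576)
            if lo > alpha:
                break
    return (1 + exceed) / (1 + done)


def _wilson(k: int, n: int, z: float) -> tuple[float, float]:
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return centre - half, centre + half


def tdt_test(
    trios: list[TrioGenotypes],
    snps: list[SnpRecord],
    snp,
    effect_allele: str | None = None,
    n_perm: int | None = None,
    seed: int | None = None,
) -> TdtResult:
    """Full single-marker TDT: counts, relative risk, exact p and,
    optionally, a permutation p.

    When ``effect_allele`` is omitted the over-transmitted allele is used,
    matching how published trio tables orient the "effect allele" column.
    """
    j, rec = _resolve_snp(snps, snp)
    if effect_allele is None:
        counts = count_transmissions(trios, snps, snp, rec.allele_b)
        if counts.U > counts.T:
            counts = TransmissionCount(rec.snp_id, rec.allele_a, counts.U, counts.T)
    else:
        counts = count_transmissions(trios, snps, snp, effect_allele)
    G = trios_to_array(trios)
    g = G[:, :2, j, :]
    called = g != MISSING
    eff = 0 if counts.effect_allele == rec.allele_a else 1
    eaf = float((g == eff).sum() / called.sum()) if called.any() else float("nan")
    p_perm = None
    if n_perm:
        p_perm = tdt_permutation_p(counts.T, counts.U, n_perm=n_perm, seed=seed)
    return TdtResult(
        counts=counts,
        rr=tdt_rr(counts.T, counts.U),
        p_exact=tdt_exact_p(counts.T, counts.U),
        eaf_parents=eaf,
        p_perm=p_perm,
    )


# ---------------------------------------------------------------------------
# Conditional screen for secondary signals


@dataclass
class ConditionalScanResult:
    """Outcome of the secondary-signal screen.

    ``table`` has one row per candidate (snp_id, statistic, p_perm,
    n_informative, selected); ``selected`` lists the SNP ids with
    ``p_perm <= alpha`` in input order.
    """

    table: pd.DataFrame
    selected: list[str]
    index_snp: str
    alpha: float


def conditional_scan(
    trios: list[TrioGenotypes],
    snps: list[SnpRecord],
    index_snp,
    candidate_snps=None,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ConditionalScanResult:
    """Screen for SNPs carrying association information beyond an index SNP.

    Rationale: if the index SNP were the only causal variant, transmission
    of two-marker haplotypes carrying it would not depend on the allele at
    any other SNP.  For each candidate, two-marker haplotypes (index,
    candidate) are phased; the informative meioses for the conditional test
    are those whose transmitted and untransmitted haplotypes share the same
    index allele but differ at the candidate (when the index alleles differ
    the transmission is already explained by the index under the null).
    Within each index-allele stratum the candidate transmission is tested
    against 1/2 with a stratified McNemar-type statistic, and the null is
    generated by flipping candidate transmissions per parental meiosis
    within strata.

    A candidate in perfect LD with the index has no informative meioses and
    is never selected.
    """
    from .haplotypes import em_phase  # deferred import: avoids a cycle

    _, index_rec = _resolve_snp(snps, index_snp)
    if candidate_snps is None:
        candidate_snps = [s.snp_id for s in snps if s.snp_id != index_rec.snp_id]
    ss = np.random.SeedSequence(seed)
    rows = []
    for cand, child_ss in zip(candidate_snps, ss.spawn(len(candidate_snps))):
        _, cand_rec = _resolve_snp(snps, cand)
        if cand_rec.snp_id == index_rec.snp_id:
            continue
        stat, p, n_inf = _conditional_test(
            trios, snps, index_rec, cand_rec, n_perm,
            np.random.default_rng(child_ss), em_phase,
        )
        rows.append({
            "snp_id": cand_rec.snp_id,
            "statistic": stat,
            "p_perm": p,
            "n_informative": n_inf,
            "selected": p <= alpha,
        })
    table = pd.DataFrame(
        rows, columns=["snp_id", "statistic", "p_perm", "n_informative", "selected"])
    selected = table.loc[table["selected"], "snp_id"].tolist()
    return ConditionalScanResult(table, selected, index_rec.snp_id, alpha)


def _conditional_test(trios, snps, index_rec, cand_rec, n_perm, rng, em_phase):
    from .haplotypes import (
        _null_transmission_groups,
        _observed_pair_matrix,
        _resolve_indices,
        _sample_null_pair_matrices,
    )

    phasing = em_phase(trios, snps, [index_rec.snp_id, cand_rec.snp_id])
    haps = phasing.haplotypes  # (H, 2): columns (index allele, candidate allele)
    H = len(phasing.freqs)
    i_all, c_all = haps[:, 0], haps[:, 1]
    same_i = i_all[:, None] == i_all[None, :]
    mask_T = same_i & (c_all[:, None] == 1) & (c_all[None, :] == 0)
    mask_U = same_i & (c_all[:, None] == 0) & (c_all[None, :] == 1)
    strata = [((i_all[:, None] == s) & mask_T, (i_all[:, None] == s) & mask_U)
              for s in (0, 1)]

    def statistic(M: np.ndarray) -> np.ndarray:
        out = 0.0
        for m_T, m_U in strata:
            T_s = (M * m_T).sum(axis=(-2, -1))
            U_s = (M * m_U).sum(axis=(-2, -1))
            tot = T_s + U_s
            live = tot > 1e-12
            out = out + np.where(live, (T_s - U_s) ** 2 / np.where(live, tot, 1.0), 0.0)
        return out

    M_obs = _observed_pair_matrix(phasing)
    n_inf = float((M_obs * (mask_T | mask_U)).sum())
    if n_inf <= 0:
        return 0.0, 1.0, 0.0
    obs = float(statistic(M_obs))
    flagged = set(phasing.flagged_families)
    trios_used = [t for t in trios if t.family_id not in flagged]
    snp_indices = _resolve_indices(snps, [index_rec.snp_id, cand_rec.snp_id])
    groups = _null_transmission_groups(
        trios_used, snp_indices, phasing.freqs, condition_col=0)
    M_perm = _sample_null_pair_matrices(groups, n_perm, rng, H)
    perm_stats = statistic(M_perm)
    p = (1 + int((perm_stats >= obs - 1e-12).sum())) / (1 + n_perm)
    return obs, p, n_inf
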