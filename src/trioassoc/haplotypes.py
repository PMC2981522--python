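"""Trio-aware haplotype phasing, LD measures and the weighted haplotype TDT.

Phase in nuclear families is often determined outright by the trio
structure; where it is not (double heterozygotes, missing genotypes), an
EM algorithm over founder haplotype frequencies assigns posterior weights
to every Mendelian-consistent configuration.  Downstream tests then use
fractional, posterior-weighted transmitted/untransmitted haplotype counts,
which is why published trio haplotype tables contain decimal counts.

The permutation null for the haplotype TDT swaps the transmitted and
untransmitted haplotype of a parental meiosis (weights carried along),
which is exactly the TDT null of transmission symmetry and preserves the
founder genotypes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, SnpRecord, TrioGenotypes

logger = logging.getLogger(__name__)

__all__ = [
    "PhasedTrio",
    "PhasingResult",
    "HapTestResult",
    "enumerate_configs",
    "em_phase",
    "ld_measures",
    "hap_tdt",
    "best_two_marker_scan",
]

_MAX_SUBSET = 10  # enumeration is exponential in the number of SNPs


@dataclass
class PhasedTrio:
    """Mendelian-consistent phase configurations of one family with
    posterior weights.

    Each configuration is a 4-tuple of haplotype indices
    (transmitted_father, untransmitted_father, transmitted_mother,
    untransmitted_mother); weights are >= 0 and sum to 1.
    """

    family_id: str
    configs: np.ndarray  # (n_cfg, 4) int
    weights: np.ndarray  # (n_cfg,) float


@dataclass
class PhasingResult:
    """Converged EM phasing over a SNP subset.

    ``haplotypes[h]`` gives the allele codes of haplotype index ``h`` (one
    column per subset SNP); ``freqs`` are founder-haplotype frequencies.
    """

    snp_records: list[SnpRecord]
    haplotypes: np.ndarray  # (H, m) int8 allele codes
    freqs: np.ndarray  # (H,)
    trios: list[PhasedTrio]
    loglik: float
    n_iter: int
    converged: bool
    flagged_families: list[str] = field(default_factory=list)

    @property
    def hap_strings(self) -> list[str]:
        out = []
        for row in self.haplotypes:
            out.append("".join(
                (s.allele_a if a == 0 else s.allele_b)
                for s, a in zip(self.snp_records, row)))
        return out

    def freq_dict(self) -> dict[str, float]:
        """Haplotype allele-string -> founder frequency (parents)."""
        return {h: float(f) for h, f in zip(self.hap_strings, self.freqs)}


def _hap_index(alleles: tuple[int, ...]) -> int:
    idx = 0
    for a in alleles:
        idx = (idx << 1) | a
    return idx


def _all_haplotypes(m: int) -> np.ndarray:
    H = 1 << m
    return np.array(
        [[(h >> (m - 1 - k)) & 1 for k in range(m)] for h in range(H)],
        dtype=np.int8,
    )


def _parent_ordered_pairs(gt: np.ndarray) -> list[tuple[int, int]]:
    """All ordered (transmitted, untransmitted) haplotype-index pairs
    consistent with a parent's genotypes over the subset."""
    per_snp: list[list[tuple[int, int]]] = []
    for a, b in gt:
        if a == MISSING or b == MISSING:
            per_snp.append([(0, 0), (0, 1), (1, 0), (1, 1)])
        elif a == b:
            per_snp.append([(int(a), int(a))])
        else:
            per_snp.append([(0, 1), (1, 0)])
    pairs = []
    for combo in itertools.product(*per_snp):
        h1 = _hap_index(tuple(c[0] for c in combo))
        h2 = _hap_index(tuple(c[1] for c in combo))
        pairs.append((h1, h2))
    return pairs


def enumerate_configs(trio, snp_indices=None) -> np.ndarray:
    """All Mendelian-consistent phase configurations of one trio.

    ``trio`` is a :class:`TrioGenotypes` or a (3, m, 2) genotype array;
    ``snp_indices`` restricts to a subset of SNP columns.  Returns an array
    of deduplicated (t_father, u_father, t_mother, u_mother) haplotype
    indices; missing genotypes are summed over (every consistent fill
    contributes its configurations).  An empty result means the family
    carries a Mendelian inconsistency over the subset.
    """
    g = trio.genotypes if isinstance(trio, TrioGenotypes) else np.asarray(trio)
    if snp_indices is not None:
        g = g[:, list(snp_indices), :]
    m = g.shape[1]
    if m > _MAX_SUBSET:
        raise ValueError(f"subset of {m} SNPs exceeds enumeration bound {_MAX_SUBSET}")
    father, mother, child = g[0], g[1], g[2]
    mbits = m - 1

    child_sets = []
    for a, b in child:
        if a == MISSING or b == MISSING:
            child_sets.append(None)  # matches anything
        else:
            child_sets.append(frozenset([(int(a), int(b)), (int(b), int(a))]))

    configs = set()
    for ft, fu in _parent_ordered_pairs(father):
        for mt, mu in _parent_ordered_pairs(mother):
            ok = True
            for k in range(m):
                cs = child_sets[k]
                if cs is None:
                    continue
                fa = (ft >> (mbits - k)) & 1
                ma = (mt >> (mbits - k)) & 1
                if (fa, ma) not in cs:
                    ok = False
                    break
            if ok:
                configs.add((ft, fu, mt, mu))
    if not configs:
        return np.zeros((0, 4), dtype=np.int64)
    return np.array(sorted(configs), dtype=np.int64)


def _group_by_pattern(trios: list[TrioGenotypes], snp_indices) -> dict:
    """Group trio indices by their genotype pattern over the subset, so the
    exponential configuration enumeration runs once per distinct pattern."""
    groups: dict[bytes, list[int]] = {}
    for i, t in enumerate(trios):
        key = t.genotypes[:, list(snp_indices), :].tobytes()
        groups.setdefault(key, []).append(i)
    return groups


def _resolve_indices(snps: list[SnpRecord], snp_subset) -> list[int]:
    idx = []
    ids = [s.snp_id for s in snps]
    for s in snp_subset:
        if isinstance(s, SnpRecord):
            idx.append(ids.index(s.snp_id))
        elif isinstance(s, (int, np.integer)):
            idx.append(int(s))
        else:
            idx.append(ids.index(s))
    return idx


def em_phase(
    trios: list[TrioGenotypes],
    snps: list[SnpRecord],
    snp_subset,
    tol: float = 1e-8,
    max_iter: int = 1000,
    prune_tol: float = 1e-10,
    n_restarts: int = 0,
    seed: int | np.random.Generator | None = None,
) -> PhasingResult:
    """EM estimation of founder haplotype frequencies with trio phasing.

    E-step: each Mendelian-consistent configuration of a family is weighted
    by the product of its four founder-haplotype frequencies.  M-step:
    frequencies are re-estimated from the weighted founder-haplotype counts.
    Iteration stops when the log-likelihood gain falls below ``tol``.
    Initial frequencies are uniform; haplotypes whose frequency falls below
    ``prune_tol`` are zeroed between iterations.

    The EM surface can have local optima (and the uniform start can sit on
    a symmetric saddle); ``n_restarts`` adds that many random Dirichlet
    starts (seeded by ``seed``) and keeps the best final likelihood.

    In data without phase ambiguity this reduces to direct counting in a
    single iteration.
    """
    snp_indices = _resolve_indices(snps, snp_subset)
    records = [snps[j] for j in snp_indices]
    m = len(snp_indices)
    H = 1 << m

    groups = _group_by_pattern(trios, snp_indices)
    pattern_cfgs: list[np.ndarray] = []
    pattern_count: list[int] = []
    pattern_members: list[list[int]] = []
    flagged: list[str] = []
    for key, members in groups.items():
        cfgs = enumerate_configs(trios[members[0]], snp_indices)
        if len(cfgs) == 0:
            flagged.extend(trios[i].family_id for i in members)
            logger.warning(
                "%d famil%s with no consistent phase configuration excluded",
                len(members), "y" if len(members) == 1 else "ies")
            continue
        pattern_cfgs.append(cfgs)
        pattern_count.append(len(members))
        pattern_members.append(members)

    n_used = sum(pattern_count)

    def run_em(freqs0: np.ndarray):
        freqs = freqs0.copy()
        loglik = -np.inf
        converged = False
        it = 0
        weights: list[np.ndarray] = [np.empty(0)] * len(pattern_cfgs)
        for it in range(1, max_iter + 1):
            counts = np.zeros(H)
            new_ll = 0.0
            for gi, cfgs in enumerate(pattern_cfgs):
                like = freqs[cfgs].prod(axis=1)  # product of 4 founder freqs
                tot = like.sum()
                if tot <= 0:
                    w = np.full(len(cfgs), 1.0 / len(cfgs))
                    new_ll += pattern_count[gi] * -np.inf
                else:
                    w = like / tot
                    new_ll += pattern_count[gi] * np.log(tot)
                weights[gi] = w
                np.add.at(counts, cfgs.ravel(),
                          np.repeat(w, 4) * pattern_count[gi])
            freqs = counts / (4 * n_used) if n_used else freqs
            freqs[freqs < prune_tol] = 0.0
            s = freqs.sum()
            if s > 0:
                freqs = freqs / s
            if new_ll - loglik < tol and np.isfinite(new_ll):
                loglik = new_ll
                converged = True
                break
            loglik = new_ll
        return freqs, loglik, it, converged, weights

    freqs, loglik, it, converged, weights_per_pattern = run_em(np.full(H, 1.0 / H))
    if n_restarts > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        for _ in range(n_restarts):
            cand = run_em(rng.dirichlet(np.ones(H)))
            if cand[1] > loglik + 1e-12:
                freqs, loglik, it, converged, weights_per_pattern = cand
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)

    phased: list[PhasedTrio | None] = [None] * len(trios)
    for gi, members in enumerate(pattern_members):
        cfgs, w = pattern_cfgs[gi], weights_per_pattern[gi]
        for i in members:
            phased[i] = PhasedTrio(trios[i].family_id, cfgs, w.copy())
    return PhasingResult(
        snp_records=records,
        haplotypes=_all_haplotypes(m),
        freqs=freqs,
        trios=[p for p in phased if p is not None],
        loglik=float(loglik),
        n_iter=it,
        converged=converged,
        flagged_families=flagged,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo transmission null
#
# Swapping transmitted/untransmitted labels while keeping the posterior phase
# weights fixed is anti-conservative: re-randomising a transmission changes
# the child genotype and with it the phase-ambiguity structure the weights
# came from.  The null is therefore sampled properly: per parental meiosis a
# gamete is redrawn given the parental genotypes (haplotype pairs weighted by
# the EM frequency estimates, each pair member transmitted with probability
# 1/2), the pseudo-child genotype is re-masked with the observed missingness,
# and the expected fractional counts of the pseudo-family are recomputed by
# the same E-step.  Founder genotypes are preserved throughout, so the
# robustness of the TDT to population structure carries over.


def _estep_pair_matrix(cfgs: np.ndarray, freqs: np.ndarray, H: int) -> np.ndarray:
    """Expected (transmitted, untransmitted) haplotype-pair counts of one
    family: M[a, b] = E[#meioses transmitting a and withholding b]."""
    M = np.zeros((H, H))
    if len(cfgs) == 0:
        return M
    like = freqs[cfgs].prod(axis=1)
    tot = like.sum()
    w = like / tot if tot > 0 else np.full(len(cfgs), 1.0 / len(cfgs))
    np.add.at(M, (cfgs[:, 0], cfgs[:, 1]), w)
    np.add.at(M, (cfgs[:, 2], cfgs[:, 3]), w)
    return M


def _null_transmission_groups(
    trios: list[TrioGenotypes],
    snp_indices: list[int],
    freqs: np.ndarray,
    condition_col: int | None = None,
) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Precompute, per distinct family pattern, the null outcome
    distribution and its expected pair-count matrices.

    Returns (n_families, outcome_probs, M_per_outcome) per group, where
    ``M_per_outcome`` has shape (n_outcomes, H, H).  With ``condition_col``
    set, outcomes are restricted to those reproducing the child's observed
    genotype at that subset column (the conditional null of the
    secondary-signal screen).
    """
    m = len(snp_indices)
    H = 1 << m
    mbits = m - 1

    pair_cache: dict[bytes, list[tuple[int, int, float]]] = {}

    def parent_pairs(gt: np.ndarray):
        key = gt.tobytes()
        if key not in pair_cache:
            out = []
            for h1, h2 in _parent_ordered_pairs(gt):
                w = freqs[h1] * freqs[h2]
                if w > 0:
                    out.append((h1, h2, w))
            pair_cache[key] = out
        return pair_cache[key]

    groups: dict[bytes, list[int]] = {}
    trio_sub = []
    for i, t in enumerate(trios):
        g = t.genotypes[:, snp_indices, :]
        child_mask = (g[2] == MISSING).any(axis=-1)
        key = g[0].tobytes() + g[1].tobytes() + child_mask.tobytes()
        if condition_col is not None:
            key += g[2, condition_col].tobytes()
        groups.setdefault(key, []).append(i)
        trio_sub.append(g)

    out = []
    for members in groups.values():
        g = trio_sub[members[0]]
        child_mask = (g[2] == MISSING).any(axis=-1)
        cond_gt = None
        if condition_col is not None and not child_mask[condition_col]:
            cond_gt = tuple(sorted(g[2, condition_col].tolist()))
        outcome_probs: dict[tuple, float] = {}
        for fh1, fh2, wf in parent_pairs(g[0]):
            for mh1, mh2, wm in parent_pairs(g[1]):
                child = []
                for k in range(m):
                    if child_mask[k]:
                        child.append((MISSING, MISSING))
                    else:
                        fa = (fh1 >> (mbits - k)) & 1
                        ma = (mh1 >> (mbits - k)) & 1
                        child.append((min(fa, ma), max(fa, ma)))
                if cond_gt is not None and child[condition_col] != cond_gt:
                    continue
                key = tuple(child)
                outcome_probs[key] = outcome_probs.get(key, 0.0) + wf * wm
        if not outcome_probs:
            continue  # pattern impossible under the estimated frequencies
        keys = list(outcome_probs)
        probs = np.array([outcome_probs[k] for k in keys])
        probs /= probs.sum()
        Ms = np.empty((len(keys), H, H))
        for o, child in enumerate(keys):
            pseudo = np.stack([g[0], g[1], np.array(child, dtype=np.int8)])
            cfgs = enumerate_configs(pseudo)
            Ms[o] = _estep_pair_matrix(cfgs, freqs, H)
        out.append((len(members), probs, Ms))
    return out


def _sample_null_pair_matrices(
    groups, n_perm: int, rng: np.random.Generator, H: int
) -> np.ndarray:
    """Draw ``n_perm`` null samples of the total pair-count matrix."""
    M = np.zeros((n_perm, H * H))
    for n_g, probs, Ms in groups:
        counts = rng.multinomial(n_g, probs, size=n_perm).astype(float)
        M += counts @ Ms.reshape(len(probs), H * H)
    return M.reshape(n_perm, H, H)


def _observed_pair_matrix(phasing: PhasingResult) -> np.ndarray:
    H = len(phasing.freqs)
    M = np.zeros((H, H))
    for pt in phasing.trios:
        cfg, w = pt.configs, pt.weights
        np.add.at(M, (cfg[:, 0], cfg[:, 1]), w)
        np.add.at(M, (cfg[:, 2], cfg[:, 3]), w)
    return M


def ld_measures(hap_freqs) -> tuple[float, float]:
    """D' and r² from two-SNP haplotype frequencies.

    ``hap_freqs`` is a length-4 array in haplotype-index order
    (00, 01, 10, 11), where the first position is the first SNP and allele
    code 1 is the "B" allele; or a :class:`PhasingResult` over two SNPs.
    """
    if isinstance(hap_freqs, PhasingResult):
        hap_freqs = hap_freqs.freqs
    f = np.asarray(hap_freqs, dtype=float)
    if f.shape != (4,):
        raise ValueError("need 4 two-SNP haplotype frequencies")
    f = f / f.sum()
    p_a = f[2] + f[3]  # allele 1 at first SNP
    p_b = f[1] + f[3]  # allele 1 at second SNP
    q_a, q_b = 1 - p_a, 1 - p_b
    if min(p_a, q_a, p_b, q_b) <= 0:
        raise ValueError("LD undefined for a monomorphic SNP")
    D = f[3] - p_a * p_b
    if D >= 0:
        d_max = min(p_a * q_b, q_a * p_b)
    else:
        d_max = min(p_a * p_b, q_a * q_b)
    d_prime = 0.0 if d_max == 0 else abs(D) / d_max
    r2 = D * D / (p_a * q_a * p_b * q_b)
    return float(d_prime), float(r2)


@dataclass
class HapTestResult:
    """Weighted haplotype TDT over one SNP subset.

    ``table`` has one row per haplotype with nonzero transmissions:
    haplotype string, founder frequency, fractional T and U, transmission
    ratio, and (if computed) the haplotypic relative risk with Wald CI
    relative to the most frequent haplotype.
    """

    snp_ids: tuple[str, ...]
    table: pd.DataFrame
    statistic: float
    p_perm: float
    n_perm: int
    phasing: PhasingResult

    @property
    def transmission_ratio(self) -> pd.Series:
        return self.table.set_index("haplotype")["transmission_ratio"]


def _meiosis_matrices(phasing: PhasingResult) -> tuple[np.ndarray, np.ndarray]:
    """Per-parent fractional contribution matrices C_T, C_U of shape
    (n_parents, H); swapping a parent's row between the two matrices is the
    permutation flip."""
    H = len(phasing.freqs)
    P = 2 * len(phasing.trios)
    C_T = np.zeros((P, H))
    C_U = np.zeros((P, H))
    for i, pt in enumerate(phasing.trios):
        pf, pm = 2 * i, 2 * i + 1
        cfg, w = pt.configs, pt.weights
        np.add.at(C_T[pf], cfg[:, 0], w)
        np.add.at(C_U[pf], cfg[:, 1], w)
        np.add.at(C_T[pm], cfg[:, 2], w)
        np.add.at(C_U[pm], cfg[:, 3], w)
    return C_T, C_U


def hap_tdt(
    trios: list[TrioGenotypes],
    snps: list[SnpRecord],
    snp_pair,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    phasing: PhasingResult | None = None,
    compute_hrr: bool = True,
) -> HapTestResult:
    """Weighted haplotype TDT with a permutation-based global p-value.

    Fractional transmitted/untransmitted counts ``T_h``/``U_h`` accumulate
    posterior phase weights over parental meioses.  The global statistic is
    the haplotype-summed McNemar form ``Σ_h (T_h - U_h)² / (T_h + U_h)``
    over haplotypes with any transmissions.  The permutation null swaps the
    transmitted and untransmitted haplotype of each parental meiosis with
    probability 1/2; ``p = (1 + exceedances) / (1 + n_perm)``.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d gives an unstable permutation p", n_perm)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if phasing is None:
        phasing = em_phase(trios, snps, snp_pair)
    M_obs = _observed_pair_matrix(phasing)
    T = M_obs.sum(axis=1)
    U = M_obs.sum(axis=0)

    def statistic(M: np.ndarray) -> np.ndarray:
        T_arr = M.sum(axis=-1)
        U_arr = M.sum(axis=-2)
        tot = T_arr + U_arr
        live_ = tot > 1e-12
        terms = np.where(live_, (T_arr - U_arr) ** 2 / np.where(live_, tot, 1.0), 0.0)
        return terms.sum(axis=-1)

    obs = float(statistic(M_obs))
    snp_indices = _resolve_indices(snps, [s.snp_id for s in phasing.snp_records])
    used = set(phasing.flagged_families)
    trios_used = [t for t in trios if t.family_id not in used]
    groups = _null_transmission_groups(trios_used, snp_indices, phasing.freqs)
    M_perm = _sample_null_pair_matrices(groups, n_perm, rng, len(phasing.freqs))
    perm_stats = statistic(M_perm)
    p = (1 + int((perm_stats >= obs - 1e-12).sum())) / (1 + n_perm)
    live = (T + U) > 1e-12

    strings = phasing.hap_strings
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(U > 0, T / np.where(U > 0, U, 1.0), np.nan)
    tab = pd.DataFrame({
        "haplotype": strings,
        "frequency": phasing.freqs,
        "T": T,
        "U": U,
        "transmission_ratio": ratio,
    })
    tab = tab[live].reset_index(drop=True)
    if compute_hrr and len(tab) > 1:
        from .clr import hrr_per_haplotype

        try:
            hrr = hrr_per_haplotype(phasing)
        except ValueError as exc:  # e.g. every set uninformative
            logger.warning("hRR not computed: %s", exc)
        else:
            tab = tab.merge(hrr, on="haplotype", how="left")
    return HapTestResult(
        snp_ids=tuple(s.snp_id for s in phasing.snp_records),
        table=tab,
        statistic=obs,
        p_perm=p,
        n_perm=n_perm,
        phasing=phasing,
    )


def best_two_marker_scan(
    trios: list[TrioGenotypes],
    snps: list[SnpRecord],
    selected_snps,
    n_perm: int = 10_000,
    seed: int | None = None,
    compute_hrr: bool = False,
) -> tuple[pd.DataFrame, list[HapTestResult]]:
    """Haplotype-TDT every unordered pair of the selected SNPs and rank by
    permutation p (Bonferroni-adjusted p reported alongside).

    Ties are broken by genomic coordinates, so the ranking is invariant to
    the input SNP order.  Returns the ranking table and the per-pair
    results in ranked order.
    """
    idx = _resolve_indices(snps, selected_snps)
    if len(idx) < 2:
        raise ValueError("need at least two selected SNPs")
    recs = sorted((snps[j] for j in idx), key=lambda s: (s.chrom, s.pos_bp))
    pairs = list(itertools.combinations(recs, 2))
    ss = np.random.SeedSequence(seed)
    results = []
    for (s1, s2), child_ss in zip(pairs, ss.spawn(len(pairs))):
        res = hap_tdt(
            trios, snps, [s1.snp_id, s2.snp_id], n_perm=n_perm,
            seed=np.random.default_rng(child_ss), compute_hrr=compute_hrr,
        )
        results.append(res)
    n_pairs = len(pairs)
    rows = [{
        "snp1": r.snp_ids[0],
        "snp2": r.snp_ids[1],
        "pos1": r.phasing.snp_records[0].pos_bp,
        "pos2": r.phasing.snp_records[1].pos_bp,
        "statistic": r.statistic,
        "p_perm": r.p_perm,
        "p_bonferroni": min(1.0, r.p_perm * n_pairs),
    } for r in results]
    tab = pd.DataFrame(rows)
    order = tab.sort_values(["p_perm", "pos1", "pos2"]).index
    tab = tab.loc[order].reset_index(drop=True)
    tab.insert(0, "rank", np.arange(1, n_pairs + 1))
    return tab, [results[i] for i in order]
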