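"""Power of the TDT for case-parent trio designs.

Model: a biallelic SNP with risk-allele frequency ``maf`` in Hardy-Weinberg
equilibrium, a multiplicative (log-additive) per-allele relative risk ``r``,
and ascertainment on an affected child under the rare-disease
approximation.  Under ascertainment each transmitted founder allele is the
risk allele with probability ``p r / (p r + q)`` while untransmitted
alleles retain the population frequency; transmissions from heterozygous
parents are then Bernoulli(r / (1 + r)).

``power_analytic`` evaluates a normal approximation of the resulting
binomial TDT; ``power_simulate`` is its Monte-Carlo twin using the exact
two-sided binomial test, which is the recommended estimate (the analytic
form ignores binomial discreteness).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tdt import exact_p_vectorized

__all__ = ["PowerSpec", "power_analytic", "power_simulate"]


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters of a TDT power computation.

    ``rr_per_allele`` is the multiplicative per-allele relative risk of the
    minor (risk) allele; ``alpha_two_sided`` the two-sided significance
    level of the exact TDT."""

    n_trios: int
    maf: float
    rr_per_allele: float
    alpha_two_sided: float = 0.05
    n_reps: int = 5000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if self.n_trios < 1:
            raise ValueError("n_trios must be >= 1")
        if self.rr_per_allele < 1:
            raise ValueError(
                "rr_per_allele must be >= 1; reparameterize to the risk allele")
        if not 0 < self.alpha_two_sided < 1:
            raise ValueError("alpha_two_sided must be in (0, 1)")


def _ascertained_params(p: float, r: float) -> tuple[float, float]:
    """(P(parent heterozygous | affected child), P(transmit risk | het))."""
    q = 1 - p
    p_t = p * r / (p * r + q)  # transmitted allele is the risk allele
    p_het = p_t * q + (1 - p_t) * p
    return p_het, r / (1 + r)


def power_analytic(spec: PowerSpec) -> float:
    """Normal-approximation power of the two-sided TDT.

    The number of informative meioses is fixed at its expectation
    ``n = 2 N P(het | affected)``; the TDT z-statistic ``(2T - n)/sqrt(n)``
    with ``T ~ Binomial(n, r/(1+r))`` is compared against the two-sided
    normal critical value.
    """
    p_het, h = _ascertained_params(spec.maf, spec.rr_per_allele)
    n = 2 * spec.n_trios * p_het
    if n <= 0:
        return spec.alpha_two_sided
    z_a = stats.norm.ppf(1 - spec.alpha_two_sided / 2)
    hi = (n + z_a * np.sqrt(n)) / 2  # reject when T >= hi or T <= lo
    lo = (n - z_a * np.sqrt(n)) / 2
    sd = np.sqrt(n * h * (1 - h))
    return float(stats.norm.sf((hi - n * h) / sd) + stats.norm.cdf((lo - n * h) / sd))


def simulate_tdt_counts(
    n_trios: int, maf: float, rr: float, n_reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (T, n_informative) for ``n_reps`` replicates of an ascertained
    trio sample by rejection sampling.

    Parental genotypes are drawn from HWE, the child by random
    transmission, and the trio is accepted with probability proportional to
    ``rr``^(child risk-allele count) — the rare-disease ascertainment.
    """
    T = np.zeros(n_reps, dtype=np.int64)
    n_inf = np.zeros(n_reps, dtype=np.int64)
    need = np.full(n_reps, n_trios, dtype=np.int64)
    accept_rate = ((1 - maf) + maf * rr) ** 2 / rr**2
    while True:
        total = int(need.sum())
        if total == 0:
            break
        batch = int(total / accept_rate * 1.2) + 64
        par = rng.random((batch, 4)) < maf  # father a1 a2, mother a1 a2
        tf = rng.integers(0, 2, batch)
        tm = rng.integers(0, 2, batch)
        cf = par[np.arange(batch), tf]
        cm = par[np.arange(batch), 2 + tm]
        k_child = cf.astype(int) + cm.astype(int)
        keep = rng.random(batch) < rr**k_child / rr**2
        par, cf, cm = par[keep], cf[keep], cm[keep]
        rep = np.repeat(np.arange(n_reps), need)
        take = min(len(rep), len(par))
        rep, par, cf, cm = rep[:take], par[:take], cf[:take], cm[:take]
        het_f = par[:, 0] != par[:, 1]
        het_m = par[:, 2] != par[:, 3]
        t = np.where(het_f, cf, 0) + np.where(het_m, cm, 0)
        k = het_f.astype(int) + het_m.astype(int)
        np.add.at(T, rep, t)
        np.add.at(n_inf, rep, k)
        need -= np.bincount(rep, minlength=n_reps)
    return T, n_inf


def power_simulate(spec: PowerSpec) -> tuple[float, float]:
    """Monte-Carlo power of the exact two-sided TDT, with its standard error.

    Each replicate simulates ``n_trios`` ascertained trios, counts
    transmissions from heterozygous parents, and applies the exact binomial
    TDT at ``alpha_two_sided``.  Returns (power, Monte-Carlo SE).
    """
    if spec.n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    rng = np.random.default_rng(spec.seed)
    T, n = simulate_tdt_counts(
        spec.n_trios, spec.maf, spec.rr_per_allele, spec.n_reps, rng)
    pvals = exact_p_vectorized(T, n)
    rejected = pvals <= spec.alpha_two_sided
    power = float(rejected.mean())
    se = float(np.sqrt(power * (1 - power) / spec.n_reps))
    return power, se
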