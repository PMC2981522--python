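"""Conditional logistic regression on case/pseudo-control sets from trios.

Each phased trio yields a matched set of four offspring: the real affected
child (the transmitted haplotype pair) and the three pseudo-controls formed
by the other combinations of the four parental haplotypes.  Conditioning on
the set removes all between-family confounding; under a log-additive model
exp(beta) is the per-copy relative risk of the coded allele or haplotype.

Phase uncertainty
-----------------
When phase is ambiguous the family's likelihood is a *mixture* over its
parental phase assignments phi, with prior weights proportional to the
product of the four founder-haplotype frequencies:

    L_fam(beta) =  sum_c  pi_phi(c) exp(x_case(c) . beta)
                  ---------------------------------------------
                   sum_phi pi_phi  sum_{m=1..4} exp(x_m(phi) . beta)

where c runs over the Mendelian-consistent (phase, transmission)
configurations and the denominator sums each phase's four possible
offspring once.  This is the correct conditional likelihood; the simpler
alternative of raising each configuration's set term to its posterior
weight (a geometric mean) systematically attenuates coefficients of
covariates whose haplotype assignment is uncertain, and is retained only
as ``method="weighted"`` for comparison.

For a single biallelic SNP with dosage coding the maximum conditional
likelihood is available in closed form and equals the transmission ratio
T/U — a useful internal consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .haplotypes import PhasingResult

__all__ = [
    "MatchedSets",
    "CLRFit",
    "build_pseudo_controls",
    "fit_clr",
    "hrr_per_haplotype",
    "allele_dosage_covariates",
    "haplotype_dosage_covariates",
]


@dataclass
class MatchedSets:
    """Covariates of matched 1-case : 3-pseudo-control sets.

    Configuration-level view (used by the posterior-weighted method):
    ``X`` has shape (n_cfg, 4, p) with member 0 the case, ``posterior`` the
    phase posterior weight and ``family`` the family index of each
    configuration.

    Phase-level view (used by the mixture likelihood): ``num_logpi`` /
    ``num_X`` give the log prior weight and case covariates of every
    consistent configuration; ``den_logpi`` / ``den_X`` the log prior and
    covariates of each distinct parental phase's four possible offspring
    (each phase counted once).
    """

    X: np.ndarray  # (n_cfg, 4, p)
    posterior: np.ndarray  # (n_cfg,)
    family: np.ndarray  # (n_cfg,) int
    names: list[str]
    num_logpi: np.ndarray  # (n_cfg,)
    den_logpi: np.ndarray  # (n_phi,)
    den_X: np.ndarray  # (n_phi, 4, p)
    den_family: np.ndarray  # (n_phi,) int
    n_families: int

    @property
    def n_sets(self) -> int:
        return self.X.shape[0]


@dataclass
class CLRFit:
    """A converged conditional-logistic fit.

    ``rr = exp(beta)`` with Wald 95% CI and p per covariate.  ``loglik_null``
    is the log-likelihood at beta = 0, enabling a likelihood-ratio test."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    converged: bool
    n_sets: float
    loglik: float
    loglik_null: float
    n_iter: int
    method: str = "mixture"

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci(self) -> np.ndarray:
        z = stats.norm.ppf(0.975)
        return np.exp(np.stack([self.beta - z * self.se, self.beta + z * self.se], 1))

    @property
    def p_wald(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.beta / self.se, np.inf)
        return 2 * stats.norm.sf(np.abs(z))

    @property
    def p_lr(self) -> float:
        """Likelihood-ratio p of the whole model against beta = 0."""
        lr = 2 * (self.loglik - self.loglik_null)
        return float(stats.chi2.sf(max(lr, 0.0), df=len(self.beta)))

    @property
    def table(self) -> pd.DataFrame:
        ci = self.ci
        return pd.DataFrame({
            "covariate": self.names,
            "beta": self.beta,
            "se": self.se,
            "rr": self.rr,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p_wald": self.p_wald,
        })


def allele_dosage_covariates(
    phasing: PhasingResult, effect_alleles: dict[str, str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Per-haplotype dosage design: one column per SNP counting copies of
    its effect allele (default: ``allele_b``)."""
    effect_alleles = effect_alleles or {}
    H, m = phasing.haplotypes.shape
    cov = np.zeros((H, m))
    names = []
    for k, rec in enumerate(phasing.snp_records):
        eff = effect_alleles.get(rec.snp_id, rec.allele_b)
        code = 0 if eff == rec.allele_a else 1
        cov[:, k] = (phasing.haplotypes[:, k] == code).astype(float)
        names.append(f"{rec.snp_id}:{eff}")
    return cov, names


def haplotype_dosage_covariates(
    phasing: PhasingResult, reference: int | str | None = None
) -> tuple[np.ndarray, list[str], int]:
    """One dosage column per non-reference haplotype with nonzero founder
    frequency.  Default reference: the most frequent haplotype."""
    strings = phasing.hap_strings
    if reference is None:
        ref = int(np.argmax(phasing.freqs))
    elif isinstance(reference, str):
        if reference not in strings:
            raise ValueError(f"reference haplotype {reference!r} not observed")
        ref = strings.index(reference)
    else:
        ref = int(reference)
    if phasing.freqs[ref] <= 0:
        raise ValueError("reference haplotype not observed in founders")
    keep = [h for h in range(len(strings)) if h != ref and phasing.freqs[h] > 0]
    cov = np.zeros((len(strings), len(keep)))
    for col, h in enumerate(keep):
        cov[h, col] = 1.0
    return cov, [strings[h] for h in keep], ref


def build_pseudo_controls(
    phasing: PhasingResult,
    hap_covariates: np.ndarray,
    names: list[str] | None = None,
) -> MatchedSets:
    """Assemble matched sets from every phase configuration of every trio.

    ``hap_covariates`` (H, p) gives the covariate contribution of one
    haplotype copy; offspring covariates are the sum over their two
    haplotypes (log-additive coding).  For each configuration
    (t_f, u_f, t_m, u_m) the case is (t_f, t_m) and the pseudo-controls are
    (t_f, u_m), (u_f, t_m) and (u_f, u_m).  Both the posterior-weighted
    configuration view and the prior-weighted phase view (see module
    docstring) are populated.
    """
    hap_covariates = np.atleast_2d(np.asarray(hap_covariates, dtype=float))
    p = hap_covariates.shape[1]
    names = names or [f"x{i}" for i in range(p)]
    freqs = phasing.freqs
    tiny = 1e-300

    cfg_rows, post_rows, fam_rows, num_logpi = [], [], [], []
    den_rows, den_logpi, den_fam = [], [], []
    for fam, pt in enumerate(phasing.trios):
        cfg, w = pt.configs, pt.weights
        pi = freqs[cfg].prod(axis=1)
        keep = pi > 0
        if not keep.any():
            # frequencies pruned away every configuration: fall back to
            # uniform priors so the family still contributes
            pi = np.full(len(cfg), 1.0)
            keep = np.ones(len(cfg), bool)
        cfg, w, pi = cfg[keep], w[keep], pi[keep]
        pi = pi / pi.sum()
        cfg_rows.append(cfg)
        post_rows.append(w / max(w.sum(), tiny))
        fam_rows.append(np.full(len(cfg), fam))
        num_logpi.append(np.log(pi + tiny))
        # distinct parental phases: unordered pair per parent
        seen: dict[tuple, float] = {}
        for (tf, uf, tm, um), pi_c in zip(cfg, pi):
            key = (min(tf, uf), max(tf, uf), min(tm, um), max(tm, um))
            if key not in seen:
                seen[key] = pi_c
        for (f1, f2, m1, m2), pi_phi in seen.items():
            den_rows.append((f1, f2, m1, m2))
            den_logpi.append(np.log(pi_phi + tiny))
            den_fam.append(fam)

    if not cfg_rows:
        empty = np.zeros(0)
        return MatchedSets(np.zeros((0, 4, p)), empty, empty.astype(int), names,
                           empty, empty, np.zeros((0, 4, p)), empty.astype(int), 0)

    cfgs = np.concatenate(cfg_rows)
    tf, uf, tm, um = cfgs.T
    X = np.stack([
        hap_covariates[tf] + hap_covariates[tm],
        hap_covariates[tf] + hap_covariates[um],
        hap_covariates[uf] + hap_covariates[tm],
        hap_covariates[uf] + hap_covariates[um],
    ], axis=1)
    den = np.array(den_rows)
    f1, f2, m1, m2 = den.T
    den_X = np.stack([
        hap_covariates[f1] + hap_covariates[m1],
        hap_covariates[f1] + hap_covariates[m2],
        hap_covariates[f2] + hap_covariates[m1],
        hap_covariates[f2] + hap_covariates[m2],
    ], axis=1)
    return MatchedSets(
        X=X,
        posterior=np.concatenate(post_rows),
        family=np.concatenate(fam_rows),
        names=names,
        num_logpi=np.concatenate(num_logpi),
        den_logpi=np.array(den_logpi),
        den_X=den_X,
        den_family=np.array(den_fam),
        n_families=len(phasing.trios),
    )


class _GroupedTerms:
    """Log-sum-exp statistics of ``a_i = logpi_i + x_i . beta`` grouped by
    family, for families stored contiguously."""

    def __init__(self, logpi: np.ndarray, X: np.ndarray, family: np.ndarray):
        order = np.argsort(family, kind="stable")
        self.logpi = logpi[order]
        self.X = X[order]
        self.family = family[order]
        fams, starts = np.unique(self.family, return_index=True)
        self.fams = fams
        self.starts = starts
        self.entry_group = np.searchsorted(fams, self.family)

    def stats(self, beta: np.ndarray):
        a = self.logpi + self.X @ beta
        amax = np.maximum.reduceat(a, self.starts)
        w = np.exp(a - amax[self.entry_group])
        sw = np.add.reduceat(w, self.starts)
        lse = amax + np.log(sw)
        wn = w / sw[self.entry_group]
        means = np.zeros((len(self.fams), self.X.shape[1]))
        np.add.at(means, self.entry_group, wn[:, None] * self.X)
        sxx = (wn[:, None] * self.X).T @ self.X
        cov = sxx - means.T @ means  # sum over families of within-family cov
        return lse, means, cov


def _flatten_members(logpi: np.ndarray, X: np.ndarray, family: np.ndarray):
    """Expand (n, 4, p) member covariates to flat entries sharing logpi."""
    n, m, p = X.shape
    return (np.repeat(logpi, m), X.reshape(n * m, p), np.repeat(family, m))


def fit_clr(
    matched_sets: MatchedSets,
    method: str = "mixture",
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CLRFit:
    """Maximise the conditional likelihood by Newton-Raphson.

    ``method="mixture"`` (default) uses the phase-mixture likelihood;
    ``method="weighted"`` raises each configuration's set term to its
    posterior phase weight.  Steps are halved on log-likelihood overshoot.
    Monotone likelihoods (separation) are reported with ``converged=False``;
    a singular design raises, naming the collinear covariates.
    """
    ms = matched_sets
    if ms.n_sets == 0:
        raise ValueError("no informative sets (covariates constant within every set)")
    p = ms.X.shape[2]

    # Families where every possible offspring has identical covariates are
    # uninformative; detect via within-family spread of the denominator.
    den_flat = ms.den_X.reshape(-1, p)
    den_fam_flat = np.repeat(ms.den_family, 4)
    informative = np.zeros(ms.n_families, bool)
    spread = ms.den_X.max(axis=1) - ms.den_X.min(axis=1)  # (n_phi, p)
    np.logical_or.at(informative, ms.den_family, (spread > 0).any(axis=1))
    if not informative.any():
        raise ValueError("no informative sets (covariates constant within every set)")
    n_eff = float(informative.sum())

    # Rank check on within-family contrasts.
    ref = np.zeros((ms.n_families, p))
    first = np.unique(den_fam_flat, return_index=True)[1]
    ref[np.unique(den_fam_flat)] = den_flat[first]
    contrasts = den_flat - ref[den_fam_flat]
    if np.linalg.matrix_rank(contrasts) < p:
        _, _, vt = np.linalg.svd(contrasts, full_matrices=False)
        bad = [ms.names[i] for i in np.nonzero(np.abs(vt[-1]) > 1e-6)[0]]
        raise ValueError(f"singular design; collinear covariates: {bad}")

    if method == "mixture":
        keep_num = informative[ms.family]
        keep_den = informative[ms.den_family]
        num = _GroupedTerms(ms.num_logpi[keep_num], ms.X[keep_num, 0, :],
                            ms.family[keep_num])
        lp, xx, ff = _flatten_members(ms.den_logpi[keep_den],
                                      ms.den_X[keep_den], ms.den_family[keep_den])
        den = _GroupedTerms(lp, xx, ff)

        def loglik_grad_hess(beta):
            lse_n, m_n, c_n = num.stats(beta)
            lse_d, m_d, c_d = den.stats(beta)
            ll = float(lse_n.sum() - lse_d.sum())
            grad = m_n.sum(axis=0) - m_d.sum(axis=0)
            hess = c_n - c_d
            return ll, grad, hess

    elif method == "weighted":
        keep = informative[ms.family] & (ms.posterior > 0)
        X, w = ms.X[keep], ms.posterior[keep]

        def loglik_grad_hess(beta):
            eta = X @ beta  # (n, 4)
            lse = logsumexp(eta, axis=1)
            ll = float((w * (eta[:, 0] - lse)).sum())
            pi = np.exp(eta - lse[:, None])
            xbar = np.einsum("nm,nmp->np", pi, X)
            grad = (w[:, None] * (X[:, 0, :] - xbar)).sum(axis=0)
            xc = X - xbar[:, None, :]
            hess = -np.einsum("n,nm,nmp,nmq->pq", w, pi, xc, xc)
            return ll, grad, hess

    else:
        raise ValueError(f"unknown method {method!r}")

    beta = np.zeros(p)
    ll, grad, hess = loglik_grad_hess(beta)
    ll_null = ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = loglik_grad_hess(cand)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2
        beta, ll_prev = cand, ll
        ll, grad, hess = ll_new, grad_new, hess_new
        if abs(ll - ll_prev) < tol:
            converged = True
            break
    if np.abs(beta).max() > 15:
        converged = False  # monotone likelihood / separation
    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    return CLRFit(
        names=ms.names,
        beta=beta,
        se=se,
        converged=converged,
        n_sets=n_eff,
        loglik=ll,
        loglik_null=ll_null,
        n_iter=it,
        method=method,
    )


def hrr_per_haplotype(
    phasing: PhasingResult,
    reference: int | str | None = None,
    method: str = "mixture",
) -> pd.DataFrame:
    """Haplotypic relative risks under an additive haplotypic model.

    Fits one dosage coefficient per non-reference haplotype (reference =
    most frequent).  Returns a table with one row per haplotype including
    the reference (hRR 1 by definition).
    """
    cov, names, ref = haplotype_dosage_covariates(phasing, reference)
    ms = build_pseudo_controls(phasing, cov, names)
    fit = fit_clr(ms, method=method)
    ci = fit.ci
    rows = [{
        "haplotype": phasing.hap_strings[ref],
        "hRR": 1.0, "hrr_ci_low": np.nan, "hrr_ci_high": np.nan,
        "hrr_p": np.nan, "is_reference": True,
    }]
    for i, name in enumerate(fit.names):
        rows.append({
            "haplotype": name,
            "hRR": float(fit.rr[i]),
            "hrr_ci_low": float(ci[i, 0]),
            "hrr_ci_high": float(ci[i, 1]),
            "hrr_p": float(fit.p_wald[i]),
            "is_reference": False,
        })
    return pd.DataFrame(rows)
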