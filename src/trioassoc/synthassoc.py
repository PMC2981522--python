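"""Synthetic-association assessment for trio data.

"Synthetic association" is the hypothesis that the association signal of a
common non-coding SNP (or haplotype) is driven by rarer functional variants
residing on the haplotype background the SNP tags.  The analyses here probe
that hypothesis three ways:

1. stratify the fractional haplotype transmissions by coding-variant
   background (variant-bearing vs wild-type haplotypes);
2. remove carrier families and compare association results before/after;
3. fit joint conditional-logistic models of the common SNPs together with
   collapsed (carrier-burden) coding-variant covariates.

Coding variants are assigned to parental haplotypes by treating each
collapsed variant class as one extra biallelic locus in the trio-EM
phasing; heterozygous carriers contribute the variant allele on exactly one
of their haplotypes, with phase resolved probabilistically like any other
locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clr import CLRFit, allele_dosage_covariates, build_pseudo_controls, fit_clr
from .haplotypes import HapTestResult, em_phase, hap_tdt, _meiosis_matrices
from .io import SnpRecord, TrioGenotypes
from .tdt import TdtResult, tdt_test

logger = logging.getLogger(__name__)

PROTECTIVE_POLYMORPHISM = "protective_polymorphism"
FUNCTIONAL_MUTATION = "functional_mutation"
_MEMBERS = ("father", "mother", "child")

__all__ = [
    "CodingVariantTable",
    "StratifiedTransmissionTable",
    "CarrierRemovalResult",
    "JointModelsResult",
    "collapse",
    "augment_with_background",
    "stratified_transmissions",
    "carrier_removal_analysis",
    "joint_models",
    "PROTECTIVE_POLYMORPHISM",
    "FUNCTIONAL_MUTATION",
]


@dataclass
class CodingVariantTable:
    """Carrier status of named coding variants per individual.

    ``statuses`` is indexed by (family_id, member) with member in
    {"father", "mother", "child"}, one column per variant, values 0/1 or
    NaN for missing.  ``classes`` maps each variant to its class label
    (e.g. protective polymorphism vs functional mutation).
    """

    statuses: pd.DataFrame
    classes: dict[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.statuses.columns) - set(self.classes)
        if unknown:
            raise ValueError(f"variants without a class label: {sorted(unknown)}")

    def variants_in_class(self, class_label: str) -> list[str]:
        return [v for v, c in self.classes.items()
                if c == class_label and v in self.statuses.columns]

    def to_tsv(self, path: str | Path) -> Path:
        rows = []
        for (fid, member), row in self.statuses.iterrows():
            for v in self.statuses.columns:
                if pd.isna(row[v]):
                    continue
                rows.append({
                    "individual_id": f"{fid}_{member[0]}" if member != "child"
                    else f"{fid}_c",
                    "variant_id": v,
                    "class": self.classes[v],
                    "status": int(row[v]),
                })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return Path(path)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodingVariantTable":
        df = pd.read_csv(path, sep="\t", dtype={"status": "Int64"})
        classes = dict(zip(df["variant_id"], df["class"]))
        suffix_to_member = {"f": "father", "m": "mother", "c": "child"}
        recs = {}
        for _, r in df.iterrows():
            fid, _, suf = r["individual_id"].rpartition("_")
            member = suffix_to_member.get(suf)
            if member is None:
                raise ValueError(f"cannot infer member role from {r['individual_id']!r}")
            recs.setdefault((fid, member), {})[r["variant_id"]] = float(r["status"])
        statuses = pd.DataFrame.from_dict(recs, orient="index")
        statuses.index = pd.MultiIndex.from_tuples(statuses.index,
                                                   names=["family_id", "member"])
        return cls(statuses=statuses, classes=classes)


def collapse(variant_table: CodingVariantTable, class_label: str) -> pd.Series:
    """Carrier-burden collapsing: indicator of carrying >= 1 variant of the
    class, per individual.  Missing statuses count as non-carrier (logged)."""
    variants = variant_table.variants_in_class(class_label)
    if not variants:
        raise ValueError(f"no variants in class {class_label!r}")
    sub = variant_table.statuses[variants]
    n_missing = int(sub.isna().sum().sum())
    if n_missing:
        logger.info("collapse(%s): %d missing statuses treated as non-carrier",
                    class_label, n_missing)
    return (sub.fillna(0) > 0).any(axis=1).astype(int).rename(class_label)


def augment_with_background(
    trios: list[TrioGenotypes],
    snps: list[SnpRecord],
    snp_pair,
    variant_table: CodingVariantTable,
    class_labels: list[str],
) -> tuple[list[SnpRecord], list[TrioGenotypes]]:
    """Append one collapsed pseudo-locus per variant class to the SNP pair.

    Carriers (all observed carriers are heterozygous) get the het genotype
    W/V at the pseudo-locus, non-carriers W/W, so the EM phasing places the
    variant allele on one parental haplotype probabilistically.
    """
    from .haplotypes import _resolve_indices

    idx = _resolve_indices(snps, snp_pair)
    base = [snps[j] for j in idx]
    indicators = {c: collapse(variant_table, c) for c in class_labels}
    aug_snps = list(base)
    for k, c in enumerate(class_labels):
        aug_snps.append(SnpRecord(
            snp_id=f"class:{c}", chrom=base[0].chrom,
            pos_bp=base[-1].pos_bp + 1 + k, allele_a="W", allele_b="V"))
    aug_trios = []
    for t in trios:
        g = t.genotypes[:, idx, :]
        cols = []
        for c in class_labels:
            ind = indicators[c]
            col = np.zeros((3, 1, 2), dtype=np.int8)
            for mi, member in enumerate(_MEMBERS):
                status = ind.get((t.family_id, member), 0)
                col[mi, 0] = (0, 1) if status else (0, 0)
            cols.append(col)
        aug_trios.append(TrioGenotypes(t.family_id, np.concatenate([g] + cols, axis=1)))
    return aug_snps, aug_trios


@dataclass
class StratifiedTransmissionTable:
    """Haplotype transmissions stratified by coding-variant background.

    One row per (two-marker haplotype, background) cell: expected founder
    frequency under independence (product of the marginals), estimated
    frequency, fractional T and U, and the transmission ratio (NaN where
    T + U = 0, the published tables print "-")."""

    table: pd.DataFrame
    background_class: str
    marginal: pd.DataFrame  # unstratified per-haplotype T/U


def stratified_transmissions(
    trios: list[TrioGenotypes],
    snps: list[SnpRecord],
    snp_pair,
    variant_table: CodingVariantTable,
    background_class: str = PROTECTIVE_POLYMORPHISM,
) -> StratifiedTransmissionTable:
    """Fractional T/U per (two-marker haplotype x coding background) cell.

    The SNP pair plus the collapsed background locus are phased jointly
    (three loci, eight haplotypes); cell counts are the phase-weighted
    transmissions of each extended haplotype.  Summing cells over the
    background reproduces the unstratified haplotype table exactly.
    """
    aug_snps, aug_trios = augment_with_background(
        trios, snps, snp_pair, variant_table, [background_class])
    phasing = em_phase(aug_trios, aug_snps, [s.snp_id for s in aug_snps])
    C_T, C_U = _meiosis_matrices(phasing)
    T = C_T.sum(axis=0)
    U = C_U.sum(axis=0)
    haps = phasing.haplotypes  # (8, 3): snp1, snp2, background
    pair_strings = []
    for row in haps:
        pair_strings.append("".join(
            (s.allele_a if a == 0 else s.allele_b)
            for s, a in zip(phasing.snp_records[:2], row[:2])))
    background = np.where(haps[:, 2] == 1, "variant", "wild_type")

    freqs = phasing.freqs
    pair_marg: dict[str, float] = {}
    bg_marg: dict[str, float] = {}
    for h in range(len(freqs)):
        pair_marg[pair_strings[h]] = pair_marg.get(pair_strings[h], 0.0) + freqs[h]
        bg_marg[background[h]] = bg_marg.get(background[h], 0.0) + freqs[h]

    rows = []
    for h in range(len(freqs)):
        tu = T[h] + U[h]
        rows.append({
            "haplotype": pair_strings[h],
            "background": background[h],
            "expected_freq": pair_marg[pair_strings[h]] * bg_marg[background[h]],
            "estimated_freq": freqs[h],
            "T": T[h],
            "U": U[h],
            "transmission_ratio": (T[h] / U[h]) if U[h] > 0 and tu > 0 else np.nan,
        })
    table = pd.DataFrame(rows).sort_values(
        ["background", "haplotype"]).reset_index(drop=True)
    marginal = (table.groupby("haplotype", as_index=False)[["T", "U"]].sum())
    marginal["transmission_ratio"] = marginal["T"] / marginal["U"]
    return StratifiedTransmissionTable(table, background_class, marginal)


@dataclass
class CarrierRemovalResult:
    """Association results before and after removing carrier families."""

    n_removed: int
    member: str
    snp_table: pd.DataFrame  # per SNP: RR and exact p before/after
    hap_before: HapTestResult
    hap_after: HapTestResult
    tdt_before: dict[str, TdtResult]
    tdt_after: dict[str, TdtResult]


def carrier_removal_analysis(
    trios: list[TrioGenotypes],
    snps: list[SnpRecord],
    snp_pair,
    variant_table: CodingVariantTable,
    class_labels: list[str] | None = None,
    member: str = "child",
    n_perm: int = 2000,
    seed: int | None = None,
) -> CarrierRemovalResult:
    """Re-run single-marker TDT and haplotype TDT after dropping trios
    whose ``member`` (default: the affected child) carries any variant of
    the listed classes.

    If the common-SNP signal were synthetic — generated entirely by coding
    variants riding the tagged haplotype — removal would shrink the
    haplotype effect toward the null; an independent common-haplotype
    effect is left essentially unchanged.
    """
    if member not in _MEMBERS + ("any",):
        raise ValueError(f"member must be one of {_MEMBERS + ('any',)}")
    class_labels = class_labels or sorted(set(variant_table.classes.values()))
    carrier = pd.Series(0, index=variant_table.statuses.index, dtype=int)
    for c in class_labels:
        carrier |= collapse(variant_table, c)

    def is_carrier_family(fid: str) -> bool:
        if member == "any":
            return any(carrier.get((fid, mb), 0) for mb in _MEMBERS)
        return bool(carrier.get((fid, member), 0))

    kept = [t for t in trios if not is_carrier_family(t.family_id)]
    n_removed = len(trios) - len(kept)
    if not kept:
        raise ValueError("carrier removal leaves no trios")

    from .haplotypes import _resolve_indices

    idx = _resolve_indices(snps, snp_pair)
    pair_ids = [snps[j].snp_id for j in idx]
    ss = np.random.SeedSequence(seed).spawn(2)
    tdt_before = {sid: tdt_test(trios, snps, sid) for sid in pair_ids}
    tdt_after = {
        sid: tdt_test(kept, snps, sid,
                      effect_allele=tdt_before[sid].counts.effect_allele)
        for sid in pair_ids
    }
    hap_before = hap_tdt(trios, snps, pair_ids, n_perm=n_perm,
                         seed=np.random.default_rng(ss[0]))
    hap_after = hap_tdt(kept, snps, pair_ids, n_perm=n_perm,
                        seed=np.random.default_rng(ss[1]))
    rows = [{
        "snp_id": sid,
        "effect_allele": tdt_before[sid].counts.effect_allele,
        "rr_before": tdt_before[sid].rr.rr,
        "rr_after": tdt_after[sid].rr.rr,
        "p_before": tdt_before[sid].p_exact,
        "p_after": tdt_after[sid].p_exact,
    } for sid in pair_ids]
    return CarrierRemovalResult(
        n_removed=n_removed,
        member=member,
        snp_table=pd.DataFrame(rows),
        hap_before=hap_before,
        hap_after=hap_after,
        tdt_before=tdt_before,
        tdt_after=tdt_after,
    )


@dataclass
class JointModelsResult:
    """Hierarchical conditional-logistic models.

    model1: the two common SNP dosages; model2: the collapsed coding-variant
    covariate(s) only; model3: all covariates jointly.  ``model2_error``
    carries the failure message when the coding covariates alone are
    uninformative (e.g. no carriers), in which case model3 degrades to
    model1 and says so in ``notes``."""

    model1: CLRFit
    model2: CLRFit | None
    model3: CLRFit
    model2_error: str | None = None
    notes: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        frames = []
        for name, fit in (("model1", self.model1), ("model2", self.model2),
                          ("model3", self.model3)):
            if fit is None:
                continue
            t = fit.table.copy()
            t.insert(0, "model", name)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)


def joint_models(
    trios: list[TrioGenotypes],
    snps: list[SnpRecord],
    snp_pair,
    variant_table: CodingVariantTable,
    class_labels: list[str] | None = None,
    effect_alleles: dict[str, str] | None = None,
    class_directions: dict[str, str] | None = None,
) -> JointModelsResult:
    """Fit the three hierarchical models of SNPs and collapsed coding
    variants on matched case/pseudo-control sets.

    Coding-variant classes enter as per-haplotype dosages after extended
    phasing.  ``class_directions`` maps a class to "wild_type" or
    "variant": for protective polymorphisms the wild-type (major) allele is
    the risk-direction covariate, for functional mutations the mutated
    allele is (the defaults).
    """
    class_labels = class_labels or sorted(set(variant_table.classes.values()))
    class_directions = class_directions or {}
    aug_snps, aug_trios = augment_with_background(
        trios, snps, snp_pair, variant_table, class_labels)
    phasing = em_phase(aug_trios, aug_snps, [s.snp_id for s in aug_snps])

    snp_cov, snp_names = allele_dosage_covariates(phasing, effect_alleles)
    snp_cov, snp_names = snp_cov[:, :2], snp_names[:2]
    H = phasing.haplotypes.shape[0]
    class_cov = np.zeros((H, len(class_labels)))
    class_names = []
    notes: list[str] = []
    live_classes = []
    for k, c in enumerate(class_labels):
        bit = phasing.haplotypes[:, 2 + k].astype(float)
        direction = class_directions.get(
            c, "wild_type" if c == PROTECTIVE_POLYMORPHISM else "variant")
        class_cov[:, k] = (1.0 - bit) if direction == "wild_type" else bit
        class_names.append(f"{c}:{direction}")
        carried = phasing.freqs[phasing.haplotypes[:, 2 + k] == 1].sum()
        if carried <= 0:
            notes.append(f"class {c!r} has no carriers; dropped from model 3")
        else:
            live_classes.append(k)

    model1 = fit_clr(build_pseudo_controls(phasing, snp_cov, snp_names))
    model2 = None
    model2_error = None
    try:
        model2 = fit_clr(build_pseudo_controls(phasing, class_cov, class_names))
    except ValueError as exc:
        model2_error = f"no informative sets for covariate: {exc}"
        logger.warning("model 2 failed: %s", model2_error)
    if live_classes:
        cov3 = np.concatenate([snp_cov, class_cov[:, live_classes]], axis=1)
        names3 = snp_names + [class_names[k] for k in live_classes]
        model3 = fit_clr(build_pseudo_controls(phasing, cov3, names3))
    else:
        model3 = model1
        notes.append("model 3 degenerates to model 1 (no informative coding class)")
    return JointModelsResult(model1=model1, model2=model2, model3=model3,
                             model2_error=model2_error, notes=notes)
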