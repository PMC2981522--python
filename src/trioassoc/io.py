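"""Reading and writing case-parent trio genotypes in PLINK PED/MAP text format.

Conventions
-----------
* Physical coordinates are 1-based and region selection is inclusive on both
  ends, matching the convention of published SNP tables.
* Genotypes are unordered allele pairs.  Internally each genotype is stored
  as a pair of allele codes (0 = ``allele_a``, 1 = ``allele_b``, -1 =
  missing), canonicalised to ascending order, so ``A G`` and ``G A`` are the
  same genotype.
* A family contributes to analysis only as a complete trio (father, mother,
  affected child).  Families whose parent pointers cannot be resolved are
  dropped with a logged warning, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

MISSING = -1
_MISSING_SYMBOL = "0"

__all__ = [
    "SnpRecord",
    "TrioGenotypes",
    "Region",
    "read_ped_map",
    "write_ped_map",
    "select_region",
    "trios_to_array",
    "parse_region",
]


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP with a physical position.

    ``allele_a`` and ``allele_b`` are the two allele symbols; genotype code 0
    refers to ``allele_a`` and code 1 to ``allele_b``.
    """

    snp_id: str
    chrom: str
    pos_bp: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"{self.snp_id}: pos_bp must be >= 1")
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.snp_id}: alleles must differ")


@dataclass
class TrioGenotypes:
    """Genotypes of one family: father, mother and affected child.

    ``genotypes`` has shape (3, M, 2): members in the fixed order
    (father, mother, child), M SNPs, two allele codes per genotype.
    """

    family_id: str
    genotypes: np.ndarray  # (3, M, 2) int8, codes {0, 1, MISSING}

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.ndim != 3 or g.shape[0] != 3 or g.shape[2] != 2:
            raise ValueError("genotypes must have shape (3, M, 2)")
        self.genotypes = canonicalize_genotypes(g)

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


@dataclass(frozen=True)
class Region:
    """A 1-based, inclusive genomic interval."""

    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")

    @property
    def width_bp(self) -> int:
        """Span between the end coordinates, as printed in SNP tables."""
        return self.end_bp - self.start_bp


def canonicalize_genotypes(g: np.ndarray) -> np.ndarray:
    """Sort allele codes within each genotype; any missing allele makes the
    whole genotype missing."""
    g = np.asarray(g, dtype=np.int8).copy()
    g.sort(axis=-1)
    miss = (g == MISSING).any(axis=-1)
    g[miss] = MISSING
    return g


def trios_to_array(trios: list[TrioGenotypes]) -> np.ndarray:
    """Stack trio genotypes into one (n_families, 3, M, 2) array."""
    if not trios:
        return np.zeros((0, 3, 0, 2), dtype=np.int8)
    return np.stack([t.genotypes for t in trios])


def parse_region(text: str) -> Region:
    """Parse ``chr18:55879013-56243921`` into a :class:`Region`."""
    chrom, _, span = text.partition(":")
    start, _, end = span.partition("-")
    if not (chrom and start and end):
        raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end")
    return Region(chrom, int(start.replace(",", "")), int(end.replace(",", "")))


def select_region(snps: list[SnpRecord], region: Region) -> list[SnpRecord]:
    """SNPs with ``region.start_bp <= pos_bp <= region.end_bp``, in
    coordinate order.  An empty result is returned, not raised."""
    hits = sorted(
        (s for s in snps
         if s.chrom == region.chrom and region.start_bp <= s.pos_bp <= region.end_bp),
        key=lambda s: s.pos_bp,
    )
    if not hits:
        logger.info("select_region: no SNPs in %s:%d-%d",
                    region.chrom, region.start_bp, region.end_bp)
    return hits


# ---------------------------------------------------------------------------
# PED/MAP parsing


def _read_map(map_path: str | Path) -> list[tuple[str, str, int]]:
    entries = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValueError(f"{map_path}:{ln}: MAP line must have 4 columns")
            chrom, snp_id, _cm, bp = parts
            entries.append((chrom, snp_id, int(bp)))
    return entries


def read_ped_map(
    ped_path: str | Path, map_path: str | Path
) -> tuple[list[SnpRecord], list[TrioGenotypes]]:
    """Read a PED/MAP pair and assemble complete trios.

    The PED dialect is whitespace-delimited with six leading columns
    (family, individual, father, mother, sex, phenotype) followed by two
    allele columns per SNP; ``0`` encodes a missing allele.  Allele symbols
    per SNP are taken from the data (at most two, else a format error); the
    lexicographically smaller symbol becomes ``allele_a``.  A SNP with fewer
    than two observed symbols gets ``N`` as the placeholder second allele.
    """
    map_entries = _read_map(map_path)
    m = len(map_entries)
    ncol = 6 + 2 * m

    individuals: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != ncol:
                raise ValueError(
                    f"{ped_path}:{ln}: expected {ncol} columns for {m} SNPs, "
                    f"got {len(parts)}"
                )
            fid, iid, fa, mo, _sex, _phe = parts[:6]
            alleles = np.array(parts[6:], dtype=object).reshape(m, 2)
            key = (fid, iid)
            individuals[key] = {"father": fa, "mother": mo, "alleles": alleles}
            order.append(key)

    # Allele dictionary per SNP from observed symbols.
    symbols: list[set[str]] = [set() for _ in range(m)]
    for rec in individuals.values():
        for j in range(m):
            for a in rec["alleles"][j]:
                if a != _MISSING_SYMBOL:
                    symbols[j].add(a)
    snps: list[SnpRecord] = []
    for (chrom, snp_id, bp), obs in zip(map_entries, symbols):
        if len(obs) > 2:
            raise ValueError(f"SNP {snp_id}: more than 2 alleles observed: {sorted(obs)}")
        syms = sorted(obs)
        if len(syms) == 0:
            syms = ["N", "NN"]
        elif len(syms) == 1:
            syms = [syms[0], "N"]
        snps.append(SnpRecord(snp_id, chrom, bp, syms[0], syms[1]))

    code = [{s.allele_a: 0, s.allele_b: 1, _MISSING_SYMBOL: MISSING} for s in snps]

    def encode(alleles: np.ndarray) -> np.ndarray:
        g = np.empty((m, 2), dtype=np.int8)
        for j in range(m):
            g[j, 0] = code[j][alleles[j, 0]]
            g[j, 1] = code[j][alleles[j, 1]]
        return g

    # Assemble one complete trio per family, preserving file order.
    trios: list[TrioGenotypes] = []
    seen_fids: list[str] = []
    for fid, iid in order:
        rec = individuals[(fid, iid)]
        fa, mo = rec["father"], rec["mother"]
        if fa == "0" or mo == "0":
            continue  # a founder, not a child
        if fid in seen_fids:
            continue
        if (fid, fa) not in individuals or (fid, mo) not in individuals:
            logger.warning("family %s: parents of %s not in PED; family dropped",
                           fid, iid)
            continue
        g = np.stack([
            encode(individuals[(fid, fa)]["alleles"]),
            encode(individuals[(fid, mo)]["alleles"]),
            encode(rec["alleles"]),
        ])
        trios.append(TrioGenotypes(fid, g))
        seen_fids.append(fid)
    return snps, trios


def write_ped_map(
    snps: list[SnpRecord],
    trios: list[TrioGenotypes],
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write trios to ``<out_prefix>.ped`` / ``<out_prefix>.map``.

    Output is readable by :func:`read_ped_map` with a lossless round trip up
    to allele ordering within genotypes.  Children are written as affected
    (phenotype 2), parents as unaffected (1).
    """
    out_prefix = Path(out_prefix)
    ped_path = out_prefix.with_suffix(".ped")
    map_path = out_prefix.with_suffix(".map")
    symbols = [(s.allele_a, s.allele_b) for s in snps]

    def fmt(g: np.ndarray) -> str:
        cols = []
        for j, (a, b) in enumerate(symbols):
            lut = {0: a, 1: b, MISSING: _MISSING_SYMBOL}
            cols.append(f"{lut[int(g[j, 0])]} {lut[int(g[j, 1])]}")
        return " ".join(cols)

    with open(ped_path, "w") as fh:
        for t in trios:
            fid = t.family_id
            f_id, m_id, c_id = f"{fid}_f", f"{fid}_m", f"{fid}_c"
            fh.write(f"{fid} {f_id} 0 0 1 1 {fmt(t.genotypes[0])}\n")
            fh.write(f"{fid} {m_id} 0 0 2 1 {fmt(t.genotypes[1])}\n")
            fh.write(f"{fid} {c_id} {f_id} {m_id} 0 2 {fmt(t.genotypes[2])}\n")
    with open(map_path, "w") as fh:
        for s in snps:
            fh.write(f"{s.chrom} {s.snp_id} 0 {s.pos_bp}\n")
    return ped_path, map_path
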