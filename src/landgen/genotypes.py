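"""Haploid SNP genotype container and within/among-population statistics.

The central object is :class:`GenotypeMatrix`: haploid calls (one allele per
individual and locus, coded ``0..k-1``, ``-1`` = missing) plus a population
label per individual.  On top of it the module provides locus filtering,
per-population diversity summaries (percent polymorphic loci, mean observed
alleles, gene diversity), Weir & Cockerham pairwise F_ST from allele-frequency
variance components, and multilocus-genotype (clone) summaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "FstResult",
    "MlgSummary",
    "read_genotypes",
    "write_genotype_csv",
    "write_vcf",
    "locus_filter",
    "diversity_stats",
    "pairwise_fst",
    "multilocus_genotypes",
]


@dataclass
class GenotypeMatrix:
    """Haploid multilocus genotypes with population labels.

    Parameters
    ----------
    individuals : list of str
        Individual identifiers, one per row of ``calls``.
    populations : ndarray of str
        Population label per individual.
    loci : list of str
        Locus identifiers, one per column of ``calls``.
    calls : ndarray of int, shape (n_individuals, n_loci)
        Haploid allele codes ``0..k-1`` per locus; ``MISSING`` (-1) for
        no-calls.
    """

    individuals: list[str]
    populations: np.ndarray
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.populations = np.asarray(self.populations, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int16)
        n_ind, n_loc = self.calls.shape
        if len(self.individuals) != n_ind:
            raise ValueError("individuals/calls shape mismatch")
        if len(self.populations) != n_ind:
            raise ValueError("every individual needs exactly one population label")
        if len(self.loci) != n_loc:
            raise ValueError("loci/calls shape mismatch")
        if n_ind < 1 or n_loc < 1:
            raise ValueError("need at least one individual and one locus")
        if (self.calls < MISSING).any():
            raise ValueError("allele codes must be >= 0 (or -1 for missing)")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def population_ids(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        return list(dict.fromkeys(self.populations))

    def subset_populations(self, pops: list[str]) -> "GenotypeMatrix":
        keep = np.isin(self.populations, list(pops))
        if not keep.any():
            raise ValueError("no individuals left after population subset")
        return GenotypeMatrix(
            [i for i, k in zip(self.individuals, keep) if k],
            self.populations[keep],
            list(self.loci),
            self.calls[keep],
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_popmap(path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("population map needs two columns: individual,population")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_genotypes(path, fmt: str = "genotype-csv", popmap=None) -> GenotypeMatrix:
    """Read haploid genotypes from a CSV table or a haploid VCF.

    ``genotype-csv``: rows are individuals; the first two columns are the
    individual id and the population label, remaining columns are loci; empty
    cells are missing.  ``vcf-haploid``: single-allele GT fields ("0", "1",
    "."); REF/ALT order defines the allele coding; ``popmap`` (CSV
    individual,population) is required.
    """
    if fmt == "genotype-csv":
        df = pd.read_csv(path, dtype=str)
        if df.shape[0] == 0 or df.shape[1] < 3:
            raise ValueError(f"empty or malformed genotype table: {path}")
        individuals = df.iloc[:, 0].tolist()
        populations = df.iloc[:, 1].to_numpy(dtype=object)
        if popmap is not None:
            pm = _read_popmap(popmap)
            missing = [i for i in individuals if i not in pm]
            if missing:
                raise ValueError(f"individual(s) absent from population map: {missing}")
            populations = np.array([pm[i] for i in individuals], dtype=object)
        loci = df.columns[2:].tolist()
        calls = (
            df.iloc[:, 2:]
            .apply(pd.to_numeric, errors="raise")
            .fillna(MISSING)
            .to_numpy(dtype=np.int16)
        )
        return GenotypeMatrix(individuals, populations, loci, calls)
    if fmt == "vcf-haploid":
        return _read_vcf_haploid(path, popmap)
    raise ValueError(f"unknown genotype format: {fmt!r}")


def _read_vcf_haploid(path, popmap) -> GenotypeMatrix:
    import pysam

    if popmap is None:
        raise ValueError("vcf-haploid input requires a population map")
    pm = _read_popmap(popmap)
    vf = pysam.VariantFile(str(path))
    individuals = list(vf.header.samples)
    if not individuals:
        raise ValueError(f"VCF without samples: {path}")
    absent = [i for i in individuals if i not in pm]
    if absent:
        raise ValueError(f"individual(s) absent from population map: {absent}")
    loci: list[str] = []
    cols: list[np.ndarray] = []
    for k, rec in enumerate(vf):
        loci.append(rec.id or f"{rec.chrom}:{rec.pos}")
        col = np.full(len(individuals), MISSING, dtype=np.int16)
        for j, sample in enumerate(individuals):
            gt = rec.samples[sample]["GT"]
            alleles = [a for a in gt if a is not None]
            if len(gt) > 1:
                raise ValueError(
                    f"diploid GT at record {loci[-1]} sample {sample}: expected haploid calls"
                )
            if alleles:
                col[j] = alleles[0]
        cols.append(col)
    if not loci:
        raise ValueError(f"VCF without variant records: {path}")
    populations = np.array([pm[i] for i in individuals], dtype=object)
    return GenotypeMatrix(individuals, populations, loci, np.column_stack(cols))


def write_genotype_csv(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(gm.calls.astype(object), columns=gm.loci)
    df = df.mask(df == MISSING, other=pd.NA)
    df.insert(0, "population", gm.populations)
    df.insert(0, "individual", gm.individuals)
    df.to_csv(path, index=False)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write haploid calls as a minimal biallelic(+) VCF (text, uncompressed)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.individuals) + "\n")
        alphabet = "ACGT"
        for k, locus in enumerate(gm.loci):
            col = gm.calls[:, k]
            n_codes = int(col.max()) + 1 if (col >= 0).any() else 1
            n_codes = max(n_codes, 2)
            alt = ",".join(alphabet[1:n_codes])
            gts = "\t".join("." if c == MISSING else str(int(c)) for c in col)
            fh.write(f"1\t{k + 1}\t{locus}\tA\t{alt}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def locus_filter(
    gm: GenotypeMatrix,
    max_missing: float = 0.25,
    drop_monomorphic: bool = True,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop loci with too much missing data and (optionally) monomorphic loci.

    A locus is dropped when its missing fraction exceeds ``max_missing``
    (strictly), or when at most one distinct allele is observed across all
    individuals.  Returns the filtered matrix and a report of dropped loci
    with reasons; surviving locus order is preserved.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    n = gm.n_individuals
    dropped: list[tuple[str, str]] = []
    keep = np.ones(gm.n_loci, dtype=bool)
    for k in range(gm.n_loci):
        col = gm.calls[:, k]
        miss_frac = float((col == MISSING).sum()) / n
        if miss_frac > max_missing:
            keep[k] = False
            dropped.append((gm.loci[k], f"missing fraction {miss_frac:.3f} > {max_missing}"))
            continue
        if drop_monomorphic and len(np.unique(col[col != MISSING])) <= 1:
            keep[k] = False
            dropped.append((gm.loci[k], "monomorphic"))
    if not keep.any():
        raise ValueError("all loci removed by filter")
    report = pd.DataFrame(dropped, columns=["locus", "reason"])
    out = GenotypeMatrix(
        list(gm.individuals),
        gm.populations.copy(),
        [l for l, k in zip(gm.loci, keep) if k],
        gm.calls[:, keep],
    )
    return out, report


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def _allele_counts(calls: np.ndarray, n_alleles: int) -> np.ndarray:
    """Counts per (locus, allele) for a block of haploid calls."""
    n_loci = calls.shape[1]
    counts = np.zeros((n_loci, n_alleles), dtype=np.int64)
    for a in range(n_alleles):
        counts[:, a] = (calls == a).sum(axis=0)
    return counts


def diversity_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-population diversity summary.

    Returns a DataFrame indexed by population with columns ``n_ind``, ``PL``
    (percent of loci with >=2 observed alleles among loci with >=1 call),
    ``n_a`` (mean distinct observed alleles over *all* loci; a locus with no
    call in the population contributes 0, which is why n_a can fall below 1)
    and ``H_S`` (small-sample-corrected gene diversity ``n/(n-1)*(1-sum p^2)``
    averaged over loci with >=2 calls).
    """
    n_alleles = int(gm.calls.max()) + 1 if (gm.calls >= 0).any() else 1
    rows = []
    for pop in gm.population_ids:
        sel = gm.populations == pop
        if not sel.any():
            raise ValueError(f"population with zero individuals: {pop}")
        calls = gm.calls[sel]
        counts = _allele_counts(calls, n_alleles)
        n_obs = counts.sum(axis=1)                      # calls per locus
        k_obs = (counts > 0).sum(axis=1)                # distinct alleles per locus
        typed = n_obs >= 1
        pl = 100.0 * (k_obs >= 2).sum() / typed.sum() if typed.any() else 0.0
        na = float(k_obs.mean())
        multi = n_obs >= 2
        if multi.any():
            n = n_obs[multi].astype(float)
            p = counts[multi] / n[:, None]
            hs_loc = n / (n - 1.0) * (1.0 - (p**2).sum(axis=1))
            hs = float(hs_loc.mean())
        else:
            hs = 0.0
        rows.append((pop, int(sel.sum()), pl, na, hs))
    return pd.DataFrame(rows, columns=["population", "n_ind", "PL", "n_a", "H_S"]).set_index(
        "population"
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham pairwise F_ST
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    """Pairwise multilocus theta (F_ST) matrix with summary statistics.

    ``matrix`` is symmetric over populations with NaN diagonal; a cell is NaN
    when a pair has no informative locus.  ``mean``/``sd`` summarize the
    non-NaN off-diagonal values (each unordered pair counted once).
    """

    matrix: pd.DataFrame
    mean: float
    sd: float

    def long(self) -> pd.DataFrame:
        """One row per unordered pair: pop_i, pop_j, fst."""
        pops = list(self.matrix.index)
        rows = [
            (pops[i], pops[j], self.matrix.iat[i, j])
            for i, j in itertools.combinations(range(len(pops)), 2)
        ]
        return pd.DataFrame(rows, columns=["pop_i", "pop_j", "fst"])


def _pair_theta_terms(
    counts_1: np.ndarray, counts_2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Variance components (a, a+b) per (locus, allele) for one pair.

    Implements the two-population haploid Weir-Cockerham ANOVA: with sample
    sizes n_i and allele frequencies p_i,

        MSP = sum_i n_i (p_i - p_bar)^2 / (r - 1)
        MSG = sum_i n_i p_i (1 - p_i) / sum_i (n_i - 1)
        n_c = (sum n_i - sum n_i^2 / sum n_i) / (r - 1)
        a = (MSP - MSG) / n_c,   b = MSG

    Loci are informative when both populations have >=1 call and the pooled
    within-population degrees of freedom sum_i (n_i - 1) are positive.
    """
    n1 = counts_1.sum(axis=1).astype(float)
    n2 = counts_2.sum(axis=1).astype(float)
    ok = (n1 >= 1) & (n2 >= 1) & (n1 + n2 - 2 > 0)
    if not ok.any():
        return np.zeros((0,)), np.zeros((0,))
    n1, n2 = n1[ok], n2[ok]
    c1, c2 = counts_1[ok].astype(float), counts_2[ok].astype(float)
    p1 = c1 / n1[:, None]
    p2 = c2 / n2[:, None]
    ntot = n1 + n2
    pbar = (c1 + c2) / ntot[:, None]
    msp = n1[:, None] * (p1 - pbar) ** 2 + n2[:, None] * (p2 - pbar) ** 2  # r-1 = 1
    msg = (n1[:, None] * p1 * (1 - p1) + n2[:, None] * p2 * (1 - p2)) / (ntot - 2)[:, None]
    nc = ntot - (n1**2 + n2**2) / ntot
    a = (msp - msg) / nc[:, None]
    return a.ravel(), (a + msg).ravel()


def pairwise_fst(gm: GenotypeMatrix) -> FstResult:
    """Multilocus Weir-Cockerham theta for every population pair.

    theta = sum(a) / sum(a+b) over all informative (locus, allele) cells;
    negative estimates are kept unclamped and pairs without informative loci
    are NaN.
    """
    pops = gm.population_ids
    if len(pops) < 2:
        raise ValueError("pairwise F_ST needs at least two populations")
    n_alleles = int(gm.calls.max()) + 1 if (gm.calls >= 0).any() else 1
    counts = {
        pop: _allele_counts(gm.calls[gm.populations == pop], n_alleles) for pop in pops
    }
    mat = np.full((len(pops), len(pops)), np.nan)
    for i, j in itertools.combinations(range(len(pops)), 2):
        a, ab = _pair_theta_terms(counts[pops[i]], counts[pops[j]])
        denom = ab.sum()
        if denom != 0.0:
            mat[i, j] = mat[j, i] = a.sum() / denom
    off = mat[np.triu_indices(len(pops), k=1)]
    off = off[~np.isnan(off)]
    mean = float(off.mean()) if off.size else float("nan")
    sd = float(off.std(ddof=1)) if off.size > 1 else float("nan")
    return FstResult(pd.DataFrame(mat, index=pops, columns=pops), mean, sd)


# ---------------------------------------------------------------------------
# Multilocus genotypes
# ---------------------------------------------------------------------------

@dataclass
class MlgSummary:
    """Non-redundant multilocus genotype (MLG) summary.

    Two individuals share an MLG iff their call vectors are identical at every
    locus, with missing treated as a state of its own.
    """

    n_mlg: int
    mlg_of_individual: dict[str, int]
    shared_across_populations: int
    mean_pairwise_diff: float
    counts: pd.Series = field(repr=False, default=None)


def multilocus_genotypes(gm: GenotypeMatrix) -> MlgSummary:
    """Identify non-redundant multilocus genotypes and their dissimilarity.

    ``mean_pairwise_diff`` averages, over all unordered pairs of *distinct*
    MLGs, the proportion of pairwise-complete loci (both calls non-missing)
    at which the two vectors differ; NaN when fewer than two MLGs or no pair
    has a complete locus.
    """
    uniq, inverse = np.unique(gm.calls, axis=0, return_inverse=True)
    n_mlg = uniq.shape[0]
    mlg_of = {ind: int(m) for ind, m in zip(gm.individuals, inverse)}
    shared = 0
    for m in range(n_mlg):
        if len(set(gm.populations[inverse == m])) >= 2:
            shared += 1
    obs = uniq != MISSING
    diffs: list[float] = []
    # chunk the pair enumeration so study-scale inputs stay in memory
    for i in range(n_mlg - 1):
        both = obs[i] & obs[i + 1 :]
        denom = both.sum(axis=1)
        ndiff = ((uniq[i] != uniq[i + 1 :]) & both).sum(axis=1)
        ok = denom > 0
        diffs.extend((ndiff[ok] / denom[ok]).tolist())
    mpd = float(np.mean(diffs)) if diffs else float("nan")
    counts = pd.Series(inverse).value_counts().sort_index()
    return MlgSummary(n_mlg, mlg_of, shared, mpd, counts)
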