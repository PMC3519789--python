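"""Tandemly arrayed genes, family dispersion, and duplicate-pair statistics.

A tandem array (TAG) is a maximal chain of same-family loci on one
chromosome with consecutive gaps <= 5 cM; arrays whose gaps are all
<= 1 cM form the tighter "1cM" class.  Family dispersion over
chromosomes is tested by permutation: family labels are redistributed
over the fixed set of mapped positions and the number of chromosomes
occupied per family is re-counted.  Duplicate gene pairs carrying an age
label (ancient = predating the gymnosperm-angiosperm split, recent =
postdating it) are summarised by same-chromosome vs translocated counts,
a chi-square against equal expectation, and a Welch t comparison of the
same-chromosome distances of the two age classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .map import GeneLocus, GeneticMap


@dataclass
class TagArray:
    family_id: str
    chromosome: str
    loci: list[GeneLocus]
    window_class: str  # "1cM" | "5cM"

    @property
    def span(self) -> float:
        pos = [l.position for l in self.loci]
        return max(pos) - min(pos)

    @property
    def size(self) -> int:
        return len(self.loci)


def detect_tags(gmap: GeneticMap, w_inner: float = 1.0, w_outer: float = 5.0) -> list[TagArray]:
    """Detect tandem arrays per family x chromosome.

    Single-linkage chaining with a gap cap: loci sorted by position are
    chained while consecutive gaps are <= ``w_outer``; chains of >= 2
    members become arrays.  An array is class "1cM" iff *all* its
    consecutive gaps are <= ``w_inner``, else "5cM".
    """
    if w_inner > w_outer:
        raise ValueError("w_inner must be <= w_outer")
    arrays: list[TagArray] = []
    for fam, members in sorted(gmap.by_family().items()):
        by_chrom: dict[str, list[GeneLocus]] = {}
        for l in members:
            by_chrom.setdefault(l.chromosome, []).append(l)
        for chrom in sorted(by_chrom):
            loci = sorted(by_chrom[chrom], key=lambda l: (l.position, l.locus_id))
            chain = [loci[0]]
            for l in loci[1:]:
                if l.position - chain[-1].position <= w_outer:
                    chain.append(l)
                else:
                    _emit(arrays, fam, chrom, chain, w_inner)
                    chain = [l]
            _emit(arrays, fam, chrom, chain, w_inner)
    return arrays


def _emit(arrays: list[TagArray], fam: str, chrom: str, chain: list[GeneLocus],
          w_inner: float) -> None:
    if len(chain) < 2:
        return
    gaps = [b.position - a.position for a, b in zip(chain, chain[1:])]
    cls = "1cM" if all(g <= w_inner for g in gaps) else "5cM"
    arrays.append(TagArray(fam, chrom, list(chain), cls))


# ---------------------------------------------------------------------
# Family dispersion permutation test
# ---------------------------------------------------------------------

@dataclass
class DispersionTestResult:
    observed: np.ndarray          # families occupying exactly k chromosomes, k=1..C
    simulated_mean: np.ndarray    # mean simulated counts per category
    chi_square: float
    df: int
    p_value: float
    replicates: int
    family_ids: list[str]
    family_observed: dict[str, int]      # observed chromosome count per family
    family_p: dict[str, float]           # empirical P(sim count <= observed)
    flagged: list[str] = field(default_factory=list)  # clustered at p <= 0.05


def permute_family_dispersion(
    gmap: GeneticMap,
    R: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    min_family_size: int = 2,
) -> DispersionTestResult:
    """Permutation test of gene-family clustering onto chromosomes.

    Families with >= ``min_family_size`` mapped members are considered
    (default 2: singletons trivially occupy one chromosome and carry no
    clustering signal, but they may be included with 1).  Observed: for
    each family, the number of distinct chromosomes its members occupy;
    these are tabulated into categories k = 1..C.  Null: family labels
    are randomly reassigned over the fixed set of mapped loci each
    replicate and the tabulation repeated.  chi-square compares observed
    category counts to the mean simulated counts (categories whose
    simulated expectation is < 1 are pooled upward); df = C - 1.  Each
    family also gets an empirical p = fraction of replicates in which a
    random family of its size occupies as few or fewer chromosomes;
    families at p <= alpha are flagged as clustered.
    """
    if R < 100:
        raise ValueError("R must be >= 100")
    rng = np.random.default_rng(seed)
    fams = {f: loci for f, loci in gmap.by_family().items()
            if len(loci) >= min_family_size}
    if not fams:
        raise ValueError(f"no family with >= {min_family_size} mapped members")
    C = len(gmap.lengths)
    chrom_index = {c: i for i, c in enumerate(gmap.chromosomes)}
    member_chroms = np.array([chrom_index[l.chromosome] for l in gmap.loci])
    fam_ids = sorted(fams)
    sizes = np.array([len(fams[f]) for f in fam_ids])

    def count_chromosomes(assigned: np.ndarray) -> np.ndarray:
        # assigned: chromosome index per member, concatenated by family
        out = np.empty(len(fam_ids), dtype=int)
        start = 0
        for i, s in enumerate(sizes):
            out[i] = len(np.unique(assigned[start:start + s]))
            start += s
        return out

    obs_per_family = np.array(
        [len({l.chromosome for l in fams[f]}) for f in fam_ids]
    )
    observed = np.bincount(obs_per_family, minlength=C + 1)[1:]

    n_members = int(sizes.sum())
    sim_counts = np.zeros((R, C), dtype=float)
    sim_le = np.zeros(len(fam_ids), dtype=int)
    for r in range(R):
        # redistribute the family members over the mapped positions
        idx = rng.choice(len(member_chroms), size=n_members, replace=False)
        per_fam = count_chromosomes(member_chroms[idx])
        sim_counts[r] = np.bincount(per_fam, minlength=C + 1)[1:]
        sim_le += per_fam <= obs_per_family

    sim_mean = sim_counts.mean(axis=0)
    chi2 = _pooled_chisq(observed.astype(float), sim_mean)
    df = C - 1
    p = float(stats.chi2.sf(chi2, df))
    fam_p = {f: float(v) / R for f, v in zip(fam_ids, sim_le)}
    flagged = [f for f in fam_ids if fam_p[f] <= alpha]
    return DispersionTestResult(
        observed=observed, simulated_mean=sim_mean, chi_square=chi2, df=df,
        p_value=p, replicates=R, family_ids=fam_ids,
        family_observed=dict(zip(fam_ids, obs_per_family.tolist())),
        family_p=fam_p, flagged=flagged,
    )


def _pooled_chisq(observed: np.ndarray, expected: np.ndarray) -> float:
    """Pearson chi-square with categories of expectation < 1 pooled upward."""
    obs, exp = [], []
    o_acc = e_acc = 0.0
    # pool from the high-k tail downward so small categories merge upward
    for o, e in zip(observed[::-1], expected[::-1]):
        o_acc += o
        e_acc += e
        if e_acc >= 1.0:
            obs.append(o_acc)
            exp.append(e_acc)
            o_acc = e_acc = 0.0
    if e_acc > 0:
        if exp:
            obs[-1] += o_acc
            exp[-1] += e_acc
        else:
            obs.append(o_acc)
            exp.append(e_acc)
    obs_a, exp_a = np.array(obs), np.array(exp)
    mask = exp_a > 0
    return float(np.sum((obs_a[mask] - exp_a[mask]) ** 2 / exp_a[mask]))


# ---------------------------------------------------------------------
# Chi-square against equal expectation; duplicate distance statistics
# ---------------------------------------------------------------------

def equal_expected_chisq(counts: Sequence[float]) -> float:
    """Pearson chi-square of observed counts against equal expected frequencies."""
    c = np.asarray(counts, dtype=float)
    if c.size < 2:
        raise ValueError("need >= 2 categories")
    total = c.sum()
    if total <= 0:
        raise ValueError("total count must be > 0")
    expected = total / c.size
    return float(np.sum((c - expected) ** 2 / expected))


@dataclass(frozen=True)
class ClassifiedPair:
    """A duplicate gene pair with an age label and its two map positions."""

    family_id: str
    gene_a: str
    gene_b: str
    chrom_a: str
    pos_a: float
    chrom_b: str
    pos_b: float
    age: str  # "ancient" | "recent" | other labels pass through untested

    @property
    def same_chromosome(self) -> bool:
        return self.chrom_a == self.chrom_b

    @property
    def distance(self) -> float | None:
        return abs(self.pos_a - self.pos_b) if self.same_chromosome else None


@dataclass
class TranslocationStats:
    counts: dict[str, tuple[int, int]]        # age -> (same_chromosome, translocated)
    chi_square: dict[str, float]              # age -> chi2 vs 50:50
    chi_p: dict[str, float]
    distances: dict[str, list[float]]         # age -> same-chromosome distances
    mean_distance: dict[str, float]
    welch_t: float | None                     # recent vs ancient distance means
    welch_df: float | None
    welch_p: float | None


def duplicate_distance_stats(
    pairs: Sequence[ClassifiedPair],
    classes: tuple[str, str] = ("recent", "ancient"),
) -> TranslocationStats:
    """Translocation counts and same-chromosome distance statistics per age class.

    The Welch two-sample t (unequal variances, Welch-Satterthwaite df)
    compares the same-chromosome distances of ``classes[0]`` against
    ``classes[1]``; with fewer than 2 distances in either class the t is
    reported as not testable (None).
    """
    counts, chi2, chip, dists, means = {}, {}, {}, {}, {}
    for age in classes:
        sub = [p for p in pairs if p.age == age]
        same = [p for p in sub if p.same_chromosome]
        counts[age] = (len(same), len(sub) - len(same))
        if sub:
            chi2[age] = equal_expected_chisq(counts[age])
            chip[age] = float(stats.chi2.sf(chi2[age], 1))
        else:
            chi2[age] = float("nan")
            chip[age] = float("nan")
        d = [p.distance for p in same]
        dists[age] = d
        means[age] = float(np.mean(d)) if d else float("nan")
    a, b = dists[classes[0]], dists[classes[1]]
    if len(a) >= 2 and len(b) >= 2:
        res = stats.ttest_ind(a, b, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    else:
        t = p = df = None
    return TranslocationStats(counts, chi2, chip, dists, means, t, df, p)
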