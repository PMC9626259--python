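"""Individual identification from multilocus genotypes, and sex-ratio inference.

Biopsy samples are resolved to individuals by exact genotype matching:
two samples are the same whale when they agree at every mutually typed locus
and at least ``min_match_loci`` loci were compared. Samples typed at fewer
than ``min_typed_loci`` loci are excluded. Locus-level summaries (number of
alleles K, observed/expected heterozygosity, probability of identity) follow
the standard population-genetics definitions, and sex ratios are tested
against parity with central two-tailed exact binomial tests plus
Clopper–Pearson confidence limits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import binom

MISSING = None


@dataclass
class GenotypeProfile:
    """One biopsy sample: sex-marker call plus per-locus allele pairs.

    Allele pairs are stored sorted within locus; a missing locus is ``None``.
    """

    sample_id: str
    date: pd.Timestamp | None
    sex_call: str                       # "M", "F" or "U"
    genotype: list                      # per-locus (a, b) tuple or None

    def typed_loci(self) -> np.ndarray:
        return np.array([g is not None for g in self.genotype])

    @property
    def n_typed(self) -> int:
        return int(self.typed_loci().sum())


def profiles_from_frame(df: pd.DataFrame, locus_names: list[str] | None = None) -> list[GenotypeProfile]:
    """Build profiles from a genotype table with ``<locus>_a``/``<locus>_b`` columns."""
    if locus_names is None:
        locus_names = [c[:-2] for c in df.columns if c.endswith("_a")
                       and f"{c[:-2]}_b" in df.columns]
    profiles = []
    for _, row in df.iterrows():
        genotype = []
        for name in locus_names:
            a, b = row[f"{name}_a"], row[f"{name}_b"]
            if pd.isna(a) or pd.isna(b):
                genotype.append(None)
            else:
                genotype.append(tuple(sorted((int(a), int(b)))))
        date = pd.to_datetime(row["date"]) if "date" in row and pd.notna(row.get("date")) else None
        profiles.append(GenotypeProfile(
            sample_id=str(row["sample_id"]),
            date=date,
            sex_call=str(row.get("sex_marker", "U")),
            genotype=genotype,
        ))
    return profiles


@dataclass
class LocusStats:
    locus_name: str
    K: int
    H_O: float
    H_E: float                 # unbiased (2n/(2n-1)) correction
    H_E_uncorrected: float
    P_ID: float
    n_typed: int


def locus_statistics(profiles: list[GenotypeProfile],
                     locus_names: list[str] | None = None) -> list[LocusStats]:
    """Per-locus K, H_O, H_E and probability of identity.

    P_ID = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2, the probability that two
    random Hardy–Weinberg individuals share a genotype at the locus.
    H_E carries the small-sample 2n/(2n-1) correction.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    n_loci = len(profiles[0].genotype)
    if locus_names is None:
        locus_names = [f"locus{i + 1}" for i in range(n_loci)]
    out = []
    for li in range(n_loci):
        pairs = [p.genotype[li] for p in profiles if p.genotype[li] is not None]
        if not pairs:
            raise ValueError(f"locus {locus_names[li]} has no typed individuals")
        n = len(pairs)
        alleles = np.array([a for pair in pairs for a in pair])
        uniq, counts = np.unique(alleles, return_counts=True)
        freqs = counts / counts.sum()
        h_o = float(np.mean([a != b for a, b in pairs]))
        h_e_raw = float(1.0 - np.sum(freqs ** 2))
        h_e = float(2 * n / (2 * n - 1) * h_e_raw) if n > 1 else h_e_raw
        p_id = float(np.sum(freqs ** 4)
                     + sum((2 * freqs[i] * freqs[j]) ** 2
                           for i in range(len(freqs)) for j in range(i + 1, len(freqs))))
        out.append(LocusStats(locus_name=locus_names[li], K=len(uniq), H_O=h_o,
                              H_E=h_e, H_E_uncorrected=h_e_raw, P_ID=p_id, n_typed=n))
    return out


def pid_from_frequencies(freqs: np.ndarray) -> float:
    """Probability of identity from population allele frequencies."""
    f = np.asarray(freqs, dtype=float)
    if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must form a simplex")
    hom = np.sum(f ** 4)
    het = sum((2 * f[i] * f[j]) ** 2
              for i in range(len(f)) for j in range(i + 1, len(f)))
    return float(hom + het)


@dataclass
class CombinedPID:
    subset_size: int
    min: float
    max: float
    mean: float


def combined_pid(pids, subset_size: int) -> CombinedPID:
    """Range and mean of the product of per-locus P_ID over all locus subsets
    of the given size (loci treated as independent)."""
    vals = [s.P_ID if isinstance(s, LocusStats) else float(s) for s in pids]
    if not 1 <= subset_size <= len(vals):
        raise ValueError("subset_size must be in [1, n_loci]")
    products = [float(np.prod(c)) for c in itertools.combinations(vals, subset_size)]
    return CombinedPID(subset_size=subset_size, min=min(products),
                       max=max(products), mean=float(np.mean(products)))


@dataclass
class IdentityCluster:
    individual_id: str
    sample_ids: list
    dates: list
    consensus_sex: str            # "M"/"F"/"U"; "conflict" when members disagree
    sex_conflict: bool
    min_loci_compared: int


@dataclass
class MatchResult:
    clusters: list
    excluded: list                # sample_ids with too few typed loci
    near_matches: list            # (id_a, id_b, n_compared) pairs with exactly 1 mismatch


def _compare(a: GenotypeProfile, b: GenotypeProfile) -> tuple[int, int]:
    """(number of mutually typed loci, mismatches among them)."""
    compared = mismatch = 0
    for ga, gb in zip(a.genotype, b.genotype):
        if ga is not None and gb is not None:
            compared += 1
            mismatch += ga != gb
    return compared, mismatch


def match_genotypes(profiles: list[GenotypeProfile],
                    min_match_loci: int = 7,
                    min_typed_loci: int = 7) -> MatchResult:
    """Cluster samples into individuals by transitive closure of exact matches.

    A pairwise match requires zero mismatches at mutually typed loci and at
    least ``min_match_loci`` loci compared. Pairs with exactly one mismatch
    are reported as near-matches for QC, never merged. Clusters whose members
    carry conflicting sex calls are flagged rather than silently merged.
    """
    usable = [p for p in profiles if p.n_typed >= min_typed_loci]
    excluded = [p.sample_id for p in profiles if p.n_typed < min_typed_loci]
    parent = list(range(len(usable)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    near = []
    pair_min_compared: dict = {}
    for i, j in itertools.combinations(range(len(usable)), 2):
        compared, mism = _compare(usable[i], usable[j])
        if compared >= min_match_loci and mism == 0:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
            pair_min_compared[(i, j)] = compared
        elif compared >= min_match_loci and mism == 1:
            near.append((usable[i].sample_id, usable[j].sample_id, compared))

    groups: dict = {}
    for i in range(len(usable)):
        groups.setdefault(find(i), []).append(i)
    clusters = []
    # deterministic ordering: by first sample id in each group
    for k, members in enumerate(sorted(groups.values(),
                                       key=lambda m: usable[m[0]].sample_id)):
        sexes = {usable[i].sex_call for i in members} - {"U"}
        conflict = len(sexes) > 1
        consensus = ("conflict" if conflict
                     else (sexes.pop() if sexes else "U"))
        compared = [pair_min_compared.get((min(i, j), max(i, j)))
                    for i, j in itertools.combinations(members, 2)]
        compared = [c for c in compared if c is not None]
        clusters.append(IdentityCluster(
            individual_id=f"I{k:04d}",
            sample_ids=[usable[i].sample_id for i in members],
            dates=[usable[i].date for i in members],
            consensus_sex=consensus,
            sex_conflict=conflict,
            min_loci_compared=min(compared) if compared else usable[members[0]].n_typed,
        ))
    return MatchResult(clusters=clusters, excluded=excluded, near_matches=near)


def exact_binomial_test(k: int, n: int, p0: float = 0.5) -> float:
    """Central two-tailed exact binomial p-value: min(1, 2*min(lower, upper tail))."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n and n >= 1")
    lower = binom.cdf(k, n, p0)
    upper = binom.sf(k - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def binomial_confidence_limits(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson exact limits for a binomial proportion, as fractions."""
    if not 0 < conf < 1:
        raise ValueError("conf must lie in (0, 1)")
    if n < 1 or not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n and n >= 1")
    a = (1.0 - conf) / 2.0
    lo = 0.0 if k == 0 else float(beta_dist.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1.0 - a, k + 1, n - k))
    return lo, hi


@dataclass
class SexTally:
    stratum: str
    n_males: int
    n_females: int
    ratio_MF: float               # nan when no females
    binomial_p: float             # nan when empty
    male_fraction: float
    male_cl: tuple
    female_fraction: float
    female_cl: tuple


def _tally(stratum: str, n_m: int, n_f: int, conf: float) -> SexTally:
    n = n_m + n_f
    if n == 0:
        return SexTally(stratum, 0, 0, float("nan"), float("nan"),
                        float("nan"), (float("nan"), float("nan")),
                        float("nan"), (float("nan"), float("nan")))
    return SexTally(
        stratum=stratum, n_males=n_m, n_females=n_f,
        ratio_MF=n_m / n_f if n_f else float("nan"),
        binomial_p=exact_binomial_test(n_m, n),
        male_fraction=n_m / n,
        male_cl=binomial_confidence_limits(n_m, n, conf),
        female_fraction=n_f / n,
        female_cl=binomial_confidence_limits(n_f, n, conf),
    )


def sex_ratio_report(clusters: list[IdentityCluster], conf: float = 0.95) -> list[SexTally]:
    """Per-year and total sex tallies over resolved individuals.

    An individual contributes once per year in which it was sampled (within-
    year replicates collapse to the individual) and once to the total row.
    Clusters with unknown or conflicting sex are omitted from the tallies.
    """
    sexed = [c for c in clusters if c.consensus_sex in ("M", "F")]
    years = sorted({d.year for c in sexed for d in c.dates if d is not None})
    out = []
    for y in years:
        in_year = [c for c in sexed if any(d is not None and d.year == y for d in c.dates)]
        n_m = sum(c.consensus_sex == "M" for c in in_year)
        n_f = sum(c.consensus_sex == "F" for c in in_year)
        out.append(_tally(str(y), n_m, n_f, conf))
    n_m = sum(c.consensus_sex == "M" for c in sexed)
    n_f = sum(c.consensus_sex == "F" for c in sexed)
    out.append(_tally("total", n_m, n_f, conf))
    return out


def locus_stats_frame(stats: list[LocusStats]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in stats])


def sex_tally_frame(tallies: list[SexTally]) -> pd.DataFrame:
    rows = []
    for t in tallies:
        rows.append({
            "stratum": t.stratum, "n_males": t.n_males, "n_females": t.n_females,
            "ratio_MF": t.ratio_MF, "binomial_p": t.binomial_p,
            "male_pct": 100 * t.male_fraction,
            "male_cl_lo_pct": 100 * t.male_cl[0], "male_cl_hi_pct": 100 * t.male_cl[1],
            "female_pct": 100 * t.female_fraction,
            "female_cl_lo_pct": 100 * t.female_cl[0],
            "female_cl_hi_pct": 100 * t.female_cl[1],
        })
    return pd.DataFrame(rows)
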