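"""Population-genetic statistics on control-region variant profiles.

Implements the haplotype-level statistics used in mtDNA phylogeography:
Nei's haplotype diversity, nucleotide diversity, pairwise Phi_ST from a
two-population AMOVA on Hamming distances, island-model gene-flow
estimates (Nm), hierarchical AMOVA with permutation tests, and Pearson
chi-squared cohort tests on haplogroup counts.

The AMOVA follows the classical hierarchical sums-of-squares
decomposition on pairwise distances: total variance is partitioned
among groups of populations (sigma_a, tested by Phi_CT), among
populations within groups (sigma_b, Phi_SC) and within populations
(sigma_c); Phi_ST = (sigma_a + sigma_b) / total.  The squared
inter-individual distance is the plain count of mismatching variant
labels, i.e. the "number of differences" metric, matching the distance
the haplotype network uses.  Significance comes from permutation: whole
populations are shuffled across groups for Phi_CT, individuals across
populations within groups for Phi_SC, and individuals across all
populations for Phi_ST; P is the proportion of permuted statistics at
least as large as the observed one.

For a maternally inherited haploid marker the island model gives
Phi_ST = 1 / (2 Nm + 1), hence Nm = (1 - Phi_ST) / (2 Phi_ST).  Note
that published Nm tables may rest on a different convention (e.g. the
diploid 4Nm form); the formula used here is the standard one for mtDNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .window import HaplotypeProfile, hamming_distance

_EPS = 1e-12


@dataclass
class PopulationSample:
    population: str
    profiles: list[HaplotypeProfile]

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError(f"population {self.population!r} has no profiles")

    @property
    def n(self) -> int:
        return len(self.profiles)


def haplotype_diversity(pop: PopulationSample) -> float:
    """Nei's unbiased haplotype diversity h = n/(n-1) * (1 - sum p_i^2)."""
    n = pop.n
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    counts: dict[str, int] = {}
    for p in pop.profiles:
        key = p.canonical_key
        counts[key] = counts.get(key, 0) + 1
    sum_p2 = sum((c / n) ** 2 for c in counts.values())
    return n / (n - 1) * (1.0 - sum_p2)


def nucleotide_diversity(pop: PopulationSample, window_length: int) -> float:
    """Mean pairwise Hamming distance per site over all unordered pairs."""
    n = pop.n
    if n < 2:
        raise ValueError("nucleotide diversity needs n >= 2")
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += hamming_distance(pop.profiles[i], pop.profiles[j])
    n_pairs = n * (n - 1) // 2
    return total / n_pairs / window_length


def distance_matrix(profiles: list[HaplotypeProfile]) -> np.ndarray:
    """Symmetric matrix of pairwise Hamming distances."""
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = hamming_distance(profiles[i], profiles[j])
    return d


def _pair_sums(d: np.ndarray, assignment: np.ndarray, n_pops: int) -> np.ndarray:
    """M[p, q] = sum of d over individuals of populations p and q (full)."""
    one_hot = np.zeros((d.shape[0], n_pops))
    one_hot[np.arange(d.shape[0]), assignment] = 1.0
    return one_hot.T @ d @ one_hot


def _two_level(m: np.ndarray, pop_sizes: np.ndarray) -> tuple[float, float]:
    """(sigma_among, sigma_within) of a flat populations-only AMOVA."""
    n_total = int(pop_sizes.sum())
    n_pops = len(pop_sizes)
    ssd_total = m.sum() / 2.0 / n_total
    ssd_wp = float(np.sum(np.diag(m) / 2.0 / pop_sizes))
    ssd_ap = ssd_total - ssd_wp
    df_wp = n_total - n_pops
    sigma_w = ssd_wp / df_wp if df_wp > 0 else 0.0
    n_coef = (n_total - float(np.sum(pop_sizes**2)) / n_total) / (n_pops - 1)
    sigma_a = (ssd_ap / (n_pops - 1) - sigma_w) / n_coef
    return sigma_a, sigma_w


def pairwise_phist(pop_a: PopulationSample, pop_b: PopulationSample) -> float:
    """Phi_ST between two populations from their AMOVA variance components.

    Negative values (within-variance exceeding among-variance) are
    reported as computed.  Identical monomorphic populations give 0.
    """
    if pop_a.n < 2 or pop_b.n < 2:
        raise ValueError("pairwise Phi_ST needs n >= 2 in both populations")
    profiles = pop_a.profiles + pop_b.profiles
    assignment = np.array([0] * pop_a.n + [1] * pop_b.n)
    d = distance_matrix(profiles)
    m = _pair_sums(d, assignment, 2)
    sigma_a, sigma_w = _two_level(m, np.array([pop_a.n, pop_b.n], dtype=float))
    total = sigma_a + sigma_w
    if abs(total) < _EPS:
        return 0.0
    return sigma_a / total


def nm_from_phist(phi_st: float) -> float:
    """Island-model gene flow for a haploid maternal marker.

    Nm = (1 - Phi_ST) / (2 Phi_ST); a non-positive Phi_ST means no
    detectable differentiation and the estimate diverges to infinity.
    """
    if phi_st > 1:
        raise ValueError("Phi_ST cannot exceed 1")
    if phi_st <= 0:
        return math.inf
    return (1.0 - phi_st) / (2.0 * phi_st)


@dataclass
class AMOVAResult:
    """Hierarchical variance components with permutation P-values.

    ``components`` holds the raw (possibly negative) variance estimates;
    ``percentages`` are computed from the raw values and sum to 100;
    ``display_percentages`` clip negative components to zero for
    presentation.
    """

    components: dict[str, float]
    percentages: dict[str, float]
    display_percentages: dict[str, float]
    phi_statistics: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int
    seed: int
    sums_of_squares: dict[str, float] = field(default_factory=dict)
    degrees_of_freedom: dict[str, int] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "components": self.components,
            "percentages": self.percentages,
            "display_percentages": self.display_percentages,
            "phi_statistics": self.phi_statistics,
            "p_values": self.p_values,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "sums_of_squares": self.sums_of_squares,
            "degrees_of_freedom": self.degrees_of_freedom,
        }

    def to_text(self) -> str:
        lines = ["AMOVA (pairwise-difference distances)"]
        for name in ("among_groups", "among_pops_within_groups", "within_pops"):
            pct = self.display_percentages[name]
            p = self.p_values.get(name)
            p_str = f"  P = {p:.4f}" if p is not None else ""
            lines.append(f"  {name:<26s} {self.components[name]: .5f}  ({pct:6.2f}%){p_str}")
        phi = self.phi_statistics
        lines.append(f"  Phi_CT = {phi['phi_ct']:.5f}  Phi_SC = {phi['phi_sc']:.5f}  "
                     f"Phi_ST = {phi['phi_st']:.5f}")
        lines.append(f"  permutations = {self.n_permutations}, seed = {self.seed}")
        return "\n".join(lines)


def _hierarchical(m: np.ndarray, pop_sizes: np.ndarray,
                  group_of_pop: np.ndarray) -> dict[str, float]:
    """Variance components and Phi statistics of a two-tier hierarchy."""
    n_total = float(pop_sizes.sum())
    n_pops = len(pop_sizes)
    groups = np.unique(group_of_pop)
    n_groups = len(groups)

    ssd_total = m.sum() / 2.0 / n_total
    ssd_wp = float(np.sum(np.diag(m) / 2.0 / pop_sizes))
    ssd_wg = 0.0
    sum_npsq_over_ng = 0.0
    sum_ngsq = 0.0
    for g in groups:
        sel = group_of_pop == g
        n_g = float(pop_sizes[sel].sum())
        ssd_wg += m[np.ix_(sel, sel)].sum() / 2.0 / n_g
        sum_npsq_over_ng += float(np.sum(pop_sizes[sel] ** 2)) / n_g
        sum_ngsq += n_g**2
    ssd_ag = ssd_total - ssd_wg
    ssd_apwg = ssd_wg - ssd_wp

    df_ag = n_groups - 1
    df_apwg = n_pops - n_groups
    df_wp = int(n_total) - n_pops

    sigma_c = ssd_wp / df_wp if df_wp > 0 else 0.0
    n_coef = ((n_total - sum_npsq_over_ng) / df_apwg) if df_apwg > 0 else 1.0
    sigma_b = ((ssd_apwg / df_apwg - sigma_c) / n_coef) if df_apwg > 0 else 0.0
    sum_npsq = float(np.sum(pop_sizes**2))
    n_prime = (sum_npsq_over_ng - sum_npsq / n_total) / df_ag
    n_dprime = (n_total - sum_ngsq / n_total) / df_ag
    sigma_a = (ssd_ag / df_ag - sigma_c - n_prime * sigma_b) / n_dprime

    total = sigma_a + sigma_b + sigma_c
    phi_ct = sigma_a / total if abs(total) > _EPS else 0.0
    phi_st = (sigma_a + sigma_b) / total if abs(total) > _EPS else 0.0
    bc = sigma_b + sigma_c
    phi_sc = sigma_b / bc if abs(bc) > _EPS else 0.0
    return {
        "sigma_a": sigma_a, "sigma_b": sigma_b, "sigma_c": sigma_c,
        "phi_ct": phi_ct, "phi_sc": phi_sc, "phi_st": phi_st,
        "ssd_total": ssd_total, "ssd_ag": ssd_ag, "ssd_apwg": ssd_apwg, "ssd_wp": ssd_wp,
        "df_ag": df_ag, "df_apwg": df_apwg, "df_wp": df_wp,
    }


def amova(populations: list[PopulationSample],
          group_assignment: dict[str, str],
          n_permutations: int = 10100,
          seed: int = 0,
          components: tuple[str, ...] = ("CT", "SC", "ST"),
          metric: str = "differences") -> AMOVAResult:
    """Hierarchical AMOVA of populations nested in groups.

    ``group_assignment`` maps population names to group labels (at least
    two groups).  ``components`` selects which Phi statistics receive a
    permutation P-value; each uses its appropriate permutation unit.
    ``metric="differences"`` uses pairwise mismatch counts (Phi-style);
    ``metric="haplotype_incidence"`` reduces every non-zero distance to
    1, giving the frequency-only (F-statistic-style) analysis.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    if metric not in ("differences", "haplotype_incidence"):
        raise ValueError("metric must be 'differences' or 'haplotype_incidence'")
    names = [p.population for p in populations]
    missing = [n for n in names if n not in group_assignment]
    if missing:
        raise ValueError(f"populations without group assignment: {missing}")
    group_labels = sorted(set(group_assignment[n] for n in names))
    if len(group_labels) < 2:
        raise ValueError("AMOVA needs at least two groups")
    for g in set(group_assignment.values()):
        if g not in (group_assignment[n] for n in names):
            raise ValueError(f"group {g!r} has zero populations")

    profiles = [pr for p in populations for pr in p.profiles]
    assignment = np.concatenate([
        np.full(p.n, i, dtype=int) for i, p in enumerate(populations)])
    pop_sizes = np.array([p.n for p in populations], dtype=float)
    group_of_pop = np.array([group_labels.index(group_assignment[n]) for n in names])

    d = distance_matrix(profiles)
    if metric == "haplotype_incidence":
        d = (d > 0).astype(float)
    m = _pair_sums(d, assignment, len(populations))
    obs = _hierarchical(m, pop_sizes, group_of_pop)

    rng = np.random.default_rng(seed)
    p_values: dict[str, float] = {}

    if "CT" in components:
        count = 0
        for _ in range(n_permutations):
            perm = _hierarchical(m, pop_sizes, rng.permutation(group_of_pop))
            if perm["phi_ct"] >= obs["phi_ct"] - _EPS:
                count += 1
        p_values["among_groups"] = count / n_permutations

    if "SC" in components:
        count = 0
        for _ in range(n_permutations):
            shuffled = assignment.copy()
            for gi in range(len(group_labels)):
                pops_in_g = np.where(group_of_pop == gi)[0]
                mask = np.isin(assignment, pops_in_g)
                shuffled[mask] = rng.permutation(assignment[mask])
            m_perm = _pair_sums(d, shuffled, len(populations))
            perm = _hierarchical(m_perm, pop_sizes, group_of_pop)
            if perm["phi_sc"] >= obs["phi_sc"] - _EPS:
                count += 1
        p_values["among_pops_within_groups"] = count / n_permutations

    if "ST" in components:
        count = 0
        for _ in range(n_permutations):
            m_perm = _pair_sums(d, rng.permutation(assignment), len(populations))
            perm = _hierarchical(m_perm, pop_sizes, group_of_pop)
            if perm["phi_st"] >= obs["phi_st"] - _EPS:
                count += 1
        p_values["within_pops"] = count / n_permutations

    comps = {
        "among_groups": obs["sigma_a"],
        "among_pops_within_groups": obs["sigma_b"],
        "within_pops": obs["sigma_c"],
    }
    total = sum(comps.values())
    if abs(total) > _EPS:
        percentages = {k: 100.0 * v / total for k, v in comps.items()}
    else:
        percentages = {k: 0.0 for k in comps}
    clipped = {k: max(v, 0.0) for k, v in comps.items()}
    clip_total = sum(clipped.values())
    display = ({k: 100.0 * v / clip_total for k, v in clipped.items()}
               if clip_total > _EPS else {k: 0.0 for k in comps})
    return AMOVAResult(
        components=comps,
        percentages=percentages,
        display_percentages=display,
        phi_statistics={"phi_ct": obs["phi_ct"], "phi_sc": obs["phi_sc"],
                        "phi_st": obs["phi_st"]},
        p_values=p_values,
        n_permutations=n_permutations,
        seed=seed,
        sums_of_squares={k: obs[k] for k in ("ssd_total", "ssd_ag", "ssd_apwg", "ssd_wp")},
        degrees_of_freedom={k: obs[k] for k in ("df_ag", "df_apwg", "df_wp")},
    )


@dataclass(frozen=True)
class ChiSqResult:
    haplogroup: str
    table: tuple[tuple[int, int], tuple[int, int]]
    statistic: float
    df: int
    p_value: float
    low_expected: bool = False


def chi2_cohort_test(haplogroup_counts: tuple[int, int],
                     cohort_sizes: tuple[int, int],
                     haplogroup: str = "") -> ChiSqResult:
    """Pearson chi-squared (no continuity correction) on a 2x2 table.

    Rows are the two cohorts; columns are membership in the haplogroup
    vs the rest.  An expected cell below 1 sets ``low_expected`` rather
    than suppressing the result.
    """
    (k1, k2), (n1, n2) = haplogroup_counts, cohort_sizes
    if n1 < 1 or n2 < 1:
        raise ValueError("both cohorts must be non-empty")
    if k1 > n1 or k2 > n2:
        raise ValueError("haplogroup count exceeds cohort size")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    col_sums = table.sum(axis=0)
    expected = np.outer(table.sum(axis=1), col_sums) / table.sum()
    low = bool((expected < 1).any())
    if (col_sums == 0).any():
        # the haplogroup is absent (or universal) in both cohorts:
        # proportions are identical by construction
        stat, p = 0.0, 1.0
    else:
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ChiSqResult(haplogroup=haplogroup,
                       table=((k1, n1 - k1), (k2, n2 - k2)),
                       statistic=float(stat), df=1, p_value=float(p),
                       low_expected=low)
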