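"""Synthetic single-cross hybrid populations with known genetic architecture.

The generator emulates the construction of maize single-cross hybrids from
two divergent heterotic groups of fully inbred lines:

1. inbred lines are drawn from group-specific allele frequencies under a
   Balding–Nichols drift model (``simulate_lines``);
2. groups are recovered from the additive relationship matrix by
   2-means on the leading principal components (``assign_heterotic_groups``);
3. a partial diallel crosses every line of one group with every line of
   the other, the hybrid genotype at each locus being the expectation of
   the parental allelic contributions (``partial_diallel``);
4. a pleiotropic QTN architecture assigns additive and dominance effects
   to marker subsets (``sample_architecture``); and
5. phenotypes are built as y = mu + W_A a* + W_D d* + e with the residual
   variance scaled to a requested broad-sense heritability
   (``simulate_phenotypes``).

The parametric genetic values g and the additive/dominance variance
components are exposed as ground truth for model evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .genotypes import MarkerMatrix, allele_freq, code_cockerham
from .kinship import RelationshipMatrix, additive_grm, dominance_grm

__all__ = [
    "HISTORICAL_H2",
    "GeneticArchitecture",
    "TrueSignal",
    "PhenotypeTable",
    "HybridStudy",
    "simulate_lines",
    "assign_heterotic_groups",
    "expected_hybrid_genotype",
    "partial_diallel",
    "sample_architecture",
    "parametric_variances",
    "simulate_phenotypes",
    "simulate_hybrid_study",
]

#: Historical mean broad-sense heritabilities of the five maize traits
#: (plant height, ear height, ear length, ear row number, kernel weight).
HISTORICAL_H2 = {"PH": 0.569, "EH": 0.662, "EL": 0.381, "ERN": 0.57, "KW": 0.418}


@dataclass
class GeneticArchitecture:
    """Per-trait QTN index sets and per-locus effect vectors.

    ``a_star`` and ``d_star`` have shape (n_traits, n_loci) with zeros off
    the QTN index sets.  ``pleiotropy_table`` holds, for each effect kind,
    the t x t counts of QTN shared between trait pairs.
    """

    a_star: np.ndarray
    d_star: np.ndarray
    qtn_additive: list[np.ndarray]
    qtn_dominance: list[np.ndarray]
    pleiotropy_table: dict[str, np.ndarray]
    trait_names: list[str]

    def __post_init__(self) -> None:
        self.a_star = np.asarray(self.a_star, dtype=float)
        self.d_star = np.asarray(self.d_star, dtype=float)
        if self.a_star.shape != self.d_star.shape:
            raise ValueError("a_star and d_star shapes differ")
        # nonzero effects must sit exactly on the QTN index sets (a drawn
        # effect of exactly zero, e.g. a zero effect scale, is allowed)
        for t, idx in enumerate(self.qtn_additive):
            nz = np.nonzero(self.a_star[t])[0]
            if not np.isin(nz, idx).all():
                raise ValueError("a_star nonzeros do not match qtn_additive")
        for t, idx in enumerate(self.qtn_dominance):
            nz = np.nonzero(self.d_star[t])[0]
            if not np.isin(nz, idx).all():
                raise ValueError("d_star nonzeros do not match qtn_dominance")

    @property
    def n_traits(self) -> int:
        return self.a_star.shape[0]

    @property
    def n_loci(self) -> int:
        return self.a_star.shape[1]

    def to_json_dict(self) -> dict:
        return {
            "trait_names": list(self.trait_names),
            "n_loci": int(self.n_loci),
            "qtn_additive": [idx.tolist() for idx in self.qtn_additive],
            "qtn_dominance": [idx.tolist() for idx in self.qtn_dominance],
            "a_star_nonzero": [
                self.a_star[t, idx].tolist()
                for t, idx in enumerate(self.qtn_additive)
            ],
            "d_star_nonzero": [
                self.d_star[t, idx].tolist()
                for t, idx in enumerate(self.qtn_dominance)
            ],
        }


@dataclass
class TrueSignal:
    """Parametric genetic values and variance components of a simulation.

    ``sigma2_alpha``/``sigma2_delta`` are the locus-sum variances
    sigma_a^2 = Σ 2p(1-p)[a+d(q-p)]² and sigma_d^2 = Σ (2p(1-p)d)²,
    which assume Hardy–Weinberg and linkage equilibrium at the coding
    frequencies.  ``V_alpha_emp``/``V_delta_emp`` are the empirical trait
    covariance matrices of the realized components W_A a* and W_D d* over
    the simulated hybrids — the truth actually present in the sample (a
    diallel of two divergent groups is not an HWE population, so the two
    need not agree).
    """

    g: np.ndarray  # n x t parametric genetic values (mu + W_A a* + W_D d*)
    g_additive: np.ndarray  # n x t, W_A a*
    g_dominance: np.ndarray  # n x t, W_D d*
    mu: np.ndarray  # t
    sigma2_alpha: np.ndarray  # t, locus-sum formula
    sigma2_delta: np.ndarray  # t, locus-sum formula
    sigma2_g: np.ndarray  # t, empirical var of g over hybrids
    V_alpha_emp: np.ndarray  # t x t empirical cov of W_A a*
    V_delta_emp: np.ndarray  # t x t empirical cov of W_D d*
    trait_names: list[str] = field(default_factory=list)


@dataclass
class PhenotypeTable:
    """Hybrids x traits phenotypes with requested heritabilities."""

    y: np.ndarray
    h2: np.ndarray
    trait_names: list[str]
    individual_ids: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.h2 = np.atleast_1d(np.asarray(self.h2, dtype=float))
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.y)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if np.any((self.h2 <= 0) | (self.h2 >= 1)):
            raise ValueError("heritabilities must lie in (0, 1)")
        if self.y.shape[1] != len(self.trait_names):
            raise ValueError("trait_names length mismatch")

    def to_frame(self) -> pd.DataFrame:
        values = np.where(self.missing_mask, np.nan, self.y)
        return pd.DataFrame(
            values, index=self.individual_ids, columns=self.trait_names
        )


def simulate_lines(
    n_lines: int,
    n_loci: int,
    n_groups: int = 2,
    divergence: float = 0.2,
    seed: Optional[int] = None,
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9),
) -> MarkerMatrix:
    """Fully inbred lines (dosages in {0, 2}) from diverged groups.

    Group-specific allele frequencies are drawn around a shared ancestral
    frequency with a Balding–Nichols Beta model whose F parameter equals
    ``divergence``; at divergence 0 the groups share the ancestral
    frequencies exactly.  Lines are split as evenly as possible across
    groups and their ids encode the simulated group ("g0_l000", ...).
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = ancestral_freq_range
    p0 = rng.uniform(lo, hi, size=n_loci)
    sizes = [n_lines // n_groups] * n_groups
    for i in range(n_lines - sum(sizes)):
        sizes[i] += 1
    values = np.empty((n_lines, n_loci))
    ids = []
    row = 0
    for grp, size in enumerate(sizes):
        if divergence == 0.0 or divergence == 1.0:
            if divergence == 0.0:
                pg = p0
            else:  # complete drift: each locus fixed for one allele
                pg = (rng.random(n_loci) < p0).astype(float)
        else:
            f = divergence
            pg = rng.beta(p0 * (1 - f) / f, (1 - p0) * (1 - f) / f)
        values[row : row + size] = 2.0 * (rng.random((size, n_loci)) < pg)
        ids.extend(f"g{grp}_l{row + i:03d}" for i in range(size))
        row += size
    locus_ids = np.array([f"m{j:05d}" for j in range(n_loci)])
    return MarkerMatrix(values=values, locus_ids=locus_ids, individual_ids=np.array(ids))


def assign_heterotic_groups(
    a: Union[RelationshipMatrix, np.ndarray],
    n_groups: int = 2,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Cluster individuals on the leading principal components of A.

    Individuals are projected on the top-2 eigenvectors of the additive
    relationship matrix and partitioned by (seeded) k-means.  Labels are
    arbitrary up to permutation.
    """
    values = a.values if isinstance(a, RelationshipMatrix) else np.asarray(a)
    n = values.shape[0]
    if n < n_groups:
        raise ValueError("fewer individuals than groups")
    if n_groups == 1:
        return np.zeros(n, dtype=int)
    eigval, eigvec = np.linalg.eigh(values)
    if eigval[-2] <= 1e-10 * max(eigval[-1], 1.0):
        raise ValueError("relationship matrix is rank-deficient (< 2); cannot project")
    proj = eigvec[:, -2:] * np.sqrt(eigval[-2:])
    km = KMeans(n_clusters=n_groups, n_init=10, random_state=seed)
    return km.fit_predict(proj)


def expected_hybrid_genotype(p_parent1, p_parent2):
    """Expected hybrid dosage at a locus from parental A1 frequencies.

    E(m) = 2 p1 p2 + p1(1-p2) + p2(1-p1), which simplifies to p1 + p2.
    Accepts scalars or arrays in [0, 1].
    """
    p1 = np.asarray(p_parent1, dtype=float)
    p2 = np.asarray(p_parent2, dtype=float)
    if np.any(p1 < 0) or np.any(p1 > 1) or np.any(p2 < 0) or np.any(p2 > 1):
        raise ValueError("parental allele frequencies must lie in [0, 1]")
    out = 2.0 * p1 * p2 + p1 * (1.0 - p2) + p2 * (1.0 - p1)
    if out.ndim == 0:
        return float(out)
    return out


def partial_diallel(
    lines_group1: MarkerMatrix,
    lines_group2: MarkerMatrix,
    n_per_group: Union[int, tuple[int, int]] = 20,
    return_parent_freqs: bool = False,
):
    """All crosses between the first n lines of each heterotic group.

    The per-locus hybrid dosage is the expected genotype of the cross of
    the parental within-line allele frequencies (dosage/2, i.e. {0, 1} for
    fully inbred parents; residual-heterozygosity fractional dosages pass
    through unchanged).  Hybrid ids encode the parent pair as "P1xP2".
    With ``return_parent_freqs`` the two n_hybrids x n_loci parental
    frequency matrices are returned as well (exact dominance coding of
    fractional hybrid dosages needs them).
    """
    n1, n2 = (n_per_group, n_per_group) if isinstance(n_per_group, int) else n_per_group
    if lines_group1.n_individuals < n1 or lines_group2.n_individuals < n2:
        raise ValueError("a group has fewer lines than n_per_group")
    if not np.array_equal(lines_group1.locus_ids, lines_group2.locus_ids):
        raise ValueError("groups disagree on loci")
    overlap = set(lines_group1.individual_ids[:n1]) & set(
        lines_group2.individual_ids[:n2]
    )
    if overlap:
        raise ValueError(f"parent sets overlap between groups: {sorted(overlap)[:5]}")
    if lines_group1.missing_mask.any() or lines_group2.missing_mask.any():
        raise ValueError("parental matrices contain missing values; impute first")
    p1 = lines_group1.values[:n1] / 2.0
    p2 = lines_group2.values[:n2] / 2.0
    q = p1.shape[1]
    pl = np.repeat(p1, n2, axis=0)  # parent-1-major ordering of crosses
    po = np.tile(p2, (n1, 1))
    values = expected_hybrid_genotype(pl, po)
    ids = np.array(
        [
            f"{i1}x{i2}"
            for i1 in lines_group1.individual_ids[:n1]
            for i2 in lines_group2.individual_ids[:n2]
        ]
    )
    hybrids = MarkerMatrix(
        values=values, locus_ids=lines_group1.locus_ids.copy(), individual_ids=ids
    )
    if return_parent_freqs:
        return hybrids, (pl, po)
    return hybrids


def sample_architecture(
    n_loci: int,
    n_add_qtn: int = 100,
    n_dom_qtn: int = 100,
    n_traits: int = 5,
    pleiotropy_fraction: float = 0.2,
    effect_distribution=None,
    seed: Optional[int] = None,
    trait_names: Optional[Sequence[str]] = None,
    effect_scale: Union[float, Sequence[float]] = 1.0,
    dominance_scale: Union[float, Sequence[float]] = 1.0,
    align_shared_signs: bool = True,
) -> GeneticArchitecture:
    """Sample per-trait QTN index sets and effects with partial pleiotropy.

    Per trait, ``n_add_qtn`` additive and ``n_dom_qtn`` dominance QTN
    positions are drawn without replacement.  Each trait after the first
    shares a fraction ``pleiotropy_fraction`` of its QTN positions with
    the previous trait (chain sharing), inducing genetic correlation; with
    ``align_shared_signs`` the shared effects keep the sign of the earlier
    trait so the induced correlation is positive.  Effects default to
    standard normal draws scaled by ``effect_scale``/``dominance_scale``
    (scalar or per trait).
    """
    if not 0.0 <= pleiotropy_fraction <= 1.0:
        raise ValueError("pleiotropy_fraction must lie in [0, 1]")
    if n_add_qtn + n_dom_qtn > n_loci:
        raise ValueError("n_add_qtn + n_dom_qtn exceeds n_loci")
    rng = np.random.default_rng(seed)
    if effect_distribution is None:
        effect_distribution = rng.standard_normal
    if trait_names is None:
        trait_names = (
            list(HISTORICAL_H2) if n_traits == 5 else [f"T{t+1}" for t in range(n_traits)]
        )
    trait_names = list(trait_names)
    a_scale = np.broadcast_to(np.atleast_1d(effect_scale), (n_traits,))
    d_scale = np.broadcast_to(np.atleast_1d(dominance_scale), (n_traits,))

    def _draw_sets(n_qtn: int) -> tuple[list[np.ndarray], np.ndarray]:
        """Chain-shared QTN sets plus the table of imposed shared counts."""
        sets: list[np.ndarray] = []
        table = np.zeros((n_traits, n_traits), dtype=int)
        n_shared = int(round(pleiotropy_fraction * n_qtn))
        for t in range(n_traits):
            if t == 0 or n_shared == 0:
                idx = rng.choice(n_loci, size=n_qtn, replace=False)
            else:
                shared = rng.choice(sets[t - 1], size=n_shared, replace=False)
                pool = np.setdiff1d(np.arange(n_loci), shared)
                fresh = rng.choice(pool, size=n_qtn - n_shared, replace=False)
                idx = np.concatenate([shared, fresh])
                table[t - 1, t] = table[t, t - 1] = n_shared
            sets.append(np.sort(idx))
        return sets, table

    qtn_add, table_add = _draw_sets(n_add_qtn)
    qtn_dom, table_dom = _draw_sets(n_dom_qtn)

    def _effects(sets, scales) -> np.ndarray:
        eff = np.zeros((n_traits, n_loci))
        for t, idx in enumerate(sets):
            eff[t, idx] = effect_distribution(idx.size) * scales[t]
            if align_shared_signs and t > 0:
                shared = np.intersect1d(idx, sets[t - 1])
                if shared.size:
                    eff[t, shared] = np.abs(eff[t, shared]) * np.sign(
                        np.where(eff[t - 1, shared] == 0, 1.0, eff[t - 1, shared])
                    )
        return eff

    a_star = _effects(qtn_add, a_scale)
    d_star = _effects(qtn_dom, d_scale)

    return GeneticArchitecture(
        a_star=a_star,
        d_star=d_star,
        qtn_additive=qtn_add,
        qtn_dominance=qtn_dom,
        pleiotropy_table={"additive": table_add, "dominance": table_dom},
        trait_names=trait_names,
    )


def parametric_variances(p: np.ndarray, a_star: np.ndarray, d_star: np.ndarray):
    """Locus-sum additive and dominance variances.

    sigma_alpha^2 = Σ_k 2 p_k q_k [a_k + d_k (q_k - p_k)]²  and
    sigma_delta^2 = Σ_k (2 p_k q_k d_k)², with q = 1 - p.  Accepts 1-D
    (single trait) or 2-D (traits x loci) effect arrays.
    """
    p = np.asarray(p, dtype=float)
    a = np.atleast_2d(np.asarray(a_star, dtype=float))
    d = np.atleast_2d(np.asarray(d_star, dtype=float))
    if a.shape[1] != p.size or d.shape[1] != p.size:
        raise ValueError("effect vectors and allele frequencies differ in length")
    q = 1.0 - p
    het = 2.0 * p * q
    s2a = np.sum(het * (a + d * (q - p)) ** 2, axis=1)
    s2d = np.sum((het * d) ** 2, axis=1)
    if np.asarray(a_star).ndim == 1:
        return float(s2a[0]), float(s2d[0])
    return s2a, s2d


def simulate_phenotypes(
    hybrids: MarkerMatrix,
    arch: GeneticArchitecture,
    h2: Union[float, Sequence[float]],
    mu: Union[float, Sequence[float]] = 0.0,
    seed: Optional[int] = None,
) -> tuple[PhenotypeTable, TrueSignal]:
    """Phenotypes at requested broad-sense heritabilities.

    g = mu + W_A a* + W_D d* per trait; residuals are i.i.d. normal with
    variance sigma_e^2 = sigma_g^2 (1 - h2)/h2 where sigma_g^2 is the
    empirical variance of g over the hybrids, so the realized broad-sense
    heritability matches the request up to sampling noise.  Incidence
    matrices are coded at the hybrid-population allele frequencies.
    """
    t = arch.n_traits
    h2 = np.broadcast_to(np.atleast_1d(np.asarray(h2, dtype=float)), (t,)).copy()
    mu = np.broadcast_to(np.atleast_1d(np.asarray(mu, dtype=float)), (t,)).copy()
    if np.any((h2 <= 0) | (h2 >= 1)):
        raise ValueError("h2 must lie in (0, 1)")
    if hybrids.n_loci != arch.n_loci:
        raise ValueError("architecture and genotypes disagree on n_loci")
    rng = np.random.default_rng(seed)
    p = allele_freq(hybrids)
    inc = code_cockerham(hybrids, p)
    g_add = inc.W_A @ arch.a_star.T
    g_dom = inc.W_D @ arch.d_star.T
    g = mu + g_add + g_dom
    sigma2_g = np.var(g, axis=0, ddof=1)
    if np.any(sigma2_g <= 0):
        raise ValueError("a trait has zero genetic variance; cannot scale residuals")
    sigma2_e = sigma2_g * (1.0 - h2) / h2
    e = rng.standard_normal(g.shape) * np.sqrt(sigma2_e)
    y = g + e
    s2a, s2d = parametric_variances(p, arch.a_star, arch.d_star)
    truth = TrueSignal(
        g=g,
        g_additive=g_add,
        g_dominance=g_dom,
        mu=mu,
        sigma2_alpha=s2a,
        sigma2_delta=s2d,
        sigma2_g=sigma2_g,
        V_alpha_emp=np.atleast_2d(np.cov(g_add.T, ddof=1)),
        V_delta_emp=np.atleast_2d(np.cov(g_dom.T, ddof=1)),
        trait_names=list(arch.trait_names),
    )
    pheno = PhenotypeTable(
        y=y,
        h2=h2,
        trait_names=list(arch.trait_names),
        individual_ids=hybrids.individual_ids.copy(),
    )
    return pheno, truth


@dataclass
class HybridStudy:
    """Bundle of one simulated hybrid study (the full generator pipeline)."""

    lines: MarkerMatrix
    hybrids: MarkerMatrix
    incidence_WA: np.ndarray
    incidence_WD: np.ndarray
    allele_freq: np.ndarray
    A: RelationshipMatrix
    D: RelationshipMatrix
    architecture: GeneticArchitecture
    phenotypes: PhenotypeTable
    truth: TrueSignal


def simulate_hybrid_study(
    n_lines: int = 80,
    n_loci: int = 1000,
    n_per_group: Union[int, tuple[int, int]] = 20,
    divergence: float = 0.2,
    n_add_qtn: int = 100,
    n_dom_qtn: int = 100,
    n_traits: int = 5,
    pleiotropy_fraction: float = 0.2,
    h2: Union[float, Sequence[float], str] = "historical",
    mu: Union[float, Sequence[float]] = 0.0,
    dominance_scale: Union[float, Sequence[float]] = 1.0,
    seed: Optional[int] = None,
) -> HybridStudy:
    """Run the full generator: lines -> diallel -> architecture -> phenotypes.

    ``h2`` may be a scalar, a per-trait list, or "historical" for the five
    maize traits' historical heritabilities.  All randomness derives from
    ``seed`` through independently spawned streams per stage.
    """
    ss = np.random.SeedSequence(seed)
    s_lines, s_arch, s_pheno = ss.spawn(3)
    if isinstance(h2, str):
        if h2 != "historical":
            raise ValueError("h2 preset must be 'historical'")
        if n_traits != 5:
            raise ValueError("historical h2 preset requires 5 traits")
        h2_vec = np.array(list(HISTORICAL_H2.values()))
        trait_names: Optional[list[str]] = list(HISTORICAL_H2)
    else:
        h2_vec = np.broadcast_to(np.atleast_1d(np.asarray(h2, float)), (n_traits,))
        trait_names = None
    lines = simulate_lines(
        n_lines, n_loci, n_groups=2, divergence=divergence, seed=s_lines
    )
    group = np.array([iid.startswith("g0") for iid in lines.individual_ids])
    g1 = lines.select_individuals(lines.individual_ids[group])
    g2 = lines.select_individuals(lines.individual_ids[~group])
    hybrids = partial_diallel(g1, g2, n_per_group=n_per_group)
    arch = sample_architecture(
        n_loci,
        n_add_qtn=n_add_qtn,
        n_dom_qtn=n_dom_qtn,
        n_traits=n_traits,
        pleiotropy_fraction=pleiotropy_fraction,
        seed=s_arch,
        trait_names=trait_names,
        dominance_scale=dominance_scale,
    )
    pheno, truth = simulate_phenotypes(hybrids, arch, h2=h2_vec, mu=mu, seed=s_pheno)
    p = allele_freq(hybrids)
    inc = code_cockerham(hybrids, p)
    A = additive_grm(inc.W_A, p, ids=hybrids.individual_ids)
    D = dominance_grm(inc.W_D, p, ids=hybrids.individual_ids)
    return HybridStudy(
        lines=lines,
        hybrids=hybrids,
        incidence_WA=inc.W_A,
        incidence_WD=inc.W_D,
        allele_freq=p,
        A=A,
        D=D,
        architecture=arch,
        phenotypes=pheno,
        truth=truth,
    )
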