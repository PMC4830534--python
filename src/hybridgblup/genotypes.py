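"""Marker-dosage matrices and Cockerham incidence coding.

Dosages count copies of the A1 allele (0 = A2A2, 1 = A1A2, 2 = A1A1).
Fractional dosages are allowed and arise as *expected* hybrid genotypes
from crosses of non-fixed parents, or from mean imputation.  The additive
and dominance incidence matrices W_A and W_D follow Cockerham's
orthogonal parameterization:

    W_A: 2-2p (A1A1),  1-2p (A1A2),  -2p (A2A2)
    W_D: -2(1-p)^2,    2p(1-p),      -2p^2

where p is the frequency of A1 at the locus in the reference population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "IncidencePair",
    "allele_freq",
    "impute_mean",
    "systematic_sample",
    "code_cockerham",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_vcf",
]


@dataclass
class MarkerMatrix:
    """Individuals x loci dosage matrix with an explicit missing mask.

    ``values`` holds float dosages in [0, 2]; missing cells carry NaN and
    are flagged in ``missing_mask``.  Row and column identifiers must be
    unique.
    """

    values: np.ndarray
    locus_ids: np.ndarray
    individual_ids: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D individuals x loci array")
        self.locus_ids = np.asarray(self.locus_ids)
        self.individual_ids = np.asarray(self.individual_ids)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, q = self.values.shape
        if self.locus_ids.shape != (q,):
            raise ValueError("locus_ids length does not match number of loci")
        if self.individual_ids.shape != (n,):
            raise ValueError("individual_ids length does not match rows")
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape mismatch")
        if len(set(self.locus_ids.tolist())) != q:
            raise ValueError("locus_ids are not unique")
        if len(set(self.individual_ids.tolist())) != n:
            raise ValueError("individual_ids are not unique")
        observed = self.values[~self.missing_mask]
        if observed.size and (np.nanmin(observed) < 0 or np.nanmax(observed) > 2):
            raise ValueError("non-missing dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    def select_loci(self, locus_ids: Sequence) -> "MarkerMatrix":
        """Return a copy restricted to ``locus_ids`` (in the given order)."""
        pos = {lid: i for i, lid in enumerate(self.locus_ids.tolist())}
        idx = np.array([pos[lid] for lid in locus_ids], dtype=int)
        return MarkerMatrix(
            values=self.values[:, idx],
            locus_ids=self.locus_ids[idx],
            individual_ids=self.individual_ids.copy(),
            missing_mask=self.missing_mask[:, idx],
        )

    def select_individuals(self, individual_ids: Sequence) -> "MarkerMatrix":
        pos = {iid: i for i, iid in enumerate(self.individual_ids.tolist())}
        idx = np.array([pos[iid] for iid in individual_ids], dtype=int)
        return MarkerMatrix(
            values=self.values[idx],
            locus_ids=self.locus_ids.copy(),
            individual_ids=self.individual_ids[idx],
            missing_mask=self.missing_mask[idx],
        )


@dataclass
class IncidencePair:
    """Additive (W_A) and dominance (W_D) Cockerham incidence matrices."""

    W_A: np.ndarray
    W_D: np.ndarray

    def __post_init__(self) -> None:
        self.W_A = np.asarray(self.W_A, dtype=float)
        self.W_D = np.asarray(self.W_D, dtype=float)
        if self.W_A.shape != self.W_D.shape:
            raise ValueError("W_A and W_D must have identical shapes")


def allele_freq(m: MarkerMatrix) -> np.ndarray:
    """Per-locus frequency of the counted (A1) allele.

    p_k is the mean non-missing dosage at locus k divided by 2.  A locus
    with no observed genotype at all is an error.
    """
    masked = np.where(m.missing_mask, np.nan, m.values)
    n_obs = (~m.missing_mask).sum(axis=0)
    if np.any(n_obs == 0):
        bad = m.locus_ids[n_obs == 0]
        raise ValueError(f"locus entirely missing: {bad[:5].tolist()}")
    with np.errstate(invalid="ignore"):
        p = np.nanmean(masked, axis=0) / 2.0
    return p


def impute_mean(m: MarkerMatrix) -> MarkerMatrix:
    """Replace each missing cell by its locus mean dosage (2 p_k)."""
    if not m.missing_mask.any():
        return replace(m, values=m.values.copy(), missing_mask=m.missing_mask.copy())
    p = allele_freq(m)  # errors out on fully missing loci
    values = m.values.copy()
    rows, cols = np.nonzero(m.missing_mask)
    values[rows, cols] = 2.0 * p[cols]
    return MarkerMatrix(
        values=values,
        locus_ids=m.locus_ids.copy(),
        individual_ids=m.individual_ids.copy(),
        missing_mask=np.zeros_like(m.missing_mask),
    )


def systematic_sample(
    locus_ids: Sequence,
    step: int,
    seed: Optional[int] = None,
    chromosomes: Optional[Sequence] = None,
) -> np.ndarray:
    """Systematic (every ``step``-th) locus sample with a random start.

    The first locus is drawn uniformly from positions 1..step (seeded) and
    every step-th locus thereafter is kept.  If ``chromosomes`` labels are
    given, sampling restarts independently within each chromosome.
    """
    locus_ids = np.asarray(locus_ids)
    if step < 1:
        raise ValueError("step must be >= 1")
    rng = np.random.default_rng(seed)
    if chromosomes is None:
        groups = [np.arange(locus_ids.size)]
    else:
        chromosomes = np.asarray(chromosomes)
        if chromosomes.shape != locus_ids.shape:
            raise ValueError("chromosomes length mismatch")
        # preserve first-appearance order of chromosome labels
        _, first = np.unique(chromosomes, return_index=True)
        labels = chromosomes[np.sort(first)]
        groups = [np.nonzero(chromosomes == lab)[0] for lab in labels]
    picked = []
    for idx in groups:
        if step > idx.size:
            raise ValueError(
                f"step ({step}) exceeds number of loci ({idx.size}) in a group"
            )
        start = int(rng.integers(0, step))
        picked.append(idx[start::step])
    return locus_ids[np.concatenate(picked)]


def _class_probabilities(
    g: np.ndarray,
    parent_freqs: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Genotype-class probabilities (A1A1, A1A2, A2A2) for each cell.

    Integer dosages are exact genotypes.  Fractional dosages are expected
    genotypes of a cross: with parental A1 frequencies (pl, po) the class
    probabilities are (pl*po, pl(1-po)+po(1-pl), (1-pl)(1-po)).  When the
    parents are unknown the dosage g is split symmetrically (pl = po =
    g/2), which reduces to the exact coding at integer g of fixed crosses.
    """
    if parent_freqs is not None:
        pl, po = (np.asarray(x, dtype=float) for x in parent_freqs)
        if pl.shape != g.shape or po.shape != g.shape:
            raise ValueError("parent frequency arrays must match dosage shape")
        if not np.allclose(pl + po, g, atol=1e-8):
            raise ValueError("parent frequencies inconsistent with dosages (pl+po != g)")
        p11 = pl * po
        phet = pl * (1.0 - po) + po * (1.0 - pl)
        p22 = (1.0 - pl) * (1.0 - po)
        return p11, phet, p22
    is_int = np.isclose(g, np.round(g), atol=1e-9)
    half = g / 2.0
    p11 = np.where(is_int, g == 2.0, half**2)
    phet = np.where(is_int, g == 1.0, 2.0 * half * (1.0 - half))
    p22 = np.where(is_int, g == 0.0, (1.0 - half) ** 2)
    return p11.astype(float), phet.astype(float), p22.astype(float)


def code_cockerham(
    m: MarkerMatrix,
    p: np.ndarray,
    parent_freqs: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> IncidencePair:
    """Cockerham additive/dominance incidence matrices for dosages in [0,2].

    ``p`` is the per-locus A1 frequency in the reference population used
    for centering.  The additive code is linear in the dosage (W_A = g -
    2p), so it applies unchanged to fractional expected genotypes.  The
    dominance code is the genotype-class-probability-weighted average of
    the three Cockerham codes; for hybrids, ``parent_freqs`` = (p_parent1,
    p_parent2) per cell gives the exact cross probabilities.
    """
    if m.missing_mask.any():
        raise ValueError("marker matrix has missing values; impute first")
    p = np.asarray(p, dtype=float)
    if p.shape != (m.n_loci,):
        raise ValueError("allele frequency length mismatch")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    g = m.values
    if np.any(g < 0) or np.any(g > 2):
        raise ValueError("dosage outside [0, 2]")
    W_A = g - 2.0 * p
    p11, phet, p22 = _class_probabilities(g, parent_freqs)
    c11 = -2.0 * (1.0 - p) ** 2
    chet = 2.0 * p * (1.0 - p)
    c22 = -2.0 * p**2
    W_D = p11 * c11 + phet * chet + p22 * c22
    return IncidencePair(W_A=W_A, W_D=W_D)


# ---------------------------------------------------------------------------
# I/O: genotype CSV/TSV and (optional) VCF


def read_genotype_csv(path, sep: str = ",") -> MarkerMatrix:
    """Read individuals x loci dosages (first column = individual id)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = df.to_numpy(dtype=float)
    return MarkerMatrix(
        values=values,
        locus_ids=df.columns.to_numpy(),
        individual_ids=df.index.astype(str).to_numpy(),
    )


def write_genotype_csv(m: MarkerMatrix, path, sep: str = ",") -> None:
    values = np.where(m.missing_mask, np.nan, m.values)
    df = pd.DataFrame(values, index=m.individual_ids, columns=m.locus_ids)
    df.to_csv(path, sep=sep, index_label="individual")


def read_vcf(path) -> MarkerMatrix:
    """Read biallelic sites from a VCF into ALT-allele dosages.

    Multiallelic sites are skipped; missing genotypes and half-calls are
    masked.  Requires cyvcf2 (``pip install hybridgblup[vcf]``).
    """
    from cyvcf2 import VCF  # lazy: optional dependency

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples)
    cols: list[np.ndarray] = []
    ids: list[str] = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gts = np.asarray(var.genotypes, dtype=object)
        dos = np.empty(len(samples))
        for i, gt in enumerate(gts):
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:  # missing or half-call
                dos[i] = np.nan
            else:
                dos[i] = float((a1 > 0) + (a2 > 0))
        cols.append(dos)
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
    if not cols:
        raise ValueError("no biallelic sites found in VCF")
    values = np.column_stack(cols)
    return MarkerMatrix(values=values, locus_ids=np.asarray(ids), individual_ids=samples)
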