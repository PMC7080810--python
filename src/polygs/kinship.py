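"""Relationship matrices and diversity summaries.

Builds the pedigree numerator relationship matrix A (tabular method), the
VanRaden genomic relationship matrix G, the genomic dominance matrix D,
and group-coancestry / status-number summaries used to track the
diversity of selected sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import MISSING, GenotypeMatrix, PedigreeTable, RelationshipMatrix


@dataclass
class CoancestrySummary:
    """Group coancestry theta and status number Ns = 1 / (2 theta)."""

    theta: float
    status_number: float
    n: int


def _toposort(ped: PedigreeTable) -> list[str]:
    """Parents before offspring; raises on pedigree cycles."""
    parents = {
        r.id: tuple(p for p in (r.dam, r.sire) if p is not None)
        for r in ped.records.itertuples()
    }
    # parents referenced but not listed are base founders
    for p in {p for ps in parents.values() for p in ps}:
        parents.setdefault(p, ())
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(node: str, stack: list[str]):
        st = state.get(node, 0)
        if st == 1:
            raise ValueError(f"pedigree cycle involving {node!r}")
        if st == 2:
            return
        state[node] = 1
        stack.append(node)
        for p in parents[node]:
            visit(p, stack)
        stack.pop()
        state[node] = 2
        order.append(node)

    for node in list(parents):
        visit(node, [])
    return order


def build_A(pedigree: PedigreeTable, mode: str = "full") -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    ``mode='partial'`` masks every sire to unknown first (the maternal
    half-sib view of a polycross whose fathers were never recorded).
    Unknown parents are unrelated, non-inbred base founders.
    """
    if mode not in ("full", "partial"):
        raise ValueError(f"mode must be 'full' or 'partial', got {mode!r}")
    if mode == "partial":
        pedigree = pedigree.mask_sires()
    order = _toposort(pedigree)
    idx = {iid: k for k, iid in enumerate(order)}
    par = {r.id: (r.dam, r.sire) for r in pedigree.records.itertuples()}
    n = len(order)
    a = np.zeros((n, n))
    for iid in order:
        i = idx[iid]
        dam, sire = par.get(iid, (None, None))
        di = idx[dam] if dam is not None else None
        si = idx[sire] if sire is not None else None
        row = np.zeros(n)
        if di is not None:
            row += 0.5 * a[di]
        if si is not None:
            row += 0.5 * a[si]
        a[i, :i] = row[:i]
        a[:i, i] = row[:i]
        a[i, i] = 1.0 + (0.5 * a[di, si] if di is not None and si is not None else 0.0)
    kind = "A_partial" if mode == "partial" else "A_full"
    return RelationshipMatrix(ids=order, values=a, kind=kind)


def _centred_dosage(genotypes: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    if (genotypes.calls == MISSING).any():
        raise ValueError("genomic matrices require complete genotypes; impute first")
    m = genotypes.calls.astype(float)
    p = m.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic")
    return m[:, poly], p[poly]


def build_G(genotypes: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix.

    G = (M - 2p)(M - 2p)' / (2 sum_j p_j (1 - p_j)), with allele
    frequencies estimated from the genotyped individuals themselves.
    Monomorphic SNPs are dropped.
    """
    m, p = _centred_dosage(genotypes)
    w = m - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    g = w @ w.T / denom
    return RelationshipMatrix(ids=list(genotypes.ids), values=g, kind="G")


def build_D(genotypes: GenotypeMatrix) -> RelationshipMatrix:
    """Genomic dominance relationship matrix.

    With p the frequency of the counted (alt) allele and q = 1 - p, the
    dominance design codes genotypes {0, 1, 2} -> {-2p^2, 2pq, -2q^2}
    (zero mean under Hardy-Weinberg); D = WW' / sum_j (2 p_j q_j)^2.
    """
    m, p = _centred_dosage(genotypes)
    q = 1.0 - p
    w = np.empty_like(m)
    codes0 = -2.0 * p**2
    codes1 = 2.0 * p * q
    codes2 = -2.0 * q**2
    w[:] = codes0
    r1, c1 = np.where(m == 1)
    w[r1, c1] = codes1[c1]
    r2, c2 = np.where(m == 2)
    w[r2, c2] = codes2[c2]
    denom = np.sum((2.0 * p * q) ** 2)
    d = w @ w.T / denom
    return RelationshipMatrix(ids=list(genotypes.ids), values=d, kind="D")


def group_coancestry(K: RelationshipMatrix, subset=None) -> CoancestrySummary:
    """Group coancestry of a (sub)population and its status number.

    theta is the average pairwise kinship over all ordered pairs including
    self-pairs; for an additive relationship input, kinship = a_ij / 2, so
    theta = sum(A) / (2 n^2).  Ns = 1 / (2 theta): the number of
    unrelated, non-inbred individuals carrying equivalent diversity.
    """
    ids = list(subset) if subset is not None else list(K.ids)
    if not ids:
        raise ValueError("subset must be non-empty")
    a = K.submatrix(ids)
    n = len(ids)
    theta = a.sum() / (2.0 * n * n)
    if theta <= 0:
        raise ValueError(
            "non-positive group coancestry (possible with a centred G); "
            "use a pedigree-based A or a shifted G for diversity summaries"
        )
    return CoancestrySummary(theta=float(theta), status_number=float(1.0 / (2.0 * theta)), n=n)
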