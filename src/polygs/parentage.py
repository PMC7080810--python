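"""SNP-based parentage: maternal verification, paternity assignment with a
simulated delta criterion, clustering of offspring from non-genotyped
fathers, contamination flagging, and the equal-contribution test.

The pair likelihood is the classic pairwise parentage LOD: at each locus
the probability of the observed offspring genotype given the candidate
parent pair (Mendelian transmission, mixed with a frequency-based call at
the genotyping error rate) is compared with its probability under random
parents drawn from the allele frequencies; per-locus log ratios are
summed over non-missing loci.  The delta score is the LOD gap between the
two best candidate pairs, and its critical value at a stated confidence
is calibrated by simulating offspring under the stated error rate and
sampled-parent fraction.  Sibship reconstruction for offspring of
ungenotyped fathers is done by relatedness-graph clustering (a
substitution for full-pedigree sibship likelihood methods) validated
against simulated truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MISSING, GenotypeMatrix, RelationshipMatrix

log = logging.getLogger(__name__)

# Transmission tables over dosage-coded biallelic genotypes.
_GAMETE = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])  # P(transmit alt | dosage)


def _pair_transmission() -> np.ndarray:
    t = np.zeros((3, 3, 3))
    for gd in range(3):
        for gs in range(3):
            for ad in range(2):
                for as_ in range(2):
                    t[gd, gs, ad + as_] += _GAMETE[gd, ad] * _GAMETE[gs, as_]
    return t


PAIR_T = _pair_transmission()


def _hw_priors(freqs: np.ndarray) -> np.ndarray:
    """(m, 3) Hardy-Weinberg genotype probabilities per locus."""
    p = np.asarray(freqs, float)
    return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)


def _single_transmission(freqs: np.ndarray) -> np.ndarray:
    """(m, 3, 3): P(offspring | one known parent, other parent random)."""
    p = np.asarray(freqs, float)
    m = len(p)
    t = np.zeros((m, 3, 3))
    pop = np.stack([1 - p, p], axis=1)  # transmitted-allele distribution
    for gp in range(3):
        for ap in range(2):
            for aq in range(2):
                t[:, gp, ap + aq] += _GAMETE[gp, ap] * pop[:, aq]
    return t


def floor_freqs(freqs: np.ndarray, n_individuals: int) -> np.ndarray:
    """Keep allele frequencies away from 0/1 (floor at 1/(2N+1))."""
    eps = 1.0 / (2 * n_individuals + 1)
    out = np.clip(freqs, eps, 1 - eps)
    if np.any(out != freqs):
        log.debug("floored %d allele frequencies", int(np.sum(out != freqs)))
    return out


def pair_likelihood(
    offspring: np.ndarray,
    dam: np.ndarray | None,
    sire: np.ndarray | None,
    error_rate: float,
    allele_freqs: np.ndarray,
) -> float:
    """Parent-pair (or single-parent) LOD score for one offspring.

    LOD = sum over non-missing loci of
    log[ ((1-e) T(g_o | parents) + e HW(g_o)) / HW(g_o) ],
    where T is the Mendelian transmission probability (single-parent T
    integrates the unknown parent over the allele frequencies) and HW the
    Hardy-Weinberg genotype probability.  Opposite-homozygote exclusions
    at e = 0 give -inf.
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValueError(f"error_rate must be in [0, 0.5), got {error_rate}")
    off = np.asarray(offspring)
    hw = _hw_priors(allele_freqs)
    loci = off != MISSING
    if dam is not None and sire is not None:
        loci = loci & (np.asarray(dam) != MISSING) & (np.asarray(sire) != MISSING)
        t = PAIR_T[np.clip(dam, 0, 2), np.clip(sire, 0, 2), np.clip(off, 0, 2)]
    else:
        par = dam if dam is not None else sire
        if par is None:
            raise ValueError("at least one parent genotype is required")
        loci = loci & (np.asarray(par) != MISSING)
        t1 = _single_transmission(allele_freqs)
        t = t1[np.arange(len(off)), np.clip(par, 0, 2), np.clip(off, 0, 2)]
    denom = hw[np.arange(len(off)), np.clip(off, 0, 2)]
    num = (1.0 - error_rate) * t + error_rate * denom
    with np.errstate(divide="ignore"):
        terms = np.log(num[loci]) - np.log(denom[loci])
    return float(terms.sum())


def _lod_vs_fathers(
    off_calls: np.ndarray,
    dam_calls: np.ndarray,
    father_calls: np.ndarray,
    error_rate: float,
    allele_freqs: np.ndarray,
) -> np.ndarray:
    """(n_off, n_fathers) pair LODs, vectorised over loci and fathers.

    ``dam_calls`` is per-offspring (aligned with off_calls rows).
    """
    n_off, m = off_calls.shape
    n_f = father_calls.shape[0]
    hw = _hw_priors(allele_freqs)
    denom = hw[np.arange(m)[None, :], np.clip(off_calls, 0, 2)]  # (n_off, m)
    lods = np.zeros((n_off, n_f))
    valid_od = (off_calls != MISSING) & (dam_calls != MISSING)
    for fi in range(n_f):
        fc = father_calls[fi]
        valid = valid_od & (fc != MISSING)[None, :]
        t = PAIR_T[
            np.clip(dam_calls, 0, 2), np.clip(fc, 0, 2)[None, :], np.clip(off_calls, 0, 2)
        ]
        num = (1.0 - error_rate) * t + error_rate * denom
        with np.errstate(divide="ignore"):
            terms = np.where(valid, np.log(num) - np.log(denom), 0.0)
        lods[:, fi] = terms.sum(axis=1)
    return lods


def _single_lod_matrix(
    off_calls: np.ndarray,
    parent_calls: np.ndarray,
    error_rate: float,
    allele_freqs: np.ndarray,
) -> np.ndarray:
    """(n_off, n_par) single-parent LODs."""
    n_off, m = off_calls.shape
    hw = _hw_priors(allele_freqs)
    t1 = _single_transmission(allele_freqs)  # (m, 3, 3)
    denom = hw[np.arange(m)[None, :], np.clip(off_calls, 0, 2)]
    out = np.zeros((n_off, parent_calls.shape[0]))
    for pi in range(parent_calls.shape[0]):
        pc = parent_calls[pi]
        valid = (off_calls != MISSING) & (pc != MISSING)[None, :]
        t = t1[np.arange(m)[None, :], np.clip(pc, 0, 2)[None, :], np.clip(off_calls, 0, 2)]
        num = (1.0 - error_rate) * t + error_rate * denom
        with np.errstate(divide="ignore"):
            terms = np.where(valid, np.log(num) - np.log(denom), 0.0)
        out[:, pi] = terms.sum(axis=1)
    return out


def mismatch_fraction(off: np.ndarray, parent: np.ndarray) -> float:
    """Opposite-homozygote fraction over jointly non-missing loci."""
    valid = (off != MISSING) & (parent != MISSING)
    if not valid.any():
        return np.nan
    opp = np.abs(off[valid].astype(int) - parent[valid].astype(int)) == 2
    return float(opp.mean())


@dataclass
class ParentageResult:
    """Per-offspring assignment table.

    status: confirmed | reassigned | clustered_unknown_sire | contaminant |
    unassigned (mothers) / sire_unknown (awaiting clustering).
    """

    table: pd.DataFrame

    def status_counts(self) -> pd.Series:
        return self.table["status"].value_counts()


@dataclass
class DeltaThreshold:
    critical_delta: float
    confidence: float
    n_simulated: int
    error_rate: float
    sampled_fraction: float

    def __post_init__(self):
        if self.critical_delta < 0:
            raise ValueError("critical delta must be >= 0")


def verify_mothers(
    offspring: GenotypeMatrix,
    candidate_mothers: GenotypeMatrix,
    expected_mother: dict[str, str],
    error_rate: float = 0.02,
    mismatch_cut: float = 0.025,
) -> ParentageResult:
    """Confirm or reassign the recorded mother of each offspring.

    Confirmed iff the single-parent LOD against the expected mother is
    positive and the opposite-homozygote mismatch fraction is below
    ``mismatch_cut``; otherwise all candidate mothers are searched and the
    best qualifying one is a reassignment; offspring matching none are
    unassigned (e.g. progeny of an ungenotyped foreign mother).
    """
    freqs = floor_freqs(
        np.nan_to_num(candidate_mothers.allele_freqs(), nan=0.5),
        candidate_mothers.n_individuals,
    )
    lods = _single_lod_matrix(offspring.calls, candidate_mothers.calls, error_rate, freqs)
    midx = {m: i for i, m in enumerate(candidate_mothers.ids)}
    rows = []
    for k, oid in enumerate(offspring.ids):
        exp = expected_mother.get(oid)
        if exp is None or exp not in midx:
            if exp is not None:
                log.warning("expected mother %r of %r not genotyped", exp, oid)
            exp_i = None
        else:
            exp_i = midx[exp]
        chosen, status, lod, mm = None, "unassigned", np.nan, np.nan
        if exp_i is not None:
            mm = mismatch_fraction(offspring.calls[k], candidate_mothers.calls[exp_i])
            lod = lods[k, exp_i]
            if lod > 0 and mm < mismatch_cut:
                chosen, status = exp, "confirmed"
        if chosen is None:
            order = np.argsort(-lods[k], kind="stable")
            for ci in order:
                mm_c = mismatch_fraction(offspring.calls[k], candidate_mothers.calls[ci])
                if lods[k, ci] > 0 and mm_c < mismatch_cut:
                    chosen = candidate_mothers.ids[ci]
                    status = "confirmed" if chosen == exp else "reassigned"
                    lod, mm = lods[k, ci], mm_c
                    break
        rows.append(
            {
                "id": oid,
                "assigned_dam": chosen,
                "lod_dam": lod,
                "mismatch_fraction": mm,
                "status": status,
            }
        )
    return ParentageResult(pd.DataFrame(rows))


def estimate_delta_threshold(
    candidate_fathers: GenotypeMatrix,
    allele_freqs: np.ndarray,
    n_simulated: int = 10_000,
    error_rate: float = 0.02,
    sampled_fraction: float = 0.5,
    confidence: float = 0.95,
    seed: int = 0,
) -> DeltaThreshold:
    """Calibrate the critical delta score by offspring simulation.

    Each simulated offspring has a Hardy-Weinberg dam and a true sire that
    is a genotyped candidate with probability ``sampled_fraction`` (else a
    foreign Hardy-Weinberg genotype); observed offspring calls are
    perturbed at ``error_rate``.  The critical delta is the smallest value
    d such that, among simulated offspring whose best candidate has
    positive LOD and delta >= d, the fraction whose best candidate is the
    true sire reaches ``confidence``.  Zero when even d = 0 qualifies.
    """
    if candidate_fathers.n_individuals < 2:
        raise ValueError("need at least two candidate fathers to calibrate delta")
    rng = np.random.default_rng(seed)
    freqs = floor_freqs(np.asarray(allele_freqs, float), max(candidate_fathers.n_individuals, 1))
    m = len(freqs)
    n_f = candidate_fathers.n_individuals

    dams = rng.binomial(2, freqs, size=(n_simulated, m)).astype(np.int8)
    from_sampled = rng.random(n_simulated) < sampled_fraction
    true_idx = np.where(from_sampled, rng.integers(0, n_f, size=n_simulated), -1)
    sires = np.empty((n_simulated, m), dtype=np.int8)
    sires[from_sampled] = candidate_fathers.calls[true_idx[from_sampled]]
    n_foreign = int((~from_sampled).sum())
    sires[~from_sampled] = rng.binomial(2, freqs, size=(n_foreign, m)).astype(np.int8)

    def gam(g):
        het = g == 1
        out = (g // 2).astype(np.int8)
        out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
        return out

    off = gam(dams) + gam(sires)
    err = rng.random(off.shape) < error_rate
    off[err] = rng.binomial(2, np.broadcast_to(freqs, off.shape)[err]).astype(np.int8)

    lods = _lod_vs_fathers(off, dams, candidate_fathers.calls, error_rate, freqs)
    order = np.argsort(-lods, axis=1, kind="stable")
    best, second = order[:, 0], order[:, 1]
    rowidx = np.arange(n_simulated)
    delta = lods[rowidx, best] - lods[rowidx, second]
    eligible = lods[rowidx, best] > 0
    correct = eligible & (best == true_idx)

    crit = _critical_delta(delta[eligible], correct[eligible], confidence)
    return DeltaThreshold(
        critical_delta=crit,
        confidence=confidence,
        n_simulated=n_simulated,
        error_rate=error_rate,
        sampled_fraction=sampled_fraction,
    )


def _critical_delta(delta: np.ndarray, correct: np.ndarray, confidence: float) -> float:
    """Smallest delta whose at-or-above assignment set is >= confidence correct."""
    if len(delta) == 0:
        return 0.0
    order = np.argsort(-delta, kind="stable")
    d_sorted = delta[order]
    c_cum = np.cumsum(correct[order])
    frac = c_cum / np.arange(1, len(delta) + 1)
    ok = frac >= confidence
    if not ok.any():
        top = d_sorted[np.isfinite(d_sorted)]
        return float(top[0]) + 1e-9 if len(top) else 1e9  # accept none
    if ok[-1]:
        return 0.0  # every assignment qualifies: unambiguous limit
    last = np.where(ok)[0].max()
    d = d_sorted[last]
    if not np.isfinite(d):  # all qualifying deltas are exclusions of the runner-up
        finite = d_sorted[np.isfinite(d_sorted)]
        d = finite[0] if len(finite) else 0.0
    return float(max(d, 0.0))


def assign_paternity(
    offspring: GenotypeMatrix,
    candidate_fathers: GenotypeMatrix,
    dam_assignments: dict[str, str],
    dam_genotypes: GenotypeMatrix,
    threshold: DeltaThreshold,
    allele_freqs: np.ndarray | None = None,
) -> ParentageResult:
    """Assign the best candidate sire where the delta criterion holds.

    The sire is assigned iff delta >= critical_delta, delta > 0 (ties are
    never assigned), the pair LOD of the best candidate exceeds the
    second's, and the sire's own single-parent LOD is positive; otherwise
    the offspring stays sire-unknown for clustering.
    """
    error_rate = threshold.error_rate
    if allele_freqs is None:
        allele_freqs = np.nan_to_num(candidate_fathers.allele_freqs(), nan=0.5)
    freqs = floor_freqs(np.asarray(allele_freqs, float), candidate_fathers.n_individuals)
    didx = {d: i for i, d in enumerate(dam_genotypes.ids)}
    dam_rows = np.array(
        [
            didx.get(dam_assignments.get(oid, ""), -1)
            for oid in offspring.ids
        ]
    )
    known = dam_rows >= 0
    dam_calls = np.full_like(offspring.calls, MISSING)
    dam_calls[known] = dam_genotypes.calls[dam_rows[known]]
    lods = _lod_vs_fathers(offspring.calls, dam_calls, candidate_fathers.calls, error_rate, freqs)
    sire_lods = _single_lod_matrix(offspring.calls, candidate_fathers.calls, error_rate, freqs)
    order = np.argsort(-lods, axis=1, kind="stable")
    rows = []
    for k, oid in enumerate(offspring.ids):
        b, s = order[k, 0], order[k, 1]
        with np.errstate(invalid="ignore"):
            delta = lods[k, b] - lods[k, s]
        if np.isnan(delta):  # both candidates excluded outright
            delta = 0.0
        lod_pair = lods[k, b]
        assign = (
            delta >= threshold.critical_delta
            and delta > 0
            and sire_lods[k, b] > 0
        )
        rows.append(
            {
                "id": oid,
                "assigned_dam": dam_assignments.get(oid),
                "assigned_sire": candidate_fathers.ids[b] if assign else None,
                "lod_pair": lod_pair,
                "delta": delta,
                "lod_sire": sire_lods[k, b],
                "status": "confirmed" if assign else "sire_unknown",
            }
        )
    return ParentageResult(pd.DataFrame(rows))


def cluster_unassigned_sires(
    offspring_ids: list[str],
    relatedness: RelationshipMatrix,
    mother_of: dict[str, str] | None = None,
    half_sib_threshold: float = 0.125,
) -> dict[str, list[str]]:
    """Group sire-unknown offspring into putative paternal families.

    Builds a graph over the offspring with an edge wherever the pairwise
    genomic relatedness — minus the 0.25 expected for maternal half-sibs
    when the two share an assigned mother — exceeds ``half_sib_threshold``
    (default halfway between unrelated and paternal half-sib).  Connected
    components, labelled ``c_1, c_2, ...`` in order of decreasing size
    (ties by smallest member id), are the clusters.
    """
    ids = sorted(offspring_ids)
    if not ids:
        return {}
    sub = relatedness.submatrix(ids)
    g = nx.Graph()
    g.add_nodes_from(ids)
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            rel = sub[i, j]
            if mother_of is not None and mother_of.get(ids[i]) == mother_of.get(ids[j]):
                rel -= 0.25
            if rel > half_sib_threshold:
                g.add_edge(ids[i], ids[j])
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return {f"c_{k + 1}": comp for k, comp in enumerate(comps)}


def flag_contaminants(
    clusters: dict[str, list[str]], min_family_size: int = 7
) -> ParentageResult:
    """Flag clusters smaller than ``min_family_size`` as pollen contamination.

    Large clusters are retained as paternal families of non-genotyped
    polymix fathers; small ones are foreign-pollen events whose offspring
    are excluded from model fitting.
    """
    rows = []
    for label, members in clusters.items():
        contaminant = len(members) < min_family_size
        for oid in members:
            rows.append(
                {
                    "id": oid,
                    "assigned_sire": "foreign" if contaminant else f"unknown cluster {label}",
                    "cluster": label,
                    "cluster_size": len(members),
                    "status": "contaminant" if contaminant else "clustered_unknown_sire",
                }
            )
    df = pd.DataFrame(rows, columns=["id", "assigned_sire", "cluster", "cluster_size", "status"])
    return ParentageResult(df.sort_values("id").reset_index(drop=True))


def test_equal_contribution(father_counts) -> tuple[float, float]:
    """Chi-squared goodness-of-fit of realised sire counts against equal
    male reproductive success (df = n_fathers - 1)."""
    counts = np.asarray(list(father_counts.values()) if isinstance(father_counts, dict) else father_counts, float)
    if len(counts) < 2:
        raise ValueError("need at least two fathers")
    total = counts.sum()
    if total == 0:
        raise ValueError("zero total offspring")
    chi2, p = stats.chisquare(counts)
    return float(chi2), float(p)
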