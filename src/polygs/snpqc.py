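"""SNP quality control and kNN genotype imputation.

Marker filters follow genotyping-array practice for conifer progeny
trials: per-SNP call rate, minor-allele frequency, the per-locus fixation
index F_e = 1 - H_obs / H_exp (a large |F_e| flags paralogous or
clustering-failure SNPs), a Mendelian-incompatibility rate against known
parents, and an exact per-family segregation test.  Missing calls are
imputed with a k-nearest-neighbour scheme whose distance is computed over
the l markers most correlated with the target marker (an LD-ranked
simplification of LD-kNNi), with a masking-based self-reported accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MISSING, GenotypeMatrix, PedigreeTable

log = logging.getLogger(__name__)

#: filter thresholds; a SNP is excluded when call_rate < 0.85, maf < 0.01,
#: |fe| >= 0.50, mendel error rate >= 0.05, or the fraction of families
#: with significant segregation departure exceeds 0.25.
DEFAULT_THRESHOLDS = {
    "min_call_rate": 0.85,
    "min_maf": 0.01,
    "max_abs_fe": 0.50,
    "max_mendel_error": 0.05,
    "max_seg_family_fraction": 0.25,
    "seg_alpha": 0.05,
}


@dataclass
class SnpStats:
    """Per-SNP summary statistics as a DataFrame indexed by SNP id."""

    table: pd.DataFrame  # columns: call_rate, maf, fe [, mendel_error_rate, seg_fraction]

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


@dataclass
class QCReport:
    retained: list[str]
    excluded: dict[str, list[str]]  # snp_id -> list of failed filter names
    thresholds: dict
    per_filter_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if set(self.retained) & set(self.excluded):
            raise ValueError("a SNP cannot be both retained and excluded")
        counts: dict[str, int] = {}
        for reasons in self.excluded.values():
            for r in reasons:
                counts[r] = counts.get(r, 0) + 1
        self.per_filter_counts = counts

    @property
    def n_total(self) -> int:
        return len(self.retained) + len(self.excluded)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"snp_id": s, "retained": True, "failed": ""} for s in self.retained]
        rows += [
            {"snp_id": s, "retained": False, "failed": ",".join(r)}
            for s, r in self.excluded.items()
        ]
        return pd.DataFrame(rows)


def compute_snp_stats(genotypes: GenotypeMatrix) -> SnpStats:
    """Call rate, MAF and fixation index per SNP.

    fe = 1 - H_obs / H_exp with H_exp = 2 p (1 - p); SNPs with no calls
    get call_rate 0 and NaN maf/fe (auto-excluded downstream).
    """
    calls = genotypes.calls
    observed = calls != MISSING
    n_obs = observed.sum(axis=0)
    call_rate = n_obs / genotypes.n_individuals
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, np.where(observed, calls, 0).sum(axis=0) / (2 * np.maximum(n_obs, 1)), np.nan)
        maf = np.minimum(p, 1.0 - p)
        h_obs = np.where(n_obs > 0, (observed & (calls == 1)).sum(axis=0) / np.maximum(n_obs, 1), np.nan)
        h_exp = 2.0 * p * (1.0 - p)
        fe = np.where(h_exp > 0, 1.0 - h_obs / h_exp, np.nan)
    table = pd.DataFrame(
        {"call_rate": call_rate, "maf": maf, "fe": fe}, index=genotypes.snp_ids
    )
    return SnpStats(table)


def filter_snps(stats: SnpStats, thresholds: dict | None = None) -> QCReport:
    """Apply call-rate / MAF / |Fe| filters; a SNP may fail several."""
    thr = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    retained, excluded = [], {}
    for snp, row in stats.table.iterrows():
        reasons = []
        if row["call_rate"] < thr["min_call_rate"]:
            reasons.append("call_rate")
        if np.isnan(row["maf"]):
            reasons.append("all_missing")
        elif row["maf"] < thr["min_maf"]:
            reasons.append("maf")
        if not np.isnan(row["fe"]) and abs(row["fe"]) >= thr["max_abs_fe"]:
            reasons.append("fe")
        if reasons:
            excluded[snp] = reasons
        else:
            retained.append(snp)
    return QCReport(retained=retained, excluded=excluded, thresholds=thr)


# Mendelian transmission support: pair_ok[gd, gs, go] = offspring dosage go
# possible given parent dosages gd, gs; pair_prob gives the Mendelian ratio.
def _transmission_tables():
    gam = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])  # P(transmit alt | dosage)
    prob = np.zeros((3, 3, 3))
    for gd in range(3):
        for gs in range(3):
            for ad in range(2):
                for as_ in range(2):
                    prob[gd, gs, ad + as_] += gam[gd, ad] * gam[gs, as_]
    return prob


PAIR_PROB = _transmission_tables()


def _exact_multinomial_p(counts: np.ndarray, probs: np.ndarray) -> float:
    """Exact multinomial goodness-of-fit p-value (sum of outcomes with
    pmf <= observed pmf).  Counts observed in a zero-probability category
    give p = 0 exactly."""
    counts = np.asarray(counts, int)
    probs = np.asarray(probs, float)
    if np.any((probs == 0) & (counts > 0)):
        return 0.0
    keep = probs > 0
    counts, probs = counts[keep], probs[keep]
    n = counts.sum()
    dist = stats.multinomial(n, probs)
    p_obs = dist.pmf(counts)
    if len(counts) == 1:
        return 1.0
    total = 0.0
    if len(counts) == 2:
        ks = np.arange(n + 1)
        pmfs = dist.pmf(np.column_stack([ks, n - ks]))
        return float(pmfs[pmfs <= p_obs * (1 + 1e-9)].sum())
    # three categories: enumerate compositions
    for i in range(n + 1):
        ks = np.arange(n - i + 1)
        pmfs = dist.pmf(np.column_stack([np.full_like(ks, i), ks, n - i - ks]))
        total += pmfs[pmfs <= p_obs * (1 + 1e-9)].sum()
    return float(min(total, 1.0))


def mendelian_filter(
    offspring: GenotypeMatrix,
    parents: GenotypeMatrix,
    pedigree: PedigreeTable,
    alpha: float = 0.05,
    family_fraction_cut: float = 0.25,
    error_rate_cut: float = 0.05,
    min_family_size: int = 2,
) -> QCReport:
    """Exclude SNPs with high Mendelian-incompatibility rates or recurrent
    segregation departures.

    A comparison is incompatible when the offspring genotype has zero
    Mendelian probability given the genotyped parent(s) (for a single
    parent this is the opposite-homozygote test).  The segregation test is
    an exact multinomial test of offspring genotype counts against the
    Mendelian ratios implied by the parental genotypes, run per full-sib
    family; families with fewer than ``min_family_size`` offspring are
    skipped.  Exclusion when the incompatibility rate >= ``error_rate_cut``
    or the significant-family fraction > ``family_fraction_cut``.
    """
    pidx = {iid: k for k, iid in enumerate(parents.ids)}
    fam_members: dict[tuple, list[int]] = {}
    single: list[tuple[int, int]] = []  # (offspring row, parent row)
    oidx = {iid: k for k, iid in enumerate(offspring.ids)}
    for rec in pedigree.records.itertuples():
        if rec.id not in oidx:
            continue
        o = oidx[rec.id]
        d = pidx.get(rec.dam) if rec.dam is not None else None
        s = pidx.get(rec.sire) if rec.sire is not None else None
        if d is not None and s is not None:
            fam_members.setdefault((d, s), []).append(o)
        elif d is not None:
            single.append((o, d))
        elif s is not None:
            single.append((o, s))

    n_snp = offspring.n_snps
    incompat = np.zeros(n_snp)
    informative = np.zeros(n_snp)
    seg_sig = np.zeros(n_snp)
    seg_families = np.zeros(n_snp)

    oc = offspring.calls
    pc = parents.calls
    for (d, s), members in fam_members.items():
        rows = oc[members]  # (f, m)
        ok = (rows != MISSING) & (pc[d] != MISSING) & (pc[s] != MISSING)
        probs = PAIR_PROB[
            np.clip(pc[d], 0, 2), np.clip(pc[s], 0, 2), np.clip(rows, 0, 2)
        ]
        bad = ok & (probs == 0)
        incompat += bad.sum(axis=0)
        informative += ok.sum(axis=0)
        if len(members) >= min_family_size:
            exp = PAIR_PROB[np.clip(pc[d], 0, 2), np.clip(pc[s], 0, 2)]  # (m, 3)
            for j in range(n_snp):
                if pc[d, j] == MISSING or pc[s, j] == MISSING:
                    continue
                obs = rows[:, j]
                obs = obs[obs != MISSING]
                if len(obs) < min_family_size:
                    continue
                counts = np.bincount(obs, minlength=3)
                seg_families[j] += 1
                if _exact_multinomial_p(counts, exp[j]) < alpha:
                    seg_sig[j] += 1
        else:
            log.debug("family %s skipped from segregation test (<%d offspring)",
                      (d, s), min_family_size)
    for o, pr in single:
        ok = (oc[o] != MISSING) & (pc[pr] != MISSING)
        opp = ok & (np.abs(oc[o].astype(int) - pc[pr].astype(int)) == 2)
        incompat += opp
        informative += ok

    with np.errstate(invalid="ignore", divide="ignore"):
        err_rate = np.where(informative > 0, incompat / np.maximum(informative, 1), 0.0)
        seg_frac = np.where(seg_families > 0, seg_sig / np.maximum(seg_families, 1), 0.0)
    retained, excluded = [], {}
    for j, snp in enumerate(offspring.snp_ids):
        reasons = []
        if informative[j] > 0 and err_rate[j] >= error_rate_cut:
            reasons.append("mendel_error")
        if seg_families[j] > 0 and seg_frac[j] > family_fraction_cut:
            reasons.append("segregation")
        if reasons:
            excluded[snp] = reasons
        else:
            retained.append(snp)
    thr = {
        "alpha": alpha,
        "family_fraction_cut": family_fraction_cut,
        "error_rate_cut": error_rate_cut,
    }
    report = QCReport(retained=retained, excluded=excluded, thresholds=thr)
    report.mendel_error_rate = pd.Series(err_rate, index=offspring.snp_ids)
    report.seg_departure_family_fraction = pd.Series(seg_frac, index=offspring.snp_ids)
    return report


def _impute_matrix(calls: np.ndarray, missing_mask: np.ndarray, k: int, l: int) -> np.ndarray:
    """Fill masked entries in-place on a copy; see :func:`impute_knn`."""
    n, m = calls.shape
    out = calls.copy()
    work = calls.astype(float)
    work[missing_mask] = np.nan
    col_mean = np.nanmean(work, axis=0)
    col_mean = np.where(np.isnan(col_mean), 1.0, col_mean)
    filled = np.where(np.isnan(work), col_mean, work)
    centred = filled - filled.mean(axis=0)
    norms = np.sqrt((centred**2).sum(axis=0))
    norms[norms == 0] = 1.0
    unit = centred / norms
    modes = np.zeros(m, dtype=np.int8)
    for j in range(m):
        obs = calls[~missing_mask[:, j], j]
        if len(obs):
            modes[j] = np.bincount(obs, minlength=3).argmax()
    for j in np.where(missing_mask.any(axis=0))[0]:
        # l markers most squared-correlated with marker j (excluding itself)
        r2 = (unit.T @ unit[:, j]) ** 2
        r2[j] = -np.inf
        panel = np.argsort(-r2, kind="stable")[:l]
        donors = np.where(~missing_mask[:, j])[0]
        targets = np.where(missing_mask[:, j])[0]
        if len(donors) == 0:
            out[targets, j] = modes[j]
            log.warning("marker %d has no observed donors; filled with mode", j)
            continue
        dist = (
            (filled[np.ix_(targets, panel)][:, None, :] - filled[np.ix_(donors, panel)][None, :, :])
            ** 2
        ).sum(axis=2)
        kk = min(k, len(donors))
        for t, ti in enumerate(targets):
            nearest = donors[np.argsort(dist[t], kind="stable")[:kk]]
            votes = np.bincount(calls[nearest, j], minlength=3)
            out[ti, j] = votes.argmax()
    return out


def impute_knn(
    genotypes: GenotypeMatrix,
    k: int = 5,
    l: int = 20,
    n_mask: int = 10_000,
    seed: int = 0,
) -> tuple[GenotypeMatrix, float]:
    """Impute missing calls from the modal genotype of the k nearest
    individuals, distance measured over the l markers most correlated with
    the target marker.

    Self-reported accuracy masks ``n_mask`` observed calls at random,
    imputes them with the same scheme, and scores the exact-match
    fraction.  Observed calls are never altered.
    """
    missing = genotypes.calls == MISSING
    frac = missing.mean()
    if frac >= 0.5:
        raise ValueError(f"missing fraction {frac:.2f} too high to impute")
    rng = np.random.default_rng(seed)
    obs_rows, obs_cols = np.where(~missing)
    n_mask = min(n_mask, len(obs_rows))
    pick = rng.choice(len(obs_rows), size=n_mask, replace=False)
    mask_eval = missing.copy()
    mask_eval[obs_rows[pick], obs_cols[pick]] = True
    imputed_eval = _impute_matrix(genotypes.calls, mask_eval, k, l)
    truth = genotypes.calls[obs_rows[pick], obs_cols[pick]]
    guess = imputed_eval[obs_rows[pick], obs_cols[pick]]
    accuracy = float((truth == guess).mean()) if n_mask else 1.0

    if missing.any():
        filled = _impute_matrix(genotypes.calls, missing, k, l)
    else:
        filled = genotypes.calls.copy()
    out = GenotypeMatrix(ids=list(genotypes.ids), snp_ids=list(genotypes.snp_ids), calls=filled)
    return out, accuracy


def mode_impute(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Baseline: fill every missing call with the marker's modal genotype."""
    calls = genotypes.calls.copy()
    for j in range(genotypes.n_snps):
        col = calls[:, j]
        obs = col[col != MISSING]
        if len(obs):
            col[col == MISSING] = np.bincount(obs, minlength=3).argmax()
        else:
            col[col == MISSING] = 1
    return GenotypeMatrix(ids=list(genotypes.ids), snp_ids=list(genotypes.snp_ids), calls=calls)
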