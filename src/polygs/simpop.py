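"""Synthetic breeding-population generator.

Emulates two white-spruce progeny-test designs so the full analysis chain
(QC, parentage recovery, relationship matrices, REML, cross-validation,
gain reporting) can be exercised with known truth:

* a **polycross**: each of ``n_mothers`` females pollinated with a common
  polymix of ``n_polymix_fathers`` males whose realised contributions are
  unequal (Dirichlet-distributed) and contaminated at a small rate by
  foreign pollen;
* a **partial diallel**: biparental full-sib crosses confined to breeding
  groups.

Markers are simulated unlinked, each at Hardy-Weinberg proportions for a
frequency drawn from ``maf_range``.  Traits follow the individual-tree
mixed model: phenotype = mean + site + block(site) + additive value +
site-specific additive deviation + residual, with component variances set
from the target narrow-sense heritability and type-B (across-site
genetic) correlation of each trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, PedigreeTable, TraitTable


@dataclass(frozen=True)
class TraitSpec:
    """Target genetic architecture for one trait.

    h2 is the narrow-sense heritability sigma2_a / (sigma2_a + sigma2_sa +
    sigma2_e); r_b the type-B correlation sigma2_a / (sigma2_a + sigma2_sa);
    mean and cv_percent set the phenotypic scale (sd = mean * cv / 100).
    """

    name: str
    h2: float
    r_b: float
    mean: float
    cv_percent: float
    dominance_fraction: float = 0.0  # sigma2_d as a fraction of sigma2_a

    def __post_init__(self):
        if not 0.0 < self.h2 < 1.0:
            raise ValueError(f"target h2 must be in (0,1), got {self.h2}")
        if not 0.0 < self.r_b <= 1.0:
            raise ValueError(f"target r_B must be in (0,1], got {self.r_b}")
        if self.mean == 0:
            raise ValueError("phenotypic mean must be non-zero")

    def variance_components(self) -> dict[str, float]:
        sigma_p2 = (self.mean * self.cv_percent / 100.0) ** 2
        s_a = self.h2 * sigma_p2
        s_sa = s_a * (1.0 / self.r_b - 1.0)
        s_e = sigma_p2 - s_a - s_sa
        if s_e <= 0:
            raise ValueError(
                f"trait {self.name!r}: h2={self.h2}, r_B={self.r_b} leave no "
                "residual variance"
            )
        return {
            "sigma2_a": s_a,
            "sigma2_sa": s_sa,
            "sigma2_e": s_e,
            "sigma2_d": self.dominance_fraction * s_a,
            "sigma2_p": sigma_p2,
        }


#: Default trait panel: growth and wood-quality traits of a mature spruce
#: progeny trial (means/CVs on their usual measurement scales; h2 and r_B
#: in the moderate range typical of GBLUP estimates for such trials).
DEFAULT_TRAITS = (
    TraitSpec("height", 0.20, 0.60, 941.4, 20.5),
    TraitSpec("dbh", 0.21, 0.70, 132.4, 23.0),
    TraitSpec("volume", 0.22, 0.65, 61.2, 58.2),
    TraitSpec("velocity", 0.41, 0.92, 3.3, 13.8),
    TraitSpec("density", 0.37, 0.99, 374.1, 7.8),
)


@dataclass
class SimConfig:
    """All knobs of the generator; the same seed reproduces every draw."""

    n_mothers: int = 38
    n_polymix_fathers: int = 19
    n_shared_parents: int = 3  # parents crossed both as female and as male
    offspring_per_mother: int = 23
    male_skew: float = 3.0  # Dirichlet concentration; +inf => equal contributions
    contamination_rate: float = 0.026
    contaminant_reuse_prob: float = 0.2
    n_snp: int = 4092
    maf_range: tuple[float, float] = (0.01, 0.5)
    #: fraction of each additive variance tagged by the genotyped markers;
    #: the remainder is an infinitesimal (pedigree-transmitted) polygenic
    #: tier the SNP panel cannot see (one SNP per gene locus does not
    #: capture all genic variation)
    marker_tagged_fraction: float = 0.7
    n_sites: int = 3
    n_blocks: int = 4
    trait_specs: tuple[TraitSpec, ...] = DEFAULT_TRAITS
    genotyping_error_rate: float = 0.001
    missing_rate: float = 0.002
    # diallel-specific defaults (54 crosses over 42 parents in 3 groups)
    n_crosses: int = 54
    n_diallel_parents: int = 42
    n_groups: int = 3
    family_size: int = 28
    seed: int = 0

    def __post_init__(self):
        for name in ("contamination_rate", "genotyping_error_rate", "missing_rate",
                     "marker_tagged_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.n_shared_parents > min(self.n_mothers, self.n_polymix_fathers):
            raise ValueError("n_shared_parents exceeds a parent pool")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))

    @property
    def mother_ids(self) -> list[str]:
        return [f"M{i + 1:03d}" for i in range(self.n_mothers)]

    @property
    def father_ids(self) -> list[str]:
        """Polymix ids; the last n_shared_parents coincide with mothers."""
        own = [f"F{i + 1:03d}" for i in range(self.n_polymix_fathers - self.n_shared_parents)]
        shared = self.mother_ids[: self.n_shared_parents]
        return own + shared


@dataclass
class TruePedigree:
    """Ground-truth parentage of simulated offspring."""

    dam: dict[str, str]
    sire: dict[str, str]
    contaminant: dict[str, bool]
    father_counts: dict[str, int]

    @property
    def offspring_ids(self) -> list[str]:
        return list(self.dam)

    def to_table(self, include_parents: tuple[str, ...] = ()) -> PedigreeTable:
        rows = [(p, None, None) for p in include_parents]
        rows += [(o, self.dam[o], self.sire[o]) for o in self.dam]
        return PedigreeTable.from_tuples(rows)


@dataclass
class TraitArchitecture:
    """Realised per-trait genetic architecture (marker-effect mode).

    Marker effects are drawn i.i.d. normal with variance
    sigma2_a / (2 sum_j p_j q_j), the calibration that makes the additive
    values of a non-inbred pedigree have base-population variance sigma2_a
    and covariance sigma2_a * A_ij in expectation (unlinked loci, founders
    at Hardy-Weinberg).  Site-specific deviations use independent effect
    vectors calibrated the same way against sigma2_sa.  Component
    variances are therefore stated on the founder (base-population) scale,
    the reference a pedigree analysis estimates.
    """

    snp_effects: dict[str, np.ndarray]  # trait -> per-SNP additive effects
    site_effects: dict[str, np.ndarray]  # trait -> fixed site means
    block_effects: dict[str, np.ndarray]  # trait -> (site, block) effects
    components: dict[str, dict[str, float]]  # trait -> variance components


# ---------------------------------------------------------------------------
# parents and matings


def simulate_parents(config: SimConfig) -> GenotypeMatrix:
    """Draw founder genotypes at Hardy-Weinberg proportions.

    One frequency per SNP is drawn uniformly from ``maf_range``; each
    parent's dosage is Binomial(2, p).  Parents carry no missing calls.
    """
    rng = config.rng(stream=1)
    ids = list(dict.fromkeys(config.mother_ids + config.father_ids))
    p = rng.uniform(*config.maf_range, size=config.n_snp)
    calls = rng.binomial(2, p, size=(len(ids), config.n_snp)).astype(np.int8)
    snp_ids = [f"snp{j + 1:05d}" for j in range(config.n_snp)]
    return GenotypeMatrix(ids=ids, snp_ids=snp_ids, calls=calls)


def _mendelian_gametes(geno: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted allele per locus from dosage-coded parent rows."""
    # dosage 0 -> transmit 0; 2 -> 1; 1 -> Bernoulli(1/2)
    het = geno == 1
    gam = (geno // 2).astype(np.int8)
    gam[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return gam


def _apply_observation_model(
    calls: np.ndarray, freqs: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Genotyping error (call replaced by a Hardy-Weinberg draw) then missingness."""
    out = calls.copy()
    if config.genotyping_error_rate > 0:
        err = rng.random(out.shape) < config.genotyping_error_rate
        redraw = rng.binomial(2, np.broadcast_to(freqs, out.shape)[err]).astype(np.int8)
        out[err] = redraw
    if config.missing_rate > 0:
        miss = rng.random(out.shape) < config.missing_rate
        out[miss] = MISSING
    return out


def simulate_polycross(
    parents: GenotypeMatrix, config: SimConfig
) -> tuple[GenotypeMatrix, TruePedigree]:
    """Mate every mother to the shared polymix with skewed male success.

    A single paternal-contribution vector is drawn for the whole
    realisation from a symmetric Dirichlet with concentration
    ``male_skew`` (``inf`` forces exactly equal probabilities).  Each
    offspring is independently contaminated with probability
    ``contamination_rate``, in which case its sire is a foreign genotype
    simulated from the founder allele frequencies (re-used across events
    with probability ``contaminant_reuse_prob``, mimicking a single
    foreign tree shedding pollen over several maternal families).
    """
    if config.n_polymix_fathers < 1:
        raise ValueError("polycross requires at least one polymix father")
    rng = config.rng(stream=2)
    mothers = config.mother_ids
    fathers = config.father_ids
    freqs = parents.allele_freqs()

    if np.isinf(config.male_skew):
        contrib = np.full(len(fathers), 1.0 / len(fathers))
    else:
        contrib = rng.dirichlet(np.full(len(fathers), config.male_skew))

    par_rows = {iid: parents.calls[k] for k, iid in enumerate(parents.ids)}
    foreign: list[tuple[str, np.ndarray]] = []
    off_ids, dams, sires, flags, rows = [], [], [], [], []
    for mi, mother in enumerate(mothers):
        for oi in range(config.offspring_per_mother):
            oid = f"O{mi + 1:03d}_{oi + 1:03d}"
            contaminated = rng.random() < config.contamination_rate
            if contaminated:
                if foreign and rng.random() < config.contaminant_reuse_prob:
                    sire, sire_geno = foreign[rng.integers(len(foreign))]
                else:
                    sire = f"X{len(foreign) + 1:03d}"
                    sire_geno = rng.binomial(2, freqs).astype(np.int8)
                    foreign.append((sire, sire_geno))
            else:
                sire = fathers[rng.choice(len(fathers), p=contrib)]
                sire_geno = par_rows[sire]
            geno = _mendelian_gametes(par_rows[mother], rng) + _mendelian_gametes(
                sire_geno, rng
            )
            off_ids.append(oid)
            dams.append(mother)
            sires.append(sire)
            flags.append(contaminated)
            rows.append(geno)

    calls = _apply_observation_model(np.array(rows, dtype=np.int8), freqs, config, rng)
    counts: dict[str, int] = {f: 0 for f in fathers}
    for s, flag in zip(sires, flags):
        if not flag:
            counts[s] += 1
    ped = TruePedigree(
        dam=dict(zip(off_ids, dams)),
        sire=dict(zip(off_ids, sires)),
        contaminant=dict(zip(off_ids, flags)),
        father_counts=counts,
    )
    geno = GenotypeMatrix(ids=off_ids, snp_ids=parents.snp_ids, calls=calls)
    return geno, ped


def make_cross_list(config: SimConfig, rng=None) -> list[tuple[str, str, str, int]]:
    """Generate a within-group partial-diallel cross list.

    Parents are dealt into ``n_groups`` breeding groups; crosses pair
    distinct parents within a group, cycling so each parent is used at
    least once and no pair repeats.
    """
    rng = rng or config.rng(stream=3)
    ids = [f"P{i + 1:03d}" for i in range(config.n_diallel_parents)]
    groups: dict[str, list[str]] = {
        f"G{g + 1}": ids[g :: config.n_groups] for g in range(config.n_groups)
    }
    crosses = []
    per_group = [config.n_crosses // config.n_groups] * config.n_groups
    for g in range(config.n_crosses % config.n_groups):
        per_group[g] += 1
    for (gname, members), want in zip(groups.items(), per_group):
        seen = set()
        k = 0
        step = 1
        while len([c for c in crosses if c[2] == gname]) < want:
            dam = members[k % len(members)]
            sire = members[(k + step) % len(members)]
            k += 1
            if k % len(members) == 0:
                step += 1
            if dam == sire or (dam, sire) in seen or (sire, dam) in seen:
                continue
            seen.add((dam, sire))
            crosses.append((dam, sire, gname, config.family_size))
    return crosses


def simulate_diallel(
    parents: GenotypeMatrix,
    config: SimConfig,
    cross_list: list[tuple[str, str, str, int]] | None = None,
) -> tuple[GenotypeMatrix, TruePedigree]:
    """Full-sib families from a (generated or supplied) within-group cross list.

    ``cross_list`` rows are (dam, sire, group, family_size).  Supplying a
    cross pairing parents from different groups raises; so does a
    non-positive family size.  Note the parent pool here is its own set of
    diallel founders unless a cross list over ``parents.ids`` is supplied.
    """
    rng = config.rng(stream=4)
    if cross_list is None:
        ids = [f"P{i + 1:03d}" for i in range(config.n_diallel_parents)]
        p = rng.uniform(*config.maf_range, size=config.n_snp)
        calls = rng.binomial(2, p, size=(len(ids), config.n_snp)).astype(np.int8)
        parents = GenotypeMatrix(ids=ids, snp_ids=[f"snp{j + 1:05d}" for j in range(config.n_snp)], calls=calls)
        cross_list = make_cross_list(config, rng)
    group_of: dict[str, str] = {}
    for dam, sire, group, size in cross_list:
        if size <= 0:
            raise ValueError(f"family size must be positive, got {size} for {dam}x{sire}")
        for parent in (dam, sire):
            if group_of.setdefault(parent, group) != group:
                raise ValueError(
                    f"cross {dam}x{sire} pairs parents across breeding groups"
                )
    freqs = parents.allele_freqs()
    par_rows = {iid: parents.calls[k] for k, iid in enumerate(parents.ids)}
    off_ids, dams, sires, groups_, rows = [], [], [], [], []
    for ci, (dam, sire, group, size) in enumerate(cross_list):
        for oi in range(size):
            off_ids.append(f"D{ci + 1:03d}_{oi + 1:03d}")
            dams.append(dam)
            sires.append(sire)
            groups_.append(group)
            rows.append(
                _mendelian_gametes(par_rows[dam], rng)
                + _mendelian_gametes(par_rows[sire], rng)
            )
    calls = _apply_observation_model(np.array(rows, dtype=np.int8), freqs, config, rng)
    counts: dict[str, int] = {}
    for s in sires:
        counts[s] = counts.get(s, 0) + 1
    ped = TruePedigree(
        dam=dict(zip(off_ids, dams)),
        sire=dict(zip(off_ids, sires)),
        contaminant={o: False for o in off_ids},
        father_counts=counts,
    )
    geno = GenotypeMatrix(ids=off_ids, snp_ids=parents.snp_ids, calls=calls)
    geno.group_of = dict(zip(off_ids, groups_))  # design factor carried alongside
    return geno, ped


# ---------------------------------------------------------------------------
# phenotypes


def build_architecture(
    genotypes: GenotypeMatrix, config: SimConfig, rng=None
) -> TraitArchitecture:
    """Draw marker effects and design effects for every configured trait.

    Site means are fixed effects with spread 0.3 x phenotypic SD and block
    (within site) effects with spread 0.1 x phenotypic SD — large enough
    that ignoring them would visibly bias the genetic analysis, small
    enough to stay trial-like.
    """
    rng = rng or config.rng(stream=5)
    snp_effects, site_effects, block_effects, components = {}, {}, {}, {}
    for spec in config.trait_specs:
        comps = spec.variance_components()
        sigma_p = np.sqrt(comps["sigma2_p"])
        snp_effects[spec.name] = rng.standard_normal(genotypes.n_snps)
        site_effects[spec.name] = rng.normal(0.0, 0.3 * sigma_p, size=config.n_sites)
        block_effects[spec.name] = rng.normal(
            0.0, 0.1 * sigma_p, size=(config.n_sites, config.n_blocks)
        )
        components[spec.name] = comps
    return TraitArchitecture(snp_effects, site_effects, block_effects, components)


def _gene_drop_values(
    pedigree: "TruePedigree", offspring_ids: list[str], variance: float, rng
) -> np.ndarray:
    """Infinitesimal additive values: founders ~ N(0, v), offspring =
    parent average + Mendelian sampling N(0, v/2)."""
    founders = sorted(
        {pedigree.dam[o] for o in offspring_ids}
        | {pedigree.sire[o] for o in offspring_ids}
    )
    sd = np.sqrt(variance)
    fval = dict(zip(founders, rng.normal(0.0, sd, size=len(founders))))
    ms = rng.normal(0.0, np.sqrt(variance / 2.0), size=len(offspring_ids))
    return np.array(
        [0.5 * (fval[pedigree.dam[o]] + fval[pedigree.sire[o]]) for o in offspring_ids]
    ) + ms


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    arch: TraitArchitecture,
    config: SimConfig,
    pedigree: "TruePedigree | None" = None,
    true_calls: np.ndarray | None = None,
    group_of: dict[str, str] | None = None,
    rng=None,
    return_truth: bool = False,
):
    """Phenotype = mean + site + block(site) + a + sa + (d) + e.

    Additive values have two tiers: a marker-tagged part (mean-centred
    dosage x effect, base-population variance scale — see
    :class:`TraitArchitecture`) carrying ``marker_tagged_fraction`` of the
    additive variance, and, when the true pedigree is supplied, an
    infinitesimal polygenic part transmitted through the pedigree (founder
    values plus Mendelian sampling) carrying the remainder — emulating a
    SNP panel that tags most but not all genic variation.  Site-specific
    additive deviations are built the same two-tier way against sigma2_sa,
    independently per site, realising the target type-B correlation.
    Individuals are assigned to sites and blocks family-agnostically at
    random.  ``true_calls`` lets the caller pass pre-error genotypes so
    the observation model does not leak into the genetic values.
    """
    rng = rng or config.rng(stream=6)
    f_tag = config.marker_tagged_fraction if pedigree is not None else 1.0
    calls = true_calls if true_calls is not None else genotypes.calls
    calls = np.where(calls == MISSING, 1, calls).astype(float)
    n = genotypes.n_individuals
    site = rng.integers(0, config.n_sites, size=n)
    block = rng.integers(0, config.n_blocks, size=n)

    centred = calls - calls.mean(axis=0)
    p_hat = np.clip(calls.mean(axis=0) / 2.0, 1e-6, 1 - 1e-6)
    sum2pq = float(2.0 * np.sum(p_hat * (1.0 - p_hat)))
    data = {
        "id": genotypes.ids,
        "site": [f"S{s + 1}" for s in site],
        "block": [f"B{b + 1}" for b in block],
    }
    if group_of is not None:
        data["group"] = [group_of[i] for i in genotypes.ids]
    truth: dict[str, np.ndarray] = {}
    for spec in config.trait_specs:
        comps = arch.components[spec.name]
        a = centred @ arch.snp_effects[spec.name] * np.sqrt(
            f_tag * comps["sigma2_a"] / sum2pq
        )
        if f_tag < 1.0:
            a = a + _gene_drop_values(
                pedigree, genotypes.ids, (1.0 - f_tag) * comps["sigma2_a"], rng
            )
        if comps["sigma2_sa"] > 0:
            scale_sa = np.sqrt(f_tag * comps["sigma2_sa"] / sum2pq)
            sa_all = np.empty((config.n_sites, n))
            for s in range(config.n_sites):
                eff = rng.standard_normal(genotypes.n_snps)
                sa_all[s] = centred @ eff * scale_sa
                if f_tag < 1.0:
                    sa_all[s] += _gene_drop_values(
                        pedigree, genotypes.ids,
                        (1.0 - f_tag) * comps["sigma2_sa"], rng,
                    )
            sa = sa_all[site, np.arange(n)]
        else:
            sa = np.zeros(n)
        if comps["sigma2_d"] > 0:
            q_hat = 1.0 - p_hat
            w = np.empty_like(calls)
            w[:] = (-2.0 * p_hat**2)[None, :]
            w[calls == 1] = (2.0 * p_hat * q_hat)[np.where(calls == 1)[1]]
            w[calls == 2] = (-2.0 * q_hat**2)[np.where(calls == 2)[1]]
            denom_d = float(np.sum((2.0 * p_hat * q_hat) ** 2))
            d = w @ rng.standard_normal(genotypes.n_snps) * np.sqrt(
                comps["sigma2_d"] / denom_d
            )
        else:
            d = np.zeros(n)
        e = rng.normal(0.0, np.sqrt(comps["sigma2_e"]), size=n)
        y = (
            spec.mean
            + arch.site_effects[spec.name][site]
            + arch.block_effects[spec.name][site, block]
            + a
            + sa
            + d
            + e
        )
        data[spec.name] = y
        truth[spec.name] = a
    table = TraitTable(pd.DataFrame(data))
    if return_truth:
        return table, truth
    return table


def compute_volume(height_m, dbh_cm):
    """Stem volume without bark (dm^3) from height (m) and DBH (cm).

    The regional allometric model 0.0344 * DBH^1.8329 * Height^1.1793.
    """
    height_m = np.asarray(height_m, dtype=float)
    dbh_cm = np.asarray(dbh_cm, dtype=float)
    if np.any(height_m <= 0) or np.any(dbh_cm <= 0):
        raise ValueError("height and DBH must be positive")
    out = 0.0344 * dbh_cm**1.8329 * height_m**1.1793
    return float(out) if out.ndim == 0 else out
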