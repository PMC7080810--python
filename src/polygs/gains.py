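"""Expected genetic gain from forward selection and diversity of the
selected set.

Gain is the mean cross-validated GEBV of the top-fraction selections
expressed as a percentage of the phenotypic mean, corrected by the
predictive accuracy (PACC) from cross-validation, and standardised per
year by the time to deployment (7 years for a polycross scheme whose
crosses take 2 years; 9 for a partial-diallel scheme).  The status number
of the selected set tracks how much diversity selection retains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .datatypes import RelationshipMatrix
from .kinship import group_coancestry

YEARS_POLYCROSS = 7
YEARS_FULLSIB = 9


@dataclass
class GainReport:
    trait: str
    fraction: float
    years: float
    gain_pct: float
    gain_pct_se: float
    corrected_gain_pct: float
    corrected_gain_pct_se: float
    gain_per_year_pct: float
    gain_per_year_pct_se: float
    status_number: float | None
    n_selected: int
    per_rep: pd.DataFrame = field(repr=False, default=None)


def select_top(gebvs: pd.Series, fraction: float) -> list[str]:
    """Ids of the ceil(fraction * n) individuals with highest GEBV.

    GEBVs must be cross-validated (no-own-phenotype) predictions for the
    forward-selection reading of gain.  Ties are broken by id order so
    selection is deterministic.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("selection fraction must be in (0, 1]")
    if len(gebvs) == 0:
        raise ValueError("no candidates to select from")
    n_sel = ceil(fraction * len(gebvs))
    ordered = sorted(gebvs.index, key=lambda i: (-gebvs[i], str(i)))
    return list(ordered[:n_sel])


def expected_gain(
    gebvs_per_rep: list[pd.Series],
    phenotypic_mean: float,
    pacc: float,
    years: float,
    fraction: float = 0.05,
    trait: str = "",
    relationships: RelationshipMatrix | None = None,
) -> GainReport:
    """Gain report averaged over cross-validation repetitions.

    Per repetition: gain% = 100 x mean(selected GEBV) / phenotypic mean;
    corrected gain% = gain% x PACC; gain per year = corrected / years.
    Standard errors are across-repetition standard errors.  When a
    relationship matrix is supplied, the status number of the selected
    set is averaged over repetitions too.
    """
    if phenotypic_mean == 0:
        raise ZeroDivisionError("phenotypic mean is zero; percent gain undefined")
    rows = []
    for rep, gebvs in enumerate(gebvs_per_rep):
        sel = select_top(gebvs, fraction)
        gain = 100.0 * float(gebvs.loc[sel].mean()) / phenotypic_mean
        ns = (
            group_coancestry(relationships, subset=sel).status_number
            if relationships is not None
            else np.nan
        )
        rows.append(
            {
                "rep": rep,
                "gain_pct": gain,
                "corrected_gain_pct": gain * pacc,
                "gain_per_year_pct": gain * pacc / years,
                "status_number": ns,
                "n_selected": len(sel),
            }
        )
    per_rep = pd.DataFrame(rows)
    nrep = len(per_rep)
    se = lambda c: float(per_rep[c].std(ddof=1) / np.sqrt(nrep)) if nrep > 1 else 0.0
    return GainReport(
        trait=trait,
        fraction=fraction,
        years=years,
        gain_pct=float(per_rep["gain_pct"].mean()),
        gain_pct_se=se("gain_pct"),
        corrected_gain_pct=float(per_rep["corrected_gain_pct"].mean()),
        corrected_gain_pct_se=se("corrected_gain_pct"),
        gain_per_year_pct=float(per_rep["gain_per_year_pct"].mean()),
        gain_per_year_pct_se=se("gain_per_year_pct"),
        status_number=float(per_rep["status_number"].mean()) if relationships is not None else None,
        n_selected=int(per_rep["n_selected"].iloc[0]),
        per_rep=per_rep,
    )


def selection_diversity(selected: list[str], relationships: RelationshipMatrix) -> float:
    """Status number of the selected set (delegates to group coancestry)."""
    return group_coancestry(relationships, subset=selected).status_number
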