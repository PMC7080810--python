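"""Core in-memory containers shared across the pipeline.

Genotypes are alt-allele dosages in {0, 1, 2} with -1 marking a missing
call; pedigrees are per-individual dam/sire links where ``None`` (or the
string ``"0"``/empty in files) marks an unknown parent; phenotypes live in
a plain :class:`pandas.DataFrame` with ``id``, ``site``, ``block``,
optional ``group`` factor columns followed by one column per trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic SNPs, coded as alt-allele dosage 0/1/2.

    ``calls`` is an int8 array with :data:`MISSING` (-1) for no-calls.
    """

    ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.ids)} ids x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype call {self.calls[i, j]} at "
                f"individual {self.ids[i]!r}, SNP {self.snp_ids[j]!r}"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def index_of(self, ids) -> np.ndarray:
        lookup = {iid: k for k, iid in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise KeyError(f"unknown individual id {exc.args[0]!r}") from exc

    def subset(self, ids=None, snp_ids=None) -> "GenotypeMatrix":
        rows = self.index_of(ids) if ids is not None else np.arange(self.n_individuals)
        if snp_ids is not None:
            slookup = {s: k for k, s in enumerate(self.snp_ids)}
            cols = np.array([slookup[s] for s in snp_ids], dtype=int)
        else:
            cols = np.arange(self.n_snps)
        return GenotypeMatrix(
            ids=[self.ids[r] for r in rows],
            snp_ids=[self.snp_ids[c] for c in cols],
            calls=self.calls[np.ix_(rows, cols)].copy(),
        )

    def allele_freqs(self) -> np.ndarray:
        """Alt-allele frequency per SNP over non-missing calls (NaN if none)."""
        calls = self.calls.astype(float)
        calls[self.calls == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(calls, axis=0) / 2.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.calls, index=self.ids, columns=self.snp_ids)
        return df.mask(df == MISSING)


@dataclass
class PedigreeTable:
    """Per-individual parent links; either parent may be unknown (None)."""

    records: pd.DataFrame  # columns: id, dam, sire  (object dtype, None = unknown)

    @classmethod
    def from_tuples(cls, tuples) -> "PedigreeTable":
        df = pd.DataFrame(tuples, columns=["id", "dam", "sire"])
        return cls(df)

    def __post_init__(self) -> None:
        df = self.records
        need = {"id", "dam", "sire"}
        if not need.issubset(df.columns):
            raise ValueError(f"pedigree needs columns {sorted(need)}")
        df = df[["id", "dam", "sire"]].copy()
        for col in df.columns:
            df[col] = df[col].astype(object)
            df.loc[df[col].isin(["", "0", 0, np.nan]) | df[col].isna(), col] = None
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate pedigree entry for id {dup!r}")
        self.records = df.reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return list(self.records["id"])

    def parents_of(self, iid):
        row = self.records.loc[self.records["id"] == iid]
        if row.empty:
            return (None, None)
        return (row["dam"].iloc[0], row["sire"].iloc[0])

    def mask_sires(self) -> "PedigreeTable":
        """Partial-pedigree variant: keep dams, drop all sire links."""
        df = self.records.copy()
        df["sire"] = None
        return PedigreeTable(df)


#: factor columns recognised in a phenotype table; everything else numeric is a trait
FACTOR_COLS = ("id", "site", "block", "group")


@dataclass
class TraitTable:
    """Phenotypes with site/block/(breeding-)group design factors."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("id", "site", "block"):
            if col not in df.columns:
                raise ValueError(f"phenotype table needs column {col!r}")
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicated phenotype row for id {dup!r}")
        df = df.copy()
        for col in ("site", "block", "group"):
            if col in df.columns:
                df[col] = df[col].astype(str)
        self.data = df.reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return list(self.data["id"])

    @property
    def trait_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in FACTOR_COLS]

    @property
    def has_group(self) -> bool:
        return "group" in self.data.columns and self.data["group"].nunique() > 1

    def subset(self, ids) -> "TraitTable":
        sel = self.data[self.data["id"].isin(set(ids))]
        return TraitTable(sel.reset_index(drop=True))


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix tagged by kind (A_partial, A_full, G, D)."""

    ids: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        lookup = {iid: k for k, iid in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not in relationship matrix") from exc

    def submatrix(self, ids) -> np.ndarray:
        idx = self.index_of(ids)
        return self.values[np.ix_(idx, idx)]

    def inbreeding(self) -> np.ndarray:
        """F_i = diagonal - 1 (meaningful for additive kinds)."""
        return np.diag(self.values) - 1.0

    def conditioned(self, weight: float = 0.99) -> "RelationshipMatrix":
        """Blend with the identity (weight*K + (1-weight)*I) to guarantee
        invertibility; only needed by consumers that invert K itself."""
        vals = weight * self.values + (1.0 - weight) * np.eye(self.n)
        return RelationshipMatrix(self.ids, vals, self.kind)
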