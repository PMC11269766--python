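"""Co-dominant multilocus genotype tables.

Alleles are positive integer labels; 0 marks a missing allele call.  A
genotype is an unordered allele pair per locus, with either both alleles
observed or both missing.  Tables round-trip through a GenAlEx-style CSV
layout: one row per individual with ``id``, ``population``, ``window``
columns followed by two columns per locus (``<locus>_1``, ``<locus>_2``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GenotypeTable"]


@dataclass
class GenotypeTable:
    ids: np.ndarray                  # (n,) individual labels
    pops: np.ndarray                 # (n,) population / patch labels
    windows: np.ndarray              # (n,) landscape-window labels
    alleles: np.ndarray              # (n, n_loci, 2) int, 0 = missing
    locus_names: tuple[str, ...] = ()
    years: np.ndarray | None = None  # optional sampling year per individual

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.pops = np.asarray(self.pops)
        self.windows = np.asarray(self.windows)
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n = len(self.ids)
        if self.alleles.shape[0] != n or self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n, n_loci, 2)")
        if not self.locus_names:
            self.locus_names = tuple(f"L{i+1}" for i in range(self.alleles.shape[1]))
        half_missing = (self.alleles == 0).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("a genotype must have both alleles present or both missing")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def populations(self) -> list:
        seen: dict = {}
        for p in self.pops:
            seen.setdefault(p, None)
        return list(seen)

    def subset(self, mask: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(
            self.ids[mask], self.pops[mask], self.windows[mask],
            self.alleles[mask], self.locus_names,
            None if self.years is None else self.years[mask],
        )

    def for_pop(self, pop) -> "GenotypeTable":
        return self.subset(self.pops == pop)

    def for_window(self, window) -> "GenotypeTable":
        return self.subset(self.windows == window)

    def total_distinct_alleles(self) -> int:
        """Number of distinct observed alleles summed over loci."""
        return int(sum(
            len(np.unique(self.alleles[:, l, :][self.alleles[:, l, :] > 0]))
            for l in range(self.n_loci)
        ))

    # ---- CSV I/O -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        cols = {"id": self.ids, "population": self.pops, "window": self.windows}
        if self.years is not None:
            cols["year"] = self.years
        for l, name in enumerate(self.locus_names):
            cols[f"{name}_1"] = self.alleles[:, l, 0]
            cols[f"{name}_2"] = self.alleles[:, l, 1]
        return pd.DataFrame(cols)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeTable":
        for col in ("id", "population", "window"):
            if col not in df.columns:
                raise ValueError(f"genotype table missing required column {col!r}")
        locus_cols = [c for c in df.columns if c.endswith("_1")]
        loci = [c[:-2] for c in locus_cols]
        for name in loci:
            if f"{name}_2" not in df.columns:
                raise ValueError(f"locus {name!r} lacks its second allele column")
        n = len(df)
        alleles = np.zeros((n, len(loci), 2), dtype=np.int64)
        for l, name in enumerate(loci):
            a1 = pd.to_numeric(df[f"{name}_1"], errors="coerce")
            a2 = pd.to_numeric(df[f"{name}_2"], errors="coerce")
            if a1.isna().any() or a2.isna().any():
                bad = int((a1.isna() | a2.isna()).idxmax())
                raise ValueError(f"non-numeric allele call at row {bad}, locus {name!r}")
            alleles[:, l, 0] = a1.to_numpy()
            alleles[:, l, 1] = a2.to_numpy()
        years = df["year"].to_numpy() if "year" in df.columns else None
        return cls(
            df["id"].to_numpy(), df["population"].to_numpy(),
            df["window"].to_numpy(), alleles, tuple(loci), years,
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "GenotypeTable":
        return cls.from_frame(pd.read_csv(path))
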