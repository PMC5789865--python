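"""Risk-allele dosage matrix shared by every pipeline stage.

Genotypes are stored as risk-allele dosages (0, 1 or 2 copies of the risk
allele) in a float array with ``NaN`` marking missing calls, one row per
sample and one column per SNP marker. Each sample carries a population
label so downstream stages can stratify without re-joining metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix"]


@dataclass
class GenotypeMatrix:
    """Samples x markers risk-allele dosages with population labels.

    Parameters
    ----------
    dosages
        Float array of shape ``(n_samples, n_markers)`` with values in
        ``{0, 1, 2}`` and ``NaN`` for missing genotypes.
    sample_ids
        Unique sample identifiers, one per row.
    rsids
        Marker identifiers, one per column.
    populations
        Population label per sample. Defaults to ``"pop"`` for all.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    rsids: list[str]
    populations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array (samples x markers)")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.rsids) != m:
            raise ValueError(f"{len(self.rsids)} rsids for {m} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if not self.populations:
            self.populations = ["pop"] * n
        if len(self.populations) != n:
            raise ValueError("one population label required per sample")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def marker_index(self, rsid: str) -> int:
        try:
            return self.rsids.index(rsid)
        except ValueError:
            raise KeyError(f"marker {rsid!r} not in matrix") from None

    def subset(
        self,
        sample_idx: np.ndarray | list[int] | None = None,
        marker_idx: np.ndarray | list[int] | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given row/column indices."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(si, mi)].copy(),
            sample_ids=[self.sample_ids[i] for i in si],
            rsids=[self.rsids[j] for j in mi],
            populations=[self.populations[i] for i in si],
        )

    def select_markers(self, rsids: list[str]) -> "GenotypeMatrix":
        return self.subset(marker_idx=[self.marker_index(r) for r in rsids])

    def by_population(self) -> dict[str, "GenotypeMatrix"]:
        pops = np.asarray(self.populations)
        return {
            label: self.subset(sample_idx=np.flatnonzero(pops == label))
            for label in dict.fromkeys(self.populations)
        }

    def allele_frequencies(self) -> np.ndarray:
        """Risk-allele frequency per marker from non-missing calls (NaN if none)."""
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Mean of empty slice")
            return np.nanmean(self.dosages, axis=0) / 2.0

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.rsids)
        df.insert(0, "population", self.populations)
        df.index.name = "sample_id"
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        pops = df["population"].tolist() if "population" in df.columns else []
        dose = df.drop(columns=["population"], errors="ignore")
        return cls(
            dosages=dose.to_numpy(dtype=float),
            sample_ids=[str(s) for s in dose.index],
            rsids=[str(c) for c in dose.columns],
            populations=[str(p) for p in pops],
        )

    @classmethod
    def concat_samples(cls, parts: list["GenotypeMatrix"]) -> "GenotypeMatrix":
        """Stack cohorts sharing the same marker set."""
        first = parts[0]
        for p in parts[1:]:
            if p.rsids != first.rsids:
                raise ValueError("marker sets differ between cohorts")
        return cls(
            dosages=np.vstack([p.dosages for p in parts]),
            sample_ids=[s for p in parts for s in p.sample_ids],
            rsids=list(first.rsids),
            populations=[q for p in parts for q in p.populations],
        )
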