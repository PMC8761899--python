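"""Genotype matrix container shared by the simulation and QC modules.

Genotypes of near-inbred lines at biallelic SNPs are coded as the dose of
the alternate allele: 0 (homozygous reference), 1 (residual heterozygote),
2 (homozygous alternate). Missing calls are stored as NaN in a float array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan


@dataclass
class GenotypeMatrix:
    """Lines x markers allele-dose matrix with marker and line metadata.

    Parameters
    ----------
    values
        Float array of shape ``(n_lines, n_markers)`` holding values in
        ``{0, 1, 2}`` with NaN for missing calls.
    line_ids
        Line identifiers, length ``n_lines``.
    populations
        Population label per line (e.g. the cross each RIL belongs to).
    markers
        DataFrame with columns ``id``, ``chrom``, ``pos`` (one row per
        marker, in column order of ``values``).
    """

    values: np.ndarray
    line_ids: np.ndarray
    populations: np.ndarray
    markers: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = np.asarray(self.line_ids)
        self.populations = np.asarray(self.populations)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D lines x markers array")
        n_lines, n_markers = self.values.shape
        if len(self.line_ids) != n_lines or len(self.populations) != n_lines:
            raise ValueError("line metadata length does not match matrix")
        if len(self.markers) != n_markers:
            raise ValueError("marker metadata length does not match matrix")
        observed = self.values[~np.isnan(self.values)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype values must be in {0, 1, 2} or missing")

    # -- basic properties -------------------------------------------------
    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def marker_ids(self) -> np.ndarray:
        return self.markers["id"].to_numpy()

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def missing_rate_per_marker(self) -> np.ndarray:
        return self.missing_mask.mean(axis=0)

    def missing_rate_per_line(self) -> np.ndarray:
        return self.missing_mask.mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0) / 2.0

    def minor_allele_freq(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    # -- selection --------------------------------------------------------
    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values[:, index],
            self.line_ids,
            self.populations,
            self.markers.iloc[np.asarray(index)].reset_index(drop=True),
        )

    def take_lines(self, index: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(index)
        return GenotypeMatrix(
            self.values[idx], self.line_ids[idx], self.populations[idx], self.markers
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values.copy(),
            self.line_ids.copy(),
            self.populations.copy(),
            self.markers.copy(),
        )

    # -- I/O ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Lines as rows, marker ids as columns."""
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.marker_ids)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.insert(0, "population", self.populations)
        df.to_csv(path, sep="\t", index_label="line")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="line")
        populations = df.pop("population").to_numpy()
        ids = df.columns.to_numpy()
        chrom, pos = _parse_marker_ids(ids)
        markers = pd.DataFrame({"id": ids, "chrom": chrom, "pos": pos})
        return cls(df.to_numpy(dtype=float), df.index.to_numpy(), populations, markers)


def _parse_marker_ids(ids) -> tuple[np.ndarray, np.ndarray]:
    """Recover (chrom, pos) from ids of the form ``chrom_pos``; fall back to chrU."""
    chrom, pos = [], []
    for mid in ids:
        head, _, tail = str(mid).rpartition("_")
        if head and tail.isdigit():
            chrom.append(head)
            pos.append(int(tail))
        else:
            chrom.append("chrU")
            pos.append(0)
    return np.asarray(chrom), np.asarray(pos)
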