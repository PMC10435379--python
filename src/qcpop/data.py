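"""Core in-memory containers shared by every pipeline stage.

Genotypes are held as a dense ``int8`` sample x variant matrix counting copies
of the declared counted allele (``allele1``), with ``-1`` for missing calls.
Variant and sample annotations travel alongside as pandas DataFrames, the way
a PLINK fileset pairs .bed with .bim/.fam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

#: columns required in the variant map (``.bim``-equivalent)
VARIANT_COLUMNS = ["id", "chrom", "pos", "allele1", "allele2"]

#: columns required in the sample manifest (``.fam``-equivalent, extended)
SAMPLE_COLUMNS = ["id", "sex"]


@dataclass
class GenotypeDataset:
    """Sample x variant genotype calls plus variant map and sample manifest.

    Parameters
    ----------
    calls
        ``(n_samples, n_variants)`` int8 array with values {0, 1, 2, -1};
        counts of ``allele1`` per variant, -1 meaning missing.
    variants
        DataFrame with at least :data:`VARIANT_COLUMNS`; ``pos`` is 1-based.
        May carry ``probeset``, ``array_version`` etc.
    samples
        DataFrame with at least :data:`SAMPLE_COLUMNS`; may carry ``region``,
        ``plate``, ``well``, ``box``, ``batch``, ``age`` etc.
    """

    calls: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (samples x variants)")
        if self.calls.shape[0] != len(self.samples):
            raise ValueError(
                f"calls has {self.calls.shape[0]} rows but manifest lists "
                f"{len(self.samples)} samples"
            )
        if self.calls.shape[1] != len(self.variants):
            raise ValueError(
                f"calls has {self.calls.shape[1]} columns but variant map "
                f"lists {len(self.variants)} variants"
            )
        for col in VARIANT_COLUMNS:
            if col not in self.variants.columns:
                raise ValueError(f"variant map missing column {col!r}")
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample manifest missing column {col!r}")
        bad = ~np.isin(self.calls, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("calls contain values outside {-1, 0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of the counted allele per variant (NaN if all missing)."""
        g = np.ma.masked_equal(self.calls, MISSING)
        with np.errstate(invalid="ignore"):
            af = g.mean(axis=0).filled(np.nan) / 2.0
        return np.asarray(af, dtype=float)

    def call_rate(self, axis: int = 0) -> np.ndarray:
        """Fraction of non-missing calls per variant (axis=0) or sample (axis=1)."""
        return 1.0 - (self.calls == MISSING).mean(axis=axis)

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeDataset":
        """Row/column subset keeping manifests aligned (indices or boolean masks)."""
        s = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        v = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        if s.dtype == bool:
            s = np.flatnonzero(s)
        if v.dtype == bool:
            v = np.flatnonzero(v)
        return GenotypeDataset(
            calls=self.calls[np.ix_(s, v)],
            variants=self.variants.iloc[v].reset_index(drop=True),
            samples=self.samples.iloc[s].reset_index(drop=True),
        )

    def autosomal_mask(self) -> np.ndarray:
        chrom = self.variants["chrom"].astype(str)
        return ~chrom.isin(["X", "Y", "23", "24", "MT", "XY", "25", "26"]).to_numpy()


@dataclass
class GeneticMap:
    """Per-chromosome recombination map: position (bp) -> cumulative cM.

    ``tables`` maps chromosome name to a DataFrame with strictly increasing
    ``pos`` (bp) and non-decreasing ``cm`` columns.
    """

    tables: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, tab in self.tables.items():
            pos = np.asarray(tab["pos"], dtype=float)
            cm = np.asarray(tab["cm"], dtype=float)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"map positions not strictly increasing on {chrom}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"map cM not non-decreasing on {chrom}")

    def interpolate(self, chrom, positions) -> np.ndarray:
        """Genetic position in cM at ``positions`` (linear, clamped at ends)."""
        key = str(chrom)
        if key not in self.tables:
            raise KeyError(f"chromosome {chrom!r} not covered by the genetic map")
        tab = self.tables[key]
        return np.interp(
            np.asarray(positions, dtype=float),
            np.asarray(tab["pos"], dtype=float),
            np.asarray(tab["cm"], dtype=float),
        )

    def chrom_length_cm(self, chrom) -> float:
        tab = self.tables[str(chrom)]
        return float(np.asarray(tab["cm"])[-1] - np.asarray(tab["cm"])[0])

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for chrom, tab in self.tables.items():
            f = pd.DataFrame({"chrom": chrom, "pos": tab["pos"], "cm": tab["cm"]})
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneticMap":
        tables = {
            str(chrom): grp[["pos", "cm"]].reset_index(drop=True)
            for chrom, grp in frame.groupby("chrom", sort=False)
        }
        return cls(tables=tables)

    @classmethod
    def uniform(cls, chrom_sizes: dict, cm_per_mb: float = 1.0) -> "GeneticMap":
        """Constant-rate map: ``chrom_sizes`` maps chromosome -> length in bp."""
        tables = {}
        for chrom, size in chrom_sizes.items():
            tables[str(chrom)] = pd.DataFrame(
                {"pos": [1.0, float(size)], "cm": [0.0, size / 1e6 * cm_per_mb]}
            )
        return cls(tables=tables)
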