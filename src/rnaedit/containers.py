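"""Core in-memory containers shared across the pipeline.

Coordinates are 0-based half-open internally; exported site tables are
1-based (column ``pos_1based``), which is stated in their headers.
All base counts are expressed on the *transcribed* strand: counts from
reads over a minus-strand gene are complemented before being stored, so
an A-to-I editing event always appears as an A→G mismatch here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Required columns of a site table.
SITE_COLUMNS = ["contig", "pos", "strand", "ref_base"]


def complement(base: str) -> str:
    return COMPLEMENT[base]


@dataclass
class BaseCountMatrix:
    """Per-site, per-sample base counts on the transcribed strand.

    Attributes
    ----------
    sites:
        DataFrame with columns ``contig``, ``pos`` (0-based), ``strand``
        (strand of the owning gene), ``ref_base`` (reference base on the
        transcribed strand).
    counts:
        int array of shape ``(n_sites, n_samples, 4)`` in A,C,G,T order,
        on the transcribed strand.
    samples:
        sample identifiers, one per column.
    """

    sites: pd.DataFrame
    counts: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        missing = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValueError(f"site table lacks columns: {missing}")
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[2] != 4:
            raise ValueError("counts must have shape (n_sites, n_samples, 4)")
        if self.counts.shape[0] != len(self.sites):
            raise ValueError("counts and site table disagree on n_sites")
        if self.counts.shape[1] != len(self.samples):
            raise ValueError("counts and sample list disagree on n_samples")
        if (self.counts < 0).any():
            raise ValueError("negative base counts")
        dup = self.sites.duplicated(subset=["contig", "pos"])
        if dup.any():
            raise ValueError("duplicate site positions per contig")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def coverage(self) -> np.ndarray:
        """(n_sites, n_samples) total read coverage, = A+C+G+T."""
        return self.counts.sum(axis=2)

    def base(self, base: str) -> np.ndarray:
        """(n_sites, n_samples) counts of a single base."""
        return self.counts[:, :, BASE_INDEX[base]]

    @property
    def ref_codes(self) -> np.ndarray:
        return self.sites["ref_base"].map(BASE_INDEX).to_numpy()

    def subset_sites(self, index) -> "BaseCountMatrix":
        idx = np.asarray(index)
        return BaseCountMatrix(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            counts=self.counts[idx],
            samples=list(self.samples),
        )


@dataclass
class EditingMatrix:
    """Sites × samples editing indices with a validity mask.

    ``values`` holds g/(a+g) per cell as a fraction; cells where the
    denominator is zero, or where the sample was excluded at the site
    (multi-editing filter), are NaN. ``samples`` carries per-sample
    metadata with at least a ``sample`` column and optionally ``tissue``
    and ``group``.
    """

    values: np.ndarray
    sites: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sites = self.sites.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        if self.values.shape != (len(self.sites), len(self.samples)):
            raise ValueError("values shape does not match sites × samples")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise ValueError("editing indices must lie in [0, 1]")
        if "sample" not in self.samples.columns:
            raise ValueError("sample metadata needs a 'sample' column")
        if self.samples["sample"].duplicated().any():
            raise ValueError("duplicate sample ids")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_means(self) -> np.ndarray:
        """Per-site mean over valid cells; NaN when no cell is valid."""
        with np.errstate(invalid="ignore"):
            out = np.full(self.n_sites, np.nan)
            valid = np.isfinite(self.values)
            any_valid = valid.any(axis=1)
            out[any_valid] = np.nanmean(self.values[any_valid], axis=1)
        return out

    def column_order(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples["sample"])}
        try:
            return np.array([lookup[s] for s in sample_ids])
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from exc
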