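"""Core containers shared across pipeline stages.

The community table is a thin, validated wrapper around a pandas DataFrame in
samples x taxa orientation; sample metadata ("sample frame") is a plain
DataFrame indexed by sample ID with design factors and soil covariates.
Distance matrices use :class:`skbio.DistanceMatrix` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Soil covariates carried by every sample frame (mg/kg except OM, in %).
SOIL_VARS = ("TN", "TP", "NH4_N", "NO3_N", "AP", "OM", "AK")

#: Design factors carried by every sample frame.
FACTOR_VARS = ("plant", "year", "replicate")


@dataclass
class CommunityTable:
    """Abundance matrix of samples x taxa with optional taxonomy strings.

    Parameters
    ----------
    counts
        DataFrame with sample IDs as index and taxon IDs as columns;
        entries are non-negative counts (or abundances).
    taxonomy
        Optional mapping taxon ID -> taxonomy string.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValidationError("community table contains negative entries")
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate sample IDs")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicate taxon IDs")
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalize counts to relative abundances (zero rows stay zero)."""
        totals = self.counts.sum(axis=1)
        safe = totals.replace(0, 1)
        return self.counts.div(safe, axis=0)

    def subset_samples(self, sample_ids) -> "CommunityTable":
        missing = set(sample_ids) - set(self.counts.index)
        if missing:
            raise ValidationError(f"unknown sample IDs: {sorted(missing)}")
        return CommunityTable(self.counts.loc[list(sample_ids)].copy(), self.taxonomy)

    def drop_empty_taxa(self) -> "CommunityTable":
        keep = self.counts.columns[self.counts.sum(axis=0) > 0]
        return CommunityTable(self.counts[keep].copy(), self.taxonomy)


def validate_sample_frame(frame: pd.DataFrame, table: CommunityTable | None = None) -> pd.DataFrame:
    """Check a sample frame's contract; returns the frame for chaining.

    Requires unique sample IDs, finite soil covariates, and (if a community
    table is supplied) an exact ID match with it.
    """
    if frame.index.has_duplicates:
        raise ValidationError("duplicate sample IDs in sample frame")
    present = [v for v in SOIL_VARS if v in frame.columns]
    if present:
        vals = frame[present].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite soil covariates")
    if table is not None:
        missing = set(table.sample_ids) - set(frame.index.astype(str))
        extra = set(frame.index.astype(str)) - set(table.sample_ids)
        if missing or extra:
            raise ValidationError(
                f"sample frame / community table ID mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
    return frame


def group_labels(frame: pd.DataFrame, by=("plant", "year")) -> pd.Series:
    """Concatenate design factors into a single group label per sample.

    The default (plant, year) grouping yields the study's eight
    plant-by-year communities (e.g. ``grass_y1`` ... ``legume_y4``).
    """
    parts = [frame[b].astype(str) for b in by]
    lab = parts[0]
    for p in parts[1:]:
        lab = lab.str.cat(p, sep="_y" if p.name == "year" else "_")
    return lab.rename("group")
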