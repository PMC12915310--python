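"""Profile matrices: GCF presence/absence and metabolite feature tables.

The metabolome container pairs a samples x features abundance matrix with a
feature-metadata table (m/z, retention time, MS2 flag, pathway category) and a
sample-metadata table (strain, medium, source, clade), mirroring the shape of
an MZmine quantification export plus its sidecar annotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "build_presence",
    "filter_ms2",
    "normalize",
    "aggregate_by_strain",
    "category_composition",
    "read_feature_table",
]

NORMALIZE_METHODS = ("tic", "log1p_tic", "none")


@dataclass
class FeatureTable:
    data: pd.DataFrame  # samples x features, nonnegative
    feature_meta: pd.DataFrame  # indexed by feature id: mz, rt, has_ms2, category
    sample_meta: pd.DataFrame  # indexed by sample id: strain, medium, source, clade

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundances must be nonnegative")
        if not self.data.columns.equals(self.feature_meta.index):
            missing = set(self.data.columns) ^ set(self.feature_meta.index)
            raise ValueError(f"feature metadata mismatch: {sorted(missing)[:5]}")
        if not self.data.index.equals(self.sample_meta.index):
            missing = set(self.data.index) ^ set(self.sample_meta.index)
            raise ValueError(f"sample metadata mismatch: {sorted(missing)[:5]}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


def build_presence(bgc_records: pd.DataFrame) -> pd.DataFrame:
    """Strain x GCF binary presence from a BGC table with family membership.

    An entry is 1 iff the strain carries at least one BGC of that family;
    multiplicity is deliberately discarded. Families with no member in any
    strain simply have no column.
    """
    if "gcf_id" not in bgc_records.columns:
        raise ValueError("BGC table has no gcf_id column")
    missing = bgc_records[bgc_records["gcf_id"].isna()]
    if len(missing):
        raise ValueError(
            "BGCs missing gcf_id: " + ", ".join(missing["bgc_id"].astype(str).head(10))
        )
    table = pd.crosstab(bgc_records["genome_id"], bgc_records["gcf_id"])
    presence = (table > 0).astype(np.int64)
    presence.index.name = None
    presence.columns.name = None
    return presence.sort_index(axis=0).sort_index(axis=1)


def filter_ms2(table: FeatureTable) -> FeatureTable:
    """Keep only features with an MS/MS fragmentation spectrum."""
    if table.feature_meta["has_ms2"].isna().any():
        raise ValueError("has_ms2 undefined for some features")
    keep = table.feature_meta.index[table.feature_meta["has_ms2"].astype(bool)]
    if len(keep) == 0:
        warnings.warn("MS2 filter removed every feature", stacklevel=2)
    return FeatureTable(
        data=table.data.loc[:, keep],
        feature_meta=table.feature_meta.loc[keep],
        sample_meta=table.sample_meta,
    )


def normalize(table: FeatureTable, method: str = "log1p_tic") -> FeatureTable:
    """Total-ion-current scaling per sample, optionally followed by log1p.

    ``tic`` rescales each sample row to unit sum (all-zero rows are left
    untouched with a warning); ``log1p_tic`` additionally applies log1p;
    ``none`` is the identity.
    """
    if method not in NORMALIZE_METHODS:
        raise ValueError(f"unknown normalization {method!r}; choose from {NORMALIZE_METHODS}")
    if method == "none":
        return table
    values = table.data.to_numpy(dtype=float).copy()
    sums = values.sum(axis=1)
    zero = sums == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero sample row(s) left unscaled", stacklevel=2
        )
    values[~zero] /= sums[~zero, None]
    if method == "log1p_tic":
        values = np.log1p(values)
    return replace(table, data=pd.DataFrame(values, index=table.data.index, columns=table.data.columns))


def aggregate_by_strain(table: FeatureTable) -> FeatureTable:
    """Collapse samples to one row per strain (arithmetic mean per feature).

    Needed when a strain-level metabolome is compared against a strain-level
    tree: each strain's samples across media are averaged. Sample metadata is
    collapsed to the strain-level fields (source, clade).
    """
    strains = table.sample_meta["strain"]
    if strains.isna().any():
        raise ValueError("sample without strain assignment")
    data = table.data.groupby(strains).mean()
    meta = (
        table.sample_meta.groupby(strains)
        .agg({"source": "first", "clade": "first"})
        .assign(strain=lambda df: df.index)
    )
    data.index.name = None
    meta.index.name = None
    return FeatureTable(data=data, feature_meta=table.feature_meta, sample_meta=meta)


def category_composition(feature_meta: pd.DataFrame) -> pd.DataFrame:
    """Count and percentage of features per pathway category.

    Uncategorized features fall into ``unknown`` with a warning. Percentages
    are full precision; round only at presentation.
    """
    cats = feature_meta["category"].copy()
    n_missing = int(cats.isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} uncategorized feature(s) assigned 'unknown'", stacklevel=2)
        cats = cats.fillna("unknown")
    counts = cats.value_counts().sort_index()
    total = int(counts.sum())
    out = pd.DataFrame({"count": counts})
    out["percent"] = 100.0 * out["count"] / total
    out.index.name = "category"
    return out


def read_feature_table(
    quant_csv: str, feature_meta_tsv: str, sample_meta_tsv: str
) -> FeatureTable:
    """Read an MZmine-style quantification CSV plus metadata sidecars.

    The quantification file may be oriented either way; feature ids are taken
    from the metadata sidecar to disambiguate.
    """
    data = pd.read_csv(quant_csv, index_col=0)
    feature_meta = pd.read_csv(feature_meta_tsv, sep="\t", index_col=0)
    sample_meta = pd.read_csv(sample_meta_tsv, sep="\t", index_col=0)
    if set(data.index) <= set(feature_meta.index):  # features in rows -> transpose
        data = data.T
    data = data.loc[sample_meta.index, feature_meta.index]
    return FeatureTable(data=data, feature_meta=feature_meta, sample_meta=sample_meta)
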