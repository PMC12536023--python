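"""Desikan-Killiany micro-region to lobe (macro-region) mapping and
PAF aggregation.

The 68 cortical parcels of the Desikan-Killiany atlas are grouped into
10 macro-regions — frontal, parietal, temporal, occipital and cingulate
per hemisphere — and per-parcel PAF estimates are averaged within each
macro-region over the parcels that produced a valid (in-band) peak.  A
macro-region with no valid parcel is missing, not zero.

The insula, which the five-lobe scheme does not place, is assigned to
the temporal macro-region by adjacency; ship your own two-column table
to override.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "MACRO_LOBES",
    "RegionMap",
    "load_region_map",
    "aggregate_macro",
    "validity_proportion",
]

MACRO_LOBES = ("cingulate", "frontal", "occipital", "parietal", "temporal")
#: parcels per lobe in one hemisphere (insula counted as temporal)
EXPECTED_LOBE_COUNTS = {
    "frontal": 11,
    "parietal": 5,
    "temporal": 10,
    "occipital": 4,
    "cingulate": 4,
}


@dataclass(frozen=True)
class RegionMap:
    """Lookup from (micro_region, hemisphere) to macro-region."""

    table: pd.DataFrame  # columns: micro_region, hemisphere, macro_region

    def __post_init__(self) -> None:
        t = self.table
        required = {"micro_region", "hemisphere", "macro_region"}
        if not required.issubset(t.columns):
            raise ValueError(f"region map must have columns {sorted(required)}")
        if len(t) != 68:
            raise ValueError(f"region map must have exactly 68 entries, got {len(t)}")
        if t.duplicated(["micro_region", "hemisphere"]).any():
            raise ValueError("duplicate micro-region entries in region map")
        macros = t.groupby(["hemisphere", "macro_region"]).size()
        if len(macros) != 10:
            raise ValueError("region map must target exactly 10 macro-regions")
        left = t[t.hemisphere == "left"].set_index("micro_region")["macro_region"]
        right = t[t.hemisphere == "right"].set_index("micro_region")["macro_region"]
        if not left.sort_index().equals(right.sort_index()):
            raise ValueError("left/right assignments must be mirror-symmetric")

    @property
    def macro_regions(self) -> list[str]:
        """The 10 macro-region labels, e.g. 'temporal_left'."""
        return sorted(
            f"{m}_{h}"
            for h in ("left", "right")
            for m in self.table[self.table.hemisphere == h].macro_region.unique()
        )

    def micro_count(self, macro: str, hemisphere: str) -> int:
        t = self.table
        return int(((t.macro_region == macro) & (t.hemisphere == hemisphere)).sum())

    def lookup(self, micro_region: str, hemisphere: str) -> str:
        t = self.table
        hit = t[(t.micro_region == micro_region) & (t.hemisphere == hemisphere)]
        if hit.empty:
            raise KeyError(f"unknown region {micro_region!r} ({hemisphere})")
        return hit.macro_region.iloc[0]


def load_region_map(path: str | None = None) -> RegionMap:
    """Load the built-in Desikan-Killiany lobe map, or an override file."""
    if path is None:
        ref = resources.files("pafreact.data").joinpath("dk_region_map.tsv")
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep=None, engine="python")
    return RegionMap(table=table.reset_index(drop=True))


def aggregate_macro(
    micro_estimates: pd.DataFrame, region_map: RegionMap | None = None
) -> pd.DataFrame:
    """Average valid micro-region PAF estimates within macro-regions.

    ``micro_estimates`` needs columns ``micro_region``, ``hemisphere`` and
    ``paf_hz`` (NaN marks an absent peak), plus any grouping identifiers
    (``subject``, ``condition`` ...), which are carried through.  Returns
    one row per group x macro-region with the mean of the valid estimates
    (``paf_hz`` NaN when no parcel was valid) and the validity counts.
    """
    region_map = region_map or load_region_map()
    df = micro_estimates.copy()
    known = region_map.table.set_index(["micro_region", "hemisphere"])["macro_region"]
    keys = pd.MultiIndex.from_frame(df[["micro_region", "hemisphere"]])
    missing = ~keys.isin(known.index)
    if missing.any():
        bad = df.loc[missing, ["micro_region", "hemisphere"]].drop_duplicates()
        raise KeyError(f"unknown region labels: {bad.to_records(index=False).tolist()}")
    df["macro_region"] = known.loc[keys].to_numpy()
    df["region"] = df["macro_region"] + "_" + df["hemisphere"]

    group_cols = [
        c for c in ("subject", "diagnosis", "condition") if c in df.columns
    ] + ["hemisphere", "macro_region", "region"]
    out = (
        df.groupby(group_cols, sort=True, dropna=False)["paf_hz"]
        .agg(paf_hz="mean", n_valid_micro="count", n_total_micro="size")
        .reset_index()
    )
    out["n_valid_micro"] = out["n_valid_micro"].astype(int)
    out["n_total_micro"] = out["n_total_micro"].astype(int)
    return out


def validity_proportion(
    micro_estimates: pd.DataFrame,
    region_map: RegionMap | None = None,
    by: tuple[str, ...] = ("diagnosis", "condition"),
) -> pd.DataFrame:
    """Percentage of micro-region estimates with a valid in-band peak.

    The denominator for one macro-region is (number of parcels in the
    macro-region) x (number of participants in the group); the numerator
    counts estimates with non-missing ``paf_hz``.
    """
    region_map = region_map or load_region_map()
    if micro_estimates.empty:
        raise ValueError("no estimates to summarize")
    df = micro_estimates.copy()
    known = region_map.table.set_index(["micro_region", "hemisphere"])["macro_region"]
    keys = pd.MultiIndex.from_frame(df[["micro_region", "hemisphere"]])
    df["macro_region"] = known.loc[keys].to_numpy()
    df["region"] = df["macro_region"] + "_" + df["hemisphere"]
    cols = [c for c in by if c in df.columns] + ["region"]
    out = (
        df.groupby(cols, sort=True)["paf_hz"]
        .agg(n_valid="count", n_total="size")
        .reset_index()
    )
    out["valid_pct"] = 100.0 * out["n_valid"] / out["n_total"]
    return out
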