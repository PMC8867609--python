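"""Sample- and site-level quality filters for read-level data.

Three filters with strict boundary semantics:

* conversion: samples with bisulfite conversion rate < 0.95 are removed
  (whole-sample);
* depth: (sample, region) pairs with fewer than 100 reads are removed;
* site missingness: CpG sites whose pooled fraction of 'N' calls across
  retained samples exceeds 0.30 are dropped from site-level statistics.

Conversion and depth are independent criteria (their order does not
change the surviving set); site missingness depends on which samples
survive and is applied last. All filters are idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import ReadPatternSet, RegionPanel, SampleMeta
from .regionstats import sample_beta_frame

REASONS = ("low_conversion", "low_depth", "high_missing", "pass")

DEFAULT_MIN_CONVERSION = 0.95
DEFAULT_MIN_DEPTH = 100
DEFAULT_MAX_SITE_MISSING = 0.30


@dataclass
class QCReport:
    """Outcome of the QC filters.

    ``sample_records``: one row per (sample_id, region_id) with depth,
    conversion_rate, kept flag and reason. ``site_records``: one row per
    (region_id, position) with the pooled missing fraction and kept flag.
    """

    sample_records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample_id", "region_id", "depth", "conversion_rate",
                     "kept", "reason"]
        )
    )
    site_records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["region_id", "position", "missing_fraction", "kept"]
        )
    )

    def kept_sample_regions(self) -> set[tuple[str, str]]:
        df = self.sample_records
        return set(
            zip(df.loc[df["kept"], "sample_id"], df.loc[df["kept"], "region_id"])
        )

    def site_mask(self, panel: RegionPanel) -> np.ndarray:
        df = self.site_records
        sub = df[df["region_id"] == panel.region_id].set_index("position")
        return np.array(
            [bool(sub.loc[p, "kept"]) if p in sub.index else True
             for p in panel.cpg_positions]
        )


def filter_conversion(
    meta: Mapping[str, SampleMeta],
    threshold: float = DEFAULT_MIN_CONVERSION,
) -> set[str]:
    """Sample ids removed for conversion rate strictly below *threshold*."""
    missing = [sid for sid, m in meta.items() if m.conversion_rate is None]
    if missing:
        raise ValidationError(
            f"conversion_rate missing for samples: {sorted(missing)}"
        )
    return {sid for sid, m in meta.items() if m.conversion_rate < threshold}


def filter_depth(
    rps: ReadPatternSet,
    threshold: int = DEFAULT_MIN_DEPTH,
) -> set[tuple[str, str]]:
    """(sample, region) pairs with total read count strictly below *threshold*."""
    depth = rps.depth_table()
    low = depth[depth["depth"] < threshold]
    return set(zip(low["sample_id"], low["region_id"]))


def site_missing_fractions(
    rps: ReadPatternSet,
    panel: RegionPanel,
    sample_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Pooled per-site fraction of 'N' calls over all covering reads."""
    df = rps.region_entries(panel.region_id, sample_ids)
    L = panel.n_cpgs
    n_calls = np.zeros(L, dtype=np.int64)
    total = 0
    for pattern, count in zip(df["pattern"], df["count"]):
        arr = np.frombuffer(pattern.encode("ascii"), dtype=np.uint8)
        n_calls += (arr == ord("N")) * count
        total += count
    if total == 0:
        return np.ones(L)
    return n_calls / total


def filter_site_missing(
    rps: ReadPatternSet,
    panel: RegionPanel,
    threshold: float = DEFAULT_MAX_SITE_MISSING,
    sample_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Boolean keep-mask per CpG site; missing fraction > threshold drops it."""
    frac = site_missing_fractions(rps, panel, sample_ids)
    return frac <= threshold


def apply_qc(
    rps: ReadPatternSet,
    panels: Mapping[str, RegionPanel],
    meta: Mapping[str, SampleMeta],
    min_conversion: float = DEFAULT_MIN_CONVERSION,
    min_depth: int = DEFAULT_MIN_DEPTH,
    max_site_missing: float = DEFAULT_MAX_SITE_MISSING,
) -> tuple[ReadPatternSet, QCReport]:
    """Run conversion -> depth -> site-missing filters and build the report."""
    bad_conversion = filter_conversion(meta, min_conversion)
    bad_depth = filter_depth(rps, min_depth)

    depth = rps.depth_table().set_index(["sample_id", "region_id"])["depth"]
    sample_rows = []
    removed_pairs: set[tuple[str, str]] = set()
    for sid in rps.sample_ids:
        for rid in rps.region_ids:
            key = (sid, rid)
            d = int(depth.get(key, 0))
            if d == 0:
                continue  # pair absent from input
            if sid in bad_conversion:
                reason, kept = "low_conversion", False
            elif key in bad_depth:
                reason, kept = "low_depth", False
            else:
                reason, kept = "pass", True
            if not kept:
                removed_pairs.add(key)
            sample_rows.append(
                {
                    "sample_id": sid,
                    "region_id": rid,
                    "depth": d,
                    "conversion_rate": meta[sid].conversion_rate,
                    "kept": kept,
                    "reason": reason,
                }
            )
    filtered = rps.drop_sample_regions(removed_pairs)

    site_rows = []
    for rid, panel in panels.items():
        if rid not in filtered.region_ids:
            frac = np.ones(panel.n_cpgs)
        else:
            frac = site_missing_fractions(filtered, panel)
        for pos, f in zip(panel.cpg_positions, frac):
            site_rows.append(
                {
                    "region_id": rid,
                    "position": pos,
                    "missing_fraction": float(f),
                    "kept": bool(f <= max_site_missing),
                }
            )
    report = QCReport(
        sample_records=pd.DataFrame(sample_rows),
        site_records=pd.DataFrame(site_rows),
    )
    return filtered, report


def replicate_concordance(
    rps: ReadPatternSet,
    panels: Mapping[str, RegionPanel],
    meta: Mapping[str, SampleMeta],
    min_shared_sites: int = 3,
) -> pd.DataFrame:
    """Pearson correlation of per-CpG betas for each replicate pair.

    Beta vectors concatenate all regions' jointly observed sites. Pairs
    with fewer than *min_shared_sites* shared sites get a missing r.
    """
    pairs = [
        (m.replicate_of, sid)
        for sid, m in meta.items()
        if m.replicate_of is not None
    ]
    for orig, rep in pairs:
        if orig not in meta:
            raise ValidationError(f"replicate {rep!r}: unknown original {orig!r}")
    rows = []
    for orig, rep in pairs:
        xs, ys = [], []
        for panel in panels.values():
            if panel.region_id not in rps.region_ids:
                continue
            frame = sample_beta_frame(rps, panel)
            if orig not in frame.index or rep not in frame.index:
                continue
            a = frame.loc[orig].to_numpy(dtype=float)
            b = frame.loc[rep].to_numpy(dtype=float)
            mask = ~np.isnan(a) & ~np.isnan(b)
            xs.append(a[mask])
            ys.append(b[mask])
        x = np.concatenate(xs) if xs else np.array([])
        y = np.concatenate(ys) if ys else np.array([])
        if x.size < min_shared_sites:
            warnings.warn(
                f"replicate pair ({orig!r}, {rep!r}): only {x.size} shared "
                "sites; correlation undefined",
                stacklevel=2,
            )
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"original": orig, "replicate": rep,
                     "n_shared_sites": int(x.size), "pearson_r": r})
    return pd.DataFrame(
        rows, columns=["original", "replicate", "n_shared_sites", "pearson_r"]
    )
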