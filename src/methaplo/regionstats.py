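"""Read-level statistics for a targeted region.

Per-CpG methylated/unmethylated read counts (C_i, T_i) and betas, the
region's weighted methylation level

    WML = sum_i C_i / sum_i (C_i + T_i),

the distinct-pattern haplotype table with read fractions P and
within-pattern methylation fractions f, the methylation haplotype burden

    MHB = sum_patterns f * P,

and pairwise-complete Spearman comethylation between CpG sites.

When every read covers every CpG ('N'-free patterns) MHB and WML agree
exactly; this algebraic identity is property-tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_formats import ReadPatternSet, RegionPanel


@dataclass
class RegionProfile:
    """Per-CpG read support for one sample (or pooled group) in one region."""

    region_id: str
    sample_id: str | None
    c: np.ndarray  # reads supporting methylated cytosine per site
    t: np.ndarray  # reads supporting unmethylated cytosine per site
    site_kept: np.ndarray | None = None  # QC mask; None = all retained

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=np.int64)
        if self.c.shape != self.t.shape:
            raise ValidationError("C and T vectors differ in length")
        if np.any(self.c < 0) or np.any(self.t < 0):
            raise ValidationError("negative read counts")
        if self.site_kept is None:
            self.site_kept = np.ones(self.c.shape, dtype=bool)
        else:
            self.site_kept = np.asarray(self.site_kept, dtype=bool)

    @property
    def n(self) -> int:
        return self.c.size

    @property
    def betas(self) -> np.ndarray:
        """Per-site beta C/(C+T); NaN where no informative reads."""
        tot = self.c + self.t
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(tot > 0, self.c / np.maximum(tot, 1), np.nan)
        return out


def _pattern_counts(rps: ReadPatternSet, region_id: str,
                    sample_ids=None) -> pd.DataFrame:
    df = rps.region_entries(region_id, sample_ids)
    if df.empty:
        raise ValidationError(f"no reads for region {region_id!r}")
    return df


def site_betas(
    rps: ReadPatternSet,
    panel: RegionPanel,
    sample_ids: Sequence[str] | None = None,
) -> dict[str, RegionProfile]:
    """Per-sample RegionProfile for one region.

    C_i counts reads with 'M' at site i, T_i reads with 'U'; 'N' calls
    contribute to neither.
    """
    df = _pattern_counts(rps, panel.region_id, sample_ids)
    L = panel.n_cpgs
    out: dict[str, RegionProfile] = {}
    for sid, grp in df.groupby("sample_id", sort=True):
        c = np.zeros(L, dtype=np.int64)
        t = np.zeros(L, dtype=np.int64)
        for pattern, count in zip(grp["pattern"], grp["count"]):
            if len(pattern) != L:
                raise ValidationError(
                    f"sample {sid!r} region {panel.region_id!r}: pattern length "
                    f"{len(pattern)} != {L}"
                )
            arr = np.frombuffer(pattern.encode("ascii"), dtype=np.uint8)
            c += (arr == ord("M")) * count
            t += (arr == ord("U")) * count
        out[sid] = RegionProfile(region_id=panel.region_id, sample_id=sid, c=c, t=t)
    return out


def pooled_profile(
    rps: ReadPatternSet,
    panel: RegionPanel,
    sample_ids: Sequence[str] | None = None,
) -> RegionProfile:
    """Single profile pooling reads across samples."""
    profiles = site_betas(rps, panel, sample_ids)
    c = np.sum([p.c for p in profiles.values()], axis=0)
    t = np.sum([p.t for p in profiles.values()], axis=0)
    return RegionProfile(region_id=panel.region_id, sample_id=None, c=c, t=t)


def wml(profile: RegionProfile) -> float:
    """Weighted methylation level over retained sites."""
    kept = profile.site_kept
    total = int(np.sum(profile.c[kept]) + np.sum(profile.t[kept]))
    if total == 0:
        raise ValidationError(
            f"region {profile.region_id!r} sample {profile.sample_id!r}: "
            "no informative calls for WML"
        )
    return float(np.sum(profile.c[kept]) / total)


# ---------------------------------------------------------------------------
# Haplotype table and burden
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeTable:
    """Distinct methylation patterns of one region with read fractions."""

    region_id: str
    table: pd.DataFrame  # columns: pattern, reads, P, f
    total_reads: int


def haplotype_table(
    rps: ReadPatternSet,
    panel: RegionPanel,
    sample_ids: Sequence[str] | None = None,
) -> HaplotypeTable:
    """Distinct-pattern table with P = reads/total and f = #M/(#M+#U).

    Patterns consisting entirely of 'N' are dropped before totals are
    taken, so every remaining pattern has a defined f. Patterns are keyed
    on the full string including 'N' ("MN" and "MU" are distinct).
    """
    df = _pattern_counts(rps, panel.region_id, sample_ids)
    agg = df.groupby("pattern", sort=True)["count"].sum().reset_index()
    n_m = agg["pattern"].str.count("M")
    n_u = agg["pattern"].str.count("U")
    informative = (n_m + n_u) > 0
    agg = agg[informative]
    n_m, n_u = n_m[informative], n_u[informative]
    if agg.empty:
        raise ValidationError(
            f"region {panel.region_id!r}: no pattern with informative calls"
        )
    total = int(agg["count"].sum())
    table = pd.DataFrame(
        {
            "pattern": agg["pattern"].to_numpy(),
            "reads": agg["count"].to_numpy(dtype=np.int64),
            "P": agg["count"].to_numpy(dtype=float) / total,
            "f": (n_m / (n_m + n_u)).to_numpy(dtype=float),
        }
    )
    return HaplotypeTable(region_id=panel.region_id, table=table, total_reads=total)


def mhb(ht: HaplotypeTable) -> float:
    """Methylation haplotype burden: sum of f x P over patterns."""
    if ht.table.empty:
        raise ValidationError(f"region {ht.region_id!r}: empty haplotype table")
    psum = float(ht.table["P"].sum())
    if not math.isclose(psum, 1.0, abs_tol=1e-9):
        raise ValidationError(
            f"region {ht.region_id!r}: pattern fractions sum to {psum}, not 1"
        )
    return float((ht.table["f"] * ht.table["P"]).sum())


# ---------------------------------------------------------------------------
# Comethylation
# ---------------------------------------------------------------------------

@dataclass
class ComethylationMatrix:
    region_id: str
    rho: pd.DataFrame      # site x site Spearman correlations
    n_pairs: pd.DataFrame  # samples used per pair


def comethylation(
    betas: pd.DataFrame,
    region_id: str = "",
    min_samples: int = 3,
) -> ComethylationMatrix:
    """Pairwise-complete Spearman correlation between CpG sites.

    *betas* is samples x sites (NaN = unobserved). Pairs with fewer than
    *min_samples* jointly observed samples get a missing entry. Ties use
    average ranks.
    """
    sites = list(betas.columns)
    k = len(sites)
    rho = np.full((k, k), np.nan)
    n_mat = np.zeros((k, k), dtype=int)
    vals = betas.to_numpy(dtype=float)
    for i in range(k):
        rho[i, i] = 1.0
        n_mat[i, i] = int(np.sum(~np.isnan(vals[:, i])))
        for j in range(i + 1, k):
            mask = ~np.isnan(vals[:, i]) & ~np.isnan(vals[:, j])
            n = int(mask.sum())
            n_mat[i, j] = n_mat[j, i] = n
            if n < min_samples:
                continue
            r = stats.spearmanr(vals[mask, i], vals[mask, j]).statistic
            rho[i, j] = rho[j, i] = r
    return ComethylationMatrix(
        region_id=region_id,
        rho=pd.DataFrame(rho, index=sites, columns=sites),
        n_pairs=pd.DataFrame(n_mat, index=sites, columns=sites),
    )


def sample_beta_frame(
    rps: ReadPatternSet,
    panel: RegionPanel,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Samples x sites beta DataFrame for one region (NaN = no coverage)."""
    profiles = site_betas(rps, panel, sample_ids)
    rows = {sid: prof.betas for sid, prof in profiles.items()}
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(panel.cpg_positions)
    ).sort_index()


def wml_by_sample(
    rps: ReadPatternSet,
    panel: RegionPanel,
    sample_ids: Sequence[str] | None = None,
    site_kept: np.ndarray | None = None,
) -> pd.Series:
    """Per-sample WML for one region, honoring a site-level QC mask."""
    profiles = site_betas(rps, panel, sample_ids)
    out = {}
    for sid, prof in profiles.items():
        if site_kept is not None:
            prof.site_kept = np.asarray(site_kept, dtype=bool)
        out[sid] = wml(prof)
    return pd.Series(out, name=f"{panel.region_id}_WML").sort_index()


def mhb_by_sample(
    rps: ReadPatternSet,
    panel: RegionPanel,
    sample_ids: Sequence[str] | None = None,
) -> pd.Series:
    """Per-sample MHB for one region."""
    df = rps.region_entries(panel.region_id, sample_ids)
    out = {}
    for sid in sorted(df["sample_id"].unique()):
        ht = haplotype_table(rps, panel, sample_ids=[sid])
        out[sid] = mhb(ht)
    return pd.Series(out, name=f"{panel.region_id}_MHB").sort_index()
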