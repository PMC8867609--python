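"""Readers, writers and domain containers for every on-disk format.

Conventions
-----------
* All in-memory CpG coordinates are 1-based inclusive; BED files on disk
  are 0-based half-open (1-based position = BED start + 1).
* Tabular files are tab-separated UTF-8; missing values are written "NA";
  comment/header lines start with '#'.
* Read-level methylation calls use the alphabet {M, U, N}: methylated,
  unmethylated, missing. Pattern length always equals the region's CpG
  count ('N' is explicit, patterns are never shortened).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

PATTERN_ALPHABET = frozenset("MUN")

ANNOTATION_COLUMNS = [
    "probe_id",
    "chrom",
    "position",
    "gene",
    "detection_flag",
    "bead_flag",
    "snp_flag",
    "multihit_flag",
    "cpg_flag",
]


# ---------------------------------------------------------------------------
# Region panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionPanel:
    """Ordered CpG coordinates of one targeted amplicon region."""

    region_id: str
    chrom: str
    cpg_positions: tuple[int, ...]
    gene: str | None = None
    anchor_probe: str | None = None

    def __post_init__(self) -> None:
        pos = tuple(int(p) for p in self.cpg_positions)
        if not pos:
            raise ValidationError(f"region {self.region_id!r}: no CpG positions")
        if any(p < 1 for p in pos):
            raise ValidationError(f"region {self.region_id!r}: positions must be >= 1")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValidationError(
                f"region {self.region_id!r}: CpG positions not strictly increasing"
            )
        object.__setattr__(self, "cpg_positions", pos)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


def read_region_panel(path) -> dict[str, RegionPanel]:
    """Parse a BED file (one CpG per record, name = region id) into panels.

    BED records are 0-based half-open; the stored coordinate is start + 1.
    Unsorted CpGs within a region are auto-sorted with a warning.
    """
    per_region: dict[str, dict] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: expected >=4 BED fields")
            chrom, start_s, end_s, name = fields[0], fields[1], fields[2], fields[3]
            try:
                start = int(start_s)
                end = int(end_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if end <= start or start < 0:
                raise ParseError(f"{path}: line {lineno}: invalid interval {start}-{end}")
            rec = per_region.setdefault(name, {"chrom": chrom, "positions": []})
            if rec["chrom"] != chrom:
                raise ParseError(
                    f"{path}: line {lineno}: region {name!r} spans multiple chromosomes"
                )
            rec["positions"].append(start + 1)

    panels: dict[str, RegionPanel] = {}
    for name, rec in per_region.items():
        positions = rec["positions"]
        if sorted(positions) != positions:
            warnings.warn(
                f"region {name!r}: CpG records out of order in BED; sorting",
                stacklevel=2,
            )
            positions = sorted(positions)
        panels[name] = RegionPanel(
            region_id=name, chrom=rec["chrom"], cpg_positions=tuple(positions)
        )
    return panels


def write_region_panel(panels: Mapping[str, RegionPanel], path) -> None:
    """Write panels back to 0-based half-open BED (inverse of the reader)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for panel in panels.values():
            for pos in panel.cpg_positions:
                fh.write(f"{panel.chrom}\t{pos - 1}\t{pos}\t{panel.region_id}\n")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleMeta:
    sample_id: str
    status: str  # "case" | "control"
    age: float | None = None
    family_history_bc: int | None = None
    family_history_other: int | None = None
    conversion_rate: float | None = None
    cell_type: str | None = None
    replicate_of: str | None = None

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValidationError(
                f"sample {self.sample_id!r}: status must be case/control, "
                f"got {self.status!r}"
            )
        if self.conversion_rate is not None and not (0.0 <= self.conversion_rate <= 1.0):
            raise ValidationError(
                f"sample {self.sample_id!r}: conversion_rate {self.conversion_rate} "
                "outside [0, 1]"
            )


_META_COLUMNS = [
    "sample_id",
    "status",
    "age",
    "family_history_bc",
    "family_history_other",
    "conversion_rate",
    "cell_type",
    "replicate_of",
]


def read_sample_meta(path) -> dict[str, SampleMeta]:
    df = pd.read_csv(path, sep="\t", comment=None, dtype=str, keep_default_na=False)
    df.columns = [c.lstrip("#") for c in df.columns]
    missing_cols = {"sample_id", "status"} - set(df.columns)
    if missing_cols:
        raise ParseError(f"{path}: missing columns {sorted(missing_cols)}")
    out: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in out:
            raise ValidationError(f"{path}: duplicate sample_id {sid!r}")

        def _opt(col, cast):
            val = row.get(col, "NA")
            return None if val in ("", "NA") else cast(val)

        out[sid] = SampleMeta(
            sample_id=sid,
            status=row["status"],
            age=_opt("age", float),
            family_history_bc=_opt("family_history_bc", int),
            family_history_other=_opt("family_history_other", int),
            conversion_rate=_opt("conversion_rate", float),
            cell_type=_opt("cell_type", str),
            replicate_of=_opt("replicate_of", str),
        )
    return out


def write_sample_meta(meta: Mapping[str, SampleMeta], path) -> None:
    def _fmt(v):
        if v is None:
            return "NA"
        if isinstance(v, float):
            return repr(v)
        return str(v)

    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(_META_COLUMNS) + "\n")
        for sm in meta.values():
            fh.write(
                "\t".join(_fmt(getattr(sm, c)) for c in _META_COLUMNS) + "\n"
            )


# ---------------------------------------------------------------------------
# Read-level methylation patterns
# ---------------------------------------------------------------------------

class ReadPatternSet:
    """Collapsed per-sample, per-region read methylation patterns with counts.

    Entries with identical (sample_id, region_id, pattern) are collapsed by
    summing counts at construction, so the key is unique by invariant.
    """

    def __init__(self, entries: Iterable[tuple[str, str, str, int]]):
        rows = []
        for sample_id, region_id, pattern, count in entries:
            if set(pattern) - PATTERN_ALPHABET:
                bad = "".join(sorted(set(pattern) - PATTERN_ALPHABET))
                raise ValidationError(
                    f"sample {sample_id!r} region {region_id!r}: pattern "
                    f"{pattern!r} contains invalid characters {bad!r}"
                )
            count = int(count)
            if count < 1:
                raise ValidationError(
                    f"sample {sample_id!r} region {region_id!r}: count {count} < 1"
                )
            rows.append((sample_id, region_id, pattern, count))
        if rows:
            df = pd.DataFrame(rows, columns=["sample_id", "region_id", "pattern", "count"])
            df = (
                df.groupby(["sample_id", "region_id", "pattern"], as_index=False, sort=True)[
                    "count"
                ]
                .sum()
            )
        else:
            df = pd.DataFrame(columns=["sample_id", "region_id", "pattern", "count"])
            df["count"] = df["count"].astype(int)
        self._df = df

    # -- accessors ---------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        """Underlying collapsed table (copy)."""
        return self._df.copy()

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReadPatternSet):
            return NotImplemented
        return self._df.equals(other._df)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self._df["sample_id"].unique())

    @property
    def region_ids(self) -> list[str]:
        return sorted(self._df["region_id"].unique())

    def subset(self, sample_ids=None, region_ids=None) -> "ReadPatternSet":
        df = self._df
        if sample_ids is not None:
            df = df[df["sample_id"].isin(set(sample_ids))]
        if region_ids is not None:
            df = df[df["region_id"].isin(set(region_ids))]
        return ReadPatternSet(df.itertuples(index=False, name=None))

    def drop_sample_regions(self, pairs: set[tuple[str, str]]) -> "ReadPatternSet":
        """Remove all entries whose (sample_id, region_id) is in *pairs*."""
        keys = list(zip(self._df["sample_id"], self._df["region_id"]))
        mask = [k not in pairs for k in keys]
        return ReadPatternSet(self._df[mask].itertuples(index=False, name=None))

    def depth_table(self) -> pd.DataFrame:
        """Reads per (sample_id, region_id)."""
        return (
            self._df.groupby(["sample_id", "region_id"], as_index=False)["count"]
            .sum()
            .rename(columns={"count": "depth"})
        )

    def region_entries(self, region_id: str, sample_ids=None) -> pd.DataFrame:
        df = self._df[self._df["region_id"] == region_id]
        if sample_ids is not None:
            df = df[df["sample_id"].isin(set(sample_ids))]
        return df

    # -- validation --------------------------------------------------------

    def validate_against_panel(self, panels: Mapping[str, RegionPanel]) -> None:
        for sample_id, region_id, pattern, _ in self._df.itertuples(index=False, name=None):
            panel = panels.get(region_id)
            if panel is None:
                raise ValidationError(
                    f"sample {sample_id!r}: unknown region {region_id!r}"
                )
            if len(pattern) != panel.n_cpgs:
                raise ValidationError(
                    f"sample {sample_id!r} region {region_id!r}: pattern length "
                    f"{len(pattern)} != {panel.n_cpgs} CpGs"
                )


def read_read_patterns(path) -> ReadPatternSet:
    entries = []
    with open(path, "rt", encoding="utf-8") as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header_seen = True
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 columns")
            sample_id, region_id, pattern, count_s = fields
            try:
                count = int(count_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad count {count_s!r}") from exc
            entries.append((sample_id, region_id, pattern, count))
        if entries and not header_seen:
            warnings.warn(f"{path}: no '#' header line found", stacklevel=2)
    return ReadPatternSet(entries)


def write_read_patterns(rps: ReadPatternSet, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#sample_id\tregion_id\tpattern\tcount\n")
        for row in rps.frame.itertuples(index=False, name=None):
            fh.write("\t".join(str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Array-style beta matrix
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """Probes x samples beta-value matrix with probe annotations.

    ``annotations`` is indexed by probe_id and carries chrom, 1-based
    position, gene symbol and binary trouble flags (1 = flagged) plus
    ``cpg_flag`` (1 = genuine CpG probe). ``values`` is a float DataFrame
    (probe_id x sample_id, NaN = missing). ``groups`` maps each sample
    column to "case" or "control".
    """

    annotations: pd.DataFrame
    values: pd.DataFrame
    groups: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self) -> None:
        if not self.annotations.index.is_unique:
            dup = self.annotations.index[self.annotations.index.duplicated()][0]
            raise ValidationError(f"duplicate probe_id {dup!r}")
        if not self.annotations.index.equals(self.values.index):
            raise ValidationError("annotation and value probe indices differ")
        vals = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((vals < 0) | (vals > 1)):
                raise ValidationError("beta values outside [0, 1]")
        bad_groups = set(self.groups.dropna()) - {"case", "control"}
        if bad_groups:
            raise ValidationError(f"invalid group labels {sorted(bad_groups)}")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValidationError(f"samples without group labels: {sorted(missing)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def case_ids(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == "case"]

    def control_ids(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == "control"]

    def select_probes(self, probe_ids) -> "BetaMatrix":
        idx = self.values.index.intersection(pd.Index(probe_ids))
        return BetaMatrix(
            annotations=self.annotations.loc[idx].copy(),
            values=self.values.loc[idx].copy(),
            groups=self.groups.copy(),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, BetaMatrix):
            return NotImplemented
        return (
            self.annotations.equals(other.annotations)
            and self.values.equals(other.values)
            and self.groups.equals(other.groups)
        )


def read_beta_matrix(path) -> BetaMatrix:
    group_line = None
    header = None
    data_rows = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#group"):
                group_line = line.split("\t")
                continue
            if line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ParseError(f"{path}: line {lineno}: column count mismatch")
            data_rows.append(fields)
    if header is None:
        raise ParseError(f"{path}: no header line")
    if header[: len(ANNOTATION_COLUMNS)] != ANNOTATION_COLUMNS:
        raise ParseError(
            f"{path}: expected leading annotation columns {ANNOTATION_COLUMNS}"
        )
    sample_ids = header[len(ANNOTATION_COLUMNS):]

    ann_rows, val_rows = [], []
    for lineno_rel, fields in enumerate(data_rows):
        ann_rows.append(fields[: len(ANNOTATION_COLUMNS)])
        vals = []
        for v in fields[len(ANNOTATION_COLUMNS):]:
            if v == "NA":
                vals.append(np.nan)
            else:
                x = float(v)
                if not (0.0 <= x <= 1.0):
                    raise ValidationError(
                        f"{path}: beta value {v} outside [0, 1] "
                        f"(probe {fields[0]!r})"
                    )
                vals.append(x)
        val_rows.append(vals)

    ann = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS).set_index("probe_id")
    ann["position"] = ann["position"].astype(int)
    for col in ("detection_flag", "bead_flag", "snp_flag", "multihit_flag", "cpg_flag"):
        ann[col] = ann[col].astype(int)
    values = pd.DataFrame(val_rows, index=ann.index, columns=sample_ids, dtype=float)

    if group_line is not None:
        labels = group_line[1:]
        if len(labels) != len(sample_ids):
            raise ParseError(f"{path}: #group line has {len(labels)} labels, "
                             f"expected {len(sample_ids)}")
        groups = pd.Series(labels, index=sample_ids, dtype=object)
    else:
        groups = pd.Series(index=pd.Index(sample_ids), dtype=object)
    return BetaMatrix(annotations=ann, values=values, groups=groups)


def write_beta_matrix(bm: BetaMatrix, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        if len(bm.groups.dropna()):
            fh.write("#group\t" + "\t".join(bm.groups[s] for s in bm.sample_ids) + "\n")
        fh.write("\t".join(ANNOTATION_COLUMNS + list(bm.sample_ids)) + "\n")
        ann = bm.annotations
        for probe_id in bm.probe_ids:
            row = ann.loc[probe_id]
            cells = [
                str(probe_id),
                str(row["chrom"]),
                str(int(row["position"])),
                str(row["gene"]),
                str(int(row["detection_flag"])),
                str(int(row["bead_flag"])),
                str(int(row["snp_flag"])),
                str(int(row["multihit_flag"])),
                str(int(row["cpg_flag"])),
            ]
            for v in bm.values.loc[probe_id]:
                cells.append("NA" if pd.isna(v) else repr(float(v)))
            fh.write("\t".join(cells) + "\n")
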