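"""Synthetic cohort generators.

Two generators:

* :func:`simulate_read_cohort` — read-level targeted bisulfite data with
  correlated adjacent-CpG calls (stationary first-order Markov chain),
  between-subject variability on the logit scale, case/control shifts,
  Poisson depth, incomplete bisulfite conversion (U -> M only) and
  missing calls ('N').
* :func:`simulate_beta_cohorts` — two independent array-style cohorts
  sharing probe identities, with spiked case/control mean-beta shifts,
  truncated-normal noise, optional blacklist flags and missingness.

Both are deterministic given their seed; the read simulator derives one
PRNG stream per subject from the master seed so subjects can be generated
in any order (or in parallel) without changing the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .errors import ValidationError
from .io_formats import BetaMatrix, ReadPatternSet, RegionPanel, SampleMeta

_CALL_CHARS = np.array(["U", "M", "N"])


@dataclass(frozen=True)
class EffectSpec:
    """Case-vs-control shift on the logit of methylation probability."""

    target: str  # region_id (read simulator) or probe_id
    delta_logit: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_logit):
            raise ValidationError(f"effect for {self.target!r}: non-finite delta_logit")

    @property
    def direction(self) -> str:
        return "hyper-in-case" if self.delta_logit >= 0 else "hypo-in-case"


@dataclass
class SimConfig:
    """Parameters of the read-level cohort simulator.

    ``baseline_pi`` may be a single probability applied to every CpG or a
    mapping region_id -> per-CpG probabilities.
    """

    n_cases: int
    n_controls: int
    depth_mean: float = 200.0
    rho: float = 0.0
    baseline_pi: float | Mapping[str, Sequence[float]] = 0.5
    subject_sd: float = 0.0
    conversion_rate: float = 1.0
    miss_rate: float = 0.0
    seed: int = 0
    fixed_depth: bool = False
    age_mean: float = 52.0
    age_sd: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValidationError(f"rho {self.rho} outside [0, 1)")
        if not (0.0 <= self.conversion_rate <= 1.0):
            raise ValidationError("conversion_rate outside [0, 1]")
        if not (0.0 <= self.miss_rate <= 1.0):
            raise ValidationError("miss_rate outside [0, 1]")
        if self.depth_mean < 1:
            raise ValidationError("depth_mean must be >= 1")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValidationError("cohort sizes must be non-negative")


def _region_pi(cfg: SimConfig, panel: RegionPanel) -> np.ndarray:
    if isinstance(cfg.baseline_pi, Mapping):
        pi = np.asarray(cfg.baseline_pi[panel.region_id], dtype=float)
        if pi.shape != (panel.n_cpgs,):
            raise ValidationError(
                f"baseline_pi for {panel.region_id!r}: expected {panel.n_cpgs} values"
            )
    else:
        pi = np.full(panel.n_cpgs, float(cfg.baseline_pi))
    if np.any((pi < 0.0) | (pi > 1.0)):
        raise ValidationError("baseline_pi values outside [0, 1]")
    return pi


def _markov_reads(rng: np.random.Generator, p: np.ndarray, rho: float,
                  n_reads: int) -> np.ndarray:
    """Binary read matrix (n_reads x L) with marginals p and lag-1 corr rho."""
    L = p.size
    x = np.empty((n_reads, L), dtype=np.int8)
    x[:, 0] = rng.random(n_reads) < p[0]
    for j in range(1, L):
        pj, pk = p[j - 1], p[j]
        if pj <= 0.0 or pj >= 1.0:
            p1 = p0 = pk  # degenerate previous site: fall back to marginal
        else:
            # E[X_{j-1} X_j] matching the requested lag-1 correlation
            e11 = pj * pk + rho * np.sqrt(pj * (1 - pj) * pk * (1 - pk))
            p1 = e11 / pj          # P(X_j = 1 | X_{j-1} = 1)
            p0 = (pk - e11) / (1 - pj)
        if p1 > 1.0 or p0 < 0.0:
            warnings.warn(
                "requested (pi, rho) combination infeasible; clipping transition "
                "probabilities", stacklevel=3,
            )
            p1, p0 = min(p1, 1.0), max(p0, 0.0)
        u = rng.random(n_reads)
        prev = x[:, j - 1] == 1
        x[:, j] = np.where(prev, u < p1, u < p0)
    return x


def simulate_read_cohort(
    panels: Mapping[str, RegionPanel],
    cfg: SimConfig,
    effects: Sequence[EffectSpec] = (),
) -> tuple[ReadPatternSet, dict[str, SampleMeta]]:
    """Generate a case/control read-level cohort over *panels*.

    Per subject s and region r a random effect b ~ Normal(0, subject_sd)
    shifts every CpG's methylation logit; cases get an extra region-level
    delta from *effects*. Reads follow a stationary first-order Markov
    chain across CpG index. Unmethylated calls flip to 'M' with
    probability 1 - conversion_rate; every call independently becomes 'N'
    with probability miss_rate.
    """
    if not panels:
        raise ValidationError("empty region panel")
    delta_by_region = {e.target: e.delta_logit for e in effects}
    region_ids = sorted(panels)

    n_total = cfg.n_cases + cfg.n_controls
    master = np.random.SeedSequence(cfg.seed)
    subject_seeds = master.spawn(n_total + 1)
    meta_rng = np.random.default_rng(subject_seeds[-1])

    entries: list[tuple[str, str, str, int]] = []
    meta: dict[str, SampleMeta] = {}
    width = max(4, len(str(n_total)))
    for idx in range(n_total):
        is_case = idx < cfg.n_cases
        status = "case" if is_case else "control"
        sid = f"{status}_{idx + 1:0{width}d}"
        rng = np.random.default_rng(subject_seeds[idx])
        for rid in region_ids:
            panel = panels[rid]
            pi = _region_pi(cfg, panel)
            b = rng.normal(0.0, cfg.subject_sd) if cfg.subject_sd > 0 else 0.0
            delta = delta_by_region.get(rid, 0.0) if is_case else 0.0
            p = expit(logit(pi) + b + delta)
            n_reads = (
                int(round(cfg.depth_mean))
                if cfg.fixed_depth
                else int(rng.poisson(cfg.depth_mean))
            )
            if n_reads == 0:
                continue
            x = _markov_reads(rng, p, cfg.rho, n_reads)
            if cfg.conversion_rate < 1.0:
                flip = (x == 0) & (rng.random(x.shape) < 1.0 - cfg.conversion_rate)
                x = np.where(flip, 1, x)
            if cfg.miss_rate > 0.0:
                x = np.where(rng.random(x.shape) < cfg.miss_rate, 2, x)
            chars = _CALL_CHARS[x]
            patterns, counts = np.unique(
                np.array(["".join(row) for row in chars]), return_counts=True
            )
            for pat, cnt in zip(patterns, counts):
                entries.append((sid, rid, str(pat), int(cnt)))
        age = float(np.round(meta_rng.normal(cfg.age_mean, cfg.age_sd), 1))
        meta[sid] = SampleMeta(
            sample_id=sid,
            status=status,
            age=age,
            family_history_bc=int(meta_rng.random() < 0.04),
            family_history_other=int(meta_rng.random() < 0.2),
            conversion_rate=cfg.conversion_rate,
        )
    return ReadPatternSet(entries), meta


# ---------------------------------------------------------------------------
# Array-style cohorts
# ---------------------------------------------------------------------------

def _truncated_betas(rng: np.random.Generator, mean: np.ndarray,
                     sd: float) -> np.ndarray:
    if sd <= 0:
        return np.clip(mean, 0.0, 1.0)
    a = (0.0 - mean) / sd
    b = (1.0 - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)


def _one_beta_cohort(
    rng: np.random.Generator,
    ann: pd.DataFrame,
    baseline: np.ndarray,
    spiked: np.ndarray,
    delta_beta: float,
    noise_sd: float,
    n_case: int,
    n_ctrl: int,
    miss_frac: float,
    prefix: str,
) -> BetaMatrix:
    n_probes = len(ann)
    samples = [f"{prefix}_case_{i + 1:04d}" for i in range(n_case)] + [
        f"{prefix}_ctrl_{i + 1:04d}" for i in range(n_ctrl)
    ]
    groups = pd.Series(
        ["case"] * n_case + ["control"] * n_ctrl, index=samples, dtype=object
    )
    mean = np.tile(baseline[:, None], (1, n_case + n_ctrl))
    mean[spiked, :n_case] += delta_beta
    mean = np.clip(mean, 1e-6, 1 - 1e-6)
    betas = _truncated_betas(rng, mean, noise_sd)
    if miss_frac > 0:
        mask = rng.random(betas.shape) < miss_frac
        betas = np.where(mask, np.nan, betas)
    values = pd.DataFrame(betas, index=ann.index, columns=samples, dtype=float)
    return BetaMatrix(annotations=ann.copy(), values=values, groups=groups)


def simulate_beta_cohorts(
    n_probes: int,
    n_spiked: int,
    delta_beta: float,
    noise_sd: float,
    n1_case: int,
    n1_ctrl: int,
    n2_case: int,
    n2_ctrl: int,
    seed: int,
    blacklist_frac: float = 0.0,
    miss_frac: float = 0.0,
) -> tuple[BetaMatrix, BetaMatrix]:
    """Two independent cohorts sharing probe identities and spiked effects.

    The first ``n_spiked`` probes carry a case-minus-control mean shift of
    ``delta_beta`` in both cohorts. A ``blacklist_frac`` fraction of the
    remaining probes receives one randomly chosen trouble flag (bead,
    detection, SNP, multihit, non-CpG, or X/Y location).
    """
    if not (0 <= n_spiked <= n_probes):
        raise ValidationError("n_spiked must lie in [0, n_probes]")
    for n in (n1_case, n1_ctrl, n2_case, n2_ctrl):
        if n < 0:
            raise ValidationError("cohort sizes must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    probe_ids = [f"cg{i:06d}" for i in range(n_probes)]
    ann = pd.DataFrame(
        {
            "chrom": ["chr1"] * n_probes,
            "position": np.arange(1, n_probes + 1) * 1000,
            "gene": [f"GENE{i % max(1, n_probes // 2):04d}" for i in range(n_probes)],
            "detection_flag": 0,
            "bead_flag": 0,
            "snp_flag": 0,
            "multihit_flag": 0,
            "cpg_flag": 1,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    spiked = np.zeros(n_probes, dtype=bool)
    spiked[:n_spiked] = True
    if blacklist_frac > 0:
        candidates = np.flatnonzero(~spiked)
        n_bad = int(round(blacklist_frac * candidates.size))
        bad = rng.choice(candidates, size=n_bad, replace=False)
        kinds = rng.integers(0, 6, size=n_bad)
        flag_cols = ["detection_flag", "bead_flag", "snp_flag", "multihit_flag"]
        for i, kind in zip(bad, kinds):
            if kind < 4:
                ann.iloc[i, ann.columns.get_loc(flag_cols[kind])] = 1
            elif kind == 4:
                ann.iloc[i, ann.columns.get_loc("cpg_flag")] = 0
            else:
                ann.iloc[i, ann.columns.get_loc("chrom")] = "chrX"

    baseline = rng.uniform(0.2, 0.8, size=n_probes)
    bm1 = _one_beta_cohort(
        rng, ann, baseline, spiked, delta_beta, noise_sd, n1_case, n1_ctrl,
        miss_frac, "c1",
    )
    bm2 = _one_beta_cohort(
        rng, ann, baseline, spiked, delta_beta, noise_sd, n2_case, n2_ctrl,
        miss_frac, "c2",
    )
    return bm1, bm2
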