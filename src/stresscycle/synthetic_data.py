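"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators mirror the three experimental data types the pipeline
consumes, so every stage can be exercised end to end without any external
download:

* paired fold-change tables over a genome-sized gene universe with a
  planted shared regulon (plus condition-specific genes and log-normal
  biological scatter),
* translation shut-off time courses with first-order decay and
  multiplicative densitometry noise, and
* qPCR Ct tables derived from known template ratios with technical-
  triplicate cycle noise.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .decay_kinetics import DecayTimecourse
from .qpcr_quant import CtRecord, CtTable
from .transcriptome_sets import FoldChangeTable

__all__ = [
    "RegulonSimSpec",
    "DecaySimSpec",
    "simulate_regulon_pair",
    "simulate_decay",
    "simulate_ct_table",
]


@dataclass(frozen=True)
class RegulonSimSpec:
    """Two stress conditions acting on a shared regulon.

    Defaults emulate a ~4000-gene bacterial genome in which two membrane
    stresses each flip roughly 470 genes up and 280 genes down, most of
    them shared — the regime in which directional regulon overlaps carry
    z-scores far above chance.  Effects are log-normal: a planted gene gets
    ratio 2**x with x ~ Normal(effect_log2fc_mean, effect_log2fc_sd) (sign
    flipped for down-regulated genes); unplanted genes get
    x ~ Normal(0, null_log2fc_sd).  Shared genes are planted in both
    conditions; specific genes are drawn independently per condition from
    the remaining pool, so with zero shared counts the two regulons are
    independent uniform subsets — the exact null of the overlap statistic.
    """

    N_genes: int = 4000
    n_up_shared: int = 350
    n_down_shared: int = 200
    n_up_specific: int = 120
    n_down_specific: int = 80
    effect_log2fc_mean: float = 2.0
    effect_log2fc_sd: float = 0.3
    null_log2fc_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_up_shared, self.n_down_shared,
                  self.n_up_specific, self.n_down_specific)
        if any(c < 0 for c in counts):
            raise ValueError("planted gene counts must be non-negative")
        if (self.n_up_shared + self.n_down_shared
                + self.n_up_specific + self.n_down_specific) > self.N_genes:
            raise ValueError("planted gene counts exceed the universe size")
        if self.effect_log2fc_sd < 0 or self.null_log2fc_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class DecaySimSpec:
    """A first-order decay measured by replicate densitometry.

    Defaults follow the common shut-off design: sampling every 10 min for
    an hour, three replicates, 10% multiplicative noise, and a half-life
    of 26 min (an unstressed cell-cycle regulator).  Short-lived proteins
    (t1/2 of a few minutes) need the denser 0,3,6,9,12,20,30-min schedule.
    """

    t_half_true: float = 26.0
    times: tuple[float, ...] = (0, 10, 20, 30, 40, 50, 60)
    n_replicates: int = 3
    noise_cv: float = 0.10
    detection_limit: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_half_true <= 0:
            raise ValueError("true half-life must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("at least one replicate is required")
        if self.detection_limit < 0:
            raise ValueError("detection limit must be non-negative")


DENSE_SCHEDULE: tuple[float, ...] = (0, 3, 6, 9, 12, 20, 30)


def _gene_ids(n: int) -> np.ndarray:
    width = len(str(n))
    return np.array([f"g{i:0{width}d}" for i in range(1, n + 1)])


def simulate_regulon_pair(
    spec: RegulonSimSpec,
) -> tuple[FoldChangeTable, FoldChangeTable]:
    """Draw a pair of fold-change tables with a planted shared regulon."""
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.N_genes)
    order = rng.permutation(spec.N_genes)
    n_sh_up, n_sh_dn = spec.n_up_shared, spec.n_down_shared
    shared_up = order[:n_sh_up]
    shared_dn = order[n_sh_up : n_sh_up + n_sh_dn]
    pool = order[n_sh_up + n_sh_dn :]

    tables = []
    for cond in ("condA", "condB"):
        pick = rng.permutation(pool)
        spec_up = pick[: spec.n_up_specific]
        spec_dn = pick[spec.n_up_specific : spec.n_up_specific + spec.n_down_specific]
        log2fc = rng.normal(0.0, spec.null_log2fc_sd, size=spec.N_genes)
        for idx, sign in ((shared_up, +1), (shared_dn, -1),
                          (spec_up, +1), (spec_dn, -1)):
            log2fc[idx] = sign * rng.normal(
                spec.effect_log2fc_mean, spec.effect_log2fc_sd, size=idx.size
            )
        entries = dict(zip(genes.tolist(), (2.0 ** log2fc).tolist()))
        tables.append(FoldChangeTable(cond, entries))
    return tables[0], tables[1]


def simulate_decay(spec: DecaySimSpec) -> DecayTimecourse:
    """Exponential decay with log-normal multiplicative noise, mean 1.

    intensity(r, t) = exp(-ln2 * t / t_half_true) * eps, with eps log-normal
    of mean 1 and coefficient of variation ``noise_cv``, drawn independently
    for every replicate and time point (including t = 0, so normalization
    error at the anchor point is part of the model).  Bands fainter than
    ``detection_limit`` (as a fraction of the initial signal) fall below the
    blot background and are recorded as 0 — on a sparse sampling grid this
    censors the tail of fast-decaying proteins, which is why they need the
    dense early schedule.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.times, dtype=float)
    signal = np.exp(-math.log(2) * t / spec.t_half_true)
    if spec.noise_cv > 0:
        sigma2 = math.log(1.0 + spec.noise_cv**2)
        eps = rng.lognormal(
            mean=-sigma2 / 2,
            sigma=math.sqrt(sigma2),
            size=(spec.n_replicates, t.size),
        )
    else:
        eps = np.ones((spec.n_replicates, t.size))
    intensities = signal[None, :] * eps
    intensities[intensities < spec.detection_limit] = 0.0
    return DecayTimecourse(
        condition_label=f"sim_thalf_{spec.t_half_true:g}",
        times=t,
        intensities=intensities,
    )


def simulate_ct_table(
    true_fold_changes: Mapping[str, float],
    base_ct: float = 20.0,
    ct_noise_sd: float = 0.2,
    seed: int = 0,
    reference_target: str = "16S",
    n_technical: int = 3,
) -> CtTable:
    """Ct table for a treated-vs-control design with known template ratios.

    Every target amplifies from relative template 1 in the control sample
    and from ``true_fold_changes[target]`` in the treated sample; the
    reference amplicon has ratio 1 in both.  Each record carries
    ``n_technical`` replicate Ct values: base_ct - log2(template) plus
    Normal(0, ct_noise_sd) cycle noise.
    """
    for target, ratio in true_fold_changes.items():
        if ratio <= 0:
            raise ValueError(f"template ratio for {target!r} must be positive")
    rng = np.random.default_rng(seed)
    records: list[CtRecord] = []
    for sample, template_of in (
        ("control", {t: 1.0 for t in true_fold_changes}),
        ("treated", dict(true_fold_changes)),
    ):
        template_of = {**template_of, reference_target: 1.0}
        for target, template in template_of.items():
            cts = base_ct - math.log2(template) + rng.normal(
                0.0, ct_noise_sd, size=n_technical
            )
            role = "reference" if target == reference_target else "target"
            records.append(
                CtRecord(sample, target, tuple(float(c) for c in cts), role)
            )
    return CtTable(tuple(records))
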