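"""Comparative-Ct qRT-PCR quantification and ChIP-qPCR percent-of-input.

All arithmetic is in base-2 cycle space assuming perfect amplification
efficiency (one template doubling per cycle): relative expression is
2^(-ddCt) against a reference transcript (e.g. 16S rRNA) and a control
condition; ChIP enrichment is the immunoprecipitated DNA as a percentage of
the total input chromatin after correcting the input Ct for the fraction of
input actually assayed.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "CtRecord",
    "CtTable",
    "QuantResult",
    "mean_ct",
    "relative_expression_ddct",
    "percent_input",
    "relative_occupancy",
    "ddct_from_table",
]

_ROLES = ("target", "reference", "input", "ip")


@dataclass(frozen=True)
class CtRecord:
    """One amplicon in one sample: technical-replicate Ct values and a role."""

    sample_label: str
    target_label: str
    ct_values: tuple[float, ...]
    role: str = "target"

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")
        if len(self.ct_values) < 1:
            raise ValueError("at least one technical replicate is required")
        for ct in self.ct_values:
            if not (math.isfinite(ct) and ct > 0):
                raise ValueError(f"Ct values must be finite and > 0, got {ct!r}")

    @property
    def mean_ct(self) -> float:
        return statistics.fmean(self.ct_values)

    @property
    def sd_ct(self) -> float:
        if len(self.ct_values) < 2:
            return 0.0
        return statistics.stdev(self.ct_values)


@dataclass(frozen=True)
class CtTable:
    records: tuple[CtRecord, ...]

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            # ChIP designs carry an input and an ip record for the same
            # sample/target, so the role is part of the identity
            key = (rec.sample_label, rec.target_label, rec.role)
            if key in seen:
                raise ValueError(f"duplicate record for sample/target/role {key}")
            seen.add(key)

    def get(
        self, sample_label: str, target_label: str, role: str | None = None
    ) -> CtRecord:
        for rec in self.records:
            if (rec.sample_label, rec.target_label) == (sample_label, target_label):
                if role is None or rec.role == role:
                    return rec
        raise KeyError(f"no record for sample {sample_label!r}, target {target_label!r}")

    def targets(self, role: str = "target") -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.role == role and rec.target_label not in out:
                out.append(rec.target_label)
        return out


@dataclass(frozen=True)
class QuantResult:
    """A derived quantity (fold-change or percentage) with its formula tag."""

    label: str
    value: float
    basis: str
    uncertainty: float = 0.0

    def __post_init__(self) -> None:
        if self.basis in ("percent_input", "relative_occupancy") and self.value < 0:
            raise ValueError("percent values must be non-negative")
        if self.basis == "ddct" and self.value <= 0:
            raise ValueError("fold-changes must be positive")


def mean_ct(ct_values: float | Iterable[float]) -> float:
    """Mean of technical-replicate Ct values; scalars pass through."""
    if isinstance(ct_values, (int, float)):
        return float(ct_values)
    return statistics.fmean(ct_values)


def relative_expression_ddct(
    ct_target_treated: float | Sequence[float],
    ct_ref_treated: float | Sequence[float],
    ct_target_control: float | Sequence[float],
    ct_ref_control: float | Sequence[float],
) -> float:
    """Comparative-Ct fold change 2^(-ddCt) of target, treated vs control.

    dCt = Ct(target) - Ct(reference) within each condition, and
    ddCt = dCt(treated) - dCt(control).  Technical replicates (lists) are
    averaged to a mean Ct before the formula is applied.
    """
    d_treated = mean_ct(ct_target_treated) - mean_ct(ct_ref_treated)
    d_control = mean_ct(ct_target_control) - mean_ct(ct_ref_control)
    ddct = d_treated - d_control
    return 2.0 ** (-ddct)


def percent_input(
    ct_input: float | Sequence[float],
    input_fraction: float,
    ct_ip: float | Sequence[float],
) -> float:
    """ChIP recovery as percent of total input chromatin.

    Only a fraction of the input is assayed (5% in a typical protocol), so
    the input Ct is first adjusted to represent 100% of the chromatin by
    subtracting log2(1/input_fraction) cycles; the result is
    100 * 2^(adjusted_input_ct - ct_ip).
    """
    if not (0 < input_fraction <= 1):
        raise ValueError("input_fraction must lie in (0, 1]")
    adjusted_input = mean_ct(ct_input) - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted_input - mean_ct(ct_ip))


def relative_occupancy(
    percent_input_condition: float, percent_input_baseline: float
) -> float:
    """Percent-of-input under a condition expressed as percent of baseline."""
    if percent_input_baseline <= 0:
        raise ValueError("baseline percent-of-input must be positive")
    if percent_input_condition < 0:
        raise ValueError("percent-of-input cannot be negative")
    return 100.0 * percent_input_condition / percent_input_baseline


def ddct_from_table(
    table: CtTable,
    reference_target: str,
    control_sample: str,
    treated_samples: Sequence[str] | None = None,
) -> list[QuantResult]:
    """Relative expression for every target in every treated sample.

    The Ct spread of technical triplicates is propagated, assuming perfect
    efficiency and independent errors, to a multiplicative uncertainty band:
    the reported ``uncertainty`` is the fold-change times
    (2^(sd_ddct) - 1), with sd_ddct the root-sum-square of the four
    standard errors of the mean Ct values.
    """
    samples = [r.sample_label for r in table.records]
    if treated_samples is None:
        treated_samples = [s for s in dict.fromkeys(samples) if s != control_sample]
    results: list[QuantResult] = []
    for sample in treated_samples:
        for target in table.targets("target"):
            try:
                rec_t = table.get(sample, target)
                rec_tc = table.get(control_sample, target)
            except KeyError:
                continue
            try:
                ref_t = table.get(sample, reference_target)
                ref_c = table.get(control_sample, reference_target)
            except KeyError as exc:
                raise ValueError(
                    f"missing reference record {reference_target!r}"
                ) from exc
            value = relative_expression_ddct(
                rec_t.ct_values, ref_t.ct_values, rec_tc.ct_values, ref_c.ct_values
            )
            sem2 = sum(
                (r.sd_ct**2) / len(r.ct_values) for r in (rec_t, ref_t, rec_tc, ref_c)
            )
            uncertainty = value * (2.0 ** math.sqrt(sem2) - 1.0)
            results.append(
                QuantResult(
                    label=f"{sample}:{target}",
                    value=value,
                    basis="ddct",
                    uncertainty=uncertainty,
                )
            )
    if not results:
        raise ValueError("no target records matched the requested samples")
    return results
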