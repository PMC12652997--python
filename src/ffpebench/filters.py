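"""GATK-style hard filtering of annotated variant records.

A record fails a criterion only when the annotation is present AND strictly
violates its inequality (boundary values pass); absent annotations are
*skipped*, never failed — failing on absence would mass-fail records that
simply lack rank-sum annotations.  QUAL comes from the VCF QUAL column; every
other criterion reads a site INFO annotation.

Default thresholds (overridable via config):

=============  =========  ==========
criterion      SNV        indel
=============  =========  ==========
QD <           2.0        2.0
QUAL <         30.0       30.0
SOR >          3.0        10.0
FS >           60.0       200.0
MQ <           40.0       (unused)
MQRankSum <    -12.5      (unused)
ReadPosRankSum <  -8.0    -20.0
=============  =========  ==========

MNV records are evaluated with SNV thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .variants import CallSet, VariantClass, VariantRecord

__all__ = [
    "Criterion",
    "FilterThresholds",
    "FilterVerdict",
    "evaluate_record",
    "apply_filters",
]


@dataclass(frozen=True, slots=True)
class Criterion:
    """One hard-filter rule: fail when ``value <op> threshold`` strictly."""

    name: str  # annotation key; "QUAL" reads the QUAL column
    op: str  # "<" fails low values, ">" fails high values
    threshold: float

    def violates(self, value: float) -> bool:
        return value < self.threshold if self.op == "<" else value > self.threshold


def _snv_defaults() -> tuple[Criterion, ...]:
    return (
        Criterion("QD", "<", 2.0),
        Criterion("QUAL", "<", 30.0),
        Criterion("SOR", ">", 3.0),
        Criterion("FS", ">", 60.0),
        Criterion("MQ", "<", 40.0),
        Criterion("MQRankSum", "<", -12.5),
        Criterion("ReadPosRankSum", "<", -8.0),
    )


def _indel_defaults() -> tuple[Criterion, ...]:
    return (
        Criterion("QD", "<", 2.0),
        Criterion("QUAL", "<", 30.0),
        Criterion("FS", ">", 200.0),
        Criterion("ReadPosRankSum", "<", -20.0),
        Criterion("SOR", ">", 10.0),
    )


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter criteria per variant class, with standard defaults."""

    snv: tuple[Criterion, ...] = field(default_factory=_snv_defaults)
    indel: tuple[Criterion, ...] = field(default_factory=_indel_defaults)

    @classmethod
    def from_config(cls, cfg: dict) -> "FilterThresholds":
        """Build thresholds from a ``{"snv": {...}, "indel": {...}}`` mapping.

        Values override the default threshold for the named criterion; the
        inequality direction is fixed by the criterion name.
        """
        out = {}
        for vclass, defaults in (("snv", _snv_defaults()), ("indel", _indel_defaults())):
            overrides = cfg.get(vclass, {}) or {}
            by_name = {c.name: c for c in defaults}
            for name, thr in overrides.items():
                if name not in by_name:
                    raise ValueError(f"unknown {vclass} filter criterion {name!r}")
                by_name[name] = Criterion(name, by_name[name].op, float(thr))
            out[vclass] = tuple(by_name.values())
        return cls(snv=out["snv"], indel=out["indel"])

    def for_record(self, record: VariantRecord) -> tuple[Criterion, ...]:
        cls = record.variant_class
        if cls in (VariantClass.DELETION, VariantClass.INSERTION):
            return self.indel
        return self.snv  # snv; mnv uses snv thresholds


@dataclass(frozen=True, slots=True)
class FilterVerdict:
    passed: bool
    failed_criteria: tuple[str, ...]
    skipped_criteria: tuple[str, ...]

    def __post_init__(self):
        if self.passed != (len(self.failed_criteria) == 0):
            raise ValueError("passed flag inconsistent with failed criteria")


def evaluate_record(record: VariantRecord, thresholds: Optional[FilterThresholds] = None
                    ) -> FilterVerdict:
    """Evaluate every applicable criterion; absent annotations are skipped."""
    thresholds = thresholds or FilterThresholds()
    failed, skipped = [], []
    for crit in thresholds.for_record(record):
        value = record.qual if crit.name == "QUAL" else record.annotations.get(crit.name)
        if value is None:
            skipped.append(crit.name)
        elif crit.violates(value):
            failed.append(crit.name)
    return FilterVerdict(not failed, tuple(failed), tuple(skipped))


def apply_filters(
    cs: CallSet,
    thresholds: Optional[FilterThresholds] = None,
    enabled: bool = True,
) -> tuple[CallSet, pd.DataFrame]:
    """Stamp FILTER labels on all records and return the passing subset.

    With ``enabled=False`` (e.g. DeepVariant output, which ships pre-filtered
    by its model) records are returned unchanged with an all-pass summary.
    Returns ``(pass-only CallSet, per-class pass/fail summary)``.
    """
    thresholds = thresholds or FilterThresholds()
    passing = CallSet(cs.samples, provenance=cs.provenance)
    tallies: dict[str, dict[str, int]] = {}
    for rec in cs:
        cls = rec.variant_class.value
        tally = tallies.setdefault(cls, {"pass": 0, "fail": 0})
        if not enabled:
            tally["pass"] += 1
            passing.add(rec)
            continue
        verdict = evaluate_record(rec, thresholds)
        rec.filters = verdict.failed_criteria  # () means PASS
        if verdict.passed:
            tally["pass"] += 1
            passing.add(rec)
        else:
            tally["fail"] += 1
    summary = pd.DataFrame(
        [{"variant_class": vc, "pass": t["pass"], "fail": t["fail"],
          "total": t["pass"] + t["fail"]}
         for vc, t in sorted(tallies.items())]
    )
    return passing, summary
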