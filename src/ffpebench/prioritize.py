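"""Recessive-disease variant prioritization.

Implements the private-homozygote filtering cascade used to pinpoint a causal
variant for a monogenic autosomal-recessive condition: for each affected case
the candidate keys are those where the case is homozygous-alternate (1/1)
while every control genome is homozygous-reference (0/0) or missing (./.);
candidates are then successively restricted to protein-changing annotations
(impact MODERATE or HIGH), autosomes, and a mapped critical interval.  Keys
absent from the control call set count as missing in all controls (their
genotype is unobservable without joint genotyping).

Tier counts are monotonically non-increasing and the across-case "shared"
column is bounded by every per-case count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .variants import (
    AlleleKey,
    CallSet,
    GenotypeClass,
    PROTEIN_CHANGING,
)

__all__ = [
    "CohortSpec",
    "IntervalSet",
    "PrioritizationReport",
    "TIERS",
    "private_hom_alt",
    "shared_private",
    "filter_protein_changing",
    "filter_autosomes",
    "filter_interval",
    "prioritize",
]


@dataclass(frozen=True)
class CohortSpec:
    """Affected cases plus the control cohort they are filtered against."""

    case_samples: tuple[str, ...]
    control_callset: CallSet

    def __post_init__(self):
        overlap = set(self.case_samples) & set(self.control_callset.samples)
        if overlap:
            raise ValueError(f"samples {sorted(overlap)} appear as both case and control")

    @property
    def n_controls(self) -> int:
        return len(self.control_callset.samples)


class IntervalSet:
    """Non-overlapping 1-based inclusive genomic intervals (critical interval)."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        merged: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in intervals:
            if start < 1 or end < start:
                raise ValueError(f"bad interval {contig}:{start}-{end}")
            merged.setdefault(contig, []).append((start, end))
        self.intervals: list[tuple[str, int, int]] = []
        self._trees: dict[str, IntervalTree] = {}
        for contig in sorted(merged):
            spans = sorted(merged[contig])
            out = [spans[0]]
            for s, e in spans[1:]:
                ps, pe = out[-1]
                if s <= pe + 1:
                    out[-1] = (ps, max(pe, e))
                else:
                    out.append((s, e))
            self.intervals.extend((contig, s, e) for s, e in out)
            # interval tree is half-open; +1 makes the inclusive end queryable
            self._trees[contig] = IntervalTree.from_tuples((s, e + 1) for s, e in out)

    @classmethod
    def from_bed(cls, path) -> "IntervalSet":
        from .io import read_bed

        return cls(read_bed(path))

    @property
    def total_span(self) -> int:
        return sum(e - s + 1 for _, s, e in self.intervals)

    def contains(self, contig: str, pos: int) -> bool:
        tree = self._trees.get(contig)
        return bool(tree is not None and tree.overlaps(pos))

    def __len__(self) -> int:
        return len(self.intervals)


def _control_clear(key: AlleleKey, controls: CallSet) -> bool:
    """True if every control genotype at *key* is hom-ref or missing."""
    rec = controls.records.get(key)
    if rec is None:
        return True  # unobserved in controls == missing everywhere
    for gt in rec.genotypes:
        a, b = gt.allele_indices
        if a is None or b is None:
            continue
        if a == 1 or b == 1:
            return False
    return True


def private_hom_alt(case_cs: CallSet, case: str, cohort: CohortSpec) -> set[AlleleKey]:
    """Keys where *case* is hom-alt and no control carries the alternate allele."""
    i = case_cs.sample_index(case)
    controls = cohort.control_callset
    out = set()
    for rec in case_cs:
        a, b = rec.genotypes[i].allele_indices
        if a == 1 and b == 1 and _control_clear(rec.key, controls):
            out.add(rec.key)
    return out


def shared_private(per_case_keys: Sequence[set[AlleleKey]]) -> set[AlleleKey]:
    """Intersection of per-case private key sets (the "shared" column)."""
    if not per_case_keys:
        raise ValueError("need at least one case key set")
    shared = set(per_case_keys[0])
    for keys in per_case_keys[1:]:
        shared &= keys
    return shared


def filter_protein_changing(keys: Iterable[AlleleKey], cs: CallSet) -> set[AlleleKey]:
    """Keep keys annotated MODERATE or HIGH impact; missing impact is dropped."""
    out = set()
    for k in keys:
        rec = cs.records.get(k)
        if rec is not None and rec.impact in PROTEIN_CHANGING:
            out.add(k)
    return out


def filter_autosomes(keys: Iterable[AlleleKey], autosome_names: Sequence[str]) -> set[AlleleKey]:
    """Keep keys on configured autosomes (drops sex chromosomes and unplaced contigs)."""
    if not autosome_names:
        raise ValueError("autosome list must be configured (empty list given)")
    allowed = set(autosome_names)
    return {k for k in keys if k.contig in allowed}


def filter_interval(keys: Iterable[AlleleKey], iv: IntervalSet) -> set[AlleleKey]:
    """Keep keys whose position falls inside the critical interval (ends inclusive)."""
    return {k for k in keys if iv.contains(k.contig, k.pos)}


#: Ordered tier names of the prioritization cascade.
TIERS = (
    "total_hom_alt",
    "private",
    "private_protein_changing",
    "private_protein_changing_autosomal",
    "private_protein_changing_in_interval",
)


@dataclass
class PrioritizationReport:
    """Tiered per-case and shared candidate counts plus surviving keys."""

    case_samples: tuple[str, ...]
    per_case_counts: dict  # sample -> {tier: count}
    shared_counts: dict  # tier -> count
    per_case_keys: dict  # sample -> {tier: set[AlleleKey]}
    shared_keys: dict  # tier -> set[AlleleKey]
    n_controls: int = 0

    @property
    def final_shared_keys(self) -> set[AlleleKey]:
        return self.shared_keys[TIERS[-1]]

    def to_frame(self) -> pd.DataFrame:
        """Table with one row per tier, one column per case plus "shared"."""
        rows = []
        for tier in TIERS:
            row = {"tier": tier}
            for s in self.case_samples:
                row[s] = self.per_case_counts[s][tier]
            row["shared"] = self.shared_counts[tier]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "n_controls": self.n_controls,
            "per_case": self.per_case_counts,
            "shared": self.shared_counts,
            "final_shared_keys": [list(k) for k in sorted(self.final_shared_keys)],
        }


def prioritize(
    case_cs: CallSet,
    cohort: CohortSpec,
    intervals: IntervalSet,
    autosomes: Sequence[str],
) -> PrioritizationReport:
    """Run the full cascade: hom-alt -> private -> protein-changing -> autosomal -> interval.

    Each case is filtered independently against the controls (other cases'
    genotypes do not constrain a case's private set); the shared column is the
    across-case intersection at every tier.
    """
    per_case_keys: dict[str, dict[str, set]] = {}
    for case in cohort.case_samples:
        i = case_cs.sample_index(case)
        total = {
            rec.key for rec in case_cs
            if rec.genotypes[i].allele_indices == (1, 1)
        }
        private = private_hom_alt(case_cs, case, cohort)
        protein = filter_protein_changing(private, case_cs)
        autosomal = filter_autosomes(protein, autosomes)
        in_interval = filter_interval(autosomal, intervals)
        per_case_keys[case] = dict(zip(TIERS, (total, private, protein, autosomal, in_interval)))
    shared_keys = {
        tier: shared_private([per_case_keys[c][tier] for c in cohort.case_samples])
        for tier in TIERS
    }
    return PrioritizationReport(
        case_samples=tuple(cohort.case_samples),
        per_case_counts={c: {t: len(per_case_keys[c][t]) for t in TIERS}
                         for c in cohort.case_samples},
        shared_counts={t: len(shared_keys[t]) for t in TIERS},
        per_case_keys=per_case_keys,
        shared_keys=shared_keys,
        n_controls=cohort.n_controls,
    )
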