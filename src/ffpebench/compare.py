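"""Truth-set construction and call-set benchmarking.

A truth set is the intersection of two callers' call sets (concordance between
independent callers minimizes caller-specific artifacts).  A query call set is
then benchmarked sample-by-sample against the truth set: a sample's variant
set is the allele keys at which its genotype is het or hom-alt (hom-ref and
missing calls are excluded), and

* true positives  (TP) are keys in both truth and query sets,
* false negatives (FN) are truth keys missing from the query,
* false positives (FP) are query keys absent from the truth,
* concordant calls are TP keys whose genotype class matches exactly.

Derived rates use the conventions
``precision = TP/(TP+FP)``, ``recall = TP/(TP+FN)``,
``fn_rate = FN/truth_total``, ``fp_rate = FP/(TP+FP)`` and
``genotype_concordance = concordant/TP``; any ratio with a zero denominator is
*undefined* (``None``), never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .variants import (
    AlleleKey,
    CallSet,
    GenotypeClass,
    class_matches,
    genotype_class,
)

__all__ = [
    "ComparisonCounts",
    "Metrics",
    "intersect_callsets",
    "sample_variant_classes",
    "compare_sample",
    "performance_metrics",
    "benchmark_report",
]


@dataclass(frozen=True, slots=True)
class ComparisonCounts:
    """Per-sample raw benchmarking counts (tp+fn = truth_total, tp+fp = query_total)."""

    truth_total: int
    query_total: int
    tp: int
    fp: int
    fn: int
    concordant: int

    def __post_init__(self):
        if self.tp + self.fn != self.truth_total or self.tp + self.fp != self.query_total:
            raise ValueError(f"inconsistent counts: {self}")
        if not 0 <= self.concordant <= self.tp:
            raise ValueError(f"concordant outside [0, tp]: {self}")


@dataclass(frozen=True, slots=True)
class Metrics:
    """Derived rates on [0, 1]; ``None`` encodes an undefined (0/0) ratio."""

    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    fn_rate: Optional[float]
    fp_rate: Optional[float]
    genotype_concordance: Optional[float]

    def as_percent(self, ndigits: int = 2) -> dict:
        """Rounded percentage view mirroring published-table formatting."""
        from dataclasses import fields

        return {
            f.name: None if (v := getattr(self, f.name)) is None else round(v * 100.0, ndigits)
            for f in fields(self)
        }


def intersect_callsets(
    a: CallSet,
    b: CallSet,
    variant_class: Optional[str] = None,
) -> tuple[CallSet, CallSet, CallSet]:
    """Partition two call sets' allele keys into (shared, unique_a, unique_b).

    The shared call set carries genotypes/annotations from *a* (the designated
    primary).  ``variant_class`` ("snv", "indel", "mnv") restricts the
    comparison to one class.  Disjoint sample lists or contig namespaces are
    warned about, not fatal (site-level sharing is still defined).
    """
    if not set(a.samples) & set(b.samples):
        warnings.warn("call sets share no sample names; genotype-level results "
                      "will come from the primary call set only")
    contigs_a = {k.contig for k in a.keys()}
    contigs_b = {k.contig for k in b.keys()}
    if contigs_a and contigs_b and not contigs_a & contigs_b:
        warnings.warn("call sets share no contig names (chr-prefix mismatch?); "
                      "the intersection will be empty")
    keys_a = {k for k in a.keys() if variant_class is None or class_matches(k, variant_class)}
    keys_b = {k for k in b.keys() if variant_class is None or class_matches(k, variant_class)}
    shared = a.subset(keys_a & keys_b, provenance=f"shared({a.provenance},{b.provenance})")
    unique_a = a.subset(keys_a - keys_b, provenance=f"unique({a.provenance})")
    unique_b = b.subset(keys_b - keys_a, provenance=f"unique({b.provenance})")
    return shared, unique_a, unique_b


def sample_variant_classes(
    cs: CallSet,
    sample: str,
    variant_class: Optional[str] = None,
) -> dict[AlleleKey, GenotypeClass]:
    """The sample's variant set: key -> genotype class, het/hom-alt calls only."""
    i = cs.sample_index(sample)
    out = {}
    for rec in cs:
        if variant_class is not None and not class_matches(rec.key, variant_class):
            continue
        cls = genotype_class(rec.genotypes[i])
        if cls in (GenotypeClass.HET, GenotypeClass.HOM_ALT):
            out[rec.key] = cls
    return out


def compare_sample(
    truth: CallSet,
    query: CallSet,
    sample: str,
    variant_class: Optional[str] = None,
) -> ComparisonCounts:
    """Benchmark one sample's query calls against the truth set.

    Hom-ref and missing genotypes are excluded from both sides before the key
    intersection; concordance compares genotype classes at TP keys.
    """
    t = sample_variant_classes(truth, sample, variant_class)
    q = sample_variant_classes(query, sample, variant_class)
    tp_keys = t.keys() & q.keys()
    concordant = sum(1 for k in tp_keys if t[k] == q[k])
    return ComparisonCounts(
        truth_total=len(t),
        query_total=len(q),
        tp=len(tp_keys),
        fp=len(q) - len(tp_keys),
        fn=len(t) - len(tp_keys),
        concordant=concordant,
    )


def _ratio(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def performance_metrics(c: ComparisonCounts) -> Metrics:
    """Precision/recall/F1 and rate conventions from raw comparison counts."""
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return Metrics(
        precision=precision,
        recall=recall,
        f1=f1,
        fn_rate=_ratio(c.fn, c.truth_total),
        fp_rate=_ratio(c.fp, c.tp + c.fp),
        genotype_concordance=_ratio(c.concordant, c.tp),
    )


def benchmark_report(
    truth: CallSet,
    query: CallSet,
    samples: Optional[Sequence[str]] = None,
    variant_classes: Sequence[str] = ("snv", "indel"),
) -> pd.DataFrame:
    """Tidy benchmarking table: one row per sample x variant class.

    Columns carry both raw counts and percentage metrics; percentages are
    rounded to two decimals (full precision is available via
    :func:`performance_metrics`).  MNV records fall outside both the "snv" and
    "indel" strata and are reported only if explicitly requested.
    """
    if samples is None:
        samples = [s for s in truth.samples if s in query.samples]
    rows = []
    for vc in variant_classes:
        for s in samples:
            c = compare_sample(truth, query, s, variant_class=vc)
            m = performance_metrics(c).as_percent()
            rows.append({
                "sample": s, "variant_class": vc,
                "truth_total": c.truth_total, "query_total": c.query_total,
                "tp": c.tp, "fp": c.fp, "fn": c.fn, "concordant": c.concordant,
                "precision_pct": m["precision"], "recall_pct": m["recall"],
                "f1_pct": m["f1"], "fn_rate_pct": m["fn_rate"],
                "fp_rate_pct": m["fp_rate"],
                "genotype_concordance_pct": m["genotype_concordance"],
            })
    return pd.DataFrame(rows)
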