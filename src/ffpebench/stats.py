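"""Call-set characterization statistics and substitution spectra.

Implements the standard germline call-set quality indicators — the
transition/transversion (Ts/Tv) ratio, heterozygous/homozygous-alternate
(het/hom) ratio, deletion/insertion ratio, singleton and multiallelic-site
counts — and the per-sample 12-class single-nucleotide substitution spectrum
with Poisson standard errors (se = sqrt(count), scaled to calls per 10 Mb).

Genome-wide expectations in mammals: Ts/Tv ~ 2.0-2.1 and del/ins ~ 1; marked
departures (e.g. Ts/Tv near 1 in caller-unique calls, or excess C>T / G>A in
formalin-fixed material) indicate artifact enrichment.

All ratios are ``None`` (undefined) when their denominator is zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .variants import (
    AlleleKey,
    CallSet,
    GenotypeClass,
    VariantClass,
    classify_allele,
    genotype_class,
)

__all__ = [
    "SPECTRUM_CLASSES",
    "DEAMINATION_CLASSES",
    "TRANSITIONS",
    "CallSetSummary",
    "SpectrumResult",
    "SpectrumContrast",
    "ts_tv_ratio",
    "ts_tv_from_counts",
    "del_ins_ratio",
    "del_ins_from_counts",
    "het_hom_ratio",
    "mean_het_hom",
    "singleton_count",
    "multiallelic_site_count",
    "summarize_callset",
    "substitution_spectrum",
    "mean_spectrum",
    "spectrum_contrast",
    "deamination_multiplier_estimate",
    "spectrum_table",
    "plot_spectra",
]

#: The 12 ordered ref>alt substitution classes (raw orientation, not collapsed).
SPECTRUM_CLASSES = (
    "A>C", "A>G", "A>T", "C>A", "C>G", "C>T",
    "G>A", "G>C", "G>T", "T>A", "T>C", "T>G",
)

#: Classes produced by cytosine / 5-methylcytosine deamination (FFPE hallmark).
DEAMINATION_CLASSES = ("C>T", "G>A")

#: Transition substitutions (A<->G, C<->T); everything else is a transversion.
TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


def _require_class(keys: Iterable[AlleleKey], allowed: set, what: str) -> list[AlleleKey]:
    keys = list(keys)
    for k in keys:
        if classify_allele(k) not in allowed:
            raise ValueError(f"{what} computed on non-{what} key {k} "
                             f"({classify_allele(k).value})")
    return keys


def ts_tv_from_counts(ts: int, tv: int) -> Optional[float]:
    """Ts/Tv from pre-tabulated counts; ``None`` when tv is zero."""
    return None if tv == 0 else ts / tv


def del_ins_from_counts(n_del: int, n_ins: int) -> Optional[float]:
    """del/ins from pre-tabulated counts; ``None`` when there are no insertions."""
    return None if n_ins == 0 else n_del / n_ins


def ts_tv_ratio(snv_keys: Iterable[AlleleKey]) -> Optional[float]:
    """Transition/transversion ratio of an SNV key collection.

    Raises if a non-SNV key is supplied; returns ``None`` when there are no
    transversions.
    """
    keys = _require_class(snv_keys, {VariantClass.SNV}, "snv")
    ts = sum(1 for k in keys if (k.ref, k.alt) in TRANSITIONS)
    tv = len(keys) - ts
    return None if tv == 0 else ts / tv


def del_ins_ratio(indel_keys: Iterable[AlleleKey]) -> Optional[float]:
    """Deletion/insertion ratio; ``None`` when there are no insertions."""
    keys = _require_class(indel_keys, {VariantClass.DELETION, VariantClass.INSERTION}, "indel")
    n_del = sum(1 for k in keys if classify_allele(k) is VariantClass.DELETION)
    n_ins = len(keys) - n_del
    return None if n_ins == 0 else n_del / n_ins


def het_hom_ratio(cs: CallSet, sample: str) -> Optional[float]:
    """het / hom-alt count over one sample's non-ref, non-missing calls."""
    i = cs.sample_index(sample)
    het = hom = 0
    for rec in cs:
        cls = genotype_class(rec.genotypes[i])
        if cls is GenotypeClass.HET:
            het += 1
        elif cls is GenotypeClass.HOM_ALT:
            hom += 1
    return None if hom == 0 else het / hom


def mean_het_hom(cs: CallSet) -> Optional[float]:
    """Arithmetic mean of per-sample het/hom ratios (undefined samples skipped)."""
    ratios = [r for s in cs.samples if (r := het_hom_ratio(cs, s)) is not None]
    return None if not ratios else float(np.mean(ratios))


def singleton_count(cs: CallSet, variant_class: Optional[str] = None) -> int:
    """Allele keys whose non-ref genotype occurs in exactly one cohort sample."""
    from .variants import class_matches

    n = 0
    for rec in cs:
        if variant_class is not None and not class_matches(rec.key, variant_class):
            continue
        carriers = sum(
            1 for gt in rec.genotypes
            if genotype_class(gt) in (GenotypeClass.HET, GenotypeClass.HOM_ALT)
        )
        if carriers == 1:
            n += 1
    return n


def multiallelic_site_count(cs: CallSet, variant_class: Optional[str] = None) -> int:
    """Distinct (contig, pos, ref) sites whose records carry multiallelic origin."""
    from .variants import class_matches

    sites = set()
    for rec in cs:
        if not rec.multiallelic_origin:
            continue
        if variant_class is not None and not class_matches(rec.key, variant_class):
            continue
        sites.add((rec.key.contig, rec.key.pos, rec.key.ref))
    return len(sites)


@dataclass(frozen=True, slots=True)
class CallSetSummary:
    """Shared/unique call-set characterization (one column of a summary table)."""

    n_snv: int
    n_indel: int
    n_mnv: int
    n_multiallelic_sites: int
    ts: int
    tv: int
    ts_tv: Optional[float]
    n_del: int
    n_ins: int
    del_ins: Optional[float]
    n_singleton_snv: int
    n_singleton_indel: int
    het_hom_per_sample: dict
    het_hom_mean: Optional[float]


def summarize_callset(cs: CallSet) -> CallSetSummary:
    snv_keys = [k for k in cs.keys() if classify_allele(k) is VariantClass.SNV]
    indel_keys = [k for k in cs.keys()
                  if classify_allele(k) in (VariantClass.DELETION, VariantClass.INSERTION)]
    n_mnv = len(cs) - len(snv_keys) - len(indel_keys)
    ts = sum(1 for k in snv_keys if (k.ref, k.alt) in TRANSITIONS)
    tv = len(snv_keys) - ts
    n_del = sum(1 for k in indel_keys if classify_allele(k) is VariantClass.DELETION)
    n_ins = len(indel_keys) - n_del
    per_sample = {s: het_hom_ratio(cs, s) for s in cs.samples}
    return CallSetSummary(
        n_snv=len(snv_keys),
        n_indel=len(indel_keys),
        n_mnv=n_mnv,
        n_multiallelic_sites=multiallelic_site_count(cs),
        ts=ts,
        tv=tv,
        ts_tv=None if tv == 0 else ts / tv,
        n_del=n_del,
        n_ins=n_ins,
        del_ins=None if n_ins == 0 else n_del / n_ins,
        n_singleton_snv=singleton_count(cs, "snv"),
        n_singleton_indel=singleton_count(cs, "indel"),
        het_hom_per_sample=per_sample,
        het_hom_mean=mean_het_hom(cs),
    )


@dataclass(frozen=True, slots=True)
class SpectrumResult:
    """12-class substitution counts with per-10-Mb rates and Poisson SEs."""

    class_counts: tuple[int, ...]  # ordered as SPECTRUM_CLASSES
    genome_size: int  # bp used as rate denominator
    sample: str = ""
    label: str = ""

    @property
    def scale(self) -> float:
        """Number of 10-Mb windows in the genome (rate denominator)."""
        return self.genome_size / 1e7

    @property
    def rates_per_10mb(self) -> tuple[float, ...]:
        return tuple(c / self.scale for c in self.class_counts)

    @property
    def poisson_se(self) -> tuple[float, ...]:
        return tuple(np.sqrt(c) / self.scale for c in self.class_counts)

    @property
    def total(self) -> int:
        return int(sum(self.class_counts))

    def count_of(self, cls: str) -> int:
        return self.class_counts[SPECTRUM_CLASSES.index(cls)]


def substitution_spectrum(cs: CallSet, sample: str, genome_size: int,
                          label: str = "") -> SpectrumResult:
    """Per-sample substitution spectrum over the sample's non-ref SNV calls.

    ``genome_size`` (bp) is the rate denominator and must be supplied
    explicitly; rates are calls per 10 Mb with Poisson standard errors
    sqrt(count) on the same scale.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    i = cs.sample_index(sample)
    idx = {c: j for j, c in enumerate(SPECTRUM_CLASSES)}
    counts = [0] * len(SPECTRUM_CLASSES)
    for rec in cs:
        k = rec.key
        if classify_allele(k) is not VariantClass.SNV:
            continue
        if genotype_class(rec.genotypes[i]) in (GenotypeClass.HET, GenotypeClass.HOM_ALT):
            counts[idx[f"{k.ref}>{k.alt}"]] += 1
    return SpectrumResult(tuple(counts), genome_size, sample=sample,
                          label=label or cs.provenance)


def mean_spectrum(spectra: list[SpectrumResult], label: str = "mean") -> SpectrumResult:
    """Average per-class counts across samples (rates average identically)."""
    if not spectra:
        raise ValueError("no spectra to average")
    gsizes = {s.genome_size for s in spectra}
    if len(gsizes) > 1:
        raise ValueError("spectra have differing genome sizes")
    counts = np.mean([s.class_counts for s in spectra], axis=0)
    return SpectrumResult(tuple(counts), spectra[0].genome_size, sample="mean", label=label)


@dataclass(frozen=True, slots=True)
class SpectrumContrast:
    """Per-class rate differences (b - a) and ratios (b / a) of two spectra."""

    classes: tuple[str, ...]
    rate_diff: tuple[float, ...]
    rate_ratio: tuple[Optional[float], ...]

    def diff_of(self, cls: str) -> float:
        return self.rate_diff[self.classes.index(cls)]

    def ratio_of(self, cls: str) -> Optional[float]:
        return self.rate_ratio[self.classes.index(cls)]


def spectrum_contrast(a: SpectrumResult, b: SpectrumResult) -> SpectrumContrast:
    """Contrast spectrum *b* against baseline *a* (same genome size required)."""
    if a.genome_size != b.genome_size:
        raise ValueError("spectra computed against different genome sizes")
    ra, rb = a.rates_per_10mb, b.rates_per_10mb
    diffs = tuple(y - x for x, y in zip(ra, rb))
    ratios = tuple(None if x == 0 else y / x for x, y in zip(ra, rb))
    return SpectrumContrast(SPECTRUM_CLASSES, diffs, ratios)


def deamination_multiplier_estimate(contrast: SpectrumContrast) -> Optional[float]:
    """Estimate the fold-enrichment of deamination classes in an inflated spectrum.

    Under an injection model whose per-class excess is proportional to the
    baseline class count — rate_c for the ten non-deamination classes and
    m x rate_c for C>T and G>A — each class ratio satisfies ratio-1 = excess
    fraction, so m = mean(ratio_deam - 1) / mean(ratio_other - 1).
    Returns ``None`` if any needed ratio is undefined or the non-deamination
    excess is zero/negative.
    """
    deam, other = [], []
    for cls, ratio in zip(contrast.classes, contrast.rate_ratio):
        if ratio is None:
            return None
        (deam if cls in DEAMINATION_CLASSES else other).append(ratio - 1.0)
    denom = float(np.mean(other))
    return None if denom <= 0 else float(np.mean(deam)) / denom


def spectrum_table(spectra: list[SpectrumResult]) -> pd.DataFrame:
    """Tidy spectrum table: one row per class x sample x call set."""
    rows = []
    for s in spectra:
        for cls, count, rate, se in zip(SPECTRUM_CLASSES, s.class_counts,
                                        s.rates_per_10mb, s.poisson_se):
            rows.append({
                "callset": s.label, "sample": s.sample, "class": cls,
                "count": count, "rate_per_10mb": rate, "poisson_se": se,
            })
    return pd.DataFrame(rows)


def plot_spectra(spectra: list[SpectrumResult], path, title: str = "") -> None:
    """Grouped bar plot of substitution rates with Poisson error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    x = np.arange(len(SPECTRUM_CLASSES))
    width = 0.8 / max(len(spectra), 1)
    for j, s in enumerate(spectra):
        ax.bar(x + j * width, s.rates_per_10mb, width,
               yerr=s.poisson_se, capsize=2,
               label=s.label or s.sample or f"set {j}")
    ax.set_xticks(x + width * (len(spectra) - 1) / 2)
    ax.set_xticklabels(SPECTRUM_CLASSES, rotation=45)
    ax.set_ylabel("calls per 10 Mb")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
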