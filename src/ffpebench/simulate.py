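"""Synthetic germline call sets with the statistical structure the analyses assume.

The generator emulates, at desk scale, the inputs of a matched fresh-frozen /
FFPE whole-genome comparison:

* a multi-sample germline *truth set* whose Ts/Tv, het/hom and del/ins ratios
  hit configurable genome-wide targets (defaults 2.1 / 1.35 / 1.04),
* two imperfect *callers* with configurable false-negative, false-positive and
  genotype-error rates (false positives drawn with a low Ts/Tv mix, as
  caller-unique calls show in practice),
* an *FFPE artifact* layer that inflates the C>T / G>A substitution classes by
  a deamination multiplier on top of a uniform excess false-positive rate,
* a case/control *cohort* with a planted homozygous, HIGH-impact causal
  variant for exercising the recessive-prioritization cascade end to end.

Positions are abstract coordinates on a toy genome; no reference FASTA is
synthesized, and reference bases are only consistent per record.  All
randomness flows from explicit seeds; a fixed seed reproduces byte-identical
VCF output.

Genotypes follow a biallelic Hardy-Weinberg model with Beta(a, b)-distributed
allele frequency.  The cohort-level het/hom-alt ratio under this model is
``E[2f(1-f)] / E[f^2] = 2b / (a + 1)`` — conditioning on segregating sites
cancels exactly — so the Beta shape is calibrated in closed form:
``b = target_het_hom * (a + 1) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .variants import (
    AlleleKey,
    CallSet,
    GenotypeClass,
    Impact,
    VariantRecord,
    genotype,
    genotype_class,
)

__all__ = [
    "Contig",
    "GenomeModel",
    "TruthParams",
    "CallerProfile",
    "FFPEArtifactProfile",
    "beta_for_het_hom",
    "generate_truth",
    "simulate_caller",
    "inject_ffpe_artifacts",
    "generate_cohort",
]

_BASES = ("A", "C", "G", "T")
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True, slots=True)
class Contig:
    name: str
    length: int
    category: str = "autosome"  # autosome | sex | unplaced


@dataclass(frozen=True)
class GenomeModel:
    """Ordered contigs with autosome/sex/unplaced labels."""

    contigs: tuple[Contig, ...]

    def __post_init__(self):
        names = [c.name for c in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate contig names")
        if any(c.length < 1 for c in self.contigs):
            raise ValueError("contig lengths must be >= 1")

    @property
    def genome_size(self) -> int:
        return sum(c.length for c in self.contigs)

    @property
    def autosomes(self) -> list[str]:
        return [c.name for c in self.contigs if c.category == "autosome"]

    @classmethod
    def toy(cls, contig_length: int = 10_000_000) -> "GenomeModel":
        """Small default genome: 5 autosomes, one X, one unplaced scaffold."""
        contigs = [Contig(f"chr{i}", contig_length) for i in range(1, 6)]
        contigs.append(Contig("chrX", contig_length, "sex"))
        contigs.append(Contig("chrUn_scaffold1", contig_length, "unplaced"))
        return cls(tuple(contigs))

    def locate(self, offsets: np.ndarray) -> list[tuple[str, int]]:
        """Map global 0-based offsets to (contig, 1-based position)."""
        bounds = np.cumsum([c.length for c in self.contigs])
        idx = np.searchsorted(bounds, offsets, side="right")
        starts = bounds - np.array([c.length for c in self.contigs])
        return [(self.contigs[i].name, int(off - starts[i]) + 1)
                for i, off in zip(idx, offsets)]


def beta_for_het_hom(target_het_hom: float, alpha: float = 1.0) -> tuple[float, float]:
    """Beta(a, b) allele-frequency shape hitting a target het/hom-alt ratio.

    Closed form from E[2f(1-f)]/E[f^2] = 2b/(a+1); conditioning on the site
    segregating in the sampled cohort cancels from the ratio.
    """
    if target_het_hom <= 0:
        raise ValueError("target het/hom must be positive")
    return alpha, target_het_hom * (alpha + 1.0) / 2.0


@dataclass(frozen=True)
class TruthParams:
    """Truth-set generator settings; defaults match genome-wide expectations."""

    n_snv: int = 10_000
    n_indel: int = 3_000
    target_ts_tv: float = 2.1
    target_het_hom: float = 1.35
    target_del_ins: float = 1.04
    #: fraction of SNV sites given a second alternate allele; shared
    #: genome-wide call sets show multiallelic SNV sites at the ~0.1% level
    multiallelic_fraction: float = 0.001
    n_samples: int = 3
    af_alpha: float = 1.0  # Beta shape a; b is calibrated from target_het_hom
    #: fraction of records drawn with annotations violating one hard-filter
    #: criterion (for exercising hard filtering); 0 = all-passing annotations
    fail_fraction: float = 0.0
    impact_probs: tuple[float, float, float, float] = (0.01, 0.04, 0.15, 0.80)
    seed: int = 0

    def __post_init__(self):
        if self.n_snv < 0 or self.n_indel < 0:
            raise ValueError("variant counts must be >= 0")
        for r in (self.target_ts_tv, self.target_het_hom, self.target_del_ins):
            if r <= 0:
                raise ValueError("target ratios must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class CallerProfile:
    """Error model of one imperfect caller."""

    fn_rate: float = 0.05  # per-record miss probability
    fp_rate: float = 0.04  # expected false positives per true record
    genotype_error_rate: float = 0.01  # per-sample chance a TP genotype class flips
    fp_ts_tv: float = 1.0  # Ts/Tv of false-positive SNVs (caller-unique calls ~1)
    seed: int = 0

    def __post_init__(self):
        for p in (self.fn_rate, self.genotype_error_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")


@dataclass(frozen=True)
class FFPEArtifactProfile:
    """Deamination-driven excess false positives layered onto a call set.

    Per substitution class c with current count n_c, the injected extra count
    is Poisson with mean ``extra_fp_rate * n_c`` for the ten non-deamination
    classes and ``deamination_multiplier * extra_fp_rate * n_c`` for C>T and
    G>A, so (ratio - 1) recovers the multiplier as a ratio of class excesses.
    Defaults reflect the 15-20% transition inflation reported for
    hard-filtered FFPE call sets relative to matched fresh-frozen data.
    """

    deamination_multiplier: float = 2.5
    extra_fp_rate: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if self.deamination_multiplier < 1:
            raise ValueError("deamination multiplier must be >= 1")
        if self.extra_fp_rate < 0:
            raise ValueError("extra_fp_rate must be >= 0")


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def _unique_offsets(rng: np.random.Generator, genome_size: int, n: int,
                    exclude: Optional[set] = None) -> np.ndarray:
    """Draw n distinct global offsets, avoiding ``exclude``."""
    if n > genome_size - len(exclude or ()):
        raise ValueError(f"cannot place {n} variants on a {genome_size} bp genome")
    exclude = exclude or set()
    chosen: list[int] = []
    seen = set(exclude)
    while len(chosen) < n:
        draw = rng.integers(0, genome_size, size=int((n - len(chosen)) * 1.3) + 16)
        for off in draw:
            off = int(off)
            if off not in seen:
                seen.add(off)
                chosen.append(off)
                if len(chosen) == n:
                    break
    return np.array(sorted(chosen), dtype=np.int64)


def _draw_snv_alleles(rng: np.random.Generator, n: int, ts_tv: float) -> list[tuple[str, str]]:
    """Draw n (ref, alt) SNV pairs with transition probability ts/(1+ts_tv)."""
    p_ts = ts_tv / (1.0 + ts_tv)
    is_ts = rng.random(n) < p_ts
    refs = rng.integers(0, 4, size=n)
    out = []
    for i in range(n):
        ref = _BASES[refs[i]]
        if is_ts[i]:
            alt = _TRANSITION_PARTNER[ref]
        else:
            choices = [b for b in _BASES if b != ref and b != _TRANSITION_PARTNER[ref]]
            alt = choices[rng.integers(0, 2)]
        out.append((ref, alt))
    return out


def _draw_indel_alleles(rng: np.random.Generator, n: int, del_ins: float
                        ) -> list[tuple[str, str]]:
    """Anchored indels; deletion probability del_ins/(1+del_ins); lengths 1-3 bp."""
    p_del = del_ins / (1.0 + del_ins)
    out = []
    for _ in range(n):
        anchor = _BASES[rng.integers(0, 4)]
        length = int(rng.integers(1, 4))
        extra = "".join(_BASES[j] for j in rng.integers(0, 4, size=length))
        if rng.random() < p_del:
            out.append((anchor + extra, anchor))
        else:
            out.append((anchor, anchor + extra))
    return out


def _hw_segregating(rng: np.random.Generator, a: float, b: float, n_sites: int,
                    n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Beta allele frequencies + Hardy-Weinberg copy counts, conditioned on
    each site segregating (>= 1 non-ref genotype among the samples).

    Rejection resamples frequency and genotypes jointly, i.e. draws from the
    conditional model pi(f | segregating) x HW; the cohort het/hom ratio under
    this conditioning equals the unconditional 2b/(a+1) (see module docstring).
    Returns ``(freqs, gts)`` with gts shaped (n_sites, n_samples), values 0/1/2.
    """
    freqs = rng.beta(a, b, size=n_sites)
    gts = rng.binomial(2, freqs[:, None], size=(n_sites, n_samples))
    if n_samples > 0:
        while True:
            mask = gts.sum(axis=1) == 0
            n_bad = int(mask.sum())
            if n_bad == 0:
                break
            freqs[mask] = rng.beta(a, b, size=n_bad)
            gts[mask] = rng.binomial(2, freqs[mask, None], size=(n_bad, n_samples))
    return freqs, gts


_GT_BY_COPIES = None


def _copies_to_calls(copies: Sequence[int]) -> tuple:
    global _GT_BY_COPIES
    if _GT_BY_COPIES is None:
        _GT_BY_COPIES = {0: genotype(0, 0), 1: genotype(0, 1), 2: genotype(1, 1),
                         -1: genotype(None, None)}
    table = _GT_BY_COPIES
    return tuple(table[int(c)] for c in copies)


def _passing_annotations(rng: np.random.Generator) -> tuple[float, dict]:
    """QUAL and INFO values comfortably inside every hard-filter boundary."""
    qual = float(50.0 + rng.gamma(2.0, 200.0))
    ann = {
        "QD": float(8.0 + rng.gamma(2.0, 6.0)),
        "SOR": float(rng.uniform(0.2, 2.0)),
        "FS": float(rng.uniform(0.0, 20.0)),
        "MQ": float(rng.uniform(50.0, 60.0)),
        "MQRankSum": float(rng.normal(0.0, 1.0)),
        "ReadPosRankSum": float(rng.normal(0.0, 1.0)),
    }
    return qual, ann


_FAILING_VALUES = {
    "QD": 0.5, "QUAL": 10.0, "SOR": 9.0, "FS": 90.0,
    "MQ": 25.0, "MQRankSum": -20.0, "ReadPosRankSum": -25.0,
}


def _maybe_failing_annotations(rng: np.random.Generator, fail: bool,
                               is_indel: bool) -> tuple[float, dict]:
    qual, ann = _passing_annotations(rng)
    if fail:
        snv_criteria = ["QD", "QUAL", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum"]
        indel_criteria = ["QD", "QUAL", "FS", "ReadPosRankSum", "SOR"]
        crit = (indel_criteria if is_indel else snv_criteria)[
            rng.integers(0, 5 if is_indel else 7)]
        if crit == "QUAL":
            qual = _FAILING_VALUES["QUAL"]
        elif crit == "FS" and is_indel:
            ann["FS"] = 250.0
        elif crit == "SOR" and is_indel:
            ann["SOR"] = 12.0
        elif crit == "ReadPosRankSum" and is_indel:
            ann["ReadPosRankSum"] = -25.0
        else:
            ann[crit] = _FAILING_VALUES[crit]
    return qual, ann


_IMPACTS = (Impact.HIGH, Impact.MODERATE, Impact.LOW, Impact.MODIFIER)


def _draw_impact(rng: np.random.Generator, probs) -> Impact:
    return _IMPACTS[int(rng.choice(4, p=probs))]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_truth(genome: GenomeModel, params: TruthParams) -> CallSet:
    """Generate a multi-sample germline truth call set.

    Substitution classes are drawn to hit ``target_ts_tv`` in expectation,
    indels to hit ``target_del_ins``; per-sample genotypes follow the
    calibrated Hardy-Weinberg/Beta model; a ``multiallelic_fraction`` of SNV
    sites receives a second alternate allele (decomposed into two records
    flagged ``multiallelic_origin``).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    n_total = params.n_snv + params.n_indel
    samples = [f"sample{i + 1}" for i in range(params.n_samples)]
    cs = CallSet(samples, provenance="synthetic-truth")
    if n_total == 0:
        return cs

    offsets = _unique_offsets(rng, genome.genome_size, n_total)
    loci = genome.locate(offsets)
    rng.shuffle(loci)
    snv_alleles = _draw_snv_alleles(rng, params.n_snv, params.target_ts_tv)
    indel_alleles = _draw_indel_alleles(rng, params.n_indel, params.target_del_ins)
    alleles = snv_alleles + indel_alleles
    is_indel = [False] * params.n_snv + [True] * params.n_indel

    a, b = beta_for_het_hom(params.target_het_hom, params.af_alpha)
    _, gt_matrix = _hw_segregating(rng, a, b, n_total, params.n_samples)
    fail_mask = rng.random(n_total) < params.fail_fraction

    n_multi = int(round(params.multiallelic_fraction * params.n_snv))
    multi_sites = set(rng.choice(params.n_snv, size=n_multi, replace=False)) if n_multi else set()

    for i, ((contig, pos), (ref, alt)) in enumerate(zip(loci, alleles)):
        qual, ann = _maybe_failing_annotations(rng, bool(fail_mask[i]), is_indel[i])
        multi = i in multi_sites
        cs.add(VariantRecord(
            key=AlleleKey(contig, pos, ref, alt),
            genotypes=_copies_to_calls(gt_matrix[i]),
            qual=qual,
            annotations=ann,
            impact=_draw_impact(rng, params.impact_probs),
            multiallelic_origin=multi,
        ))
        if multi:
            # second alternate allele at the same site, carried het by one
            # sample; drawn under the same transition probability so the
            # call-set Ts/Tv stays on target
            partner = _TRANSITION_PARTNER[ref]
            cands = [x for x in _BASES if x not in (ref, alt)]
            p_ts = params.target_ts_tv / (1.0 + params.target_ts_tv)
            if partner in cands and rng.random() < p_ts:
                alt2 = partner
            else:
                tv_cands = [x for x in cands if x != partner]
                alt2 = tv_cands[int(rng.integers(0, len(tv_cands)))]
            carrier = int(rng.integers(0, params.n_samples))
            copies = [0] * params.n_samples
            copies[carrier] = 1
            qual2, ann2 = _passing_annotations(rng)
            cs.add(VariantRecord(
                key=AlleleKey(contig, pos, ref, alt2),
                genotypes=_copies_to_calls(copies),
                qual=qual2,
                annotations=ann2,
                impact=_draw_impact(rng, params.impact_probs),
                multiallelic_origin=True,
            ))
    return cs


def _flip_genotype(gt):
    """Corrupt a genotype class: het <-> hom-alt; hom-ref/missing unchanged."""
    cls = genotype_class(gt)
    if cls is GenotypeClass.HET:
        return genotype(1, 1)
    if cls is GenotypeClass.HOM_ALT:
        return genotype(0, 1)
    return gt


def simulate_caller(truth: CallSet, profile: CallerProfile,
                    genome: GenomeModel, provenance: str = "synthetic-caller") -> CallSet:
    """Derive an imperfect caller's output from the truth set.

    Each truth record is dropped with probability ``fn_rate``; surviving
    per-sample genotypes are class-corrupted with probability
    ``genotype_error_rate``; ``round(fp_rate * n_truth)`` false-positive
    records are added at fresh positions with SNV classes drawn at
    ``fp_ts_tv`` (false positives are genotyped het in every sample, making
    per-sample precision predictable from the configured rate).
    """
    rng = np.random.default_rng(profile.seed)
    query = CallSet(truth.samples, provenance=provenance)
    n_samples = len(truth.samples)
    records = truth.sorted_records()
    keep = rng.random(len(records)) >= profile.fn_rate
    err = rng.random((len(records), n_samples)) < profile.genotype_error_rate
    for i, rec in enumerate(records):
        if not keep[i]:
            continue
        gts = rec.genotypes
        if err[i].any():
            gts = tuple(_flip_genotype(g) if err[i][j] else g for j, g in enumerate(gts))
        query.add(VariantRecord(
            key=rec.key, genotypes=gts, qual=rec.qual,
            annotations=dict(rec.annotations), impact=rec.impact,
            multiallelic_origin=rec.multiallelic_origin,
        ))

    n_fp = int(round(profile.fp_rate * len(records)))
    if n_fp:
        taken = {_global_offset(genome, k.contig, k.pos) for k in truth.keys()}
        offsets = _unique_offsets(rng, genome.genome_size, n_fp, exclude=taken)
        loci = genome.locate(offsets)
        n_snv_truth = sum(1 for k in truth.keys() if len(k.ref) == 1 and len(k.alt) == 1)
        snv_frac = n_snv_truth / max(len(records), 1)
        fp_is_snv = rng.random(n_fp) < snv_frac
        snv_pairs = iter(_draw_snv_alleles(rng, int(fp_is_snv.sum()), profile.fp_ts_tv))
        indel_pairs = iter(_draw_indel_alleles(rng, n_fp - int(fp_is_snv.sum()), 1.0))
        het_all = _copies_to_calls([1] * n_samples)
        for j, (contig, pos) in enumerate(loci):
            ref, alt = next(snv_pairs) if fp_is_snv[j] else next(indel_pairs)
            qual, ann = _passing_annotations(rng)
            key = AlleleKey(contig, pos, ref, alt)
            if key in query.records:
                continue
            query.add(VariantRecord(key=key, genotypes=het_all, qual=qual,
                                    annotations=ann, impact=None))
    return query


def _global_offset(genome: GenomeModel, contig: str, pos: int) -> int:
    off = 0
    for c in genome.contigs:
        if c.name == contig:
            return off + pos - 1
        off += c.length
    raise KeyError(contig)


def inject_ffpe_artifacts(query: CallSet, profile: FFPEArtifactProfile,
                          genome: GenomeModel,
                          provenance: str = "synthetic-ffpe") -> CallSet:
    """Add deamination-enriched false-positive SNVs to a call set.

    See :class:`FFPEArtifactProfile` for the per-class injection model.  With
    ``extra_fp_rate = 0`` the call set is returned unchanged (new object, same
    records).
    """
    from .stats import SPECTRUM_CLASSES, DEAMINATION_CLASSES

    rng = np.random.default_rng(profile.seed)
    out = CallSet(query.samples, dict(query.records), provenance=provenance)
    if profile.extra_fp_rate == 0:
        return out
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    for k in query.keys():
        if len(k.ref) == 1 and len(k.alt) == 1:
            counts[f"{k.ref}>{k.alt}"] += 1
    extra_per_class = {}
    for cls in SPECTRUM_CLASSES:
        lam = profile.extra_fp_rate * counts[cls]
        if cls in DEAMINATION_CLASSES:
            lam *= profile.deamination_multiplier
        extra_per_class[cls] = int(rng.poisson(lam))
    n_extra = sum(extra_per_class.values())
    if n_extra == 0:
        return out
    taken = {_global_offset(genome, k.contig, k.pos) for k in query.keys()}
    offsets = _unique_offsets(rng, genome.genome_size, n_extra, exclude=taken)
    loci = genome.locate(offsets)
    het_all = _copies_to_calls([1] * len(query.samples))
    j = 0
    for cls in SPECTRUM_CLASSES:
        ref, alt = cls.split(">")
        for _ in range(extra_per_class[cls]):
            contig, pos = loci[j]
            j += 1
            qual, ann = _passing_annotations(rng)
            out.add(VariantRecord(key=AlleleKey(contig, pos, ref, alt),
                                  genotypes=het_all, qual=qual, annotations=ann))
    return out


def generate_cohort(
    genome: GenomeModel,
    n_controls: int,
    seed: int,
    n_cases: int = 3,
    n_background: int = 2_000,
    planted: Optional[AlleleKey] = None,
    planted_impact: Impact = Impact.HIGH,
    interval: Optional[Sequence[tuple[str, int, int]]] = None,
    target_het_hom: float = 1.35,
    control_missing_rate: float = 0.02,
    impact_probs: tuple[float, float, float, float] = (0.01, 0.04, 0.15, 0.80),
) -> tuple[CallSet, CallSet, AlleleKey]:
    """Simulate a case/control cohort with a planted recessive causal variant.

    Background variants share Beta-distributed allele frequencies between
    cases and controls (Hardy-Weinberg genotypes; controls additionally
    missing at ``control_missing_rate``).  The planted key — supplied, or
    auto-placed inside ``interval`` (first autosomal interval) if given,
    otherwise on the first autosome — is hom-alt in every case, hom-ref or
    missing in every control, and annotated ``planted_impact``.

    Returns ``(case call set, control call set, planted key)``.
    """
    if n_controls < 0:
        raise ValueError("n_controls must be >= 0")
    rng = np.random.default_rng(seed)
    case_names = [f"case{i + 1}" for i in range(n_cases)]
    control_names = [f"control{i + 1:04d}" for i in range(n_controls)]

    if planted is None:
        if interval:
            contig, start, end = interval[0]
            pos = int(rng.integers(start, end + 1))
        else:
            contig = genome.autosomes[0]
            pos = int(rng.integers(1, genome.contigs[0].length + 1))
        ref, alt = _draw_snv_alleles(rng, 1, 2.1)[0]
        planted = AlleleKey(contig, pos, ref, alt)

    offsets = _unique_offsets(rng, genome.genome_size, n_background,
                              exclude={_global_offset(genome, planted.contig, planted.pos)})
    loci = genome.locate(offsets)
    n_bg_snv = int(round(n_background * 0.8))
    alleles = (_draw_snv_alleles(rng, n_bg_snv, 2.1)
               + _draw_indel_alleles(rng, n_background - n_bg_snv, 1.04))
    rng.shuffle(alleles)

    a, b = beta_for_het_hom(target_het_hom)
    freqs, case_gt = _hw_segregating(rng, a, b, n_background, n_cases)
    control_gt = rng.binomial(2, freqs[:, None], size=(n_background, n_controls)) \
        if n_controls else np.zeros((n_background, 0), dtype=int)
    missing = rng.random(control_gt.shape) < control_missing_rate
    control_gt = np.where(missing, -1, control_gt)

    case_cs = CallSet(case_names, provenance="synthetic-cases")
    control_cs = CallSet(control_names, provenance="synthetic-controls")
    for i, ((contig, pos), (ref, alt)) in enumerate(zip(loci, alleles)):
        key = AlleleKey(contig, pos, ref, alt)
        impact = _draw_impact(rng, impact_probs)
        qual, ann = _passing_annotations(rng)
        case_cs.add(VariantRecord(key=key, genotypes=_copies_to_calls(case_gt[i]),
                                  qual=qual, annotations=ann, impact=impact))
        if n_controls:
            control_cs.add(VariantRecord(key=key,
                                         genotypes=_copies_to_calls(control_gt[i]),
                                         qual=qual, annotations=dict(ann)))

    qual, ann = _passing_annotations(rng)
    case_cs.add(VariantRecord(key=planted,
                              genotypes=_copies_to_calls([2] * n_cases),
                              qual=qual, annotations=ann, impact=planted_impact))
    if n_controls:
        planted_controls = np.where(rng.random(n_controls) < control_missing_rate, -1, 0)
        control_cs.add(VariantRecord(key=planted,
                                     genotypes=_copies_to_calls(planted_controls),
                                     qual=qual, annotations=dict(ann)))
    return case_cs, control_cs, planted
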