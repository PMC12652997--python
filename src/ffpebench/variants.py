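"""Core domain types for allele-level germline variant analysis.

Everything downstream (comparison, statistics, filtering, prioritization)
operates on *decomposed, trimmed* allele-level records: one record per
(contig, pos, ref, alt) with per-sample genotypes expressed relative to that
single focal alternate allele.  This makes call sets from different variant
callers directly comparable by set arithmetic, approximating the allele
matching of ``bcftools isec`` without requiring a reference genome.

Coordinates are 1-based inclusive (VCF convention) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

__all__ = [
    "VariantClass",
    "GenotypeClass",
    "Impact",
    "AlleleKey",
    "GenotypeCall",
    "VariantRecord",
    "CallSet",
    "genotype",
    "trim_redundant_bases",
    "decompose_genotype",
    "decompose",
    "classify_allele",
    "genotype_class",
    "validate_key",
]

_VALID_BASES = frozenset("ACGTN")


class VariantClass(str, Enum):
    SNV = "snv"
    INSERTION = "insertion"
    DELETION = "deletion"
    MNV = "mnv"


class GenotypeClass(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


class Impact(str, Enum):
    """snpEff-style functional impact classes (ANN field, third subfield)."""

    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"


#: Impact classes considered protein-changing in recessive-disease filtering.
PROTEIN_CHANGING = frozenset({Impact.HIGH, Impact.MODERATE})


class AlleleKey(NamedTuple):
    """Normalized identity of one alternate allele: the unit of all set operations."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str


def validate_key(key: AlleleKey) -> None:
    """Raise ``ValueError`` if *key* violates the AlleleKey invariants.

    A valid key has pos >= 1, non-empty uppercase A/C/G/T/N alleles,
    ref != alt, and is in trimmed canonical form.
    """
    if key.pos < 1:
        raise ValueError(f"position must be >= 1, got {key.pos}")
    for label, allele in (("ref", key.ref), ("alt", key.alt)):
        if not allele:
            raise ValueError(f"{label} allele is empty in {key}")
        if not set(allele) <= _VALID_BASES:
            raise ValueError(f"{label} allele {allele!r} contains non-ACGTN characters")
    if key.ref == key.alt:
        raise ValueError(f"ref == alt in {key}")
    if trim_redundant_bases(key.pos, key.ref, key.alt) != (key.pos, key.ref, key.alt):
        raise ValueError(f"{key} is not in trimmed canonical form")


def trim_redundant_bases(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Remove redundant shared bases from a ref/alt pair.

    Shared trailing bases are removed first, then shared leading bases with
    ``pos`` incremented accordingly; at least one base always remains in each
    allele.  Idempotent.  No reference-FASTA left-alignment is attempted.
    """
    if not ref or not alt:
        raise ValueError("ref and alt must be non-empty")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True, slots=True)
class GenotypeCall:
    """A diploid genotype as a pair of allele indices (``None`` = missing).

    Comparison semantics ignore phase and index order: two calls are
    equivalent when their allele-index multisets match.
    """

    allele_indices: tuple[Optional[int], Optional[int]]
    phased: bool = False

    @property
    def is_missing(self) -> bool:
        return any(i is None for i in self.allele_indices)

    def sorted_indices(self) -> tuple[Optional[int], Optional[int]]:
        a, b = self.allele_indices
        if a is None or b is None:
            return self.allele_indices
        return (a, b) if a <= b else (b, a)

    def equivalent(self, other: "GenotypeCall") -> bool:
        """Phase- and order-insensitive genotype equality."""
        return self.sorted_indices() == other.sorted_indices()

    def __str__(self) -> str:
        sep = "|" if self.phased else "/"
        return sep.join("." if i is None else str(i) for i in self.allele_indices)


_GT_CACHE: dict[tuple, GenotypeCall] = {}


def genotype(a: Optional[int], b: Optional[int], phased: bool = False) -> GenotypeCall:
    """Interned :class:`GenotypeCall` constructor (cheap for large cohorts)."""
    key = (a, b, phased)
    call = _GT_CACHE.get(key)
    if call is None:
        call = _GT_CACHE[key] = GenotypeCall((a, b), phased)
    return call


def genotype_class(gt: GenotypeCall, focal: int = 1) -> GenotypeClass:
    """Classify a genotype relative to the focal alternate allele.

    Any missing index makes the call ``missing`` (half-missing calls such as
    ``./1`` are treated conservatively as missing).  Non-focal alternate
    indices count as reference for the focal record.
    """
    a, b = gt.allele_indices
    if a is None or b is None:
        return GenotypeClass.MISSING
    copies = (a == focal) + (b == focal)
    if copies == 2:
        return GenotypeClass.HOM_ALT
    if copies == 1:
        return GenotypeClass.HET
    return GenotypeClass.HOM_REF


def classify_allele(key: AlleleKey) -> VariantClass:
    """Classify a trimmed allele as snv / insertion / deletion / mnv."""
    lr, la = len(key.ref), len(key.alt)
    if lr == 1 and la == 1:
        return VariantClass.SNV
    if la > lr:
        return VariantClass.INSERTION
    if lr > la:
        return VariantClass.DELETION
    return VariantClass.MNV


def decompose_genotype(gt: GenotypeCall, focal_alt: int) -> GenotypeCall:
    """Re-express a (possibly multiallelic) genotype relative to one focal alt.

    The focal alternate index maps to 1; every other non-missing index
    (reference or non-focal alternate) maps to 0; missing stays missing.
    """

    def remap(i: Optional[int]) -> Optional[int]:
        if i is None:
            return None
        return 1 if i == focal_alt else 0

    a, b = gt.allele_indices
    return genotype(remap(a), remap(b), gt.phased)


@dataclass(slots=True)
class VariantRecord:
    """One decomposed allele-level record with per-sample genotypes."""

    key: AlleleKey
    genotypes: tuple[GenotypeCall, ...]
    qual: Optional[float] = None
    #: site-level numeric annotations (QD, SOR, FS, MQ, MQRankSum, ReadPosRankSum ...)
    annotations: dict = field(default_factory=dict)
    impact: Optional[Impact] = None
    multiallelic_origin: bool = False
    #: failed filter labels; empty tuple means PASS / unfiltered
    filters: tuple[str, ...] = ()

    @property
    def variant_class(self) -> VariantClass:
        return classify_allele(self.key)

    def genotype_for(self, sample_index: int) -> GenotypeCall:
        return self.genotypes[sample_index]


def decompose(
    contig: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    genotypes: Sequence[GenotypeCall],
    qual: Optional[float] = None,
    annotations: Optional[dict] = None,
    impacts: Optional[Sequence[Optional[Impact]]] = None,
    filters: tuple[str, ...] = (),
    multiallelic_origin: Optional[bool] = None,
) -> list[VariantRecord]:
    """Decompose a raw VCF site into one trimmed record per alternate allele.

    Genotypes of each record count copies of the focal alt only; other alts
    are treated as non-focal (reference-like) for that record.  Each record's
    alleles are trimmed via :func:`trim_redundant_bases`.
    """
    if not alts:
        raise ValueError("site has no alternate alleles")
    multi = len(alts) > 1 if multiallelic_origin is None else multiallelic_origin
    records = []
    for i, alt in enumerate(alts, start=1):
        tpos, tref, talt = trim_redundant_bases(pos, ref, alt)
        key = AlleleKey(contig, tpos, tref, talt)
        gts = tuple(decompose_genotype(gt, i) for gt in genotypes)
        records.append(
            VariantRecord(
                key=key,
                genotypes=gts,
                qual=qual,
                annotations=dict(annotations or {}),
                impact=impacts[i - 1] if impacts else None,
                multiallelic_origin=multi,
                filters=filters,
            )
        )
    return records


class CallSet:
    """A multi-sample collection of allele-level records indexed by AlleleKey.

    At most one record per key; all records share the sample list.
    """

    def __init__(
        self,
        samples: Sequence[str],
        records: Optional[dict[AlleleKey, VariantRecord]] = None,
        provenance: str = "",
    ):
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample names")
        self.samples: tuple[str, ...] = tuple(samples)
        self.records: dict[AlleleKey, VariantRecord] = records if records is not None else {}
        self.provenance = provenance
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records.values())

    def __contains__(self, key: AlleleKey) -> bool:
        return key in self.records

    def keys(self) -> Iterable[AlleleKey]:
        return self.records.keys()

    def sample_index(self, sample: str) -> int:
        try:
            return self._sample_index[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} not in call set {self.provenance!r} "
                           f"(samples: {list(self.samples)})") from None

    def add(self, record: VariantRecord) -> None:
        if len(record.genotypes) != len(self.samples):
            raise ValueError(
                f"record has {len(record.genotypes)} genotypes for "
                f"{len(self.samples)} samples"
            )
        self.records[record.key] = record

    def genotype_of(self, key: AlleleKey, sample: str) -> GenotypeCall:
        return self.records[key].genotypes[self.sample_index(sample)]

    def genotype_class_of(self, key: AlleleKey, sample: str) -> GenotypeClass:
        return genotype_class(self.genotype_of(key, sample))

    # -- derived views ------------------------------------------------------------
    def subset(self, keys: Iterable[AlleleKey], provenance: Optional[str] = None) -> "CallSet":
        recs = {k: self.records[k] for k in keys if k in self.records}
        return CallSet(self.samples, recs, provenance if provenance is not None else self.provenance)

    def subset_class(self, variant_class: "str | VariantClass | None") -> "CallSet":
        """Records of one class; ``"indel"`` selects insertions and deletions."""
        if variant_class is None:
            return self
        keys = [k for k in self.records if class_matches(k, variant_class)]
        return self.subset(keys)

    def with_samples(self, samples: Sequence[str]) -> "CallSet":
        """Project onto a subset of samples (genotype columns)."""
        idx = [self.sample_index(s) for s in samples]
        out = CallSet(samples, provenance=self.provenance)
        for rec in self:
            out.add(replace(rec, genotypes=tuple(rec.genotypes[i] for i in idx)))
        return out

    def sorted_records(self, contig_order: Optional[Sequence[str]] = None) -> list[VariantRecord]:
        if contig_order:
            rank = {c: i for i, c in enumerate(contig_order)}
            sort_key = lambda r: (rank.get(r.key.contig, len(rank)), r.key.contig,
                                  r.key.pos, r.key.ref, r.key.alt)
        else:
            sort_key = lambda r: r.key
        return sorted(self.records.values(), key=sort_key)

    def __repr__(self) -> str:
        return (f"CallSet({len(self.records)} records, "
                f"{len(self.samples)} samples, provenance={self.provenance!r})")


def class_matches(key: AlleleKey, variant_class: "str | VariantClass") -> bool:
    """True if *key* belongs to the given class; ``"indel"`` = insertion or deletion."""
    cls = classify_allele(key)
    if variant_class == "indel":
        return cls in (VariantClass.INSERTION, VariantClass.DELETION)
    return cls == VariantClass(variant_class)
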