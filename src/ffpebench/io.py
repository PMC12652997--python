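"""VCF and BED input/output.

VCF reading and writing go through :mod:`pysam`.  Sites are decomposed into
allele-level records on read (see :mod:`ffpebench.variants`); on write each
record becomes one biallelic VCF line, with multiallelic origin preserved in
an INFO flag so that a written call set round-trips losslessly.

BED intervals are 0-based half-open on disk and converted to the package's
1-based inclusive convention on read.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import pysam

from .variants import (
    AlleleKey,
    CallSet,
    GenotypeCall,
    Impact,
    VariantRecord,
    decompose,
    genotype,
)

__all__ = ["read_vcf", "write_vcf", "read_bed", "write_bed"]

#: INFO keys carried as numeric site annotations.
ANNOTATION_KEYS = ("QD", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

#: INFO flag used to preserve multiallelic origin across write/read cycles.
_MULTI_FLAG = "MULTIALLELIC"

_VALID_BASES = frozenset("ACGTN")


def _parse_impacts(ann_value, alts: Sequence[str]) -> list[Optional[Impact]]:
    """Extract per-alt impact from a snpEff-style ANN field.

    The impact is the third pipe-delimited subfield; entries are matched to
    alternate alleles by the first subfield, falling back to the first entry.
    """
    if ann_value is None:
        return [None] * len(alts)
    entries = ann_value if isinstance(ann_value, (tuple, list)) else [ann_value]
    per_allele: dict[str, Impact] = {}
    first: Optional[Impact] = None
    for entry in entries:
        fields = str(entry).split("|")
        if len(fields) < 3:
            continue
        try:
            imp = Impact(fields[2])
        except ValueError:
            continue
        if first is None:
            first = imp
        per_allele.setdefault(fields[0], imp)
    return [per_allele.get(alt, first if len(alts) == 1 else None) for alt in alts]


def read_vcf(path, sample_subset: Optional[Sequence[str]] = None) -> CallSet:
    """Read a VCF (plain or bgzipped) into a decomposed, trimmed :class:`CallSet`.

    Parameters
    ----------
    path:
        VCF v4.x file with a GT FORMAT field.
    sample_subset:
        If given, keep only these samples (order preserved as given).

    Raises
    ------
    FileNotFoundError, ValueError
        Unreadable file, missing GT definition, or unknown subset sample.
    """
    path = str(path)
    if not Path(path).exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    pysam.set_verbosity(0)  # suppress harmless missing-index chatter
    with pysam.VariantFile(path) as vf:
        if "GT" not in vf.header.formats:
            raise ValueError(f"{path}: VCF has no GT FORMAT field; genotypes are required")
        all_samples = list(vf.header.samples)
        if sample_subset is not None:
            missing = [s for s in sample_subset if s not in all_samples]
            if missing:
                raise ValueError(f"{path}: samples {missing} absent from VCF "
                                 f"(available: {all_samples})")
            samples = list(sample_subset)
        else:
            samples = all_samples
        cs = CallSet(samples, provenance=path)
        for site in vf:
            ref = (site.ref or "").upper()
            raw_alts = site.alts or ()
            alts = [a.upper() for a in raw_alts
                    if a is not None and set(a.upper()) <= _VALID_BASES]
            if not alts or not ref or not set(ref) <= _VALID_BASES:
                continue  # symbolic / spanning-deletion / SV alts are out of scope
            gts = []
            for s in samples:
                sdata = site.samples[s]
                gt_raw = sdata.get("GT", (None, None))
                if gt_raw is None or len(gt_raw) == 0:
                    gt_raw = (None, None)
                elif len(gt_raw) == 1:  # haploid call: duplicate the single allele
                    gt_raw = (gt_raw[0], gt_raw[0])
                gts.append(genotype(gt_raw[0], gt_raw[1], bool(sdata.phased)))
            annotations = {}
            for k in ANNOTATION_KEYS:
                if k in site.info:
                    v = site.info[k]
                    if isinstance(v, (tuple, list)):
                        v = v[0]
                    if v is not None:
                        annotations[k] = float(v)
            # map surviving alts back to their original allele indices
            alt_index = {a.upper(): i for i, a in enumerate(raw_alts, start=1) if a}
            ann = site.info.get("ANN") if "ANN" in vf.header.info else None
            impacts = _parse_impacts(ann, alts)
            filters = tuple(site.filter.keys())
            if filters == ("PASS",):
                filters = ()
            multi = len(raw_alts) > 1 or (_MULTI_FLAG in site.info)
            for alt, imp in zip(alts, impacts):
                focal = alt_index[alt]
                rec = decompose(
                    site.contig, site.pos, ref, [alt],
                    genotypes=[_refocus(g, focal) for g in gts],
                    qual=site.qual,
                    annotations=annotations,
                    impacts=[imp],
                    filters=filters,
                    multiallelic_origin=multi,
                )[0]
                if rec.key in cs.records:
                    warnings.warn(f"{path}: duplicate allele key {rec.key}; keeping first")
                    continue
                cs.add(rec)
    return cs


def _refocus(gt: GenotypeCall, focal: int) -> GenotypeCall:
    """Remap raw allele indices so the focal alt becomes index 1, others 0."""
    a, b = gt.allele_indices
    remap = lambda i: None if i is None else (1 if i == focal else 0)
    return genotype(remap(a), remap(b), gt.phased)


_KNOWN_FILTERS = ("QD", "QUAL", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum")


def _build_header(cs: CallSet, contigs) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs:
        if length is not None:
            header.add_line(f"##contig=<ID={name},length={length}>")
        else:
            header.add_line(f"##contig=<ID={name}>")
    for k in ANNOTATION_KEYS:
        header.add_line(f'##INFO=<ID={k},Number=1,Type=Float,Description="{k} annotation">')
    header.add_line(f'##INFO=<ID={_MULTI_FLAG},Number=0,Type=Flag,'
                    'Description="Record decomposed from a multiallelic site">')
    header.add_line('##INFO=<ID=ANN,Number=.,Type=String,'
                    'Description="Functional annotations: Allele|Annotation|Impact|Gene">')
    extra = sorted({lab for rec in cs for lab in rec.filters} - set(_KNOWN_FILTERS) - {"PASS"})
    for label in (*_KNOWN_FILTERS, *extra):
        header.add_line(f'##FILTER=<ID={label},Description="Hard-filter criterion {label} failed">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in cs.samples:
        header.add_sample(s)
    return header


def write_vcf(cs: CallSet, path, genome=None) -> None:
    """Write a :class:`CallSet` as a sorted biallelic VCF (bgzipped iff ``*.gz``).

    Output is fully deterministic for a given call set: same bytes every time.
    ``genome`` (a :class:`~ffpebench.simulate.GenomeModel`) supplies contig
    order and lengths for the header; otherwise contigs are emitted in
    lexicographic order without lengths.
    """
    path = str(path)
    if genome is not None:
        contigs = [(c.name, c.length) for c in genome.contigs]
        order = [c.name for c in genome.contigs]
    else:
        order = sorted({k.contig for k in cs.keys()})
        contigs = [(name, None) for name in order]
    header = _build_header(cs, contigs)
    mode = "wz" if path.endswith(".gz") else "w"
    with pysam.VariantFile(path, mode, header=header) as out:
        for rec in cs.sorted_records(contig_order=order):
            site = out.new_record(
                contig=rec.key.contig,
                start=rec.key.pos - 1,
                alleles=(rec.key.ref, rec.key.alt),
                qual=rec.qual,
            )
            if rec.filters:
                for label in rec.filters:
                    site.filter.add(label)
            else:
                site.filter.add("PASS")
            for k, v in rec.annotations.items():
                site.info[k] = float(v)
            if rec.multiallelic_origin:
                site.info[_MULTI_FLAG] = True
            if rec.impact is not None:
                site.info["ANN"] = f"{rec.key.alt}|custom|{rec.impact.value}|"
            for i, s in enumerate(cs.samples):
                gt = rec.genotypes[i]
                site.samples[s]["GT"] = gt.allele_indices
                site.samples[s].phased = gt.phased
            out.write(site)


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read a BED file into 1-based inclusive (contig, start, end) tuples."""
    path = str(path)
    if not Path(path).exists():
        raise FileNotFoundError(f"BED not found: {path}")
    rows = []
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["contig", "start", "end"],
                     dtype={"contig": str})
    for contig, start, end in df.itertuples(index=False):
        rows.append((contig, int(start) + 1, int(end)))
    return rows


def write_bed(intervals, path) -> None:
    """Write 1-based inclusive (contig, start, end) intervals as 0-based BED."""
    with open(path, "w") as fh:
        for contig, start, end in intervals:
            fh.write(f"{contig}\t{start - 1}\t{end}\n")
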