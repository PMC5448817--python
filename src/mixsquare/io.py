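"""Annotation and alignment input, quantification table output.

GTF input follows the Ensembl attribute dialect (``gene_id``/``transcript_id``
on exon records).  Alignments are read from SAM or BAM with pysam; splice
blocks are taken from the CIGAR (N operations separate blocks) and a fragment
is compatible with an isoform when every aligned base is exonic and the
splice junctions agree exactly with the isoform structure.
"""

from __future__ import annotations

import bisect
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .components import FragmentObservation
from .transcripts import GeneLocus, TranscriptModel

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationIndex",
    "FragmentExtractionConfig",
    "ExtractionResult",
    "read_annotation",
    "write_gtf",
    "extract_fragments",
    "write_results",
]


@dataclass
class AnnotationIndex:
    """All gene loci of an annotation, keyed by gene id."""

    loci: dict[str, GeneLocus] = field(default_factory=dict)
    contigs: set[str] = field(default_factory=set)

    def __len__(self):
        return len(self.loci)

    def transcripts(self):
        for gid in sorted(self.loci):
            for t in self.loci[gid].transcripts:
                yield t


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, value = chunk.split(" ", 1)
        out[key] = value.strip().strip('"')
    return out


def read_annotation(gtf_path) -> AnnotationIndex:
    """Build gene loci from a GTF file (Ensembl attribute dialect).

    Transcript lengths are the sum of exon widths; loci and transcripts are
    ordered deterministically by (gene_id, transcript_id).  Malformed records
    raise with the offending line number; transcripts without exons are
    skipped with a warning.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    declared: set[str] = set()
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{gtf_path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attr = fields[:9]
            if feature not in ("exon", "transcript"):
                continue
            attrs = _parse_gtf_attributes(attr)
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id")
            if tid is None or gid is None:
                raise ValueError(
                    f"{gtf_path}:{lineno}: missing gene_id/transcript_id attribute"
                )
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(f"{gtf_path}:{lineno}: non-integer coordinates") from None
            known = meta.get(tid)
            if known is not None and known != (gid, chrom, strand):
                raise ValueError(
                    f"{gtf_path}:{lineno}: duplicate transcript_id {tid!r} "
                    "with conflicting gene/contig/strand"
                )
            meta[tid] = (gid, chrom, strand)
            if feature == "transcript":
                if tid in declared and tid not in exons:
                    raise ValueError(
                        f"{gtf_path}:{lineno}: duplicate transcript record {tid!r}"
                    )
                declared.add(tid)
            else:
                exons.setdefault(tid, []).append((start_i, end_i))

    loci: dict[str, list[TranscriptModel]] = {}
    contigs = set()
    for tid in sorted(meta):
        gid, chrom, strand = meta[tid]
        if tid not in exons:
            warnings.warn(f"transcript {tid} has no exons; skipped")
            continue
        tx = TranscriptModel(
            id=tid,
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            exons=tuple(sorted(exons[tid])),
        )
        loci.setdefault(gid, []).append(tx)
        contigs.add(chrom)
    index = AnnotationIndex(contigs=contigs)
    for gid in sorted(loci):
        index.loci[gid] = GeneLocus(gene_id=gid, transcripts=loci[gid])
    return index


def write_gtf(loci, path) -> None:
    """Write loci as Ensembl-dialect GTF exon records."""
    if isinstance(loci, AnnotationIndex):
        loci = [loci.loci[g] for g in sorted(loci.loci)]
    with open(path, "w") as fh:
        for locus in loci:
            for t in sorted(locus.transcripts, key=lambda t: t.id):
                for s, e in t.exons:
                    attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.id}";'
                    fh.write(
                        f"{t.chrom}\tmixsquare\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                    )


@dataclass
class FragmentExtractionConfig:
    mode: str = "paired"  # or "single"
    min_mapping_quality: int = 0
    count_multimaps_as_distinct: bool = True

    def __post_init__(self):
        if self.mode not in ("paired", "single"):
            raise ValueError(f"unknown extraction mode {self.mode!r}")


@dataclass
class ExtractionResult:
    """Per-locus fragment observations plus bookkeeping counts."""

    per_locus: dict[str, list[FragmentObservation]]
    n_units: int = 0  # fragments in paired mode, reads in single mode
    n_retained: int = 0
    n_discarded: int = 0
    n_orphans: int = 0

    def get(self, gene_id, default=None):
        return self.per_locus.get(gene_id, default)

    def __getitem__(self, gene_id):
        return self.per_locus[gene_id]

    def items(self):
        return self.per_locus.items()


class _LocusLookup:
    """Contig-indexed interval lookup from genomic span to candidate loci."""

    def __init__(self, annotation: AnnotationIndex):
        self.by_contig: dict[str, tuple[list[int], list[tuple[int, str]]]] = {}
        spans: dict[str, list[tuple[int, int, str]]] = {}
        for gid, locus in annotation.loci.items():
            lo = min(t.exons[0][0] for t in locus.transcripts)
            hi = max(t.exons[-1][1] for t in locus.transcripts)
            spans.setdefault(locus.chrom, []).append((lo, hi, gid))
        for contig, entries in spans.items():
            entries.sort()
            starts = [e[0] for e in entries]
            self.by_contig[contig] = (starts, [(e[1], e[2]) for e in entries])

    def overlapping(self, contig: str, lo: int, hi: int) -> list[str]:
        entry = self.by_contig.get(contig)
        if entry is None:
            return []
        starts, rest = entry
        idx = bisect.bisect_right(starts, hi)
        return [gid for (end, gid), s in zip(rest[:idx], starts[:idx]) if end >= lo]


def _read_blocks(rec) -> list[tuple[int, int]]:
    """Aligned genomic blocks, 1-based inclusive, merging adjacent
    match blocks not separated by a splice (N) gap."""
    blocks = []
    pos = rec.reference_start  # 0-based
    for op, ln in rec.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            blocks.append((pos + 1, pos + ln))
            pos += ln
        elif op == 2:  # D consumes reference without splice
            if blocks:
                pos += ln
                s, _ = blocks[-1]
                blocks[-1] = (s, pos)
            else:
                pos += ln
        elif op == 3:  # N: splice gap
            pos += ln
        # I, S, H, P consume no reference
    merged = []
    for b in blocks:
        if merged and b[0] == merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], b[1])
        else:
            merged.append(list(b))
    return [tuple(b) for b in merged]


def _single_end_observation(locus: GeneLocus, blocks, frag_id) -> FragmentObservation | None:
    comp = {}
    for t in locus.transcripts:
        mapped = t.map_blocks(blocks)
        if mapped is None:
            continue
        s, span = mapped
        # fragment start = downstream (3'-direction) end of the read in
        # transcript orientation; length is unknown
        comp[t.id] = (s + span - 1, None)
    if not comp:
        return None
    return FragmentObservation(id=frag_id, compatibility=comp)


def _paired_observation(locus: GeneLocus, blocks1, blocks2, frag_id) -> FragmentObservation | None:
    comp = {}
    for t in locus.transcripts:
        m1 = t.map_blocks(blocks1)
        m2 = t.map_blocks(blocks2)
        if m1 is None or m2 is None:
            continue
        s = min(m1[0], m2[0])
        e = max(m1[0] + m1[1] - 1, m2[0] + m2[1] - 1)
        comp[t.id] = (s, e - s + 1)
    if not comp:
        return None
    return FragmentObservation(id=frag_id, compatibility=comp)


def extract_fragments(
    sam_path, annotation: AnnotationIndex, config: FragmentExtractionConfig | None = None
) -> ExtractionResult:
    """Turn SAM/BAM alignments into per-locus fragment observations.

    In paired mode mates are combined into one fragment whose start is the
    5'-most transcript base and whose length is the spliced span; in single
    mode each read yields a fragment whose start is the read's downstream
    end in transcript orientation and whose length is unknown.  Every
    alignment record is its own fragment (multi-mappers are not collapsed).
    """
    config = config or FragmentExtractionConfig()
    lookup = _LocusLookup(annotation)
    result = ExtractionResult(per_locus={})
    mode = "rb" if str(sam_path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(sam_path), mode, check_sq=False) as fh:
        if config.mode == "single":
            for rec in fh:
                if rec.is_unmapped or rec.mapping_quality < config.min_mapping_quality:
                    continue
                result.n_units += 1
                blocks = _read_blocks(rec)
                if not blocks:
                    result.n_discarded += 1
                    continue
                placed = False
                for gid in lookup.overlapping(rec.reference_name, blocks[0][0], blocks[-1][1]):
                    obs = _single_end_observation(
                        annotation.loci[gid], blocks, rec.query_name
                    )
                    if obs is not None:
                        result.per_locus.setdefault(gid, []).append(obs)
                        placed = True
                if placed:
                    result.n_retained += 1
                else:
                    result.n_discarded += 1
        else:
            pending: dict[str, list] = {}
            for rec in fh:
                if rec.is_unmapped or rec.mapping_quality < config.min_mapping_quality:
                    continue
                if not rec.is_paired:
                    result.n_units += 1
                    result.n_discarded += 1
                    result.n_orphans += 1
                    continue
                key = rec.query_name
                mate = None
                bucket = pending.setdefault(key, [])
                for i, other in enumerate(bucket):
                    if (
                        other.is_read1 != rec.is_read1
                        and other.reference_name == rec.reference_name
                        and other.reference_start == rec.next_reference_start
                        and rec.reference_start == other.next_reference_start
                    ):
                        mate = bucket.pop(i)
                        break
                if mate is None:
                    bucket.append(rec)
                    continue
                result.n_units += 1
                b1, b2 = _read_blocks(mate), _read_blocks(rec)
                if not b1 or not b2:
                    result.n_discarded += 1
                    continue
                lo = min(b1[0][0], b2[0][0])
                hi = max(b1[-1][1], b2[-1][1])
                placed = False
                for gid in lookup.overlapping(rec.reference_name, lo, hi):
                    obs = _paired_observation(annotation.loci[gid], b1, b2, key)
                    if obs is not None:
                        result.per_locus.setdefault(gid, []).append(obs)
                        placed = True
                if placed:
                    result.n_retained += 1
                else:
                    result.n_discarded += 1
            orphans = sum(len(v) for v in pending.values())
            if orphans:
                logger.info("%d orphan mate records discarded", orphans)
                result.n_orphans += orphans
                result.n_units += orphans
                result.n_discarded += orphans
    return result


def write_results(
    results,
    out_path,
    total_mapped_fragments: int | None = None,
    distributions_path=None,
    n_bins: int = 100,
) -> pd.DataFrame:
    """Write per-transcript quantification to a TSV table.

    ``results`` is an iterable of fitted ``Mix2Results``.  Columns:
    gene_id, transcript_id, length, alpha, est_count, fpkm, group_id.
    Optionally writes per-transcript binned start distributions.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to write")
    if total_mapped_fragments is None:
        total_mapped_fragments = int(round(sum(r.n_fragments for r in results)))
    rows = []
    dist_rows = []
    for res in sorted(results, key=lambda r: r.locus.gene_id):
        fpkm = res.fpkm(total_mapped_fragments)
        order = np.argsort([t.id for t in res.locus.transcripts])
        for i in order:
            t = res.locus.transcripts[i]
            rows.append(
                {
                    "gene_id": t.gene_id,
                    "transcript_id": t.id,
                    "length": t.length,
                    "alpha": res.alpha[i],
                    "est_count": res.expected_counts[i],
                    "fpkm": fpkm[i],
                    "group_id": int(res.params.group_of[i]),
                }
            )
            if distributions_path is not None:
                from .bias import bin_profile

                prof = bin_profile(res.start_distribution(i), n_bins)
                dist_rows.append([t.id] + list(prof))
    df = pd.DataFrame(rows)
    df.to_csv(out_path, sep="\t", index=False, float_format="%.10g")
    if distributions_path is not None:
        cols = ["transcript_id"] + [f"bin_{b}" for b in range(n_bins)]
        pd.DataFrame(dist_rows, columns=cols).to_csv(
            distributions_path, sep="\t", index=False, float_format="%.10g"
        )
    return df
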