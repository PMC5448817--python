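"""Transcript and locus structures with genome/transcript coordinate maps.

Transcript coordinates are 1-based positions along the spliced transcript,
with position 1 at the transcript's 5' end.  Genome coordinates are 1-based
inclusive (SAM convention).  For minus-strand transcripts the two systems run
in opposite directions: transcript position 1 maps to the highest genomic
coordinate of the last exon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = ["TranscriptModel", "GeneLocus"]


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript: exon structure, strand and derived length."""

    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        if not exons:
            raise ValueError(f"transcript {self.id}: no exons")
        prev_end = -1
        for start, end in exons:
            if start < 1 or end < start:
                raise ValueError(f"transcript {self.id}: bad exon ({start}, {end})")
            if start <= prev_end:
                raise ValueError(
                    f"transcript {self.id}: exons overlap or are unsorted"
                )
            prev_end = end
        object.__setattr__(self, "exons", exons)

    @property
    def length(self) -> int:
        """Spliced length l(t), the sum of exon widths."""
        return sum(e - s + 1 for s, e in self.exons)

    @cached_property
    def _exon_arrays(self):
        starts = np.array([s for s, _ in self.exons], dtype=np.int64)
        ends = np.array([e for _, e in self.exons], dtype=np.int64)
        widths = ends - starts + 1
        # cumulative transcript offset of each exon in genome order (5'->3'
        # for '+', 3'->5' for '-')
        offsets = np.concatenate([[0], np.cumsum(widths)[:-1]])
        return starts, ends, widths, offsets

    # -- coordinate maps ---------------------------------------------------

    def to_genome(self, tpos: int) -> int:
        """Genome coordinate of transcript position ``tpos`` (1-based)."""
        L = self.length
        if not 1 <= tpos <= L:
            raise ValueError(f"transcript position {tpos} outside 1..{L}")
        starts, ends, widths, offsets = self._exon_arrays
        # position counted in genome order along the spliced transcript
        gorder = tpos - 1 if self.strand == "+" else L - tpos
        k = int(np.searchsorted(offsets, gorder, side="right") - 1)
        return int(starts[k] + (gorder - offsets[k]))

    def to_transcript(self, gpos: int) -> int | None:
        """Transcript coordinate of genomic position, or None if intronic."""
        starts, ends, widths, offsets = self._exon_arrays
        k = int(np.searchsorted(starts, gpos, side="right") - 1)
        if k < 0 or gpos > ends[k]:
            return None
        gorder = int(offsets[k] + (gpos - starts[k]))
        return gorder + 1 if self.strand == "+" else self.length - gorder

    def genome_positions(self) -> np.ndarray:
        """Genomic coordinate of every transcript base, in transcript order."""
        starts, ends, _, _ = self._exon_arrays
        pieces = [np.arange(s, e + 1, dtype=np.int64) for s, e in zip(starts, ends)]
        arr = np.concatenate(pieces)
        return arr if self.strand == "+" else arr[::-1]

    def blocks(self, tstart: int, span: int) -> list[tuple[int, int]]:
        """Genomic blocks (ascending, 1-based inclusive) covered by
        transcript positions ``tstart .. tstart+span-1``."""
        if span < 1:
            raise ValueError("span must be >= 1")
        tend = tstart + span - 1
        if tend > self.length:
            raise ValueError("span extends past transcript end")
        g1, g2 = self.to_genome(tstart), self.to_genome(tend)
        lo, hi = min(g1, g2), max(g1, g2)
        out = []
        for s, e in self.exons:
            bs, be = max(s, lo), min(e, hi)
            if bs <= be:
                out.append((bs, be))
        return out

    def map_blocks(self, blocks) -> tuple[int, int] | None:
        """Map aligned genomic blocks onto this transcript.

        ``blocks`` are ascending 1-based inclusive genomic intervals
        (CIGAR N gaps separate them).  Returns ``(s, span)`` in transcript
        coordinates when every base is exonic and splice junctions agree
        with this transcript's structure, else None.
        """
        tcoords = []
        total = 0
        for bs, be in blocks:
            t0, t1 = self.to_transcript(bs), self.to_transcript(be)
            if t0 is None or t1 is None:
                return None
            if abs(t1 - t0) != be - bs:  # block crosses one of our introns
                return None
            tcoords.extend((t0, t1))
            total += be - bs + 1
        tmin, tmax = min(tcoords), max(tcoords)
        if tmax - tmin + 1 != total:  # gap does not match an intron exactly
            return None
        return tmin, tmax - tmin + 1


@dataclass
class GeneLocus:
    """A gene and its N annotated isoforms: the unit of quantification."""

    gene_id: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self):
        if not self.transcripts:
            raise ValueError("a locus needs at least one transcript")
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise ValueError(
                    f"transcript {t.id} belongs to {t.gene_id}, not {self.gene_id}"
                )

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    def index_of(self, transcript_id: str) -> int:
        for i, t in enumerate(self.transcripts):
            if t.id == transcript_id:
                return i
        raise KeyError(transcript_id)

    @cached_property
    def _pair_maps(self):
        """For each ordered transcript pair (i, k): position translation and
        contiguity prefix sums, enabling vectorised fragment compatibility."""
        n = self.n_transcripts
        gmaps = [t.genome_positions() for t in self.transcripts]
        trans = {}
        for i in range(n):
            Li = self.transcripts[i].length
            gi = gmaps[i]
            for k in range(n):
                if i == k:
                    continue
                A = np.zeros(Li + 1, dtype=np.int64)
                if self.transcripts[i].strand == self.transcripts[k].strand:
                    gk = gmaps[k]
                    Lk = self.transcripts[k].length
                    asc = gk if self.transcripts[k].strand == "+" else gk[::-1]
                    idx = np.searchsorted(asc, gi)
                    hit = (idx < Lk) & (asc[np.minimum(idx, Lk - 1)] == gi)
                    kcoord = np.where(
                        hit,
                        idx + 1 if self.transcripts[k].strand == "+" else Lk - idx,
                        0,
                    )
                    A[1:] = kcoord
                run = (A[1:Li] > 0) & (A[2:] == A[1:Li] + 1)
                S = np.concatenate([[0], np.cumsum(run.astype(np.int64))])
                trans[(i, k)] = (A, S)
        return trans

    def translate_fragments(
        self,
        i: int,
        starts: np.ndarray,
        lengths: np.ndarray,
        read_length: int | None = 50,
    ):
        """Map fragments given in transcript-i coordinates onto every isoform.

        Returns ``(compat, s_mat, l_mat)`` with shape (R, N): boolean
        compatibility, per-isoform start and implied spliced span.  Column i
        is the identity.

        With ``read_length`` set (the default, matching paired-end
        sequencing), only the two terminal read windows of each fragment are
        required to map contiguously onto the other isoform — the unobserved
        interior is not checked, and the implied span on that isoform may
        differ from the originating one.  With ``read_length=None`` the whole
        fragment base run must be contiguous.
        """
        starts = np.asarray(starts, dtype=np.int64)
        lengths = np.asarray(lengths, dtype=np.int64)
        R, N = len(starts), self.n_transcripts
        compat = np.zeros((R, N), dtype=bool)
        s_mat = np.zeros((R, N), dtype=np.int64)
        l_mat = np.zeros((R, N), dtype=np.int64)
        compat[:, i] = True
        s_mat[:, i] = starts
        l_mat[:, i] = lengths
        ends = starts + lengths - 1
        if read_length is None:
            windows = [(starts, ends)]
        else:
            rl = np.minimum(read_length, lengths)
            windows = [(starts, starts + rl - 1), (ends - rl + 1, ends)]

        def run_ok(A, S, a, b):
            # the run a..b of transcript i maps contiguously onto k
            return (A[a] > 0) & ((b == a) | (S[b - 1] - S[a - 1] == b - a))

        for k in range(N):
            if k == i:
                continue
            A, S = self._pair_maps[(i, k)]
            ok = np.ones(R, dtype=bool)
            lo = np.full(R, np.iinfo(np.int64).max)
            hi = np.zeros(R, dtype=np.int64)
            for a, b in windows:
                ok &= run_ok(A, S, a, b)
                wa, wb = A[a], A[b]
                lo = np.minimum(lo, np.minimum(wa, wb))
                hi = np.maximum(hi, np.maximum(wa, wb))
            compat[:, k] = ok
            s_mat[ok, k] = lo[ok]
            l_mat[ok, k] = hi[ok] - lo[ok] + 1
        return compat, s_mat, l_mat
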