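"""Positionally biased RNA-Seq fragment simulator.

Fragments are sampled from the locus superposition: an isoform is drawn
from Dirichlet abundances, a start position from the isoform's biased
start distribution and a length from a Gaussian (mean 200 bp, sd 80 bp)
truncated to the admissible range.  Four bias families are provided:

* ``cufflinks``  — the fragment start distribution implied by a uniform
  fragmentation model with a Gaussian fragment length distribution:
  p(s) is proportional to the probability mass of lengths that still fit,
  sum_{l=1}^{L-s+1} phi(l);
* ``five_prime``, ``three_prime``, ``five_three_prime`` — an initial
  biased shape defined over relative position, rescaled to the transcript
  length, multiplied pointwise by the cufflinks bias and renormalized.

The initial shapes are exponential-decay stand-ins (rate 5 over relative
position) for 5' bias, its mirror for 3' bias, and their normalized sum
for 5'+3' bias; custom shape vectors are accepted.

Sampled fragments can be written as 50 bp paired-end reads to a SAM file
whose coordinates round-trip exactly through ``mixsquare.io``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .components import FragmentLengthModel
from .model import FragmentTable
from .transcripts import GeneLocus, TranscriptModel

__all__ = [
    "BiasModel",
    "SimulationDesign",
    "LocusDataset",
    "cufflinks_start_bias",
    "make_biased_distribution",
    "sample_locus_dataset",
    "fragments_to_sam",
    "build_design",
    "transcriptome_profile",
    "random_transcriptome",
    "BIAS_KINDS",
]

BIAS_KINDS = ("cufflinks", "five_prime", "three_prime", "five_three_prime")

_SHAPE_GRID = 1000  # resolution of the relative-position initial shapes


def _decay_shape(rate: float, n: int = _SHAPE_GRID) -> np.ndarray:
    x = np.linspace(0.0, 1.0, n)
    shape = np.exp(-rate * x)
    return shape / shape.sum()


@dataclass
class BiasModel:
    """Simulator-side true fragment-start bias for arbitrary lengths."""

    kind: str = "cufflinks"
    initial_shape: np.ndarray | None = None
    decay_rate: float = 5.0
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.kind not in BIAS_KINDS + ("custom",):
            raise ValueError(f"unknown bias kind {self.kind!r}")
        if self.kind == "custom" and self.initial_shape is None:
            raise ValueError("custom bias needs an initial_shape")
        if self.initial_shape is None and self.kind != "cufflinks":
            r = self.decay_rate
            if self.kind == "five_prime":
                self.initial_shape = _decay_shape(r)
            elif self.kind == "three_prime":
                self.initial_shape = _decay_shape(r)[::-1].copy()
            else:  # five_three_prime
                both = _decay_shape(r) + _decay_shape(r)[::-1]
                self.initial_shape = both / both.sum()

    def start_distribution(
        self, length: int, length_model: FragmentLengthModel | None = None
    ) -> np.ndarray:
        dist = self._cache.get(length)
        if dist is None:
            dist = make_biased_distribution(self, length, length_model)
            self._cache[length] = dist
        return dist


def cufflinks_start_bias(
    length: int, length_model: FragmentLengthModel | None = None
) -> np.ndarray:
    """Start distribution of the uniform-fragmentation model:
    p(s) proportional to sum_{l=1}^{L-s+1} phi(l), phi = Gaussian(200, 80)
    at integer lengths; renormalized."""
    if length < 1:
        raise ValueError("length must be >= 1")
    lm = length_model or FragmentLengthModel()
    cs = lm._density_cumsum(length)
    p = cs[::-1].copy()  # p[s-1] = sum of phi over 1..L-s+1
    total = p.sum()
    return p / total


def make_biased_distribution(
    bias: BiasModel, length: int, length_model: FragmentLengthModel | None = None
) -> np.ndarray:
    """Initial relative-position shape rescaled to ``length`` positions,
    multiplied by the cufflinks bias and renormalized.  A uniform initial
    shape reproduces the cufflinks bias exactly."""
    base = cufflinks_start_bias(length, length_model)
    if bias.kind == "cufflinks" and bias.initial_shape is None:
        return base
    shape = np.asarray(bias.initial_shape, dtype=float)
    if np.ptp(shape) == 0:  # uniform initial shape: exactly the base bias
        return base
    xp = np.linspace(0.0, 1.0, len(shape))
    x = (np.arange(length) + 0.5) / length
    init = np.interp(x, xp, shape)
    dist = init * base
    return dist / dist.sum()


@dataclass
class LocusDataset:
    """Sampled fragments plus the generating truth for one locus."""

    locus: GeneLocus
    fragments: FragmentTable
    origin: np.ndarray  # generating transcript index per fragment
    alpha: np.ndarray
    start_distributions: list[np.ndarray]
    seed: int


def sample_locus_dataset(
    locus: GeneLocus,
    bias: BiasModel,
    n_fragments: int,
    seed: int,
    length_model: FragmentLengthModel | None = None,
    alpha: np.ndarray | None = None,
    read_length: int | None = 50,
) -> LocusDataset:
    """Sample ``n_fragments`` fragments from the biased locus superposition.

    Abundances default to a uniform Dirichlet draw; the starts follow the
    bias model's per-length distribution and lengths the truncated Gaussian.
    Per-isoform compatibility reproduces what paired ``read_length`` bp reads
    of the fragment would show after alignment (pass ``read_length=None`` to
    require the whole fragment run instead).
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    lm = length_model or FragmentLengthModel()
    rng = np.random.default_rng(seed)
    N = locus.n_transcripts
    if alpha is None:
        alpha = rng.dirichlet(np.ones(N))
    else:
        alpha = np.asarray(alpha, dtype=float)
    dists = [bias.start_distribution(t.length, lm) for t in locus.transcripts]
    counts = rng.multinomial(n_fragments, alpha)
    blocks = []
    for i, t in enumerate(locus.transcripts):
        c = int(counts[i])
        if c == 0:
            continue
        starts = rng.choice(t.length, size=c, p=dists[i]) + 1
        max_len = t.length - starts + 1
        cs = lm._density_cumsum(t.length)
        u = rng.uniform(0.0, cs[max_len - 1])
        lengths = np.searchsorted(cs, u) + 1
        lengths = np.minimum(lengths, max_len)
        compat, s_mat, l_mat = locus.translate_fragments(i, starts, lengths, read_length=read_length)
        blocks.append((np.full(c, i), compat, s_mat, l_mat))
    origin = np.concatenate([b[0] for b in blocks])
    table = FragmentTable(
        np.concatenate([b[1] for b in blocks]),
        np.concatenate([b[2] for b in blocks]),
        np.concatenate([b[3] for b in blocks]),
        single_end=False,
    )
    # shuffle so fragment order carries no information
    perm = rng.permutation(len(table))
    table = FragmentTable(
        table.compat[perm], table.starts[perm], table.lengths[perm], single_end=False
    )
    return LocusDataset(
        locus=locus,
        fragments=table,
        origin=origin[perm],
        alpha=alpha,
        start_distributions=dists,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# SAM output


def _cigar_for_blocks(blocks) -> str:
    parts = []
    for k, (s, e) in enumerate(blocks):
        if k:
            gap = s - blocks[k - 1][1] - 1
            parts.append(f"{gap}N")
        parts.append(f"{e - s + 1}M")
    return "".join(parts)


def fragments_to_sam(
    dataset: LocusDataset,
    out_path,
    read_length: int = 50,
    contig_lengths: dict[str, int] | None = None,
    append_datasets: list[LocusDataset] | None = None,
) -> int:
    """Write sampled fragments as paired-end reads to a SAM file.

    Each fragment emits a properly paired record pair with junction-split
    CIGARs; fragments shorter than the read length are emitted as a fully
    overlapping pair (counted in the return value).
    """
    datasets = [dataset] + (append_datasets or [])
    contigs: dict[str, int] = dict(contig_lengths or {})
    for ds in datasets:
        for t in ds.locus.transcripts:
            end = t.exons[-1][1] + 1000
            contigs[t.chrom] = max(contigs.get(t.chrom, 0), end)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in sorted(contigs.items())],
    }
    n_short = 0
    with pysam.AlignmentFile(str(out_path), "w", header=header) as out:
        tid_of = {sq["SN"]: k for k, sq in enumerate(header["SQ"])}
        counter = itertools.count()
        for ds in datasets:
            locus = ds.locus
            for r in range(len(ds.fragments)):
                i = int(ds.origin[r])
                t = locus.transcripts[i]
                s = int(ds.fragments.starts[r, i])
                l = int(ds.fragments.lengths[r, i])
                rl = read_length
                if l < read_length:
                    n_short += 1
                    rl = l
                qname = f"frag{next(counter)}:{locus.gene_id}"
                spans = [(s, rl), (s + l - rl, rl)]
                recs = []
                for tpos, span in spans:
                    blocks = t.blocks(tpos, span)
                    recs.append(blocks)
                left_first = recs[0][0][0] <= recs[1][0][0]
                lo = min(recs[0][0][0], recs[1][0][0])
                hi = max(recs[0][-1][1], recs[1][-1][1])
                tlen = hi - lo + 1
                for mate, blocks in enumerate(recs):
                    a = pysam.AlignedSegment()
                    a.query_name = qname
                    a.reference_id = tid_of[t.chrom]
                    a.reference_start = blocks[0][0] - 1
                    a.cigarstring = _cigar_for_blocks(blocks)
                    read1 = mate == 0
                    rev = (t.strand == "+") == (mate == 1)
                    flag = 0x1 | 0x2
                    flag |= 0x40 if read1 else 0x80
                    if rev:
                        flag |= 0x10
                    else:
                        flag |= 0x20
                    a.flag = flag
                    other = recs[1 - mate]
                    a.next_reference_id = tid_of[t.chrom]
                    a.next_reference_start = other[0][0] - 1
                    a.template_length = tlen if blocks[0][0] == lo else -tlen
                    span_len = sum(e - b + 1 for b, e in blocks)
                    a.query_sequence = "A" * span_len
                    a.mapping_quality = 50
                    out.write(a)
    return n_short


# ---------------------------------------------------------------------------
# study design


@dataclass
class SimulationDesign:
    """The artificial-data design: genes x abundance draws x sample sizes
    x bias models."""

    genes: list[GeneLocus]
    abundance_draws: int = 200
    sample_sizes: tuple[int, ...] = (500, 1000, 5000, 10000)
    biases: tuple[str, ...] = BIAS_KINDS
    seed: int = 0


def derive_seed(master_seed: int, *keys) -> int:
    """Stable per-dataset seed below 2**31 derived from the master seed."""
    entropy = [int(master_seed)]
    for k in keys:
        if isinstance(k, str):
            entropy.extend(k.encode())
        else:
            entropy.append(int(k))
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1)[0] % (2**31))


def build_design(design: SimulationDesign) -> pd.DataFrame:
    """Enumerate every (gene, abundance draw, sample size, bias) dataset
    with its derived seed.  Row count is the product of the dimensions."""
    rows = []
    for g, locus in enumerate(design.genes):
        for draw in range(design.abundance_draws):
            for size in design.sample_sizes:
                for bias in design.biases:
                    rows.append(
                        {
                            "gene_id": locus.gene_id,
                            "draw": draw,
                            "n_fragments": size,
                            "bias": bias,
                            "seed": derive_seed(design.seed, g, draw, size, bias),
                        }
                    )
    return pd.DataFrame(rows)


def transcriptome_profile(annotation, seed: int, decay: float = 6.9) -> pd.DataFrame:
    """Exponential rank-abundance expression profile over genes with a
    uniform Dirichlet split across each gene's isoforms.

    ``decay`` sets the dynamic range: the lowest-ranked gene is
    exp(-decay) times the highest (default ~3 orders of magnitude).
    Returns one row per transcript with gene weight, isoform fraction and
    overall expression weight (weights sum to 1).
    """
    gene_ids = sorted(annotation.loci) if hasattr(annotation, "loci") else sorted(
        l.gene_id for l in annotation
    )
    loci = (
        annotation.loci
        if hasattr(annotation, "loci")
        else {l.gene_id: l for l in annotation}
    )
    n = len(gene_ids)
    if n < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    ranks = rng.permutation(n)
    w = np.exp(-decay * ranks / max(n - 1, 1))
    w = w / w.sum()
    rows = []
    for gid, weight in zip(gene_ids, w):
        locus = loci[gid]
        frac = rng.dirichlet(np.ones(locus.n_transcripts))
        for t, f in zip(locus.transcripts, frac):
            rows.append(
                {
                    "gene_id": gid,
                    "transcript_id": t.id,
                    "gene_weight": weight,
                    "isoform_fraction": f,
                    "weight": weight * f,
                }
            )
    return pd.DataFrame(rows)


def random_transcriptome(
    n_genes: int,
    seed: int,
    min_isoforms: int = 2,
    max_isoforms: int = 8,
) -> list[GeneLocus]:
    """Generate a synthetic multi-isoform transcriptome.

    Each gene gets its own contig, 5-12 exons with realistic widths and
    introns, and 2-8 isoforms formed by exon skipping relative to the full
    isoform.  Used for transcriptome-scale evaluation.
    """
    rng = np.random.default_rng(seed)
    loci = []
    for g in range(n_genes):
        gid = f"SYNG{g:05d}"
        chrom = f"chr_{gid}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(5, 13))
        widths = rng.integers(80, 400, size=n_exons)
        introns = rng.integers(200, 2000, size=n_exons - 1)
        starts = np.zeros(n_exons, dtype=np.int64)
        starts[0] = 1000
        for k in range(1, n_exons):
            starts[k] = starts[k - 1] + widths[k - 1] + introns[k - 1]
        exons = [(int(s), int(s + w - 1)) for s, w in zip(starts, widths)]
        n_iso = int(rng.integers(min_isoforms, max_isoforms + 1))
        chosen = {tuple(range(n_exons))}
        isoforms = [tuple(range(n_exons))]
        attempts = 0
        while len(isoforms) < n_iso and attempts < 50:
            attempts += 1
            keep = np.nonzero(rng.random(n_exons) < 0.75)[0]
            if len(keep) < 2:
                continue
            key = tuple(int(k) for k in keep)
            if key in chosen:
                continue
            chosen.add(key)
            isoforms.append(key)
        transcripts = [
            TranscriptModel(
                id=f"{gid}.t{j}",
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=tuple(exons[k] for k in iso),
            )
            for j, iso in enumerate(isoforms)
        ]
        loci.append(GeneLocus(gene_id=gid, transcripts=transcripts))
    return loci
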