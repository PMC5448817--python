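"""Seven bundled synthetic gene fixtures for the artificial-data design.

These stand in for a small panel of real multi-isoform genes: between 4 and
15 isoforms per gene, covering skipped exons, alternative 5' and 3' ends,
intron retention and both strands, with spliced lengths from under 300 bp
to over 5000 bp.  All structures are generated in code (synthetic); real
annotation can be loaded through :mod:`mixsquare.io` instead.
"""

from __future__ import annotations

from .transcripts import GeneLocus, TranscriptModel

__all__ = ["seven_test_genes"]


def _lay_out(widths, introns, origin=1000):
    exons = []
    pos = origin
    for k, w in enumerate(widths):
        exons.append((pos, pos + w - 1))
        pos += w + (introns[k] if k < len(introns) else 0)
    return exons


def _resolve(exons, recipe):
    """Turn an isoform recipe into exon intervals.

    Items: ``k`` (exon index), ``("merge", a, b)`` (intron retention from
    exon a through exon b), ``("trim5", k, cut)`` / ``("trim3", k, cut)``
    (alternative start/end inside exon k, in genome orientation).
    """
    out = []
    for item in recipe:
        if isinstance(item, int):
            out.append(exons[item])
        elif item[0] == "merge":
            _, a, b = item
            out.append((exons[a][0], exons[b][1]))
        elif item[0] == "trim5":
            _, k, cut = item
            s, e = exons[k]
            out.append((s + cut, e))
        elif item[0] == "trim3":
            _, k, cut = item
            s, e = exons[k]
            out.append((s, e - cut))
        else:
            raise ValueError(f"bad isoform item {item!r}")
    return tuple(sorted(out))


def _gene(gene_id, chrom, strand, widths, introns, isoform_recipes):
    exons = _lay_out(widths, introns)
    transcripts = [
        TranscriptModel(
            id=f"{gene_id}.t{j + 1}",
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=_resolve(exons, recipe),
        )
        for j, recipe in enumerate(isoform_recipes)
    ]
    return GeneLocus(gene_id=gene_id, transcripts=transcripts)


def seven_test_genes() -> list[GeneLocus]:
    genes = []

    # SYNF1: 4 isoforms, cassette exons
    genes.append(
        _gene(
            "SYNF1", "fix1", "+",
            [300, 200, 150, 250, 400], [500, 700, 450, 600],
            [
                [0, 1, 2, 3, 4],
                [0, 2, 3, 4],
                [0, 1, 3, 4],
                [0, 3, 4],
            ],
        )
    )

    # SYNF2: 5 isoforms, alternative 5' starts and one skip
    genes.append(
        _gene(
            "SYNF2", "fix2", "+",
            [250, 180, 220, 300, 350, 200], [400, 900, 350, 800, 500],
            [
                [0, 1, 2, 3, 4, 5],
                [1, 2, 3, 4, 5],
                [2, 3, 4, 5],
                [0, 1, 3, 4, 5],
                [("trim5", 1, 60), 2, 3, 5],
            ],
        )
    )

    # SYNF3: 6 isoforms, intron retention, minus strand
    genes.append(
        _gene(
            "SYNF3", "fix3", "-",
            [400, 150, 250, 300, 500], [600, 350, 900, 400],
            [
                [0, 1, 2, 3, 4],
                [("merge", 0, 1), 2, 3, 4],
                [0, 2, 3, 4],
                [0, 1, ("merge", 2, 3), 4],
                [1, 2, 3, 4],
                [0, 1, 2],
            ],
        )
    )

    # SYNF4: 8 isoforms, mixed events, includes a short (<300 bp) isoform
    genes.append(
        _gene(
            "SYNF4", "fix4", "+",
            [220, 130, 180, 240, 160, 300, 280], [500, 450, 700, 300, 650, 400],
            [
                [0, 1, 2, 3, 4, 5, 6],
                [0, 2, 3, 4, 5, 6],
                [0, 1, 3, 4, 5, 6],
                [0, 1, 2, 4, 5, 6],
                [0, 1, 2, 3, 5, 6],
                [2, 3, 4, 5, 6],
                [0, 1, ("merge", 2, 3), 4, 5, 6],
                [1, 2],
            ],
        )
    )

    # SYNF5: 10 isoforms, long gene with alternative 3' ends, minus strand
    genes.append(
        _gene(
            "SYNF5", "fix5", "-",
            [350, 280, 300, 260, 320, 400, 380, 450], [800, 600, 1200, 500, 900, 700, 1000],
            [
                [0, 1, 2, 3, 4, 5, 6, 7],
                [0, 1, 2, 3, 4, 5, 6],
                [0, 1, 2, 3, 4, 5],
                [0, 2, 3, 4, 5, 6, 7],
                [0, 1, 3, 4, 5, 6, 7],
                [0, 1, 2, 4, 5, 6, 7],
                [0, 1, 2, 3, 5, 6, 7],
                [0, 1, 2, 3, 4, ("trim3", 5, 150)],
                [2, 3, 4, 5, 6, 7],
                [0, 1, ("merge", 3, 4), 5, 6, 7],
            ],
        )
    )

    # SYNF6: 12 isoforms over 9 exons
    genes.append(
        _gene(
            "SYNF6", "fix6", "+",
            [180, 150, 200, 170, 220, 190, 240, 210, 260],
            [400, 550, 300, 700, 350, 600, 450, 500],
            [
                [0, 1, 2, 3, 4, 5, 6, 7, 8],
                [0, 2, 3, 4, 5, 6, 7, 8],
                [0, 1, 3, 4, 5, 6, 7, 8],
                [0, 1, 2, 4, 5, 6, 7, 8],
                [0, 1, 2, 3, 5, 6, 7, 8],
                [0, 1, 2, 3, 4, 6, 7, 8],
                [0, 1, 2, 3, 4, 5, 7, 8],
                [0, 1, 2, 3, 4, 5, 6, 8],
                [0, 1, 2, 3, 4, 5, 6, 7],
                [1, 2, 3, 4, 5, 6, 7, 8],
                [0, ("merge", 1, 2), 3, 4, 5, 6, 7, 8],
                [0, 1, 2, 5, 6, 7, 8],
            ],
        )
    )

    # SYNF7: 15 isoforms, widest length spread (about 250 bp to 5600 bp)
    genes.append(
        _gene(
            "SYNF7", "fix7", "+",
            [500, 300, 450, 250, 600, 400, 550, 350, 700, 500, 480, 520],
            [900, 700, 1100, 600, 800, 1300, 500, 950, 750, 1000, 850],
            [
                list(range(12)),
                [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
                [0, 1, 2, 3, 4, 5, 6, 7, 8],
                [0, 1, 2, 3, 4, 5, 6],
                [0, 1, 2, 3, 4],
                [0, 1, 2],
                [0, 3],
                [0, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11],
                [0, 1, 2, 3, 5, 6, 7, 8, 9, 10, 11],
                [0, 1, 2, 3, 4, 5, 7, 8, 9, 10, 11],
                [0, 1, 2, 3, 4, 5, 6, 7, 9, 10, 11],
                [2, 3, 4, 5, 6, 7, 8, 9, 10, 11],
                [4, 5, 6, 7, 8, 9, 10, 11],
                [0, 1, ("merge", 2, 3), 4, 5, 6, 7, 8, 9, 10, 11],
                [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, ("trim3", 10, 200)],
            ],
        )
    )
    return genes
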