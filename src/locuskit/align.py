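"""Pairwise alignment of near-identical paralogs and discriminating-site
enumeration.

Two paralogous gene copies that are >97% identical differ at a sparse set of
*discriminating sites* — alignment columns where the two copies carry
different, non-gap bases. Those sites are what make a hybrid (chimeric) gene
mappable base-by-base onto its two parents. This module produces a global
pairwise alignment with coordinate maps back to each input, and enumerates
the discriminating sites, optionally grouped by labelled regions (e.g.
Exon1/Intron/Exon2) given on the first sequence's coordinates.

Scoring is fixed and declared: match +1, mismatch −1, first base of a gap −4,
each further gap base −1. For copies at ≥97% identity this strongly favours
substitution columns over gap calls, so the site list is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

from .errors import InputError, RegionError

MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_OPEN_SCORE = -4  # charged on the first base of each gap
GAP_EXTEND_SCORE = -1

_VALID_BASES = set("ACGTN")


def sanitize_sequence(seq: str, name: str = "sequence") -> str:
    """Uppercase, convert U→T, and reject anything outside ACGTN."""
    s = str(seq).strip().upper().replace("U", "T")
    if not s:
        raise InputError(f"{name} is empty")
    bad = sorted(set(s) - _VALID_BASES)
    if bad:
        raise InputError(f"{name} contains non-nucleotide symbols: {', '.join(bad)}")
    return s


@dataclass
class PairwiseAlignment:
    """Global alignment of two sequences with per-column coordinate maps.

    ``coord_map_a[c]`` / ``coord_map_b[c]`` give the 1-based source position
    shown in alignment column ``c`` (``None`` for a gap). ``identity_percent``
    is computed over columns where both sequences are non-gap.
    """

    seq_a: str
    seq_b: str
    aligned_a: str
    aligned_b: str
    coord_map_a: list[int | None]
    coord_map_b: list[int | None]
    identity_percent: float
    score: float

    def __post_init__(self) -> None:
        assert self.aligned_a.replace("-", "") == self.seq_a
        assert self.aligned_b.replace("-", "") == self.seq_b

    @property
    def length(self) -> int:
        return len(self.aligned_a)


@dataclass(frozen=True)
class DiscriminatingSite:
    """An alignment column where the two paralogs disagree (no gaps, no N)."""

    column: int  # 0-based alignment column
    pos_a: int  # 1-based in sequence A
    pos_b: int  # 1-based in sequence B
    base_a: str
    base_b: str
    region_label: str | None = None


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN_SCORE
    aligner.extend_gap_score = GAP_EXTEND_SCORE
    return aligner


def align_paralogs(seq_a: str, seq_b: str) -> PairwiseAlignment:
    """Globally align two paralog sequences under the declared scoring.

    Deterministic: the first alignment of the aligner's canonical traceback
    enumeration is taken. De-gapping the output reproduces the inputs
    exactly (asserted).
    """
    a = sanitize_sequence(seq_a, "sequence A")
    b = sanitize_sequence(seq_b, "sequence B")
    alignment = _make_aligner().align(a, b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])

    coord_a: list[int | None] = []
    coord_b: list[int | None] = []
    pa = pb = 0
    matches = 0
    both = 0
    for ca, cb in zip(row_a, row_b):
        if ca != "-":
            pa += 1
            coord_a.append(pa)
        else:
            coord_a.append(None)
        if cb != "-":
            pb += 1
            coord_b.append(pb)
        else:
            coord_b.append(None)
        if ca != "-" and cb != "-":
            both += 1
            if ca == cb:
                matches += 1
    identity = 100.0 * matches / both if both else 0.0
    return PairwiseAlignment(
        seq_a=a,
        seq_b=b,
        aligned_a=row_a,
        aligned_b=row_b,
        coord_map_a=coord_a,
        coord_map_b=coord_b,
        identity_percent=identity,
        score=float(alignment.score),
    )


Region = tuple[str, int, int]  # (label, start, end) 1-based inclusive on sequence A


def _check_regions(regions: Sequence[Region], span: int) -> None:
    intervals = sorted((s, e, lab) for lab, s, e in regions)
    for s, e, lab in intervals:
        if s < 1 or e > span or s > e:
            raise RegionError(
                f"region {lab!r} [{s}, {e}] outside sequence A span [1, {span}]"
            )
    for (s1, e1, l1), (s2, e2, l2) in zip(intervals, intervals[1:]):
        if s2 <= e1:
            raise RegionError(f"regions {l1!r} and {l2!r} overlap")


def enumerate_discriminating_sites(
    aln: PairwiseAlignment,
    regions: Sequence[Region] | None = None,
) -> list[DiscriminatingSite]:
    """List every substitution column of the alignment.

    Gap columns are excluded; columns where either base is N are treated as
    non-informative. Region labels, if given, are intervals on sequence A
    (1-based inclusive) and must not overlap.
    """
    if regions is not None:
        _check_regions(regions, len(aln.seq_a))
    sites: list[DiscriminatingSite] = []
    for col, (ca, cb) in enumerate(zip(aln.aligned_a, aln.aligned_b)):
        if ca in "-N" or cb in "-N" or ca == cb:
            continue
        pos_a = aln.coord_map_a[col]
        pos_b = aln.coord_map_b[col]
        assert pos_a is not None and pos_b is not None
        label = None
        if regions is not None:
            for lab, s, e in regions:
                if s <= pos_a <= e:
                    label = lab
                    break
        sites.append(DiscriminatingSite(col, pos_a, pos_b, ca, cb, label))
    return sites


def site_region_counts(sites: Iterable[DiscriminatingSite]) -> dict[str, int]:
    """Count discriminating sites per region label (None → 'unlabelled')."""
    counts: dict[str, int] = {}
    for s in sites:
        key = s.region_label if s.region_label is not None else "unlabelled"
        counts[key] = counts.get(key, 0) + 1
    return counts


def identity_matrix(seqs: Mapping[str, str] | Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Symmetric percent-identity matrix over named sequences.

    Each off-diagonal cell is the identity of the global pairwise alignment
    of the two sequences; the diagonal is 100.
    """
    items = list(seqs.items()) if isinstance(seqs, Mapping) else list(seqs)
    if len(items) < 2:
        raise InputError("identity_matrix needs at least two sequences")
    names = [n for n, _ in items]
    mat = pd.DataFrame(100.0, index=names, columns=names)
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            ident = align_paralogs(items[i][1], items[j][1]).identity_percent
            mat.iloc[i, j] = ident
            mat.iloc[j, i] = ident
    return mat
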