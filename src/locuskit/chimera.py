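"""Mapping a chimeric (hybrid) gene onto its two parental paralogs.

A deletion-forming nonallelic homologous recombination (NAHR) event between
two same-orientation paralogs fuses them into a single chimeric gene: the 5'
part derives from the upstream parent ("A"), the 3' part from the downstream
parent ("B"). Because the parents differ only at sparse discriminating
sites, the crossover cannot be pinpointed — it can only be bounded between
the last site at which the hybrid matches parent A and the first site at
which it matches parent B. The number of candidate inter-base junctions in
that window is ``first_b_pos − last_a_pos``.

The same logic deduces the genomic deletion size: the distance between the
primers on the intact haplotype minus the observed fusion-amplicon length,
or equivalently the ATG-to-ATG distance between the two recombining copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq

from . import align as _align
from .align import DiscriminatingSite, PairwiseAlignment, align_paralogs
from .errors import (
    CoverageError,
    FrameError,
    InputError,
    NoSignalError,
    UnsupportedEventError,
)

MAX_SIMPLE_CROSSOVERS = 2  # more switches than this is flagged "complex"


@dataclass(frozen=True)
class SiteAssignment:
    """One discriminating site classified against the hybrid.

    ``state`` is "A" when the hybrid carries the parent-A base, "B" for the
    parent-B base, "novel" when it matches neither, and "uncallable" when
    the hybrid has a gap or N at the site. ``hybrid_pos`` counts from the
    hybrid's own ATG (1-based).
    """

    site: DiscriminatingSite
    state: str
    hybrid_base: str | None
    hybrid_pos: int | None


@dataclass(frozen=True)
class BreakpointInterval:
    """Bounds on one crossover: junction lies strictly between the flanking
    informative sites; ``junction_count = first_b_pos − last_a_pos`` counts
    the candidate inter-base junctions."""

    last_a_pos: int
    first_b_pos: int
    junction_count: int

    def __post_init__(self) -> None:
        assert self.first_b_pos > self.last_a_pos
        assert self.junction_count == self.first_b_pos - self.last_a_pos >= 1


@dataclass
class ChimeraReport:
    assignments: list[SiteAssignment]
    crossover_count: int
    intervals: list[BreakpointInterval]
    novel_sites: list[SiteAssignment]
    conversion_flag: bool
    complex_flag: bool = False


@dataclass(frozen=True)
class DeletionDeduction:
    """Deletion size implied by a fusion amplicon spanning two primers."""

    primer_span: int
    amplicon_length: int
    deletion_length: int

    @property
    def deletion_kb(self) -> float:
        return self.deletion_length / 1000.0


@dataclass(frozen=True)
class SynonymyRecord:
    parent: str  # "A" or "B"
    coding_pos: int
    codon_index: int
    ref_codon: str
    alt_codon: str
    synonymous: bool


@dataclass
class ProteinDiffReport:
    aa_differences: list[tuple[int, str, str]]
    synonymy_records: list[SynonymyRecord]


def classify_hybrid_sites(
    hybrid: str,
    aln: PairwiseAlignment,
    sites: Sequence[DiscriminatingSite],
) -> list[SiteAssignment]:
    """Assign each discriminating site of the A/B alignment a parental state
    in the hybrid.

    The hybrid is aligned to parent A (the frame the sites' ``pos_a`` refer
    to); each site's hybrid base is read through that alignment and compared
    with the two parental bases. Raises :class:`CoverageError` when the
    hybrid covers fewer than half of the site positions (truncated input).
    """
    hyb = _align.sanitize_sequence(hybrid, "hybrid")
    hyb_aln = align_paralogs(aln.seq_a, hyb)
    # parent-A position -> (hybrid position, hybrid base)
    a_to_h: dict[int, tuple[int, str]] = {}
    for pa, ph in zip(hyb_aln.coord_map_a, hyb_aln.coord_map_b):
        if pa is not None and ph is not None:
            a_to_h[pa] = (ph, hyb[ph - 1])

    out: list[SiteAssignment] = []
    missing = 0
    for site in sites:
        hit = a_to_h.get(site.pos_a)
        if hit is None or hit[1] == "N":
            missing += 1
            out.append(SiteAssignment(site, "uncallable", None, None))
            continue
        hpos, hbase = hit
        if hbase == site.base_a:
            state = "A"
        elif hbase == site.base_b:
            state = "B"
        else:
            state = "novel"
        out.append(SiteAssignment(site, state, hbase, hpos))
    if sites and missing > 0.5 * len(sites):
        raise CoverageError(
            f"hybrid covers only {len(sites) - missing}/{len(sites)} "
            "discriminating sites; input looks truncated"
        )
    return out


def localize_breakpoints(assignments: Sequence[SiteAssignment]) -> ChimeraReport:
    """Bound every crossover of the hybrid's parental mosaic.

    The A/B states (novel and uncallable sites are excluded from
    segmentation but reported) are segmented with the minimal number of
    switches — for directly observed states that is simply the number of
    adjacent state changes. Each switch yields one
    :class:`BreakpointInterval` between the flanking informative sites, in
    hybrid ATG coordinates. A pattern A…B…A or B…A…B sets
    ``conversion_flag`` (candidate gene-conversion tract); more than
    ``MAX_SIMPLE_CROSSOVERS`` switches sets ``complex_flag``.
    """
    informative = [a for a in assignments if a.state in ("A", "B")]
    novel = [a for a in assignments if a.state == "novel"]
    if not informative:
        raise NoSignalError("all sites novel or uncallable; no parental signal")
    informative.sort(key=lambda a: a.hybrid_pos)

    intervals: list[BreakpointInterval] = []
    for prev, cur in zip(informative, informative[1:]):
        if prev.state != cur.state:
            intervals.append(
                BreakpointInterval(
                    last_a_pos=prev.hybrid_pos,
                    first_b_pos=cur.hybrid_pos,
                    junction_count=cur.hybrid_pos - prev.hybrid_pos,
                )
            )
    crossovers = len(intervals)
    states = [informative[0].state]
    for a in informative[1:]:
        if a.state != states[-1]:
            states.append(a.state)
    conversion = len(states) >= 3 and states[0] == states[-1]
    return ChimeraReport(
        assignments=list(assignments),
        crossover_count=crossovers,
        intervals=intervals,
        novel_sites=novel,
        conversion_flag=conversion,
        complex_flag=crossovers > MAX_SIMPLE_CROSSOVERS,
    )


def deduce_deletion_from_amplicon(primer_span: int, amplicon_length: int) -> DeletionDeduction:
    """Deletion size = primer span on the intact haplotype − fusion-amplicon
    length. Both must be positive and the span strictly larger."""
    if amplicon_length <= 0 or primer_span <= 0:
        raise InputError("primer_span and amplicon_length must be positive")
    if amplicon_length >= primer_span:
        raise InputError(
            f"amplicon ({amplicon_length} bp) is not shorter than the primer "
            f"span ({primer_span} bp); no deletion implied"
        )
    return DeletionDeduction(primer_span, amplicon_length, primer_span - amplicon_length)


def expected_deletion_from_annotation(annotation, donor: str, acceptor: str) -> int:
    """ATG-to-ATG genomic distance between two same-family, same-strand
    copies — the deletion size an NAHR event between them would produce.

    ``annotation`` is an iterable of features with ``gene_id``, ``start``,
    ``end``, ``strand`` and ``family`` attributes (e.g.
    :class:`locuskit.synthetic.GeneFeature`).
    """
    feats = {f.gene_id: f for f in annotation}
    try:
        d, a = feats[donor], feats[acceptor]
    except KeyError as exc:
        raise InputError(f"gene {exc.args[0]!r} not in annotation") from None
    if d.family != a.family or d.family == "unique":
        raise InputError(f"{donor} and {acceptor} are not same-family paralogs")
    if d.strand != a.strand:
        raise UnsupportedEventError(
            f"{donor} and {acceptor} are on opposite strands; inversion-forming "
            "NAHR is unsupported"
        )
    atg = lambda f: f.start if f.strand == "+" else f.end
    return abs(atg(a) - atg(d))


def _codons(seq: str) -> list[str]:
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def protein_consequences(cds_a: str, cds_b: str, cds_hybrid: str) -> ProteinDiffReport:
    """Residue-level differences between the parents, and a synonymy verdict
    for every coding position where the hybrid differs from either parent.

    ``codon_index = ceil(coding_pos / 3)``; a substitution is synonymous when
    the reference and alternate codons translate identically under the
    standard code. Partial CDS (no start/stop check) is accepted, but the
    length must be a multiple of three.
    """
    seqs = {}
    for name, s in (("A", cds_a), ("B", cds_b), ("hybrid", cds_hybrid)):
        s = _align.sanitize_sequence(s, f"CDS {name}")
        if len(s) % 3:
            raise FrameError(f"CDS {name} length {len(s)} not divisible by 3")
        seqs[name] = s

    prot = {k: str(Seq(v).translate()) for k, v in seqs.items()}
    aa_diffs = [
        (i + 1, ra, rb)
        for i, (ra, rb) in enumerate(zip(prot["A"], prot["B"]))
        if ra != rb
    ]

    records: list[SynonymyRecord] = []
    cod = {k: _codons(v) for k, v in seqs.items()}
    for parent in ("A", "B"):
        n = min(len(seqs[parent]), len(seqs["hybrid"]))
        for pos in range(1, n + 1):
            if seqs[parent][pos - 1] == seqs["hybrid"][pos - 1]:
                continue
            ci = math.ceil(pos / 3)
            ref_codon = cod[parent][ci - 1]
            alt_codon = cod["hybrid"][ci - 1]
            records.append(
                SynonymyRecord(
                    parent=parent,
                    coding_pos=pos,
                    codon_index=ci,
                    ref_codon=ref_codon,
                    alt_codon=alt_codon,
                    synonymous=str(Seq(ref_codon).translate())
                    == str(Seq(alt_codon).translate()),
                )
            )
    return ProteinDiffReport(aa_differences=aa_diffs, synonymy_records=records)
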