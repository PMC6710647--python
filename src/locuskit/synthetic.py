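"""Ground-truthed synthetic loci for testing NAHR and copy-number analyses.

The simulator emulates a repeated-gene locus of the kind found at the
soybean seed-coat *I* locus: a ~250-kb region carrying a dozen near-identical
(≥97%) gene-family copies arranged in tandem clusters and a large inverted
repeat whose two arms are exact reverse complements flanking a unique
central gene, interleaved with single-copy ("unique") genes. On such a
locus it can:

* apply a deletion-forming NAHR event between two same-orientation family
  copies, producing a chimeric fusion gene and an exactly-known deleted
  interval (the ATG-to-ATG distance between the copies);
* generate a normalized coverage track for the mutant aligned back to the
  parent reference, under a uniform multi-mapping allocation model — unique
  sequence inside the deletion drops to zero while repeated copies dim in
  proportion to the surviving/original copy ratio;
* draw digital-PCR partition counts under Poisson chamber loading;
* plant variant tables with a high-density introgression block over a low
  background.

Every stochastic choice is driven by a mandatory seed, and all planted
structure (paralog discriminating sites, deleted intervals, variant
positions) is recorded as machine-readable truth, so downstream detectors
can be tested against exact expectations without any external data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .dpcr import DpcrAssay
from .errors import InputError, LayoutError, UnsupportedEventError
from .scan import CoverageTrack, VariantTable
from .seqs import reverse_complement

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


# ---------------------------------------------------------------------------
# configuration types

@dataclass(frozen=True)
class ClusterSpec:
    """A block of family genes placed left-to-right from ``start``.

    ``genes`` are (name, strand, family) triples; ``spacers`` are the gaps
    (in bases) between consecutive gene ends and starts. A cluster with
    ``mirror_of`` set does not draw new sequence: its whole block (genes and
    intervening spacers) is the exact reverse complement of the named
    cluster's block, with ``genes`` naming the mirrored copies in their new
    left-to-right order.
    """

    name: str
    start: int
    genes: tuple[tuple[str, str, str], ...]
    spacers: tuple[int, ...] = ()
    mirror_of: str | None = None


@dataclass(frozen=True)
class LocusConfig:
    genome_length: int
    clusters: tuple[ClusterSpec, ...]
    unique_genes: tuple[tuple[str, int, int], ...]  # (name, length, start)
    seed: int
    template_lengths: tuple[int, int, int] = (180, 125, 990)  # exon1, intron, exon2
    per_site_divergence: float = 0.02

    @property
    def template_length(self) -> int:
        return sum(self.template_lengths)

    @property
    def template_regions(self) -> list[tuple[str, int, int]]:
        e1, intron, e2 = self.template_lengths
        return [
            ("Exon1", 1, e1),
            ("Intron", e1 + 1, e1 + intron),
            ("Exon2", e1 + intron + 1, e1 + intron + e2),
        ]

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_site_divergence <= 1.0:
            raise InputError("per_site_divergence must lie in [0, 1]")
        if self.genome_length < 1:
            raise InputError("genome_length must be positive")


@dataclass(frozen=True)
class GeneFeature:
    gene_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # "+" or "-"
    family: str  # family id, or "unique"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def atg(self) -> int:
        """Genomic coordinate of the first template base (the ATG)."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class NahrEvent:
    donor_gene_id: str
    acceptor_gene_id: str
    crossover_junction: int  # switch between template positions j and j+1
    deleted_interval: tuple[int, int]  # 1-based inclusive, pre-event frame
    chimera_id: str

    @property
    def deletion_length(self) -> int:
        s, e = self.deleted_interval
        return e - s + 1


@dataclass(frozen=True)
class CoverageSimConfig:
    mean_depth: float  # expected normalized depth at single-copy sequence
    seed: int
    multimap_identity_threshold: float = 0.95
    noise_dispersion: float = 0.05  # CV^2 of the gamma depth multiplier

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise InputError("mean_depth must be positive")
        if not 0 < self.multimap_identity_threshold <= 1:
            raise InputError("multimap_identity_threshold must lie in (0, 1]")
        if self.noise_dispersion < 0:
            raise InputError("noise_dispersion must be non-negative")


@dataclass(frozen=True)
class DpcrSimConfig:
    chambers: int
    lambda_ref: float
    true_copy_ratio: float
    replicates: int
    seed: int

    def __post_init__(self) -> None:
        if self.chambers < 1:
            raise InputError("chambers must be >= 1")
        if self.lambda_ref <= 0:
            raise InputError("lambda_ref must be positive")
        if self.true_copy_ratio < 0:
            raise InputError("true_copy_ratio must be non-negative")


@dataclass(frozen=True)
class IntrogressionConfig:
    background_rate: float  # variants per kb
    block_interval: tuple[int, int]  # 1-based inclusive
    block_rate: float
    seed: int

    def __post_init__(self) -> None:
        if not self.block_rate >= self.background_rate >= 0:
            raise InputError("need block_rate >= background_rate >= 0")


@dataclass
class SyntheticLocus:
    """A simulated locus: sequence + annotation + planted truth."""

    contig: str
    sequence: str
    features: list[GeneFeature]
    truth_sites: dict[tuple[str, str], tuple[int, ...]]
    config: LocusConfig
    events: list[NahrEvent] = field(default_factory=list)

    @property
    def genome_length(self) -> int:
        return len(self.sequence)

    def feature(self, gene_id: str) -> GeneFeature:
        for f in self.features:
            if f.gene_id == gene_id:
                return f
        raise InputError(f"gene {gene_id!r} not annotated on {self.contig}")

    def gene_sequence(self, gene_id: str) -> str:
        """ATG-oriented (template-frame) sequence of a gene."""
        f = self.feature(gene_id)
        s = self.sequence[f.start - 1 : f.end]
        return s if f.strand == "+" else reverse_complement(s)

    def family_members(self, family: str | None = None) -> list[GeneFeature]:
        return [
            f
            for f in self.features
            if f.family != "unique" and (family is None or f.family == family)
        ]

    def pair_truth(self, gene_a: str, gene_b: str) -> tuple[int, ...]:
        return self.truth_sites[tuple(sorted((gene_a, gene_b)))]


# ---------------------------------------------------------------------------
# sequence helpers

def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(template: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. per-site substitution at ``rate`` with transition:transversion
    weight 2:1 (transition probability 1/2, each transversion 1/4)."""
    out = template.copy()
    if rate <= 0:
        return out
    hits = np.flatnonzero(rng.random(len(template)) < rate)
    draws = rng.random(len(hits))
    for i, u in zip(hits, draws):
        base = out[i]
        if u < 0.5:
            out[i] = _TRANSITION[base]
        elif u < 0.75:
            out[i] = _TRANSVERSIONS[base][0]
        else:
            out[i] = _TRANSVERSIONS[base][1]
    return out


def _compute_truth(
    members: dict[str, str],
    families: dict[str, str],
) -> dict[tuple[str, str], tuple[int, ...]]:
    """Positions (1-based, template frame) where each within-family pair of
    ATG-oriented member sequences differ."""
    truth: dict[tuple[str, str], tuple[int, ...]] = {}
    ids = sorted(members)
    for ga, gb in itertools.combinations(ids, 2):
        if families[ga] != families[gb]:
            continue
        sa, sb = members[ga], members[gb]
        if len(sa) != len(sb):  # pragma: no cover - construction guarantees equal
            raise InputError(f"family members {ga}/{gb} have unequal lengths")
        a = np.frombuffer(sa.encode(), dtype="S1")
        b = np.frombuffer(sb.encode(), dtype="S1")
        truth[(ga, gb)] = tuple(int(i) + 1 for i in np.flatnonzero(a != b))
    return truth


# ---------------------------------------------------------------------------
# locus construction

def build_locus(config: LocusConfig, contig: str = "locus") -> SyntheticLocus:
    """Emit a deterministic synthetic locus from its configuration.

    Family genes within one family are mutually alignable gap-free at the
    template length: each member is the family template with i.i.d. planted
    substitutions (per-member rate = per_site_divergence / 2, so that two
    members differ at roughly the configured rate). Mirror clusters are
    exact reverse complements of their source block. The discriminating
    sites of every within-family pair are recorded as truth.
    """
    rng = np.random.default_rng(config.seed)
    genome = _random_bases(rng, config.genome_length)
    tlen = config.template_length

    templates: dict[str, np.ndarray] = {}
    features: list[GeneFeature] = []
    block_spans: dict[str, tuple[int, int]] = {}
    rate = config.per_site_divergence / 2.0

    def _place(arr: np.ndarray, start: int, end: int, name: str) -> None:
        if start < 1 or end > config.genome_length:
            raise LayoutError(
                f"feature {name!r} [{start}, {end}] outside genome "
                f"[1, {config.genome_length}]"
            )
        genome[start - 1 : end] = arr

    for cluster in config.clusters:
        if cluster.mirror_of is not None:
            continue
        if len(cluster.spacers) != max(len(cluster.genes) - 1, 0):
            raise InputError(
                f"cluster {cluster.name!r}: need one spacer per adjacent gene pair"
            )
        pos = cluster.start
        for idx, (name, strand, family) in enumerate(cluster.genes):
            template = templates.get(family)
            if template is None:
                template = _random_bases(rng, tlen)
                template[:3] = list("ATG")
                templates[family] = template
            member = _mutate(template, rate, rng)
            placed = member if strand == "+" else np.array(
                list(reverse_complement("".join(member)))
            )
            end = pos + tlen - 1
            _place(placed, pos, end, name)
            features.append(GeneFeature(name, pos, end, strand, family))
            if idx < len(cluster.spacers):
                pos = end + 1 + cluster.spacers[idx]
            else:
                pos = end + 1
        block_spans[cluster.name] = (cluster.start, features[-1].end)

    for cluster in config.clusters:
        if cluster.mirror_of is None:
            continue
        source = next(
            (c for c in config.clusters if c.name == cluster.mirror_of), None
        )
        if source is None or source.mirror_of is not None:
            raise InputError(
                f"cluster {cluster.name!r} mirrors unknown cluster {cluster.mirror_of!r}"
            )
        src_start, src_end = block_spans[source.name]
        block = "".join(genome[src_start - 1 : src_end])
        rc = np.array(list(reverse_complement(block)))
        block_len = len(rc)
        end = cluster.start + block_len - 1
        _place(rc, cluster.start, end, cluster.name)
        block_spans[cluster.name] = (cluster.start, end)

        src_feats = [f for f in features if source.start <= f.start <= src_end]
        src_feats.sort(key=lambda f: f.start)
        mirrored = list(reversed(src_feats))
        if len(cluster.genes) != len(mirrored):
            raise InputError(
                f"mirror cluster {cluster.name!r} names {len(cluster.genes)} genes "
                f"but source has {len(mirrored)}"
            )
        for (name, strand, family), src in zip(cluster.genes, mirrored):
            rel_start = src_end - src.end  # 0-based offset within mirrored block
            new_start = cluster.start + rel_start
            new_end = new_start + src.length - 1
            flipped = "-" if src.strand == "+" else "+"
            if strand != flipped or family != src.family:
                raise InputError(
                    f"mirror cluster {cluster.name!r}: gene {name!r} must be the "
                    f"{flipped}-strand {src.family} copy of {src.gene_id!r}"
                )
            features.append(GeneFeature(name, new_start, new_end, flipped, family))

    for name, length, start in config.unique_genes:
        end = start + length - 1
        _place(_random_bases(rng, length), start, end, name)
        features.append(GeneFeature(name, start, end, "+", "unique"))

    features.sort(key=lambda f: f.start)
    for f1, f2 in zip(features, features[1:]):
        if f2.start <= f1.end:
            raise LayoutError(
                f"features {f1.gene_id!r} and {f2.gene_id!r} overlap "
                f"([{f1.start},{f1.end}] vs [{f2.start},{f2.end}])"
            )
    # mirror blocks (and their sources) are copied wholesale, so nothing
    # else may intrude on those spans; ordinary cluster spacers are plain
    # background and stay available
    guarded = {
        name
        for c in config.clusters
        if c.mirror_of is not None
        for name in (c.name, c.mirror_of)
    }
    for f in features:
        for cname in guarded:
            bs, be = block_spans[cname]
            cluster = next(c for c in config.clusters if c.name == cname)
            in_cluster = any(g[0] == f.gene_id for g in cluster.genes)
            if not in_cluster and f.start <= be and f.end >= bs:
                raise LayoutError(
                    f"features {f.gene_id!r} and cluster block {cname!r} overlap"
                )

    sequence = "".join(genome)
    locus = SyntheticLocus(contig, sequence, features, {}, config)
    members = {f.gene_id: locus.gene_sequence(f.gene_id) for f in locus.family_members()}
    families = {f.gene_id: f.family for f in locus.family_members()}
    locus.truth_sites = _compute_truth(members, families)
    return locus


# ---------------------------------------------------------------------------
# the inverted-repeat-allele preset

GENE_FAMILY = "CHS"


def i_i_allele_config(seed: int, per_site_divergence: float = 0.02) -> LocusConfig:
    """Preset emulating a silencing-allele locus on a 250-kb genome.

    Twelve family copies: a donor copy (CHS5) and, 138,092 bases downstream,
    a same-orientation acceptor copy (CHS1); four tandem copies between
    them; and a ~27-kb inverted repeat of two exactly reverse-complementary
    three-gene arms flanking one unique central gene. Eight unique genes lie
    between the donor and acceptor ATGs, so a donor→acceptor NAHR deletes
    ten family copies and eight unique genes.
    """
    tlen = sum((180, 125, 990))
    gene = lambda n: n + tlen - 1
    clusters = (
        ClusterSpec("donor", 70_000, (("CHS5", "+", GENE_FAMILY),)),
        ClusterSpec(
            "tandem",
            88_000,
            (
                ("CHS9", "+", GENE_FAMILY),
                ("CHS4b", "+", GENE_FAMILY),
                ("CHS3b", "+", GENE_FAMILY),
                ("CHS1b", "+", GENE_FAMILY),
            ),
            (5_705, 5_705, 5_705),
        ),
        ClusterSpec(
            "arm1",
            170_000,
            (
                ("CHS1a", "+", GENE_FAMILY),
                ("CHS3a", "+", GENE_FAMILY),
                ("CHS4a", "+", GENE_FAMILY),
            ),
            (3_505, 3_505),
        ),
        ClusterSpec(
            "arm2",
            186_605,
            (
                ("CHS4c", "-", GENE_FAMILY),
                ("CHS3c", "-", GENE_FAMILY),
                ("CHS1c", "-", GENE_FAMILY),
            ),
            mirror_of="arm1",
        ),
        ClusterSpec("acceptor", 208_092, (("CHS1", "+", GENE_FAMILY),)),
    )
    unique = (
        ("subtilisin", 3_000, 30_000),
        ("epimerase", 3_000, 64_000),
        ("u1", 2_000, 73_000),
        ("u2", 2_000, 120_000),
        ("u3", 2_000, 130_000),
        ("u4", 2_000, 140_000),
        ("u5", 2_000, 150_000),
        ("hypothetical", 2_000, 183_000),
        ("u7", 2_000, 199_000),
        ("u8", 2_000, 202_500),
        ("galactosidase", 3_000, 215_000),
    )
    return LocusConfig(
        genome_length=250_000,
        clusters=clusters,
        unique_genes=unique,
        seed=seed,
        per_site_divergence=per_site_divergence,
    )


PRESETS = {"i-i-allele": i_i_allele_config}


# ---------------------------------------------------------------------------
# NAHR

def apply_nahr(
    locus: SyntheticLocus, donor: str, acceptor: str, junction: int
) -> tuple[SyntheticLocus, NahrEvent]:
    """Recombine two same-orientation family copies, deleting the span
    between their homologous positions.

    The crossover switches template strands between aligned (ATG-anchored)
    positions ``junction`` and ``junction + 1``; the donor contributes the
    prefix through ``junction`` and the acceptor the suffix. The deleted
    interval has exactly the ATG-to-ATG length, independent of the junction,
    and the donor's locus now carries a single chimeric gene. Opposite-strand
    pairs are rejected (that NAHR geometry forms an inversion, not a
    deletion).
    """
    fd, fa = locus.feature(donor), locus.feature(acceptor)
    if fd.family != fa.family or fd.family == "unique":
        raise InputError(f"{donor} and {acceptor} are not same-family paralogs")
    if fd.strand != fa.strand:
        raise UnsupportedEventError(
            f"{donor} and {acceptor} lie on opposite strands; inversion-forming "
            "NAHR is unsupported"
        )
    tlen = fd.length
    if fa.length != tlen:
        raise InputError("donor and acceptor have different template lengths")
    if not 1 <= junction <= tlen:
        raise InputError(f"junction {junction} outside template [1, {tlen}]")
    upstream_ok = fd.start < fa.start if fd.strand == "+" else fd.end > fa.end
    if not upstream_ok:
        raise InputError(
            f"donor {donor!r} must be ATG-upstream of acceptor {acceptor!r}"
        )

    j = junction
    if fd.strand == "+":
        del_start, del_end = fd.start + j, fa.start + j - 1
        chim_start = fd.start
    else:
        del_start, del_end = fa.end - j + 1, fd.end - j
        chim_start = fa.start
    del_len = del_end - del_start + 1
    assert del_len == abs(fa.atg - fd.atg)

    chimera_id = f"{donor}:{acceptor}"
    seq = locus.sequence
    mutant_seq = seq[: del_start - 1] + seq[del_end:]

    new_feats: list[GeneFeature] = []
    for f in locus.features:
        if f.gene_id in (donor, acceptor):
            continue
        if f.start >= del_start and f.end <= del_end:
            continue  # wholly deleted
        if f.end < del_start:
            new_feats.append(f)
        elif f.start > del_end:
            new_feats.append(
                replace(f, start=f.start - del_len, end=f.end - del_len)
            )
        # partially overlapping non-participant features are dropped
    new_feats.append(
        GeneFeature(chimera_id, chim_start, chim_start + tlen - 1, fd.strand, fd.family)
    )
    new_feats.sort(key=lambda f: f.start)

    mutant = SyntheticLocus(
        locus.contig,
        mutant_seq,
        new_feats,
        {},
        locus.config,
        events=locus.events + [
            NahrEvent(donor, acceptor, j, (del_start, del_end), chimera_id)
        ],
    )
    # the fused gene must read donor-prefix + acceptor-suffix
    expected = locus.gene_sequence(donor)[:j] + locus.gene_sequence(acceptor)[j:]
    assert mutant.gene_sequence(chimera_id) == expected
    assert mutant.genome_length + del_len == locus.genome_length

    members = {
        f.gene_id: mutant.gene_sequence(f.gene_id) for f in mutant.family_members()
    }
    families = {f.gene_id: f.family for f in mutant.family_members()}
    mutant.truth_sites = _compute_truth(members, families)
    return mutant, mutant.events[-1]


# ---------------------------------------------------------------------------
# coverage simulation

def _surviving_parent_positions(parent_len: int, events: Sequence[NahrEvent]) -> np.ndarray:
    """Boolean mask over parent coordinates of positions still present after
    replaying the deletion events in order (each event's interval is in its
    own pre-event frame)."""
    idx = np.arange(1, parent_len + 1)
    for ev in events:
        s, e = ev.deleted_interval
        idx = np.concatenate([idx[: s - 1], idx[e:]])
    mask = np.zeros(parent_len, dtype=bool)
    mask[idx - 1] = True
    return mask


def _identity_groups(locus: SyntheticLocus, threshold: float) -> list[set[str]]:
    """Connected components of family members under pairwise identity >=
    threshold (identity from planted truth sites)."""
    members = locus.family_members()
    ids = [f.gene_id for f in members]
    parent = {g: g for g in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (ga, gb), sites in locus.truth_sites.items():
        tlen = locus.feature(ga).length
        identity = 1.0 - len(sites) / tlen
        if identity >= threshold:
            parent[find(ga)] = find(gb)
    groups: dict[str, set[str]] = {}
    for g in ids:
        groups.setdefault(find(g), set()).add(g)
    return list(groups.values())


def simulate_coverage(
    locus: SyntheticLocus,
    mutant: SyntheticLocus,
    config: CoverageSimConfig,
) -> CoverageTrack:
    """Normalized coverage of the mutant's reads over the parent reference.

    Reads are not simulated individually; the track is drawn around a
    closed-form expectation. Single-copy positions keep ``mean_depth`` where
    they survive in the mutant and drop to zero inside deletions. Positions
    in family genes receive ``mean_depth × S/C`` where ``C`` counts the
    reference copies of the gene's identity-sharing group and ``S`` the
    copies (including any chimera) surviving in the mutant — reads from the
    survivors multi-map uniformly across all reference copies. Noise is a
    per-base gamma multiplier with CV² = ``noise_dispersion`` (0 → exact
    expectation). Values are already on the `count × 10⁶ / total reads`
    scale.
    """
    if mutant.contig != locus.contig or mutant.config != locus.config:
        raise InputError("mutant does not derive from the given parent locus")
    rng = np.random.default_rng(config.seed)
    n = locus.genome_length
    expected = np.full(n, config.mean_depth, dtype=float)

    surviving = _surviving_parent_positions(n, mutant.events)
    expected[~surviving] = 0.0

    groups = _identity_groups(locus, config.multimap_identity_threshold)
    surviving_ids = {f.gene_id for f in mutant.family_members()}
    donor_of_chimera = {ev.chimera_id: ev.donor_gene_id for ev in mutant.events}
    for group in groups:
        c_total = len(group)
        s_total = 0
        for gid in surviving_ids:
            root = donor_of_chimera.get(gid, gid)
            if root in group:
                s_total += 1
        level = config.mean_depth * s_total / c_total
        for gid in group:
            f = locus.feature(gid)
            expected[f.start - 1 : f.end] = level

    if config.noise_dispersion > 0:
        d = config.noise_dispersion
        noisy = np.zeros_like(expected)
        pos = expected > 0
        noisy[pos] = rng.gamma(shape=1.0 / d, scale=d * expected[pos])
        values = noisy
    else:
        values = expected
    return CoverageTrack(locus.contig, 1, n, values, total_reads=1_000_000)


# ---------------------------------------------------------------------------
# digital PCR and variant simulation

def simulate_dpcr(config: DpcrSimConfig, sample_label: str = "sample") -> list[DpcrAssay]:
    """Draw replicate digital-PCR panels under Poisson chamber loading.

    Per replicate: target positives ~ Binomial(n, 1 − exp(−λ_ref·ratio)),
    reference positives ~ Binomial(n, 1 − exp(−λ_ref)).
    """
    rng = np.random.default_rng(config.seed)
    p_t = 1.0 - math.exp(-config.lambda_ref * config.true_copy_ratio)
    p_r = 1.0 - math.exp(-config.lambda_ref)
    assays = []
    for i in range(config.replicates):
        assays.append(
            DpcrAssay(
                chambers=config.chambers,
                positives_target=int(rng.binomial(config.chambers, p_t)),
                positives_ref=int(rng.binomial(config.chambers, p_r)),
                replicate_id=f"rep{i + 1}",
                sample_label=sample_label,
            )
        )
    return assays


def _draw_positions(
    rng: np.random.Generator, candidates: np.ndarray, rate_per_kb: float
) -> np.ndarray:
    n = rng.poisson(rate_per_kb * len(candidates) / 1000.0)
    n = min(n, len(candidates))
    if n == 0:
        return np.empty(0, dtype=int)
    return rng.choice(candidates, size=n, replace=False)


def _alleles(rng: np.random.Generator, k: int) -> tuple[np.ndarray, np.ndarray]:
    ref_idx = rng.integers(0, 4, size=k)
    alt_idx = (ref_idx + rng.integers(1, 4, size=k)) % 4
    return _BASES[ref_idx], _BASES[alt_idx]


def simulate_variants(
    config: IntrogressionConfig, genome_length: int, contig: str = "locus"
) -> VariantTable:
    """Plant a variant table: Poisson counts at ``background_rate`` per kb
    outside the block and ``block_rate`` inside, positions unique and
    sorted."""
    bs, be = config.block_interval
    if not 1 <= bs <= be <= genome_length:
        raise InputError("block_interval must lie inside the genome")
    rng = np.random.default_rng(config.seed)
    inside = np.arange(bs, be + 1)
    outside = np.concatenate([np.arange(1, bs), np.arange(be + 1, genome_length + 1)])
    pos = np.concatenate(
        [
            _draw_positions(rng, outside, config.background_rate),
            _draw_positions(rng, inside, config.block_rate),
        ]
    )
    pos = np.sort(pos)
    ref, alt = _alleles(rng, len(pos))
    import pandas as pd

    return VariantTable(
        pd.DataFrame({"contig": contig, "pos": pos, "ref": ref, "alt": alt}),
        source_label="simulated",
    )


def simulate_variant_pair(
    config: IntrogressionConfig,
    genome_length: int,
    shared_fraction: float,
    contig: str = "locus",
) -> tuple[VariantTable, VariantTable, float]:
    """Two variant tables with a planted fraction of exactly shared records.

    Table B keeps ``round(shared_fraction × len(A))`` of A's records verbatim
    and replaces the rest with fresh non-colliding positions, so the
    directional sharing A→B is planted exactly. Returns (A, B, planted
    percent).
    """
    if not 0 <= shared_fraction <= 1:
        raise InputError("shared_fraction must lie in [0, 1]")
    import pandas as pd

    a = simulate_variants(config, genome_length, contig)
    rng = np.random.default_rng(config.seed + 1)
    n = len(a)
    k = int(round(shared_fraction * n))
    keep_idx = np.sort(rng.choice(n, size=k, replace=False))
    kept = a.records.iloc[keep_idx]
    n_new = n - k
    taken = set(a.records.pos)
    free = np.array([p for p in range(1, genome_length + 1) if p not in taken])
    new_pos = np.sort(rng.choice(free, size=n_new, replace=False))
    ref, alt = _alleles(rng, n_new)
    fresh = pd.DataFrame({"contig": contig, "pos": new_pos, "ref": ref, "alt": alt})
    b = VariantTable(
        pd.concat([kept, fresh], ignore_index=True), source_label="simulated-pair"
    )
    planted = 100.0 * k / n if n else 100.0
    return a, b, planted


# ---------------------------------------------------------------------------
# synthetic stand-in for the CHS5/CHS1 paralog pair

def synthetic_chs_pair() -> tuple[str, str, list[tuple[str, int, int]]]:
    """Synthetic stand-in for a CHS5/CHS1-like paralog pair (NOT the
    deposited sequences, which are not redistributable here).

    Returns (seq_a, seq_b, regions) — two 1,295-base gene sequences
    (Exon1 1–180, Intron 181–305, Exon2 306–1295) planted with the
    difference layout reported for that pair: 4 discriminating sites in
    Exon 1, 21 in the intron, and 19 in Exon 2 including one in the stop
    codon; sites at ATG positions 578, 719 and 1061 with no site between
    578–719 or 719–1061; the 719 difference is the third base of the
    phenylalanine codon 198 (coding position 594, TTC↔TTT, synonymous); and
    exactly three amino-acid differences (codons 9, 100 and the last
    residue, Val↔Leu).
    """
    rng = np.random.default_rng(20190801)
    seq = _random_bases(rng, 1295)
    seq[:3] = list("ATG")

    def set_codon(coding_pos_first: int, codon: str, exon2: bool) -> None:
        g = coding_pos_first + 125 if exon2 else coding_pos_first
        seq[g - 1 : g + 2] = list(codon)

    edits: list[tuple[int, str]] = []  # (genomic pos, base_b)

    # Exon 1: codon 9 nonsynonymous (AGA->ACA), three synonymous CTx sites
    set_codon(25, "AGA", exon2=False)
    edits.append((26, "C"))
    for codon_i in (20, 40, 55):
        first = 3 * codon_i - 2
        set_codon(first, "CTA", exon2=False)
        edits.append((first + 2, "G"))

    # Intron: 21 unconstrained differences
    for g in range(185, 290, 5):  # 185, 190, ..., 285
        edits.append((g, _TRANSITION["".join(seq[g - 1])]))

    # Exon 2 synonymous third-position sites before 578 and after 1061
    for codon_i in (70, 80, 90, 110, 120, 130, 140, 150, 330, 340, 350, 360, 370):
        first = 3 * codon_i - 2
        set_codon(first, "CTA", exon2=True)
        edits.append((first + 2 + 125, "G"))
    # codon 100 nonsynonymous (GAA->GCA), genomic 424
    set_codon(298, "GAA", exon2=True)
    edits.append((424, "C"))
    # site 578 = third base of codon 151, synonymous
    set_codon(451, "CTA", exon2=True)
    edits.append((578, "G"))
    # site 719 = Phe codon 198 third base, TTC->TTT
    set_codon(592, "TTC", exon2=True)
    edits.append((719, "T"))
    # site 1061 = third base of codon 312, synonymous
    set_codon(934, "CTA", exon2=True)
    edits.append((1061, "G"))
    # last residue Val->Leu (GTG->TTG, first base, genomic 1290)
    set_codon(1165, "GTG", exon2=True)
    edits.append((1290, "T"))
    # stop codon difference TAA->TGA (second base, genomic 1294)
    set_codon(1168, "TAA", exon2=True)
    edits.append((1294, "G"))

    seq_a = "".join(seq)
    b = seq.copy()
    for g, base in edits:
        if seq_a[g - 1] == base:  # pragma: no cover - layout guarantees a change
            raise AssertionError(f"planted edit at {g} does not change the base")
        b[g - 1] = base
    seq_b = "".join(b)
    regions = [("Exon1", 1, 180), ("Intron", 181, 305), ("Exon2", 306, 1295)]
    return seq_a, seq_b, regions


def extract_cds(gene_seq: str, regions: Sequence[tuple[str, int, int]]) -> str:
    """Concatenate the exon intervals (labels not starting with 'Intron')."""
    return "".join(
        gene_seq[s - 1 : e]
        for lab, s, e in regions
        if not lab.lower().startswith("intron")
    )
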