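"""Synthetic multi-strain study generator with planted truth for every stage.

The generator emulates the data regime of an unmapped-read triage study:

* an *alternative* assembly (the ancestor genome) and a *primary* reference
  derived from it by excising reference-gap blocks (sequence the primary
  assembly is missing) and strain-divergent blocks (sequence private to the
  second strain behind the alternative assembly), with a coverage annotation
  marking the alternative minus the strain-divergent blocks;
* a phylogeny of strains whose genomes accumulate substitutions along
  branches and acquire novel inserted segments — on internal branches
  (inherited by the whole clade, hence *shared*) or terminal branches
  (*strain-specific*);
* Y contigs (with an optional pseudoautosomal block copied from the
  alternative assembly) and contaminant genomes with a genus taxonomy;
* paired-end reads of the *unmapped* set: fragments wholly inside
  primary-shared sequence are resampled away (they would have mapped), and
  the emitted mix contains quality artifacts, adapter read-through pairs,
  contaminant pairs, Y pairs for male strains, and half-mapped pairs
  straddling a planted deletion breakpoint.

Every emitted pair carries a truth row, including the origin category the
classification stage should assign, derived from geometry at generation time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import _kmers, formats
from .classify import ReferenceSet
from .formats import (
    Anchor,
    Interval,
    ReadPair,
    SequenceRecord,
    TaxonomyRow,
)

_GENERA = (
    ("Escherichia", "Bacteria"),
    ("Staphylococcus", "Bacteria"),
    ("Pseudomonas", "Bacteria"),
    ("Lactobacillus", "Bacteria"),
    ("Sinsheimervirus", "Viruses"),
    ("Saccharomyces", "Fungi"),
    ("Candida", "Fungi"),
    ("Bacillus", "Bacteria"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated experiment.

    Fractions are of emitted read pairs unless stated otherwise. ``n_pairs``
    is the number of unmapped pairs emitted per strain (the pipeline's input
    unit); coverage of the underlying genome follows from it.
    """

    seed: int = 0
    n_strains: int = 8
    genome_length: int = 500_000
    gap_fraction: float = 0.08           # of the alternative missing from primary
    sd_specific_fraction: float = 0.04   # of the alternative not covered by primary-strain data
    n_gap_blocks: int = 10
    n_sd_blocks: int = 8
    n_y_contigs: int = 3
    y_contig_length: int = 10_000
    y_par_fraction: float = 0.2          # of the first Y contig copied from the alternative
    n_contaminant_genomes: int = 6
    contaminant_length: int = 25_000
    substitution_rate: float = 3e-4      # per base per unit branch length
    shared_insert_rate: float = 8.0      # expected inserts per internal branch
    strain_insert_rate: float = 3.0      # expected inserts per terminal branch
    insert_length_range: tuple[int, int] = (600, 2500)
    copy_inserts_from_reference: bool = False  # homology stress mode
    read_length: int = 100
    fragment_mean: float = 500.0
    fragment_sd: float = 60.0
    n_pairs: int = 20_000
    error_rate: float = 0.0
    low_quality_read_fraction: float = 0.40
    adapter_readthrough_fraction: float = 0.05
    contaminant_read_fraction: float = 0.03
    variation_pair_fraction: float = 0.05
    y_read_fraction: float = 0.08        # male strains only
    male_strains: tuple[str, ...] = ("strain_1", "strain_4")

    def __post_init__(self) -> None:
        fracs = dict(
            gap_fraction=self.gap_fraction,
            sd_specific_fraction=self.sd_specific_fraction,
            error_rate=self.error_rate,
            low_quality_read_fraction=self.low_quality_read_fraction,
            adapter_readthrough_fraction=self.adapter_readthrough_fraction,
            contaminant_read_fraction=self.contaminant_read_fraction,
            variation_pair_fraction=self.variation_pair_fraction,
            y_read_fraction=self.y_read_fraction,
            y_par_fraction=self.y_par_fraction,
        )
        for name, value in fracs.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")
        if self.read_length >= self.fragment_mean:
            raise ValueError("read_length must be below fragment_mean")
        if self.genome_length < 10 * self.fragment_mean:
            raise ValueError("genome_length must be at least 10 x fragment_mean")
        if self.gap_fraction + self.sd_specific_fraction >= 1.0:
            raise ValueError("gap_fraction + sd_specific_fraction must be < 1")

    @property
    def insert_tolerance(self) -> float:
        """In-pair insert tolerance used throughout: 4 x fragment SD."""
        return 4.0 * self.fragment_sd


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

def simulate_phylogeny(n_strains: int, seed: int) -> dendropy.Tree:
    """A random rooted binary tree with positive branch lengths.

    The topology is a balanced random bipartition: each clade splits into two
    random halves, so every leaf sits at a similar depth — the bushy shape of
    laboratory-strain phylogenies, where many substrains radiate from a few
    founder stocks. Leaves are named strain_1..strain_n; topology and lengths
    are deterministic for a given seed.
    """
    if n_strains < 2:
        raise ValueError("n_strains must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(labels: list[str]) -> dendropy.Node:
        node = dendropy.Node()
        if len(labels) == 1:
            node.taxon = taxa.new_taxon(labels[0])
            return node
        order = rng.permutation(len(labels))
        half = len(labels) // 2
        left = [labels[i] for i in order[:half]]
        right = [labels[i] for i in order[half:]]
        for part in (left, right):
            child = build(part)
            node.add_child(child)
            child.edge.length = float(rng.exponential(1.0)) + 0.05
        return node

    tree.seed_node = build([f"strain_{i + 1}" for i in range(n_strains)])
    tree.seed_node.edge.length = None
    return tree


# ---------------------------------------------------------------------------
# References
# ---------------------------------------------------------------------------

@dataclass
class ReferenceBundle:
    """References plus the planted geometry downstream truth is derived from."""

    refs: ReferenceSet
    ancestor: np.ndarray                  # 2-bit codes of the alternative assembly
    gap_blocks: list[tuple[int, int]]     # alt coords excised from the primary
    sd_blocks: list[tuple[int, int]]      # alt coords uncovered by primary-strain data
    par_alt: Optional[tuple[int, int]]    # alt source interval of the Y PAR block
    par_y: Optional[tuple[str, int, int]]  # (y contig id, start, end)

    @property
    def excised_blocks(self) -> list[tuple[int, int]]:
        return sorted(self.gap_blocks + self.sd_blocks)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int64)


def _place_blocks(
    rng: np.random.Generator,
    genome_length: int,
    lengths: Sequence[int],
    margin: int,
) -> list[tuple[int, int]]:
    """Non-overlapping blocks with at least ``margin`` bp between/around them."""
    n = len(lengths)
    if n == 0:
        return []
    total = sum(lengths) + (n + 1) * margin
    free = genome_length - total
    if free < 0:
        raise ValueError("genome too short for the requested blocks")
    cuts = np.sort(rng.integers(0, free + 1, size=n))
    blocks = []
    pos = margin
    prev_cut = 0
    for length, cut in zip(lengths, cuts):
        pos += int(cut - prev_cut)
        prev_cut = int(cut)
        blocks.append((pos, pos + length))
        pos += length + margin
    return blocks


def _split_lengths(total: int, n_blocks: int, min_block: int = 600) -> list[int]:
    if total <= 0:
        return []
    n = max(1, min(n_blocks, total // max(min_block, 1)))
    base = total // n
    lengths = [base] * n
    lengths[-1] += total - base * n
    return lengths


def simulate_references(config: SimulationConfig) -> ReferenceBundle:
    """Build the reference side of a study from one config.

    The alternative assembly is the ancestor genome; the primary reference is
    the alternative minus the gap and strain-divergent blocks; the coverage
    annotation is the alternative minus the strain-divergent blocks. Y contigs
    and contaminant genomes are independent random sequences, except for an
    optional PAR block copied from the alternative into the first Y contig.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    G = config.genome_length
    ancestor = _random_seq(rng, G)

    margin = int(3 * config.fragment_mean)
    gap_lengths = _split_lengths(int(config.gap_fraction * G), config.n_gap_blocks)
    sd_lengths = _split_lengths(
        int(config.sd_specific_fraction * G), config.n_sd_blocks
    )
    # interleave gap and sd blocks randomly while keeping each kind's lengths
    labeled = [(l, "gap") for l in gap_lengths] + [(l, "sd") for l in sd_lengths]
    order = rng.permutation(len(labeled))
    labeled = [labeled[i] for i in order]
    all_blocks = _place_blocks(rng, G, [l for l, _ in labeled], margin)
    gap_blocks = sorted(b for b, (_, kind) in zip(all_blocks, labeled) if kind == "gap")
    sd_blocks = sorted(b for b, (_, kind) in zip(all_blocks, labeled) if kind == "sd")

    excised = sorted(gap_blocks + sd_blocks)
    keep = np.ones(G, dtype=bool)
    for s, e in excised:
        keep[s:e] = False
    primary = ancestor[keep]

    coverage = []
    pos = 0
    for s, e in sorted(sd_blocks):
        if s > pos:
            coverage.append(Interval("alt_1", pos, s))
        pos = e
    if pos < G:
        coverage.append(Interval("alt_1", pos, G))

    # Y contigs, optionally with a PAR block copied from covered shared sequence
    y_contigs = []
    par_alt = par_y = None
    par_len = int(config.y_par_fraction * config.y_contig_length)
    for i in range(config.n_y_contigs):
        codes = _random_seq(rng, config.y_contig_length)
        if i == 0 and par_len >= 2 * config.read_length:
            src = _pick_clear_interval(rng, G, excised, par_len, margin=200)
            codes[:par_len] = ancestor[src : src + par_len]
            par_alt = (src, src + par_len)
            par_y = ("y_1", 0, par_len)
        y_contigs.append(SequenceRecord(f"y_{i + 1}", _kmers.decode(codes)))

    contaminants = []
    taxonomy = []
    for i in range(config.n_contaminant_genomes):
        genus, kingdom = _GENERA[i % len(_GENERA)]
        cid = f"contam_{i + 1}"
        contaminants.append(
            SequenceRecord(cid, _kmers.decode(_random_seq(rng, config.contaminant_length)))
        )
        taxonomy.append(TaxonomyRow(cid, kingdom, genus))

    refs = ReferenceSet(
        primary=[SequenceRecord("primary_1", _kmers.decode(primary))],
        alternative=[SequenceRecord("alt_1", _kmers.decode(ancestor))],
        y_contigs=y_contigs,
        contaminant=contaminants,
        coverage=coverage,
        taxonomy=taxonomy,
    )
    return ReferenceBundle(refs, ancestor, list(gap_blocks), list(sd_blocks), par_alt, par_y)


def _pick_clear_interval(
    rng: np.random.Generator,
    genome_length: int,
    blocks: Sequence[tuple[int, int]],
    length: int,
    margin: int,
) -> int:
    """Random start of an interval clear of all blocks (plus margin)."""
    for _ in range(10_000):
        s = int(rng.integers(margin, genome_length - length - margin))
        if not _overlaps_any(blocks, s - margin, s + length + margin):
            return s
    raise RuntimeError("could not place a clear interval")


def _overlaps_any(blocks: Sequence[tuple[int, int]], start: int, end: int) -> bool:
    for s, e in blocks:
        if s < end and e > start:
            return True
    return False


# ---------------------------------------------------------------------------
# Strain genomes
# ---------------------------------------------------------------------------

@dataclass
class InsertRecord:
    insert_id: int
    kind: str                      # novel_shared | novel_strain_specific
    length: int
    strains: list[str]             # hosting leaves
    # per-strain coordinates, filled after leaf genomes are final
    coords: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass
class StrainGenome:
    name: str
    index: int                      # 0-based leaf index (seed derivation)
    codes: np.ndarray               # 2-bit codes
    alt_pos: np.ndarray             # per-base alternative coordinate, -1 inside inserts
    insert_id: np.ndarray           # per-base insert id, -1 outside inserts
    male: bool

    def __len__(self) -> int:
        return len(self.codes)


def simulate_strain_genomes(
    tree: dendropy.Tree,
    references: ReferenceBundle,
    config: SimulationConfig,
) -> tuple[dict[str, StrainGenome], dict[int, InsertRecord]]:
    """Evolve strain genomes down the tree from the ancestor genome.

    Substitutions accumulate per branch at ``substitution_rate x branch
    length`` per base. Inserted segments (novel random sequence by default)
    arise as Poisson events on each branch: internal-branch inserts are
    inherited by the whole descendant clade, terminal-branch inserts by one
    leaf. The registry records every insert's hosting strains and coordinates.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    registry: dict[int, InsertRecord] = {}
    next_id = [0]
    G = len(references.ancestor)

    root_state = (
        references.ancestor.copy(),
        np.arange(G, dtype=np.int64),
        np.full(G, -1, dtype=np.int64),
    )

    def evolve(state, edge_length, is_terminal):
        codes, alt_pos, ins_id = (a.copy() for a in state)
        # substitutions
        p = config.substitution_rate * edge_length
        if p > 0:
            n_sub = rng.binomial(len(codes), min(p, 1.0))
            if n_sub:
                pos = rng.choice(len(codes), size=n_sub, replace=False)
                shift = rng.integers(1, 4, size=n_sub)
                codes[pos] = (codes[pos] + shift) % 4
        # inserted segments
        rate = config.strain_insert_rate if is_terminal else config.shared_insert_rate
        n_ins = rng.poisson(rate)
        for _ in range(n_ins):
            lo, hi = config.insert_length_range
            length = int(rng.integers(lo, hi + 1))
            if config.copy_inserts_from_reference:
                src = int(rng.integers(0, G - length))
                seg = references.ancestor[src : src + length].copy()
                n_mut = max(1, int(0.05 * length))
                mpos = rng.choice(length, size=n_mut, replace=False)
                seg[mpos] = (seg[mpos] + rng.integers(1, 4, size=n_mut)) % 4
            else:
                seg = _random_seq(rng, length)
            # never split an existing insert: keeps every insert contiguous in
            # every hosting genome, so registry coordinates stay exact
            for _ in range(10_000):
                at = int(rng.integers(0, len(codes) + 1))
                if (
                    at == 0
                    or at == len(codes)
                    or ins_id[at - 1] < 0
                    or ins_id[at] != ins_id[at - 1]
                ):
                    break
            else:
                raise RuntimeError("could not place insert outside existing inserts")
            iid = next_id[0]
            next_id[0] += 1
            registry[iid] = InsertRecord(
                iid,
                "novel_strain_specific" if is_terminal else "novel_shared",
                length,
                [],
            )
            codes = np.concatenate([codes[:at], seg, codes[at:]])
            alt_pos = np.concatenate(
                [alt_pos[:at], np.full(length, -1, dtype=np.int64), alt_pos[at:]]
            )
            ins_id = np.concatenate(
                [ins_id[:at], np.full(length, iid, dtype=np.int64), ins_id[at:]]
            )
        return codes, alt_pos, ins_id

    strains: dict[str, StrainGenome] = {}

    def walk(node, state):
        children = node.child_nodes()
        for child in children:
            is_leaf = child.is_leaf()
            child_state = evolve(state, child.edge.length or 0.0, is_leaf)
            if is_leaf:
                name = child.taxon.label
                codes, alt_pos, ins_id = child_state
                strains[name] = StrainGenome(
                    name,
                    len(strains),
                    codes,
                    alt_pos,
                    ins_id,
                    male=name in config.male_strains,
                )
            else:
                walk(child, child_state)

    walk(tree.seed_node, root_state)

    # leaf indexes follow strain number so seeds are stable under traversal order
    order = sorted(strains)
    for i, name in enumerate(sorted(strains, key=lambda s: int(s.split("_")[1]))):
        strains[name].index = i

    for name, sg in strains.items():
        present = np.unique(sg.insert_id[sg.insert_id >= 0])
        for iid in present.tolist():
            rec = registry[iid]
            rec.strains.append(name)
            where = np.nonzero(sg.insert_id == iid)[0]
            rec.coords[name] = (int(where[0]), int(where[-1]) + 1)
    for rec in registry.values():
        rec.strains.sort()
    return strains, registry


def truth_contigs(
    strain: StrainGenome,
    registry: dict[int, InsertRecord],
    min_length: int = 500,
) -> list[SequenceRecord]:
    """The strain's copies of its inserted segments (the assembly ground truth)."""
    out = []
    for iid, rec in sorted(registry.items()):
        if strain.name not in rec.coords:
            continue
        s, e = rec.coords[strain.name]
        if e - s < min_length:
            continue
        out.append(
            SequenceRecord(
                f"{strain.name}_ins{iid}", _kmers.decode(strain.codes[s:e])
            )
        )
    return out


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

@dataclass
class ReadSimResult:
    sample: str
    r1: list[SequenceRecord]
    r2: list[SequenceRecord]
    half_mapped: list[tuple[ReadPair, Anchor]]
    truth: pd.DataFrame

    @property
    def n_pairs(self) -> int:
        return len(self.r1) + len(self.half_mapped)


_PHRED_GOOD = (30, 41)   # half-open upper bound for rng.integers
_PHRED_BAD = (2, 21)


def _quality_string(
    rng: np.random.Generator, length: int, error_mask: Optional[np.ndarray]
) -> str:
    q = rng.integers(*_PHRED_GOOD, size=length)
    if error_mask is not None and error_mask.any():
        q[error_mask] = rng.integers(*_PHRED_BAD, size=int(error_mask.sum()))
    return "".join(chr(int(v) + 33) for v in q)


def _bad_quality_string(rng: np.random.Generator, length: int) -> str:
    q = rng.integers(*_PHRED_BAD, size=length)
    return "".join(chr(int(v) + 33) for v in q)


def _apply_errors(
    rng: np.random.Generator, codes: np.ndarray, error_rate: float
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    if error_rate <= 0:
        return codes, None
    mask = rng.random(len(codes)) < error_rate
    if mask.any():
        codes = codes.copy()
        shift = rng.integers(1, 4, size=int(mask.sum()))
        codes[mask] = (codes[mask] + shift) % 4
    return codes, mask


class _BlockIndex:
    """Sorted-array interval arithmetic over disjoint blocks (alt coords)."""

    def __init__(self, blocks: Sequence[tuple[int, int]]):
        blocks = sorted(blocks)
        self.starts = np.array([b[0] for b in blocks], dtype=np.int64)
        self.ends = np.array([b[1] for b in blocks], dtype=np.int64)

    def overlaps(self, start: int, end: int) -> bool:
        if len(self.starts) == 0:
            return False
        j = int(np.searchsorted(self.ends, start, side="right"))
        return j < len(self.starts) and self.starts[j] < end

    def contains(self, pos: int) -> bool:
        if len(self.starts) == 0:
            return False
        j = int(np.searchsorted(self.starts, pos, side="right")) - 1
        return j >= 0 and pos < self.ends[j]


def simulate_reads(
    strain: StrainGenome,
    references: ReferenceBundle,
    config: SimulationConfig,
    registry: Optional[dict[int, InsertRecord]] = None,
) -> ReadSimResult:
    """Emit the unmapped read set of one strain, with truth labels.

    Fragments are sampled uniformly over the strain genome and rejected when
    wholly inside primary-shared sequence (those reads would have mapped);
    spike-in categories (artifact, adapter read-through, contamination, Y,
    breakpoint pairs) are mixed in at the configured fractions. Mates that
    would partially straddle an insert or PAR boundary are resampled so every
    pair's origin is geometrically unambiguous. The truth table's
    ``expected_category`` column is derived from the same geometry.
    """
    if config.n_pairs <= 0:
        raise ValueError("n_pairs must be positive (coverage too low)")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 404, strain.index])
    )
    rl = config.read_length
    G = len(strain.codes)

    gap_idx = _BlockIndex(references.gap_blocks)
    sd_idx = _BlockIndex(references.sd_blocks)
    ins_present = strain.insert_id >= 0
    ins_cum = np.concatenate(([0], np.cumsum(ins_present)))
    registry = registry or {}

    # planted-deletion geometry lives on the primary reference
    primary_codes = _kmers.encode(references.refs.primary[0].sequence)
    primary_runs = _primary_safe_runs(references, min_run=2200)

    y_codes = [_kmers.encode(c.sequence) for c in references.refs.y_contigs]
    y_lengths = np.array([len(c) for c in y_codes])
    contam_codes = [_kmers.encode(c.sequence) for c in references.refs.contaminant]
    contam_ids = [c.id for c in references.refs.contaminant]

    def draw_fragment(lo: Optional[int] = None, hi: Optional[int] = None) -> int:
        mean, sd = config.fragment_mean, config.fragment_sd
        lo = max(rl, int(mean - 4 * sd) + 1) if lo is None else lo
        hi = int(mean + 4 * sd) - 1 if hi is None else hi
        while True:
            f = int(round(rng.normal(mean, sd)))
            if lo <= f <= hi:
                return f

    def fragment_reads(source: np.ndarray, start: int, frag: int):
        m1 = source[start : start + rl]
        m2 = _kmers.revcomp_codes(source[start + frag - rl : start + frag])
        return m1, m2

    r1: list[SequenceRecord] = []
    r2: list[SequenceRecord] = []
    half_mapped: list[tuple[ReadPair, Anchor]] = []
    truth_rows: list[dict] = []

    y_frac = config.y_read_fraction if strain.male else 0.0
    thresholds = np.cumsum(
        [
            config.low_quality_read_fraction,
            config.adapter_readthrough_fraction,
            config.contaminant_read_fraction,
            config.variation_pair_fraction,
            y_frac,
        ]
    )
    cat_names = ("artifact", "adapter", "contaminant", "variation", "y", "genome")

    for i in range(config.n_pairs):
        pid = f"{strain.name}_p{i:06d}"
        u = rng.random()
        cat = cat_names[int(np.searchsorted(thresholds, u, side="right"))]

        if cat == "artifact":
            frag = draw_fragment()
            start = int(rng.integers(0, G - frag + 1))
            m1, m2 = fragment_reads(strain.codes, start, frag)
            q1 = _bad_quality_string(rng, rl)
            q2 = _bad_quality_string(rng, rl)
            r1.append(SequenceRecord(f"{pid}/1", _kmers.decode(m1), q1))
            r2.append(SequenceRecord(f"{pid}/2", _kmers.decode(m2), q2))
            truth_rows.append(
                _truth(pid, "artifact", "low_qc", strain.name, strain.name, start, start + frag)
            )
            continue

        if cat == "adapter":
            frag = int(rng.integers(int(0.7 * rl), int(0.95 * rl) + 1))
            start = int(rng.integers(0, G - frag + 1))
            insert_part = strain.codes[start : start + frag]
            fill = rl - frag
            from .qc import TRUSEQ_R1, TRUSEQ_R2

            m1 = np.concatenate([insert_part, _kmers.encode(TRUSEQ_R1[:fill])])
            m2 = np.concatenate(
                [_kmers.revcomp_codes(insert_part), _kmers.encode(TRUSEQ_R2[:fill])]
            )
            m1, e1 = _apply_errors(rng, m1, config.error_rate)
            m2, e2 = _apply_errors(rng, m2, config.error_rate)
            r1.append(SequenceRecord(f"{pid}/1", _kmers.decode(m1), _quality_string(rng, rl, e1)))
            r2.append(SequenceRecord(f"{pid}/2", _kmers.decode(m2), _quality_string(rng, rl, e2)))
            origin = _genome_origin(
                strain, references, gap_idx, sd_idx, ins_cum, registry,
                start, start + frag, rl=frag, strict=False,
            )[0]
            truth_rows.append(
                _truth(pid, origin, "remaining", strain.name, strain.name,
                       start, start + frag, adapter=True)
            )
            continue

        if cat == "contaminant":
            gi = int(rng.integers(0, len(contam_codes)))
            src = contam_codes[gi]
            frag = draw_fragment(hi=min(len(src) - 1, int(config.fragment_mean + 4 * config.fragment_sd) - 1))
            start = int(rng.integers(0, len(src) - frag + 1))
            m1, m2 = fragment_reads(src, start, frag)
            _emit(rng, config, r1, r2, pid, m1, m2)
            truth_rows.append(
                _truth(pid, "contamination", "contamination", strain.name,
                       contam_ids[gi], start, start + frag)
            )
            continue

        if cat == "variation":
            pair, anchor, row = _variation_pair(
                rng, config, primary_codes, primary_runs, pid, strain.name
            )
            half_mapped.append((pair, anchor))
            truth_rows.append(row)
            continue

        if cat == "y":
            ci, start, frag = _sample_y_fragment(rng, config, y_lengths, references, rl, draw_fragment)
            src = y_codes[ci]
            m1, m2 = fragment_reads(src, start, frag)
            _emit(rng, config, r1, r2, pid, m1, m2)
            expected = "y_only"
            if references.par_y is not None and ci == 0:
                _, ps, pe = references.par_y
                if start >= ps and start + frag <= pe:
                    expected = "alt_and_y"
            truth_rows.append(
                _truth(pid, "y", expected, strain.name,
                       references.refs.y_contigs[ci].id, start, start + frag)
            )
            continue

        # genome-derived unmapped pair (rejection-sampled past primary-shared)
        for _attempt in range(100_000):
            frag = draw_fragment()
            start = int(rng.integers(0, G - frag + 1))
            origin, expected = _genome_origin(
                strain, references, gap_idx, sd_idx, ins_cum, registry,
                start, start + frag, rl=rl, strict=True,
            )
            if origin not in ("reference", None):
                break
        else:
            raise RuntimeError("could not sample a non-reference fragment")
        m1, m2 = fragment_reads(strain.codes, start, frag)
        _emit(rng, config, r1, r2, pid, m1, m2)
        truth_rows.append(
            _truth(pid, origin, expected, strain.name, strain.name, start, start + frag)
        )

    truth = pd.DataFrame(truth_rows)
    return ReadSimResult(strain.name, r1, r2, half_mapped, truth)


def _emit(rng, config, r1, r2, pid, m1, m2) -> None:
    m1, e1 = _apply_errors(rng, m1, config.error_rate)
    m2, e2 = _apply_errors(rng, m2, config.error_rate)
    r1.append(
        SequenceRecord(f"{pid}/1", _kmers.decode(m1), _quality_string(rng, len(m1), e1))
    )
    r2.append(
        SequenceRecord(f"{pid}/2", _kmers.decode(m2), _quality_string(rng, len(m2), e2))
    )


def _truth(
    pid, origin, expected, strain, seq, start, end, adapter=False, half=False
) -> dict:
    return dict(
        pair_id=pid,
        true_origin=origin,
        expected_category=expected,
        source_strain=strain,
        source_seq=seq,
        source_start=int(start),
        source_end=int(end),
        adapter=bool(adapter),
        half_mapped=bool(half),
    )


def _genome_origin(
    strain: StrainGenome,
    references: ReferenceBundle,
    gap_idx: _BlockIndex,
    sd_idx: _BlockIndex,
    ins_cum: np.ndarray,
    registry: dict[int, InsertRecord],
    start: int,
    end: int,
    rl: int,
    strict: bool,
) -> tuple[Optional[str], Optional[str]]:
    """Origin and expected category of a strain-genome fragment.

    Returns (None, None) for fragments that must be resampled (a mate
    partially straddles an insert boundary) when ``strict`` is set.
    """
    m1 = (start, min(start + rl, end))
    m2 = (max(end - rl, start), end)
    n_ins_frag = int(ins_cum[end] - ins_cum[start])
    if n_ins_frag > 0:
        iid = None
        for ms, me in (m1, m2):
            n = int(ins_cum[me] - ins_cum[ms])
            if n == 0:
                continue
            if n == me - ms and strain.insert_id[ms] == strain.insert_id[me - 1]:
                iid = int(strain.insert_id[ms])
            elif strict:
                return None, None  # partial straddle: resample
            else:
                first = strain.insert_id[ms:me]
                iid = int(first[first >= 0][0])
        if iid is None:  # insert wholly in the unsequenced inner gap
            inner = strain.insert_id[m1[1]:m2[0]]
            iid = int(inner[inner >= 0][0])
        kind = registry[iid].kind if iid in registry else "novel_strain_specific"
        return kind, "remaining"

    # purely ancestral: alt coordinates are contiguous per mate
    a_start = int(strain.alt_pos[start])
    a_end = int(strain.alt_pos[end - 1]) + 1
    overlaps = gap_idx.overlaps(a_start, a_end) or sd_idx.overlaps(a_start, a_end)
    if not overlaps:
        return "reference", None
    mid1 = int(strain.alt_pos[m1[0]]) + (m1[1] - m1[0]) // 2
    mid2 = int(strain.alt_pos[m2[0]]) + (m2[1] - m2[0]) // 2
    covered1 = not sd_idx.contains(mid1)
    covered2 = not sd_idx.contains(mid2)
    if covered1 or covered2:
        return "alt_missing_region", "alt_missing_region"
    return "alt_other", "alt_other"


def _primary_safe_runs(
    references: ReferenceBundle, min_run: int
) -> list[tuple[int, int]]:
    """Primary-coordinate runs of shared covered sequence, clear of all blocks
    and of the PAR source, long enough to host a planted breakpoint."""
    avoid = list(references.excised_blocks)
    if references.par_alt is not None:
        avoid.append(references.par_alt)
    avoid.sort()
    G = len(references.ancestor)
    runs_alt = []
    pos = 0
    for s, e in avoid:
        if s > pos:
            runs_alt.append((pos, s))
        pos = max(pos, e)
    if pos < G:
        runs_alt.append((pos, G))
    # map alt runs to primary coordinates (shift by excised bp before them)
    excised = references.excised_blocks
    ex_starts = np.array([b[0] for b in excised], dtype=np.int64)
    ex_len = np.array([b[1] - b[0] for b in excised], dtype=np.int64)
    ex_cum = np.concatenate(([0], np.cumsum(ex_len)))

    def to_primary(p: int) -> int:
        j = int(np.searchsorted(ex_starts, p, side="right"))
        return p - int(ex_cum[j])

    out = []
    pad = 60
    for s, e in runs_alt:
        s, e = s + pad, e - pad
        if e - s >= min_run:
            out.append((to_primary(s), to_primary(e)))
    if not out:
        raise RuntimeError("no primary run long enough for breakpoint pairs")
    return out


def _variation_pair(
    rng: np.random.Generator,
    config: SimulationConfig,
    primary: np.ndarray,
    runs: list[tuple[int, int]],
    pid: str,
    strain_name: str,
) -> tuple[ReadPair, Anchor, dict]:
    """A half-mapped pair straddling a planted deletion on the primary reference.

    The anchored mate maps cleanly; the other mate's two halves flank a
    deletion of 250-450 bp whose breakpoint sits at the mate's midpoint, so an
    anchored split search places both halves with a positive gap.
    """
    rl = config.read_length
    half = rl // 2
    f = int(rng.integers(2 * rl + 20, int(config.fragment_mean + 2 * config.fragment_sd)))
    d = int(rng.integers(250, 451))
    span = f + d
    weights = np.array([max(0, e - s - span) for s, e in runs], dtype=float)
    ri = int(rng.choice(len(runs), p=weights / weights.sum()))
    a = int(rng.integers(runs[ri][0], runs[ri][1] - span))

    mate1 = primary[a : a + rl]  # anchored, forward
    j = a + f - half             # breakpoint at the unmapped mate's midpoint
    left = primary[j - half : j]
    right = primary[j + d : j + d + half]
    mate2 = _kmers.revcomp_codes(np.concatenate([left, right]))

    m1, e1 = _apply_errors(rng, mate1, config.error_rate)
    m2, e2 = _apply_errors(rng, mate2, config.error_rate)
    q1 = _quality_string(rng, rl, e1)
    q2 = _quality_string(rng, rl, e2)
    pair = ReadPair(
        pid,
        SequenceRecord(f"{pid}/1", _kmers.decode(m1), q1),
        SequenceRecord(f"{pid}/2", _kmers.decode(m2), q2),
        expected_read_length=rl,
        expected_fragment=(config.fragment_mean, config.insert_tolerance),
    )
    anchor = Anchor(Interval("primary_1", a, a + rl), "+", mapped_mate=1)
    row = _truth(
        pid, "variation", "variation", strain_name, "primary_1", a, a + span, half=True
    )
    return pair, anchor, row


def _sample_y_fragment(rng, config, y_lengths, references, rl, draw_fragment):
    """Y fragment with PAR-boundary-unambiguous mates."""
    total = float(y_lengths.sum())
    for _ in range(10_000):
        ci = int(rng.choice(len(y_lengths), p=y_lengths / total))
        frag = draw_fragment(hi=min(int(y_lengths[ci]) - 1,
                                    int(config.fragment_mean + 4 * config.fragment_sd) - 1))
        start = int(rng.integers(0, y_lengths[ci] - frag + 1))
        if references.par_y is None or ci != 0:
            return ci, start, frag
        _, ps, pe = references.par_y
        ok = True
        for ms, me in ((start, start + rl), (start + frag - rl, start + frag)):
            inside = ms >= ps and me <= pe
            outside = me <= ps or ms >= pe
            if not (inside or outside):
                ok = False
                break
        if ok:
            return ci, start, frag
    raise RuntimeError("could not sample a PAR-unambiguous Y fragment")


# ---------------------------------------------------------------------------
# Whole-study driver and writers
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimulationConfig
    tree: dendropy.Tree
    references: ReferenceBundle
    strains: dict[str, StrainGenome]
    registry: dict[int, InsertRecord]
    reads: dict[str, ReadSimResult]

    @property
    def strain_names(self) -> list[str]:
        return sorted(self.strains, key=lambda s: int(s.split("_")[1]))

    def contigs(self, min_length: int = 500) -> dict[str, list[SequenceRecord]]:
        return {
            name: truth_contigs(self.strains[name], self.registry, min_length)
            for name in self.strain_names
        }


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate references, strain genomes and reads for every strain."""
    tree = simulate_phylogeny(config.n_strains, config.seed)
    bundle = simulate_references(config)
    strains, registry = simulate_strain_genomes(tree, bundle, config)
    reads = {
        name: simulate_reads(strains[name], bundle, config, registry)
        for name in sorted(strains, key=lambda s: int(s.split("_")[1]))
    }
    return SimulatedStudy(config, tree, bundle, strains, registry, reads)


def write_study(study: SimulatedStudy, outdir: str | os.PathLike) -> None:
    """Write a study in the on-disk layout the pipeline consumes.

    refs/{primary,alternative,y,contaminant}.fasta, refs/coverage.bed,
    refs/taxonomy.tsv, strains/<s>_R{1,2}.fastq, strains/<s>_halfmapped.sam,
    truth/<s>.tsv, contigs/<s>.fasta, tree.nwk.
    """
    outdir = os.fspath(outdir)
    for sub in ("refs", "strains", "truth", "contigs"):
        os.makedirs(os.path.join(outdir, sub), exist_ok=True)
    refs = study.references.refs
    formats.write_fasta(refs.primary, os.path.join(outdir, "refs", "primary.fasta"))
    formats.write_fasta(refs.alternative, os.path.join(outdir, "refs", "alternative.fasta"))
    formats.write_fasta(refs.y_contigs, os.path.join(outdir, "refs", "y.fasta"))
    formats.write_fasta(refs.contaminant, os.path.join(outdir, "refs", "contaminant.fasta"))
    formats.write_bed(refs.coverage, os.path.join(outdir, "refs", "coverage.bed"))
    formats.write_taxonomy(refs.taxonomy, os.path.join(outdir, "refs", "taxonomy.tsv"))
    formats.write_newick(study.tree, os.path.join(outdir, "tree.nwk"))
    primary_lengths = {r.id: len(r) for r in refs.primary}
    for name in study.strain_names:
        sim = study.reads[name]
        formats.write_fastq(sim.r1, os.path.join(outdir, "strains", f"{name}_R1.fastq"))
        formats.write_fastq(sim.r2, os.path.join(outdir, "strains", f"{name}_R2.fastq"))
        formats.write_half_mapped_sam(
            sim.half_mapped,
            primary_lengths,
            os.path.join(outdir, "strains", f"{name}_halfmapped.sam"),
        )
        formats.write_tsv(sim.truth, os.path.join(outdir, "truth", f"{name}.tsv"))
        formats.write_fasta(
            truth_contigs(study.strains[name], study.registry),
            os.path.join(outdir, "contigs", f"{name}.fasta"),
        )
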