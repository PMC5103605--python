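"""Synthetic data generation with recorded planted truth.

Every input the enrichment pipeline consumes can be generated here: a species
tree, multi-copy locus sequences evolved on it under Jukes-Cantor, paired
sequencing reads from sonication-sized fragments, genomes with planted
high-copy repeats, and discrete morphological matrices evolved under the Mk
model. Each generator is a pure function of its inputs and a seed, and each
returns the planted truth needed to score downstream inference exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import dendropy
import numpy as np

from ._seq import BASES, random_seq, revcomp


@dataclass
class SimulationConfig:
    """Knobs for the sequence-level simulators.

    Defaults mirror the study conditions: PE150 reads from ~175-300 bp
    sonication fragments.  ``substitution_rate`` scales branch lengths into
    expected substitutions per site.
    """

    seed: int = 0
    n_taxa: int = 20
    locus_length: int = 1000
    substitution_rate: float = 0.05
    duplication_spec: list[tuple[str, float]] = field(default_factory=list)
    coverage: float = 50.0
    read_length: int = 150
    fragment_range: tuple[int, int] = (175, 300)
    error_rate: float = 0.0
    repeat_spec: tuple[int, int] = (30, 0)  # (motif length, copy number)

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if self.locus_length < 1:
            raise ValueError("locus_length must be >= 1")
        if self.substitution_rate < 0:
            raise ValueError("substitution_rate must be >= 0")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        lo, hi = self.fragment_range
        if lo > hi or lo < 1:
            raise ValueError("fragment_range must satisfy 1 <= min <= max")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be a probability")


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded alongside generated data."""

    species_tree: str | None = None  # newick
    gene_trees: dict[str, str] = field(default_factory=dict)
    ortholog_assignment: dict[str, tuple[str, int]] = field(default_factory=dict)
    repeat_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    misaligned_segments: dict[str, tuple[int, int]] = field(default_factory=dict)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1, sort_keys=True)


def simulate_species_tree(n_taxa: int, seed: int) -> dendropy.Tree:
    """Random binary rooted ultrametric tree with ``n_taxa`` leaves.

    Built by coalescent-style random pairwise joins with exponential waiting
    times, so all branch lengths are positive.  Deterministic given ``seed``.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    rng = np.random.default_rng(seed)
    ns = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_taxa)])
    nodes = []
    for tax in ns:
        node = dendropy.Node(taxon=tax)
        node.age = 0.0
        nodes.append(node)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0)) if k > 1 else 0.0
        t += 0.01  # keep internal branches bounded away from zero
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = dendropy.Node()
        parent.age = t
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = parent.age - child.age
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    # stable internal labels so duplication events can reference nodes
    for idx, node in enumerate(tree.preorder_node_iter()):
        if node.taxon is None:
            node.label = f"n{idx}"
    return tree


def _jc_mutate(seq: np.ndarray, distance: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor: each site substitutes with p = 3/4 (1 - exp(-4d/3))."""
    if distance <= 0:
        return seq.copy()
    p = 0.75 * (1.0 - np.exp(-4.0 * distance / 3.0))
    out = seq.copy()
    hit = rng.random(seq.size) < p
    n_hit = int(hit.sum())
    if n_hit:
        # substitute to one of the three other bases, uniformly
        out[hit] = (out[hit] + rng.integers(1, 4, size=n_hit)) % 4
    return out


def _seq_to_str(arr: np.ndarray) -> str:
    return "".join(BASES[i] for i in arr)


def evolve_locus(
    tree: dendropy.Tree,
    config: SimulationConfig,
    locus_id: str = "locus",
    seed: int | None = None,
) -> tuple[dict[str, dict[int, str]], SyntheticTruth]:
    """Evolve a locus down ``tree`` under Jukes-Cantor, with optional duplications.

    ``config.duplication_spec`` lists ``(node_label, extra_divergence)`` events:
    at each named node (leaf taxon label or internal ``n<i>`` label) the current
    copies duplicate, and the new copy accrues ``extra_divergence`` expected
    substitutions per site before continuing to evolve down the subtree.

    Returns ``{taxon: {copy_index: sequence}}`` plus a :class:`SyntheticTruth`
    whose ``ortholog_assignment`` maps ``"{locus}|{taxon}|c{copy}"`` to
    ``(locus_id, copy_index)``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    labels = {n.taxon.label if n.taxon else n.label for n in tree}
    dup_by_node: dict[str, list[float]] = {}
    for node_label, extra in config.duplication_spec:
        if node_label not in labels:
            raise ValueError(f"duplication references unknown node {node_label!r}")
        dup_by_node.setdefault(node_label, []).append(float(extra))

    root_seq = rng.integers(0, 4, size=config.locus_length)
    rate = config.substitution_rate
    out: dict[str, dict[int, str]] = {}
    truth = SyntheticTruth(species_tree=tree.as_string(schema="newick").strip())
    n_copies = 0

    def descend(node: dendropy.Node, copies: list[tuple[int, np.ndarray]]) -> None:
        nonlocal n_copies
        label = node.taxon.label if node.taxon else node.label
        if node is not tree.seed_node and node.edge.length:
            d = rate * node.edge.length
            copies = [(cid, _jc_mutate(s, d, rng)) for cid, s in copies]
        for extra in dup_by_node.get(label, []):
            new = []
            for cid, s in copies:
                n_copies += 1
                new.append((n_copies, _jc_mutate(s, extra, rng)))
            copies = copies + new
        if node.is_leaf():
            taxon = node.taxon.label
            out[taxon] = {cid: _seq_to_str(s) for cid, s in copies}
            for cid in out[taxon]:
                truth.ortholog_assignment[f"{locus_id}|{taxon}|c{cid}"] = (locus_id, cid)
        else:
            for child in node.child_nodes():
                descend(child, copies)

    descend(tree.seed_node, [(0, root_seq)])
    return out, truth


@dataclass
class ReadPair:
    """One sequenced fragment: forward mate, reverse-complemented mate."""

    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError("sequence and quality lengths differ")


_Q40 = chr(40 + 33)
_Q10 = chr(10 + 33)


def _read_with_errors(
    template: str, error_rate: float, rng: np.random.Generator
) -> tuple[str, str]:
    """Apply per-base errors; error bases get Q10, clean bases Q40."""
    if error_rate <= 0:
        return template, _Q40 * len(template)
    seq = list(template)
    qual = [_Q40] * len(template)
    for i in range(len(seq)):
        if rng.random() < error_rate:
            seq[i] = BASES[(BASES.index(seq[i]) + int(rng.integers(1, 4))) % 4]
            qual[i] = _Q10
    return "".join(seq), "".join(qual)


def simulate_reads(
    sequence: str,
    config: SimulationConfig,
    read_prefix: str = "frag",
    seed: int | None = None,
) -> list[ReadPair]:
    """Paired reads from uniform fragments of ``sequence``.

    Fragment lengths are uniform over ``config.fragment_range``; each fragment
    yields a forward ``read_length`` prefix and the reverse complement of its
    ``read_length`` suffix.  The number of pairs targets ``coverage`` mean
    depth: ``round(coverage * len(sequence) / (2 * read_length))``.
    """
    lo, hi = config.fragment_range
    if len(sequence) < hi:
        raise ValueError(
            f"sequence length {len(sequence)} shorter than max fragment {hi}"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_pairs = int(round(config.coverage * len(sequence) / (2.0 * config.read_length)))
    pairs = []
    for i in range(n_pairs):
        flen = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(sequence) - flen + 1))
        frag = sequence[start : start + flen]
        r1 = frag[: config.read_length]
        r2 = revcomp(frag[-config.read_length :])
        s1, q1 = _read_with_errors(r1, config.error_rate, rng)
        s2, q2 = _read_with_errors(r2, config.error_rate, rng)
        pairs.append(ReadPair(f"{read_prefix}:{i}", s1, q1, s2, q2))
    return pairs


def plant_repeat(
    genome: str, motif: str, copies: int, seed: int
) -> tuple[str, list[tuple[int, int]]]:
    """Insert ``copies`` copies of ``motif`` at random positions.

    Returns the expanded genome and the 0-based half-open intervals of each
    inserted copy in the *returned* genome's coordinates.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if copies < 0:
        raise ValueError("copies must be >= 0")
    rng = np.random.default_rng(seed)
    positions = sorted(int(p) for p in rng.integers(0, len(genome) + 1, size=copies))
    out = []
    intervals = []
    prev = 0
    offset = 0
    for p in positions:
        out.append(genome[prev:p])
        intervals.append((p + offset, p + offset + len(motif)))
        out.append(motif)
        offset += len(motif)
        prev = p
    out.append(genome[prev:])
    return "".join(out), intervals


@dataclass
class MorphMatrix:
    """Taxa-by-character discrete state matrix; '?' encodes missing.

    Characters are numbered from 1 in all reports, matching the convention of
    systematics software.
    """

    taxa: list[str]
    states: np.ndarray  # int matrix, -1 = missing
    n_states: int = 0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if self.states.ndim != 2 or self.states.shape[0] != len(self.taxa):
            raise ValueError("states must be (n_taxa, n_chars)")
        if self.states.shape[1] < 1:
            raise ValueError("need >= 1 character")
        if self.n_states == 0:
            self.n_states = int(self.states.max()) + 1

    @property
    def n_chars(self) -> int:
        return self.states.shape[1]

    def to_nexus(self) -> str:
        symbols = "".join(str(i) for i in range(self.n_states))
        rows = []
        width = max(len(t) for t in self.taxa) + 2
        for i, t in enumerate(self.taxa):
            cells = "".join(
                "?" if s < 0 else str(s) for s in self.states[i]
            )
            rows.append(f"    {t:<{width}}{cells}")
        body = "\n".join(rows)
        return (
            "#NEXUS\n"
            "BEGIN DATA;\n"
            f"  DIMENSIONS NTAX={len(self.taxa)} NCHAR={self.n_chars};\n"
            f"  FORMAT DATATYPE=STANDARD SYMBOLS=\"{symbols}\" MISSING=?;\n"
            "  MATRIX\n"
            f"{body}\n"
            "  ;\n"
            "END;\n"
        )


def simulate_morph_matrix(
    tree: dendropy.Tree,
    n_chars: int,
    rate: float,
    seed: int,
    n_states: int = 2,
) -> MorphMatrix:
    """Evolve unordered discrete characters on ``tree`` under the Mk model.

    The Mk process leaves each state at total rate ``rate`` and moves to the
    other ``k - 1`` states uniformly; over a branch of length ``t`` the chance
    of observing a different state is ``(k-1)/k * (1 - exp(-k*rate*t/(k-1)))``.
    """
    if n_chars < 1:
        raise ValueError("n_chars must be >= 1")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if n_states < 2:
        raise ValueError("need >= 2 states")
    rng = np.random.default_rng(seed)
    k = n_states

    def p_change(t: float) -> float:
        return (k - 1) / k * (1.0 - np.exp(-k * rate * t / (k - 1)))

    states: dict[int, np.ndarray] = {}
    taxa = []
    rows = []
    root_states = rng.integers(0, k, size=n_chars)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            cur = root_states
        else:
            parent = states[id(node.parent_node)]
            t = node.edge.length or 0.0
            cur = parent.copy()
            hit = rng.random(n_chars) < p_change(t)
            n_hit = int(hit.sum())
            if n_hit:
                cur[hit] = (cur[hit] + rng.integers(1, k, size=n_hit)) % k
        states[id(node)] = cur
        if node.is_leaf():
            taxa.append(node.taxon.label)
            rows.append(cur)
    return MorphMatrix(taxa=taxa, states=np.vstack(rows), n_states=k)


def inject_shuffled_segment(
    aligned_seq: str, start: int, length: int, seed: int
) -> tuple[str, tuple[int, int]]:
    """Replace ``length`` columns of one aligned row with a shuffled copy.

    Emulates a grossly misaligned segment for masking tests; returns the
    modified row and the planted (start, end) half-open interval.
    """
    if start < 0 or start + length > len(aligned_seq):
        raise ValueError("segment outside sequence")
    rng = np.random.default_rng(seed)
    seg = list(aligned_seq[start : start + length])
    # re-draw rather than permute so short segments are reliably disrupted
    seg = [BASES[i] for i in rng.integers(0, 4, size=length)]
    return aligned_seq[:start] + "".join(seg) + aligned_seq[start + length :], (
        start,
        start + length,
    )
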