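"""Domain types and I/O for RNA alignments, trees, secondary structures and result tables.

Conventions
-----------
* RNA alphabet ``A, C, G, U`` (indices 0-3); ``-`` and ``N`` are missing data.
* Site coordinates are 1-based in every report and file; internal numpy
  indexing is 0-based and never leaks into output.
* Secondary structure files hold one dot-bracket line, optionally followed by
  ``REGION <start> <end> <label>`` lines (1-based, inclusive) assigning helix
  (I-V), loop (A-E) or ``bulge`` labels to site ranges.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("rnacoevo")

ALPHABET = "ACGU"
GAP_CODE = -1
_CHAR2CODE = {c: i for i, c in enumerate(ALPHABET)}
_CHAR2CODE.update({"-": GAP_CODE, "N": GAP_CODE, ".": GAP_CODE})

#: canonical Watson-Crick dinucleotides (site i, site j), wobble excluded
WATSON_CRICK = frozenset({"AU", "UA", "GC", "CG"})
WOBBLE = frozenset({"GU", "UG"})


class RnacoevoError(Exception):
    """Base class for all package errors."""


class AlignmentShapeError(RnacoevoError):
    pass


class AlphabetError(RnacoevoError):
    pass


class TreeParseError(RnacoevoError):
    pass


class BindingError(RnacoevoError):
    pass


class StructureParseError(RnacoevoError):
    pass


class AnnotationError(RnacoevoError):
    pass


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def encode_sequence(seq: str) -> np.ndarray:
    """Encode an RNA string into int8 codes (gap/N -> -1); DNA T is accepted."""
    s = seq.upper().replace("T", "U")
    out = np.empty(len(s), dtype=np.int8)
    for k, ch in enumerate(s):
        try:
            out[k] = _CHAR2CODE[ch]
        except KeyError:
            raise AlphabetError(f"illegal character {ch!r} at position {k + 1}")
    return out


def decode_sequence(codes: np.ndarray) -> str:
    return "".join("-" if c < 0 else ALPHABET[c] for c in codes)


@dataclass
class RnaAlignment:
    """A gapped RNA multiple sequence alignment.

    ``codes`` has shape (n_taxa, n_sites); rows follow ``names`` order.
    """

    names: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise AlignmentShapeError("alignment matrix must be 2-D")
        if len(self.names) != self.codes.shape[0]:
            raise AlignmentShapeError("names/rows mismatch")
        if len(set(self.names)) != len(self.names):
            dup = sorted({n for n in self.names if self.names.count(n) > 1})
            raise AlignmentShapeError(f"duplicate taxon names: {dup}")

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def sequence(self, name: str) -> str:
        return decode_sequence(self.codes[self.names.index(name)])

    def column(self, site: int) -> np.ndarray:
        """0-based column accessor."""
        return self.codes[:, site]

    def gap_fraction(self) -> np.ndarray:
        return (self.codes < 0).mean(axis=0)

    def ungapped_sites(self, max_gap_fraction: float = 0.5) -> np.ndarray:
        """0-based indices of sites retained for coevolution statistics.

        Columns where more than ``max_gap_fraction`` of taxa carry a gap are
        discarded, mirroring the removal of ambiguously aligned sites.
        """
        return np.flatnonzero(self.gap_fraction() <= max_gap_fraction)

    @classmethod
    def from_sequences(cls, names: list[str], seqs: list[str]) -> "RnaAlignment":
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise AlignmentShapeError(f"ragged sequence lengths: {sorted(lengths)}")
        if not seqs:
            raise AlignmentShapeError("empty alignment")
        rows = []
        for name, s in zip(names, seqs):
            try:
                rows.append(encode_sequence(s))
            except AlphabetError as exc:
                raise AlphabetError(f"taxon {name!r}: {exc}") from None
        return cls(list(names), np.vstack(rows))


def read_alignment(path, fmt: str = "fasta") -> RnaAlignment:
    """Read a FASTA alignment, normalising T->U and case."""
    if fmt != "fasta":
        raise ValueError(f"unsupported alignment format: {fmt}")
    names: list[str] = []
    seqs: list[str] = []
    with open(path) as fh:
        cur: list[str] | None = None
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                names.append(line[1:].split()[0])
                cur = []
                seqs.append(cur)  # type: ignore[arg-type]
            else:
                if cur is None:
                    raise AlignmentShapeError("sequence data before first FASTA header")
                cur.append(line)
    if not names:
        raise AlignmentShapeError(f"no FASTA records in {path}")
    return RnaAlignment.from_sequences(names, ["".join(s) for s in seqs])


def write_alignment(aln: RnaAlignment, path) -> None:
    with open(path, "w") as fh:
        for i, name in enumerate(aln.names):
            fh.write(f">{name}\n{decode_sequence(aln.codes[i])}\n")


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """A rooted phylogeny stored as flat arrays for fast traversal.

    Node 0..n_nodes-1; ``parent[root] == -1``; ``lengths`` are expected
    substitutions/site on the edge above each node (0 for the root).
    """

    parent: np.ndarray
    lengths: np.ndarray
    labels: list[str | None]
    root: int

    children: list[list[int]] = field(init=False)
    postorder: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=float)
        n = self.parent.size
        if not np.all(np.isfinite(self.lengths)) or np.any(self.lengths < 0):
            raise TreeParseError("branch lengths must be finite and non-negative")
        if (self.parent < 0).sum() != 1 or self.parent[self.root] != -1:
            raise TreeParseError("tree must have exactly one root")
        self.children = [[] for _ in range(n)]
        for v in range(n):
            p = self.parent[v]
            if p >= 0:
                self.children[p].append(v)
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        self.postorder = np.array(order[::-1], dtype=np.int64)
        self._preorder = np.array(order, dtype=np.int64)
        # Euler intervals for O(1) ancestry tests
        tin = np.zeros(n, dtype=np.int64)
        tout = np.zeros(n, dtype=np.int64)
        t = 0
        stack2: list[tuple[int, bool]] = [(self.root, False)]
        while stack2:
            v, done = stack2.pop()
            if done:
                tout[v] = t
                t += 1
            else:
                tin[v] = t
                t += 1
                stack2.append((v, True))
                stack2.extend((c, False) for c in self.children[v])
        self._tin, self._tout = tin, tout
        self._lca_matrix: np.ndarray | None = None
        depth = np.zeros(n, dtype=np.int64)
        for v in self._preorder:
            if self.parent[v] >= 0:
                depth[v] = depth[self.parent[v]] + 1
        self.depth = depth

    # -- basic structure -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def preorder(self) -> np.ndarray:
        return self._preorder

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    @property
    def leaves(self) -> np.ndarray:
        return np.array([v for v in range(self.n_nodes) if not self.children[v]])

    @property
    def internal_nodes(self) -> np.ndarray:
        return np.array([v for v in range(self.n_nodes) if self.children[v]])

    def leaf_labels(self) -> list[str]:
        return [self.labels[v] or f"leaf{v}" for v in self.leaves]

    def is_ancestor(self, a: int, b: int) -> bool:
        """True when ``a`` is an ancestor of ``b`` (strictly or equal)."""
        return bool(self._tin[a] <= self._tin[b] and self._tout[b] <= self._tout[a])

    def lca(self, a: int, b: int) -> int:
        while not self.is_ancestor(a, b):
            a = self.parent[a]
        return a

    def lca_matrix(self) -> np.ndarray:
        """Dense (n, n) lowest-common-ancestor table, cached.

        Built in O(n^2) from contiguous preorder subtree slices.
        """
        if self._lca_matrix is not None:
            return self._lca_matrix
        n = self.n_nodes
        pos = np.empty(n, dtype=np.int64)
        pos[self._preorder] = np.arange(n)
        size = np.ones(n, dtype=np.int64)
        for v in self.postorder:
            p = self.parent[v]
            if p >= 0:
                size[p] += size[v]
        M = np.empty((n, n), dtype=np.int64)
        for w in self._preorder:
            a = pos[w]
            sl = slice(a, a + size[w])
            M[a, sl] = w
            M[sl, a] = w
            kids = self.children[w]
            for x in range(len(kids)):
                sx = slice(pos[kids[x]], pos[kids[x]] + size[kids[x]])
                for y in range(x + 1, len(kids)):
                    sy = slice(pos[kids[y]], pos[kids[y]] + size[kids[y]])
                    M[sx, sy] = w
                    M[sy, sx] = w
        self._lca_matrix = M[np.ix_(pos, pos)]
        return self._lca_matrix

    def path_nodes(self, a: int, b: int) -> list[int]:
        """Nodes on the tree path from a to b, inclusive."""
        m = self.lca(a, b)
        left = []
        v = a
        while v != m:
            left.append(v)
            v = self.parent[v]
        right = []
        v = b
        while v != m:
            right.append(v)
            v = self.parent[v]
        return left + [m] + right[::-1]

    def total_length(self) -> float:
        return float(self.lengths.sum())

    def node_depths(self) -> np.ndarray:
        """Root-to-node path length in expected substitutions/site."""
        d = np.zeros(self.n_nodes)
        for v in self._preorder:
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.lengths[v]
        return d

    # -- alignment binding ----------------------------------------------
    def bind(self, aln: RnaAlignment) -> np.ndarray:
        """Map each leaf node to its alignment row; raise if a label is missing."""
        row = {name: i for i, name in enumerate(aln.names)}
        out = np.full(self.n_nodes, -1, dtype=np.int64)
        for v in self.leaves:
            lab = self.labels[v]
            if lab not in row:
                raise BindingError(f"leaf {lab!r} absent from alignment")
            out[v] = row[lab]
        return out

    # -- construction ----------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree) -> "PhyloTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n)
        labels: list[str | None] = [None] * n
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise TreeParseError("missing branch length on a non-root edge")
                lengths[i] = float(nd.edge.length)
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label:
                labels[i] = nd.label
        root = int(np.flatnonzero(parent < 0)[0])
        tree = cls(parent, lengths, labels, root)
        if len(tree.children[root]) > 2:
            logger.warning(
                "tree root is multifurcating (%d children); treating it as the root "
                "for LCA classification", len(tree.children[root]),
            )
        return tree

    def to_newick(self) -> str:
        def fmt(v: int) -> str:
            lab = self.labels[v] or ""
            lab = lab.replace(" ", "_")
            if self.is_leaf(v):
                core = lab
            else:
                core = "(" + ",".join(fmt(c) for c in self.children[v]) + ")" + lab
            if v == self.root:
                return core
            return f"{core}:{self.lengths[v]:.10g}"

        return fmt(self.root) + ";"


def read_tree(path) -> PhyloTree:
    """Read a rooted Newick tree (branch lengths required on non-root edges)."""
    import dendropy

    try:
        dtree = dendropy.Tree.get(path=str(path), schema="newick",
                                  suppress_internal_node_taxa=False,
                                  preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeParseError(f"cannot parse Newick file {path}: {exc}") from None
    return PhyloTree.from_dendropy(dtree)


def parse_tree_string(newick: str) -> PhyloTree:
    import dendropy

    try:
        dtree = dendropy.Tree.get(data=newick, schema="newick",
                                  suppress_internal_node_taxa=False,
                                  preserve_underscores=True)
    except Exception as exc:
        raise TreeParseError(f"cannot parse Newick string: {exc}") from None
    return PhyloTree.from_dendropy(dtree)


def write_tree(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

NEAR_LOOP = "near-loop"
NEAR_BULGE = "near-bulge"
OTHER = "other"

#: unpaired runs up to this length count as bulges when no REGION labels are given
_BULGE_MAX_RUN = 2


@dataclass
class SecondaryStructure:
    """Pair table plus helix/loop region annotation for one consensus structure.

    ``pair_table[k]`` is the 0-based partner of site k, or -1 when unpaired.
    """

    pair_table: np.ndarray
    region_of_site: list[str | None]

    def __post_init__(self) -> None:
        self.pair_table = np.asarray(self.pair_table, dtype=np.int64)
        pt = self.pair_table
        paired = np.flatnonzero(pt >= 0)
        if np.any(pt[paired] == paired):
            raise StructureParseError("site paired to itself")
        if not np.all(pt[pt[paired]] == paired):
            raise StructureParseError("pair table is not an involution")
        self.position_class = self._position_classes()

    @property
    def n_sites(self) -> int:
        return self.pair_table.size

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """0-based (i, j) with i < j, 5'-to-3' order."""
        return [(i, int(j)) for i, j in enumerate(self.pair_table) if 0 <= i < j]

    def helix_of(self, site: int) -> str | None:
        reg = self.region_of_site[site]
        if reg is not None and reg.upper() in {"I", "II", "III", "IV", "V"}:
            return reg.upper()
        return None

    def _position_classes(self) -> list[str | None]:
        """Near-loop / near-bulge / other for every paired site.

        A paired site is "near" when it or its partner sits next to (sequence
        distance 1) an unpaired site.  The flavour comes from the neighbouring
        unpaired region's label when present, else from the run length of the
        unpaired stretch.
        """
        pt = self.pair_table
        n = pt.size
        run_id = np.full(n, -1)
        runs: list[tuple[int, int]] = []
        k = 0
        while k < n:
            if pt[k] < 0:
                start = k
                while k < n and pt[k] < 0:
                    run_id[k] = len(runs)
                    k += 1
                runs.append((start, k - 1))
            else:
                k += 1

        def neighbour_kind(site: int) -> str | None:
            kinds = []
            for nb in (site - 1, site + 1):
                if 0 <= nb < n and pt[nb] < 0:
                    reg = self.region_of_site[nb]
                    if reg is not None:
                        kinds.append(NEAR_BULGE if reg.lower() == "bulge" else NEAR_LOOP)
                    else:
                        a, b = runs[run_id[nb]]
                        kinds.append(NEAR_BULGE if b - a + 1 <= _BULGE_MAX_RUN else NEAR_LOOP)
            if not kinds:
                return None
            # loop adjacency dominates: breaking the pair would enlarge the loop
            return NEAR_LOOP if NEAR_LOOP in kinds else NEAR_BULGE

        out: list[str | None] = [None] * n
        for site in range(n):
            if pt[site] < 0:
                continue
            kind = neighbour_kind(site) or neighbour_kind(int(pt[site]))
            out[site] = kind if kind is not None else OTHER
        return out

    @classmethod
    def from_dotbracket(cls, db: str,
                        regions: list[tuple[int, int, str]] | None = None
                        ) -> "SecondaryStructure":
        pt = pair_table_from_dotbracket(db)
        region: list[str | None] = [None] * len(db)
        if regions:
            claimed = np.zeros(len(db), dtype=bool)
            for start, end, label in regions:
                if not (1 <= start <= end <= len(db)):
                    raise AnnotationError(f"REGION {start} {end} out of range 1..{len(db)}")
                sl = slice(start - 1, end)
                if claimed[sl].any():
                    raise AnnotationError(f"REGION {start} {end} {label} overlaps a previous region")
                claimed[sl] = True
                for k in range(start - 1, end):
                    region[k] = label
        return cls(pt, region)


def pair_table_from_dotbracket(db: str) -> np.ndarray:
    pt = np.full(len(db), -1, dtype=np.int64)
    stack: list[int] = []
    for k, ch in enumerate(db):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            if not stack:
                raise StructureParseError(f"unbalanced ')' at site {k + 1}")
            i = stack.pop()
            pt[i], pt[k] = k, i
        elif ch != ".":
            raise StructureParseError(f"illegal structure character {ch!r} at site {k + 1}")
    if stack:
        raise StructureParseError(f"unbalanced '(' at site {stack[-1] + 1}")
    return pt


def dotbracket_from_pair_table(pt: np.ndarray) -> str:
    out = []
    for i, j in enumerate(pt):
        out.append("." if j < 0 else ("(" if i < j else ")"))
    return "".join(out)


def read_structure(path) -> SecondaryStructure:
    """Read a dot-bracket file with optional REGION annotation lines."""
    db = None
    regions: list[tuple[int, int, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith(">"):
                continue
            if line.upper().startswith("REGION"):
                parts = line.split()
                if len(parts) != 4:
                    raise AnnotationError(f"malformed REGION line: {line!r}")
                regions.append((int(parts[1]), int(parts[2]), parts[3]))
            elif db is None:
                db = line
            else:
                raise StructureParseError("multiple dot-bracket lines in structure file")
    if db is None:
        raise StructureParseError(f"no dot-bracket line in {path}")
    return SecondaryStructure.from_dotbracket(db, regions)


def write_structure(ss: SecondaryStructure, path) -> None:
    with open(path, "w") as fh:
        fh.write(dotbracket_from_pair_table(ss.pair_table) + "\n")
        k = 0
        n = ss.n_sites
        while k < n:
            lab = ss.region_of_site[k]
            if lab is None:
                k += 1
                continue
            start = k
            while k < n and ss.region_of_site[k] == lab:
                k += 1
            fh.write(f"REGION {start + 1} {k} {lab}\n")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    """Serialize a result table as TSV with a header, stable column order."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def table_to_string(df: pd.DataFrame) -> str:
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()
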