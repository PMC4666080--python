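"""Secondary structure and elastic-network connectivity.

A secondary structure is a set of double-helical regions (maximal ungapped
stacks of base pairs) plus the complementary unpaired runs (loops).  The
elastic network connects, inside every helix, each bead to its first, second
and third strand neighbours (connectivity, bending, torsion), to its paired
counterpart, and to the counterpart's first neighbours; loop and hinge beads
carry only their two strand-neighbour springs.  All springs share one force
constant.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .params import ModelParameters, DEFAULT_PARAMS

__all__ = [
    "Helix",
    "SecondaryStructure",
    "Spring",
    "SpringNetwork",
    "ParseError",
    "UnsupportedFeatureError",
    "InvalidTopologyError",
    "GeometryInconsistencyError",
    "parse_dot_bracket",
    "build_spring_network",
    "assign_equilibrium_lengths",
    "read_helix_table",
    "write_helix_table",
]

_BRACKETS = {"(": ")", "[": "]", "{": "}"}
_CLOSERS = {v: k for k, v in _BRACKETS.items()}

SPRING_KINDS = ("backbone", "bend", "torsion", "basepair", "cross", "loop")


class ParseError(ValueError):
    """Malformed dot-bracket input."""


class UnsupportedFeatureError(ValueError):
    """Structurally valid input outside the supported model class."""


class InvalidTopologyError(ValueError):
    """Secondary structure that cannot yield a valid spring network."""


class GeometryInconsistencyError(ValueError):
    """Reference geometry incompatible with the spring network."""


@dataclass(frozen=True)
class Helix:
    """One double-helical region in 1-based inclusive strand coordinates.

    Segment A (``a_start..a_end``) runs 5'->3'; segment B
    (``b_start..b_end``) is antiparallel, so residue ``a_start`` pairs with
    ``b_end`` and ``a_end`` with ``b_start``.
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.a_start <= self.a_end < self.b_start <= self.b_end):
            raise InvalidTopologyError(
                f"helix segments must satisfy a_start<=a_end<b_start<=b_end, "
                f"got {(self.a_start, self.a_end, self.b_start, self.b_end)}"
            )
        if self.a_end - self.a_start != self.b_end - self.b_start:
            raise InvalidTopologyError("helix segments must have equal length")

    @property
    def n_bp(self) -> int:
        return self.a_end - self.a_start + 1

    def pairs(self) -> list[tuple[int, int]]:
        """Base pairs as 1-based (i, j) tuples with i < j."""
        return [
            (self.a_start + k, self.b_end - k) for k in range(self.n_bp)
        ]


@dataclass
class SecondaryStructure:
    """Strand length plus helix/loop segmentation."""

    n_residues: int
    helices: list[Helix]

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise InvalidTopologyError("n_residues must be positive")
        seen: set[int] = set()
        for h in self.helices:
            if h.n_bp < 1:
                raise InvalidTopologyError("helix with N_bp < 1")
            for seg in (range(h.a_start, h.a_end + 1), range(h.b_start, h.b_end + 1)):
                for r in seg:
                    if not 1 <= r <= self.n_residues:
                        raise InvalidTopologyError(
                            f"residue {r} outside strand of length {self.n_residues}"
                        )
                    if r in seen:
                        raise InvalidTopologyError(f"residue {r} in two helices")
                    seen.add(r)

    @property
    def n_helices(self) -> int:
        return len(self.helices)

    def pair_table(self) -> np.ndarray:
        """0-based partner array: ``pt[i] = j`` if i pairs j, else -1."""
        pt = np.full(self.n_residues, -1, dtype=np.int64)
        for h in self.helices:
            for i, j in h.pairs():
                pt[i - 1] = j - 1
                pt[j - 1] = i - 1
        return pt

    def loops(self) -> list[tuple[int, int]]:
        """Maximal unpaired runs as 0-based inclusive (start, end) tuples."""
        pt = self.pair_table()
        runs: list[tuple[int, int]] = []
        i = 0
        while i < self.n_residues:
            if pt[i] < 0:
                j = i
                while j + 1 < self.n_residues and pt[j + 1] < 0:
                    j += 1
                runs.append((i, j))
                i = j + 1
            else:
                i += 1
        return runs

    def helix_of(self) -> np.ndarray:
        """0-based helix index per residue, -1 for unpaired residues."""
        out = np.full(self.n_residues, -1, dtype=np.int64)
        for k, h in enumerate(self.helices):
            out[h.a_start - 1 : h.a_end] = k
            out[h.b_start - 1 : h.b_end] = k
        return out

    def loop_faces(self) -> list[dict]:
        """Decompose the unpaired regions into structural faces.

        Each face is the set of unpaired residues (0-based) lying on one
        loop of the secondary-structure graph, classified as ``hairpin``
        (closed by one helix), ``internal`` (between two helices: internal
        loop or bulge), ``multiloop`` (junction of three or more helices —
        the hinge) or ``exterior`` (5'/3' tails and inter-domain links).
        """
        pt = self.pair_table()
        by_outer = {h.a_start - 1: h for h in self.helices}
        faces: list[dict] = []

        def scan(lo: int, hi: int, entry: Helix | None) -> None:
            beads: list[int] = []
            n_child = 0
            k = lo
            while k <= hi:
                if pt[k] < 0:
                    beads.append(k)
                    k += 1
                else:
                    h = by_outer[k]
                    n_child += 1
                    scan(h.a_end, h.b_start - 2, h)
                    k = h.b_end
            if entry is None:
                kind = "exterior"
            elif n_child == 0:
                kind = "hairpin"
            elif n_child == 1:
                kind = "internal"
            else:
                kind = "multiloop"
            faces.append({"kind": kind, "beads": beads, "entry": entry,
                          "n_helices": n_child + (0 if entry is None else 1)})

        scan(0, self.n_residues - 1, None)
        return faces

    def to_dot_bracket(self) -> str:
        chars = ["."] * self.n_residues
        for h in self.helices:
            for i, j in h.pairs():
                chars[i - 1] = "("
                chars[j - 1] = ")"
        return "".join(chars)


@dataclass(frozen=True)
class Spring:
    """Harmonic connector between beads ``i`` and ``j`` (0-based, i < j)."""

    i: int
    j: int
    kind: str
    l_e: float = float("nan")  # A; NaN until assigned from a reference geometry
    H: float = float("nan")    # kBT/A^2

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise InvalidTopologyError(f"self-spring on bead {self.i}")
        if self.i > self.j:
            raise InvalidTopologyError("spring indices must satisfy i < j")
        if self.i < 0:
            raise InvalidTopologyError("negative bead index")
        if self.kind not in SPRING_KINDS:
            raise InvalidTopologyError(f"unknown spring kind {self.kind!r}")


@dataclass
class SpringNetwork:
    """The elastic network: typed springs over ``n_beads`` beads."""

    n_beads: int
    springs: list[Spring]

    def __post_init__(self) -> None:
        pairs = [(s.i, s.j) for s in self.springs]
        if len(pairs) != len(set(pairs)):
            raise InvalidTopologyError("duplicate spring pair")
        for s in self.springs:
            if s.j >= self.n_beads:
                raise InvalidTopologyError(f"spring bead {s.j} out of range")

    def pair_set(self) -> set[tuple[int, int]]:
        return {(s.i, s.j) for s in self.springs}

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(i, j, l_e, H) arrays in a stable order for the simulation kernels."""
        order = sorted(range(len(self.springs)), key=lambda k: (self.springs[k].i, self.springs[k].j))
        i = np.array([self.springs[k].i for k in order], dtype=np.int64)
        j = np.array([self.springs[k].j for k in order], dtype=np.int64)
        le = np.array([self.springs[k].l_e for k in order])
        hh = np.array([self.springs[k].H for k in order])
        return i, j, le, hh

    def is_connected(self) -> bool:
        if self.n_beads == 1:
            return True
        adj: list[list[int]] = [[] for _ in range(self.n_beads)]
        for s in self.springs:
            adj[s.i].append(s.j)
            adj[s.j].append(s.i)
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return len(seen) == self.n_beads

    def to_frame(self) -> pd.DataFrame:
        i, j, le, hh = self.as_arrays()
        kinds = [s.kind for s in sorted(self.springs, key=lambda s: (s.i, s.j))]
        return pd.DataFrame({"i": i, "j": j, "kind": kinds, "l_e": le, "H": hh})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _pair_list_from_dot_bracket(text: str) -> list[tuple[int, int]]:
    stacks: dict[str, list[int]] = {k: [] for k in _BRACKETS}
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(text):
        if ch == ".":
            continue
        if ch in _BRACKETS:
            stacks[ch].append(pos)
        elif ch in _CLOSERS:
            opener = _CLOSERS[ch]
            if not stacks[opener]:
                raise ParseError(f"unbalanced {ch!r} at position {pos + 1}")
            pairs.append((stacks[opener].pop(), pos))
        else:
            raise ParseError(f"illegal character {ch!r} at position {pos + 1}")
    for opener, stack in stacks.items():
        if stack:
            raise ParseError(f"unbalanced {opener!r} at position {stack[-1] + 1}")
    return sorted(pairs)


def _pairs_cross(p: tuple[int, int], q: tuple[int, int]) -> bool:
    (a, b), (c, d) = p, q
    return (a < c < b < d) or (c < a < d < b)


def parse_dot_bracket(text: str) -> SecondaryStructure:
    """Parse a dot-bracket string into helices and loops.

    Helices are maximal stacks of consecutively nested pairs; a bulge or
    internal loop of one or more nucleotides on either strand terminates a
    helix.  Multiple bracket alphabets ``()[]{}`` are accepted, but only
    nested (pseudoknot-free) pairings are supported.
    """
    text = "".join(text.split())
    if not text:
        raise ParseError("empty structure string")
    pairs = _pair_list_from_dot_bracket(text)
    for a in range(len(pairs)):
        for b in range(a + 1, len(pairs)):
            if _pairs_cross(pairs[a], pairs[b]):
                raise UnsupportedFeatureError(
                    f"pseudoknotted pairing {pairs[a]} x {pairs[b]} is not supported"
                )
    # group consecutively stacked pairs into helices
    helices: list[Helix] = []
    pairs_set = set(pairs)
    used: set[tuple[int, int]] = set()
    for p in pairs:
        if p in used:
            continue
        i, j = p
        run = [p]
        while (i + 1, j - 1) in pairs_set:
            i, j = i + 1, j - 1
            run.append((i, j))
        used.update(run)
        a0, b1 = run[0]
        a1, b0 = run[-1]
        helices.append(Helix(a0 + 1, a1 + 1, b0 + 1, b1 + 1))
    return SecondaryStructure(n_residues=len(text), helices=helices)


def read_helix_table(source) -> SecondaryStructure:
    """Read a TSV helix table (name, a_start, a_end, b_start, b_end; 1-based).

    The strand length is taken from an ``# n_residues = N`` comment line if
    present, otherwise from the largest coordinate in the table.
    """
    if hasattr(source, "read"):
        raw = source.read()
    else:
        with open(source) as fh:
            raw = fh.read()
    n_residues = None
    for line in raw.splitlines():
        if line.startswith("#") and "n_residues" in line:
            n_residues = int(line.split("=")[1])
    df = pd.read_csv(io.StringIO(raw), sep="\t", comment="#")
    helices = [
        Helix(int(r.a_start), int(r.a_end), int(r.b_start), int(r.b_end), str(r.name))
        for r in df.itertuples(index=False)
    ]
    if n_residues is None:
        n_residues = max(h.b_end for h in helices) if helices else 1
    return SecondaryStructure(n_residues=n_residues, helices=helices)


def write_helix_table(ss: SecondaryStructure, path) -> None:
    df = pd.DataFrame(
        [
            {"name": h.name or f"H{k + 1}", "a_start": h.a_start, "a_end": h.a_end,
             "b_start": h.b_start, "b_end": h.b_end}
            for k, h in enumerate(ss.helices)
        ],
        columns=["name", "a_start", "a_end", "b_start", "b_end"],
    )
    with open(path, "w") as fh:
        fh.write(f"# n_residues = {ss.n_residues}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_spring_network(
    ss: SecondaryStructure,
    params: ModelParameters = DEFAULT_PARAMS,
    junction_stiffening: bool = True,
) -> SpringNetwork:
    """Construct the elastic network for a secondary structure.

    Within every helix (local indices 0..N_bp-1 on segment A, with the
    counterpart of local bead ``k`` at local index ``k + N_bp``) each bead is
    connected to its first, second and third neighbours along its own helix
    piece, to its counterpart, and to the counterpart's first neighbours.
    These rules are truncated at helix boundaries.  Every strand-consecutive
    bead pair not already sprung (loops, hinges, helix/loop joints) receives
    a backbone spring, which keeps the chain a single connected component.

    Loop beads (hairpin and internal loops) carry only their two
    first-neighbour springs.  With ``junction_stiffening`` (the default),
    unpaired beads of multibranch junctions and exterior tails — the hinge
    region — are treated as strand continuation and also receive second-
    and third-neighbour (bending/torsion) springs, which preserves the
    built arrangement of the arms around the hinge; without it the hinge
    obeys the loop rule and the junction is fully flexible.

    Equilibrium lengths are left unset (NaN); see
    :func:`assign_equilibrium_lengths`.
    """
    H = params.spring_H
    springs: dict[tuple[int, int], Spring] = {}

    def add(i: int, j: int, kind: str) -> None:
        if i > j:
            i, j = j, i
        key = (i, j)
        if key not in springs:  # first rule to claim a pair names its kind
            springs[key] = Spring(i, j, kind, H=H)

    for h in ss.helices:
        if h.n_bp < 1:
            raise InvalidTopologyError("helix with N_bp < 1")
        n = h.n_bp
        # local -> 0-based strand index
        seg_a = [h.a_start - 1 + k for k in range(n)]          # local 0..n-1
        seg_b = [h.b_end - 1 - k for k in range(n)]            # local n..2n-1, pairs seg_a[k]
        local = seg_a + seg_b

        def intra(piece_offset: int, k: int, dk: int, kind: str) -> None:
            if 0 <= k + dk < n:
                add(local[piece_offset + k], local[piece_offset + k + dk], kind)

        for k in range(n):
            for off in (0, n):  # both helix pieces
                intra(off, k, 1, "backbone")   # rule (a)
                intra(off, k, 2, "bend")       # rule (b)
                intra(off, k, 3, "torsion")    # rule (c)
            add(local[k], local[k + n], "basepair")            # rule (d)
            for dk in (-1, 1):                                 # rule (e)
                if 0 <= k + dk < n:
                    add(local[k], local[n + k + dk], "cross")

    # strand connectivity across loops, hinges and helix boundaries
    for k in range(ss.n_residues - 1):
        add(k, k + 1, "backbone")

    if junction_stiffening and ss.helices:
        hinge = set()
        for face in ss.loop_faces():
            if face["kind"] in ("multiloop", "exterior"):
                hinge.update(face["beads"])
        for k in sorted(hinge):
            for dk, kind in ((2, "bend"), (3, "torsion")):
                for j in (k - dk, k + dk):
                    if 0 <= j < ss.n_residues:
                        add(k, j, kind)

    net = SpringNetwork(n_beads=ss.n_residues, springs=list(springs.values()))
    if not net.is_connected():
        raise InvalidTopologyError("spring network is not a single component")
    return net


def assign_equilibrium_lengths(
    net: SpringNetwork,
    ref_coords: np.ndarray,
    params: ModelParameters = DEFAULT_PARAMS,
) -> SpringNetwork:
    """Set each spring's equilibrium length from a reference conformation.

    ``ref_coords`` must hold the ideal-geometry build, so helix springs
    acquire their A-form distances and loop backbone springs come out at
    ``l_e1 = 2 sigma`` (touching beads).
    """
    coords = np.asarray(ref_coords, dtype=float)
    if coords.shape != (net.n_beads, 3):
        raise GeometryInconsistencyError(
            f"reference coordinates shape {coords.shape} != ({net.n_beads}, 3)"
        )
    out: list[Spring] = []
    lmax = 5.0 * params.l_e1
    for s in net.springs:
        le = float(np.linalg.norm(coords[s.j] - coords[s.i]))
        if not (0.0 < le <= lmax):
            raise GeometryInconsistencyError(
                f"spring ({s.i},{s.j}) has reference length {le:.2f} A "
                f"outside (0, {lmax:.2f}]"
            )
        out.append(Spring(s.i, s.j, s.kind, l_e=le, H=s.H))
    return SpringNetwork(n_beads=net.n_beads, springs=out)
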