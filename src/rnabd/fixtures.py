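"""Built-in study systems.

``trna_phe``
    Yeast phenylalanine tRNA, 76 nt, the classic cloverleaf: acceptor stem
    (7 bp), D stem (4 bp), anticodon stem (5 bp), T stem (5 bp), three
    hairpin loops, a multibranch hinge and the 3' NCCA tail.  Pairing
    follows the standard cloverleaf of the 1EHZ crystal structure.

``5s_rrna``
    E. coli 5S ribosomal RNA, 120 nt, five double helices arranged as a
    three-way hinge: helix I closes the molecule; helices II-III (with an
    internal loop and a hairpin) form one arm, helices IV-V the other.
    The exact per-residue ranges are a consensus encoding modelled on the
    1C2X chain C secondary structure; small differences from any particular
    literature table shift the solution properties only within their
    sampling uncertainty.
"""

from __future__ import annotations

from .analysis import ArmDefinition
from .topology import Helix, SecondaryStructure

__all__ = ["FIXTURES", "load_fixture", "trna_arms"]

_TRNA_HELICES = [
    Helix(1, 7, 66, 72, "acceptor stem"),
    Helix(10, 13, 22, 25, "D stem"),
    Helix(27, 31, 39, 43, "anticodon stem"),
    Helix(49, 53, 61, 65, "T stem"),
]

_5S_HELICES = [
    Helix(1, 10, 110, 119, "helix I"),
    Helix(16, 23, 60, 67, "helix II"),
    Helix(28, 34, 46, 52, "helix III"),
    Helix(80, 86, 91, 97, "helix IV"),
    Helix(70, 77, 100, 107, "helix V"),
]

FIXTURES = {
    "trna_phe": (76, _TRNA_HELICES),
    "5s_rrna": (120, _5S_HELICES),
}


def trna_arms() -> ArmDefinition:
    """Acceptor-stem and anticodon-stem bead lists (0-based), ordered from
    the hinge-proximal end of each stem to its tip."""
    acceptor = []
    for k in range(7):  # inner pair (residues 7:66) first, CCA end last
        acceptor += [6 - k, 65 + k]
    anticodon = []
    for k in range(5):  # multiloop side (residues 27:43) first
        anticodon += [26 + k, 42 - k]
    return ArmDefinition(stem_a=tuple(acceptor), stem_b=tuple(anticodon))


def load_fixture(name: str):
    """Return ``(SecondaryStructure, ArmDefinition or None)`` for a fixture."""
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    n, helices = FIXTURES[name]
    ss = SecondaryStructure(n_residues=n, helices=list(helices))
    arms = trna_arms() if name == "trna_phe" else None
    return ss, arms
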