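"""Ideal A-form duplex coordinates and initial-conformation assembly.

The initial build places every helix as a rigid ideal A-form duplex and
every loop on a circular arc of touching beads (chord spacing ``l_e1``),
arranged by a recursive radial layout: each loop is a circle whose boundary
carries its unpaired beads and the attachment chords of its helices, and
each helix extends radially away from its parent loop toward its child
loop.  The layout only has to be topologically faithful and clash-free;
equilibrium properties come from trajectory averages after equilibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import ModelParameters, DEFAULT_PARAMS
from .topology import Helix, SecondaryStructure

__all__ = ["Conformation", "BuildError", "build_a_form_duplex",
           "assemble_initial_conformation"]


class BuildError(RuntimeError):
    """Initial-conformation assembly failure."""


@dataclass
class Conformation:
    """N x 3 bead-centre coordinates in Angstrom."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Conformation":
        return Conformation(self.coords.copy())


def build_a_form_duplex(
    n_bp: int, params: ModelParameters = DEFAULT_PARAMS
) -> Conformation:
    """Ideal right-handed A-form duplex with local helix indexing.

    Bead ``k`` of segment A sits at cylindrical position
    ``(r, k*twist, k*rise)``; its counterpart (local index ``k + n_bp``)
    sits at the same axial height, offset azimuthally by the phase angle.
    """
    if n_bp < 1:
        raise ValueError("n_bp must be >= 1")
    r = params.helix_radius
    phi = math.radians(params.phase_angle)
    k = np.arange(n_bp)
    theta = k * params.twist_per_bp
    z = k * params.rise
    seg_a = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    seg_b = np.column_stack([r * np.cos(theta + phi), r * np.sin(theta + phi), z])
    return Conformation(np.vstack([seg_a, seg_b]))


# ---------------------------------------------------------------------------
# loop-circle machinery
# ---------------------------------------------------------------------------

def _chord_angles(chords: np.ndarray) -> tuple[float, np.ndarray]:
    """Circle radius and per-edge central angles for a closed chord cycle.

    Solves ``sum_i alpha_i(R) = 2 pi`` where every chord subtends its minor
    arc, or — when the cycle cannot close that way (short hairpins) — with
    the largest chord subtending its reflex (major) arc.
    """
    chords = np.asarray(chords, dtype=float)
    m = len(chords)
    if m < 3:
        raise BuildError("loop cycle needs at least three edges")
    imax = int(np.argmax(chords))
    cmax = chords[imax]
    r_min = cmax / 2.0

    def f_minor(R: float) -> float:
        return 2.0 * np.sum(np.arcsin(np.clip(chords / (2.0 * R), -1, 1))) - 2 * np.pi

    if f_minor(r_min) >= 0.0:
        hi = r_min
        while f_minor(hi) > 0:
            hi *= 2.0
        R = brentq(lambda x: f_minor(x), r_min, hi, xtol=1e-12)
        alphas = 2.0 * np.arcsin(chords / (2.0 * R))
        return R, alphas

    # reflex mode: the largest chord takes the major arc
    rest = np.delete(chords, imax)
    if rest.sum() <= cmax + 1e-9:
        raise BuildError(
            "loop arc cannot close: boundary path shorter than the helix "
            "width it must span (loop too short)"
        )

    def g(R: float) -> float:
        return (2.0 * np.sum(np.arcsin(np.clip(rest / (2.0 * R), -1, 1)))
                - 2.0 * np.arcsin(min(cmax / (2.0 * R), 1.0)))

    lo, hi = r_min, r_min
    found = False
    for _ in range(200):
        hi *= 1.2
        if g(lo) == 0.0:
            hi = lo
            found = True
            break
        if g(lo) * g(hi) < 0:
            found = True
            break
        lo = hi
    if not found:
        raise BuildError("loop arc closure failed; consider a larger arc radius")
    R = brentq(g, lo, hi, xtol=1e-12) if hi > lo else lo
    alphas = 2.0 * np.arcsin(np.clip(chords / (2.0 * R), -1, 1))
    alphas[imax] = 2.0 * np.pi - alphas[imax]
    return R, alphas


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise BuildError("zero-length direction in layout")
    return v / n


def _rotation_from_frames(e1l, e3l, e1g, e3g) -> np.ndarray:
    """Proper rotation mapping local frame (e1, e3x e1, e3) onto global."""
    bl = np.column_stack([e1l, np.cross(e3l, e1l), e3l])
    bg = np.column_stack([e1g, np.cross(e3g, e1g), e3g])
    return bg @ bl.T


# ---------------------------------------------------------------------------
# secondary-structure tree
# ---------------------------------------------------------------------------

class _LoopNode:
    """Elements (0-based bead index or child Helix) in strand order."""

    def __init__(self, entry: Helix | None):
        self.entry = entry
        self.elements: list[object] = []


def _build_tree(ss: SecondaryStructure) -> tuple[_LoopNode, dict[int, _LoopNode]]:
    by_outer = {h.a_start - 1: h for h in ss.helices}
    pt = ss.pair_table()
    children: dict[int, _LoopNode] = {}

    def scan(lo: int, hi: int, node: _LoopNode) -> None:
        k = lo
        while k <= hi:
            if pt[k] < 0:
                node.elements.append(k)
                k += 1
            else:
                h = by_outer.get(k)
                if h is None:  # paired but not a helix 5' end: topology error
                    raise BuildError(f"stray pairing at residue {k + 1}")
                node.elements.append(h)
                child = _LoopNode(h)
                children[id(h)] = child
                scan(h.a_end, h.b_start - 2, child)
                k = h.b_end

    root = _LoopNode(None)
    scan(0, ss.n_residues - 1, root)
    return root, children


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_initial_conformation(
    ss: SecondaryStructure,
    params: ModelParameters = DEFAULT_PARAMS,
    seed: int = 0,
) -> Conformation:
    """Build a clash-free initial conformation for a secondary structure.

    Deterministic given ``seed``: attempt 0 is the clean planar-star layout;
    if any two beads come closer than ``0.8 * l_e1`` the loop planes are
    tilted by small seeded random angles and the layout is retried (up to
    500 attempts).
    """
    rng = np.random.default_rng(seed)
    last_min = np.inf
    for attempt in range(500):
        tilt = 0.0 if attempt == 0 else 0.03 * min(attempt, 10)
        coords = _layout_once(ss, params, rng, tilt)
        dmin = _min_pair_distance(coords)
        if dmin >= 0.8 * params.l_e1:
            return Conformation(coords)
        last_min = min(last_min, dmin)
    raise BuildError(
        f"could not place all beads without clashes after 500 attempts "
        f"(closest approach {last_min:.2f} A); consider a larger arc radius"
    )


def _min_pair_distance(coords: np.ndarray) -> float:
    from scipy.spatial.distance import pdist

    if coords.shape[0] < 2:
        return np.inf
    return float(pdist(coords).min())


def _layout_once(
    ss: SecondaryStructure,
    params: ModelParameters,
    rng: np.random.Generator,
    tilt: float,
) -> np.ndarray:
    le1 = params.l_e1
    w = params.duplex_width
    root, children = _build_tree(ss)
    coords = np.full((ss.n_residues, 3), np.nan)

    def place_helix(h: Helix, g1: np.ndarray, g2: np.ndarray, u: np.ndarray) -> None:
        """Place duplex with outer attachments (a_start, b_end) at g1, g2."""
        n = h.n_bp
        local = build_a_form_duplex(n, params).coords
        a0, b0 = local[0], local[n]           # outer attachment pair, local
        e1l = _unit(b0 - a0)
        e3l = np.array([0.0, 0.0, 1.0])
        e1g = _unit(g2 - g1)
        rot = _rotation_from_frames(e1l, e3l, e1g, _unit(u))
        shift = 0.5 * (g1 + g2) - rot @ (0.5 * (a0 + b0))
        glob = local @ rot.T + shift
        seg_a = np.arange(h.a_start - 1, h.a_end)
        seg_b = np.arange(h.b_end - 1, h.b_start - 2, -1)  # local order n..2n-1
        coords[seg_a] = glob[:n]
        coords[seg_b] = glob[n:]
        # child loop beyond the inner end (blunt duplex end: nothing to place)
        child = children[id(h)]
        if child.elements:
            gi1 = coords[h.a_end - 1]
            gi2 = coords[h.b_start - 1]
            axis = _unit(rot @ e3l)
            place_loop(child, gi1, gi2, axis)

    def place_loop(node: _LoopNode, g1, g2, u) -> None:
        """Place a loop whose entry chord endpoints g1 (5') and g2 (3') and
        outward direction u are fixed by the parent helix."""
        # boundary cycle: entry chord, then elements from g1 side to g2 side
        pts: list[object] = ["entry_a"]
        edges: list[float] = []
        for el in node.elements:
            if isinstance(el, Helix):
                edges.append(le1)
                pts.append(("ha", el))
                edges.append(w)
                pts.append(("hb", el))
            else:
                edges.append(le1)
                pts.append(el)
        edges.append(le1)
        pts.append("entry_b")
        edges.append(w)  # closing entry chord back to entry_a
        R, alphas = _chord_angles(np.array(edges))
        alpha_close = alphas[-1]

        ghat = _unit(g2 - g1)
        p_hat = _unit(u - np.dot(u, ghat) * ghat)
        if tilt:
            ang = rng.uniform(-tilt, tilt)
            p_hat = _unit(math.cos(ang) * p_hat + math.sin(ang) * np.cross(ghat, p_hat))
        mid = 0.5 * (g1 + g2)
        d = math.sqrt(max(R * R - 0.25 * np.dot(g2 - g1, g2 - g1), 0.0))
        side = 1.0 if alpha_close <= np.pi else -1.0
        center = mid + side * d * p_hat
        e1 = _unit(g1 - center)
        n_hat = _unit(np.cross(ghat, p_hat))
        target = (2.0 * np.pi - alpha_close) % (2.0 * np.pi)
        v2 = g2 - center
        e2 = None
        for sgn in (1.0, -1.0):
            cand = sgn * np.cross(n_hat, e1)
            ang2 = math.atan2(np.dot(v2, cand), np.dot(v2, e1)) % (2.0 * np.pi)
            if abs(ang2 - target) < 1e-6 or abs(ang2 - target) > 2 * np.pi - 1e-6:
                e2 = cand
                break
        if e2 is None:
            raise BuildError("loop circle orientation failed")

        theta = 0.0
        positions: dict[object, np.ndarray] = {}
        for edge, tag in zip(alphas[:-1], pts[1:]):
            theta += edge
            positions[tag] = center + R * (math.cos(theta) * e1 + math.sin(theta) * e2)
        # assign bead positions and recurse into child helices
        for el in node.elements:
            if isinstance(el, Helix):
                ga = positions[("ha", el)]
                gb = positions[("hb", el)]
                cm = 0.5 * (ga + gb)
                u_child = cm - center
                if np.linalg.norm(u_child) < 1e-9:
                    u_child = p_hat
                place_helix(el, ga, gb, _unit(u_child))
            else:
                coords[el] = positions[el]

    # ---- root: open exterior laid along a line ("clothesline") ----
    x = 0.0
    ux = np.array([1.0, 0.0, 0.0])
    uy = np.array([0.0, 1.0, 0.0])
    for el in root.elements:
        if isinstance(el, Helix):
            g1 = np.array([x, 0.0, 0.0])
            g2 = np.array([x + w, 0.0, 0.0])
            place_helix(el, g1, g2, uy)
            x += w + le1
        else:
            coords[el] = np.array([x, 0.0, 0.0])
            x += le1

    if np.isnan(coords).any():
        raise BuildError("layout left unplaced beads")
    return coords
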